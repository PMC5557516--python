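# Methods

## The merging model

`taxmerge` treats each classifier's per-sample output as a noisy,
incomplete observation of one underlying community and integrates N of
them per taxonomic rank, independently at each of the seven canonical
ranks (superkingdom, phylum, class, order, family, genus, species).

**Normalization.**  Tools differ in whether unclassified reads are
counted, so every input profile is first rescaled per rank so that
classified abundances sum to 100%.  Only classified mass is modelled.

**Co-occurrence score.**  For a taxon reported at a rank, `i` counts
reporting tools and `j` counts tool databases containing the taxon
(ancestor-closed, so a database holding a species also "contains" its
genus).  The score `S = (i+1)^2/(j+1)` measures corroboration relative
to opportunity: it is strictly increasing in `i`, strictly decreasing
in `j`, equals `i+1` on the diagonal, and therefore favours a taxon
reported by both of the only two databases covering it over a taxon
reported twice but present in six databases.  A tool reporting a taxon
absent from its own database profile still increments `i` but not `j`
(the two counts are kept independent; the case is logged as a likely
stale database profile).

**Abundance integration.**  The merged abundance of a taxon is the
harmonic mean of the reporting tools' normalized abundances.  The
harmonic mean is dominated by the smaller values, so one tool's gross
over-estimate barely moves it (hm(1, 100) ≈ 1.98 against an arithmetic
mean of 50.5).

**Bin filtering.**  Per rank, scores are divided into `B` equal-width
bins over the observed score range (top edge closed; a degenerate
all-equal range puts everything in the top bin, so filtering falls back
to a pure abundance percentile).  Within each bin, entries sorted by
descending integrated abundance keep the top `ceil(f * bin_size)`
entries, where `f = ((bin+1)/B)^k` and the exponent k is 3, 2, 1, 1/2,
1/3 for modes very-precise … very-sensitive.  The family is the
package's own choice of a one-parameter percentile schedule satisfying
the constraints the method requires — monotone non-decreasing per bin,
keep-everything in the top bin, uniformly ordered across the five
modes (which also guarantees nested survivor sets) — and it is
pluggable (`MergeConfig.mode_function`) so an alternative schedule can
be swapped in without touching the pipeline.  A minimum abundance
cutoff (default 1e-4 percentage points, i.e. one part in 10^6 of the
community) removes entries before the percentile rule, reflecting the
lowest abundance the user believes distinguishable from noise.
Survivors are re-normalized to 100% per rank; ranks are not forced to
be hierarchically consistent with one another (each rank is an
independent estimate).  Output ordering is deterministic (abundance
descending, then taxid), so runs are byte-reproducible.

## Binning-to-profile estimation

A binning tool's output (read id, assigned bases, taxon) is converted
by `abundance(n) = assigned_bases(n) / reference_length(n)`, where the
reference length comes from the tool's database profile; internal ranks
carry cumulative sums over descendants.  Database profiles store one
pooled reference length per taxon rather than per-sequence lengths;
summing bases before dividing by the pooled length differs from
summing per-reference ratios only when reference lengths within one
taxon are strongly skewed, and the per-rank normalization removes any
common scale, so the final profile is insensitive to this pooling for
all practical purposes.  Reads assigned directly to an internal taxon
(LCA-style binners) divide by that taxon's pooled ancestor-closed
length, which keeps the cumulative rule well defined.

## Taxonomy handling

All identifiers are resolved against one NCBI-style dump (nodes/names/
merged).  Stale ids are chased through merged redirects; unresolvable
entries are dropped with counted warnings rather than failing, because
real tool outputs contain ids from older taxonomy versions.  The rank
name "domain" is aliased to "superkingdom".  Sub-species entries
(strain, subspecies, no-rank below species) are projected up to their
species ancestor, since evaluation and most tools operate at species.
TAXPATH columns of input files are not trusted; lineages are always
recomputed from the dump.

## Synthetic ensembles

The generator emulates the regime the merge is designed for: a
log-normal community (location 0, scale 1.5 — a few dominant species
over a long tail) of 50 species; 6 tools; each tool's database covers a
species with probability 0.8; a covered species is reported with
probability 0.7 (so per-tool species sensitivity ≈ 0.56); reported
abundances carry multiplicative log-normal noise with CV 0.3
(mean-preserving); and each tool adds 15 false species, drawn from a
disjoint per-tool pool so false taxa essentially never co-occur, at
abundances uniform below the community's 10th percentile.  These
defaults are the package's reference study conditions; a `shared_fps`
flag makes the false pools common across tools to probe the merge's
failure mode (corroborated false positives).  Synthetic binning draws
reads multinomially proportional to abundance × reference length, so
the estimation step recovers the input profile up to multinomial noise.

What the generator does *not* model: sequence-level effects (read
errors, conserved regions, close genomes), correlated tool errors (two
k-mer classifiers confusing the same sibling species), or the huge
false-positive counts of real binning tools.  Passing tests therefore
demonstrate the correctness and qualitative behaviour of the merging
logic under its stated assumptions, not classifier accuracy on reads.

## Problem sizes and known behaviour

The replicated experiments use 20 seeds of the default ensemble
(140-species taxonomy, 6 tools); this is the package's reference
experiment size and runs in seconds.  Under these conditions the merged
profile beats the best single tool's species sensitivity in ~19/20
replicates and roughly quarters the species-level L1 abundance error
relative to a typical tool (20/20 replicates).  One behaviour is worth
stating plainly: because the percentile filter keeps a *fraction* of
each score bin, the number of surviving false positives scales with the
false-positive load of the lowest bin.  With all six synthetic tools
contributing 15 uncorroborated false species each (i=1, j=1, S=2, all
landing in the bottom bin), the default linear mode keeps ~25% of that
bin and the merged false-positive count comes out near — sometimes
above — the per-tool average of 15.  Precise modes cut that bin to a
few entries and reach precision ≈ 1.0 at a sensitivity cost; sensitive
modes keep more of it.  In mixed real-world ensembles, where binning
tools contribute orders of magnitude more false positives than
profilers, the merged count sits far below the tool average; with
uniformly low-FP tools the linear mode trades a handful of extra false
positives for its sensitivity gain.

## Numerical choices

Normalization tolerance 1e-9 per rank; profile files round abundances
to six decimals (round-trips are exact at that precision and
byte-stable from the second write onward); abundance ties in the
filter break by higher score then lower taxid; empty bins are skipped;
a bin with keep-fraction f > 0 always keeps at least one entry
(ceiling).  All randomness flows through `numpy.random.default_rng`
with explicit seeds; per-tool streams are seeded as `[seed, 2, tool]`
so tools are independent but reproducible.
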
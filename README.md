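# taxmerge

Ensemble merging of metagenomic taxonomic profiles.

Whole-metagenome shotgun samples are routinely profiled with several
taxonomic classifiers — profilers that report relative abundances
directly, and binning tools that assign every read to a taxon.  The
tools disagree: each has its own reference database, its own blind
spots, and its own tail of false identifications.  `taxmerge` integrates
the per-sample outputs of N such tools into a single enhanced profile,
for microbiome researchers who want to exploit the complementarity of
existing classifiers instead of trusting any single one.

## Method

For every taxon reported at a rank, two counts are collected: `i`, the
number of tools that reported it, and `j`, the number of tool reference
databases that contain it (so `j` is the number of *opportunities* to
report it).  The taxon's score is

```
S(i, j) = (i + 1)^2 / (j + 1)
```

which is high for taxa reported by most of the tools able to report
them, low for taxa present in many databases but rarely called, and
intentionally biased upward on the `i = j` diagonal (benefit of the
doubt for taxa covered by few databases).  Per rank, scores are split
into `B` equal-width bins (default 4); within each bin, taxa are sorted
by integrated abundance — the harmonic mean of the reporting tools'
normalized abundances, which damps single-tool outliers — and only the
top fraction of each bin survives.  That fraction is `x^k` with
`x = (bin+1)/B` and `k` set by the *mode*: `very-precise` (x³),
`precise` (x²), `linear` (x, default), `sensitive` (√x),
`very-sensitive` (∛x).  Survivors are re-normalized to 100% per rank.

Binning outputs are first converted to profiles: the abundance of taxon
*n* is the sum of bases assigned to *n* divided by the total reference
length of *n* in that tool's database, with internal ranks carrying the
cumulative sum over descendants.

## Worked example

```python
from taxmerge import MergeConfig, merge_profiles, evaluate
from taxmerge.synthetic import EnsembleSpec, generate_ensemble

ens = generate_ensemble(EnsembleSpec(seed=1))   # 50 species, 6 noisy tools
final, detailed = merge_profiles(ens.profiles, ens.dbprofiles,
                                 MergeConfig(mode="linear"), ens.tree)
m = evaluate(final, ens.truth).per_rank["species"]
best = max(evaluate(p.normalize(), ens.truth).per_rank["species"].sensitivity
           for p in ens.profiles)
print(f"merged sensitivity {m.sensitivity:.2f} vs best single tool {best:.2f}")
print(f"merged FP {m.fp}, L1 error {m.l1:.1f}")
```

prints

```
merged sensitivity 0.74 vs best single tool 0.72
merged FP 18, L1 error 22.0
```

i.e. the merged profile recovers more of the simulated community than
the best individual tool (each single tool finds only ~56% of species
because of database gaps and misses), and its abundance error (L1, the
sum of absolute abundance differences, 0–200 scale) is far below a
typical single tool's (~85–100 on this fixture).

The same pipeline runs from the shell on files — CAMI/BioBoxes
profiling and binning formats, NCBI-style taxonomy dumps — via the
`taxmerge` command (`merge`, `estimate`, `eval`, `generate`,
`subsample`, `dbprofile`); `taxmerge merge manifest.yaml` writes the
merged profile, a detailed per-taxon table (i, j, S, bin, per-tool
abundances), per-tool normalized profiles and a Krona-compatible text
export.

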
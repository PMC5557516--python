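"""Synthetic ensembles for testing the merge end to end without downloads.

The generator emulates the statistical structure the merge exploits in
real multi-classifier runs:

* a ground-truth community with log-normal species abundances (a few
  dominant species, a long low-abundance tail);
* per-tool reference databases covering only a random subset of the true
  species (database gaps bound attainable sensitivity);
* per-tool reports that miss some in-database species, perturb abundances
  with multiplicative log-normal noise, and add low-abundance false
  species largely unique to each tool — so true taxa co-occur across
  tools while false ones rarely do.

It does **not** emulate sequence-level effects (read errors, genome
similarity between close species), so passing tests demonstrate the
merge logic, not classifier accuracy on real reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_io import (
    BinningAssignment,
    BinningResult,
    DatabaseProfile,
    RankedProfile,
    _ancestor_close,
    write_database_profile,
    write_profile,
)
from .taxonomy import FIXED_RANKS, TaxonomyTree, write_taxonomy_dumps


@dataclass
class EnsembleSpec:
    """Study conditions for a synthetic multi-tool ensemble.

    ``db_coverage`` is the probability a true species is present in a
    tool's reference database; ``tool_sensitivity`` the probability a
    present-and-covered species is actually reported; ``fp_per_tool`` the
    number of false species each tool adds at low abundance.  Abundances
    are log-normal(``abundance_mu``, ``abundance_sigma``) and each tool
    perturbs them with multiplicative noise of coefficient of variation
    ``abundance_noise_cv``.  ``shared_fps`` makes the false species pool
    common to all tools, the merge's failure mode (false co-occurrence).
    """

    n_species: int = 50
    n_tools: int = 6
    db_coverage: float = 0.8
    tool_sensitivity: float = 0.7
    fp_per_tool: int = 15
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    abundance_noise_cv: float = 0.3
    seed: int = 0
    shared_fps: bool = False

    def __post_init__(self) -> None:
        for p in (self.db_coverage, self.tool_sensitivity):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.n_species, self.n_tools) < 1 or self.fp_per_tool < 0:
            raise ValueError("counts must be non-negative (tools/species >= 1)")


# -- taxonomy ------------------------------------------------------------


def generate_taxonomy(
    n_species: int, seed: int = 0, n_merged: int = 0
) -> TaxonomyTree:
    """Random seven-rank taxonomy with ``n_species`` species leaves.

    Node counts shrink geometrically toward the root and parents are
    sampled uniformly, so every species lineage carries all seven
    canonical ranks.  ``n_merged`` adds synthetic old-id redirects for
    exercising merged-id resolution.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {"species": n_species}
    shrink = {"genus": 3, "family": 2, "order": 2, "class": 2, "phylum": 2}
    prev = n_species
    for rank, factor in shrink.items():
        prev = max(1, math.ceil(prev / factor))
        counts[rank] = prev
    counts["superkingdom"] = min(2, counts["phylum"])

    parent: dict[int, int] = {1: 1}
    rank: dict[int, str] = {1: "no rank"}
    name: dict[int, str] = {1: "root"}
    next_id = 2
    ids_at: dict[str, list[int]] = {}
    for r in FIXED_RANKS:
        ids_at[r] = list(range(next_id, next_id + counts[r]))
        next_id += counts[r]
        above = ids_at[FIXED_RANKS[FIXED_RANKS.index(r) - 1]] if r != "superkingdom" else [1]
        for taxid in ids_at[r]:
            parent[taxid] = int(rng.choice(above))
            rank[taxid] = r
            name[taxid] = f"{r.capitalize()}_{taxid}"

    merged: dict[int, int] = {}
    if n_merged:
        species = ids_at["species"]
        for k in range(n_merged):
            merged[next_id + k] = int(rng.choice(species))
    return TaxonomyTree(parent=parent, rank=rank, name=name, merged=merged, root=1)


def species_leaves(tree: TaxonomyTree) -> list[int]:
    return sorted(t for t, r in tree.rank.items() if r == "species")


# -- community and tools --------------------------------------------------


def _propagate(species_abund: dict[int, float], tree: TaxonomyTree) -> RankedProfile:
    """Build a full ranked profile from species abundances by cumulative sums."""
    profile = RankedProfile()
    for taxid, ab in species_abund.items():
        for rank, ancestor in tree.lineage_at_ranks(taxid).items():
            profile.add(rank, ancestor, ab)
    return profile


def generate_truth(
    spec: EnsembleSpec, tree: TaxonomyTree, species: list[int] | None = None
) -> RankedProfile:
    """Ground-truth community: log-normal species abundances, normalized.

    Higher ranks are cumulative sums of their species descendants, each
    rank normalized to 100 independently.
    """
    rng = np.random.default_rng([spec.seed, 1])
    if species is None:
        leaves = species_leaves(tree)
        if len(leaves) < spec.n_species:
            raise ValueError("tree has fewer species than requested")
        species = [int(t) for t in rng.choice(leaves, spec.n_species, replace=False)]
    draws = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, len(species))
    truth = _propagate(dict(zip(species, draws)), tree).normalize()
    truth.tool_id = "truth"
    return truth


def simulate_tool(
    spec: EnsembleSpec,
    truth: RankedProfile,
    tool_index: int,
    tree: TaxonomyTree,
    fp_pool: list[int] | None = None,
) -> tuple[RankedProfile, DatabaseProfile]:
    """One tool's noisy report plus its database profile.

    The database covers a Bernoulli(``db_coverage``) subset of the true
    species plus this tool's false species; the report covers a
    Bernoulli(``tool_sensitivity``) subset of the covered truth, with
    multiplicative log-normal abundance noise, plus ``fp_per_tool`` false
    species at abundances below the 10th percentile of the truth.
    """
    if tool_index >= spec.n_tools:
        raise ValueError("tool_index out of range")
    rng = np.random.default_rng([spec.seed, 2, tool_index])
    tool_id = f"tool{tool_index}"
    true_species = sorted(truth.at("species"))
    true_ab = truth.at("species")

    if fp_pool is None:
        off = [t for t in species_leaves(tree) if t not in true_ab]
        if spec.shared_fps:
            fp_pool = off
        else:  # disjoint round-robin chunks so false taxa rarely co-occur
            fp_pool = off[tool_index :: spec.n_tools]
    n_fp = min(spec.fp_per_tool, len(fp_pool))
    fp_species = (
        [int(t) for t in rng.choice(fp_pool, n_fp, replace=False)] if n_fp else []
    )

    in_db = [t for t in true_species if rng.random() < spec.db_coverage]
    db_taxa: dict[int, int | None] = {
        t: int(rng.integers(1_000_000, 5_000_001)) for t in in_db + fp_species
    }
    dbp = DatabaseProfile(tool_id=tool_id, taxa=_ancestor_close(db_taxa, tree))

    reported: dict[int, float] = {}
    if spec.abundance_noise_cv > 0:
        sigma = math.sqrt(math.log1p(spec.abundance_noise_cv**2))
    else:
        sigma = 0.0
    for t in in_db:
        if rng.random() < spec.tool_sensitivity:
            noise = rng.lognormal(-(sigma**2) / 2, sigma) if sigma else 1.0
            reported[t] = true_ab[t] * noise
    if fp_species:
        low = float(np.percentile(list(true_ab.values()), 10))
        for t in fp_species:
            reported[t] = float(rng.uniform(0, low)) or low * 1e-6
    profile = _propagate(reported, tree).normalize() if reported else RankedProfile()
    profile.sample_id = truth.sample_id
    profile.tool_id = tool_id
    return profile, dbp


def simulate_binning(
    profile: RankedProfile,
    n_reads: int,
    read_length: int,
    tree: TaxonomyTree,
    seed: int = 0,
) -> tuple[BinningResult, DatabaseProfile]:
    """Per-read assignments whose abundance estimate recovers ``profile``.

    Reads are drawn multinomially with probability proportional to
    species abundance x reference length (more abundant and longer
    genomes attract more reads), with reference lengths uniform in
    1-5 Mb recorded in the returned database profile, so dividing summed
    bases by reference length recovers the input relative abundances.
    """
    rng = np.random.default_rng(seed)
    species = sorted(profile.at("species"))
    if not species:
        raise ValueError("profile has no species entries")
    ab = np.array([profile.at("species")[t] for t in species], dtype=float)
    ref_len = rng.integers(1_000_000, 5_000_001, size=len(species))
    probs = ab * ref_len
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)
    result = BinningResult(sample_id=profile.sample_id, tool_id=profile.tool_id or "binner")
    read_no = 0
    for taxid, k in zip(species, counts):
        for _ in range(int(k)):
            result.assignments.append(BinningAssignment(f"r{read_no}", read_length, taxid))
            read_no += 1
    dbp = DatabaseProfile(
        tool_id=result.tool_id,
        taxa=_ancestor_close(
            {t: int(length) for t, length in zip(species, ref_len)}, tree
        ),
    )
    return result, dbp


# -- whole-ensemble convenience -------------------------------------------


@dataclass
class Ensemble:
    spec: EnsembleSpec
    tree: TaxonomyTree
    truth: RankedProfile
    profiles: list[RankedProfile] = field(default_factory=list)
    dbprofiles: list[DatabaseProfile] = field(default_factory=list)


def generate_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Taxonomy + truth + one (profile, database profile) pair per tool.

    The taxonomy holds ``n_species`` true species plus a disjoint pool of
    ``n_tools * fp_per_tool`` off-truth species the tools draw their
    false reports from.
    """
    n_total = spec.n_species + spec.n_tools * spec.fp_per_tool
    tree = generate_taxonomy(n_total, seed=spec.seed)
    truth = generate_truth(spec, tree)
    ens = Ensemble(spec=spec, tree=tree, truth=truth)
    for k in range(spec.n_tools):
        profile, dbp = simulate_tool(spec, truth, k, tree)
        ens.profiles.append(profile)
        ens.dbprofiles.append(dbp)
    return ens


def write_ensemble(ens: Ensemble, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact in the formats the readers accept."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_taxonomy_dumps(ens.tree, out_dir / "taxonomy")
    truth_path = out_dir / "truth.profile.tsv"
    write_profile(ens.truth, truth_path, ens.tree)
    paths["truth"] = truth_path
    for profile, dbp in zip(ens.profiles, ens.dbprofiles):
        ppath = out_dir / f"{profile.tool_id}.profile.tsv"
        dpath = out_dir / f"{dbp.tool_id}.db.tsv"
        write_profile(profile, ppath, ens.tree)
        write_database_profile(dbp, dpath)
        paths[profile.tool_id] = ppath
        paths[f"{dbp.tool_id}.db"] = dpath
    return paths
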
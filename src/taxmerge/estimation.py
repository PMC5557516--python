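"""Binning-to-abundance estimation, per-rank normalization, sub-sampling.

A binning tool assigns each read individually to a taxon, so its output
must be converted into a relative-abundance profile before it can be
merged with profiler outputs.  The abundance of a taxon is the total
number of bases assigned to it divided by the total length of its
reference sequences (longer genomes attract proportionally more reads, so
dividing by reference length removes that bias); abundances of internal
taxa are the cumulative sum over their descendants.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .profile_io import BinningResult, DatabaseProfile, RankedProfile
from .taxonomy import FIXED_RANKS, TaxonomyTree

logger = logging.getLogger("taxmerge")


def estimate_abundance(
    binning: BinningResult,
    dbprofile: DatabaseProfile,
    tree: TaxonomyTree,
    counters: dict[str, int] | None = None,
) -> RankedProfile:
    """Convert per-read assignments into an (un-normalized) ranked profile.

    Per directly-assigned taxon ``n``: abundance = (sum of assigned bases
    of its reads) / (total reference length of ``n`` in the tool's
    database profile).  Each canonical rank then carries, for every taxon,
    the cumulative sum of the direct values of that taxon and all its
    descendants.  Assignments to taxa absent from the database profile are
    dropped with a counted warning (a stale id — the tool cannot have
    classified against a reference it lacks); a zero reference length is
    fatal.
    """
    counters = counters if counters is not None else {}
    bases: dict[int, int] = {}
    for a in binning.assignments:
        if a.taxid not in dbprofile:
            counters["not_in_db"] = counters.get("not_in_db", 0) + 1
            logger.warning(
                "assignment to taxid %d absent from %s database profile; dropped",
                a.taxid,
                dbprofile.tool_id,
            )
            continue
        bases[a.taxid] = bases.get(a.taxid, 0) + a.length

    profile = RankedProfile(sample_id=binning.sample_id, tool_id=binning.tool_id)
    for rank in FIXED_RANKS:  # all ranks exist, possibly empty
        profile.ranks.setdefault(rank, {})
    for taxid, total_bases in bases.items():
        ref_len = dbprofile.length_of(taxid)
        if ref_len is None:
            raise ValueError(
                f"database profile {dbprofile.tool_id!r} has no reference length "
                f"for taxid {taxid}"
            )
        if ref_len == 0:
            raise ValueError(f"zero reference length for taxid {taxid}")
        direct = total_bases / ref_len
        # cumulative rule: a direct value contributes to the taxon's entry
        # at every canonical rank on its lineage
        for rank, ancestor in tree.lineage_at_ranks(taxid).items():
            profile.add(rank, ancestor, direct)
    return profile


def normalize_profile(profile: RankedProfile) -> RankedProfile:
    """Rescale every rank independently to sum to 100 (idempotent)."""
    return profile.normalize()


def subsample_reads(
    reads: Sequence,
    fraction: float = 1.0,
    with_replacement: bool = False,
    seed: int = 0,
    shards: int | None = None,
    shard_index: int = 0,
) -> list:
    """Randomly sub-sample a read collection, deterministically per seed.

    Without replacement a uniform subset of ``floor(fraction * N)``
    distinct reads is returned; with replacement the same number of
    uniform draws.  Input order is preserved within the selection.
    Alternatively ``shards`` splits the collection into that many disjoint
    near-equal random shards and returns shard ``shard_index`` — the
    "divide one sample among k tools" scheme.
    """
    rng = np.random.default_rng(seed)
    n = len(reads)
    if shards is not None:
        if not (0 <= shard_index < shards):
            raise ValueError(f"shard_index {shard_index} out of range for {shards} shards")
        perm = rng.permutation(n)
        idx = sorted(int(i) for i in np.array_split(perm, shards)[shard_index])
        return [reads[i] for i in idx]
    if not (0 < fraction <= 1.0) and not with_replacement:
        raise ValueError(f"fraction must be in (0, 1] without replacement, got {fraction}")
    if fraction <= 0:
        raise ValueError(f"fraction must be positive, got {fraction}")
    k = int(fraction * n)
    if k < 1:
        raise ValueError(f"fraction {fraction} of {n} reads selects no read")
    if with_replacement:
        idx = sorted(int(i) for i in rng.integers(0, n, size=k))
    else:
        idx = sorted(int(i) for i in rng.choice(n, size=k, replace=False))
    return [reads[i] for i in idx]


def subsample_fastx(
    in_path: str,
    out_path: str,
    fraction: float = 1.0,
    with_replacement: bool = False,
    seed: int = 0,
    shards: int | None = None,
    shard_index: int = 0,
    fmt: str | None = None,
) -> int:
    """Sub-sample a FASTQ/FASTA file on disk; returns the number written."""
    from Bio import SeqIO

    if fmt is None:
        with open(in_path) as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
    records = list(SeqIO.parse(in_path, fmt))
    chosen = subsample_reads(
        records,
        fraction=fraction,
        with_replacement=with_replacement,
        seed=seed,
        shards=shards,
        shard_index=shard_index,
    )
    return SeqIO.write(chosen, out_path, fmt)
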
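"""Ensemble merging of taxonomic profiles.

The merge integrates N normalized per-tool profiles into one profile per
sample, exploiting two signals that a single classifier cannot provide:

* **co-occurrence** — how many tools reported a taxon (``i``), against how
  many tool databases could possibly have reported it (``j``).  Each taxon
  gets the score ``S = (i+1)^2 / (j+1)``: high when a taxon is reported by
  most of the tools able to report it, low when many databases contain it
  but few tools called it.  The square biases the score upward on the
  ``i == j`` diagonal, giving the benefit of the doubt to taxa that only
  few databases cover.
* **abundance agreement** — the integrated abundance of a taxon is the
  harmonic mean of the per-tool normalized abundances, which damps the
  influence of a single tool's outlier estimate.

Taxa are then grouped into ``B`` equal-width score bins per rank, and
within each bin only the top fraction (by integrated abundance) survives;
the fraction per bin comes from the selected *mode* function, trading
precision against sensitivity.  All steps run independently per rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from .profile_io import DatabaseProfile, RankedProfile
from .taxonomy import FIXED_RANKS, TaxonomyTree

logger = logging.getLogger("taxmerge")

#: Mode-function family: keep-fraction = x**exponent where x = (bin+1)/B is
#: the normalized bin position.  Larger exponents keep less in low-score
#: bins (more precise); roots keep more (more sensitive).  The top bin
#: always keeps everything (x = 1).
MODE_EXPONENTS: dict[str, float] = {
    "very-precise": 3.0,
    "precise": 2.0,
    "linear": 1.0,
    "sensitive": 1.0 / 2.0,
    "very-sensitive": 1.0 / 3.0,
}

MODES: tuple[str, ...] = tuple(MODE_EXPONENTS)


@dataclass
class MergedEntry:
    """Per-taxon merge state at one rank (pre- and post-filter)."""

    taxid: int
    rank: str
    occurrences: int  # i: tools reporting the taxon at this rank
    db_presence: int  # j: tool databases containing the taxon
    score: float  # (i+1)^2 / (j+1)
    per_tool_abundances: dict[str, float] = field(default_factory=dict)
    integrated_abundance: float = 0.0  # harmonic mean of per-tool values
    bin_index: int = -1


@dataclass
class MergeConfig:
    """Tunable parameters of the merge.

    ``bins``: number of equal-width score bins per rank (default 4).
    ``mode``: percentile-function name, very-precise..very-sensitive.
    ``abundance_cutoff``: minimum integrated abundance (percentage points)
    a taxon must reach to survive, applied before the percentile rule.
    ``ranks``: ordered subset of the canonical ranks to process.
    """

    bins: int = 4
    mode: str = "linear"
    abundance_cutoff: float = 0.0001
    ranks: tuple[str, ...] = FIXED_RANKS
    mode_function: Callable[[int, int], float] | None = None  # plug-in override

    def __post_init__(self) -> None:
        if self.bins < 1:
            raise ValueError(f"bins must be >= 1, got {self.bins}")
        if self.abundance_cutoff < 0:
            raise ValueError("abundance_cutoff must be >= 0")
        if self.mode_function is None and self.mode not in MODE_EXPONENTS:
            raise ValueError(
                f"unknown mode {self.mode!r}; choose from {sorted(MODE_EXPONENTS)}"
            )
        bad = [r for r in self.ranks if r not in FIXED_RANKS]
        if bad:
            raise ValueError(f"unknown ranks {bad}")
        self.ranks = tuple(r for r in FIXED_RANKS if r in self.ranks)

    @classmethod
    def from_file(cls, path: str | Path) -> "MergeConfig":
        """Load a ``key: value`` text config (keys as the field names)."""
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            key, val = key.strip(), val.strip()
            if key == "bins":
                kwargs["bins"] = int(val)
            elif key == "mode":
                kwargs["mode"] = val
            elif key == "abundance_cutoff":
                kwargs["abundance_cutoff"] = float(val)
            elif key == "ranks":
                kwargs["ranks"] = tuple(r.strip() for r in val.split(",") if r.strip())
            else:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        return cls(**kwargs)


# -- elementary operations ----------------------------------------------


def score_taxon(i: int, j: int) -> float:
    """Co-occurrence score S = (i+1)^2 / (j+1).

    ``i`` = tools that reported the taxon, ``j`` = tool databases that
    contain it.  Equals ``i+1`` on the diagonal; strictly increasing in
    ``i``, strictly decreasing in ``j``.
    """
    if i < 0 or j < 0:
        raise ValueError(f"counts must be non-negative, got i={i}, j={j}")
    return (i + 1) ** 2 / (j + 1)


def integrate_abundance(values: Iterable[float]) -> float:
    """Harmonic mean of the reporting tools' normalized abundances.

    Robust to a single tool wildly over-estimating: the harmonic mean of
    [1, 100] is ~1.98, far below the arithmetic mean 50.5.
    """
    vals = list(values)
    if not vals:
        raise ValueError("at least one abundance value required")
    if any(v <= 0 for v in vals):
        raise ValueError(f"abundances must be positive, got {vals}")
    return len(vals) / sum(1.0 / v for v in vals)


def collect_entries(
    profiles: list[RankedProfile],
    dbprofiles: list[DatabaseProfile],
    rank: str,
) -> list[MergedEntry]:
    """Gather per-taxon occurrence/database counts and per-tool abundances.

    One entry per taxid reported by at least one tool at this rank.  A
    taxon reported by a tool whose own database profile lacks it still
    counts toward ``i`` (the report happened) but not ``j``; this keeps
    the two counts independent and is logged as a likely stale database
    profile.
    """
    tool_ids = [p.tool_id for p in profiles]
    if len(set(tool_ids)) != len(tool_ids):
        raise ValueError(f"duplicate tool ids among profiles: {tool_ids}")
    entries: dict[int, MergedEntry] = {}
    for profile in profiles:
        for taxid, ab in profile.at(rank).items():
            if ab <= 0:
                continue
            e = entries.get(taxid)
            if e is None:
                e = entries[taxid] = MergedEntry(
                    taxid=taxid, rank=rank, occurrences=0, db_presence=0, score=0.0
                )
            e.occurrences += 1
            e.per_tool_abundances[profile.tool_id] = ab
    for e in entries.values():
        e.db_presence = sum(1 for dbp in dbprofiles if e.taxid in dbp)
        e.score = score_taxon(e.occurrences, e.db_presence)
        e.integrated_abundance = integrate_abundance(e.per_tool_abundances.values())
        reporting_without_db = [
            p.tool_id
            for p, dbp in zip_by_tool(profiles, dbprofiles)
            if p.tool_id in e.per_tool_abundances and dbp is not None and e.taxid not in dbp
        ]
        if reporting_without_db:
            logger.debug(
                "taxid %d at %s reported by %s but absent from their database "
                "profile (stale profile?)",
                e.taxid,
                rank,
                reporting_without_db,
            )
    return sorted(entries.values(), key=lambda e: e.taxid)


def zip_by_tool(
    profiles: list[RankedProfile], dbprofiles: list[DatabaseProfile]
) -> list[tuple[RankedProfile, DatabaseProfile | None]]:
    """Pair each profile with its tool's database profile (None if missing)."""
    by_id = {d.tool_id: d for d in dbprofiles}
    return [(p, by_id.get(p.tool_id)) for p in profiles]


def assign_bins(entries: list[MergedEntry], bins: int) -> list[MergedEntry]:
    """Assign each entry an equal-width score bin over this rank's range.

    Bin width is (Smax - Smin)/B; the top edge is closed so the maximum
    score lands in bin B-1.  A degenerate range (all scores equal) puts
    every entry in the top bin, degrading gracefully to a pure
    percentile-on-abundance rule.
    """
    if bins < 1:
        raise ValueError(f"bins must be >= 1, got {bins}")
    if not entries:
        return entries
    scores = [e.score for e in entries]
    smin, smax = min(scores), max(scores)
    if smax == smin:
        for e in entries:
            e.bin_index = bins - 1
        return entries
    width = (smax - smin) / bins
    for e in entries:
        e.bin_index = min(int((e.score - smin) / width), bins - 1)
    return entries


def mode_percentile(bin_index: int, bins: int, mode: str) -> float:
    """Fraction of top-abundance taxa kept in a bin under a given mode.

    With x = (bin_index+1)/bins the family is x^3 (very-precise), x^2
    (precise), x (linear), sqrt(x) (sensitive), cbrt(x) (very-sensitive):
    monotone in the bin for every mode, and the top bin always keeps 1.
    """
    if not 0 <= bin_index < bins:
        raise ValueError(f"bin_index {bin_index} out of range for {bins} bins")
    try:
        exponent = MODE_EXPONENTS[mode]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}") from None
    x = (bin_index + 1) / bins
    return x**exponent


def filter_bins(entries: list[MergedEntry], config: MergeConfig) -> list[MergedEntry]:
    """Apply the abundance cutoff, then the per-bin percentile rule.

    Entries below ``abundance_cutoff`` are removed outright.  Within each
    bin the remaining entries are sorted by descending integrated
    abundance and the top ``ceil(keep_fraction * bin_size)`` survive, so
    any non-empty bin keeps at least one taxon.  Boundary ties break by
    higher score, then lower taxid.
    """
    keep_fn = config.mode_function or (
        lambda b, B: mode_percentile(b, B, config.mode)
    )
    alive = [e for e in entries if e.integrated_abundance >= config.abundance_cutoff]
    survivors: list[MergedEntry] = []
    by_bin: dict[int, list[MergedEntry]] = {}
    for e in alive:
        by_bin.setdefault(e.bin_index, []).append(e)
    for bin_index, group in by_bin.items():
        frac = keep_fn(bin_index, config.bins)
        group.sort(key=lambda e: (-e.integrated_abundance, -e.score, e.taxid))
        n_keep = math.ceil(frac * len(group))
        survivors.extend(group[:n_keep])
    return survivors


def merge_profiles(
    profiles: list[RankedProfile],
    dbprofiles: list[DatabaseProfile],
    config: MergeConfig | None = None,
    tree: TaxonomyTree | None = None,
) -> tuple[RankedProfile, list[MergedEntry]]:
    """Run the full merge and return (final profile, detailed entries).

    Per rank: normalize inputs, collect occurrence/database counts, score,
    integrate abundances, bin by score, filter, then re-normalize the
    survivors to 100% and sort by descending abundance.  The detailed list
    retains i, j, S, bin and per-tool abundances for every *pre-filter*
    entry, for inspection of what the filter did.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    config = config or MergeConfig()
    missing_db = {p.tool_id for p in profiles} - {d.tool_id for d in dbprofiles}
    if missing_db:
        logger.warning(
            "no database profile for tool(s) %s; they contribute 0 to every "
            "database-presence count",
            sorted(missing_db),
        )
    normalized = [p.normalize() for p in profiles]
    sample_id = profiles[0].sample_id
    final = RankedProfile(sample_id=sample_id, tool_id="merged")
    detailed: list[MergedEntry] = []
    for rank in config.ranks:
        entries = collect_entries(normalized, dbprofiles, rank)
        if not entries:
            continue
        assign_bins(entries, config.bins)
        detailed.extend(entries)
        for e in filter_bins(entries, config):
            final.add(rank, e.taxid, e.integrated_abundance)
    return final.normalize(), detailed
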
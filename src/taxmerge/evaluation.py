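"""Profile evaluation against a gold standard.

Binary metrics (TP/FP/FN, sensitivity, precision) compare the *sets* of
taxa per rank; the quantitative L1 norm sums absolute abundance
differences over the union of taxa, so it ranges from 0 (identical) to
200 (disjoint) when both profiles are normalized to 100 per rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .profile_io import DatabaseProfile, RankedProfile
from .taxonomy import FIXED_RANKS


@dataclass
class RankMetrics:
    tp: int
    fp: int
    fn: int
    l1: float

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return self.tp / denom if denom else None


@dataclass
class EvalResult:
    per_rank: dict[str, RankMetrics] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rank\ttp\tfp\tfn\tsensitivity\tprecision\tl1"]
        for rank in FIXED_RANKS:
            m = self.per_rank.get(rank)
            if m is None:
                continue
            sens = f"{m.sensitivity:.6f}" if m.sensitivity is not None else "NA"
            prec = f"{m.precision:.6f}" if m.precision is not None else "NA"
            lines.append(f"{rank}\t{m.tp}\t{m.fp}\t{m.fn}\t{sens}\t{prec}\t{m.l1:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


def evaluate(predicted: RankedProfile, truth: RankedProfile) -> EvalResult:
    """Per-rank TP/FP/FN, sensitivity, precision and L1 norm.

    Both profiles must be normalized (each non-empty rank summing to 100);
    missing taxa count as abundance 0 in the L1 sum.  Ranks empty in both
    profiles are omitted.
    """
    for name, prof in (("predicted", predicted), ("truth", truth)):
        if not prof.is_normalized():
            raise ValueError(f"{name} profile is not normalized per rank")
    result = EvalResult()
    for rank in FIXED_RANKS:
        pred = predicted.at(rank)
        true = truth.at(rank)
        if not pred and not true:
            continue
        pset, tset = set(pred), set(true)
        l1 = sum(abs(pred.get(t, 0.0) - true.get(t, 0.0)) for t in pset | tset)
        result.per_rank[rank] = RankMetrics(
            tp=len(pset & tset), fp=len(pset - tset), fn=len(tset - pset), l1=l1
        )
    return result


def max_attainable_sensitivity(
    truth: RankedProfile, dbprofiles: list[DatabaseProfile]
) -> dict[str, float | None]:
    """Upper bound on sensitivity given the tools' database coverage.

    A taxon absent from every tool's reference database can never be
    reported, so per rank the bound is |truth ∩ union(databases)| / |truth|.
    """
    out: dict[str, float | None] = {}
    for rank in FIXED_RANKS:
        true = set(truth.at(rank))
        if not true:
            out[rank] = None
            continue
        covered = {t for t in true if any(t in dbp for dbp in dbprofiles)}
        out[rank] = len(covered) / len(true)
    return out
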
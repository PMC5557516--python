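"""Readers and writers for the formats the pipeline touches.

Three on-disk formats are supported:

* CAMI/BioBoxes *profiling* format — header lines starting ``@``
  (``@SampleID``, ``@Version``, ``@Ranks``), a ``@@TAXID RANK TAXPATH
  TAXPATHSN PERCENTAGE`` column header, tab-separated data rows.  Read and
  written bit-reproducibly.
* BioBoxes *binning* format (``@@SEQUENCEID ... TAXID`` columns) and a plain
  3-column TSV (sequence id, assigned length, taxid) — read only.
* Per-tool *database profiles*: 2-column TSV (taxid, total reference length)
  recording which taxa a tool's reference database can identify.

All taxon identifiers are resolved against a :class:`~taxmerge.taxonomy
.TaxonomyTree` on the way in; unresolvable entries are dropped with counted
warnings because real tool outputs contain stale ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .taxonomy import (
    FIXED_RANKS,
    RANK_INDEX,
    TaxonomyTree,
    normalize_rank,
)

logger = logging.getLogger("taxmerge")

PROFILE_VERSION = "0.9.1"


class FormatError(Exception):
    """Fatal problem in an input file (message names file and line)."""


@dataclass
class RankedProfile:
    """Per-sample taxonomic profile: one taxid->abundance map per rank.

    Abundances are on the 0-100 (percentage) scale.  Within a rank taxids
    are unique; after :meth:`normalize` each non-empty rank sums to 100.
    """

    sample_id: str = "S"
    tool_id: str = ""
    ranks: dict[str, dict[int, float]] = field(default_factory=dict)

    def at(self, rank: str) -> dict[int, float]:
        return self.ranks.get(rank, {})

    def add(self, rank: str, taxid: int, abundance: float) -> None:
        """Accumulate abundance for a taxon at a rank (summing duplicates)."""
        bucket = self.ranks.setdefault(rank, {})
        bucket[taxid] = bucket.get(taxid, 0.0) + abundance

    def nonempty_ranks(self) -> list[str]:
        return [r for r in FIXED_RANKS if self.ranks.get(r)]

    def normalize(self) -> "RankedProfile":
        """Rescale each rank independently so it sums to 100.

        A rank whose sum is zero is left all-zero with a warning; empty
        ranks stay empty.  Idempotent.
        """
        out = RankedProfile(self.sample_id, self.tool_id)
        for rank, vals in self.ranks.items():
            total = sum(vals.values())
            if not vals:
                continue
            if total == 0:
                logger.warning(
                    "rank %s of %s sums to zero; left unnormalized", rank, self.tool_id
                )
                out.ranks[rank] = dict(vals)
            else:
                out.ranks[rank] = {t: v * 100.0 / total for t, v in vals.items()}
        return out

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return all(
            abs(sum(v.values()) - 100.0) <= tol
            for v in self.ranks.values()
            if v and sum(v.values()) > 0
        )


@dataclass
class BinningAssignment:
    sequence_id: str
    length: int  # bases used in the assignment
    taxid: int


@dataclass
class BinningResult:
    """Per-read taxon assignments emitted by a binning tool."""

    sample_id: str = "S"
    tool_id: str = ""
    assignments: list[BinningAssignment] = field(default_factory=list)
    dropped: int = 0  # unresolvable rows discarded at read time


@dataclass
class DatabaseProfile:
    """Taxa a tool's reference database covers, with total reference length.

    Ancestor-closed: whenever a taxon is present every canonical-rank
    ancestor is present too (a database holding a species can identify its
    genus), with reference lengths summed upward.  Lengths may be None for
    profilers whose binning-abundance path is never used.
    """

    tool_id: str = ""
    taxa: dict[int, int | None] = field(default_factory=dict)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.taxa

    def length_of(self, taxid: int) -> int | None:
        return self.taxa.get(taxid)


# -- placement helper ----------------------------------------------------


def _place_taxid(
    tree: TaxonomyTree, taxid: int, declared_rank: str | None
) -> tuple[int, str] | None:
    """Decide the (taxid, rank) a resolved input row lands at.

    Nodes at a canonical rank stay there; sub-species nodes are projected
    up to their species ancestor; anything else (e.g. a subphylum) is not
    placeable and returns None.
    """
    own_rank = normalize_rank(tree.rank.get(taxid, ""))
    if own_rank in RANK_INDEX:
        if declared_rank and normalize_rank(declared_rank) not in (own_rank,):
            logger.warning(
                "taxid %d declared at rank %r but taxonomy says %r; using taxonomy",
                taxid,
                declared_rank,
                own_rank,
            )
        return taxid, own_rank
    lineage = tree.lineage_at_ranks(taxid)
    if "species" in lineage:  # below species: project up
        return lineage["species"], "species"
    return None


# -- profiling format ----------------------------------------------------


def read_profile(
    path: str | Path,
    tree: TaxonomyTree,
    tool_id: str = "",
    counters: dict[str, int] | None = None,
) -> RankedProfile:
    """Read a CAMI/BioBoxes profiling file into a :class:`RankedProfile`.

    Rows are taxid-resolved and rank-normalised; sub-species rows are
    projected to their species ancestor and summed there; rows at ranks
    outside the canonical seven are dropped with a counted warning.
    Abundances on a 0-1 scale are auto-detected and rescaled to 0-100.
    """
    path = Path(path)
    counters = counters if counters is not None else {}
    sample_id = "S"
    columns: list[str] | None = None
    profile = RankedProfile(sample_id=sample_id, tool_id=tool_id or path.stem)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("@@"):
                columns = [c.strip().upper() for c in line[2:].split("\t")]
                continue
            if line.startswith("@"):
                key, _, val = line[1:].partition(":")
                if key.strip().lower() == "sampleid":
                    profile.sample_id = val.strip()
                continue
            if columns is None:
                raise FormatError(f"{path}:{lineno}: data row before '@@' header")
            fields = line.split("\t")
            row = dict(zip(columns, fields))
            try:
                taxid = int(row["TAXID"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad TAXID field") from exc
            try:
                pct = float(row["PERCENTAGE"])
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad PERCENTAGE field") from exc
            if pct < 0:
                raise FormatError(f"{path}:{lineno}: negative percentage {pct}")
            if pct == 0:
                continue
            resolved = tree.resolve(taxid)
            if resolved is None:
                counters["unresolved"] = counters.get("unresolved", 0) + 1
                logger.warning("%s:%d: unresolvable taxid %d dropped", path, lineno, taxid)
                continue
            placed = _place_taxid(tree, resolved, row.get("RANK"))
            if placed is None:
                counters["unplaceable_rank"] = counters.get("unplaceable_rank", 0) + 1
                logger.warning(
                    "%s:%d: taxid %d at non-canonical rank dropped", path, lineno, resolved
                )
                continue
            ptaxid, prank = placed
            if ptaxid in profile.at(prank):
                counters["duplicate_summed"] = counters.get("duplicate_summed", 0) + 1
                logger.warning(
                    "%s:%d: duplicate taxid %d at %s; abundances summed",
                    path,
                    lineno,
                    ptaxid,
                    prank,
                )
            profile.add(prank, ptaxid, pct)

    if columns is None:
        raise FormatError(f"{path}: missing '@@' column header")

    sums = [sum(v.values()) for v in profile.ranks.values() if v]
    if sums and all(s <= 1.5 for s in sums):
        logger.warning("%s: abundances look 0-1 scaled; rescaling to percentages", path)
        for vals in profile.ranks.values():
            for t in vals:
                vals[t] *= 100.0
    return profile


def write_profile(profile: RankedProfile, path: str | Path, tree: TaxonomyTree) -> None:
    """Write a profile in CAMI/BioBoxes profiling format.

    Ranks appear in canonical order; entries within a rank sorted by
    descending abundance then ascending taxid; TAXPATH/TAXPATHSN are
    recomputed from the taxonomy so the output is internally consistent.
    """
    path = Path(path)
    lines = [
        f"@SampleID:{profile.sample_id}",
        f"@Version:{PROFILE_VERSION}",
        "@Ranks:" + "|".join(FIXED_RANKS),
        "@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE",
    ]
    for rank in FIXED_RANKS:
        entries = profile.at(rank)
        for taxid, ab in sorted(entries.items(), key=lambda kv: (-kv[1], kv[0])):
            if tree.resolve(taxid) is None:
                raise FormatError(f"unresolvable taxid {taxid} in profile for {path}")
            lineage = tree.lineage_at_ranks(taxid)
            upto = RANK_INDEX[rank]
            ids = [lineage[r] for r in FIXED_RANKS[: upto + 1] if r in lineage]
            taxpath = "|".join(str(t) for t in ids)
            taxpath_sn = "|".join(tree.name.get(t, str(t)) for t in ids)
            lines.append(f"{taxid}\t{rank}\t{taxpath}\t{taxpath_sn}\t{ab:.6f}")
    path.write_text("\n".join(lines) + "\n")


# -- binning format ------------------------------------------------------


def read_binning(
    path: str | Path,
    tree: TaxonomyTree,
    tool_id: str = "",
    default_read_length: int = 100,
    keep_first: bool = False,
    counters: dict[str, int] | None = None,
) -> BinningResult:
    """Read per-read assignments from plain TSV or BioBoxes binning format.

    Plain rows are ``sequence-id <TAB> assigned-length <TAB> taxid``; the
    BioBoxes dialect declares ``SEQUENCEID``/``TAXID`` (and optionally a
    length) columns via a ``@@`` header — when no length column exists
    ``default_read_length`` is used.  Duplicate sequence ids are fatal
    unless ``keep_first``.
    """
    path = Path(path)
    counters = counters if counters is not None else {}
    result = BinningResult(tool_id=tool_id or path.stem)
    columns: list[str] | None = None
    seen: set[str] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@@"):
                columns = [c.strip().upper() for c in line[2:].split("\t")]
                continue
            if line.startswith("@"):
                continue
            fields = line.split("\t")
            if columns is not None:
                row = dict(zip(columns, fields))
                try:
                    seqid = row["SEQUENCEID"]
                    taxid = int(row["TAXID"])
                except (KeyError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad binning row") from exc
                length_field = row.get("LENGTH") or row.get("_LENGTH")
                length = int(float(length_field)) if length_field else default_read_length
            else:
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 columns")
                seqid = fields[0]
                try:
                    length = int(float(fields[1]))
                    taxid = int(fields[2])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            if seqid in seen:
                if keep_first:
                    counters["duplicate_skipped"] = counters.get("duplicate_skipped", 0) + 1
                    continue
                raise FormatError(f"{path}:{lineno}: duplicate sequence id {seqid!r}")
            seen.add(seqid)
            resolved = tree.resolve(taxid)
            if resolved is None:
                counters["unresolved"] = counters.get("unresolved", 0) + 1
                result.dropped += 1
                logger.warning("%s:%d: unresolvable taxid %d dropped", path, lineno, taxid)
                continue
            result.assignments.append(BinningAssignment(seqid, length, resolved))
    return result


# -- database profiles ---------------------------------------------------


def _ancestor_close(
    taxa: dict[int, int | None], tree: TaxonomyTree
) -> dict[int, int | None]:
    """Expand a taxon->length map so every canonical ancestor is present.

    Reference lengths are summed into ancestors (a genus' reference length
    is the total over its species); None lengths propagate as None-safe.
    """
    closed: dict[int, int | None] = {}
    for taxid, length in taxa.items():
        lineage = tree.lineage_at_ranks(taxid)
        nodes = set(lineage.values()) | {taxid}
        for node in nodes:
            if length is None:
                closed.setdefault(node, None)
            else:
                prev = closed.get(node)
                closed[node] = length if prev is None else prev + length
    return closed


def read_database_profile(
    path: str | Path,
    tree: TaxonomyTree,
    tool_id: str = "",
    counters: dict[str, int] | None = None,
) -> DatabaseProfile:
    """Read a 2-column (taxid, total reference length) database profile.

    The result is ancestor-closed with lengths summed upward.  The length
    column may be absent for pure profilers.
    """
    path = Path(path)
    counters = counters if counters is not None else {}
    taxa: dict[int, int | None] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "@")):
                continue
            fields = line.split("\t")
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad taxid") from exc
            length: int | None = None
            if len(fields) > 1 and fields[1].strip():
                try:
                    length = int(float(fields[1]))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad length") from exc
                if length <= 0:
                    raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            resolved = tree.resolve(taxid)
            if resolved is None:
                counters["unresolved"] = counters.get("unresolved", 0) + 1
                logger.warning("%s:%d: unresolvable taxid %d dropped", path, lineno, taxid)
                continue
            if resolved in taxa:
                if length is not None:
                    taxa[resolved] = (taxa[resolved] or 0) + length
            else:
                taxa[resolved] = length
    return DatabaseProfile(
        tool_id=tool_id or path.stem, taxa=_ancestor_close(taxa, tree)
    )


def write_database_profile(dbp: DatabaseProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxid in sorted(dbp.taxa):
            length = dbp.taxa[taxid]
            fh.write(f"{taxid}\t{length if length is not None else ''}\n")


def build_database_profile(
    accession2taxid: str | Path,
    sequence_lengths: str | Path,
    tree: TaxonomyTree,
    tool_id: str = "",
    counters: dict[str, int] | None = None,
) -> DatabaseProfile:
    """Build a database profile from accession->taxid and accession->length maps.

    Per-taxon total length is the sum over that taxon's reference sequences;
    accessions present in only one of the two files are dropped with a
    counted warning.  An empty intersection is fatal.
    """
    counters = counters if counters is not None else {}

    def read_map(p: str | Path, parse) -> dict[str, object]:
        out: dict[str, object] = {}
        with open(p) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise FormatError(f"{p}:{lineno}: expected 2 columns")
                try:
                    out[fields[0]] = parse(fields[1])
                except ValueError as exc:
                    raise FormatError(f"{p}:{lineno}: bad value {fields[1]!r}") from exc
        return out

    acc2tax = read_map(accession2taxid, int)
    acc2len = read_map(sequence_lengths, lambda v: int(float(v)))
    shared = set(acc2tax) & set(acc2len)
    unmatched = len(set(acc2tax) ^ set(acc2len))
    if unmatched:
        counters["unmatched_accessions"] = counters.get("unmatched_accessions", 0) + unmatched
        logger.warning("%d accession(s) missing from one of the two maps", unmatched)
    if not shared:
        raise FormatError("no accession is present in both input files")

    taxa: dict[int, int | None] = {}
    for acc in shared:
        resolved = tree.resolve(acc2tax[acc])  # type: ignore[arg-type]
        if resolved is None:
            counters["unresolved"] = counters.get("unresolved", 0) + 1
            continue
        prev = taxa.get(resolved)
        taxa[resolved] = acc2len[acc] if prev is None else prev + acc2len[acc]  # type: ignore[operator]
    return DatabaseProfile(tool_id=tool_id, taxa=_ancestor_close(taxa, tree))
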
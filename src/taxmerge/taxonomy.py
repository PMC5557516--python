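"""NCBI-style taxonomy handling.

Profiles produced by different classifiers routinely disagree on taxon
identifiers and names because each tool ships a reference database built
against a different taxonomy snapshot.  A single recent taxonomy is loaded
once and every identifier flowing through the pipeline is resolved against
it: stale identifiers are redirected through ``merged.dmp``, names are
matched case-insensitively, and sub-species entries are projected up to the
species rank where the ensemble operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger("taxmerge")

#: Canonical ranks, broadest to narrowest.  All per-rank processing in the
#: pipeline is restricted to these seven levels.
FIXED_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(FIXED_RANKS)}

#: Dialect aliases normalised on input ("domain" is the common alternative
#: top-rank name; NCBI dumps use "superkingdom").
RANK_ALIASES: dict[str, str] = {
    "domain": "superkingdom",
    "superkingdom": "superkingdom",
}

#: Ranks treated as below species: entries at these ranks are projected up
#: to their species ancestor unless strain passthrough is requested.
SUBSPECIES_RANKS = frozenset(
    {"strain", "subspecies", "varietas", "forma", "isolate", "no rank", "biotype", "serotype"}
)


def normalize_rank(rank: str) -> str:
    """Map dialect rank names onto the canonical vocabulary."""
    return RANK_ALIASES.get(rank.strip().lower(), rank.strip().lower())


class TaxonomyError(Exception):
    """Fatal taxonomy parse or consistency problem."""


@dataclass
class TaxonomyTree:
    """In-memory taxonomy: parent/rank/name maps plus merged-id redirects.

    Invariants: every non-root node's parent chain terminates at ``root``;
    ``merged`` keys never collide with live node ids.
    """

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    merged: dict[int, int] = field(default_factory=dict)
    root: int = 1

    _name_index: dict[str, list[int]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for taxid, par in self.parent.items():
            if taxid != self.root and par not in self.parent:
                raise TaxonomyError(
                    f"node {taxid} has parent {par} which is absent from the tree"
                )
        # cycle check: every chain must reach the root
        for taxid in self.parent:
            seen = set()
            node = taxid
            while node != self.root:
                if node in seen:
                    raise TaxonomyError(f"cycle detected at node {node}")
                seen.add(node)
                node = self.parent[node]
        overlap = set(self.merged) & set(self.parent)
        if overlap:
            raise TaxonomyError(
                f"merged ids collide with live node ids: {sorted(overlap)[:5]}"
            )

    # -- resolution ------------------------------------------------------

    def resolve(self, taxid: int) -> int | None:
        """Return the current id for ``taxid``, or None if unknown.

        Merged ids are chased until a live node is reached; idempotent.
        """
        seen = set()
        while taxid not in self.parent:
            if taxid in seen or taxid not in self.merged:
                return None
            seen.add(taxid)
            taxid = self.merged[taxid]
        return taxid

    def resolve_name(self, name: str, rank: str | None = None) -> int | None:
        """Case-insensitive exact scientific-name lookup.

        If ``rank`` is given the hit must carry that rank.  Ambiguous names
        (several live taxids) resolve to None with a warning rather than an
        arbitrary pick.
        """
        if self._name_index is None:
            idx: dict[str, list[int]] = {}
            for taxid, nm in self.name.items():
                idx.setdefault(nm.lower(), []).append(taxid)
            self._name_index = idx
        hits = self._name_index.get(name.strip().lower(), [])
        if rank is not None:
            want = normalize_rank(rank)
            hits = [t for t in hits if normalize_rank(self.rank.get(t, "")) == want]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            logger.warning("ambiguous name %r matches taxids %s; dropping", name, hits)
        return None

    # -- lineage ---------------------------------------------------------

    def lineage_at_ranks(self, taxid: int) -> dict[str, int]:
        """Walk the parent chain and collect the canonical-rank ancestors.

        The returned map contains ``taxid`` itself under its own rank when
        that rank is canonical; ranks missing from the chain are absent.
        """
        if taxid not in self.parent:
            raise TaxonomyError(f"lineage requested for unresolved taxid {taxid}")
        out: dict[str, int] = {}
        node = taxid
        while True:
            r = normalize_rank(self.rank.get(node, ""))
            if r in RANK_INDEX and r not in out:
                out[r] = node
            if node == self.root:
                break
            node = self.parent[node]
        return out

    def project_to_rank(self, taxid: int, rank: str) -> int | None:
        """Ancestor of ``taxid`` at canonical ``rank`` (or None)."""
        return self.lineage_at_ranks(taxid).get(rank)

    def name_lineage(self, taxid: int, upto_rank: str | None = None) -> list[str]:
        """Scientific names from superkingdom down to ``taxid``'s rank."""
        lin = self.lineage_at_ranks(taxid)
        stop = RANK_INDEX[upto_rank] if upto_rank else len(FIXED_RANKS) - 1
        return [
            self.name.get(lin[r], str(lin[r]))
            for r in FIXED_RANKS[: stop + 1]
            if r in lin
        ]


# -- dump parsing --------------------------------------------------------


def _parse_dmp_line(line: str) -> list[str]:
    # NCBI dump dialect: fields separated by "\t|\t", rows end "\t|".
    return line.rstrip("\n").rstrip("\t|").split("\t|\t")


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-style nodes/names/merged dump files.

    ``nodes.dmp`` columns 1-3 (taxid, parent, rank) are used; ``names.dmp``
    rows flagged "scientific name"; ``merged.dmp`` columns 1-2.  Ranks
    outside the canonical list are stored verbatim.
    """
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    root = None
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            try:
                taxid, par = int(fields[0]), int(fields[1])
            except (ValueError, IndexError) as exc:
                raise TaxonomyError(
                    f"{nodes_path}:{lineno}: cannot parse node row: {line!r}"
                ) from exc
            parent[taxid] = par
            rank[taxid] = normalize_rank(fields[2]) if len(fields) > 2 else "no rank"
            if taxid == par:
                root = taxid

    if root is None:
        raise TaxonomyError(f"{nodes_path}: no root node (taxid == parent) found")

    name: dict[int, str] = {}
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _parse_dmp_line(line)
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise TaxonomyError(
                    f"{names_path}:{lineno}: cannot parse name row: {line!r}"
                ) from exc
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class == "scientific name":
                name[taxid] = fields[1]

    merged: dict[int, int] = {}
    if merged_path is not None:
        with open(merged_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = _parse_dmp_line(line)
                try:
                    merged[int(fields[0])] = int(fields[1])
                except (ValueError, IndexError) as exc:
                    raise TaxonomyError(
                        f"{merged_path}:{lineno}: cannot parse merged row: {line!r}"
                    ) from exc

    return TaxonomyTree(parent=parent, rank=rank, name=name, merged=merged, root=root)


def write_taxonomy_dumps(tree: TaxonomyTree, out_dir: str | Path) -> dict[str, Path]:
    """Write a tree back out as nodes/names/merged dump files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out_dir / "nodes.dmp",
        "names": out_dir / "names.dmp",
        "merged": out_dir / "merged.dmp",
    }
    with open(paths["nodes"], "w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank[taxid]}\t|\n")
    with open(paths["names"], "w") as fh:
        for taxid in sorted(tree.parent):
            nm = tree.name.get(taxid, f"taxon-{taxid}")
            fh.write(f"{taxid}\t|\t{nm}\t|\t\t|\tscientific name\t|\n")
    with open(paths["merged"], "w") as fh:
        for old in sorted(tree.merged):
            fh.write(f"{old}\t|\t{tree.merged[old]}\t|\n")
    return paths
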
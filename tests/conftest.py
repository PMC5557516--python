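"""Shared fixtures: hand-built taxonomies and small profile files."""

from __future__ import annotations

import textwrap

import pytest

from taxmerge.taxonomy import TaxonomyTree, load_taxonomy

# Minimal NCBI-dialect dump: root 1; Bacteria (superkingdom) 2;
# Proteobacteria (phylum) 1224; plus a merged redirect 666 -> 1224.
MINI_NODES = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tsuperkingdom\t|\n"
    "1224\t|\t2\t|\tphylum\t|\n"
)
MINI_NAMES = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
    "1224\t|\tProteobacteria\t|\t\t|\tscientific name\t|\n"
    "1224\t|\tpurple bacteria\t|\t\t|\tsynonym\t|\n"
)
MINI_MERGED = "666\t|\t1224\t|\n"


@pytest.fixture()
def mini_dump(tmp_path):
    nodes = tmp_path / "nodes.dmp"
    names = tmp_path / "names.dmp"
    merged = tmp_path / "merged.dmp"
    nodes.write_text(MINI_NODES)
    names.write_text(MINI_NAMES)
    merged.write_text(MINI_MERGED)
    return nodes, names, merged


@pytest.fixture()
def mini_tree(mini_dump):
    return load_taxonomy(*mini_dump)


def make_lineage_tree() -> TaxonomyTree:
    """Hand-built 7-rank taxonomy: two species under one genus, plus a
    strain below one of them and a merged redirect onto a species."""
    parent = {
        1: 1,
        2: 1,  # superkingdom Bacteria
        10: 2,  # phylum
        11: 10,  # class
        12: 11,  # order
        13: 12,  # family
        14: 13,  # genus
        21: 14,  # species A
        22: 14,  # species B
        31: 21,  # strain below species A
    }
    rank = {
        1: "no rank",
        2: "superkingdom",
        10: "phylum",
        11: "class",
        12: "order",
        13: "family",
        14: "genus",
        21: "species",
        22: "species",
        31: "strain",
    }
    name = {
        1: "root",
        2: "Bacteria",
        10: "Phylum_10",
        11: "Class_11",
        12: "Order_12",
        13: "Family_13",
        14: "Genus_14",
        21: "Species_A",
        22: "Species_B",
        31: "Strain_31",
    }
    return TaxonomyTree(parent=parent, rank=rank, name=name, merged={777: 21}, root=1)


@pytest.fixture()
def lineage_tree():
    return make_lineage_tree()


@pytest.fixture()
def profile_text():
    """Two-row CAMI profiling file on the minimal taxonomy."""
    return textwrap.dedent(
        """\
        @SampleID:sample1
        @Version:0.9.1
        @Ranks:superkingdom|phylum|class|order|family|genus|species
        @@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE
        2\tsuperkingdom\t2\tBacteria\t100.0
        1224\tphylum\t2|1224\tBacteria|Proteobacteria\t100.0
        """
    )
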
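"""Core merge: scoring, harmonic mean, binning, mode filtering, pipeline."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxmerge.merge import (
    MODES,
    MergeConfig,
    MergedEntry,
    assign_bins,
    collect_entries,
    filter_bins,
    integrate_abundance,
    merge_profiles,
    mode_percentile,
    score_taxon,
)
from taxmerge.profile_io import DatabaseProfile, RankedProfile, _ancestor_close
from taxmerge.synthetic import generate_taxonomy, species_leaves


class TestScore:
    def test_origin(self):
        assert score_taxon(0, 0) == 1.0

    def test_diagonal_is_count_plus_one(self):
        for k in range(11):
            assert score_taxon(k, k) == pytest.approx(k + 1)

    def test_off_diagonal(self):
        assert score_taxon(3, 3) == 4.0
        assert score_taxon(1, 5) == pytest.approx(4 / 6)

    def test_exact_over_grid(self):
        for i, j in itertools.product(range(11), repeat=2):
            assert score_taxon(i, j) == (i + 1) ** 2 / (j + 1)

    def test_monotone_in_counts(self):
        for i, j in itertools.product(range(10), repeat=2):
            assert score_taxon(i + 1, j) > score_taxon(i, j)
            assert score_taxon(i, j + 1) < score_taxon(i, j)

    def test_negative_fatal(self):
        with pytest.raises(ValueError):
            score_taxon(-1, 0)


class TestHarmonicMean:
    def test_equal_values(self):
        assert integrate_abundance([0.2, 0.2, 0.2]) == pytest.approx(0.2)

    def test_two_values(self):
        assert integrate_abundance([10, 40]) == pytest.approx(16.0)

    def test_outlier_damping(self):
        hm = integrate_abundance([1, 100])
        assert hm == pytest.approx(200 / 101)  # ~1.98, << arithmetic mean 50.5
        assert hm < 50.5 / 10

    def test_non_positive_fatal(self):
        with pytest.raises(ValueError):
            integrate_abundance([1.0, 0.0])
        with pytest.raises(ValueError):
            integrate_abundance([])

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=100.0), min_size=1, max_size=8)
    )
    def test_closed_form(self, vals):
        assert integrate_abundance(vals) == pytest.approx(
            len(vals) / sum(1 / v for v in vals)
        )

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=100.0), min_size=2, max_size=8)
    )
    def test_never_exceeds_arithmetic_mean(self, vals):
        assert integrate_abundance(vals) <= sum(vals) / len(vals) + 1e-9


def profile(tool_id, species_abund):
    return RankedProfile(tool_id=tool_id, ranks={"species": dict(species_abund)})


def dbp(tool_id, taxids):
    return DatabaseProfile(tool_id=tool_id, taxa={t: None for t in taxids})


class TestCollectEntries:
    def test_occurrence_and_db_counts(self):
        profiles = [profile(f"t{k}", {7: 100.0}) for k in range(3)]
        profiles += [profile(f"t{k}", {8: 100.0}) for k in range(3, 6)]
        dbps = [dbp(f"t{k}", [7]) for k in range(4)] + [dbp("t4", [8]), dbp("t5", [8])]
        entries = {e.taxid: e for e in collect_entries(profiles, dbps, "species")}
        assert entries[7].occurrences == 3 and entries[7].db_presence == 4
        assert entries[8].occurrences == 3 and entries[8].db_presence == 2

    def test_report_without_db_counts_i_not_j(self):
        profiles = [profile("t0", {7: 100.0})]
        entries = collect_entries(profiles, [dbp("t0", [])], "species")
        assert entries[0].occurrences == 1 and entries[0].db_presence == 0

    def test_unreported_taxon_absent(self):
        entries = collect_entries([profile("t0", {7: 100.0})], [dbp("t0", [7, 8])], "species")
        assert [e.taxid for e in entries] == [7]

    def test_duplicate_tool_ids_fatal(self):
        with pytest.raises(ValueError, match="duplicate"):
            collect_entries([profile("t0", {7: 1.0}), profile("t0", {8: 1.0})], [], "species")


def entry(taxid, score=1.0, abundance=1.0, bin_index=0):
    e = MergedEntry(taxid=taxid, rank="species", occurrences=1, db_presence=1, score=score)
    e.integrated_abundance = abundance
    e.bin_index = bin_index
    return e


class TestAssignBins:
    def test_unit_spaced_scores(self):
        entries = [entry(t, score=s) for t, s in enumerate([1, 2, 3, 4])]
        assign_bins(entries, 4)
        assert [e.bin_index for e in entries] == [0, 1, 2, 3]  # closed top edge

    def test_degenerate_range_top_bin(self):
        entries = [entry(t, score=2.5) for t in range(5)]
        assign_bins(entries, 4)
        assert all(e.bin_index == 3 for e in entries)

    def test_single_bin(self):
        entries = [entry(t, score=s) for t, s in enumerate([1.0, 9.0])]
        assign_bins(entries, 1)
        assert all(e.bin_index == 0 for e in entries)

    def test_bad_bin_count_fatal(self):
        with pytest.raises(ValueError):
            assign_bins([entry(1)], 0)


class TestModePercentile:
    def test_top_bin_keeps_everything(self):
        for mode in MODES:
            for bins in (1, 4, 7):
                assert mode_percentile(bins - 1, bins, mode) == pytest.approx(1.0)

    def test_linear_midpoint(self):
        assert mode_percentile(1, 4, "linear") == pytest.approx(0.5)

    def test_extreme_modes_at_bottom_bin(self):
        assert mode_percentile(0, 4, "very-precise") == pytest.approx(0.015625)
        assert mode_percentile(0, 4, "very-sensitive") == pytest.approx(0.25 ** (1 / 3))

    def test_mode_ordering_per_bin(self):
        for bins in (2, 4, 8):
            for b in range(bins):
                fracs = [mode_percentile(b, bins, m) for m in MODES]
                assert fracs == sorted(fracs)

    def test_monotone_in_bin(self):
        for mode in MODES:
            fracs = [mode_percentile(b, 6, mode) for b in range(6)]
            assert fracs == sorted(fracs)

    def test_unknown_mode_fatal(self):
        with pytest.raises(ValueError):
            mode_percentile(0, 4, "extra-crispy")


class TestFilterBins:
    def test_keeps_top_half_by_abundance(self):
        entries = [entry(t, abundance=float(t + 1), bin_index=1) for t in range(10)]
        cfg = MergeConfig(bins=2, mode="linear", abundance_cutoff=0.0)
        # bin 1 of 2 under linear keeps (1+1)/2 = 1.0; use bin 0 for 0.5
        for e in entries:
            e.bin_index = 0
        out = filter_bins(entries, cfg)
        assert sorted(e.taxid for e in out) == [5, 6, 7, 8, 9]

    def test_keep_fraction_one_keeps_all(self):
        entries = [entry(t, abundance=float(t + 1), bin_index=1) for t in range(7)]
        out = filter_bins(entries, MergeConfig(bins=2, abundance_cutoff=0.0))
        assert len(out) == 7

    def test_cutoff_dominates_top_bin(self):
        entries = [
            entry(1, abundance=50.0, bin_index=3),
            entry(2, abundance=1e-6, bin_index=3),
        ]
        out = filter_bins(entries, MergeConfig(bins=4, abundance_cutoff=1e-4))
        assert [e.taxid for e in out] == [1]

    def test_nonempty_bin_keeps_at_least_one(self):
        entries = [entry(t, abundance=float(t), bin_index=0) for t in range(1, 4)]
        out = filter_bins(entries, MergeConfig(bins=4, mode="very-precise", abundance_cutoff=0.0))
        assert len(out) == 1 and out[0].taxid == 3


def six_tool_fixture():
    """Six tools reporting the same 10 true species plus 5 unique false
    species each, with identical databases covering the true species and
    each tool's own false species."""
    tree = generate_taxonomy(60, seed=11)
    leaves = species_leaves(tree)
    true_species = leaves[:10]
    profiles, dbps = [], []
    for k in range(6):
        fps = leaves[10 + 5 * k : 15 + 5 * k]
        ranks = {t: 10.0 for t in true_species}
        ranks.update({t: 0.01 for t in fps})
        profiles.append(RankedProfile(tool_id=f"t{k}", ranks={"species": ranks}))
        dbps.append(
            DatabaseProfile(
                tool_id=f"t{k}",
                taxa=_ancestor_close({t: 1 for t in true_species + fps}, tree),
            )
        )
    return tree, true_species, profiles, dbps


class TestMergeProfiles:
    def test_single_tool_identity(self, lineage_tree):
        p = RankedProfile(tool_id="t0", ranks={"species": {21: 30.0, 22: 10.0}})
        d = DatabaseProfile(tool_id="t0", taxa={21: None, 22: None})
        final, detailed = merge_profiles([p], [d], MergeConfig(bins=1), lineage_tree)
        assert final.at("species")[21] == pytest.approx(75.0)
        assert final.at("species")[22] == pytest.approx(25.0)
        assert {e.taxid for e in detailed} == {21, 22}

    def test_true_species_survive_false_cut_in_precise_mode(self):
        tree, true_species, profiles, dbps = six_tool_fixture()
        final, detailed = merge_profiles(
            profiles, dbps, MergeConfig(mode="very-precise"), tree
        )
        survivors = set(final.at("species"))
        assert set(true_species) <= survivors
        by_taxid = {e.taxid: e for e in detailed if e.rank == "species"}
        for t in true_species:  # i=6, top bin
            assert by_taxid[t].occurrences == 6
            assert by_taxid[t].bin_index == 3
        false_survivors = survivors - set(true_species)
        # false species: i=1, j=1, score 2 -> low bin, nearly all cut
        assert len(false_survivors) <= 2

    def test_linear_mode_keeps_more_false_than_precise(self):
        tree, true_species, profiles, dbps = six_tool_fixture()
        fp_count = {}
        for mode in ("very-precise", "linear", "very-sensitive"):
            final, _ = merge_profiles(profiles, dbps, MergeConfig(mode=mode), tree)
            fp_count[mode] = len(set(final.at("species")) - set(true_species))
        assert fp_count["very-precise"] <= fp_count["linear"] <= fp_count["very-sensitive"]

    def test_survivor_sets_nested_across_modes(self):
        tree, _, profiles, dbps = six_tool_fixture()
        prev: set[int] | None = None
        for mode in MODES:
            final, _ = merge_profiles(profiles, dbps, MergeConfig(mode=mode), tree)
            current = set(final.at("species"))
            if prev is not None:
                assert prev <= current
            prev = current

    def test_disjoint_tools_identical_databases_degenerate_bin(self, lineage_tree):
        p1 = RankedProfile(tool_id="a", ranks={"species": {21: 100.0}})
        p2 = RankedProfile(tool_id="b", ranks={"species": {22: 100.0}})
        shared = {21: None, 22: None}
        dbps = [DatabaseProfile("a", dict(shared)), DatabaseProfile("b", dict(shared))]
        final, detailed = merge_profiles([p1, p2], dbps, MergeConfig(), lineage_tree)
        sp = [e for e in detailed if e.rank == "species"]
        assert all(e.score == sp[0].score for e in sp)
        assert all(e.bin_index == 3 for e in sp)  # degenerate range -> top bin
        assert set(final.at("species")) == {21, 22}

    def test_conservation_per_rank(self):
        tree, _, profiles, dbps = six_tool_fixture()
        for mode in MODES:
            final, _ = merge_profiles(profiles, dbps, MergeConfig(mode=mode), tree)
            for rank in final.nonempty_ranks():
                assert sum(final.at(rank).values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            merge_profiles([], [], MergeConfig(), None)


class TestMergeConfig:
    def test_defaults(self):
        cfg = MergeConfig()
        assert cfg.bins == 4 and cfg.mode == "linear"
        assert cfg.abundance_cutoff == pytest.approx(1e-4)
        assert cfg.ranks == (
            "superkingdom", "phylum", "class", "order", "family", "genus", "species",
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            MergeConfig(bins=0)
        with pytest.raises(ValueError):
            MergeConfig(mode="nope")
        with pytest.raises(ValueError):
            MergeConfig(ranks=("kingdom",))

    def test_from_file(self, tmp_path):
        cfg_file = tmp_path / "merge.cfg"
        cfg_file.write_text(
            "# comment\nbins: 6\nmode: precise\nabundance_cutoff: 0.01\n"
            "ranks: genus, species\n"
        )
        cfg = MergeConfig.from_file(cfg_file)
        assert cfg.bins == 6 and cfg.mode == "precise"
        assert cfg.abundance_cutoff == pytest.approx(0.01)
        assert cfg.ranks == ("genus", "species")

    def test_pluggable_mode_function(self):
        cfg = MergeConfig(mode_function=lambda b, B: 1.0)
        entries = [entry(t, abundance=float(t), bin_index=0) for t in range(1, 5)]
        assert len(filter_bins(entries, cfg)) == 4
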
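"""Census construction, expansion calling and pathway-matrix reporting."""

import numpy as np
import pandas as pd
import pytest

from metexpand import synth
from metexpand.census import (
    CopyNumberSummary,
    ExpansionCall,
    FunctionalCensus,
    PathwayDefinition,
    build_census,
    call_expansions,
    copy_number_summary,
    group_means,
    pathway_matrix,
)


@pytest.fixture
def small_taxonomy():
    return pd.DataFrame(
        {"genus": ["GenA", "GenA", "GenB"], "suborder": ["SubX", "SubX", "SubX"]},
        index=pd.Index(["g1", "g2", "g3"], name="genome_id"),
    )


class TestBuildCensus:
    def test_counts_features_per_role(self, small_taxonomy):
        ann = pd.DataFrame(
            {
                "genome_id": ["g1", "g1", "g3"],
                "feature_id": ["f1", "f2", "f9"],
                "role": ["pk", "pk", "pfk"],
            }
        )
        census = build_census(ann, small_taxonomy)
        assert census.counts.at["g1", "pk"] == 2
        assert census.counts.at["g2", "pk"] == 0  # absent genome gets zeros
        assert census.counts.at["g3", "pfk"] == 1

    def test_duplicate_rows_deduplicated_with_warning(self, small_taxonomy):
        ann = pd.DataFrame(
            {
                "genome_id": ["g1", "g1"],
                "feature_id": ["f1", "f1"],
                "role": ["pk", "pk"],
            }
        )
        with pytest.warns(UserWarning, match="duplicate"):
            census = build_census(ann, small_taxonomy)
        assert census.counts.at["g1", "pk"] == 1

    def test_genome_without_taxonomy_is_hard_error(self, small_taxonomy):
        ann = pd.DataFrame(
            {"genome_id": ["orphan"], "feature_id": ["f1"], "role": ["pk"]}
        )
        with pytest.raises(ValueError, match="orphan"):
            build_census(ann, small_taxonomy)

    def test_tsv_round_trip_identity(self, tmp_path):
        census = synth.gen_census(synth.CensusSpec(seed=5))
        path = tmp_path / "census.tsv"
        census.write_tsv(path)
        back = FunctionalCensus.read_tsv(path)
        pd.testing.assert_frame_equal(
            census.counts.sort_index(), back.counts[census.counts.columns]
        )
        pd.testing.assert_frame_equal(
            census.taxonomy.sort_index(), back.taxonomy.loc[census.taxonomy.sort_index().index]
        )


class TestGroupMeans:
    def test_arithmetic_mean_per_group(self, small_taxonomy):
        counts = pd.DataFrame({"pk": [1, 3, 5]}, index=small_taxonomy.index)
        census = FunctionalCensus(counts, small_taxonomy)
        means = group_means(census, "genus")
        assert means.at["GenA", "pk"] == 2.0
        assert means.at["GenB", "pk"] == 5.0  # single-genome genus

    def test_suborder_mean_is_genome_weighted_combination(self):
        census = synth.gen_census(synth.CensusSpec(seed=13))
        genus_means = group_means(census, "genus")
        sub_means = group_means(census, "suborder")
        n_per_genus = census.taxonomy.groupby("genus").size()
        genus_sub = census.taxonomy.drop_duplicates("genus").set_index("genus")["suborder"]
        for sub in sub_means.index:
            genera = genus_sub[genus_sub == sub].index
            w = n_per_genus[genera] / n_per_genus[genera].sum()
            expected = (genus_means.loc[genera].T * w).T.sum()
            assert np.allclose(sub_means.loc[sub], expected)

    def test_unknown_level_rejected(self, small_taxonomy):
        counts = pd.DataFrame({"pk": [1, 1, 1]}, index=small_taxonomy.index)
        with pytest.raises(ValueError, match="level"):
            group_means(FunctionalCensus(counts, small_taxonomy), "family")


def _census_from_genus_means(means):
    """One genome per genus, integer counts equal to the target means."""
    tax = pd.DataFrame(
        {
            "genus": [f"G{i}" for i in range(len(means))],
            "suborder": ["S0"] * len(means),
        },
        index=pd.Index([f"g{i}" for i in range(len(means))], name="genome_id"),
    )
    counts = pd.DataFrame({"pk": means}, index=tax.index)
    return FunctionalCensus(counts, tax)


class TestCallExpansions:
    def test_mean_plus_sd_rule_worked_example(self):
        census = _census_from_genus_means([1, 1, 1, 2, 1])
        calls = call_expansions(census, "genus")
        by_group = {c.group: c for c in calls}
        assert by_group["G3"].phylum_mean == pytest.approx(1.2)
        assert by_group["G3"].phylum_sd == pytest.approx(np.sqrt(0.2), abs=1e-12)
        assert [c.group for c in calls if c.flagged] == ["G3"]

    def test_threshold_is_inclusive_at_the_boundary(self):
        census = _census_from_genus_means([2, 2, 2])
        calls = call_expansions(census, "genus")
        assert all(c.flagged for c in calls)  # SD 0: all groups sit at the boundary

    def test_single_group_is_error(self):
        census = _census_from_genus_means([1])
        with pytest.raises(ValueError, match="2 groups"):
            call_expansions(census, "genus")

    def test_invariant_to_genome_and_role_order(self):
        census = synth.gen_census(synth.CensusSpec(seed=17))
        calls = call_expansions(census)
        shuffled = FunctionalCensus(
            census.counts.iloc[::-1, ::-1],
            census.taxonomy.iloc[::-1],
            census.role_catalog,
        )
        calls_shuffled = call_expansions(shuffled)
        key = lambda cs: sorted((c.group, c.role, c.flagged) for c in cs)
        assert key(calls) == key(calls_shuffled)

    def test_monotone_in_group_mean_at_fixed_threshold(self):
        census = _census_from_genus_means([1, 1, 1, 2, 1])
        calls = call_expansions(census)
        threshold = calls[0].phylum_mean + calls[0].phylum_sd
        for c in calls:
            if c.group_mean >= threshold:
                assert c.flagged


def _make_calls(n_genera, suborder, role, n_flagged):
    calls = []
    for i in range(n_genera):
        calls.append(
            ExpansionCall(
                group=f"{suborder}_gen{i}", role=role,
                group_mean=2.0, phylum_mean=1.0, phylum_sd=0.5,
                flagged=i < n_flagged,
            )
        )
    return calls


class TestPathwayMatrix:
    def _taxonomy(self, suborder, n_genera):
        return pd.DataFrame(
            {
                "genus": [f"{suborder}_gen{i}" for i in range(n_genera)],
                "suborder": [suborder] * n_genera,
            },
            index=pd.Index([f"{suborder}_g{i}" for i in range(n_genera)], name="genome_id"),
        )

    def test_percentage_denominator_matches_reference_cells(self):
        # 7 flagged pairs over 3 genera x 10-enzyme pathway -> 23.3%
        pathway = PathwayDefinition("GLY", tuple(f"r{i}" for i in range(10)))
        calls = []
        for i, role in enumerate(pathway.roles):
            calls.extend(_make_calls(3, "SubA", role, 1 if i < 7 else 0))
        matrix = pathway_matrix(calls, [pathway], self._taxonomy("SubA", 3))
        assert matrix.percentages.at["SubA", "GLY"] == pytest.approx(100 * 7 / 30)
        assert matrix.formatted().at["SubA", "GLY"] == 23.3

    def test_two_genera_cell(self):
        # 5 flagged pairs over 2 genera x 10 enzymes -> 25.0%
        pathway = PathwayDefinition("GLY", tuple(f"r{i}" for i in range(10)))
        calls = []
        for i, role in enumerate(pathway.roles):
            calls.extend(_make_calls(2, "SubB", role, 1 if i < 5 else 0))
        matrix = pathway_matrix(calls, [pathway], self._taxonomy("SubB", 2))
        assert matrix.percentages.at["SubB", "GLY"] == pytest.approx(25.0)

    def test_zero_flags_marked_ne(self):
        pathway = PathwayDefinition("GLY", ("r0", "r1"))
        calls = _make_calls(2, "SubC", "r0", 0) + _make_calls(2, "SubC", "r1", 0)
        matrix = pathway_matrix(calls, [pathway], self._taxonomy("SubC", 2))
        assert np.isnan(matrix.percentages.at["SubC", "GLY"])
        assert matrix.formatted().at["SubC", "GLY"] == "NE"

    def test_unknown_pathway_role_is_error(self):
        pathway = PathwayDefinition("GLY", ("missing_role",))
        calls = _make_calls(2, "SubD", "r0", 1)
        with pytest.raises(ValueError, match="unknown roles"):
            pathway_matrix(calls, [pathway], self._taxonomy("SubD", 2))

    def test_entries_bounded(self):
        census = synth.gen_census(
            synth.CensusSpec(
                planted_expansions=(("Genus001", "gly_enzyme_1", 4.0),), seed=2
            )
        )
        calls = call_expansions(census)
        pathway = PathwayDefinition("GLY", tuple(census.roles))
        matrix = pathway_matrix(calls, [pathway], census.taxonomy)
        vals = matrix.percentages.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 100


class TestCopyNumberSummary:
    def test_reference_partition_percentage(self):
        # 302 single-copy genomes of 327 -> 92%
        summary = CopyNumberSummary.from_histogram({1: 302, 2: 25})
        assert summary.n_genomes == 327
        assert summary.single_copy_percent == 92

    def test_multi_copy_histogram(self):
        hist = {1: 3, 2: 281, 3: 2, 4: 1}
        summary = CopyNumberSummary.from_histogram(hist)
        assert summary.histogram == hist
        assert summary.n_genomes == 287

    def test_census_partition(self, ):
        census = synth.gen_census(synth.CensusSpec(seed=1))
        role = census.roles[0]
        summary = copy_number_summary(census, role)
        assert sum(summary.histogram.values()) == summary.n_genomes
        all_single = (census.counts[role] == 1).sum()
        assert summary.histogram.get(1, 0) == all_single

    def test_all_single_copy_is_100_percent(self, small_taxonomy):
        counts = pd.DataFrame({"pk": [1, 1, 1]}, index=small_taxonomy.index)
        census = FunctionalCensus(counts, small_taxonomy)
        assert copy_number_summary(census, "pk").single_copy_percent == 100

    def test_empty_partition_is_error(self, small_taxonomy):
        counts = pd.DataFrame({"pk": [1, 1, 1]}, index=small_taxonomy.index)
        census = FunctionalCensus(counts, small_taxonomy)
        with pytest.raises(ValueError, match="empty"):
            copy_number_summary(census, "pk", partition=[])
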
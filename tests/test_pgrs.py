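import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from barrisk.genotypes import GenotypeMatrix, RiskLocus
from barrisk.pgrs import (
    MissingPolicy,
    PolygenicScoreModel,
    compare_groups,
    compute_pgrs,
    estimate_insample_ors,
)

from conftest import brute_force_mannwhitney_p


def make_matrix(dosages, ors, groups=None):
    """dosages: list of per-sample dosage tuples; ors: per-locus odds ratios."""
    loci = [RiskLocus(f"rs{j}", "A", "G", o) for j, o in enumerate(ors)]
    dosage = pd.DataFrame(
        np.array(dosages, dtype=float),
        index=[f"s{i}" for i in range(len(dosages))],
        columns=[l.snp_id for l in loci],
    )
    groups = groups or {s: "g" for s in dosage.index}
    return GenotypeMatrix(dosage, loci, groups)


class TestComputePgrs:
    def test_hand_computed_score(self):
        matrix = make_matrix([(2, 1, 0)], [2.0, 0.5, 3.0])
        scores = compute_pgrs(matrix, {"rs0": 2.0, "rs1": 0.5, "rs2": 3.0})
        # 2 ln2 + 1 ln(1/2) + 0 ln3 = ln2
        assert scores["score"].iloc[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_zero_dosages_and_unit_ors_score_zero(self):
        matrix = make_matrix([(0, 0, 0), (0, 0, 0)], [2.0, 0.5, 3.0])
        assert (compute_pgrs(matrix, {"rs0": 2.0, "rs1": 0.5, "rs2": 3.0})["score"] == 0).all()
        matrix = make_matrix([(2, 1, 0), (1, 1, 2)], [1.0, 1.0, 1.0])
        assert (compute_pgrs(matrix, {f"rs{j}": 1.0 for j in range(3)})["score"] == 0).all()

    def test_rejects_nonpositive_or_and_empty_panel(self):
        matrix = make_matrix([(1, 1, 1)], [2.0, 0.5, 3.0])
        with pytest.raises(ValueError, match="positive"):
            compute_pgrs(matrix, {"rs0": 0.0, "rs1": 0.5, "rs2": 3.0})
        with pytest.raises(ValueError, match="empty locus set"):
            compute_pgrs(matrix, {})

    def test_frequency_imputation_of_missing(self):
        matrix = make_matrix([(2,), (0,), (np.nan,)], [2.0])
        scores = compute_pgrs(matrix, {"rs0": 2.0})
        # cohort risk-allele frequency over non-missing = 0.5 -> imputed dosage 1
        assert scores.loc["s2", "score"] == pytest.approx(np.log(2))
        assert scores.loc["s2", "n_imputed"] == 1
        omit = compute_pgrs(matrix, {"rs0": 2.0}, missing_policy=MissingPolicy.OMIT_LOCUS)
        assert omit.loc["s2", "score"] == 0.0
        drop = compute_pgrs(matrix, {"rs0": 2.0}, missing_policy=MissingPolicy.OMIT_SAMPLE)
        assert "s2" not in drop.index

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_additivity_over_panel_split(self, data):
        n_loci = data.draw(st.integers(2, 8))
        n_samples = data.draw(st.integers(1, 6))
        ors = data.draw(
            st.lists(st.floats(0.1, 10), min_size=n_loci, max_size=n_loci)
        )
        dosages = data.draw(
            st.lists(
                st.lists(st.sampled_from([0, 1, 2]), min_size=n_loci, max_size=n_loci),
                min_size=n_samples,
                max_size=n_samples,
            )
        )
        matrix = make_matrix(dosages, ors)
        weights = {f"rs{j}": ors[j] for j in range(n_loci)}
        cut = data.draw(st.integers(1, n_loci - 1))
        left = {k: v for k, v in weights.items() if int(k[2:]) < cut}
        right = {k: v for k, v in weights.items() if int(k[2:]) >= cut}
        full = compute_pgrs(matrix.subset_loci(list(weights)), weights)["score"]
        part = (
            compute_pgrs(matrix.subset_loci(list(left)), left)["score"]
            + compute_pgrs(matrix.subset_loci(list(right)), right)["score"]
        )
        assert np.allclose(full, part, atol=1e-10)

    def test_allele_flip_shifts_scores_by_constant(self):
        rng = np.random.default_rng(7)
        ors = [2.0, 0.5, 3.0, 1.2]
        dosages = rng.integers(0, 3, size=(8, 4))
        matrix = make_matrix(dosages.tolist(), ors)
        weights = {f"rs{j}": o for j, o in enumerate(ors)}
        base = compute_pgrs(matrix, weights)["score"]
        flipped_matrix = matrix.flipped()
        flipped_weights = {k: 1.0 / v for k, v in weights.items()}
        flipped = compute_pgrs(flipped_matrix, flipped_weights)["score"]
        shift = flipped - base
        expected = -2.0 * sum(np.log(o) for o in ors)
        assert np.allclose(shift, expected, atol=1e-12)


class TestInsampleOrs:
    @staticmethod
    def cohort_with_counts():
        # cases: 10 het -> a=10, b=10; controls: 5 het + 5 hom-other -> c=5, d=15
        dosages = [(1,)] * 10 + [(1,)] * 5 + [(0,)] * 5
        groups = {f"s{i}": ("case" if i < 10 else "control") for i in range(20)}
        return make_matrix(dosages, [1.5], groups)

    def test_closed_form_or(self):
        table = estimate_insample_ors(self.cohort_with_counts(), "case", "control")
        row = table.loc["rs0"]
        assert row["odds_ratio"] == pytest.approx(3.0)
        assert (row["a"], row["b"], row["c"], row["d"]) == (10, 10, 5, 15)
        assert not row["corrected"]

    def test_equal_frequencies_give_unit_or(self):
        dosages = [(1,)] * 4 + [(1,)] * 4
        groups = {f"s{i}": ("case" if i < 4 else "control") for i in range(8)}
        table = estimate_insample_ors(make_matrix(dosages, [1.5], groups), "case", "control")
        assert table.loc["rs0", "odds_ratio"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        # cases: 5 hom-risk -> a=10, b=0; controls as above -> c=5, d=15
        dosages = [(2,)] * 5 + [(1,)] * 5 + [(0,)] * 5
        groups = {f"s{i}": ("case" if i < 5 else "control") for i in range(15)}
        table = estimate_insample_ors(make_matrix(dosages, [1.5], groups), "case", "control")
        row = table.loc["rs0"]
        assert row["corrected"]
        assert row["odds_ratio"] == pytest.approx((10.5 * 15.5) / (0.5 * 5.5))

    def test_all_missing_group_gives_nan_with_warning(self):
        dosages = [(np.nan,)] * 2 + [(1,)] * 2
        groups = {f"s{i}": ("case" if i < 2 else "control") for i in range(4)}
        with pytest.warns(UserWarning, match="undefined"):
            table = estimate_insample_ors(make_matrix(dosages, [1.5], groups), "case", "control")
        assert np.isnan(table.loc["rs0", "odds_ratio"])

    def test_unknown_group_raises(self, cohort):
        with pytest.raises(ValueError, match="nope"):
            estimate_insample_ors(cohort, "nope", "control")


def score_table(values_by_group):
    rows = []
    for group, values in values_by_group.items():
        for i, v in enumerate(values):
            rows.append((f"{group}{i}", group, float(v)))
    return pd.DataFrame(rows, columns=["sample_id", "group", "score"]).set_index("sample_id")


class TestCompareGroups:
    def test_fully_separated_small_groups(self):
        res = compare_groups(score_table({"a": [1, 2, 3], "b": [4, 5, 6]}), ["a", "b"])
        row = res.pairwise.iloc[0]
        assert row["u_statistic"] == 0.0
        assert row["p_value"] == pytest.approx(0.1)
        assert row["method"] == "exact"

    def test_identical_groups_give_p_one(self):
        res = compare_groups(score_table({"a": [1, 2, 3], "b": [1, 2, 3]}), ["a", "b"])
        row = res.pairwise.iloc[0]
        assert row["u_statistic"] == pytest.approx(4.5)  # mid-value nm/2
        assert row["p_value"] == pytest.approx(1.0)

    def test_separated_groups_match_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(score_table({"a": x, "b": y}), ["a", "b"])
        assert res.pairwise.iloc[0]["p_value"] == pytest.approx(brute_force_mannwhitney_p(x, y))

    def test_ties_fall_back_to_normal_approximation(self):
        res = compare_groups(score_table({"a": [1, 1, 2], "b": [1, 2, 3]}), ["a", "b"])
        assert res.pairwise.iloc[0]["method"] == "normal-approximation-with-tie-correction"

    def test_pairwise_covers_all_pairs_once(self):
        res = compare_groups(
            score_table({"a": [1, 2], "b": [3, 4], "c": [5, 6]}), ["a", "b", "c"]
        )
        pairs = set(map(tuple, res.pairwise[["group_a", "group_b"]].to_numpy()))
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}
        assert 0 <= res.omnibus_p <= 1

    def test_absent_group_named_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            compare_groups(score_table({"a": [1], "b": [2]}), ["a", "ghost"])

    def test_bonferroni_scales_p(self):
        table = score_table({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        raw = compare_groups(table, ["a", "b", "c"])
        adj = compare_groups(table, ["a", "b", "c"], bonferroni=True)
        assert np.allclose(
            adj.pairwise["p_value"], np.minimum(1.0, raw.pairwise["p_value"] * 3)
        )

    def test_omnibus_null_calibration(self):
        """Kruskal-Wallis p under the null is approximately uniform."""
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            table = score_table(
                {"a": rng.normal(size=10), "b": rng.normal(size=10), "c": rng.normal(size=10)}
            )
            if compare_groups(table, ["a", "b", "c"]).omnibus_p < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 0.035


class TestModelSurface:
    def test_literature_fit_summary_and_medians(self, cohort):
        res = PolygenicScoreModel(cohort, or_source="literature").fit(
            compare=["case", "control"]
        )
        assert set(res.median_by_group().index) == {"case", "control"}
        text = res.summary()
        assert "literature" in text and "Kruskal-Wallis" in text

    def test_in_sample_fit_uses_estimated_weights(self, cohort):
        res = PolygenicScoreModel(
            cohort, or_source="in_sample", case_group="case", control_group="control"
        ).fit()
        assert res.association is not None
        assert set(res.weights) <= set(cohort.locus_ids)
        assert (res.scores["or_source"] == "in_sample").all()

    def test_score_plot_renders(self, cohort):
        import matplotlib

        matplotlib.use("Agg")
        res = PolygenicScoreModel(cohort).fit()
        ax = res.plot()
        assert len(ax.get_xticklabels()) == 2

    def test_in_sample_requires_group_labels(self, cohort):
        with pytest.raises(ValueError, match="case_group"):
            PolygenicScoreModel(cohort, or_source="in_sample")
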
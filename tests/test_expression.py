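import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from barrisk.expression import (
    ExpressionMatrix,
    differential_expression,
    expression_floor,
    normalize,
    pca_qc,
    read_count_table,
    subtract_baseline,
    write_count_table,
)

from conftest import brute_force_bh


def make_matrix(counts, lengths, conditions):
    genes = [f"g{i}" for i in range(len(counts))]
    samples = list(conditions)
    df = pd.DataFrame(np.array(counts), index=genes, columns=samples)
    return ExpressionMatrix(df, pd.Series([float(x) for x in lengths], index=genes), conditions)


class TestNormalize:
    def test_single_gene_tpm_is_point_mass(self):
        m = normalize(make_matrix([[7]], [1234], {"s1": "a"}))
        assert m.tpm.iloc[0, 0] == pytest.approx(1_000_000)

    def test_equal_genes_split_tpm_evenly(self):
        m = normalize(make_matrix([[10], [10]], [500, 500], {"s1": "a"}))
        assert list(m.tpm["s1"]) == pytest.approx([500_000, 500_000])

    def test_length_weighted_rates(self):
        m = normalize(make_matrix([[10], [10]], [1000, 2000], {"s1": "a"}))
        assert m.tpm["s1"].to_list() == pytest.approx([2e6 / 3, 1e6 / 3])
        # RPKM = count * 1e9 / (length * library size); library = 20
        assert m.rpkm["s1"].to_list() == pytest.approx([5e5, 2.5e5])

    def test_zero_library_sample_named(self):
        with pytest.raises(ValueError, match="s2"):
            normalize(make_matrix([[1, 0]], [100], {"s1": "a", "s2": "a"}))

    @settings(max_examples=25, deadline=None)
    @given(
        counts=st.lists(
            st.lists(st.integers(0, 1000), min_size=2, max_size=2),
            min_size=2,
            max_size=20,
        ).filter(lambda rows: all(sum(col) > 0 for col in zip(*rows)))
    )
    def test_tpm_sums_to_one_million(self, counts):
        lengths = [100 + 37 * i for i in range(len(counts))]
        m = normalize(make_matrix(counts, lengths, {"s1": "a", "s2": "b"}))
        assert np.allclose(m.tpm.sum(axis=0), 1e6, atol=1e-3)


class TestExpressionFloor:
    def test_boundary_is_inclusive(self):
        m = make_matrix([[1], [1]], [100, 100], {"s1": "a"})
        normalize(m)
        m.rpkm = pd.DataFrame({"s1": [2.0, 1.999]}, index=m.genes)
        assert expression_floor(m, 2.0) == ["g0"]

    def test_zero_count_gene_excluded_threshold_zero_keeps_all(self):
        m = normalize(make_matrix([[0], [10]], [100, 100], {"s1": "a"}))
        assert expression_floor(m, 0.5) == ["g1"]
        assert expression_floor(m, 0.0) == ["g0", "g1"]


def two_group_matrix(mean_a, mean_b, n=4, noise=0.01, seed=0):
    """Genes at given RPKM-scale means; tiny noise keeps tests deterministic."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(len(mean_a))]
    cond = {f"a{i}": "A" for i in range(n)} | {f"b{i}": "B" for i in range(n)}
    data = {}
    for i in range(n):
        data[f"a{i}"] = np.array(mean_a) * (1 + rng.normal(0, noise, len(genes)))
        data[f"b{i}"] = np.array(mean_b) * (1 + rng.normal(0, noise, len(genes)))
    m = make_matrix(np.zeros((len(genes), 2 * n), dtype=int), [1000] * len(genes), cond)
    layer = pd.DataFrame(data, index=genes)[list(cond)]
    m.rpkm = layer
    m.tpm = layer
    return m


class TestDifferentialExpression:
    def test_three_criterion_rule(self):
        m = two_group_matrix(
            mean_a=[10.0, 1.9, 3.0, 10.0],
            mean_b=[1.0, 1.0, 2.5, 9.0],
        )
        table = differential_expression(m, "A", "B")
        # strong FC, high mean, tiny p -> pass
        assert table.loc["g0", "pass"]
        # max group mean 1.9 <= 2 -> fail regardless of p
        assert not table.loc["g1", "pass"]
        # FC 1.2 < 1.5 -> fail
        assert not table.loc["g2", "pass"]
        assert table.loc["g2", "fold_change"] == pytest.approx(1.2, rel=0.05)
        # FC ~10/9 also fails
        assert not table.loc["g3", "pass"]
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()

    def test_zero_mean_gene_gets_infinite_fold_change(self):
        m = two_group_matrix(mean_a=[5.0, 5.0], mean_b=[0.0, 1.0])
        table = differential_expression(m, "A", "B")
        assert np.isinf(table.loc["g0", "fold_change"])
        assert table.loc["g0", "direction"] == "up"

    def test_direction_is_relative_to_first_group(self):
        m = two_group_matrix(mean_a=[10.0, 1.0], mean_b=[1.0, 10.0])
        table = differential_expression(m, "A", "B")
        assert table.loc["g0", "direction"] == "up"
        assert table.loc["g1", "direction"] == "down"

    def test_small_group_rejected(self):
        m = two_group_matrix(mean_a=[5.0], mean_b=[1.0], n=4)
        m.condition_of[:] = ["A"] + ["B"] * 7
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(m, "A", "B")

    def test_threshold_monotonicity(self):
        """Loosening any threshold never loses passing genes."""
        rng = np.random.default_rng(5)
        means_a = rng.lognormal(1, 1.5, 60)
        means_b = means_a * rng.choice([1.0, 1.4, 2.0, 4.0], 60)
        m = two_group_matrix(means_a.tolist(), means_b.tolist(), n=5, noise=0.2, seed=6)
        strict = differential_expression(m, "A", "B")
        for kwargs in (
            {"max_mean_threshold": 1.0},
            {"fc_threshold": 1.2},
            {"q_threshold": 0.2},
        ):
            loose = differential_expression(m, "A", "B", **kwargs)
            assert strict["pass"].sum() <= loose["pass"].sum()
            assert set(strict.index[strict["pass"]]) <= set(loose.index[loose["pass"]])

    def test_ranksum_alternative_runs(self):
        m = two_group_matrix(mean_a=[10.0, 2.0], mean_b=[1.0, 2.0], n=5)
        table = differential_expression(m, "A", "B", test="ranksum")
        assert table.loc["g0", "p_value"] < table.loc["g1", "p_value"]


class TestBenjaminiHochberg:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 300))
            _, q, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, brute_force_bh(p), atol=1e-12)


class TestSubtraction:
    def test_named_example(self):
        report = subtract_baseline({"g1", "g2", "g3", "g4", "g5"}, {"g2", "g4"})
        assert report.remaining == {"g1", "g3", "g5"}
        assert (report.n_exposed, report.n_baseline, report.n_intersection, report.n_remaining) == (5, 2, 2, 3)

    def test_identity_and_annihilation(self):
        a = {"x", "y"}
        assert subtract_baseline(a, set()).remaining == a
        assert subtract_baseline(a, a).remaining == set()

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    def test_size_arithmetic(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        r = subtract_baseline(a, b)
        assert r.n_remaining + r.n_intersection == r.n_exposed


class TestPcaQc:
    def test_duplicated_profiles_share_coordinates(self):
        rng = np.random.default_rng(0)
        profile = rng.lognormal(2, 1, 50)
        counts = np.column_stack([profile, profile, rng.lognormal(2, 1, 50)]).astype(int) + 1
        m = normalize(make_matrix(counts, [1000] * 50, {"s1": "a", "s2": "a", "s3": "a"}))
        report = pca_qc(m, k=2)
        assert np.allclose(report.coordinates.loc["s1"], report.coordinates.loc["s2"], atol=1e-8)
        assert np.all(np.diff(report.variance_explained) <= 1e-12)
        assert report.variance_explained.sum() <= 1 + 1e-9

    def test_planted_outlier_flagged_among_clones(self):
        rng = np.random.default_rng(1)
        profile = rng.lognormal(3, 1, 200)
        cols = {f"s{i}": (profile * (1 + rng.normal(0, 0.01, 200))).astype(int) for i in range(11)}
        cols["odd"] = rng.permutation(profile).astype(int)
        cond = {s: "a" for s in cols}
        m = normalize(make_matrix(np.column_stack(list(cols.values())), [1000] * 200, cond))
        m.raw_counts.columns = list(cols)
        m.rpkm.columns = list(cols)
        m.tpm.columns = list(cols)
        report = pca_qc(m, k=2)
        assert report.flagged() == ["odd"]

    def test_k_must_be_below_sample_count(self):
        m = normalize(make_matrix([[1, 2, 3], [4, 5, 6]], [100, 100], {"s1": "a", "s2": "a", "s3": "a"}))
        with pytest.raises(ValueError, match="k="):
            pca_qc(m, k=3)


class TestCountTableIO:
    def test_round_trip(self, tmp_path):
        m = make_matrix([[3, 4], [5, 6]], [100, 200], {"s1": "a", "s2": "b"})
        path = tmp_path / "counts.tsv"
        write_count_table(m, path)
        back = read_count_table(path, {"s1": "a", "s2": "b"})
        pd.testing.assert_frame_equal(back.raw_counts, m.raw_counts)
        assert back.gene_lengths.to_list() == m.gene_lengths.to_list()

    def test_missing_length_column_rejected(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("gene\ts1\ng0\t5\n")
        with pytest.raises(ValueError, match="gene_length"):
            read_count_table(path, {"s1": "a"})
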
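"""CPM/FPKM, expression filter, detection and concordance metrics."""

import numpy as np
import pandas as pd
import pytest

from covdrift.expression import (
    CountsMatrix,
    cpm,
    detection_counts,
    filter_low_expression,
    fpkm,
    proportion_assigned,
    source_concordance,
)


def make_matrix(counts: dict, lengths: dict, biotypes: dict | None = None):
    df = pd.DataFrame(counts).T
    df.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "length_nt": pd.Series(lengths),
            "biotype": pd.Series(biotypes or {g: "protein_coding" for g in lengths}),
        }
    )
    return CountsMatrix(df, meta)


class TestNormalization:
    def test_cpm_definition_and_conservation(self):
        m = make_matrix(
            {"g1": {"s1": 10, "s2": 0}, "g2": {"s1": 999_990, "s2": 100}},
            {"g1": 1000, "g2": 1000},
        )
        c = cpm(m)
        assert c.loc["g1", "s1"] == pytest.approx(10.0)
        assert c.loc["g1", "s2"] == 0.0
        np.testing.assert_allclose(c.sum(axis=0), 1e6, rtol=1e-9)

    def test_fpkm_definition(self):
        m = make_matrix(
            {"g1": {"s1": 100}, "g2": {"s1": 999_900}}, {"g1": 1000, "g2": 1000}
        )
        assert fpkm(m).loc["g1", "s1"] == pytest.approx(100.0)

    def test_doubling_length_halves_fpkm_not_cpm(self):
        counts = {"g1": {"s1": 100}, "g2": {"s1": 100}}
        short = make_matrix(counts, {"g1": 1000, "g2": 1000})
        long = make_matrix(counts, {"g1": 2000, "g2": 1000})
        assert fpkm(long).loc["g1", "s1"] == pytest.approx(
            fpkm(short).loc["g1", "s1"] / 2
        )
        assert cpm(long).loc["g1", "s1"] == cpm(short).loc["g1", "s1"]

    def test_fpkm_hand_example(self):
        # 50 fragments, 500 nt, 2M library -> 50 / (0.5 kb * 2) = 50
        m = make_matrix(
            {"g1": {"s1": 50}, "g2": {"s1": 1_999_950}}, {"g1": 500, "g2": 1000}
        )
        assert fpkm(m).loc["g1", "s1"] == pytest.approx(50.0)

    def test_zero_library_size_names_sample(self):
        m = make_matrix({"g1": {"s1": 1, "s2": 0}}, {"g1": 100})
        with pytest.raises(ValueError, match="s2"):
            cpm(m)


class TestFilter:
    def build(self, pass_samples_per_gene, n_samples=30):
        """Genes engineered to exceed CPM=FPKM=1 in a chosen number of samples."""
        rows = {}
        for gi, k in enumerate(pass_samples_per_gene):
            # high count in k samples, zero elsewhere
            rows[f"g{gi}"] = {f"s{j}": (500 if j < k else 0) for j in range(n_samples)}
        # ballast gene keeps library sizes comparable in every sample
        rows["ballast"] = {f"s{j}": 100_000 for j in range(n_samples)}
        lengths = {g: 1000 for g in rows}
        return make_matrix(rows, lengths)

    def test_boundary_exactly_five_samples_retained(self):
        m = self.build([5, 4, 6, 0])
        res = filter_low_expression(m)
        assert "g0" in res.retained and "g2" in res.retained
        assert "g1" in res.dropped and "g3" in res.dropped

    def test_conjunction_fpkm_and_cpm(self):
        # long transcript: CPM > 1 in 10 samples but FPKM > 1 in none
        counts = {"g1": {f"s{j}": (200 if j < 10 else 0) for j in range(30)},
                  "ballast": {f"s{j}": 1_000_000 for j in range(30)}}
        m = make_matrix(counts, {"g1": 1_000_000, "ballast": 1000})
        res = filter_low_expression(m)
        assert "g1" in res.dropped

    def test_exactly_one_is_not_greater_than_one(self):
        # engineer CPM == 1 exactly: count 1 in library of 1e6
        counts = {"g1": {f"s{j}": 1 for j in range(30)},
                  "ballast": {f"s{j}": 999_999 for j in range(30)}}
        m = make_matrix(counts, {"g1": 1000, "ballast": 1000})
        c = cpm(m)
        assert (c.loc["g1"] == 1.0).all()
        assert "g1" in filter_low_expression(m).dropped

    def test_monotone_in_counts(self, rng):
        base = rng.integers(0, 50, size=(12, 8))
        extra = base + rng.integers(0, 20, size=base.shape)
        for arr_lo, arr_hi in [(base, extra)]:
            mk = lambda a: CountsMatrix(
                pd.DataFrame(a, index=[f"g{i}" for i in range(12)],
                             columns=[f"s{j}" for j in range(8)]),
                pd.DataFrame({"length_nt": 500, "biotype": "protein_coding"},
                             index=[f"g{i}" for i in range(12)]),
            )
            lo = filter_low_expression(mk(arr_lo), min_samples=3)
            hi = filter_low_expression(mk(arr_hi), min_samples=3)
            assert lo.retained <= hi.retained

    def test_invariant_to_row_and_column_order(self, rng):
        arr = rng.integers(0, 2000, size=(10, 8))
        genes = [f"g{i}" for i in range(10)]
        samples = [f"s{j}" for j in range(8)]
        meta = pd.DataFrame({"length_nt": 800, "biotype": "protein_coding"},
                            index=genes)
        m1 = CountsMatrix(pd.DataFrame(arr, index=genes, columns=samples), meta)
        perm_g = list(rng.permutation(genes))
        perm_s = list(rng.permutation(samples))
        m2 = CountsMatrix(
            pd.DataFrame(arr, index=genes, columns=samples).loc[perm_g, perm_s], meta
        )
        assert (filter_low_expression(m1, min_samples=3).retained
                == filter_low_expression(m2, min_samples=3).retained)

    def test_per_biotype_tallies(self):
        m = make_matrix(
            {"g1": {f"s{j}": 500 for j in range(6)},
             "g2": {f"s{j}": 500 for j in range(6)},
             "g3": {f"s{j}": 0 for j in range(6)}},
            {"g1": 1000, "g2": 1000, "g3": 1000},
            {"g1": "protein_coding", "g2": "lncRNA", "g3": "pseudogene"},
        )
        res = filter_low_expression(m)
        assert res.per_biotype_retained["protein_coding"] == 1
        assert res.per_biotype_retained["lncRNA"] == 1
        assert res.per_biotype_retained["pseudogene"] == 0


class TestDetectionAndAssignment:
    def test_detection_pre_and_post_filter(self):
        m = make_matrix(
            {"g1": {"s1": 5, "s2": 0}, "g2": {"s1": 0, "s2": 0},
             "g3": {"s1": 2, "s2": 2}},
            {"g1": 100, "g2": 100, "g3": 100},
        )
        res = filter_low_expression(m, min_samples=1)
        det = detection_counts(m, res).set_index("sample_id")
        assert det.loc["s1", "detected_pre"] == 2
        assert det.loc["s2", "detected_pre"] == 1
        assert (det["detected_post"] <= det["detected_pre"]).all()

    def test_proportion_assigned_values_and_bounds(self):
        r = proportion_assigned({"a": 15_000_000, "b": 0, "c": 12_000_000},
                                {"a": 30_000_000, "b": 5, "c": 30_000_000})
        assert r["a"] == pytest.approx(0.5)
        assert r["b"] == 0.0
        assert r["c"] == pytest.approx(0.4)

    def test_proportion_scale_invariant(self):
        r1 = proportion_assigned({"a": 3}, {"a": 10})
        r2 = proportion_assigned({"a": 3_000_000}, {"a": 10_000_000})
        assert r1["a"] == r2["a"]

    def test_assigned_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="assigned"):
            proportion_assigned({"a": 11}, {"a": 10})


class TestConcordance:
    def test_identical_columns_give_unit_correlation(self):
        m = make_matrix(
            {f"g{i}": {"a": 10 * i + 1, "b": 10 * i + 1, "c": 5}
             for i in range(20)},
            {f"g{i}": 500 for i in range(20)},
        )
        r = source_concordance(m, {"subj1": ("a", "b")})
        assert r["subj1"] == pytest.approx(1.0)

    def test_technical_replicates_exceed_0_99(self, rng):
        # shared expected abundances, independent Poisson sampling per column
        mu = np.exp(rng.uniform(np.log(1), np.log(5000), size=2000))
        cols = {s: rng.poisson(mu * 20) for s in ("jugular", "coccygeal")}
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(2000)])
        meta = pd.DataFrame({"length_nt": 1000, "biotype": "protein_coding"},
                            index=counts.index)
        r = source_concordance(
            CountsMatrix(counts, meta), {"subj": ("jugular", "coccygeal")}
        )
        assert r["subj"] > 0.99

    def test_anticorrelated_toy_is_negative(self):
        vals = np.arange(10) * 100 + 1
        m = make_matrix(
            {f"g{i}": {"a": int(vals[i]), "b": int(vals[::-1][i])}
             for i in range(10)},
            {f"g{i}": 500 for i in range(10)},
        )
        assert source_concordance(m, {"s": ("a", "b")})["s"] < 0

    def test_missing_pair_member_rejected(self):
        m = make_matrix({"g1": {"a": 1}}, {"g1": 100})
        with pytest.raises(KeyError, match="b"):
            source_concordance(m, {"s": ("a", "b")})
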
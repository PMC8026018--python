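"""Normalization, per-gene testing and the signature filter chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fibropath import diffexpr


def _welch_by_hand(a, b):
    """Textbook Welch statistic and two-sided p, independent of scipy."""
    import math

    from scipy.stats import t as tdist

    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, 2 * tdist.sf(abs(t), df)


class TestQuantileNormalize:
    def test_hand_example_two_columns(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = diffexpr.quantile_normalize(m)
        expected = [2.5, 3.5, 4.5]
        assert np.allclose(sorted(out["s1"]), expected)
        assert np.allclose(sorted(out["s2"]), expected)

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(diffexpr.quantile_normalize(m), m)

    @settings(derandomize=True, max_examples=25)
    @given(
        arrays(
            float,
            (8, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_idempotent_and_columns_share_multiset(self, values):
        m = pd.DataFrame(values, columns=list("abcd"))
        once = diffexpr.quantile_normalize(m)
        twice = diffexpr.quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())
        cols = [np.sort(once[c].to_numpy()) for c in once.columns]
        for c in cols[1:]:
            assert np.array_equal(cols[0], c)

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            diffexpr.quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestNormalizeAndTest:
    def _toy(self, shift=0.0, seed=0, n=10, sd=0.1):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        samples = [f"c{i}" for i in range(n)] + [f"k{i}" for i in range(n)]
        base = rng.uniform(5, 9, size=(20, 1))
        vals = base + rng.normal(0, sd, size=(20, 2 * n))
        vals[0, :n] += shift
        groups = pd.Series(["case"] * n + ["control"] * n, index=samples)
        return pd.DataFrame(vals, index=genes, columns=samples), groups

    def test_flat_gene_logfc_zero_p_one(self):
        m, g = self._toy()
        m.iloc[5] = 7.0  # identical in both groups
        out = diffexpr.normalize_and_test(m, g).set_index("gene")
        assert out.loc["g5", "logFC"] == pytest.approx(0.0)
        assert out.loc["g5", "p"] == pytest.approx(1.0)

    def test_planted_shift_detected_and_matches_hand_welch(self):
        m, g = self._toy(shift=2.0, seed=1)
        out = diffexpr.normalize_and_test(m, g).set_index("gene")
        assert out.loc["g0", "p"] < 1e-3
        a = m.loc["g0", g[g == "case"].index].to_numpy()
        b = m.loc["g0", g[g == "control"].index].to_numpy()
        _, p_hand = _welch_by_hand(a, b)
        assert out.loc["g0", "p"] == pytest.approx(p_hand, rel=1e-9)
        assert out.loc["g0", "logFC"] == pytest.approx(a.mean() - b.mean())

    def test_swapping_groups_negates_logfc(self):
        m, g = self._toy(shift=1.0, seed=2)
        swapped = g.map({"case": "control", "control": "case"})
        a = diffexpr.normalize_and_test(m, g).set_index("gene")["logFC"]
        b = diffexpr.normalize_and_test(m, swapped).set_index("gene")["logFC"]
        assert np.allclose(a, -b)

    def test_log2_unnormalized_roundtrip(self):
        m, g = self._toy(shift=2.0, seed=3)
        out = diffexpr.normalize_and_test(m, g, log2_state="log2_unnormalized")
        assert out.set_index("gene").loc["g0", "p"] < 0.01

    def test_counts_platform_end_to_end(self):
        from fibropath import synthdata

        ds, truth = synthdata.generate_expression_dataset(
            n_genes=200, platform="counts", effect_size=3.0, noise_sd=0.1,
            frac_de=0.1, seed=8,
        )
        out = diffexpr.normalize_and_test(
            ds.values, ds.groups, platform="counts"
        )
        sig = set(out[out["p"] < 0.05]["gene"])
        planted = truth.de_gene_ids()
        assert len(planted & sig) / len(planted) >= 0.8


class TestCpmFilter:
    def _counts(self, rows, lib=1_000_000):
        genes = [f"g{i}" for i in range(len(rows))]
        df = pd.DataFrame(rows, index=genes, columns=["c1", "c2", "k1", "k2"])
        # pad library to the requested size with a filler gene
        filler = pd.DataFrame(
            [np.maximum(lib - df.sum(axis=0), 0)], index=["filler"]
        )
        g = pd.Series(
            ["case", "case", "control", "control"], index=df.columns
        )
        return pd.concat([df, filler]), g

    def test_all_zero_gene_removed(self):
        m, g = self._counts([[0, 0, 0, 0], [10, 10, 10, 10]])
        out = diffexpr.cpm_filter(m, g)
        assert "g0" not in out.index and "g1" in out.index

    def test_cpm_one_in_both_groups_kept(self):
        m, g = self._counts([[1, 1, 2, 2]])
        assert "g0" in diffexpr.cpm_filter(m, g).index

    def test_passing_in_only_one_group_removed(self):
        m, g = self._counts([[5, 5, 0, 0]])
        assert "g0" not in diffexpr.cpm_filter(m, g).index

    def test_zero_library_rejected(self):
        m = pd.DataFrame(
            {"c1": [0, 0], "c2": [1, 1], "k1": [1, 1], "k2": [1, 1]}
        )
        g = pd.Series(["case", "case", "control", "control"], index=m.columns)
        with pytest.raises(ValueError):
            diffexpr.cpm_filter(m, g)


class TestTmmFactors:
    def test_identical_libraries_all_one(self):
        m = pd.DataFrame(
            np.tile([[10], [200], [35], [90]], (1, 3)),
            columns=["a", "b", "c"],
        )
        f = diffexpr.tmm_factors(m)
        assert np.allclose(f, 1.0)

    def test_pure_depth_change_factor_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 500, size=100)
        m = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        f = diffexpr.tmm_factors(m)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_geometric_mean_one_invariant(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.integers(0, 1000, size=(200, 5)),
            columns=list("abcde"),
        )
        f = diffexpr.tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_two_sample_trimmed_mean_matches_brute_force(self):
        """Step-by-step M/A trimming on a small table, recomputed inline."""
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 400, size=(18, 2)).astype(float)
        counts[:4, 0] *= 6  # composition shift on a minority of genes
        m = pd.DataFrame(counts, columns=["obs", "ref"])
        lib = counts.sum(axis=0)

        po, pr = counts[:, 0] / lib[0], counts[:, 1] / lib[1]
        M = np.log2(po / pr)
        A = 0.5 * np.log2(po * pr)
        w = (lib[0] - counts[:, 0]) / (lib[0] * counts[:, 0]) + (
            lib[1] - counts[:, 1]
        ) / (lib[1] * counts[:, 1])
        n = len(M)
        keep = np.ones(n, bool)
        for vals, frac in ((M, 0.3), (A, 0.05)):
            order = np.argsort(np.argsort(vals, kind="stable"), kind="stable") + 1
            lo = np.floor(n * frac) + 1
            keep &= (order >= lo) & (order <= n + 1 - lo)
        expected_log = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])

        f = diffexpr.tmm_factors(m)
        # factors are rescaled to geometric mean 1; recover the pair ratio
        ratio = f["obs"] / f["ref"]
        assert np.log2(ratio) == pytest.approx(expected_log, rel=1e-9)


class TestExtractSignature:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "logFC", "p"])

    def test_dual_sign_probes_excluded(self):
        t = self._table([("gA", 1.0, 0.01), ("gA", -1.0, 0.01), ("gB", 2.0, 0.01)])
        sig = diffexpr.extract_signature(t)
        assert "gA" not in sig.over + sig.under
        assert sig.over == ["gB"]

    def test_lowest_p_duplicate_retained(self):
        t = self._table([("gA", 1.0, 0.01), ("gA", 3.0, 0.001)])
        sig = diffexpr.extract_signature(t)
        assert sig.provenance.set_index("gene").loc["gA", "p"] == 0.001

    def test_insignificant_rows_dropped_before_duplicate_resolution(self):
        # the p=.20 negative probe must not trigger the dual-sign rule
        t = self._table([("gA", 1.0, 0.01), ("gA", -1.0, 0.20)])
        sig = diffexpr.extract_signature(t)
        assert sig.over == ["gA"]

    def test_top_n_cap_matches_sort_oracle(self, rng):
        genes = [f"g{i:04d}" for i in range(300)]
        fc = rng.normal(0, 2, size=300)
        fc[fc == 0] = 1.0
        t = self._table(list(zip(genes, fc, np.full(300, 0.01))))
        sig = diffexpr.extract_signature(t, top_n=150)
        over = sorted(
            [(g, f) for g, f in zip(genes, fc) if f > 0],
            key=lambda kv: (-abs(kv[1]), kv[0]),
        )
        assert sig.over == [g for g, _ in over[:150]]
        assert len(sig.over) <= 150 and len(sig.under) <= 150

    def test_empty_after_filter_is_empty_signature(self):
        t = self._table([("gA", 1.0, 0.5)])
        sig = diffexpr.extract_signature(t)
        assert sig.over == [] and sig.under == []

    def test_over_under_disjoint(self, rng):
        genes = rng.choice([f"g{i}" for i in range(50)], size=120)
        t = self._table(
            list(zip(genes, rng.normal(0, 1, 120), rng.uniform(0, 0.04, 120)))
        )
        sig = diffexpr.extract_signature(t)
        assert not set(sig.over) & set(sig.under)


class TestAggregate:
    def test_union_across_experiments(self):
        s1 = diffexpr.GeneSignature("d", ["gA"], ["gX"], ["e1"])
        s2 = diffexpr.GeneSignature("d", ["gB"], ["gX"], ["e2"])
        agg = diffexpr.aggregate_signatures([s1, s2], "d")
        assert set(agg.over) == {"gA", "gB"}
        assert agg.under == ["gX"]
        assert agg.source_experiments == ["e1", "e2"]
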
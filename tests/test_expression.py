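"""Comparative-Ct arithmetic and the group-comparison statistical cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phyloarray as pa
from phyloarray import expression


def _ct_table(rows):
    """rows: (sample, group, gene, mean_ct) -> triplicate long table."""
    records = [
        {"sample_id": s, "group": g, "gene": gene, "replicate": r, "ct": ct}
        for (s, g, gene, ct) in rows
        for r in (1, 2, 3)
    ]
    return pd.DataFrame.from_records(records)


class TestRelativeQuantity:
    def test_hand_computed_rq(self):
        # calibrator dCt = 9 (HC), target sample dCt = 25 - 15 = 10 -> RQ 0.5
        ct = _ct_table(
            [
                ("hc1", "HC", "18S", 16.0), ("hc1", "HC", "IL-10", 25.0),
                ("cd1", "CD", "18S", 15.0), ("cd1", "CD", "IL-10", 25.0),
            ]
        )
        rq = expression.relative_quantity(ct, calibrator="HC")
        cd = rq[rq["sample_id"] == "cd1"].iloc[0]
        assert cd["delta_ct"] == pytest.approx(10.0)
        assert cd["delta_delta_ct"] == pytest.approx(1.0)
        assert cd["rq"] == pytest.approx(0.5)
        hc = rq[rq["sample_id"] == "hc1"].iloc[0]
        assert hc["rq"] == pytest.approx(1.0)  # calibrator cohort centers at 1

    def test_rq_invariant_to_constant_ct_offset_per_sample(self):
        ct = _ct_table(
            [
                ("a", "HC", "18S", 15.0), ("a", "HC", "g", 24.0),
                ("b", "CD", "18S", 14.0), ("b", "CD", "g", 26.0),
            ]
        )
        shifted = ct.copy()
        shifted.loc[shifted["sample_id"] == "b", "ct"] += 3.0  # more input cDNA
        rq1 = expression.relative_quantity(ct)
        rq2 = expression.relative_quantity(shifted)
        np.testing.assert_allclose(rq1["rq"], rq2["rq"])

    def test_missing_control_gene_fails(self):
        ct = _ct_table([("a", "HC", "g", 24.0)])
        with pytest.raises(ValueError, match="18S"):
            expression.relative_quantity(ct)

    def test_noisy_replicates_flagged(self):
        ct = _ct_table([("a", "HC", "18S", 15.0), ("a", "HC", "g", 24.0)])
        ct.loc[(ct["gene"] == "g") & (ct["replicate"] == 3), "ct"] += 2.0
        rq = expression.relative_quantity(ct)
        assert rq["high_replicate_sd"].iloc[0]

    def test_rq_ratio_equals_two_to_minus_ddct_difference(self, null_cohort):
        _, meta, _ = null_cohort
        ct = pa.simulate_ct_table(
            meta, ["18S", "IL-10", "IFN-g"],
            shifts={("CD", "IL-10"): -1.0, ("CD", "IFN-g"): -3.0}, seed=2,
        )
        rq = expression.relative_quantity(ct)
        ratio = expression.rq_ratio(rq, "IL-10", "IFN-g")
        wide = rq.pivot(index="sample_id", columns="gene", values="delta_delta_ct")
        expected = 2.0 ** (-(wide["IL-10"] - wide["IFN-g"]))
        np.testing.assert_allclose(ratio, expected)


class TestBHAdjust:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            expression.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_edge_cases(self):
        assert expression.bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(expression.bh_adjust([1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            expression.bh_adjust([0.5, 1.5])

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.uniform(size=12))
        adj = expression.bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


class TestGatedGroupTest:
    def _values(self, shift_tcd=0.0, dist="normal", seed=0, n=8):
        rng = np.random.default_rng(seed)
        groups, values = [], []
        for g, mu in (("HC", 0.0), ("CD", 0.0), ("T-CD", shift_tcd)):
            groups += [g] * n
            noise = rng.standard_cauchy(n) if dist == "cauchy" else rng.normal(size=n)
            values += list(mu + noise)
        idx = [f"s{i}" for i in range(3 * n)]
        return pd.Series(values, index=idx), pd.Series(groups, index=idx)

    def test_identical_groups_flag_nothing(self):
        v, g = self._values(seed=1)
        res = expression.gated_group_test(v, g)
        assert not res.pairwise["significant"].any()

    def test_large_shift_detected_in_most_runs(self):
        hits = 0
        for seed in range(20):
            v, g = self._values(shift_tcd=10.0, seed=seed)
            res = expression.gated_group_test(v, g)
            pair = res.pairwise
            tcd = pair[(pair["group_a"] == "T-CD") | (pair["group_b"] == "T-CD")]
            hits += tcd["significant"].all()
        assert hits >= 19

    def test_heavy_tails_route_to_nonparametric_branch(self):
        nonpar = 0
        for seed in range(20):
            v, g = self._values(dist="cauchy", seed=seed)
            nonpar += expression.gated_group_test(v, g).test_used == "kruskal_ranksum"
        assert nonpar > 10

    def test_constant_values_rejected(self):
        idx = [f"s{i}" for i in range(6)]
        v = pd.Series(1.0, index=idx)
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=idx)
        with pytest.raises(ValueError, match="constant"):
            expression.gated_group_test(v, g)


class TestGenusTTests:
    def test_null_cohorts_yield_no_discoveries(self, template):
        frac = []
        for seed in range(10):
            abund, meta = pa.simulate_abundances(template, pa.SimulationConfig(seed=seed))
            res = pa.genus_ttests(abund, meta)
            frac.append((res["p_adj"] < 0.05).mean())
        assert np.mean(frac) < 0.01

    def test_planted_groups_dominate_smallest_adjusted_p(self, template):
        cfg = pa.SimulationConfig(seed=0, effect_multiplier=8.0)
        abund, meta = pa.simulate_abundances(template, cfg)
        res = pa.genus_ttests(abund, meta).sort_values("p_adj")
        top = set(res.index[:8])
        assert len(top & set(pa.DEFAULT_PLANTED_GROUPS)) >= 5

    def test_copied_cohorts_give_p_one(self):
        abund = pd.DataFrame(
            np.tile(np.arange(1.0, 5.0)[:, None], (1, 6)),
            index=list("abcd"), columns=[f"s{i}" for i in range(6)],
        )
        meta = pd.DataFrame({"group": ["HC"] * 3 + ["CD"] * 3}, index=abund.columns)
        res = pa.genus_ttests(abund, meta)
        np.testing.assert_allclose(res["p"], 1.0)


class TestSpearmanAndRegression:
    def test_monotone_and_antitone_correlations(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        y = pd.DataFrame({"up": np.exp(np.arange(10.0)), "down": -np.arange(10.0)})
        rho, _, _ = expression.spearman_matrix(x, y)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        x = pd.DataFrame({"x": np.arange(8.0)})
        y = pd.DataFrame({"flat": np.ones(8)})
        rho, p, p_adj = expression.spearman_matrix(x, y)
        assert np.isnan(rho.loc["x", "flat"])

    def test_independent_data_rarely_significant_after_fdr(self):
        rng = np.random.default_rng(3)
        hits = []
        for _ in range(100):
            x = pd.DataFrame(rng.normal(size=(10, 4)))
            y = pd.DataFrame(rng.normal(size=(10, 3)))
            _, _, p_adj = expression.spearman_matrix(x, y)
            hits.append((p_adj.to_numpy() < 0.05).mean())
        assert np.mean(hits) < 0.02

    def test_exact_line_and_hand_computed_fit(self):
        x = np.arange(5.0)
        res = expression.simple_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0) and res.r_squared == pytest.approx(1.0)
        # 4-point closed form via scipy oracle recomputed by formulas
        x4, y4 = np.array([0.0, 1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0, 5.0])
        res4 = expression.simple_regression(x4, y4)
        sxx = np.sum((x4 - x4.mean()) ** 2)
        sxy = np.sum((x4 - x4.mean()) * (y4 - y4.mean()))
        assert res4.slope == pytest.approx(sxy / sxx)
        assert res4.r_squared == pytest.approx(sxy**2 / (sxx * np.sum((y4 - y4.mean()) ** 2)))

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            expression.simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
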
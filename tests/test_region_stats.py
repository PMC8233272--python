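"""Negative-binomial GLM statistics: calibration, recovery, adjustments, diagnostics."""
import numpy as np
import pandas as pd
import pytest

from lsfmatlas import synth
from lsfmatlas.region_stats import (
    analyze_counts,
    bh_fdr,
    dunnett_adjust,
    fit_region_nbglm,
    glm_diagnostics,
)

DESIGN_2 = pd.DataFrame(
    {"animal_id": [f"a{i}" for i in range(12)], "group": ["ctrl"] * 6 + ["trt"] * 6}
)
DESIGN_4 = pd.DataFrame(
    {
        "animal_id": [f"a{i}" for i in range(24)],
        "group": ["ctrl"] * 6 + ["t1"] * 6 + ["t2"] * 6 + ["t3"] * 6,
    }
)


def brute_force_bh(p):
    """Step-up reference: adjusted_i = min over tail of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestBHFDR:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFit:
    def test_effect_recovery(self):
        """Mean estimated log2 fold change within +-0.15 of the simulated 1.0."""
        est = []
        for rep in range(200):
            counts = synth.simulate_counts([1], DESIGN_2, 100.0, {"trt": 1.0}, 5.0, seed=2000 + rep)
            est.append(fit_region_nbglm(counts, DESIGN_2, "ctrl")[1].log2fc[0])
        assert abs(np.mean(est) - 1.0) <= 0.15

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 inside the exact binomial 95% band (200 reps)."""
        from scipy import stats

        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            counts = synth.simulate_counts([1], DESIGN_2, 100.0, {}, 5.0, seed=1000 + rep)
            rej += fit_region_nbglm(counts, DESIGN_2, "ctrl")[1].pvalues[0] < 0.05
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= rej <= hi

    def test_near_poisson_dispersion(self):
        """In the Poisson limit (theta = 1e6) the fitted mean-variance ratio stays near 1."""
        big = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(50)], "group": ["ctrl"] * 25 + ["trt"] * 25}
        )
        counts = synth.simulate_counts(range(20), big, 50.0, {}, 1e6, seed=7)
        fits = fit_region_nbglm(counts, big, "ctrl")
        ratios = []
        for rid, f in fits.items():
            sub = counts[counts["region_id"] == rid]["count"].to_numpy(float)
            mu = sub.mean()
            ratios.append((mu + mu**2 / f.theta) / mu)
        assert 0.8 <= np.mean(ratios) <= 1.2

    def test_all_zero_region_flagged(self):
        counts = synth.simulate_counts([1], DESIGN_2, 10.0, {}, 5.0, seed=3)
        counts["count"] = 0
        fit = fit_region_nbglm(counts, DESIGN_2, "ctrl")[1]
        assert fit.all_zero and not fit.converged

    def test_group_requirements(self):
        bad = pd.DataFrame({"animal_id": ["a", "b", "c"], "group": ["ctrl", "ctrl", "trt"]})
        counts = pd.DataFrame(
            {"animal_id": ["a", "b", "c"], "group": ["ctrl", "ctrl", "trt"], "region_id": 1, "count": [1, 2, 3]}
        )
        with pytest.raises(ValueError, match="2 animals"):
            fit_region_nbglm(counts, bad, "ctrl")


class TestDunnett:
    def test_single_treatment_equals_unadjusted(self):
        counts = synth.simulate_counts([1], DESIGN_2, 100.0, {"trt": 0.7}, 5.0, seed=11)
        fit = fit_region_nbglm(counts, DESIGN_2, "ctrl")[1]
        adj = dunnett_adjust(fit, seed=0)
        assert abs(adj[0] - fit.pvalues[0]) <= 1e-3

    def test_adjusted_never_below_raw(self):
        counts = synth.simulate_counts([1], DESIGN_4, 100.0, {"t1": 0.5}, 5.0, seed=12)
        fit = fit_region_nbglm(counts, DESIGN_4, "ctrl")[1]
        adj = dunnett_adjust(fit, seed=0, n_mc=50_000)
        assert (adj >= fit.pvalues - 1e-12).all()

    def test_familywise_error_controlled(self):
        """Exchangeable null with 3 treatments: FWER at alpha=0.05 in the binomial band."""
        from scipy import stats

        n_rep = 200
        fw = 0
        for rep in range(n_rep):
            counts = synth.simulate_counts([1], DESIGN_4, 100.0, {}, 5.0, seed=3000 + rep)
            fit = fit_region_nbglm(counts, DESIGN_4, "ctrl")[1]
            adj = dunnett_adjust(fit, seed=rep, n_mc=20_000)
            fw += bool((adj < 0.05).any())
        lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
        assert lo <= fw <= hi

    def test_determinism(self):
        counts = synth.simulate_counts([1], DESIGN_4, 100.0, {}, 5.0, seed=13)
        fit = fit_region_nbglm(counts, DESIGN_4, "ctrl")[1]
        np.testing.assert_array_equal(dunnett_adjust(fit, seed=5), dunnett_adjust(fit, seed=5))


class TestDiagnostics:
    def test_gross_outlier_gets_max_cooks(self):
        counts = synth.simulate_counts([1], DESIGN_2, 100.0, {}, 10.0, seed=21)
        idx = counts.index[3]
        counts.loc[idx, "count"] = int(50 * counts["count"].mean())
        fit = fit_region_nbglm(counts, DESIGN_2, "ctrl")[1]
        diag = glm_diagnostics(fit, counts, DESIGN_2)
        assert diag["influential_points"]
        assert diag["max_cooks_index"] == 3

    def test_low_count_flag(self):
        counts = pd.DataFrame(
            {
                "animal_id": DESIGN_2["animal_id"],
                "group": DESIGN_2["group"],
                "region_id": 1,
                "count": [4, 4, 4, 4, 4, 4, 12, 12, 12, 12, 12, 12],
            }
        )
        fit = fit_region_nbglm(counts, DESIGN_2, "ctrl")[1]
        diag = glm_diagnostics(fit, counts, DESIGN_2)
        assert diag["low_count"]

    def test_clean_null_rarely_flagged(self):
        """Calibration: on well-specified data the Cook screen flags few points."""
        frac = []
        for rep in range(100):
            counts = synth.simulate_counts([1], DESIGN_2, 100.0, {}, 10.0, seed=4000 + rep)
            fit = fit_region_nbglm(counts, DESIGN_2, "ctrl")[1]
            diag = glm_diagnostics(fit, counts, DESIGN_2)
            cooks = diag["cooks_distance"]
            frac.append((cooks > 4.0 / len(cooks)).mean())
        assert np.mean(frac) <= 0.10


class TestSpillover:
    def test_adjacency_and_candidate(self):
        from lsfmatlas.region_stats import region_adjacency, spillover_candidates
        from lsfmatlas.types import LabelVolume

        labels = np.zeros((2, 2, 6), np.int64)
        labels[:, :, :2] = 1
        labels[:, :, 2:4] = 2
        labels[:, :, 4:] = 3
        adj = region_adjacency(LabelVolume(labels, 20.0))
        assert adj[1] == {2} and adj[2] == {1, 3}
        counts = pd.DataFrame(
            {"animal_id": ["m"] * 3, "group": ["g"] * 3, "region_id": [1, 2, 3], "count": [500, 4, 30]}
        )
        spill = spillover_candidates(counts, adj, ratio=10.0)
        assert spill[2] == 1  # region 2 borders region 1 with >= 10x the counts
        assert spill[1] is None and spill[3] is None


class TestAnalyzeCounts:
    def test_end_to_end_with_collapse(self):
        ont, collapse_map, _ = synth.make_reference_ontology()
        leaves = ont.leaves[:6]
        counts = synth.simulate_counts(leaves, DESIGN_2, 50.0, {"trt": 1.0}, 5.0, seed=31)
        out = analyze_counts(counts, DESIGN_2, "ctrl", ont, collapse_map, seed=0)
        assert (out["q"] >= out["p_dunnett"] - 1e-12).all()
        collapsed_ids = {collapse_map[l] for l in leaves}
        assert set(out["region_id"]) == collapsed_ids

    def test_pipeline_determinism(self):
        counts = synth.simulate_counts([1, 2, 3], DESIGN_2, 50.0, {"trt": 0.5}, 5.0, seed=32)
        o1 = analyze_counts(counts, DESIGN_2, "ctrl", seed=9)
        o2 = analyze_counts(counts, DESIGN_2, "ctrl", seed=9)
        pd.testing.assert_frame_equal(o1, o2)
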
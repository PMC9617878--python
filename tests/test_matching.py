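"""Propensity scores, greedy PSM, CEM weights, random controls, balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from mineforest.matching import (
    MatchingError,
    PropensityModel,
    balance,
    cem_match,
    common_support,
    fit_propensity,
    psm_match,
    random_controls,
)


def manual_model(frame, scores):
    """PropensityModel with hand-set scores, bypassing the logistic fit."""
    s = pd.Series(scores, index=frame.pixel_id.values, dtype=float)
    return PropensityModel(
        coefficients=pd.Series(dtype=float),
        scores=s,
        linear_predictor=np.log(s / (1 - s)),
        confounders=[],
    )


def make_frame(n_t=30, n_c=60, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    n = n_t + n_c
    treated = np.r_[np.ones(n_t, int), np.zeros(n_c, int)]
    f = pd.DataFrame(
        {
            "pixel_id": np.arange(n),
            "treated": treated,
            "mean_treecover": rng.normal(50 + shift * treated, 10),
            "sd_treecover": rng.normal(12, 3, n),
            "dist_road": rng.gamma(2, 2000, n) + (-shift * 200) * treated,
            "elevation": rng.normal(1200, 80, n),
            "slope": rng.gamma(2, 1.5, n),
            "popdens": rng.gamma(2, 30, n),
            "burned": rng.integers(0, 2, n),
            "aez": rng.integers(0, 3, n),
            "protected": rng.integers(0, 2, n),
            "pre_loss": rng.integers(0, 2, n),
        }
    )
    return f


def brute_force_psm(frame, scores, caliper, exact):
    """Independent greedy-in-order oracle with explicit loops."""
    s = dict(zip(frame.pixel_id, scores))
    rows = frame.set_index("pixel_id")
    treated = sorted(
        frame.pixel_id[frame.treated == 1], key=lambda i: (-s[i], i)
    )
    controls = set(frame.pixel_id[frame.treated == 0])
    pairs = []
    for t in treated:
        cands = []
        for c in controls:
            if all(rows.loc[t, e] == rows.loc[c, e] for e in exact):
                cands.append((abs(s[t] - s[c]), c))
        if not cands:
            continue
        d, c = min(cands)
        if d <= caliper:
            pairs.append((t, c))
            controls.discard(c)
    return pairs


class TestPropensity:
    def test_null_model_recovers_treated_fraction(self):
        f = make_frame(n_t=200, n_c=200, seed=1)
        m = fit_propensity(f)
        assert m.scores.mean() == pytest.approx(0.5, abs=0.05)
        # no confounder carries signal: standardised slopes are all small
        slopes = m.coefficients.drop("const")
        assert np.abs(slopes @ np.ones(len(slopes))) < 5

    def test_single_binary_confounder_closed_form(self):
        # treated: 50/50 on the factor; controls: 20/80 -> slope log 4
        rows = (
            [(1, 1)] * 50 + [(1, 0)] * 50 + [(0, 1)] * 20 + [(0, 0)] * 80
        )
        f = pd.DataFrame(rows, columns=["treated", "burned"])
        f["pixel_id"] = np.arange(len(f))
        m = fit_propensity(f, ["burned"])
        assert m.coefficients["burned"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_matches_generic_optimizer_mle(self):
        f = make_frame(n_t=60, n_c=90, seed=2, shift=4.0)
        confs = ["mean_treecover", "dist_road", "slope"]
        m = fit_propensity(f, confs)
        X = np.column_stack([np.ones(len(f))] + [f[c] for c in confs])
        yv = f.treated.values.astype(float)

        def nll(b):
            eta = X @ b
            return np.sum(np.logaddexp(0, eta)) - eta @ yv

        def grad(b):
            p = 1 / (1 + np.exp(-(X @ b)))
            return X.T @ (p - yv)

        res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        np.testing.assert_allclose(m.coefficients.values, res.x, atol=1e-6)

    def test_constant_confounder_rejected(self):
        f = make_frame()
        f["elevation"] = 100.0
        with pytest.raises(MatchingError, match="elevation"):
            fit_propensity(f, ["elevation", "slope"])


class TestCommonSupport:
    def test_identical_ranges_drop_nothing(self):
        f = make_frame(seed=3)
        m = fit_propensity(f)
        kept = common_support(f, m)
        lo = max(m.scores[f.pixel_id[f.treated == 1]].min(),
                 m.scores[f.pixel_id[f.treated == 0]].min())
        hi = min(m.scores[f.pixel_id[f.treated == 1]].max(),
                 m.scores[f.pixel_id[f.treated == 0]].max())
        # brute-force interval filter
        want = f[(m.scores[f.pixel_id].values >= lo) & (m.scores[f.pixel_id].values <= hi)]
        assert len(kept) == len(want)
        np.testing.assert_array_equal(kept.pixel_id.values, want.pixel_id.values)


class TestPSM:
    def test_identical_units_match_at_distance_zero(self):
        f = make_frame(n_t=1, n_c=1, seed=4)
        m = manual_model(f, [0.5, 0.5])
        ms = psm_match(f, m, exact=())
        assert len(ms.pairs) == 1
        assert ms.pairs.distance.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_caliper_drops_unmatched_treated(self):
        f = make_frame(n_t=1, n_c=1, seed=5)
        m = manual_model(f, [0.9, 0.1])  # sole control far beyond any caliper
        with pytest.raises(MatchingError):
            psm_match(f, m, caliper_sd=1e-9, exact=())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        f = make_frame(n_t=8, n_c=20, seed=seed, shift=3.0)
        m = fit_propensity(f, ["mean_treecover", "dist_road"])
        exact = ["protected", "aez"]
        ms = psm_match(f, m, caliper_sd=0.5, exact=exact)
        scores = m.scores[f.pixel_id].values
        caliper = 0.5 * scores.std(ddof=1)
        want = brute_force_psm(f, scores, caliper, exact)
        got = list(zip(ms.pairs.treated_id, ms.pairs.control_id))
        assert got == want

    def test_every_pair_respects_constraints(self):
        f = make_frame(n_t=20, n_c=60, seed=9, shift=2.0)
        m = fit_propensity(f)
        ms = psm_match(f, m)
        scores = m.scores
        caliper = 0.25 * scores[f.pixel_id].values.std(ddof=1)
        rows = f.set_index("pixel_id")
        for t, c in zip(ms.pairs.treated_id, ms.pairs.control_id):
            assert abs(scores[t] - scores[c]) <= caliper + 1e-12
            assert rows.loc[t, "protected"] == rows.loc[c, "protected"]
            assert rows.loc[t, "aez"] == rows.loc[c, "aez"]
        assert ms.pairs.control_id.is_unique


class TestCEM:
    def test_single_stratum_keeps_everything(self):
        f = make_frame(n_t=5, n_c=10, seed=6)
        for c in ["mean_treecover", "sd_treecover", "dist_road", "elevation",
                  "slope", "popdens"]:
            f[c] = 1.0  # constant -> one bin
        for c in ["burned", "aez", "protected", "pre_loss"]:
            f[c] = 0
        ms = cem_match(f)
        assert len(ms.weights) == 15
        w_c = ms.weights.loc[ms.weights.treated == 0, "weight"]
        assert w_c.nunique() == 1

    def test_disjoint_strata_error(self):
        f = make_frame(n_t=5, n_c=5, seed=7)
        f["aez"] = f["treated"]  # no stratum mixes arms
        with pytest.raises(MatchingError):
            cem_match(f, confounders=["aez"])

    def test_hand_worked_stratum_weights(self):
        # stratum A: 2 treated, 1 control; stratum B: 1 treated, 3 controls
        f = pd.DataFrame(
            {
                "pixel_id": range(7),
                "treated": [1, 1, 0, 1, 0, 0, 0],
                "aez": [0, 0, 0, 1, 1, 1, 1],
            }
        )
        ms = cem_match(f, confounders=["aez"])
        w = ms.weights.set_index("pixel_id").weight
        # M_T = 3, M_C = 4; control in A: (2/1)*(4/3); controls in B: (1/3)*(4/3)
        assert w[2] == pytest.approx(2 * 4 / 3)
        assert w[4] == pytest.approx(4 / 9)
        assert (w[[0, 1, 3]] == 1.0).all()

    def test_cem_weight_totals(self):
        f = make_frame(n_t=25, n_c=70, seed=8, shift=2.0)
        ms = cem_match(f, bins=3, confounders=["mean_treecover", "dist_road", "burned"])
        w = ms.weights
        M_T = (w.treated == 1).sum()
        M_C = (w.treated == 0).sum()
        # global: weighted controls preserve the control total
        assert w.loc[w.treated == 0, "weight"].sum() == pytest.approx(M_C)
        # per stratum: control weights sum proportional to the treated count
        for _, grp in w.groupby("stratum"):
            m_t = (grp.treated == 1).sum()
            got = grp.loc[grp.treated == 0, "weight"].sum()
            assert got == pytest.approx(m_t * M_C / M_T)


class TestRandomControls:
    def test_pool_equal_to_treated_returned_in_full(self):
        f = make_frame(n_t=10, n_c=10, seed=10)
        ms = random_controls(f, seed=1)
        assert set(ms.weights.pixel_id) == set(f.pixel_id)

    def test_seed_determinism(self):
        f = make_frame(n_t=10, n_c=40, seed=11)
        a = random_controls(f, seed=3).weights.pixel_id.values
        b = random_controls(f, seed=3).weights.pixel_id.values
        np.testing.assert_array_equal(a, b)

    def test_draw_is_uniform_over_pool(self):
        f = make_frame(n_t=3, n_c=12, seed=12)
        pool = f.pixel_id[f.treated == 0].values
        counts = pd.Series(0, index=pool)
        for s in range(5000):
            ms = random_controls(f, seed=s)
            chosen = ms.weights.pixel_id[ms.weights.treated == 0]
            counts[chosen] += 1
        expected = 5000 * 3 / 12
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=len(pool) - 1) > 0.01


class TestBalance:
    def test_identical_groups_zero_smd(self):
        f = make_frame(n_t=20, n_c=20, seed=13)
        cols = f.columns.difference(["pixel_id", "treated"])
        f.loc[f.treated == 0, cols] = f.loc[f.treated == 1, cols].values
        m = fit_propensity(f, ["mean_treecover", "slope"])
        ms = psm_match(f, m, exact=())
        rep = balance(f, ms)
        assert np.allclose(rep.smd_before, 0.0)

    def test_exact_matched_categorical_smd_zero(self):
        f = make_frame(n_t=15, n_c=60, seed=14, shift=2.0)
        m = fit_propensity(f)
        ms = psm_match(f, m)
        rep = balance(f, ms).set_index("confounder")
        assert rep.loc["protected", "smd_after"] == pytest.approx(0.0, abs=1e-12)
        assert rep.loc["aez", "smd_after"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_smd(self):
        f = pd.DataFrame(
            {
                "pixel_id": range(8),
                "treated": [1, 1, 1, 1, 0, 0, 0, 0],
                "mean_treecover": [50.0, 60, 55, 65, 40, 45, 50, 45],
            }
        )
        ms = random_controls(f, seed=0)
        rep = balance(f, ms, ["mean_treecover"])
        mt, mc = 57.5, 45.0
        vt = np.var([50, 60, 55, 65], ddof=0)
        vc = np.var([40, 45, 50, 45], ddof=0)
        want = (mt - mc) / np.sqrt((vt + vc) / 2)
        assert rep.smd_before.iloc[0] == pytest.approx(want)

    def test_psm_improves_balance_on_confounded_frames(self):
        # assignment genuinely driven by the covariates, as when mines prefer
        # accessible, low-opportunity-cost land
        improved = 0
        n_frames = 30
        for seed in range(n_frames):
            rng = np.random.default_rng(100 + seed)
            n = 400
            f = make_frame(n_t=0, n_c=n, seed=100 + seed)
            z = lambda c: (f[c] - f[c].mean()) / f[c].std()
            score = (0.8 * z("mean_treecover") - 0.8 * z("dist_road")
                     + 0.5 * z("popdens") - 0.4 * z("elevation") - 1.2)
            f["treated"] = (rng.random(n) < 1 / (1 + np.exp(-score))).astype(int)
            if f.treated.sum() < 10:
                continue
            try:
                m = fit_propensity(f)
                ms = psm_match(common_support(f, m), m)
                rep = balance(f, ms)
            except MatchingError:
                continue
            if np.nanmean(np.abs(rep.smd_after)) <= np.nanmean(np.abs(rep.smd_before)):
                improved += 1
        assert improved >= 0.8 * n_frames
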
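"""Statistical matching: propensity scores, greedy 1-1 PSM, coarsened exact
matching, random controls, and covariate-balance diagnostics.

The propensity score is a logistic regression of treatment on the
confounders (fitted by IRLS through statsmodels). PSM is 1-1 nearest
neighbour without replacement, processed in descending propensity order,
under a caliper of 0.25 SD of the score and exact agreement on the
categorical confounders; treated units with no admissible control are
dropped. CEM coarsens each continuous confounder into (by default) five
equal-frequency bins, keeps strata containing both groups, and reweights
controls within each stratum to the treated count. Balance is summarised by
standardised mean differences before and after matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MatchingError",
    "PropensityModel",
    "MatchedSet",
    "fit_propensity",
    "common_support",
    "psm_match",
    "cem_match",
    "random_controls",
    "balance",
]

DEFAULT_CONFOUNDERS = [
    "mean_treecover", "sd_treecover", "dist_road", "elevation", "slope",
    "popdens", "burned", "aez", "protected", "pre_loss",
]
CATEGORICAL = {"aez"}
DEFAULT_EXACT = ("protected", "aez")
CONTINUOUS = ["mean_treecover", "sd_treecover", "dist_road", "elevation", "slope", "popdens"]


class MatchingError(RuntimeError):
    pass


@dataclass
class PropensityModel:
    coefficients: pd.Series
    scores: pd.Series  # indexed by pixel_id, in (0, 1)
    linear_predictor: pd.Series
    confounders: list
    frame_id: str = ""


@dataclass
class MatchedSet:
    scheme: str
    weights: pd.DataFrame  # columns: pixel_id, treated, weight[, stratum]
    pairs: pd.DataFrame | None = None  # treated_id, control_id, distance
    dropped: list = field(default_factory=list)

    @property
    def n_treated(self):
        return int((self.weights.treated == 1).sum())

    def select(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Matched rows of ``frame`` with a ``weight`` column attached."""
        out = frame.merge(self.weights[["pixel_id", "weight"]], on="pixel_id")
        return out


def _design(frame: pd.DataFrame, confounders) -> pd.DataFrame:
    X = pd.DataFrame(index=frame.index)
    for name in confounders:
        col = frame[name]
        if name in CATEGORICAL and col.nunique() > 2:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[name] = col.astype(float)
    return X


def fit_propensity(frame: pd.DataFrame, confounders=None) -> PropensityModel:
    """Logistic propensity model fitted by IRLS.

    Constant confounders and clean failures (separation, non-convergence)
    raise :class:`MatchingError` naming the offending variable where it can
    be identified.
    """
    confounders = list(confounders or DEFAULT_CONFOUNDERS)
    if frame.treated.nunique() < 2:
        raise MatchingError("need both treated and control rows")
    X = _design(frame, confounders)
    constant = [c for c in X.columns if X[c].nunique() == 1]
    if constant:
        raise MatchingError(f"constant confounder(s): {', '.join(constant)}")
    X = sm.add_constant(X)
    model = sm.GLM(frame.treated.values.astype(float), X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels raises PerfectSeparation subclasses
        raise MatchingError(f"propensity fit failed: {exc}") from exc
    if not res.converged:
        raise MatchingError("propensity IRLS did not converge")
    eta = pd.Series(np.asarray(res.predict(X, which="linear")), index=frame.pixel_id.values)
    score = pd.Series(np.asarray(res.predict(X)), index=frame.pixel_id.values)
    if np.any((score <= 1e-12) | (score >= 1 - 1e-12)):
        bad = res.params.abs().idxmax()
        raise MatchingError(f"degenerate propensity scores (separation; check {bad})")
    return PropensityModel(
        coefficients=res.params,
        scores=score,
        linear_predictor=eta,
        confounders=confounders,
    )


def common_support(frame: pd.DataFrame, model: PropensityModel) -> pd.DataFrame:
    """Drop rows outside the overlapping propensity-score range."""
    s = model.scores.loc[frame.pixel_id].values
    t = frame.treated.values == 1
    lo = max(s[t].min(), s[~t].min())
    hi = min(s[t].max(), s[~t].max())
    if lo > hi:
        raise MatchingError("no common support: propensity ranges are disjoint")
    keep = (s >= lo) & (s <= hi)
    return frame[keep].reset_index(drop=True)


def psm_match(frame: pd.DataFrame, model: PropensityModel, caliper_sd: float = 0.25,
              exact=DEFAULT_EXACT, caliper_scale: str = "score") -> MatchedSet:
    """Greedy 1-1 nearest-neighbour PSM without replacement.

    Treated units are processed in descending propensity order (ties broken
    by pixel_id); each takes the still-unmatched control with the smallest
    score distance among those equal on the ``exact`` variables and within
    ``caliper_sd`` score standard deviations (probability scale by default,
    ``caliper_scale='linear'`` for the linear predictor).
    """
    values = model.scores if caliper_scale == "score" else model.linear_predictor
    if caliper_scale not in ("score", "linear"):
        raise ValueError("caliper_scale must be 'score' or 'linear'")
    s = values.loc[frame.pixel_id].values
    caliper = caliper_sd * s.std(ddof=1) if caliper_sd is not None else np.inf

    exact = [e for e in (exact or []) if e in frame.columns]
    sig = list(zip(*[frame[e].values for e in exact])) if exact else [()] * len(frame)

    treated_idx = np.flatnonzero(frame.treated.values == 1)
    control_idx = np.flatnonzero(frame.treated.values == 0)
    order = sorted(treated_idx, key=lambda i: (-s[i], frame.pixel_id.values[i]))

    available = set(control_idx)
    pairs, dropped = [], []
    pid = frame.pixel_id.values
    for i in order:
        best, best_d = None, np.inf
        for j in available:
            if sig[j] != sig[i]:
                continue
            d = abs(s[i] - s[j])
            if d < best_d or (d == best_d and best is not None and pid[j] < pid[best]):
                best, best_d = j, d
        if best is None or best_d > caliper:
            dropped.append(pid[i])
            continue
        available.discard(best)
        pairs.append((pid[i], pid[best], best_d))
    if not pairs:
        raise MatchingError("PSM produced no matches")
    pairs_df = pd.DataFrame(pairs, columns=["treated_id", "control_id", "distance"])
    weights = pd.DataFrame(
        {
            "pixel_id": np.concatenate([pairs_df.treated_id.values, pairs_df.control_id.values]),
            "treated": np.r_[np.ones(len(pairs_df), int), np.zeros(len(pairs_df), int)],
            "weight": 1.0,
        }
    )
    return MatchedSet("psm", weights, pairs_df, dropped)


def cem_match(frame: pd.DataFrame, bins: int = 5, confounders=None) -> MatchedSet:
    """Coarsened exact matching with standard CEM weights.

    Continuous confounders are cut into ``bins`` equal-frequency bins
    (computed on the pooled frame); categoricals stay exact. Strata lacking
    either group are discarded. Within stratum s the control weight is
    (m_T^s / m_C^s) * (M_C / M_T), treated weights are 1, so weighted
    controls total the treated count within every stratum up to the global
    normalisation.
    """
    confounders = list(confounders or DEFAULT_CONFOUNDERS)
    sig = pd.DataFrame(index=frame.index)
    for name in confounders:
        col = frame[name]
        if name in CONTINUOUS and col.nunique() > bins:
            edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)))
            sig[name] = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, len(edges) - 2)
        else:
            sig[name] = col
    strata = sig.apply(tuple, axis=1)

    t = frame.treated.values == 1
    matched_strata = set(strata[t]) & set(strata[~t])
    if not matched_strata:
        raise MatchingError("CEM: no stratum contains both treated and control units")
    keep = strata.isin(matched_strata)
    kept = frame[keep].copy()
    kept_strata = strata[keep]
    m_t = kept_strata[kept.treated == 1].value_counts()
    m_c = kept_strata[kept.treated == 0].value_counts()
    M_T, M_C = m_t.sum(), m_c.sum()
    w = np.where(
        kept.treated.values == 1,
        1.0,
        (m_t.loc[kept_strata].values / m_c.loc[kept_strata].values) * (M_C / M_T),
    )
    weights = pd.DataFrame(
        {
            "pixel_id": kept.pixel_id.values,
            "treated": kept.treated.values,
            "weight": w,
            "stratum": pd.factorize(kept_strata)[0],
        }
    )
    dropped = list(frame.pixel_id.values[~keep.values & t])
    return MatchedSet("cem", weights, None, dropped)


def random_controls(frame: pd.DataFrame, seed: int) -> MatchedSet:
    """Unmatched sensitivity scheme: a uniform draw of controls, one per
    treated unit, without replacement."""
    rng = np.random.default_rng(seed)
    treated_ids = frame.pixel_id.values[frame.treated.values == 1]
    pool = frame.pixel_id.values[frame.treated.values == 0]
    if pool.size < treated_ids.size:
        raise MatchingError(
            f"control pool ({pool.size}) smaller than treated count ({treated_ids.size})"
        )
    chosen = rng.choice(np.sort(pool), size=treated_ids.size, replace=False)
    pairs = pd.DataFrame(
        {"treated_id": np.sort(treated_ids), "control_id": np.sort(chosen), "distance": np.nan}
    )
    weights = pd.DataFrame(
        {
            "pixel_id": np.concatenate([treated_ids, chosen]),
            "treated": np.r_[np.ones(treated_ids.size, int), np.zeros(chosen.size, int)],
            "weight": 1.0,
        }
    )
    return MatchedSet("random", weights, pairs, [])


def _weighted_mean_var(x, w):
    m = np.average(x, weights=w)
    v = np.average((x - m) ** 2, weights=w)
    return m, v


def balance(frame: pd.DataFrame, matched: MatchedSet, confounders=None) -> pd.DataFrame:
    """Standardised mean differences before and after matching.

    SMD = (mean_T - mean_C) / sqrt((var_T + var_C) / 2), computed unweighted
    on the full frame ("before") and with matching weights on the matched
    rows ("after"). Binary and coded categorical confounders are compared as
    numerics. A zero pooled SD yields SMD 0 when the means agree and NaN
    (flagged) otherwise.
    """
    confounders = list(confounders or DEFAULT_CONFOUNDERS)
    if len(matched.weights) == 0:
        raise MatchingError("matched set is empty")
    after = matched.select(frame)

    rows = []
    for name in confounders:
        rec = {"confounder": name}
        for label, data, w in (
            ("smd_before", frame, np.ones(len(frame))),
            ("smd_after", after, after.weight.values),
        ):
            t = data.treated.values == 1
            x = data[name].values.astype(float)
            mt, vt = _weighted_mean_var(x[t], w[t])
            mc, vc = _weighted_mean_var(x[~t], w[~t])
            pooled = np.sqrt((vt + vc) / 2.0)
            if pooled == 0:
                rec[label] = 0.0 if mt == mc else np.nan
            else:
                rec[label] = (mt - mc) / pooled
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["n_treated_after"] = matched.n_treated
    out["n_control_after"] = int((matched.weights.treated == 0).sum())
    return out
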
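"""Model checking: posterior predictive simulation, simulated quantile
residuals, and empirical variograms with permutation envelopes.

Quantile residuals follow the standard simulated construction: with R
posterior-predictive replicates per observation, the residual

    q = (#{rep < y} + U #{rep = y} + U0) / (R + 1),  U, U0 ~ Uniform(0, 1)

is Uniform(0, 1) under a correctly specified model, which turns arbitrary
discrete responses into a screenable quantity. Residual spatial structure
is screened with an empirical semivariogram (pairs within the same year,
pooled over years) against a pointwise envelope from random relabelings of
residuals over pixel locations — a design-based check that needs no model
refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .countmodel import zinb_rvs
from .outcome import PosteriorDraws

__all__ = [
    "posterior_predictive",
    "quantile_residuals",
    "variogram",
    "VariogramResult",
    "report",
]


def posterior_predictive(draws: PosteriorDraws, n_rep: int = 200, seed: int = 0,
                         include_latents: bool = True):
    """Simulate ``n_rep`` replicate datasets, one per (thinned) posterior draw.

    Returns ``(replicates, summary)``: replicates of shape (n_rep, n_rows)
    and a table of tail probabilities P(T(rep) >= T(obs)) for the zero
    proportion, the maximum, and the total count.
    """
    rng = np.random.default_rng(seed)
    idx = np.linspace(0, draws.n_draws - 1, n_rep).astype(int)
    eta = draws.linear_predictor(include_latents=include_latents)[idx]
    mu = np.exp(np.clip(eta, -30, 30))
    reps = zinb_rvs(mu, draws.k[idx, None], draws.pi[idx, None], rng)

    y = draws.design["y"]
    stats = {
        "prop_zero": lambda a: (a == 0).mean(axis=-1),
        "max": lambda a: a.max(axis=-1),
        "total": lambda a: a.sum(axis=-1),
    }
    rows = []
    for name, fn in stats.items():
        obs = float(fn(y[None, :])[0])
        rep_stat = fn(reps)
        rows.append(
            {
                "statistic": name,
                "observed": obs,
                "replicate_mean": float(rep_stat.mean()),
                "tail_prob": float((rep_stat >= obs).mean()),
            }
        )
    return reps, pd.DataFrame(rows)


def quantile_residuals(replicates: np.ndarray, observed: np.ndarray, seed: int = 0) -> np.ndarray:
    """Randomized quantile residuals in (0, 1), one per observation."""
    replicates = np.asarray(replicates)
    observed = np.asarray(observed)
    n_rep = replicates.shape[0]
    if n_rep < 100:
        raise ValueError("need at least 100 replicates per observation")
    rng = np.random.default_rng(seed)
    below = (replicates < observed[None, :]).sum(axis=0)
    equal = (replicates == observed[None, :]).sum(axis=0)
    u = rng.random(observed.shape)
    u0 = rng.random(observed.shape)
    q = (below + u * equal + u0) / (n_rep + 1.0)
    return np.clip(q, 1e-12, 1 - 1e-12)


@dataclass
class VariogramResult:
    bins: pd.DataFrame  # bin_lo, bin_hi, bin_mid, gamma, env_lo, env_hi, n_pairs, outside

    @property
    def fraction_inside(self) -> float:
        ok = self.bins[self.bins.n_pairs > 0]
        if len(ok) == 0:
            return np.nan
        return float((~ok.outside).mean())


def variogram(residuals: pd.DataFrame, bins: np.ndarray | None = None,
              n_bins: int = 10, min_distance: float = 4_000.0,
              n_permutations: int = 199, seed: int = 0,
              envelope: tuple = (0.5, 99.5)) -> VariogramResult:
    """Empirical semivariogram of residuals with a permutation envelope.

    ``residuals`` needs columns x, y, year, resid; pairs are formed within
    years and pooled. Default bins: ``n_bins`` equal-width classes from
    ``min_distance`` (the post-subsample spacing) to half the frame
    diameter. The envelope relabels residuals over locations independently
    within each year.
    """
    if residuals[["x", "y"]].drop_duplicates().shape[0] < 30:
        raise ValueError("need at least 30 distinct locations")
    rng = np.random.default_rng(seed)
    pts = residuals[["x", "y"]].values
    if bins is None:
        span = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        bins = np.linspace(min_distance, span / 2.0, n_bins + 1)
    bins = np.asarray(bins, dtype=float)

    # pair lists per year (locations repeat across years)
    years = residuals.year.values
    gamma_num = np.zeros(len(bins) - 1)
    n_pairs = np.zeros(len(bins) - 1, dtype=int)
    per_year = []
    for yr in np.unique(years):
        sel = np.flatnonzero(years == yr)
        p = pts[sel]
        iu, ju = np.triu_indices(len(sel), k=1)
        d = np.linalg.norm(p[iu] - p[ju], axis=1)
        which = np.digitize(d, bins) - 1
        ok = (which >= 0) & (which < len(bins) - 1)
        per_year.append((sel, iu[ok], ju[ok], which[ok]))

    def gamma_of(res_vec):
        num = np.zeros(len(bins) - 1)
        cnt = np.zeros(len(bins) - 1, dtype=int)
        for sel, iu, ju, which in per_year:
            r = res_vec[sel]
            sq = 0.5 * (r[iu] - r[ju]) ** 2
            num += np.bincount(which, weights=sq, minlength=len(bins) - 1)
            cnt += np.bincount(which, minlength=len(bins) - 1)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan), cnt

    resid = residuals.resid.values
    gamma, n_pairs = gamma_of(resid)

    perms = np.empty((n_permutations, len(bins) - 1))
    shuffled = resid.copy()
    for b in range(n_permutations):
        for sel, *_ in per_year:
            shuffled[sel] = rng.permutation(shuffled[sel])
        perms[b], _ = gamma_of(shuffled)
    lo = np.nanpercentile(perms, envelope[0], axis=0)
    hi = np.nanpercentile(perms, envelope[1], axis=0)

    table = pd.DataFrame(
        {
            "bin_lo": bins[:-1],
            "bin_hi": bins[1:],
            "bin_mid": 0.5 * (bins[:-1] + bins[1:]),
            "gamma": gamma,
            "env_lo": lo,
            "env_hi": hi,
            "n_pairs": n_pairs,
        }
    )
    table["outside"] = (table.gamma < table.env_lo) | (table.gamma > table.env_hi)
    table.loc[table.n_pairs == 0, "outside"] = False
    return VariogramResult(table)


def report(ate_estimates, balance_reports=None, diag_summaries=None) -> pd.DataFrame:
    """Per-mine summary table with no-effect flags at both interval levels.

    Mirrors the study's decision rule: a mine shows evidence of an effect
    only when its aggregated HPD interval excludes zero.
    """
    if not ate_estimates:
        raise ValueError("no ATE estimates supplied")
    rows = []
    for est in ate_estimates:
        agg = est.table[est.table.year == "ALL"].iloc[0]
        rec = {
            "mine_id": est.mine_id,
            "ate_mean_m2": agg["mean"],
            "ate_mean_ha": agg["mean"] / 10_000.0,
            "hpd80_lo": agg["hpd80_lo"],
            "hpd80_hi": agg["hpd80_hi"],
            "hpd95_lo": agg["hpd95_lo"],
            "hpd95_hi": agg["hpd95_hi"],
            "excludes_zero_80": est.excludes_zero(80),
            "excludes_zero_95": est.excludes_zero(95),
        }
        rows.append(rec)
    out = pd.DataFrame(rows)
    if balance_reports:
        smd = {
            mid: float(np.nanmean(np.abs(b["smd_after"]))) for mid, b in balance_reports.items()
        }
        out["mean_abs_smd_after"] = out.mine_id.map(smd)
    if diag_summaries:
        for col in ("ks_pvalue", "variogram_fraction_inside"):
            out[col] = out.mine_id.map(
                {mid: d.get(col, np.nan) for mid, d in diag_summaries.items()}
            )
    return out
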
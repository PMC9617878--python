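"""End-to-end orchestration: simulate -> metric -> design -> match -> fit ->
diagnose, with stage caching, a manifest, and the sensitivity suite.

Each stage writes plain-text artifacts (CSV/GeoJSON/TIFF/JSON) under the
run directory and is skipped when its outputs already exist, so partial
reruns resume; the manifest records the configuration, seeds and SHA-256
hashes of every artifact for reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from .canopy import aggregate_blocks, canopy_loss_pixels
from .design import StudyDesignError, assemble_frame, control_pool, systematic_subsample, treated_mask
from .diagnostics import posterior_predictive, quantile_residuals, report, variogram
from .io import read_landscape, write_landscape
from .landscape import LandscapeConfig, pixel_covariate_table, simulate_landscape
from .matching import (
    MatchingError,
    balance,
    cem_match,
    common_support,
    fit_propensity,
    psm_match,
    random_controls,
)
from .outcome import ModelSpec, default_covariates, estimate_ate, fit_model, prepare_response

__all__ = ["RunConfig", "run", "sensitivity_suite", "SENSITIVITY_VARIANTS"]


@dataclass
class RunConfig:
    """One pipeline configuration; defaults mirror the main analysis
    (25 km buffer, exploration-lease pool, PSM, 4000 posterior draws)."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    buffer_km: float = 25.0
    pool: str = "lel"  # or "anywhere"
    scheme: str = "psm"  # psm | cem | random
    draws: int = 4000
    temporal: str = "exchangeable"
    rho0_km: float = 50.0  # PC range prior scale: P(rho > rho0) = 0.95
    subsample_scheme: str = "one_per_tile"
    caliper_sd: float = 0.25
    cem_bins: int = 5
    region_merges: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "runs/main"

    @property
    def buffer_m(self) -> float:
        return self.buffer_km * 1000.0

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"]["covariate_effects"] = dict(self.landscape.covariate_effects)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _usable_confounders(frame: pd.DataFrame) -> list:
    """Confounders safe for the propensity logistic in this frame.

    Drops constants and discrete confounders with a level present in only
    one arm (quasi-separation would send the IRLS coefficient to infinity);
    such variables still participate in matching through the exact-match
    constraint where applicable.
    """
    from .matching import CONTINUOUS, DEFAULT_CONFOUNDERS

    out = []
    for c in DEFAULT_CONFOUNDERS:
        col = frame[c]
        if col.nunique() <= 1:
            continue
        if c not in CONTINUOUS:
            tab = pd.crosstab(col, frame.treated)
            if tab.shape[1] < 2 or (tab.min(axis=1) == 0).any():
                continue
        out.append(c)
    return out


def _fit_propensity_robust(frame, confs, log, mid):
    """Propensity fit with the standard separation fallback: when the IRLS
    fails or separates, drop the worst-balanced remaining confounder and
    refit (it still matters for matching via the exact constraint where
    applicable)."""

    def worst_balance(cands):
        smds = {}
        t = frame.treated.values == 1
        for c in cands:
            x = frame[c].values.astype(float)
            pooled = np.sqrt((x[t].var() + x[~t].var()) / 2)
            smds[c] = abs(x[t].mean() - x[~t].mean()) / pooled if pooled > 0 else 0.0
        return max(smds, key=smds.get)

    confs = list(confs)
    while True:
        try:
            return fit_propensity(frame, confs), confs
        except MatchingError as exc:
            if len(confs) <= 2:
                raise
            named = [c for c in confs if c in str(exc)]
            drop = named[0] if named else worst_balance(confs)
            confs.remove(drop)
            log(f"[match] {mid}: propensity refit without '{drop}' ({exc})")


def _mine_seed(base: int, mine_id: str) -> int:
    h = int(hashlib.sha256(mine_id.encode()).hexdigest(), 16)
    return int((base + h) % (2**31 - 1))


def run(config: RunConfig, log=print) -> Path:
    """Execute every stage for every mine; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_json(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # -- simulate -----------------------------------------------------------
    land_dir = out / "landscape"
    if not (land_dir / "meta.json").exists():
        log(f"[simulate] generating landscape (seed {config.landscape.seed})")
        covariates, leases, stack, effects = simulate_landscape(config.landscape)
        write_landscape(stack, leases, covariates, config.landscape, land_dir)
        truth = {"theta": effects.theta, "baseline_logit": effects.baseline_logit,
                 "coefficients": effects.coefficients}
        (land_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    stack, leases, cov_table, meta = read_landscape(land_dir)
    log(f"[simulate] {len(leases)} leases, grid {stack.shape}")

    # -- metric -------------------------------------------------------------
    metric_path = out / "metric.csv"
    lcfg = config.landscape
    if not metric_path.exists():
        log("[metric] aggregating canopy loss to 1 km^2")
        blocks = aggregate_blocks(stack, lcfg.block_edge_cells, n_years=lcfg.n_years)
        canopy_loss_pixels(blocks, lcfg.pixel_size).to_csv(metric_path, index=False)
    metric = pd.read_csv(metric_path)

    # -- design / match / fit / diagnose per mine ---------------------------
    (out / "frames").mkdir(exist_ok=True)
    (out / "matched").mkdir(exist_ok=True)
    (out / "ate").mkdir(exist_ok=True)
    (out / "diagnostics").mkdir(exist_ok=True)
    n_cols = lcfg.pixel_shape[1]
    pool_ids = control_pool(leases, lcfg, config.buffer_m, pool=config.pool)
    pool_ids = systematic_subsample(pool_ids, n_cols, scheme=config.subsample_scheme)

    estimates, balances, diags, counts = [], {}, {}, []
    for mine in leases.active_lmls:
        mid = mine.lease_id
        frame_path = out / "frames" / f"{mid}.csv"
        try:
            if not frame_path.exists():
                t_ids = treated_mask(mine, lcfg, config.buffer_m)
                t_ids = systematic_subsample(t_ids, n_cols, scheme=config.subsample_scheme)
                c_ids = np.setdiff1d(pool_ids, t_ids)
                frame = assemble_frame(mine, t_ids, c_ids, metric, cov_table, lcfg,
                                       region_merges=config.region_merges)
                frame.to_csv(frame_path, index=False)
            frame = pd.read_csv(frame_path)
        except StudyDesignError as exc:
            log(f"[design] {mid}: skipped ({exc})")
            continue
        log(f"[design] {mid}: {int(frame.treated.sum())} treated / "
            f"{int((1 - frame.treated).sum())} candidate controls")

        matched_path = out / "matched" / f"{mid}.csv"
        confs = _usable_confounders(frame)
        try:
            if config.scheme == "psm":
                model, confs = _fit_propensity_robust(frame, confs, log, mid)
                supported = common_support(frame, model)
                matched = psm_match(supported, model, caliper_sd=config.caliper_sd)
                bal = balance(frame, matched, confs)
            elif config.scheme == "cem":
                matched = cem_match(frame, bins=config.cem_bins, confounders=confs)
                bal = balance(frame, matched, confs)
            elif config.scheme == "random":
                matched = random_controls(frame, seed=_mine_seed(config.seed, mid))
                bal = balance(frame, matched, confs)
            else:
                raise ValueError(f"unknown scheme {config.scheme}")
        except MatchingError as exc:
            log(f"[match] {mid}: skipped ({exc})")
            continue
        matched_frame = matched.select(frame)
        matched_frame.to_csv(matched_path, index=False)
        bal.to_csv(out / "matched" / f"{mid}_balance.csv", index=False)
        balances[mid] = bal
        counts.append({"mine_id": mid, "n_treated": matched.n_treated,
                       "n_control": len(matched.weights) - matched.n_treated,
                       "n_dropped": len(matched.dropped)})
        log(f"[match] {mid}: {matched.n_treated} pairs ({config.scheme}), "
            f"{len(matched.dropped)} treated dropped")

        prepared = prepare_response(matched_frame)
        spec = ModelSpec(covariates=default_covariates(matched_frame),
                         temporal=config.temporal,
                         rho0=config.rho0_km * 1000.0)
        fit_seed = _mine_seed(config.seed + 7, mid)
        log(f"[fit] {mid}: {len(prepared)} pixel-years, {config.draws} draws")
        draws = fit_model(prepared, spec, draws=config.draws, seed=fit_seed)
        est = estimate_ate(draws, prepared)
        est.table.assign(mine_id=mid).to_csv(out / "ate" / f"{mid}.csv", index=False)
        estimates.append(est)

        reps, ppsum = posterior_predictive(draws, n_rep=200, seed=fit_seed + 1)
        resid = quantile_residuals(reps, draws.design["y"], seed=fit_seed + 2)
        rdf = pd.DataFrame(
            {
                "x": prepared.x.values, "y": prepared.y.values,
                "year": prepared.year.values, "resid": resid,
            }
        )
        ks = sstats.kstest(resid, "uniform")
        try:
            vg = variogram(rdf, seed=fit_seed + 3)
            frac = vg.fraction_inside
            vg.bins.to_csv(out / "diagnostics" / f"{mid}_variogram.csv", index=False)
        except ValueError:
            frac = np.nan
        ppsum.to_csv(out / "diagnostics" / f"{mid}_ppc.csv", index=False)
        diags[mid] = {"ks_pvalue": float(ks.pvalue), "variogram_fraction_inside": frac,
                      **draws.diagnostics}

    if estimates:
        summary = report(estimates, balances, diags)
        summary.to_csv(out / "report.csv", index=False)
        lines = [f"mineforest run: {out}"]
        for _, r in summary.iterrows():
            verdict = "EFFECT (80% HPD excludes 0)" if r.excludes_zero_80 else "no effect detected"
            lines.append(
                f"  {r.mine_id}: ATE {r.ate_mean_ha:+.2f} ha "
                f"[80%: {r.hpd80_lo / 1e4:+.2f}, {r.hpd80_hi / 1e4:+.2f}] -> {verdict}"
            )
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        log("\n".join(lines))
    pd.DataFrame(counts).to_csv(out / "dataset_sizes.csv", index=False)

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in {".csv", ".json", ".geojson", ".txt"}:
            manifest["stages"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# the five sensitivity variants beside "main": alternative matching schemes
# and the buffer rescalings (2x and 0.4x, i.e. 50 km and 10 km around the
# 25 km default)
SENSITIVITY_VARIANTS = {
    "main": {},
    "cem": {"scheme": "cem"},
    "anywhere": {"pool": "anywhere"},
    "random": {"scheme": "random"},
    "buffer_wide": {"buffer_scale": 2.0},
    "buffer_narrow": {"buffer_scale": 0.4},
}


def sensitivity_suite(base: RunConfig, log=print) -> pd.DataFrame:
    """Run the five sensitivity variants beside the main configuration and
    tabulate per-mine ATEs and no-effect flags side by side."""
    rows = []
    base_out = Path(base.outdir)
    for name, overrides in SENSITIVITY_VARIANTS.items():
        overrides = dict(overrides)
        scale = overrides.pop("buffer_scale", None)
        if scale is not None:
            overrides["buffer_km"] = base.buffer_km * scale
        cfg = dataclasses.replace(base, outdir=str(base_out / name), **overrides)
        log(f"== sensitivity variant: {name} ==")
        rundir = run(cfg, log=log)
        rpt = rundir / "report.csv"
        if rpt.exists():
            t = pd.read_csv(rpt)
            t.insert(0, "variant", name)
            rows.append(t)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(base_out / "sensitivity.csv", index=False)
    return table
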
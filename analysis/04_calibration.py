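"""Validate the ATE estimator against ground truth.

Two simulation studies on matched-style frames drawn from the outcome
model's own generative process (300 pixels x 5 years, ZINB with per-year
Matern fields):

* null calibration — theta = 0: the fraction of aggregated 80% / 95% HPD
  intervals excluding zero should sit near 0.20 / 0.05;
* effect recovery — treated expected loss doubled (theta = log 2): the
  aggregated posterior-mean ATE should be positive and the 95% HPD should
  cover the true mean difference in nearly all replicates.

Writes results/calibration.csv. Replicate counts are kept desk-sized
(default 20 + 10); scripts/acceptance.py runs the full-size version.
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED  # noqa: E402

import numpy as np
import pandas as pd

from mineforest.calibration import (
    NULL_CALIBRATION_SPEC,
    draw_prior_hyperparameters,
    simulate_matched_frame,
)
from mineforest.outcome import ModelSpec, estimate_ate, fit_model, prepare_response


def one_fit(theta, seed, draws=1000):
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    hyp = draw_prior_hyperparameters(rng)
    frame, truth = simulate_matched_frame(n_pixels=300, n_years=5, theta=theta,
                                          seed=seed, **hyp)
    prep = prepare_response(frame)
    fitted = fit_model(prep, ModelSpec(**NULL_CALIBRATION_SPEC), draws=draws, seed=seed)
    est = estimate_ate(fitted, prep, estimand="att" if theta else "arm_contrast")
    agg = est.table[est.table.year == "ALL"].iloc[0]
    return {
        "theta": theta,
        "seed": seed,
        "ate_mean": agg["mean"],
        "hpd80_lo": agg.hpd80_lo, "hpd80_hi": agg.hpd80_hi,
        "hpd95_lo": agg.hpd95_lo, "hpd95_hi": agg.hpd95_hi,
        "true_ate": truth.true_ate,
        "excl80": agg.hpd80_lo > 0 or agg.hpd80_hi < 0,
        "excl95": agg.hpd95_lo > 0 or agg.hpd95_hi < 0,
        "covers95": agg.hpd95_lo <= truth.true_ate <= agg.hpd95_hi,
    }


def main(n_null=20, n_effect=10):
    t0 = time.time()
    rows = []
    print(f"null calibration ({n_null} replicates) ...")
    for i in range(n_null):
        rows.append(one_fit(0.0, SEED + i))
    print(f"effect recovery ({n_effect} replicates, treated loss x2) ...")
    for i in range(n_effect):
        rows.append(one_fit(np.log(2.0), SEED + 1000 + i))
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "calibration.csv", index=False)

    null = table[table.theta == 0]
    eff = table[table.theta > 0]
    print(f"\nnull:   80% HPD excludes zero in {null.excl80.mean():.0%} "
          f"(target ~20%), 95% in {null.excl95.mean():.0%} (target ~5%)")
    print(f"effect: posterior mean positive in {(eff.ate_mean > 0).mean():.0%}, "
          f"95% HPD covers the truth in {eff.covers95.mean():.0%}")
    print(f"[{time.time() - t0:.0f} s]")


if __name__ == "__main__":
    main()
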
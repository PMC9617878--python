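"""Generate the synthetic study landscape.

A 70 x 70 km planar region with 25 m cells emulating satellite-derived
tree-cover and loss-year rasters, exploration/mining/small-scale lease
polygons with road-confounded mine placement, and the confounder layers the
matching stage needs. Scales are desk-sized stand-ins for the national
setting: buffers of 6 km play the role of the 25 km buffers, with the
sensitivity suite scaling them by the same 0.4x / 2x factors the original
design used (10 and 50 km around 25 km).

Writes runs/main/landscape/ (TIFF + GeoJSON + CSV) and prints headline
numbers. Downstream scripts reuse the cached landscape.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, RUN_DIR, base_config  # noqa: E402

from mineforest.io import write_landscape
from mineforest.landscape import simulate_landscape


def main():
    config = base_config().landscape
    print(f"simulating {config.width / 1e3:.0f} x {config.height / 1e3:.0f} km landscape "
          f"(seed {config.seed}) ...")
    covariates, leases, stack, effects = simulate_landscape(config)
    out = RUN_DIR / "landscape"
    write_landscape(stack, leases, covariates, config, out)

    lost = (stack.lossyear > 0).mean()
    print(f"  leases: {len(leases)} "
          f"({len(leases.of_type('LML'))} mining, {len(leases.of_type('LEL'))} exploration, "
          f"{len(leases.of_type('SSL'))} small-scale)")
    for m in leases.active_lmls:
        print(f"    {m.lease_id}: active from year {m.active_from}, "
              f"area {m.polygon.area / 1e6:.1f} km^2, region {m.region}")
    print(f"  fine cells cleared over {config.n_years} years: {lost:.1%}")
    print(f"  true treatment effect theta = {effects.theta}")
    print(f"  written to {out}")


if __name__ == "__main__":
    main()
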
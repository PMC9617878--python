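"""Study-design geometry: treated masks, control pools, subsampling, frame
assembly and its filters."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import box

from mineforest.canopy import aggregate_blocks, canopy_loss_pixels
from mineforest.design import (
    StudyDesignError,
    assemble_frame,
    control_pool,
    systematic_subsample,
    treated_mask,
)
from mineforest.grids import pixel_grid
from mineforest.landscape import LandscapeConfig, Lease, LeaseSet, pixel_covariate_table


def toy_config(**kw):
    defaults = dict(width=20_000.0, height=20_000.0, n_years=10, n_regions=1, seed=0)
    defaults.update(kw)
    return LandscapeConfig(**defaults)


def brute_force_touching(geom, config):
    """Independent oracle: per-pixel polygon/square intersection test."""
    pid, px, py, _, _ = pixel_grid(config.width, config.height, config.pixel_size)
    half = config.pixel_size / 2
    out = []
    for i, (x, y) in enumerate(zip(px, py)):
        sq = box(x - half, y - half, x + half, y + half)
        inter = sq.intersection(geom)
        if not inter.is_empty and inter.area > 0:
            out.append(pid[i])
    return np.array(out)


class TestTreatedMask:
    def test_zero_buffer_single_pixel_interior(self):
        cfg = toy_config()
        lease = Lease("LML01", "LML", box(3_100.0, 5_100.0, 3_900.0, 5_900.0), 1)
        ids = treated_mask(lease, cfg, buffer_distance=0.0)
        # the lease sits strictly inside pixel (row 5, col 3)
        np.testing.assert_array_equal(ids, [5 * 20 + 3])

    def test_disc_geometry(self):
        cfg = toy_config()
        lease = Lease("LML01", "LML", box(9_990.0, 9_990.0, 10_010.0, 10_010.0), 1)
        ids = treated_mask(lease, cfg, buffer_distance=3_000.0)
        pid, px, py, _, _ = pixel_grid(cfg.width, cfg.height, cfg.pixel_size)
        # every pixel whose centre is within 3 km of the point must be in
        centre_in = pid[np.hypot(px - 10_000, py - 10_000) <= 3_000]
        assert np.isin(centre_in, ids).all()

    def test_matches_brute_force_oracle(self):
        cfg = toy_config()
        poly = shapely.Polygon([(2_000, 2_000), (8_500, 3_000), (6_000, 9_500)])
        lease = Lease("LML01", "LML", poly, 2)
        for dist in (0.0, 1_500.0):
            got = np.sort(treated_mask(lease, cfg, dist))
            want = brute_force_touching(poly.buffer(dist) if dist else poly, cfg)
            np.testing.assert_array_equal(got, want)

    def test_monotone_in_buffer_distance(self):
        cfg = toy_config()
        lease = Lease("LML01", "LML", box(8_000, 8_000, 9_000, 9_000), 1)
        masks = [set(treated_mask(lease, cfg, d)) for d in (1_000, 2_500, 5_000)]
        assert masks[0] <= masks[1] <= masks[2]

    def test_off_grid_lease_warns_empty(self):
        cfg = toy_config()
        lease = Lease("LML01", "LML", box(50_000, 50_000, 51_000, 51_000), 1)
        with pytest.warns(UserWarning):
            ids = treated_mask(lease, cfg, buffer_distance=100.0)
        assert ids.size == 0


class TestControlPool:
    def test_no_lels_gives_empty_pool(self):
        cfg = toy_config()
        leases = LeaseSet([Lease("LML01", "LML", box(1_000, 1_000, 2_000, 2_000), 1)])
        with pytest.warns(UserWarning):
            assert control_pool(leases, cfg, 1_000.0).size == 0

    def test_isolated_lel_fully_available(self):
        cfg = toy_config()
        lel = box(12_000, 12_000, 16_000, 16_000)
        leases = LeaseSet(
            [
                Lease("LEL01", "LEL", lel, None),
                Lease("LML01", "LML", box(1_000, 1_000, 1_500, 1_500), 1),
            ]
        )
        ids = control_pool(leases, cfg, buffer_distance=2_000.0)
        np.testing.assert_array_equal(np.sort(ids), brute_force_touching(lel, cfg))

    def test_pool_disjoint_from_treated(self):
        cfg = toy_config()
        lml = Lease("LML01", "LML", box(5_000, 5_000, 6_000, 6_000), 1)
        leases = LeaseSet(
            [lml, Lease("LEL01", "LEL", box(4_000, 4_000, 12_000, 12_000), None)]
        )
        treated = set(treated_mask(lml, cfg, 2_000.0))
        pool = set(control_pool(leases, cfg, 2_000.0))
        assert treated.isdisjoint(pool)

    def test_set_algebra_oracle(self):
        cfg = toy_config()
        lel = box(2_000, 2_000, 18_000, 12_000)
        lml = box(6_000, 5_000, 8_000, 7_000)
        ssl = box(14_000, 9_000, 15_000, 10_000)
        leases = LeaseSet(
            [
                Lease("LEL01", "LEL", lel, None),
                Lease("LML01", "LML", lml, 3),
                Lease("SSL01", "SSL", ssl, None),
            ]
        )
        dist = 1_500.0
        got = np.sort(control_pool(leases, cfg, dist))
        excl = lml.buffer(dist).union(ssl.buffer(5_000.0))
        want = np.setdiff1d(
            brute_force_touching(lel.difference(excl), cfg),
            brute_force_touching(excl, cfg),
        )
        np.testing.assert_array_equal(got, want)

    def test_anywhere_variant_ignores_lel_restriction(self):
        cfg = toy_config()
        lml = Lease("LML01", "LML", box(5_000, 5_000, 6_000, 6_000), 1)
        leases = LeaseSet([lml])
        ids = control_pool(leases, cfg, 2_000.0, pool="anywhere")
        total = cfg.pixel_shape[0] * cfg.pixel_shape[1]
        assert 0 < ids.size < total
        assert set(ids).isdisjoint(treated_mask(lml, cfg, 2_000.0))


class TestSystematicSubsample:
    def test_8x8_grid_keeps_4(self):
        ids = np.arange(64)
        kept = systematic_subsample(ids, n_cols=8)
        assert kept.size == 4

    def test_idempotent_and_deterministic(self):
        ids = np.arange(400)
        once = systematic_subsample(ids, n_cols=20)
        twice = systematic_subsample(once, n_cols=20)
        np.testing.assert_array_equal(once, twice)

    def test_retained_spacing_at_least_4km(self):
        ids = np.arange(30 * 30)
        kept = systematic_subsample(ids, n_cols=30)
        rows, cols = kept // 30, kept % 30
        pts = np.column_stack([rows, cols]) * 1000.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 4_000.0

    def test_quarter_scheme_retains_25_percent(self):
        ids = np.arange(40 * 40)
        kept = systematic_subsample(ids, n_cols=40, scheme="quarter")
        assert kept.size == ids.size // 4


class TestAssembleFrame:
    @pytest.fixture()
    def metric_and_covariates(self, small_config, small_landscape):
        cov, leases, stack, _ = small_landscape
        blocks = aggregate_blocks(stack, small_config.block_edge_cells,
                                  n_years=small_config.n_years)
        metric = canopy_loss_pixels(blocks, small_config.pixel_size)
        return metric, pixel_covariate_table(small_config, cov), leases

    def test_frame_satisfies_all_filters(self, small_config, metric_and_covariates):
        metric, ctab, leases = metric_and_covariates
        mine = leases.active_lmls[0]
        t_ids = treated_mask(mine, small_config)
        c_ids = np.setdiff1d(control_pool(leases, small_config), t_ids)
        frame = assemble_frame(mine, t_ids, c_ids, metric, ctab, small_config)
        assert (frame.mean_treecover >= 10.0).all()
        assert frame.pixel_id.is_unique
        assert set(frame.treated.unique()) == {0, 1}
        assert frame.region.nunique() == 1

    def test_late_mine_keeps_three_years(self, small_config, metric_and_covariates):
        metric, ctab, leases = metric_and_covariates
        mine = leases.active_lmls[0]
        late = Lease(mine.lease_id, "LML", mine.polygon, small_config.n_years - 2)
        t_ids = treated_mask(late, small_config)
        c_ids = np.setdiff1d(control_pool(leases, small_config), t_ids)
        frame = assemble_frame(late, t_ids, c_ids, metric, ctab, small_config)
        loss_cols = [c for c in frame.columns if c.startswith("loss_Y")]
        assert loss_cols == ["loss_Y1", "loss_Y2", "loss_Y3"]

    def test_too_late_mine_aborts(self, small_config, metric_and_covariates):
        metric, ctab, leases = metric_and_covariates
        mine = leases.active_lmls[0]
        too_late = Lease(mine.lease_id, "LML", mine.polygon, small_config.n_years)
        with pytest.raises(StudyDesignError):
            assemble_frame(too_late, [1], [2], metric, ctab, small_config)

    def test_majority_region_restriction(self, small_config, metric_and_covariates):
        metric, ctab, leases = metric_and_covariates
        mine = leases.active_lmls[0]
        t_ids = treated_mask(mine, small_config)
        c_ids = np.setdiff1d(control_pool(leases, small_config), t_ids)
        ctab2 = ctab.copy()
        # paint a minority of treated pixels into another region
        n_flip = max(1, len(t_ids) // 3)
        ctab2.loc[ctab2.pixel_id.isin(t_ids[:n_flip]), "region"] = "P9"
        frame = assemble_frame(mine, t_ids, c_ids, metric, ctab2, small_config)
        assert (frame.region != "P9").all()
        # and region merging brings them back
        merged = assemble_frame(mine, t_ids, c_ids, metric, ctab2, small_config,
                                region_merges={"P9": "P1"})
        assert merged.treated.sum() >= frame.treated.sum()
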
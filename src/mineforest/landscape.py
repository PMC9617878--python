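"""Synthetic mining landscapes with a known clearing process.

Generates everything the real study had to download: a fine-resolution
tree-cover / loss-year raster stack, mining-lease polygons (large-scale
mining leases, large-scale exploration leases, small-scale leases), and the
confounder layers used for matching — with the generative parameters
retained so every downstream stage can be validated against ground truth.

The clearing process is a discrete-time first-clearing hazard: per fine cell
and year,

    logit h = baseline + sum_c beta_c z_c + field(s) + theta * treated(s, t)

where ``z_c`` are standardised covariate grids, ``field`` is a Matern(nu=1)
Gaussian random field, and ``treated(s, t)`` is true once the cell falls in
an active mining lease or its buffer. On top of the hazard, an independent
block-level "suppression" event (probability ``zero_inflation`` per 1 km^2
block-year) forces zero clearing in that block-year; this is what gives the
aggregated response its excess zeros.

Covariate scales (documented per variable): tree cover, elevation, slope,
distance-to-road and population density are fine grids (aggregated to pixel
means for the matching table); burning evidence, agro-ecological zone,
protection and region are generated directly at the 1 km^2 pixel scale.
Confounding is built in twice over: mines prefer road-proximate exploration
leases, and the hazard itself responds to road distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon, box

from .grids import FineRasterStack, pixel_grid
from .spatial import grf_sample_grid_fast

__all__ = [
    "LandscapeConfig",
    "Lease",
    "LeaseSet",
    "Covariates",
    "TrueEffects",
    "generate_covariates",
    "place_leases",
    "simulate_loss",
    "simulate_landscape",
]

LML, LEL, SSL = "LML", "LEL", "SSL"

DEFAULT_EFFECTS = {
    "treecover": 0.25,  # denser woodland carries more clearing (charcoal)
    "dist_road": -0.6,  # access is the dominant driver
    "slope": -0.3,
    "popdens": 0.4,
    "elevation": -0.1,
}


@dataclass
class LandscapeConfig:
    """Free parameters of the generator.

    Distances are metres. ``treatment_multiplier`` (theta) is the ground
    truth log-odds offset on the clearing hazard inside active lease +
    buffer areas — the quantity the outcome model is later asked to
    recover. Defaults emulate a moderately deforested miombo-like region:
    a baseline hazard of ~0.7%/yr for an average forest cell, spatially
    clustered clearing, and ~25% of block-years suppressed to zero.
    """

    width: float = 40_000.0
    height: float = 40_000.0
    fine_cell_size: float = 25.0
    block_edge_cells: int = 4
    pixel_size: float = 1000.0
    n_years: int = 12
    baseline_logit: float = -5.0
    covariate_effects: dict = dc_field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    field_variance: float = 0.6
    field_range: float = 5_000.0
    treatment_multiplier: float = 0.0
    zero_inflation: float = 0.25
    n_lml: int = 2
    n_lel: int = 10
    n_ssl: int = 3
    buffer_distance: float = 25_000.0
    confound_strength: float = 1.0
    n_roads: int = 4
    n_towns: int = 4
    n_regions: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")
        if self.field_variance < 0 or self.field_range <= 0:
            raise ValueError("invalid spatial field parameters")
        block = self.block_edge_cells * self.fine_cell_size
        if abs(self.pixel_size / block - round(self.pixel_size / block)) > 1e-9:
            raise ValueError("block size must divide the pixel size")
        for extent in (self.width, self.height):
            if abs(extent / self.fine_cell_size - round(extent / self.fine_cell_size)) > 1e-9:
                raise ValueError("extent is not divisible by the fine cell size")
            if abs(extent / self.pixel_size - round(extent / self.pixel_size)) > 1e-9:
                raise ValueError("extent is not divisible by the pixel size")

    @property
    def fine_shape(self):
        return (
            int(round(self.height / self.fine_cell_size)),
            int(round(self.width / self.fine_cell_size)),
        )

    @property
    def pixel_shape(self):
        return (
            int(round(self.height / self.pixel_size)),
            int(round(self.width / self.pixel_size)),
        )


@dataclass
class Lease:
    lease_id: str
    lease_type: str  # LML | LEL | SSL
    polygon: Polygon
    active_from: int | None  # 1-based year; None = never active
    region: str = ""


@dataclass
class LeaseSet:
    leases: list

    def of_type(self, lease_type):
        return [l for l in self.leases if l.lease_type == lease_type]

    @property
    def active_lmls(self):
        return [l for l in self.of_type(LML) if l.active_from is not None]

    def __len__(self):
        return len(self.leases)

    def __iter__(self):
        return iter(self.leases)


@dataclass
class Covariates:
    """Fine-grid and pixel-scale confounder layers plus source geometry."""

    fine: dict  # name -> (ny, nx) array: treecover, elevation, slope, dist_road, popdens
    pixel: pd.DataFrame  # pixel_id, x, y, burned, aez, protected, region
    roads: list  # LineStrings
    region_of_xy: object  # callable (x, y) -> region label


@dataclass
class TrueEffects:
    theta: float
    baseline_logit: float
    coefficients: dict
    field: np.ndarray
    covariate_z: dict  # standardised covariate grids entering the hazard


def _region_label(x, width, n_regions):
    """Vertical-strip 'provinces' (returns array of labels for x coords)."""
    edges = np.linspace(0, width, n_regions + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_regions - 1)
    return np.array([f"P{i + 1}" for i in np.atleast_1d(idx)])


def _point_segment_distance(px, py, seg):
    (x1, y1), (x2, y2) = seg
    dx, dy = x2 - x1, y2 - y1
    denom = dx * dx + dy * dy
    if denom == 0:
        return np.hypot(px - x1, py - y1)
    t = np.clip(((px - x1) * dx + (py - y1) * dy) / denom, 0.0, 1.0)
    return np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def distance_to_roads(xx, yy, roads):
    """True Euclidean distance from points to the nearest road segment."""
    d = np.full(np.shape(xx), np.inf, dtype=float)
    for road in roads:
        coords = np.asarray(road.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            d = np.minimum(d, _point_segment_distance(xx, yy, (a, b)))
    return d


def _sample_roads(config, rng):
    """Poisson-line-style road network: long chords plus short feeder roads.

    Feeders branch off the main chords, putting road-distance variation at
    the kilometre scale everywhere instead of only along a few corridors.
    """
    roads = []
    n = max(int(config.n_roads), 0)
    extent = box(0, 0, config.width, config.height)
    diag = math.hypot(config.width, config.height)
    for _ in range(n):
        cx = rng.uniform(0, config.width)
        cy = rng.uniform(0, config.height)
        angle = rng.uniform(0, np.pi)
        dx, dy = math.cos(angle), math.sin(angle)
        line = LineString(
            [(cx - diag * dx, cy - diag * dy), (cx + diag * dx, cy + diag * dy)]
        )
        clipped = line.intersection(extent)
        if not clipped.is_empty and clipped.length > 0:
            roads.append(clipped)
    mains = list(roads)
    for _ in range(3 * n):
        if not mains:
            break
        host = mains[rng.integers(len(mains))]
        if host.geom_type != "LineString":
            continue
        start = host.interpolate(rng.uniform(0, host.length))
        angle = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(3_000, 12_000)
        feeder = LineString(
            [
                (start.x, start.y),
                (start.x + length * math.cos(angle), start.y + length * math.sin(angle)),
            ]
        ).intersection(extent)
        if not feeder.is_empty and feeder.length > 0:
            roads.append(feeder)
    return roads


def generate_covariates(config: LandscapeConfig, seed=None) -> Covariates:
    """Sample all confounder layers for one landscape.

    With ``field_variance == 0`` every sampled field is constant, so the
    continuous covariates collapse to their deterministic components.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ny, nx = config.fine_shape
    cell = config.fine_cell_size
    x = (np.arange(nx) + 0.5) * cell
    y = (np.arange(ny) + 0.5) * cell
    xx, yy = np.meshgrid(x, y)

    var = config.field_variance
    # tree cover: smooth field pushed through a logistic onto [0, 100]%
    f_tc = grf_sample_grid_fast((ny, nx), cell, rho=4 * config.field_range, sigma=np.sqrt(var), rng=rng)
    treecover = 100.0 / (1.0 + np.exp(-(0.6 + 1.5 * f_tc)))

    # elevation: long-range smooth field + regional tilt; slope from gradient
    f_el = grf_sample_grid_fast((ny, nx), cell, rho=2 * config.field_range, sigma=np.sqrt(var), rng=rng)
    elevation = 1200.0 + 120.0 * f_el + 0.0003 * xx
    gy, gx = np.gradient(elevation, cell)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    roads = _sample_roads(config, rng)
    if roads:
        dist_road = distance_to_roads(xx, yy, roads)
    else:
        dist_road = np.full((ny, nx), math.hypot(config.width, config.height))

    # towns sit on roads and villages scatter everywhere, so population
    # density varies both regionally and within any buffer-sized window
    popdens = np.full((ny, nx), 1.0)

    def add_settlement(tx, ty, amp, scale):
        nonlocal popdens
        popdens = popdens + amp * np.exp(
            -((xx - tx) ** 2 + (yy - ty) ** 2) / (2 * scale**2)
        )

    for _ in range(config.n_towns):
        if roads:
            road = roads[rng.integers(len(roads))]
            pt = road.interpolate(rng.uniform(0, road.length))
            tx, ty = pt.x, pt.y
        else:
            tx, ty = rng.uniform(0, config.width), rng.uniform(0, config.height)
        add_settlement(tx, ty, rng.uniform(50, 300), rng.uniform(2_000, 6_000))
    n_villages = 8 * config.n_towns
    for _ in range(n_villages):
        add_settlement(
            rng.uniform(0, config.width), rng.uniform(0, config.height),
            rng.uniform(3, 30), rng.uniform(800, 2_500),
        )

    # pixel-scale layers
    pid, px, py, npr, npc = pixel_grid(config.width, config.height, config.pixel_size)
    f_burn = grf_sample_grid_fast((npr, npc), config.pixel_size, rho=6 * config.field_range,
                             sigma=np.sqrt(var), rng=rng).ravel()
    burned = (rng.random(pid.size) < 1.0 / (1.0 + np.exp(-(-1.6 + f_burn)))).astype(int)
    f_aez = grf_sample_grid_fast((npr, npc), config.pixel_size, rho=10 * config.field_range,
                            sigma=1.0, rng=rng).ravel()
    if np.ptp(f_aez) == 0:
        aez = np.zeros(pid.size, dtype=int)
    else:
        aez = np.searchsorted(np.quantile(f_aez, [1 / 3, 2 / 3]), f_aez)

    # protected areas: one rectangle per ~2000 km^2, ~10% of the extent
    protected_polys = []
    n_pa = max(1, int(config.width * config.height / 2_000e6))
    for _ in range(n_pa):
        w = rng.uniform(0.15, 0.3) * config.width
        h = rng.uniform(0.15, 0.3) * config.height
        x0 = rng.uniform(0, config.width - w)
        y0 = rng.uniform(0, config.height - h)
        protected_polys.append(box(x0, y0, x0 + w, y0 + h))
    protected = np.zeros(pid.size, dtype=int)
    for poly in protected_polys:
        protected |= shapely.contains_xy(poly, px, py).astype(int)

    region = _region_label(px, config.width, config.n_regions)
    pixel = pd.DataFrame(
        {"pixel_id": pid, "x": px, "y": py, "burned": burned, "aez": aez,
         "protected": protected, "region": region}
    )

    def region_of_xy(qx, qy):
        return _region_label(np.asarray(qx, dtype=float), config.width, config.n_regions)

    fine = {
        "treecover": treecover,
        "elevation": elevation,
        "slope": slope,
        "dist_road": dist_road,
        "popdens": popdens,
    }
    return Covariates(fine=fine, pixel=pixel, roads=roads, region_of_xy=region_of_xy)


def _irregular_polygon(cx, cy, radius, rng, n_vertices=9):
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = radius * rng.uniform(0.6, 1.0, n_vertices)
    pts = np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
    poly = Polygon(pts).buffer(0)
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _sample_point_in(poly, rng, max_tries=200):
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(max_tries):
        p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if shapely.contains_xy(poly, p[0], p[1]):
            return p
    c = poly.representative_point()
    return (c.x, c.y)


def place_leases(config: LandscapeConfig, covariates: Covariates, seed=None,
                 max_tries=50) -> LeaseSet:
    """Place exploration leases, then mines inside them, then small-scale leases.

    Mine (LML) placement is *confounded*: an exploration lease is selected
    with probability proportional to exp(-confound_strength * d_road / 5 km)
    evaluated at its centroid, so mines end up near roads — exactly the
    assignment bias statistical matching must remove. ``confound_strength``
    of 0 makes the choice uniform.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 1_000_003
    )
    extent = box(0, 0, config.width, config.height)
    leases = []

    lels = []
    for i in range(config.n_lel):
        for _ in range(max_tries):
            cx = rng.uniform(0.1 * config.width, 0.9 * config.width)
            cy = rng.uniform(0.1 * config.height, 0.9 * config.height)
            # exploration targets accessible ground too (half the mine-level
            # road bias), which keeps treated and control covariates
            # overlapping the way real lease geography does
            if config.confound_strength > 0 and covariates.roads:
                d = float(distance_to_roads(np.array([cx]), np.array([cy]),
                                            covariates.roads)[0])
                if rng.random() > math.exp(-0.5 * config.confound_strength * d / 5_000.0):
                    continue
            radius = rng.uniform(0.06, 0.12) * min(config.width, config.height)
            poly = _irregular_polygon(cx, cy, radius, rng).intersection(extent)
            if poly.is_empty or poly.area < 0.25 * np.pi * radius**2:
                continue
            if all(not poly.intersects(l.polygon) for l in lels):
                break
        else:
            raise RuntimeError(f"could not place exploration lease {i} without overlap")
        lease = Lease(f"LEL{i + 1:02d}", LEL, poly, None)
        lels.append(lease)
        leases.append(lease)

    if config.n_lml > 0 and not lels:
        raise RuntimeError("mines require at least one exploration lease")

    # road distance at LEL centroids drives the confounded choice
    if config.n_lml > 0:
        cents = np.array([[l.polygon.centroid.x, l.polygon.centroid.y] for l in lels])
        d_road = distance_to_roads(cents[:, 0], cents[:, 1], covariates.roads)
        logw = -config.confound_strength * d_road / 5_000.0
        w = np.exp(logw - logw.max())
        w /= w.sum()

    lo, hi = 1, max(config.n_years - 5, 1)
    for i in range(config.n_lml):
        for attempt in range(max_tries):
            host = lels[rng.choice(len(lels), p=w)]
            cx, cy = _sample_point_in(host.polygon, rng)
            radius = rng.uniform(0.2, 0.45) * np.sqrt(host.polygon.area / np.pi)
            poly = _irregular_polygon(cx, cy, radius, rng).intersection(host.polygon)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
            if poly.is_empty or poly.area < 1e4:
                continue
            existing = [l.polygon for l in leases if l.lease_type == LML]
            if all(not poly.intersects(p) for p in existing):
                break
        else:
            raise RuntimeError(f"could not place mining lease {i} inside an exploration lease")
        active = int(rng.integers(lo, hi + 1))
        leases.append(Lease(f"LML{i + 1:02d}", LML, poly, active))

    for i in range(config.n_ssl):
        cx = rng.uniform(0, config.width)
        cy = rng.uniform(0, config.height)
        poly = _irregular_polygon(cx, cy, rng.uniform(400, 1_200), rng).intersection(extent)
        if poly.is_empty:
            continue
        leases.append(Lease(f"SSL{i + 1:02d}", SSL, poly, None))

    for lease in leases:
        c = lease.polygon.centroid
        lease.region = str(covariates.region_of_xy(c.x, c.y)[0])
    return LeaseSet(leases)


def _standardise(grid):
    sd = grid.std()
    if sd == 0:
        return np.zeros_like(grid)
    return (grid - grid.mean()) / sd


def treated_fine_mask(config: LandscapeConfig, lease: Lease) -> np.ndarray:
    """Fine-cell centres inside the buffered lease polygon."""
    ny, nx = config.fine_shape
    cell = config.fine_cell_size
    buffered = lease.polygon.buffer(config.buffer_distance)
    xs = (np.arange(nx) + 0.5) * cell
    ys = (np.arange(ny) + 0.5) * cell
    xx, yy = np.meshgrid(xs, ys)
    # cheap bounding-box prefilter before the exact polygon test
    minx, miny, maxx, maxy = buffered.bounds
    cand = (xx >= minx) & (xx <= maxx) & (yy >= miny) & (yy <= maxy)
    out = np.zeros((ny, nx), dtype=bool)
    if cand.any():
        out[cand] = shapely.contains_xy(buffered, xx[cand], yy[cand])
    return out


def simulate_loss(config: LandscapeConfig, covariates: Covariates,
                  leases: LeaseSet, seed=None):
    """Run the first-clearing hazard forward and return rasters + truth.

    Returns ``(FineRasterStack, TrueEffects)``. Suppression operates on the
    1 km^2 block lattice: a suppressed block-year records no loss at all,
    whatever the hazard said.
    """
    rng = np.random.default_rng(
        (config.seed if seed is None else seed) + 2_000_003
    )
    ny, nx = config.fine_shape
    z = {name: _standardise(covariates.fine[name])
         for name in config.covariate_effects if name in covariates.fine}
    field = grf_sample_grid_fast((ny, nx), config.fine_cell_size,
                            rho=config.field_range,
                            sigma=np.sqrt(config.field_variance), rng=rng)
    eta0 = np.full((ny, nx), config.baseline_logit) + field
    for name, beta in config.covariate_effects.items():
        if name in z:
            eta0 = eta0 + beta * z[name]

    theta = config.treatment_multiplier
    masks = [(l.active_from, treated_fine_mask(config, l)) for l in leases.active_lmls]

    ppr = int(round(config.pixel_size / config.fine_cell_size))  # fine cells per pixel edge
    npr, npc = config.pixel_shape
    lossyear = np.zeros((ny, nx), dtype=np.int32)
    alive = np.ones((ny, nx), dtype=bool)
    for t in range(1, config.n_years + 1):
        eta = eta0.copy()
        if theta != 0.0:
            for active_from, mask in masks:
                if t >= active_from:
                    eta[mask] += theta
        else:
            pass  # hazard unchanged under the null
        p = 1.0 / (1.0 + np.exp(-eta))
        newly = alive & (rng.random((ny, nx)) < p)
        suppressed = rng.random((npr, npc)) < config.zero_inflation
        if suppressed.any():
            supp_fine = np.repeat(np.repeat(suppressed, ppr, axis=0), ppr, axis=1)
            newly &= ~supp_fine
        lossyear[newly] = t
        alive &= ~newly

    stack = FineRasterStack(
        treecover2000=covariates.fine["treecover"],
        lossyear=lossyear,
        cell_size=config.fine_cell_size,
    )
    effects = TrueEffects(
        theta=theta,
        baseline_logit=config.baseline_logit,
        coefficients=dict(config.covariate_effects),
        field=field,
        covariate_z=z,
    )
    return stack, effects


def pixel_covariate_table(config: LandscapeConfig, covariates: Covariates) -> pd.DataFrame:
    """Confounders at the 1 km^2 analysis scale.

    Continuous fine grids are aggregated by the pixel mean; the pixel-scale
    layers (burned, aez, protected, region) are joined through unchanged.
    """
    ppr = int(round(config.pixel_size / config.fine_cell_size))
    npr, npc = config.pixel_shape

    def agg(grid):
        return grid.reshape(npr, ppr, npc, ppr).mean(axis=(1, 3)).ravel()

    out = covariates.pixel.copy()
    for name in ("dist_road", "elevation", "slope", "popdens"):
        out[name] = agg(covariates.fine[name])
    return out


def simulate_landscape(config: LandscapeConfig):
    """Covariates, leases and loss rasters from one top-level seed."""
    covariates = generate_covariates(config)
    leases = place_leases(config, covariates)
    stack, effects = simulate_loss(config, covariates, leases)
    return covariates, leases, stack, effects
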
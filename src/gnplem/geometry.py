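"""Cell geometry and intracellular GNP placement scenarios.

The cell is an axis-aligned ellipsoid centred at the origin (default
semi-axes 7.75 × 5.75 × 5.75 µm, i.e. 15.5 µm by 11.5 µm elliptical
diameters with the third axis taken equal to the minor one) containing a
spherical nucleus of radius 4 µm. GNPs are confined to the cytoplasm —
inside the cell, outside the nucleus — matching the experimental
observation that the particles traffic through the endo-lysosomal pathway
and do not enter the nucleus.

Three placement scenarios are modelled:

``uniform_cytoplasm``
    individually dispersed GNPs, uniform over the cytoplasm;
``perinuclear``
    uniform proposals thinned with probability exp(−d/λ) where d is the
    distance to the nucleus surface (λ = ``decay_length_um``);
``vesicle``
    GNPs confined in 500 nm endosomal vesicles of 100 GNPs each, vesicle
    centres uniform over the cytoplasm with the whole vesicle kept inside it.

All sampling is driven by ``numpy.random.default_rng(seed)``; identical
configuration (including seed) reproduces placements bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gnplem.units import NM_PER_UM

__all__ = [
    "CellGeometry",
    "VesicleSpec",
    "PlacementConfig",
    "GNPPlacement",
    "SCENARIOS",
    "pack_vesicles",
    "distance_to_nucleus_surface",
    "sample_gnp_positions",
]

SCENARIOS = ("uniform_cytoplasm", "perinuclear", "vesicle")


@dataclass(frozen=True)
class CellGeometry:
    """Ellipsoidal cell with a centred spherical nucleus; lengths in µm."""

    semi_axis_a: float = 7.75
    semi_axis_b: float = 5.75
    semi_axis_c: float = 5.75
    nucleus_radius: float = 4.0

    def __post_init__(self) -> None:
        axes = (self.semi_axis_a, self.semi_axis_b, self.semi_axis_c)
        if any(a <= 0 for a in axes):
            raise ValueError(f"all semi-axes must be positive, got {axes}")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.nucleus_radius >= min(axes):
            raise ValueError("nucleus sphere must lie strictly inside the cell ellipsoid")

    @property
    def semi_axes(self) -> np.ndarray:
        return np.array([self.semi_axis_a, self.semi_axis_b, self.semi_axis_c])

    def inside_cell(self, points: np.ndarray, margin_um: float = 0.0) -> np.ndarray:
        """True where points lie inside the cell ellipsoid shrunk by ``margin_um``."""
        pts = np.atleast_2d(points)
        axes = self.semi_axes - margin_um
        if np.any(axes <= 0):
            raise ValueError("margin exceeds a semi-axis")
        q = np.sum((pts / axes) ** 2, axis=1)
        return q <= 1.0 + 1e-12

    def outside_nucleus(self, points: np.ndarray, margin_um: float = 0.0) -> np.ndarray:
        """True where points lie at or beyond the nucleus surface + margin."""
        pts = np.atleast_2d(points)
        r = np.linalg.norm(pts, axis=1)
        return r >= self.nucleus_radius + margin_um - 1e-12

    def in_cytoplasm(self, points: np.ndarray, margin_um: float = 0.0) -> np.ndarray:
        return self.inside_cell(points, margin_um) & self.outside_nucleus(points, margin_um)


@dataclass(frozen=True)
class VesicleSpec:
    """Endosomal vesicle: 500 nm diameter holding 100 GNPs by default."""

    diameter_nm: float = 500.0
    occupancy: int = 100

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("vesicle diameter must be positive")
        if self.occupancy < 1:
            raise ValueError("vesicle occupancy must be >= 1")

    @property
    def radius_um(self) -> float:
        return self.diameter_nm / 2.0 / NM_PER_UM


@dataclass(frozen=True)
class PlacementConfig:
    """Scenario, GNP count/diameter and seed for one placement draw.

    ``min_center_separation_um`` (vesicle scenario only): if set, vesicle
    centres are dart-thrown to respect that minimum pairwise distance, with
    a retry budget. Left at None, centres may overlap — at the study scale
    (3670 vesicles of 500 nm) the cytoplasm is packed near the hard-sphere
    random-sequential-addition saturation limit, where strict non-overlap
    is unattainable by dart throwing and has negligible dosimetric effect.
    """

    scenario: str
    n_gnp: int
    gnp_diameter_nm: float = 10.0
    decay_length_um: float = 1.0
    seed: int = 0
    min_center_separation_um: float | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.n_gnp < 0:
            raise ValueError("n_gnp must be >= 0")
        if self.gnp_diameter_nm <= 0:
            raise ValueError("gnp_diameter_nm must be positive")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be positive")


@dataclass(frozen=True)
class GNPPlacement:
    """Sampled GNP coordinates (µm, cell-centred) plus the generating config."""

    coordinates: np.ndarray
    gnp_diameter_nm: float
    config: PlacementConfig
    vesicle_centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return self.coordinates.shape[0]


def pack_vesicles(n_gnp: int, occupancy: int) -> int:
    """Number of vesicles needed for ``n_gnp`` GNPs at ``occupancy`` per vesicle."""
    if occupancy < 1:
        raise ValueError("occupancy must be >= 1")
    if n_gnp < 0:
        raise ValueError("n_gnp must be >= 0")
    return -(-n_gnp // occupancy)


def distance_to_nucleus_surface(point, geom: CellGeometry) -> float:
    """Signed distance (µm) from a point to the nucleus surface; negative inside."""
    p = np.asarray(point, dtype=float)
    return float(np.linalg.norm(p, axis=-1) - geom.nucleus_radius)


def _uniform_in_ellipsoid(rng: np.random.Generator, n: int, axes: np.ndarray) -> np.ndarray:
    """Uniform points in an axis-aligned ellipsoid via the unit-ball transform."""
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return d * r[:, None] * axes


def _sample_cytoplasm(
    rng: np.random.Generator,
    n: int,
    geom: CellGeometry,
    margin_um: float = 0.0,
    accept_fn=None,
) -> np.ndarray:
    """Rejection-sample ``n`` cytoplasm points, optionally thinned by ``accept_fn``."""
    axes = geom.semi_axes - margin_um
    out = np.empty((n, 3))
    got = 0
    batch = max(4 * n, 1024)
    while got < n:
        cand = _uniform_in_ellipsoid(rng, batch, axes)
        keep = np.linalg.norm(cand, axis=1) >= geom.nucleus_radius + margin_um
        cand = cand[keep]
        if accept_fn is not None and cand.size:
            cand = cand[rng.random(cand.shape[0]) < accept_fn(cand)]
        take = min(n - got, cand.shape[0])
        out[got : got + take] = cand[:take]
        got += take
    return out


def _sample_vesicle_centers(
    rng: np.random.Generator,
    n_vesicles: int,
    geom: CellGeometry,
    spec: VesicleSpec,
    min_sep_um: float | None,
    max_attempts_per_vesicle: int = 2000,
) -> np.ndarray:
    margin = spec.radius_um
    if min_sep_um is None:
        return _sample_cytoplasm(rng, n_vesicles, geom, margin_um=margin)
    centers = np.empty((n_vesicles, 3))
    min_sep2 = min_sep_um**2
    for i in range(n_vesicles):
        for _ in range(max_attempts_per_vesicle):
            c = _sample_cytoplasm(rng, 1, geom, margin_um=margin)[0]
            if i == 0 or np.min(np.sum((centers[:i] - c) ** 2, axis=1)) >= min_sep2:
                centers[i] = c
                break
        else:
            raise RuntimeError(
                f"could not place vesicle {i + 1}/{n_vesicles} without overlap after "
                f"{max_attempts_per_vesicle} attempts; use fewer or smaller vesicles, "
                "or set min_center_separation_um=None"
            )
    return centers


def sample_gnp_positions(
    geom: CellGeometry,
    cfg: PlacementConfig,
    vesicles: VesicleSpec | None = None,
) -> GNPPlacement:
    """Draw GNP coordinates for one scenario.

    Vesicle scenario: ``ceil(n_gnp / occupancy)`` vesicle centres are placed
    uniformly in the cytoplasm (whole vesicle inside it), then each vesicle is
    filled with ``occupancy`` GNPs uniform in its sphere; the last vesicle
    holds the remainder. Every emitted GNP satisfies the cytoplasm predicate;
    the rare vesicle-interior draw that would cross the cell boundary is
    redrawn within its vesicle.
    """
    if cfg.scenario == "vesicle":
        if vesicles is None:
            raise ValueError("vesicle scenario requires a VesicleSpec")
    elif vesicles is not None:
        raise ValueError(f"VesicleSpec given but scenario is {cfg.scenario!r}")
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_gnp == 0:
        return GNPPlacement(np.empty((0, 3)), cfg.gnp_diameter_nm, cfg)

    if cfg.scenario == "uniform_cytoplasm":
        coords = _sample_cytoplasm(rng, cfg.n_gnp, geom)
        return GNPPlacement(coords, cfg.gnp_diameter_nm, cfg)

    if cfg.scenario == "perinuclear":
        lam = cfg.decay_length_um

        def accept(pts: np.ndarray) -> np.ndarray:
            d = np.linalg.norm(pts, axis=1) - geom.nucleus_radius
            return np.exp(-d / lam)

        coords = _sample_cytoplasm(rng, cfg.n_gnp, geom, accept_fn=accept)
        return GNPPlacement(coords, cfg.gnp_diameter_nm, cfg)

    # vesicle scenario
    assert vesicles is not None
    n_ves = pack_vesicles(cfg.n_gnp, vesicles.occupancy)
    centers = _sample_vesicle_centers(rng, n_ves, geom, vesicles, cfg.min_center_separation_um)
    counts = np.full(n_ves, vesicles.occupancy)
    counts[-1] = cfg.n_gnp - vesicles.occupancy * (n_ves - 1)
    offsets = _uniform_in_ellipsoid(rng, cfg.n_gnp, np.full(3, vesicles.radius_um))
    coords = np.repeat(centers, counts, axis=0) + offsets
    bad = ~geom.in_cytoplasm(coords)
    owner = np.repeat(np.arange(n_ves), counts)
    guard = 0
    while np.any(bad):
        idx = np.flatnonzero(bad)
        redo = _uniform_in_ellipsoid(rng, idx.size, np.full(3, vesicles.radius_um))
        coords[idx] = centers[owner[idx]] + redo
        bad = np.zeros(len(coords), dtype=bool)
        bad[idx] = ~geom.in_cytoplasm(coords[idx])
        guard += 1
        if guard > 1000:
            raise RuntimeError("vesicle interior resampling did not converge")
    return GNPPlacement(coords, cfg.gnp_diameter_nm, cfg, vesicle_centers=centers)
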
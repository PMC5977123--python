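"""Seeded synthetic-data generators emulating the study's measurements.

Every generator is a pure function of its parameters and seed, and its
defaults are the study conditions: four treatment arms (saline, GNP-RGD,
cisplatin, GNP-RGD;CIS) with and without a 2 Gy fraction, nine clonogenic
plates per arm, the reported per-cell GNP uptake means, the reported 53BP1
foci densities at the reported nucleus counts, and the TEM core-diameter
sample (10.04 ± 0.89 nm, n = 50).

Mechanisms are the simplest consistent with the downstream estimators:
colony counts are Binomial(plated, PE × SF); per-cell gold masses are
lognormal around count × particle mass at a stated coefficient of
variation; foci counts are Poisson with intensity density × nuclear area,
areas lognormal; TEM diameters are normal truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gnplem.assays import FociRecord, PlateRecord, UptakeMeasurement
from gnplem.units import gnp_gold_mass_g

__all__ = [
    "StudyDesign",
    "ExperimentMetadata",
    "UPTAKE_MEANS",
    "UPTAKE_CV",
    "FOCI_DENSITIES",
    "FOCI_N_NUCLEI",
    "gen_colony_counts",
    "gen_uptake_measurements",
    "gen_foci_counts",
    "gen_tem_diameters",
]

#: Reported per-cell GNP counts for the three constructs.
UPTAKE_MEANS: dict[str, float] = {
    "GNP": 56_000.0,
    "GNP-RGD": 358_000.0,
    "GNP-RGD;CIS": 367_000.0,
}

#: Coefficients of variation implied by the printed spread of the counts.
UPTAKE_CV: dict[str, float] = {
    "GNP": 1_200.0 / 56_000.0,
    "GNP-RGD": 47_000.0 / 358_000.0,
    "GNP-RGD;CIS": 6_600.0 / 367_000.0,
}

#: Reported 53BP1 foci per µm² of projected nuclear area, irradiated arms.
FOCI_DENSITIES: dict[str, float] = {
    "IR saline": 0.024,
    "IR GNP-RGD": 0.026,
    "IR CIS": 0.026,
    "IR GNP-RGD;CIS": 0.040,
}

#: Nuclei imaged per arm.
FOCI_N_NUCLEI: dict[str, int] = {
    "IR saline": 274,
    "IR GNP-RGD": 310,
    "IR CIS": 307,
    "IR GNP-RGD;CIS": 357,
}


def _default_true_sf() -> dict[tuple[str, float], float]:
    return {
        ("saline", 0.0): 1.0,
        ("GNP-RGD", 0.0): 1.0,
        ("CIS", 0.0): 0.61,
        ("GNP-RGD;CIS", 0.0): 0.60,
        ("saline", 2.0): 0.31,
        ("GNP-RGD", 2.0): 0.25,
        ("CIS", 2.0): 0.23,
        ("GNP-RGD;CIS", 2.0): 0.16,
    }


@dataclass(frozen=True)
class StudyDesign:
    """Clonogenic study layout: arms, ground-truth SFs, plating and seed.

    ``true_sf`` maps (agent, dose in Gy) to the clonogenic survival fraction
    that arm exhibits relative to the unirradiated saline control; defaults
    are the study's reported values. Nine plates per arm reflect n = 9 cell
    preparations over three independent set-ups.
    """

    true_sf: dict[tuple[str, float], float] = field(default_factory=_default_true_sf)
    pe: float = 0.5
    plates_per_condition: int = 9
    cells_plated: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pe <= 1:
            raise ValueError(f"plating efficiency must lie in (0, 1], got {self.pe}")
        for cond, sf in self.true_sf.items():
            if not 0 <= sf <= 1:
                raise ValueError(f"true SF for {cond} must lie in [0, 1], got {sf}")
            if self.pe * sf > 1:
                raise ValueError(f"pe × sf > 1 for {cond}")
        if self.plates_per_condition < 1 or self.cells_plated < 1:
            raise ValueError("plates_per_condition and cells_plated must be >= 1")

    @staticmethod
    def condition_label(agent: str, dose_gy: float) -> str:
        return f"{agent} @ {dose_gy:g} Gy"


@dataclass(frozen=True)
class ExperimentMetadata:
    """Construct and exposure metadata echoed into synthetic outputs."""

    gnp_concentration_nM: float = 0.3
    cisplatin_concentration_nM: float = 435.0
    cisplatin_per_gnp: float = 620.0
    calnn_per_gnp: float = 300.0
    rgd_per_gnp: float = 18.0  # reported range 16-20
    incubation_h: float = 16.0

    def __post_init__(self) -> None:
        vals = (
            self.gnp_concentration_nM,
            self.cisplatin_concentration_nM,
            self.cisplatin_per_gnp,
            self.calnn_per_gnp,
            self.rgd_per_gnp,
            self.incubation_h,
        )
        if any(v < 0 for v in vals):
            raise ValueError("metadata values must be >= 0")


def gen_colony_counts(design: StudyDesign) -> list[PlateRecord]:
    """Simulate every plate of the study: colonies ~ Binomial(plated, PE × SF)."""
    rng = np.random.default_rng(design.seed)
    records: list[PlateRecord] = []
    for (agent, dose), sf in design.true_sf.items():
        p = design.pe * sf
        counts = rng.binomial(design.cells_plated, p, size=design.plates_per_condition)
        label = design.condition_label(agent, dose)
        for rep, c in enumerate(counts):
            records.append(
                PlateRecord(
                    condition=label,
                    cells_plated=design.cells_plated,
                    colonies=int(c),
                    replicate=rep,
                )
            )
    return records


def _lognormal_around(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal draws with the requested arithmetic mean and CV."""
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def gen_uptake_measurements(
    means: dict[str, float] | None = None,
    cv: dict[str, float] | float | None = None,
    n: int = 9,
    seed: int = 0,
    gnp_diameter_nm: float = 10.0,
    spread: str = "sd",
) -> dict[str, list[UptakeMeasurement]]:
    """Per-cell gold masses for each construct, lognormal around count × mass.

    ``spread`` says how a CV derived from a printed ± value is interpreted:
    as a per-cell-preparation SD (``"sd"``, default) or as an SEM of the
    printed mean (``"sem"``), in which case the per-measurement CV is
    scaled up by √n.
    """
    if spread not in ("sd", "sem"):
        raise ValueError("spread must be 'sd' or 'sem'")
    means = means or UPTAKE_MEANS
    if cv is None:
        cv_map = {k: UPTAKE_CV.get(k, 0.1) for k in means}
    elif isinstance(cv, dict):
        cv_map = cv
    else:
        cv_map = {k: float(cv) for k in means}
    if any(v < 0 for v in cv_map.values()):
        raise ValueError("cv must be >= 0")
    particle_mass = gnp_gold_mass_g(gnp_diameter_nm)
    rng = np.random.default_rng(seed)
    out: dict[str, list[UptakeMeasurement]] = {}
    for label, count in means.items():
        c = cv_map[label] * (np.sqrt(n) if spread == "sem" else 1.0)
        masses = _lognormal_around(rng, count * particle_mass, c, n)
        out[label] = [UptakeMeasurement(float(m), gnp_diameter_nm) for m in masses]
    return out


def gen_foci_counts(
    densities: dict[str, float] | None = None,
    n_nuclei: dict[str, int] | None = None,
    area_median_um2: float = 150.0,
    area_sigma: float = 0.35,
    seed: int = 0,
) -> dict[str, list[FociRecord]]:
    """53BP1 foci tables per arm: areas lognormal, counts Poisson(density × area)."""
    densities = densities or FOCI_DENSITIES
    n_nuclei = n_nuclei or {k: FOCI_N_NUCLEI.get(k, 300) for k in densities}
    if any(d < 0 for d in densities.values()):
        raise ValueError("densities must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, list[FociRecord]] = {}
    for label, dens in densities.items():
        n = n_nuclei[label]
        areas = rng.lognormal(np.log(area_median_um2), area_sigma, size=n)
        counts = rng.poisson(dens * areas)
        out[label] = [
            FociRecord(nucleus_id=i, foci_count=int(c), projected_area_um2=float(a))
            for i, (c, a) in enumerate(zip(counts, areas))
        ]
    return out


def gen_tem_diameters(
    mean_nm: float = 10.04,
    sd_nm: float = 0.89,
    n: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """TEM core-diameter sample: normal draws truncated at > 0."""
    if sd_nm < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = rng.normal(mean_nm, sd_nm, size=n)
    while np.any(out <= 0):  # physical diameters only; renormalize the tail
        bad = out <= 0
        out[bad] = rng.normal(mean_nm, sd_nm, size=int(bad.sum()))
    return out
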
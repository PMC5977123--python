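"""Clonogenic, DNA-damage and uptake statistics.

Implements the wet-lab arithmetic of the study: plating efficiency and
survival fraction from colony counts, mean ± SEM summaries, percent-decrease
sensitization metrics with delta-method errors, 53BP1 foci densities per
projected nuclear area, ICP-AES gold-mass → GNP-count conversion, and the
pairwise Welch two-sample t-test used for significance calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from gnplem.units import gnp_gold_mass_g

__all__ = [
    "PlateRecord",
    "SFEstimate",
    "FociRecord",
    "UptakeMeasurement",
    "plating_efficiency",
    "survival_fraction",
    "summarize_sf",
    "percent_decrease_with_error",
    "foci_density",
    "gnp_count_from_gold_mass",
    "fold_change",
    "sf_by_condition",
    "welch_t_test",
]


@dataclass(frozen=True)
class PlateRecord:
    """One clonogenic dish: cells seeded and colonies counted."""

    condition: str
    cells_plated: int
    colonies: int
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.colonies <= self.cells_plated:
            raise ValueError(
                f"colonies must lie in [0, cells_plated], got {self.colonies}/{self.cells_plated}"
            )


@dataclass(frozen=True)
class SFEstimate:
    """Survival fraction as mean ± SEM over n replicates."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        # a non-toxic arm can legitimately land just above 1 by sampling
        # noise; only overshoot beyond 3 SEM indicates a bad PE normalization
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if not -1e-9 <= self.mean <= 1 + max(3 * self.sem, 1e-9):
            raise ValueError(
                f"survival fraction mean must lie in [0, 1] up to noise, got {self.mean}"
            )


@dataclass(frozen=True)
class FociRecord:
    """53BP1 foci count and 2D projected area (µm²) for one nucleus."""

    nucleus_id: int
    foci_count: int
    projected_area_um2: float

    def __post_init__(self) -> None:
        if self.projected_area_um2 <= 0:
            raise ValueError("projected area must be positive")
        if self.foci_count < 0:
            raise ValueError("foci count must be >= 0")


@dataclass(frozen=True)
class UptakeMeasurement:
    """Per-cell gold mass (g) from ICP-AES, with the construct's core diameter."""

    gold_mass_per_cell_g: float
    gnp_diameter_nm: float = 10.0

    def __post_init__(self) -> None:
        if self.gold_mass_per_cell_g < 0:
            raise ValueError("gold mass must be >= 0")


def plating_efficiency(control_plates: Sequence[PlateRecord]) -> float:
    """Pooled plating efficiency: Σ colonies / Σ cells plated over control dishes."""
    plates = list(control_plates)
    if not plates:
        raise ValueError("need at least one control plate")
    plated = sum(p.cells_plated for p in plates)
    if plated == 0:
        raise ValueError("total cells plated is zero")
    colonies = sum(p.colonies for p in plates)
    pe = colonies / plated
    if pe == 0:
        warnings.warn("plating efficiency is 0; downstream survival fractions are undefined")
    return pe


def survival_fraction(treated_plate: PlateRecord, pe: float) -> float:
    """SF = colonies / (cells plated × PE)."""
    if pe <= 0:
        raise ValueError("plating efficiency must be > 0")
    return treated_plate.colonies / (treated_plate.cells_plated * pe)


def summarize_sf(replicate_sfs: Iterable[float]) -> SFEstimate:
    """Mean ± SEM (sample SD / √n) over replicate survival fractions."""
    vals = np.asarray(list(replicate_sfs), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two replicates for a SEM")
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size))
    return SFEstimate(mean=mean, sem=sem, n=vals.size)


def percent_decrease_with_error(a: SFEstimate, b: SFEstimate) -> tuple[float, float]:
    """Percent decrease of ``b`` relative to reference ``a``, with error.

    Returns ``(100 × (1 − b/a), err)`` where the error propagates the two SEMs
    through the ratio by the first-order delta method:
    err² = (100/a)²·sem_b² + (100·b/a²)²·sem_a².
    """
    if a.mean <= 0:
        raise ValueError("reference mean must be > 0")
    pct = 100.0 * (1.0 - b.mean / a.mean)
    err = math.hypot(100.0 / a.mean * b.sem, 100.0 * b.mean / a.mean**2 * a.sem)
    return pct, err


def foci_density(records: Sequence[FociRecord]) -> tuple[float, float]:
    """Pooled foci density (Σ counts / Σ areas, per µm²) and per-nucleus SEM.

    The point estimate pools counts over the total imaged area, matching how
    the imaging statistic is reported; the SEM is taken over the per-nucleus
    densities.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one nucleus record")
    counts = np.array([r.foci_count for r in recs], dtype=float)
    areas = np.array([r.projected_area_um2 for r in recs], dtype=float)
    total_area = float(areas.sum())
    if total_area <= 0:
        raise ValueError("total projected area is zero")
    density = float(counts.sum()) / total_area
    per_cell = counts / areas
    sem = float(np.std(per_cell, ddof=1) / math.sqrt(per_cell.size)) if per_cell.size > 1 else 0.0
    return density, sem


def gnp_count_from_gold_mass(m: UptakeMeasurement) -> float:
    """GNPs per cell from the measured gold mass and the particle mass."""
    return m.gold_mass_per_cell_g / gnp_gold_mass_g(m.gnp_diameter_nm)


def fold_change(a: float, b: float) -> float:
    """Ratio b/a, e.g. RGD-modified over bare-GNP uptake."""
    if a <= 0:
        raise ValueError("reference count must be > 0")
    return b / a


def sf_by_condition(
    records: Sequence[PlateRecord], control_label: str
) -> tuple[dict[str, SFEstimate], float]:
    """Standard clonogenic analysis of a plate table.

    Pools the control condition's plates into a plating efficiency, converts
    every plate to a survival fraction against it, and summarizes each
    condition as mean ± SEM. Returns ``(estimates by condition, PE)``.
    """
    by_cond: dict[str, list[PlateRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)
    if control_label not in by_cond:
        raise ValueError(f"control condition {control_label!r} not present")
    pe = plating_efficiency(by_cond[control_label])
    ests = {
        cond: summarize_sf([survival_fraction(p, pe) for p in recs])
        for cond, recs in by_cond.items()
    }
    return ests, pe


def welch_t_test(sample_a: Iterable[float], sample_b: Iterable[float]) -> tuple[float, float]:
    """Welch unequal-variance two-sample t-test; returns (statistic, two-sided p)."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("both samples are degenerate (zero variance) with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
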
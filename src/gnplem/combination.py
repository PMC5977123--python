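"""Bliss-independence combination analysis and Poisson tumor control.

Bliss independence is the null model for two non-interacting agents: their
surviving fractions multiply, SF_AB = SF_A × SF_B (equivalently, in effect
space, E_AB = E_A + E_B − E_A·E_B). An observed combination SF within
``k_sigma`` SEMs of the product is called additive; significantly below,
synergistic; above, antagonistic.

Tumor control assumes independent clonogen kill: after n identical
treatments each leaving a fraction SF, the expected survivors from N0
initial clonogens are N0·SF^n and the Poisson tumor-control probability is
TCP = exp(−survivors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from gnplem.assays import SFEstimate

__all__ = [
    "CombinationResult",
    "TCPResult",
    "bliss_expected_sf",
    "bliss_classify",
    "survivors_after_fractions",
    "poisson_tcp",
    "min_fractions_for_tcp",
]


@dataclass(frozen=True)
class CombinationResult:
    sf_expected: float
    sf_observed: SFEstimate
    call: str  # synergistic | additive | antagonistic
    k_sigma: float = 2.0


@dataclass(frozen=True)
class TCPResult:
    n0: float
    sf_per_treatment: float
    n_treatments: int
    survivors: float
    tcp: float


def bliss_expected_sf(sf_a: float, sf_b: float) -> float:
    """Expected combination SF under Bliss independence: SF_A × SF_B."""
    for name, v in (("sf_a", sf_a), ("sf_b", sf_b)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return sf_a * sf_b


def bliss_classify(expected: float, observed: SFEstimate, k_sigma: float = 2.0) -> CombinationResult:
    """Classify a combination against its Bliss expectation.

    Additive if |observed − expected| ≤ k_sigma × SEM; synergistic if the
    observed survival is significantly lower; antagonistic if higher.
    """
    if observed.sem < 0:
        raise ValueError("observed SEM must be >= 0")
    band = k_sigma * observed.sem
    if abs(observed.mean - expected) <= band:
        call = "additive"
    elif observed.mean < expected:
        call = "synergistic"
    else:
        call = "antagonistic"
    return CombinationResult(sf_expected=expected, sf_observed=observed, call=call, k_sigma=k_sigma)


def survivors_after_fractions(n0: float, sf: float, n: int) -> float:
    """Expected surviving clonogens after n treatments: n0 × sf^n."""
    if not 0 < sf <= 1:
        raise ValueError(f"sf must lie in (0, 1], got {sf}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    return n0 * sf**n


def poisson_tcp(survivors: float) -> float:
    """Poisson tumor control probability exp(−survivors)."""
    if survivors < 0:
        raise ValueError("survivors must be >= 0")
    return math.exp(-survivors)


def min_fractions_for_tcp(
    n0: float,
    sf: float,
    target_tcp: float,
    max_fractions: int = 10_000,
) -> TCPResult:
    """Smallest treatment count reaching the target TCP, by brute-force scan."""
    if not 0 < target_tcp < 1:
        raise ValueError("target_tcp must lie in (0, 1)")
    for n in range(max_fractions + 1):
        surv = survivors_after_fractions(n0, sf, n)
        tcp = poisson_tcp(surv)
        if tcp >= target_tcp:
            return TCPResult(n0=n0, sf_per_treatment=sf, n_treatments=n, survivors=surv, tcp=tcp)
    raise ValueError(
        f"target TCP {target_tcp} unreachable within {max_fractions} treatments at sf={sf}"
    )
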
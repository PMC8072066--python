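"""Clonal expansion of a single mutant clone in the stem-cell hierarchy.

A pre-leukemic mutation arising in compartment ``s`` is modeled as a factor
``x >= 1`` on the proliferation rate ``lambda_i`` of the mutated population and
all of its downstream progeny: ``lambda_i -> x * lambda_i`` for ``i >= s``.
Because ``kappa_i = alpha_i - (lambda_i - delta_i)``, the mutant inverse
residence times are ``kappa_i_mut = kappa_i - (x - 1) * lambda_i``.

Mutant counts ``m_i(t)`` obey the same linear cascade as the wild-type
populations, seeded with a single founder cell in the compartment of origin
(deterministic continuum treatment; stochastic extinction of small clones is
not modeled).  The readout is the mutant fraction of the MPP pool,
``p(t) = m_K(t) / n_K(t)``, with the wild-type MPP size in the denominator by
default (a bounded-fraction variant adds the mutants to the denominator).

The clone persists ("immortal" MPP representation) iff the slowest mutant
eigenvalue is non-negative growth, i.e. ``min_{i>=s} kappa_i_mut(x) <= 0``.
The minimal such factor is ``x* = min_{i>=s} (alpha_i + delta_i) / lambda_i``
(clamped at 1 from below), which the bisection search reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (InitialState, KineticRates, ModelTopology, Trajectory,
                    _cascade_eval, closed_form_cascade, solve_populations)

__all__ = [
    "MutationScenario",
    "apply_mutation",
    "solve_mutant",
    "mutant_mpp_fraction",
    "find_immortal_threshold",
    "threshold_closed_form",
]


@dataclass(frozen=True)
class MutationScenario:
    """A single mutant clone: compartment of origin and proliferation factor."""

    origin: int                 # 0-based compartment index
    factor: float = 1.0         # x >= 1, multiplies lambda for i >= origin
    m0: float = 1.0             # founder cells in the origin compartment

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("proliferation factor must be >= 1")
        if self.m0 < 0:
            raise ValueError("initial mutant load must be non-negative")


def _require_split(rates: KineticRates, origin: int) -> None:
    if rates.lam is None:
        raise ValueError(
            "mutation modeling needs the lambda/delta split of the net "
            "proliferation rate for the origin compartment and downstream")
    if origin < 0 or origin >= rates.n_compartments:
        raise ValueError(f"origin index {origin} out of range")


def apply_mutation(rates: KineticRates, scenario: MutationScenario) -> KineticRates:
    """Kinetics of the mutant lineage: ``lambda -> x * lambda`` from the origin
    downstream; upstream compartments are untouched (they carry no mutants)."""
    _require_split(rates, scenario.origin)
    lam = rates.lam.copy()
    lam[scenario.origin:] *= scenario.factor
    return KineticRates.from_lambda_delta(rates.alpha, lam, rates.delta)


def mutant_kappa(rates: KineticRates, scenario: MutationScenario) -> np.ndarray:
    """Mutant inverse residence times ``kappa_i - (x - 1) * lambda_i`` (i >= s)."""
    return apply_mutation(rates, scenario).kappa


def solve_mutant(rates: KineticRates, scenario: MutationScenario, times,
                 *, method: str = "cascade") -> np.ndarray:
    """Expected mutant counts ``m_i(t)`` (K, T).

    The mutant subsystem starts at the origin compartment (everything upstream
    stays zero) and follows the cascade with mutant kappa.  ``method`` is
    ``'cascade'`` (analytic) or ``'ivp'`` (numerical cross-check).
    """
    mut = apply_mutation(rates, scenario)
    k = rates.n_compartments
    times = np.asarray(times, dtype=float)
    m0 = np.zeros(k)
    m0[scenario.origin] = scenario.m0
    s = scenario.origin
    if method == "cascade":
        m_sub = _cascade_eval(mut.alpha[s:-1], mut.kappa[s:], m0[s:], times)
    elif method == "ivp":
        topo = ModelTopology(tuple(f"c{i}" for i in range(k - s)))
        sub = KineticRates.from_kappa(mut.alpha[s:], mut.kappa[s:])
        traj = solve_populations(sub, InitialState(n0=m0[s:]), times, topology=topo)
        m_sub = traj.n
    else:
        raise ValueError("method must be 'cascade' or 'ivp'")
    m = np.zeros((k, len(times)))
    m[s:] = m_sub
    return m


def mutant_mpp_fraction(rates: KineticRates, init: InitialState,
                        scenario: MutationScenario, times, *,
                        include_mutants_in_denominator: bool = False) -> np.ndarray:
    """Mutant fraction of the MPP pool, ``p(t) = m_K(t) / n_K(t)``.

    By default the denominator is the wild-type MPP size (so an expanding
    clone can exceed 1); ``include_mutants_in_denominator`` switches to
    ``m_K / (n_K + m_K)``, which is bounded in [0, 1].
    """
    times = np.asarray(times, dtype=float)
    n = closed_form_cascade(rates, init, times).n
    n_mpp = n[-1]
    if np.any(n_mpp <= 0):
        raise ValueError("wild-type MPP size is non-positive on the grid")
    m_mpp = solve_mutant(rates, scenario, times)[-1]
    if include_mutants_in_denominator:
        return m_mpp / (n_mpp + m_mpp)
    return m_mpp / n_mpp


def threshold_closed_form(rates: KineticRates, origin: int) -> tuple[float, int]:
    """Exact immortality threshold.

    The mutant subsystem's eigenvalues are ``-kappa_i_mut`` for ``i >= s``, so
    persistence requires ``min_{i>=s} kappa_i_mut <= 0``; solving for x gives
    ``x* = min_{i>=s} (alpha_i + delta_i) / lambda_i``, clamped at 1.  Returns
    ``(x*, index of the compartment achieving the minimum)``.
    """
    _require_split(rates, origin)
    s = origin
    lam = rates.lam[s:]
    if np.all(lam <= 0):
        raise ValueError("no compartment at or below the origin proliferates; "
                         "no finite threshold exists")
    with np.errstate(divide="ignore"):
        xs = np.where(lam > 0, (rates.alpha[s:] + rates.delta[s:]) / lam, np.inf)
    j = int(np.argmin(xs))
    return float(max(xs[j], 1.0)), s + j


def find_immortal_threshold(rates: KineticRates, origin: int, *,
                            tol: float = 1e-6, x_max: float = 1e3) -> tuple[float, int]:
    """Minimal proliferation factor giving a persistent mutant MPP population.

    Bisects on x until the dominant decay rate ``min_{i>=s} kappa_i_mut(x)``
    is zero within ``tol`` (the boundary between washout and unbounded
    growth).  Returns ``(x*, compartment index achieving the minimum)``.
    """
    _require_split(rates, origin)
    s = origin

    def slowest(x: float) -> float:
        kap = rates.kappa[s:] - (x - 1.0) * rates.lam[s:]
        return float(np.min(kap))

    if slowest(1.0) <= 0.0:
        # the origin (or something downstream) is already self-sustaining
        kap = rates.kappa[s:] - 0.0
        return 1.0, s + int(np.argmin(kap))
    lo, hi = 1.0, 2.0
    while slowest(hi) > 0.0:
        hi *= 2.0
        if hi > x_max:
            raise ValueError(f"no immortality threshold below x = {x_max:g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if slowest(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    x_star = 0.5 * (lo + hi)
    kap = rates.kappa[s:] - (x_star - 1.0) * rates.lam[s:]
    return x_star, s + int(np.argmin(kap))
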
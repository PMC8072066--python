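"""Deterministic dynamics of label propagation through a linear stem-cell hierarchy.

The model tracks K compartments arranged in a linear differentiation chain
(default: HSC-U -> HSC-D -> ST-HSC -> MPP).  Compartment i is characterized by

* ``alpha_i`` — differentiation rate (per day): per-cell flux into compartment
  i+1;
* ``beta_i = lambda_i - delta_i`` — net proliferation rate (per day):
  proliferation minus death;
* ``kappa_i = alpha_i - beta_i`` — inverse residence time (per day): the decay
  rate of the compartment's content if its influx were removed.  Small kappa
  means high self-renewal.

Expected compartment sizes ``n_i(t)`` obey::

    dn_1/dt = -kappa_1 n_1
    dn_i/dt = alpha_{i-1} n_{i-1} - kappa_i n_i     (i > 1)

Labeled cells created by a one-time heritable Cre/reporter induction follow the
same kinetics, so the expected labeled counts ``l_i(t)`` obey the analogous
system with initial condition ``l_i(0) = f_i(0) n_i(0)``.  The labeled
*frequency* ``f_i = l_i / n_i`` — the quantity actually measured by flow
cytometry — obeys::

    df_1/dt = 0
    df_i/dt = alpha_{i-1} (n_{i-1}/n_i) (f_{i-1} - f_i)     (i > 1)

The two most immature compartments (HSC-U, HSC-D) are hidden inside a single
flow-cytometric HSC gate; the observable HSC count is ``n_U + n_D`` and the
observable HSC labeled frequency is the count-weighted average of the two
hidden frequencies.

All rates are per day; times are in days.  Summaries may report rates per week
(rate * 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "DEFAULT_COMPARTMENTS",
    "HSC_GATE",
    "ModelTopology",
    "KineticRates",
    "InitialState",
    "Trajectory",
    "DegenerateSpectrumError",
    "DegenerateSpectrumWarning",
    "NonPositivePopulationError",
    "cascade_coefficients",
    "closed_form_cascade",
    "solve_populations",
    "solve_labeled_counts",
    "solve_label_frequencies",
    "aggregate_hsc",
    "normalize_to_hsc",
    "steady_state_model",
]

DEFAULT_COMPARTMENTS = ("HSC-U", "HSC-D", "ST-HSC", "MPP")

#: compartments hidden inside the flow-cytometric HSC gate
HSC_GATE = ("HSC-U", "HSC-D")


class DegenerateSpectrumError(ValueError):
    """Raised when the analytic cascade is requested with repeated kappa values."""


class DegenerateSpectrumWarning(UserWarning):
    """Emitted when repeated kappa values are resolved by a tiny perturbation."""


class NonPositivePopulationError(ValueError):
    """A compartment size became non-positive where positivity is required."""

    def __init__(self, compartment: str, time: float):
        self.compartment = compartment
        self.time = time
        super().__init__(
            f"compartment {compartment!r} has non-positive expected size "
            f"at t = {time:g} days; labeled frequencies are undefined there"
        )


@dataclass(frozen=True)
class ModelTopology:
    """Ordered linear chain of compartments; compartment i-1 feeds compartment i."""

    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self):
        if len(self.compartments) == 0:
            raise ValueError("topology needs at least one compartment")
        if len(set(self.compartments)) != len(self.compartments):
            raise ValueError("compartment names must be unique")
        object.__setattr__(self, "compartments", tuple(self.compartments))

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def index(self, name: str) -> int:
        try:
            return self.compartments.index(name)
        except ValueError:
            raise KeyError(f"unknown compartment {name!r}") from None

    def hsc_gate_indices(self) -> tuple[int, ...]:
        """Indices of the hidden subcompartments pooled in the observed HSC gate."""
        missing = [c for c in HSC_GATE if c not in self.compartments]
        if missing:
            raise KeyError(f"topology lacks HSC gate compartment(s): {missing}")
        return tuple(self.index(c) for c in HSC_GATE)


def _as_vec(x, k: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (k,):
        raise ValueError(f"{name} must have shape ({k},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class KineticRates:
    """Per-compartment kinetic rates (per day).

    ``alpha`` and ``beta`` are required; ``lam``/``delta`` (proliferation and
    death) are optional but must satisfy ``beta = lam - delta`` when given.
    ``kappa = alpha - beta`` is derived.
    """

    alpha: np.ndarray
    beta: np.ndarray
    lam: np.ndarray | None = None
    delta: np.ndarray | None = None

    def __post_init__(self):
        k = len(np.atleast_1d(np.asarray(self.alpha)))
        object.__setattr__(self, "alpha", _as_vec(self.alpha, k, "alpha"))
        object.__setattr__(self, "beta", _as_vec(self.beta, k, "beta"))
        if np.any(self.alpha < 0):
            raise ValueError("differentiation rates alpha must be non-negative")
        if (self.lam is None) != (self.delta is None):
            raise ValueError("lam and delta must be given together")
        if self.lam is not None:
            object.__setattr__(self, "lam", _as_vec(self.lam, k, "lam"))
            object.__setattr__(self, "delta", _as_vec(self.delta, k, "delta"))
            if np.any(self.lam < 0) or np.any(self.delta < 0):
                raise ValueError("lam and delta must be non-negative")
            if not np.allclose(self.beta, self.lam - self.delta, rtol=0, atol=1e-12):
                raise ValueError("beta must equal lam - delta")

    @classmethod
    def from_kappa(cls, alpha, kappa) -> "KineticRates":
        alpha = np.asarray(alpha, dtype=float)
        kappa = np.asarray(kappa, dtype=float)
        return cls(alpha=alpha, beta=alpha - kappa)

    @classmethod
    def from_lambda_delta(cls, alpha, lam, delta) -> "KineticRates":
        lam = np.asarray(lam, dtype=float)
        delta = np.asarray(delta, dtype=float)
        return cls(alpha=np.asarray(alpha, dtype=float), beta=lam - delta,
                   lam=lam, delta=delta)

    @property
    def kappa(self) -> np.ndarray:
        return self.alpha - self.beta

    @property
    def n_compartments(self) -> int:
        return len(self.alpha)

    def per_week(self) -> pd.DataFrame:
        """Rates summarised per week (rate * 7) — convenient for reporting."""
        return pd.DataFrame(
            {"alpha_per_week": self.alpha * 7.0,
             "beta_per_week": self.beta * 7.0,
             "kappa_per_week": self.kappa * 7.0}
        )


@dataclass(frozen=True)
class InitialState:
    """Initial expected counts and, optionally, initial labeled frequencies.

    ``f0`` may be a single array (one anonymous label) or a mapping
    label-id -> array for multi-reporter designs.
    """

    n0: np.ndarray
    f0: Mapping[str, np.ndarray] | np.ndarray | None = None

    def __post_init__(self):
        k = len(np.atleast_1d(np.asarray(self.n0)))
        object.__setattr__(self, "n0", _as_vec(self.n0, k, "n0"))
        if np.any(self.n0 < 0):
            raise ValueError("initial counts n0 must be non-negative")
        if self.f0 is not None:
            if isinstance(self.f0, Mapping):
                f0 = {lab: _as_vec(v, k, f"f0[{lab}]") for lab, v in self.f0.items()}
                for lab, v in f0.items():
                    if np.any((v < 0) | (v > 1)):
                        raise ValueError(f"f0[{lab}] must lie in [0, 1]")
                object.__setattr__(self, "f0", f0)
            else:
                v = _as_vec(self.f0, k, "f0")
                if np.any((v < 0) | (v > 1)):
                    raise ValueError("f0 must lie in [0, 1]")
                object.__setattr__(self, "f0", v)

    def f0_for(self, label: str | None) -> np.ndarray:
        if self.f0 is None:
            raise ValueError("initial state carries no labeling frequencies")
        if isinstance(self.f0, Mapping):
            if label is None:
                if len(self.f0) == 1:
                    return next(iter(self.f0.values()))
                raise ValueError(f"label must be one of {sorted(self.f0)}")
            return self.f0[label]
        return self.f0


@dataclass
class Trajectory:
    """Time-indexed expected counts / labeled counts / labeled frequencies."""

    times: np.ndarray
    topology: ModelTopology
    n: np.ndarray | None = None          # (K, T)
    l: np.ndarray | None = None          # (K, T)
    f: np.ndarray | None = None          # (K, T)
    label: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-d grid")

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format export: (time, compartment, label, n, l, f)."""
        frames = []
        for i, comp in enumerate(self.topology.compartments):
            frames.append(pd.DataFrame({
                "time_days": self.times,
                "compartment": comp,
                "label": self.label if self.label is not None else "",
                "n": self.n[i] if self.n is not None else np.nan,
                "l": self.l[i] if self.l is not None else np.nan,
                "f": self.f[i] if self.f is not None else np.nan,
            }))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# analytic cascade (sum-of-exponentials solution of the linear chain)
# ---------------------------------------------------------------------------

def _resolve_degenerate(kappa: np.ndarray, tol: float, on_degenerate: str) -> np.ndarray:
    """Ensure pairwise-distinct decay rates, perturbing or raising as configured."""
    kap = kappa.astype(float).copy()
    scale = max(1.0, float(np.max(np.abs(kap))))
    changed = False
    # nudge successive collisions apart deterministically
    for _ in range(len(kap)):
        order = np.argsort(kap, kind="stable")
        collided = False
        for a, b in zip(order[:-1], order[1:]):
            if abs(kap[a] - kap[b]) < tol * scale:
                if on_degenerate == "raise":
                    raise DegenerateSpectrumError(
                        f"kappa values {kap[a]:g} and {kap[b]:g} coincide within "
                        f"tolerance {tol:g}; the sum-of-exponentials form is degenerate"
                    )
                kap[b] += 1e-9 * scale
                collided = changed = True
        if not collided:
            break
    if changed:
        warnings.warn(
            "repeated kappa values perturbed by 1e-9 to evaluate the analytic cascade",
            DegenerateSpectrumWarning, stacklevel=3,
        )
    return kap


def cascade_coefficients(coupling: np.ndarray, kappa: np.ndarray, x0: np.ndarray,
                         *, degenerate_tol: float = 1e-9,
                         on_degenerate: str = "perturb") -> tuple[np.ndarray, np.ndarray]:
    """Coefficients of the exact solution of a linear bidiagonal cascade.

    The system ``dx_1/dt = -kappa_1 x_1``,
    ``dx_i/dt = coupling_{i-1} x_{i-1} - kappa_i x_i`` with pairwise-distinct
    kappa has solution ``x_i(t) = sum_j C[i, j] exp(-kappa_j t)``.  Returns
    ``(C, kappa_used)``.
    """
    k = len(kappa)
    kap = _resolve_degenerate(np.asarray(kappa, dtype=float), degenerate_tol, on_degenerate)
    c = np.zeros((k, k))
    c[0, 0] = x0[0]
    for i in range(1, k):
        c[i, :i] = coupling[i - 1] * c[i - 1, :i] / (kap[i] - kap[:i])
        c[i, i] = x0[i] - c[i, :i].sum()
    return c, kap


def _cascade_eval(coupling, kappa, x0, times, **kw) -> np.ndarray:
    c, kap = cascade_coefficients(coupling, kappa, x0, **kw)
    return c @ np.exp(-np.outer(kap, np.asarray(times, dtype=float)))


def closed_form_cascade(rates: KineticRates, init: InitialState, times,
                        *, topology: ModelTopology | None = None,
                        degenerate_tol: float = 1e-9,
                        on_degenerate: str = "perturb") -> Trajectory:
    """Exact sum-of-exponentials solution for the expected compartment sizes.

    Valid for pairwise-distinct inverse residence times; a repeated spectrum is
    perturbed by 1e-9 with a warning (or raises if ``on_degenerate='raise'``).
    Serves as the analytic oracle for the numerical integrator.
    """
    topo = topology or ModelTopology(DEFAULT_COMPARTMENTS[: rates.n_compartments])
    times = np.asarray(times, dtype=float)
    n = _cascade_eval(rates.alpha[:-1], rates.kappa, init.n0, times,
                      degenerate_tol=degenerate_tol, on_degenerate=on_degenerate)
    return Trajectory(times=times, topology=topo, n=n)


# ---------------------------------------------------------------------------
# numerical solvers
# ---------------------------------------------------------------------------

def _check_grid(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("times must be a 1-d grid with at least two points")
    if times[0] != 0:
        raise ValueError("times must start at 0 (days since effective induction)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def _integrate(rhs, y0, times, method, rtol, atol):
    sol = solve_ivp(rhs, (times[0], times[-1]), y0, t_eval=times,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol.y


def solve_populations(rates: KineticRates, init: InitialState, times,
                      *, topology: ModelTopology | None = None,
                      method: str = "LSODA", rtol: float = 1e-9,
                      atol: float = 1e-12) -> Trajectory:
    """Integrate the expected-compartment-size system numerically."""
    topo = topology or ModelTopology(DEFAULT_COMPARTMENTS[: rates.n_compartments])
    if rates.n_compartments != topo.n_compartments:
        raise ValueError("rates dimension does not match topology")
    if len(init.n0) != topo.n_compartments:
        raise ValueError("initial state dimension does not match topology")
    times = _check_grid(times)
    alpha, kappa = rates.alpha, rates.kappa

    def rhs(_t, n):
        dn = -kappa * n
        dn[1:] += alpha[:-1] * n[:-1]
        return dn

    n = _integrate(rhs, init.n0, times, method, rtol, atol)
    return Trajectory(times=times, topology=topo, n=n)


def solve_labeled_counts(rates: KineticRates, init: InitialState, times,
                         *, label: str | None = None,
                         topology: ModelTopology | None = None,
                         method: str = "LSODA", rtol: float = 1e-9,
                         atol: float = 1e-12) -> Trajectory:
    """Integrate total and labeled counts; ``l`` follows the same cascade with
    ``l(0) = f(0) * n(0)``."""
    traj = solve_populations(rates, init, times, topology=topology,
                             method=method, rtol=rtol, atol=atol)
    f0 = init.f0_for(label)
    alpha, kappa = rates.alpha, rates.kappa

    def rhs(_t, l):
        dl = -kappa * l
        dl[1:] += alpha[:-1] * l[:-1]
        return dl

    l = _integrate(rhs, f0 * init.n0, traj.times, method, rtol, atol)
    traj.l = l
    traj.label = label
    return traj


def solve_label_frequencies(rates: KineticRates, init: InitialState, times,
                            *, label: str | None = None,
                            topology: ModelTopology | None = None,
                            method: str = "LSODA", rtol: float = 1e-9,
                            atol: float = 1e-12) -> Trajectory:
    """Integrate labeled frequencies directly (numerically preferable to l/n
    when compartments are small)."""
    topo = topology or ModelTopology(DEFAULT_COMPARTMENTS[: rates.n_compartments])
    times = _check_grid(times)
    f0 = init.f0_for(label)
    k = topo.n_compartments
    alpha, kappa = rates.alpha, rates.kappa

    def rhs(_t, y):
        n, f = y[:k], y[k:]
        dn = -kappa * n
        dn[1:] += alpha[:-1] * n[:-1]
        df = np.zeros(k)
        df[1:] = alpha[:-1] * (n[:-1] / n[1:]) * (f[:-1] - f[1:])
        return np.concatenate([dn, df])

    y = _integrate(rhs, np.concatenate([init.n0, f0]), times, method, rtol, atol)
    n, f = y[:k], y[k:]
    bad = n <= 0
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise NonPositivePopulationError(topo.compartments[i], times[j])
    return Trajectory(times=times, topology=topo, n=n, f=f, label=label)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def aggregate_hsc(traj: Trajectory) -> tuple[np.ndarray, np.ndarray | None]:
    """Pool the hidden HSC subcompartments into the observed HSC gate.

    Returns ``(count, frequency)`` where ``count = n_U + n_D`` and
    ``frequency = (f_U n_U + f_D n_D) / (n_U + n_D)`` (None if the trajectory
    carries no frequencies).
    """
    iu, idn = traj.topology.hsc_gate_indices()
    if traj.n is None:
        raise ValueError("trajectory carries no compartment sizes")
    total = traj.n[iu] + traj.n[idn]
    if np.any(total <= 0):
        t = traj.times[np.argwhere(total <= 0)[0, 0]]
        raise NonPositivePopulationError("HSC (U+D)", t)
    freq = None
    if traj.f is not None:
        freq = (traj.f[iu] * traj.n[iu] + traj.f[idn] * traj.n[idn]) / total
    elif traj.l is not None:
        freq = (traj.l[iu] + traj.l[idn]) / total
    return total, freq


def normalize_to_hsc(traj: Trajectory) -> dict[str, np.ndarray]:
    """Labeled frequencies of compartments downstream of the HSC gate, scaled
    to the aggregate HSC labeled frequency at the same time point.

    Time points where the HSC frequency is zero are masked to NaN with a
    warning.
    """
    _, f_hsc = aggregate_hsc(traj)
    if f_hsc is None:
        raise ValueError("trajectory carries no labeling information")
    gate = set(traj.topology.hsc_gate_indices())
    down = [i for i in range(traj.topology.n_compartments) if i not in gate]
    zero = f_hsc == 0
    if np.any(zero):
        warnings.warn(
            f"HSC labeled frequency is zero at {int(zero.sum())} time point(s); "
            "normalized values masked to NaN", stacklevel=2,
        )
    denom = np.where(zero, np.nan, f_hsc)
    if traj.f is not None:
        fd = traj.f
    else:
        fd = traj.l / traj.n
    return {traj.topology.compartments[i]: fd[i] / denom for i in down}


def steady_state_model(kappa, f0, times) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous steady-state label-propagation model.

    With constant compartment sizes the steady-state flux balance
    ``alpha_{i-1} n_{i-1} = kappa_i n_i`` reduces the frequency dynamics to
    ``df_i/dt = kappa_i (f_{i-1} - f_i)`` with ``f_1`` constant.  ``kappa``
    gives the relaxation rates of compartments 2..K (all > 0).

    Returns ``(f, normalized)`` where ``normalized = f_i / f_1`` (NaN if
    ``f_1 = 0``).
    """
    kappa = np.asarray(kappa, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if len(f0) != len(kappa) + 1:
        raise ValueError("f0 must have one more entry than kappa (compartment 1 relaxes nothing)")
    if np.any(kappa <= 0):
        raise ValueError("steady state with positive influx requires kappa > 0")
    times = _check_grid(times)

    def rhs(_t, f):
        df = np.zeros_like(f)
        df[1:] = kappa * (f[:-1] - f[1:])
        return df

    f = _integrate(rhs, f0, times, "LSODA", 1e-9, 1e-12)
    norm = f / f[0] if f0[0] != 0 else np.full_like(f, np.nan)
    return f, norm
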
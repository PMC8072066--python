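"""Joint weighted-least-squares fitting and profile-likelihood uncertainty.

The model is fit to one or more pooled datasets simultaneously.  All datasets
share one kinetics block (differentiation rates ``alpha``, inverse residence
times ``kappa`` — or equivalently net proliferation rates ``beta`` — and
initial compartment sizes ``n0``); each dataset contributes its own initial
labeling frequencies ``f0`` for the four compartments.  The fitted observables
per dataset are the aggregate HSC labeled frequency, the HSC-normalized
ST-HSC and MPP labeled frequencies, and the three observed compartment sizes,
each weighted by its pooled-variance SEM:

    SSR(theta) = sum over datasets, streams, bins of ((model - mean) / SEM)^2

Positive rates and counts are optimized on the log scale, frequencies on the
logit scale, and sign-unconstrained parameters (kappa of the most immature
compartment, or beta) on the natural scale.  Optimization is multi-start
(Latin-hypercube starts on the transformed scale, seed-controlled) local least
squares.

Uncertainty is quantified by profile likelihood: each parameter is walked on
its transformed scale, re-optimizing all others, until the objective exceeds
the optimum by the chi-square(1 df) quantile (3.84 at 95%); crossings are
located by linear interpolation, and a side that never crosses within the
configured span is reported as unbounded.  Prediction profile bands minimize /
maximize a model prediction subject to the same objective increase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2, qmc

from .data import HSC_COMPARTMENT, PooledDataset
from .model import DEFAULT_COMPARTMENTS, ModelTopology, _cascade_eval

__all__ = [
    "Stream",
    "FitDataset",
    "Parameter",
    "FitSpec",
    "FitResult",
    "ProfileCI",
    "make_fitspec",
    "fit_datasets_from_pooled",
    "weighted_ssr",
    "fit_joint",
    "fit_fixed_kinetics",
    "profile_likelihood_ci",
    "profile_all",
    "prediction_profile_band",
    "labeling_specificity",
]

_PENALTY = 1e4  # per-residual stand-in where the model is not evaluable


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stream:
    """One observable time series: (compartment, quantity) with binned stats."""

    compartment: str
    quantity: str            # 'frequency' | 'norm_frequency' | 'count'
    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray

    def __post_init__(self):
        for name in ("times", "mean", "sem"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sem <= 0):
            raise ValueError(f"stream ({self.compartment}, {self.quantity}) has "
                             "non-positive SEMs")


@dataclass(frozen=True)
class FitDataset:
    dataset_id: str
    streams: tuple[Stream, ...]

    @property
    def n_residuals(self) -> int:
        return sum(len(s.times) for s in self.streams)


_DEFAULT_STREAMS = (
    (HSC_COMPARTMENT, "frequency"),
    ("ST-HSC", "norm_frequency"),
    ("MPP", "norm_frequency"),
    (HSC_COMPARTMENT, "count"),
    ("ST-HSC", "count"),
    ("MPP", "count"),
)


def fit_datasets_from_pooled(pooled: PooledDataset,
                             *, include_counts: bool = True) -> list[FitDataset]:
    """Extract the fitted observable streams from a pooled dataset (one
    :class:`FitDataset` per dataset id present)."""
    if "sem" not in pooled.stats.columns:
        raise ValueError("pooled dataset has no SEMs; run pooled_variance_sem first")
    out = []
    for ds, grp in pooled.stats.groupby("dataset_id", sort=True):
        streams = []
        for comp, qty in _DEFAULT_STREAMS:
            if qty == "count" and not include_counts:
                continue
            sel = grp[(grp["compartment"] == comp) & (grp["quantity"] == qty)]
            sel = sel.sort_values("time")
            if len(sel) == 0:
                continue
            streams.append(Stream(comp, qty, sel["time"].to_numpy(),
                                  sel["mean"].to_numpy(), sel["sem"].to_numpy()))
        out.append(FitDataset(dataset_id=str(ds), streams=tuple(streams)))
    return out


# ---------------------------------------------------------------------------
# parameters and spec
# ---------------------------------------------------------------------------

_FWD = {"log": np.log, "logit": logit, "identity": lambda v: v}
_INV = {"log": np.exp, "logit": expit, "identity": lambda x: x}


@dataclass(frozen=True)
class Parameter:
    name: str
    value: float                      # natural scale
    transform: str = "log"
    free: bool = True
    start_bounds: tuple[float, float] = (-8.0, 0.0)   # transformed scale
    hard_bounds: tuple[float, float] = (-13.8, 3.0)   # transformed scale
    profile_span: float = 14.0                        # transformed scale

    def to_transformed(self) -> float:
        return float(_FWD[self.transform](self.value))

    def from_transformed(self, x: float) -> float:
        return float(_INV[self.transform](x))


@dataclass
class FitSpec:
    """Parameter layout of a (possibly multi-dataset) fit.

    Shared block: ``alpha.<comp>`` for all but the terminal compartment,
    either ``kappa.<comp>`` for every compartment (``kinetics='kappa'``) or
    ``beta.<comp>`` (``kinetics='beta'``, with the terminal differentiation
    rate fixed at ``alpha_last``), and ``n0.<comp>``.  Per-dataset block:
    ``f0.<dataset>.<comp>``.
    """

    topology: ModelTopology
    dataset_ids: tuple[str, ...]
    params: dict[str, Parameter]
    kinetics: str = "kappa"
    alpha_last: float = 0.1

    # -- parameter bookkeeping -------------------------------------------
    @property
    def free_names(self) -> list[str]:
        return [n for n, p in self.params.items() if p.free]

    def x0_free(self) -> np.ndarray:
        return np.array([self.params[n].to_transformed() for n in self.free_names])

    def values(self) -> dict[str, float]:
        return {n: p.value for n, p in self.params.items()}

    def set_values(self, values: Mapping[str, float]) -> None:
        for n, v in values.items():
            if n in self.params:
                self.params[n] = replace(self.params[n], value=float(v))

    def with_fixed(self, names: Sequence[str],
                   values: Mapping[str, float] | None = None) -> "FitSpec":
        params = dict(self.params)
        for n in names:
            v = values[n] if values and n in values else params[n].value
            params[n] = replace(params[n], value=float(v), free=False)
        return FitSpec(self.topology, self.dataset_ids, params,
                       self.kinetics, self.alpha_last)

    def natural_from_free(self, x_free: np.ndarray) -> dict[str, float]:
        vals = {n: p.value for n, p in self.params.items()}
        for n, x in zip(self.free_names, x_free):
            vals[n] = self.params[n].from_transformed(x)
        return vals

    # -- model blocks -----------------------------------------------------
    def kinetics_arrays(self, vals: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        comps = self.topology.compartments
        k = len(comps)
        alpha = np.empty(k)
        for i, c in enumerate(comps[:-1]):
            alpha[i] = vals[f"alpha.{c}"]
        alpha[-1] = self.alpha_last
        if self.kinetics == "kappa":
            kappa = np.array([vals[f"kappa.{c}"] for c in comps])
        else:
            beta = np.array([vals[f"beta.{c}"] for c in comps])
            kappa = alpha - beta
        n0 = np.array([vals[f"n0.{c}"] for c in comps])
        return alpha, kappa, n0

    def f0_array(self, vals: Mapping[str, float], dataset_id: str) -> np.ndarray:
        return np.array([vals[f"f0.{dataset_id}.{c}"] for c in self.topology.compartments])


def make_fitspec(dataset_ids: Sequence[str], *,
                 topology: ModelTopology | None = None,
                 kinetics: str = "kappa",
                 alpha_last: float = 0.1,
                 values: Mapping[str, float] | None = None) -> FitSpec:
    """Build a default fit specification for the given dataset ids."""
    if kinetics not in ("kappa", "beta"):
        raise ValueError("kinetics must be 'kappa' or 'beta'")
    topo = topology or ModelTopology()
    comps = topo.compartments
    params: dict[str, Parameter] = {}
    for c in comps[:-1]:
        params[f"alpha.{c}"] = Parameter(f"alpha.{c}", 0.05, "log", True,
                                         (-8.0, 0.5), (-13.8, 3.0))
    if kinetics == "kappa":
        # the most immature compartment may shrink or expand: sign-free
        params[f"kappa.{comps[0]}"] = Parameter(
            f"kappa.{comps[0]}", 0.0, "identity", True, (-0.02, 0.05),
            (-1.0, 1.0), profile_span=0.5)
        for c in comps[1:]:
            params[f"kappa.{c}"] = Parameter(f"kappa.{c}", 0.02, "log", True,
                                             (-9.0, -1.0), (-13.8, 3.0))
    else:
        for c in comps:
            params[f"beta.{c}"] = Parameter(
                f"beta.{c}", 0.0, "identity", True, (-0.05, 0.15), (-5.0, 5.0),
                profile_span=1.0)
    for c, guess in zip(comps, (2e3, 1e4, 5e4, 2e5)):
        params[f"n0.{c}"] = Parameter(f"n0.{c}", guess, "log", True,
                                      (np.log(1e2), np.log(1e6)),
                                      (np.log(10.0), np.log(1e8)))
    for ds in dataset_ids:
        for c in comps:
            params[f"f0.{ds}.{c}"] = Parameter(
                f"f0.{ds}.{c}", 0.05, "logit", True,
                (logit(1e-3), logit(0.6)), (logit(1e-6), logit(1 - 1e-3)))
    spec = FitSpec(topo, tuple(dataset_ids), params, kinetics, float(alpha_last))
    if values:
        spec.set_values(values)
    return spec


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class _Objective:
    """Precompiled residual evaluator for a spec + datasets."""

    def __init__(self, spec: FitSpec, datasets: Sequence[FitDataset]):
        self.spec = spec
        self.datasets = list(datasets)
        topo = spec.topology
        self.iu, self.id_ = topo.hsc_gate_indices()
        self.comp_index = {c: topo.index(c) for c in topo.compartments}
        # per dataset: union time grid and per-stream index into it
        self.grids = []
        for ds in self.datasets:
            tu = np.unique(np.concatenate([s.times for s in ds.streams]))
            idx = [np.searchsorted(tu, s.times) for s in ds.streams]
            self.grids.append((tu, idx))
        self.n_residuals = sum(ds.n_residuals for ds in self.datasets)
        self.penalty_hits = 0

    def _predict(self, alpha, kappa, n0, f0, tu):
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n = _cascade_eval(alpha[:-1], kappa, n0, tu)
            l = _cascade_eval(alpha[:-1], kappa, f0 * n0, tu)
            n_hsc = n[self.iu] + n[self.id_]
            f_hsc = (l[self.iu] + l[self.id_]) / n_hsc
        return n, l, n_hsc, f_hsc

    def stream_prediction(self, vals: Mapping[str, float], dataset_id: str,
                          compartment: str, quantity: str, times) -> np.ndarray:
        """Model prediction for one observable stream at arbitrary times."""
        alpha, kappa, n0 = self.spec.kinetics_arrays(vals)
        f0 = self.spec.f0_array(vals, dataset_id)
        tu = np.asarray(times, dtype=float)
        n, l, n_hsc, f_hsc = self._predict(alpha, kappa, n0, f0, tu)
        return self._lookup(compartment, quantity, n, l, n_hsc, f_hsc)

    def _lookup(self, comp, qty, n, l, n_hsc, f_hsc):
        if comp == HSC_COMPARTMENT:
            return f_hsc if qty in ("frequency", "norm_frequency") else n_hsc
        i = self.comp_index[comp]
        if qty == "count":
            return n[i]
        with np.errstate(all="ignore"):
            f = l[i] / n[i]
            return f / f_hsc if qty == "norm_frequency" else f

    def residuals(self, vals: Mapping[str, float]) -> np.ndarray:
        out = []
        alpha, kappa, n0 = self.spec.kinetics_arrays(vals)
        for ds, (tu, idx) in zip(self.datasets, self.grids):
            f0 = self.spec.f0_array(vals, ds.dataset_id)
            n, l, n_hsc, f_hsc = self._predict(alpha, kappa, n0, f0, tu)
            for s, ix in zip(ds.streams, idx):
                pred = self._lookup(s.compartment, s.quantity, n, l, n_hsc, f_hsc)[ix]
                out.append((pred - s.mean) / s.sem)
        r = np.concatenate(out)
        bad = ~np.isfinite(r) | (np.abs(r) > _PENALTY)
        if bad.any():
            self.penalty_hits += 1
            r = np.where(bad, _PENALTY, r)
        return r

    def ssr(self, vals: Mapping[str, float]) -> float:
        r = self.residuals(vals)
        return float(r @ r)

    def residual_fn(self):
        spec = self.spec

        def fn(x_free: np.ndarray) -> np.ndarray:
            return self.residuals(spec.natural_from_free(x_free))

        return fn


def weighted_ssr(values: Mapping[str, float], datasets: Sequence[FitDataset],
                 spec: FitSpec) -> float:
    """Weighted sum of squared residuals of the model at ``values``."""
    return _Objective(spec, datasets).ssr(values)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class ProfileCI:
    name: str
    level: float
    lower: float | None
    upper: float | None
    lower_unbounded: bool
    upper_unbounded: bool
    curve: pd.DataFrame        # columns: value (natural), objective

    @property
    def has_finite_bound(self) -> bool:
        return not (self.lower_unbounded and self.upper_unbounded)


@dataclass
class FitResult:
    spec: FitSpec
    datasets: list[FitDataset]
    values: dict[str, float]          # natural scale, all parameters
    objective: float                  # weighted SSR at the optimum
    free_names: list[str]
    x_free: np.ndarray                # transformed-scale optimum
    jac: np.ndarray | None
    n_residuals: int
    start_objectives: list[tuple[float, float]]   # (initial, final) per start
    message: str = ""
    profiles: dict[str, ProfileCI] = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def reduced_objective(self) -> float:
        dof = self.n_residuals - self.n_free
        if dof <= 0:
            raise ValueError("no residual degrees of freedom")
        return self.objective / dof

    def se_transformed(self) -> np.ndarray:
        """Approximate standard errors on the transformed scale from J'J."""
        if self.jac is None or self.n_free == 0:
            return np.full(self.n_free, np.nan)
        jtj = self.jac.T @ self.jac
        with np.errstate(all="ignore"):
            cov = np.linalg.pinv(jtj)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        return se

    def summary(self) -> str:
        lines = [f"weighted SSR: {self.objective:.6g} "
                 f"({self.n_residuals} residuals, {self.n_free} free parameters)"]
        for n in self.free_names:
            v = self.values[n]
            extra = f"  [{v * 7:.4g} /week]" if n.split(".")[0] in ("alpha", "beta", "kappa") else ""
            ci = ""
            if n in self.profiles:
                p = self.profiles[n]
                lo = "unbounded" if p.lower_unbounded else f"{p.lower:.4g}"
                hi = "unbounded" if p.upper_unbounded else f"{p.upper:.4g}"
                ci = f"  CI95 [{lo}, {hi}]"
            lines.append(f"  {n} = {v:.6g}{extra}{ci}")
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        d = {
            "objective": self.objective,
            "n_residuals": self.n_residuals,
            "values": self.values,
            "free": self.free_names,
            "profiles": {
                n: {"level": p.level, "lower": p.lower, "upper": p.upper,
                    "lower_unbounded": p.lower_unbounded,
                    "upper_unbounded": p.upper_unbounded}
                for n, p in self.profiles.items()
            },
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _informed_start(spec: FitSpec, datasets: Sequence[FitDataset]) -> dict[str, float]:
    """Heuristic data-driven start: initial sizes from first-bin counts (the
    hidden HSC gate split 1:5 upstream:downstream), initial labeling from
    first-bin frequencies spread across the gate."""
    vals = spec.values()
    comps = spec.topology.compartments
    for ds in datasets:
        by = {(s.compartment, s.quantity): s for s in ds.streams}
        c_hsc = by.get((HSC_COMPARTMENT, "count"))
        if c_hsc is not None and len(c_hsc.mean):
            vals[f"n0.{comps[0]}"] = max(c_hsc.mean[0] / 6.0, 10.0)
            vals[f"n0.{comps[1]}"] = max(5.0 * c_hsc.mean[0] / 6.0, 10.0)
        for comp in ("ST-HSC", "MPP"):
            s = by.get((comp, "count"))
            if s is not None and len(s.mean):
                vals[f"n0.{comp}"] = max(s.mean[0], 10.0)
        f = by.get((HSC_COMPARTMENT, "frequency"))
        if f is not None and len(f.mean):
            fh = float(np.clip(f.mean[0], 1e-3, 0.95))
            vals[f"f0.{ds.dataset_id}.{comps[0]}"] = min(1.5 * fh, 0.95)
            vals[f"f0.{ds.dataset_id}.{comps[1]}"] = max(0.5 * fh, 1e-3)
            for comp in ("ST-HSC", "MPP"):
                s = by.get((comp, "norm_frequency"))
                if s is not None and len(s.mean):
                    vals[f"f0.{ds.dataset_id}.{comp}"] = float(
                        np.clip(s.mean[0] * fh, 1e-4, 0.9))
    return vals


def _optimize(fn, x0, max_nfev=3000, bounds=(-np.inf, np.inf)):
    lo, hi = bounds
    x0 = np.clip(x0, lo, hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return optimize.least_squares(fn, x0, method="trf", x_scale="jac",
                                      bounds=bounds, max_nfev=max_nfev)


def fit_joint(datasets: Sequence[FitDataset], spec: FitSpec, *,
              n_starts: int = 32, seed: int | None = 0,
              use_informed_start: bool = True, max_nfev: int = 3000) -> FitResult:
    """Multi-start weighted least squares with shared kinetics.

    Starts are Latin-hypercube samples of the free parameters on the
    transformed scale (within each parameter's start bounds), plus the spec's
    current values and a data-informed heuristic start.  Deterministic given
    ``seed``.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    obj = _Objective(spec, datasets)
    fn = obj.residual_fn()
    free = spec.free_names
    if not free:
        vals = spec.values()
        ssr = obj.ssr(vals)
        return FitResult(spec, list(datasets), vals, ssr, [], np.empty(0),
                         None, obj.n_residuals, [], message="no free parameters")

    starts = [spec.x0_free()]
    if use_informed_start:
        informed = spec.with_fixed([])  # copy
        informed.set_values(_informed_start(spec, datasets))
        starts.append(informed.x0_free())
    n_lhs = max(n_starts - len(starts), 0)
    if n_lhs:
        lo = np.array([spec.params[n].start_bounds[0] for n in free])
        hi = np.array([spec.params[n].start_bounds[1] for n in free])
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        starts.extend(lo + sampler.random(n_lhs) * (hi - lo))
    hard = (np.array([spec.params[n].hard_bounds[0] for n in free]),
            np.array([spec.params[n].hard_bounds[1] for n in free]))

    best = None
    start_objectives = []
    for x0 in starts:
        r0 = fn(np.asarray(x0, dtype=float))
        try:
            res = _optimize(fn, np.asarray(x0, dtype=float), max_nfev, hard)
        except (ValueError, np.linalg.LinAlgError):
            continue   # numerically hopeless start; others remain
        start_objectives.append((float(r0 @ r0), float(2 * res.cost)))
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("no optimization start converged")

    vals = spec.natural_from_free(best.x)
    return FitResult(spec, list(datasets), vals, float(2 * best.cost),
                     list(free), best.x.copy(), best.jac, obj.n_residuals,
                     start_objectives, message=best.message)


def fit_fixed_kinetics(datasets: Sequence[FitDataset] | FitDataset,
                       fixed: "FitResult | Mapping[str, float]", *,
                       spec: FitSpec | None = None,
                       n_starts: int = 8, seed: int | None = 0,
                       **kw) -> FitResult:
    """Fit only the initial labeling frequencies, with kinetics and initial
    sizes fixed (out-of-sample prediction of a new Cre driver)."""
    if isinstance(datasets, FitDataset):
        datasets = [datasets]
    fixed_values = fixed.values if isinstance(fixed, FitResult) else dict(fixed)
    if spec is None:
        base = fixed.spec if isinstance(fixed, FitResult) else None
        spec = make_fitspec([ds.dataset_id for ds in datasets],
                            topology=base.topology if base else None,
                            kinetics=base.kinetics if base else "kappa",
                            alpha_last=base.alpha_last if base else 0.1)
    shared = [n for n in spec.params
              if n.split(".")[0] in ("alpha", "kappa", "beta", "n0")]
    missing = [n for n in shared if n not in fixed_values]
    if missing:
        raise ValueError(f"fixed kinetics incomplete; missing {missing}")
    spec = spec.with_fixed(shared, {n: fixed_values[n] for n in shared})
    return fit_joint(datasets, spec, n_starts=n_starts, seed=seed, **kw)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _reoptimize_fixed(fit: FitResult, name: str, x_fixed: float,
                      warm: np.ndarray | None, max_nfev: int = 800):
    """Objective minimized over all free parameters except ``name``, which is
    held at transformed value ``x_fixed``."""
    spec = fit.spec
    natural = spec.params[name].from_transformed(x_fixed)
    sub = spec.with_fixed([name], {name: natural})
    sub.set_values(fit.values)
    sub.params[name] = replace(sub.params[name], value=natural, free=False)
    obj = _Objective(sub, fit.datasets)
    fn = obj.residual_fn()
    if not sub.free_names:
        return float(obj.ssr(sub.values())), np.empty(0)
    x0 = warm if warm is not None else sub.x0_free()
    hard = (np.array([sub.params[n].hard_bounds[0] for n in sub.free_names]),
            np.array([sub.params[n].hard_bounds[1] for n in sub.free_names]))
    res = _optimize(fn, x0, max_nfev, hard)
    return float(2 * res.cost), res.x


def profile_likelihood_ci(fit: FitResult, name: str, *, level: float = 0.95,
                          max_steps: int = 40, init_step: float | None = None,
                          span: float | None = None) -> ProfileCI:
    """Profile-likelihood confidence interval for one free parameter.

    Walks the parameter on its transformed scale in both directions,
    re-optimizing the remaining parameters (warm-started from the previous
    profile point), with an adaptive step targeting a fraction of the
    chi-square threshold per move.  The crossing is located by linear
    interpolation; a side is flagged unbounded if the threshold is not reached
    within ``span`` transformed units of the optimum.
    """
    if name not in fit.free_names:
        raise KeyError(f"{name!r} is not a free parameter of this fit")
    par = fit.spec.params[name]
    delta = chi2.ppf(level, 1)
    threshold = fit.objective + delta
    i_free = fit.free_names.index(name)
    x_best = fit.x_free[i_free]
    warm_template = np.delete(fit.x_free, i_free)
    span = span if span is not None else par.profile_span
    if init_step is None:
        se = fit.se_transformed()
        se_i = se[i_free] if np.isfinite(se[i_free]) and se[i_free] > 0 else 0.1
        init_step = float(np.clip(0.4 * se_i, 1e-3, span / 8))

    records = [(par.from_transformed(x_best), fit.objective)]
    bounds: dict[int, tuple[float | None, bool]] = {}
    for sign in (-1, 1):
        step = init_step
        prev_x, prev_obj = x_best, fit.objective
        warm = warm_template.copy()
        bound, unbounded = None, True
        for _ in range(max_steps):
            x_try = prev_x + sign * step
            terminal = abs(x_try - x_best) >= span
            if terminal:
                x_try = x_best + sign * span
            try:
                obj, warm_new = _reoptimize_fixed(fit, name, x_try, warm)
            except Exception:   # failed profile point: recorded, profile continues
                prev_x = x_try
                continue
            if len(warm_new):
                warm = warm_new
            records.append((par.from_transformed(x_try), obj))
            if obj > threshold:
                # bracket found: refine the crossing by bisection, then
                # interpolate linearly inside the final bracket
                x_lo, o_lo, x_hi, o_hi = prev_x, prev_obj, x_try, obj
                for _ in range(4):
                    x_mid = 0.5 * (x_lo + x_hi)
                    try:
                        o_mid, warm = _reoptimize_fixed(fit, name, x_mid, warm)[:2]
                    except Exception:
                        break
                    records.append((par.from_transformed(x_mid), o_mid))
                    if o_mid > threshold:
                        x_hi, o_hi = x_mid, o_mid
                    else:
                        x_lo, o_lo = x_mid, o_mid
                frac = (threshold - o_lo) / max(o_hi - o_lo, 1e-12)
                x_cross = x_lo + (x_hi - x_lo) * np.clip(frac, 0.0, 1.0)
                bound, unbounded = par.from_transformed(x_cross), False
                break
            if terminal:
                break
            dobj = obj - prev_obj
            if dobj < delta / 10:
                step = min(step * 1.8, span / 3)
            elif dobj > delta / 2:
                step = max(step / 2, 1e-4)
            prev_x, prev_obj = x_try, obj
        bounds[sign] = (bound, unbounded)

    curve = pd.DataFrame(sorted(records), columns=["value", "objective"])
    lo, lo_unb = bounds[-1]
    hi, hi_unb = bounds[1]
    return ProfileCI(name=name, level=level, lower=lo, upper=hi,
                     lower_unbounded=lo_unb, upper_unbounded=hi_unb, curve=curve)


def profile_all(fit: FitResult, names: Sequence[str] | None = None,
                **kw) -> dict[str, ProfileCI]:
    """Profile several (default: all free) parameters; attaches to the fit."""
    names = list(names) if names is not None else list(fit.free_names)
    for n in names:
        fit.profiles[n] = profile_likelihood_ci(fit, n, **kw)
    return fit.profiles


# ---------------------------------------------------------------------------
# prediction profile bands
# ---------------------------------------------------------------------------

def prediction_profile_band(fit: FitResult, dataset_id: str, compartment: str,
                            quantity: str, time: float, *, level: float = 0.95,
                            include_observation_noise: bool = False) -> tuple[float, float]:
    """Prediction-profile band for one model observable at one time.

    Minimizes / maximizes the model prediction subject to the objective not
    exceeding the optimum by the chi-square(1) quantile.  With
    ``include_observation_noise`` the band is widened by +/- z * SEM of the
    matching data stream (validation-style band for a new bin mean).
    """
    obj = _Objective(fit.spec, fit.datasets)
    fn = obj.residual_fn()
    delta = chi2.ppf(level, 1)
    threshold = fit.objective + delta
    free = fit.free_names
    hard = (np.array([fit.spec.params[n].hard_bounds[0] for n in free]),
            np.array([fit.spec.params[n].hard_bounds[1] for n in free]))

    def g(x):
        vals = fit.spec.natural_from_free(x)
        return float(obj.stream_prediction(vals, dataset_id, compartment,
                                           quantity, [time])[0])

    best_pred = g(fit.x_free)
    # stiff pseudo-observation pinning the prediction at a target value; the
    # profile of the true SSR over the achieved prediction traces the
    # prediction profile.  The pin must dominate every data weight.
    try:
        sem0 = _stream_sem_at(fit, dataset_id, compartment, quantity, time)
    except KeyError:
        sem0 = max(abs(best_pred), 1e-6)
    w = 50.0 / sem0
    step0 = 0.5 * sem0

    def ssr_at_target(g0, x_warm):
        def fn_aug(x):
            return np.concatenate([fn(x), [w * (g(x) - g0)]])
        res = _optimize(fn_aug, x_warm, max_nfev=400, bounds=hard)
        r = fn(res.x)
        return float(r @ r), float(g(res.x)), res.x

    edges = []
    for sign in (-1.0, 1.0):
        step = step0
        prev_g, prev_obj = best_pred, fit.objective
        target = best_pred
        warm = fit.x_free.copy()
        edge = prev_g
        for _ in range(60):
            target += sign * step
            try:
                o_try, g_ach, warm = ssr_at_target(target, warm)
            except (ValueError, np.linalg.LinAlgError):
                break
            if o_try > threshold:
                frac = (threshold - prev_obj) / max(o_try - prev_obj, 1e-12)
                edge = prev_g + (g_ach - prev_g) * float(np.clip(frac, 0.0, 1.0))
                break
            dobj = o_try - prev_obj
            if dobj < delta / 10:
                step *= 1.8
            elif dobj > delta / 2:
                step *= 0.5
            prev_g, prev_obj, edge = g_ach, o_try, g_ach
        edges.append(edge)
    lo, hi = min(edges[0], best_pred), max(edges[1], best_pred)
    if include_observation_noise:
        z = float(chi2.ppf(level, 1) ** 0.5)
        sem = _stream_sem_at(fit, dataset_id, compartment, quantity, time)
        lo, hi = lo - z * sem, hi + z * sem
    return lo, hi


def _stream_sem_at(fit, dataset_id, compartment, quantity, time) -> float:
    for ds in fit.datasets:
        if ds.dataset_id != dataset_id:
            continue
        for s in ds.streams:
            if s.compartment == compartment and s.quantity == quantity:
                return float(s.sem[np.argmin(np.abs(s.times - time))])
    raise KeyError(f"no stream ({compartment}, {quantity}) in dataset {dataset_id}")


# ---------------------------------------------------------------------------
# labeling specificity
# ---------------------------------------------------------------------------

def labeling_specificity(fit: FitResult) -> pd.DataFrame:
    """Per-dataset HSC-U:HSC-D initial-labeling ratios and their pairwise
    ratios (driver specificity).

    The ratio interval is propagated conservatively from profile CIs of the
    two frequencies when available: minimum ratio = lower(f0_U) / upper(f0_D).
    A zero HSC-D labeling gives an unbounded (infinite) ratio.
    """
    comps = fit.spec.topology.compartments
    u, d = comps[0], comps[1]
    rows = []
    for ds in fit.spec.dataset_ids:
        fu, fd = fit.values[f"f0.{ds}.{u}"], fit.values[f"f0.{ds}.{d}"]
        ratio = fu / fd if fd > 0 else np.inf
        lo = hi = np.nan
        pu, pd_ = fit.profiles.get(f"f0.{ds}.{u}"), fit.profiles.get(f"f0.{ds}.{d}")
        if pu is not None and pd_ is not None:
            fu_lo = 0.0 if pu.lower_unbounded else pu.lower
            fu_hi = 1.0 if pu.upper_unbounded else pu.upper
            fd_lo = 0.0 if pd_.lower_unbounded else pd_.lower
            fd_hi = 1.0 if pd_.upper_unbounded else pd_.upper
            lo = fu_lo / fd_hi if fd_hi > 0 else np.inf
            hi = fu_hi / fd_lo if fd_lo > 0 else np.inf
        rows.append({"dataset_id": ds, "f0_U": fu, "f0_D": fd,
                     "ratio": ratio, "ratio_lo": lo, "ratio_hi": hi})
    df = pd.DataFrame(rows).set_index("dataset_id")
    for a in df.index:
        for b in df.index:
            if a != b:
                df.loc[a, f"specificity_vs_{b}"] = df.loc[a, "ratio"] / df.loc[b, "ratio"]
    return df
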
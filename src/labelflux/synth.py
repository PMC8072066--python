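"""Synthetic cross-sectional lineage-tracing cohorts.

Generates per-mouse observation tables with the statistical structure the
analysis assumes: cohorts of mice measured once each (cross-sectionally) at a
handful of time points over at most 40 weeks, with labeled frequencies in the
observed HSC / ST-HSC / MPP gates driven by the four-compartment
label-propagation model under driver-specific initial labeling of the two
hidden HSC subcompartments.

Measurement noise is a stand-in for unpublished per-mouse error structure:

* frequency — the labeled fraction among ``C`` sampled cells is drawn
  binomially (``C`` per compartment; HSC-gate compartments are rare, so fewer
  cells are scored there);
* count — expected compartment size times multiplicative lognormal noise.

Both can be switched off (``cells_sampled=None``, ``count_log_sd=0``) for
noise-free end-to-end identity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (DEFAULT_COMPARTMENTS, InitialState, KineticRates,
                    ModelTopology, _cascade_eval)
from .data import HSC_COMPARTMENT, NORMALIZED_COMPARTMENTS

__all__ = [
    "CohortDesign",
    "default_truth",
    "preset_designs",
    "generate_cohort",
    "generate_multi_dataset",
    "truth_manifest",
]

#: default cells scored per compartment when drawing binomial frequency noise
DEFAULT_CELLS_SAMPLED = {"HSC": 200, "ST-HSC": 200, "MPP": 1000}


@dataclass(frozen=True)
class CohortDesign:
    """Design of one synthetic cohort (one Cre driver / dataset)."""

    dataset_id: str
    times: tuple[float, ...]                    # days since effective induction
    mice_per_time: tuple[int, ...]
    f0: tuple[float, float, float, float]       # initial labeling (U, D, ST, MPP)
    time_zero_offset: float = 2.0               # days; raw time = time + offset
    cells_sampled: Mapping[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_CELLS_SAMPLED))
    count_log_sd: float = 0.2

    def __post_init__(self):
        if len(self.times) != len(self.mice_per_time):
            raise ValueError("times and mice_per_time must have equal length")
        if any(m < 1 for m in self.mice_per_time):
            raise ValueError("each time point needs at least one mouse")
        if any(not 0 <= v <= 1 for v in self.f0):
            raise ValueError("initial labeling frequencies must lie in [0, 1]")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "mice_per_time", tuple(int(m) for m in self.mice_per_time))
        object.__setattr__(self, "f0", tuple(float(v) for v in self.f0))

    @property
    def n_mice(self) -> int:
        return sum(self.mice_per_time)

    def labeling_ratio(self) -> float:
        """HSC-U : HSC-D initial labeling ratio (inf if HSC-D unlabeled)."""
        return self.f0[0] / self.f0[1] if self.f0[1] > 0 else float("inf")


def default_truth() -> tuple[KineticRates, InitialState]:
    """Reference kinetics and initial sizes used as generator truth.

    Chosen to reflect the consensus picture of unperturbed adult mouse
    hematopoiesis: a small near-quiescent HSC-U pool that slowly expands
    (kappa_1 < 0) and differentiates about once per 50 cell-weeks; an active
    HSC-D pool several-fold larger, with each cell differentiating about once
    per week; a faster-turnover ST-HSC pool; and a large, almost self-renewing
    MPP pool (small kappa_4).  Death rates are config inputs; the lambda/delta
    split below keeps all proliferation rates positive.
    """
    alpha = np.array([1.0 / 50.0 / 7.0, 1.0 / 7.0, 0.10, 0.10])
    kappa = np.array([-0.002, 0.001, 0.03, 0.02])
    delta = np.array([0.002, 0.02, 0.05, 0.10])
    lam = (alpha - kappa) + delta        # beta = alpha - kappa = lam - delta
    rates = KineticRates.from_lambda_delta(alpha, lam, delta)
    n0 = np.array([2000.0, 12000.0, 50000.0, 200000.0])
    return rates, InitialState(n0=n0)


def preset_designs() -> dict[str, CohortDesign]:
    """Named cohort designs emulating the three published Cre drivers plus the
    two-label toy used to illustrate labeling heterogeneity.

    Initial HSC-U:HSC-D labeling ratios encode the driver specificities
    (Tie2 21:1, Fgd5 4:1, Krt18 30:1).  The Tie2-style design has eight pooled
    time bins with per-bin mouse counts (41, 61, 21, 8, 39, 34, 21, 17); the
    Fgd5-style design has eight distinct time points of a ~56-mouse cohort;
    the Krt18-style design is a sparse 18-mouse cohort with a 1-day time-zero
    offset.
    """
    toy_noise = dict(cells_sampled=None, count_log_sd=0.0)
    return {
        "tie2-like": CohortDesign(
            dataset_id="tie2",
            times=(10, 38, 62, 86, 116, 141, 169, 198),
            mice_per_time=(41, 61, 21, 8, 39, 34, 21, 17),
            f0=(0.42, 0.02, 0.004, 0.002),
            time_zero_offset=2.0,
        ),
        "fgd5-like": CohortDesign(
            dataset_id="fgd5",
            times=(7, 35, 70, 105, 140, 175, 210, 266),
            mice_per_time=(7, 7, 7, 7, 7, 7, 7, 7),
            f0=(0.28, 0.07, 0.012, 0.006),
            time_zero_offset=2.0,
        ),
        "krt18-like": CohortDesign(
            dataset_id="krt18",
            times=(6, 27, 69, 139, 209, 279),
            mice_per_time=(3, 3, 3, 3, 3, 3),
            f0=(0.30, 0.01, 0.002, 0.001),
            time_zero_offset=1.0,
        ),
        "toy-I": CohortDesign(
            dataset_id="toy-I",
            times=tuple(range(0, 281, 14)), mice_per_time=(3,) * 21,
            f0=(0.5, 0.0, 0.0, 0.0), time_zero_offset=0.0, **toy_noise,
        ),
        "toy-J": CohortDesign(
            dataset_id="toy-J",
            times=tuple(range(0, 281, 14)), mice_per_time=(3,) * 21,
            f0=(0.5, 0.5, 0.0, 0.0), time_zero_offset=0.0, **toy_noise,
        ),
    }


def _expected_observables(rates: KineticRates, n0: np.ndarray, f0: np.ndarray,
                          times: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Exact expected (frequency, count) per observed compartment at ``times``
    via the analytic cascade (n and l are both linear cascades; f = l/n)."""
    n = _cascade_eval(rates.alpha[:-1], rates.kappa, n0, times)
    l = _cascade_eval(rates.alpha[:-1], rates.kappa, f0 * n0, times)
    n_hsc = n[0] + n[1]
    return {
        HSC_COMPARTMENT: ((l[0] + l[1]) / n_hsc, n_hsc),
        "ST-HSC": (l[2] / n[2], n[2]),
        "MPP": (l[3] / n[3], n[3]),
    }


def generate_cohort(rates: KineticRates, init: InitialState, design: CohortDesign,
                    *, rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Simulate one cross-sectional cohort as a validated observation table.

    Each mouse is measured once; the table reports *raw* measurement times
    (design time + time-zero offset), so the full preprocessing pipeline can
    be exercised on the output.  Deterministic given an integer seed or a
    seeded ``Generator``.
    """
    rng = np.random.default_rng(rng)
    times = np.asarray(design.times, dtype=float)
    expect = _expected_observables(rates, init.n0, np.asarray(design.f0), times)

    rows = []
    mouse = 0
    for j, (t, n_mice) in enumerate(zip(times, design.mice_per_time)):
        for _ in range(n_mice):
            mid = f"{design.dataset_id}_m{mouse:04d}"
            mouse += 1
            for comp, (f_exp, n_exp) in expect.items():
                f_true, n_true = float(f_exp[j]), float(n_exp[j])
                if design.cells_sampled is None:
                    f_obs = f_true
                else:
                    c = int(design.cells_sampled[comp])
                    f_obs = rng.binomial(c, min(max(f_true, 0.0), 1.0)) / c
                if design.count_log_sd > 0:
                    # mean-one multiplicative noise (lognormal with E = 1)
                    sd = design.count_log_sd
                    n_obs = n_true * rng.lognormal(-0.5 * sd * sd, sd)
                else:
                    n_obs = n_true
                rows.append({
                    "mouse_id": mid,
                    "dataset_id": design.dataset_id,
                    "time_days": t + design.time_zero_offset,
                    "compartment": comp,
                    "frequency": min(max(f_obs, 0.0), 1.0),
                    "count": n_obs,
                })
    return pd.DataFrame(rows)


def generate_multi_dataset(rates: KineticRates, init: InitialState,
                           designs: Sequence[CohortDesign],
                           *, seed: int | None = None) -> list[pd.DataFrame]:
    """Simulate several cohorts sharing one set of kinetics, differing only in
    initial labeling and cohort structure (the joint-fit assumption)."""
    if len(designs) < 1:
        raise ValueError("need at least one design")
    streams = np.random.default_rng(seed).spawn(len(designs))
    return [generate_cohort(rates, init, d, rng=r) for d, r in zip(designs, streams)]


def truth_manifest(rates: KineticRates, init: InitialState,
                   designs: Sequence[CohortDesign], seed: int | None) -> dict:
    """JSON-serialisable record of the generating truth, for recovery tests."""
    return {
        "seed": seed,
        "rates": {
            "alpha": rates.alpha.tolist(),
            "beta": rates.beta.tolist(),
            "kappa": rates.kappa.tolist(),
            **({"lambda": rates.lam.tolist(), "delta": rates.delta.tolist()}
               if rates.lam is not None else {}),
        },
        "n0": init.n0.tolist(),
        "designs": [
            {**asdict(d), "cells_sampled": dict(d.cells_sampled) if d.cells_sampled else None}
            for d in designs
        ],
    }
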
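"""Per-mouse observation tables and the preprocessing pipeline.

Cross-sectional lineage-tracing cohorts arrive as tidy delimited text with one
row per (mouse, compartment): days since induction, dataset (Cre driver) id,
compartment name, labeled-cell frequency, and optionally the compartment cell
count.  The pipeline applies, in order:

1. time-zero adjustment — measurements are referenced to the time tamoxifen is
   assumed to have taken effect (default offset 2 days; 1 day for sparse
   designs such as Krt18);
2. windowing to 40 weeks (280 days, inclusive), excluding aging-related drift;
3. per-mouse HSC normalization — downstream labeled frequencies divided by the
   same mouse's HSC labeled frequency;
4. pooling of nearby time points into bins, with per-bin means;
5. pooled-variance SEMs — within-bin variances are pooled across bins (and by
   default across datasets) per observable stream, so bins with few mice
   borrow strength from the rest of the time course:
   ``s2_pooled = sum_g (n_g - 1) s2_g / sum_g (n_g - 1)`` and
   ``SEM_bin = sqrt(s2_pooled / n_bin)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "TIE2_BINS",
    "HSC_COMPARTMENT",
    "NORMALIZED_COMPARTMENTS",
    "ObservationError",
    "PooledDataset",
    "load_observations",
    "validate_observations",
    "adjust_time_zero",
    "restrict_window",
    "add_hsc_normalized",
    "pool_timepoints",
    "pooled_variance_sem",
    "normalize_pooled_to_hsc",
]

REQUIRED_COLUMNS = ("mouse_id", "dataset_id", "time_days", "compartment", "frequency")
OPTIONAL_COLUMNS = ("count",)

#: observed compartment holding the pooled HSC gate
HSC_COMPARTMENT = "HSC"
#: compartments whose frequencies are normalized to the HSC frequency
NORMALIZED_COMPARTMENTS = ("ST-HSC", "MPP")

#: pooling intervals (days, inclusive) used for the densely sampled Tie2-style
#: time course; eight bins, matching the number of distinct time points in an
#: Fgd5-style design
TIE2_BINS = ((0, 20), (27, 50), (55, 69), (78, 95),
             (104, 129), (130, 153), (160, 179), (188, 208))


class ObservationError(ValueError):
    """Validation failure in an observation table; carries offending row labels."""

    def __init__(self, message: str, rows=None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows[:10]}{'...' if len(self.rows) > 10 else ''})"
        super().__init__(message)


def validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise ObservationError("observation table is empty")
    out = df.copy()
    out["time_days"] = pd.to_numeric(out["time_days"], errors="coerce")
    out["frequency"] = pd.to_numeric(out["frequency"], errors="coerce")
    if "count" in out.columns:
        out["count"] = pd.to_numeric(out["count"], errors="coerce")
    else:
        out["count"] = np.nan

    bad = out.index[out["time_days"].isna() | out["frequency"].isna()]
    if len(bad):
        raise ObservationError("unparseable time or frequency values", bad)
    bad = out.index[(out["frequency"] < 0) | (out["frequency"] > 1)]
    if len(bad):
        raise ObservationError("labeled frequencies must lie in [0, 1]", bad)
    bad = out.index[out["count"] < 0]
    if len(bad):
        raise ObservationError("counts must be non-negative", bad)

    key = ["mouse_id", "dataset_id", "time_days", "compartment"]
    dup = out.index[out.duplicated(key, keep=False)]
    if len(dup):
        raise ObservationError("duplicate (mouse, dataset, time, compartment) rows", dup)
    return out


def load_observations(path, *, sep: str | None = None,
                      column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a delimited observation table.

    ``column_map`` maps file column names to the canonical schema, e.g.
    ``{"days": "time_days"}``.  The delimiter is sniffed unless given.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ObservationError(f"missing or empty observation file: {path}")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_observations(df)


def adjust_time_zero(df: pd.DataFrame,
                     offset_days: float | Mapping[str, float]) -> pd.DataFrame:
    """Shift the time axis so t=0 is the first effective measurement.

    ``offset_days`` is a scalar or a per-dataset mapping (days after tamoxifen
    injection at which the label is assumed effective).  Rows whose adjusted
    time is negative are dropped with a warning.
    """
    out = df.copy()
    if isinstance(offset_days, Mapping):
        off = out["dataset_id"].map(offset_days)
        if off.isna().any():
            missing = sorted(out.loc[off.isna(), "dataset_id"].unique())
            raise ObservationError(f"no time-zero offset for dataset(s): {missing}")
    else:
        off = float(offset_days)
    out["time_days"] = out["time_days"] - off
    neg = out["time_days"] < 0
    if neg.any():
        warnings.warn(f"dropping {int(neg.sum())} row(s) before effective induction",
                      stacklevel=2)
        out = out.loc[~neg]
    return out.reset_index(drop=True)


def restrict_window(df: pd.DataFrame, max_days: float = 280.0) -> pd.DataFrame:
    """Keep rows with time <= max_days (inclusive; default 40 weeks)."""
    if max_days <= 0:
        raise ValueError("max_days must be positive")
    out = df.loc[df["time_days"] <= max_days].reset_index(drop=True)
    dropped = len(df) - len(out)
    if dropped:
        warnings.warn(f"dropped {dropped} row(s) beyond {max_days:g} days", stacklevel=2)
    return out


def add_hsc_normalized(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``norm_frequency`` column: each mouse's downstream labeled
    frequency divided by the same mouse's HSC labeled frequency.

    HSC rows get NaN; mice whose HSC frequency is zero are masked with a
    warning.
    """
    out = df.copy()
    hsc = out[out["compartment"] == HSC_COMPARTMENT]
    key = ["mouse_id", "dataset_id", "time_days"]
    denom = hsc.set_index(key)["frequency"]
    idx = pd.MultiIndex.from_frame(out[key])
    mapped = pd.Series(denom.reindex(idx).to_numpy(), index=out.index)
    zero = (mapped == 0) & (out["compartment"] != HSC_COMPARTMENT)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} normalized value(s) masked: HSC frequency is zero",
            stacklevel=2)
        mapped[zero] = np.nan
    out["norm_frequency"] = np.where(
        out["compartment"].isin(NORMALIZED_COMPARTMENTS),
        out["frequency"] / mapped.to_numpy(), np.nan)
    return out


@dataclass
class PooledDataset:
    """Binned per-(dataset, compartment, quantity) summaries plus pooled variances.

    ``stats`` columns: dataset_id, compartment, quantity, bin_lo, bin_hi, time,
    mean, var, n.  ``pooled_variance`` is filled by :func:`pooled_variance_sem`,
    which also adds an ``sem`` column.
    """

    stats: pd.DataFrame
    bin_edges: tuple[tuple[float, float], ...]
    pooled_variance: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.stats.to_csv(path, index=False)


def _check_bins(bin_edges) -> tuple[tuple[float, float], ...]:
    edges = tuple((float(lo), float(hi)) for lo, hi in bin_edges)
    for lo, hi in edges:
        if hi < lo:
            raise ValueError(f"bin ({lo}, {hi}) has hi < lo")
    ordered = sorted(edges)
    for (lo1, hi1), (lo2, hi2) in zip(ordered[:-1], ordered[1:]):
        if lo2 <= hi1:
            raise ValueError(f"bins ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap")
    return edges


def pool_timepoints(df: pd.DataFrame,
                    bin_edges: Sequence[tuple[float, float]] | None = None,
                    *, bin_time: str = "mean") -> PooledDataset:
    """Pool nearby time points into bins and compute per-bin summaries.

    ``bin_edges`` are inclusive (lo, hi) intervals in days; ``None`` makes each
    distinct observed time its own bin.  The representative bin time is the
    within-bin mean of observation times (``bin_time='mean'``, default) or the
    interval midpoint (``'midpoint'``).  Rows outside all bins are dropped with
    a warning.  Each quantity present (frequency, count, norm_frequency) is
    summarised separately; missing values do not contribute.
    """
    if bin_time not in ("mean", "midpoint"):
        raise ValueError("bin_time must be 'mean' or 'midpoint'")
    if bin_edges is None:
        uniq = np.unique(df["time_days"].to_numpy())
        bin_edges = [(t, t) for t in uniq]
    edges = _check_bins(bin_edges)

    t = df["time_days"].to_numpy()
    which = np.full(len(df), -1)
    for b, (lo, hi) in enumerate(edges):
        which[(t >= lo) & (t <= hi)] = b
    if np.any(which < 0):
        warnings.warn(f"dropping {int((which < 0).sum())} row(s) outside all bins",
                      stacklevel=2)
    work = df.loc[which >= 0].copy()
    work["_bin"] = which[which >= 0]

    quantities = [q for q in ("frequency", "count", "norm_frequency") if q in work.columns]
    rows = []
    for (ds, comp, b), grp in work.groupby(["dataset_id", "compartment", "_bin"], sort=True):
        lo, hi = edges[int(b)]
        for q in quantities:
            vals = grp[q].dropna().to_numpy()
            if len(vals) == 0:
                continue
            time = grp.loc[grp[q].notna(), "time_days"].mean() if bin_time == "mean" \
                else 0.5 * (lo + hi)
            rows.append({
                "dataset_id": ds, "compartment": comp, "quantity": q,
                "bin_lo": lo, "bin_hi": hi, "time": time,
                "mean": vals.mean(),
                "var": vals.var(ddof=1) if len(vals) > 1 else np.nan,
                "n": len(vals),
            })
    stats = pd.DataFrame(rows)
    return PooledDataset(stats=stats, bin_edges=edges)


def pooled_variance_sem(pooled: PooledDataset, *, per_dataset: bool = False) -> PooledDataset:
    """Attach pooled-variance SEMs to a :class:`PooledDataset`.

    One pooled variance is computed per observable stream — per (compartment,
    quantity), across all bins and (by default) all datasets — and each bin's
    SEM is ``sqrt(pooled_variance / n_bin)``.  ``per_dataset=True`` pools
    within each dataset instead.
    """
    stats = pooled.stats.copy()
    keys = ["compartment", "quantity"] + (["dataset_id"] if per_dataset else [])
    records = []
    for key, grp in stats.groupby(keys, sort=True):
        dof = (grp["n"] - 1).to_numpy(dtype=float)
        var = grp["var"].to_numpy(dtype=float)
        usable = (dof > 0) & np.isfinite(var)
        if not usable.any():
            raise ObservationError(
                f"all bins in stream {key} are singletons; pooled variance "
                "undefined — supply an explicit variance")
        pv = float((dof[usable] * var[usable]).sum() / dof[usable].sum())
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["pooled_variance"] = pv
        records.append(rec)
    pv_table = pd.DataFrame(records)
    merged = stats.merge(pv_table, on=keys, how="left")
    merged["sem"] = np.sqrt(merged["pooled_variance"] / merged["n"])
    return PooledDataset(stats=merged, bin_edges=pooled.bin_edges,
                         pooled_variance=pv_table)


def normalize_pooled_to_hsc(pooled: PooledDataset) -> PooledDataset:
    """Derive HSC-normalized frequency streams at the bin level.

    For each (dataset, bin), the normalized value of a downstream compartment
    is the ratio of bin-mean labeled frequencies, ``mean_f(comp) /
    mean_f(HSC)``, and its SEM follows by error propagation from the two
    means' SEMs (per-mouse noise in different flow gates is treated as
    independent).  Normalizing the bin means rather than averaging per-mouse
    ratios avoids the upward ratio bias that noisy per-mouse HSC frequencies
    would introduce.  Requires SEMs (run :func:`pooled_variance_sem` first);
    appends ``norm_frequency`` rows, replacing any already present.
    """
    if "sem" not in pooled.stats.columns:
        raise ValueError("pooled dataset has no SEMs; run pooled_variance_sem first")
    stats = pooled.stats[pooled.stats["quantity"] != "norm_frequency"].copy()
    freq = stats[stats["quantity"] == "frequency"]
    hsc = freq[freq["compartment"] == HSC_COMPARTMENT].set_index(
        ["dataset_id", "bin_lo", "bin_hi"])
    rows = []
    for comp in NORMALIZED_COMPARTMENTS:
        sub = freq[freq["compartment"] == comp]
        for _, r in sub.iterrows():
            key = (r["dataset_id"], r["bin_lo"], r["bin_hi"])
            if key not in hsc.index:
                continue
            h = hsc.loc[key]
            if h["mean"] <= 0:
                warnings.warn(
                    f"bin {key} has zero mean HSC frequency; normalized value "
                    "skipped", stacklevel=2)
                continue
            ratio = r["mean"] / h["mean"]
            sem = ratio * np.sqrt((r["sem"] / r["mean"]) ** 2
                                  + (h["sem"] / h["mean"]) ** 2) \
                if r["mean"] > 0 else r["sem"] / h["mean"]
            rows.append({
                "dataset_id": r["dataset_id"], "compartment": comp,
                "quantity": "norm_frequency", "bin_lo": r["bin_lo"],
                "bin_hi": r["bin_hi"], "time": r["time"], "mean": ratio,
                "var": np.nan, "n": r["n"], "pooled_variance": np.nan,
                "sem": sem,
            })
    out = pd.concat([stats, pd.DataFrame(rows)], ignore_index=True)
    return PooledDataset(stats=out, bin_edges=pooled.bin_edges,
                         pooled_variance=pooled.pooled_variance)
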
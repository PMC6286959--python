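"""QC-RLSC drift correction and statistics for injection-ordered peak areas.

GC-MS batches drift: detector response changes smoothly with injection
order. Quality-control-based robust LOESS signal correction (QC-RLSC)
removes that drift per metabolite by fitting a LOESS curve to the repeated
QC injections (one pooled sample injected throughout the run) against
injection index, interpolating the curve at every injection, and dividing
each value by curve/median(QC) — so a flat QC series leaves the data
untouched and the QC median is the anchor of the corrected scale.

Downstream: log2 fold changes vs time-matched control and a cell-means
two-way ANOVA (treatment x time) with Sidak or Bonferroni posttests on
treatment-vs-control contrasts at each timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import StudyDesign

logger = logging.getLogger(__name__)

META_COLUMNS = ["injection_index", "sample_id", "is_qc"]
MIN_QC = 5


class InvalidRunError(ValueError):
    """Raised when a metabolomics run violates its structural invariants."""


@dataclass
class MetabolomicsRun:
    """Injection-ordered peak-area table.

    ``table`` columns: injection_index (strictly increasing), sample_id,
    is_qc (bool), then one column per metabolite (peak areas >= 0, NaN for
    missing). ``flags`` records per-metabolite correction notes.
    """

    table: pd.DataFrame
    flags: dict[str, str] = field(default_factory=dict)

    @property
    def metabolite_ids(self) -> list[str]:
        return [c for c in self.table.columns if c not in META_COLUMNS]

    def validate(self) -> None:
        idx = self.table["injection_index"].to_numpy()
        if not (np.diff(idx) > 0).all():
            raise InvalidRunError("injection indices must be strictly increasing")
        qc = self.table["is_qc"].to_numpy(dtype=bool)
        if qc.sum() < MIN_QC:
            raise InvalidRunError(f"need >= {MIN_QC} QC injections, got {int(qc.sum())}")
        sample_idx = idx[~qc]
        if len(sample_idx) and (idx[qc].min() > sample_idx.min() or idx[qc].max() < sample_idx.max()):
            raise InvalidRunError("QC injections must bracket the sample injections")
        areas = self.table[self.metabolite_ids].to_numpy(dtype=float)
        if np.nanmin(areas) < 0:
            raise InvalidRunError("peak areas must be >= 0")


def qc_rlsc(run: MetabolomicsRun, loess_span: float = 0.75) -> MetabolomicsRun:
    """Remove injection-order drift per metabolite using the QC series.

    For each metabolite with at least 5 usable QC measurements, a robust
    LOESS curve (degree 1) is fitted to QC area vs injection index; the
    correction factor at each injection is the curve value (clamped to the
    QC range at the ends) divided by the QC median, and every value —
    samples and QCs alike — is divided by its factor. Metabolites with
    fewer than 5 usable QCs are left uncorrected and flagged.
    """
    run.validate()
    table = run.table.copy()
    flags = dict(run.flags)
    qc_mask = table["is_qc"].to_numpy(dtype=bool)
    all_idx = table["injection_index"].to_numpy(dtype=float)
    qc_idx = all_idx[qc_mask]
    out_of_range = (all_idx < qc_idx.min()) | (all_idx > qc_idx.max())
    for met in run.metabolite_ids:
        values = table[met].to_numpy(dtype=float)
        qc_vals = values[qc_mask]
        usable = np.isfinite(qc_vals) & (qc_vals > 0)
        if usable.sum() < MIN_QC:
            flags[met] = "uncorrected: <5 usable QCs"
            logger.warning("qc_rlsc: %s left uncorrected (<5 usable QCs)", met)
            continue
        fit = lowess(qc_vals[usable], qc_idx[usable], frac=loess_span, it=3,
                     return_sorted=True)
        # np.interp clamps beyond the QC range: nearest-curve-value extrapolation
        curve = np.interp(all_idx, fit[:, 0], fit[:, 1])
        qc_median = float(np.median(qc_vals[usable]))
        factor = curve / qc_median
        if np.any(factor <= 0):
            flags[met] = "uncorrected: non-positive correction curve"
            logger.warning("qc_rlsc: %s left uncorrected (curve <= 0)", met)
            continue
        table[met] = values / factor
        if out_of_range.any():
            flags.setdefault(met, "extrapolated beyond QC range for some injections")
    return MetabolomicsRun(table=table, flags=flags)


def qc_cv(run: MetabolomicsRun) -> pd.Series:
    """Coefficient of variation (sd/mean) of the QC injections per metabolite."""
    qc = run.table.loc[run.table["is_qc"].astype(bool), run.metabolite_ids]
    return qc.std(ddof=1) / qc.mean()


def metabolite_lfc(run: MetabolomicsRun, design: StudyDesign) -> pd.DataFrame:
    """log2(mean treatment / mean time-matched control) per metabolite/cell.

    Cells with a non-positive or missing control mean yield NaN. Columns:
    metabolite, treatment, timepoint, lfc.
    """
    samples = run.table.loc[~run.table["is_qc"].astype(bool)]
    sample_map = samples.set_index("sample_id")
    rows = []
    for trt in design.test_treatments:
        for tp in design.timepoints:
            t_ids, c_ids = design.contrast(trt, tp)
            t_ids = [s for s in t_ids if s in sample_map.index]
            c_ids = [s for s in c_ids if s in sample_map.index]
            for met in run.metabolite_ids:
                tm = sample_map.loc[t_ids, met].mean() if t_ids else np.nan
                cm = sample_map.loc[c_ids, met].mean() if c_ids else np.nan
                if not np.isfinite(cm) or cm <= 0 or not np.isfinite(tm) or tm <= 0:
                    lfc = np.nan
                else:
                    lfc = float(np.log2(tm / cm))
                rows.append({"metabolite": met, "treatment": trt, "timepoint": tp, "lfc": lfc})
    return pd.DataFrame(rows)


def sidak(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak family adjustment: 1 - (1 - p)^m."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def bonferroni(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Bonferroni family adjustment: min(1, m * p)."""
    return np.minimum(1.0, m * np.asarray(p, dtype=float))


def two_way_anova_posttest(
    values: np.ndarray,
    factor_treatment: np.ndarray,
    factor_time: np.ndarray,
    method: str = "sidak",
    control: str | None = None,
) -> pd.DataFrame:
    """Cell-means two-way ANOVA with per-timepoint posttests.

    The posttest contrasts each treatment against the control at each
    timepoint using the pooled error mean square of the full layout; the
    family for adjustment is the set of timepoint comparisons of one
    treatment (m = number of timepoints). Requires a fully crossed layout
    with >= 2 non-missing replicates per cell.

    Returns one row per (treatment, timepoint) with mean_diff, p, p_adj
    and a significance flag at p_adj <= 0.05.
    """
    if method not in ("sidak", "bonferroni"):
        raise ValueError(f"unknown posttest method {method!r}")
    adjust = sidak if method == "sidak" else bonferroni
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float),
         "trt": np.asarray(factor_treatment),
         "time": np.asarray(factor_time)}
    ).dropna(subset=["y"])
    treatments = list(dict.fromkeys(np.asarray(factor_treatment)))
    timepoints = list(dict.fromkeys(np.asarray(factor_time)))
    if control is None:
        control = treatments[0]
    cells = df.groupby(["trt", "time"])["y"]
    counts = cells.size()
    for trt in treatments:
        for tp in timepoints:
            if (trt, tp) not in counts.index or counts[(trt, tp)] < 2:
                raise InvalidRunError(f"cell ({trt}, {tp}) has <2 non-missing replicates")
    cell_means = cells.mean()
    keyed = df.set_index(["trt", "time"])
    resid = keyed["y"] - keyed.index.map(cell_means)
    sse = float((resid**2).sum())
    df_err = len(df) - len(counts)
    mse = sse / df_err
    m = len(timepoints)
    rows = []
    for trt in treatments:
        if trt == control:
            continue
        for tp in timepoints:
            n1, n2 = counts[(trt, tp)], counts[(control, tp)]
            diff = cell_means[(trt, tp)] - cell_means[(control, tp)]
            if mse > 0:
                t = diff / np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
                p = float(2.0 * stats.t.sf(abs(t), df_err))
            else:
                p = 1.0 if diff == 0 else 0.0
            p_adj = float(adjust(p, m))
            rows.append(
                {"treatment": trt, "timepoint": tp, "mean_diff": float(diff),
                 "p": p, "p_adj": p_adj, "significant": p_adj <= 0.05}
            )
    return pd.DataFrame(rows)


def metabolite_posttests(
    run: MetabolomicsRun, design: StudyDesign, method: str = "sidak"
) -> pd.DataFrame:
    """two_way_anova_posttest per metabolite on log2 peak areas, stacked."""
    samples = run.table.loc[~run.table["is_qc"].astype(bool)].set_index("sample_id")
    frame = design.to_frame()
    frame = frame[frame["sample_id"].isin(samples.index)]
    frames = []
    for met in run.metabolite_ids:
        vals = samples.loc[frame["sample_id"], met].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logvals = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
        res = two_way_anova_posttest(
            logvals, frame["treatment"].to_numpy(), frame["timepoint"].to_numpy(),
            method=method, control=design.control,
        )
        res.insert(0, "metabolite", met)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
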
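"""Differential-region calling on promoter tiling arrays.

Histone-acetylation ChIP-chip and MeDIP-chip methylation tracks share one
analysis: slide a fixed-size probe window (7 probes, discarded when its
genomic span exceeds 750 bp) along each promoter, test treatment vs
time-matched control arrays by one-way ANOVA on per-array window means,
control the FDR across all windows of the contrast by Benjamini-Hochberg,
and collapse to gene level. A gene is called when any of its windows
passes; its score is the median over probes in significant windows of
(median treatment signal - median control signal), so a positive score
means hyper-acetylation/-methylation and a negative score hypo.

Probes within a window are correlated, so arrays -- not probes -- act as
the replicates in the ANOVA. With two groups F = t^2 and the p-value
equals the pooled two-sample t-test's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .expression import bh_adjust

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "gene"]


@dataclass(frozen=True)
class Window:
    """A run of consecutive probes inside one promoter."""

    gene: str
    probe_ids: tuple[str, ...]
    chrom: str
    start: int  # 1-based inclusive
    end: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class TilingTrack:
    """Ordered genomic probes with per-sample log2 signals.

    ``probes`` has columns (chrom, start, end, probe_id, gene) with 1-based
    inclusive coordinates, sorted by (chrom, start); ``signals`` is indexed
    by probe_id with one column per sample; ``promoters`` maps gene ->
    (chrom, start, end) promoter intervals (1-based inclusive).
    """

    probes: pd.DataFrame
    signals: pd.DataFrame
    promoters: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise ValueError(f"probe table lacks columns {missing}")
        sorted_probes = self.probes.sort_values(["chrom", "start"], kind="stable")
        if not (sorted_probes["probe_id"].to_numpy() == self.probes["probe_id"].to_numpy()).all():
            self.probes = sorted_probes.reset_index(drop=True)
        if not set(self.probes["probe_id"]) <= set(self.signals.index):
            raise ValueError("signals missing for some probes")

    def validate_against(self, design: StudyDesign) -> None:
        unknown = set(self.signals.columns) - set(design.sample_ids)
        if unknown:
            raise ValueError(f"signal samples not in design: {sorted(unknown)}")


def make_windows(
    track: TilingTrack,
    n_probes: int = 7,
    max_span_bp: int = 750,
    step: int = 1,
) -> list[Window]:
    """Enumerate fixed-size probe windows within each promoter.

    Every run of ``n_probes`` consecutive probes of one gene whose genomic
    span (last end - first start + 1) is at most ``max_span_bp`` yields a
    window; runs advance by ``step`` probes and never cross promoter
    boundaries. Promoters with fewer than ``n_probes`` probes yield none.
    """
    if n_probes < 2:
        raise ValueError("n_probes must be >= 2")
    windows: list[Window] = []
    for gene, grp in track.probes.groupby("gene", sort=True):
        grp = grp.sort_values("start", kind="stable")
        if len(grp) < n_probes:
            logger.info("promoter %s has %d (<%d) probes; no windows", gene, len(grp), n_probes)
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ids = grp["probe_id"].to_numpy()
        chrom = grp["chrom"].iloc[0]
        for i in range(0, len(grp) - n_probes + 1, step):
            span = ends[i + n_probes - 1] - starts[i] + 1
            if span <= max_span_bp:
                windows.append(
                    Window(
                        gene=gene,
                        probe_ids=tuple(ids[i : i + n_probes]),
                        chrom=chrom,
                        start=int(starts[i]),
                        end=int(ends[i + n_probes - 1]),
                    )
                )
    return windows


def _two_group_f(
    means_t: np.ndarray, means_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA for two groups of per-array window means.

    ``means_t``/``means_c`` have shape (n_windows, n_arrays). Returns
    (F, p, mean_diff). Degenerate windows (zero within-group variance) get
    p = 1 when the group means agree and p = 0 otherwise.
    """
    n1, n2 = means_t.shape[1], means_c.shape[1]
    m1 = means_t.mean(axis=1)
    m2 = means_c.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((means_t - m1[:, None]) ** 2).sum(axis=1) + ((means_c - m2[:, None]) ** 2).sum(axis=1)
    df1, df2 = 1, n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    zero_w = ssw == 0
    if np.any(zero_w):
        same = zero_w & (ssb == 0)
        diff = zero_w & (ssb > 0)
        f = np.where(same, 0.0, f)
        p = np.where(same, 1.0, p)
        f = np.where(diff, np.inf, f)
        p = np.where(diff, 0.0, p)
        if diff.any():
            logger.warning("%d degenerate windows: zero variance, nonzero difference", diff.sum())
    return f, p, m1 - m2


def window_anova(
    window_signals: pd.DataFrame,
    treatment_samples: Sequence[str],
    control_samples: Sequence[str],
) -> tuple[float, float, float]:
    """One-way ANOVA on per-array means of one window's probe signals.

    ``window_signals`` is probes x samples. Each array contributes the mean
    of its probe signals; treatment vs control is then a two-group ANOVA,
    identical to the pooled two-sample t-test (F = t^2).
    """
    if len(treatment_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >=2 samples per group")
    mt = window_signals[list(treatment_samples)].mean(axis=0).to_numpy()[None, :]
    mc = window_signals[list(control_samples)].mean(axis=0).to_numpy()[None, :]
    f, p, d = _two_group_f(mt, mc)
    return float(f[0]), float(p[0]), float(d[0])


def direction_by_median(
    gene_probe_signals: pd.DataFrame,
    treatment_samples: Sequence[str],
    control_samples: Sequence[str],
) -> int:
    """Sign of (median treatment value - median control value); 0 on a tie.

    Medians are taken over all (probe, array) values of each group.
    """
    if not len(treatment_samples) or not len(control_samples):
        raise ValueError("empty sample group")
    mt = float(np.median(gene_probe_signals[list(treatment_samples)].to_numpy()))
    mc = float(np.median(gene_probe_signals[list(control_samples)].to_numpy()))
    return int(np.sign(mt - mc))


def call_regions(
    track: TilingTrack,
    design: StudyDesign,
    treatment: str,
    timepoint: str,
    fdr_threshold: float = 0.01,
    n_probes: int = 7,
    max_span_bp: int = 750,
    layer: str = "HA",
    windows: list[Window] | None = None,
) -> pd.DataFrame:
    """Call differentially modified genes for one contrast.

    BH runs across all window p-values of the contrast jointly; a gene is
    emitted when at least one of its windows has FDR below the threshold.
    Columns: gene, layer, treatment, timepoint, direction, score,
    best_window_p, fdr. Genes whose score ties at exactly 0 carry no
    direction and are dropped (they cannot enter hyper/hypo counts).
    """
    t_samples, c_samples = design.contrast(treatment, timepoint)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("need >=2 arrays per group")
    if windows is None:
        windows = make_windows(track, n_probes=n_probes, max_span_bp=max_span_bp)
    empty = pd.DataFrame(
        columns=["gene", "layer", "treatment", "timepoint", "direction", "score",
                 "best_window_p", "fdr"]
    )
    if not windows:
        logger.warning("no windows for contrast %s@%s", treatment, timepoint)
        return empty

    sig = track.signals
    pos = {p: i for i, p in enumerate(sig.index)}
    idx = np.array([[pos[p] for p in w.probe_ids] for w in windows])
    xt = sig[t_samples].to_numpy(dtype=float)
    xc = sig[c_samples].to_numpy(dtype=float)
    means_t = xt[idx].mean(axis=1)  # (n_windows, n_arrays)
    means_c = xc[idx].mean(axis=1)
    _, p, _ = _two_group_f(means_t, means_c)
    fdr = bh_adjust(p)

    passing = fdr < fdr_threshold
    if not passing.any():
        return empty
    rows = []
    win_genes = np.array([w.gene for w in windows])
    med_t = np.median(xt, axis=1)  # per-probe medians across arrays
    med_c = np.median(xc, axis=1)
    probe_diff = med_t - med_c
    for gene in np.unique(win_genes[passing]):
        mask = passing & (win_genes == gene)
        gene_probe_idx = np.unique(idx[mask])
        score = float(np.median(probe_diff[gene_probe_idx]))
        direction = int(np.sign(score))
        if direction == 0:
            logger.info("gene %s: zero score at %s@%s; no direction", gene, treatment, timepoint)
            continue
        gmask = win_genes == gene
        rows.append(
            {
                "gene": gene,
                "layer": layer,
                "treatment": treatment,
                "timepoint": timepoint,
                "direction": direction,
                "score": score,
                "best_window_p": float(p[gmask].min()),
                "fdr": float(fdr[mask].min()),
            }
        )
    return pd.DataFrame(rows) if rows else empty


def call_all_contrasts(
    track: TilingTrack,
    design: StudyDesign,
    fdr_threshold: float = 0.01,
    n_probes: int = 7,
    max_span_bp: int = 750,
    layer: str = "HA",
) -> pd.DataFrame:
    """call_regions for every (test treatment, timepoint), stacked."""
    windows = make_windows(track, n_probes=n_probes, max_span_bp=max_span_bp)
    frames = [
        call_regions(
            track, design, trt, tp, fdr_threshold=fdr_threshold,
            n_probes=n_probes, max_span_bp=max_span_bp, layer=layer, windows=windows,
        )
        for trt in design.test_treatments
        for tp in design.timepoints
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["gene", "layer", "treatment", "timepoint", "direction", "score",
                     "best_window_p", "fdr"]
        )
    return pd.concat(frames, ignore_index=True)
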
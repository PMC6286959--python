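"""Cross-omics integration: impact counts, epigenome-transcriptome
coupling, post-washout persistence, concordance, and pathway ranking.

All operations consume the flat call tables produced by the expression
and tiling modules (one row per feature per contrast) and work at gene
level. The headline statistics:

* impact counts — how many features each endpoint calls up/down (or
  hyper/hypo) per treatment and timepoint;
* Spearman rank correlation between gene-expression LFC and the
  epigenetic region score among genes carrying both calls at a timepoint;
* persistence — the share of recovery-phase (R3) epigenetic calls that
  were already present with the same direction on the last treatment day
  (T5), computed per direction;
* concordance — among genes with a persistent histone mark and a
  significantly altered mRNA at R3 (|LFC| >= 0.58), whether the mark's
  direction matches the expression direction (up/HA+ or down/HA-);
* pathway ranking — average treatment-phase LFC per gene, gated on
  significant modulation by the positive-control compound.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Default per-endpoint significance rules for impact counting: mRNA at
#: p < 0.001 (no fold-change floor), miRNA at p < 0.05, tiling layers at
#: windowed FDR < 0.01 (already enforced by the region caller).
COUNT_CUTOFFS = {"mRNA": ("p", 1e-3), "miRNA": ("p", 0.05)}


def significance_stars(p: float) -> str:
    """Conventional alpha stars: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def impact_counts(
    de_calls: pd.DataFrame | None = None,
    region_calls: pd.DataFrame | None = None,
    mirna_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Count significant features per (endpoint, treatment, timepoint, direction).

    Expression-type tables are filtered by the endpoint's preset cutoff
    (mRNA p<0.001; miRNA p<0.05); region tables arrive pre-thresholded at
    windowed FDR<0.01 and are counted as-is. Directions +1/-1 partition
    each cell's total. Region tables may mix layers (HA, DM); each layer is
    its own endpoint.
    """
    pieces = []

    def _count(table: pd.DataFrame, endpoint: str) -> None:
        if table is None or not len(table):
            return
        tab = table.copy()
        if endpoint in COUNT_CUTOFFS:
            col, cutoff = COUNT_CUTOFFS[endpoint]
            tab = tab[tab[col] < cutoff]
        tab = tab[tab["direction"] != 0]
        grouped = (
            tab.groupby(["treatment", "timepoint", "direction"], sort=True)
            .size()
            .reset_index(name="n")
        )
        grouped.insert(0, "endpoint", endpoint)
        pieces.append(grouped)

    _count(de_calls, "mRNA")
    _count(mirna_calls, "miRNA")
    if region_calls is not None and len(region_calls):
        designs = region_calls.groupby("layer")
        for layer, tab in designs:
            _count(tab, str(layer))
    if not pieces:
        return pd.DataFrame(columns=["endpoint", "treatment", "timepoint", "direction", "n"])
    return pd.concat(pieces, ignore_index=True)


def build_records(
    ge_calls: pd.DataFrame,
    ha_calls: pd.DataFrame | None = None,
    dm_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge GE diff calls with HA/DM region calls per (gene, treatment, timepoint).

    GE tables must carry a ``feature`` (or ``gene``) column; epigenetic
    direction/score columns are NaN/0 where no region call exists.
    """
    ge = ge_calls.copy()
    if "gene" not in ge.columns:
        ge = ge.rename(columns={"feature": "gene"})
    out = ge[["gene", "treatment", "timepoint", "lfc", "p", "fdr", "direction"]].rename(
        columns={"lfc": "ge_lfc", "p": "ge_p", "fdr": "ge_fdr", "direction": "ge_direction"}
    )
    for calls, tag in ((ha_calls, "ha"), (dm_calls, "dm")):
        if calls is None or not len(calls):
            out[f"{tag}_direction"] = np.nan
            out[f"{tag}_score"] = np.nan
            continue
        sub = calls[["gene", "treatment", "timepoint", "direction", "score"]].rename(
            columns={"direction": f"{tag}_direction", "score": f"{tag}_score"}
        )
        out = out.merge(sub, on=["gene", "treatment", "timepoint"], how="left")
    return out


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(ry)))
    n = len(x)
    # Spearman as Pearson on ranks, vectorised over all permutations
    rx_c = rx - rx.mean()
    perms_c = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (perms_c**2).sum(axis=1))
    rhos = (perms_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def correlate_epi_ge(
    records: pd.DataFrame,
    layer: str,
    treatment: str,
    timepoint: str,
    min_n: int = 4,
    use: str = "score",
    ge_significant_only: bool = True,
    ge_p_cutoff: float = 1e-3,
) -> dict | None:
    """Spearman correlation of GE LFC with an epigenetic layer's score.

    The gene set is genes with both a differential-expression call (p
    below ``ge_p_cutoff`` unless ``ge_significant_only`` is off) and an
    epigenetic region call at the (treatment, timepoint). ``use`` selects
    the epigenetic variable: the signed region ``score`` (default) or the
    bare ``direction``. Returns {rho, p, n, stars} or None when fewer
    than ``min_n`` genes qualify; the p-value is exact (full permutation)
    for n <= 9 and the t-approximation otherwise.
    """
    tag = layer.lower()
    sub = records[(records["treatment"] == treatment) & (records["timepoint"] == timepoint)]
    sub = sub[sub[f"{tag}_direction"].notna()]
    if ge_significant_only:
        sub = sub[sub["ge_p"] < ge_p_cutoff]
    n = len(sub)
    if n < min_n:
        logger.info("correlate_epi_ge: only %d genes for %s/%s@%s", n, layer, treatment, timepoint)
        return None
    x = sub["ge_lfc"].to_numpy(dtype=float)
    y = sub[f"{tag}_{'score' if use == 'score' else 'direction'}"].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if n <= 9:
        p = _exact_spearman_p(x, y, rho)
    return {"rho": rho, "p": float(p), "n": n, "stars": significance_stars(float(p))}


def persistence(
    calls_t5: pd.DataFrame, calls_r3: pd.DataFrame, layer: str | None = None,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Per-direction persistence of epigenetic calls from T5 into R3.

    For each direction d: n_R3 = number of R3 calls with direction d,
    n_persistent = those whose gene already had direction d at T5, and
    pct_persistent = 100 * n_persistent / n_R3 (0 when n_R3 = 0). n_T5 is
    reported alongside so the forward rate (persistent / T5 calls) is also
    available.
    """
    def _dirs(calls: pd.DataFrame) -> dict[str, int]:
        if calls is None or not len(calls):
            return {}
        return dict(zip(calls["gene"], calls["direction"].astype(int)))

    t5 = _dirs(calls_t5)
    r3 = _dirs(calls_r3)
    rows = []
    for d, label in ((1, "hyper"), (-1, "hypo")):
        r3_genes = {g for g, v in r3.items() if v == d}
        persistent = sorted(g for g in r3_genes if t5.get(g) == d)
        n_r3 = len(r3_genes)
        n_t5 = sum(1 for v in t5.values() if v == d)
        rows.append(
            {"layer": layer, "treatment": treatment, "direction": label,
             "n_T5": n_t5, "n_R3": n_r3, "n_persistent": len(persistent),
             "pct_persistent": 100.0 * len(persistent) / n_r3 if n_r3 else 0.0,
             "persistent_genes": ",".join(persistent)}
        )
    return pd.DataFrame(rows)


def persistent_gene_set(calls_t5: pd.DataFrame, calls_r3: pd.DataFrame) -> pd.DataFrame:
    """Genes called at both T5 and R3 with the same direction."""
    merged = calls_t5.merge(calls_r3, on="gene", suffixes=("_t5", "_r3"))
    merged = merged[merged["direction_t5"] == merged["direction_r3"]]
    return merged[["gene", "direction_r3"]].rename(columns={"direction_r3": "direction"})


def concordance(
    persistent_ha: pd.DataFrame,
    ge_calls_r3: pd.DataFrame,
    lfc_cutoff: float = 0.58,
    p_cutoff: float = 1e-3,
) -> pd.DataFrame:
    """Label persistent-HA genes by agreement with their R3 expression.

    The gene set is persistent-HA genes whose R3 mRNA is significant
    (p < p_cutoff) with |LFC| >= lfc_cutoff (about 1.5-fold). A gene is
    consistent when sign(ge_lfc) equals the HA direction (up-regulated
    with hyper-acetylation or down-regulated with hypo-acetylation) and
    inconsistent otherwise; consistent + inconsistent = total.
    """
    ge = ge_calls_r3.copy()
    if "gene" not in ge.columns:
        ge = ge.rename(columns={"feature": "gene"})
    ge = ge[(ge["p"] < p_cutoff) & (ge["lfc"].abs() >= lfc_cutoff)]
    merged = persistent_ha[["gene", "direction"]].merge(
        ge[["gene", "lfc", "p"]], on="gene", how="inner"
    )
    merged = merged.rename(columns={"direction": "ha_direction", "lfc": "ge_lfc", "p": "ge_p"})
    merged["consistent"] = np.sign(merged["ge_lfc"]).astype(int) == merged["ha_direction"].astype(int)
    return merged.reset_index(drop=True)


def concordance_summary(table: pd.DataFrame) -> dict[str, int]:
    total = len(table)
    consistent = int(table["consistent"].sum()) if total else 0
    return {"total": total, "consistent": consistent, "inconsistent": total - consistent}


def rank_pathway(
    diff_calls: pd.DataFrame,
    pathway_genes: Sequence[str],
    positive_control: str,
    test_treatment: str,
    treatment_timepoints: Sequence[str] = ("T1", "T3", "T5"),
    p_cutoff: float = 1e-3,
) -> pd.DataFrame:
    """Rank pathway genes by average treatment-phase LFC of the test compound.

    Genes never significantly modulated by the positive control at any
    treatment timepoint are removed; the survivors are sorted descending
    by the test treatment's average LFC over those timepoints. Pathway
    genes absent from the calls are retained with missing values and
    flagged (``in_data`` = False).
    """
    if not len(pathway_genes):
        raise ValueError("pathway gene list is empty")
    calls = diff_calls.copy()
    if "gene" not in calls.columns:
        calls = calls.rename(columns={"feature": "gene"})
    calls = calls[calls["timepoint"].isin(treatment_timepoints)]
    rows = []
    for gene in pathway_genes:
        sub = calls[calls["gene"] == gene]
        if not len(sub):
            logger.warning("rank_pathway: %s absent from calls", gene)
            rows.append({"gene": gene, "in_data": False, "gated_out": False,
                         "avg_lfc_control": np.nan, "avg_lfc_test": np.nan})
            continue
        pc = sub[sub["treatment"] == positive_control]
        tt = sub[sub["treatment"] == test_treatment]
        gated_out = not (pc["p"] < p_cutoff).any()
        row = {"gene": gene, "in_data": True, "gated_out": gated_out,
               "avg_lfc_control": pc["lfc"].mean() if len(pc) else np.nan,
               "avg_lfc_test": tt["lfc"].mean() if len(tt) else np.nan}
        for tp in treatment_timepoints:
            v = tt[tt["timepoint"] == tp]["lfc"]
            row[f"lfc_{tp}"] = float(v.iloc[0]) if len(v) else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    retained = table[table["in_data"] & ~table["gated_out"]].sort_values(
        "avg_lfc_test", ascending=False, kind="stable"
    )
    flagged = table[~table["in_data"]]
    return pd.concat([retained, flagged], ignore_index=True)


def mirna_overlap(
    mirna_calls: pd.DataFrame,
    reference: tuple[str, str],
    other_treatment: str,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Cross-treatment profile of miRNAs significant in a reference condition.

    For every miRNA significant (FDR < cutoff) in the reference
    (treatment, timepoint), report its LFC and significance across the
    other treatment's timepoints; ``shared`` marks timepoints where the
    miRNA is significant under both compounds.
    """
    calls = mirna_calls.copy()
    if "gene" not in calls.columns and "feature" in calls.columns:
        calls = calls.rename(columns={"feature": "gene"})
    ref_trt, ref_tp = reference
    ref = calls[(calls["treatment"] == ref_trt) & (calls["timepoint"] == ref_tp)
                & (calls["fdr"] < fdr_cutoff)]
    rows = []
    for _, r in ref.iterrows():
        sub = calls[(calls["gene"] == r["gene"]) & (calls["treatment"] == other_treatment)]
        for _, o in sub.iterrows():
            rows.append(
                {"mirna": r["gene"], "reference_treatment": ref_trt,
                 "reference_timepoint": ref_tp, "reference_lfc": r["lfc"],
                 "other_treatment": other_treatment, "timepoint": o["timepoint"],
                 "lfc": o["lfc"], "fdr": o["fdr"], "shared": bool(o["fdr"] < fdr_cutoff)}
            )
    return pd.DataFrame(
        rows, columns=["mirna", "reference_treatment", "reference_timepoint",
                       "reference_lfc", "other_treatment", "timepoint", "lfc", "fdr", "shared"]
    )
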
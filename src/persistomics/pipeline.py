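"""End-to-end orchestration: configuration, the full synthetic run, a
Markdown report, and plain-text format validation.

`run_all` goes from a config (currently: a synthetic block plus per-layer
cutoffs) to the final integrated report, writing every intermediate table
as TSV plus a provenance manifest (config hash, seeds, package version)
sufficient to reproduce the run byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .design import generate_design
from .expression import call_de, diff_all_contrasts
from .integration import (build_records, concordance, concordance_summary,
                          correlate_epi_ge, impact_counts, mirna_overlap,
                          persistence, persistent_gene_set, rank_pathway)
from .metabolomics import metabolite_lfc, metabolite_posttests, qc_cv, qc_rlsc
from .synthetic import (simulate_expression, simulate_metabolomics,
                        simulate_tiling, uniform_magnitudes)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; round-trips through YAML/JSON."""

    # design
    n_treatments: int = 3
    timepoints: tuple[str, ...] = ("T1", "T3", "T5", "R3")
    n_replicates: int = 3
    seed: int = 0
    # synthetic block
    n_genes: int = 300
    de_fraction: float = 0.3
    effect_size: float = 1.5
    effect_dist: str = "uniform"  # "constant" or "uniform" (continuous magnitudes)
    d0: float = 4.0
    s0_sq: float = 0.03
    n_mirnas: int = 60
    mirna_de_fraction: float = 0.15
    tiling_genes: int = 120
    region_fraction: float = 0.4
    tiling_effect_size: float = 1.0
    persistence_fraction: float = 0.3
    coupling_rho: float = 0.75
    tiling_noise_sd: float = 0.2
    n_metabolites: int = 30
    drift_amplitude: float = 0.3
    qc_every: int = 10
    # cutoffs (published defaults)
    mrna_p_cutoff: float = 1e-3
    mirna_fdr_cutoff: float = 0.05
    tiling_fdr: float = 0.01
    concordance_lfc: float = 0.58
    window_probes: int = 7
    window_span_bp: int = 750
    loess_span: float = 0.75
    posttest: str = "sidak"
    positive_control: str = "KBrO3"
    test_treatment: str = "OTA"
    pathway_files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mrna_p_cutoff", "mirna_fdr_cutoff", "tiling_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        self.timepoints = tuple(self.timepoints)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Synthetic data -> differential calls -> integration -> report.

    Writes every intermediate TSV, a run manifest, and ``report.md`` to
    ``out_dir``; returns a summary dict with the headline numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("simulate")
        design = generate_design(cfg.n_treatments, cfg.timepoints, cfg.n_replicates,
                                 seed=cfg.seed)
        io.write_design(design, out / "design.tsv")
        if cfg.effect_dist == "constant":
            effect = cfg.effect_size
        elif cfg.effect_dist == "uniform":
            effect = uniform_magnitudes(0.5 * cfg.effect_size, 1.5 * cfg.effect_size)
        else:
            raise ValueError(f"unknown effect_dist {cfg.effect_dist!r}")
        expr, ge_truth = simulate_expression(
            design, cfg.n_genes, cfg.de_fraction, effect,
            cfg.d0, cfg.s0_sq, seed=cfg.seed,
        )
        mirna, mirna_truth = simulate_expression(
            design, cfg.n_mirnas, cfg.mirna_de_fraction, effect,
            cfg.d0, cfg.s0_sq, seed=cfg.seed + 1, feature_prefix="mir",
        )
        ha_track, ha_truth = simulate_tiling(
            design, n_genes=cfg.tiling_genes, region_fraction=cfg.region_fraction,
            effect_size=cfg.tiling_effect_size,
            persistence_fraction=cfg.persistence_fraction,
            coupling_rho=cfg.coupling_rho, ge_truth=ge_truth,
            noise_sd=cfg.tiling_noise_sd, layer="HA", seed=cfg.seed + 2,
        )
        dm_track, dm_truth = simulate_tiling(
            design, n_genes=cfg.tiling_genes, region_fraction=cfg.region_fraction / 2,
            effect_size=cfg.tiling_effect_size,
            persistence_fraction=cfg.persistence_fraction,
            coupling_rho=0.0, ge_truth=None,
            noise_sd=cfg.tiling_noise_sd, layer="DM", seed=cfg.seed + 3,
        )
        run, metab_truth = simulate_metabolomics(
            design, cfg.n_metabolites, cfg.drift_amplitude, cfg.qc_every,
            seed=cfg.seed + 4,
        )
        io.write_matrix(expr, out / "expression.tsv")
        io.write_matrix(mirna, out / "mirna.tsv")
        io.write_track(ha_track, out / "ha_probes.gff3", out / "ha_signals.tsv",
                       out / "ha_promoters.bed")
        io.write_track(dm_track, out / "dm_probes.gff3", out / "dm_signals.tsv",
                       out / "dm_promoters.bed")
        io.write_run_csv(run, out / "metabolomics_run.csv")
        truth = ge_truth.merged_with(ha_truth).merged_with(dm_truth).merged_with(metab_truth)
        io.write_truth(truth, out / "truth.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", str(exc)) from exc

    try:
        _stage("diff-expr")
        ge_calls = diff_all_contrasts(expr, design)
        mirna_calls = diff_all_contrasts(mirna, design)
        io.write_calls(ge_calls, out / "ge_calls.tsv")
        io.write_calls(mirna_calls, out / "mirna_calls.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("diff-expr", str(exc)) from exc

    try:
        _stage("diff-tiling")
        from .tiling import call_all_contrasts

        ha_calls = call_all_contrasts(ha_track, design, fdr_threshold=cfg.tiling_fdr,
                                      n_probes=cfg.window_probes,
                                      max_span_bp=cfg.window_span_bp, layer="HA")
        dm_calls = call_all_contrasts(dm_track, design, fdr_threshold=cfg.tiling_fdr,
                                      n_probes=cfg.window_probes,
                                      max_span_bp=cfg.window_span_bp, layer="DM")
        io.write_calls(ha_calls, out / "ha_calls.tsv")
        io.write_calls(dm_calls, out / "dm_calls.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("diff-tiling", str(exc)) from exc

    try:
        _stage("metab")
        cv_before = qc_cv(run)
        corrected = qc_rlsc(run, loess_span=cfg.loess_span)
        cv_after = qc_cv(corrected)
        io.write_run_csv(corrected, out / "metabolomics_corrected.csv")
        lfc_table = metabolite_lfc(corrected, design)
        posttests = metabolite_posttests(corrected, design, method=cfg.posttest)
        fig7 = lfc_table.merge(posttests[["metabolite", "treatment", "timepoint",
                                          "p_adj", "significant"]],
                               on=["metabolite", "treatment", "timepoint"], how="left")
        io.write_calls(lfc_table, out / "metabolite_lfc.tsv")
        io.write_calls(fig7, out / "metabolite_summary.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("metab", str(exc)) from exc

    try:
        _stage("integrate")
        counts = impact_counts(ge_calls, pd.concat([ha_calls, dm_calls], ignore_index=True)
                               if len(ha_calls) or len(dm_calls) else None, mirna_calls)
        io.write_calls(counts, out / "impact_counts.tsv")
        records = build_records(ge_calls, ha_calls, dm_calls)
        io.write_calls(records, out / "integration_records.tsv")

        corr_rows = []
        for layer in ("HA", "DM"):
            for trt in design.test_treatments:
                for tp in design.timepoints:
                    res = correlate_epi_ge(records, layer, trt, tp,
                                           ge_p_cutoff=cfg.mrna_p_cutoff)
                    if res is not None:
                        corr_rows.append({"layer": layer, "treatment": trt,
                                          "timepoint": tp, **res})
        corr_table = pd.DataFrame(corr_rows)
        io.write_calls(corr_table, out / "epi_ge_correlation.tsv")

        pers_frames, conc_frames = [], []
        for layer, calls in (("HA", ha_calls), ("DM", dm_calls)):
            for trt in design.test_treatments:
                t5 = calls[(calls["treatment"] == trt) & (calls["timepoint"] == "T5")]
                r3 = calls[(calls["treatment"] == trt) & (calls["timepoint"] == "R3")]
                pers_frames.append(persistence(t5, r3, layer=layer, treatment=trt))
                if layer == "HA":
                    pers_set = persistent_gene_set(t5, r3)
                    ge_r3 = ge_calls[(ge_calls["treatment"] == trt)
                                     & (ge_calls["timepoint"] == "R3")]
                    conc = concordance(pers_set, ge_r3, lfc_cutoff=cfg.concordance_lfc,
                                       p_cutoff=cfg.mrna_p_cutoff)
                    conc.insert(0, "treatment", trt)
                    conc_frames.append(conc)
        pers_table = pd.concat(pers_frames, ignore_index=True)
        conc_table = (pd.concat(conc_frames, ignore_index=True) if conc_frames
                      else pd.DataFrame())
        io.write_calls(pers_table, out / "persistence.tsv")
        io.write_calls(conc_table, out / "concordance.tsv")

        pathway_tables = {}
        for name, path in cfg.pathway_files.items():
            ranking = rank_pathway(ge_calls, io.read_gene_list(path),
                                   cfg.positive_control, cfg.test_treatment,
                                   p_cutoff=cfg.mrna_p_cutoff)
            io.write_calls(ranking, out / f"pathway_{name}.tsv")
            pathway_tables[name] = ranking

        overlap = mirna_overlap(mirna_calls, (cfg.positive_control, "T5"),
                                cfg.test_treatment, fdr_cutoff=cfg.mirna_fdr_cutoff)
        io.write_calls(overlap, out / "mirna_overlap.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("integrate", str(exc)) from exc

    summary = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "n_ge_calls_significant": int((ge_calls["p"] < cfg.mrna_p_cutoff).sum()),
        "n_ha_calls": int(len(ha_calls)),
        "n_dm_calls": int(len(dm_calls)),
        "qc_cv_before_median": float(cv_before.median()),
        "qc_cv_after_median": float(cv_after.median()),
        "concordance": concordance_summary(conc_table) if len(conc_table) else
        {"total": 0, "consistent": 0, "inconsistent": 0},
    }
    _write_manifest(cfg, out, summary)
    _write_report(out, counts, corr_table, pers_table, conc_table, summary)
    return summary


def _write_manifest(cfg: PipelineConfig, out: Path, summary: dict) -> None:
    manifest = {"package": "persistomics", "version": __version__,
                "config": cfg.to_dict(), "config_hash": cfg.digest(),
                "summary": summary}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _fmt_table(df: pd.DataFrame) -> str:
    if not len(df):
        return "(empty)\n"
    return "```\n" + df.to_string(index=False, float_format=lambda v: f"{v:.3f}") + "\n```\n"


def _write_report(out: Path, counts, corr, pers, conc, summary) -> None:
    lines = ["# Integrated multi-omics report", ""]
    lines += ["## Impact counts (features per endpoint/condition/direction)", "",
              _fmt_table(counts)]
    lines += ["## Epigenome-transcriptome Spearman correlation", "", _fmt_table(corr)]
    lines += ["## Post-washout persistence (T5 -> R3)", "",
              _fmt_table(pers.drop(columns=["persistent_genes"], errors="ignore"))]
    lines += ["## Persistent-mark / expression concordance", ""]
    cs = summary["concordance"]
    lines += [f"{cs['total']} genes: {cs['consistent']} consistent, "
              f"{cs['inconsistent']} inconsistent", ""]
    lines += ["## Provenance", "",
              f"config hash `{summary['config_hash']}`, seed {summary['seed']}", ""]
    (out / "report.md").write_text("\n".join(lines))


def validate_formats(paths: dict[str, str | Path]) -> list[dict]:
    """Validate pipeline input files; returns per-file pass/fail entries.

    Keys select the check: gff3 (1-based, start<=end), bed (0-based
    half-open, start<end), matrix+design (sample agreement), run_csv
    (strictly increasing injection order). Unreadable files fail without
    raising.
    """
    results = []

    def _entry(path, ok, messages):
        results.append({"path": str(path), "ok": ok, "messages": messages})

    for kind, path in paths.items():
        msgs: list[str] = []
        try:
            if kind.startswith("gff3"):
                with open(path) as fh:
                    for i, line in enumerate(fh, 1):
                        if line.startswith("#") or not line.strip():
                            continue
                        f = line.rstrip("\n").split("\t")
                        if len(f) != 9:
                            msgs.append(f"line {i}: expected 9 columns, got {len(f)}")
                            continue
                        start, end = int(f[3]), int(f[4])
                        if start < 1:
                            msgs.append(f"line {i}: GFF3 start must be >= 1")
                        if end < start:
                            msgs.append(f"line {i}: end < start")
            elif kind.startswith("bed"):
                with open(path) as fh:
                    for i, line in enumerate(fh, 1):
                        if not line.strip() or line.startswith(("#", "track")):
                            continue
                        f = line.rstrip("\n").split("\t")
                        start, end = int(f[1]), int(f[2])
                        if start < 0:
                            msgs.append(f"line {i}: BED start must be >= 0")
                        if end <= start:
                            msgs.append(f"line {i}: BED end must exceed start")
            elif kind.startswith("run_csv"):
                run = io.read_run_csv(path)
                idx = run.table["injection_index"].to_numpy()
                bad = np.where(np.diff(idx) <= 0)[0]
                for b in bad:
                    msgs.append(f"row {b + 2}: injection_index not increasing")
            elif kind.startswith("matrix"):
                matrix = io.read_matrix(path)
                design_path = paths.get("design")
                if design_path:
                    design = io.read_design(design_path)
                    unknown = set(matrix.columns) - set(design.sample_ids)
                    for s in sorted(unknown):
                        msgs.append(f"sample {s!r} absent from design")
            elif kind.startswith("design"):
                io.read_design(path)
            else:
                msgs.append(f"unknown validation kind {kind!r}")
        except Exception as exc:  # noqa: BLE001
            msgs.append(f"unreadable: {exc}")
        _entry(path, not msgs, msgs)
    return results
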
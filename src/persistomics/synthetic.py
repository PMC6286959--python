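"""Synthetic multi-omics data with planted ground truth.

Every layer of the repeat-dose/recovery study is emulated with known
truth so the full pipeline is testable without any array download:

* expression (mRNA or miRNA): gene-wise variances drawn from a scaled
  inverse-chi-square prior (the moderated-t noise model), planted signed
  log2 fold changes in the test-treatment cells;
* promoter tiling tracks (HA/DM): contiguous hyper/hypo probe regions
  planted per gene and timepoint, with a tunable T5->R3 persistence
  fraction and a Gaussian-copula rank coupling between planted HA effect
  sizes and planted expression LFCs (target Spearman rho);
* GC-MS peak areas: multiplicative smooth injection-order drift applied
  to samples and interleaved QC injections alike, log-normal noise.

All generators take an explicit seed and are bit-deterministic; every
planted effect is recorded in :class:`SimTruth` before noise is added.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .metabolomics import MetabolomicsRun, InvalidRunError, MIN_QC
from .tiling import TilingTrack

logger = logging.getLogger(__name__)


@dataclass
class SimTruth:
    """Ground-truth bookkeeping for a simulated study.

    ``de_genes``: gene -> {timepoint: signed LFC}.
    ``epi_regions``: gene -> layer -> {timepoint: {direction, effect, start, end}}.
    ``persistence_set``: genes whose T5 epigenetic region persists at R3.
    ``coupling_rho``: target Spearman rho between planted HA effects and GE LFCs.
    ``drift``: metabolite -> drift description; ``metabolite_lfc``: planted fold changes.
    """

    seed: int
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    epi_regions: dict[str, dict[str, dict[str, dict]]] = field(default_factory=dict)
    persistence_set: list[str] = field(default_factory=list)
    coupling_rho: float | None = None
    drift: dict[str, dict] = field(default_factory=dict)
    metabolite_lfc: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "de_genes": self.de_genes,
                "epi_regions": self.epi_regions,
                "persistence_set": self.persistence_set,
                "coupling_rho": self.coupling_rho,
                "drift": self.drift,
                "metabolite_lfc": self.metabolite_lfc,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            de_genes=d.get("de_genes", {}),
            epi_regions=d.get("epi_regions", {}),
            persistence_set=d.get("persistence_set", []),
            coupling_rho=d.get("coupling_rho"),
            drift=d.get("drift", {}),
            metabolite_lfc=d.get("metabolite_lfc", {}),
        )

    def merged_with(self, other: "SimTruth") -> "SimTruth":
        out = SimTruth(seed=self.seed)
        out.de_genes = {**self.de_genes, **other.de_genes}
        for gene, layers in list(self.epi_regions.items()) + list(other.epi_regions.items()):
            out.epi_regions.setdefault(gene, {}).update(layers)
        out.persistence_set = sorted(set(self.persistence_set) | set(other.persistence_set))
        out.coupling_rho = other.coupling_rho if other.coupling_rho is not None else self.coupling_rho
        out.drift = {**self.drift, **other.drift}
        out.metabolite_lfc = {**self.metabolite_lfc, **other.metabolite_lfc}
        return out


def uniform_magnitudes(lo: float = 0.5, hi: float = 2.5) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Continuous effect-magnitude distribution for planted DE genes.

    Constant planted magnitudes make the LFC marginal two-valued, which
    ties all ranks within a sign group and caps any attainable Spearman
    coupling; a continuous spread is required whenever rank coupling to
    the epigenetic layer is under study.
    """

    def draw(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(lo, hi, n)

    return draw


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(
    design: StudyDesign,
    n_genes: int = 2000,
    de_fraction: float = 0.1,
    effect_size: float | Callable[[np.random.Generator, int], np.ndarray] = 1.0,
    d0: float = 4.0,
    s0_sq: float = 0.03,
    seed: int = 0,
    timepoints: tuple[str, ...] | None = None,
    feature_prefix: str = "g",
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a gene-level log2 expression matrix with planted DE genes.

    Gene variances follow a scaled inverse-chi-square(d0, s0_sq) prior;
    baselines are uniform on [6, 12] log2 units. A fraction ``de_fraction``
    of genes receive a signed LFC (magnitude ``effect_size`` or drawn from
    a callable) in every test-treatment cell at the planted timepoints
    (all four by default, emulating effects that persist through washout).
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if d0 <= 0 or s0_sq <= 0:
        raise ValueError("d0 and s0_sq must be positive")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes, feature_prefix)
    if timepoints is None:
        timepoints = design.timepoints
    s2 = d0 * s0_sq / rng.chisquare(d0, n_genes)
    baseline = rng.uniform(6.0, 12.0, n_genes)

    n_de = math.floor(n_genes * de_fraction)
    if de_fraction > 0 and n_de < 1:
        warnings.warn("n_genes * de_fraction < 1; planting zero DE genes", stacklevel=2)
    truth = SimTruth(seed=seed)
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    if callable(effect_size):
        magnitudes = np.asarray(effect_size(rng, n_de), dtype=float)
    else:
        magnitudes = np.full(n_de, float(effect_size))
    lfc_by_gene = np.zeros(n_genes)
    for i, g_idx in enumerate(de_idx):
        lfc = float(signs[i] * magnitudes[i])
        lfc_by_gene[g_idx] = lfc
        truth.de_genes[genes[g_idx]] = {tp: lfc for tp in timepoints}

    data = np.empty((n_genes, len(design.samples)))
    sd = np.sqrt(s2)
    for j, sample in enumerate(design.samples):
        shift = np.zeros(n_genes)
        if sample.treatment != design.control and sample.timepoint in timepoints:
            shift = lfc_by_gene
        data[:, j] = baseline + shift + rng.normal(0.0, sd)
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="feature"),
                          columns=design.sample_ids)
    return matrix, truth


def _monotone_effect(z: np.ndarray, effect_size: float) -> np.ndarray:
    """Strictly increasing map from copula scores to detectable effects.

    sign(z) * (0.6 + 1.4 * (2*Phi(|z|) - 1)) * effect_size: order-preserving
    in z (so Spearman correlations with z are untouched) with magnitudes in
    [0.6, 2.0] * effect_size — bounded away from zero so every planted
    region is detectable, yet spread widely enough that measurement noise
    on recovered scores cannot scramble the within-sign rank order.
    """
    mag = (0.6 + 1.4 * (2.0 * stats.norm.cdf(np.abs(z)) - 1.0)) * effect_size
    return np.where(z >= 0, mag, -mag)


def simulate_tiling(
    design: StudyDesign,
    n_genes: int = 200,
    probes_per_promoter: int = 20,
    probe_spacing_bp: int = 100,
    probe_length_bp: int = 50,
    region_fraction: float = 0.3,
    effect_size: float = 1.0,
    persistence_fraction: float = 0.3,
    coupling_rho: float = 0.0,
    ge_truth: SimTruth | None = None,
    noise_sd: float = 0.2,
    layer: str = "HA",
    region_probes: int = 10,
    seed: int = 0,
) -> tuple[TilingTrack, SimTruth]:
    """Simulate a promoter tiling track with planted hyper/hypo regions.

    Each gene gets one promoter of ``probes_per_promoter`` probes at
    ``probe_spacing_bp`` spacing (defaults span 1.95 kb, comparable to
    deluxe promoter tiling density). A fraction ``region_fraction`` of
    genes carry a contiguous ``region_probes``-probe region shifted by a
    signed effect in every test-treatment array at the treatment
    timepoints; exactly floor(persistence_fraction * n_region) of those
    genes keep the same-direction region at the recovery timepoints.

    When ``ge_truth`` is given, region genes are drawn preferentially from
    its DE genes and their signed effects are rank-coupled to the planted
    GE LFCs through a Gaussian copula targeting Spearman ``coupling_rho``.
    """
    if probe_spacing_bp <= 0:
        raise ValueError("probe_spacing_bp must be positive")
    if not 0 <= region_fraction <= 1 or not 0 <= persistence_fraction <= 1:
        raise ValueError("region_fraction and persistence_fraction must lie in [0, 1]")
    if not -1 <= coupling_rho <= 1:
        raise ValueError("coupling_rho must lie in [-1, 1]")
    if probes_per_promoter < 7:
        raise ValueError("each promoter needs >= 7 probes")
    if region_probes > probes_per_promoter:
        raise ValueError("region_probes cannot exceed probes_per_promoter")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    prom_span = (probes_per_promoter - 1) * probe_spacing_bp + probe_length_bp
    gap = 5 * probe_spacing_bp

    probe_rows = []
    prom_rows = []
    for gi, gene in enumerate(genes):
        prom_start = 1 + gi * (prom_span + gap)
        prom_rows.append({"gene": gene, "chrom": "chr1", "start": prom_start,
                          "end": prom_start + prom_span - 1})
        for pj in range(probes_per_promoter):
            start = prom_start + pj * probe_spacing_bp
            probe_rows.append(
                {"chrom": "chr1", "start": start, "end": start + probe_length_bp - 1,
                 "probe_id": f"{gene}_p{pj:02d}", "gene": gene}
            )
    probes = pd.DataFrame(probe_rows)
    promoters = pd.DataFrame(prom_rows)

    n_region = math.floor(n_genes * region_fraction)
    truth = SimTruth(seed=seed, coupling_rho=coupling_rho if ge_truth is not None else None)

    # Choose region genes: DE genes first so effects can be coupled to GE.
    ref_tp = design.treatment_timepoints[-1] if design.treatment_timepoints else design.timepoints[0]
    de_genes = sorted(set(ge_truth.de_genes) & set(genes)) if ge_truth else []
    others = [g for g in genes if g not in set(de_genes)]
    coupled = list(rng.permutation(de_genes))[:n_region]
    rest = list(rng.permutation(others))[: n_region - len(coupled)]
    region_genes = coupled + rest

    effects: dict[str, float] = {}
    if coupled:
        ge_lfc = np.array([ge_truth.de_genes[g].get(ref_tp, 0.0) for g in coupled])
        # Spearman target rho_s corresponds to Pearson rho_p on the copula scale
        rho_p = 2.0 * np.sin(np.pi * coupling_rho / 6.0)
        z_x = stats.norm.ppf((stats.rankdata(ge_lfc) - 0.5) / len(ge_lfc))
        z_y = rho_p * z_x + np.sqrt(max(0.0, 1.0 - rho_p**2)) * rng.standard_normal(len(coupled))
        for g, e in zip(coupled, _monotone_effect(z_y, effect_size)):
            effects[g] = float(e)
    for g in rest:
        sign = float(rng.choice([-1.0, 1.0]))
        effects[g] = sign * (0.6 + 1.4 * rng.uniform()) * effect_size

    n_persist = math.floor(persistence_fraction * len(region_genes))
    persistent = list(rng.permutation(region_genes))[:n_persist]
    truth.persistence_set = sorted(persistent)

    # Region occupies a central contiguous probe block.
    first_probe = (probes_per_promoter - region_probes) // 2
    region_block = range(first_probe, first_probe + region_probes)
    affected_tps: dict[str, tuple[str, ...]] = {}
    for gene in region_genes:
        tps = list(design.treatment_timepoints)
        if gene in set(persistent):
            tps += list(design.recovery_timepoints)
        affected_tps[gene] = tuple(tps)
        prom = promoters.set_index("gene").loc[gene]
        r_start = int(prom["start"]) + first_probe * probe_spacing_bp
        r_end = r_start + (region_probes - 1) * probe_spacing_bp + probe_length_bp - 1
        truth.epi_regions[gene] = {
            layer: {
                tp: {"direction": int(np.sign(effects[gene])), "effect": effects[gene],
                     "start": r_start, "end": r_end}
                for tp in tps
            }
        }

    region_set = {(g, pj) for g in region_genes for pj in region_block}
    n_probes_total = len(probes)
    sample_cols = design.sample_ids
    data = rng.normal(0.0, noise_sd, size=(n_probes_total, len(sample_cols)))
    probe_gene = probes["gene"].to_numpy()
    probe_j = np.array([int(pid.rsplit("p", 1)[1]) for pid in probes["probe_id"]])
    in_region = np.array([(g, pj) in region_set for g, pj in zip(probe_gene, probe_j)])
    effect_vec = np.array([effects.get(g, 0.0) for g in probe_gene]) * in_region
    for j, sample in enumerate(design.samples):
        if sample.treatment == design.control:
            continue
        active = np.array([sample.timepoint in affected_tps.get(g, ()) for g in probe_gene])
        data[:, j] += effect_vec * active
    signals = pd.DataFrame(data, index=pd.Index(probes["probe_id"], name="probe_id"),
                           columns=sample_cols)
    track = TilingTrack(probes=probes, signals=signals, promoters=promoters)
    return track, truth


def default_drift(amplitude: float) -> Callable[[np.ndarray, int], np.ndarray]:
    """Linear multiplicative drift: 1 + amplitude * (t - 1) / (T - 1)."""

    def fn(t: np.ndarray, total: int) -> np.ndarray:
        if total <= 1:
            return np.ones_like(np.asarray(t, dtype=float))
        return 1.0 + amplitude * (np.asarray(t, dtype=float) - 1.0) / (total - 1)

    return fn


def qc_injection_count(n_samples: int, qc_every: int) -> int:
    """QCs under the interleaving rule: first, one per qc_every-1 samples, last."""
    return math.ceil(n_samples / (qc_every - 1)) + 1


def simulate_metabolomics(
    design: StudyDesign,
    n_metabolites: int = 30,
    drift_amplitude: float = 0.3,
    qc_every: int = 10,
    noise_cv: float = 0.08,
    affected_fraction: float = 0.2,
    effect_lfc: float = 1.5,
    seed: int = 0,
) -> tuple[MetabolomicsRun, SimTruth]:
    """Simulate an injection-ordered GC-MS batch with QC injections.

    The run opens with a QC, inserts one QC after every ``qc_every - 1``
    study samples, and closes with a QC. A smooth multiplicative drift
    (linear, ending at 1 + drift_amplitude) applies identically to QCs and
    samples; noise is log-normal with CV ``noise_cv``. A fraction of
    metabolites carries a planted log2 fold change in all test-treatment
    cells at every timepoint (recorded in the truth).
    """
    if qc_every < 2:
        raise ValueError("qc_every must be >= 2")
    if drift_amplitude < 0:
        raise ValueError("drift_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    mets = _gene_ids(n_metabolites, prefix="met")
    sample_order = list(rng.permutation(design.sample_ids))

    injections: list[tuple[str, bool]] = [("QC", True)]
    for i, sid in enumerate(sample_order):
        injections.append((sid, False))
        if (i + 1) % (qc_every - 1) == 0 and i + 1 < len(sample_order):
            injections.append(("QC", True))
    injections.append(("QC", True))
    n_inj = len(injections)
    n_qc = sum(1 for _, q in injections if q)
    if n_qc < MIN_QC:
        raise InvalidRunError(
            f"only {n_qc} QC injections (need >= {MIN_QC}); lower qc_every or enlarge the design"
        )

    truth = SimTruth(seed=seed)
    base = rng.uniform(1e5, 1e7, n_metabolites)
    n_affected = math.floor(n_metabolites * affected_fraction)
    affected_idx = rng.choice(n_metabolites, size=n_affected, replace=False) if n_affected else []
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    for k, mi in enumerate(affected_idx):
        truth.metabolite_lfc[mets[mi]] = float(signs[k] * effect_lfc)
    drift_fn = default_drift(drift_amplitude)
    for m in mets:
        truth.drift[m] = {"kind": "linear", "amplitude": drift_amplitude}

    sample_info = {s.sample_id: s for s in design.samples}
    t_idx = np.arange(1, n_inj + 1)
    drift = drift_fn(t_idx, n_inj)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    rows = []
    for pos, (sid, is_qc) in enumerate(injections):
        fold = np.ones(n_metabolites)
        if not is_qc:
            s = sample_info[sid]
            if s.treatment != design.control:
                for k, mi in enumerate(affected_idx):
                    fold[mi] = 2.0 ** (signs[k] * effect_lfc)
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_metabolites))
        areas = base * fold * drift[pos] * noise
        rows.append({"injection_index": pos + 1,
                     "sample_id": sid if not is_qc else f"QC_{pos + 1:03d}",
                     "is_qc": is_qc,
                     **{m: areas[i] for i, m in enumerate(mets)}})
    run = MetabolomicsRun(table=pd.DataFrame(rows))
    run.validate()
    return run, truth
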
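"""Readers and writers for the pipeline's plain-text formats.

Conventions: feature matrices and call tables are TSV; probe tracks are
GFF3 (1-based inclusive coordinates, score column unused — signals live
in a wide TSV companion keyed by probe id); promoter maps are BED
(0-based half-open, converted to 1-based inclusive on read); metabolomics
runs are CSV with injection_index / sample_id / is_qc metadata columns;
simulation truth is JSON.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .design import StudyDesign
from .metabolomics import MetabolomicsRun, META_COLUMNS
from .synthetic import SimTruth
from .tiling import PROBE_COLUMNS, TilingTrack

GFF_SOURCE = "persistomics"
GFF_TYPE = "microarray_probe"


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "feature")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> StudyDesign:
    return StudyDesign.from_frame(pd.read_csv(path, sep="\t"))


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_probes_gff3(track: TilingTrack, path: str | Path) -> None:
    """One probe per GFF3 line; gene membership in the attributes column."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in track.probes.itertuples():
            attrs = f"ID={row.probe_id};gene={row.gene}"
            fh.write(
                f"{row.chrom}\t{GFF_SOURCE}\t{GFF_TYPE}\t{row.start}\t{row.end}"
                f"\t.\t.\t.\t{attrs}\n"
            )


def read_probes_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv)
            rows.append(
                {"chrom": fields[0], "start": int(fields[3]), "end": int(fields[4]),
                 "probe_id": attrs.get("ID", ""), "gene": attrs.get("gene", "")}
            )
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


def write_promoters_bed(promoters: pd.DataFrame, path: str | Path) -> None:
    """Promoter intervals as BED (0-based half-open; name = gene)."""
    with open(path, "w") as fh:
        for row in promoters.itertuples():
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


def read_promoters_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, gene = line.rstrip("\n").split("\t")[:4]
            rows.append({"gene": gene, "chrom": chrom, "start": int(start) + 1,
                         "end": int(end)})
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def write_track(track: TilingTrack, probes_path: str | Path,
                signals_path: str | Path, promoters_path: str | Path) -> None:
    write_probes_gff3(track, probes_path)
    track.signals.to_csv(signals_path, sep="\t", index_label="probe_id")
    write_promoters_bed(track.promoters, promoters_path)


def read_track(probes_path: str | Path, signals_path: str | Path,
               promoters_path: str | Path) -> TilingTrack:
    probes = read_probes_gff3(probes_path)
    signals = pd.read_csv(signals_path, sep="\t", index_col="probe_id")
    promoters = read_promoters_bed(promoters_path)
    return TilingTrack(probes=probes, signals=signals, promoters=promoters)


def write_run_csv(run: MetabolomicsRun, path: str | Path) -> None:
    run.table.to_csv(path, index=False)


def read_run_csv(path: str | Path) -> MetabolomicsRun:
    table = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"run CSV lacks columns {missing}")
    table["is_qc"] = table["is_qc"].astype(bool)
    return MetabolomicsRun(table=table)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
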
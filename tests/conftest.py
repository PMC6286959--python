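import numpy as np
import pandas as pd
import pytest

from persistomics.design import generate_design
from persistomics.tiling import TilingTrack


@pytest.fixture(scope="session")
def design2():
    """Two arms (control + OTA), four timepoints, three replicates."""
    return generate_design(2, n_reps=3, seed=1)


@pytest.fixture(scope="session")
def design3():
    """Full three-arm layout: control, OTA, KBrO3."""
    return generate_design(3, n_reps=3, seed=1)


def make_track(gene_probes: dict[str, int], signals: pd.DataFrame | None = None,
               spacing: int = 100, probe_len: int = 50,
               samples: list[str] | None = None, seed: int = 0) -> TilingTrack:
    """Small hand-built track: one promoter per gene, evenly spaced probes."""
    rows, prom_rows = [], []
    pos = 1
    for gene, n in gene_probes.items():
        start0 = pos
        for j in range(n):
            s = start0 + j * spacing
            rows.append({"chrom": "chr1", "start": s, "end": s + probe_len - 1,
                         "probe_id": f"{gene}_p{j:02d}", "gene": gene})
        prom_rows.append({"gene": gene, "chrom": "chr1", "start": start0,
                          "end": start0 + (n - 1) * spacing + probe_len - 1})
        pos = start0 + n * spacing + 500
    probes = pd.DataFrame(rows)
    promoters = pd.DataFrame(prom_rows)
    if signals is None:
        if samples is None:
            samples = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(seed)
        signals = pd.DataFrame(
            rng.normal(0, 0.2, size=(len(probes), len(samples))),
            index=pd.Index(probes["probe_id"], name="probe_id"), columns=samples,
        )
    return TilingTrack(probes=probes, signals=signals, promoters=promoters)
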
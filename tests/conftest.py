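import numpy as np
import pandas as pd
import pytest

from chromoplast import SimConfig
from chromoplast.marks import GeneAnnotation, PeakSet
from chromoplast.pws import CalibrationModel


@pytest.fixture
def calib() -> CalibrationModel:
    return CalibrationModel("linear", {"b": 0.05})


@pytest.fixture
def cfg() -> SimConfig:
    return SimConfig(seed=7)


@pytest.fixture
def toy_peaks() -> dict[str, PeakSet]:
    """Hand-placed peak sets on two small chromosomes."""
    k4 = PeakSet(
        "H3K4me3",
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [1_000, 50_000, 10_000],
                "end": [2_000, 51_000, 12_000],
            }
        ),
    )
    k27 = PeakSet(
        "H3K27me3",
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "start": [1_500, 80_000],
                "end": [2_500, 81_000],
            }
        ),
    )
    return {"H3K4me3": k4, "H3K27me3": k27}


@pytest.fixture
def twelve_gene_annotation() -> GeneAnnotation:
    rng = np.random.default_rng(11)
    rows = []
    for i in range(12):
        rows.append(
            {
                "gene_id": f"g{i + 1}",
                "chrom": "chr1" if i < 8 else "chr2",
                "strand": "+" if rng.random() < 0.5 else "-",
                "tss": int(rng.integers(2_000, 100_000)),
            }
        )
    return GeneAnnotation(pd.DataFrame(rows))


def brute_force_tss_overlap(peaks: PeakSet, annotation: GeneAnnotation, window: int = 2000):
    """Independent all-pairs interval-overlap oracle for peak->TSS assignment."""
    out = {}
    for _, gene in annotation.genes.iterrows():
        lo, hi = gene["tss"] - window, gene["tss"] + window
        hits = []
        for idx, pk in peaks.intervals.iterrows():
            if pk["chrom"] != gene["chrom"]:
                continue
            # half-open overlap by >= 1 bp
            if max(pk["start"], lo) < min(pk["end"], hi):
                hits.append(idx)
        out[gene["gene_id"]] = hits
    return out
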
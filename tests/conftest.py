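import numpy as np
import pandas as pd
import pytest

from ribote.counting import CountTable
from ribote.simulate import make_transcriptome, simulate_fragments


@pytest.fixture(scope="session")
def toy_transcriptome():
    """30 random transcripts with planted uAUG ground truth."""
    return make_transcriptome(30, seed=3)


@pytest.fixture(scope="session")
def deep_ribo_fragments():
    """~1e5 Ribo fragments over 100 long transcripts (default profile)."""
    txs, _ = make_transcriptome(100, seed=4)
    design = pd.DataFrame(
        {"library_type": ["Ribo"], "replicate": ["rep1"], "tissue": ["mesoderm"]},
        index=pd.Index(["mesoderm_Ribo_rep1"], name="library_id"),
    )
    counts = pd.DataFrame({"mesoderm_Ribo_rep1": 1000}, index=list(txs))
    table = CountTable(counts=counts, design=design)
    return txs, simulate_fragments(txs, table, seed=2)


def make_count_table(counts: np.ndarray, design_rows: list[dict]) -> CountTable:
    """Assemble a CountTable from a raw matrix and library descriptions."""
    design = pd.DataFrame(design_rows)
    design.index = pd.Index(
        [
            f"{r['tissue']}_{r['library_type']}_{r['replicate']}"
            for r in design_rows
        ],
        name="library_id",
    )
    genes = pd.Index([f"g{i}" for i in range(counts.shape[0])], name="gene_id")
    return CountTable(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        design=design,
    )


def paired_design(n_reps: int = 3, tissues: tuple[str, ...] = ("mesoderm",)) -> list[dict]:
    """Standard paired Ribo/RNA design rows, tissue-major."""
    return [
        {"library_type": lib, "replicate": f"rep{r}", "tissue": t}
        for t in tissues
        for r in range(1, n_reps + 1)
        for lib in ("RNA", "Ribo")
    ]
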
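"""A-site assignment and codon-masked CDS counting.

Ribosome-protected fragments are attributed to the codon in the ribosomal
A site using a length-dependent offset from the fragment 5' end. Counting
over the CDS excludes the first 15 and last 5 codons, where initiation
pileup (amplified by cycloheximide) and termination artefacts distort the
elongation signal. RNA-Seq fragments are positioned by the same offset rule
so the two library types are counted over identical windows.

Coordinates are 0-based, half-open; codon k occupies CDS nucleotides
[3k, 3k+3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "asite_offset",
    "assign_asite",
    "count_cds",
    "build_count_table",
]

MASK_START_CODONS = 15
MASK_END_CODONS = 5


@dataclass
class CountTable:
    """Gene x library count matrix with its design description.

    counts : DataFrame, genes (rows) x library ids (columns)
    design : DataFrame indexed by library id with columns
             library_type ('Ribo'/'RNA'), replicate, tissue
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("count columns and design rows must match in order")
        for col in ("library_type", "replicate", "tissue"):
            if col not in self.design.columns:
                raise ValueError(f"design missing column {col!r}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, counts_path, design_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        if design_path is not None:
            self.design.to_csv(design_path, sep="\t", index_label="library_id")

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        design = pd.read_csv(design_path, sep="\t", index_col="library_id")
        return cls(counts=counts, design=design)


def asite_offset(length: int) -> int:
    """A-site offset (nt from the fragment 5' end) for a fragment length.

    Piecewise-constant in length: <=29 nt -> +14, 30-31 nt -> +15,
    32-35 nt -> +16, >=36 nt -> +17.
    """
    if length < 1:
        raise ValueError("fragment length must be >= 1")
    if length <= 29:
        return 14
    if length <= 31:
        return 15
    if length <= 35:
        return 16
    return 17


def _asite_offsets(lengths: np.ndarray) -> np.ndarray:
    """Vectorized :func:`asite_offset`."""
    lengths = np.asarray(lengths)
    out = np.full(lengths.shape, 17)
    out[lengths <= 35] = 16
    out[lengths <= 31] = 15
    out[lengths <= 29] = 14
    return out


def assign_asite(
    fragments: pd.DataFrame, transcripts: dict
) -> tuple[pd.DataFrame, int]:
    """Attach an A-site position to every fragment; drop out-of-bounds ones.

    The same length-based rule is applied to both library types. Fragments
    whose A-site falls at or beyond the transcript end are dropped (and
    counted), not clipped.

    Returns (fragments with an added 'asite' column, n_dropped).
    """
    if fragments.empty:
        out = fragments.copy()
        out["asite"] = pd.Series(dtype=int)
        return out, 0
    asite = fragments["pos5"].to_numpy() + _asite_offsets(fragments["length"].to_numpy())
    tx_len = fragments["transcript_id"].map(
        {g: t.length for g, t in transcripts.items()}
    ).to_numpy()
    keep = (asite >= 0) & (asite < tx_len)
    out = fragments.loc[keep].copy()
    out["asite"] = asite[keep]
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("assign_asite: dropped %d fragments with out-of-bounds A-sites", n_dropped)
    return out, n_dropped


def count_cds(
    positions: np.ndarray,
    transcript,
    mask_start_codons: int = MASK_START_CODONS,
    mask_end_codons: int = MASK_END_CODONS,
) -> int:
    """Count assigned positions inside the masked CDS window of a transcript.

    The window is [cds_start + 3*mask_start_codons, cds_end - 3*mask_end_codons)
    so with the default masks codons 0-14 and the final 5 codons never count.
    """
    lo = transcript.cds_start + 3 * mask_start_codons
    hi = transcript.cds_end - 3 * mask_end_codons
    if hi <= lo:
        raise ValueError(
            f"{transcript.gene_id}: CDS too short for the codon mask "
            f"({transcript.cds_len} nt <= {3 * (mask_start_codons + mask_end_codons)})"
        )
    positions = np.asarray(positions)
    return int(((positions >= lo) & (positions < hi)).sum())


def build_count_table(
    fragments: pd.DataFrame,
    transcripts: dict,
    mask_start_codons: int = MASK_START_CODONS,
    mask_end_codons: int = MASK_END_CODONS,
) -> CountTable:
    """Build the gene x library table of codon-masked CDS counts.

    Fragments are A-site assigned (both library types, identically), then
    counted by A-site membership in the masked CDS window. Genes whose CDS
    is too short for the mask are excluded and logged.
    """
    mask_nt = 3 * (mask_start_codons + mask_end_codons)
    genes = [g for g in transcripts if transcripts[g].cds_len > mask_nt]
    skipped = [g for g in transcripts if transcripts[g].cds_len <= mask_nt]
    if skipped:
        log.warning(
            "build_count_table: %d genes excluded (CDS too short for %d-nt mask)",
            len(skipped),
            mask_nt,
        )
    assigned, _ = assign_asite(fragments, transcripts)
    if assigned.empty:
        design = pd.DataFrame(
            columns=["library_type", "replicate", "tissue"]
        ).rename_axis("library_id")
        counts = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
        return CountTable(counts=counts, design=design)
    lo = assigned["transcript_id"].map(
        {g: t.cds_start + 3 * mask_start_codons for g, t in transcripts.items()}
    )
    hi = assigned["transcript_id"].map(
        {g: t.cds_end - 3 * mask_end_codons for g, t in transcripts.items()}
    )
    in_window = (assigned["asite"] >= lo) & (assigned["asite"] < hi)
    windowed = assigned.loc[in_window & assigned["transcript_id"].isin(genes)]
    lib_id = (
        windowed["tissue"].astype(str)
        + "_"
        + windowed["library"].astype(str)
        + "_"
        + windowed["replicate"].astype(str)
    )
    table = (
        pd.crosstab(windowed["transcript_id"], lib_id)
        .reindex(index=genes, fill_value=0)
        .rename_axis(index="gene_id", columns=None)
    )
    design_rows = (
        pd.DataFrame(
            {
                "library_id": lib_id,
                "library_type": windowed["library"].to_numpy(),
                "replicate": windowed["replicate"].to_numpy(),
                "tissue": windowed["tissue"].to_numpy(),
            }
        )
        .drop_duplicates("library_id")
        .set_index("library_id")
        .sort_index()
    )
    table = table.reindex(columns=design_rows.index, fill_value=0)
    return CountTable(counts=table, design=design_rows)
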
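"""Transcript models: one canonical isoform per gene, in transcript coordinates.

All downstream computation is transcript-relative: a transcript is a single
contiguous sequence partitioned into 5'UTR, CDS and 3'UTR. Coordinates are
0-based, half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "read_transcripts",
    "write_transcripts",
]


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript with its functional-region extents.

    Parameters
    ----------
    gene_id : str
        Gene identifier (one canonical transcript per gene).
    sequence : str
        Full transcript sequence, 5'UTR + CDS + 3'UTR, DNA alphabet.
    utr5_len, cds_len, utr3_len : int
        Region lengths in nucleotides. The CDS must be a multiple of 3 and
        include the stop codon.
    transcript_id : str
        Isoform identifier; defaults to ``gene_id``.
    canonical : bool
        Whether the annotation marks this isoform as canonical.
    """

    gene_id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    transcript_id: str = ""
    canonical: bool = False

    def __post_init__(self) -> None:
        if not self.transcript_id:
            object.__setattr__(self, "transcript_id", self.gene_id)
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError("region lengths must be non-negative")
        if self.sequence and len(self.sequence) != self.utr5_len + self.cds_len + self.utr3_len:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"sum of region lengths {self.utr5_len + self.cds_len + self.utr3_len}"
            )

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds_start(self) -> int:
        """0-based transcript coordinate of the first CDS nucleotide."""
        return self.utr5_len

    @property
    def cds_end(self) -> int:
        """0-based transcript coordinate one past the last CDS nucleotide."""
        return self.utr5_len + self.cds_len

    @property
    def utr5(self) -> str:
        return self.sequence[: self.utr5_len]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def region_of(self, pos: int) -> str:
        """Region name ('utr5', 'cds', 'utr3') of a transcript position."""
        if not 0 <= pos < self.length:
            raise IndexError(f"position {pos} outside transcript [0, {self.length})")
        if pos < self.cds_start:
            return "utr5"
        if pos < self.cds_end:
            return "cds"
        return "utr3"


def write_transcripts(
    transcripts: Iterable[TranscriptModel],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write transcript sequences as FASTA and region extents as a TSV.

    The TSV columns are gene_id, transcript_id, utr5_len, cds_len, utr3_len.
    """
    transcripts = list(transcripts)
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description=t.gene_id)
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tutr5_len\tcds_len\tutr3_len\n")
        for t in transcripts:
            fh.write(
                f"{t.gene_id}\t{t.transcript_id}\t{t.utr5_len}\t{t.cds_len}\t{t.utr3_len}\n"
            )


def read_transcripts(
    fasta_path: str | Path, annotation_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load transcripts written by :func:`write_transcripts`, keyed by gene."""
    seqs: Mapping[str, str] = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    out: dict[str, TranscriptModel] = {}
    with open(annotation_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tid = parts[idx["transcript_id"]]
            gene = parts[idx["gene_id"]]
            out[gene] = TranscriptModel(
                gene_id=gene,
                transcript_id=tid,
                sequence=seqs.get(tid, ""),
                utr5_len=int(parts[idx["utr5_len"]]),
                cds_len=int(parts[idx["cds_len"]]),
                utr3_len=int(parts[idx["utr3_len"]]),
            )
    return out
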
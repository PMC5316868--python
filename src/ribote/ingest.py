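"""Read preprocessing and alignment bookkeeping.

Covers the steps between raw sequencing output and the fragment table the
pipeline consumes: 3' adapter trimming, mean-quality filtering, layered
removal of rRNA/tRNA/snRNA contaminants followed by unique-mapper selection,
and reduction of a multi-isoform annotation to one canonical transcript per
gene. Alignment itself is delegated to an external aligner; this module only
applies the post-alignment filtering rules and records per-library attrition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

from .transcripts import TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "ReadRecord",
    "LibraryStats",
    "trim_adapter",
    "filter_quality",
    "layered_filter",
    "select_canonical",
    "read_fastq",
    "load_sam_fragments",
]


@dataclass(frozen=True)
class ReadRecord:
    """One raw sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.id}: sequence and qualities differ in length")


@dataclass
class LibraryStats:
    """Per-library survivor counts through the layered filter."""

    total_reads: int
    reads_after_contaminant_removal: int
    unique_mapped_reads: int

    def __post_init__(self) -> None:
        if not (
            self.total_reads
            >= self.reads_after_contaminant_removal
            >= self.unique_mapped_reads
            >= 0
        ):
            raise ValueError("library stats must be monotonically non-increasing")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def trim_adapter(
    read: ReadRecord, adapter: str, min_len: int = 15, min_overlap: int = 3
) -> ReadRecord | None:
    """Remove a 3' adapter from a read; discard if too short afterwards.

    The earliest position where the remaining read suffix equals a prefix of
    the adapter (the adapter may run off the read's 3' end) is trimmed, with
    a minimum suffix/prefix overlap to avoid spurious 1-2 nt matches.
    Matching is exact. Returns None when the trimmed read is shorter than
    ``min_len``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    cut = len(seq)
    for i in range(len(seq) - min_overlap + 1):
        tail = seq[i:]
        if adapter.startswith(tail[: len(adapter)]) and len(tail) >= min_overlap:
            cut = i
            break
    trimmed = ReadRecord(read.id, seq[:cut], read.qualities[:cut])
    return trimmed if len(trimmed.sequence) >= min_len else None


def filter_quality(
    read: ReadRecord, threshold: float = 33, mode: str = "mean"
) -> bool:
    """Keep a read iff its quality exceeds ``threshold``.

    ``mode='mean'`` (default) compares the mean per-base Phred score;
    ``mode='min'`` requires every base to exceed the threshold. Empty reads
    are discarded.
    """
    if not read.qualities:
        return False
    if mode == "mean":
        return sum(read.qualities) / len(read.qualities) > threshold
    if mode == "min":
        return min(read.qualities) > threshold
    raise ValueError(f"unknown quality mode {mode!r}")


def layered_filter(
    alignments: pd.DataFrame,
    contaminant_col: str = "contaminant",
    n_hits_col: str = "n_hits",
) -> tuple[pd.DataFrame, LibraryStats]:
    """Apply the layered alignment filter and record attrition.

    First discards fragments flagged as aligning to a contaminant class
    (rRNA/tRNA/snRNA), then keeps only fragments with exactly one
    transcriptome alignment. Returns the surviving fragments and a
    :class:`LibraryStats` with the survivor count of each layer.
    """
    total = len(alignments)
    clean = alignments.loc[~alignments[contaminant_col].astype(bool)]
    unique = clean.loc[clean[n_hits_col] == 1]
    stats = LibraryStats(
        total_reads=total,
        reads_after_contaminant_removal=len(clean),
        unique_mapped_reads=len(unique),
    )
    return unique.drop(columns=[contaminant_col, n_hits_col]), stats


def select_canonical(
    isoforms: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick one canonical isoform per gene.

    A tagged canonical isoform wins; otherwise the longest CDS, then the
    longest transcript, then the lexicographically smallest transcript id.
    Genes with zero isoforms cannot appear; an empty input maps to an empty
    result.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    out: dict[str, TranscriptModel] = {}
    for gene, isos in by_gene.items():
        tagged = [t for t in isos if t.canonical]
        pool = tagged if tagged else isos
        out[gene] = min(
            pool, key=lambda t: (-t.cds_len, -t.length, t.transcript_id)
        )
    return out


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream reads from a FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            id=rec.id,
            sequence=str(rec.seq),
            qualities=tuple(rec.letter_annotations["phred_quality"]),
        )


def load_sam_fragments(
    path,
    library: str,
    replicate: str = "rep1",
    tissue: str = "mesoderm",
    unique_only: bool = True,
) -> pd.DataFrame:
    """Load transcriptome alignments from SAM/BAM into the fragment table.

    References are transcript ids; the NH tag (when present) gives the
    number of alignments, used for unique-mapper selection. Unmapped and
    secondary records are skipped.
    """
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if unique_only and aln.has_tag("NH") and aln.get_tag("NH") != 1:
                continue
            rows.append(
                {
                    "transcript_id": aln.reference_name,
                    "pos5": aln.reference_start,
                    "length": aln.query_length or aln.infer_query_length() or 0,
                    "library": library,
                    "replicate": replicate,
                    "tissue": tissue,
                }
            )
    return pd.DataFrame(
        rows, columns=["transcript_id", "pos5", "length", "library", "replicate", "tissue"]
    )
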
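"""Library-quality diagnostics for footprint and RNA libraries.

Four standard checks establish that a ribosome-profiling library carries
genuine elongation signal: a fragment-length distribution with a discrete
mode near 30 nt (the ribosome footprint size), a read partition dominated by
the CDS, a 3-nt periodicity of A-sites within the CDS, and metagene density
profiles around the CDS start and stop. Both library types are positioned by
the same length-based A-site rule so their windows are directly comparable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import assign_asite

log = logging.getLogger(__name__)

__all__ = [
    "MetageneProfile",
    "length_histogram",
    "region_distribution",
    "frame_periodicity",
    "metagene",
]

# metagene gene filters: short UTRs or CDSs make the +/-150 nt windows
# overlap region boundaries; sparse genes add mostly noise
MIN_UTR5 = 50
MIN_UTR3 = 50
MIN_CDS = 500
MIN_READS = 300

START_WINDOW = (-30, 150)  # relative to CDS start, half-open
STOP_WINDOW = (-150, 30)  # relative to CDS end, half-open


@dataclass
class MetageneProfile:
    """Averaged normalized read density around CDS boundaries.

    start_window : density at positions -30..+149 relative to the CDS start
    stop_window : density at positions -150..+29 relative to the CDS end
    n_genes_used : genes surviving the length and read-count filters
    """

    start_window: np.ndarray
    stop_window: np.ndarray
    n_genes_used: int
    start_positions: np.ndarray = field(
        default_factory=lambda: np.arange(*START_WINDOW)
    )
    stop_positions: np.ndarray = field(default_factory=lambda: np.arange(*STOP_WINDOW))

    def __post_init__(self) -> None:
        self.start_window = np.asarray(self.start_window, dtype=float)
        self.stop_window = np.asarray(self.stop_window, dtype=float)
        if self.start_window.size != 180 or self.stop_window.size != 180:
            raise ValueError("metagene windows must each span exactly 180 nt")

    def plot(self, ax=None):
        """Line plot of both windows (start panel solid, stop panel dashed)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.start_positions, self.start_window, label="CDS start")
        ax.plot(self.stop_positions, self.stop_window, "--", label="CDS end")
        ax.set_xlabel("position relative to CDS boundary (nt)")
        ax.set_ylabel("mean normalized density")
        ax.legend()
        return ax


def length_histogram(fragments: pd.DataFrame) -> dict[int, int]:
    """Histogram of fragment lengths; values sum to the fragment count."""
    if fragments.empty:
        return {}
    return dict(sorted(Counter(fragments["length"].astype(int)).items()))


def region_distribution(
    fragments: pd.DataFrame, transcripts: dict
) -> tuple[dict[str, float], int]:
    """Fractions of assigned positions in 5'UTR / CDS / 3'UTR.

    Fragments are A-site assigned first; out-of-bounds assignments are
    excluded and returned as the second element. Fractions sum to 1 whenever
    any fragment is assignable.
    """
    assigned, n_dropped = assign_asite(fragments, transcripts)
    if assigned.empty:
        return {"utr5": 0.0, "cds": 0.0, "utr3": 0.0}, n_dropped
    cds_start = assigned["transcript_id"].map(
        {g: t.cds_start for g, t in transcripts.items()}
    )
    cds_end = assigned["transcript_id"].map(
        {g: t.cds_end for g, t in transcripts.items()}
    )
    pos = assigned["asite"]
    n = len(assigned)
    n_cds = int(((pos >= cds_start) & (pos < cds_end)).sum())
    n_utr5 = int((pos < cds_start).sum())
    return (
        {"utr5": n_utr5 / n, "cds": n_cds / n, "utr3": (n - n_cds - n_utr5) / n},
        n_dropped,
    )


def frame_periodicity(
    fragments: pd.DataFrame, transcripts: dict
) -> dict[int, float]:
    """Reading-frame fractions of A-sites inside the CDS.

    Frame = (A-site - CDS start) mod 3; only CDS A-sites contribute.
    """
    assigned, _ = assign_asite(fragments, transcripts)
    if assigned.empty:
        return {0: 0.0, 1: 0.0, 2: 0.0}
    cds_start = assigned["transcript_id"].map(
        {g: t.cds_start for g, t in transcripts.items()}
    )
    cds_end = assigned["transcript_id"].map(
        {g: t.cds_end for g, t in transcripts.items()}
    )
    in_cds = (assigned["asite"] >= cds_start) & (assigned["asite"] < cds_end)
    if not in_cds.any():
        return {0: 0.0, 1: 0.0, 2: 0.0}
    frames = ((assigned["asite"] - cds_start) % 3)[in_cds]
    counts = frames.value_counts().reindex([0, 1, 2], fill_value=0)
    total = counts.sum()
    return {f: counts[f] / total for f in (0, 1, 2)}


def metagene(
    fragments: pd.DataFrame,
    transcripts: dict,
    min_utr5: int = MIN_UTR5,
    min_utr3: int = MIN_UTR3,
    min_cds: int = MIN_CDS,
    min_reads: int = MIN_READS,
) -> MetageneProfile:
    """Metagene density profiles around the CDS start and stop.

    Genes pass the filter when 5'UTR >= ``min_utr5`` nt, 3'UTR >=
    ``min_utr3`` nt, CDS >= ``min_cds`` nt and at least ``min_reads``
    fragments have an assigned position anywhere on the transcript
    (boundaries inclusive). Each surviving gene's per-nt read counts are
    divided by that gene's total assigned reads before averaging, so every
    gene contributes equally regardless of expression.
    """
    assigned, _ = assign_asite(fragments, transcripts)
    start_lo, start_hi = START_WINDOW
    stop_lo, stop_hi = STOP_WINDOW
    start_sum = np.zeros(start_hi - start_lo)
    stop_sum = np.zeros(stop_hi - stop_lo)
    n_used = 0
    if not assigned.empty:
        for gene, group in assigned.groupby("transcript_id", sort=False):
            tx = transcripts.get(gene)
            if tx is None:
                continue
            if (
                tx.utr5_len < min_utr5
                or tx.utr3_len < min_utr3
                or tx.cds_len < min_cds
                or len(group) < min_reads
            ):
                continue
            pos = group["asite"].to_numpy()
            total = len(group)
            rel_start = pos - tx.cds_start
            sel = (rel_start >= start_lo) & (rel_start < start_hi)
            start_sum += (
                np.bincount(rel_start[sel] - start_lo, minlength=start_hi - start_lo)
                / total
            )
            rel_stop = pos - tx.cds_end
            sel = (rel_stop >= stop_lo) & (rel_stop < stop_hi)
            stop_sum += (
                np.bincount(rel_stop[sel] - stop_lo, minlength=stop_hi - stop_lo)
                / total
            )
            n_used += 1
    if n_used == 0:
        log.warning("metagene: no genes pass the filters; empty profile")
        return MetageneProfile(start_sum, stop_sum, 0)
    return MetageneProfile(start_sum / n_used, stop_sum / n_used, n_used)
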
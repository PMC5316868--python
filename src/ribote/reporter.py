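"""Dual-luciferase reporter TE and polysome-association statistics.

The reporter assay couples a test 5'UTR to Firefly luciferase (Fluc) with a
co-transfected Renilla (Rluc) control; translational efficiency is the
activity ratio corrected for mRNA levels, relative to a reference UTR
construct (the HBB 5'UTR), so the reference maps to 1. The polysome assay
quantifies an mRNA across sucrose-gradient fractions by qPCR, normalizing
each fraction's recovery by an in-vitro-transcribed Fluc spike-in, and
reports the percentage of the mRNA in the heavy (actively translating)
fractions. Group comparisons use Student's t-test with the conventional
star notation (** p<0.01, * p<0.05, NS otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReporterMeasurement",
    "FractionProfile",
    "reporter_te",
    "reporter_te_by_batch",
    "heavy_polysome_fraction",
    "delta_log2_heavy",
    "compare_groups",
    "mark_heavy",
]


@dataclass(frozen=True)
class ReporterMeasurement:
    """One reporter transfection: luminescence and RNA for both luciferases."""

    construct: str
    fluc_activity: float
    rluc_activity: float
    fluc_rna: float
    rluc_rna: float
    batch: str = "batch1"

    def __post_init__(self) -> None:
        for name in ("fluc_activity", "rluc_activity", "fluc_rna", "rluc_rna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.construct}: {name} must be positive")

    @property
    def normalized_te(self) -> float:
        """(Fluc/Rluc activity) / (Fluc/Rluc RNA), before referencing."""
        return (self.fluc_activity / self.rluc_activity) / (
            self.fluc_rna / self.rluc_rna
        )


@dataclass(frozen=True)
class FractionProfile:
    """Sucrose-gradient qPCR profile of one mRNA.

    fractions : sequence of (qpcr_quantity, spikein_quantity, heavy) with
    at least one heavy and one non-heavy fraction.
    """

    fractions: tuple[tuple[float, float, bool], ...]

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValueError("need at least 2 fractions")
        flags = [h for _, _, h in self.fractions]
        if not (any(flags) and not all(flags)):
            raise ValueError("need at least one heavy and one non-heavy fraction")
        for q, s, _ in self.fractions:
            if s <= 0:
                raise ValueError("spike-in quantity must be positive")
            if q < 0:
                raise ValueError("qPCR quantity must be non-negative")


def mark_heavy(
    quantities: Sequence[tuple[float, float]], first_heavy_index: int
) -> FractionProfile:
    """Build a profile marking fractions >= ``first_heavy_index`` as heavy.

    Which gradient fractions count as 'heavy polysomes' depends on the
    apparatus; membership is therefore an input, with this helper for the
    common by-index convention.
    """
    return FractionProfile(
        tuple(
            (q, s, i >= first_heavy_index) for i, (q, s) in enumerate(quantities)
        )
    )


def reporter_te(
    measurement: ReporterMeasurement, reference: ReporterMeasurement
) -> float:
    """Relative reporter TE: RNA-corrected Fluc/Rluc over the reference.

    TE = [(Fluc_act/Rluc_act) / (Fluc_RNA/Rluc_RNA)] divided by the same
    quantity for the reference construct, which therefore maps to 1.
    """
    return measurement.normalized_te / reference.normalized_te


def reporter_te_by_batch(
    measurements: Sequence[ReporterMeasurement],
    references: Sequence[ReporterMeasurement],
) -> tuple[float, float, list[float]]:
    """Per-batch referenced TE, averaged across batches.

    Each measurement is referenced against the reference from its own batch;
    returns (mean, SD across batches, per-batch values).
    """
    ref_by_batch = {r.batch: r for r in references}
    values = []
    for m in measurements:
        if m.batch not in ref_by_batch:
            raise ValueError(f"no reference measurement for batch {m.batch!r}")
        values.append(reporter_te(m, ref_by_batch[m.batch]))
    arr = np.asarray(values)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return float(arr.mean()), sd, values


def heavy_polysome_fraction(profile: FractionProfile) -> float:
    """Percent of an mRNA in the heavy-polysome fractions.

    Each fraction's qPCR quantity is divided by its spike-in quantity to
    correct for recovery, then the heavy share of the corrected total is
    returned in percent.
    """
    corrected = np.array([q / s for q, s, _ in profile.fractions])
    total = corrected.sum()
    if total <= 0:
        raise ValueError("profile has no signal")
    heavy = sum(c for c, (_, _, h) in zip(corrected, profile.fractions) if h)
    return float(100.0 * heavy / total)


def delta_log2_heavy(profile_a: FractionProfile, profile_b: FractionProfile) -> float:
    """log2 change in heavy-polysome percentage between two profiles."""
    pa = heavy_polysome_fraction(profile_a)
    pb = heavy_polysome_fraction(profile_b)
    if pa <= 0 or pb <= 0:
        raise ValueError("heavy-polysome percentage must be positive")
    return float(np.log2(pa / pb))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, str]:
    """Two-sided two-sample t-test with significance stars.

    Student's t (equal variance) by default; ``equal_var=False`` gives
    Welch's test. Returns (p, stars) with ** for p<0.01, * for p<0.05 and
    NS otherwise.
    """
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("each group needs at least 2 values")
    p = float(
        stats.ttest_ind(values_a, values_b, equal_var=equal_var).pvalue
    )
    if np.isnan(p):  # zero variance in both identical groups
        p = 1.0
    stars = "**" if p < 0.01 else "*" if p < 0.05 else "NS"
    return p, stars
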
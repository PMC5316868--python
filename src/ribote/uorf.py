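"""5'-UTR start-site annotation and in-silico mutagenesis.

Scans a 5'UTR for upstream initiation sites — every uAUG regardless of
context, plus near-cognate codons (one substitution away from AUG) in a
favourable Kozak context — and classifies the reading frame opened at each
site relative to the main ORF:

* ``uORF``: an in-frame stop occurs before the CDS start;
* ``oORF``: the frame crosses the CDS start without a stop and is out of
  frame with the main ORF (overlapping ORF);
* ``in-frame-extension``: no upstream stop and frame offset 0, i.e. an
  N-terminal extension of the main protein.

The mutagenesis operations mirror the classic reporter dissection of such
landscapes: point-mutating a start codon away (AUG -> AAG/CAG), disrupting
a uORF stop codon (e.g. UGA -> AGA, which fuses the uORF into the
downstream frame), and inserting 1-2 nt just before the CDS to shift
upstream frames.

Sequences may be given as DNA or RNA; annotation is invariant under the
T/U representation. All coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "StartSiteAnnotation",
    "MutationSpec",
    "MutationResult",
    "NEAR_COGNATE_CODONS",
    "STOP_CODONS",
    "kozak_favourable",
    "classify_orf",
    "find_start_sites",
    "apply_mutation",
    "cluster_start_sites",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# the 9 codons at Hamming distance 1 from ATG
NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "ACG", "AGG", "AAG", "ATA", "ATC", "ATT"}
)

_VALID = set("ACGT")


def _normalize(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    if set(s) - _VALID:
        raise ValueError(f"{label} contains non-nucleotide characters")
    return s


@dataclass(frozen=True)
class StartSiteAnnotation:
    """One upstream initiation site.

    position : 0-based offset of the codon start within the 5'UTR
    codon : the 3-nt start codon (DNA alphabet)
    canonical : True for AUG
    kozak_favourable : context call at this site
    orf_class : 'uORF', 'oORF' or 'in-frame-extension'
    stop_position : 0-based offset (in 5'UTR+CDS coordinates) of the stop
        codon terminating the reading frame, or None if no stop is reached
    in_frame_with_main : frame offset to the main ORF is 0
    """

    position: int
    codon: str
    canonical: bool
    kozak_favourable: bool
    orf_class: str
    stop_position: int | None
    in_frame_with_main: bool


@dataclass(frozen=True)
class MutationSpec:
    """One mutagenesis operation on a 5'UTR.

    kind : 'start_point_mutation' (replace a start codon, typically with
        AAG or CAG), 'stop_point_mutation' (replace a stop codon, e.g.
        TGA -> AGA) or 'insertion' (insert bases; position defaults to just
        before the main CDS for frameshifts).
    position : 0-based UTR offset the operation applies at
    bases : replacement codon or inserted bases
    """

    kind: str
    position: int
    bases: str

    def __post_init__(self) -> None:
        if self.kind not in ("start_point_mutation", "stop_point_mutation", "insertion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if not self.bases:
            raise ValueError("bases must be non-empty")


@dataclass
class MutationResult:
    """A mutated UTR with its fresh start-site annotation."""

    utr: str
    cds: str
    sites: list[StartSiteAnnotation]
    new_start_created: bool


def kozak_favourable(
    seq: str, codon_start: int, convention: str = "adjacent"
) -> bool:
    """Favourable-context call for the codon at ``codon_start`` of ``seq``.

    ``convention='adjacent'`` (default): G at position -1 (immediately 5' of
    the codon) and A/G at +3 (the first nt after the codon, the codon
    occupying 0-2). ``convention='standard'`` uses the classical Kozak
    numbering instead: A/G at -3 and G at +4 (i.e. the nt right after the
    codon under 1-based A-of-AUG = +1 numbering). Missing context at a
    sequence edge is unfavourable.
    """
    if convention == "adjacent":
        up, down = codon_start - 1, codon_start + 3
        if up < 0 or down >= len(seq):
            return False
        return seq[up] == "G" and seq[down] in "AG"
    if convention == "standard":
        up, down = codon_start - 3, codon_start + 3
        if up < 0 or down >= len(seq):
            return False
        return seq[up] in "AG" and seq[down] == "G"
    raise ValueError(f"unknown Kozak convention {convention!r}")


def classify_orf(
    position: int, utr: str, cds: str
) -> tuple[str, int | None, bool]:
    """Classify the reading frame opened at a UTR position.

    Translates in-frame triplets from ``position`` through the UTR and on
    into the CDS until a stop codon. A uORF requires its stop codon to lie
    entirely within the 5'UTR; a frame whose first stop straddles or
    follows the CDS start overlaps the main ORF (oORF when out of frame).
    Returns (orf_class, stop_position or None, in_frame_with_main).
    """
    utr = _normalize(utr, "utr")
    cds = _normalize(cds, "cds")
    full = utr + cds
    cds_start = len(utr)
    in_frame = (cds_start - position) % 3 == 0
    i = position
    while i + 3 <= len(full):
        if full[i : i + 3] in STOP_CODONS:
            if i + 3 <= cds_start:
                return "uORF", i, in_frame
            break
        i += 3
    return ("in-frame-extension" if in_frame else "oORF"), (
        i if i + 3 <= len(full) else None
    ), in_frame


def find_start_sites(
    utr: str,
    cds: str,
    near_cognates: Iterable[str] = NEAR_COGNATE_CODONS,
    kozak_convention: str = "adjacent",
) -> list[StartSiteAnnotation]:
    """Annotate every upstream initiation site in a 5'UTR.

    Reports each AUG in the UTR in any context, and each near-cognate codon
    whose context is Kozak-favourable. The context window may extend into
    the CDS for sites near the UTR/CDS boundary.
    """
    utr = _normalize(utr, "utr")
    cds = _normalize(cds, "cds")
    if cds and not cds.startswith("ATG"):
        raise ValueError("cds must start with ATG")
    near = {_normalize(c, "near_cognate") for c in near_cognates}
    full = utr + cds
    sites: list[StartSiteAnnotation] = []
    for pos in range(len(utr) - 2):
        codon = utr[pos : pos + 3]
        canonical = codon == "ATG"
        kozak = kozak_favourable(full, pos, convention=kozak_convention)
        if not canonical and not (codon in near and kozak):
            continue
        orf_class, stop, in_frame = classify_orf(pos, utr, cds)
        sites.append(
            StartSiteAnnotation(
                position=pos,
                codon=codon,
                canonical=canonical,
                kozak_favourable=kozak,
                orf_class=orf_class,
                stop_position=stop,
                in_frame_with_main=in_frame,
            )
        )
    return sites


def apply_mutation(
    utr: str,
    cds: str,
    spec: MutationSpec,
    **scan_kwargs,
) -> MutationResult:
    """Apply one mutagenesis operation and re-annotate the UTR.

    Start-codon point mutations remove that site from the annotation (the
    replacement may itself create a new start, which is flagged rather than
    forbidden). Insertions at the CDS boundary shift every surviving
    upstream frame by len(bases) mod 3.
    """
    utr = _normalize(utr, "utr")
    cds = _normalize(cds, "cds")
    bases = _normalize(spec.bases, "bases")
    if spec.kind in ("start_point_mutation", "stop_point_mutation"):
        if not 0 <= spec.position <= len(utr) - len(bases):
            raise ValueError("mutation runs outside the UTR")
        new_utr = utr[: spec.position] + bases + utr[spec.position + len(bases) :]
    else:  # insertion
        if not 0 <= spec.position <= len(utr):
            raise ValueError("insertion position outside the UTR")
        new_utr = utr[: spec.position] + bases + utr[spec.position :]
    before = {
        s.position for s in find_start_sites(utr, cds, **scan_kwargs) if s.canonical
    }
    sites = find_start_sites(new_utr, cds, **scan_kwargs)
    if spec.kind == "insertion":
        # positions at/after the insertion moved by len(bases)
        shifted = {
            p + len(bases) if p >= spec.position else p for p in before
        }
        new_start = any(
            s.canonical and s.position not in shifted for s in sites
        )
    else:
        new_start = any(
            s.canonical and s.position not in before for s in sites
        )
    return MutationResult(utr=new_utr, cds=cds, sites=sites, new_start_created=new_start)


def cluster_start_sites(
    positions: Iterable[int], max_gap: int = 50
) -> list[list[int]]:
    """Group start-site positions into clusters separated by > max_gap nt.

    Purely descriptive: uAUGs in real 5'UTRs often occur in clusters, and
    deletion constructs typically target a cluster as a unit.
    """
    pos = sorted(positions)
    if not pos:
        return []
    clusters = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] <= max_gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters
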
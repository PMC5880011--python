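"""Protein-level consequences of intron retention.

Retaining an intron in the mature transcript has one of three outcomes for
the encoded protein, evaluated in the reading frame of the preceding exons:

* ``ptc_truncation`` -- the retained intron encodes a premature termination
  codon (a stop codon whose three bases all lie inside the intron), so the
  protein is truncated;
* ``frameshift_novel_peptide`` -- no in-intron stop, but the intron length
  is not divisible by 3, shifting the frame of all downstream exons;
* ``in_frame_insertion`` -- length divisible by 3 and no in-intron stop:
  a clean insertion of extra residues.

By default stops are only sought inside the retained intron
(``ptc_scope="intron_only"``); ``ptc_scope="full_transcript"`` additionally
scans the (possibly frame-shifted) downstream exon sequence for stops
upstream of the transcript end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .formats_io import GeneModel

__all__ = [
    "RetentionConsequence",
    "classify_retention",
    "summarize_consequences",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class RetentionConsequence:
    intron_key: str
    causes_frameshift: bool
    introduces_ptc: bool
    category: str
    first_stop_offset: int | None  # index of the stop codon, counted in the
    # upstream frame from the first codon containing intron bases

    def __post_init__(self) -> None:
        assert (self.category == "ptc_truncation") == self.introduces_ptc
        if self.category == "in_frame_insertion":
            assert not self.causes_frameshift and not self.introduces_ptc


def classify_retention(intron, model: GeneModel,
                       ptc_scope: str = "intron_only") -> RetentionConsequence:
    """Classify the consequence of retaining one intron of ``model``.

    The retained segment is read in the upstream reading frame: the
    phase-completing tail of the preceding exon, the intron, and as much
    downstream exon sequence as needed to complete the final codon.
    """
    if ptc_scope not in ("intron_only", "full_transcript"):
        raise ValueError(f"unknown ptc_scope {ptc_scope!r}")
    cds = model.cds_sequence
    off = intron.cds_offset
    if intron.gene_id != model.gene_id or not 0 < off < len(cds):
        raise ValueError(f"intron {intron.key} does not belong to {model.gene_id}")
    iseq = intron.sequence
    length = len(iseq)
    phase = off % 3
    causes_frameshift = length % 3 != 0

    # upstream-frame segment starting at the last codon boundary before the
    # intron; the intron occupies [phase, phase + length) within it
    segment = cds[off - phase:off] + iseq + cds[off:]
    first_stop: int | None = None
    first_overlap_codon = 0  # codon 0 of the segment always contains intron
    # bases when phase > 0 is completed by them; for phase 0 the intron opens
    # the segment, so codon 0 overlaps in every case
    n_codons_scan = (phase + length + 2) // 3  # codons overlapping the intron
    introduces_ptc = False
    for j in range(n_codons_scan):
        codon = segment[3 * j:3 * j + 3]
        if len(codon) < 3:
            break
        fully_inside = 3 * j >= phase and 3 * j + 3 <= phase + length
        if codon in _STOPS and fully_inside:
            introduces_ptc = True
            first_stop = j - first_overlap_codon
            break

    if not introduces_ptc and ptc_scope == "full_transcript":
        # scan the whole retained transcript downstream of the intron start,
        # stopping before the final (annotated or frame-shifted) codon
        retained = cds[:off] + iseq + cds[off:]
        start = (off - phase)
        last_full = (len(retained) // 3) * 3 - 3
        for pos in range(start, last_full, 3):
            codon = retained[pos:pos + 3]
            if codon in _STOPS:
                introduces_ptc = True
                first_stop = (pos - start) // 3
                break

    if introduces_ptc:
        category = "ptc_truncation"
    elif causes_frameshift:
        category = "frameshift_novel_peptide"
    else:
        category = "in_frame_insertion"
    return RetentionConsequence(
        intron_key=intron.key, causes_frameshift=causes_frameshift,
        introduces_ptc=introduces_ptc, category=category,
        first_stop_offset=first_stop)


def summarize_consequences(consequences: list[RetentionConsequence]) -> dict[str, float]:
    """Category fractions plus the frameshift/PTC marginals (fractions of
    the three categories sum to 1)."""
    if not consequences:
        raise ValueError("no consequences to summarize")
    n = len(consequences)
    counts = Counter(c.category for c in consequences)
    return {
        "n": n,
        "ptc_truncation": counts.get("ptc_truncation", 0) / n,
        "frameshift_novel_peptide": counts.get("frameshift_novel_peptide", 0) / n,
        "in_frame_insertion": counts.get("in_frame_insertion", 0) / n,
        "frameshift_fraction": sum(c.causes_frameshift for c in consequences) / n,
        "ptc_fraction": sum(c.introduces_ptc for c in consequences) / n,
    }
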
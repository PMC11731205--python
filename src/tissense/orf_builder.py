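"""Extend called initiation sites to open reading frames.

An ORF runs from its TIS codon to the first in-frame stop (TAA/TAG/TGA).
Initiation at near-cognate codons still yields methionine, so the first
residue is always reported as M.  ORFs that run off the transcript end
without a stop are retained but flagged incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io import STOP_CODONS, TranscriptRecord

IN_FRAME_CLASSES = frozenset({"annotated", "internal_in_frame"})


@dataclass
class ORFCall:
    """A detected TIS extended to its open reading frame."""

    transcript_id: str
    gene_id: str
    tis_position: int
    stop_position: int | None
    length_aa: int
    peptide: str
    complete: bool
    orf_class: str | None = None
    cds_overlap_frame: int | None = None
    sample_id: str | None = None
    p_value: float | None = None
    q_value: float | None = None


def scan_orf(sequence: str, tis: int) -> tuple[int | None, int]:
    """First in-frame stop from ``tis`` and the coding span in codons.

    Returns ``(stop_position, n_codons)`` where ``stop_position`` is the first
    nucleotide of the stop codon, or ``None`` if the frame runs off the
    transcript; ``n_codons`` excludes the stop.
    """
    if not (0 <= tis <= len(sequence) - 3):
        raise ValueError(f"TIS {tis} outside sequence of length {len(sequence)}")
    pos = tis
    while pos + 3 <= len(sequence):
        if sequence[pos : pos + 3] in STOP_CODONS:
            return pos, (pos - tis) // 3
        pos += 3
    return None, (pos - tis) // 3


def translate_orf(sequence: str, tis: int) -> tuple[int | None, str]:
    """Translate from ``tis`` to the first in-frame stop; initiator becomes M."""
    stop, n_codons = scan_orf(sequence, tis)
    span = sequence[tis : tis + 3 * n_codons]
    peptide = str(Seq(span).translate()) if span else ""
    if peptide:
        peptide = "M" + peptide[1:]
    return stop, peptide


def build_orf(transcript: TranscriptRecord, tis: int | object) -> ORFCall:
    """Build the ORFCall for a TIS on ``transcript``.

    ``tis`` may be a position or any object with transcript_id/position/
    p_value/q_value attributes (a TISCandidate); significance metadata is
    carried over when present.
    """
    if isinstance(tis, int):
        pos, p, q = tis, None, None
    else:
        if tis.transcript_id != transcript.transcript_id:
            raise ValueError("candidate and transcript ids disagree")
        pos = tis.position
        p = getattr(tis, "p_value", None)
        q = getattr(tis, "q_value", None)
    stop, peptide = translate_orf(transcript.sequence, pos)
    return ORFCall(
        transcript_id=transcript.transcript_id,
        gene_id=transcript.gene_id,
        tis_position=pos,
        stop_position=stop,
        length_aa=len(peptide),
        peptide=peptide,
        complete=stop is not None,
        p_value=p,
        q_value=q,
    )


def resolve_multi_transcript(calls: list[ORFCall]) -> ORFCall:
    """Pick one call when a TIS is assigned to several transcripts of a gene.

    In-frame ORFs (annotated or internal in-frame) win over out-of-frame
    ones; remaining ties go to the longest peptide, then to the
    lexicographically smallest transcript id.
    """
    if not calls:
        raise ValueError("no calls to resolve")

    def key(c: ORFCall) -> tuple:
        return (
            0 if (c.orf_class in IN_FRAME_CLASSES) else 1,
            -c.length_aa,
            c.transcript_id,
        )

    return min(calls, key=key)
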
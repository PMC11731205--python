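"""Positional classification of ORF calls relative to the annotated CDS.

Classes partition all calls: a transcript without a CDS yields ``lncRNA``;
on coding transcripts the TIS position relative to [cds_start, cds_end)
decides between ``annotated`` (exactly at the start), ``upstream``,
``downstream``, and the two internal classes separated by reading frame.
An upstream ORF that extends into the CDS is still classed upstream by its
TIS; whether it overlaps the CDS and in which relative frame is recorded
separately, because catalog conventions may label such an ORF out-of-frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import TranscriptRecord
from .orf_builder import ORFCall

ORF_CLASSES = (
    "annotated",
    "upstream",
    "downstream",
    "internal_in_frame",
    "internal_out_of_frame",
    "lncRNA",
)


@dataclass(frozen=True)
class Classification:
    label: str
    overlaps_cds: bool = False
    relative_frame: int | None = None


def classify(orf: ORFCall, transcript: TranscriptRecord) -> Classification:
    """Assign the positional class of ``orf`` on ``transcript``."""
    if orf.transcript_id != transcript.transcript_id:
        raise ValueError("ORF and transcript ids disagree")
    if not transcript.is_coding:
        return Classification("lncRNA")
    cds_start, cds_end = transcript.cds_start, transcript.cds_end
    tis = orf.tis_position
    frame = (tis - cds_start) % 3
    if tis == cds_start:
        return Classification("annotated", overlaps_cds=True, relative_frame=0)
    if tis < cds_start:
        end = orf.stop_position + 3 if orf.stop_position is not None else transcript.length
        return Classification(
            "upstream", overlaps_cds=end > cds_start, relative_frame=frame
        )
    if tis >= cds_end:
        return Classification("downstream", overlaps_cds=False, relative_frame=frame)
    label = "internal_in_frame" if frame == 0 else "internal_out_of_frame"
    return Classification(label, overlaps_cds=True, relative_frame=frame)


def classify_calls(
    calls: list[ORFCall], tset, in_place: bool = True
) -> list[ORFCall]:
    """Classify a batch of calls, writing the label onto each call."""
    out = []
    for call in calls:
        cls = classify(call, tset[call.transcript_id])
        call.orf_class = cls.label
        call.cds_overlap_frame = cls.relative_frame if cls.overlaps_cds else None
        out.append(call)
    return out
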
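"""Readers and writers for the formats the pipeline touches.

Every coordinate in this package is 0-based, half-open, in transcript space,
on the sense strand.  Annotation rows use ``cds_start``/``cds_end`` with that
convention; SAM records are transcript-space (one reference per transcript),
single-end, forward strand.
"""

from __future__ import annotations

import gzip
import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

BIOTYPE_CODING = "coding"
BIOTYPE_LNCRNA = "lncRNA"


class TranscriptomeError(ValueError):
    """A transcript record or annotation row violates the model invariants."""


class FootprintError(ValueError):
    """A footprint file cannot be interpreted against the transcriptome."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: sequence plus (for coding biotypes) its CDS interval."""

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.biotype not in (BIOTYPE_CODING, BIOTYPE_LNCRNA):
            raise TranscriptomeError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if self.biotype == BIOTYPE_CODING:
            if self.cds_start is None or self.cds_end is None:
                raise TranscriptomeError(
                    f"{self.transcript_id}: coding transcript lacks CDS bounds"
                )
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise TranscriptomeError(
                    f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise TranscriptomeError(
                    f"{self.transcript_id}: CDS length "
                    f"{self.cds_end - self.cds_start} is not a multiple of 3"
                )
            if self.sequence[self.cds_start : self.cds_start + 3] != START_CODON:
                raise TranscriptomeError(
                    f"{self.transcript_id}: CDS does not begin with ATG"
                )
        else:
            if self.cds_start is not None or self.cds_end is not None:
                raise TranscriptomeError(
                    f"{self.transcript_id}: lncRNA transcript carries CDS bounds"
                )

    @property
    def is_coding(self) -> bool:
        return self.biotype == BIOTYPE_CODING

    @property
    def length(self) -> int:
        return len(self.sequence)


class TranscriptSet(Mapping[str, TranscriptRecord]):
    """An immutable, id-keyed collection of validated transcripts."""

    def __init__(self, records: Iterable[TranscriptRecord]):
        self._records: dict[str, TranscriptRecord] = {}
        for rec in records:
            if rec.transcript_id in self._records:
                raise TranscriptomeError(
                    f"duplicate transcript id {rec.transcript_id!r}"
                )
            self._records[rec.transcript_id] = rec

    def __getitem__(self, key: str) -> TranscriptRecord:
        return self._records[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def coding(self) -> Iterator[TranscriptRecord]:
        return (r for r in self._records.values() if r.is_coding)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptSet):
            return NotImplemented
        return self._records == other._records


ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "biotype", "cds_start", "cds_end"]


def load_transcriptome(fasta_path: str | Path, annotation_path: str | Path) -> TranscriptSet:
    """Load sequences from FASTA and CDS intervals from the annotation TSV.

    Every annotation row must name a FASTA record; invariant violations are
    rejected with a message naming the offending transcript.
    """
    with _open_text(fasta_path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise TranscriptomeError(f"annotation lacks columns {missing}")
    records = []
    for row in ann.itertuples(index=False):
        if row.transcript_id not in seqs:
            raise TranscriptomeError(
                f"annotation row for {row.transcript_id!r} has no FASTA sequence"
            )
        coding = row.biotype == BIOTYPE_CODING
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                biotype=row.biotype,
                sequence=seqs[row.transcript_id],
                cds_start=int(row.cds_start) if coding else None,
                cds_end=int(row.cds_end) if coding else None,
            )
        )
    return TranscriptSet(records)


def write_transcriptome(
    tset: TranscriptSet, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    with _open_text(fasta_path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(r.sequence), id=r.transcript_id, description="") for r in tset.values()),
            fh,
            "fasta",
        )
    rows = [
        {
            "transcript_id": r.transcript_id,
            "gene_id": r.gene_id,
            "biotype": r.biotype,
            "cds_start": r.cds_start if r.cds_start is not None else "",
            "cds_end": r.cds_end if r.cds_end is not None else "",
        }
        for r in tset.values()
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(annotation_path, sep="\t", index=False)


FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "read_length"]


@dataclass(eq=False)
class FootprintSet:
    """Aligned ribosome footprints as a table of 5'-end positions.

    ``df`` has columns transcript_id, five_prime_pos, read_length; one row per
    read.  ``n_skipped`` counts records dropped during loading, by reason.
    """

    df: pd.DataFrame
    n_skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = self.df[FOOTPRINT_COLUMNS].reset_index(drop=True)
        self.df["five_prime_pos"] = self.df["five_prime_pos"].astype("int64")
        self.df["read_length"] = self.df["read_length"].astype("int64")

    def __len__(self) -> int:
        return len(self.df)

    def sorted(self) -> "FootprintSet":
        df = self.df.sort_values(FOOTPRINT_COLUMNS, kind="mergesort").reset_index(drop=True)
        return FootprintSet(df, dict(self.n_skipped))

    def equals(self, other: "FootprintSet") -> bool:
        return self.sorted().df.equals(other.sorted().df)

    @classmethod
    def empty(cls) -> "FootprintSet":
        return cls(pd.DataFrame(columns=FOOTPRINT_COLUMNS))


def _infer_footprint_format(path: str | Path) -> str:
    name = str(path)
    if name.endswith((".sam", ".bam", ".sam.gz")):
        return "sam"
    return "tsv"


def load_footprints(
    path: str | Path, tset: TranscriptSet, format: str | None = None
) -> FootprintSet:
    """Load footprint alignments from transcript-space SAM/BAM or TSV.

    Unmapped, secondary, supplementary and reverse-strand records are skipped
    and tallied in ``n_skipped``; out-of-bounds positions likewise.  A
    reference/transcript id absent from ``tset`` is an error.
    """
    fmt = format or _infer_footprint_format(path)
    skipped: dict[str, int] = {
        "unmapped": 0,
        "secondary": 0,
        "supplementary": 0,
        "reverse_strand": 0,
        "out_of_bounds": 0,
    }
    rows: dict[str, list] = {c: [] for c in FOOTPRINT_COLUMNS}

    def _keep(tid: str, pos: int, rlen: int) -> None:
        if tid not in tset:
            raise FootprintError(f"footprint references unknown transcript {tid!r}")
        if not (0 <= pos < tset[tid].length):
            skipped["out_of_bounds"] += 1
            return
        rows["transcript_id"].append(tid)
        rows["five_prime_pos"].append(pos)
        rows["read_length"].append(rlen)

    if fmt == "sam":
        save = pysam.set_verbosity(0)  # silence missing-index warnings
        try:
            with pysam.AlignmentFile(str(path), check_sq=False) as sam:
                for read in sam:
                    if read.is_unmapped:
                        skipped["unmapped"] += 1
                        continue
                    if read.is_secondary:
                        skipped["secondary"] += 1
                        continue
                    if read.is_supplementary:
                        skipped["supplementary"] += 1
                        continue
                    if read.is_reverse:
                        skipped["reverse_strand"] += 1
                        continue
                    rlen = read.infer_read_length() or read.query_length
                    _keep(read.reference_name, int(read.reference_start), int(rlen))
        finally:
            pysam.set_verbosity(save)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
        if missing:
            raise FootprintError(f"footprint TSV lacks columns {missing}")
        for row in df.itertuples(index=False):
            _keep(str(row.transcript_id), int(row.five_prime_pos), int(row.read_length))
    else:
        raise ValueError(f"unknown footprint format {fmt!r}")

    n_skipped = {k: v for k, v in skipped.items() if v}
    if n_skipped:
        logger.info("load_footprints: skipped %s", n_skipped)
    if not rows["transcript_id"]:
        return FootprintSet(pd.DataFrame(columns=FOOTPRINT_COLUMNS), n_skipped)
    return FootprintSet(pd.DataFrame(rows), n_skipped)


def write_footprints_tsv(fpset: FootprintSet, path: str | Path) -> None:
    fpset.df.to_csv(path, sep="\t", index=False)


def write_footprints_sam(fpset: FootprintSet, tset: TranscriptSet, path: str | Path) -> None:
    """Write footprints as transcript-space SAM (forward strand, ungapped)."""
    refs = list(tset)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": tid, "LN": tset[tid].length} for tid in refs],
    }
    ref_index = {tid: i for i, tid in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(fpset.df.itertuples(index=False)):
            tid, pos, rlen = row.transcript_id, int(row.five_prime_pos), int(row.read_length)
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i}"
            a.flag = 0
            a.reference_id = ref_index[tid]
            a.reference_start = pos
            a.mapping_quality = 255
            a.cigarstring = f"{rlen}M"
            seq = tset[tid].sequence[pos : pos + rlen]
            a.query_sequence = seq if len(seq) == rlen else "N" * rlen
            out.write(a)


def load_expression(path: str | Path) -> dict[str, float]:
    """Load a two-column gene-expression table (gene_id, rpkm)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "rpkm"]:
        raise ValueError(f"expression table must have columns gene_id, rpkm; got {list(df.columns)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in expression table: {dups}")
    if (df["rpkm"] < 0).any():
        raise ValueError("negative RPKM value in expression table")
    return dict(zip(df["gene_id"].astype(str), df["rpkm"].astype(float)))


def write_expression(expression: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": list(expression), "rpkm": [expression[g] for g in expression]}
    ).to_csv(path, sep="\t", index=False)
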
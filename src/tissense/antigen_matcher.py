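"""Match a catalog of antigen-encoding ORFs against per-sample ORF calls.

An antigen catalog lists epitope peptides together with the ORF expected to
encode them (gene, optionally transcript and expected TIS) and a catalog
class label.  Catalog labels and positional classifier labels follow
different conventions — an out-of-frame catalog ORF may initiate upstream
of the CDS and be classed "upstream" by TIS position — so matching never
requires label equality.

Two detection criteria are supported: ``peptide_containment`` (default)
declares an antigen detected in a sample when any significant ORF call on
its gene contains the epitope as a substring of the called peptide;
``exact_tis`` requires a significant TIS at the expected position on the
stated transcript.  Antigens genotypically absent from a sample are never
detected there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .orf_builder import ORFCall

CATALOG_CLASSES = ("annotated", "out_of_frame", "upstream", "alternative", "lncRNA")


@dataclass
class AntigenRecord:
    """An epitope with its expected encoding ORF.

    ``present_in_sample`` maps sample ids to genotype presence; ``None``
    means present in every sample.
    """

    antigen_id: str
    epitope: str
    gene_id: str
    class_label: str
    transcript_id: str | None = None
    expected_tis: int | None = None
    present_in_sample: dict[str, bool] | None = None

    def __post_init__(self) -> None:
        if len(self.epitope) < 8:
            raise ValueError(
                f"{self.antigen_id}: epitope {self.epitope!r} shorter than 8 aa"
            )
        if self.class_label not in CATALOG_CLASSES:
            raise ValueError(
                f"{self.antigen_id}: unknown catalog class {self.class_label!r}"
            )

    def is_present(self, sample_id: str | None) -> bool:
        if self.present_in_sample is None or sample_id is None:
            return True
        return self.present_in_sample.get(sample_id, True)

    @property
    def orf_key(self) -> tuple:
        """Antigens sharing this key are encoded by the same ORF."""
        if self.transcript_id is not None and self.expected_tis is not None:
            return (self.gene_id, self.transcript_id, self.expected_tis)
        return (self.gene_id, None, self.antigen_id)


@dataclass
class DetectionMatrix:
    """ORF x sample detection booleans with class and presence annotation."""

    detected: pd.DataFrame  # bool, index orf_id, columns sample ids
    present: pd.DataFrame  # bool, same shape
    meta: pd.DataFrame  # index orf_id; columns class_label, gene_id

    def __post_init__(self) -> None:
        if (self.detected & ~self.present).any().any():
            raise ValueError("detection matrix marks an absent ORF as detected")

    @property
    def samples(self) -> list[str]:
        return list(self.detected.columns)


def match_antigen(
    antigen: AntigenRecord,
    calls: list[ORFCall],
    mode: str = "peptide_containment",
    sample_id: str | None = None,
    tis_tolerance: int = 0,
) -> bool:
    """Was this antigen's ORF detected among one sample's significant calls?"""
    if not antigen.is_present(sample_id):
        return False
    if mode == "peptide_containment":
        return any(
            call.gene_id == antigen.gene_id and antigen.epitope in call.peptide
            for call in calls
        )
    if mode == "exact_tis":
        if antigen.expected_tis is None:
            raise ValueError(
                f"{antigen.antigen_id}: exact_tis matching requires expected_tis"
            )
        return any(
            call.transcript_id == antigen.transcript_id
            and abs(call.tis_position - antigen.expected_tis) <= tis_tolerance
            for call in calls
        )
    raise ValueError(f"unknown match mode {mode!r}")


def build_matrix(
    catalog: list[AntigenRecord],
    calls_by_sample: dict[str, list[ORFCall]],
    mode: str = "peptide_containment",
    tis_tolerance: int = 0,
) -> DetectionMatrix:
    """Build the ORF x sample detection matrix.

    Antigens encoded by the same ORF are collapsed to one row; the ORF is
    detected in a sample if any of its epitopes matches there, and present
    if any of its antigens is present.
    """
    samples = list(calls_by_sample)
    groups: dict[tuple, list[AntigenRecord]] = {}
    for ag in catalog:
        groups.setdefault(ag.orf_key, []).append(ag)

    orf_ids, det_rows, pres_rows, meta_rows = [], [], [], []
    for key in groups:
        members = groups[key]
        gene, transcript, tis = key
        orf_id = (
            f"{gene}:{transcript}:{tis}" if transcript is not None else f"{gene}:{tis}"
        )
        orf_ids.append(orf_id)
        det_rows.append(
            [
                any(
                    match_antigen(ag, calls_by_sample[s], mode, s, tis_tolerance)
                    for ag in members
                )
                for s in samples
            ]
        )
        pres_rows.append([any(ag.is_present(s) for ag in members) for s in samples])
        meta_rows.append(
            {"class_label": members[0].class_label, "gene_id": gene}
        )
    detected = pd.DataFrame(det_rows, index=orf_ids, columns=samples, dtype=bool)
    present = pd.DataFrame(pres_rows, index=orf_ids, columns=samples, dtype=bool)
    meta = pd.DataFrame(meta_rows, index=orf_ids)
    return DetectionMatrix(detected=detected, present=present, meta=meta)


CATALOG_COLUMNS = [
    "antigen_id",
    "epitope",
    "gene_id",
    "transcript_id",
    "expected_tis",
    "class_label",
    "present_in",
]


def write_catalog(catalog: list[AntigenRecord], path: str | Path) -> None:
    """Write the antigen catalog TSV.

    ``present_in`` is '*' for ubiquitous antigens, else a comma-separated
    list of sample ids where the antigen is present.
    """
    rows = []
    for ag in catalog:
        present = (
            "*"
            if ag.present_in_sample is None
            else ",".join(s for s, ok in sorted(ag.present_in_sample.items()) if ok)
        )
        rows.append(
            {
                "antigen_id": ag.antigen_id,
                "epitope": ag.epitope,
                "gene_id": ag.gene_id,
                "transcript_id": ag.transcript_id or "",
                "expected_tis": "" if ag.expected_tis is None else ag.expected_tis,
                "class_label": ag.class_label,
                "present_in": present,
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def load_catalog(path: str | Path, samples: list[str] | None = None) -> list[AntigenRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    catalog = []
    for row in df.itertuples(index=False):
        present: dict[str, bool] | None
        if row.present_in == "*":
            present = None
        else:
            listed = set(filter(None, row.present_in.split(",")))
            universe = samples if samples is not None else sorted(listed)
            present = {s: s in listed for s in universe}
        catalog.append(
            AntigenRecord(
                antigen_id=row.antigen_id,
                epitope=row.epitope,
                gene_id=row.gene_id,
                class_label=row.class_label,
                transcript_id=row.transcript_id or None,
                expected_tis=int(row.expected_tis) if row.expected_tis else None,
                present_in_sample=present,
            )
        )
    return catalog
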
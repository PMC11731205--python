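"""Synthetic transcriptomes, antigen catalogs and harringtonine-style footprints.

The generator plants ORFs of every positional class — annotated, upstream,
internal in/out-of-frame, downstream, and ORFs on lncRNAs — at recorded
coordinates with recorded peptides, then simulates initiating-ribosome
footprint data over them: per-nucleotide P-site intensity proportional to
gene expression, active TIS codons boosted by a fold-enrichment factor,
counts drawn from a negative binomial, and read 5' ends displaced from the
P-site by a per-read-length offset.  Everything is a pure function of the
seed, so downstream stages can be validated against exact ground truth.

Upstream/downstream/lncRNA ORFs are planted as self-contained cassettes
(start codon, non-stop body, stop) so their peptides are independent of
the surrounding random sequence.  Internal out-of-frame ORFs are written
into the CDS in a shifted frame under the constraint that the canonical
frame stays stop-free; their stop is wherever the shifted frame first
terminates, as in real transcripts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pathlib import Path

from .antigen_matcher import AntigenRecord
from .io import (
    BIOTYPE_CODING,
    BIOTYPE_LNCRNA,
    STOP_CODONS,
    FootprintSet,
    TranscriptRecord,
    TranscriptSet,
)
from .orf_builder import translate_orf

_BASES = np.array(list("ACGT"))
ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
NON_STOP_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
NEAR_COGNATE_CODONS = sorted(
    {"ATG"[:i] + b + "ATG"[i + 1 :] for i in range(3) for b in "ACGT"} - {"ATG"}
)

PLANT_CLASSES = (
    "annotated",
    "upstream",
    "downstream",
    "internal_in_frame",
    "internal_out_of_frame",
    "lncRNA",
)


class SimulationError(ValueError):
    """The requested simulation is infeasible or inconsistent."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    Defaults describe a small but realistic harringtonine experiment:
    transcript architecture in the range of human mRNAs, expression spread
    over roughly 0.1-1000 RPKM, a strong initiation pile-up at active start
    codons over a negative-binomially dispersed elongation background, and
    footprint lengths 28-31 nt with P-site offsets of 12-13 nt.
    """

    n_coding_transcripts: int = 40
    n_lncrna_transcripts: int = 8
    utr5_length_range: tuple[int, int] = (90, 240)
    cds_length_range: tuple[int, int] = (300, 900)  # nt, multiples of 3
    utr3_length_range: tuple[int, int] = (60, 240)
    planted_orf_mix: dict[str, int] = field(
        default_factory=lambda: {
            "upstream": 1,
            "internal_in_frame": 1,
            "internal_out_of_frame": 1,
            "downstream": 1,
            "lncRNA": 1,
        }
    )
    planted_orf_length_range_aa: tuple[int, int] = (12, 40)
    expression_log10_mean: float = 0.8
    expression_log10_sd: float = 0.8
    initiation_enrichment: float = 20.0
    elongation_scale: float = 1.0  # harringtonine run-off down-weighting
    nb_dispersion: float = 5.0  # variance = mu + mu^2 / dispersion
    offset_map: dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 12, 31: 13}
    )
    read_length_weights: dict[int, float] = field(
        default_factory=lambda: {28: 0.25, 29: 0.35, 30: 0.25, 31: 0.15}
    )
    total_reads: int = 100_000
    start_codon_mode: str = "ATG"  # or "near_cognate" for non-annotated plants
    uorf_overlap_cds: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("utr5_length_range", "cds_length_range", "utr3_length_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise SimulationError(f"{name} must be a non-negative interval")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3:
            raise SimulationError("cds_length_range bounds must be multiples of 3")
        if lo < 12:
            raise SimulationError("cds_length_range minimum must be >= 12 nt")
        if self.initiation_enrichment < 1:
            raise SimulationError("initiation_enrichment must be >= 1")
        if self.nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be > 0")
        if self.elongation_scale <= 0:
            raise SimulationError("elongation_scale must be > 0")
        unknown = set(self.planted_orf_mix) - set(PLANT_CLASSES)
        if unknown:
            raise SimulationError(f"unknown planted ORF classes {sorted(unknown)}")
        missing = set(self.read_length_weights) - set(self.offset_map)
        if missing:
            raise SimulationError(
                f"offset_map lacks offsets for read lengths {sorted(missing)}"
            )
        if self.start_codon_mode not in ("ATG", "near_cognate"):
            raise SimulationError(f"unknown start_codon_mode {self.start_codon_mode!r}")
        n_up = self.planted_orf_mix.get("upstream", 0)
        lmin = self.planted_orf_length_range_aa[0]
        if n_up and not self.uorf_overlap_cds:
            if self.utr5_length_range[1] < n_up * 3 * (lmin + 1):
                raise SimulationError(
                    "utr5_length_range too short for the requested upstream ORFs: "
                    f"need {n_up * 3 * (lmin + 1)} nt for {n_up} uORF(s) of >= {lmin} aa"
                )
        n_down = self.planted_orf_mix.get("downstream", 0)
        if n_down and self.utr3_length_range[1] < n_down * 3 * (lmin + 1):
            raise SimulationError(
                "utr3_length_range too short for the requested downstream ORFs: "
                f"need {n_down * 3 * (lmin + 1)} nt for {n_down} ORF(s) of >= {lmin} aa"
            )


@dataclass(frozen=True)
class PlantedORF:
    transcript_id: str
    gene_id: str
    tis: int  # 0-based position of the start codon's first nt
    stop: int | None  # first nt of the stop codon
    orf_class: str
    peptide: str


@dataclass
class GroundTruth:
    planted: list[PlantedORF]
    expression: dict[str, float]

    def by_class(self, orf_class: str) -> list[PlantedORF]:
        return [p for p in self.planted if p.orf_class == orf_class]

    def for_transcript(self, transcript_id: str) -> list[PlantedORF]:
        return [p for p in self.planted if p.transcript_id == transcript_id]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)]) if n else ""


def _cassette(rng: np.random.Generator, n_aa: int, start_codon: str) -> str:
    """Self-contained ORF: start codon, n_aa-1 non-stop codons, one stop."""
    body = rng.choice(NON_STOP_CODONS, size=n_aa - 1)
    stop = rng.choice(sorted(STOP_CODONS))
    return start_codon + "".join(body) + stop


def _place_cassettes(
    rng: np.random.Generator, utr_len: int, cassettes: list[str]
) -> tuple[str, list[int]]:
    """Lay cassettes into a random UTR at disjoint positions, left to right."""
    need = sum(len(c) for c in cassettes)
    if need > utr_len:
        raise SimulationError(
            f"UTR of {utr_len} nt cannot hold cassettes totalling {need} nt"
        )
    seq = list(_random_nt(rng, utr_len))
    starts = []
    cursor = 0
    remaining = need
    for cas in cassettes:
        start = int(rng.integers(cursor, utr_len - remaining + 1))
        seq[start : start + len(cas)] = cas
        starts.append(start)
        cursor = start + len(cas)
        remaining -= len(cas)
    return "".join(seq), starts


def _sample_start_codon(rng: np.random.Generator, mode: str) -> str:
    if mode == "near_cognate":
        return str(rng.choice(["ATG"] + NEAR_COGNATE_CODONS))
    return "ATG"


def _build_coding_transcript(
    rng: np.random.Generator, config: SimConfig, tid: str, gid: str
) -> tuple[TranscriptRecord, list[PlantedORF]]:
    mix = config.planted_orf_mix
    lmin, lmax = config.planted_orf_length_range_aa
    for _ in range(200):
        n_codons = int(
            rng.integers(config.cds_length_range[0] // 3, config.cds_length_range[1] // 3 + 1)
        )
        codons = (
            ["ATG"]
            + list(rng.choice(NON_STOP_CODONS, size=n_codons - 2))
            + [str(rng.choice(sorted(STOP_CODONS)))]
        )
        used: set[int] = {0, n_codons - 1}
        plants: list[tuple[int, str]] = []  # (cds-relative tis, class)

        ok = True
        # internal in-frame: flip a codon to ATG; the ORF shares the CDS stop.
        for _ in range(mix.get("internal_in_frame", 0)):
            hi = n_codons - 1 - lmin
            avail = [k for k in range(2, hi + 1) if k not in used and k + 1 not in used]
            if not avail:
                ok = False
                break
            k = int(rng.choice(avail))
            codons[k] = "ATG"
            used.update({k, k + 1})
            plants.append((3 * k, "internal_in_frame"))
        if not ok:
            continue
        # internal out-of-frame: write ATG across a codon boundary in frame d.
        for _ in range(mix.get("internal_out_of_frame", 0)):
            avail = [
                j
                for j in range(2, n_codons - 2 - lmin)
                if not {j, j + 1} & used
            ]
            if not avail:
                ok = False
                break
            j = int(rng.choice(avail))
            d = int(rng.integers(1, 3))
            merged = codons[j] + codons[j + 1]
            for _ in range(50):
                free = list(merged)
                free[d : d + 3] = "ATG"
                cj, cj1 = "".join(free[:3]), "".join(free[3:])
                if cj not in STOP_CODONS and cj1 not in STOP_CODONS:
                    codons[j], codons[j + 1] = cj, cj1
                    break
                merged = _random_nt(rng, 3) + _random_nt(rng, 3)
            else:
                ok = False
                break
            used.update({j, j + 1})
            plants.append((3 * j + d, "internal_out_of_frame"))
        if not ok:
            continue

        cds = "".join(codons)

        # 5' UTR with upstream plants
        n_up = mix.get("upstream", 0)
        up_cassettes = []
        if n_up and not config.uorf_overlap_cds:
            for _ in range(n_up):
                budget = config.utr5_length_range[1] // (3 * n_up) - 1
                la = int(rng.integers(lmin, min(lmax, budget) + 1))
                up_cassettes.append(
                    _cassette(rng, la, _sample_start_codon(rng, config.start_codon_mode))
                )
            need = sum(len(c) for c in up_cassettes)
            u5 = int(
                rng.integers(
                    max(config.utr5_length_range[0], need),
                    config.utr5_length_range[1] + 1,
                )
            )
            utr5, up_starts = _place_cassettes(rng, u5, up_cassettes)
        else:
            u5 = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
            utr5 = _random_nt(rng, u5)
            up_starts = []
            if n_up and config.uorf_overlap_cds:
                # out-of-frame uORF whose TIS sits in the UTR and whose frame
                # has no stop before the canonical start (derived afterwards)
                deltas = [d for d in range(4, min(u5, 31)) if d % 3]
                if not deltas:
                    ok = False
                else:
                    delta = int(rng.choice(deltas))
                    tis = u5 - delta
                    utr5 = utr5[:tis] + "ATG" + utr5[tis + 3 :]
                    up_starts = [tis]
            if not ok:
                continue

        # 3' UTR with downstream plants
        n_down = mix.get("downstream", 0)
        down_cassettes = []
        for _ in range(n_down):
            budget = config.utr3_length_range[1] // (3 * max(n_down, 1)) - 1
            la = int(rng.integers(lmin, min(lmax, budget) + 1))
            down_cassettes.append(
                _cassette(rng, la, _sample_start_codon(rng, config.start_codon_mode))
            )
        if down_cassettes:
            need = sum(len(c) for c in down_cassettes)
            u3 = int(
                rng.integers(
                    max(config.utr3_length_range[0], need),
                    config.utr3_length_range[1] + 1,
                )
            )
            utr3, down_starts = _place_cassettes(rng, u3, down_cassettes)
        else:
            u3 = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
            utr3 = _random_nt(rng, u3)
            down_starts = []

        sequence = utr5 + cds + utr3
        cds_start = len(utr5)
        record = TranscriptRecord(
            transcript_id=tid,
            gene_id=gid,
            biotype=BIOTYPE_CODING,
            sequence=sequence,
            cds_start=cds_start,
            cds_end=cds_start + len(cds),
        )

        planted: list[PlantedORF] = []
        tis_list: list[tuple[int, str]] = [(cds_start, "annotated")]
        tis_list += [(cds_start + rel, cls) for rel, cls in plants]
        tis_list += [(s, "upstream") for s in up_starts]
        tis_list += [(cds_start + len(cds) + s, "downstream") for s in down_starts]
        for tis, cls in tis_list:
            stop, peptide = translate_orf(sequence, tis)
            if stop is None or len(peptide) < (
                lmin if cls in ("internal_out_of_frame",) else 1
            ):
                ok = False
                break
            if cls == "upstream" and config.uorf_overlap_cds and stop < cds_start:
                ok = False  # overlap requested but the frame stopped in the UTR
                break
            planted.append(PlantedORF(tid, gid, tis, stop, cls, peptide))
        if ok:
            return record, planted
    raise SimulationError(
        f"could not satisfy planted ORF constraints for {tid} after 200 attempts"
    )


def _build_lncrna_transcript(
    rng: np.random.Generator, config: SimConfig, tid: str, gid: str
) -> tuple[TranscriptRecord, list[PlantedORF]]:
    lmin, lmax = config.planted_orf_length_range_aa
    length = int(
        rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1)
        + rng.integers(config.cds_length_range[0], config.cds_length_range[1] + 1)
        + rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1)
    )
    n_orfs = max(1, config.planted_orf_mix.get("lncRNA", 1))
    cassettes = [
        _cassette(rng, int(rng.integers(lmin, lmax + 1)), "ATG") for _ in range(n_orfs)
    ]
    sequence, starts = _place_cassettes(rng, length, cassettes)
    record = TranscriptRecord(
        transcript_id=tid, gene_id=gid, biotype=BIOTYPE_LNCRNA, sequence=sequence
    )
    planted = []
    for s in starts:
        stop, peptide = translate_orf(sequence, s)
        planted.append(PlantedORF(tid, gid, s, stop, "lncRNA", peptide))
    return record, planted


def generate_transcriptome(config: SimConfig) -> tuple[TranscriptSet, GroundTruth]:
    """Generate a transcriptome with planted ORFs and ground-truth expression."""
    rng = np.random.default_rng(config.seed)
    records: list[TranscriptRecord] = []
    planted: list[PlantedORF] = []
    for i in range(config.n_coding_transcripts):
        tid, gid = f"TX{i:04d}", f"GENE{i:04d}"
        rec, orfs = _build_coding_transcript(rng, config, tid, gid)
        records.append(rec)
        planted.extend(orfs)
    for i in range(config.n_lncrna_transcripts):
        tid = f"LNC{i:04d}"
        gid = f"GENE{config.n_coding_transcripts + i:04d}"
        rec, orfs = _build_lncrna_transcript(rng, config, tid, gid)
        records.append(rec)
        planted.extend(orfs)
    expression = {
        rec.gene_id: float(
            10.0 ** rng.normal(config.expression_log10_mean, config.expression_log10_sd)
        )
        for rec in records
    }
    return TranscriptSet(records), GroundTruth(planted=planted, expression=expression)


#: catalog class label -> ground-truth plant classes it draws from
CATALOG_TO_PLANT = {
    "annotated": ("annotated",),
    "upstream": ("upstream",),
    "out_of_frame": ("internal_out_of_frame",),
    "alternative": ("internal_in_frame",),
    "lncRNA": ("lncRNA",),
}


def plant_antigens(
    tset: TranscriptSet,
    truth: GroundTruth,
    class_mix: dict[str, int],
    epitope_length: int = 9,
    seed: int = 0,
    samples: list[str] | None = None,
    restricted_fraction: float = 0.0,
) -> list[AntigenRecord]:
    """Draw an antigen catalog from the planted ORFs.

    Each antigen's epitope is a contiguous in-frame window of its source
    ORF's peptide.  ``class_mix`` maps catalog class labels to counts.
    With ``restricted_fraction`` > 0 and a sample list, that fraction of
    antigens is made genotype-restricted to a random non-empty subset of
    samples (they cannot be detected elsewhere).
    """
    rng = np.random.default_rng(seed)
    catalog: list[AntigenRecord] = []
    idx = 0
    for label in sorted(class_mix):
        count = class_mix[label]
        if label not in CATALOG_TO_PLANT:
            raise ValueError(f"unknown catalog class {label!r}")
        pool = [
            p
            for cls in CATALOG_TO_PLANT[label]
            for p in truth.by_class(cls)
            if len(p.peptide) >= epitope_length
        ]
        if count > len(pool):
            raise ValueError(
                f"requested {count} antigens of class {label!r} but only "
                f"{len(pool)} planted ORFs with peptides >= {epitope_length} aa exist"
            )
        chosen = [pool[j] for j in rng.permutation(len(pool))[:count]]
        for p in chosen:
            off = int(rng.integers(0, len(p.peptide) - epitope_length + 1))
            present: dict[str, bool] | None = None
            if samples and restricted_fraction > 0 and rng.random() < restricted_fraction:
                n_pos = int(rng.integers(1, len(samples)))
                pos = set(rng.choice(samples, size=n_pos, replace=False))
                present = {s: s in pos for s in samples}
            catalog.append(
                AntigenRecord(
                    antigen_id=f"AG{idx:03d}",
                    epitope=p.peptide[off : off + epitope_length],
                    gene_id=p.gene_id,
                    class_label=label,
                    transcript_id=p.transcript_id,
                    expected_tis=p.tis,
                    present_in_sample=present,
                )
            )
            idx += 1
    return catalog


def simulate_footprints(
    tset: TranscriptSet,
    truth: GroundTruth,
    config: SimConfig,
    active_tis: set[tuple[str, int]] | None = None,
    seed: int | None = None,
) -> FootprintSet:
    """Simulate footprint 5' ends from the planted-ORF intensity model.

    Per-nucleotide P-site intensity is proportional to the gene's
    expression times ``elongation_scale``; the three nucleotides of each
    active TIS codon get expression times ``initiation_enrichment``
    instead.  Intensities are scaled so their sum is ``total_reads``,
    counts are drawn NB(mu, dispersion), and each read's 5' end is its
    P-site minus the offset for its sampled length.  Reads whose 5' end
    would fall before the transcript start are dropped and counted.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    all_planted = {(p.transcript_id, p.tis) for p in truth.planted}
    if active_tis is None:
        active = all_planted
    else:
        active = set(active_tis)
        unknown = active - all_planted
        if unknown:
            raise SimulationError(f"active_tis not planted: {sorted(unknown)[:3]}")

    tids = list(tset)
    intensities = []
    for tid in tids:
        rec = tset[tid]
        w = truth.expression[rec.gene_id]
        mu = np.full(rec.length, w * config.elongation_scale, dtype=float)
        for p in truth.for_transcript(tid):
            if (tid, p.tis) in active:
                mu[p.tis : p.tis + 3] = w * config.initiation_enrichment
        intensities.append(mu)
    total = sum(float(m.sum()) for m in intensities)
    scale = config.total_reads / total

    lengths = np.array(sorted(config.read_length_weights), dtype=np.int64)
    weights = np.array([config.read_length_weights[int(L)] for L in lengths])
    weights = weights / weights.sum()
    offsets = np.array([config.offset_map[int(L)] for L in lengths], dtype=np.int64)

    frames = []
    n_dropped = 0
    for tid, mu in zip(tids, intensities):
        mu = mu * scale
        k = config.nb_dispersion
        counts = rng.negative_binomial(k, k / (k + mu))
        psites = np.repeat(np.arange(len(mu), dtype=np.int64), counts)
        if psites.size == 0:
            continue
        # length distribution: inverse-CDF on the configured weights
        li = np.searchsorted(np.cumsum(weights), rng.random(psites.size), side="right")
        five = psites - offsets[li]
        keep = five >= 0
        n_dropped += int((~keep).sum())
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": tid,
                    "five_prime_pos": five[keep],
                    "read_length": lengths[li[keep]],
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(
            ["transcript_id", "five_prime_pos", "read_length"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["transcript_id", "five_prime_pos", "read_length"])
    skipped = {"negative_five_prime": n_dropped} if n_dropped else {}
    return FootprintSet(df, skipped)


GROUND_TRUTH_COLUMNS = ["transcript_id", "gene_id", "tis", "stop", "orf_class", "peptide"]


def write_ground_truth(truth: GroundTruth, orf_path: str | Path, expression_path: str | Path) -> None:
    rows = [
        {
            "transcript_id": p.transcript_id,
            "gene_id": p.gene_id,
            "tis": p.tis,
            "stop": "" if p.stop is None else p.stop,
            "orf_class": p.orf_class,
            "peptide": p.peptide,
        }
        for p in truth.planted
    ]
    pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS).to_csv(orf_path, sep="\t", index=False)
    from .io import write_expression

    write_expression(truth.expression, expression_path)


def load_ground_truth(orf_path: str | Path, expression_path: str | Path) -> GroundTruth:
    from .io import load_expression

    df = pd.read_csv(orf_path, sep="\t", dtype={"stop": "object"}, keep_default_na=False)
    planted = [
        PlantedORF(
            transcript_id=str(r.transcript_id),
            gene_id=str(r.gene_id),
            tis=int(r.tis),
            stop=int(r.stop) if str(r.stop) else None,
            orf_class=str(r.orf_class),
            peptide=str(r.peptide),
        )
        for r in df.itertuples(index=False)
    ]
    return GroundTruth(planted=planted, expression=load_expression(expression_path))
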
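"""End-to-end orchestration: simulate -> offsets -> tracks -> call -> ORFs ->
classify -> match -> report.

``analyze_sample`` is the per-sample analysis core shared by the CLI and the
test-bench.  ``run_end_to_end`` drives a full simulated study from one
config and seed, writing each stage's table plus a provenance record, and
is byte-deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .antigen_matcher import (
    AntigenRecord,
    DetectionMatrix,
    build_matrix,
    load_catalog,
    write_catalog,
)
from .io import (
    FootprintSet,
    TranscriptSet,
    load_expression,
    load_transcriptome,
    write_expression,
    write_footprints_sam,
    write_footprints_tsv,
    write_transcriptome,
)
from .orf_builder import ORFCall, build_orf, resolve_multi_transcript
from .orf_classifier import classify_calls
from .psite import OffsetMap, build_psite_tracks, estimate_offsets
from .report import class_summary, detection_histogram, expression_strata, sensitivity
from .simulate import (
    GroundTruth,
    SimConfig,
    generate_transcriptome,
    plant_antigens,
    simulate_footprints,
    write_ground_truth,
)
from .tis_caller import (
    ATG_ONLY,
    NEAR_COGNATE_START_CODONS,
    BackgroundError,
    NBBackground,
    TISCandidate,
    call_tis,
    find_candidates,
    fit_background,
    pool_dispersion,
    scan_start_codons,
    test_candidates,
)


@dataclass
class CallerParams:
    """Tunable parameters of the TIS-calling stages."""

    codon_set: frozenset[str] = NEAR_COGNATE_START_CODONS
    alpha: float = 0.05
    min_count: int = 5
    search_window: tuple[int, int] = (10, 15)
    length_range: tuple[int, int] = (25, 35)
    min_reads_per_length: int = 100
    exclusion_radius: int = 1
    min_codons: int = 20
    min_dispersion: float = 0.1
    shared_dispersion: bool = True


@dataclass
class SampleResult:
    sample_id: str | None
    offsets: OffsetMap
    candidates: list[TISCandidate]
    calls: list[ORFCall]
    n_scanned: int
    skipped_transcripts: list[str] = field(default_factory=list)


def analyze_sample(
    footprints: FootprintSet,
    tset: TranscriptSet,
    params: CallerParams | None = None,
    sample_id: str | None = None,
    offsets: OffsetMap | None = None,
) -> SampleResult:
    """Run one sample through offset estimation, TIS calling and ORF building.

    The BH correction uses the total number of scanned start-codon
    positions as the testing burden, so the low-count prefilter does not
    shrink the multiplicity.  Background fitting masks every start-codon
    position (sequence-defined), keeping the background estimate free of
    initiation signal without count-based selection.  By default the NB
    size parameter is shared across transcripts (median of per-transcript
    moment estimates) while the background mean stays per-transcript; see
    :func:`tissense.tis_caller.pool_dispersion`.
    """
    params = params or CallerParams()
    if offsets is None:
        offsets = estimate_offsets(
            footprints,
            tset,
            search_window=params.search_window,
            length_range=params.length_range,
            min_reads_per_length=params.min_reads_per_length,
        )
    tracks, _ = build_psite_tracks(footprints, offsets, tset)

    fitted = []
    skipped: list[str] = []
    for tid, rec in tset.items():
        positions = scan_start_codons(rec, params.codon_set)
        if positions.size == 0:
            continue
        try:
            background = fit_background(
                tracks[tid],
                positions,
                exclusion_radius=params.exclusion_radius,
                min_codons=params.min_codons,
                min_dispersion=params.min_dispersion,
            )
        except BackgroundError:
            # start-codon-dense or short transcript: fall back to fitting on
            # all codon bins.  Any initiation signal then inflates the
            # background mean, which can only make its tests conservative.
            try:
                background = fit_background(
                    tracks[tid],
                    [],
                    min_codons=params.min_codons,
                    min_dispersion=params.min_dispersion,
                )
            except BackgroundError:
                skipped.append(tid)
                continue
        fitted.append((rec, positions, background))

    k_shared = (
        pool_dispersion([bg for _, _, bg in fitted]) if params.shared_dispersion else None
    )
    candidates: list[TISCandidate] = []
    n_scanned = 0
    for rec, positions, background in fitted:
        if params.shared_dispersion and k_shared is not None:
            background = NBBackground(
                mu=background.mu, size=k_shared, n_codons=background.n_codons
            )
        n_scanned += int(positions.size)
        cands = find_candidates(tracks[rec.transcript_id], rec, params.codon_set, params.min_count)
        candidates.extend(test_candidates(cands, background))

    significant = call_tis(candidates, alpha=params.alpha, n_tests=n_scanned)

    raw_calls = []
    for cand in significant:
        call = build_orf(tset[cand.transcript_id], cand)
        call.sample_id = sample_id
        raw_calls.append(call)
    classify_calls(raw_calls, tset)

    by_tis: dict[tuple[str, int], list[ORFCall]] = {}
    for call in raw_calls:
        by_tis.setdefault((call.gene_id, call.tis_position), []).append(call)
    calls = [resolve_multi_transcript(group) for group in by_tis.values()]
    calls.sort(key=lambda c: (c.transcript_id, c.tis_position))
    return SampleResult(
        sample_id=sample_id,
        offsets=offsets,
        candidates=candidates,
        calls=calls,
        n_scanned=n_scanned,
        skipped_transcripts=skipped,
    )


class AntigenConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    class_mix: dict[str, int] = {
        "annotated": 12,
        "upstream": 5,
        "out_of_frame": 5,
        "alternative": 5,
        "lncRNA": 3,
    }
    epitope_length: int = 9
    restricted_fraction: float = 0.0


class PipelineConfig(BaseModel):
    """Schema-validated configuration of a full simulated study."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    n_samples: int = 6
    footprint_format: Literal["tsv", "sam"] = "tsv"
    simulate: dict[str, Any] = {}
    antigens: AntigenConfig = AntigenConfig()
    caller: dict[str, Any] = {}
    match_mode: Literal["peptide_containment", "exact_tis"] = "peptide_containment"
    expression_thresholds: tuple[float, ...] = (1.0, 10.0)


def _caller_params(overrides: dict[str, Any]) -> CallerParams:
    overrides = dict(overrides)
    codons = overrides.pop("codon_set", "near")
    if isinstance(codons, str):
        codon_set = ATG_ONLY if codons.upper() == "ATG" else NEAR_COGNATE_START_CODONS
    else:
        codon_set = frozenset(codons)
    for key in ("search_window", "length_range"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return CallerParams(codon_set=codon_set, **overrides)


def sample_seed(seed: int, index: int) -> int:
    """Per-sample child seed, kept below 2**31."""
    return (seed * 1_000_003 + 7_919 * (index + 1)) % (2**31)


def write_offsets(offsets: OffsetMap, path: Path) -> None:
    rows = [
        {
            "read_length": L,
            "offset": offsets.offsets[L],
            "score": offsets.profiles.get(L, {}).get(offsets.offsets[L], ""),
            "n_reads": offsets.n_reads.get(L, ""),
        }
        for L in sorted(offsets.offsets)
    ]
    pd.DataFrame(rows, columns=["read_length", "offset", "score", "n_reads"]).to_csv(
        path, sep="\t", index=False
    )


def load_offsets(path: Path) -> OffsetMap:
    df = pd.read_csv(path, sep="\t")
    return OffsetMap(
        offsets={int(r.read_length): int(r.offset) for r in df.itertuples()},
        n_reads={int(r.read_length): int(r.n_reads) for r in df.itertuples()},
    )


CALL_COLUMNS = [
    "sample_id",
    "transcript_id",
    "gene_id",
    "tis_position",
    "stop_position",
    "length_aa",
    "peptide",
    "complete",
    "orf_class",
    "cds_overlap_frame",
    "p_value",
    "q_value",
]


def calls_to_frame(calls: list[ORFCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id or "",
            "transcript_id": c.transcript_id,
            "gene_id": c.gene_id,
            "tis_position": c.tis_position,
            "stop_position": "" if c.stop_position is None else c.stop_position,
            "length_aa": c.length_aa,
            "peptide": c.peptide,
            "complete": c.complete,
            "orf_class": c.orf_class or "",
            "cds_overlap_frame": "" if c.cds_overlap_frame is None else c.cds_overlap_frame,
            "p_value": "" if c.p_value is None else f"{c.p_value:.6e}",
            "q_value": "" if c.q_value is None else f"{c.q_value:.6e}",
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> list[ORFCall]:
    calls = []
    for r in df.itertuples(index=False):
        calls.append(
            ORFCall(
                transcript_id=str(r.transcript_id),
                gene_id=str(r.gene_id),
                tis_position=int(r.tis_position),
                stop_position=int(r.stop_position) if str(r.stop_position) else None,
                length_aa=int(r.length_aa),
                peptide=str(r.peptide),
                complete=bool(r.complete) if not isinstance(r.complete, str) else r.complete == "True",
                orf_class=str(r.orf_class) or None,
                cds_overlap_frame=int(r.cds_overlap_frame) if str(r.cds_overlap_frame) else None,
                sample_id=str(r.sample_id) or None,
                p_value=float(r.p_value) if str(r.p_value) else None,
                q_value=float(r.q_value) if str(r.q_value) else None,
            )
        )
    return calls


def load_calls(path: Path) -> list[ORFCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str))


def write_matrix(matrix: DetectionMatrix, path: Path) -> None:
    out = matrix.meta.copy()
    for s in matrix.samples:
        out[f"detected_{s}"] = matrix.detected[s]
    for s in matrix.samples:
        out[f"present_{s}"] = matrix.present[s]
    out["n_detected"] = (matrix.detected & matrix.present).sum(axis=1)
    out["n_present"] = matrix.present.sum(axis=1)
    out.index.name = "orf_id"
    out.to_csv(path, sep="\t")


def load_matrix(path: Path) -> DetectionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="orf_id")
    samples = [c.removeprefix("detected_") for c in df.columns if c.startswith("detected_")]
    detected = df[[f"detected_{s}" for s in samples]].astype(bool)
    detected.columns = samples
    present = df[[f"present_{s}" for s in samples]].astype(bool)
    present.columns = samples
    return DetectionMatrix(
        detected=detected, present=present, meta=df[["class_label", "gene_id"]]
    )


def write_report(
    matrix: DetectionMatrix,
    calls_by_sample: dict[str, list[ORFCall]],
    expression: dict[str, float],
    out_dir: Path,
    thresholds: tuple[float, ...] = (1.0, 10.0),
) -> dict[str, Any]:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = class_summary(calls_by_sample)
    summary.per_sample.to_csv(out_dir / "class_summary_per_sample.tsv", sep="\t")
    summary.union.to_csv(out_dir / "class_summary_union.tsv", sep="\t")
    sens_any = sensitivity(matrix, scope="any_sample")
    sens_all = sensitivity(matrix, scope="all_samples")
    pd.concat(
        {"any_sample": sens_any.table, "all_samples": sens_all.table},
        names=["scope", "class_label"],
    ).to_csv(out_dir / "sensitivity.tsv", sep="\t")
    hist = detection_histogram(matrix)
    hist.to_csv(out_dir / "detection_histogram.tsv", sep="\t")
    strata, no_data = expression_strata(matrix, expression, thresholds)
    strata.to_csv(out_dir / "expression_strata.tsv", sep="\t", index=False)
    no_data.to_csv(out_dir / "expression_no_data.tsv", sep="\t", index=False)
    summary_json = {
        "n_orfs": int(len(matrix.detected)),
        "n_samples": len(matrix.samples),
        "pooled_sensitivity_any_sample_pct": float(
            sens_any.table.loc["pooled", "sensitivity_pct"]
        ),
        "pooled_sensitivity_all_samples_pct": float(
            sens_all.table.loc["pooled", "sensitivity_pct"]
        ),
        "class_shares_pct": {k: float(v) for k, v in summary.shares_pct.items()},
    }
    (out_dir / "summary.json").write_text(json.dumps(summary_json, indent=2) + "\n")
    return summary_json


def run_end_to_end(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Simulate a multi-sample study and analyze it stage by stage.

    Returns the report summary dict; all stage outputs and a provenance
    record land under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, Any] = {"version": __version__, "config": config.model_dump()}

    sim = SimConfig(seed=config.seed, **config.simulate)
    tset, truth = generate_transcriptome(sim)
    write_transcriptome(tset, out_dir / "transcriptome.fa", out_dir / "annotation.tsv")
    write_ground_truth(truth, out_dir / "ground_truth.tsv", out_dir / "expression.tsv")
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    catalog = plant_antigens(
        tset,
        truth,
        class_mix=config.antigens.class_mix,
        epitope_length=config.antigens.epitope_length,
        seed=sample_seed(config.seed, config.n_samples + 1),
        samples=samples,
        restricted_fraction=config.antigens.restricted_fraction,
    )
    write_catalog(catalog, out_dir / "catalog.tsv")
    provenance["simulate"] = {
        "n_transcripts": len(tset),
        "n_planted_orfs": len(truth.planted),
        "n_antigens": len(catalog),
    }

    params = _caller_params(config.caller)
    calls_by_sample: dict[str, list[ORFCall]] = {}
    provenance["samples"] = {}
    for i, s in enumerate(samples):
        fps = simulate_footprints(tset, truth, sim, seed=sample_seed(config.seed, i))
        if config.footprint_format == "sam":
            write_footprints_sam(fps, tset, out_dir / f"footprints_{s}.sam")
        else:
            write_footprints_tsv(fps, out_dir / f"footprints_{s}.tsv")
        result = analyze_sample(fps, tset, params, sample_id=s)
        write_offsets(result.offsets, out_dir / f"offsets_{s}.tsv")
        calls_to_frame(result.calls).to_csv(
            out_dir / f"calls_{s}.tsv", sep="\t", index=False
        )
        calls_by_sample[s] = result.calls
        provenance["samples"][s] = {
            "n_reads": len(fps),
            "n_scanned_positions": result.n_scanned,
            "n_candidates": len(result.candidates),
            "n_calls": len(result.calls),
            "n_skipped_transcripts": len(result.skipped_transcripts),
        }

    matrix = build_matrix(catalog, calls_by_sample, mode=config.match_mode)
    write_matrix(matrix, out_dir / "detection_matrix.tsv")
    summary = write_report(
        matrix,
        calls_by_sample,
        truth.expression,
        out_dir / "report",
        thresholds=config.expression_thresholds,
    )
    provenance["report"] = summary
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return summary
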
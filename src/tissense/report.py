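"""Summary statistics: class tallies, detection sensitivity, expression strata.

Sensitivity is the proportion of true antigen-encoding ORFs that the
profiling pipeline detected, per ORF class and pooled, under one of two
scopes: ``any_sample`` (detected in at least one sample, among ORFs present
in at least one) or ``all_samples`` (detected in every sample, among ORFs
present in every sample).  Percentages are rounded half-away-from-zero to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .antigen_matcher import DetectionMatrix
from .orf_builder import ORFCall
from .orf_classifier import ORF_CLASSES


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round half-away-from-zero, e.g. 63.55 -> 63.6 (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return float("nan")
    return round_pct(100.0 * numerator / denominator)


def matrix_from_class_counts(
    counts: dict[str, tuple[int, int]],
    n_samples: int = 6,
    detected_in: str = "one",
) -> DetectionMatrix:
    """Build a detection matrix from per-class (detected, total) counts.

    Useful for feeding published per-class detection outcomes through the
    sensitivity machinery.  All ORFs are present in every sample; the first
    ``detected`` ORFs of each class are marked detected in the first sample
    (``detected_in="one"``) or in every sample (``"all"``).
    """
    if detected_in not in ("one", "all"):
        raise ValueError(f"detected_in must be 'one' or 'all', got {detected_in!r}")
    samples = [f"S{i + 1}" for i in range(n_samples)]
    orf_ids, det_rows, meta_rows = [], [], []
    for cls in counts:
        detected, total = counts[cls]
        if not 0 <= detected <= total:
            raise ValueError(f"{cls}: detected {detected} outside [0, {total}]")
        for i in range(total):
            orf_ids.append(f"{cls}_{i}")
            hit = i < detected
            det_rows.append(
                [hit] * n_samples if detected_in == "all" else [hit] + [False] * (n_samples - 1)
            )
            meta_rows.append({"class_label": cls, "gene_id": f"{cls}_gene{i}"})
    detected_df = pd.DataFrame(det_rows, index=orf_ids, columns=samples, dtype=bool)
    present = pd.DataFrame(True, index=orf_ids, columns=samples)
    meta = pd.DataFrame(meta_rows, index=orf_ids)
    return DetectionMatrix(detected=detected_df, present=present, meta=meta)


SUMMARY_FIELDS = ["n_tis", "n_genes", "mean_orf_length_aa"]


@dataclass
class ClassSummary:
    """Per-sample and cross-sample-union ORF class tallies."""

    per_sample: pd.DataFrame  # MultiIndex (sample, class) -> SUMMARY_FIELDS
    union: pd.DataFrame  # index class -> SUMMARY_FIELDS
    shares_pct: pd.Series  # class -> % of unique TISs in the union


def _tally(calls: list[ORFCall]) -> pd.DataFrame:
    rows = {}
    by_class: dict[str, list[ORFCall]] = {}
    for c in calls:
        by_class.setdefault(c.orf_class, []).append(c)
    for cls in ORF_CLASSES:
        group = by_class.get(cls, [])
        complete = [c.length_aa for c in group if c.complete]
        rows[cls] = {
            "n_tis": len({(c.transcript_id, c.tis_position) for c in group}),
            "n_genes": len({c.gene_id for c in group}),
            "mean_orf_length_aa": float(np.mean(complete)) if complete else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_FIELDS]
    df.index.name = "orf_class"
    return df


def class_summary(calls_by_sample: dict[str, list[ORFCall]]) -> ClassSummary:
    """Tally TIS and gene counts and mean complete-ORF lengths per class.

    The union counts each (transcript, position) TIS once across samples.
    ``shares_pct`` gives each class's percentage of the union TIS total.
    """
    per_sample = pd.concat(
        {s: _tally(calls) for s, calls in calls_by_sample.items()},
        names=["sample_id", "orf_class"],
    )
    seen: dict[tuple[str, int], ORFCall] = {}
    for calls in calls_by_sample.values():
        for c in calls:
            seen.setdefault((c.transcript_id, c.tis_position), c)
    union = _tally(list(seen.values()))
    total = int(union["n_tis"].sum())
    shares = pd.Series(
        {cls: percentage(int(union.loc[cls, "n_tis"]), total) for cls in union.index},
        name="share_pct",
    )
    return ClassSummary(per_sample=per_sample, union=union, shares_pct=shares)


@dataclass
class SensitivityReport:
    """Detected/total counts and percentage per class plus a pooled row."""

    table: pd.DataFrame  # index class + "pooled"; n_detected, n_total, sensitivity_pct
    scope: str
    class_filter: tuple[str, ...] | None


def sensitivity(
    matrix: DetectionMatrix,
    scope: str = "any_sample",
    class_filter: list[str] | None = None,
) -> SensitivityReport:
    """Per-class and pooled detection sensitivity of the antigen-ORF catalog.

    ``class_filter`` restricts the pooled row (and the table) to the given
    catalog classes; the denominator follows the scope's presence rule.
    """
    if scope == "any_sample":
        in_scope = matrix.present.any(axis=1)
        hit = (matrix.detected & matrix.present).any(axis=1)
    elif scope == "all_samples":
        in_scope = matrix.present.all(axis=1)
        hit = matrix.detected.all(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    classes = matrix.meta["class_label"]
    keep = in_scope
    if class_filter is not None:
        keep = keep & classes.isin(class_filter)
    rows = {}
    for cls in classes[keep].unique():
        sel = keep & (classes == cls)
        rows[cls] = {"n_detected": int(hit[sel].sum()), "n_total": int(sel.sum())}
    rows["pooled"] = {"n_detected": int(hit[keep].sum()), "n_total": int(keep.sum())}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["sensitivity_pct"] = [
        percentage(r.n_detected, r.n_total) for r in table.itertuples()
    ]
    table.index.name = "class_label"
    return SensitivityReport(
        table=table,
        scope=scope,
        class_filter=tuple(class_filter) if class_filter else None,
    )


def detection_histogram(matrix: DetectionMatrix) -> pd.Series:
    """ORF counts by the number of samples in which each was detected (0..n)."""
    n = len(matrix.samples)
    per_orf = (matrix.detected & matrix.present).sum(axis=1)
    counts = np.bincount(per_orf.to_numpy(), minlength=n + 1)
    hist = pd.Series(counts, index=range(n + 1), name="n_orfs")
    hist.index.name = "n_samples_detected"
    assert int(hist.sum()) == len(matrix.detected)
    return hist


def expression_strata(
    matrix: DetectionMatrix,
    expression: dict[str, float],
    thresholds: tuple[float, ...] = (1.0, 10.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tab of detection count x expression bin x catalog class.

    Returns ``(table, no_data)``: ``table`` is long-form with columns
    class_label, expression_bin, n_samples_detected, n_orfs over ORFs whose
    gene has an expression value; ORFs lacking one are tallied separately
    in ``no_data``, not silently dropped.
    """
    edges = [0.0, *thresholds, float("inf")]
    labels = (
        [f"<{thresholds[0]:g}"]
        + [f"{lo:g}-{hi:g}" for lo, hi in zip(thresholds[:-1], thresholds[1:])]
        + [f">{thresholds[-1]:g}"]
    )
    per_orf = (matrix.detected & matrix.present).sum(axis=1)
    rows = []
    missing: dict[str, int] = {}
    for orf_id in matrix.detected.index:
        gene = matrix.meta.loc[orf_id, "gene_id"]
        cls = matrix.meta.loc[orf_id, "class_label"]
        if gene not in expression:
            missing[cls] = missing.get(cls, 0) + 1
            continue
        rpkm = expression[gene]
        bin_idx = int(np.searchsorted(edges[1:-1], rpkm, side="right"))
        rows.append(
            {
                "class_label": cls,
                "expression_bin": labels[bin_idx],
                "n_samples_detected": int(per_orf[orf_id]),
                "n_orfs": 1,
            }
        )
    table = (
        pd.DataFrame(rows, columns=["class_label", "expression_bin", "n_samples_detected", "n_orfs"])
        .groupby(["class_label", "expression_bin", "n_samples_detected"], as_index=False)
        .sum()
    )
    no_data = pd.DataFrame(
        [{"class_label": c, "n_orfs": n} for c, n in sorted(missing.items())],
        columns=["class_label", "n_orfs"],
    )
    return table, no_data
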
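"""Repeat-family RNA quantification with DNA-transposon background adjustment.

The quantification chain is

    counts -> FPKM -> background-adjusted FPKM -> adjusted cpm -> log2FC

with FPKM = count * 1e9 / (unit_length_bp * library_size). The background
level B is the pooled FPKM of the inactive DNA-transposon classes
(transpositionally dead repeats that should carry no genuine transcription);
adjusted FPKM is max(FPKM - B, 0), and multiplying back by unit length in kb
returns the value to the cpm scale, so background removal is the only net
transformation. Fold changes between conditions are computed on
median-of-ratios-normalized adjusted cpm with a pseudocount, without any
dispersion shrinkage or significance testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AlignedFragmentSet, RepeatAnnotation, SampleManifest
from .chip import FamilyCountTable
from .errors import UsageError, ValidationError

log = logging.getLogger(__name__)

POOLED_BACKGROUND_UNIT = "__background_pooled__"
BACKGROUND_MODES = ("pooled", "mean_of_units")


@dataclass
class FilterReport:
    """Per-sample accounting of the rRNA/mRNA read filter.

    input = removed_rrna + removed_mrna + retained, with rRNA taking
    priority over mRNA for reads overlapping both.
    """

    table: pd.DataFrame  # rows: sample; cols: input, removed_rrna, removed_mrna, retained

    def validate(self) -> None:
        t = self.table
        if not (t["input"] == t[["removed_rrna", "removed_mrna", "retained"]].sum(axis=1)).all():
            raise ValidationError("filter report violates conservation")


@dataclass
class ExpressionTable:
    """Per-unit expression values across samples.

    ``background_fpkm`` (B) is recorded per sample once
    :func:`background_adjust` has run; the pooled background row
    ``__background_pooled__`` then has adjusted values identically zero.
    """

    counts: pd.DataFrame
    unit_length: pd.Series
    library_size: pd.Series
    row_meta: pd.DataFrame
    fpkm: pd.DataFrame
    adjusted_fpkm: pd.DataFrame | None = None
    adjusted_cpm: pd.DataFrame | None = None
    background_fpkm: pd.Series | None = None
    background_mode: str | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DifferentialTable:
    """Per-unit condition means (normalized adjusted cpm) and log2FC."""

    table: pd.DataFrame  # mean_a_cpm, mean_b_cpm, log2fc (+ row meta columns)
    condition_a: str
    condition_b: str
    pseudocount_cpm: float
    size_factors: pd.Series


# ---------------------------------------------------------------------------
# read filtering
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: Sequence[tuple[str, int, int]]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in intervals:
        by_contig.setdefault(contig, []).append((start, end))
    out = {}
    for contig, spans in by_contig.items():
        spans.sort()
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype="int64").reshape(-1, 2)
        out[contig] = (arr[:, 0], arr[:, 1])
    return out


def _overlaps_any(
    fragments: AlignedFragmentSet, merged: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Boolean per fragment: >=1 bp overlap with any merged interval."""
    f = fragments.frame
    out = np.zeros(len(f), dtype=bool)
    contigs = f["contig"].to_numpy()
    starts = f["start"].to_numpy()
    ends = f["end"].to_numpy()
    for contig, (ms, me) in merged.items():
        sel = contigs == contig
        if not sel.any():
            continue
        s, e = starts[sel], ends[sel]
        # fragment [s, e) overlaps some [ms_i, me_i) iff the first interval
        # ending after s starts before e
        idx = np.searchsorted(me, s, side="right")
        hit = (idx < len(ms)) & (ms[np.clip(idx, 0, len(ms) - 1)] < e)
        out[np.flatnonzero(sel)] = hit
    return out


def filter_reads(
    fragments: AlignedFragmentSet,
    rrna_intervals: Sequence[tuple[str, int, int]] = (),
    mrna_intervals: Sequence[tuple[str, int, int]] = (),
    sample_id: str = "sample",
) -> tuple[AlignedFragmentSet, FilterReport]:
    """Drop fragments overlapping rRNA (first) or mRNA (second) intervals.

    A fragment overlapping both sets is attributed to rRNA only.
    """
    n_in = len(fragments)
    is_rrna = (
        _overlaps_any(fragments, _merge_intervals(rrna_intervals))
        if len(rrna_intervals)
        else np.zeros(n_in, dtype=bool)
    )
    is_mrna = (
        _overlaps_any(fragments, _merge_intervals(mrna_intervals))
        if len(mrna_intervals)
        else np.zeros(n_in, dtype=bool)
    )
    is_mrna &= ~is_rrna
    keep = ~(is_rrna | is_mrna)
    retained = AlignedFragmentSet(
        fragments.frame.loc[keep].reset_index(drop=True).copy(),
        fragments.n_skipped_unmapped,
    )
    report = FilterReport(
        pd.DataFrame(
            {
                "input": [n_in],
                "removed_rrna": [int(is_rrna.sum())],
                "removed_mrna": [int(is_mrna.sum())],
                "retained": [int(keep.sum())],
            },
            index=pd.Index([sample_id], name="sample_id"),
        )
    )
    report.validate()
    return retained, report


# ---------------------------------------------------------------------------
# FPKM and background adjustment
# ---------------------------------------------------------------------------


def fpkm(counts: FamilyCountTable) -> ExpressionTable:
    """FPKM = count * 1e9 / (unit_length_bp * library_size)."""
    if (counts.library_size <= 0).any():
        zero = list(counts.library_size.index[counts.library_size <= 0])
        raise ValidationError(f"zero/negative library size for samples {zero}")
    lib = counts.library_size.reindex(counts.counts.columns).astype(float)
    lengths = counts.unit_length.reindex(counts.counts.index).astype(float)
    table = counts.counts.astype(float).mul(1e9).div(lib, axis=1).div(lengths, axis=0)
    return ExpressionTable(
        counts=counts.counts,
        unit_length=counts.unit_length,
        library_size=counts.library_size,
        row_meta=counts.row_meta,
        fpkm=table,
    )


def background_adjust(
    expr: ExpressionTable,
    annotation: RepeatAnnotation | None = None,
    background_classes: Sequence[str] | None = None,
    background_mode: str = "pooled",
) -> ExpressionTable:
    """Subtract the DNA-transposon background FPKM, flooring at zero.

    pooled (default): B = total background-class count * 1e9 /
    (total background-class bp * library_size) per sample, i.e. the FPKM of
    all background repeats treated as one unit. mean_of_units: B is the
    mean of the per-unit FPKMs of the background units. A pooled background
    row is appended whose adjusted values are zero by construction (pooled
    mode). adjusted_cpm = adjusted_fpkm * unit_length / 1000.
    """
    if background_mode not in BACKGROUND_MODES:
        raise UsageError(f"background_mode must be one of {BACKGROUND_MODES}")
    if background_classes is None:
        if annotation is None:
            background_classes = ("DNA",)
        else:
            background_classes = tuple(annotation.background_classes)
    if not background_classes:
        raise ValidationError("no background classes configured")
    bg_rows = expr.row_meta.index[expr.row_meta["class_"].isin(background_classes)]
    bg_rows = [u for u in bg_rows if u in expr.counts.index]
    if not bg_rows:
        raise ValidationError(
            f"background classes {tuple(background_classes)} absent from the count table"
        )
    lib = expr.library_size.reindex(expr.counts.columns).astype(float)
    bg_len = float(expr.unit_length.loc[bg_rows].sum())
    bg_counts = expr.counts.loc[bg_rows].sum(axis=0).astype(float)
    if background_mode == "pooled":
        B = bg_counts * 1e9 / (bg_len * lib)
    else:
        B = expr.fpkm.loc[bg_rows].mean(axis=0)
    B.name = "background_fpkm"

    fpkm_ext = expr.fpkm.copy()
    counts_ext = expr.counts.copy()
    lengths_ext = expr.unit_length.copy()
    meta_ext = expr.row_meta.copy()
    # pooled background unit: FPKM == B in pooled mode, so adjusted == 0
    fpkm_ext.loc[POOLED_BACKGROUND_UNIT] = bg_counts * 1e9 / (bg_len * lib)
    counts_ext.loc[POOLED_BACKGROUND_UNIT] = expr.counts.loc[bg_rows].sum(axis=0)
    lengths_ext.loc[POOLED_BACKGROUND_UNIT] = bg_len
    meta_ext.loc[POOLED_BACKGROUND_UNIT] = {
        "class_": "+".join(background_classes),
        "family": "pooled_background",
    }

    adjusted_fpkm = (fpkm_ext - B).clip(lower=0.0)
    adjusted_cpm = adjusted_fpkm.mul(lengths_ext.reindex(adjusted_fpkm.index) / 1000.0, axis=0)
    return ExpressionTable(
        counts=counts_ext,
        unit_length=lengths_ext,
        library_size=expr.library_size,
        row_meta=meta_ext,
        fpkm=fpkm_ext,
        adjusted_fpkm=adjusted_fpkm,
        adjusted_cpm=adjusted_cpm,
        background_fpkm=B,
        background_mode=background_mode,
    )


# ---------------------------------------------------------------------------
# fold change and reactivation calls
# ---------------------------------------------------------------------------


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Classical median-of-ratios size factors.

    Per sample, the median over units (restricted to units with a strictly
    positive geometric mean across samples) of count / geometric-mean.
    Returns all-ones when no unit is positive in every sample.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        log.warning("size factors undefined (no all-positive unit); falling back to 1.0")
        return pd.Series(1.0, index=counts.columns, name="size_factor")
    sub = arr[positive]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(sub) - log_gm, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _normalized_adjusted_cpm(expr: ExpressionTable) -> tuple[pd.DataFrame, pd.Series]:
    if expr.adjusted_cpm is None:
        raise UsageError("run background_adjust before log2fc")
    sf = median_of_ratios_size_factors(expr.counts.drop(index=POOLED_BACKGROUND_UNIT, errors="ignore"))
    lib = expr.library_size.reindex(expr.counts.columns).astype(float)
    # cpm already divides by library size; the residual composition factor is
    # sf relative to depth, rescaled to geometric mean 1 across samples
    resid = sf * float(np.exp(np.mean(np.log(lib)))) / lib
    resid = resid / float(np.exp(np.mean(np.log(resid))))
    normalized = expr.adjusted_cpm.div(resid, axis=1)
    return normalized, sf


def log2fc(
    expr: ExpressionTable,
    manifest: SampleManifest,
    condition_a: str,
    condition_b: str,
    pseudocount_cpm: float = 0.5,
) -> DifferentialTable:
    """Per-unit log2 fold change of condition_a over condition_b.

    Replicate means are taken on median-of-ratios-normalized adjusted cpm;
    log2FC = log2((mean_a + p) / (mean_b + p)) with pseudocount p in cpm.
    """
    if pseudocount_cpm <= 0:
        raise UsageError("pseudocount_cpm must be > 0")
    normalized, sf = _normalized_adjusted_cpm(expr)
    ids_a = [
        e.sample_id
        for e in manifest.select(assay="rna", condition=condition_a)
        if e.sample_id in normalized.columns
    ]
    ids_b = [
        e.sample_id
        for e in manifest.select(assay="rna", condition=condition_b)
        if e.sample_id in normalized.columns
    ]
    if not ids_a or not ids_b:
        raise UsageError(
            f"need >=1 RNA replicate per condition; found {len(ids_a)} for "
            f"{condition_a!r} and {len(ids_b)} for {condition_b!r}"
        )
    for cond, ids in ((condition_a, ids_a), (condition_b, ids_b)):
        if float(expr.counts[ids].to_numpy().sum()) == 0:
            raise ValidationError(f"condition {cond!r} has all-zero counts")
    mean_a = normalized[ids_a].mean(axis=1)
    mean_b = normalized[ids_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount_cpm) / (mean_b + pseudocount_cpm))
    table = pd.DataFrame(
        {"mean_a_cpm": mean_a, "mean_b_cpm": mean_b, "log2fc": lfc}
    ).join(expr.row_meta)
    return DifferentialTable(
        table=table,
        condition_a=condition_a,
        condition_b=condition_b,
        pseudocount_cpm=pseudocount_cpm,
        size_factors=sf,
    )


def reactivation_report(
    contrasts: Mapping[str, DifferentialTable],
    log2fc_threshold: float = 1.0,
    min_cpm: float = 1.0,
    exclude_classes: Sequence[str] = ("DNA",),
) -> pd.DataFrame:
    """Units called reactivated per contrast.

    A unit is called when log2FC > threshold and its treatment-condition
    mean adjusted cpm exceeds ``min_cpm``. Units of the background classes
    (DNA transposons by default) are listed but never called: they are the
    subtraction reference, so their adjusted expression sits at the
    detection floor where fold changes are dominated by floored noise.
    The report carries per-unit calls with class/family labels so
    per-class tallies are a groupby away.
    """
    rows = []
    for name, diff in contrasts.items():
        t = diff.table
        called = (
            (t["log2fc"] > log2fc_threshold)
            & (t["mean_a_cpm"] > min_cpm)
            & ~t["class_"].isin(exclude_classes)
        )
        for unit in t.index:
            if unit == POOLED_BACKGROUND_UNIT:
                continue
            rows.append(
                {
                    "contrast": name,
                    "unit": unit,
                    "class_": t.loc[unit, "class_"],
                    "family": t.loc[unit, "family"],
                    "log2fc": t.loc[unit, "log2fc"],
                    "mean_treatment_cpm": t.loc[unit, "mean_a_cpm"],
                    "reactivated": bool(called.loc[unit]),
                }
            )
    return pd.DataFrame(rows)


def reactivation_tallies(report: pd.DataFrame) -> pd.DataFrame:
    """Per-contrast, per-class/family counts of reactivated units."""
    if report.empty:
        return pd.DataFrame(columns=["contrast", "class_", "family", "n_units", "n_reactivated"])
    g = report.groupby(["contrast", "class_", "family"], sort=True)
    out = g.agg(n_units=("unit", "size"), n_reactivated=("reactivated", "sum")).reset_index()
    out["n_reactivated"] = out["n_reactivated"].astype(int)
    return out
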
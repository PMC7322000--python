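"""Methylation-dependent interaction screen on unique-peptide counts.

Proteins co-purifying with a bait under two methylation states (e.g.
wild-type vs Dnmt1-null cells) are ranked by the pseudocounted ratio

    R = (n_ref + c) / (n_cmp + c),        c = 1 by default,

where n_ref / n_cmp are unique-peptide counts in the reference
(methylated) and comparison (demethylated) condition. The display filter
keeps proteins detected by at least ``min_total_peptides`` peptides in
either condition; the hit filter additionally requires > ``hit_min_peptides``
peptides and a > ``hit_fold`` depletion in the comparison condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UsageError, ValidationError


@dataclass
class PeptideCountTable:
    """Protein-level unique-peptide counts in exactly two conditions."""

    counts: pd.DataFrame  # index: protein; columns: [ref_condition, cmp_condition]
    ref_condition: str
    cmp_condition: str

    def __post_init__(self) -> None:
        cols = list(self.counts.columns)
        if cols != [self.ref_condition, self.cmp_condition]:
            if set(cols) == {self.ref_condition, self.cmp_condition}:
                self.counts = self.counts[[self.ref_condition, self.cmp_condition]]
            else:
                raise UsageError(
                    f"count table columns {cols} do not match conditions "
                    f"({self.ref_condition!r}, {self.cmp_condition!r})"
                )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValidationError("peptide counts must be integers")
            self.counts = self.counts.astype("int64")
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("peptide counts must be non-negative")

    def swapped(self) -> "PeptideCountTable":
        return PeptideCountTable(
            self.counts[[self.cmp_condition, self.ref_condition]],
            ref_condition=self.cmp_condition,
            cmp_condition=self.ref_condition,
        )


@dataclass
class ScreenResult:
    """Ranked screen output; rows sorted by R descending."""

    table: pd.DataFrame  # n_ref, n_cmp, ratio, log2_ratio, shown, hit, rank
    pseudocount: float
    ref_condition: str
    cmp_condition: str
    params: dict


def read_peptide_counts(
    path: str | Path, ref_condition: str, cmp_condition: str
) -> PeptideCountTable:
    """Read a TSV of (protein, <condition columns>) unique-peptide counts."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    for cond in (ref_condition, cmp_condition):
        if cond not in frame.columns:
            raise UsageError(f"{path}: no column {cond!r}; found {list(frame.columns)}")
    return PeptideCountTable(
        frame[[ref_condition, cmp_condition]], ref_condition, cmp_condition
    )


def screen(
    table: PeptideCountTable,
    pseudocount: float = 1.0,
    min_total_peptides: int = 3,
    hit_min_peptides: int = 6,
    hit_fold: float = 2.0,
    hit_on_best_condition: bool = True,
    raw_ratio_filter: bool = False,
) -> ScreenResult:
    """Rank proteins by the pseudocounted methylation-dependence ratio.

    shown: max(n_ref, n_cmp) >= min_total_peptides (default 3).
    hit: detection > hit_min_peptides peptides (default 6; max over the two
    conditions unless ``hit_on_best_condition`` is False, then reference
    only) AND R > hit_fold (default 2). With ``raw_ratio_filter`` the fold
    condition is evaluated on raw counts (n_ref > hit_fold * n_cmp) while
    R and the ranking stay pseudocounted. Ranking is by R descending with
    ties broken by n_ref descending then protein id, so output order is
    byte-stable.
    """
    if pseudocount <= 0:
        raise UsageError("pseudocount must be > 0")
    if min_total_peptides < 0 or hit_min_peptides < 0 or hit_fold < 0:
        raise UsageError("thresholds must be >= 0")
    n_ref = table.counts[table.ref_condition]
    n_cmp = table.counts[table.cmp_condition]
    ratio = (n_ref + pseudocount) / (n_cmp + pseudocount)
    log2_ratio = np.log2(ratio)
    best = np.maximum(n_ref, n_cmp)
    shown = best >= min_total_peptides
    detected = best if hit_on_best_condition else n_ref
    fold_ok = (n_ref > hit_fold * n_cmp) if raw_ratio_filter else (ratio > hit_fold)
    hit = (detected > hit_min_peptides) & fold_ok
    out = pd.DataFrame(
        {
            "n_ref": n_ref,
            "n_cmp": n_cmp,
            "ratio": ratio,
            "log2_ratio": log2_ratio,
            "shown": shown,
            "hit": hit,
        }
    )
    out = out.assign(_protein=out.index.astype(str))
    out = out.sort_values(
        by=["ratio", "n_ref", "_protein"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_protein")
    out["rank"] = np.arange(1, len(out) + 1)
    return ScreenResult(
        table=out,
        pseudocount=pseudocount,
        ref_condition=table.ref_condition,
        cmp_condition=table.cmp_condition,
        params={
            "min_total_peptides": min_total_peptides,
            "hit_min_peptides": hit_min_peptides,
            "hit_fold": hit_fold,
            "hit_on_best_condition": hit_on_best_condition,
        },
    )


def top_dependent(result: ScreenResult, margin: float = 2.0) -> dict:
    """The rank-1 shown protein and its separation from the runner-up.

    separation = R(top) / R(second shown protein); ``clear_top`` flags
    separation >= margin (default 2, the strong-dependence criterion).
    """
    shown = result.table[result.table["shown"]]
    if len(shown) < 2:
        raise ValidationError("top_dependent needs >=2 shown proteins")
    top, second = shown.index[0], shown.index[1]
    separation = float(shown["ratio"].iloc[0] / shown["ratio"].iloc[1])
    return {
        "protein": top,
        "ratio": float(shown["ratio"].iloc[0]),
        "runner_up": second,
        "separation": separation,
        "clear_top": separation >= margin,
        "margin": margin,
    }


def export_scatter(result: ScreenResult, path: str | Path) -> None:
    """Plot-ready TSV on the pseudocounted scale (both axes log-safe)."""
    c = result.pseudocount
    out = pd.DataFrame(
        {
            "protein": result.table.index,
            "ref_plus_pseudocount": result.table["n_ref"] + c,
            "cmp_plus_pseudocount": result.table["n_cmp"] + c,
            "shown": result.table["shown"],
            "hit": result.table["hit"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_screen_tsv(result: ScreenResult, path: str | Path) -> None:
    result.table.rename_axis("protein").to_csv(path, sep="\t")
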
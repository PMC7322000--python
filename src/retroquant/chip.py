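"""ChIP-seq enrichment at repeat families, ICRs, and LTR metaprofiles.

The core statistic is the depth-normalized ratio

    E(unit) = mean_cpm(treatment replicates) / mean_cpm(control replicates)

with cpm = count * 1e6 / library_size, computed per repeat unit (subfamily
by default) after duplicate removal. Replicates are averaged on the cpm
scale so a deeply sequenced replicate cannot dominate the mean. Units whose
control mean is zero are flagged rather than assigned an infinite ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import (
    AlignedFragmentSet,
    IcrInterval,
    RepeatAnnotation,
    RepeatInterval,
    SampleManifest,
)
from .errors import UsageError, ValidationError

log = logging.getLogger(__name__)

COUNT_MODES = ("midpoint", "any_overlap", "fractional")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FamilyCountTable:
    """Fragment counts per repeat unit (rows) per sample (columns).

    ``unit_length`` is the summed bp of each unit's intervals;
    ``library_size`` is the total mapped (deduplicated) fragments per
    sample, of which ``unassigned`` fell outside every unit.
    """

    counts: pd.DataFrame
    unit_length: pd.Series
    library_size: pd.Series
    unassigned: pd.Series
    row_meta: pd.DataFrame
    level: str = "subfamily"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count in FamilyCountTable")
        if (self.unit_length.reindex(self.counts.index) <= 0).any():
            raise ValidationError("every quantified unit needs positive length")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def cpm(self) -> pd.DataFrame:
        lib = self.library_size.reindex(self.counts.columns)
        if (lib <= 0).any():
            raise ValidationError("library_size must be positive for cpm")
        return self.counts * 1e6 / lib

    def merge(self, other: "FamilyCountTable") -> "FamilyCountTable":
        """Column-wise merge of two tables over the same units."""
        if not self.counts.index.equals(other.counts.index):
            raise ValidationError("cannot merge count tables with different units")
        return FamilyCountTable(
            counts=pd.concat([self.counts, other.counts], axis=1),
            unit_length=self.unit_length,
            library_size=pd.concat([self.library_size, other.library_size]),
            unassigned=pd.concat([self.unassigned, other.unassigned]),
            row_meta=self.row_meta,
            level=self.level,
        )


@dataclass
class EnrichmentTable:
    """Per-unit treatment/control cpm means and their ratio E."""

    table: pd.DataFrame  # mean_treatment_cpm, mean_control_cpm, ratio, enriched, control_zero
    n_treatment: int
    n_control: int
    tau: float


@dataclass
class MetaProfile:
    """Mean coverage across element copies, rescaled per segment.

    ``values`` has ``3 * n_bins`` entries spanning 5'LTR, internal and
    3'LTR; bin 0 is always the element's 5' end (minus-strand copies are
    reversed before averaging). ``contrast`` is mean(5'LTR)/mean(3'LTR).
    """

    values: np.ndarray
    n_bins: int
    n_elements: int
    contrast: float

    @property
    def segment_means(self) -> dict[str, float]:
        b = self.n_bins
        return {
            "five_prime_ltr": float(self.values[:b].mean()),
            "internal": float(self.values[b : 2 * b].mean()),
            "three_prime_ltr": float(self.values[2 * b :].mean()),
        }


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def deduplicate(fragments: AlignedFragmentSet) -> AlignedFragmentSet:
    """Remove duplicate fragments sharing (contig, start, strand).

    The first fragment in (contig, start, end) sort order is retained from
    each duplicate group, mirroring samtools-style rmdup on single-end
    data. Idempotent; unsorted input is sorted first with a log notice.
    """
    if not fragments.is_sorted():
        log.info("deduplicate: input not sorted; sorting internally")
        fragments = fragments.sorted()
    f = fragments.frame
    keep = ~f.duplicated(subset=["contig", "start", "strand"], keep="first")
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("deduplicate: removed %d duplicate fragments", n_removed)
    out = f.loc[keep].reset_index(drop=True).copy()
    return AlignedFragmentSet(out, fragments.n_skipped_unmapped)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def _interval_arrays(
    intervals: Sequence[RepeatInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray, list[RepeatInterval]]]:
    """Per-contig (starts, ends, intervals) sorted by start."""
    by_contig: dict[str, list[RepeatInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out = {}
    for contig, ivs in by_contig.items():
        ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end, iv.instance_id))
        out[contig] = (
            np.array([iv.start for iv in ivs], dtype="int64"),
            np.array([iv.end for iv in ivs], dtype="int64"),
            ivs,
        )
    return out


def _contig_disjoint(starts: np.ndarray, ends: np.ndarray) -> bool:
    return bool((starts[1:] >= ends[:-1]).all()) if len(starts) > 1 else True


def _assign_midpoint(
    fragments: AlignedFragmentSet,
    arrays: dict[str, tuple[np.ndarray, np.ndarray, list[RepeatInterval]]],
    unit_of: Mapping[str, str],
    unit_pos: Mapping[str, int],
) -> tuple[np.ndarray, int]:
    """Unit index per fragment (-1 = unassigned) under the midpoint rule."""
    f = fragments.frame
    mids = fragments.midpoints
    assign = np.full(len(f), -1, dtype="int64")
    contigs = f["contig"].to_numpy()
    for contig, (starts, ends, ivs) in arrays.items():
        sel = np.flatnonzero(contigs == contig)
        if sel.size == 0:
            continue
        m = mids[sel]
        if _contig_disjoint(starts, ends):
            unit_idx = np.array(
                [unit_pos[unit_of[iv.instance_id]] for iv in ivs], dtype="int64"
            )
            idx = np.searchsorted(starts, m, side="right") - 1
            ok = (idx >= 0) & (m < ends[np.clip(idx, 0, None)])
            assign[sel[ok]] = unit_idx[idx[ok]]
        else:
            tree = IntervalTree.from_tuples((iv.start, iv.end, iv) for iv in ivs)
            for j, mid in zip(sel, m):
                hits = [h.data for h in tree.at(mid)]
                if hits:
                    best = min(hits, key=lambda iv: (iv.start, iv.instance_id))
                    assign[j] = unit_pos[unit_of[best.instance_id]]
    n_unassigned = int((assign < 0).sum())
    return assign, n_unassigned


def _overlap_hits(tree: IntervalTree, start: int, end: int) -> list:
    return [h.data for h in tree.overlap(start, end)]


def count_by_unit(
    fragments: AlignedFragmentSet | Mapping[str, AlignedFragmentSet],
    annotation: RepeatAnnotation,
    level: str = "subfamily",
    mode: str = "midpoint",
    sample_id: str = "sample",
) -> FamilyCountTable:
    """Count fragments per repeat unit for one sample or a mapping of samples.

    midpoint (default): a fragment belongs to the unit containing its floor
    midpoint (at most one). any_overlap: the unit with maximal overlap, ties
    to the smaller start then lexicographic instance_id. fractional:
    overlap-proportional weights summing to <= 1 per fragment.
    """
    if len(annotation) == 0:
        raise ValidationError("count_by_unit: empty annotation")
    if mode not in COUNT_MODES:
        raise UsageError(f"unknown counting mode {mode!r}; expected one of {COUNT_MODES}")
    if isinstance(fragments, AlignedFragmentSet):
        fragments = {sample_id: fragments}

    unit_lengths = annotation.unit_lengths(level)
    units = list(unit_lengths.index)
    unit_pos = {u: i for i, u in enumerate(units)}
    unit_of = {iv.instance_id: iv.unit(level) for iv in annotation.intervals}
    arrays = _interval_arrays(annotation.intervals)

    dtype = float if mode == "fractional" else "int64"
    counts = pd.DataFrame(
        np.zeros((len(units), len(fragments)), dtype=dtype),
        index=pd.Index(units, name="unit"),
        columns=list(fragments),
    )
    library_size = pd.Series({s: len(fs) for s, fs in fragments.items()}, name="library_size")
    unassigned = pd.Series(0, index=list(fragments), name="unassigned", dtype=dtype)

    trees: dict[str, IntervalTree] | None = None
    if mode in ("any_overlap", "fractional"):
        trees = {
            contig: IntervalTree.from_tuples((iv.start, iv.end, iv) for iv in ivs)
            for contig, (_, _, ivs) in arrays.items()
        }

    for sid, fragset in fragments.items():
        f = fragset.frame
        if mode == "midpoint":
            assign, n_un = _assign_midpoint(fragset, arrays, unit_of, unit_pos)
            vals = np.bincount(assign[assign >= 0], minlength=len(units))
            counts[sid] = vals
            unassigned[sid] = n_un
        elif mode == "any_overlap":
            col = np.zeros(len(units), dtype="int64")
            n_un = 0
            for contig, start, end in zip(f["contig"], f["start"], f["end"]):
                hits = _overlap_hits(trees[contig], start, end) if contig in trees else []
                if not hits:
                    n_un += 1
                    continue
                best = max(
                    hits,
                    key=lambda iv: (
                        min(end, iv.end) - max(start, iv.start),
                        -iv.start,
                        _NegStr(iv.instance_id),
                    ),
                )
                col[unit_pos[unit_of[best.instance_id]]] += 1
            counts[sid] = col
            unassigned[sid] = n_un
        else:  # fractional
            col = np.zeros(len(units), dtype=float)
            n_un = 0.0
            for contig, start, end in zip(f["contig"], f["start"], f["end"]):
                hits = _overlap_hits(trees[contig], start, end) if contig in trees else []
                if not hits:
                    n_un += 1.0
                    continue
                flen = end - start
                total_w = 0.0
                for iv in hits:
                    w = (min(end, iv.end) - max(start, iv.start)) / flen
                    col[unit_pos[unit_of[iv.instance_id]]] += w
                    total_w += w
                n_un += max(0.0, 1.0 - total_w)
            counts[sid] = col
            unassigned[sid] = n_un

    return FamilyCountTable(
        counts=counts,
        unit_length=unit_lengths,
        library_size=library_size,
        unassigned=unassigned,
        row_meta=annotation.unit_meta(level),
        level=level,
    )


class _NegStr:
    """Reverse-order key wrapper so max() picks the lexicographically smaller id."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrichment(
    counts: FamilyCountTable,
    manifest: SampleManifest,
    treatment_key: Mapping[str, str],
    control_key: Mapping[str, str],
    tau: float = 1.5,
) -> EnrichmentTable:
    """Treatment-over-control cpm ratio per unit.

    ``treatment_key``/``control_key`` are manifest field matches, e.g.
    ``{"assay": "chip", "target": "O-GlcNAc", "condition": "WT"}``. Rows
    whose control cpm mean is zero are flagged ``control_zero`` and
    excluded from the enriched classification.
    """
    t_ids = [e.sample_id for e in manifest.select(**treatment_key) if e.sample_id in counts.samples]
    c_ids = [e.sample_id for e in manifest.select(**control_key) if e.sample_id in counts.samples]
    if not t_ids or not c_ids:
        raise UsageError(
            f"no samples for treatment={dict(treatment_key)} control={dict(control_key)}; "
            f"available (assay, target, condition) keys: {manifest.available_keys()}"
        )
    cpm = counts.cpm()
    mean_t = cpm[t_ids].mean(axis=1)
    mean_c = cpm[c_ids].mean(axis=1)
    control_zero = mean_c == 0
    ratio = pd.Series(np.nan, index=cpm.index, dtype=float)
    ratio.loc[~control_zero] = mean_t[~control_zero] / mean_c[~control_zero]
    table = pd.DataFrame(
        {
            "mean_treatment_cpm": mean_t,
            "mean_control_cpm": mean_c,
            "ratio": ratio,
            "control_zero": control_zero,
            "enriched": (~control_zero) & (ratio > tau),
        }
    )
    return EnrichmentTable(table=table, n_treatment=len(t_ids), n_control=len(c_ids), tau=tau)


def icrs_as_annotation(icrs: Sequence[IcrInterval]) -> RepeatAnnotation:
    """Recast ICR intervals as a one-unit-per-ICR annotation for counting."""
    if not icrs:
        raise ValidationError("empty ICR set")
    return RepeatAnnotation(
        [
            RepeatInterval(
                icr.contig, icr.start, icr.end, "+", icr.name, "ICR", "ICR", f"{icr.name}.1", "unassigned"
            )
            for icr in icrs
        ],
        background_classes=(),
    )


def icr_occupancy(
    fragments_by_sample: Mapping[str, AlignedFragmentSet],
    icrs: Sequence[IcrInterval],
    manifest: SampleManifest,
    targets: Sequence[str],
    tau: float = 1.5,
    condition: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Per-ICR enrichment for each ChIP target, plus a cross-classification.

    For each target, treatment samples are its ChIP replicates and the
    control group is the matched input/IgG set from the manifest. ICRs with
    a zero control mean for any target are excluded from the summary
    denominators. The summary reports, over evaluable ICRs, how many are
    enriched in each single target, in both/all, in at least one, and in
    none at threshold ``tau``.
    """
    if len(targets) < 2:
        raise UsageError("icr_occupancy requires >=2 targets")
    ann = icrs_as_annotation(icrs)
    counts = count_by_unit(dict(fragments_by_sample), ann, level="subfamily", mode="midpoint")
    per_target: dict[str, pd.DataFrame] = {}
    for target in targets:
        chip_entries = manifest.select(assay="chip", target=target)
        if condition:
            chip_entries = [e for e in chip_entries if e.condition == condition]
        if not chip_entries:
            raise UsageError(f"no ChIP samples for target {target!r} in manifest")
        cond = chip_entries[0].condition
        controls = manifest.controls_for(target, cond)
        if not controls:
            raise UsageError(f"no control samples for target {target!r}")
        ctrl = controls[0]
        res = enrichment(
            counts,
            manifest,
            {"assay": "chip", "target": target, "condition": cond},
            {"assay": ctrl.assay, "target": ctrl.target, "condition": ctrl.condition},
            tau=tau,
        )
        per_target[target] = res.table
    table = pd.concat(per_target, axis=1)
    evaluable = ~np.logical_or.reduce(
        [per_target[t]["control_zero"].to_numpy() for t in targets]
    )
    flags = pd.DataFrame({t: per_target[t]["enriched"] for t in targets}).loc[evaluable]
    summary = {
        "n_icrs": len(icrs),
        "n_evaluable": int(evaluable.sum()),
        "n_excluded_control_zero": int((~evaluable).sum()),
        "enriched_in_both": int(flags.all(axis=1).sum()),
        "enriched_in_either": int(flags.any(axis=1).sum()),
        "enriched_in_neither": int((~flags.any(axis=1)).sum()),
        "per_target": {t: int(flags[t].sum()) for t in targets},
        "tau": tau,
    }
    return table, summary


# ---------------------------------------------------------------------------
# coverage and metaprofile
# ---------------------------------------------------------------------------


def coverage_from_fragments(
    fragments: AlignedFragmentSet,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-bp fragment coverage per contig."""
    f = fragments.frame
    lengths: dict[str, int] = dict(contig_lengths) if contig_lengths else {}
    if not lengths:
        for contig, end in zip(f["contig"], f["end"]):
            lengths[contig] = max(lengths.get(contig, 0), int(end))
    out = {c: np.zeros(n, dtype=float) for c, n in lengths.items()}
    for contig, grp in f.groupby("contig", sort=False):
        if contig not in out:
            continue
        arr = np.zeros(len(out[contig]) + 1)
        np.add.at(arr, np.clip(grp["start"].to_numpy(), 0, len(out[contig])), 1.0)
        np.add.at(arr, np.clip(grp["end"].to_numpy(), 0, len(out[contig])), -1.0)
        out[contig] = np.cumsum(arr[:-1])
    return out


def _group_ltr_copies(
    intervals: Sequence[RepeatInterval],
) -> list[tuple[RepeatInterval, RepeatInterval, RepeatInterval]]:
    """Complete (5'LTR, internal, 3'LTR) copies from role-labeled intervals.

    Copies are detected as runs of three contiguous intervals whose roles
    read 5'LTR-internal-3'LTR along the element's own orientation.
    """
    copies = []
    ivs = sorted(intervals, key=lambda iv: (iv.contig, iv.start))
    i = 0
    while i + 2 < len(ivs):
        a, b, c = ivs[i], ivs[i + 1], ivs[i + 2]
        contiguous = (
            a.contig == b.contig == c.contig and a.end == b.start and b.end == c.start
        )
        same_strand = a.strand == b.strand == c.strand
        plus = (a.role, b.role, c.role) == ("five_prime_ltr", "internal", "three_prime_ltr")
        minus = (a.role, b.role, c.role) == ("three_prime_ltr", "internal", "five_prime_ltr")
        if contiguous and same_strand and (
            (a.strand == "+" and plus) or (a.strand == "-" and minus)
        ):
            if a.strand == "+":
                copies.append((a, b, c))
            else:
                copies.append((c, b, a))
            i += 3
        else:
            i += 1
    return copies


def _rebin(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean-pool a per-bp vector into n_bins equal real-width bins."""
    cum = np.concatenate(([0.0], np.cumsum(values)))
    edges = np.linspace(0.0, len(values), n_bins + 1)
    integ = np.interp(edges, np.arange(len(values) + 1), cum)
    widths = np.diff(edges)
    return np.diff(integ) / widths


def ltr_metaprofile(
    fragments: AlignedFragmentSet,
    annotation: RepeatAnnotation,
    subfamily: str,
    n_bins: int = 20,
    contig_lengths: Mapping[str, int] | None = None,
) -> MetaProfile:
    """Coverage metaprofile over complete LTR-structured copies of a subfamily.

    Each copy's 5'LTR, internal and 3'LTR segments are rescaled to
    ``n_bins`` bins by mean pooling; minus-strand copies are reversed so
    bin 0 is the element's 5' end. The returned contrast is
    mean(5'LTR bins) / mean(3'LTR bins).
    """
    members = [iv for iv in annotation.intervals if iv.subfamily == subfamily]
    copies = _group_ltr_copies(members)
    if not copies:
        raise ValidationError(
            f"no complete role-labeled copies of {subfamily!r}; assign "
            "five_prime_ltr/internal/three_prime_ltr roles first"
        )
    need = {iv.contig for trio in copies for iv in trio}
    cov = coverage_from_fragments(fragments, contig_lengths)
    for contig in need:
        if contig not in cov:
            cov[contig] = np.zeros(max(iv.end for t in copies for iv in t if iv.contig == contig))
    profiles = np.zeros((len(copies), 3 * n_bins))
    for k, (ltr5, internal, ltr3) in enumerate(copies):
        segs = []
        for iv in (ltr5, internal, ltr3):
            arr = cov[iv.contig]
            v = arr[iv.start : iv.end].astype(float)
            if len(v) < iv.length:  # coverage array shorter than interval
                v = np.concatenate([v, np.zeros(iv.length - len(v))])
            if iv.strand == "-":
                v = v[::-1]
            segs.append(_rebin(v, n_bins))
        profiles[k] = np.concatenate(segs)
    values = profiles.mean(axis=0)
    m5 = values[:n_bins].mean()
    m3 = values[2 * n_bins :].mean()
    contrast = float(m5 / m3) if m3 > 0 else float("nan")
    return MetaProfile(values=values, n_bins=n_bins, n_elements=len(copies), contrast=contrast)


# ---------------------------------------------------------------------------
# count table serialization
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: FamilyCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#retroquant-counts\tv1\n")
        fh.write(f"#level\t{counts.level}\n")
        def fmt(v: float) -> str:
            v = float(v)
            return str(int(v)) if v.is_integer() else repr(v)

        for sid in counts.samples:
            fh.write(f"#library_size\t{sid}\t{fmt(counts.library_size[sid])}\n")
            fh.write(f"#unassigned\t{sid}\t{fmt(counts.unassigned[sid])}\n")
        body = counts.row_meta.join(counts.unit_length).join(counts.counts)
        body.to_csv(fh, sep="\t")


def read_counts_tsv(path: str | Path) -> FamilyCountTable:
    level = "subfamily"
    library_size: dict[str, float] = {}
    unassigned: dict[str, float] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "#level":
                level = fields[1]
            elif fields[0] == "#library_size":
                library_size[fields[1]] = float(fields[2])
            elif fields[0] == "#unassigned":
                unassigned[fields[1]] = float(fields[2])
    body = pd.read_csv(path, sep="\t", skiprows=header_lines, index_col=0)
    meta_cols = ["class_", "family"]
    sample_cols = [c for c in body.columns if c not in meta_cols + ["unit_length"]]
    lib = pd.Series(library_size, name="library_size")
    if (lib == np.floor(lib)).all():
        lib = lib.astype("int64")
    return FamilyCountTable(
        counts=body[sample_cols],
        unit_length=body["unit_length"],
        library_size=lib,
        unassigned=pd.Series(unassigned, name="unassigned"),
        row_meta=body[meta_cols],
        level=level,
    )
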
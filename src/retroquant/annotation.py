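"""Annotation and alignment I/O.

All internal coordinates are 0-based half-open; 1-based inclusive
conventions appear only at format boundaries (SAM, RepeatMasker ``.out``).

Repeat intervals carry a four-level hierarchy (class -> family ->
subfamily -> instance) plus an element-role label used for LTR elements
(``five_prime_ltr`` / ``internal`` / ``three_prime_ltr``); the BED dialect
encodes ``subfamily|family|class|role`` in the name field so the
annotation stays a plain BED6 file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError, UsageError, ValidationError

log = logging.getLogger(__name__)

ROLES = ("five_prime_ltr", "internal", "three_prime_ltr", "solo", "unassigned")
LEVELS = ("subfamily", "family", "class_")
ALLELES = ("maternal", "paternal", "unknown")


@dataclass(frozen=True)
class RepeatInterval:
    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    class_: str
    instance_id: str
    role: str = "unassigned"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def unit(self, level: str) -> str:
        if level not in LEVELS:
            raise UsageError(f"unknown level {level!r}; expected one of {LEVELS}")
        return getattr(self, level)


@dataclass(frozen=True)
class IcrInterval:
    """An imprinting control region (differentially methylated locus)."""

    contig: str
    start: int
    end: int
    name: str
    methylated_allele: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid ICR {self.name} {self.contig}:{self.start}-{self.end}"
            )
        if self.methylated_allele not in ALLELES:
            raise ValidationError(
                f"ICR {self.name}: methylated_allele must be one of {ALLELES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class RepeatAnnotation:
    """Hierarchical repeat interval set.

    Every interval is reachable through exactly one
    class -> family -> subfamily index path; unit lengths at any level are
    the summed span of the member intervals.
    """

    def __init__(
        self,
        intervals: Iterable[RepeatInterval],
        background_classes: Iterable[str] = ("DNA",),
        contig_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[RepeatInterval] = sorted(
            intervals, key=lambda iv: (iv.contig, iv.start, iv.end, iv.instance_id)
        )
        self.background_classes = set(background_classes)
        self.contig_lengths = dict(contig_lengths) if contig_lengths else None
        seen: set[str] = set()
        for iv in self.intervals:
            if iv.instance_id in seen:
                raise ValidationError(f"duplicate instance_id {iv.instance_id!r}")
            seen.add(iv.instance_id)
            if self.contig_lengths is not None:
                if iv.contig not in self.contig_lengths:
                    raise ValidationError(
                        f"interval {iv.instance_id} on unknown contig {iv.contig!r}"
                    )
                if iv.end > self.contig_lengths[iv.contig]:
                    raise ValidationError(
                        f"interval {iv.instance_id} extends past end of {iv.contig}"
                    )
        self.index: dict[str, dict[str, dict[str, list[RepeatInterval]]]] = {}
        for iv in self.intervals:
            (
                self.index.setdefault(iv.class_, {})
                .setdefault(iv.family, {})
                .setdefault(iv.subfamily, [])
                .append(iv)
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def units(self, level: str = "subfamily") -> dict[str, list[RepeatInterval]]:
        """Intervals grouped by unit name at the requested level."""
        if level not in LEVELS:
            raise UsageError(f"unknown level {level!r}; expected one of {LEVELS}")
        out: dict[str, list[RepeatInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.unit(level), []).append(iv)
        return out

    def unit_lengths(self, level: str = "subfamily") -> pd.Series:
        lengths = {u: sum(iv.length for iv in ivs) for u, ivs in self.units(level).items()}
        s = pd.Series(lengths, dtype="int64", name="unit_length")
        s.index.name = "unit"
        return s.sort_index()

    def unit_meta(self, level: str = "subfamily") -> pd.DataFrame:
        """class_/family labels per unit at ``level`` (first interval wins)."""
        rows = {}
        for unit, ivs in self.units(level).items():
            iv = ivs[0]
            rows[unit] = {"class_": iv.class_, "family": iv.family}
        meta = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        meta.index.name = "unit"
        return meta

    def subset(self, subfamilies: Iterable[str]) -> "RepeatAnnotation":
        keep = set(subfamilies)
        return RepeatAnnotation(
            [iv for iv in self.intervals if iv.subfamily in keep],
            background_classes=self.background_classes,
            contig_lengths=self.contig_lengths,
        )


@dataclass
class AlignedFragmentSet:
    """Per-sample genomic fragments, sorted by (contig, start, end).

    Backed by a DataFrame with columns contig, start, end, strand,
    multimapper, duplicate.
    """

    frame: pd.DataFrame
    n_skipped_unmapped: int = 0

    COLUMNS = ("contig", "start", "end", "strand", "multimapper", "duplicate")

    @classmethod
    def from_arrays(
        cls,
        contig: Sequence[str] | np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: Sequence[str] | np.ndarray,
        multimapper: np.ndarray | None = None,
        n_skipped_unmapped: int = 0,
    ) -> "AlignedFragmentSet":
        n = len(start)
        frame = pd.DataFrame(
            {
                "contig": np.asarray(contig, dtype=object),
                "start": np.asarray(start, dtype="int64"),
                "end": np.asarray(end, dtype="int64"),
                "strand": np.asarray(strand, dtype=object),
                "multimapper": (
                    np.zeros(n, dtype=bool) if multimapper is None else np.asarray(multimapper, bool)
                ),
                "duplicate": np.zeros(n, dtype=bool),
            }
        )
        fs = cls(frame, n_skipped_unmapped=n_skipped_unmapped)
        fs.validate()
        return fs.sorted()

    def validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            return
        if (f["start"].to_numpy() < 0).any():
            raise ValidationError("negative fragment coordinate")
        if (f["end"].to_numpy() <= f["start"].to_numpy()).any():
            raise ValidationError("fragment with end <= start")

    def sorted(self) -> "AlignedFragmentSet":
        f = self.frame.sort_values(
            ["contig", "start", "end"], kind="mergesort", ignore_index=True
        )
        return AlignedFragmentSet(f, self.n_skipped_unmapped)

    def is_sorted(self) -> bool:
        f = self.frame
        if len(f) < 2:
            return True
        key = pd.MultiIndex.from_frame(f[["contig", "start", "end"]])
        return key.is_monotonic_increasing

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def midpoints(self) -> np.ndarray:
        """Floor midpoint, ``start + (end - start) // 2``."""
        s = self.frame["start"].to_numpy()
        e = self.frame["end"].to_numpy()
        return s + (e - s) // 2


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: str
    assay: str  # chip | input | igg | rna
    target: str = ""  # e.g. "O-GlcNAc", "TRIM28"; empty for untargeted input/rna
    condition: str = ""
    replicate: int = 1


ASSAYS = ("chip", "input", "igg", "rna")
CONTROL_ASSAYS = ("input", "igg")


class SampleManifest:
    """Maps sample ids to file roles (ChIP/input/IgG; RNA condition/replicate)."""

    def __init__(self, entries: Iterable[ManifestEntry]) -> None:
        self.entries = list(entries)
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("sample_id values must be unique in a manifest")
        for e in self.entries:
            if e.assay not in ASSAYS:
                raise ValidationError(
                    f"sample {e.sample_id}: assay {e.assay!r} not one of {ASSAYS}"
                )
            if e.replicate < 1:
                raise ValidationError(f"sample {e.sample_id}: replicate must be >= 1")
        for e in self.entries:
            if e.assay == "chip" and not self.controls_for(e.target, e.condition):
                raise ValidationError(
                    f"ChIP sample {e.sample_id} (target={e.target!r}, "
                    f"condition={e.condition!r}) has no matched input/IgG control"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def select(self, **key: str) -> list[ManifestEntry]:
        """Entries matching every given field exactly."""
        out = []
        for e in self.entries:
            if all(getattr(e, k) == v for k, v in key.items()):
                out.append(e)
        return out

    def controls_for(self, target: str, condition: str) -> list[ManifestEntry]:
        """Matched controls: target-specific first, else shared (untargeted)."""
        for want_target in (target, ""):
            hits = [
                e
                for e in self.entries
                if e.assay in CONTROL_ASSAYS
                and e.target == want_target
                and e.condition == condition
            ]
            if hits:
                return hits
        return []

    def available_keys(self) -> list[tuple[str, str, str]]:
        return sorted({(e.assay, e.target, e.condition) for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_bed_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split("|")
    subfamily = parts[0] if parts[0] else "unknown"
    family = parts[1] if len(parts) > 1 and parts[1] else subfamily
    class_ = parts[2] if len(parts) > 2 and parts[2] else family
    role = parts[3] if len(parts) > 3 and parts[3] else "unassigned"
    return subfamily, family, class_, role


def read_repeat_bed(
    path: str | Path,
    background_classes: Iterable[str] = ("DNA",),
    contig_lengths: Mapping[str, int] | None = None,
) -> RepeatAnnotation:
    """Read a BED6+ repeat annotation.

    The name field encodes ``subfamily|family|class|role`` (role optional);
    an optional 7th column supplies an explicit instance_id, otherwise ids
    are auto-assigned as ``<subfamily>.<ordinal>``.
    """
    intervals: list[RepeatInterval] = []
    counters: dict[str, int] = {}
    raw: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if end <= start or start < 0:
                raise ValidationError(f"{path}:{lineno}: need 0 <= start < end")
            strand = fields[5] if fields[5] in ("+", "-") else "+"
            subfamily, family, class_, role = _parse_bed_name(fields[3])
            explicit_id = fields[6] if len(fields) > 6 and fields[6] else None
            raw.append((fields[0], start, end, strand, subfamily, family, class_, role, explicit_id))
    # preserve input order, ties broken by (contig, start)
    for contig, start, end, strand, subfamily, family, class_, role, explicit_id in raw:
        if explicit_id is None:
            counters[subfamily] = counters.get(subfamily, 0) + 1
            explicit_id = f"{subfamily}.{counters[subfamily]}"
        intervals.append(
            RepeatInterval(contig, start, end, strand, subfamily, family, class_, explicit_id, role)
        )
    return RepeatAnnotation(intervals, background_classes, contig_lengths)


def write_repeat_bed(annotation: RepeatAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annotation.intervals:
            name = f"{iv.subfamily}|{iv.family}|{iv.class_}|{iv.role}"
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t{iv.instance_id}\n"
            )


_RM_SKIP_PREFIXES = ("SW", "score", "")


def read_repeatmasker_table(
    path: str | Path,
    background_classes: Iterable[str] = ("DNA",),
) -> RepeatAnnotation:
    """Read a RepeatMasker ``.out``-style table.

    Coordinates are 1-based inclusive in the file and converted to 0-based
    half-open. The class/family column is split on "/"; a bare class (no
    slash) is used for both levels. Roles are left ``unassigned``.
    """
    intervals: list[RepeatInterval] = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] in ("SW", "score") or line.startswith("  SW"):
                continue
            if len(fields) < 11:
                raise ParseError(
                    f"{path}:{lineno}: expected >=11 whitespace-delimited columns "
                    "(missing class/family column?)"
                )
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            contig = fields[4]
            strand = "-" if fields[8] in ("C", "-") else "+"
            subfamily = fields[9]
            cf = fields[10]
            if "/" in cf:
                class_, family = cf.split("/", 1)
            else:
                class_ = family = cf
            counters[subfamily] = counters.get(subfamily, 0) + 1
            intervals.append(
                RepeatInterval(
                    contig,
                    begin - 1,
                    end,
                    strand,
                    subfamily,
                    family,
                    class_,
                    f"{subfamily}.{counters[subfamily]}",
                    "unassigned",
                )
            )
    return RepeatAnnotation(intervals, background_classes)


def read_icr_bed(path: str | Path) -> list[IcrInterval]:
    """Read ICRs from BED; name field is ``name`` or ``name|methylated_allele``."""
    icrs: list[IcrInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 fields for an ICR")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            name, _, allele = fields[3].partition("|")
            icrs.append(IcrInterval(fields[0], start, end, name, allele or "unknown"))
    return icrs


def write_icr_bed(icrs: Sequence[IcrInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for icr in icrs:
            fh.write(f"{icr.contig}\t{icr.start}\t{icr.end}\t{icr.name}|{icr.methylated_allele}\n")


def read_fragments(path: str | Path, dialect: str = "bed") -> AlignedFragmentSet:
    """Read aligned fragments from a SAM or BED file.

    SAM: unmapped, secondary and supplementary records are skipped (the
    skipped count is kept on the returned set); the multimapper flag is set
    for mapping quality 0. BED: chrom/start/end(/name/score/strand).
    """
    if dialect == "sam":
        return _read_fragments_sam(path)
    if dialect == "bed":
        return _read_fragments_bed(path)
    raise UsageError(f"unknown fragment dialect {dialect!r}; expected 'sam' or 'bed'")


def _read_fragments_sam(path: str | Path) -> AlignedFragmentSet:
    contigs, starts, ends, strands, multi = [], [], [], [], []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            contigs.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
            multi.append(rec.mapping_quality == 0)
    if skipped:
        log.info("read_fragments: skipped %d unmapped/secondary records from %s", skipped, path)
    return AlignedFragmentSet.from_arrays(
        contigs,
        np.asarray(starts, dtype="int64"),
        np.asarray(ends, dtype="int64"),
        strands,
        np.asarray(multi, dtype=bool),
        n_skipped_unmapped=skipped,
    )


def _read_fragments_bed(path: str | Path) -> AlignedFragmentSet:
    contigs, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative coordinate")
            contigs.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+")
    return AlignedFragmentSet.from_arrays(
        contigs,
        np.asarray(starts, dtype="int64"),
        np.asarray(ends, dtype="int64"),
        strands,
    )


def write_fragments_bed(fragments: AlignedFragmentSet, path: str | Path) -> None:
    f = fragments.frame
    with open(path, "w") as fh:
        for contig, start, end, strand in zip(f["contig"], f["start"], f["end"], f["strand"]):
            fh.write(f"{contig}\t{start}\t{end}\t.\t0\t{strand}\n")


def write_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-bp coverage as run-length-merged bedGraph; zero runs omitted."""
    with open(path, "w") as fh:
        for contig in sorted(coverage):
            values = np.asarray(coverage[contig], dtype=float)
            if values.size == 0:
                continue
            if not np.isfinite(values).all():
                raise ValidationError(f"non-finite coverage value on {contig}")
            if (values < 0).any():
                raise ValidationError(f"negative coverage value on {contig}")
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for s, e in zip(starts, ends):
                v = float(values[s])
                if v == 0:
                    continue
                fh.write(f"{contig}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Read bedGraph back into per-bp arrays (inverse of :func:`write_bedgraph`)."""
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            spans.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    out: dict[str, np.ndarray] = {}
    for contig, rows in spans.items():
        length = (
            contig_lengths[contig] if contig_lengths else max(e for _, e, _ in rows)
        )
        arr = np.zeros(length, dtype=float)
        for s, e, v in rows:
            arr[s:e] = v
        out[contig] = arr
    return out


MANIFEST_COLUMNS = ("sample_id", "path", "assay", "target", "condition", "replicate")


def read_manifest(path: str | Path) -> SampleManifest:
    """Read a sample manifest TSV with columns sample_id/path/assay/target/condition/replicate."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    entries = [
        ManifestEntry(
            sample_id=row.sample_id,
            path=row.path,
            assay=row.assay,
            target=row.target,
            condition=row.condition,
            replicate=int(row.replicate),
        )
        for row in frame.itertuples()
    ]
    return SampleManifest(entries)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, sep="\t", index=False)


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Contig lengths of a FASTA genome (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), build_index=True, rebuild=False) as fa:
        return {name: len(rec) for name, rec in fa.records.items()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
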
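"""Synthetic genomes, fragment sets, RNA counts and peptide tables.

Everything downstream estimates is planted here with a known value, so the
whole pipeline is verifiable at desk scale: a toy genome carries a
multi-family repeat landscape (LTR elements with 5'LTR-internal-3'LTR
structure, LINEs, SINEs and transpositionally dead DNA transposons) plus
imprinting control regions; ChIP samples draw fragment midpoints from a
piecewise-constant intensity proportional to the planted enrichment;
RNA-seq is simulated at the counts level (negative binomial per repeat
copy, aggregated to the subfamily unit); peptide tables plant one
methylation-dependent interactor among correlated background proteins.

Every generator is a pure function of (config, seed): the same seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AlignedFragmentSet,
    IcrInterval,
    ManifestEntry,
    RepeatAnnotation,
    RepeatInterval,
    SampleManifest,
)
from .chip import FamilyCountTable
from .errors import UsageError, ValidationError
from .screen import PeptideCountTable


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    n_contigs: int = 1
    contig_length: int = 2_000_000


@dataclass(frozen=True)
class FamilySpec:
    subfamily: str
    class_: str
    family: str
    n_copies: int
    element_length: int
    has_ltr_structure: bool = False
    ltr_length: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 0 or self.element_length <= 0:
            raise ValidationError(f"{self.subfamily}: copies >= 0 and length > 0 required")
        if self.has_ltr_structure:
            if self.ltr_length <= 0 or 2 * self.ltr_length >= self.element_length:
                raise ValidationError(
                    f"{self.subfamily}: need 0 < 2*ltr_length < element_length"
                )


@dataclass(frozen=True)
class IcrSpec:
    name: str
    length: int = 2000
    methylated_allele: str = "maternal"


@dataclass(frozen=True)
class ChipTargetSpec:
    """Planted enrichment landscape for one ChIP target.

    ``enrichment`` maps subfamily -> intensity factor e (>= 0, 1 = no
    enrichment); ``promoter_boost`` multiplies the intensity over
    five_prime_ltr intervals only; ``icr_enrichment`` maps ICR name (or
    "*") -> e. Controls (input/IgG) use e = 1 everywhere.
    """

    target: str
    enrichment: Mapping[str, float] = field(default_factory=dict)
    promoter_boost: Mapping[str, float] = field(default_factory=dict)
    icr_enrichment: Mapping[str, float] = field(default_factory=dict)
    n_chip_replicates: int = 3
    control_assay: str = "input"  # input (shared) or igg (target-matched)
    n_control_replicates: int = 2
    condition: str = "WT"

    def __post_init__(self) -> None:
        for d in (self.enrichment, self.promoter_boost, self.icr_enrichment):
            for k, v in d.items():
                if not np.isfinite(v) or v < 0:
                    raise ValidationError(f"enrichment factor for {k!r} must be finite and >= 0")
        if self.control_assay not in ("input", "igg"):
            raise ValidationError("control_assay must be 'input' or 'igg'")


@dataclass(frozen=True)
class ChipSpec:
    targets: tuple[ChipTargetSpec, ...] = ()
    depth: int = 100_000
    fragment_length: int = 200
    control_depth: int | None = None  # defaults to depth

    def __post_init__(self) -> None:
        if self.depth < 0 or self.fragment_length <= 0:
            raise ValidationError("depth >= 0 and fragment_length > 0 required")


@dataclass(frozen=True)
class RnaSpec:
    """Counts-level RNA model.

    ``expression`` maps subfamily -> expected signal cpm at baseline;
    ``effects`` maps (subfamily, condition) -> planted log2 fold change
    relative to baseline. Every unit additionally receives nonspecific
    background at ``background_cpm_per_kb`` cpm per kb of unit length (DNA
    transposons receive only this), and the remaining library mass is
    non-repeat transcriptome. Counts are negative binomial per repeat copy
    with the given dispersion and summed to the unit.
    """

    conditions: Mapping[str, int] = field(default_factory=lambda: {"WT": 3, "Dnmt1KO": 3})
    expression: Mapping[str, float] = field(default_factory=dict)
    effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    background_cpm_per_kb: float = 10.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        for cond, n in self.conditions.items():
            if n < 1:
                raise ValidationError(f"condition {cond!r} needs >= 1 replicate")
        for sub, v in self.expression.items():
            if v < 0:
                raise ValidationError(f"expression for {sub!r} must be >= 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


@dataclass(frozen=True)
class ProteomicsSpec:
    """Two-condition peptide-count model.

    Background proteins share a latent abundance between the two
    conditions: counts are C + U with a common Poisson component C of mean
    correlation * background_mean, which mimics the strong run-to-run
    correlation of peptide counts for methylation-independent interactors
    while keeping Poisson(background_mean) marginals. Planted hits draw
    independent Poisson counts at their distinct per-condition means.
    """

    n_background: int = 50
    background_mean: float = 5.0
    correlation: float = 0.9
    planted_hits: tuple[tuple[str, float, float], ...] = (("OGT", 20.0, 2.0),)
    ref_condition: str = "WT"
    cmp_condition: str = "Dnmt1KO"

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise ValidationError("need >= 1 background protein")
        if not 0 <= self.correlation <= 1:
            raise ValidationError("correlation must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeSpec = GenomeSpec()
    families: tuple[FamilySpec, ...] = ()
    icrs: tuple[IcrSpec, ...] = ()
    chip: ChipSpec = ChipSpec()
    rna: RnaSpec = RnaSpec()
    proteomics: ProteomicsSpec = ProteomicsSpec()


@dataclass
class GroundTruth:
    """Planted values of every parameter the pipeline estimates."""

    chip_enrichment: dict = field(default_factory=dict)  # target -> {unit: e}
    chip_expected_ratio: dict = field(default_factory=dict)  # target -> {unit: e*L/Z}
    promoter_boost: dict = field(default_factory=dict)  # target -> {subfamily: boost}
    icr_enrichment: dict = field(default_factory=dict)  # target -> {icr: e}
    rna_expected_cpm: dict = field(default_factory=dict)  # condition -> {unit: cpm}
    rna_log2fc: dict = field(default_factory=dict)  # condition -> {unit: planted lfc}
    planted_hits: list = field(default_factory=list)  # [(protein, mean_ref, mean_cmp)]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=str)


@dataclass
class GenomeBuild:
    contig_lengths: dict[str, int]
    annotation: RepeatAnnotation
    icrs: list[IcrInterval]
    sequences: dict[str, str] | None = None


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _place_without_overlap(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    contig_length: int,
    length: int,
    max_tries: int = 1000,
) -> int:
    """Uniform random start for a [start, start+length) span avoiding overlap."""
    import bisect

    for _ in range(max_tries):
        start = int(rng.integers(0, contig_length - length + 1))
        end = start + length
        i = bisect.bisect_left(occupied, (start, start))
        ok = True
        if i > 0 and occupied[i - 1][1] > start:
            ok = False
        if ok and i < len(occupied) and occupied[i][0] < end:
            ok = False
        if ok:
            occupied.insert(i, (start, end))
            return start
    raise ValidationError(
        "could not place repeat copy without overlap after "
        f"{max_tries} tries; lower the repeat density or enlarge the genome"
    )


def simulate_genome(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
    with_sequence: bool = True,
) -> GenomeBuild:
    """Build a toy genome: repeats placed uniformly without overlap, ICRs in gaps.

    LTR-structured families emit three intervals per copy (five_prime_ltr,
    internal, three_prime_ltr); minus-strand copies have the 3'LTR leftmost
    in genomic coordinates. Sequence content is random uniform nucleotides
    (counting never looks at it) and can be skipped for speed.
    """
    rng = _rng(config.seed if seed is None else seed)
    g = config.genome
    contig_lengths = {f"chr{i + 1}": g.contig_length for i in range(g.n_contigs)}
    planted_bp = sum(f.n_copies * f.element_length for f in config.families)
    total_bp = g.n_contigs * g.contig_length
    if planted_bp > 0.8 * total_bp:
        raise ValidationError(
            f"planted repeat length {planted_bp} exceeds 80% of genome length {total_bp}"
        )
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    contigs = list(contig_lengths)
    intervals: list[RepeatInterval] = []
    # place longer elements first so dense configurations still fit
    for fam in sorted(config.families, key=lambda f: -f.element_length):
        for copy_i in range(1, fam.n_copies + 1):
            contig = contigs[int(rng.integers(0, len(contigs)))]
            start = _place_without_overlap(
                rng, occupied[contig], contig_lengths[contig], fam.element_length
            )
            strand = "+" if rng.random() < 0.5 else "-"
            stem = f"{fam.subfamily}.{copy_i}"
            if fam.has_ltr_structure:
                L = fam.ltr_length
                mid = fam.element_length - 2 * L
                spans = [(start, start + L), (start + L, start + L + mid), (start + L + mid, start + fam.element_length)]
                roles = ["five_prime_ltr", "internal", "three_prime_ltr"]
                if strand == "-":
                    roles = roles[::-1]
                for (s, e), role in zip(spans, roles):
                    intervals.append(
                        RepeatInterval(
                            contig, s, e, strand, fam.subfamily, fam.family, fam.class_,
                            f"{stem}:{role}", role,
                        )
                    )
            else:
                role = "solo" if fam.class_ == "LTR" else "unassigned"
                intervals.append(
                    RepeatInterval(
                        contig, start, start + fam.element_length, strand,
                        fam.subfamily, fam.family, fam.class_, stem, role,
                    )
                )
    icrs: list[IcrInterval] = []
    for spec in config.icrs:
        contig = contigs[int(rng.integers(0, len(contigs)))]
        start = _place_without_overlap(rng, occupied[contig], contig_lengths[contig], spec.length)
        icrs.append(IcrInterval(contig, start, start + spec.length, spec.name, spec.methylated_allele))
    sequences = None
    if with_sequence:
        alphabet = np.frombuffer(b"ACGT", dtype="S1")
        sequences = {
            c: alphabet[rng.integers(0, 4, size=n)].tobytes().decode()
            for c, n in contig_lengths.items()
        }
    annotation = RepeatAnnotation(intervals, contig_lengths=contig_lengths)
    return GenomeBuild(contig_lengths, annotation, icrs, sequences)


# ---------------------------------------------------------------------------
# ChIP fragments
# ---------------------------------------------------------------------------


def _intensity_segments(
    contig_lengths: Mapping[str, int],
    annotation: RepeatAnnotation,
    icrs: Sequence[IcrInterval],
    spec: ChipTargetSpec,
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Piecewise-constant intensity e(x): (contig, start, end) segments + factors."""
    enriched: list[tuple[str, int, int, float]] = []
    for iv in annotation.intervals:
        e = float(spec.enrichment.get(iv.subfamily, 1.0))
        if iv.role == "five_prime_ltr":
            e *= float(spec.promoter_boost.get(iv.subfamily, 1.0))
        if e != 1.0:
            enriched.append((iv.contig, iv.start, iv.end, e))
    for icr in icrs:
        e = float(spec.icr_enrichment.get(icr.name, spec.icr_enrichment.get("*", 1.0)))
        if e != 1.0:
            enriched.append((icr.contig, icr.start, icr.end, e))
    segments: list[tuple[str, int, int]] = []
    factors: list[float] = []
    by_contig: dict[str, list[tuple[int, int, float]]] = {c: [] for c in contig_lengths}
    for contig, s, e, f in enriched:
        by_contig[contig].append((s, e, f))
    for contig, length in contig_lengths.items():
        pos = 0
        for s, e, f in sorted(by_contig[contig]):
            if s < pos:
                raise ValidationError("overlapping enriched intervals in ChIP spec")
            if s > pos:
                segments.append((contig, pos, s))
                factors.append(1.0)
            segments.append((contig, s, e))
            factors.append(f)
            pos = e
        if pos < length:
            segments.append((contig, pos, length))
            factors.append(1.0)
    return segments, np.asarray(factors)


def simulate_chip_sample(
    contig_lengths: Mapping[str, int],
    annotation: RepeatAnnotation,
    icrs: Sequence[IcrInterval],
    spec: ChipTargetSpec,
    depth: int,
    fragment_length: int,
    seed: int | np.random.Generator,
    control: bool = False,
) -> AlignedFragmentSet:
    """Draw exactly ``depth`` fragments with midpoints ~ planted intensity.

    Controls (``control=True``) use intensity 1 everywhere. Fragments are
    ``fragment_length`` bp, shifted to stay inside the contig, with random
    strand.
    """
    rng = _rng(seed)
    if control:
        neutral = ChipTargetSpec(target=spec.target)
        segments, factors = _intensity_segments(contig_lengths, annotation, icrs, neutral)
    else:
        segments, factors = _intensity_segments(contig_lengths, annotation, icrs, spec)
    seg_len = np.array([e - s for _, s, e in segments], dtype=float)
    weights = seg_len * factors
    total = weights.sum()
    if total <= 0:
        raise ValidationError("intensity is zero everywhere")
    seg_idx = rng.choice(len(segments), size=depth, p=weights / total)
    offsets = rng.random(depth)
    starts_arr = np.array([s for _, s, _ in segments], dtype=float)
    mids = (starts_arr[seg_idx] + offsets * seg_len[seg_idx]).astype("int64")
    contigs_per_seg = np.array([c for c, _, _ in segments], dtype=object)
    frag_contigs = contigs_per_seg[seg_idx]
    lengths = np.array([contig_lengths[c] for c in frag_contigs], dtype="int64")
    starts = np.clip(mids - fragment_length // 2, 0, lengths - fragment_length)
    ends = starts + fragment_length
    strands = np.where(rng.random(depth) < 0.5, "+", "-").astype(object)
    return AlignedFragmentSet.from_arrays(frag_contigs, starts, ends, strands)


def expected_chip_ratio(
    contig_lengths: Mapping[str, int],
    annotation: RepeatAnnotation,
    icrs: Sequence[IcrInterval],
    spec: ChipTargetSpec,
    level: str = "subfamily",
) -> dict[str, float]:
    """Infinite-depth cpm ratio per unit: e_u * L / Z, Z = integral of e(x).

    For units mixing intensities (e.g. boosted 5'LTRs within a subfamily)
    the length-weighted mean intensity over the unit is used.
    """
    L = float(sum(contig_lengths.values()))
    segments, factors = _intensity_segments(contig_lengths, annotation, icrs, spec)
    seg_len = np.array([e - s for _, s, e in segments], dtype=float)
    Z = float((seg_len * factors).sum())
    out: dict[str, float] = {}
    for unit, ivs in annotation.units(level).items():
        num = 0.0
        den = 0.0
        for iv in ivs:
            e = float(spec.enrichment.get(iv.subfamily, 1.0))
            if iv.role == "five_prime_ltr":
                e *= float(spec.promoter_boost.get(iv.subfamily, 1.0))
            num += e * iv.length
            den += iv.length
        out[unit] = (num / den) * L / Z
    return out


def simulate_chip_experiment(
    config: SimulationConfig,
    build: GenomeBuild,
    seed: int | None = None,
) -> tuple[dict[str, AlignedFragmentSet], SampleManifest, GroundTruth]:
    """All ChIP/control samples of the configured targets, plus the manifest.

    The seed is expanded into one substream per sample so individual
    samples can be regenerated independently.
    """
    base_seed = config.seed if seed is None else seed
    samples: dict[str, AlignedFragmentSet] = {}
    entries: list[ManifestEntry] = []
    truth = GroundTruth()
    control_depth = config.chip.control_depth or config.chip.depth
    streams = iter(np.random.SeedSequence(base_seed).spawn(
        sum(t.n_chip_replicates + t.n_control_replicates for t in config.chip.targets)
    ))
    for t in config.chip.targets:
        truth.chip_enrichment[t.target] = {
            u: float(t.enrichment.get(u, 1.0))
            for u in build.annotation.unit_lengths().index
        }
        truth.chip_expected_ratio[t.target] = expected_chip_ratio(
            build.contig_lengths, build.annotation, build.icrs, t
        )
        truth.promoter_boost[t.target] = dict(t.promoter_boost)
        truth.icr_enrichment[t.target] = {
            icr.name: float(t.icr_enrichment.get(icr.name, t.icr_enrichment.get("*", 1.0)))
            for icr in build.icrs
        }
        for rep in range(1, t.n_chip_replicates + 1):
            sid = f"{t.target}_chip_{rep}"
            samples[sid] = simulate_chip_sample(
                build.contig_lengths, build.annotation, build.icrs, t,
                config.chip.depth, config.chip.fragment_length,
                np.random.default_rng(next(streams)),
            )
            entries.append(ManifestEntry(sid, "", "chip", t.target, t.condition, rep))
        ctl_target = t.target if t.control_assay == "igg" else ""
        for rep in range(1, t.n_control_replicates + 1):
            sid = f"{t.target}_{t.control_assay}_{rep}"
            samples[sid] = simulate_chip_sample(
                build.contig_lengths, build.annotation, build.icrs, t,
                control_depth, config.chip.fragment_length,
                np.random.default_rng(next(streams)), control=True,
            )
            entries.append(ManifestEntry(sid, "", t.control_assay, ctl_target, t.condition, rep))
    return samples, SampleManifest(entries), truth


def simulate_uniform_fragments(
    contig_lengths: Mapping[str, int],
    depth: int,
    fragment_length: int,
    seed: int | np.random.Generator,
) -> AlignedFragmentSet:
    """Uniform-intensity fragments (an input/IgG-like sample)."""
    rng = _rng(seed)
    contigs = list(contig_lengths)
    lens = np.array([contig_lengths[c] for c in contigs], dtype=float)
    idx = rng.choice(len(contigs), size=depth, p=lens / lens.sum())
    mids = (rng.random(depth) * lens[idx]).astype("int64")
    frag_contigs = np.array(contigs, dtype=object)[idx]
    clens = lens[idx].astype("int64")
    starts = np.clip(mids - fragment_length // 2, 0, clens - fragment_length)
    ends = starts + fragment_length
    strands = np.where(rng.random(depth) < 0.5, "+", "-").astype(object)
    return AlignedFragmentSet.from_arrays(frag_contigs, starts, ends, strands)


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    out = np.zeros(mean.shape, dtype="int64")
    pos = mean > 0
    out[pos] = rng.negative_binomial(n, p[pos])
    return out


def simulate_rna_counts(
    annotation: RepeatAnnotation,
    rna_spec: RnaSpec,
    depth: int,
    seed: int | np.random.Generator,
) -> tuple[FamilyCountTable, SampleManifest, GroundTruth]:
    """Counts-level RNA simulation per condition x replicate.

    Expected unit cpm = background_cpm_per_kb * unit_kb + expression *
    2**effect; the remaining library mass is non-repeat transcriptome and
    enters only the library size (reported as unassigned). Counts are NB
    per copy (dispersion as configured) and summed per unit; each
    replicate's library size is its realized total count.
    """
    if depth < 0:
        raise ValidationError("depth must be >= 0")
    rng = _rng(seed)
    unit_lengths = annotation.unit_lengths("subfamily")
    units = list(unit_lengths.index)
    copy_lists = annotation.units("subfamily")
    truth = GroundTruth()
    cols: dict[str, np.ndarray] = {}
    libs: dict[str, int] = {}
    unassigned: dict[str, int] = {}
    entries: list[ManifestEntry] = []
    # abundance weights on a nominal per-million scale; the non-repeat
    # transcriptome weight is fixed at baseline, so planted effects shift
    # library composition the way genuine reactivation does
    def weight(u: str, cond: str | None) -> float:
        bg = rna_spec.background_cpm_per_kb * unit_lengths[u] / 1000.0
        sig = float(rna_spec.expression.get(u, 0.0))
        eff = 0.0 if cond is None else float(rna_spec.effects.get((u, cond), 0.0))
        return bg + sig * 2.0**eff

    baseline_total = sum(weight(u, None) for u in units)
    if baseline_total > 1e6:
        raise ValidationError(
            f"baseline unit weight total {baseline_total:.0f} exceeds 1e6; lower expression"
        )
    other_w = 1e6 - baseline_total
    for cond, n_reps in rna_spec.conditions.items():
        w = {u: weight(u, cond) for u in units}
        W = other_w + sum(w.values())
        truth.rna_expected_cpm[cond] = {u: 1e6 * w[u] / W for u in units}
        truth.rna_log2fc[cond] = {
            u: float(rna_spec.effects.get((u, cond), 0.0)) for u in units
        }
        for rep in range(1, n_reps + 1):
            sid = f"rna_{cond}_{rep}"
            col = np.zeros(len(units), dtype="int64")
            for i, u in enumerate(units):
                ivs = copy_lists[u]
                copy_len = np.array([iv.length for iv in ivs], dtype=float)
                mean = depth * (w[u] / W) * copy_len / copy_len.sum()
                col[i] = int(_nb_draw(rng, mean, rna_spec.dispersion).sum())
            other = int(rng.poisson(depth * other_w / W)) if depth else 0
            cols[sid] = col
            libs[sid] = int(col.sum()) + other
            unassigned[sid] = other
            entries.append(ManifestEntry(sid, "", "rna", "", cond, rep))
    counts = pd.DataFrame(cols, index=pd.Index(units, name="unit"), dtype="int64")
    table = FamilyCountTable(
        counts=counts,
        unit_length=unit_lengths,
        library_size=pd.Series(libs, name="library_size"),
        unassigned=pd.Series(unassigned, name="unassigned"),
        row_meta=annotation.unit_meta("subfamily"),
        level="subfamily",
    )
    return table, SampleManifest(entries), truth


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------


def simulate_peptide_table(
    spec: ProteomicsSpec,
    seed: int | np.random.Generator,
) -> tuple[PeptideCountTable, GroundTruth]:
    """Unique-peptide counts with planted methylation-dependent interactors."""
    rng = _rng(seed)
    names, ref, cmp_ = [], [], []
    common_mean = spec.correlation * spec.background_mean
    indep_mean = (1.0 - spec.correlation) * spec.background_mean
    width = len(str(spec.n_background))
    for i in range(1, spec.n_background + 1):
        c = rng.poisson(common_mean)
        names.append(f"BG{i:0{width}d}")
        ref.append(c + rng.poisson(indep_mean))
        cmp_.append(c + rng.poisson(indep_mean))
    truth = GroundTruth()
    for name, mean_ref, mean_cmp in spec.planted_hits:
        names.append(name)
        ref.append(rng.poisson(mean_ref))
        cmp_.append(rng.poisson(mean_cmp))
        truth.planted_hits.append([name, float(mean_ref), float(mean_cmp)])
    counts = pd.DataFrame(
        {spec.ref_condition: ref, spec.cmp_condition: cmp_},
        index=pd.Index(names, name="protein"),
        dtype="int64",
    )
    return PeptideCountTable(counts, spec.ref_condition, spec.cmp_condition), truth
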
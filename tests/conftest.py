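import numpy as np
import pandas as pd
import pytest

from retroquant import (
    AlignedFragmentSet,
    FamilyCountTable,
    ManifestEntry,
    RepeatAnnotation,
    RepeatInterval,
    SampleManifest,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_fragments(rows, n_skipped=0):
    """rows: iterable of (contig, start, end, strand)."""
    rows = list(rows)
    return AlignedFragmentSet.from_arrays(
        [r[0] for r in rows],
        np.array([r[1] for r in rows], dtype="int64"),
        np.array([r[2] for r in rows], dtype="int64"),
        [r[3] for r in rows],
        n_skipped_unmapped=n_skipped,
    )


def random_fragments(rng, n, contigs=("chr1",), max_pos=10_000, frag_len=(20, 200)):
    contig = np.array(contigs, dtype=object)[rng.integers(0, len(contigs), n)]
    start = rng.integers(0, max_pos, n)
    length = rng.integers(frag_len[0], frag_len[1] + 1, n)
    strand = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    return AlignedFragmentSet.from_arrays(contig, start, start + length, strand)


def make_annotation(rows, background_classes=("DNA",)):
    """rows: (contig, start, end, strand, subfamily, family, class_, id, role)."""
    return RepeatAnnotation(
        [RepeatInterval(*r) for r in rows], background_classes=background_classes
    )


def random_disjoint_annotation(rng, n_intervals, contigs=("chr1",), span=10_000, n_subfamilies=5):
    """Non-overlapping random intervals spread over subfamilies."""
    rows = []
    k = 0
    for contig in contigs:
        cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_intervals, replace=False))
        for i in range(0, len(cuts) - 1, 2):
            s, e = int(cuts[i]), int(cuts[i + 1])
            if e <= s:
                continue
            k += 1
            sub = f"SF{k % n_subfamilies}"
            rows.append((contig, s, e, "+", sub, "FAM", "LTR", f"iv{k}", "unassigned"))
    return make_annotation(rows)


def make_counts(counts_dict, unit_length, library_size, classes=None, level="subfamily"):
    """counts_dict: {sample: {unit: count}}."""
    counts = pd.DataFrame(counts_dict).fillna(0)
    counts.index.name = "unit"
    units = list(counts.index)
    classes = classes or {u: "LTR" for u in units}
    meta = pd.DataFrame(
        {"class_": [classes[u] for u in units], "family": ["FAM"] * len(units)},
        index=counts.index,
    )
    return FamilyCountTable(
        counts=counts,
        unit_length=pd.Series(unit_length, name="unit_length"),
        library_size=pd.Series(library_size, name="library_size"),
        unassigned=pd.Series(0, index=counts.columns, name="unassigned"),
        row_meta=meta,
        level=level,
    )


def chip_manifest(n_treat=3, n_ctrl=2, target="O-GlcNAc", condition="WT"):
    entries = [
        ManifestEntry(f"chip_{i}", "", "chip", target, condition, i) for i in range(1, n_treat + 1)
    ] + [
        ManifestEntry(f"input_{i}", "", "input", "", condition, i) for i in range(1, n_ctrl + 1)
    ]
    return SampleManifest(entries)


def rna_manifest(conditions):
    """conditions: {condition: n_replicates}; sample ids rna_<cond>_<i>."""
    entries = []
    for cond, n in conditions.items():
        entries.extend(
            ManifestEntry(f"rna_{cond}_{i}", "", "rna", "", cond, i) for i in range(1, n + 1)
        )
    return SampleManifest(entries)
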
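"""Counting, deduplication, enrichment ratios, ICR occupancy, metaprofiles."""

import numpy as np
import pandas as pd
import pytest

from retroquant import (
    AlignedFragmentSet,
    UsageError,
    ValidationError,
    count_by_unit,
    coverage_from_fragments,
    deduplicate,
    enrichment,
    icr_occupancy,
    ltr_metaprofile,
    read_counts_tsv,
    write_counts_tsv,
)
from retroquant.annotation import IcrInterval, ManifestEntry, SampleManifest

from conftest import (
    chip_manifest,
    make_annotation,
    make_counts,
    make_fragments,
    random_disjoint_annotation,
    random_fragments,
)


# ---------------------------------------------------------------------------
# deduplicate
# ---------------------------------------------------------------------------


class TestDeduplicate:
    def test_key_includes_strand(self):
        fs = make_fragments(
            [("chr1", 100, 150, "+"), ("chr1", 100, 150, "+"), ("chr1", 100, 150, "+"),
             ("chr1", 100, 150, "-")]
        )
        out = deduplicate(fs)
        assert len(out) == 2
        assert set(out.frame["strand"]) == {"+", "-"}

    def test_idempotent_on_unique_set(self, rng):
        fs = random_fragments(rng, 50, max_pos=100_000)
        once = deduplicate(fs)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_matches_set_based_oracle(self, rng):
        fs = random_fragments(rng, 1000, max_pos=300, frag_len=(10, 30))
        out = deduplicate(fs)
        # independent oracle: unique (contig, start, strand) keys
        keys = set(zip(fs.frame["contig"], fs.frame["start"], fs.frame["strand"]))
        assert len(out) == len(keys)
        out_keys = set(zip(out.frame["contig"], out.frame["start"], out.frame["strand"]))
        assert out_keys == keys
        # first-in-sort-order retention: kept end is the minimum end per key
        ends = {}
        for c, s, e, st in zip(fs.frame["contig"], fs.frame["start"], fs.frame["end"], fs.frame["strand"]):
            k = (c, s, st)
            ends[k] = min(ends.get(k, e), e)
        for c, s, e, st in zip(out.frame["contig"], out.frame["start"], out.frame["end"], out.frame["strand"]):
            assert ends[(c, s, st)] == e


# ---------------------------------------------------------------------------
# count_by_unit
# ---------------------------------------------------------------------------


def brute_force_counts(fragset, annotation, level, mode):
    """Per-fragment Python re-evaluation of the assignment rules."""
    units = {u: 0.0 for u in annotation.unit_lengths(level).index}
    unassigned = 0.0
    ivs = annotation.intervals
    for _, row in fragset.frame.iterrows():
        c, s, e = row["contig"], row["start"], row["end"]
        mid = s + (e - s) // 2
        if mode == "midpoint":
            hits = [iv for iv in ivs if iv.contig == c and iv.start <= mid < iv.end]
            if hits:
                best = min(hits, key=lambda iv: (iv.start, iv.instance_id))
                units[best.unit(level)] += 1
            else:
                unassigned += 1
        elif mode == "any_overlap":
            hits = [iv for iv in ivs if iv.contig == c and iv.start < e and s < iv.end]
            if hits:
                best = max(
                    hits,
                    key=lambda iv: (min(e, iv.end) - max(s, iv.start), -iv.start),
                )
                # explicit id tie-break among equal (overlap, start)
                key = (min(e, best.end) - max(s, best.start), best.start)
                tied = [
                    iv for iv in hits
                    if (min(e, iv.end) - max(s, iv.start), iv.start) == key
                ]
                best = min(tied, key=lambda iv: iv.instance_id)
                units[best.unit(level)] += 1
            else:
                unassigned += 1
        else:  # fractional
            hits = [iv for iv in ivs if iv.contig == c and iv.start < e and s < iv.end]
            if not hits:
                unassigned += 1
                continue
            total = 0.0
            for iv in hits:
                w = (min(e, iv.end) - max(s, iv.start)) / (e - s)
                units[iv.unit(level)] += w
                total += w
            unassigned += max(0.0, 1.0 - total)
    return units, unassigned


class TestCountByUnit:
    def test_midpoint_boundary_example(self):
        ann = make_annotation(
            [
                ("chr1", 50, 160, "+", "A", "F", "LTR", "a1", "unassigned"),
                ("chr1", 160, 300, "+", "B", "F", "LTR", "b1", "unassigned"),
            ]
        )
        fs = make_fragments([("chr1", 100, 200, "+")])  # midpoint 150, in A
        t = count_by_unit(fs, ann)
        assert t.counts.loc["A", "sample"] == 1
        assert t.counts.loc["B", "sample"] == 0

    def test_fragment_outside_all_units_unassigned(self):
        ann = make_annotation([("chr1", 0, 100, "+", "A", "F", "LTR", "a1", "unassigned")])
        fs = make_fragments([("chr1", 500, 600, "+")])
        t = count_by_unit(fs, ann)
        assert t.counts["sample"].sum() == 0
        assert t.unassigned["sample"] == 1

    def test_empty_annotation_rejected(self):
        fs = make_fragments([("chr1", 0, 10, "+")])
        with pytest.raises(ValidationError):
            count_by_unit(fs, make_annotation([]))

    def test_unknown_level_and_mode(self):
        ann = make_annotation([("chr1", 0, 100, "+", "A", "F", "LTR", "a1", "unassigned")])
        fs = make_fragments([("chr1", 0, 10, "+")])
        with pytest.raises(UsageError):
            count_by_unit(fs, ann, level="order")
        with pytest.raises(UsageError):
            count_by_unit(fs, ann, mode="nearest")

    @pytest.mark.parametrize("mode", ["midpoint", "any_overlap", "fractional"])
    def test_matches_brute_force_and_conserves(self, rng, mode):
        for _ in range(5):
            ann = random_disjoint_annotation(rng, 40, contigs=("chr1", "chr2"), span=5000)
            fs = random_fragments(rng, 300, contigs=("chr1", "chr2", "chr3"), max_pos=5200)
            t = count_by_unit(fs, ann, mode=mode)
            expect, expect_un = brute_force_counts(fs, ann, "subfamily", mode)
            for u in t.counts.index:
                assert t.counts.loc[u, "sample"] == pytest.approx(expect[u], abs=1e-9)
            assert t.unassigned["sample"] == pytest.approx(expect_un, abs=1e-9)
            # conservation: assigned + unassigned = total fragments
            assert t.counts["sample"].sum() + t.unassigned["sample"] == pytest.approx(len(fs), abs=1e-9)

    def test_levels_aggregate_consistently(self, rng):
        ann = make_annotation(
            [
                ("chr1", 0, 100, "+", "A1", "ERVK", "LTR", "a1", "unassigned"),
                ("chr1", 200, 300, "+", "A2", "ERVK", "LTR", "a2", "unassigned"),
                ("chr1", 400, 500, "+", "B1", "L1", "LINE", "b1", "unassigned"),
            ]
        )
        fs = random_fragments(rng, 500, max_pos=600, frag_len=(10, 50))
        sub = count_by_unit(fs, ann, level="subfamily")
        fam = count_by_unit(fs, ann, level="family")
        cls = count_by_unit(fs, ann, level="class_")
        assert fam.counts.loc["ERVK", "sample"] == sub.counts.loc[["A1", "A2"], "sample"].sum()
        assert cls.counts.loc["LINE", "sample"] == sub.counts.loc["B1", "sample"]


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


class TestEnrichment:
    def _counts(self, treat, ctrl, lib=1_000_000):
        samples = {}
        for i, v in enumerate(treat, 1):
            samples[f"chip_{i}"] = {"U": v}
        for i, v in enumerate(ctrl, 1):
            samples[f"input_{i}"] = {"U": v}
        return make_counts(samples, {"U": 1000}, {s: lib for s in samples})

    def test_printed_definition_arithmetic(self):
        # cpm means {4, 6, 5} over {2.5, 2.5} -> E = 5 / 2.5 = 2.0
        counts = self._counts([4, 6, 5], [2.5, 2.5])
        res = enrichment(
            counts, chip_manifest(3, 2),
            {"assay": "chip", "target": "O-GlcNAc", "condition": "WT"},
            {"assay": "input", "target": "", "condition": "WT"},
        )
        assert res.table.loc["U", "ratio"] == pytest.approx(2.0)
        assert res.n_treatment == 3 and res.n_control == 2

    def test_identical_samples_give_unit_ratio(self, rng):
        vals = rng.integers(10, 100, 4)
        counts = self._counts(vals[:2], vals[:2])
        res = enrichment(
            counts, chip_manifest(2, 2),
            {"assay": "chip", "target": "O-GlcNAc", "condition": "WT"},
            {"assay": "input", "target": "", "condition": "WT"},
        )
        assert res.table.loc["U", "ratio"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = self._counts([40, 60, 50], [25, 25], lib=1_000_000)
        scaled = self._counts([400, 600, 500], [250, 250], lib=10_000_000)
        keys = (
            {"assay": "chip", "target": "O-GlcNAc", "condition": "WT"},
            {"assay": "input", "target": "", "condition": "WT"},
        )
        r1 = enrichment(base, chip_manifest(3, 2), *keys)
        r2 = enrichment(scaled, chip_manifest(3, 2), *keys)
        pd.testing.assert_series_equal(r1.table["ratio"], r2.table["ratio"])

    def test_control_zero_flagged_not_infinite(self):
        counts = self._counts([10, 10], [0, 0])
        res = enrichment(
            counts, chip_manifest(2, 2),
            {"assay": "chip", "target": "O-GlcNAc", "condition": "WT"},
            {"assay": "input", "target": "", "condition": "WT"},
        )
        row = res.table.loc["U"]
        assert row["control_zero"]
        assert np.isnan(row["ratio"])
        assert not row["enriched"]

    def test_missing_samples_error_lists_keys(self):
        counts = self._counts([1], [1])
        with pytest.raises(UsageError, match="available"):
            enrichment(
                counts, chip_manifest(1, 1),
                {"assay": "chip", "target": "TRIM28", "condition": "WT"},
                {"assay": "input", "target": "", "condition": "WT"},
            )


# ---------------------------------------------------------------------------
# ICR occupancy
# ---------------------------------------------------------------------------


class TestIcrOccupancy:
    def _setup(self, rng, e_by_target, depth=30_000):
        """Two targets over one 2 kb ICR on a 100 kb contig."""
        icrs = [IcrInterval("chr1", 40_000, 42_000, "Kcnq1ot1", "maternal")]
        L = 100_000
        entries, frags = [], {}
        for target, e in e_by_target.items():
            for rep in (1, 2):
                sid = f"{target}_chip_{rep}"
                frags[sid] = _weighted_fragments(rng, L, icrs[0], e, depth)
                entries.append(ManifestEntry(sid, "", "chip", target, "WT", rep))
            sid = f"{target}_input_1"
            frags[sid] = _weighted_fragments(rng, L, icrs[0], 1.0, depth)
            entries.append(ManifestEntry(sid, "", "input", target, "WT", 1))
        return frags, icrs, SampleManifest(entries)

    def test_both_targets_enriched_classified_both(self, rng):
        frags, icrs, man = self._setup(rng, {"O-GlcNAc": 3.0, "TRIM28": 3.0})
        table, summary = icr_occupancy(frags, icrs, man, ["O-GlcNAc", "TRIM28"])
        assert summary["enriched_in_both"] == 1
        assert summary["enriched_in_neither"] == 0

    def test_null_classified_neither(self, rng):
        frags, icrs, man = self._setup(rng, {"O-GlcNAc": 1.0, "TRIM28": 1.0})
        table, summary = icr_occupancy(frags, icrs, man, ["O-GlcNAc", "TRIM28"])
        assert summary["enriched_in_neither"] == 1

    def test_control_zero_excluded_from_denominators(self):
        icrs = [IcrInterval("chr1", 100, 300, "Peg3", "maternal")]
        frags = {
            "T1_chip_1": make_fragments([("chr1", 150, 250, "+")] * 5),
            "T1_input_1": make_fragments([("chr1", 5000, 5100, "+")] * 5),
            "T2_chip_1": make_fragments([("chr1", 150, 250, "+")] * 5),
            "T2_input_1": make_fragments([("chr1", 150, 250, "+")] * 5),
        }
        man = SampleManifest(
            [
                ManifestEntry("T1_chip_1", "", "chip", "T1", "WT", 1),
                ManifestEntry("T1_input_1", "", "input", "T1", "WT", 1),
                ManifestEntry("T2_chip_1", "", "chip", "T2", "WT", 1),
                ManifestEntry("T2_input_1", "", "input", "T2", "WT", 1),
            ]
        )
        table, summary = icr_occupancy(frags, icrs, man, ["T1", "T2"])
        assert summary["n_excluded_control_zero"] == 1
        assert summary["n_evaluable"] == 0

    def test_requires_two_targets(self, rng):
        frags, icrs, man = self._setup(rng, {"O-GlcNAc": 2.0})
        with pytest.raises(UsageError):
            icr_occupancy(frags, icrs, man, ["O-GlcNAc"])

    def test_empty_icr_set_rejected(self, rng):
        frags, icrs, man = self._setup(rng, {"O-GlcNAc": 2.0, "TRIM28": 2.0})
        with pytest.raises(ValidationError):
            icr_occupancy(frags, [], man, ["O-GlcNAc", "TRIM28"])


def _weighted_fragments(rng, L, icr, e, depth, frag_len=100):
    """Fragment midpoints with intensity e over the ICR, 1 elsewhere."""
    w_icr = e * (icr.end - icr.start)
    w_bg = L - (icr.end - icr.start)
    inside = rng.random(depth) < w_icr / (w_icr + w_bg)
    mids = np.where(
        inside,
        rng.integers(icr.start, icr.end, depth),
        rng.integers(0, L, depth),
    )
    starts = np.clip(mids - frag_len // 2, 0, L - frag_len)
    return AlignedFragmentSet.from_arrays(
        np.full(depth, "chr1", dtype=object),
        starts,
        starts + frag_len,
        np.full(depth, "+", dtype=object),
    )


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------


def _ltr_annotation(start=1000, ltr=100, internal=400, strand="+", contig="chr1"):
    total = 2 * ltr + internal
    spans = [(start, start + ltr), (start + ltr, start + ltr + internal), (start + ltr + internal, start + total)]
    roles = ["five_prime_ltr", "internal", "three_prime_ltr"]
    if strand == "-":
        roles = roles[::-1]
    rows = [
        (contig, s, e, strand, "IAP", "ERVK", "LTR", f"IAP.1:{r}", r)
        for (s, e), r in zip(spans, roles)
    ]
    return make_annotation(rows)


class TestMetaprofile:
    def test_uniform_coverage_flat_profile(self, rng):
        ann = _ltr_annotation()
        # tile fragments uniformly: one per position
        fs = make_fragments([("chr1", p, p + 50, "+") for p in range(0, 2000, 1)])
        mp = ltr_metaprofile(fs, ann, "IAP", n_bins=10, contig_lengths={"chr1": 3000})
        assert mp.contrast == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(mp.values, mp.values[0])

    def test_minus_strand_equals_mirrored_plus(self, rng):
        cov_frags = [("chr1", int(p), int(p) + 20, "+") for p in rng.integers(900, 1700, 500)]
        plus = ltr_metaprofile(
            make_fragments(cov_frags), _ltr_annotation(strand="+"), "IAP",
            n_bins=8, contig_lengths={"chr1": 3000},
        )
        # mirror the fragment set around the element centre => minus-strand copy
        lo, hi = 1000, 1600
        mirrored = [("chr1", lo + hi - e, lo + hi - s, "+") for _, s, e, _ in cov_frags]
        minus = ltr_metaprofile(
            make_fragments(mirrored), _ltr_annotation(strand="-"), "IAP",
            n_bins=8, contig_lengths={"chr1": 3000},
        )
        np.testing.assert_allclose(minus.values, plus.values, atol=1e-9)

    def test_no_role_labels_rejected(self):
        ann = make_annotation([("chr1", 0, 500, "+", "IAP", "ERVK", "LTR", "i1", "solo")])
        fs = make_fragments([("chr1", 10, 60, "+")])
        with pytest.raises(ValidationError, match="role"):
            ltr_metaprofile(fs, ann, "IAP")

    def test_profile_averages_across_copies(self):
        rows = []
        for k, start in enumerate((1000, 5000), start=1):
            for (s, e), r in zip(
                [(start, start + 100), (start + 100, start + 500), (start + 500, start + 600)],
                ["five_prime_ltr", "internal", "three_prime_ltr"],
            ):
                rows.append(("chr1", s, e, "+", "IAP", "ERVK", "LTR", f"IAP.{k}:{r}", r))
        ann = make_annotation(rows)
        # copy 1 covered at depth 2, copy 2 at depth 4 over the 5'LTR only
        frags = [("chr1", 1000, 1100, "+")] * 2 + [("chr1", 5000, 5100, "+")] * 4
        mp = ltr_metaprofile(make_fragments(frags), ann, "IAP", n_bins=4, contig_lengths={"chr1": 8000})
        assert mp.n_elements == 2
        assert mp.values[:4] == pytest.approx([3.0] * 4)  # mean of 2 and 4
        assert np.all(mp.values[4:] == 0)


# ---------------------------------------------------------------------------
# coverage + counts round trip
# ---------------------------------------------------------------------------


def test_coverage_matches_naive_accumulation(rng):
    fs = random_fragments(rng, 400, max_pos=900, frag_len=(5, 60))
    cov = coverage_from_fragments(fs, {"chr1": 1000})
    naive = np.zeros(1000)
    for _, row in fs.frame.iterrows():
        naive[row["start"] : row["end"]] += 1
    np.testing.assert_array_equal(cov["chr1"], naive)


def test_counts_tsv_round_trip(tmp_path, rng):
    ann = random_disjoint_annotation(rng, 20)
    fs = {"s1": random_fragments(rng, 500), "s2": random_fragments(rng, 700)}
    t = count_by_unit(fs, ann)
    p = tmp_path / "counts.tsv"
    write_counts_tsv(t, p)
    back = read_counts_tsv(p)
    pd.testing.assert_frame_equal(back.counts, t.counts)
    pd.testing.assert_series_equal(back.library_size, t.library_size)
    assert back.level == t.level
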
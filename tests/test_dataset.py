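"""Anchor normalization, negative-class construction, balancing and splits."""

import numpy as np
import pytest

from insuloop import dataset as ds
from insuloop import seqcore as sc
from insuloop.seqcore import (Anchor, GenomicInterval as GI, LoopPair,
                              MotifHit, Peak)


def mkanchor(chrom, center, side="none", klass=sc.TRUE_ANCHOR, half=500):
    return Anchor(GI(chrom, center - half, center + half), center,
                  side=side, klass=klass)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def brute_force_merge(intervals):
    """Transitive-closure oracle: repeat pairwise merging in any order."""
    items = [(i.chrom, i.start, i.end) for i in set(intervals)]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                ov = min(a[2], b[2]) - max(a[1], b[1])
                la, lb = a[2] - a[1], b[2] - b[1]
                if ov > 0.9 * la or ov > 0.9 * lb:
                    items[i] = (a[0], min(a[1], b[1]), max(a[2], b[2]))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


class TestNormalizeAnchors:
    def test_forced_merge_by_09_rule(self):
        merged = ds.normalize_anchors([GI("chr1", 1000, 2000),
                                       GI("chr1", 1050, 2050)])
        assert [(m.start, m.end) for m in merged] == [(1000, 2050)]

    def test_disjoint_unchanged(self):
        ivs = [GI("chr1", 0, 100), GI("chr1", 5000, 5100)]
        assert ds.normalize_anchors(ivs) == ivs

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(20):
            ivs = []
            for _k in range(rng.integers(2, 12)):
                start = int(rng.integers(0, 5000))
                length = int(rng.integers(50, 1000))
                ivs.append(GI("chr1", start, start + length))
            got = [(m.chrom, m.start, m.end)
                   for m in ds.normalize_anchors(ivs)]
            assert sorted(got) == brute_force_merge(ivs)


class TestStandardize:
    def test_trim_to_4000_around_peak(self):
        a = Anchor(GI("chr1", 0, 10000), 6000)
        out = ds.standardize_anchor(a, 4000)
        assert (out.interval.start, out.interval.end) == (4000, 8000)

    def test_fixpoint(self):
        a = Anchor(GI("chr1", 4000, 8000), 6000)
        assert ds.standardize_anchor(a, 4000).interval == a.interval

    def test_all_lengths_exactly_4000(self, rng):
        for _ in range(100):
            start = int(rng.integers(0, 100000))
            length = int(rng.integers(100, 20000))
            peak = start + int(rng.integers(0, length))
            a = Anchor(GI("chr1", start, start + length), peak)
            assert ds.standardize_anchor(a, 4000).interval.length == 4000


# ---------------------------------------------------------------------------
# non-anchors
# ---------------------------------------------------------------------------

class TestBuildNonanchors:
    GENOME = {"chr1": "A" * 50_000}

    def test_peak_inside_true_anchor_excluded_from_type1(self):
        peaks = [Peak("chr1", 10000, 10400, summit=10200),
                 Peak("chr1", 30000, 30400, summit=30200)]
        hits = [MotifHit("chr1", 10150, 10170, "+", pvalue=1e-6),
                MotifHit("chr1", 30150, 30170, "+", pvalue=1e-6)]
        anchors = [mkanchor("chr1", 10200)]
        out = ds.build_nonanchors(sc.NONANCHOR_TYPE1, peaks, hits, anchors,
                                  self.GENOME, 1000)
        assert [a.peak_center for a in out] == [30200]

    def test_motif_covered_by_peak_excluded_from_type2(self):
        peaks = [Peak("chr1", 10000, 10400, summit=10200)]
        hits = [MotifHit("chr1", 10150, 10170, "+", pvalue=1e-6),
                MotifHit("chr1", 20000, 20020, "-", pvalue=1e-6)]
        out = ds.build_nonanchors(sc.NONANCHOR_TYPE2, peaks, hits, [],
                                  self.GENOME, 1000)
        assert [a.peak_center for a in out] == [20010]

    def test_type3_matches_enumeration_oracle(self):
        hits = [MotifHit("chr1", 4000 * i + 100, 4000 * i + 120, "+",
                         pvalue=1e-6) for i in (2, 5, 9)]
        out = ds.build_nonanchors(sc.NONANCHOR_TYPE3, [], hits, [],
                                  self.GENOME, 4000, stride=4000)
        # brute force: stride-4000 windows not overlapping any hit
        expected = [s for s in range(0, 50_000 - 4000 + 1, 4000)
                    if not any(s < h.end and h.start < s + 4000 for h in hits)]
        assert [a.interval.start for a in out] == expected

    def test_empty_pool_warns(self, caplog):
        with caplog.at_level("WARNING"):
            out = ds.build_nonanchors(sc.NONANCHOR_TYPE1, [], [], [],
                                      self.GENOME, 1000)
        assert out == [] and "empty" in caplog.text


# ---------------------------------------------------------------------------
# span cap and non-loops
# ---------------------------------------------------------------------------

def sorted_interpolation_percentile(values, q):
    """Independent percentile oracle: linear interpolation between order
    statistics at rank (n-1) * q/100."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (v[hi] - v[lo]) * (pos - lo)


class TestSpanCap:
    def test_constant_and_single(self):
        loops = [LoopPair(mkanchor("chr1", 10_000, "left"),
                          mkanchor("chr1", 510_000, "right"))]
        assert ds.compute_span_cap(loops) == 500_000
        assert ds.compute_span_cap(loops * 5) == 500_000

    def test_matches_interpolation_oracle(self, rng):
        spans = rng.integers(5000, 500_000, size=1000)
        loops = [LoopPair(mkanchor("chr1", 10_000, "left"),
                          mkanchor("chr1", 10_000 + int(s), "right"))
                 for s in spans]
        assert ds.compute_span_cap(loops) == pytest.approx(
            sorted_interpolation_percentile(spans, 75))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ds.compute_span_cap([])


def _motif_for(anchor, strand, p=1e-6):
    c = anchor.peak_center
    return MotifHit(anchor.chrom, c - 10, c + 9, strand, pvalue=p)


class TestBuildNonloops:
    def setup_method(self):
        # six true anchors on one chromosome, alternating strands
        self.anchors = [mkanchor("chr1", 10_000 + 3000 * i) for i in range(6)]
        self.strands = ["+", "-", "+", "+", "-", "-"]
        self.hits = [_motif_for(a, s) for a, s in zip(self.anchors, self.strands)]

    def brute_pairs(self, want, span_cap, positives=()):
        pos_keys = {lp.key for lp in positives}
        out = []
        for i, a in enumerate(self.anchors):
            for j, b in enumerate(self.anchors):
                if j <= i:
                    continue
                span = b.peak_center - a.peak_center
                if span > span_cap:
                    continue
                sa, sb = self.strands[i], self.strands[j]
                if want == "convergent" and (sa, sb) != ("+", "-"):
                    continue
                if want == "tandem" and sa != sb:
                    continue
                if want == "divergent" and (sa, sb) != ("-", "+"):
                    continue
                if ("chr1", a.peak_center, b.peak_center) in pos_keys:
                    continue
                out.append((a.peak_center, b.peak_center))
        return sorted(out)

    @pytest.mark.parametrize("label,want", [("nonloop_type1", "convergent"),
                                            ("nonloop_type2", "tandem"),
                                            ("nonloop_type3", "divergent")])
    def test_counts_match_pair_enumeration_oracle(self, label, want):
        cap = 7000.0
        got = ds.build_nonloops(label, self.anchors, [], self.hits, cap)
        keys = sorted((lp.left.peak_center, lp.right.peak_center) for lp in got)
        assert keys == self.brute_pairs(want, cap)

    def test_span_cap_is_strict(self):
        cap = 2999.0  # adjacent anchors are 3000 apart -> all excluded
        assert ds.build_nonloops("nonloop_type1", self.anchors, [],
                                 self.hits, cap) == []

    def test_positive_pairs_excluded(self):
        positives = [LoopPair(
            Anchor(self.anchors[0].interval, self.anchors[0].peak_center,
                   side="left"),
            Anchor(self.anchors[1].interval, self.anchors[1].peak_center,
                   side="right"))]
        cap = 7000.0
        got = ds.build_nonloops("nonloop_type1", self.anchors, [], self.hits,
                                cap, positive_loops=positives)
        keys = {(lp.left.peak_center, lp.right.peak_center) for lp in got}
        assert (10_000, 13_000) not in keys

    def test_orientation_taxonomy(self):
        # (+, -) pair is convergent: eligible for type1, not type2/3
        pair = self.anchors[:2]
        hits = self.hits[:2]
        assert ds.build_nonloops("nonloop_type1", pair, [], hits, 1e9)
        assert not ds.build_nonloops("nonloop_type2", pair, [], hits, 1e9)
        assert not ds.build_nonloops("nonloop_type3", pair, [], hits, 1e9)

    def test_best_pvalue_hit_decides_orientation(self):
        a, b = self.anchors[:2]
        hits = [_motif_for(a, "-", p=1e-8), _motif_for(a, "+", p=1e-6),
                _motif_for(b, "-", p=1e-6)]
        # best hit on a is '-', so (a, b) is tandem, not convergent
        assert not ds.build_nonloops("nonloop_type1", [a, b], [], hits, 1e9)
        assert ds.build_nonloops("nonloop_type2", [a, b], [], hits, 1e9)

    def test_type4_and_type5_partners(self):
        true_a = [self.anchors[0]]
        non_with_motif = [mkanchor("chr1", 14_000, klass=sc.NONANCHOR_TYPE1)]
        non_plain = [mkanchor("chr1", 16_000, klass=sc.NONANCHOR_TYPE3)]
        hits = [self.hits[0], _motif_for(non_with_motif[0], "-")]
        t4 = ds.build_nonloops("nonloop_type4", true_a,
                               non_with_motif + non_plain, hits, 1e9)
        assert [(lp.left.peak_center, lp.right.peak_center) for lp in t4] == \
            [(10_000, 14_000)]
        t5 = ds.build_nonloops("nonloop_type5", true_a,
                               non_with_motif + non_plain, hits, 1e9)
        assert [(lp.left.peak_center, lp.right.peak_center) for lp in t5] == \
            [(10_000, 16_000)]


class TestLabelOrientation:
    def test_roles_and_both_side_exclusion(self):
        a = mkanchor("chr1", 10_000)
        b = mkanchor("chr1", 20_000)
        c = mkanchor("chr1", 30_000)
        loops = [LoopPair(Anchor(a.interval, 10_000, side="left"),
                          Anchor(b.interval, 20_000, side="right")),
                 LoopPair(Anchor(b.interval, 20_000, side="left"),
                          Anchor(c.interval, 30_000, side="right"))]
        out = ds.label_orientation([a, b, c], loops)
        sides = {x.peak_center: x.side for x in out}
        # b is both a left and a right anchor -> excluded
        assert sides == {10_000: "left", 30_000: "right"}


# ---------------------------------------------------------------------------
# assembly / balancing / augmentation / splits
# ---------------------------------------------------------------------------

def _mini_universe(rng, n_pos_per_chrom=20, chroms=("chr1", "chr2", "chr16",
                                                    "chr7")):
    genome = {c: "".join(rng.choice(list("ACGT"), size=40_000)) for c in chroms}
    positives, negs = [], {sc.NONANCHOR_TYPE1: [], sc.NONANCHOR_TYPE2: [],
                           sc.NONANCHOR_TYPE3: []}
    for c in chroms:
        for i in range(n_pos_per_chrom):
            positives.append(mkanchor(c, 1000 + 800 * i, half=200))
        for i, k in enumerate(negs):
            for j in range(n_pos_per_chrom):
                negs[k].append(mkanchor(c, 20_000 + 800 * (3 * j + i),
                                        half=200, klass=k))
    return genome, positives, negs


class TestAssembleAndSplit:
    def test_negative_mix_and_balance(self, rng):
        genome, positives, negs = _mini_universe(rng)
        sets = ds.assemble_and_split(positives, negs, "anchor",
                                     ds.DatasetSplit(), genome, 400,
                                     augment=False, seed=0)
        tr = sets["train"]
        n_pos = int(tr.y.sum())
        assert n_pos == (tr.y == 0).sum()  # balanced
        counts = tr.manifest[tr.y == 0].klass.value_counts()
        assert counts[sc.NONANCHOR_TYPE1] == round(0.5 * n_pos)
        assert counts[sc.NONANCHOR_TYPE2] == round(0.3 * n_pos)
        assert counts[sc.NONANCHOR_TYPE3] == n_pos - round(0.5 * n_pos) - round(0.3 * n_pos)

    def test_test_partition_keeps_all_negatives(self, rng):
        genome, positives, negs = _mini_universe(rng)
        sets = ds.assemble_and_split(positives, negs, "anchor",
                                     ds.DatasetSplit(), genome, 400,
                                     augment=False, seed=0)
        n_neg_test = int((sets["test"].y == 0).sum())
        assert n_neg_test == 3 * 20  # every chr7 negative of each type

    def test_no_chromosome_leakage(self, rng):
        genome, positives, negs = _mini_universe(rng)
        sets = ds.assemble_and_split(positives, negs, "anchor",
                                     ds.DatasetSplit(), genome, 400,
                                     augment=False, seed=0)
        seen = {p: set(sets[p].manifest.chrom) for p in sets}
        assert seen["train"] & seen["val"] == set()
        assert seen["train"] & seen["test"] == set()
        assert seen["val"] & seen["test"] == set()

    def test_augmentation_doubles_and_reverse_complements(self, rng):
        genome, positives, negs = _mini_universe(rng)
        plain = ds.assemble_and_split(positives, negs, "anchor",
                                      ds.DatasetSplit(), genome, 400,
                                      augment=False, seed=0)
        aug = ds.assemble_and_split(positives, negs, "anchor",
                                    ds.DatasetSplit(), genome, 400,
                                    augment=True, seed=0)
        n = plain["train"].y.size
        assert aug["train"].y.size == 2 * n
        x = aug["train"].inputs[0]
        assert np.array_equal(x[n:], sc.rc_encoded(x[:n]))

    def test_loop_mix_ratios(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=200_000)),
                  "chr16": "".join(rng.choice(list("ACGT"), size=200_000)),
                  "chr7": "".join(rng.choice(list("ACGT"), size=200_000))}
        def mkloop(c, i, label=sc.POSITIVE):
            return LoopPair(mkanchor(c, 2000 + 900 * i, "left", half=200),
                            mkanchor(c, 2000 + 900 * i + 50_000, "right",
                                     half=200), label=label)
        positives = [mkloop(c, i) for c in genome for i in range(40)]
        negs = {t: [mkloop(c, 50 + i, t) for c in genome for i in range(40)]
                for t in sc.NONLOOP_TYPES}
        sets = ds.assemble_and_split(positives, negs, "loop",
                                     ds.DatasetSplit(), genome, 400,
                                     augment=False, seed=0)
        tr = sets["train"]
        n_pos = int(tr.y.sum())
        counts = tr.manifest[tr.y == 0].type.value_counts()
        expect = {"nonloop_type1": 0.5, "nonloop_type2": 0.1,
                  "nonloop_type3": 0.1, "nonloop_type4": 0.2,
                  "nonloop_type5": 0.1}
        for t, frac in expect.items():
            assert abs(counts.get(t, 0) - frac * n_pos) <= 1

    def test_loop_augmentation_swaps_sides(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=200_000))}
        loops = [LoopPair(mkanchor("chr1", 2000 + 900 * i, "left", half=200),
                          mkanchor("chr1", 2000 + 900 * i + 50_000, "right",
                                   half=200)) for i in range(10)]
        negs = {"nonloop_type1": [LoopPair(
            mkanchor("chr1", 2400 + 900 * i, "left", half=200),
            mkanchor("chr1", 2400 + 900 * i + 50_000, "right", half=200),
            label="nonloop_type1") for i in range(10)]}
        sets = ds.assemble_and_split(loops, negs, "loop",
                                     ds.DatasetSplit(test_chroms=frozenset({"chrX"}),
                                                     val_chroms=frozenset({"chrY"})),
                                     genome, 400, augment=True, seed=0)
        xl, xr = sets["train"].inputs
        n = sets["train"].y.size // 2
        assert np.array_equal(xl[n:], sc.rc_encoded(xr[:n]))
        assert np.array_equal(xr[n:], sc.rc_encoded(xl[:n]))

    def test_small_pool_renormalized(self, rng, caplog):
        genome, positives, negs = _mini_universe(rng)
        negs[sc.NONANCHOR_TYPE1] = negs[sc.NONANCHOR_TYPE1][:3]  # starve type 1
        with caplog.at_level("INFO"):
            sets = ds.assemble_and_split(positives, negs, "anchor",
                                         ds.DatasetSplit(), genome, 400,
                                         augment=False, seed=0)
        tr = sets["train"]
        assert int(tr.y.sum()) == int((tr.y == 0).sum())  # still balanced
        assert "renormalizing" in caplog.text
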
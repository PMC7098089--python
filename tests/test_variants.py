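"""Variant application, loop scoring, deletion scans and cohort summaries."""

import numpy as np
import pytest

from insuloop import models as md
from insuloop import variants as ve
from insuloop.seqcore import (Anchor, GenomicInterval as GI, LoopPair,
                              Variant, extract_window)

RNG = np.random.default_rng(17)
GENOME = {"chr1": "".join(RNG.choice(list("ACGT"), size=60_000))}


def window(start, length=4000):
    return GI("chr1", start, start + length)


def ref_window(w):
    return extract_window(GENOME, w.chrom, w.start + w.length // 2, w.length)


class TestApplyVariants:
    def test_single_snv_substitutes_one_base(self):
        w = window(10_000)
        pos = 11_234
        ref = GENOME["chr1"][pos]
        alt = "A" if ref != "A" else "C"
        seq, n = ve.apply_variants_to_window(
            GENOME, w, [Variant("chr1", pos, ref, alt, "s")])
        assert n == 1 and len(seq) == 4000
        expected = list(ref_window(w))
        expected[pos - w.start] = alt
        assert seq == "".join(expected)

    def test_zero_variants_identity(self):
        w = window(10_000)
        seq, n = ve.apply_variants_to_window(GENOME, w, [])
        assert n == 0 and seq == ref_window(w)

    def test_400_base_deletion_restores_length_center_anchored(self):
        w = window(10_000)
        center = 12_000
        dstart = 10_500  # deletion fully left of the window center
        ref = GENOME["chr1"][dstart:dstart + 401]
        v = Variant("chr1", dstart, ref, ref[0], "s")
        seq, n = ve.apply_variants_to_window(GENOME, w, [v])
        assert n == 1 and len(seq) == 4000
        # independent construction: delete from the chromosome string, then
        # re-cut 4000 bases around the (shifted) original center base
        edited = GENOME["chr1"][:dstart + 1] + GENOME["chr1"][dstart + 401:]
        c_edit = center - 400
        assert seq == edited[c_edit - 2000:c_edit + 2000]
        # right half of the window is untouched
        assert seq[2000:] == ref_window(w)[2000:]

    def test_deletion_overlapping_window_edge(self):
        w = window(10_000)
        dstart = 9_900  # starts before the window
        ref = GENOME["chr1"][dstart:dstart + 301]
        v = Variant("chr1", dstart, ref, ref[0], "s")
        seq, n = ve.apply_variants_to_window(GENOME, w, [v])
        assert n == 1 and len(seq) == 4000

    def test_insertion_recenters_symmetrically(self):
        w = window(10_000)
        pos = 11_000
        ref = GENOME["chr1"][pos]
        v = Variant("chr1", pos, ref, ref + "GATTACA", "s")
        seq, n = ve.apply_variants_to_window(GENOME, w, [v])
        assert n == 1 and len(seq) == 4000
        edited = GENOME["chr1"][:pos + 1] + "GATTACA" + GENOME["chr1"][pos + 1:]
        c_edit = 12_000 + 7
        assert seq == edited[c_edit - 2000:c_edit + 2000]

    def test_snv_then_inverse_restores_reference(self):
        w = window(10_000)
        pos = 11_500
        ref = GENOME["chr1"][pos]
        alt = "G" if ref != "G" else "T"
        seq1, _ = ve.apply_variants_to_window(
            GENOME, w, [Variant("chr1", pos, ref, alt, "s")])
        genome2 = {"chr1": GENOME["chr1"][:pos] + alt + GENOME["chr1"][pos + 1:]}
        seq2, _ = ve.apply_variants_to_window(
            genome2, w, [Variant("chr1", pos, alt, ref, "s")])
        assert seq2 == ref_window(w)

    def test_ref_mismatch_rejected(self, caplog):
        w = window(10_000)
        pos = 11_000
        wrong = "A" if GENOME["chr1"][pos] != "A" else "C"
        with caplog.at_level("INFO"):
            seq, n = ve.apply_variants_to_window(
                GENOME, w, [Variant("chr1", pos, wrong, "G", "s")])
        assert n == 0 and seq == ref_window(w)
        assert "mismatch" in caplog.text

    def test_overlapping_variants_keep_leftmost(self):
        w = window(10_000)
        pos = 11_000
        ref3 = GENOME["chr1"][pos:pos + 3]
        v1 = Variant("chr1", pos, ref3, ref3[0], "s")          # deletes 2 bases
        v2 = Variant("chr1", pos + 1, GENOME["chr1"][pos + 1],
                     "A" if GENOME["chr1"][pos + 1] != "A" else "C", "s")
        seq_both, n = ve.apply_variants_to_window(GENOME, w, [v2, v1])
        seq_first, _ = ve.apply_variants_to_window(GENOME, w, [v1])
        assert n == 1 and seq_both == seq_first


# ---------------------------------------------------------------------------
# loop scoring with a tiny (untrained) model
# ---------------------------------------------------------------------------

CFG = md.ModelConfig(anchor_length=400, rnn_window=80, scale=1 / 16)


@pytest.fixture(scope="module")
def loop_model():
    cnn = md.build_model("cnn_anchor", CFG, 0)
    rnn = md.build_model("rnn_anchor", CFG, 1)
    anchor = md.build_model("anchor", CFG, 2, components={"cnn": cnn,
                                                          "rnn": rnn})
    orient = md.build_model("orientation", CFG, 3,
                            components={"anchor": anchor})
    return md.build_model("loop", CFG, 4, components={"anchor": anchor,
                                                      "orientation": orient})


@pytest.fixture(scope="module")
def toy_loop():
    return LoopPair(Anchor(GI("chr1", 10_000, 10_400), 10_200, side="left"),
                    Anchor(GI("chr1", 30_000, 30_400), 30_200, side="right"))


class TestScoreLoops:
    def test_totality_and_zero_variant_bit_equality(self, loop_model, toy_loop):
        variants = {
            "s_empty": [],
            "s_far": [Variant("chr1", 50_000, GENOME["chr1"][50_000],
                              "A" if GENOME["chr1"][50_000] != "A" else "C",
                              "s_far")],
            "s_hit": [Variant("chr1", 10_100, GENOME["chr1"][10_100],
                              "A" if GENOME["chr1"][10_100] != "A" else "C",
                              "s_hit")],
        }
        records = ve.score_loops(loop_model, {"L0": toy_loop}, GENOME, variants)
        assert len(records) == 3  # one per (loop, sample)
        by_sample = {r.sample_id: r for r in records}
        assert by_sample["s_empty"].delta == 0.0
        assert by_sample["s_empty"].p_alt == by_sample["s_empty"].p_ref
        assert by_sample["s_far"].delta == 0.0
        assert by_sample["s_hit"].n_variants_applied == 1

    def test_probabilities_in_unit_interval(self, loop_model, toy_loop):
        records = ve.score_loops(loop_model, {"L0": toy_loop}, GENOME,
                                 {"s": []})
        r = records[0]
        assert 0.0 <= r.p_ref <= 1.0 and 0.0 <= r.p_alt <= 1.0


class TestSaturationScan:
    def test_one_delta_per_position(self, loop_model, toy_loop):
        region = GI("chr1", 10_050, 10_450)  # 400 bases over the left anchor
        out = ve.saturation_deletion_scan(loop_model, toy_loop, region, GENOME)
        # positions 10_400..10_449 fall outside the 400-base anchor window
        assert len(out) == 350
        region = GI("chr1", 10_000, 10_400)
        out = ve.saturation_deletion_scan(loop_model, toy_loop, region, GENOME)
        assert len(out) == 400
        assert list(out.pos) == list(range(10_000, 10_400))

    def test_region_outside_anchors_warns_and_empty(self, loop_model, toy_loop,
                                                    caplog):
        with caplog.at_level("WARNING"):
            out = ve.saturation_deletion_scan(
                loop_model, toy_loop, GI("chr1", 50_000, 50_100), GENOME)
        assert out.empty and "outside" in caplog.text


# ---------------------------------------------------------------------------
# thresholds and cohort summary
# ---------------------------------------------------------------------------

def rec(loop, sample, delta, p_ref=0.9):
    return ve.DisruptionRecord(loop, sample, p_ref, p_ref - delta, 1)


class TestDisruptionThreshold:
    def test_matches_interpolation_oracle(self):
        deltas = [0.01 * k for k in range(1, 101)]
        records = [rec("L", f"s{i}", d) for i, d in enumerate(deltas)]
        got = ve.disruption_threshold(records)
        v = sorted(deltas)
        pos = (len(v) - 1) * 0.9
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = v[lo] + (v[hi] - v[lo]) * (pos - lo)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_deltas(self):
        records = [rec("L", f"s{i}", 0.25) for i in range(5)]
        assert ve.disruption_threshold(records) == pytest.approx(0.25)

    def test_negative_deltas_excluded(self):
        records = [rec("L", "a", -0.5), rec("L", "b", 0.2), rec("L", "c", 0.4)]
        assert ve.disruption_threshold(records, percentile=50) == \
            pytest.approx(0.3)

    def test_no_reductions_error(self):
        with pytest.raises(ValueError):
            ve.disruption_threshold([rec("L", "a", -0.1), rec("L", "b", 0.0)])


class TestSummarizeDisruption:
    def make_records(self, rng, n_loops=5, n_samples=20):
        deltas = rng.uniform(-0.1, 0.5, size=(n_loops, n_samples))
        records = [rec(f"L{i}", f"s{j:02d}", deltas[i, j])
                   for i in range(n_loops) for j in range(n_samples)]
        return deltas, records

    def test_matches_brute_force_enumeration(self, rng):
        deltas, records = self.make_records(rng)
        threshold = 0.3
        summary = ve.summarize_disruption(records, threshold,
                                          recurrence_fraction=0.10)
        # brute force: loop disrupted in a sample iff delta >= threshold
        hit = deltas >= threshold
        min_count = max(1, int(np.floor(0.10 * 20)))
        expect = sorted(f"L{i}" for i in range(5)
                        if hit[i].sum() >= min_count)
        assert summary.recurrent_loops == expect
        assert summary.min_count == min_count
        for j in range(20):
            assert summary.per_sample_counts[f"s{j:02d}"] == hit[:, j].sum()

    def test_recurrence_rounding_modes(self):
        # 10% of 241 patients: floor -> 24 (matching cohort arithmetic), ceil -> 25
        records = [rec("L0", f"s{j}", 0.5 if j < 24 else -0.1)
                   for j in range(241)]
        floor_sum = ve.summarize_disruption(records, 0.4, rounding="floor")
        ceil_sum = ve.summarize_disruption(records, 0.4, rounding="ceil")
        assert floor_sum.min_count == 24 and floor_sum.recurrent_loops == ["L0"]
        assert ceil_sum.min_count == 25 and ceil_sum.recurrent_loops == []

    def test_gene_containment_requires_full_inclusion(self):
        loop = LoopPair(Anchor(GI("chr1", 1000, 2000), 1500, side="left"),
                        Anchor(GI("chr1", 9000, 10_000), 9500, side="right"))
        genes = {"inside": GI("chr1", 3000, 4000),
                 "straddling": GI("chr1", 9500, 10_500)}
        records = [rec("L0", f"s{j}", 0.5) for j in range(10)]
        summary = ve.summarize_disruption(records, 0.4, loops={"L0": loop},
                                          genes=genes)
        assert summary.genes_in_recurrent_loops == ["inside"]
        hit, miss = summary.gene_sample_partition["inside"]
        assert len(hit) == 10 and miss == []

    def test_raising_threshold_never_increases_count(self, rng):
        _, records = self.make_records(rng)
        counts = []
        for t in (0.1, 0.2, 0.3, 0.4):
            s = ve.summarize_disruption(records, t)
            counts.append(int(s.per_sample_counts.sum()))
        assert counts == sorted(counts, reverse=True)
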
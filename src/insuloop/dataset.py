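"""Dataset construction: anchor normalization, negative classes, splits.

Turns loops, binding peaks and motif hits into standardized 4000-base
anchors, the three non-anchor and five non-loop negative classes, balanced
and reverse-complement-augmented training sets, and chromosome-held-out
splits (default: chr7/chr8 test, chr16 validation).

Negative taxonomy
-----------------
Non-anchors: type 1 = bound peak (contains a motif) that anchors no loop;
type 2 = motif occurrence not covered by any peak; type 3 = windows free of
motif occurrences. Non-loops: type 1/2/3 = pairs of true anchors whose motif
orientations are convergent / tandem / divergent; type 4 = a true anchor
paired with a motif-bearing non-anchor in convergent orientation; type 5 = a
true anchor paired with a motif-free non-anchor. Non-loop spans are capped
at the 75th percentile of true-loop spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import (Anchor, GenomicInterval, LoopPair, MotifHit, Peak,
                      NONANCHOR_TYPE1, NONANCHOR_TYPE2, NONANCHOR_TYPE3,
                      NONLOOP_TYPES, TRUE_ANCHOR,
                      encode_batch, extract_window, rc_encoded)

logger = logging.getLogger(__name__)

ANCHOR_NEGATIVE_MIX = {NONANCHOR_TYPE1: 0.50, NONANCHOR_TYPE2: 0.30,
                       NONANCHOR_TYPE3: 0.20}
LOOP_NEGATIVE_MIX = {"nonloop_type1": 0.50, "nonloop_type2": 0.10,
                     "nonloop_type3": 0.10, "nonloop_type4": 0.20,
                     "nonloop_type5": 0.10}


# ---------------------------------------------------------------------------
# anchor normalization and standardization
# ---------------------------------------------------------------------------

def _merge_rule(a: GenomicInterval, b: GenomicInterval) -> bool:
    ov = a.overlap(b)
    return ov > 0.9 * a.length or ov > 0.9 * b.length


def normalize_anchors(raw_anchors: Sequence[GenomicInterval]
                      ) -> list[GenomicInterval]:
    """Merge near-equal anchors to a fixpoint.

    Two anchors are considered equal and merged (interval union) when their
    overlap exceeds 0.9x the length of either one. Merging is repeated in
    coordinate order until no pair qualifies, which makes the result
    independent of input order.
    """
    intervals = sorted(set((i.chrom, i.start, i.end) for i in raw_anchors))
    intervals = [GenomicInterval(c, s, e) for c, s, e in intervals]
    changed = True
    while changed:
        changed = False
        out: list[GenomicInterval] = []
        for iv in intervals:
            if out and _merge_rule(out[-1], iv) and out[-1].chrom == iv.chrom:
                prev = out.pop()
                out.append(GenomicInterval(iv.chrom,
                                           min(prev.start, iv.start),
                                           max(prev.end, iv.end)))
                changed = True
            else:
                out.append(iv)
        intervals = out
    return intervals


def normalize_loops(loops: Sequence[LoopPair],
                    peaks: Sequence[Peak] | None = None
                    ) -> tuple[list[Anchor], list[LoopPair]]:
    """Normalize loop anchors and re-express loops over the merged set.

    The peak center of a merged anchor is its midpoint, unless ``peaks``
    provides a summit, in which case the summit of the longest contributing
    peak is used. Duplicate loops collapsing onto the same merged pair are
    deduplicated.
    """
    raw = [lp.left.interval for lp in loops] + [lp.right.interval for lp in loops]
    merged = normalize_anchors(raw)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    def find(iv: GenomicInterval) -> GenomicInterval:
        best, best_ov = None, -1
        for cand in by_chrom.get(iv.chrom, ()):
            ov = cand.overlap(iv)
            if ov > best_ov:
                best, best_ov = cand, ov
        return best

    centers: dict[tuple, int] = {}
    if peaks:
        best_len: dict[tuple, int] = {}
        for p in peaks:
            m = find(p)
            if m is None:
                continue
            key = (m.chrom, m.start, m.end)
            if p.length > best_len.get(key, -1):
                best_len[key] = p.length
                centers[key] = p.summit

    anchors: dict[tuple, Anchor] = {}
    for iv in merged:
        key = (iv.chrom, iv.start, iv.end)
        pc = centers.get(key, iv.midpoint)
        anchors[key] = Anchor(iv, pc, klass=TRUE_ANCHOR)

    out: dict[tuple, LoopPair] = {}
    for lp in loops:
        a = anchors[(lambda m: (m.chrom, m.start, m.end))(find(lp.left.interval))]
        b = anchors[(lambda m: (m.chrom, m.start, m.end))(find(lp.right.interval))]
        if a.peak_center == b.peak_center:
            continue  # both anchors merged into one region
        if a.peak_center > b.peak_center:
            a, b = b, a
        new = LoopPair(replace(a, side="left"), replace(b, side="right"))
        out.setdefault(new.key, new)
    return list(anchors.values()), list(out.values())


def standardize_anchor(anchor: Anchor, target_length: int = 4000) -> Anchor:
    """Trim or expand an anchor to ``target_length`` centered at its peak."""
    pc = anchor.peak_center
    iv = GenomicInterval(anchor.chrom, pc - target_length // 2,
                         pc - target_length // 2 + target_length,
                         anchor.interval.strand)
    return replace(anchor, interval=iv)


def standardize_loop(loop: LoopPair, target_length: int = 4000) -> LoopPair:
    return LoopPair(standardize_anchor(loop.left, target_length),
                    standardize_anchor(loop.right, target_length),
                    label=loop.label)


# ---------------------------------------------------------------------------
# negative anchors
# ---------------------------------------------------------------------------

def _overlaps_any(iv: GenomicInterval, others: Mapping[str, np.ndarray]) -> bool:
    """Overlap test against {chrom: sorted (n, 2) start/end array}."""
    arr = others.get(iv.chrom)
    if arr is None or not len(arr):
        return False
    i = np.searchsorted(arr[:, 0], iv.end)  # candidates starting before iv.end
    return bool((arr[:i, 1] > iv.start).any())


def _index_intervals(ivs: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    by: dict[str, list] = {}
    for iv in ivs:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in by.items()}


def build_nonanchors(klass: str, peaks: Sequence[Peak],
                     motif_hits: Sequence[MotifHit],
                     true_anchors: Sequence[Anchor],
                     genome: Mapping[str, str],
                     anchor_length: int = 4000, *,
                     stride: int | None = None,
                     n_windows: int | None = None,
                     seed: int = 0) -> list[Anchor]:
    """Build one of the three non-anchor negative classes, standardized.

    type 1: peaks that contain a motif hit but overlap no true anchor,
    centered at peak summits. type 2: motif hits covered by no peak, centered
    on the motif. type 3: windows overlapping no motif hit, enumerated at
    ``stride`` (default: anchor_length) and, when ``n_windows`` is given,
    subsampled with a seeded RNG.
    """
    hit_idx = _index_intervals(motif_hits)
    peak_idx = _index_intervals(peaks)
    anchor_idx = _index_intervals(a.interval for a in true_anchors)

    out: list[Anchor] = []
    if klass == NONANCHOR_TYPE1:
        for p in peaks:
            if _overlaps_any(p, hit_idx) and not _overlaps_any(p, anchor_idx):
                out.append(standardize_anchor(
                    Anchor(p, p.summit, klass=klass), anchor_length))
    elif klass == NONANCHOR_TYPE2:
        for h in motif_hits:
            if not _overlaps_any(h, peak_idx):
                out.append(standardize_anchor(
                    Anchor(h, h.midpoint, klass=klass), anchor_length))
    elif klass == NONANCHOR_TYPE3:
        step = stride or anchor_length
        candidates: list[Anchor] = []
        for chrom in sorted(genome):
            size = len(genome[chrom])
            for start in range(0, size - anchor_length + 1, step):
                iv = GenomicInterval(chrom, start, start + anchor_length)
                if not _overlaps_any(iv, hit_idx):
                    candidates.append(Anchor(iv, iv.midpoint, klass=klass))
        if n_windows is not None and n_windows < len(candidates):
            rng = np.random.default_rng(seed)
            pick = rng.choice(len(candidates), size=n_windows, replace=False)
            candidates = [candidates[i] for i in sorted(pick)]
        out = candidates
    else:
        raise ValueError(f"unknown non-anchor class {klass!r}")
    if not out:
        logger.warning("build_nonanchors(%s): empty candidate pool", klass)
    return out


# ---------------------------------------------------------------------------
# loops and non-loops
# ---------------------------------------------------------------------------

def compute_span_cap(positive_loops: Sequence[LoopPair]) -> float:
    """75th percentile (linear interpolation) of true-loop spans."""
    if not positive_loops:
        raise ValueError("no positive loops")
    return float(np.percentile([lp.span for lp in positive_loops], 75))


def anchor_orientation_class(anchor: Anchor, motif_hits: Sequence[MotifHit]
                             ) -> str | None:
    """Strand of the anchor's best-p-value contained motif hit, or None."""
    best: MotifHit | None = None
    for h in motif_hits:
        if h.overlap(anchor.interval) > 0 and (best is None or h.pvalue < best.pvalue):
            best = h
    return best.strand if best else None


def build_nonloops(label: str, true_anchors: Sequence[Anchor],
                   nonanchors: Sequence[Anchor],
                   motif_hits: Sequence[MotifHit],
                   span_cap: float, *,
                   positive_loops: Sequence[LoopPair] = (),
                   max_pairs: int | None = None,
                   seed: int = 0) -> list[LoopPair]:
    """Enumerate non-loop candidate pairs of one of the five classes.

    Pairs are ordered left/right by coordinate, constrained to span <=
    ``span_cap`` and to be absent from the positive loop set. Orientation
    classes come from each anchor's best-p-value motif hit; anchors without
    any hit are skipped (with a logged count) for classes 1-4. When
    ``max_pairs`` is set the enumeration is subsampled with a seeded RNG.
    """
    if label not in NONLOOP_TYPES:
        raise ValueError(f"unknown non-loop class {label!r}")
    positive_keys = {lp.key for lp in positive_loops}

    def strands(anchors):
        info, skipped = [], 0
        for a in anchors:
            s = anchor_orientation_class(a, motif_hits)
            if s is None:
                skipped += 1
            info.append((a, s))
        return info, skipped

    true_info, skipped_true = strands(true_anchors)
    if skipped_true and label != "nonloop_type5":
        logger.info("build_nonloops(%s): %d true anchors without motif hits "
                    "skipped", label, skipped_true)

    def emit(a: Anchor, b: Anchor) -> LoopPair | None:
        if a.chrom != b.chrom:
            return None
        if a.peak_center > b.peak_center:
            a, b = b, a
        elif a.peak_center == b.peak_center:
            return None
        lp = LoopPair(replace(a, side="left"), replace(b, side="right"),
                      label=label)
        if lp.span > span_cap or lp.key in positive_keys:
            return None
        return lp

    pairs: list[LoopPair] = []
    if label in ("nonloop_type1", "nonloop_type2", "nonloop_type3"):
        want = {"nonloop_type1": ("+", "-"), "nonloop_type3": ("-", "+")}
        infos = sorted(((a, s) for a, s in true_info if s is not None),
                       key=lambda t: (t[0].chrom, t[0].peak_center))
        for i, (a, sa) in enumerate(infos):
            for b, sb in infos[i + 1:]:
                if b.chrom != a.chrom or b.peak_center - a.peak_center > span_cap:
                    break
                if label == "nonloop_type2":
                    ok = sa == sb
                else:
                    ok = (sa, sb) == want[label]
                if ok:
                    lp = emit(a, b)
                    if lp:
                        pairs.append(lp)
    elif label == "nonloop_type4":
        non_info, skipped_non = strands(nonanchors)
        non_info = [(a, s) for a, s in non_info if s is not None]
        if skipped_non:
            logger.info("build_nonloops(type4): %d non-anchors without motif "
                        "hits skipped", skipped_non)
        for a, sa in true_info:
            if sa is None:
                continue
            for b, sb in non_info:
                if a.chrom != b.chrom:
                    continue
                first, second = ((a, sa), (b, sb)) if a.peak_center < b.peak_center \
                    else ((b, sb), (a, sa))
                if (first[1], second[1]) != ("+", "-"):
                    continue
                lp = emit(a, b)
                if lp:
                    pairs.append(lp)
    elif label == "nonloop_type5":
        plain = [a for a in nonanchors
                 if anchor_orientation_class(a, motif_hits) is None]
        for a, _sa in true_info:
            for b in plain:
                if a.chrom != b.chrom:
                    continue
                lp = emit(a, b)
                if lp:
                    pairs.append(lp)

    if max_pairs is not None and max_pairs < len(pairs):
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(pick)]
    return pairs


def label_orientation(true_anchors: Sequence[Anchor],
                      positive_loops: Sequence[LoopPair]) -> list[Anchor]:
    """Label anchors left/right by loop role; drop anchors playing both roles.

    Left anchors are the negative class and right anchors the positive class
    of the orientation task.
    """
    roles: dict[tuple, set[str]] = {}
    for lp in positive_loops:
        roles.setdefault((lp.chrom, lp.left.peak_center), set()).add("left")
        roles.setdefault((lp.chrom, lp.right.peak_center), set()).add("right")
    out = []
    for a in true_anchors:
        r = roles.get((a.chrom, a.peak_center), set())
        if len(r) == 1:
            out.append(replace(a, side=next(iter(r))))
    return out


# ---------------------------------------------------------------------------
# assembly, balancing, augmentation, splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSplit:
    """Chromosome-held-out partitioning (no chromosome leaks across parts)."""

    test_chroms: frozenset = frozenset({"chr7", "chr8"})
    val_chroms: frozenset = frozenset({"chr16"})

    def __post_init__(self) -> None:
        if set(self.test_chroms) & set(self.val_chroms):
            raise ValueError("test and validation chromosomes overlap")

    def part(self, chrom: str) -> str:
        if chrom in self.test_chroms:
            return "test"
        if chrom in self.val_chroms:
            return "val"
        return "train"


@dataclass
class SplitSet:
    """Encoded samples of one partition: inputs, labels and a manifest."""

    inputs: tuple[np.ndarray, ...]
    y: np.ndarray
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)


def _allocate_mix(n_total: int, pools: dict[str, int], mix: dict[str, float]
                  ) -> dict[str, int]:
    """Largest-remainder allocation of n_total over pools per the mix,
    renormalizing (with a log) over pools too small to honor their share."""
    mix = {k: v for k, v in mix.items() if pools.get(k, 0) > 0}
    if not mix:
        return {}
    alloc = {k: 0 for k in mix}
    remaining_types = dict(mix)
    remaining_n = n_total
    # iteratively cap exhausted pools and renormalize
    while remaining_n > 0 and remaining_types:
        total_w = sum(remaining_types.values())
        shares = {k: remaining_n * w / total_w for k, w in remaining_types.items()}
        floor = {k: int(s) for k, s in shares.items()}
        rema = sorted(shares, key=lambda k: shares[k] - floor[k], reverse=True)
        leftover = remaining_n - sum(floor.values())
        for k in rema[:leftover]:
            floor[k] += 1
        capped = {k: min(floor[k], pools[k] - alloc[k]) for k in floor}
        if all(capped[k] == floor[k] for k in floor):
            for k in floor:
                alloc[k] += floor[k]
            break
        hit_cap = [k for k in floor if capped[k] < floor[k]]
        for k in floor:
            alloc[k] += capped[k]
        remaining_n -= sum(capped.values())
        for k in hit_cap:
            logger.info("negative pool %s exhausted at %d; renormalizing mix",
                        k, alloc[k])
            remaining_types.pop(k)
        remaining_types = {k: v for k, v in remaining_types.items()
                           if alloc[k] < pools[k]}
    return alloc


def anchors_to_array(anchors: Sequence[Anchor], genome: Mapping[str, str],
                     length: int) -> np.ndarray:
    seqs = [extract_window(genome, a.chrom, a.peak_center, length)
            for a in anchors]
    return encode_batch(seqs)


def loops_to_arrays(loops: Sequence[LoopPair], genome: Mapping[str, str],
                    length: int) -> tuple[np.ndarray, np.ndarray]:
    xl = anchors_to_array([lp.left for lp in loops], genome, length)
    xr = anchors_to_array([lp.right for lp in loops], genome, length)
    return xl, xr


def _anchor_manifest(samples, labels) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [a.chrom for a in samples],
        "peak_center": [a.peak_center for a in samples],
        "klass": [a.klass for a in samples],
        "side": [a.side for a in samples],
        "label": labels,
    })


def _loop_manifest(samples, labels) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [lp.chrom for lp in samples],
        "left_center": [lp.left.peak_center for lp in samples],
        "right_center": [lp.right.peak_center for lp in samples],
        "type": [lp.label for lp in samples],
        "label": labels,
    })


def assemble_and_split(positives: Sequence,
                       negatives_by_type: Mapping[str, Sequence],
                       task: str,
                       split: DatasetSplit,
                       genome: Mapping[str, str],
                       anchor_length: int = 4000, *,
                       augment: bool = True,
                       mix: Mapping[str, float] | None = None,
                       seed: int = 0) -> dict[str, SplitSet]:
    """Build balanced, augmented train/val and imbalanced test sets.

    ``task`` is ``"anchor"`` (samples are Anchors; positives vs non-anchor
    classes), ``"orientation"`` (samples are side-labeled Anchors; right =
    positive, left = negative) or ``"loop"`` (samples are LoopPairs).

    Train and validation have equal positive and negative totals, negatives
    drawn per the configured type mix with a seeded RNG; the test partition
    keeps every negative. With ``augment``, each training sample also
    contributes its reverse complement (loops: both anchors complemented and
    left/right swapped).
    """
    if task not in ("anchor", "orientation", "loop"):
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    mix = dict(mix) if mix is not None else (
        LOOP_NEGATIVE_MIX if task == "loop" else ANCHOR_NEGATIVE_MIX)

    chrom_of = (lambda s: s.chrom)
    by_part_pos: dict[str, list] = {"train": [], "val": [], "test": []}
    for s in positives:
        by_part_pos[split.part(chrom_of(s))].append(s)
    by_part_neg: dict[str, dict[str, list]] = {
        p: {t: [] for t in negatives_by_type} for p in by_part_pos}
    for t, samples in negatives_by_type.items():
        for s in samples:
            by_part_neg[split.part(chrom_of(s))][t].append(s)

    out: dict[str, SplitSet] = {}
    for part in ("train", "val", "test"):
        pos = list(by_part_pos[part])
        negs_by_type = by_part_neg[part]
        if part == "test":
            chosen = [s for t in sorted(negs_by_type) for s in negs_by_type[t]]
        else:
            pools = {t: len(v) for t, v in negs_by_type.items()}
            alloc = _allocate_mix(len(pos), pools, mix)
            chosen = []
            for t in sorted(alloc):
                pool = negs_by_type[t]
                pick = rng.choice(len(pool), size=alloc[t], replace=False)
                chosen.extend(pool[i] for i in sorted(pick))
        samples = pos + chosen
        y = np.array([1] * len(pos) + [0] * len(chosen), dtype=np.int8)

        if task == "loop":
            xl, xr = loops_to_arrays(samples, genome, anchor_length)
            inputs = [xl, xr]
            manifest = _loop_manifest(samples, y)
        else:
            x = anchors_to_array(samples, genome, anchor_length)
            inputs = [x]
            manifest = _anchor_manifest(samples, y)

        if augment and part == "train" and len(samples):
            if task == "loop":
                inputs = [np.concatenate([inputs[0], rc_encoded(inputs[1])]),
                          np.concatenate([inputs[1], rc_encoded(inputs[0])])]
            else:
                inputs = [np.concatenate([inputs[0], rc_encoded(inputs[0])])]
            y = np.concatenate([y, y])
            manifest = pd.concat([manifest.assign(strand="+"),
                                  manifest.assign(strand="-")],
                                 ignore_index=True)
        out[part] = SplitSet(tuple(np.ascontiguousarray(a) for a in inputs),
                             y, manifest)
    return out


def orientation_samples(sided_anchors: Sequence[Anchor]
                        ) -> tuple[list[Anchor], list[Anchor]]:
    """Split side-labeled anchors into (positives=right, negatives=left)."""
    rights = [a for a in sided_anchors if a.side == "right"]
    lefts = [a for a in sided_anchors if a.side == "left"]
    return rights, lefts
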
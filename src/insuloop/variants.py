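"""Variant application and loop-disruption scoring.

Applies sample variants to anchor windows, scores reference vs alternate
loop probabilities, runs single-base saturation deletion scans, and calls
recurrently disrupted loops across a cohort.

Window restoration after indels is center-anchored: edits are applied to a
wide reference slab around the window, the edited coordinate of the original
window center is tracked, and the fixed-length window is re-cut around that
center — net deletions pull reference sequence in from the flanks, net
insertions push it out, and the peak stays at the window center so per-base
coordinates (CAM, scans) remain meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import (GenomicInterval, LoopPair, Variant, encode_batch,
                      extract_window)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisruptionRecord:
    """Reference vs alternate loop probability for one (loop, sample) pair."""

    loop_id: str
    sample_id: str
    p_ref: float
    p_alt: float
    n_variants_applied: int

    @property
    def delta(self) -> float:
        """Loop probability reduction: p_ref - p_alt (positive = weakened)."""
        return self.p_ref - self.p_alt


# ---------------------------------------------------------------------------
# editing machinery
# ---------------------------------------------------------------------------

def _select_nonoverlapping(edits: list[tuple[int, int, str]]
                           ) -> tuple[list[tuple[int, int, str]], int]:
    """Sort by position; on overlap keep the leftmost, reject later ones."""
    edits = sorted(edits)
    kept: list[tuple[int, int, str]] = []
    rejected = 0
    last_end = -1
    for pos, ref_len, alt in edits:
        if pos < last_end:
            rejected += 1
            continue
        kept.append((pos, ref_len, alt))
        last_end = pos + max(ref_len, 1)
    return kept, rejected


def _apply_edits(genome: Mapping[str, str], window: GenomicInterval,
                 edits: Sequence[tuple[int, int, str]]) -> str:
    """Apply (pos, ref_len, alt) edits; return the recentered window sequence.

    Edits are applied right-to-left on a reference slab that extends beyond
    the window by the window length plus the total deleted footprint, so a
    deletion larger than the window still pulls in distal reference.
    """
    seq = genome[window.chrom]
    L = window.length
    center = window.start + L // 2
    margin = L + sum(r for _, r, _ in edits) + 1
    slab_start = center - L // 2 - margin
    slab_end = center + (L - L // 2) + margin
    pad_left = max(0, -slab_start)
    pad_right = max(0, slab_end - len(seq))
    slab = ("N" * pad_left + seq[max(0, slab_start):min(len(seq), slab_end)]
            + "N" * pad_right)

    pieces = list(slab)
    c_rel = center - slab_start
    shift = 0  # net length change left of (or at) the center
    for pos, ref_len, alt in sorted(edits, reverse=True):
        rel = pos - slab_start
        pieces[rel:rel + ref_len] = list(alt)
        if pos + ref_len <= center:
            shift += len(alt) - ref_len
        elif pos <= center < pos + ref_len:
            # center inside the edited footprint: map it onto the replacement
            off = min(center - pos, max(len(alt) - 1, 0))
            shift += (pos + off) - center
    c_edit = c_rel + shift
    edited = "".join(pieces)
    start = c_edit - L // 2
    end = start + L
    out = edited[max(0, start):max(0, end)]
    out = "N" * max(0, -start) + out + "N" * max(0, end - len(edited))
    return out


def apply_variants_to_window(genome: Mapping[str, str],
                             window: GenomicInterval,
                             variants: Sequence[Variant]
                             ) -> tuple[str, int]:
    """Apply a sample's variants to one window.

    Only variants whose reference footprint overlaps the window are applied;
    ref-mismatching variants and later members of overlapping pairs are
    rejected with a log. Returns ``(sequence, n_applied)`` with the sequence
    exactly ``window.length`` bases long.
    """
    seq = genome[window.chrom]
    edits: list[tuple[int, int, str]] = []
    for v in variants:
        if v.chrom != window.chrom:
            continue
        if v.end <= window.start or v.pos >= window.end:
            continue
        if seq[v.pos:v.end].upper() != v.ref:
            logger.info("variant %s:%d %s>%s rejected: reference mismatch",
                        v.chrom, v.pos1, v.ref, v.alt)
            continue
        edits.append((v.pos, len(v.ref), v.alt))
    kept, rejected = _select_nonoverlapping(edits)
    if rejected:
        logger.info("%d overlapping variants rejected in %s:%d-%d",
                    rejected, window.chrom, window.start, window.end)
    if not kept:
        return (extract_window(genome, window.chrom,
                               window.start + window.length // 2,
                               window.length), 0)
    return _apply_edits(genome, window, kept), len(kept)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _loop_windows(loop: LoopPair) -> tuple[GenomicInterval, GenomicInterval]:
    return loop.left.interval, loop.right.interval


def score_loop(model, loop: LoopPair, genome: Mapping[str, str],
               variants_by_sample: Mapping[str, Sequence[Variant]],
               loop_id: str | None = None) -> list[DisruptionRecord]:
    """Reference vs per-sample alternate loop probabilities for one loop.

    The reference probability is computed once; samples with no variant
    overlapping either anchor window reuse it bit-for-bit (delta exactly 0).
    """
    recs = score_loops(model, {loop_id or "loop": loop}, genome,
                       variants_by_sample)
    return recs


def score_loops(model, loops: Mapping[str, LoopPair],
                genome: Mapping[str, str],
                variants_by_sample: Mapping[str, Sequence[Variant]]
                ) -> list[DisruptionRecord]:
    """Score every (loop, sample) pair; exactly one record per pair."""
    loop_ids = list(loops)
    L = None
    ref_pairs = []
    for lid in loop_ids:
        wl, wr = _loop_windows(loops[lid])
        L = wl.length
        ref_pairs.append((
            extract_window(genome, wl.chrom, wl.start + L // 2, L),
            extract_window(genome, wr.chrom, wr.start + L // 2, L)))
    xl = encode_batch([p[0] for p in ref_pairs])
    xr = encode_batch([p[1] for p in ref_pairs])
    p_ref = model.predict((xl, xr))

    records: list[DisruptionRecord] = []
    edited: list[tuple[int, str, int, str, str]] = []  # loop idx, sample, n, seqs
    for sample, variants in variants_by_sample.items():
        for i, lid in enumerate(loop_ids):
            wl, wr = _loop_windows(loops[lid])
            sl, nl = apply_variants_to_window(genome, wl, variants)
            sr, nr = apply_variants_to_window(genome, wr, variants)
            n = nl + nr
            if n == 0:
                records.append(DisruptionRecord(lid, sample,
                                                float(p_ref[i]),
                                                float(p_ref[i]), 0))
            else:
                edited.append((i, sample, n, sl, sr))
    if edited:
        xl = encode_batch([e[3] for e in edited])
        xr = encode_batch([e[4] for e in edited])
        p_alt = model.predict((xl, xr))
        for (i, sample, n, _, _), pa in zip(edited, p_alt):
            records.append(DisruptionRecord(loop_ids[i], sample,
                                            float(p_ref[i]), float(pa), n))
    return records


def saturation_deletion_scan(model, loop: LoopPair,
                             region: GenomicInterval,
                             genome: Mapping[str, str],
                             batch_size: int = 128) -> pd.DataFrame:
    """Delta in loop probability for deleting each single base of ``region``.

    Returns one row per position (columns: chrom, pos, delta). Positions
    falling outside both anchor windows yield an empty result with a warning.
    """
    wl, wr = _loop_windows(loop)
    L = wl.length
    positions = [p for p in range(region.start, region.end)
                 if region.chrom == wl.chrom]
    in_left = [p for p in positions if wl.start <= p < wl.end]
    in_right = [p for p in positions if wr.start <= p < wr.end]
    if not in_left and not in_right:
        logger.warning("scan region %s:%d-%d outside both anchor windows",
                       region.chrom, region.start, region.end)
        return pd.DataFrame(columns=["chrom", "pos", "delta"])

    sl_ref = extract_window(genome, wl.chrom, wl.start + L // 2, L)
    sr_ref = extract_window(genome, wr.chrom, wr.start + L // 2, L)
    p_ref = float(model.predict((encode_batch([sl_ref]),
                                 encode_batch([sr_ref])))[0])

    rows = []
    pairs: list[tuple[str, str]] = []
    for pos in positions:
        if wl.start <= pos < wl.end:
            sl = _apply_edits(genome, wl, [(pos, 1, "")])
            sr = sr_ref
        elif wr.start <= pos < wr.end:
            sl = sl_ref
            sr = _apply_edits(genome, wr, [(pos, 1, "")])
        else:
            continue
        pairs.append((sl, sr))
        rows.append(pos)
    deltas = np.empty(len(pairs))
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        p = model.predict((encode_batch([c[0] for c in chunk]),
                           encode_batch([c[1] for c in chunk])))
        deltas[i:i + len(chunk)] = p_ref - p
    return pd.DataFrame({"chrom": region.chrom, "pos": rows, "delta": deltas})


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def disruption_threshold(records: Sequence[DisruptionRecord],
                         percentile: float = 90.0) -> float:
    """Cutoff for calling a loop disrupted: the given percentile (linear
    interpolation) of positive loop-probability reductions pooled across all
    samples and loops."""
    reductions = np.array([r.delta for r in records if r.delta > 0])
    if reductions.size == 0:
        raise ValueError("no positive loop-probability reductions")
    return float(np.percentile(reductions, percentile))


@dataclass
class DisruptionSummary:
    per_sample_counts: pd.Series
    recurrent_loops: list[str]
    genes_in_recurrent_loops: list[str]
    gene_sample_partition: dict[str, tuple[list[str], list[str]]]
    min_count: int


def summarize_disruption(records: Sequence[DisruptionRecord],
                         threshold: float,
                         loops: Mapping[str, LoopPair] | None = None,
                         genes: Mapping[str, GenomicInterval] | None = None,
                         recurrence_fraction: float = 0.10,
                         rounding: str = "floor") -> DisruptionSummary:
    """Cohort-level disruption summary.

    A loop is disrupted in a sample iff its reduction >= threshold. A loop is
    recurrent when disrupted in at least ``recurrence_fraction`` of samples
    (minimum count = floor(fraction x n_samples) by default, ceil via
    ``rounding``). A gene lies in a loop iff its interval is fully contained
    in [left anchor start, right anchor end]; for each such gene the cohort
    is partitioned into samples with vs without a disruption of a containing
    recurrent loop.
    """
    samples = sorted({r.sample_id for r in records})
    n_samples = len(samples)
    rounder = math.floor if rounding == "floor" else math.ceil
    min_count = max(1, rounder(recurrence_fraction * n_samples))

    disrupted: dict[str, set[str]] = {}
    per_sample = {s: 0 for s in samples}
    for r in records:
        if r.delta >= threshold:
            disrupted.setdefault(r.loop_id, set()).add(r.sample_id)
            per_sample[r.sample_id] += 1
    recurrent = sorted(lid for lid, ss in disrupted.items()
                       if len(ss) >= min_count)

    genes_in: list[str] = []
    partition: dict[str, tuple[list[str], list[str]]] = {}
    if loops and genes:
        for gname, gi in genes.items():
            containing = []
            for lid in recurrent:
                lp = loops[lid]
                span = GenomicInterval(lp.chrom, lp.left.interval.start,
                                       lp.right.interval.end)
                if span.contains(gi):
                    containing.append(lid)
            if containing:
                genes_in.append(gname)
                hit = sorted({s for lid in containing for s in disrupted[lid]})
                partition[gname] = (hit, [s for s in samples if s not in hit])
    return DisruptionSummary(
        per_sample_counts=pd.Series(per_sample).sort_index(),
        recurrent_loops=recurrent,
        genes_in_recurrent_loops=sorted(genes_in),
        gene_sample_partition=partition,
        min_count=min_count)
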
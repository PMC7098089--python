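"""Desk-scale recovery studies on the synthetic loop grammar.

These drive the whole pipeline end to end: simulate a genome with planted
grammar, build balanced augmented datasets with chromosome-held-out splits,
train the five-model stack at reduced width (scale 1/8, 1000-base anchors),
and measure how well each model recovers the planted structure — anchor
versus bound-decoy discrimination, left/right orientation, loop pairing
against convergent non-loops, single-base deletion scans and CAM motif
enrichment.

Problem sizes (1000 loops over ten 1.4-Mb chromosomes, two test and one
validation chromosome) are chosen so the full study trains in minutes on one
CPU while leaving each task statistically well-posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataset import (DatasetSplit, assemble_and_split, build_nonloops,
                      compute_span_cap, orientation_samples)
from .models import (ModelConfig, average_precision, build_model, train_model)
from .seqcore import (GenomicInterval, NONANCHOR_TYPE1, NONANCHOR_TYPE2,
                      NONANCHOR_TYPE3, TRUE_ANCHOR, encode_batch,
                      extract_window)
from .synthetic import (FixtureBundle, SyntheticGrammar,
                        simulate_genome_and_loops, simulate_variants,
                        truth_to_anchors)
from .variants import (saturation_deletion_scan, score_loops)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Problem sizes and training schedule of the desk-scale recovery study."""

    n_chrom: int = 10
    chrom_length: int = 1_400_000
    n_loops: int = 1000
    anchor_length: int = 1000
    rnn_window: int = 200
    scale: float = 0.125
    test_chroms: tuple = ("chr9", "chr10")
    val_chroms: tuple = ("chr8",)
    cnn_stage1_epochs: int = 24  # compact-subset stage (crosses the plateau)
    curriculum_size: int = 1200
    cnn_epochs: int = 4          # full-set refinement stage
    rnn_epochs: int = 6
    head_epochs: int = 60
    orientation_epochs: int = 10
    loop_epochs: int = 150
    loop_learning_rate: float = 1e-3  # head-only fit; lower rate is stabler
    loop_patience: int = 30
    cam_anchors: int = 150
    cam_quantile: float = 0.99
    patience: int = 8
    learning_rate: float = 3e-3  # grammar recovery is update-limited
    max_nonloops_per_type: int = 1500
    n_samples: int = 20
    variants_per_sample: int = 6
    augment: bool = False  # strand augmentation off: eval uses one strand

    def model_config(self, **overrides) -> ModelConfig:
        base = dict(anchor_length=self.anchor_length,
                    rnn_window=self.rnn_window, scale=self.scale,
                    patience=self.patience, learning_rate=self.learning_rate)
        base.update(overrides)
        return ModelConfig(**base)

    def split(self) -> DatasetSplit:
        return DatasetSplit(frozenset(self.test_chroms),
                            frozenset(self.val_chroms))


def generate_bundle(study: StudyConfig, seed: int) -> FixtureBundle:
    grammar = SyntheticGrammar(anchor_length=study.anchor_length, seed=seed)
    bundle = simulate_genome_and_loops(grammar, n_chrom=study.n_chrom,
                                       chrom_length=study.chrom_length,
                                       n_loops=study.n_loops)
    return simulate_variants(grammar, bundle, n_samples=study.n_samples,
                             variants_per_sample=study.variants_per_sample,
                             seed=seed + 7)


def build_datasets(bundle: FixtureBundle, study: StudyConfig, seed: int
                   ) -> dict:
    """Anchor, orientation and loop datasets with chromosome-held-out splits."""
    split = study.split()
    truth = bundle.truth
    L = study.anchor_length
    genome = bundle.genome

    positives = truth_to_anchors(truth, TRUE_ANCHOR)
    negs = {k: truth_to_anchors(truth, k)
            for k in (NONANCHOR_TYPE1, NONANCHOR_TYPE2, NONANCHOR_TYPE3)}
    anchor_sets = assemble_and_split(positives, negs, "anchor", split,
                                     genome, L, augment=study.augment,
                                     seed=seed)

    rights, lefts = orientation_samples(positives)
    orient_sets = assemble_and_split(rights, {"left": lefts}, "orientation",
                                     split, genome, L, mix={"left": 1.0},
                                     augment=study.augment, seed=seed + 1)

    span_cap = compute_span_cap(bundle.loops)
    nonanchors = negs[NONANCHOR_TYPE1] + negs[NONANCHOR_TYPE2] + negs[NONANCHOR_TYPE3]
    nonloops = {}
    for i, t in enumerate(("nonloop_type1", "nonloop_type2", "nonloop_type3",
                           "nonloop_type4", "nonloop_type5")):
        nonloops[t] = build_nonloops(
            t, bundle.anchors, nonanchors, bundle.motif_hits, span_cap,
            positive_loops=bundle.loops,
            max_pairs=study.max_nonloops_per_type, seed=seed + 2 + i)
    loop_sets = assemble_and_split(bundle.loops, nonloops, "loop", split,
                                   genome, L, augment=study.augment,
                                   seed=seed + 10)
    return {"split": split, "anchor": anchor_sets, "orientation": orient_sets,
            "loop": loop_sets, "nonloops": nonloops, "span_cap": span_cap}


def _balanced_subset(train_set, n_total: int, seed: int):
    """Class-balanced random subset of a training set (inputs, labels)."""
    inputs, y = train_set
    if y.shape[0] <= n_total:
        return train_set
    rng = np.random.default_rng(seed)
    picked = []
    for label in (0, 1):
        idx = np.nonzero(y == label)[0]
        take = min(len(idx), n_total // 2)
        picked.append(rng.choice(idx, size=take, replace=False))
    idx = np.sort(np.concatenate(picked))
    return (tuple(a[idx] for a in inputs), y[idx])


def train_stack(datasets: Mapping, study: StudyConfig, seed: int) -> dict:
    """Train CNN, RNN, combined anchor, orientation and loop models in order.

    The CNN trains in two stages: first on a balanced random subset of the
    training set, then on the full set. Global max pooling gives motif tasks
    a long low-gradient plateau before a filter locks onto the discriminative
    k-mer; the plateau breaks through sample repetition, so a compact first
    stage crosses it in a fraction of the full-set epoch cost, and the short
    second stage refines the working solution on all data.
    """

    def data(task):
        s = datasets[task]
        return ((s["train"].inputs, s["train"].y),
                (s["val"].inputs, s["val"].y))

    a_train, a_val = data("anchor")
    cnn = build_model("cnn_anchor", study.model_config(max_epochs=study.cnn_epochs),
                      seed)
    sub = _balanced_subset(a_train, study.curriculum_size, seed + 99)
    train_model(cnn, sub, a_val,
                config=study.model_config(max_epochs=study.cnn_stage1_epochs,
                                          patience=study.cnn_stage1_epochs),
                seed=seed + 100)
    train_model(cnn, a_train, a_val,
                config=study.model_config(max_epochs=study.cnn_epochs),
                seed=seed + 100)
    rnn = build_model("rnn_anchor", study.model_config(max_epochs=study.rnn_epochs),
                      seed + 1)
    train_model(rnn, a_train, a_val, seed=seed + 101)

    anchor = build_model("anchor", study.model_config(max_epochs=study.head_epochs),
                         seed + 2, components={"cnn": cnn, "rnn": rnn})
    train_model(anchor, a_train, a_val, seed=seed + 102)

    o_train, o_val = data("orientation")
    orientation = build_model(
        "orientation", study.model_config(max_epochs=study.orientation_epochs),
        seed + 3, components={"anchor": anchor})
    train_model(orientation, o_train, o_val, seed=seed + 103)

    l_train, l_val = data("loop")
    loop_cfg = study.model_config(max_epochs=study.loop_epochs,
                                  learning_rate=study.loop_learning_rate,
                                  patience=study.loop_patience)
    loop = build_model("loop", loop_cfg, seed + 4,
                       components={"anchor": anchor,
                                   "orientation": orientation})
    train_model(loop, l_train, l_val, seed=seed + 104)
    return {"cnn": cnn, "rnn": rnn, "anchor": anchor,
            "orientation": orientation, "loop": loop}


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _part_rows(truth, split: DatasetSplit, part: str):
    return truth[truth.chrom.map(split.part) == part]


def anchor_eval_arrays(bundle: FixtureBundle, study: StudyConfig
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out true anchors vs bound (chip-only) decoys, prevalence ~0.5."""
    split = study.split()
    truth = _part_rows(bundle.truth, split, "test")
    rows = truth[truth.kind.isin([TRUE_ANCHOR, NONANCHOR_TYPE1])]
    seqs = [extract_window(bundle.genome, r.chrom, int(r.center),
                           study.anchor_length) for _, r in rows.iterrows()]
    y = (rows.kind == TRUE_ANCHOR).to_numpy().astype(np.int8)
    return encode_batch(seqs), y


def orientation_eval_arrays(bundle: FixtureBundle, study: StudyConfig
                            ) -> tuple[np.ndarray, np.ndarray]:
    split = study.split()
    truth = _part_rows(bundle.truth, split, "test")
    rows = truth[truth.kind == TRUE_ANCHOR]
    seqs = [extract_window(bundle.genome, r.chrom, int(r.center),
                           study.anchor_length) for _, r in rows.iterrows()]
    y = (rows.side == "right").to_numpy().astype(np.int8)
    return encode_batch(seqs), y


def loop_eval_arrays(bundle: FixtureBundle, datasets: Mapping,
                     study: StudyConfig, seed: int
                     ) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray]:
    """Balanced held-out eval: true loops vs convergent non-loops (type 1)."""
    split = study.split()
    pos = [lp for lp in bundle.loops if split.part(lp.chrom) == "test"]
    neg = [lp for lp in datasets["nonloops"]["nonloop_type1"]
           if split.part(lp.chrom) == "test"]
    n = min(len(pos), len(neg))
    rng = np.random.default_rng(seed)
    pos = [pos[i] for i in sorted(rng.choice(len(pos), size=n, replace=False))]
    neg = [neg[i] for i in sorted(rng.choice(len(neg), size=n, replace=False))]
    pairs = pos + neg
    xl = encode_batch([extract_window(bundle.genome, lp.chrom,
                                      lp.left.peak_center, study.anchor_length)
                       for lp in pairs])
    xr = encode_batch([extract_window(bundle.genome, lp.chrom,
                                      lp.right.peak_center, study.anchor_length)
                       for lp in pairs])
    y = np.array([1] * n + [0] * n, dtype=np.int8)
    return (xl, xr), y


def evaluate_stack(models: Mapping, bundle: FixtureBundle, datasets: Mapping,
                   study: StudyConfig, seed: int) -> dict[str, float]:
    x, y = anchor_eval_arrays(bundle, study)
    metrics = {
        "ap_cnn_type1": average_precision(y, models["cnn"].predict(x)),
        "ap_rnn_type1": average_precision(y, models["rnn"].predict(x)),
        "ap_anchor_type1": average_precision(y, models["anchor"].predict(x)),
        "anchor_eval_prevalence": float(y.mean()),
        "anchor_eval_n": int(y.size),
    }
    xo, yo = orientation_eval_arrays(bundle, study)
    metrics["ap_orientation"] = average_precision(
        yo, models["orientation"].predict(xo))
    metrics["orientation_eval_n"] = int(yo.size)

    (xl, xr), yl = loop_eval_arrays(bundle, datasets, study, seed + 20)
    metrics["ap_loop_type1"] = average_precision(
        yl, models["loop"].predict((xl, xr)))
    metrics["loop_eval_prevalence"] = float(yl.mean())
    metrics["loop_eval_n"] = int(yl.size)
    return metrics


def run_recovery_study(seed: int, study: StudyConfig | None = None) -> dict:
    """Simulate, build, train and evaluate; returns bundle/datasets/models/metrics."""
    study = study or StudyConfig()
    bundle = generate_bundle(study, seed)
    datasets = build_datasets(bundle, study, seed + 1)
    models = train_stack(datasets, study, seed + 2)
    metrics = evaluate_stack(models, bundle, datasets, study, seed + 3)
    return {"study": study, "bundle": bundle, "datasets": datasets,
            "models": models, "metrics": metrics}


# ---------------------------------------------------------------------------
# perturbation study (saturation scan + neutral-variant floor)
# ---------------------------------------------------------------------------

def run_perturbation_study(loop_model, bundle: FixtureBundle,
                           study: StudyConfig, seed: int,
                           region_length: int = 400,
                           n_loops: int = 5) -> dict:
    """Miniature of the known-deletion validation on held-out loops.

    For each of the first ``n_loops`` held-out loops: (1) a saturation scan
    of single-base deletions across a 400-base region containing the left
    anchor's planted core motif, counting how many of the top-10 deltas fall
    within the motif +/- 5 bases; (2) ablation of the anchor's full planted
    motif module (core plus cofactor — the analog of deleting a whole
    binding element); (3) a matched neutral null of single substitutions in
    the same anchor window away from every planted element. Medians across
    loops are reported (per-loop responses vary with where each loop sits on
    the probability scale); the null pools all loops.
    """
    from .variants import _apply_edits  # shared editing machinery
    split = study.split()
    truth = bundle.truth
    test_loops = [(i, lp) for i, lp in enumerate(bundle.loops)
                  if split.part(lp.chrom) == "test"][:n_loops]
    rng = np.random.default_rng(seed)

    top10_counts: list[int] = []
    ablation_deltas: list[float] = []
    neutral_deltas: list[float] = []
    first_scan = None
    first_region = None
    for loop_id, loop in test_loops:
        row = truth[(truth.loop_id == loop_id) & (truth.side == "left")].iloc[0]
        core_mid = (int(row.core_start) + int(row.core_end)) // 2
        region = GenomicInterval(loop.chrom, core_mid - region_length // 2,
                                 core_mid - region_length // 2 + region_length)
        scan = saturation_deletion_scan(loop_model, loop, region,
                                        bundle.genome)
        top10 = scan.nlargest(10, "delta")
        lo, hi = int(row.core_start) - 5, int(row.core_end) + 5
        top10_counts.append(int(((top10.pos >= lo) & (top10.pos < hi)).sum()))
        if first_scan is None:
            first_scan, first_region = scan, region

        wl, wr = loop.left.interval, loop.right.interval
        L = wl.length
        sl_ref = extract_window(bundle.genome, wl.chrom, wl.start + L // 2, L)
        sr_ref = extract_window(bundle.genome, wr.chrom, wr.start + L // 2, L)
        p_ref = float(loop_model.predict((encode_batch([sl_ref]),
                                          encode_batch([sr_ref])))[0])
        edits = [(int(row.core_start),
                  int(row.core_end) - int(row.core_start), ""),
                 (int(row.cofactor_start),
                  int(row.cofactor_end) - int(row.cofactor_start), "")]
        sl_ablate = _apply_edits(bundle.genome, wl, sorted(edits))
        p_ablate = float(loop_model.predict((encode_batch([sl_ablate]),
                                             encode_batch([sr_ref])))[0])
        ablation_deltas.append(p_ref - p_ablate)

        spans = [(int(row[k + "_start"]), int(row[k + "_end"]))
                 for k in ("core", "extra", "cofactor", "sig")
                 if row[k + "_start"] >= 0]
        chrom_seq = bundle.genome[wl.chrom]
        alt_windows = []
        while len(alt_windows) < 60:
            pos = int(rng.integers(wl.start + 10, wl.end - 10))
            if all(not (s - 30 <= pos < e + 30) for s, e in spans):
                ref = chrom_seq[pos]
                alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
                alt_windows.append(_apply_edits(bundle.genome, wl,
                                                [(pos, 1, alt)]))
        p_neutral = loop_model.predict(
            (encode_batch(alt_windows),
             encode_batch([sr_ref] * len(alt_windows))))
        neutral_deltas.extend((p_ref - p_neutral).tolist())

    return {"scan": first_scan,
            "top10_in_motif": float(np.median(top10_counts)),
            "top10_counts": top10_counts,
            "ablation_delta": float(np.median(ablation_deltas)),
            "ablation_deltas": ablation_deltas,
            "neutral_delta_p99": float(np.percentile(neutral_deltas, 99)),
            "n_neutral": len(neutral_deltas),
            "region": first_region,
            "loop_ids": [i for i, _ in test_loops]}


def run_cam_study(model, bundle: FixtureBundle, study: StudyConfig,
                  n_anchors: int | None = None, seed: int = 0) -> dict:
    """CAM peak enrichment in planted motif spans on held-out anchors."""
    from .interpretation import cam_profiles, motif_enrichment_test
    if n_anchors is None:
        n_anchors = study.cam_anchors
    split = study.split()
    truth = _part_rows(bundle.truth, split, "test")
    rows = truth[truth.kind == TRUE_ANCHOR].head(n_anchors)
    seqs = [extract_window(bundle.genome, r.chrom, int(r.center),
                           study.anchor_length) for _, r in rows.iterrows()]
    x = encode_batch(seqs)
    profiles = cam_profiles(model, x,
                            min_height_quantile=study.cam_quantile)
    spans = []
    for _, r in rows.iterrows():
        origin = int(r.center) - study.anchor_length // 2
        anchor_spans = []
        for s, e in ((r.core_start, r.core_end), (r.extra_start, r.extra_end),
                     (r.cofactor_start, r.cofactor_end),
                     (r.sig_start, r.sig_end)):
            if s >= 0:
                anchor_spans.append((int(s) - origin, int(e) - origin))
        spans.append(anchor_spans)
    frac, expected, pvalue = motif_enrichment_test(profiles, spans)
    return {"profiles": profiles, "observed_fraction": frac,
            "expected_fraction": expected, "pvalue": pvalue}
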
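"""Synthetic genomes with a planted, learnable insulator-loop grammar.

The generator emits a complete labeled universe — genome, loops, anchors,
binding peaks, motif occurrences, variants — in the same standard formats the
real pipeline reads, so every downstream stage is trainable and testable at
desk scale.

The grammar
-----------
Every candidate site is a fixed-length window on a random-background genome:

* **true anchor** — contains an oriented core motif (the CTCF-motif analog),
  a cofactor motif (the cohesin-co-binding analog, present only at true
  anchors), and a side signature marking whether the anchor is the left or
  right end of its loop. Core orientation follows loop geometry: convergent
  loops (probability ``convergent_fraction``) put the core on + at the left
  anchor and on - at the right; the remainder are tandem (both anchors share
  a random strand).
* **chip-only decoy** — core motif plus a binding peak but no cofactor
  (a bound site that anchors no loop); carries a random side signature so
  anchor-vs-decoy discrimination genuinely requires the cofactor.
* **motif-only decoy** — core motif without any peak.
* **background window** — no core motif; a fraction ``cofactor_decoy_rate``
  contains a stray cofactor, so neither motif alone identifies an anchor.

Planted instances are degenerate: each base mutates with probability
``mutation_rate``, and motif-table p-values are a deterministic function of
edit distance (crossing the FIMO threshold for badly degraded copies). With
probability ``motif_strand_noise`` a true anchor additionally carries a
second, better-scoring core motif on a uniformly random strand, so the
best-hit orientation class is only weakly informative about loop side —
mirroring real anchors, where about half contain multiple motifs and
orientation alone cannot pair loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqcore import (Anchor, GenomicInterval, LoopPair, MotifHit, Peak,
                      Variant, NONANCHOR_TYPE1, NONANCHOR_TYPE2,
                      NONANCHOR_TYPE3, TRUE_ANCHOR, reverse_complement,
                      write_fasta, write_loops, write_motif_hits, write_peaks,
                      write_variants)

logger = logging.getLogger(__name__)

BASES4 = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticGrammar:
    """Parameters of the planted loop grammar (defaults are the desk-scale
    study conditions: 1000-base anchors on multi-megabase toy chromosomes)."""

    core_motif: str = "CCACCAGGTGGCGCTAGTC"        # 19 b, orientation-specific
    cofactor_motif: str = "GTACGCAT"                # 8 b, true anchors only
    left_signature: str = "ATCGAACTGG"              # 10 b
    right_signature: str = "TGGCATTCAA"             # 10 b
    gc_background: float = 0.41
    loop_span_range: tuple = (4000, 20000)          # log-uniform, bases
    convergent_fraction: float = 0.85
    chip_decoy_rate: float = 0.40                   # decoy slot -> chip-only
    motif_decoy_rate: float = 0.25                  # decoy slot -> motif-only
    cofactor_decoy_rate: float = 0.30               # background w/ stray cofactor
    motif_strand_noise: float = 0.90                # extra core-motif rate
    mutation_rate: float = 0.05
    anchor_length: int = 1000
    seed: int = 0

    # element offsets relative to the window center (starts)
    COFACTOR_OFFSET = -64
    SIGNATURE_OFFSET = -40
    CORE_OFFSET = 241          # functional core sits right of center
    EXTRA_CORE_OFFSET = -330   # noise core sits left of center

    def __post_init__(self) -> None:
        if self.core_motif == reverse_complement(self.core_motif):
            raise ValueError("core motif must differ from its reverse complement")
        if not 0.0 <= self.convergent_fraction <= 1.0:
            raise ValueError("convergent_fraction must lie in [0, 1]")


@dataclass
class FixtureBundle:
    """Everything the generator knows about one synthetic universe."""

    grammar: SyntheticGrammar
    genome: dict[str, str]
    loops: list[LoopPair]
    anchors: list[Anchor]          # true anchors, standardized, side-labeled
    peaks: list[Peak]
    motif_hits: list[MotifHit]     # rows below the FIMO threshold
    all_motif_rows: list[MotifHit]  # including super-threshold rows
    truth: pd.DataFrame            # one row per planted site
    genes: list[GenomicInterval] = field(default_factory=list)
    variants_by_sample: dict[str, list[Variant]] = field(default_factory=dict)
    variant_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _mutate(motif: str, rng: np.random.Generator, rate: float
            ) -> tuple[str, int]:
    """Per-base mutation at ``rate``; returns (sequence, edit count)."""
    seq = list(motif)
    edits = 0
    for i, b in enumerate(seq):
        if rng.random() < rate:
            choices = [c for c in "ACGT" if c != b]
            seq[i] = choices[rng.integers(3)]
            edits += 1
    return "".join(seq), edits


def _motif_pvalue(edits: int, scale: float = 1.0) -> float:
    """Deterministic p-value from edit distance: exact matches score 1e-6 and
    each edit costs a factor of 8, crossing the 5e-5 FIMO cutoff at 3 edits."""
    return min(0.99, scale * 1e-6 * 8.0 ** edits)


class _SiteWriter:
    """Paste planted elements into a per-chromosome background array."""

    def __init__(self, chrom: str, seq: np.ndarray):
        self.chrom = chrom
        self.seq = seq

    def paste(self, pos: int, s: str) -> None:
        self.seq[pos:pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES4[rng.choice(4, size=n, p=p)]


def simulate_genome_and_loops(grammar: SyntheticGrammar,
                              n_chrom: int = 4,
                              chrom_length: int = 400_000,
                              n_loops: int = 100) -> FixtureBundle:
    """Generate a genome with planted loops, decoys, peaks and motif rows.

    Loops are laid out left to right along each chromosome (spans drawn
    log-uniformly from the grammar range); decoy windows fill the gaps
    between paired anchors. Raises a generation error when the requested
    loops do not fit the chromosome length.
    """
    rng = np.random.default_rng(grammar.seed)
    g = grammar
    W = g.anchor_length
    half = W // 2
    per_chrom = int(np.ceil(n_loops / n_chrom))
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]

    genome: dict[str, str] = {}
    loops: list[LoopPair] = []
    anchors: list[Anchor] = []
    peaks: list[Peak] = []
    rows: list[MotifHit] = []
    truth_rows: list[dict] = []
    genes: list[GenomicInterval] = []
    site_counter = 0
    loops_placed = 0

    def plant_core(w: _SiteWriter, center: int, strand: str, offset: int,
                   pscale: float = 1.0) -> tuple[int, int, int]:
        motif = g.core_motif if strand == "+" else reverse_complement(g.core_motif)
        seq, edits = _mutate(motif, rng, g.mutation_rate)
        start = center + offset
        w.paste(start, seq)
        p = _motif_pvalue(edits, pscale)
        rows.append(MotifHit(w.chrom, start, start + len(motif), strand, pvalue=p))
        return start, start + len(motif), edits

    def plant_site(w: _SiteWriter, center: int, kind: str, side: str,
                   loop_id: int, strand: str) -> dict:
        nonlocal site_counter
        rec = {"site_id": site_counter, "chrom": w.chrom,
               "start": center - half, "end": center - half + W,
               "center": center, "kind": kind, "side": side,
               "loop_id": loop_id, "core_strand": strand,
               "core_start": -1, "core_end": -1,
               "extra_start": -1, "extra_end": -1, "extra_strand": ".",
               "cofactor_start": -1, "cofactor_end": -1,
               "sig_start": -1, "sig_end": -1}
        site_counter += 1
        if kind in (TRUE_ANCHOR, NONANCHOR_TYPE1, NONANCHOR_TYPE2):
            cs, ce, _ = plant_core(w, center, strand, g.CORE_OFFSET)
            rec["core_start"], rec["core_end"] = cs, ce
            if rng.random() < g.motif_strand_noise:
                xstrand = "+" if rng.random() < 0.5 else "-"
                jitter = int(rng.integers(-20, 21))
                xs, xe, _ = plant_core(w, center, xstrand,
                                       g.EXTRA_CORE_OFFSET + jitter,
                                       pscale=0.01)
                rec["extra_start"], rec["extra_end"] = xs, xe
                rec["extra_strand"] = xstrand
        if kind == TRUE_ANCHOR:
            cof, _ = _mutate(g.cofactor_motif, rng, g.mutation_rate)
            cstart = center + g.COFACTOR_OFFSET + int(rng.integers(-8, 9))
            w.paste(cstart, cof)
            rec["cofactor_start"], rec["cofactor_end"] = cstart, cstart + len(cof)
        if kind in (TRUE_ANCHOR, NONANCHOR_TYPE1, NONANCHOR_TYPE2):
            sig_side = side if kind == TRUE_ANCHOR else \
                ("left" if rng.random() < 0.5 else "right")
            sig = g.left_signature if sig_side == "left" else g.right_signature
            sig, _ = _mutate(sig, rng, g.mutation_rate)
            sstart = center + g.SIGNATURE_OFFSET + int(rng.integers(-8, 9))
            w.paste(sstart, sig)
            rec["sig_start"], rec["sig_end"] = sstart, sstart + len(sig)
        if kind == NONANCHOR_TYPE3 and rng.random() < g.cofactor_decoy_rate:
            # stray cofactor plus a stray signature, but no core motif: with
            # these decoys in the background class, no pair of the three
            # planted elements identifies an anchor without the core, so a
            # trained model must weight the core motif itself
            cof, _ = _mutate(g.cofactor_motif, rng, g.mutation_rate)
            cstart = center + g.COFACTOR_OFFSET + int(rng.integers(-8, 9))
            w.paste(cstart, cof)
            rec["cofactor_start"], rec["cofactor_end"] = cstart, cstart + len(cof)
            sig = g.left_signature if rng.random() < 0.5 else g.right_signature
            sig, _ = _mutate(sig, rng, g.mutation_rate)
            sstart = center + g.SIGNATURE_OFFSET + int(rng.integers(-8, 9))
            w.paste(sstart, sig)
            rec["sig_start"], rec["sig_end"] = sstart, sstart + len(sig)
        if kind in (TRUE_ANCHOR, NONANCHOR_TYPE1):
            # wide enough to cover the core motif planted right of center
            peaks.append(Peak(w.chrom, center - 300, center + 300,
                              summit=center))
        truth_rows.append(rec)
        return rec

    def decoy_kind() -> str:
        r = rng.random()
        if r < g.chip_decoy_rate:
            return NONANCHOR_TYPE1
        if r < g.chip_decoy_rate + g.motif_decoy_rate:
            return NONANCHOR_TYPE2
        return NONANCHOR_TYPE3

    lo, hi = g.loop_span_range
    for chrom in chroms:
        seq = _background(rng, chrom_length, g.gc_background)
        w = _SiteWriter(chrom, seq)
        cursor = W  # leading margin
        for _ in range(per_chrom):
            if loops_placed >= n_loops:
                break
            span = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            left_center = cursor + half
            right_center = left_center + span
            if right_center + half + W > chrom_length:
                raise RuntimeError(
                    f"site placement failed on {chrom}: increase chrom_length "
                    f"or reduce n_loops")
            if rng.random() < g.convergent_fraction:
                s_left, s_right = "+", "-"
            else:
                s = "+" if rng.random() < 0.5 else "-"
                s_left = s_right = s
            lrec = plant_site(w, left_center, TRUE_ANCHOR, "left",
                              loops_placed, s_left)
            rrec = plant_site(w, right_center, TRUE_ANCHOR, "right",
                              loops_placed, s_right)
            la = Anchor(GenomicInterval(chrom, left_center - half,
                                        left_center - half + W),
                        left_center, side="left")
            ra = Anchor(GenomicInterval(chrom, right_center - half,
                                        right_center - half + W),
                        right_center, side="right")
            loops.append(LoopPair(la, ra))
            anchors.extend([la, ra])
            # a gene fully inside every fifth loop
            if loops_placed % 5 == 0 and span > 2 * W:
                genes.append(GenomicInterval(
                    chrom, left_center + half + 50, right_center - half - 50))
            # fill the interior with decoys
            pos = left_center + half + int(rng.integers(400, 900))
            while pos + W + 400 <= right_center - half:
                plant_site(w, pos + half, decoy_kind(), "none", -1,
                           "+" if rng.random() < 0.5 else "-")
                pos += W + int(rng.integers(400, 900))
            cursor = right_center + half + int(rng.integers(400, 900))
            loops_placed += 1
        genome[chrom] = seq.tobytes().decode("ascii")

    if loops_placed < n_loops:
        raise RuntimeError("site placement failed: increase chrom_length "
                           "or n_chrom")

    # spurious super-threshold motif rows exercising the FIMO p-value filter
    n_spurious = max(2, site_counter // 20)
    for _ in range(n_spurious):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_length - len(g.core_motif)))
        rows.append(MotifHit(chrom, start, start + len(g.core_motif),
                             "+" if rng.random() < 0.5 else "-",
                             pvalue=float(rng.uniform(5e-5, 1e-3))))

    truth = pd.DataFrame(truth_rows)
    kept = [h for h in rows if h.pvalue < 5e-5]
    return FixtureBundle(grammar=grammar, genome=genome, loops=loops,
                         anchors=anchors, peaks=peaks, motif_hits=kept,
                         all_motif_rows=rows, truth=truth, genes=genes)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variants(grammar: SyntheticGrammar, bundle: FixtureBundle,
                      n_samples: int = 20,
                      disrupting_fraction: float = 0.5,
                      variants_per_sample: int = 6,
                      seed: int | None = None) -> FixtureBundle:
    """Assign each sample motif-disrupting and matched neutral variants.

    Disrupting variants are SNVs or short deletions inside the planted core
    or cofactor motifs of true loop anchors. Neutral variants fall inside
    anchor windows but at least 30 bases away from any planted element, so
    they perturb model input without touching the grammar. Reference alleles
    always match the synthetic genome.
    """
    rng = np.random.default_rng(grammar.seed + 1 if seed is None else seed)
    truth = bundle.truth
    anchors = truth[truth.kind == TRUE_ANCHOR]
    n_disrupt = int(round(variants_per_sample * disrupting_fraction))
    n_neutral = variants_per_sample - n_disrupt

    variants_by_sample: dict[str, list[Variant]] = {}
    vrows: list[dict] = []
    for si in range(n_samples):
        sample = f"S{si:03d}"
        picked: list[Variant] = []
        used: set[tuple[str, int]] = set()

        def add(chrom: str, pos: int, ref_len: int, label: str, loop_id: int,
                snv: bool) -> None:
            seq = bundle.genome[chrom]
            if any(c == chrom and abs(p - pos) < 25 for c, p in used):
                return
            if snv:
                ref = seq[pos]
                alts = [c for c in "ACGT" if c != ref]
                alt = alts[rng.integers(3)]
            else:
                ref = seq[pos:pos + 1 + ref_len]
                alt = seq[pos]
            if "N" in ref:
                return
            v = Variant(chrom, pos, ref, alt, sample_id=sample)
            picked.append(v)
            used.add((chrom, pos))
            vrows.append({"sample": sample, "chrom": chrom, "pos": pos,
                          "ref": ref, "alt": alt, "label": label,
                          "loop_id": loop_id})

        rows = anchors.iloc[rng.choice(len(anchors), size=n_disrupt,
                                       replace=False)]
        for _, r in rows.iterrows():
            if rng.random() < 0.5 and r.cofactor_start >= 0:
                lo_, hi_ = int(r.cofactor_start), int(r.cofactor_end)
            else:
                lo_, hi_ = int(r.core_start), int(r.core_end)
            pos = int(rng.integers(lo_, hi_ - 3))
            add(r.chrom, pos, int(rng.integers(1, 4)), "disrupting",
                int(r.loop_id), snv=bool(rng.random() < 0.5))

        rows = anchors.iloc[rng.choice(len(anchors), size=n_neutral,
                                       replace=False)]
        for _, r in rows.iterrows():
            spans = [(r.core_start, r.core_end), (r.extra_start, r.extra_end),
                     (r.cofactor_start, r.cofactor_end), (r.sig_start, r.sig_end)]
            for _try in range(50):
                pos = int(rng.integers(r.start + 10, r.end - 10))
                if all(s < 0 or not (s - 30 <= pos < e + 30) for s, e in spans):
                    break
            else:
                continue
            # neutral variants are substitutions: an indel away from any
            # planted element still shifts every downstream base relative to
            # the model's positional grid, which is a register change, not a
            # content-neutral background edit
            add(r.chrom, pos, 1, "neutral", int(r.loop_id), snv=True)
        variants_by_sample[sample] = picked

    bundle.variants_by_sample = variants_by_sample
    bundle.variant_truth = pd.DataFrame(vrows)
    return bundle


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_fixture_bundle(bundle: FixtureBundle, out_dir: str | Path
                         ) -> dict[str, Path]:
    """Write the bundle as standard-format files, all re-readable by the
    package's own readers. Same grammar seed -> byte-identical directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "loops": out / "loops.bedpe",
        "anchors": out / "anchors.bed",
        "peaks": out / "peaks.narrowPeak",
        "motifs": out / "motifs.tsv",
        "variants": out / "variants.vcf",
        "truth": out / "truth.tsv",
        "genes": out / "genes.bed",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_loops(bundle.loops, paths["loops"])
    with open(paths["anchors"], "w") as fh:
        for a in bundle.anchors:
            fh.write(f"{a.chrom}\t{a.interval.start}\t{a.interval.end}"
                     f"\t{a.side}\n")
    write_peaks(bundle.peaks, paths["peaks"])
    write_motif_hits(bundle.all_motif_rows, paths["motifs"])
    contigs = {c: len(s) for c, s in bundle.genome.items()}
    write_variants(bundle.variants_by_sample or {}, paths["variants"],
                   contigs=contigs)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        for i, gi in enumerate(bundle.genes):
            fh.write(f"{gi.chrom}\t{gi.start}\t{gi.end}\tgene{i}\n")
    if len(bundle.variant_truth):
        bundle.variant_truth.to_csv(out / "variant_truth.tsv", sep="\t",
                                    index=False)
    return paths


def truth_to_anchors(truth: pd.DataFrame, kind: str) -> list[Anchor]:
    """Candidate-window Anchors of one provenance class from the truth table."""
    out = []
    for _, r in truth[truth.kind == kind].iterrows():
        out.append(Anchor(GenomicInterval(r.chrom, int(r.start), int(r.end)),
                          int(r.center),
                          side=r.side if r.side in ("left", "right") else "none",
                          klass=kind))
    return out
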
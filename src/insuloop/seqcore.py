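"""Domain types, standard-format I/O, window extraction and sequence encoding.

Coordinate convention: every interval in this package is 0-based half-open
(BED native). VCF positions are converted on ingest by subtracting 1. FIMO
coordinates (1-based inclusive) are converted on ingest as well.

Alphabet convention: sequences are uppercase over {A, C, G, T, N}; any other
letter (IUPAC ambiguity codes included) is mapped to N at read time, because
the one-hot encoding has exactly one non-base channel.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TO_N = str.maketrans({c: "N" for c in
                       "BDEFHIJKLMOPQRSUVWXYZbdefhijklmopqrsuvwxyz"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A standard-format file could not be parsed; message names the line."""


class DialectError(ParseError):
    """A BED-family file has an unsupported or inconsistent column count."""


def clean_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT letter to N."""
    return seq.upper().translate(_TO_N)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)``.

    ``strand`` is one of ``'+'``, ``'-'`` or ``'.'`` (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        # start may be negative for standardized windows hanging off a contig
        # edge; extraction N-pads such overhangs. File readers only ever
        # produce non-negative coordinates.
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)


@dataclass(frozen=True)
class Peak(GenomicInterval):
    """A binding-site interval with a summit position (absolute coordinate)."""

    summit: int = -1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.summit < 0:
            object.__setattr__(self, "summit", self.midpoint)


@dataclass(frozen=True)
class MotifHit(GenomicInterval):
    """A motif occurrence with strand and match p-value."""

    pvalue: float = 1.0


# anchor provenance classes
TRUE_ANCHOR = "true_anchor"
NONANCHOR_TYPE1 = "nonanchor_type1"  # bound peak, no loop
NONANCHOR_TYPE2 = "nonanchor_type2"  # motif, no binding
NONANCHOR_TYPE3 = "nonanchor_type3"  # neither motif nor peak

# loop labels
POSITIVE = "positive"
NONLOOP_TYPES = tuple(f"nonloop_type{i}" for i in range(1, 6))


@dataclass(frozen=True)
class Anchor:
    """A loop-anchor candidate: an interval plus its peak center and labels.

    ``side`` marks the anchor's role in loops (left/right/ambiguous/none) and
    ``klass`` its provenance (true anchor or one of the non-anchor classes).
    """

    interval: GenomicInterval
    peak_center: int
    side: str = "none"
    klass: str = TRUE_ANCHOR

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "ambiguous", "none"):
            raise ValueError(f"invalid side {self.side!r}")
        if not (self.interval.start <= self.peak_center < self.interval.end):
            raise ValueError("peak_center outside interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class LoopPair:
    """An ordered (left, right) anchor pair with a loop/non-loop label.

    ``span`` is the distance in bases between the two anchor peak centers.
    """

    left: Anchor
    right: Anchor
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.left.interval.start >= self.right.interval.start:
            raise ValueError("left anchor must start before right anchor")

    @property
    def chrom(self) -> str:
        return self.left.chrom

    @property
    def span(self) -> int:
        return self.right.peak_center - self.left.peak_center

    @property
    def key(self) -> tuple:
        return (self.chrom, self.left.peak_center, self.right.peak_center)


@dataclass(frozen=True)
class Variant:
    """A small variant tied to a sample.

    ``pos`` is 0-based (converted from the 1-based source record); ``pos1``
    recovers the source convention. ``vclass`` is SNV/insertion/deletion,
    derived from allele lengths.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    vclass: str = field(init=False, default="")

    def __post_init__(self) -> None:
        for allele in (self.ref, self.alt):
            if not allele or any(c not in _BASE_INDEX for c in allele):
                raise ValueError(f"invalid allele {allele!r}")
        if len(self.ref) == len(self.alt) == 1:
            vclass = "SNV"
        elif len(self.ref) > len(self.alt):
            vclass = "deletion"
        elif len(self.ref) < len(self.alt):
            vclass = "insertion"
        else:
            vclass = "MNV"
        object.__setattr__(self, "vclass", vclass)

    @property
    def pos1(self) -> int:
        return self.pos + 1

    @property
    def end(self) -> int:
        """0-based end of the reference footprint."""
        return self.pos + len(self.ref)


class EncodedSequence:
    """One-hot base matrix: one row per position, 5 channels (A, C, G, T, N)."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values)
        if values.ndim != 2 or values.shape[1] != 5:
            raise ValueError("encoded sequence must have 5 channels")
        if not np.all(values.sum(axis=1) == 1):
            raise ValueError("every row must have exactly one 1")
        self.values = values

    def __len__(self) -> int:
        return self.values.shape[0]

    def decode(self) -> str:
        idx = np.argmax(self.values, axis=1)
        return "".join(BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: sequence}``.

    Sequences are uppercased and non-ACGT letters mapped to N; chromosome
    names are the header words up to the first whitespace.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if not first:
            raise ParseError(f"{path}: empty FASTA file (line {lineno})")
        if not first.startswith(">"):
            raise ParseError(
                f"{path}: line {lineno}: expected FASTA header, got {first.strip()!r}"
            )
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        genome[record.id] = clean_sequence(str(record.seq))
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _split_fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_loops(path: str | Path, anchor_length: int | None = None
               ) -> list[LoopPair]:
    """Read a BEDPE-style loop file into ordered intra-chromosomal pairs.

    Anchors are reordered so ``left.start < right.start``; inter-chromosomal
    records are dropped with a logged count. Peak centers default to interval
    midpoints.
    """
    loops: list[LoopPair] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = _split_fields(line)
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected >=6 BEDPE columns")
            try:
                c1, s1, e1, c2, s2, e2 = (
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric coordinate ({exc})"
                ) from None
            if c1 != c2:
                dropped += 1
                continue
            a = GenomicInterval(c1, s1, e1)
            b = GenomicInterval(c2, s2, e2)
            if b.start < a.start:
                a, b = b, a
            loops.append(LoopPair(
                left=Anchor(a, a.midpoint, side="left"),
                right=Anchor(b, b.midpoint, side="right"),
            ))
    if dropped:
        logger.info("read_loops(%s): dropped %d inter-chromosomal records",
                    path, dropped)
    return loops


def write_loops(loops: Iterable[LoopPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            li, ri = lp.left.interval, lp.right.interval
            fh.write(f"{li.chrom}\t{li.start}\t{li.end}"
                     f"\t{ri.chrom}\t{ri.start}\t{ri.end}\t1\n")


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a BED3-6 or narrowPeak file (dialect auto-detected by columns).

    For narrowPeak, a non-negative summit offset (column 10) is stored as an
    absolute position; otherwise the summit defaults to the interval midpoint.
    """
    peaks: list[Peak] = []
    ncols_seen: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = _split_fields(line)
            n = len(fields)
            if n not in (3, 4, 5, 6, 10):
                raise DialectError(
                    f"{path}: line {lineno}: {n} columns is neither BED3-6 nor narrowPeak")
            if ncols_seen is None:
                ncols_seen = n
            elif n != ncols_seen:
                raise DialectError(
                    f"{path}: line {lineno}: mixed column counts ({n} vs {ncols_seen})")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            summit = -1
            if n == 10:
                offset = int(fields[9])
                if offset >= 0:
                    summit = start + offset
            strand = fields[5] if n >= 6 and fields[5] in "+-" else "."
            peaks.append(Peak(chrom, start, end, strand, summit=summit))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak (10 columns, summit offset in column 10)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t0\t{p.strand}"
                     f"\t0\t-1\t-1\t{p.summit - p.start}\n")


FIMO_COLUMNS = ("motif_id", "motif_alt_id", "sequence_name", "start", "stop",
                "strand", "score", "p-value", "q-value", "matched_sequence")


def read_motif_hits(path: str | Path, p_threshold: float = 5e-5
                    ) -> list[MotifHit]:
    """Read a FIMO-style TSV, keeping hits with p-value strictly below threshold.

    FIMO start/stop are 1-based inclusive; converted to 0-based half-open.
    """
    hits: list[MotifHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty FIMO file")
        cols = header.split("\t")
        try:
            i_seq = cols.index("sequence_name")
            i_start = cols.index("start")
            i_stop = cols.index("stop")
            i_strand = cols.index("strand")
            i_p = cols.index("p-value")
        except ValueError as exc:
            raise ParseError(f"{path}: missing FIMO column: {exc}") from None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                p = float(fields[i_p])
                start1 = int(fields[i_start])
                stop1 = int(fields[i_stop])
                strand = fields[i_strand]
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if p >= p_threshold:
                continue
            hits.append(MotifHit(fields[i_seq], start1 - 1, stop1,
                                 strand, pvalue=p))
    return hits


def write_motif_hits(hits: Iterable[MotifHit], path: str | Path,
                     motif_id: str = "CORE") -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FIMO_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{motif_id}\t{motif_id}\t{h.chrom}\t{h.start + 1}\t{h.end}"
                     f"\t{h.strand}\t0.0\t{h.pvalue:.3e}\t{h.pvalue:.3e}\t.\n")


def read_variants(path: str | Path) -> dict[str, list[Variant]]:
    """Read a VCF into ``{sample_id: [Variant, ...]}``.

    Multi-allelic records are split into one Variant per alternate allele.
    Sample association comes from genotype columns (any non-reference,
    non-missing genotype carries the variant). A VCF without sample columns
    yields a single group keyed ``"sample"``. Records with invalid alleles
    are rejected and logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    grouped: dict[str, list[Variant]] = defaultdict(list)
    rejected = 0
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            try:
                proto = Variant(rec.CHROM, rec.POS - 1, clean_sequence(rec.REF),
                                clean_sequence(alt))
            except ValueError:
                rejected += 1
                continue
            if not samples:
                grouped["sample"].append(replace(proto, sample_id="sample"))
                continue
            gts = rec.genotype.array()
            for si, sample in enumerate(samples):
                alleles = gts[si][:-1]
                if np.any(alleles == ai + 1):
                    grouped[sample].append(replace(proto, sample_id=sample))
    if rejected:
        logger.info("read_variants(%s): rejected %d invalid records", path, rejected)
    return dict(grouped)


def write_variants(variants_by_sample: Mapping[str, Sequence[Variant]],
                   path: str | Path, contigs: Mapping[str, int] | None = None
                   ) -> None:
    """Write a minimal multi-sample VCF (GT-only) readable by cyvcf2."""
    samples = sorted(variants_by_sample)
    # collate identical records shared across samples
    by_site: dict[tuple, set[str]] = defaultdict(set)
    for sample, variants in variants_by_sample.items():
        for v in variants:
            by_site[(v.chrom, v.pos, v.ref, v.alt)].add(sample)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), carriers in sorted(by_site.items()):
            gts = "\t".join("0/1" if s in carriers else "0/0" for s in samples)
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# window extraction and encoding
# ---------------------------------------------------------------------------

def extract_window(genome: Mapping[str, str], chrom: str, center: int,
                   length: int) -> str:
    """Return the ``length``-base window centered at ``center``.

    The window is ``[center - length//2, center + length//2)``; positions
    beyond the contig ends are filled with N so the result always has exactly
    ``length`` characters.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    if length == 0:
        return ""
    seq = genome[chrom]
    start = center - length // 2
    end = start + length
    lo = max(start, 0)
    hi = min(end, len(seq))
    if lo >= hi:  # window entirely off the contig
        return "N" * length
    return "N" * (lo - start) + seq[lo:hi] + "N" * (end - hi)


def one_hot_encode(seq: str) -> EncodedSequence:
    """One-hot encode a sequence over {A, C, G, T, N} into an m x 5 matrix."""
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        lut[ord(base)] = i
    values = np.zeros((len(seq), 5), dtype=np.uint8)
    if len(seq):
        values[np.arange(len(seq)), lut[idx]] = 1
    return EncodedSequence(values)


def encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """One-hot encode equal-length sequences into an (n, m, 5) uint8 array."""
    if not seqs:
        return np.zeros((0, 0, 5), dtype=np.uint8)
    return np.stack([one_hot_encode(s).values for s in seqs])


def reverse_complement(seq: str) -> str:
    """Reverse-complement over {A, C, G, T, N}; an involution."""
    return seq.translate(_COMPLEMENT)[::-1]


def rc_encoded(x: np.ndarray) -> np.ndarray:
    """Reverse-complement a one-hot array (..., m, 5) without decoding.

    Reverses the position axis and swaps channels A<->T and C<->G.
    """
    return x[..., ::-1, [3, 2, 1, 0, 4]]
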
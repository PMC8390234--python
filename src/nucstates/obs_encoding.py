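"""Directional nucleosome-level observation encoding.

Positioned-nucleosome calls, histone-mark peak calls and a gene annotation
are combined into per-gene integer observation sequences.  Each nucleosome
is one "bin"; the symbol emitted for a bin is the bitmask of histone marks
whose peaks sufficiently overlap it, drawn from an alphabet of ``2**n``
symbols for ``n`` declared marks (symbol 0 = no marks).  Sequences run
5'->3' in gene orientation over the window ``[TSS - upstream, TTS +
downstream]``.

All coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

#: Default mark ordering; index in this tuple is the bit index of the mark.
DEFAULT_MARK_ORDER: tuple[str, ...] = (
    "H3K4me3",
    "H3K4me1",
    "H3K27ac",
    "H3K79me2",
    "H3K36me3",
    "H3K9me3",
    "H3K27me3",
)

DEFAULT_UPSTREAM_BP = 100_000
DEFAULT_DOWNSTREAM_BP = 10_000


@dataclass(frozen=True)
class NucleosomeRecord:
    """One positioned nucleosome with peak-caller attributes.

    ``signal`` holds smoothed coverage samples at 10 bp/point over the
    nucleosome span (may be empty when the caller did not export it).
    """

    chrom: str
    start: int
    end: int
    dyad: int
    height: float = 0.0
    width: float = 1.0
    area: float = 0.0
    pval_peak: float = 0.0
    pval_valley: float = 0.0
    signal: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"nucleosome span empty: {self.chrom}:{self.start}-{self.end}")
        if not (self.start <= self.dyad < self.end):
            raise ValueError(f"dyad {self.dyad} outside span {self.start}-{self.end}")
        if self.height < 0 or self.width <= 0 or self.area < 0:
            raise ValueError("height/area must be >= 0 and width > 0")


@dataclass(frozen=True)
class MarkPeak:
    """A histone-mark peak interval carrying the mark's bit index."""

    chrom: str
    start: int
    end: int
    mark_id: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak span empty: {self.chrom}:{self.start}-{self.end}")
        if self.mark_id < 0:
            raise ValueError("mark_id must be >= 0")


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its 5' TSS and 3' TTS.

    For ``+`` strand genes ``tss < tts``; for ``-`` strand genes the 5' end
    is the numerically larger coordinate, so ``tss > tts``.
    """

    chrom: str
    tss: int
    tts: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tts <= self.tss:
            raise ValueError(f"gene {self.gene_id}: TTS before TSS on + strand")
        if self.strand == "-" and self.tss <= self.tts:
            raise ValueError(f"gene {self.gene_id}: TTS after TSS on - strand")


@dataclass(frozen=True)
class ObservationSequence:
    """Ordered observation symbols for one gene, 5'->3' in gene orientation.

    ``nucleosome_refs`` is a parallel tuple of opaque nucleosome identifiers
    (list indices when produced by :func:`build_sequences`).
    """

    gene_id: str
    symbols: tuple[int, ...]
    nucleosome_refs: tuple[Hashable, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.nucleosome_refs):
            raise ValueError("symbols and nucleosome_refs must be parallel")

    def __len__(self) -> int:
        return len(self.symbols)


def filter_fragments(
    fragments: Iterable[tuple], min_len: int = 130, max_len: int = 180
) -> list[tuple]:
    """Keep fragments whose length is within ``[min_len, max_len]`` (inclusive).

    Fragments are ``(chrom, start, end)`` or ``(start, end)`` tuples.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = []
    for frag in fragments:
        start, end = frag[-2], frag[-1]
        length = end - start
        if length < 0:
            raise ValueError(f"negative-length fragment: {frag}")
        if min_len <= length <= max_len:
            kept.append(frag)
    return kept


def encode_observation(marks_present: Iterable[int], n: int) -> int:
    """Bitmask symbol for a set of mark bit indices: sum of ``2**mark_id``."""
    symbol = 0
    for mark_id in set(marks_present):
        if not 0 <= mark_id < n:
            raise ValueError(f"mark_id {mark_id} out of range for {n} marks")
        symbol |= 1 << mark_id
    return symbol


def decode_observation(symbol: int, n: int) -> set[int]:
    """Inverse of :func:`encode_observation`: the set of bits set in ``symbol``."""
    if not 0 <= symbol < (1 << n):
        raise ValueError(f"symbol {symbol} out of range for {n} marks")
    return {bit for bit in range(n) if symbol & (1 << bit)}


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def assign_marks(
    nucleosome: NucleosomeRecord,
    peaks: Sequence[MarkPeak],
    min_overlap_frac: float = 0.5,
) -> set[int]:
    """Marks whose peaks cover ``>= min_overlap_frac`` of the nucleosome span.

    Overlap is the union coverage of that mark's peaks intersected with the
    nucleosome (same-mark peaks are merged first so overlapping peaks are
    not double-counted).  Peaks on other chromosomes are ignored.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    span = nucleosome.end - nucleosome.start
    by_mark: dict[int, list[tuple[int, int]]] = {}
    for peak in peaks:
        if peak.chrom != nucleosome.chrom:
            continue
        by_mark.setdefault(peak.mark_id, []).append((peak.start, peak.end))
    assigned = set()
    for mark_id, intervals in by_mark.items():
        covered = 0
        for start, end in _merge_intervals(intervals):
            covered += max(0, min(end, nucleosome.end) - max(start, nucleosome.start))
        if covered >= min_overlap_frac * span:
            assigned.add(mark_id)
    return assigned


def encode_nucleosomes(
    nucleosomes: Sequence[NucleosomeRecord],
    peaks: Sequence[MarkPeak],
    n_marks: int,
    min_overlap_frac: float = 0.5,
) -> np.ndarray:
    """Vectorized per-nucleosome symbol assignment.

    Equivalent to ``encode_observation(assign_marks(nuc, peaks), n_marks)``
    for every nucleosome, but grouped by chromosome and mark for speed.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    symbols = np.zeros(len(nucleosomes), dtype=np.int64)
    if not nucleosomes:
        return symbols

    # index nucleosomes per chromosome
    by_chrom: dict[str, list[int]] = {}
    for i, nuc in enumerate(nucleosomes):
        by_chrom.setdefault(nuc.chrom, []).append(i)

    peaks_by: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for peak in peaks:
        if peak.mark_id >= n_marks:
            raise ValueError(f"mark_id {peak.mark_id} out of range for {n_marks} marks")
        peaks_by.setdefault((peak.chrom, peak.mark_id), []).append((peak.start, peak.end))

    for (chrom, mark_id), intervals in peaks_by.items():
        idx = by_chrom.get(chrom)
        if not idx:
            continue
        merged = _merge_intervals(intervals)
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        # cumulative covered length up to each merged-interval end
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        for i in idx:
            nuc = nucleosomes[i]
            lo = np.searchsorted(ends, nuc.start, side="right")
            hi = np.searchsorted(starts, nuc.end, side="left")
            if lo >= hi:
                continue
            covered = cum[hi] - cum[lo]
            covered -= max(0, nuc.start - starts[lo])
            covered -= max(0, ends[hi - 1] - nuc.end)
            if covered >= min_overlap_frac * (nuc.end - nuc.start):
                symbols[i] |= 1 << mark_id
    return symbols


def gene_window(
    gene: GeneRecord,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
) -> tuple[int, int]:
    """Genomic (left, right) span of the gene-centric training window."""
    if gene.strand == "+":
        left, right = gene.tss - upstream_bp, gene.tts + downstream_bp
    else:
        left, right = gene.tts - downstream_bp, gene.tss + upstream_bp
    return max(0, left), max(0, right)


def build_sequences(
    nucleosomes: Sequence[NucleosomeRecord],
    peaks: Sequence[MarkPeak],
    genes: Sequence[GeneRecord],
    n_marks: int,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
    downstream_bp: int = DEFAULT_DOWNSTREAM_BP,
    min_overlap_frac: float = 0.5,
) -> list[ObservationSequence]:
    """One observation sequence per gene over its training window.

    Nucleosome membership is tested by dyad; a nucleosome falling in two
    gene windows appears in both sequences (sequences are treated as
    independent during training).  Symbol order is reversed for ``-``
    strand genes so every sequence runs 5'->3'.  Genes with identical TSS
    are processed in gene_id lexical order.  ``nucleosome_refs`` are
    indices into ``nucleosomes``.
    """
    symbols = encode_nucleosomes(nucleosomes, peaks, n_marks, min_overlap_frac)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {nuc.chrom for nuc in nucleosomes}:
        idx = np.array([i for i, nuc in enumerate(nucleosomes) if nuc.chrom == chrom])
        dyads = np.array([nucleosomes[i].dyad for i in idx])
        order = np.argsort(dyads, kind="stable")
        by_chrom[chrom] = (idx[order], dyads[order])

    sequences = []
    for gene in sorted(genes, key=lambda g: (g.chrom, min(g.tss, g.tts), g.gene_id)):
        left, right = gene_window(gene, upstream_bp, downstream_bp)
        if gene.chrom in by_chrom:
            idx_sorted, dyads_sorted = by_chrom[gene.chrom]
            lo = np.searchsorted(dyads_sorted, left, side="left")
            hi = np.searchsorted(dyads_sorted, right, side="left")
            member = idx_sorted[lo:hi]
        else:
            member = np.array([], dtype=np.int64)
        if gene.strand == "-":
            member = member[::-1]
        sequences.append(
            ObservationSequence(
                gene_id=gene.gene_id,
                symbols=tuple(int(symbols[i]) for i in member),
                nucleosome_refs=tuple(int(i) for i in member),
            )
        )
    return sequences
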
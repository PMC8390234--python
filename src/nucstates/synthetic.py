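"""Seeded generators for every input the pipeline consumes.

All functions take an explicit ``numpy.random.Generator`` or integer seed
and are deterministic under it.  Output formats match what the real
pipeline reads: nucleosome records with caller attributes and 10 bp/point
smoothed signal, per-mark peak files, a gene table, raw-read pileups, and
skipped-exon event tables — plus the generating ground truth so recovery
can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hmm_core import HmmModel
from .nuc_org import NucArraySignal
from .obs_encoding import GeneRecord, MarkPeak, NucleosomeRecord, decode_observation
from .splicing import SeEvent


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class GroundTruth:
    """What the generators actually sampled, for recovery tests."""

    model: HmmModel | None = None
    state_paths: dict[str, np.ndarray] = field(default_factory=dict)
    array_period_bp: float | None = None
    archetypes: tuple[str, ...] = ()
    se_labels: tuple[bool, ...] = ()
    n_cutoff: int | None = None


def random_structured_model(
    n_states: int,
    n_symbols: int,
    seed=0,
    self_loop: float = 0.8,
    emission_conc: float = 0.3,
    anchor_mass: float = 0.0,
) -> HmmModel:
    """A ground-truth HMM with sticky transitions and spiky emissions.

    Self-transitions get ``self_loop`` mass (runs of equal states, as real
    nucleosome arrays show); emission rows are Dirichlet(emission_conc),
    i.e. concentrated on few symbols so states are identifiable.  With
    ``anchor_mass`` > 0 each state additionally puts that much mass on its
    own distinct symbol (requires n_states <= n_symbols), which guarantees
    the states are mutually distinguishable.
    """
    rng = _rng(seed)
    if n_states < 1 or n_symbols < 2:
        raise ValueError("need n_states >= 1 and n_symbols >= 2")
    if anchor_mass and n_states > n_symbols:
        raise ValueError("distinct anchors need n_states <= n_symbols")
    if n_states == 1:
        A = np.ones((1, 1))
    else:
        off = (1.0 - self_loop) / (n_states - 1)
        A = np.full((n_states, n_states), off)
        np.fill_diagonal(A, self_loop)
    pi = np.full(n_states, 1.0 / n_states)
    B = rng.dirichlet(np.full(n_symbols, emission_conc), size=n_states)
    if anchor_mass:
        anchors = rng.permutation(n_symbols)[:n_states]
        B = B * (1.0 - anchor_mass)
        B[np.arange(n_states), anchors] += anchor_mass
    B = np.maximum(B, 1e-8)
    B /= B.sum(axis=1, keepdims=True)
    return HmmModel(pi, A, B)


def simulate_genome(
    n_genes: int,
    gene_len_range: tuple[int, int] = (5_000, 20_000),
    seed=0,
    chrom: str = "chrS",
    gap_range: tuple[int, int] = (1_000, 5_000),
    origin: int = 10_000,
) -> tuple[list[GeneRecord], dict[str, int]]:
    """Non-overlapping genes with unique TSS on both strands of one chromosome."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = _rng(seed)
    genes = []
    cursor = origin
    for i in range(n_genes):
        length = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        left, right = cursor, cursor + length
        if strand == "+":
            genes.append(GeneRecord(chrom, left, right, "+", f"gene{i:04d}"))
        else:
            genes.append(GeneRecord(chrom, right, left, "-", f"gene{i:04d}"))
        cursor = right + int(rng.integers(gap_range[0], gap_range[1] + 1))
    sizes = {chrom: cursor + origin}
    return genes, sizes


def _inps_attributes(
    rng: np.random.Generator, n_reads: int, read_sd: float
) -> tuple[float, float, float, float, tuple[float, ...]]:
    """Plausible caller attributes for a pileup of given sharpness."""
    height = n_reads / (read_sd * np.sqrt(2 * np.pi)) * 10.0
    width = 2.355 * read_sd  # Gaussian FWHM
    area = float(n_reads)
    signal = tuple(
        float(max(0.0, height * np.exp(-0.5 * ((x - 70) / read_sd) ** 2)))
        for x in range(0, 140, 10)
    )
    return height, width, area, height, signal


def simulate_states_and_marks(
    genes: Sequence[GeneRecord],
    model: HmmModel,
    n_marks: int,
    seed=0,
    spacing_mean: float = 185.0,
    spacing_sd: float = 15.0,
    nuc_width: int = 140,
    flank_bp: int = 0,
) -> tuple[list[NucleosomeRecord], list[MarkPeak], GroundTruth]:
    """Tile each gene with nucleosomes and emit marks from a known HMM.

    States follow the model's Markov chain 5'->3' per gene; each
    nucleosome's observation symbol is sampled from the state's emission
    row and decoded into mark peaks that exactly cover the nucleosome span
    (overlap fraction 1), so re-encoding recovers the sampled symbols.
    """
    rng = _rng(seed)
    if model.n_symbols > (1 << n_marks):
        raise ValueError("model alphabet larger than 2**n_marks")
    nucleosomes: list[NucleosomeRecord] = []
    peaks: list[MarkPeak] = []
    truth = GroundTruth(model=model.copy())
    for gene in genes:
        left = min(gene.tss, gene.tts) - flank_bp
        right = max(gene.tss, gene.tts) + flank_bp
        positions = []
        pos = left + nuc_width
        while pos + nuc_width < right:
            positions.append(int(pos))
            pos += max(nuc_width + 10, rng.normal(spacing_mean, spacing_sd))
        if not positions:
            truth.state_paths[gene.gene_id] = np.array([], dtype=np.int64)
            continue
        T = len(positions)
        states = np.empty(T, dtype=np.int64)
        states[0] = rng.choice(model.n_states, p=model.pi)
        for t in range(1, T):
            states[t] = rng.choice(model.n_states, p=model.A[states[t - 1]])
        symbols = np.array(
            [rng.choice(model.n_symbols, p=model.B[s]) for s in states], dtype=np.int64
        )
        # genomic order is 5'->3' for +, reversed for - strand genes
        if gene.strand == "-":
            truth.state_paths[gene.gene_id] = states.copy()
            states = states[::-1]
            symbols = symbols[::-1]
        else:
            truth.state_paths[gene.gene_id] = states.copy()
        for dyad, symbol in zip(positions, symbols):
            start, end = dyad - nuc_width // 2, dyad + nuc_width // 2
            n_reads = int(rng.integers(40, 120))
            h, w, a, p, sig = _inps_attributes(rng, n_reads, read_sd=20.0)
            nucleosomes.append(
                NucleosomeRecord(
                    chrom=gene.chrom,
                    start=start,
                    end=end,
                    dyad=dyad,
                    height=h,
                    width=w,
                    area=a,
                    pval_peak=p,
                    pval_valley=p * 0.5,
                    signal=sig,
                )
            )
            for mark_id in decode_observation(int(symbol), n_marks):
                peaks.append(MarkPeak(gene.chrom, start, end, mark_id))
    nucleosomes.sort(key=lambda n: (n.chrom, n.dyad))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.mark_id))
    return nucleosomes, peaks, truth


def simulate_array_signal(
    period_bp: float = 185.0,
    n_nucleosomes: int = 5,
    decay: float = 1.0,
    noise_sd: float = 0.0,
    fs: int = 100,
    window_bp: int = 1000,
    peak_sd_bp: float = 45.0,
    seed=0,
    state: int = 0,
) -> NucArraySignal:
    """Periodic Gaussian-peak train plus white noise at ``fs`` points/kb.

    Peak k sits at ``k * period_bp`` with amplitude ``decay**k``.  Noise is
    added at the native sample rate (as a smoothed-coverage signal would
    carry it); values are clipped at zero.
    """
    if period_bp <= 0:
        raise ValueError("period_bp must be > 0")
    rng = _rng(seed)
    bp_per_point = 1000.0 / fs
    n_points = int(window_bp / bp_per_point)
    x_bp = np.arange(n_points) * bp_per_point
    values = np.zeros(n_points)
    for k in range(n_nucleosomes):
        center = k * period_bp
        if center - 4 * peak_sd_bp > window_bp:
            break
        values += decay**k * np.exp(-0.5 * ((x_bp - center) / peak_sd_bp) ** 2)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_points)
    return NucArraySignal(state=state, values=np.clip(values, 0.0, None), fs=fs)


def simulate_reads_and_inps(
    n_pairs: int,
    seed=0,
    chrom: str = "chrS",
    spacing_bp: int = 400,
    well_sd: float = 10.0,
    fuzzy_sd: float = 55.0,
    reads_per_nuc: int = 80,
) -> tuple[list[NucleosomeRecord], list[int], tuple[str, ...], GroundTruth]:
    """Alternating well-positioned / fuzzy nucleosomes with raw reads.

    Returns (records, read_centers, archetypes, truth); archetype i applies
    to record i.  Caller attributes are derived from each nucleosome's own
    generated pileup so attribute- and read-based scores stay coupled.
    """
    rng = _rng(seed)
    records: list[NucleosomeRecord] = []
    read_centers: list[int] = []
    archetypes: list[str] = []
    pos = 10_000
    for i in range(2 * n_pairs):
        archetype = "well" if i % 2 == 0 else "fuzzy"
        base_sd = well_sd if archetype == "well" else fuzzy_sd
        sd = base_sd * float(rng.uniform(0.8, 1.2))  # per-nucleosome diversity
        n_reads = reads_per_nuc + int(rng.integers(-10, 11))
        offsets = rng.normal(0.0, sd, size=n_reads)
        centers = np.round(pos + offsets).astype(int)
        read_centers.extend(int(c) for c in centers)

        # pileup-derived attributes at 10 bp/point over a 147 bp span;
        # Gaussian smoothing (sd 15 bp) mimics caller smoothing and keeps
        # ragged fuzzy pileups from yielding spuriously narrow FWHMs
        start, end = pos - 73, pos + 74
        in_span = centers[(centers >= start) & (centers < end)]
        hist = np.bincount(in_span - start, minlength=end - start).astype(float)
        k_x = np.arange(-30, 31)
        kernel = np.exp(-0.5 * (k_x / 15.0) ** 2)
        kernel /= kernel.sum()
        smoothed = np.convolve(hist, kernel, mode="same")
        height = float(smoothed.max()) * 10.0
        half = smoothed.max() / 2.0
        above = np.flatnonzero(smoothed >= half)
        width = float(above[-1] - above[0] + 1) if above.size else 1.0
        area = float(n_reads)
        pval_peak = height * (1.0 + 0.05 * rng.normal())
        pval_valley = max(0.0, height * 0.5 * (1.0 + 0.05 * rng.normal()))
        sig = tuple(float(v) for v in smoothed[::10] * 10.0)
        records.append(
            NucleosomeRecord(
                chrom=chrom,
                start=start,
                end=end,
                dyad=pos,
                height=height,
                width=width,
                area=area,
                pval_peak=pval_peak,
                pval_valley=pval_valley,
                signal=sig,
            )
        )
        archetypes.append(archetype)
        pos += spacing_bp
    truth = GroundTruth(archetypes=tuple(archetypes))
    return records, sorted(read_centers), tuple(archetypes), truth


def simulate_se_table(
    n_events: int,
    reliable_frac: float = 0.5,
    seed=0,
    chrom: str = "chrS",
    n_cutoff: int = 20,
) -> tuple[list[SeEvent], tuple[bool, ...], GroundTruth]:
    """SE event table with planted reliable/unreliable labels.

    Reliable events get ``X + Y >= n_cutoff`` with ``Y >= 1`` and CI widths
    above the overall median; unreliable events sit low on both counts and
    CI width.  Labels are the generating intent re-checked against the
    rules, so they are exactly recoverable given the same ``n_cutoff``.
    """
    if not 0 <= reliable_frac <= 1:
        raise ValueError("reliable_frac must be in [0, 1]")
    rng = _rng(seed)
    events: list[SeEvent] = []
    intents: list[bool] = []
    pos = 50_000
    for i in range(n_events):
        reliable = rng.random() < reliable_frac
        if reliable:
            x = int(rng.integers(n_cutoff, 3 * n_cutoff))
            y = int(rng.integers(1, max(2, n_cutoff // 2)))
            ci = float(rng.uniform(0.55, 0.95))
        else:
            if rng.random() < 0.5:
                x = int(rng.integers(0, n_cutoff))  # fails X+Y
                y = int(rng.integers(0, 2))
            else:
                x = int(rng.integers(n_cutoff, 3 * n_cutoff))
                y = 0  # fails Y >= 1
            ci = float(rng.uniform(0.05, 0.45))
        start = pos
        end = pos + int(rng.integers(80, 300))
        strand = "+" if rng.random() < 0.5 else "-"
        events.append(SeEvent(f"se{i:04d}", chrom, start, end, strand, x, y, ci))
        intents.append(reliable)
        pos = end + int(rng.integers(500, 2_000))
    median_ci = float(np.median([e.ci_width for e in events]))
    labels = tuple(
        (e.x_reads + e.y_reads >= n_cutoff) and e.y_reads >= 1 and e.ci_width > median_ci
        for e in events
    )
    truth = GroundTruth(se_labels=labels, n_cutoff=n_cutoff)
    return events, labels, truth
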
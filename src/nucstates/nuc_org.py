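"""Nucleosome arrays and organization scores.

An *array* is a maximal run of same-state nucleosomes whose consecutive
dyad gaps stay under a threshold (default 350 bp).  Per-state array
coverage signals (native 10 bp/point) are averaged over a 1 kb window
anchored at each array start, linearly interpolated to 1 bp/point, and
converted to the frequency domain by Welch's method; the phasing score is
1000x the peak spectral density in the 4-10 Hz band (genomic periods
100-250 bp at fs=1000).  Spacing is the mean distance between local maxima
of the averaged signal.  Positioning combines a raw-read reference score
(rNP) with a call-attribute score (NP); both use interquartile-range
normalization of their inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .obs_encoding import NucleosomeRecord

DEFAULT_MAX_GAP_BP = 350
DEFAULT_WINDOW_BP = 1000
DEFAULT_BAND_HZ = (4.0, 10.0)
_DENOM_FLOOR = 1e-6


@dataclass
class NucArray:
    """A run of same-state nucleosomes ordered 5'->3' (genomically)."""

    state: int
    members: tuple[int, ...]  # indices into the decoded nucleosome list
    chrom: str
    start: int  # first member's start bp


@dataclass
class NucArraySignal:
    """Averaged array coverage over a fixed window.

    ``fs`` is in points per kb: 100 native (10 bp/point), 1000 after
    interpolation (1 bp/point).
    """

    state: int
    values: np.ndarray
    fs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PsdTable:
    freqs: np.ndarray
    density: np.ndarray


@dataclass
class PhasingSpacing:
    state: int
    phasing_score: float
    spacing_bp: float  # NaN when fewer than 2 maxima
    psd: PsdTable | None = None


@dataclass
class PositioningRecord:
    index: int  # nucleosome ref
    np_score: float
    rnp_score: float | None = None


# ---------------------------------------------------------------------------
# arrays


def detect_arrays(
    nucleosomes: Sequence[NucleosomeRecord],
    states: Sequence[int],
    max_gap: int = DEFAULT_MAX_GAP_BP,
) -> tuple[list[NucArray], dict[int, float]]:
    """Group decoded nucleosomes into same-state arrays.

    Input must be sorted by (chrom, dyad).  A run breaks on chromosome
    change, state change, or a consecutive dyad gap >= ``max_gap``.
    Returns the arrays and the per-state mean member count ("Ave No.").
    """
    if len(nucleosomes) != len(states):
        raise ValueError("nucleosomes and states must be parallel")
    prev = None
    for nuc in nucleosomes:
        key = (nuc.chrom, nuc.dyad)
        if prev is not None and key < prev:
            raise ValueError("nucleosomes must be sorted by (chrom, dyad)")
        prev = key

    arrays: list[NucArray] = []
    run: list[int] = []

    def flush() -> None:
        if run:
            first = nucleosomes[run[0]]
            arrays.append(
                NucArray(
                    state=int(states[run[0]]),
                    members=tuple(run),
                    chrom=first.chrom,
                    start=first.start,
                )
            )

    for i, nuc in enumerate(nucleosomes):
        if run:
            last = nucleosomes[run[-1]]
            if (
                nuc.chrom != last.chrom
                or states[i] != states[run[-1]]
                or nuc.dyad - last.dyad >= max_gap
            ):
                flush()
                run = []
        run.append(i)
    flush()

    mean_len: dict[int, float] = {}
    for state in sorted({arr.state for arr in arrays}):
        lengths = [len(arr.members) for arr in arrays if arr.state == state]
        mean_len[state] = float(np.mean(lengths))
    return arrays, mean_len


def array_signal(
    arrays: Sequence[NucArray],
    nucleosomes: Sequence[NucleosomeRecord],
    window_bp: int = DEFAULT_WINDOW_BP,
    native_fs: int = 100,
) -> NucArraySignal | None:
    """Mean aligned coverage of the arrays over ``window_bp`` from each start.

    Member signals (10 bp/point) are placed at their offset from the array
    start; arrays shorter than the window are zero-padded.  Returns None
    when ``arrays`` is empty.
    """
    if not arrays:
        return None
    bp_per_point = 1000 // native_fs
    n_points = window_bp // bp_per_point
    acc = np.zeros(n_points)
    for arr in arrays:
        sig = np.zeros(n_points)
        for i in arr.members:
            nuc = nucleosomes[i]
            offset = (nuc.start - arr.start) // bp_per_point
            values = np.asarray(nuc.signal, dtype=float)
            if offset >= n_points or values.size == 0:
                continue
            take = min(values.size, n_points - offset)
            sig[offset : offset + take] += values[:take]
        acc += sig
    return NucArraySignal(state=arrays[0].state, values=acc / len(arrays), fs=native_fs)


def interpolate(signal: NucArraySignal, target_fs: int = 1000) -> NucArraySignal:
    """Linear upsampling; original samples are preserved at their positions."""
    if target_fs % signal.fs != 0:
        raise ValueError(f"target_fs {target_fs} is not a multiple of fs {signal.fs}")
    factor = target_fs // signal.fs
    if factor == 1:
        return NucArraySignal(signal.state, signal.values.copy(), signal.fs)
    n = signal.values.size
    x_old = np.arange(n) * factor
    x_new = np.arange(n * factor)
    values = np.interp(x_new, x_old, signal.values)
    return NucArraySignal(signal.state, values, target_fs)


# ---------------------------------------------------------------------------
# phasing


def welch_psd(
    signal: NucArraySignal,
    frame_len: int = 512,
    hop: int | None = None,
) -> PsdTable:
    """Welch power-spectral-density estimate with a Hanning window.

    Frames of ``frame_len`` samples taken every ``hop`` samples (default
    frame_len/2) are windowed, their periodograms ``|FFT|^2 / M`` averaged.
    """
    x = signal.values
    M = frame_len
    if M > x.size:
        raise ValueError(f"frame_len {M} exceeds signal length {x.size}")
    R = hop if hop is not None else M // 2
    if R < 1:
        raise ValueError("hop must be >= 1")
    # periodic Hann: DC leaks only into the two adjacent bins
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(M) / M))
    starts = range(0, x.size - M + 1, R)
    frames = np.stack([w * x[s : s + M] for s in starts])
    periodograms = np.abs(np.fft.rfft(frames, axis=1)) ** 2 / M
    freqs = np.fft.rfftfreq(M, d=1.0 / signal.fs)
    return PsdTable(freqs=freqs, density=periodograms.mean(axis=0))


def phasing_score(psd: PsdTable, band: tuple[float, float] = DEFAULT_BAND_HZ) -> float:
    """1000x the maximum spectral density inside ``band`` (Hz, inclusive)."""
    lo, hi = band
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} contains no PSD frequencies")
    return 1000.0 * float(psd.density[sel].max())


def freq_to_period(freq: float, fs: float = 1000.0) -> float:
    """Genomic period (bp) for a frequency at sample rate ``fs``: fs/freq."""
    if freq <= 0:
        raise ValueError("frequency must be > 0")
    return fs / freq


def period_to_freq(period: float, fs: float = 1000.0) -> float:
    if period <= 0:
        raise ValueError("period must be > 0")
    return fs / period


# ---------------------------------------------------------------------------
# spacing


def local_maxima(values: np.ndarray, min_prominence_frac: float = 0.0) -> np.ndarray:
    """Indices of local maxima; flat plateaus yield their middle index
    (lower-middle for even plateau lengths).

    ``min_prominence_frac`` > 0 additionally requires each maximum to have
    a topographic prominence of at least that fraction of the signal's
    range, which suppresses sampling-noise wiggles; 0 keeps every strict
    local maximum.
    """
    x = np.asarray(values, dtype=float)
    prominence = None
    if min_prominence_frac > 0:
        span = float(x.max() - x.min())
        if span > 0:
            prominence = min_prominence_frac * span
    peaks, _ = find_peaks(x, prominence=prominence)
    return peaks


def spacing(signal: NucArraySignal, min_prominence_frac: float = 0.2) -> float:
    """Mean consecutive distance (bp) between local maxima; NaN if < 2."""
    peaks = local_maxima(signal.values, min_prominence_frac)
    if peaks.size < 2:
        return math.nan
    bp_per_point = 1000.0 / signal.fs
    return float(np.diff(peaks).mean() * bp_per_point)


def spacing_first_k(signal: NucArraySignal, k: int = 4, min_prominence_frac: float = 0.2) -> float:
    """Mean of the first ``k`` inter-maximum intervals (NaN if < 2 maxima)."""
    peaks = local_maxima(signal.values, min_prominence_frac)
    if peaks.size < 2:
        return math.nan
    diffs = np.diff(peaks)[:k]
    return float(diffs.mean() * 1000.0 / signal.fs)


def spacing_range(
    spacing_nucs: float,
    interval: int,
    rank: int,
    coef_range: float = 1.0,
) -> tuple[float, float]:
    """Allowed spacing band for the nucleosome of order ``interval + 1``.

    ``[spacing - interval*(5 + rank*coef), spacing + interval*(5 + rank*coef)]``;
    ``rank`` is the state's descending phasing-score rank (1 = highest).
    Interval 0 gives the degenerate range (first nucleosome always kept).
    """
    if coef_range < 0:
        raise ValueError("coef_range must be >= 0")
    if interval < 0:
        raise ValueError("interval must be >= 0")
    if rank < 1:
        raise ValueError("rank must be >= 1")
    half = interval * (5.0 + rank * coef_range)
    return (spacing_nucs - half, spacing_nucs + half)


def array_spacing_mask(
    dyads: Sequence[int],
    spacing_nucs: float,
    rank: int,
    coef_range: float = 1.0,
) -> np.ndarray:
    """Per-member retention mask for one array's dyads.

    Member k (0-based; interval = k) is kept iff its observed spacing
    ``dyad[k] - dyad[k-1]`` falls inside :func:`spacing_range`.  The first
    member (interval 0) is always kept.
    """
    dyads = np.asarray(dyads)
    mask = np.ones(dyads.size, dtype=bool)
    for k in range(1, dyads.size):
        lo, hi = spacing_range(spacing_nucs, k, rank, coef_range)
        observed = dyads[k] - dyads[k - 1]
        mask[k] = lo <= observed <= hi
    return mask


# ---------------------------------------------------------------------------
# positioning


def iqr_normalize(values: Sequence[float]) -> np.ndarray:
    """Interquartile-range normalization: (x - Q1) / (Q3 - Q1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for IQR normalization")
    q1, q3 = np.percentile(x, [25, 75])
    if q3 - q1 <= 0:
        raise ValueError("IQR is zero; values are too concentrated")
    return (x - q1) / (q3 - q1)


def rnp_features(
    read_centers: Sequence[int], nucleosome: NucleosomeRecord, smooth_bp: int = 10
) -> tuple[float, float, float] | None:
    """(enrich, std, fwhm) of read centers around the nucleosome dyad.

    enrich: count of centers within +/-73 bp of the dyad; std: standard
    deviation of center offsets within the nucleosome span; fwhm: width at
    half maximum of the center histogram over the span, smoothed with a
    ``smooth_bp`` moving average.  Returns None when no read falls in the
    span (rNP is then absent for this nucleosome).
    """
    centers = np.asarray(read_centers)
    in_span = centers[(centers >= nucleosome.start) & (centers < nucleosome.end)]
    if in_span.size == 0:
        return None
    offsets = in_span - nucleosome.dyad
    enrich = float(np.count_nonzero(np.abs(centers - nucleosome.dyad) <= 73))
    std = float(np.std(offsets))
    hist = np.bincount(in_span - nucleosome.start, minlength=nucleosome.end - nucleosome.start)
    kernel = np.ones(smooth_bp) / smooth_bp
    smoothed = np.convolve(hist.astype(float), kernel, mode="same")
    half = smoothed.max() / 2.0
    above = np.flatnonzero(smoothed >= half)
    fwhm = float(above[-1] - above[0] + 1) if above.size else 1.0
    return enrich, std, fwhm


def rnp_score(
    enrich: Sequence[float], fwhm: Sequence[float], std: Sequence[float]
) -> np.ndarray:
    """Reference positioning score: norm(enrich) / (norm(fwhm) + norm(std)).

    The three feature populations are IQR-normalized jointly over the
    nucleosome set; the denominator is floored at 1e-6.
    """
    num = iqr_normalize(enrich)
    denom = iqr_normalize(fwhm) + iqr_normalize(std)
    return num / np.maximum(denom, _DENOM_FLOOR)


def np_score(
    nucleosomes: Sequence[NucleosomeRecord],
    arrays: Sequence[Sequence[int]] | None = None,
) -> np.ndarray:
    """Call-attribute positioning score per nucleosome.

    ``NP = (height + log2(pval_peak * pval_valley + 1) + area) / (3 * width)``
    over IQR-normalized attribute populations.  The last nucleosome of each
    array has its valley p-value replaced by the global median first (the
    value is unreliable at array ends).  Width denominators are floored;
    the log2 argument is floored at a small positive value since normalized
    p-value products can dip below -1.
    """
    if len(nucleosomes) < 4:
        raise ValueError("need at least 4 nucleosomes for population normalization")
    height = np.array([n.height for n in nucleosomes], dtype=float)
    width = np.array([n.width for n in nucleosomes], dtype=float)
    area = np.array([n.area for n in nucleosomes], dtype=float)
    pp = np.array([n.pval_peak for n in nucleosomes], dtype=float)
    pv = np.array([n.pval_valley for n in nucleosomes], dtype=float)

    if arrays is not None:
        median_pv = float(np.median(pv))
        for members in arrays:
            if len(members) > 0:
                pv[members[-1]] = median_pv

    def norm_or_zero(x: np.ndarray) -> np.ndarray:
        # a constant attribute column (e.g. every valley p-value replaced by
        # the median when all arrays are singletons) carries no information
        try:
            return iqr_normalize(x)
        except ValueError:
            warnings.warn("attribute column has zero IQR; normalized to 0")
            return np.zeros_like(x)

    height = norm_or_zero(height)
    width = norm_or_zero(width)
    area = norm_or_zero(area)
    pp = norm_or_zero(pp)
    pv = norm_or_zero(pv)

    log_term = np.log2(np.maximum(pp * pv + 1.0, _DENOM_FLOOR))
    return (height + log_term + area) / (3.0 * np.maximum(width, _DENOM_FLOOR))


def positioning_filter(
    scores: Sequence[float],
    states: Sequence[int] | None = None,
    q_low: float = 0.05,
    q_high: float = 0.95,
) -> tuple[np.ndarray, dict[int, float] | float]:
    """Drop scores outside the [q_low, q_high] quantiles of their group.

    With ``states``, quantiles and means are computed within each state's
    score group; otherwise over the whole population.  Returns (retained
    mask, per-state mean dict or scalar mean).
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("require 0 <= q_low < q_high <= 1")
    scores = np.asarray(scores, dtype=float)
    if states is None:
        lo, hi = np.quantile(scores, [q_low, q_high])
        mask = (scores >= lo) & (scores <= hi)
        return mask, float(scores[mask].mean())
    states = np.asarray(states)
    mask = np.zeros(scores.size, dtype=bool)
    means: dict[int, float] = {}
    for state in np.unique(states):
        sel = states == state
        lo, hi = np.quantile(scores[sel], [q_low, q_high])
        keep = sel & (scores >= lo) & (scores <= hi)
        mask |= keep
        means[int(state)] = float(scores[keep].mean())
    return mask, means


def phasing_and_spacing(
    signal: NucArraySignal,
    frame_len: int = 512,
    hop: int | None = None,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    target_fs: int = 1000,
    spacing_intervals: int | None = 4,
) -> PhasingSpacing:
    """Interpolate, run Welch, and score one state's array signal."""
    upsampled = interpolate(signal, target_fs)
    M = min(frame_len, upsampled.values.size)
    psd = welch_psd(upsampled, frame_len=M, hop=hop if hop is not None else M // 2)
    score = phasing_score(psd, band)
    if spacing_intervals is None:
        space = spacing(upsampled)
    else:
        space = spacing_first_k(upsampled, spacing_intervals)
    return PhasingSpacing(state=signal.state, phasing_score=score, spacing_bp=space, psd=psd)
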
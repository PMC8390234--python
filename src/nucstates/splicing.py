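"""Skipped-exon reliability filtering and splicing-potentiality scoring.

Candidate skipped-exon (SE) events carry isoform-exclusive read counts
X (inclusion-only) and Y (exclusion-only) and the width of the inclusion
level's confidence interval.  Rule 1 keeps events with ``X + Y >= N`` and
``Y >= 1``; Rule 2 keeps events whose CI width exceeds the median CI width
(the printed direction; an inversion flag is provided).  Events passing
both rules form the reliable group (rSE); the rest are unreliable (urSE).

Per functional state, the splicing potentiality (SPSE) is the product of
three [0,1]-rescaled components: the discrete Frechet distance between the
rSE and urSE mean array signals, the absolute difference of median
positioning scores, and the state's normalized event-count coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class SeEvent:
    """One skipped-exon candidate event."""

    event_id: str
    chrom: str
    start: int
    end: int
    strand: str
    x_reads: int
    y_reads: int
    ci_width: float

    def __post_init__(self) -> None:
        if self.x_reads < 0 or self.y_reads < 0:
            raise ValueError("read counts must be nonnegative")
        if not 0 <= self.ci_width <= 1:
            raise ValueError("ci_width must be in [0, 1]")


@dataclass
class SpseResult:
    nucs_id: int
    frechet: float
    diff_nucpos: float
    coef_event_counts: float
    spse: float
    affinity: float = np.nan


def derive_n_cutoff(events: Sequence[SeEvent], quantile: float = 0.75) -> int:
    """Default Rule-1 cutoff: a quantile of the X+Y frequency distribution."""
    totals = [e.x_reads + e.y_reads for e in events]
    return int(np.ceil(np.quantile(totals, quantile)))


def classify_se(
    events: Sequence[SeEvent],
    n_cutoff: int | None = None,
    invert_rule2: bool = False,
) -> tuple[list[SeEvent], list[SeEvent]]:
    """Partition events into (reliable, unreliable).

    Reliable = Rule 1 (X + Y >= N and Y >= 1) AND Rule 2 (CI width > median
    CI width; ``invert_rule2`` flips the comparison to <).  With ``n_cutoff``
    unset, N is derived from the X+Y distribution (75th percentile).
    """
    if not events:
        raise ValueError("empty event list")
    if n_cutoff is None:
        n_cutoff = derive_n_cutoff(events)
    if n_cutoff < 1:
        raise ValueError("n_cutoff must be >= 1")
    median_ci = float(np.median([e.ci_width for e in events]))
    reliable, unreliable = [], []
    for e in events:
        rule1 = (e.x_reads + e.y_reads >= n_cutoff) and e.y_reads >= 1
        rule2 = e.ci_width < median_ci if invert_rule2 else e.ci_width > median_ci
        (reliable if rule1 and rule2 else unreliable).append(e)
    return reliable, unreliable


def _as_points(curve) -> np.ndarray:
    arr = np.asarray(curve, dtype=float)
    if arr.ndim == 1:  # y values paired with their x-index
        arr = np.column_stack([np.arange(arr.size), arr])
    if arr.size == 0:
        raise ValueError("empty curve")
    return arr


def frechet_distance(curve_a, curve_b) -> float:
    """Discrete Frechet distance between two point sequences.

    1-D inputs are treated as y-values at x = 0, 1, 2, ...; distances are
    Euclidean.  Dynamic program over the monotone-coupling lattice.
    """
    a = _as_points(curve_a)
    b = _as_points(curve_b)
    dist = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    n, m = dist.shape
    ca = np.empty((n, m))
    ca[0, 0] = dist[0, 0]
    for j in range(1, m):
        ca[0, j] = max(ca[0, j - 1], dist[0, j])
    for i in range(1, n):
        ca[i, 0] = max(ca[i - 1, 0], dist[i, 0])
        for j in range(1, m):
            ca[i, j] = max(min(ca[i - 1, j], ca[i, j - 1], ca[i - 1, j - 1]), dist[i, j])
    return float(ca[n - 1, m - 1])


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def spse(
    frechet: Mapping[int, float],
    diff_nucpos: Mapping[int, float],
    rse_counts: Mapping[int, float],
    total_counts: Mapping[int, float],
) -> list[SpseResult]:
    """Splicing potentiality per functional state.

    ``SPSE = norm(frdist) * norm(|diff_nucpos|) * coef`` where norm is a
    min-max rescale to [0,1] across the compared states and ``coef`` is the
    min-max-normalized share of the state's nucleosomes found in reliable
    events (rse_count / total_count).
    """
    ids = sorted(frechet)
    if len(ids) < 2:
        raise ValueError("need >= 2 states for min-max normalization")
    if sorted(diff_nucpos) != ids or sorted(rse_counts) != ids or sorted(total_counts) != ids:
        raise ValueError("component mappings must cover the same state ids")
    fr = _minmax(np.array([frechet[i] for i in ids], dtype=float))
    dp = _minmax(np.abs(np.array([diff_nucpos[i] for i in ids], dtype=float)))
    raw_coef = np.array(
        [rse_counts[i] / total_counts[i] if total_counts[i] > 0 else 0.0 for i in ids]
    )
    coef = _minmax(raw_coef)
    return [
        SpseResult(
            nucs_id=i,
            frechet=float(frechet[i]),
            diff_nucpos=float(diff_nucpos[i]),
            coef_event_counts=float(coef[k]),
            spse=float(fr[k] * dp[k] * coef[k]),
        )
        for k, i in enumerate(ids)
    ]


def se_affinity(
    observed: Mapping[int, float], abundance: Mapping[int, float]
) -> dict[int, float]:
    """Observed / predicted SE event counts per state.

    Predicted = total observed events x the state's abundance (the
    random-association null).  Zero abundance with nonzero observed counts
    yields inf (flagged by the caller).
    """
    ids = sorted(observed)
    if sorted(abundance) != ids:
        raise ValueError("observed and abundance must cover the same state ids")
    total_ab = sum(abundance.values())
    if not np.isclose(total_ab, 1.0, atol=1e-6):
        raise ValueError(f"abundances must sum to 1, got {total_ab}")
    total = sum(observed.values())
    out = {}
    for i in ids:
        predicted = total * abundance[i]
        if predicted == 0:
            out[i] = np.inf if observed[i] > 0 else np.nan
        else:
            out[i] = observed[i] / predicted
    return out


def exon_profile(
    dyads_by_state: Mapping[int, Sequence[int]],
    exons: Sequence[tuple[str, int, int, str]] | Sequence,
    dyad_chroms: Mapping[int, Sequence[str]] | None = None,
    flank_bp: int = 1000,
    bin_bp: int = 50,
) -> dict[int, np.ndarray]:
    """Per-state meta-exon nucleosome frequency profile.

    ``exons`` are (chrom, start, end, strand) tuples; dyads are binned by
    their strand-oriented offset from each exon center within
    ``+/- flank_bp`` and each state's histogram is normalized to sum 1.
    ``dyad_chroms`` optionally gives each dyad's chromosome (parallel to
    the dyad lists); without it all coordinates are assumed comparable.
    """
    n_bins = 2 * flank_bp // bin_bp
    out: dict[int, np.ndarray] = {}
    for state, dyads in dyads_by_state.items():
        hist = np.zeros(n_bins)
        dyads = np.asarray(dyads)
        chroms = None if dyad_chroms is None else np.asarray(dyad_chroms[state])
        for exon in exons:
            chrom, start, end, strand = exon[0], int(exon[1]), int(exon[2]), exon[3]
            center = (start + end) // 2
            sel_dyads = dyads if chroms is None else dyads[chroms == chrom]
            offsets = sel_dyads - center
            if strand == "-":
                offsets = -offsets
            offsets = offsets[(offsets >= -flank_bp) & (offsets < flank_bp)]
            if offsets.size:
                hist += np.bincount((offsets + flank_bp) // bin_bp, minlength=n_bins)[:n_bins]
        total = hist.sum()
        out[state] = hist / total if total > 0 else hist
    return out
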
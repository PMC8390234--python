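"""Genomic-region context for decoded states and the functional summary.

The gene-centric window is tiled, 5'->3', as: Distal (-100 kb .. -10 kb),
Proximal (-10 kb .. -1 kb), Promoter (-1 kb .. TSS), Gene-body (TSS..TTS,
measured as percent of gene length), Downstream (TTS .. +10 kb).  Upstream
and downstream regions use 1 kb bins and the gene body 100 percent-length
bins.  Nucleosomes are assigned to bins by dyad, strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm_core import MarkStateMatrix
from .obs_encoding import GeneRecord, NucleosomeRecord

REGION_LABELS = ("Distal", "Proximal", "Promoter", "Gene-body", "Downstream")


@dataclass(frozen=True)
class RegionScheme:
    """Offsets (bp relative to TSS/TTS) delimiting the region tiling."""

    upstream_bp: int = 100_000
    distal_end_bp: int = 10_000  # Distal: [-upstream, -distal_end)
    promoter_bp: int = 1_000  # Proximal: [-distal_end, -promoter); Promoter: [-promoter, 0)
    downstream_bp: int = 10_000
    genebody_bins: int = 100
    flank_bin_bp: int = 1_000

    def __post_init__(self) -> None:
        if not self.upstream_bp > self.distal_end_bp > self.promoter_bp > 0:
            raise ValueError("require upstream > distal_end > promoter > 0")

    @property
    def n_upstream_bins(self) -> int:
        return self.upstream_bp // self.flank_bin_bp

    @property
    def n_downstream_bins(self) -> int:
        return self.downstream_bp // self.flank_bin_bp

    @property
    def n_bins(self) -> int:
        return self.n_upstream_bins + self.genebody_bins + self.n_downstream_bins

    def bin_labels(self) -> list[str]:
        labels = []
        for i in range(self.n_upstream_bins):
            offset = -self.upstream_bp + i * self.flank_bin_bp
            labels.append(f"TSS{offset // 1000}kb")
        labels += [f"GB{p}%" for p in range(self.genebody_bins)]
        labels += [f"TTS+{i}kb" for i in range(self.n_downstream_bins)]
        return labels

    def region_of_bin(self, b: int) -> str:
        nu = self.n_upstream_bins
        if b < nu:
            offset = -self.upstream_bp + b * self.flank_bin_bp
            if offset < -self.distal_end_bp:
                return "Distal"
            if offset < -self.promoter_bp:
                return "Proximal"
            return "Promoter"
        if b < nu + self.genebody_bins:
            return "Gene-body"
        return "Downstream"


def _gene_bin(
    dyad: int, gene: GeneRecord, scheme: RegionScheme
) -> int | None:
    """Bin index of a dyad inside this gene's window, or None."""
    if gene.strand == "+":
        rel = dyad - gene.tss
        gene_len = gene.tts - gene.tss
    else:
        rel = gene.tss - dyad
        gene_len = gene.tss - gene.tts
    if rel < -scheme.upstream_bp:
        return None
    if rel < 0:
        return (rel + scheme.upstream_bp) // scheme.flank_bin_bp
    if rel < gene_len:
        pct = int(rel * scheme.genebody_bins // gene_len)
        return scheme.n_upstream_bins + min(pct, scheme.genebody_bins - 1)
    rel_tts = rel - gene_len
    if rel_tts < scheme.downstream_bp:
        return (
            scheme.n_upstream_bins
            + scheme.genebody_bins
            + rel_tts // scheme.flank_bin_bp
        )
    return None


def region_profile(
    nucleosomes: Sequence[NucleosomeRecord],
    states: Sequence[int],
    genes: Sequence[GeneRecord],
    scheme: RegionScheme = RegionScheme(),
) -> pd.DataFrame:
    """Per-state binned frequency profile across the gene-centric window.

    Rows are states, columns region bins; each row is normalized to sum 1.
    Genes shorter than one gene-body bin are skipped with a warning.
    """
    if len(nucleosomes) != len(states):
        raise ValueError("nucleosomes and states must be parallel")
    usable = []
    for gene in genes:
        if abs(gene.tts - gene.tss) < scheme.genebody_bins:
            warnings.warn(f"gene {gene.gene_id} shorter than one bin; skipped")
            continue
        usable.append(gene)

    state_ids = sorted(set(int(s) for s in states))
    counts = np.zeros((len(state_ids), scheme.n_bins))
    row_of = {s: i for i, s in enumerate(state_ids)}
    by_chrom: dict[str, list[GeneRecord]] = {}
    for gene in usable:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for nuc, state in zip(nucleosomes, states):
        for gene in by_chrom.get(nuc.chrom, ()):
            b = _gene_bin(nuc.dyad, gene, scheme)
            if b is not None:
                counts[row_of[int(state)], int(b)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        profile = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(profile, index=state_ids, columns=scheme.bin_labels())


def dominant_region(
    profiles: pd.DataFrame, scheme: RegionScheme = RegionScheme()
) -> dict[int, str]:
    """Most enriched region per state.

    Enrichment = state's mass fraction in the region divided by the
    all-state mass fraction there; exact ties join labels with '/'.
    """
    bin_regions = np.array([scheme.region_of_bin(b) for b in range(len(profiles.columns))])
    state_region = pd.DataFrame(
        {r: profiles.loc[:, bin_regions == r].sum(axis=1) for r in REGION_LABELS}
    )
    background = state_region.sum(axis=0)
    background = background / background.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = state_region.div(background, axis=1).fillna(0.0)
    result = {}
    for state, row in ratio.iterrows():
        best = row.max()
        winners = [r for r in REGION_LABELS if np.isclose(row[r], best)]
        result[int(state)] = "/".join(winners)
    return result


def mark_call(
    mark_state: MarkStateMatrix, threshold: float = 0.5
) -> dict[int, tuple[str, ...]]:
    """Marks whose marginal probability is >= threshold, per state."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    n_marks = mark_state.probs.shape[1]
    names = mark_state.mark_order or tuple(f"mark{i}" for i in range(n_marks))
    return {
        state: tuple(names[m] for m in range(n_marks) if mark_state.probs[state, m] >= threshold)
        for state in range(mark_state.probs.shape[0])
    }


def build_summary(
    mark_sets: Mapping[int, Sequence[str]],
    org_table: pd.DataFrame,
    dominant_regions: Mapping[int, str],
    label_map: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Join per-state annotations into the functional-state summary table.

    ``org_table`` must be indexed by state with columns ave_no, spacing,
    positioning, phasing.  States with no called marks get the label
    'unlabeled'.  Missing metrics become NaN with a warning.
    """
    states = sorted(mark_sets)
    rows = []
    for state in states:
        marks = tuple(mark_sets[state])
        if label_map and state in label_map:
            label = label_map[state]
        elif not marks:
            label = "unlabeled"
        else:
            label = f"NucS{state}"
        row = {
            "state": state,
            "label": label,
            "marks": "/".join(marks) if marks else "",
            "region": dominant_regions.get(state, ""),
        }
        for col in ("ave_no", "spacing", "positioning", "phasing"):
            if state in org_table.index and col in org_table.columns:
                row[col] = org_table.loc[state, col]
            else:
                warnings.warn(f"state {state}: missing metric {col}")
                row[col] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("state")
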
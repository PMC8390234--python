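"""Run configuration: a single YAML document validated on load.

The configuration (including the mark ordering that fixes bit indices) is
hashed and the hash written into every bespoke output header so runs are
traceable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .obs_encoding import DEFAULT_MARK_ORDER


@dataclass
class RunConfig:
    mark_order: tuple[str, ...] = DEFAULT_MARK_ORDER
    min_overlap_frac: float = 0.5
    upstream_bp: int = 100_000
    downstream_bp: int = 10_000
    fragment_min_bp: int = 130
    fragment_max_bp: int = 180
    state_min: int = 15
    state_max: int = 25
    replicates: int = 5
    first_iters: int = 300
    second_iters: int = 200
    tol: float = 1e-4
    prune_cutoff: float = 0.005
    array_max_gap_bp: int = 350
    welch_frame_len: int = 512
    welch_hop: int | None = None
    band_low_hz: float = 4.0
    band_high_hz: float = 10.0
    spacing_coef_range: float = 1.0
    quantile_low: float = 0.05
    quantile_high: float = 0.95
    mark_threshold: float = 0.5
    se_n_cutoff: int | None = None
    se_invert_rule2: bool = False
    seed: int = 0
    chrom_naming: str = "chr"  # "chr" or "plain"

    def __post_init__(self) -> None:
        self.mark_order = tuple(self.mark_order)
        if len(set(self.mark_order)) != len(self.mark_order):
            raise ValueError("mark_order has duplicate entries")
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must be in (0, 1]")
        if self.state_min > self.state_max:
            raise ValueError("state_min must be <= state_max")
        if not 0 <= self.quantile_low < self.quantile_high <= 1:
            raise ValueError("bad quantile cutoffs")
        if self.band_low_hz >= self.band_high_hz:
            raise ValueError("band_low_hz must be < band_high_hz")

    @property
    def n_marks(self) -> int:
        return len(self.mark_order)

    @property
    def n_symbols(self) -> int:
        return 1 << self.n_marks

    @property
    def state_range(self) -> range:
        return range(self.state_min, self.state_max + 1)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def normalize_chrom(self, chrom: str) -> str:
        """Map chromosome names to the configured convention."""
        bare = chrom[3:] if chrom.startswith("chr") else chrom
        return f"chr{bare}" if self.chrom_naming == "chr" else bare
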
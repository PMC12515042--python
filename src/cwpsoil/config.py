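"""Run configuration for the pipeline.

All defaults reproduce the published analysis settings: per-kingdom
rarefaction depths of 12000/8000/5000/250 reads, a core community defined
as the top 10% of phylotypes by mean relative abundance present in at least
four crop wild progenitor (CWP) species, co-presence edges at P < .05,
walktrap with 4-step random walks, K-means over k = 2..10 scored by the
Calinski-Harabasz index on the first 5 weighted PCA axes, a VIF screen at 5,
1000 bootstrap replicates, and chained predictive-mean-matching imputation
with 999 cycles and 5 donors.  An empty config file therefore reproduces
the reference settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import yaml

KINGDOMS = ("bacteria", "fungi", "protists", "invertebrates")

DEFAULT_RAREFACTION_DEPTHS = {
    "bacteria": 12000,
    "fungi": 8000,
    "protists": 5000,
    "invertebrates": 250,
}


@dataclasses.dataclass
class RunConfig:
    """Validated bundle of every tunable constant used by the pipeline."""

    seed: int = 0
    rarefaction_depths: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RAREFACTION_DEPTHS)
    )
    core_top_fraction: float = 0.10
    core_min_cwps: int = 4
    edge_alpha: float = 0.05
    walktrap_steps: int = 4
    kmeans_k_range: tuple[int, int] = (2, 10)
    kmeans_n_starts: int = 25
    n_pca_axes: int = 5
    vif_threshold: float = 5.0
    n_bootstrap: int = 1000
    imputation_cycles: int = 999
    imputation_donors: int = 5
    main_module_min_size: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.core_top_fraction <= 1:
            raise ValueError(
                f"core_top_fraction must be in (0, 1], got {self.core_top_fraction}"
            )
        if not 0 < self.edge_alpha < 1:
            raise ValueError(f"edge_alpha must be in (0, 1), got {self.edge_alpha}")
        for name in (
            "core_min_cwps",
            "walktrap_steps",
            "n_pca_axes",
            "n_bootstrap",
            "imputation_cycles",
            "imputation_donors",
            "kmeans_n_starts",
            "main_module_min_size",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.vif_threshold <= 0:
            raise ValueError(f"vif_threshold must be positive, got {self.vif_threshold}")
        self.rarefaction_depths = dict(self.rarefaction_depths)
        for kingdom, depth in self.rarefaction_depths.items():
            if depth <= 0:
                raise ValueError(
                    f"rarefaction depth for {kingdom} must be positive, got {depth}"
                )
        lo, hi = self.kmeans_k_range = tuple(self.kmeans_k_range)  # type: ignore[assignment]
        if lo < 2 or hi < lo:
            raise ValueError(
                f"kmeans_k_range must be an interval with lower bound >= 2, got {self.kmeans_k_range}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key/value YAML file; absent keys keep their defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "kmeans_k_range" in raw:
            raw["kmeans_k_range"] = tuple(raw["kmeans_k_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kmeans_k_range"] = list(self.kmeans_k_range)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, logged with every run."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str, kingdom: str | None = None) -> int:
        """Deterministically split the root seed per stage (and kingdom).

        Every source of randomness in the pipeline draws from one of these
        derived seeds, so stages can be re-run in isolation and still match
        a full-pipeline run bit for bit.
        """
        label = f"{self.seed}:{stage}" + (f":{kingdom}" if kingdom else "")
        digest = hashlib.sha256(label.encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)
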
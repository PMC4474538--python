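"""Analysis configuration: one flat record of every tunable parameter."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Every knob of the stratification pipeline, with field defaults
    matching the published protocol: propagation retention a=0.7 converged
    to 1e-3, top 10% of network edges, k=11 nearest neighbors, lambda=200,
    objective tolerance 0.1, K in {3,4,5,6}, 500 replicates at 80%
    subsampling."""

    alpha: float = 0.7
    propagation_tol: float = 1e-3
    propagation_max_iter: int = 1000
    top_fraction: float = 0.10
    normalization: str = "symmetric-degree"  # none | symmetric-degree | row-stochastic
    knn_k: int = 11
    knn_binary: bool = True
    knn_from_thresholded: bool = True
    lam: float = 200.0
    nmf_tol: float = 0.1
    nmf_max_iter: int = 2000
    K_list: list[int] = field(default_factory=lambda: [3, 4, 5, 6])
    n_reps: int = 500
    subsample: float = 0.8
    seed: int = 0
    min_full_mutations: int = 6
    min_panel_mutations: int = 1

    def __post_init__(self) -> None:
        if not self.K_list:
            raise ValueError("K_list must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load from a flat or dotted-key YAML mapping; keyword overrides
        (e.g. CLI flags) win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        flat: dict = {}
        alias = {
            "network.top_fraction": "top_fraction",
            "network.normalization": "normalization",
            "network.knn_k": "knn_k",
            "network.knn_binary": "knn_binary",
            "propagation.alpha": "alpha",
            "propagation.tol": "propagation_tol",
            "nmf.lam": "lam",
            "nmf.tol": "nmf_tol",
            "consensus.n_reps": "n_reps",
            "consensus.subsample": "subsample",
            "consensus.seed": "seed",
        }
        for key, value in data.items():
            flat[alias.get(key, key)] = value
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def digest(self) -> str:
        """Stable short hash for provenance records."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
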
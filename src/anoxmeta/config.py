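"""Pipeline configuration: every tunable threshold in one round-trippable
YAML-backed object."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .data import PRESENCE_POLICIES, ValidationError


@dataclass
class PipelineConfig:
    """All thresholds and tuning constants of the analysis chain.

    Defaults are the conventional ones: detection alpha 0.05; the
    three-part DE rule (>2-fold, p < 0.05, PPDE > 0.96); enrichment
    |z| > 1.96; markers >50-fold in >=2 (species A, with abiotic
    exclusion) or >=3 (species B) comparisons; species-specific quorums
    3-of-4 and 4-of-5.
    """

    detection_alpha: float = 0.05
    presence_policy: str = "all_reps_of_any_condition"
    cybert_window: int = 101
    cybert_v0: float = 10.0
    fold: float = 2.0
    p: float = 0.05
    ppde: float = 0.96
    z_threshold: float = 1.96
    bonferroni: bool = False
    marker_fold: float = 50.0
    marker_k_a: int = 2
    marker_k_b: int = 3
    exclude_abiotic_up_a: bool = True
    exclude_abiotic_up_b: bool = False
    consensus_k_a: int = 3
    consensus_k_b: int = 4
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        checks = [
            (0 < self.detection_alpha < 1, "detection_alpha in (0,1)"),
            (self.presence_policy in PRESENCE_POLICIES,
             f"presence_policy one of {PRESENCE_POLICIES}"),
            (self.cybert_window >= 1 and self.cybert_window % 2 == 1,
             "cybert_window odd and >= 1"),
            (self.cybert_v0 >= 0, "cybert_v0 >= 0"),
            (self.fold >= 1, "fold >= 1"),
            (0 < self.p <= 1, "p in (0,1]"),
            (0 <= self.ppde <= 1, "ppde in [0,1]"),
            (self.z_threshold > 0, "z_threshold > 0"),
            (self.marker_fold > 1, "marker_fold > 1"),
            (self.marker_k_a >= 1 and self.marker_k_b >= 1, "marker quorums >= 1"),
            (self.consensus_k_a >= 1 and self.consensus_k_b >= 1, "consensus quorums >= 1"),
            (self.seed >= 0, "seed >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(f"config constraint violated: {msg}")

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(
                f"unknown config key(s): {sorted(unknown)}; allowed: {sorted(known)}"
            )
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file '{path}' must hold a key/value mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
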
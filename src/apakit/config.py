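"""Pipeline configuration: thresholds, signal catalogues, and defaults.

All genomic coordinates inside the package are 0-based half-open; GTF I/O is
1-based inclusive. Offsets around a cleavage locus are expressed in transcript
orientation with the locus base at offset 0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Canonical polyadenylation-signal hexamers searched in the [-30, -10] window
#: upstream of a cleavage locus, in priority order (most common first).
DEFAULT_HEXAMERS: tuple[str, ...] = (
    "AATAAA", "ATTAAA", "TATAAA", "AGTAAA", "AATACA", "CATAAA",
    "AATATA", "GATAAA", "AATGAA", "AATAAT", "AAGAAA", "ACTAAA",
    "AATAGA", "ATTACA", "AACAAA", "ATTATA", "AACAAG", "AATAAG",
)


@dataclass
class AtlasConfig:
    """Thresholds for atlas construction (cleavage extraction through spacing)."""

    protocol: str = "rev"                    # 'rev': read antisense to transcript
    hexamer_window: tuple[int, int] = (-30, -10)  # hexamer start offsets, inclusive
    hexamers: tuple[str, ...] = DEFAULT_HEXAMERS
    priming_window: tuple[int, int] = (-10, 10)   # internal-priming scan, inclusive
    max_a_run: int = 6                       # remove if a run of > max_a_run As
    max_sparse_a: int = 8                    # remove if >max_sparse_a As per 10 nt
    cluster_radius: int = 5                  # nt absorbed around a dominant locus
    min_spacing: int = 125                   # nt between accepted representatives
    hexamer_stage: str = "cluster"           # 'cluster' or 'event'

    def validate(self) -> None:
        if self.protocol not in ("rev", "fwd"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for h in self.hexamers:
            if len(h) != 6:
                raise ValueError(f"hexamer {h!r} is not 6 nt")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if self.cluster_radius < 0:
            raise ValueError("cluster_radius must be >= 0")


@dataclass
class QuantConfig:
    """Thresholds for abundance filtering, switch testing and correlations."""

    min_presence: float = 0.25       # site nonzero in >= this fraction of samples
    min_group_count: int = 10        # summed count needed in tumor AND in normal
    min_minor_fraction: float = 0.05  # pooled count vs the gene's major site
    fdr: float = 0.05
    min_pairs: int = 10              # complete tumor/normal pairs per tested gene
    min_shared_samples: int = 10
    rho_threshold: float = 0.1
    rho_two_sided: bool = False      # count genes with Rho > t (False) or |Rho| > t
    n_permutations: int = 10_000


@dataclass
class AnnotationConfig:
    extension_bp: int = 5_000        # downstream extension past the annotated end
    min_gap_for_full: int = 10_000   # closer neighbours split the gap in half
    same_strand_neighbors: bool = False


@dataclass
class SurvivalConfig:
    cv_folds: int = 5
    min_samples: int = 40
    max_missing_rate: float = 0.2
    risk_orientation: str = "source"  # 'source': PI > median -> low-risk
    penalty_grid_size: int = 30


@dataclass
class PipelineConfig:
    """Aggregate configuration echoed into every run directory."""

    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def echo(self, path: str | Path) -> None:
        """Write the effective configuration as YAML (lists for tuples)."""
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section in ("atlas", "quant", "annotation", "survival"):
            sub = raw.get(section, {})
            target = getattr(cfg, section)
            for key, value in sub.items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown config key {section}.{key}")
                current = getattr(target, key)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(target, key, value)
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        cfg.atlas.validate()
        return cfg


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
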
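"""Analysis configuration.

All distance parameters are in Å, densities in kg/L. The defaults are the
working values of the pH-series hydration analysis this package implements:
waters are clustered across conditions at 1.0 Å, residues are considered
water-binding within 3.6 Å, hydration shells extend 5 Å from the protein,
trajectory water density is accumulated on a 0.5 Å grid and thresholded at
6 kg/L, and λ samples below 0.2 / above 0.8 count as protonated /
deprotonated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    #: single-linkage cutoff for cross-condition water clustering, Å
    cluster_cutoff: float = 1.0
    #: water–residue contact cutoff (nearest-residue assignment, bound-water
    #: counting, residence shells), Å
    residue_cutoff: float = 3.6
    #: hydration-shell extent around the protein, Å
    shell_cutoff: float = 5.0
    #: voxel edge of the trajectory water-density grid, Å
    grid_spacing: float = 0.5
    #: smoothed-density threshold for counting a hydration site, kg/L
    density_threshold: float = 6.0
    #: density peaks closer than this are merged into one site, Å
    merge_distance: float = 1.0
    #: λ below this counts as protonated
    lambda_low: float = 0.2
    #: λ above this counts as deprotonated
    lambda_high: float = 0.8
    #: distance tolerance for detecting symmetry-equivalent solvent ties, Å
    symmetry_tolerance: float = 1e-3
    #: density-smoothing neighbourhood: 6 (face-adjacent) or 18 (+edges)
    smoothing_neighbors: int = 6
    #: hydration-site position from merged peaks: "density"-weighted or "uniform"
    site_position_weighting: str = "density"
    #: use the literal printed deprotonation-fraction convention
    #: (n_prot in the numerator) instead of the default n_deprot numerator
    literal_deprotonation: bool = False
    #: ion–water hydrogen-bond distance flag, Å
    hbond_distance: float = 3.5
    #: solvent probe radius for accessible surface area, Å
    asa_probe: float = 1.4
    #: sphere sample points per atom for accessible surface area
    asa_points: int = 960

    def __post_init__(self) -> None:
        for name in ("cluster_cutoff", "residue_cutoff", "shell_cutoff",
                     "grid_spacing", "density_threshold", "merge_distance",
                     "symmetry_tolerance", "hbond_distance", "asa_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.lambda_low < self.lambda_high:
            raise ValueError("lambda_low must be < lambda_high")
        if self.smoothing_neighbors not in (6, 18):
            raise ValueError("smoothing_neighbors must be 6 or 18")
        if self.site_position_weighting not in ("density", "uniform"):
            raise ValueError("site_position_weighting must be 'density' or 'uniform'")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a configuration from a YAML mapping of field names to values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))
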
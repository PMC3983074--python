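"""Parameter tables and the scoring configuration.

All numeric constants of the empirical scoring function (term weights, vdW
well parameters, polar ramps, desolvation class weights, torsional barriers,
SASA overlap parameters, interaction-typing rules) live in
``data/params.yaml``.  The shipped values are this package's own calibration
for the toy systems in :mod:`gadock.fixtures`; they are documented defaults,
not a reproduction of any other program's parameter set.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

__all__ = ["load_param_table", "ScoringConfig", "vdw_radius"]


@functools.lru_cache(maxsize=1)
def load_param_table() -> dict:
    with resources.files("gadock.data").joinpath("params.yaml").open() as fh:
        return yaml.safe_load(fh)


def vdw_radius(element: str) -> float:
    """Bondi-style van der Waals radius in Angstrom (used for sterics/SASA)."""
    table = load_param_table()["vdw_radii"]
    return float(table.get(element, table["default"]))


@dataclass
class ScoringConfig:
    """Weights and switches of the composite scoring function.

    ``vdw_form``, ``polar_tolerance_scale`` and ``dihedral_weight_scale`` are
    the three knobs the staged search schedule varies between GA stages; all
    are at their final values (6-12 / 1.0 / 1.0) for MC and minimisation.
    """

    weights: dict = field(default_factory=lambda: dict(
        load_param_table()["term_weights"]))
    vdw_form: str = "6-12"                 # "4-8" during early GA stages
    polar_mode: str = "attractive+repulsive"  # SF3; "attractive-only" drops repulsion
    use_desolvation: bool = False          # SF5 switches this on
    polar_distance_tolerance: float = 0.6  # Angstrom, base ramp width
    polar_angle_tolerance: float = 30.0    # degrees, base ramp width
    polar_tolerance_scale: float = 1.0     # >=1, relaxed in GA1/GA2
    dihedral_weight_scale: float = 1.0     # in [0,1], reduced in GA1/GA2
    vdw_cap: float = 100.0                 # short-range cap, score units
    scale_14: float = 0.5                  # 1-4 intra-ligand vdW scaling

    def validate(self):
        for k, v in self.weights.items():
            if not (v == v and abs(v) < 1e12):
                raise ValueError(f"non-finite weight {k}")
        if self.vdw_form not in ("4-8", "6-12"):
            raise ValueError(f"unknown vdw form {self.vdw_form!r}")
        return self

    @classmethod
    def sf3(cls) -> "ScoringConfig":
        """Default scoring function: repulsive polar term, no desolvation."""
        return cls()

    @classmethod
    def sf5(cls) -> "ScoringConfig":
        """Solvation scoring function: desolvation on, repulsive polar off."""
        return cls(polar_mode="attractive-only", use_desolvation=True)

    def for_stage(self, vdw_form: str, polar_tolerance_scale: float,
                  dihedral_weight_scale: float) -> "ScoringConfig":
        return replace(self, vdw_form=vdw_form,
                       polar_tolerance_scale=polar_tolerance_scale,
                       dihedral_weight_scale=dihedral_weight_scale)
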
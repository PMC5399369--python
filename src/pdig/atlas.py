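"""The 8-region cortico-basal ganglia-thalamocortical (CBGT) atlas.

The network nodes are the eight regions classically implicated in
Parkinson's disease motor circuitry: three cortical territories
(sensorimotor/motor, associative, limbic) and five subcortical structures
(caudate, putamen, pallidum, thalamus, substantia nigra).  Each region
carries a surface area S_i (mm^2) used to normalize fiber-density edge
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CBGT_REGIONS: tuple[str, ...] = (
    "caudate",
    "putamen",
    "pallidum",
    "thalamus",
    "motor_cortex",
    "associative_cortex",
    "limbic_cortex",
    "substantia_nigra",
)

# Plausible per-hemisphere-pair surface areas (mm^2).  Cortical territories
# are orders of magnitude larger than deep nuclei; the absolute values only
# rescale edge weights, they never change group contrasts.
_DEFAULT_AREAS: dict[str, float] = {
    "caudate": 1200.0,
    "putamen": 1600.0,
    "pallidum": 700.0,
    "thalamus": 2200.0,
    "motor_cortex": 9500.0,
    "associative_cortex": 16000.0,
    "limbic_cortex": 7000.0,
    "substantia_nigra": 350.0,
}


@dataclass(frozen=True)
class RoiAtlas:
    """Named regions with surface areas, fixed to exactly 8 nodes.

    Parameters
    ----------
    surface_areas
        Mapping region name -> surface area in mm^2 (all positive).
    """

    surface_areas: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AREAS)
    )

    def __post_init__(self) -> None:
        if len(self.surface_areas) != 8:
            raise ValueError(
                f"atlas must define exactly 8 regions, got {len(self.surface_areas)}"
            )
        if len(set(self.surface_areas)) != len(self.surface_areas):
            raise ValueError("region names must be unique")
        for name, area in self.surface_areas.items():
            if not area > 0:
                raise ValueError(f"surface area of {name!r} must be > 0, got {area}")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.surface_areas)

    def area(self, region: str) -> float:
        try:
            return self.surface_areas[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}; atlas has {self.regions}")

    def index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}; atlas has {self.regions}")


DEFAULT_ATLAS = RoiAtlas()
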
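"""Band edges and rule tables for the three scoring systems.

The numeric content lives in ``score_rules.yaml`` next to this module so the
conventions (band closures, the 950 HU boundary, Guy's precedence order) are
visible and overridable without touching code.  :func:`load_rules` parses that
file into a frozen :class:`ScoreRules`; the module-level :data:`DEFAULT_RULES`
is what every scoring function uses unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import yaml

__all__ = ["ScoreRules", "ShalinRules", "StoneRules", "GuysRules", "load_rules", "DEFAULT_RULES"]


@dataclass(frozen=True)
class ShalinRules:
    size_band_edges_mm2: tuple[float, ...]
    hydronephrosis_points: Mapping[str, int]
    anatomy_points: Mapping[str, int]
    tract_cutoff_mm: float
    hu_cutoff: float
    calyx_threshold: int
    strata: Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class StoneRules:
    size_band_edges_mm2: tuple[float, ...]
    tract_cutoff_mm: float
    obstruction_points: Mapping[str, int]
    calyx_threshold: int
    staghorn_points: int
    density_cutoff: float
    strata: Mapping[str, tuple[int, int]]


@dataclass(frozen=True)
class GuysRules:
    #: ordered (grade, predicate-names) pairs; first match wins
    precedence: tuple[tuple[str, tuple[str, ...]], ...]


@dataclass(frozen=True)
class ScoreRules:
    area_formula: str  # "rectangle" | "ellipse"
    shalin: ShalinRules
    stone: StoneRules
    guys: GuysRules

    def __post_init__(self) -> None:
        if self.area_formula not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown area_formula {self.area_formula!r}")


def _strata(raw: Mapping[str, Sequence[int]]) -> dict[str, tuple[int, int]]:
    return {label: (int(lo), int(hi)) for label, (lo, hi) in raw.items()}


def load_rules(text: str | None = None) -> ScoreRules:
    """Parse a rules document (the packaged one by default) into ScoreRules."""
    if text is None:
        text = resources.files("nephroscore").joinpath("score_rules.yaml").read_text()
    raw = yaml.safe_load(text)
    sh = raw["shalin"]
    st = raw["stone"]
    return ScoreRules(
        area_formula=raw["area_formula"],
        shalin=ShalinRules(
            size_band_edges_mm2=tuple(float(x) for x in sh["size_band_edges_mm2"]),
            hydronephrosis_points=dict(sh["hydronephrosis_points"]),
            anatomy_points=dict(sh["anatomy_points"]),
            tract_cutoff_mm=float(sh["tract_cutoff_mm"]),
            hu_cutoff=float(sh["hu_cutoff"]),
            calyx_threshold=int(sh["calyx_threshold"]),
            strata=_strata(sh["strata"]),
        ),
        stone=StoneRules(
            size_band_edges_mm2=tuple(float(x) for x in st["size_band_edges_mm2"]),
            tract_cutoff_mm=float(st["tract_cutoff_mm"]),
            obstruction_points=dict(st["obstruction_points"]),
            calyx_threshold=int(st["calyx_threshold"]),
            staghorn_points=int(st["staghorn_points"]),
            density_cutoff=float(st["density_cutoff"]),
            strata=_strata(st["strata"]),
        ),
        guys=GuysRules(
            precedence=tuple(
                (rule["grade"], tuple(rule["any"])) for rule in raw["guys"]["precedence"]
            ),
        ),
    )


DEFAULT_RULES: ScoreRules = load_rules()
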
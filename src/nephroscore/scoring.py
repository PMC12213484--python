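"""Nephrolithometry scoring: SHA.LIN, S.T.O.N.E. and Guy's stone grade.

All three scores summarise the complexity of a renal stone case from
preoperative non-contrast CT ahead of percutaneous nephrolithotomy (PCNL):

* **SHA.LIN** — six additive components: total **S**tone burden (summed
  cross-sectional area over all stones, mm²), **H**ydronephrosis grade,
  **A**natomical distribution within the collecting system, **L**ength of the
  percutaneous tract (skin to stone centre), the CT density **I**ndicator
  (mean Hounsfield units over five sampled points) and **N**umber of involved
  calyces.  Totals span 6–17; higher means a more complex case.
* **S.T.O.N.E.** — five additive components (size of the *largest* stone,
  tract length, obstruction, number of calyces / staghorn, stone density),
  totals 5–13.
* **Guy's grade** — an ordinal I–IV classification by stone distribution and
  renal anatomy, assigned by precedence rules rather than addition.

Every band edge and rule table is taken from :mod:`nephroscore.rules`
(backed by ``score_rules.yaml``) so the conventions are auditable; each
function accepts an alternative :class:`~nephroscore.rules.ScoreRules`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .rules import DEFAULT_RULES, ScoreRules

__all__ = [
    "Hydronephrosis",
    "AnatomicClass",
    "GuysGrade",
    "StoneProfile",
    "ShalinComponents",
    "StoneComponents",
    "ScorePanel",
    "stone_burden_total",
    "largest_stone_area",
    "mean_ct_hu",
    "shalin_components",
    "shalin_total",
    "shalin_stratum",
    "stone_nephrolithometry",
    "stone_stratum",
    "guys_grade",
    "score_panel",
    "enumerate_shalin_totals",
    "enumerate_stone_totals",
]


class Hydronephrosis(str, enum.Enum):
    """Collecting-system dilatation, pre-graded on CT (3-level ordinal)."""

    NONE_OR_MILD = "none_or_mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class AnatomicClass(str, enum.Enum):
    """Distribution of the stone(s) within the pelvicalyceal system."""

    PELVIS_OR_MID_LOWER_CALYX = "pelvis_or_mid_lower_calyx"
    UPPER_CALYX = "upper_calyx"
    DIVERTICULUM_OR_PARTIAL_STAGHORN = "diverticulum_or_partial_staghorn"
    COMPLETE_STAGHORN = "complete_staghorn"


class GuysGrade(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class ShalinComponents(NamedTuple):
    s: int  # stone burden band, 1-4
    h: int  # hydronephrosis, 1-3
    a: int  # anatomical distribution, 1-4
    l: int  # tract length, 1-2
    i: int  # CT density indicator, 1-2
    n: int  # involved calyces, 1-2


class StoneComponents(NamedTuple):
    s: int  # largest-stone size band, 1-4
    t: int  # tract length, 1-2
    o: int  # obstruction, 1-2
    n: int  # calyces / staghorn, 1-3
    e: int  # density ("essence"), 1-2


@dataclass(frozen=True)
class StoneProfile:
    """CT-derived stone features for one patient (the raw scoring inputs).

    Parameters
    ----------
    stones
        ``(length_mm, width_mm)`` per stone; normalised on construction so
        that width <= length.  Must be non-empty with positive dimensions.
    hydronephrosis, anatomic_class
        Pre-graded ordinal/categorical CT readings.
    tract_length_mm
        Skin-to-stone-centre distance, mm.
    hu_points
        Exactly five Hounsfield-unit measurements (one central + four
        surrounding points on the largest stone cross-section).
    involved_calyces
        Number of calyces containing stones (0 for a purely pelvic stone).
    abnormal_anatomy, neuro_condition
        Guy's-grade inputs: abnormal collecting system (e.g. horseshoe
        kidney) and neurological condition (spina bifida / spinal injury).
    """

    stones: tuple[tuple[float, float], ...]
    hydronephrosis: Hydronephrosis
    anatomic_class: AnatomicClass
    tract_length_mm: float
    hu_points: tuple[float, float, float, float, float]
    involved_calyces: int
    abnormal_anatomy: bool = False
    neuro_condition: bool = False

    def __post_init__(self) -> None:
        stones = tuple(
            (float(max(a, b)), float(min(a, b))) for a, b in self.stones
        )
        if not stones:
            raise ValueError("StoneProfile requires at least one stone")
        for length, width in stones:
            if not (length > 0 and width > 0):
                raise ValueError("stone dimensions must be strictly positive")
        object.__setattr__(self, "stones", stones)
        object.__setattr__(self, "hydronephrosis", Hydronephrosis(self.hydronephrosis))
        object.__setattr__(self, "anatomic_class", AnatomicClass(self.anatomic_class))
        if not self.tract_length_mm > 0:
            raise ValueError("tract_length_mm must be positive")
        hu = tuple(float(x) for x in self.hu_points)
        if len(hu) != 5:
            raise ValueError(f"hu_points must have exactly 5 entries, got {len(hu)}")
        object.__setattr__(self, "hu_points", hu)
        if int(self.involved_calyces) != self.involved_calyces or self.involved_calyces < 0:
            raise ValueError("involved_calyces must be a non-negative integer")
        object.__setattr__(self, "involved_calyces", int(self.involved_calyces))


@dataclass(frozen=True)
class ScorePanel:
    """The three scores for one profile, with components and risk strata."""

    shalin_components: ShalinComponents
    shalin_total: int
    shalin_stratum: str
    stone_components: StoneComponents
    stone_total: int
    stone_stratum: str
    guys_grade: GuysGrade


def _stone_area(length_mm: float, width_mm: float, area_formula: str) -> float:
    area = length_mm * width_mm
    if area_formula == "ellipse":
        area *= math.pi / 4.0
    return area


def stone_burden_total(
    stones: Iterable[tuple[float, float]], *, rules: ScoreRules = DEFAULT_RULES
) -> float:
    """Summed cross-sectional area over all stones, mm² (the SHA.LIN burden).

    Each stone contributes ``length × width`` (or ``π/4·length·width`` when
    ``rules.area_formula == "ellipse"``); the total is the plain sum.
    """
    stones = list(stones)
    if not stones:
        raise ValueError("stone list must be non-empty")
    for length, width in stones:
        if not (length > 0 and width > 0):
            raise ValueError("stone dimensions must be strictly positive")
    return float(sum(_stone_area(l, w, rules.area_formula) for l, w in stones))


def largest_stone_area(
    stones: Iterable[tuple[float, float]], *, rules: ScoreRules = DEFAULT_RULES
) -> float:
    """Cross-sectional area of the single largest stone (S.T.O.N.E. burden)."""
    stones = list(stones)
    if not stones:
        raise ValueError("stone list must be non-empty")
    return float(max(_stone_area(l, w, rules.area_formula) for l, w in stones))


def mean_ct_hu(hu_points: Sequence[float]) -> float:
    """Mean of the five HU point measurements (stone density indicator)."""
    if len(hu_points) != 5:
        raise ValueError(f"expected exactly 5 HU points, got {len(hu_points)}")
    return float(sum(hu_points)) / 5.0


def _size_points(area_mm2: float, edges: Sequence[float]) -> int:
    # edges (400, 800, 1600): area < 400 -> 1, ..., >= 1600 -> 4
    return 1 + sum(area_mm2 >= e for e in edges)


def shalin_components(
    profile: StoneProfile, *, rules: ScoreRules = DEFAULT_RULES
) -> ShalinComponents:
    """Look up the six SHA.LIN component points for a profile."""
    r = rules.shalin
    return ShalinComponents(
        s=_size_points(stone_burden_total(profile.stones, rules=rules), r.size_band_edges_mm2),
        h=r.hydronephrosis_points[profile.hydronephrosis.value],
        a=r.anatomy_points[profile.anatomic_class.value],
        l=1 if profile.tract_length_mm <= r.tract_cutoff_mm else 2,
        i=1 if mean_ct_hu(profile.hu_points) <= r.hu_cutoff else 2,
        n=1 if profile.involved_calyces < r.calyx_threshold else 2,
    )


def shalin_total(profile: StoneProfile, *, rules: ScoreRules = DEFAULT_RULES) -> int:
    """SHA.LIN total: the sum of the six component points (range 6–17)."""
    return int(sum(shalin_components(profile, rules=rules)))


def _stratum(total: int, strata: dict[str, tuple[int, int]], what: str) -> str:
    for label, (lo, hi) in strata.items():
        if lo <= total <= hi:
            return label
    raise ValueError(f"{what} total {total} is outside the attainable range")


def shalin_stratum(total: int, *, rules: ScoreRules = DEFAULT_RULES) -> str:
    """Risk stratum label ("6-8", "9-11", "12-14", "15-17") for a total."""
    return _stratum(int(total), rules.shalin.strata, "SHA.LIN")


def stone_stratum(total: int, *, rules: ScoreRules = DEFAULT_RULES) -> str:
    """S.T.O.N.E. risk stratum label ("5-6", "7-8", "9-13")."""
    return _stratum(int(total), rules.stone.strata, "S.T.O.N.E.")


def stone_nephrolithometry(
    profile: StoneProfile, *, rules: ScoreRules = DEFAULT_RULES
) -> tuple[StoneComponents, int, str]:
    """S.T.O.N.E. score: components, total (5–13) and stratum label.

    Size points come from the *largest* single stone's area; the calyx
    component awards ``staghorn_points`` for a complete staghorn stone and
    otherwise follows the calyx-count threshold.
    """
    r = rules.stone
    if profile.anatomic_class is AnatomicClass.COMPLETE_STAGHORN:
        n_pts = r.staghorn_points
    elif profile.involved_calyces >= r.calyx_threshold:
        n_pts = 2
    else:
        n_pts = 1
    comps = StoneComponents(
        s=_size_points(largest_stone_area(profile.stones, rules=rules), r.size_band_edges_mm2),
        t=1 if profile.tract_length_mm <= r.tract_cutoff_mm else 2,
        o=r.obstruction_points[profile.hydronephrosis.value],
        n=n_pts,
        e=1 if mean_ct_hu(profile.hu_points) < r.density_cutoff else 2,
    )
    total = int(sum(comps))
    return comps, total, stone_stratum(total, rules=rules)


def _guys_predicates(profile: StoneProfile, stone_count: int) -> dict[str, bool]:
    multiple = stone_count > 1
    return {
        "complete_staghorn": profile.anatomic_class is AnatomicClass.COMPLETE_STAGHORN,
        "neuro_condition": profile.neuro_condition,
        "partial_staghorn_or_diverticulum": (
            profile.anatomic_class is AnatomicClass.DIVERTICULUM_OR_PARTIAL_STAGHORN
        ),
        "multiple_stones_abnormal_anatomy": multiple and profile.abnormal_anatomy,
        "solitary_upper_calyx": (
            not multiple and profile.anatomic_class is AnatomicClass.UPPER_CALYX
        ),
        "multiple_stones_normal_anatomy": multiple and not profile.abnormal_anatomy,
        "solitary_abnormal_anatomy": not multiple and profile.abnormal_anatomy,
        "always": True,
    }


def guys_grade(
    profile: StoneProfile, stone_count: int, *, rules: ScoreRules = DEFAULT_RULES
) -> GuysGrade:
    """Guy's stone grade I–IV by the encoded precedence rules (first match wins)."""
    if stone_count < 1:
        raise ValueError("stone_count must be >= 1")
    preds = _guys_predicates(profile, stone_count)
    for grade, names in rules.guys.precedence:
        if any(preds[name] for name in names):
            return GuysGrade(grade)
    raise RuntimeError("Guy's precedence rules did not match any grade")


def score_panel(
    profile: StoneProfile, stone_count: int | None = None, *, rules: ScoreRules = DEFAULT_RULES
) -> ScorePanel:
    """Compute all three scores consistently from one profile.

    ``stone_count`` defaults to ``len(profile.stones)``.
    """
    if stone_count is None:
        stone_count = len(profile.stones)
    sh = shalin_components(profile, rules=rules)
    sh_total = int(sum(sh))
    st_comps, st_total, st_stratum = stone_nephrolithometry(profile, rules=rules)
    return ScorePanel(
        shalin_components=sh,
        shalin_total=sh_total,
        shalin_stratum=shalin_stratum(sh_total, rules=rules),
        stone_components=st_comps,
        stone_total=st_total,
        stone_stratum=st_stratum,
        guys_grade=guys_grade(profile, stone_count, rules=rules),
    )


# ---------------------------------------------------------------------------
# Exhaustive enumeration over the component category cross-products.
# Representative raw inputs realise each category band; the totals attainable
# over the full cross-product characterise the score's range.
# ---------------------------------------------------------------------------

_AREA_REPS = (300.0, 600.0, 1200.0, 1700.0)  # one area inside each size band


def _profile_with(area_mm2: float, hydro: Hydronephrosis, anatomy: AnatomicClass,
                  tract: float, hu: float, calyces: int) -> StoneProfile:
    return StoneProfile(
        stones=((area_mm2 / 10.0, 10.0),),
        hydronephrosis=hydro,
        anatomic_class=anatomy,
        tract_length_mm=tract,
        hu_points=(hu,) * 5,
        involved_calyces=calyces,
    )


def enumerate_shalin_totals(*, rules: ScoreRules = DEFAULT_RULES) -> list[int]:
    """SHA.LIN totals over the full 4x3x4x2x2x2 = 192 category cross-product."""
    totals = []
    for area in _AREA_REPS:
        for hydro in Hydronephrosis:
            for anatomy in AnatomicClass:
                for tract in (90.0, 110.0):
                    for hu in (900.0, 1000.0):
                        for calyces in (2, 3):
                            totals.append(shalin_total(
                                _profile_with(area, hydro, anatomy, tract, hu, calyces),
                                rules=rules))
    return totals


def enumerate_stone_totals(*, rules: ScoreRules = DEFAULT_RULES) -> list[int]:
    """S.T.O.N.E. totals over the 4x2x2x3x2 = 96 component cross-product.

    The three calyx-component categories are realised as (2 calyces,
    non-staghorn), (3 calyces, non-staghorn) and complete staghorn.
    """
    calyx_cases = (
        (2, AnatomicClass.PELVIS_OR_MID_LOWER_CALYX),
        (3, AnatomicClass.PELVIS_OR_MID_LOWER_CALYX),
        (3, AnatomicClass.COMPLETE_STAGHORN),
    )
    totals = []
    for area in _AREA_REPS:
        for tract in (90.0, 110.0):
            for hydro in (Hydronephrosis.NONE_OR_MILD, Hydronephrosis.MODERATE):
                for calyces, anatomy in calyx_cases:
                    for hu in (900.0, 1000.0):
                        _, total, _ = stone_nephrolithometry(
                            _profile_with(area, hydro, anatomy, tract, hu, calyces),
                            rules=rules)
                        totals.append(total)
    return totals
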
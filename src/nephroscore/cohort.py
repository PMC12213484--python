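"""Patient-level PCNL cohort: data model, CSV I/O and derived variables.

A cohort is a flat table of one row per patient carrying demographics, the
CT stone profile, and perioperative outcomes.  The canonical serialisation is
a UTF-8 comma-separated file with a header row; stones are packed into one
column as a semicolon-delimited ``LxW`` list (e.g. ``"30x20;10x10"``) and the
five HU point measurements as a semicolon-delimited list.

Derived variables implemented here:

* estimated blood loss (EBL) = collected fluid volume − irrigation volume,
  dichotomised at 250 ml (``high`` strictly above the cutoff);
* stone-free status (SFS) = largest residual fragment < 4 mm;
* complication = presence of any Clavien-Dindo grade;
* the three nephrolithometry scores and their risk strata
  (:func:`attach_scores`).
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import scoring
from .rules import DEFAULT_RULES, ScoreRules
from .scoring import AnatomicClass, GuysGrade, Hydronephrosis, StoneProfile

__all__ = [
    "PatientRecord",
    "CohortTable",
    "CohortSchemaError",
    "CohortParseError",
    "estimated_blood_loss",
    "dichotomize_ebl",
    "label_sfs",
    "read_cohort_csv",
    "write_cohort_csv",
    "attach_scores",
    "summarize_cohort",
    "stratum_outcome_rates",
    "proportion_pct",
    "EBL_CUTOFF_ML",
    "SFS_RESIDUAL_CUTOFF_MM",
    "COLUMN_DICTIONARY",
]

EBL_CUTOFF_ML = 250.0
SFS_RESIDUAL_CUTOFF_MM = 4.0

#: column name -> (dtype description, units / allowed tokens)
COLUMN_DICTIONARY: dict[str, tuple[str, str]] = {
    "patient_id": ("str", "unique opaque identifier"),
    "age_years": ("float", "years, > 0"),
    "sex": ("category", "male | female"),
    "bmi": ("float", "kg/m^2, > 0"),
    "side": ("category", "left | right"),
    "stones": ("str", 'semicolon-delimited "LxW" mm pairs, e.g. "30x20;10x10"'),
    "hydronephrosis": ("category", "none_or_mild | moderate | severe"),
    "anatomic_class": (
        "category",
        "pelvis_or_mid_lower_calyx | upper_calyx | diverticulum_or_partial_staghorn | complete_staghorn",
    ),
    "tract_length_mm": ("float", "mm, skin to stone center, > 0"),
    "hu_points": ("str", "semicolon-delimited 5 HU values"),
    "involved_calyces": ("int", ">= 0"),
    "abnormal_anatomy": ("bool", "true | false"),
    "neuro_condition": ("bool", "true | false"),
    "stone_count": ("int", ">= 1"),
    "residual_stone_mm": ("float?", "mm, >= 0; empty if sfs supplied directly"),
    "sfs": ("bool?", "true | false; empty if residual_stone_mm supplied"),
    "hb_change_mgdl": ("float", "mg/dl haemoglobin change"),
    "irrigation_ml": ("float?", "ml, >= 0"),
    "collected_ml": ("float?", "ml, >= irrigation_ml"),
    "ebl_ml": ("float?", "ml, >= 0; alternative to irrigation/collected pair"),
    "ot_min": ("float", "operative time, minutes, > 0"),
    "plos_days": ("float", "postoperative length of stay, days, > 0"),
    "clavien_grade": ("category?", "I | II | III | IV; empty = no complication"),
}

REQUIRED_COLUMNS = tuple(c for c in COLUMN_DICTIONARY if not COLUMN_DICTIONARY[c][0].endswith("?"))

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False}


class CohortSchemaError(ValueError):
    """A required column is missing or malformed at the schema level."""


class CohortParseError(ValueError):
    """A cell failed to parse; carries the offending row index."""

    def __init__(self, row: int, column: str, message: str):
        super().__init__(f"row {row}, column {column!r}: {message}")
        self.row = row
        self.column = column


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics, stone profile and perioperative outcomes."""

    patient_id: str
    age_years: float
    sex: str  # male | female
    bmi: float
    side: str  # left | right
    profile: StoneProfile
    stone_count: int
    hb_change_mgdl: float
    ot_min: float
    plos_days: float
    residual_stone_mm: float | None = None
    sfs: bool | None = None
    irrigation_ml: float | None = None
    collected_ml: float | None = None
    ebl_ml: float | None = None
    clavien_grade: str | None = None  # I..IV, None = no complication

    def __post_init__(self) -> None:
        if (self.residual_stone_mm is None) == (self.sfs is None):
            raise ValueError(
                f"patient {self.patient_id}: exactly one of residual_stone_mm or sfs required"
            )
        pair = self.irrigation_ml is not None and self.collected_ml is not None
        if pair == (self.ebl_ml is not None):
            raise ValueError(
                f"patient {self.patient_id}: EBL must be resolvable from exactly one of "
                "(irrigation_ml & collected_ml) or ebl_ml"
            )
        if self.clavien_grade is not None and self.clavien_grade not in ("I", "II", "III", "IV"):
            raise ValueError(f"invalid clavien_grade {self.clavien_grade!r}")
        if self.stone_count < 1:
            raise ValueError("stone_count must be >= 1")

    def resolved_ebl_ml(self) -> float:
        if self.ebl_ml is not None:
            return float(self.ebl_ml)
        return estimated_blood_loss(self.collected_ml, self.irrigation_ml)

    def resolved_sfs(self) -> bool:
        if self.sfs is not None:
            return bool(self.sfs)
        return label_sfs(self.residual_stone_mm)


def estimated_blood_loss(collected_ml: float, irrigation_ml: float) -> float:
    """EBL (ml) = total collected fluid (blood + irrigation) − irrigation used."""
    if collected_ml < 0 or irrigation_ml < 0:
        raise ValueError("fluid volumes must be non-negative")
    if collected_ml < irrigation_ml:
        raise ValueError(
            f"collected volume ({collected_ml}) below irrigation volume ({irrigation_ml}): "
            "physically impossible record"
        )
    return float(collected_ml - irrigation_ml)


def dichotomize_ebl(ebl_ml: float, cutoff_ml: float = EBL_CUTOFF_ML) -> str:
    """Classify blood loss as ``"high"`` (strictly above cutoff) or ``"low"``."""
    if ebl_ml < 0:
        raise ValueError("ebl_ml must be non-negative")
    return "high" if ebl_ml > cutoff_ml else "low"


def label_sfs(residual_stone_mm: float, cutoff_mm: float = SFS_RESIDUAL_CUTOFF_MM) -> bool:
    """Stone-free status: largest residual fragment strictly below 4 mm."""
    if residual_stone_mm < 0:
        raise ValueError("residual_stone_mm must be non-negative")
    return residual_stone_mm < cutoff_mm


def _format_float(x: float) -> str:
    # repr round-trips; strip the trailing ".0" for integral values
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _serialize_stones(stones: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{_format_float(l)}x{_format_float(w)}" for l, w in stones)


def _parse_stones(text: str) -> tuple[tuple[float, float], ...]:
    out = []
    for part in text.split(";"):
        l, _, w = part.partition("x")
        out.append((float(l), float(w)))
    return tuple(out)


class CohortTable:
    """Ordered collection of patients, column-addressable for analysis.

    Backed by a :class:`pandas.DataFrame` in canonical form (one row per
    patient, the documented column set, typed cells with ``None``/NaN for
    absent optionals).  Extra columns are preserved through I/O.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
        if len(df) < 1:
            raise CohortSchemaError("cohort must contain at least one patient")
        ids = df["patient_id"].astype(str)
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            raise CohortSchemaError(f"duplicate patient_id(s): {dupes}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[PatientRecord]) -> "CohortTable":
        rows = []
        for rec in records:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "age_years": rec.age_years,
                    "sex": rec.sex,
                    "bmi": rec.bmi,
                    "side": rec.side,
                    "stones": _serialize_stones(rec.profile.stones),
                    "hydronephrosis": rec.profile.hydronephrosis.value,
                    "anatomic_class": rec.profile.anatomic_class.value,
                    "tract_length_mm": rec.profile.tract_length_mm,
                    "hu_points": ";".join(_format_float(x) for x in rec.profile.hu_points),
                    "involved_calyces": rec.profile.involved_calyces,
                    "abnormal_anatomy": rec.profile.abnormal_anatomy,
                    "neuro_condition": rec.profile.neuro_condition,
                    "stone_count": rec.stone_count,
                    "residual_stone_mm": rec.residual_stone_mm,
                    "sfs": rec.sfs,
                    "hb_change_mgdl": rec.hb_change_mgdl,
                    "irrigation_ml": rec.irrigation_ml,
                    "collected_ml": rec.collected_ml,
                    "ebl_ml": rec.ebl_ml,
                    "ot_min": rec.ot_min,
                    "plos_days": rec.plos_days,
                    "clavien_grade": rec.clavien_grade,
                }
            )
        return cls(pd.DataFrame(rows))

    def records(self) -> Iterator[PatientRecord]:
        for i, row in self.df.iterrows():
            try:
                yield _row_to_record(row)
            except (ValueError, TypeError) as exc:
                raise CohortParseError(int(i), "<record>", str(exc)) from exc

    def profile(self, i: int) -> StoneProfile:
        return _row_to_profile(self.df.iloc[i])


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return bool(value)


def _row_to_profile(row: pd.Series) -> StoneProfile:
    stones = row["stones"]
    if isinstance(stones, str):
        stones = _parse_stones(stones)
    hu = row["hu_points"]
    if isinstance(hu, str):
        hu = tuple(float(x) for x in hu.split(";"))
    return StoneProfile(
        stones=tuple(stones),
        hydronephrosis=Hydronephrosis(row["hydronephrosis"]),
        anatomic_class=AnatomicClass(row["anatomic_class"]),
        tract_length_mm=float(row["tract_length_mm"]),
        hu_points=tuple(hu),
        involved_calyces=int(row["involved_calyces"]),
        abnormal_anatomy=bool(row["abnormal_anatomy"]),
        neuro_condition=bool(row["neuro_condition"]),
    )


def _row_to_record(row: pd.Series) -> PatientRecord:
    grade = row.get("clavien_grade")
    if isinstance(grade, float) and math.isnan(grade):
        grade = None
    # A table that has passed through attach_scores carries both the raw
    # measurement and the derived label; the measurement is authoritative,
    # but a contradictory pair is rejected rather than silently dropped.
    residual = _opt_float(row.get("residual_stone_mm"))
    sfs = _opt_bool(row.get("sfs"))
    if residual is not None and sfs is not None:
        if label_sfs(residual) != sfs:
            raise ValueError(
                f"sfs={sfs} contradicts residual_stone_mm={residual}")
        sfs = None
    irrigation = _opt_float(row.get("irrigation_ml"))
    collected = _opt_float(row.get("collected_ml"))
    ebl = _opt_float(row.get("ebl_ml"))
    if irrigation is not None and collected is not None and ebl is not None:
        if abs(estimated_blood_loss(collected, irrigation) - ebl) > 1e-6:
            raise ValueError(
                f"ebl_ml={ebl} contradicts collected-irrigation="
                f"{collected - irrigation}")
        ebl = None
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        bmi=float(row["bmi"]),
        side=str(row["side"]),
        profile=_row_to_profile(row),
        stone_count=int(row["stone_count"]),
        hb_change_mgdl=float(row["hb_change_mgdl"]),
        ot_min=float(row["ot_min"]),
        plos_days=float(row["plos_days"]),
        residual_stone_mm=residual,
        sfs=sfs,
        irrigation_ml=irrigation,
        collected_ml=collected,
        ebl_ml=ebl,
        clavien_grade=grade if grade is None else str(grade),
    )


_PARSERS = {
    "str": str,
    "float": float,
    "float?": float,
    "int": int,
    "category": str,
    "category?": str,
    "bool": lambda s: _BOOL_TOKENS[s.lower()],
    "bool?": lambda s: _BOOL_TOKENS[s.lower()],
}


def read_cohort_csv(path_or_buf) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row required) into a CohortTable.

    Raises :class:`CohortSchemaError` for a missing required column and
    :class:`CohortParseError` (with the row index) for an unparseable cell.
    Unknown columns are preserved verbatim.
    """
    raw = pd.read_csv(path_or_buf, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    out: dict[str, list] = {}
    for col in raw.columns:
        spec = COLUMN_DICTIONARY.get(col)
        if spec is None:
            out[col] = raw[col].tolist()  # unknown column: preserve as text
            continue
        kind = spec[0]
        optional = kind.endswith("?")
        parse = _PARSERS.get(kind, str)
        values = []
        for i, cell in enumerate(raw[col]):
            if cell == "":
                if optional:
                    values.append(None)
                    continue
                raise CohortParseError(i, col, "required value is empty")
            try:
                values.append(parse(cell))
            except (ValueError, KeyError) as exc:
                raise CohortParseError(i, col, f"cannot parse {cell!r}") from exc
        out[col] = values
    df = pd.DataFrame(out)
    table = CohortTable(df)
    for _ in table.records():  # validate record-level invariants eagerly
        pass
    return table


def _cell_to_text(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        return _format_float(float(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


def write_cohort_csv(table: CohortTable, path_or_buf) -> None:
    """Write the canonical CSV form (UTF-8, '.' decimal point, header row)."""
    text = table.df.map(_cell_to_text)
    text.to_csv(path_or_buf, index=False)


def cohort_to_csv_text(table: CohortTable) -> str:
    """Canonical serialisation as a string (useful for determinism checks)."""
    buf = io.StringIO()
    write_cohort_csv(table, buf)
    return buf.getvalue()


def attach_scores(table: CohortTable, *, rules: ScoreRules = DEFAULT_RULES) -> CohortTable:
    """Return a cohort with score and derived-outcome columns attached.

    Adds, per row: ``stone_burden_mm2``, ``largest_stone_mm2``, ``mean_hu``,
    ``shalin_total``/``shalin_stratum``, ``stone_total``/``stone_stratum``,
    ``guys_grade``, resolved ``ebl_ml``, ``ebl_class``, resolved ``sfs`` and
    ``complication``.  Deterministic and idempotent: existing derived columns
    are recomputed from the raw inputs.
    """
    df = table.df.copy()
    derived: dict[str, list] = {k: [] for k in (
        "stone_burden_mm2", "largest_stone_mm2", "mean_hu",
        "shalin_total", "shalin_stratum", "stone_total", "stone_stratum",
        "guys_grade", "ebl_ml", "ebl_class", "sfs", "complication",
    )}
    for i, rec in enumerate(table.records()):
        try:
            panel = scoring.score_panel(rec.profile, rec.stone_count, rules=rules)
            ebl = rec.resolved_ebl_ml()
            derived["stone_burden_mm2"].append(
                scoring.stone_burden_total(rec.profile.stones, rules=rules))
            derived["largest_stone_mm2"].append(
                scoring.largest_stone_area(rec.profile.stones, rules=rules))
            derived["mean_hu"].append(scoring.mean_ct_hu(rec.profile.hu_points))
            derived["shalin_total"].append(panel.shalin_total)
            derived["shalin_stratum"].append(panel.shalin_stratum)
            derived["stone_total"].append(panel.stone_total)
            derived["stone_stratum"].append(panel.stone_stratum)
            derived["guys_grade"].append(panel.guys_grade.value)
            derived["ebl_ml"].append(ebl)
            derived["ebl_class"].append(dichotomize_ebl(ebl))
            derived["sfs"].append(rec.resolved_sfs())
            derived["complication"].append(rec.clavien_grade is not None)
        except ValueError as exc:
            raise CohortParseError(i, "<derived>", str(exc)) from exc
    for col, values in derived.items():
        df[col] = values
    return CohortTable(df)


def proportion_pct(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` (NaN for an empty group)."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


# ---------------------------------------------------------------------------
# Cohort summary (the "table one")
# ---------------------------------------------------------------------------

# Fixed per-variable reporting/testing policy so the layout is deterministic:
# ("normal", col)       -> mean +/- SD, t-test
# ("skewed", col)       -> median (IQR), Mann-Whitney U
# ("categorical", col)  -> counts (%), chi-squared / Fisher
SUMMARY_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("age_years", "normal", "Age (years)"),
    ("sex", "categorical", "Sex"),
    ("bmi", "skewed", "BMI (kg/m2)"),
    ("side", "categorical", "Side"),
    ("stone_burden_mm2", "skewed", "Stone burden (mm2)"),
    ("mean_hu", "skewed", "Stone HU"),
    ("hydronephrosis", "categorical", "Hydronephrosis"),
    ("anatomic_class", "categorical", "Anatomic distribution"),
    ("calyx_group", "categorical", "Involved calyces (0-2 / >=3)"),
    ("tract_group", "categorical", "Tract length (<=100 / >100 mm)"),
    ("hb_change_mgdl", "skewed", "Hemoglobin change (mg/dl)"),
    ("ebl_class", "categorical", "Estimated blood loss (>250 / <=250 ml)"),
    ("ot_min", "skewed", "Operative time (min)"),
    ("plos_days", "skewed", "Postoperative stay (days)"),
    ("complication", "categorical", "Complications"),
    ("guys_grade_num", "skewed", "Guy's score"),
    ("stone_total", "skewed", "S.T.O.N.E. score"),
    ("shalin_total", "skewed", "SHA.LIN score"),
)

_GUYS_NUM = {"I": 1, "II": 2, "III": 3, "IV": 4}


def _summary_frame(df: pd.DataFrame) -> pd.DataFrame:
    aux = df.copy()
    aux["calyx_group"] = np.where(aux["involved_calyces"] >= 3, ">=3", "0-2")
    aux["tract_group"] = np.where(aux["tract_length_mm"] > 100, ">100", "<=100")
    aux["guys_grade_num"] = aux["guys_grade"].map(_GUYS_NUM)
    return aux


def summarize_cohort(table: CohortTable, group_by: str = "sfs") -> pd.DataFrame:
    """Per-group descriptive summary with between-group tests.

    One row per variable (or per level of a categorical variable) with
    columns ``variable, level, <group1>, <group2>, test, p_value``.  The
    reporting style (mean±SD vs median (IQR) vs counts (%)) is fixed per
    variable so the layout is deterministic.  Requires scores attached.
    """
    from . import inference  # deferred: inference does not import cohort

    df = _summary_frame(table.df)
    if group_by not in df.columns:
        raise CohortSchemaError(f"grouping column {group_by!r} not present (attach scores first)")
    groups = [True, False] if df[group_by].dtype == bool else sorted(df[group_by].unique())
    if len(groups) != 2:
        raise ValueError(f"summarize_cohort requires a binary grouping, got {groups}")
    g1 = df[df[group_by] == groups[0]]
    g2 = df[df[group_by] == groups[1]]
    names = [f"{group_by}={g}" for g in groups]

    rows = []
    for col, kind, label in SUMMARY_LAYOUT:
        if col not in df.columns:
            continue
        if g1.empty or g2.empty:
            comp_p, test_name = float("nan"), "empty-group"
        else:
            comp = inference.compare_groups(df, col, group_by, kind=kind)
            comp_p, test_name = comp.p_value, comp.test
        if kind in ("normal", "skewed"):
            cells = []
            for g in (g1, g2):
                x = g[col].astype(float)
                if x.empty:
                    cells.append("(empty group)")
                elif kind == "normal":
                    cells.append(f"{x.mean():.1f} ± {x.std(ddof=1):.1f}")
                else:
                    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
                    cells.append(f"{med:.1f} ({q1:.1f}–{q3:.1f})")
            rows.append({"variable": label, "level": "", names[0]: cells[0],
                         names[1]: cells[1], "test": test_name, "p_value": comp_p})
        else:
            levels = sorted(df[col].astype(str).unique())
            for level in levels:
                cells = []
                for g in (g1, g2):
                    if g.empty:
                        cells.append("(empty group)")
                    else:
                        k = int((g[col].astype(str) == level).sum())
                        cells.append(f"{k} ({proportion_pct(k, len(g)):.1f}%)")
                rows.append({"variable": label, "level": level, names[0]: cells[0],
                             names[1]: cells[1], "test": test_name, "p_value": comp_p})
    return pd.DataFrame(rows)


def stratum_outcome_rates(table: CohortTable, *, rules: ScoreRules = DEFAULT_RULES) -> pd.DataFrame:
    """Stone-free and complication rates per risk stratum of each system.

    Returns one row per (system, stratum) with columns ``system, stratum, n,
    stone_free, stone_free_pct, complications, complication_pct``.  An empty
    stratum is reported with ``n = 0`` and NaN (undefined) rates rather than
    being dropped.
    """
    df = table.df
    for col in ("shalin_stratum", "stone_stratum", "guys_grade", "sfs", "complication"):
        if col not in df.columns:
            raise CohortSchemaError(f"column {col!r} missing: call attach_scores first")
    systems = {
        "guys": ("guys_grade", ["I", "II", "III", "IV"]),
        "stone": ("stone_stratum", list(rules.stone.strata)),
        "shalin": ("shalin_stratum", list(rules.shalin.strata)),
    }
    rows = []
    for system, (col, levels) in systems.items():
        for level in levels:
            sub = df[df[col].astype(str) == level]
            n = len(sub)
            sf = int(sub["sfs"].sum()) if n else 0
            comp = int(sub["complication"].sum()) if n else 0
            rows.append({
                "system": system, "stratum": level, "n": n,
                "stone_free": sf, "stone_free_pct": proportion_pct(sf, n),
                "complications": comp, "complication_pct": proportion_pct(comp, n),
            })
    return pd.DataFrame(rows)
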
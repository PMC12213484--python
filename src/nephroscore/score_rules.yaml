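# Band edges and rule tables for the three nephrolithometry scores.
# Every numeric boundary used by the scoring functions lives here so a
# reviewer can audit or override it (pass a custom ScoreRules to the
# scoring functions).
#
# area_formula: how a stone's cross-sectional area is computed from its
# longest length and width on CT.
#   rectangle : length * width          (default; the convention the score uses)
#   ellipse   : pi/4 * length * width
area_formula: rectangle

shalin:
  # Stone burden (S): summed cross-sectional area over ALL stones, mm^2.
  # Bands are closed on the printed side: [0,400) -> 1, [400,800) -> 2,
  # [800,1600) -> 3, >=1600 -> 4.
  size_band_edges_mm2: [400, 800, 1600]
  # Hydronephrosis (H): pre-graded 3-level ordinal.
  hydronephrosis_points:
    none_or_mild: 1
    moderate: 2
    severe: 3
  # Anatomical distribution (A).
  anatomy_points:
    pelvis_or_mid_lower_calyx: 1
    upper_calyx: 2
    diverticulum_or_partial_staghorn: 3
    complete_staghorn: 4
  # Length of tract (L): skin to stone center, mm; <=100 -> 1, >100 -> 2.
  tract_cutoff_mm: 100
  # Indicator of CT (I): mean of the five HU points; <=950 -> 1, >950 -> 2.
  hu_cutoff: 950
  # Number of involved calyces (N): 0-2 -> 1, >=3 -> 2.
  calyx_threshold: 3
  # Risk strata on the total (6..17).
  strata:
    "6-8": [6, 8]
    "9-11": [9, 11]
    "12-14": [12, 14]
    "15-17": [15, 17]

stone:
  # S.T.O.N.E.: same size bands but applied to the LARGEST single stone.
  size_band_edges_mm2: [400, 800, 1600]
  tract_cutoff_mm: 100
  # Obstruction (O): none/mild -> 1, moderate or severe -> 2.
  obstruction_points:
    none_or_mild: 1
    moderate: 2
    severe: 2
  # Number of involved calyces (N): 0-2 -> 1, >=3 -> 2, complete staghorn -> 3.
  calyx_threshold: 3
  staghorn_points: 3
  # Essence/density (E): boundary is < 950 -> 1, >= 950 -> 2.  Note this is
  # deliberately the opposite closure from SHA.LIN's <=950/>950.
  density_cutoff: 950
  strata:
    "5-6": [5, 6]
    "7-8": [7, 8]
    "9-13": [9, 13]

guys:
  # Ordered precedence: the first matching rule (top to bottom) assigns the
  # grade.  Predicate names are the vocabulary the scoring module implements.
  precedence:
    - grade: "IV"
      any: [complete_staghorn, neuro_condition]
    - grade: "III"
      any: [partial_staghorn_or_diverticulum, multiple_stones_abnormal_anatomy]
    - grade: "II"
      any: [solitary_upper_calyx, multiple_stones_normal_anatomy, solitary_abnormal_anatomy]
    - grade: "I"
      any: [always]
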
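from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

import nephroscore as ns

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return ns.calibrate_defaults()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """A 300-patient synthetic cohort with scores attached (fixed seed)."""
    cfg = replace(default_config, n=300, seed=11)
    return ns.attach_scores(ns.generate_cohort(cfg))


def make_profile(
    *,
    stones=((30.0, 20.0),),
    hydronephrosis=ns.Hydronephrosis.NONE_OR_MILD,
    anatomic_class=ns.AnatomicClass.PELVIS_OR_MID_LOWER_CALYX,
    tract_length_mm=90.0,
    hu_points=(900.0,) * 5,
    involved_calyces=2,
    abnormal_anatomy=False,
    neuro_condition=False,
):
    return ns.StoneProfile(
        stones=stones,
        hydronephrosis=hydronephrosis,
        anatomic_class=anatomic_class,
        tract_length_mm=tract_length_mm,
        hu_points=hu_points,
        involved_calyces=involved_calyces,
        abnormal_anatomy=abnormal_anatomy,
        neuro_condition=neuro_condition,
    )
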
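"""Shared fixtures: small synthetic cohorts and FreeSurfer stats fixtures.

All fixture data is generated programmatically; hypothesis runs
derandomized so the suite is reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import normdev as nd
from normdev.regions import ASEG_STRUCTURES, DESTRIEUX_LABELS

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: a small region subset used throughout the unit tests to keep fits fast
SUBSET = [
    "lh_G_front_middle",
    "lh_S_central",
    "rh_G_precuneus",
    "rh_S_temporal_sup",
    "Left-Hippocampus",
    "Right-Amygdala",
]


@pytest.fixture(scope="session")
def small_config() -> nd.SimulationConfig:
    return nd.default_config(
        seed=101,
        n_reference=600,
        n_sites=2,
        group_specs={
            "PD-high": nd.GroupSpec(n=20, burden_mean_regions_affected=2,
                                    effect_size_sd_units=-2.5),
            "DLB": nd.GroupSpec(n=20, burden_mean_regions_affected=6,
                                effect_size_sd_units=-2.5),
        },
        controls_per_clinical_site=60,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return nd.generate_reference_cohort(small_config)


@pytest.fixture(scope="session")
def small_clinical(small_config, small_reference):
    _, truth = small_reference
    return nd.generate_clinical_cohort(small_config, truth)


@pytest.fixture(scope="session")
def small_model(small_reference):
    ref, _ = small_reference
    return nd.fit_normative_model(ref, regions=SUBSET)


@pytest.fixture(scope="session")
def calibrated_model(small_model, small_clinical):
    clin, _ = small_clinical
    model = small_model
    for site in pd.unique(clin["site"]):
        model = nd.recalibrate_site(
            model, clin[(clin["site"] == site) & (clin["group"] == "Control")]
        )
    return model


# ---------------------------------------------------------------------------
# FreeSurfer stats fixtures
# ---------------------------------------------------------------------------

def make_aparc_stats(values: dict[str, float]) -> str:
    """Synthetic aparc.a2009s.stats file text with given ThickAvg values."""
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        "# hemi lh",
        "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd "
        "MeanCurv GausCurv FoldInd CurvInd",
    ]
    for i, label in enumerate(DESTRIEUX_LABELS):
        thick = values[label]
        lines.append(
            f"{label} {1000 + i} {700 + i} {2000 + i} {thick:.3f} 0.500 0.120 0.030 10 1.2"
        )
    return "\n".join(lines) + "\n"


def make_aseg_stats(values: dict[str, float]) -> str:
    """Synthetic aseg.stats text; includes extra structures like real files."""
    lines = [
        "# Title Segmentation Statistics",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean "
        "normStdDev normMin normMax normRange",
    ]
    rows = [name for name, _ in ASEG_STRUCTURES] + ["WM-hypointensities", "CSF", "Optic-Chiasm"]
    for i, name in enumerate(rows):
        vol = values.get(name, 500.0 + i)
        lines.append(f"{i + 1} {i + 2} {int(vol)} {vol:.1f} {name} 100.0 5.0 80.0 120.0 40.0")
    return "\n".join(lines) + "\n"


@pytest.fixture()
def freesurfer_files(tmp_path):
    rng = np.random.default_rng(3)
    lh = {lbl: float(rng.uniform(1.5, 3.5)) for lbl in DESTRIEUX_LABELS}
    rh = {lbl: float(rng.uniform(1.5, 3.5)) for lbl in DESTRIEUX_LABELS}
    aseg = {name: float(rng.uniform(500, 20000)) for name, _ in ASEG_STRUCTURES}
    paths = {
        "lh": tmp_path / "lh.aparc.a2009s.stats",
        "rh": tmp_path / "rh.aparc.a2009s.stats",
        "aseg": tmp_path / "aseg.stats",
    }
    paths["lh"].write_text(make_aparc_stats(lh))
    paths["rh"].write_text(make_aparc_stats(rh))
    paths["aseg"].write_text(make_aseg_stats(aseg))
    return paths, lh, rh, aseg
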
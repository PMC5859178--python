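"""Shared fixtures: calibration, noiseless optics, and a session-scoped
synthetic demo cohort run once and inspected by several tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from guvpore.pipeline import PipelineConfig, make_demo_cohort, run_pipeline
from guvpore.segmentation import CalibrationParams
from guvpore.synthetic import OpticalParams

settings.register_profile(
    "guvpore",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("guvpore")


@pytest.fixture(scope="session")
def calibration() -> CalibrationParams:
    return CalibrationParams(pixel_size=0.5)


@pytest.fixture(scope="session")
def noiseless_optics() -> OpticalParams:
    return OpticalParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """A seeded 6-vesicle cohort with logistic A_norm(E) truth (E50 = 200 V/mm,
    lower plateau 0.7) plus its full pipeline run."""
    root = tmp_path_factory.mktemp("demo_cohort")
    cohort_csv = make_demo_cohort(root, seed=1, n_guvs=6)
    config = PipelineConfig(
        cohort_csv=str(cohort_csv), output_dir=str(root / "results"), seed=1
    )
    manifest = run_pipeline(config)
    return dict(root=root, cohort_csv=cohort_csv, config=config, manifest=manifest)
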
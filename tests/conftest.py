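import numpy as np
import pytest
from hypothesis import settings

from flaxcoi import (
    CalibrationTargets,
    IndividualRecord,
    calibrate_to_targets,
    default_model,
    generate_population,
)

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_h_records():
    """Five hypertensive respondents with unit weights and fixed BPs
    straddling the conversion window above the 140/90 cut-points."""
    specs = [
        (30, 143.0, 80.0, False),
        (50, 141.0, 92.0, False),
        (60, 150.0, 95.0, False),
        (70, 140.5, 88.0, False),
        (40, 139.0, 91.5, False),
    ]
    return [
        IndividualRecord(f"T{i}", age, "M", sbp, dbp, med, 1.0)
        for i, (age, sbp, dbp, med) in enumerate(specs)
    ]


@pytest.fixture
def mixed_records():
    """Small mixed population: hypertensive and normotensive, medicated
    and not, fractional weights."""
    specs = [
        ("A", 25, "F", 118.0, 75.0, False, 2.4),
        ("B", 52, "M", 141.5, 82.0, False, 1.1),
        ("C", 67, "F", 132.0, 84.0, True, 3.3),
        ("D", 71, "M", 155.0, 95.0, True, 0.8),
        ("E", 45, "F", 125.0, 91.0, False, 2.6),
        ("F", 38, "M", 110.0, 70.0, False, 1.9),
    ]
    return [IndividualRecord(*s) for s in specs]


@pytest.fixture(scope="session")
def calibrated_model():
    """Default model calibrated once per session to the published
    overall-prevalence anchor (20.02%)."""
    result = calibrate_to_targets(
        default_model(),
        CalibrationTargets(overall_prevalence=0.2002),
        n_probe=20_000,
        seed=3,
        tolerance=0.005,
    )
    return result.model


@pytest.fixture(scope="session")
def calibrated_population(calibrated_model):
    """An n=20,000 draw from the calibrated model (independent seed)."""
    return generate_population(calibrated_model, 20_000, seed=101)
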
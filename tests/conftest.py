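import numpy as np
import pandas as pd
import pytest

from nlepi.io_formats import ExpressionMatrix
from nlepi.synthetic import SimulationConfig, generate_expression


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Hand-built 3-probe x 4-sample matrix (2 RM, 2 HN)."""
    probes = ["p1", "p2", "p3"]
    samples = ["r1", "r2", "h1", "h2"]
    intensities = pd.DataFrame(
        [[100.0, 120.0, 30.0, 35.0], [50.0, 55.0, 52.0, 48.0], [5.0, 4.0, 6.0, 7.0]],
        index=probes,
        columns=samples,
    )
    detection = pd.DataFrame(
        [["P", "P", "P", "P"], ["P", "P", "M", "P"], ["A", "A", "A", "A"]],
        index=probes,
        columns=samples,
    )
    groups = pd.Series(["RM", "RM", "HN", "HN"], index=samples)
    return ExpressionMatrix(intensities, detection, groups)


@pytest.fixture
def planted_matrix():
    """Small two-group matrix with 5 strong planted 4-fold probes."""
    config = SimulationConfig(
        n_probes=60,
        n_rm=9,
        n_hn=9,
        n_pm=0,
        n_de=5,
        fold_range=(4.0, 4.0),
        cv=0.15,
        frac_unexpressed=0.0,
        seed=5,
    )
    return generate_expression(config)
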
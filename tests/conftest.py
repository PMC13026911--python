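import math

import numpy as np
import pytest

from qpcrcurve.standard_curve import CalibrationPoint

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.3219, perfect doubling


def noise_free_cq(x, intercept=34.0, efficiency=1.0):
    """Cq of an aliquot holding x targets, no measurement noise."""
    return intercept - np.log10(x) / math.log10(1.0 + efficiency)


@pytest.fixture
def exact_line_points():
    """Noise-free calibration points on Cq = -3.3219 log10(N) + 34."""
    pts = []
    for log_n in range(0, 7):
        for rep in range(3):
            pts.append(
                CalibrationPoint(
                    log10_copies=float(log_n),
                    cq=PERFECT_SLOPE * log_n + 34.0,
                    level_id=f"L{log_n}",
                    replicate_id=str(rep),
                )
            )
    return pts


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def poisson_cqs(n_expected, n_rep, rng, sigma_tech=0.0, intercept=34.0,
                efficiency=1.0):
    """Replicate Cq vector (NaN = negative) under the aliquoting model."""
    x = rng.poisson(n_expected, n_rep)
    cq = np.full(n_rep, np.nan)
    pos = x > 0
    cq[pos] = intercept - np.log10(x[pos]) / math.log10(1.0 + efficiency)
    if sigma_tech > 0:
        cq[pos] += rng.normal(0.0, sigma_tech, int(pos.sum()))
    return cq
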
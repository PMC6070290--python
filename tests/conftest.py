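"""Shared fixtures: the printed parameter sets of the study figures."""

import numpy as np
import pytest

from commonsgame import ModelParams


@pytest.fixture(scope="session")
def fig1():
    """Slowly growing resource: r < e_c."""
    return ModelParams(r=0.3, R_m=1000.0, N=1000, b_m=0.5, alpha=0.5, p=0.5, beta=0.5)


@pytest.fixture(scope="session")
def figure_params(fig1):
    """All seven distinct printed parameter sets, keyed by figure panel."""
    return {
        "fig1": fig1,
        "fig2A": fig1.with_(r=0.6),
        "fig2C": fig1.with_(r=0.6, p=0.05),
        "fig2E": fig1.with_(r=0.6, p=0.01, beta=0.1),
        "fig3A": fig1.with_(r=1.0),
        "fig3C": fig1.with_(r=1.0, p=0.2),
        "fig3E": fig1.with_(r=1.0, N=100, R_m=100.0, p=0.1),
    }


def random_params(rng: np.random.Generator, margin_r: float = 0.02, margin_pb: float = 0.01):
    """Draw a random, non-boundary parameter set at the study's scales.

    Rejection-samples until r is bounded away from both gain rates and
    p*beta from both fine thresholds, so the regime is unambiguous and the
    slowest contraction rate stays above the margins (keeps integration
    horizons bounded).
    """
    while True:
        params = ModelParams(
            r=float(rng.uniform(0.1, 1.5)),
            R_m=1000.0,
            N=1000,
            b_m=float(rng.uniform(0.3, 0.7)),
            alpha=float(rng.uniform(0.3, 1.0)),
            p=float(rng.uniform(0.1, 0.9)),
            beta=float(rng.uniform(0.1, 0.8)),
        )
        e_c = params.b_m * params.N / params.R_m
        e_d = e_c * (1 + params.alpha)
        tau_c = params.b_m * params.alpha * (1 - e_c / params.r)
        tau_d = params.b_m * params.alpha * (1 - e_d / params.r)
        pb = params.p_beta
        if abs(params.r - e_c) < margin_r or abs(params.r - e_d) < margin_r:
            continue
        if abs(pb - tau_c) < margin_pb or abs(pb - tau_d) < margin_pb:
            continue
        return params
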
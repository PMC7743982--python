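"""Shared fixtures and independent oracles for the test suite.

The oracle functions here re-derive the p53 module's behaviour directly
from the printed constants (if/else switching logic, scalar exponential
solutions, quadratic root formulas) without going through the package's
model machinery, so that implementation and oracle stay independent.
"""

from __future__ import annotations

import numpy as np
import pytest

from pldesys import builtin_p53_model, enumerate_delta_regions

# printed constants of the switching model (source parameter table)
PAR = {
    "p1": 8.8,
    "p20": 2.4,
    "p21": 21.6,
    "p30": 0.5172,
    "p31": 3.6204,
    "d10": 9.8395e-5,
    "d11": 6.5435e-5,
    "d12": 9.8395e-5,
    "d2": 1.375e-5,
    "d3": 3e-5,
    "k10": 1.5e-4,
    "k11": 1.4713e-4,
}
THETA = {"P": 4.5e4, "N1": 4e4, "N2": 8e4, "T": 1e5}
INIT = {"P": 2.6858e4, "M": 1.1166e4, "N": 1.5438e4, "T": 1.7240e5}

# printed stationary-point table: stress -> (domain ranks, coordinates)
RSP_TABLE = {
    0.0: ((0, 2, 0), (33559, 14656, 159888, 17240)),
    1.5: ((1, 1, 1), (53714, 644381, 53800, 137920)),
    9.0: ((1, 0, 1), (89435, 170976, 3568, 137920)),
}


def p53_rhs_reference(state, R):
    """Direct if/else evaluation of the switching-model right-hand side."""
    P, M, N, T = state
    ZP = 1.0 if P >= THETA["P"] else 0.0
    ZN1 = 1.0 if N >= THETA["N1"] else 0.0
    ZN2 = 1.0 if N >= THETA["N2"] else 0.0
    ZT = 1.0 if T >= THETA["T"] else 0.0
    d1 = PAR["d10"] + PAR["d11"] * ZN1 + PAR["d12"] * ZN2
    p2 = PAR["p20"] + PAR["p21"] * ZP
    p3 = PAR["p30"] + PAR["p31"] * ZP
    k1 = PAR["k10"] - PAR["k11"] * ZT
    d2R = PAR["d2"] * (1.0 + R)
    return np.array(
        [
            PAR["p1"] - d1 * P,
            p2 - d2R * M - k1 * M,
            k1 * M - d2R * N,
            p3 - PAR["d3"] * T,
        ]
    )


def p53_closed_form_reference(x0, R, domain_ranks, t):
    """Specialised per-domain solution formulas of the p53 module.

    Independent of the package's matrix-exponential path: scalar
    exponentials for P and T, variation-of-parameters result for M and N.
    """
    zP = 1.0 if domain_ranks[0] >= 1 else 0.0
    zN1 = 1.0 if domain_ranks[1] >= 1 else 0.0
    zN2 = 1.0 if domain_ranks[1] >= 2 else 0.0
    zT = 1.0 if domain_ranks[2] >= 1 else 0.0
    d1 = PAR["d10"] + PAR["d11"] * zN1 + PAR["d12"] * zN2
    p2 = PAR["p20"] + PAR["p21"] * zP
    p3 = PAR["p30"] + PAR["p31"] * zP
    k1 = PAR["k10"] - PAR["k11"] * zT
    d2R = PAR["d2"] * (1.0 + R)
    P0, M0, N0, T0 = x0
    a = d2R + k1
    P = PAR["p1"] / d1 + (P0 - PAR["p1"] / d1) * np.exp(-d1 * t)
    M = p2 / a + (M0 - p2 / a) * np.exp(-a * t)
    N = (
        k1 * p2 / (d2R * a)
        - (M0 - p2 / a) * np.exp(-a * t)
        + (N0 + M0 - p2 / d2R) * np.exp(-d2R * t)
    )
    T = p3 / PAR["d3"] + (T0 - p3 / PAR["d3"]) * np.exp(-PAR["d3"] * t)
    return np.array([P, M, N, T])


def quadratic_roots_n_equals_theta(theta, k1, p2):
    """Roots in R of  theta*d2^2*(1+R)^2 + theta*d2*k1*(1+R) - k1*p2 = 0.

    This is the condition "focal N coordinate equals theta", the quadratic
    whose positive root bounds RSP/SSP stress ranges.
    """
    d2 = PAR["d2"]
    # in u = 1 + R:  theta*d2^2 u^2 + theta*d2*k1 u - k1 p2 = 0
    a, b, c = theta * d2**2, theta * d2 * k1, -k1 * p2
    roots = np.roots([a, b, c])
    return sorted(float(u - 1.0) for u in roots if np.isreal(u))


@pytest.fixture(scope="session")
def p53():
    return builtin_p53_model()


@pytest.fixture(scope="session")
def regions(p53):
    return enumerate_delta_regions(p53)


def region_by_pins(regions, pins: set, theta_t_side: str | None = None):
    for r in regions:
        if set(r.pinned) != pins:
            continue
        if theta_t_side is None or r.side_of("theta_T") == theta_t_side:
            return r
    raise AssertionError("region not found")


@pytest.fixture(scope="session")
def ssp1_region(regions):
    """Delta(theta_P, M, theta_N2, T < theta_T)."""
    return region_by_pins(regions, {("P", "theta_P"), ("N", "theta_N2")}, "below")


@pytest.fixture(scope="session")
def ssp2_region(regions):
    """Delta(theta_P, M, theta_N2, T > theta_T)."""
    return region_by_pins(regions, {("P", "theta_P"), ("N", "theta_N2")}, "above")


@pytest.fixture(scope="session")
def triple_region(regions):
    return region_by_pins(
        regions, {("P", "theta_P"), ("N", "theta_N2"), ("T", "theta_T")}
    )
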
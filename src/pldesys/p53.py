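"""Bundled p53-MDM2-PTEN regulatory-module models.

Two versions of the same four-species module are provided:

* :func:`builtin_p53_model` -- the piece-wise linear switching model.
  Variables: nuclear p53 (``P``), cytoplasmic MDM2 (``M``), nuclear MDM2
  (``N``) and PTEN (``T``).  p53 is degraded at a rate stepped up by nuclear
  MDM2 (two thresholds on ``N``), p53 above its threshold boosts MDM2 and
  PTEN production, and PTEN above its threshold throttles MDM2 nuclear
  import.  External stress ``R`` scales MDM2 degradation by ``(1+R)``.
  With four thresholds the state space splits into 2 x 3 x 2 = 12 domains.

* :class:`NonlinearModel` -- the smooth ODE comparison model with Hill-type
  production (exponent 4 in ``P``) and a saturating transport factor
  (quadratic in ``T``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ModelError,
    PLDEModel,
    RateTerm,
    SwitchedCoefficient,
    SwitchingVariable,
    ThresholdSpec,
    VariableSpec,
)

__all__ = [
    "P53_PARAMS",
    "P53_THRESHOLDS",
    "P53_INITIAL",
    "builtin_p53_model",
    "NonlinearModel",
    "builtin_nonlinear_model",
    "nonlinear_rhs",
]

# rate constants of the switching model (s^-1; production in molecules/s)
P53_PARAMS = {
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

# thresholds (molecules)
P53_THRESHOLDS = {
    "theta_P": 4.5e4,
    "theta_N1": 4e4,
    "theta_N2": 8e4,
    "theta_T": 1e5,
}

# initial amounts (molecules)
P53_INITIAL = {"P": 2.6858e4, "M": 1.1166e4, "N": 1.5438e4, "T": 1.7240e5}


def builtin_p53_model() -> PLDEModel:
    """The p53 regulatory module as a validated :class:`PLDEModel`."""
    p = P53_PARAMS
    th = P53_THRESHOLDS
    x0 = P53_INITIAL
    k1 = SwitchedCoefficient(p["k10"], (("Z_T", -p["k11"]),))
    model = PLDEModel(
        name="p53",
        variables=[
            VariableSpec("P", x0["P"], "nuclear p53"),
            VariableSpec("M", x0["M"], "cytoplasmic MDM2"),
            VariableSpec("N", x0["N"], "nuclear MDM2"),
            VariableSpec("T", x0["T"], "PTEN"),
        ],
        thresholds=[
            ThresholdSpec("theta_P", "P", th["theta_P"]),
            ThresholdSpec("theta_N1", "N", th["theta_N1"]),
            ThresholdSpec("theta_N2", "N", th["theta_N2"]),
            ThresholdSpec("theta_T", "T", th["theta_T"]),
        ],
        switches=[
            SwitchingVariable("Z_P", "theta_P"),
            SwitchingVariable("Z_N1", "theta_N1"),
            SwitchingVariable("Z_N2", "theta_N2"),
            SwitchingVariable("Z_T", "theta_T"),
        ],
        equations={
            "P": [
                RateTerm("p1", "production", SwitchedCoefficient(p["p1"])),
                RateTerm(
                    "d1",
                    "first-order-loss",
                    SwitchedCoefficient(
                        p["d10"], (("Z_N1", p["d11"]), ("Z_N2", p["d12"]))
                    ),
                ),
            ],
            "M": [
                RateTerm(
                    "p2",
                    "production",
                    SwitchedCoefficient(p["p20"], (("Z_P", p["p21"]),)),
                ),
                RateTerm(
                    "d2",
                    "first-order-loss",
                    SwitchedCoefficient(p["d2"]),
                    stress_scaled=True,
                ),
                RateTerm("k1", "transfer-out", k1),
            ],
            "N": [
                RateTerm("k1", "transfer-in", k1, source="M"),
                RateTerm(
                    "d2",
                    "first-order-loss",
                    SwitchedCoefficient(p["d2"]),
                    stress_scaled=True,
                ),
            ],
            "T": [
                RateTerm(
                    "p3",
                    "production",
                    SwitchedCoefficient(p["p30"], (("Z_P", p["p31"]),)),
                ),
                RateTerm("d3", "first-order-loss", SwitchedCoefficient(p["d3"])),
            ],
        },
    )
    model.validate()
    return model


@dataclass(frozen=True)
class NonlinearModel:
    """Smooth comparison model of the p53 module.

    ``k2`` is the fourth-power half-saturation constant of the Hill factor
    ``P^4 / (P^4 + k2)`` and ``k3`` the squared half-saturation of the
    transport factor ``k3 / (k3 + T^2)``.  The default values are stored
    verbatim from the source parameter table; note that at molecule-count
    scale they leave both saturation factors essentially constant, which is
    dimensionally inconsistent with the stated oscillatory dynamics (see
    docs/methods.md).  Use :func:`builtin_nonlinear_model` with
    ``scale="rescaled"`` for a dimensionally consistent variant.
    """

    p1: float = 8.8
    p2: float = 440.0
    p3: float = 100.0
    d1: float = 1.375e-14
    d2: float = 1.375e-5
    d3: float = 3e-5
    k1: float = 1.925e-4
    k2: float = 1e-5  # "mol^4": already the 4th-power constant
    k3: float = 1.5e-5  # "mol^2": already the squared constant

    variable_names: tuple[str, ...] = ("P", "M", "N", "T")

    def __post_init__(self):
        for f in ("p1", "p2", "p3", "d1", "d2", "d3", "k1", "k2", "k3"):
            if getattr(self, f) <= 0:
                raise ModelError(f"nonlinear parameter {f!r} must be positive")

    def rhs(self, state, R: float = 0.0) -> np.ndarray:
        """Time derivatives for a nonnegative state ``[P, M, N, T]``."""
        x = np.asarray(state, dtype=float)
        if np.any(x < 0):
            raise ValueError("nonlinear model state must be nonnegative")
        P, M, N, T = x
        hill_p = P**4 / (P**4 + self.k2) if P > 0 else 0.0
        transport = self.k1 * self.k3 / (self.k3 + T**2)
        deg = self.d2 * (1.0 + R)
        return np.array(
            [
                self.p1 - self.d1 * N**2 * P,
                self.p2 * hill_p - deg * M - transport * M,
                transport * M - deg * N,
                self.p3 * hill_p - self.d3 * T,
            ]
        )


def builtin_nonlinear_model(scale: str = "printed") -> NonlinearModel:
    """Return the nonlinear model with its default or rescaled saturation.

    ``scale="printed"`` keeps the half-saturation constants exactly as
    published.  ``scale="rescaled"`` reads the printed magnitudes at the
    10^5-molecule scale (``k2 = (1e5)^4``, ``k3 = (1.5e5)^2``), which makes
    the Hill and transport factors active in the physiological range and
    reproduces the qualitative dynamics of the switching model.
    """
    if scale == "printed":
        return NonlinearModel()
    if scale == "rescaled":
        return NonlinearModel(k2=(1e5) ** 4, k3=(1.5e5) ** 2)
    raise ValueError(f"unknown scale {scale!r}: use 'printed' or 'rescaled'")


def nonlinear_rhs(state, R: float = 0.0, model: NonlinearModel | None = None) -> np.ndarray:
    """Convenience wrapper around :meth:`NonlinearModel.rhs`."""
    return (model or NonlinearModel()).rhs(state, R)
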
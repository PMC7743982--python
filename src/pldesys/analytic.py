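"""Closed-form per-domain solutions, focal points and switching times.

Inside one domain the dynamics are ``dx/dt = A x + b`` with constant A, b.
The solution is evaluated through the spectral decomposition of A (with a
matrix-exponential fallback for defective or singular A, so eigenvalue
collisions are handled without special cases), and the focal point is
``x* = -A^{-1} b`` -- the point every trajectory of the domain relaxes
toward, whether or not it lies inside the domain.

For variables whose within-domain dynamics are scalar first-order
(``dx/dt = p - d x``), the threshold-crossing time has the classical
logarithmic closed form; the general case is handled numerically on the
closed-form trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .model import DomainLabel, PLDEModel, evaluate_switching_state, linear_system

__all__ = [
    "AffineFlow",
    "FocalPoint",
    "SwitchingTime",
    "domain_flow",
    "closed_form_solution",
    "focal_point",
    "switching_time",
    "crossing_time_numeric",
    "UnsupportedDynamicsError",
]

_COND_LIMIT = 1e10


class UnsupportedDynamicsError(ValueError):
    """The requested analytic shortcut does not apply to these dynamics."""


class AffineFlow:
    """Exact flow of ``dx/dt = A x + b``.

    Evaluation is vectorised over time: ``flow(x0, t)`` accepts a scalar or
    an array of times and returns the state(s).
    """

    def __init__(self, A: np.ndarray, b: np.ndarray):
        self.A = np.asarray(A, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.n = self.A.shape[0]
        w, V = np.linalg.eig(self.A)
        self.eigenvalues = w
        self._spectral = False
        self.focal: np.ndarray | None = None
        invertible = np.min(np.abs(w)) > 1e-14 * max(np.max(np.abs(w)), 1.0)
        if invertible:
            self.focal = np.linalg.solve(self.A, -self.b)
            if np.linalg.cond(V) < _COND_LIMIT:
                self._spectral = True
                self._V = V
                self._Vinv = np.linalg.inv(V)
        # fallback: exponential of the augmented homogeneous system
        if not self._spectral:
            self._Maug = np.zeros((self.n + 1, self.n + 1))
            self._Maug[: self.n, : self.n] = self.A
            self._Maug[: self.n, self.n] = self.b

    @property
    def fastest_rate(self) -> float:
        """Largest |Re eigenvalue| -- sets the shortest relaxation time."""
        return float(np.max(np.abs(self.eigenvalues.real)))

    def __call__(self, x0: np.ndarray, t) -> np.ndarray:
        x0 = np.asarray(x0, dtype=float)
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self._spectral:
            c = self._Vinv @ (x0 - self.focal)
            phases = np.exp(np.outer(t_arr, self.eigenvalues))  # (m, n)
            out = self.focal + (phases * c) @ self._V.T
            out = np.real_if_close(out, tol=1e6).real
        else:
            aug = np.concatenate([x0, [1.0]])
            out = np.empty((t_arr.size, self.n))
            for i, ti in enumerate(t_arr):
                out[i] = (expm(self._Maug * ti) @ aug)[: self.n]
        return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out

    def rate(self, x: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(x, dtype=float) + self.b


@dataclass(frozen=True)
class FocalPoint:
    """Equilibrium of one domain's frozen affine dynamics.

    ``coordinates`` is ``None`` when A is singular (no focal point);
    ``in_domain`` records whether the point lies in its own domain, i.e.
    whether it is a regular stationary point of the switched system.
    """

    domain: DomainLabel
    coordinates: dict[str, float] | None
    in_domain: bool


@dataclass(frozen=True)
class SwitchingTime:
    """Analytic threshold-crossing verdict for a scalar first-order variable.

    ``time`` is ``None`` for the "never" cases; ``case`` is one of
    ``at-start``, ``at-focal`` (starts in steady state), ``focal-at-threshold``
    (reaches the threshold only asymptotically), ``crosses`` (finite time by
    the log formula) and ``same-side``.
    """

    variable: str
    threshold: str
    time: float | None
    case: str


def domain_flow(model: PLDEModel, domain: DomainLabel, R: float = 0.0) -> AffineFlow:
    A, b = linear_system(model, domain, R)
    return AffineFlow(A, b)


def closed_form_solution(model, domain, R, init, t):
    """Exact frozen-domain state at time(s) ``t`` from the ``init`` state."""
    flow = domain_flow(model, domain, R)
    x0 = model.state_array(init) if isinstance(init, dict) else np.asarray(init, float)
    return flow(x0, t)


def focal_point(model: PLDEModel, domain: DomainLabel, R: float = 0.0) -> FocalPoint:
    flow = domain_flow(model, domain, R)
    if flow.focal is None:
        return FocalPoint(domain, None, False)
    coords = model.state_dict(flow.focal)
    return FocalPoint(
        domain, coords, evaluate_switching_state(model, coords) == domain
    )


def _scalar_rate(model: PLDEModel, domain: DomainLabel, R: float, variable: str):
    """(decay rate d, asymptote x_inf) if the variable is scalar first-order."""
    A, b = linear_system(model, domain, R)
    i = model.variable_index(variable)
    off = np.delete(A[i], i)
    if np.any(off != 0.0):
        raise UnsupportedDynamicsError(
            f"within-domain dynamics of {variable!r} are not scalar first-order; "
            "use crossing_time_numeric"
        )
    d = -A[i, i]
    if d <= 0:
        raise UnsupportedDynamicsError(f"{variable!r} has no decay in this domain")
    return d, b[i] / d


def switching_time(
    model: PLDEModel,
    variable: str,
    domain: DomainLabel,
    R: float,
    init,
    threshold: str | None = None,
    rtol: float = 1e-12,
) -> SwitchingTime:
    """Analytic time at which a scalar first-order variable meets a threshold.

    Implements the four-case analysis: starting in the focal point or on the
    same side as it never crosses; a focal point exactly on the threshold is
    approached but never crossed; opposite sides give the finite logarithmic
    crossing time.
    """
    thr_specs = model.thresholds_on(variable)
    if threshold is None:
        if len(thr_specs) != 1:
            raise ValueError(
                f"{variable!r} has {len(thr_specs)} thresholds; pass threshold="
            )
        thr = thr_specs[0]
    else:
        thr = model.threshold_by_name(threshold)
        if thr.variable != variable:
            raise ValueError(f"threshold {thr.name!r} is not on {variable!r}")
    d, x_inf = _scalar_rate(model, domain, R, variable)
    x0 = float(init[variable]) if isinstance(init, dict) else float(
        np.asarray(init, float)[model.variable_index(variable)]
    )
    theta = thr.value
    scale = max(abs(x0), abs(x_inf), theta)
    if abs(x0 - theta) <= rtol * scale:
        return SwitchingTime(variable, thr.name, 0.0, "at-start")
    if abs(x0 - x_inf) <= rtol * scale:
        return SwitchingTime(variable, thr.name, None, "at-focal")
    if abs(x_inf - theta) <= rtol * scale:
        return SwitchingTime(variable, thr.name, None, "focal-at-threshold")
    if (x0 - theta) * (x_inf - theta) < 0:
        t = np.log((x0 - x_inf) / (theta - x_inf)) / d
        return SwitchingTime(variable, thr.name, float(t), "crosses")
    return SwitchingTime(variable, thr.name, None, "same-side")


def crossing_time_numeric(
    model: PLDEModel,
    domain: DomainLabel,
    R: float,
    init,
    threshold: str,
    t_max: float | None = None,
    atol: float = 1e-6,
    focal_rtol: float = 1e-9,
) -> float | None:
    """Earliest ``t > 0`` at which a variable meets its threshold.

    Works on the frozen-domain closed-form trajectory by sign bracketing on
    a sampling grid followed by root polishing (absolute tolerance ``atol``
    seconds).  Returns 0 when the variable starts exactly at the threshold
    with a nonzero velocity, and ``None`` when the trajectory relaxes to the
    focal point without a sign change.
    """
    thr = model.threshold_by_name(threshold)
    i = model.variable_index(thr.variable)
    flow = domain_flow(model, domain, R)
    x0 = model.state_array(init) if isinstance(init, dict) else np.asarray(init, float)
    g0 = x0[i] - thr.value
    if abs(g0) <= 1e-12 * max(abs(x0[i]), thr.value):
        if flow.rate(x0)[i] != 0.0:
            return 0.0
        g0 = 0.0
    sgn = np.sign(g0) if g0 != 0 else np.sign(flow.rate(x0)[i])
    if sgn == 0:
        return None  # resting exactly on the threshold

    def h(t):
        return sgn * (flow(x0, t)[i] - thr.value)

    rate = flow.fastest_rate
    dt = (1.0 / rate) / 20.0 if rate > 0 else (t_max or 1e6) / 1e4
    t_lo, h_lo = 0.0, abs(g0)
    chunk = 256
    while True:
        ts = t_lo + dt * np.arange(1, chunk + 1)
        if t_max is not None:
            ts = ts[ts <= t_max]
            if ts.size == 0:
                return None
        X = flow(x0, ts)
        H = sgn * (X[:, i] - thr.value)
        neg = np.nonzero(H <= 0.0)[0]
        if neg.size:
            k = neg[0]
            a = t_lo if k == 0 else ts[k - 1]
            b = ts[k]
            if h(a) <= 0:  # crossing essentially at the bracket edge
                return float(a)
            return float(brentq(h, a, b, xtol=atol))
        t_lo, h_lo = ts[-1], H[-1]
        if flow.focal is not None:
            ref = np.maximum(np.abs(flow.focal), 1.0)
            if np.max(np.abs(X[-1] - flow.focal) / ref) < focal_rtol:
                return None
        if t_max is not None and t_lo >= t_max:
            return None
        if flow.focal is None and t_lo > 1e16:
            return None
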
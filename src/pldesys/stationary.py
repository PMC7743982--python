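"""Transition graphs, regular and singular stationary points, stress ranges.

A *regular* stationary point (RSP) is a focal point that lies inside its own
domain; every RSP of a PLDE model is asymptotically stable.  A *singular*
stationary point (SSP) sits on one or more thresholds: the pinned switching
variables take fractional "singular" values in [0, 1] chosen so that the
flow balances exactly on the threshold face.  SSPs organise the limit-cycle
oscillations of the switched system.

Candidate faces (Δ-regions) pin one threshold per variable and constrain
every remaining threshold to a side.  No pre-screening shortcut is applied:
models with transport violate the assumptions of production/degradation-only
screening, so every region is scanned.  Stress-validity ranges are computed
numerically (grid scan plus bisection); closed-form quadratic roots are used
only as independent oracles in the test suite, keeping the module
model-agnostic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import root

from .analytic import FocalPoint, focal_point
from .model import (
    DomainLabel,
    ModelError,
    PLDEModel,
    affine_parts,
    evaluate_switching_state,
)

__all__ = [
    "Interval",
    "DeltaRegion",
    "StationaryPoint",
    "TransitionGraph",
    "transition_graph",
    "find_rsps",
    "rsp_existence_range",
    "enumerate_delta_regions",
    "solve_singular_state",
    "find_ssp",
    "ssp_existence_range",
    "singular_admissibility_range",
    "singular_value_polynomial",
    "side_condition_critical_z",
    "classify_ssp_stability",
]


@dataclass(frozen=True)
class Interval:
    """A stress interval with explicit open/closed endpoint flags."""

    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = False

    def contains(self, r: float) -> bool:
        lo_ok = r >= self.lo if self.lo_closed else r > self.lo
        hi_ok = r <= self.hi if self.hi_closed else r < self.hi
        return lo_ok and hi_ok

    def rounded(self, ndigits: int = 4) -> tuple[float, float]:
        hi = self.hi if math.isinf(self.hi) else round(self.hi, ndigits)
        return (round(self.lo, ndigits), hi)

    def __str__(self) -> str:
        lb = "[" if self.lo_closed else "("
        rb = "]" if self.hi_closed else ")"
        lo, hi = self.rounded()
        hi_s = "+inf" if math.isinf(self.hi) else f"{hi:.4f}"
        return f"{lb}{lo:.4f}, {hi_s}{rb}"


@dataclass(frozen=True)
class DeltaRegion:
    """A face of the threshold arrangement.

    ``pinned`` holds (variable, threshold-name) pairs held exactly at the
    threshold (at most one per variable); ``sides`` fixes each remaining
    threshold to "below" or "above".
    """

    pinned: tuple[tuple[str, str], ...]
    sides: tuple[tuple[str, str], ...]

    def pinned_variables(self) -> tuple[str, ...]:
        return tuple(v for v, _ in self.pinned)

    def pinned_threshold(self, variable: str) -> str | None:
        for v, t in self.pinned:
            if v == variable:
                return t
        return None

    def side_of(self, threshold: str) -> str | None:
        for t, s in self.sides:
            if t == threshold:
                return s
        return None

    def describe(self, model: PLDEModel) -> str:
        parts = []
        for v in model.variable_names:
            thr = self.pinned_threshold(v)
            if thr is not None:
                parts.append(thr)
                continue
            cons = [
                (t.name, self.side_of(t.name))
                for t in model.thresholds_on(v)
                if self.side_of(t.name) is not None
            ]
            if not cons:
                parts.append(v)
            else:
                # report the tightest informative bound
                sym = {"below": "<", "above": ">="}
                parts.append(
                    ",".join(f"{v}{sym[s]}{t}" for t, s in cons)
                )
        return "Delta(" + ", ".join(parts) + ")"


@dataclass
class StationaryPoint:
    """An RSP or SSP with location, anchor and stress-validity metadata."""

    kind: str  # "RSP" | "SSP"
    location: dict[str, float]
    domain: DomainLabel | None = None
    region: DeltaRegion | None = None
    singular_z: dict[str, float] = field(default_factory=dict)
    stress_range: Interval | None = None
    stability: str | None = None  # stable | unstable | numeric-undecided


@dataclass
class TransitionGraph:
    """Directed graph over domains: source -> domain holding its focal point."""

    graph: nx.DiGraph
    sinks: list[DomainLabel]
    cycles: list[list[DomainLabel]]
    flagged: list[DomainLabel]  # no edge: singular A or focal on a threshold
    focal_points: dict[tuple[int, ...], FocalPoint]


# ---------------------------------------------------------------------------
# transition graph and regular stationary points


def _focal_on_threshold(model: PLDEModel, coords: dict[str, float]) -> bool:
    for t in model.thresholds:
        if abs(coords[t.variable] - t.value) <= 1e-12 * t.value:
            return True
    return False


def transition_graph(model: PLDEModel, R: float = 0.0) -> TransitionGraph:
    g = nx.DiGraph()
    sinks, flagged = [], []
    focals = {}
    for dom in model.all_domains():
        g.add_node(dom)
    for dom in model.all_domains():
        fp = focal_point(model, dom, R)
        focals[dom.ranks] = fp
        if fp.coordinates is None or _focal_on_threshold(model, fp.coordinates):
            flagged.append(dom)
            continue
        dest = evaluate_switching_state(model, fp.coordinates)
        if dest == dom:
            sinks.append(dom)
        else:
            g.add_edge(dom, dest)
    cycles = [c for c in nx.simple_cycles(g) if len(c) > 1]
    return TransitionGraph(g, sinks, cycles, flagged, focals)


def find_rsps(model: PLDEModel, R: float = 0.0) -> list[StationaryPoint]:
    """All regular stationary points at stress ``R`` (each one stable)."""
    out = []
    for dom in model.all_domains():
        fp = focal_point(model, dom, R)
        if fp.coordinates is not None and fp.in_domain:
            out.append(
                StationaryPoint(
                    kind="RSP",
                    location=fp.coordinates,
                    domain=dom,
                    stability="stable",
                )
            )
    return out


# ---------------------------------------------------------------------------
# stress-validity ranges (numeric-first: grid scan + bisection)


def _runs(mask: np.ndarray):
    """Contiguous True runs as (first_index, last_index) pairs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts, ends))


def _bisect_boundary(pred, r_true: float, r_false: float, tol: float) -> float:
    while abs(r_false - r_true) > tol:
        mid = 0.5 * (r_true + r_false)
        if pred(mid):
            r_true = mid
        else:
            r_false = mid
    return 0.5 * (r_true + r_false)


def _intervals_from_grid(pred, grid: np.ndarray, mask: np.ndarray, tol: float,
                         open_ended_hi: bool) -> list[Interval]:
    out = []
    for i0, i1 in _runs(mask):
        if i0 == 0:
            lo = grid[0]
        else:
            lo = _bisect_boundary(pred, grid[i0], grid[i0 - 1], tol)
        if i1 == len(grid) - 1 and open_ended_hi:
            hi = math.inf
        elif i1 == len(grid) - 1:
            hi = grid[-1]
        else:
            hi = _bisect_boundary(pred, grid[i1], grid[i1 + 1], tol)
        out.append(
            Interval(lo, hi, lo_closed=bool(pred(lo)),
                     hi_closed=False if math.isinf(hi) else bool(pred(hi)))
        )
    return out


def rsp_existence_range(
    model: PLDEModel,
    domain: DomainLabel,
    r_max: float = 20.0,
    grid_step: float = 1e-3,
    tol: float = 1e-6,
) -> list[Interval]:
    """Stress values for which the domain's focal point is its own RSP.

    Scans ``R`` on a grid, then refines every boundary by bisection to
    ``tol``.  An interval reaching ``r_max`` is reported open-ended.
    Endpoints are meant to be displayed rounded to 4 decimals.
    """
    A0, A1, b0, b1 = affine_parts(model, domain)
    grid = np.arange(0.0, r_max + grid_step / 2, grid_step)
    fac = (1.0 + grid)[:, None, None]
    A = A0[None] + fac * A1[None]
    b = b0[None] + (1.0 + grid)[:, None] * b1[None]
    try:
        X = np.linalg.solve(A, -b[..., None])[..., 0]
    except np.linalg.LinAlgError:  # singular A somewhere: fall back pointwise
        X = np.full((grid.size, len(model.variables)), np.nan)
        for i, r in enumerate(grid):
            try:
                X[i] = np.linalg.solve(A0 + (1 + r) * A1, -(b0 + (1 + r) * b1))
            except np.linalg.LinAlgError:
                pass
    mask = np.ones(grid.size, dtype=bool)
    for v in domain.variables:
        iv = model.variable_index(v)
        thr = model.thresholds_on(v)
        r = domain.rank_of(v)
        vals = X[:, iv]
        if r > 0:
            mask &= vals >= thr[r - 1].value
        if r < len(thr):
            mask &= vals < thr[r].value
    mask &= np.all(np.isfinite(X), axis=1)

    def pred(rr: float) -> bool:
        fp = focal_point(model, domain, rr)
        return fp.coordinates is not None and fp.in_domain

    return _intervals_from_grid(pred, grid, mask, tol, open_ended_hi=True)


# ---------------------------------------------------------------------------
# Δ-regions and singular stationary points


def enumerate_delta_regions(model: PLDEModel) -> list[DeltaRegion]:
    """Every candidate SSP face: 1..k pinned thresholds (one per variable)
    crossed with all consistent side assignments of the unpinned thresholds."""
    dvars = model.domain_variables
    pin_choices = [[None, *model.thresholds_on(v)] for v in dvars]
    regions = []
    for pins in itertools.product(*pin_choices):
        if all(p is None for p in pins):
            continue
        pinned = tuple(
            (v, p.name) for v, p in zip(dvars, pins) if p is not None
        )
        # forced sides on pinned variables' remaining thresholds
        forced = []
        free_vars = []
        for v, p in zip(dvars, pins):
            if p is None:
                if model.thresholds_on(v):
                    free_vars.append(v)
                continue
            for t in model.thresholds_on(v):
                if t.name == p.name:
                    continue
                forced.append((t.name, "above" if p.value >= t.value else "below"))
        # consistent rank assignments for unpinned thresholded variables
        rank_choices = [range(len(model.thresholds_on(v)) + 1) for v in free_vars]
        for ranks in itertools.product(*rank_choices):
            sides = list(forced)
            for v, r in zip(free_vars, ranks):
                for j, t in enumerate(model.thresholds_on(v)):
                    sides.append((t.name, "above" if r >= j + 1 else "below"))
            regions.append(DeltaRegion(pinned=pinned, sides=tuple(sides)))
    return regions


class _SingularSystem:
    """Compiled steady-state residual of one Δ-region.

    Unknowns ``y = [z_1..z_k, x_1..x_m / scale]``: one singular switching
    value per pinned threshold, then the unpinned variables' amounts.
    """

    def __init__(self, model: PLDEModel, region: DeltaRegion):
        self.model = model
        self.region = region
        self.pinned_value = {
            v: model.threshold_by_name(t).value for v, t in region.pinned
        }
        self.z_unknowns = [
            model.switch_for_threshold(t).name for _, t in region.pinned
        ]
        self.x_unknowns = [
            v for v in model.variable_names if v not in self.pinned_value
        ]
        self.scale = float(np.mean([t.value for t in model.thresholds])) or 1.0
        self.z_fixed: dict[str, float] = {}
        for s in model.switches:
            if s.name in self.z_unknowns:
                continue
            thr = model.threshold_by_name(s.threshold)
            if thr.variable in self.pinned_value:
                self.z_fixed[s.name] = (
                    1.0 if self.pinned_value[thr.variable] >= thr.value else 0.0
                )
            else:
                side = region.side_of(thr.name)
                if side is None:
                    raise ModelError(
                        f"region gives no side for threshold {thr.name!r}"
                    )
                self.z_fixed[s.name] = 1.0 if side == "above" else 0.0

    def unpack(self, y: np.ndarray):
        k = len(self.z_unknowns)
        z = dict(self.z_fixed)
        z.update(zip(self.z_unknowns, (float(v) for v in y[:k])))
        x = dict(self.pinned_value)
        x.update(
            zip(self.x_unknowns, (float(v) * self.scale for v in y[k:]))
        )
        return z, x

    def residual(self, y: np.ndarray, R: float) -> np.ndarray:
        z, x = self.unpack(y)
        res = np.empty(len(self.model.variable_names))
        for i, var in enumerate(self.model.variable_names):
            acc = 0.0
            for term in self.model.equations.get(var, []):
                c = term.coefficient.value(z)
                if term.stress_scaled:
                    c *= 1.0 + R
                if term.kind == "production":
                    acc += c
                elif term.kind in ("first-order-loss", "transfer-out"):
                    acc -= c * x[var]
                else:
                    acc += c * x[term.source]
            res[i] = acc
        return res

    def default_guess(self) -> np.ndarray:
        ranks = {}
        for v in self.model.domain_variables:
            thr = self.model.thresholds_on(v)
            if v in self.pinned_value:
                pv = self.pinned_value[v]
                ranks[v] = sum(1 for t in thr if pv >= t.value)
            else:
                ranks[v] = sum(
                    1
                    for t in thr
                    if self.region.side_of(t.name) == "above"
                )
        dom = self.model.domain([ranks[v] for v in self.model.domain_variables])
        fp = focal_point(self.model, dom, 0.0)
        xg = []
        for v in self.x_unknowns:
            val = None
            if fp.coordinates is not None:
                val = fp.coordinates[v]
            if val is None or not np.isfinite(val) or val <= 0:
                val = self.scale
            xg.append(val / self.scale)
        return np.array([0.5] * len(self.z_unknowns) + xg)


def solve_singular_state(
    model: PLDEModel,
    region: DeltaRegion,
    R: float,
    guess: np.ndarray | None = None,
):
    """Solve the steady-state algebra of a Δ-region without admissibility checks.

    Returns ``(z, states, ok, y)``: the full switching-value map (singular
    values included), the full state map, a convergence flag, and the raw
    solution vector (useful for warm-starting continuation in R).
    """
    sys_ = _SingularSystem(model, region)
    y0 = sys_.default_guess() if guess is None else np.asarray(guess, float)
    sol = root(lambda y: sys_.residual(y, R), y0, method="hybr")
    y = sol.x
    res = sys_.residual(y, R)
    # equation scales: largest single term magnitude at the solution
    z, x = sys_.unpack(y)
    ok = bool(sol.success)
    if ok:
        for i, var in enumerate(model.variable_names):
            scale_i = 0.0
            for term in model.equations.get(var, []):
                c = term.coefficient.value(z)
                if term.stress_scaled:
                    c *= 1.0 + R
                mag = abs(c)
                if term.kind != "production":
                    ref = x[var] if term.kind != "transfer-in" else x[term.source]
                    mag = abs(c * ref)
                scale_i = max(scale_i, mag)
            if abs(res[i]) > 1e-8 * max(scale_i, 1e-300):
                ok = False
                break
    singular = {name: z[name] for name in sys_.z_unknowns}
    return z, x, ok, y, singular


_ZTOL = 1e-9


def find_ssp(
    model: PLDEModel,
    region: DeltaRegion,
    R: float,
    guess: np.ndarray | None = None,
) -> StationaryPoint | None:
    """SSP of a Δ-region at stress ``R``, or ``None``.

    A valid SSP requires (i) every singular switching value in [0, 1] and
    (ii) every unpinned variable on the side its region prescribes
    ("above" includes the threshold itself, matching the at-or-above
    switching convention; "below" is strict).
    """
    z, x, ok, _, singular = solve_singular_state(model, region, R, guess)
    if not ok or not _admissible(model, region, x, singular):
        return None
    singular = {k: min(max(v, 0.0), 1.0) for k, v in singular.items()}
    return StationaryPoint(
        kind="SSP", location=x, region=region, singular_z=singular
    )


def _admissible(
    model: PLDEModel,
    region: DeltaRegion,
    x: dict[str, float],
    singular: dict[str, float],
) -> bool:
    for val in singular.values():
        if not -_ZTOL <= val <= 1.0 + _ZTOL:
            return False
    pinned_vars = dict(region.pinned)
    for t in model.thresholds:
        side = region.side_of(t.name)
        if side is None or t.variable in pinned_vars:
            continue
        v = x[t.variable]
        if side == "above" and v < t.value * (1 - 1e-12):
            return False
        if side == "below" and v >= t.value * (1 - 1e-12):
            return False
    return True


def _scan_region(
    model: PLDEModel,
    region: DeltaRegion,
    check,
    r_max: float,
    grid_step: float,
    tol: float,
) -> list[Interval]:
    """Grid scan of an SSP predicate with warm-started continuation in R."""
    grid = np.arange(0.0, r_max + grid_step / 2, grid_step)
    mask = np.zeros(grid.size, dtype=bool)
    warm: np.ndarray | None = None
    for i, rr in enumerate(grid):
        z, x, ok, y, singular = solve_singular_state(model, region, rr, warm)
        if ok:
            warm = y
        mask[i] = ok and check(x, singular)

    def pred(rr: float) -> bool:
        z, x, ok, _, singular = solve_singular_state(model, region, rr, warm)
        return ok and check(x, singular)

    return _intervals_from_grid(pred, grid, mask, tol, open_ended_hi=True)


def ssp_existence_range(
    model: PLDEModel,
    region: DeltaRegion,
    r_max: float = 15.0,
    grid_step: float = 1e-3,
    tol: float = 1e-6,
) -> list[Interval]:
    """Stress values for which the region carries a valid SSP.

    Grid scan (default step 0.001) with warm-started continuation, each
    boundary refined by bisection to ``tol``; endpoints are displayed
    rounded to 4 decimals.
    """
    return _scan_region(
        model,
        region,
        lambda x, singular: _admissible(model, region, x, singular),
        r_max,
        grid_step,
        tol,
    )


def singular_admissibility_range(
    model: PLDEModel,
    region: DeltaRegion,
    switch: str,
    r_max: float = 15.0,
    grid_step: float = 1e-3,
    tol: float = 1e-6,
) -> list[Interval]:
    """Stress window in which one singular switching value stays in [0, 1],
    ignoring the region's side conditions and the other switching values."""
    return _scan_region(
        model,
        region,
        lambda x, singular: switch in singular
        and -_ZTOL <= singular[switch] <= 1 + _ZTOL,
        r_max,
        grid_step,
        tol,
    )


def singular_value_polynomial(
    model: PLDEModel,
    region: DeltaRegion,
    switch: str,
    degree: int = 2,
    r_points: np.ndarray | None = None,
) -> np.ndarray:
    """Polynomial coefficients (ascending powers of R) of a singular
    switching value.

    The singular value of an affine model is a rational function of stress;
    where its denominator is R-independent (true for the bundled model's
    worked region) it is an exact polynomial.  The fit residual is checked
    and a ``ValueError`` raised if the polynomial model does not hold.
    """
    if r_points is None:
        r_points = np.linspace(0.0, 2.0, degree + 3)
    vals = []
    warm = None
    for rr in r_points:
        z, x, ok, y, singular = solve_singular_state(model, region, rr, warm)
        if not ok:
            raise ValueError(f"singular system unsolvable at R={rr}")
        warm = y
        vals.append(singular[switch])
    coeffs = np.polynomial.polynomial.polyfit(r_points, vals, degree)
    fit = np.polynomial.polynomial.polyval(r_points, coeffs)
    if np.max(np.abs(fit - vals)) > 1e-8 * max(1.0, np.max(np.abs(vals))):
        raise ValueError(
            f"singular value of {switch!r} is not degree-{degree} polynomial in R"
        )
    return coeffs


def side_condition_critical_z(
    model: PLDEModel, region: DeltaRegion, threshold: str
) -> tuple[str, float]:
    """Singular switching value at which an unpinned variable's steady state
    sits exactly on its threshold.

    Only supports variables whose steady-state equation involves no other
    unpinned variable (e.g. scalar production/decay), in which case the
    equation is affine in exactly one singular switching value.
    """
    thr = model.threshold_by_name(threshold)
    var = thr.variable
    sys_ = _SingularSystem(model, region)
    if var in sys_.pinned_value:
        raise ValueError(f"{threshold!r} is pinned in this region")

    def eq_residual(zval: dict[str, float]) -> float:
        acc = 0.0
        for term in model.equations.get(var, []):
            c = term.coefficient.value(zval)
            if term.kind == "production":
                acc += c
            elif term.kind in ("first-order-loss", "transfer-out"):
                acc -= c * thr.value
            else:
                src = term.source
                if src in sys_.pinned_value:
                    acc += c * sys_.pinned_value[src]
                else:
                    raise ValueError(
                        f"steady state of {var!r} couples to unpinned {src!r}"
                    )
        return acc

    base = dict(sys_.z_fixed, **{n: 0.0 for n in sys_.z_unknowns})
    r0 = eq_residual(base)
    slopes = {}
    for name in sys_.z_unknowns:
        probe = dict(base, **{name: 1.0})
        s = eq_residual(probe) - r0
        if s != 0.0:
            slopes[name] = s
    if len(slopes) != 1:
        raise ValueError(
            f"steady state of {var!r} must depend on exactly one singular "
            f"switching value (found {sorted(slopes)})"
        )
    (name, s), = slopes.items()
    return name, -r0 / s


# ---------------------------------------------------------------------------
# empirical SSP stability


def classify_ssp_stability(
    model: PLDEModel,
    ssp: StationaryPoint,
    R: float,
    radius: float = 0.01,
    n_probes: int = 3,
    seed: int = 0,
    t_end: float = 2e6,
) -> str:
    """Probe an SSP with perturbed simulations and classify its stability.

    Initial states are drawn in a ball of relative ``radius`` (scaled per
    variable by its nearest threshold, or its SSP value when unthresholded)
    around the SSP.  "stable" requires every probe to settle on a limit
    cycle straddling all the SSP's pinned thresholds; probes attracted to
    other stationary behaviour give "unstable"; anything else is
    "numeric-undecided".
    """
    from .simulate import detect_oscillation, simulate  # local: avoid cycle

    rng = np.random.default_rng(seed)
    scales = {}
    for v in model.variable_names:
        thr = model.thresholds_on(v)
        scales[v] = min(thr, key=lambda t: abs(t.value - ssp.location[v])).value if thr else abs(
            ssp.location[v]
        )
    pinned_thr = [t for _, t in (ssp.region.pinned if ssp.region else ())]
    verdicts = []
    for _ in range(max(n_probes, 1)):
        x0 = {
            v: ssp.location[v] + radius * scales[v] * rng.uniform(-1, 1)
            for v in model.variable_names
        }
        if radius == 0.0:
            x0 = dict(ssp.location)
        traj = simulate(model, x0, R, t_end)
        summ = detect_oscillation(traj, model=model)
        if summ.classification == "limit-cycle" and all(
            t in summ.anchor_thresholds for t in pinned_thr
        ):
            verdicts.append("stable")
        elif summ.classification in ("fixed-point", "limit-cycle"):
            verdicts.append("unstable")
        else:
            verdicts.append("undecided")
    if all(v == "stable" for v in verdicts):
        return "stable"
    if any(v == "unstable" for v in verdicts):
        return "unstable"
    return "numeric-undecided"
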
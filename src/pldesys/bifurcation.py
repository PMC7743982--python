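"""Stress-parameter sweeps and bifurcation diagrams.

For each stress value the analytic stationary candidates (RSPs, SSPs) are
computed first, then each candidate is probed by a simulation seeded next to
it; attractors that survive probing are recorded with their post-transient
extrema and period and stitched into branches across adjacent grid points by
attractor identity.  Undecided classifications leave gaps, never
interpolated records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model import PLDEModel, DomainLabel
from .p53 import NonlinearModel
from .simulate import detect_oscillation, simulate, simulate_nonlinear
from .stationary import (
    DeltaRegion,
    enumerate_delta_regions,
    find_rsps,
    find_ssp,
)

__all__ = [
    "BranchRecord",
    "BifurcationBranch",
    "sweep",
    "sweep_nonlinear",
    "coexistence_report",
    "branch_table",
    "cycle_onset",
    "plot_bifurcation",
]


@dataclass
class BranchRecord:
    R: float
    minima: dict[str, float]
    maxima: dict[str, float]
    period: float | None


@dataclass
class BifurcationBranch:
    branch_id: int
    attractor_type: str  # "RSP" | "SSP-cycle"
    anchor: object  # DomainLabel or DeltaRegion
    records: list[BranchRecord] = field(default_factory=list)

    @property
    def r_values(self) -> np.ndarray:
        return np.array([rec.R for rec in self.records])


def _anchor_key(kind: str, anchor) -> tuple:
    if isinstance(anchor, DomainLabel):
        return (kind, "domain", anchor.ranks)
    if isinstance(anchor, DeltaRegion):
        return (kind, "region", anchor.pinned, anchor.sides)
    return (kind, "other", anchor)


def _cycle_respects_sides(model, region: DeltaRegion, summary) -> bool:
    """Post-transient cycle must straddle the pinned thresholds and stay on
    the prescribed side of every other threshold."""
    pinned = dict(region.pinned)
    for v, t in region.pinned:
        if t not in summary.anchor_thresholds:
            return False
    for t in model.thresholds:
        side = region.side_of(t.name)
        if side is None or t.variable in pinned:
            continue
        mn, mx = summary.extrema[t.variable]
        if side == "below" and mx >= t.value:
            return False
        if side == "above" and mn < t.value:
            return False
    return True


def sweep(
    model: PLDEModel,
    r_grid,
    regions: list[DeltaRegion] | None = None,
    t_end: float = 1.5e6,
    rsp_probe_t: float = 4e5,
    perturb: float = 0.01,
    probe_initial: bool = True,
    sample_dt: float = 600.0,
) -> list[BifurcationBranch]:
    """Sweep stress over ``r_grid`` and classify attractors at each value.

    RSP candidates are probed from a ``perturb``-relative offset and must
    relax back; SSP candidates are probed from the SSP offset by ``perturb``
    and must sustain a limit cycle consistent with their region.  With
    ``probe_initial`` the model's initial state is probed too, attributed to
    whichever candidate attractor captures it.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    if regions is None:
        regions = [reg for reg in enumerate_delta_regions(model) if len(reg.pinned) >= 2]

    branches: list[BifurcationBranch] = []
    open_branches: dict[tuple, BifurcationBranch] = {}
    next_id = 0

    for R in r_grid:
        found: dict[tuple, BranchRecord] = {}

        for rsp in find_rsps(model, R):
            x0 = {v: val * (1 + perturb) for v, val in rsp.location.items()}
            traj = simulate(model, x0, R, rsp_probe_t, sample_dt=sample_dt)
            final = traj.states[-1]
            target = model.state_array(rsp.location)
            ref = np.maximum(np.abs(target), 1.0)
            if np.max(np.abs(final - target) / ref) < perturb:
                key = _anchor_key("RSP", rsp.domain)
                found[key] = BranchRecord(
                    float(R), dict(rsp.location), dict(rsp.location), None
                )

        for region in regions:
            ssp = find_ssp(model, region, R)
            if ssp is None:
                continue
            x0 = {v: val * (1 + perturb) for v, val in ssp.location.items()}
            traj = simulate(model, x0, R, t_end, sample_dt=sample_dt)
            summ = detect_oscillation(traj, model=model)
            if summ.classification == "limit-cycle" and _cycle_respects_sides(
                model, region, summ
            ):
                key = _anchor_key("SSP-cycle", region)
                found[key] = BranchRecord(
                    float(R),
                    {v: mn for v, (mn, mx) in summ.extrema.items()},
                    {v: mx for v, (mn, mx) in summ.extrema.items()},
                    summ.period,
                )

        if probe_initial and not found:
            # nothing survived probing; see where the nominal initial state goes
            traj = simulate(model, model.initial_state(), R, t_end, sample_dt=sample_dt)
            summ = detect_oscillation(traj, model=model)
            if summ.classification == "limit-cycle":
                key = ("SSP-cycle", "anchors", tuple(sorted(summ.anchor_thresholds)))
                found[key] = BranchRecord(
                    float(R),
                    {v: mn for v, (mn, mx) in summ.extrema.items()},
                    {v: mx for v, (mn, mx) in summ.extrema.items()},
                    summ.period,
                )

        # stitch into branches
        for key, rec in found.items():
            if key in open_branches:
                open_branches[key].records.append(rec)
            else:
                br = BifurcationBranch(next_id, key[0], key[2:], [rec])
                next_id += 1
                branches.append(br)
                open_branches[key] = br
        for key in list(open_branches):
            if key not in found:
                del open_branches[key]

    return branches


def sweep_nonlinear(
    nl_model: NonlinearModel,
    r_grid,
    t_end: float = 2e6,
    seed: int = 0,
    n_starts: int = 4,
    perturb: float = 0.01,
    init=None,
) -> list[BifurcationBranch]:
    """Bifurcation sweep of the smooth comparison model.

    Steady states are located by root solving from several seeded starting
    points, probed by simulation for stability; a limit cycle is probed from
    the supplied (or default) initial state.  Branch identity for steady
    states is carried across grid points by proximity.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    rng = np.random.default_rng(seed)
    if init is None:
        init = np.array([2.6858e4, 1.1166e4, 1.5438e4, 1.7240e5])
    init = np.asarray(init, dtype=float)

    branches: list[BifurcationBranch] = []
    open_fixed: list[tuple[np.ndarray, BifurcationBranch]] = []
    cycle_branch: BifurcationBranch | None = None
    next_id = 0

    for R in r_grid:
        starts = [init] + [
            init * np.exp(rng.uniform(-1.5, 1.5, size=init.size))
            for _ in range(n_starts - 1)
        ]
        steady: list[np.ndarray] = []
        for x0 in starts:
            sol = root(lambda y: nl_model.rhs(np.abs(y), R), x0, method="hybr")
            if not sol.success:
                continue
            xs = np.abs(sol.x)
            if np.max(np.abs(nl_model.rhs(xs, R))) > 1e-6:
                continue
            if any(np.allclose(xs, s, rtol=1e-4) for s in steady):
                continue
            steady.append(xs)

        stable_states = []
        for xs in steady:
            traj = simulate_nonlinear(
                nl_model, xs * (1 + perturb), R, t_end / 4, sample_dt=3600.0
            )
            ref = np.maximum(np.abs(xs), 1.0)
            if np.max(np.abs(traj.states[-1] - xs) / ref) < 10 * perturb:
                stable_states.append(xs)

        new_open: list[tuple[np.ndarray, BifurcationBranch]] = []
        for xs in stable_states:
            rec = BranchRecord(
                float(R),
                dict(zip(nl_model.variable_names, xs)),
                dict(zip(nl_model.variable_names, xs)),
                None,
            )
            match = None
            for prev, br in open_fixed:
                # proximity in log-amounts: same branch if no component moved
                # more than ~3x between adjacent grid points
                if np.max(np.abs(np.log((xs + 1.0) / (prev + 1.0)))) < 1.1:
                    match = br
                    break
            if match is None:
                match = BifurcationBranch(next_id, "steady-state", None, [])
                next_id += 1
                branches.append(match)
            match.records.append(rec)
            new_open.append((xs, match))
        open_fixed = new_open

        traj = simulate_nonlinear(nl_model, init, R, t_end, sample_dt=1800.0)
        mid = traj.states[traj.times >= traj.times[-1] / 2]
        amp = (mid.max(axis=0) - mid.min(axis=0)) / np.maximum(
            np.abs(mid).max(axis=0), 1e-300
        )
        if np.any(amp > 1e-2):
            # oscillatory response from the nominal initial condition
            y = mid[:, 0] - 0.5 * (mid[:, 0].max() + mid[:, 0].min())
            up = np.nonzero((y[:-1] < 0) & (y[1:] >= 0))[0]
            tw = traj.times[traj.times >= traj.times[-1] / 2]
            period = float(np.mean(np.diff(tw[up]))) if up.size >= 3 else None
            rec = BranchRecord(
                float(R),
                dict(zip(nl_model.variable_names, mid.min(axis=0))),
                dict(zip(nl_model.variable_names, mid.max(axis=0))),
                period,
            )
            if cycle_branch is None:
                cycle_branch = BifurcationBranch(next_id, "oscillation", None, [])
                next_id += 1
                branches.append(cycle_branch)
            cycle_branch.records.append(rec)
        else:
            cycle_branch = None

    return branches


def coexistence_report(branches: list[BifurcationBranch]) -> dict[float, list[tuple]]:
    """Per-stress multiset of coexisting attractors (multistability map)."""
    out: dict[float, list[tuple]] = {}
    for br in branches:
        for rec in br.records:
            out.setdefault(rec.R, []).append((br.attractor_type, br.branch_id))
    return {r: sorted(v) for r, v in sorted(out.items())}


def branch_table(branches: list[BifurcationBranch]) -> pd.DataFrame:
    rows = []
    for br in branches:
        for rec in br.records:
            for v in rec.minima:
                rows.append(
                    {
                        "branch": br.branch_id,
                        "type": br.attractor_type,
                        "R": rec.R,
                        "var": v,
                        "min": rec.minima[v],
                        "max": rec.maxima[v],
                        "period": rec.period if rec.period is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def cycle_onset(branches: list[BifurcationBranch], region: DeltaRegion) -> float | None:
    """Smallest grid stress at which the cycle of ``region`` survives."""
    key_tail = _anchor_key("SSP-cycle", region)[2:]
    rs = [
        rec.R
        for br in branches
        if br.attractor_type == "SSP-cycle" and br.anchor == key_tail
        for rec in br.records
    ]
    return min(rs) if rs else None


def plot_bifurcation(branches, variables=("P", "N", "T"), thresholds=None):
    """Three-panel min/max bifurcation diagram (one panel per variable)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(variables), 1, figsize=(7, 9), sharex=True)
    for ax, v in zip(np.atleast_1d(axes), variables):
        for br in branches:
            rs = br.r_values
            mn = [rec.minima.get(v, np.nan) for rec in br.records]
            mx = [rec.maxima.get(v, np.nan) for rec in br.records]
            ax.plot(rs, mn, ".", ms=2, label=f"branch {br.branch_id} min")
            ax.plot(rs, mx, ".", ms=2, label=f"branch {br.branch_id} max")
        if thresholds:
            for name, (var, val) in thresholds.items():
                if var == v:
                    ax.axhline(val, color="0.6", lw=0.7, ls="--")
        ax.set_ylabel(v)
    np.atleast_1d(axes)[-1].set_xlabel("stress R (a.u.)")
    fig.tight_layout()
    return fig
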
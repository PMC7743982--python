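"""Reproducible stratified test fixtures for oracle-equivalence suites.

States are drawn uniformly inside each domain's bounding box (kept within a
decade of the outermost thresholds) so that every domain of the model is
exercised; stress values cycle through the qualitative regime windows of
the bundled p53 model (single low-stress RSP, the window where the upper
cycle coexists, the mid-stress RSP window, the wide oscillatory window, and
the high-stress RSP regime).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PLDEModel

__all__ = ["FixtureCase", "fixture_generator", "P53_REGIME_WINDOWS"]

# stress regime windows of the bundled model, as found by its own
# stationary analysis (RSP and SSP existence ranges)
P53_REGIME_WINDOWS = (
    (0.0, 0.8635),
    (0.8635, 1.0322),
    (1.0322, 1.9154),
    (1.9154, 7.7038),
    (7.7038, 12.0),
)


@dataclass(frozen=True)
class FixtureCase:
    state: dict[str, float]
    R: float
    domain_ranks: tuple[int, ...]


def fixture_generator(
    seed: int,
    count: int,
    model: PLDEModel | None = None,
    r_windows=P53_REGIME_WINDOWS,
) -> list[FixtureCase]:
    """``count`` reproducible (state, R) cases, stratified over all domains.

    Domains are visited round-robin (so ``count`` >= the number of domains
    guarantees at least one case per domain); amounts stay nonnegative and
    within a factor of ten of the thresholds.
    """
    if count <= 0:
        raise ValueError("count must be positive")
    if model is None:
        from .p53 import builtin_p53_model

        model = builtin_p53_model()
    rng = np.random.default_rng(seed)
    domains = list(model.all_domains())
    all_thr = [t.value for t in model.thresholds]
    lo_global, hi_global = min(all_thr) / 10.0, max(all_thr) * 10.0
    cases = []
    for i in range(count):
        dom = domains[i % len(domains)]
        state = {}
        for v in model.variable_names:
            thr = model.thresholds_on(v)
            if not thr:
                state[v] = float(rng.uniform(lo_global, hi_global))
                continue
            r = dom.rank_of(v)
            lo = thr[r - 1].value if r > 0 else thr[0].value / 10.0
            hi = thr[r].value if r < len(thr) else thr[-1].value * 10.0
            state[v] = float(rng.uniform(lo, hi))
        lo_r, hi_r = r_windows[i % len(r_windows)]
        cases.append(
            FixtureCase(state=state, R=float(rng.uniform(lo_r, hi_r)),
                        domain_ranks=dom.ranks)
        )
    return cases
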
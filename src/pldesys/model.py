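"""Declarative piece-wise linear differential-equation (PLDE) models.

A PLDE model describes a set of molecular species whose dynamics are affine
within each *domain* of state space.  Domains are delimited by thresholds on
the species amounts; each threshold carries a binary switching variable
``Z`` that is 0 below the threshold and 1 at or above it.  Rate coefficients
are affine in the switching variables, so inside a fixed domain the system
reduces to ``dx/dt = A x + b`` with constant ``A`` and ``b``.

An external, dimensionless stress intensity ``R >= 0`` may scale selected
first-order rates by ``(1 + R)``; it is the natural bifurcation parameter of
such models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelError",
    "VariableSpec",
    "ThresholdSpec",
    "SwitchingVariable",
    "SwitchedCoefficient",
    "RateTerm",
    "PLDEModel",
    "DomainLabel",
    "evaluate_switching_state",
    "effective_parameters",
    "affine_parts",
    "linear_system",
]

RATE_KINDS = ("production", "first-order-loss", "transfer-out", "transfer-in")


class ModelError(ValueError):
    """Raised when a model definition violates its structural invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """A molecular species tracked by the model.

    Amounts are molecule counts (dimensionless numbers of molecules).
    """

    name: str
    initial: float
    description: str = ""


@dataclass(frozen=True)
class ThresholdSpec:
    """A switching threshold on one variable, in molecules."""

    name: str
    variable: str
    value: float


@dataclass(frozen=True)
class SwitchingVariable:
    """Binary indicator attached to a threshold: 0 below, 1 at-or-above."""

    name: str
    threshold: str


@dataclass(frozen=True)
class SwitchedCoefficient:
    """Rate coefficient affine in the switching variables.

    ``base`` is the coefficient with every switch at 0; each entry of
    ``deltas`` adds ``increment * Z`` for the named switching variable.
    Units: s^-1 for first-order terms, molecules s^-1 for production (the
    bundled model's source prints production rates as s^-1; we document the
    molecules s^-1 reading in the field descriptions).
    """

    base: float
    deltas: tuple[tuple[str, float], ...] = ()

    def value(self, z: Mapping[str, float]) -> float:
        return self.base + sum(inc * z[name] for name, inc in self.deltas)

    def switch_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.deltas)


@dataclass(frozen=True)
class RateTerm:
    """One additive term of a variable's rate law.

    kind:
        ``production``       constant inflow (coefficient, molecules/s)
        ``first-order-loss`` outflow proportional to the variable itself
        ``transfer-out``     mass leaving the variable (paired elsewhere)
        ``transfer-in``      mass arriving from ``source``
    ``stress_scaled`` multiplies the resolved coefficient by ``(1 + R)``.
    """

    name: str
    kind: str
    coefficient: SwitchedCoefficient
    source: str | None = None
    stress_scaled: bool = False


@dataclass(frozen=True)
class DomainLabel:
    """Discrete subsystem identifier: per-variable threshold rank vector.

    ``ranks[i]`` counts how many of ``variables[i]``'s thresholds lie at or
    below the current amount (the at-threshold state counts as *above*, the
    >= convention used throughout the package).
    """

    variables: tuple[str, ...]
    ranks: tuple[int, ...]

    def rank_of(self, variable: str) -> int:
        return self.ranks[self.variables.index(variable)]

    def with_rank(self, variable: str, rank: int) -> "DomainLabel":
        i = self.variables.index(variable)
        ranks = list(self.ranks)
        ranks[i] = rank
        return DomainLabel(self.variables, tuple(ranks))

    def __str__(self) -> str:  # {020}-style compact notation
        return "{" + "".join(str(r) for r in self.ranks) + "}"


@dataclass
class PLDEModel:
    """A piece-wise linear model with state-dependent switching."""

    variables: list[VariableSpec]
    thresholds: list[ThresholdSpec]
    switches: list[SwitchingVariable]
    equations: dict[str, list[RateTerm]]
    name: str = "model"

    # ---- basic lookups -------------------------------------------------

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable_index(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise ModelError(f"unknown variable {name!r}") from None

    def initial_state(self) -> dict[str, float]:
        return {v.name: v.initial for v in self.variables}

    def thresholds_on(self, variable: str) -> list[ThresholdSpec]:
        """Thresholds on one variable, in increasing value order."""
        return sorted(
            (t for t in self.thresholds if t.variable == variable),
            key=lambda t: t.value,
        )

    @property
    def domain_variables(self) -> tuple[str, ...]:
        """Variables that carry at least one threshold, in model order."""
        with_thr = {t.variable for t in self.thresholds}
        return tuple(v.name for v in self.variables if v.name in with_thr)

    def threshold_by_name(self, name: str) -> ThresholdSpec:
        for t in self.thresholds:
            if t.name == name:
                return t
        raise ModelError(f"unknown threshold {name!r}")

    def switch_for_threshold(self, threshold: str) -> SwitchingVariable:
        for s in self.switches:
            if s.threshold == threshold:
                return s
        raise ModelError(f"no switching variable attached to threshold {threshold!r}")

    def switch_by_name(self, name: str) -> SwitchingVariable:
        for s in self.switches:
            if s.name == name:
                return s
        raise ModelError(f"unknown switching variable {name!r}")

    # ---- domains -------------------------------------------------------

    def all_domains(self) -> Iterator[DomainLabel]:
        dvars = self.domain_variables
        ranges = [range(len(self.thresholds_on(v)) + 1) for v in dvars]
        for ranks in itertools.product(*ranges):
            yield DomainLabel(dvars, ranks)

    def n_domains(self) -> int:
        return int(
            np.prod([len(self.thresholds_on(v)) + 1 for v in self.domain_variables])
        )

    def domain(self, ranks: Sequence[int]) -> DomainLabel:
        dvars = self.domain_variables
        ranks = tuple(int(r) for r in ranks)
        if len(ranks) != len(dvars):
            raise ModelError(f"expected {len(dvars)} rank components, got {len(ranks)}")
        for v, r in zip(dvars, ranks):
            if not 0 <= r <= len(self.thresholds_on(v)):
                raise ModelError(f"rank {r} out of range for variable {v!r}")
        return DomainLabel(dvars, ranks)

    def switch_values(self, domain: DomainLabel) -> dict[str, int]:
        """Binary value of every switching variable in the given domain."""
        z = {}
        for s in self.switches:
            thr = self.threshold_by_name(s.threshold)
            siblings = self.thresholds_on(thr.variable)
            j = siblings.index(thr)
            z[s.name] = 1 if domain.rank_of(thr.variable) >= j + 1 else 0
        return z

    def state_array(self, state: Mapping[str, float]) -> np.ndarray:
        missing = [n for n in self.variable_names if n not in state]
        if missing:
            raise ModelError(f"state is missing variable {missing[0]!r}")
        return np.array([float(state[n]) for n in self.variable_names])

    def state_dict(self, x: np.ndarray) -> dict[str, float]:
        return dict(zip(self.variable_names, (float(v) for v in x)))

    # ---- validation ----------------------------------------------------

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelError("variable names are not unique")
        for v in self.variables:
            if v.initial < 0:
                raise ModelError(f"initial amount of {v.name!r} is negative")
        tnames = [t.name for t in self.thresholds]
        if len(set(tnames)) != len(tnames):
            raise ModelError("threshold names are not unique")
        for t in self.thresholds:
            if t.value <= 0:
                raise ModelError(f"threshold {t.name!r} must be positive")
            if t.variable not in names:
                raise ModelError(f"threshold {t.name!r} refers to unknown variable {t.variable!r}")
        for v in names:
            vals = [t.value for t in self.thresholds_on(v)]
            if len(set(vals)) != len(vals):
                raise ModelError(f"thresholds on {v!r} must have distinct values")
        snames = [s.name for s in self.switches]
        if len(set(snames)) != len(snames):
            raise ModelError("switching-variable names are not unique")
        for s in self.switches:
            self.threshold_by_name(s.threshold)
        for var, terms in self.equations.items():
            if var not in names:
                raise ModelError(f"equation for unknown variable {var!r}")
            for term in terms:
                if term.kind not in RATE_KINDS:
                    raise ModelError(f"unknown rate kind {term.kind!r} in equation of {var!r}")
                if term.kind == "transfer-in":
                    if term.source is None:
                        raise ModelError(f"transfer-in term {term.name!r} needs a source")
                    if term.source not in names:
                        raise ModelError(f"transfer-in source {term.source!r} is unknown")
                for sname in term.coefficient.switch_names():
                    self.switch_by_name(sname)
        self._check_transfer_pairing()
        self._check_positive_coefficients()

    def _check_transfer_pairing(self) -> None:
        outs = {}
        ins = {}
        for var, terms in self.equations.items():
            for term in terms:
                if term.kind == "transfer-out":
                    outs[(var, term.name)] = term.coefficient
                elif term.kind == "transfer-in":
                    ins[(term.source, term.name)] = term.coefficient
        for key, coeff in outs.items():
            if key not in ins:
                raise ModelError(
                    f"transfer-out {key[1]!r} on {key[0]!r} has no matching transfer-in"
                )
            if ins[key] != coeff:
                raise ModelError(
                    f"transfer {key[1]!r} moves mass with mismatched coefficients"
                )
        for key in ins:
            if key not in outs:
                raise ModelError(
                    f"transfer-in {key[1]!r} from {key[0]!r} has no matching transfer-out"
                )

    def _check_positive_coefficients(self) -> None:
        # every resolved rate must stay positive in every domain (e.g. the
        # bundled model's transport requires k10 > k11)
        for domain in self.all_domains():
            z = self.switch_values(domain)
            for var, terms in self.equations.items():
                for term in terms:
                    if term.coefficient.value(z) <= 0:
                        raise ModelError(
                            f"coefficient {term.name!r} of {var!r} is non-positive "
                            f"in domain {domain}"
                        )


def evaluate_switching_state(model: PLDEModel, state: Mapping[str, float]) -> DomainLabel:
    """Map a concrete state to its domain label (>= at-threshold convention)."""
    model.state_array(state)  # rejects missing variables by name
    dvars = model.domain_variables
    ranks = []
    for v in dvars:
        x = float(state[v])
        ranks.append(sum(1 for t in model.thresholds_on(v) if x >= t.value))
    return DomainLabel(dvars, tuple(ranks))


def effective_parameters(
    model: PLDEModel, domain: DomainLabel, R: float = 0.0
) -> dict[str, float]:
    """Resolve every rate coefficient for a domain at stress ``R``.

    Stress-scaled coefficients are returned multiplied by ``(1 + R)``.
    Coefficients sharing a name (the two halves of a transfer) must agree.
    """
    z = model.switch_values(domain)
    out: dict[str, float] = {}
    for var, terms in model.equations.items():
        for term in terms:
            val = term.coefficient.value(z)
            if term.stress_scaled:
                val *= 1.0 + R
            if term.name in out and not np.isclose(out[term.name], val, rtol=1e-12):
                raise ModelError(f"coefficient name {term.name!r} resolves inconsistently")
            out[term.name] = val
    return out


def affine_parts(
    model: PLDEModel, domain: DomainLabel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stress decomposition of the frozen-domain affine system.

    Returns ``(A0, A1, b0, b1)`` with ``A(R) = A0 + (1+R)*A1`` and
    ``b(R) = b0 + (1+R)*b1``; only stress-scaled terms contribute to the
    ``*1`` parts.
    """
    n = len(model.variables)
    A0 = np.zeros((n, n))
    A1 = np.zeros((n, n))
    b0 = np.zeros(n)
    b1 = np.zeros(n)
    z = model.switch_values(domain)
    for var, terms in model.equations.items():
        i = model.variable_index(var)
        for term in terms:
            c = term.coefficient.value(z)
            A, b = (A1, b1) if term.stress_scaled else (A0, b0)
            if term.kind == "production":
                b[i] += c
            elif term.kind in ("first-order-loss", "transfer-out"):
                A[i, i] -= c
            elif term.kind == "transfer-in":
                A[i, model.variable_index(term.source)] += c
            else:  # pragma: no cover - validate() rejects unknown kinds
                raise ModelError(f"unknown rate kind {term.kind!r}")
    return A0, A1, b0, b1


def linear_system(
    model: PLDEModel, domain: DomainLabel, R: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical affine form ``dx/dt = A x + b`` of one domain at stress R."""
    A0, A1, b0, b1 = affine_parts(model, domain)
    return A0 + (1.0 + R) * A1, b0 + (1.0 + R) * b1
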
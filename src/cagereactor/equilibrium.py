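"""Multi-component binding models and equilibrium speciation.

The equilibrium problem: given components j with analytical (total)
concentrations T_j and complex species s with overall formation constants
beta_s and stoichiometric counts nu_sj, find free concentrations x_j such
that the mass balances

    T_j = x_j + sum_s nu_sj * beta_s * prod_k x_k**nu_sk

hold for every component.  The solver works on u = ln(x) (free
concentrations strictly positive by construction), using damped Newton
iterations; the Jacobian in log variables,

    J_jk = delta_jk * x_j + sum_s nu_sj * nu_sk * c_s,

is symmetric positive definite for feasible states, so Newton steps with a
backtracking line search converge robustly even with formation constants
spanning many orders of magnitude (beta ~ 1e7-1e9 M^-2 here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Component",
    "ComplexSpecies",
    "BindingModel",
    "StepwisePair",
    "SpeciationResult",
    "SpeciationError",
    "overall_beta",
    "cooperativity_alpha",
    "disproportionation_constant",
    "path_consistency",
    "PathConsistency",
    "solve_free_concentrations",
    "speciation_profile",
]


class SpeciationError(RuntimeError):
    """Raised when the speciation solver fails to converge; carries the
    last relative mass-balance residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class Component:
    """A free chemical component with its total (analytical) concentration in M."""

    name: str
    total: float

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError(f"total concentration of {self.name!r} must be >= 0")


@dataclass(frozen=True)
class ComplexSpecies:
    """A complex assembled from components, with overall formation constant
    stored as log10(beta); beta has units M^(1 - sum of counts)."""

    name: str
    stoichiometry: Mapping[str, int]
    log_beta: float

    def __post_init__(self) -> None:
        st = {k: int(v) for k, v in self.stoichiometry.items() if v}
        if not st:
            raise ValueError(f"species {self.name!r} has empty stoichiometry")
        if any(v < 0 for v in st.values()):
            raise ValueError(f"species {self.name!r} has negative counts")
        object.__setattr__(self, "stoichiometry", st)

    @property
    def beta(self) -> float:
        return 10.0 ** self.log_beta


@dataclass(frozen=True)
class BindingModel:
    """The equilibrium problem definition: components plus complex species."""

    components: tuple[Component, ...]
    species: tuple[ComplexSpecies, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "species", tuple(self.species))
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        snames = [s.name for s in self.species]
        if len(set(snames)) != len(snames):
            raise ValueError("species names must be unique")
        known = set(names)
        for s in self.species:
            missing = set(s.stoichiometry) - known
            if missing:
                raise ValueError(
                    f"species {s.name!r} references undeclared components {sorted(missing)}"
                )

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def totals(self) -> dict[str, float]:
        return {c.name: c.total for c in self.components}

    def with_totals(self, **totals: float) -> "BindingModel":
        """Return a copy with some component totals replaced (values in M)."""
        unknown = set(totals) - set(self.component_names)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        comps = tuple(
            Component(c.name, totals.get(c.name, c.total)) for c in self.components
        )
        return BindingModel(comps, self.species)

    def species_by_name(self, name: str) -> ComplexSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def with_log_beta(self, **log_betas: float) -> "BindingModel":
        """Return a copy with some species' log10(beta) replaced."""
        unknown = set(log_betas) - set(self.species_names)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        sp = tuple(
            ComplexSpecies(s.name, s.stoichiometry, log_betas.get(s.name, s.log_beta))
            for s in self.species
        )
        return BindingModel(self.components, sp)


@dataclass(frozen=True)
class StepwisePair:
    """Stepwise binding constants (M^-1) for sequential occupation of the
    cage's two hemispheres: K_first for the solvate host + guest step,
    K_second for the 1:1 complex + guest step."""

    k_first: float
    k_second: float

    def __post_init__(self) -> None:
        if self.k_first <= 0 or self.k_second <= 0:
            raise ValueError("stepwise constants must be > 0")


@dataclass
class SpeciationResult:
    """Free-component and complex concentrations (M) satisfying mass balance
    at one composition; ``residual_norm`` is the largest relative balance error."""

    free: dict[str, float]
    complexes: dict[str, float]
    residual_norm: float

    def concentration(self, name: str) -> float:
        if name in self.free:
            return self.free[name]
        return self.complexes[name]


# ---------------------------------------------------------------------------
# Derived binding metrics


def overall_beta(pair: StepwisePair) -> float:
    """Overall 2:1 formation constant beta (M^-2) = K_first * K_second."""
    return pair.k_first * pair.k_second


def cooperativity_alpha(pair: StepwisePair) -> float:
    """Statistically corrected cooperativity factor alpha = 4 K_second / K_first.

    alpha = 1 for independent identical sites (K_second = K_first / 4 after
    statistical correction), > 1 positive and < 1 negative cooperativity.
    """
    return 4.0 * pair.k_second / pair.k_first


def disproportionation_constant(
    beta_hetero: float, beta_homo_a: float, beta_homo_b: float
) -> float:
    """Equilibrium constant for (A)2-host + (B)2-host <-> 2 (A.B)-host.

    K_dispro = beta_het**2 / (beta_AA * beta_BB); the statistical value for
    non-interacting identical sites is 4.
    """
    if beta_hetero <= 0 or beta_homo_a <= 0 or beta_homo_b <= 0:
        raise ValueError("formation constants must be > 0")
    return beta_hetero**2 / (beta_homo_a * beta_homo_b)


@dataclass(frozen=True)
class PathConsistency:
    residual: float
    passed: bool


def path_consistency(
    path1: StepwisePair, path2: StepwisePair, rel_tol: float = 0.01
) -> PathConsistency:
    """Check that two stepwise addition orders give the same overall beta.

    The overall constant of a ternary complex is a state function: the
    product of stepwise constants must agree whichever guest binds first.
    Returns the relative residual |b1 - b2| / max(b1, b2) and a pass flag.
    """
    b1, b2 = overall_beta(path1), overall_beta(path2)
    residual = abs(b1 - b2) / max(b1, b2)
    return PathConsistency(residual=residual, passed=residual <= rel_tol)


# ---------------------------------------------------------------------------
# Speciation solver


def _complex_concentrations(
    log_x: np.ndarray, nu: np.ndarray, log_beta_ln: np.ndarray
) -> np.ndarray:
    return np.exp(log_beta_ln + nu @ log_x)


def solve_free_concentrations(
    model: BindingModel,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciationResult:
    """Solve the mass-balance equations for the free concentrations.

    Components with a total of exactly zero are eliminated (their free
    concentration and every species containing them are zero).  Newton
    iterations run on log-free-concentrations with a backtracking line
    search; the initial guess free = totals is always feasible.
    """
    totals_all = model.totals()
    active = [c.name for c in model.components if c.total > 0]
    dead = set(totals_all) - set(active)

    free = {name: 0.0 for name in dead}
    complexes = {
        s.name: 0.0 for s in model.species if set(s.stoichiometry) & dead
    }
    live_species = [s for s in model.species if not set(s.stoichiometry) & dead]

    if not active:
        return SpeciationResult(free=free, complexes=complexes, residual_norm=0.0)

    totals = np.array([totals_all[n] for n in active])
    if not live_species:
        free.update(dict(zip(active, totals)))
        return SpeciationResult(free=free, complexes=complexes, residual_norm=0.0)

    nu = np.array(
        [[s.stoichiometry.get(n, 0) for n in active] for s in live_species],
        dtype=float,
    )
    ln_beta = np.array([s.log_beta * math.log(10.0) for s in live_species])

    log_x = np.log(totals)  # initial guess: free = totals

    def residual(lx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.exp(lx)
        c = _complex_concentrations(lx, nu, ln_beta)
        f = x + nu.T @ c - totals
        return f, x, c

    f, x, c = residual(log_x)
    best_rel = np.max(np.abs(f) / totals)
    for _ in range(max_iter):
        rel = np.max(np.abs(f) / totals)
        if rel <= tol:
            break
        # J_jk = delta_jk x_j + sum_s nu_sj nu_sk c_s  (SPD)
        jac = np.diag(x) + nu.T @ (nu * c[:, None])
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            step = -f / np.maximum(np.diag(jac), 1e-300)
        # damp: cap the log-step to keep iterates finite
        maxstep = np.max(np.abs(step))
        if maxstep > 5.0:
            step *= 5.0 / maxstep
        norm0 = np.linalg.norm(f / totals)
        lam = 1.0
        for _ls in range(40):
            trial = log_x + lam * step
            f_t, x_t, c_t = residual(trial)
            if np.linalg.norm(f_t / totals) < norm0:
                log_x, f, x, c = trial, f_t, x_t, c_t
                break
            lam *= 0.5
        else:  # line search stalled
            break
        best_rel = min(best_rel, np.max(np.abs(f) / totals))

    rel = np.max(np.abs(f) / totals)
    if rel > 1e-9:
        raise SpeciationError(
            f"speciation solver did not converge (relative residual {rel:.3e})",
            residual=float(rel),
        )
    free.update(dict(zip(active, np.exp(log_x))))
    complexes.update(dict(zip([s.name for s in live_species], c)))
    return SpeciationResult(free=free, complexes=complexes, residual_norm=float(rel))


def speciation_profile(
    model: BindingModel,
    titrant: str,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Solve speciation along a titration grid of the titrant's total (M).

    Returns a DataFrame with one row per grid point: the titrant total,
    the free concentration of every component (``free_<name>`` columns) and
    the concentration of every complex, all in M.
    """
    if titrant not in model.component_names:
        raise ValueError(f"unknown titrant {titrant!r}")
    grid = list(grid)
    if any(t < 0 for t in grid):
        raise ValueError("grid totals must be >= 0")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid totals must be monotone non-decreasing")

    rows = []
    for i, total in enumerate(grid):
        try:
            res = solve_free_concentrations(model.with_totals(**{titrant: total}))
        except SpeciationError as exc:
            raise SpeciationError(
                f"speciation failed at grid index {i} (titrant total {total:g} M): {exc}",
                residual=exc.residual,
            ) from exc
        row: dict[str, float] = {"titrant_total": total}
        row.update({f"free_{k}": v for k, v in res.free.items()})
        row.update(res.complexes)
        rows.append(row)
    return pd.DataFrame(rows)
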
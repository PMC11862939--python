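"""Seeded synthetic observations with the statistical structure of the
study's NMR and HPLC data.

The generators emulate concentration-level observables only, never raw
spectra: NMR-style integrals carry ~5% multiplicative (lognormal) noise,
HPLC-style quantitation ~3% additive Gaussian noise relative to the
largest signal.  Every generator takes an explicit seed; identical inputs
give byte-identical outputs, and zero noise reproduces the forward model
exactly.

Default conditions mirror the study: mM-scale totals, tight binding
(K ~ 1e3-1e5 M^-1, beta ~ 1e7-1e9 M^-2), slow first-order in-cage
reaction (k ~ 1e-5 s^-1) sampled sparsely over 48 h, and a very slow
second-order bulk reaction (k ~ 1e-8 M^-1 s^-1) at 25 mM monitored over
10 days with a fixed 2:1 regioisomer channel ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import constants as C
from . import models
from .equilibrium import BindingModel, solve_free_concentrations
from .fitting import (
    RatioObservation,
    TitrationDataset,
    fit_stepwise_constants,
)
from .kinetics import (
    BulkReactionModel,
    KineticNetwork,
    TimeCourse,
    build_cage_network,
    fit_k_bulk,
    fit_k_intra_full_curve,
    initial_rates_estimate,
    simulate_bulk,
    simulate_network,
)

__all__ = [
    "NoiseSpec",
    "Scenario",
    "DEFAULT_CAGE_SCHEDULE",
    "DEFAULT_BULK_SCHEDULE",
    "DEFAULT_INITIAL_RATE_SCHEDULE",
    "titration_scenario",
    "hetero_titration_scenario",
    "cage_kinetics_scenario",
    "bulk_scenario",
    "gen_titration_dataset",
    "gen_cage_time_course",
    "gen_initial_rate_runs",
    "gen_bulk_time_course",
    "pinned_ternary_state",
    "recovery_suite",
]

HOUR = 3600.0
DAY = 86400.0

#: NMR monitoring schedule for the in-cage reaction (s): sparse points to 48 h.
DEFAULT_CAGE_SCHEDULE: tuple[float, ...] = tuple(
    h * HOUR for h in (0.5, 1, 2, 4, 8, 12, 24, 36, 48)
)
#: HPLC monitoring schedule for the bulk reaction (s): 8 points over 10 days.
DEFAULT_BULK_SCHEDULE: tuple[float, ...] = tuple(
    np.linspace(1.25, 10.0, 8) * DAY
)
#: Dense early-time schedule used for initial-rates runs (s): 15 min steps to 2 h.
DEFAULT_INITIAL_RATE_SCHEDULE: tuple[float, ...] = tuple(
    np.arange(1, 9) * 0.25 * HOUR
)


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise description with an explicit seed.

    ``level`` is the relative standard deviation for
    ``multiplicative-lognormal`` noise and the absolute standard deviation
    (M) for ``additive-gaussian`` noise.
    """

    kind: Literal["multiplicative-lognormal", "additive-gaussian"]
    level: float
    seed: int

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError("noise level must be >= 0")
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.level == 0:
            return values.copy()
        if self.kind == "multiplicative-lognormal":
            return values * np.exp(rng.normal(0.0, self.level, size=values.shape))
        return np.clip(values + rng.normal(0.0, self.level, size=values.shape), 0.0, None)


@dataclass(frozen=True)
class Scenario:
    """A named study condition: a binding model with totals, the relevant
    rate constants, and a sampling schedule (s)."""

    name: str
    model: BindingModel
    schedule: tuple[float, ...]
    guest_pair: tuple[str, str] | None = None
    k_intra: float | None = None
    k_bulk_14: float | None = None
    k_bulk_15: float | None = None
    titrant: str | None = None
    titration_equivs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValueError("schedule must be strictly increasing")


# ---------------------------------------------------------------------------
# Default scenarios (the study conditions)


def titration_scenario(
    guest: str = "4a",
    host_total: float = 2e-3,
    equivs: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
) -> Scenario:
    """Homo-guest NMR titration: guest added stepwise to a 2 mM cage solution."""
    return Scenario(
        name=f"titration-{guest}",
        model=models.homo_binding_model(guest, host_total, 0.0),
        schedule=(1.0,),
        titrant=guest,
        titration_equivs=equivs,
    )


def hetero_titration_scenario(
    pair: tuple[str, str] = ("4a", "5"),
    host_total: float = 2e-3,
    equiv_sets: tuple[tuple[float, float], ...] = ((2.0, 2.0), (1.0, 2.0)),
) -> Scenario:
    """Pairwise-inclusion experiment: both guests added to the cage, the
    hetero/homo complex ratio read from the NMR integrals."""
    ga, gb = pair
    e0 = equiv_sets[0]
    return Scenario(
        name=f"hetero-{ga}-{gb}",
        model=models.pair_binding_model(
            ga, gb, host_total, e0[0] * host_total, e0[1] * host_total
        ),
        schedule=(1.0,),
        guest_pair=pair,
        titration_equivs=tuple(e for es in equiv_sets for e in es),  # bookkeeping
        titrant=None,
    )


def cage_kinetics_scenario(
    pair: tuple[str, str] = ("4b", "5"),
    ratio: tuple[float, float, float] = (1.0, 1.0, 2.0),
    host_total: float = 2e-3,
    k_intra: float | None = None,
    schedule: tuple[float, ...] = DEFAULT_CAGE_SCHEDULE,
) -> Scenario:
    """In-cage cycloaddition monitored by NMR at a host:azide:alkyne molar ratio."""
    ga, gb = pair
    if k_intra is None:
        product = C.product_name(pair).split("@")[0]
        k = C.RATE_CONSTANTS[product]["k_intra"]
    else:
        k = k_intra
    return Scenario(
        name=f"cage-{ga}-{gb}-" + ":".join(f"{r:g}" for r in ratio),
        model=models.pair_binding_model(
            ga, gb, ratio[0] * host_total, ratio[1] * host_total, ratio[2] * host_total
        ),
        schedule=schedule,
        guest_pair=pair,
        k_intra=k,
    )


def bulk_scenario(
    conc: float = 25e-3,
    k_14: float | None = None,
    regio_ratio: float = C.REGIO_RATIO_14_TO_15,
    schedule: tuple[float, ...] = DEFAULT_BULK_SCHEDULE,
) -> Scenario:
    """Bulk cycloaddition at 25 mM reactants monitored by HPLC."""
    k14 = k_14 if k_14 is not None else C.RATE_CONSTANTS["6b"]["k_bulk"]
    model = models.pair_binding_model("4b", "5", 0.0, conc, conc)
    return Scenario(
        name=f"bulk-{conc * 1e3:g}mM",
        model=model,
        schedule=schedule,
        guest_pair=("4b", "5"),
        k_bulk_14=k14,
        k_bulk_15=k14 / regio_ratio,
    )


# ---------------------------------------------------------------------------
# Generators


def gen_titration_dataset(scenario: Scenario, noise: NoiseSpec) -> TitrationDataset:
    """Synthetic NMR-integral ratio observations for a titration scenario.

    Homo titrations observe ([1:1]/[free host], [2:1]/[1:1]) at every
    titrant equivalence point; hetero (pairwise) scenarios observe the
    hetero/homo ternary complex ratio at each stated composition.  True
    ratios come from the speciation solver and are multiplied by lognormal
    noise.  The returned dataset's skeleton carries the true model so that
    fits start from (and are checked against) the generating constants.
    """
    rng = noise.rng()
    obs: list[RatioObservation] = []
    model = scenario.model
    host = C.HOST
    sigma = max(noise.level, 1e-6)

    if scenario.titrant is not None:  # homo titration
        guest = scenario.titrant
        mono = C.species_name(guest)
        homo = C.species_name(guest, guest)
        host_total = model.totals()[host]
        pairs = ((mono, host), (homo, mono))
        for equiv in scenario.titration_equivs or ():
            comp = {host: host_total, guest: equiv * host_total}
            res = solve_free_concentrations(model.with_totals(**comp))
            for num, den in pairs:
                r_true = res.concentration(num) / max(res.concentration(den), 1e-300)
                if not (1e-3 < r_true < 1e3):
                    continue  # unreadably small/large integral ratio
                r_obs = float(noise.apply(np.array([r_true]), rng)[0])
                obs.append(RatioObservation(comp, num, den, r_obs, sigma))
        free = (mono, homo)
    else:  # pairwise hetero scenario: only the hetero beta is free
        ga, gb = scenario.guest_pair
        hetero = C.species_name(ga, gb)
        homo_a = C.species_name(ga, ga)
        host_total = model.totals()[host]
        equivs = scenario.titration_equivs or (2.0, 2.0)
        comps = [
            {host: host_total, ga: ea * host_total, gb: eb * host_total}
            for ea, eb in zip(equivs[::2], equivs[1::2])
        ]
        for comp in comps:
            res = solve_free_concentrations(model.with_totals(**comp))
            r_true = res.concentration(hetero) / max(res.concentration(homo_a), 1e-300)
            r_obs = float(noise.apply(np.array([r_true]), rng)[0])
            obs.append(RatioObservation(comp, hetero, homo_a, r_obs, sigma))
        free = (hetero,)
    return TitrationDataset(observations=obs, skeleton=model, free_species=free)


def gen_cage_time_course(
    scenario: Scenario,
    k_intra: float | None = None,
    noise: NoiseSpec | None = None,
) -> TimeCourse:
    """Product-complex concentration sampled on the scenario schedule.

    The network starts from the equilibrium speciation of the binding model
    (complexation is fast on the reaction's time scale), multiplicative
    noise emulates NMR integral scatter, and noisy values are clipped at 0.
    """
    k = k_intra if k_intra is not None else scenario.k_intra
    product = C.product_name(scenario.guest_pair)
    net = build_cage_network(
        scenario.model, k, product=product, pre_equilibrated=True
    )
    sim = simulate_network(net, scenario.schedule)
    y = sim.values[product]
    if noise is not None and noise.level > 0:
        y = np.clip(noise.apply(y, noise.rng()), 0.0, None)
    return TimeCourse(
        times=np.asarray(scenario.schedule),
        values={product: y},
        sigma=noise.level if noise else None,
    )


def pinned_ternary_state(
    model: BindingModel,
    ternary_conc: float,
    free_guest: float = 1e-3,
) -> dict[str, float]:
    """An exactly equilibrated network state with the ternary complex at a
    prescribed concentration.

    Both free guests are set to ``free_guest`` (M), the free host follows
    from beta_het, and every other complex from its own beta, so all six
    binding equilibria are simultaneously satisfied (detailed balance) and
    the ternary concentration stays buffered during the early reaction
    phase.  This mirrors kinetic runs characterised by their measured
    ternary-complex concentration rather than by total compositions.
    """
    host = C.HOST
    guests = sorted(set(model.component_names) - {host})
    ga, gb = guests
    beta = {s.name: s.beta for s in model.species}
    hetero = C.species_name(ga, gb)
    h_free = ternary_conc / (beta[hetero] * free_guest * free_guest)
    state = {host: h_free, ga: free_guest, gb: free_guest}
    for s in model.species:
        st = s.stoichiometry
        state[s.name] = s.beta * h_free * free_guest ** (st.get(ga, 0) + st.get(gb, 0))
    return state


def gen_initial_rate_runs(
    ternary_concs: Sequence[float] = (0.54e-3, 0.32e-3, 0.10e-3),
    k_intra: float = C.RATE_CONSTANTS["6b"]["k_intra"],
    noise: NoiseSpec | None = None,
    pair: tuple[str, str] = ("4b", "5"),
    schedule: Sequence[float] = DEFAULT_INITIAL_RATE_SCHEDULE,
    free_guest: float = 5e-3,
) -> list[tuple[TimeCourse, float]]:
    """Early-time product time courses at prescribed ternary concentrations.

    One run per ternary concentration: the network starts from the
    detailed-balance state of :func:`pinned_ternary_state`, is integrated
    over the dense early schedule, and the product series receives
    multiplicative noise.  Returns (time course, ternary concentration)
    pairs ready for :func:`cagereactor.kinetics.initial_rates_estimate`.
    """
    model = models.pair_binding_model(pair[0], pair[1], 1e-3, 1e-3, 1e-3)
    product = C.product_name(pair)
    rng = noise.rng() if noise is not None else None
    runs = []
    for ternary in ternary_concs:
        net = build_cage_network(model, k_intra, product=product)
        net = net.with_initial(pinned_ternary_state(model, ternary, free_guest))
        sim = simulate_network(net, schedule)
        y = sim.values[product]
        if noise is not None and noise.level > 0:
            y = np.clip(noise.apply(y, rng), 0.0, None)
        tc = TimeCourse(
            times=np.asarray(schedule, dtype=float),
            values={product: y},
            sigma=noise.level if noise else None,
        )
        runs.append((tc, ternary))
    return runs


def gen_bulk_time_course(
    scenario: Scenario,
    k_14: float | None = None,
    k_15: float | None = None,
    noise: NoiseSpec | None = None,
) -> TimeCourse:
    """Both regioisomer product concentrations on the HPLC schedule.

    ``noise.level`` is interpreted relative to the largest 1,4-product
    signal (HPLC calibration-curve quantitation): the absolute Gaussian
    standard deviation is level * max(P14).
    """
    k14 = k_14 if k_14 is not None else scenario.k_bulk_14
    k15 = k_15 if k_15 is not None else scenario.k_bulk_15
    totals = scenario.model.totals()
    ga, gb = scenario.guest_pair
    bulk = BulkReactionModel(k14, k15, totals[ga], totals[gb])
    sim = simulate_bulk(bulk, scenario.schedule)
    p14, p15 = sim.values["P14"], sim.values["P15"]
    if noise is not None and noise.level > 0:
        rng = noise.rng()
        abs_level = noise.level * float(np.max(p14))
        spec = NoiseSpec("additive-gaussian", abs_level, noise.seed)
        p14 = spec.apply(p14, rng)
        p15 = spec.apply(p15, rng)
    return TimeCourse(
        times=np.asarray(scenario.schedule),
        values={"P14": p14, "P15": p15},
        sigma=noise.level if noise else None,
    )


# ---------------------------------------------------------------------------
# Recovery harness


def _one_recovery(kind: str, seed: int, noise_level: float) -> tuple[str, float, float]:
    """Run one generate->estimate round trip; returns (parameter, truth, estimate)."""
    if kind == "initial_rates":
        truth = C.RATE_CONSTANTS["6b"]["k_intra"]
        runs = gen_initial_rate_runs(
            k_intra=truth,
            noise=NoiseSpec("multiplicative-lognormal", noise_level, seed),
        )
        est = initial_rates_estimate(runs).k_intra
        return "k_intra", truth, est
    if kind == "full_curve":
        truth = C.RATE_CONSTANTS["6b"]["k_intra"]
        scen = cage_kinetics_scenario(k_intra=truth)
        tc = gen_cage_time_course(
            scen, noise=NoiseSpec("multiplicative-lognormal", noise_level, seed)
        )
        template = build_cage_network(
            scen.model, 1e-5, product=C.product_name(scen.guest_pair),
            pre_equilibrated=True,
        )
        est = fit_k_intra_full_curve(tc, template).k_intra
        return "k_intra", truth, est
    if kind == "bulk":
        truth = C.RATE_CONSTANTS["6b"]["k_bulk"]
        scen = bulk_scenario(k_14=truth)
        tc = gen_bulk_time_course(
            scen, noise=NoiseSpec("additive-gaussian", noise_level, seed)
        )
        skeleton = BulkReactionModel(1e-8, 0.5e-8, 25e-3, 25e-3)
        obs = TimeCourse(tc.times, {"P14": tc.values["P14"]})
        est = fit_k_bulk(obs, skeleton).k_14
        return "k_bulk", truth, est
    if kind == "binding_hetero":
        scen = hetero_titration_scenario()
        hetero = C.species_name("4a", "5")
        truth = scen.model.species_by_name(hetero).beta
        ds = gen_titration_dataset(
            scen, NoiseSpec("multiplicative-lognormal", noise_level, seed)
        )
        fit = fit_stepwise_constants(ds, window=1.5, grid_step=0.25)
        return "beta_het", truth, 10.0 ** fit.estimates[hetero]
    raise ValueError(f"unknown recovery scenario {kind!r}")


def recovery_suite(
    n_replicates: int,
    scenario_kinds: Sequence[str] = ("initial_rates", "bulk"),
    noise_level: float = 0.05,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Seeded generate->fit round trips summarised per parameter.

    Returns one row per scenario kind with the truth, the median relative
    error, the relative RMSE and the fraction of replicates landing within
    +/-25% of the truth.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for kind in scenario_kinds:
        rels = []
        for i in range(n_replicates):
            param, truth, est = _one_recovery(kind, base_seed + 7919 * i + 1, noise_level)
            rels.append((est - truth) / truth)
        rels = np.array(rels)
        rows.append(
            {
                "scenario": kind,
                "parameter": param,
                "truth": truth,
                "n": n_replicates,
                "median_abs_rel_error": float(np.median(np.abs(rels))),
                "rel_rmse": float(np.sqrt(np.mean(rels**2))),
                "coverage_25pct": float(np.mean(np.abs(rels) <= 0.25)),
            }
        )
    return pd.DataFrame(rows)
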
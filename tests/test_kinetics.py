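"""Mass-action network integration, rate-constant estimation and
acceleration metrics."""

import math
import warnings

import numpy as np
import pytest

from cagereactor import constants as C, models
from cagereactor.equilibrium import solve_free_concentrations
from cagereactor.kinetics import (
    AccelerationResult,
    BulkReactionModel,
    EstimationError,
    KineticNetwork,
    NetworkError,
    Reaction,
    TimeCourse,
    build_cage_network,
    effective_molarity,
    em_to_entropy,
    entropy_to_em,
    fit_k_bulk,
    fit_k_intra_full_curve,
    initial_rates_estimate,
    simulate_bulk,
    simulate_network,
    time_to_conversion,
)
from cagereactor.synthetic import (
    NoiseSpec,
    bulk_scenario,
    cage_kinetics_scenario,
    gen_bulk_time_course,
    gen_cage_time_course,
)

PRODUCT_6B = C.product_name(("4b", "5"))


# ---------------------------------------------------------------------------
# Network construction and integration


def test_cage_network_structure(pair_model_4b5):
    net = build_cage_network(pair_model_4b5, 5e-5, product=PRODUCT_6B)
    reversible = [r for r in net.reactions if r.reversible]
    irreversible = [r for r in net.reactions if not r.reversible]
    assert len(reversible) == 6
    assert len(irreversible) == 1
    assert len(net.species) == 9
    assert irreversible[0].k_forward == 5e-5
    assert irreversible[0].reactants == {"4b.5@1": 1}
    # every stepwise off-rate is k_on / K_step
    for rxn in reversible:
        assert rxn.k_reverse > 0


def test_cage_network_requires_all_five_complexes():
    incomplete = models.homo_binding_model("4b", 2e-3, 2e-3)
    with pytest.raises(NetworkError):
        build_cage_network(incomplete, 5e-5)


def test_zero_rate_constants_freeze_the_state():
    net = KineticNetwork(
        species={"A": 1e-3, "B": 2e-3, "P": 0.0},
        reactions=[Reaction({"A": 1, "B": 1}, {"P": 1}, 0.0)],
    )
    tc = simulate_network(net, [10.0, 1e5])
    assert np.allclose(tc.values["A"], 1e-3)
    assert np.allclose(tc.values["P"], 0.0)


def test_second_order_network_matches_closed_form():
    """A + B -> P with equal initial concentrations follows
    P(t) = A0^2 k t / (1 + A0 k t)."""
    a0, k = 25e-3, 5.6e-8
    net = KineticNetwork(
        species={"A": a0, "B": a0, "P": 0.0},
        reactions=[Reaction({"A": 1, "B": 1}, {"P": 1}, k)],
    )
    times = np.logspace(4, 7, 8)
    tc = simulate_network(net, times)
    expected = a0 * a0 * k * times / (1 + a0 * k * times)
    assert np.allclose(tc.values["P"], expected, rtol=1e-6)


def test_mass_conservation_along_cage_trajectory(pair_model_4b5):
    net = build_cage_network(pair_model_4b5, 5e-5, product=PRODUCT_6B,
                             pre_equilibrated=True)
    tc = simulate_network(net, np.linspace(600, 1.728e5, 12))
    totals = pair_model_4b5.totals()
    host = (
        tc.values["cage"] + tc.values["4b@1"] + tc.values["5@1"]
        + tc.values["4b.4b@1"] + tc.values["5.5@1"] + tc.values["4b.5@1"]
        + tc.values[PRODUCT_6B]
    )
    guest_b = (
        tc.values["5"] + tc.values["5@1"] + 2 * tc.values["5.5@1"]
        + tc.values["4b.5@1"] + tc.values[PRODUCT_6B]
    )
    assert np.allclose(host, totals["cage"], rtol=1e-7)
    assert np.allclose(guest_b, totals["5"], rtol=1e-7)


def test_unreactive_network_relaxes_to_equilibrium_speciation(pair_model_4b5):
    """With k_intra = 0 the long-time network state equals the equilibrium
    solver's speciation (detailed balance, cross-module consistency)."""
    net = build_cage_network(pair_model_4b5, 0.0, product=PRODUCT_6B)
    tc = simulate_network(net, [1.0, 100.0])
    eq = solve_free_concentrations(pair_model_4b5)
    for name, conc in eq.complexes.items():
        assert tc.values[name][-1] == pytest.approx(conc, rel=1e-6)
    for name, conc in eq.free.items():
        assert tc.values[name][-1] == pytest.approx(conc, rel=1e-6)


def test_product_complex_dominates_after_48_hours(pair_model_4b5):
    """At the 1:1:2 study composition the product complex is by far the
    dominant cage species after 48 h (the only one whose NMR signals would
    be observed): most of the host converted and an order of magnitude
    above every remaining complex."""
    net = build_cage_network(pair_model_4b5, 5e-5, product=PRODUCT_6B,
                             pre_equilibrated=True)
    tc = simulate_network(net, [1.728e5])
    final = {name: tc.values[name][-1] for name in tc.values}
    product = final.pop(PRODUCT_6B)
    assert product / 2e-3 > 0.75
    other_host = [v for n, v in final.items() if n.endswith("@1") or n == "cage"]
    assert product > 5 * max(other_host)


# ---------------------------------------------------------------------------
# Initial-rates estimation


def test_exact_linear_runs_recover_rate_constant_exactly():
    k = 5e-5
    concs = [0.54e-3, 0.32e-3, 0.10e-3]
    times = np.linspace(600, 7200, 6)
    runs = [
        (TimeCourse(times, {"P": k * c * times}), c) for c in concs
    ]
    res = initial_rates_estimate(runs)
    assert res.k_intra == pytest.approx(k, rel=1e-12)
    # v0 at the highest ternary concentration is k * c = 2.7e-8 M/s
    assert res.v0[0] == pytest.approx(2.7e-8, rel=1e-9)


def test_initial_rates_window_needs_three_points():
    times = np.array([600.0, 1200.0, 1800.0])
    runs = [
        (TimeCourse(times, {"P": 1e-7 * times}), 0.5e-3),
        (TimeCourse(times, {"P": 5e-8 * times}), 0.25e-3),
    ]
    with pytest.raises(EstimationError, match="window"):
        initial_rates_estimate(runs, plateau=1e-5, window_fraction=0.001)


def test_initial_rates_requires_distinct_concentrations():
    times = np.linspace(600, 3600, 5)
    run = (TimeCourse(times, {"P": 1e-8 * times}), 0.5e-3)
    with pytest.raises(EstimationError):
        initial_rates_estimate([run, run])


# ---------------------------------------------------------------------------
# Full-curve fitting


def _template(model):
    return build_cage_network(model, 1e-5, product=PRODUCT_6B, pre_equilibrated=True)


def test_full_curve_fit_recovers_noise_free_rate(pair_model_4b5):
    scen = cage_kinetics_scenario()
    tc = gen_cage_time_course(scen, noise=None)
    fit = fit_k_intra_full_curve(tc, _template(scen.model))
    assert fit.k_intra == pytest.approx(5e-5, rel=1e-6)


def test_full_curve_fit_with_noise_within_twenty_percent():
    scen = cage_kinetics_scenario()
    tc = gen_cage_time_course(
        scen, noise=NoiseSpec("multiplicative-lognormal", 0.05, 11)
    )
    fit = fit_k_intra_full_curve(tc, _template(scen.model))
    assert fit.k_intra == pytest.approx(5e-5, rel=0.20)


def test_three_molar_ratio_scenarios_average():
    """The averaging protocol over 1:1:1, 1:1:2 and 1:5:5 compositions gives
    a mean rate constant consistent with the generating value."""
    estimates = []
    for i, ratio in enumerate([(1, 1, 1), (1, 1, 2), (1, 5, 5)]):
        scen = cage_kinetics_scenario(ratio=ratio)
        tc = gen_cage_time_course(
            scen, noise=NoiseSpec("multiplicative-lognormal", 0.05, 40 + i)
        )
        fit = fit_k_intra_full_curve(tc, _template(scen.model))
        estimates.append(fit.k_intra)
    assert np.mean(estimates) == pytest.approx(5e-5, rel=0.20)


def test_doubling_on_rate_leaves_fitted_k_intra_unchanged():
    """Pre-equilibrium insensitivity: the fitted in-cage rate constant moves
    by far less than 1% when the reference on-rate doubles."""
    scen = cage_kinetics_scenario()
    tc = gen_cage_time_course(scen, noise=None)
    fits = []
    for kon in (1e7, 2e7):
        tpl = build_cage_network(
            scen.model, 1e-5, k_on_reference=kon, product=PRODUCT_6B,
            pre_equilibrated=True,
        )
        fits.append(fit_k_intra_full_curve(tc, tpl).k_intra)
    assert abs(fits[1] - fits[0]) / fits[0] < 0.01


# ---------------------------------------------------------------------------
# Bulk reaction


def test_bulk_with_zero_rates_produces_nothing():
    tc = simulate_bulk(BulkReactionModel(0.0, 0.0, 25e-3, 25e-3), [1e5, 1e6])
    assert np.allclose(tc.values["P14"], 0.0)
    assert np.allclose(tc.values["P15"], 0.0)


def test_bulk_single_channel_matches_closed_form():
    tc = simulate_bulk(BulkReactionModel(5.6e-8, 0.0, 25e-3, 25e-3), [1e6])
    assert tc.values["P14"][-1] == pytest.approx(3.495e-5, rel=1e-4)


def test_regioisomer_ratio_equals_rate_constant_ratio():
    """Parallel channels share the encounter term: P14/P15 = k14/k15 at all
    sampled times."""
    model = BulkReactionModel(5.6e-8, 2.8e-8, 25e-3, 25e-3)
    tc = simulate_bulk(model, np.logspace(4, 6.5, 9))
    ratio = tc.values["P14"] / tc.values["P15"]
    assert np.allclose(ratio, 2.0, rtol=1e-6)


def test_fit_k_bulk_noise_free_exact():
    scen = bulk_scenario()
    tc = gen_bulk_time_course(scen, noise=None)
    obs = TimeCourse(tc.times, {"P14": tc.values["P14"]})
    fit = fit_k_bulk(obs, BulkReactionModel(1e-8, 0.5e-8, 25e-3, 25e-3))
    assert fit.k_14 == pytest.approx(5.6e-8, rel=1e-6)
    assert fit.k_15 == pytest.approx(2.8e-8, rel=1e-6)


@pytest.mark.parametrize("k_true, seed", [(5.6e-8, 7), (3.6e-8, 13)])
def test_fit_k_bulk_with_hplc_noise_within_fifteen_percent(k_true, seed):
    scen = bulk_scenario(k_14=k_true)
    tc = gen_bulk_time_course(scen, noise=NoiseSpec("additive-gaussian", 0.03, seed))
    obs = TimeCourse(tc.times, {"P14": tc.values["P14"]})
    fit = fit_k_bulk(obs, BulkReactionModel(1e-8, 0.5e-8, 25e-3, 25e-3))
    assert fit.k_14 == pytest.approx(k_true, rel=0.15)


def test_fit_k_bulk_rejects_all_zero_data():
    obs = TimeCourse(np.array([1e4, 1e5]), {"P14": np.zeros(2)})
    with pytest.raises(EstimationError):
        fit_k_bulk(obs, BulkReactionModel(1e-8, 0.5e-8, 25e-3, 25e-3))


# ---------------------------------------------------------------------------
# Acceleration metrics


def test_effective_molarity_values():
    assert effective_molarity(5.0e-5, 5.6e-8) == pytest.approx(892.86, rel=1e-4)
    assert effective_molarity(8.1e-5, 3.6e-8) == pytest.approx(2.25e3, rel=1e-3)
    assert effective_molarity(5.6e-8, 5.6e-8) == 1.0
    with pytest.raises(ValueError):
        effective_molarity(1e-5, 0.0)


def test_em_entropy_round_trip():
    d_s, dd_g = em_to_entropy(1.0e3)
    assert d_s == pytest.approx(-13.7, abs=0.05)
    assert dd_g == pytest.approx(4.1, abs=0.05)
    assert em_to_entropy(1.0)[0] == 0.0
    assert C.round_sig(entropy_to_em(-35.0), 1) == pytest.approx(4e7)
    # inverse consistency
    em = 893.0
    assert entropy_to_em(em_to_entropy(em)[0]) == pytest.approx(em, rel=1e-12)


def test_acceleration_result_invariants():
    acc = AccelerationResult.from_rates(5.0e-5, 5.6e-8)
    assert acc.em == acc.k_intra / acc.k_bulk
    assert acc.delta_s == pytest.approx(-C.R_CAL * math.log(acc.em), rel=1e-12)
    assert acc.delta_g == pytest.approx(acc.temperature * abs(acc.delta_s) / 1000,
                                        rel=1e-12)


def test_time_to_conversion_closed_form():
    model = BulkReactionModel(5.6e-8, 0.0, 2e-3, 2e-3)
    assert time_to_conversion(model, 0.0) == 0.0
    t = time_to_conversion(model, 1e-3)
    assert t == pytest.approx(500 / 5.6e-8, rel=1e-12)  # ~283 years
    assert t / (365.25 * 86400) == pytest.approx(283, abs=1)
    with pytest.raises(ValueError):
        time_to_conversion(model, 2e-3)  # full conversion unreachable
    # monotone divergence toward the limit
    ts = [time_to_conversion(model, x) for x in (0.5e-3, 1e-3, 1.9e-3, 1.99e-3)]
    assert all(b > a for a, b in zip(ts, ts[1:]))


def test_time_to_conversion_unequal_concentrations_matches_simulation():
    model = BulkReactionModel(5.6e-8, 2.8e-8, 25e-3, 10e-3)
    target = 2e-3
    t = time_to_conversion(model, target)
    tc = simulate_bulk(model, [t])
    assert tc.values["P14"][-1] == pytest.approx(target, rel=1e-6)
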
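"""Builders for the binding models of the cage / pyridine-N-oxide system."""

from __future__ import annotations

import math

from . import constants as C
from .equilibrium import BindingModel, Component, ComplexSpecies, StepwisePair


def stepwise_pair(first: str, second: str, variant: str = "text") -> StepwisePair:
    """Stepwise constants for adding `first` then `second` to the cage."""
    k2 = C.stepwise_constants(variant)[(first, second)]
    return StepwisePair(C.K_FIRST[first], k2)


def homo_binding_model(
    guest: str,
    host_total: float,
    guest_total: float,
    variant: str = "text",
) -> BindingModel:
    """Two-reagent model: cage solvate + one guest forming the 1:1 and the
    2:1 homo inclusion complexes (totals in M)."""
    pair = stepwise_pair(guest, guest, variant)
    return BindingModel(
        components=(
            Component(C.HOST, host_total),
            Component(guest, guest_total),
        ),
        species=(
            ComplexSpecies(
                C.species_name(guest), {C.HOST: 1, guest: 1}, math.log10(pair.k_first)
            ),
            ComplexSpecies(
                C.species_name(guest, guest),
                {C.HOST: 1, guest: 2},
                math.log10(pair.k_first * pair.k_second),
            ),
        ),
    )


def pair_binding_model(
    guest_a: str,
    guest_b: str,
    host_total: float,
    total_a: float,
    total_b: float,
    variant: str = "text",
    use_reported_betas: bool = True,
) -> BindingModel:
    """Three-reagent, five-species model: both 1:1 complexes, both homo 2:1
    complexes and the hetero ternary complex (totals in M).

    With ``use_reported_betas`` the overall constants are the published
    2-significant-figure values; otherwise they are products of the stepwise
    constants (the two differ by rounding only).
    """
    def beta_overall(guests: tuple[str, ...]) -> float:
        if use_reported_betas:
            return C.BETA_OVERALL[frozenset(guests)]
        first, second = guests
        return C.K_FIRST[first] * C.stepwise_constants(variant)[(first, second)]

    species = (
        ComplexSpecies(
            C.species_name(guest_a), {C.HOST: 1, guest_a: 1},
            math.log10(C.K_FIRST[guest_a]),
        ),
        ComplexSpecies(
            C.species_name(guest_b), {C.HOST: 1, guest_b: 1},
            math.log10(C.K_FIRST[guest_b]),
        ),
        ComplexSpecies(
            C.species_name(guest_a, guest_a), {C.HOST: 1, guest_a: 2},
            math.log10(beta_overall((guest_a, guest_a))),
        ),
        ComplexSpecies(
            C.species_name(guest_b, guest_b), {C.HOST: 1, guest_b: 2},
            math.log10(beta_overall((guest_b, guest_b))),
        ),
        ComplexSpecies(
            C.species_name(guest_a, guest_b), {C.HOST: 1, guest_a: 1, guest_b: 1},
            math.log10(beta_overall((guest_a, guest_b))),
        ),
    )
    return BindingModel(
        components=(
            Component(C.HOST, host_total),
            Component(guest_a, total_a),
            Component(guest_b, total_b),
        ),
        species=species,
    )
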
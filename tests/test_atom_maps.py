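"""Carbon-transition maps: construction invariants, worked traces, round-trip."""

import numpy as np
import pytest

from fructoflux.atom_maps import (
    CO2_SLOT,
    CarbonMap,
    Species,
    apply_map,
    build_default_network,
    label_balance,
    lumped_ppp_cycle,
    network_from_dict,
    network_to_dict,
)
from fructoflux.isotopomer import PoolDistribution, mix, positional_fractions


def _random_dist(species, rng, max_patterns=5):
    n = species.n_carbons
    k = int(rng.integers(1, min(max_patterns, 1 << n) + 1))
    pats = rng.choice(1 << n, size=k, replace=False)
    w = rng.random(k) + 1e-3
    w /= w.sum()
    return PoolDistribution(species, {int(p): float(f) for p, f in zip(pats, w)})


def test_carbon_map_construction_rejects_bad_maps():
    hexose = Species("hexose", 6)
    triose = Species("triose", 3)
    # a substrate carbon left unmapped
    with pytest.raises(ValueError, match="exactly once"):
        CarbonMap("bad", (triose,), (triose,), {(0, 1): (0, 1), (0, 2): (0, 2)})
    # two substrate carbons sent to the same product carbon
    with pytest.raises(ValueError, match="exactly one"):
        CarbonMap(
            "bad", (triose,), (triose,),
            {(0, 1): (0, 1), (0, 2): (0, 1), (0, 3): (0, 3)},
        )
    # carbon count not conserved (hexose -> triose, no CO2)
    with pytest.raises(ValueError):
        CarbonMap(
            "bad", (hexose,), (triose,),
            {(0, i): (0, i) for i in range(1, 4)},
        )


def test_direct_route_is_identity_on_the_hexose_backbone(network):
    """Glucose C2 reaches fructose C2 through uptake + dephosphorylation."""
    glc = PoolDistribution.pure(network.species["glucose"], (2,))
    (f6p,), _ = apply_map(network["glucose_uptake"], [glc])
    (fru,), _ = apply_map(network["f6p_phosphatase"], [f6p])
    assert fru.to_strings() == {"[2]": 1.0}


def test_hexose_c1_and_c6_converge_on_the_same_triose_carbon(network):
    """Cleavage + TPI equilibration sends both hexose C1 and C6 to GAP C3."""
    f6p_sp = network.species["F6P"]
    for start in (1, 6):
        (top, bottom), _ = apply_map(
            network["aldolase_split"], [PoolDistribution.pure(f6p_sp, (start,))]
        )
        pool = mix([(top, 0.5), (bottom, 0.5)])
        m = positional_fractions(pool)
        assert m.at(3) == pytest.approx(0.5)
        assert m.at(1) == m.at(2) == 0.0


def test_pyruvate_and_fermentation_product_maps(network):
    """[2-13C]glucose label lands on pyruvate C2, ethanol C2 and acetate C1."""
    tri = PoolDistribution.pure(network.species["triose"], (2,))
    (pyr,), _ = apply_map(network["triose_to_pyruvate"], [tri])
    assert pyr.to_strings() == {"[2]": 1.0}
    (eth,), co2_eth = apply_map(network["pyruvate_to_ethanol"], [pyr])
    assert eth.to_strings() == {"[2]": 1.0} and co2_eth == 0.0
    (ace,), _ = apply_map(network["pyruvate_to_acetate"], [pyr])
    assert ace.to_strings() == {"[1]": 1.0}
    # the carboxyl carbon is lost on decarboxylation
    (pyr1,), _ = apply_map(
        network["triose_to_pyruvate"],
        [PoolDistribution.pure(network.species["triose"], (1,))],
    )
    (eth1,), co2_1 = apply_map(network["pyruvate_to_ethanol"], [pyr1])
    assert eth1.to_strings() == {"[]": 1.0} and co2_1 == 1.0


def test_apply_map_identity_and_slot_mismatch(network):
    glc = PoolDistribution.pure(network.species["glucose"], (2,))
    (out,), co2 = apply_map(network["glucose_uptake"], [glc])
    assert out.to_strings() == {"[2]": 1.0} and co2 == 0.0
    with pytest.raises(ValueError, match="expected"):
        apply_map(network["glucose_uptake"], [out])  # F6P fed where glucose expected


def test_condensation_of_half_labeled_triose_pool(network):
    """50% label at GAP C3 condensed with itself gives the four-way split."""
    tri_sp = network.species["triose"]
    pool = PoolDistribution.from_strings(tri_sp, {"[3]": 0.5, "[]": 0.5})
    (f6p,), _ = apply_map(network["aldolase_condense"], [pool, pool])
    assert f6p.to_strings() == pytest.approx(
        {"[1]": 0.25, "[6]": 0.25, "[1,6]": 0.25, "[]": 0.25}
    )


@pytest.mark.parametrize(
    "input_positions, expected_f6p, expected_triose, expected_co2",
    [
        # first cycle on [2-13C]: one [1-13C] + one [1,3-13C] F6P, CO2 cold
        ((2,), {"[1]": 0.5, "[1,3]": 0.5}, {"[]": 1.0}, 0.0),
        # C1 label is lost oxidatively
        ((1,), {"[]": 1.0}, {"[]": 1.0}, 1.0),
        # second cycle on [1,3-13C]: the [2,3-13C] trace species appears
        ((1, 3), {"[2]": 0.5, "[2,3]": 0.5}, {"[]": 1.0}, 1.0),
    ],
)
def test_lumped_ppp_cycle_worked_examples(
    network, input_positions, expected_f6p, expected_triose, expected_co2
):
    hexose = PoolDistribution.pure(network.species["F6P"], input_positions)
    f6p, triose, co2 = lumped_ppp_cycle(hexose, network)
    assert f6p.to_strings() == pytest.approx(expected_f6p, abs=1e-12)
    assert triose.to_strings() == pytest.approx(expected_triose, abs=1e-12)
    assert co2 == pytest.approx(expected_co2, abs=1e-12)


def test_ppp_cycle_rejects_non_hexose(network):
    tri = PoolDistribution.unlabeled(network.species["triose"])
    with pytest.raises(ValueError, match="6-carbon"):
        lumped_ppp_cycle(tri, network)


def test_label_conservation_through_every_map(network):
    """Expected labeled carbons in == out (+CO2) to 1e-12, random inputs."""
    rng = np.random.default_rng(42)
    for rxn in network.reactions.values():
        for _ in range(10):
            inputs = [_random_dist(sp, rng) for sp in rxn.substrates]
            lab_in, lab_out = label_balance(rxn, inputs)
            assert lab_in == pytest.approx(lab_out, abs=1e-12), rxn.name


def test_reversal_composition_sends_c1_to_equal_c1_c6_mass(network):
    """Split -> TPI pool -> condense turns [1-13C]hexose into equal [1]/[6]."""
    f6p_sp = network.species["F6P"]
    (top, bottom), _ = apply_map(
        network["aldolase_split"], [PoolDistribution.pure(f6p_sp, (1,))]
    )
    pool = mix([(top, 0.5), (bottom, 0.5)])
    (back,), _ = apply_map(network["aldolase_condense"], [pool, pool])
    got = back.to_strings()
    assert got["[1]"] == pytest.approx(got["[6]"], abs=1e-12)
    assert got["[1]"] > 0


def test_network_serialization_roundtrip(network, tmp_path):
    payload = network_to_dict(network)
    assert any(
        entry.startswith("(0,1)->(CO2,")
        for rxn in payload["reactions"] if rxn["name"] == "ppp_cycle"
        for entry in rxn["mapping"]
    )
    rebuilt = network_from_dict(payload)
    assert set(rebuilt.reactions) == set(network.reactions)
    for name, rxn in network.reactions.items():
        assert rebuilt.reactions[name].mapping == rxn.mapping
    f6p = PoolDistribution.pure(rebuilt.species["F6P"], (2,))
    out, _, _ = lumped_ppp_cycle(f6p, rebuilt)
    assert out.to_strings() == {"[1]": 0.5, "[1,3]": 0.5}
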
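"""Atom-transition maps for the fructose-6-phosphate node of a fructophilic yeast.

The network models how resting cells fed a single glucose pulse route carbon
around fructose-6-phosphate (F6P): direct uptake (hexokinase + phosphoglucose
isomerase, carbons untouched), dephosphorylation of F6P to free fructose,
cleavage to the triose-phosphate pool (aldolase + triose-phosphate isomerase),
gluconeogenic re-condensation of two trioses back to F6P, a lumped pentose
phosphate pathway (PPP) cycle, and the minor fermentation/overflow sinks
(ethanol, glycerol, pyruvate, acetate, dihydroxyacetone, TCA intermediates).

Each reaction carries a :class:`CarbonMap`: an explicit bijection from
substrate carbons to product carbons (with CO2 as a reserved sink slot).
Pushing isotopomer distributions through these maps is what turns a flux
hypothesis into predicted NMR labeling patterns.

Conventions
-----------
* Carbon positions are 1-based, standard sugar numbering (C1 = the
  aldehyde/keto-proximal carbon).
* The triose pool is a single TPI-equilibrated pool expressed in
  glyceraldehyde-3-phosphate (GAP) coordinates; the DHAP half of a cleaved
  hexose is re-indexed through the TPI map (DHAP C1<->GAP C3, C2<->C2,
  C3<->C1) on entry.  Hence hexose C1 and C6 both land on GAP C3 — the origin
  of the C1<->C6 (and C2<->C5, C3<->C4) label reversal diagnostic of
  aldolase back-flux.
* Condensations draw their substrate molecules independently from the
  respective pools (well-mixed assumption).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import yaml

from .isotopomer import PoolDistribution, mix, n_labeled

#: reserved product-slot identifier for carbons lost as CO2
CO2_SLOT = "CO2"

MapEntry = tuple[tuple[int, int], tuple[object, int]]


@dataclass(frozen=True)
class Species:
    """A metabolite pool with a fixed carbon skeleton."""

    name: str
    n_carbons: int
    compartment: str = "intracellular"  # extracellular | intracellular | sink

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")
        if self.compartment not in ("extracellular", "intracellular", "sink"):
            raise ValueError(f"{self.name}: unknown compartment {self.compartment!r}")


@dataclass
class CarbonMap:
    """Atom-to-atom transition map of one (possibly lumped) reaction.

    ``substrates`` and ``products`` list one :class:`Species` per molecule
    slot (stoichiometry is expressed by repeating a species).  ``mapping``
    sends every substrate carbon ``(slot, position)`` to a product carbon
    ``(slot, position)`` or to the reserved ``CO2_SLOT``.
    """

    name: str
    substrates: tuple[Species, ...]
    products: tuple[Species, ...]
    mapping: dict[tuple[int, int], tuple[object, int]]

    def __post_init__(self) -> None:
        self.substrates = tuple(self.substrates)
        self.products = tuple(self.products)
        sub_carbons = {
            (s, pos)
            for s, sp in enumerate(self.substrates)
            for pos in range(1, sp.n_carbons + 1)
        }
        if set(self.mapping) != sub_carbons:
            missing = sub_carbons - set(self.mapping)
            extra = set(self.mapping) - sub_carbons
            raise ValueError(
                f"{self.name}: substrate carbons mapped exactly once required; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        prod_carbons = {
            (s, pos)
            for s, sp in enumerate(self.products)
            for pos in range(1, sp.n_carbons + 1)
        }
        images = [v for v in self.mapping.values() if v[0] != CO2_SLOT]
        if len(images) != len(set(images)) or set(images) != prod_carbons:
            raise ValueError(
                f"{self.name}: every non-CO2 product carbon must be the image of "
                "exactly one substrate carbon"
            )
        n_sub = sum(sp.n_carbons for sp in self.substrates)
        n_prod = sum(sp.n_carbons for sp in self.products)
        if n_sub != n_prod + self.n_co2:
            raise ValueError(f"{self.name}: carbon count not conserved")

    @property
    def n_co2(self) -> int:
        return sum(1 for v in self.mapping.values() if v[0] == CO2_SLOT)


def apply_map(
    cmap: CarbonMap, inputs: list[PoolDistribution] | tuple[PoolDistribution, ...]
) -> tuple[list[PoolDistribution], float]:
    """Push substrate isotopomer distributions through a carbon map.

    Substrate slots are assumed independent (condensation = product measure).
    Returns one distribution per product slot and the expected labeled
    fraction of the CO2 carbons released (0.0 for decarboxylation-free maps).
    """
    if len(inputs) != len(cmap.substrates):
        raise ValueError(
            f"{cmap.name}: expected {len(cmap.substrates)} substrate pools, "
            f"got {len(inputs)}"
        )
    for slot, (pool, sp) in enumerate(zip(inputs, cmap.substrates)):
        if pool.species.name != sp.name or pool.species.n_carbons != sp.n_carbons:
            raise ValueError(
                f"{cmap.name} slot {slot}: expected {sp.name}, got {pool.species.name}"
            )

    # per product slot: list of (dest_shift, src_slot, src_shift)
    routes: list[list[tuple[int, int, int]]] = [[] for _ in cmap.products]
    co2_routes: list[tuple[int, int]] = []
    for (s_slot, s_pos), (p_slot, p_pos) in cmap.mapping.items():
        s_shift = cmap.substrates[s_slot].n_carbons - s_pos
        if p_slot == CO2_SLOT:
            co2_routes.append((s_slot, s_shift))
        else:
            p_shift = cmap.products[p_slot].n_carbons - p_pos
            routes[p_slot].append((p_shift, s_slot, s_shift))

    # Each product slot's distribution depends only on the substrate slots
    # it draws carbons from; enumerating those (instead of the full joint)
    # is exact because slots are independent and inter-product correlations
    # are not part of the return value.
    out: list[dict[int, float]] = []
    for p_slot, slot_routes in enumerate(routes):
        involved = sorted({s_slot for _, s_slot, _ in slot_routes})
        index = {s: i for i, s in enumerate(involved)}
        acc: dict[int, float] = {}
        for combo in itertools.product(
            *(inputs[s].fractions.items() for s in involved)
        ):
            w = 1.0
            for _, frac in combo:
                w *= frac
            if w == 0.0:
                continue
            prod_pat = 0
            for p_shift, s_slot, s_shift in slot_routes:
                prod_pat |= (combo[index[s_slot]][0] >> s_shift & 1) << p_shift
            acc[prod_pat] = acc.get(prod_pat, 0.0) + w
        out.append(acc)

    # CO2 labeling needs only per-slot marginals
    co2_labeled = 0.0
    for s_slot, s_shift in co2_routes:
        co2_labeled += sum(
            frac * (pat >> s_shift & 1)
            for pat, frac in inputs[s_slot].fractions.items()
        )

    products = [
        PoolDistribution(sp, acc) for sp, acc in zip(cmap.products, out)
    ]
    co2_fraction = co2_labeled / cmap.n_co2 if cmap.n_co2 else 0.0
    return products, co2_fraction


@dataclass
class Network:
    """The fixed F6P-node network: species, carbon maps, designated nodes."""

    species: dict[str, Species]
    reactions: dict[str, CarbonMap]
    nodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rxn in self.reactions.values():
            for sp in (*rxn.substrates, *rxn.products):
                if self.species.get(sp.name) != sp:
                    raise ValueError(
                        f"reaction {rxn.name}: species {sp.name} not registered"
                    )
        for role, name in self.nodes.items():
            if name not in self.species and name not in self.reactions:
                raise ValueError(f"designated node {role} -> unknown species {name}")

    def __getitem__(self, reaction_name: str) -> CarbonMap:
        return self.reactions[reaction_name]

    @property
    def sink_names(self) -> tuple[str, ...]:
        return tuple(
            s.name for s in self.species.values() if s.compartment == "sink"
        )


def _identity_map(name: str, sub: Species, prod: Species) -> CarbonMap:
    return CarbonMap(
        name,
        (sub,),
        (prod,),
        {(0, i): (0, i) for i in range(1, sub.n_carbons + 1)},
    )


def build_default_network() -> Network:
    """The resting-cell tracer network around the F6P node.

    Reactions: glucose uptake (identity on the hexose backbone),
    F6P dephosphorylation to fructose (identity), aldolase cleavage to two
    trioses (with TPI re-indexing of the DHAP half), reverse aldolase
    condensation, the lumped PPP cycle (3 hexoses -> 2 F6P + 1 triose +
    3 CO2), and triose drains to the observed minor products.
    """
    glucose = Species("glucose", 6, "extracellular")
    f6p = Species("F6P", 6, "intracellular")
    triose = Species("triose", 3, "intracellular")
    fructose = Species("fructose", 6, "extracellular")
    pyruvate = Species("pyruvate", 3, "sink")
    ethanol = Species("ethanol", 2, "sink")
    acetate = Species("acetate", 2, "sink")
    glycerol = Species("glycerol", 3, "sink")
    dha = Species("dihydroxyacetone", 3, "sink")
    tca = Species("tca", 3, "sink")
    co2 = Species("CO2", 1, "sink")

    species = {
        s.name: s
        for s in (glucose, f6p, triose, fructose, pyruvate, ethanol, acetate,
                  glycerol, dha, tca, co2)
    }

    # F6P C1-C3 -> DHAP, C4-C6 -> GAP; DHAP re-indexed via TPI into GAP
    # coordinates (DHAP C1 -> GAP C3, C2 -> C2, C3 -> GAP C1).
    aldolase_split = CarbonMap(
        "aldolase_split",
        (f6p,),
        (triose, triose),
        {
            (0, 1): (0, 3), (0, 2): (0, 2), (0, 3): (0, 1),
            (0, 4): (1, 1), (0, 5): (1, 2), (0, 6): (1, 3),
        },
    )
    aldolase_condense = CarbonMap(
        "aldolase_condense",
        (triose, triose),
        (f6p,),
        {
            (0, 3): (0, 1), (0, 2): (0, 2), (0, 1): (0, 3),
            (1, 1): (0, 4), (1, 2): (0, 5), (1, 3): (0, 6),
        },
    )

    # Lumped PPP cycle: each hexose loses C1 oxidatively (6PGDH), the three
    # pentoses recombine through TK1 (X5P + R5P -> S7P + GAP),
    # TA (S7P + GAP -> F6P + E4P) and TK2 (X5P + E4P -> F6P + GAP).
    # Composition in terms of the source hexoses A (-> X5P), B (-> R5P),
    # C (-> X5P):
    #   F6P#1 = (A2, A3, B2, A4, A5, A6)
    #   F6P#2 = (C2, C3, B3, B4, B5, B6)
    #   triose out = (C4, C5, C6) in GAP coordinates
    ppp_cycle = CarbonMap(
        "ppp_cycle",
        (f6p, f6p, f6p),
        (f6p, f6p, triose),
        {
            (0, 1): (CO2_SLOT, 1), (1, 1): (CO2_SLOT, 1), (2, 1): (CO2_SLOT, 1),
            (0, 2): (0, 1), (0, 3): (0, 2), (1, 2): (0, 3),
            (0, 4): (0, 4), (0, 5): (0, 5), (0, 6): (0, 6),
            (2, 2): (1, 1), (2, 3): (1, 2), (1, 3): (1, 3),
            (1, 4): (1, 4), (1, 5): (1, 5), (1, 6): (1, 6),
            (2, 4): (2, 1), (2, 5): (2, 2), (2, 6): (2, 3),
        },
    )

    # Glycolytic lower branch: the triose pool (GAP coordinates) drains to
    # pyruvate position-for-position, so hexose C1/C6 -> pyruvate C3,
    # C2/C5 -> C2, C3/C4 -> C1.
    triose_to_pyruvate = _identity_map("triose_to_pyruvate", triose, pyruvate)
    # Decarboxylation of pyruvate C1; product carbon numbering follows the
    # NMR naming used for fermentation products ([2-13C]glucose gives
    # [2-13C]ethanol and [1-13C]acetate).
    pyruvate_to_ethanol = CarbonMap(
        "pyruvate_to_ethanol",
        (pyruvate,),
        (ethanol,),
        {(0, 1): (CO2_SLOT, 1), (0, 2): (0, 2), (0, 3): (0, 1)},
    )
    pyruvate_to_acetate = CarbonMap(
        "pyruvate_to_acetate",
        (pyruvate,),
        (acetate,),
        {(0, 1): (CO2_SLOT, 1), (0, 2): (0, 1), (0, 3): (0, 2)},
    )
    pyruvate_to_tca = _identity_map("pyruvate_to_tca", pyruvate, tca)
    triose_to_glycerol = _identity_map("triose_to_glycerol", triose, glycerol)
    # DHA is on the DHAP side: undo the TPI re-indexing.
    triose_to_dha = CarbonMap(
        "triose_to_dha",
        (triose,),
        (dha,),
        {(0, 1): (0, 3), (0, 2): (0, 2), (0, 3): (0, 1)},
    )

    reactions = {
        r.name: r
        for r in (
            _identity_map("glucose_uptake", glucose, f6p),
            _identity_map("f6p_phosphatase", f6p, fructose),
            aldolase_split,
            aldolase_condense,
            ppp_cycle,
            triose_to_pyruvate,
            pyruvate_to_ethanol,
            pyruvate_to_acetate,
            pyruvate_to_tca,
            triose_to_glycerol,
            triose_to_dha,
        )
    }
    nodes = {
        "glucose_ext": "glucose",
        "f6p": "F6P",
        "triose_pool": "triose",
        "fructose_ext": "fructose",
        "ppp": "ppp_cycle",
        "co2": "CO2",
    }
    return Network(species, reactions, nodes)


def lumped_ppp_cycle(
    hexose: PoolDistribution, network: Network | None = None
) -> tuple[PoolDistribution, PoolDistribution, float]:
    """One lumped PPP turn: 3 hexose-P -> 2 F6P + 1 triose-P + 3 CO2.

    The three consumed hexoses are drawn independently from ``hexose``; the
    returned F6P distribution is the equal-weight mixture of the two product
    molecules.  Returns ``(f6p_out, triose_out, co2_labeled_fraction)``.
    """
    if hexose.species.n_carbons != 6:
        raise ValueError("PPP cycle expects a 6-carbon hexose distribution")
    net = network if network is not None else build_default_network()
    cmap = net["ppp_cycle"]
    hexose = PoolDistribution(cmap.substrates[0], dict(hexose.fractions))
    (f6p_a, f6p_b, triose_out), co2_frac = apply_map(cmap, [hexose] * 3)
    f6p_out = mix([(f6p_a, 0.5), (f6p_b, 0.5)])
    return f6p_out, triose_out, co2_frac


def label_balance(
    cmap: CarbonMap, inputs: list[PoolDistribution]
) -> tuple[float, float]:
    """Expected labeled carbons (in, out incl. CO2) for one reaction event."""
    products, co2_frac = apply_map(cmap, inputs)
    lab_in = sum(
        sum(f * n_labeled(p) for p, f in pool.fractions.items()) for pool in inputs
    )
    lab_out = sum(
        sum(f * n_labeled(p) for p, f in pool.fractions.items()) for pool in products
    )
    return lab_in, lab_out + co2_frac * cmap.n_co2


# ---------------------------------------------------------------------------
# serialization


def network_to_dict(net: Network) -> dict:
    """Plain-dict form of a network (YAML/JSON-safe)."""
    return {
        "species": [
            {"name": s.name, "n_carbons": s.n_carbons, "compartment": s.compartment}
            for s in net.species.values()
        ],
        "nodes": dict(net.nodes),
        "reactions": [
            {
                "name": r.name,
                "substrates": [s.name for s in r.substrates],
                "products": [s.name for s in r.products],
                "mapping": sorted(
                    f"({ss},{sp})->({ps},{pp})"
                    for (ss, sp), (ps, pp) in r.mapping.items()
                ),
            }
            for r in net.reactions.values()
        ],
    }


def network_from_dict(payload: dict) -> Network:
    species = {
        d["name"]: Species(d["name"], int(d["n_carbons"]), d["compartment"])
        for d in payload["species"]
    }
    reactions = {}
    for rd in payload["reactions"]:
        mapping: dict[tuple[int, int], tuple[object, int]] = {}
        for entry in rd["mapping"]:
            src, dst = entry.split("->")
            ss, sp = src.strip("() ").split(",")
            ps, pp = dst.strip("() ").split(",")
            pslot: object = CO2_SLOT if ps == CO2_SLOT else int(ps)
            mapping[(int(ss), int(sp))] = (pslot, int(pp))
        reactions[rd["name"]] = CarbonMap(
            rd["name"],
            tuple(species[n] for n in rd["substrates"]),
            tuple(species[n] for n in rd["products"]),
            mapping,
        )
    return Network(species, reactions, dict(payload.get("nodes", {})))


def save_network(net: Network, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path) -> Network:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))
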
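"""Independent molecule-tracking Monte-Carlo oracle.

Re-derives the carbon shuffles of every reaction from the biochemistry
(aldolase/TPI, oxidative decarboxylation, transketolase/transaldolase) with
its own representation — labeled positions as frozensets — deliberately NOT
importing the package's atom maps, so it can serve as an independent check
of the deterministic simulator.

The sampler reproduces the quasi-steady pools stochastically: reservoirs of
recent F6P / triose molecules are turned over by flux-proportional events,
and after burn-in each newly produced F6P molecule is counted as one
excreted fructose (excretion samples the pool uniformly).
"""

from __future__ import annotations

import random
from collections import Counter

Labels = frozenset


def split_hexose(hexose: Labels) -> tuple[Labels, Labels]:
    """Aldolase cleavage; both halves in GAP coordinates (TPI-equilibrated).

    Hexose C1,C2,C3 -> DHAP C3,C2,C1 (as GAP); C4,C5,C6 -> GAP C1,C2,C3.
    """
    top = frozenset(4 - c for c in hexose if c <= 3)
    bottom = frozenset(c - 3 for c in hexose if c >= 4)
    return top, bottom


def condense(first: Labels, second: Labels) -> Labels:
    """Reverse aldolase: first triose -> hexose C1-C3, second -> C4-C6."""
    return frozenset({4 - c for c in first} | {c + 3 for c in second})


def ppp_cycle(
    hex_a: Labels, hex_b: Labels, hex_c: Labels
) -> tuple[Labels, Labels, Labels, int]:
    """Oxidative PPP on three hexose-P: 2 F6P + 1 triose + 3 CO2.

    Each hexose loses C1; the pentose carbons are renumbered 1..5.  A and C
    become X5P, B becomes R5P; TK1/TA/TK2 recombination gives
    F6P#1 = (a1,a2,b1,a3,a4,a5), F6P#2 = (c1,c2,b2,b3,b4,b5),
    GAP = (c3,c4,c5).  Returns the number of labeled CO2 as well.
    """
    co2 = sum(1 in h for h in (hex_a, hex_b, hex_c))
    a = {c - 1 for c in hex_a if c > 1}
    b = {c - 1 for c in hex_b if c > 1}
    c_ = {c - 1 for c in hex_c if c > 1}
    f6p1 = frozenset(
        pos
        for pos, (src, carbon) in enumerate(
            [(a, 1), (a, 2), (b, 1), (a, 3), (a, 4), (a, 5)], start=1
        )
        if carbon in src
    )
    f6p2 = frozenset(
        pos
        for pos, (src, carbon) in enumerate(
            [(c_, 1), (c_, 2), (b, 2), (b, 3), (b, 4), (b, 5)], start=1
        )
        if carbon in src
    )
    triose = frozenset(c - 2 for c in c_ if c >= 3)
    return f6p1, f6p2, triose, co2


def sample_fructose_patterns(
    f_in: float,
    f_fru: float,
    f_ppp: float,
    f_r: float,
    tracer: int,
    n_samples: int,
    seed: int,
    burn_in: int = 30000,
    reservoir: int = 2000,
) -> Counter:
    """Counter of fructose labeling patterns over ``n_samples`` molecules."""
    rng = random.Random(seed)
    glc = frozenset({tracer})
    f_split = f_in + f_r - f_fru - f_ppp / 3.0
    s_total = f_in + f_r + 2.0 * f_ppp / 3.0
    split_pushes = 2.0 * f_split / s_total  # expected split trioses per F6P event

    f6p_res: list[Labels] = [frozenset()] * reservoir
    tri_res: list[Labels] = [frozenset()] * reservoir
    ppp_pending: list[Labels] = []
    i_f6p = i_tri = 0
    counts: Counter = Counter()

    for step in range(burn_in + n_samples):
        r = rng.random() * s_total
        if r < f_in:
            mol = glc
        elif r < f_in + f_r:
            mol = condense(rng.choice(tri_res), rng.choice(tri_res))
        else:
            if not ppp_pending:
                p1, p2, tri, _ = ppp_cycle(
                    rng.choice(f6p_res), rng.choice(f6p_res), rng.choice(f6p_res)
                )
                ppp_pending.extend((p1, p2))
                tri_res[i_tri % reservoir] = tri
                i_tri += 1
            mol = ppp_pending.pop()
        f6p_res[i_f6p % reservoir] = mol
        i_f6p += 1

        n_push = int(split_pushes)
        if rng.random() < split_pushes - n_push:
            n_push += 1
        for _ in range(n_push):
            top, bottom = split_hexose(rng.choice(f6p_res))
            tri_res[i_tri % reservoir] = top if rng.random() < 0.5 else bottom
            i_tri += 1

        if step >= burn_in:
            counts[mol] += 1
    return counts
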
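"""Algebra of positional-isotopomer distributions.

A labeling pattern of an n-carbon metabolite is a binary word over the
positions 1..n (1 = carbon carries a 13C label).  Patterns are stored as
integers with the most significant bit corresponding to C1, so that for a
hexose the pattern ``[1,3]`` (C1 and C3 labeled) is ``0b101000``.  Pool
compositions are sparse mole-fraction maps over patterns; positional mole
fractions m_i (the marginal labeled fraction at carbon i) are the quantities
that enter the flux-inference formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids a circular import
    from .atom_maps import Species

#: renormalize silently below this drift of the fraction sum from 1
RENORM_TOL = 1e-9
#: hard error above this drift
DRIFT_TOL = 1e-6

Pattern = int


class NormalizationError(ValueError):
    """Mole fractions drift too far from summing to one."""


def pattern_from_positions(positions: Iterable[int], n_carbons: int) -> Pattern:
    """Encode labeled carbon positions (1-based) as an integer pattern."""
    p = 0
    for pos in positions:
        if not 1 <= pos <= n_carbons:
            raise ValueError(f"carbon position {pos} outside 1..{n_carbons}")
        p |= 1 << (n_carbons - pos)
    return p


def positions_from_pattern(pattern: Pattern, n_carbons: int) -> tuple[int, ...]:
    """Decode an integer pattern into sorted labeled positions (1-based)."""
    if pattern < 0 or pattern >= (1 << n_carbons):
        raise ValueError(f"pattern {pattern} does not fit in {n_carbons} carbons")
    return tuple(i for i in range(1, n_carbons + 1) if pattern >> (n_carbons - i) & 1)


def parse_pattern(text: str) -> tuple[int, ...]:
    """Parse the bracketed pattern syntax, e.g. ``"[1,3]"`` -> ``(1, 3)``.

    ``"[]"`` denotes the unlabeled isotopomer.
    """
    text = text.strip()
    if not (text.startswith("[") and text.endswith("]")):
        raise ValueError(f"malformed pattern string {text!r}; expected e.g. '[1,3]'")
    inner = text[1:-1].strip()
    if not inner:
        return ()
    try:
        positions = tuple(sorted(int(tok) for tok in inner.split(",")))
    except ValueError as exc:
        raise ValueError(f"malformed pattern string {text!r}") from exc
    if len(set(positions)) != len(positions) or any(p < 1 for p in positions):
        raise ValueError(f"malformed pattern string {text!r}")
    return positions


def format_pattern(pattern: Pattern, n_carbons: int) -> str:
    """Format an integer pattern as ``"[1,3]"`` (``"[]"`` if unlabeled)."""
    return "[" + ",".join(str(i) for i in positions_from_pattern(pattern, n_carbons)) + "]"


def n_labeled(pattern: Pattern) -> int:
    """Number of labeled carbons in a pattern."""
    return int(pattern).bit_count()


@dataclass
class PoolDistribution:
    """Sparse mole-fraction distribution over labeling patterns of one pool.

    Fractions must be non-negative and sum to 1 within ``DRIFT_TOL``; small
    drift (numerical round-off from repeated mixing) is silently renormalized.
    Only patterns with strictly positive mass are stored.
    """

    species: "Species"
    fractions: dict[Pattern, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.species.n_carbons
        limit = 1 << n
        clean: dict[Pattern, float] = {}
        total = 0.0
        for pat, frac in self.fractions.items():
            if not 0 <= pat < limit:
                raise ValueError(
                    f"pattern {pat} does not fit {self.species.name} ({n} carbons)"
                )
            if frac < 0:
                raise ValueError(f"negative mole fraction {frac} for pattern {pat}")
            if frac > 0.0:
                clean[pat] = clean.get(pat, 0.0) + frac
                total += frac
        if abs(total - 1.0) > DRIFT_TOL:
            raise NormalizationError(
                f"{self.species.name} fractions sum to {total:.9g}, drift exceeds {DRIFT_TOL}"
            )
        if abs(total - 1.0) > RENORM_TOL:
            clean = {p: f / total for p, f in clean.items()}
        elif total != 1.0 and total > 0:
            clean = {p: f / total for p, f in clean.items()}
        self.fractions = clean

    # -- constructors ------------------------------------------------------

    @classmethod
    def unlabeled(cls, species: "Species") -> "PoolDistribution":
        return cls(species, {0: 1.0})

    @classmethod
    def pure(cls, species: "Species", positions: Iterable[int]) -> "PoolDistribution":
        """Distribution with all mass on one isotopomer."""
        return cls(species, {pattern_from_positions(positions, species.n_carbons): 1.0})

    @classmethod
    def from_strings(
        cls, species: "Species", fractions: Mapping[str, float]
    ) -> "PoolDistribution":
        return cls(
            species,
            {
                pattern_from_positions(parse_pattern(k), species.n_carbons): v
                for k, v in fractions.items()
            },
        )

    # -- queries -----------------------------------------------------------

    def to_strings(self) -> dict[str, float]:
        n = self.species.n_carbons
        return {format_pattern(p, n): f for p, f in sorted(self.fractions.items())}

    def fraction_of(self, positions: Iterable[int]) -> float:
        """Mole fraction of one exact isotopomer, by labeled positions."""
        return self.fractions.get(
            pattern_from_positions(positions, self.species.n_carbons), 0.0
        )

    def prune(self, threshold: float = 1e-15) -> "PoolDistribution":
        """Drop patterns below ``threshold`` mass and renormalize."""
        kept = {p: f for p, f in self.fractions.items() if f >= threshold}
        if not kept:
            kept = {0: 1.0}
        return PoolDistribution(self.species, kept)


@dataclass(frozen=True)
class PositionalFractions:
    """Per-position labeled mole fractions m_1..m_n of one pool."""

    species_name: str
    m: tuple[float, ...]

    def __post_init__(self) -> None:
        for i, mi in enumerate(self.m, start=1):
            if not -1e-12 <= mi <= 1 + 1e-12:
                raise ValueError(f"m_{i} = {mi} outside [0, 1]")

    def at(self, position: int) -> float:
        """m_i for a 1-based carbon position."""
        if not 1 <= position <= len(self.m):
            raise ValueError(f"position {position} outside 1..{len(self.m)}")
        return self.m[position - 1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.m, dtype=float)


def positional_fractions(pool: PoolDistribution) -> PositionalFractions:
    """Marginal labeled mole fraction at each carbon position.

    m_i sums the fractions of all patterns labeled at position i; this is the
    quantity an inverse-gated 13C-NMR peak integral reports for carbon i.
    """
    n = pool.species.n_carbons
    m = [0.0] * n
    for pat, frac in pool.fractions.items():
        for i in range(1, n + 1):
            if pat >> (n - i) & 1:
                m[i - 1] += frac
    return PositionalFractions(pool.species.name, tuple(min(mi, 1.0) for mi in m))


def mix(pools: Sequence[tuple[PoolDistribution, float]]) -> PoolDistribution:
    """Flux- (or mole-) weighted mixture of distributions of one species."""
    if not pools:
        raise ValueError("nothing to mix")
    ref = pools[0][0].species
    total = 0.0
    acc: dict[Pattern, float] = {}
    for pool, weight in pools:
        if pool.species.name != ref.name or pool.species.n_carbons != ref.n_carbons:
            raise ValueError(
                f"species mismatch in mix: {pool.species.name} vs {ref.name}"
            )
        if weight < 0:
            raise ValueError(f"negative mix weight {weight}")
        total += weight
        for pat, frac in pool.fractions.items():
            acc[pat] = acc.get(pat, 0.0) + weight * frac
    if total <= 0:
        raise ValueError("mix weights are all zero")
    return PoolDistribution(ref, {p: f / total for p, f in acc.items()})


def labeled_carbon_content(pool: PoolDistribution) -> float:
    """Expected number of labeled carbons per molecule of the pool."""
    return sum(frac * n_labeled(pat) for pat, frac in pool.fractions.items())
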
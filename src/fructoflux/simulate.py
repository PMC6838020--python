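"""Forward simulation of the resting-cell single-tracer pulse experiment.

Model
-----
Non-growing cells receive a pulse of glucose 13C-labeled at one carbon
(C1 or C2).  Fluxes are zero-order (constant) while glucose remains and stop
at exhaustion; the intracellular hexose-P and triose-P pools are quasi-steady
(zero holdup), so their labeling compositions are the flux-weighted mixtures
of their inputs and are obtained by fixed-point iteration:

* F6P is fed by glucose uptake (f_in), by reverse-aldolase condensation of
  two trioses (f_r, hexose units), and by the PPP return ((2/3)·f_ppp);
* the triose pool is fed by aldolase cleavage of F6P (2 molecules per hexose)
  and by the PPP triose return ((1/3)·f_ppp), and is drained by condensation
  (2·f_r) and by the sinks.

Because the glucose pool keeps a fixed labeling pattern, the quasi-steady
compositions are time-invariant until exhaustion; extracellular fructose and
the sink products accumulate linearly with those frozen compositions.  That
is exactly the regime in which the steady-state inference formulas apply.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .atom_maps import Network, apply_map, build_default_network
from .isotopomer import (
    PoolDistribution,
    format_pattern,
    mix,
    n_labeled,
    parse_pattern,
    pattern_from_positions,
)

DEFAULT_SINK_SPLIT = {
    "ethanol": 0.70,
    "glycerol": 0.10,
    "pyruvate": 0.06,
    "acetate": 0.05,
    "dihydroxyacetone": 0.04,
    "tca": 0.05,
}

#: carbon counts of the species appearing in time-course tables
SPECIES_CARBONS = {
    "glucose": 6, "fructose": 6, "F6P": 6, "triose": 3,
    "pyruvate": 3, "glycerol": 3, "dihydroxyacetone": 3, "tca": 3,
    "ethanol": 2, "acetate": 2, "CO2": 1,
}

TSV_COLUMNS = ("time_min", "species", "pattern", "conc_mM")


@dataclass
class FluxConfig:
    """Ground-truth (or hypothesized) flux set of the resting-cell model.

    All fluxes in mM/min referred to the extracellular volume; f_ppp and f_r
    in hexose equivalents.  ``sink_split`` gives the fractions of the net
    triose consumption routed to each terminal product.
    """

    f_in: float
    f_fru: float
    f_ppp: float = 0.0
    f_r: float = 0.0
    glucose_0: float = 50.0
    tracer: int = 1
    sink_split: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SINK_SPLIT)
    )

    def __post_init__(self) -> None:
        for name in ("f_in", "f_fru", "f_ppp", "f_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.glucose_0 <= 0:
            raise ValueError("glucose_0 must be > 0")
        if self.tracer not in (1, 2):
            raise ValueError("tracer must be carbon 1 or 2")
        s = sum(self.sink_split.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"sink_split sums to {s}, expected 1")
        if any(v < 0 for v in self.sink_split.values()):
            raise ValueError("sink_split fractions must be >= 0")
        if self.f_glyc_net < -1e-12:
            raise ValueError(
                "net F6P->glycolysis flux f_in - f_fru - f_ppp/3 is negative"
            )
        if self.f_split < -1e-12:
            raise ValueError("aldolase cleavage flux would be negative")
        if self.f_sink_total < -1e-12:
            raise ValueError("net triose consumption by sinks would be negative")

    @property
    def f_glyc_net(self) -> float:
        """Net F6P consumption by glycolysis+PPP carbon loss (hexose units)."""
        return self.f_in - self.f_fru - self.f_ppp / 3.0

    @property
    def f_split(self) -> float:
        """Gross aldolase cleavage flux (hexose units): F6P in minus other outs."""
        return self.f_in + self.f_r - self.f_fru - self.f_ppp / 3.0

    @property
    def f_sink_total(self) -> float:
        """Net triose consumption by the sinks (triose units)."""
        return 2.0 * self.f_split + self.f_ppp / 3.0 - 2.0 * self.f_r

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FluxConfig":
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SimState:
    """Quasi-steady intracellular compositions and the fixed sink makeup."""

    f6p: PoolDistribution
    triose: PoolDistribution
    fructose: PoolDistribution
    sink_dists: dict[str, PoolDistribution]
    co2_labeled_fraction_ppp: float
    sink_rates: dict[str, float]        # product formation, mM/min
    co2_rate: float                     # total CO2 carbon release, mM/min
    co2_labeled_rate: float             # labeled CO2 carbon release, mM/min


_DEFAULT_NETWORK: Network | None = None
_STEADY_CACHE: dict[tuple, SimState] = {}


def _shared_default_network() -> Network:
    global _DEFAULT_NETWORK
    if _DEFAULT_NETWORK is None:
        _DEFAULT_NETWORK = build_default_network()
    return _DEFAULT_NETWORK


def solve_steady_pools(
    config: FluxConfig,
    network: Network | None = None,
    tol: float = 1e-14,
    max_iter: int = 500,
    prune: float = 1e-13,
) -> SimState:
    """Fixed point of the quasi-steady F6P / triose-pool label balance.

    Patterns below ``prune`` mole fraction are dropped between iterations;
    solutions are cached per (config, network) since the fixed point is
    deterministic.
    """
    net = network if network is not None else _shared_default_network()
    cache_key = (config.config_hash(), id(net), tol, prune)
    cached = _STEADY_CACHE.get(cache_key)
    if cached is not None:
        return cached
    f6p_sp = net.species["F6P"]
    tri_sp = net.species["triose"]
    glc = PoolDistribution.pure(net.species["glucose"], (config.tracer,))
    glc_as_f6p = PoolDistribution(f6p_sp, dict(glc.fractions))

    d_f6p = PoolDistribution.unlabeled(f6p_sp)
    d_tri = PoolDistribution.unlabeled(tri_sp)
    condense = net["aldolase_condense"]
    split = net["aldolase_split"]
    ppp = net["ppp_cycle"]
    ppp_co2 = 0.0

    for _ in range(max_iter):
        sources = [(glc_as_f6p, config.f_in)]
        if config.f_r > 0:
            (cond,), _ = apply_map(condense, [d_tri, d_tri])
            sources.append((cond, config.f_r))
        if config.f_ppp > 0:
            (ppp_a, ppp_b, ppp_tri), ppp_co2 = apply_map(ppp, [d_f6p] * 3)
            sources.append((mix([(ppp_a, 0.5), (ppp_b, 0.5)]), 2.0 / 3.0 * config.f_ppp))
        new_f6p = mix(sources).prune(prune)

        tri_sources = []
        if config.f_split > 0:
            (top, bottom), _ = apply_map(split, [new_f6p])
            tri_sources.append((mix([(top, 0.5), (bottom, 0.5)]), 2.0 * config.f_split))
        if config.f_ppp > 0:
            tri_sources.append((ppp_tri, config.f_ppp / 3.0))
        new_tri = (
            mix(tri_sources).prune(prune) if tri_sources else
            PoolDistribution.unlabeled(tri_sp)
        )

        delta = _l1(new_f6p, d_f6p) + _l1(new_tri, d_tri)
        d_f6p, d_tri = new_f6p, new_tri
        if delta < tol:
            break
    else:
        raise RuntimeError("steady-pool fixed point did not converge")

    # recompute PPP CO2 labeling at the converged composition
    if config.f_ppp > 0:
        _, ppp_co2 = apply_map(ppp, [d_f6p] * 3)

    fructose, _ = apply_map(net["f6p_phosphatase"], [d_f6p])
    (pyr,), _ = apply_map(net["triose_to_pyruvate"], [d_tri])
    (eth,), eth_co2 = apply_map(net["pyruvate_to_ethanol"], [pyr])
    (ace,), ace_co2 = apply_map(net["pyruvate_to_acetate"], [pyr])
    (tca,), _ = apply_map(net["pyruvate_to_tca"], [pyr])
    (gly,), _ = apply_map(net["triose_to_glycerol"], [d_tri])
    (dha,), _ = apply_map(net["triose_to_dha"], [d_tri])
    sink_dists = {
        "ethanol": eth, "acetate": ace, "pyruvate": pyr, "tca": tca,
        "glycerol": gly, "dihydroxyacetone": dha,
    }

    rates = {
        name: config.sink_split.get(name, 0.0) * config.f_sink_total
        for name in sink_dists
    }
    # CO2: 3 per 3 hexoses through PPP (i.e. f_ppp carbons/min) plus one per
    # pyruvate decarboxylated on the ethanol and acetate routes.
    co2_rate = config.f_ppp + rates["ethanol"] + rates["acetate"]
    co2_labeled_rate = (
        config.f_ppp * ppp_co2
        + rates["ethanol"] * eth_co2
        + rates["acetate"] * ace_co2
    )
    state = SimState(
        f6p=d_f6p,
        triose=d_tri,
        fructose=fructose[0],
        sink_dists=sink_dists,
        co2_labeled_fraction_ppp=ppp_co2,
        sink_rates=rates,
        co2_rate=co2_rate,
        co2_labeled_rate=co2_labeled_rate,
    )
    _STEADY_CACHE[cache_key] = state
    return state


def _l1(a: PoolDistribution, b: PoolDistribution) -> float:
    keys = set(a.fractions) | set(b.fractions)
    return sum(abs(a.fractions.get(k, 0.0) - b.fractions.get(k, 0.0)) for k in keys)


@dataclass
class TimeCourse:
    """Tidy (time, species, pattern, concentration) table with provenance."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = set(TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"time course missing columns {sorted(missing)}")
        if (df["time_min"] < 0).any():
            bad = int(df.index[df["time_min"] < 0][0]) + 1
            raise ValueError(f"negative time at data row {bad}")
        if (df["conc_mM"] < 0).any():
            bad = int(df.index[df["conc_mM"] < 0][0]) + 1
            raise ValueError(f"negative concentration at data row {bad}")
        self.data = df.reset_index(drop=True)

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.data["time_min"].to_numpy(dtype=float))

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.data["species"]))

    def species_total(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-time total concentration of one species (summed over patterns)."""
        if species not in set(self.data["species"]):
            raise KeyError(f"species {species!r} not in time course")
        sub = self.data[self.data["species"] == species]
        grouped = sub.groupby("time_min", sort=True)["conc_mM"].sum()
        return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)

    def pattern_concentrations(
        self, species: str, time: float
    ) -> dict[str, float]:
        sub = self.data[
            (self.data["species"] == species)
            & (np.isclose(self.data["time_min"], time))
        ]
        if sub.empty:
            raise KeyError(f"no rows for {species!r} at t={time}")
        return dict(zip(sub["pattern"], sub["conc_mM"]))

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        with open(sidecar, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_tsv(cls, path) -> "TimeCourse":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = set(TSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for i, pat in enumerate(df["pattern"]):
            try:
                parse_pattern(str(pat))
            except ValueError as exc:
                raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
        if (df["conc_mM"] < 0).any():
            row = int(df.index[df["conc_mM"] < 0][0]) + 1
            raise ValueError(f"{path}: row {row}: negative concentration")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        metadata = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                metadata = json.load(fh)
        return cls(df, metadata)


def total_species_timecourse(
    tc: TimeCourse, species: str
) -> tuple[np.ndarray, np.ndarray]:
    """Series of (time, total mM) for one species."""
    return tc.species_total(species)


def labeled_carbon_series(tc: TimeCourse) -> tuple[np.ndarray, np.ndarray]:
    """Total labeled carbons (mM carbon) summed over all pools, per time."""
    df = tc.data.copy()
    df["labeled"] = [
        conc * len(parse_pattern(pat))
        for pat, conc in zip(df["pattern"], df["conc_mM"])
    ]
    grouped = df.groupby("time_min", sort=True)["labeled"].sum()
    return grouped.index.to_numpy(dtype=float), grouped.to_numpy(dtype=float)


def run_resting_cell(
    config: FluxConfig,
    time_grid: Sequence[float],
    network: Network | None = None,
    dt: float = 0.1,
    output_threshold: float = 1e-12,
) -> TimeCourse:
    """Simulate the tracer pulse and sample the supernatant at ``time_grid``.

    Explicit time stepping with step <= ``dt`` min; all fluxes stop once
    glucose is exhausted (the final step is shortened to hit exhaustion
    exactly).  Pattern rows with concentration below ``output_threshold``
    (relative to the pulse size) are omitted from the table.
    """
    grid = list(time_grid)
    if not grid or grid[0] != 0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("time grid must start at 0 and be strictly increasing")
    if dt <= 0 or dt > 0.1:
        raise ValueError("dt must be in (0, 0.1] min")
    net = network if network is not None else _shared_default_network()
    state = solve_steady_pools(config, net)

    tracer_pattern = format_pattern(
        pattern_from_positions((config.tracer,), 6), 6
    )

    glucose = config.glucose_0
    fructose = 0.0
    sinks = {name: 0.0 for name in state.sink_dists}
    co2_total = 0.0
    co2_labeled = 0.0

    rows: list[tuple[float, str, str, float]] = []

    def emit(t: float) -> None:
        rows.append((t, "glucose", tracer_pattern, glucose))
        cutoff = output_threshold * config.glucose_0
        if fructose == 0.0:
            rows.append((t, "fructose", "[]", 0.0))
        else:
            for pat, frac in sorted(state.fructose.fractions.items()):
                conc = fructose * frac
                if conc > cutoff:
                    rows.append((t, "fructose", format_pattern(pat, 6), conc))
        for name, dist in state.sink_dists.items():
            n = dist.species.n_carbons
            total = sinks[name]
            if total == 0.0:
                rows.append((t, name, "[]", 0.0))
                continue
            for pat, frac in sorted(dist.fractions.items()):
                conc = total * frac
                if conc > cutoff:
                    rows.append((t, name, format_pattern(pat, n), conc))
        rows.append((t, "CO2", "[]", max(co2_total - co2_labeled, 0.0)))
        rows.append((t, "CO2", "[1]", co2_labeled))

    t = 0.0
    grid_iter = iter(grid)
    next_out = next(grid_iter)
    done = False
    while not done:
        if abs(t - next_out) < 1e-9:
            emit(next_out)
            nxt = next(grid_iter, None)
            if nxt is None:
                break
            next_out = nxt
        step = min(dt, next_out - t)
        if config.f_in > 0 and glucose > 0:
            dt_eff = min(step, glucose / config.f_in)
        elif glucose > 0:
            dt_eff = step
        else:
            dt_eff = 0.0
        if dt_eff > 0:
            glucose = max(glucose - config.f_in * dt_eff, 0.0)
            fructose += config.f_fru * dt_eff
            for name, rate in state.sink_rates.items():
                sinks[name] += rate * dt_eff
            co2_total += state.co2_rate * dt_eff
            co2_labeled += state.co2_labeled_rate * dt_eff
        t += step

    df = pd.DataFrame(rows, columns=list(TSV_COLUMNS))
    metadata = {
        "tracer": config.tracer,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": None,
        "noise": None,
        "dt_min": dt,
        "generator": f"fructoflux {__version__}",
    }
    return TimeCourse(df, metadata)


def fructose_composition(
    config: FluxConfig, network: Network | None = None
) -> PoolDistribution:
    """Steady labeling composition of excreted fructose for a flux set."""
    return solve_steady_pools(config, network).fructose


def conservation_error(tc: TimeCourse, config: FluxConfig) -> float:
    """Max relative deviation of total labeled carbon from the pulse label.

    The pulse carries one labeled carbon per glucose molecule, so the labeled
    carbon inventory over all pools plus CO2 should stay at ``glucose_0`` mM.
    """
    _, labeled = labeled_carbon_series(tc)
    return float(np.max(np.abs(labeled - config.glucose_0)) / config.glucose_0)
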
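"""Synthetic NMR-style supernatant tables for the tracer experiments.

The generator wraps the deterministic simulator with a measurement model
emulating quantitative 13C-NMR of culture supernatants: independent Gaussian
error per quantified peak (a relative term for integration/ phasing error
plus an absolute baseline term), clamping at zero, and a detection limit
below which a species is simply not observed.  It exists so that the
inference pipeline can be exercised end-to-end, with known ground truth,
without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .atom_maps import Network
from .simulate import FluxConfig, TimeCourse, run_resting_cell

#: sampling grid of the resting-cell assay, minutes
DEFAULT_TIME_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 120.0)

# Published point estimates for the wild-type-derived double-deletion strain
# used as the shipped ground truth (mM/min; glucose_0 in mM).
FIXTURE_F_IN = 1.47
FIXTURE_F_FRU = 0.68
FIXTURE_F_PPP = 0.08
FIXTURE_GLUCOSE_0 = 50.0
#: back-flux as a fraction of the forward glycolytic flux (f_glyc + f_r)
FIXTURE_R_BACK = 0.48


@dataclass
class NoiseModel:
    """Measurement noise for one synthetic experiment.

    sd of each concentration = ``relative_sd * value + absolute_sd`` (mM);
    values are clamped at zero and censored to zero below
    ``detection_limit``.  Fully deterministic given ``seed``.
    """

    relative_sd: float = 0.05
    absolute_sd: float = 0.05
    detection_limit: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.relative_sd, self.absolute_sd, self.detection_limit) < 0:
            raise ValueError("noise parameters must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_experiment(
    config: FluxConfig,
    noise: NoiseModel | None = None,
    time_grid: Sequence[float] = DEFAULT_TIME_GRID,
    network: Network | None = None,
) -> TimeCourse:
    """Simulate one tracer experiment and apply the measurement model.

    Rows are perturbed in their fixed table order, so output is byte-stable
    for a given (config, noise, grid).
    """
    noise = noise if noise is not None else NoiseModel()
    tc = run_resting_cell(config, time_grid, network)
    df = tc.data.copy()
    if noise.relative_sd > 0 or noise.absolute_sd > 0:
        rng = np.random.default_rng(noise.seed)
        conc = df["conc_mM"].to_numpy(dtype=float)
        sd = noise.relative_sd * conc + noise.absolute_sd
        conc = np.clip(conc + rng.normal(size=conc.shape) * sd, 0.0, None)
        df["conc_mM"] = conc
    if noise.detection_limit > 0:
        df.loc[df["conc_mM"] < noise.detection_limit, "conc_mM"] = 0.0
    metadata = dict(tc.metadata)
    metadata["noise"] = noise.to_dict()
    metadata["seed"] = noise.seed
    return TimeCourse(df, metadata)


def reference_fixture() -> tuple[FluxConfig, FluxConfig]:
    """The shipped ground-truth flux set, one config per tracer position.

    The back-flux is not stated directly as a rate; it is fixed by requiring
    f_r / (f_glyc + f_r) = 48% with the forward glycolytic denominator
    f_glyc = f_in - f_fru, i.e. f_r = 0.48/0.52 * (f_in - f_fru).
    """
    f_glyc = FIXTURE_F_IN - FIXTURE_F_FRU
    f_r = FIXTURE_R_BACK / (1.0 - FIXTURE_R_BACK) * f_glyc
    make = lambda tracer: FluxConfig(
        f_in=FIXTURE_F_IN,
        f_fru=FIXTURE_F_FRU,
        f_ppp=FIXTURE_F_PPP,
        f_r=f_r,
        glucose_0=FIXTURE_GLUCOSE_0,
        tracer=tracer,
    )
    return make(1), make(2)
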
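"""Steady-state flux inference from tracer time courses.

Estimation strategy
-------------------
* **Uptake and excretion rates.**  Glucose consumption and fructose
  accumulation are approximately linear while glucose lasts; both rates are
  ordinary-least-squares slopes over the pre-exhaustion window (grid points
  at which glucose is still above the detection limit).
* **Back-flux f_r.**  Under a C1 tracer the pentose phosphate pathway
  cannot label fructose (the tracer carbon is lost as CO2), so any
  [6-13C]fructose comes from triose molecules re-condensed by aldolase.
  At composition steady state the ratio of original to reversed label is
  (2·f_in + f_r) / f_r, inverted here as f_r = 2·f_in / (m_orig/m_rev - 1).
* **PPP flux f_ppp.**  Under a C2 tracer the first PPP cycle converts three
  [2-13C]hexoses into one [1-13C]- and one [1,3-13C]-F6P, so C1-labeled
  fructose marks PPP turnover while C2/C5 label marks the direct route
  (with reversal).  With positional mole fractions m_1, m_2, m_5 of
  steady-state fructose, f_ppp = 1.5·m_1·f_in / (1.5·m_1 + m_2 + m_5);
  the 1.5 accounts for two fructoses made per three glucoses consumed.

Uncertainties are seeded bootstrap SDs: residual resampling for the linear
fits, pairs resampling of the steady-window time points for the
fraction-based estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .isotopomer import PositionalFractions, parse_pattern
from .simulate import SPECIES_CARBONS, TimeCourse

DEFAULT_T_STEADY = 30.0
DEFAULT_DETECTION_LIMIT = 0.1
DEFAULT_BOOTSTRAP = 200


class ModelViolationError(ValueError):
    """Observed labeling is inconsistent with the flux model."""


def fit_linear_rate(
    times, values, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """OLS slope magnitude and its standard error for a concentration series.

    ``window`` restricts the fit to ``window[0] <= t <= window[1]``.
    Consumption and production rates are both reported positive.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t, v = t[keep], v[keep]
    if t.size < 3:
        raise ValueError(f"need at least 3 points for a rate fit, got {t.size}")
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in rate fit")
    res = stats.linregress(t, v)
    return abs(float(res.slope)), float(res.stderr)


def steady_state_fractions(
    tc: TimeCourse,
    species: str,
    t_min: float = DEFAULT_T_STEADY,
    n_carbons: int | None = None,
) -> PositionalFractions:
    """Concentration-weighted positional mole fractions over ``t >= t_min``."""
    conc = _window_pattern_concentrations(tc, species, t_min)
    total = sum(sum(c.values()) for c in conc.values())
    if total <= 0:
        raise ValueError(
            f"all {species} concentrations are zero for t >= {t_min}"
        )
    if n_carbons is None:
        n_carbons = SPECIES_CARBONS.get(species)
    if n_carbons is None:
        n_carbons = max(
            (max(parse_pattern(p), default=0) for c in conc.values() for p in c),
            default=1,
        )
    return _fractions_from_concentrations(
        species, list(conc.values()), n_carbons
    )


def _window_pattern_concentrations(
    tc: TimeCourse, species: str, t_min: float
) -> dict[float, dict[str, float]]:
    if species not in set(tc.data["species"]):
        raise KeyError(f"species {species!r} not in time course")
    sub = tc.data[(tc.data["species"] == species) & (tc.data["time_min"] >= t_min)]
    times = sorted(set(sub["time_min"]))
    if len(times) < 2:
        raise ValueError(
            f"need >= 2 time points at t >= {t_min} for {species}, got {len(times)}"
        )
    return {
        t: dict(
            zip(
                sub[sub["time_min"] == t]["pattern"],
                sub[sub["time_min"] == t]["conc_mM"],
            )
        )
        for t in times
    }


def _fractions_from_concentrations(
    species: str, per_time: list[dict[str, float]], n_carbons: int
) -> PositionalFractions:
    m = np.zeros(n_carbons)
    total = 0.0
    for conc in per_time:
        for pat, c in conc.items():
            total += c
            for pos in parse_pattern(pat):
                m[pos - 1] += c
    if total <= 0:
        raise ValueError(f"all {species} concentrations zero in window")
    return PositionalFractions(species, tuple(np.clip(m / total, 0.0, 1.0)))


def estimate_backflux(m_orig: float, m_rev: float, f_in: float) -> float:
    """Invert the original/reversed-label ratio for the aldolase back-flux.

    With rho = m_orig/m_rev = (2·f_in + f_r)/f_r, returns
    f_r = 2·f_in/(rho - 1).  A reversed fraction of zero means no detectable
    back-flux; m_orig <= m_rev has no non-negative solution and signals a
    violated model.
    """
    if f_in <= 0:
        raise ValueError("f_in must be > 0")
    if m_rev < 0 or m_orig < 0:
        raise ValueError("mole fractions must be >= 0")
    if m_rev == 0.0:
        return 0.0
    if m_orig == 0.0:
        raise ModelViolationError("original-label fraction is zero")
    if m_orig <= m_rev:
        raise ModelViolationError(
            f"original fraction {m_orig:.4g} <= reversed fraction {m_rev:.4g}: "
            "the label ratio (2 f_in + f_r)/f_r cannot be <= 1"
        )
    rho = m_orig / m_rev
    return 2.0 * f_in / (rho - 1.0)


def estimate_ppp(m1: float, m2: float, m5: float, f_in: float) -> float:
    """PPP entry flux from C2-tracer fructose positional fractions.

    f_ppp = 1.5·m1·f_in / (1.5·m1 + m2 + m5); scale-free in the m's.
    """
    if f_in <= 0:
        raise ValueError("f_in must be > 0")
    if min(m1, m2, m5) < 0:
        raise ValueError("mole fractions must be >= 0")
    denom = 1.5 * m1 + m2 + m5
    if denom == 0:
        raise ValueError("m1, m2, m5 are all zero")
    return 1.5 * m1 * f_in / denom


def bootstrap_sd(statistic, data, B: int = DEFAULT_BOOTSTRAP, seed: int = 0) -> float:
    """SD of ``statistic`` over ``B`` bootstrap resamples of ``data`` rows."""
    if B < 50:
        raise ValueError("use at least 50 bootstrap replicates")
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    n = data.shape[0]
    reps = np.array(
        [statistic(data[rng.integers(0, n, size=n)]) for _ in range(B)],
        dtype=float,
    )
    return float(np.std(reps, ddof=1))


def slope_bootstrap_sd(
    times, values, B: int = DEFAULT_BOOTSTRAP, seed: int = 0
) -> float:
    """Residual-bootstrap SD of an OLS slope (0 for exactly linear data)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    res = stats.linregress(t, v)
    fitted = res.intercept + res.slope * t
    resid = v - fitted
    if np.allclose(resid, 0.0):
        return 0.0
    rng = np.random.default_rng(seed)
    n = t.size
    reps = np.empty(B)
    for b in range(B):
        vb = fitted + resid[rng.integers(0, n, size=n)]
        reps[b] = stats.linregress(t, vb).slope
    return float(np.std(reps, ddof=1))


@dataclass
class FluxEstimate:
    """Inferred flux set with bootstrap SDs and the headline ratios."""

    f_in: float
    f_fru: float
    f_r: float
    f_ppp: float
    f_in_sd: float = 0.0
    f_fru_sd: float = 0.0
    f_r_sd: float = 0.0
    f_ppp_sd: float = 0.0
    r_back: float = 0.0        # f_r / (f_glyc_net + f_r)
    r_back_sd: float = 0.0
    r_divert: float = 0.0      # f_fru / (f_in - f_fru)
    r_divert_sd: float = 0.0
    f_r_c2: float | None = None  # cross-check from the C2 tracer (m2 vs m5)
    reversed_fraction_c1: float | None = None  # m6 of fructose, C1 tracer
    window: tuple[float, float] = (0.0, 0.0)
    t_steady: float = DEFAULT_T_STEADY
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("f_in", "f_fru", "f_r", "f_ppp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.r_back < 1.0:
            raise ValueError("r_back must be in [0, 1)")
        if self.r_divert < 0:
            raise ValueError("r_divert must be >= 0")

    @property
    def f_glyc_net(self) -> float:
        return self.f_in - self.f_fru

    def to_dict(self) -> dict:
        d = asdict(self)
        d["f_glyc_net"] = self.f_glyc_net
        return d

    def summary(self) -> str:
        lines = [
            "flux estimate (mM/min unless noted)",
            f"  fit window           : {self.window[0]:g}-{self.window[1]:g} min"
            f" | steady state from {self.t_steady:g} min",
            f"  f_in   (uptake)      : {self.f_in:8.4f} +/- {self.f_in_sd:.4f}",
            f"  f_fru  (F6P->fru)    : {self.f_fru:8.4f} +/- {self.f_fru_sd:.4f}",
            f"  f_r    (back-flux)   : {self.f_r:8.4f} +/- {self.f_r_sd:.4f}",
            f"  f_ppp  (PPP entry)   : {self.f_ppp:8.4f} +/- {self.f_ppp_sd:.4f}",
            f"  r_back  [% fwd glyc] : {100 * self.r_back:8.2f} +/- {100 * self.r_back_sd:.2f}",
            f"  r_divert [% net glyc]: {100 * self.r_divert:8.2f} +/- {100 * self.r_divert_sd:.2f}",
        ]
        if self.f_r_c2 is not None:
            lines.append(f"  f_r cross-check (C2) : {self.f_r_c2:8.4f}")
        if self.reversed_fraction_c1 is not None:
            lines.append(
                f"  reversed label m6(C1): {self.reversed_fraction_c1:8.4f}"
            )
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


def _tracer_of(tc: TimeCourse) -> int:
    meta = tc.metadata.get("tracer")
    if meta in (1, 2):
        return int(meta)
    # fall back to the glucose pattern at t = 0
    pats = tc.pattern_concentrations("glucose", float(tc.times[0]))
    labeled = [parse_pattern(p) for p, c in pats.items() if c > 0]
    for pos in (1, 2):
        if any(p == (pos,) for p in labeled):
            return pos
    raise ValueError("cannot determine tracer position from time course")


def _uptake_window(
    tc: TimeCourse, detection_limit: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grid times before glucose exhaustion, with glucose/fructose totals."""
    t_glc, glc = tc.species_total("glucose")
    above = glc > detection_limit
    if above.all():
        cut = len(t_glc)
    else:
        cut = int(np.argmin(above))  # first exhausted point
    t_win = t_glc[:cut]
    t_fru, fru = tc.species_total("fructose")
    fru_win = np.array(
        [fru[np.searchsorted(t_fru, t)] for t in t_win]
    )
    return t_win, glc[:cut], fru_win


def infer_all(
    tc_c1: TimeCourse,
    tc_c2: TimeCourse,
    t_steady: float = DEFAULT_T_STEADY,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
) -> FluxEstimate:
    """Full flux inference from a C1- and a C2-tracer experiment.

    f_in and f_fru are fit on the pre-exhaustion window of each experiment
    and averaged across the two tracers; f_r comes from the C1 experiment's
    m1/m6 ratio (the C2-based m2/m5 estimate is reported as a cross-check);
    f_ppp from the C2 experiment's m1/m2/m5 formula.
    """
    if _tracer_of(tc_c1) != 1 or _tracer_of(tc_c2) != 2:
        raise ValueError(
            "expected a [1-13C] experiment first and a [2-13C] experiment second"
        )

    windows, slopes_in, slopes_fru = [], [], []
    series = []
    for tc in (tc_c1, tc_c2):
        t_win, glc, fru = _uptake_window(tc, detection_limit)
        if t_win.size < 3:
            raise ValueError(
                "fewer than 3 pre-exhaustion points; cannot fit uptake rate"
            )
        slopes_in.append(fit_linear_rate(t_win, glc)[0])
        slopes_fru.append(fit_linear_rate(t_win, fru)[0])
        windows.append((float(t_win[0]), float(t_win[-1])))
        series.append((t_win, glc, fru))
    f_in = float(np.mean(slopes_in))
    f_fru = float(np.mean(slopes_fru))

    ss_c1 = steady_state_fractions(tc_c1, "fructose", t_steady)
    ss_c2 = steady_state_fractions(tc_c2, "fructose", t_steady)
    f_r = estimate_backflux(ss_c1.at(1), ss_c1.at(6), f_in)
    f_ppp = estimate_ppp(ss_c2.at(1), ss_c2.at(2), ss_c2.at(5), f_in)
    try:
        f_r_c2 = estimate_backflux(ss_c2.at(2), ss_c2.at(5), f_in)
    except ModelViolationError:
        f_r_c2 = None

    f_glyc = f_in - f_fru
    r_back = f_r / (f_glyc + f_r) if (f_glyc + f_r) > 0 else 0.0
    r_divert = f_fru / f_glyc if f_glyc > 0 else 0.0

    sds = _bootstrap_all(
        series, (tc_c1, tc_c2), t_steady, n_bootstrap, seed
    )

    notes = []
    if ss_c1.at(6) > 0:
        notes.append(
            f"reversed-label fraction m6 = {ss_c1.at(6):.3f} under the C1 tracer"
        )
    return FluxEstimate(
        f_in=f_in,
        f_fru=f_fru,
        f_r=f_r,
        f_ppp=f_ppp,
        r_back=r_back,
        r_divert=r_divert,
        f_r_c2=f_r_c2,
        reversed_fraction_c1=ss_c1.at(6),
        window=windows[0],
        t_steady=t_steady,
        notes=notes,
        **sds,
    )


def _bootstrap_all(
    series, tcs, t_steady: float, B: int, seed: int
) -> dict[str, float]:
    """Bootstrap SDs for all estimates (residual + window-pairs resampling)."""
    rng = np.random.default_rng(seed)
    fits = []
    for t_win, glc, fru in series:
        for v in (glc, fru):
            res = stats.linregress(t_win, v)
            fitted = res.intercept + res.slope * t_win
            fits.append((t_win, fitted, v - fitted))
    window_conc = [
        list(_window_pattern_concentrations(tc, "fructose", t_steady).values())
        for tc in tcs
    ]

    reps: dict[str, list[float]] = {
        k: [] for k in ("f_in", "f_fru", "f_r", "f_ppp", "r_back", "r_divert")
    }
    for _ in range(B):
        slopes = []
        for t_win, fitted, resid in fits:
            n = t_win.size
            vb = fitted + resid[rng.integers(0, n, size=n)]
            slopes.append(abs(stats.linregress(t_win, vb).slope))
        f_in_b = 0.5 * (slopes[0] + slopes[2])
        f_fru_b = 0.5 * (slopes[1] + slopes[3])

        ms = []
        for conc_list in window_conc:
            n = len(conc_list)
            sample = [conc_list[i] for i in rng.integers(0, n, size=n)]
            ms.append(_fractions_from_concentrations("fructose", sample, 6))
        try:
            f_r_b = estimate_backflux(ms[0].at(1), ms[0].at(6), f_in_b)
        except (ModelViolationError, ValueError):
            f_r_b = np.nan
        try:
            f_ppp_b = estimate_ppp(ms[1].at(1), ms[1].at(2), ms[1].at(5), f_in_b)
        except ValueError:
            f_ppp_b = np.nan
        f_glyc_b = f_in_b - f_fru_b
        reps["f_in"].append(f_in_b)
        reps["f_fru"].append(f_fru_b)
        reps["f_r"].append(f_r_b)
        reps["f_ppp"].append(f_ppp_b)
        reps["r_back"].append(
            f_r_b / (f_glyc_b + f_r_b) if f_glyc_b + f_r_b > 0 else np.nan
        )
        reps["r_divert"].append(f_fru_b / f_glyc_b if f_glyc_b > 0 else np.nan)

    out = {}
    for key, values in reps.items():
        arr = np.asarray(values, dtype=float)
        good = arr[np.isfinite(arr)]
        out[f"{key}_sd"] = float(np.std(good, ddof=1)) if good.size > 1 else 0.0
    return out
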
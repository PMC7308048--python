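"""Statistics for the functional assays: protein decay, reporter, and flow data.

Cycloheximide-chase densitometry is normalized to percent of the t = 0 signal
and fitted with a one-phase exponential decay

    y(t) = plateau + (y0 - plateau) * exp(-K * t),        K >= 0

from which the half-life is ln(2)/K.  Whether two conditions share a decay
constant is decided with the extra sum-of-squares F test between the nested
shared-K and separate-K fits.  Dual-luciferase readings are normalized
per-well by the co-transfected Renilla signal and scaled to a reference
condition; flow-cytometry surface expression is summarized as
nMFI = MFI(sample) / MFI(control).

The default decay model fixes y0 = 100 and plateau = 0 (a plain exponential
on the percent scale, matching the t = 0 = 100% normalization); both
parameters can be freed.  Fitting profiles the linear parameters out in
closed form and minimizes over K with a deterministic log-spaced grid plus
bounded refinement, so results carry no seed dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist

__all__ = [
    "DecayCurve",
    "DecayFit",
    "FTestResult",
    "normalize_chx",
    "fit_one_phase_decay",
    "compare_decay_constants",
    "normalize_luciferase",
    "compute_nmfi",
    "percent_of_reference",
]

LN2 = math.log(2.0)
_K_MAX = 50.0  # per hour; half-life under a minute is out of assay resolution
_K_GRID = np.concatenate([[0.0], np.logspace(-4, math.log10(_K_MAX), 120)])


@dataclass
class DecayCurve:
    """A decay time course: hours post-treatment and signal values.

    On the percent-of-t0 convention the first value is 100 at time 0; raw
    (unnormalized) curves are accepted as long as times start at 0 and
    strictly increase.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0 or self.times[0] != 0.0:
            raise ValueError("the time course must start at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DecayFit:
    K: float
    y0: float
    plateau: float
    half_life: float
    rss: float
    n_points: int
    n_params: int


@dataclass
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p: float
    rss_shared: float
    rss_separate: float


def normalize_chx(
    times: np.ndarray,
    target: np.ndarray,
    control: np.ndarray,
) -> DecayCurve:
    """Convert raw target/loading-control densitometry to percent of t = 0.

    value(t) = 100 * (target(t)/control(t)) / (target(0)/control(0)).
    """
    times = np.asarray(times, dtype=float)
    target = np.asarray(target, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(times) == 0 or times[0] != 0.0:
        raise ValueError("the t = 0 point is required for normalization")
    if np.any(control <= 0):
        raise ValueError("loading-control intensities must be positive")
    ratio = target / control
    return DecayCurve(times=times, values=100.0 * ratio / ratio[0])


def _n_free_params(plateau_mode: str, y0_mode: str) -> int:
    if plateau_mode not in ("fixed_zero", "free"):
        raise ValueError(f"unknown plateau mode {plateau_mode!r}")
    if y0_mode not in ("fixed_100", "free"):
        raise ValueError(f"unknown y0 mode {y0_mode!r}")
    return 1 + (plateau_mode == "free") + (y0_mode == "free")


def _profile_fit(
    t: np.ndarray, y: np.ndarray, K: float, plateau_mode: str, y0_mode: str
) -> tuple[float, float, float]:
    """Best (rss, y0, plateau) for fixed K: linear parameters in closed form."""
    e = np.exp(-K * t)
    if plateau_mode == "fixed_zero" and y0_mode == "fixed_100":
        r = y - 100.0 * e
        return float(r @ r), 100.0, 0.0
    if plateau_mode == "fixed_zero":  # y = y0 * e
        denom = float(e @ e)
        y0 = float(e @ y) / denom
        r = y - y0 * e
        return float(r @ r), y0, 0.0
    if y0_mode == "fixed_100":  # y - 100 e = plateau * (1 - e)
        u = 1.0 - e
        denom = float(u @ u)
        if denom == 0.0:  # K == 0: curve is the constant 100
            r = y - 100.0
            return float(r @ r), 100.0, 100.0
        plateau = float(u @ (y - 100.0 * e)) / denom
        r = y - (plateau + (100.0 - plateau) * e)
        return float(r @ r), 100.0, plateau
    # both free: y = plateau + (y0 - plateau) e  ==  A + B e
    X = np.column_stack([np.ones_like(e), e])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    A, B = float(coef[0]), float(coef[1])
    r = y - (A + B * e)
    return float(r @ r), A + B, A


def _minimize_rss(
    curves: list[tuple[np.ndarray, np.ndarray]], plateau_mode: str, y0_mode: str
) -> tuple[float, float]:
    """Minimize the pooled rss over a single K shared by all ``curves``."""

    def rss(K: float) -> float:
        return sum(
            _profile_fit(t, y, K, plateau_mode, y0_mode)[0] for t, y in curves
        )

    grid_rss = np.array([rss(K) for K in _K_GRID])
    i = int(np.argmin(grid_rss))
    lo = _K_GRID[max(0, i - 1)]
    hi = _K_GRID[min(len(_K_GRID) - 1, i + 1)]
    if hi > lo:
        res = minimize_scalar(
            rss, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if res.fun <= grid_rss[i]:
            return float(res.x), float(res.fun)
    return float(_K_GRID[i]), float(grid_rss[i])


def fit_one_phase_decay(
    curve: DecayCurve,
    plateau_mode: str = "fixed_zero",
    y0_mode: str = "fixed_100",
) -> DecayFit:
    """Least-squares one-phase decay fit with K constrained to be >= 0.

    A perfectly flat curve yields K = 0 with an infinite half-life (flagged
    by the value, not an error).
    """
    n_params = _n_free_params(plateau_mode, y0_mode)
    t, y = curve.times, curve.values
    if len(t) < n_params + 1:
        raise ValueError(
            f"need at least {n_params + 1} points to fit {n_params} parameters"
        )
    K, rss = _minimize_rss([(t, y)], plateau_mode, y0_mode)
    _, y0, plateau = _profile_fit(t, y, K, plateau_mode, y0_mode)
    half_life = math.inf if K == 0.0 else LN2 / K
    return DecayFit(
        K=K,
        y0=y0,
        plateau=plateau,
        half_life=half_life,
        rss=rss,
        n_points=len(t),
        n_params=n_params,
    )


def compare_decay_constants(
    curve_a: DecayCurve,
    curve_b: DecayCurve,
    plateau_mode: str = "fixed_zero",
    y0_mode: str = "fixed_100",
) -> FTestResult:
    """Extra sum-of-squares F test: do two conditions share a decay constant?

    The null model fits both curves with one shared K (other parameters per
    the modes, separately per curve); the alternative fits a separate K per
    curve.  F = ((rss0 - rss1)/df_num) / (rss1/df_den) with df_num = 1 and
    df_den = n_total - p_alt, referred to the F distribution.
    """
    p_per_curve = _n_free_params(plateau_mode, y0_mode)
    pairs = [(curve_a.times, curve_a.values), (curve_b.times, curve_b.values)]
    n_total = len(curve_a.times) + len(curve_b.times)
    params_alt = 2 * p_per_curve
    df_den = n_total - params_alt
    if df_den <= 0:
        raise ValueError("not enough points for the separate-K model")
    K_shared, rss_shared = _minimize_rss(pairs, plateau_mode, y0_mode)
    rss_separate = 0.0
    for t, y in pairs:
        _, rss_i = _minimize_rss([(t, y)], plateau_mode, y0_mode)
        # the shared optimum is feasible for each curve; never exceed it
        rss_separate += min(rss_i, _profile_fit(t, y, K_shared, plateau_mode, y0_mode)[0])
    df_num = params_alt - (2 * (p_per_curve - 1) + 1)  # always 1
    if rss_separate == 0.0:
        F = 0.0 if rss_shared <= 0.0 else math.inf
    else:
        F = max(0.0, (rss_shared - rss_separate) / df_num / (rss_separate / df_den))
    p = float(f_dist.sf(F, df_num, df_den)) if math.isfinite(F) else 0.0
    return FTestResult(
        F=F,
        df_num=df_num,
        df_den=df_den,
        p=p,
        rss_shared=rss_shared,
        rss_separate=rss_separate,
    )


def normalize_luciferase(
    firefly: np.ndarray,
    renilla: np.ndarray,
    conditions: list[str],
    reference_condition: str,
) -> np.ndarray:
    """Per-well firefly/Renilla ratios scaled so the reference mean is 1.

    The returned values are fold activations relative to the reference
    condition (e.g. empty vector or untreated wells).
    """
    firefly = np.asarray(firefly, dtype=float)
    renilla = np.asarray(renilla, dtype=float)
    if firefly.shape != renilla.shape or len(conditions) != len(firefly):
        raise ValueError("firefly, renilla, and conditions must align")
    if np.any(renilla <= 0):
        raise ValueError("Renilla readings must be positive")
    ratio = firefly / renilla
    mask = np.array([c == reference_condition for c in conditions])
    if not mask.any():
        raise ValueError(f"reference condition {reference_condition!r} not present")
    return ratio / float(ratio[mask].mean())


def compute_nmfi(mfi_sample: float, mfi_control: float) -> float:
    """nMFI = MFI(sample) / MFI(control); both must be positive."""
    if mfi_sample <= 0 or mfi_control <= 0:
        raise ValueError("MFI values must be positive")
    return mfi_sample / mfi_control


def percent_of_reference(nmfi_sample: float, nmfi_reference: float) -> float:
    """Express a sample's nMFI as a percentage of a reference (e.g. wild type)."""
    if nmfi_reference <= 0:
        raise ValueError("reference nMFI must be positive")
    return 100.0 * nmfi_sample / nmfi_reference
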
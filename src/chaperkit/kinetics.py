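"""Two-state binding kinetics from biolayer-interferometry sensorgrams.

A sensorgram records the optical wavelength shift of a client-loaded
biosensor while a chaperone at concentration ``C`` associates
(``y = a (1 - exp(-k_obs t)) + y0 t``) or dissociates
(``y = a exp(-k_off t) + y0 t``); ``y0`` is a linear baseline-drift slope.
For a 1:1 interaction the observed association rate is linear in
concentration, ``k_obs = k_on C + k_off``, so an ordinary least-squares
line through ``(C, k_obs)`` yields ``k_on`` (slope), and the equilibrium
dissociation constant is ``K_d = k_off / k_on``.

The module also quantifies relative chaperone activity from
light-scattering aggregation traces: the slope of the late linear segment
of an aggregation curve is converted into an equivalent wild-type
chaperone:client ratio through a one-phase exponential-decay standard
curve, ``S(r) = S_inf + A exp(-r / tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "Sensorgram",
    "PhaseFit",
    "KineticParams",
    "fit_association",
    "fit_dissociation",
    "regress_kobs",
    "assemble_kinetics",
    "aggregation_slope",
    "ActivityStandardCurve",
    "relative_activity",
    "KineticsFit",
]

ASSOCIATION = "assoc"
DISSOCIATION = "dissoc"


@dataclass
class Sensorgram:
    """One phase of a time/signal binding trace.

    Parameters
    ----------
    curve_id : str
        Identifier shared by the association/dissociation pair.
    phase : {"assoc", "dissoc"}
    conc : float
        Chaperone concentration in molar. Must be positive for
        association phases (it enters the ``k_obs`` regression).
    t, y : ndarray
        Time (s, strictly increasing, >= 10 points) and signal.
    """

    curve_id: str
    phase: str
    conc: float
    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.phase not in (ASSOCIATION, DISSOCIATION):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) < 10:
            raise ValueError("need at least 10 points per phase")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase == ASSOCIATION and not self.conc > 0:
            raise ValueError("association phase requires conc > 0")


@dataclass
class PhaseFit:
    """Least-squares estimate for a single sensorgram phase."""

    a: float
    rate: float  # k_obs (association) or k_off (dissociation), 1/s
    y0: float  # baseline drift slope, signal/s
    rss: float
    se: np.ndarray  # standard errors of (a, rate, y0)
    converged: bool = True
    flag: str | None = None  # "no_binding", "non_convergence", ...

    @property
    def se_rate(self) -> float:
        return float(self.se[1])


def _assoc_model(t: np.ndarray, a: float, k: float, y0: float) -> np.ndarray:
    return a * (1.0 - np.exp(-k * t)) + y0 * t


def _dissoc_model(t: np.ndarray, a: float, k: float, y0: float) -> np.ndarray:
    return a * np.exp(-k * t) + y0 * t


def estimate_noise(y: np.ndarray) -> float:
    """Point-to-point noise estimate, sd of first differences / sqrt(2)."""
    d = np.diff(np.asarray(y, dtype=float))
    return float(np.std(d) / np.sqrt(2.0)) if len(d) else 0.0


def _fit_phase(curve: Sensorgram, model, p0: np.ndarray, n_starts: int,
               rng_seed: int = 0) -> PhaseFit:
    t, y = curve.t, curve.y
    bounds = ([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    best = None
    rng = np.random.default_rng(rng_seed)
    starts = [p0]
    for _ in range(n_starts - 1):
        jit = p0 * np.array([
            1 + 0.2 * rng.standard_normal(),
            np.exp(0.5 * rng.standard_normal()),
            1 + 0.2 * rng.standard_normal(),
        ])
        jit[1] = max(jit[1], 1e-10)
        starts.append(jit)
    for start in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=start, bounds=bounds, maxfev=2000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        if rss <= max(len(t) * estimate_noise(y) ** 2 * 4, 1e-20):
            break  # good enough; skip remaining starts
    if best is None:
        nan3 = np.full(3, np.nan)
        return PhaseFit(np.nan, np.nan, np.nan, np.inf, nan3,
                        converged=False, flag="non_convergence")
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return PhaseFit(float(popt[0]), float(popt[1]), float(popt[2]), rss, se)


def fit_association(curve: Sensorgram, n_starts: int = 5) -> PhaseFit:
    """Fit ``y = a (1 - exp(-k_obs t)) + y0 t`` to an association phase.

    A flat trace (signal range below 5x the point-to-point noise
    estimate) is returned with ``flag="no_binding"`` instead of a rate.
    """
    if curve.phase != ASSOCIATION:
        raise ValueError("fit_association requires an association phase")
    t, y = curve.t, curve.y
    noise = estimate_noise(y)
    if np.ptp(y) < 5 * noise or np.ptp(y) == 0:
        return PhaseFit(0.0, np.nan, 0.0, float(np.sum((y - y.mean()) ** 2)),
                        np.full(3, np.nan), converged=False, flag="no_binding")
    # init: plateau from the tail, k_obs from time-to-63% of the plateau
    a0 = y[-1]
    reached = np.abs(y) >= 0.632 * abs(a0)
    idx = int(np.argmax(reached)) if reached.any() else len(t) // 2
    k0 = 1.0 / max(t[max(idx, 1)], t[1] if t[1] > 0 else 1e-6)
    p0 = np.array([a0 if a0 != 0 else np.ptp(y), k0, 0.0])
    return _fit_phase(curve, _assoc_model, p0, n_starts)


def fit_dissociation(curve: Sensorgram, n_starts: int = 5) -> PhaseFit:
    """Fit ``y = a exp(-k_off t) + y0 t`` to a dissociation phase."""
    if curve.phase != DISSOCIATION:
        raise ValueError("fit_dissociation requires a dissociation phase")
    t, y = curve.t, curve.y
    noise = estimate_noise(y)
    if np.ptp(y) < 5 * noise or np.ptp(y) == 0:
        return PhaseFit(0.0, np.nan, 0.0, float(np.sum((y - y.mean()) ** 2)),
                        np.full(3, np.nan), converged=False, flag="no_binding")
    a0 = y[0]
    # log-linearised decay over the first half for the rate seed
    mid = max(len(t) // 2, 2)
    yy = y[:mid] - y[:mid].min() + 1e-12
    slope, _, _, _, _ = stats.linregress(t[:mid], np.log(np.abs(yy) + 1e-12))
    k0 = abs(slope) if slope < 0 else 1.0 / max(t[-1] / 3, t[1])
    p0 = np.array([a0 if a0 != 0 else np.ptp(y), max(k0, 1e-6), 0.0])
    return _fit_phase(curve, _dissoc_model, p0, n_starts)


def regress_kobs(fits: Sequence[tuple[float, float]]):
    """OLS line through (concentration, k_obs): slope=k_on, intercept=k_off.

    Returns ``(k_on, k_off_intercept, r_squared, se_slope, flag)``.
    Requires >= 3 distinct concentrations; a negative slope is flagged.
    """
    fits = [(float(c), float(k)) for c, k in fits]
    concs = np.array([c for c, _ in fits])
    kobs = np.array([k for _, k in fits])
    if len(np.unique(concs)) < 3:
        raise ValueError("need k_obs at >= 3 distinct concentrations")
    res = stats.linregress(concs, kobs)
    flag = "nonpositive_slope" if res.slope <= 0 else None
    return (float(res.slope), float(res.intercept),
            float(res.rvalue ** 2), float(res.stderr), flag)


@dataclass
class KineticParams:
    """Assembled rate constants; ``K_d = k_off / k_on`` by construction."""

    k_on: float  # 1/(M s)
    k_off: float  # 1/s
    K_d: float  # M
    se_kon: float
    se_koff: float
    se_kd: float
    n_curves: int
    r_squared: float = np.nan
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")


def pool_koff(rates: Sequence[float], ses: Sequence[float]):
    """Inverse-variance weighted mean of per-curve k_off estimates.

    Falls back to the unweighted mean when standard errors are
    unavailable or degenerate (e.g. noiseless fits with ~zero se).
    """
    rates = np.asarray(rates, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(rates)
    rates, ses = rates[ok], ses[ok]
    if len(rates) == 0:
        raise ValueError("no finite k_off estimates to pool")
    usable = np.isfinite(ses) & (ses > 1e-12 * np.abs(rates))
    if usable.all() and len(rates) > 1:
        w = 1.0 / ses**2
        mean = float(np.sum(w * rates) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
    else:
        mean = float(np.mean(rates))
        se = float(np.std(rates, ddof=1) / np.sqrt(len(rates))) \
            if len(rates) > 1 else float(ses[0]) if np.isfinite(ses[0]) else 0.0
    return mean, se


def assemble_kinetics(assoc_fits: Sequence[tuple[float, PhaseFit]],
                      dissoc_fits: Sequence[PhaseFit]) -> KineticParams:
    """Combine phase fits into (k_on, k_off, K_d) with delta-method errors.

    ``assoc_fits`` is a sequence of ``(concentration_M, PhaseFit)``;
    ``dissoc_fits`` a sequence of dissociation-phase fits whose rates
    are pooled by inverse-variance weighting.
    """
    pts = [(c, f.rate) for c, f in assoc_fits
           if f.converged and np.isfinite(f.rate)]
    if len(pts) < 3:
        raise ValueError("need >= 3 converged association fits")
    k_on, _, r2, se_kon, flag = regress_kobs(pts)
    if flag:
        raise ValueError("k_obs does not increase with concentration")
    drates = [f.rate for f in dissoc_fits if f.converged]
    dses = [f.se_rate for f in dissoc_fits if f.converged]
    k_off, se_koff = pool_koff(drates, dses)
    kd = k_off / k_on
    se_kd = kd * np.sqrt((se_koff / k_off) ** 2 + (se_kon / k_on) ** 2) \
        if k_off > 0 and k_on > 0 else np.nan
    return KineticParams(k_on=k_on, k_off=k_off, K_d=kd, se_kon=se_kon,
                         se_koff=se_koff, se_kd=float(se_kd),
                         n_curves=len(pts) + len(drates), r_squared=r2)


class KineticsFit(BaseEstimator):
    """Estimator over a full multi-concentration sensorgram set.

    ``fit`` takes a list of :class:`Sensorgram` (both phases, any order),
    fits each phase, regresses ``k_obs`` on concentration and pools the
    dissociation rates.

    Attributes
    ----------
    k_on_, k_off_, kd_ : float
        Assembled rate constants (1/(M s), 1/s, M).
    params_ : KineticParams
    assoc_fits_, dissoc_fits_ : list
    """

    def __init__(self, n_starts: int = 5):
        self.n_starts = n_starts

    def fit(self, sensorgrams: Sequence[Sensorgram], y=None):
        assoc = [s for s in sensorgrams if s.phase == ASSOCIATION]
        dissoc = [s for s in sensorgrams if s.phase == DISSOCIATION]
        self.assoc_fits_ = [(s.conc, fit_association(s, self.n_starts))
                            for s in assoc]
        self.dissoc_fits_ = [fit_dissociation(s, self.n_starts)
                             for s in dissoc]
        self.params_ = assemble_kinetics(self.assoc_fits_, self.dissoc_fits_)
        self.k_on_ = self.params_.k_on
        self.k_off_ = self.params_.k_off
        self.kd_ = self.params_.K_d
        return self


def aggregation_slope(time_min: np.ndarray, signal: np.ndarray,
                      window: tuple[float, float] = (180.0, 240.0)) -> float:
    """Least-squares slope of an aggregation trace inside a time window.

    Default window is the late linear segment, 180-240 min.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    lo, hi = window
    m = (t >= lo) & (t <= hi)
    if m.sum() < 2:
        raise ValueError("fewer than 2 points inside the slope window")
    res = stats.linregress(t[m], y[m])
    return float(res.slope)


class ActivityStandardCurve(BaseEstimator):
    """One-phase exponential-decay standard curve for chaperone activity.

    Fits ``S(r) = S_inf + A exp(-r / tau)`` to aggregation slopes ``S``
    measured at wild-type chaperone:client molar ratios ``r`` (the
    calibration spans ratios 0.0375-2 by default in the synthetic data).
    Inverting the curve converts a variant's slope into the equivalent
    wild-type ratio; relative activity is that ratio divided by the
    ratio actually assayed.
    """

    def __init__(self, require_monotone: bool = True):
        self.require_monotone = require_monotone

    def fit(self, ratios: np.ndarray, slopes: np.ndarray):
        r = np.asarray(ratios, dtype=float)
        s = np.asarray(slopes, dtype=float)
        if len(r) < 3:
            raise ValueError("need >= 3 calibration points")
        order = np.argsort(r)
        r, s = r[order], s[order]
        amp0 = s[0] - s[-1]
        p0 = [s[-1], amp0 if amp0 != 0 else 1.0, max(np.median(r), 1e-3)]
        popt, _ = optimize.curve_fit(
            lambda rr, plateau, amp, tau: plateau + amp * np.exp(-rr / tau),
            r, s, p0=p0, maxfev=5000)
        self.plateau_, self.amplitude_, self.tau_ = map(float, popt)
        self.ratio_range_ = (float(r[0]), float(r[-1]))
        grid = np.linspace(r[0], r[-1], 256)
        vals = self.predict(grid)
        d = np.diff(vals)
        if self.require_monotone and not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("fitted standard curve is not monotone "
                             "over the calibrated range")
        return self

    def predict(self, ratios: np.ndarray) -> np.ndarray:
        """Aggregation slope expected at the given wild-type ratios."""
        r = np.asarray(ratios, dtype=float)
        return self.plateau_ + self.amplitude_ * np.exp(-r / self.tau_)

    def invert(self, slope: float) -> tuple[float, bool]:
        """Equivalent wild-type ratio for a slope; clamps out-of-range.

        Returns ``(ratio, clamped)``.
        """
        lo, hi = self.ratio_range_
        s_lo, s_hi = self.predict(np.array([lo, hi]))
        smin, smax = min(s_lo, s_hi), max(s_lo, s_hi)
        clamped = False
        s = float(slope)
        if s < smin:
            s, clamped = smin, True
        elif s > smax:
            s, clamped = smax, True
        # analytic inverse of plateau + A exp(-r/tau)
        arg = (s - self.plateau_) / self.amplitude_
        arg = max(arg, 1e-300)
        ratio = -self.tau_ * np.log(arg)
        ratio = float(np.clip(ratio, lo, hi))
        return ratio, clamped


def relative_activity(variant_slope: float, standard: ActivityStandardCurve,
                      assay_ratio: float) -> tuple[float, bool]:
    """Variant activity as a fraction of wild type.

    The variant's aggregation slope is mapped through the standard curve
    to the wild-type ratio that would produce the same slope; relative
    activity is ``equivalent_ratio / assay_ratio``. Returns
    ``(activity, clamped)``.
    """
    if assay_ratio <= 0:
        raise ValueError("assay_ratio must be positive")
    eq_ratio, clamped = standard.invert(variant_slope)
    return eq_ratio / assay_ratio, clamped
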
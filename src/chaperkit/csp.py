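"""Chemical-shift perturbation mapping and one-site titration fitting.

Amide CSPs combine the proton and nitrogen shift changes between two
2D correlation spectra as ``CSP = sqrt(dH^2 + (0.2 dN)^2)`` (the 0.2
weight compensates the wider 15N dispersion). Secondary shifts subtract
tabulated random-coil Ca/Cb values and report residual secondary
structure. A ligand titration observed in fast exchange follows the
one-site binding isotherm

    d_obs = d_max * ((Kd + P0 + L0) - sqrt((Kd + P0 + L0)^2 - 4 P0 L0))
            / (2 P0)

with labeled-protein concentration ``P0`` and total ligand ``L0``;
nonlinear least squares per residue recovers ``(Kd, d_max)`` and the
per-residue dissociation constants are pooled by median with a
bootstrap confidence interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "PeakList",
    "CSPProfile",
    "TitrationSeries",
    "OneSiteFit",
    "match_peaks",
    "compute_csp",
    "secondary_shifts",
    "one_site_delta",
    "fit_one_site",
    "titration_from_peaklists",
    "OneSiteBindingFit",
    "load_random_coil_table",
]

NITROGEN_WEIGHT = 0.2


@dataclass
class PeakList:
    """Per-residue amide peak table from one 2D spectrum.

    ``data`` columns: residue (int, unique), aa (1-letter code),
    dH_ppm, dN_ppm, intensity, and optionally dCa_ppm, dCb_ppm,
    overlap (bool).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        required = {"residue", "aa", "dH_ppm", "dN_ppm", "intensity"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"peak list missing columns: {sorted(missing)}")
        if d["residue"].duplicated().any():
            dup = d.loc[d["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue indices: {dup}")
        for col in ("dH_ppm", "dN_ppm"):
            if not np.isfinite(d[col].to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in {col}")
        if "overlap" not in d.columns:
            d = d.assign(overlap=False)
        self.data = d.sort_values("residue").reset_index(drop=True)

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def match_peaks(reference: PeakList, query: PeakList,
                max_dist: float = 0.05) -> pd.DataFrame:
    """Pair peaks by residue index; flag ambiguous neighbours as overlapped.

    Residues present in both lists are paired. A reference peak with
    more than one query peak within ``max_dist`` in the weighted
    ``(dH, 0.2 dN)`` plane is ambiguous: it and all the query peaks
    involved are flagged ``overlapped``. Returns a table with columns
    residue, status in {ok, missing, overlapped}.
    """
    ref, qry = reference.data, query.data
    all_res = np.union1d(ref["residue"], qry["residue"])
    status = pd.Series("ok", index=all_res)
    in_ref = np.isin(all_res, ref["residue"])
    in_qry = np.isin(all_res, qry["residue"])
    status[~(in_ref & in_qry)] = "missing"
    # ambiguity in shift space
    q_xy = np.column_stack([qry["dH_ppm"],
                            NITROGEN_WEIGHT * qry["dN_ppm"]])
    r_xy = np.column_stack([ref["dH_ppm"],
                            NITROGEN_WEIGHT * ref["dN_ppm"]])
    d2 = ((r_xy[:, None, :] - q_xy[None, :, :]) ** 2).sum(axis=2)
    within = d2 <= max_dist**2
    for i, res in enumerate(ref["residue"].to_numpy()):
        hits = within[i]
        if hits.sum() > 1:
            status[res] = "overlapped"
            status[qry["residue"].to_numpy()[hits]] = "overlapped"
    # pre-flagged overlaps propagate
    for pl in (ref, qry):
        if "overlap" in pl.columns:
            flagged = pl.loc[pl["overlap"].astype(bool), "residue"]
            status[np.intersect1d(flagged, all_res)] = "overlapped"
    out = pd.DataFrame({"residue": all_res,
                        "status": status.loc[all_res].to_numpy()})
    return out


@dataclass
class CSPProfile:
    """Per-residue chemical-shift perturbations."""

    data: pd.DataFrame  # residue, csp, status

    def values(self, ok_only: bool = True) -> pd.Series:
        d = self.data
        if ok_only:
            d = d[d["status"] == "ok"]
        return d.set_index("residue")["csp"]


def compute_csp(a: PeakList, b: PeakList,
                max_dist: float = 0.05) -> CSPProfile:
    """CSP = sqrt(dH^2 + (0.2 dN)^2) between two matched peak lists."""
    pairing = match_peaks(a, b, max_dist=max_dist)
    da = a.data.set_index("residue")
    db = b.data.set_index("residue")
    rows = []
    for res, status in zip(pairing["residue"], pairing["status"]):
        if status != "ok":
            rows.append((res, np.nan, status))
            continue
        dh = da.loc[res, "dH_ppm"] - db.loc[res, "dH_ppm"]
        dn = da.loc[res, "dN_ppm"] - db.loc[res, "dN_ppm"]
        rows.append((res, float(np.hypot(dh, NITROGEN_WEIGHT * dn)), "ok"))
    return CSPProfile(pd.DataFrame(rows, columns=["residue", "csp", "status"]))


def load_random_coil_table() -> pd.DataFrame:
    """Packaged random-coil Ca/Cb reference shifts (ppm), per residue type."""
    ref = importlib.resources.files("chaperkit.data") / "random_coil_shifts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def secondary_shifts(peaks: PeakList,
                     coil_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Secondary shifts dCa - coil(aa), dCb - coil(aa) per residue.

    Residues whose type is missing from the table (or glycine Cb) are
    skipped. Returns columns residue, aa, d_ca, d_cb.
    """
    if coil_table is None:
        coil_table = load_random_coil_table()
    coil = coil_table.set_index("aa")
    rows = []
    d = peaks.data
    if "dCa_ppm" not in d.columns:
        raise ValueError("peak list carries no Ca/Cb shifts")
    for _, r in d.iterrows():
        aa = r["aa"]
        if aa not in coil.index:
            continue
        dca = r["dCa_ppm"] - coil.loc[aa, "ca_ppm"]
        cb_ref = coil.loc[aa, "cb_ppm"]
        dcb = (r.get("dCb_ppm", np.nan) - cb_ref) \
            if np.isfinite(cb_ref) else np.nan
        rows.append((r["residue"], aa, float(dca), float(dcb)))
    return pd.DataFrame(rows, columns=["residue", "aa", "d_ca", "d_cb"])


# ---------------------------------------------------------------------------
# one-site titration

def one_site_delta(kd, dmax, p0, l0):
    """Closed-form fast-exchange one-site isotherm, any concentration unit.

    Evaluates ``dmax * PL / P0`` where ``PL`` solves the binding
    quadratic; written as ``PL = 2 P0 L0 / (b + sqrt(b^2 - 4 P0 L0))``
    with ``b = Kd + P0 + L0``, which avoids the catastrophic
    cancellation of the textbook form when ``4 P0 L0 << b^2``.
    """
    kd = np.asarray(kd, dtype=float)
    l0 = np.asarray(l0, dtype=float)
    b = kd + p0 + l0
    disc = np.sqrt(np.maximum(b * b - 4.0 * p0 * l0, 0.0))
    pl = np.where(b + disc > 0, 2.0 * p0 * l0 / (b + disc), 0.0)
    return dmax * pl / p0


def solve_equilibrium_delta(kd: float, dmax: float, p0: float,
                            l0: float) -> float:
    """Oracle: d_obs from numerically solving mass action + mass balance.

    Root of ``(P0 - x)(L0 - x) = Kd x`` on ``[0, min(P0, L0)]`` by
    bisection; independent of the closed form above.
    """
    if l0 == 0:
        return 0.0
    f = lambda x: (p0 - x) * (l0 - x) - kd * x
    hi = min(p0, l0)
    x = optimize.brentq(f, 0.0, hi, xtol=1e-18, rtol=8.9e-16)
    return dmax * x / p0


@dataclass
class TitrationSeries:
    """Titration of a labeled protein with a ligand, fast exchange.

    ``p0``: labeled protein concentration (mM), held constant.
    ``l0``: total ligand concentrations (mM), strictly increasing,
    non-negative. ``deltas``: DataFrame indexed by residue with one
    column per titration point (observed CSPs in ppm).
    """

    p0: float
    l0: np.ndarray
    deltas: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.l0 = np.asarray(self.l0, dtype=float)
        if np.any(self.l0 < 0) or np.any(np.diff(self.l0) <= 0):
            raise ValueError("l0 must be non-negative, strictly increasing")
        if self.deltas.shape[1] != len(self.l0):
            raise ValueError("deltas must have one column per l0 point")


def titration_from_peaklists(peaklists, p0: float, l0,
                             max_dist: float = 0.05) -> TitrationSeries:
    """Assemble a titration series from one peak list per point.

    The first list is the apo reference (its ligand concentration must
    be 0); each subsequent point contributes the per-residue CSP
    against the reference. Residues overlapped or missing at any point
    are dropped.
    """
    l0 = np.asarray(l0, dtype=float)
    if len(peaklists) != len(l0):
        raise ValueError("need one peak list per ligand concentration")
    if l0[0] != 0:
        raise ValueError("first point must be the apo reference (L0 = 0)")
    ref = peaklists[0]
    cols = {}
    for i, pl in enumerate(peaklists):
        prof = compute_csp(pl, ref, max_dist=max_dist)
        cols[i] = prof.values(ok_only=True)
    table = pd.DataFrame(cols).dropna()
    table.index.name = "residue"
    return TitrationSeries(p0=p0, l0=l0[1:], deltas=table[list(
        range(1, len(l0)))])


@dataclass
class OneSiteFit:
    """Per-residue one-site fits plus the pooled dissociation constant."""

    per_residue: pd.DataFrame  # residue, kd, dmax, se_kd, rss, status
    pooled_kd: float
    pooled_ci: tuple[float, float]
    n_accepted: int


def _fit_residue(l0: np.ndarray, dobs: np.ndarray, p0: float,
                 kd_bounds: tuple[float, float]):
    dmax0 = max(dobs.max(), 1e-6)
    best = None
    for kd0 in (p0 + l0.max(), l0.max() / 2, 10 * l0.max()):
        kd0 = float(np.clip(kd0, *kd_bounds))
        try:
            popt, pcov = optimize.curve_fit(
                lambda ll, kd, dmax: one_site_delta(kd, dmax, p0, ll),
                l0, dobs, p0=[kd0, 2 * dmax0],
                bounds=([kd_bounds[0], 0.0], [kd_bounds[1], np.inf]),
                maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum(
            (one_site_delta(popt[0], popt[1], p0, l0) - dobs) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    return best


def fit_one_site(series: TitrationSeries,
                 min_delta: float = 0.015,
                 kd_bounds: tuple[float, float] = (1e-4, 1e3),
                 n_boot: int = 500,
                 seed: int = 0) -> OneSiteFit:
    """Per-residue nonlinear least squares for (Kd, d_max), median pooling.

    Residues whose largest observed CSP is below ``min_delta`` (default
    three times a 0.005 ppm noise floor) are excluded from pooling, as
    are residues that fail to converge. Fits whose Kd lands on the box
    bounds are kept but flagged ``poorly_determined``. The pooled Kd is
    the median over accepted residues with a bootstrap percentile CI.
    """
    if len(series.l0) < 4:
        raise ValueError("need >= 4 titration points per residue")
    rng = np.random.default_rng(seed)
    rows = []
    for res, dobs in series.deltas.iterrows():
        dobs = dobs.to_numpy(dtype=float)
        if np.nanmax(np.abs(dobs)) < min_delta:
            rows.append((res, np.nan, np.nan, np.nan, np.nan, "below_floor"))
            continue
        best = _fit_residue(series.l0, dobs, series.p0, kd_bounds)
        if best is None:
            rows.append((res, np.nan, np.nan, np.nan, np.nan,
                         "non_convergence"))
            continue
        (kd, dmax), pcov, rss = best
        se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
        status = "ok"
        if kd <= kd_bounds[0] * 1.01 or kd >= kd_bounds[1] * 0.99:
            status = "poorly_determined"
        rows.append((res, float(kd), float(dmax), se_kd, rss, status))
    per = pd.DataFrame(
        rows, columns=["residue", "kd", "dmax", "se_kd", "rss", "status"])
    accepted = per.loc[per["status"].isin(["ok", "poorly_determined"]), "kd"]
    accepted = accepted.dropna().to_numpy()
    if len(accepted) == 0:
        return OneSiteFit(per, np.nan, (np.nan, np.nan), 0)
    pooled = float(np.median(accepted))
    if len(accepted) > 1 and n_boot > 0:
        boots = np.median(
            rng.choice(accepted, size=(n_boot, len(accepted))), axis=1)
        ci = (float(np.percentile(boots, 2.5)),
              float(np.percentile(boots, 97.5)))
    else:
        ci = (pooled, pooled)
    return OneSiteFit(per, pooled, ci, int(len(accepted)))


class OneSiteBindingFit(BaseEstimator):
    """Estimator wrapper around :func:`fit_one_site`.

    Attributes after ``fit``: ``kd_`` (pooled, mM), ``ci_``,
    ``per_residue_``, ``result_``.
    """

    def __init__(self, min_delta: float = 0.015,
                 kd_bounds: tuple[float, float] = (1e-4, 1e3),
                 n_boot: int = 500, seed: int = 0):
        self.min_delta = min_delta
        self.kd_bounds = kd_bounds
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, series: TitrationSeries, y=None):
        res = fit_one_site(series, min_delta=self.min_delta,
                           kd_bounds=self.kd_bounds, n_boot=self.n_boot,
                           seed=self.seed)
        self.result_ = res
        self.kd_ = res.pooled_kd
        self.ci_ = res.pooled_ci
        self.per_residue_ = res.per_residue
        return self

    def predict(self, l0: np.ndarray, dmax: float = 1.0,
                p0: float | None = None) -> np.ndarray:
        """Isotherm evaluated at the pooled Kd."""
        if p0 is None:
            raise ValueError("p0 required")
        return one_site_delta(self.kd_, dmax, p0, np.asarray(l0, float))
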
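"""Synthetic data generators with known ground truth.

Every input the analysis stages consume can be generated here: BLI-style
association/dissociation sensorgrams with linear baseline drift,
seven-point one-site titration series, distance-derived PRE intensity
ratio profiles, and a cradle-shaped two-chain bead scaffold with
charged concave/convex faces and disordered N-terminal tails.

The scaffold emulates a cradle-shaped chaperone dimer whose structured
core spans residues 29-124 per chain (so annotation files using that
numbering read identically for real coordinates): beads sit on a
half-cylindrical shell (radius 11 A) opening upward, positively
charged residues line the concave face, a smaller set of positive
residues sits on the displaced convex face, and four rim residues
(110/112, 120/121) define the upper cavity plane. The 28-residue tails
carry the acidic/basic pattern of the disordered N terminus (D2, D10,
K12, K18, K20 and the critical D26).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .csp import TitrationSeries, one_site_delta
from .kinetics import ASSOCIATION, DISSOCIATION, Sensorgram
from .pre import PREProfile
from .tail import (TAIL_CHARGES_DEFAULT, Scaffold, TailEnsemble,
                   build_cavity_plane, sample_coil, score_ensemble,
                   signed_distance)

__all__ = [
    "GroundTruth",
    "SyntheticSystemConfig",
    "DEFAULT_CONCENTRATIONS_M",
    "DEFAULT_TITRATION_RATIOS",
    "TAIL_SEQUENCE_DEFAULT",
    "simulate_sensorgram",
    "simulate_sensorgram_series",
    "simulate_titration",
    "simulate_pre_profile",
    "build_synthetic_scaffold",
    "simulate_scaffold_and_tails",
    "simulate_standard_curve",
]

#: the five-point concentration series used throughout (molar)
DEFAULT_CONCENTRATIONS_M = (0.25e-6, 0.5e-6, 1.0e-6, 1.5e-6, 2.0e-6)
#: the seven ligand:protein molar ratios of the titration schedule
DEFAULT_TITRATION_RATIOS = (2.0, 6.0, 10.0, 14.0, 20.0, 30.0, 40.0)
#: synthetic 28-residue tail with the charge pattern of the N terminus
TAIL_SEQUENCE_DEFAULT = "SDSSSTSGSDSKGSSHHKGKSSSHQDMM"


@dataclass
class GroundTruth:
    """True parameter values recorded next to each synthetic dataset.

    Any subset of the fields may be populated; invariants are checked
    for whatever is present (positive rates and distances, and
    ``K_d = k_off / k_on`` to 1e-12 relative when all three are given).
    """

    kinetic_params: dict = field(default_factory=dict)
    titration_truth: dict = field(default_factory=dict)
    pre_truth: dict = field(default_factory=dict)
    tail_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in self.kinetic_params.items():
            for key in ("k_on", "k_off"):
                if key in p and not p[key] > 0:
                    raise ValueError(f"{name}: {key} must be positive")
            if {"k_on", "k_off", "K_d"} <= set(p):
                if abs(p["K_d"] - p["k_off"] / p["k_on"]) > 1e-12 * p["K_d"]:
                    raise ValueError(f"{name}: K_d != k_off/k_on")
        kd = self.titration_truth.get("kd")
        if kd is not None and not kd > 0:
            raise ValueError("titration K_d must be positive")
        for res, dist in self.pre_truth.get("mean_distance", {}).items():
            if not dist > 0:
                raise ValueError(f"residue {res}: distance must be positive")


# ---------------------------------------------------------------------------
# sensorgrams

def simulate_sensorgram(k_on: float, k_off: float, conc: float,
                        t_assoc: float, t_dissoc: float,
                        amplitude: float = 1.0,
                        noise_sd: float | None = None,
                        drift_slope: float = 0.0,
                        n_points: int = 60,
                        seed: int = 0,
                        curve_id: str = "curve"):
    """Forward-simulate one association/dissociation sensorgram pair.

    Association: ``y = a (1 - exp(-k_obs t)) + y0 t`` with
    ``k_obs = k_on * conc + k_off`` and plateau
    ``a = amplitude * conc / (conc + K_d)`` (fractional occupancy at
    equilibrium). Dissociation starts from the association end level
    and decays with ``k_off``, with its own drift term. Homoscedastic
    Gaussian noise is added pointwise; the default ``noise_sd`` is 1%
    of the association plateau.

    Returns ``(assoc, dissoc, truth)`` where ``truth`` is a
    :class:`GroundTruth` whose metadata records ``k_obs``.
    """
    if conc <= 0:
        raise ValueError("concentration must be positive")
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    if t_assoc <= 0 or t_dissoc <= 0:
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)
    kd = k_off / k_on
    k_obs = k_on * conc + k_off
    a = amplitude * conc / (conc + kd)
    if noise_sd is None:
        noise_sd = 0.01 * a
    t1 = np.linspace(0.0, t_assoc, n_points)
    y1 = a * (1.0 - np.exp(-k_obs * t1)) + drift_slope * t1
    a_diss = a * (1.0 - np.exp(-k_obs * t_assoc))
    t2 = np.linspace(0.0, t_dissoc, n_points)
    y2 = a_diss * np.exp(-k_off * t2) + drift_slope * t2
    if noise_sd > 0:
        y1 = y1 + rng.normal(0.0, noise_sd, size=y1.shape)
        y2 = y2 + rng.normal(0.0, noise_sd, size=y2.shape)
    assoc = Sensorgram(curve_id, ASSOCIATION, conc, t1, y1)
    dissoc = Sensorgram(curve_id, DISSOCIATION, conc, t2, y2)
    truth = GroundTruth(kinetic_params={curve_id: {
        "k_on": k_on, "k_off": k_off, "K_d": kd, "k_obs": k_obs,
        "a": a, "drift_slope": drift_slope, "conc": conc}})
    return assoc, dissoc, truth


def simulate_sensorgram_series(k_on: float, k_off: float,
                               concentrations=DEFAULT_CONCENTRATIONS_M,
                               t_assoc: float | None = None,
                               t_dissoc: float | None = None,
                               noise_frac: float = 0.01,
                               drift_slope: float = 0.0,
                               n_points: int = 60,
                               seed: int = 0):
    """The default multi-concentration experiment: one pair per level.

    Phase durations default to several characteristic times of the
    slowest process so every curve resolves its rate: ``t_assoc`` spans
    4 / k_obs at the lowest concentration, ``t_dissoc`` 4 / k_off.
    ``noise_frac`` scales the full-occupancy amplitude (1.0 signal
    unit). Returns ``(sensorgrams, truth)`` with all pairs flattened.
    """
    concentrations = tuple(float(c) for c in concentrations)
    k_obs_min = k_on * min(concentrations) + k_off
    if t_assoc is None:
        t_assoc = 4.0 / k_obs_min
    if t_dissoc is None:
        t_dissoc = 4.0 / k_off
    rng = np.random.default_rng(seed)
    curves = []
    truth = GroundTruth(kinetic_params={"series": {
        "k_on": k_on, "k_off": k_off, "K_d": k_off / k_on}})
    for i, conc in enumerate(concentrations):
        sub = int(rng.integers(0, 2**31 - 1))
        a, d, tr = simulate_sensorgram(
            k_on, k_off, conc, t_assoc, t_dissoc,
            noise_sd=noise_frac * 1.0 * conc / (conc + k_off / k_on),
            drift_slope=drift_slope, n_points=n_points, seed=sub,
            curve_id=f"c{i}")
        curves.extend([a, d])
        truth.kinetic_params[f"c{i}"] = tr.kinetic_params[f"c{i}"]
    return curves, truth


# ---------------------------------------------------------------------------
# titrations

def simulate_titration(kd: float, dmax, p0: float = 0.1,
                       ratios=DEFAULT_TITRATION_RATIOS,
                       noise_sd: float = 0.005,
                       seed: int = 0) -> TitrationSeries:
    """Forward-simulate a fast-exchange titration series.

    ``kd`` and ``p0`` in mM; ``dmax`` is a per-residue mapping (or a
    scalar applied to residues 1..10) of maximum CSPs in ppm; negative
    values are rejected. The default schedule is seven ligand:protein
    molar ratios 2, 6, 10, 14, 20, 30, 40 at ``p0 = 0.1`` mM.
    """
    if kd <= 0 or p0 <= 0:
        raise ValueError("kd and p0 must be positive")
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    if np.isscalar(dmax):
        dmax = {res: float(dmax) for res in range(1, 11)}
    if any(v < 0 for v in dmax.values()):
        raise ValueError("negative d_max rejected")
    l0 = p0 * ratios
    rng = np.random.default_rng(seed)
    rows = {}
    for res, dm in dmax.items():
        clean = one_site_delta(kd, dm, p0, l0)
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) \
            if noise_sd > 0 else clean
        rows[res] = noisy
    deltas = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=range(len(l0)))
    deltas.index.name = "residue"
    return TitrationSeries(p0=p0, l0=l0, deltas=deltas,
                           truth={"kd": kd, "dmax": dict(dmax), "p0": p0})


# ---------------------------------------------------------------------------
# PRE forward model

def _calibrate_gamma(r2_dia: float, t_evo: float,
                     ref_distance: float = 15.0,
                     ref_ratio: float = 2.0) -> float:
    """Global constant K with Gamma2 = K <r^-6>, set so that a mean
    label-amide distance of ``ref_distance`` gives ``ref_ratio``."""
    f = lambda g: np.log1p(g / r2_dia) + g * t_evo - np.log(ref_ratio)
    gamma_ref = optimize.brentq(f, 0.0, 1e4)
    return gamma_ref * ref_distance**6


def simulate_pre_profile(ensemble: TailEnsemble, scaffold: Scaffold,
                         r2_dia: float = 20.0,
                         total_evolution_time: float = 0.01,
                         noise_sd: float = 0.0,
                         ratio_cap: float = 10.0,
                         min_distance: float = 1.0,
                         seed: int = 0,
                         variant: str = "synthetic") -> PREProfile:
    """Distance-derived PRE intensity-ratio profile over the scaffold.

    For every structured residue the ensemble-averaged ``<r^-6>``
    between the surrogate label beads (all conformers, both chains) and
    the residue bead (both chains) gives ``Gamma2 = K <r^-6>``; the
    transfer function ``ratio = (1 + Gamma2/R2) exp(Gamma2 t)`` maps
    ``Gamma2 = 0`` to ratio 1 and grows monotonically as the mean
    distance shrinks. ``K`` is calibrated so a 15 A mean distance
    yields ratio 2. Ratios are capped at ``ratio_cap`` (the display
    ceiling); beads closer than ``min_distance`` are flagged vanished.
    Optional Gaussian noise perturbs the reported ratios.
    """
    if ensemble.label_positions is None or len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty with label positions")
    k_cal = _calibrate_gamma(r2_dia, total_evolution_time)
    labels = ensemble.label_positions.reshape(-1, 3)
    rng = np.random.default_rng(seed)
    rows = []
    truth_dist = {}
    for res in sorted({int(r) for r in scaffold.residues}):
        beads = scaffold.coords[scaffold.residues == res]
        d = np.linalg.norm(labels[:, None, :] - beads[None, :, :], axis=2)
        if np.any(d <= 0):
            rows.append((res, ratio_cap, "vanished"))
            continue
        mean_r6 = float(np.mean(d**-6.0))
        truth_dist[res] = float(mean_r6 ** (-1.0 / 6.0))
        if d.min() < min_distance:
            rows.append((res, ratio_cap, "vanished"))
            continue
        gamma = k_cal * mean_r6
        log_ratio = np.log1p(gamma / r2_dia) + gamma * total_evolution_time
        ratio = ratio_cap if log_ratio > np.log(ratio_cap) \
            else float(np.exp(log_ratio))
        if noise_sd > 0:
            ratio += rng.normal(0.0, noise_sd)
        ratio = float(np.clip(ratio, 1e-6, ratio_cap))
        status = "ok" if ratio < ratio_cap else "vanished"
        rows.append((res, ratio, status))
    data = pd.DataFrame(rows, columns=["residue", "ratio", "status"])
    data["i_dia"] = 1.0
    data["i_para"] = 1.0 / data["ratio"]
    prof = PREProfile(data[["residue", "i_dia", "i_para", "ratio", "status"]],
                      variant=variant, label_site="CI")
    prof.truth = GroundTruth(pre_truth={"mean_distance": truth_dist})
    return prof


# ---------------------------------------------------------------------------
# scaffold + tails

CONCAVE_CHARGED = (43, 50, 54, 55, 61, 62, 89, 96, 121, 122)
CONVEX_CHARGED = (33, 38, 47, 58, 75, 81, 102, 117)


def _default_charge_map() -> dict:
    charges = dict(TAIL_CHARGES_DEFAULT)
    charges.update({r: 1 for r in CONCAVE_CHARGED})
    charges.update({r: 1 for r in CONVEX_CHARGED})
    charges.update({110: -1, 112: 1, 120: -1, 121: 1})
    return charges


@dataclass
class SyntheticSystemConfig:
    """Layout and noise parameters of the synthetic cradle system."""

    n_residues_structured: int = 96  # per chain, residues 29..124
    tail_length: int = 28
    concave_residues: tuple = CONCAVE_CHARGED + (65,)
    convex_residues: tuple = CONVEX_CHARGED
    charge_map: dict = field(default_factory=_default_charge_map)
    noise_sd: float = 0.01
    drift_slope: float = 0.0
    seed: int = 0
    n_conformers: int = 1000
    keep_frac: float = 0.05
    radius: float = 11.0

    def __post_init__(self) -> None:
        if set(self.concave_residues) & set(self.convex_residues):
            raise ValueError("concave and convex sets must be disjoint")
        if self.tail_length < 1:
            raise ValueError("tail_length must be >= 1")


# designed bead placements (chain A; chain B mirrors x -> -x),
# (x, phi_degrees, radius_override or None). The tail anchor sits on
# the +y wall with a clear corridor down to the bottom-center residue
# 89 — the only concave charge inside the residue-26 bead's reach —
# while the remaining charged concave sites line the opposite wall.
_DESIGNED_SITES = {
    29: (-12.0, 55.0, None),   # tail anchor
    89: (-10.0, 30.0, None),   # bottom-center acidic-bead target
    54: (-15.0, -50.0, None), 55: (-18.0, -50.0, None),
    61: (-8.0, -50.0, None), 62: (-11.0, -50.0, None),
    43: (-25.0, -45.0, None), 50: (-24.0, -40.0, None),
    65: (-3.0, -45.0, None), 96: (-16.0, -35.0, None),
    122: (-12.0, -80.0, None),
    110: (-18.0, 80.0, None), 112: (-22.0, 80.0, None),
    120: (-6.0, -80.0, None), 121: (-10.0, -80.0, None),
}


def _shell_position(x: float, phi_deg: float, radius: float) -> np.ndarray:
    phi = np.deg2rad(phi_deg)
    return np.array([x, radius * np.sin(phi), -radius * np.cos(phi)])


def build_synthetic_scaffold(config: SyntheticSystemConfig | None = None
                             ) -> Scaffold:
    """Cradle-shaped two-chain bead scaffold (residues 29-124 per chain).

    Beads lie on a half-cylindrical shell opening toward +z; chain A
    occupies x < 0, chain B is the mirror image. Key residues (the
    charged concave/convex sites, the rim plane residues and the tail
    anchor) are placed at designed positions; the remaining beads fill
    the shell on a regular grid. Convex-annotated residues sit on an
    outer shell 4 A above the concave surface.
    """
    if config is None:
        config = SyntheticSystemConfig()
    R = config.radius
    n = config.n_residues_structured
    chains, residues, coords = [], [], []
    for chain, sign in (("A", 1.0), ("B", -1.0)):
        for i in range(n):
            res = 29 + i
            if res in _DESIGNED_SITES:
                x, phi, rad = _DESIGNED_SITES[res]
                rad = R if rad is None else rad
                if res in config.convex_residues:
                    rad = R + 4.0
                pos = _shell_position(sign * x, phi, rad)
            else:
                col, row = divmod(i, 12)
                phi = -80.0 + 160.0 * row / 11.0
                x = -(2.5 + 2.8 * col)
                rad = R + 4.0 if res in config.convex_residues else R
                pos = _shell_position(sign * x, phi, rad)
            chains.append(chain)
            residues.append(res)
            coords.append(pos)
    # the whole inner face is concave; only the displaced outer-shell
    # beads are convex (charged subsets are what enrichment counts use)
    surface = {r: "concave"
               for r in range(29, 29 + config.n_residues_structured)}
    surface.update({r: "convex" for r in config.convex_residues})
    structured_charges = {r: c for r, c in config.charge_map.items() if r >= 29}
    return Scaffold(chains=np.array(chains), residues=np.array(residues),
                    coords=np.array(coords), charges=structured_charges,
                    surface_class=surface)


def annotation_frame(config: SyntheticSystemConfig) -> pd.DataFrame:
    """Surface-class/charge annotation table for the structured region."""
    rows = []
    for res in range(29, 29 + config.n_residues_structured):
        cls = ("concave" if res in config.concave_residues else
               "convex" if res in config.convex_residues else "other")
        rows.append((res, cls, config.charge_map.get(res, 0)))
    return pd.DataFrame(rows, columns=["residue", "surface_class", "charge"])


def simulate_scaffold_and_tails(config: SyntheticSystemConfig | None = None):
    """Scaffold + thermally weighted tail ensemble + ground truth.

    Samples ``config.n_conformers`` raw self-avoiding coils, scores
    them with the surrogate potential, and keeps the lowest-energy
    ``config.keep_frac`` of the pool — the energy-refined ensemble the
    selection protocol works with, in which electrostatically
    favourable conformers (e.g. the acidic residue-26 bead dipping
    into the positively charged cavity) are enriched. The returned
    :class:`GroundTruth` records the per-conformer cavity-contact flag
    (residue-26 bead strictly below the cavity plane in either chain)
    and the contact fraction.
    """
    if config is None:
        config = SyntheticSystemConfig()
    scaffold = build_synthetic_scaffold(config)
    seq = TAIL_SEQUENCE_DEFAULT[:config.tail_length].ljust(
        config.tail_length, "S")
    ensemble = sample_coil(config.n_conformers, seq, scaffold,
                           seed=config.seed)
    tail_charges = {r: c for r, c in config.charge_map.items()
                    if r <= config.tail_length}
    ensemble.charges = tail_charges
    energies = score_ensemble(ensemble, scaffold)
    n_keep = max(int(len(ensemble) * config.keep_frac), 1)
    weighted = ensemble.subset(np.sort(np.argsort(energies)[:n_keep]))
    plane = build_cavity_plane(scaffold)
    d26 = weighted.d26_positions()
    sd = signed_distance(plane, d26.reshape(-1, 3)).reshape(d26.shape[:2])
    contact = (sd < 0).any(axis=1)
    truth = GroundTruth(tail_truth={
        "sequence": seq,
        "charges": dict(tail_charges),
        "cavity_contact": contact,
        "contact_fraction": float(contact.mean()),
    })
    return scaffold, weighted, truth


# ---------------------------------------------------------------------------
# activity standard-curve data

def simulate_standard_curve(plateau: float = 0.2, amplitude: float = 2.0,
                            tau: float = 0.5,
                            ratios=(0.0375, 0.075, 0.15, 0.3, 0.5, 0.75,
                                    1.0, 1.5, 2.0),
                            noise_sd: float = 0.0, seed: int = 0):
    """Aggregation slopes on a one-phase exponential-decay standard curve.

    ``S(r) = plateau + amplitude * exp(-r / tau)`` over chaperone:client
    ratios spanning 0.0375-2. Returns ``(ratios, slopes)``.
    """
    r = np.asarray(ratios, dtype=float)
    s = plateau + amplitude * np.exp(-r / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sd, size=s.shape)
    return r, s
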
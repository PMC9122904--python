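"""Paramagnetic relaxation enhancement (PRE) profile analysis.

A nitroxide spin label broadens the resonances of amides within
~35 A of the unpaired electron; the effect is quantified per residue
as the ratio of peak intensities in the diamagnetic (reduced) and
paramagnetic (oxidized) states, ``ratio = I_red / I_ox``. Ratios near
1 mean no contact; large ratios mean the label spends time close to
that amide. The module computes those profiles, counts how strongly
charged residues on the concave (client-binding) versus convex face of
a cradle-shaped scaffold exceed a reference ratio, compares variant
profiles by RMSD and mean signed deviation, and assigns each variant
to one of four categories relative to a control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .csp import PeakList, match_peaks

__all__ = [
    "PREProfile",
    "SurfaceAnnotation",
    "PREComparison",
    "compute_pre_ratios",
    "surface_enrichment",
    "pre_rmsd",
    "classify_variant",
    "PREVariantClassifier",
    "CATEGORIES",
]

CATEGORIES = ("similar", "below_diagonal", "large_bidirectional", "moderate")


@dataclass
class PREProfile:
    """Per-residue I_red/I_ox ratios with status flags.

    ``data`` columns: residue, i_dia, i_para, ratio, status in
    {ok, overlapped, missing, vanished}. Vanished peaks (paramagnetic
    intensity below the noise floor) carry the display-cap ratio.
    """

    data: pd.DataFrame
    variant: str = ""
    label_site: str = ""

    def ratios(self, include_vanished: bool = False) -> pd.Series:
        keep = ["ok", "vanished"] if include_vanished else ["ok"]
        d = self.data[self.data["status"].isin(keep)]
        return d.set_index("residue")["ratio"]


@dataclass
class SurfaceAnnotation:
    """Residue -> surface class {concave, convex, other} and charge."""

    data: pd.DataFrame  # residue, surface_class, charge

    def __post_init__(self) -> None:
        bad = set(self.data["surface_class"]) - {"concave", "convex", "other"}
        if bad:
            raise ValueError(f"unknown surface classes: {sorted(bad)}")
        if self.data["residue"].duplicated().any():
            raise ValueError("duplicate residues in annotation")

    @classmethod
    def from_tsv(cls, path) -> "SurfaceAnnotation":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def compute_pre_ratios(para: PeakList, dia: PeakList,
                       noise_floor: float = 0.0,
                       ratio_cap: float = 10.0,
                       max_dist: float = 0.05,
                       rescale_median: bool = False,
                       variant: str = "", label_site: str = "") -> PREProfile:
    """I_red/I_ox per residue from paired paramagnetic/diamagnetic lists.

    Only residues with non-overlapping peaks in both spectra get a
    ratio. A paramagnetic intensity below ``noise_floor`` marks the
    peak as vanished: the ratio is reported capped at ``ratio_cap``
    (the 0-10 display ceiling by default). Intensities are assumed
    pre-scaled per acquisition; ``rescale_median`` divides each list
    by its median intensity first (off by default).
    """
    for pl, name in ((para, "paramagnetic"), (dia, "diamagnetic")):
        if (pl.data["intensity"] < 0).any():
            raise ValueError(f"negative intensities in {name} list")
    pairing = match_peaks(dia, para, max_dist=max_dist)
    ip = para.data.set_index("residue")["intensity"]
    idia = dia.data.set_index("residue")["intensity"]
    if rescale_median:
        ip = ip / ip.median()
        idia = idia / idia.median()
    rows = []
    for res, status in zip(pairing["residue"], pairing["status"]):
        if status != "ok":
            rows.append((res, np.nan, np.nan, np.nan, status))
            continue
        i_p, i_d = float(ip.loc[res]), float(idia.loc[res])
        if i_p <= noise_floor or i_p == 0:
            rows.append((res, i_d, i_p, ratio_cap, "vanished"))
        else:
            rows.append((res, i_d, i_p, i_d / i_p, "ok"))
    data = pd.DataFrame(
        rows, columns=["residue", "i_dia", "i_para", "ratio", "status"])
    return PREProfile(data, variant=variant, label_site=label_site)


def surface_enrichment(profile: PREProfile, annot: SurfaceAnnotation,
                       threshold: float = 2.0,
                       include_vanished: bool = True) -> dict:
    """Count charged concave vs convex residues above a ratio threshold.

    Returns the 2x2 table {class: (n_above, n_total)} over charged
    residues only, plus a Fisher exact p-value and odds ratio
    (descriptive; the classes are small).
    """
    ratios = profile.ratios(include_vanished=include_vanished)
    ann = annot.data.set_index("residue")
    counts = {}
    table = np.zeros((2, 2), dtype=int)
    for i, cls in enumerate(("concave", "convex")):
        sel = ann[(ann["surface_class"] == cls) & (ann["charge"] != 0)]
        res = np.intersect1d(sel.index.to_numpy(), ratios.index.to_numpy())
        above = int((ratios.loc[res] > threshold).sum())
        counts[cls] = (above, int(len(res)))
        table[i] = (above, len(res) - above)
    if min(counts["concave"][1], counts["convex"][1]) == 0:
        odds, p = np.nan, np.nan
    else:
        odds, p = stats.fisher_exact(table)
    return {"counts": counts, "table": table, "odds_ratio": float(odds)
            if np.isfinite(odds) else np.nan, "p_value": p,
            "threshold": threshold}


@dataclass
class PREComparison:
    """Variant-vs-reference comparison of two PRE profiles."""

    variant: str
    reference: str
    shared_residues: np.ndarray
    rmsd: float
    mean_signed_dev: float
    category: str | None = None

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def pre_rmsd(variant: PREProfile, reference: PREProfile,
             include_vanished: bool = False,
             min_shared: int = 10) -> PREComparison:
    """RMSD and mean signed deviation over shared ok residues.

    ``rmsd = sqrt(mean (r_var - r_ref)^2)``;
    ``mean_signed_dev = mean (r_var - r_ref)``. Requires at least
    ``min_shared`` shared residues. Vanished (capped) ratios are
    excluded by default.
    """
    rv = variant.ratios(include_vanished=include_vanished)
    rr = reference.ratios(include_vanished=include_vanished)
    shared = np.intersect1d(rv.index.to_numpy(), rr.index.to_numpy())
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared residues (< {min_shared})")
    diff = rv.loc[shared].to_numpy() - rr.loc[shared].to_numpy()
    return PREComparison(
        variant=variant.variant, reference=reference.variant,
        shared_residues=shared,
        rmsd=float(np.sqrt(np.mean(diff**2))),
        mean_signed_dev=float(np.mean(diff)))


def classify_variant(cmp: PREComparison, control_rmsd: float,
                     similar_mult: float = 1.25,
                     below_mult: float = -0.5,
                     large_mult: float = 2.5) -> str:
    """Assign one of four categories relative to the control comparison.

    The rule is a total function of (rmsd, mean signed deviation):
    ``similar`` if rmsd <= similar_mult * control_rmsd; else
    ``below_diagonal`` if the mean signed deviation <=
    below_mult * control_rmsd (profile systematically weaker than the
    reference); else ``large_bidirectional`` if
    rmsd >= large_mult * control_rmsd; else ``moderate``.
    """
    if not control_rmsd > 0:
        raise ValueError("control_rmsd must be positive")
    if cmp.rmsd <= similar_mult * control_rmsd:
        cat = "similar"
    elif cmp.mean_signed_dev <= below_mult * control_rmsd:
        cat = "below_diagonal"
    elif cmp.rmsd >= large_mult * control_rmsd:
        cat = "large_bidirectional"
    else:
        cat = "moderate"
    cmp.category = cat
    return cat


class PREVariantClassifier(BaseEstimator):
    """Four-way PRE-profile classifier calibrated on a control comparison.

    ``fit`` takes the control comparison (or a bare control RMSD);
    ``predict`` maps comparisons to categories.
    """

    def __init__(self, similar_mult: float = 1.25,
                 below_mult: float = -0.5, large_mult: float = 2.5):
        self.similar_mult = similar_mult
        self.below_mult = below_mult
        self.large_mult = large_mult

    def fit(self, control, y=None):
        rmsd = control.rmsd if isinstance(control, PREComparison) \
            else float(control)
        if not rmsd > 0:
            raise ValueError("control RMSD must be positive")
        self.control_rmsd_ = rmsd
        return self

    def predict(self, comparisons) -> list[str]:
        single = isinstance(comparisons, PREComparison)
        if single:
            comparisons = [comparisons]
        out = [classify_variant(c, self.control_rmsd_,
                                similar_mult=self.similar_mult,
                                below_mult=self.below_mult,
                                large_mult=self.large_mult)
               for c in comparisons]
        return out[0] if single else out
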
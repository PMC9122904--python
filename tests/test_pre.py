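"""PRE ratio profiles, enrichment, RMSD comparison and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chaperkit.pre import (CATEGORIES, PREProfile, PREVariantClassifier,
                           SurfaceAnnotation, classify_variant,
                           compute_pre_ratios, pre_rmsd, surface_enrichment)
from chaperkit.csp import PeakList
from chaperkit.synthetic import simulate_pre_profile
from chaperkit.tail import Scaffold, TailEnsemble


def intensity_list(residues, intensity):
    return PeakList(pd.DataFrame({
        "residue": residues, "aa": ["A"] * len(residues),
        "dH_ppm": np.linspace(7, 10, len(residues)),
        "dN_ppm": np.linspace(105, 130, len(residues)),
        "intensity": intensity}))


def profile_from_ratios(ratios: dict, variant="v") -> PREProfile:
    data = pd.DataFrame({"residue": list(ratios), "i_dia": 1.0,
                         "i_para": [1.0 / r for r in ratios.values()],
                         "ratio": list(ratios.values()), "status": "ok"})
    return PREProfile(data, variant=variant)


class TestRatios:
    def test_equal_intensities_give_unit_ratio(self):
        res = list(range(1, 11))
        prof = compute_pre_ratios(intensity_list(res, np.ones(10)),
                                  intensity_list(res, np.ones(10)))
        assert np.allclose(prof.ratios().to_numpy(), 1.0)

    def test_tenfold_attenuation(self):
        res = list(range(1, 6))
        prof = compute_pre_ratios(intensity_list(res, np.full(5, 0.1)),
                                  intensity_list(res, np.ones(5)))
        assert np.allclose(prof.ratios().to_numpy(), 10.0)

    def test_vanished_peak_capped_and_flagged(self):
        res = [1, 2]
        prof = compute_pre_ratios(intensity_list(res, [0.0, 1.0]),
                                  intensity_list(res, [1.0, 1.0]),
                                  noise_floor=0.05, ratio_cap=10.0)
        row = prof.data.set_index("residue").loc[1]
        assert row["status"] == "vanished" and row["ratio"] == 10.0

    def test_negative_intensity_rejected(self):
        res = [1, 2]
        with pytest.raises(ValueError):
            compute_pre_ratios(intensity_list(res, [-1.0, 1.0]),
                               intensity_list(res, [1.0, 1.0]))


    def test_median_rescaling_restores_unit_ratio(self):
        res = list(range(1, 11))
        prof = compute_pre_ratios(intensity_list(res, 5.0 * np.ones(10)),
                                  intensity_list(res, np.ones(10)),
                                  rescale_median=True)
        assert np.allclose(prof.ratios().to_numpy(), 1.0)


class TestEnrichment:
    ANNOT = SurfaceAnnotation(pd.DataFrame({
        "residue": list(range(1, 21)),
        "surface_class": ["concave"] * 6 + ["convex"] * 8 + ["other"] * 6,
        "charge": [1] * 6 + [1] * 8 + [0] * 6}))

    def test_constructed_counts(self):
        # all concave charged above 2; two of eight convex above 2
        ratios = {r: 5.0 for r in range(1, 7)}
        ratios.update({r: (3.0 if r in (7, 8) else 1.2)
                       for r in range(7, 15)})
        ratios.update({r: 1.0 for r in range(15, 21)})
        out = surface_enrichment(profile_from_ratios(ratios), self.ANNOT)
        assert out["counts"]["concave"] == (6, 6)
        assert out["counts"]["convex"] == (2, 8)

    def test_uniform_unit_ratios_no_exceedance(self):
        out = surface_enrichment(
            profile_from_ratios({r: 1.0 for r in range(1, 21)}), self.ANNOT)
        assert out["counts"]["concave"][0] == 0
        assert out["counts"]["convex"][0] == 0

    def test_random_profile_matches_bruteforce_count(self, rng):
        ratios = {r: float(rng.uniform(0, 6)) for r in range(1, 21)}
        out = surface_enrichment(profile_from_ratios(ratios), self.ANNOT,
                                 threshold=2.0)
        ann = self.ANNOT.data.set_index("residue")
        for cls in ("concave", "convex"):
            expected = sum(1 for r, v in ratios.items()
                           if ann.loc[r, "surface_class"] == cls
                           and ann.loc[r, "charge"] != 0 and v > 2.0)
            assert out["counts"][cls][0] == expected

    def test_empty_class_undefined_not_error(self):
        annot = SurfaceAnnotation(pd.DataFrame({
            "residue": [1, 2], "surface_class": ["concave", "concave"],
            "charge": [1, 1]}))
        out = surface_enrichment(profile_from_ratios({1: 3.0, 2: 1.0}),
                                 annot)
        assert np.isnan(out["odds_ratio"])


class TestRmsd:
    def test_identical_profiles_zero(self):
        p = profile_from_ratios({r: 2.0 for r in range(1, 15)})
        assert pre_rmsd(p, p).rmsd == 0.0

    def test_constant_offset(self):
        a = profile_from_ratios({r: 2.0 for r in range(1, 15)})
        b = profile_from_ratios({r: 3.0 for r in range(1, 15)})
        cmp_ = pre_rmsd(b, a)
        assert cmp_.rmsd == pytest.approx(1.0)
        assert cmp_.mean_signed_dev == pytest.approx(1.0)

    def test_random_profiles_match_sum_oracle(self, rng):
        res = range(1, 31)
        ra = {r: float(rng.uniform(0.5, 8)) for r in res}
        rb = {r: float(rng.uniform(0.5, 8)) for r in res}
        cmp_ = pre_rmsd(profile_from_ratios(ra), profile_from_ratios(rb))
        diffs = [ra[r] - rb[r] for r in res]
        assert cmp_.rmsd == pytest.approx(
            np.sqrt(sum(d * d for d in diffs) / len(diffs)), rel=1e-14)
        assert cmp_.mean_signed_dev == pytest.approx(
            sum(diffs) / len(diffs), rel=1e-14)

    @given(st.lists(st.tuples(st.floats(0.1, 10), st.floats(0.1, 10)),
                    min_size=10, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetry_and_antisymmetry(self, pairs):
        ra = {i + 1: a for i, (a, _) in enumerate(pairs)}
        rb = {i + 1: b for i, (_, b) in enumerate(pairs)}
        ab = pre_rmsd(profile_from_ratios(ra), profile_from_ratios(rb))
        ba = pre_rmsd(profile_from_ratios(rb), profile_from_ratios(ra))
        assert ab.rmsd == pytest.approx(ba.rmsd, rel=1e-12)
        assert ab.mean_signed_dev == pytest.approx(-ba.mean_signed_dev,
                                                   abs=1e-12)

    def test_too_few_shared_residues_rejected(self):
        a = profile_from_ratios({r: 1.0 for r in range(1, 6)})
        with pytest.raises(ValueError):
            pre_rmsd(a, a)


class TestClassification:
    def test_control_self_consistency_similar(self):
        from chaperkit.pre import PREComparison
        cmp_ = PREComparison("v", "r", np.arange(10), 0.78, 0.0)
        assert classify_variant(cmp_, 0.78) == "similar"

    def test_downshifted_profile_below_diagonal(self):
        a = profile_from_ratios({r: 4.0 for r in range(1, 15)})
        b = profile_from_ratios({r: 2.0 for r in range(1, 15)})
        cmp_ = pre_rmsd(b, a)
        assert classify_variant(cmp_, 0.78) == "below_diagonal"

    def test_symmetric_large_deviations(self, rng):
        base = {r: 4.0 for r in range(1, 21)}
        dev = {r: 4.0 + (3 * 0.78 if r % 2 else -3 * 0.78)
               for r in range(1, 21)}
        cmp_ = pre_rmsd(profile_from_ratios(dev), profile_from_ratios(base))
        assert classify_variant(cmp_, 0.78) == "large_bidirectional"

    @given(rmsd=st.floats(0.0, 5.0), msd=st.floats(-5.0, 5.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_total_function(self, rmsd, msd):
        from chaperkit.pre import PREComparison
        msd = float(np.clip(msd, -rmsd, rmsd))
        cmp_ = PREComparison("v", "r", np.arange(10), rmsd, msd)
        assert classify_variant(cmp_, 0.78) in CATEGORIES

    def test_classifier_estimator(self):
        from chaperkit.pre import PREComparison
        clf = PREVariantClassifier().fit(0.78)
        cmps = [PREComparison("a", "r", np.arange(10), 0.8, 0.0),
                PREComparison("b", "r", np.arange(10), 2.2, 0.0)]
        assert clf.predict(cmps) == ["similar", "large_bidirectional"]


def toy_scaffold(extra: dict) -> Scaffold:
    """Minimal valid scaffold: required residues far away, plus extras.

    ``extra`` maps residue -> chain-A coordinate; chain B copies are
    displaced to 1e6 so they contribute nothing.
    """
    far = 1e6
    chains, residues, coords = [], [], []
    required = [29, 110, 112, 120, 121]
    for ch, off in (("A", 0.0), ("B", far)):
        for i, r in enumerate(required):
            chains.append(ch)
            residues.append(r)
            coords.append([far + off + i * 10, far, far])
        for r, pos in extra.items():
            chains.append(ch)
            residues.append(r)
            coords.append(list(np.asarray(pos) + off))
    return Scaffold(np.array(chains), np.array(residues), np.array(coords),
                    surface_class={110: "concave"})


def ensemble_with_labels(labels: np.ndarray) -> TailEnsemble:
    n = len(labels)
    ens = TailEnsemble(np.zeros((n, 1, 28, 3)), np.zeros(n), np.arange(n))
    ens.label_positions = labels.reshape(n, 1, 3)
    return ens


class TestForwardPREModel:
    def test_infinite_distance_ratio_one(self):
        sc = toy_scaffold({60: (5e5, 0.0, 0.0)})
        ens = ensemble_with_labels(np.zeros((3, 3)))
        prof = simulate_pre_profile(ens, sc)
        assert prof.data.set_index("residue").loc[60, "ratio"] == \
            pytest.approx(1.0, abs=1e-9)

    def test_calibration_distance_gives_ratio_two(self):
        # label equidistant (15 A) from both symmetric copies of the bead
        far = 1e6
        chains = np.array(["A"] * 6 + ["B"] * 6)
        residues = np.array([29, 110, 112, 120, 121, 60] * 2)
        coords = np.full((12, 3), far)
        coords[:5] += np.arange(5)[:, None] * 10
        coords[6:11] += np.arange(5)[:, None] * 10 + far
        coords[5] = (15.0, 0.0, 0.0)
        coords[11] = (-15.0, 0.0, 0.0)
        sc = Scaffold(chains, residues, coords,
                      surface_class={110: "concave"})
        ens = ensemble_with_labels(np.zeros((1, 3)))
        prof = simulate_pre_profile(ens, sc)
        assert prof.data.set_index("residue").loc[60, "ratio"] == \
            pytest.approx(2.0, rel=1e-6)

    def test_monotone_in_distance(self):
        sc = toy_scaffold({60: (12.0, 0.0, 0.0), 61: (18.0, 0.0, 0.0)})
        ens = ensemble_with_labels(np.zeros((1, 3)))
        d = simulate_pre_profile(ens, sc).data.set_index("residue")
        assert d.loc[60, "ratio"] > d.loc[61, "ratio"]

    def test_three_conformer_hand_summed_average(self):
        # independent oracle: explicit per-conformer r^-6 average
        dists = np.array([14.0, 17.0, 25.0])
        sc = toy_scaffold({60: (0.0, 0.0, 0.0)})
        labels = np.column_stack([dists, np.zeros(3), np.zeros(3)])
        ens = ensemble_with_labels(labels)
        r2, t = 20.0, 0.01
        prof = simulate_pre_profile(ens, sc, r2_dia=r2,
                                    total_evolution_time=t)
        # calibration: gamma* solves (1 + g/r2) exp(g t) = 2 at 15 A
        from scipy.optimize import brentq
        g15 = brentq(lambda g: (1 + g / r2) * np.exp(g * t) - 2.0, 0, 1e3)
        k = g15 * 15.0**6
        mean_r6 = np.mean(dists**-6.0) / 2  # far chain-B bead dilutes
        gamma = k * mean_r6
        expected = (1 + gamma / r2) * np.exp(gamma * t)
        assert prof.data.set_index("residue").loc[60, "ratio"] == \
            pytest.approx(expected, rel=1e-9)
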
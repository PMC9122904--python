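# Methods

`chaperkit` implements the quantitative analyses used to characterise
how an ATP-independent, cradle-shaped chaperone dimer releases its
clients: two-state binding kinetics from biolayer-interferometry (BLI)
sensorgrams, relative chaperone activity from aggregation-curve
slopes, chemical-shift-perturbation (CSP) mapping and one-site
titration fitting, paramagnetic-relaxation-enhancement (PRE) profile
comparison, and a coarse-grained protocol for modelling the disordered
N-terminal tail and its electrostatic excursions into the
client-binding cavity. Every analysis can be exercised on synthetic
data with recorded ground truth; this note documents the models, the
defaults and their rationale, and what the synthetic systems do and do
not emulate.

## Binding kinetics

Association and dissociation phases are modelled as

    y_assoc(t) = a (1 - e^{-k_obs t}) + y0 t
    y_dissoc(t) = a e^{-k_off t} + y0 t

with `a` the maximal wavelength shift and `y0` a linear baseline-drift
slope (we read the drift term literally as `y0*t`). For a 1:1
interaction `k_obs = k_on C + k_off`, so an ordinary least-squares
line through `(C, k_obs)` over the concentration series gives `k_on`
(slope); `K_d = k_off / k_on`.

Numerical choices:

- Each phase is fitted by bounded nonlinear least squares
  (`scipy.optimize.curve_fit`, trust-region reflective). The rate is
  seeded from the time to reach 63% of the tail level (association) or
  a log-linearised early decay (dissociation); up to five jittered
  restarts run before a fit is declared non-convergent.
- A flat trace — signal range below five times the point-to-point
  noise estimate `sd(diff(y))/sqrt(2)` — is flagged `no_binding`
  rather than fitted.
- `k_off` is pooled across dissociation curves by inverse-variance
  weighting (falling back to a plain mean when the per-curve standard
  errors are degenerate, e.g. for noiseless fits); the `K_d` standard
  error uses the delta method. Per-curve fitting with pooling, rather
  than one global fit, was chosen for diagnosability; a shared-plateau
  global fit is deliberately not implemented.

The default experiment is the five-point series 0.25, 0.5, 1, 1.5,
2 uM with phase durations spanning four characteristic times of the
slowest process, 60 samples per phase, and homoscedastic Gaussian
noise of 1% of the association plateau (instrument noise magnitude and
sampling rate are package choices — typical for BLI — not reported
values). The recovery study grid spans `k_on` in [1e4, 1e6] /(M s) and
`k_off` in [1e-3, 2e-2] /s: with this concentration schedule that
keeps `K_d` between ~1 nM and 2 uM, i.e. inside the window the series
can actually resolve. Weaker affinities than the highest analyte
concentration leave the `k_obs` regression unidentifiable — an
experimental-design constraint, not a fitting failure — so they are
outside the validated grid.

## Chaperone activity

The late linear segment (180-240 min by default) of a light-scattering
aggregation trace is summarised by its least-squares slope. A standard
curve of slope versus wild-type chaperone:client molar ratio
(calibrated over ratios 0.0375-2) is fitted with a one-phase
exponential decay `S(r) = S_inf + A e^{-r/tau}` (the model family is
given; the parameterisation is ours) and inverted analytically; the
relative activity of a variant is its equivalent wild-type ratio
divided by the ratio actually assayed. Slopes outside the calibrated
range are clamped to it and flagged. A fitted standard curve that is
not strictly monotone over the calibrated range is rejected.

## CSP and one-site titration

Amide CSPs combine proton and nitrogen shift changes as
`CSP = sqrt(dH^2 + (0.2 dN)^2)`. Peaks are paired by residue number;
a reference peak with more than one query peak within `max_dist`
(default 0.05 ppm) in the weighted shift plane is ambiguous, and all
peaks involved are excluded as overlapped. Secondary shifts subtract a
packaged random-coil Ca/Cb table (standard reference values;
replaceable via the `coil_table` argument).

Fast-exchange titrations follow the one-site isotherm

    d_obs = d_max ((Kd + P0 + L0) - sqrt((Kd + P0 + L0)^2 - 4 P0 L0)) / (2 P0)

evaluated in the cancellation-stable form
`PL = 2 P0 L0 / (b + sqrt(b^2 - 4 P0 L0))`, which agrees with a
bisection solution of the binding equilibrium to better than 1e-9
relative everywhere tested. Per-residue nonlinear least squares
recovers `(K_d, d_max)` with `K_d` box bounds of [1e-4, 1e3] mM; fits
on the bounds are flagged poorly determined (expected whenever
`K_d >> max L0`). Residues whose largest observed CSP is below an
acceptance floor (default 0.015 ppm, three times the 0.005 ppm noise
default) are excluded from pooling; the pooled `K_d` is the median
over accepted residues with a bootstrap percentile CI. Median pooling
was chosen because one aggregate constant is reported from fits of
individually selected residues; both the per-residue fits and the
pooled value are exposed.

The default schedule is seven ligand:protein ratios (2, 6, 10, 14,
20, 30, 40) at `P0 = 0.1` mM. For a 4.7 mM ground-truth constant this
is a deliberately hard regime — the largest ligand concentration
(4 mM) does not reach `K_d`, so individual residues are
ill-conditioned — and the recovery study validates the pooled median
to within 25% rather than a tighter bound.

## PRE profiles

The PRE effect is quantified per residue as `ratio = I_red / I_ox`
between diamagnetic and paramagnetic peak intensities; ratios are
computed only for residues unoverlapped in both spectra. A
paramagnetic peak below the noise floor is "vanished": its ratio is
reported capped at 10 (the display ceiling) and flagged, and vanished
ratios are excluded from RMSD comparisons by default (both modes are
exposed; how vanished peaks were treated originally is not stated).
Intensities are assumed pre-scaled per acquisition; an optional
median-intensity rescaling exists but is off by default.

Surface enrichment counts how many charged concave versus charged
convex residues exceed a reference ratio (default 2), with a
descriptive Fisher exact test on the 2x2 table.

Profiles are compared by `rmsd = sqrt(mean (r_var - r_ref)^2)` and the
mean signed deviation over shared residues (at least 10 required).
Variants are assigned to four categories relative to a control
comparison whose RMSD defines the noise band: `similar` if
`rmsd <= 1.25 x control`; else `below_diagonal` if the mean signed
deviation is `<= -0.5 x control` (systematically weaker PRE,
label-cavity distances increased overall); else `large_bidirectional`
if `rmsd >= 2.5 x control`; else `moderate`. The verbal category
descriptions come with example RMSD levels but no decision rule; these
multipliers reproduce the reported groupings (similar at 0.78-0.89,
moderate at 1.23-1.74, large at 1.98-2.23, below-diagonal for the
variant with negative deviations) when applied to comparisons
constructed at those levels, and are configuration-overridable.

## Coarse-grained tail protocol

The structured dimer is a one-bead-per-residue scaffold (virtual
C-alpha chain); the 28-residue disordered tail attaches to structured
residue 29 of each chain and is sampled as a self-avoiding coil:
3.8 A virtual bonds, 4.0 A clash radius, uniformly random step
directions with rejection, both tails grown per conformer (the second
avoiding the first). The all-atom generate/refine/rank machinery is
replaced by a surrogate potential, in units of kT:

- soft-sphere repulsion `10 (4.0 - r)^2` inside the clash radius;
- screened Coulomb `3.0 q_i q_j (7.0/r) e^{-r/7.9}` between charged
  beads: Bjerrum length 7.0 A (water, 25 C), Debye length 7.9 A
  (150 mM monovalent salt, the experimental ionic strength). The
  prefactor 3.0 restores realistic Arg/Lys-Asp contact strengths
  (~3 kT) that centre-to-centre bead distances otherwise
  underestimate, consistent with residue-level statistical contact
  potentials.

The protocol steps are exact re-implementations of their geometric
definitions: the upper cavity plane is the total-least-squares plane
through four points (per chain, the geometric centers of the
residue-110/112 beads and of the residue-120/121 beads), oriented so
the cavity interior is on the negative side; "inside the cavity"
means strictly negative signed distance of the residue-26 bead (no
lateral bounds, matching the stated construction; a conformer is
removed if either chain's bead is inside, configurable to both);
distance exactly zero is kept. Top-k selection takes the k
lowest-energy conformers with ties broken by conformer id. Frame
resampling picks indices `floor(i*len/n)` — uniform stride, first
frame included. The spin label is a pseudo-bead 6 A off the
residue-25/26 midpoint along the local chain normal, standing in for
the nitroxide oxygen of a cysteine-insertion label at that position.

Thermal ensembles are produced two ways: `metropolis_trajectory`, a
pivot-move Monte Carlo sampler (optionally mixing in jump proposals
from a pre-sampled coil pool to hop between binding basins), and the
energy-rank route used by the generators — score a large raw coil pool
and keep the lowest-energy fraction (default 5%), mirroring the
minimise-and-select logic of the original protocol. The rank route is
deterministic given the pool and is what the charge-contrast study
uses, because pivot MC dwell times in multi-kT electrostatic basins
exceed desk-scale trajectory lengths.

## Synthetic cradle system

The scaffold places 96 beads per chain (residues 29-124, preserving
the crystallographic numbering so annotation files transfer) on a
half-cylindrical shell of radius 11 A opening upward, chain B
mirroring chain A. Key residues are placed by design: the four
plane-defining rim residues sit exactly coplanar; the tail anchor sits
on one wall with a clear corridor to the cavity bottom, where the
residue-89 bead is the only concave charge within reach of the
residue-26 bead (three virtual bonds from the anchor); the remaining
charged concave sites (43, 50, 54, 55, 61, 62, 96, 121, 122) line the
opposite wall and rim, spread along the long axis so no deep
multi-contact traps form; eight positively charged convex residues
sit on an outer shell 4 A above the surface. Tail charges follow the
disordered N terminus: acidic beads at positions 2, 10 and 26, basic
at 12, 18 and 20. The tail sequence string is a synthetic stand-in
with that charge pattern.

This geometry makes the two mechanistic contrasts identifiable at
desk scale: an acidic residue-26 bead is enriched inside the cavity
(and a basified one excluded), and reversing the residue-89 charge
relocates the label cloud outward, measured as the in-cavity fraction
and the median radial distance from the cavity long axis (the leading
principal component of the concave beads, through their centroid).
The paired-seed study uses 20 seeds, pools of 3000 coils and the top
5% rank ensemble; both contrasts hold in >= 19/20 pairs.

The PRE forward model maps ensemble-averaged `<r^-6>` between label
bead and residue bead (all conformers, both chains) to
`Gamma_2 = K <r^-6>`, and to a ratio via
`ratio = (1 + Gamma_2/R_2) e^{Gamma_2 t}` with `R_2 = 20 /s` and
`t = 10 ms`; `K` is calibrated once so a 15 A mean distance gives
ratio 2, keeping profiles on the 0-10 display scale. No original PRE
back-calculation exists to match; this transfer function is a
declared surrogate with the right limits (ratio 1 at infinite
distance, monotone in distance).

What the synthetic systems do not emulate: force-field energetics,
solvent, side-chain packing, client proteins, peak-position overlap
structure of real spectra, heteroscedastic or correlated instrument
noise, and any absolute PRE magnitudes. Passing recovery studies
therefore demonstrate the correctness and conditioning of the
estimators under the declared noise models, not instrument-level
accuracy on real data.

## Problem sizes

Default study sizes were chosen so the full validation suite runs on
one CPU in minutes: the kinetics grid uses 10x10 cells x 100 seeds
with 60-point phases; the titration study 100 replicates x 10
residues; the charge-contrast study 20 seeds x 3000-coil pools. All
sizes are arguments and scale up directly.

## Known limitations

- The one-bead tail has no sequence-dependent stiffness or secondary
  structure propensity; its end-to-end scaling is checked only to be
  consistent with a self-avoiding walk exponent in [0.5, 0.7].
- The kinetics module fits single-exponential phases only; no
  mass-transport-limited or heterogeneous-ligand models.
- Per-residue titration fits in the weak-binding regime are reported
  with box-bound flags rather than profile-likelihood intervals.
- The four-way PRE classification is a declared operationalisation of
  verbal category descriptions; the multipliers are configurable and
  comparisons near the band edges are sensitive to the control RMSD.
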
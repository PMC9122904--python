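"""Coarse-grained disordered-tail conformer protocol.

The structured chaperone dimer is represented as one bead per residue
(virtual C-alpha chain); the disordered N-terminal tail (residues 1-28,
attached to structured residue 29 of each chain) is sampled as a
self-avoiding random coil with a 3.8 A virtual bond. Conformers are
scored with a surrogate potential — soft-sphere repulsion inside a
4.0 A clash radius plus Debye-Hueckel screened Coulomb interactions
between charged beads (Bjerrum length 7.0 A, screening length 7.9 A,
the 150 mM-salt value; energies are therefore in units of kT).

The protocol mirrors the modeling pipeline it coarse-grains: sample a
pool of coils, score them, discard conformers whose residue-26 bead
(the acidic D26 analog) sits inside the binding cavity — "inside"
meaning strictly on the negative side of the best-fit plane through
four rim points (the per-chain geometric centers of the residue
110/112 and 120/121 beads) — and keep the lowest-energy structures.
Spin-label occupancy of the cavity is summarized from a cloud of
surrogate label positions: the in-cavity fraction (negative side of
the plane) and the median radial distance from the cavity long axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scaffold",
    "TailEnsemble",
    "CavityPlane",
    "CavityAxis",
    "LabelCloud",
    "BOND_LENGTH",
    "CLASH_RADIUS",
    "BJERRUM_LENGTH",
    "DEBYE_LENGTH",
    "sample_coil",
    "score_ensemble",
    "pair_energy",
    "build_cavity_plane",
    "fit_plane",
    "signed_distance",
    "filter_d26_inside",
    "select_topk",
    "resample_frames",
    "label_occupancy",
    "boltzmann_resample",
    "make_energy_fn",
    "metropolis_trajectory",
]

BOND_LENGTH = 3.8  # A, virtual C-alpha bond
CLASH_RADIUS = 4.0  # A, soft-sphere onset
SOFT_K = 10.0  # kT/A^2 soft-sphere spring constant
BJERRUM_LENGTH = 7.0  # A, water at 25 C; makes energies come out in kT
DEBYE_LENGTH = 7.9  # A, 150 mM monovalent salt
# contact-strength factor for the one-bead-per-residue representation:
# bare Debye-Hueckel between bead centers at the 4.0 A clash distance
# gives ~1 kT for a +1/-1 pair, well short of the 2-3 kT typical of
# Arg/Lys-Asp salt bridges in residue-level coarse-grained potentials
# (side chains approach closer than the backbone beads); the factor
# restores that contact strength.
ELEC_STRENGTH = 3.0
D26_RESIDUE = 26
LABEL_OFFSET = 6.0  # A, surrogate nitroxide bead offset from the chain

TAIL_CHARGES_DEFAULT = {2: -1, 10: -1, 12: 1, 18: 1, 20: 1, 26: -1}


@dataclass
class Scaffold:
    """Bead scaffold of the structured dimer (residues 29-124, 2 chains).

    ``coords`` has shape (n_beads, 3); ``chains`` and ``residues`` give
    per-bead chain id and residue number; ``charges`` maps residue
    number -> integer charge (applied on both chains);
    ``surface_class`` maps residue -> {concave, convex, other}.
    """

    chains: np.ndarray
    residues: np.ndarray
    coords: np.ndarray
    charges: dict = field(default_factory=dict)
    surface_class: dict = field(default_factory=dict)
    anchor_residue: int = 29
    plane_residues: tuple = (110, 112, 120, 121)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite scaffold coordinates")
        if len(set(self.chains)) != 2:
            raise ValueError("scaffold must have exactly two chains")
        for r in self.plane_residues + (self.anchor_residue,):
            for ch in sorted(set(self.chains)):
                if not np.any((self.chains == ch) & (self.residues == r)):
                    raise ValueError(f"residue {r} missing from chain {ch}")

    def bead(self, chain: str, residue: int) -> np.ndarray:
        m = (self.chains == chain) & (self.residues == residue)
        if not m.any():
            raise KeyError((chain, residue))
        return self.coords[m][0]

    @property
    def chain_ids(self) -> list:
        return sorted(set(self.chains))

    def charge_array(self) -> np.ndarray:
        return np.array([self.charges.get(int(r), 0) for r in self.residues],
                        dtype=float)

    def concave_centroid(self) -> np.ndarray:
        m = np.array([self.surface_class.get(int(r), "other") == "concave"
                      for r in self.residues])
        if not m.any():
            raise ValueError("no concave-annotated beads")
        return self.coords[m].mean(axis=0)

    def long_axis(self) -> np.ndarray:
        """Unit vector of the cradle long axis (leading PCA component
        of the concave beads)."""
        m = np.array([self.surface_class.get(int(r), "other") == "concave"
                      for r in self.residues])
        pts = self.coords[m] - self.coords[m].mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        v = vt[0]
        return v / np.linalg.norm(v)


@dataclass
class TailEnsemble:
    """Sampled tail conformers for both chains.

    ``coords`` shape (n_conformers, n_chains, tail_length, 3): bead j
    is residue j+1 (residues 1..tail_length, N to C; the C-terminal
    bead bonds to the scaffold anchor). ``energies`` may be NaN until
    scored. ``label_positions`` shape (n_conformers, n_chains, 3).
    """

    coords: np.ndarray
    energies: np.ndarray
    ids: np.ndarray
    sequence: str = ""
    charges: dict = field(default_factory=lambda: dict(TAIL_CHARGES_DEFAULT))
    label_positions: np.ndarray | None = None
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        self.ids = np.asarray(self.ids)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def tail_length(self) -> int:
        return self.coords.shape[2]

    def d26_positions(self) -> np.ndarray:
        """(n_conformers, n_chains, 3) positions of the residue-26 bead."""
        return self.coords[:, :, D26_RESIDUE - 1, :]

    def subset(self, idx: np.ndarray) -> "TailEnsemble":
        lp = None if self.label_positions is None \
            else self.label_positions[idx]
        return TailEnsemble(self.coords[idx], self.energies[idx],
                            self.ids[idx], self.sequence, dict(self.charges),
                            lp, self.n_failed)

    def charge_array(self) -> np.ndarray:
        return np.array([self.charges.get(j + 1, 0)
                         for j in range(self.tail_length)], dtype=float)


# ---------------------------------------------------------------------------
# coil sampling

def _grow_tails_batch(anchor: np.ndarray, n_conf: int, n_beads: int,
                      scaffold_coords: np.ndarray,
                      extra_obstacles: np.ndarray | None,
                      rng: np.random.Generator,
                      max_tries: int = 60,
                      n_candidates: int = 8):
    """Grow one self-avoiding tail per conformer, all in parallel.

    Chains grow from the anchor (C terminus, bonded to it) toward the
    N terminus with fixed virtual bonds; each step rejection-samples a
    direction whose new bead clears the clash radius against the
    scaffold, the per-conformer ``extra_obstacles`` (the other chain's
    tail) and the non-bonded beads of its own tail. Returns
    ``(coords, ok)`` with coords (n_conf, n_beads, 3), index 0 = the
    N-terminal residue, and a boolean success mask.
    """
    placed = np.full((n_conf, n_beads, 3), np.nan)
    prev = np.tile(anchor, (n_conf, 1))
    ok = np.ones(n_conf, dtype=bool)
    for step in range(n_beads):  # places bead n_beads-1-step (N-ward)
        active = np.flatnonzero(ok)
        done = np.zeros(len(active), dtype=bool)
        for _ in range(max_tries):
            todo = active[~done]
            if len(todo) == 0:
                break
            v = rng.standard_normal((len(todo), n_candidates, 3))
            v /= np.linalg.norm(v, axis=2, keepdims=True)
            cand = prev[todo, None, :] + BOND_LENGTH * v
            clash2 = CLASH_RADIUS**2
            diff = cand[:, :, None, :] - scaffold_coords[None, None, :, :]
            d2_scaf = np.einsum("ijkl,ijkl->ijk", diff, diff)
            if step == 0:
                # the anchor bead itself is bonded: exempt it
                exempt = np.all(scaffold_coords == anchor, axis=1)
                d2_scaf[:, :, exempt] = np.inf
            good = (d2_scaf >= clash2).all(axis=2)
            if extra_obstacles is not None:
                diff = (cand[:, :, None, :] -
                        extra_obstacles[todo][:, None, :, :])
                d2_x = np.einsum("ijkl,ijkl->ijk", diff, diff)
                good &= (d2_x >= clash2).all(axis=2)
            if step >= 2:  # own beads, excluding the bonded neighbour
                own = placed[todo][:, n_beads - step + 1:, :]
                diff = cand[:, :, None, :] - own[:, None, :, :]
                d2_own = np.einsum("ijkl,ijkl->ijk", diff, diff)
                good &= (np.nan_to_num(d2_own, nan=np.inf)
                         >= clash2).all(axis=2)
            hit = good.any(axis=1)
            first = np.argmax(good, axis=1)
            sel = todo[hit]
            placed[sel, n_beads - 1 - step] = cand[hit, first[hit]]
            prev[sel] = cand[hit, first[hit]]
            done[np.isin(active, sel)] = True
        ok[active[~done]] = False
    return placed, ok


def sample_coil(n: int, sequence: str, scaffold: Scaffold,
                seed: int = 0, max_restarts: int = 5) -> TailEnsemble:
    """Sample ``n`` self-avoiding coil conformers anchored to the scaffold.

    One tail is grown per chain; the second chain's tail additionally
    avoids the first. Conformers whose growth stalls are regrown up to
    ``max_restarts`` times and finally skipped (``n_failed``).
    Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not sequence:
        raise ValueError("sequence must be non-empty")
    n_beads = len(sequence)
    rng = np.random.default_rng(seed)
    chain_ids = scaffold.chain_ids
    anchors = [scaffold.bead(ch, scaffold.anchor_residue)
               for ch in chain_ids]
    coords = np.full((n, len(chain_ids), n_beads, 3), np.nan)
    alive = np.ones(n, dtype=bool)
    for _ in range(max_restarts):
        todo = np.flatnonzero(alive & np.isnan(coords[:, 0, 0, 0]))
        if len(todo) == 0:
            break
        for k, anchor in enumerate(anchors):
            extra = coords[:, k - 1] if k > 0 else None
            sub, ok = _grow_tails_batch(
                anchor, len(todo), n_beads, scaffold.coords,
                None if extra is None else extra[todo], rng)
            coords[todo[ok], k] = sub[ok]
            if k > 0:
                # chains grown after a failure leave the conformer invalid
                coords[todo[~ok], :, :, :] = np.nan
            else:
                coords[todo[~ok], 0, 0, 0] = np.nan
    good = ~np.isnan(coords[:, :, :, 0]).any(axis=(1, 2))
    n_failed = int((~good).sum())
    ens = TailEnsemble(coords[good], np.full(int(good.sum()), np.nan),
                       np.flatnonzero(good), sequence=sequence,
                       n_failed=n_failed)
    ens.label_positions = compute_label_positions(ens)
    return ens


def compute_label_positions(ensemble: TailEnsemble) -> np.ndarray:
    """Surrogate spin-label bead: 6 A off the residue-25/26 midpoint.

    The offset direction is the local chain normal, the unit cross
    product of the two virtual bonds flanking bead 25 (falls back to an
    arbitrary perpendicular for near-collinear geometry).
    """
    c = ensemble.coords
    if c.shape[2] < D26_RESIDUE:
        return None  # tail too short to carry the insertion-site label
    b24, b25, b26 = c[:, :, 23], c[:, :, 24], c[:, :, 25]
    mid = 0.5 * (b25 + b26)
    v1 = b26 - b25
    v2 = b24 - b25
    normal = np.cross(v1, v2)
    norm = np.linalg.norm(normal, axis=-1, keepdims=True)
    small = norm[..., 0] < 1e-8
    if small.any():
        # arbitrary perpendicular to v1
        alt = np.cross(v1, np.array([1.0, 0.0, 0.0]))
        alt_n = np.linalg.norm(alt, axis=-1, keepdims=True)
        alt = np.where(alt_n < 1e-8,
                       np.cross(v1, np.array([0.0, 1.0, 0.0])), alt)
        normal = np.where(small[..., None], alt, normal)
        norm = np.linalg.norm(normal, axis=-1, keepdims=True)
    return mid + LABEL_OFFSET * normal / norm


# ---------------------------------------------------------------------------
# scoring

def pair_energy(q1: float, q2: float, r: float) -> float:
    """Screened-Coulomb pair energy (kT) plus soft-sphere repulsion."""
    e = (ELEC_STRENGTH * q1 * q2 * BJERRUM_LENGTH *
         np.exp(-r / DEBYE_LENGTH) / max(r, 1e-6))
    if r < CLASH_RADIUS:
        e += SOFT_K * (CLASH_RADIUS - r) ** 2
    return float(e)


def score_ensemble(ensemble: TailEnsemble, scaffold: Scaffold,
                   clash_penalty_cap: float = 1e4) -> np.ndarray:
    """Surrogate energy (kT) of every conformer; also stored in-place.

    Terms: tail-scaffold and tail-tail screened Coulomb between charged
    beads, soft-sphere repulsion inside the clash radius for all
    non-bonded pairs. The bond between each C-terminal tail bead and
    its anchor is excluded. Overlapping beads contribute a large but
    finite penalty (capped at ``clash_penalty_cap`` per conformer).
    """
    n, n_chains, L, _ = ensemble.coords.shape
    if n == 0:
        return ensemble.energies
    tails = ensemble.coords.reshape(n, n_chains * L, 3)
    q_tail_chain = ensemble.charge_array()
    q_tail = np.tile(q_tail_chain, n_chains)
    q_scaf = scaffold.charge_array()

    # tail-scaffold
    d_ts = np.linalg.norm(
        tails[:, :, None, :] - scaffold.coords[None, None, :, :], axis=3)
    d_ts = np.maximum(d_ts, 1e-6)
    # exempt the anchor bond (last bead of each chain vs its anchor bead)
    anchor_mask = np.zeros((n_chains * L, len(scaffold.coords)), dtype=bool)
    for k, ch in enumerate(scaffold.chain_ids):
        j = np.flatnonzero((scaffold.chains == ch) &
                           (scaffold.residues == scaffold.anchor_residue))[0]
        anchor_mask[k * L + (L - 1), j] = True
    e_elec = (ELEC_STRENGTH * q_tail[None, :, None] * q_scaf[None, None, :] *
              BJERRUM_LENGTH * np.exp(-d_ts / DEBYE_LENGTH) / d_ts)
    overlap = np.maximum(CLASH_RADIUS - d_ts, 0.0)
    overlap[:, anchor_mask] = 0.0
    e_soft = SOFT_K * overlap**2
    energy = (e_elec + e_soft).sum(axis=(1, 2))

    # tail-tail (within and across chains)
    d_tt = np.linalg.norm(tails[:, :, None, :] - tails[:, None, :, :], axis=3)
    d_tt = np.maximum(d_tt, 1e-6)
    iu, ju = np.triu_indices(n_chains * L, k=1)
    same_chain = (iu // L) == (ju // L)
    bonded = same_chain & (np.abs(iu - ju) == 1)
    keep = ~bonded
    iuk, juk = iu[keep], ju[keep]
    d_pairs = d_tt[:, iuk, juk]
    qq = q_tail[iuk] * q_tail[juk]
    e_tt = (ELEC_STRENGTH * qq[None, :] * BJERRUM_LENGTH *
            np.exp(-d_pairs / DEBYE_LENGTH) / d_pairs)
    e_tt += SOFT_K * np.maximum(CLASH_RADIUS - d_pairs, 0.0) ** 2
    energy += e_tt.sum(axis=1)
    energy = np.minimum(energy, clash_penalty_cap)
    ensemble.energies = energy
    return energy


def make_energy_fn(scaffold: Scaffold, tail_charges: dict,
                   n_chains: int, tail_len: int):
    """Precompiled single-conformer energy function for MC sampling.

    Returns ``f(coords)`` with ``coords`` of shape
    (n_chains, tail_len, 3), evaluating the same surrogate potential
    as :func:`score_ensemble`.
    """
    L = tail_len
    q_tail = np.tile(np.array([tail_charges.get(j + 1, 0)
                               for j in range(L)], dtype=float), n_chains)
    q_scaf = scaffold.charge_array()
    scaf = scaffold.coords
    anchor_pairs = []
    for k, ch in enumerate(scaffold.chain_ids[:n_chains]):
        j = np.flatnonzero((scaffold.chains == ch) &
                           (scaffold.residues == scaffold.anchor_residue))[0]
        anchor_pairs.append((k * L + (L - 1), int(j)))
    # electrostatics only involves charged beads; soft-sphere needs all
    tq_idx = np.flatnonzero(q_tail != 0)
    sq_idx = np.flatnonzero(q_scaf != 0)
    qq_ts = (q_tail[tq_idx][:, None] * q_scaf[sq_idx][None, :] *
             ELEC_STRENGTH * BJERRUM_LENGTH)
    scaf_q = scaf[sq_idx]
    iu, ju = np.triu_indices(n_chains * L, k=1)
    bonded = ((iu // L) == (ju // L)) & (np.abs(iu - ju) == 1)
    iuk, juk = iu[~bonded], ju[~bonded]
    charged_pair = (q_tail[iuk] != 0) & (q_tail[juk] != 0)
    iq, jq = iuk[charged_pair], juk[charged_pair]
    qq_tt = q_tail[iq] * q_tail[jq] * ELEC_STRENGTH * BJERRUM_LENGTH

    def energy(coords: np.ndarray) -> float:
        flat = coords.reshape(n_chains * L, 3)
        diff = flat[:, None, :] - scaf[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        overlap2 = d2 < CLASH_RADIUS**2
        for ti, si in anchor_pairs:
            overlap2[ti, si] = False
        e = 0.0
        if overlap2.any():
            dov = np.sqrt(d2[overlap2])
            e += SOFT_K * float(np.sum((CLASH_RADIUS - dov) ** 2))
        dq = np.sqrt(np.maximum(d2[np.ix_(tq_idx, sq_idx)], 1e-12))
        e += float(np.sum(qq_ts * np.exp(-dq / DEBYE_LENGTH) / dq))
        dp = flat[iuk] - flat[juk]
        d2tt = np.einsum("ij,ij->i", dp, dp)
        ov = d2tt < CLASH_RADIUS**2
        if ov.any():
            dov = np.sqrt(d2tt[ov])
            e += SOFT_K * float(np.sum((CLASH_RADIUS - dov) ** 2))
        dpq = flat[iq] - flat[jq]
        dqq = np.sqrt(np.maximum(np.einsum("ij,ij->i", dpq, dpq), 1e-12))
        e += float(np.sum(qq_tt * np.exp(-dqq / DEBYE_LENGTH) / dqq))
        return e

    return energy


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def metropolis_trajectory(scaffold: Scaffold, init: TailEnsemble,
                          n_frames: int = 1000,
                          steps_per_frame: int = 10,
                          kt: float = 1.0,
                          burn_in_frames: int = 100,
                          proposal_pool: TailEnsemble | None = None,
                          p_jump: float = 0.15,
                          seed: int = 0) -> TailEnsemble:
    """Metropolis Monte Carlo trajectory of the anchored tails.

    A desk-scale surrogate for thermal (MD) sampling: pivot moves
    rotate the N-terminal segment of a randomly chosen chain about a
    randomly chosen bead (or the anchor) by a Gaussian-distributed
    angle; moves are accepted with the Metropolis criterion on the
    surrogate energy at temperature ``kt``. Bond lengths are preserved
    exactly by construction; self-avoidance is enforced by the
    soft-sphere term. One frame is recorded every ``steps_per_frame``
    attempted moves after ``burn_in_frames`` discarded frames.

    ``init`` supplies the starting conformer (its first entry) and the
    tail charges. ``proposal_pool`` optionally provides pre-sampled
    coil conformers; with probability ``p_jump`` a move proposes a
    uniformly drawn pool member instead of a pivot, which lets the
    chain hop between binding basins that pivot moves alone cross
    slowly. Deterministic under ``seed``.
    """
    if len(init) == 0:
        raise ValueError("init ensemble is empty")
    n_chains, L = init.coords.shape[1], init.coords.shape[2]
    anchors = np.stack([scaffold.bead(ch, scaffold.anchor_residue)
                        for ch in scaffold.chain_ids[:n_chains]])
    energy = make_energy_fn(scaffold, init.charges, n_chains, L)
    rng = np.random.default_rng(seed)
    state = init.coords[0].copy()
    e_cur = energy(state)
    frames = np.empty((n_frames, n_chains, L, 3))
    energies = np.empty(n_frames)
    total = (n_frames + burn_in_frames) * steps_per_frame
    rec = 0
    pool = None if proposal_pool is None or len(proposal_pool) == 0 \
        else proposal_pool.coords
    for step in range(total):
        if pool is not None and rng.random() < p_jump:
            trial = pool[int(rng.integers(len(pool)))].copy()
        else:
            c = int(rng.integers(n_chains))
            j = int(rng.integers(1, L + 1))  # rotate beads [0:j) about it
            pivot = anchors[c] if j == L else state[c, j]
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = rng.normal(0.0, 1.0)
            R = _rotation_matrix(axis, angle)
            trial = state.copy()
            trial[c, :j] = (state[c, :j] - pivot) @ R.T + pivot
        e_new = energy(trial)
        if e_new <= e_cur or rng.random() < np.exp(-(e_new - e_cur) / kt):
            state, e_cur = trial, e_new
        if (step + 1) % steps_per_frame == 0:
            frame = (step + 1) // steps_per_frame - 1
            if frame >= burn_in_frames:
                frames[rec] = state
                energies[rec] = e_cur
                rec += 1
    traj = TailEnsemble(frames, energies, np.arange(n_frames),
                        sequence=init.sequence, charges=dict(init.charges))
    traj.label_positions = compute_label_positions(traj)
    return traj


def boltzmann_resample(ensemble: TailEnsemble, n: int,
                       kt: float = 1.0, seed: int = 0) -> TailEnsemble:
    """Importance-resample conformers with weights exp(-E/kT).

    Stands in for thermal sampling: the raw coil pool is geometry-only,
    so electrostatic preferences enter through this reweighting.
    """
    e = ensemble.energies
    if np.isnan(e).any():
        raise ValueError("score the ensemble before resampling")
    w = np.exp(-(e - e.min()) / kt)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ensemble), size=n, replace=True, p=w)
    return ensemble.subset(np.sort(idx))


# ---------------------------------------------------------------------------
# cavity geometry

@dataclass
class CavityPlane:
    """Best-fit plane through the four rim points; normal points away
    from the cavity interior (the concave centroid has negative signed
    distance)."""

    point: np.ndarray
    normal: np.ndarray
    defining_points: np.ndarray  # (4, 3)
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("normal must be a unit vector")


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane through points.

    Returns (centroid, unit normal, rms point-plane residual). The
    normal is the singular vector of the smallest singular value.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("defining points are collinear or degenerate")
    normal = vt[-1] / np.linalg.norm(vt[-1])
    resid = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return centroid, normal, resid


def build_cavity_plane(scaffold: Scaffold) -> CavityPlane:
    """Upper cavity plane from four per-chain rim-residue centers.

    The four defining points are, for each chain, the geometric center
    of the residue-110 and -112 beads and the geometric center of the
    residue-120 and -121 beads. The plane is the total-least-squares
    fit; the normal is oriented so the concave centroid lies strictly
    on the negative side.
    """
    r1, r2, r3, r4 = scaffold.plane_residues
    points = []
    for ch in scaffold.chain_ids:
        points.append(0.5 * (scaffold.bead(ch, r1) + scaffold.bead(ch, r2)))
        points.append(0.5 * (scaffold.bead(ch, r3) + scaffold.bead(ch, r4)))
    points = np.array(points)
    centroid, normal, resid = fit_plane(points)
    cav = scaffold.concave_centroid()
    if np.dot(cav - centroid, normal) > 0:
        normal = -normal
    if np.isclose(np.dot(cav - centroid, normal), 0.0):
        raise ValueError("cavity centroid lies on the plane; geometry "
                         "degenerate")
    return CavityPlane(centroid, normal, points, resid)


def signed_distance(plane: CavityPlane, points: np.ndarray) -> np.ndarray:
    """Signed point-plane distance; negative = cavity side."""
    return (np.asarray(points, dtype=float) - plane.point) @ plane.normal


def filter_d26_inside(ensemble: TailEnsemble, plane: CavityPlane,
                      mode: str = "either"):
    """Remove conformers whose residue-26 bead lies inside the cavity.

    "Inside" is a strictly negative signed distance to the plane
    (distance exactly 0 is kept). ``mode="either"`` drops a conformer
    when either chain's bead 26 is inside; ``mode="both"`` only when
    both are. Returns ``(filtered_ensemble, n_removed)``.
    """
    if mode not in ("either", "both"):
        raise ValueError("mode must be 'either' or 'both'")
    d26 = ensemble.d26_positions()  # (n, chains, 3)
    sd = signed_distance(plane, d26.reshape(-1, 3)).reshape(d26.shape[:2])
    inside = sd < 0
    drop = inside.any(axis=1) if mode == "either" else inside.all(axis=1)
    keep = np.flatnonzero(~drop)
    return ensemble.subset(keep), int(drop.sum())


def select_topk(ensemble: TailEnsemble, k: int = 3):
    """The ``k`` lowest-energy conformers, ties broken by conformer id.

    If the ensemble is smaller than ``k``, everything is returned with
    ``flagged=True``. Returns ``(subset, flagged)``.
    """
    if np.isnan(ensemble.energies).any():
        raise ValueError("score the ensemble before selection")
    if len(ensemble) <= k:
        order = np.lexsort((ensemble.ids, ensemble.energies))
        return ensemble.subset(order), len(ensemble) < k
    order = np.lexsort((ensemble.ids, ensemble.energies))[:k]
    return ensemble.subset(order), False


# ---------------------------------------------------------------------------
# label clouds

@dataclass
class LabelCloud:
    """Label positions from uniformly resampled trajectory frames."""

    positions: np.ndarray  # (n_frames, n_chains, 3)
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices)
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def flat(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)


def resample_frames(trajectory: TailEnsemble, n: int = 1000) -> LabelCloud:
    """Uniform-stride frame resampling, first frame included.

    Selected indices are ``floor(i * len / n)`` for ``i = 0..n-1``:
    length 2000 with n = 1000 gives every 2nd frame starting at 0, and
    n = len gives every frame. Requires ``len >= n``.
    """
    m = len(trajectory)
    if m < n:
        raise ValueError(f"trajectory has {m} frames < n = {n}")
    idx = (np.arange(n) * m) // n
    if trajectory.label_positions is None:
        trajectory.label_positions = compute_label_positions(trajectory)
    return LabelCloud(trajectory.label_positions[idx], idx)


@dataclass
class CavityAxis:
    """Line through the cavity centroid along the cradle long axis."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.direction)
        if n < 1e-8:
            raise ValueError("degenerate axis direction")
        self.direction = np.asarray(self.direction, dtype=float) / n

    @classmethod
    def from_scaffold(cls, scaffold: Scaffold) -> "CavityAxis":
        return cls(scaffold.concave_centroid(), scaffold.long_axis())


def label_occupancy(cloud: LabelCloud, plane: CavityPlane, axis: CavityAxis,
                    reference: LabelCloud | None = None) -> dict:
    """Cavity-occupancy metrics of a label cloud.

    Returns in_cavity_fraction (fraction of positions on the negative
    side of the plane), median_radial_distance (A, from the cavity
    axis), and, when a reference cloud is given, edge_relocation_score
    = this cloud's median radial distance minus the reference's.
    """
    pos = cloud.flat()
    if len(pos) == 0:
        raise ValueError("empty label cloud")
    sd = signed_distance(plane, pos)
    rel = pos - axis.point
    along = rel @ axis.direction
    radial = np.linalg.norm(rel - along[:, None] * axis.direction, axis=1)
    out = {
        "in_cavity_fraction": float(np.mean(sd < 0)),
        "median_radial_distance": float(np.median(radial)),
        "n_positions": int(len(pos)),
    }
    if reference is not None:
        ref = label_occupancy(reference, plane, axis)
        out["edge_relocation_score"] = (out["median_radial_distance"] -
                                        ref["median_radial_distance"])
    return out
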
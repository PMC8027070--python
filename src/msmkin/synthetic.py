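"""Synthetic receptor trajectories with planted, fully known kinetics.

The generator emulates the inputs of the ensemble analysis — multi-replica
MD trajectories of a two-domain receptor (a fixed "7TM" core plus a mobile
"ECD" helix) hopping between metastable conformational states — with every
downstream quantity recoverable from a known ground truth: the hidden
macrostate path is sampled from a reversible transition matrix built from a
symmetric rate skeleton, each frame is a per-state reference conformer plus
isotropic Gaussian noise and a random rigid-body transform (so the pipeline
must superpose before measuring anything), and the per-state conformers are
constructed so the ECD tilt angle and ECD-7TM COM distance land exactly on
the per-state targets.

No force field and no integrator: this is a statistical stand-in for MD,
not a physical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from . import geometry, msm, tpt
from .structio import (ResidueGroup, StructureFrame, TrajectoryEnsemble,
                       logger, mass_of_element, write_run_metadata,
                       write_table, write_trajectory_pdb, write_coord_table)

DEFAULT_STATE_NAMES = ("closed", "semi-open", "open", "ECD-unrestricted")


def default_transition_matrix(self_prob: float = 0.97) -> np.ndarray:
    """Reversible 4-state transition matrix from a symmetric rate skeleton.

    Off-diagonal connectivity weights couple closed<->semi-open<->open as the
    main pathway with weaker direct and ECD-unrestricted shortcuts; every
    row's self-transition probability is exactly ``self_prob``, and the
    stationary distribution is proportional to the skeleton row sums (hence
    non-uniform). Reversibility holds by construction.
    """
    if not 0 < self_prob < 1:
        raise ValueError("self_prob must be in (0, 1)")
    w = np.array([
        #  closed  semi   open  unres
        [0.0, 3.0, 1.0, 0.5],    # closed
        [3.0, 0.0, 2.5, 1.5],    # semi-open
        [1.0, 2.5, 0.0, 2.5],    # open
        [0.5, 1.5, 2.5, 0.0],    # ECD-unrestricted
    ])
    x = w.copy()
    off = w.sum(axis=1)
    np.fill_diagonal(x, off * self_prob / (1.0 - self_prob))
    t = x / x.sum(axis=1, keepdims=True)
    return t


@dataclass
class GroundTruthSpec:
    """Parameters of the planted kinetics and the per-state toy conformers.

    Defaults mirror the study conditions the pipeline targets: 4 metastable
    macrostates, 5 replicas of 5,000 frames (within the 4,519-14,281
    conformations-per-trajectory range of the source ensembles), per-state
    self-transition probability 0.97 at the generation timestep, 40
    pseudo-residues with full backbone (N, CA, C, O), and 0.2 A Cartesian
    noise — small against the > 4 A inter-state reference RMSD.
    """

    n_states: int = 4
    state_names: tuple = DEFAULT_STATE_NAMES
    transition_matrix: np.ndarray = field(
        default_factory=default_transition_matrix)
    state_theta_deg: tuple = (90.0, 60.0, 40.0, 60.0)
    state_d_ang: tuple = (47.0, 50.0, 53.0, 65.0)
    sigma_ang: float = 0.2
    n_residues: int = 40
    n_replicas: int = 5
    n_frames: int = 5000
    dt_ns: float = 0.2
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("true transition matrix must be row-stochastic")
        pi = tpt.stationary_distribution(t)
        if np.abs(pi[:, None] * t - (pi[:, None] * t).T).max() > 1e-10:
            raise ValueError("true transition matrix must be reversible")
        self.transition_matrix = t
        if not (len(self.state_theta_deg) == len(self.state_d_ang)
                == self.n_states):
            raise ValueError("per-state targets must match n_states")
        if self.n_residues < 4:
            raise ValueError("need at least 4 pseudo-residues")
        labels = [geometry.classify_state(th, d)
                  for th, d in zip(self.state_theta_deg, self.state_d_ang)]
        if len(set(labels)) != self.n_states:
            raise ValueError(
                f"per-state (theta, d) means must fall in distinct state "
                f"regions; got {labels}")

    @property
    def stationary_distribution(self) -> np.ndarray:
        return tpt.stationary_distribution(self.transition_matrix)

    @property
    def n_core_residues(self) -> int:
        return self.n_residues // 2

    def ecd_group(self) -> ResidueGroup:
        return ResidueGroup.from_range("ECD", "A", self.n_core_residues + 1,
                                       self.n_residues)

    def tm7_group(self) -> ResidueGroup:
        return ResidueGroup.from_range("7TM", "A", 1, self.n_core_residues)

    def ecl1_group(self) -> ResidueGroup:
        base = 1
        return ResidueGroup("ECL1", tuple(("A", base + i) for i in (6, 8, 10)))

    def ecl3_group(self) -> ResidueGroup:
        base = 1
        return ResidueGroup("ECL3", tuple(("A", base + i) for i in (7, 9, 11)))

    def helix_group(self) -> ResidueGroup:
        """The 18 C-terminal ECD residues whose summed carbonyl vector
        defines the tilt angle (the analysis convention for the N-terminal
        receptor helix)."""
        n_helix = min(18, self.n_residues - self.n_core_residues)
        return ResidueGroup.from_range(
            "ecd-helix", "A", self.n_residues - n_helix + 1, self.n_residues)

    def groups(self) -> dict[str, ResidueGroup]:
        return {"ecd": self.ecd_group(), "tm7": self.tm7_group(),
                "ecl1": self.ecl1_group(), "ecl3": self.ecl3_group()}


# ---------------------------------------------------------------------------
# Reference conformers
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": np.array([-1.00, 0.35, -0.80]),
    "CA": np.zeros(3),
    "C": np.array([1.05, 0.30, 0.70]),
}


def _core_topology_coords(n_core: int) -> tuple[list, np.ndarray]:
    """Ring-like rigid core. Residue pairs (2k, 2k+1) sit mirror-symmetric
    about the xz-plane so the ECL1/ECL3 COM distances to an ECD placed in
    that plane stay nearly equal (the default states are never on-side)."""
    records, coords = [], []
    for i in range(n_core):
        mag = np.radians(14.0 + 9.0 * (i // 2))
        ang = mag if i % 2 == 0 else -mag
        z = -5.0 - 1.3 * ((i // 2) % 5)
        ca = np.array([8.0 * np.cos(ang), 8.0 * np.sin(ang), z])
        for atom in ("N", "CA", "C", "O"):
            if atom == "O":
                xyz = ca + _BACKBONE_OFFSETS["C"] + np.array([0.25, 1.15, 0.35])
            else:
                xyz = ca + _BACKBONE_OFFSETS[atom]
            records.append(("A", i + 1, "ALA", atom))
            coords.append(xyz)
    return records, np.asarray(coords)


def _ecd_canonical_coords(n_ecd: int) -> np.ndarray:
    """Idealized ECD helix along +z with every carbonyl C->O vector exactly
    +z, so a rigid rotation by theta sets the tilt angle exactly."""
    coords = []
    for j in range(n_ecd):
        ang = np.radians(100.0) * j
        ca = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * j])
        n = ca + np.array([-0.90 * np.cos(ang + 0.8),
                           -0.90 * np.sin(ang + 0.8), -0.85])
        c = ca + np.array([1.00 * np.cos(ang - 0.9),
                           1.00 * np.sin(ang - 0.9), 0.60])
        o = c + np.array([0.0, 0.0, 1.23])
        coords.extend([n, ca, c, o])
    return np.asarray(coords)


def _rot_y(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def build_reference_conformers(spec: GroundTruthSpec) -> list[StructureFrame]:
    """Deterministic per-state toy conformers.

    The core is identical across states; the ECD helix is rigid-rotated by
    theta about y (its summed C->O vector then makes exactly theta with +z)
    and translated so its backbone COM sits exactly at distance d from the
    core backbone COM, along the direction tilted -theta/2 from +z in the
    xz-plane. Placing the COM on the side opposite the tilt means no single
    global rotation can absorb both the orientation and the position
    difference of two states, which keeps distinct states geometrically well
    separated (inter-reference CA RMSD >> noise).
    """
    n_core = spec.n_core_residues
    n_ecd = spec.n_residues - n_core
    core_records, core_coords = _core_topology_coords(n_core)
    ecd_canonical = _ecd_canonical_coords(n_ecd)
    ecd_records = [("A", n_core + 1 + j, "ALA", atom)
                   for j in range(n_ecd) for atom in ("N", "CA", "C", "O")]
    records = core_records + ecd_records
    chain, res_id, res_name, atom_name = map(np.array, zip(*records))
    masses = np.array([mass_of_element(a[0]) for a in atom_name])

    core_w = masses[:len(core_coords)]
    core_com = (core_w[:, None] * core_coords).sum(0) / core_w.sum()
    ecd_w = masses[len(core_coords):]

    conformers = []
    for k in range(spec.n_states):
        theta, d = spec.state_theta_deg[k], spec.state_d_ang[k]
        rot = _rot_y(theta)
        ecd = ecd_canonical @ rot.T
        com = (ecd_w[:, None] * ecd).sum(0) / ecd_w.sum()
        half = np.radians(-theta / 2.0)
        target = core_com + d * np.array([np.sin(half), 0.0, np.cos(half)])
        ecd = ecd + (target - com)
        frame = StructureFrame(
            chain_id=chain, res_id=res_id.astype(int), res_name=res_name,
            atom_name=atom_name,
            coord=np.vstack([core_coords, ecd]), mass=masses, frame_index=k)
        conformers.append(frame)

    # separability guard: planted noise must stay well below state contrast
    ca = conformers[0].ca_indices()
    for i in range(spec.n_states):
        for j in range(i + 1, spec.n_states):
            r = geometry.rmsd(conformers[i].coord[ca],
                              conformers[j].coord[ca], fit=True)
            if r <= 4.0 * spec.sigma_ang:
                raise ValueError(
                    f"states {i} and {j} are not separable: reference CA "
                    f"RMSD {r:.2f} A <= 4 sigma ({4 * spec.sigma_ang:.2f} A)")
    return conformers


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def sample_markov_chain(t: np.ndarray, n_steps: int,
                        rng: np.random.Generator,
                        init: int | None = None) -> np.ndarray:
    """Sample a state path from a row-stochastic matrix; the initial state
    is drawn from the stationary distribution unless given."""
    t = np.asarray(t, dtype=float)
    cum = np.cumsum(t, axis=1)
    path = np.empty(n_steps, dtype=int)
    if init is None:
        pi = tpt.stationary_distribution(t)
        init = int(rng.choice(len(pi), p=pi))
    path[0] = init
    u = rng.random(n_steps)
    for step in range(1, n_steps):
        path[step] = np.searchsorted(cum[path[step - 1]], u[step])
    return path


@dataclass
class SyntheticBundle:
    """A generated ensemble plus everything needed to score recovery."""

    ensemble: TrajectoryEnsemble
    hidden_labels: dict[str, np.ndarray]
    spec: GroundTruthSpec
    reference_conformers: list[StructureFrame]
    true_pi: np.ndarray
    true_slowest_timescale_ns: float
    true_transition_times_ns: dict[tuple[int, int], float]

    def stacked_labels(self) -> np.ndarray:
        return np.concatenate([self.hidden_labels[r]
                               for r in self.ensemble.replica_ids])


def simulate_trajectories(spec: GroundTruthSpec,
                          seed: int | None = None) -> SyntheticBundle:
    """Generate the multi-replica synthetic ensemble.

    Per replica (seed streams derived from the master seed by fixed
    replica-index offsets): a hidden macrostate path sampled from the true
    transition matrix; each frame is the current state's reference conformer
    plus isotropic Gaussian noise plus a uniformly random rigid-body
    rotation and translation.
    """
    master = spec.seed if seed is None else seed
    conformers = build_reference_conformers(spec)
    ref_coords = np.stack([c.coord for c in conformers])
    t_true = spec.transition_matrix
    coords: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for rep in range(spec.n_replicas):
        rng = np.random.default_rng(np.random.SeedSequence((master, rep)))
        path = sample_markov_chain(t_true, spec.n_frames, rng)
        xyz = ref_coords[path]
        xyz = xyz + rng.normal(0.0, spec.sigma_ang, size=xyz.shape)
        quat = rng.normal(size=(spec.n_frames, 4))
        rots = Rotation.from_quat(quat / np.linalg.norm(quat, axis=1,
                                                        keepdims=True))
        shift = rng.uniform(-15.0, 15.0, size=(spec.n_frames, 1, 3))
        xyz = np.einsum("fni,fji->fnj", xyz, rots.as_matrix()) + shift
        rep_id = f"rep{rep}"
        coords[rep_id] = xyz
        labels[rep_id] = path
    ensemble = TrajectoryEnsemble(topology=conformers[0].with_coord(
        conformers[0].coord), coords=coords, dt_ns=spec.dt_ns)
    lam = np.sort(np.linalg.eigvals(t_true).real)[::-1]
    true_ts = (np.inf if lam[1] >= 1.0
               else -spec.dt_ns / np.log(lam[1]))
    times = tpt.pairwise_transition_times(t_true, spec.dt_ns)
    logger.info("synthetic bundle: %d replicas x %d frames, seed %s",
                spec.n_replicas, spec.n_frames, master)
    return SyntheticBundle(ensemble=ensemble, hidden_labels=labels, spec=spec,
                           reference_conformers=conformers,
                           true_pi=spec.stationary_distribution,
                           true_slowest_timescale_ns=float(true_ts),
                           true_transition_times_ns=times)


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path,
                 format: str = "coord-table") -> None:
    """Persist a bundle: per-replica trajectory files, hidden labels, and
    the ground truth as JSON run metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo = bundle.ensemble.topology
    for rep in bundle.ensemble.replica_ids:
        xyz = bundle.ensemble.coords[rep]
        if format == "multi-model-pdb":
            write_trajectory_pdb(out / f"{rep}.pdb", topo, xyz)
        elif format == "coord-table":
            write_coord_table(out / f"{rep}.csv", topo, xyz)
        else:
            raise ValueError(f"unknown format {format!r}")
    rows = [{"replica": rep, "frame": i, "microstate": int(lab)}
            for rep in bundle.ensemble.replica_ids
            for i, lab in enumerate(bundle.hidden_labels[rep])]
    write_table(rows, out / "labels.csv", "state-sequence")
    write_run_metadata(out / "truth.json", {
        "seed": bundle.spec.seed,
        "n_states": bundle.spec.n_states,
        "state_names": list(bundle.spec.state_names),
        "dt_ns": bundle.spec.dt_ns,
        "transition_matrix": bundle.spec.transition_matrix,
        "stationary_distribution": bundle.true_pi,
        "slowest_timescale_ns": bundle.true_slowest_timescale_ns,
        "transition_times_ns": {f"{a}->{b}": v for (a, b), v in
                                bundle.true_transition_times_ns.items()},
    })


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """How well the full pipeline recovered the planted kinetics."""

    purity: float
    macro_to_true: np.ndarray
    lumped_transition_matrix: np.ndarray   # reordered to true-state ids
    lumped_pi: np.ndarray
    pi_l1_error: float
    max_row_l1_error: float
    slowest_timescale_ns: float
    true_slowest_timescale_ns: float
    timescale_rel_error: float
    transition_time_rel_errors: dict[tuple[int, int], float]
    median_time_rel_error: float

    def as_dict(self) -> dict:
        return {
            "purity": self.purity,
            "pi_l1_error": self.pi_l1_error,
            "max_row_l1_error": self.max_row_l1_error,
            "timescale_rel_error": self.timescale_rel_error,
            "median_time_rel_error": self.median_time_rel_error,
        }


def recovery_report(bundle: SyntheticBundle, n_microstates: int = 40,
                    lag_frames: int = 1, seed: int | None = None
                    ) -> RecoveryReport:
    """Run the full pipeline on a bundle and score it against the truth.

    Stages: k-centers microstates under fitted CA RMSD -> reversible MSM at
    ``lag_frames`` -> slowest implied timescale -> PCCA lumping into the true
    macrostate count -> best label matching (Hungarian assignment) for purity
    -> re-estimated 4x4 macrostate matrix -> TPT transition times, each
    compared with the planted ground truth.
    """
    spec = bundle.spec
    ens = bundle.ensemble
    clustering = msm.kcenters_cluster(ens, n_microstates, seed=seed)
    model = msm.estimate_msm(clustering.by_replica, lag_frames, dt_ns=ens.dt_ns)
    est_ts = float(model.timescales(1)[0])

    lump = msm.pcca_macrostates(model.transition_matrix,
                                model.stationary_distribution, spec.n_states)
    micro_to_macro = _full_micro_to_macro(clustering, model, lump, ens)
    macro_frames = {rep: micro_to_macro[a]
                    for rep, a in clustering.by_replica.items()}

    hidden = bundle.stacked_labels()
    macro_stacked = np.concatenate([macro_frames[r] for r in ens.replica_ids])
    confusion = np.zeros((spec.n_states, spec.n_states))
    np.add.at(confusion, (macro_stacked, hidden), 1)
    rows, cols = linear_sum_assignment(-confusion)
    macro_to_true = np.empty(spec.n_states, dtype=int)
    macro_to_true[rows] = cols
    purity = float(confusion[rows, cols].sum() / confusion.sum())

    relabeled = {rep: macro_to_true[m] for rep, m in macro_frames.items()}
    lumped = msm.estimate_msm(relabeled, lag_frames, dt_ns=ens.dt_ns)
    if lumped.n_states != spec.n_states:
        raise ValueError("lumped model lost macrostates after trimming")
    order = np.argsort(lumped.active_set)
    t_lump = lumped.transition_matrix[np.ix_(order, order)]
    pi_lump = lumped.stationary_distribution[order]

    t_true = spec.transition_matrix
    # compare like with like: the truth propagated to the analysis lag
    t_ref = np.linalg.matrix_power(t_true, lag_frames)
    pi_l1 = float(np.abs(pi_lump - bundle.true_pi).sum())
    row_l1 = float(np.abs(t_lump - t_ref).sum(axis=1).max())
    ts_rel = abs(est_ts - bundle.true_slowest_timescale_ns) \
        / bundle.true_slowest_timescale_ns

    est_times = tpt.pairwise_transition_times(t_lump, lumped.lag_ns)
    rel_errors = {}
    for pair, true_t in bundle.true_transition_times_ns.items():
        est_t = est_times.get(pair, np.inf)
        if np.isfinite(true_t):
            rel_errors[pair] = abs(est_t - true_t) / true_t
    median_err = float(np.median(list(rel_errors.values())))
    return RecoveryReport(
        purity=purity, macro_to_true=macro_to_true,
        lumped_transition_matrix=t_lump, lumped_pi=pi_lump,
        pi_l1_error=pi_l1, max_row_l1_error=row_l1,
        slowest_timescale_ns=est_ts,
        true_slowest_timescale_ns=bundle.true_slowest_timescale_ns,
        timescale_rel_error=float(ts_rel),
        transition_time_rel_errors=rel_errors,
        median_time_rel_error=median_err)


def _full_micro_to_macro(clustering: msm.KCentersResult,
                         model: msm.MarkovStateModel,
                         lump: msm.MacrostateAssignment,
                         ens: TrajectoryEnsemble) -> np.ndarray:
    """Macrostate of every microstate, assigning microstates outside the
    active set to the macrostate of the closest active center (by fitted
    CA RMSD between the center conformations)."""
    k = len(clustering.center_indices)
    out = np.full(k, -1, dtype=int)
    out[model.active_set] = lump.labels
    missing = np.flatnonzero(out < 0)
    if missing.size:
        ca = ens.topology.ca_indices()
        stacked, _ = ens.stacked(ca)
        centers = stacked[clustering.center_indices]
        for m in missing:
            d = geometry.rmsd_batch(centers[model.active_set], centers[m])
            out[m] = lump.labels[int(np.argmin(d))]
    return out
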
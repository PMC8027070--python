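"""Structural order parameters and conformational state classification.

Implements the geometric observables used to characterize class B GPCR
ensembles: the extracellular-domain (ECD) tilt angle theta (angle between the
summed backbone carbonyl C->O vector of the N-terminal helix and the membrane
normal), mass-weighted backbone center-of-mass distances between residue
groups (ECD-7TM, ECD-ECL1, ECD-ECL3), least-squares superposition and
C-alpha RMSD, inter-helix contact counting, and the mapping of each frame's
(theta, d) pair onto the closed / semi-open / open / intermediate /
ECD-unrestricted / on-side state vocabulary.

The membrane normal is taken as +z of the input frame; frames from
arbitrarily oriented sources should be superposed onto a membrane-oriented
reference first (``compute_order_parameters(..., align=True)`` does this).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import ResidueGroup, StructureFrame, TrajectoryEnsemble, logger

STATE_LABELS = ("closed", "semi-open", "open", "intermediate",
                "ECD-unrestricted", "on-side")


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None
           ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing
    ``|| (mobile @ R.T + t) - reference ||`` in the least-squares sense.

    Raises on mismatched atom counts, fewer than 3 atoms, or (near-)collinear
    selections, for which the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mismatched atom counts for superposition")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(0)
    rc = (w[:, None] * reference).sum(0)
    m = mobile - mc
    r = reference - rc
    sv_m = np.linalg.svd(m * np.sqrt(w)[:, None], compute_uv=False)
    if sv_m[1] < 1e-8 * max(sv_m[0], 1.0):
        raise ValueError("degenerate (collinear) selection for superposition")
    h = (w[:, None] * m).T @ r
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def superpose_kabsch(mobile: StructureFrame, reference: StructureFrame,
                     selection: ResidueGroup | None = None
                     ) -> tuple[np.ndarray, np.ndarray, StructureFrame]:
    """Superpose ``mobile`` onto ``reference`` over ``selection`` (all atoms
    if None); returns (rotation, translation, transformed copy)."""
    if selection is None:
        idx_m = np.arange(mobile.n_atoms)
        idx_r = np.arange(reference.n_atoms)
    else:
        idx_m = selection.resolve(mobile)
        idx_r = selection.resolve(reference)
    rot, trans = kabsch(mobile.coord[idx_m], reference.coord[idx_r])
    moved = mobile.with_coord(mobile.coord @ rot.T + trans)
    return rot, trans, moved


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray, fit: bool = True) -> float:
    """RMSD between two conformations, optionally after optimal superposition."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched atom counts")
    if a.shape[0] == 0:
        raise ValueError("zero atoms")
    if fit and a.shape[0] >= 3:
        return float(rmsd_batch(a[None], b, fit=True)[0])
    if fit:
        a = a - a.mean(0)
        b = b - b.mean(0)
        if a.shape[0] == 1:
            return 0.0
        # 2 points: optimal rotation aligns the segment directions exactly
        na, nb = np.linalg.norm(a[1] - a[0]), np.linalg.norm(b[1] - b[0])
        return float(abs(na - nb) / 2.0)
    return float(np.sqrt(((a - b) ** 2).sum(-1).mean()))


def rmsd_batch(coords: np.ndarray, reference: np.ndarray,
               fit: bool = True) -> np.ndarray:
    """RMSD of each frame in ``coords`` (F, n, 3) to ``reference`` (n, 3).

    The fitted branch uses the covariance/SVD identity
    ``min_R ||A R - B||^2 = tr(A'A) + tr(B'B) - 2 (s1 + s2 +/- s3)``,
    batched over frames, so k-centers clustering over 1e5 frames stays
    vectorized end to end.
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    n = reference.shape[0]
    if not fit:
        return np.sqrt(((coords - reference) ** 2).sum(-1).mean(-1))
    c = coords - coords.mean(axis=1, keepdims=True)
    r = reference - reference.mean(0)
    ga = (c ** 2).sum(axis=(1, 2))
    gb = (r ** 2).sum()
    h = np.einsum("fni,nj->fij", c, r)
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.sign(np.linalg.det(h))
    sign[sign == 0] = 1.0
    traces = s[:, 0] + s[:, 1] + sign * s[:, 2]
    msd = np.maximum(ga + gb - 2.0 * traces, 0.0) / n
    return np.sqrt(msd)


def rmsd_ca(frame_a: StructureFrame, frame_b: StructureFrame,
            fit: bool = True) -> float:
    """C-alpha RMSD between two frames (the microstate clustering metric)."""
    ia, ib = frame_a.ca_indices(), frame_b.ca_indices()
    if ia.size == 0 or ib.size == 0:
        raise ValueError("zero atoms: no CA atoms in frame")
    if ia.size != ib.size:
        raise ValueError("mismatched CA counts")
    return rmsd(frame_a.coord[ia], frame_b.coord[ib], fit=fit)


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

def group_com(frame: StructureFrame, group: ResidueGroup) -> np.ndarray:
    idx = group.resolve(frame)
    w = frame.mass[idx]
    return (w[:, None] * frame.coord[idx]).sum(0) / w.sum()


def group_com_distance(frame: StructureFrame, group_a: ResidueGroup,
                       group_b: ResidueGroup) -> float:
    """Distance between the mass-weighted (backbone) COMs of two groups, A."""
    return float(np.linalg.norm(group_com(frame, group_a)
                                - group_com(frame, group_b)))


def helix_tilt_angle(frame: StructureFrame, helix_residues: ResidueGroup,
                     axis: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Tilt of a helix: angle in [0, 180] deg between the sum of backbone
    carbonyl C->O vectors over the helix residues and ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    vec = np.zeros(3)
    for chain, res in helix_residues.members:
        ic = frame.atom_indices(chain, res, "C")
        io = frame.atom_indices(chain, res, "O")
        if ic.size != 1 or io.size != 1:
            raise ValueError(
                f"residue {chain}:{res} lacks backbone C/O atoms")
        vec += frame.coord[io[0]] - frame.coord[ic[0]]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise ValueError("zero-length summed carbonyl vector")
    cosang = np.clip(vec @ axis / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateDefinition:
    """One conformational state: a theta band combined with a d ceiling."""
    name: str
    theta_min: float  # exclusive lower bound when min_exclusive
    theta_max: float  # inclusive upper bound
    min_exclusive: bool = False


@dataclass(frozen=True)
class StateClassifier:
    """Total classifier over (theta, d, d_ECL1, d_ECL3).

    Precedence: d > ``d_unrestricted_max`` -> ECD-unrestricted; then the
    on-side rule (ECD-ECL1 COM distance at least ``onside_gap`` A shorter
    than ECD-ECL3); then theta bands; anything unmatched -> intermediate.
    The default bands put band edges midway between the point values
    (closed > 80 deg, semi-open ~60, open ~40).
    """

    d_unrestricted_max: float = 55.0
    onside_gap: float = 10.0
    bands: tuple[StateDefinition, ...] = (
        StateDefinition("closed", 80.0, 180.0, min_exclusive=True),
        StateDefinition("intermediate", 70.0, 80.0),
        StateDefinition("semi-open", 50.0, 70.0),
        StateDefinition("open", 30.0, 50.0),
    )

    def __post_init__(self):
        seen = []
        for b in self.bands:
            if not b.theta_min < b.theta_max:
                raise ValueError(f"degenerate theta band for {b.name!r}")
            for o in seen:
                lo, hi = max(b.theta_min, o.theta_min), min(b.theta_max, o.theta_max)
                if lo < hi:
                    raise ValueError(
                        f"overlapping theta bands {b.name!r}/{o.name!r}")
            seen.append(b)

    def classify(self, theta: float, d: float,
                 d_ecl1: float | None = None,
                 d_ecl3: float | None = None) -> str:
        if d > self.d_unrestricted_max:
            return "ECD-unrestricted"
        if (d_ecl1 is not None and d_ecl3 is not None
                and d_ecl3 - d_ecl1 >= self.onside_gap):
            return "on-side"
        for b in self.bands:
            lo_ok = theta > b.theta_min if b.min_exclusive else theta >= b.theta_min
            if lo_ok and (theta <= b.theta_max if b.min_exclusive
                          else theta < b.theta_max or
                          (b.theta_max == 180.0 and theta == 180.0)):
                return b.name
        return "intermediate"

    def classify_series(self, theta: np.ndarray, d: np.ndarray,
                        d_ecl1: np.ndarray | None = None,
                        d_ecl3: np.ndarray | None = None) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        d = np.asarray(d, dtype=float)
        out = np.full(theta.shape, "intermediate", dtype="U16")
        for b in self.bands:
            lo = theta > b.theta_min if b.min_exclusive else theta >= b.theta_min
            hi = (theta <= b.theta_max if b.min_exclusive or b.theta_max == 180.0
                  else theta < b.theta_max)
            out[lo & hi] = b.name
        if d_ecl1 is not None and d_ecl3 is not None:
            onside = (np.asarray(d_ecl3) - np.asarray(d_ecl1)) >= self.onside_gap
            out[onside] = "on-side"
        out[d > self.d_unrestricted_max] = "ECD-unrestricted"
        return out


def classify_state(theta: float, d: float, d_ecl1: float | None = None,
                   d_ecl3: float | None = None,
                   classifier: StateClassifier | None = None) -> str:
    """Assign one frame's order parameters to a conformational state label."""
    return (classifier or StateClassifier()).classify(theta, d, d_ecl1, d_ecl3)


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def count_contacts(frame: StructureFrame, group_a: ResidueGroup,
                   group_b: ResidueGroup, cutoff: float = 4.5) -> int:
    """Number of residue pairs (a in A, b in B) whose closest selected-atom
    distance is below ``cutoff`` (default 4.5 A over heavy atoms — a package
    choice; no canonical cutoff exists)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    shared = set(group_a.members) & set(group_b.members)
    if shared:
        raise ValueError(f"overlapping groups: {sorted(shared)[:5]}")
    ia, ib = group_a.resolve(frame), group_b.resolve(frame)
    dmat = cdist(frame.coord[ia], frame.coord[ib])
    key_a = [f"{c}|{r}" for c, r in
             zip(frame.chain_id[ia], frame.res_id[ia])]
    key_b = [f"{c}|{r}" for c, r in
             zip(frame.chain_id[ib], frame.res_id[ib])]
    df = pd.DataFrame({"a": np.repeat(key_a, len(ib)),
                       "b": np.tile(key_b, len(ia)),
                       "d": dmat.ravel()})
    mind = df.groupby(["a", "b"])["d"].min()
    return int((mind < cutoff).sum())


# ---------------------------------------------------------------------------
# Per-ensemble order-parameter pipeline
# ---------------------------------------------------------------------------

def _com_series(coords: np.ndarray, idx: np.ndarray, mass: np.ndarray
                ) -> np.ndarray:
    w = mass[idx]
    return np.einsum("fni,n->fi", coords[:, idx], w) / w.sum()


def compute_order_parameters(
        ensemble: TrajectoryEnsemble,
        groups: Mapping[str, ResidueGroup],
        helix: ResidueGroup,
        axis: Sequence[float] = (0.0, 0.0, 1.0),
        classifier: StateClassifier | None = None,
        align: bool = True,
        align_group: ResidueGroup | None = None,
        reference: StructureFrame | None = None) -> pd.DataFrame:
    """Per-frame theta, ECD-7TM / ECD-ECL1 / ECD-ECL3 COM distances and
    state labels for a whole ensemble.

    ``groups`` must name ``ecd`` and ``tm7``; ``ecl1``/``ecl3`` are optional
    (without them the on-side rule is never triggered). With ``align=True``
    every frame is first superposed (Kabsch over ``align_group``, default the
    7TM core) onto ``reference`` (default the first frame), which restores
    the membrane-frame z-axis for arbitrarily oriented trajectories;
    distances are rigid-invariant either way.
    """
    classifier = classifier or StateClassifier()
    for req in ("ecd", "tm7"):
        if req not in groups:
            raise KeyError(f"groups must define {req!r}")
    topo = ensemble.topology
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    reference = reference or ensemble.frame(ensemble.replica_ids[0], 0)
    fit_group = align_group or groups["tm7"]
    fit_idx = fit_group.resolve(topo)
    ref_fit = reference.coord[fit_group.resolve(reference)]
    ref_fit_c = ref_fit - ref_fit.mean(0)

    idx_ecd = groups["ecd"].resolve(topo)
    idx_tm7 = groups["tm7"].resolve(topo)
    idx_ecl1 = groups["ecl1"].resolve(topo) if "ecl1" in groups else None
    idx_ecl3 = groups["ecl3"].resolve(topo) if "ecl3" in groups else None
    ic, io = [], []
    for chain, res in helix.members:
        c_i = topo.atom_indices(chain, res, "C")
        o_i = topo.atom_indices(chain, res, "O")
        if c_i.size != 1 or o_i.size != 1:
            raise ValueError(f"helix residue {chain}:{res} lacks C/O atoms")
        ic.append(c_i[0])
        io.append(o_i[0])
    ic, io = np.array(ic), np.array(io)

    rows = []
    for rep in ensemble.replica_ids:
        xyz = ensemble.coords[rep]
        if align:
            xyz = _align_frames(xyz, fit_idx, ref_fit, ref_fit_c)
        carbonyl = (xyz[:, io] - xyz[:, ic]).sum(axis=1)
        norms = np.linalg.norm(carbonyl, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-length summed carbonyl vector")
        theta = np.degrees(np.arccos(np.clip(carbonyl @ axis / norms, -1, 1)))
        com_ecd = _com_series(xyz, idx_ecd, topo.mass)
        d = np.linalg.norm(com_ecd - _com_series(xyz, idx_tm7, topo.mass), axis=1)
        d1 = (np.linalg.norm(com_ecd - _com_series(xyz, idx_ecl1, topo.mass), axis=1)
              if idx_ecl1 is not None else np.full_like(d, np.nan))
        d3 = (np.linalg.norm(com_ecd - _com_series(xyz, idx_ecl3, topo.mass), axis=1)
              if idx_ecl3 is not None else np.full_like(d, np.nan))
        state = classifier.classify_series(
            theta, d,
            d1 if idx_ecl1 is not None else None,
            d3 if idx_ecl3 is not None else None)
        n = xyz.shape[0]
        rows.append(pd.DataFrame({
            "replica": rep, "frame": np.arange(n),
            "time_ns": np.arange(n) * ensemble.dt_ns,
            "theta_deg": theta, "d_ecd_7tm": d,
            "d_ecd_ecl1": d1, "d_ecd_ecl3": d3, "state": state}))
    out = pd.concat(rows, ignore_index=True)
    logger.info("order parameters computed for %d frames (%d replicas)",
                len(out), ensemble.n_replicas)
    return out


def _align_frames(xyz: np.ndarray, fit_idx: np.ndarray, ref_fit: np.ndarray,
                  ref_fit_c: np.ndarray) -> np.ndarray:
    """Batched Kabsch of every frame's fit selection onto the reference."""
    sel = xyz[:, fit_idx]
    mc = sel.mean(axis=1, keepdims=True)
    selc = sel - mc
    h = np.einsum("fni,nj->fij", selc, ref_fit_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", u, vt)))
    u[:, :, 2] *= d[:, None]
    rot = np.einsum("fij,fjk->fki", u, vt)  # (F,3,3), acts as coord @ rot.T
    centered = xyz - mc
    moved = np.einsum("fni,fji->fnj", centered, rot) + ref_fit.mean(0)
    return moved
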
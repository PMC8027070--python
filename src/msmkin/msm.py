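"""Markov state model construction and validation.

The microstate pipeline follows standard MSM practice: Gonzalez farthest-point
k-centers discretization under the fitted C-alpha RMSD metric, sliding-window
transition counting at a lag time tau (never across replica boundaries),
ergodic trimming to the largest strongly connected set, maximum-likelihood
estimation of a reversible transition matrix by self-consistent fixed-point
iteration on symmetric flows, implied-timescale scans for lag selection,
Chapman-Kolmogorov validation with bootstrap error bands, and classic
sign-structure PCCA lumping into metastable macrostates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import rmsd_batch
from .structio import TrajectoryEnsemble, logger


class NotConvergedError(RuntimeError):
    pass


class DisconnectedError(ValueError):
    pass


# ---------------------------------------------------------------------------
# k-centers clustering
# ---------------------------------------------------------------------------

@dataclass
class KCentersResult:
    center_indices: np.ndarray          # (k,) indices into the stacked frames
    assignments: np.ndarray             # (F,) microstate per stacked frame
    distances: np.ndarray               # (F,) distance to assigned center
    radii: np.ndarray                   # (k,) max distance within each cluster
    center_refs: list | None = None     # (replica, frame) provenance
    by_replica: dict | None = None      # replica -> (n_frames,) assignments

    @property
    def max_radius(self) -> float:
        return float(self.radii.max())


def kcenters(n_frames: int, dist_to: Callable[[int], np.ndarray], k: int,
             seed: int | None = None) -> KCentersResult:
    """Gonzalez greedy k-centers over an abstract metric.

    ``dist_to(i)`` must return the distances from frame ``i`` to every frame.
    The first center is frame 0 unless ``seed`` is given (seeded random
    start); each subsequent center is the frame farthest from all existing
    centers, ties broken toward the lowest frame index. This guarantees a
    maximum cluster radius within a factor 2 of the optimal k-center radius.
    """
    if not 1 <= k <= n_frames:
        raise ValueError(f"k={k} outside 1..{n_frames}")
    if seed is None:
        first = 0
    else:
        first = int(np.random.default_rng(seed).integers(n_frames))
    centers = [first]
    dmin = np.asarray(dist_to(first), dtype=float)
    assign = np.zeros(n_frames, dtype=int)
    for c in range(1, k):
        nxt = int(np.argmax(dmin))  # argmax returns the lowest tied index
        centers.append(nxt)
        d_new = np.asarray(dist_to(nxt), dtype=float)
        closer = d_new < dmin
        dmin = np.where(closer, d_new, dmin)
        assign[closer] = c
    radii = np.zeros(k)
    np.maximum.at(radii, assign, dmin)
    return KCentersResult(center_indices=np.asarray(centers),
                          assignments=assign, distances=dmin, radii=radii)


def kcenters_cluster(ensemble: TrajectoryEnsemble, k: int,
                     seed: int | None = None,
                     atom_indices: np.ndarray | None = None) -> KCentersResult:
    """k-centers microstate discretization of an ensemble under fitted
    C-alpha RMSD (the clustering metric of the MSM stage).

    ``atom_indices`` overrides the default C-alpha selection, e.g. to cluster
    on all backbone atoms.
    """
    if atom_indices is None:
        atom_indices = ensemble.topology.ca_indices()
        if atom_indices.size == 0:
            raise ValueError("topology has no CA atoms")
    stacked, refs = ensemble.stacked(atom_indices)
    # hot path: frames centered once, metric evaluated in single precision
    # (metric error ~1e-3 A, far below any physically meaningful cluster
    # radius; centers/assignments are index-valued so results stay exact)
    centered = (stacked - stacked.mean(axis=1, keepdims=True)).astype(np.float32)
    sqnorm = (centered ** 2).sum(axis=(1, 2))
    n_atoms = centered.shape[1]

    def dist_to(i: int) -> np.ndarray:
        h = np.einsum("fni,nj->fij", centered, centered[i])
        s = np.linalg.svd(h, compute_uv=False)
        sign = np.where(np.linalg.det(h) < 0, -1.0, 1.0)
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        msd = np.maximum(sqnorm + sqnorm[i] - 2.0 * trace, 0.0) / n_atoms
        return np.sqrt(msd)

    result = kcenters(stacked.shape[0], dist_to, k, seed=seed)
    result.center_refs = [refs[i] for i in result.center_indices]
    by_rep, pos = {}, 0
    for rep in ensemble.replica_ids:
        n = ensemble.n_frames(rep)
        by_rep[rep] = result.assignments[pos:pos + n]
        pos += n
    result.by_replica = by_rep
    logger.info("k-centers: k=%d over %d frames, max radius %.3f A",
                k, stacked.shape[0], result.max_radius)
    return result


# ---------------------------------------------------------------------------
# Transition counting and reversible estimation
# ---------------------------------------------------------------------------

def _as_sequences(assignments) -> list[np.ndarray]:
    if isinstance(assignments, Mapping):
        seqs = list(assignments.values())
    elif isinstance(assignments, np.ndarray) and assignments.ndim == 1:
        seqs = [assignments]
    else:
        seqs = list(assignments)
    return [np.asarray(s, dtype=int) for s in seqs]


def count_transitions(assignments, lag_frames: int, sliding: bool = True,
                      n_states: int | None = None) -> np.ndarray:
    """Count matrix C_ij of observed i -> j transitions at the given lag,
    summed over replicas, never across replica boundaries."""
    seqs = _as_sequences(assignments)
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    for s in seqs:
        if lag_frames >= len(s):
            raise ValueError(
                f"lag {lag_frames} not shorter than replica length {len(s)}")
    if n_states is None:
        n_states = max(int(s.max()) for s in seqs) + 1
    c = np.zeros((n_states, n_states), dtype=np.int64)
    for s in seqs:
        if sliding:
            src, dst = s[:-lag_frames], s[lag_frames:]
        else:
            src, dst = s[:-lag_frames:lag_frames], s[lag_frames::lag_frames]
        np.add.at(c, (src, dst), 1)
    return c


def largest_connected_set(c: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the transition
    graph (edges where C_ij > 0); ties broken toward the most counts."""
    n = c.shape[0]
    n_comp, labels = connected_components(csr_matrix(c > 0),
                                          directed=True, connection="strong")
    best, best_key = None, None
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        key = (members.size, int(c[np.ix_(members, members)].sum()),
               -int(members[0]))
        if best_key is None or key > best_key:
            best, best_key = members, key
    return best


def reversible_mle(c: np.ndarray, tol: float = 1e-10,
                   max_iter: int = 1_000_000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Reversible transition-matrix MLE on a strongly connected count matrix.

    Self-consistent fixed-point iteration on the symmetric flow variables
    x_ij = x_ji (x_ij proportional to pi_i T_ij at the optimum):

        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

    with c_i the row sums of C and x_i the row sums of x. Converged when the
    largest relative change of any x_ij falls below ``tol``. Returns the
    row-stochastic T and its stationary distribution pi.
    """
    c = np.asarray(c, dtype=float)
    if c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    if (c < 0).any() or not np.allclose(c, np.round(c)):
        raise ValueError("count matrix must hold non-negative integers")
    lcc = largest_connected_set(c)
    if lcc.size != c.shape[0]:
        raise DisconnectedError(
            f"count matrix not strongly connected: largest component has "
            f"{lcc.size}/{c.shape[0]} states")
    if tol <= 0:
        raise ValueError("tol must be positive")
    csym = c + c.T
    crow = c.sum(axis=1)
    x = csym / csym.sum()
    mask = csym > 0
    for _ in range(max_iter):
        xrow = x.sum(axis=1)
        denom = crow / xrow
        x_new = np.zeros_like(x)
        x_new[mask] = csym[mask] / (denom[:, None] + denom[None, :])[mask]
        x_new /= x_new.sum()
        delta = np.abs(x_new[mask] - x[mask]) / np.maximum(x[mask], 1e-300)
        x = x_new
        if delta.max() < tol:
            break
    else:
        raise NotConvergedError(
            f"reversible MLE did not converge in {max_iter} iterations")
    xrow = x.sum(axis=1)
    t = x / xrow[:, None]
    pi = xrow / xrow.sum()
    return t, pi


def eigensystem(t: np.ndarray, pi: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Real spectral decomposition of a reversible T via the symmetrized
    matrix D^{1/2} T D^{-1/2}; eigenvalues sorted descending.

    Returns (eigenvalues, left eigenvectors (rows), right eigenvectors
    (columns)); the first right eigenvector is constant, the first left one
    is pi.
    """
    sqrt_pi = np.sqrt(pi)
    s = sqrt_pi[:, None] * t / sqrt_pi[None, :]
    asym = np.abs(s - s.T).max()
    if asym > 1e-6:
        raise ValueError(
            f"transition matrix violates detailed balance (|S - S'| = "
            f"{asym:.2e}); eigenvalues may be complex")
    w, v = np.linalg.eigh((s + s.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    right = v / sqrt_pi[:, None]
    left = (v * sqrt_pi[:, None]).T
    # fix sign: make the stationary pair positive
    if right[0, 0] < 0:
        right[:, 0] *= -1
        left[0, :] *= -1
    return w, left, right


@dataclass
class MarkovStateModel:
    """Reversible MSM over the active (largest strongly connected) set."""

    transition_matrix: np.ndarray      # (m, m) row-stochastic, reversible
    stationary_distribution: np.ndarray
    count_matrix: np.ndarray           # full counts, all states
    active_set: np.ndarray             # original state ids of the active set
    lag_frames: int
    lag_ns: float
    eigenvalues: np.ndarray = field(init=False)
    left_eigenvectors: np.ndarray = field(init=False)
    right_eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self):
        w, l, r = eigensystem(self.transition_matrix,
                              self.stationary_distribution)
        self.eigenvalues, self.left_eigenvectors, self.right_eigenvectors = w, l, r

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def timescales(self, m: int | None = None) -> np.ndarray:
        """Implied timescales -tau / ln(lambda_i) in ns for the largest
        eigenvalues below 1; non-positive eigenvalues yield NaN."""
        if m is None:
            m = min(10, self.n_states - 1)
        lam = self.eigenvalues[1:m + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = np.where(lam > 0, -self.lag_ns / np.log(lam), np.nan)
        ts[lam >= 1.0] = np.inf
        return ts


def estimate_msm(assignments, lag_frames: int, dt_ns: float = 1.0,
                 tol: float = 1e-10, max_iter: int = 1_000_000
                 ) -> MarkovStateModel:
    """Count transitions, trim to the largest strongly connected set (frames
    outside it are reported, not silently dropped) and estimate the
    reversible MLE transition matrix."""
    c_full = count_transitions(assignments, lag_frames)
    active = largest_connected_set(c_full)
    if active.size < c_full.shape[0]:
        dropped = sorted(set(range(c_full.shape[0])) - set(active.tolist()))
        logger.warning(
            "ergodic trimming: %d of %d microstates outside the largest "
            "strongly connected set were removed: %s",
            len(dropped), c_full.shape[0], dropped[:20])
    c_active = c_full[np.ix_(active, active)]
    t, pi = reversible_mle(c_active, tol=tol, max_iter=max_iter)
    return MarkovStateModel(transition_matrix=t, stationary_distribution=pi,
                            count_matrix=c_full, active_set=active,
                            lag_frames=lag_frames, lag_ns=lag_frames * dt_ns)


# ---------------------------------------------------------------------------
# Implied timescales
# ---------------------------------------------------------------------------

@dataclass
class ImpliedTimescaleScan:
    lags_frames: np.ndarray
    lags_ns: np.ndarray
    timescales_ns: np.ndarray  # (n_lags, m), sorted descending per lag

    def is_flat(self, rel_tol: float = 0.2) -> bool:
        """Heuristic lag-selection check: slowest timescale flat across the
        scanned lags within ``rel_tol`` relative spread."""
        t1 = self.timescales_ns[:, 0]
        t1 = t1[np.isfinite(t1)]
        return bool(len(t1) and (t1.max() - t1.min()) / t1.mean() < rel_tol)


def implied_timescales(assignments, lags_frames: Sequence[int],
                       dt_ns: float = 1.0, m: int | None = None
                       ) -> ImpliedTimescaleScan:
    """Implied-timescale scan over a lag grid; used to pick the lag where
    the curves flatten (the Markovian regime)."""
    rows = []
    m_eff = m
    for lag in lags_frames:
        model = estimate_msm(assignments, lag, dt_ns=dt_ns)
        if model.n_states < 2:
            logger.warning("lag %d: single-state active set, no finite "
                           "timescale", lag)
            ts = np.full(m_eff or 1, np.nan)
        else:
            ts = model.timescales(m)
        if m_eff is None:
            m_eff = len(ts)
        row = np.full(m_eff, np.nan)
        row[:min(len(ts), m_eff)] = ts[:m_eff]
        rows.append(row)
    lags = np.asarray(list(lags_frames))
    return ImpliedTimescaleScan(lags_frames=lags, lags_ns=lags * dt_ns,
                                timescales_ns=np.vstack(rows))


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKResult:
    sets: list
    multiples: np.ndarray
    predicted: np.ndarray   # (n_sets, n_multiples) set persistence from T^n
    estimated: np.ndarray   # persistence from the model re-estimated at n*tau
    residual: np.ndarray    # |predicted - estimated|
    band: np.ndarray        # bootstrap error band on the estimate

    def within_band(self, scale: float = 1.0) -> np.ndarray:
        return self.residual <= scale * self.band


def _set_persistence(t: np.ndarray, pi: np.ndarray, active: np.ndarray,
                     members: np.ndarray) -> float:
    """pi-weighted probability of still being in the set after one step of t."""
    pos = {s: i for i, s in enumerate(active.tolist())}
    idx = np.array([pos[s] for s in members.tolist() if s in pos], dtype=int)
    if idx.size == 0:
        return np.nan
    w = pi[idx] / pi[idx].sum()
    return float(w @ t[np.ix_(idx, idx)].sum(axis=1))


def ck_test(assignments, base_lag: int, multiples: Sequence[int],
            sets: Sequence[Sequence[int]], dt_ns: float = 1.0,
            n_bootstrap: int = 100, seed: int = 0,
            band_sigma: float = 2.58) -> CKResult:
    """Chapman-Kolmogorov test: does T(tau)^n predict the model estimated
    directly at n*tau?

    For each microstate set S the persistence probability (stationary-weighted
    probability of remaining in S) is propagated with powers of the base-lag
    reversible T and compared with the value from a reversible MSM
    re-estimated at each multiple. Error bands are ``band_sigma`` times the
    bootstrap standard deviation of the direct estimate, obtained by
    resampling replicas with replacement (a single replica is split into 8
    contiguous segments first).
    """
    seqs = _as_sequences(assignments)
    sets = [np.asarray(s, dtype=int) for s in sets]
    if any(s.size == 0 for s in sets):
        raise ValueError("empty microstate set in CK test")
    multiples = np.asarray(list(multiples), dtype=int)
    base = estimate_msm(seqs, base_lag, dt_ns=dt_ns)
    t_pow = {1: base.transition_matrix}

    predicted = np.zeros((len(sets), len(multiples)))
    estimated = np.zeros_like(predicted)
    band = np.zeros_like(predicted)

    boot_seqs = seqs if len(seqs) >= 2 else _split_segments(seqs[0], 8)
    rng = np.random.default_rng(seed)

    for j, mult in enumerate(multiples):
        if mult not in t_pow:
            t_pow[mult] = np.linalg.matrix_power(base.transition_matrix, mult)
        direct = (base if mult == 1
                  else estimate_msm(seqs, base_lag * mult, dt_ns=dt_ns))
        boots = np.empty((n_bootstrap, len(sets)))
        for b in range(n_bootstrap):
            pick = rng.integers(len(boot_seqs), size=len(boot_seqs))
            try:
                bm = estimate_msm([boot_seqs[p] for p in pick],
                                  base_lag * mult, dt_ns=dt_ns)
                boots[b] = [_set_persistence(bm.transition_matrix,
                                             bm.stationary_distribution,
                                             bm.active_set, s) for s in sets]
            except (ValueError, DisconnectedError):
                boots[b] = np.nan
        for i, s in enumerate(sets):
            predicted[i, j] = _set_persistence(
                t_pow[mult], base.stationary_distribution, base.active_set, s)
            estimated[i, j] = _set_persistence(
                direct.transition_matrix, direct.stationary_distribution,
                direct.active_set, s)
            band[i, j] = band_sigma * np.nanstd(boots[:, i], ddof=1)
    residual = np.abs(predicted - estimated)
    return CKResult(sets=[s.tolist() for s in sets], multiples=multiples,
                    predicted=predicted, estimated=estimated,
                    residual=residual, band=band)


def _split_segments(seq: np.ndarray, n: int) -> list[np.ndarray]:
    edges = np.linspace(0, len(seq), n + 1).astype(int)
    return [seq[a:b] for a, b in zip(edges[:-1], edges[1:]) if b - a > 1]


# ---------------------------------------------------------------------------
# PCCA macrostate lumping
# ---------------------------------------------------------------------------

@dataclass
class MacrostateAssignment:
    n_macrostates: int
    labels: np.ndarray          # (m,) macrostate id per microstate
    populations: np.ndarray     # (n,) aggregate stationary probability

    def members(self, macro: int) -> np.ndarray:
        return np.flatnonzero(self.labels == macro)


def pcca_macrostates(t: np.ndarray, pi: np.ndarray, n: int
                     ) -> MacrostateAssignment:
    """Classic sign-structure Perron Cluster Cluster Analysis.

    Microstates are lumped by recursive bisection on the dominant right
    eigenvectors of the reversible T: for each eigenvector psi_2..psi_n the
    current cluster with the largest psi-spread is split at the sign change
    (or at the midpoint when one-signed, which makes the n = n_microstates
    limit the identity partition). Every microstate ends up assigned.
    """
    t = np.asarray(t, dtype=float)
    m = t.shape[0]
    if not 2 <= n <= m:
        raise ValueError(f"n={n} outside 2..{m}")
    w, _, right = eigensystem(t, np.asarray(pi, dtype=float))
    labels = np.zeros(m, dtype=int)
    next_label = 1
    for comp in range(1, n):
        psi = right[:, comp]
        spreads = [psi[labels == lab].max() - psi[labels == lab].min()
                   if (labels == lab).sum() > 1 else -1.0
                   for lab in range(next_label)]
        target = int(np.argmax(spreads))
        inside = labels == target
        vals = psi[inside]
        if vals.min() < 0.0 <= vals.max():
            split = psi >= 0.0
        else:
            split = psi >= (vals.min() + vals.max()) / 2.0
        labels[inside & split] = next_label
        next_label += 1
    # deterministic relabeling by first microstate index
    order = sorted(range(n), key=lambda lab: int(np.argmax(labels == lab)))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels])
    pops = np.array([pi[labels == lab].sum() for lab in range(n)])
    return MacrostateAssignment(n_macrostates=n, labels=labels,
                                populations=pops)
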
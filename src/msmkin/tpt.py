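"""Transition-path theory on Markov state models.

Given a transition matrix and disjoint source (A) and sink (B) microstate
sets: forward/backward committors, the gross and net reactive flux network,
iterative widest-path (bottleneck) pathway decomposition, and the
transition-time estimator used for the receptor ensembles — the lag time
divided by the minimum net flux along the dominant transition path (with the
total reactive flux available as an alternative denominator). Fluxes are
per-lag probabilities, so transition times carry the lag's physical units.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structio import logger


class NoReactiveFluxError(ValueError):
    pass


def stationary_distribution(t: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left Perron
    eigenvector, normalized)."""
    t = np.asarray(t, dtype=float)
    w, v = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _check_sets(n: int, a: Sequence[int], b: Sequence[int]):
    a = np.asarray(sorted(set(int(i) for i in a)), dtype=int)
    b = np.asarray(sorted(set(int(i) for i in b)), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("source and sink sets must be disjoint")
    if a.min() < 0 or a.max() >= n or b.min() < 0 or b.max() >= n:
        raise ValueError("set members outside the state space")
    return a, b


def committors(t: np.ndarray, a: Sequence[int], b: Sequence[int],
               pi: np.ndarray | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Forward committor q+ (probability of reaching B before A) and backward
    committor q- (probability of having come last from A), from the committor
    linear systems of T and of the time-reversed chain.

    Under detailed balance q- = 1 - q+; the general time-reversed route is
    used so non-reversible inputs are still handled correctly.
    """
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    a, b = _check_sets(n, a, b)
    q_plus = _forward_committor(t, a, b)
    if pi is None:
        pi = stationary_distribution(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rev = np.where(pi[:, None] > 0,
                         (t.T * pi[None, :]) / pi[:, None], 0.0)
    q_minus = _forward_committor(t_rev, b, a)  # reach A (backward) before B
    return q_plus, q_minus


def _forward_committor(t: np.ndarray, a: np.ndarray, b: np.ndarray
                       ) -> np.ndarray:
    n = t.shape[0]
    q = np.zeros(n)
    q[b] = 1.0
    inter = np.setdiff1d(np.arange(n), np.union1d(a, b))
    if inter.size:
        m = np.eye(inter.size) - t[np.ix_(inter, inter)]
        rhs = t[np.ix_(inter, b)].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular committor system: some intermediate states cannot "
                "reach A or B") from err
    return np.clip(q, 0.0, 1.0)


@dataclass
class Pathway:
    states: list[int]
    bottleneck_flux: float


@dataclass
class FluxNetwork:
    """Reactive flux network between source set A and sink set B."""

    source: np.ndarray
    sink: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    pi: np.ndarray
    gross_flux: np.ndarray   # f_ij = pi_i q-_i T_ij q+_j, zero diagonal
    net_flux: np.ndarray     # f+_ij = max(0, f_ij - f_ji)
    total_flux: float        # reactive flux out of A

    def check_conservation(self, tol: float = 1e-10) -> float:
        """Max |inflow - outflow| of net flux over intermediate states."""
        inter = np.setdiff1d(np.arange(len(self.pi)),
                             np.union1d(self.source, self.sink))
        if inter.size == 0:
            return 0.0
        imbalance = self.net_flux[:, inter].sum(0) - self.net_flux[inter].sum(1)
        worst = float(np.abs(imbalance).max())
        if worst > tol:
            raise ValueError(f"net flux not conserved: imbalance {worst:.2e}")
        return worst


def reactive_flux(t: np.ndarray, a: Sequence[int], b: Sequence[int],
                  pi: np.ndarray | None = None) -> FluxNetwork:
    """Gross/net reactive flux and total A->B flux for the chain ``t``."""
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    a, b = _check_sets(n, a, b)
    if pi is None:
        pi = stationary_distribution(t)
    q_plus, q_minus = committors(t, a, b, pi=pi)
    gross = pi[:, None] * q_minus[:, None] * t * q_plus[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.clip(gross - gross.T, 0.0, None)
    outside = np.setdiff1d(np.arange(n), a)
    total = float(net[np.ix_(a, outside)].sum())
    return FluxNetwork(source=a, sink=b, q_plus=q_plus, q_minus=q_minus,
                       pi=pi, gross_flux=gross, net_flux=net,
                       total_flux=total)


def _widest_path(net: np.ndarray, a: np.ndarray, b: np.ndarray
                 ) -> tuple[list[int], float] | None:
    """Max-bottleneck path from any node of A to any node of B on the
    net-flux graph; deterministic lowest-index tie-breaking."""
    n = net.shape[0]
    bottleneck = np.full(n, -1.0)
    pred = np.full(n, -1, dtype=int)
    heap = []
    for s in a:
        bottleneck[s] = np.inf
        heapq.heappush(heap, (-np.inf, int(s)))
    done = np.zeros(n, dtype=bool)
    b_set = set(b.tolist())
    while heap:
        neg, u = heapq.heappop(heap)
        if done[u] or -neg < bottleneck[u]:
            continue
        done[u] = True
        if u in b_set:
            path = [u]
            while pred[path[-1]] != -1:
                path.append(pred[path[-1]])
            return path[::-1], float(bottleneck[u])
        for v in np.flatnonzero(net[u] > 0.0):
            cand = min(bottleneck[u], net[u, v])
            if cand > bottleneck[v]:
                bottleneck[v] = cand
                pred[v] = u
                heapq.heappush(heap, (-cand, int(v)))
    return None


def top_pathways(flux: FluxNetwork, n_paths: int | None = None,
                 flux_fraction: float = 1.0 - 1e-10) -> list[Pathway]:
    """Iterative bottleneck decomposition of the net-flux network.

    Repeatedly extracts the widest (maximum-bottleneck) A->B path, records
    its bottleneck flux and subtracts it along the path, until ``n_paths``
    paths are found or ``flux_fraction`` of the total reactive flux is
    accounted for. For reversible chains the decomposition is exhaustive:
    the bottleneck fluxes sum to the total reactive flux.
    """
    if flux.total_flux <= 0:
        raise NoReactiveFluxError("no reactive flux between source and sink")
    residual = flux.net_flux.copy()
    paths: list[Pathway] = []
    accounted = 0.0
    target = flux_fraction * flux.total_flux
    while n_paths is None or len(paths) < n_paths:
        found = _widest_path(residual, flux.source, flux.sink)
        if found is None:
            break
        nodes, bneck = found
        if bneck <= 0:
            break
        for u, v in zip(nodes[:-1], nodes[1:]):
            residual[u, v] -= bneck
        paths.append(Pathway(states=[int(s) for s in nodes],
                             bottleneck_flux=bneck))
        accounted += bneck
        if accounted >= target:
            break
    if not paths:
        raise NoReactiveFluxError("no pathway connects source to sink")
    return paths


@dataclass
class TransitionTimeReport:
    """Transition time between two state sets: lag / (minimum net flux)."""

    source: list[int]
    sink: list[int]
    time_ns: float
    lag_ns: float
    min_net_flux: float         # per-lag probability used as denominator
    mode: str                   # "dominant" (bottleneck of top path) | "total"
    dominant_path: list[int] | None = None


def transition_time(flux: FluxNetwork, lag_ns: float,
                    mode: str = "dominant") -> TransitionTimeReport:
    """Time to complete one A->B transition: the lag time divided by the
    minimum net flux in the transition path.

    ``mode="dominant"`` (default) reads the minimum net flux as the
    bottleneck flux of the first-extracted (widest) pathway; ``mode="total"``
    divides by the total reactive flux instead. Both are physically sensible
    readings and both are reported by the pipeline.
    """
    if lag_ns <= 0:
        raise ValueError("lag_ns must be positive")
    if mode == "dominant":
        top = top_pathways(flux, n_paths=1)[0]
        denom, path = top.bottleneck_flux, top.states
    elif mode == "total":
        denom, path = flux.total_flux, None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if denom <= 0:
        raise NoReactiveFluxError("no reactive flux")
    return TransitionTimeReport(source=flux.source.tolist(),
                                sink=flux.sink.tolist(),
                                time_ns=lag_ns / denom, lag_ns=lag_ns,
                                min_net_flux=denom, mode=mode,
                                dominant_path=path)


def pairwise_transition_times(t: np.ndarray, lag_ns: float,
                              sets: Sequence[Sequence[int]] | None = None,
                              mode: str = "dominant"
                              ) -> dict[tuple[int, int], float]:
    """Transition times between all ordered pairs of state sets (each state
    its own set by default). Pairs with no reactive flux map to inf."""
    t = np.asarray(t, dtype=float)
    if sets is None:
        sets = [[i] for i in range(t.shape[0])]
    pi = stationary_distribution(t)
    out: dict[tuple[int, int], float] = {}
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i == j:
                continue
            try:
                fl = reactive_flux(t, a, b, pi=pi)
                out[(i, j)] = transition_time(fl, lag_ns, mode=mode).time_ns
            except (NoReactiveFluxError, np.linalg.LinAlgError):
                out[(i, j)] = np.inf
    return out
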
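"""Free-energy surfaces, barriers, and binding thermodynamics.

Free-energy maps are Boltzmann inversions of conformational density over a
pair of order parameters, F = -RT ln(rho / rho_max), so the most occupied bin
sits at F = 0 and empty bins are masked. Barriers between basins are the
minimax path value over the 4-connected occupied-bin graph (the operational
reading of a saddle height on a 2D map). Binding affinities interconvert
with free energies via dG_b = RT ln K_d at the 1 M standard state; MM-GBSA
style per-replica totals and per-frame per-residue decompositions (computed
by an external energy engine) are aggregated here, never evaluated.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Gas constant in kcal / (mol K).
R_KCAL_PER_MOL_K = 1.98720e-3


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """2D binned density with Boltzmann-inverted free energies (kcal/mol).

    ``free_energy`` is NaN on empty bins; occupied bins satisfy F >= 0 with
    the minimum exactly 0 at the densest bin.
    """

    counts: np.ndarray
    free_energy: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature_k: float
    x_label: str = "x"
    y_label: str = "y"

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_table(self) -> pd.DataFrame:
        ix, iy = np.meshgrid(np.arange(self.counts.shape[0]),
                             np.arange(self.counts.shape[1]), indexing="ij")
        return pd.DataFrame({
            "x_index": ix.ravel(), "y_index": iy.ravel(),
            "x_center": self.x_centers[ix.ravel()],
            "y_center": self.y_centers[iy.ravel()],
            "count": self.counts.ravel().astype(int),
            "free_energy_kcal_mol": self.free_energy.ravel()})


def fes_from_density(x: np.ndarray, y: np.ndarray,
                     bins: tuple[int, int] = (36, 30),
                     range_: tuple[tuple[float, float], tuple[float, float]]
                     = ((0.0, 180.0), (20.0, 80.0)),
                     temperature_k: float = 310.0,
                     x_label: str = "theta_deg",
                     y_label: str = "d_ecd_7tm") -> FreeEnergySurface:
    """Free-energy map from conformation density over an order-parameter
    pair; defaults bin (theta, d) on [0, 180] deg x [20, 80] A."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need >= 1 paired samples")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    counts, xe, ye = np.histogram2d(x, y, bins=bins, range=range_)
    if counts.sum() == 0:
        raise ValueError("all samples fall outside the bin range")
    rt = R_KCAL_PER_MOL_K * temperature_k
    with np.errstate(divide="ignore"):
        f = -rt * np.log(counts / counts.max())
    f[counts == 0] = np.nan
    return FreeEnergySurface(counts=counts, free_energy=f, x_edges=xe,
                             y_edges=ye, temperature_k=temperature_k,
                             x_label=x_label, y_label=y_label)


def _as_bin_mask(surface: FreeEnergySurface, region) -> np.ndarray:
    shape = surface.counts.shape
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != shape:
            raise ValueError("basin mask shape mismatch")
        return region
    mask = np.zeros(shape, dtype=bool)
    for i, j in np.atleast_2d(region):
        mask[int(i), int(j)] = True
    return mask


def barrier_between(surface: FreeEnergySurface, basin_a, basin_b) -> float:
    """Barrier from basin A to basin B in kcal/mol.

    Computed as the minimax path value over the 4-connected graph of
    occupied bins (minimize, over paths, the maximum free energy touched)
    minus the free-energy minimum of basin A; masked (empty) bins are
    impassable. Raises if either basin has no occupied bins or the basins
    are disconnected through occupied bins.
    """
    mask_a = _as_bin_mask(surface, basin_a) & surface.occupied
    mask_b = _as_bin_mask(surface, basin_b) & surface.occupied
    if not mask_a.any() or not mask_b.any():
        raise ValueError("basin has no occupied bins")
    f = surface.free_energy
    nx, ny = f.shape
    best = np.full((nx, ny), np.inf)
    heap = []
    for i, j in zip(*np.nonzero(mask_a)):
        best[i, j] = f[i, j]
        heapq.heappush(heap, (f[i, j], int(i), int(j)))
    while heap:
        val, i, j = heapq.heappop(heap)
        if val > best[i, j]:
            continue
        if mask_b[i, j]:
            return float(val - f[mask_a].min())
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and surface.occupied[ni, nj]:
                cand = max(val, f[ni, nj])
                if cand < best[ni, nj]:
                    best[ni, nj] = cand
                    heapq.heappush(heap, (cand, ni, nj))
    raise ValueError("basins are disconnected through occupied bins")


# ---------------------------------------------------------------------------
# Affinity <-> free energy
# ---------------------------------------------------------------------------

def delta_g_from_kd(kd_molar: float, temperature_k: float = 310.0) -> float:
    """Binding free energy dG_b = RT ln K_d (kcal/mol, 1 M standard state)."""
    if kd_molar <= 0 or temperature_k <= 0:
        raise ValueError("K_d and temperature must be positive")
    return R_KCAL_PER_MOL_K * temperature_k * float(np.log(kd_molar))


def kd_from_delta_g(delta_g_kcal: float, temperature_k: float = 310.0) -> float:
    """Inverse of :func:`delta_g_from_kd`; exact round trip."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(delta_g_kcal / (R_KCAL_PER_MOL_K * temperature_k)))


# ---------------------------------------------------------------------------
# Replica and per-residue aggregation
# ---------------------------------------------------------------------------

@dataclass
class ReplicaAggregate:
    mean: float
    sd: float     # sample (n-1) standard deviation, the error-bar convention
    n: int


def aggregate_replicas(values: Sequence[float]) -> ReplicaAggregate:
    """Mean and sample standard deviation of per-replica binding energies
    (the five-replica averaging convention for MM-GBSA totals)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replica values")
    return ReplicaAggregate(mean=float(vals.mean()),
                            sd=float(vals.std(ddof=1)), n=vals.size)


@dataclass
class DecompositionSummary:
    table: pd.DataFrame          # residue, mean_kcal_mol, rank
    conserved: bool | None       # None when no total column was supplied
    max_total_deviation: float


def per_residue_summary(energy_table: pd.DataFrame,
                        window: slice | tuple | None = None,
                        total_column: str = "total",
                        conservation_tol: float = 1e-6
                        ) -> DecompositionSummary:
    """Time-averaged per-residue free-energy decomposition.

    ``energy_table`` has one row per frame and one column per residue
    (kcal/mol), optionally a ``total`` column against which the additivity
    of the decomposition is checked. ``window`` restricts the frames:
    a slice, or ``("last", n)`` for the final n frames (the convention of
    averaging over the tail of the trajectory). The result is ranked with
    the strongest (most negative) contributors first.
    """
    df = pd.DataFrame(energy_table)
    if window is None:
        win = df
    elif isinstance(window, slice):
        win = df.iloc[window]
    elif isinstance(window, tuple) and window[0] == "last":
        win = df.iloc[-int(window[1]):]
    else:
        raise ValueError(f"unsupported window spec {window!r}")
    if len(win) == 0:
        raise ValueError("empty frame window")
    residue_cols = [c for c in win.columns if c != total_column]
    conserved, max_dev = None, 0.0
    if total_column in win.columns:
        dev = (win[residue_cols].sum(axis=1) - win[total_column]).abs()
        max_dev = float(dev.max())
        conserved = bool(max_dev <= conservation_tol)
    means = win[residue_cols].mean(axis=0)
    out = pd.DataFrame({"residue": residue_cols,
                        "mean_kcal_mol": means.to_numpy(dtype=float)})
    out = out.sort_values("mean_kcal_mol", kind="stable",
                          ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return DecompositionSummary(table=out, conserved=conserved,
                                max_total_deviation=max_dev)
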
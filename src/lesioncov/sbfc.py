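"""Seed-based functional connectivity (SBFC) from low-rank connectome loadings.

A dense functional connectome is represented by its principal-component
loadings (voxels x c); functional connectivity between two voxels is the
inner product of their unit-normalized (optionally eigenvalue-weighted)
loading rows.  For each subcortical seed voxel, the cortical connectivity map
is Fisher z-transformed, smoothed, and correlated with a lesion covariance
network's cortical values; significance per seed comes from the network's
surrogate ensemble, and multiplicity over seeds is handled by permutation-
style cluster-level family-wise-error correction on the surrogate null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .grids import BrainMap, ValidationError, VoxelGrid, smooth
from .nulls import SurrogateEnsemble

logger = logging.getLogger(__name__)

ATANH_EPS = 1e-7


@dataclass
class ConnectomeComponents:
    """Low-rank loadings approximating a dense functional connectome.

    ``loadings`` rows span cortex and subcortical grey matter (the ``domain``
    mask); ``weights`` are per-component scales (eigenvalue-like).  With
    ``weighted`` on (default) rows are scaled by the weights before unit
    normalization.
    """

    grid: VoxelGrid
    domain: str
    loadings: np.ndarray           # voxels x c
    weights: np.ndarray | None = None
    weighted: bool = True

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape[0] != self.grid.n_voxels(self.domain):
            raise ValidationError("loadings row count != domain voxel count")
        if self.loadings.shape[1] < 1:
            raise ValidationError("need at least one component")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    def _rows(self) -> np.ndarray:
        L = self.loadings
        if self.weighted and self.weights is not None:
            L = L * self.weights[None, :]
        return L

    def unit_rows(self) -> np.ndarray:
        L = self._rows()
        nrm = np.linalg.norm(L, axis=1, keepdims=True)
        out = np.zeros_like(L)
        nz = nrm[:, 0] > 0
        out[nz] = L[nz] / nrm[nz]
        return out

    def domain_positions(self, mask_name: str) -> np.ndarray:
        """Row positions of ``mask_name`` voxels within the loading domain."""
        dom = self.grid.mask_indices(self.domain)
        sub = self.grid.mask_indices(mask_name)
        pos = np.searchsorted(dom, sub)
        if not np.array_equal(dom[pos], sub):
            raise ValidationError(f"mask {mask_name!r} not contained in {self.domain!r}")
        return pos


def seed_map(cc: ConnectomeComponents, seed_position: int,
             cortex_positions: np.ndarray,
             unit_rows: np.ndarray | None = None) -> np.ndarray:
    """Connectivity of one seed row with every cortical row.

    Values are inner products of unit rows (correlations of the low-rank
    connectome), clipped away from +/-1 so the Fisher transform is finite.
    ``unit_rows`` lets scans over many seeds reuse one normalization pass.
    """
    U = cc.unit_rows() if unit_rows is None else unit_rows
    srow = U[seed_position]
    if not np.any(srow):
        raise ValidationError("seed voxel has a zero loading row")
    r = U[cortex_positions] @ srow
    return np.clip(r, -1 + ATANH_EPS, 1 - ATANH_EPS)


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh transform; inputs must lie in (-1, 1)."""
    v = np.asarray(values, dtype=float)
    if np.any(np.abs(v) >= 1):
        raise ValidationError("fisher_z requires values strictly inside (-1, 1)")
    return np.arctanh(v)


@dataclass
class SeedCluster:
    voxel_positions: np.ndarray   # positions within the subcortical mask
    extent: int
    fwe_p: float
    peak_r: float


@dataclass
class SeedPMap:
    grid: VoxelGrid
    subcortical_mask: str
    r: np.ndarray                 # per-seed correlation with the LCN
    p: np.ndarray                 # per-seed uncorrected surrogate p
    voxel_alpha: float | None = None
    clusters: list[SeedCluster] = field(default_factory=list)
    null_r: np.ndarray | None = None   # seeds x N surrogate correlations

    def suprathreshold(self, voxel_alpha: float) -> np.ndarray:
        return self.p < voxel_alpha

    def r_map(self) -> BrainMap:
        return BrainMap(self.grid, self.subcortical_mask, self.r)

    def p_map(self) -> BrainMap:
        return BrainMap(self.grid, self.subcortical_mask, self.p)

    def cluster_label_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=np.int32)
        idx = self.grid.mask_indices(self.subcortical_mask)
        flat = vol.ravel()
        for ci, cl in enumerate(self.clusters, start=1):
            flat[idx[cl.voxel_positions]] = ci
        return vol


def _standardize_rows(M: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=1, keepdims=True)
    sd = Mc.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return Mc / sd


def seed_scan(
    cc: ConnectomeComponents,
    lcn_cortex: BrainMap,
    ensemble: SurrogateEnsemble,
    fwhm_mm: float = 5.0,
    cortex_mask: str = "cortex",
    subcortical_mask: str = "subcortical",
) -> SeedPMap:
    """Scan every subcortical seed for correspondence with one LCN.

    Per seed: low-rank connectivity map over cortex -> Fisher z -> Gaussian
    smoothing (``fwhm_mm``) -> Pearson r with the LCN's cortical values.  The
    LCN's surrogate ensemble (built on the same cortical domain) provides the
    one-sided null for every seed; the full seeds-x-surrogates correlation
    matrix is retained for the subsequent cluster-level correction.
    """
    if lcn_cortex.domain != cortex_mask:
        raise ValidationError("lcn_cortex must live on the cortex domain")
    if ensemble.values.shape[1] != lcn_cortex.values.size:
        raise ValidationError("ensemble domain differs from the LCN's cortical domain")
    grid = cc.grid
    cortex_pos = cc.domain_positions(cortex_mask)
    seed_pos = cc.domain_positions(subcortical_mask)
    n_seeds = seed_pos.size

    U = cc.unit_rows()
    maps = np.empty((n_seeds, cortex_pos.size))
    for i, sp in enumerate(seed_pos):
        z = fisher_z(seed_map(cc, sp, cortex_pos, unit_rows=U))
        maps[i] = smooth(BrainMap(grid, cortex_mask, z), fwhm_mm).values

    M = _standardize_rows(maps)
    V = M.shape[1]
    zl = _standardize_rows(lcn_cortex.values[None, :])[0]
    r_obs = M @ zl / V
    Zs = _standardize_rows(ensemble.values)
    null_r = M @ Zs.T / V                     # seeds x N
    p = (1 + (null_r >= r_obs[:, None]).sum(axis=1)) / (1 + ensemble.n)
    return SeedPMap(grid, subcortical_mask, r_obs, p, null_r=null_r)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValidationError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def _label_clusters(grid: VoxelGrid, mask_name: str, supra: np.ndarray,
                    structure: np.ndarray) -> list[np.ndarray]:
    vol = np.zeros(grid.shape, dtype=bool)
    idx = grid.mask_indices(mask_name)
    vol.ravel()[idx[supra]] = True
    labels, n = ndimage.label(vol, structure=structure)
    lab_at = labels.ravel()[idx]
    return [np.flatnonzero(lab_at == li) for li in range(1, n + 1)]


def cluster_fwe(
    pmap: SeedPMap,
    voxel_alpha: float = 0.001,
    cluster_alpha: float = 0.05,
    connectivity: int = 26,
) -> SeedPMap:
    """Cluster-level family-wise-error correction over subcortical seeds.

    Seeds with uncorrected p < ``voxel_alpha`` are formed into connected
    clusters.  The null distribution of maximum cluster extent treats each
    surrogate in turn as the "observed" map, ranking it against the remaining
    surrogates (leave-one-out), thresholding at the same ``voxel_alpha`` and
    recording the largest surviving cluster.  A cluster is retained when
    ``fwe_p = (1 + #{null max extent >= extent}) / (1 + N) < cluster_alpha``.
    """
    if not (0 < voxel_alpha < 1 and 0 < cluster_alpha < 1):
        raise ValidationError("alphas must lie in (0, 1)")
    if pmap.null_r is None:
        raise ValidationError("pmap lacks the surrogate correlation matrix")
    N = pmap.null_r.shape[1]
    if 1.0 / (1 + N) >= voxel_alpha:
        logger.warning(
            "voxel_alpha %g unattainable with %d surrogates (min p %.4g); "
            "no seed can pass", voxel_alpha, N, 1.0 / (1 + N))
    structure = _connectivity_structure(connectivity)

    supra = pmap.suprathreshold(voxel_alpha)
    observed = _label_clusters(pmap.grid, pmap.subcortical_mask, supra, structure)

    # leave-one-out null: count_ge[i, s] = #{t: null_r[i,t] >= null_r[i,s]}
    count_ge = rankdata(-pmap.null_r, axis=1, method="max")
    null_p = count_ge / N          # = (1 + (count_ge - 1)) / (1 + (N - 1))
    null_max = np.zeros(N, dtype=int)
    for s in range(N):
        comps = _label_clusters(pmap.grid, pmap.subcortical_mask,
                                null_p[:, s] < voxel_alpha, structure)
        if comps:
            null_max[s] = max(len(c) for c in comps)

    clusters = []
    for members in observed:
        extent = len(members)
        fwe_p = float((1 + np.sum(null_max >= extent)) / (1 + N))
        if fwe_p < cluster_alpha:
            clusters.append(SeedCluster(members, extent, fwe_p,
                                        float(np.max(pmap.r[members]))))
    clusters.sort(key=lambda c: -c.extent)
    return SeedPMap(pmap.grid, pmap.subcortical_mask, pmap.r, pmap.p,
                    voxel_alpha, clusters, pmap.null_r)
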
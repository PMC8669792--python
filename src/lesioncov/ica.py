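"""Spatial ICA of lesion cohorts.

The lesion stack (subjects x voxels, binary) is decomposed into ``k``
spatially independent components: voxels act as samples and subjects as
observations, mirroring how a subject-concatenated 4D volume is decomposed in
probabilistic ICA.  Each component yields a spatial z-map (the lesion
covariance network, LCN) and one score per subject (the mixing weight), and
subjects are grouped by their highest-scoring component.

z-scaling: the source estimate in data units is divided by a global residual
noise standard deviation — the variance left outside the k-dimensional
principal subspace — so map magnitudes behave like z-statistics for the
downstream mixture-model thresholding.  Sign convention: maps are flipped so
their skewness is nonnegative (lesion "activation" is positive).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .grids import BrainMap, LesionStack, ValidationError

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-stage seed below 2**31, derived from a master seed."""
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ICADecomposition:
    k: int
    z_maps: np.ndarray            # k x voxels
    subject_scores: np.ndarray    # subjects x k, unit-variance columns
    explained_variance: np.ndarray
    converged: bool
    seed: int
    grid: object = None
    domain: str = "brain"
    noise_sd: float = 1.0

    def z_map(self, j: int) -> BrainMap:
        return BrainMap(self.grid, self.domain, self.z_maps[j])


def decompose(stack: LesionStack, k: int, seed: int, max_restarts: int = 10) -> ICADecomposition:
    """Decompose a folded lesion stack into ``k`` spatial components.

    Voxel columns are mean-centred, reduced to ``k`` principal dimensions,
    and rotated by symmetric fixed-point ICA (log-cosh contrast) over the
    spatial dimension.  Deterministic for a fixed seed; up to
    ``max_restarts`` reruns with derived seeds on non-convergence (a still
    unconverged result is returned flagged, not raised).
    """
    X = np.asarray(stack.matrix, dtype=float)
    n, V = X.shape
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds subject count {n}")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValidationError("need at least k distinct lesion patterns")

    Xc = X - X.mean(axis=0)  # centre each voxel column
    # principal subspace over voxels-as-samples: eigendecompose the
    # subject-space covariance via thin SVD of Xc (n x V)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / V  # variance of each principal coordinate over voxels
    if k < len(eigvals):
        noise_var = float(np.mean(eigvals[k:]))
    else:
        noise_var = float(eigvals[-1])
    noise_sd = np.sqrt(max(noise_var, np.finfo(float).tiny))

    # whitened spatial sources of the principal subspace: k x V, unit variance
    Y = np.sqrt(V) * Vt[:k]

    if k == 1:
        S = Y.copy()
        converged = True
    else:
        S, converged = _fastica_rotate(Y, seed, max_restarts)

    # mixing in data units: Xc ~= A0 @ S with S rows unit-variance, orthogonal
    A0 = Xc @ S.T / V  # n x k
    amp = A0.std(axis=0, ddof=0)
    amp[amp == 0] = np.finfo(float).tiny
    scores = A0 / amp
    z_maps = S * amp[:, None] / noise_sd

    # sign convention: nonnegative skewness
    signs = np.where(skew(z_maps, axis=1) < 0, -1.0, 1.0)
    z_maps *= signs[:, None]
    scores *= signs[None, :]

    # order components by explained variance (mixing amplitude)
    order = np.argsort(-amp)
    z_maps = z_maps[order]
    scores = scores[:, order]
    expl = (amp**2)[order]

    return ICADecomposition(
        k=k,
        z_maps=z_maps,
        subject_scores=scores,
        explained_variance=expl,
        converged=converged,
        seed=seed,
        grid=stack.grid,
        domain="brain",
        noise_sd=noise_sd,
    )


def _fastica_rotate(Y: np.ndarray, seed: int, max_restarts: int) -> tuple[np.ndarray, bool]:
    """Symmetric FastICA rotation of pre-whitened k x V data."""
    k = Y.shape[0]
    for attempt in range(max_restarts + 1):
        rs = derive_seed(seed, f"fastica:{attempt}") if attempt else seed
        ica = FastICA(
            n_components=k,
            algorithm="parallel",
            fun="logcosh",
            whiten=False,
            max_iter=1000,
            tol=1e-6,
            random_state=rs,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            S = ica.fit_transform(Y.T).T  # k x V
            hit_limit = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if not hit_limit:
            return S, True
        logger.warning("FastICA did not converge (attempt %d); restarting", attempt)
    logger.warning("FastICA unconverged after %d restarts; returning flagged result", max_restarts)
    return S, False


# ---------------------------------------------------------------------------
# Group assignment


def assign_groups(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each subject to the component with the highest score.

    Returns 1-based group labels and an ambiguity margin (difference between
    the top two scores, in score-sd units) supporting the check that no
    subject loads strongly on several components at once.  Exact ties go to
    the lowest component index (logged).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    groups = np.argmax(scores, axis=1) + 1
    srt = np.sort(scores, axis=1)
    margin = srt[:, -1] - srt[:, -2] if scores.shape[1] > 1 else np.abs(scores[:, 0])
    n_tied = int(np.sum(margin == 0)) if scores.shape[1] > 1 else 0
    if n_tied:
        logger.info("%d subjects with exact score ties assigned to lowest index", n_tied)
    return groups, margin


# ---------------------------------------------------------------------------
# Cross-cohort component matching


@dataclass
class ComponentMatch:
    permutation: np.ndarray        # index into b for each component of a
    correlations: np.ndarray       # per matched pair
    p_values: np.ndarray | None = None
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)


def match_components(
    a: ICADecomposition,
    b: ICADecomposition,
    ensembles: list | None = None,
    method: str = "pearson",
) -> ComponentMatch:
    """Optimal pairing of two decompositions' components.

    The bijection maximizes total absolute spatial correlation (Hungarian
    assignment).  If surrogate ensembles for ``a``'s maps are supplied, each
    pair gets a one-sided non-parametric p-value on |r|.
    """
    from .nulls import _corr_many, correlate_values

    ka, kb = a.k, b.k
    R = np.empty((ka, kb))
    for i in range(ka):
        for j in range(kb):
            R[i, j] = correlate_values(a.z_maps[i], b.z_maps[j], method)
    rows, cols = linear_sum_assignment(-np.abs(R))
    rs = R[rows, cols]
    unmatched_a = [i for i in range(ka) if i not in set(rows)]
    unmatched_b = [j for j in range(kb) if j not in set(cols)]

    p_values = None
    if ensembles is not None:
        p_values = np.empty(len(rows))
        for idx, (i, j) in enumerate(zip(rows, cols)):
            null_r = np.abs(_corr_many(ensembles[i].values, b.z_maps[j], method))
            N = null_r.size
            p_values[idx] = (1 + np.sum(null_r >= abs(rs[idx]))) / (1 + N)

    perm = np.full(ka, -1, dtype=int)
    perm[rows] = cols
    return ComponentMatch(perm, rs, p_values, unmatched_a, unmatched_b)
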
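"""Synthetic lesion cohorts with known ground truth.

Every statistical structure the analysis assumes can be planted here and
recovered by the downstream stages:

* an ellipsoidal "brain" on a mirrorable voxel grid, with a cortical shell,
  a subcortical interior, and ``k`` anchor voxels on an inner "ventricle"
  arc — one anchor per latent source;
* ``k`` spatially disjoint source weight maps extending from their anchor
  toward the cortex; each subject draws a latent source class and a binary
  lesion as the top-occupancy excursion set of source + smoothed noise;
* clinical labels (grade, molecular subtype) drawn from per-source
  multinomials, and survival times with group-dependent hazards;
* connectivity maps mixing a source with autocorrelated noise at a known
  weight, plus streamline-density stand-ins;
* a low-rank connectome whose components embed each source's cortical
  pattern together with a paired subcortical node.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, label

from .grids import BrainMap, LesionMask, ValidationError, VoxelGrid
from .sbfc import ConnectomeComponents

# Study-scale defaults: cohort of ~240 subjects in three location groups.
DEFAULT_N_SUBJECTS = 240
DEFAULT_K = 3
DEFAULT_SHAPE = (24, 24, 24)
DEFAULT_VOXEL_MM = (4.0, 4.0, 4.0)
DEFAULT_OCCUPANCY = 0.06
DEFAULT_NOISE_SD = 0.6
DEFAULT_NOISE_FWHM_VOX = 2.0
DEFAULT_RIGHT_FRACTION = 0.3

# per-source P(grade): source 1 enriched for lower-grade tumours
GRADE_PROBS = {
    1: {"LGG": 0.70, "GBM": 0.30},
    2: {"LGG": 0.35, "GBM": 0.65},
    3: {"LGG": 0.45, "GBM": 0.55},
}
# per-source P(molecular subtype): source 1 enriched for IDH-mut/1p19q-codel
SUBTYPE_PROBS = {
    1: {"IDH-wt": 0.25, "IDH-mut/1p19q-codel": 0.45, "IDH-mut/1p19q-non-codel": 0.30},
    2: {"IDH-wt": 0.65, "IDH-mut/1p19q-codel": 0.10, "IDH-mut/1p19q-non-codel": 0.25},
    3: {"IDH-wt": 0.55, "IDH-mut/1p19q-codel": 0.15, "IDH-mut/1p19q-non-codel": 0.30},
}
# planted log hazard ratios vs group 3 (group 1 protective, HR 0.6)
DEFAULT_GROUP_LOG_HR = {1: float(np.log(0.6)), 2: 0.0, 3: 0.0}
DEFAULT_AGE_LOG_HR = 0.7
BASELINE_HAZARD_PER_MONTH = 0.035
CENSOR_HAZARD_PER_MONTH = 0.015


@dataclass
class GroundTruth:
    grid: VoxelGrid
    k: int
    source_maps: np.ndarray          # k x brain voxels, nonnegative weights
    anchors: np.ndarray              # k x 3 voxel indices
    node_centers: np.ndarray         # k x 3 paired subcortical node centres
    subject_sources: np.ndarray | None = None
    clinical_params: dict = field(default_factory=dict)
    connectivity_params: dict = field(default_factory=dict)

    def source_map(self, j: int, domain: str = "brain") -> BrainMap:
        if domain == "brain":
            return BrainMap(self.grid, "brain", self.source_maps[j])
        vol = BrainMap(self.grid, "brain", self.source_maps[j]).to_volume()
        return BrainMap.from_volume(self.grid, domain, vol)


def _ellipsoid_radius(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoid radius per voxel (1.0 at the brain surface)."""
    axes = [np.arange(s) - (s - 1) / 2.0 for s in shape]
    semi = [0.47 * s for s in shape]
    zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum((z / a) ** 2 for z, a in zip(zz, semi)))


def make_grid(shape=DEFAULT_SHAPE, voxel_mm=DEFAULT_VOXEL_MM, k: int = DEFAULT_K,
              seed: int = 0) -> VoxelGrid:
    """Build a mirrorable synthetic grid with brain/cortex/subcortical masks
    and ``k`` ventricle-arc anchor voxels (stored as the mask ``anchors``).

    The brain is an ellipsoid symmetric across the midline axis; the cortex
    is its outer shell, the subcortical mask an interior left-hemisphere
    band, and anchors sit on an inner arc with pairwise spacing >= 8 voxels.
    """
    if any(s < 16 for s in shape):
        raise ValidationError("shape must be at least 16 voxels per axis")
    r = _ellipsoid_radius(shape)
    brain = r <= 1.0
    cortex = (r > 0.72) & brain
    grid = VoxelGrid(tuple(shape), tuple(voxel_mm), midline_axis=0)
    left = np.indices(shape)[0] < shape[0] / 2.0

    center = (np.asarray(shape) - 1) / 2.0
    # anchors on an inner arc in the left hemisphere: vary the
    # anterior-posterior / inferior angles, fixed small lateral offset
    angles = np.linspace(-2.0, 2.0, k)
    arc_r = 0.22 * min(shape)
    anchors = []
    for th in angles:
        pos = center + np.array([
            -0.18 * shape[0],
            arc_r * np.sin(th),
            arc_r * np.cos(th) - 0.05 * shape[2],
        ])
        anchors.append(np.rint(pos).astype(int))
    anchors = np.array(anchors)

    # paired subcortical nodes sit partway between each anchor and the centre
    nodes = np.rint(center + 0.75 * (anchors - center)).astype(int)

    # subcortical mask: left-hemisphere band around the node depth, away from
    # the cortex shell
    sub = (r > 0.28) & (r <= 0.62) & left & ~cortex & brain
    grid.add_mask("brain", brain)
    grid.add_mask("cortex", cortex & brain)
    grid.add_mask("subcortical", sub)
    grid.add_mask("gray", (cortex & brain) | sub)
    anchor_mask = np.zeros(shape, dtype=bool)
    anchor_mask[tuple(anchors.T)] = True
    grid.add_mask("anchors", anchor_mask)
    node_mask = np.zeros(shape, dtype=bool)
    node_mask[tuple(nodes.T)] = True
    grid.add_mask("nodes", node_mask)
    grid._anchors = anchors
    grid._nodes = nodes
    return grid


def _source_field(grid: VoxelGrid, anchor: np.ndarray, target: np.ndarray,
                  sigma_vox: float) -> np.ndarray:
    """Gaussian weight around the segment anchor -> cortical target."""
    shape = grid.shape
    pts = np.indices(shape).reshape(3, -1).T.astype(float)
    a, b = anchor.astype(float), target.astype(float)
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0) if denom > 0 else np.zeros(len(pts))
    proj = a + t[:, None] * ab
    d2 = ((pts - proj) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma_vox**2)).reshape(shape)


def make_truth(shape=DEFAULT_SHAPE, voxel_mm=DEFAULT_VOXEL_MM, k: int = DEFAULT_K,
               seed: int = 0, source_sigma_vox: float = 2.6) -> GroundTruth:
    """Grid plus ``k`` disjoint source maps reaching from ventricle anchors
    into the cortical shell (half-max supports pairwise Dice <= 0.1)."""
    grid = make_grid(shape, voxel_mm, k, seed)
    anchors = grid._anchors
    center = (np.asarray(shape) - 1) / 2.0
    brain = grid.mask("brain")
    maps = []
    for a in anchors:
        # cortical target: push the anchor direction outward to radius ~0.88
        d = a - center
        d[0] = min(d[0], -1.0)  # stay in the left hemisphere
        d = d / np.linalg.norm(d)
        target = np.rint(center + d * 0.40 * min(shape)).astype(int)
        f = _source_field(grid, a, target, source_sigma_vox)
        maps.append(f[brain])
    sources = np.array(maps)
    sources /= sources.max(axis=1, keepdims=True)
    return GroundTruth(grid, k, sources, anchors, grid._nodes,
                       clinical_params={
                           "grade_probs": GRADE_PROBS,
                           "subtype_probs": SUBTYPE_PROBS,
                           "group_log_hr": DEFAULT_GROUP_LOG_HR,
                           "age_log_hr": DEFAULT_AGE_LOG_HR,
                       })


def sample_lesions(
    truth: GroundTruth,
    n: int = DEFAULT_N_SUBJECTS,
    occupancy: float = DEFAULT_OCCUPANCY,
    noise_sd: float = DEFAULT_NOISE_SD,
    noise_fwhm_vox: float = DEFAULT_NOISE_FWHM_VOX,
    right_fraction: float = DEFAULT_RIGHT_FRACTION,
    seed: int = 0,
    class_probs: np.ndarray | None = None,
    occupancy_spread: float = 0.6,
) -> list[LesionMask]:
    """Draw ``n`` binary lesions from the planted sources.

    Subject i draws a source class, adds smoothed Gaussian noise (relative
    sd ``noise_sd``) to the source weight map, keeps the top fraction of
    in-brain voxels, and prunes to the connected component containing the
    source anchor.  Lesion volumes vary across subjects, as tumour volumes
    do: the per-subject fraction is ``occupancy`` scaled by a lognormal
    factor (sigma ``occupancy_spread``).  A ``right_fraction`` of subjects
    is mirrored to the right hemisphere to exercise folding.
    """
    if not 0 < occupancy < 0.5:
        raise ValidationError("occupancy must be in (0, 0.5)")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    brain = grid.mask("brain")
    k = truth.k
    probs = np.full(k, 1.0 / k) if class_probs is None else np.asarray(class_probs)
    classes = rng.choice(k, size=n, p=probs)
    truth.subject_sources = classes + 1
    sigma = noise_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    n_brain = int(brain.sum())
    if occupancy_spread > 0:
        q_i = occupancy * np.exp(rng.normal(0.0, occupancy_spread, size=n))
        q_i = np.clip(q_i, occupancy / 4, min(4 * occupancy, 0.49))
    else:
        q_i = np.full(n, occupancy)
    masks = []
    source_vols = [truth.source_map(j).to_volume() for j in range(k)]
    for i in range(n):
        c = classes[i]
        for attempt in range(6):
            field3d = source_vols[c]
            if noise_sd > 0:
                noise = gaussian_filter(rng.standard_normal(grid.shape), sigma)
                noise /= max(noise[brain].std(), 1e-12)
                field3d = field3d + noise_sd * noise
            n_keep = max(int(round(q_i[i] * n_brain)), 1)
            vals = field3d[brain]
            cut = np.partition(vals, -n_keep)[-n_keep]
            lesion = np.zeros(grid.shape, dtype=np.uint8)
            lesion[brain] = (vals >= cut).astype(np.uint8)
            labels, nlab = label(lesion)
            if nlab == 0:
                continue
            keep_lab = labels[tuple(truth.anchors[c])]
            if keep_lab == 0:
                # anchor voxel itself dipped below threshold; keep the
                # component carrying the most source weight instead
                weight = np.bincount(labels.ravel(), weights=source_vols[c].ravel())
                keep_lab = int(np.argmax(weight[1:])) + 1
            lesion = (labels == keep_lab).astype(np.uint8)
            break
        else:
            raise ValidationError(f"subject {i}: pruning emptied the lesion repeatedly")
        hemi = "left"
        if rng.random() < right_fraction:
            lesion = grid.mirror(lesion)
            hemi = "right"
        masks.append(LesionMask(f"sub-{i:04d}", grid, lesion[brain], hemi))
    return masks


def sample_clinical(truth: GroundTruth, seed: int = 0,
                    group_log_hr: dict | None = None,
                    age_log_hr: float | None = None,
                    grade_probs: dict | None = None,
                    subtype_probs: dict | None = None,
                    censor_hazard: float = CENSOR_HAZARD_PER_MONTH):
    """Clinical table for the sampled subjects (requires ``sample_lesions``
    to have assigned latent classes).

    Grade and subtype are drawn from per-source multinomials; age ~
    N(53, 15); survival is exponential with log-hazard
    ``beta_group + beta_age * 1[age > median]`` plus independent exponential
    censoring.  Planted effects are recorded in ``truth.clinical_params``.
    """
    from .clinical import CohortTable
    import pandas as pd

    if truth.subject_sources is None:
        raise ValidationError("sample_lesions must run first to assign classes")
    rng = np.random.default_rng(seed)
    glhr = {**DEFAULT_GROUP_LOG_HR, **(group_log_hr or {})}
    alhr = DEFAULT_AGE_LOG_HR if age_log_hr is None else age_log_hr
    gp = grade_probs or GRADE_PROBS
    sp = subtype_probs or SUBTYPE_PROBS
    rows = []
    classes = truth.subject_sources
    age = rng.normal(53, 15, size=len(classes))
    med = np.median(age)
    for i, c in enumerate(classes):
        g = rng.choice(list(gp[c]), p=list(gp[c].values()))
        st = rng.choice(list(sp[c]), p=list(sp[c].values()))
        lam = BASELINE_HAZARD_PER_MONTH * np.exp(glhr[c] + alhr * (age[i] > med))
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(1.0 / censor_hazard) if censor_hazard > 0 else np.inf
        rows.append({
            "subject_id": f"sub-{i:04d}",
            "lcn_group": int(c),
            "grade": g,
            "subtype": st,
            "age_years": float(age[i]),
            "gender": rng.choice(["male", "female"]),
            "survival_months": float(min(t_event, t_cens)),
            "event": int(t_event <= t_cens),
        })
    truth.clinical_params.update({"group_log_hr": glhr, "age_log_hr": alhr})
    return CohortTable(pd.DataFrame(rows))


def _smoothed_noise(grid: VoxelGrid, domain: str, fwhm_vox: float,
                    rng: np.random.Generator) -> np.ndarray:
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vol = gaussian_filter(rng.standard_normal(grid.shape), sigma)
    v = vol[grid.mask(domain)]
    return (v - v.mean()) / max(v.std(), 1e-12)


def make_connectivity(
    truth: GroundTruth,
    a: float,
    smooth_fwhm_vox: float = 4.0,
    seed: int = 0,
    source_index: int = 0,
    domain: str = "brain",
    structural: bool = False,
):
    """One synthetic connectivity network: ``a``-weighted mix of a
    unit-normalized source map with unit-normalized smoothed noise.

    With ``structural=True`` also returns a nonnegative streamline-density
    stand-in (the squared network values)."""
    if not 0 <= a <= 1:
        raise ValidationError("mixing weight a must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    src = truth.source_map(source_index, domain).values
    src = (src - src.mean()) / max(src.std(), 1e-12)
    noise = _smoothed_noise(truth.grid, domain, smooth_fwhm_vox, rng)
    net = BrainMap(truth.grid, domain, a * src + (1 - a) * noise)
    truth.connectivity_params[f"net_s{source_index}_seed{seed}"] = a
    if structural:
        density = net.with_values(net.values**2)
        return net, density
    return net


def make_connectome(truth: GroundTruth, c: int | None = None, seed: int = 0,
                    noise_weight: float = 0.3,
                    node_gain: float = 1.5,
                    noise_fwhm_vox: float = 3.0,
                    embed_sources: bool = True) -> ConnectomeComponents:
    """Low-rank connectome loadings embedding each source.

    Component j (j < k) carries source j's cortical pattern together with a
    Gaussian bump (amplitude ``node_gain``) on its paired subcortical node,
    so seeds inside that node reproduce the source's cortical map; the
    remaining components are smoothed noise at relative weight
    ``noise_weight``.  With ``embed_sources=False`` every component is noise
    (the global-null connectome).
    """
    k = truth.k
    if c is None:
        c = k + 5
    if c < k:
        raise ValidationError("need at least k components")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    dom = "gray"
    gray_idx = grid.mask_indices(dom)
    coords = np.argwhere(grid.mask(dom)).astype(float)
    V = gray_idx.size
    L = np.empty((V, c))
    first_noise = k if embed_sources else 0
    if embed_sources:
        for j in range(k):
            vol = truth.source_map(j).to_volume()
            # add the paired subcortical node bump
            d2 = ((coords - truth.node_centers[j]) ** 2).sum(axis=1)
            node_bump = node_gain * np.exp(-d2 / (2.0 * 2.0**2))
            L[:, j] = vol.ravel()[gray_idx] + node_bump
    for j in range(first_noise, c):
        L[:, j] = noise_weight * _smoothed_noise(grid, dom, noise_fwhm_vox, rng)
    if not embed_sources:
        L /= noise_weight  # pure-noise connectome needs no relative scale
    return ConnectomeComponents(grid, dom, L, weights=np.ones(c), weighted=True)


def planted_subcortical_region(truth: GroundTruth, j: int,
                               node_gain: float = 1.5,
                               frac: float = 0.5) -> np.ndarray:
    """Positions (within the subcortical mask) of the planted signal region
    for source ``j``: voxels where the embedded loading pattern (source tube
    plus node bump) exceeds ``frac`` of its subcortical maximum."""
    grid = truth.grid
    sub_idx = grid.mask_indices("subcortical")
    coords = np.argwhere(grid.mask("subcortical")).astype(float)
    vol = truth.source_map(j).to_volume()
    d2 = ((coords - truth.node_centers[j]) ** 2).sum(axis=1)
    signal = vol.ravel()[sub_idx] + node_gain * np.exp(-d2 / (2.0 * 2.0**2))
    return np.flatnonzero(signal >= frac * signal.max())
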
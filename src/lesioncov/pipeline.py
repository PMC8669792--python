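"""End-to-end orchestration of the lesion-covariance-network analysis.

``run_all`` executes fold -> stack -> ICA -> mixture thresholding -> group
assignment -> clinical statistics -> surrogate ensembles -> connectivity
correspondence -> subcortical seed scan -> cluster FWE, writing standard
artifacts (NIfTI maps, TSV tables, a JSON run report) under an output
directory.  Any stage can be run standalone; a failed stage marks itself
failed in the report and downstream stages are skipped.

All thresholds live in :class:`RunConfig`; per-stage random seeds are
derived from one master seed by stage-name hashing, so adding a stage never
perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical import CohortTable, cox_fit, crosstab_test, km_curve, plot_km
from .grids import BrainMap, fold_to_left, stack, write_map
from .ica import assign_groups, decompose, derive_seed
from .mixture import fit_mixture, threshold
from .nulls import adjust, make_surrogates, surrogate_test
from .sbfc import ConnectomeComponents, cluster_fwe, seed_scan

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    output_dir: str
    k: int = 3
    n_surrogates: int = 999
    voxel_alpha: float = 0.001
    cluster_alpha: float = 0.05
    mixture_threshold: float = 0.5
    smoothing_fwhm_mm: float = 5.0
    streamline_fraction: float = 0.01
    correction: str = "bonferroni"
    functional_method: str = "pearson"
    structural_method: str = "spearman"
    master_seed: int = 0
    cluster_connectivity: int = 26

    def __post_init__(self) -> None:
        for a in (self.voxel_alpha, self.cluster_alpha):
            if not 0 < a < 1:
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_surrogates < 99:
            raise ValueError("n_surrogates must be >= 99 to resolve p at 0.01")

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Flat ``key = value`` text config."""
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        parsed = {}
        for key, val in kv.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                parsed[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                parsed[key] = int(val)
            elif isinstance(default, float):
                parsed[key] = float(val)
            else:
                parsed[key] = val
        parsed.update(overrides)
        return cls(**parsed)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = ""

    def record(self, name: str, status: str, seconds: float, **info) -> None:
        self.stages[name] = {"status": status, "seconds": round(seconds, 3), **info}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"version": self.version, "config": self.config,
                       "stages": self.stages}, fh, indent=2, default=str)


def run_all(
    config: RunConfig,
    masks: list,
    clinical: CohortTable | None = None,
    functional_networks: dict | None = None,
    structural_networks: dict | None = None,
    connectome: ConnectomeComponents | None = None,
    write_nifti: bool = True,
) -> RunReport:
    """Run every stage on in-memory inputs, writing artifacts to
    ``config.output_dir``.  Missing optional inputs skip their stage with a
    warning rather than failing the run."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)
    ctx: dict = {}

    stages = [
        ("fold_stack", lambda: _stage_fold_stack(config, masks, ctx)),
        ("decompose", lambda: _stage_decompose(config, ctx, out, write_nifti)),
        ("mixture", lambda: _stage_mixture(config, ctx, out, write_nifti)),
        ("assign", lambda: _stage_assign(config, ctx, out)),
        ("clinical", lambda: _stage_clinical(config, clinical, ctx, out)),
        ("surrogates", lambda: _stage_surrogates(config, ctx)),
        ("correspond", lambda: _stage_correspond(
            config, functional_networks, structural_networks, ctx, out)),
        ("sbfc", lambda: _stage_sbfc(config, connectome, ctx, out, write_nifti)),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            report.record(name, "skipped", 0.0, reason="upstream failure")
            continue
        t0 = time.perf_counter()
        try:
            info = fn() or {}
            status = info.pop("_status", "ok")
            report.record(name, status, time.perf_counter() - t0, **info)
        except Exception as exc:
            logger.exception("stage %s failed", name)
            report.record(name, "failed", time.perf_counter() - t0, error=str(exc))
            failed = True
    report.save(out / "report.json")
    return report


def _stage_fold_stack(config, masks, ctx):
    folded = [fold_to_left(m) for m in masks]
    ctx["stack"] = stack(folded)
    return {"n_subjects": ctx["stack"].n_subjects,
            "n_voxels": int(ctx["stack"].matrix.shape[1])}


def _stage_decompose(config, ctx, out, write_nifti):
    seed = derive_seed(config.master_seed, "decompose")
    dec = decompose(ctx["stack"], config.k, seed)
    ctx["decomposition"] = dec
    if write_nifti:
        for j in range(dec.k):
            write_map(dec.z_map(j), out / f"lcn{j + 1}_zmap.nii.gz")
    with open(out / "decomposition.json", "w") as fh:
        json.dump({"k": dec.k, "seed": dec.seed, "converged": bool(dec.converged),
                   "explained_variance": dec.explained_variance.tolist()}, fh, indent=2)
    return {"k": dec.k, "converged": bool(dec.converged)}


def _stage_mixture(config, ctx, out, write_nifti):
    dec = ctx["decomposition"]
    lcn_maps = []
    for j in range(dec.k):
        fit = fit_mixture(dec.z_map(j), component=j)
        lcn_maps.append(threshold(fit, config.mixture_threshold))
        if write_nifti:
            write_map(lcn_maps[-1].posterior, out / f"lcn{j + 1}_posterior.nii.gz")
    ctx["lcn_maps"] = lcn_maps
    return {"support_sizes": [m.n_voxels for m in lcn_maps]}


def _stage_assign(config, ctx, out):
    dec = ctx["decomposition"]
    groups, margin = assign_groups(dec.subject_scores)
    ctx["groups"] = groups
    df = pd.DataFrame({"subject_id": ctx["stack"].subject_ids})
    for j in range(dec.k):
        df[f"score_{j + 1}"] = dec.subject_scores[:, j]
    df["group"] = groups
    df["margin"] = margin
    df.to_csv(out / "subject_scores.tsv", sep="\t", index=False)
    counts = np.bincount(groups, minlength=dec.k + 1)[1:]
    return {"group_sizes": counts.tolist()}


def _stage_clinical(config, clinical, ctx, out):
    if clinical is None:
        logger.warning("no clinical table; skipping clinical stage")
        return {"_status": "skipped", "reason": "no clinical table"}
    df = clinical.df.copy()
    assigned = pd.DataFrame({"subject_id": ctx["stack"].subject_ids,
                             "lcn_group": ctx["groups"]})
    df = df.drop(columns=["lcn_group"]).merge(assigned, on="subject_id", how="inner")
    table = CohortTable(df)
    results = {}
    for var in ("grade", "subtype"):
        r = crosstab_test(table, "lcn_group", var)
        results[f"chi2_{var}"] = {
            "statistic": r.statistic, "df": r.df, "p": r.p,
            "adjusted_residuals": r.adjusted_residuals.to_dict(),
            "posthoc_p": r.posthoc_p.to_dict(),
        }
    m1 = cox_fit(table, ["lcn_group", "age_years", "gender"])
    m2 = cox_fit(table, ["lcn_group", "age_years", "gender", "grade", "subtype"])
    for name, m in (("cox_demographic", m1), ("cox_full", m2)):
        results[name] = {
            "n": m.n, "events": m.events, "converged": m.converged,
            "hazard_ratios": m.hazard_ratios.to_dict(),
            "se_log_hr": m.se_log_hr.to_dict(), "p": m.p.to_dict(),
            "flags": m.flags,
        }
    with open(out / "clinical.json", "w") as fh:
        json.dump(results, fh, indent=2)
    plot_km(table, out / "km_curves.png")
    curves = km_curve(table)
    pd.concat([df.assign(group=g) for g, df in curves.items()]).to_csv(
        out / "km_curves.tsv", sep="\t", index=False)
    return {"n": len(table)}


def _stage_surrogates(config, ctx):
    dec = ctx["decomposition"]
    seed = derive_seed(config.master_seed, "surrogates")
    ensembles = []
    for j in range(dec.k):
        ensembles.append(make_surrogates(
            dec.z_map(j), config.n_surrogates,
            derive_seed(seed, f"lcn{j}"), source_id=f"lcn{j + 1}"))
    ctx["ensembles"] = ensembles
    return {"n_surrogates": config.n_surrogates}


def _stage_correspond(config, functional, structural, ctx, out):
    from .grids import streamline_mask

    dec = ctx["decomposition"]
    rows = []
    for modality, nets, method in (
        ("functional", functional, config.functional_method),
        ("structural", structural, config.structural_method),
    ):
        if not nets:
            continue
        fam = []
        for net_name, net in nets.items():
            density = None
            if isinstance(net, tuple):
                net, density = net
            subset = None
            if density is not None:
                subset = streamline_mask(density, config.streamline_fraction)
                if subset.size < 10:
                    logger.warning(
                        "streamline mask for %s keeps %d voxels; comparing on "
                        "the full domain instead", net_name, subset.size)
                    subset = None
            for j in range(dec.k):
                lcn = _restrict(dec.z_map(j), net.domain)
                t = surrogate_test(lcn, net, _restrict_ensemble(ctx["ensembles"][j], dec.z_map(j), net.domain),
                                   method, subset, f"lcn{j + 1}", net_name)
                fam.append((modality, net_name, j + 1, method, t))
        padj = adjust([t.p_uncorrected for *_, t in fam], config.correction)
        for (modality, net_name, j, method, t), pa in zip(fam, padj):
            rows.append({"modality": modality, "lcn": j, "network": net_name,
                         "method": method, "r": t.r_observed,
                         "p": t.p_uncorrected, "p_adj": float(pa)})
    if not rows:
        logger.warning("no connectivity networks supplied; correspondence skipped")
        return {"_status": "skipped", "reason": "no networks"}
    df = pd.DataFrame(rows)
    df.to_csv(out / "correspondence.tsv", sep="\t", index=False)
    n_sig = int((df["p_adj"] < 0.05).sum())
    return {"n_tests": len(df), "n_significant": n_sig}


def _restrict(bmap: BrainMap, domain: str) -> BrainMap:
    if bmap.domain == domain:
        return bmap
    return BrainMap.from_volume(bmap.grid, domain, bmap.to_volume())


def _restrict_ensemble(ensemble, source_map, domain):
    """Project an ensemble built on the source map's domain onto a sub-domain."""
    if domain == source_map.domain:
        return ensemble
    grid = source_map.grid
    src_idx = grid.mask_indices(source_map.domain)
    sub_idx = grid.mask_indices(domain)
    pos = np.searchsorted(src_idx, sub_idx)
    if not np.array_equal(src_idx[pos], sub_idx):
        raise ValueError(f"domain {domain!r} not contained in {source_map.domain!r}")
    import copy

    out = copy.copy(ensemble)
    out.values = ensemble.values[:, pos]
    return out


def _stage_sbfc(config, connectome, ctx, out, write_nifti):
    if connectome is None:
        logger.warning("no connectome; skipping seed-based stage")
        return {"_status": "skipped", "reason": "no connectome"}
    dec = ctx["decomposition"]
    grid = connectome.grid
    results = []
    for j in range(dec.k):
        lcn_cortex = _restrict(dec.z_map(j), "cortex")
        ens = _restrict_ensemble(ctx["ensembles"][j], dec.z_map(j), "cortex")
        pmap = seed_scan(connectome, lcn_cortex, ens, config.smoothing_fwhm_mm)
        pmap = cluster_fwe(pmap, config.voxel_alpha, config.cluster_alpha,
                           config.cluster_connectivity)
        if write_nifti:
            write_map(pmap.p_map(), out / f"lcn{j + 1}_seed_p.nii.gz")
            import nibabel as nib
            nib.save(nib.Nifti1Image(pmap.cluster_label_volume(), grid.default_affine()),
                     str(out / f"lcn{j + 1}_clusters.nii.gz"))
        coords = np.argwhere(grid.mask("subcortical"))
        for ci, cl in enumerate(pmap.clusters, start=1):
            peak_pos = cl.voxel_positions[np.argmax(pmap.r[cl.voxel_positions])]
            peak_mm = coords[peak_pos] * np.asarray(grid.voxel_size_mm)
            results.append({"lcn": j + 1, "cluster": ci, "extent": cl.extent,
                            "peak_r": cl.peak_r, "fwe_p": cl.fwe_p,
                            "peak_mm": peak_mm.tolist()})
        ctx.setdefault("seed_pmaps", []).append(pmap)
    pd.DataFrame(results).to_csv(out / "clusters.tsv", sep="\t", index=False)
    return {"n_clusters": len(results)}
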
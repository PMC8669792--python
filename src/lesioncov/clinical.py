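"""Clinical association and survival statistics for LCN groups.

Associations between a patient's lesion-covariance-network group and
pathology variables (tumour grade GBM/LGG; IDH/1p19q molecular subtype) are
tested with Pearson chi-square contingency tests, followed by post-hoc
adjusted standardized residuals whose two-sided normal p-values are
Bonferroni-multiplied by the cell count.  Survival is summarized with
Kaplan-Meier curves and modelled with Cox proportional-hazards regressions
(Breslow tie handling), with the age covariate binned at the cohort median.
Patients with missing data are excluded listwise per analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import chi2_contingency, norm
from statsmodels.duration.hazard_regression import PHReg

from .grids import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "subject_id", "lcn_group", "grade", "subtype",
    "age_years", "gender", "survival_months", "event",
]


@dataclass
class CohortTable:
    """Per-subject clinical covariates, LCN group and survival outcome.

    ``event`` is 1 for death, 0 for censoring.  Missing values are allowed in
    any field except ``subject_id`` and are dropped per analysis.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"CohortTable missing columns {missing}")
        if self.df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject ids")
        surv = self.df["survival_months"].dropna()
        if (surv < 0).any():
            raise ValidationError("negative survival time")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Contingency tests with post-hoc residuals


@dataclass
class ChiSquareResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    statistic: float
    df: int
    p: float
    adjusted_residuals: pd.DataFrame
    posthoc_p: pd.DataFrame      # two-sided normal p x cell count (Bonferroni)
    n: int


def adjusted_residuals(observed: np.ndarray) -> np.ndarray:
    """Adjusted standardized residuals (O-E)/sqrt(E(1-rs/n)(1-cs/n))."""
    O = np.asarray(observed, dtype=float)
    n = O.sum()
    rs = O.sum(axis=1, keepdims=True)
    cs = O.sum(axis=0, keepdims=True)
    E = rs * cs / n
    denom = np.sqrt(E * (1 - rs / n) * (1 - cs / n))
    return (O - E) / denom


def residual_posthoc_p(residual: float, n_cells: int) -> float:
    """Bonferroni post-hoc p of one adjusted residual: min(1, cells * 2(1-Phi(|r|)))."""
    return float(min(1.0, n_cells * 2.0 * norm.sf(abs(residual))))


def crosstab_test(table: CohortTable, row: str, col: str,
                  raw_residuals: bool = False) -> ChiSquareResult:
    """Pearson chi-square test of independence (no continuity correction)
    with per-cell post-hoc residual p-values.

    ``raw_residuals`` switches the post-hoc residuals to (O-E)/sqrt(E).
    """
    sub = table.df[[row, col]].dropna()
    ct = pd.crosstab(sub[row], sub[col])
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise ValidationError("need >= 2 levels in each variable")
    stat, p, dof, expected = chi2_contingency(ct.values, correction=False)
    if (expected < 1).any():
        logger.warning("expected cell count below 1; chi-square may be unreliable")
    if raw_residuals:
        res = (ct.values - expected) / np.sqrt(expected)
    else:
        res = adjusted_residuals(ct.values)
    cells = ct.size
    ph = np.vectorize(residual_posthoc_p)(res, cells)
    as_df = lambda a: pd.DataFrame(a, index=ct.index, columns=ct.columns)
    return ChiSquareResult(ct, as_df(expected), float(stat), int(dof), float(p),
                           as_df(res), as_df(ph), int(ct.values.sum()))


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(table: CohortTable, group_field: str = "lcn_group") -> dict:
    """Product-limit survival estimate per group.

    Returns ``{group: DataFrame(time, survival, at_risk)}``; censored
    subjects leave the risk set at their censoring time.
    """
    sub = table.df[[group_field, "survival_months", "event"]].dropna()
    out = {}
    for g, gdf in sub.groupby(group_field):
        kmf = KaplanMeierFitter()
        kmf.fit(gdf["survival_months"], gdf["event"])
        times = kmf.survival_function_.index.to_numpy()
        out[g] = pd.DataFrame({
            "time": times,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": [kmf.event_table.loc[:t, "at_risk"].iloc[-1] if t in kmf.event_table.index
                        else np.nan for t in times],
        })
    return out


def plot_km(table: CohortTable, path, group_field: str = "lcn_group") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = km_curve(table, group_field)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, df in curves.items():
        ax.step(df["time"], df["survival"], where="post", label=str(g))
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.legend(title=group_field)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    terms: list
    coefficients: pd.Series
    hazard_ratios: pd.Series
    se_log_hr: pd.Series
    p: pd.Series
    n: int
    events: int
    converged: bool
    flags: list = field(default_factory=list)
    reference_levels: dict = field(default_factory=dict)


DEFAULT_REFERENCES = {"lcn_group": 3, "grade": "GBM", "subtype": "IDH-wt", "gender": "female"}


def cox_fit(table: CohortTable, terms: list[str],
            reference_levels: dict | None = None) -> CoxFit:
    """Cox proportional-hazards regression on the cohort.

    Categorical terms are dummy-coded against ``reference_levels`` (defaults:
    LCN3, GBM, IDH-wt, female); ``age_years`` enters as the indicator
    age > cohort median.  Partial likelihood uses Breslow tie handling; a fit
    that fails to converge or shows a monotone likelihood is returned flagged.
    """
    refs = {**DEFAULT_REFERENCES, **(reference_levels or {})}
    cols = ["survival_months", "event"] + terms
    sub = table.df[cols].dropna().copy()
    if len(sub) == 0 or sub["event"].sum() == 0:
        raise ValidationError("need at least one observed event")

    X = pd.DataFrame(index=sub.index)
    flags = []
    for t in terms:
        if t == "age_years":
            med = sub["age_years"].median()
            X["age_above_median"] = (sub["age_years"] > med).astype(float)
        elif sub[t].dtype.kind in "ifu" and sub[t].nunique() > 6:
            X[t] = sub[t].astype(float)
        else:
            ref = refs.get(t)
            levels = [l for l in pd.unique(sub[t]) if l != ref]
            for lv in sorted(map(str, levels)):
                match = sub[t].astype(str) == lv
                X[f"{t}[{lv}]"] = match.astype(float)
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            flags.append(f"constant covariate {c}")
            X = X.drop(columns=[c])
    if X.shape[1] == 0:
        raise ValidationError("no usable covariates (all constant)")

    model = PHReg(
        sub["survival_months"].to_numpy(dtype=float),
        X.astype(float),
        status=sub["event"].to_numpy(dtype=int),
        ties="breslow",
    )
    converged = True
    try:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = model.fit(maxiter=200)
    except Exception as exc:  # singular information, monotone likelihood, ...
        flags.append(f"non-convergence: {exc}")
        empty = pd.Series(dtype=float)
        return CoxFit(terms, empty, empty, empty, empty, len(sub),
                      int(sub["event"].sum()), False, flags, refs)
    coef = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)):
        flags.append("non-finite estimates (possible monotone likelihood)")
        converged = False
    elif (coef.abs() > 15).any():
        flags.append("extreme coefficient (possible monotone likelihood/separation)")
    return CoxFit(
        terms,
        coef,
        np.exp(coef),
        se,
        pd.Series(res.pvalues, index=X.columns),
        len(sub),
        int(sub["event"].sum()),
        converged,
        flags,
        refs,
    )
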
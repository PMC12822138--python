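"""Cluster characterization: descriptive cross-cluster tests, the four
registered multinomial logistic models (cluster membership vs reference),
collinearity diagnostics, and the baseline cognition models."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("gmpatterns")

__all__ = [
    "CrosstabResult",
    "crosstab_compare",
    "ModelSpec",
    "MODEL_REGISTRY",
    "fit_multinomial",
    "variance_inflation",
    "fit_cognition_models",
]

Z975 = float(stats.norm.ppf(0.975))


# --------------------------------------------------------------------------
# descriptive cross-cluster tests
# --------------------------------------------------------------------------

@dataclass
class CrosstabResult:
    variable: str
    test: str                      # chi2 | anova | kruskal
    statistic: float
    df: float
    p: float
    summary: pd.DataFrame          # per-cluster row in Table-1 style


def crosstab_compare(variable: pd.Series, labels, kind: str = "categorical",
                     name: str | None = None) -> CrosstabResult:
    """Compare one variable across clusters.

    ``kind`` declares the triage: ``categorical`` -> chi-square on the
    contingency table, ``normal`` -> one-way ANOVA, ``nonnormal`` ->
    Kruskal-Wallis.  The summary holds mean +/- SD (continuous) or
    n (%) per category (categorical) for each cluster.
    """
    labels = np.asarray(labels)
    name = name or (variable.name if variable.name else "variable")
    v = pd.Series(np.asarray(variable), name=name)
    ok = v.notna().to_numpy()
    v, lab = v[ok], labels[ok]
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")

    if kind == "categorical":
        tab = pd.crosstab(v, pd.Series(lab, name="cluster", index=v.index))
        if (tab.sum(axis=1) == 0).any():
            tab = tab.loc[tab.sum(axis=1) > 0]
            logger.warning("crosstab %s: dropped empty categories", name)
        if tab.shape[0] < 2:
            raise ValueError(f"{name!r} has no variation; chi-square undefined")
        stat, p, df, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        pct = tab / tab.sum(axis=0)
        summary = tab.astype(str) + " (" + (100 * pct).round(1).astype(str) + "%)"
        return CrosstabResult(name, "chi2", float(stat), float(df), float(p),
                              summary)

    groups = [v[lab == u].to_numpy(dtype=float) for u in uniq]
    if np.ptp(np.concatenate(groups)) == 0:
        raise ValueError(f"{name!r} is constant; no test possible")
    if kind == "normal":
        stat, p = stats.f_oneway(*groups)
        test, df = "anova", float(uniq.size - 1)
    elif kind == "nonnormal":
        stat, p = stats.kruskal(*groups)
        test, df = "kruskal", float(uniq.size - 1)
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    summary = pd.DataFrame(
        {u: {"mean": float(np.mean(g)), "sd": float(np.std(g, ddof=1))}
         for u, g in zip(uniq, groups)}).T
    summary.index.name = "cluster"
    return CrosstabResult(name, test, float(stat), df, float(p), summary)


# --------------------------------------------------------------------------
# multinomial models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A registered multinomial model: named predictor set with reference
    levels for categorical predictors."""

    name: str
    predictors: tuple[str, ...]
    #: categorical predictor -> reference level (its dummies drop this level)
    reference_levels: dict[str, str] = field(default_factory=dict)
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"model {self.name!r}: duplicate predictors")


#: The four registered models characterizing cluster membership.
MODEL_REGISTRY: dict[str, ModelSpec] = {
    "clinical": ModelSpec("clinical", (
        "sex_female", "education_higher", "apoe4", "smoking_ever",
        "alcohol_atrisk", "physical_inactivity", "overweight",
        "triglycerides_high", "ldl_tertile", "hdl_low", "hypertension",
        "heart_disease", "stroke_tia", "diabetes", "depression", "tbi",
    ), reference_levels={"ldl_tertile": "T1"}),
    "neuroimaging": ModelSpec("neuroimaging", (
        "fa_tertile", "wmhv_tertile",
    ), reference_levels={"fa_tertile": "T1", "wmhv_tertile": "T1"}),
    "inflammation": ModelSpec("inflammation", (
        "homocysteine_high", "crp_high",
    )),
    "csf": ModelSpec("csf", ("abeta_pos", "ttau_pos", "ptau_pos")),
}


def _build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = []
    for pred in spec.predictors:
        if pred not in data.columns:
            raise ValueError(f"model {spec.name!r}: predictor {pred!r} missing")
        col = data[pred]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = spec.reference_levels.get(pred)
            levels = sorted(col.dropna().unique())
            if ref is None:
                ref = levels[0]
            elif ref not in levels:
                raise ValueError(f"model {spec.name!r}: reference level "
                                 f"{ref!r} absent from {pred!r}")
            for lev in levels:
                if lev != ref:
                    cols.append(pd.Series((col == lev).astype(float),
                                          name=f"{pred}[{lev}]").where(col.notna()))
        else:
            cols.append(col.astype(float))
    return pd.concat(cols, axis=1)


def fit_multinomial(data: pd.DataFrame, labels, spec: ModelSpec,
                    reference: int = 1) -> pd.DataFrame:
    """Maximum-likelihood multinomial logit of cluster membership on the
    spec's predictors, baseline category = the reference cluster.

    Returns tidy records (model, predictor, contrast, OR, ci_low, ci_high,
    p, n) with Wald 95% intervals, one row per predictor level per
    non-reference cluster.  Complete cases only; a warning is logged below
    10 cases per parameter.
    """
    X = _build_design(data, spec)
    y = pd.Series(np.asarray(labels), index=X.index, name="cluster")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    n = len(y)
    levels = np.unique(y)
    if levels.size < 2:
        raise ValueError("outcome must have at least 2 levels")
    if reference not in levels:
        raise ValueError(f"reference cluster {reference} absent")
    # put the reference first so it is the MNLogit baseline category
    order = [reference] + [int(l) for l in levels if l != reference]
    y_coded = y.map({lab: i for i, lab in enumerate(order)})

    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        aliased = [c for c in corr.columns
                   if (corr.loc[c].drop(c) > 1 - 1e-10).any()]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    n_par = Xc.shape[1] * (levels.size - 1)
    if n < 10 * n_par:
        logger.warning("model %s: %d complete cases for %d parameters "
                       "(< 10 per parameter)", spec.name, n, n_par)

    model = sm.MNLogit(y_coded.to_numpy(), Xc.to_numpy())
    try:
        res = model.fit(method="newton", maxiter=spec.max_iter,
                        tol=spec.tol, disp=0)
    except np.linalg.LinAlgError as e:  # pragma: no cover - separation
        raise RuntimeError(f"model {spec.name!r} failed to converge "
                           f"(possible separation): {e}") from None
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"model {spec.name!r} did not converge; check for "
                           "separation or sparse cells")

    rows = []
    pred_names = list(Xc.columns)
    for j, clus in enumerate(order[1:]):  # equation j contrasts clus vs ref
        for i, pname in enumerate(pred_names):
            if pname == "const":
                continue
            beta = res.params[i, j]
            se = res.bse[i, j]
            rows.append({
                "model": spec.name, "predictor": pname,
                "contrast": f"{clus}_vs_{reference}",
                "cluster": int(clus),
                "OR": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - Z975 * se)),
                "ci_high": float(np.exp(beta + Z975 * se)),
                "p": float(res.pvalues[i, j]),
                "n": n,
            })
    return pd.DataFrame(rows)


def variance_inflation(design: pd.DataFrame,
                       flag_threshold: float = 1.7) -> pd.DataFrame:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the other
    predictors (with intercept).  Exact collinearity yields +inf, flagged.
    The default flag threshold matches the bound observed in the source
    analysis (all VIF < 1.7)."""
    X = design.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors for VIF")
    rows = []
    for col in X.columns:
        y = X[col].to_numpy()
        others = sm.add_constant(X.drop(columns=col), has_constant="add")
        res = sm.OLS(y, others.to_numpy()).fit()
        r2 = min(res.rsquared, 1.0)
        vif = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": col, "vif": float(vif),
                     "flagged": bool(vif > flag_threshold)})
    return pd.DataFrame(rows)


def fit_cognition_models(data: pd.DataFrame, labels,
                         outcomes: tuple[str, ...] | None = None,
                         reference: int = 1) -> pd.DataFrame:
    """Identity-link Gaussian models of each cognitive outcome on cluster
    indicators (reference cluster omitted): beta, SE, p per cluster per
    outcome.  Default outcomes: global composite + the five domains."""
    labels = pd.Series(np.asarray(labels), index=data.index, name="cluster")
    uniq = np.unique(labels)
    if outcomes is None:
        from .rois import COGNITIVE_DOMAINS
        outcomes = ("global_cognition",) + COGNITIVE_DOMAINS
    for u in uniq:
        if (labels == u).sum() == 0:  # pragma: no cover - unique() precludes
            raise ValueError(f"cluster {u} is empty")
    if reference not in uniq:
        raise ValueError(f"reference cluster {reference} absent")
    dummies = pd.get_dummies(labels, prefix="cluster").astype(float)
    dummies = dummies.drop(columns=f"cluster_{reference}")
    X = sm.add_constant(dummies, has_constant="add")
    rows = []
    for out in outcomes:
        y = data[out].astype(float)
        ok = y.notna()
        res = sm.GLM(y[ok].to_numpy(), X.loc[ok].to_numpy(),
                     family=sm.families.Gaussian()).fit()
        for i, cname in enumerate(X.columns):
            if cname == "const":
                continue
            rows.append({"outcome": out,
                         "cluster": int(cname.split("_")[-1]),
                         "beta": float(res.params[i]),
                         "se": float(res.bse[i]),
                         "p": float(res.pvalues[i]),
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)
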
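"""Five-year trajectory models: linear mixed-effects fits per outcome with
cluster x time interactions, FDR across the outcome battery, comparison of
random-effects structures, and attrition analysis.

Timepoint is coded 0/1 for the two visits, so each cluster's interaction
coefficient (beta_slope) is its *excess change per follow-up interval*
relative to the reference cluster.  Models are estimated by maximum
likelihood (not REML) so AIC/BIC are comparable across random-effects
structures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, optimize

from .association import CrosstabResult, crosstab_compare
from .effects import bh_fdr

logger = logging.getLogger("gmpatterns")

__all__ = [
    "LongitudinalSpec",
    "LongitudinalFit",
    "make_long_table",
    "fit_longitudinal_model",
    "fdr_across_outcomes",
    "compare_random_effect_structures",
    "attrition_table",
]

RANDOM_STRUCTURES = ("intercept_slope", "intercept", "slope")


@dataclass(frozen=True)
class LongitudinalSpec:
    """Model specification shared across the outcome battery."""

    outcomes: tuple[str, ...]
    random_structure: str = "intercept_slope"
    #: cluster-specific residual variances (custom ML fit) when True
    heterogeneous: bool = False
    reference: int = 1
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(f"random_structure must be one of {RANDOM_STRUCTURES}")


@dataclass
class LongitudinalFit:
    """One fitted outcome model with its slope contrasts."""

    outcome: str
    contrasts: pd.DataFrame     # cluster, beta_slope, se, p
    timepoint_beta: float       # reference-cluster change per interval
    joint_wald_p: float         # overall cluster x time interaction
    llf: float
    aic: float
    bic: float
    converged: bool
    n_obs: int
    n_subjects: int
    random_structure: str


def make_long_table(baseline: pd.DataFrame, followup: pd.DataFrame,
                    outcomes: tuple[str, ...], labels: pd.Series,
                    covariates: tuple[str, ...] = ("sex_female", "education_years"),
                    ) -> pd.DataFrame:
    """Stack the two visits into one long table: subject_id, timepoint
    (0/1), outcome columns, cluster and baseline covariates.  Only
    subjects present in the follow-up table contribute a visit-2 row."""
    base = baseline.set_index("subject_id")
    fu = followup.set_index("subject_id")
    missing = [o for o in outcomes if o not in base.columns or o not in fu.columns]
    if missing:
        raise ValueError(f"outcomes absent from both visits: {missing}")
    v1 = base[list(outcomes)].copy()
    v1["timepoint"] = 0.0
    v2 = fu[list(outcomes)].copy()
    v2["timepoint"] = 1.0
    long = pd.concat([v1, v2]).rename_axis("subject_id").reset_index()
    long["cluster"] = long["subject_id"].map(labels).astype(int)
    for cov in covariates:
        long[cov] = long["subject_id"].map(base[cov])
    return long


def _fixed_design(data: pd.DataFrame, reference: int,
                  covariates: tuple[str, ...]) -> tuple[pd.DataFrame, list[int]]:
    """Intercept, timepoint, cluster dummies, timepoint x cluster dummies,
    covariates.  Returns the design and the interaction column clusters."""
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["timepoint"] = data["timepoint"].astype(float)
    clusters = sorted(int(c) for c in data["cluster"].unique())
    inter_clusters = []
    for c in clusters:
        if c == reference:
            continue
        ind = (data["cluster"] == c).astype(float)
        X[f"cluster_{c}"] = ind
        X[f"tp_x_cluster_{c}"] = ind * X["timepoint"]
        inter_clusters.append(c)
    for cov in covariates:
        if cov in data.columns:
            X[cov] = data[cov].astype(float)
    return X, inter_clusters


def fit_longitudinal_model(data: pd.DataFrame, outcome: str,
                           spec: LongitudinalSpec,
                           covariates: tuple[str, ...] = ("sex_female", "education_years"),
                           ) -> LongitudinalFit:
    """Fit one outcome's mixed model on the long table.

    Fixed effects: timepoint, cluster, timepoint x cluster, covariates.
    Random effects per subject follow ``spec.random_structure``.  The
    homoscedastic model uses statsmodels MixedLM (ML); the heterogeneous
    flag switches to a direct ML fit with cluster-specific residual
    variances.  Returns per-cluster slope contrasts (the interaction
    coefficients), a joint Wald test of the overall interaction, and
    ML-based AIC/BIC.
    """
    cols = ["subject_id", "timepoint", "cluster", outcome, *covariates]
    d = data[[c for c in cols if c in data.columns]].dropna()
    X, inter_clusters = _fixed_design(d, spec.reference, covariates)
    # a cluster with no follow-up rows leaves an all-zero interaction
    # column; drop it (and its contrast) rather than fitting a singular
    # design
    dead = [c for c in inter_clusters
            if np.ptp(X[f"tp_x_cluster_{c}"].to_numpy()) == 0]
    if dead:
        logger.warning("outcome %s: no follow-up data for clusters %s; "
                       "their slope contrasts are not estimable", outcome, dead)
        X = X.drop(columns=[f"tp_x_cluster_{c}" for c in dead])
        inter_clusters = [c for c in inter_clusters if c not in dead]
    y = d[outcome].to_numpy(dtype=float)
    groups = d["subject_id"].to_numpy()
    n_subj = len(np.unique(groups))
    if (pd.Series(groups).value_counts() >= 2).mean() < 0.30:
        logger.warning("outcome %s: fewer than 30%% of subjects have 2 visits",
                       outcome)

    if spec.heterogeneous:
        return _fit_heteroscedastic(d, X, y, outcome, spec, inter_clusters)

    re_formula = {"intercept_slope": ["const", "timepoint"],
                  "intercept": ["const"],
                  "slope": ["timepoint"]}[spec.random_structure]
    exog_re = X[re_formula].to_numpy()

    model = sm.MixedLM(y, X.to_numpy(), groups=groups, exog_re=exog_re)
    # Powell first (robust on ridged likelihoods), then gradient polish;
    # plain lbfgs from the default start can stall on a flat ridge and
    # report convergence at a worse optimum.
    res, converged = None, False
    for method in (["powell", "lbfgs"], ["powell"], ["nm"]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=False, maxiter=spec.max_iter, method=method)
        except np.linalg.LinAlgError:
            continue
        if res.converged:
            converged = True
            break
    if res is None:
        logger.warning("outcome %s (%s): likelihood evaluation failed",
                       outcome, spec.random_structure)
        return LongitudinalFit(outcome, pd.DataFrame(), float("nan"),
                               float("nan"), float("nan"), float("nan"),
                               float("nan"), False, len(y), n_subj,
                               spec.random_structure)
    if not converged:
        logger.warning("outcome %s: mixed model did not converge", outcome)

    names = list(X.columns)
    fe = pd.Series(res.fe_params, index=names)
    se = pd.Series(res.bse_fe, index=names)
    rows = []
    for c in inter_clusters:
        nm = f"tp_x_cluster_{c}"
        beta, s = float(fe[nm]), float(se[nm])
        rows.append({"outcome": outcome, "cluster": c, "beta_slope": beta,
                     "se": s, "p": 2 * stats.norm.sf(abs(beta / s))})
    contrasts = pd.DataFrame(rows)

    # joint Wald test over the interaction coefficients
    idx = [names.index(f"tp_x_cluster_{c}") for c in inter_clusters]
    beta_i = fe.to_numpy()[idx]
    cov_i = np.asarray(res.cov_params())[np.ix_(idx, idx)]
    try:
        w = float(beta_i @ np.linalg.solve(cov_i, beta_i))
        joint_p = float(stats.chi2.sf(w, df=len(idx)))
    except np.linalg.LinAlgError:
        joint_p = float("nan")

    q = exog_re.shape[1]
    k_par = len(names) + q * (q + 1) // 2 + 1  # fixed + RE covariance + scale
    llf = float(res.llf)
    n_obs = len(y)
    aic = -2 * llf + 2 * k_par
    bic = -2 * llf + np.log(n_obs) * k_par
    return LongitudinalFit(outcome, contrasts, float(fe["timepoint"]),
                           joint_p, llf, aic, bic, converged, n_obs, n_subj,
                           spec.random_structure)


def _fit_heteroscedastic(d: pd.DataFrame, X: pd.DataFrame, y: np.ndarray,
                         outcome: str, spec: LongitudinalSpec,
                         inter_clusters: list[int]) -> LongitudinalFit:
    """Direct ML for the cluster-heteroscedastic model.

    Marginal covariance per subject: V_i = Z_i G Z_i' + sigma2_{c(i)} I,
    G parameterized by its Cholesky factor.  Beta is profiled out by GLS
    at each step; the optimizer runs over the covariance parameters only.
    """
    names = list(X.columns)
    Xa = X.to_numpy()
    subj_codes, subj_idx = np.unique(d["subject_id"].to_numpy(), return_inverse=True)
    clusters = sorted(int(c) for c in d["cluster"].unique())
    cl_of_subj = np.zeros(len(subj_codes), dtype=int)
    cl_map = {c: i for i, c in enumerate(clusters)}
    for s in range(len(subj_codes)):
        rows = np.flatnonzero(subj_idx == s)
        cl_of_subj[s] = cl_map[int(d["cluster"].to_numpy()[rows[0]])]

    zcols = {"intercept_slope": [0, 1], "intercept": [0], "slope": [1]}[
        spec.random_structure]
    tp = d["timepoint"].to_numpy(dtype=float)
    Zfull = np.column_stack([np.ones_like(tp), tp])[:, zcols]
    q = Zfull.shape[1]
    k_cl = len(clusters)
    sd0 = np.std(y) or 1.0

    blocks = [np.flatnonzero(subj_idx == s) for s in range(len(subj_codes))]

    def unpack(theta):
        L = np.zeros((q, q))
        tril = np.tril_indices(q)
        vals = theta[: q * (q + 1) // 2].copy()
        L[tril] = vals
        for i in range(q):
            L[i, i] = np.exp(L[i, i])
        G = L @ L.T
        sig2 = np.exp(theta[q * (q + 1) // 2:])
        return G, sig2

    def profile(theta):
        G, sig2 = unpack(theta)
        XtVX = np.zeros((Xa.shape[1], Xa.shape[1]))
        XtVy = np.zeros(Xa.shape[1])
        logdet = 0.0
        quads = []
        for s, rows in enumerate(blocks):
            Z = Zfull[rows]
            V = Z @ G @ Z.T + sig2[cl_of_subj[s]] * np.eye(len(rows))
            Vi = np.linalg.inv(V)
            sign, ld = np.linalg.slogdet(V)
            logdet += ld
            Xi = Xa[rows]
            XtVX += Xi.T @ Vi @ Xi
            XtVy += Xi.T @ Vi @ y[rows]
            quads.append((rows, Vi))
        beta = np.linalg.solve(XtVX, XtVy)
        ss = 0.0
        for rows, Vi in quads:
            r = y[rows] - Xa[rows] @ beta
            ss += r @ Vi @ r
        nll = 0.5 * (logdet + ss + len(y) * np.log(2 * np.pi))
        return nll, beta, XtVX

    # log-diagonal init: diagonal entries of L hold log values
    tril = np.tril_indices(q)
    init = np.zeros(q * (q + 1) // 2)
    diag_pos = [i for i, (r, c) in enumerate(zip(*tril)) if r == c]
    init[diag_pos] = np.log(0.5 * sd0)
    theta0 = np.concatenate([init, np.full(k_cl, np.log(0.25 * sd0**2))])

    res = optimize.minimize(lambda t: profile(t)[0], theta0, method="L-BFGS-B",
                            options={"maxiter": spec.max_iter})
    nll, beta, XtVX = profile(res.x)
    cov_beta = np.linalg.inv(XtVX)
    fe = pd.Series(beta, index=names)
    se = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    rows_out = []
    for c in inter_clusters:
        nm = f"tp_x_cluster_{c}"
        b, s = float(fe[nm]), float(se[nm])
        rows_out.append({"outcome": outcome, "cluster": c, "beta_slope": b,
                         "se": s, "p": 2 * stats.norm.sf(abs(b / s))})
    idx = [names.index(f"tp_x_cluster_{c}") for c in inter_clusters]
    bi = beta[idx]
    ci = cov_beta[np.ix_(idx, idx)]
    w = float(bi @ np.linalg.solve(ci, bi))
    joint_p = float(stats.chi2.sf(w, df=len(idx)))
    k_par = len(names) + q * (q + 1) // 2 + k_cl
    llf = -float(nll)
    n_obs = len(y)
    return LongitudinalFit(outcome, pd.DataFrame(rows_out), float(fe["timepoint"]),
                           joint_p, llf, -2 * llf + 2 * k_par,
                           -2 * llf + np.log(n_obs) * k_par,
                           bool(res.success), n_obs, len(subj_codes),
                           spec.random_structure + "+heteroscedastic")


def fdr_across_outcomes(fits: list[LongitudinalFit]) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment across the whole outcome battery's
    slope-contrast p-values.  Non-converged fits are excluded from the
    family with a warning."""
    good = [f for f in fits if f.converged]
    dropped = [f.outcome for f in fits if not f.converged]
    if dropped:
        logger.warning("FDR family excludes non-converged outcomes: %s", dropped)
    if not good:
        raise ValueError("no converged outcome models")
    table = pd.concat([f.contrasts for f in good], ignore_index=True)
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    return table


def compare_random_effect_structures(data: pd.DataFrame, outcome: str,
                                     spec: LongitudinalSpec,
                                     ) -> pd.DataFrame:
    """Fit the three random-effects structures (intercept+slope, intercept
    only, slope only) on identical data and fixed effects; report AIC/BIC
    per structure and mark the minimizer of each criterion.  Non-converged
    fits are retained, flagged as non-comparable."""
    rows = []
    for structure in RANDOM_STRUCTURES:
        s = LongitudinalSpec(outcomes=(outcome,), random_structure=structure,
                             heterogeneous=spec.heterogeneous,
                             reference=spec.reference, max_iter=spec.max_iter)
        fit = fit_longitudinal_model(data, outcome, s)
        rows.append({"outcome": outcome, "structure": structure,
                     "llf": fit.llf, "aic": fit.aic, "bic": fit.bic,
                     "converged": fit.converged})
    table = pd.DataFrame(rows)
    comparable = table[table["converged"]]
    table["best_aic"] = False
    table["best_bic"] = False
    if not comparable.empty:
        table.loc[comparable["aic"].idxmin(), "best_aic"] = True
        table.loc[comparable["bic"].idxmin(), "best_bic"] = True
    return table


def attrition_table(baseline: pd.DataFrame, status: pd.Series,
                    labels: pd.Series,
                    variables: dict[str, str] | None = None,
                    ) -> tuple[pd.DataFrame, list[CrosstabResult]]:
    """Compare baseline characteristics across follow-up status groups
    (participant / dropout / deceased).

    ``variables`` maps column name -> kind (categorical / normal /
    nonnormal); the cluster-by-status comparison is always included.
    Returns the per-variable test summary and the full results.  Empty
    status groups are omitted with a warning."""
    base = baseline.set_index("subject_id")
    st = status.reindex(base.index)
    if st.isna().any():
        raise ValueError("status missing for some subjects")
    counts = st.value_counts()
    for g in ("participant", "dropout", "deceased"):
        if counts.get(g, 0) == 0:
            logger.warning("attrition: status group %r is empty", g)
    if variables is None:
        variables = {}

    results: list[CrosstabResult] = []
    cl = labels.reindex(base.index).astype(str)
    for var, series, kind in [("cluster", cl, "categorical")] + [
            (v, base[v], k) for v, k in variables.items()]:
        try:
            results.append(crosstab_compare(series, st.to_numpy(), kind,
                                            name=var))
        except ValueError as e:
            logger.warning("attrition: %s not testable (%s)", var, e)
            results.append(CrosstabResult(var, "none", float("nan"),
                                          float("nan"), float("nan"),
                                          pd.DataFrame()))
    summary = pd.DataFrame([{"variable": r.variable, "test": r.test,
                             "statistic": r.statistic, "df": r.df, "p": r.p}
                            for r in results])
    return summary, results
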
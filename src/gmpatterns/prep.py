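"""Morphometry preparation: from raw regional tables to the 41-feature
analysis matrix, plus the derived clinical indicators.

Steps, in pipeline order: average left/right hemisphere measures, regress
subcortical volumes on total intracranial volume (TIV) and keep the
residuals, compute surface-area-weighted cortical signatures, apply the
fixed tertile schemes and dichotomization cutoffs, and standardize the
cognitive battery against baseline means and SDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rois import (
    AD_SIGNATURE_ROIS,
    ALL_ROIS,
    COGNITIVE_DOMAINS,
    CORTICAL_ROIS,
    RESILIENCE_SIGNATURE_ROIS,
    SUBCORTICAL_ROIS,
)

logger = logging.getLogger("gmpatterns")

__all__ = [
    "average_hemispheres",
    "adjust_volumes_for_tiv",
    "build_feature_matrix",
    "compute_signatures",
    "categorize_tertiles",
    "TERTILE_SCHEMES",
    "derive_risk_indicators",
    "standardize_cognition",
]

HEMI_PREFIXES = (("lh_", "rh_"), ("Left-", "Right-"), ("left_", "right_"))


def _strip_hemi(col: str) -> tuple[str, str] | None:
    """Return (side, roi) if the column carries a hemisphere prefix."""
    for i, (lh, rh) in enumerate(HEMI_PREFIXES):
        if col.startswith(lh):
            return "lh", col[len(lh):]
        if col.startswith(rh):
            return "rh", col[len(rh):]
    return None


def average_hemispheres(table: pd.DataFrame) -> pd.DataFrame:
    """Average paired left/right columns into one column per ROI.

    Accepts FreeSurfer-style prefixes (``lh_``/``rh_``, ``Left-``/
    ``Right-``).  Already-averaged columns pass through untouched, making
    the operation idempotent.  Unpaired hemisphere columns are an error.
    """
    sides: dict[str, dict[str, str]] = {}
    passthrough: list[str] = []
    for col in table.columns:
        hit = _strip_hemi(col)
        if hit is None:
            passthrough.append(col)
        else:
            side, roi = hit
            sides.setdefault(roi, {})[side] = col

    orphans = [cols[s] for roi, cols in sides.items()
               for s in cols if len(cols) != 2]
    if orphans:
        raise ValueError(f"unpaired hemisphere columns: {sorted(orphans)}")

    out = table[passthrough].copy()
    for roi, cols in sides.items():
        out[roi] = (table[cols["lh"]].to_numpy()
                    + table[cols["rh"]].to_numpy()) / 2.0
    return out


def _tiv_residuals(y: np.ndarray, tiv: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, TIV] by least squares over complete cases."""
    out = np.full_like(y, np.nan, dtype=float)
    ok = np.isfinite(y) & np.isfinite(tiv)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete cases to fit the TIV regression")
    t = tiv[ok]
    if np.ptp(t) == 0:
        raise ValueError("TIV is constant across subjects; regression is degenerate")
    X = np.column_stack([np.ones(ok.sum()), t])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out[ok] = y[ok] - X @ beta
    return out


def adjust_volumes_for_tiv(table: pd.DataFrame,
                           volume_cols: tuple[str, ...] = SUBCORTICAL_ROIS,
                           tiv_col: str = "tiv") -> pd.DataFrame:
    """Replace each volume column by residuals from its simple linear
    regression on TIV (intercept included).  Thickness columns pass
    through unchanged; subjects with missing TIV get missing residuals.
    """
    if tiv_col not in table.columns:
        raise ValueError(f"missing TIV column {tiv_col!r}: cannot adjust volumes")
    out = table.copy()
    tiv = table[tiv_col].to_numpy(dtype=float)
    for col in volume_cols:
        if col in out.columns:
            out[col] = _tiv_residuals(table[col].to_numpy(dtype=float), tiv)
    return out


def build_feature_matrix(table: pd.DataFrame,
                         tiv_col: str = "tiv") -> pd.DataFrame:
    """Hemisphere-average (if needed) and TIV-adjust, returning the n x 41
    feature matrix indexed by subject_id in canonical ROI order."""
    t = average_hemispheres(table)
    missing = [r for r in ALL_ROIS if r not in t.columns]
    if missing:
        raise ValueError(f"missing ROI columns: {missing}")
    if t["subject_id"].duplicated().any():
        raise ValueError("duplicated subject_id values")
    t = adjust_volumes_for_tiv(t, tiv_col=tiv_col)
    return t.set_index("subject_id")[list(ALL_ROIS)]


def compute_signatures(table: pd.DataFrame,
                       area_suffix: str = "_area",
                       ad_rois: tuple[str, ...] = AD_SIGNATURE_ROIS,
                       resilience_rois: tuple[str, ...] = RESILIENCE_SIGNATURE_ROIS,
                       ) -> pd.DataFrame:
    """Surface-area-weighted cortical signatures.

    For a region set R, the signature is sum(area_r * thickness_r) /
    sum(area_r) per subject; with equal areas this reduces to the plain
    mean.  Missing area columns fall back to equal weights with a log
    note.  Returns mean_thickness, ad_signature, resilience_signature and
    (if present) hippocampus.
    """
    def weighted(rois: tuple[str, ...], label: str) -> pd.Series:
        missing = [r for r in rois if r not in table.columns]
        if missing:
            logger.warning("signature %s: missing ROI columns %s", label, missing)
            rois = tuple(r for r in rois if r not in missing)
            if not rois:
                return pd.Series(np.nan, index=table.index)
        th = table[list(rois)].to_numpy(dtype=float)
        acols = [r + area_suffix for r in rois]
        if all(a in table.columns for a in acols):
            w = table[acols].to_numpy(dtype=float)
        else:
            logger.info("signature %s: no surface areas, using equal weights", label)
            w = np.ones_like(th)
        return pd.Series((th * w).sum(axis=1) / w.sum(axis=1), index=table.index)

    out = pd.DataFrame(index=table.index)
    out["mean_thickness"] = weighted(CORTICAL_ROIS, "mean_thickness")
    out["ad_signature"] = weighted(ad_rois, "ad_signature")
    out["resilience_signature"] = weighted(resilience_rois, "resilience_signature")
    if "hippocampus" in table.columns:
        out["hippocampus"] = table["hippocampus"]
    return out


@dataclass(frozen=True)
class TertileScheme:
    """Fixed (not data-driven) cutpoints; the middle interval is closed, so
    a value equal to either printed boundary falls in T2."""

    name: str
    lower: float  # T1 below, T2 from here
    upper: float  # T2 up to here, T3 above

    def assign(self, value: float) -> str | float:
        if value is None or not np.isfinite(value):
            return np.nan
        if value < self.lower:
            return "T1"
        if value <= self.upper:
            return "T2"
        return "T3"


#: Printed tertile cutpoints: lesion burden (TIV-normalized WMHV),
#: skeleton fractional anisotropy, and LDL cholesterol (mmol/L).  The LDL
#: notation (T1 <= 3, T2 = 3.1-3.9, T3 >= 4) leaves the gaps 3-3.1 and
#: 3.9-4 unassigned; both go to T2, consistent with the closed middle
#: interval used for the other schemes.
TERTILE_SCHEMES: dict[str, TertileScheme] = {
    "WMHV": TertileScheme("WMHV", 2.7, 5.5),
    "FA": TertileScheme("FA", 0.3, 0.4),
    "LDL": TertileScheme("LDL", 3.0 + 1e-12, 4.0 - 1e-12),
}
# LDL: T1 is printed "<= 3" (boundary in T1) and T3 ">= 4" (boundary in
# T3); represent by nudging the cutpoints by an epsilon well below the
# measurement resolution (0.1 mmol/L).


def categorize_tertiles(values, scheme: str):
    """Map continuous values to T1/T2/T3 under a registered fixed scheme."""
    if scheme not in TERTILE_SCHEMES:
        raise ValueError(f"unknown tertile scheme {scheme!r}; "
                         f"registered: {sorted(TERTILE_SCHEMES)}")
    s = TERTILE_SCHEMES[scheme]
    if np.isscalar(values):
        return s.assign(float(values))
    arr = pd.Series(values, dtype=float)
    return arr.map(s.assign)


#: Dichotomization cutoffs, verbatim from the study protocol.
CUTOFFS = {
    "overweight_bmi": 25.0,          # kg/m^2, >=
    "alcohol_g_week": 100.0,         # g/week, >=
    "sbp": 140.0,                    # mmHg, >=
    "dbp": 90.0,                     # mmHg, >=
    "triglycerides": 1.7,            # mmol/L, >=
    "hdl_men": 1.03,                 # mmol/L, < (low)
    "hdl_women": 1.29,               # mmol/L, < (low)
    "homocysteine": 13.5,            # umol/L, > (elevated)
    "crp": 8.0,                      # mg/L, >= (high)
    "abeta42": 530.0,                # pg/mL, <= (amyloid-positive)
    "ttau": 350.0,                   # pg/mL, >= (positive)
    "ptau": 80.0,                    # pg/mL, >= (positive)
}


def derive_risk_indicators(cov: pd.DataFrame) -> pd.DataFrame:
    """Apply the printed dichotomizations to a raw covariate table.

    Recognized input columns (all optional): bmi, alcohol_g_week, sbp,
    dbp, antihypertensive, triglycerides, lipid_lowering, hdl, sex_female,
    homocysteine, crp, abeta42, ttau, ptau, wmhv, fa, ldl, smoking_ever,
    physical_inactivity.  Missing values propagate as missing flags.
    """
    def ge(x, c):
        return np.where(np.isfinite(x), (x >= c).astype(float), np.nan)

    def gt(x, c):
        return np.where(np.isfinite(x), (x > c).astype(float), np.nan)

    def le(x, c):
        return np.where(np.isfinite(x), (x <= c).astype(float), np.nan)

    out = pd.DataFrame(index=cov.index)
    c = CUTOFFS

    if "bmi" in cov:
        bmi = cov["bmi"].to_numpy(dtype=float)
        if np.any(bmi[np.isfinite(bmi)] <= 0):
            raise ValueError("BMI must be strictly positive")
        out["overweight"] = ge(bmi, c["overweight_bmi"])
    if "alcohol_g_week" in cov:
        out["alcohol_atrisk"] = ge(cov["alcohol_g_week"].astype(float), c["alcohol_g_week"])
    if "sbp" in cov and "dbp" in cov:
        bp = np.fmax(ge(cov["sbp"].astype(float), c["sbp"]),
                     ge(cov["dbp"].astype(float), c["dbp"]))
        if "antihypertensive" in cov:
            bp = np.fmax(bp, cov["antihypertensive"].astype(float))
        out["hypertension"] = bp
    if "triglycerides" in cov:
        tg = ge(cov["triglycerides"].astype(float), c["triglycerides"])
        if "lipid_lowering" in cov:
            tg = np.fmax(tg, cov["lipid_lowering"].astype(float))
        out["triglycerides_high"] = tg
    if "hdl" in cov and "sex_female" in cov:
        thr = np.where(cov["sex_female"].astype(float) > 0,
                       c["hdl_women"], c["hdl_men"])
        hdl = cov["hdl"].to_numpy(dtype=float)
        out["hdl_low"] = np.where(np.isfinite(hdl), (hdl < thr).astype(float), np.nan)
    if "homocysteine" in cov:
        out["homocysteine_high"] = gt(cov["homocysteine"].astype(float), c["homocysteine"])
    if "crp" in cov:
        out["crp_high"] = ge(cov["crp"].astype(float), c["crp"])
    if "abeta42" in cov:
        out["abeta_pos"] = le(cov["abeta42"].astype(float), c["abeta42"])
    if "ttau" in cov:
        out["ttau_pos"] = ge(cov["ttau"].astype(float), c["ttau"])
    if "ptau" in cov:
        out["ptau_pos"] = ge(cov["ptau"].astype(float), c["ptau"])
    for name, scheme in (("wmhv", "WMHV"), ("fa", "FA"), ("ldl", "LDL")):
        if name in cov:
            out[f"{name}_tertile"] = categorize_tertiles(cov[name], scheme)
    for flag in ("smoking_ever", "physical_inactivity"):
        if flag in cov:
            out[flag] = cov[flag].astype(float)

    for col in out.columns:
        n_miss = int(pd.isna(out[col]).sum())
        if n_miss:
            logger.info("derived indicator %s: %d missing", col, n_miss)
    return out


def standardize_cognition(baseline: pd.DataFrame,
                          followup: pd.DataFrame | None = None,
                          domains: dict[str, list[str]] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """z-score the cognitive battery against baseline means and SDs.

    ``domains`` maps each domain to its constituent test columns (default:
    each canonical domain is its own single test).  Each test is z-scored
    with the baseline mean/SD; domain scores average the constituent test
    z-scores; the global composite is the mean of the five domain scores.
    Follow-up scores are standardized with the *baseline* parameters.
    """
    if domains is None:
        domains = {d: [d] for d in COGNITIVE_DOMAINS}
    tests = sorted({t for ts in domains.values() for t in ts})
    params: dict[str, tuple[float, float]] = {}
    for t in tests:
        col = baseline[t].astype(float)
        if col.notna().sum() < 2:
            raise ValueError(f"test {t!r}: need >= 2 non-missing baseline values")
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0:
            raise ValueError(f"test {t!r}: zero baseline SD")
        params[t] = (mu, sd)

    def apply(tab: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=tab.index)
        for dom, ts in domains.items():
            zs = [(tab[t].astype(float) - params[t][0]) / params[t][1] for t in ts]
            out[dom] = pd.concat(zs, axis=1).mean(axis=1)
        out["global_cognition"] = out[list(domains)].mean(axis=1)
        return out

    base_z = apply(baseline)
    fu_z = apply(followup) if followup is not None else None
    return base_z, fu_z
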
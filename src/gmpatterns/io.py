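"""Table readers/writers, run configuration and the end-to-end pipeline.

Everything is delimited text: cohort tables in/out as CSV/TSV, the run
configuration and provenance manifest as YAML.  A run writes every stage
artifact into one directory; the same config and seed reproduce
byte-identical label and effect-map files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import MODEL_REGISTRY, fit_cognition_models, fit_multinomial
from .cluster import (
    ClusterSolution,
    ForestParams,
    cluster_features,
    stability_gap,
)
from .effects import roi_effect_table
from .longitudinal import (
    LongitudinalSpec,
    attrition_table,
    compare_random_effect_structures,
    fdr_across_outcomes,
    fit_longitudinal_model,
    make_long_table,
)
from .prep import build_feature_matrix, derive_risk_indicators, standardize_cognition
from .rois import ALL_ROIS, COGNITIVE_DOMAINS
from .synthetic import SyntheticCohort, default_paper_config, generate_cohort

logger = logging.getLogger("gmpatterns")

__all__ = [
    "RunConfig",
    "read_cohort_tables",
    "write_cohort",
    "run_pipeline",
]

EXIT_VALIDATION = 2
EXIT_CONVERGENCE = 3


@dataclass
class RunConfig:
    """One reproducible run.  Either ``scenario`` names a synthetic
    scenario or ``baseline_path``/``followup_path`` point at cohort
    tables."""

    output_dir: str = "gmpatterns_run"
    scenario: str | None = "paper-default"
    baseline_path: str | None = None
    followup_path: str | None = None
    n_subjects: int = 746
    ntree: int = 1000
    mtry: int = 6
    nodesize: int = 3
    k_min: int = 2
    k_max: int = 8
    k_forced: int | None = None
    mds_dims: int = 3
    #: "largest" (default) or an explicit cluster id
    reference_policy: str = "largest"
    models: tuple[str, ...] = ("clinical", "neuroimaging", "inflammation", "csf")
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        d = asdict(self)
        d["models"] = list(d["models"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def forest_params(self) -> ForestParams:
        return ForestParams(ntree=self.ntree, mtry=self.mtry,
                            nodesize=self.nodesize, seed=self.seed)

    def reference_cluster(self, labels: np.ndarray) -> int:
        if self.reference_policy == "largest":
            vals, counts = np.unique(labels, return_counts=True)
            return int(vals[np.argmax(counts)])
        return int(self.reference_policy)


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _read_table(path: str | Path, mapping: dict[str, str] | None = None
                ) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    t = pd.read_csv(path, sep=sep)
    if mapping:
        t = t.rename(columns=mapping)
    return t


def read_cohort_tables(baseline_path: str | Path,
                       followup_path: str | Path | None = None,
                       mapping: dict[str, str] | str | Path | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read baseline (and optionally follow-up) cohort tables.

    Accepts wide per-subject tables, or long stats-exporter layout with
    columns (subject_id, roi, hemisphere, value) which is pivoted to wide
    ``{lh,rh}_roi`` columns.  ``mapping`` renames vendor columns to the
    canonical ROI vocabulary (dict, or path to a two-column CSV).
    """
    if isinstance(mapping, (str, Path)):
        m = pd.read_csv(mapping)
        mapping = dict(zip(m.iloc[:, 0], m.iloc[:, 1]))
    base = _read_table(baseline_path, mapping)
    if {"roi", "hemisphere", "value"}.issubset(base.columns):
        base = (base.pivot_table(index="subject_id",
                                 columns=["hemisphere", "roi"], values="value")
                .pipe(lambda t: t.set_axis(
                    [f"{h}_{r}" for h, r in t.columns], axis=1))
                .reset_index())
    if "subject_id" not in base.columns:
        raise ValueError("baseline table lacks mandatory column 'subject_id'")
    if base["subject_id"].duplicated().any():
        dupes = base.loc[base["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes[:5]}")
    known = set(ALL_ROIS) | {"subject_id", "tiv"}
    unknown = [c for c in base.columns
               if c not in known and not c.startswith(("lh_", "rh_", "Left-", "Right-"))]
    if unknown:
        logger.info("preserving %d non-canonical columns: %s ...",
                    len(unknown), unknown[:8])
    fu = _read_table(followup_path, mapping) if followup_path else None
    return base, fu


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write baseline/follow-up tables, the ground-truth sidecar and the
    config echo as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"baseline": out / "baseline.csv",
             "truth": out / "true_labels.csv",
             "config": out / "cohort_config.yaml"}
    cohort.baseline_table.to_csv(paths["baseline"], index=False)
    cohort.true_labels.rename("true_label").to_csv(paths["truth"])
    cfg = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
           for k, v in asdict(cohort.config).items()
           if k not in ("covariate_specs",)}
    cfg["slope_effects"] = {k: list(map(float, v))
                            for k, v in cohort.config.slope_effects.items()}
    cfg["covariate_specs"] = [asdict(s) for s in cohort.config.covariate_specs]
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    if cohort.followup_table is not None:
        paths["followup"] = out / "followup.csv"
        cohort.followup_table.to_csv(paths["followup"], index=False)
    if cohort.status is not None:
        paths["status"] = out / "followup_status.csv"
        cohort.status.to_csv(paths["status"])
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _float_format(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run_pipeline(config: RunConfig) -> Path:
    """Execute prep -> clustering -> effect maps -> associations ->
    longitudinal on a synthetic scenario or user tables, writing every
    artifact plus a provenance manifest into the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": yaml.safe_load(config.to_yaml()),
                      "software": {"gmpatterns": __version__,
                                   "numpy": np.__version__,
                                   "pandas": pd.__version__},
                      "stages": {}, "failed_stage": None}
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, index=index, float_format="%.10g")
        artifacts[name] = p

    try:
        # ---- stage: cohort / prep -------------------------------------
        if config.scenario is not None:
            cc = default_paper_config(n_subjects=config.n_subjects,
                                      seed=config.seed)
            if config.scenario == "paper-default":
                pass
            elif config.scenario == "null":
                cc = cc.replace(roi_effects=np.zeros_like(cc.roi_effects))
            else:
                raise ValueError(f"unknown scenario {config.scenario!r}")
            cohort = generate_cohort(cc)
            write_cohort(cohort, out / "cohort")
            baseline = cohort.baseline_table
            followup = cohort.followup_table
            status = cohort.status
        else:
            baseline, followup = read_cohort_tables(config.baseline_path,
                                                    config.followup_path)
            status = None
        features = build_feature_matrix(baseline)
        save("feature_matrix", features, index=True)
        manifest["stages"]["prep"] = {"n_subjects": len(features)}

        # ---- stage: clustering ----------------------------------------
        sol = cluster_features(
            features, params=config.forest_params(),
            k_range=tuple(range(config.k_min, config.k_max + 1)),
            mds_dims=config.mds_dims, k=config.k_forced)
        labels = pd.Series(sol.labels, index=features.index, name="cluster")
        save("labels", labels.reset_index())
        save("validity_table", sol.validity_table)
        save("importance", pd.DataFrame({"roi": list(features.columns),
                                         "importance": sol.importance}))
        save("mds_coordinates",
             pd.DataFrame(sol.mds_coordinates, index=features.index,
                          columns=[f"mds{i+1}" for i in
                                   range(sol.mds_coordinates.shape[1])]),
             index=True)
        manifest["stages"]["cluster"] = {"k": sol.k,
                                         "sizes": np.bincount(sol.labels)[1:].tolist()}

        # ---- stage: effect maps ---------------------------------------
        reference = config.reference_cluster(sol.labels)
        eff = roi_effect_table(features, sol.labels, reference=reference)
        save("effect_maps", eff)
        manifest["stages"]["effects"] = {
            "reference": reference,
            "n_discriminative": int(eff["discriminative"].sum())}

        # ---- stage: associations --------------------------------------
        cog_base, _ = standardize_cognition(baseline.set_index("subject_id"))
        indicators = derive_risk_indicators(baseline.set_index("subject_id"))
        assoc_data = pd.concat([baseline.set_index("subject_id"), indicators
                                .drop(columns=[c for c in indicators
                                               if c in baseline.columns])],
                               axis=1)
        records = []
        for mname in config.models:
            spec = MODEL_REGISTRY[mname]
            try:
                records.append(fit_multinomial(assoc_data, labels, spec,
                                               reference=reference))
            except (ValueError, RuntimeError) as e:
                logger.warning("model %s skipped: %s", mname, e)
        if records:
            save("associations", pd.concat(records, ignore_index=True))
        cogm = fit_cognition_models(cog_base, labels.loc[cog_base.index],
                                    reference=reference)
        save("cognition_models", cogm)
        manifest["stages"]["association"] = {"models": list(config.models)}

        # ---- stage: longitudinal --------------------------------------
        if followup is not None:
            outcomes = tuple(c for c in followup.columns
                             if c not in ("subject_id", "years"))
            long = make_long_table(baseline, followup, outcomes, labels)
            lspec = LongitudinalSpec(outcomes=outcomes)
            fits = [fit_longitudinal_model(long, o, lspec) for o in outcomes]
            slopes = fdr_across_outcomes(fits)
            save("slope_contrasts", slopes)
            comp = pd.concat([compare_random_effect_structures(long, o, lspec)
                              for o in outcomes[:3]], ignore_index=True)
            save("random_structure_comparison", comp)
            if status is not None:
                summary, _ = attrition_table(baseline, status, labels)
                save("attrition", summary)
            manifest["stages"]["longitudinal"] = {"n_outcomes": len(outcomes)}
    except Exception as e:
        manifest["failed_stage"] = repr(e)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
        raise

    manifest["checksums"] = {k: _sha256(p) for k, p in sorted(artifacts.items())}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    _write_data_dictionary(out)
    return out


def _write_data_dictionary(out: Path) -> None:
    dd = {
        "labels.csv": "subject_id; cluster (1..k, 1 = largest)",
        "feature_matrix.csv": "subject_id; 41 hemisphere-averaged, "
                              "TIV-adjusted morphometry features",
        "validity_table.csv": "k; dunn; calinski_harabasz; composite (mean z)",
        "importance.csv": "roi; mean impurity-decrease importance",
        "mds_coordinates.csv": "subject_id; classical MDS coordinates",
        "effect_maps.csv": "roi; cluster; d; t; p; p_adj; discriminative",
        "associations.csv": "model; predictor; contrast; OR; ci_low; "
                            "ci_high; p; n",
        "cognition_models.csv": "outcome; cluster; beta; se; p; n",
        "slope_contrasts.csv": "outcome; cluster; beta_slope; se; p; p_adj",
        "random_structure_comparison.csv": "outcome; structure; llf; aic; "
                                           "bic; converged; best_aic; best_bic",
        "attrition.csv": "variable; test; statistic; df; p",
    }
    (out / "data_dictionary.yaml").write_text(yaml.safe_dump(dd, sort_keys=True))
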
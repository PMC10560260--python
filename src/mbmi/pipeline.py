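"""End-to-end orchestration: simulate -> preprocess -> fit -> score -> associate.

Every run writes plain-text artifacts plus a machine-readable manifest
(parameters, seeds, package version, SHA-256 of each output) so any output is
reproducible from its manifest alone and any stage can be swapped for a
hand-built fixture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from . import synthetic, qc, regression, scoring, associations
from .tables import LipidTable, write_phenotypes


@dataclass
class RunConfig:
    """Parameters of one pipeline run (also loadable from YAML)."""

    out_dir: str = "mbmi_run"
    seed: int = 0
    # simulate
    n_samples: int = 2000
    n_species: int = 575
    signal_r2: float = 0.6
    delta_effect: float = 0.5
    batch_cv: float = 0.10
    qc_replicates: int = 200
    # fit
    penalty: str = "ridge"
    lam: float | str = "optimize"
    folds: int = 10
    inner_folds: int = 5
    # score
    assumed_qc_bmi: float = 26.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis on a synthetic cohort; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        gen_cfg = synthetic.GeneratorConfig(
            n_samples=config.n_samples, n_species=config.n_species,
            n_classes=min(33, config.n_species),
            signal_r2=config.signal_r2, delta_effect=config.delta_effect,
            batch_cv=config.batch_cv, qc_replicates=config.qc_replicates,
            seed=config.seed,
        )
        cohort = synthetic.generate_cohort(gen_cfg)
        cohort.lipids.write(out / "cohort")
        write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")

        stage = "preprocess"
        corrected = qc.batch_median_center(cohort.lipids)
        _, cv_summary = qc.compute_cv(corrected, group="PQC")

        stage = "fit"
        pheno = cohort.phenotypes
        features = pd.concat(
            [corrected.cohort().data.loc[pheno.index], pheno[["age", "sex"]]],
            axis=1)
        spec = regression.ModelSpec(
            penalty=config.penalty, lam=config.lam, folds=config.folds,
            inner_folds=config.inner_folds, seed=config.seed)
        cvp = regression.crossval_predict(features, pheno["bmi"], spec)
        cv_r2 = regression.variance_explained(cvp.pbmi, pheno["bmi"])
        model = regression.fit_bmi_model(
            features, pheno["bmi"], spec,
            lam=cvp.lambda_mean if config.lam == "optimize" else None)

        stage = "score"
        line = scoring.fit_reference_line(cvp.pbmi, pheno["bmi"])
        model.reference_line = line.to_dict()
        model.to_json(out / "model.json")
        scores = scoring.compute_mbmi(pheno["bmi"], cvp.pbmi, line)
        scores.index = pheno.index
        scores["quintile"], quintile_sizes = scoring.assign_quintiles(
            scores["mbmi_delta"])
        scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample_id")

        nist = corrected.subset(sample_type="NIST")
        qc_precision = None
        if nist.n_samples >= 2:
            nist_features = nist.data.copy()
            nist_features["age"] = 52.5
            nist_features["sex"] = 0.55
            nist_pbmi = regression.external_apply(model, nist_features)
            nist_scores = scoring.compute_mbmi(
                np.full(len(nist_pbmi), config.assumed_qc_bmi), nist_pbmi, line)
            qc_precision = scoring.score_precision(nist_scores["mbmi"])

        stage = "associate"
        cohort_lipids = corrected.cohort().data.loc[pheno.index]
        covars = pheno[["age", "sex"]]
        rec_bmi = associations.lipid_association(cohort_lipids, pheno["bmi"], covars)
        rec_delta = associations.lipid_association(
            cohort_lipids, scores["mbmi_delta"], covars)
        mirror = associations.coefficient_mirror(rec_bmi, rec_delta)
        rec_bmi.to_csv(out / "associations_bmi.tsv", sep="\t")
        rec_delta.to_csv(out / "associations_mbmi_delta.tsv", sep="\t")

        stage = "outcomes"
        adj = pheno[["age", "sex", "bmi"]]
        or_quintiles = associations.outcome_logistic(
            pheno["t2dm_prev"], scores["quintile"], adj)
        or_quintiles.drop(columns=["covariates", "flags"]).to_csv(
            out / "t2dm_odds_ratios.tsv", sep="\t")
        incident_free = pheno["t2dm_prev"] == 0
        nested = associations.nested_model_comparison(
            pheno["t2dm_prev"], adj, scores["mbmi_delta"])
        cox = associations.outcome_cox(
            pheno.loc[incident_free, "cve_incident"],
            pheno.loc[incident_free, "age"],
            pheno.loc[incident_free, "age"] + pheno.loc[incident_free, "cve_time"],
            scores.loc[incident_free, "mbmi_delta"],
            pheno.loc[incident_free, ["sex", "bmi", "smoking"]])

        stage = "report"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": {k: v for k, v in asdict(config).items()},
            "n_excluded_prevalent_t2dm": int((~incident_free).sum()),
            "results": {
                "median_qc_cv_pct": cv_summary["median_cv"],
                "fraction_species_cv_below_20": cv_summary["fraction_below_20"],
                "cv_r2_pbmi_bmi": cv_r2,
                "lambda_mean": cvp.lambda_mean,
                "lambda_range": list(cvp.lambda_range),
                "reference_line": line.to_dict(),
                "quintile_sizes": quintile_sizes,
                "nist_mbmi_cv_pct": qc_precision,
                "mirror_r_squared": mirror.r_squared,
                "mirror_amplification": mirror.amplification,
                "or_q5_vs_q1_t2dm": float(or_quintiles.loc["Q5 vs Q1", "estimate"]),
                "hr_cve_per_unit_mbmi_delta": float(cox["estimate"].iloc[0]),
                "aic_with_mbmi_delta": nested.aic_with,
                "aic_without_mbmi_delta": nested.aic_without,
                "lrt_p": nested.lrt_p,
            },
        }
        outputs = sorted(p for p in out.iterdir() if p.suffix in (".tsv", ".json"))
        manifest["outputs"] = {p.name: _sha256(p) for p in outputs}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
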
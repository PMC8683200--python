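"""End-to-end analysis orchestration.

``run_full_analysis`` wires the stages together — univariate behavioral
report, SNV filtering cascade, leave-one-out AUC grid selection, lasso
refit with selective inference — and writes a deterministic report bundle:

* ``table1.tsv`` — univariate associations,
* ``filter_report.json`` — cascade accounting,
* ``cv_grid.tsv`` — (alpha, lambda, log lambda, pooled LOO AUC) grid,
* ``table2.tsv`` — adjusted odds ratios and selective p-values,
* ``run_log.json`` — every effective parameter plus the seed.

Identical config and inputs produce byte-identical outputs; partial outputs
are removed if a stage fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .cv import DEFAULT_ALPHAS, grid_search
from .filters import DEFAULT_COVARIATES, filter_pipeline
from .inference import table2_report
from .simulate import SyntheticCohortSpec, generate_cohort, study_mirror_fixture
from .univariate import table1_report

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    genotype_path: str | None = None
    phenotype_path: str | None = None
    genotype_format: str = "tsv"
    study_mirror: bool = False
    synthetic: bool = False
    variation_threshold: float = 0.02
    missingness_threshold: float = 0.05
    audit_cutoff: float = 8
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    n_lambda: int = 100
    min_ratio: float = 0.01
    outcome_positive: str = "ex_smoker"
    or_source: str = "debiased"
    impute: str = "mode"
    seed: int = 2021
    out_dir: str = "snvnet_out"

    def validate(self) -> None:
        problems = []
        if not (self.study_mirror or self.synthetic):
            if not self.genotype_path or not self.phenotype_path:
                problems.append(
                    "genotype_path/phenotype_path: required unless study_mirror or synthetic"
                )
        for name in ("variation_threshold", "missingness_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                problems.append(f"{name}: must be in (0, 1), got {v}")
        if not 0 < self.audit_cutoff <= 40:
            problems.append(f"audit_cutoff: must be in (0, 40], got {self.audit_cutoff}")
        if not self.alphas or any(not 0 <= a <= 1 for a in self.alphas):
            problems.append(f"alphas: must be a non-empty subset of [0, 1], got {self.alphas}")
        if self.n_lambda < 1:
            problems.append(f"n_lambda: must be >= 1, got {self.n_lambda}")
        if not 0 < self.min_ratio < 1:
            problems.append(f"min_ratio: must be in (0, 1), got {self.min_ratio}")
        if self.outcome_positive not in ("ex_smoker", "smoker"):
            problems.append(f"outcome_positive: unknown value {self.outcome_positive!r}")
        if self.or_source not in ("debiased", "lasso"):
            problems.append(f"or_source: unknown value {self.or_source!r}")
        if self.impute not in ("mode", "mean"):
            problems.append(f"impute: unknown value {self.impute!r}")
        if problems:
            raise ValueError("invalid config:\n  " + "\n  ".join(problems))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config: unknown fields {sorted(unknown)}")
        for tup in ("covariates", "alphas"):
            if tup in data:
                data[tup] = tuple(data[tup])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["alphas"] = list(self.alphas)
        return d


def _load_inputs(config: RunConfig):
    if config.study_mirror:
        return study_mirror_fixture(seed=config.seed)
    if config.synthetic:
        return generate_cohort(SyntheticCohortSpec(seed=config.seed))
    G = cio.read_genotype_matrix(config.genotype_path, format=config.genotype_format)
    pheno = cio.read_phenotypes(config.phenotype_path)
    return G, pheno


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory results (table1 rows, design, filter
    report, CV result, inference rows) and the paths written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, payload, fmt: str) -> Path:
        path = out / name
        cio.write_report(payload, path, format=fmt)
        written.append(path)
        return path

    try:
        G, pheno = _load_inputs(config)

        table1 = table1_report(pheno)
        emit("table1.tsv", [r.to_record() for r in table1], "tsv")

        design, filt = filter_pipeline(
            G,
            pheno,
            variation_threshold=config.variation_threshold,
            missingness_threshold=config.missingness_threshold,
            covariates=config.covariates,
            outcome_positive=config.outcome_positive,
            impute=config.impute,
            audit_cutoff=config.audit_cutoff,
        )
        emit("filter_report.json", filt.to_dict(), "json")

        cv = grid_search(
            design.X,
            design.y,
            alphas=config.alphas,
            n_lambda=config.n_lambda,
            min_ratio=config.min_ratio,
        )
        emit("cv_grid.tsv", cv.grid_records(), "tsv")

        n_cov = len(config.covariates)
        label_by_id = {s.id: s.label for s in G.snvs}
        labels = list(config.covariates) + [
            label_by_id[sid] for sid in design.predictor_names[n_cov:]
        ]
        rows, fit = table2_report(
            design.X, design.y, cv, labels, n_covariates=n_cov, or_source=config.or_source
        )
        emit("table2.tsv", [r.to_record() for r in rows], "tsv")

        import numpy as _np

        emit(
            "run_log.json",
            {
                "config": config.to_dict(),
                "n_samples": G.n_samples,
                "n_snvs": G.n_snvs,
                "n_complete_case": filt.n_complete_case,
                "n_retained_snvs": filt.n_retained_snvs,
                "best_alpha": cv.best_alpha,
                "best_lambda": cv.best_lam,
                "best_log_lambda": float(_np.log(cv.best_lam)),
                "best_loo_auc": cv.best_auc,
                "inference_lambda": fit.lam,
                "n_selected": len(rows),
                "fit_converged": bool(fit.converged),
            },
            "json",
        )
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return {
        "table1": table1,
        "design": design,
        "filter_report": filt,
        "cv": cv,
        "table2": rows,
        "fit": fit,
        "out_dir": str(out),
    }
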
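"""SNV filtering cascade and regression design construction.

The cascade reduces the raw candidate-gene variant panel to a regression-ready
design in a fixed stage order:

1. **complete-case** — drop participants missing any regression covariate
   (default set: hazardous alcohol via AUDIT, past-30-day marijuana use,
   past-30-day cocaine use, GAD-7 anxiety score);
2. **variation filter** — drop SNVs whose non-modal genotype fraction among
   non-missing calls (computed on the complete-case samples) is below 2%;
3. **missingness filter** — drop SNVs with >= 5% missing calls;
4. **duplicate collapse** — among SNVs with identical genotype vectors over
   the complete-case samples, keep the lexicographically first id.

Each input SNV is accounted to exactly one stage in the
:class:`FilterReport`. Retained SNVs enter the design as additive 0/1/2
dosages; residual missing calls (< 5% per column by construction) are imputed
to the column's modal genotype so the design stays on {0,1,2} support
(mean-dosage imputation is available behind a flag). The outcome is coded
1 for the group of interest — ex-smokers by default, since the multivariable
model targets long-term nonsmoking status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, OUTCOME_EX_SMOKER, OUTCOME_SMOKER, PhenotypeTable
from .univariate import AUDIT_HAZARDOUS_CUTOFF

__all__ = [
    "FilterReport",
    "DesignMatrix",
    "DEFAULT_COVARIATES",
    "variation_filter",
    "missingness_filter",
    "collapse_identical",
    "complete_case",
    "build_design",
    "filter_pipeline",
]

#: Regression covariates used for complete-case restriction and the design.
DEFAULT_COVARIATES = ("hazardous_alcohol", "marijuana_30d", "cocaine_30d", "gad7")

#: Phenotype column whose presence each covariate requires.
_COVARIATE_SOURCE = {
    "hazardous_alcohol": "audit_score",
    "marijuana_30d": "marijuana_30d",
    "cocaine_30d": "cocaine_30d",
    "gad7": "gad7",
    "cesd": "cesd",
    "age": "age",
}


@dataclass
class FilterReport:
    """Accounting of the filtering cascade; every input SNV lands in one stage."""

    n_input_snvs: int
    n_low_variation: int
    n_high_missing: int
    n_duplicate_collapsed: int
    n_retained_snvs: int
    n_input_samples: int
    n_complete_case: int
    removed_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        total = (
            self.n_low_variation
            + self.n_high_missing
            + self.n_duplicate_collapsed
            + self.n_retained_snvs
        )
        if total != self.n_input_snvs:
            raise ValueError(
                f"filter accounting broken: stages sum to {total}, input {self.n_input_snvs}"
            )
        if self.n_complete_case > self.n_input_samples:
            raise ValueError("complete cases exceed input samples")

    def to_dict(self) -> dict:
        return {
            "n_input_snvs": self.n_input_snvs,
            "n_low_variation": self.n_low_variation,
            "n_high_missing": self.n_high_missing,
            "n_duplicate_collapsed": self.n_duplicate_collapsed,
            "n_retained_snvs": self.n_retained_snvs,
            "n_input_samples": self.n_input_samples,
            "n_complete_case": self.n_complete_case,
            "removed_ids": {k: list(v) for k, v in self.removed_ids.items()},
        }


@dataclass
class DesignMatrix:
    """Complete, missing-free regression design.

    Columns are clinical covariates first, then SNV dosages. ``y`` is 1 for
    the ``outcome_positive`` group.
    """

    sample_ids: list[str]
    predictor_names: list[str]
    X: np.ndarray
    y: np.ndarray
    outcome_positive: str = OUTCOME_EX_SMOKER
    standardization: dict | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape != (len(self.sample_ids), len(self.predictor_names)):
            raise ValueError("design dimensions inconsistent")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary 0/1")


def variation_filter(
    G: GenotypeMatrix, threshold: float = 0.02
) -> tuple[list[str], list[str]]:
    """Split SNV ids into (retained, removed) by non-modal genotype fraction.

    An SNV is removed iff, among its non-missing calls, the fraction of
    genotypes differing from the modal genotype is below ``threshold``.
    SNVs with zero non-missing calls are removed here.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError(f"variation threshold must be in (0, 0.5], got {threshold}")
    retained, removed = [], []
    for j, snv in enumerate(G.snvs):
        col = G.dosage[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            removed.append(snv.id)
            continue
        counts = np.array([(obs == g).sum() for g in (0.0, 1.0, 2.0)])
        nonmodal_frac = 1.0 - counts.max() / obs.size
        (removed if nonmodal_frac < threshold else retained).append(snv.id)
    return retained, removed


def missingness_filter(
    G: GenotypeMatrix, threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Split SNV ids into (retained, removed) by missing-call fraction >= threshold."""
    frac = np.isnan(G.dosage).mean(axis=0)
    retained = [s.id for s, f in zip(G.snvs, frac) if f < threshold]
    removed = [s.id for s, f in zip(G.snvs, frac) if f >= threshold]
    return retained, removed


def collapse_identical(
    G: GenotypeMatrix, samples: list[str] | None = None
) -> tuple[list[str], list[str]]:
    """Collapse SNVs with identical genotype vectors over the given samples.

    Within each group of identical columns (missing compared as equal), the
    lexicographically first id is kept. Identity is judged only over
    ``samples`` (the complete-case set in the pipeline), so two SNVs that
    differ solely on excluded participants still collapse.
    """
    sub = G if samples is None else G.subset(samples=samples)
    coded = np.nan_to_num(sub.dosage, nan=3.0).astype(np.int8)
    groups: dict[bytes, list[str]] = {}
    for j, snv in enumerate(sub.snvs):
        groups.setdefault(coded[:, j].tobytes(), []).append(snv.id)
    retained, removed = [], []
    order = {s.id: j for j, s in enumerate(G.snvs)}
    for ids in groups.values():
        ids_sorted = sorted(ids)
        retained.append(ids_sorted[0])
        removed.extend(ids_sorted[1:])
    retained.sort(key=order.__getitem__)
    removed.sort(key=order.__getitem__)
    return retained, removed


def complete_case(
    pheno: PhenotypeTable, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> list[str]:
    """Sample ids of participants with every listed covariate non-missing."""
    keep = np.ones(len(pheno), dtype=bool)
    for cov in covariates:
        if cov not in _COVARIATE_SOURCE:
            raise ValueError(f"unknown covariate {cov!r}")
        keep &= pheno.df[_COVARIATE_SOURCE[cov]].notna().to_numpy()
    return [s for s, k in zip(pheno.sample_ids, keep) if k]


def _covariate_columns(
    pheno: PhenotypeTable,
    sample_ids: list[str],
    covariates: tuple[str, ...],
    audit_cutoff: float = AUDIT_HAZARDOUS_CUTOFF,
) -> np.ndarray:
    df = pheno.df.set_index("sample_id").loc[sample_ids]
    cols = []
    for cov in covariates:
        if cov == "hazardous_alcohol":
            vals = (df["audit_score"] >= audit_cutoff).astype(float)
        elif cov in ("marijuana_30d", "cocaine_30d"):
            vals = df[cov].astype(float)
        else:
            vals = df[_COVARIATE_SOURCE[cov]].astype(float)
        cols.append(vals.to_numpy(dtype=float))
    return np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))


def build_design(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    retained_snvs: list[str],
    retained_samples: list[str],
    outcome_positive: str = OUTCOME_EX_SMOKER,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    impute: str = "mode",
    audit_cutoff: float = AUDIT_HAZARDOUS_CUTOFF,
) -> DesignMatrix:
    """Assemble the missing-free design: clinical covariates then SNV dosages.

    Residual missing dosages are imputed to the column's modal genotype
    (default) or the column mean (``impute="mean"``).
    """
    if outcome_positive not in (OUTCOME_SMOKER, OUTCOME_EX_SMOKER):
        raise ValueError(f"unknown outcome_positive {outcome_positive!r}")
    missing_samples = set(retained_samples) - set(G.samples)
    if missing_samples:
        raise ValueError(f"samples absent from genotype matrix: {sorted(missing_samples)[:3]}")
    sub = G.subset(samples=retained_samples, snv_ids=retained_snvs)
    dosage = sub.dosage
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        nan = np.isnan(col)
        if not nan.any():
            continue
        obs = col[~nan]
        if obs.size == 0:
            raise ValueError(f"SNV {retained_snvs[j]!r} has no observed calls")
        if impute == "mode":
            counts = [(obs == g).sum() for g in (0.0, 1.0, 2.0)]
            fill = float(np.argmax(counts))
        elif impute == "mean":
            fill = float(obs.mean())
        else:
            raise ValueError(f"unknown imputation {impute!r}")
        col[nan] = fill
    Xc = _covariate_columns(pheno, retained_samples, covariates, audit_cutoff)
    X = np.column_stack([Xc, dosage]) if Xc.size else dosage
    outcome = pheno.df.set_index("sample_id").loc[retained_samples, "outcome"]
    y = (outcome == outcome_positive).to_numpy(dtype=float)
    return DesignMatrix(
        sample_ids=list(retained_samples),
        predictor_names=list(covariates) + list(retained_snvs),
        X=X,
        y=y,
        outcome_positive=outcome_positive,
    )


def filter_pipeline(
    G: GenotypeMatrix,
    pheno: PhenotypeTable,
    variation_threshold: float = 0.02,
    missingness_threshold: float = 0.05,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    outcome_positive: str = OUTCOME_EX_SMOKER,
    impute: str = "mode",
    audit_cutoff: float = AUDIT_HAZARDOUS_CUTOFF,
) -> tuple[DesignMatrix, FilterReport]:
    """Run the full cascade: complete-case -> variation -> missingness ->
    duplicate collapse -> design assembly."""
    cc_samples = complete_case(pheno, covariates)
    if not cc_samples:
        raise ValueError("no complete-case participants")
    G_cc = G.subset(samples=cc_samples)

    keep1, low_var = variation_filter(G_cc, variation_threshold)
    G1 = G_cc.subset(snv_ids=keep1)
    keep2, high_miss = missingness_filter(G1, missingness_threshold)
    G2 = G_cc.subset(snv_ids=keep2)
    keep3, dups = collapse_identical(G2)

    design = build_design(
        G, pheno, keep3, cc_samples,
        outcome_positive=outcome_positive, covariates=covariates, impute=impute,
        audit_cutoff=audit_cutoff,
    )
    report = FilterReport(
        n_input_snvs=G.n_snvs,
        n_low_variation=len(low_var),
        n_high_missing=len(high_miss),
        n_duplicate_collapsed=len(dups),
        n_retained_snvs=len(keep3),
        n_input_samples=G.n_samples,
        n_complete_case=len(cc_samples),
        removed_ids={
            "low_variation": low_var,
            "high_missing": high_miss,
            "duplicate": dups,
            "incomplete_samples": [s for s in pheno.sample_ids if s not in set(cc_samples)],
        },
    )
    return design, report
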
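"""Synthetic genotype-phenotype cohorts.

Two entry points:

* :func:`generate_cohort` — a stochastic simulator with the statistical
  structure the analysis assumes: Hardy-Weinberg genotypes with
  Gaussian-copula linkage-disequilibrium blocks, designated low-variation /
  high-missingness / duplicate-profile SNV columns, behavioral covariates
  with realistic co-use coupling, and a logistic outcome model combining
  per-allele genetic effects with behavioral effects. Defaults emulate the
  study cohort: 194 participants (142 current/recent smokers, 52 long-term
  ex-smokers), 759 SNVs across the 12 candidate genes of which 124 are
  low-variation, 458 high-missingness and 21 duplicate profiles, and 37
  participants with incomplete regression covariates.

* :func:`study_mirror_fixture` — a deterministic cohort whose filtering and
  univariate accounting is exact by construction (counts are specification,
  not simulation): the cascade yields 759 -> -124 -> -458 -> -21 -> 156 SNVs
  and 157 complete cases, and the behavioral 2x2 margins equal the published
  univariate tables (61/139 vs 9/52 marijuana, 35/139 vs 1/52 cocaine,
  25/131 vs 2/48 hazardous alcohol, 72/140 vs 24/52 male, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .io import (
    CANDIDATE_GENES,
    EDUCATION_LEVELS,
    GenotypeMatrix,
    OUTCOME_EX_SMOKER,
    OUTCOME_SMOKER,
    PhenotypeTable,
    SnvMeta,
)

__all__ = ["SyntheticCohortSpec", "generate_cohort", "study_mirror_fixture"]

#: Ex-smoker-oriented log-odds for the behavioral covariates, on the scale of
#: the published univariate associations (substance use opposes quitting).
DEFAULT_BEHAVIORAL_EFFECTS = {
    "hazardous_alcohol": -math.log(5.43),
    "marijuana_30d": -math.log(3.73),
    "cocaine_30d": -math.log(17.2),
    "gad7": -0.08,  # per anxiety point
}

_GENE_CHROM = {
    "IREB2": ("15", 78_460_000),
    "SLC25A21": ("14", 37_140_000),
    "SEMA6D": ("15", 47_470_000),
    "CHRNA3": ("15", 78_880_000),
    "CHRNA4": ("20", 63_340_000),
    "CHRNA5": ("15", 78_850_000),
    "CHRNB4": ("15", 78_910_000),
    "PSMA4": ("15", 78_830_000),
    "DNMT3B": ("20", 31_350_000),
    "CADM2": ("3", 85_980_000),
    "CYP2A6": ("19", 40_840_000),
    "HTR2B": ("2", 231_110_000),
}


@dataclass
class SyntheticCohortSpec:
    """Parameters of the cohort simulator (defaults = the study conditions)."""

    n_samples: int = 194
    n_snvs: int = 759
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_low_variation: int = 124
    n_high_missing: int = 458
    n_duplicate: int = 21
    n_incomplete_pheno: int = 37
    missing_rate_high: float = 0.08
    ld_block_size: int = 5
    ld_rho: float = 0.7
    causal_effects: dict = field(default_factory=lambda: {0: math.log(2.02)})
    behavioral_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIORAL_EFFECTS)
    )
    baseline_prevalence: float = 52 / 194
    seed: int = 2021

    def __post_init__(self):
        designated = self.n_low_variation + self.n_high_missing + self.n_duplicate
        if designated >= self.n_snvs:
            raise ValueError("designated degenerate SNVs must leave normal columns")
        if self.n_duplicate > self.n_snvs - designated:
            raise ValueError("more duplicates than available partner columns")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.missing_rate_high < 0.05:
            raise ValueError("missing_rate_high must be >= 0.05")
        if self.n_incomplete_pheno > self.n_samples:
            raise ValueError("incomplete participants exceed sample size")

    @property
    def n_normal(self) -> int:
        return self.n_snvs - self.n_low_variation - self.n_high_missing - self.n_duplicate


def _snv_metadata(n_snvs: int) -> list[SnvMeta]:
    """Deterministic SNV metadata spread over the 12 candidate genes."""
    genes = list(CANDIDATE_GENES)
    per_gene = np.array_split(np.arange(n_snvs), len(genes))
    bases = "ACGT"
    metas = [None] * n_snvs
    for g_idx, idxs in enumerate(per_gene):
        gene = genes[g_idx]
        chrom, base_pos = _GENE_CHROM[gene]
        for order, j in enumerate(idxs):
            ref = bases[j % 4]
            alt = bases[(j + 1) % 4]
            metas[j] = SnvMeta(
                id=f"s{j:04d}", chrom=chrom, pos=base_pos + 17 * (order + 1),
                ref=ref, alt=alt, gene=gene,
            )
    return metas


def _copula_genotypes(rng, n: int, mafs: np.ndarray, block: int, rho: float) -> np.ndarray:
    """HW genotypes with within-block Gaussian-copula allele correlation."""
    p = len(mafs)
    thresh = ndtri(np.clip(mafs, 1e-12, 1 - 1e-12))
    dosage = np.zeros((n, p))
    n_blocks = math.ceil(p / block)
    for hap in range(2):
        shared = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, p))
        block_of = np.arange(p) // block
        Z = math.sqrt(rho) * shared[:, block_of] + math.sqrt(1 - rho) * eps
        dosage += (Z < thresh[None, :]).astype(float)
    return dosage


def _calibrate_intercept(lp: np.ndarray, prevalence: float) -> float:
    f = lambda c: float(np.mean(expit(lp + c))) - prevalence
    return brentq(f, -30.0, 30.0)


def generate_cohort(spec: SyntheticCohortSpec) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Draw a reproducible cohort from the spec.

    Column layout: ``n_normal`` ordinary SNVs first, then the designated
    low-variation, high-missingness, and duplicate-profile columns (each
    duplicate copies normal column ``k``). ``causal_effects`` keys index this
    layout. The outcome is Bernoulli with
    ``logit P(ex_smoker) = intercept + sum(genetic) + sum(behavioral)``,
    the intercept calibrated so the mean simulated prevalence matches
    ``baseline_prevalence``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_snvs
    n_norm, n_lv, n_hm, n_dup = (
        spec.n_normal, spec.n_low_variation, spec.n_high_missing, spec.n_duplicate,
    )

    mafs = rng.uniform(*spec.maf_range, size=p)
    mafs[n_norm:n_norm + n_lv] = 0.003  # forces non-modal fraction < 2%
    dosage = _copula_genotypes(rng, n, mafs, spec.ld_block_size, spec.ld_rho)

    # high-missingness block: exact missing count >= missing_rate_high
    n_miss = math.ceil(spec.missing_rate_high * n)
    for j in range(n_norm + n_lv, n_norm + n_lv + n_hm):
        rows = rng.choice(n, size=n_miss, replace=False)
        dosage[rows, j] = np.nan
    # duplicate-profile block: copy a distinct normal partner column each
    for k in range(n_dup):
        dosage[:, n_norm + n_lv + n_hm + k] = dosage[:, k]

    # behavioral covariates with positive co-use coupling (Gaussian copula)
    cop_rho = 0.25
    shared = rng.standard_normal(n)
    latents = {
        name: math.sqrt(cop_rho) * shared + math.sqrt(1 - cop_rho) * rng.standard_normal(n)
        for name in ("hazardous_alcohol", "marijuana_30d", "cocaine_30d")
    }
    prevalences = {"hazardous_alcohol": 0.15, "marijuana_30d": 0.37, "cocaine_30d": 0.19}
    exposed = {k: latents[k] < ndtri(prevalences[k]) for k in latents}
    audit = np.where(
        exposed["hazardous_alcohol"],
        8 + rng.integers(0, 13, size=n),
        np.minimum(7, rng.poisson(2.5, size=n)),
    ).astype(float)
    gad7 = np.clip(np.round(rng.normal(7.3, 6.2, size=n)), 0, 21)
    cesd = np.clip(np.round(rng.normal(20.7, 12.2, size=n)), 0, 60)

    # outcome model
    lp = np.zeros(n)
    for j, beta in spec.causal_effects.items():
        col = dosage[:, j]
        fill = col[~np.isnan(col)]
        mode = float(np.argmax([(fill == g).sum() for g in (0.0, 1.0, 2.0)])) if fill.size else 0.0
        lp += beta * np.nan_to_num(col, nan=mode)
    eff = spec.behavioral_effects
    lp += eff.get("hazardous_alcohol", 0.0) * (audit >= 8)
    lp += eff.get("marijuana_30d", 0.0) * exposed["marijuana_30d"]
    lp += eff.get("cocaine_30d", 0.0) * exposed["cocaine_30d"]
    lp += eff.get("gad7", 0.0) * gad7
    intercept = _calibrate_intercept(lp, spec.baseline_prevalence)
    is_ex = rng.random(n) < expit(lp + intercept)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "outcome": np.where(is_ex, OUTCOME_EX_SMOKER, OUTCOME_SMOKER),
            "age": np.round(rng.normal(53.3, 9.9, size=n), 1),
            "gender": rng.choice(
                ["male", "female", "transgender"], size=n, p=[0.495, 0.495, 0.01]
            ),
            "race": rng.choice(["black", "white", "other"], size=n, p=[0.763, 0.041, 0.196]),
            "latino": rng.random(n) < 0.232,
            "education": rng.choice(list(EDUCATION_LEVELS), size=n, p=[0.382, 0.278, 0.24, 0.1]),
            "audit_score": audit,
            "marijuana_30d": exposed["marijuana_30d"],
            "cocaine_30d": exposed["cocaine_30d"],
            "cesd": cesd,
            "gad7": gad7,
        }
    )
    for col in ("latino", "marijuana_30d", "cocaine_30d"):
        df[col] = df[col].astype("boolean")
    # blank one regression covariate per designated incomplete participant
    incomplete = rng.choice(n, size=spec.n_incomplete_pheno, replace=False)
    blank_cols = ("audit_score", "marijuana_30d", "cocaine_30d", "gad7")
    for k, i in enumerate(incomplete):
        col = blank_cols[k % len(blank_cols)]
        df.loc[i, col] = pd.NA if col in ("marijuana_30d", "cocaine_30d") else np.nan

    G = GenotypeMatrix(
        samples=df["sample_id"].tolist(), snvs=_snv_metadata(p), dosage=dosage
    )
    return G, PhenotypeTable(df)


# ----------------------------------------------------------------------------
# Deterministic study-mirror fixture
# ----------------------------------------------------------------------------

def _pick(rng, pool: np.ndarray, k: int) -> np.ndarray:
    return rng.choice(pool, size=k, replace=False)


def _enforce_nonmodal(col: np.ndarray, cc_idx: np.ndarray, minimum: int) -> None:
    """Flip modal complete-case entries to hets until the column has at least
    ``minimum`` non-modal non-missing calls over the complete-case samples."""
    obs_idx = cc_idx[~np.isnan(col[cc_idx])]
    obs = col[obs_idx]
    counts = np.array([(obs == g).sum() for g in (0.0, 1.0, 2.0)])
    modal = float(np.argmax(counts))
    nonmodal = obs_idx[col[obs_idx] != modal]
    deficit = minimum - len(nonmodal)
    if deficit <= 0:
        return
    modal_rows = obs_idx[col[obs_idx] == modal]
    flip_to = 1.0 if modal != 1.0 else 0.0
    col[modal_rows[:deficit]] = flip_to


def study_mirror_fixture(seed: int = 2021) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Deterministic cohort reproducing the study's accounting exactly.

    For any seed: 194 participants (142 smokers / 52 ex-smokers), 37 with a
    missing regression covariate (157 complete cases); 759 SNVs of which
    exactly 124 fail the <2% variation filter, exactly 458 of the remainder
    fail the >=5% missingness filter, and exactly 21 duplicate another SNV's
    genotype profile over the complete-case samples, leaving 156. Behavioral
    2x2 margins match the published univariate table cell-for-cell. The seed
    only varies the arbitrary filler (who exactly is exposed, genotype draws);
    all counts are enforced by construction.
    """
    rng = np.random.default_rng(seed)
    n_smk, n_ex, n = 142, 52, 194
    smk = np.arange(n_smk)
    ex = np.arange(n_smk, n)

    # -- missingness pattern for the four regression covariates (union = 37)
    mj_missing = smk[:3]                      # also cocaine-missing
    audit_missing = np.concatenate([smk[3:14], ex[:4]])       # 11 + 4
    gad_missing = np.concatenate([smk[14:29], ex[4:8]])       # 15 + 4
    incomplete = np.unique(np.concatenate([mj_missing, audit_missing, gad_missing]))
    assert len(incomplete) == 37
    cc_mask = np.ones(n, dtype=bool)
    cc_mask[incomplete] = False
    cc_idx = np.flatnonzero(cc_mask)  # 157 complete cases

    # -- behavioral covariates with the published margins
    def assign(pool: np.ndarray, k: int) -> np.ndarray:
        flag = np.zeros(n, dtype=bool)
        flag[_pick(rng, pool, k)] = True
        return flag

    mj_obs_smk = np.setdiff1d(smk, mj_missing)       # 139
    marijuana = assign(mj_obs_smk, 61) | assign(ex, 9)
    cocaine = assign(mj_obs_smk, 35) | assign(ex, 1)
    audit_obs_smk = np.setdiff1d(smk, audit_missing[:11])    # 131
    audit_obs_ex = np.setdiff1d(ex, audit_missing[11:])      # 48
    hazardous = assign(audit_obs_smk, 25) | assign(audit_obs_ex, 2)
    audit = np.where(hazardous, 8 + rng.integers(0, 13, n), rng.integers(0, 8, n)).astype(float)
    audit[audit_missing] = np.nan

    marijuana_col = pd.array(marijuana, dtype="boolean")
    cocaine_col = pd.array(cocaine, dtype="boolean")
    marijuana_col[mj_missing] = pd.NA
    cocaine_col[mj_missing] = pd.NA

    gender = np.empty(n, dtype=object)
    gender[smk] = ["male"] * 72 + ["female"] * 68 + ["transgender"] * 2
    gender[ex] = ["male"] * 24 + ["female"] * 28
    gender[smk] = rng.permutation(gender[smk])
    gender[ex] = rng.permutation(gender[ex])

    latino = pd.array(np.zeros(n, dtype=bool), dtype="boolean")
    latino_missing_smk = _pick(rng, smk, 2)
    latino_obs_smk = np.setdiff1d(smk, latino_missing_smk)
    latino[_pick(rng, latino_obs_smk, 33)] = True
    latino[_pick(rng, ex, 12)] = True
    latino[latino_missing_smk] = pd.NA

    race = np.empty(n, dtype=object)
    race[smk] = ["white"] * 8 + ["black"] * 110 + ["other"] * 24
    race[ex] = ["black"] * 38 + ["other"] * 14
    race[smk] = rng.permutation(race[smk])
    race[ex] = rng.permutation(race[ex])

    education = np.empty(n, dtype=object)
    edu_counts_smk = (57, 37, 35, 13)
    edu_counts_ex = (17, 17, 10, 8)
    education[smk] = rng.permutation(np.repeat(EDUCATION_LEVELS, edu_counts_smk))
    education[ex] = rng.permutation(np.repeat(EDUCATION_LEVELS, edu_counts_ex))

    age = np.round(np.concatenate([rng.normal(52.5, 10.0, n_smk), rng.normal(55.2, 9.6, n_ex)]), 1)
    cesd = np.clip(np.round(np.concatenate(
        [rng.normal(21.2, 12.2, n_smk), rng.normal(19.2, 12.4, n_ex)])), 0, 60)
    gad7 = np.clip(np.round(np.concatenate(
        [rng.normal(8.1, 6.3, n_smk), rng.normal(5.3, 5.3, n_ex)])), 0, 21)
    gad7 = gad7.astype(float)
    gad7[gad_missing] = np.nan

    df = pd.DataFrame(
        {
            "sample_id": [f"P{i:03d}" for i in range(n)],
            "outcome": [OUTCOME_SMOKER] * n_smk + [OUTCOME_EX_SMOKER] * n_ex,
            "age": age,
            "gender": gender,
            "race": race,
            "latino": latino,
            "education": education,
            "audit_score": audit,
            "marijuana_30d": marijuana_col,
            "cocaine_30d": cocaine_col,
            "cesd": cesd,
            "gad7": gad7,
        }
    )
    pheno = PhenotypeTable(df)

    # -- genotype columns: 156 retained + 124 low-variation + 458 high-missing
    #    + 21 duplicates = 759, with counts exact over the 157 complete cases
    n_ret, n_lv, n_hm, n_dup = 156, 124, 458, 21
    cols: list[np.ndarray] = []

    def hw_column(maf: float) -> np.ndarray:
        return (rng.random(n) < maf).astype(float) + (rng.random(n) < maf)

    retained = []
    seen = set()
    for _ in range(n_ret):
        while True:
            col = hw_column(rng.uniform(0.1, 0.4))
            m = int(rng.integers(0, 3))
            if m:
                col[_pick(rng, cc_idx, m)] = np.nan
            _enforce_nonmodal(col, cc_idx, 5)
            key = np.nan_to_num(col[cc_idx], nan=3.0).astype(np.int8).tobytes()
            if key not in seen:
                seen.add(key)
                retained.append(col)
                break
    low_var = []
    for _ in range(n_lv):
        col = np.zeros(n)
        col[rng.choice(cc_idx)] = 1.0  # a single het: 1/157 < 2% variation
        col[incomplete] = hw_column(0.2)[incomplete]
        low_var.append(col)
    high_missing = []
    for _ in range(n_hm):
        col = hw_column(rng.uniform(0.15, 0.35))
        col[_pick(rng, cc_idx, int(rng.integers(12, 25)))] = np.nan  # >= 8/157 = 5%
        _enforce_nonmodal(col, cc_idx, 6)
        high_missing.append(col)
    duplicates = []
    for k in range(n_dup):
        col = retained[k].copy()
        i_off = int(rng.choice(incomplete))  # differ only on an excluded sample
        col[i_off] = 1.0 if (np.isnan(col[i_off]) or col[i_off] != 1.0) else 0.0
        duplicates.append(col)

    order = rng.permutation(n_ret + n_lv + n_hm + n_dup)
    all_cols = retained + low_var + high_missing + duplicates
    dosage = np.column_stack([all_cols[j] for j in order])
    G = GenotypeMatrix(
        samples=df["sample_id"].tolist(), snvs=_snv_metadata(759), dosage=dosage
    )
    return G, pheno
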
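import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snvnet.filters import (
    build_design,
    collapse_identical,
    complete_case,
    filter_pipeline,
    missingness_filter,
    variation_filter,
)
from snvnet.glm import newton_logistic
from snvnet.io import GenotypeMatrix, PhenotypeTable, SnvMeta


def _matrix(cols: dict[str, np.ndarray]) -> GenotypeMatrix:
    ids = list(cols)
    n = len(next(iter(cols.values())))
    return GenotypeMatrix(
        samples=[f"S{i:03d}" for i in range(n)],
        snvs=[SnvMeta(i, "1", k + 1, "A", "C") for k, i in enumerate(ids)],
        dosage=np.column_stack([cols[i] for i in ids]),
    )


class TestVariationFilter:
    def test_threshold_boundaries(self):
        n = 194
        constant = np.zeros(n)
        one_het = np.zeros(n)
        one_het[0] = 1.0  # 1/194 = 0.52% < 2%
        five = np.zeros(n)
        five[:5] = 1.0  # 5/194 = 2.58% >= 2%
        G = _matrix({"const": constant, "one": one_het, "five": five})
        retained, removed = variation_filter(G, 0.02)
        assert removed == ["const", "one"]
        assert retained == ["five"]

    def test_all_missing_column_removed(self):
        G = _matrix({"gone": np.full(10, np.nan), "ok": np.tile([0.0, 1.0], 5)})
        retained, removed = variation_filter(G)
        assert removed == ["gone"] and retained == ["ok"]

    def test_bad_threshold(self):
        G = _matrix({"a": np.zeros(4)})
        with pytest.raises(ValueError):
            variation_filter(G, 0.0)


class TestMissingnessFilter:
    @pytest.mark.parametrize("n_missing, kept", [(0, True), (9, True), (10, False)])
    def test_five_percent_boundary(self, n_missing, kept):
        n = 194  # 10/194 = 5.15% >= 5%; 9/194 = 4.64% < 5%
        col = np.tile([0.0, 1.0, 2.0, 1.0], n // 4 + 1)[:n]
        col[:n_missing] = np.nan
        G = _matrix({"x": col})
        retained, removed = missingness_filter(G, 0.05)
        assert (retained == ["x"]) is kept


class TestCollapseIdentical:
    def test_three_identical_keep_one(self):
        base = np.tile([0.0, 1.0, 2.0], 4)
        G = _matrix({"a": base, "b": base.copy(), "c": base.copy(), "d": 2 - base})
        retained, removed = collapse_identical(G)
        assert retained == ["a", "d"]
        assert removed == ["b", "c"]

    def test_scoped_to_given_samples(self):
        a = np.array([0.0, 1.0, 2.0, 0.0])
        b = a.copy()
        b[3] = 2.0  # differs only on the last (excluded) sample
        G = _matrix({"a": a, "b": b})
        retained, removed = collapse_identical(G, samples=["S000", "S001", "S002"])
        assert retained == ["a"] and removed == ["b"]
        retained_full, removed_full = collapse_identical(G)
        assert removed_full == []

    def test_missing_pattern_part_of_profile(self):
        a = np.array([0.0, np.nan, 2.0])
        b = np.array([0.0, 0.0, 2.0])
        G = _matrix({"a": a, "b": b})
        _, removed = collapse_identical(G)
        assert removed == []


class TestCompleteCase:
    def test_any_missing_rule_and_empty_list(self, mirror):
        _, pheno = mirror
        ids = complete_case(pheno)
        assert len(ids) == 157
        assert complete_case(pheno, covariates=()) == pheno.sample_ids
        # a participant missing only the audit score is excluded
        missing_audit = pheno.df.loc[pheno.df["audit_score"].isna(), "sample_id"]
        assert set(missing_audit).isdisjoint(ids)

    def test_unknown_covariate(self, mirror):
        _, pheno = mirror
        with pytest.raises(ValueError, match="unknown covariate"):
            complete_case(pheno, covariates=("bmi",))


class TestBuildDesign:
    def test_dosage_coding_and_imputation_support(self, mirror):
        G, pheno = mirror
        ids = complete_case(pheno)
        keep, _ = variation_filter(G.subset(samples=ids))
        design = build_design(G, pheno, keep[:20], ids)
        snv_block = design.X[:, 4:]
        assert np.isin(snv_block, (0.0, 1.0, 2.0)).all()
        assert not np.isnan(design.X).any()

    def test_outcome_flip_negates_unpenalized_coefficients(self, rng):
        n = 120
        X = rng.standard_normal((n, 3))
        y = (rng.random(n) < 0.4).astype(float)
        f1 = newton_logistic(X, y)
        f2 = newton_logistic(X, 1 - y)
        assert np.allclose(f1.coefs, -f2.coefs, atol=1e-6)
        assert f1.intercept == pytest.approx(-f2.intercept, abs=1e-6)

    def test_missing_sample_errors(self, mirror):
        G, pheno = mirror
        with pytest.raises(ValueError, match="absent"):
            build_design(G, pheno, [G.snvs[0].id], ["nobody"])


class TestFilterPipeline:
    def test_mirror_accounting(self, mirror_design):
        design, rep = mirror_design
        assert (
            rep.n_input_snvs,
            rep.n_low_variation,
            rep.n_high_missing,
            rep.n_duplicate_collapsed,
            rep.n_retained_snvs,
        ) == (759, 124, 458, 21, 156)
        assert rep.n_complete_case == 157
        assert design.X.shape == (157, 160)
        assert design.y.sum() == 44  # complete-case ex-smokers

    def test_clean_common_snvs_all_retained(self, rng):
        n, p = 60, 12
        dosage = rng.integers(0, 3, size=(n, p)).astype(float)
        G = _matrix({f"v{j:02d}": dosage[:, j] for j in range(p)})
        pheno = _simple_pheno(n)
        design, rep = filter_pipeline(G, pheno)
        assert rep.n_retained_snvs == p
        assert rep.n_complete_case == n

    def test_idempotent_on_own_output(self, small_cohort):
        G, pheno = small_cohort
        design, rep = filter_pipeline(G, pheno)
        G2 = G.subset(
            samples=design.sample_ids,
            snv_ids=design.predictor_names[4:],
        )
        pheno2 = PhenotypeTable(
            pheno.df[pheno.df["sample_id"].isin(design.sample_ids)].reset_index(drop=True)
        )
        _, rep2 = filter_pipeline(G2, pheno2)
        assert rep2.n_low_variation == 0
        assert rep2.n_high_missing == 0
        assert rep2.n_duplicate_collapsed == 0
        assert rep2.n_retained_snvs == rep.n_retained_snvs

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=15, deadline=None)
    def test_accounting_identity_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 25
        dosage = rng.integers(0, 3, size=(n, p)).astype(float)
        dosage[rng.random((n, p)) < 0.1] = np.nan
        dosage[:, rng.integers(0, p)] = 0.0  # at least one constant column
        j_dup = int(rng.integers(0, p - 1))
        dosage[:, j_dup + 1] = dosage[:, j_dup]
        G = _matrix({f"v{j:02d}": dosage[:, j] for j in range(p)})
        pheno = _simple_pheno(n, rng=rng, n_missing=5)
        _, rep = filter_pipeline(G, pheno)
        assert (
            rep.n_low_variation
            + rep.n_high_missing
            + rep.n_duplicate_collapsed
            + rep.n_retained_snvs
            == p
        )
        stage_ids = (
            rep.removed_ids["low_variation"]
            + rep.removed_ids["high_missing"]
            + rep.removed_ids["duplicate"]
        )
        assert len(stage_ids) == len(set(stage_ids))  # stages disjoint


def _simple_pheno(n: int, rng=None, n_missing: int = 0) -> PhenotypeTable:
    rng = rng or np.random.default_rng(1)
    out = np.array(["smoker"] * (n - n // 3) + ["ex_smoker"] * (n // 3))
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "outcome": out,
            "age": rng.normal(53, 10, n).round(1),
            "gender": rng.choice(["male", "female"], n),
            "race": rng.choice(["black", "white", "other"], n),
            "latino": pd.array(rng.random(n) < 0.2, dtype="boolean"),
            "education": rng.choice(
                ["less_than_hs", "hs_graduate", "some_college", "college_graduate"], n
            ),
            "audit_score": rng.integers(0, 20, n).astype(float),
            "marijuana_30d": pd.array(rng.random(n) < 0.3, dtype="boolean"),
            "cocaine_30d": pd.array(rng.random(n) < 0.2, dtype="boolean"),
            "cesd": rng.integers(0, 50, n).astype(float),
            "gad7": rng.integers(0, 21, n).astype(float),
        }
    )
    if n_missing:
        idx = rng.choice(n, size=n_missing, replace=False)
        df.loc[idx, "gad7"] = np.nan
    return PhenotypeTable(df)
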
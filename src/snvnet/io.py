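"""Cohort data containers and I/O.

Two in-memory containers carry the whole analysis:

* :class:`GenotypeMatrix` — samples x SNVs additive-dosage array (0/1/2 alt-allele
  counts, NaN for missing calls) plus per-SNV metadata (chromosome, 1-based
  position, ref/alt alleles, candidate-gene symbol).
* :class:`PhenotypeTable` — one row per participant: smoking outcome
  (current/recent smoker vs long-term ex-smoker) and behavioral covariates
  (age, gender, race, Latino/a ethnicity, education, AUDIT alcohol score,
  past-30-day marijuana and cocaine use, CESD-20 depression, GAD-7 anxiety).

The canonical interchange format is a tab-delimited dosage table (one row per
sample, header of SNV ids, ``NA`` = missing) with a metadata sidecar TSV
(columns id, chrom, pos, ref, alt, gene). VCF (GT-only, biallelic) is
supported read-only as a convenience. Phenotypes travel as CSV with blank
cells for missing values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnvMeta",
    "GenotypeMatrix",
    "PhenotypeTable",
    "CANDIDATE_GENES",
    "EDUCATION_LEVELS",
    "OUTCOME_SMOKER",
    "OUTCOME_EX_SMOKER",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_report",
    "read_report",
]

#: The 12 candidate genes targeted by the sequencing panel.
CANDIDATE_GENES = (
    "IREB2", "SLC25A21", "SEMA6D", "CHRNA3", "CHRNA4", "CHRNA5",
    "CHRNB4", "PSMA4", "DNMT3B", "CADM2", "CYP2A6", "HTR2B",
)

EDUCATION_LEVELS = ("less_than_hs", "hs_graduate", "some_college", "college_graduate")
OUTCOME_SMOKER = "smoker"
OUTCOME_EX_SMOKER = "ex_smoker"

_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """Raised when an input file or in-memory container violates its contract."""


@dataclass(frozen=True)
class SnvMeta:
    """Metadata for one single-nucleotide variant.

    Positions are 1-based (VCF convention). ``gene`` is one of the candidate
    genes or ``"other"``.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"SNV {self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"SNV {self.id}: ref and alt alleles are identical ({self.ref})")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if len(allele) != 1 or allele not in _BASES:
                raise ValidationError(
                    f"SNV {self.id}: {label} allele {allele!r} is not a single base"
                )

    @property
    def label(self) -> str:
        """Report label, e.g. ``SLC25A21: Chr.14 pos.37148248 T->C``."""
        return f"{self.gene}: Chr.{self.chrom} pos.{self.pos} {self.ref}->{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples x SNVs additive dosage matrix with a missingness mask.

    ``dosage`` is a float array; every non-missing entry is 0.0, 1.0 or 2.0
    (count of alt alleles), missing calls are ``NaN``. Missing never coerces
    to 0.
    """

    samples: list[str]
    snvs: list[SnvMeta]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snvs)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snvs)} SNVs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        ids = [s.id for s in self.snvs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNV ids")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValidationError(f"dosage value {bad!r} outside {{0, 1, 2}}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def snv_ids(self) -> list[str]:
        return [s.id for s in self.snvs]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def n_missing(self) -> int:
        return int(np.isnan(self.dosage).sum())

    def subset(
        self,
        samples: Sequence[str] | None = None,
        snv_ids: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset by sample ids and/or SNV ids (order follows the arguments)."""
        sample_idx = {s: i for i, s in enumerate(self.samples)}
        snv_idx = {s.id: j for j, s in enumerate(self.snvs)}
        rows = (
            np.arange(self.n_samples)
            if samples is None
            else np.array([sample_idx[s] for s in samples], dtype=int)
        )
        cols = (
            np.arange(self.n_snvs)
            if snv_ids is None
            else np.array([snv_idx[s] for s in snv_ids], dtype=int)
        )
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            snvs=[self.snvs[j] for j in cols],
            dosage=self.dosage[np.ix_(rows, cols)].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.snvs == other.snvs
            and self.dosage.shape == other.dosage.shape
            and bool(
                np.all(
                    (np.isnan(self.dosage) & np.isnan(other.dosage))
                    | (self.dosage == other.dosage)
                )
            )
        )


# ----------------------------------------------------------------------------
# Phenotypes
# ----------------------------------------------------------------------------

#: Column order of the phenotype CSV.
PHENO_COLUMNS = (
    "sample_id",
    "outcome",
    "age",
    "gender",
    "race",
    "latino",
    "education",
    "audit_score",
    "marijuana_30d",
    "cocaine_30d",
    "cesd",
    "gad7",
)

_BOOL_COLS = ("latino", "marijuana_30d", "cocaine_30d")
_SCORE_RANGES = {"audit_score": (0, 40), "cesd": (0, 60), "gad7": (0, 21)}


@dataclass
class PhenotypeTable:
    """Participant covariates and binary smoking outcome.

    Backed by a :class:`pandas.DataFrame` with the columns of
    ``PHENO_COLUMNS``; boolean covariates use the nullable ``boolean`` dtype
    and scores are floats with ``NaN`` for missing.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing_cols = [c for c in PHENO_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table missing columns: {missing_cols}")
        df = df.loc[:, list(PHENO_COLUMNS)].reset_index(drop=True)
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad_outcome = ~df["outcome"].isin([OUTCOME_SMOKER, OUTCOME_EX_SMOKER])
        if bad_outcome.any():
            raise ValidationError(
                f"invalid outcome value {df.loc[bad_outcome, 'outcome'].iloc[0]!r}"
            )
        for col in _BOOL_COLS:
            df[col] = df[col].astype("boolean")
        for col in ("age", "audit_score", "cesd", "gad7"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        for col, (lo, hi) in _SCORE_RANGES.items():
            vals = df[col].dropna()
            out = vals[(vals < lo) | (vals > hi)]
            if len(out):
                raise ValidationError(
                    f"{col} value {out.iloc[0]:g} outside instrument range [{lo}, {hi}]"
                )
        edu = df["education"].dropna()
        bad_edu = edu[~edu.isin(EDUCATION_LEVELS)]
        if len(bad_edu):
            raise ValidationError(f"unknown education level {bad_edu.iloc[0]!r}")
        for col in ("gender", "race", "education"):
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def n_smokers(self) -> int:
        return int((self.df["outcome"] == OUTCOME_SMOKER).sum())

    @property
    def n_ex_smokers(self) -> int:
        return int((self.df["outcome"] == OUTCOME_EX_SMOKER).sum())

    def is_smoker(self) -> np.ndarray:
        return (self.df["outcome"] == OUTCOME_SMOKER).to_numpy()

    def hazardous_alcohol(self, cutoff: float = 8) -> pd.Series:
        """AUDIT >= cutoff (nullable boolean; missing where the score is missing)."""
        score = self.df["audit_score"]
        return (score >= cutoff).astype("boolean").where(score.notna(), pd.NA)

    def equals(self, other: "PhenotypeTable") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f":
                ok = ((x.isna() & y.isna()) | (x == y)).all()
            else:
                ok = ((x.isna() & y.isna()) | (x == y).fillna(False)).all()
            if not ok:
                return False
        return True


# ----------------------------------------------------------------------------
# Genotype I/O
# ----------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.tsv")


def write_genotype_matrix(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a dosage TSV and its ``*.meta.tsv`` metadata sidecar."""
    path = Path(path)
    ids = G.snv_ids
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for i, sample in enumerate(G.samples):
            row = [
                "NA" if math.isnan(v) else str(int(v)) for v in G.dosage[i]
            ]
            fh.write(sample + "\t" + "\t".join(row) + "\n")
    with open(_meta_path(path), "w") as fh:
        fh.write("id\tchrom\tpos\tref\talt\tgene\n")
        for s in G.snvs:
            fh.write(f"{s.id}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.gene}\n")


def _read_genotype_tsv(path: Path, metadata_path: Path | None) -> GenotypeMatrix:
    if metadata_path is None:
        metadata_path = _meta_path(path)
    if not Path(metadata_path).exists():
        raise FileNotFoundError(f"SNV metadata sidecar not found: {metadata_path}")
    meta_df = pd.read_csv(metadata_path, sep="\t", dtype={"chrom": str})
    meta = {
        row.id: SnvMeta(
            id=str(row.id), chrom=str(row.chrom), pos=int(row.pos),
            ref=str(row.ref), alt=str(row.alt), gene=str(row.gene),
        )
        for row in meta_df.itertuples()
    }
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise ValidationError("dosage TSV must start with a 'sample_id' column")
    snv_ids = list(df.columns[1:])
    unknown = [s for s in snv_ids if s not in meta]
    if unknown:
        raise ValidationError(f"SNV {unknown[0]!r} missing from metadata sidecar")
    samples = df["sample_id"].tolist()
    dosage = np.empty((len(samples), len(snv_ids)))
    for j, sid in enumerate(snv_ids):
        col = df[sid].to_numpy()
        for i, cell in enumerate(col):
            if cell in ("NA", "", "."):
                dosage[i, j] = np.nan
            elif cell in ("0", "1", "2"):
                dosage[i, j] = float(cell)
            else:
                raise ValidationError(
                    f"dosage {cell!r} outside {{0,1,2,NA}} at sample {samples[i]!r}, SNV {sid!r}"
                )
    return GenotypeMatrix(samples=samples, snvs=[meta[s] for s in snv_ids], dosage=dosage)


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snvs: list[SnvMeta] = []
    cols: list[np.ndarray] = []
    for k, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValidationError(
                f"multi-allelic VCF record at {variant.CHROM}:{variant.POS} unsupported"
            )
        gene = "other"
        try:
            info_gene = variant.INFO.get("GENE")
            if info_gene:
                gene = str(info_gene)
        except Exception:
            pass
        vid = variant.ID or f"{variant.CHROM}_{variant.POS}"
        snvs.append(
            SnvMeta(id=vid, chrom=str(variant.CHROM), pos=int(variant.POS),
                    ref=str(variant.REF), alt=str(variant.ALT[0]), gene=gene)
        )
        col = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            # half-calls and no-calls map to missing
            if any(a < 0 for a in alleles) or len(alleles) != 2:
                continue
            col[i] = float(sum(1 for a in alleles if a == 1))
        cols.append(col)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, snvs=snvs, dosage=dosage)


def read_genotype_matrix(
    path: str | Path,
    format: str = "tsv",
    metadata_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from a dosage TSV (+ metadata sidecar) or a VCF.

    VCF parsing is GT-based: dosage is the alt-allele count; ``./.`` and
    half-calls become missing; multi-allelic records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_genotype_tsv(path, Path(metadata_path) if metadata_path else None)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


# ----------------------------------------------------------------------------
# Phenotype I/O
# ----------------------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    """Write the phenotype CSV (blank = missing; booleans as 1/0)."""
    df = pheno.df.copy()
    for col in _BOOL_COLS:
        df[col] = df[col].map({True: "1", False: "0"}).astype(object)
    df.to_csv(path, index=False, na_rep="")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read and validate a phenotype CSV (blank cells = missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map(
                {1: True, 0: False, "1": True, "0": False,
                 1.0: True, 0.0: False, True: True, False: False}
            ).astype("boolean")
    return PhenotypeTable(df)


# ----------------------------------------------------------------------------
# Report serialization
# ----------------------------------------------------------------------------

def _round6(x):
    """Round floats to 6 significant digits, recursively, for stable output."""
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if math.isnan(x) or math.isinf(x):
            return None if math.isnan(x) else ("inf" if x > 0 else "-inf")
        return float(f"{x:.6g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis report deterministically.

    JSON keeps insertion order with floats at 6 significant digits; the TSV
    format expects a list of flat records (one row each).
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_round6(report), fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        if not isinstance(report, (list, tuple)):
            raise ValueError("tsv format requires a list of flat records")
        rows = [_round6(dict(r)) for r in report]
        cols = list(rows[0].keys()) if rows else []
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in rows:
                fh.write("\t".join("" if r[c] is None else str(r[c]) for c in cols) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path):
    """Inverse of :func:`write_report` for the JSON format."""
    with open(path) as fh:
        return json.load(fh)
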
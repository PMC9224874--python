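"""In-memory containers shared across the pipeline.

All containers are thin, validated wrappers around pandas objects so that
indexing, alignment and I/O stay idiomatic; the wrappers only enforce the
cross-module contracts (consistent sample/variant/gene axes, dosage range,
allele sanity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]

CLINICAL_BINARY = ["sex", "smoking", "family_history", "upper_gi", "perianal"]
CLINICAL_MULTICLASS = {
    "location": ["ileal", "colonic", "ileocolonic"],
    "behavior": ["inflammatory", "stricturing", "penetrating"],
}
CLINICAL_NUMERIC = ["age"]
CLINICAL_COLUMNS = CLINICAL_NUMERIC + ["sex", "smoking", "family_history", "location", "upper_gi", "behavior", "perianal"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic variants, alternative-allele dosage in [0, 2].

    ``dosages``: DataFrame indexed by sample id, columns are variant ids;
    missing calls are NaN.  ``variants``: per-variant metadata indexed by
    variant id with columns chrom, pos, ref, alt.  ``complete`` optionally
    holds the pre-missingness dosages (synthetic bookkeeping only).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame
    complete: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if list(self.dosages.columns) != list(self.variants.index):
            raise DataError("dosage columns and variant metadata ids disagree")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise DataError(f"variant metadata lacks columns: {missing}")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise DataError("dosages outside [0, 2]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        d = self.dosages
        comp = self.complete
        if samples is not None:
            d = d.loc[list(samples)]
            comp = comp.loc[list(samples)] if comp is not None else None
        v = self.variants
        if variants is not None:
            d = d[list(variants)]
            v = v.loc[list(variants)]
            comp = comp[list(variants)] if comp is not None else None
        return GenotypeMatrix(d, v, comp)

    def reindex_samples(self, sample_ids) -> "GenotypeMatrix":
        """Align rows to ``sample_ids``; unknown ids are an error."""
        unknown = [s for s in sample_ids if s not in self.dosages.index]
        if unknown:
            raise DataError(f"unknown sample ids: {unknown[:5]}")
        return self.subset(samples=sample_ids)


@dataclass
class WeightDB:
    """Per-tissue linear imputation models.

    ``weights``: DataFrame with columns gene, variant_id, effect_allele,
    non_effect_allele, weight — one row per (gene, variant).
    """

    weights: pd.DataFrame
    tissue: str = "synthetic"

    REQUIRED = ["gene", "variant_id", "effect_allele", "non_effect_allele", "weight"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.weights.columns]
        if missing:
            raise DataError(f"weight table lacks columns: {missing}")
        if len(self.weights) == 0:
            raise DataError("empty weight table")
        dup = self.weights.duplicated(subset=["gene", "variant_id"])
        if dup.any():
            pair = self.weights.loc[dup.idxmax(), ["gene", "variant_id"]]
            raise DataError(f"duplicate weight row for gene={pair['gene']} variant={pair['variant_id']}")
        if not np.isfinite(self.weights["weight"].to_numpy(dtype=float)).all():
            raise DataError("non-finite weight")
        same = self.weights["effect_allele"] == self.weights["non_effect_allele"]
        if same.any():
            raise DataError("effect and non-effect alleles identical for some records")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.weights["gene"]))

    def snps_per_gene(self) -> pd.Series:
        return self.weights.groupby("gene", sort=False).size()

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.weights[self.weights["gene"] == gene]


@dataclass
class ExpressionMatrix:
    """Samples x genes imputed expression (unitless, relative scale)."""

    values: pd.DataFrame
    coverage: pd.Series  # per gene: fraction of model variants used

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.coverage.index):
            raise DataError("expression columns and coverage index disagree")
        cov = self.coverage.to_numpy(dtype=float)
        if cov.size and (cov.min() < 0 or cov.max() > 1):
            raise DataError("coverage outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_clinical(df: pd.DataFrame, require_label: bool = False) -> pd.DataFrame:
    """Check a clinical table against the cohort schema; returns the table."""
    cols = CLINICAL_COLUMNS + (["label"] if require_label else [])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"clinical table lacks columns: {missing}")
    if df[CLINICAL_COLUMNS].isna().any().any():
        raise DataError("clinical table contains missing values")
    for col, levels in CLINICAL_MULTICLASS.items():
        bad = set(df[col]) - set(levels)
        if bad:
            raise DataError(f"unknown {col} levels: {sorted(bad)}")
    if require_label:
        bad = set(df["label"]) - {"NDR", "DR"}
        if bad:
            raise DataError(f"unknown labels: {sorted(bad)}")
    return df


def labels_to_binary(labels: pd.Series) -> pd.Series:
    """Map NDR/DR (or 0/1) labels to ints: NDR (case) = 1, DR (control) = 0."""
    if labels.dtype == object:
        bad = set(labels) - {"NDR", "DR"}
        if bad:
            raise DataError(f"unknown labels: {sorted(bad)}")
        return (labels == "NDR").astype(int)
    vals = set(pd.unique(labels))
    if not vals <= {0, 1}:
        raise DataError(f"labels must be NDR/DR or 0/1, got {sorted(vals)[:5]}")
    return labels.astype(int)
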
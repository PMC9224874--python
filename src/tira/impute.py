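"""Genotype-to-expression imputation with PredictDB-style cis weights.

A gene's imputed expression is the scalar product of its model's regression
coefficients with the harmonized alternative-allele dosages of the model
variants found in the genotype data:

    T_g(sample) = sum_k  w_gk * d_k(sample)

Harmonization reconciles the weight model's effect/non-effect alleles with
the genotype file's ref/alt: matching orientation keeps the dosage, swapped
orientation flips d -> 2 - d, and any other allele pair is skipped with a
recorded reason.  Missing dosages are mean-imputed per variant by default
(the cohort mean can be frozen for out-of-cohort transforms, preserving
linearity across concatenated cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, WeightDB
from .errors import ConfigError, DataError
from .io import load_weight_db  # re-exported: the module's loading surface

__all__ = ["load_weight_db", "harmonize", "ExpressionImputer", "impute"]

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


def harmonize(variant: pd.Series, w: pd.Series, ambiguous: str = "match") -> tuple[str, str]:
    """Resolve one (variant, weight) pair to a dosage transform.

    Returns ``(action, reason)`` with action in {"identity", "flip", "skip"}.
    ``ambiguous="drop"`` skips strand-ambiguous A/T and C/G sites; the
    default accepts them on an exact id+allele match only.
    """
    ref, alt = str(variant["ref"]), str(variant["alt"])
    eff, non = str(w["effect_allele"]), str(w["non_effect_allele"])
    if ambiguous not in {"match", "drop"}:
        raise ConfigError(f"unknown ambiguous policy {ambiguous!r}")
    if ambiguous == "drop" and frozenset((ref, alt)) in _AMBIGUOUS:
        return "skip", "strand ambiguous"
    if (non, eff) == (ref, alt):
        return "identity", ""
    if (non, eff) == (alt, ref):
        return "flip", ""
    return "skip", "allele mismatch"


@dataclass
class _GeneModel:
    variants: list[str]
    weights: np.ndarray
    flip: np.ndarray  # bool per variant
    n_model: int  # variants in the weight model (incl. unusable)


class ExpressionImputer:
    """Transformer: GenotypeMatrix -> ExpressionMatrix under a WeightDB.

    fit() resolves harmonization per (gene, variant) and freezes per-variant
    mean dosages for missing-call imputation; transform() applies the linear
    models.  Follows the scikit-learn fit/transform idiom (fitted state in
    trailing-underscore attributes) while operating on the domain containers.

    Parameters
    ----------
    db : WeightDB
    missing : "mean" | "skip"
        Missing dosage handling: replace with the variant's (frozen) cohort
        mean, or treat the variant as absent for that sample (dosage 0 after
        centering is not attempted; the term is dropped).
    ambiguous : "match" | "drop"
        Strand-ambiguous site policy passed to :func:`harmonize`.
    """

    def __init__(self, db: WeightDB, missing: str = "mean", ambiguous: str = "match"):
        if missing not in {"mean", "skip"}:
            raise ConfigError(f"unknown missing policy {missing!r}")
        self.db = db
        self.missing = missing
        self.ambiguous = ambiguous

    def get_params(self, deep: bool = True) -> dict:
        return {"db": self.db, "missing": self.missing, "ambiguous": self.ambiguous}

    def set_params(self, **params) -> "ExpressionImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ConfigError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, g: GenotypeMatrix) -> "ExpressionImputer":
        variants = g.variants
        present = set(g.variant_ids)
        models: dict[str, _GeneModel] = {}
        skipped: list[tuple[str, str, str]] = []
        dropped: list[str] = []
        any_overlap = False
        for gene, rows in self.db.weights.groupby("gene", sort=False):
            vids, ws, flips = [], [], []
            for _, w in rows.iterrows():
                vid = w["variant_id"]
                if vid not in present:
                    skipped.append((gene, vid, "not genotyped"))
                    continue
                any_overlap = True
                action, reason = harmonize(variants.loc[vid], w, ambiguous=self.ambiguous)
                if action == "skip":
                    skipped.append((gene, vid, reason))
                    continue
                vids.append(vid)
                ws.append(float(w["weight"]))
                flips.append(action == "flip")
            if vids:
                models[gene] = _GeneModel(vids, np.asarray(ws), np.asarray(flips, dtype=bool), len(rows))
            else:
                dropped.append(gene)
        if not any_overlap:
            raise DataError(
                f"no overlap between {g.n_variants} genotyped variants and "
                f"{len(self.db.weights)} weight-db variants (tissue {self.db.tissue})"
            )
        self.models_ = models
        self.dropped_genes_ = dropped
        self.skipped_ = pd.DataFrame(skipped, columns=["gene", "variant_id", "reason"])
        self.mean_dosage_ = g.dosages.mean()  # per-variant, NaN-aware
        return self

    def transform(self, g: GenotypeMatrix) -> ExpressionMatrix:
        if not hasattr(self, "models_"):
            raise ConfigError("ExpressionImputer is not fitted")
        dosages = g.dosages
        out = {}
        coverage = {}
        for gene, m in self.models_.items():
            d = dosages[m.variants].to_numpy(dtype=float)
            if self.missing == "mean":
                means = self.mean_dosage_[m.variants].to_numpy(dtype=float)
                nan = np.isnan(d)
                if nan.any():
                    d = np.where(nan, np.broadcast_to(means, d.shape), d)
            else:  # skip: drop the term for that sample
                d = np.nan_to_num(d, nan=0.0)
            d = np.where(m.flip, 2.0 - d, d)
            out[gene] = np.ascontiguousarray(d) @ np.ascontiguousarray(m.weights)
            coverage[gene] = len(m.variants) / m.n_model
        values = pd.DataFrame(out, index=g.sample_ids)
        return ExpressionMatrix(values, pd.Series(coverage, name="coverage"))

    def fit_transform(self, g: GenotypeMatrix) -> ExpressionMatrix:
        return self.fit(g).transform(g)


def impute(g: GenotypeMatrix, db: WeightDB, missing: str = "mean", ambiguous: str = "match") -> ExpressionMatrix:
    """One-shot imputation (fit and transform on the same cohort)."""
    return ExpressionImputer(db, missing=missing, ambiguous=ambiguous).fit_transform(g)
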
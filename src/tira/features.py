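"""Model-ready feature assembly.

Clinical covariates are encoded as in the modeling protocol: dichotomous
variables to 0/1 with a recorded level map, multiclass variables (disease
location, disease behavior) to one-hot columns over the declared level
order with no reference level dropped, and numeric variables (age) passed
through to standardization.  Gene features are the imputed expression
values.  Standardization is (x - mean)/SD with population SD, fitted on a
designated sample subset (per-trial training split by default; a global
mode standardizes once on the full cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CLINICAL_BINARY, CLINICAL_MULTICLASS, CLINICAL_NUMERIC, ExpressionMatrix, validate_clinical
from .errors import ConfigError, DataError

__all__ = ["ClinicalEncoder", "Standardizer", "FeatureMatrix", "encode_clinical", "assemble", "standardize"]

#: Recorded binary level maps (value -> 0/1).
_BINARY_MAPS = {"sex": {"female": 0, "male": 1}}


class ClinicalEncoder:
    """Transformer: clinical table -> numeric design columns.

    Fitted attributes: ``level_maps_`` (binary value maps), ``onehot_levels_``
    (declared level order per multiclass variable), ``columns_`` (output
    column order).  ``inverse_transform`` restores the original table from
    the recorded maps.
    """

    def fit(self, clinical: pd.DataFrame) -> "ClinicalEncoder":
        validate_clinical(clinical)
        self.level_maps_ = {}
        for col in CLINICAL_BINARY:
            if clinical[col].dtype == object:
                self.level_maps_[col] = dict(_BINARY_MAPS.get(col) or {lvl: i for i, lvl in enumerate(sorted(set(clinical[col])))})
            else:
                self.level_maps_[col] = {0: 0, 1: 1}
        self.onehot_levels_ = {col: list(levels) for col, levels in CLINICAL_MULTICLASS.items()}
        cols = list(CLINICAL_NUMERIC) + list(CLINICAL_BINARY)
        for col, levels in self.onehot_levels_.items():
            cols += [f"{col}={lvl}" for lvl in levels]
        self.columns_ = cols
        return self

    def transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "columns_"):
            raise ConfigError("ClinicalEncoder is not fitted")
        validate_clinical(clinical)
        out = pd.DataFrame(index=clinical.index)
        for col in CLINICAL_NUMERIC:
            out[col] = clinical[col].astype(float)
        for col in CLINICAL_BINARY:
            mapping = self.level_maps_[col]
            unseen = set(clinical[col]) - set(mapping)
            if unseen:
                raise DataError(f"unseen level(s) in {col}: {sorted(map(str, unseen))}")
            out[col] = clinical[col].map(mapping).astype(float)
        for col, levels in self.onehot_levels_.items():
            unseen = set(clinical[col]) - set(levels)
            if unseen:
                raise DataError(f"unseen level(s) in {col}: {sorted(map(str, unseen))}")
            for lvl in levels:
                out[f"{col}={lvl}"] = (clinical[col] == lvl).astype(float)
        return out[self.columns_]

    def fit_transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        return self.fit(clinical).transform(clinical)

    def inverse_transform(self, encoded: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=encoded.index)
        for col in CLINICAL_NUMERIC:
            out[col] = encoded[col]
        for col in CLINICAL_BINARY:
            inv = {v: k for k, v in self.level_maps_[col].items()}
            out[col] = encoded[col].astype(int).map(inv)
        for col, levels in self.onehot_levels_.items():
            block = encoded[[f"{col}={lvl}" for lvl in levels]].to_numpy()
            if not np.allclose(block.sum(axis=1), 1.0):
                raise DataError(f"one-hot group {col} does not sum to 1")
            out[col] = [levels[i] for i in block.argmax(axis=1)]
        return out

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "ClinicalEncoder":
        if params:
            raise ConfigError("ClinicalEncoder has no parameters")
        return self


@dataclass
class FeatureMatrix:
    """Encoded (not yet standardized) design matrix with per-column metadata.

    ``provenance`` tags each column "gene" or "clinical"; ``encoding`` tags
    it "numeric" (to be standardized), "binary", or "onehot".
    """

    data: pd.DataFrame
    provenance: dict[str, str]
    encoding: dict[str, str]

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if set(cols) != set(self.provenance) or set(cols) != set(self.encoding):
            raise DataError("feature metadata does not match columns")
        if self.data.isna().any().any():
            raise DataError("feature matrix contains missing values")

    @property
    def numeric_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.encoding[c] == "numeric"]

    def restrict(self, provenance: str) -> "FeatureMatrix":
        cols = [c for c in self.data.columns if self.provenance[c] == provenance]
        return FeatureMatrix(self.data[cols], {c: provenance for c in cols}, {c: self.encoding[c] for c in cols})


class Standardizer:
    """(x - mean)/SD per column, population SD, fitted on a sample subset.

    Zero-variance columns (on the fit subset) are dropped with a warning
    and recorded in ``dropped_``.
    """

    def fit(self, data: pd.DataFrame, fit_on=None) -> "Standardizer":
        sub = data.loc[list(fit_on)] if fit_on is not None else data
        if len(sub) == 0:
            raise ConfigError("empty fit subset")
        mean = sub.mean()
        sd = sub.std(ddof=0)
        self.dropped_ = list(sd.index[sd == 0])
        if self.dropped_:
            warnings.warn(f"dropping {len(self.dropped_)} zero-variance feature(s): {self.dropped_[:5]}", stacklevel=2)
        keep = [c for c in data.columns if c not in set(self.dropped_)]
        self.mean_ = mean[keep]
        self.sd_ = sd[keep]
        self.record_ = {"sd_convention": "population", "fit_n": len(sub)}
        return self

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mean_"):
            raise ConfigError("Standardizer is not fitted")
        return (data[self.mean_.index] - self.mean_) / self.sd_

    def fit_transform(self, data: pd.DataFrame, fit_on=None) -> pd.DataFrame:
        return self.fit(data, fit_on=fit_on).transform(data)


def encode_clinical(clinical: pd.DataFrame) -> FeatureMatrix:
    """Encode the clinical table into a FeatureMatrix (label column ignored)."""
    enc = ClinicalEncoder().fit(clinical)
    data = enc.transform(clinical)
    encoding = {c: ("numeric" if c in CLINICAL_NUMERIC else "onehot" if "=" in c else "binary") for c in data.columns}
    return FeatureMatrix(data, {c: "clinical" for c in data.columns}, encoding)


def assemble(expr: ExpressionMatrix | None, clinical: pd.DataFrame | None, mode: str = "genes+clinical") -> FeatureMatrix:
    """Join gene and clinical features per the experiment mode."""
    if mode not in {"genes-only", "clinical-only", "genes+clinical"}:
        raise ConfigError(f"unknown feature mode {mode!r}")
    parts = []
    if mode != "clinical-only":
        if expr is None:
            raise ConfigError("gene features requested but no expression given")
        gene_fm = FeatureMatrix(
            expr.values, {c: "gene" for c in expr.values.columns}, {c: "numeric" for c in expr.values.columns}
        )
        parts.append(gene_fm)
    if mode != "genes-only":
        if clinical is None:
            raise ConfigError("clinical features requested but no clinical table given")
        parts.append(encode_clinical(clinical))
    if len(parts) == 2 and list(parts[0].data.index) != list(parts[1].data.index):
        raise DataError("expression and clinical sample ids disagree")
    data = pd.concat([p.data for p in parts], axis=1)
    prov = {k: v for p in parts for k, v in p.provenance.items()}
    enc = {k: v for p in parts for k, v in p.encoding.items()}
    return FeatureMatrix(data, prov, enc)


def standardize(fm: FeatureMatrix, fit_on=None) -> tuple[FeatureMatrix, Standardizer]:
    """Standardize the numeric columns of a FeatureMatrix; returns the scaler.

    Binary and one-hot columns pass through unchanged.  Numeric columns with
    zero variance on the fit subset are dropped from the output.
    """
    num = fm.numeric_columns
    scaler = Standardizer().fit(fm.data[num], fit_on=fit_on)
    out = fm.data.drop(columns=scaler.dropped_).copy()
    scaled = scaler.transform(fm.data)
    out[scaled.columns] = scaled
    keep = [c for c in out.columns]
    return (
        FeatureMatrix(out, {c: fm.provenance[c] for c in keep}, {c: fm.encoding[c] for c in keep}),
        scaler,
    )
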
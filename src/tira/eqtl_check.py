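"""Direction-concordance between group allele frequencies, eQTL signs, and
model coefficient signs.

Logic: if cases carry fewer copies of an expression-lowering allele, their
imputed expression is higher, so a positive case/control association
coefficient is the concordant direction — i.e. concordant iff

    sign(freq_case - freq_control) * eqtl_slope_sign == model_beta_sign.

eQTL records are supplied as a small TSV (external effect sizes are inputs,
never recomputed here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, labels_to_binary
from .errors import DataError

__all__ = ["EqtlRecord", "ConcordanceResult", "read_eqtl_tsv", "group_allele_freq", "concordance", "freq_diff_test"]


@dataclass
class EqtlRecord:
    variant_id: str
    gene_id: str
    effect_allele: str
    slope_sign: int  # +1 or -1
    slope: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.slope_sign not in (-1, 1):
            raise DataError("slope_sign must be +1 or -1")
        if self.slope is not None and np.sign(self.slope) != self.slope_sign:
            raise DataError("slope_sign inconsistent with slope")


@dataclass
class ConcordanceResult:
    gene_id: str
    freq_case: float
    freq_control: float
    freq_diff_sign: int  # sign(freq_case - freq_control); 0 = indeterminate
    eqtl_slope_sign: int
    model_beta_sign: int
    concordant: bool | None  # None when indeterminate


def read_eqtl_tsv(path: str | Path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"source", "variant_id", "gene_id", "effect_allele", "slope"}
    if not need <= set(df.columns):
        raise DataError(f"eQTL TSV lacks columns: {sorted(need - set(df.columns))}")
    return [
        EqtlRecord(r.variant_id, r.gene_id, r.effect_allele, int(np.sign(r.slope)), float(r.slope), r.source)
        for r in df.itertuples()
    ]


def group_allele_freq(g: GenotypeMatrix, labels: pd.Series, variant_id: str) -> tuple[float, float]:
    """Alt-allele frequency in cases and controls: sum(dosage) / (2 * non-missing)."""
    if variant_id not in g.dosages.columns:
        raise DataError(f"variant {variant_id} absent from genotypes")
    y = labels_to_binary(labels.loc[g.sample_ids])
    col = g.dosages[variant_id]
    out = []
    for grp in (1, 0):
        sub = col[y == grp].dropna()
        if len(sub) == 0:
            raise DataError(f"group {grp} empty or all-missing at {variant_id}")
        out.append(float(sub.sum() / (2 * len(sub))))
    return out[0], out[1]


def concordance(freqs: tuple[float, float], eqtl: EqtlRecord, beta_sign: int) -> ConcordanceResult:
    """Sign-concordance of allele-frequency difference, eQTL slope, and model beta."""
    if beta_sign not in (-1, 1):
        raise DataError("beta_sign must be +1 or -1")
    fc, f0 = freqs
    if not (0 <= fc <= 1 and 0 <= f0 <= 1):
        raise DataError("frequencies must lie in [0,1]")
    d = int(np.sign(fc - f0))
    conc = None if d == 0 else (d * eqtl.slope_sign == beta_sign)
    return ConcordanceResult(eqtl.gene_id, fc, f0, d, eqtl.slope_sign, beta_sign, conc)


def freq_diff_test(case_counts: tuple[int, int], control_counts: tuple[int, int]) -> float:
    """Two-sided exact test on the allele-count 2x2 table.

    ``case_counts`` and ``control_counts`` are (alt, ref) allele counts per
    group.  Convention: Fisher exact on the allele table (recorded here; a
    genotypic trend test is deliberately not the default since the printed
    group frequencies are allele-based).
    """
    table = np.array([list(case_counts), list(control_counts)])
    if (table < 0).any():
        raise DataError("negative allele counts")
    if table.sum(axis=1).min() == 0:
        raise DataError("empty group")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
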
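"""Genotype quality control.

Sample filters: call rate > 95%, heterozygosity rate within ±3 SD of the
cohort mean (SD taken over the samples that pass the call-rate filter;
single pass, call rate first).  Variant filters: minor allele frequency
>= 0.05 and an exact Hardy–Weinberg test p >= 0.001.  The HWE test is the
Levene–Haldane conditional (exact) test, the convention of standard GWAS
QC tooling; it is computed here in exact integer arithmetic, so ties in the
conditional probability are resolved without floating-point ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ConfigError, DataError

__all__ = ["QCThresholds", "QCReport", "hwe_exact", "sample_qc", "variant_qc", "apply_qc"]


@dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.95
    het_sd_bound: float = 3.0
    maf_min: float = 0.05
    hwe_p_min: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.sample_call_rate_min <= 1 and 0 <= self.maf_min <= 0.5 and 0 <= self.hwe_p_min <= 1):
            raise ConfigError("QC thresholds out of range")
        if self.het_sd_bound <= 0:
            raise ConfigError("het_sd_bound must be positive")


@dataclass
class QCReport:
    """Per-sample / per-variant metrics with pass flags and removal counts."""

    samples: pd.DataFrame | None = None
    variants: pd.DataFrame | None = None
    removed: dict[str, int] = field(default_factory=dict)

    @property
    def retained_samples(self) -> list[str]:
        if self.samples is None:
            raise DataError("no sample metrics in report")
        return list(self.samples.index[self.samples["pass"]])

    @property
    def retained_variants(self) -> list[str]:
        if self.variants is None:
            raise DataError("no variant metrics in report")
        return list(self.variants.index[self.variants["pass"]])


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value (Levene–Haldane, mid-p off).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability is less than or equal
    to that of the observed count.  Monomorphic sites return 1.0.
    """
    a, b, c = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(a, b, c) < 0:
        raise ConfigError("genotype counts must be nonnegative")
    n = a + b + c
    if n == 0:
        raise ConfigError("need at least one observation")
    n_ref, n_alt = 2 * a + b, b + 2 * c
    if n_ref == 0 or n_alt == 0:
        return 1.0
    # Integer weights W(h) proportional to the conditional pmf of the
    # heterozygote count h: W(h) = 2^h * n! / (homref! h! homalt!).
    h_min = n_ref % 2
    h_max = min(n_ref, n_alt)
    fact_n = factorial(n)
    weights = {}
    for h in range(h_min, h_max + 1, 2):
        weights[h] = (2**h) * fact_n // (factorial((n_ref - h) // 2) * factorial(h) * factorial((n_alt - h) // 2))
    w_obs = weights[b]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def _call_rate(dosages: pd.DataFrame, axis: int) -> pd.Series:
    return dosages.notna().mean(axis=axis)


def _het_rate(dosages: pd.DataFrame) -> pd.Series:
    """Heterozygous calls / non-missing calls per sample (hard-call rounding)."""
    rounded = dosages.round()
    het = rounded.eq(1).sum(axis=1)
    nonmiss = dosages.notna().sum(axis=1)
    return (het / nonmiss.where(nonmiss > 0)).fillna(0.0)


def sample_qc(g: GenotypeMatrix, t: QCThresholds | None = None) -> QCReport:
    """Call-rate filter, then heterozygosity outlier filter.

    The heterozygosity mean/SD (population SD) are computed over the samples
    that survive the call-rate filter; a sample exactly on the bound passes.
    """
    t = t or QCThresholds()
    if g.n_samples < 2:
        raise DataError("sample QC needs >= 2 samples")
    call = _call_rate(g.dosages, axis=1)
    pass_call = call > t.sample_call_rate_min
    het = _het_rate(g.dosages)
    mu = het[pass_call].mean() if pass_call.any() else np.nan
    sd = het[pass_call].std(ddof=0) if pass_call.any() else np.nan
    if pass_call.any():
        within = (het - mu).abs() <= t.het_sd_bound * sd + 1e-15
    else:
        within = pd.Series(False, index=het.index)
    passed = pass_call & within
    df = pd.DataFrame({"call_rate": call, "het_rate": het, "pass_call_rate": pass_call, "pass_het": within, "pass": passed})
    df.index.name = "sample_id"
    removed = {
        "call_rate": int((~pass_call).sum()),
        "heterozygosity": int((pass_call & ~within).sum()),
    }
    return QCReport(samples=df, removed=removed)


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    rounded = np.round(col[np.isfinite(col)]).astype(int)
    return int((rounded == 0).sum()), int((rounded == 1).sum()), int((rounded == 2).sum())


def variant_qc(g: GenotypeMatrix, t: QCThresholds | None = None) -> QCReport:
    """MAF and exact-HWE variant filters (run after sample QC).

    MAF is min(f, 1-f) with f = mean dosage / 2 over non-missing calls; a
    variant with zero non-missing calls is removed with reason "no data".
    """
    t = t or QCThresholds()
    dos = g.dosages.to_numpy(dtype=float)
    rows = []
    for j, vid in enumerate(g.variant_ids):
        col = dos[:, j]
        n_obs = int(np.isfinite(col).sum())
        if n_obs == 0:
            rows.append((vid, 0.0, np.nan, np.nan, False, "no data"))
            continue
        f = np.nanmean(col) / 2.0
        maf = min(f, 1.0 - f)
        p_hwe = hwe_exact(*_genotype_counts(col))
        ok = (maf >= t.maf_min) and (p_hwe >= t.hwe_p_min)
        reason = "" if ok else ("maf" if maf < t.maf_min else "hwe")
        rows.append((vid, n_obs / len(col), maf, p_hwe, ok, reason))
    df = pd.DataFrame(rows, columns=["id", "call_rate", "maf", "hwe_p", "pass", "reason"]).set_index("id")
    removed = {
        "no data": int((df["reason"] == "no data").sum()),
        "maf": int((df["reason"] == "maf").sum()),
        "hwe": int((df["reason"] == "hwe").sum()),
    }
    return QCReport(variants=df, removed=removed)


def apply_qc(g: GenotypeMatrix, t: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Sample QC then variant QC; returns the filtered matrix and a merged report."""
    t = t or QCThresholds()
    srep = sample_qc(g, t)
    g2 = g.subset(samples=srep.retained_samples)
    vrep = variant_qc(g2, t)
    g3 = g2.subset(variants=vrep.retained_variants)
    report = QCReport(samples=srep.samples, variants=vrep.variants, removed={**srep.removed, **vrep.removed})
    return g3, report
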
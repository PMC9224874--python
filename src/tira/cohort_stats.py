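"""Baseline cohort comparisons between NDR and DR groups.

Continuous characteristics are compared with the pooled-variance Student
t-test (computable from printed group summaries); categorical ones with the
Pearson chi-square test without continuity correction, falling back to the
two-sided Fisher exact test when any observed margin cell is zero or any
expected count is below 1.  The test used is recorded per row; per-row
overrides allow forcing either test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CLINICAL_BINARY, CLINICAL_MULTICLASS, CLINICAL_NUMERIC, labels_to_binary, validate_clinical
from .errors import DataError

__all__ = ["SummaryStat", "pooled_t_from_summary", "chi_square", "fisher_exact_2x2", "table1"]


@dataclass
class SummaryStat:
    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2 or self.sd < 0:
            raise DataError("summary needs n >= 2 and sd >= 0")


def pooled_t_from_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, int, float]:
    """Student pooled-variance t-test from (n, mean, sd) summaries."""
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        return 0.0, a.n + b.n - 2, 1.0
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True)
    return float(t), a.n + b.n - 2, float(p)


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if arr.ndim != 2 or (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise DataError("contingency table must be 2-D nonnegative integers")
    return np.round(arr).astype(int)


def chi_square(t, correction: str = "none") -> tuple[float, int, float]:
    """Pearson chi-square; df = (r-1)(c-1); continuity correction off by default."""
    arr = _as_table(t)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("zero margin row/column")
    res = stats.chi2_contingency(arr, correction=(correction == "yates"))
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact_2x2(t) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability convention)."""
    arr = _as_table(t)
    if arr.shape != (2, 2):
        raise DataError("fisher_exact_2x2 needs a 2x2 table")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


#: Continuous / categorical rows of the baseline table, in report order.
_TABLE1_ROWS = CLINICAL_NUMERIC + ["sex", "smoking", "family_history", "location", "upper_gi", "behavior", "perianal"]


def _crosstab(series: pd.Series, y: pd.Series, levels=None) -> np.ndarray:
    """Rows = NDR, DR; columns = levels of the variable."""
    if levels is None:
        levels = sorted(set(series))
    return np.array([[int(((series == lvl) & (y == grp)).sum()) for lvl in levels] for grp in (1, 0)])


def table1(clinical: pd.DataFrame, overrides: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-variable NDR-vs-DR comparison with the test recorded per row.

    ``overrides`` maps a variable name to "chi2" or "fisher" (2x2 only) to
    force that test for the row.
    """
    validate_clinical(clinical, require_label=True)
    overrides = overrides or {}
    y = labels_to_binary(clinical["label"])
    rows = []
    for var in _TABLE1_ROWS:
        if var in CLINICAL_NUMERIC:
            g1, g0 = clinical.loc[y == 1, var], clinical.loc[y == 0, var]
            a = SummaryStat("NDR", len(g1), g1.mean(), g1.std(ddof=1))
            b = SummaryStat("DR", len(g0), g0.mean(), g0.std(ddof=1))
            _, _, p = pooled_t_from_summary(a, b)
            rows.append((var, "pooled-t", p, f"{a.mean:.1f} ({a.sd:.1f})", f"{b.mean:.1f} ({b.sd:.1f})"))
            continue
        levels = CLINICAL_MULTICLASS.get(var)
        if levels is None and clinical[var].dtype == object:
            levels = sorted(set(clinical[var]))
        tab = _crosstab(clinical[var], y, levels=levels)
        forced = overrides.get(var)
        expected = stats.contingency.expected_freq(tab) if tab.min() >= 0 else None
        use_fisher = forced == "fisher" or (
            forced is None and tab.shape == (2, 2) and ((tab == 0).any() or (expected < 1).any())
        )
        if use_fisher and tab.shape == (2, 2):
            p, test = fisher_exact_2x2(tab), "fisher"
        else:
            _, _, p = chi_square(tab)
            test = "chi2"
        summ1 = "/".join(str(v) for v in tab[0])
        summ0 = "/".join(str(v) for v in tab[1])
        rows.append((var, test, p, summ1, summ0))
    return pd.DataFrame(rows, columns=["variable", "test", "p", "NDR", "DR"]).set_index("variable")
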
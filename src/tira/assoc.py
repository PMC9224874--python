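"""Univariate logistic association of imputed expression with NDR/DR status.

For each gene, a maximum-likelihood fit of logit P(NDR) = alpha + beta * x
with a two-sided Wald p-value (the PrediXcan association convention).
Expression is standardized before fitting by default so beta is the log-odds
per SD of imputed expression and comparable across genes; a raw-scale mode
is available.  Perfect separation is detected and reported as a flagged
result rather than a finite estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import ExpressionMatrix, labels_to_binary
from .errors import DataError

__all__ = ["AssociationResult", "univariate_logistic", "assoc_all"]


@dataclass
class AssociationResult:
    gene_id: str
    beta: float
    se: float
    p: float
    n_used: int
    flag: str = ""  # "", "separation", "not converged"


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    x1, x0 = x[y == 1], x[y == 0]
    return x1.min() > x0.max() or x1.max() < x0.min()


def univariate_logistic(x: pd.Series | np.ndarray, y, standardize: bool = True, gene_id: str = "") -> AssociationResult:
    """Single-gene logistic association; flags separation and non-convergence."""
    xv = np.asarray(x, dtype=float)
    yv = labels_to_binary(pd.Series(y)).to_numpy()
    if len(xv) != len(yv):
        raise DataError("x and y lengths differ")
    if yv.min() == yv.max():
        raise DataError("single-class labels")
    sd = xv.std()
    if sd == 0:
        raise DataError("constant expression vector")
    if standardize:
        xv = (xv - xv.mean()) / sd
    if _is_separated(xv, yv):
        return AssociationResult(gene_id, np.nan, np.nan, np.nan, len(xv), flag="separation")
    design = sm.add_constant(xv)
    try:
        fit = sm.Logit(yv, design).fit(disp=0, maxiter=200)
    except Exception:
        return AssociationResult(gene_id, np.nan, np.nan, np.nan, len(xv), flag="not converged")
    if not fit.mle_retvals.get("converged", True) or not np.isfinite(fit.bse[1]) or fit.bse[1] <= 0:
        return AssociationResult(gene_id, np.nan, np.nan, np.nan, len(xv), flag="not converged")
    return AssociationResult(gene_id, float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), len(xv))


def assoc_all(expr: ExpressionMatrix | pd.DataFrame, y, standardize: bool = True) -> pd.DataFrame:
    """Per-gene association table sorted by p (beta > 0 = risk-increasing for NDR).

    No multiple-testing adjustment is applied by default (raw p-values);
    a Benjamini–Hochberg column can be added with ``adjust`` in the CLI.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 2:
        raise DataError("need >= 2 genes")
    rows = []
    for gene in values.columns:
        try:
            r = univariate_logistic(values[gene], y, standardize=standardize, gene_id=gene)
        except DataError as exc:
            r = AssociationResult(gene, np.nan, np.nan, np.nan, len(values), flag=str(exc))
        rows.append(r)
    df = pd.DataFrame(
        [(r.gene_id, r.beta, r.se, r.p, r.n_used, r.flag, "NDR-risk" if r.beta > 0 else "NDR-protective" if r.beta < 0 else "")
         for r in rows],
        columns=["gene", "beta", "se", "p", "n", "flag", "direction"],
    )
    return df.sort_values("p", na_position="last", kind="mergesort").reset_index(drop=True)
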
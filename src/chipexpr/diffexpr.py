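"""Knockdown differential expression.

Microarray-style preprocessing (background correction with a positivity
floor, log2 transform, quantile normalization between arrays, optional
probe-to-gene collapsing), a per-gene two-sample pooled-variance Student's
t-test against the knockdown condition, Benjamini–Hochberg adjustment, and
the decreased/increased gene-set definition at an adjusted-p cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ValidationError


@dataclass
class DEResult:
    """Per-gene differential expression between knockdown and control.

    ``delta`` = mean(knockdown) − mean(control); ``direction`` is
    'decreased' / 'increased' (significant at the chosen alpha) or 'ns'.
    """

    gene_id: str
    mean_control: float
    mean_knockdown: float
    delta: float
    t_stat: float
    p: float
    p_adj: float
    direction: str


def background_correct_half(signal: np.ndarray, background: np.ndarray,
                            floor: float = 0.5) -> np.ndarray:
    """Background-subtract with a positivity floor: max(signal − bg, floor).

    The floor guarantees strictly positive corrected intensities so a log
    transform is always defined.
    """
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if signal.shape != background.shape:
        raise ValidationError(
            f"signal shape {signal.shape} != background shape {background.shape}"
        )
    if np.any(background < 0):
        raise ValidationError("background intensities must be non-negative")
    return np.maximum(signal - background, floor)


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Force all columns (arrays) to share one common value distribution.

    Each column's sorted values are replaced by the row means of the
    column-wise sorted matrix; ties within a column receive the mean of
    the quantile values they span.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 columns")
    if not np.all(np.isfinite(matrix)):
        raise ValidationError("missing values are not allowed")
    reference = np.sort(matrix, axis=0).mean(axis=1)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        # average rank handles ties: tied entries get the mean of the
        # reference quantiles their ranks span
        ranks = stats.rankdata(col, method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (reference[lo] + reference[hi]) / 2.0
    return out


def gene_t_test(expr: ExpressionMatrix, gene_id: str) -> Tuple[float, float]:
    """Two-sample pooled-variance Student's t for one gene, two-sided p.

    t = (mean_control − mean_knockdown)/se, so an expression increase
    after knockdown gives a negative t.
    Degenerate case: zero pooled variance with equal means gives t=0, p=1.
    """
    row = expr.row(gene_id)
    idx_c = [i for i, s in enumerate(expr.sample_ids)
             if expr.condition_map[s] == "control"]
    idx_k = [i for i, s in enumerate(expr.sample_ids)
             if expr.condition_map[s] == "knockdown"]
    if len(idx_c) < 2 or len(idx_k) < 2:
        raise ValidationError("need >= 2 samples per condition")
    c, k = row[idx_c], row[idx_k]
    if np.var(c, ddof=1) == 0 and np.var(k, ddof=1) == 0 and c.mean() == k.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(c, k, equal_var=True)
    return float(t), float(p)


def bh_adjust(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    ``method='bonferroni'`` is available as a conservative alternative.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=sm_method)[1]


def run_de(expr: ExpressionMatrix, alpha: float = 0.001,
           adjust_method: str = "bh") -> List[DEResult]:
    """Full per-gene DE table: t, p, BH-adjusted p, direction at ``alpha``.

    Vectorised over genes; direction refers to expression after knockdown
    ('decreased' = lower in knockdown than control).
    """
    control = expr.columns_for("control")
    knockdown = expr.columns_for("knockdown")
    if control.shape[1] < 2 or knockdown.shape[1] < 2:
        raise ValidationError("need >= 2 samples per condition")
    import warnings as _warnings
    with _warnings.catch_warnings():
        # degenerate rows (zero variance after tie-heavy normalization)
        # are mapped to t=0, p=1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(control, knockdown, axis=1, equal_var=True)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    p_adj = bh_adjust(p, method=adjust_method)
    mean_c = control.mean(axis=1)
    mean_k = knockdown.mean(axis=1)
    delta = mean_k - mean_c
    results = []
    for i, gene_id in enumerate(expr.row_ids):
        if p_adj[i] < alpha and delta[i] < 0:
            direction = "decreased"
        elif p_adj[i] < alpha and delta[i] > 0:
            direction = "increased"
        else:
            direction = "ns"
        results.append(DEResult(gene_id, float(mean_c[i]), float(mean_k[i]),
                                float(delta[i]), float(t[i]), float(p[i]),
                                float(p_adj[i]), direction))
    return results


def de_sets(results: Sequence[DEResult], alpha: float,
            use_adjusted: bool = True) -> Tuple[Set[str], Set[str]]:
    """(decreased-after-knockdown, increased-after-knockdown) gene-id sets.

    By default significance is the BH-adjusted p.  ``use_adjusted=False``
    thresholds the raw p instead — appropriate for small designs (a
    handful of arrays per condition) where the t-test's few degrees of
    freedom bound the attainable adjusted p well above a stringent alpha.
    """
    key = (lambda r: r.p_adj) if use_adjusted else (lambda r: r.p)
    decreased = {r.gene_id for r in results if key(r) < alpha and r.delta < 0}
    increased = {r.gene_id for r in results if key(r) < alpha and r.delta > 0}
    return decreased, increased


def preprocess_microarray(
    signal: np.ndarray, background: np.ndarray,
    log2: bool = True,
) -> np.ndarray:
    """Background-correct (positivity floor), optional log2, quantile-normalize."""
    corrected = background_correct_half(signal, background)
    if log2:
        corrected = np.log2(corrected)
    return quantile_normalize(corrected)


def collapse_probes(values: np.ndarray, probe_ids: Sequence[str],
                    probe_to_gene: Dict[str, str]) -> Tuple[List[str], np.ndarray]:
    """Collapse multiple probes per gene to the per-gene median profile."""
    df = pd.DataFrame(values, index=[probe_to_gene.get(p, p) for p in probe_ids])
    collapsed = df.groupby(level=0).median()
    return [str(i) for i in collapsed.index], collapsed.to_numpy()


def write_de_table(results: Sequence[DEResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmean_control\tmean_knockdown\tdelta\tt\tp\tp_adj\tdirection\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.mean_control:.6g}\t{r.mean_knockdown:.6g}\t"
                f"{r.delta:.6g}\t{r.t_stat:.6g}\t{r.p:.6g}\t{r.p_adj:.6g}\t"
                f"{r.direction}\n"
            )


def read_de_table(path: str) -> List[DEResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        DEResult(str(r.gene_id), r.mean_control, r.mean_knockdown, r.delta,
                 r.t, r.p, r.p_adj, r.direction)
        for r in df.itertuples(index=False)
    ]
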
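"""Differential expression / accessibility on feature x sample count matrices.

Study-scale DEG/DAR lists in this field come from dedicated count-model
packages run on centrally normalised data.  This module provides two
routes behind one table schema:

* a fully specified, self-contained negative-binomial Wald test (median-of-
  ratios size factors, method-of-moments per-feature overdispersion,
  delta-method variance of the log2 group means) so the whole pipeline is
  testable end-to-end without any external download, and
* a pass-through loader for externally computed differential tables, whose
  significance flags are re-derived here so threshold semantics stay
  uniform.

Significance thresholds are strict on both sides: ``padj < max_padj`` and
``|log2fc| > min_abs_log2fc``.  Defaults follow the study: expression uses
padj < 0.001, accessibility FDR < 0.01, both with |log2FC| > log2(1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .genomic_io import CountMatrix, read_differential_table
from .stats import bh_adjust

__all__ = [
    "DiffParams",
    "DEG_PARAMS",
    "DAR_PARAMS",
    "size_factors",
    "nb_wald_test",
    "apply_thresholds",
    "load_external_differential",
]

LN2_SQ = np.log(2.0) ** 2


@dataclass
class DiffParams:
    max_padj: float = 0.001
    min_abs_log2fc: float = float(np.log2(1.5))
    pseudocount: float = 0.5
    dispersion_floor: float = 1e-8

    def __post_init__(self) -> None:
        if self.max_padj <= 0 or self.min_abs_log2fc <= 0:
            raise ValueError("thresholds must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def DEG_PARAMS() -> DiffParams:
    """Expression thresholds: padj < 0.001, |log2FC| > log2(1.5)."""
    return DiffParams(max_padj=0.001)


def DAR_PARAMS() -> DiffParams:
    """Accessibility thresholds: FDR < 0.01, |log2FC| > log2(1.5)."""
    return DiffParams(max_padj=0.01)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    The per-feature geometric mean is taken over samples, restricted to
    features with strictly positive counts in every sample; each sample's
    factor is the median over those features of count / geometric mean.
    """
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "consider a pseudocount before computing size factors"
        )
    logx = np.log(x[allpos])
    geo = np.exp(logx.mean(axis=1, keepdims=True))
    factors = np.median(x[allpos] / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald_test(
    cm: CountMatrix,
    sf: pd.Series | None = None,
    params: DiffParams | None = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of exposed vs control group means.

    Per feature, with normalised counts ``y = k / s``: ``log2fc =
    log2((m1 + c) / (m0 + c))`` over group means; a single
    method-of-moments overdispersion ``alpha = max(floor, (pooled within-
    group variance − pooled mean) / pooled mean²)``; delta-method variance
    of each group's log2 mean ``Vg = (1/(m_g + c) + alpha) / (n_g ln²2)``;
    ``z = log2fc / sqrt(V0 + V1)`` referred two-sided to a Student-t
    distribution with ``n0 + n1 - 2`` degrees of freedom (the variance is
    estimated from few replicates, and the t reference is what keeps the
    null p-values uniform at these group sizes).  Features with all-zero
    counts in both groups are reported untested (NaN p); BH runs over the
    tested features only.
    """
    params = params or DiffParams()
    ctrl = cm.group_samples("control")
    expo = cm.group_samples("exposed")
    if len(ctrl) < 2 or len(expo) < 2:
        raise ValueError("each group needs >= 2 samples")
    if sf is None:
        sf = size_factors(cm.counts)
    sf = sf.loc[cm.counts.columns]
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    y = cm.counts.to_numpy(float) / sf.to_numpy(float)[None, :]
    i0 = [cm.counts.columns.get_loc(s) for s in ctrl]
    i1 = [cm.counts.columns.get_loc(s) for s in expo]
    y0, y1 = y[:, i0], y[:, i1]
    n0, n1 = y0.shape[1], y1.shape[1]
    m0 = y0.mean(axis=1)
    m1 = y1.mean(axis=1)
    c = params.pseudocount
    log2fc = np.log2((m1 + c) / (m0 + c))

    ss0 = ((y0 - m0[:, None]) ** 2).sum(axis=1)
    ss1 = ((y1 - m1[:, None]) ** 2).sum(axis=1)
    pooled_var = (ss0 + ss1) / (n0 + n1 - 2)
    pooled_mean = np.concatenate([y0, y1], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, params.dispersion_floor)
    alpha = np.maximum(alpha, params.dispersion_floor)

    v0 = (1.0 / (m0 + c) + alpha) / (n0 * LN2_SQ)
    v1 = (1.0 / (m1 + c) + alpha) / (n1 * LN2_SQ)
    z = log2fc / np.sqrt(v0 + v1)
    tested = (m0 + m1) > 0
    p = np.full(len(z), np.nan)
    p[tested] = 2.0 * t_dist.sf(np.abs(z[tested]), df=n0 + n1 - 2)
    p = np.minimum(p, 1.0)
    padj = np.full(len(z), np.nan)
    if tested.any():
        padj[tested] = bh_adjust(p[tested])
    table = pd.DataFrame(
        {
            "feature": cm.counts.index.astype(str),
            "base_mean": pooled_mean,
            "log2fc": log2fc,
            "alpha": alpha,
            "z": z,
            "p": p,
            "padj": padj,
        }
    )
    return apply_thresholds(table, params)


def apply_thresholds(table: pd.DataFrame, params: DiffParams) -> pd.DataFrame:
    """Set ``significant`` and ``direction`` with strict threshold semantics.

    A feature sitting exactly at ``padj == max_padj`` or ``|log2fc| ==
    min_abs_log2fc`` is *not* significant.
    """
    out = table.copy()
    padj = out["padj"].to_numpy(float)
    lfc = out["log2fc"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        sig = (padj < params.max_padj) & (np.abs(lfc) > params.min_abs_log2fc)
    out["significant"] = np.where(np.isnan(padj), False, sig)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", None))
    out["direction"] = direction
    return out


def load_external_differential(path, params: DiffParams | None = None) -> pd.DataFrame:
    """Load a third-party differential table and re-apply thresholds.

    The file must carry the documented header (feature, log2fc, p, padj,
    significant, direction); the incoming significance flags are replaced so
    that strict-threshold semantics match the internal test.
    """
    table = read_differential_table(path)
    return apply_thresholds(table, params or DiffParams())
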
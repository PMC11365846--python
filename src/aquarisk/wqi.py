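"""Integrated-weight drinking-water quality index.

Two objective weighting routes — information entropy and CRITIC
(inter-criteria correlation) — are computed from the cohort's min–max
normalised parameter matrix, merged into a single weight vector, and applied
to per-parameter quality ratings to produce the index and its class label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    WQI_PARAMETERS,
    WQI_SCHEME,
    ClassificationScheme,
    StandardsTable,
)

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import SampleTable, WaterSample

__all__ = [
    "NormalizedMatrix",
    "WeightSet",
    "WqiResult",
    "normalize",
    "entropy_weights",
    "critic_weights",
    "integrate_weights",
    "quality_rating",
    "compute_wqi",
    "weight_pipeline",
]


class DegenerateColumnWarning(UserWarning):
    """A parameter is constant across the cohort and carries no information."""


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-wise min–max normalised parameter matrix with its extremes."""

    y: pd.DataFrame
    column_min: pd.Series
    column_max: pd.Series

    @property
    def parameters(self) -> list[str]:
        return list(self.y.columns)

    @property
    def degenerate(self) -> pd.Series:
        return self.column_max == self.column_min


@dataclass(frozen=True)
class WeightSet:
    """Entropy, CRITIC and integrated weight vectors plus their ingredients."""

    wj1: pd.Series
    wj2: pd.Series
    wj: pd.Series
    method: str
    p: float
    ej: pd.Series
    sj_info: pd.Series
    delta: pd.Series
    r: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"entropy_wj1": self.wj1, "critic_wj2": self.wj2,
             "integrated_wj": self.wj, "ej": self.ej,
             "sj_info": self.sj_info, "delta": self.delta}
        )


@dataclass(frozen=True)
class WqiResult:
    qj: pd.DataFrame       # per sample x parameter quality ratings (%)
    wqi: pd.Series         # per sample index
    label: pd.Series       # per sample class


def normalize(
    samples: "SampleTable | pd.DataFrame",
    parameters: Sequence[str] = WQI_PARAMETERS,
) -> NormalizedMatrix:
    """Min–max normalise the m x n parameter matrix columnwise to [0, 1].

    Requires m >= 2.  Zero-range columns normalise to all zeros and emit a
    :class:`DegenerateColumnWarning`.
    """
    x = samples if isinstance(samples, pd.DataFrame) else samples.matrix(parameters)
    x = x.loc[:, list(parameters)].astype(float)
    if len(x) < 2:
        raise ValueError(f"need at least 2 samples to normalise, got {len(x)}")
    lo, hi = x.min(axis=0), x.max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        warnings.warn(
            f"constant column(s) {list(span.index[degenerate])} normalised to 0",
            DegenerateColumnWarning,
            stacklevel=2,
        )
    safe = span.replace(0, 1.0)
    y = (x - lo) / safe
    y.loc[:, degenerate] = 0.0
    return NormalizedMatrix(y=y, column_min=lo, column_max=hi)


def entropy_weights(norm: NormalizedMatrix) -> pd.Series:
    """Shannon-entropy weights of the normalised columns.

    P_ij = Y_ij / sum_i Y_ij (0 where the column sum is 0), information
    entropy e_j = -(1/ln m) * sum_i P_ij ln P_ij with 0·ln 0 := 0, and
    w_j = (1 - e_j) / sum(1 - e_j).  A degenerate column gets e_j = 1 and
    therefore zero weight; all columns degenerate is an error.
    """
    y = norm.y.to_numpy(dtype=float)
    m = y.shape[0]
    col_sum = y.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(col_sum > 0, y / np.where(col_sum > 0, col_sum, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ej = -plogp.sum(axis=0) / np.log(m)
    ej = np.where(col_sum > 0, ej, 1.0)
    one_minus = 1.0 - ej
    total = one_minus.sum()
    if total <= 0:
        raise ValueError("all columns are degenerate; entropy weights undefined")
    return pd.Series(one_minus / total, index=norm.y.columns, name="wj1")


def information_entropy(norm: NormalizedMatrix) -> pd.Series:
    """Per-column information entropy e_j (same convention as entropy_weights)."""
    y = norm.y.to_numpy(dtype=float)
    m = y.shape[0]
    col_sum = y.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(col_sum > 0, y / np.where(col_sum > 0, col_sum, 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ej = -plogp.sum(axis=0) / np.log(m)
    return pd.Series(np.where(col_sum > 0, ej, 1.0), index=norm.y.columns, name="ej")


def critic_weights(norm: NormalizedMatrix) -> pd.Series:
    """CRITIC weights: S_j = delta_j * sum_k (1 - r_jk), w_j = S_j / sum S.

    delta_j is the (n-1) standard deviation of the normalised column and r the
    Pearson correlation matrix; a zero-variance column contributes zero
    correlation (and zero weight).
    """
    delta, sj, _, _ = _critic_parts(norm)
    total = sj.sum()
    if total <= 0:
        # perfectly mutually correlated columns carry no contrast information;
        # fall back to pure-dispersion weights
        if delta.sum() > 0:
            return pd.Series(delta / delta.sum(), index=norm.y.columns, name="wj2")
        raise ValueError("all columns are degenerate; CRITIC weights undefined")
    return pd.Series(sj / total, index=norm.y.columns, name="wj2")


def _critic_parts(
    norm: NormalizedMatrix,
) -> tuple[pd.Series, pd.Series, pd.Series, pd.DataFrame]:
    y = norm.y
    if len(y) < 3:
        warnings.warn("fewer than 3 samples: correlations are degenerate",
                      stacklevel=3)
    delta = y.std(ddof=1)
    r = y.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(r.values, 1.0)
    sj = delta * (1.0 - r).sum(axis=1)
    sj = sj.fillna(0.0)
    return delta, sj, (1.0 - r).sum(axis=1), r


def integrate_weights(
    wj1: pd.Series | Mapping[str, float],
    wj2: pd.Series | Mapping[str, float],
    method: str = "product",
    p: float = 0.5,
) -> pd.Series:
    """Merge the two weight vectors.

    ``method='product'``: w_j = w1_j w2_j / sum(w1 w2) (self-normalising).
    ``method='convex'``: w_j = p w1_j + (1-p) w2_j with p in [0, 1].
    """
    wj1 = pd.Series(wj1, dtype=float)
    wj2 = pd.Series(wj2, dtype=float).reindex(wj1.index)
    if wj2.isna().any():
        raise ValueError("weight vectors index different parameters")
    if method == "product":
        prod = wj1 * wj2
        total = prod.sum()
        if total <= 0:
            raise ValueError("product weights vanish; cannot normalise")
        out = prod / total
    elif method == "convex":
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {p}")
        out = p * wj1 + (1.0 - p) * wj2
    else:
        raise ValueError("method must be 'product' or 'convex'")
    return out.rename("wj")


def weight_pipeline(
    samples: "SampleTable | pd.DataFrame",
    parameters: Sequence[str] = WQI_PARAMETERS,
    method: str = "product",
    p: float = 0.5,
) -> WeightSet:
    """Normalise, weight by both routes, and integrate, in one call."""
    norm = normalize(samples, parameters)
    wj1 = entropy_weights(norm)
    ej = information_entropy(norm)
    delta, sj, _, r = _critic_parts(norm)
    wj2 = critic_weights(norm)
    wj = integrate_weights(wj1, wj2, method=method, p=p)
    return WeightSet(wj1=wj1, wj2=wj2, wj=wj, method=method, p=p,
                     ej=ej, sj_info=sj, delta=delta, r=r)


def quality_rating(
    sample: "WaterSample",
    standards: StandardsTable,
    parameters: Sequence[str] = WQI_PARAMETERS,
) -> pd.Series:
    """Per-parameter quality rating Q_j = 100 (C_j - C_jp) / (S_j - C_jp).

    Q_j is 0 at the pure-water ideal and 100 at the standard; pH is rated
    against ideal 7 / standard 7.5.
    """
    out = {}
    for param in parameters:
        if param not in standards:
            raise KeyError(f"no standard for parameter {param!r}")
        sj, cjp = standards.sj(param), standards.cjp(param)
        out[param] = (sample.parameter(param) - cjp) / (sj - cjp) * 100.0
    return pd.Series(out, name=sample.sample_id)


def compute_wqi(
    samples: "SampleTable",
    weights: pd.Series | Mapping[str, float],
    standards: StandardsTable,
    scheme: ClassificationScheme = WQI_SCHEME,
) -> WqiResult:
    """Index = sum_j W_j Q_j per sample, with its class label."""
    weights = pd.Series(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError(f"weights must sum to 1, got {weights.sum()}")
    qj = pd.DataFrame(
        [quality_rating(s, standards, list(weights.index)) for s in samples]
    )
    wqi = (qj * weights).sum(axis=1).rename("wqi")
    label = wqi.map(scheme.classify).rename("wqi_label")
    return WqiResult(qj=qj, wqi=wqi, label=label)
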
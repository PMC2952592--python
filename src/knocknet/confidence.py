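"""Edge-confidence matrices from single-gene knockout steady states.

A knockout compendium directly exposes causal influence: if deleting gene
*i* moves the steady state of gene *j*, then *j* is downstream of *i*.
Four scores quantify "moves", in increasing statistical sophistication:

``D``
    absolute deviation from wild type, ``|x^i_j - x^wt_j|``;
``ND``
    the same deviation normalized by the wild-type level of the target,
    so responses of weakly and strongly expressed genes are comparable;
``ZD``
    z-score of the deviation within the target gene's column — how unusual
    the response to knockout *i* is relative to all other knockouts;
``ZR``
    z-score of the *raw* post-knockout value within the target's column.
    Using raw values rather than deviations avoids subtracting one noisy
    measurement from another, which is why this variant benchmarks best.

All four return an N x N non-negative matrix with zero diagonal (a gene
cannot be its own regulator).  For the z-score variants the per-target
location and scale are computed with the sample (n-1) standard deviation
and, by default, exclude the target's own knockout row, whose raw value is
structurally zero and would otherwise bias the scale.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datasets import ConfidenceMatrix, ExpressionDataset
from .errors import ValidationError

__all__ = [
    "deviation_matrix",
    "normalized_deviation_matrix",
    "zscore_deviation_matrix",
    "zscore_raw_matrix",
    "confidence_matrix",
    "CONFIDENCE_METHODS",
]


def _deviations(data: ExpressionDataset) -> np.ndarray:
    return np.abs(data.knockout - data.wildtype[np.newaxis, :])


def _zero_diagonal(scores: np.ndarray) -> np.ndarray:
    np.fill_diagonal(scores, 0.0)
    return scores


def deviation_matrix(data: ExpressionDataset) -> ConfidenceMatrix:
    """Absolute deviation from wild type (tag ``D``)."""
    scores = _zero_diagonal(_deviations(data))
    return ConfidenceMatrix(scores=scores, method_tag="D", gene_names=list(data.gene_names))


def normalized_deviation_matrix(
    data: ExpressionDataset, zero_wildtype: str = "error"
) -> ConfidenceMatrix:
    """Deviation from wild type divided by the target's wild-type level
    (tag ``ND``).

    Parameters
    ----------
    zero_wildtype
        ``"error"`` (default) raises if any wild-type level is zero;
        ``"floor"`` substitutes machine epsilon with a warning.
    """
    wt = data.wildtype.copy()
    zero = wt == 0
    if zero.any():
        if zero_wildtype == "floor":
            warnings.warn(
                f"{int(zero.sum())} wild-type level(s) are zero; "
                "flooring at machine epsilon for normalization",
                stacklevel=2,
            )
            wt[zero] = np.finfo(float).eps
        else:
            bad = data.gene_names[int(np.nonzero(zero)[0][0])]
            raise ValidationError(
                f"wild-type level of {bad} is zero; cannot normalize "
                '(pass zero_wildtype="floor" to substitute machine epsilon)'
            )
    scores = _zero_diagonal(_deviations(data) / wt[np.newaxis, :])
    return ConfidenceMatrix(scores=scores, method_tag="ND", gene_names=list(data.gene_names))


def _column_zscores(
    values: np.ndarray, include_self_knockout: bool, ddof: int
) -> np.ndarray:
    """Per-column |z| of ``values`` (rows = knockouts, columns = targets).

    Column statistics optionally exclude the diagonal observation (the
    target's own knockout).  Zero-variance columns carry no signal and are
    zeroed with a warning rather than raising.
    """
    n = values.shape[0]
    if n < 3:
        raise ValidationError(
            "z-score confidence needs at least 3 knockout experiments "
            f"(got {n}): the scale needs >= 2 observations after "
            "excluding the target's own knockout"
        )
    if include_self_knockout:
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=ddof)
    else:
        mask = ~np.eye(n, dtype=bool)
        cnt = n - 1
        mu = np.where(mask, values, 0.0).sum(axis=0) / cnt
        sq = np.where(mask, (values - mu[np.newaxis, :]) ** 2, 0.0).sum(axis=0)
        sd = np.sqrt(sq / (cnt - ddof))
    z = np.zeros_like(values)
    ok = sd > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} target column(s) have zero standard "
            "deviation; their confidences are set to 0",
            stacklevel=3,
        )
    z[:, ok] = np.abs(values[:, ok] - mu[np.newaxis, ok]) / sd[np.newaxis, ok]
    return _zero_diagonal(z)


def zscore_deviation_matrix(
    data: ExpressionDataset, include_self_knockout: bool = False, ddof: int = 1
) -> ConfidenceMatrix:
    """Column-wise z-score of the absolute deviations (tag ``ZD``)."""
    scores = _column_zscores(_deviations(data), include_self_knockout, ddof)
    return ConfidenceMatrix(scores=scores, method_tag="ZD", gene_names=list(data.gene_names))


def zscore_raw_matrix(
    data: ExpressionDataset, include_self_knockout: bool = False, ddof: int = 1
) -> ConfidenceMatrix:
    """Column-wise z-score of the raw post-knockout values (tag ``ZR``)."""
    scores = _column_zscores(data.knockout.copy(), include_self_knockout, ddof)
    return ConfidenceMatrix(scores=scores, method_tag="ZR", gene_names=list(data.gene_names))


CONFIDENCE_METHODS = {
    "D": deviation_matrix,
    "ND": normalized_deviation_matrix,
    "ZD": zscore_deviation_matrix,
    "ZR": zscore_raw_matrix,
}


def confidence_matrix(data: ExpressionDataset, method: str, **kwargs) -> ConfidenceMatrix:
    """Dispatch on a method tag in ``{"D", "ND", "ZD", "ZR"}``."""
    try:
        fn = CONFIDENCE_METHODS[method]
    except KeyError:
        raise ValidationError(
            f"unknown confidence method {method!r}; choose from "
            f"{sorted(CONFIDENCE_METHODS)}"
        ) from None
    return fn(data, **kwargs)
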
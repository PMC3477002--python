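"""Similarity (dissimilarity) measures between n-mer frequency vectors.

Four measures are supported, indexed by :class:`Measure`:

* ``ONE_NORM``   — :math:`s_1(x,y) = \\sum_i |x_i - y_i|`
* ``TWO_NORM``   — :math:`s_2(x,y) = (\\sum_i |x_i - y_i|^2)^{1/2}`
* ``INF_NORM``   — :math:`s_\\infty(x,y) = \\max_i |x_i - y_i|`
* ``KL``         — :math:`s_{kl}(x,y) = \\sum_i x_i \\ln(x_i / y_i)`

All are dissimilarities: smaller means more similar, and nearest-neighbor
search minimizes them.  The sums run over all :math:`4^n` implicit
coordinates but are evaluated over the union of the two sparse supports;
for smoothed vectors the block of coordinates where both operands hold
their shared zero-count value contributes in closed form, so no dense
materialization is needed even at n = 10.

The KL divergence is asymmetric: ``x`` is the query sequence and ``y``
the candidate neighbor.  It requires strictly positive operands, which
add-one smoothing guarantees (see :mod:`taxosep.kmer`).
"""

from __future__ import annotations

import enum
import math

import numpy as np

from .kmer import FrequencyVector

__all__ = ["Measure", "s1", "s2", "s_inf", "s_kl", "similarity"]


class Measure(str, enum.Enum):
    """The closed set of similarity measures {1, 2, ∞, kl}."""

    ONE_NORM = "1"
    TWO_NORM = "2"
    INF_NORM = "inf"
    KL = "kl"

    @classmethod
    def coerce(cls, value: "Measure | str | int") -> "Measure":
        if isinstance(value, cls):
            return value
        value = str(value).lower()
        aliases = {"infinity": "inf", "∞": "inf", "l1": "1", "l2": "2"}
        return cls(aliases.get(value, value))

    @property
    def needs_smoothing(self) -> bool:
        return self is Measure.KL


class SmoothingRequiredError(ValueError):
    """KL divergence applied to operands with a zero where the other is nonzero."""


def _check_compatible(x: FrequencyVector, y: FrequencyVector) -> None:
    if x.n != y.n:
        raise ValueError(f"dimension mismatch: n={x.n} vs n={y.n}")
    if x.smoothed != y.smoothed:
        raise ValueError("operands must share the same smoothing state")


def _union_values(x: FrequencyVector, y: FrequencyVector):
    """Aligned value arrays over the union of supports, plus the union size."""
    union = np.union1d(x.indices, y.indices)
    xv = np.full(union.shape, x.zero_value)
    xv[np.searchsorted(union, x.indices)] = x.values
    yv = np.full(union.shape, y.zero_value)
    yv[np.searchsorted(union, y.indices)] = y.values
    return xv, yv, union.size


def s1(x: FrequencyVector, y: FrequencyVector) -> float:
    """1-norm distance between the implicit dense vectors."""
    _check_compatible(x, y)
    xv, yv, u = _union_values(x, y)
    rest = (x.dim - u) * abs(x.zero_value - y.zero_value)
    return float(np.abs(xv - yv).sum() + rest)


def s2(x: FrequencyVector, y: FrequencyVector) -> float:
    """2-norm (Euclidean) distance."""
    _check_compatible(x, y)
    xv, yv, u = _union_values(x, y)
    rest = (x.dim - u) * (x.zero_value - y.zero_value) ** 2
    return float(math.sqrt(np.square(xv - yv).sum() + rest))


def s_inf(x: FrequencyVector, y: FrequencyVector) -> float:
    """∞-norm (Chebyshev) distance."""
    _check_compatible(x, y)
    xv, yv, u = _union_values(x, y)
    m = float(np.abs(xv - yv).max(initial=0.0))
    if u < x.dim:
        m = max(m, abs(x.zero_value - y.zero_value))
    return m


def s_kl(x: FrequencyVector, y: FrequencyVector) -> float:
    """Kullback-Leibler divergence of query ``x`` from neighbor candidate ``y``.

    Zero-count coordinates shared by both operands contribute
    ``(dim - |union|) * v_x * ln(v_x / v_y)`` in closed form, where
    ``v_x``, ``v_y`` are the operands' shared zero-count values.

    Raises
    ------
    SmoothingRequiredError
        If an unsmoothed operand has a zero where the other is nonzero
        (the divergence would involve ``ln 0`` or division by zero).
    """
    _check_compatible(x, y)
    xv, yv, u = _union_values(x, y)
    if np.any((xv > 0) & (yv == 0)) or np.any((xv == 0) & (yv > 0)):
        raise SmoothingRequiredError(
            "KL divergence needs strictly positive operands; apply add-one smoothing"
        )
    support = xv > 0
    acc = float(np.sum(xv[support] * np.log(xv[support] / yv[support])))
    if u < x.dim and x.zero_value > 0:
        acc += (x.dim - u) * x.zero_value * math.log(x.zero_value / y.zero_value)
    return acc


_DISPATCH = {
    Measure.ONE_NORM: s1,
    Measure.TWO_NORM: s2,
    Measure.INF_NORM: s_inf,
    Measure.KL: s_kl,
}


def similarity(measure: Measure | str, x: FrequencyVector, y: FrequencyVector) -> float:
    """Evaluate the chosen measure; ``x`` is the query for the asymmetric KL."""
    return _DISPATCH[Measure.coerce(measure)](x, y)
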
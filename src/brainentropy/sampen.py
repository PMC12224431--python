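"""Sample entropy (SampEn) of univariate time series and node-by-time matrices.

SampEn quantifies the irregularity of a signal as the negative log of the
conditional probability that two length-``m`` subsequences ("templates") that
match within a tolerance still match when extended by one point:

    SampEn(m, r) = -ln( A / B )

where ``B`` counts template pairs whose Chebyshev (maximum-coordinate)
distance is at most ``r * SD(series)`` at length ``m`` and ``A`` counts the
same pairs at length ``m + 1``.  Higher values mean a less predictable
signal; a perfectly repeating series has SampEn near zero.

Conventions (fixed here and used identically by the brute-force oracle):

* templates of both lengths are taken from start positions ``0 .. N-m-1``
  (0-based), so every length-``m`` template has a length-``m+1`` extension
  and ``A <= B`` is guaranteed;
* pairs are unordered (``i < j``) and self-pairs are excluded;
* the match criterion is a closed comparison, ``distance <= r * SD``
  (Richman-Moorman convention);
* SD is the sample standard deviation (``ddof=1``);
* the logarithm is natural, so values are in nats.

A zero match count at either length makes the ratio undefined; this is
reported as a flagged result, never as an exception or an infinity, so that
downstream group statistics can exclude such nodes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "SampEnParams",
    "EntropyResult",
    "SeriesTooShortError",
    "DegenerateSeriesError",
    "count_template_matches",
    "compute_sampen",
    "compute_sampen_matrix",
    "brute_force_sampen",
]


class SeriesTooShortError(ValueError):
    """Series has fewer than ``m + 2`` timepoints."""


class DegenerateSeriesError(ValueError):
    """Series has zero variance, so the tolerance ``r * SD`` would be 0."""


@dataclass(frozen=True)
class SampEnParams:
    """Template length ``m`` and tolerance multiplier ``r``.

    Defaults ``m=3, r=0.3`` are the values used for parcellated BOLD
    time series throughout this package.
    """

    m: int = 3
    r: float = 0.3

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"m must be a positive integer, got {self.m!r}")
        if not self.r > 0:
            raise ValueError(f"r must be positive, got {self.r!r}")


@dataclass(frozen=True)
class EntropyResult:
    """Outcome of one SampEn computation.

    ``value`` is NaN when the ratio is undefined (either count is zero) or
    the input column was degenerate; ``note`` carries the reason in the
    degenerate case.  ``defined`` distinguishes a real entropy value from a
    flagged one.
    """

    value: float
    b_count: int
    a_count: int
    n_timepoints: int
    note: str | None = None

    @property
    def defined(self) -> bool:
        return self.b_count > 0 and self.a_count > 0 and self.note is None


def _as_series(series: Sequence[float] | np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {x.shape}")
    if x.size < m + 2:
        raise SeriesTooShortError(
            f"series of length {x.size} is too short for m={m}; need at least {m + 2}"
        )
    return x


def _tolerance(x: np.ndarray, r: float) -> float:
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSeriesError("series has zero variance; tolerance r*SD would be 0")
    return r * sd


@njit(cache=True)
def _match_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    # Templates start at 0 .. nt-1 with nt = n - m.  Sorting by the first
    # coordinate lets the inner scan stop as soon as the first-coordinate
    # gap exceeds tol, which prunes the vast majority of pairs.
    n = x.shape[0]
    nt = n - m
    order = np.argsort(x[:nt])
    b = 0
    a = 0
    for oi in range(nt):
        i = order[oi]
        xi = x[i]
        for oj in range(oi + 1, nt):
            j = order[oj]
            if x[j] - xi > tol:
                break
            ok = True
            for k in range(1, m):
                if abs(x[i + k] - x[j + k]) > tol:
                    ok = False
                    break
            if ok:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    return b, a


def count_template_matches(
    series: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()
) -> tuple[int, int]:
    """Count matching template pairs at lengths ``m`` and ``m+1``.

    Returns ``(b_count, a_count)`` over unordered pairs of distinct
    templates; ``a_count <= b_count`` always, because an ``(m+1)``-match is
    an ``m``-match under the Chebyshev distance.

    Raises
    ------
    SeriesTooShortError
        if the series has fewer than ``m + 2`` points.
    DegenerateSeriesError
        if the series has zero variance.
    """
    x = _as_series(series, params.m)
    tol = _tolerance(x, params.r)
    b, a = _match_counts(x, params.m, tol)
    return int(b), int(a)


def compute_sampen(
    series: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()
) -> EntropyResult:
    """Sample entropy of a univariate series.

    Returns a flagged (NaN-valued) :class:`EntropyResult` when either match
    count is zero, rather than raising, so callers can keep partial results.
    """
    x = _as_series(series, params.m)
    tol = _tolerance(x, params.r)
    b, a = _match_counts(x, params.m, tol)
    if b == 0 or a == 0:
        return EntropyResult(float("nan"), int(b), int(a), x.size)
    return EntropyResult(-float(np.log(a / b)), int(b), int(a), x.size)


def compute_sampen_matrix(
    matrix: np.ndarray,
    params: SampEnParams = SampEnParams(),
    node_ids: Sequence[int] | None = None,
) -> list[EntropyResult]:
    """SampEn of every column of a timepoints-by-nodes matrix.

    Column order is preserved.  Degenerate (zero-variance) columns yield a
    flagged result carrying the reason instead of halting the whole matrix;
    a too-short matrix is an error because it affects every column.
    """
    values = np.asarray(matrix, dtype=np.float64)
    if values.ndim != 2:
        raise ValueError(f"expected a 2-D timepoints-by-nodes matrix, got shape {values.shape}")
    t, k = values.shape
    if node_ids is not None and len(node_ids) != k:
        raise ValueError(f"matrix has {k} columns but {len(node_ids)} node ids were declared")
    if t < params.m + 2:
        raise SeriesTooShortError(
            f"matrix has {t} timepoints; need at least {params.m + 2} for m={params.m}"
        )
    # column loop calls the counting kernel directly; per-column validation
    # reduces to the vectorized SD check below.  Transposing makes each
    # column a contiguous row, which the kernel scans far faster.
    values = np.ascontiguousarray(values.T).T
    sds = np.std(values, axis=0, ddof=1)
    results: list[EntropyResult] = []
    for col in range(k):
        sd = sds[col]
        if sd == 0.0 or not np.isfinite(sd):
            results.append(EntropyResult(
                float("nan"), 0, 0, t,
                note="series has zero variance; tolerance r*SD would be 0"))
            continue
        b, a = _match_counts(values[:, col], params.m, params.r * float(sd))
        if b == 0 or a == 0:
            results.append(EntropyResult(float("nan"), int(b), int(a), t))
        else:
            results.append(EntropyResult(-float(np.log(a / b)), int(b), int(a), t))
    return results


def brute_force_sampen(
    series: Sequence[float] | np.ndarray, params: SampEnParams = SampEnParams()
) -> EntropyResult:
    """Literal double-loop SampEn, used as an independent test oracle.

    No vectorization, sorting or early exit beyond the definition itself:
    every unordered pair of templates is compared coordinate by coordinate.
    Same conventions (template pool, closed comparison, ddof=1 SD, natural
    log) as :func:`compute_sampen`.
    """
    x = _as_series(series, params.m)
    tol = _tolerance(x, params.r)
    m = params.m
    vals = [float(v) for v in x]
    nt = len(vals) - m
    b = 0
    a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs(vals[i + k] - vals[j + k])
                if diff > d:
                    d = diff
            if d <= tol:
                b += 1
                d1 = max(d, abs(vals[i + m] - vals[j + m]))
                if d1 <= tol:
                    a += 1
    if b == 0 or a == 0:
        return EntropyResult(float("nan"), b, a, len(vals))
    import math

    return EntropyResult(-math.log(a / b), b, a, len(vals))
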
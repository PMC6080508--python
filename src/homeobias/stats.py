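"""Shared statistical primitives.

Everything downstream of the expression tables reduces to four operations:
a two-sample Student's t-test with a ternary outcome (lower / equal /
greater at a significance level alpha), Benjamini-Hochberg FDR control,
log2 fold changes on pseudocounted means, and the hypergeometric upper
tail used for term enrichment.

The t-test is the pooled-variance (Student's) form by default; Welch's
form is available behind ``equal_var=False``.  Two conventions matter for
exactness on noise-free data:

* zero pooled variance with (near-)equal means gives p = 1 and EQ;
* zero pooled variance with unequal means gives p = 0 and the direction
  of the mean difference.

"Near-equal" is a relative comparison at 1e-9, so that values assembled
by float arithmetic (e.g. a pair total ``3*m + m`` against a parent mean
``4*m``) compare as intended.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _spstats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError

#: default significance level for ternary test outcomes
DEFAULT_ALPHA = 0.05

#: relative tolerance used for "exactly equal" in degenerate-variance tests
REL_TOL = 1e-9


class Direction(enum.Enum):
    """Ternary comparison outcome of sample x against sample y."""

    LT = "LT"
    EQ = "EQ"
    GT = "GT"


_CODE_TO_DIRECTION = {-1: Direction.LT, 0: Direction.EQ, 1: Direction.GT}
_DIRECTION_TO_CODE = {v: k for k, v in _CODE_TO_DIRECTION.items()}


def direction_from_code(code: int) -> Direction:
    return _CODE_TO_DIRECTION[int(code)]


def direction_code(direction: Direction) -> int:
    return _DIRECTION_TO_CODE[direction]


@dataclass(frozen=True)
class TestOutcome:
    """Result of a ternary two-sample comparison.

    ``direction`` is EQ exactly when ``p > alpha`` at the alpha the caller
    used; otherwise it carries the sign of ``mean_x - mean_y``.
    """

    p: float
    direction: Direction
    mean_x: float
    mean_y: float


def _as_replicates(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InvalidInputError(
            f"{name} must be a 1-d vector with at least 2 replicates, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def _nearly_equal(a: float, b: float) -> bool:
    return bool(np.isclose(a, b, rtol=REL_TOL, atol=0.0))


def t_test(x, y, alpha: float = DEFAULT_ALPHA, equal_var: bool = True) -> TestOutcome:
    """Two-sided two-sample t-test with a ternary outcome.

    Parameters
    ----------
    x, y
        Replicate vectors (length >= 2 each).
    alpha
        Significance level; ``p <= alpha`` yields a directional outcome.
    equal_var
        Pooled-variance (Student's) test when True, Welch's when False.
    """
    x = _as_replicates(x, "x")
    y = _as_replicates(y, "y")
    mean_x = float(np.mean(x))
    mean_y = float(np.mean(y))
    degenerate = np.ptp(x) == 0.0 and np.ptp(y) == 0.0
    if degenerate:
        if _nearly_equal(x[0], y[0]):
            return TestOutcome(1.0, Direction.EQ, mean_x, mean_y)
        direction = Direction.GT if x[0] > y[0] else Direction.LT
        return TestOutcome(0.0, direction, mean_x, mean_y)
    with warnings.catch_warnings():
        # near-identical (but not constant) samples trip a scipy
        # precision warning; the p-value is still well-defined
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(_spstats.ttest_ind(x, y, equal_var=equal_var).pvalue)
    if np.isnan(p):  # pragma: no cover - guarded by the degenerate branch
        p = 1.0 if _nearly_equal(mean_x, mean_y) else 0.0
    if p > alpha:
        direction = Direction.EQ
    else:
        direction = Direction.GT if mean_x > mean_y else Direction.LT
    return TestOutcome(p, direction, mean_x, mean_y)


def t_test_many(
    X, Y, alpha: float = DEFAULT_ALPHA, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise ternary t-tests for matrices of replicate vectors.

    ``X`` and ``Y`` are (n_items, n_replicates) arrays; replicate counts may
    differ between the two matrices but not within one.  Returns
    ``(p, direction_code, mean_x, mean_y)`` where direction codes are
    -1 (LT), 0 (EQ), +1 (GT).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("X and Y must have the same number of rows")
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise InvalidInputError("need at least 2 replicates per sample")
    mean_x = X.mean(axis=1)
    mean_y = Y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows trip a scipy precision warning; they are resolved
        # below by the degenerate-variance convention
        warnings.simplefilter("ignore", RuntimeWarning)
        p = _spstats.ttest_ind(X, Y, axis=1, equal_var=equal_var).pvalue
    p = np.asarray(p, dtype=float)
    # degenerate rows: both samples constant -> exact-equality convention
    degenerate = (np.ptp(X, axis=1) == 0.0) & (np.ptp(Y, axis=1) == 0.0)
    if degenerate.any():
        eq = np.isclose(X[degenerate, 0], Y[degenerate, 0], rtol=REL_TOL, atol=0.0)
        p[degenerate] = np.where(eq, 1.0, 0.0)
    p = np.nan_to_num(p, nan=1.0)
    close = np.isclose(mean_x, mean_y, rtol=REL_TOL, atol=0.0)
    sign = np.sign(mean_x - mean_y).astype(np.int8)
    sign[close] = 0
    direction = np.where(p <= alpha, sign, 0).astype(np.int8)
    return p, direction, mean_x, mean_y


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; values are clamped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError("pvalues must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_x, mean_y, pseudocount: float = 1.0):
    """log2((mean_x + c) / (mean_y + c)) with pseudocount c > 0."""
    if pseudocount <= 0:
        raise InvalidInputError("pseudocount must be > 0")
    mean_x = np.asarray(mean_x, dtype=float)
    mean_y = np.asarray(mean_y, dtype=float)
    if np.any(mean_x < 0) or np.any(mean_y < 0):
        raise InvalidInputError("means must be non-negative")
    out = np.log2((mean_x + pseudocount) / (mean_y + pseudocount))
    return float(out) if out.ndim == 0 else out


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a study set of size ``n`` drawn from a background of
    size ``N`` containing ``K`` successes (the one-sided Fisher convention
    used for term enrichment).
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise InvalidInputError(f"{name} must be a non-negative integer")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N or K > N or k > min(n, K):
        raise InvalidInputError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    return float(min(1.0, _spstats.hypergeom.sf(k - 1, N, K, n)))
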
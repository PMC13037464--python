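"""Pearson correlation with a two-sided permutation test.

The field procedure for abundance-covariate associations: compute the
product-moment coefficient and assess it against the permutation null
(y shuffled against fixed x) with 20 000 iterations, two-sided, at
alpha = 0.05.  When n! does not exceed the requested iterations the test
switches to exhaustive enumeration and the p-value is exact.

Monte-Carlo p-values use the add-one (include-observed) convention by
default, so p > 0 always; the plain proportion is reported alongside.
A tie guard of 1e-12 on |r| absorbs bit-level float differences between
permutations of identical multisets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional

import numpy as np

from .errors import UndefinedResultError, ValidationError

logger = logging.getLogger("redoxniche")

#: floating-point tie guard on |r| comparisons
TIE_EPS = 1e-12


@dataclass
class PermTestResult:
    r: float
    p_value: float  # add-one convention (exact k/n! on the exhaustive path)
    p_plain: float  # plain proportion (identical to p_value when exhaustive)
    n_obs: int
    n_perm: int
    exhaustive: bool
    seed: Optional[int] = None


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedResultError(
            "correlation undefined for a zero-variance vector"
        )
    return x, y


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _check_xy(x, y)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def perm_cor_test(
    x,
    y,
    n_perm: int = 20000,
    seed: Optional[int] = None,
) -> PermTestResult:
    """Two-sided permutation test of the Pearson correlation.

    Permutes ``y`` against fixed ``x`` and counts permutations with
    ``|r_perm| >= |r_obs| - 1e-12``.  Switches to exhaustive enumeration
    of all n! pairings when ``n! <= n_perm`` (p exact, seed unused).
    Pairs with a missing value in either vector are dropped listwise.
    """
    if n_perm < 1:
        raise ValidationError("n_perm >= 1 required")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.all():
        logger.info("dropped %d incomplete pair(s)", int((~keep).sum()))
        x, y = x[keep], y[keep]
    x, y = _check_xy(x, y)
    n = len(x)
    r_obs = pearson_r(x, y)

    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))

    if math.factorial(n) <= n_perm:
        perms = np.array(list(permutations(yc)))
        r_all = perms @ xc / denom
        k = int(np.count_nonzero(np.abs(r_all) >= abs(r_obs) - TIE_EPS))
        p = k / math.factorial(n)
        return PermTestResult(
            r=r_obs, p_value=p, p_plain=p, n_obs=n,
            n_perm=math.factorial(n), exhaustive=True, seed=None,
        )

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(yc, (n_perm, 1)), axis=1)
    r_all = perms @ xc / denom
    k = int(np.count_nonzero(np.abs(r_all) >= abs(r_obs) - TIE_EPS))
    return PermTestResult(
        r=r_obs,
        p_value=(k + 1) / (n_perm + 1),
        p_plain=k / n_perm,
        n_obs=n,
        n_perm=n_perm,
        exhaustive=False,
        seed=seed,
    )
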
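"""Independent oracles used by the tests, kept free of the package's own
transform and inference code paths.

* Haar DWT as an explicit orthogonal matrix product.
* Fisher's exact two-sided p by exhaustive hypergeometric enumeration in
  exact rational arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np


def haar_matrix(n: int) -> np.ndarray:
    """Single-level orthonormal Haar analysis matrix for even length n.

    Rows 0..n/2-1 average adjacent pairs, rows n/2..n-1 difference them
    with the (x0 - x1)/sqrt(2) sign convention.
    """
    assert n % 2 == 0
    h = np.zeros((n, n))
    s = 1.0 / np.sqrt(2.0)
    for i in range(n // 2):
        h[i, 2 * i] = h[i, 2 * i + 1] = s
        h[n // 2 + i, 2 * i] = s
        h[n // 2 + i, 2 * i + 1] = -s
    return h


def haar_dwt1_oracle(x):
    """(approx, detail) of a single-level Haar transform via the matrix."""
    x = np.asarray(x, dtype=float)
    n = x.size
    y = haar_matrix(n) @ x
    return y[: n // 2], y[n // 2 :]


def haar_dwt2_oracle(img):
    """Single-level 2-D Haar subbands via two matrix products.

    Returns (approx, horizontal, vertical, diagonal) where 'horizontal'
    is high-pass along rows (axis 0) / low-pass along columns.
    """
    img = np.asarray(img, dtype=float)
    r, c = img.shape
    t = haar_matrix(r) @ img @ haar_matrix(c).T
    hr, hc = r // 2, c // 2
    return t[:hr, :hc], t[hr:, :hc], t[:hr, hc:], t[hr:, hc:]


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of hypergeometric point probabilities that do
    not exceed the observed table's, computed in exact rationals."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def point(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = point(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((point(k) for k in range(lo, hi + 1) if point(k) <= p_obs), Fraction(0))
    return float(total)
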
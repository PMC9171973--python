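"""Pairwise similarity metrics and similarity-matrix construction.

Binary fingerprints are compared with the Tanimoto coefficient
(structural similarity) or the Rogot-Goldberg index (pharmacological
similarity). For a pair of equal-length bit vectors the four basic counts
are

    a = common on-bits, b = on only in x, c = on only in y,
    d = common off-bits,

and

    Tanimoto       T = a / (a + b + c)
    Rogot-Goldberg S = a / (2a + b + c) + d / (2d + b + c)

Unlike Tanimoto, the Rogot-Goldberg index also rewards agreement on
*inactive* positions: two fingerprints that are both all-zero score 0.5
(each compound predicted inactive everywhere — informative agreement),
whereas their Tanimoto similarity is 0. Any additive term with a zero
denominator contributes 0, which is what makes the all-zero pair score 0.5.

Real-valued descriptor vectors are compared by Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chem import BitVector, DescriptorVector

__all__ = [
    "PairCounts",
    "SimilarityMatrix",
    "pair_counts",
    "rogot_goldberg",
    "tanimoto",
    "spearman_similarity",
    "similarity_matrix",
]


@dataclass(frozen=True)
class PairCounts:
    a: int  # common on-bits
    b: int  # on in first only
    c: int  # on in second only
    d: int  # common off-bits

    @property
    def length(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric n x n similarity matrix with its molecule-id order."""

    values: np.ndarray
    ids: tuple[str, ...]
    metric: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.ids) != arr.shape[0]:
            raise ValueError("id count must match matrix size")
        if not np.allclose(arr, arr.T):
            raise ValueError("similarity matrix must be symmetric")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "ids", tuple(self.ids))

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def _as_bits(x) -> np.ndarray:
    if isinstance(x, BitVector):
        return x.bits
    arr = np.asarray(x, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D bit sequence")
    return arr


def pair_counts(x, y) -> PairCounts:
    """Exact (a, b, c, d) contingency counts for two equal-length bit vectors."""
    bx, by = _as_bits(x), _as_bits(y)
    if bx.size != by.size:
        raise ValueError(f"length mismatch: {bx.size} vs {by.size}")
    a = int(np.sum(bx & by))
    b = int(np.sum(bx & ~by & 1))
    c = int(np.sum(~bx & by & 1))
    d = bx.size - a - b - c
    return PairCounts(a=a, b=b, c=c, d=d)


def rogot_goldberg(x, y) -> float:
    """Rogot-Goldberg index in [0, 1]; zero-denominator terms contribute 0."""
    pc = pair_counts(x, y)
    if pc.length == 0:
        raise ValueError("fingerprints must be non-empty")
    s = 0.0
    if 2 * pc.a + pc.b + pc.c > 0:
        s += pc.a / (2 * pc.a + pc.b + pc.c)
    if 2 * pc.d + pc.b + pc.c > 0:
        s += pc.d / (2 * pc.d + pc.b + pc.c)
    return s


def tanimoto(x, y) -> float:
    """Tanimoto coefficient a/(a+b+c); defined as 0 for two all-zero vectors."""
    pc = pair_counts(x, y)
    denom = pc.a + pc.b + pc.c
    return pc.a / denom if denom > 0 else 0.0


def spearman_similarity(u, v) -> float:
    """Spearman rank correlation of two descriptor vectors (average-rank ties)."""
    uu = u.values if isinstance(u, DescriptorVector) else np.asarray(u, dtype=float)
    vv = v.values if isinstance(v, DescriptorVector) else np.asarray(v, dtype=float)
    if uu.size != vv.size:
        raise ValueError(f"length mismatch: {uu.size} vs {vv.size}")
    if uu.size < 2:
        raise ValueError("need at least two entries")
    if np.ptp(uu) == 0 or np.ptp(vv) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(uu, vv).statistic
    return float(rho)


def tanimoto_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tanimoto similarities between every row of X and every row of Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("bit-length mismatch")
    A = X @ Y.T
    denom = X.sum(axis=1)[:, None] + Y.sum(axis=1)[None, :] - A
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, A / np.where(denom > 0, denom, 1), 0.0)


_BIT_METRICS = ("tanimoto", "rogot_goldberg")


def _bit_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized all-pairs similarity for a stack of bit rows."""
    X = X.astype(np.float64)
    n, L = X.shape
    A = X @ X.T                      # common on-bits
    on = X.sum(axis=1)
    B = on[:, None] - A              # on in i only
    C = on[None, :] - A              # on in j only
    D = L - A - B - C
    if metric == "tanimoto":
        denom = A + B + C
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(denom > 0, A / denom, 0.0)
    else:
        S = np.zeros((n, n))
        d1 = 2 * A + B + C
        d2 = 2 * D + B + C
        with np.errstate(invalid="ignore", divide="ignore"):
            S += np.where(d1 > 0, A / np.where(d1 > 0, d1, 1), 0.0)
            S += np.where(d2 > 0, D / np.where(d2 > 0, d2, 1), 0.0)
    return S


def similarity_matrix(items, metric: str, ids=None) -> SimilarityMatrix:
    """All-pairs similarity matrix over homogeneous encodings.

    ``items`` is a sequence of :class:`BitVector` (for ``tanimoto`` /
    ``rogot_goldberg``) or :class:`DescriptorVector` (for ``spearman``).
    """
    items = list(items)
    if not items:
        raise ValueError("no items")
    if ids is None:
        ids = tuple(str(i) for i in range(len(items)))
    if metric in _BIT_METRICS:
        if not all(isinstance(it, BitVector) for it in items):
            raise ValueError(f"metric {metric!r} requires bit vectors")
        encs = {it.encoding for it in items}
        lens = {it.length for it in items}
        if len(encs) > 1 or len(lens) > 1:
            raise ValueError(f"mixed encodings/lengths: {encs} {lens}")
        X = np.stack([it.bits for it in items])
        S = _bit_matrix(X, metric)
    elif metric == "spearman":
        if not all(isinstance(it, DescriptorVector) for it in items):
            raise ValueError("metric 'spearman' requires descriptor vectors")
        lens = {it.length for it in items}
        if len(lens) > 1:
            raise ValueError(f"mixed descriptor lengths: {lens}")
        n = len(items)
        S = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = spearman_similarity(items[i], items[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    S = (S + S.T) / 2.0  # kill float asymmetry
    return SimilarityMatrix(values=S, ids=tuple(ids), metric=metric)
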
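"""Similarity-search evaluation: query/test splits, AUC, EF10, thresholds.

Protocol, per pharmacological class:

* The **query set** is 10 randomly chosen class actives plus 10 decoys per
  query active (110 compounds).
* The **test set** is every remaining class active plus 10 fresh decoys per
  test active, so the test-set active fraction is exactly 1/11 ~ 0.091.
* Each test compound is scored by its *nearest neighbor* similarity — the
  maximum similarity to any query compound — and the test set is sorted by
  decreasing score.

The sorted list is summarized by the ROC AUC (Mann-Whitney form, ties
counted 1/2) and the enrichment factor at the top 10%:

    EF(chi) = (P_chi / N_chi) / (P_total / N_total).

Two threshold diagnostics accompany the search: the G-mean-optimal
operating threshold on the ROC curve, and the structural-diversity
threshold S_c = Z*sigma + y computed from the pooled k-nearest-neighbor
similarities within the class (small S_c = structurally diverse class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import rogot_goldberg, tanimoto

__all__ = [
    "SearchSplit",
    "RankedList",
    "EnrichmentResult",
    "DiversityThreshold",
    "make_search_split",
    "rank_test_set",
    "auc",
    "enrichment_factor",
    "optimal_threshold",
    "diversity_threshold",
    "run_benchmark",
]

_METRICS = {"tanimoto": tanimoto, "rogot_goldberg": rogot_goldberg}


@dataclass(frozen=True)
class SearchSplit:
    """Disjoint query and test sets with the fixed 1:10 active:decoy ratio."""

    query_actives: tuple[str, ...]
    query_decoys: tuple[str, ...]
    test_actives: tuple[str, ...]
    test_decoys: tuple[str, ...]
    seed: int

    @property
    def query(self) -> tuple[str, ...]:
        return self.query_actives + self.query_decoys

    @property
    def active_fraction(self) -> float:
        n_act = len(self.test_actives)
        return n_act / (n_act + len(self.test_decoys))


@dataclass(frozen=True)
class RankedList:
    """Test compounds sorted by decreasing nearest-neighbor similarity."""

    scores: np.ndarray
    is_active: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        a = np.asarray(self.is_active, dtype=bool)
        if s.size != a.size or s.size == 0:
            raise ValueError("scores and flags must be equal-length, non-empty")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("scores must be non-increasing")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "is_active", a)

    @property
    def p_total(self) -> int:
        return int(self.is_active.sum())

    @property
    def n_total(self) -> int:
        return int(self.is_active.size)


@dataclass(frozen=True)
class EnrichmentResult:
    chi: float
    p_chi: int
    n_chi: int
    p_total: int
    n_total: int

    @property
    def ef(self) -> float:
        base = self.p_total / self.n_total
        return (self.p_chi / self.n_chi) / base


@dataclass(frozen=True)
class DiversityThreshold:
    s_c: float
    y: float       # mean of pooled k-NN similarities
    sigma: float   # sd of pooled k-NN similarities
    k: int
    z: float


def make_search_split(
    class_actives: Sequence[str],
    decoy_pool: Sequence[str],
    seed: int = 0,
    n_query_actives: int = 10,
    decoys_per_active: int = 10,
) -> SearchSplit:
    """Draw one seeded query/test split for a pharmacological class."""
    ids = list(class_actives)
    if len(ids) <= n_query_actives:
        raise ValueError(
            f"class has {len(ids)} actives; need more than {n_query_actives} "
            "to leave a non-empty test set"
        )
    rng = np.random.default_rng(seed)
    n_decoys = decoys_per_active * len(ids)
    pool = list(decoy_pool)
    if len(pool) < n_decoys:
        raise ValueError(
            f"decoy pool of {len(pool)} too small: need {n_decoys}"
        )
    act_perm = rng.permutation(len(ids))
    q_act = [ids[i] for i in act_perm[:n_query_actives]]
    t_act = [ids[i] for i in act_perm[n_query_actives:]]
    dec_idx = rng.choice(len(pool), size=n_decoys, replace=False)
    decs = [pool[i] for i in dec_idx]
    n_qd = decoys_per_active * n_query_actives
    return SearchSplit(
        query_actives=tuple(q_act),
        query_decoys=tuple(decs[:n_qd]),
        test_actives=tuple(t_act),
        test_decoys=tuple(decs[n_qd:]),
        seed=seed,
    )


def rank_test_set(
    split: SearchSplit,
    metric: str,
    fingerprints: Mapping[str, object],
    seed: int = 0,
    include_query_decoys: bool = True,
) -> RankedList:
    """Score test compounds by max similarity to the query set and sort.

    Ties are broken by a seeded shuffle before a stable descending sort,
    so tied blocks appear in a reproducible random order.
    """
    sim = _METRICS[metric]
    query_ids = split.query if include_query_decoys else split.query_actives
    try:
        qfps = [fingerprints[q] for q in query_ids]
        test_ids = list(split.test_actives) + list(split.test_decoys)
        tfps = [fingerprints[t] for t in test_ids]
    except KeyError as exc:
        raise KeyError(f"missing fingerprint for compound {exc.args[0]!r}") from None
    flags = np.array(
        [True] * len(split.test_actives) + [False] * len(split.test_decoys)
    )
    scores = np.array([max(sim(t, q) for q in qfps) for t in tfps])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(scores.size)
    order = perm[np.argsort(-scores[perm], kind="stable")]
    return RankedList(scores=scores[order], is_active=flags[order])


def auc(ranked: RankedList) -> float:
    """ROC AUC as the Mann-Whitney statistic, tied scores counted 1/2."""
    pos = ranked.scores[ranked.is_active]
    neg = ranked.scores[~ranked.is_active]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs both actives and inactives")
    ranks = stats.rankdata(ranked.scores)  # average ranks handle ties
    r_pos = ranks[ranked.is_active].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def enrichment_factor(ranked: RankedList, chi: float = 0.10) -> EnrichmentResult:
    """EF(chi): active rate in the top chi fraction over the base rate.

    The top-fraction size is the nearest integer to chi * N (half rounds
    up), with a minimum of 1.
    """
    if not 0 < chi < 1:
        raise ValueError("chi must lie in (0, 1)")
    n_chi = max(1, int(np.floor(chi * ranked.n_total + 0.5)))
    p_chi = int(ranked.is_active[:n_chi].sum())
    return EnrichmentResult(
        chi=chi,
        p_chi=p_chi,
        n_chi=n_chi,
        p_total=ranked.p_total,
        n_total=ranked.n_total,
    )


def optimal_threshold(ranked: RankedList) -> float:
    """Similarity threshold maximizing G-mean = sqrt(sensitivity*specificity).

    A compound scoring >= threshold is called active. Candidate thresholds
    are the distinct observed scores; ties in G-mean resolve to the lowest
    threshold.
    """
    p, n = ranked.p_total, ranked.n_total - ranked.p_total
    if p == 0 or n == 0:
        raise ValueError("need both classes to choose a threshold")
    best_t, best_g = None, -1.0
    for t in np.unique(ranked.scores):  # ascending: low thresholds first
        called = ranked.scores >= t
        sens = np.sum(called & ranked.is_active) / p
        spec = np.sum(~called & ~ranked.is_active) / n
        g = float(np.sqrt(sens * spec))
        if g > best_g + 1e-12:
            best_t, best_g = float(t), g
    return best_t


def diversity_threshold(
    fingerprints: Sequence[object],
    metric: str = "tanimoto",
    k: int = 5,
    z: float = 0.5,
) -> DiversityThreshold:
    """Structural-diversity threshold S_c = Z*sigma + y for one class.

    For each compound, take its k highest similarities to the other class
    members; pool all k*n values; y and sigma are the pooled mean and
    sample standard deviation.
    """
    n = len(fingerprints)
    if n <= k:
        raise ValueError(f"class size {n} must exceed k={k}")
    sim = _METRICS[metric]
    pooled: list[float] = []
    for i in range(n):
        sims = sorted(
            (sim(fingerprints[i], fingerprints[j]) for j in range(n) if j != i),
            reverse=True,
        )
        pooled.extend(sims[:k])
    arr = np.asarray(pooled)
    y = float(arr.mean())
    sigma = float(arr.std(ddof=1))
    return DiversityThreshold(s_c=z * sigma + y, y=y, sigma=sigma, k=k, z=z)


def run_benchmark(
    class_members: Mapping[str, Sequence[str]],
    decoy_pool: Sequence[str],
    metric: str,
    fingerprints: Mapping[str, object],
    n_repeats: int = 50,
    seed: int = 0,
    chi: float = 0.10,
) -> pd.DataFrame:
    """Repeated similarity searches per class; mean +/- sd of AUC and EF.

    Returns one row per class with columns ``mean_auc, sd_auc, mean_ef10,
    sd_ef10, opt_threshold_mean, s_c``. With ``n_repeats=1`` the sd columns
    are reported as 0.
    """
    rows = []
    for ci, (cls, members) in enumerate(sorted(class_members.items())):
        aucs, efs, thrs = [], [], []
        for r in range(n_repeats):
            rep_seed = (seed * 104729 + ci * 1009 + r) % (2**31 - 1)
            split = make_search_split(members, decoy_pool, seed=rep_seed)
            ranked = rank_test_set(split, metric, fingerprints, seed=rep_seed)
            aucs.append(auc(ranked))
            efs.append(enrichment_factor(ranked, chi=chi).ef)
            thrs.append(optimal_threshold(ranked))
        div = diversity_threshold([fingerprints[m] for m in members], metric=metric)
        sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        rows.append(
            {
                "class": cls,
                "metric": metric,
                "n_repeats": n_repeats,
                "mean_auc": float(np.mean(aucs)),
                "sd_auc": sd(aucs),
                "mean_ef10": float(np.mean(efs)),
                "sd_ef10": sd(efs),
                "opt_threshold_mean": float(np.mean(thrs)),
                "s_c": div.s_c,
            }
        )
    return pd.DataFrame(rows)
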
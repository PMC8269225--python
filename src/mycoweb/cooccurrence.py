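"""Exact probabilistic co-occurrence model for presence/absence data.

For two species observed in ``n1`` and ``n2`` of ``N`` sites, the number of
shared sites ``J`` under independent random placement follows the exact
combinatorial distribution of Veech's probabilistic model,

    P(J = j) = C(n1, j) C(N - n1, n2 - j) / C(N, n2),

a hypergeometric law.  A pair co-occurs significantly when the upper tail
``P(J >= j_obs)`` falls below alpha (positive association) and co-excludes
when the lower tail ``P(J <= j_obs)`` does (negative association).  Both
tails include the observed count.  The model is analytically exact, makes
no distributional assumption about abundances, and is among the most
conservative association screens in use for microbial survey data.

All arithmetic is done with log-gamma binomial coefficients so that site
numbers in the thousands do not overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .community_io import PresenceMatrix

logger = logging.getLogger(__name__)

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"
SIGN_NONE = "none"

ASSOCIATION_COLUMNS = [
    "otu_a", "otu_b", "N", "n1", "n2", "j_obs", "expected_j", "p_lt", "p_gt", "sign",
]


@dataclass(frozen=True)
class PairOccurrence:
    """Occurrence summary for one unordered species pair."""

    otu_a: str
    otu_b: str
    N: int
    n1: int
    n2: int
    j_obs: int

    def __post_init__(self) -> None:
        if not (0 <= self.n1 <= self.N and 0 <= self.n2 <= self.N):
            raise ValueError(f"occurrence counts must lie in [0, N={self.N}]")
        lo, hi = self.support()
        if not lo <= self.j_obs <= hi:
            raise ValueError(
                f"j_obs={self.j_obs} outside support [{lo}, {hi}] "
                f"for N={self.N}, n1={self.n1}, n2={self.n2}"
            )

    def support(self) -> tuple[int, int]:
        return max(0, self.n1 + self.n2 - self.N), min(self.n1, self.n2)


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def cooccurrence_pmf(N: int, n1: int, n2: int, j: int) -> float:
    """P(J = j) for independent placement of two species across N sites.

    Returns 0 for ``j`` outside the support (not an error); raises for
    invalid ``N``, ``n1``, ``n2``.
    """
    if N < 0 or not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"invalid occurrence counts n1={n1}, n2={n2} for N={N}")
    if j < max(0, n1 + n2 - N) or j > min(n1, n2):
        return 0.0
    logp = _log_binom(n1, j) + _log_binom(N - n1, n2 - j) - _log_binom(N, n2)
    return float(np.exp(logp))


def pair_pvalues(pair: PairOccurrence) -> tuple[float, float]:
    """Inclusive lower/upper tail probabilities at the observed count.

    ``p_lt = P(J <= j_obs)`` and ``p_gt = P(J >= j_obs)``; the two sum to
    ``1 + P(J = j_obs)`` since the observed count belongs to both tails.
    """
    lo, hi = pair.support()
    pmf = np.array([cooccurrence_pmf(pair.N, pair.n1, pair.n2, k) for k in range(lo, hi + 1)])
    i = pair.j_obs - lo
    p_lt = float(pmf[: i + 1].sum())
    p_gt = float(pmf[i:].sum())
    return min(p_lt, 1.0), min(p_gt, 1.0)


def classify_pair(p_lt: float, p_gt: float, alpha: float = 0.05) -> str:
    """Classify a pair: positive if ``p_gt < alpha``, negative if ``p_lt < alpha``.

    Comparisons are strict; both tails can never be significant at any
    alpha < 0.5 because the inclusive tails sum to at least 1.
    """
    if not 0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    if p_gt < alpha:
        return SIGN_POSITIVE
    if p_lt < alpha:
        return SIGN_NEGATIVE
    return SIGN_NONE


def _vectorised_tails(N: int, n1: np.ndarray, n2: np.ndarray, j: np.ndarray):
    """Inclusive tail probabilities for many pairs at once.

    Walks the support of every pair simultaneously with the hypergeometric
    ratio recurrence pmf(k+1)/pmf(k) = (n1-k)(n2-k)/((k+1)(N-n1-n2+k+1)),
    accumulating both tails in log space.
    """
    n1 = np.asarray(n1, dtype=np.int64)
    n2 = np.asarray(n2, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    lo = np.maximum(0, n1 + n2 - N)
    hi = np.minimum(n1, n2)
    # log pmf at the lower end of each support
    logpmf = _log_binom(n1, lo) + _log_binom(N - n1, n2 - lo) - _log_binom(N, n2)
    neg_inf = np.float64(-np.inf)
    log_lt = np.where(lo <= j, logpmf, neg_inf)
    log_gt = np.where(lo >= j, logpmf, neg_inf)
    width = int((hi - lo).max()) if len(n1) else 0
    k = lo.astype(np.float64)
    for _ in range(width):
        active = k < hi
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = (
                np.log(n1 - k) + np.log(n2 - k) - np.log(k + 1) - np.log(N - n1 - n2 + k + 1)
            )
        step = np.where(active, logpmf + logratio, neg_inf)
        logpmf = np.where(active, step, logpmf)
        k = np.where(active, k + 1, k)
        log_lt = np.where(active & (k <= j), np.logaddexp(log_lt, logpmf), log_lt)
        log_gt = np.where(active & (k >= j), np.logaddexp(log_gt, logpmf), log_gt)
    return np.minimum(np.exp(log_lt), 1.0), np.minimum(np.exp(log_gt), 1.0)


def all_pair_associations(
    m: PresenceMatrix,
    alpha: float = 0.05,
    min_expected: float | None = None,
) -> pd.DataFrame:
    """Exact association test for every unordered OTU pair of a presence matrix.

    Occurrence counts come from column sums and co-occurrence counts from
    the column Gram matrix, so the combinatorics is the only per-pair work.
    Pairs whose species show no variation (present in 0 or all N samples)
    carry no evidence and are classified ``none``.

    Parameters
    ----------
    m
        Presence/absence matrix (samples x OTUs).
    alpha
        Significance level for the strict tail comparison (default 0.05).
    min_expected
        If given, pairs with expected co-occurrence ``n1*n2/N`` below this
        value are classified ``none`` (off by default).

    Returns
    -------
    DataFrame with one row per unordered pair:
    ``otu_a, otu_b, N, n1, n2, j_obs, expected_j, p_lt, p_gt, sign``.
    """
    if m.n_otus < 2 or m.n_samples < 2:
        raise ValueError("need at least 2 OTUs and 2 samples")
    x = m.values.astype(np.int64)
    N = m.n_samples
    occ = x.sum(axis=0)
    if (occ == 0).any():
        absent = [m.otu_ids[i] for i in np.flatnonzero(occ == 0)[:5]]
        raise ValueError(f"OTUs present in no sample (filter first): {absent}")
    gram = x.T @ x
    ia, ib = np.triu_indices(m.n_otus, k=1)
    n1, n2, j = occ[ia], occ[ib], gram[ia, ib]
    logger.info("testing %d OTU pairs over %d samples", len(ia), N)
    p_lt, p_gt = _vectorised_tails(N, n1, n2, j)
    expected = n1 * n2 / N
    sign = np.full(len(ia), SIGN_NONE, dtype=object)
    sign[p_gt < alpha] = SIGN_POSITIVE
    sign[p_lt < alpha] = SIGN_NEGATIVE
    degenerate = (n1 == 0) | (n1 == N) | (n2 == 0) | (n2 == N)
    sign[degenerate] = SIGN_NONE
    if min_expected is not None:
        sign[expected < min_expected] = SIGN_NONE
    otus = np.asarray(m.otu_ids, dtype=object)
    table = pd.DataFrame(
        {
            "otu_a": otus[ia],
            "otu_b": otus[ib],
            "N": N,
            "n1": n1,
            "n2": n2,
            "j_obs": j,
            "expected_j": expected,
            "p_lt": p_lt,
            "p_gt": p_gt,
            "sign": sign,
        }
    )
    table.attrs["alpha"] = alpha
    return table


def bh_adjust(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Optional Benjamini-Hochberg re-classification across all pairs.

    The default pipeline thresholds raw per-pair tail probabilities; this
    helper returns a copy whose ``sign`` is based on BH-adjusted q-values
    of the smaller tail instead.
    """
    from statsmodels.stats.multitest import multipletests

    out = table.copy()
    p_min = np.minimum(out["p_lt"], out["p_gt"])
    reject, _, _, _ = multipletests(p_min, alpha=alpha, method="fdr_bh")
    sign = np.full(len(out), SIGN_NONE, dtype=object)
    upper = out["p_gt"] < out["p_lt"]
    sign[reject & upper] = SIGN_POSITIVE
    sign[reject & ~upper] = SIGN_NEGATIVE
    out["sign"] = sign
    return out


def write_associations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_associations(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"otu_a": str, "otu_b": str})
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    return table
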
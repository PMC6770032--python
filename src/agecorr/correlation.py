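"""Spearman rank correlation against continuous age, with exact small-sample p-values.

The screening question is whether a feature's expression varies monotonically
with patient age at diagnosis.  Spearman's rank correlation is the statistic of
choice because it needs neither normality nor linearity, and because its null
distribution is free of the data when the covariate (age) has no ties — which
the day-resolution age construction guarantees.

Three p-value regimes are provided, mirroring standard statistical-package
practice:

``exact``
    Full enumeration of the permutation null of ``S = sum(d_i^2)`` (the rank
    difference statistic), for small n.  Implemented as a subset dynamic
    program equivalent to enumerating all ``n!`` permutations.
``edgeworth``
    A one-term symmetric Edgeworth expansion of the null CDF of ``S`` for
    intermediate n.  ``S`` is symmetric under the null, so the skewness term
    vanishes and the first correction involves only the excess kurtosis, for
    which an exact closed form in ``n`` is used (see ``_excess_kurtosis``).
``t_approx``
    The classical ``t = rho * sqrt((n-2)/(1-rho^2))`` approximation with
    ``n - 2`` degrees of freedom, for large n.

All two-sided p-values are ``min(1, 2 * smaller tail)`` on the ``S``
distribution, the observed value included in the tail.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_EXACT_MAX",
    "DEFAULT_EDGEWORTH_MAX",
    "exact_s_distribution",
    "spearman_rho",
    "spearman_p_exact",
    "correlate_matrix",
    "ScreeningConfig",
    "ScreeningOutcome",
    "classify",
    "screen",
    "heatmap_order",
]

#: Largest n handled by full enumeration by default.
DEFAULT_EXACT_MAX = 10
#: Largest n handled by the Edgeworth expansion by default (t beyond).
DEFAULT_EDGEWORTH_MAX = 1289

# Hard ceiling for the enumeration DP: counts are held in int64 and n! must
# stay below 2**63 (13! ~ 6.2e9 is fine; the DP memory grows as 2**n).
_EXACT_HARD_MAX = 13


@functools.lru_cache(maxsize=16)
def exact_s_distribution(n: int) -> np.ndarray:
    """Exact null distribution of ``S = sum (i - pi(i))^2`` over permutations.

    Returns an int64 array ``counts`` of length ``n(n^2-1)/3 + 1`` where
    ``counts[s]`` is the number of the ``n!`` permutations with statistic
    ``S = s``.  Computed by a dynamic program over subsets of assigned ranks:
    positions are filled left to right, the bitmask records which ranks have
    been used, and the partial-sum histogram is convolved with the squared
    displacement of each candidate rank.  Exactly equivalent to brute-force
    enumeration, but O(2^n * n * S_max) instead of O(n!).
    """
    if not 1 <= n <= _EXACT_HARD_MAX:
        raise ValueError(
            f"exact enumeration supports 1 <= n <= {_EXACT_HARD_MAX}, got {n}"
        )
    size = n * (n * n - 1) // 3 + 1
    dp: list[np.ndarray | None] = [None] * (1 << n)
    start = np.zeros(size, dtype=np.int64)
    start[0] = 1
    dp[0] = start
    for mask in range(1 << n):
        cur = dp[mask]
        if cur is None:
            continue
        pos = mask.bit_count()
        if pos == n:
            continue
        for rank in range(n):
            if mask >> rank & 1:
                continue
            d2 = (pos - rank) ** 2
            nxt = mask | (1 << rank)
            tgt = dp[nxt]
            if tgt is None:
                tgt = np.zeros(size, dtype=np.int64)
                dp[nxt] = tgt
            if d2:
                tgt[d2:] += cur[: size - d2]
            else:
                tgt += cur
        dp[mask] = None  # free intermediate levels as we go
    out = dp[(1 << n) - 1]
    assert out is not None
    out.flags.writeable = False
    return out


def _excess_kurtosis_s(n: int) -> float:
    """Exact excess kurtosis of the null distribution of S (and of rho).

    Closed form recovered by exact rational interpolation of the enumerated
    null distributions for n = 4..13 (the variance ``n^2(n-1)(n+1)^2/36`` and
    this kurtosis reproduce every enumerated moment exactly).
    """
    return (-114.0 * n * n - 30.0 * n + 216.0) / (25.0 * n * (n - 1) * (n + 1))


def _s_from_rho(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    return (1.0 - np.asarray(rho, dtype=float)) * n * (n * n - 1) / 6.0


def _p_exact(rho: np.ndarray, n: int) -> np.ndarray:
    counts = exact_s_distribution(n)
    cum = np.cumsum(counts, dtype=np.float64)
    total = cum[-1]
    s = np.rint(_s_from_rho(rho, n)).astype(np.int64)
    s = np.clip(s, 0, len(counts) - 1)
    lower = cum[s] / total                       # P(S <= s)
    upper = 1.0 - np.where(s > 0, cum[s - 1], 0.0) / total  # P(S >= s)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _p_edgeworth(rho: np.ndarray, n: int) -> np.ndarray:
    mu = n * (n * n - 1) / 6.0
    sd = n * math.sqrt(n - 1.0) * (n + 1) / 6.0
    s = _s_from_rho(np.abs(rho), n)              # |rho| side: s <= mu
    # S moves on a lattice of spacing 2; +1 is the half-step continuity
    # correction for the lower (inclusive) tail.
    z = (s + 1.0 - mu) / sd
    tail = stats.norm.cdf(z) - stats.norm.pdf(z) * (
        _excess_kurtosis_s(n) / 24.0
    ) * (z ** 3 - 3.0 * z)
    tail = np.clip(tail, np.finfo(float).tiny, 1.0)
    return np.minimum(1.0, 2.0 * tail)


def _p_t(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(np.abs(rho), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, np.finfo(float).tiny, None))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _p_values(
    rho: np.ndarray,
    n: int,
    n_exact_max: int = DEFAULT_EXACT_MAX,
    edgeworth_max: int = DEFAULT_EDGEWORTH_MAX,
) -> tuple[np.ndarray, str]:
    """Vectorised two-sided p-values for a common sample size n."""
    if n < 3:
        raise ValueError(f"Spearman p-value requires n >= 3, got n={n}")
    if n_exact_max > _EXACT_HARD_MAX:
        raise ValueError(
            f"n_exact_max={n_exact_max} exceeds enumeration ceiling {_EXACT_HARD_MAX}"
        )
    rho = np.asarray(rho, dtype=float)
    if np.any(np.abs(rho[np.isfinite(rho)]) > 1.0 + 1e-12):
        bad = rho[np.abs(rho) > 1.0 + 1e-12][0]
        raise ValueError(f"|rho| must be <= 1, got {bad}")
    rho = np.clip(rho, -1.0, 1.0)
    if n <= n_exact_max:
        return _p_exact(rho, n), "exact"
    if n <= edgeworth_max:
        return _p_edgeworth(rho, n), "edgeworth"
    return _p_t(rho, n), "t_approx"


def spearman_p_exact(
    rho: float,
    n: int,
    n_exact_max: int = DEFAULT_EXACT_MAX,
    edgeworth_max: int = DEFAULT_EDGEWORTH_MAX,
) -> tuple[float, str]:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    Assumes tie-free data (integer S lattice); with ties the caller should
    treat the result as approximate.  Returns ``(p, method)`` where method is
    one of ``exact``, ``edgeworth``, ``t_approx`` depending on n and the
    configured branch points.
    """
    p, method = _p_values(np.asarray([rho]), n, n_exact_max, edgeworth_max)
    return float(p[0]), method


def spearman_rho(x, y) -> float:
    """Spearman's rho of two equal-length vectors.

    Uses mid-ranks, i.e. the product-moment correlation of the rank vectors;
    without ties this equals ``1 - 6*sum(d^2) / (n(n^2-1))``.  A constant
    vector has no rank ordering and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"Spearman rho requires n >= 3, got n={n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("rho undefined: constant input vector (all ranks tied)")
    if len(np.unique(x)) == n and len(np.unique(y)) == n:
        # tie-free: the closed form is exact (no floating cancellation)
        d2 = ((rx - ry) ** 2).sum()
        return float(1.0 - 6.0 * d2 / (n * (n * n - 1)))
    return float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * sx * sy))


def correlate_matrix(
    matrix,
    samples,
    tissue: str,
    n_exact_max: int = DEFAULT_EXACT_MAX,
    edgeworth_max: int = DEFAULT_EDGEWORTH_MAX,
) -> pd.DataFrame:
    """Spearman correlation of every feature against age in one tissue class.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Features x samples expression values.
    samples : sequence of SampleRecord
        Clinical records carrying ``tissue`` and the derived ``age_years``.
    tissue : {"tumor", "normal"}
        Which tissue class to correlate within.

    Returns a DataFrame with one row per feature and columns
    ``feature_id, tissue, n, rho, p, method, ties``.  Constant features get
    NaN rho/p and method ``undefined``; they are never classified downstream.
    """
    by_id = {s.sample_id: s for s in samples}
    sel = [sid for sid in matrix.sample_ids if sid in by_id and by_id[sid].tissue == tissue]
    if len(sel) < 3:
        raise ValueError(
            f"need >= 3 overlapping {tissue!r} samples between matrix and metadata, "
            f"found {len(sel)}"
        )
    ages = np.array([by_id[sid].age_years for sid in sel], dtype=float)
    if len(np.unique(ages)) < len(ages):
        warnings.warn(
            "tied ages detected: exact Spearman p-values assume a tie-free "
            "covariate and are approximate here",
            stacklevel=2,
        )
    values = matrix.data.loc[:, sel].to_numpy(dtype=float)
    n = len(sel)

    rank_age = stats.rankdata(ages)
    za = rank_age - rank_age.mean()
    za_norm = np.sqrt((za ** 2).sum())

    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    zr = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((zr ** 2).sum(axis=1))
    constant = norms == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (zr @ za) / (norms * za_norm)
    rho[constant] = np.nan
    rho = np.clip(rho, -1.0, 1.0)

    p = np.full(rho.shape, np.nan)
    ok = ~constant
    p_ok, method = _p_values(rho[ok], n, n_exact_max, edgeworth_max)
    p[ok] = p_ok

    # a feature has expression ties iff some mid-rank is non-integer or a
    # value repeats; detect via count of distinct values per row
    ties = np.array([len(np.unique(row)) < n for row in values])

    return pd.DataFrame(
        {
            "feature_id": list(matrix.feature_ids),
            "tissue": tissue,
            "n": n,
            "rho": rho,
            "p": p,
            "method": np.where(constant, "undefined", method),
            "ties": ties,
        }
    )


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the age-correlation screen.

    alpha
        Nominal two-sided significance level; no multiple-testing correction
        is applied (nominal p-values by design).
    rho_min
        Minimum |rho| for a feature to count as age-correlated (strict
        inequality: rho > rho_min or rho < -rho_min).
    normal_p_floor
        A tumor-classified feature is a *tumor-specific* candidate only when
        its normal-tissue p-value is >= this floor (inclusive), i.e. when the
        age trend is absent from non-neoplastic tissue and therefore not
        attributable to physiological growth.  0.05 by default; 0.4 is the
        stricter published alternative.
    """

    alpha: float = 0.05
    rho_min: float = 0.3
    normal_p_floor: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 <= self.rho_min <= 1.0:
            raise ValueError(f"rho_min must be in [0, 1], got {self.rho_min}")
        if not 0.0 <= self.normal_p_floor < 1.0:
            raise ValueError(
                f"normal_p_floor must be in [0, 1), got {self.normal_p_floor}"
            )


def classify(results: pd.DataFrame, config: ScreeningConfig) -> tuple[frozenset, frozenset]:
    """Split one tissue's correlation results into (positive, negative) sets.

    A feature is positively age-correlated when rho > rho_min and p < alpha,
    anti-correlated when rho < -rho_min and p < alpha.  NaN rows (constant
    features) are never classified.
    """
    sig = results["p"] < config.alpha
    pos = results.loc[sig & (results["rho"] > config.rho_min), "feature_id"]
    neg = results.loc[sig & (results["rho"] < -config.rho_min), "feature_id"]
    return frozenset(pos), frozenset(neg)


@dataclass(frozen=True)
class ScreeningOutcome:
    """Age-correlated feature sets per tissue plus tumor-specific candidates."""

    tumor_positive: frozenset
    tumor_negative: frozenset
    normal_positive: frozenset
    normal_negative: frozenset
    tumor_specific_candidates: frozenset
    ineligible_missing_normal: frozenset
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    @property
    def tumor_correlated(self) -> frozenset:
        return self.tumor_positive | self.tumor_negative

    def counts(self) -> dict:
        return {
            "tumor_positive": len(self.tumor_positive),
            "tumor_negative": len(self.tumor_negative),
            "normal_positive": len(self.normal_positive),
            "normal_negative": len(self.normal_negative),
            "tumor_specific_candidates": len(self.tumor_specific_candidates),
            "ineligible_missing_normal": len(self.ineligible_missing_normal),
        }


def screen(
    tumor_results: pd.DataFrame,
    normal_results: pd.DataFrame,
    config: ScreeningConfig | None = None,
) -> ScreeningOutcome:
    """Classify features in both tissues and select tumor-specific candidates.

    A candidate must be age-correlated in tumor (|rho| > rho_min, p < alpha)
    and must *not* show the trend in normal tissue (normal p >=
    ``normal_p_floor``, inclusive).  Features absent from the normal results
    (or with undefined normal p) cannot be judged tumor-specific and are
    reported separately as ineligible.
    """
    config = config or ScreeningConfig()
    if len(tumor_results) == 0 or len(normal_results) == 0:
        raise ValueError("empty correlation result list: nothing to screen")
    t_pos, t_neg = classify(tumor_results, config)
    n_pos, n_neg = classify(normal_results, config)

    normal_p = normal_results.set_index("feature_id")["p"]
    tumor_sig = t_pos | t_neg
    eligible = {f for f in tumor_sig if f in normal_p.index and np.isfinite(normal_p[f])}
    candidates = frozenset(
        f for f in eligible if normal_p[f] >= config.normal_p_floor
    )
    return ScreeningOutcome(
        tumor_positive=t_pos,
        tumor_negative=t_neg,
        normal_positive=n_pos,
        normal_negative=n_neg,
        tumor_specific_candidates=candidates,
        ineligible_missing_normal=frozenset(tumor_sig - eligible),
        config=config,
    )


def heatmap_order(results: pd.DataFrame, samples) -> tuple[list, list]:
    """Display ordering for an age-correlation heat map (no rendering).

    Returns ``(sample_ids, feature_ids)``: columns sorted by increasing age,
    rows by correlation sign (positive block first) then by decreasing rho.
    """
    tissue = results["tissue"].iloc[0]
    cols = sorted(
        (s for s in samples if s.tissue == tissue), key=lambda s: s.age_years
    )
    rows = results.dropna(subset=["rho"]).sort_values("rho", ascending=False)
    return [s.sample_id for s in cols], rows["feature_id"].tolist()
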
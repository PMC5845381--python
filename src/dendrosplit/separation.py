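"""Separation score between two cell populations.

The score rests on one assumption: if two populations are distinct cell
types, at least one gene is differentially expressed between them. Each
gene is tested with an independent Welch's t-test (robust to unequal
variances and group sizes) and the score is

    s(X, Y) = -log10(min_i p_i)

the negative log of the smallest per-gene p-value. Large scores mean
well-separated populations. p-values are computed in log space directly
from the t log-survival-function, so extremely significant genes keep a
finite -log10 p far past float underflow; genes whose p truly underflows
even in log space (both group variances zero, different means) score +inf
and are ranked among themselves by |t|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

_LN10 = np.log(10.0)


def _log_t_sf_extreme(t_abs: float, df: float) -> float:
    """log of the Student-t survival function for |t| far in the tail.

    Uses sf(t) = 0.5 * I_x(df/2, 1/2) with x = df/(df + t^2) and the
    hypergeometric series for the regularised incomplete beta, keeping the
    x^(df/2) factor in log space. Whenever the plain survival function
    underflows, x <= 1/2, so the series converges geometrically.
    """
    a = df / 2.0
    b = 0.5
    x = df / (df + t_abs * t_abs)
    # 2F1(1, a+b; a+1; x) = sum_n ((a+b)_n / (a+1)_n) x^n
    term = 1.0
    total = 1.0
    n = 0
    while term > 1e-18 * total and n < 100000:
        term *= x * (a + b + n) / (a + 1 + n)
        total += term
        n += 1
    log_ix = (
        a * np.log(x)
        + b * np.log1p(-x)
        - np.log(a)
        - special.betaln(a, b)
        + np.log(total)
    )
    return float(np.log(0.5) + log_ix)


@dataclass(frozen=True)
class WelchResult:
    """Welch's t-test summary for a single gene: t, Welch-Satterthwaite df,
    and the base-10 log of the two-sided p-value (<= 0; -inf on underflow)."""

    t_stat: float
    df: float
    p_value_log10: float


@dataclass
class SeparationResult:
    """Per-gene Welch statistics for one candidate split, plus the score.

    ``ranked_genes`` sorts gene indices by significance: p ascending, ties
    by |t| descending, final ties by gene order. ``score`` is the -log10 of
    the smallest p (+inf when that p underflows even in log space).
    """

    score: float
    t_stat: np.ndarray
    df: np.ndarray
    p_value_log10: np.ndarray
    ranked_genes: np.ndarray

    @property
    def best_gene_index(self) -> int:
        return int(self.ranked_genes[0])

    @property
    def n_genes(self) -> int:
        return self.t_stat.shape[0]

    def gene_result(self, i: int) -> WelchResult:
        return WelchResult(
            t_stat=float(self.t_stat[i]),
            df=float(self.df[i]),
            p_value_log10=float(self.p_value_log10[i]),
        )


def _welch_arrays(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch's t-test over the columns (genes) of A and B.

    Returns (t, df, log10 two-sided p) arrays of length M. A gene is
    degenerate when both groups are constant up to floating-point jitter
    (sample sd <= 1e-12 of the value scale): it gets t=0, p=1 when the two
    constants agree to the same tolerance, and t=+/-inf, log10 p=-inf
    (true underflow) when they differ. The relative tolerance stops
    last-ulp noise — e.g. radii of mathematically identical points — from
    masquerading as infinitely significant separation.
    """
    n1, n2 = A.shape[0], B.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 cells for Welch's t-test")
    m1 = A.mean(axis=0)
    m2 = B.mean(axis=0)
    v1 = A.var(axis=0, ddof=1)
    v2 = B.var(axis=0, ddof=1)
    se1 = v1 / n1
    se2 = v2 / n2
    se = se1 + se2
    diff = m1 - m2

    tol = 1e-12 * np.maximum(np.abs(m1), np.abs(m2))
    degenerate = (np.sqrt(v1) <= tol) & (np.sqrt(v2) <= tol)
    se_safe = np.where(degenerate, 1.0, se)
    t = diff / np.sqrt(se_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = se_safe**2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    df = np.where(degenerate, float(n1 + n2 - 2), df)
    # two-sided p in log space: log10 p = (ln 2 + logsf(|t|, df)) / ln 10;
    # scipy's logsf itself hits -inf in the extreme tail, where the
    # incomplete-beta series takes over
    logsf = stats.t.logsf(np.abs(t), df)
    for i in np.flatnonzero(np.isneginf(logsf) & ~degenerate):
        logsf[i] = _log_t_sf_extreme(float(np.abs(t[i])), float(df[i]))
    log10p = (np.log(2.0) + logsf) / _LN10
    log10p = np.minimum(log10p, 0.0)

    if degenerate.any():
        shifted = degenerate & (np.abs(diff) > tol)
        flat = degenerate & (np.abs(diff) <= tol)
        t = np.where(shifted, np.where(diff > 0, np.inf, -np.inf), t)
        t = np.where(flat, 0.0, t)
        log10p = np.where(shifted, -np.inf, log10p)
        log10p = np.where(flat, 0.0, log10p)
    return t, df, log10p


def welch_t_test(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Welch's two-sample t-test for a single gene (two-sided, log-space p)."""
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    t, df, log10p = _welch_arrays(x, y)
    return WelchResult(t_stat=float(t[0]), df=float(df[0]), p_value_log10=float(log10p[0]))


def _rank_genes(log10p: np.ndarray, t: np.ndarray) -> np.ndarray:
    abs_t = np.abs(t)
    # lexsort: last key is primary. p ascending, |t| descending, index ascending.
    return np.lexsort((np.arange(log10p.shape[0]), -abs_t, log10p))


def separation_score(A: np.ndarray, B: np.ndarray) -> SeparationResult:
    """Score how separated two populations are, gene by gene.

    Parameters are ``(n1, M)`` and ``(n2, M)`` expression submatrices over
    the same M genes. Symmetric in its arguments (t flips sign only).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("populations must be 2-D with the same gene count")
    t, df, log10p = _welch_arrays(A, B)
    ranked = _rank_genes(log10p, t)
    best = ranked[0]
    score = -log10p[best]  # -(-inf) -> +inf on underflow
    return SeparationResult(
        score=float(score),
        t_stat=t,
        df=df,
        p_value_log10=log10p,
        ranked_genes=ranked,
    )


def top_genes(
    result: SeparationResult, k: int, gene_ids: list[str] | None = None
) -> list[tuple[str, float, float]]:
    """The k most significant genes as (gene_id, log10 p, t) tuples.

    Ordered by p ascending, |t| descending on ties, gene order on exact
    ties. ``k`` larger than the gene count returns all genes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = result.ranked_genes[: min(k, result.n_genes)]
    if gene_ids is None:
        gene_ids = [str(i) for i in range(result.n_genes)]
    return [
        (gene_ids[i], float(result.p_value_log10[i]), float(result.t_stat[i]))
        for i in idx
    ]
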
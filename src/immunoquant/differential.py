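"""Negative-binomial exact differential expression with BH correction.

Implements the classical exact test for overdispersed count data in the
clonotype-vs-rest setting: library sizes are first equalized by total-count
scaling (each cell's counts are scaled to the geometric-mean depth and
rounded to integers), each group's counts for a gene are collapsed to a
pseudo-sum, and the two-sided p-value is the probability -- under negative
binomial sums with a shared per-cell mean and a given dispersion,
conditional on the observed total -- of all splits whose probability does
not exceed that of the observed split (the minimum-likelihood rule).
With dispersion 0 the test reduces to the exact binomial (Poisson) test.

Dispersion is estimated per gene by method of moments on normalized counts,
``alpha = max(0, (var - mean) / mean**2)`` (0 at or below the Poisson
boundary), without shrinkage.  Multiple testing is handled by the
Benjamini--Hochberg step-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "size_factors",
    "equalize_libraries",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "run_de",
]

# Relative tolerance when comparing split probabilities to the observed one;
# guards the minimum-likelihood sum against floating-point ties.
_TIE_RTOL = 1e-10


def size_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Total-count size factors: per-cell depth over geometric-mean depth."""
    mat = np.asarray(counts, dtype=float)
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every cell must have a positive total count")
    return lib / np.exp(np.mean(np.log(lib)))


def equalize_libraries(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Scale each cell to the geometric-mean depth and round to integers."""
    mat = np.asarray(counts, dtype=float)
    sf = size_factors(mat)
    return np.rint(mat / sf).astype(np.int64)


def estimate_dispersion(counts_for_gene, size_factors=None) -> float:
    """Method-of-moments NB dispersion for one gene.

    Counts are normalized by ``size_factors`` (taken as 1 when omitted) and
    the dispersion is ``max(0, (var - mean) / mean**2)`` with the sample
    variance; at or below the Poisson boundary (var <= mean) the estimate
    is 0.  An all-zero gene returns 0.
    """
    y = np.asarray(counts_for_gene, dtype=float)
    if y.size < 2:
        raise ValueError("dispersion estimation needs >= 2 observations")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if size_factors is not None:
        sf = np.asarray(size_factors, dtype=float)
        if sf.shape != y.shape:
            raise ValueError("size_factors must match counts in length")
        y = y / sf
    m = y.mean()
    if m == 0:
        return 0.0
    v = y.var(ddof=1)
    return max(0.0, (v - m) / m**2)


def _nb_logpmf(x: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """log pmf of NB with given mean and dispersion (var = m + a*m^2).

    Dispersions below 1e-10 are evaluated as Poisson: the distributions are
    numerically indistinguishable there and a huge size parameter 1/a would
    degrade the NB pmf.
    """
    if dispersion < 1e-10:
        return stats.poisson.logpmf(x, mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom.logpmf(x, r, p)


def nb_exact_test(group_a, group_b, dispersion: float) -> float:
    """Exact two-sided NB test for a single gene between two cell groups.

    ``group_a`` and ``group_b`` are equalized (equal-depth) integer count
    vectors.  Each group is collapsed to its pseudo-sum; a sum of ``n`` iid
    NB(mu, alpha) cells is NB with mean ``n*mu`` and dispersion ``alpha/n``.
    Under the shared null mean (pooled), the p-value is the total
    conditional probability, given the observed grand total, of splits no
    more probable than the observed one.  Exchangeable identical groups
    give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError(f"dispersion must be >= 0, got {dispersion}")
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    y_a = int(round(a.sum()))
    y_b = int(round(b.sum()))
    s = y_a + y_b
    if s == 0:
        return 1.0
    mu = s / (n_a + n_b)

    x = np.arange(s + 1)
    log_f = _nb_logpmf(x, n_a * mu, dispersion / n_a) + _nb_logpmf(
        x[::-1], n_b * mu, dispersion / n_b
    )
    log_total = logsumexp(log_f)
    log_obs = log_f[y_a]
    keep = log_f <= log_obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(log_f[keep]) - log_total)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted values, in input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j``, clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_de(counts: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Gene-wise NB exact test of one cell group against the other.

    Parameters
    ----------
    counts : pandas.DataFrame
        Genes x cells non-negative integer matrix.
    groups : pandas.Series
        Cell -> group label, exactly two labels; the lexicographically
        first label is group A (reported fold-changes are A over B).

    Returns
    -------
    pandas.DataFrame
        One row per gene with ``gene, mean_a, mean_b, log2_fc, dispersion,
        p, q``, ordered by q then p then gene name.

    Notes
    -----
    Dispersion is estimated per gene within each group (method of moments
    on the equalized counts) and combined as a degrees-of-freedom-weighted
    average, so a real between-group difference does not masquerade as
    overdispersion.
    """
    groups = pd.Series(groups)
    if set(groups.index) != set(counts.columns):
        raise ValueError("groups must be indexed by exactly the cells of the count matrix")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    groups = groups.reindex(counts.columns)
    eq = equalize_libraries(counts)
    mask_a = (groups == labels[0]).to_numpy()
    mat_a, mat_b = eq[:, mask_a], eq[:, ~mask_a]
    n_a, n_b = mat_a.shape[1], mat_b.shape[1]

    rows = []
    for i, gene in enumerate(counts.index):
        a, b = mat_a[i], mat_b[i]
        if a.sum() + b.sum() == 0:
            rows.append((gene, 0.0, 0.0, np.nan, 0.0, 1.0))
            continue
        disp_a = estimate_dispersion(a) if n_a >= 2 else 0.0
        disp_b = estimate_dispersion(b) if n_b >= 2 else 0.0
        w_a, w_b = max(n_a - 1, 0), max(n_b - 1, 0)
        disp = (w_a * disp_a + w_b * disp_b) / max(w_a + w_b, 1)
        p = nb_exact_test(a, b, disp)
        mean_a, mean_b = a.mean(), b.mean()
        with np.errstate(divide="ignore"):
            log2_fc = np.log2(mean_a / mean_b) if mean_b > 0 else np.inf
        rows.append((gene, mean_a, mean_b, log2_fc, disp, p))

    out = pd.DataFrame(
        rows, columns=["gene", "mean_a", "mean_b", "log2_fc", "dispersion", "p"]
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p", "gene"], kind="mergesort").reset_index(drop=True)
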
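"""Audic-Claverie differential expression with length and library-size
normalization.

The Audic-Claverie statistic compares the counts of one transcript in two
libraries of sizes N1, N2.  Given x reads in the first library, the
posterior probability of seeing y in the second is

    p(y | x) = r**y * Gamma(x + y + 1)
               / (Gamma(x + 1) * Gamma(y + 1) * (1 + r)**(x + y + 1)),

with r = N2 / N1 — for integer x a negative binomial in y with size x + 1
and success probability 1 / (1 + r).  Two modifications adapt it to
reference-free RNA-seq:

* x and y are *reads per kilobase* of the transcript, removing length bias
  (expected counts grow with transcript length);
* across a series of pairwise comparisons, N1, N2, x and y are all
  rescaled to the smallest library in the series, so comparisons carry
  equal statistical weight regardless of sequencing depth.

Real-valued x, y are handled by the Gamma-function form; tails use the
continuous extension of the negative-binomial survival function
(regularized incomplete beta).  Two-sided p-values double the smaller
inclusive tail, capped at 1.  FDR control is Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

from .catalog import ConsistencyError
from .readcount import CountTable


def audic_pmf(x, y, n1, n2):
    """Posterior probability mass p(y | x) at r = N2/N1 (log-space)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("x and y must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    log_p = (
        y * np.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    return np.exp(log_p)


def _tails(x, y, r):
    """Inclusive lower and upper tails of p(. | x) at y (continuous in y).

    Upper: P(Y >= y) = I_q(y, x + 1), q = r / (1 + r) (y > 0; else 1).
    Lower: 1 - upper + pmf, the inclusive complement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    q = r / (1.0 + r)
    with np.errstate(invalid="ignore"):
        upper = np.where(y > 0, betainc(np.maximum(y, 1e-300), x + 1.0, q), 1.0)
    pmf = audic_pmf(x, y, 1.0, r)
    lower = np.clip(1.0 - upper + pmf, 0.0, 1.0)
    return lower, upper


def _oriented_pvalue(x, y, r):
    """min(1, 2 * smaller inclusive tail) conditioning on x."""
    lower, upper = _tails(x, y, r)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def audic_pvalue(x, y, n1, n2):
    """Two-sided p-value: twice the smaller inclusive tail, capped at 1.

    The doubled-tail construction conditions on the first count, and its
    tails are not symmetric under exchanging the two libraries (the
    posterior's size parameter follows the conditioning count).  The
    reported p is therefore the larger of the two orientations, which is
    exactly exchange-symmetric, conservative, and leaves the reference
    values (p = 1 for equal counts; p = 1/4 for 0 vs 3 at equal sizes)
    unchanged.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    p = np.maximum(_oriented_pvalue(x, y, r), _oriented_pvalue(y, x, 1.0 / r))
    # keep p in (0, 1]: the beta tail underflows for extreme count pairs
    return np.maximum(p, 1e-300)


def audic_test(c1, c2, length_kb, n1, n2, n_min=None):
    """Length-normalized, size-rescaled two-sided Audic-Claverie p-value.

    x = (c1/length_kb) * (N_min/N1) and y = (c2/length_kb) * (N_min/N2);
    both sampling sizes are rescaled to N_min (within a single pair the
    default N_min = min(N1, N2)).  Vectorized over counts and lengths.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    length_kb = np.asarray(length_kb, dtype=float)
    if (length_kb <= 0).any():
        raise ValueError("lengths must be positive")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if n_min is None:
        n_min = min(n1, n2)
    if n_min > min(n1, n2):
        raise ValueError("N_min may not exceed the smaller library size")
    x = (c1 / length_kb) * (n_min / n1)
    y = (c2 / length_kb) * (n_min / n2)
    return audic_pvalue(x, y, n_min, n_min)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dets(
    counts: CountTable,
    lib_a: str,
    lib_b: str,
    lengths: pd.Series,
    norm: pd.DataFrame | None = None,
    fdr_cutoff: float = 0.01,
    fc_cutoff: float = 2.0,
    n_min: float | None = None,
    zero_rpkm_eps: float = 1e-3,
) -> pd.DataFrame:
    """Call differentially expressed units between two libraries.

    Units with zero counts in both libraries are excluded from testing.
    Fold change is the ratio of TMM-adjusted RPKM values (``zero_rpkm_eps``
    added to both sides only when one side is zero); ``call`` is "up"
    (higher in ``lib_a``) or "down" iff q < fdr_cutoff and the
    larger/smaller RPKM ratio exceeds fc_cutoff, else "ns".
    """
    for lib in (lib_a, lib_b):
        if lib not in counts.libraries:
            raise ConsistencyError(f"library {lib!r} not in count table")
    c1 = counts.column(lib_a)
    c2 = counts.column(lib_b)
    lens = pd.Series(lengths).reindex(counts.units)
    if lens.isna().any():
        raise ConsistencyError("length missing for some units")

    tested = (c1 + c2) > 0
    idx = counts.units[tested]
    c1t = c1[tested].to_numpy(dtype=float)
    c2t = c2[tested].to_numpy(dtype=float)
    len_kb = lens[tested].to_numpy(dtype=float) / 1e3

    n1 = float(counts.totals[lib_a])
    n2 = float(counts.totals[lib_b])
    p = audic_test(c1t, c2t, len_kb, n1, n2, n_min=n_min)
    q = bh_fdr(p)

    if norm is not None:
        ne1 = float(norm.loc[lib_a, "N_eff"])
        ne2 = float(norm.loc[lib_b, "N_eff"])
    else:
        ne1, ne2 = n1, n2
    rpkm1 = c1t / (len_kb * ne1 / 1e6)
    rpkm2 = c2t / (len_kb * ne2 / 1e6)
    one_zero = (rpkm1 == 0) ^ (rpkm2 == 0)
    r1 = np.where(one_zero, rpkm1 + zero_rpkm_eps, rpkm1)
    r2 = np.where(one_zero, rpkm2 + zero_rpkm_eps, rpkm2)
    log2fc = np.log2(r1 / r2)
    fc = np.maximum(r1 / r2, r2 / r1)

    call = np.where(
        (q < fdr_cutoff) & (fc > fc_cutoff),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    out = pd.DataFrame(
        {
            "unit_id": idx,
            "c1": c1t.astype(int),
            "c2": c2t.astype(int),
            "x": (c1t / len_kb) * ((n_min if n_min is not None else min(n1, n2)) / n1),
            "y": (c2t / len_kb) * ((n_min if n_min is not None else min(n1, n2)) / n2),
            "rpkm1": rpkm1,
            "rpkm2": rpkm2,
            "p": p,
            "q": q,
            "log2fc": log2fc,
            "call": call,
        }
    ).set_index("unit_id")
    return out


def write_det_tsv(dets: pd.DataFrame, path) -> None:
    dets.to_csv(path, sep="\t", float_format="%.10g")


def read_det_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="unit_id", comment="#")
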
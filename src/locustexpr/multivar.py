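"""Library-level principal component analysis of expression profiles.

Libraries are the observations, transcripts the variables.  Transcripts
detected in fewer than a minimum number of libraries (default 6) are
removed, each surviving transcript's RPKM profile is standardized to zero
mean and unit variance across libraries, and the decomposition is taken
on the small library x library matrix (equivalent, for scores and
variance fractions, to the eigen-decomposition of the transcript
correlation matrix).  Libraries receive component scores, transcripts
loadings; signs are fixed so the largest-magnitude loading of each
component is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    pass


@dataclass
class PCAResult:
    variance_fraction: pd.Series   # per component, sums to 1
    scores: pd.DataFrame           # libraries x components
    loadings: pd.DataFrame         # transcripts x components
    n_retained: int                # transcripts surviving the filters

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variance_fraction": self.variance_fraction,
                "cumulative": self.variance_fraction.cumsum(),
            }
        )


def pca_libraries(
    expr: pd.DataFrame,
    detected: pd.DataFrame | None = None,
    min_libraries: int = 6,
) -> PCAResult:
    """PCA of libraries over standardized transcript expression.

    ``expr`` is transcripts x libraries (RPKM).  ``detected`` is an
    optional boolean matrix of the same shape (count >= 1); without it,
    expr > 0 is used (identical under the RPKM definition here).
    Transcripts detected in fewer than ``min_libraries`` libraries, and
    transcripts with zero variance after filtering, are dropped.
    """
    if expr.shape[1] < 2:
        raise DegenerateInputError("need at least two libraries")
    det = (expr > 0) if detected is None else detected.reindex_like(expr)
    keep = det.sum(axis=1) >= min_libraries
    mat = expr.loc[keep]
    sd = mat.std(axis=1, ddof=1)
    mat = mat.loc[sd > 0]
    if mat.shape[0] < 2:
        raise DegenerateInputError("fewer than two transcripts survive filtering")

    z = (mat.sub(mat.mean(axis=1), axis=0)).div(mat.std(axis=1, ddof=1), axis=0)
    # observations = libraries: SVD of the (libraries x transcripts) matrix
    x = z.to_numpy().T
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| positive per component
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0

    var = s ** 2
    frac = var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        variance_fraction=pd.Series(frac, index=comps),
        scores=pd.DataFrame(u * s, index=expr.columns, columns=comps),
        loadings=pd.DataFrame(vt.T, index=mat.index, columns=comps),
        n_retained=mat.shape[0],
    )


def group_association(scores: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per component: R^2 of scores explained by a categorical grouping.

    Used to ask which component separates developmental stages and which
    separates phases.
    """
    g = groups.reindex(scores.index)
    out = {}
    for comp in scores.columns:
        y = scores[comp]
        grand = y.mean()
        ss_tot = ((y - grand) ** 2).sum()
        ss_between = sum(
            len(sub) * (sub.mean() - grand) ** 2 for _, sub in y.groupby(g)
        )
        out[comp] = 0.0 if ss_tot == 0 else ss_between / ss_tot
    return pd.Series(out)
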
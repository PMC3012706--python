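"""Library normalization (TMM) and adjusted RPKM expression values.

Libraries sequenced from different conditions differ in RNA composition:
if one condition devotes a large share of its output to a few transcripts,
every other transcript is under-sampled there even at equal sequencing
depth.  The trimmed mean of M-values (TMM; Robinson & Oshlack 2010)
estimates a per-library scaling factor from the doubly trimmed, weighted
mean of per-gene log relative-abundance ratios against a reference
library.  The effective library size is N_eff = N * sqrt(f), and RPKM is
computed against the effective size:

    RPKM(t, lib) = count / ((length_t / 1e3) * (N_eff / 1e6))

Cluster members inherit their unit's count, each normalized by its own
length.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .catalog import ClusterMap, ConsistencyError
from .readcount import CountTable


class DegenerateInputError(ValueError):
    """No usable genes remain for normalization."""


def tmm_factor(
    obs: pd.Series | np.ndarray,
    ref: pd.Series | np.ndarray,
    n_obs: float | None = None,
    n_ref: float | None = None,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM normalization factor of ``obs`` against ``ref``.

    Genes with a zero count in either library are excluded.  M (log2 ratio
    of relative abundances) and A (mean log2 relative abundance) are each
    trimmed symmetrically (defaults 30% / 5%), and the factor is
    2**(weighted mean of surviving M), weights the inverse delta-method
    variances (n - c) / (n * c) summed over the two libraries.
    """
    o = np.asarray(obs, dtype=float)
    r = np.asarray(ref, dtype=float)
    if o.shape != r.shape:
        raise ValueError("libraries must share the unit universe")
    n_o = float(o.sum()) if n_obs is None else float(n_obs)
    n_r = float(r.sum()) if n_ref is None else float(n_ref)
    if n_o <= 0 or n_r <= 0:
        raise DegenerateInputError("library totals must be positive")

    keep = (o > 0) & (r > 0)
    o, r = o[keep], r[keep]
    if o.size == 0:
        raise DegenerateInputError("no units expressed in both libraries")

    m = np.log2((o / n_o) / (r / n_r))
    a = 0.5 * np.log2((o / n_o) * (r / n_r))

    n = m.size
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        raise DegenerateInputError("no units survive trimming")

    m, o, r = m[keep2], o[keep2], r[keep2]
    if weighted:
        var = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
        var = np.where(var <= 0, np.nan, var)
        with np.errstate(invalid="ignore"):
            num = np.nansum(m / var)
            den = np.nansum(1.0 / var)
        mean_m = num / den if den > 0 else float(np.mean(m))
    else:
        mean_m = float(np.mean(m))
    if abs(mean_m) < 1e-10:
        mean_m = 0.0
    return float(2.0 ** mean_m)


def effective_size(n: float, f: float) -> float:
    """Effective library size: N multiplied by the square root of f."""
    if n <= 0 or f <= 0:
        raise ValueError("library size and factor must be positive")
    return n * math.sqrt(f)


def tmm_normalize(
    counts: CountTable,
    ref_library: str,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    renorm: str = "ref",
) -> pd.DataFrame:
    """Per-library TMM factors and effective sizes against ``ref_library``.

    ``renorm="ref"`` (default) leaves the reference at f = 1 exactly;
    ``renorm="geomean"`` rescales factors to geometric mean 1.  The choice
    shifts every factor by one constant and cancels in all cross-library
    ratios.  Returns a DataFrame indexed by library with columns
    ``N``, ``f``, ``N_eff``, ``reference``.
    """
    if ref_library not in counts.libraries:
        raise ConsistencyError(f"reference library {ref_library!r} not in count table")
    ref = counts.column(ref_library)
    n_ref = float(counts.totals[ref_library])
    rows = {}
    for lib in counts.libraries:
        if lib == ref_library:
            f = 1.0
        else:
            f = tmm_factor(
                counts.column(lib), ref, counts.totals[lib], n_ref,
                logratio_trim, abundance_trim,
            )
        rows[lib] = f
    factors = pd.Series(rows)
    if renorm == "geomean":
        factors = factors / np.exp(np.log(factors).mean())
    elif renorm != "ref":
        raise ValueError(f"unknown renorm mode {renorm!r}")
    out = pd.DataFrame(
        {
            "N": counts.totals.astype(float),
            "f": factors,
            "N_eff": [effective_size(counts.totals[lib], factors[lib]) for lib in factors.index],
        }
    )
    out["reference"] = ref_library
    out.index.name = "library"
    return out


def rpkm_matrix(
    counts: CountTable,
    lengths: pd.Series,
    norm: pd.DataFrame | None = None,
    clusters: ClusterMap | None = None,
) -> pd.DataFrame:
    """Adjusted RPKM per transcript (or unit) per library.

    With ``clusters`` given, every member transcript inherits its unit's
    count and is normalized by its own length; otherwise rows are the
    counting units themselves.  ``norm`` supplies effective sizes; without
    it the raw assigned totals are used.
    """
    if norm is not None:
        n_eff = norm["N_eff"].reindex(counts.libraries)
        if n_eff.isna().any():
            raise ConsistencyError("normalization table misses libraries")
    else:
        n_eff = counts.totals.astype(float)
    if (n_eff <= 0).any():
        raise ValueError("effective sizes must be positive")

    if clusters is None:
        mat = counts.counts
        row_ids = mat.index
    else:
        member_units = clusters.assignments.sort_index()
        mat = counts.counts.reindex(member_units.values)
        mat.index = member_units.index
        row_ids = mat.index

    lens = pd.Series(lengths).reindex(row_ids)
    if lens.isna().any():
        missing = row_ids[lens.isna()][0]
        raise ConsistencyError(f"no length for {missing!r}")
    if (lens <= 0).any():
        raise ValueError("lengths must be positive")

    denom = np.outer(lens.values / 1e3, n_eff.values / 1e6)
    rpkm = pd.DataFrame(mat.values / denom, index=row_ids, columns=counts.libraries)
    return rpkm


def write_norm_tsv(norm: pd.DataFrame, path) -> None:
    norm.to_csv(path, sep="\t", float_format="%.10g")


def read_norm_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="library", comment="#")
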
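"""Term-enrichment testing of a gene list against a catalog background.

For each term a 2x2 table is formed GOstat-style: the supplied list versus
the *rest* of the background (so the list does not contaminate its own
reference):

    a = list members annotated with the term       b = list members without it
    c = background-only members with the term      d = background-only without it

The p-value comes from a Pearson chi-square test (1 df, no continuity
correction) unless any expected count under independence falls below 5,
in which case the two-sided Fisher exact test (point-mass method) is used.
Raw p-values are reported by default; Benjamini-Hochberg correction is
available but off by default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ConsistencyError
from .diffexpr import bh_fdr


def enrich_test(a: int, b: int, c: int, d: int) -> tuple[float, str]:
    """Two-sided p for one 2x2 table, with the chi-square/Fisher dispatch.

    Returns ``(p, test)`` where test is ``"chi-square"`` or ``"fisher"``.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    n = table.sum()
    if n == 0:
        raise ValueError("all-zero 2x2 table is untestable")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected == 0).any():
        # a zero margin: no contrast to test
        return 1.0, "chi-square"
    if expected.min() < 5:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(p), "fisher"
    stat = ((table - expected) ** 2 / expected).sum()
    p = float(stats.chi2.sf(stat, df=1))
    return min(p, 1.0), "chi-square"


def _terms_frame(annotation) -> pd.DataFrame:
    """Normalize annotation input to a (gene_id, term_id) frame."""
    if isinstance(annotation, pd.DataFrame):
        if not {"gene_id", "term_id"} <= set(annotation.columns):
            raise ValueError("annotation frame needs gene_id and term_id columns")
        return annotation[["gene_id", "term_id"]].astype(str)
    if isinstance(annotation, Mapping):
        rows = [(g, t) for t, genes in annotation.items() for g in genes]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"]).astype(str)
    raise TypeError("annotation must be a DataFrame or a term -> genes mapping")


def enrich_scan(
    gene_list: Iterable[str],
    annotation,
    background: Iterable[str],
    alpha: float = 0.01,
    correct: bool = False,
) -> pd.DataFrame:
    """Test every term with >=1 background member against the gene list.

    Returns one row per term: the 2x2 counts, the expected list-overlap
    under independence, the test used, p (and q if ``correct``), the
    direction ("enriched" when the list overlap exceeds expectation) and a
    significance flag at ``alpha``.
    """
    genes = set(map(str, gene_list))
    bg = set(map(str, background))
    if not genes <= bg:
        raise ConsistencyError("gene list must be a subset of the background")
    ann = _terms_frame(annotation)
    ann = ann[ann["gene_id"].isin(bg)]
    n_list = len(genes)
    n_rest = len(bg) - n_list

    rows = []
    for term, members in sorted(ann.groupby("term_id")["gene_id"]):
        mem = set(members)
        a = len(mem & genes)
        b = n_list - a
        c = len(mem) - a
        d = n_rest - c
        p, test = enrich_test(a, b, c, d)
        expected_a = n_list * len(mem) / len(bg) if bg else 0.0
        rows.append(
            {
                "term_id": term,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "expected_a": expected_a,
                "test": test,
                "p": p,
                "direction": "enriched" if a > expected_a else "depleted",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term_id", "a", "b", "c", "d", "expected_a", "test", "p", "direction"],
    )
    if len(out) and correct:
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = (out["q"] < alpha) & (out["direction"] == "enriched")
    elif len(out):
        out["significant"] = (out["p"] < alpha) & (out["direction"] == "enriched")
    return out.set_index("term_id") if len(out) else out


# ---- annotation I/O ------------------------------------------------------

def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    """One gene_id/term_id pair per line (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene_id", "term_id"], dtype=str)
    return df


def write_annotation_tsv(annotation, path: str | Path) -> None:
    _terms_frame(annotation).to_csv(path, sep="\t", index=False)
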
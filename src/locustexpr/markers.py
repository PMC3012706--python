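"""Phase-marker screens over the 2-phase x 6-stage expression design.

Two screens identify candidate marker transcripts distinguishing the
gregarious (G) from the solitary (S) phase across development:

* *phase-specific*: detected (>=1 assigned read) in at least 5 of the 6
  developmental stages of one phase but undetected in at least 4 stages of
  the other phase;
* *stable-difference*: over the 5 post-egg stages, coefficient of
  variability (sd/mean) below 0.3 within the phase groups, mean ratio of
  the two groups above 1.5, and a two-sample (Welch) t-test p below 0.05.

The printed CV clause reads "within gregarious phase group or solitary
phase group"; whether one or both groups must be stable is ambiguous, so
the requirement is a mode switch (default: both groups).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STAGES = ("egg", "instar12", "instar3", "instar4", "instar5", "adult")
POST_EGG_STAGES = STAGES[1:]
PHASES = ("G", "S")


def _check_phase_stage_columns(df: pd.DataFrame, stages) -> None:
    if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 2:
        raise ValueError("expected columns as a (phase, stage) MultiIndex")
    for phase in PHASES:
        have = set(df[phase].columns) if phase in df.columns.get_level_values(0) else set()
        if not set(stages) <= have:
            raise ValueError(f"phase {phase!r} misses stages {set(stages) - have}")


def phase_stage_matrix(values: pd.DataFrame, design) -> pd.DataFrame:
    """Reshape a unit x library matrix to (phase, stage) MultiIndex columns.

    ``design`` is an iterable of library descriptors with ``library_id``,
    ``phase`` and ``stage`` attributes (one library per phase x stage).
    """
    cols = {}
    for lib in design:
        cols[(lib.phase, lib.stage)] = values[lib.library_id]
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["phase", "stage"])
    return out


def specific_markers(
    presence: pd.DataFrame,
    min_present: int = 5,
    min_absent: int = 4,
) -> pd.DataFrame:
    """Presence/absence screen over all 6 stages of both phases.

    ``presence`` is boolean with (phase, stage) MultiIndex columns.  A unit
    is flagged toward phase P iff detected in >= ``min_present`` stages of
    P and undetected in >= ``min_absent`` stages of the other phase.
    """
    _check_phase_stage_columns(presence, STAGES)
    n_stages = len(STAGES)
    present = {p: presence[p][list(STAGES)].sum(axis=1) for p in PHASES}
    calls = []
    for phase, other in (("G", "S"), ("S", "G")):
        flag = (present[phase] >= min_present) & ((n_stages - present[other]) >= min_absent)
        for unit in presence.index[flag]:
            calls.append(
                {
                    "unit_id": unit,
                    "marker_class": "phase-specific",
                    "direction": "gregarious" if phase == "G" else "solitary",
                    "n_present_G": int(present["G"][unit]),
                    "n_present_S": int(present["S"][unit]),
                }
            )
    return pd.DataFrame(
        calls, columns=["unit_id", "marker_class", "direction", "n_present_G", "n_present_S"]
    )


def stable_markers(
    expr: pd.DataFrame,
    cv_max: float = 0.3,
    ratio_min: float = 1.5,
    alpha: float = 0.05,
    cv_mode: str = "both",
) -> pd.DataFrame:
    """Stable-difference screen over the 5 post-egg stages.

    ``expr`` holds expression values (RPKM) with (phase, stage) MultiIndex
    columns; egg columns, if present, are ignored.  ``cv_mode`` "both"
    requires CV < cv_max in both phase groups, "either" in at least one.
    """
    if cv_mode not in ("both", "either"):
        raise ValueError("cv_mode must be 'both' or 'either'")
    _check_phase_stage_columns(expr, POST_EGG_STAGES)
    g = expr["G"][list(POST_EGG_STAGES)]
    s = expr["S"][list(POST_EGG_STAGES)]

    mean_g, mean_s = g.mean(axis=1), s.mean(axis=1)
    usable = (mean_g > 0) & (mean_s > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("stable-marker screen: %d units skipped (zero group mean)", n_skipped)

    cv_g = g.std(axis=1, ddof=1) / mean_g
    cv_s = s.std(axis=1, ddof=1) / mean_s
    ratio = np.maximum(mean_g / mean_s, mean_s / mean_g)
    t_p = pd.Series(
        stats.ttest_ind(g, s, axis=1, equal_var=False).pvalue, index=expr.index
    )

    if cv_mode == "both":
        cv_ok = (cv_g < cv_max) & (cv_s < cv_max)
    else:
        cv_ok = (cv_g < cv_max) | (cv_s < cv_max)
    flag = usable & cv_ok & (ratio > ratio_min) & (t_p < alpha)

    out = pd.DataFrame(
        {
            "unit_id": expr.index[flag],
            "marker_class": "stable-difference",
            "direction": np.where(mean_g[flag] > mean_s[flag], "gregarious", "solitary"),
            "cv_G": cv_g[flag].values,
            "cv_S": cv_s[flag].values,
            "mean_ratio": ratio[flag].values,
            "t_p": t_p[flag].values,
        }
    )
    return out.reset_index(drop=True)


def screen_markers(
    presence: pd.DataFrame,
    expr: pd.DataFrame,
    cv_max: float = 0.3,
    ratio_min: float = 1.5,
    alpha: float = 0.05,
    cv_mode: str = "both",
) -> pd.DataFrame:
    """Run both screens and concatenate the calls.

    Units flagged by both screens (possible on noisy data) are kept with
    both rows and marked in an ``overlap`` column rather than dropped.
    """
    spec = specific_markers(presence)
    stab = stable_markers(expr, cv_max, ratio_min, alpha, cv_mode)
    out = pd.concat([spec, stab], ignore_index=True)
    if len(out):
        dup = out["unit_id"].duplicated(keep=False)
        out["overlap"] = dup
        if dup.any():
            log.info("marker screens overlap on %d units", out.loc[dup, "unit_id"].nunique())
    return out


def write_marker_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.10g")
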
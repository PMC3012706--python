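"""Synthetic data with known ground truth for the whole pipeline.

Emulates the 2-phase x 6-stage locust design: 12 libraries (gregarious and
solitary at egg, 1st+2nd, 3rd, 4th, 5th instar and adult), with the two
4th-instar libraries (G4, S4) deeply sequenced across many lanes.  The
generator plants, per counting unit:

* negative-binomial counts (variance mu + phi*mu^2; phi = 0 is Poisson)
  around mean = baseline x stage factor x phase fold x library scaling;
* a phase effect on a fraction of units whose fold grows with stage;
* phase-specific markers (zero mean in the off phase) and stable-ratio
  markers (stage-flat, constant fold between phases);
* composition bias: a few very-high-abundance units in one phase, the
  canonical stressor for TMM normalization;
* isoform/paralog clusters whose match records reconstruct exactly under
  the expression clustering preset, plus sub-threshold decoy matches;
* simulated alignments with controllable intra-cluster multireads and
  cross-cluster noise hits;
* term annotations with one planted enriched term among the DE units.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ClusterMap, ConsistencyError, TranscriptCatalog
from .markers import STAGES
from .readcount import ALN_COLUMNS, CountTable
from .seqcluster import MatchRecord


@dataclass(frozen=True)
class Library:
    library_id: str
    phase: str              # "G" or "S"
    stage: str              # one of STAGES
    depth: float = 1.0      # sequencing depth multiplier
    n_lanes: int = 1

    def __post_init__(self) -> None:
        if self.phase not in ("G", "S"):
            raise ValueError("phase must be 'G' or 'S'")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.depth <= 0 or self.n_lanes < 1:
            raise ValueError("depth must be positive and n_lanes >= 1")


def default_design(deep_depth: float = 20.0, deep_lanes: int = 20) -> tuple[Library, ...]:
    """The 12-library design; G4/S4 (4th instar) deep, one lane elsewhere."""
    libs = []
    for phase in ("G", "S"):
        for stage in STAGES:
            if stage == "instar4":
                libs.append(Library(f"{phase}4", phase, stage, deep_depth, deep_lanes))
            else:
                libs.append(Library(f"{phase}_{stage}", phase, stage, 1.0, 1))
    return tuple(libs)


@dataclass(frozen=True)
class EffectSpec:
    """Planted effects.  All folds are ratios > 1 applied multiplicatively
    upward in the favored phase."""

    de_fraction: float = 0.10
    fold_by_stage: tuple = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    stage_sigma: float = 0.6            # log-normal sd of shared stage modulation
    abundance_sigma: float = 1.0        # log-normal sd of baseline abundance
    base_mean_per_kb: float = 10.0      # expected reads/kb at depth 1
    min_mean: float = 3.0               # floor on baseline mean count (depth 1)
    n_specific_markers: int = 32
    specific_marker_min_mean: float = 10.0
    n_stable_markers: int = 8
    stable_marker_fold: float = 2.5
    stable_marker_min_mean: float = 100.0
    n_composition_bias: int = 50
    composition_fold: float = 8.0
    library_scaling_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if any(f <= 1 for f in self.fold_by_stage):
            raise ValueError("planted folds must exceed 1")
        if self.stable_marker_fold <= 1 or self.composition_fold <= 1:
            raise ValueError("planted folds must exceed 1")
        for name in ("stage_sigma", "abundance_sigma", "library_scaling_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


NULL_EFFECTS = EffectSpec(
    de_fraction=0.0, n_specific_markers=0, n_stable_markers=0,
    n_composition_bias=0, library_scaling_sigma=0.0,
)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    de_status: pd.DataFrame            # unit_id, stage, fold, up_phase
    marker_status: pd.Series           # unit -> none|specific-G|specific-S|stable-G|stable-S
    enriched_terms: dict[str, float] = field(default_factory=dict)
    true_cluster: pd.Series = None     # type: ignore[assignment]
    true_library_scaling: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.de_status) and (self.de_status["fold"] <= 1).any():
            raise ValueError("planted folds must exceed 1")
        if self.true_library_scaling is not None and (self.true_library_scaling <= 0).any():
            raise ValueError("library scaling factors must be positive")
        if not self.marker_status.index.is_unique:
            raise ValueError("each unit appears exactly once in marker_status")

    @property
    def de_units(self) -> set[str]:
        return set(self.de_status["unit_id"].unique())

    @property
    def marker_units(self) -> set[str]:
        return set(self.marker_status.index[self.marker_status != "none"])

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.de_status.to_csv(outdir / "truth_de.tsv", sep="\t", index=False, float_format="%.10g")
        self.marker_status.rename("marker_status").rename_axis("unit_id").to_csv(
            outdir / "truth_markers.tsv", sep="\t"
        )
        pd.Series(self.enriched_terms, dtype=float).rename("factor").rename_axis("term_id").to_csv(
            outdir / "truth_terms.tsv", sep="\t"
        )
        if self.true_cluster is not None:
            self.true_cluster.rename("cluster_id").rename_axis("transcript_id").to_csv(
                outdir / "truth_clusters.tsv", sep="\t"
            )
        if self.true_library_scaling is not None:
            self.true_library_scaling.rename("scaling").rename_axis("library").to_csv(
                outdir / "truth_scaling.tsv", sep="\t", float_format="%.10g"
            )


# ---- samplers ------------------------------------------------------------

def _sampler(spec, integer: bool = False):
    """Turn a distribution spec into rng -> array function.

    Accepts an int/float (constant), a tuple ("uniform_int", lo, hi),
    ("lognormal", median, sigma_log), or a callable(rng, size).
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        if spec <= 0:
            raise ValueError("constant sampler value must be positive")
        return lambda rng, size: np.full(size, spec)
    kind = spec[0]
    if kind == "uniform_int":
        _, lo, hi = spec
        if lo <= 0 or hi < lo:
            raise ValueError("uniform_int bounds must satisfy 0 < lo <= hi")
        return lambda rng, size: rng.integers(lo, hi + 1, size=size)
    if kind == "lognormal":
        _, median, sigma = spec
        if median <= 0 or sigma < 0:
            raise ValueError("lognormal needs positive median and sigma >= 0")
        return lambda rng, size: np.exp(rng.normal(np.log(median), sigma, size=size))
    raise ValueError(f"unknown sampler spec {spec!r}")


# ---- catalog / clusters --------------------------------------------------

def make_catalog(
    n_singletons: int,
    n_clusters: int,
    cluster_size_sampler=("uniform_int", 2, 4),
    length_sampler=("lognormal", 1000, 0.7),
    seed: int = 0,
    with_sequences: bool = False,
    n_decoy_matches: int | None = None,
) -> tuple[TranscriptCatalog, ClusterMap, list[MatchRecord]]:
    """Catalog with planted similarity clusters and their match records.

    Cluster members are chained by matches with overlap ratio in
    (0.85, 0.99) of the shorter member and identity in (0.965, 0.995), so
    the expression preset (>0.80, >0.96) reconstructs the emitted cluster
    map exactly.  Decoy matches between different clusters carry identity
    <= 0.95 and never create edges.  Lengths are clipped to >= 100 bp.
    """
    if n_singletons < 0 or n_clusters < 0:
        raise ValueError("counts must be non-negative")
    if n_singletons + n_clusters == 0:
        raise ValueError("catalog would be empty")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    size_fn = _sampler(cluster_size_sampler, integer=True)
    len_fn = _sampler(length_sampler)

    cluster_sizes = np.maximum(2, np.asarray(size_fn(rng, n_clusters), dtype=int))
    n_total = n_singletons + int(cluster_sizes.sum())
    lengths = np.maximum(100, np.asarray(len_fn(rng, n_total), dtype=float)).astype(int)
    ids = [f"T{i + 1:05d}" for i in range(n_total)]

    assignments: dict[str, str] = {}
    matches: list[MatchRecord] = []
    pos = 0
    for t in ids[:n_singletons]:
        assignments[t] = t
    pos = n_singletons
    cluster_members: list[list[str]] = []
    for size in cluster_sizes:
        members = ids[pos : pos + size]
        member_lengths = {t: int(lengths[pos + k]) for k, t in enumerate(members)}
        pos += size
        cluster_members.append(members)
        rep = max(members, key=lambda t: (member_lengths[t], tuple(-ord(ch) for ch in t)))
        for t in members:
            assignments[t] = rep
        for a, b in zip(members, members[1:]):
            short = min(member_lengths[a], member_lengths[b])
            overlap = int(short * rng.uniform(0.85, 0.99))
            identity = float(rng.uniform(0.965, 0.995))
            matches.append(MatchRecord(a, b, overlap, identity))

    catalog = TranscriptCatalog(lengths=pd.Series(lengths, index=ids))
    if n_decoy_matches is None:
        n_decoy_matches = n_total // 5
    for _ in range(n_decoy_matches):
        i, j = rng.integers(0, n_total, size=2)
        a, b = ids[i], ids[j]
        if a == b or assignments[a] == assignments[b]:
            continue
        short = int(min(lengths[i], lengths[j]))
        matches.append(
            MatchRecord(a, b, int(short * rng.uniform(0.2, 0.9)), float(rng.uniform(0.5, 0.95)))
        )

    reps = sorted(set(assignments.values()))
    clusters = ClusterMap(
        assignments=pd.Series(assignments).reindex(catalog.ids),
        representatives=pd.Series(reps, index=reps),
    )
    if with_sequences:
        alphabet = np.array(list("ACGT"))
        catalog.sequences = {
            t: "".join(alphabet[rng.integers(0, 4, size=catalog.lengths[t])]) for t in catalog.ids
        }
    return catalog, clusters, matches


# ---- counts --------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_counts(
    catalog: TranscriptCatalog,
    design,
    effects: EffectSpec | None = None,
    dispersion: float = 0.05,
    seed: int = 0,
    clusters: ClusterMap | None = None,
) -> tuple[CountTable, SimTruth]:
    """Negative-binomial counts per counting unit per library, plus truth.

    mean(u, lib) = baseline_u * stage_factor(u, stage) * phase_fold(u, lib)
                   * scaling_lib * depth_lib; the recorded per-library size
    equals the column sum (all simulated reads are accounted for).
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    design = tuple(design)
    if len(design) < 2:
        raise ValueError("design needs at least two libraries")
    if effects is None:
        effects = EffectSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    if clusters is None:
        clusters = ClusterMap.singletons(catalog.ids)
    clusters.check_partition(catalog)
    units = clusters.units.sort_values()
    n = len(units)
    unit_len_kb = catalog.lengths.reindex(clusters.representatives.reindex(units)).to_numpy() / 1e3

    n_special = effects.n_specific_markers + effects.n_stable_markers + effects.n_composition_bias
    n_de = int(round(effects.de_fraction * n))
    if n_special + n_de > n:
        raise ValueError("more planted units requested than units available")
    order = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = order[cursor : cursor + k]
        cursor += k
        return out

    spec_idx = take(effects.n_specific_markers)
    stab_idx = take(effects.n_stable_markers)
    comp_idx = take(effects.n_composition_bias)
    de_idx = take(n_de)

    baseline = np.maximum(
        effects.min_mean,
        np.exp(rng.normal(np.log(effects.base_mean_per_kb), effects.abundance_sigma, size=n))
        * unit_len_kb,
    )
    baseline[spec_idx] = np.maximum(baseline[spec_idx], effects.specific_marker_min_mean)
    baseline[stab_idx] = np.maximum(baseline[stab_idx], effects.stable_marker_min_mean)

    stage_factor = np.exp(rng.normal(0.0, effects.stage_sigma, size=(n, len(STAGES))))
    stage_factor[stab_idx, :] = 1.0  # stable markers are stage-flat by definition

    # phase multipliers: up_phase gets the fold, the other phase stays at 1
    up_phase = np.full(n, "", dtype=object)
    half = len(spec_idx) // 2
    up_phase[spec_idx[:half]] = "G"
    up_phase[spec_idx[half:]] = "S"
    up_phase[stab_idx[: len(stab_idx) // 2]] = "G"
    up_phase[stab_idx[len(stab_idx) // 2 :]] = "S"
    up_phase[comp_idx] = "G"  # composition bias concentrated in one phase
    up_phase[de_idx] = np.where(rng.random(len(de_idx)) < 0.5, "G", "S")

    fold_by_stage = dict(zip(STAGES, effects.fold_by_stage))
    marker_status = pd.Series("none", index=units, dtype=object)
    marker_status.iloc[spec_idx[:half]] = "specific-G"
    marker_status.iloc[spec_idx[half:]] = "specific-S"
    marker_status.iloc[stab_idx[: len(stab_idx) // 2]] = "stable-G"
    marker_status.iloc[stab_idx[len(stab_idx) // 2 :]] = "stable-S"

    scaling = np.exp(rng.normal(0.0, effects.library_scaling_sigma, size=len(design)))
    lib_ids = [lib.library_id for lib in design]

    mu = np.zeros((n, len(design)))
    for j, lib in enumerate(design):
        s = STAGES.index(lib.stage)
        m = baseline * stage_factor[:, s]
        # growing phase effect for DE units
        fold = np.ones(n)
        fold[de_idx] = np.where(
            up_phase[de_idx] == lib.phase, fold_by_stage[lib.stage], 1.0
        )
        fold[comp_idx] = np.where(
            up_phase[comp_idx] == lib.phase, effects.composition_fold, 1.0
        )
        fold[stab_idx] = np.where(
            up_phase[stab_idx] == lib.phase, effects.stable_marker_fold, 1.0
        )
        m = m * fold
        # specific markers: silent in the off phase
        off = spec_idx[up_phase[spec_idx] != lib.phase]
        m[off] = 0.0
        mu[:, j] = m * scaling[j] * lib.depth

    counts = _nb_draw(rng, mu, dispersion)
    table = pd.DataFrame(counts, index=units, columns=lib_ids)
    count_table = CountTable(table, totals=table.sum(axis=0))

    de_rows = []
    comp_set = set(comp_idx.tolist())
    for i in np.concatenate([de_idx, comp_idx]).astype(int):
        unit = units[i]
        for stage in STAGES:
            fold = effects.composition_fold if i in comp_set else fold_by_stage[stage]
            de_rows.append(
                {"unit_id": unit, "stage": stage, "fold": fold, "up_phase": up_phase[i]}
            )
    truth = SimTruth(
        de_status=pd.DataFrame(de_rows, columns=["unit_id", "stage", "fold", "up_phase"]),
        marker_status=marker_status,
        true_cluster=clusters.assignments.copy(),
        true_library_scaling=pd.Series(scaling * [lib.depth for lib in design], index=lib_ids),
    )
    return count_table, truth


def simulate_pair(
    n_units: int = 5000,
    de_fraction: float = 0.0,
    fold: float = 4.0,
    depth: float = 1.0,
    dispersion: float = 0.0,
    base_mean_per_kb: float = 10.0,
    seed: int = 0,
) -> tuple[CountTable, SimTruth, TranscriptCatalog]:
    """Two-library comparison with an optional planted constant fold.

    Convenience wrapper for null (Poisson, no DE) and power studies; the
    two libraries share one stage so the stage factor cancels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    lengths = np.maximum(100, np.exp(rng.normal(np.log(1000), 0.7, size=n_units))).astype(int)
    catalog = TranscriptCatalog(pd.Series(lengths, index=[f"T{i + 1:05d}" for i in range(n_units)]))
    design = (
        Library("A", "G", "instar4", depth, 1),
        Library("B", "S", "instar4", depth, 1),
    )
    effects = EffectSpec(
        de_fraction=de_fraction,
        fold_by_stage=tuple(fold for _ in STAGES),
        stage_sigma=0.0,
        base_mean_per_kb=base_mean_per_kb,
        n_specific_markers=0,
        n_stable_markers=0,
        n_composition_bias=0,
        library_scaling_sigma=0.0,
    )
    counts, truth = simulate_counts(catalog, design, effects, dispersion, seed=seed)
    return counts, truth, catalog


# ---- alignments ----------------------------------------------------------

def simulate_alignments(
    catalog: TranscriptCatalog,
    counts: CountTable,
    clusters: ClusterMap | None = None,
    intra_cluster_multimap_rate: float = 0.0,
    cross_cluster_noise_rate: float = 0.0,
    seed: int = 0,
    design=None,
) -> pd.DataFrame:
    """One alignment record per simulated read.

    Each read originates from a member of its unit.  With probability
    ``intra_cluster_multimap_rate`` a read from a multi-member cluster
    additionally hits a second member of the same cluster; with
    probability ``cross_cluster_noise_rate`` it gains a spurious hit
    outside its unit (which makes the counting rule discard it).  At both
    rates zero, ``assign_reads`` reproduces the generating counts exactly.
    """
    for rate in (intra_cluster_multimap_rate, cross_cluster_noise_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
    if clusters is None:
        clusters = ClusterMap.singletons(catalog.ids)
    unknown = set(counts.units) - set(clusters.units)
    if unknown:
        raise ConsistencyError(f"counts reference unknown units: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    member_lists = {u: clusters.members(u) for u in counts.units}
    all_ids = list(catalog.ids)
    unit_of = clusters._unit_of
    lanes = {lib.library_id: lib.n_lanes for lib in design} if design else {}

    frames = []
    for lib in counts.libraries:
        col = counts.column(lib).to_numpy()
        n_reads = int(col.sum())
        if n_reads == 0:
            continue
        unit_idx = np.repeat(np.arange(len(counts.units)), col)
        unit_arr = counts.units.to_numpy()[unit_idx]
        sizes = np.array([len(member_lists[u]) for u in counts.units])[unit_idx]
        pick = (rng.random(n_reads) * sizes).astype(int)
        multi = (sizes >= 2) & (rng.random(n_reads) < intra_cluster_multimap_rate)
        second = (pick + 1 + (rng.random(n_reads) * (sizes - 1)).astype(int)) % np.maximum(sizes, 2)
        noise = rng.random(n_reads) < cross_cluster_noise_rate
        noise_pick = rng.integers(0, len(all_ids), size=n_reads)
        lane_pick = rng.integers(0, lanes.get(lib, 1), size=n_reads)

        hits_col = []
        for i in range(n_reads):
            members = member_lists[unit_arr[i]]
            hits = [members[pick[i]]]
            if multi[i]:
                hits.append(members[second[i]])
            if noise[i]:
                t = all_ids[noise_pick[i]]
                if unit_of[t] == unit_arr[i]:
                    t = all_ids[(noise_pick[i] + 1) % len(all_ids)]
                    if unit_of[t] == unit_arr[i]:  # tiny catalogs: walk further
                        for t2 in all_ids:
                            if unit_of[t2] != unit_arr[i]:
                                t = t2
                                break
                if t not in hits:
                    hits.append(t)
            hits_col.append(tuple(hits))
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{lib}:r{i + 1:07d}" for i in range(n_reads)],
                    "library": lib,
                    "lane": [f"L{k + 1}" for k in lane_pick],
                    "hits": hits_col,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=ALN_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---- annotations ---------------------------------------------------------

def simulate_annotation(
    truth: SimTruth,
    n_terms: int = 50,
    term_size_sampler=("uniform_int", 20, 80),
    planted_factor: float = 4.0,
    planted_term: str = "TERM0001",
    seed: int = 0,
) -> pd.DataFrame:
    """Random term assignments with one term enriched among DE units.

    Background terms are assigned independently of DE status; the planted
    term's membership probability is multiplied by ``planted_factor`` for
    units carrying a planted phase effect.  ``planted_factor = 1`` is the
    null configuration.  Updates ``truth.enriched_terms`` in place.
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    if planted_factor < 1:
        raise ValueError("enrichment factor must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    genes = np.asarray(truth.marker_status.index)
    n_genes = len(genes)
    de_mask = np.isin(genes, sorted(truth.de_units))
    size_fn = _sampler(term_size_sampler)

    rows = []
    for j in range(n_terms):
        term = f"TERM{j + 1:04d}"
        target = float(np.asarray(size_fn(rng, 1))[0])
        p = min(1.0, target / n_genes)
        prob = np.full(n_genes, p)
        if term == planted_term:
            prob = np.where(de_mask, np.minimum(1.0, planted_factor * p), p)
        members = genes[rng.random(n_genes) < prob]
        rows.extend((g, term) for g in members)
    truth.enriched_terms = {planted_term: planted_factor}
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


# ---- evaluation helpers --------------------------------------------------

def precision_recall(called: set, truth: set) -> tuple[float, float]:
    """Set-level precision and recall (empty call set gives precision 1)."""
    called, truth = set(called), set(truth)
    tp = len(called & truth)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall
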
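"""The ground-truthed generator: determinism, conservation, round trips."""

import numpy as np
import pandas as pd
import pytest

from locustexpr import seqcluster
from locustexpr.catalog import ConsistencyError
from locustexpr.readcount import assign_reads
from locustexpr.simdata import (
    NULL_EFFECTS,
    EffectSpec,
    Library,
    default_design,
    make_catalog,
    precision_recall,
    simulate_alignments,
    simulate_annotation,
    simulate_counts,
    simulate_pair,
)


SMALL_EFFECTS = EffectSpec(
    de_fraction=0.1, n_specific_markers=4, n_stable_markers=2, n_composition_bias=2
)


def test_no_clusters_requested_gives_singletons():
    cat, cm, matches = make_catalog(3, 0, seed=1)
    assert len(cat) == 3 and cm.n_units == 3 and matches == []


def test_forced_cluster_is_connected():
    cat, cm, matches = make_catalog(0, 1, cluster_size_sampler=3, seed=7, n_decoy_matches=0)
    assert len(cat) == 3 and cm.n_units == 1
    assert len(matches) >= 2
    rebuilt = seqcluster.build_clusters(matches, cat)
    assert rebuilt.n_units == 1


def test_catalog_determinism():
    a = make_catalog(10, 3, seed=42)
    b = make_catalog(10, 3, seed=42)
    pd.testing.assert_series_equal(a[0].lengths, b[0].lengths)
    pd.testing.assert_series_equal(a[1].assignments, b[1].assignments)
    assert a[2] == b[2]


def test_match_records_reconstruct_cluster_map():
    cat, cm, matches = make_catalog(50, 20, seed=3)
    rebuilt = seqcluster.build_clusters(matches, cat)
    pd.testing.assert_series_equal(
        rebuilt.assignments.sort_index(), cm.assignments.sort_index()
    )
    assert (cat.lengths >= 100).all()


def test_invalid_parameters_raise():
    with pytest.raises(ValueError):
        make_catalog(-1, 0)
    with pytest.raises(ValueError):
        make_catalog(5, 1, cluster_size_sampler=-2)
    with pytest.raises(ValueError):
        EffectSpec(fold_by_stage=(0.5,) * 6)
    with pytest.raises(ValueError):
        Library("x", "G", "instar4", depth=-1)


def test_counts_conservation_and_determinism():
    cat, cm, _ = make_catalog(100, 10, seed=5)
    design = default_design(deep_depth=2.0, deep_lanes=2)
    c1, t1 = simulate_counts(cat, design, seed=9, clusters=cm)
    c2, t2 = simulate_counts(cat, design, seed=9, clusters=cm)
    pd.testing.assert_frame_equal(c1.counts, c2.counts)
    pd.testing.assert_series_equal(c1.totals, c1.counts.sum(axis=0))
    assert (t1.true_library_scaling > 0).all()
    assert (t1.de_status["fold"] > 1).all()


def test_null_configuration_means_match():
    # no planted effects, Poisson: the two phase libraries of one stage
    # differ only by sampling noise
    counts, truth, cat = simulate_pair(2000, de_fraction=0.0, dispersion=0.0, seed=1)
    a, b = counts.column("A"), counts.column("B")
    big = (a + b) > 50
    ratio = a[big].sum() / b[big].sum()
    assert ratio == pytest.approx(1.0, abs=0.05)
    assert truth.de_units == set()


def test_planted_two_fold_ratio_recovered():
    # pooled over many planted units, empirical mean ratio ~= configured fold
    counts, truth, _ = simulate_pair(4000, de_fraction=0.2, fold=2.0,
                                     dispersion=0.0, depth=5.0, seed=2)
    de = sorted(truth.de_units)
    up_g = set(truth.de_status.loc[truth.de_status["up_phase"] == "G", "unit_id"])
    a = counts.counts.loc[de, "A"].to_numpy(dtype=float)
    b = counts.counts.loc[de, "B"].to_numpy(dtype=float)
    hi = np.where([u in up_g for u in de], a, b)
    lo = np.where([u in up_g for u in de], b, a)
    assert hi.sum() / lo.sum() == pytest.approx(2.0, rel=0.05)


def test_empty_catalog_raises():
    with pytest.raises(ValueError):
        make_catalog(0, 0)


def test_zero_rate_alignment_round_trip():
    cat, cm, _ = make_catalog(60, 8, seed=4)
    design = default_design(deep_depth=2.0, deep_lanes=3)
    counts, _ = simulate_counts(cat, design, SMALL_EFFECTS, seed=4, clusters=cm)
    aln = simulate_alignments(cat, counts, cm, 0.0, 0.0, seed=4, design=design)
    back = assign_reads(aln, cm)
    pd.testing.assert_frame_equal(
        back.counts.reindex(index=counts.units, columns=counts.libraries), counts.counts
    )
    # conservation: one simulated read per count
    assert len(aln) == int(counts.counts.values.sum())


def test_full_intra_rate_doubles_hits_in_two_member_cluster():
    cat, cm, _ = make_catalog(0, 1, cluster_size_sampler=2, seed=8, n_decoy_matches=0)
    design = (Library("A", "G", "egg"), Library("B", "S", "egg"))
    counts, _ = simulate_counts(cat, design, EffectSpec(
        de_fraction=0, n_specific_markers=0, n_stable_markers=0,
        n_composition_bias=0), seed=8, clusters=cm)
    aln = simulate_alignments(cat, counts, cm, 1.0, 0.0, seed=8)
    assert (aln["hits"].map(len) == 2).all()
    units = {cm.unit_of(h) for hits in aln["hits"] for h in hits}
    assert len(units) == 1
    # intra-cluster multireads still count once for the cluster unit
    back = assign_reads(aln, cm)
    pd.testing.assert_frame_equal(
        back.counts.reindex(columns=counts.libraries), counts.counts
    )


def test_full_cross_noise_discards_everything():
    cat, cm, _ = make_catalog(30, 3, seed=6)
    design = (Library("A", "G", "egg"), Library("B", "S", "egg"))
    counts, _ = simulate_counts(cat, design, EffectSpec(
        de_fraction=0, n_specific_markers=0, n_stable_markers=0,
        n_composition_bias=0), seed=6, clusters=cm)
    aln = simulate_alignments(cat, counts, cm, 0.0, 1.0, seed=6)
    back = assign_reads(aln, cm)
    assert back.totals.sum() == 0
    assert back.discarded.sum() == len(aln) == int(counts.counts.values.sum())


def test_alignment_rates_validated():
    cat, cm, _ = make_catalog(5, 0, seed=1)
    design = (Library("A", "G", "egg"), Library("B", "S", "egg"))
    counts, _ = simulate_counts(cat, design, NULL_EFFECTS, seed=1, clusters=cm)
    with pytest.raises(ValueError):
        simulate_alignments(cat, counts, cm, 1.5, 0.0)


def test_annotation_integrity_and_null_factor():
    counts, truth, cat = simulate_pair(800, de_fraction=0.2, fold=2.0, seed=3)
    ann = simulate_annotation(truth, n_terms=30, planted_factor=1.0, seed=3)
    assert set(ann["gene_id"]) <= set(cat.ids)
    # factor 1: planted term's DE fraction matches background in expectation
    members = set(ann.loc[ann["term_id"] == "TERM0001", "gene_id"])
    de = truth.de_units
    frac_term = len(members & de) / max(len(members), 1)
    frac_bg = len(de) / len(cat.ids)
    assert frac_term == pytest.approx(frac_bg, abs=0.12)
    with pytest.raises(ValueError):
        simulate_annotation(truth, n_terms=5, planted_factor=0.5)


def test_alignment_determinism():
    cat, cm, _ = make_catalog(40, 5, seed=2)
    design = default_design(deep_depth=1.0, deep_lanes=2)
    counts, _ = simulate_counts(cat, design, SMALL_EFFECTS, seed=2, clusters=cm)
    a1 = simulate_alignments(cat, counts, cm, 0.3, 0.05, seed=2, design=design)
    a2 = simulate_alignments(cat, counts, cm, 0.3, 0.05, seed=2, design=design)
    pd.testing.assert_frame_equal(a1, a2)


def test_precision_recall_helper():
    assert precision_recall({"a", "b"}, {"a", "c"}) == (0.5, 0.5)
    assert precision_recall(set(), {"a"}) == (1.0, 0.0)
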
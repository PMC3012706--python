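"""End-to-end pipeline: simulate -> cluster -> count -> normalize ->
differential expression -> markers / enrichment / PCA / QC.

Stages run in dependency order, exchange plain TSV files inside one output
directory, and are checksum-guarded: re-running a stage whose inputs and
configuration are unchanged is a no-op.  A provenance line carrying the
configuration hash and seed heads every output file, and run.log records
the sizes, thresholds and discarded-record counts per stage.

Deep libraries are represented by one randomly selected lane for every
cross-library analysis (stage-series differential expression, markers,
PCA); the full-depth counts are used only for the dedicated deep-pair
comparison, which runs at its own stricter FDR cutoff.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    asmqc,
    diffexpr,
    enrich,
    markers,
    multivar,
    normexpr,
    readcount,
    seqcluster,
    simdata,
)
from .catalog import ClusterMap, TranscriptCatalog
from .markers import STAGES
from .readcount import CountTable

log = logging.getLogger("locustexpr.pipeline")


class StageDependencyError(RuntimeError):
    """A stage's upstream output is missing."""


@dataclass
class PipelineConfig:
    outdir: str = "locustexpr_out"
    seed: int = 1

    # synthetic-data block (used by the simulate stage)
    n_singletons: int = 1800
    n_clusters: int = 100
    deep_depth: float = 20.0
    deep_lanes: int = 20
    dispersion: float = 0.05
    intra_cluster_multimap_rate: float = 0.3
    cross_cluster_noise_rate: float = 0.01
    n_terms: int = 50
    planted_term_factor: float = 4.0

    # thresholds (defaults are the study's printed values)
    cluster_overlap: float = 0.80
    cluster_identity: float = 0.96
    fdr: float = 0.01
    fdr_deep: float = 1e-5
    fold_change: float = 2.0
    marker_cv_max: float = 0.3
    marker_ratio_min: float = 1.5
    marker_alpha: float = 0.05
    marker_cv_mode: str = "both"
    enrich_alpha: float = 0.01
    pca_min_libraries: int = 6
    reference_library: str = "S_egg"

    # external inputs (override the simulate stage)
    lengths_path: str | None = None
    matches_path: str | None = None
    alignments_path: str | None = None
    annotation_path: str | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("cluster_overlap", 0, 1), ("cluster_identity", 0, 1),
            ("fdr", 0, 1), ("fdr_deep", 0, 1), ("marker_cv_max", 0, 10),
            ("marker_alpha", 0, 1), ("enrich_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # a location, not a parameter
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _provenance_line(config: PipelineConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def _stamp(path: Path, config: PipelineConfig) -> None:
    """Prepend the provenance line to a text output file."""
    body = path.read_text()
    path.write_text(_provenance_line(config) + body)


class PipelineRunner:
    """Executes stages with checksum guards inside ``config.outdir``."""

    def __init__(self, config: PipelineConfig) -> None:
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(self.outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        self._handler = handler

    def close(self) -> None:
        log.removeHandler(self._handler)
        self._handler.close()

    # -- guard machinery --------------------------------------------

    def _guard(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        """True if the stage can be skipped (inputs and config unchanged)."""
        for p in inputs:
            if not p.exists():
                raise StageDependencyError(
                    f"stage '{stage}' needs {p.name}; run the producing stage first"
                )
        token = self.config.config_hash() + "".join(_file_hash(p) for p in inputs)
        marker = self.outdir / f".stage_{stage}.hash"
        if marker.exists() and marker.read_text() == token and all(o.exists() for o in outputs):
            log.info("stage %s: inputs unchanged, skipping", stage)
            return True
        marker_tmp = token
        self._pending = (marker, marker_tmp)
        return False

    def _done(self) -> None:
        marker, token = self._pending
        marker.write_text(token)

    # -- stages ------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        out = self.outdir
        outputs = [out / n for n in ("lengths.tsv", "matches.tsv", "alignments.tsv",
                                     "annotation.tsv", "truth_de.tsv")]
        if self._guard("simulate", [], outputs):
            return
        catalog, clusters, matches = simdata.make_catalog(
            cfg.n_singletons, cfg.n_clusters, seed=cfg.seed
        )
        design = simdata.default_design(cfg.deep_depth, cfg.deep_lanes)
        counts, truth = simdata.simulate_counts(
            catalog, design, dispersion=cfg.dispersion, seed=cfg.seed, clusters=clusters
        )
        alignments = simdata.simulate_alignments(
            catalog, counts, clusters,
            cfg.intra_cluster_multimap_rate, cfg.cross_cluster_noise_rate,
            seed=cfg.seed, design=design,
        )
        annotation = simdata.simulate_annotation(
            truth, cfg.n_terms, planted_factor=cfg.planted_term_factor, seed=cfg.seed
        )
        catalog.write_lengths(out / "lengths.tsv")
        seqcluster.write_match_tsv(matches, out / "matches.tsv")
        readcount.write_alignment_tsv(alignments, out / "alignments.tsv")
        enrich.write_annotation_tsv(annotation, out / "annotation.tsv")
        truth.write(out)
        for p in outputs[:4]:
            _stamp(p, cfg)
        log.info(
            "simulate: %d transcripts, %d units, %d matches, %d reads, %d terms",
            len(catalog), clusters.n_units, len(matches), len(alignments), cfg.n_terms,
        )
        self._done()

    def cluster(self) -> None:
        cfg = self.config
        out = self.outdir
        lengths = Path(cfg.lengths_path) if cfg.lengths_path else out / "lengths.tsv"
        matches = Path(cfg.matches_path) if cfg.matches_path else out / "matches.tsv"
        if self._guard("cluster", [lengths, matches], [out / "clusters.tsv"]):
            return
        catalog = TranscriptCatalog.read_lengths(lengths)
        records = seqcluster.read_match_tsv(matches)
        cmap = seqcluster.build_clusters(
            records, catalog, cfg.cluster_overlap, cfg.cluster_identity
        )
        cmap.write_tsv(out / "clusters.tsv")
        _stamp(out / "clusters.tsv", cfg)
        log.info(
            "cluster: %d transcripts -> %d units (overlap>%.2f identity>%.2f)",
            len(catalog), cmap.n_units, cfg.cluster_overlap, cfg.cluster_identity,
        )
        self._done()

    def count(self) -> None:
        cfg = self.config
        out = self.outdir
        aln_path = Path(cfg.alignments_path) if cfg.alignments_path else out / "alignments.tsv"
        outputs = [out / "counts.tsv", out / "counts_onelane.tsv", out / "lane_detection.tsv"]
        if self._guard("count", [aln_path, out / "clusters.tsv"], outputs):
            return
        alignments = readcount.read_alignment_tsv(aln_path)
        cmap = ClusterMap.read_tsv(out / "clusters.tsv")
        counts = readcount.assign_reads(alignments, cmap)
        counts.write_tsv(out / "counts.tsv")

        # deep libraries -> one randomly selected lane for cross-library work
        deep = [lib for lib in counts.libraries
                if alignments.loc[alignments["library"] == lib, "lane"].nunique() > 1]
        sub = alignments
        for lib in deep:
            sub = readcount.downsample_to_lane(sub, lib, seed=cfg.seed)
        counts_one = readcount.assign_reads(sub, cmap)
        counts_one.write_tsv(out / "counts_onelane.tsv")

        det = readcount.detection_by_lanes(alignments, cmap)
        det.rename_axis("unit_id").to_csv(out / "lane_detection.tsv", sep="\t")
        for p in outputs:
            _stamp(p, cfg)
        log.info(
            "count: %d reads, assigned %d, discarded %d; deep libraries %s down-sampled",
            len(alignments), int(counts.totals.sum()), int(counts.discarded.sum()), deep,
        )
        self._done()

    def normalize(self) -> None:
        cfg = self.config
        out = self.outdir
        outputs = [out / "norm.tsv", out / "rpkm.tsv"]
        if self._guard("normalize", [out / "counts_onelane.tsv", out / "clusters.tsv"], outputs):
            return
        counts = CountTable.read_tsv(out / "counts_onelane.tsv")
        cmap = ClusterMap.read_tsv(out / "clusters.tsv")
        lengths = TranscriptCatalog.read_lengths(self._lengths_path()).lengths
        unit_lengths = lengths.reindex(cmap.representatives.reindex(counts.units))
        unit_lengths.index = counts.units
        norm = normexpr.tmm_normalize(counts, cfg.reference_library)
        normexpr.write_norm_tsv(norm, out / "norm.tsv")
        rpkm = normexpr.rpkm_matrix(counts, unit_lengths, norm)
        rpkm.rename_axis("unit_id").to_csv(out / "rpkm.tsv", sep="\t", float_format="%.10g")
        for p in outputs:
            _stamp(p, cfg)
        log.info("normalize: TMM factors in [%.3f, %.3f], reference %s",
                 norm["f"].min(), norm["f"].max(), cfg.reference_library)
        self._done()

    def _lengths_path(self) -> Path:
        return (Path(self.config.lengths_path)
                if self.config.lengths_path else self.outdir / "lengths.tsv")

    def _unit_lengths(self, counts: CountTable, cmap: ClusterMap) -> pd.Series:
        lengths = TranscriptCatalog.read_lengths(self._lengths_path()).lengths
        unit_lengths = lengths.reindex(cmap.representatives.reindex(counts.units))
        unit_lengths.index = counts.units
        return unit_lengths

    def detest(self) -> None:
        cfg = self.config
        out = self.outdir
        inputs = [out / "counts.tsv", out / "counts_onelane.tsv",
                  out / "norm.tsv", out / "clusters.tsv"]
        outputs = [out / "dets_summary.tsv", out / "dets_deep.tsv"] + [
            out / f"dets_{stage}.tsv" for stage in STAGES
        ]
        if self._guard("detest", inputs, outputs):
            return
        counts_one = CountTable.read_tsv(out / "counts_onelane.tsv")
        counts_full = CountTable.read_tsv(out / "counts.tsv")
        cmap = ClusterMap.read_tsv(out / "clusters.tsv")
        norm = normexpr.read_norm_tsv(out / "norm.tsv")
        unit_lengths = self._unit_lengths(counts_one, cmap)
        design = simdata.default_design()
        by_stage = {lib.stage: {} for lib in design}
        for lib in design:
            by_stage[lib.stage][lib.phase] = lib.library_id

        n_min = float(counts_one.totals.min())
        summary = []
        for stage in STAGES:
            lib_g, lib_s = by_stage[stage]["G"], by_stage[stage]["S"]
            dets = diffexpr.call_dets(
                counts_one, lib_g, lib_s, unit_lengths, norm,
                fdr_cutoff=cfg.fdr, fc_cutoff=cfg.fold_change, n_min=n_min,
            )
            diffexpr.write_det_tsv(dets, out / f"dets_{stage}.tsv")
            n_up = int((dets["call"] == "up").sum())
            n_down = int((dets["call"] == "down").sum())
            summary.append({"stage": stage, "n_up": n_up, "n_down": n_down,
                            "n_det": n_up + n_down, "n_tested": len(dets)})
            log.info("detest %s: %d up, %d down of %d tested", stage, n_up, n_down, len(dets))

        # deep pair at full depth, stricter FDR
        deep_g, deep_s = by_stage["instar4"]["G"], by_stage["instar4"]["S"]
        norm_deep = normexpr.tmm_normalize(counts_full.subset([deep_g, deep_s]), deep_s)
        dets_deep = diffexpr.call_dets(
            counts_full, deep_g, deep_s, self._unit_lengths(counts_full, cmap), norm_deep,
            fdr_cutoff=cfg.fdr_deep, fc_cutoff=cfg.fold_change,
        )
        diffexpr.write_det_tsv(dets_deep, out / "dets_deep.tsv")
        log.info("detest deep pair: %d up, %d down (FDR<%g)",
                 int((dets_deep["call"] == "up").sum()),
                 int((dets_deep["call"] == "down").sum()), cfg.fdr_deep)
        pd.DataFrame(summary).to_csv(out / "dets_summary.tsv", sep="\t", index=False)
        for p in outputs:
            _stamp(p, cfg)
        self._done()

    def markers_stage(self) -> None:
        cfg = self.config
        out = self.outdir
        inputs = [out / "counts_onelane.tsv", out / "rpkm.tsv"]
        if self._guard("markers", inputs, [out / "markers.tsv"]):
            return
        counts = CountTable.read_tsv(out / "counts_onelane.tsv")
        rpkm = pd.read_csv(out / "rpkm.tsv", sep="\t", index_col="unit_id", comment="#")
        design = simdata.default_design()
        presence = markers.phase_stage_matrix((counts.counts >= 1), design)
        expr = markers.phase_stage_matrix(rpkm, design)
        calls = markers.screen_markers(
            presence, expr, cfg.marker_cv_max, cfg.marker_ratio_min,
            cfg.marker_alpha, cfg.marker_cv_mode,
        )
        markers.write_marker_tsv(calls, out / "markers.tsv")
        _stamp(out / "markers.tsv", cfg)
        log.info("markers: %d calls (%d specific, %d stable)", len(calls),
                 int((calls["marker_class"] == "phase-specific").sum()) if len(calls) else 0,
                 int((calls["marker_class"] == "stable-difference").sum()) if len(calls) else 0)
        self._done()

    def enrich_stage(self) -> None:
        cfg = self.config
        out = self.outdir
        ann_path = Path(cfg.annotation_path) if cfg.annotation_path else out / "annotation.tsv"
        inputs = [out / "dets_deep.tsv", ann_path, out / "counts.tsv"]
        outputs = [out / "enrich_up.tsv", out / "enrich_down.tsv"]
        if self._guard("enrich", inputs, outputs):
            return
        dets = diffexpr.read_det_tsv(out / "dets_deep.tsv")
        annotation = enrich.read_annotation_tsv(ann_path)
        background = CountTable.read_tsv(out / "counts.tsv").units
        for direction, path in (("up", outputs[0]), ("down", outputs[1])):
            gene_list = dets.index[dets["call"] == direction]
            rows = enrich.enrich_scan(gene_list, annotation, background, cfg.enrich_alpha)
            rows.to_csv(path, sep="\t", float_format="%.10g")
            n_sig = int(rows["significant"].sum()) if len(rows) else 0
            log.info("enrich %s: %d genes, %d/%d terms significant at p<%g",
                     direction, len(gene_list), n_sig, len(rows), cfg.enrich_alpha)
        for p in outputs:
            _stamp(p, cfg)
        self._done()

    def pca(self) -> None:
        cfg = self.config
        out = self.outdir
        inputs = [out / "rpkm.tsv", out / "counts_onelane.tsv"]
        outputs = [out / "pca_scores.tsv", out / "pca_loadings.tsv", out / "pca_scree.tsv"]
        if self._guard("pca", inputs, outputs):
            return
        rpkm = pd.read_csv(out / "rpkm.tsv", sep="\t", index_col="unit_id", comment="#")
        counts = CountTable.read_tsv(out / "counts_onelane.tsv")
        res = multivar.pca_libraries(rpkm, counts.counts >= 1, cfg.pca_min_libraries)
        res.scores.rename_axis("library").to_csv(outputs[0], sep="\t", float_format="%.10g")
        res.loadings.rename_axis("unit_id").to_csv(outputs[1], sep="\t", float_format="%.10g")
        res.scree().rename_axis("component").to_csv(outputs[2], sep="\t", float_format="%.10g")
        for p in outputs:
            _stamp(p, cfg)
        log.info("pca: %d transcripts retained, PC1 %.1f%%, PC2 %.1f%%",
                 res.n_retained, 100 * res.variance_fraction.iloc[0],
                 100 * res.variance_fraction.iloc[1])
        self._done()

    def asmqc_stage(self) -> None:
        cfg = self.config
        out = self.outdir
        if self._guard("asmqc", [self._lengths_path()], [out / "asmqc.tsv"]):
            return
        lengths = TranscriptCatalog.read_lengths(self._lengths_path()).lengths
        stats = asmqc.length_stats(lengths)
        stats.to_series().rename("value").rename_axis("metric").to_csv(
            out / "asmqc.tsv", sep="\t", float_format="%.10g"
        )
        _stamp(out / "asmqc.tsv", cfg)
        log.info("asmqc: %d sequences, N50 %d bp", stats.n_sequences, stats.n50)
        self._done()

    # -- orchestration ----------------------------------------------

    def run(self, with_simulation: bool = True) -> dict:
        if with_simulation:
            self.simulate()
        self.cluster()
        self.count()
        self.normalize()
        self.detest()
        self.markers_stage()
        self.enrich_stage()
        self.pca()
        self.asmqc_stage()
        summary = self._summary()
        with open(self.outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary

    def _summary(self) -> dict:
        out = self.outdir
        dets = pd.read_csv(out / "dets_summary.tsv", sep="\t", comment="#")
        scree = pd.read_csv(out / "pca_scree.tsv", sep="\t", comment="#")
        qc = pd.read_csv(out / "asmqc.tsv", sep="\t", comment="#")
        n_markers = max(
            0, sum(1 for line in open(out / "markers.tsv") if not line.startswith("#")) - 1
        )
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "dets_by_stage": dets.set_index("stage")["n_det"].to_dict(),
            "pc1_variance_fraction": float(scree["variance_fraction"].iloc[0]),
            "n_marker_calls": n_markers,
            "n50": int(qc.set_index("metric").loc["n50", "value"]),
        }


def run_pipeline(config: PipelineConfig, with_simulation: bool = True) -> dict:
    runner = PipelineRunner(config)
    try:
        return runner.run(with_simulation=with_simulation)
    finally:
        runner.close()
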
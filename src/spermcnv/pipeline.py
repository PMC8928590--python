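"""End-to-end orchestration: simulate -> filter -> segdup -> enrich ->
arms -> share -> annotate, with per-stage TSV outputs and a run manifest.

Stages write their tables atomically (temp file + rename) under
``out_dir/<stage>/``; the manifest (config snapshot, input checksums,
seeds, package version, per-stage row counts) is written last, so a
manifest on disk certifies a completed run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path
from typing import Callable

import pandas as pd

from . import __version__
from .annotate import annotate_features, fisher_enrichment, qtl_term_map, read_qtl_bed
from .config import PipelineConfig
from .enrichment import permutation_test, results_frame
from .genome import GenomeDef
from .positional import bin_arm_distribution, relative_positions, terminal_enrichment_test
from .regions import Region, flank_regions, merge_regions, per_chromosome_summary
from .repeats import RepeatIndex, read_repeat_table, repeat_content
from .segdup import read_pair_table, summarize_segdup_pairs, nonredundant_fragments
from .sharing import OverlapRule, cluster_events, clusters_frame, remove_singletons, venn_summary
from .simulate import (
    generate_callsets,
    generate_genome,
    generate_repeats,
    generate_segdup_pairs,
    write_simulation,
)
from .variants import (
    CNV_TYPES,
    filter_by_length,
    filter_by_support,
    parse_sv_vcf,
    read_coverage_table,
    tally_by_group,
    write_sv_vcf,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "segdup", "enrich", "arms", "share", "annotate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Mutable run context shared between stages."""

    def __init__(self, config: PipelineConfig, out_dir: str | Path | None = None,
                 seed: int | None = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.out_dir = Path(out_dir if out_dir is not None else config.out_dir)
        self.genome: GenomeDef | None = None
        self.repeats = None
        self.segdup_pairs = None
        self.raw_calls = None
        self.filtered_calls = None
        self.coverage = None
        self.cnv_regions: list[Region] | None = None
        self.clusters = None
        self.row_counts: dict[str, dict[str, int]] = {}
        self.input_checksums: dict[str, str] = {}

    def stage_dir(self, stage: str) -> Path:
        d = self.out_dir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    # -- stages ---------------------------------------------------------------

    def run_simulate(self) -> None:
        cfg = self.config.simulate
        if cfg is None:
            self._load_inputs()
            return
        cfg = dataclasses.replace(cfg, seed=self.seed)
        self.genome = generate_genome(cfg)
        self.repeats = generate_repeats(self.genome, cfg)
        self.segdup_pairs = generate_segdup_pairs(self.genome, cfg)
        sim = generate_callsets(self.genome, self.repeats, cfg)
        write_simulation(self.stage_dir("simulate"), cfg, self.genome,
                         self.repeats, self.segdup_pairs, sim)
        self.raw_calls = sim.all_calls()
        self.coverage = sim.coverage
        self.row_counts["simulate"] = {
            "events": len(sim.events), "calls": len(sim.calls),
            "repeats": len(self.repeats), "segdup_pairs": len(self.segdup_pairs),
        }

    def _load_inputs(self) -> None:
        inp = self.config.inputs
        if inp.chrom_sizes is None:
            raise FileNotFoundError("inputs.chrom_sizes is required without simulate")
        self.genome = GenomeDef.read_chrom_sizes(self._checked(inp.chrom_sizes))
        if inp.repeats:
            self.repeats = read_repeat_table(self._checked(inp.repeats))
        if inp.segdup_pairs:
            self.segdup_pairs = read_pair_table(self._checked(inp.segdup_pairs))
        if inp.coverage:
            self.coverage = read_coverage_table(self._checked(inp.coverage))
        calls = []
        for entry in inp.vcfs:
            calls.extend(
                parse_sv_vcf(self._checked(entry["path"]), entry["sample_id"],
                             entry["group"])
            )
        self.raw_calls = calls
        self.row_counts["simulate"] = {"calls": len(calls)}

    def _checked(self, p: str) -> Path:
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path}")
        self.input_checksums[str(path)] = _sha256(path)
        return path

    def run_filter(self) -> None:
        if self.raw_calls is None:
            raise RuntimeError("no calls loaded; run the simulate stage first")
        policy = self.config.filter
        kept = filter_by_support(
            filter_by_length(self.raw_calls, policy), self.coverage or {}, policy
        )
        self.filtered_calls = kept
        d = self.stage_dir("filter")
        write_sv_vcf(kept, self.genome, d / "filtered.vcf")
        tally = tally_by_group(kept, self.genome)
        _atomic_write(tally, d / "tally.tsv")
        cnvs = [c for c in kept if c.svtype in CNV_TYPES]
        self.cnv_regions = merge_regions(cnvs, genome=self.genome)
        self.row_counts["filter"] = {
            "input": len(self.raw_calls), "kept": len(kept),
            "cnv_regions": len(self.cnv_regions),
        }

    def run_segdup(self) -> None:
        if self.segdup_pairs is None:
            logger.info("no SegDup pair table; stage skipped")
            self.row_counts["segdup"] = {"pairs": 0}
            return
        d = self.stage_dir("segdup")
        summary = summarize_segdup_pairs(self.segdup_pairs)
        frags = nonredundant_fragments(self.segdup_pairs)
        regions = merge_regions(frags, genome=self.genome)
        _atomic_write(per_chromosome_summary(regions, self.genome),
                      d / "per_chromosome.tsv")
        pd.DataFrame([{
            "n_pairs": summary.n_pairs,
            **{f"pct_identity_gt{int(t * 100)}": v
               for t, v in summary.pct_identity_gt.items()},
            "pct_reversed": summary.pct_reversed,
            "pct_interchromosomal": summary.pct_interchromosomal,
            "n_unique_fragments": summary.n_unique_fragments,
            "n_merged_regions": len(regions),
        }]).to_csv(d / "pair_summary.tsv", sep="\t", index=False)
        self.row_counts["segdup"] = {
            "pairs": summary.n_pairs, "fragments": summary.n_unique_fragments,
            "merged_regions": len(regions),
        }

    def run_enrich(self) -> None:
        if not self.cnv_regions or self.repeats is None:
            logger.info("no CNV regions or repeat annotation; stage skipped")
            self.row_counts["enrich"] = {"targets": 0}
            return
        d = self.stage_dir("enrich")
        params = self.config.enrichment
        index = RepeatIndex(self.repeats)
        targets: dict[str, list[Region]] = {"cnv": self.cnv_regions}
        for size in params.flank_sizes:
            targets[f"{size // 1000}kbF"] = merge_regions(
                flank_regions(self.cnv_regions, size, self.genome),
                genome=self.genome,
            )
        frames = []
        for label, regs in targets.items():
            res = permutation_test(
                regs, index, self.genome, n_iter=params.n_iter,
                seed=self.seed, metrics=params.metrics, classes=params.classes,
            )
            frame = results_frame(res, seed=self.seed)
            frame.insert(0, "target", label)
            frames.append(frame)
        _atomic_write(pd.concat(frames, ignore_index=True), d / "enrichment.tsv")
        self.row_counts["enrich"] = {k: len(v) for k, v in targets.items()}

    def run_arms(self) -> None:
        if self.filtered_calls is None:
            raise RuntimeError("arms stage requires the filter stage")
        d = self.stage_dir("arms")
        params = self.config.positional
        profiles = []
        tests = []
        for svtype in ("all",) + CNV_TYPES:
            calls = (self.filtered_calls if svtype == "all"
                     else [c for c in self.filtered_calls if c.svtype == svtype])
            if calls:
                frac = relative_positions(calls, self.genome)
                profiles.append(
                    bin_arm_distribution(frac, params.bin_width, svtype=svtype).to_frame()
                )
            try:
                r = terminal_enrichment_test(
                    self.filtered_calls, self.genome,
                    terminal_frac=params.terminal_frac, window=params.window,
                    svtype=svtype,
                )
                tests.append({"svtype": svtype, "p_value": r.p_value,
                              "p_value_pooled": r.p_value_pooled,
                              "n_chromosomes": r.n_chromosomes})
            except ValueError as exc:
                logger.warning("terminal test (%s) skipped: %s", svtype, exc)
        _atomic_write(pd.concat(profiles, ignore_index=True), d / "arm_profile.tsv")
        _atomic_write(pd.DataFrame(tests), d / "terminal_test.tsv")
        self.row_counts["arms"] = {"profiles": len(profiles), "tests": len(tests)}

    def run_share(self) -> None:
        if self.filtered_calls is None:
            raise RuntimeError("share stage requires the filter stage")
        d = self.stage_dir("share")
        params = self.config.sharing
        rule = OverlapRule(params.min_overlap_bp, params.reciprocal)
        clusters = cluster_events(self.filtered_calls, rule)
        nonsingle = remove_singletons(clusters)
        self.clusters = nonsingle
        _atomic_write(clusters_frame(clusters), d / "clusters.tsv")
        venn = venn_summary(nonsingle)
        _atomic_write(venn, d / "venn.tsv")
        self.row_counts["share"] = {
            "clusters": len(clusters), "non_singletons": len(nonsingle),
        }

    def run_annotate(self) -> None:
        inp = self.config.inputs
        if self.clusters is None or not (inp.annotation or inp.qtl_bed):
            logger.info("no annotation inputs; stage skipped")
            self.row_counts["annotate"] = {"regions": 0}
            return
        d = self.stage_dir("annotate")
        regions = [cl.region for cl in self.clusters]
        counts: dict[str, int] = {"regions": len(regions)}
        if inp.annotation:
            hits = annotate_features(regions, self._checked(inp.annotation))
            _atomic_write(hits, d / "gene_overlap.tsv")
            counts["gene_hits"] = len(hits)
        if inp.qtl_bed:
            qtls = read_qtl_bed(self._checked(inp.qtl_bed))
            term_map = qtl_term_map(regions, qtls)
            universe = list(range(len(regions)))
            target = sorted({i for ids in term_map.values() for i in ids})
            if term_map:
                enr = fisher_enrichment(target, universe, term_map)
                _atomic_write(enr, d / "qtl_enrichment.tsv")
                counts["qtl_terms"] = len(enr)
        self.row_counts["annotate"] = counts

    # -- driver ---------------------------------------------------------------

    def run(self, stages: tuple[str, ...] = STAGES) -> Path:
        runners: dict[str, Callable[[], None]] = {
            "simulate": self.run_simulate,
            "filter": self.run_filter,
            "segdup": self.run_segdup,
            "enrich": self.run_enrich,
            "arms": self.run_arms,
            "share": self.run_share,
            "annotate": self.run_annotate,
        }
        for stage in stages:
            t0 = time.perf_counter()
            try:
                runners[stage]()
            except Exception as exc:
                raise StageError(stage, exc) from exc
            logger.info("stage %-9s done in %.2fs", stage, time.perf_counter() - t0)
        return self.write_manifest()

    def write_manifest(self) -> Path:
        manifest = {
            "tool": "spermcnv",
            "version": __version__,
            "seed": self.seed,
            "config": _config_snapshot(self.config),
            "input_checksums": self.input_checksums,
            "row_counts": self.row_counts,
        }
        path = self.out_dir / "manifest.json"
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
        return path


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return {
        f.name: enc(getattr(config, f.name))
        for f in dataclasses.fields(config)
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 seed: int | None = None,
                 stages: tuple[str, ...] = STAGES) -> PipelineRun:
    """Execute the stages in dependency order; manifest written last."""
    run = PipelineRun(config, out_dir=out_dir, seed=seed)
    run.run(stages)
    return run
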
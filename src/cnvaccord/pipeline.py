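"""End-to-end workflow: simulate/ingest -> (normalize/decode) -> per-cohort
association -> combined accordance -> CNV summary -> recombination context.

The pipeline is driven by a :class:`PipelineConfig`, seeds every source
of randomness from one master seed (a per-stage seed tree, so stages
can be rerun in isolation), logs a row-count funnel per stage, and
writes every intermediate table as TSV plus a key/value manifest that
suffices to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cnv import blocks_to_cnvs, call_raw_cnvs, summarize_raw_cnvs
from .hmm import decode_states, fit_hmm
from .models import (
    AccordanceResults,
    CohortAssociation,
    CohortAssociationResults,
    CrossCohortAccordance,
)
from .normalize import quantile_normalize
from .recomb import assign_groups, compare_recomb_groups, hotspot_overlap, recomb_levels
from .simulate import emit_intensities, make_recomb_map, make_snp_map, simulate_cohort
from .types import CNVRecord, HMMParams, RecombMap, RiskRegionSpec, SNPMap, StateMatrix

logger = logging.getLogger("cnvaccord")


@dataclass
class PipelineConfig:
    """All knobs of the combined analysis, with the default desk-scale
    study conditions (a 400/400 discovery cohort and a 160/170
    validation cohort over 2,000 SNPs)."""

    # synthetic inputs
    n_snps: int = 2000
    chrom_weights: dict | None = None
    mean_spacing: float = 10_000.0
    ref_cases: int = 400
    ref_controls: int = 400
    test_cases: int = 160
    test_controls: int = 170
    risk_regions: list[RiskRegionSpec] = field(default_factory=list)
    background_rate: float = 2.0
    n_hotspots: int = 30
    hot_rate: float = 10.0
    base_rate: float = 0.5

    # optional file inputs (override simulation when set)
    snp_map_path: str | None = None
    ref_states_path: str | None = None
    test_states_path: str | None = None
    genetic_map_paths: list[str] | None = None
    hotspot_bed_path: str | None = None

    # HMM stage (bypassed by default: association layers are state-based)
    use_hmm_path: bool = False
    n_training: int = 66
    emission_means: tuple = (-1.0, -0.5, 0.0, 0.5, 1.0)
    emission_sd: float = 0.08
    hmm_max_iter: int = 20

    # testing thresholds
    t_pm: int = 100
    candidate_fdr: float = 0.15
    window_fdr: float = 0.15
    half_width: int = 2
    max_gap: int = 30_000
    min_loci: int = 3
    fp_budget: float = 1.0
    rf_tail: str = "ge"
    recomb_window: int = 10_000
    recomb_n_perm: int = 1000

    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        for name, lo, hi in (
            ("candidate_fdr", 0, 1), ("window_fdr", 0, 1), ("background_rate", 0, np.inf),
            ("fp_budget", 0, np.inf), ("t_pm", 1, np.inf), ("half_width", 0, np.inf),
            ("min_loci", 1, np.inf),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi or (name in ("fp_budget",) and v == 0):
                raise ValueError(f"{name}={v} out of valid range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        regions = [RiskRegionSpec(**r) for r in raw.pop("risk_regions", [])]
        return cls(risk_regions=regions, **raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    snp_map: SNPMap
    recomb_map: RecombMap
    reference: StateMatrix
    testing: StateMatrix
    ref_results: CohortAssociationResults
    test_results: CohortAssociationResults
    accordance: AccordanceResults
    risk_loci: pd.DataFrame
    cnv_records: list[CNVRecord]
    singular_loci: pd.DataFrame
    raw_cnv_stats: pd.DataFrame
    recomb_summary: pd.DataFrame
    recomb_p: float
    hotspot_counts: dict
    manifest: dict


def _stage_seeds(master: int, n: int = 16) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; see the module docstring."""
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"master_seed": config.seed}

    # -- stage 1: inputs ----------------------------------------------------
    logger.info("stage=inputs")
    if config.snp_map_path:
        snp_map = cio.read_snp_map(config.snp_map_path)
    else:
        snp_map = make_snp_map(
            config.n_snps, config.chrom_weights, config.mean_spacing, seed=seeds[0]
        )
    if config.genetic_map_paths:
        recomb_map = cio.read_genetic_maps(config.genetic_map_paths, config.hotspot_bed_path)
    else:
        recomb_map = make_recomb_map(
            snp_map, config.n_hotspots, config.hot_rate, config.base_rate, seed=seeds[1]
        )
    if config.ref_states_path:
        reference = cio.read_state_matrix(config.ref_states_path, cohort_id="reference")
    else:
        reference = simulate_cohort(
            snp_map, config.ref_cases, config.ref_controls, config.risk_regions,
            config.background_rate, seed=seeds[2], cohort_id="reference",
        )
    if config.test_states_path:
        testing = cio.read_state_matrix(config.test_states_path, cohort_id="testing")
    else:
        testing = simulate_cohort(
            snp_map, config.test_cases, config.test_controls, config.risk_regions,
            config.background_rate, seed=seeds[3], cohort_id="testing",
        )
    manifest["n_snps"] = len(snp_map)
    manifest["reference_size"] = f"{reference.n_cases}/{reference.n_controls}"
    manifest["testing_size"] = f"{testing.n_cases}/{testing.n_controls}"

    # -- stage 2: optional intensity -> state decoding ----------------------
    if config.use_hmm_path:
        logger.info("stage=decode")
        training = simulate_cohort(
            snp_map, config.n_training // 2, config.n_training - config.n_training // 2,
            [], config.background_rate, seed=seeds[4], cohort_id="training",
        )
        raw = [
            emit_intensities(m, config.emission_means, config.emission_sd, seed=s)
            for m, s in ((training, seeds[5]), (reference, seeds[6]), (testing, seeds[7]))
        ]
        norm = quantile_normalize(raw)
        init = HMMParams.default(means=config.emission_means, sd=config.emission_sd)
        params = fit_hmm(norm[0], init, max_iter=config.hmm_max_iter, snp_map=snp_map)
        reference = decode_states(norm[1], params, snp_map, reference.labels, "reference")
        testing = decode_states(norm[2], params, snp_map, testing.labels, "testing")

    # -- stage 3: per-cohort association ------------------------------------
    logger.info("stage=associate")
    fit_kwargs = dict(
        t_pm=config.t_pm, candidate_fdr=config.candidate_fdr, window_fdr=config.window_fdr,
        half_width=config.half_width, max_gap=config.max_gap,
    )
    ref_results = CohortAssociation(reference, snp_map).fit(seed=seeds[8], **fit_kwargs)
    test_results = CohortAssociation(testing, snp_map).fit(seed=seeds[9], **fit_kwargs)
    manifest["reference_candidates"] = int(ref_results.sites["candidate"].sum())
    manifest["testing_candidates"] = int(test_results.sites["candidate"].sum())
    manifest["reference_window_passing"] = len(ref_results.window_passing)
    manifest["testing_window_passing"] = len(test_results.window_passing)
    logger.info(
        "candidates ref=%s test=%s window-passing ref=%s test=%s",
        manifest["reference_candidates"], manifest["testing_candidates"],
        manifest["reference_window_passing"], manifest["testing_window_passing"],
    )

    # -- stage 4: combined accordance ---------------------------------------
    logger.info("stage=combine")
    accordance = CrossCohortAccordance(reference, testing, snp_map).fit(
        t_pm=config.t_pm, tail=config.rf_tail,
        ref_perm_masks=ref_results.perm_masks, test_perm_masks=test_results.perm_masks,
    )
    risk_loci = accordance.select_risk_loci(ref_results, fp_budget=config.fp_budget)
    manifest["risk_loci"] = len(risk_loci)
    logger.info("risk loci=%s", len(risk_loci))

    # -- stage 5: CNV summary -----------------------------------------------
    logger.info("stage=summarize")
    stats_frames = []
    for cohort in (reference, testing):
        segs = call_raw_cnvs(cohort, snp_map)
        st = summarize_raw_cnvs(segs, cohort)
        st.insert(0, "cohort", cohort.cohort_id)
        stats_frames.append(st)
    raw_cnv_stats = pd.concat(stats_frames, ignore_index=True)
    records, singular = blocks_to_cnvs(
        risk_loci[["snp_id", "chrom", "pos", "best_hypothesis", "locus_type"]].reset_index(drop=True),
        max_gap=config.max_gap, min_loci=config.min_loci, dataset=reference.cohort_id,
        type_col="locus_type",
    )
    manifest["cnv_records"] = len(records)
    manifest["singular_risk_loci"] = len(singular)

    # -- stage 6: recombination context -------------------------------------
    logger.info("stage=recomb")
    sites = ref_results.sites
    groups = assign_groups(
        len(sites),
        np.flatnonzero(sites["candidate"].to_numpy()),
        np.flatnonzero(sites["passed"].to_numpy()),
        snp_map.index_of(risk_loci["snp_id"]) if len(risk_loci) else np.array([], dtype=np.int64),
    )
    levels = recomb_levels(sites, recomb_map, config.recomb_window)
    try:
        recomb_summary, recomb_p = compare_recomb_groups(
            levels, groups, n_perm=config.recomb_n_perm, seed=seeds[10]
        )
    except ValueError:
        logger.warning("recombination group comparison skipped (fewer than 2 groups)")
        recomb_summary, recomb_p = pd.DataFrame(
            columns=["group", "n", "sum_level", "mean_level"]
        ), float("nan")
    hotspot_counts = hotspot_overlap(records, recomb_map.hotspots)

    result = PipelineResult(
        config=config, snp_map=snp_map, recomb_map=recomb_map,
        reference=reference, testing=testing,
        ref_results=ref_results, test_results=test_results, accordance=accordance,
        risk_loci=risk_loci, cnv_records=records, singular_loci=singular,
        raw_cnv_stats=raw_cnv_stats, recomb_summary=recomb_summary, recomb_p=recomb_p,
        hotspot_counts=hotspot_counts, manifest=manifest,
    )
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir) -> list[Path]:
    """Write the result bundle as TSV/BED files plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    _tsv(result.risk_loci, "risk_loci.tsv")
    _tsv(cio.cnv_records_to_frame(result.cnv_records), "cnvs.tsv")
    cio.write_cnv_bed(result.cnv_records, out / "cnvs.bed")
    written.append(out / "cnvs.bed")
    _tsv(result.accordance.rf_table, "rf_sites.tsv")
    _tsv(result.raw_cnv_stats, "raw_cnv_stats.tsv")
    _tsv(result.recomb_summary, "recomb_groups.tsv")
    _tsv(result.ref_results.sites, "sites_reference.tsv")
    _tsv(result.test_results.sites, "sites_testing.tsv")
    _tsv(result.accordance.scatter_data(result.ref_results), "rf_scatter.tsv")

    manifest = dict(result.manifest)
    cfg = dataclasses.asdict(result.config)
    cfg["risk_regions"] = [dataclasses.asdict(r) for r in result.config.risk_regions]
    for k, v in cfg.items():
        manifest[f"config.{k}"] = v
    manifest["recomb_p"] = result.recomb_p
    manifest["hotspot_counts"] = result.hotspot_counts
    cio.write_manifest(manifest, out / "manifest.txt")
    written.append(out / "manifest.txt")
    return written
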
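"""Raw CNV calling, descriptive statistics and risk-locus summarization.

A *raw* CNV is a per-individual run of three or more consecutive SNPs
sharing one abnormal copy-number state (not 2), never crossing a
chromosome boundary; runs of mixed abnormal states are not merged.
Risk loci that survive all association stages are separately chained
into summarized CNV records when at least ``min_loci`` of them are
consecutive (neighboring-SNP distance <= 30 kb); a chain is typed
Amplification or Deletion only when every member locus votes that way,
otherwise Abnormal.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .types import NORMAL_STATE, CNVRecord, SNPMap, StateMatrix


def cnv_size_kb(start_pos: int, end_pos: int) -> float:
    """CNV size in kb: (end - start)/1000 rounded half-up to one decimal.

    Integer arithmetic avoids float half-way artefacts (30 395 bp must
    round to 30.4 kb, not 30.3).
    """
    if end_pos <= start_pos:
        raise ValueError("end_pos must exceed start_pos")
    diff = int(end_pos) - int(start_pos)
    return ((diff + 50) // 100) / 10.0


def call_raw_cnvs(states: StateMatrix, snp_map: SNPMap, min_snps: int = 3) -> pd.DataFrame:
    """All maximal >=3-SNP single-state abnormal runs, per individual.

    Returns a DataFrame with one row per segment: individual_id, label,
    chrom, first_snp_index, last_snp_index, start_pos, end_pos, state,
    n_snps, size_bp (end - start).
    """
    if states.n_snps != len(snp_map):
        raise ValueError("state matrix and SNP map disagree on the number of SNPs")
    pos = snp_map.positions
    chrom = snp_map.chroms
    rows = []
    # chromosome changes break runs: encode (chrom, state) jointly
    chrom_offset = chrom.astype(np.int64) * 10
    for i in range(states.n_individuals):
        s = states.states[i].astype(np.int64)
        code = chrom_offset + s
        boundaries = np.flatnonzero(np.diff(code)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [len(s)]))
        for a, b in zip(starts, stops):
            if s[a] == NORMAL_STATE or b - a < min_snps:
                continue
            rows.append(
                (
                    states.individual_ids[i],
                    states.labels[i],
                    int(chrom[a]),
                    int(a),
                    int(b - 1),
                    int(pos[a]),
                    int(pos[b - 1]),
                    int(s[a]),
                    int(b - a),
                    int(pos[b - 1] - pos[a]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "label",
            "chrom",
            "first_snp_index",
            "last_snp_index",
            "start_pos",
            "end_pos",
            "state",
            "n_snps",
            "size_bp",
        ],
    )


def summarize_raw_cnvs(segments: pd.DataFrame, states: StateMatrix) -> pd.DataFrame:
    """Descriptive raw-CNV statistics per cohort arm.

    One row per label (case/control): average CNVs per individual
    (zero-CNV individuals included in the denominator), SNPs per CNV
    (min/max/average) and CNV size in bp (min/max/average).
    """
    rows = []
    for label, n_ind in (("case", states.n_cases), ("control", states.n_controls)):
        sub = segments[segments["label"] == label] if len(segments) else segments
        if len(sub) == 0:
            warnings.warn(f"no raw CNVs in the {label} arm; reporting zeros", stacklevel=2)
            rows.append((label, 0.0, 0, 0, 0.0, 0, 0, 0.0))
            continue
        rows.append(
            (
                label,
                len(sub) / n_ind,
                int(sub["n_snps"].min()),
                int(sub["n_snps"].max()),
                float(sub["n_snps"].mean()),
                int(sub["size_bp"].min()),
                int(sub["size_bp"].max()),
                float(sub["size_bp"].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "cnvs_per_individual",
            "snps_per_cnv_min",
            "snps_per_cnv_max",
            "snps_per_cnv_avg",
            "size_bp_min",
            "size_bp_max",
            "size_bp_avg",
        ],
    )


_HYP_TO_TYPE = {"gain": "Amplification", "loss": "Deletion", "abnm": "Abnormal"}


def blocks_to_cnvs(
    risk_loci: pd.DataFrame,
    max_gap: int = 30_000,
    min_loci: int = 3,
    dataset: str = "cohort",
    type_col: str = "best_hypothesis",
) -> tuple[list[CNVRecord], pd.DataFrame]:
    """Chain consecutive risk loci into CNV records.

    ``risk_loci`` needs columns snp_id, chrom, pos and ``type_col`` and
    must be sorted by (chrom, pos). Maximal chains with successive gaps
    <= ``max_gap`` and >= ``min_loci`` members become
    :class:`~cnvaccord.types.CNVRecord` (all-gain -> Amplification,
    all-loss -> Deletion, mixed -> Abnormal); shorter chains are
    returned as the singular-risk-locus DataFrame.

    The pipeline passes the *directional* locus type (loss vs gain by
    the smaller Fisher p) in ``type_col``: the abnormal hypothesis nests
    the directional ones, so typing records by the raw three-way best
    hypothesis would flip clean deletions to Abnormal whenever sampling
    noise lets the nested test edge ahead at a single member site.
    """
    if len(risk_loci) == 0:
        return [], risk_loci.copy()
    chrom = risk_loci["chrom"].to_numpy()
    pos = risk_loci["pos"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(risk_loci))):
        raise ValueError("risk loci must be sorted by (chrom, pos)")

    new_chain = np.concatenate(
        ([True], (chrom[1:] != chrom[:-1]) | ((pos[1:] - pos[:-1]) > max_gap))
    )
    chain_id = np.cumsum(new_chain)
    records: list[CNVRecord] = []
    singular_idx: list[int] = []
    for _, idx in pd.Series(range(len(risk_loci))).groupby(chain_id):
        ii = idx.to_numpy()
        if len(ii) < min_loci:
            singular_idx.extend(ii.tolist())
            continue
        hyps = set(risk_loci[type_col].iloc[ii])
        if hyps == {"gain"}:
            cnv_type = "Amplification"
        elif hyps == {"loss"}:
            cnv_type = "Deletion"
        else:
            cnv_type = "Abnormal"
        records.append(
            CNVRecord(
                dataset=dataset,
                chrom=int(chrom[ii[0]]),
                start_pos=int(pos[ii[0]]),
                end_pos=int(pos[ii[-1]]),
                cnv_type=cnv_type,
                member_snp_ids=tuple(risk_loci["snp_id"].iloc[ii]),
            )
        )
    return records, risk_loci.iloc[singular_idx].copy()


def neighboring_genes(
    risk_loci: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    flank: int = 100_000,
) -> list[str]:
    """Unique gene names within +/- ``flank`` bp of any risk locus.

    ``gene_annotation`` needs columns chrom, start, end, name (1-based,
    closed intervals, sorted by chrom then start). A gene counts when
    its interval intersects [pos - flank, pos + flank], boundaries
    included. Returns a deduplicated, sorted list.
    """
    ann = gene_annotation
    if len(ann) == 0 or len(risk_loci) == 0:
        return []
    if not ann.sort_values(["chrom", "start"]).index.equals(ann.index):
        raise ValueError("gene annotation must be sorted by (chrom, start)")
    hits: set[str] = set()
    for chrom, sub in risk_loci.groupby("chrom"):
        genes = ann[ann["chrom"] == chrom]
        if len(genes) == 0:
            continue
        gs = genes["start"].to_numpy()
        ge = genes["end"].to_numpy()
        for pos in sub["pos"].to_numpy():
            overlap = (ge >= pos - flank) & (gs <= pos + flank)
            hits.update(genes["name"].to_numpy()[overlap])
    return sorted(hits)


def load_published_cnvs() -> pd.DataFrame:
    """The published table of 22 CNVs predicted in the EAGLE lung-cancer
    cohort (chrom, band, 1-based start/end, printed kb size, type),
    shipped with the package as a worked reference for the
    size-arithmetic and record-shape conventions."""
    with resources.files("cnvaccord.data").joinpath("eagle_predicted_cnvs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
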
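"""Recombination-rate context for risk loci and summarized CNVs.

Each SNP gets a recombination *level*: log10 of the maximum map rate
inside a 10 kb region centred on the SNP (rates floored at 1e-4 cM/Mb
so the log is finite). Levels are compared across the selection funnel
groups — not_sig, snp_based, window, window_Rf, each SNP labelled by
the furthest stage it passed — with a label-permutation p-value for the
window_Rf vs not_sig contrast. Summarized CNVs are intersected with
hotspot intervals under closed 1-based coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import CNVRecord, RecombMap

RATE_FLOOR = 1e-4
GROUPS = ("not_sig", "snp_based", "window", "window_Rf")


def recomb_level(pos: int, chrom: int, recomb_map: RecombMap, window: int = 10_000) -> float:
    """log10(max rate over map intervals intersecting pos +/- window/2).

    Returns NaN when no interval of the map touches the region (the
    caller excludes such sites from group sums).
    """
    half = window / 2.0
    iv = recomb_map.chrom_intervals(chrom)
    if len(iv) == 0:
        return float("nan")
    lo, hi = pos - half, pos + half
    hit = iv[(iv["end"] >= lo) & (iv["start"] <= hi)]
    if len(hit) == 0:
        return float("nan")
    return float(np.log10(max(hit["rate"].max(), RATE_FLOOR)))


def recomb_levels(loci: pd.DataFrame, recomb_map: RecombMap, window: int = 10_000) -> np.ndarray:
    """Vector of recombination levels for a (chrom, pos) locus table.

    Equivalent to calling :func:`recomb_level` per row, but slices the
    map once per chromosome.
    """
    half = window / 2.0
    out = np.full(len(loci), np.nan)
    chroms = loci["chrom"].to_numpy()
    positions = loci["pos"].to_numpy()
    for chrom in np.unique(chroms):
        iv = recomb_map.chrom_intervals(int(chrom))
        if len(iv) == 0:
            continue
        starts = iv["start"].to_numpy()
        ends = iv["end"].to_numpy()
        rates = iv["rate"].to_numpy()
        where = np.flatnonzero(chroms == chrom)
        for i in where:
            hit = (ends >= positions[i] - half) & (starts <= positions[i] + half)
            if hit.any():
                out[i] = np.log10(max(rates[hit].max(), RATE_FLOOR))
    return out


def assign_groups(
    n_sites: int,
    snp_based_idx: np.ndarray,
    window_idx: np.ndarray,
    window_rf_idx: np.ndarray,
) -> np.ndarray:
    """Hierarchical, exclusive funnel groups: each site is labelled by the
    most advanced selection stage it passed."""
    groups = np.array(["not_sig"] * n_sites, dtype=object)
    groups[np.asarray(snp_based_idx, dtype=np.int64)] = "snp_based"
    groups[np.asarray(window_idx, dtype=np.int64)] = "window"
    groups[np.asarray(window_rf_idx, dtype=np.int64)] = "window_Rf"
    return groups


def compare_recomb_groups(
    levels: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-group summed/mean levels and a permutation p-value.

    The p-value tests whether the mean level in the ``window_Rf`` group
    exceeds the ``not_sig`` mean, by shuffling the group labels between
    those two groups ``n_perm`` times (one-sided, add-one estimator).
    Groups with no finite level are dropped with a warning.
    """
    levels = np.asarray(levels, dtype=float)
    groups = np.asarray(groups, dtype=object)
    finite = np.isfinite(levels)
    rows = []
    present = []
    for g in GROUPS:
        m = (groups == g) & finite
        if m.sum() == 0:
            warnings.warn(f"recombination group '{g}' is empty; dropped", stacklevel=2)
            continue
        present.append(g)
        rows.append((g, int(m.sum()), float(levels[m].sum()), float(levels[m].mean())))
    summary = pd.DataFrame(rows, columns=["group", "n", "sum_level", "mean_level"])
    if len(present) < 2:
        raise ValueError("need at least two non-empty groups to compare")
    if "window_Rf" not in present or "not_sig" not in present:
        return summary, float("nan")

    a = levels[(groups == "window_Rf") & finite]
    b = levels[(groups == "not_sig") & finite]
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if pooled[: len(a)].mean() - pooled[len(a):].mean() >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return summary, float(p)


def hotspot_overlap(cnvs: list[CNVRecord], hotspots: pd.DataFrame) -> dict[str, tuple[int, int]]:
    """Per-CNV-type (overlapping, total) counts against hotspot intervals.

    A CNV overlaps when any hotspot interval intersects its closed
    1-based [start_pos, end_pos] span — a single shared bp counts.
    """
    out: dict[str, tuple[int, int]] = {}
    for rec in cnvs:
        hs = hotspots[hotspots["chrom"] == rec.chrom] if len(hotspots) else hotspots
        hit = False
        if len(hs):
            hit = bool(((hs["end"] >= rec.start_pos) & (hs["start"] <= rec.end_pos)).any())
        n_over, n_tot = out.get(rec.cnv_type, (0, 0))
        out[rec.cnv_type] = (n_over + int(hit), n_tot + 1)
    return out
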
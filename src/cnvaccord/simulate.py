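"""Synthetic two-cohort test bed with known embedded risk CNVs.

Emulates the structure of a pair of SNP-array case-control cohorts (a
larger discovery cohort and a smaller validation cohort): an ordered
autosomal SNP map, per-individual copy-number states with case-enriched
risk regions and sporadic background CNVs, Gaussian probe intensities,
and a piecewise-constant recombination map with hotspot intervals.
Everything is seeded and bit-reproducible so downstream stages can be
tested against ground truth.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    NORMAL_STATE,
    AUTOSOMES,
    IntensityMatrix,
    RecombMap,
    RiskRegionSpec,
    SNPMap,
    StateMatrix,
)

#: abnormal states a sporadic background CNV may take
_BACKGROUND_STATES = np.array([0, 1, 3, 4])


def _rng(seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def make_snp_map(
    n_snps: int,
    chrom_weights: Mapping[int, float] | None = None,
    mean_spacing: float = 10_000.0,
    seed: int | None = None,
    *,
    large_gap_frac: float | None = None,
    large_gap_min: int = 30_000,
    rng: np.random.Generator | None = None,
) -> SNPMap:
    """Draw an ordered autosomal SNP map.

    SNPs are allocated to chromosomes multinomially according to
    ``chrom_weights`` (default: uniform over chromosomes 1-22) and
    inter-SNP gaps are exponential with mean ``mean_spacing`` bp. When
    ``large_gap_frac`` is given, that fraction of gaps (rounded, chosen
    at random) is forced above ``large_gap_min`` so the 30 kb
    consecutiveness rule downstream has material to act on; otherwise
    large gaps arise only from the exponential tail.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if mean_spacing <= 0:
        raise ValueError("mean_spacing must be > 0")
    gen = _rng(seed, rng)
    if chrom_weights is None:
        chrom_weights = {c: 1.0 for c in AUTOSOMES}
    chroms = sorted(chrom_weights)
    if not set(chroms).issubset(AUTOSOMES):
        raise ValueError("chromosomes must be autosomes 1..22")
    w = np.array([chrom_weights[c] for c in chroms], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("chrom_weights must be non-negative with positive sum")
    counts = gen.multinomial(n_snps, w / w.sum())

    rows = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        gaps = gen.exponential(mean_spacing, size=k)
        if large_gap_frac is not None:
            n_large = int(round(large_gap_frac * k))
            if n_large:
                which = gen.choice(k, size=n_large, replace=False)
                gaps[which] = large_gap_min + gen.exponential(mean_spacing, size=n_large)
        steps = np.maximum(1, np.round(gaps).astype(np.int64))
        pos = np.cumsum(steps)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    table = pd.concat(rows, ignore_index=True)
    table["snp_id"] = [f"rs{i:07d}" for i in range(len(table))]
    return SNPMap(table[["snp_id", "chrom", "pos"]])


def _truncated_geometric(gen: np.random.Generator, mean: float, minimum: int, size: int) -> np.ndarray:
    """Geometric lengths (support >= 1, given mean) conditioned on >= minimum."""
    p = 1.0 / mean
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draw = gen.geometric(p, size=max(size - filled, 8))
        keep = draw[draw >= minimum]
        take = min(len(keep), size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_cohort(
    snp_map: SNPMap,
    n_cases: int,
    n_controls: int,
    risk_regions: Sequence[RiskRegionSpec] = (),
    background_rate: float = 2.0,
    seed: int | None = None,
    *,
    bg_mean_len: float = 5.0,
    bg_min_len: int = 3,
    cohort_id: str = "cohort",
    rng: np.random.Generator | None = None,
) -> StateMatrix:
    """Simulate a case-control cohort of copy-number states.

    The baseline is diploid (state 2) everywhere. Sporadic background
    CNVs — Poisson(``background_rate``) segments per individual, lengths
    geometric with mean ``bg_mean_len`` SNPs truncated at
    ``bg_min_len``, a uniform abnormal state — are laid down by an
    identical process in cases and controls. Risk regions are then
    stamped on top: each individual carries the whole region in a single
    state (3 for amplification, 1 for deletion) with the carrier
    frequency of its label.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("n_cases and n_controls must be >= 1")
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    n_snps = len(snp_map)
    for reg in risk_regions:
        if reg.start_snp_index < 0 or reg.end_snp_index >= n_snps:
            raise ValueError("risk region indices out of SNP map bounds")
    gen = _rng(seed, rng)
    n = n_cases + n_controls
    labels = np.array(["case"] * n_cases + ["control"] * n_controls, dtype=object)
    states = np.full((n, n_snps), NORMAL_STATE, dtype=np.int8)

    # chromosome block of every SNP index, for clipping background segments
    blocks = snp_map.chrom_blocks()
    block_stop = np.empty(n_snps, dtype=np.int64)
    for _, a, b in blocks:
        block_stop[a:b] = b

    if background_rate > 0:
        n_segs = gen.poisson(background_rate, size=n)
        total = int(n_segs.sum())
        if total:
            starts = gen.integers(0, n_snps, size=total)
            lengths = _truncated_geometric(gen, bg_mean_len, bg_min_len, total)
            seg_states = _BACKGROUND_STATES[gen.integers(0, 4, size=total)]
            owner = np.repeat(np.arange(n), n_segs)
            for ind, s, L, st in zip(owner, starts, lengths, seg_states):
                stop = min(s + L, block_stop[s])
                states[ind, s:stop] = st

    case = labels == "case"
    for reg in risk_regions:
        freq = np.where(case, reg.carrier_freq_cases, reg.carrier_freq_controls)
        carriers = gen.random(n) < freq
        states[carriers, reg.start_snp_index : reg.end_snp_index + 1] = reg.carrier_state

    return StateMatrix(states=states, labels=labels, cohort_id=cohort_id)


def emit_intensities(
    states: StateMatrix,
    emission_means: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
    emission_sd: float = 0.15,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> IntensityMatrix:
    """Draw Gaussian probe intensities around each entry's true state mean."""
    means = np.asarray(emission_means, dtype=float)
    if means.shape != (5,):
        raise ValueError("emission_means must have 5 entries (states 0..4)")
    if np.any(np.diff(means) <= 0):
        raise ValueError("emission_means must be strictly increasing")
    if emission_sd < 0:
        raise ValueError("emission_sd must be >= 0")
    gen = _rng(seed, rng)
    mu = means[states.states.astype(np.int64)]
    if emission_sd == 0:
        return IntensityMatrix(signal=mu)
    return IntensityMatrix(signal=mu + gen.normal(0.0, emission_sd, size=mu.shape))


def make_recomb_map(
    snp_map: SNPMap,
    n_hotspots: int,
    hot_rate: float = 10.0,
    base_rate: float = 0.5,
    seed: int | None = None,
    *,
    hotspot_width: int = 2_000,
    pad: int = 10_000,
    rng: np.random.Generator | None = None,
) -> RecombMap:
    """Build a step-function recombination map over the SNP map's span.

    Each chromosome covered by the map gets a background interval at
    ``base_rate`` (cM/Mb) spanning its SNPs plus ``pad`` bp on each
    side; ``n_hotspots`` short intervals of width ``hotspot_width`` at
    ``hot_rate`` are carved out at random non-overlapping positions and
    recorded in the hotspot list.
    """
    if n_hotspots < 0:
        raise ValueError("n_hotspots must be >= 0")
    if not hot_rate > base_rate >= 0:
        raise ValueError("require hot_rate > base_rate >= 0")
    gen = _rng(seed, rng)
    spans = []  # (chrom, lo, hi)
    for chrom, a, b in snp_map.chrom_blocks():
        pos = snp_map.positions[a:b]
        spans.append((chrom, max(1, int(pos[0]) - pad), int(pos[-1]) + pad))

    lengths = np.array([hi - lo + 1 for _, lo, hi in spans], dtype=float)
    alloc = gen.multinomial(n_hotspots, lengths / lengths.sum()) if n_hotspots else np.zeros(len(spans), dtype=int)

    iv_rows, hs_rows = [], []
    for (chrom, lo, hi), k in zip(spans, alloc):
        span_len = hi - lo + 1
        hs: list[tuple[int, int]] = []
        if k > 0:
            if span_len < (hotspot_width + 2) * k:
                raise ValueError("chromosome span too short for requested hotspots")
            for _ in range(1000):
                starts = np.sort(gen.integers(lo, hi - hotspot_width + 1, size=k))
                if k == 1 or np.all(np.diff(starts) > hotspot_width):
                    hs = [(int(s), int(s) + hotspot_width - 1) for s in starts]
                    break
            else:  # pragma: no cover - practically unreachable
                raise RuntimeError("failed to place non-overlapping hotspots")
        cursor = lo
        for s, e in hs:
            if s > cursor:
                iv_rows.append((chrom, cursor, s - 1, base_rate))
            iv_rows.append((chrom, s, e, hot_rate))
            hs_rows.append((chrom, s, e))
            cursor = e + 1
        if cursor <= hi:
            iv_rows.append((chrom, cursor, hi, base_rate))

    intervals = pd.DataFrame(iv_rows, columns=["chrom", "start", "end", "rate"])
    hotspots = pd.DataFrame(hs_rows, columns=["chrom", "start", "end"])
    return RecombMap(intervals=intervals, hotspots=hotspots)
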
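"""Core containers for copy-number-state association analysis.

Everything downstream of probe-intensity decoding operates on integer
copy-number states in {0..4} (2 = normal diploid) laid over an ordered
autosomal SNP map. The containers here are deliberately thin wrappers
around numpy arrays / pandas frames with the invariants the analysis
relies on checked at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_STATES = 5
NORMAL_STATE = 2

#: carrier-state sets for the three per-site hypotheses
HYPOTHESES = ("loss", "gain", "abnm")
CARRIER_STATES: Mapping[str, tuple[int, ...]] = {
    "loss": (0, 1),
    "gain": (3, 4),
    "abnm": (0, 1, 3, 4),
}

AUTOSOMES = tuple(range(1, 23))


class UndefinedFDRError(ValueError):
    """Raised when an FDR is requested at a threshold no observed site attains."""


def _as_int_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError(f"{name} must be integer-valued")
        arr = np.round(arr).astype(np.int64)
    return arr


@dataclass(frozen=True)
class SNPMap:
    """Ordered autosomal SNP coordinates.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``snp_id`` (str), ``chrom`` (int, 1-22), ``pos`` (int,
        1-based bp). Must be sorted by (chrom, pos) with strictly
        increasing positions within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"snp_id", "chrom", "pos"}
        if not required.issubset(t.columns):
            raise ValueError(f"SNPMap table needs columns {sorted(required)}")
        chrom = _as_int_array(t["chrom"].to_numpy(), "chrom")
        pos = _as_int_array(t["pos"].to_numpy(), "pos")
        if len(t) == 0:
            raise ValueError("SNPMap must contain at least one SNP")
        if chrom.min() < 1 or chrom.max() > 22:
            raise ValueError("chrom must lie in 1..22 (autosomes only)")
        order = np.lexsort((pos, chrom))
        if not np.array_equal(order, np.arange(len(t))):
            raise ValueError("SNPMap must be sorted by (chrom, pos)")
        same = chrom[1:] == chrom[:-1]
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("positions must be strictly increasing within a chromosome")
        if t["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in SNPMap")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.table["chrom"].to_numpy().astype(np.int64)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos"].to_numpy().astype(np.int64)

    def chrom_blocks(self) -> list[tuple[int, int, int]]:
        """Contiguous index blocks, one per chromosome: (chrom, start, stop)."""
        chrom = self.chroms
        breaks = np.flatnonzero(np.diff(chrom)) + 1
        starts = np.concatenate(([0], breaks))
        stops = np.concatenate((breaks, [len(chrom)]))
        return [(int(chrom[a]), int(a), int(b)) for a, b in zip(starts, stops)]

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = pd.Index(self.table["snp_id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            raise KeyError("snp_id not present in SNPMap")
        return idx


@dataclass(frozen=True)
class RiskRegionSpec:
    """Ground-truth case-enriched CNV region used by the cohort simulator."""

    chrom: int
    start_snp_index: int
    end_snp_index: int  # inclusive
    cnv_type: str  # "amplification" or "deletion"
    carrier_freq_cases: float
    carrier_freq_controls: float

    def __post_init__(self):
        if self.cnv_type not in ("amplification", "deletion"):
            raise ValueError("cnv_type must be 'amplification' or 'deletion'")
        if self.end_snp_index < self.start_snp_index + 2:
            raise ValueError("risk region must span at least 3 SNPs")
        for f in (self.carrier_freq_cases, self.carrier_freq_controls):
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequencies must lie in [0, 1]")

    @property
    def carrier_state(self) -> int:
        return 3 if self.cnv_type == "amplification" else 1

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.start_snp_index, self.end_snp_index + 1)


@dataclass(frozen=True)
class StateMatrix:
    """Per-individual, per-SNP integer copy-number states with labels."""

    states: np.ndarray  # (n_individuals, n_snps) int
    labels: np.ndarray  # (n_individuals,) of {"case", "control"}
    cohort_id: str = "cohort"
    individual_ids: np.ndarray | None = None

    def __post_init__(self):
        states = np.asarray(self.states)
        labels = np.asarray(self.labels)
        if states.ndim != 2:
            raise ValueError("states must be 2-D (individuals x SNPs)")
        if states.size and (states.min() < 0 or states.max() >= N_STATES):
            raise ValueError("states must lie in {0,...,4}")
        if labels.shape != (states.shape[0],):
            raise ValueError("labels length must equal number of individuals")
        if not set(np.unique(labels)).issubset({"case", "control"}):
            raise ValueError("labels must be 'case' or 'control'")
        object.__setattr__(self, "states", states.astype(np.int8, copy=False))
        object.__setattr__(self, "labels", labels.astype(object))
        if self.individual_ids is None:
            ids = np.array(
                [f"{self.cohort_id}_{l}_{i}" for i, l in enumerate(labels)], dtype=object
            )
            object.__setattr__(self, "individual_ids", ids)
        else:
            ids = np.asarray(self.individual_ids, dtype=object)
            if ids.shape != (states.shape[0],):
                raise ValueError("individual_ids length mismatch")
            object.__setattr__(self, "individual_ids", ids)

    @property
    def n_individuals(self) -> int:
        return self.states.shape[0]

    @property
    def n_snps(self) -> int:
        return self.states.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == "case"

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())


@dataclass(frozen=True)
class IntensityMatrix:
    """Real-valued probe-signal matrix (individuals x SNPs)."""

    signal: np.ndarray

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be 2-D (individuals x SNPs)")
        if not np.all(np.isfinite(sig)):
            raise ValueError("signal must be finite")
        object.__setattr__(self, "signal", sig)

    @property
    def n_individuals(self) -> int:
        return self.signal.shape[0]

    @property
    def n_snps(self) -> int:
        return self.signal.shape[1]


@dataclass(frozen=True)
class RecombMap:
    """Piecewise-constant recombination-rate map plus hotspot intervals.

    ``intervals``: DataFrame(chrom, start, end, rate) — 1-based inclusive
    bp intervals, sorted and non-overlapping within each chromosome, rate
    in cM/Mb. ``hotspots``: DataFrame(chrom, start, end), same convention.
    """

    intervals: pd.DataFrame
    hotspots: pd.DataFrame

    def __post_init__(self):
        iv = self.intervals
        if not {"chrom", "start", "end", "rate"}.issubset(iv.columns):
            raise ValueError("intervals need columns chrom,start,end,rate")
        if (iv["rate"] < 0).any():
            raise ValueError("rates must be >= 0")
        for df, what in ((iv, "intervals"), (self.hotspots, "hotspots")):
            if len(df) == 0:
                continue
            if (df["end"] < df["start"]).any():
                raise ValueError(f"{what}: end < start")
            for _, sub in df.groupby("chrom"):
                s = sub.sort_values("start")
                if not s.index.equals(sub.index):
                    raise ValueError(f"{what} must be sorted by (chrom, start)")
                if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"{what} must be non-overlapping")

    def chrom_intervals(self, chrom: int) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


@dataclass(frozen=True)
class HMMParams:
    """Five-state Gaussian hidden Markov model over copy-number states 0-4."""

    initial: np.ndarray  # (5,)
    transition: np.ndarray  # (5, 5) row-stochastic
    means: np.ndarray  # (5,) emission means
    sds: np.ndarray  # (5,) emission standard deviations, > 0

    def __post_init__(self):
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        if init.shape != (N_STATES,) or trans.shape != (N_STATES, N_STATES):
            raise ValueError("initial must be length 5, transition 5x5")
        if means.shape != (N_STATES,) or sds.shape != (N_STATES,):
            raise ValueError("means and sds must have length 5")
        if abs(init.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(trans.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if np.any(init < 0) or np.any(trans < 0):
            raise ValueError("probabilities must be non-negative")
        if np.any(sds <= 0):
            raise ValueError("emission sds must be > 0")
        for name, arr in (("initial", init), ("transition", trans), ("means", means), ("sds", sds)):
            object.__setattr__(self, name, arr)

    @classmethod
    def default(cls, means: Sequence[float] = (-1.0, -0.5, 0.0, 0.5, 1.0),
                sd: float = 0.15, self_prob: float = 0.999,
                normal_prior: float = 0.996) -> "HMMParams":
        """A generic well-separated parameterization: sticky transitions and
        a strong prior on the diploid state."""
        off = (1.0 - self_prob) / (N_STATES - 1)
        trans = np.full((N_STATES, N_STATES), off)
        np.fill_diagonal(trans, self_prob)
        init = np.full(N_STATES, (1.0 - normal_prior) / (N_STATES - 1))
        init[NORMAL_STATE] = normal_prior
        return cls(init, trans, np.asarray(means, float), np.full(N_STATES, sd))


@dataclass(frozen=True)
class CNVRecord:
    """A summarized CNV built from consecutive risk loci (published-table shape)."""

    dataset: str
    chrom: int
    start_pos: int
    end_pos: int
    cnv_type: str  # Amplification | Deletion | Abnormal
    member_snp_ids: tuple[str, ...] = ()
    band: str = ""

    def __post_init__(self):
        if self.end_pos <= self.start_pos:
            raise ValueError("CNVRecord requires start_pos < end_pos")
        if self.cnv_type not in ("Amplification", "Deletion", "Abnormal"):
            raise ValueError("cnv_type must be Amplification, Deletion or Abnormal")

    @property
    def size_kb(self) -> float:
        from .cnv import cnv_size_kb

        return cnv_size_kb(self.start_pos, self.end_pos)
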
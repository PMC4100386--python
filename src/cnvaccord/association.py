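"""Per-SNP case-control testing of copy-number-state distributions.

Each SNP site yields a 2x5 case/control-by-state contingency table. It
is tested five ways: a Pearson chi-square on the observed-state columns,
Fisher exact tests on the three collapsed carrier hypotheses (loss =
states {0,1}, gain = {3,4}, abnm = {0,1,3,4}), and a Cochran-Armitage
trend test with copy numbers as scores. Window-based testing then sums
-log10 of the best-hypothesis p over the SNPs flanking a candidate, and
significance is calibrated with a permutation FDR (case/control labels
reshuffled, cohort sizes preserved).

Two equivalent code paths exist: a readable single-site path on top of
scipy (``tabulate_site`` / ``test_site``) and a vectorized batch path
used by the permutation layer, which evaluates the Fisher tail by exact
hypergeometric enumeration through a log-gamma lookup. The test suite
pins the two paths against each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import (
    CARRIER_STATES,
    HYPOTHESES,
    N_STATES,
    SNPMap,
    StateMatrix,
    UndefinedFDRError,
)

#: floor applied to p-values before -log10 in window statistics
P_FLOOR = 1.0 / (2.0e6)
_STATE_SCORES = np.arange(N_STATES, dtype=float)


# ---------------------------------------------------------------------------
# single-site path
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteTable:
    """Case/control-by-state counts at one SNP, with the collapsed 2x2s."""

    counts: np.ndarray  # (2, 5): row 0 = cases, row 1 = controls
    collapsed: dict  # hypothesis -> (2, 2): [[carrier, non-carrier] per row]


@dataclass(frozen=True)
class SiteTestResult:
    snp_id: str
    p_pearson: float
    p_loss: float
    p_gain: float
    p_abnm: float
    p_trend: float
    best_hypothesis: str

    @property
    def p_best(self) -> float:
        return min(self.p_loss, self.p_gain, self.p_abnm)


def tabulate_site(states: StateMatrix, snp_index: int) -> SiteTable:
    """Exact 2x5 cross-tabulation of one site, plus the hypothesis 2x2s."""
    if not 0 <= snp_index < states.n_snps:
        raise ValueError(f"snp_index {snp_index} out of range")
    col = states.states[:, snp_index].astype(np.int64)
    case = states.case_mask
    counts = np.zeros((2, N_STATES), dtype=np.int64)
    np.add.at(counts[0], col[case], 1)
    np.add.at(counts[1], col[~case], 1)
    collapsed = {}
    for h, members in CARRIER_STATES.items():
        carrier = counts[:, list(members)].sum(axis=1)
        collapsed[h] = np.column_stack([carrier, counts.sum(axis=1) - carrier])
    return SiteTable(counts=counts, collapsed=collapsed)


def _pearson_p_single(table: np.ndarray) -> float:
    """Pearson chi-square on the columns actually observed; degenerate -> 1."""
    t = table[:, table.sum(axis=0) > 0]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 1.0
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(max(p, 1e-300))


def trend_test_p(table: np.ndarray, scores: np.ndarray = _STATE_SCORES) -> float:
    """Cochran-Armitage trend p on a 2xK table (copy numbers as scores)."""
    p = _trend_p_batch(np.asarray(table, dtype=float)[None, :, :], scores)
    return float(p[0])


def test_site(table: SiteTable, snp_id: str = "") -> SiteTestResult:
    """All five tests at one site. Degenerate (zero-variance) tables give p=1."""
    counts = table.counts
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("both cohorts must be non-empty")
    p_hyp = {}
    for h in HYPOTHESES:
        t = table.collapsed[h]
        if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
            p_hyp[h] = 1.0  # nobody (or everybody) is a carrier
        else:
            p_hyp[h] = float(max(stats.fisher_exact(t, alternative="two-sided")[1], 1e-300))
    best = min(HYPOTHESES, key=lambda h: p_hyp[h])
    return SiteTestResult(
        snp_id=snp_id,
        p_pearson=_pearson_p_single(counts),
        p_loss=p_hyp["loss"],
        p_gain=p_hyp["gain"],
        p_abnm=p_hyp["abnm"],
        p_trend=trend_test_p(counts),
        best_hypothesis=best,
    )


# ---------------------------------------------------------------------------
# batch path (vectorized over sites; used directly and by permutations)
# ---------------------------------------------------------------------------

def site_state_counts(states: StateMatrix, case_mask: np.ndarray | None = None) -> np.ndarray:
    """(n_snps, 2, 5) state counts for every site under the given labels."""
    if case_mask is None:
        case_mask = states.case_mask
    s = states.states
    counts = np.empty((s.shape[1], 2, N_STATES), dtype=np.int64)
    for k in range(N_STATES):
        m = s == k
        counts[:, 0, k] = m[case_mask].sum(axis=0)
        counts[:, 1, k] = m[~case_mask].sum(axis=0)
    return counts


def permuted_state_counts(states: StateMatrix, perm_masks: np.ndarray) -> np.ndarray:
    """(T_pm, n_snps, 2, 5) counts under each permuted case mask.

    ``perm_masks`` is a (T_pm, n_individuals) boolean array; every row
    must preserve the original number of cases.
    """
    s = states.states
    T = perm_masks.shape[0]
    pm = perm_masks.astype(np.float32)
    out = np.empty((T, s.shape[1], 2, N_STATES), dtype=np.int64)
    for k in range(N_STATES):
        onehot = (s == k).astype(np.float32)
        tot = onehot.sum(axis=0)
        case = pm @ onehot  # (T, n_snps)
        out[:, :, 0, k] = np.rint(case).astype(np.int64)
        out[:, :, 1, k] = np.rint(tot - case).astype(np.int64)
    return out


def permutation_masks(case_mask: np.ndarray, t_pm: int, rng: np.random.Generator) -> np.ndarray:
    """T_pm random relabelings, each with the original case/control sizes."""
    if t_pm < 1:
        raise ValueError("t_pm must be >= 1")
    n = len(case_mask)
    out = np.zeros((t_pm, n), dtype=bool)
    n_case = int(np.sum(case_mask))
    for m in range(t_pm):
        idx = rng.permutation(n)[:n_case]
        out[m, idx] = True
    return out


def pearson_chi2_p(counts: np.ndarray) -> np.ndarray:
    """Vectorized Pearson chi-square p for (..., 2, K) tables, restricted to
    observed-state columns; tables with < 2 observed columns give p = 1."""
    counts = np.asarray(counts, dtype=float)
    col = counts.sum(axis=-2)
    row = counts.sum(axis=-1)
    N = row.sum(axis=-1)
    observed = col > 0
    dof = observed.sum(axis=-1) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        E = row[..., :, None] * col[..., None, :] / N[..., None, None]
        cell = np.where(E > 0, (counts - E) ** 2 / np.where(E > 0, E, 1.0), 0.0)
    chi2 = cell.sum(axis=(-1, -2))
    valid = (dof >= 1) & (row > 0).all(axis=-1)
    p = np.ones_like(chi2)
    if np.any(valid):
        p[valid] = stats.chi2.sf(chi2[valid], dof[valid])
    return np.maximum(p, 1e-300)


def _log_factorials(n_max: int) -> np.ndarray:
    """Lookup table: entry i = log(i!)."""
    return gammaln(np.arange(n_max + 1, dtype=float) + 1.0)


def fisher_exact_p_batch(a: np.ndarray, K: np.ndarray, n_case: int, n_ctrl: int,
                         lgam: np.ndarray | None = None) -> np.ndarray:
    """Two-sided Fisher exact p for many 2x2 tables with common row totals.

    ``a`` = carriers among cases, ``K`` = total carriers; the tables are
    [[a, n_case - a], [K - a, n_ctrl - (K - a)]]. The whole conditional
    hypergeometric support is enumerated and all outcomes at most as
    probable as the observed one are summed, which is the scipy
    two-sided convention (relative tie tolerance 1e-7).
    """
    a = np.asarray(a, dtype=np.int64)
    K = np.asarray(K, dtype=np.int64)
    N = n_case + n_ctrl
    if lgam is None:
        lgam = _log_factorials(N)

    def lchoose(n, k):
        return lgam[n] - lgam[k] - lgam[n - k]

    kmin = np.maximum(0, K - n_ctrl)
    kmax = np.minimum(K, n_case)
    width = int((kmax - kmin).max()) + 1 if a.size else 1
    k = kmin[:, None] + np.arange(width)[None, :]
    valid = k <= kmax[:, None]
    ksafe = np.where(valid, k, 0)
    logpmf = (
        lchoose(n_case, ksafe)
        + lchoose(n_ctrl, np.where(valid, K[:, None] - ksafe, 0))
        - lchoose(N, K)[:, None]
    )
    log_obs = (
        lchoose(n_case, a) + lchoose(n_ctrl, K - a) - lchoose(N, K)
    )
    include = valid & (logpmf <= log_obs[:, None] + 1e-7)
    p = np.where(include, np.exp(logpmf), 0.0).sum(axis=1)
    return np.clip(p, 1e-300, 1.0)


def _trend_p_batch(counts: np.ndarray, scores: np.ndarray = _STATE_SCORES) -> np.ndarray:
    """Cochran-Armitage trend p for (..., 2, K) tables."""
    counts = np.asarray(counts, dtype=float)
    r = counts[..., 0, :]
    n = counts.sum(axis=-2)
    R1 = r.sum(axis=-1)
    N = n.sum(axis=-1)
    R2 = N - R1
    T1 = (scores * r).sum(axis=-1)
    Tn = (scores * n).sum(axis=-1)
    T2 = (scores**2 * n).sum(axis=-1)
    num = N * T1 - R1 * Tn
    den = R1 * R2 * (N * T2 - Tn**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, N * num**2 / np.where(den > 0, den, 1.0), 0.0)
    p = np.where(den > 0, stats.chi2.sf(stat, 1), 1.0)
    return np.maximum(p, 1e-300)


def batch_site_tests(counts: np.ndarray) -> dict[str, np.ndarray]:
    """All per-site tests for a stack of (n_sites, 2, 5) tables.

    Returns arrays ``p_pearson``, ``p_loss``, ``p_gain``, ``p_abnm``,
    ``p_trend``, ``p_best`` and integer ``best_hypothesis`` codes
    indexing :data:`~cnvaccord.types.HYPOTHESES`.
    """
    counts = np.asarray(counts)
    n_case = int(counts[0, 0].sum())
    n_ctrl = int(counts[0, 1].sum())
    lgam = _log_factorials(n_case + n_ctrl)
    out: dict[str, np.ndarray] = {"p_pearson": pearson_chi2_p(counts)}
    hyp_ps = []
    for h in HYPOTHESES:
        members = list(CARRIER_STATES[h])
        carriers = counts[:, :, members].sum(axis=2)
        p = fisher_exact_p_batch(carriers[:, 0], carriers.sum(axis=1), n_case, n_ctrl, lgam)
        out[f"p_{h}"] = p
        hyp_ps.append(p)
    hyp = np.stack(hyp_ps, axis=1)
    out["best_hypothesis"] = np.argmin(hyp, axis=1)
    out["p_best"] = hyp.min(axis=1)
    out["p_trend"] = _trend_p_batch(counts)
    return out


def test_all_sites(states: StateMatrix, snp_map: SNPMap) -> pd.DataFrame:
    """Per-site test table for a whole cohort (batch path)."""
    if states.n_snps != len(snp_map):
        raise ValueError("state matrix and SNP map disagree on the number of SNPs")
    res = batch_site_tests(site_state_counts(states))
    return pd.DataFrame(
        {
            "snp_id": snp_map.snp_ids,
            "chrom": snp_map.chroms,
            "pos": snp_map.positions,
            "p_pearson": res["p_pearson"],
            "p_loss": res["p_loss"],
            "p_gain": res["p_gain"],
            "p_abnm": res["p_abnm"],
            "p_trend": res["p_trend"],
            "p_best": res["p_best"],
            "best_hypothesis": np.array(HYPOTHESES, dtype=object)[res["best_hypothesis"]],
        }
    )


# ---------------------------------------------------------------------------
# window-based testing
# ---------------------------------------------------------------------------

def window_members(snp_map: SNPMap, half_width: int, max_gap: int) -> np.ndarray:
    """(n_snps, 2*half_width+1) member-index matrix, -1 where absent.

    A window extends up to ``half_width`` consecutive SNPs on each side
    of the focal SNP, never crosses a chromosome boundary, and is
    truncated at the first inter-SNP gap exceeding ``max_gap`` bp.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    n = len(snp_map)
    pos = snp_map.positions
    members = np.full((n, 2 * half_width + 1), -1, dtype=np.int64)
    for _, a, b in snp_map.chrom_blocks():
        gap_ok = (pos[a + 1 : b] - pos[a : b - 1]) <= max_gap  # gap_ok[j]: between a+j and a+j+1
        for i in range(a, b):
            lo = i
            for _ in range(half_width):
                if lo - 1 >= a and gap_ok[lo - 1 - a]:
                    lo -= 1
                else:
                    break
            hi = i
            for _ in range(half_width):
                if hi + 1 < b and gap_ok[hi - a]:
                    hi += 1
                else:
                    break
            members[i, : hi - lo + 1] = np.arange(lo, hi + 1)
    return members


def window_statistics(
    p_hyp: np.ndarray,
    best_hypothesis: np.ndarray,
    members: np.ndarray,
    p_floor: float = P_FLOOR,
) -> np.ndarray:
    """S_w per site: sum over window members of -log10 p under the focal
    site's best hypothesis. ``p_hyp`` is (n_sites, 3) ordered as
    :data:`~cnvaccord.types.HYPOTHESES`; ``members`` from
    :func:`window_members`."""
    neglog = -np.log10(np.maximum(p_hyp, p_floor))  # (n, 3)
    gathered = neglog[np.maximum(members, 0), :]  # (n, w, 3)
    mask = (members >= 0)[:, :, None]
    per_hyp = (gathered * mask).sum(axis=1)  # (n, 3)
    return per_hyp[np.arange(len(members)), best_hypothesis]


def window_test(
    results: pd.DataFrame,
    snp_map: SNPMap,
    candidates: list[str],
    half_width: int = 2,
    max_gap: int = 30_000,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Window statistics for candidate SNPs.

    ``results`` must be the per-site table from :func:`test_all_sites`
    (or equivalent, with p_loss/p_gain/p_abnm and best_hypothesis).
    Returns one row per candidate: snp_id, member snp_ids, s_w.
    """
    known = set(results["snp_id"])
    missing = [c for c in candidates if c not in known]
    if missing:
        raise ValueError(f"candidates not among tested sites: {missing[:5]}")
    members = window_members(snp_map, half_width, max_gap)
    p_hyp = results[["p_loss", "p_gain", "p_abnm"]].to_numpy()
    hyp_code = np.array([HYPOTHESES.index(h) for h in results["best_hypothesis"]])
    s_w = window_statistics(p_hyp, hyp_code, members, p_floor)
    idx = snp_map.index_of(candidates)
    ids = snp_map.snp_ids
    return pd.DataFrame(
        {
            "snp_id": ids[idx],
            "members": [tuple(ids[m[m >= 0]]) for m in members[idx]],
            "s_w": s_w[idx],
        }
    )


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def permutation_fdr(observed: np.ndarray, ensemble: np.ndarray, threshold: float) -> float:
    """Raw permutation FDR at a statistic threshold (ties counted with >=):

        FDR(t) = [sum_m #{i: S_i^(m) >= t}] / (T_pm * #{i: S_i >= t})

    clamped to [0, 1]. Raises :class:`UndefinedFDRError` when no
    observed site attains the threshold.
    """
    observed = np.asarray(observed, dtype=float)
    ensemble = np.atleast_2d(np.asarray(ensemble, dtype=float))
    t_pm = ensemble.shape[0]
    n_obs = int((observed >= threshold).sum())
    if n_obs == 0:
        raise UndefinedFDRError(f"no observed statistic reaches threshold {threshold}")
    n_null = int((ensemble >= threshold).sum())
    return float(min(1.0, n_null / (t_pm * n_obs)))


def fdr_qvalues(observed: np.ndarray, ensemble: np.ndarray) -> np.ndarray:
    """Per-site monotone FDR (q-values) from a permutation ensemble.

    The raw FDR is evaluated at every attained observed threshold and
    each site receives the minimum raw FDR over all thresholds it still
    passes, which makes the estimate non-increasing in the statistic.
    """
    observed = np.asarray(observed, dtype=float)
    ensemble = np.atleast_2d(np.asarray(ensemble, dtype=float))
    t_pm = ensemble.shape[0]
    thresholds = np.unique(observed)  # ascending
    obs_sorted = np.sort(observed)
    null_sorted = np.sort(ensemble.ravel())
    n_obs_ge = len(observed) - np.searchsorted(obs_sorted, thresholds, side="left")
    n_null_ge = null_sorted.size - np.searchsorted(null_sorted, thresholds, side="left")
    raw = np.minimum(1.0, n_null_ge / (t_pm * n_obs_ge))
    q_at_threshold = np.minimum.accumulate(raw)
    return q_at_threshold[np.searchsorted(thresholds, observed)]
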
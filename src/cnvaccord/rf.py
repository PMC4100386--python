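"""Cross-cohort accordance testing: the relative factor Rf.

For each SNP site, four models compare the copy-number-state
distribution of a group in the Testing cohort with a group in the
Reference cohort:

    M00  Testing cases    vs Reference cases
    M10  Testing controls vs Reference cases
    M01  Testing cases    vs Reference controls
    M11  Testing controls vs Reference controls

Each model p-value is a Pearson chi-square on the 2xK group-by-state
table (observed-state columns only; degenerate tables give p = 1). The
relative factor combines them:

    Rf = P(M00) * P(M11) / (P(M01) * P(M10))

High Rf means the case/case and control/control distributions agree
while the cross comparisons differ — the association pattern replicates
across cohorts. Rf significance is calibrated by permuting labels
independently within each cohort and counting the accordance tail
(Rf >= threshold by default; the low tail is available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import pearson_chi2_p, site_state_counts, _pearson_p_single
from .types import SNPMap, StateMatrix, UndefinedFDRError

#: floor applied to the four model p-values before forming the ratio
RF_P_FLOOR = 1e-12


@dataclass(frozen=True)
class RfModels:
    """The four cross-cohort model p-values at one site."""

    p00: float
    p01: float
    p10: float
    p11: float

    def __post_init__(self):
        for name in ("p00", "p01", "p10", "p11"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


def _group_counts(states: StateMatrix, case_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-site 1x5 state counts for (cases, controls)."""
    counts = site_state_counts(states, case_mask)
    return counts[:, 0, :], counts[:, 1, :]


def model_pvalues(reference: StateMatrix, testing: StateMatrix, snp_index: int) -> RfModels:
    """The four model p-values at one site (single-site scipy path)."""
    if reference.n_snps != testing.n_snps:
        raise ValueError("reference and testing cohorts must share the SNP map")
    if not 0 <= snp_index < reference.n_snps:
        raise ValueError("snp_index out of range")
    if min(reference.n_cases, reference.n_controls, testing.n_cases, testing.n_controls) == 0:
        raise ValueError("both cohorts must contain cases and controls")

    def dist(states: StateMatrix, group: str) -> np.ndarray:
        mask = states.case_mask if group == "case" else ~states.case_mask
        col = states.states[mask, snp_index].astype(np.int64)
        return np.bincount(col, minlength=5)

    rc, rx = dist(reference, "case"), dist(reference, "control")
    tc, tx = dist(testing, "case"), dist(testing, "control")
    floor = lambda p: max(p, RF_P_FLOOR)
    return RfModels(
        p00=floor(_pearson_p_single(np.vstack([tc, rc]))),
        p10=floor(_pearson_p_single(np.vstack([tx, rc]))),
        p01=floor(_pearson_p_single(np.vstack([tc, rx]))),
        p11=floor(_pearson_p_single(np.vstack([tx, rx]))),
    )


def relative_factor(models: RfModels) -> float:
    """Rf = (p00 * p11) / (p01 * p10)."""
    return (models.p00 * models.p11) / (models.p01 * models.p10)


def batch_model_pvalues(
    ref_counts: tuple[np.ndarray, np.ndarray],
    test_counts: tuple[np.ndarray, np.ndarray],
    p_floor: float = RF_P_FLOOR,
) -> dict[str, np.ndarray]:
    """Vectorized model p-values for all sites.

    ``ref_counts`` / ``test_counts`` are (case, control) pairs of
    (n_sites, 5) count arrays, e.g. from :func:`_group_counts`.
    """
    rc, rx = ref_counts
    tc, tx = test_counts
    out = {}
    for name, top, bottom in (
        ("p00", tc, rc),
        ("p10", tx, rc),
        ("p01", tc, rx),
        ("p11", tx, rx),
    ):
        tables = np.stack([top, bottom], axis=1)  # (n, 2, 5)
        out[name] = np.maximum(pearson_chi2_p(tables), p_floor)
    return out


def batch_relative_factor(reference: StateMatrix, testing: StateMatrix,
                          ref_mask: np.ndarray | None = None,
                          test_mask: np.ndarray | None = None,
                          p_floor: float = RF_P_FLOOR) -> pd.DataFrame:
    """Model p-values and Rf for every site under (possibly permuted) labels."""
    models = batch_model_pvalues(
        _group_counts(reference, ref_mask), _group_counts(testing, test_mask), p_floor
    )
    rf = models["p00"] * models["p11"] / (models["p01"] * models["p10"])
    return pd.DataFrame({**models, "rf": rf, "log10_rf": np.log10(rf)})


def rf_fdr(observed_rf: np.ndarray, ensemble_rf: np.ndarray, rf_site: float,
           tail: str = "ge") -> float:
    """Permutation FDR of the relative factor at threshold ``rf_site``.

        FDR(rf_site) = [sum_m #{i: Rf_i^(m) in tail}] / (T_pm * #{i: Rf_i in tail})

    ``tail='ge'`` counts the accordance tail Rf >= rf_site (default);
    ``tail='le'`` counts Rf <= rf_site. Clamped to [0, 1].
    """
    observed = np.asarray(observed_rf, dtype=float)
    ensemble = np.atleast_2d(np.asarray(ensemble_rf, dtype=float))
    if tail not in ("ge", "le"):
        raise ValueError("tail must be 'ge' or 'le'")
    hit = (lambda x: x >= rf_site) if tail == "ge" else (lambda x: x <= rf_site)
    n_obs = int(hit(observed).sum())
    if n_obs == 0:
        raise UndefinedFDRError(f"no observed Rf in the {tail} tail of {rf_site}")
    n_null = int(hit(ensemble).sum())
    return float(min(1.0, n_null / (ensemble.shape[0] * n_obs)))


def select_risk_loci(
    window_results: pd.DataFrame,
    rf_results: pd.DataFrame,
    joint_null_sw: np.ndarray,
    joint_null_rf: np.ndarray,
    s_w_threshold: float,
    fp_budget: float = 1.0,
) -> pd.DataFrame:
    """Joint (window, Rf) risk-locus selection under a false-positive budget.

    ``window_results`` carries the window-passing sites (columns snp_id,
    s_w, passed); ``rf_results`` the per-site rf aligned by snp_id.
    ``joint_null_sw`` / ``joint_null_rf`` are (T_pm, n_candidate)
    permutation statistics at the same candidate sites. The Rf cutoff is
    the smallest attained threshold t for which the permutation-expected
    number of null sites jointly passing (S_w >= s_w_threshold, rf >= t)
    falls below ``fp_budget``; selected sites are the window-passing
    sites with rf >= t.
    """
    if fp_budget <= 0:
        raise ValueError("fp_budget must be > 0")
    merged = window_results.merge(rf_results[["snp_id", "rf"]], on="snp_id", how="left")
    passing = merged[merged["passed"]].copy() if "passed" in merged else merged.copy()
    if len(passing) == 0:
        return passing.assign(selected=pd.Series(dtype=bool))

    t_pm = joint_null_sw.shape[0]
    null_window_pass = joint_null_sw >= s_w_threshold
    candidates_t = np.sort(passing["rf"].unique())  # ascending
    chosen = None
    for t in candidates_t:
        expected_null = float((null_window_pass & (joint_null_rf >= t)).sum()) / t_pm
        if expected_null < fp_budget:
            chosen = t
            break
    if chosen is None:
        warnings.warn(
            "no Rf threshold satisfies the false-positive budget; selecting nothing",
            stacklevel=2,
        )
        return passing.iloc[0:0].assign(selected=pd.Series(dtype=bool))
    out = passing[passing["rf"] >= chosen].copy()
    out["rf_cutoff"] = chosen
    return out
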
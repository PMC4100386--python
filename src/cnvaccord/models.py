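"""Model/results objects for the two analysis stages.

:class:`CohortAssociation` fits one case-control cohort: per-site
multi-hypothesis testing, permutation-FDR candidate selection and
window-based testing. :class:`CrossCohortAccordance` fits the combined
two-cohort analysis: the relative factor Rf at every site, its
permutation FDR, and joint (window, Rf) risk-locus selection under a
false-positive budget. Both follow the familiar model.fit() -> results
pattern; the results objects carry the tables, the permutation
ensembles and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import rf as rfmod
from .types import HYPOTHESES, SNPMap, StateMatrix


class CohortAssociation:
    """Single-cohort CNV association model.

    Parameters
    ----------
    states : StateMatrix
        Integer copy-number states with case/control labels.
    snp_map : SNPMap
        Ordered autosomal SNP coordinates matching the state columns.
    """

    def __init__(self, states: StateMatrix, snp_map: SNPMap):
        if states.n_snps != len(snp_map):
            raise ValueError("state matrix and SNP map disagree on the number of SNPs")
        if states.n_cases == 0 or states.n_controls == 0:
            raise ValueError("cohort must contain both cases and controls")
        self.states = states
        self.snp_map = snp_map

    def fit(
        self,
        t_pm: int = 100,
        candidate_fdr: float = 0.15,
        window_fdr: float = 0.15,
        half_width: int = 2,
        max_gap: int = 30_000,
        p_floor: float = assoc.P_FLOOR,
        seed: int | None = None,
        perm_masks: np.ndarray | None = None,
    ) -> "CohortAssociationResults":
        """Run the SNP-based and window-based stages with permutation FDR.

        ``perm_masks`` lets a caller share one permutation set across
        stages and cohorts (the combined analysis does this); otherwise
        ``t_pm`` fresh permutations are drawn from ``seed``.
        """
        if perm_masks is None:
            rng = np.random.default_rng(seed)
            perm_masks = assoc.permutation_masks(self.states.case_mask, t_pm, rng)
        t_pm = perm_masks.shape[0]

        sites = assoc.test_all_sites(self.states, self.snp_map)
        s_snp = -np.log10(np.maximum(sites["p_best"].to_numpy(), p_floor))
        members = assoc.window_members(self.snp_map, half_width, max_gap)
        hyp_code = np.array([HYPOTHESES.index(h) for h in sites["best_hypothesis"]])
        p_hyp = sites[["p_loss", "p_gain", "p_abnm"]].to_numpy()
        s_w = assoc.window_statistics(p_hyp, hyp_code, members, p_floor)

        n = len(sites)
        s_snp_ens = np.empty((t_pm, n))
        s_w_ens = np.empty((t_pm, n))
        perm_counts = assoc.permuted_state_counts(self.states, perm_masks)
        for m in range(t_pm):
            res = assoc.batch_site_tests(perm_counts[m])
            s_snp_ens[m] = -np.log10(np.maximum(res["p_best"], p_floor))
            pm_hyp = np.column_stack([res["p_loss"], res["p_gain"], res["p_abnm"]])
            s_w_ens[m] = assoc.window_statistics(pm_hyp, res["best_hypothesis"], members, p_floor)

        q_snp = assoc.fdr_qvalues(s_snp, s_snp_ens)
        candidate = q_snp <= candidate_fdr
        cand_idx = np.flatnonzero(candidate)

        q_w = np.full(n, np.nan)
        passed = np.zeros(n, dtype=bool)
        if len(cand_idx):
            q_w_cand = assoc.fdr_qvalues(s_w[cand_idx], s_w_ens[:, cand_idx])
            q_w[cand_idx] = q_w_cand
            passed[cand_idx] = q_w_cand <= window_fdr

        sites = sites.assign(
            s_snp=s_snp, fdr_snp=q_snp, candidate=candidate, s_w=s_w, fdr_window=q_w, passed=passed
        )
        return CohortAssociationResults(
            model=self,
            sites=sites,
            members=members,
            perm_masks=perm_masks,
            s_snp_ensemble=s_snp_ens,
            s_w_ensemble=s_w_ens,
            candidate_fdr=candidate_fdr,
            window_fdr=window_fdr,
        )


@dataclass
class CohortAssociationResults:
    """Fitted single-cohort association results."""

    model: CohortAssociation
    sites: pd.DataFrame
    members: np.ndarray
    perm_masks: np.ndarray
    s_snp_ensemble: np.ndarray
    s_w_ensemble: np.ndarray
    candidate_fdr: float
    window_fdr: float

    @property
    def candidates(self) -> pd.DataFrame:
        return self.sites[self.sites["candidate"]]

    @property
    def window_passing(self) -> pd.DataFrame:
        return self.sites[self.sites["passed"]]

    @property
    def s_w_threshold(self) -> float:
        """Smallest window statistic among window-passing sites (inf if none)."""
        passing = self.window_passing
        return float(passing["s_w"].min()) if len(passing) else float("inf")

    def summary(self) -> str:
        st = self.model.states
        passing = self.window_passing
        lines = [
            "Cohort association results",
            "==========================",
            f"cohort:            {st.cohort_id}",
            f"cases/controls:    {st.n_cases}/{st.n_controls}",
            f"sites tested:      {len(self.sites)}",
            f"permutations:      {self.perm_masks.shape[0]}",
            f"candidates (FDR<={self.candidate_fdr}): {int(self.sites['candidate'].sum())}",
            f"window-passing (FDR<={self.window_fdr}): {len(passing)}",
        ]
        if len(passing):
            lines.append(f"attained window FDR: {passing['fdr_window'].max():.6g}")
        return "\n".join(lines)


class CrossCohortAccordance:
    """Combined two-cohort accordance model (relative factor Rf).

    The larger (discovery) cohort is the Reference, the smaller
    (validation) cohort the Testing dataset.
    """

    def __init__(self, reference: StateMatrix, testing: StateMatrix, snp_map: SNPMap):
        if reference.n_snps != testing.n_snps or reference.n_snps != len(snp_map):
            raise ValueError("cohorts must share the SNP map")
        self.reference = reference
        self.testing = testing
        self.snp_map = snp_map

    def fit(
        self,
        t_pm: int = 100,
        seed: int | None = None,
        tail: str = "ge",
        p_floor: float = rfmod.RF_P_FLOOR,
        ref_perm_masks: np.ndarray | None = None,
        test_perm_masks: np.ndarray | None = None,
    ) -> "AccordanceResults":
        """Compute Rf at every site and its permutation ensemble.

        Labels are permuted independently within each cohort; supplying
        ``ref_perm_masks``/``test_perm_masks`` shares a permutation set
        with the per-cohort fits.
        """
        rng = np.random.default_rng(seed)
        if ref_perm_masks is None:
            ref_perm_masks = assoc.permutation_masks(self.reference.case_mask, t_pm, rng)
        if test_perm_masks is None:
            test_perm_masks = assoc.permutation_masks(self.testing.case_mask, t_pm, rng)
        if ref_perm_masks.shape[0] != test_perm_masks.shape[0]:
            raise ValueError("permutation sets must have equal size")
        t_pm = ref_perm_masks.shape[0]

        table = rfmod.batch_relative_factor(self.reference, self.testing, p_floor=p_floor)
        table.insert(0, "snp_id", self.snp_map.snp_ids)

        n = len(table)
        rf_ens = np.empty((t_pm, n))
        for m in range(t_pm):
            perm = rfmod.batch_relative_factor(
                self.reference,
                self.testing,
                ref_mask=ref_perm_masks[m],
                test_mask=test_perm_masks[m],
                p_floor=p_floor,
            )
            rf_ens[m] = perm["rf"].to_numpy()

        rf_obs = table["rf"].to_numpy()
        signed = rf_obs if tail == "ge" else -rf_obs
        signed_ens = rf_ens if tail == "ge" else -rf_ens
        table["fdr_rf"] = assoc.fdr_qvalues(signed, signed_ens)
        table["significant"] = False
        return AccordanceResults(
            model=self, rf_table=table, rf_ensemble=rf_ens, tail=tail,
            ref_perm_masks=ref_perm_masks, test_perm_masks=test_perm_masks,
        )


@dataclass
class AccordanceResults:
    """Fitted cross-cohort accordance results."""

    model: CrossCohortAccordance
    rf_table: pd.DataFrame
    rf_ensemble: np.ndarray
    tail: str
    ref_perm_masks: np.ndarray
    test_perm_masks: np.ndarray
    risk_loci: pd.DataFrame | None = field(default=None)

    def select_risk_loci(
        self, reference_results: CohortAssociationResults, fp_budget: float = 1.0
    ) -> pd.DataFrame:
        """Joint (window, Rf) selection against the false-positive budget.

        ``reference_results`` must be the fitted discovery-cohort
        results whose permutation set matches this fit. Returns the
        risk-locus table (snp_id, chrom, pos, best_hypothesis, s_w, rf)
        and marks the selected sites in ``rf_table['significant']``.
        """
        sites = reference_results.sites
        cand_idx = np.flatnonzero(sites["candidate"].to_numpy())
        window_results = sites.loc[
            cand_idx,
            ["snp_id", "chrom", "pos", "best_hypothesis", "p_loss", "p_gain", "s_w", "passed"],
        ].reset_index(drop=True)
        # directional locus type for CNV summarization: the abnm hypothesis
        # nests loss/gain, so direction comes from the smaller of those two
        window_results["locus_type"] = np.where(
            window_results["p_loss"] <= window_results["p_gain"], "loss", "gain"
        )
        selected = rfmod.select_risk_loci(
            window_results,
            self.rf_table,
            joint_null_sw=reference_results.s_w_ensemble[:, cand_idx],
            joint_null_rf=self.rf_ensemble[:, cand_idx],
            s_w_threshold=reference_results.s_w_threshold,
            fp_budget=fp_budget,
        )
        selected = selected.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self.rf_table["significant"] = self.rf_table["snp_id"].isin(selected["snp_id"]).to_numpy()
        self.risk_loci = selected
        return selected

    def scatter_data(self, reference_results: CohortAssociationResults) -> pd.DataFrame:
        """Per-site -log10(p) vs log10(Rf) table for accordance scatter plots."""
        sites = reference_results.sites
        return pd.DataFrame(
            {
                "snp_id": sites["snp_id"],
                "neglog10_p_pearson": -np.log10(sites["p_pearson"]),
                "neglog10_p_gain": -np.log10(sites["p_gain"]),
                "log10_rf": self.rf_table["log10_rf"],
                "significant": self.rf_table["significant"],
            }
        )

    def summary(self) -> str:
        ref, test = self.model.reference, self.model.testing
        lines = [
            "Cross-cohort accordance results",
            "===============================",
            f"reference cohort:  {ref.cohort_id} ({ref.n_cases}/{ref.n_controls})",
            f"testing cohort:    {test.cohort_id} ({test.n_cases}/{test.n_controls})",
            f"sites:             {len(self.rf_table)}",
            f"permutations:      {self.rf_ensemble.shape[0]}",
            f"tail:              {self.tail}",
            f"median log10(Rf):  {self.rf_table['log10_rf'].median():.4g}",
        ]
        if self.risk_loci is not None:
            lines.append(f"risk loci selected: {len(self.risk_loci)}")
        return "\n".join(lines)
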
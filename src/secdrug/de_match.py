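"""Wilcoxon rank-sum differential expression and reverse signature matching.

Differential expression between two sample groups uses the non-parametric
Wilcoxon rank-sum (Mann-Whitney U) test per gene — exact when both groups
have at most 25 samples and the gene's values are tie-free, the normal
approximation with continuity correction otherwise. Fold change is computed
on group means with a pseudocount, ``log2FC = log2((mean_A + c)/(mean_B +
c))``, and a gene is called significant when its raw p-value is below the
p threshold and |log2FC| meets the fold-change threshold (Benjamini-Hochberg
adjusted q-values are reported alongside but do not gate by default).

Reverse matching asks which genes move one way in a patient contrast (e.g.
biochemical recurrence vs none) and the *opposite* way after drug treatment
— evidence that the drug may reverse the recurrence signature. The headline
direction, reported first, is up-in-patients / down-after-treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 25


@dataclass
class DifferentialExpressionResult:
    """Per-gene DE table plus the thresholds that defined significance."""

    table: pd.DataFrame  # index gene; log2FC, p, p_adj, mean_A, mean_B, significant, direction
    group_A: str
    group_B: str
    p_threshold: float
    fc_threshold: float

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


@dataclass
class ReverseMatchResult:
    table: pd.DataFrame  # matched genes with both contrasts' direction and log2FC
    summary: dict        # counts per (patient_direction, treatment_direction)


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized per-column rank-sum p-values for samples x genes arrays."""
    n_a, n_genes = a.shape
    n_b = b.shape[0]
    p = np.ones(n_genes)
    pooled = np.vstack([a, b])
    constant = np.ptp(pooled, axis=0) == 0
    live = ~constant
    if live.any():
        av, bv = a[:, live], b[:, live]
        # tie-free columns qualify for the exact null distribution
        tie_free = np.array(
            [len(np.unique(pooled[:, j])) == n_a + n_b for j in np.where(live)[0]]
        )
        pv = np.ones(av.shape[1])
        exact_ok = tie_free & (max(n_a, n_b) <= EXACT_MAX_N)
        if exact_ok.any():
            res = stats.mannwhitneyu(
                av[:, exact_ok], bv[:, exact_ok], alternative="two-sided",
                method="exact", axis=0,
            )
            pv[exact_ok] = np.atleast_1d(res.pvalue)
        if (~exact_ok).any():
            res = stats.mannwhitneyu(
                av[:, ~exact_ok], bv[:, ~exact_ok], alternative="two-sided",
                method="asymptotic", axis=0,
            )
            pv[~exact_ok] = np.atleast_1d(res.pvalue)
        p[live] = pv
    return np.minimum(p, 1.0)


def differential_expression(
    expr_A: pd.DataFrame,
    expr_B: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.0,
    pseudocount: float = 1.0,
    group_names: tuple[str, str] = ("A", "B"),
    min_samples: int = 3,
) -> DifferentialExpressionResult:
    """Per-gene Wilcoxon rank-sum DE between two samples x genes frames.

    Expression is assumed normalized upstream and non-negative (fold change
    uses a pseudocount). Genes constant across both groups get p = 1 and
    log2FC = 0. ``fc_threshold`` is on the |log2FC| scale, so the default
    pair (0.05, 1.0) calls genes with p < 0.05 and at least a two-fold mean
    change.
    """
    genes = expr_A.columns
    if not genes.equals(expr_B.columns):
        shared = genes.intersection(expr_B.columns)
        if len(shared) == 0:
            raise ValueError("no shared genes between groups")
        expr_A, expr_B = expr_A[shared], expr_B[shared]
        genes = shared
    if len(expr_A) < min_samples or len(expr_B) < min_samples:
        raise ValueError(f"need >= {min_samples} samples per group")

    a = expr_A.to_numpy(dtype=float)
    b = expr_B.to_numpy(dtype=float)
    p = _wilcoxon_p(a, b)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    constant = np.ptp(np.vstack([a, b]), axis=0) == 0
    log2fc[constant] = 0.0
    p_adj = multipletests(p, method="fdr_bh")[1]
    significant = (p < p_threshold) & (np.abs(log2fc) >= fc_threshold)
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p": p,
            "p_adj": p_adj,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "significant": significant,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=genes,
    )
    return DifferentialExpressionResult(
        table, group_names[0], group_names[1], p_threshold, fc_threshold
    )


def reverse_match(
    patient_de: DifferentialExpressionResult,
    treatment_de: DifferentialExpressionResult,
) -> ReverseMatchResult:
    """Genes significant in both contrasts with opposite directions.

    The match table lists up-in-patient / down-after-treatment genes first
    (the candidates whose recurrence-associated elevation the treatment may
    reverse), then the mirror direction. Raises when the two gene spaces do
    not overlap.
    """
    shared = patient_de.table.index.intersection(treatment_de.table.index)
    if len(shared) == 0:
        raise ValueError("no overlap between patient and treatment gene spaces")
    pt = patient_de.table.loc[shared]
    tx = treatment_de.table.loc[shared]
    both_sig = pt["significant"] & tx["significant"]
    opposite = pt["direction"] != tx["direction"]
    matched = shared[both_sig & opposite]
    table = pd.DataFrame(
        {
            "patient_direction": pt.loc[matched, "direction"],
            "treatment_direction": tx.loc[matched, "direction"],
            "patient_log2FC": pt.loc[matched, "log2FC"],
            "treatment_log2FC": tx.loc[matched, "log2FC"],
        },
        index=matched,
    )
    # headline direction (up-in-patient) first, then alphabetically
    table = (
        table.assign(_gene=table.index)
        .sort_values(["patient_direction", "treatment_direction", "_gene"],
                     ascending=[False, True, True])
        .drop(columns="_gene")
    )
    summary = {
        "up_down": int(((table["patient_direction"] == "up")
                        & (table["treatment_direction"] == "down")).sum()),
        "down_up": int(((table["patient_direction"] == "down")
                        & (table["treatment_direction"] == "up")).sum()),
        "n_matched": int(len(table)),
        "n_shared_genes": int(len(shared)),
    }
    return ReverseMatchResult(table, summary)
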
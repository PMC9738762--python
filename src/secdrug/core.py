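"""The secDrug algorithm: resistance classification and secondary-drug ranking.

Given a drug x cell-line IC50 panel and a primary (standard-of-care) drug,
cell lines are classified as *resistant* when their primary-drug IC50 exceeds
an empirical quantile of the primary drug's IC50 distribution. Candidate
secondary drugs ("secDrugs") are then ranked by how many of those resistant
lines they can kill — a line counts as killed by drug k when its IC50 for k
falls at or below a kill threshold, by default the per-drug median across all
lines (a relative criterion that is immune to cross-drug potency-scale
differences). Ties in kill count are broken by the lower mean log10 IC50 over
the evaluable resistant lines, then lexicographically by drug id so that the
ranking is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pgx_io import DoseResponsePanel

#: minimum evaluable lines for a stable empirical quantile
MIN_EVALUABLE = 4

#: drugs measured on fewer than this fraction of resistant lines are flagged
LOW_COVERAGE_FRACTION = 0.5


@dataclass(frozen=True)
class KillRule:
    """Criterion deciding whether drug k kills a resistant line.

    mode="per_drug_quantile": kill iff IC50 <= the q_kill quantile of drug
    k's IC50 across all lines (default median). mode="absolute": kill iff
    IC50 <= cutoff_nM.
    """

    mode: str = "per_drug_quantile"
    q_kill: float | None = 0.5
    cutoff_nM: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "per_drug_quantile":
            if self.q_kill is None or not 0 < self.q_kill < 1:
                raise ValueError("per_drug_quantile mode needs q_kill in (0,1)")
            if self.cutoff_nM is not None:
                raise ValueError("cutoff_nM must be unset in per_drug_quantile mode")
        elif self.mode == "absolute":
            if self.cutoff_nM is None or self.cutoff_nM <= 0:
                raise ValueError("absolute mode needs cutoff_nM > 0")
            if self.q_kill is not None:
                raise ValueError("q_kill must be unset in absolute mode")
        else:
            raise ValueError(f"unknown kill-rule mode {self.mode!r}")

    def threshold(self, drug_values: np.ndarray) -> float:
        vals = drug_values[np.isfinite(drug_values)]
        if self.mode == "per_drug_quantile":
            if vals.size == 0:
                return np.nan
            return float(np.quantile(vals, self.q_kill))
        return float(self.cutoff_nM)


@dataclass
class ResistanceClassification:
    """Sensitive/resistant labels against a primary drug.

    ``resistant`` means IC50 strictly greater than ``threshold_value`` (the
    empirical q-quantile, linear-interpolation definition); lines with a
    missing primary-drug IC50 are ``unknown``.
    """

    primary_drug_id: str
    quantile_q: float
    threshold_value: float
    labels: pd.Series  # cell_line_id -> {"sensitive", "resistant", "unknown"}

    @property
    def resistant_lines(self) -> list[str]:
        return list(self.labels.index[self.labels == "resistant"])

    @property
    def sensitive_lines(self) -> list[str]:
        return list(self.labels.index[self.labels == "sensitive"])


@dataclass
class SecDrugRanking:
    """Ranked secondary-drug table plus the settings that produced it."""

    table: pd.DataFrame
    primary_drug_id: str
    classification: ResistanceClassification
    kill_rule: KillRule

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


def classify_resistance(
    panel: DoseResponsePanel, primary_drug_id: str, q: float = 0.75
) -> ResistanceClassification:
    """Label cell lines sensitive/resistant to the primary drug.

    The threshold is the empirical ``q``-quantile (linear interpolation
    between order statistics) of the primary drug's non-missing IC50s; a
    line is resistant iff its IC50 is strictly above it. Requires at least
    4 evaluable lines and 0 < q < 1.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if primary_drug_id not in panel.ic50.index:
        raise KeyError(f"primary drug {primary_drug_id!r} not in panel")
    row = panel.ic50.loc[primary_drug_id]
    vals = row.dropna()
    if len(vals) < MIN_EVALUABLE:
        raise ValueError(
            f"only {len(vals)} evaluable lines for {primary_drug_id!r}; "
            f"need >= {MIN_EVALUABLE} for a stable quantile"
        )
    threshold = float(np.quantile(vals.to_numpy(), q))
    labels = pd.Series("unknown", index=row.index, dtype=object)
    labels[vals.index[vals > threshold]] = "resistant"
    labels[vals.index[vals <= threshold]] = "sensitive"
    return ResistanceClassification(primary_drug_id, q, threshold, labels)


def rank_secdrugs(
    panel: DoseResponsePanel,
    classification: ResistanceClassification,
    kill_rule: KillRule = KillRule(),
    drug_annotations: pd.DataFrame | None = None,
) -> SecDrugRanking:
    """Rank candidate secondary drugs by kills among resistant lines.

    For each candidate drug k (the primary drug is excluded):

    * ``kill_count``  — resistant lines with a present IC50 at or below the
      kill threshold for k;
    * ``n_evaluable_resistant`` — resistant lines with a present IC50;
    * ``mean_log_ic50_resistant`` — mean log10 IC50 (nM) over those lines,
      the tie-break statistic.

    Sort order: kill_count descending, mean_log_ic50_resistant ascending,
    drug_id ascending; ``rank`` is the 1-based position. Drugs measured on
    fewer than half of the resistant lines are flagged ``low_coverage`` but
    kept. Raises if there are no resistant lines (lower ``q``) or no
    candidate drugs.
    """
    resistant = classification.resistant_lines
    if not resistant:
        raise ValueError(
            "no resistant lines at the chosen quantile; lower q in "
            "classify_resistance to obtain a resistant set"
        )
    candidates = [d for d in panel.drug_ids if d != classification.primary_drug_id]
    if not candidates:
        raise ValueError("no candidate drug besides the primary")

    records = []
    for drug in candidates:
        row = panel.ic50.loc[drug]
        thr = kill_rule.threshold(row.to_numpy(dtype=float))
        res_vals = row[resistant].dropna()
        n_eval = int(len(res_vals))
        kill = int((res_vals <= thr).sum()) if np.isfinite(thr) else 0
        mean_log = float(np.log10(res_vals).mean()) if n_eval else np.nan
        records.append(
            {
                "drug_id": drug,
                "kill_count": kill,
                "n_evaluable_resistant": n_eval,
                "mean_log_ic50_resistant": mean_log,
                "kill_threshold_nM": thr,
                "low_coverage": n_eval < LOW_COVERAGE_FRACTION * len(resistant),
            }
        )
    table = pd.DataFrame.from_records(records)
    # NaN tie-break means (no evaluable lines) sort after any finite mean
    sort_mean = table["mean_log_ic50_resistant"].fillna(np.inf)
    order = np.lexsort(
        (table["drug_id"].to_numpy(), sort_mean.to_numpy(), -table["kill_count"].to_numpy())
    )
    table = table.iloc[order].reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if drug_annotations is not None:
        table = table.join(
            drug_annotations[["target", "target_pathway"]], on="drug_id"
        )
    else:
        table["target"] = pd.NA
        table["target_pathway"] = pd.NA
    cols = [
        "rank", "drug_id", "kill_count", "n_evaluable_resistant",
        "mean_log_ic50_resistant", "kill_threshold_nM", "target",
        "target_pathway", "low_coverage",
    ]
    return SecDrugRanking(table[cols], classification.primary_drug_id, classification, kill_rule)
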
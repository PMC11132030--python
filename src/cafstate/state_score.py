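"""RT-qPCR processing and the composite myCAF:IL-iCAF state score.

Expression is measured as cycle thresholds (Ct); the log2 expression of a
gene relative to the housekeeping reference (RPL37A in the original panel)
is -(Ct_gene - Ct_reference). The state score contrasts myCAF-associated
genes (ACTA2, COL1A1, TAGLN) against IL-iCAF-associated genes (IL6, IL24,
CXCL8, TMEM158), each optionally weighted by its in-vivo log2 fold change,
and is normalised to a baseline condition by subtraction so the baseline
scores exactly zero. Higher scores mean a more myofibroblastic profile,
lower scores a more inflammatory one.

There is no single canonical algebra for composites of this kind, so the
functional form is pluggable: the default is the difference of weighted
means, with weighted-sum and absolute-weight variants selectable; the
strategy used is recorded in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MYCAF_GENES",
    "ILICAF_GENES",
    "REFERENCE_GENE",
    "QpcrScoreInputs",
    "qpcr_log2_rel",
    "mycaf_ilicaf_score",
    "score_table",
    "compare_state_scores",
]

MYCAF_GENES = ("ACTA2", "COL1A1", "TAGLN")
ILICAF_GENES = ("IL6", "IL24", "CXCL8", "TMEM158")
REFERENCE_GENE = "RPL37A"


def qpcr_log2_rel(ct_table: pd.DataFrame, reference_gene: str = REFERENCE_GENE) -> pd.DataFrame:
    """Log2 expression relative to the reference gene, per (condition, replicate).

    value = -(Ct_gene - Ct_reference). Input columns: condition, replicate,
    gene, ct.
    """
    required = {"condition", "replicate", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(ct_table["ct"].astype(float))):
        raise ValueError("Ct values must be finite")

    out_rows = []
    for (cond, rep), grp in ct_table.groupby(["condition", "replicate"], sort=True):
        ref = grp.loc[grp["gene"] == reference_gene, "ct"]
        if ref.empty:
            raise ValueError(
                f"reference gene {reference_gene!r} missing in condition "
                f"{cond!r}, replicate {rep}"
            )
        ref_ct = float(ref.iloc[0])
        for _, row in grp.iterrows():
            if row["gene"] == reference_gene:
                continue
            out_rows.append(
                {
                    "condition": cond,
                    "replicate": rep,
                    "gene": row["gene"],
                    "log2_rel": -(float(row["ct"]) - ref_ct),
                }
            )
    return pd.DataFrame(out_rows, columns=["condition", "replicate", "gene", "log2_rel"])


def _weighted_mean_diff(q: pd.Series, w_my: dict, w_il: dict) -> float:
    my = np.mean([w_my[g] * q[g] for g in w_my])
    il = np.mean([w_il[g] * q[g] for g in w_il])
    return float(my - il)


def _weighted_sum_diff(q: pd.Series, w_my: dict, w_il: dict) -> float:
    return float(sum(w_my[g] * q[g] for g in w_my) - sum(w_il[g] * q[g] for g in w_il))


def _abs_weight_mean_diff(q: pd.Series, w_my: dict, w_il: dict) -> float:
    my = np.mean([abs(w_my[g]) * q[g] for g in w_my])
    il = np.mean([abs(w_il[g]) * q[g] for g in w_il])
    return float(my - il)


STRATEGIES: dict[str, Callable] = {
    "weighted_mean_diff": _weighted_mean_diff,
    "weighted_sum_diff": _weighted_sum_diff,
    "abs_weight_mean_diff": _abs_weight_mean_diff,
}


@dataclass
class QpcrScoreInputs:
    """Everything the composite score needs for one condition/replicate set.

    log2_rel : tidy frame from :func:`qpcr_log2_rel`.
    mycaf_weights / ilicaf_weights : in-vivo log2FC weight per gene for the
        myCAF set I and the IL-iCAF set J (unit weights if unspecified).
    baseline : condition whose score is subtracted from every condition.
    """

    log2_rel: pd.DataFrame
    baseline: str
    mycaf_weights: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in MYCAF_GENES}
    )
    ilicaf_weights: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in ILICAF_GENES}
    )

    def __post_init__(self) -> None:
        if not self.mycaf_weights or not self.ilicaf_weights:
            raise ValueError("both gene sets must be non-empty")
        common = set(self.mycaf_weights) & set(self.ilicaf_weights)
        if common:
            raise ValueError(f"genes in both sets: {sorted(common)}")
        for w in (*self.mycaf_weights.values(), *self.ilicaf_weights.values()):
            if not np.isfinite(w):
                raise ValueError("weights must be finite")
        if self.baseline not in set(self.log2_rel["condition"]):
            raise ValueError(f"baseline condition {self.baseline!r} not in table")


def _raw_score(q: pd.Series, inputs: QpcrScoreInputs, strategy: str) -> float:
    missing = (set(inputs.mycaf_weights) | set(inputs.ilicaf_weights)) - set(q.index)
    if missing:
        raise ValueError(f"genes missing from measurements: {sorted(missing)}")
    return STRATEGIES[strategy](q, inputs.mycaf_weights, inputs.ilicaf_weights)


def mycaf_ilicaf_score(
    inputs: QpcrScoreInputs, strategy: str = "weighted_mean_diff"
) -> tuple[pd.DataFrame, dict]:
    """Baseline-normalised myCAF:IL-iCAF score per (condition, replicate).

    raw(condition, replicate) = strategy(q, weights); the reported score is
    raw minus the baseline condition's mean raw score, so the baseline
    averages exactly zero. Returns (scores frame, metadata).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
    wide = inputs.log2_rel.pivot_table(
        index=["condition", "replicate"], columns="gene", values="log2_rel"
    )
    raw = wide.apply(lambda q: _raw_score(q, inputs, strategy), axis=1)
    baseline_mean = raw.xs(inputs.baseline, level="condition").mean()
    scores = (raw - baseline_mean).rename("score").reset_index()
    meta = {
        "strategy": strategy,
        "baseline": inputs.baseline,
        "baseline_mean_raw": float(baseline_mean),
        "mycaf_genes": sorted(inputs.mycaf_weights),
        "ilicaf_genes": sorted(inputs.ilicaf_weights),
    }
    return scores, meta


def score_table(
    ct_table: pd.DataFrame,
    baseline: str,
    reference_gene: str = REFERENCE_GENE,
    mycaf_weights: dict[str, float] | None = None,
    ilicaf_weights: dict[str, float] | None = None,
    strategy: str = "weighted_mean_diff",
) -> tuple[pd.DataFrame, dict]:
    """Convenience wrapper: Ct table straight to baseline-normalised scores."""
    rel = qpcr_log2_rel(ct_table, reference_gene)
    kwargs = {}
    if mycaf_weights is not None:
        kwargs["mycaf_weights"] = mycaf_weights
    if ilicaf_weights is not None:
        kwargs["ilicaf_weights"] = ilicaf_weights
    inputs = QpcrScoreInputs(log2_rel=rel, baseline=baseline, **kwargs)
    return mycaf_ilicaf_score(inputs, strategy)


def compare_state_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided Welch t-tests on replicate scores between conditions.

    Input columns: condition, score (one row per replicate). P-values are
    BH-FDR adjusted across the pairs.
    """
    conditions = sorted(scores["condition"].unique())
    rows = []
    for a, b in combinations(conditions, 2):
        x = scores.loc[scores["condition"] == a, "score"].astype(float)
        y = scores.loc[scores["condition"] == b, "score"].astype(float)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            {"group_a": a, "group_b": b, "statistic": float(t), "p_value": float(p),
             "mean_a": float(x.mean()), "mean_b": float(y.mean())}
        )
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value",
                                      "mean_a", "mean_b"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out
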
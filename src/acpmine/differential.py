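"""The differential-enrichment mining funnel.

Candidate peptides are filtered through an ordered cascade over a
peptides-x-samples CPM matrix with case (disease) and control (healthy)
groups:

1. presence — nonzero CPM in at least one sample;
2. significance — two-tailed Wilcoxon rank-sum per peptide, Benjamini–
   Hochberg adjusted over the present peptides, FDR < 0.05;
3. effect size — |log2 fold change| (control over case, pseudocount-
   stabilized) above a cutoff of 2;
4. direction — positive log2FC, i.e. enriched in controls (the working
   hypothesis being that protective peptides are depleted in disease);
5. abundance floor — mean relative abundance (CPM / 1e6) in the control
   group above 2e-4.

All thresholds are strict inequalities and configurable; the funnel
reports per-peptide statistics and the retained ids at every stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix

__all__ = [
    "FunnelConfig",
    "FunnelReport",
    "presence_filter",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "run_funnel",
]

STAGES = ("input", "present", "significant", "fc_pass", "ctrl_enriched", "abundant")


@dataclass(frozen=True)
class FunnelConfig:
    """Thresholds of the filter cascade (all strict inequalities)."""

    fdr_threshold: float = 0.05
    log2fc_cutoff: float = 2.0
    abundance_floor: float = 2e-4     # on the scale named by floor_scale
    pseudocount: float = 0.5          # CPM offset for zero-safe ratios
    floor_scale: str = "relative"     # "relative" (fraction) or "cpm"
    floor_group: str = "control"      # group whose mean is compared to the floor

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "log2fc_cutoff", "abundance_floor", "pseudocount"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.floor_scale not in ("relative", "cpm"):
            raise ValueError("floor_scale must be 'relative' or 'cpm'")
        if self.floor_group not in ("control", "case"):
            raise ValueError("floor_group must be 'control' or 'case'")


@dataclass
class FunnelReport:
    """Stage-by-stage retention counts and ids."""

    counts: dict[str, int]
    retained_ids: dict[str, list[str]]

    def __post_init__(self) -> None:
        vals = [self.counts[s] for s in STAGES]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("funnel counts must be non-increasing across stages")

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({
            "stage": list(STAGES),
            "n_retained": [self.counts[s] for s in STAGES],
            "retained_ids": [",".join(self.retained_ids[s]) for s in STAGES],
        }).to_csv(path, sep="\t", index=False)


def presence_filter(matrix: AbundanceMatrix) -> list[str]:
    """Ids of peptides with CPM > 0 in at least one sample of either group."""
    if matrix.values.empty:
        raise ValueError("empty abundance matrix")
    mask = (matrix.values > 0).any(axis=1)
    return list(matrix.values.index[mask])


def wilcoxon_rank_sum(values_ctrl: Sequence[float], values_case: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) p-value.

    Uses the exact null distribution when the smaller group has at most 8
    observations and there are no ties; otherwise the normal approximation
    with tie and continuity corrections. Identical constant inputs give
    p = 1.
    """
    a = np.asarray(values_ctrl, dtype=float)
    b = np.asarray(values_case, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    if len(a) + len(b) < 2:
        raise ValueError("need at least two values in total")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_ctrl: float, mean_case: float, pseudocount: float = 0.5) -> float:
    """log2((mean_ctrl + pc) / (mean_case + pc)); positive = control-enriched."""
    if mean_ctrl < 0 or mean_case < 0:
        raise ValueError("means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return float(np.log2((mean_ctrl + pseudocount) / (mean_case + pseudocount)))


def run_funnel(matrix: AbundanceMatrix,
               config: Optional[FunnelConfig] = None) -> tuple[pd.DataFrame, FunnelReport]:
    """Execute the full mining funnel on a two-group abundance matrix.

    Returns a per-peptide results table (for all peptides passing the
    presence stage; BH adjustment is computed over exactly those) and the
    stage-by-stage :class:`FunnelReport`.
    """
    config = config or FunnelConfig()
    groups = matrix.group_labels
    ctrl_cols = list(groups.index[groups == "control"])
    case_cols = list(groups.index[groups == "case"])
    if not ctrl_cols or not case_cols:
        raise ValueError("abundance matrix must contain both control and case samples")

    all_ids = list(matrix.values.index)
    present = presence_filter(matrix) if all_ids else []
    vals = matrix.values.loc[present]
    ctrl = vals[ctrl_cols].to_numpy(dtype=float)
    case = vals[case_cols].to_numpy(dtype=float)

    pvals = np.array([wilcoxon_rank_sum(ctrl[i], case[i]) for i in range(len(present))])
    fdr = bh_adjust(pvals) if len(present) else np.array([])
    mean_ctrl = ctrl.mean(axis=1) if len(present) else np.array([])
    mean_case = case.mean(axis=1) if len(present) else np.array([])
    lfc = np.array([log2_fold_change(mc, mk, config.pseudocount)
                    for mc, mk in zip(mean_ctrl, mean_case)])
    enriched = np.where(lfc > 0, "control", np.where(lfc < 0, "case", "none"))

    results = pd.DataFrame({
        "peptide_id": present,
        "mean_ctrl": mean_ctrl,
        "mean_case": mean_case,
        "p_value": pvals,
        "fdr": fdr,
        "log2fc": lfc,
        "enriched_in": enriched,
    }).set_index("peptide_id", drop=False)

    sig = results[results["fdr"] < config.fdr_threshold]
    fc = sig[sig["log2fc"].abs() > config.log2fc_cutoff]
    ctrl_enr = fc[fc["log2fc"] > 0]
    floor_mean = ctrl_enr["mean_ctrl"] if config.floor_group == "control" else ctrl_enr["mean_case"]
    floor_val = floor_mean / 1e6 if config.floor_scale == "relative" else floor_mean
    abundant = ctrl_enr[floor_val > config.abundance_floor]

    retained = {
        "input": all_ids,
        "present": present,
        "significant": list(sig.index),
        "fc_pass": list(fc.index),
        "ctrl_enriched": list(ctrl_enr.index),
        "abundant": list(abundant.index),
    }
    report = FunnelReport(
        counts={stage: len(ids) for stage, ids in retained.items()},
        retained_ids=retained,
    )
    return results.reset_index(drop=True), report
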
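"""Benchmark metrics for simulated differential-accessibility runs.

True positive rate (power), false discovery proportion, observed-FDR curves
over replicates, and the true discovery rate (TDR) among top-ranked
differential calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datest import bh_adjust, call_differential

__all__ = [
    "confusion_metrics",
    "fdr_curve",
    "tdr_at_top",
    "evaluation_report",
]

DEFAULT_PERCENTAGES = (20, 40, 60, 80, 100)


def confusion_metrics(calls, truth) -> tuple[float, float]:
    """(TPR, FDP) of a call set against the truth.

    TPR = TP / (TP + FN); FDP = FP / max(1, FP + TP) — the guarded
    denominator makes the FDP of an empty call set zero.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must align on the same peaks")
    tp = int(np.count_nonzero(calls & truth))
    fp = int(np.count_nonzero(calls & ~truth))
    fn = int(np.count_nonzero(~calls & truth))
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    fdp = fp / max(1, fp + tp)
    return float(tpr), float(fdp)


def fdr_curve(pvalue_replicates, truth_replicates, nominal_grid) -> pd.DataFrame:
    """Observed FDR (mean FDP over replicates) at each nominal BH level.

    Parameters
    ----------
    pvalue_replicates : list of per-replicate p-value arrays (NaN allowed)
    truth_replicates : matching list of boolean truth arrays
    nominal_grid : nominal FDR levels at which peaks are called by BH
    """
    if len(pvalue_replicates) == 0:
        raise ValueError("at least one replicate is required")
    if len(pvalue_replicates) != len(truth_replicates):
        raise ValueError("replicate lists must have equal length")
    rows = []
    for nominal in nominal_grid:
        fdps = []
        for pvals, truth in zip(pvalue_replicates, truth_replicates):
            fdr = bh_adjust(pvals)
            with np.errstate(invalid="ignore"):
                calls = np.isfinite(fdr) & (fdr < nominal)
            _, fdp = confusion_metrics(calls, truth)
            fdps.append(fdp)
        rows.append({"nominal": float(nominal),
                     "observed_fdr": float(np.mean(fdps)),
                     "n_replicates": len(fdps)})
    return pd.DataFrame(rows)


def tdr_at_top(results: pd.DataFrame, truth,
               percentages=DEFAULT_PERCENTAGES,
               fdr_cut: float = 0.05, lfc_cut: float = 0.5) -> dict:
    """True discovery rate among the top-ranked differential calls.

    Peaks are first called differential (FDR and |log2FC| thresholds), then
    ranked by p-value ascending with ties broken by the LRT statistic
    descending; TDR(q) is the fraction of truly differential peaks among
    the top q% of the called set. With no called peaks all values are NaN.
    """
    truth = np.asarray(truth, dtype=bool)
    if len(results) != truth.size:
        raise ValueError("results and truth must align on the same peaks")
    called = call_differential(results, fdr_cut, lfc_cut)
    out: dict[int, float] = {}
    idx = np.flatnonzero(called)
    if idx.size == 0:
        return {int(q): float("nan") for q in percentages}
    sub = results.iloc[idx]
    order = np.lexsort((-sub["lambda_lr"].to_numpy(),
                        sub["pvalue"].to_numpy()))
    ranked_truth = truth[idx[order]]
    for q in percentages:
        k = max(1, int(np.ceil(q / 100.0 * idx.size)))
        out[int(q)] = float(np.mean(ranked_truth[:k]))
    return out


def evaluation_report(results: pd.DataFrame, truth,
                      nominal_grid=(0.01, 0.05, 0.1, 0.15, 0.2),
                      percentages=DEFAULT_PERCENTAGES,
                      fdr_cut: float = 0.05,
                      lfc_cut: float = 0.5) -> pd.DataFrame:
    """Tidy single-replicate report: TPR, FDP, observed FDR per nominal
    level, and TDR per top percentage."""
    truth = np.asarray(truth, dtype=bool)
    calls = call_differential(results, fdr_cut, lfc_cut)
    tpr, fdp = confusion_metrics(calls, truth)
    rows = [{"metric": "tpr", "level": fdr_cut, "value": tpr},
            {"metric": "fdp", "level": fdr_cut, "value": fdp}]
    curve = fdr_curve([results["pvalue"].to_numpy()], [truth], nominal_grid)
    for _, r in curve.iterrows():
        rows.append({"metric": "observed_fdr", "level": r["nominal"],
                     "value": r["observed_fdr"]})
    for q, v in tdr_at_top(results, truth, percentages, fdr_cut,
                           lfc_cut).items():
        rows.append({"metric": "tdr", "level": q, "value": v})
    return pd.DataFrame(rows)
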
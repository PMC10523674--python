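"""Benchmarking calibrations and comparing methods statistically.

Four metrics grade a finished characterization of one nerve: the number of
delivered stimulation trains, the injected charge Q = PA*PW at each found
level, the sensation quality index, and a proxy mapping time (stimulus
count times a per-stimulus time constant -- simulated runs have no
meaningful wall clock).

Method comparison follows standard nonparametric practice for small paired
designs: a Kolmogorov-Smirnov normality screen (reported only; the pipeline
stays nonparametric regardless), a Friedman omnibus test per metric, then
pairwise Wilcoxon signed-rank tests at a Bonferroni-corrected threshold
(0.05 / number of pairs; 0.0083 for four methods).  Healthy versus
neuropathic cohorts are independent groups and use Mann-Whitney U.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Intensity, QualityWeights, quality_index
from .calibration import (
    CalibrationLimits,
    CalibrationResult,
    VirtualResponder,
    bfa_calibrate,
    run_calibration,
    scripted_naive_calibrate,
)

__all__ = [
    "score_result",
    "proxy_time",
    "compare_methods",
    "compare_groups",
    "run_benchmark",
    "summarize_records",
]


def score_result(
    result: CalibrationResult,
    target: Intensity = Intensity.HIGH,
    weights: QualityWeights = QualityWeights(),
) -> float:
    """Sensation quality index of a calibration's final high-level report.

    A calibration that never produced a final report scores 0; one that
    finished without reaching the target intensity scores with I = 0 but
    keeps credit for comfort and somatotopy.
    """
    r = result.high_report
    if r is None:
        return 0.0
    reached = int(r.intensity == target and result.converged_high)
    return quality_index(
        reached, int(r.stype), int(r.location), r.se, weights
    )


def proxy_time(result: CalibrationResult, t_stim: float = 5.0, t_report: float = 15.0) -> float:
    """Simulation proxy of mapping time (s): n_stims * (t_stim + t_report).

    Not a wall-clock measurement -- a bookkeeping constant per stimulus
    (train delivery plus the subject's report).
    """
    if t_stim <= 0 or t_report <= 0:
        raise ValueError("time constants must be positive")
    return result.n_stims * (t_stim + t_report)


METRICS = ("n_stims", "low_charge", "high_charge", "quality", "proxy_time")


def compare_methods(
    records: pd.DataFrame,
    metrics=("n_stims", "quality", "proxy_time"),
    alpha: float = 0.05,
) -> dict:
    """Nonparametric comparison of calibration methods on paired records.

    ``records`` must hold one row per subject x nerve x method.  Returns a
    dict of DataFrames: ``normality`` (KS screen), ``friedman`` (omnibus per
    metric) and ``pairwise`` (Wilcoxon signed-rank with Bonferroni-corrected
    significance flags).
    """
    methods = sorted(records["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    n_pairs = len(methods) * (len(methods) - 1) // 2
    threshold = alpha / n_pairs
    normality_rows, friedman_rows, pairwise_rows = [], [], []
    for metric in metrics:
        wide = records.pivot_table(
            index=["subject_id", "nerve"], columns="method", values=metric
        )
        missing = wide.isna()
        if missing.any().any():
            cell = missing.stack()
            bad = cell[cell].index[0]
            raise ValueError(f"missing record for subject x nerve x method = {bad}")
        for m in methods:
            x = wide[m].to_numpy(float)
            sd = x.std(ddof=1)
            if sd > 0:
                stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
            else:
                stat, p = np.nan, np.nan
            normality_rows.append(
                {"metric": metric, "method": m, "ks_stat": stat, "p": p}
            )
        if len(methods) >= 3:
            fr = stats.friedmanchisquare(*[wide[m] for m in methods])
            friedman_rows.append(
                {"metric": metric, "statistic": fr.statistic, "p": fr.pvalue}
            )
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                diff = wide[a].to_numpy(float) - wide[b].to_numpy(float)
                if np.allclose(diff, 0.0):
                    stat, p = 0.0, 1.0
                else:
                    res = stats.wilcoxon(
                        wide[a], wide[b], zero_method="wilcox", mode="auto"
                    )
                    stat, p = res.statistic, res.pvalue
                pairwise_rows.append(
                    {
                        "metric": metric,
                        "method_a": a,
                        "method_b": b,
                        "statistic": stat,
                        "p": p,
                        "threshold": threshold,
                        "significant": bool(p < threshold),
                    }
                )
    return {
        "normality": pd.DataFrame(normality_rows),
        "friedman": pd.DataFrame(friedman_rows),
        "pairwise": pd.DataFrame(pairwise_rows),
        "threshold": threshold,
    }


def compare_groups(x, y) -> dict:
    """Mann-Whitney U for two independent groups (healthy vs neuropathic)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def _record(subject, method: str, result: CalibrationResult, seed: int) -> dict:
    from .core import charge as q

    return {
        "subject_id": subject.subject_id,
        "nerve": subject.nerve,
        "method": method,
        "n_stims": result.n_stims,
        "low_charge": q(result.low_params) if result.converged_low else np.nan,
        "high_charge": q(result.high_params) if result.converged_high else np.nan,
        "quality": score_result(result),
        "proxy_time": proxy_time(result),
        "converged_low": result.converged_low,
        "converged_high": result.converged_high,
        "seed": seed,
    }


def run_benchmark(
    cohort,
    agent_low,
    agent_high,
    dataset: pd.DataFrame,
    methods=("RL", "BFA", "naive"),
    limits: CalibrationLimits = CalibrationLimits(),
    seed: int = 0,
) -> pd.DataFrame:
    """Run every requested calibration method on every cohort member.

    Method failures are recorded (non-converged rows), never raised.
    Returns one BenchmarkRecord row per subject x method.
    """
    rows = []
    for subject in cohort:
        responder = VirtualResponder(subject)
        for method in methods:
            if method == "RL":
                result = run_calibration(
                    agent_low, agent_high, responder, dataset, limits
                )
            elif method == "BFA":
                result = bfa_calibrate(responder, dataset, limits)
            elif method == "naive":
                result = scripted_naive_calibrate(responder, limits)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(_record(subject, method, result, seed))
    return pd.DataFrame(rows)


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean +/- SD of every metric, to two decimals."""
    out = []
    for method, grp in records.groupby("method"):
        row = {"method": method}
        for metric in METRICS:
            x = grp[metric].dropna()
            row[f"{metric}_mean"] = round(float(x.mean()), 2) if len(x) else np.nan
            row[f"{metric}_sd"] = round(float(x.std(ddof=1)), 2) if len(x) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def records_markdown(records: pd.DataFrame) -> str:
    """Summary report: per-method means +/- SD in a Markdown table."""
    summary = summarize_records(records)
    lines = ["| method | " + " | ".join(METRICS) + " |",
             "|" + "---|" * (len(METRICS) + 1)]
    for _, row in summary.iterrows():
        cells = [
            f"{row[f'{m}_mean']} ± {row[f'{m}_sd']}" for m in METRICS
        ]
        lines.append("| " + row["method"] + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)
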
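"""Noise tolerance of the developing-line fit.

Microarray time courses carry measurement noise; this module measures how
far the fitted line can be corrupted before test-sample projections
change.  A growing fraction of probes in the line-construction course is
randomly replaced (by default with draws from the same time point's
empirical value distribution, which destroys per-gene temporal signal
while preserving each column's marginal), the line is re-fitted, a test
dataset is re-projected, and stability is summarised by the Spearman
correlation of the projected positions against the unperturbed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .devline import DevelopingLineModel, TimeCourse
from .expr_io import ExpressionDataset

__all__ = [
    "perturb_timecourse",
    "robustness_curve",
    "tolerated_fraction",
    "RobustnessCurve",
]


def perturb_timecourse(tc: TimeCourse, fraction: float, seed: int,
                       scheme: str = "column-resample") -> TimeCourse:
    """Randomly replace a fraction of probes' values (seeded, bit-stable).

    ``round(fraction * n)`` probes are chosen uniformly at random.  Under
    ``scheme="column-resample"`` each chosen probe's value at every time
    point is replaced by a draw (with replacement) from that time point's
    full empirical distribution; under ``scheme="time-permute"`` the
    chosen probe's own values are permuted across time points.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if scheme not in ("column-resample", "time-permute"):
        raise ValueError(f"unknown scheme {scheme!r}")
    vals = tc.values.to_numpy(dtype=float, copy=True)
    n, t = vals.shape
    k = round(fraction * n)
    if k == 0:
        return TimeCourse(values=tc.values.copy())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    if scheme == "column-resample":
        for j in range(t):
            vals[chosen, j] = rng.choice(tc.values.iloc[:, j].to_numpy(),
                                         size=k, replace=True)
    else:
        for i in chosen:
            vals[i, :] = rng.permutation(vals[i, :])
    return TimeCourse(values=pd.DataFrame(vals, index=tc.values.index.copy(),
                                          columns=tc.values.columns.copy()))


@dataclass
class RobustnessCurve:
    """Per-fraction stability summary of projections under perturbation.

    ``summary`` has one row per fraction with the median/mean Spearman
    correlation against the unperturbed projections and the mean
    across-replicate projection variance (averaged over samples);
    ``projections`` holds every (fraction, replicate, sample, projection)
    record; ``failures`` counts skipped replicates per fraction.
    """

    summary: pd.DataFrame
    projections: pd.DataFrame
    baseline: pd.Series
    failures: dict[float, int] = field(default_factory=dict)

    def save(self, tsv_path, json_path=None) -> None:
        self.projections.to_csv(tsv_path, sep="\t", index=False,
                                float_format="%.6g")
        if json_path is not None:
            self.summary.to_json(json_path, orient="index", indent=2)


def robustness_curve(tc: TimeCourse, test: ExpressionDataset,
                     fractions=None, replicates: int = 20, seed: int = 0,
                     scheme: str = "column-resample") -> RobustnessCurve:
    """Perturb, re-fit and re-project over a grid of replacement fractions.

    ``fractions`` defaults to 1%..20% in 1% steps.  Each fraction gets
    ``replicates`` independent perturbations; a replicate whose re-fit
    fails is recorded and skipped.
    """
    if fractions is None:
        fractions = [k / 100 for k in range(1, 21)]
    fractions = list(fractions)
    if not fractions:
        raise ValueError("need at least one fraction")
    probes = tc.values.index
    test_mat = test.values.loc[probes].to_numpy(dtype=float)
    sample_ids = list(test.values.columns)

    base_line = DevelopingLineModel(tc).fit()
    baseline = pd.Series(base_line.project(test_mat), index=sample_ids,
                         name="projection")

    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(fractions) * replicates) % (2**31)

    records = []
    rows = []
    failures: dict[float, int] = {}
    for fi, frac in enumerate(fractions):
        proj_by_rep = []
        failed = 0
        for rep in range(replicates):
            s = int(child_seeds[fi * replicates + rep])
            try:
                pline = DevelopingLineModel(
                    perturb_timecourse(tc, frac, seed=s, scheme=scheme)
                ).fit()
            except Exception:
                failed += 1
                continue
            proj = pline.project(test_mat)
            proj_by_rep.append(proj)
            for sid, p in zip(sample_ids, proj):
                records.append((frac, rep, sid, p))
        failures[frac] = failed
        if not proj_by_rep:
            rows.append((frac, np.nan, np.nan, np.nan, failed))
            continue
        arr = np.array(proj_by_rep)  # reps x samples
        if len(sample_ids) > 1:
            rhos = [stats.spearmanr(baseline.to_numpy(), row).statistic
                    for row in arr]
        else:
            rhos = [1.0] * arr.shape[0]
        rows.append((frac, float(np.median(rhos)), float(np.mean(rhos)),
                     float(arr.var(axis=0, ddof=0).mean()), failed))

    summary = pd.DataFrame(
        rows, columns=["fraction", "median_spearman", "mean_spearman",
                       "mean_projection_variance", "failures"],
    ).set_index("fraction")
    projections = pd.DataFrame(
        records, columns=["fraction", "replicate", "sample", "projection"])
    return RobustnessCurve(summary=summary, projections=projections,
                           baseline=baseline, failures=failures)


def tolerated_fraction(curve: RobustnessCurve, criterion: float = 0.95
                       ) -> float:
    """Largest perturbation fraction whose median Spearman correlation
    with the unperturbed projections stays >= ``criterion``; 0 if none."""
    s = curve.summary["median_spearman"]
    if len(s) == 0:
        raise ValueError("empty robustness curve")
    ok = s[s >= criterion]
    return float(ok.index.max()) if len(ok) else 0.0
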
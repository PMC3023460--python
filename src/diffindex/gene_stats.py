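"""Significance calls on developing-line weights.

Each probe's weight on an oriented developing line measures its expression
change along differentiation.  Weights are standardised against their own
empirical mean and standard deviation, converted to two-sided normal
p-values, and adjusted by Benjamini-Hochberg FDR; probes passing both the
p and FDR cuts are split into up- (positive weight) and down-regulated
lists.  A permutation null (re-fitting on column-shuffled time courses) is
available as an alternative to the parametric normal null.

Published cutoff presets: ``results2011`` (p < 0.01, FDR < 0.1) and
``methods2011`` (p < 0.001, FDR < 0.1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .devline import DevelopingLineModel, DevelopingLineResults, TimeCourse

__all__ = [
    "CUTOFF_PRESETS",
    "weight_significance",
    "select_significant",
    "common_genes",
    "collapse_to_genes",
]

CUTOFF_PRESETS: dict[str, dict[str, float]] = {
    "results2011": {"p_cut": 0.01, "fdr_cut": 0.1},
    "methods2011": {"p_cut": 0.001, "fdr_cut": 0.1},
}


def weight_significance(line: DevelopingLineResults, null: str = "normal",
                        n_permutations: int = 200,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-probe z, p and BH-FDR for the weights of an oriented line.

    Returns a DataFrame indexed by probe id with columns ``weight``,
    ``z``, ``p``, ``fdr``, ``direction``.  ``null="normal"`` tests the
    standardised weight against N(0, 1); ``null="permutation"`` compares
    |weight| with weights re-fitted on time courses whose values are
    independently shuffled within each probe (requires the line to carry
    its model).
    """
    if not line.oriented:
        raise ValueError("orient the line before significance testing")
    w = line.weights.to_numpy(dtype=float)
    if w.size < 3:
        raise ValueError("need at least 3 probes")
    sd = w.std(ddof=1)
    if sd == 0:
        raise ValueError("weights have zero variance")
    z = (w - w.mean()) / sd
    if null == "normal":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif null == "permutation":
        p = _permutation_pvalues(line, n_permutations, seed)
    else:
        raise ValueError(f"unknown null {null!r}")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "weight": w,
            "z": z,
            "p": p,
            "fdr": fdr,
            "direction": np.where(w > 0, "up", "down"),
        },
        index=line.weights.index.copy(),
    )
    table.index.name = "probe_id"
    return table


def _permutation_pvalues(line: DevelopingLineResults, n_permutations: int,
                         seed: int | None) -> np.ndarray:
    if line.model is None:
        raise ValueError("permutation null needs the fitted model attached")
    rng = np.random.default_rng(seed)
    tc = line.model.timecourse
    vals = tc.values.to_numpy(dtype=float)
    obs = np.abs(line.weights.to_numpy(dtype=float))
    exceed = np.ones_like(obs)  # +1 pseudo-count: p is never 0
    done = 1
    for _ in range(n_permutations):
        perm = np.take_along_axis(
            vals, rng.permuted(
                np.broadcast_to(np.arange(vals.shape[1]), vals.shape).copy(),
                axis=1),
            axis=1)
        try:
            null_line = DevelopingLineModel(
                TimeCourse(values=pd.DataFrame(perm, index=tc.values.index,
                                               columns=tc.values.columns))
            ).fit()
        except Exception:
            continue
        exceed += np.abs(null_line.weights.to_numpy(dtype=float)) >= obs
        done += 1
    return exceed / done


def select_significant(table: pd.DataFrame, p_cut: float = 0.01,
                       fdr_cut: float = 0.1,
                       preset: str | None = None
                       ) -> tuple[list[str], list[str]]:
    """Probes with p < p_cut and FDR < fdr_cut, as (up, down) id lists."""
    if preset is not None:
        cuts = CUTOFF_PRESETS[preset]
        p_cut, fdr_cut = cuts["p_cut"], cuts["fdr_cut"]
    if not (0 < p_cut < 1 and 0 < fdr_cut < 1):
        raise ValueError("cutoffs must lie in (0, 1)")
    if len(table) == 0:
        return [], []
    hit = table[(table["p"] < p_cut) & (table["fdr"] < fdr_cut)]
    up = sorted(hit.index[hit["direction"] == "up"])
    down = sorted(hit.index[hit["direction"] == "down"])
    return up, down


def common_genes(lists_a: tuple[list[str], list[str]],
                 lists_b: tuple[list[str], list[str]]
                 ) -> tuple[list[str], list[str]]:
    """Intersect two (up, down) selections: up∩up and down∩down, sorted."""
    up = sorted(set(lists_a[0]) & set(lists_b[0]))
    down = sorted(set(lists_a[1]) & set(lists_b[1]))
    return up, down


def collapse_to_genes(table: pd.DataFrame, probe_to_gene: pd.Series
                      ) -> pd.DataFrame:
    """Collapse a probe-level weight table to gene symbols, keeping the
    probe with the largest |z| per symbol.  ``probe_to_gene`` maps probe id
    to symbol; unmapped probes are dropped."""
    mapped = table.join(probe_to_gene.rename("gene"), how="inner")
    mapped = mapped.loc[mapped["gene"].notna()]
    order = mapped["z"].abs().sort_values(ascending=False).index
    mapped = mapped.loc[order]
    collapsed = mapped[~mapped["gene"].duplicated()].set_index("gene")
    return collapsed.sort_index()
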
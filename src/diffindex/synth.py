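"""Synthetic data generators with the structure the model assumes.

These emulate the three kinds of input the pipeline consumes, so every
stage can be exercised without external downloads:

* a differentiation time course — per-gene Gaussian baseline, a planted
  subset of signal genes drifting monotonically (fixed per-step magnitude,
  random sign) and i.i.d. Gaussian measurement noise;
* sample cohorts linearly interpolated between the course's
  undifferentiated and differentiated endpoints (ESC-like at mixing 0,
  fibroblast-like at 1, iPSC-like between), plus noise;
* interaction networks with planted down-linker-up seesaw motifs on
  disjoint gene triples and random background edges.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .devline import TimeCourse
from .expr_io import ExpressionDataset, _empty_annotations

__all__ = [
    "gen_timecourse",
    "gen_cohort",
    "gen_network",
    "PlantedNetwork",
]


def gen_timecourse(n_genes: int = 2000, t: int = 5, n_signal: int = 100,
                   drift_scale: float = 1.0, noise_sd: float = 0.2,
                   seed: int = 0) -> tuple[TimeCourse, list[str]]:
    """A time course with a planted monotone-drift gene subset.

    Baseline values are N(0, 1) per gene; each of the ``n_signal`` signal
    genes drifts by ``+-drift_scale`` per step (sign chosen at random);
    every measurement gets N(0, noise_sd) noise.  Returns the course and
    the planted signal-gene ids.  With ``noise_sd=0`` the course is exactly
    collinear, so the fitted line's equal-angle residual is 0.
    """
    if n_genes <= t:
        raise ValueError(f"need n_genes > t (got {n_genes} <= {t})")
    if not 0 <= n_signal <= n_genes:
        raise ValueError("n_signal must lie in [0, n_genes]")
    if t < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="probe_id")
    baseline = rng.normal(0.0, 1.0, size=n_genes)
    drift = np.zeros(n_genes)
    signal_idx = rng.choice(n_genes, size=n_signal, replace=False)
    drift[signal_idx] = drift_scale * rng.choice([-1.0, 1.0], size=n_signal)
    cols = {}
    for i in range(t):
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 \
            else 0.0
        cols[f"t{i}"] = baseline + i * drift + noise
    values = pd.DataFrame(cols, index=genes)
    planted = sorted(genes[signal_idx])
    return TimeCourse(values=values), planted


def gen_cohort(tc: TimeCourse, alphas, noise_sd: float = 0.2, seed: int = 0,
               labels=None) -> ExpressionDataset:
    """Samples interpolated between the course's endpoints.

    Sample k is ``(1 - alpha_k) * X_1 + alpha_k * X_t`` plus
    N(0, noise_sd) noise.  ``labels`` gives each sample's cell type;
    by default alpha <= 0.05 is labelled "ESC", alpha >= 0.95
    "fibroblast", anything between "iPSC".
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if np.any((alphas < 0) | (alphas > 1)):
        raise ValueError("mixing alphas must lie in [0, 1]")
    if labels is None:
        labels = ["ESC" if a <= 0.05 else "fibroblast" if a >= 0.95
                  else "iPSC" for a in alphas]
    if len(labels) != len(alphas):
        raise ValueError("alphas and labels must have the same length")
    rng = np.random.default_rng(seed)
    x1 = tc.values.iloc[:, 0].to_numpy(dtype=float)
    xt = tc.values.iloc[:, -1].to_numpy(dtype=float)
    n = len(x1)
    cols = {}
    for k, a in enumerate(alphas):
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        cols[f"S{k:03d}"] = (1.0 - a) * x1 + a * xt + noise
    values = pd.DataFrame(cols, index=tc.values.index.copy())
    ann = _empty_annotations(values.columns)
    ann["cell_type"] = list(labels)
    ann["source_dataset"] = "synthetic"
    return ExpressionDataset(values=values, sample_annotations=ann)


@dataclass
class PlantedNetwork:
    """A generated network with its planted-motif ground truth."""

    graph: nx.Graph
    motifs: list[tuple[str, str, str]]  # (down, linker, up) triples


def gen_network(up: list[str], down: list[str], unchanged: list[str],
                n_motifs: int, n_background_edges: int = 0, seed: int = 0
                ) -> PlantedNetwork:
    """Plant ``n_motifs`` disjoint down-linker-up paths plus background.

    Each motif takes one fresh gene from ``down``, ``unchanged`` and
    ``up`` and wires down-linker and linker-up edges.  Background edges
    are sampled uniformly over remaining gene pairs, rejecting (where
    possible) edges that would complete a new motif around an unplanted
    linker.
    """
    if n_motifs > min(len(up), len(down), len(unchanged)):
        raise ValueError(
            f"cannot plant {n_motifs} disjoint motifs from "
            f"{len(down)} down / {len(unchanged)} unchanged / {len(up)} up "
            "genes"
        )
    rng = np.random.default_rng(seed)
    up, down, unchanged = sorted(up), sorted(down), sorted(unchanged)
    g = nx.Graph()
    g.add_nodes_from(up + down + unchanged)
    motifs = []
    for i in range(n_motifs):
        d, l, u = down[i], unchanged[i], up[i]
        g.add_edge(d, l)
        g.add_edge(l, u)
        motifs.append((d, l, u))
    state = {**{x: "up" for x in up}, **{x: "down" for x in down},
             **{x: "unchanged" for x in unchanged}}
    planted_linkers = {m[1] for m in motifs}
    nodes = sorted(g.nodes)
    added = 0
    attempts = 0
    max_attempts = 50 * max(n_background_edges, 1)
    while added < n_background_edges and attempts < max_attempts:
        attempts += 1
        a, b = (nodes[i] for i in rng.choice(len(nodes), size=2,
                                             replace=False))
        if g.has_edge(a, b):
            continue
        if _completes_new_motif(g, state, planted_linkers, a, b):
            continue
        g.add_edge(a, b)
        added += 1
    # fall back to unconstrained edges if rejection exhausted the budget
    max_edges = len(nodes) * (len(nodes) - 1) // 2
    while added < n_background_edges and g.number_of_edges() < max_edges:
        a, b = (nodes[i] for i in rng.choice(len(nodes), size=2,
                                             replace=False))
        if not g.has_edge(a, b):
            g.add_edge(a, b)
            added += 1
    return PlantedNetwork(graph=g, motifs=motifs)


def _completes_new_motif(g: nx.Graph, state: dict[str, str],
                         planted_linkers: set[str], a: str, b: str) -> bool:
    for x, y in ((a, b), (b, a)):
        if state[x] != "unchanged" or x in planted_linkers or \
                state[y] not in ("up", "down"):
            continue
        have = {state[nb] for nb in g[x] if state[nb] in ("up", "down")}
        have.add(state[y])
        if "up" in have and "down" in have:
            return True
    return False
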
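"""The 2-D differentiation-index coordinate and the distance index.

Two developing lines fitted to different differentiation processes form
the axes of a plane; every expression profile is placed on it by its two
projections.  Cell-type regions are summarised by per-axis mean and
standard deviation, and each sample's *distance index* (Di) compares its
Euclidean distances to the ESC-region and fibroblast-region centres:

    Di = d_ES / (d_ES + d_Fib)

so Di = 0 at the ESC centre, 1 at the fibroblast centre, and smaller
values mean more ESC-like.  The mean Di of all ESC samples serves as the
pass/fail threshold for scoring induced pluripotent cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .devline import DevelopingLineResults, project
from .expr_io import ExpressionDataset

__all__ = [
    "DifferentiationCoordinate",
    "DistanceIndexResults",
    "Region",
    "build_coordinate",
    "place_samples",
    "summarize_regions",
    "distance_index",
    "esc_threshold",
    "classify",
]


@dataclass
class Region:
    """Per-axis mean/sd summary of one cell type's projection region."""

    cell_type: str
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    count: int

    @property
    def center(self) -> tuple[float, float]:
        return (self.mean_x, self.mean_y)


class DifferentiationCoordinate:
    """A 2-D coordinate whose axes are two developing lines.

    Both lines are restricted to their common probes (lexicographic
    order) before any projection; weights are never re-fitted.
    """

    def __init__(self, line_x: DevelopingLineResults,
                 line_y: DevelopingLineResults,
                 name_x: str = "axis_x", name_y: str = "axis_y",
                 warn_fraction: float = 0.9) -> None:
        common = line_x.weights.index.intersection(line_y.weights.index)
        if len(common) == 0:
            raise ValueError("the two lines share no probes")
        common = common.sort_values()
        for name, line in ((name_x, line_x), (name_y, line_y)):
            frac = len(common) / line.n_probes
            if frac < warn_fraction:
                warnings.warn(
                    f"probe intersection covers {frac:.1%} of {name}'s "
                    f"probes (< {warn_fraction:.0%})",
                    stacklevel=2,
                )
        self.probe_ids: list[str] = list(common)
        self.axis_x = line_x.restrict(common)
        self.axis_y = line_y.restrict(common)
        self.name_x = name_x
        self.name_y = name_y

    def place_samples(self, ds: ExpressionDataset,
                      missing_fraction: float = 0.1) -> pd.DataFrame:
        """Project every sample of ``ds`` onto both axes.

        Returns a DataFrame indexed by sample id with columns
        ``cell_type``, ``source_dataset``, ``x``, ``y``.  Probes missing
        from ``ds`` beyond ``missing_fraction`` of the coordinate's probes
        raise an error; below that, the coordinate is restricted (with a
        warning) to the probes present.
        """
        probes = pd.Index(self.probe_ids)
        present = probes.intersection(ds.values.index)
        n_missing = len(probes) - len(present)
        if n_missing:
            if n_missing > missing_fraction * len(probes):
                raise ValueError(
                    f"dataset lacks {n_missing}/{len(probes)} coordinate "
                    "probes"
                )
            warnings.warn(
                f"dataset lacks {n_missing} coordinate probes; projecting "
                "on the common subset",
                stacklevel=2,
            )
            ax, ay = self.axis_x.restrict(present), self.axis_y.restrict(present)
            probes = present
        else:
            ax, ay = self.axis_x, self.axis_y
        mat = ds.values.loc[list(probes)].to_numpy(dtype=float)
        pts = pd.DataFrame(index=ds.values.columns.copy())
        ann = ds.sample_annotations
        pts["cell_type"] = ann["cell_type"].to_numpy()
        pts["source_dataset"] = ann["source_dataset"].to_numpy()
        pts["x"] = project(ax, mat)
        pts["y"] = project(ay, mat)
        return pts

    def score(self, ds: ExpressionDataset, esc_label: str = "ESC",
              fib_label: str = "fibroblast", form: str = "normalized",
              threshold: float | None = None) -> "DistanceIndexResults":
        """Place samples, anchor the ESC/fibroblast centres, and compute
        every sample's distance index and pass/fail call.

        The anchors are the mean (x, y) of all samples carrying
        ``esc_label`` / ``fib_label``; the threshold, unless given, is the
        mean Di of the ESC samples.
        """
        points = self.place_samples(ds)
        return score_points(points, esc_label=esc_label, fib_label=fib_label,
                            form=form, threshold=threshold)

    def plot(self, points: pd.DataFrame, regions=None, ax=None,
             n_sd: float = 1.0):
        """Scatter the placed samples with per-cell-type 1-sd axis-aligned
        region ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        if regions is None:
            regions = summarize_regions(points)
        cmap = plt.get_cmap("tab10")
        labels = sorted(points["cell_type"].unique())
        for k, label in enumerate(labels):
            sub = points[points["cell_type"] == label]
            ax.scatter(sub["x"], sub["y"], s=18, label=label or "(unlabeled)",
                       color=cmap(k % 10))
        for region in regions:
            k = labels.index(region.cell_type)
            ax.add_patch(Ellipse(region.center, 2 * n_sd * region.sd_x,
                                 2 * n_sd * region.sd_y, fill=False,
                                 edgecolor=cmap(k % 10), linestyle="--"))
        ax.set_xlabel(self.name_x)
        ax.set_ylabel(self.name_y)
        ax.legend(fontsize=8)
        return ax


def build_coordinate(line_x: DevelopingLineResults,
                     line_y: DevelopingLineResults,
                     name_x: str = "axis_x", name_y: str = "axis_y"
                     ) -> DifferentiationCoordinate:
    """Functional constructor for :class:`DifferentiationCoordinate`."""
    return DifferentiationCoordinate(line_x, line_y, name_x, name_y)


def place_samples(coord: DifferentiationCoordinate, ds: ExpressionDataset
                  ) -> pd.DataFrame:
    return coord.place_samples(ds)


def summarize_regions(points: pd.DataFrame) -> list[Region]:
    """Per-cell-type projection regions: mean and sample sd (ddof=1) on
    each axis; a single-sample region gets sd 0 with a warning."""
    if len(points) == 0:
        raise ValueError("no sample points to summarise")
    regions = []
    for label, sub in points.groupby("cell_type", sort=True):
        n = len(sub)
        if n == 1:
            warnings.warn(
                f"cell type {label!r} has a single sample; sd set to 0",
                stacklevel=2,
            )
        regions.append(Region(
            cell_type=str(label),
            mean_x=float(sub["x"].mean()),
            mean_y=float(sub["y"].mean()),
            sd_x=float(sub["x"].std(ddof=1)) if n > 1 else 0.0,
            sd_y=float(sub["y"].std(ddof=1)) if n > 1 else 0.0,
            count=n,
        ))
    return regions


def distance_index(point, esc_center, fib_center,
                   form: str = "normalized") -> float:
    """Distance index of one (x, y) point given the two anchor centres.

    ``form="normalized"`` (default): d_ES / (d_ES + d_Fib), in [0, 1].
    ``form="ratio"``: the unnormalised d_ES / d_Fib.
    """
    p = np.asarray(point, dtype=float)[:2] if not hasattr(point, "x") else \
        np.array([point.x, point.y], dtype=float)
    e = np.asarray(esc_center, dtype=float)
    f = np.asarray(fib_center, dtype=float)
    if np.allclose(e, f):
        raise ValueError("ESC and fibroblast anchors coincide")
    d_es = float(np.linalg.norm(p - e))
    d_fib = float(np.linalg.norm(p - f))
    if form == "normalized":
        return d_es / (d_es + d_fib)
    if form == "ratio":
        if d_fib == 0:
            raise ZeroDivisionError("point at the fibroblast anchor")
        return d_es / d_fib
    raise ValueError(f"unknown distance-index form {form!r}")


def esc_threshold(esc_points: pd.DataFrame, esc_center, fib_center,
                  form: str = "normalized") -> float:
    """Mean distance index over the ESC samples — the pass/fail cut."""
    if len(esc_points) == 0:
        raise ValueError("no ESC points; cannot set a threshold")
    dis = [distance_index((r.x, r.y), esc_center, fib_center, form=form)
           for r in esc_points.itertuples()]
    return float(np.mean(dis))


def classify(di: float, threshold: float) -> str:
    """'pass' when di <= threshold (boundary inclusive), else 'fail'."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return "fail" if di > threshold else "pass"


@dataclass
class DistanceIndexResults:
    """Distance-index scores for a cohort of placed samples.

    ``table`` has one row per sample: cell_type, source_dataset, x, y,
    di, call.  The threshold is the mean ESC Di unless overridden.
    """

    table: pd.DataFrame
    esc_center: tuple[float, float]
    fib_center: tuple[float, float]
    threshold: float
    form: str = "normalized"
    regions: list[Region] = field(default_factory=list)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Distance-index report",
            "=" * 62,
            f"samples: {len(t)}   form: {self.form}",
            f"ESC anchor:        ({self.esc_center[0]:.4g}, {self.esc_center[1]:.4g})",
            f"fibroblast anchor: ({self.fib_center[0]:.4g}, {self.fib_center[1]:.4g})",
            f"threshold (mean ESC Di): {self.threshold:.5f}",
            "",
            f"{'sample':<24}{'cell_type':<14}{'Di':>10}  call",
        ]
        for r in t.itertuples():
            lines.append(
                f"{str(r.Index):<24}{str(r.cell_type):<14}{r.di:>10.5f}  {r.call}"
            )
        by = t.groupby("cell_type")["call"].apply(
            lambda s: f"{(s == 'pass').sum()}/{len(s)} pass")
        lines.append("")
        lines.extend(f"{k}: {v}" for k, v in by.items())
        return "\n".join(lines)

    def save(self, tsv_path, json_path=None) -> None:
        self.table.to_csv(tsv_path, sep="\t", float_format="%.6g",
                          index_label="sample_id")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump({
                    "esc_center": list(self.esc_center),
                    "fib_center": list(self.fib_center),
                    "threshold": self.threshold,
                    "form": self.form,
                }, fh, indent=2)


def score_points(points: pd.DataFrame, esc_label: str = "ESC",
                 fib_label: str = "fibroblast", form: str = "normalized",
                 threshold: float | None = None) -> DistanceIndexResults:
    """Anchor ESC/fibroblast centres from labelled points and score all."""
    regions = summarize_regions(points)
    by_label = {r.cell_type: r for r in regions}
    for label in (esc_label, fib_label):
        if label not in by_label:
            raise ValueError(f"no samples labelled {label!r} to anchor on")
    esc_c = by_label[esc_label].center
    fib_c = by_label[fib_label].center
    table = points.copy()
    table["di"] = [distance_index((r.x, r.y), esc_c, fib_c, form=form)
                   for r in points.itertuples()]
    if threshold is None:
        threshold = esc_threshold(points[points["cell_type"] == esc_label],
                                  esc_c, fib_c, form=form)
    table["call"] = [classify(d, threshold) if threshold > 0
                     else ("pass" if d == 0 else "fail")
                     for d in table["di"]]
    return DistanceIndexResults(table=table, esc_center=esc_c,
                                fib_center=fib_c, threshold=threshold,
                                form=form, regions=regions)
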
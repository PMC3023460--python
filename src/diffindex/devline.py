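"""The time-ordered linear model: fitting developing lines.

A differentiation time course with expression profiles ``X_1 .. X_t`` in
gene space traces a piecewise-linear path through its segment vectors
``a_i = X_{i+1} - X_i``.  The *developing line* is the co-bisector of these
segments: the direction ``v`` in span{a_i} making the same angle with every
segment.  Projecting the time points onto ``v`` then preserves both their
order and the ratios of consecutive distances, and among all equal-angle
bisectors the in-span one maximises the common cosine, so it is the
single linear axis that best represents the differentiation direction.

The co-bisector is written as ``v = sum_j lambda_j a_j`` with ``lambda_1``
fixed to 1 (the choice only rescales ``v``); the equal-angle condition
``<a_i, v> / |a_i| = c`` for all ``i`` gives a linear system in
``lambda_2 .. lambda_{t-1}`` and ``c``, solved by minimal-norm least
squares so that rank-deficient (e.g. collinear) courses still yield the
unique normalised direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeCourse",
    "TimeCourseError",
    "FitError",
    "segment_vectors",
    "DevelopingLineModel",
    "DevelopingLineResults",
    "fit_developing_line",
    "project",
    "orient_line",
    "load_line",
]


class TimeCourseError(ValueError):
    """Raised for invalid time-course input."""


class FitError(RuntimeError):
    """Raised when the equal-angle system cannot be satisfied."""


@dataclass
class TimeCourse:
    """A time-ordered, log-scale expression matrix (n probes x t stages).

    Requires ``t >= 2`` and more probes than time points, and no two
    consecutive stages identical (every segment vector must have positive
    norm; average replicates upstream before constructing the course).
    """

    values: pd.DataFrame  # probes x time stages, in time order

    def __post_init__(self) -> None:
        n, t = self.values.shape
        if t < 2:
            raise TimeCourseError(f"need at least 2 time points, got {t}")
        if n <= t:
            raise TimeCourseError(
                f"need more probes than time points (n={n}, t={t})"
            )
        if self.values.index.has_duplicates:
            raise TimeCourseError("duplicate probe ids in time course")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise TimeCourseError("time course contains non-finite values")
        seg = np.diff(vals, axis=1)
        norms = np.linalg.norm(seg, axis=0)
        if np.any(norms == 0):
            i = int(np.argmin(norms))
            raise TimeCourseError(
                f"time points {i} and {i + 1} are identical; average "
                "replicates before fitting"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def time_labels(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataset(cls, ds, time_order=None) -> "TimeCourse":
        """Build a course from an ExpressionDataset, ordered by time_index
        annotations or by an explicit ``time_order`` list of sample ids."""
        if time_order is None:
            ti = ds.sample_annotations["time_index"]
            if ti.isna().any():
                raise TimeCourseError(
                    "dataset lacks time_index annotations; pass time_order"
                )
            time_order = list(ti.sort_values().index)
        return cls(values=ds.values[list(time_order)])


def segment_vectors(tc: TimeCourse) -> np.ndarray:
    """Head-to-tail segment vectors a_i = X_{i+1} - X_i, shape (n, t-1).

    Invariant to adding any constant profile to every stage.
    """
    return np.diff(tc.values.to_numpy(dtype=float), axis=1)


@dataclass
class DevelopingLineResults:
    """A fitted developing line (the co-bisector) and its diagnostics.

    Attributes
    ----------
    weights : pandas.Series
        Per-probe coefficient of the co-bisector ``v``; the magnitude
        measures how much the probe changes along differentiation, the sign
        (on an oriented line) whether it goes up or down.
    lambdas : numpy.ndarray
        Combination coefficients over the segments, ``lambdas[0] == 1``.
    cosine_constant : float
        The common value ``c = <a_i, v> / |a_i|``.
    segment_norms : numpy.ndarray
        ``|a_i|`` for each segment.
    residual : float
        Max relative deviation from the equal-angle condition.
    oriented : bool
        True when projections increase with time along the course.
    """

    weights: pd.Series
    lambdas: np.ndarray
    cosine_constant: float
    segment_norms: np.ndarray
    residual: float
    oriented: bool
    time_labels: list[str] = field(default_factory=list)
    model: "DevelopingLineModel | None" = field(default=None, repr=False)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def n_probes(self) -> int:
        return len(self.weights)

    def project(self, sample) -> float | np.ndarray:
        """Project expression profile(s) onto the line: P = <s, v>/|v|."""
        return project(self, sample)

    def restrict(self, probes) -> "DevelopingLineResults":
        """Restrict the line to a probe subset (no re-fit)."""
        idx = pd.Index(probes)
        missing = idx.difference(self.weights.index)
        if len(missing):
            raise KeyError(f"probes not on the line: {list(missing[:5])}")
        return DevelopingLineResults(
            weights=self.weights.loc[list(probes)],
            lambdas=self.lambdas.copy(),
            cosine_constant=self.cosine_constant,
            segment_norms=self.segment_norms.copy(),
            residual=self.residual,
            oriented=self.oriented,
            time_labels=list(self.time_labels),
        )

    def weight_significance(self, **kwargs) -> pd.DataFrame:
        from . import gene_stats

        return gene_stats.weight_significance(self, **kwargs)

    def summary(self) -> str:
        lines = [
            "Developing line (time-ordered linear model, co-bisector fit)",
            "=" * 62,
            f"probes:            {self.n_probes}",
            f"time points:       {len(self.segment_norms) + 1}"
            + (f"  ({' -> '.join(self.time_labels)})" if self.time_labels else ""),
            f"cosine constant c: {self.cosine_constant:.6g}",
            f"|v|:               {np.linalg.norm(self.weights.to_numpy()):.6g}",
            f"equal-angle residual: {self.residual:.3e}",
            f"oriented:          {self.oriented}",
            f"lambdas:           {np.array2string(self.lambdas, precision=4)}",
            f"segment norms:     {np.array2string(self.segment_norms, precision=4)}",
        ]
        w = self.weights.abs().sort_values(ascending=False)
        lines.append("top |weight| probes: " + ", ".join(
            f"{p} ({self.weights[p]:+.3g})" for p in w.index[:5]))
        return "\n".join(lines)

    def save(self, weights_path, sidecar_path) -> None:
        """Serialise as a (probe_id, weight) TSV plus a JSON sidecar."""
        self.weights.rename("weight").to_csv(weights_path, sep="\t",
                                             float_format="%.12g")
        meta = {
            "lambdas": [float(x) for x in self.lambdas],
            "cosine_constant": float(self.cosine_constant),
            "segment_norms": [float(x) for x in self.segment_norms],
            "residual": float(self.residual),
            "oriented": bool(self.oriented),
            "time_labels": list(self.time_labels),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_line(weights_path, sidecar_path) -> DevelopingLineResults:
    """Load a line serialised by :meth:`DevelopingLineResults.save`."""
    w = pd.read_csv(weights_path, sep="\t", index_col=0)["weight"]
    w.index = w.index.astype(str)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return DevelopingLineResults(
        weights=w.astype(float),
        lambdas=np.asarray(meta["lambdas"], dtype=float),
        cosine_constant=float(meta["cosine_constant"]),
        segment_norms=np.asarray(meta["segment_norms"], dtype=float),
        residual=float(meta["residual"]),
        oriented=bool(meta["oriented"]),
        time_labels=list(meta.get("time_labels", [])),
    )


class DevelopingLineModel:
    """Fits the co-bisector developing line to a differentiation time course.

    Parameters
    ----------
    timecourse : TimeCourse or pandas.DataFrame
        Probes x time-stages matrix in time order (log scale, normalised).

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame([[0, 1, 1], [0, 0, 1], [0, 0, 0], [0, 0, 0]],
    ...                  index=list("pqrs"), columns=["t0", "t1", "t2"])
    >>> res = DevelopingLineModel(X).fit()
    >>> [round(res.project(X[c].to_numpy()), 5) for c in X]
    [0.0, 0.70711, 1.41421]
    """

    def __init__(self, timecourse) -> None:
        if isinstance(timecourse, pd.DataFrame):
            timecourse = TimeCourse(values=timecourse)
        if not isinstance(timecourse, TimeCourse):
            raise TypeError("timecourse must be a TimeCourse or DataFrame")
        self.timecourse = timecourse

    @classmethod
    def from_dataset(cls, ds, time_order=None) -> "DevelopingLineModel":
        return cls(TimeCourse.from_dataset(ds, time_order=time_order))

    def fit(self, tolerance: float = 1e-8, orient: bool = True
            ) -> DevelopingLineResults:
        """Solve the equal-angle system and return the fitted line.

        ``tolerance`` bounds the allowed relative deviation of the
        per-segment cosines from their common value; ``orient`` flips the
        line, if needed, so projections increase with time.
        """
        tc = self.timecourse
        A = segment_vectors(tc)  # n x (t-1)
        norms = np.linalg.norm(A, axis=0)
        m = A.shape[1]
        G = A.T @ A
        # unknowns u = (lambda_2 .. lambda_m, c); lambda_1 = 1
        M = np.empty((m, m))
        M[:, : m - 1] = G[:, 1:]
        M[:, m - 1] = -norms
        b = -G[:, 0]
        sol, *_ = np.linalg.lstsq(M, b, rcond=None)
        lambdas = np.concatenate([[1.0], sol[: m - 1]])
        c = float(sol[m - 1])
        v = A @ lambdas

        cosines = (A.T @ v) / norms
        scale = max(abs(c), np.linalg.norm(v) * 1e-3, np.finfo(float).tiny)
        residual = float(np.max(np.abs(cosines - c)) / scale)
        if residual > tolerance:
            raise FitError(
                f"equal-angle condition violated: relative residual "
                f"{residual:.3e} > tolerance {tolerance:.1e}"
            )
        res = DevelopingLineResults(
            weights=pd.Series(v, index=tc.values.index.copy(), name="weight"),
            lambdas=lambdas,
            cosine_constant=c,
            segment_norms=norms,
            residual=residual,
            oriented=False,
            time_labels=tc.time_labels,
            model=self,
        )
        if orient:
            res = orient_line(res, tc)
        return res


def fit_developing_line(tc: TimeCourse, tolerance: float = 1e-8,
                        orient: bool = True) -> DevelopingLineResults:
    """Functional wrapper around :meth:`DevelopingLineModel.fit`."""
    return DevelopingLineModel(tc).fit(tolerance=tolerance, orient=orient)


def project(line: DevelopingLineResults, sample) -> float | np.ndarray:
    """Projection position P = <sample, v> / |v| on a developing line.

    ``sample`` is a vector over ``line.probe_ids`` (or a matrix with one
    column per sample).  Invariant under positive rescaling of ``v``.
    """
    v = line.weights.to_numpy(dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("line weights have zero norm")
    s = np.asarray(sample, dtype=float)
    if s.shape[0] != v.shape[0]:
        raise ValueError(
            f"sample has {s.shape[0]} probes, line has {v.shape[0]}"
        )
    p = s.T @ v / nv
    return float(p) if p.ndim == 0 else p


def orient_line(line: DevelopingLineResults, tc: TimeCourse
                ) -> DevelopingLineResults:
    """Flip the line's sign, if needed, so the course's projections
    increase with time (ESC -> differentiated); positive weights then mean
    up-regulation along differentiation."""
    P = project(line, tc.values.to_numpy(dtype=float))
    flip = P[-1] < P[0]
    weights = -line.weights if flip else line.weights.copy()
    c = -line.cosine_constant if flip else line.cosine_constant
    return DevelopingLineResults(
        weights=weights,
        lambdas=line.lambdas.copy(),
        cosine_constant=c,
        segment_norms=line.segment_norms.copy(),
        residual=line.residual,
        oriented=True,
        time_labels=list(line.time_labels),
        model=line.model,
    )
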
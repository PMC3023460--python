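"""Reading, normalising and aligning expression matrices.

Microarray intensities from different laboratories are made comparable by
log-transforming and median-centring every sample within its own dataset.
Probes are treated as independent transcripts, so cross-dataset alignment
is a plain intersection of probe identifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "ExpressionIOError",
    "read_series_matrix",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "normalize",
    "align_probes",
]


class ExpressionIOError(ValueError):
    """Raised for malformed expression files or inconsistent datasets."""


ANNOTATION_COLUMNS = ("cell_type", "source_dataset", "time_index")


@dataclass
class ExpressionDataset:
    """A probes x samples expression matrix with per-sample annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Expression matrix, rows indexed by probe id, columns by sample id.
        Log-scale after :func:`normalize`.
    platform : str
        Platform identifier (e.g. ``"GPL570"``), empty when unknown.
    sample_annotations : pandas.DataFrame
        One row per sample; columns ``cell_type``, ``source_dataset`` and
        ``time_index`` (nullable integer).
    """

    values: pd.DataFrame
    platform: str = ""
    sample_annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ExpressionIOError(f"duplicate probe ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ExpressionIOError(f"duplicate sample ids: {list(dups[:5])}")
        if self.sample_annotations is None:
            self.sample_annotations = _empty_annotations(self.values.columns)
        else:
            missing = self.sample_annotations.index.difference(self.values.columns)
            if len(missing):
                raise ExpressionIOError(
                    f"annotations reference unknown samples: {list(missing[:5])}"
                )
            self.sample_annotations = self.sample_annotations.reindex(
                self.values.columns
            )
            self.sample_annotations.index.name = "sample_id"
            for col in ANNOTATION_COLUMNS:
                if col not in self.sample_annotations.columns:
                    self.sample_annotations[col] = (
                        pd.NA if col == "time_index" else ""
                    )
            self.sample_annotations["cell_type"] = (
                self.sample_annotations["cell_type"].fillna("")
            )
            self.sample_annotations["source_dataset"] = (
                self.sample_annotations["source_dataset"].fillna("")
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_types(self) -> pd.Series:
        return self.sample_annotations["cell_type"]

    def subset_probes(self, probes) -> "ExpressionDataset":
        missing = pd.Index(probes).difference(self.values.index)
        if len(missing):
            raise ExpressionIOError(f"probes not in dataset: {list(missing[:5])}")
        return replace(self, values=self.values.loc[list(probes)])

    def normalize(self, log_base: float = 2.0, pseudocount: float = 0.0,
                  already_log: bool = False, per_dataset: bool = False
                  ) -> "ExpressionDataset":
        return normalize(self, log_base=log_base, pseudocount=pseudocount,
                         already_log=already_log, per_dataset=per_dataset)


def _empty_annotations(sample_ids) -> pd.DataFrame:
    ann = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    ann["cell_type"] = ""
    ann["source_dataset"] = ""
    ann["time_index"] = pd.array([pd.NA] * len(ann), dtype="Int64")
    return ann


def read_series_matrix(path) -> ExpressionDataset:
    """Read a GEO Series-Matrix file into an :class:`ExpressionDataset`.

    The dialect: ``!``-prefixed header lines, then a tab-separated table
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``
    whose first row holds sample ids and first column probe ids.  Values are
    returned exactly as found; no normalisation is applied.
    """
    platform = ""
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            low = line.lower()
            if low.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if low.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, False
                saw_end = True
                break
            if in_table:
                if not line.strip():
                    raise ExpressionIOError(
                        f"{path}: blank line {lineno} inside the table block"
                    )
                table_lines.append(line)
            elif line.startswith("!Series_platform_id"):
                parts = line.split("\t")
                if len(parts) > 1:
                    platform = parts[1].strip().strip('"')
    if not saw_begin:
        raise ExpressionIOError(f"{path}: no series_matrix_table_begin marker")
    if not saw_end:
        raise ExpressionIOError(
            f"{path}: table block lacks the series_matrix_table_end marker"
        )
    if len(table_lines) < 2:
        raise ExpressionIOError(f"{path}: table block has no data rows")

    header = [c.strip('"') for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    ncol = len(header)
    probes: list[str] = []
    rows: list[list[float]] = []
    for offset, line in enumerate(table_lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != ncol:
            raise ExpressionIOError(
                f"{path}: table row {offset} has {len(parts)} fields, "
                f"expected {ncol}"
            )
        probes.append(parts[0].strip('"'))
        try:
            rows.append([float(x.strip('"')) if x.strip('"') not in ("", "null", "NA")
                         else np.nan for x in parts[1:]])
        except ValueError as exc:
            raise ExpressionIOError(f"{path}: table row {offset}: {exc}") from exc
    values = pd.DataFrame(rows, index=pd.Index(probes, name="probe_id"),
                          columns=sample_ids, dtype=float)
    return ExpressionDataset(values=values, platform=platform)


def read_tsv_matrix(path, annotations=None) -> ExpressionDataset:
    """Read a plain TSV matrix (first column probe ids, first row sample ids).

    ``annotations`` optionally names a TSV with columns ``sample_id``,
    ``cell_type``, ``source_dataset``, ``time_index``; samples without a row
    keep empty labels.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = "probe_id"
    ann = None
    if annotations is not None:
        ann_tbl = pd.read_csv(annotations, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in ann_tbl.columns:
            raise ExpressionIOError(f"{annotations}: missing sample_id column")
        unknown = set(ann_tbl["sample_id"]) - set(values.columns)
        if unknown:
            raise ExpressionIOError(
                f"{annotations}: annotations for unknown samples: "
                f"{sorted(unknown)[:5]}"
            )
        ann = ann_tbl.set_index("sample_id")
        if "time_index" in ann.columns:
            ann["time_index"] = ann["time_index"].astype("Int64")
    return ExpressionDataset(values=values.astype(float), sample_annotations=ann)


def write_tsv_matrix(ds: ExpressionDataset, path, annotations=None) -> None:
    """Write the matrix (and optionally the annotations) as TSV."""
    ds.values.to_csv(path, sep="\t", float_format="%.12g")
    if annotations is not None:
        ds.sample_annotations.to_csv(annotations, sep="\t")


def normalize(ds: ExpressionDataset, log_base: float = 2.0,
              pseudocount: float = 0.0, already_log: bool = False,
              per_dataset: bool = False) -> ExpressionDataset:
    """Log-transform and median-centre an expression dataset.

    Unless ``already_log``, every value has ``pseudocount`` added and is
    log-transformed in base ``log_base``; then each sample column has its
    median subtracted (``per_dataset=True`` instead subtracts the single
    global median of the whole dataset).  The input is left unmodified and
    the operation is idempotent once the data are on the log scale.
    """
    vals = ds.values.to_numpy(dtype=float, copy=True)
    if not already_log:
        shifted = vals + pseudocount
        if np.any(shifted <= 0):
            bad = np.argwhere(shifted <= 0)[0]
            raise ExpressionIOError(
                "nonpositive value at probe "
                f"{ds.values.index[bad[0]]!r}, sample "
                f"{ds.values.columns[bad[1]]!r}; pass a pseudocount or "
                "already_log=True"
            )
        vals = np.log(shifted) / np.log(log_base)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise ExpressionIOError(
            f"non-finite value at probe {ds.values.index[bad[0]]!r}, "
            f"sample {ds.values.columns[bad[1]]!r}"
        )
    if per_dataset:
        vals = vals - np.median(vals)
    else:
        vals = vals - np.median(vals, axis=0, keepdims=True)
    out = pd.DataFrame(vals, index=ds.values.index.copy(),
                       columns=ds.values.columns.copy())
    return ExpressionDataset(values=out, platform=ds.platform,
                             sample_annotations=ds.sample_annotations.copy())


def align_probes(datasets: list[ExpressionDataset],
                 warn_fraction: float = 0.9) -> list[ExpressionDataset]:
    """Restrict datasets to their common probes, in lexicographic order.

    Emits a warning when the intersection covers less than ``warn_fraction``
    of any input's probes; raises on an empty intersection.
    """
    if not datasets:
        raise ExpressionIOError("align_probes needs at least one dataset")
    common = datasets[0].values.index
    for ds in datasets[1:]:
        common = common.intersection(ds.values.index)
    if len(common) == 0:
        raise ExpressionIOError("no probes shared by all datasets")
    common = common.sort_values()
    for k, ds in enumerate(datasets):
        frac = len(common) / ds.values.shape[0]
        if frac < warn_fraction:
            warnings.warn(
                f"probe intersection covers {frac:.1%} of dataset {k}'s "
                f"probes (< {warn_fraction:.0%})",
                stacklevel=2,
            )
    return [ds.subset_probes(common) for ds in datasets]
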
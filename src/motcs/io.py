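"""Core data containers and delimited-text readers/writers.

An :class:`OmicsMatrix` is a named samples x features table for one omics
view (mRNA expression, miRNA expression, or gene/probe-level DNA
methylation).  Expression values are nonnegative; methylation beta values
live in [0, 1]; missing entries (NaN) are permitted only in methylation
input, which is imputed downstream.
"""

from __future__ import annotations

import io as _stdlib_io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIEW_NAMES = ("mRNA", "miRNA", "methylation")


class MotcsError(ValueError):
    """Raised for malformed inputs; message names the offending item."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MotcsError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """One omics view: M samples (rows) by N named features (columns)."""

    view_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (M, N) float64; NaN marks missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise MotcsError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OmicsMatrix(self.view_name, list(sample_ids),
                           list(self.feature_ids), self.values[idx])

    def subset_features(self, feature_ids: list[str]) -> "OmicsMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return OmicsMatrix(self.view_name, list(self.sample_ids),
                           list(feature_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)


@dataclass
class SubtypeLabelSet:
    """Per-sample subtype assignments over an ordered class vocabulary."""

    sample_ids: list[str]
    class_names: list[str]
    labels: np.ndarray  # (M,) int class indices

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.class_names, "class")
        if len(self.class_names) < 2:
            raise MotcsError("need at least 2 subtype classes")
        if self.labels.shape != (len(self.sample_ids),):
            raise MotcsError("labels length does not match sample_ids")
        if self.labels.min() < 0 or self.labels.max() >= len(self.class_names):
            raise MotcsError("label index out of range of class_names")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, sample_ids: list[str]) -> "SubtypeLabelSet":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SubtypeLabelSet(list(sample_ids), list(self.class_names),
                               self.labels[idx])


@dataclass
class DriverCatalog:
    """Curated driver identifiers: coding gene symbols and miRNA ids."""

    coding_drivers: set[str] = field(default_factory=set)
    noncoding_drivers: set[str] = field(default_factory=set)

    def for_view(self, view_name: str) -> set[str]:
        """Driver namespace relevant to a view (miRNA ids vs gene symbols)."""
        if view_name == "miRNA":
            return self.noncoding_drivers
        return self.coding_drivers

    def is_empty(self) -> bool:
        return not self.coding_drivers and not self.noncoding_drivers


@dataclass
class ProbeAnnotation:
    """Methylation probe annotation table.

    Columns: probe_id, gene, dist_tss (bp; positive = upstream of the TSS on
    the gene's strand), chrom, flagged (blacklist member such as SNP probes).
    """

    table: pd.DataFrame

    REQUIRED = ("probe_id", "gene", "dist_tss", "chrom", "flagged")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise MotcsError(f"probe annotation missing columns: {missing}")
        _check_unique(list(self.table["probe_id"]), "probe")


# --------------------------------------------------------------------- readers

def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path, view_name: str, sep: str | None = None,
                features_in_rows: bool = False) -> OmicsMatrix:
    """Read a delimited sample x feature matrix.

    The header row carries feature ids and the first column sample ids;
    ``features_in_rows=True`` transposes files stored the other way around
    (a common omics export layout).  Blank cells become NaN.  Missing values
    are rejected outside the methylation view, where KNN imputation applies.
    """
    if sep is None:
        sep = _sniff_sep(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise MotcsError(f"{path}: empty file")
    header = lines[0].split(sep)
    ncol = len(header)
    # duplicates must be caught on the raw text: pandas would mangle them
    _check_unique(header[1:], "column")
    _check_unique([ln.split(sep, 1)[0] for ln in lines[1:]], "row")
    for lineno, ln in enumerate(lines[1:], start=2):
        if len(ln.split(sep)) != ncol:
            raise MotcsError(f"{path}: ragged row at line {lineno} "
                             f"({len(ln.split(sep))} fields, expected {ncol})")
    df = pd.read_csv(_stdlib_io.StringIO("\n".join(lines)), sep=sep,
                     index_col=0)
    if features_in_rows:
        df = df.T
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    m = OmicsMatrix(view_name, sample_ids, feature_ids,
                    df.to_numpy(dtype=np.float64))
    if view_name != "methylation" and m.has_missing():
        raise MotcsError(
            f"{path}: missing values are only accepted in methylation input")
    return m


def write_matrix(m: OmicsMatrix, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def read_labels(path, sep: str | None = None) -> SubtypeLabelSet:
    """Read a two-column (sample_id, subtype) table; class order = first
    appearance order in the file."""
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise MotcsError(f"{path}: label file needs >= 2 columns")
    samples = [str(s) for s in df.iloc[:, 0]]
    subtype = [str(s) for s in df.iloc[:, 1]]
    class_names: list[str] = []
    for s in subtype:
        if s not in class_names:
            class_names.append(s)
    labels = np.array([class_names.index(s) for s in subtype])
    return SubtypeLabelSet(samples, class_names, labels)


def write_labels(labels: SubtypeLabelSet, path, sep: str = "\t") -> None:
    pd.DataFrame({
        "sample_id": labels.sample_ids,
        "subtype": [labels.class_names[i] for i in labels.labels],
    }).to_csv(path, sep=sep, index=False)


def read_driver_catalog(coding_path=None, noncoding_path=None) -> DriverCatalog:
    """Read one-identifier-per-line driver lists (whitespace-trimmed,
    deduplicated); either path may be None for an empty set."""

    def _read(path) -> set[str]:
        if path is None:
            return set()
        with open(path) as fh:
            return {ln.strip() for ln in fh if ln.strip()}

    return DriverCatalog(_read(coding_path), _read(noncoding_path))


def write_driver_catalog(catalog: DriverCatalog, coding_path,
                         noncoding_path) -> None:
    for path, ids in ((coding_path, catalog.coding_drivers),
                      (noncoding_path, catalog.noncoding_drivers)):
        with open(path, "w") as fh:
            for x in sorted(ids):
                fh.write(x + "\n")


def read_probe_annotation(path, sep: str | None = None) -> ProbeAnnotation:
    if sep is None:
        sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    df["flagged"] = df["flagged"].astype(bool)
    return ProbeAnnotation(df)


def write_probe_annotation(ann: ProbeAnnotation, path, sep: str = "\t") -> None:
    ann.table.to_csv(path, sep=sep, index=False)


# ------------------------------------------------------------------- alignment

def align_views(views: list[OmicsMatrix],
                labels: SubtypeLabelSet) -> tuple[list[OmicsMatrix],
                                                  SubtypeLabelSet]:
    """Restrict all views and labels to samples with complete multi-omics
    profiles, ordered as in the label set."""
    if not views:
        raise MotcsError("align_views needs at least one view")
    common = set(labels.sample_ids)
    for v in views:
        common &= set(v.sample_ids)
    if not common:
        raise MotcsError("no sample is present in every view and the labels")
    ordered = [s for s in labels.sample_ids if s in common]
    return ([v.subset_samples(ordered) for v in views], labels.subset(ordered))
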
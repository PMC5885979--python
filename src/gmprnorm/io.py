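"""Reading, validating and writing count tables, labels and size factors.

The in-memory contract is :class:`CountTable`: a feature-by-sample matrix of
non-negative integer counts (``c_ki`` = count of feature *k* in sample *i*)
with unique feature and sample identifiers.  The dense on-disk dialect is
features-in-rows with a header row of sample ids, tab- or comma-separated —
the dominant OTU-table convention.  Sparse input uses matrix-market
coordinate triplets plus two sidecar id files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import ValidationError

__all__ = [
    "CountTable",
    "SampleLabels",
    "SizeFactors",
    "read_count_table",
    "write_count_table",
    "read_labels",
    "write_size_factors",
    "read_size_factors",
    "normalize_counts",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(x for x in ids if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class CountTable:
    """Feature × sample matrix of non-negative counts.

    Parameters
    ----------
    feature_ids : unique row identifiers (OTUs, genes, taxa).
    sample_ids : unique column identifiers.
    counts : ``(q, n)`` array; non-negative, integral unless
        ``allow_real`` was set (pre-normalized input; rejected by the
        simulators and by any operation requiring raw counts).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    allow_real: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if counts.shape[0] < 1:
            raise ValidationError("a count table needs at least one feature")
        if not np.all(np.isfinite(counts.astype(float))):
            bad = np.argwhere(~np.isfinite(counts.astype(float)))[0]
            raise ValidationError(
                f"non-finite entry at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if self.allow_real:
            self.counts = counts.astype(float)
        else:
            rounded = np.rint(counts.astype(float))
            if not np.array_equal(rounded, counts.astype(float)):
                bad = np.argwhere(rounded != counts.astype(float))[0]
                raise ValidationError(
                    f"non-integer count at feature {self.feature_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r} "
                    "(pass allow_real=True for pre-normalized input)"
                )
            self.counts = counts.astype(np.int64)

    # -- conveniences -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def prevalence(self) -> np.ndarray:
        """Fraction of samples in which each feature is nonzero."""
        return (self.counts > 0).mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, allow_real: bool = False) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy(), allow_real=allow_real)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            self.counts[:, idx],
            allow_real=self.allow_real,
        )


@dataclass
class SampleLabels:
    """Per-sample categorical labels (group for DAA, subject for ICC)."""

    sample_ids: list[str]
    group: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.group = [str(g) for g in self.group]
        if len(self.group) != len(self.sample_ids):
            raise ValidationError("labels and sample ids differ in length")

    def aligned_to(self, table: CountTable) -> "SampleLabels":
        """Reorder labels to match a table's sample order; error on mismatch."""
        mapping = dict(zip(self.sample_ids, self.group))
        missing = [s for s in table.sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples without labels: {missing[:5]}")
        return SampleLabels(list(table.sample_ids), [mapping[s] for s in table.sample_ids])

    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group:
            seen.setdefault(g, None)
        return list(seen)


@dataclass
class SizeFactors:
    """Per-sample positive scale estimates ``s_i`` with provenance.

    ``median_rescaled`` records whether the factors have been divided by
    their median so that different methods live on a common scale.
    """

    sample_ids: list[str]
    values: np.ndarray
    method: str
    median_rescaled: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValidationError("size factor vector does not match sample ids")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValidationError(f"{self.method} size factors must be finite and > 0")

    def aligned_to(self, table: CountTable) -> "SizeFactors":
        mapping = dict(zip(self.sample_ids, self.values))
        missing = [s for s in table.sample_ids if s not in mapping]
        if missing:
            raise ValidationError(f"samples without size factors: {missing[:5]}")
        return SizeFactors(
            list(table.sample_ids),
            np.array([mapping[s] for s in table.sample_ids]),
            self.method,
            self.median_rescaled,
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DELIMS = {"tsv": "\t", "csv": ","}


def _sidecar_paths(path: str | os.PathLike) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix else p
    return Path(f"{stem}.features.txt"), Path(f"{stem}.samples.txt")


def read_count_table(
    path: str | os.PathLike,
    fmt: str = "tsv",
    samples_in_rows: bool = False,
    allow_real: bool = False,
    feature_ids_path: str | os.PathLike | None = None,
    sample_ids_path: str | os.PathLike | None = None,
) -> CountTable:
    """Read a count table from disk.

    ``fmt`` is one of ``tsv``, ``csv`` (dense; first column = feature ids,
    header = sample ids) or ``mtx-triplet`` (matrix-market coordinate file
    with ``<stem>.features.txt`` / ``<stem>.samples.txt`` id sidecars,
    overridable via the two path arguments).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt in _DELIMS:
        df = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0, header=0,
                         na_filter=True, keep_default_na=True)
        if df.isna().to_numpy().any():
            raise ValidationError(f"missing values are not permitted: {path}")
        if samples_in_rows:
            df = df.T
        return CountTable.from_dataframe(df, allow_real=allow_real)
    if fmt == "mtx-triplet":
        feat_p, samp_p = _sidecar_paths(path)
        if feature_ids_path is not None:
            feat_p = Path(feature_ids_path)
        if sample_ids_path is not None:
            samp_p = Path(sample_ids_path)
        mat = scipy.io.mmread(os.fspath(path))
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        feature_ids = feat_p.read_text().split()
        sample_ids = samp_p.read_text().split()
        if samples_in_rows:
            counts = counts.T
            feature_ids, sample_ids = sample_ids, feature_ids
        return CountTable(feature_ids, sample_ids, counts, allow_real=allow_real)
    raise ValueError(f"unknown format {fmt!r}; expected tsv, csv, or mtx-triplet")


def write_count_table(table: CountTable, path: str | os.PathLike, fmt: str = "tsv") -> None:
    """Write a table so that :func:`read_count_table` reproduces it exactly."""
    path = Path(path)
    if fmt in _DELIMS:
        table.to_dataframe().to_csv(path, sep=_DELIMS[fmt], index_label="feature_id")
        return
    if fmt == "mtx-triplet":
        feat_p, samp_p = _sidecar_paths(path)
        scipy.io.mmwrite(os.fspath(path), scipy.sparse.coo_matrix(table.counts))
        feat_p.write_text("\n".join(table.feature_ids) + "\n")
        samp_p.write_text("\n".join(table.sample_ids) + "\n")
        return
    raise ValueError(f"unknown format {fmt!r}; expected tsv, csv, or mtx-triplet")


def read_labels(path: str | os.PathLike) -> SampleLabels:
    """Read two-column TSV (sample_id, group); a header line is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"label file needs two columns: {path}")
    if list(df.iloc[0, :2]) == ["sample_id", "group"]:
        df = df.iloc[1:]
    if df.iloc[:, :2].isna().to_numpy().any():
        raise ValidationError(f"missing values in label file: {path}")
    return SampleLabels(list(df.iloc[:, 0]), list(df.iloc[:, 1]))


def write_size_factors(sf: SizeFactors, path: str | os.PathLike) -> None:
    pd.DataFrame({"sample_id": sf.sample_ids, "size_factor": sf.values}).to_csv(
        path, sep="\t", index=False
    )


def read_size_factors(path: str | os.PathLike, method: str = "unknown") -> SizeFactors:
    df = pd.read_csv(path, sep="\t")
    return SizeFactors(list(df["sample_id"].astype(str)), df["size_factor"].to_numpy(), method)


def normalize_counts(table: CountTable, sf: SizeFactors) -> np.ndarray:
    """Divide each sample's counts by its size factor.

    Returns the ``(q, n)`` matrix of normalized abundances
    ``c_ki / s_i``; zeros stay zeros.
    """
    sf = sf.aligned_to(table)
    return table.counts.astype(float) / sf.values[np.newaxis, :]


def rescale_by_median(sf: SizeFactors) -> SizeFactors:
    """Divide size factors by their median, putting methods on one scale."""
    med = float(np.median(sf.values))
    return replace(sf, values=sf.values / med, median_rescaled=True)
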
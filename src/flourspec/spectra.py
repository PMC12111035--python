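"""Spectra containers, CSV I/O, train/prediction splits, and standardization.

The exchange object throughout the package is :class:`SpectraSet`: an
``n_samples x n_wavelengths`` absorbance matrix on a strictly increasing
wavelength grid (nm), with unique sample ids and an optional per-sample
reference value (e.g. sedimentation value in mL or falling number in s).

The CSV dialect is deliberately plain: one header row whose fields are the
numeric wavelengths plus, optionally, a ``sample_id`` column and one named
reference column; one row per sample. A transposed layout
(wavelengths-as-rows) is accepted via ``orientation="rows"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "SplitPlan",
    "StandardizerParams",
    "read_spectra_csv",
    "write_spectra_csv",
    "make_split",
    "fit_standardizer",
    "subset_wavelengths",
    "SpectraFormatError",
]


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the dialect (duplicate or
    non-numeric wavelength headers, non-numeric cells, ...)."""


@dataclass
class SpectraSet:
    """Wavelength grid + absorbance matrix + ids + optional reference values."""

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    reference: np.ndarray | None = None
    reference_label: str | None = None

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float).ravel()
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if p != self.wavelengths_nm.size:
            raise ValueError(
                f"absorbance has {p} columns but the grid has "
                f"{self.wavelengths_nm.size} wavelengths"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains NaN/Inf")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float).ravel()
            if self.reference.size != n:
                raise ValueError("reference length does not match sample count")
            if not np.all(np.isfinite(self.reference)):
                raise ValueError("reference contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def take_samples(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset (e.g. the training side of a split)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            wavelengths_nm=self.wavelengths_nm.copy(),
            absorbance=self.absorbance[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            reference=None if self.reference is None else self.reference[idx],
            reference_label=self.reference_label,
        )


@dataclass
class SplitPlan:
    """Deterministic train/prediction partition of 0..n-1."""

    train_indices: np.ndarray
    prediction_indices: np.ndarray
    fraction: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_indices": self.train_indices.tolist(),
                "prediction_indices": self.prediction_indices.tolist(),
                "fraction": self.fraction,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            np.asarray(d["train_indices"], dtype=int),
            np.asarray(d["prediction_indices"], dtype=int),
            float(d["fraction"]),
            int(d["seed"]),
        )


def make_split(n_samples: int, fraction: float, seed: int) -> SplitPlan:
    """Randomly partition ``n_samples`` into training/prediction sets.

    The training size is ``round(fraction * n)`` with half-away-from-zero
    rounding, so 921 samples at 0.8 give 737/184 and 904 give 723/181.
    The permutation is driven only by ``seed``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_train = math.floor(fraction * n_samples + 0.5)
    if n_train < 1 or n_train > n_samples - 1:
        raise ValueError(
            f"degenerate split: {n_train}/{n_samples - n_train} from "
            f"n={n_samples}, fraction={fraction}"
        )
    perm = np.random.default_rng(seed).permutation(n_samples)
    return SplitPlan(
        train_indices=np.sort(perm[:n_train]),
        prediction_indices=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass
class StandardizerParams:
    """Column-wise standardization parameters fit on training data only.

    Uses the population SD convention (divide by n). Columns with zero
    variance are flagged and their scale set to 1 so transformed values are
    exactly zero.
    """

    mean: np.ndarray
    scale: np.ndarray
    constant_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    target_mean: float | None = None
    target_scale: float | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale + self.mean

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        if self.target_mean is None:
            raise ValueError("standardizer was fit without a target")
        return (np.asarray(y, dtype=float) - self.target_mean) / self.target_scale

    def inverse_transform_target(self, y: np.ndarray) -> np.ndarray:
        if self.target_mean is None:
            raise ValueError("standardizer was fit without a target")
        return np.asarray(y, dtype=float) * self.target_scale + self.target_mean

    def to_json(self) -> str:
        return json.dumps(
            {
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
                "constant_columns": self.constant_columns.astype(int).tolist(),
                "target_mean": self.target_mean,
                "target_scale": self.target_scale,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StandardizerParams":
        d = json.loads(text)
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            constant_columns=np.asarray(d["constant_columns"], dtype=bool),
            target_mean=d["target_mean"],
            target_scale=d["target_scale"],
        )


def fit_standardizer_arrays(
    X: np.ndarray, y: np.ndarray | None = None
) -> StandardizerParams:
    """Fit :class:`StandardizerParams` on raw arrays (population SD)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 training samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd <= 0
    scale = np.where(constant, 1.0, sd)
    tm = ts = None
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        tm = float(y.mean())
        tsd = float(y.std(ddof=0))
        ts = tsd if tsd > 0 else 1.0
    return StandardizerParams(mean, scale, constant, tm, ts)


def fit_standardizer(train: SpectraSet, standardize_target: bool = False) -> StandardizerParams:
    """Fit column means/SDs (and optionally target mean/SD) on a training set."""
    y = None
    if standardize_target:
        if train.reference is None:
            raise ValueError("standardize_target requested but set has no reference")
        y = train.reference
    return fit_standardizer_arrays(train.absorbance, y)


def subset_wavelengths(s: SpectraSet, subset) -> SpectraSet:
    """Extract the columns named by a wavelength subset (or raw indices).

    Columns are taken in the order given; reference values are untouched.
    """
    indices = np.asarray(getattr(subset, "indices", subset), dtype=int)
    p = s.n_wavelengths
    if indices.size and (indices.min() < 0 or indices.max() >= p):
        raise IndexError(f"wavelength index out of range for p={p}")
    grid = s.wavelengths_nm[indices]
    if np.any(np.diff(grid) <= 0):
        order = np.argsort(indices)
        indices = indices[order]
        grid = s.wavelengths_nm[indices]
    return SpectraSet(
        wavelengths_nm=grid,
        absorbance=s.absorbance[:, indices],
        sample_ids=list(s.sample_ids),
        reference=None if s.reference is None else s.reference.copy(),
        reference_label=s.reference_label,
    )


def read_spectra_csv(
    path: str | Path,
    reference_column: str | None = None,
    orientation: str = "columns",
) -> SpectraSet:
    """Read a spectra CSV into a validated :class:`SpectraSet`.

    ``orientation="columns"`` (default): header = wavelengths (+ optional
    ``sample_id`` and reference columns), one row per sample.
    ``orientation="rows"``: the file is transposed (wavelengths down the
    first column, one column per sample); no reference column support.
    """
    path = Path(path)
    if orientation == "rows":
        df = pd.read_csv(path, index_col=0)
        df = df.T
        df.columns = [str(c) for c in df.columns]
        df.insert(0, "sample_id", df.index.astype(str))
        df = df.reset_index(drop=True)
    elif orientation == "columns":
        with open(path) as fh:
            header = [c.strip().strip('"') for c in fh.readline().rstrip("\n").split(",")]
        if len(set(header)) != len(header):  # pandas would mangle duplicates
            raise SpectraFormatError("duplicate wavelength in header")
        df = pd.read_csv(path, dtype=str)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    columns = [str(c) for c in df.columns]
    sample_ids = None
    if "sample_id" in columns:
        sample_ids = [str(v) for v in df["sample_id"]]
        df = df.drop(columns=["sample_id"])
        columns = [c for c in columns if c != "sample_id"]

    reference = None
    if reference_column is not None:
        if reference_column not in columns:
            raise KeyError(f"reference column {reference_column!r} not in header")
        try:
            reference = df[reference_column].astype(float).to_numpy()
        except ValueError as exc:
            raise SpectraFormatError(
                f"non-numeric value in reference column {reference_column!r}: {exc}"
            ) from exc
        df = df.drop(columns=[reference_column])
        columns = [c for c in columns if c != reference_column]

    try:
        wavelengths = np.array([float(c) for c in columns])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    if np.unique(wavelengths).size != wavelengths.size:
        raise SpectraFormatError("duplicate wavelength in header")

    n = len(df)
    if n < 1:
        raise SpectraFormatError("file contains no sample rows")
    matrix = np.empty((n, wavelengths.size))
    for j, col in enumerate(columns):
        for i, cell in enumerate(df[col]):
            try:
                matrix[i, j] = float(cell)
            except (TypeError, ValueError):
                raise SpectraFormatError(
                    f"non-numeric cell at row {i}, column {col!r}: {cell!r}"
                ) from None

    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    matrix = matrix[:, order]
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    return SpectraSet(
        wavelengths_nm=wavelengths,
        absorbance=matrix,
        sample_ids=sample_ids,
        reference=reference,
        reference_label=reference_column,
    )


def write_spectra_csv(s: SpectraSet, path: str | Path) -> None:
    """Write the columns dialect at full float precision (read round-trips)."""
    path = Path(path)
    cols: dict[str, object] = {"sample_id": s.sample_ids}
    if s.reference is not None:
        cols[s.reference_label or "reference"] = [repr(float(v)) for v in s.reference]
    for j, w in enumerate(s.wavelengths_nm):
        cols[repr(float(w))] = [repr(float(v)) for v in s.absorbance[:, j]]
    pd.DataFrame(cols).to_csv(path, index=False)
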
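"""Spectral containers, file I/O and pipeline configuration.

Two plain-text formats are supported:

* ``two_column`` — one spectrum per ASCII file, rows of ``wavenumber intensity``
  (whitespace or comma separated).  A multi-spectrum set maps to a directory of
  such files plus a sidecar label table.
* ``matrix_csv`` — one CSV holding the shared wavenumber axis in the first
  column (header ``wavenumber_cm-1``) and one intensity column per spectrum,
  headed by its sample id.

Labels always live in a separate two-column CSV (``sample_id,label``) so the
spectral files stay purely numeric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    AxisError,
    ConfigurationError,
    EmptyInputError,
    InputError,
    ParseError,
)

logger = logging.getLogger("sersml")

WAVENUMBER_HEADER = "wavenumber_cm-1"


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr at INFO (DEBUG with ``verbose``)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A single Raman spectrum: intensity counts on a wavenumber axis (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_id: str = "s0"
    label: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise InputError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise InputError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < 2:
            raise InputError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise AxisError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("intensities must be finite")

    @property
    def n(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectrumSet:
    """Aligned spectra: one shared axis, an (n_samples, n_points) matrix,
    per-row labels and sample ids."""

    axis: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        if not np.all(np.diff(self.axis) > 0):
            raise AxisError("shared axis must be strictly increasing")
        if self.matrix.shape[1] != self.axis.size:
            raise AxisError(
                f"matrix has {self.matrix.shape[1]} columns, axis has {self.axis.size}"
            )
        n = self.matrix.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise InputError("labels and ids must match the number of rows")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("intensity matrix must be finite")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in sorted order (ignores missing labels)."""
        return sorted({l for l in self.labels if l is not None})

    def spectra(self) -> list[Spectrum]:
        return [
            Spectrum(self.axis, row, sample_id=str(sid), label=lab)
            for row, sid, lab in zip(self.matrix, self.ids, self.labels)
        ]

    def subset(self, index: np.ndarray) -> "SpectrumSet":
        index = np.asarray(index)
        return SpectrumSet(
            self.axis, self.matrix[index], self.labels[index], self.ids[index]
        )

    def map_rows(self, fn) -> "SpectrumSet":
        """Apply ``fn(Spectrum) -> Spectrum`` to every row, keeping the axis."""
        rows = []
        for spec in self.spectra():
            out = fn(spec)
            rows.append(out.intensities)
        return SpectrumSet(self.axis, np.vstack(rows), self.labels, self.ids)

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise EmptyInputError("no spectra supplied")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.n != axis.size or not np.allclose(s.wavenumbers, axis):
                raise AxisError(f"spectrum {s.sample_id!r} is not on the shared axis")
        return cls(
            axis,
            np.vstack([s.intensities for s in spectra]),
            np.array([s.label for s in spectra], dtype=object),
            np.array([s.sample_id for s in spectra], dtype=object),
        )


@dataclass
class PipelineConfig:
    """End-to-end run settings (simulator, preprocessing, model, split, seed)."""

    seed: int = 0
    model: str = "svm"  # svm | cnn
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    simulator: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self) -> None:
        f = self.split_fractions
        if len(f) != 3 or any(x <= 0 for x in f):
            raise ConfigurationError("split fractions must be three positive numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ConfigurationError("split fractions must sum to 1 within 1e-9")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ConfigurationError("seed must be a non-negative integer")
        if self.model not in ("svm", "cnn"):
            raise ConfigurationError("model must be 'svm' or 'cnn'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "split_fractions" in data:
            data["split_fractions"] = tuple(data["split_fractions"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "seed": int(self.seed),
            "model": self.model,
            "split_fractions": list(self.split_fractions),
            "simulator": self.simulator,
            "preprocessing": self.preprocessing,
            "output_dir": self.output_dir,
        }
        path.write_text(yaml.safe_dump(data))
        return path


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_float(token: str, path: Path, lineno: int) -> float:
    try:
        value = float(token)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed numeric field {token!r}") from exc
    if not math.isfinite(value):
        raise ParseError(f"{path}:{lineno}: non-finite value {token!r}")
    return value


def _read_two_column_file(path: Path) -> tuple[np.ndarray, np.ndarray]:
    wn, it = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(tokens)}")
            wn.append(_parse_float(tokens[0], path, lineno))
            it.append(_parse_float(tokens[1], path, lineno))
    if not wn:
        raise EmptyInputError(f"{path}: empty spectrum file")
    wn_arr, it_arr = np.array(wn), np.array(it)
    if not np.all(np.diff(wn_arr) > 0):
        raise AxisError(f"{path}: wavenumber column is not strictly increasing")
    return wn_arr, it_arr


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id,label`` CSV into a dict."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: label table needs sample_id and label columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(spectra: SpectrumSet, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": spectra.ids, "label": spectra.labels}).to_csv(
        path, index=False
    )
    return path


def _default_label_path(path: Path) -> Path:
    return path.with_suffix(".labels.csv") if path.suffix else path / "labels.csv"


def read_spectra(
    path: str | Path,
    format: str = "matrix_csv",
    labels: str | Path | None = None,
) -> SpectrumSet:
    """Read spectra from ``path`` in the declared format.

    ``two_column`` accepts a single file (one spectrum) or a directory of
    files; ``matrix_csv`` reads a single matrix CSV.  A sidecar label table is
    attached when present (``labels`` path, or the default sidecar location).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "two_column":
        if path.is_dir():
            files = sorted(p for p in path.iterdir() if p.suffix in (".txt", ".tsv", ".dat"))
            if not files:
                raise EmptyInputError(f"{path}: no two-column spectrum files")
        else:
            files = [path]
        spectra = []
        axis = None
        for f in files:
            wn, it = _read_two_column_file(f)
            if axis is None:
                axis = wn
            elif wn.size != axis.size or not np.allclose(wn, axis):
                raise AxisError(f"{f}: axis differs from the first spectrum")
            spectra.append(Spectrum(wn, it, sample_id=f.stem))
        result = SpectrumSet.from_spectra(spectra)
    elif format == "matrix_csv":
        if path.stat().st_size == 0:
            raise EmptyInputError(f"{path}: empty file")
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"{path}: {exc}") from exc
        if df.shape[1] < 2:
            raise EmptyInputError(f"{path}: no intensity columns")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[
                [not np.issubdtype(d, np.number) for d in df.dtypes]
            ].tolist()
            raise ParseError(f"{path}: non-numeric values in columns {bad}")
        if not np.all(np.isfinite(values)):
            rows = np.where(~np.isfinite(values).all(axis=1))[0]
            raise ParseError(f"{path}: non-finite value near data row {rows[0] + 2}")
        axis = values[:, 0]
        if not np.all(np.diff(axis) > 0):
            raise AxisError(f"{path}: wavenumber column is not strictly increasing")
        ids = np.array([str(c) for c in df.columns[1:]], dtype=object)
        result = SpectrumSet(
            axis, values[:, 1:].T, np.array([None] * len(ids), dtype=object), ids
        )
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    label_path = Path(labels) if labels else _default_label_path(path)
    if label_path.exists():
        table = read_labels(label_path)
        result = SpectrumSet(
            result.axis,
            result.matrix,
            np.array([table.get(str(i)) for i in result.ids], dtype=object),
            result.ids,
        )
    return result


def write_spectra(
    spectra: SpectrumSet,
    path: str | Path,
    format: str = "matrix_csv",
) -> Path:
    """Write a SpectrumSet; the inverse of :func:`read_spectra` within 1e-9."""
    if spectra.n_samples == 0:
        raise EmptyInputError("refusing to write an empty SpectrumSet")
    path = Path(path)
    if format == "two_column":
        path.mkdir(parents=True, exist_ok=True)
        for spec in spectra.spectra():
            out = path / f"{spec.sample_id}.txt"
            np.savetxt(
                out,
                np.column_stack([spec.wavenumbers, spec.intensities]),
                fmt="%.12g",
            )
    elif format == "matrix_csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            spectra.matrix.T, columns=[str(i) for i in spectra.ids]
        )
        df.insert(0, WAVENUMBER_HEADER, spectra.axis)
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        raise ConfigurationError(f"unknown format {format!r}")
    if any(l is not None for l in spectra.labels):
        write_labels(spectra, _default_label_path(path))
    return path
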
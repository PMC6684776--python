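"""Spectrum and fingerprint-matrix containers and plain-text I/O.

A *fingerprint* here is a full-profile signal — a MALDI-TOF mass spectrum
(m/z in Da vs. intensity) or a UPLC chromatogram (retention time in min vs.
absorbance) — exported as two-column ASCII.  Single-sample signals are held
as :class:`Spectrum`; a labelled collection resampled onto a shared axis is a
:class:`FingerprintMatrix` (samples x points), the unit on which alignment,
preprocessing and classification operate.

Intensities are kept verbatim at I/O time: instrument exports may contain
negative values after baseline handling, and clamping is a preprocessing
decision, not a parsing one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "FingerprintMatrix",
    "read_spectrum_ascii",
    "write_spectrum_ascii",
    "resample_to_grid",
    "average_replicates",
    "assemble_matrix",
    "read_matrix_csv",
    "write_matrix_csv",
]


@dataclass
class Spectrum:
    """One sample's signal: a strictly increasing axis plus intensities.

    Parameters
    ----------
    axis:
        x-values (m/z in Da or retention time in min), strictly increasing,
        length >= 2.
    intensity:
        Same length as ``axis``; may be negative (see module docstring).
    sample_id, replicate_id, class_label:
        Bookkeeping labels carried through resampling and averaging.
    """

    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: int | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise ValueError(
                f"axis length {self.axis.size} != intensity length {self.intensity.size}"
            )
        if self.axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        diffs = np.diff(self.axis)
        if np.any(diffs == 0):
            raise ValueError("duplicate axis values")
        if np.any(diffs < 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size


@dataclass
class FingerprintMatrix:
    """Samples x points matrix with a shared axis and per-row labels."""

    X: np.ndarray
    axis: np.ndarray
    sample_ids: list[str]
    class_labels: list[str | None] | None = None
    class_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = self.X.shape
        if self.axis.size != p:
            raise ValueError("axis length must match number of columns")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ValueError("one sample_id per row required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample_ids")
        if self.class_labels is not None:
            if len(self.class_labels) != n:
                raise ValueError("one class_label per row required")
            if self.class_set is None:
                seen: list[str] = []
                for c in self.class_labels:
                    if c is not None and c not in seen:
                        seen.append(c)
                self.class_set = tuple(seen)
            bad = {c for c in self.class_labels if c is not None} - set(self.class_set)
            if bad:
                raise ValueError(f"class labels {sorted(bad)} outside class set {self.class_set}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    def labels_array(self) -> np.ndarray:
        if self.class_labels is None:
            raise ValueError("matrix has no class labels")
        return np.asarray(self.class_labels, dtype=object)

    def row(self, i: int) -> Spectrum:
        label = None if self.class_labels is None else self.class_labels[i]
        return Spectrum(self.axis, self.X[i], sample_id=self.sample_ids[i], class_label=label)


def read_spectrum_ascii(path: str | Path, sample_id: str | None = None,
                        replicate_id: int | None = None,
                        class_label: str | None = None) -> Spectrum:
    """Parse a two-column ASCII spectrum (whitespace or comma delimited).

    Lines starting with ``#`` and blank lines are skipped.  The axis is
    sorted ascending if needed (input order preserved when already sorted);
    duplicate axis values are an error.  A malformed line raises
    ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed numeric value") from exc
    axis = np.array(xs)
    intensity = np.array(ys)
    if axis.size >= 2 and np.any(np.diff(axis) < 0):
        order = np.argsort(axis, kind="stable")
        axis, intensity = axis[order], intensity[order]
    if axis.size >= 2 and np.any(np.diff(axis) == 0):
        raise ValueError(f"{path.name}: duplicate axis values")
    return Spectrum(axis, intensity, sample_id=sample_id or path.stem,
                    replicate_id=replicate_id, class_label=class_label)


def write_spectrum_ascii(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two whitespace-delimited columns (full double
    precision, so the text round trip is exact)."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id={s.sample_id}")
        if s.class_label is not None:
            fh.write(f" class={s.class_label}")
        if s.replicate_id is not None:
            fh.write(f" replicate={s.replicate_id}")
        fh.write("\n")
        for x, y in zip(s.axis, s.intensity):
            fh.write(f"{x:.17g} {y:.17g}\n")


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (0 outside its axis)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.size >= 2 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    intensity = np.interp(grid, s.axis, s.intensity, left=0.0, right=0.0)
    if grid.size < 2:
        raise ValueError("grid needs at least 2 points to form a spectrum")
    return Spectrum(grid, intensity, sample_id=s.sample_id,
                    replicate_id=s.replicate_id, class_label=s.class_label)


def average_replicates(replicates: Sequence[Spectrum]) -> Spectrum:
    """Point-wise mean of replicate acquisitions of one sample.

    All replicates must share the same axis and ``sample_id``; the mean
    spectrum has its ``replicate_id`` cleared.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for r in replicates[1:]:
        if not np.array_equal(r.axis, first.axis):
            raise ValueError("replicates have mismatched axes")
        if r.sample_id != first.sample_id:
            raise ValueError(
                f"mixed sample_ids: {r.sample_id!r} vs {first.sample_id!r}"
            )
    # canonical summation order (by replicate_id when distinct) so the mean
    # is invariant to the order replicates are passed in
    ordered = list(replicates)
    ids = [r.replicate_id for r in ordered]
    if None not in ids and len(set(ids)) == len(ids):
        ordered.sort(key=lambda r: r.replicate_id)
    mean = np.mean([r.intensity for r in ordered], axis=0)
    return Spectrum(first.axis, mean, sample_id=first.sample_id,
                    replicate_id=None, class_label=first.class_label)


def assemble_matrix(samples: Sequence[Spectrum],
                    class_set: tuple[str, ...] | None = None) -> FingerprintMatrix:
    """Stack one spectrum per sample into a FingerprintMatrix (row order = input order)."""
    if len(samples) == 0:
        raise ValueError("no spectra to assemble")
    first = samples[0]
    for s in samples[1:]:
        if not np.array_equal(s.axis, first.axis):
            raise ValueError(f"axis mismatch for sample {s.sample_id!r}")
    X = np.vstack([s.intensity for s in samples])
    labels = [s.class_label for s in samples]
    if all(c is None for c in labels):
        labels = None
    return FingerprintMatrix(X, first.axis.copy(), [s.sample_id for s in samples],
                             class_labels=labels, class_set=class_set)


def write_matrix_csv(m: FingerprintMatrix, path: str | Path) -> None:
    """CSV layout: header = sample_id,class_label,<axis values>; one row per sample."""
    cols = [f"{x:.17g}" for x in m.axis]
    df = pd.DataFrame(m.X, columns=cols)
    df.insert(0, "class_label", ["" if c is None else c for c in (m.class_labels or [None] * m.n_samples)])
    df.insert(0, "sample_id", m.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_matrix_csv(path: str | Path) -> FingerprintMatrix:
    df = pd.read_csv(path, dtype={"sample_id": str, "class_label": str})
    if list(df.columns[:2]) != ["sample_id", "class_label"]:
        raise ValueError("matrix CSV must start with sample_id,class_label columns")
    axis = np.array([float(c) for c in df.columns[2:]])
    X = df.iloc[:, 2:].to_numpy(dtype=float)
    raw_labels = df["class_label"].tolist()
    labels: list[str | None] | None = [None if (isinstance(c, float) or c == "") else c
                                       for c in raw_labels]
    if all(c is None for c in labels):
        labels = None
    return FingerprintMatrix(X, axis, df["sample_id"].tolist(), class_labels=labels)
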
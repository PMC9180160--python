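"""Data model and I/O for wavenumber-gridded spectra.

A :class:`Spectrum` is a single sample's intensity trace on a strictly
monotone wavenumber grid (cm^-1), carrying a photometric mode flag
(absorbance or transmittance), an opaque sample id and an optional integer
class label.  A :class:`SpectraSet` is an ordered collection of spectra
sharing one grid and one mode, stored as a dense matrix.

Conversions follow the Beer-Lambert convention with fractional
transmittance: T = 10**(-A), A = -log10(T).
"""

from __future__ import annotations

import csv
import enum
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Mode",
    "Spectrum",
    "SpectraSet",
    "absorbance_to_transmittance",
    "transmittance_to_absorbance",
    "average_replicates",
    "read_spectra_table",
    "write_spectra_table",
]

#: floor applied to transmittance values before taking log10
ZERO_TRANSMITTANCE_FLOOR = 1e-10

#: numerical slack allowed at the [0, 1] transmittance bounds
_BOUND_TOL = 1e-9


class Mode(str, enum.Enum):
    """Photometric mode of a spectrum."""

    ABSORBANCE = "absorbance"
    TRANSMITTANCE = "transmittance"


class ModeMismatchError(ValueError):
    """Raised when an operation receives a spectrum in the wrong mode."""


class GridMismatchError(ValueError):
    """Raised when spectra on different wavenumber grids are combined."""


class SpectraParseError(ValueError):
    """Raised on malformed spectra table files; names the offending row/column."""


def _check_grid(wavenumbers: np.ndarray) -> None:
    if wavenumbers.ndim != 1 or wavenumbers.size < 2:
        raise ValueError("wavenumber grid must be 1-D with at least 2 points")
    d = np.diff(wavenumbers)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavenumber grid must be strictly monotone")


def _check_values(values: np.ndarray, mode: Mode) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError("intensity values must be finite")
    if mode is Mode.TRANSMITTANCE:
        if values.min() < -_BOUND_TOL or values.max() > 1.0 + _BOUND_TOL:
            raise ValueError("transmittance values must lie in [0, 1]")
    else:
        if values.min() < -_BOUND_TOL:
            raise ValueError("absorbance values must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """One sample's spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray
    values: np.ndarray
    mode: Mode
    sample_id: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "mode", Mode(self.mode))
        if wn.shape != vals.shape:
            raise ValueError("wavenumbers and values must have identical length")
        _check_grid(wn)
        _check_values(vals, self.mode)
        if self.label is not None and int(self.label) < 1:
            raise ValueError("class labels are positive integers (1..L)")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SpectraSet:
    """Ordered spectra sharing one wavenumber grid and one mode.

    Stored densely: ``values`` is an ``(n_samples, n_points)`` matrix.
    ``labels`` is either None or an integer array with entries in ``1..L``.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    mode: Mode
    sample_ids: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mode = Mode(self.mode)
        _check_grid(self.wavenumbers)
        if self.values.shape[1] != self.wavenumbers.size:
            raise GridMismatchError("value matrix width does not match grid length")
        _check_values(self.values, self.mode)
        n = self.values.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("one sample_id per spectrum required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("one label per spectrum required")
            if self.labels.min() < 1:
                raise ValueError("class labels are positive integers (1..L)")

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise ValueError("empty spectra collection")
        ref = spectra[0]
        for s in spectra[1:]:
            if s.mode is not ref.mode:
                raise ModeMismatchError("all spectra in a set must share one mode")
            if not np.array_equal(s.wavenumbers, ref.wavenumbers):
                raise GridMismatchError("all spectra in a set must share one grid")
        labels = None
        if all(s.label is not None for s in spectra):
            labels = np.array([s.label for s in spectra], dtype=int)
        return cls(
            wavenumbers=ref.wavenumbers.copy(),
            values=np.vstack([s.values for s in spectra]),
            mode=ref.mode,
            sample_ids=[s.sample_id for s in spectra],
            labels=labels,
        )

    def __len__(self) -> int:
        return self.values.shape[0]

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(
            wavenumbers=self.wavenumbers,
            values=self.values[i],
            mode=self.mode,
            sample_id=self.sample_ids[i],
            label=None if self.labels is None else int(self.labels[i]),
        )

    def subset(self, index: np.ndarray) -> "SpectraSet":
        """Row-subset the set (boolean mask or integer index array)."""
        index = np.asarray(index)
        ids = [self.sample_ids[i] for i in np.arange(len(self))[index]] \
            if index.dtype == bool else [self.sample_ids[i] for i in index]
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            values=self.values[index],
            mode=self.mode,
            sample_ids=ids,
            labels=None if self.labels is None else self.labels[index],
        )

    def with_values(self, values: np.ndarray, mode: Mode | None = None) -> "SpectraSet":
        return SpectraSet(
            wavenumbers=self.wavenumbers,
            values=values,
            mode=self.mode if mode is None else mode,
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
        )


def absorbance_to_transmittance(s: Spectrum | SpectraSet) -> Spectrum | SpectraSet:
    """Convert absorbance to fractional transmittance, T = 10**(-A)."""
    if s.mode is not Mode.ABSORBANCE:
        raise ModeMismatchError("input must be in absorbance mode")
    t = np.power(10.0, -np.asarray(s.values, dtype=float))
    if isinstance(s, SpectraSet):
        return s.with_values(t, mode=Mode.TRANSMITTANCE)
    return replace(s, values=t, mode=Mode.TRANSMITTANCE)


def transmittance_to_absorbance(s: Spectrum | SpectraSet) -> Spectrum | SpectraSet:
    """Convert fractional transmittance to absorbance, A = -log10(T).

    Zero (or negative round-off) transmittance is floored at
    ``ZERO_TRANSMITTANCE_FLOOR`` before the log; a warning reports how many
    points were floored.
    """
    if s.mode is not Mode.TRANSMITTANCE:
        raise ModeMismatchError("input must be in transmittance mode")
    t = np.asarray(s.values, dtype=float)
    floored = int(np.count_nonzero(t < ZERO_TRANSMITTANCE_FLOOR))
    if floored:
        warnings.warn(
            f"{floored} transmittance value(s) at or below the floor "
            f"{ZERO_TRANSMITTANCE_FLOOR:g} were clipped before log10",
            stacklevel=2,
        )
    a = -np.log10(np.maximum(t, ZERO_TRANSMITTANCE_FLOOR))
    if isinstance(s, SpectraSet):
        return s.with_values(a, mode=Mode.ABSORBANCE)
    return replace(s, values=a, mode=Mode.ABSORBANCE)


def average_replicates(replicates: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate scans of one sample.

    All replicates must share grid and mode.  The returned sample id is the
    longest common prefix of the replicate ids (stripped of trailing
    separators), falling back to the first replicate's id.
    """
    if len(replicates) == 0:
        raise ValueError("at least one replicate required")
    ref = replicates[0]
    for r in replicates[1:]:
        if r.mode is not ref.mode:
            raise ModeMismatchError("replicates must share one mode")
        if not np.array_equal(r.wavenumbers, ref.wavenumbers):
            raise GridMismatchError("replicates must share one grid")
    mean = np.mean([r.values for r in replicates], axis=0)
    sid = os.path.commonprefix([r.sample_id for r in replicates]).rstrip("_-. ")
    if not sid:
        sid = ref.sample_id
    return Spectrum(
        wavenumbers=ref.wavenumbers,
        values=mean,
        mode=ref.mode,
        sample_id=sid,
        label=ref.label,
    )


# ---------------------------------------------------------------------------
# Spectra table I/O
#
# Format: delimited text, header row `sample_id,label,w1,...,wN` where the
# wi are wavenumber values in cm^-1 (monotone either direction); one sample
# per row.  An empty label cell means "unlabeled".
# ---------------------------------------------------------------------------


def read_spectra_table(
    path: str | os.PathLike,
    mode: Mode | str = Mode.ABSORBANCE,
    delimiter: str = ",",
) -> SpectraSet:
    """Read a spectra table; see module docstring for the dialect."""
    mode = Mode(mode)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise SpectraParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 4 or header[0] != "sample_id" or header[1] != "label":
        raise SpectraParseError(
            f"{path}: header must start with 'sample_id{delimiter}label' "
            "followed by at least two wavenumber columns"
        )
    try:
        wn = np.array([float(w) for w in header[2:]])
    except ValueError as exc:
        raise SpectraParseError(f"{path}: non-numeric wavenumber in header: {exc}") from exc
    try:
        _check_grid(wn)
    except ValueError as exc:
        raise SpectraParseError(f"{path}: bad header grid: {exc}") from exc

    ids: list[str] = []
    labels: list[int | None] = []
    values = np.empty((len(rows) - 1, wn.size))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SpectraParseError(
                f"{path}: row {r} has {len(row)} cells, expected {len(header)}"
            )
        ids.append(row[0])
        labels.append(int(row[1]) if row[1].strip() else None)
        for c, cell in enumerate(row[2:], start=3):
            try:
                values[r - 2, c - 3] = float(cell)
            except ValueError as exc:
                raise SpectraParseError(
                    f"{path}: non-numeric cell at row {r}, column {c}"
                ) from exc
    label_arr = None
    if all(l is not None for l in labels) and labels:
        label_arr = np.array(labels, dtype=int)
    return SpectraSet(
        wavenumbers=wn, values=values, mode=mode, sample_ids=ids, labels=label_arr
    )


def write_spectra_table(
    sset: SpectraSet, path: str | os.PathLike, delimiter: str = ","
) -> None:
    """Write a spectra table at full precision (round-trips exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["sample_id", "label"] + [repr(float(w)) for w in sset.wavenumbers])
        for i in range(len(sset)):
            label = "" if sset.labels is None else str(int(sset.labels[i]))
            writer.writerow(
                [sset.sample_ids[i], label] + [repr(float(v)) for v in sset.values[i]]
            )
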
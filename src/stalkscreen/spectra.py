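"""Data model and I/O for FTIR absorbance spectra.

A :class:`Spectrum` is a single absorbance trace on a wavenumber grid;
a :class:`SpectraSet` is a collection of spectra sharing one grid, with
an optional row-aligned reference table of known target values (e.g.
sugar concentrations in mM, or digestibility in μg·mgDW⁻¹·h⁻¹).

Grids are stored in descending wavenumber order (the mid-IR instrument
convention, 4,000 → 400 cm⁻¹); readers normalise ascending inputs and
record the flip in metadata.  The canonical on-disk dialect is a wide
CSV: one row per sample, header = wavenumbers, a ``sample_id`` column,
and reference columns carrying a ``ref:`` name prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

REF_PREFIX = "ref:"
ID_COLUMN = "sample_id"


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_monotone(grid: np.ndarray) -> int:
    """Return -1 for strictly descending, +1 for strictly ascending."""
    d = np.diff(grid)
    if np.all(d < 0):
        return -1
    if np.all(d > 0):
        return 1
    raise ValueError("wavenumber grid must be strictly monotone")


@dataclass
class Spectrum:
    """One absorbance spectrum on a strictly monotone wavenumber grid."""

    wavenumbers: np.ndarray
    absorbances: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_array(self.wavenumbers, "wavenumbers")
        self.absorbances = _as_float_array(self.absorbances, "absorbances")
        if self.wavenumbers.size != self.absorbances.size:
            raise ValueError("wavenumbers and absorbances must have equal length")
        if self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        _check_monotone(self.wavenumbers)


@dataclass
class SpectraSet:
    """n_samples spectra on a shared descending grid, plus optional reference."""

    grid: np.ndarray
    matrix: np.ndarray
    sample_ids: list[str]
    reference: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = _as_float_array(self.grid, "grid")
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if _check_monotone(self.grid) > 0:
            # normalise to the descending instrument convention
            self.grid = self.grid[::-1].copy()
            self.matrix = self.matrix[:, ::-1].copy()
            self.metadata = {**self.metadata, "grid_flipped": True}
        if self.matrix.shape[1] != self.grid.size:
            raise ValueError("matrix width must equal grid length")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids length must equal number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if self.reference is not None:
            if len(self.reference) != self.matrix.shape[0]:
                raise ValueError("reference table must be row-aligned with matrix")
            self.reference = self.reference.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.grid.size

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid.copy(), self.matrix[i].copy(), self.sample_ids[i])

    def copy_with(self, *, grid=None, matrix=None, reference="keep") -> "SpectraSet":
        ref = self.reference if isinstance(reference, str) else reference
        ref = None if ref is None else ref.copy()
        return SpectraSet(
            grid=self.grid.copy() if grid is None else grid,
            matrix=self.matrix.copy() if matrix is None else matrix,
            sample_ids=list(self.sample_ids),
            reference=ref,
            metadata=dict(self.metadata),
        )


def read_spectra_table(path, dialect: str = "wide_csv") -> SpectraSet:
    """Read a wide-CSV spectra table.

    The header holds numeric wavenumbers plus a ``sample_id`` column and
    optional ``ref:``-prefixed reference columns.  Ascending grids are
    reoriented to descending order.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if ID_COLUMN not in df.columns:
        raise ValueError(f"missing {ID_COLUMN!r} column")
    ref_cols = [c for c in df.columns if c.startswith(REF_PREFIX)]
    wn_cols = [c for c in df.columns if c != ID_COLUMN and c not in ref_cols]
    try:
        grid = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric header cell: {exc}") from None
    matrix = df[wn_cols].to_numpy(dtype=float)
    if np.isnan(matrix).any():
        raise ValueError("ragged rows: missing absorbance values")
    reference = None
    if ref_cols:
        reference = df[ref_cols].rename(
            columns={c: c[len(REF_PREFIX):] for c in ref_cols}
        )
        if reference.isna().any().any():
            raise ValueError("ragged rows: missing reference values")
    ids = df[ID_COLUMN].astype(str).tolist()
    return SpectraSet(grid=grid, matrix=matrix, sample_ids=ids, reference=reference)


def write_spectra_table(sset: SpectraSet, path) -> None:
    """Write a SpectraSet in the wide-CSV dialect (inverse of the reader)."""
    df = pd.DataFrame(sset.matrix, columns=[repr(float(w)) for w in sset.grid])
    df.insert(0, ID_COLUMN, sset.sample_ids)
    if sset.reference is not None:
        for c in sset.reference.columns:
            df[REF_PREFIX + str(c)] = sset.reference[c].to_numpy()
    df.to_csv(path, index=False)


def truncate_region(sset: SpectraSet, high_wn: float, low_wn: float) -> SpectraSet:
    """Restrict to grid points g with ``low_wn <= g <= high_wn`` (inclusive).

    The reference table is carried through unchanged.
    """
    if not high_wn > low_wn:
        raise ValueError("bounds inverted: high_wn must exceed low_wn")
    mask = (sset.grid >= low_wn) & (sset.grid <= high_wn)
    if mask.sum() < 2:
        raise ValueError("empty selection: fewer than 2 grid points in region")
    return sset.copy_with(grid=sset.grid[mask], matrix=sset.matrix[:, mask])


def align_to_grid(sset: SpectraSet, target_grid: Sequence[float]) -> SpectraSet:
    """Linearly interpolate every spectrum onto ``target_grid``.

    No extrapolation: the target must lie within the source span.
    """
    target = _as_float_array(target_grid, "target_grid")
    if target.size < 2:
        raise ValueError("target grid needs at least 2 points")
    _check_monotone(target)
    target = target[np.argsort(-target)]  # store descending
    lo, hi = sset.grid.min(), sset.grid.max()
    if target.min() < lo or target.max() > hi:
        raise ValueError("target grid outside source span (no extrapolation)")
    src_asc = sset.grid[::-1]
    tgt_asc = target[::-1]
    out = np.empty((sset.n_samples, target.size))
    for i in range(sset.n_samples):
        out[i] = np.interp(tgt_asc, src_asc, sset.matrix[i, ::-1])[::-1]
    return sset.copy_with(grid=target, matrix=out)
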
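"""Spectral pretreatment operators.

Implements the pretreatments used for FTIR calibration work:
Savitzky–Golay smoothing / derivatives, extended multiplicative
scatter correction (EMSC), and mean centering.  A
:class:`PreprocessRecipe` records an ordered list of steps together
with any state fitted on the calibration set (the EMSC reference
spectrum), so prediction-time preprocessing is provably identical to
calibration-time preprocessing: a fitted recipe is frozen and applying
it never re-estimates fitted state.

Savitzky–Golay edge handling shrinks the output to valid interior
points and trims the grid accordingly — no fabricated edge values
enter the downstream regression.  Derivatives are taken with respect
to wavenumber (AU·cm^k for the k-th derivative), accounting for the
descending storage order of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from stalkscreen.spectra import SpectraSet, truncate_region

_EMSC_B_MIN = 1e-8


def _grid_step(grid: np.ndarray) -> float:
    """Signed constant grid spacing; raises on non-uniform grids."""
    d = np.diff(grid)
    step = d[0]
    if np.any(np.abs(d - step) > 1e-6):
        raise ValueError("operation requires a uniformly spaced grid")
    return step


def savgol(sset: SpectraSet, window: int, polyorder: int = 2,
           deriv: int = 0) -> SpectraSet:
    """Savitzky–Golay convolution per spectrum.

    ``deriv > 0`` yields d^k A / dν^k in AU·cm^k.  Output is trimmed to
    the interior points where the full window fits.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if deriv > polyorder:
        raise ValueError("deriv must not exceed polyorder")
    if window > sset.n_wavenumbers:
        raise ValueError("window exceeds number of grid points")
    step = _grid_step(sset.grid)
    out = savgol_filter(sset.matrix, window, polyorder, deriv=deriv,
                        delta=abs(step), axis=1)
    if step < 0 and deriv % 2 == 1:
        out = -out  # grid stored descending: flip odd-derivative sign
    half = window // 2
    sl = slice(half, sset.n_wavenumbers - half)
    return sset.copy_with(grid=sset.grid[sl].copy(), matrix=out[:, sl].copy())


@dataclass
class EMSCState:
    """Fitted EMSC state: the reference (mean calibration) spectrum."""

    grid: np.ndarray
    reference: np.ndarray


def fit_emsc(calibration: SpectraSet) -> EMSCState:
    if calibration.n_samples == 0:
        raise ValueError("EMSC needs a non-empty calibration set")
    return EMSCState(grid=calibration.grid.copy(),
                     reference=calibration.matrix.mean(axis=0))


def _emsc_basis(grid: np.ndarray, reference: np.ndarray) -> np.ndarray:
    # wavenumber rescaled to [-1, 1] for conditioning; the corrected
    # spectrum is invariant to this affine reparameterisation
    u = (grid - grid.mean()) / (0.5 * (grid.max() - grid.min()))
    return np.column_stack([np.ones_like(u), u, u ** 2, reference])


def apply_emsc(sset: SpectraSet, state: EMSCState) -> SpectraSet:
    """Regress each spectrum on [1, ν, ν², m] and remove offset/scatter.

    corrected = (s − a·1 − d·ν − e·ν²) / b  with  s ≈ a + d·ν + e·ν² + b·m.
    """
    if sset.grid.size != state.grid.size or not np.allclose(sset.grid, state.grid):
        raise ValueError("grid mismatch between set and EMSC state")
    basis = _emsc_basis(state.grid, state.reference)
    coef, *_ = np.linalg.lstsq(basis, sset.matrix.T, rcond=None)
    b = coef[3]
    if np.any(np.abs(b) < _EMSC_B_MIN):
        raise ValueError("degenerate scatter fit: spectrum orthogonal to reference")
    poly = basis[:, :3] @ coef[:3]  # (p, n)
    corrected = (sset.matrix - poly.T) / b[:, None]
    return sset.copy_with(matrix=corrected)


def fit_center(X: np.ndarray) -> np.ndarray:
    """Column means of a calibration matrix."""
    return np.asarray(X, dtype=float).mean(axis=0)


def apply_center(X: np.ndarray, means: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    means = np.asarray(means, dtype=float)
    if X.shape[1] != means.size:
        raise ValueError("centering means length mismatch")
    return X - means


class PreprocessRecipe:
    """Ordered, freezable pretreatment pipeline.

    Steps are dicts ``{"op": ..., "params": {...}}`` with ops among
    ``truncate`` (high, low), ``savgol`` (window, polyorder, deriv),
    ``emsc`` (reference fitted on the calibration set) and
    ``mean_center`` (column means fitted on the calibration set).
    """

    def __init__(self, steps: list[dict] | None = None):
        self.steps = [dict(s) for s in (steps or [])]
        self.fitted = False
        self._state: list[dict] = []

    def add(self, op: str, **params) -> "PreprocessRecipe":
        if self.fitted:
            raise ValueError("recipe is frozen after fitting")
        if op not in ("truncate", "savgol", "emsc", "mean_center"):
            raise ValueError(f"unknown preprocessing op {op!r}")
        self.steps.append({"op": op, "params": params})
        return self

    def _apply_step(self, sset: SpectraSet, step: dict, state: dict,
                    fitting: bool) -> SpectraSet:
        op, params = step["op"], step["params"]
        if op == "truncate":
            return truncate_region(sset, params["high"], params["low"])
        if op == "savgol":
            return savgol(sset, params["window"],
                          params.get("polyorder", 2), params.get("deriv", 0))
        if op == "emsc":
            if fitting:
                st = fit_emsc(sset)
                state["grid"] = st.grid
                state["reference"] = st.reference
            st = EMSCState(grid=np.asarray(state["grid"], dtype=float),
                           reference=np.asarray(state["reference"], dtype=float))
            return apply_emsc(sset, st)
        if op == "mean_center":
            if fitting:
                state["means"] = fit_center(sset.matrix)
            return sset.copy_with(
                matrix=apply_center(sset.matrix,
                                    np.asarray(state["means"], dtype=float)))
        raise ValueError(f"unknown preprocessing op {op!r}")

    def fit(self, calibration: SpectraSet) -> SpectraSet:
        """Fit stateful steps on the calibration set; returns it transformed."""
        if self.fitted:
            raise ValueError("recipe already fitted (frozen)")
        self._state = [{} for _ in self.steps]
        out = calibration
        for step, state in zip(self.steps, self._state):
            out = self._apply_step(out, step, state, fitting=True)
        self.fitted = True
        return out

    def apply(self, sset: SpectraSet) -> SpectraSet:
        """Apply the frozen recipe; never re-estimates fitted state."""
        if not self.fitted and any(s["op"] in ("emsc", "mean_center")
                                   for s in self.steps):
            raise ValueError("recipe with fitted state must be fit before apply")
        out = sset
        state_list = self._state if self.fitted else [{} for _ in self.steps]
        for step, state in zip(self.steps, state_list):
            out = self._apply_step(out, step, state, fitting=False)
        return out

    def to_dict(self) -> dict:
        def enc(v):
            return v.tolist() if isinstance(v, np.ndarray) else v
        return {
            "steps": [dict(s) for s in self.steps],
            "fitted": self.fitted,
            "state": [{k: enc(v) for k, v in st.items()} for st in self._state],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessRecipe":
        recipe = cls([dict(s) for s in d["steps"]])
        recipe.fitted = bool(d.get("fitted", False))
        recipe._state = [dict(st) for st in d.get("state", [])]
        if recipe.fitted and len(recipe._state) != len(recipe.steps):
            raise ValueError("corrupt recipe: state/step length mismatch")
        return recipe
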
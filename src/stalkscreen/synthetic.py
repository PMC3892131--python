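"""Synthetic spectra, calibration designs, and stalk populations.

Generators emulating the statistical structure of the screening
pipeline's inputs, so every stage can be exercised without instrument
or field data:

* juice spectra — Beer–Lambert-like linear mixtures of three
  overlapping pure-sugar component spectra (Gaussian bands) on a broad
  water background, with iid Gaussian noise;
* bagasse spectra — latent cell-wall composition on the simplex
  (cellulose-, xylan- and lignin-like components), multiplicative
  scatter and additive offset (to exercise EMSC), with digestibility a
  noisy affine function of the composition spanning the observed
  0.95–12.1 μg·mgDW⁻¹·h⁻¹ range;
* stalk populations — geometry drawn under the conical-frustum model
  with internode measurements following the fixed-ratio model, truths
  retained for recovery tests.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from stalkscreen.spectra import SpectraSet
from stalkscreen.stalk_geometry import (
    DEFAULT_FIXED_RATIOS,
    FixedRatioTable,
    StalkGeometry,
    volumetric_ratio,
)

SUGARS = ("sucrose", "glucose", "fructose")
WALL_COMPONENTS = ("cellulose", "xylan", "lignin")

#: Default descending instrument-style grid: 1,800 → 800 cm⁻¹, 4 cm⁻¹ step.
DEFAULT_GRID = np.arange(1800.0, 799.0, -4.0)

#: Calibration concentration ranges (mM), bracketing typical sweet
#: sorghum juice (low/medium/high samples span 120–461 / 52–126 /
#: 22–70 mM for sucrose / glucose / fructose).
DESIGN_RANGES = {
    "sucrose": (0.0, 600.0),
    "glucose": (0.0, 300.0),
    "fructose": (0.0, 150.0),
}

#: Observed digestibility span of a diverse bagasse collection.
D_RANGE_DEFAULT = (0.95, 12.1)


@dataclass
class Band:
    """One Gaussian absorption band: centre/width in cm⁻¹, height in AU
    per unit concentration."""

    center: float
    width: float
    height: float


@dataclass
class ComponentLibrary:
    """Per-component Gaussian band lists on a shared grid."""

    grid: np.ndarray
    components: dict = field(default_factory=dict)

    def spectrum(self, name: str) -> np.ndarray:
        """Absorbance per unit concentration of one component on the grid."""
        if name not in self.components:
            raise KeyError(f"unknown component {name!r}")
        out = np.zeros_like(self.grid)
        for b in self.components[name]:
            out += b.height * np.exp(-0.5 * ((self.grid - b.center) / b.width) ** 2)
        return out


def make_component_library(seed: int = 0,
                           grid: np.ndarray | None = None) -> ComponentLibrary:
    """Deterministic band library for the synthetic mixture system.

    Each sugar receives three bands near shared anchor positions
    (guaranteeing pairwise spectral overlap within 30 cm⁻¹, so
    quantification genuinely requires multivariate regression) plus
    2–4 unique bands in the 870–1,160 cm⁻¹ sugar region.  Water gets a
    single broad band near 1,635 cm⁻¹.  Cell-wall components carry
    bands across the 1,800–850 cm⁻¹ fingerprint region.
    """
    rng = np.random.default_rng(seed)
    grid = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, dtype=float)
    lib = ComponentLibrary(grid=grid)
    anchors = (1055.0, 1030.0, 995.0)
    for sugar in SUGARS:
        bands = [
            Band(center=a + rng.uniform(-5.0, 5.0),
                 width=rng.uniform(10.0, 22.0),
                 height=rng.uniform(0.8e-3, 1.8e-3))
            for a in anchors
        ]
        for _ in range(int(rng.integers(2, 5))):
            bands.append(Band(center=rng.uniform(870.0, 1160.0),
                              width=rng.uniform(8.0, 18.0),
                              height=rng.uniform(0.4e-3, 1.5e-3)))
        lib.components[sugar] = bands
    lib.components["water"] = [Band(center=1635.0, width=120.0, height=0.35)]
    # Wall components share a dominant common lignocellulose band set
    # (real bagasse spectra look largely alike) plus smaller
    # component-specific bands carrying the composition signal.  The
    # shared core cancels across the composition simplex, keeping the
    # scatter coefficient estimated by EMSC nearly composition-free.
    core_spec = ((1160.0, 16.0, 0.30), (1105.0, 14.0, 0.25),
                 (1030.0, 18.0, 0.35), (898.0, 12.0, 0.15),
                 (1600.0, 15.0, 0.18), (1510.0, 10.0, 0.12),
                 (1240.0, 14.0, 0.15), (1735.0, 12.0, 0.10),
                 (1370.0, 12.0, 0.12))
    core = [Band(center=c + rng.uniform(-3.0, 3.0),
                 width=w + rng.uniform(-2.0, 2.0), height=h)
            for c, w, h in core_spec]
    wall_centers = {
        "cellulose": ((1055.0, 12.0), (1315.0, 10.0), (985.0, 12.0)),
        "xylan": ((1045.0, 14.0), (1460.0, 12.0), (1210.0, 10.0)),
        "lignin": ((1515.0, 8.0), (1268.0, 10.0), (1595.0, 9.0)),
    }
    for name, centers in wall_centers.items():
        own = [Band(center=c + rng.uniform(-3.0, 3.0),
                    width=w + rng.uniform(-2.0, 2.0),
                    height=0.07 * rng.uniform(0.6, 1.4))
               for c, w in centers]
        lib.components[name] = list(core) + own
    return lib


@dataclass
class MixtureDesign:
    """Rows of sugar concentrations (mM) with design metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.table)


def factorial_design(levels: dict | int = 6,
                     ranges: dict | None = None) -> MixtureDesign:
    """Full factorial calibration design over equally spaced levels.

    The default 6×6×6 grid over the shipped ranges yields the
    216-mixture calibration set.
    """
    ranges = dict(DESIGN_RANGES) if ranges is None else dict(ranges)
    if isinstance(levels, int):
        levels = {s: levels for s in SUGARS}
    axes = []
    for sugar in SUGARS:
        n = int(levels[sugar])
        lo, hi = ranges[sugar]
        if n < 1:
            raise ValueError("levels must be >= 1")
        if lo > hi:
            raise ValueError(f"invalid range for {sugar}: ({lo}, {hi})")
        axes.append(np.linspace(lo, hi, n) if n > 1 else np.array([lo]))
    rows = list(product(*axes))
    table = pd.DataFrame(rows, columns=list(SUGARS))
    return MixtureDesign(table=table, metadata={
        "levels": {s: int(levels[s]) for s in SUGARS},
        "ranges": {s: list(map(float, ranges[s])) for s in SUGARS},
    })


def random_design(n: int, ranges: dict | None = None,
                  seed: int = 0) -> MixtureDesign:
    """Uniform random concentrations over the calibration ranges
    (independent validation sets)."""
    ranges = dict(DESIGN_RANGES) if ranges is None else dict(ranges)
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {s: rng.uniform(*ranges[s], size=n) for s in SUGARS})
    return MixtureDesign(table=table, metadata={
        "random": True, "n": int(n), "seed": int(seed),
        "ranges": {s: list(map(float, ranges[s])) for s in SUGARS},
    })


def default_juice_noise_sd(lib: ComponentLibrary,
                           ranges: dict | None = None,
                           fraction: float = 0.002) -> float:
    """Noise SD as a fraction (default 0.2%) of the maximum sugar band
    absorbance at mid-range concentration."""
    ranges = dict(DESIGN_RANGES) if ranges is None else dict(ranges)
    peak = max(0.5 * (ranges[s][0] + ranges[s][1]) * lib.spectrum(s).max()
               for s in SUGARS)
    return fraction * peak


def simulate_juice_spectra(design: MixtureDesign, lib: ComponentLibrary,
                           noise_sd: float | None = None,
                           seed: int = 0) -> SpectraSet:
    """A(ν) = water(ν) + Σ_i c_i·ε_i(ν) + N(0, noise_sd), with the
    design attached as the reference table."""
    if noise_sd is None:
        noise_sd = default_juice_noise_sd(lib)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    conc = design.table[list(SUGARS)].to_numpy(dtype=float)
    comps = np.vstack([lib.spectrum(s) for s in SUGARS])  # (3, p)
    base = lib.spectrum("water")[None, :] + conc @ comps
    noise = rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 0.0
    ids = [f"mix-{i:04d}" for i in range(conc.shape[0])]
    return SpectraSet(grid=lib.grid.copy(), matrix=base + noise,
                      sample_ids=ids,
                      reference=design.table[list(SUGARS)].copy(),
                      metadata={"noise_sd": float(noise_sd), "seed": int(seed)})


def simulate_bagasse_set(n: int, lib: ComponentLibrary,
                         d_range: tuple = D_RANGE_DEFAULT,
                         noise_sd_spectral: float = 0.001,
                         noise_sd_d: float = 0.3,
                         scatter_sd: float = 0.05,
                         offset_sd: float = 0.01,
                         seed: int = 0) -> SpectraSet:
    """Bagasse spectra with latent wall composition and noisy digestibility.

    Latent digestibility is drawn uniformly over ``d_range`` (screening
    calibration sets are assembled to approach a uniform digestibility
    distribution); the wall composition x = (cellulose, xylan, lignin)
    on the simplex is derived from it so that digestibility is exactly
    affine in x, with the non-cellulosic remainder split by a Beta(3, 2)
    draw.  Spectrum = m·Σ x_j ε_j(ν) + a + noise with multiplicative
    scatter m ~ LogNormal(0, scatter_sd) and additive offset
    a ~ N(0, offset_sd) (exercising EMSC); the digestibility reference
    carries N(0, noise_sd_d) assay noise.
    """
    if n < 2:
        raise ValueError("need n >= 2 bagasse samples")
    lo, hi = d_range
    if not hi > lo:
        raise ValueError("invalid digestibility range")
    rng = np.random.default_rng(seed)
    comps = np.vstack([lib.spectrum(c) for c in WALL_COMPONENTS])  # (3, p)
    d_latent = rng.uniform(lo, hi, size=n)
    x_cell = (d_latent - lo) / (hi - lo)
    split = rng.beta(3.0, 2.0, size=n)
    x = np.column_stack([x_cell, (1.0 - x_cell) * split,
                         (1.0 - x_cell) * (1.0 - split)])  # (n, 3)
    clean = x @ comps
    m = rng.lognormal(0.0, scatter_sd, size=n) if scatter_sd > 0 else np.ones(n)
    a = rng.normal(0.0, offset_sd, size=n) if offset_sd > 0 else np.zeros(n)
    noise = (rng.normal(0.0, noise_sd_spectral, size=clean.shape)
             if noise_sd_spectral > 0 else 0.0)
    matrix = clean * m[:, None] + a[:, None] + noise
    d = d_latent.copy()
    if noise_sd_d > 0:
        d += rng.normal(0.0, noise_sd_d, size=n)
    ids = [f"bagasse-{i:04d}" for i in range(n)]
    reference = pd.DataFrame({
        "digestibility": d,
        "cellulose": x[:, 0], "xylan": x[:, 1], "lignin": x[:, 2],
    })
    return SpectraSet(grid=lib.grid.copy(), matrix=matrix, sample_ids=ids,
                      reference=reference,
                      metadata={"seed": int(seed), "d_range": [lo, hi]})


#: Whole-stalk population conditions: heights and fresh weights span the
#: printed field ranges of the 15 correlation genotypes.
STALK_HEIGHT_RANGE_CM = (237.0, 338.0)
STALK_FW_RANGE_G = (228.0, 941.0)


def simulate_stalk_population(n: int,
                              ratios: FixedRatioTable = DEFAULT_FIXED_RATIOS,
                              noise_cv: float = 0.05,
                              seed: int = 0) -> pd.DataFrame:
    """Paired field table: whole-stalk truths + fourth-internode measures.

    Geometry obeys the frustum invariants; each internode measurement
    equals the whole-stalk value × V_ratio × fixed ratio × (1 +
    N(0, noise_cv)) for extensive analytes (V_ratio omitted for
    intensive ones).  Whole-stalk truths are retained (``ws_*``
    columns) for recovery tests.
    """
    if n < 3:
        raise ValueError("need n >= 3 stalks")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    H = rng.uniform(*STALK_HEIGHT_RANGE_CM, size=n)
    R = rng.uniform(0.8, 1.6, size=n)
    r = R * rng.uniform(0.55, 0.90, size=n)
    H_B = H * rng.uniform(0.08, 0.22, size=n)
    L_SI = rng.uniform(8.0, 20.0, size=n)

    ws = {
        "FW": rng.uniform(*STALK_FW_RANGE_G, size=n),
        "sucrose": rng.uniform(120.0, 461.0, size=n),
        "glucose": rng.uniform(52.0, 126.0, size=n),
        "fructose": rng.uniform(22.0, 70.0, size=n),
        "digestibility": rng.uniform(*D_RANGE_DEFAULT, size=n),
    }
    ws["DW"] = ws["FW"] * rng.uniform(0.18, 0.32, size=n)

    v_ratio = np.array([
        volumetric_ratio(StalkGeometry(H[i], R[i], r[i], H_B[i], L_SI[i]))
        for i in range(n)
    ])
    data = {
        "sample_id": [f"stalk-{i:04d}" for i in range(n)],
        "H_cm": H, "R_cm": R, "r_cm": r, "HB_cm": H_B, "LSI_cm": L_SI,
        "v_ratio": v_ratio,
    }
    for analyte, truth in ws.items():
        ar = ratios[analyte]
        eps = rng.normal(0.0, noise_cv, size=n) if noise_cv > 0 else np.zeros(n)
        scale = v_ratio if ar.extensive else 1.0
        data[f"ws_{analyte}"] = truth
        data[f"in_{analyte}"] = truth * scale * ar.ratio * (1.0 + eps)
    return pd.DataFrame(data)
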
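"""Conical-frustum stalk geometry and internode-to-whole-stalk extrapolation.

A sorghum-type stalk is modelled as a conical frustum of height ``H``
with base radius ``R`` and top radius ``r``:

    V_WS = πH/3 · (r² + rR + R²)

The sampled internode occupies the segment [H_B, H_B + L_SI] along the
stalk; its end radii follow the linear taper

    R_I = R − H_B·(R−r)/H,    r_I = R − (H_B + L_SI)·(R−r)/H

and its volume is the frustum formula on that segment.  The volumetric
ratio ``V_ratio = V_SI / V_WS`` extrapolates extensive internode
measurements (fresh/dry weight, sugar mass) to the whole stalk by
division; intensive quantities (concentrations, digestibility rates)
are corrected only by an empirically determined fixed
internode-to-whole-stalk ratio per analyte.

All lengths are in cm, masses in g.  Field sheets record diameters;
the loader halves them once at ingest so every type stores radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class StalkGeometry:
    """Field measurements of one stalk (cm): H, R, r, H_B, L_SI."""

    H: float       # stalk height
    R: float       # base radius
    r: float       # top radius
    H_B: float = 0.0   # base of stalk → bottom of sampled internode
    L_SI: float = 0.0  # sampled internode length

    def __post_init__(self) -> None:
        if not self.H > 0:
            raise ValueError("stalk height H must be positive")
        if not self.r > 0:
            raise ValueError("top radius r must be positive")
        if self.R < self.r:
            raise ValueError("inverted taper rejected: base radius R must be >= r")
        if self.H_B < 0:
            raise ValueError("H_B must be non-negative")
        if self.L_SI < 0:
            raise ValueError("L_SI must be non-negative")
        if self.H_B + self.L_SI > self.H * (1 + 1e-12):
            raise ValueError("sampled internode extends beyond stalk (H_B + L_SI > H)")


@dataclass
class AnalyteRatio:
    """Fixed internode-to-whole-stalk ratio for one analyte."""

    ratio: float
    se: float = 0.0
    extensive: bool = True

    def __post_init__(self) -> None:
        if not self.ratio > 0:
            raise ValueError("fixed ratio must be positive")


@dataclass
class FixedRatioTable:
    """Per-analyte fixed ratios with standard errors and extensivity flags."""

    ratios: dict = field(default_factory=dict)

    def __getitem__(self, analyte: str) -> AnalyteRatio:
        if analyte not in self.ratios:
            raise KeyError(f"unknown analyte {analyte!r}")
        return self.ratios[analyte]

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.ratios

    def analytes(self) -> list[str]:
        return list(self.ratios)


#: Fourth-internode defaults determined on 15 field-grown sweet sorghum
#: genotypes; species-specific and overridable via config.
DEFAULT_FIXED_RATIOS = FixedRatioTable({
    "FW": AnalyteRatio(0.91, 0.02, extensive=True),
    "DW": AnalyteRatio(1.00, 0.02, extensive=True),
    "sucrose": AnalyteRatio(0.97, 0.02, extensive=False),
    "glucose": AnalyteRatio(1.05, 0.02, extensive=False),
    "fructose": AnalyteRatio(0.97, 0.02, extensive=False),
    "digestibility": AnalyteRatio(1.29, 0.05, extensive=False),
})


def whole_stalk_volume(g: StalkGeometry) -> float:
    """Frustum volume of the whole stalk, cm³."""
    return np.pi * g.H / 3.0 * (g.r ** 2 + g.r * g.R + g.R ** 2)


def internode_radii(g: StalkGeometry) -> tuple[float, float]:
    """(R_I, r_I): end radii of the sampled internode by linear taper."""
    slope = (g.R - g.r) / g.H
    R_I = g.R - g.H_B * slope
    r_I = g.R - (g.H_B + g.L_SI) * slope
    return R_I, r_I


def internode_volume(g: StalkGeometry) -> float:
    """Frustum volume of the sampled internode segment, cm³."""
    if not g.L_SI > 0:
        raise ValueError("internode length L_SI must be positive")
    R_I, r_I = internode_radii(g)
    return np.pi * g.L_SI / 3.0 * (R_I ** 2 + r_I * R_I + r_I ** 2)


def volumetric_ratio(g: StalkGeometry) -> float:
    """V_ratio = V_SI / V_WS, in (0, 1]."""
    return internode_volume(g) / whole_stalk_volume(g)


def extrapolate_to_whole_stalk(value: float, v_ratio: float,
                               fixed_ratio: float = 1.0,
                               extensive: bool = True) -> float:
    """Whole-stalk estimate from a sampled-internode measurement.

    Extensive quantities (masses): value / V_ratio / fixed_ratio.
    Intensive quantities (concentrations, rates): value / fixed_ratio.
    """
    if not 0 < v_ratio <= 1:
        raise ValueError("v_ratio must be in (0, 1]")
    if not fixed_ratio > 0:
        raise ValueError("fixed_ratio must be positive")
    if extensive:
        return value / v_ratio / fixed_ratio
    return value / fixed_ratio


@dataclass
class RatioEstimate:
    ratio: float
    se: float
    correlation: float
    rmsep_pct: float
    n: int
    extensive: bool


def estimate_fixed_ratios(paired: pd.DataFrame,
                          analytes: dict | None = None) -> dict:
    """Estimate fixed ratios from paired internode / whole-stalk data.

    ``paired`` needs per-analyte columns ``in_<analyte>`` and
    ``ws_<analyte>`` plus a ``v_ratio`` column (or the geometry columns
    ``H_cm, R_cm, r_cm, HB_cm, LSI_cm`` from which it is computed).
    ``analytes`` maps analyte name → extensive flag; defaults to the
    shipped fixed-ratio table's convention.

    Per analyte: ratio = mean(extrapolated internode value /
    whole-stalk value), its standard error, the Pearson correlation of
    extrapolated versus whole-stalk values, and RMSEP% — the RMSE of
    ratio-adjusted estimates relative to the whole-stalk mean, ×100.
    """
    if analytes is None:
        analytes = {a: DEFAULT_FIXED_RATIOS[a].extensive
                    for a in DEFAULT_FIXED_RATIOS.analytes()
                    if f"in_{a}" in paired.columns}
    if not analytes:
        raise ValueError("no analyte columns found")
    if "v_ratio" in paired.columns:
        v_ratio = paired["v_ratio"].to_numpy(dtype=float)
    else:
        v_ratio = np.array([
            volumetric_ratio(StalkGeometry(row.H_cm, row.R_cm, row.r_cm,
                                           row.HB_cm, row.LSI_cm))
            for row in paired.itertuples()
        ])
    out = {}
    for analyte, extensive in analytes.items():
        iv = paired[f"in_{analyte}"].to_numpy(dtype=float)
        ws = paired[f"ws_{analyte}"].to_numpy(dtype=float)
        n = iv.size
        if n < 3:
            raise ValueError(f"insufficient pairs for {analyte!r} (need >= 3)")
        extrap = iv / v_ratio if extensive else iv
        per_sample = extrap / ws
        ratio = float(per_sample.mean())
        se = float(per_sample.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if np.ptp(ws) > 0 and np.ptp(extrap) > 0:
            corr = float(np.corrcoef(extrap, ws)[0, 1])
        else:
            corr = 1.0 if np.allclose(extrap, ws * ratio) else float("nan")
        adjusted = extrap / ratio
        rmse = float(np.sqrt(np.mean((adjusted - ws) ** 2)))
        rmsep_pct = 100.0 * rmse / float(ws.mean())
        out[analyte] = RatioEstimate(ratio=ratio, se=se, correlation=corr,
                                     rmsep_pct=rmsep_pct, n=n,
                                     extensive=extensive)
    return out


def read_field_table(path) -> pd.DataFrame:
    """Read a field-measurement CSV, halving diameter columns to radii.

    Expected columns: ``sample_id, H_cm, base_diameter_cm,
    top_diameter_cm, HB_cm, LSI_cm`` plus optional measurement columns
    (``FW_g, DW_g`` and analyte columns).  Radii columns ``R_cm, r_cm``
    are accepted as an alternative to diameters.
    """
    df = pd.read_csv(path)
    if "base_diameter_cm" in df.columns:
        df["R_cm"] = df.pop("base_diameter_cm").astype(float) / 2.0
    if "top_diameter_cm" in df.columns:
        df["r_cm"] = df.pop("top_diameter_cm").astype(float) / 2.0
    required = {"sample_id", "H_cm", "R_cm", "r_cm", "HB_cm", "LSI_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"field table missing columns: {sorted(missing)}")
    return df
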
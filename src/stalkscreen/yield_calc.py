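"""Total fermentable sugar yield: V·[S] + B·D, with unit conversions.

``V`` is juice volume per stalk (mL), ``[S]`` total soluble sugar
concentration (g/100 mL), ``B`` whole-stalk dry biomass (g DW) and
``D`` cell-wall digestibility (μg reducing sugar·mgDW⁻¹·h⁻¹) under an
assumed cellulase digestion duration (default 24 h).  Reducing-sugar
mass released from the cell wall is counted as fermentable sugar 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Molar masses, g/mol.
MOLAR_MASS = {
    "sucrose": 342.30,
    "glucose": 180.16,
    "fructose": 180.16,
}

#: Density of juice water used to convert FW − DW grams to mL.
WATER_DENSITY_G_PER_ML = 1.0


def molar_to_mass_conc(conc_mm: float, analyte: str) -> float:
    """mM → g/100 mL:  conc(mol/L) · M(g/mol) / 10."""
    if analyte not in MOLAR_MASS:
        raise ValueError(f"unknown analyte {analyte!r}")
    if conc_mm < 0:
        raise ValueError("concentration must be non-negative")
    return conc_mm / 1000.0 * MOLAR_MASS[analyte] / 10.0


def total_sugar_conc(sucrose_mm: float, glucose_mm: float,
                     fructose_mm: float) -> float:
    """Total soluble sugars in g/100 mL (sum of the three conversions)."""
    return (molar_to_mass_conc(sucrose_mm, "sucrose")
            + molar_to_mass_conc(glucose_mm, "glucose")
            + molar_to_mass_conc(fructose_mm, "fructose"))


def juice_volume_estimate(fw_g: float, dw_g: float,
                          density_g_per_ml: float = WATER_DENSITY_G_PER_ML,
                          extraction_efficiency: float = 1.0) -> float:
    """Juice volume (mL) from whole-stalk fresh and dry weight.

    The water fraction FW − DW (g) is taken as juice at the given
    density; an extraction-efficiency factor (default 1) can account
    for juice retained in the bagasse.
    """
    if dw_g < 0 or fw_g < 0:
        raise ValueError("weights must be non-negative")
    if dw_g > fw_g:
        raise ValueError("dry weight exceeds fresh weight")
    return (fw_g - dw_g) / density_g_per_ml * extraction_efficiency


def cell_wall_sugar_yield(b_g_dw: float, d_rate: float,
                          hours: float = 24.0) -> float:
    """Grams of reducing sugar released: D · (B in mg) · hours · 10⁻⁶."""
    if b_g_dw < 0 or d_rate < 0 or hours < 0:
        raise ValueError("inputs must be non-negative")
    return d_rate * (b_g_dw * 1000.0) * hours * 1e-6


@dataclass
class YieldInputs:
    """Per-stalk inputs to the fermentable sugar yield equation."""

    V_ml: float                  # juice volume
    S_g_per_100ml: float         # total soluble sugar concentration
    B_g_dw: float                # whole-stalk dry biomass
    D_rate: float                # digestibility, μg·mgDW⁻¹·h⁻¹
    digestion_hours: float = 24.0

    def __post_init__(self) -> None:
        for name in ("V_ml", "S_g_per_100ml", "B_g_dw", "D_rate",
                     "digestion_hours"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class YieldResult:
    """Fermentable sugar per stalk, grams, by fraction and total."""

    soluble_sugar_g: float
    cell_wall_sugar_g: float
    total_g: float


def total_fermentable_yield(inputs: YieldInputs) -> YieldResult:
    """soluble = V/100 · [S];  cell wall = B·D over the digestion window."""
    soluble = inputs.V_ml / 100.0 * inputs.S_g_per_100ml
    wall = cell_wall_sugar_yield(inputs.B_g_dw, inputs.D_rate,
                                 inputs.digestion_hours)
    return YieldResult(soluble_sugar_g=soluble, cell_wall_sugar_g=wall,
                       total_g=soluble + wall)
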
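"""Reference-value arithmetic for the two calibrated traits.

Acetyl bromide lignin: wood powder is solubilised in 25% acetyl
bromide/acetic acid (default 1 mg in 1 mL), a 100 µL aliquot is diluted to
2 mL, and the A280 of the solution gives the lignin mass fraction by
Beer-Lambert with the published extinction coefficient
ε = 20.09 L g⁻¹ cm⁻¹.  Under the default dilution the cuvette wood
concentration is 0.05 g L⁻¹, so lignin % = A280 × 100 / (20.09 × 0.05)
= A280 × 99.552.

Gross calorific value: bomb calorimetry against benzoic acid
(26457 J g⁻¹).  The standard run fixes the calorimeter constant
C = E_std · m / ΔT; a sample run then yields E = C · ΔT / m.

Also provides the trait-correlation statistic (squared Pearson r with a
two-sided t-test p-value) used to ask whether lignin predicts the energy
content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LigninAssay",
    "CalorimetryRun",
    "BENZOIC_ACID_J_PER_G",
    "ACETYL_BROMIDE_EPSILON",
    "lignin_percent",
    "calorimeter_constant",
    "gross_calorific_value",
    "trait_correlation",
]

#: Certified net calorific value of the benzoic-acid standard, J g^-1.
BENZOIC_ACID_J_PER_G = 26457.0
#: Extinction coefficient of acetyl-bromide-solubilised lignin, L g^-1 cm^-1.
ACETYL_BROMIDE_EPSILON = 20.09


@dataclass(frozen=True)
class LigninAssay:
    """One acetyl bromide assay observation (defaults = standard dilution)."""

    a280: float
    sample_mass_mg: float = 1.0
    moisture_fraction: float = 0.0
    reaction_volume_mL: float = 1.0
    aliquot_mL: float = 0.1
    final_volume_mL: float = 2.0
    epsilon: float = ACETYL_BROMIDE_EPSILON
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.a280 < 0:
            raise ValueError("a280 must be >= 0")
        for name in ("sample_mass_mg", "reaction_volume_mL", "aliquot_mL",
                     "final_volume_mL", "epsilon", "path_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.moisture_fraction < 1.0:
            raise ValueError("moisture_fraction must be in [0, 1)")


def lignin_percent(assay: LigninAssay) -> float:
    """Lignin as % w/w of oven-dry wood from one assay.

    The cuvette wood concentration is
    c = (m_dry / V_reaction) × (V_aliquot / V_final) in g L⁻¹ with
    m_dry = m_air_dry × (1 − moisture); the lignin mass fraction is
    A280 / (ε · c · path), returned ×100.
    """
    mass_dry_g = assay.sample_mass_mg * 1e-3 * (1.0 - assay.moisture_fraction)
    c = (mass_dry_g / (assay.reaction_volume_mL * 1e-3)) * (
        assay.aliquot_mL / assay.final_volume_mL
    )
    if c <= 0:
        raise ValueError("zero cuvette concentration")
    return 100.0 * assay.a280 / (assay.epsilon * c * assay.path_cm)


@dataclass(frozen=True)
class CalorimetryRun:
    """One bomb-calorimeter combustion."""

    delta_T: float
    sample_mass_g: float
    calorimeter_constant: float | None = None
    standard_value: float = BENZOIC_ACID_J_PER_G

    def __post_init__(self) -> None:
        if self.delta_T <= 0:
            raise ValueError("delta_T must be > 0")
        if self.sample_mass_g <= 0:
            raise ValueError("sample_mass_g must be > 0")


def calorimeter_constant(standard_run: CalorimetryRun) -> float:
    """Effective heat capacity C = E_std · m / ΔT from a benzoic-acid run."""
    return standard_run.standard_value * standard_run.sample_mass_g / standard_run.delta_T


def gross_calorific_value(run: CalorimetryRun, constant: float | None = None) -> float:
    """Gross calorific value E = C · ΔT / m (J g⁻¹)."""
    C = run.calorimeter_constant if constant is None else constant
    if C is None or C <= 0:
        raise ValueError("calorimeter constant not set")
    return C * run.delta_T / run.sample_mass_g


def trait_correlation(
    lignin_values: Sequence[float], energy_values: Sequence[float]
) -> tuple[float, float]:
    """Squared Pearson correlation and two-sided p-value of paired traits.

    The p-value comes from the t transform t = r·√((n−2)/(1−r²)) with n−2
    degrees of freedom.
    """
    x = np.asarray(lignin_values, dtype=float)
    y = np.asarray(energy_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the traits")
    res = stats.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)
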
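"""PTV margin from variance components via the van Herk recipe.

With N fractions per patient, the inter-fraction component is
re-apportioned between the systematic and random roles:

    Sigma_eff^2 = Sigma_pt^2 + sigma_fr^2 / N
    sigma_eff^2 = (1 - 1/N) * sigma_fr^2 + sigma_intra^2

and the margin is ``2.5 * Sigma_eff + 0.7 * sigma_eff`` — the coefficients
that keep the CTV minimum dose at 95% of prescription for 90% of patients.
The margin is one-dimensional: it applies along the measurement direction
in the beam's-eye-view plane, not as an isotropic 3-D expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .varcomp import VarianceComponents

VAN_HERK_SYSTEMATIC = 2.5
VAN_HERK_RANDOM = 0.7


def effective_errors(sigma_pt: float, sigma_fr: float, sigma_intra: float,
                     n_fractions: int) -> tuple[float, float]:
    """Effective systematic and random SDs (mm) at N fractions.

    At N=1 the whole inter-fraction variance acts systematically; as
    N grows it migrates to the random pool.
    """
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    for name, val in (("sigma_pt", sigma_pt), ("sigma_fr", sigma_fr),
                      ("sigma_intra", sigma_intra)):
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    sigma_eff_sys = math.sqrt(sigma_pt**2 + sigma_fr**2 / n_fractions)
    sigma_eff_rand = math.sqrt((1.0 - 1.0 / n_fractions) * sigma_fr**2 + sigma_intra**2)
    return sigma_eff_sys, sigma_eff_rand


def ptv_margin(sigma_eff_sys: float, sigma_eff_rand: float,
               c_sys: float = VAN_HERK_SYSTEMATIC,
               c_rand: float = VAN_HERK_RANDOM) -> float:
    """Margin (mm) = c_sys * Sigma_eff + c_rand * sigma_eff."""
    if sigma_eff_sys < 0 or sigma_eff_rand < 0:
        raise ValueError("effective errors must be >= 0")
    if c_sys < 0 or c_rand < 0:
        raise ValueError("margin coefficients must be >= 0")
    return c_sys * sigma_eff_sys + c_rand * sigma_eff_rand


@dataclass(frozen=True)
class MarginResult:
    """Margin computation for one fraction count, all lengths in mm."""

    n_fractions: int
    sigma_pt_mm: float
    sigma_fr_mm: float
    sigma_intra_mm: float
    sigma_eff_sys_mm: float
    sigma_eff_rand_mm: float
    ptv_margin_mm: float
    c_sys: float = VAN_HERK_SYSTEMATIC
    c_rand: float = VAN_HERK_RANDOM

    def to_dict(self) -> dict:
        return {
            "n_fractions": self.n_fractions,
            "sigma_pt_mm": self.sigma_pt_mm,
            "sigma_fr_mm": self.sigma_fr_mm,
            "sigma_intra_mm": self.sigma_intra_mm,
            "sigma_eff_systematic_mm": self.sigma_eff_sys_mm,
            "sigma_eff_random_mm": self.sigma_eff_rand_mm,
            "ptv_margin_mm": self.ptv_margin_mm,
            "coefficients": {"systematic": self.c_sys, "random": self.c_rand},
            "scope": "one-dimensional margin along the measurement direction "
                     "in the beam's-eye-view plane",
        }

    def table(self) -> str:
        """Rendered text report: error block, effective block, margin."""
        lines = [
            f"{'':<36}{'(mm)':>8}",
            "Breath-hold error components",
            f"  Inter-patient SD (Sigma_pt){'':<7}{self.sigma_pt_mm:>8.2f}",
            f"  Inter-fraction SD (sigma_fr){'':<6}{self.sigma_fr_mm:>8.2f}",
            f"  Intra-fraction SD (sigma_intra){'':<3}{self.sigma_intra_mm:>8.2f}",
            f"Effective errors at N = {self.n_fractions}",
            f"  Systematic (Sigma_eff){'':<12}{self.sigma_eff_sys_mm:>8.2f}",
            f"  Random (sigma_eff){'':<16}{self.sigma_eff_rand_mm:>8.2f}",
            f"PTV margin ({self.c_sys} Sigma_eff + {self.c_rand} sigma_eff)"
            f"{self.ptv_margin_mm:>8.2f}",
            "(one direction on the BEV plane)",
        ]
        return "\n".join(lines)


def margin_report(components: VarianceComponents, n_fractions: int,
                  c_sys: float = VAN_HERK_SYSTEMATIC,
                  c_rand: float = VAN_HERK_RANDOM) -> MarginResult:
    """Chain the effective-error split and the margin for a fitted model."""
    s_sys, s_rand = effective_errors(components.sigma_pt, components.sigma_fr,
                                     components.sigma_intra, n_fractions)
    return MarginResult(
        n_fractions=int(n_fractions),
        sigma_pt_mm=components.sigma_pt,
        sigma_fr_mm=components.sigma_fr,
        sigma_intra_mm=components.sigma_intra,
        sigma_eff_sys_mm=s_sys,
        sigma_eff_rand_mm=s_rand,
        ptv_margin_mm=ptv_margin(s_sys, s_rand, c_sys, c_rand),
        c_sys=c_sys, c_rand=c_rand,
    )
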
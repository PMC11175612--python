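"""qPCR closed forms: primer efficiency from a dilution series and
reference-normalised fold change from threshold-cycle (CT) values.

Efficiency of a primer pair is estimated from the slope ``s`` of the
CT-vs-log(dilution) standard curve for dilution factor ``d``::

    E = d ** (-1 / s)

A perfect doubling per cycle gives E = 2 (e.g. d = 10, s = -3.3219);
primer pairs are conventionally accepted when E lies in [1.9, 2.2].

Fold change between control and mutant conditions, normalised to a reference
gene, uses the delta-CT form::

    fold = 2**(CT_goi_control - CT_goi_mutant) / 2**(CT_ref_control - CT_ref_mutant)

which is invariant to adding a constant to all four CT values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EfficiencyReport", "qpcr_efficiency", "qpcr_fold_change",
           "EFFICIENCY_BAND"]

EFFICIENCY_BAND = (1.9, 2.2)


@dataclass(frozen=True)
class EfficiencyReport:
    efficiency: float
    dilution: float
    slope: float
    in_band: bool
    band: tuple[float, float] = EFFICIENCY_BAND


def qpcr_efficiency(d: float, s: float) -> EfficiencyReport:
    """Amplification efficiency E = d**(-1/s) with the [1.9, 2.2] band flag."""
    if not d > 1:
        raise ValueError("dilution factor d must be > 1")
    if s == 0:
        raise ValueError("slope s must be non-zero")
    e = d ** (-1.0 / s)
    lo, hi = EFFICIENCY_BAND
    return EfficiencyReport(efficiency=float(e), dilution=float(d), slope=float(s),
                            in_band=lo <= e <= hi)


def qpcr_fold_change(ct_goi_control: float, ct_goi_mutant: float,
                     ct_ref_control: float, ct_ref_mutant: float) -> float:
    """Reference-normalised fold change from four CT values (mutant relative
    to control)."""
    for name, val in (("ct_goi_control", ct_goi_control),
                      ("ct_goi_mutant", ct_goi_mutant),
                      ("ct_ref_control", ct_ref_control),
                      ("ct_ref_mutant", ct_ref_mutant)):
        if val is None:
            raise ValueError(f"missing CT value: {name}")
        if val < 0:
            raise ValueError(f"{name} must be >= 0 cycles, got {val}")
    d_goi = ct_goi_control - ct_goi_mutant
    d_ref = ct_ref_control - ct_ref_mutant
    return float(2.0**d_goi / 2.0**d_ref)
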
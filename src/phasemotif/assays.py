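"""Closed-form readout calculations for condensate bench assays.

Relative turbidity converts plate-reader absorbance at 600 nm into a
percent scale: tau_rel% = 100 - 100 * 10^(-A600).  Encapsulation
efficiency compares total fluorophore concentration with what remains in
the supernatant after pelleting the droplets: %EE = 100 * (CT - Csup)/CT.
"""

from __future__ import annotations

import warnings


def relative_turbidity(a600: float, blank: float = 0.0) -> float:
    """Relative turbidity in percent from absorbance at 600 nm.

    Optional blank absorbance is subtracted first.  Monotone increasing in
    a600, 0 at a600 = 0, asymptote 100.
    """
    a600 = a600 - blank
    if a600 < 0:
        raise ValueError(f"negative blank-corrected absorbance {a600}")
    return 100.0 - 100.0 * 10.0 ** (-a600)


def encapsulation_efficiency(c_total: float, c_sup: float) -> float:
    """Encapsulation efficiency in percent from total and supernatant concentrations.

    Scale-invariant in the concentration units.  A supernatant reading above
    the total (evaporation/measurement noise) clamps to 0 with a warning.
    """
    if c_total <= 0:
        raise ValueError(f"c_total must be positive, got {c_total}")
    if c_sup < 0:
        raise ValueError(f"c_sup must be non-negative, got {c_sup}")
    if c_sup > c_total:
        warnings.warn(
            f"supernatant concentration {c_sup} exceeds total {c_total}; EE clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * (c_total - c_sup) / c_total
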
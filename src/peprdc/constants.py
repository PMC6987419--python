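"""Physical constants and default parameter tables.

Everything here is configuration: gyromagnetic ratios, reference bond
lengths, dipolar normalization factors, Karplus coefficients and the
qualitative coupling-class cutoffs.  All are overridable; the shipped values
are standard literature numbers, not fitted quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Gyromagnetic ratios, rad s^-1 T^-1
GAMMA = {
    "H": 2.6752218744e8,
    "C": 6.728284e7,
    "N": -2.7116e7,
}

#: Reference (vibrationally averaged) bond lengths, Å
BOND_LENGTHS = {
    "N-HN": 1.041,
    "CA-HA": 1.117,
    "C-CA": 1.526,
    "N-C": 1.329,
    "CB-HB": 1.117,
}

_MU0 = 4.0e-7 * math.pi
_H_PLANCK = 6.62607015e-34


def dmax_hz(gamma_i: float, gamma_j: float, r_angstrom: float) -> float:
    """Static dipolar interaction constant (Hz) for a pair at distance r.

    D(θ) = dmax · bᵀ S b for a unit bond vector b and Saupe matrix S.
    """
    r = r_angstrom * 1e-10
    return -_MU0 * _H_PLANCK * gamma_i * gamma_j / (16.0 * math.pi**3 * r**3)


@dataclass(frozen=True)
class DipolarConstants:
    """Per-coupling-type dipolar constants and N-H normalization factors.

    ``factor(t)`` is the signed ratio dmax(t)/dmax(N-HN); dividing an observed
    coupling of type t by it expresses the coupling on the ¹D_NH scale.
    The N-HN factor is identically 1.
    """

    gammas: dict = field(default_factory=lambda: dict(GAMMA))
    bond_lengths: dict = field(default_factory=lambda: dict(BOND_LENGTHS))

    _PAIRS = {
        "N-HN": ("N", "H", "N-HN"),
        "CA-HA": ("C", "H", "CA-HA"),
        "C-CA": ("C", "C", "C-CA"),
        "N-C": ("N", "C", "N-C"),
        "CB-HB": ("C", "H", "CB-HB"),
        # a summed pair of two C-H couplings shares the single-pair constant
        "SUM-CBHB": ("C", "H", "CB-HB"),
    }

    def dmax(self, rdc_type: str) -> float:
        try:
            gi, gj, rkey = self._PAIRS[rdc_type]
        except KeyError:
            raise KeyError(f"unknown RDC type {rdc_type!r}") from None
        return dmax_hz(self.gammas[gi], self.gammas[gj], self.bond_lengths[rkey])

    def factor(self, rdc_type: str) -> float:
        return self.dmax(rdc_type) / self.dmax("N-HN")


DEFAULT_CONSTANTS = DipolarConstants()

#: Karplus coefficients (A, B, C) in J = A cos²θ + B cosθ + C, Hz.
#: Generic ³J(HαHβ) and ³J(NHβ) parameter sets; configuration defaults.
KARPLUS_HAHB = (9.5, -1.6, 1.8)
KARPLUS_NHB = (-4.4, 1.2, 0.1)

#: Quantitative → qualitative mapping for ³J(HαHβ) (Hz).
JHAHB_SMALL_MAX = 5.0
JHAHB_LARGE_MIN = 10.0
#: The rotamer-averaging band reported for methylene ³J(HαHβ).
JHAHB_AVERAGE_BAND = (5.0, 9.0)
#: Methine high thresholds; Thr is lower because of the oxygen substituent.
JMETHINE_HIGH = {"VAL": 10.0, "ILE": 10.0, "THR": 9.0}
JMETHINE_LOW = 5.0

#: |³J(NHβ)| class cutoffs (Hz): small ≤ first, large ≥ second.
JNHB_CLASS_CUTOFFS = (1.5, 3.0)
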
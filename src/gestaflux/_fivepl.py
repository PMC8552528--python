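"""Five-parameter logistic (5PL) curve primitives.

The 5PL is the standard calibration function for bead-based immunoassays:

    FI(x) = d + (a - d) / (1 + (x / c)**b)**g

where ``a`` is the zero-concentration (background) asymptote, ``d`` the
saturating asymptote, ``c`` the inflection-scale concentration, ``b`` the
slope and ``g`` the asymmetry.  ``g = 1`` recovers the symmetric 4PL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FivePL:
    """5PL parameter set; strictly monotone between the asymptotes for b, g > 0."""

    a: float  # response at zero concentration
    b: float  # slope factor (> 0)
    c: float  # inflection-scale concentration (> 0)
    d: float  # response at saturating concentration
    g: float = 1.0  # asymmetry (> 0); 1 == 4PL

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0 or self.g <= 0:
            raise ValueError("5PL requires b > 0, c > 0, g > 0")
        if self.a == self.d:
            raise ValueError("5PL asymptotes must differ")

    @property
    def increasing(self) -> bool:
        return self.d > self.a

    def __call__(self, conc):
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            out = self.d + (self.a - self.d) / (1.0 + (conc / self.c) ** self.b) ** self.g
        return out

    def inverse(self, fi):
        """Concentration at response ``fi``; NaN outside the open asymptote interval."""
        fi = np.asarray(fi, dtype=float)
        lo, hi = sorted((self.a, self.d))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (self.a - self.d) / (fi - self.d)
            inner = ratio ** (1.0 / self.g) - 1.0
            conc = self.c * inner ** (1.0 / self.b)
        conc = np.where((fi > lo) & (fi < hi), conc, np.nan)
        return conc

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.g])


def fivepl(conc, a, b, c, d, g):
    """Functional form, convenient for curve fitting."""
    conc = np.asarray(conc, dtype=float)
    return d + (a - d) / (1.0 + (conc / c) ** b) ** g
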
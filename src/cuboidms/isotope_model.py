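"""Theoretical isotopic envelopes and peak-height ratios for tryptic peptides.

The central abstraction is a *ratio model*: given a monoisotopic mass, it
predicts the expected peak-height ratio ``I[i+1] / I[i]`` between
consecutive isotopic peaks.  Envelopes are always derived by chaining
these ratios from the monoisotopic peak, so the ratio model is the single
source of truth shared by deconvolution scoring, detector-saturation
correction, and the synthetic-data generator.

The default model is averagine based: the average amino-acid composition
C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 is scaled to the target mass and
the aggregated isotope distribution is computed by polynomial convolution
of the elemental isotope distributions.  A user-supplied table of ratio
polynomial coefficients can replace it (:class:`TableRatioModel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

#: Senko's averagine: average elemental composition per 111.1254 Da
#: (average mass) of peptide.
AVERAGINE_COMPOSITION: dict[str, float] = {
    "C": 4.9384,
    "H": 7.7583,
    "N": 1.3577,
    "O": 1.4773,
    "S": 0.0417,
}

ELEMENT_MONO_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Aggregated (nucleon-count) isotope abundance vectors, index = extra
#: neutrons relative to the lightest isotope.
ELEMENT_ISOTOPE_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

#: Monoisotopic mass of one averagine unit.
AVERAGINE_MONO_MASS = sum(
    AVERAGINE_COMPOSITION[el] * ELEMENT_MONO_MASS[el] for el in AVERAGINE_COMPOSITION
)


class IsotopeModelRangeError(ValueError):
    """Requested a ratio outside the model's valid monoisotopic mass range."""

    def __init__(self, message: str, isotope_index: int):
        super().__init__(message)
        self.isotope_index = isotope_index


@runtime_checkable
class IsotopeRatioModel(Protocol):
    """Contract for peak-height-ratio models."""

    def ratio(self, monoisotopic_mass: float, isotope_index: int) -> float:
        """Expected ``I[i+1]/I[i]`` for a peptide of the given mass."""
        ...

    def valid_mass_range(self, isotope_index: int) -> tuple[float, float]:
        """(min Da, max Da) over which ``ratio`` is defined for this index."""
        ...


def _power_truncated(dist: np.ndarray, n: int, n_terms: int) -> np.ndarray:
    """``dist`` convolved with itself ``n`` times, truncated to n_terms."""
    result = np.zeros(n_terms)
    result[0] = 1.0
    base = np.zeros(n_terms)
    base[: len(dist)] = dist[:n_terms]
    while n > 0:
        if n & 1:
            result = np.convolve(result, base)[:n_terms]
        base = np.convolve(base, base)[:n_terms]
        n >>= 1
    return result


class AveragineRatioModel:
    """Peak-height ratios from the aggregated averagine isotope distribution.

    Parameters
    ----------
    mass_min, mass_max : float
        Valid monoisotopic mass range in Da.  Outside it, :meth:`ratio`
        raises :class:`IsotopeModelRangeError`.
    max_isotopes : int
        Number of isotope peaks kept when convolving distributions.
    """

    def __init__(self, mass_min: float = 500.0, mass_max: float = 5000.0, max_isotopes: int = 10):
        self.mass_min = float(mass_min)
        self.mass_max = float(mass_max)
        self.max_isotopes = int(max_isotopes)
        self._dist_cached = lru_cache(maxsize=4096)(self._distribution)

    def valid_mass_range(self, isotope_index: int) -> tuple[float, float]:
        return (self.mass_min, self.mass_max)

    def composition(self, monoisotopic_mass: float) -> dict[str, int]:
        """Integer elemental composition of averagine scaled to the mass.

        C, N, O and S counts are rounded to the nearest integer; hydrogens
        absorb the remaining mass so the monoisotopic mass is matched as
        closely as an integer formula allows.
        """
        n_units = monoisotopic_mass / AVERAGINE_MONO_MASS
        counts = {
            el: max(0, int(round(n_units * AVERAGINE_COMPOSITION[el])))
            for el in ("C", "N", "O", "S")
        }
        heavy_mass = sum(counts[el] * ELEMENT_MONO_MASS[el] for el in counts)
        counts["H"] = max(
            0, int(round((monoisotopic_mass - heavy_mass) / ELEMENT_MONO_MASS["H"]))
        )
        return counts

    def _distribution(self, mass_key: int) -> np.ndarray:
        counts = self.composition(float(mass_key))
        dist = np.zeros(self.max_isotopes)
        dist[0] = 1.0
        for el, n in counts.items():
            if n > 0:
                dist = np.convolve(
                    dist,
                    _power_truncated(
                        np.asarray(ELEMENT_ISOTOPE_ABUNDANCE[el]), n, self.max_isotopes
                    ),
                )[: self.max_isotopes]
        return dist

    def ratio(self, monoisotopic_mass: float, isotope_index: int) -> float:
        if isotope_index < 0:
            raise IsotopeModelRangeError("isotope_index must be >= 0", isotope_index)
        lo, hi = self.valid_mass_range(isotope_index)
        if not lo <= monoisotopic_mass <= hi:
            raise IsotopeModelRangeError(
                f"mass {monoisotopic_mass:.1f} Da outside model range "
                f"[{lo:.0f}, {hi:.0f}] for isotope index {isotope_index}",
                isotope_index,
            )
        # 1 Da mass resolution is ample for aggregated peptide envelopes
        dist = self._dist_cached(int(round(monoisotopic_mass)))
        if isotope_index + 1 >= len(dist) or dist[isotope_index] <= 0:
            raise IsotopeModelRangeError(
                f"ratio undefined for isotope index {isotope_index}", isotope_index
            )
        return float(dist[isotope_index + 1] / dist[isotope_index])


@dataclass(frozen=True)
class ConstantRatioModel:
    """Stub model with a fixed ratio everywhere; for tests and injection."""

    value: float = 0.5
    mass_min: float = 0.0
    mass_max: float = float("inf")

    def ratio(self, monoisotopic_mass: float, isotope_index: int) -> float:
        if not self.mass_min <= monoisotopic_mass <= self.mass_max:
            raise IsotopeModelRangeError("mass outside stub range", isotope_index)
        return self.value

    def valid_mass_range(self, isotope_index: int) -> tuple[float, float]:
        return (self.mass_min, self.mass_max)


class TableRatioModel:
    """Ratio model from a plug-in CSV of polynomial coefficients.

    Schema: one row per isotope index with columns ``isotope_index``,
    ``mass_min``, ``mass_max`` and ``c0, c1, ... cK``; the ratio at mass m
    is ``c0 + c1*m + ... + cK*m^K``, valid on [mass_min, mass_max].
    This is the hook for supplying published tryptic-peptide ratio
    parameterisations that are not bundled with the package.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"isotope_index", "mass_min", "mass_max"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"ratio table missing columns: {sorted(missing)}")
        coef_cols = sorted(
            (c for c in table.columns if c.startswith("c") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not coef_cols:
            raise ValueError("ratio table has no coefficient columns c0..cK")
        self._rows = {}
        for _, row in table.iterrows():
            coeffs = [float(row[c]) for c in coef_cols]
            self._rows[int(row["isotope_index"])] = (
                float(row["mass_min"]),
                float(row["mass_max"]),
                coeffs,
            )

    @classmethod
    def from_csv(cls, path) -> "TableRatioModel":
        return cls(pd.read_csv(path))

    def valid_mass_range(self, isotope_index: int) -> tuple[float, float]:
        if isotope_index not in self._rows:
            return (float("inf"), float("-inf"))  # empty range
        lo, hi, _ = self._rows[isotope_index]
        return (lo, hi)

    def ratio(self, monoisotopic_mass: float, isotope_index: int) -> float:
        if isotope_index not in self._rows:
            raise IsotopeModelRangeError(
                f"no table entry for isotope index {isotope_index}", isotope_index
            )
        lo, hi, coeffs = self._rows[isotope_index]
        if not lo <= monoisotopic_mass <= hi:
            raise IsotopeModelRangeError(
                f"mass {monoisotopic_mass:.1f} Da outside table range "
                f"[{lo:.0f}, {hi:.0f}] for isotope index {isotope_index}",
                isotope_index,
            )
        value = float(np.polynomial.polynomial.polyval(monoisotopic_mass, coeffs))
        if not np.isfinite(value) or value <= 0:
            raise IsotopeModelRangeError(
                f"table ratio non-positive at mass {monoisotopic_mass:.1f}", isotope_index
            )
        return value


def theoretical_envelope(
    monoisotopic_mass: float, n_isotopes: int, model: IsotopeRatioModel
) -> list[float]:
    """Relative isotope abundances, monoisotopic peak normalised to 1.

    ``abundances[i+1] == abundances[i] * model.ratio(mass, i)`` by
    construction; later peaks may exceed 1 at high mass.
    """
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    env = [1.0]
    for i in range(n_isotopes - 1):
        env.append(env[-1] * model.ratio(monoisotopic_mass, i))
    return env


def scoring_envelope(
    monoisotopic_mass: float, n_isotopes: int, model: IsotopeRatioModel
) -> list[float]:
    """Envelope with the mass clamped into the model's valid range.

    Deconvolution must score candidates (e.g. small MS2 fragments) whose
    mass falls outside the ratio model's strict domain; clamping to the
    nearest valid mass gives a smoothly degraded reference envelope there.
    """
    lo, hi = model.valid_mass_range(0)
    clamped = min(max(monoisotopic_mass, lo), hi)
    return theoretical_envelope(clamped, n_isotopes, model)
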
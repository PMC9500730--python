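"""Adduct m/z calculus and the SWATH acquisition-window scheme.

All species are treated as singly charged (|z| = 1), which holds for small
molecules under electrospray in the mass range covered here.  Adduct mass
deltas are sums of atomic masses of the transferred atoms minus
``charge x electron mass``, so ``adduct_mz`` is exact for ions: e.g. the
delta of [M+H]+ is the proton mass 1.0072765 Da, not the hydrogen atom mass.

The default acquisition geometry is a TOF survey scan from 50 to 1100 Da
with fixed 50 Da precursor-isolation windows, i.e. 21 windows per cycle.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .errors import ConfigurationError

# canonical adduct names per polarity (the shipped table carries the deltas)
POSITIVE_ADDUCTS = ("[M]+", "[M+H]+", "[M+Na]+", "[M+NH4]+", "[M+K]+")
NEGATIVE_ADDUCTS = (
    "[M-H]-",
    "[M+Na-2H]-",
    "[M+NH4-2H]-",
    "[M-Cl]-",
    "[M+K-2H]-",
    "[M+FA-H]-",
    "[M+H2O-H]-",
)


@dataclass(frozen=True)
class AdductDefinition:
    """A named ion species: ``m/z = neutral_mass + mass_delta`` (singly charged)."""

    name: str
    polarity: str  # "positive" | "negative"
    mass_delta: float  # Da
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ConfigurationError(f"unknown polarity {self.polarity!r}")


def _canonical(name: str) -> str:
    return name.replace(" ", "")


def load_adduct_table(path=None, chloride: str = "attach") -> dict[str, AdductDefinition]:
    """Load the adduct table (shipped CSV by default) keyed by canonical name.

    ``chloride`` selects the interpretation of the chemically anomalous
    "[M-Cl]-" species: ``"attach"`` implements chloride attachment [M+Cl]-
    (the usual ESI adduct), ``"subtract"`` the literal loss of a chlorine.
    """
    if chloride not in ("attach", "subtract"):
        raise ConfigurationError(f"chloride mode must be 'attach' or 'subtract', got {chloride!r}")
    if path is None:
        text = resources.files("swath_annotator").joinpath("adducts.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    table: dict[str, AdductDefinition] = {}
    for row in rows:
        mode = row.get("mode", "default")
        name = _canonical(row["name"])
        if name == "[M-Cl]-":
            wanted = "strict" if chloride == "subtract" else "default"
            if mode != wanted:
                continue
        elif mode == "strict":
            continue
        table[name] = AdductDefinition(
            name=name, polarity=row["polarity"], mass_delta=float(row["mass_delta"])
        )
    return table


def default_adducts(polarity: str, chloride: str = "attach") -> list[AdductDefinition]:
    """The adduct set searched per polarity: 5 positive species, 7 negative."""
    table = load_adduct_table(chloride=chloride)
    names = POSITIVE_ADDUCTS if polarity == "positive" else NEGATIVE_ADDUCTS
    if polarity not in ("positive", "negative"):
        raise ConfigurationError(f"unknown polarity {polarity!r}")
    return [table[_canonical(n)] for n in names]


def adduct_mz(neutral_mass: float, adduct: AdductDefinition | str,
              table: dict[str, AdductDefinition] | None = None) -> float:
    """m/z of ``adduct`` formed from a neutral monoisotopic mass (Da)."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral_mass must be positive, got {neutral_mass}")
    if isinstance(adduct, str):
        table = table if table is not None else load_adduct_table()
        key = _canonical(adduct)
        if key not in table:
            raise ConfigurationError(f"unknown adduct {adduct!r}")
        adduct = table[key]
    return neutral_mass + adduct.mass_delta


@dataclass(frozen=True)
class SwathWindowScheme:
    """Contiguous fixed-width precursor-isolation windows tiling [start, end).

    Windows are half-open ``[lo, hi)``; the upper edge of the last window is
    closed so ``mz == end`` is assignable.  Default: 50-1100 Da in 50 Da
    steps -> 21 windows.
    """

    start: float = 50.0
    end: float = 1100.0
    width: float = 50.0

    def __post_init__(self) -> None:
        if not (self.end > self.start and self.width > 0):
            raise ConfigurationError("require end > start and width > 0")

    @property
    def n_windows(self) -> int:
        import math

        return math.ceil((self.end - self.start) / self.width - 1e-9)

    @property
    def windows(self) -> list[tuple[float, float]]:
        return [self.window_bounds(i) for i in range(self.n_windows)]

    def window_bounds(self, index: int) -> tuple[float, float]:
        if not 0 <= index < self.n_windows:
            raise ConfigurationError(f"window index {index} outside 0..{self.n_windows - 1}")
        lo = self.start + index * self.width
        hi = min(lo + self.width, self.end)
        return (lo, hi)

    def contains(self, mz: float) -> bool:
        return self.start <= mz <= self.end

    def window_of(self, lo: float, hi: float, tol: float = 1e-6) -> int | None:
        """Index of the scheme window matching bounds (lo, hi), or None."""
        for i, (wlo, whi) in enumerate(self.windows):
            if abs(lo - wlo) <= tol and abs(hi - whi) <= tol:
                return i
        return None


def assign_window(mz: float, scheme: SwathWindowScheme) -> int:
    """SWATH window index of an m/z under the half-open [lo, hi) convention."""
    if not scheme.contains(mz):
        raise ValueError(f"m/z {mz} outside acquisition range [{scheme.start}, {scheme.end}]")
    if mz == scheme.end:
        return scheme.n_windows - 1
    return min(int((mz - scheme.start) // scheme.width), scheme.n_windows - 1)


def ppm_window(mz: float, ppm: float) -> tuple[float, float]:
    """Symmetric mass window (lo, hi) of +-``ppm`` parts-per-million around ``mz``."""
    if mz <= 0 or ppm < 0:
        raise ValueError("require mz > 0 and ppm >= 0")
    return (mz * (1.0 - ppm * 1e-6), mz * (1.0 + ppm * 1e-6))
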
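"""Shared domain types, chemical-formula arithmetic and the mineral reference table.

The quota arithmetic downstream needs three chemical facts per mineral: its
density, its Fe weight fraction (derivable from the formula) and, for
identification, its diagnostic lattice spacings.  This module owns those
facts plus the calibrated element-map containers every imaging stage consumes.

Two constant sets are supported throughout the package:

``standard``
    IUPAC 2021 abridged atomic weights (Fe = 55.845) and formula-derived
    Fe weight fractions.
``paper_compat``
    The rounded working constants of the source study of Gunflint
    microfossils (Fe molar mass 56, Fe weight fraction 0.48, mixture
    density 3.2 g/cm³), for bit-for-bit reproduction of its printed numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ATOMIC_WEIGHTS",
    "ATOMIC_WEIGHTS_VERSION",
    "AVOGADRO",
    "FE_MOLAR_MASS_PAPER",
    "ElementChannel",
    "ElementMapStack",
    "FormulaComposition",
    "MineralRef",
    "parse_formula",
    "mass_fraction",
    "mixture_density",
    "load_mineral_table",
]

AVOGADRO = 6.02214076e23
#: Rounded Fe molar mass used by the source study's quota formula.
FE_MOLAR_MASS_PAPER = 56.0

ATOMIC_WEIGHTS_VERSION = "IUPAC-2021-abridged"
#: Abridged standard atomic weights (g/mol), IUPAC 2021.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Ti": 47.867,
    "Mn": 54.938,
    "Fe": 55.845,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.38,
}


class FormulaError(ValueError):
    """Raised for malformed or chemically unknown formula strings."""


# --------------------------------------------------------------------------
# formula arithmetic
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FormulaComposition:
    """Element counts of one formula unit; fractional site occupancy allowed."""

    element_counts: Mapping[str, float]

    def __post_init__(self) -> None:
        for el, n in self.element_counts.items():
            if el not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {el!r}")
            if n <= 0:
                raise FormulaError(f"non-positive count for {el}: {n}")

    @property
    def formula_weight(self) -> float:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in self.element_counts.items())

    def mass_fractions(self) -> dict[str, float]:
        fw = self.formula_weight
        return {el: ATOMIC_WEIGHTS[el] * n / fw for el, n in self.element_counts.items()}

    def mass_fraction(self, element: str) -> float:
        if element not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {element!r}")
        return self.mass_fractions().get(element, 0.0)

    def atomic_fractions(self, elements: Sequence[str] | None = None) -> dict[str, float]:
        """Atom fractions, optionally renormalized over a subset of elements."""
        counts = dict(self.element_counts)
        if elements is not None:
            counts = {el: counts.get(el, 0.0) for el in elements}
        total = sum(counts.values())
        if total == 0:
            raise FormulaError("no atoms of the requested elements")
        return {el: n / total for el, n in counts.items()}


_TOKEN = re.compile(r"([A-Z][a-z]?)|(\d+\.\d+|\d+)|([()])")
# charge annotations like ^2+^, ^3+, 2+ after a symbol, and markdown-ish
# subscript underscores are stripped before tokenizing: EDXS-level
# stoichiometry is charge-blind.
_CHARGE = re.compile(r"\^[0-9]*[+−-]\^?|(?<=[A-Za-z)])[0-9]*[+−](?![0-9A-Za-z)])")


def parse_formula(formula: str) -> FormulaComposition:
    """Parse a mineral formula string into element counts.

    Supports integer and decimal subscripts and parenthesized groups with
    multipliers, e.g. ``"Si2O5(OH)4Fe3"`` → ``{Si: 2, O: 9, H: 4, Fe: 3}``.
    Charge annotations (``Fe^2+^``) and subscript underscores are ignored.
    """
    cleaned = _CHARGE.sub("", formula.replace("_", "").strip())
    if not cleaned:
        raise FormulaError("empty formula")

    tokens: list[str] = []
    pos = 0
    for m in _TOKEN.finditer(cleaned):
        if m.start() != pos:
            raise FormulaError(f"unparsable characters in formula {formula!r}")
        tokens.append(m.group(0))
        pos = m.end()
    if pos != len(cleaned):
        raise FormulaError(f"unparsable characters in formula {formula!r}")

    def parse_group(i: int) -> tuple[dict[str, float], int]:
        counts: dict[str, float] = {}
        while i < len(tokens):
            tok = tokens[i]
            if tok == ")":
                return counts, i
            if tok == "(":
                inner, j = parse_group(i + 1)
                if j >= len(tokens) or tokens[j] != ")":
                    raise FormulaError(f"unbalanced parentheses in {formula!r}")
                i = j + 1
                mult = 1.0
                if i < len(tokens) and tokens[i] not in "()" and not tokens[i][0].isalpha():
                    mult = float(tokens[i])
                    i += 1
                for el, n in inner.items():
                    counts[el] = counts.get(el, 0.0) + n * mult
            elif tok[0].isalpha():
                if tok not in ATOMIC_WEIGHTS:
                    raise FormulaError(f"unknown element symbol {tok!r} in {formula!r}")
                i += 1
                n = 1.0
                if i < len(tokens) and not tokens[i][0].isalpha() and tokens[i] not in "()":
                    n = float(tokens[i])
                    i += 1
                counts[tok] = counts.get(tok, 0.0) + n
            else:
                raise FormulaError(f"unexpected token {tok!r} in {formula!r}")
        return counts, i

    counts, i = parse_group(0)
    if i != len(tokens):
        raise FormulaError(f"unbalanced parentheses in {formula!r}")
    if not counts:
        raise FormulaError("empty formula")
    return FormulaComposition(counts)


def mass_fraction(comp: FormulaComposition, element: str) -> float:
    """Weight fraction of ``element`` in one formula unit (0 if absent)."""
    return comp.mass_fraction(element)


# --------------------------------------------------------------------------
# element-map containers
# --------------------------------------------------------------------------

@dataclass
class ElementChannel:
    """One calibrated 2-D element-intensity map (e.g. the Fe channel of a
    STEM-EDXS map of a FIB section)."""

    element: str
    intensities: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D grid")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")


@dataclass
class ElementMapStack:
    """A set of co-registered element channels of one FIB section, plus
    free-form acquisition metadata (section thickness, instrument tag...)."""

    channels: dict[str, ElementChannel]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shapes = {ch.intensities.shape for ch in self.channels.values()}
        sizes = {ch.pixel_size_nm for ch in self.channels.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise ValueError("all channels must share shape and pixel size")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).intensities.shape

    @property
    def pixel_size_nm(self) -> float:
        return next(iter(self.channels.values())).pixel_size_nm

    def channel(self, element: str) -> ElementChannel:
        try:
            return self.channels[element]
        except KeyError:
            raise KeyError(f"stack has no {element} channel") from None


# --------------------------------------------------------------------------
# mineral reference table
# --------------------------------------------------------------------------

@dataclass
class MineralRef:
    """One reference mineral: name, stoichiometry, density and diagnostic
    lattice spacings, with the Fe weight fraction derived from the formula."""

    name: str
    formula: str
    density_g_cm3: float
    d_spacings_angstrom: list[float] = field(default_factory=list)
    fe3_max_fraction: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.fe3_max_fraction is not None and not 0 <= self.fe3_max_fraction <= 1:
            raise ValueError("fe3_max_fraction must lie in [0, 1]")
        self.composition = parse_formula(self.formula)

    @property
    def fe_weight_fraction(self) -> float:
        return self.composition.mass_fraction("Fe")


def mixture_density(
    components: Sequence[tuple[MineralRef, float]],
    override_g_cm3: float | None = None,
) -> float:
    """Volume-fraction-weighted mean density of a mineral mixture.

    ``override_g_cm3`` forces a literal working value (e.g. the 3.2 g/cm³
    the source study rounded its 80/20 greenalite/siderite mixture to).
    """
    fractions = [f for _, f in components]
    if any(f < 0 for f in fractions):
        raise ValueError("volume fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"volume fractions must sum to 1, got {sum(fractions)}")
    if override_g_cm3 is not None:
        return override_g_cm3
    return sum(m.density_g_cm3 * f for m, f in components)


DEFAULT_MINERALS = ("greenalite", "siderite", "pyrite", "ankerite", "quartz")


def load_mineral_table(path: str | Path | None = None) -> dict[str, MineralRef]:
    """Load the shipped mineral reference table (or a user YAML of the same
    layout), keyed by mineral name."""
    if path is None:
        text = (resources.files("ferrofossil") / "data" / "minerals.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    table: dict[str, MineralRef] = {}
    for entry in raw["minerals"]:
        ref = MineralRef(
            name=entry["name"],
            formula=entry["formula"],
            density_g_cm3=float(entry["density_g_cm3"]),
            d_spacings_angstrom=[float(d) for d in entry.get("d_spacings_angstrom") or []],
            fe3_max_fraction=(
                None if entry.get("fe3_max_fraction") is None
                else float(entry["fe3_max_fraction"])
            ),
            notes=str(entry.get("source_note", "")).strip(),
        )
        table[ref.name] = ref
    return table
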
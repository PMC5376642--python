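"""Mineral identification from point compositions, lattice spacings and Fe redox.

Point EDXS spectra of nanocrystals embedded in a chert lamella are mixtures
of the crystal with the surrounding quartz, so raw compositions scatter along
a mixing line between the crystal endmember and the quartz vertex in the
Fe–Si–O ternary.  The endmember is recovered by a total-least-squares line
constrained through the (known) quartz vertex; crystals that traverse the
full section thickness are quartz-free and can be averaged directly.

Identification then proceeds by stoichiometry matching against the mineral
reference table (with both all-O and hydroxyl-blind ternaries for hydrous
phases, since EDXS O quantification is convention-dependent), by diffraction
d-spacing matching within a tolerance, and by the ferric-fraction criterion
(Fe³⁺/ΣFe below a few per mil ⇒ ferrous phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .refdb import MineralRef

__all__ = [
    "CompositionMeasurement",
    "MixingFit",
    "RedoxMeasurement",
    "DspacingMatch",
    "ternary_project",
    "fit_mixing_line",
    "si_o_ratio",
    "reference_ternaries",
    "match_stoichiometry",
    "match_dspacing",
    "redox_label",
]

logger = logging.getLogger("ferrofossil.composition")

TernaryElements = tuple[str, str, str]
DEFAULT_TERNARY: TernaryElements = ("Fe", "Si", "O")


@dataclass
class CompositionMeasurement:
    """One point-composition measurement (atomic fractions summing to 1).

    ``traverses_section`` marks crystals spanning the full lamella thickness,
    measurable without matrix interference.
    """

    atomic_fractions: Mapping[str, float]
    source: str = ""
    traverses_section: bool | None = None

    def __post_init__(self) -> None:
        total = sum(self.atomic_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"atomic fractions must sum to 1 (got {total})")
        if any(not 0 <= v <= 1 for v in self.atomic_fractions.values()):
            raise ValueError("atomic fractions must lie in [0, 1]")


def ternary_project(
    m: CompositionMeasurement | Mapping[str, float],
    elements: TernaryElements = DEFAULT_TERNARY,
) -> np.ndarray:
    """Project a measurement onto a ternary subspace (renormalized 3-vector).

    Elements outside the ternary (e.g. C) are excluded and the remainder
    renormalized; idempotent for measurements already in the subspace.
    """
    fractions = m.atomic_fractions if isinstance(m, CompositionMeasurement) else m
    vec = np.array([fractions.get(el, 0.0) for el in elements], dtype=float)
    total = vec.sum()
    if total == 0:
        raise ValueError(f"none of {elements} present in the measurement")
    return vec / total


def si_o_ratio(m: CompositionMeasurement | Mapping[str, float]) -> float:
    """Si/O atomic ratio (0.5 for quartz; convention-dependent for hydrous
    silicates, whose hydroxyl O may or may not be counted)."""
    fractions = m.atomic_fractions if isinstance(m, CompositionMeasurement) else m
    o = fractions.get("O", 0.0)
    if o <= 0:
        raise ValueError("measurement has no O")
    return fractions.get("Si", 0.0) / o


@dataclass
class MixingFit:
    """A host-constrained mixing line fitted to ternary points."""

    host: np.ndarray
    direction: np.ndarray
    collinearity_rms: float
    endmember_estimate: np.ndarray
    n_points: int


def fit_mixing_line(
    points: Sequence[np.ndarray],
    host: np.ndarray,
    traverses_section: Sequence[bool] | None = None,
) -> MixingFit:
    """Fit the contamination mixing line through the host vertex.

    Total least squares: the direction is the leading right singular vector
    of the host-centred point cloud, so the line passes exactly through the
    host (the known contaminant phase is constrained, not estimated).  The
    endmember estimate is the projection onto the line of the point farthest
    from the host — unless some points are flagged as traversing the section,
    in which case their mean is the endmember and its off-line distance
    contributes to the collinearity RMS.
    """
    pts = np.asarray(points, dtype=float)
    host = np.asarray(host, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two ternary points")
    centred = pts - host
    if np.allclose(centred, 0.0):
        raise ValueError("all points coincide with the host vertex")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0]
    # orient away from the host toward the data
    if np.mean(centred @ direction) < 0:
        direction = -direction
    proj = np.outer(centred @ direction, direction)
    residuals = centred - proj
    sq = np.sum(residuals**2, axis=1)

    if traverses_section is not None and any(traverses_section):
        flag = np.asarray(traverses_section, dtype=bool)
        endmember = pts[flag].mean(axis=0)
        off = endmember - host
        extra = float(np.sum((off - (off @ direction) * direction) ** 2))
        rms = float(np.sqrt((sq.sum() + extra) / (len(pts) + 1)))
    else:
        far = int(np.argmax(np.sum(centred**2, axis=1)))
        endmember = host + (centred[far] @ direction) * direction
        rms = float(np.sqrt(sq.mean()))
    return MixingFit(
        host=host,
        direction=direction,
        collinearity_rms=rms,
        endmember_estimate=np.asarray(endmember),
        n_points=len(pts),
    )


# --------------------------------------------------------------------------
# stoichiometry matching
# --------------------------------------------------------------------------

def reference_ternaries(
    ref: MineralRef,
    elements: TernaryElements = DEFAULT_TERNARY,
) -> dict[str, np.ndarray]:
    """Reference ternary vectors for one mineral.

    Hydrous minerals get two conventions: ``all_O`` (every O counted) and
    ``hydroxyl_blind`` (one O removed per OH, as if hydroxyl oxygen were
    invisible to quantification).
    """
    counts = dict(ref.composition.element_counts)
    out = {
        "all_O": ternary_project({el: counts.get(el, 0.0) for el in elements}, elements)
    }
    n_oh = counts.get("H", 0.0)
    if n_oh > 0 and counts.get("O", 0.0) > n_oh:
        blind = {el: counts.get(el, 0.0) for el in elements}
        blind["O"] = counts["O"] - n_oh  # one O per OH treated as unquantified
        out["hydroxyl_blind"] = ternary_project(blind, elements)
    return out


@dataclass
class StoichiometryMatch:
    mineral: str
    convention: str
    distance: float
    max_abs_deviation: float


def match_stoichiometry(
    m: CompositionMeasurement | Mapping[str, float] | np.ndarray,
    refs: Sequence[MineralRef],
    tol: float = 0.08,
    elements: TernaryElements = DEFAULT_TERNARY,
) -> StoichiometryMatch | None:
    """Nearest reference mineral in ternary space, or None.

    A reference is admissible if its maximum absolute per-axis ternary
    deviation is ≤ ``tol`` (default 0.08, chosen so greenalite-like measured
    compositions match while quartz-dominated mixtures do not); admissible
    references are ranked by Euclidean distance.  Ties yield None with a
    logged warning.
    """
    if not refs:
        raise ValueError("reference list is empty")
    vec = (
        np.asarray(m, dtype=float)
        if isinstance(m, np.ndarray)
        else ternary_project(m, elements)
    )
    candidates: list[StoichiometryMatch] = []
    for ref in refs:
        for conv, ref_vec in reference_ternaries(ref, elements).items():
            dev = np.abs(vec - ref_vec)
            if dev.max() <= tol:
                candidates.append(
                    StoichiometryMatch(
                        mineral=ref.name,
                        convention=conv,
                        distance=float(np.linalg.norm(vec - ref_vec)),
                        max_abs_deviation=float(dev.max()),
                    )
                )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c.distance)
    best = candidates[0]
    rivals = [c for c in candidates[1:] if c.mineral != best.mineral]
    if rivals and np.isclose(rivals[0].distance, best.distance):
        logger.warning(
            "ambiguous stoichiometry match: %s vs %s at distance %.4f",
            best.mineral, rivals[0].mineral, best.distance,
        )
        return None
    return best


# --------------------------------------------------------------------------
# diffraction matching
# --------------------------------------------------------------------------

@dataclass
class DspacingMatch:
    mineral: str
    n_matched: int
    mean_residual_angstrom: float
    matched_planes: list[tuple[float, float]] = field(default_factory=list)


def match_dspacing(
    observed_angstrom: Sequence[float],
    refs: Sequence[MineralRef],
    tol_angstrom: float = 0.2,
) -> list[DspacingMatch]:
    """Candidate minerals whose reference spacings explain every observation.

    A reference matches if each observed spacing lies within ``tol`` of some
    reference spacing; candidates are ranked by number of matched planes,
    then mean residual.  Invariant to the order of the observations.
    """
    if not observed_angstrom:
        raise ValueError("no observed spacings")
    results: list[DspacingMatch] = []
    for ref in refs:
        if not ref.d_spacings_angstrom:
            continue
        planes: list[tuple[float, float]] = []
        ok = True
        for obs in observed_angstrom:
            residuals = [abs(obs - d) for d in ref.d_spacings_angstrom]
            best = min(residuals)
            if best > tol_angstrom:
                ok = False
                break
            planes.append((obs, ref.d_spacings_angstrom[int(np.argmin(residuals))]))
        if ok:
            results.append(
                DspacingMatch(
                    mineral=ref.name,
                    n_matched=len(planes),
                    mean_residual_angstrom=float(
                        np.mean([abs(o - d) for o, d in planes])
                    ),
                    matched_planes=sorted(planes),
                )
            )
    results.sort(key=lambda r: (-r.n_matched, r.mean_residual_angstrom))
    return results


# --------------------------------------------------------------------------
# redox
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RedoxMeasurement:
    """A derived ferric fraction Fe³⁺/ΣFe (e.g. from EELS L-edge fitting)."""

    fe3_over_fetot: float
    method: str = "EELS"

    def __post_init__(self) -> None:
        if not 0 <= self.fe3_over_fetot <= 1:
            raise ValueError("ferric fraction must lie in [0, 1]")


def redox_label(r: RedoxMeasurement, ferrous_max: float = 0.05) -> str:
    """Classify the iron redox state: ``ferrous`` if Fe³⁺/ΣFe ≤ ferrous_max
    (well above the few-per-mil fractions of essentially ferrous silicates),
    otherwise ``mixed/ferric``."""
    return "ferrous" if r.fe3_over_fetot <= ferrous_max else "mixed/ferric"
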
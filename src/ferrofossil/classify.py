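"""Rule-based morphotype classification and the end-to-end pipeline driver.

The six dominant morphotypes are separated by printed, non-overlapping
measurement ranges — wall thickness and diameter for spheroids; presence of
septa, diameter and sheath thickness for filaments.  The classifier is a
deterministic decision tree that returns ``unclassified`` (never a
nearest-neighbour snap) for records falling in the gaps between classes,
because the population argument rests on the ranges not overlapping.  Every
decision records the rules it fired.

Fe-mineralization status compares a fossil's intracellular Fe concentration
with the matrix background bound: mineralized fossils sit about two orders
of magnitude above the matrix, non-mineralized ones at or below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .morphometry import MorphometricRecord
from .refdb import ElementMapStack
from .segmentation import (
    RegionMasks,
    area_fraction,
    assign_regions,
    label_particles,
    threshold_fe,
)
from .stereology import CellGeometry, QuotaConstants, quota_chain

__all__ = [
    "MorphotypeLabel",
    "TAXON_CLASSES",
    "classify_morphotype",
    "fe_status",
    "FossilBundle",
    "PipelineConfig",
    "run_pipeline",
    "estimate_background_concentration",
]

logger = logging.getLogger("ferrofossil.classify")

TAXON_CLASSES = (
    "Huroniospora_thin",
    "Huroniospora_thick",
    "Gminuta_T1",
    "Gminuta_T2",
    "Ggrandis_T2",
    "Animikiea_T1",
    "unclassified",
)


@dataclass
class MorphotypeLabel:
    """One classification outcome with its fired-rule trace."""

    taxon_class: str
    size_subgroup: Literal["small", "large"] | None = None
    fe_status: Literal["mineralized", "non_mineralized", "undetermined"] = "undetermined"
    rule_trace: list[str] = field(default_factory=list)


def classify_morphotype(m: MorphometricRecord) -> MorphotypeLabel:
    """Assign one record to a morphotype by the printed measurement ranges.

    Spheroids: wall 40–60 nm → thin-walled Huroniospora (subgroup small if
    d ≤ 4 μm, large if 7–9 μm); wall 110–600 nm with d 7–12 μm →
    thick-walled Huroniospora.  Filaments: without septa, sheath < 150 nm and
    d 0.9–1.5 μm → G. minuta Type 1, d > 3 μm → Animikiea Type 1; with
    septa, d 1.4–2.5 μm → G. minuta Type 2, d > 4 μm → G. grandis Type 2.
    Anything between or outside these ranges is ``unclassified``; missing
    required fields never raise, they trace to ``unclassified``.
    """
    trace: list[str] = []

    if m.shape_kind == "spheroid":
        trace.append("shape=spheroid")
        w = m.wall_thickness_nm
        if w is None:
            trace.append("missing wall_thickness -> unclassified")
            return MorphotypeLabel("unclassified", rule_trace=trace)
        d = m.diameter_um
        if 40 <= w <= 60:
            trace.append(f"wall {w:.0f} nm in 40-60 -> Huroniospora_thin")
            subgroup = None
            if d <= 4:
                subgroup = "small"
                trace.append(f"diameter {d:.2f} um <= 4 -> subgroup small")
            elif 7 <= d <= 9:
                subgroup = "large"
                trace.append(f"diameter {d:.2f} um in 7-9 -> subgroup large")
            else:
                trace.append(f"diameter {d:.2f} um outside subgroup ranges")
            return MorphotypeLabel("Huroniospora_thin", size_subgroup=subgroup, rule_trace=trace)
        if 110 <= w <= 600 and 7 <= d <= 12:
            trace.append(
                f"wall {w:.0f} nm in 110-600 and diameter {d:.2f} um in 7-12 "
                "-> Huroniospora_thick"
            )
            return MorphotypeLabel("Huroniospora_thick", rule_trace=trace)
        trace.append(f"wall {w:.0f} nm / diameter {d:.2f} um outside class ranges")
        return MorphotypeLabel("unclassified", rule_trace=trace)

    if m.shape_kind == "filament":
        trace.append("shape=filament")
        d = m.diameter_um
        if not m.has_internal_septa:
            trace.append("no septa")
            sheath_ok = m.sheath_thickness_nm is None or m.sheath_thickness_nm < 150
            if 0.9 <= d <= 1.5 and sheath_ok:
                trace.append(f"diameter {d:.2f} um in 0.9-1.5, sheath<150 -> Gminuta_T1")
                return MorphotypeLabel("Gminuta_T1", rule_trace=trace)
            if d > 3 and sheath_ok:
                trace.append(f"diameter {d:.2f} um > 3, sheath<150 -> Animikiea_T1")
                return MorphotypeLabel("Animikiea_T1", rule_trace=trace)
            if not sheath_ok:
                trace.append(f"sheath {m.sheath_thickness_nm:.0f} nm >= 150")
            trace.append(f"diameter {d:.2f} um outside sheath-class ranges")
            return MorphotypeLabel("unclassified", rule_trace=trace)
        trace.append("septa present")
        if 1.4 <= d <= 2.5:
            trace.append(f"diameter {d:.2f} um in 1.4-2.5 -> Gminuta_T2")
            return MorphotypeLabel("Gminuta_T2", rule_trace=trace)
        if d > 4:
            trace.append(f"diameter {d:.2f} um > 4 -> Ggrandis_T2")
            return MorphotypeLabel("Ggrandis_T2", rule_trace=trace)
        trace.append(f"diameter {d:.2f} um outside septate-class ranges")
        return MorphotypeLabel("unclassified", rule_trace=trace)

    trace.append(f"unknown shape kind {m.shape_kind!r} -> unclassified")
    return MorphotypeLabel("unclassified", rule_trace=trace)


def fe_status(
    c_fossil: float,
    c_background_bound: float,
    min_fold: float = 100.0,
) -> str:
    """Mineralization status from the intracellular concentration.

    ``mineralized`` requires at least ``min_fold`` (default 100, encoding the
    two-order-of-magnitude enrichment) times the background bound;
    ``non_mineralized`` means at or below the bound; in between is
    ``undetermined``.
    """
    if c_fossil < 0:
        raise ValueError("concentration must be non-negative")
    if c_background_bound <= 0:
        raise ValueError("background bound must be positive")
    if c_fossil >= min_fold * c_background_bound:
        return "mineralized"
    if c_fossil <= c_background_bound:
        return "non_mineralized"
    return "undetermined"


def estimate_background_concentration(
    seeds: Sequence[int],
    constants: QuotaConstants | None = None,
    fixed_threshold: float = 100.0,
    min_pixels: int = 4,
    **scene_overrides,
) -> dict:
    """Matrix Fe-nanocrystal concentration pooled over several sections.

    Segments background-only synthetic scenes (one per seed) with a fixed Fe
    threshold, pools particle areas over the pooled matrix area — mirroring
    how the matrix of all FIB sections is analysed together, since single
    sections contain only a handful of matrix nanocrystals — and converts the
    pooled area fraction to atoms per μm³ of matrix.  A fixed threshold is
    the recorded run parameter here because automatic (Otsu) thresholding is
    unreliable at matrix-level class imbalance.
    """
    from .synthetic import SceneParams, generate_section_scene

    constants = constants or QuotaConstants.paper_compat()
    total_area_nm2 = 0.0
    total_region_px = 0
    n_particles = 0
    px_nm = None
    for seed in seeds:
        params = SceneParams(
            seed=int(seed), crystal_volume_fraction=0.0, **scene_overrides
        )
        stack, gt = generate_section_scene(params)
        masks = gt.region_masks()
        mask = threshold_fe(stack, "fixed", fixed_threshold)
        particles = assign_regions(
            label_particles(mask, stack.pixel_size_nm, min_pixels), masks
        )
        total_area_nm2 += sum(
            p.area_nm2 for p in particles if p.region == "background"
        )
        n_particles += sum(1 for p in particles if p.region == "background")
        total_region_px += int(masks.background.sum())
        px_nm = stack.pixel_size_nm
    pooled_fraction = total_area_nm2 / (total_region_px * px_nm * px_nm)
    return {
        "concentration_atoms_per_um3": pooled_fraction
        * constants.atoms_per_um3_of_crystal,
        "pooled_area_fraction": pooled_fraction,
        "n_sections": len(seeds),
        "n_particles": n_particles,
        "pooled_background_area_um2": total_region_px * (px_nm / 1000.0) ** 2,
    }


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

@dataclass
class FossilBundle:
    """Everything known about one fossil prior to analysis: its element-map
    stack, region masks, cell geometry and morphometric record."""

    fossil_id: str
    stack: ElementMapStack
    masks: RegionMasks
    geometry: CellGeometry
    morphometrics: MorphometricRecord


@dataclass
class PipelineConfig:
    """Run parameters echoed into every report row."""

    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    min_pixels: int = 4
    connectivity: Literal[4, 8] = 8
    paper_compat: bool = False
    background_bound_atoms_per_um3: float = 1.5e6
    min_fold: float = 100.0

    def constants(self) -> QuotaConstants:
        return (
            QuotaConstants.paper_compat()
            if self.paper_compat
            else QuotaConstants.standard()
        )


def run_pipeline(
    bundles: Sequence[FossilBundle],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run segmentation → stereology → morphometry summary → classification
    for each fossil bundle; one report row per fossil.

    Per-fossil failures are isolated: a failing bundle yields a row with its
    error message, never an exception.  Deterministic for fixed inputs and
    config; no wall-clock content enters the report.
    """
    config = config or PipelineConfig()
    constants = config.constants()
    rows = []
    for b in bundles:
        row: dict = {"fossil_id": b.fossil_id, "error": ""}
        try:
            mask = threshold_fe(b.stack, config.threshold_method, config.fixed_threshold)
            particles = label_particles(
                mask, b.stack.pixel_size_nm, config.min_pixels, config.connectivity,
                stack=b.stack,
            )
            particles = assign_regions(particles, b.masks)
            counts = {r: sum(1 for p in particles if p.region == r)
                      for r in ("interior", "wall", "background")}
            f_int = area_fraction(
                particles, b.masks.interior, b.stack.pixel_size_nm, region="interior"
            )
            result = quota_chain(min(f_int, 1.0), b.geometry, constants)
            label = classify_morphotype(b.morphometrics)
            label.fe_status = fe_status(
                result.concentration_atoms_per_um3,
                config.background_bound_atoms_per_um3,
                config.min_fold,
            )
            row.update(
                {
                    "taxon_class": label.taxon_class,
                    "size_subgroup": label.size_subgroup,
                    "fe_status": label.fe_status,
                    "n_particles_interior": counts["interior"],
                    "n_particles_wall": counts["wall"],
                    "n_particles_background": counts["background"],
                    "area_fraction_interior": result.area_fraction,
                    "cell_volume_um3": result.cell_volume_um3,
                    "crystal_volume_um3": result.crystal_volume_um3,
                    "quota_atoms": result.quota_atoms,
                    "concentration_atoms_per_um3": result.concentration_atoms_per_um3,
                    "volume_convention": result.volume_convention,
                    "constants_tag": result.constants_tag,
                    "wall_thickness_nm": b.morphometrics.wall_thickness_nm,
                    "diameter_um": b.morphometrics.diameter_um,
                    "mean_segment_length_um": b.morphometrics.mean_segment_length_um,
                    "rule_trace": "; ".join(label.rule_trace),
                    "threshold_method": config.threshold_method,
                    "min_pixels": config.min_pixels,
                }
            )
        except Exception as exc:  # per-fossil isolation contract
            logger.warning("fossil %s failed: %s", b.fossil_id, exc)
            row["error"] = str(exc)
        rows.append(row)
    columns = [
        "fossil_id", "taxon_class", "size_subgroup", "fe_status",
        "n_particles_interior", "n_particles_wall", "n_particles_background",
        "area_fraction_interior", "cell_volume_um3", "crystal_volume_um3",
        "quota_atoms", "concentration_atoms_per_um3", "volume_convention",
        "constants_tag", "wall_thickness_nm", "diameter_um",
        "mean_segment_length_um", "rule_trace", "threshold_method",
        "min_pixels", "error",
    ]
    return pd.DataFrame(rows, columns=columns)
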
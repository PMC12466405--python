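"""Exclusion rules that clean the nuclei mask before NAE quantification.

The co-culture mask contains, besides PMN nuclei, sperm heads, cell debris
and NET regions.  The assay removes them with simple deterministic rules:

* a count-based drop of the smallest objects (``size_drop_fraction``),
* a count-based drop of the dimmest objects (``fi_drop_fraction``),
* an absolute area floor (``min_area_um2``),
* exclusion of objects touching the ROI border.

Species presets differ in which rules carry the weight.  Bovine sperm heads
are comparable in size to PMN nuclei but dimmer, so the percentile drops do
the work (size first removes small debris, FI second removes dim heads and
NET remnants).  Canine sperm heads are bright but small, so a hard 14 µm²
floor removes them.  The drops mirror the 10 % smallest-size / 10 % lowest-FI
compensation of the original workflow, applied per ROI; removal counts use
floor semantics (``⌊fraction·N⌋``) with ties broken by ascending label, so a
given input always yields the same survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .nuclei_segmentation import NucleusRecord


@dataclass
class FilterConfig:
    """Exclusion-rule parameters; ``None`` disables a rule."""

    size_drop_fraction: float = 0.0
    fi_drop_fraction: float = 0.0
    min_area_um2: float | None = None
    exclude_border: bool = True

    def __post_init__(self) -> None:
        for name in ("size_drop_fraction", "fi_drop_fraction"):
            f = getattr(self, name)
            if not 0 <= f < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {f}")
        if self.min_area_um2 is not None and self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")


def bovine_filter_config() -> FilterConfig:
    """Percentile-drop profile: 10 % smallest, then 10 % dimmest."""
    return FilterConfig(size_drop_fraction=0.10, fi_drop_fraction=0.10,
                        min_area_um2=None, exclude_border=True)


def canine_filter_config() -> FilterConfig:
    """Hard-floor profile: areas below 14 µm² are filtered."""
    return FilterConfig(size_drop_fraction=0.0, fi_drop_fraction=0.0,
                        min_area_um2=14.0, exclude_border=True)


def _drop_fraction(records: list[NucleusRecord], fraction: float, key) -> list[NucleusRecord]:
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    n_drop = int(fraction * len(records))
    if n_drop == 0:
        return list(records)
    ranked = sorted(records, key=lambda r: (key(r), r.label))
    doomed = {id(r) for r in ranked[:n_drop]}
    return [r for r in records if id(r) not in doomed]


def drop_smallest_fraction(records: list[NucleusRecord], fraction: float) -> list[NucleusRecord]:
    """Remove the ⌊fraction·N⌋ records with smallest physical area."""
    return _drop_fraction(records, fraction, key=lambda r: r.area_um2)


def drop_dimmest_fraction(records: list[NucleusRecord], fraction: float) -> list[NucleusRecord]:
    """Remove the ⌊fraction·N⌋ records with lowest mean fluorescence."""
    return _drop_fraction(records, fraction, key=lambda r: r.mean_fi)


def drop_below_area(records: list[NucleusRecord], min_area_um2: float) -> list[NucleusRecord]:
    """Keep records with area >= the floor; strictly-below are removed."""
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    return [r for r in records if r.area_um2 >= min_area_um2]


def keep_inside_roi(records: list[NucleusRecord]) -> list[NucleusRecord]:
    """Discard objects touching the ROI border (partially captured cells)."""
    return [r for r in records if not r.touches_roi_border]


@dataclass
class FilterAudit:
    """Per-stage survivor counts plus a per-record removal log."""

    n_input: int = 0
    after_size: int = 0
    after_fi: int = 0
    after_floor: int = 0
    after_border: int = 0
    removals: list[tuple[int, str]] = field(default_factory=list)  # (label, stage)

    def to_csv(self, records_kept: list[NucleusRecord], path) -> None:
        rows = [{"label": lab, "stage_removed_at": stage} for lab, stage in self.removals]
        rows += [{"label": r.label, "stage_removed_at": "kept"} for r in records_kept]
        pd.DataFrame(rows, columns=["label", "stage_removed_at"]).sort_values(
            "label"
        ).to_csv(path, index=False)


def apply_filters(
    records: list[NucleusRecord], config: FilterConfig
) -> tuple[list[NucleusRecord], FilterAudit]:
    """Run the full exclusion chain in the fixed order: size drop, FI drop,
    area floor, border exclusion.  Returns survivors plus an audit trail."""
    audit = FilterAudit(n_input=len(records))

    def log_removed(before: list[NucleusRecord], after: list[NucleusRecord], stage: str) -> None:
        kept = {id(r) for r in after}
        audit.removals.extend((r.label, stage) for r in before if id(r) not in kept)

    stage1 = drop_smallest_fraction(records, config.size_drop_fraction)
    log_removed(records, stage1, "size_drop")
    audit.after_size = len(stage1)

    stage2 = drop_dimmest_fraction(stage1, config.fi_drop_fraction)
    log_removed(stage1, stage2, "fi_drop")
    audit.after_fi = len(stage2)

    stage3 = (
        drop_below_area(stage2, config.min_area_um2)
        if config.min_area_um2 is not None
        else list(stage2)
    )
    log_removed(stage2, stage3, "area_floor")
    audit.after_floor = len(stage3)

    stage4 = keep_inside_roi(stage3) if config.exclude_border else list(stage3)
    log_removed(stage3, stage4, "border")
    audit.after_border = len(stage4)

    return stage4, audit
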
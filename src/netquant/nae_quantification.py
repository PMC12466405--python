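"""Nuclear-area-expansion (NAE) classification and per-sample aggregation.

A neutrophil committed to NETosis decondenses its chromatin and the
projected nuclear area grows well past the resting range.  A nucleus is
classified NETotic when its area is *strictly greater than* the threshold
(80 µm² by default, the reported resting bovine PMN nuclear area); a nucleus
at exactly the threshold is not NETotic.  For canine PMN no resting area has
been established, so the canine profile reports the mean nuclear area as its
headline metric; both metrics are always computed regardless of profile.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .nuclei_segmentation import NucleusRecord
from .object_filtering import FilterConfig, bovine_filter_config, canine_filter_config

logger = logging.getLogger(__name__)

#: Area above which a PMN nucleus counts as NETotic (µm²).
NETOTIC_THRESHOLD_UM2 = 80.0
#: Assay-validity floor on the number of counted nuclei.
MIN_TOTAL_NUCLEI = 20_000


@dataclass
class AnalysisConfig:
    """Species profile bundling every assay threshold."""

    species_profile: str = "custom"
    netotic_threshold_um2: float = NETOTIC_THRESHOLD_UM2
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    roi_strategy: str = "single_area"
    roi_params: dict = field(default_factory=dict)
    min_total_nuclei: int = MIN_TOTAL_NUCLEI
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    min_peak_separation_um: float = 4.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.netotic_threshold_um2 > 0:
            raise ValueError("netotic_threshold_um2 must be > 0")

    @property
    def headline_metric(self) -> str:
        return "mean_area" if self.species_profile == "canine" else "pct_netotic"


def bovine_analysis_config(**overrides) -> AnalysisConfig:
    """Bovine workflow: 5 mm² single area, percentile drops, % > 80 µm²."""
    cfg = AnalysisConfig(
        species_profile="bovine",
        filter_config=bovine_filter_config(),
        roi_strategy="single_area",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def canine_analysis_config(**overrides) -> AnalysisConfig:
    """Canine workflow: five random 4 mm² quadrants, 14 µm² floor, mean area."""
    cfg = AnalysisConfig(
        species_profile="canine",
        filter_config=canine_filter_config(),
        roi_strategy="random_quadrants",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class SampleSummary:
    """Aggregated NAE metrics for one sample (all ROIs pooled)."""

    n_nuclei: int
    pct_netotic: float | None
    mean_area_um2: float | None
    sd_area_um2: float | None
    per_roi: list[dict] = field(default_factory=list)
    low_count_warning: bool = False


def classify_netotic(record: NucleusRecord, threshold_um2: float = NETOTIC_THRESHOLD_UM2) -> NucleusRecord:
    """Return a copy with ``is_netotic = area_um2 > threshold`` (strict)."""
    return replace(record, is_netotic=record.area_um2 > threshold_um2)


def _metrics(areas: list[float], threshold_um2: float) -> tuple[int, float | None, float | None, float | None]:
    n = len(areas)
    if n == 0:
        return 0, None, None, None
    pct = 100.0 * sum(a > threshold_um2 for a in areas) / n
    mean = sum(areas) / n
    if n >= 2:
        sd = math.sqrt(sum((a - mean) ** 2 for a in areas) / (n - 1))
    else:
        sd = None
    return n, pct, mean, sd


def summarize_sample(records: list[NucleusRecord], config: AnalysisConfig) -> SampleSummary:
    """Pool post-filter records into the per-sample NAE summary.

    Counts nuclei, the percentage with area strictly above the NETotic
    threshold, and the mean and n−1 sample SD of the areas, overall and per
    ROI.  A warning is logged when fewer nuclei than ``min_total_nuclei``
    were counted (2×10⁴ is the assay's validity floor).
    """
    areas = [r.area_um2 for r in records]
    n, pct, mean, sd = _metrics(areas, config.netotic_threshold_um2)
    low = n < config.min_total_nuclei
    if low:
        logger.warning(
            "only %d nuclei counted; assay validity requires at least %d",
            n,
            config.min_total_nuclei,
        )
    per_roi: list[dict] = []
    roi_ids = sorted({r.roi_index for r in records if r.roi_index is not None})
    for ri in roi_ids:
        sub = [r.area_um2 for r in records if r.roi_index == ri]
        rn, rpct, rmean, rsd = _metrics(sub, config.netotic_threshold_um2)
        per_roi.append(
            {"roi_index": ri, "n_nuclei": rn, "pct_netotic": rpct,
             "mean_area_um2": rmean, "sd_area_um2": rsd}
        )
    return SampleSummary(
        n_nuclei=n,
        pct_netotic=pct,
        mean_area_um2=mean,
        sd_area_um2=sd,
        per_roi=per_roi,
        low_count_warning=low,
    )


def export_scattergram(records: list[NucleusRecord], path, plot_path=None,
                       threshold_um2: float = NETOTIC_THRESHOLD_UM2) -> None:
    """Write the per-nucleus area-vs-FI table behind the assay scattergram.

    One row per nucleus (area_um2, mean_fi, is_netotic).  When ``plot_path``
    is given, a scatter plot with a vertical line at the NETotic threshold is
    rendered alongside.
    """
    df = pd.DataFrame(
        [
            {
                "area_um2": r.area_um2,
                "mean_fi": r.mean_fi,
                "is_netotic": bool(r.is_netotic) if r.is_netotic is not None else "",
            }
            for r in records
        ],
        columns=["area_um2", "mean_fi", "is_netotic"],
    )
    df.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        if len(df):
            ax.scatter(df["area_um2"], df["mean_fi"], s=4, alpha=0.4, edgecolors="none")
        ax.axvline(threshold_um2, color="crimson", lw=1, ls="--",
                   label=f"NETotic > {threshold_um2:g} µm²")
        ax.set_xlabel("nuclear area (µm²)")
        ax.set_ylabel("mean FI")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)


def summary_to_json(summary: SampleSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_nuclei": summary.n_nuclei,
                "pct_netotic": summary.pct_netotic,
                "mean_area_um2": summary.mean_area_um2,
                "sd_area_um2": summary.sd_area_um2,
                "low_count_warning": summary.low_count_warning,
                "per_roi": summary.per_roi,
            },
            fh,
            indent=2,
        )
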
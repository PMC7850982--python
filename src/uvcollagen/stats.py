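"""ROI sampling and two-group comparison of collagen metrics.

Summary statistics are computed over randomly sampled rectangular
regions of interest (default: 50 ROIs of 600 x 400 um, sampled away
from necrosis), and groups (e.g. control vs. photodynamically primed
tumors) are compared per metric with Welch's two-sample t-test —
two-tailed, no equal-variance assumption, Welch–Satterthwaite degrees
of freedom — at alpha = 0.05.  Percent change is reported relative to
the control mean, so a positive value reads as a reduction under
treatment.  No multiple-testing correction is applied across metrics;
each metric is reported at its own per-test level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnalysisConfig, StructureLabelMap
from .fibers import FiberSummary, summarize_fibers

__all__ = [
    "RoiSet",
    "WelchResult",
    "MetricComparison",
    "GroupComparison",
    "sample_rois",
    "roi_metrics",
    "welch_t_test",
    "compare_groups",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "collagen_content_pct",
    "mean_thickness_um",
    "mean_length_um",
    "mean_orientation_deg",
)


@dataclass
class RoiSet:
    """Sampled ROI rectangles: ``((row0, col0), (height, width))`` in pixels."""

    rectangles: list[tuple[tuple[int, int], tuple[int, int]]]
    roi_size_um: tuple[float, float]
    rng_seed: int


class SamplingError(RuntimeError):
    """Raised when the requested ROIs cannot be placed."""


def sample_rois(
    image_shape: tuple[int, int],
    config: AnalysisConfig,
    exclusion_mask: Optional[np.ndarray] = None,
    max_overlap_frac: float = 0.0,
) -> RoiSet:
    """Uniform rejection sampling of ROI origins.

    ROIs lie fully inside the image and overlap the exclusion mask by
    at most ``max_overlap_frac`` of their area (default: not at all).
    Deterministic for a fixed ``config.rng_seed``; raises
    :class:`SamplingError` with a diagnostic when the geometry is
    infeasible or rejection exhausts its budget.
    """
    px = config.require_pixel_size()
    rh = int(round(config.roi_size_um[1] / px))  # height from the 400-um side
    rw = int(round(config.roi_size_um[0] / px))
    h, w = image_shape
    if rh > h or rw > w or rh < 1 or rw < 1:
        raise SamplingError(
            f"ROI of {rh} x {rw} px does not fit inside an image of {h} x {w} px"
        )
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != image_shape:
            raise SamplingError("exclusion mask shape must match image shape")
        # summed-area table for O(1) overlap queries
        integral = np.pad(np.cumsum(np.cumsum(exclusion_mask, 0), 1), ((1, 0), (1, 0)))
    rng = np.random.default_rng(config.rng_seed)
    rects = []
    budget = 1000 * config.n_rois
    attempts = 0
    while len(rects) < config.n_rois:
        if attempts >= budget:
            raise SamplingError(
                f"placed only {len(rects)}/{config.n_rois} ROIs after {budget} draws; "
                f"the exclusion mask likely leaves too little admissible area"
            )
        attempts += 1
        r0 = int(rng.integers(0, h - rh + 1))
        c0 = int(rng.integers(0, w - rw + 1))
        if exclusion_mask is not None:
            overlap = (
                integral[r0 + rh, c0 + rw]
                - integral[r0, c0 + rw]
                - integral[r0 + rh, c0]
                + integral[r0, c0]
            )
            if overlap > max_overlap_frac * rh * rw:
                continue
        rects.append(((r0, c0), (rh, rw)))
    return RoiSet(rects, config.roi_size_um, config.rng_seed)


def roi_metrics(
    labels: StructureLabelMap,
    fibers: pd.DataFrame,
    roi: tuple[tuple[int, int], tuple[int, int]],
) -> FiberSummary:
    """Fiber summary restricted to one ROI.

    Fibers are measured once on the full image; a strand belongs to an
    ROI when its centerline centroid falls inside, so partitioning the
    image into ROIs counts each strand exactly once.
    """
    return summarize_fibers(fibers, labels, roi=roi)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's two-sample t-test (two-tailed, unequal variances).

    ``t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)`` with
    Welch–Satterthwaite degrees of freedom; sample variances use
    ``ddof=1``.  Requires at least two observations per sample and a
    nonzero pooled variance.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / a.size, vb / b.size
    se2 = sa + sb
    if se2 == 0:
        raise ValueError("both samples have zero variance; the test statistic is undefined")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


@dataclass
class MetricComparison:
    metric: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: float
    p: float
    significant: bool
    percent_change: Optional[float]


@dataclass
class GroupComparison:
    """Per-metric Welch comparisons between two ROI groups."""

    metrics: dict[str, MetricComparison]
    alpha: float
    group_a_label: str = "control"
    group_b_label: str = "treated"

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "groups": [self.group_a_label, self.group_b_label],
            "metrics": {k: vars(v) for k, v in self.metrics.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table(self) -> str:
        lines = [
            f"{'metric':<24}{self.group_a_label + ' mean±sd':>22}{self.group_b_label + ' mean±sd':>22}"
            f"{'t':>9}{'df':>8}{'p':>10}{'Δ%':>8}"
        ]
        for name, m in self.metrics.items():
            pc = f"{m.percent_change:7.1f}" if m.percent_change is not None else "    n/a"
            star = "*" if m.significant else " "
            lines.append(
                f"{name:<24}{m.mean_a:13.2f}±{m.sd_a:<7.2f}{m.mean_b:13.2f}±{m.sd_b:<7.2f}"
                f"{m.t:9.3f}{m.df:8.1f}{m.p:10.4f}{pc}{star}"
            )
        return "\n".join(lines)


def _collect(summaries: Sequence[FiberSummary], metric: str) -> np.ndarray:
    values = [getattr(s, metric) for s in summaries if getattr(s, metric) is not None]
    return np.asarray(values, dtype=np.float64)


def compare_groups(
    control: Sequence[FiberSummary],
    treated: Sequence[FiberSummary],
    config: Optional[AnalysisConfig] = None,
    metrics: Sequence[str] = METRIC_NAMES,
) -> GroupComparison:
    """Welch-compare two groups of per-ROI summaries, metric by metric.

    ``percent_change`` is ``100 * (mean_control - mean_treated) /
    mean_control`` (undefined when the control mean is zero).  Metrics
    for which either group has fewer than two valid ROIs are skipped.
    """
    if len(control) == 0 or len(treated) == 0:
        raise ValueError("both groups must be non-empty")
    alpha = config.alpha if config is not None else 0.05
    out: dict[str, MetricComparison] = {}
    for metric in metrics:
        a = _collect(control, metric)
        b = _collect(treated, metric)
        if a.size < 2 or b.size < 2:
            raise ValueError(
                f"metric {metric}: need >= 2 valid ROIs per group, got {a.size} and {b.size}"
            )
        res = welch_t_test(a, b)
        pc = 100.0 * (a.mean() - b.mean()) / a.mean() if a.mean() != 0 else None
        out[metric] = MetricComparison(
            metric=metric,
            mean_a=float(a.mean()),
            sd_a=float(a.std(ddof=1)),
            n_a=int(a.size),
            mean_b=float(b.mean()),
            sd_b=float(b.std(ddof=1)),
            n_b=int(b.size),
            t=res.t,
            df=res.df,
            p=res.p,
            significant=bool(res.p < alpha),
            percent_change=pc,
        )
    return GroupComparison(out, alpha)
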
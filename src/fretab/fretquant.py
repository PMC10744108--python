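"""FRET acceptor-photobleaching quantification.

The acceptor-photobleaching readout works on four registered images of one
cell: donor pre/post bleach and acceptor pre/post bleach.  Inside the bleached
area the acceptor is destroyed, so the donor de-quenches; the efficiency is
estimated per region of interest (ROI) as

    FRET_eff = (D_post - D_pre) / D_post

and the acceptor bleach efficiency, used for quality control, as

    Bleach_eff = (1 - A_post / A_pre) * 100   [percent]

Only ROIs with bleach efficiency strictly above 60% are analysed.  The
per-cell value is the mean over up to six QC-passing measurement ROIs in the
bleached area, minus the same efficiency computed on an unbleached reference
region at least 3 µm away from the bleached region.  Per-condition tables may
be normalized to a positive-control condition (a donor-acceptor tandem
construct).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import statsum

__all__ = [
    "FretAcquisition",
    "RoiPanel",
    "RoiMeasurement",
    "CellResult",
    "CellInput",
    "PipelineConfig",
    "roi_mean",
    "fret_efficiency",
    "bleach_efficiency",
    "qc_filter",
    "cell_efficiency",
    "normalize_condition",
    "run_fret_pipeline",
    "MIN_UNBLEACHED_DISTANCE_UM",
    "DEFAULT_QC_THRESHOLD",
]

#: Minimum edge-to-edge distance between the unbleached reference ROI and the
#: bleached region, in micrometres.
MIN_UNBLEACHED_DISTANCE_UM = 3.0

#: Bleach-efficiency QC threshold in percent; ROIs must exceed it strictly.
DEFAULT_QC_THRESHOLD = 60.0


@dataclass(frozen=True)
class FretAcquisition:
    """The four registered intensity images of one cell.

    All images share one shape; ``pixel_size_um`` converts pixel distances to
    micrometres for the unbleached-reference distance constraint.
    """

    donor_pre: np.ndarray
    donor_post: np.ndarray
    acceptor_pre: np.ndarray
    acceptor_post: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(im).shape
            for im in (self.donor_pre, self.donor_post, self.acceptor_pre, self.acceptor_post)
        }
        if len(shapes) != 1:
            raise ValueError(f"channel images differ in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"expected 2-D images, got shape {shape}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.donor_pre).shape


def _mask_min_distance_um(mask_a: np.ndarray, mask_b: np.ndarray, pixel_size_um: float) -> float:
    """Minimum centre-to-centre distance between two pixel masks, in µm."""
    pts_a = np.argwhere(mask_a)
    pts_b = np.argwhere(mask_b)
    if pts_a.size == 0 or pts_b.size == 0:
        raise ValueError("cannot measure distance to an empty mask")
    # masks here are a few hundred pixels; the direct pairwise form is fine
    d2 = ((pts_a[:, None, :] - pts_b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min())) * pixel_size_um


@dataclass(frozen=True)
class RoiPanel:
    """Bleached region, up to six measurement ROIs and one unbleached reference.

    Invariants enforced at construction: every measurement ROI is nonempty and
    lies inside the bleached region; the unbleached reference is nonempty,
    disjoint from the bleached region and at least
    :data:`MIN_UNBLEACHED_DISTANCE_UM` away from it (edge-to-edge, using
    ``pixel_size_um``).
    """

    bleach_region: np.ndarray
    measurement_rois: dict[str, np.ndarray]
    unbleached_roi: np.ndarray
    pixel_size_um: float
    min_distance_um: float = MIN_UNBLEACHED_DISTANCE_UM

    def __post_init__(self) -> None:
        bleach = np.asarray(self.bleach_region, dtype=bool)
        if bleach.ndim != 2 or not bleach.any():
            raise ValueError("bleach_region must be a nonempty 2-D mask")
        if not self.measurement_rois:
            raise ValueError("at least one measurement ROI is required")
        if len(self.measurement_rois) > 6:
            raise ValueError("at most six measurement ROIs are supported")
        for name, roi in self.measurement_rois.items():
            roi = np.asarray(roi, dtype=bool)
            if roi.shape != bleach.shape:
                raise ValueError(f"ROI {name!r} shape differs from bleach region")
            if not roi.any():
                raise ValueError(f"measurement ROI {name!r} is empty")
            if (roi & ~bleach).any():
                raise ValueError(f"measurement ROI {name!r} extends outside the bleached region")
        unb = np.asarray(self.unbleached_roi, dtype=bool)
        if unb.shape != bleach.shape or not unb.any():
            raise ValueError("unbleached_roi must be a nonempty mask of matching shape")
        dist = _mask_min_distance_um(unb, bleach, self.pixel_size_um)
        if dist < self.min_distance_um:
            raise ValueError(
                f"unbleached ROI is {dist:.2f} µm from the bleached region; "
                f"≥{self.min_distance_um:g} µm required"
            )


@dataclass(frozen=True)
class RoiMeasurement:
    """Mean intensities and derived efficiencies for one measurement ROI."""

    roi_id: str
    d_pre: float
    d_post: float
    a_pre: float
    a_post: float
    fret_eff: float
    bleach_eff: float
    qc_pass: bool


@dataclass(frozen=True)
class CellResult:
    """Per-cell corrected FRET efficiency.

    ``corrected_eff`` is the mean efficiency over QC-passing ROIs minus the
    unbleached-reference efficiency.  Cells where no ROI passes QC are kept
    with ``reportable=False`` rather than dropped.
    """

    cell_id: str
    condition: str
    corrected_eff: float
    unbleached_eff: float
    n_rois_used: int
    reportable: bool
    rois: tuple[RoiMeasurement, ...] = field(default_factory=tuple)


def roi_mean(image: np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean of pixel values under a boolean mask."""
    image = np.asarray(image)
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    return float(image[mask].mean())


def fret_efficiency(d_pre: float, d_post: float) -> float:
    """Donor de-quenching efficiency (D_post - D_pre) / D_post.

    Negative values (donor loss) are returned as-is, not clamped: after the
    unbleached-region correction they carry information about drift and
    bleaching of the donor itself.
    """
    if not d_post > 0:
        raise ValueError(f"D_post must be positive, got {d_post}")
    return (d_post - d_pre) / d_post


def bleach_efficiency(a_pre: float, a_post: float) -> float:
    """Acceptor bleach efficiency in percent, (1 - A_post/A_pre) * 100."""
    if not a_pre > 0:
        raise ValueError(f"A_pre must be positive, got {a_pre}")
    return (1.0 - a_post / a_pre) * 100.0


def qc_filter(
    measurements: Sequence[RoiMeasurement], threshold_percent: float = DEFAULT_QC_THRESHOLD
) -> list[RoiMeasurement]:
    """Retain ROIs whose bleach efficiency strictly exceeds the threshold.

    The comparison is strict: an ROI bleached at exactly the threshold is
    excluded.
    """
    return [m for m in measurements if m.bleach_eff > threshold_percent]


def measure_rois(
    acq: FretAcquisition,
    panel: RoiPanel,
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> list[RoiMeasurement]:
    """Compute per-ROI intensities, efficiencies and QC flags."""
    out = []
    for name, mask in panel.measurement_rois.items():
        d_pre = roi_mean(acq.donor_pre, mask)
        d_post = roi_mean(acq.donor_post, mask)
        a_pre = roi_mean(acq.acceptor_pre, mask)
        a_post = roi_mean(acq.acceptor_post, mask)
        eff = fret_efficiency(d_pre, d_post)
        bleach = bleach_efficiency(a_pre, a_post)
        out.append(
            RoiMeasurement(
                roi_id=name,
                d_pre=d_pre,
                d_post=d_post,
                a_pre=a_pre,
                a_post=a_post,
                fret_eff=eff,
                bleach_eff=bleach,
                qc_pass=bleach > qc_threshold,
            )
        )
    return out


def cell_efficiency(
    acq: FretAcquisition,
    panel: RoiPanel,
    cell_id: str = "cell",
    condition: str = "",
    qc_threshold: float = DEFAULT_QC_THRESHOLD,
) -> CellResult:
    """Per-cell corrected efficiency.

    Mean FRET efficiency over QC-passing measurement ROIs, minus the same
    efficiency computed on the unbleached reference ROI.  If no ROI passes QC
    the cell is flagged unreportable (``corrected_eff`` is NaN) instead of
    being silently dropped.
    """
    rois = measure_rois(acq, panel, qc_threshold)
    passing = qc_filter(rois, qc_threshold)
    unb_eff = fret_efficiency(
        roi_mean(acq.donor_pre, panel.unbleached_roi),
        roi_mean(acq.donor_post, panel.unbleached_roi),
    )
    if not passing:
        return CellResult(
            cell_id=cell_id,
            condition=condition,
            corrected_eff=float("nan"),
            unbleached_eff=unb_eff,
            n_rois_used=0,
            reportable=False,
            rois=tuple(rois),
        )
    corrected = float(np.mean([m.fret_eff for m in passing])) - unb_eff
    return CellResult(
        cell_id=cell_id,
        condition=condition,
        corrected_eff=corrected,
        unbleached_eff=unb_eff,
        n_rois_used=len(passing),
        reportable=True,
        rois=tuple(rois),
    )


def normalize_condition(table: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Add a ``normalized_eff`` column: corrected_eff / mean(control corrected_eff).

    ``table`` is a per-cell frame with at least ``condition``,
    ``corrected_eff`` and ``reportable`` columns (as produced by
    :func:`run_fret_pipeline`).
    """
    if "condition" not in table or "corrected_eff" not in table:
        raise ValueError("table must have 'condition' and 'corrected_eff' columns")
    reportable = table["reportable"] if "reportable" in table else np.isfinite(table["corrected_eff"])
    control = table.loc[(table["condition"] == control_label) & reportable, "corrected_eff"]
    if control.empty:
        raise ValueError(f"control condition {control_label!r} absent or has no reportable cells")
    control_mean = float(control.mean())
    if not control_mean > 0:
        raise ValueError(
            f"control condition {control_label!r} has non-positive mean efficiency {control_mean:g}"
        )
    out = table.copy()
    out["normalized_eff"] = out["corrected_eff"] / control_mean
    return out


@dataclass(frozen=True)
class CellInput:
    """One cell of a batch: images, ROI panel and its condition label."""

    cell_id: str
    condition: str
    acquisition: FretAcquisition
    panel: RoiPanel


@dataclass(frozen=True)
class PipelineConfig:
    """Batch-level options for :func:`run_fret_pipeline`.

    ``pairs`` selects the condition pairs to test; when None every non-control
    condition is compared against ``control``.  ``test`` chooses the
    comparison: "signed-rank" pairs equal-sized groups by rank order (the
    published analysis style), "rank-sum" is the unpaired alternative.
    """

    qc_threshold: float = DEFAULT_QC_THRESHOLD
    control: str | None = None
    normalize: bool = False
    pairs: tuple[tuple[str, str], ...] | None = None
    test: str = "signed-rank"


def run_fret_pipeline(
    dataset: Sequence[CellInput], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[statsum.StatResult]]:
    """Quantify a batch of cells grouped by condition.

    Returns ``(cells, rois, stats)``: a per-cell table (with
    ``normalized_eff`` when normalization is configured), a per-ROI table, and
    the configured pairwise statistics.  Per-cell failures (e.g. all ROIs
    failing QC) appear as flagged rows; they never abort the batch.
    """
    config = config or PipelineConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    if config.normalize and config.control is None:
        raise ValueError("normalization requested but no control condition named")

    cell_rows, roi_rows = [], []
    for item in dataset:
        result = cell_efficiency(
            item.acquisition,
            item.panel,
            cell_id=item.cell_id,
            condition=item.condition,
            qc_threshold=config.qc_threshold,
        )
        cell_rows.append(
            {
                "cell_id": result.cell_id,
                "condition": result.condition,
                "corrected_eff": result.corrected_eff,
                "unbleached_eff": result.unbleached_eff,
                "n_rois_used": result.n_rois_used,
                "reportable": result.reportable,
            }
        )
        for m in result.rois:
            roi_rows.append(
                {
                    "cell_id": result.cell_id,
                    "condition": result.condition,
                    "roi_id": m.roi_id,
                    "d_pre": m.d_pre,
                    "d_post": m.d_post,
                    "a_pre": m.a_pre,
                    "a_post": m.a_post,
                    "fret_eff": m.fret_eff,
                    "bleach_eff": m.bleach_eff,
                    "qc_pass": m.qc_pass,
                }
            )
    cells = pd.DataFrame(cell_rows)
    rois = pd.DataFrame(roi_rows)

    if config.normalize:
        cells = normalize_condition(cells, config.control)
    value_col = "normalized_eff" if config.normalize else "corrected_eff"

    pairs = config.pairs
    if pairs is None and config.control is not None:
        others = [c for c in cells["condition"].unique() if c != config.control]
        pairs = tuple((c, config.control) for c in others)
    stats: list[statsum.StatResult] = []
    for a, b in pairs or ():
        xa = cells.loc[cells["condition"] == a].pipe(_reportable_values, value_col)
        xb = cells.loc[cells["condition"] == b].pipe(_reportable_values, value_col)
        stats.append(statsum.compare_groups(xa, xb, labels=(a, b), test=config.test))
    return cells, rois, stats


def _reportable_values(frame: pd.DataFrame, col: str) -> np.ndarray:
    return frame.loc[frame["reportable"], col].to_numpy(dtype=float)
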
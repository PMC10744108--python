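"""Synthetic microscopy and track data with known ground truth.

Emulates the raw inputs of an acceptor-photobleaching interaction study:

* four-channel acquisitions (donor/acceptor x pre/post bleach) of a
  nuclear-localized FRET pair, with Poisson shot noise, Gaussian read noise
  and a uniform background, stored as 16-bit images with an ROI sidecar;
* two-channel co-localization image pairs with a target Pearson correlation
  inside the nucleus;
* per-residue disorder and pLDDT tracks with declared disordered segments.

Photophysics of the FRET simulation (donor de-quenching only — sensitized
emission and acceptor cross-excitation are outside the estimator's model):
inside the bleached region the noiseless expectations are

    D_pre  = D0 * (1 - E)
    D_post = D0 * (1 - E * (1 - B))
    A_post = A_pre * (1 - B)

with ``E`` the true FRET efficiency and ``B`` the bleached fraction of the
acceptor; outside the bleached region pre and post expectations are equal.
The estimator applied downstream therefore recovers, in the noiseless limit,

    E * B / (1 - E * (1 - B))

which reduces to ``E`` at complete bleach (B = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import ioutils
from .fretquant import (
    MIN_UNBLEACHED_DISTANCE_UM,
    CellInput,
    FretAcquisition,
    RoiPanel,
)

__all__ = [
    "GroundTruth",
    "SceneLayout",
    "simulate_fret_acquisition",
    "simulate_coloc_pair",
    "simulate_tracks",
    "make_fret_dataset",
    "scenario_binary",
    "scenario_competition",
    "scenario_variants",
    "closed_form_estimate",
]


def closed_form_estimate(e_true: float, b_true: float) -> float:
    """Noiseless value of the acceptor-photobleaching estimator, E·B/(1−E(1−B))."""
    return e_true * b_true / (1.0 - e_true * (1.0 - b_true))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of one synthetic acquisition.

    ``d0``/``a0`` are mean photon counts per pixel in the nucleus; the
    defaults correspond to a moderately bright confocal acquisition well below
    16-bit saturation.
    """

    e_true: float = 0.25
    b_true: float = 0.9
    d0: float = 1000.0
    a0: float = 1000.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_true < 1.0:
            raise ValueError(f"E_true must be in [0, 1), got {self.e_true}")
        if not 0.0 <= self.b_true <= 1.0:
            raise ValueError(f"B_true must be in [0, 1], got {self.b_true}")
        if not (self.d0 > 0 and self.a0 > 0):
            raise ValueError("photon budgets D0 and A0 must be positive")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read noise must be nonnegative")


def _default_measurement_rois() -> tuple[dict, ...]:
    # six circles tiled over the bleached rectangle
    return tuple(
        {"type": "circle", "cx": cx, "cy": cy, "r": 5}
        for cy in (72, 88)
        for cx in (75, 100, 125)
    )


@dataclass(frozen=True)
class SceneLayout:
    """Geometry of one synthetic cell, in pixels.

    The nucleus is a circle, the bleached region an axis-aligned rectangle
    inside it; up to six circular measurement ROIs sit inside the bleached
    region and one unbleached reference ROI sits elsewhere in the nucleus, at
    least 3 µm (edge-to-edge) from the bleached region.
    """

    shape: tuple[int, int] = (200, 200)
    pixel_size_um: float = 0.1
    nucleus: dict = field(
        default_factory=lambda: {"type": "circle", "cx": 100, "cy": 100, "r": 80}
    )
    bleach_region: dict = field(
        default_factory=lambda: {"type": "rect", "x0": 62, "y0": 62, "x1": 138, "y1": 98}
    )
    measurement_rois: tuple[dict, ...] = field(default_factory=_default_measurement_rois)
    unbleached_roi: dict = field(
        default_factory=lambda: {"type": "circle", "cx": 100, "cy": 160, "r": 5}
    )

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not (1 <= len(self.measurement_rois) <= 6):
            raise ValueError("between one and six measurement ROIs are supported")
        masks = self.masks()
        if (masks["bleach"] & ~masks["nucleus"]).any():
            raise ValueError("bleach region extends outside the nucleus")
        for i, roi in enumerate(masks["measurement"]):
            if not roi.any():
                raise ValueError(f"measurement ROI {i} rasterizes to an empty mask")
            if (roi & ~masks["bleach"]).any():
                raise ValueError(f"measurement ROI {i} extends outside the bleach region")
        if (masks["unbleached"] & ~masks["nucleus"]).any():
            raise ValueError("unbleached ROI extends outside the nucleus")
        # the distance constraint itself is re-validated by RoiPanel
        self.panel()

    def masks(self) -> dict:
        return {
            "nucleus": ioutils.rasterize(self.nucleus, self.shape),
            "bleach": ioutils.rasterize(self.bleach_region, self.shape),
            "measurement": [
                ioutils.rasterize(s, self.shape) for s in self.measurement_rois
            ],
            "unbleached": ioutils.rasterize(self.unbleached_roi, self.shape),
        }

    def panel(self) -> RoiPanel:
        masks = self.masks()
        return RoiPanel(
            bleach_region=masks["bleach"],
            measurement_rois={
                f"roi_{i + 1}": m for i, m in enumerate(masks["measurement"])
            },
            unbleached_roi=masks["unbleached"],
            pixel_size_um=self.pixel_size_um,
            min_distance_um=MIN_UNBLEACHED_DISTANCE_UM,
        )

    def sidecar(self, gt: GroundTruth | None = None) -> dict:
        rois = {"bleach_region": self.bleach_region, "unbleached": self.unbleached_roi}
        for i, s in enumerate(self.measurement_rois):
            rois[f"roi_{i + 1}"] = dict(s)
        out = {"pixel_size_um": self.pixel_size_um, "rois": rois}
        if gt is not None:
            out["ground_truth"] = {
                "e_true": gt.e_true,
                "b_true": gt.b_true,
                "d0": gt.d0,
                "a0": gt.a0,
                "background": gt.background,
                "read_noise_sd": gt.read_noise_sd,
                "seed": gt.seed,
            }
        return out


def _expectations(gt: GroundTruth, layout: SceneLayout) -> dict[str, np.ndarray]:
    masks = layout.masks()
    nucleus = masks["nucleus"]
    bleach = masks["bleach"]
    e, b = gt.e_true, gt.b_true

    donor_pre = np.where(nucleus, gt.d0 * (1.0 - e), 0.0)
    donor_post = donor_pre.copy()
    donor_post[bleach] = gt.d0 * (1.0 - e * (1.0 - b))
    acceptor_pre = np.where(nucleus, gt.a0, 0.0)
    acceptor_post = acceptor_pre.copy()
    acceptor_post[bleach] = gt.a0 * (1.0 - b)
    return {
        "donor_pre": donor_pre,
        "donor_post": donor_post,
        "acceptor_pre": acceptor_pre,
        "acceptor_post": acceptor_post,
    }


def simulate_fret_acquisition(
    gt: GroundTruth, layout: SceneLayout | None = None, noiseless: bool = False
) -> tuple[FretAcquisition, RoiPanel, GroundTruth]:
    """Render one four-channel acquisition and its ROI panel.

    Noise model: Poisson shot noise on the expected signal counts, plus the
    uniform background, plus Gaussian read noise; images are clipped to the
    16-bit range.  With ``noiseless=True`` the float expectations (plus the
    constant background) are returned unclipped, which is the regime in which
    the downstream estimator is exact.  One top-level seed drives independent
    per-channel substreams; identical inputs give bit-identical images.
    """
    layout = layout or SceneLayout()
    expectations = _expectations(gt, layout)
    panel = layout.panel()

    if noiseless:
        images = {k: v + gt.background for k, v in expectations.items()}
    else:
        streams = np.random.SeedSequence(gt.seed).spawn(len(ioutils.CHANNEL_NAMES))
        images = {}
        for name, ss in zip(ioutils.CHANNEL_NAMES, streams):
            rng = np.random.default_rng(ss)
            counts = rng.poisson(expectations[name]).astype(float)
            counts += gt.background
            counts += rng.normal(0.0, gt.read_noise_sd, size=counts.shape)
            images[name] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

    acq = FretAcquisition(
        donor_pre=images["donor_pre"],
        donor_post=images["donor_post"],
        acceptor_pre=images["acceptor_pre"],
        acceptor_post=images["acceptor_post"],
        pixel_size_um=layout.pixel_size_um,
    )
    return acq, panel, gt


def write_fret_acquisition(outdir, basename: str, gt: GroundTruth, layout: SceneLayout | None = None):
    """Simulate and write one acquisition in the shared TIFF+JSON dialect."""
    layout = layout or SceneLayout()
    acq, _, _ = simulate_fret_acquisition(gt, layout)
    images = {
        "donor_pre": acq.donor_pre,
        "donor_post": acq.donor_post,
        "acceptor_pre": acq.acceptor_pre,
        "acceptor_post": acq.acceptor_post,
    }
    return ioutils.write_acquisition(outdir, basename, images, layout.sidecar(gt))


def simulate_coloc_pair(
    rho_target: float,
    layout: SceneLayout | None = None,
    seed: int = 0,
    mean: float = 1000.0,
    sd: float = 150.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel image pair whose nuclear Pearson correlation targets ``rho_target``.

    Inside the nucleus the two channels are built from a shared and an
    independent Gaussian field so their population correlation equals
    ``rho_target`` exactly; the sample correlation converges to it as the
    pixel count grows.  ``rho_target = ±1`` yields an exact affine copy.
    Returns ``(channel_a, channel_b, nucleus_mask)`` as float images (zero
    outside the nucleus).
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError(f"rho_target must be in [-1, 1], got {rho_target}")
    layout = layout or SceneLayout()
    nucleus = ioutils.rasterize(layout.nucleus, layout.shape)
    n = int(nucleus.sum())
    rng = np.random.default_rng(seed)
    za, zb = rng.standard_normal((2, n))
    if rho_target >= 0:
        xb = rho_target * za + math.sqrt(1.0 - rho_target**2) * zb
    else:
        xb = rho_target * za - math.sqrt(1.0 - rho_target**2) * zb
    a = np.zeros(layout.shape)
    b = np.zeros(layout.shape)
    a[nucleus] = mean + sd * za
    b[nucleus] = mean + sd * xb
    return a, b, nucleus


def simulate_tracks(
    length: int, idr_segments: Sequence[tuple[int, int]], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disorder and pLDDT tracks with declared disordered segments.

    Residues inside a declared segment (1-based inclusive) satisfy the IDR
    consensus rule — disorder score above 0.5 or pLDDT below 50 — through one
    or both criteria, chosen at random per residue; residues outside satisfy
    neither.  Segments must lie within ``[1, length]`` and be pairwise
    disjoint.
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    segs = sorted((int(s), int(e)) for s, e in idr_segments)
    inside = np.zeros(length, dtype=bool)
    for s, e in segs:
        if not (1 <= s <= e <= length):
            raise ValueError(f"segment {s}-{e} outside [1, {length}]")
        if inside[s - 1 : e].any():
            raise ValueError(f"segment {s}-{e} overlaps another segment")
        inside[s - 1 : e] = True

    rng = np.random.default_rng(seed)
    disorder = rng.uniform(0.05, 0.45, size=length)
    plddt = rng.uniform(60.0, 95.0, size=length)
    idx = np.flatnonzero(inside)
    # per flagged residue: 0 = disorder criterion, 1 = pLDDT criterion, 2 = both
    mode = rng.integers(0, 3, size=idx.size)
    dis_hit = idx[(mode == 0) | (mode == 2)]
    pl_hit = idx[(mode == 1) | (mode == 2)]
    disorder[dis_hit] = rng.uniform(0.55, 0.95, size=dis_hit.size)
    plddt[pl_hit] = rng.uniform(15.0, 45.0, size=pl_hit.size)
    return disorder, plddt


def make_fret_dataset(
    conditions: dict[str, GroundTruth],
    n_cells: int = 3,
    layout: SceneLayout | None = None,
    seed: int = 0,
    noiseless: bool = False,
) -> list[CellInput]:
    """Simulate ``n_cells`` acquisitions per condition for the batch pipeline.

    Each cell gets a distinct seed derived from ``seed`` and the condition's
    own seed, so repeated calls with the same arguments are bit-identical.
    """
    layout = layout or SceneLayout()
    dataset: list[CellInput] = []
    for ci, (label, gt) in enumerate(conditions.items()):
        for cell in range(n_cells):
            cell_seed = int(
                np.random.SeedSequence([seed, gt.seed, ci, cell]).generate_state(1)[0]
                % (2**31)
            )
            acq, panel, _ = simulate_fret_acquisition(
                replace(gt, seed=cell_seed), layout, noiseless=noiseless
            )
            dataset.append(
                CellInput(
                    cell_id=f"{label}_cell{cell + 1}",
                    condition=label,
                    acquisition=acq,
                    panel=panel,
                )
            )
    return dataset


def scenario_binary(
    e_pair: float = 0.25,
    e_positive: float = 0.35,
    b_true: float = 0.9,
    n_cells: int = 3,
    seed: int = 0,
    **gt_kwargs,
) -> list[CellInput]:
    """Binary-interaction design: FRET pair vs negative and positive controls."""
    base = GroundTruth(e_true=0.0, b_true=b_true, **gt_kwargs)
    conditions = {
        "pair": replace(base, e_true=e_pair),
        "negative-control": base,
        "positive-control": replace(base, e_true=e_positive),
    }
    return make_fret_dataset(conditions, n_cells=n_cells, seed=seed)


def scenario_competition(
    e_base: float = 0.25,
    reduction: float = 0.16,
    b_true: float = 0.9,
    n_cells: int = 12,
    seed: int = 0,
    **gt_kwargs,
) -> list[CellInput]:
    """Third-partner competition: the same FRET pair with and without a
    competitor that lowers the true efficiency by ``reduction`` (relative)."""
    base = GroundTruth(e_true=e_base, b_true=b_true, **gt_kwargs)
    conditions = {
        "pair": base,
        "pair+competitor": replace(base, e_true=e_base * (1.0 - reduction)),
    }
    return make_fret_dataset(conditions, n_cells=n_cells, seed=seed)


def scenario_variants(
    e_wildtype: float = 0.25,
    e_variant: float = 0.0,
    e_positive: float = 0.35,
    b_true: float = 0.9,
    n_cells: int = 3,
    seed: int = 0,
    **gt_kwargs,
) -> list[CellInput]:
    """Pathogenic-variant design: wildtype pair, binding-dead variant pair,
    and the tandem positive control used for normalization."""
    base = GroundTruth(e_true=0.0, b_true=b_true, **gt_kwargs)
    conditions = {
        "wildtype-pair": replace(base, e_true=e_wildtype),
        "variant-pair": replace(base, e_true=e_variant),
        "positive-control": replace(base, e_true=e_positive),
    }
    return make_fret_dataset(conditions, n_cells=n_cells, seed=seed)
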
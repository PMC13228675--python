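"""Segmentation performance battery: overlap, boundary-distance and
percent-difference metrics, in 2D (per slice) and 3D (per reconstruction).

Overlap metrics come from confusion-matrix counts (true/false positive and
negative pixels or voxels against the manual gold standard); 3D overlap
pools the per-slice counts, which is algebraically identical to averaging
them. Boundary metrics (mean surface distance, Hausdorff distance, and
their signed variants) are computed in physical millimetres between
boundary point sets. Percent differences use the manual measurement as the
reference denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .surface import extract_contours

__all__ = [
    "ConfusionCounts",
    "OverlapMetrics",
    "MetricsRecord",
    "confusion",
    "derive_metrics",
    "aggregate_3d",
    "surface_distances",
    "signed_surface_distances",
    "signed_distances_2d",
    "signed_distances_3d",
    "percent_difference",
    "evaluate_pair_2d",
    "evaluate_pair_3d",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel/voxel counts against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class OverlapMetrics:
    """Precision/recall/accuracy/DSC in percent; ``degenerate`` marks 0/0
    conventions (both masks empty, or an empty prediction)."""

    precision: float
    recall: float
    accuracy: float
    dsc: float
    degenerate: bool = False


@dataclass
class MetricsRecord:
    """One full row of the performance battery.

    Percentages in [0, 100] (signed_avpd may be negative); distances in mm.
    Distance fields are NaN when a boundary does not exist (empty mask).
    """

    precision: float
    recall: float
    accuracy: float
    dsc: float
    msd: float
    hd: float
    signed_msd: float
    signed_hd: float
    avpd: float
    signed_avpd: float
    degenerate: bool = False

    def to_row(self) -> dict:
        """Column names mirroring the standard report layout."""
        return {col: getattr(self, f) for f, col in COLUMN_BY_FIELD.items()}


#: report column name for each MetricsRecord field
COLUMN_BY_FIELD = {
    "precision": "Precision (%)",
    "recall": "Recall (%)",
    "accuracy": "Accuracy (%)",
    "dsc": "DSC (%)",
    "msd": "MSD (mm)",
    "hd": "HD (mm)",
    "signed_msd": "sMSD (mm)",
    "signed_hd": "sHD (mm)",
    "avpd": "A/VPD (%)",
    "signed_avpd": "sA/VPD (%)",
}


# ---------------------------------------------------------------------------
# overlap

def confusion(pred: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Confusion-matrix counts of a binary prediction against the gold
    standard; works for 2D and 3D grids alike."""
    p = np.asarray(pred) > 0.5
    g = np.asarray(gt) > 0.5
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def derive_metrics(c: ConfusionCounts) -> OverlapMetrics:
    """precision = tp/(tp+fp), recall = tp/(tp+fn),
    accuracy = (tp+tn)/total, dsc = 2tp/(2tp+fp+fn), each in percent.

    0/0 conventions: with both masks empty (tp=fp=fn=0) all four metrics are
    100%; an empty prediction against a nonempty gold standard yields
    precision 0%. Either case sets the ``degenerate`` flag.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    degenerate = False
    if tp + fp + fn == 0:  # both empty
        acc = 100.0 * (tp + tn) / c.total if c.total else 100.0
        return OverlapMetrics(100.0, 100.0, acc, 100.0, degenerate=True)
    if tp + fp == 0:  # empty prediction
        precision = 0.0
        degenerate = True
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:  # empty gold standard
        recall = 0.0
        degenerate = True
    else:
        recall = 100.0 * tp / (tp + fn)
    accuracy = 100.0 * (tp + tn) / c.total
    dsc = 100.0 * 2.0 * tp / (2.0 * tp + fp + fn)
    return OverlapMetrics(precision, recall, accuracy, dsc, degenerate)


def aggregate_3d(per_slice: list) -> OverlapMetrics:
    """3D overlap metrics from per-slice confusion counts.

    Counts are pooled over slices (averaging and summing give identical
    ratios) and the metrics derived from the pooled counts.
    """
    if not per_slice:
        raise ValueError("need at least one slice")
    pooled = ConfusionCounts(
        tp=sum(c.tp for c in per_slice),
        fp=sum(c.fp for c in per_slice),
        fn=sum(c.fn for c in per_slice),
        tn=sum(c.tn for c in per_slice),
    )
    return derive_metrics(pooled)


# ---------------------------------------------------------------------------
# boundary distances

_BRUTE_FORCE_LIMIT = 1000


def _directed_nn(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance from each point of a to the set b."""
    if len(a) * len(b) <= _BRUTE_FORCE_LIMIT**2:
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        return d.min(axis=1)
    return cKDTree(b).query(a)[0]


def surface_distances(
    pred_pts: np.ndarray, gt_pts: np.ndarray
) -> tuple[float, float]:
    """Symmetric (MSD, HD) between two boundary point sets, in mm.

    MSD is the mean of the two directed mean nearest-neighbour distances;
    HD is the maximum of the two directed maxima.
    """
    a = np.atleast_2d(np.asarray(pred_pts, dtype=np.float64))
    b = np.atleast_2d(np.asarray(gt_pts, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be nonempty")
    d_ab = _directed_nn(a, b)
    d_ba = _directed_nn(b, a)
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hd = max(float(d_ab.max()), float(d_ba.max()))
    return msd, hd


def _signed_from_parts(
    magnitudes: np.ndarray, inside: np.ndarray, outside_positive: bool
) -> tuple[float, float]:
    sign = np.where(inside, -1.0, 1.0)
    if not outside_positive:
        sign = -sign
    signed = sign * magnitudes
    smsd = float(signed.mean())
    shd = float(signed[np.argmax(np.abs(signed))])
    return smsd, shd


def signed_surface_distances(
    pred_pts: np.ndarray,
    gt_pts: np.ndarray,
    inside_gt: np.ndarray,
    outside_positive: bool = True,
) -> tuple[float, float]:
    """Signed (sMSD, sHD) of prediction boundary points against a closed
    gold-standard boundary.

    ``inside_gt`` is a boolean per prediction point: whether it lies inside
    the gold-standard interior. By the default convention points outside the
    reference are positive (over-segmentation > 0); ``outside_positive=False``
    flips it. sHD is the signed distance of maximal magnitude.
    """
    a = np.atleast_2d(np.asarray(pred_pts, dtype=np.float64))
    b = np.atleast_2d(np.asarray(gt_pts, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be nonempty")
    inside = np.asarray(inside_gt, dtype=bool)
    if inside.shape[0] != a.shape[0]:
        raise ValueError("need one inside/outside flag per prediction point")
    return _signed_from_parts(_directed_nn(a, b), inside, outside_positive)


def signed_distances_2d(
    pred_pts: np.ndarray,
    gt_mask: np.ndarray,
    spacing: tuple[float, float],
    outside_positive: bool = True,
) -> tuple[float, float]:
    """Signed distances of 2D boundary points (mm) against a gold-standard
    mask; interior membership by bilinear sampling of the mask."""
    dy, dx = spacing
    gt_contours = extract_contours(gt_mask, 0.0, spacing)
    if not gt_contours:
        raise ValueError("gold-standard mask has no boundary")
    gt_pts = np.vstack([c.points for c in gt_contours])
    pts = np.atleast_2d(np.asarray(pred_pts, dtype=np.float64))
    coords = np.vstack([pts[:, 1] / dy, pts[:, 0] / dx])  # (row, col)
    inside = ndimage.map_coordinates(
        (np.asarray(gt_mask) > 0.5).astype(np.float64), coords, order=1
    ) >= 0.5
    return _signed_from_parts(_directed_nn(pts, gt_pts), inside, outside_positive)


def signed_distances_3d(
    pred_pts: np.ndarray,
    gt_pts: np.ndarray,
    gt_label,
    outside_positive: bool = True,
) -> tuple[float, float]:
    """Signed 3D distances (mm); interior membership by trilinear sampling
    of the gold-standard label volume. Points are (x, y, z) mm."""
    pts = np.atleast_2d(np.asarray(pred_pts, dtype=np.float64))
    dz, dy, dx = gt_label.spacing
    oz, oy, ox = gt_label.origin
    coords = np.vstack([
        (pts[:, 2] - oz) / dz,
        (pts[:, 1] - oy) / dy,
        (pts[:, 0] - ox) / dx,
    ])
    inside = ndimage.map_coordinates(
        gt_label.voxels.astype(np.float64), coords, order=1
    ) >= 0.5
    return _signed_from_parts(_directed_nn(pts, gt_pts), inside, outside_positive)


# ---------------------------------------------------------------------------
# percent difference

def percent_difference(measured: float, reference: float) -> tuple[float, float]:
    """(absolute %, signed %) of a measured area/volume against the manual
    reference: signed = (measured - reference) / reference * 100."""
    if reference <= 0:
        raise ValueError("reference measurement must be > 0")
    signed = (measured - reference) / reference * 100.0
    return abs(signed), signed


# ---------------------------------------------------------------------------
# composite evaluations

def _boundary_points_2d(mask: np.ndarray, spacing) -> np.ndarray | None:
    cs = extract_contours(mask, 0.0, spacing)
    if not cs:
        return None
    return np.vstack([c.points for c in cs])


def evaluate_pair_2d(
    pred: np.ndarray,
    gt: np.ndarray,
    spacing: tuple[float, float],
    outside_positive: bool = True,
) -> MetricsRecord:
    """Full 2D record for one predicted slice against the manual slice.

    Overlap metrics from pixel counts; distance metrics between the
    extracted sub-pixel boundaries in mm; area percent difference from
    foreground pixel areas. An empty gold standard yields a degenerate
    record with NaN distance and percent-difference fields.
    """
    ov = derive_metrics(confusion(pred, gt))
    dy, dx = spacing
    pix = dy * dx
    area_pred = float(np.count_nonzero(np.asarray(pred) > 0.5)) * pix
    area_gt = float(np.count_nonzero(np.asarray(gt) > 0.5)) * pix
    msd = hd = smsd = shd = avpd = savpd = math.nan
    pred_pts = _boundary_points_2d(pred, spacing)
    gt_pts = _boundary_points_2d(gt, spacing)
    degenerate = ov.degenerate or gt_pts is None or pred_pts is None
    if pred_pts is not None and gt_pts is not None:
        msd, hd = surface_distances(pred_pts, gt_pts)
        smsd, shd = signed_distances_2d(pred_pts, gt, spacing, outside_positive)
    if area_gt > 0:
        avpd, savpd = percent_difference(area_pred, area_gt)
    return MetricsRecord(
        precision=ov.precision, recall=ov.recall, accuracy=ov.accuracy,
        dsc=ov.dsc, msd=msd, hd=hd, signed_msd=smsd, signed_hd=shd,
        avpd=avpd, signed_avpd=savpd, degenerate=degenerate,
    )


def evaluate_pair_3d(
    pred_masks: list,
    gt_masks: list,
    spacing: tuple[float, float],
    pred_surface,
    gt_surface,
    pred_volume: float,
    gt_volume: float,
    gt_label=None,
    outside_positive: bool = True,
) -> MetricsRecord:
    """Full 3D record for one reconstruction against the manual one.

    Overlap fields pool the per-slice confusion counts; distances use the
    stitched mesh vertex sets; the volume percent difference compares the
    enclosed volumes. Signed distances need ``gt_label`` (a
    :class:`~stvseg.volume.LabelVolume`) for the interior test and are NaN
    without it.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError("slice counts differ")
    ov = aggregate_3d([confusion(p, g) for p, g in zip(pred_masks, gt_masks)])
    pred_pts = pred_surface.vertices
    gt_pts = gt_surface.vertices
    msd, hd = surface_distances(pred_pts, gt_pts)
    smsd = shd = math.nan
    if gt_label is not None:
        smsd, shd = signed_distances_3d(pred_pts, gt_pts, gt_label,
                                        outside_positive)
    avpd, savpd = percent_difference(pred_volume, gt_volume)
    return MetricsRecord(
        precision=ov.precision, recall=ov.recall, accuracy=ov.accuracy,
        dsc=ov.dsc, msd=msd, hd=hd, signed_msd=smsd, signed_hd=shd,
        avpd=avpd, signed_avpd=savpd, degenerate=ov.degenerate,
    )
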
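"""Cell localisation for automated spectral acquisition.

Two segmentation routes over bright-field micrographs:

* classical edge-based pipelines (Sobel gradient or Canny hysteresis
  edges, then thresholding, morphological closing, hole filling and
  small-object removal);
* a small dilated-convolution network (DCN) trained per-pixel with
  impurity down-weighting: pixels labelled as impurity in the truth mask
  are trained as *background* with a reduced loss weight, so the network
  learns to reject debris rather than report it as cells.

``locate_cells`` turns a binary mask into centroids, optionally splitting
touching cells with a distance-transform watershed.  ``seg_metrics``
computes the standard pixel-level evaluation suite: accuracy (ACC),
intersection-over-union (IoU), false positive rate (FPR), false negative
rate (FNR) and overall error rate (OER = 1 - ACC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation as sk_seg

from . import nn
from .errors import RamavitError

__all__ = [
    "SegSample",
    "SegMetrics",
    "DcnConfig",
    "DcnModel",
    "edge_segment",
    "train_dcn",
    "dcn_segment",
    "locate_cells",
    "seg_metrics",
]


@dataclass
class SegSample:
    """A grayscale image in [0, 1] with an optional truth label array
    (0 background, 1 cell, 2 impurity)."""

    image: np.ndarray
    truth_mask: np.ndarray | None = None
    n_cells: int | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise RamavitError("image must be 2-D grayscale")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask)
            if self.truth_mask.shape != self.image.shape:
                raise RamavitError("truth mask shape must match the image")
            if not np.isin(self.truth_mask, (0, 1, 2)).all():
                raise RamavitError("truth labels must be 0, 1 or 2")


@dataclass(frozen=True)
class SegMetrics:
    acc: float
    iou: float
    fpr: float
    fnr: float
    oer: float


# ---------------------------------------------------------------------------
# classical segmentation

def edge_segment(
    image: np.ndarray,
    method: str = "sobel",
    threshold: float | None = None,
    canny_sigma: float = 1.5,
    closing_radius: int = 2,
    min_area: int = 8,
) -> np.ndarray:
    """Edge-based binary segmentation (Sobel gradient or Canny edges)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise RamavitError("edge_segment needs a 2-D grayscale image")
    if method == "sobel":
        grad = filters.sobel(image)
        if threshold is None:
            threshold = filters.threshold_otsu(grad) if grad.max() > 0 else np.inf
        edges = grad > threshold
    elif method == "canny":
        edges = feature.canny(image, sigma=canny_sigma)
    else:
        raise RamavitError(f"unknown method {method!r} (use 'sobel' or 'canny')")
    closed = ndi.binary_closing(
        edges, structure=morphology.disk(closing_radius), border_value=0
    )
    filled = ndi.binary_fill_holes(closed)
    return _drop_small(filled, min_area)


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    areas = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] >= min_area
    return keep[labels]


# ---------------------------------------------------------------------------
# dilated-convolution network

@dataclass(frozen=True)
class DcnConfig:
    channels: int = 12
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    impurity_weight: float = 0.2
    epochs: int = 250
    lr: float = 6e-3
    batch_images: int = 4
    seed: int = 0


class DcnModel:
    """Six-convolution dilated encoder with a per-pixel 2-class head."""

    def __init__(self, cfg: DcnConfig, rng: np.random.Generator):
        c = cfg.channels
        layers: list[nn.Layer] = [nn.Conv2d(1, c, 3, dilation=1, rng=rng), nn.BatchNorm(c), nn.ReLU()]
        for d in cfg.dilations[1:]:
            layers += [nn.Conv2d(c, c, 3, dilation=d, rng=rng), nn.BatchNorm(c), nn.ReLU()]
        layers += [nn.Conv2d(c, c, 3, dilation=1, rng=rng), nn.BatchNorm(c), nn.ReLU()]
        layers += [nn.Conv2d(c, 2, 1, dilation=1, rng=rng)]
        self.net = nn.Sequential(*layers)
        self.cfg = cfg

    def logits(self, images: np.ndarray, train: bool) -> np.ndarray:
        """(N, H, W) images -> (N, H, W, 2) logits."""
        out = self.net.forward(images[:, None, :, :], train)
        return np.moveaxis(out, 1, -1)

    def predict(self, image: np.ndarray) -> np.ndarray:
        lg = self.logits(np.asarray(image, dtype=float)[None], train=False)[0]
        return (lg[..., 1] > lg[..., 0]).astype(bool)


def train_dcn(samples: list[SegSample], cfg: DcnConfig | None = None) -> DcnModel:
    """Train the DCN on labelled images.

    Truth label 2 (impurity) is trained as background with loss weight
    ``impurity_weight`` < 1, which teaches the network to suppress debris.
    """
    cfg = cfg or DcnConfig()
    if not samples:
        raise RamavitError("train_dcn needs at least one sample")
    if any(s.truth_mask is None for s in samples):
        raise RamavitError("every training sample needs a truth mask")
    rng = np.random.default_rng(cfg.seed)
    model = DcnModel(cfg, rng)
    X = np.stack([s.image for s in samples])
    truth = np.stack([s.truth_mask for s in samples])
    y = (truth == 1).astype(int)  # impurities become background
    w = np.where(truth == 2, cfg.impurity_weight, 1.0)
    opt = nn.Adam(model.net.params(), lr=cfg.lr)
    n = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_images):
            idx = order[start : start + cfg.batch_images]
            opt.zero_grad()
            logits = model.logits(X[idx], train=True)
            _, dlogits = nn.softmax_cross_entropy(logits, y[idx], weights=w[idx])
            model.net.backward(np.moveaxis(dlogits, -1, 1))
            opt.step()
    return model


def dcn_segment(model: DcnModel, image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise RamavitError("dcn_segment needs a 2-D grayscale image")
    return model.predict(image)


# ---------------------------------------------------------------------------
# localisation and metrics

def locate_cells(
    mask: np.ndarray,
    min_area: int = 5,
    split_touching: bool = False,
    min_distance: int = 4,
) -> list[tuple[float, float]]:
    """Centroids (row, col; 0-based) of connected components >= min_area.

    With ``split_touching`` a distance-transform watershed separates
    fused blobs before centroids are taken.
    """
    mask = np.asarray(mask).astype(bool)
    if split_touching and mask.any():
        dist = ndi.distance_transform_edt(mask)
        peaks = feature.peak_local_max(
            dist, min_distance=min_distance, labels=measure.label(mask)
        )
        markers = np.zeros_like(mask, dtype=int)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        labels = sk_seg.watershed(-dist, markers, mask=mask)
    else:
        labels = measure.label(mask)
    out = []
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            out.append(tuple(float(v) for v in region.centroid))
    return out


def seg_metrics(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixel-level metrics; truth label 2 collapses to background.

    Degenerate conventions: IoU = 1 when both masks are empty; FNR = 0
    when there are no truth-positive pixels; FPR = 0 when there are no
    truth-negative pixels.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise RamavitError("prediction and truth must have the same shape")
    t = truth == 1
    tp = int(np.sum(pred & t))
    fp = int(np.sum(pred & ~t))
    fn = int(np.sum(~pred & t))
    tn = int(np.sum(~pred & ~t))
    n = pred.size
    acc = (tp + tn) / n
    union = tp + fp + fn
    iou = 1.0 if union == 0 else tp / union
    fpr = 0.0 if fp + tn == 0 else fp / (fp + tn)
    fnr = 0.0 if fn + tp == 0 else fn / (fn + tp)
    oer = (fp + fn) / n
    return SegMetrics(acc=acc, iou=iou, fpr=fpr, fnr=fnr, oer=oer)
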
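"""Two-channel fluorescence image quantification.

Nuclei are segmented on the nuclear-stain channel (DAPI/Hoechst) with an
Otsu threshold and 8-connected component labeling; a nucleus counts as
marker-positive (PI for membrane-compromised cells, EdU for proliferating
cells) when its mean within-component marker intensity exceeds a fluorescent
cutoff that can be held fixed across a batch of images. A whole-frame
marker/nuclear mean-intensity ratio serves protein-level readouts such as
HIF1α. Thresholding and labeling are delegated to scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
from skimage import filters, measure


@dataclass
class TwoChannelImage:
    """A nuclear-stain channel and a marker channel of identical shape."""

    nuclear: np.ndarray
    marker: np.ndarray

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=np.float64)
        self.marker = np.asarray(self.marker, dtype=np.float64)
        if self.nuclear.shape != self.marker.shape:
            raise ValueError("channels must share shape")
        if self.nuclear.ndim != 2:
            raise ValueError("channels must be 2-D intensity arrays")
        for name, ch in (("nuclear", self.nuclear), ("marker", self.marker)):
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"{name} channel must be finite and >= 0")

    @classmethod
    def from_tiff(cls, path) -> "TwoChannelImage":
        """Read a channel-major two-page TIFF (page 0 nuclear, page 1 marker)."""
        pages = tifffile.imread(str(path))
        if pages.ndim != 3 or pages.shape[0] != 2:
            raise ValueError(f"{path}: expected a 2-page channel-major TIFF")
        return cls(nuclear=pages[0], marker=pages[1])

    def to_tiff(self, path) -> None:
        stack = np.stack([self.nuclear, self.marker]).astype(np.float32)
        tifffile.imwrite(str(path), stack)


@dataclass
class NucleiQuantResult:
    """Counts and derived percentage for one image.

    ``percent_positive`` is NaN (undefined, never 0) when no nuclei were
    found; ``cutoff`` echoes the numeric marker cutoff actually applied so
    it can be held fixed across images.
    """

    total_nuclei: int
    positive_nuclei: int
    percent_positive: float
    centroids: pd.DataFrame = field(default_factory=pd.DataFrame)
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.positive_nuclei <= self.total_nuclei):
            raise ValueError("need 0 <= positive_nuclei <= total_nuclei")

    @property
    def undefined(self) -> bool:
        return self.total_nuclei == 0


def otsu_threshold_value(channel: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximizes between-class variance over a 256-bin
    histogram of the observed intensity range."""
    channel = np.asarray(channel, dtype=np.float64)
    if np.unique(channel).size < 2:
        raise ValueError("Otsu threshold undefined for a constant image")
    return float(filters.threshold_otsu(channel, nbins=nbins))


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary foreground mask: intensities strictly above the Otsu threshold."""
    return np.asarray(channel) > otsu_threshold_value(channel, nbins=nbins)


def count_nuclei(
    mask: np.ndarray, min_area: int = 20
) -> tuple[int, np.ndarray, pd.DataFrame]:
    """8-connected components of a binary mask with area ≥ ``min_area``.

    Returns (count, relabeled image with small components removed,
    centroid table with columns label, y, x, area).
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    kept = np.zeros_like(labels)
    rows = []
    for new_label, p in enumerate(props, start=1):
        kept[labels == p.label] = new_label
        rows.append(
            {"label": new_label, "y": p.centroid[0], "x": p.centroid[1], "area": p.area}
        )
    centroids = pd.DataFrame(rows, columns=["label", "y", "x", "area"])
    return len(props), kept, centroids


def percent_positive(
    image: TwoChannelImage,
    cutoff: Union[float, str] = "otsu",
    min_area: int = 20,
) -> NucleiQuantResult:
    """Fraction of segmented nuclei whose mean marker intensity exceeds the
    fluorescent cutoff.

    Nuclei come from Otsu thresholding + component labeling of the nuclear
    channel. ``cutoff`` is either a numeric marker intensity or ``"otsu"``
    to derive it from the marker channel; the resolved number is echoed in
    the result so batch runs can pin it. Zero segmented nuclei yield an
    undefined (NaN) percentage, never 0%.
    """
    mask = otsu_threshold(image.nuclear)
    total, labels, centroids = count_nuclei(mask, min_area=min_area)
    if cutoff == "otsu":
        cutoff_value = otsu_threshold_value(image.marker)
    else:
        cutoff_value = float(cutoff)
    if total == 0:
        return NucleiQuantResult(0, 0, float("nan"), centroids, cutoff_value)
    marker_means = np.array(
        [image.marker[labels == lab].mean() for lab in centroids["label"]]
    )
    positive_mask = marker_means > cutoff_value
    centroids = centroids.assign(
        marker_mean=marker_means, marker_positive=positive_mask
    )
    positive = int(positive_mask.sum())
    return NucleiQuantResult(
        total_nuclei=total,
        positive_nuclei=positive,
        percent_positive=100.0 * positive / total,
        centroids=centroids,
        cutoff=cutoff_value,
    )


def percent_proliferating(
    image: TwoChannelImage,
    cutoff: Union[float, str] = "otsu",
    min_area: int = 20,
) -> NucleiQuantResult:
    """EdU+/DAPI+ percentage of proliferating cells; identical contract to
    :func:`percent_positive` with the marker channel read as EdU."""
    return percent_positive(image, cutoff=cutoff, min_area=min_area)


def mean_intensity_ratio(image: TwoChannelImage) -> float:
    """Whole-frame marker/nuclear mean-intensity ratio (e.g. HIF1α / DAPI).

    A common camera gain applied to both channels cancels."""
    nuclear_mean = float(image.nuclear.mean())
    if nuclear_mean <= 0:
        raise ValueError("nuclear-channel mean must be positive")
    return float(image.marker.mean()) / nuclear_mean
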
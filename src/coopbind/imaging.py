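"""Cell-image scores: microtubule-bench mixing and nuclear aggregation.

The mixing assay tethers two fluorescent fusion proteins to microtubules and
asks whether they co-assemble: elongated microtubule clusters ("spots") are
segmented in the cytoplasm, filtered by area and width-to-length ratio, and
the per-spot channel enrichments (spot mean / cytoplasm mean) are regressed
against each other — the regression R^2 is the mixing score.  The nuclear
assay integrates background-subtracted aggregate signal relative to the
whole nucleus and the enrichment of poly-A mRNA inside aggregates.

Segmentation here is intentionally simple and fully parameterised (Otsu
thresholds, dilation bands, top-hat aggregate detection); the quantitative
scores downstream are the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology

__all__ = [
    "CellImage",
    "SegmentationMasks",
    "SpotMeasurement",
    "MixingScore",
    "AggregateScore",
    "SegmentationError",
    "InsufficientSpotsError",
    "UndefinedScoreError",
    "segment_cell",
    "detect_spots",
    "filter_spots",
    "enrichment",
    "mixing_score",
    "detect_aggregates",
    "aggregate_scores",
]


class SegmentationError(RuntimeError):
    pass


class InsufficientSpotsError(RuntimeError):
    pass


class UndefinedScoreError(RuntimeError):
    pass


@dataclass
class CellImage:
    """Named 2-D intensity channels sharing one geometry."""

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None  # micrometres per pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        self.channels = {ch: np.asarray(a, dtype=float) for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for ch, a in self.channels.items():
            if a.ndim != 2:
                raise ValueError(f"channel {ch!r} is not 2-D")
            if np.any(a < 0):
                raise ValueError(f"channel {ch!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclass
class SegmentationMasks:
    """Nucleus/cytoplasm masks plus labelled spot and aggregate maps."""

    nucleus: np.ndarray
    cytoplasm: np.ndarray
    spot_labels: np.ndarray | None = None
    aggregate_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        self.cytoplasm = np.asarray(self.cytoplasm, dtype=bool)
        if self.nucleus.shape != self.cytoplasm.shape:
            raise ValueError("mask shapes differ")
        if self.aggregate_labels is not None:
            agg = np.asarray(self.aggregate_labels)
            if np.any((agg > 0) & ~self.nucleus):
                raise ValueError("aggregates must lie inside the nucleus")


@dataclass
class SpotMeasurement:
    """Geometry and intensities of one segmented spot."""

    label: int
    area: float  # px^2
    width_to_length: float  # minor/major principal-axis ratio, in (0, 1]
    mean_intensity: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if not (0.0 < self.width_to_length <= 1.0):
            raise ValueError("width_to_length must be in (0, 1]")


@dataclass
class MixingScore:
    r_squared: float
    slope: float
    intercept: float
    n_spots: int


@dataclass
class AggregateScore:
    relative_intensity: float
    mrna_enrichment: float | None
    n_aggregates: int


def segment_cell(
    image: CellImage,
    nucleus_channel: str = "nucleus",
    cell_channel: str | None = None,
    dilation_band: int = 40,
) -> SegmentationMasks:
    """Nucleus by Otsu on the stain channel; cytoplasm = cell minus nucleus.

    The cell footprint is an Otsu threshold on ``cell_channel`` when given
    (union with the nucleus, holes filled); otherwise a ``dilation_band``-px
    dilation ring around the nucleus stands in for the cell body.
    """
    nuc_img = image[nucleus_channel]
    if nuc_img.max() <= nuc_img.min():
        raise SegmentationError("flat nucleus channel")
    nucleus = nuc_img > filters.threshold_otsu(nuc_img)
    nucleus = ndi.binary_fill_holes(nucleus)
    if cell_channel is not None:
        cell_img = image[cell_channel]
        cell = cell_img > filters.threshold_otsu(cell_img)
        cell = ndi.binary_fill_holes(cell | nucleus)
    else:
        cell = ndi.binary_dilation(nucleus, morphology.disk(1), iterations=dilation_band)
    cytoplasm = cell & ~nucleus
    return SegmentationMasks(nucleus=nucleus, cytoplasm=cytoplasm)


def detect_spots(
    image: CellImage,
    channel: str,
    masks: SegmentationMasks,
    threshold_nmads: float = 6.0,
    connectivity: int = 2,
) -> tuple[np.ndarray, list[SpotMeasurement]]:
    """Segment bright spots inside the cytoplasm and measure them.

    The intensity threshold adapts to the cytoplasm background: median plus
    ``threshold_nmads`` robust standard deviations (1.4826 * MAD).  Connected
    components become labelled spots; each is measured for area, principal
    axis width-to-length ratio, and per-channel mean intensity and
    cytoplasm-normalised enrichment.
    """
    cyto = masks.cytoplasm
    if not np.any(cyto):
        raise SegmentationError("empty cytoplasm mask")
    img = image[channel]
    bg = img[cyto]
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    thr = med + threshold_nmads * 1.4826 * max(mad, 1e-12)
    binary = (img > thr) & cyto
    labels = measure.label(binary, connectivity=connectivity)
    spot_pixels = labels > 0
    cyto_means = {
        ch: float(np.mean(image[ch][cyto & ~spot_pixels]))
        for ch in image.channels
    }
    spots: list[SpotMeasurement] = []
    for rp in measure.regionprops(labels):
        major = rp.axis_major_length
        minor = rp.axis_minor_length
        ratio = min(max(minor / major, 1e-6), 1.0) if major > 0 else 1.0
        mask = labels == rp.label
        means = {ch: float(np.mean(image[ch][mask])) for ch in image.channels}
        enr = {
            ch: means[ch] / cyto_means[ch]
            for ch in image.channels
            if cyto_means[ch] > 0
        }
        spots.append(
            SpotMeasurement(
                label=int(rp.label),
                area=float(rp.area),
                width_to_length=ratio,
                mean_intensity=means,
                enrichment=enr,
            )
        )
    masks.spot_labels = labels
    return labels, spots


def filter_spots(
    spots: list[SpotMeasurement],
    area_min: float = 20.0,
    area_max: float = 300.0,
    ratio_max: float = 0.3,
) -> list[SpotMeasurement]:
    """Keep tubular spots: area strictly inside (area_min, area_max) px^2 and
    width-to-length ratio strictly below ratio_max."""
    return [
        s
        for s in spots
        if area_min < s.area < area_max and s.width_to_length < ratio_max
    ]


def enrichment(
    spot: SpotMeasurement,
    masks: SegmentationMasks,
    image: CellImage,
    channel: str,
) -> float:
    """Spot mean intensity over cytoplasm mean intensity for one channel."""
    if masks.spot_labels is None:
        raise ValueError("masks carry no spot labels")
    cyto = masks.cytoplasm & ~(masks.spot_labels > 0)
    if not np.any(cyto):
        raise SegmentationError("empty cytoplasm mask")
    cyto_mean = float(np.mean(image[channel][cyto]))
    if cyto_mean <= 0:
        raise UndefinedScoreError("cytoplasm mean is zero: cannot normalise")
    spot_mean = float(np.mean(image[channel][masks.spot_labels == spot.label]))
    return spot_mean / cyto_mean


def mixing_score(
    measurements: list[SpotMeasurement],
    min_spots: int = 10,
    x_channel: str = "red",
    y_channel: str = "green",
) -> MixingScore:
    """Mixing score: R^2 of the per-spot enrichment regression.

    Ordinary least squares of the ``y_channel`` enrichment on the
    ``x_channel`` enrichment across spots (conventionally GFP on RFP).
    R^2 = 1 means the two proteins distribute across clusters in lockstep
    (fully mixed); R^2 near 0 means independent recruitment.
    """
    if len(measurements) < min_spots:
        raise InsufficientSpotsError(
            f"{len(measurements)} spots < required {min_spots}"
        )
    x = np.array([s.enrichment[x_channel] for s in measurements])
    y = np.array([s.enrichment[y_channel] for s in measurements])
    if np.ptp(x) == 0.0:
        raise UndefinedScoreError("zero variance in x-channel enrichments")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MixingScore(
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        slope=float(slope),
        intercept=float(intercept),
        n_spots=len(measurements),
    )


def well_mixing_score(
    images: list[CellImage],
    detect_channel: str = "red",
    nucleus_channel: str = "nucleus",
    cell_channel: str | None = "red",
    min_spots: int = 10,
    per_cell: bool = False,
    threshold_nmads: float = 6.0,
    area_min: float = 20.0,
    area_max: float = 300.0,
    ratio_max: float = 0.3,
) -> MixingScore | list[MixingScore]:
    """Full mixing-score pipeline over the cells of one well.

    Each image is segmented, spots are detected on ``detect_channel`` and
    filtered by the area / width-to-length thresholds; by default the spots
    of all cells are pooled into a single per-well regression (one score per
    well).  ``per_cell=True`` returns one score per cell instead.
    """
    pooled: list[SpotMeasurement] = []
    per_cell_scores: list[MixingScore] = []
    for image in images:
        masks = segment_cell(image, nucleus_channel, cell_channel=cell_channel)
        _, spots = detect_spots(
            image, detect_channel, masks, threshold_nmads=threshold_nmads
        )
        kept = filter_spots(spots, area_min=area_min, area_max=area_max, ratio_max=ratio_max)
        if per_cell:
            per_cell_scores.append(mixing_score(kept, min_spots=min_spots))
        else:
            pooled.extend(kept)
    if per_cell:
        return per_cell_scores
    return mixing_score(pooled, min_spots=min_spots)


def detect_aggregates(
    image: CellImage,
    masks: SegmentationMasks,
    channel: str = "green",
    tophat_radius: int = 6,
    threshold_nmads: float = 6.0,
    min_area: int = 4,
) -> np.ndarray:
    """Label bright nuclear aggregates via white top-hat + robust threshold."""
    if not np.any(masks.nucleus):
        raise SegmentationError("empty nucleus mask")
    img = image[channel]
    th = morphology.white_tophat(img, morphology.disk(tophat_radius))
    vals = th[masks.nucleus]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    binary = (th > med + threshold_nmads * 1.4826 * max(mad, 1e-12)) & masks.nucleus
    labels = measure.label(binary, connectivity=2)
    for rp in measure.regionprops(labels):
        if rp.area < min_area:
            labels[labels == rp.label] = 0
    labels = measure.label(labels > 0, connectivity=2)
    masks.aggregate_labels = labels
    return labels


def aggregate_scores(
    image: CellImage,
    masks: SegmentationMasks,
    channel: str = "green",
    fish_channel: str | None = None,
    annulus_width: int = 2,
) -> AggregateScore:
    """Nuclear-aggregation scores for one nucleus.

    relative_intensity = sum over aggregates of (intensity - local
    background, floored at 0) divided by the integrated intensity over the
    whole nucleus; the local background of each aggregate is the median
    intensity in a ``annulus_width``-px annulus around it (other aggregates
    excluded).  mrna_enrichment = mean FISH intensity over aggregate pixels /
    mean FISH intensity over the nucleus (None without a FISH channel, and
    flagged undefined when there is no aggregate).
    """
    if not np.any(masks.nucleus):
        raise SegmentationError("empty nucleus mask")
    img = image[channel]
    labels = masks.aggregate_labels
    if labels is None:
        labels = detect_aggregates(image, masks, channel=channel)
    nucleus_total = float(np.sum(img[masks.nucleus]))
    n_agg = int(labels.max())
    if n_agg == 0 or nucleus_total <= 0:
        return AggregateScore(relative_intensity=0.0, mrna_enrichment=None, n_aggregates=0)
    all_agg = labels > 0
    signal = 0.0
    for lab in range(1, n_agg + 1):
        agg = labels == lab
        ring = ndi.binary_dilation(agg, morphology.disk(1), iterations=annulus_width)
        ring = ring & ~all_agg
        bg_pixels = img[ring] if np.any(ring) else img[masks.nucleus & ~all_agg]
        local_bg = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
        signal += float(np.sum(np.maximum(img[agg] - local_bg, 0.0)))
    relative = signal / nucleus_total
    mrna = None
    if fish_channel is not None:
        fish = image[fish_channel]
        nuc_mean = float(np.mean(fish[masks.nucleus]))
        if nuc_mean > 0:
            mrna = float(np.mean(fish[all_agg])) / nuc_mean
    return AggregateScore(
        relative_intensity=relative, mrna_enrichment=mrna, n_aggregates=n_agg
    )
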
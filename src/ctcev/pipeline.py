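"""Segmentation of cartridge image stacks and per-object feature extraction.

A *cartridge* is one patient sample: a stack of 4-channel fluorescence frames
(channel order DNA, Marker1, CK, CD45) acquired at a fixed sample-plane pixel
size (default 0.67 um/pixel: a 6.7 um camera pixel behind a 10x objective).

Objects are formed per frame as 8-connected components of the union of the
per-channel foreground masks; every per-channel feature (mean intensity,
cytokeratin size, DNA-on-CK overlay fraction) is then measured inside that
channel's own contour restricted to the object.  A channel with no contour on
an object contributes a mean intensity of 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_triangle
from skimage.measure import label as _sk_label

CHANNELS = ("dna", "marker1", "ck", "cd45")
#: feature-table columns consumed by the gates
FEATURE_COLUMNS = (
    "mean_dna",
    "mean_marker1",
    "mean_ck",
    "mean_cd45",
    "mean_marker2",
    "size_ck",
    "dna_overlay_ck",
)


class PipelineError(ValueError):
    """Invalid input to the image pipeline."""


@dataclass
class CartridgeStack:
    """One cartridge's image data plus acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_channels, height, width)``.
    channel_roles
        Channel names in array order; default ``("dna", "marker1", "ck",
        "cd45")``.  A fifth ``"marker2"`` channel is supported but optional.
    pixel_size_sample
        Sample-plane pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    channel_roles: tuple = CHANNELS
    pixel_size_sample: float = 0.67
    cartridge_id: str = "cartridge"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4:
            raise PipelineError("frames must be (n_frames, n_channels, H, W)")
        if self.frames.shape[1] != len(self.channel_roles):
            raise PipelineError("channel_roles must match the channel axis")
        if self.pixel_size_sample <= 0:
            raise PipelineError("pixel_size_sample must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise PipelineError(f"stack has no channel role {role!r}") from None

    def write_tiff(self, path) -> None:
        """Write as a multi-page TIFF, frame-major / channel-minor page order.

        Each page's description records the frame index and channel role so an
        archive remains self-describing.
        """
        with tifffile.TiffWriter(path) as tif:
            for f in range(self.n_frames):
                for c, role in enumerate(self.channel_roles):
                    tif.write(
                        self.frames[f, c],
                        description=json.dumps(
                            {
                                "frame": f,
                                "channel": role,
                                "pixel_size_sample_um": self.pixel_size_sample,
                            }
                        ),
                        contiguous=False,
                    )

    @classmethod
    def read_tiff(cls, path, n_channels: int = 4, cartridge_id: str | None = None) -> "CartridgeStack":
        """Read a multi-page TIFF written by :meth:`write_tiff`.

        Falls back to positional channel order (DNA, Marker1, CK, CD45) when
        page descriptions are absent, which also covers plain 4-layer
        frame-major archives.
        """
        pixel_size = 0.67
        roles = CHANNELS[:n_channels]
        with tifffile.TiffFile(path) as tif:
            pages = np.stack([page.asarray() for page in tif.pages])
            desc = tif.pages[0].description
            if desc:
                try:
                    meta = json.loads(desc)
                    pixel_size = float(meta.get("pixel_size_sample_um", pixel_size))
                except (json.JSONDecodeError, TypeError):
                    pass
        if pages.shape[0] % n_channels:
            raise PipelineError(
                f"page count {pages.shape[0]} is not a multiple of {n_channels} channels"
            )
        n_frames = pages.shape[0] // n_channels
        frames = pages.reshape(n_frames, n_channels, *pages.shape[1:])
        return cls(
            frames=frames,
            channel_roles=roles,
            pixel_size_sample=pixel_size,
            cartridge_id=cartridge_id or str(path),
        )


@dataclass
class SegmentationConfig:
    """Parameters of the per-channel segmentation substitute.

    The multiscale algorithm of the original analysis software is not public;
    here each channel is background-subtracted (per-frame median) and
    binarized at a fixed intensity threshold above background (``method =
    "fixed"``) or at a triangle threshold (``method = "triangle"``).  The
    contract (deterministic label mask of connected foreground regions with
    area >= ``min_area``) is what downstream code relies on, so the
    implementation can be swapped.
    """

    threshold: float = 20.0
    min_area: int = 2
    method: str = "fixed"  # "fixed" | "triangle"
    background: str = "median"  # "median" | "none"
    overlay_denominator: str = "ck"  # "ck" | "dna"
    per_channel_threshold: dict = field(default_factory=dict)

    def threshold_for(self, role: str) -> float:
        return float(self.per_channel_threshold.get(role, self.threshold))

    def to_json(self) -> str:
        return json.dumps(self.__dict__, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SegmentationConfig":
        return cls(**json.loads(text))


def _background_level(image: np.ndarray, mode: str) -> float:
    if mode == "none":
        return 0.0
    return float(np.median(image))


def segment_channel(
    image: np.ndarray,
    min_area: int = 2,
    threshold: float = 20.0,
    method: str = "fixed",
    background: str = "median",
) -> np.ndarray:
    """Label connected foreground regions of one channel.

    Returns an integer label mask (0 = background) of 8-connected regions of
    the background-subtracted image above ``threshold``, keeping regions with
    at least ``min_area`` pixels.  Deterministic: labels are assigned in
    raster order of each region's first pixel.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise PipelineError("segment_channel expects a non-empty 2-D image")
    if np.isnan(image).all():
        raise PipelineError("image is all-NaN")
    bg = _background_level(image, background)
    corrected = image - bg
    if method == "triangle":
        finite = corrected[np.isfinite(corrected)]
        if finite.max() > finite.min():
            threshold = threshold_triangle(finite)
    mask = corrected > threshold
    labels = _sk_label(mask, connectivity=2)
    if min_area > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = _relabel_raster(labels)
    return labels


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..k in raster order of first occurrence."""
    flat = labels.ravel()
    nonzero = flat[flat > 0]
    if nonzero.size == 0:
        return labels
    order = pd.unique(nonzero)
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    lut[order] = np.arange(1, len(order) + 1)
    return lut[labels]


def extract_objects(stack: CartridgeStack, config: SegmentationConfig | None = None) -> pd.DataFrame:
    """Measure per-object features over all frames of a cartridge.

    Objects are 8-connected components of the union of all channels'
    foreground masks within a frame.  Per-channel mean intensities are
    background-subtracted means inside the channel's own mask restricted to
    the object (0 if the channel shows no contour there); ``size_ck`` is the
    CK-contour area in pixels; ``dna_overlay_ck`` is the fraction of the CK
    contour covered by the DNA contour.

    Returns a DataFrame with one row per object and columns ``event``,
    ``frame``, ``y``, ``x``, the :data:`FEATURE_COLUMNS`, and the bounding
    box (``min_row``, ``min_col``, ``max_row``, ``max_col``).
    """
    if config is None:
        config = SegmentationConfig()
    for role in ("dna", "marker1", "ck", "cd45"):
        stack.channel_index(role)

    rows = []
    event_id = 0
    for f in range(stack.n_frames):
        masks = {}
        corrected = {}
        for role in stack.channel_roles:
            img = stack.frames[f, stack.channel_index(role)].astype(float)
            lbl = segment_channel(
                img,
                min_area=config.min_area,
                threshold=config.threshold_for(role),
                method=config.method,
                background=config.background,
            )
            masks[role] = lbl > 0
            corrected[role] = np.clip(img - _background_level(img, config.background), 0.0, None)

        union = np.zeros(masks["dna"].shape, dtype=bool)
        for m in masks.values():
            union |= m
        obj_labels = _relabel_raster(_sk_label(union, connectivity=2))
        n_obj = obj_labels.max()
        if n_obj == 0:
            continue
        index = np.arange(1, n_obj + 1)
        slices = ndimage.find_objects(obj_labels)

        for k, sl in zip(index, slices):
            region = obj_labels[sl] == k
            means = {}
            npix = {}
            for role in stack.channel_roles:
                inmask = region & masks[role][sl]
                n = int(inmask.sum())
                npix[role] = n
                means[role] = float(corrected[role][sl][inmask].mean()) if n else 0.0
            size_ck = npix["ck"]
            ck_region = region & masks["ck"][sl]
            dna_region = region & masks["dna"][sl]
            if config.overlay_denominator == "dna":
                denom = npix["dna"]
            else:
                denom = size_ck
            overlay = float((ck_region & dna_region).sum() / denom) if denom else 0.0
            ys, xs = np.nonzero(region)
            rows.append(
                {
                    "event": event_id,
                    "frame": f,
                    "y": float(ys.mean() + sl[0].start),
                    "x": float(xs.mean() + sl[1].start),
                    "mean_dna": means["dna"],
                    "mean_marker1": means["marker1"],
                    "mean_ck": means["ck"],
                    "mean_cd45": means["cd45"],
                    "mean_marker2": means.get("marker2", 0.0),
                    "size_ck": size_ck,
                    "dna_overlay_ck": overlay,
                    "min_row": int(sl[0].start),
                    "min_col": int(sl[1].start),
                    "max_row": int(sl[0].stop),
                    "max_col": int(sl[1].stop),
                }
            )
            event_id += 1
    columns = [
        "event",
        "frame",
        "y",
        "x",
        *FEATURE_COLUMNS,
        "min_row",
        "min_col",
        "max_row",
        "max_col",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)
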
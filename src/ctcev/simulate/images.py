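"""Synthetic cartridge image stacks with known ground truth.

Emulates CellSearch-style acquisition: per cartridge, a stack of 4-channel
frames (DNA, Marker1, CK, CD45) at 0.67 um/pixel in the sample plane (6.7 um
camera pixel behind a 10x objective).  Planted object classes:

``ctc``
    cytokeratin-positive, nucleated cell, diameter > 4 um (CK disk with a
    concentric smaller DNA disk).
``tdev``
    small CK-positive particle without a nucleus (no DNA signal).
``leukocyte``
    CD45-positive nucleated cell, no CK.
``bare_nucleus``
    DNA-only object.
``debris``
    small dim CK-channel particle below the CK intensity gate.

Objects are rendered as uniform disks, blurred with a Gaussian point-spread
function, and degraded with Poisson shot noise plus additive Gaussian read
noise (the standard CCD model).  ``noise_sd = 0`` disables the noise model
entirely, which makes planted intensities analytically exact for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ctcev.pipeline import CartridgeStack, CHANNELS

#: per-class, per-channel mean signal (arbitrary units on the 0-255-like
#: scale the gates assume); chosen so each class sits clearly on its side of
#: the default gate thresholds (DNA > 45, CK > 60, CD45 <= 5)
DEFAULT_INTENSITY_MEANS = {
    "ctc": {"dna": 120.0, "marker1": 0.0, "ck": 150.0, "cd45": 0.0},
    "tdev": {"dna": 0.0, "marker1": 0.0, "ck": 140.0, "cd45": 0.0},
    "leukocyte": {"dna": 120.0, "marker1": 0.0, "ck": 0.0, "cd45": 150.0},
    "bare_nucleus": {"dna": 120.0, "marker1": 0.0, "ck": 0.0, "cd45": 0.0},
    "debris": {"dna": 0.0, "marker1": 0.0, "ck": 30.0, "cd45": 0.0},
}

#: object diameter ranges in micrometres; CTCs are strictly > 4 um
DEFAULT_DIAMETERS_UM = {
    "ctc": (6.0, 12.0),
    "tdev": (2.0, 3.6),
    "leukocyte": (7.0, 12.0),
    "bare_nucleus": (6.0, 10.0),
    "debris": (1.5, 3.0),
}

#: diameter of the nuclear (DNA) disk relative to the cell body disk
NUCLEUS_FRACTION = 0.7

CLASSES = ("ctc", "tdev", "leukocyte", "bare_nucleus", "debris")


class SimulationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class ImageSimParams:
    """Parameters of the cartridge image simulator.

    ``psf_sigma`` defaults to 0.25 um, the diffraction-limited Gaussian width
    for a 0.45 NA objective at ~550 nm emission.
    """

    frames: int = 16
    frame_shape: tuple = (256, 256)
    pixel_size_sample: float = 0.67
    n_ctc: int = 5
    n_tdev: int = 100
    n_leukocyte: int = 50
    n_bare_nucleus: int = 10
    n_debris: int = 20
    intensity_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITY_MEANS.items()})
    diameters_um: dict = field(default_factory=lambda: dict(DEFAULT_DIAMETERS_UM))
    psf_sigma: float = 0.25
    background_level: float = 5.0
    noise_sd: float = 2.0
    seed: int = 0

    def counts(self) -> dict:
        return {
            "ctc": self.n_ctc,
            "tdev": self.n_tdev,
            "leukocyte": self.n_leukocyte,
            "bare_nucleus": self.n_bare_nucleus,
            "debris": self.n_debris,
        }

    def validate(self) -> None:
        if self.frames <= 0:
            raise SimulationError("frames must be positive")
        if len(self.frame_shape) != 2 or min(self.frame_shape) <= 0:
            raise SimulationError("frame_shape must be two positive ints")
        if self.pixel_size_sample <= 0:
            raise SimulationError("pixel_size_sample must be > 0")
        if self.psf_sigma < 0:
            raise SimulationError("psf_sigma must be >= 0")
        if self.noise_sd < 0 or self.background_level < 0:
            raise SimulationError("noise_sd and background_level must be >= 0")
        for cls, n in self.counts().items():
            if n < 0:
                raise SimulationError(f"count for {cls} must be >= 0")
        for cls, channels in self.intensity_means.items():
            for ch, v in channels.items():
                if v < 0:
                    raise SimulationError(f"negative intensity for {cls}/{ch}")
        max_d = max(hi for (lo, hi) in self.diameters_um.values())
        margin = self._margin_px(max_d)
        if 2 * margin >= min(self.frame_shape):
            raise SimulationError(
                "frame_shape too small to contain the largest planted object"
            )

    def _margin_px(self, diameter_um: float) -> int:
        r_px = diameter_um / 2.0 / self.pixel_size_sample
        psf_px = self.psf_sigma / self.pixel_size_sample
        return int(math.ceil(r_px + 4.0 * psf_px + 2.0))

    def to_json_dict(self) -> dict:
        return asdict(self)


def _place_objects(params: ImageSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Assign frames, positions and diameters to all planted objects.

    Rejection-samples positions so that objects in one frame keep a clearance
    of each other; clearance covers both radii plus PSF support so planted
    objects never merge into one connected component.
    """
    psf_px = params.psf_sigma / params.pixel_size_sample
    gap = 6.0 + 8.0 * psf_px
    h, w = params.frame_shape
    placed = {f: [] for f in range(params.frames)}
    records = []
    for cls in CLASSES:
        n = params.counts()[cls]
        lo, hi = params.diameters_um[cls]
        for _ in range(n):
            d_um = float(rng.uniform(lo, hi))
            r_px = d_um / 2.0 / params.pixel_size_sample
            margin = params._margin_px(d_um)
            for attempt in range(5000):
                f = int(rng.integers(params.frames))
                y = float(rng.uniform(margin, h - margin))
                x = float(rng.uniform(margin, w - margin))
                ok = all(
                    (y - py) ** 2 + (x - px) ** 2 > (r_px + pr + gap) ** 2
                    for (py, px, pr) in placed[f]
                )
                if ok:
                    break
            else:
                raise SimulationError(
                    "could not place all objects; frame too small or too crowded"
                )
            placed[f].append((y, x, r_px))
            means = params.intensity_means[cls]
            records.append(
                {
                    "label": cls,
                    "frame": f,
                    "y": y,
                    "x": x,
                    "diameter_um": d_um,
                    "mean_dna": means.get("dna", 0.0),
                    "mean_marker1": means.get("marker1", 0.0),
                    "mean_ck": means.get("ck", 0.0),
                    "mean_cd45": means.get("cd45", 0.0),
                }
            )
    columns = [
        "label",
        "frame",
        "y",
        "x",
        "diameter_um",
        "mean_dna",
        "mean_marker1",
        "mean_ck",
        "mean_cd45",
    ]
    return pd.DataFrame(records, columns=columns)


def _add_disk(channel_img: np.ndarray, y: float, x: float, radius_px: float, value: float) -> None:
    if value <= 0 or radius_px <= 0:
        return
    h, w = channel_img.shape
    r = int(math.ceil(radius_px)) + 1
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disk = (yy - y) ** 2 + (xx - x) ** 2 <= radius_px**2
    channel_img[y0:y1, x0:x1][disk] += value


def generate_cartridge(params: ImageSimParams, cartridge_id: str = "synthetic"):
    """Simulate one cartridge.

    Returns ``(CartridgeStack, GroundTruth)`` where the ground truth is a
    DataFrame with one row per planted object (class label, frame, centroid,
    diameter in um, per-channel true mean intensity).  Pure function of
    ``params`` (including ``params.seed``): identical params give identical
    output.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rng_place, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    truth = _place_objects(params, rng_place)
    h, w = params.frame_shape
    frames = np.zeros((params.frames, len(CHANNELS), h, w), dtype=np.float64)
    psf_px = params.psf_sigma / params.pixel_size_sample

    for rec in truth.itertuples():
        r_px = rec.diameter_um / 2.0 / params.pixel_size_sample
        nucleus_r = r_px * NUCLEUS_FRACTION
        per_channel = {
            "dna": (rec.mean_dna, nucleus_r if rec.label in ("ctc", "leukocyte") else r_px),
            "marker1": (rec.mean_marker1, r_px),
            "ck": (rec.mean_ck, r_px),
            "cd45": (rec.mean_cd45, r_px),
        }
        for c, role in enumerate(CHANNELS):
            value, radius = per_channel[role]
            _add_disk(frames[rec.frame, c], rec.y, rec.x, radius, value)

    if psf_px > 0:
        for f in range(params.frames):
            for c in range(len(CHANNELS)):
                frames[f, c] = gaussian_filter(frames[f, c], psf_px)

    frames += params.background_level
    if params.noise_sd > 0:
        shot = rng_noise.poisson(np.clip(frames, 0.0, None)).astype(np.float64)
        frames = shot + rng_noise.normal(0.0, params.noise_sd, size=frames.shape)
        frames = np.clip(frames, 0.0, None)

    stack = CartridgeStack(
        frames=frames.astype(np.float32),
        channel_roles=CHANNELS,
        pixel_size_sample=params.pixel_size_sample,
        cartridge_id=cartridge_id,
    )
    return stack, truth
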
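"""Frame-differencing (pixel-difference, PD) motion scoring.

The PD method scores motion in a grayscale video without tracking: a pixel
"changed" when its absolute difference between consecutive frames reaches
``pixel_delta_min`` gray levels, a frame pair shows motion when the changed
fraction exceeds a frame-level threshold (default 8.5%, deliberately liberal
against a sensor-noise floor of about 5.5% changed pixels), and the binary
motion series is binned like the detector and observer data: 2 s bins scored
any-motion, then 30 s bins as percent of 2 s bins with motion.  The module
also provides the method-comparison statistics (Pearson r and mean percent
difference) and a synthetic video generator whose noise floor is calibrated
to a target change fraction and whose scripted "locomotion" epochs carry a
moving bright blob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_PIXEL_DELTA_MIN = 10
DEFAULT_FRAME_FRACTION_THRESHOLD = 0.085


@dataclass(frozen=True)
class FrameSequence:
    """Grayscale 8-bit frames (n, height, width) at a fixed rate (Hz)."""

    frames: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("need >= 2 frames of identical shape")
        if f.dtype != np.uint8:
            if f.min() < 0 or f.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            f = f.astype(np.uint8)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        object.__setattr__(self, "frames", f)

    def __len__(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class MethodTrace:
    """Per-30-s-bin percent locomotion for one scoring method."""

    label: str  # MDS, OBS or PD
    values: np.ndarray
    bin_width: float = 30.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("percent values must lie in [0, 100]")


def frame_change_fraction(
    seq: FrameSequence, pixel_delta_min: int = DEFAULT_PIXEL_DELTA_MIN
) -> np.ndarray:
    """Per consecutive frame pair: fraction of pixels whose absolute change
    is at least ``pixel_delta_min`` gray levels."""
    f = seq.frames.astype(np.int16)
    diff = np.abs(np.diff(f, axis=0))
    return (diff >= pixel_delta_min).mean(axis=(1, 2))


def pd_motion(
    seq: FrameSequence,
    frame_fraction_threshold: float = DEFAULT_FRAME_FRACTION_THRESHOLD,
    pixel_delta_min: int = DEFAULT_PIXEL_DELTA_MIN,
) -> np.ndarray:
    """Binary motion per frame pair: changed fraction strictly above the
    frame threshold."""
    if not 0 <= frame_fraction_threshold < 1:
        raise ValueError("frame_fraction_threshold must lie in [0, 1)")
    return (frame_change_fraction(seq, pixel_delta_min) > frame_fraction_threshold).astype(np.int8)


def binarize_and_bin(
    motion: np.ndarray,
    frame_rate: float,
    fine_bin: float = 2.0,
    coarse_bin: float = 30.0,
    label: str = "PD",
) -> MethodTrace:
    """Any-motion 2 s bins, then percent-presence 30 s bins.

    A fine bin scores 1 if any frame pair inside it shows motion; each coarse
    value is 100 × the fraction of its fine bins scoring 1.  The series is
    truncated to whole coarse bins; shorter than one coarse bin is an error.
    """
    ratio = coarse_bin / fine_bin
    if round(ratio, 9) % 1 != 0:
        raise ValueError("coarse_bin must be a multiple of fine_bin")
    m = np.asarray(motion).astype(bool)
    per_fine = int(round(fine_bin * frame_rate))
    if per_fine < 1:
        raise ValueError("fine_bin shorter than one frame interval")
    n_fine = m.size // per_fine
    fine = m[: n_fine * per_fine].reshape(n_fine, per_fine).any(axis=1)
    per_coarse = int(round(ratio))
    n_coarse = n_fine // per_coarse
    if n_coarse == 0:
        raise ValueError("series shorter than one coarse bin")
    coarse = fine[: n_coarse * per_coarse].reshape(n_coarse, per_coarse).mean(axis=1)
    return MethodTrace(label, 100.0 * coarse, coarse_bin)


def compare_methods(a: MethodTrace, b: MethodTrace) -> tuple[float, float]:
    """Pearson r over paired bins and the mean difference of a vs b in
    percent of b's mean: 100 × (mean(a) − mean(b)) / mean(b)."""
    if a.values.shape != b.values.shape:
        raise ValueError("traces must share a common bin grid")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance trace: correlation undefined")
    r = float(stats.pearsonr(a.values, b.values).statistic)
    mean_diff = float(100.0 * (a.values.mean() - b.values.mean()) / b.values.mean())
    return r, mean_diff


@dataclass(frozen=True)
class BlobSpec:
    """Moving bright square injected during scripted locomotion epochs.

    ``epochs`` are (start_s, end_s) intervals; within them the blob advances
    every frame along a raster path, producing roughly 2 × its area fraction
    of changed pixels per frame pair.
    """

    size: int = 12
    brightness: int = 255
    epochs: tuple[tuple[float, float], ...] = ()


def synth_video(
    duration: float,
    frame_rate: float,
    noise_change_fraction_target: float = 0.055,
    blob_spec: BlobSpec | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    background: int = 40,
) -> FrameSequence:
    """Static background + calibrated iid pixel noise + optional moving blob.

    Noise model: independently per frame, each pixel is raised by a large,
    always-detected offset with probability q; consecutive frames then differ
    at a pixel with probability 2q(1 − q), so q is solved from the requested
    expected change fraction.  A target of 0 disables the noise entirely.
    """
    if not 0 <= noise_change_fraction_target < 0.5:
        raise ValueError("noise target must lie in [0, 0.5)")
    h, w = shape
    n = int(round(duration * frame_rate))
    if n < 2:
        raise ValueError("duration too short for two frames")
    if blob_spec is not None and blob_spec.size >= min(h, w):
        raise ValueError("blob larger than frame")
    rng = np.random.default_rng(seed)
    frames = np.full((n, h, w), background, dtype=np.uint8)
    if noise_change_fraction_target > 0:
        q = (1.0 - np.sqrt(1.0 - 2.0 * noise_change_fraction_target)) / 2.0
        mask = rng.random((n, h, w)) < q
        frames[mask] = background + 60
    if blob_spec is not None:
        s = blob_spec.size
        step = s  # disjoint successive positions -> clean 2x area change
        cols = max(1, (w - s) // step + 1)
        rows = max(1, (h - s) // step + 1)
        pos = 0
        for i in range(n):
            t = i / frame_rate
            if any(a <= t < b for a, b in blob_spec.epochs):
                r = (pos // cols) % rows
                c = pos % cols
                frames[i, r * step : r * step + s, c * step : c * step + s] = (
                    blob_spec.brightness
                )
                pos += 1
    return FrameSequence(frames, frame_rate)
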
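"""Core containers shared across the pipeline.

A :class:`DICImage` is a 2-D grayscale differential-interference-contrast
(DIC) intensity grid with a physical pixel size.  A :class:`LabelMap` is the
per-pixel three-class segmentation product with the fixed code contract
``{0: background, 1: cell, 2: pit}``, optionally carrying per-class
posterior probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed class codes; the order (background < cell < pit) also fixes
# argmax tie-breaking in the classifier.
BACKGROUND = 0
CELL = 1
PIT = 2

CLASS_NAMES = {BACKGROUND: "background", CELL: "cell", PIT: "pit"}
CLASS_CODES = (BACKGROUND, CELL, PIT)

MIN_IMAGE_SIZE = 16


@dataclass
class DICImage:
    """A 2-D DIC intensity image, nominal range [0, 1].

    Parameters
    ----------
    intensity : ndarray, shape (H, W)
        Real-valued intensity grid.
    pixel_size_um : float
        Physical size of one pixel in micrometres.
    """

    intensity: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError(
                f"DICImage must be 2-D grayscale, got ndim={self.intensity.ndim}"
            )
        h, w = self.intensity.shape
        if h < MIN_IMAGE_SIZE or w < MIN_IMAGE_SIZE:
            raise ValueError(
                f"DICImage must be at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE} px, got {h}x{w}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("DICImage intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class LabelMap:
    """Per-pixel three-class map with codes {0 background, 1 cell, 2 pit}.

    ``posteriors`` (optional) has shape (H, W, 3) in fixed class order and
    sums to 1 per pixel.
    """

    codes: np.ndarray
    posteriors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError(f"LabelMap codes must be 2-D, got ndim={self.codes.ndim}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("LabelMap codes must be integer-typed")
        bad = np.setdiff1d(np.unique(self.codes), np.array(CLASS_CODES))
        if bad.size:
            raise ValueError(
                f"LabelMap contains invalid code {int(bad[0])}; allowed codes are 0, 1, 2"
            )
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=np.float64)
            if self.posteriors.shape != self.codes.shape + (3,):
                raise ValueError(
                    "posteriors must have shape (H, W, 3) matching codes"
                )
            sums = self.posteriors.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("posterior rows must sum to 1 within 1e-6")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape
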
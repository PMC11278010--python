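"""Core in-memory containers shared by the simulation and reduction stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DetectorFrame:
    """One 2D detector exposure with its bad-pixel mask and metadata.

    ``mask`` is True for *excluded* pixels (dead/hot); masked pixels never
    enter any downstream statistic. ``metadata`` carries acquisition context
    (scan position in mm, force in mN for indentation runs, exposure time)
    and, for simulated frames, the ground truth used to generate them.
    """

    counts: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match counts shape "
                f"{self.counts.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape
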
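"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A 3D scalar voxel grid with anisotropic physical spacing.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Voxel intensities.
    spacing_um : tuple of float
        Physical voxel size along (z, y, x), in micrometres. Light-sheet
        acquisitions typically have a coarser z step (3.5 um here) than the
        in-plane pitch.
    channel : str
        Free-form channel tag, e.g. ``"autofluo"`` or ``"ccasp3"``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (3.5, 5.0, 5.0)
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack expects 3D data, got ndim={self.data.ndim}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]
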
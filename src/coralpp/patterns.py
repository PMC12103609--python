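"""Point patterns: positions of one morph inside one observation window."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Window

#: Recognised morph labels (tentacle colour of the two cup-coral morphs).
MORPHS = ("orange", "pink")

#: Minimum number of points required for a pattern to enter spatial analysis.
MIN_ANALYSABLE_POINTS = 30


@dataclass(frozen=True)
class PointPattern:
    """Positions (cm) of one morph's individuals inside a rectangular window.

    ``coords`` is an (n, 2) float array of (x, y) positions. All points must
    lie inside the window and be finite.
    """

    coords: np.ndarray
    window: Window = field(default_factory=Window)
    morph: str = "unlabelled"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("pattern coordinates must be finite")
        if coords.size and not np.all(self.window.contains(coords[:, 0], coords[:, 1])):
            raise ValueError("pattern contains points outside the window")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def intensity(self) -> float:
        """Empirical intensity, points per cm^2."""
        return self.n / self.window.area_cm2

    @property
    def analysable(self) -> bool:
        return self.n >= MIN_ANALYSABLE_POINTS

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n
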
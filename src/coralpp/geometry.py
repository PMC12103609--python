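"""Rectangular observation windows.

All coordinates in this package are in centimetres, with the origin at the
lower-left corner of the sample quadrat, x rightward and y upward. The
study design uses a 1.75 m x 1.75 m quadrat per photograph (3.0625 m^2).
"""

from __future__ import annotations

from dataclasses import dataclass

CM2_PER_M2 = 10_000.0


@dataclass(frozen=True)
class Window:
    """A rectangular observation window anchored at the origin.

    Parameters
    ----------
    width, height : float
        Side lengths in cm; must be positive.
    """

    width: float = 175.0
    height: float = 175.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window sides must be positive")

    @property
    def area_cm2(self) -> float:
        return self.width * self.height

    @property
    def area_m2(self) -> float:
        return self.area_cm2 / CM2_PER_M2

    def contains(self, x, y) -> "np.ndarray":
        import numpy as np

        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)

    def dilated(self, margin: float) -> "Window":
        """Window grown by ``margin`` on every side (used as a simulation guard).

        The returned window is still anchored at (0, 0); callers that need
        the shifted frame subtract ``margin`` from simulated coordinates.
        """
        if margin < 0:
            raise ValueError("margin must be non-negative")
        return Window(self.width + 2 * margin, self.height + 2 * margin)


#: The study's standard sample quadrat: 1.75 m x 1.75 m.
STUDY_WINDOW = Window(175.0, 175.0)
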
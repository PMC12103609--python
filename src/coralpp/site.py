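"""A site: one annotated seabed photograph's point patterns and metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .geometry import Window
from .masks import CategoryMask
from .patterns import MIN_ANALYSABLE_POINTS, PointPattern


@dataclass
class Site:
    """All annotated patterns of one sample quadrat.

    ``patterns`` maps morph label -> :class:`PointPattern`; every pattern
    shares the site's window. ``mask`` optionally classifies the substrate.
    """

    site_id: str
    patterns: dict
    window: Window = field(default_factory=Window)
    mask: Optional[CategoryMask] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for morph, pat in self.patterns.items():
            if pat.window != self.window:
                raise ValueError(
                    f"pattern {morph!r} of site {self.site_id!r} has a different window"
                )

    def counts(self) -> dict:
        return {m: p.n for m, p in self.patterns.items()}

    def analysable_morphs(self, min_points: int = MIN_ANALYSABLE_POINTS) -> list:
        """Morphs whose pattern meets the minimum-points rule."""
        return [m for m, p in self.patterns.items() if p.n >= min_points]
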
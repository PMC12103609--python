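"""Reading and writing annotation tables, substrate masks and result tables.

On-disk formats
---------------
* Annotations: UTF-8 comma-separated text with header columns
  ``site_id, morph, x_cm, y_cm`` ("." decimal separator). Annotation
  exports that use image-style y-down coordinates can be flipped at read
  time with ``flip_y=True``; exports with renamed columns are handled via
  the ``columns`` mapping.
* Substrate masks: PNG rasters whose pixel colours are keyed to substrate
  categories by a ``{"#RRGGBB": category}`` mapping (a YAML file or a dict).
* Summaries: one CSV row per site x morph with counts, densities, group
  label, model goodness-of-fit values and reproductive parameters.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import Window
from .masks import CATEGORIES, CategoryMask
from .patterns import MORPHS, PointPattern
from .site import Site

REQUIRED_COLUMNS = ("site_id", "morph", "x_cm", "y_cm")

#: Stable column order of the per-site/morph summary table.
SUMMARY_COLUMNS = [
    "site_id",
    "morph",
    "count",
    "density_per_m2",
    "group",
    "nn_median_cm",
    "best_model",
    "pd_csr",
    "pd_hp",
    "pd_tc_10",
    "pd_tc_20",
    "pd_htc",
    "kappa_per_cm2",
    "sigma_cm",
    "mu",
    "offspring_nonempty",
    "prob_in_cluster",
]


class FormatError(ValueError):
    """A required column or field is missing or malformed."""


class LabelError(ValueError):
    """A morph label outside the recognised set."""


class BoundsError(ValueError):
    """A coordinate outside the observation window."""


class MappingError(ValueError):
    """A raster colour with no category mapping and no fallback."""


def read_site_annotations(
    path: Union[str, Path],
    window: Optional[Window] = None,
    *,
    columns: Optional[Mapping[str, str]] = None,
    flip_y: bool = False,
) -> list:
    """Read an annotation CSV into a list of :class:`Site` objects.

    Parameters
    ----------
    path : str or Path
        Delimited text file with columns ``site_id, morph, x_cm, y_cm``.
    window : Window, optional
        Observation window shared by all sites (study default 175 x 175 cm).
    columns : mapping, optional
        Renames ``{file column name: canonical name}`` applied before
        validation, to tolerate foreign annotation schemas.
    flip_y : bool
        If True, interpret y as image-style (down from the top edge) and
        flip to the package's y-up convention at read time.

    Returns
    -------
    list of Site, in order of first appearance in the file.
    """
    window = window or Window()
    df = pd.read_csv(path, float_precision="round_trip")
    if columns:
        df = df.rename(columns=dict(columns))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    bad_morph = ~df["morph"].isin(MORPHS)
    if bad_morph.any():
        row = int(df.index[bad_morph][0])
        raise LabelError(
            f"{path}: row {row + 2}: morph {df['morph'].iloc[row]!r} "
            f"not in {set(MORPHS)}"
        )

    x = pd.to_numeric(df["x_cm"], errors="coerce").to_numpy()
    y = pd.to_numeric(df["y_cm"], errors="coerce").to_numpy()
    finite = np.isfinite(x) & np.isfinite(y)
    if not finite.all():
        row = int(np.flatnonzero(~finite)[0])
        raise FormatError(f"{path}: row {row + 2}: non-numeric coordinate")
    if flip_y:
        y = window.height - y
    inside = window.contains(x, y)
    if not inside.all():
        row = int(np.flatnonzero(~inside)[0])
        raise BoundsError(
            f"{path}: row {row + 2}: point ({x[row]:g}, {y[row]:g}) outside "
            f"the {window.width:g} x {window.height:g} cm window"
        )

    df = df.assign(x_cm=x, y_cm=y)
    sites = []
    for site_id, sdf in df.groupby("site_id", sort=False):
        patterns = {}
        for morph, mdf in sdf.groupby("morph", sort=False):
            coords = mdf[["x_cm", "y_cm"]].to_numpy(dtype=float)
            patterns[morph] = PointPattern(coords, window, morph)
        sites.append(Site(str(site_id), patterns, window))
    return sites


def write_site_annotations(sites: Iterable[Site], path: Union[str, Path]) -> None:
    """Write sites back to the annotation CSV format (lossless round trip)."""
    rows = []
    for site in sites:
        for morph, pat in site.patterns.items():
            for xy in pat.coords:
                rows.append((site.site_id, morph, repr(float(xy[0])), repr(float(xy[1]))))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False)


def _parse_colour(spec: str) -> tuple:
    s = spec.lstrip("#")
    if len(s) != 6:
        raise MappingError(f"colour {spec!r} is not a #RRGGBB hex triplet")
    return tuple(int(s[i : i + 2], 16) for i in (0, 2, 4))


def read_substrate_mask(
    path: Union[str, Path],
    colour_map: Union[Mapping[str, str], str, Path],
    window: Optional[Window] = None,
    *,
    fallback: Optional[str] = None,
) -> CategoryMask:
    """Read a PNG substrate raster into a :class:`CategoryMask`.

    ``colour_map`` maps ``"#RRGGBB"`` hex colours to category names (one of
    ``boulder``, ``flat``, ``gulley``), given directly or as a YAML file with
    optional key ``fallback``. Pixels whose colour has no mapping are
    assigned the fallback category, or rejected if none is declared. Image
    row 0 (top) is the top of the window; rows are flipped to the package's
    y-up grid convention.
    """
    window = window or Window()
    if not isinstance(colour_map, Mapping):
        with open(colour_map) as fh:
            cfg = yaml.safe_load(fh)
        fallback = cfg.pop("fallback", fallback)
        colour_map = cfg
    for cat in colour_map.values():
        if cat not in CATEGORIES:
            raise MappingError(f"unknown substrate category {cat!r}")
    if fallback is not None and fallback not in CATEGORIES:
        raise MappingError(f"unknown fallback category {fallback!r}")

    img = np.asarray(Image.open(path).convert("RGB"))
    h, w = img.shape[:2]
    ratio_img = w / h
    ratio_win = window.width / window.height
    if not math.isclose(ratio_img, ratio_win, rel_tol=0.05):
        raise FormatError(
            f"{path}: raster aspect ratio {ratio_img:.3f} does not match "
            f"window aspect ratio {ratio_win:.3f}"
        )

    codes = np.full((h, w), -1, dtype=np.int16)
    for colour, cat in colour_map.items():
        r, g, b = _parse_colour(colour)
        hit = (img[..., 0] == r) & (img[..., 1] == g) & (img[..., 2] == b)
        codes[hit] = CATEGORIES.index(cat)
    unmapped = codes < 0
    if unmapped.any():
        if fallback is None:
            ij = np.argwhere(unmapped)[0]
            rgb = tuple(int(v) for v in img[ij[0], ij[1]])
            raise MappingError(
                f"{path}: pixel {tuple(ij)} colour #%02x%02x%02x has no "
                "category mapping and no fallback is declared" % rgb
            )
        codes[unmapped] = CATEGORIES.index(fallback)
    # flip to y-up grid (row 0 = bottom)
    return CategoryMask(codes[::-1], window)


def write_summary_table(summaries, path: Union[str, Path]) -> pd.DataFrame:
    """Write per-site/morph summaries as a CSV with a stable column order.

    ``summaries`` is an iterable of dicts (or dataclasses with ``__dict__``)
    carrying :data:`SUMMARY_COLUMNS` keys; missing keys become NA.
    """
    rows = [s if isinstance(s, Mapping) else vars(s) for s in summaries]
    if not rows:
        raise ValueError("no summaries to write")
    df = pd.DataFrame(rows)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[SUMMARY_COLUMNS]
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def read_summary_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_curve_table(path: Union[str, Path], r, g_obs, env_lo=None, env_hi=None) -> None:
    """Write a PCF/envelope curve as CSV (columns r_cm, g_obs, env_lo, env_hi)."""
    data = {"r_cm": np.asarray(r, dtype=float), "g_obs": np.asarray(g_obs, dtype=float)}
    if env_lo is not None:
        data["env_lo"] = np.asarray(env_lo, dtype=float)
    if env_hi is not None:
        data["env_hi"] = np.asarray(env_hi, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
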
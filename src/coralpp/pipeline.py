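"""End-to-end study orchestration.

``run_study`` drives the full analysis: load (or simulate) annotated
sites, apply the minimum-points rule, assign community groups, and for
every analysable site x morph estimate the PCF, fit the candidate models,
run Monte Carlo envelopes and Diggle's goodness-of-fit, extract
reproductive-cluster parameters and nearest-neighbour summaries, and write
the result tables, curves, figures and a manifest.

Randomness is fanned out per (site, morph) from the one global seed, so
reordering or re-running sites cannot change any result.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .community import assign_groups, density
from .envelopes import GofSettings, evaluate_site_models
from .geometry import Window
from .io import (
    SUMMARY_COLUMNS,
    read_site_annotations,
    read_substrate_mask,
    write_curve_table,
    write_summary_table,
)
from .patterns import MIN_ANALYSABLE_POINTS, MORPHS
from .pcf import nearest_neighbour_distances
from .simulate import MORPH_CODE, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings of one study run (echoed verbatim into the manifest)."""

    input_dir: Optional[Union[str, Path]] = None
    scenario: Optional[dict] = None  # passed to generate_study when no input
    out_dir: Union[str, Path] = "results"
    n_sims: int = 199
    n_drop: Optional[int] = None
    seed: int = 0
    r_max: float = 50.0
    step: float = 0.1
    bandwidth: float = 5.0
    correction: str = "translation"
    fit_range: tuple = (0.1, 25.0)
    tc_gof_ranges: tuple = (10.0, 20.0)
    min_points: int = MIN_ANALYSABLE_POINTS
    make_figures: bool = True
    log_level: str = "INFO"
    window: Window = field(default_factory=Window)

    def settings_dict(self) -> dict:
        return {
            "n_sims": self.n_sims,
            "n_drop": self.n_drop,
            "seed": self.seed,
            "r_max": self.r_max,
            "step": self.step,
            "bandwidth": self.bandwidth,
            "correction": self.correction,
            "fit_range": list(self.fit_range),
            "tc_gof_ranges": list(self.tc_gof_ranges),
            "min_points": self.min_points,
            "window": [self.window.width, self.window.height],
        }


def filter_analysable(sites, min_points: int = MIN_ANALYSABLE_POINTS):
    """Apply the minimum-points rule per pattern.

    Returns ``(retained_sites, exclusion_log)``: morph patterns with fewer
    than ``min_points`` points are dropped (logged with their count), and
    sites left with no analysable pattern are excluded entirely.
    """
    retained, log = [], []
    for site in sites:
        keep = {}
        for morph, pat in site.patterns.items():
            if pat.n >= min_points:
                keep[morph] = pat
            else:
                log.append({"site_id": site.site_id, "morph": morph, "count": pat.n})
        if keep:
            site.patterns = dict(site.patterns)  # preserve raw counts in metadata
            site.metadata = dict(site.metadata, raw_counts=site.counts())
            site.patterns = keep
            retained.append(site)
        else:
            log.append(
                {"site_id": site.site_id, "morph": "(all)", "count": sum(site.counts().values())}
            )
    return retained, log


def _site_seed(global_seed: int, site_id: str, morph: str) -> int:
    """Derived integer substream seed for one site x morph analysis."""
    site_code = zlib.crc32(site_id.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([global_seed, site_code, MORPH_CODE.get(morph, 0)])
    return int(ss.generate_state(1)[0] >> 1)


def _load_sites(config: RunConfig):
    inp = Path(config.input_dir)
    sites = read_site_annotations(inp / "annotations.csv", config.window)
    colours = inp / "substrate_colours.yaml"
    masks_dir = inp / "masks"
    if colours.exists() and masks_dir.is_dir():
        for site in sites:
            png = masks_dir / f"{site.site_id}.png"
            if png.exists():
                site.mask = read_substrate_mask(png, colours, config.window)
    return sites


def run_study(config: RunConfig):
    """Run the whole study; returns the summary DataFrame (also on disk).

    Outputs under ``config.out_dir``: ``manifest.json``, ``summary.csv``,
    ``groups.csv``, ``exclusions.csv``, per-pattern curve CSVs under
    ``curves/`` and advisory figures under ``figures/``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "curves").mkdir(exist_ok=True)

    if config.input_dir is None:
        scenario = dict(config.scenario or {})
        scenario.setdefault("seed", config.seed)
        sim_dir = out / "input"
        logger.info("simulating synthetic study into %s", sim_dir)
        generate_study(sim_dir, window=config.window, **scenario)
        config.input_dir = sim_dir

    sites = _load_sites(config)
    if not sites:
        raise RuntimeError("no sites found in input")

    sites, exclusions = filter_analysable(sites, config.min_points)
    if not sites:
        raise RuntimeError("no analysable sites after the minimum-points rule")
    pd.DataFrame(exclusions, columns=["site_id", "morph", "count"]).to_csv(
        out / "exclusions.csv", index=False
    )

    compositions = {}
    for site in sites:
        raw = site.metadata.get("raw_counts", site.counts())
        compositions[site.site_id] = (raw.get("orange", 0), raw.get("pink", 0))
    if len(sites) >= 3:
        groups = assign_groups(compositions)
        group_of = groups.labels
    else:
        logger.warning("fewer than 3 sites; skipping group assignment")
        group_of = {s.site_id: "" for s in sites}
    pd.DataFrame(
        sorted(group_of.items()), columns=["site_id", "group"]
    ).to_csv(out / "groups.csv", index=False)

    rows = []
    for site in sites:
        for morph in sorted(site.patterns):
            t0 = time.perf_counter()
            pattern = site.patterns[morph]
            row = {
                "site_id": site.site_id,
                "morph": morph,
                "count": pattern.n,
                "density_per_m2": density(pattern.n, site.window),
                "group": group_of[site.site_id],
            }
            if pattern.n >= 2:
                row["nn_median_cm"] = float(np.median(nearest_neighbour_distances(pattern)))
            try:
                settings = GofSettings(
                    n_sims=config.n_sims,
                    n_drop=config.n_drop,
                    seed=_site_seed(config.seed, site.site_id, morph),
                    r_max=config.r_max,
                    step=config.step,
                    bandwidth=config.bandwidth,
                    correction=config.correction,
                    fit_range=config.fit_range,
                    tc_gof_ranges=config.tc_gof_ranges,
                )
                ev = evaluate_site_models(site, morph, settings)
            except Exception:
                logger.exception("site %s/%s failed; continuing", site.site_id, morph)
                rows.append(row)
                continue
            row["best_model"] = ev.best_model
            key_map = {"pd_csr": "CSR", "pd_hp": "HP", "pd_htc": "HTC"}
            for col, key in key_map.items():
                if key in ev.gof:
                    row[col] = ev.gof[key].p_d
            for r_hi in config.tc_gof_ranges:
                key = f"TC_{int(r_hi)}"
                if key in ev.gof:
                    row[f"pd_tc_{int(r_hi)}"] = ev.gof[key].p_d
            tc = ev.fits.get("TC")
            if tc is not None:
                row.update(
                    kappa_per_cm2=tc.kappa_,
                    sigma_cm=tc.sigma_,
                    mu=tc.mu_,
                    offspring_nonempty=tc.offspring_nonempty_,
                    prob_in_cluster=tc.prob_in_cluster_,
                )
            for name, env in ev.envelopes.items():
                write_curve_table(
                    out / "curves" / f"{site.site_id}_{morph}_{name}.csv",
                    ev.pcf.r,
                    ev.pcf.g,
                    env.lower,
                    env.upper,
                )
            rows.append(row)
            logger.info(
                "site %s/%s: n=%d best=%s (%.1fs)",
                site.site_id,
                morph,
                pattern.n,
                row.get("best_model", "-"),
                time.perf_counter() - t0,
            )

    summary = write_summary_table(rows, out / "summary.csv")

    from . import __version__ as pkg_version

    manifest = {
        "package": "coralpp",
        "version": pkg_version,
        "numpy": np.__version__,
        "settings": config.settings_dict(),
        "input": str(config.input_dir),
        "input_sha256": hashlib.sha256(
            (Path(config.input_dir) / "annotations.csv").read_bytes()
        ).hexdigest(),
        "n_sites": len(sites),
        "n_rows": len(rows),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    if config.make_figures:
        try:
            from . import plots

            plots.make_figures(summary, out)
        except Exception:
            logger.exception("figure generation failed (advisory only)")
    return summary
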
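"""End-to-end orchestration: simulate -> preprocess -> binarize -> quantify
-> annotate -> fit, as a configured, logged, reproducible run.

A run consumes exactly one input source (a simulation config or a fixture
directory), writes every stage output with checksums into the output
directory and, when the cohort is large enough, fits the statistical layer.
Grid mode evaluates all four compensation x radius combinations but never
mixes slab settings within one statistical fit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, stats
from .core import SLAB_10_AT_31, SLAB_20_AT_29
from .fd_quant import build_sector_table
from .synthetic_octa import SimulationConfig, read_fixture_set, simulate_cohort

log = logging.getLogger("ccfdq")

MIN_EYES_PER_GROUP_FOR_STATS = 10


@dataclass
class PipelineConfig:
    output_dir: Path
    simulation: SimulationConfig | None = None
    fixtures: Path | None = None
    compensate: bool = True
    radius: int | str = 15
    icd_um: float = 24.0
    grid: bool = False
    run_stats: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.fixtures is None):
            raise ValueError("exactly one input source: simulation config or fixture directory")
        if self.fixtures is not None and not Path(self.fixtures).exists():
            raise ValueError(f"fixture directory {self.fixtures} does not exist")
        if self.radius != "adjusted":
            self.radius = int(self.radius)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = io.read_yaml(path)
        sim = raw.pop("simulation", None)
        if sim is not None:
            slab = sim.pop("slab", "10@31")
            sim["slab"] = {"10@31": SLAB_10_AT_31, "20@29": SLAB_20_AT_29}[slab]
            for tup in ("ct_sector_means_um", "lcv_width_um_range"):
                if tup in sim:
                    sim[tup] = tuple(sim[tup])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError
        blob = json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stats_payload(sector_df: pd.DataFrame, eye_df: pd.DataFrame) -> dict:
    fd_res = stats.fit_fd_mixed_model(sector_df)
    lcv_res = stats.fit_lcv_models(sector_df)
    cct_res = stats.fit_eye_level_logistic(eye_df, "cct")
    cut = stats.youden_cutoff(sector_df["ct_um"], sector_df["lcv"], sector_df["eye_id"])
    payload = {
        "fd_mixed_model": {
            "contrasts": fd_res.contrasts.reset_index().to_dict(orient="records"),
            "random_intercept_var": fd_res.random_intercept_var,
            "residual_var": fd_res.residual_var,
            "n_obs": fd_res.n_obs,
            "n_eyes": fd_res.n_eyes,
        },
        "lcv_models": {
            key: {
                "terms": {n: dataclasses.asdict(t) for n, t in res.terms.items()},
                "random_intercept_sd": res.random_intercept_sd,
                "n_obs": res.n_obs,
                "n_patients": res.n_patients,
                "separation": res.separation,
            }
            for key, res in lcv_res.items()
        },
        "eye_level_cct": {n: dataclasses.asdict(t) for n, t in cct_res.terms.items()},
        "ct_cutoff": dataclasses.asdict(cut),
    }
    return payload


def _report_text(payload: dict) -> str:
    lines = ["Choriocapillaris FD% / LCV analysis", "=" * 40, ""]
    fd = payload["fd_mixed_model"]
    lines.append(f"FD% mixed model: n={fd['n_obs']} sectors of {fd['n_eyes']} eyes")
    for c in fd["contrasts"]:
        lines.append(
            f"  {c['label']}: {c['estimate']:+.2f} FD% "
            f"[{c['ci_low_adj']:.2f}; {c['ci_high_adj']:.2f}] adj p={c['p_adj']:.4g}"
        )
    lines.append("")
    for key, m in payload["lcv_models"].items():
        for name, t in m["terms"].items():
            lines.append(
                f"LCV visibility ({key}, {name}): OR {t['odds_ratio']:.3f} "
                f"[{t['ci_low']:.3f}; {t['ci_high']:.3f}] p={t['p']:.4g} (n={m['n_obs']})"
            )
    for name, t in payload["eye_level_cct"].items():
        lines.append(
            f"LCV in >=1 sector vs {name}: OR {t['odds_ratio']:.3f} "
            f"[{t['ci_low']:.3f}; {t['ci_high']:.3f}] p={t['p']:.4g}"
        )
    cut = payload["ct_cutoff"]
    lines.append(
        f"Youden CT cutoff: <= {cut['threshold_um']:.0f} um, "
        f"sensitivity {100 * cut['sensitivity']:.0f}% "
        f"[{100 * cut['sensitivity_ci'][0]:.0f}; {100 * cut['sensitivity_ci'][1]:.0f}], "
        f"specificity {100 * cut['specificity']:.0f}% "
        f"[{100 * cut['specificity_ci'][0]:.0f}; {100 * cut['specificity_ci'][1]:.0f}]"
    )
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulation is not None:
        log.info("simulating cohort of %d eyes", config.simulation.n_eyes)
        scenes = simulate_cohort(config.simulation)
    else:
        scenes = read_fixture_set(Path(config.fixtures))

    quant = dict(compensate=config.compensate, radius=config.radius, icd_um=config.icd_um)
    sector_df, eye_df = build_sector_table(scenes, **quant)
    sector_df.to_csv(out / "sectors.csv", index=False)
    eye_df.to_csv(out / "eyes.csv", index=False)
    written = ["sectors.csv", "eyes.csv"]

    if config.grid:
        frames = []
        for comp, rad in product((True, False), (15, "adjusted")):
            sdf, _ = build_sector_table(scenes, compensate=comp, radius=rad, icd_um=config.icd_um)
            sdf["compensated"] = comp
            sdf["radius"] = str(rad)
            frames.append(sdf)
        pd.concat(frames).to_csv(out / "grid.csv", index=False)
        written.append("grid.csv")

    stats_done = False
    if config.run_stats:
        per_group = sector_df.groupby("group")["eye_id"].nunique()
        n_min = int(per_group.reindex(["control", "iamd"]).fillna(0).min())
        if n_min < MIN_EYES_PER_GROUP_FOR_STATS:
            log.warning(
                "cohort too small for stable model fits (%d eyes in the smaller group); "
                "skipping the statistics stage",
                n_min,
            )
        else:
            payload = _stats_payload(sector_df, eye_df)
            io.write_json(out / "results.json", payload)
            (out / "report.txt").write_text(_report_text(payload))
            written += ["results.json", "report.txt"]
            stats_done = True

    manifest = {
        "config_hash": config.config_hash(),
        "seed": None if config.simulation is None else config.simulation.seed,
        "n_eyes": len(scenes),
        "stats": stats_done,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "files": {name: {"sha256": io.sha256_file(out / name)} for name in written},
    }
    io.write_json(out / "manifest.json", manifest)
    return manifest
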
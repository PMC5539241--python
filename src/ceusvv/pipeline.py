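"""End-to-end seeded experiment: simulate -> extract -> quantify -> stats.

A run is configured by :class:`RunConfig`, executed by
:func:`run_experiment`, and described by a :class:`RunManifest` recording
the config hash, seed, software version and per-stage outputs.  The same
config and seed reproduce byte-identical tabular outputs: the cohort and
truth tables are written at full float precision (so a CSV round trip is
exact) and the derived report tables at 9 significant digits.

One global seed fans out to per-stage child seeds by hashing the stage name
together with the seed (:func:`derive_seed`), so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import StageError
from .imaging import save_cine, save_rois, save_tics, smooth_tic, estimate_background
from .quantify import (
    AnimalRecord,
    build_cohort_table,
    compute_mve,
    normalized_mve,
    write_cohort,
)
from .stats import CohortReport, group_comparison_report
from .synth import (
    CohortConfig,
    CohortSimulation,
    default_cohort_config,
    default_phantom,
    default_rois,
    simulate_cohort,
)

logger = logging.getLogger("ceusvv")

__all__ = [
    "RunConfig",
    "RunManifest",
    "derive_seed",
    "run_experiment",
    "make_fixtures",
    "write_report",
]

REPORT_FLOAT_FORMAT = "%.9g"


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: SHA-256 of ``"<seed>:<stage>"``
    reduced modulo 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full experiment run."""

    cohort: CohortConfig
    out_dir: Path
    seed: int = 0
    render: str = "tics"
    smooth_window: int = 1
    normalization: str = "subtracted"
    control_group: int = 0
    write_cine: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["out_dir"] = str(self.out_dir)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str]
    started: str
    finished: str

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _quantify_animals(sim: CohortSimulation, smooth_window: int, variant: str) -> pd.DataFrame:
    """Re-quantify simulated animals with explicit smoothing/normalization."""
    records = []
    dt = sim.config.destruction_time
    for a in sim.animals:
        nmve = None
        occlusive = any(
            g.plaque_occlusive for g in sim.config.groups if g.group_id == a.group_id
        )
        if not occlusive:
            mves = {}
            for name in ("adventitia", "lumen"):
                tic = a.tics[name]
                if smooth_window > 1:
                    tic = smooth_tic(tic, smooth_window)
                bg = estimate_background(tic, destruction_time=dt)
                mves[name] = compute_mve(tic, bg)
            nmve = normalized_mve(mves["adventitia"], mves["lumen"], variant).value
        records.append(
            AnimalRecord(
                animal_id=a.animal_id,
                group_id=a.group_id,
                nmve=nmve,
                cd31_mean=a.cd31.mean,
                vegf_mean=a.vegf.mean,
            )
        )
    return build_cohort_table(records)


def write_report(report: CohortReport, out_dir: Path, prefix: str = "") -> dict[str, str]:
    """Write a cohort report as CSVs plus a JSON summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("group_summary", report.summaries),
        ("pairwise", report.pairwise),
        ("correlations", report.correlations),
    ):
        p = out_dir / f"{prefix}{name}.csv"
        df.to_csv(p, index=False, float_format=REPORT_FLOAT_FORMAT)
        paths[name] = str(p)
    p = out_dir / f"{prefix}report.json"
    p.write_text(json.dumps(report.to_dict(), indent=1))
    paths["report"] = str(p)
    return paths


def run_experiment(config: RunConfig) -> RunManifest:
    """Execute all stages in order, failing fast with the stage name.

    Writes ``cohort.csv``, ``truth.csv``, the report CSVs/JSON and
    ``manifest.json`` under ``config.out_dir``; optionally the cine loops or
    cached TICs under ``cine/``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    outputs: dict[str, str] = {}

    stage = "simulate"
    try:
        logger.info("stage %s", stage)
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=derive_seed(config.seed, stage)
        )
        sim = simulate_cohort(cohort_cfg, render=config.render)
    except Exception as exc:  # noqa: BLE001 - fail fast with stage name
        raise StageError(stage, exc) from exc

    stage = "extract"
    try:
        logger.info("stage %s", stage)
        if config.write_cine:
            cine_dir = out_dir / "cine"
            cine_dir.mkdir(exist_ok=True)
            for a in sim.animals:
                if a.loop is not None:
                    save_cine(a.loop, cine_dir / f"{a.animal_id}.tif")
                save_tics(list(a.tics.values()), cine_dir / f"{a.animal_id}_tics.csv")
            outputs["cine_dir"] = str(cine_dir)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "quantify"
    try:
        logger.info("stage %s", stage)
        if config.smooth_window > 1 or config.normalization != "subtracted":
            cohort = _quantify_animals(sim, config.smooth_window, config.normalization)
        else:
            cohort = sim.cohort
        cohort_path = out_dir / "cohort.csv"
        write_cohort(cohort, cohort_path)
        truth_path = out_dir / "truth.csv"
        sim.truth.to_csv(truth_path, index=False)
        outputs["cohort"] = str(cohort_path)
        outputs["truth"] = str(truth_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "stats"
    try:
        logger.info("stage %s", stage)
        report = group_comparison_report(cohort, control_group=config.control_group)
        outputs.update(write_report(report, out_dir))
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        version=__version__,
        outputs=outputs,
        started=started,
        finished=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit the tiny deterministic fixture set used by the test suite.

    A noiseless 16x16 cine loop with known kinetics (plus its closed-form
    luminal curve), a labelled ROI file, and a 12-row cohort table (two
    animals in each of the six groups).  Everything regenerates identically
    for a fixed seed in well under five seconds.
    """
    from .kinetics import KineticsParams, replenishment_intensity
    from .synth import PhantomGeometry, render_cine_loop

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    geom = PhantomGeometry(
        image_height=16,
        image_width=16,
        lumen_band=(6, 10),
        adventitia_bands=((3, 5), (11, 13)),
    )
    lumen_k = KineticsParams(baseline=10.0, amplitude=40.0, rate=0.5, onset_time=1.0)
    adv_k = KineticsParams(baseline=10.0, amplitude=16.0, rate=0.5, onset_time=1.0)
    loop = render_cine_loop(
        geom,
        lumen_k,
        adv_k,
        noise_sd=0.0,
        frame_rate=5.0,
        duration=4.0,
        background_level=10.0,
    )
    cine_path = out_dir / "fixture_cine.tif"
    save_cine(loop, cine_path)
    paths["cine"] = cine_path

    curve = replenishment_intensity(lumen_k, loop.timestamps)
    curve_path = out_dir / "fixture_lumen_curve.csv"
    pd.DataFrame({"time_s": loop.timestamps, "intensity": curve}).to_csv(
        curve_path, index=False
    )
    paths["lumen_curve"] = curve_path

    from .imaging import RoiPolygon

    rois = [
        RoiPolygon("lumen", np.array([[1.0, 6.0], [15.0, 6.0], [15.0, 10.0], [1.0, 10.0]])),
        RoiPolygon("adventitia", np.array([[1.0, 3.0], [15.0, 3.0], [15.0, 5.0], [1.0, 5.0]])),
    ]
    roi_path = out_dir / "fixture_rois.json"
    save_rois(rois, roi_path)
    paths["rois"] = roi_path

    cfg = default_cohort_config(
        n_per_group=2, seed=derive_seed(seed, "fixtures"), duration=10.0
    )
    sim = simulate_cohort(cfg, render="tics")
    cohort_path = out_dir / "fixture_cohort.csv"
    write_cohort(sim.cohort, cohort_path)
    paths["cohort"] = cohort_path
    return paths
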
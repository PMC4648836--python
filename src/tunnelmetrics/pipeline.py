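"""End-to-end workflows: simulate -> segment -> measure -> report.

``run_simulated_study`` is the desk-scale analogue of the clinical study
loop: generate a cohort of CT phantoms with known drill diameters, segment
each, run all four measurement methods, and summarize per-method agreement
with the drill sizes (ICC, classification, mean ± SD difference).
``run_measurement`` applies the same segmentation + measurement stages to a
real volume from disk.

Runs are reproducible: all randomness flows from ``RunConfig.seed``, the
config is serialized verbatim into the output directory, and rerunning with
the same config yields bit-identical CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, measure, phantom, segmentation
from .volume import BinaryMask, CTVolume, read_volume, write_mask, write_volume

__all__ = ["RunConfig", "run_simulated_study", "run_measurement", "measure_tunnel"]

logger = logging.getLogger("tunnelmetrics")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Flat, self-documenting run configuration (serialized to JSON)."""

    # simulation
    n_tunnels: int = 24
    diameter_grid: tuple[float, ...] = phantom.DIAMETER_GRID_MM
    tunnel_length_mm: float = 30.0
    blur_sigma_voxels: float = 0.6
    noise_sd: float = 20.0
    # segmentation
    threshold_low: float = 150.0
    threshold_high: float = float("inf")
    closing_radius_mm: float = 6.0
    smooth_sigma_voxels: float = 0.5
    # measurement
    station: float = 0.5
    exclusion_radius_mm: float = 1.0
    n_slabs: int = 20
    width_mode: str = "min_feret"
    cylinder_end_trim_mm: float = 4.0
    # reproducibility / output
    seed: int = 0
    save_volumes: bool = True
    save_meshes: bool = True
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.n_tunnels < 2:
            raise ValueError("n_tunnels must be >= 2")
        if not self.diameter_grid:
            raise ValueError("diameter_grid must not be empty")
        if not 0 < self.station < 1:
            raise ValueError("station must be in (0, 1)")
        if self.threshold_low >= self.threshold_high:
            raise ValueError("threshold_low must be < threshold_high")
        self.diameter_grid = tuple(float(d) for d in self.diameter_grid)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["threshold_high"] = None if np.isinf(self.threshold_high) else self.threshold_high
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("threshold_high") is None:
            d["threshold_high"] = float("inf")
        d.pop("schema_version", None)
        if "diameter_grid" in d:
            d["diameter_grid"] = tuple(d["diameter_grid"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def _setup_run_dir(out_dir: str | Path, config: RunConfig, timestamped: bool) -> Path:
    out = Path(out_dir)
    if timestamped:
        out = out / time.strftime("run-%Y%m%d-%H%M%S")
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("config hash %s", config.config_hash)
    return out


def measure_tunnel(
    volume: CTVolume,
    seed_point_mm,
    config: RunConfig,
    truth: phantom.GroundTruth | None = None,
    tunnel_id: str = "tunnel",
) -> tuple[list[measure.MeasurementRecord], BinaryMask, object]:
    """Segment one tunnel and run all four methods.

    Returns (records, cavity mask, wall mesh)."""
    bone = segmentation.threshold_segment(volume, config.threshold_low, config.threshold_high)
    cavity = segmentation.extract_tunnel_cavity(bone, config.closing_radius_mm, seed_point_mm)
    mesh = segmentation.mask_to_mesh(cavity, smooth_sigma_voxels=config.smooth_sigma_voxels)
    records = measure.measure_all(
        mesh, cavity, truth=truth, tunnel_id=tunnel_id,
        station=config.station, exclusion_radius_mm=config.exclusion_radius_mm,
        n_slabs=config.n_slabs, width_mode=config.width_mode,
        cylinder_end_trim_mm=config.cylinder_end_trim_mm,
    )
    return records, cavity, mesh


def _write_measurements(frame: pd.DataFrame, out: Path) -> None:
    """CSV rounded to 0.01 mm (far below voxel size); JSON keeps full
    precision."""
    rounded = frame.copy()
    for col in ("diameter_mm", "error_mm"):
        if col in rounded:
            rounded[col] = rounded[col].round(2)
    rounded.to_csv(out / "measurements.csv", index=False)
    (out / "measurements.json").write_text(
        json.dumps(frame.to_dict(orient="records"), indent=2, sort_keys=True)
    )


def run_simulated_study(
    config: RunConfig | None = None,
    out_dir: str | Path = "tunnelmetrics-out",
    timestamped: bool = False,
) -> dict:
    """The full simulated study: phantom cohort -> segmentation -> four
    measurement methods -> per-method agreement report vs drill sizes.

    Per-tunnel failures are recorded and the run continues.  Returns a dict
    with the output directory, the measurement frame and the report frame.
    """
    config = config or RunConfig()
    out = _setup_run_dir(out_dir, config, timestamped)
    t0 = time.perf_counter()

    cohort, manifest = phantom.make_cohort(
        n_tunnels=config.n_tunnels,
        diameter_grid=config.diameter_grid,
        spec_template=phantom.PhantomSpec(
            tunnel_length_mm=config.tunnel_length_mm,
            blur_sigma_voxels=config.blur_sigma_voxels,
            noise_sd=config.noise_sd,
        ),
        seed=config.seed,
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    logger.info("cohort of %d phantoms generated in %.1fs", len(cohort), time.perf_counter() - t0)

    all_records: list[measure.MeasurementRecord] = []
    for vol, truth in cohort:
        t1 = time.perf_counter()
        try:
            if config.save_volumes:
                write_volume(vol, out / f"{truth.tunnel_id}.nii.gz")
                truth.to_json(out / f"{truth.tunnel_id}.truth.json")
            records, cavity, mesh = measure_tunnel(
                vol, truth.axis_point_mm, config, truth=truth, tunnel_id=truth.tunnel_id
            )
            if config.save_meshes:
                mesh.save(out / f"{truth.tunnel_id}.stl")
            all_records.extend(records)
            for r in records:
                logger.info("%s %s -> %s mm", truth.tunnel_id, r.method.value,
                            "FAIL" if not r.ok else f"{r.diameter_mm:.3f}")
        except Exception as exc:
            logger.error("tunnel %s failed outright: %s", truth.tunnel_id, exc)
            for m in measure.Method:
                all_records.append(measure.MeasurementRecord(
                    truth.tunnel_id, m, None, diagnostics={"error": str(exc)}))
        logger.info("tunnel %s done in %.1fs", truth.tunnel_id, time.perf_counter() - t1)

    frame = measure.records_to_frame(all_records)
    _write_measurements(frame, out)

    truths = {t.tunnel_id: t.true_diameter_mm for _, t in cohort}
    report = agreement.agreement_report(frame, truths)
    agreement.write_report(report, out / "agreement.csv", out / "agreement.json")
    logger.info("study complete in %.1fs", time.perf_counter() - t0)
    _teardown_logging()
    return {"out_dir": out, "measurements": frame, "report": report, "truths": truths}


def run_measurement(
    volume_path: str | Path,
    seed_point_mm,
    config: RunConfig | None = None,
    out_dir: str | Path = "tunnelmetrics-out",
    drill_record_csv: str | Path | None = None,
    tunnel_id: str = "tunnel",
) -> dict:
    """Measure a real (or on-disk phantom) volume: segment, mesh, measure.

    An agreement/difference stage runs only when a drill-record CSV
    (columns: tunnel_id, drill_diameter_mm) is supplied."""
    config = config or RunConfig()
    if seed_point_mm is None:
        raise ValueError("a seed point (mm, inside the tunnel) is required")
    out = _setup_run_dir(out_dir, config, timestamped=False)
    volume = read_volume(volume_path)

    records, cavity, mesh = measure_tunnel(volume, seed_point_mm, config, tunnel_id=tunnel_id)
    if config.save_meshes:
        mesh.save(out / f"{tunnel_id}.stl")
        write_mask(cavity, out / f"{tunnel_id}.cavity.nii.gz")
    frame = measure.records_to_frame(records)
    _write_measurements(frame, out)

    result = {"out_dir": out, "measurements": frame}
    if drill_record_csv is not None:
        drills = pd.read_csv(drill_record_csv)
        truths = dict(zip(drills["tunnel_id"].astype(str), drills["drill_diameter_mm"]))
        ok = frame.dropna(subset=["diameter_mm"])
        if tunnel_id in truths and len(ok):
            diffs = ok["diameter_mm"] - truths[tunnel_id]
            summary = pd.DataFrame({
                "method": ok["method"], "diameter_mm": ok["diameter_mm"],
                "drill_mm": truths[tunnel_id], "diff_mm": diffs,
            })
            summary.to_csv(out / "difference.csv", index=False, float_format="%.4f")
            result["differences"] = summary
    _teardown_logging()
    return result


def _teardown_logging() -> None:
    for h in list(logger.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            logger.removeHandler(h)
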
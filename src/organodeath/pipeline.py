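"""End-to-end orchestration: segment -> gate -> load stats -> plate QC.

``run_pipeline`` binds the stages together for one experiment, writes
every stage's table as CSV (stamped with the config hash and seed) and a
provenance log; each stage remains usable on its own.  A stage failure
raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .gating import DeathGater, summarize_death, validate_positive_control
from .imaging import (
    ImageStack,
    NucleusSegmenter,
    OrganoidSegmenter,
    SegmentationResult,
    quantify_well,
    segment_stack,
)
from .io import PlateMap, RunConfig, read_stack, write_table
from .load import LOAD_METRICS, dose_response_comparisons, wells_to_frame
from .viability import compute_qc

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "load_stacks"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """All tables produced by one run."""

    organoids: pd.DataFrame
    nuclei: pd.DataFrame
    gating_model: DeathGater | None
    death_counts: pd.DataFrame
    well_loads: pd.DataFrame
    growth_comparisons: pd.DataFrame
    plate_qc: pd.DataFrame | None
    positive_control: dict | None
    provenance: dict = field(default_factory=dict)


def load_stacks(image_dir: str | Path) -> dict[str, list[ImageStack]]:
    """Read every ``*.tif`` under a directory into per-well stack lists."""
    stacks: dict[str, list[ImageStack]] = {}
    for path in sorted(Path(image_dir).glob("*.tif")):
        stack = read_stack(path)
        stacks.setdefault(stack.well_id, []).append(stack)
    if not stacks:
        raise FileNotFoundError(f"no .tif stacks under {image_dir}")
    return stacks


def _pkg_version() -> str:
    try:
        return version("organodeath")
    except PackageNotFoundError:  # pragma: no cover - editable quirk
        return "unknown"


def run_pipeline(
    config: RunConfig,
    stacks: dict[str, list[ImageStack]] | str | Path,
    platemap: PlateMap,
    readings: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis for one experiment.

    Parameters
    ----------
    stacks:
        Mapping well id -> list of ImageStack (one per field), or a
        directory of TIFF stacks written by :func:`organodeath.io.write_stack`.
    platemap:
        Must contain a ``day`` column so day-0/day-10 control wells can
        be identified for gating calibration and growth normalization.
    readings:
        Optional whole-well viability table (well, day, reading); when
        omitted the plate-QC stage is skipped.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": _pkg_version(),
        "stages": [],
    }

    if not isinstance(stacks, dict):
        stacks = load_stacks(stacks)
    pm = platemap.table.set_index("well")
    if "day" not in pm.columns:
        raise PipelineError("segment", ValueError("plate map needs a 'day' column"))

    # -- segmentation ------------------------------------------------------
    try:
        oseg = OrganoidSegmenter(
            gaussian_sigma=config.gaussian_sigma,
            closing_radius=config.closing_radius,
            resize_radius=config.resize_radius,
            min_area=config.min_area,
        )
        nseg = NucleusSegmenter(
            gaussian_sigma=config.nucleus_sigma,
            min_distance=config.nucleus_min_distance,
        )
        per_well: dict[str, list[SegmentationResult]] = {}
        organoid_tables, nucleus_tables = [], []
        for well_id in sorted(stacks):
            results = []
            for stack in stacks[well_id]:
                res = segment_stack(stack, oseg, nseg, combine_mode=config.combine_mode)
                results.append(res)
                organoid_tables.append(res.organoids)
                nucleus_tables.append(res.nuclei.assign(field_id=stack.field_id))
            per_well[well_id] = results
        organoid_tables = [t for t in organoid_tables if not t.empty]
        nucleus_tables = [t for t in nucleus_tables if not t.empty]
        organoids = pd.concat(organoid_tables, ignore_index=True) if organoid_tables else pd.DataFrame()
        nuclei = pd.concat(nucleus_tables, ignore_index=True) if nucleus_tables else pd.DataFrame()
        write_table(organoids, out / "organoids.csv", config)
        write_table(nuclei, out / "nuclei.csv", config)
        provenance["stages"].append("segment")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("segment", exc) from exc

    # -- gating ------------------------------------------------------------
    gater: DeathGater | None = None
    death_counts = pd.DataFrame()
    positive_control = None
    try:
        def nuclei_of(roles: tuple[str, ...], day: int) -> pd.DataFrame:
            wells = pm[(pm["control_role"].isin(roles)) & (pm["day"] == day)].index
            return nuclei[nuclei["well_id"].isin(wells)] if not nuclei.empty else nuclei

        day0_ctrl = nuclei_of(("untreated",), 0)
        if len(day0_ctrl) >= 2:
            gater = DeathGater(
                scale=config.intensity_scale,
                theta_apoptotic=config.theta_apoptotic,
                theta_necrotic=config.theta_necrotic,
                calibrate_angles=config.calibrate_angles,
            )
            day10_ctrl = nuclei_of(("untreated",), 10)
            gater.fit(day0_ctrl, day10_ctrl if len(day10_ctrl) else None)
            rows = []
            for well_id, group in nuclei.groupby("well_id"):
                counts = summarize_death(group, gater, well_id=str(well_id))
                rows.append(counts.as_dict())
            death_counts = pd.DataFrame(rows)
            (out / "gating_model.json").write_text(
                json.dumps(gater.to_dict(), indent=2) + "\n"
            )
            write_table(death_counts, out / "death_counts.csv", config)
            stauro_wells = {
                w: nuclei[nuclei["well_id"] == w]
                for w in pm[pm["control_role"] == "staurosporine"].index
                if (nuclei["well_id"] == w).any()
            }
            untreated_wells = {
                w: nuclei[nuclei["well_id"] == w]
                for w in pm[(pm["control_role"] == "untreated") & (pm["day"] == 10)].index
                if (nuclei["well_id"] == w).any()
            }
            if stauro_wells and untreated_wells:
                ok, fracs = validate_positive_control(
                    stauro_wells, untreated_wells, gater,
                    margin=config.positive_control_margin,
                )
                positive_control = {"passed": bool(ok), **fracs}
            provenance["stages"].append("gate")
            provenance["gating_model"] = gater.to_dict()
        else:
            provenance["stages"].append("gate:skipped (no day-0 control nuclei)")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gate", exc) from exc

    # -- organoid load -----------------------------------------------------
    try:
        loads = []
        for well_id, results in per_well.items():
            geometry = stacks[well_id][0].geometry
            wl = quantify_well(
                results,
                geometry,
                well_id=well_id,
                day=int(pm.loc[well_id, "day"]) if well_id in pm.index else None,
            )
            d = wl.as_dict()
            if well_id in pm.index:
                d["dose"] = float(pm.loc[well_id, "dose"])
                d["control_role"] = pm.loc[well_id, "control_role"]
            loads.append(d)
        well_loads = pd.DataFrame(loads)
        write_table(well_loads, out / "well_loads.csv", config)
        comparisons = []
        if {"dose", "control_role", "day"} <= set(well_loads.columns):
            has_day0 = ((well_loads["day"] == 0) & (well_loads["control_role"] == "untreated")).any()
            has_day10 = ((well_loads["day"] == 10) & (well_loads["control_role"] == "untreated")).any()
            has_treated = (well_loads["control_role"] == "none").any()
            if has_day0 and has_day10 and has_treated:
                for metric in LOAD_METRICS:
                    comparisons.append(
                        dose_response_comparisons(well_loads, metric=metric)
                    )
        growth_comparisons = (
            pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
        )
        write_table(growth_comparisons, out / "growth_comparisons.csv", config)
        provenance["stages"].append("load-stats")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load-stats", exc) from exc

    # -- plate QC (optional) ----------------------------------------------
    qc_frame = None
    if readings is not None:
        try:
            annotated = (
                platemap.join_readings(readings)
                if "control_role" not in readings.columns
                else readings
            )
            qc = compute_qc(annotated, thresholds=config.qc_thresholds())
            qc_frame = pd.DataFrame([qc.as_dict()])
            write_table(qc_frame, out / "plate_qc.csv", config)
            (out / "plate_qc.txt").write_text(qc.summary() + "\n")
            provenance["stages"].append("plate-qc")
            provenance["plate_qc_passed"] = bool(qc.passed)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("plate-qc", exc) from exc

    if positive_control is not None:
        provenance["positive_control"] = positive_control
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        organoids=organoids,
        nuclei=nuclei,
        gating_model=gater,
        death_counts=death_counts,
        well_loads=well_loads,
        growth_comparisons=growth_comparisons,
        plate_qc=qc_frame,
        positive_control=positive_control,
        provenance=provenance,
    )
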
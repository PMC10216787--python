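"""File formats, configuration and provenance.

TIFF dialect: one multi-page file per field, pages ordered channel-major
(all planes of Hoechst, then Caspase 3/7 Green, then PI) with a JSON
sidecar for the acquisition geometry — readable by any TIFF viewer
without OME-XML machinery.  Plate maps and all result tables are plain
CSV; every table written through :func:`write_table` carries the run's
config hash and seed so outputs are traceable and reruns comparable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionGeometry
from .imaging import CHANNEL_NAMES, ImageStack
from .synth import CONTROL_ROLES

__all__ = [
    "PlateMap",
    "read_platemap",
    "RunConfig",
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
]

PLATEMAP_COLUMNS = ("well", "treatment", "dose", "control_role")
_WELL_PATTERN = r"^[A-P](?:[1-9]|1[0-9]|2[0-4])$"


@dataclass(frozen=True)
class PlateMap:
    """Validated well -> treatment/dose/control-role mapping for one plate."""

    plate_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PLATEMAP_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"plate map missing columns: {sorted(missing)}")
        wells = self.table["well"]
        dup = wells[wells.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate wells in plate map: {dup}")
        bad = wells[~wells.str.match(_WELL_PATTERN)].tolist()
        if bad:
            raise ValueError(f"malformed well names: {bad}")
        unknown = set(self.table["control_role"]) - set(CONTROL_ROLES)
        if unknown:
            raise ValueError(f"unknown control roles: {sorted(unknown)}")
        if (self.table["dose"].astype(float) < 0).any():
            raise ValueError("doses must be non-negative")
        # every treated well's vehicle must exist among the plate's controls
        if "vehicle" in self.table.columns:
            treated = self.table[self.table["control_role"] == "none"]
            roles = set(self.table["control_role"])
            for v in treated["vehicle"].dropna().unique():
                if v and f"vehicle_{v}" not in roles:
                    raise ValueError(
                        f"treated wells declare vehicle {v!r} but the plate "
                        f"has no vehicle_{v} control wells"
                    )

    def wells(self, control_role: str | None = None) -> list[str]:
        t = self.table
        if control_role is not None:
            t = t[t["control_role"] == control_role]
        return t["well"].tolist()

    def join_readings(self, readings: pd.DataFrame) -> pd.DataFrame:
        """Annotate a (well, day, reading) table with the plate-map columns."""
        cols = [c for c in self.table.columns if c not in readings.columns or c == "well"]
        return readings.merge(self.table[cols], on="well", how="left", validate="m:1")

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def read_platemap(path: str | Path, plate_id: str | None = None) -> PlateMap:
    """Read and validate a plate-map CSV (well, treatment, dose, control_role)."""
    path = Path(path)
    table = pd.read_csv(path)
    if "control_role" in table.columns:
        table["control_role"] = table["control_role"].fillna("none")
    return PlateMap(plate_id=plate_id or path.stem, table=table)


@dataclass
class RunConfig:
    """All tunable parameters of one end-to-end run.

    Round-trips losslessly through JSON; ``config_hash`` fingerprints
    the parameter set (not the inputs) for provenance stamping.
    """

    # segmentation
    gaussian_sigma: float = 2.0
    closing_radius: int = 2
    resize_radius: int = 2
    min_area: float = 250.0
    nucleus_sigma: float = 2.0
    nucleus_min_distance: int = 5
    channel_order: tuple[str, ...] = CHANNEL_NAMES
    pixel_size: float = 0.3
    combine_mode: str = "sum"
    # gating
    intensity_scale: str = "linear"
    theta_apoptotic: float = 60.0
    theta_necrotic: float = 30.0
    calibrate_angles: bool = False
    positive_control_margin: float = 0.2
    # QC thresholds
    growth_threshold: float = 1.5
    cv_threshold: float = 0.22
    z_threshold: float = 0.4
    dmso_bounds: tuple[float, float] = (0.8, 1.2)
    # misc
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        self.channel_order = tuple(self.channel_order)
        self.dmso_bounds = tuple(self.dmso_bounds)
        for name in ("growth_threshold", "cv_threshold", "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.channel_order) != set(CHANNEL_NAMES):
            raise ValueError(f"channel_order must be a permutation of {CHANNEL_NAMES}")

    def qc_thresholds(self) -> dict:
        return {
            "growth_ratio": self.growth_threshold,
            "cv": self.cv_threshold,
            "z_factor": self.z_threshold,
            "dmso_effect": self.dmso_bounds,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a 3-channel z-stack as channel-major multi-page TIFF + sidecar."""
    path = Path(path)
    pages = np.concatenate([stack.channels[c] for c in CHANNEL_NAMES], axis=0)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {
        "channels": list(CHANNEL_NAMES),
        "well_id": stack.well_id,
        "field_id": stack.field_id,
        "geometry": asdict(stack.geometry),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (sidecar required)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    geometry = AcquisitionGeometry(**sidecar["geometry"])
    pages = tifffile.imread(path)
    n = geometry.n_planes
    if pages.shape[0] != 3 * n:
        raise ValueError(
            f"{path} has {pages.shape[0]} pages; geometry expects {3 * n}"
        )
    order = sidecar.get("channels", list(CHANNEL_NAMES))
    chans = {name: pages[i * n : (i + 1) * n] for i, name in enumerate(order)}
    return ImageStack(
        hoechst=chans["hoechst"],
        caspase=chans["caspase"],
        pi=chans["pi"],
        geometry=geometry,
        well_id=sidecar.get("well_id", ""),
        field_id=int(sidecar.get("field_id", 0)),
    )


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a result table, stamping config hash and seed columns."""
    out = df.copy()
    if config is not None:
        out["config_hash"] = config.config_hash
        out["seed"] = config.seed
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
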
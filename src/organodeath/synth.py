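"""Ground-truth-labelled synthetic data for the organoid imaging pipeline.

Three generators live here:

``make_scene`` / ``render_scene``
    Build and rasterise a 3D scene of organoids (spheres of nuclei) plus
    sub-threshold debris into a 3-channel z-stack (Hoechst 33342,
    Caspase 3/7 Green, propidium iodide) with per-plane ground-truth
    organoid and nucleus label images.

``simulate_nuclei``
    Draw per-nucleus mean dye intensities directly (no imaging), with
    death-mode-dependent low/high channel distributions.  Used to test
    gating calibration against analytic normal-tail expectations.

``simulate_plate``
    Whole-well viability readings with exponential untreated growth, a
    four-parameter-logistic drug response at day 10 and multiplicative
    lognormal well noise.

Every generator is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry

__all__ = [
    "DEATH_MODES",
    "IntensityModel",
    "CellTruth",
    "OrganoidTruth",
    "SyntheticScene",
    "RenderedField",
    "make_scene",
    "render_scene",
    "simulate_nuclei",
    "PlateTruth",
    "make_plate_layout",
    "simulate_plate",
]

#: Classification targets, in canonical order.
DEATH_MODES = ("viable", "apoptotic", "necrotic", "late_apoptotic")

#: Which dye channels are in the "high" state for each death mode.
#: Caspase 3/7 Green marks executioner-caspase activity (apoptosis);
#: propidium iodide marks membrane permeabilisation (necrosis); both
#: high marks late apoptosis / secondary necrosis.
_MODE_HIGH = {
    "viable": (False, False),
    "apoptotic": (True, False),
    "necrotic": (False, True),
    "late_apoptotic": (True, True),
}


@dataclass(frozen=True)
class IntensityModel:
    """Dye-intensity distributions and optical nuisance parameters.

    The two dye channels are bimodal: a "low" mode (background binding,
    normal with mean ``low_mu`` and SD ``low_sd``) and a "high" mode
    (dye-positive nuclei, lognormal with mean ``high_mu``).  The default
    separation ``high_mu / low_mu = 8`` keeps gating recoverable but not
    trivial.  Intensities are arbitrary units; only ratios matter.
    """

    low_mu: float = 50.0
    low_sd: float = 10.0
    high_mu: float = 400.0
    high_sigma_log: float = 0.25
    hoechst_peak: float = 200.0
    nucleus_sigma_px: float = 3.0  # Gaussian blob SD, pixels
    body_intensity: float = 15.0  # diffuse organoid-body signal, all channels
    background: float = 5.0
    background_noise_sd: float = 2.0
    z_attenuation: float = 0.02  # fractional intensity loss per plane depth

    def draw_channel(self, high: bool, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        if high:
            s = self.high_sigma_log
            vals = rng.lognormal(np.log(self.high_mu) - 0.5 * s * s, s, size=n)
        else:
            vals = rng.normal(self.low_mu, self.low_sd, size=n)
        return np.clip(vals, 1.0, None)


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one nucleus."""

    nucleus_id: int
    organoid_id: int
    centroid: tuple[float, float, float]  # (x, y, z) um
    death_mode: str
    caspase_mu: float
    pi_mu: float


@dataclass(frozen=True)
class OrganoidTruth:
    """Ground truth for one organoid, modelled as a sphere."""

    organoid_id: int
    center: tuple[float, float, float]  # (x, y, z) um
    radius: float  # um


@dataclass
class SyntheticScene:
    """One field's worth of ground truth, ready to rasterise."""

    geometry: AcquisitionGeometry
    organoids: list[OrganoidTruth]
    cells: list[CellTruth]
    debris: list[tuple[float, float, int, float]]  # (x um, y um, plane, radius um)
    intensity: IntensityModel
    rng_seed: int

    def __post_init__(self) -> None:
        ids = {o.organoid_id for o in self.organoids}
        for c in self.cells:
            if c.organoid_id not in ids:
                raise ValueError(
                    f"cell {c.nucleus_id} references unknown organoid {c.organoid_id}"
                )
            if c.death_mode not in DEATH_MODES:
                raise ValueError(f"unknown death mode {c.death_mode!r}")

    @property
    def debris_count(self) -> int:
        return len(self.debris)

    @property
    def organoid_areas(self) -> dict[int, float]:
        """Largest analytic cross-section per organoid on the plane grid (um^2)."""
        g = self.geometry
        out: dict[int, float] = {}
        for o in self.organoids:
            zs = np.arange(g.n_planes) * g.z_step
            r2 = o.radius**2 - (zs - o.center[2]) ** 2
            out[o.organoid_id] = float(np.pi * max(r2.max(), 0.0))
        return out

    def n_cells_in_sampled_organoids(self, min_area: float = 250.0) -> int:
        """Number of nuclei sitting in organoid cross-sections of at
        least ``min_area`` um^2 on their own plane — the population the
        area-filtered per-plane pipeline is meant to sample."""
        g = self.geometry
        by_id = {o.organoid_id: o for o in self.organoids}
        n = 0
        for c in self.cells:
            org = by_id[c.organoid_id]
            z = g.plane_of(c.centroid[2]) * g.z_step
            r2 = org.radius**2 - (z - org.center[2]) ** 2
            if r2 > 0 and np.pi * r2 >= min_area:
                n += 1
        return n

    def truth_table(self) -> pd.DataFrame:
        """Per-nucleus ground truth as a tidy table."""
        return pd.DataFrame(
            {
                "nucleus_id": [c.nucleus_id for c in self.cells],
                "organoid_id": [c.organoid_id for c in self.cells],
                "x": [c.centroid[0] for c in self.cells],
                "y": [c.centroid[1] for c in self.cells],
                "z": [c.centroid[2] for c in self.cells],
                "plane": [self.geometry.plane_of(c.centroid[2]) for c in self.cells],
                "death_mode": [c.death_mode for c in self.cells],
                "caspase_mu": [c.caspase_mu for c in self.cells],
                "pi_mu": [c.pi_mu for c in self.cells],
            }
        )


@dataclass
class RenderedField:
    """Rasterised scene: 3-channel stack plus ground-truth label volumes."""

    hoechst: np.ndarray  # (planes, rows, cols) float32
    caspase: np.ndarray
    pi: np.ndarray
    organoid_labels: np.ndarray  # int32, 0 = background
    nucleus_labels: np.ndarray
    geometry: AcquisitionGeometry

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"hoechst": self.hoechst, "caspase": self.caspase, "pi": self.pi}


def _cross_section_radius(org: OrganoidTruth, z: float) -> float:
    r2 = org.radius**2 - (z - org.center[2]) ** 2
    return float(np.sqrt(r2)) if r2 > 0 else 0.0


def _sample_in_disc(
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    existing: list[tuple[float, float]],
    min_spacing: float,
    max_tries: int = 200,
) -> tuple[float, float] | None:
    """Dart-throwing sample in a disc keeping ``min_spacing`` to prior points."""
    for _ in range(max_tries):
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        x, y = center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing**2 for px, py in existing):
            return (x, y)
    return None


def make_scene(
    geometry: AcquisitionGeometry | None = None,
    n_organoids: int = 3,
    nuclei_per_organoid: int = 20,
    organoid_radius: tuple[float, float] = (20.0, 35.0),
    death_fractions: dict[str, float] | None = None,
    debris_count: int = 0,
    debris_radius: float = 2.5,
    intensity: IntensityModel | None = None,
    z_mode: str = "uniform",
    seed: int = 0,
) -> SyntheticScene:
    """Lay out a synthetic field of organoids, nuclei and debris.

    Organoids are non-overlapping spheres whose XY footprints are kept
    disjoint, so per-plane ground-truth regions never touch.  Nuclei sit
    on plane heights inside their organoid's cross-section with in-plane
    spacing >= 4 blob SDs, the regime in which seeded watershed should
    recover every nucleus.  Debris specks (radius ``debris_radius`` um,
    area well under the 250 um^2 organoid floor) land outside all
    organoid footprints.

    Parameters
    ----------
    death_fractions:
        Mapping death mode -> probability; defaults to all-viable.
    z_mode:
        ``"uniform"`` (default) draws organoid centers anywhere in the
        imaged depth, so spheres may straddle plane heights and produce
        small (sub-threshold) cross-sections — the realistic sampling
        regime.  ``"plane_centered"`` snaps each center to a plane
        height, giving every organoid one full-size cross-section; use
        it for exact-recovery oracles.
    seed:
        Single source of randomness for layout; rendering re-derives its
        own stream from the scene seed.
    """
    geometry = geometry or AcquisitionGeometry()
    intensity = intensity or IntensityModel()
    death_fractions = death_fractions or {"viable": 1.0}
    modes = list(death_fractions)
    probs = np.asarray([death_fractions[m] for m in modes], dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("death_fractions must be non-negative and sum > 0")
    probs = probs / probs.sum()

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    side_um = geometry.side_pixels * geometry.pixel_size
    depth = geometry.depth
    margin = 2.0  # um clearance between footprints

    organoids: list[OrganoidTruth] = []
    for oid in range(1, n_organoids + 1):
        placed = False
        for _ in range(500):
            radius = rng.uniform(*organoid_radius)
            if 2 * radius + 2 * margin > side_um:
                raise ValueError("organoid radius too large for the field")
            x = rng.uniform(radius + margin, side_um - radius - margin)
            y = rng.uniform(radius + margin, side_um - radius - margin)
            if z_mode == "plane_centered":
                z = float(rng.integers(geometry.n_planes)) * geometry.z_step
            elif z_mode == "uniform":
                z = rng.uniform(0, depth) if depth > 0 else 0.0
            else:
                raise ValueError(f"unknown z_mode {z_mode!r}")
            ok = all(
                np.hypot(x - o.center[0], y - o.center[1]) >= radius + o.radius + margin
                for o in organoids
            )
            if ok:
                organoids.append(OrganoidTruth(oid, (x, y, z), radius))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n_organoids} non-overlapping organoids; "
                "reduce the count or radius"
            )

    min_spacing = 4.0 * intensity.nucleus_sigma_px * geometry.pixel_size
    blob_margin = (2.0 * intensity.nucleus_sigma_px + 1.0) * geometry.pixel_size

    cells: list[CellTruth] = []
    nid = 0
    for org in organoids:
        # choose planes weighted by cross-section area so big sections get
        # proportionally more nuclei
        zs = np.arange(geometry.n_planes) * geometry.z_step
        areas = np.array([max(org.radius**2 - (z - org.center[2]) ** 2, 0.0) for z in zs])
        if areas.sum() == 0:  # sphere between planes; use nearest plane
            areas[geometry.plane_of(org.center[2])] = 1.0
        pl_probs = areas / areas.sum()
        per_plane: dict[int, list[tuple[float, float]]] = {}
        for _ in range(nuclei_per_organoid):
            for _try in range(50):
                k = int(rng.choice(geometry.n_planes, p=pl_probs))
                r_k = _cross_section_radius(org, zs[k])
                r_eff = max(r_k - blob_margin, min(2.0, max(r_k, 0.5)))
                pt = _sample_in_disc(
                    rng, org.center[:2], r_eff, per_plane.setdefault(k, []), min_spacing
                )
                if pt is not None:
                    break
            if pt is None:
                raise ValueError(
                    "could not place nuclei at the requested density; "
                    "reduce nuclei_per_organoid or increase organoid_radius"
                )
            per_plane[k].append(pt)
            nid += 1
            mode = modes[int(rng.choice(len(modes), p=probs))]
            hi_c, hi_p = _MODE_HIGH[mode]
            cells.append(
                CellTruth(
                    nucleus_id=nid,
                    organoid_id=org.organoid_id,
                    centroid=(pt[0], pt[1], float(zs[k])),
                    death_mode=mode,
                    caspase_mu=float(intensity.draw_channel(hi_c, rng)[0]),
                    pi_mu=float(intensity.draw_channel(hi_p, rng)[0]),
                )
            )

    debris: list[tuple[float, float, int, float]] = []
    for _ in range(debris_count):
        for _try in range(500):
            x = rng.uniform(debris_radius, side_um - debris_radius)
            y = rng.uniform(debris_radius, side_um - debris_radius)
            clear = all(
                np.hypot(x - o.center[0], y - o.center[1])
                > o.radius + debris_radius + margin
                for o in organoids
            )
            if clear:
                break
        else:
            raise ValueError("could not place debris clear of organoids")
        debris.append((x, y, int(rng.integers(geometry.n_planes)), debris_radius))

    return SyntheticScene(
        geometry=geometry,
        organoids=organoids,
        cells=cells,
        debris=debris,
        intensity=intensity,
        rng_seed=seed,
    )


def _add_disc(img: np.ndarray, cx: float, cy: float, radius_px: float, value: float) -> None:
    """Add ``value`` inside a disc; coordinates in pixels (x = col, y = row)."""
    n_rows, n_cols = img.shape
    r = int(np.ceil(radius_px)) + 1
    c0, r0 = int(round(cx)), int(round(cy))
    rows = slice(max(r0 - r, 0), min(r0 + r + 1, n_rows))
    cols = slice(max(c0 - r, 0), min(c0 + r + 1, n_cols))
    yy, xx = np.mgrid[rows, cols]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    img[rows, cols][mask] += value


def _set_disc_label(lbl: np.ndarray, cx: float, cy: float, radius_px: float, value: int) -> None:
    n_rows, n_cols = lbl.shape
    r = int(np.ceil(radius_px)) + 1
    c0, r0 = int(round(cx)), int(round(cy))
    rows = slice(max(r0 - r, 0), min(r0 + r + 1, n_rows))
    cols = slice(max(c0 - r, 0), min(c0 + r + 1, n_cols))
    yy, xx = np.mgrid[rows, cols]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    sub = lbl[rows, cols]
    sub[mask] = value
    lbl[rows, cols] = sub


def _add_gaussian(img: np.ndarray, cx: float, cy: float, sigma: float, peak: float) -> None:
    n_rows, n_cols = img.shape
    r = int(np.ceil(3 * sigma))
    c0, r0 = int(round(cx)), int(round(cy))
    rows = slice(max(r0 - r, 0), min(r0 + r + 1, n_rows))
    cols = slice(max(c0 - r, 0), min(c0 + r + 1, n_cols))
    yy, xx = np.mgrid[rows, cols]
    img[rows, cols] += peak * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
    )


def render_scene(scene: SyntheticScene) -> RenderedField:
    """Rasterise a scene into a 3-channel z-stack plus ground-truth labels.

    Per plane: a diffuse organoid-body disc in all channels (scattered
    light within the spheroid), a Hoechst Gaussian blob per nucleus, dye
    blobs at each nucleus's death-mode-dependent nominal intensity,
    bright debris specks, additive Gaussian background noise, and a
    linear intensity falloff of ``z_attenuation`` per plane of depth.
    Ground-truth organoid labels are the body discs; nucleus labels are
    discs of radius 2 blob SDs.  Rendering twice from the same scene is
    bit-identical.
    """
    g = scene.geometry
    g.validate()
    im = scene.intensity
    n_planes, n_rows, n_cols = g.shape
    ps = g.pixel_size

    shape = (n_planes, n_rows, n_cols)
    channels = {
        name: np.zeros(shape, dtype=np.float64) for name in ("hoechst", "caspase", "pi")
    }
    organoid_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    atten = np.clip(1.0 - im.z_attenuation * np.arange(n_planes), 0.05, None)

    for k in range(n_planes):
        z = k * g.z_step
        for org in scene.organoids:
            r_k = _cross_section_radius(org, z)
            if r_k <= 0:
                continue
            cx, cy = org.center[0] / ps, org.center[1] / ps
            for ch in channels.values():
                _add_disc(ch[k], cx, cy, r_k / ps, im.body_intensity * atten[k])
            _set_disc_label(organoid_labels[k], cx, cy, r_k / ps, org.organoid_id)

    for cell in scene.cells:
        k = g.plane_of(cell.centroid[2])
        cx, cy = cell.centroid[0] / ps, cell.centroid[1] / ps
        _add_gaussian(channels["hoechst"][k], cx, cy, im.nucleus_sigma_px, im.hoechst_peak * atten[k])
        _add_gaussian(channels["caspase"][k], cx, cy, im.nucleus_sigma_px, cell.caspase_mu * atten[k])
        _add_gaussian(channels["pi"][k], cx, cy, im.nucleus_sigma_px, cell.pi_mu * atten[k])
        _set_disc_label(nucleus_labels[k], cx, cy, 2.0 * im.nucleus_sigma_px, cell.nucleus_id)

    for x, y, k, radius in scene.debris:
        _add_disc(channels["hoechst"][k], x / ps, y / ps, radius / ps, im.hoechst_peak * atten[k])
        _add_disc(channels["caspase"][k], x / ps, y / ps, radius / ps, im.low_mu * atten[k])

    rng = np.random.default_rng(np.random.SeedSequence(entropy=scene.rng_seed, spawn_key=(1,)))
    for name in ("hoechst", "caspase", "pi"):
        noise = rng.normal(0.0, im.background_noise_sd, size=shape) if im.background_noise_sd > 0 else 0.0
        channels[name] = np.clip(channels[name] + im.background + noise, 0.0, None).astype(
            np.float32
        )

    return RenderedField(
        hoechst=channels["hoechst"],
        caspase=channels["caspase"],
        pi=channels["pi"],
        organoid_labels=organoid_labels,
        nucleus_labels=nucleus_labels,
        geometry=g,
    )


def simulate_nuclei(
    n: int,
    death_fractions: dict[str, float] | None = None,
    intensity: IntensityModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-nucleus mean dye intensities directly (no imaging step).

    Viable nuclei have independent normal Caspase and PI intensities
    (``low_mu`` +/- ``low_sd``); dye-positive channels are lognormal
    around ``high_mu``.  Returns columns ``nucleus_id``, ``mean_caspase``,
    ``mean_pi``, ``death_mode``.
    """
    intensity = intensity or IntensityModel()
    death_fractions = death_fractions or {"viable": 1.0}
    modes = list(death_fractions)
    probs = np.asarray([death_fractions[m] for m in modes], dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("death_fractions must be non-negative and sum > 0")
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    assigned = rng.choice(len(modes), size=n, p=probs)
    caspase = np.empty(n)
    pi = np.empty(n)
    labels = np.empty(n, dtype=object)
    for i, mode in enumerate(modes):
        sel = assigned == i
        m = int(sel.sum())
        if m == 0:
            continue
        hi_c, hi_p = _MODE_HIGH[mode]
        caspase[sel] = intensity.draw_channel(hi_c, rng, m)
        pi[sel] = intensity.draw_channel(hi_p, rng, m)
        labels[sel] = mode
    return pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "mean_caspase": caspase,
            "mean_pi": pi,
            "death_mode": labels,
        }
    )


# ---------------------------------------------------------------------------
# Whole-well viability plates
# ---------------------------------------------------------------------------

CONTROL_ROLES = ("untreated", "vehicle_dmso", "vehicle_ethanol", "staurosporine", "none")
NEGATIVE_ROLES = ("untreated", "vehicle_dmso", "vehicle_ethanol")


def make_plate_layout(
    doses: list[float] | None = None,
    treatment: str = "drug",
    n_replicates: int = 6,
    n_untreated: int = 6,
    n_dmso: int = 0,
    n_ethanol: int = 0,
    n_staurosporine: int = 6,
) -> pd.DataFrame:
    """Row-major 96-well layout with columns well/treatment/dose/control_role."""
    doses = [] if doses is None else doses
    rows = "ABCDEFGH"
    entries: list[dict] = []
    for _ in range(n_untreated):
        entries.append({"treatment": "none", "dose": 0.0, "control_role": "untreated"})
    for _ in range(n_dmso):
        entries.append({"treatment": "none", "dose": 0.0, "control_role": "vehicle_dmso"})
    for _ in range(n_ethanol):
        entries.append({"treatment": "none", "dose": 0.0, "control_role": "vehicle_ethanol"})
    for _ in range(n_staurosporine):
        entries.append(
            {"treatment": "staurosporine", "dose": 1.0, "control_role": "staurosporine"}
        )
    for d in doses:
        for _ in range(n_replicates):
            entries.append({"treatment": treatment, "dose": float(d), "control_role": "none"})
    if len(entries) > 96:
        raise ValueError(f"layout needs {len(entries)} wells; a plate has 96")
    for i, e in enumerate(entries):
        e["well"] = f"{rows[i // 12]}{i % 12 + 1}"
    return pd.DataFrame(entries, columns=["well", "treatment", "dose", "control_role"])


@dataclass
class PlateTruth:
    """Stated world for one simulated viability plate.

    ``layout`` needs columns ``well``, ``treatment``, ``dose``,
    ``control_role``.  Untreated signal grows exponentially at
    ``growth_rate`` per day from ``baseline`` at day 0; day-10 treated
    wells are scaled by the 4PL response at their dose; staurosporine
    positive controls are scaled to ``stauro_survival``.  Well noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``.
    """

    layout: pd.DataFrame
    true_4pl: tuple[float, float, float, float] = (1.0, 0.0, 1.0, 1.0)  # top, bottom, ic50, hill
    noise_cv: float = 0.1
    growth_rate: float = 2.0 ** 0.1  # doubles over the 10-day exposure
    baseline: float = 100.0
    stauro_survival: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        cols = {"well", "treatment", "dose", "control_role"}
        missing = cols - set(self.layout.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        if (self.layout["dose"] < 0).any():
            raise ValueError("doses must be non-negative")
        bad = set(self.layout["control_role"]) - set(CONTROL_ROLES)
        if bad:
            raise ValueError(f"unknown control roles: {sorted(bad)}")
        roles = set(self.layout["control_role"])
        if not roles & set(NEGATIVE_ROLES):
            raise ValueError("plate needs at least one negative-control well")
        if "staurosporine" not in roles:
            raise ValueError("plate needs at least one staurosporine positive-control well")
        top, bottom, ic50, hill = self.true_4pl
        if ic50 <= 0:
            raise ValueError("true ic50 must be positive")


def simulate_plate(
    truth: PlateTruth, timepoints: tuple[int, ...] = (-4, 0, 10)
) -> pd.DataFrame:
    """Simulate whole-well viability readings at the given day offsets.

    Day 0 is treatment initiation; treated wells follow the untreated
    trajectory until then.  Returns a tidy table with columns
    ``well``, ``day``, ``treatment``, ``dose``, ``control_role``,
    ``reading``.
    """
    from .viability import four_param_logistic  # deferred: avoids import cycle

    rng = np.random.default_rng(np.random.SeedSequence(entropy=truth.rng_seed, spawn_key=(2,)))
    sigma = float(np.sqrt(np.log1p(truth.noise_cv**2)))
    top, bottom, ic50, hill = truth.true_4pl

    records: list[dict] = []
    for day in timepoints:
        base = truth.baseline * truth.growth_rate ** day
        for row in truth.layout.itertuples(index=False):
            signal = base
            if day > 0:
                if row.control_role == "staurosporine":
                    signal = base * truth.stauro_survival
                elif row.control_role == "none":
                    signal = base * float(
                        four_param_logistic(row.dose, top, bottom, ic50, hill)
                    )
            noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
            records.append(
                {
                    "well": row.well,
                    "day": day,
                    "treatment": row.treatment,
                    "dose": row.dose,
                    "control_role": row.control_role,
                    "reading": signal * noise,
                }
            )
    return pd.DataFrame(records)
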
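"""Synthetic lower-leg phantom and gait-trial generator.

The phantom is an idealized straight two-bone model: a thick-walled tibia
with a transverse, callus-filled fracture gap bridged by a locked
intramedullary nail, and a thin-walled fibula that can be intact, fractured
(proximally and distally) or absent, with an optional plate spanning the
distal fibular fracture.  An interosseous-membrane sheet and a distal
syndesmosis block connect the two bones so that the fibula participates in
the load path, as it does in vivo.  The four fibular configurations are

* ``FibOP``     - distal fibular fracture plated, proximal fracture untreated
                  (the clinically treated state),
* ``FibNoOp``   - both fibular fractures present, no implant,
* ``FibIntact`` - intact fibula,
* ``NoFib``     - fibula (and its soft-tissue connections) absent.

The nail floats in a canal clearance and is tied to the bone only through
proximal and distal locking screws, so interfragmentary motion arises from
nail flexion over its free working length - the mechanism that makes locked
intramedullary nailing a "relative stability" fixation.

Grayscale values are pseudo-Hounsfield tiers (cortical / trabecular /
callus / metal / soft tissue) with seeded Gaussian noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

G_MS2 = 9.81  # gravitational acceleration, m/s^2

CONFIGURATIONS = ("FibOP", "FibNoOp", "FibIntact", "NoFib")


class Segment(IntEnum):
    """Voxel / element segment labels."""

    BACKGROUND = 0
    TIBIA = 1
    FIBULA = 2
    CALLUS = 3
    NAIL = 4
    PLATE = 5
    SCREWS = 6
    MEMBRANE = 7  # interosseous membrane, syndesmosis, soft fracture filler


#: default pseudo-HU grayscale tiers
DEFAULT_TIERS: dict[str, float] = {
    "cortical": 1400.0,
    "trabecular": 300.0,
    "callus": 100.0,
    "metal": 3000.0,
    "membrane": 50.0,
    "background": -1000.0,
}


@dataclass
class PhantomConfig:
    """Geometry and appearance of the synthetic lower-leg phantom.

    All lengths in mm.  Axial positions are measured from the distal end
    (z = 0, the fixed ankle side) toward the proximal tibial plateau
    (z = ``tibia_length_mm``, the loaded side).
    """

    configuration: str = "FibOP"
    voxel_size_mm: float = 2.0
    tibia_length_mm: float = 180.0
    tibia_outer_radius_mm: float = 14.0
    cortical_thickness_mm: float = 4.0
    fibula_radius_mm: float = 6.0
    fibula_cortical_thickness_mm: float = 2.0
    tibial_gap_mm: float = 6.0
    tibial_gap_center_frac: float = 0.35
    fibula_fracture_levels_mm: Sequence[float] | None = None  # default 0.15L, 0.85L
    fibula_gap_mm: float = 6.0
    fibula_offset_mm: float = 26.0  # tibia-fibula centre distance
    nail_radius_mm: float = 4.5
    nail_length_mm: float = 170.0
    nail_clearance_mm: float = 4.0
    locking_screw_levels_frac: tuple[float, ...] = (0.10, 0.18, 0.82, 0.90)
    locking_screw_radius_mm: float = 2.5
    plate: bool | None = None  # None -> present iff configuration == FibOP
    plate_thickness_mm: float = 3.0
    plate_half_width_mm: float = 5.0
    plate_half_length_mm: float = 14.0
    membrane_half_thickness_mm: float = 2.0
    membrane_span_frac: tuple[float, float] = (0.30, 0.90)
    syndesmosis_span_mm: tuple[float, float] = (6.0, 16.0)
    margin_mm: float = 4.0
    grayscale_tiers: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TIERS))
    noise_sd_hu: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(
                f"unknown configuration {self.configuration!r}; expected one of {CONFIGURATIONS}"
            )
        for name in (
            "voxel_size_mm",
            "tibia_length_mm",
            "tibia_outer_radius_mm",
            "cortical_thickness_mm",
            "fibula_radius_mm",
            "tibial_gap_mm",
            "nail_radius_mm",
            "nail_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nail_length_mm > self.tibia_length_mm:
            raise ValueError("nail_length_mm must not exceed tibia_length_mm")
        if self.tibial_gap_mm >= self.tibia_length_mm / 4:
            raise ValueError("tibial_gap_mm must be smaller than tibia_length_mm / 4")
        if self.plate and self.configuration == "NoFib":
            raise ValueError("invalid configuration: a fibular plate requires a fibula (NoFib)")
        if self.fibula_fracture_levels_mm is None:
            L = self.tibia_length_mm
            self.fibula_fracture_levels_mm = (0.15 * L, 0.85 * L)

    @property
    def has_plate(self) -> bool:
        if self.plate is None:
            return self.configuration == "FibOP"
        return bool(self.plate)

    @property
    def has_fibula(self) -> bool:
        return self.configuration != "NoFib"

    @property
    def fibula_gaps(self) -> tuple[float, ...]:
        """Axial gap centres actually present for this configuration."""
        if self.configuration in ("FibOP", "FibNoOp"):
            return tuple(self.fibula_fracture_levels_mm)
        return ()

    def scaled(self, factor: float) -> "PhantomConfig":
        """Uniformly scale every geometric dimension by ``factor``."""
        lengths = dict(
            tibia_length_mm=self.tibia_length_mm * factor,
            tibia_outer_radius_mm=self.tibia_outer_radius_mm * factor,
            cortical_thickness_mm=self.cortical_thickness_mm * factor,
            fibula_radius_mm=self.fibula_radius_mm * factor,
            fibula_cortical_thickness_mm=self.fibula_cortical_thickness_mm * factor,
            tibial_gap_mm=self.tibial_gap_mm * factor,
            fibula_gap_mm=self.fibula_gap_mm * factor,
            fibula_offset_mm=self.fibula_offset_mm * factor,
            nail_radius_mm=self.nail_radius_mm * factor,
            nail_length_mm=self.nail_length_mm * factor,
            nail_clearance_mm=self.nail_clearance_mm * factor,
            locking_screw_radius_mm=self.locking_screw_radius_mm * factor,
            plate_thickness_mm=self.plate_thickness_mm * factor,
            plate_half_width_mm=self.plate_half_width_mm * factor,
            plate_half_length_mm=self.plate_half_length_mm * factor,
            membrane_half_thickness_mm=self.membrane_half_thickness_mm * factor,
            syndesmosis_span_mm=(
                self.syndesmosis_span_mm[0] * factor,
                self.syndesmosis_span_mm[1] * factor,
            ),
            margin_mm=self.margin_mm * factor,
            fibula_fracture_levels_mm=tuple(z * factor for z in self.fibula_fracture_levels_mm),
        )
        return replace(self, **lengths)


@dataclass
class LabeledVoxelGrid:
    """Pseudo-CT grayscale plus integer segment labels on a regular grid."""

    grayscale: np.ndarray  # (nx, ny, nz) float
    labels: np.ndarray  # (nx, ny, nz) uint8
    voxel_size_mm: float
    origin_mm: np.ndarray  # (3,) coordinate of the grid corner (not voxel centre)

    def __post_init__(self) -> None:
        if self.grayscale.shape != self.labels.shape:
            raise ValueError("grayscale and labels must have identical shape")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.voxel_size_mm
        return tuple(
            self.origin_mm[ax] + (np.arange(self.shape[ax]) + 0.5) * h for ax in range(3)
        )

    def count(self, segment: int) -> int:
        return int(np.count_nonzero(self.labels == segment))

    # -- persistence ------------------------------------------------------

    def to_nifti(self, grayscale_path: str | Path, labels_path: str | Path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm + self.voxel_size_mm / 2.0
        nib.save(nib.Nifti1Image(self.grayscale.astype(np.float32), affine), str(grayscale_path))
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), str(labels_path))

    @classmethod
    def from_nifti(cls, grayscale_path: str | Path, labels_path: str | Path) -> "LabeledVoxelGrid":
        import nibabel as nib

        gimg = nib.load(str(grayscale_path))
        limg = nib.load(str(labels_path))
        vox = float(gimg.affine[0, 0])
        origin = np.asarray(gimg.affine[:3, 3], dtype=float) - vox / 2.0
        return cls(
            grayscale=np.asarray(gimg.dataobj, dtype=np.float64),
            labels=np.asarray(limg.dataobj, dtype=np.uint8),
            voxel_size_mm=vox,
            origin_mm=origin,
        )

    def to_raw(self, prefix: str | Path) -> None:
        """Raw little-endian binaries plus a JSON sidecar describing them."""
        prefix = Path(prefix)
        gray = self.grayscale.astype("<f4")
        labs = self.labels.astype("u1")
        gray.tofile(prefix.with_suffix(".gray.raw"))
        labs.tofile(prefix.with_suffix(".labels.raw"))
        header = {
            "shape": list(self.shape),
            "grayscale_dtype": "<f4",
            "labels_dtype": "u1",
            "order": "C",
            "voxel_size_mm": self.voxel_size_mm,
            "origin_mm": list(map(float, self.origin_mm)),
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def from_raw(cls, prefix: str | Path) -> "LabeledVoxelGrid":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        shape = tuple(header["shape"])
        gray = np.fromfile(prefix.with_suffix(".gray.raw"), dtype=header["grayscale_dtype"])
        labs = np.fromfile(prefix.with_suffix(".labels.raw"), dtype=header["labels_dtype"])
        return cls(
            grayscale=gray.reshape(shape).astype(np.float64),
            labels=labs.reshape(shape).astype(np.uint8),
            voxel_size_mm=float(header["voxel_size_mm"]),
            origin_mm=np.asarray(header["origin_mm"], dtype=float),
        )


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------


def _slab(z: np.ndarray, center: float, height: float) -> np.ndarray:
    # half-open axial slab [center - h/2, center + h/2)
    return (z >= center - height / 2.0) & (z < center + height / 2.0)


def build_phantom(config: PhantomConfig) -> LabeledVoxelGrid:
    """Generate the labelled voxel phantom for one fibular configuration.

    Geometry is deterministic in the configuration; only the grayscale noise
    consumes the seed, so the four configurations built with the same seed
    share every common voxel.
    """
    c = config
    h = c.voxel_size_mm
    L = c.tibia_length_mm
    Rt = c.tibia_outer_radius_mm
    Rf = c.fibula_radius_mm
    xf = c.fibula_offset_mm

    x_min = -Rt - c.margin_mm
    x_max = xf + Rf + c.plate_thickness_mm + c.margin_mm
    y_max = max(Rt, c.plate_half_width_mm) + c.margin_mm
    origin = np.array([x_min, -y_max, 0.0])
    nx = int(np.ceil((x_max - x_min) / h))
    ny = int(np.ceil(2 * y_max / h))
    nz = int(np.ceil(L / h))

    xs = origin[0] + (np.arange(nx) + 0.5) * h
    ys = origin[1] + (np.arange(ny) + 0.5) * h
    zs = origin[2] + (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    tiers = {**DEFAULT_TIERS, **dict(c.grayscale_tiers)}
    gray = np.full((nx, ny, nz), tiers["background"], dtype=np.float64)

    r_tib = np.hypot(X, Y)
    in_bone_z = Z < L

    # tibia: cortical shell over trabecular core
    tibia = (r_tib <= Rt) & in_bone_z
    labels[tibia] = Segment.TIBIA
    gray[tibia] = np.where(
        r_tib[tibia] > Rt - c.cortical_thickness_mm, tiers["cortical"], tiers["trabecular"]
    )

    # tibial fracture gap filled with callus
    gap_center = c.tibial_gap_center_frac * L
    gap = _slab(Z, gap_center, c.tibial_gap_mm) & (r_tib <= Rt)
    labels[gap] = Segment.CALLUS
    gray[gap] = tiers["callus"]

    # canal clearance: the nail floats free except at the locking screws
    nail_z0 = (L - c.nail_length_mm) / 2.0
    nail_z1 = nail_z0 + c.nail_length_mm
    clear_r = c.nail_radius_mm + c.nail_clearance_mm
    clearance = (
        (r_tib <= clear_r)
        & (Z >= nail_z0 - c.nail_clearance_mm)
        & (Z < nail_z1 + c.nail_clearance_mm)
        & ~_slab(Z, gap_center, c.tibial_gap_mm)
    )
    labels[clearance] = Segment.BACKGROUND
    gray[clearance] = tiers["background"]

    # intramedullary nail
    nail = (r_tib <= c.nail_radius_mm) & (Z >= nail_z0) & (Z < nail_z1)
    labels[nail] = Segment.NAIL
    gray[nail] = tiers["metal"]

    # locking screws: transverse cylinders tying nail to cortex
    for frac in c.locking_screw_levels_frac:
        zsw = frac * L
        cyl = (np.hypot(Y, Z - zsw) <= c.locking_screw_radius_mm) & (np.abs(X) <= Rt)
        screw = cyl & (labels != Segment.NAIL)
        labels[screw] = Segment.SCREWS
        gray[screw] = tiers["metal"]

    if c.has_fibula:
        r_fib = np.hypot(X - xf, Y)
        fibula = (r_fib <= Rf) & in_bone_z
        labels[fibula] = Segment.FIBULA
        gray[fibula] = np.where(
            r_fib[fibula] > Rf - c.fibula_cortical_thickness_mm,
            tiers["cortical"],
            tiers["trabecular"],
        )

        # fibular fracture gaps (soft fibrous filler)
        for zg in c.fibula_gaps:
            fg = _slab(Z, zg, c.fibula_gap_mm) & (r_fib <= Rf)
            labels[fg] = Segment.MEMBRANE
            gray[fg] = tiers["membrane"]

        # interosseous membrane sheet and distal syndesmosis block
        # overlap one voxel into either bone so the sheet shares faces with them
        mem_x = (X >= Rt - 2.0) & (X <= xf - Rf + 2.0)
        membrane = (
            mem_x
            & (np.abs(Y) <= c.membrane_half_thickness_mm)
            & (Z >= c.membrane_span_frac[0] * L)
            & (Z < c.membrane_span_frac[1] * L)
            & (labels == Segment.BACKGROUND)
        )
        labels[membrane] = Segment.MEMBRANE
        gray[membrane] = tiers["membrane"]

        synd = (
            mem_x
            & (np.abs(Y) <= c.plate_half_width_mm)
            & (Z >= c.syndesmosis_span_mm[0])
            & (Z < c.syndesmosis_span_mm[1])
            & (labels == Segment.BACKGROUND)
        )
        labels[synd] = Segment.MEMBRANE
        gray[synd] = tiers["membrane"]

        if c.has_plate:
            zg = min(c.fibula_fracture_levels_mm)  # distal fibular fracture
            plate = (
                (X >= xf + Rf)
                & (X < xf + Rf + c.plate_thickness_mm)
                & (np.abs(Y) <= c.plate_half_width_mm)
                & _slab(Z, zg, 2 * c.plate_half_length_mm)
            )
            labels[plate] = Segment.PLATE
            gray[plate] = tiers["metal"]

            for dz in (-0.6 * c.plate_half_length_mm, 0.6 * c.plate_half_length_mm):
                cyl = (
                    (np.hypot(Y, Z - (zg + dz)) <= 0.8 * c.locking_screw_radius_mm)
                    & (X >= xf - Rf + 1.0)
                    & (X < xf + Rf + c.plate_thickness_mm)
                    & (labels != Segment.NAIL)
                )
                labels[cyl] = Segment.SCREWS
                gray[cyl] = tiers["metal"]

    # seeded grayscale noise on foreground voxels
    rng = np.random.default_rng(c.seed)
    noise = rng.normal(0.0, c.noise_sd_hu, size=labels.shape)
    fg = labels != Segment.BACKGROUND
    gray[fg] += noise[fg]

    return LabeledVoxelGrid(grayscale=gray, labels=labels, voxel_size_mm=h, origin_mm=origin)


def callus_volume_analytic(config: PhantomConfig) -> float:
    """Closed-form callus volume (mm^3): gap-height cylinder annulus around the nail."""
    c = config
    return (
        c.tibial_gap_mm
        * np.pi
        * (c.tibia_outer_radius_mm**2 - c.nail_radius_mm**2)
    )


# ---------------------------------------------------------------------------
# morphological clean-up
# ---------------------------------------------------------------------------


def apply_morph_filters(
    labels: np.ndarray,
    priority: Sequence[int],
    min_island_voxels: int = 27,
    closing_radius: int = 1,
) -> np.ndarray:
    """Island removal, cavity fill and gap closing per segment.

    ``priority`` lists segment ids highest-priority first; a higher-priority
    segment is never overwritten by a lower-priority one.  Voxels claimed by
    no segment after filtering become background.
    """
    from skimage.morphology import ball

    masks: dict[int, np.ndarray] = {}
    for seg in priority:
        if seg == Segment.BACKGROUND:
            continue
        mask = labels == seg
        if mask.any():
            # island removal: drop connected components below the size threshold
            comp, n = ndimage.label(mask)
            if n:
                sizes = np.bincount(comp.ravel())
                keep = sizes >= min_island_voxels
                keep[0] = False
                mask = keep[comp]
            mask = ndimage.binary_fill_holes(mask)
            if closing_radius > 0:
                mask = ndimage.binary_closing(mask, structure=ball(closing_radius))
        if not mask.any():
            warnings.warn(f"segment {seg} is empty after morphological filtering", stacklevel=2)
        masks[seg] = mask

    out = np.zeros_like(labels)
    for seg in reversed(list(priority)):  # paint lowest priority first
        if seg == Segment.BACKGROUND:
            continue
        out[masks[seg]] = seg
    return out


DEFAULT_PRIORITY = (
    Segment.NAIL,
    Segment.SCREWS,
    Segment.PLATE,
    Segment.CALLUS,
    Segment.TIBIA,
    Segment.FIBULA,
    Segment.MEMBRANE,
)


# ---------------------------------------------------------------------------
# gait-trial synthesis
# ---------------------------------------------------------------------------


@dataclass
class GaitTrial:
    """One treadmill walking bout: vertical GRF plus joint-angle traces."""

    time_s: np.ndarray
    grf_N: np.ndarray
    joint_angles_deg: dict[str, np.ndarray]
    velocity_kmh: float
    body_mass_kg: float
    side: str = "left"
    cycle_s: float | None = None
    n_steps: int | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.grf_N = np.asarray(self.grf_N, dtype=float)
        if self.time_s.shape != self.grf_N.shape:
            raise ValueError("time_s and grf_N must have the same length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(self.grf_N < 0):
            raise ValueError("grf_N must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s, "grf_N": self.grf_N}
        for name, trace in self.joint_angles_deg.items():
            data[f"{name}_deg"] = trace
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        velocity_kmh: float,
        body_mass_kg: float,
        side: str = "left",
    ) -> "GaitTrial":
        df = pd.read_csv(path)
        angles = {
            col[: -len("_deg")]: df[col].to_numpy()
            for col in df.columns
            if col.endswith("_deg")
        }
        return cls(
            time_s=df["time_s"].to_numpy(),
            grf_N=df["grf_N"].to_numpy(),
            joint_angles_deg=angles,
            velocity_kmh=velocity_kmh,
            body_mass_kg=body_mass_kg,
            side=side,
        )


#: joint-angle channels: (name, offset deg, amplitude deg, phase rad)
DEFAULT_ANGLE_CHANNELS: tuple[tuple[str, float, float, float], ...] = (
    ("hip_flexex", 10.0, 15.0, 0.0),
    ("hip_abdadd", 0.0, 4.0, 0.8),
    ("hip_iroero", 0.0, 5.0, 1.6),
    ("knee_flexex", 25.0, 25.0, 0.4),
    ("knee_abdadd", 0.0, 3.0, 1.2),
    ("knee_iroero", 0.0, 6.0, 2.0),
    ("ankle_flexex", 0.0, 10.0, 0.9),
    ("ankle_suppro", 0.0, 5.0, 1.7),
    ("ankle_iroero", 0.0, 4.0, 2.5),
)

#: walking-velocity threshold (km/h) above which the stance GRF curve
#: degenerates from the typical two-peaked to a single-peaked shape
THRESHOLD_VELOCITY_KMH = 1.75

#: generator-side cap on step-to-step amplitude jitter
OVERSHOOT_FACTOR = 1.05


def _stance_template(s: np.ndarray, bicuspid: bool) -> np.ndarray:
    """Unit-peak vertical GRF over normalised stance phase s in [0, 1]."""
    if bicuspid:
        f = np.exp(-0.5 * ((s - 0.28) / 0.11) ** 2) + 0.95 * np.exp(
            -0.5 * ((s - 0.72) / 0.11) ** 2
        )
    else:
        f = np.exp(-0.5 * ((s - 0.55) / 0.18) ** 2)
    f *= np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.25  # force touchdown/toe-off to zero
    return f / f.max()


def synth_gait(
    velocity_kmh: float,
    body_mass_kg: float = 95.0,
    cap_kg: float | None = None,
    n_steps: int = 30,
    seed: int = 0,
    effective_load_frac: float = 0.37,
    dt_s: float = 0.01,
    stance_frac: float = 0.62,
    amp_jitter_sd: float = 0.02,
    time_jitter_sd: float = 0.02,
    side: str = "left",
    angle_channels: Sequence[tuple[str, float, float, float]] = DEFAULT_ANGLE_CHANNELS,
) -> GaitTrial:
    """Synthesize a treadmill trial of ``n_steps`` stances at one velocity.

    The stance GRF is two-peaked below :data:`THRESHOLD_VELOCITY_KMH` and
    single-peaked above it.  The per-step peak equals
    ``min(cap_kg, effective_load_frac * body_mass_kg) * g`` up to seeded
    jitter that never exceeds :data:`OVERSHOOT_FACTOR`.
    """
    if velocity_kmh <= 0:
        raise ValueError("velocity_kmh must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if cap_kg is not None and cap_kg < 0:
        raise ValueError("cap_kg must be non-negative")

    peak_kg = effective_load_frac * body_mass_kg
    if cap_kg is not None:
        peak_kg = min(peak_kg, cap_kg)
    peak_N = peak_kg * G_MS2

    cycle_s = 0.8 + 1.4 / velocity_kmh
    bicuspid = velocity_kmh <= THRESHOLD_VELOCITY_KMH
    rng = np.random.default_rng(seed)

    n_cycle = int(round(cycle_s / dt_s))
    n_stance = int(round(stance_frac * n_cycle))
    n_total = n_cycle * n_steps + n_cycle // 4  # trailing swing tail
    grf = np.zeros(n_total)

    for k in range(n_steps):
        amp = float(np.clip(rng.normal(1.0, amp_jitter_sd), 0.9, OVERSHOOT_FACTOR))
        shift = int(round(rng.normal(0.0, time_jitter_sd) * n_stance))
        i0 = k * n_cycle + max(0, shift)
        s = np.arange(n_stance) / (n_stance - 1)
        seg = peak_N * amp * _stance_template(s, bicuspid)
        i1 = min(i0 + n_stance, n_total)
        grf[i0:i1] = np.maximum(grf[i0:i1], seg[: i1 - i0])

    t = np.arange(n_total) * dt_s
    angles = {}
    for name, offset, ampl, phase in angle_channels:
        angles[name] = offset + ampl * np.sin(2 * np.pi * t / cycle_s + phase)

    return GaitTrial(
        time_s=t,
        grf_N=grf,
        joint_angles_deg=angles,
        velocity_kmh=velocity_kmh,
        body_mass_kg=body_mass_kg,
        side=side,
        cycle_s=cycle_s,
        n_steps=n_steps,
    )
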
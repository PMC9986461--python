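"""Grayscale-to-elasticity material mapping.

Bone elements receive a local Young's modulus from the pseudo-CT grayscale
through two maps: an affine Hounsfield-to-ash-density calibration and a
piecewise density-to-modulus power law with separate trabecular and
cortical regimes.  Implants, callus and soft tissue are homogeneous.

The default power-law coefficients follow widely used literature relations
(trabecular E = 6850 * rho_app^1.49 MPa with rho_app = rho_ash / 0.6;
cortical E = 10200 * rho_ash^2.01 MPa).  Taken verbatim these two curves
are discontinuous at any practical breakpoint; by default the cortical
branch is therefore rescaled to join the trabecular branch continuously at
``rho_break`` so that E(rho) is non-decreasing - the fixed-Poisson,
monotone-stiffness contract the rest of the pipeline relies on.  Set
``enforce_continuity=False`` to use the raw literature coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .phantom import Segment


@dataclass
class MaterialTable:
    """Calibration coefficients and per-segment homogeneous overrides.

    Units: HU (pseudo), g/cm^3 for densities, MPa for moduli.
    """

    hu_slope: float = 0.0008  # g/cm^3 per HU
    hu_intercept: float = 0.07  # g/cm^3
    a_trab: float = 6850.0
    b_trab: float = 1.49
    rho_app_factor: float = 0.6  # rho_app = rho_ash / rho_app_factor
    a_cort: float = 10200.0
    b_cort: float = 2.01
    rho_break: float = 1.0
    enforce_continuity: bool = True
    E_min: float = 1.0
    E_max: float = 25000.0
    poisson_bone: float = 0.3
    homogeneous_overrides: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {
            int(Segment.NAIL): (110000.0, 0.3),  # titanium alloy
            int(Segment.PLATE): (110000.0, 0.3),
            int(Segment.SCREWS): (110000.0, 0.3),
            int(Segment.CALLUS): (3.0, 0.4),  # early granulation-tissue callus
            int(Segment.MEMBRANE): (100.0, 0.4),  # interosseous membrane / fibrous tissue
        }
    )

    def __post_init__(self) -> None:
        if self.hu_slope <= 0:
            raise ValueError("hu_slope must be positive")
        for name in ("a_trab", "b_trab", "a_cort", "b_cort", "rho_break"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.poisson_bone < 0.5:
            raise ValueError("poisson_bone must lie in (0, 0.5)")
        for seg, (E, nu) in self.homogeneous_overrides.items():
            if E <= 0 or not 0 < nu < 0.5:
                raise ValueError(f"invalid override for segment {seg}: E={E}, nu={nu}")

    @property
    def a_cort_effective(self) -> float:
        if not self.enforce_continuity:
            return self.a_cort
        e_break = self.a_trab * (self.rho_break / self.rho_app_factor) ** self.b_trab
        return e_break / self.rho_break**self.b_cort

    @classmethod
    def from_dict(cls, d: Mapping) -> "MaterialTable":
        d = dict(d)
        if "homogeneous_overrides" in d:
            d["homogeneous_overrides"] = {
                int(k): tuple(v) for k, v in d["homogeneous_overrides"].items()
            }
        return cls(**d)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "hu_slope",
                "hu_intercept",
                "a_trab",
                "b_trab",
                "rho_app_factor",
                "a_cort",
                "b_cort",
                "rho_break",
                "enforce_continuity",
                "E_min",
                "E_max",
                "poisson_bone",
            )
        }
        out["homogeneous_overrides"] = {
            int(k): list(v) for k, v in self.homogeneous_overrides.items()
        }
        return out


BONE_SEGMENTS = (int(Segment.TIBIA), int(Segment.FIBULA))


def hu_to_density(hu, table: MaterialTable):
    """Affine pseudo-HU to ash-density map, clamped below at zero."""
    rho = table.hu_slope * np.asarray(hu, dtype=float) + table.hu_intercept
    return np.maximum(rho, 0.0)


def density_to_modulus(rho_ash, table: MaterialTable):
    """Piecewise power law E(rho_ash) in MPa, clamped to [E_min, E_max]."""
    rho = np.asarray(rho_ash, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho_ash must be non-negative")
    e_trab = table.a_trab * (rho / table.rho_app_factor) ** table.b_trab
    e_cort = table.a_cort_effective * rho**table.b_cort
    E = np.where(rho < table.rho_break, e_trab, e_cort)
    return np.clip(E, table.E_min, table.E_max)


def assign_materials(mesh, grid, table: MaterialTable):
    """Assign per-element (E, nu) to ``mesh`` in place and return it.

    Bone elements sample the grayscale at their centroid (nearest voxel,
    matching the constant-strain elements); every other segment takes its
    homogeneous override.  Elements whose segment has no material resolution
    raise, listing the offending element ids.
    """
    labels = np.asarray(mesh.element_label)
    E = np.zeros(len(labels), dtype=float)
    nu = np.zeros(len(labels), dtype=float)
    resolved = np.zeros(len(labels), dtype=bool)

    bone = np.isin(labels, BONE_SEGMENTS)
    if bone.any():
        cent = mesh.element_centroids()[bone]
        idx = np.floor((cent - grid.origin_mm) / grid.voxel_size_mm).astype(int)
        idx = np.clip(idx, 0, np.array(grid.shape) - 1)
        hu = grid.grayscale[idx[:, 0], idx[:, 1], idx[:, 2]]
        E[bone] = density_to_modulus(hu_to_density(hu, table), table)
        nu[bone] = table.poisson_bone
        resolved |= bone

    for seg, (e_seg, nu_seg) in table.homogeneous_overrides.items():
        sel = labels == seg
        E[sel] = e_seg
        nu[sel] = nu_seg
        resolved |= sel

    if not resolved.all():
        bad = np.nonzero(~resolved)[0]
        segs = sorted(set(labels[bad].tolist()))
        raise ValueError(
            f"no material resolution for {bad.size} elements "
            f"(segments {segs}; first ids {bad[:10].tolist()})"
        )

    mesh.element_E = E
    mesh.element_nu = nu
    return mesh
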
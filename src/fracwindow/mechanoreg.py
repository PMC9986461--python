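"""Mechanoregulation classification of callus elements.

Each callus element is assigned to exactly one healing class from its
octahedral shear strain and its hydrostatic stimulus (either hydrostatic
strain, dimensionless, or hydrostatic pressure in MPa - the literature uses
both; a flag on :class:`HealingThresholds` selects the axis).  The default
scheme mirrors the classic strain/pressure mechanoregulation diagrams:

1. ``intramembranous``  - low distortion, near-zero hydrostatic stimulus:
   direct bone formation;
2. ``endochondral``     - low distortion under compressive hydrostatic
   stimulus: bone formation via a cartilage intermediate;
3. ``fibrous``          - moderate distortion: fibrous tissue / provisional
   connective tissue (counted inside the healing window by default);
4. ``out_of_window``    - everything beyond: mechanics considered adverse
   for healing.

Rules are evaluated in order with half-open intervals [lo, hi); a value
sitting exactly on a class boundary therefore falls to the upper class
(lower-inclusive convention).  The exact numeric thresholds are
configurable; every pipeline property (partition, orderings, monotonicity)
is threshold-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import TetMesh
from .phantom import Segment

OUT_OF_WINDOW = "out_of_window"


@dataclass
class ClassRule:
    """One class: gamma_oct in [gamma_lo, gamma_hi) and stimulus in [h_lo, h_hi)."""

    name: str
    gamma_lo: float = 0.0
    gamma_hi: float = np.inf
    h_lo: float = -np.inf
    h_hi: float = np.inf


@dataclass
class HealingThresholds:
    """Ordered, first-match class rules plus the healing-window membership.

    ``axis_mode`` selects the hydrostatic stimulus: ``"strain"`` classifies
    on eps_h (dimensionless), ``"pressure"`` on hydrostatic pressure
    p = -3 K eps_h (MPa, compression positive); the interval bounds are then
    in the corresponding unit.
    """

    rules: list[ClassRule]
    healing_window: tuple[str, ...]
    axis_mode: str = "strain"

    def __post_init__(self) -> None:
        if self.axis_mode not in ("strain", "pressure"):
            raise ValueError("axis_mode must be 'strain' or 'pressure'")
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        last = self.rules[-1]
        if not (
            last.gamma_lo == 0.0
            and np.isinf(last.gamma_hi)
            and np.isneginf(last.h_lo)
            and np.isinf(last.h_hi)
        ):
            raise ValueError("last rule must be a catch-all so the partition is total")

    @property
    def class_names(self) -> list[str]:
        return [r.name for r in self.rules]

    def window_mask(self) -> np.ndarray:
        return np.array([r.name in self.healing_window for r in self.rules])


def default_thresholds(
    fibrous_in_window: bool = True, axis_mode: str = "strain"
) -> HealingThresholds:
    """Strain-based default scheme (Claes/Heigele-style magnitudes).

    gamma_oct bounds 0.05 / 0.15; hydrostatic-strain bound 5e-4 (or 0.15 MPa
    pressure when ``axis_mode='pressure'``).
    """
    h = 5e-4 if axis_mode == "strain" else 0.15
    rules = [
        ClassRule("intramembranous", 0.0, 0.05, -h, h),
        ClassRule("endochondral", 0.0, 0.05, -np.inf, -h)
        if axis_mode == "strain"
        else ClassRule("endochondral", 0.0, 0.05, h, np.inf),
        ClassRule("fibrous", 0.0, 0.15),
        ClassRule(OUT_OF_WINDOW),
    ]
    window = ["intramembranous", "endochondral"] + (["fibrous"] if fibrous_in_window else [])
    return HealingThresholds(rules=rules, healing_window=tuple(window), axis_mode=axis_mode)


def hydrostatic_stimulus(eps_h, E, nu, axis_mode: str):
    """eps_h itself, or hydrostatic pressure p = -3 K eps_h (MPa)."""
    if axis_mode == "strain":
        return np.asarray(eps_h, dtype=float)
    K = np.asarray(E, dtype=float) / (3.0 * (1.0 - 2.0 * np.asarray(nu, dtype=float)))
    return -3.0 * K * np.asarray(eps_h, dtype=float)


def classify_elements(
    eps_h,
    gamma_oct,
    thresholds: HealingThresholds,
    E=None,
    nu=None,
) -> np.ndarray:
    """Class index per element (index into ``thresholds.rules``), first match."""
    stim = (
        hydrostatic_stimulus(eps_h, E, nu, thresholds.axis_mode)
        if thresholds.axis_mode == "pressure"
        else np.asarray(eps_h, dtype=float)
    )
    g = np.asarray(gamma_oct, dtype=float)
    stim, g = np.broadcast_arrays(stim, g)
    out = np.full(g.shape, -1, dtype=int)
    for i, r in enumerate(thresholds.rules):
        hit = (
            (out < 0)
            & (g >= r.gamma_lo)
            & (g < r.gamma_hi)
            & (stim >= r.h_lo)
            & (stim < r.h_hi)
        )
        out[hit] = i
    return out


def classify_element(eps_h: float, gamma_oct: float, thresholds: HealingThresholds) -> str:
    """Scalar convenience wrapper returning the class name."""
    idx = classify_elements(np.array([eps_h]), np.array([gamma_oct]), thresholds)[0]
    return thresholds.rules[idx].name


def callus_volume_fractions(
    mesh: TetMesh,
    class_idx: np.ndarray,
    thresholds: HealingThresholds,
    callus_label: int = int(Segment.CALLUS),
) -> dict[str, float]:
    """Volume fraction of callus per class; fractions sum to one."""
    sel = np.asarray(mesh.element_label) == callus_label
    vols = mesh.element_volume()[sel]
    total = vols.sum()
    if total <= 0:
        raise ValueError("zero callus volume: no callus elements in mesh")
    idx = np.asarray(class_idx)[sel]
    return {
        r.name: float(vols[idx == i].sum() / total) for i, r in enumerate(thresholds.rules)
    }


def out_of_window_fraction(fractions: dict[str, float], thresholds: HealingThresholds) -> float:
    return float(
        sum(v for k, v in fractions.items() if k not in thresholds.healing_window)
    )


@dataclass
class HealingProfile:
    """Per-frame class volume fractions over a gait cycle, with summary."""

    frame: pd.DataFrame  # columns: frame, t_s, one column per class, out_fraction
    summary: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        long = self.frame.melt(
            id_vars=["frame", "t_s"], var_name="class", value_name="fraction"
        )
        long.to_csv(path, index=False)


def gait_profile(
    mesh: TetMesh,
    frame_invariants: list[dict],
    thresholds: HealingThresholds,
    times_s=None,
    callus_label: int = int(Segment.CALLUS),
) -> HealingProfile:
    """Classify the callus at every frame and aggregate volume fractions."""
    if not frame_invariants:
        raise ValueError("need at least one frame")
    rows = []
    for j, inv in enumerate(frame_invariants):
        idx = classify_elements(
            inv["eps_h"], inv["gamma_oct"], thresholds, mesh.element_E, mesh.element_nu
        )
        frac = callus_volume_fractions(mesh, idx, thresholds, callus_label)
        row = {"frame": j, "t_s": times_s[j] if times_s is not None else float(j)}
        row.update(frac)
        row["out_fraction"] = out_of_window_fraction(frac, thresholds)
        rows.append(row)
    df = pd.DataFrame(rows)
    out = df["out_fraction"].to_numpy()
    summary = {
        "max_out_fraction": float(out.max()),
        "argmax_frame": int(out.argmax()),
        "argmax_t_s": float(df["t_s"].iloc[int(out.argmax())]),
        "cycle_fraction_with_out": float(np.mean(out > 0)),
    }
    return HealingProfile(frame=df, summary=summary)


def sector_map(
    mesh: TetMesh,
    class_idx: np.ndarray,
    thresholds: HealingThresholds,
    n_sectors: int = 4,
    axis=(0.0, 0.0, 1.0),
    anterior=(0.0, 1.0, 0.0),
    center=None,
    callus_label: int = int(Segment.CALLUS),
) -> pd.DataFrame:
    """Out-of-window volume fraction per angular sector about the bone axis.

    Sectors are centred on the anterior direction and proceed toward the
    second in-plane axis; with the default four sectors the order is
    anterior, lateral, posterior, medial ("dorsal" = posterior).  Empty
    sectors report fraction 0 with ``empty=True``.
    """
    sel = np.asarray(mesh.element_label) == callus_label
    if not sel.any():
        raise ValueError("no callus elements in mesh")
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.asarray(anterior, float)
    a = a - (a @ axis) * axis
    a /= np.linalg.norm(a)
    b = np.cross(axis, a)

    cent = mesh.element_centroids()[sel]
    if center is None:
        center = cent.mean(axis=0)
    rel = cent - center
    ang = np.arctan2(rel @ b, rel @ a)  # 0 at anterior
    width = 2 * np.pi / n_sectors
    sector = np.floor(((ang + width / 2) % (2 * np.pi)) / width).astype(int)

    vols = mesh.element_volume()[sel]
    window = np.zeros(len(thresholds.rules), dtype=bool)
    for i, r in enumerate(thresholds.rules):
        window[i] = r.name in thresholds.healing_window
    out = ~window[np.asarray(class_idx)[sel]]

    names4 = ["anterior", "lateral", "posterior", "medial"]
    rows = []
    for s in range(n_sectors):
        m = sector == s
        vtot = vols[m].sum()
        rows.append(
            {
                "sector": s,
                "name": names4[s] if n_sectors == 4 else f"sector_{s}",
                "out_fraction": float(vols[m & out].sum() / vtot) if vtot > 0 else 0.0,
                "volume_mm3": float(vtot),
                "empty": bool(vtot == 0),
            }
        )
    return pd.DataFrame(rows)
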
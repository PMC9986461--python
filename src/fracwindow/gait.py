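"""Gait-trace processing and the parametric joint-load model.

The measured vertical ground-reaction force (GRF) drives the FE model
through a declared parametric substitute for a full musculoskeletal
inverse-dynamics stage: the axial tibial force is the GRF amplified by an
internal-force gain, and the non-axial loading (bending about the
medial-lateral axis plus a torsional component) ramps up through late
stance, peaking between terminal stance and pre-swing, with an amplitude
proportional to the per-stance peak GRF times a forefoot lever arm and
scaled linearly with walking velocity (tibial bending/torsion are known to
grow with walking speed).  The substitution is isolated behind the
:class:`~fracwindow.fem.LoadCase` interface, so externally computed joint
loads can replace it from CSV.

The module also provides the gait summaries used clinically: stance
detection, curve-shape classification (bicuspid/monocuspid), weight-bearing
compliance auditing and range-of-motion statistics with the parametric /
non-parametric test battery (Shapiro gate, t-test or Mann-Whitney for two
groups, ANOVA + Holm-Sidak or Kruskal-Wallis + Dunn for three).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .fem import LoadCase
from .phantom import G_MS2, GaitTrial

# ---------------------------------------------------------------------------
# stance detection and shape classification
# ---------------------------------------------------------------------------


def detect_steps(
    trial: GaitTrial,
    force_threshold_N: float | None = None,
    min_duration_s: float = 0.2,
) -> list[tuple[int, int]]:
    """Maximal contiguous runs with GRF above threshold, duration-filtered.

    The default threshold is 5 % of body weight.  Returns half-open index
    ranges ``(i0, i1)``; an empty list (with a warning) if nothing is found.
    """
    if force_threshold_N is None:
        force_threshold_N = 0.05 * trial.body_mass_kg * G_MS2
    above = trial.grf_N > force_threshold_N
    edges = np.diff(above.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    dt = float(np.median(np.diff(trial.time_s)))
    steps = [
        (int(i0), int(i1)) for i0, i1 in zip(starts, ends) if (i1 - i0) * dt >= min_duration_s
    ]
    if not steps:
        warnings.warn("no step found above the force threshold", stacklevel=2)
    return steps


def classify_shape(grf_segment: np.ndarray, p_rel: float = 0.05) -> str:
    """'bicuspid' (two qualifying maxima), 'monocuspid' (one) or 'irregular'."""
    seg = np.asarray(grf_segment, dtype=float)
    peak = seg.max()
    if not len(seg) or peak <= 0:
        raise ValueError("stance segment must be non-empty with a positive peak")
    locs, _ = signal.find_peaks(seg, prominence=p_rel * peak)
    n = len(locs)
    if n == 0:  # plateau or boundary maximum: analytic single bump
        return "monocuspid"
    if n == 1:
        return "monocuspid"
    if n == 2:
        return "bicuspid"
    return "irregular"


def compliance_audit(
    trial: GaitTrial, prescribed_cap_kg: float, tolerance: float = 0.02
) -> dict:
    """Peak load in kg, compliance flag, and the fraction of steps exceeding.

    Compliant iff the trial peak does not exceed the cap by more than
    ``tolerance`` (relative); a peak exactly at the cap is compliant.
    """
    peak_kg = float(trial.grf_N.max() / G_MS2)
    limit = prescribed_cap_kg * (1.0 + tolerance)
    steps = detect_steps(trial) if trial.grf_N.max() > 0 else []
    if steps:
        step_peaks = np.array([trial.grf_N[i0:i1].max() / G_MS2 for i0, i1 in steps])
        exceedance = float(np.mean(step_peaks > limit))
    else:
        exceedance = 0.0
    return {
        "peak_load_kg": peak_kg,
        "compliant": bool(peak_kg <= limit),
        "exceedance_fraction": exceedance,
        "n_steps": len(steps),
    }


@dataclass
class StanceEvents:
    """Characteristic instants of one stance phase (absolute sample indices)."""

    start: int
    end: int
    first_peak: int
    second_peak: int  # == first_peak for a monocuspid stance
    midstance: int
    terminal_stance: int
    pre_swing: int
    shape: str

    def __post_init__(self) -> None:
        for name in ("first_peak", "second_peak", "midstance", "terminal_stance", "pre_swing"):
            v = getattr(self, name)
            if not (self.start <= v < self.end):
                raise ValueError(f"{name} lies outside the stance")

    def phase_of(self, index: int) -> float:
        """Normalised stance phase of a sample index, in [0, 1]."""
        return (index - self.start) / max(self.end - 1 - self.start, 1)


def stance_events(
    grf_segment: np.ndarray,
    shape: str | None = None,
    offset: int = 0,
    p_rel: float = 0.05,
) -> StanceEvents:
    """Locate peaks, midstance, terminal stance and pre-swing in one stance.

    Bicuspid: the two prominent maxima are the peaks, midstance is the
    inter-peak minimum, terminal stance the second peak.  Monocuspid: the
    single peak serves as both maxima and as midstance.  Pre-swing is the
    last sample above 50 % of the second peak in both cases.
    """
    seg = np.asarray(grf_segment, dtype=float)
    if shape is None:
        shape = classify_shape(seg, p_rel)
    peak = seg.max()
    locs, props = signal.find_peaks(seg, prominence=p_rel * peak)
    if shape == "bicuspid":
        order = np.argsort(props["prominences"])[::-1][:2]
        p1, p2 = np.sort(locs[order])
        mid = p1 + int(np.argmin(seg[p1 : p2 + 1]))
        terminal = int(p2)
    else:
        p1 = p2 = int(locs[np.argmax(seg[locs])]) if len(locs) else int(np.argmax(seg))
        mid = terminal = int(p1)
    above = np.nonzero(seg >= 0.5 * seg[p2])[0]
    pre_swing = int(above[-1])
    return StanceEvents(
        start=offset,
        end=offset + len(seg),
        first_peak=offset + int(p1),
        second_peak=offset + int(p2),
        midstance=offset + int(mid),
        terminal_stance=offset + terminal,
        pre_swing=offset + pre_swing,
        shape=shape,
    )


# ---------------------------------------------------------------------------
# parametric joint-load model
# ---------------------------------------------------------------------------


@dataclass
class LoadModelParams:
    """Parameters of the parametric joint-load substitute.

    * ``axial_gain``: internal-force amplification of the GRF into the
      axial tibial force (muscle co-contraction), dimensionless.
    * ``lever_arm_mm``: forefoot lever converting the per-stance peak GRF
      into the late-stance bending-moment amplitude (ankle-to-centre-of-
      pressure distance during push-off).
    * ``ramp_exponent``: the moment envelope over normalised stance phase s
      is w(s) = s**a * (1 - s), normalised to unit peak (a =
      ``ramp_exponent``); it is negligible at midstance, peaks at
      s = a/(a+1) (between terminal stance and pre-swing, tracking the
      centre-of-pressure progression onto the forefoot) and vanishes at
      toe-off.
    * ``velocity_ref_kmh``: moments scale linearly with
      velocity / velocity_ref (tibial bending/torsion grow with speed).
    * ``torsion_fraction``: torsional moment as a fraction of the bending
      amplitude.
    * ``bending_sign``: sign of the bending moment about the medial-lateral
      (+x) axis; the default loads the posterior ("dorsal") callus in
      compression.
    """

    axial_gain: float = 2.5
    lever_arm_mm: float = 120.0
    ramp_exponent: float = 9.0
    velocity_ref_kmh: float = 1.5
    torsion_fraction: float = 0.25
    bending_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    bending_sign: float = 1.0
    load_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)


def _moment_envelope(stance_phase: float, a: float) -> float:
    """Unit-peak late-stance moment envelope w(s) = s^a (1 - s) / w_max."""
    s = float(np.clip(stance_phase, 0.0, 1.0))
    w_max = (a / (a + 1.0)) ** a * (1.0 / (a + 1.0))
    return s**a * (1.0 - s) / w_max


def _frame_load(
    grf_N: float,
    stance_phase: float,
    peak_grf_N: float,
    velocity_kmh: float,
    params: LoadModelParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial force (N) and moment (N*mm) vectors for one gait frame.

    The moment amplitude is the per-stance peak GRF through the forefoot
    lever, gated by the late-stance envelope, so it vanishes at touchdown
    and toe-off and peaks around pre-swing.
    """
    F = np.asarray(params.load_direction, float) * params.axial_gain * grf_N
    amp = (
        peak_grf_N
        * params.lever_arm_mm
        * _moment_envelope(stance_phase, params.ramp_exponent)
        * (velocity_kmh / params.velocity_ref_kmh)
    )
    bend = params.bending_sign * np.asarray(params.bending_axis, float)
    torsion = np.array([0.0, 0.0, 1.0]) * params.torsion_fraction
    M = amp * (bend + torsion)
    return F, M


def loads_from_gait(
    trial: GaitTrial,
    events: StanceEvents,
    anthropometry: Mapping[str, float],
    params: LoadModelParams,
    fixed_nodes: np.ndarray,
    plateau_nodes: np.ndarray,
    n_frames: int = 16,
    include_swing_frames: int = 0,
) -> list[LoadCase]:
    """Per-frame FE load cases sampled across one stance (plus swing zeros)."""
    if "body_mass_kg" not in anthropometry:
        raise ValueError("anthropometry must provide body_mass_kg")
    peak = float(trial.grf_N[events.start : events.end].max())
    cases = []
    for j in range(n_frames):
        s = j / max(n_frames - 1, 1)
        idx = events.start + s * (events.end - 1 - events.start)
        grf = float(np.interp(idx, np.arange(len(trial.grf_N)), trial.grf_N))
        F, M = _frame_load(grf, s, peak, trial.velocity_kmh, params)
        cases.append(
            LoadCase(
                name=f"frame_{j}",
                fixed_nodes=fixed_nodes,
                point_loads=[(plateau_nodes, F)],
                moments=[(plateau_nodes, M)],
                time_s=float(np.interp(idx, np.arange(len(trial.time_s)), trial.time_s)),
            )
        )
    for j in range(include_swing_frames):
        cases.append(
            LoadCase(
                name=f"swing_{j}",
                fixed_nodes=fixed_nodes,
                point_loads=[(plateau_nodes, np.zeros(3))],
                time_s=None,
            )
        )
    return cases


def load_case_at_phase(
    trial: GaitTrial,
    events: StanceEvents,
    phase: str,
    anthropometry: Mapping[str, float],
    params: LoadModelParams,
    fixed_nodes: np.ndarray,
    plateau_nodes: np.ndarray,
) -> LoadCase:
    """Single load case at a named gait instant.

    ``phase`` is one of ``midstance`` (high axial loading),
    ``terminal_stance`` (high loading with non-axial forces) or
    ``pre_swing`` (moment maximum).
    """
    if "body_mass_kg" not in anthropometry:
        raise ValueError("anthropometry must provide body_mass_kg")
    idx = {
        "midstance": events.midstance,
        "terminal_stance": events.terminal_stance,
        "pre_swing": events.pre_swing,
    }.get(phase)
    if idx is None:
        raise ValueError(f"unknown phase {phase!r}")
    F, M = _frame_load(
        float(trial.grf_N[idx]),
        events.phase_of(idx),
        float(trial.grf_N[events.start : events.end].max()),
        trial.velocity_kmh,
        params,
    )
    return LoadCase(
        name=phase,
        fixed_nodes=fixed_nodes,
        point_loads=[(plateau_nodes, F)],
        moments=[(plateau_nodes, M)],
        time_s=float(trial.time_s[idx]),
    )


def load_cases_from_csv(
    path: str | Path, fixed_nodes: np.ndarray, plateau_nodes: np.ndarray
) -> list[LoadCase]:
    """Read externally computed joint loads, replacing the parametric model.

    Expected columns: ``time_s,Fx_N,Fy_N,Fz_N,Mx_Nmm,My_Nmm,Mz_Nmm``.
    """
    df = pd.read_csv(path)
    cases = []
    for j, row in df.iterrows():
        cases.append(
            LoadCase(
                name=f"frame_{j}",
                fixed_nodes=fixed_nodes,
                point_loads=[(plateau_nodes, row[["Fx_N", "Fy_N", "Fz_N"]].to_numpy(float))],
                moments=[(plateau_nodes, row[["Mx_Nmm", "My_Nmm", "Mz_Nmm"]].to_numpy(float))],
                time_s=float(row["time_s"]),
            )
        )
    return cases


# ---------------------------------------------------------------------------
# range-of-motion statistics
# ---------------------------------------------------------------------------

ALPHA = 0.05


def _normal(groups: Sequence[np.ndarray]) -> bool:
    """Shapiro-Wilk gate at alpha = 0.05 on every group (with > 3 samples)."""
    for g in groups:
        if len(g) > 3:
            if np.ptp(g) == 0:  # degenerate: constant data, treat as parametric
                continue
            if stats.shapiro(g).pvalue < ALPHA:
                return False
    return True


def two_group_test(x: np.ndarray, y: np.ndarray) -> tuple[str, float]:
    """Unpaired t-test when both groups pass normality, else Mann-Whitney."""
    if _normal([x, y]):
        return "t-test", float(stats.ttest_ind(x, y).pvalue)
    return "mann-whitney", float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def dunn_test(groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise post-hoc with Bonferroni correction."""
    all_vals = np.concatenate(groups)
    ranks = stats.rankdata(all_vals)
    N = len(all_vals)
    # tie correction
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (N**3 - N) if N > 1 else 1.0
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    means = [rg.mean() for rg in rank_groups]
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(
                (N * (N + 1) / 12.0) * tie * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
            )
            z = abs(means[i] - means[j]) / se
            p = min(1.0, 2.0 * (1.0 - stats.norm.cdf(z)) * m)
            rows.append({"group_a": i, "group_b": j, "z": z, "p": p})
    return pd.DataFrame(rows)


def three_group_test(groups: Sequence[np.ndarray]) -> tuple[str, float, pd.DataFrame]:
    """One-way ANOVA + Holm-Sidak pairwise, or Kruskal-Wallis + Dunn."""
    from statsmodels.stats.multitest import multipletests

    if _normal(groups):
        p_global = float(stats.f_oneway(*groups).pvalue)
        raw = []
        pairs = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                raw.append(stats.ttest_ind(groups[i], groups[j]).pvalue)
                pairs.append((i, j))
        adj = multipletests(raw, alpha=ALPHA, method="holm-sidak")[1]
        post = pd.DataFrame(
            [{"group_a": i, "group_b": j, "p": p} for (i, j), p in zip(pairs, adj)]
        )
        return "anova+holm-sidak", p_global, post
    p_global = float(stats.kruskal(*groups).pvalue)
    return "kruskal+dunn", p_global, dunn_test(groups)


@dataclass
class RomSummary:
    """Range-of-motion table and group comparisons."""

    table: pd.DataFrame  # group, channel, min, max, mean_delta, sem, n_steps
    comparisons: pd.DataFrame  # channel, test, p, significant

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _per_step_ranges(trial: GaitTrial, steps: list[tuple[int, int]] | None = None):
    """Per-channel per-step angle ranges; steps segmented at stance onsets."""
    if steps is None:
        steps = detect_steps(trial)
    onsets = [i0 for i0, _ in steps]
    bounds = list(zip(onsets, onsets[1:] + [len(trial.time_s)]))
    out = {}
    for name, trace in trial.joint_angles_deg.items():
        deltas = np.array([np.ptp(trace[a:b]) for a, b in bounds])
        out[name] = {
            "min": float(trace.min()),
            "max": float(trace.max()),
            "deltas": deltas,
        }
    return out


def rom_summary(trials: Mapping[str, GaitTrial]) -> RomSummary:
    """ROM statistics per group (side or velocity) with group comparisons.

    For two groups an unpaired t-test / Mann-Whitney is used per channel; for
    three, one-way ANOVA with Holm-Sidak post-hoc or Kruskal-Wallis with
    Dunn's test (normality-gated).  Significance at p < 0.05.  A group with a
    single step reports ranges but an undefined (NaN, flagged) SEM.
    """
    per_group = {g: _per_step_ranges(t) for g, t in trials.items()}
    channels = sorted({c for stats_ in per_group.values() for c in stats_})

    rows = []
    for g, stats_ in per_group.items():
        for ch in channels:
            if ch not in stats_:
                continue
            d = stats_[ch]["deltas"]
            rows.append(
                {
                    "group": g,
                    "channel": ch,
                    "min_deg": stats_[ch]["min"],
                    "max_deg": stats_[ch]["max"],
                    "mean_delta_deg": float(d.mean()),
                    "sem_deg": float(stats.sem(d)) if len(d) > 1 else np.nan,
                    "sem_defined": len(d) > 1,
                    "n_steps": len(d),
                }
            )
    table = pd.DataFrame(rows)

    comp_rows = []
    names = list(per_group)
    for ch in channels:
        groups = [per_group[g][ch]["deltas"] for g in names if ch in per_group[g]]
        if len(groups) == 2:
            test, p = two_group_test(groups[0], groups[1])
        elif len(groups) >= 3:
            test, p, _ = three_group_test(groups)
        else:
            continue
        comp_rows.append(
            {"channel": ch, "groups": "|".join(names), "test": test, "p": p,
             "significant": bool(p < ALPHA)}
        )
    comparisons = pd.DataFrame(comp_rows)
    return RomSummary(table=table, comparisons=comparisons)
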
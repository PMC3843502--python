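"""Clinical-style post-processing of simulated steps.

A gait cycle runs between two consecutive contacts of the same leg, i.e.
two consecutive steps: the leg's stance step (double support + its single
support) followed by the opposite leg's stance step (double support + the
leg's swing).  Joint angles and moments for one side are assembled over
that window, kinetic series are low-pass filtered with a zero-phase
fourth-order Butterworth at 5 Hz, and everything is resampled onto the
standard 101-point 0-100 %-gait-cycle grid with the double-support /
single-support / swing bands expressed in % GC.

Clinical sign conventions for reports and exports (degrees; internal
angles are absolute segment orientations in radians):

    hip flexion      +  = thigh forward of the pelvis segment
    knee flexion     +  = shank folded behind the thigh
    ankle dorsiflex. +  = foot pitched up from the perpendicular posture

Joint moments are reported about the same axes: hip flexion moment +,
knee extension moment +, ankle plantar-flexion moment + (the sign flips of
the raw actuator torques are part of the mapping).  Moments are exported
both raw [N m] and body-mass normalized [N m / kg].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .dynamics import (IDX_LFT, IDX_LSH, IDX_LTH, IDX_PEL, IDX_RFT, IDX_RSH,
                       IDX_RTH, BipedModel)
from .hybrid_sim import StepRecord

GRID = np.linspace(0.0, 100.0, 101)

_ANGLE_IDX = {"left": (IDX_LTH, IDX_LSH, IDX_LFT),
              "right": (IDX_RTH, IDX_RSH, IDX_RFT)}
_TORQUE_COL = {"left": (0, 1, 2), "right": (3, 4, 5)}


class NonContiguousRecordsError(ValueError):
    """The two step records are not contiguous in time."""


@dataclass
class GaitCycleRecord:
    """One leg's kinematics/kinetics over a full gait cycle on the
    101-point % GC grid, with phase bands and scalar descriptors."""
    side: str
    grid: np.ndarray
    angles: dict            # hip/knee/ankle -> deg, clinical signs
    moments: dict           # hip/knee/ankle -> N m (filtered)
    moments_norm: dict      # N m / kg
    bands: dict             # ds1/ss/ds2/swing -> (start %, end %)
    v_gait: float
    cycle_duration: float
    body_mass: float


def clinical_angles(q: np.ndarray, side: str) -> dict:
    """Map absolute segment orientations to clinical joint angles [deg]."""
    ith, ish, ift = _ANGLE_IDX[side]
    deg = 180.0 / math.pi
    return {
        "hip": (q[:, ith] - q[:, IDX_PEL]) * deg,
        "knee": (q[:, ith] - q[:, ish]) * deg,
        "ankle": (q[:, ift] - q[:, ish] - math.pi / 2.0) * deg,
    }


def clinical_moments(u: np.ndarray, side: str) -> dict:
    """Map actuator torques to clinical joint moments [N m]:
    hip flexion +, knee extension +, ankle plantar flexion +."""
    ih, ik, ia = _TORQUE_COL[side]
    return {"hip": u[:, ih].copy(), "knee": u[:, ik].copy(), "ankle": -u[:, ia]}


def filter_kinetics(series: np.ndarray, sample_rate: float,
                    cutoff_hz: float = 5.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    The filter is designed at the given order and cutoff; applying it in
    both directions doubles the effective attenuation and removes phase
    lag, the convention in gait analysis.  DC gain is exactly 1.
    """
    series = np.asarray(series, dtype=float)
    if sample_rate < 100.0:
        raise ValueError(f"sample rate must be >= 100 Hz, got {sample_rate}")
    b, a = butter(order, cutoff_hz / (sample_rate / 2.0))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[-1] <= padlen:
        raise ValueError("series too short for filter warm-up")
    return filtfilt(b, a, series, axis=-1)


def _resample(t_src: np.ndarray, y: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    return np.interp(t_new, t_src, y)


def assemble_gait_cycle(rec_a: StepRecord, rec_b: StepRecord, side: str,
                        model: BipedModel,
                        filter_rate: float = 1000.0) -> GaitCycleRecord:
    """Assemble one gait cycle for ``side`` from two consecutive steps.

    ``rec_a`` must be the step in which ``side`` is the stance leg;
    ``rec_b`` (in which the side swings) must start where ``rec_a`` ends.
    """
    if rec_a.stance_side != side:
        raise ValueError(f"first record must have stance side '{side}'")
    if rec_b.stance_side == side:
        raise ValueError("second record must be the opposite leg's stance step")
    if abs(rec_b.t_start - rec_a.t_contact) > 1e-9:
        raise NonContiguousRecordsError(
            f"records not contiguous: {rec_a.t_contact} vs {rec_b.t_start}")
    if rec_a.u is None or rec_b.u is None:
        raise ValueError("records need kinetics; call compute_kinetics first")

    t0 = rec_a.t_start
    T = rec_b.t_contact - t0
    # uniform fine grid across the two steps for filtering
    n = max(int(round(T * filter_rate)) + 1, 64)
    t_fine = np.linspace(0.0, T, n)
    fs = (n - 1) / T

    t_src = np.concatenate([rec_a.t, rec_b.t]) - t0
    q_src = np.vstack([rec_a.q, rec_b.q])
    u_src = np.vstack([rec_a.u, rec_b.u])
    # de-duplicate the shared boundary sample
    keep = np.concatenate([[True], np.diff(t_src) > 0])
    t_src, q_src, u_src = t_src[keep], q_src[keep], u_src[keep]

    q_fine = np.stack([_resample(t_src, q_src[:, j], t_fine)
                       for j in range(q_src.shape[1])], axis=1)
    u_fine = np.stack([_resample(t_src, u_src[:, j], t_fine)
                       for j in range(u_src.shape[1])], axis=1)

    ang = clinical_angles(q_fine, side)
    mom = clinical_moments(u_fine, side)
    mom = {k: filter_kinetics(v, fs) for k, v in mom.items()}

    pct = t_fine / T * 100.0
    angles = {k: _resample(pct, v, GRID) for k, v in ang.items()}
    moments = {k: _resample(pct, v, GRID) for k, v in mom.items()}
    moments_norm = {k: v / model.total_mass for k, v in moments.items()}

    def pc(t):
        return (t - t0) / T * 100.0

    bands = {
        "ds1": (0.0, pc(rec_a.t_takeoff)),
        "ss": (pc(rec_a.t_takeoff), pc(rec_a.t_contact)),
        "ds2": (pc(rec_a.t_contact), pc(rec_b.t_takeoff)),
        "swing": (pc(rec_b.t_takeoff), 100.0),
    }
    v_gait = ((rec_a.step_length + rec_b.step_length) / T)
    return GaitCycleRecord(side=side, grid=GRID.copy(), angles=angles,
                           moments=moments, moments_norm=moments_norm,
                           bands=bands, v_gait=v_gait, cycle_duration=T,
                           body_mass=model.total_mass)


# --------------------------------------------------------------------------
# scalar descriptors
# --------------------------------------------------------------------------

def _window_mask(grid, lo, hi):
    return (grid >= lo) & (grid <= hi)


def metrics(gc: GaitCycleRecord) -> dict:
    """Scalar gait descriptors.

    Ankle plantar-flexion moment peaks follow the % GC window convention:
    first peak in early/mid stance (0-40 % GC), second peak during push-off
    (40-50 % GC); mass-normalized variants carry the ``_norm`` suffix.
    """
    g = gc.grid
    stance_end = gc.bands["ds2"][1]
    stance = _window_mask(g, 0.0, stance_end)
    early = _window_mask(g, 0.0, 40.0)
    push = _window_mask(g, 40.0, 50.0)
    ds_frac = (gc.bands["ds1"][1] - gc.bands["ds1"][0]) + \
              (gc.bands["ds2"][1] - gc.bands["ds2"][0])
    out = {
        "peak_stance_knee_flexion_deg": float(np.max(gc.angles["knee"][stance])),
        "peak_stance_ankle_plantarflexion_deg":
            float(np.max(-gc.angles["ankle"][stance])),
        "double_support_fraction_pct": float(ds_frac),
        "gait_velocity_m_s": float(gc.v_gait),
        "cycle_duration_s": float(gc.cycle_duration),
        "ankle_pf_moment_peak1_Nm": float(np.max(gc.moments["ankle"][early])),
        "ankle_pf_moment_peak2_Nm": float(np.max(gc.moments["ankle"][push])),
        "peak_knee_extension_moment_Nm":
            float(np.max(gc.moments["knee"][stance])),
    }
    for key in ("ankle_pf_moment_peak1", "ankle_pf_moment_peak2",
                "peak_knee_extension_moment"):
        out[key + "_Nm_per_kg"] = out[key + "_Nm"] / gc.body_mass
    return out


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def cycle_frame(gc: GaitCycleRecord) -> pd.DataFrame:
    cols = {"pct_gc": gc.grid}
    for j in ("hip", "knee", "ankle"):
        cols[f"{j}_angle_deg"] = gc.angles[j]
    for j in ("hip", "knee", "ankle"):
        cols[f"{j}_moment_Nm"] = gc.moments[j]
        cols[f"{j}_moment_Nm_per_kg"] = gc.moments_norm[j]
    return pd.DataFrame(cols)


def export(gcs: dict, out_dir, plots: bool = False) -> list:
    """Write per-cycle CSVs and a descriptor table.

    ``gcs`` maps a label (e.g. 'pi1') to a GaitCycleRecord.  Returns the
    list of written paths.  With ``plots=True`` a panel figure of angles
    and moments across all cycles is written as well.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for label, gc in gcs.items():
        p = out_dir / f"cycle_{label}.csv"
        cycle_frame(gc).to_csv(p, index=False, float_format="%.12g")
        written.append(p)
        rows.append({"label": label, **metrics(gc)})
    dp = out_dir / "descriptors.csv"
    pd.DataFrame(rows).to_csv(dp, index=False, float_format="%.12g")
    written.append(dp)
    if plots:
        written.append(_plot_panels(gcs, out_dir))
    return written


def _plot_panels(gcs: dict, out_dir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 3, figsize=(12, 6), sharex=True)
    joints = ("hip", "knee", "ankle")
    for label, gc in gcs.items():
        for j, joint in enumerate(joints):
            axes[0, j].plot(gc.grid, gc.angles[joint], label=label)
            axes[1, j].plot(gc.grid, gc.moments_norm[joint], label=label)
    for j, joint in enumerate(joints):
        axes[0, j].set_title(f"{joint} angle [deg]")
        axes[1, j].set_title(f"{joint} moment [N m/kg]")
        axes[1, j].set_xlabel("% gait cycle")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "cycles.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def read_cycle_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
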
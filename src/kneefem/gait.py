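"""Gait stream processing: stance events, joint angles, EMG envelopes.

Stance is detected from the vertical ground-reaction force and subdivided at
the Perry fractions — initial contact (IC, 0%), load response (LR, 16%),
mid stance (MS, 50%), terminal stance (TS, 83%) and pre-swing (PS, 100%).
Knee angles come from a joint-coordinate-system (Grood–Suntay-style)
decomposition of the femur-frame/tibia-frame relative orientation into
clinical flexion ("bending"), varus ("inversion") and internal ("inward")
rotation; the tibia–floor orientation uses the same decomposition against the
global frame. EMG is full-wave rectified, smoothed with a fourth-order
zero-lag low-pass at 6 Hz (a forward–backward second-order cascade), and
normalised to its walking-cycle maximum.

Segment frames are built from the lateral Plug-In-Gait marker subset: the
femur frame from the knee marker (RKNE), the hip point (midpoint of RASI and
RPSI) and the lateral thigh marker (RTHI); the tibia frame from the ankle
marker (RANK), RKNE and the lateral shank marker (RTIB). The long axis is Z,
the orthogonalised lateral direction X, and Y completes the right-handed
triad.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from kneefem.model import decompose_joint_rotation

#: Perry's stance-phase event fractions.
STANCE_FRACTIONS = {"IC": 0.0, "LR": 0.16, "MS": 0.50, "TS": 0.83, "PS": 1.00}

EMG_CHANNELS = ("RF", "VM", "VL", "BF", "ST")

MARKER_NAMES = (
    "RASI", "LASI", "RPSI", "LPSI", "RTHI", "RKNE", "RTIB", "RANK", "RHEE", "RTOE",
)


@dataclass
class GaitRecording:
    """Marker (200 Hz), GRF (1200 Hz) and EMG (2000 Hz) streams.

    ``markers`` has a ``time`` column plus ``<NAME>_x/_y/_z`` columns (mm);
    ``grf`` has ``time, fx, fy, fz`` (N, fz vertical); ``emg`` has ``time``
    plus one column per channel (mV).
    """

    markers: pd.DataFrame
    grf: pd.DataFrame
    emg: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def marker(self, name: str) -> np.ndarray:
        return self.markers[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy()

    def marker_frame(self, i: int) -> dict:
        """Dict of marker name -> xyz at frame index i."""
        row = self.markers.iloc[i]
        return {n: np.array([row[f"{n}_x"], row[f"{n}_y"], row[f"{n}_z"]]) for n in MARKER_NAMES}

    def frame_at_time(self, t: float) -> dict:
        i = int(np.argmin(np.abs(self.markers["time"].to_numpy() - t)))
        return self.marker_frame(i)

    # ---------------------------------------------------------------- I/O
    def save_csv(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.markers.to_csv(d / "markers.csv", index=False)
        self.grf.to_csv(d / "grf.csv", index=False)
        self.emg.to_csv(d / "emg.csv", index=False)
        (d / "meta.json").write_text(json.dumps(self.meta, sort_keys=True))

    @classmethod
    def load_csv(cls, directory: str | Path) -> "GaitRecording":
        d = Path(directory)
        return cls(
            markers=pd.read_csv(d / "markers.csv"),
            grf=pd.read_csv(d / "grf.csv"),
            emg=pd.read_csv(d / "emg.csv"),
            meta=json.loads((d / "meta.json").read_text()),
        )


@dataclass
class StanceEvents:
    """Stance window and the five Perry event timestamps."""

    start: float
    end: float
    fractions: dict = field(default_factory=lambda: dict(STANCE_FRACTIONS))
    times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("stance end must follow start")
        if not self.times:
            self.times = {
                k: self.start + f * (self.end - self.start) for k, f in self.fractions.items()
            }

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "fractions": self.fractions,
            "times": self.times,
        }


def detect_stance(grf: pd.DataFrame, threshold: float = 20.0) -> StanceEvents:
    """Detect the stance window as the longest interval with vertical GRF above
    ``threshold`` (N) and place the five Perry events inside it."""
    t = grf["time"].to_numpy()
    fz = grf["fz"].to_numpy()
    above = fz > threshold
    if not above.any():
        raise ValueError(f"no samples with vertical GRF above {threshold} N")
    # longest contiguous run
    edges = np.diff(above.astype(int))
    starts = np.where(edges == 1)[0] + 1
    ends = np.where(edges == -1)[0] + 1
    if above[0]:
        starts = np.insert(starts, 0, 0)
    if above[-1]:
        ends = np.append(ends, len(above))
    lengths = ends - starts
    k = int(np.argmax(lengths))
    return StanceEvents(start=float(t[starts[k]]), end=float(t[ends[k] - 1]))


# ------------------------------------------------------------------ frames

def _frame(origin: np.ndarray, z_point: np.ndarray, x_point: np.ndarray) -> np.ndarray:
    """Right-handed segment frame: Z along origin→z_point, X the
    orthogonalised origin→x_point direction, Y = Z × X. Returns the 3×3
    world-from-local rotation (columns X, Y, Z)."""
    z = np.asarray(z_point, float) - origin
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("degenerate segment frame (coincident markers)")
    z = z / nz
    x = np.asarray(x_point, float) - origin
    x = x - (x @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("degenerate segment frame (collinear markers)")
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def segment_frames(markers: dict) -> tuple[np.ndarray, np.ndarray]:
    """(R_femur, R_tibia) world-from-segment rotations from one marker frame."""
    hip = 0.5 * (np.asarray(markers["RASI"], float) + np.asarray(markers["RPSI"], float))
    R_f = _frame(np.asarray(markers["RKNE"], float), hip, np.asarray(markers["RTHI"], float))
    R_t = _frame(np.asarray(markers["RANK"], float), np.asarray(markers["RKNE"], float),
                 np.asarray(markers["RTIB"], float))
    return R_f, R_t


def knee_angles_jcs(markers: dict) -> tuple[float, float, float]:
    """Knee angles (flexion, varus, internal rotation) in degrees at one frame.

    Decomposes the femur-relative-to-tibia orientation with the intrinsic
    flexion → varus → internal-rotation sequence of the joint coordinate
    system. Invariant under any global rigid motion of all markers.
    """
    R_f, R_t = segment_frames(markers)
    R_rel = Rotation.from_matrix(R_f.T @ R_t)
    bending, inversion, inward = decompose_joint_rotation(R_rel)
    return bending, inversion, inward


def tibia_floor_angles(markers: dict) -> tuple[float, float, float]:
    """Tibia orientation relative to the floor, (inversion, bending, inward) deg.

    The floor is the global horizontal plane; a vertical tibia returns
    (0, 0, 0) and pure translations change nothing.
    """
    _, R_t = segment_frames(markers)
    bending, inversion, inward = decompose_joint_rotation(Rotation.from_matrix(R_t))
    return inversion, bending, inward


# ------------------------------------------------------------------ EMG

def emg_envelope(
    x: np.ndarray,
    fs: float,
    cutoff: float = 6.0,
    order: int = 4,
    normalize: bool = True,
) -> np.ndarray:
    """Linear envelope: full-wave rectification, zero-lag low-pass, normalisation.

    The filter is a forward–backward (zero-lag) Butterworth cascade whose
    effective order is ``order`` (so the default runs a second-order filter
    twice). With ``normalize`` the envelope is divided by its maximum over the
    record, giving values in [0, 1] with max exactly 1; tiny filter
    undershoots are clipped at 0.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x != 0):
        raise ValueError("all-zero signal: envelope normalisation undefined")
    if order % 2:
        raise ValueError("effective filter order must be even for a zero-lag cascade")
    rect = np.abs(x)
    b, a = butter(order // 2, cutoff / (fs / 2.0))
    env = filtfilt(b, a, rect)
    env = np.clip(env, 0.0, None)
    if normalize:
        m = env.max()
        if m <= 0:
            raise ValueError("degenerate envelope: maximum is zero")
        env = env / m
    return env


def activation_similarity(simulated: np.ndarray, envelope: np.ndarray) -> float:
    """Zero-lag Pearson correlation between a simulated activation and a
    measured EMG envelope sampled on a common %-cycle axis."""
    a = np.asarray(simulated, dtype=float)
    b = np.asarray(envelope, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share one common cycle axis")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(a, b)[0, 1])


def resample_percent_cycle(t: np.ndarray, x: np.ndarray, t0: float, t1: float, n: int = 101) -> np.ndarray:
    """Linear resampling of (t, x) onto n evenly spaced points of [t0, t1]."""
    tt = np.linspace(t0, t1, n)
    return np.interp(tt, np.asarray(t, float), np.asarray(x, float))
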
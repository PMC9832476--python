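"""Per-frame occupancy features of the selectivity filter and cavity.

Each frame is reduced to twelve numbers:

* ``s0_k .. s4_k`` — K+ occupancy of binding sites S0–S4: the coordination
  number of all potassium ions at each site center with cutoff 1.4 Å (about
  half the site length, so the value tends to 1 for an ion at the center and
  to 0 for an empty site);
* ``s0_oxy .. s4_oxy`` — oxygen coordination of each site: the coordination
  number of every oxygen atom in the system at the site center with cutoff
  3.2 Å (about the radius of a K+ first hydration shell); values above ~5
  characterize an intact, conductive-like site;
* ``cavity_k`` — the maximum of the potassium coordination number over a
  segment of equally spaced points along the pore axis through the
  intracellular cavity (the maximum makes the estimate independent of where
  along the axis the ion sits);
* ``cavity_w`` — the minimum of the oxygen coordination number along the same
  segment, which flags dehydrated stretches of the cavity.

The probed segment starts 2 Å below the lower boundary of S4 (the mean plane
of its intracellular bounding ring) and extends 20 Å toward the intracellular
compartment, sampled every 0.5 Å by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError
from .geometry import ION_PARAMS, OXYGEN_PARAMS, SwitchingParams
from .structure_io import ChannelTopology, FrameSet

__all__ = [
    "FEATURE_COLUMNS", "K_OCCUPANCY_COLUMNS", "OXYGEN_COLUMNS",
    "AxisProfile", "DwellEvent",
    "site_k_occupancy", "site_oxygen_coordination", "cavity_axis_profile",
    "cavity_k_presence", "cavity_hydration", "compute_features",
    "dwell_events", "write_features", "read_features",
]

K_OCCUPANCY_COLUMNS = [f"s{i}_k" for i in range(5)]
OXYGEN_COLUMNS = [f"s{i}_oxy" for i in range(5)]
FEATURE_COLUMNS = K_OCCUPANCY_COLUMNS + OXYGEN_COLUMNS + ["cavity_k",
                                                          "cavity_w"]


class Species(str, Enum):
    POTASSIUM = "potassium"
    OXYGEN = "oxygen"


@dataclass(frozen=True)
class AxisProfile:
    """Coordination numbers at equally spaced points along the pore axis."""

    points: np.ndarray   # (n_points, 3)
    spacing: float
    values: np.ndarray   # (n_points,)


@dataclass(frozen=True)
class DwellEvent:
    """A contiguous stay of one ion inside the cavity segment.

    ``exit_frame`` is exclusive (the first frame after the ion has left), so
    ``duration = (exit_frame - entry_frame) * frame_interval`` is the number
    of frames spent inside times the saving interval.
    """

    ion_id: int
    entry_frame: int
    exit_frame: int
    duration: float  # ns


# ---------------------------------------------------------------------------
# axis geometry
# ---------------------------------------------------------------------------

def _site_centers(frame_set: FrameSet, topology: ChannelTopology,
                  ) -> np.ndarray:
    """Site centers per frame, shape (n_frames, 5, 3)."""
    coords = frame_set.coordinates
    centers = np.empty((frame_set.n_frames, 5, 3))
    for i, site in enumerate(topology.site_definitions):
        centers[:, i] = coords[:, site.atom_indices, :].mean(axis=1)
    return centers


def _axis_geometry(frame_set: FrameSet, topology: ChannelTopology,
                   frame: int):
    """Axis direction (unit, pointing intracellular), anchor and the axial
    offset of the cavity-segment start for one frame."""
    coords = frame_set.frame(frame)
    centers = np.array([
        coords[s.atom_indices].mean(axis=0)
        for s in topology.site_definitions
    ])
    axis = topology.pore_axis.copy()
    intr = centers[4] - centers[0]  # S0 (extracellular) -> S4 (intracellular)
    if np.dot(axis, intr) < 0:
        axis = -axis
    anchor = centers.mean(axis=0)
    s4_lower = coords[list(topology.site_definitions[4].lower_ring)]
    t_lower = float(np.dot(s4_lower.mean(axis=0) - anchor, axis))
    t_start = t_lower + topology.cavity_probe.offset
    return axis, anchor, t_start


def _axis_points(frame_set: FrameSet, topology: ChannelTopology,
                 frame: int) -> np.ndarray:
    axis, anchor, t_start = _axis_geometry(frame_set, topology, frame)
    probe = topology.cavity_probe
    t = t_start + probe.spacing * np.arange(probe.n_points)
    return anchor + t[:, None] * axis


# ---------------------------------------------------------------------------
# per-frame features
# ---------------------------------------------------------------------------

def _coordination_at(points: np.ndarray, positions: np.ndarray,
                     params: SwitchingParams) -> np.ndarray:
    """Coordination number at each of several probe points (vectorized)."""
    if positions.shape[0] == 0:
        return np.zeros(points.shape[0])
    d = np.linalg.norm(points[:, None, :] - positions[None, :, :], axis=-1)
    return (1.0 / (1.0 + (d / params.d_c) ** params.numerator_exponent)
            ).sum(axis=1)


def site_k_occupancy(frame_set: FrameSet, topology: ChannelTopology,
                     frame: int = 0,
                     params: SwitchingParams = ION_PARAMS) -> np.ndarray:
    """K+ occupancy of S0–S4 for one frame (5-vector)."""
    coords = frame_set.frame(frame)
    centers = np.array([coords[s.atom_indices].mean(axis=0)
                        for s in topology.site_definitions])
    ions = coords[topology.potassium_selection]
    return _coordination_at(centers, ions, params)


def site_oxygen_coordination(frame_set: FrameSet, topology: ChannelTopology,
                             frame: int = 0,
                             params: SwitchingParams = OXYGEN_PARAMS,
                             ) -> np.ndarray:
    """Oxygen coordination of S0–S4 for one frame (5-vector)."""
    coords = frame_set.frame(frame)
    centers = np.array([coords[s.atom_indices].mean(axis=0)
                        for s in topology.site_definitions])
    oxygens = coords[topology.oxygen_selection]
    return _coordination_at(centers, oxygens, params)


def cavity_axis_profile(frame_set: FrameSet, topology: ChannelTopology,
                        species: Species | str = Species.POTASSIUM,
                        frame: int = 0) -> AxisProfile:
    """Coordination-number profile along the cavity axis segment."""
    species = Species(species)
    points = _axis_points(frame_set, topology, frame)
    coords = frame_set.frame(frame)
    if species is Species.POTASSIUM:
        positions, params = coords[topology.potassium_selection], ION_PARAMS
    else:
        positions, params = coords[topology.oxygen_selection], OXYGEN_PARAMS
    values = _coordination_at(points, positions, params)
    return AxisProfile(points, topology.cavity_probe.spacing, values)


def cavity_k_presence(frame_set: FrameSet, topology: ChannelTopology,
                      frame: int = 0) -> float:
    """Presence of K+ in the cavity: max of the potassium axis profile."""
    return float(cavity_axis_profile(frame_set, topology,
                                     Species.POTASSIUM, frame).values.max())


def cavity_hydration(frame_set: FrameSet, topology: ChannelTopology,
                     frame: int = 0) -> float:
    """Hydration of the cavity: min of the oxygen axis profile."""
    return float(cavity_axis_profile(frame_set, topology,
                                     Species.OXYGEN, frame).values.min())


def _axis_geometry_batch(frame_set: FrameSet, topology: ChannelTopology):
    """Vectorized :func:`_axis_geometry` over all frames."""
    centers = _site_centers(frame_set, topology)          # (F, 5, 3)
    axis0 = topology.pore_axis
    flip = (centers[:, 4] - centers[:, 0]) @ axis0 < 0
    axes = np.where(flip[:, None], -axis0, axis0)         # (F, 3)
    anchors = centers.mean(axis=1)                        # (F, 3)
    lower_ring = list(topology.site_definitions[4].lower_ring)
    lower = frame_set.coordinates[:, lower_ring, :].mean(axis=1)
    t_lower = ((lower - anchors) * axes).sum(axis=1)
    return axes, anchors, t_lower + topology.cavity_probe.offset, centers


def _switch_sum_batch(points: np.ndarray, atoms: np.ndarray,
                      params: SwitchingParams) -> np.ndarray:
    """Coordination number at (F, P, 3) probe points over (F, A, 3) atoms."""
    n_frames, n_points = points.shape[:2]
    if atoms.shape[1] == 0:
        return np.zeros((n_frames, n_points))
    d = np.linalg.norm(points[:, :, None, :] - atoms[:, None, :, :], axis=-1)
    return (1.0 / (1.0 + (d / params.d_c) ** params.numerator_exponent)
            ).sum(axis=-1)


def compute_features(frame_set: FrameSet, topology: ChannelTopology,
                     chunk: int = 1000) -> pd.DataFrame:
    """All twelve features for every frame.

    Returns a DataFrame with a ``frame`` column followed by
    :data:`FEATURE_COLUMNS`. Feature extraction is per frame, so it commutes
    exactly with frame striding. Frames are processed in chunks to bound
    memory.
    """
    n = frame_set.n_frames
    probe = topology.cavity_probe
    out = np.empty((n, 12))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        block = FrameSet(frame_set.coordinates[lo:hi], frame_set.atom_table,
                         frame_set.frame_interval)
        axes, anchors, t_start, centers = _axis_geometry_batch(block,
                                                               topology)
        ions = block.coordinates[:, topology.potassium_selection, :]
        oxygens = block.coordinates[:, topology.oxygen_selection, :]
        out[lo:hi, 0:5] = _switch_sum_batch(centers, ions, ION_PARAMS)
        out[lo:hi, 5:10] = _switch_sum_batch(centers, oxygens, OXYGEN_PARAMS)
        t = t_start[:, None] + probe.spacing * np.arange(probe.n_points)
        points = anchors[:, None, :] + t[:, :, None] * axes[:, None, :]
        out[lo:hi, 10] = _switch_sum_batch(points, ions, ION_PARAMS
                                           ).max(axis=1)
        out[lo:hi, 11] = _switch_sum_batch(points, oxygens, OXYGEN_PARAMS
                                           ).min(axis=1)
    df = pd.DataFrame(out, columns=FEATURE_COLUMNS)
    df.insert(0, "frame", np.arange(n))
    return df


# ---------------------------------------------------------------------------
# dwell events
# ---------------------------------------------------------------------------

def _runs_with_gaps(inside: np.ndarray, gap_tolerance: int,
                    ) -> list[tuple[int, int]]:
    """Half-open [entry, exit) runs of True, bridging gaps <= gap_tolerance."""
    frames = np.flatnonzero(inside)
    if frames.size == 0:
        return []
    runs = []
    start = prev = int(frames[0])
    for f in frames[1:]:
        f = int(f)
        if f - prev - 1 <= gap_tolerance:
            prev = f
        else:
            runs.append((start, prev + 1))
            start = prev = f
    runs.append((start, prev + 1))
    return runs


def dwell_events(frame_set: FrameSet, topology: ChannelTopology,
                 threshold_ns: float = 10.0, gap_tolerance: int = 2,
                 radial_cutoff: float = ION_PARAMS.d_c,
                 ) -> tuple[list[DwellEvent], bool]:
    """Contiguous cavity residencies of each potassium ion.

    An ion is inside the cavity when its axial coordinate falls within the
    probed segment and its radial distance from the pore axis is at most
    ``radial_cutoff`` (tied to the ion cutoff d_c = 1.4 Å). Interruptions of
    at most ``gap_tolerance`` frames do not split an event (tolerance for
    saving-interval jitter). ``any_stable`` is true iff some event lasts
    strictly longer than ``threshold_ns``.
    """
    if not frame_set.frame_interval or frame_set.frame_interval <= 0:
        raise ConfigurationError("frame_interval must be known and positive")
    if gap_tolerance < 0:
        raise ArgumentError("gap_tolerance must be >= 0")
    n_frames = frame_set.n_frames
    probe = topology.cavity_probe
    ions = topology.potassium_selection
    if ions.size == 0:
        return [], False

    inside = np.zeros((n_frames, ions.size), dtype=bool)
    for f in range(n_frames):
        axis, anchor, t_start = _axis_geometry(frame_set, topology, f)
        rel = frame_set.frame(f)[ions] - anchor
        t = rel @ axis
        radial = np.linalg.norm(rel - t[:, None] * axis[None, :], axis=1)
        inside[f] = ((t >= t_start) & (t <= t_start + probe.length)
                     & (radial <= radial_cutoff))

    events: list[DwellEvent] = []
    for col, ion_index in enumerate(ions):
        for entry, exit_ in _runs_with_gaps(inside[:, col], gap_tolerance):
            duration = (exit_ - entry) * frame_set.frame_interval
            events.append(DwellEvent(
                ion_id=int(frame_set.atom_table["atom_id"].iloc[ion_index]),
                entry_frame=entry, exit_frame=exit_, duration=duration,
            ))
    events.sort(key=lambda e: (e.entry_frame, e.ion_id))
    any_stable = any(e.duration > threshold_ns for e in events)
    return events, any_stable


# ---------------------------------------------------------------------------
# feature persistence
# ---------------------------------------------------------------------------

def write_features(features: pd.DataFrame, path: str) -> str:
    """One CSV row per frame; reloadable without trajectory access."""
    features.to_csv(path, index=False)
    return path


def read_features(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["frame", *FEATURE_COLUMNS] if c not in df.columns]
    if missing:
        raise ArgumentError(f"features file {path} lacks columns {missing}")
    return df
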
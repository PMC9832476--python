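"""Synthetic selectivity-filter ensembles with known ground truth.

The generator builds a pseudo-atom filter: six stacked rings of four carbonyl
oxygens on a perfect four-fold axis (the z axis), delineating binding sites
S0 (extracellular) to S4 (intracellular), plus potassium ions planted at
chosen site centers, a water-oxygen column through the intracellular cavity,
and isotropic Gaussian thermal noise. Because every planted quantity is
known exactly, each pipeline stage can be tested against ground truth
without microsecond trajectories.

Three geometry states are provided:

* ``conductive`` — ring diameters follow the carbonyl-carbonyl diagonal
  distances of the conductive KcsA filter (4.5–5.1 Å, intracellular to
  extracellular);
* ``widened`` — the two extracellular rings (the S0 top ring and the S0/S1
  boundary ring) inflated by +4 Å diameter, degrading sites S0 and S1 while
  leaving S3/S4 intact, as seen in channels whose outer filter dilates during
  C-type inactivation;
* ``constricted`` — the two rings bounding S2 pinched by the ratio 5.5/8.1,
  the hour-glass closed-filter geometry.

The generator emulates statistics the analysis assumes (ring geometry, ion
placement, hydration column, uncorrelated Gaussian noise); it has no
dynamics, force field or conduction kinetics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SpecificationError
from .structure_io import (
    SENTINEL_SUBUNIT,
    CavityProbe,
    ChannelTopology,
    FrameSet,
    build_topology,
)

__all__ = [
    "SyntheticSpec", "GroundTruth", "generate_ensemble", "plant_ion_dwell",
    "reference_structures", "make_topology", "markov_schedule",
    "cycling_schedule", "write_kcsa_standins",
    "RING_SPACING", "CONDUCTIVE_DIAMETERS", "WIDENED_DIAMETER_OFFSET",
    "CONSTRICTION_RATIO",
]

#: axial ring separation in Å = binding-site length (the ion cutoff
#: d_c = 1.4 Å is half of this)
RING_SPACING = 2.8

#: conductive ring diameters in Å, extracellular ring first (from the
#: carbonyl diagonal distances of the conductive KcsA filter)
CONDUCTIVE_DIAMETERS = (5.1, 5.1, 4.7, 4.7, 4.5, 4.5)

#: added to the two extracellular ring diameters in the widened state
WIDENED_DIAMETER_OFFSET = 4.0

#: applied to the S2-bounding ring diameters in the constricted state
#: (the conductive->closed Gly Cα diagonal change, 8.1 Å -> 5.5 Å)
CONSTRICTION_RATIO = 5.5 / 8.1

#: ring residue numbers, extracellular first (hERG-style author numbering)
RING_RESIDUES = (628, 627, 626, 625, 624, 623)
RING_RESNAMES = ("GLY", "PHE", "GLY", "VAL", "SER", "THR")

_GEOMETRY_STATES = ("conductive", "widened", "constricted")

#: default axial water-oxygen spacing of the cavity column, in Å
WATER_SPACING = 2.6


def state_diameters(state: str) -> tuple[float, ...]:
    """Ring diameters (extracellular first) for a named geometry state."""
    d = list(CONDUCTIVE_DIAMETERS)
    if state == "widened":
        d[0] += WIDENED_DIAMETER_OFFSET
        d[1] += WIDENED_DIAMETER_OFFSET
    elif state == "constricted":
        d[2] *= CONSTRICTION_RATIO
        d[3] *= CONSTRICTION_RATIO
    elif state != "conductive":
        raise SpecificationError(
            f"unknown geometry state {state!r}; one of {_GEOMETRY_STATES}")
    return tuple(d)


def _default_ring_z() -> tuple[float, ...]:
    # extracellular ring at the top, strictly decreasing z
    return tuple(RING_SPACING * i for i in range(5, -1, -1))


@dataclass
class SyntheticSpec:
    """Full parameterization of one generated ensemble.

    ``ion_schedule`` is one tuple of occupied site indices (0=S0 … 4=S4)
    applied to every frame, or a per-frame sequence of such tuples.
    ``cavity_dwells`` lists ``(start_frame, n_frames)`` blocks during which a
    dedicated cavity ion sits mid-cavity on the axis. ``water_gap`` is an
    absolute z interval emptied of water oxygens (a dehydration gap).
    """

    n_frames: int = 100
    frame_interval: float = 0.01  # ns
    geometry_state: str = "conductive"
    ring_radii: tuple[float, ...] | None = None
    ring_z: tuple[float, ...] = field(default_factory=_default_ring_z)
    ion_schedule: Sequence = (0, 2, 4)
    water_column: bool = True
    water_spacing: float = WATER_SPACING
    water_gap: tuple[float, float] | None = None
    noise_sigma: float = 0.1  # Å
    seed: int = 0
    cavity_dwells: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_frames < 1:
            raise SpecificationError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise SpecificationError("noise_sigma must be >= 0")
        if not self.frame_interval > 0:
            raise SpecificationError("frame_interval must be > 0")
        z = tuple(float(v) for v in self.ring_z)
        if len(z) != 6 or any(a >= b for a, b in zip(z[1:], z[:-1])):
            raise SpecificationError(
                "ring_z must be six values strictly decreasing from the "
                "extracellular to the intracellular side")
        self.ring_z = z
        if self.ring_radii is None:
            self.ring_radii = tuple(d / 2
                                    for d in state_diameters(
                                        self.geometry_state))
        elif len(self.ring_radii) != 6:
            raise SpecificationError("ring_radii must have six entries")
        for start, n in self.cavity_dwells:
            if start < 0 or start + n > self.n_frames:
                raise SpecificationError(
                    f"cavity dwell ({start}, {n}) exceeds the ensemble "
                    f"length {self.n_frames}")

    def schedule(self) -> list[tuple[int, ...]]:
        """Per-frame tuples of occupied sites, validated."""
        sched = self.ion_schedule
        if len(sched) == 0:
            sched = [()] * self.n_frames
        elif np.isscalar(sched[0]):
            sched = [tuple(sched)] * self.n_frames
        else:
            sched = [tuple(s) for s in sched]
            if len(sched) != self.n_frames:
                raise SpecificationError(
                    f"ion schedule length {len(sched)} != n_frames "
                    f"{self.n_frames}")
        for config in sched:
            if any(s < 0 or s > 4 for s in config):
                raise SpecificationError(
                    f"site indices must be 0..4, got {config}")
        return sched


@dataclass
class GroundTruth:
    """Planted truth aligned one-to-one with the generated frames."""

    occupancies: np.ndarray            # (n_frames, 5) of {0, 1}
    geometry_state: str
    dwell_events: list[tuple[int, int, float]]  # (entry, exit_excl, ns)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump({
                "occupancies": self.occupancies.astype(int).tolist(),
                "geometry_state": self.geometry_state,
                "dwell_events": [[int(a), int(b), float(d)]
                                 for a, b, d in self.dwell_events],
            }, fh)
        return path

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["occupancies"], dtype=int),
                   payload["geometry_state"],
                   [tuple(e) for e in payload["dwell_events"]])


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def cycling_schedule(configurations: Sequence[tuple[int, ...]],
                     n_frames: int, block: int = 1,
                     ) -> list[tuple[int, ...]]:
    """Deterministic schedule cycling through configurations in blocks."""
    out = []
    i = 0
    while len(out) < n_frames:
        out.extend([tuple(configurations[i % len(configurations)])] * block)
        i += 1
    return out[:n_frames]


def markov_schedule(configurations: Sequence[tuple[int, ...]],
                    n_frames: int, mean_dwell_frames: float,
                    seed: int = 0) -> list[tuple[int, ...]]:
    """Schedule with geometric dwell times: after each dwell the state jumps
    to a uniformly chosen different configuration."""
    rng = np.random.default_rng(seed)
    out: list[tuple[int, ...]] = []
    state = 0
    while len(out) < n_frames:
        dwell = int(rng.geometric(1.0 / mean_dwell_frames))
        out.extend([tuple(configurations[state])] * dwell)
        if len(configurations) > 1:
            step = int(rng.integers(1, len(configurations)))
            state = (state + step) % len(configurations)
    return out[:n_frames]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sf_base_coordinates(ring_radii, ring_z) -> np.ndarray:
    """Ideal filter oxygens, shape (4 subunits, 6 rings, 3); subunit s sits
    at azimuth s*90 deg."""
    coords = np.empty((4, 6, 3))
    for s in range(4):
        phi = math.pi / 2 * s
        for r in range(6):
            coords[s, r] = (ring_radii[r] * math.cos(phi),
                            ring_radii[r] * math.sin(phi), ring_z[r])
    return coords


def _water_z_positions(spec: SyntheticSpec) -> np.ndarray:
    if not spec.water_column:
        return np.empty(0)
    z_bottom = spec.ring_z[5]
    # cover the probed segment [z_bottom-22, z_bottom-2] with margin
    z = np.arange(z_bottom - 0.9, z_bottom - 24.5, -spec.water_spacing)
    if spec.water_gap is not None:
        lo, hi = min(spec.water_gap), max(spec.water_gap)
        z = z[(z < lo) | (z > hi)]
    return z


_ION_PARK = np.array([30.0, 30.0, 40.0])
_CAVITY_PARK = np.array([-30.0, -30.0, -45.0])


def generate_ensemble(spec: SyntheticSpec) -> tuple[FrameSet, GroundTruth]:
    """Generate a synthetic ensemble and its aligned ground truth.

    Atom order: 24 filter oxygens (subunit-major), then site ions (fixed
    roster sized to the schedule's maximum simultaneous occupancy; ions not
    engaged in a given frame are parked in the remote extracellular bulk),
    then the optional cavity ion, then the water column. Bit-identical for a
    fixed seed.
    """
    schedule = spec.schedule()
    sf = _sf_base_coordinates(spec.ring_radii, spec.ring_z)
    site_z = [(spec.ring_z[i] + spec.ring_z[i + 1]) / 2 for i in range(5)]

    n_site_ions = max((len(c) for c in schedule), default=0)
    has_cavity_ion = bool(spec.cavity_dwells)
    waters_z = _water_z_positions(spec)
    cavity_mid_z = spec.ring_z[5] - CavityProbe().offset \
        - CavityProbe().length / 2

    rows = []
    base = []
    for s in range(4):
        for r in range(6):
            rows.append(("O", RING_RESNAMES[r], RING_RESIDUES[r], s, "O"))
            base.append(sf[s, r])
    for i in range(n_site_ions):
        rows.append(("K", "K", 701 + i, SENTINEL_SUBUNIT, "K"))
        base.append(_ION_PARK + [4.0 * i, 0.0, 0.0])
    if has_cavity_ion:
        rows.append(("K", "K", 700, SENTINEL_SUBUNIT, "K"))
        base.append(_CAVITY_PARK)
    for w, z in enumerate(waters_z):
        rows.append(("O", "HOH", 801 + w, SENTINEL_SUBUNIT, "O"))
        base.append((0.0, 0.0, float(z)))
    base = np.asarray(base, dtype=float)
    n_atoms = len(rows)

    table = pd.DataFrame({
        "atom_id": np.arange(n_atoms),
        "atom_name": [r[0] for r in rows],
        "residue_name": [r[1] for r in rows],
        "residue_number": [r[2] for r in rows],
        "subunit_index": [r[3] for r in rows],
        "element": [r[4] for r in rows],
    })

    dwell_frames = np.zeros(spec.n_frames, dtype=bool)
    for start, n in spec.cavity_dwells:
        dwell_frames[start:start + n] = True

    rng = np.random.default_rng(spec.seed)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    occupancies = np.zeros((spec.n_frames, 5), dtype=int)
    for f in range(spec.n_frames):
        frame = base.copy()
        sites = sorted(schedule[f])
        for slot, site in enumerate(sites):
            frame[24 + slot] = (0.0, 0.0, site_z[site])
            occupancies[f, site] = 1
        if has_cavity_ion and dwell_frames[f]:
            frame[24 + n_site_ions] = (0.0, 0.0, cavity_mid_z)
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma,
                                       size=frame.shape)
        coords[f] = frame

    dwells = []
    for start, n in spec.cavity_dwells:
        dwells.append((start, start + n, n * spec.frame_interval))
    truth = GroundTruth(occupancies, spec.geometry_state, dwells)
    return FrameSet(coords, table, spec.frame_interval), truth


def make_topology(frame_set: FrameSet,
                  cavity_probe: CavityProbe | None = None,
                  ) -> ChannelTopology:
    """Channel topology for a generated ensemble (synthetic site scheme)."""
    return build_topology(frame_set, site_scheme="synthetic",
                          cavity_probe=cavity_probe)


def plant_ion_dwell(spec: SyntheticSpec, duration_ns: float,
                    start_frame: int = 0) -> SyntheticSpec:
    """Plant a cavity residency of ``ceil(duration/frame_interval)`` frames.

    Returns an updated copy of the spec; a zero duration plants nothing.
    """
    if duration_ns < 0:
        raise SpecificationError("duration must be >= 0")
    n = math.ceil(duration_ns / spec.frame_interval - 1e-12)
    if n == 0:
        return replace(spec, cavity_dwells=list(spec.cavity_dwells))
    if start_frame + n > spec.n_frames:
        raise SpecificationError(
            f"a {duration_ns} ns dwell needs {n} frames from frame "
            f"{start_frame}, but the ensemble has {spec.n_frames}")
    dwells = sorted(spec.cavity_dwells + [(start_frame, n)])
    for (s1, n1), (s2, _n2) in zip(dwells, dwells[1:]):
        if s1 + n1 >= s2:
            raise SpecificationError("cavity dwells must not overlap")
    return replace(spec, cavity_dwells=dwells)


# ---------------------------------------------------------------------------
# reference stand-ins
# ---------------------------------------------------------------------------

#: ring residues of the KcsA-like stand-in filter, extracellular first;
#: residue 75 carries both the carbonyl O and the side-chain OG1 ring
_KCSA_RINGS = ((79, "GLY", "O"), (78, "TYR", "O"), (77, "GLY", "O"),
               (76, "VAL", "O"), (75, "THR", "O"), (75, "THR", "OG1"))

#: published conductive Gly Cα diagonal of the reference filter (Å)
_GLY_CA_DIAMETER = 8.1
#: generic Cα ring diameter offset above the carbonyl ring (Å)
_CA_DIAMETER_OFFSET = 3.2
_CA_AZIMUTH_OFFSET = math.radians(25.0)
_CA_Z_OFFSET = 0.6


def _kcsa_standin(constricted: bool) -> FrameSet:
    """Synthetic stand-in for the KcsA filter region (NOT deposited
    coordinates): an ideal four-fold filter whose ring diameters reproduce
    the published conductive/constricted diagonal distances."""
    ring_z = _default_ring_z()
    diameters = list(CONDUCTIVE_DIAMETERS)
    ca_diameters = {}
    for (res, _rn, an), diam in zip(_KCSA_RINGS, diameters):
        if an == "O":
            ca_diameters[res] = diam + _CA_DIAMETER_OFFSET
    ca_diameters[77] = _GLY_CA_DIAMETER
    if constricted:
        diameters[2] *= CONSTRICTION_RATIO
        diameters[3] *= CONSTRICTION_RATIO
        ca_diameters[77] *= CONSTRICTION_RATIO
        ca_diameters[76] *= CONSTRICTION_RATIO

    rows, positions = [], []
    for s in range(4):
        phi = math.pi / 2 * s
        seen_ca = set()
        for r, (res, resname, atom) in enumerate(_KCSA_RINGS):
            radius = diameters[r] / 2
            rows.append((atom, resname, res, s, "O"))
            positions.append((radius * math.cos(phi),
                              radius * math.sin(phi), ring_z[r]))
            if res not in seen_ca:
                seen_ca.add(res)
                ca_r = ca_diameters[res] / 2
                rows.append(("CA", resname, res, s, "C"))
                positions.append((ca_r * math.cos(phi + _CA_AZIMUTH_OFFSET),
                                  ca_r * math.sin(phi + _CA_AZIMUTH_OFFSET),
                                  ring_z[r] + _CA_Z_OFFSET))
    table = pd.DataFrame({
        "atom_id": np.arange(len(rows)),
        "atom_name": [r[0] for r in rows],
        "residue_name": [r[1] for r in rows],
        "residue_number": [r[2] for r in rows],
        "subunit_index": [r[3] for r in rows],
        "element": [r[4] for r in rows],
    })
    return FrameSet(np.asarray(positions)[None], table)


def reference_structures() -> tuple[FrameSet, FrameSet]:
    """Paired ideal conductive/constricted single-frame filters.

    The two structures are identical except at the S2-bounding rings (their
    carbonyl oxygens and the corresponding Cα rings), which are pinched by
    the conductive-to-closed ratio 5.5/8.1 in the constricted member.
    """
    return _kcsa_standin(False), _kcsa_standin(True)


def write_kcsa_standins(directory: str) -> dict[str, str]:
    """Write synthetic stand-in PDB files for the conductive and constricted
    reference filters.

    These files are generated, idealized coordinates — stand-ins labelled
    synthetic, not deposited crystal structures — whose diagonal distances
    reproduce the published conductive (8.1 Å Gly Cα; 5.1/4.7/4.7/4.5 Å
    carbonyl) and closed (5.5 Å Gly Cα) filter geometry.
    """
    import os

    from .structure_io import write_structure

    os.makedirs(directory, exist_ok=True)
    conductive, constricted = reference_structures()
    paths = {
        "conductive": os.path.join(
            directory, "kcsa_conductive_synthetic_standin.pdb"),
        "constricted": os.path.join(
            directory, "kcsa_constricted_synthetic_standin.pdb"),
    }
    write_structure(conductive, paths["conductive"])
    write_structure(constricted, paths["constricted"])
    return paths
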
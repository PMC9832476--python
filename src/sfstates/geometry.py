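"""Geometric core: the coordination-number switching function, binding-site
centers, opposite-subunit (diagonal) distances and selectivity-filter RMSD.

The coordination number at a probe point i over an atom selection A is

    C_i = sum_{j in A} (1 - (d_ij/d_c)^6) / (1 - (d_ij/d_c)^12)
        = sum_{j in A} 1 / (1 + (d_ij/d_c)^6)

where d_ij is the probe-atom distance and d_c the cutoff. The second form is
the removable-singularity-free evaluation (the 0/0 at d = d_c cancels to 1/2)
and is the one implemented. Each atom contributes 1 at the probe point,
1/2 at d_c, and decays as (d_c/d)^6 beyond, so C_i smoothly counts atoms
within roughly d_c of the probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, MappingError, ResolutionError
from .structure_io import FrameSet, ResidueMap, SiteDefinition

__all__ = [
    "SwitchingParams", "CoordinationResult", "DistanceRecord",
    "ION_PARAMS", "OXYGEN_PARAMS",
    "switching_value", "coordination_number", "site_center",
    "opposite_distance", "sf_rmsd", "distance_table", "kabsch",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Cutoff and exponents of the rational switching function.

    The denominator exponent must be exactly twice the numerator exponent so
    the rational form factors to 1/(1 + (d/d_c)^n).
    """

    d_c: float
    numerator_exponent: int = 6
    denominator_exponent: int = 12

    def __post_init__(self):
        if not self.d_c > 0:
            raise ArgumentError("d_c must be positive")
        if self.denominator_exponent != 2 * self.numerator_exponent:
            raise ArgumentError(
                "denominator exponent must be twice the numerator exponent")


#: cutoff for K+ site occupancy: ~half the binding-site length along the axis
ION_PARAMS = SwitchingParams(d_c=1.4)
#: cutoff for oxygen coordination: ~radius of the K+ first hydration shell
OXYGEN_PARAMS = SwitchingParams(d_c=3.2)

#: per-atom contribution above which an atom counts as "contributing"
CONTRIBUTION_THRESHOLD = 0.01


@dataclass(frozen=True)
class CoordinationResult:
    value: float
    probe_point: np.ndarray
    contributing_atoms: int


@dataclass(frozen=True)
class DistanceRecord:
    """Diagonal distances of one atom ring across the four-fold pore."""

    residue_number: int
    atom_name: str
    pairwise_distances: tuple[float, float]
    mean: float


def switching_value(d, params: SwitchingParams):
    """Contribution of one atom at distance ``d`` (Å); vectorized over ``d``.

    Strictly decreasing from 1 at d=0 through 1/2 at d=d_c toward 0.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ArgumentError("distances must be non-negative")
    out = 1.0 / (1.0 + (d / params.d_c) ** params.numerator_exponent)
    return float(out) if out.ndim == 0 else out


def coordination_number(probe, positions, params: SwitchingParams,
                        ) -> CoordinationResult:
    """Coordination number at one probe point over an atom selection.

    ``positions`` is an (n, 3) array of the selected atoms' coordinates; an
    empty selection yields 0 by contract. The value is additive over disjoint
    selections.
    """
    probe = np.asarray(probe, dtype=float)
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if positions.shape[0] == 0:
        return CoordinationResult(0.0, probe, 0)
    d = np.linalg.norm(positions - probe, axis=1)
    contrib = switching_value(d, params)
    return CoordinationResult(
        float(np.sum(contrib)), probe,
        int(np.count_nonzero(contrib > CONTRIBUTION_THRESHOLD)),
    )


def site_center(site: SiteDefinition, frame: np.ndarray) -> np.ndarray:
    """Unweighted mean position of the eight delineating oxygen atoms."""
    frame = np.asarray(frame, dtype=float)
    idx = site.atom_indices
    if idx.max() >= frame.shape[0]:
        raise ResolutionError(
            f"site {site.name} references atom {int(idx.max())} but the "
            f"frame has only {frame.shape[0]} atoms"
        )
    return frame[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# opposite-subunit distances
# ---------------------------------------------------------------------------

_MATCHINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def _diagonal_pairs(points: np.ndarray) -> tuple[float, float]:
    """Diagonal distances of four ring atoms by farthest-neighbour matching.

    Of the three perfect matchings of the four atoms, the diagonals are the
    matching with maximal total distance — for a (possibly distorted) square
    this pairs each corner with the opposite one, independent of chain
    labelling.
    """
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    totals = [d[a] + d[b] for (a, b) in _MATCHINGS]
    best = _MATCHINGS[int(np.argmax(totals))]
    return float(d[best[0]]), float(d[best[1]])


def _ring_indices(table: pd.DataFrame, residue_number: int,
                  atom_name: str) -> list[int]:
    indices = []
    for subunit in range(4):
        hit = table.index[
            (table["subunit_index"] == subunit)
            & (table["residue_number"] == residue_number)
            & (table["atom_name"] == atom_name)
        ]
        if len(hit) == 0:
            raise ResolutionError(
                f"atom {atom_name!r} of residue {residue_number} absent in "
                f"subunit {subunit}"
            )
        indices.append(int(hit[0]))
    return indices


def opposite_distance(frame_set: FrameSet, residue_number: int,
                      atom_name: str, frame: int = 0) -> DistanceRecord:
    """Distances between equivalent atoms in opposite subunits.

    Reports the two diagonal pair distances of the four-atom ring and their
    arithmetic mean. For a perfectly four-fold symmetric ring the mean equals
    twice the radial distance from the pore axis.
    """
    idx = _ring_indices(frame_set.atom_table, residue_number, atom_name)
    points = frame_set.frame(frame)[idx]
    d1, d2 = _diagonal_pairs(points)
    return DistanceRecord(residue_number, atom_name, (d1, d2),
                          0.5 * (d1 + d2))


def distance_table(frame_set: FrameSet,
                   rows: list[tuple[int, str]]) -> pd.DataFrame:
    """Mean ± SD of diagonal ring distances over all frames.

    One output row per ``(residue_number, atom_name)`` with columns
    ``residue, atom, mean_A, sd_A, n_frames``. The SD is the population
    standard deviation (a single frame gives 0). Values are kept at full
    precision; round for presentation only.
    """
    if frame_set.n_frames < 1:
        raise ArgumentError("distance_table requires at least one frame")
    records = []
    for residue_number, atom_name in rows:
        idx = _ring_indices(frame_set.atom_table, residue_number, atom_name)
        pts = frame_set.coordinates[:, idx, :]  # (n_frames, 4, 3)
        d = np.linalg.norm(pts[:, :, None, :] - pts[:, None, :, :], axis=-1)
        totals = np.stack(
            [d[:, a[0], a[1]] + d[:, b[0], b[1]] for (a, b) in _MATCHINGS],
            axis=1)
        best = np.argmax(totals, axis=1)
        means = np.empty(frame_set.n_frames)
        for m, (a, b) in enumerate(_MATCHINGS):
            sel = best == m
            means[sel] = 0.5 * (d[sel, a[0], a[1]] + d[sel, b[0], b[1]])
        records.append({
            "residue": residue_number, "atom": atom_name,
            "mean_A": float(means.mean()),
            "sd_A": float(means.std(ddof=0)),
            "n_frames": frame_set.n_frames,
        })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rigid-body superposition of ``mobile`` onto ``reference``.

    Returns (rotation, mobile_centroid, reference_centroid); the transformed
    coordinates are ``(mobile - mobile_centroid) @ rotation.T +
    reference_centroid``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    return rotation, cm, cr


def _mapped_positions(frame_set: FrameSet, frame: int, residues: list[int],
                      atom_names: frozenset) -> np.ndarray:
    table = frame_set.atom_table
    coords = frame_set.frame(frame)
    rows = []
    for resnum in residues:
        for subunit in range(4):
            for name in sorted(atom_names):
                hit = table.index[
                    (table["subunit_index"] == subunit)
                    & (table["residue_number"] == resnum)
                    & (table["atom_name"] == name)
                ]
                if len(hit) == 0:
                    raise MappingError(
                        f"backbone atom {name!r} of residue {resnum} absent "
                        f"in subunit {subunit}"
                    )
                rows.append(coords[int(hit[0])])
    return np.asarray(rows)


def sf_rmsd(frame_set: FrameSet, reference: FrameSet, residue_map: ResidueMap,
            superpose: bool = True, frame: int = 0,
            reference_frame: int = 0) -> float:
    """RMSD of mapped backbone atoms over all four subunits, in Å.

    With ``superpose=True`` (default) an optimal least-squares rigid-body
    superposition is applied first; with ``superpose=False`` the deviation is
    measured in the structures' common frame (useful when both are already
    aligned to the pore axis).
    """
    q = _mapped_positions(frame_set, frame, [p[0] for p in residue_map.pairs],
                          residue_map.backbone_atom_names)
    r = _mapped_positions(reference, reference_frame,
                          [p[1] for p in residue_map.pairs],
                          residue_map.backbone_atom_names)
    if q.shape != r.shape:
        raise MappingError(
            f"mapped atom counts differ: {q.shape[0]} vs {r.shape[0]}")
    if superpose:
        rot, cq, cr = kabsch(q, r)
        q = (q - cq) @ rot.T + cr
    return float(np.sqrt(np.mean(np.sum((q - r) ** 2, axis=1))))
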
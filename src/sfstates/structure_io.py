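"""Structure and trajectory input/output for tetrameric channel pores.

This module wraps MDAnalysis for all file parsing (PDB single structures,
DCD/XTC multi-frame trajectories) and exposes the package's in-memory
containers:

* :class:`FrameSet` — an ordered stack of coordinate frames over a fixed atom
  table, with the saving interval in nanoseconds;
* :class:`ChannelTopology` — the resolved channel anatomy: the five K+ binding
  sites S0–S4 (each delineated by eight oxygen atoms, two rings of four), the
  potassium and oxygen selections, and the intracellular cavity probe segment;
* :class:`ResidueMap` — a residue correspondence between a query channel and a
  reference structure, used for selectivity-filter RMSD.

Subunits are identified by chain identifier: the four chains that contain
protein residues are the pore subunits, numbered 0–3 in order of first
appearance in the file. Solvent and ion atoms carry the sentinel subunit
:data:`SENTINEL_SUBUNIT`. Residue numbers are author numbering (1-based,
never renumbered).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ArgumentError,
    AtomCountMismatchError,
    MappingError,
    ParseError,
    ResolutionError,
    TopologyWarning,
)

#: subunit_index for atoms that do not belong to one of the four pore chains
SENTINEL_SUBUNIT = -1

#: default saving interval between stored frames, in ns (coordinates saved
#: every 10 ps is the common production setting this package assumes)
DEFAULT_FRAME_INTERVAL_NS = 0.01

#: default backbone atom set for selectivity-filter RMSD (user-overridable)
DEFAULT_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "HID", "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE",
    "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

ATOM_TABLE_COLUMNS = (
    "atom_id", "atom_name", "residue_name", "residue_number",
    "subunit_index", "element",
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system: identity, chemistry and bookkeeping metadata."""

    atom_id: int
    atom_name: str
    residue_name: str
    residue_number: int
    subunit_index: int
    element: str


@dataclass
class FrameSet:
    """Ordered coordinate frames over a fixed atom table.

    Parameters
    ----------
    coordinates : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    atom_table : pandas.DataFrame
        One row per atom with columns ``atom_id, atom_name, residue_name,
        residue_number, subunit_index, element``.
    frame_interval : float
        Time between stored frames in ns; must be positive.
    """

    coordinates: np.ndarray
    atom_table: pd.DataFrame
    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ArgumentError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != len(self.atom_table):
            raise ArgumentError(
                f"every frame must have {len(self.atom_table)} atoms "
                f"(atom_table length), got {self.coordinates.shape[1]}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ArgumentError("coordinates contain non-finite values")
        if not self.frame_interval > 0:
            raise ArgumentError("frame_interval must be > 0")
        self.atom_table = self.atom_table.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, index: int) -> np.ndarray:
        """Coordinates of one frame, shape (n_atoms, 3)."""
        return self.coordinates[index]

    def strided(self, stride: int) -> "FrameSet":
        """Every ``stride``-th frame, with the interval scaled accordingly."""
        if stride < 1:
            raise ArgumentError("stride must be a positive integer")
        return FrameSet(
            self.coordinates[::stride].copy(),
            self.atom_table.copy(),
            self.frame_interval * stride,
        )

    def atom_records(self) -> Iterable[AtomRecord]:
        for row in self.atom_table.itertuples(index=False):
            yield AtomRecord(
                int(row.atom_id), str(row.atom_name), str(row.residue_name),
                int(row.residue_number), int(row.subunit_index),
                str(row.element),
            )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "FrameSet":
        """Apply a global rigid transform (rotation then translation)."""
        coords = self.coordinates
        if rotation is not None:
            coords = coords @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            coords = coords + np.asarray(translation, dtype=float)
        return FrameSet(coords, self.atom_table.copy(), self.frame_interval)


@dataclass(frozen=True)
class SiteDefinition:
    """One K+ binding site delineated by two rings of four oxygen atoms.

    ``upper_ring`` is the extracellular bounding ring, ``lower_ring`` the
    intracellular one; ``atom_indices`` is their concatenation (8 positional
    indices into the frame set's atom table).
    """

    name: str
    upper_ring: tuple[int, int, int, int]
    lower_ring: tuple[int, int, int, int]

    @property
    def atom_indices(self) -> np.ndarray:
        return np.array(self.upper_ring + self.lower_ring, dtype=int)


@dataclass(frozen=True)
class CavityProbe:
    """Axis segment probed below the filter, toward the intracellular side.

    The segment starts ``offset`` Å below the lower boundary of S4 and extends
    ``length`` Å toward the intracellular compartment, sampled every
    ``spacing`` Å.
    """

    offset: float = 2.0
    length: float = 20.0
    spacing: float = 0.5

    @property
    def n_points(self) -> int:
        return int(round(self.length / self.spacing)) + 1


@dataclass
class ChannelTopology:
    """Resolved channel anatomy used by every downstream analysis."""

    sf_residue_range: tuple[int, int]
    pore_axis: np.ndarray
    site_definitions: list[SiteDefinition]
    potassium_selection: np.ndarray
    oxygen_selection: np.ndarray
    cavity_probe: CavityProbe = field(default_factory=CavityProbe)

    def __post_init__(self):
        if len(self.site_definitions) != 5:
            raise ArgumentError(
                f"exactly five site definitions (S0–S4) required, "
                f"got {len(self.site_definitions)}"
            )
        axis = np.asarray(self.pore_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not norm > 0:
            raise ArgumentError("pore_axis must be a nonzero vector")
        self.pore_axis = axis / norm
        self.potassium_selection = np.asarray(self.potassium_selection, int)
        self.oxygen_selection = np.asarray(self.oxygen_selection, int)
        if np.intersect1d(self.potassium_selection,
                          self.oxygen_selection).size:
            raise ArgumentError(
                "potassium and oxygen selections must be disjoint")


@dataclass
class ResidueMap:
    """Bijective residue correspondence between query and reference."""

    pairs: list[tuple[int, int]]
    backbone_atom_names: frozenset = DEFAULT_BACKBONE_ATOMS

    def __post_init__(self):
        q = [p[0] for p in self.pairs]
        r = [p[1] for p in self.pairs]
        if len(set(q)) != len(q) or len(set(r)) != len(r):
            raise MappingError(
                "residue pairs must form a bijection: duplicated residue "
                f"numbers in {self.pairs}"
            )


# ---------------------------------------------------------------------------
# element handling
# ---------------------------------------------------------------------------

def _guess_elements(names: Sequence[str], resnames: Sequence[str]) -> list:
    """Element symbols from atom names, via the MDAnalysis guesser."""
    from MDAnalysis.topology.guessers import guess_atom_element

    out = []
    for name, resname in zip(names, resnames):
        if resname.strip().upper() in {"K", "POT", "K+"}:
            out.append("K")
        else:
            out.append(str(guess_atom_element(name)).capitalize())
    return out


def _universe_to_frameset(u, frame_interval: float,
                          stride: int = 1) -> FrameSet:
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    resnames = [str(r) for r in atoms.resnames]
    resids = [int(r) for r in atoms.resids]
    try:
        chains = [str(c) for c in atoms.chainIDs]
    except AttributeError:
        chains = [str(s) for s in atoms.segids]
    try:
        elements = [str(e).capitalize() for e in atoms.elements]
        if any(e == "" for e in elements):
            raise AttributeError
    except AttributeError:
        elements = _guess_elements(names, resnames)

    # four pore subunits = the protein-bearing chains, in file order
    protein_chains: list[str] = []
    for ch, rn in zip(chains, resnames):
        if rn.strip().upper() in _PROTEIN_RESNAMES and ch not in protein_chains:
            protein_chains.append(ch)
    if len(protein_chains) != 4:
        warnings.warn(
            f"expected 4 protein chains for a tetrameric pore, found "
            f"{len(protein_chains)} ({protein_chains})", TopologyWarning,
            stacklevel=3,
        )
    chain_rank = {ch: i for i, ch in enumerate(protein_chains)}
    subunits = [
        chain_rank.get(ch, SENTINEL_SUBUNIT)
        if rn.strip().upper() in _PROTEIN_RESNAMES else SENTINEL_SUBUNIT
        for ch, rn in zip(chains, resnames)
    ]

    table = pd.DataFrame({
        "atom_id": np.arange(len(names)),
        "atom_name": names,
        "residue_name": resnames,
        "residue_number": resids,
        "subunit_index": subunits,
        "element": elements,
    })

    n_frames = len(u.trajectory)
    kept = range(0, n_frames, stride)
    coords = np.empty((len(kept), len(names), 3), dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unit-cell placeholder chatter
        for i, fi in enumerate(kept):
            u.trajectory[fi]
            coords[i] = atoms.positions
    return FrameSet(coords, table, frame_interval * stride)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_structure(path: str | os.PathLike, format: str = "PDB") -> FrameSet:
    """Read a single-structure file into a one-frame :class:`FrameSet`.

    Chain identifiers define the four pore subunits; a file with a different
    number of protein chains triggers a :class:`TopologyWarning` (the caller
    decides whether a non-tetrameric assembly is acceptable). Crystal-symmetry
    expansion is the user's responsibility: pass biological-assembly files,
    not asymmetric units, when the deposited entry stores fewer than four
    channel chains.
    """
    import MDAnalysis as mda

    if format.upper() != "PDB":
        raise ArgumentError(f"unsupported structure format: {format}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    if os.path.getsize(path) == 0:
        raise ParseError(f"empty structure file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MDAnalysis guessing chatter
            u = mda.Universe(path, format="PDB")
        if len(u.atoms) == 0:
            raise ParseError(f"no atoms parsed from {path}")
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise ParseError(f"could not parse {path} as PDB: {exc}") from exc
    return _universe_to_frameset(u, DEFAULT_FRAME_INTERVAL_NS)


def read_trajectory(topology_path: str | os.PathLike,
                    trajectory_path: str | os.PathLike,
                    stride: int = 1,
                    frame_interval: float = DEFAULT_FRAME_INTERVAL_NS,
                    trajectory_format: str | None = None) -> FrameSet:
    """Read a multi-frame trajectory (DCD/XTC, chosen by extension).

    ``frame_interval`` is the saving interval of the *stored* file in ns; the
    returned frame set's interval is scaled by ``stride``.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ArgumentError("stride must be a positive integer")
    topology_path = os.fspath(topology_path)
    trajectory_path = os.fspath(trajectory_path)
    for p in (topology_path, trajectory_path):
        if not os.path.exists(p):
            raise ParseError(f"no such file: {p}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kwargs = {}
            if trajectory_format is not None:
                kwargs["format"] = trajectory_format
            u = mda.Universe(topology_path, trajectory_path, **kwargs)
    except Exception as exc:  # noqa: BLE001
        msg = str(exc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_top = len(mda.Universe(topology_path).atoms)
        import re

        m = re.search(r"(\d+)\s+atoms", msg)
        n_traj = int(m.group(1)) if m else -1
        if "mismatch" in msg.lower() or "number of atoms" in msg.lower():
            raise AtomCountMismatchError(n_top, n_traj) from exc
        raise ParseError(
            f"could not read trajectory {trajectory_path}: {exc}") from exc
    return _universe_to_frameset(u, frame_interval, stride=stride)


def write_structure(frame_set: FrameSet, path: str | os.PathLike,
                    frame: int = 0) -> str:
    """Write one frame as a PDB file (coordinates to 3 decimals)."""
    import MDAnalysis as mda

    path = os.fspath(path)
    table = frame_set.atom_table
    n = len(table)
    resid_keys = list(zip(table["subunit_index"], table["residue_number"],
                          table["residue_name"]))
    unique_res = list(dict.fromkeys(resid_keys))
    res_index = {k: i for i, k in enumerate(unique_res)}
    atom_resindex = np.array([res_index[k] for k in resid_keys])
    sub_of_res = [k[0] for k in unique_res]
    seg_index = {s: i for i, s in enumerate(dict.fromkeys(sub_of_res))}
    res_segindex = np.array([seg_index[s] for s in sub_of_res])

    u = mda.Universe.empty(
        n, n_residues=len(unique_res), n_segments=len(seg_index),
        atom_resindex=atom_resindex, residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(table["atom_name"]))
    u.add_TopologyAttr("elements", list(table["element"]))
    u.add_TopologyAttr("resnames", [k[2] for k in unique_res])
    u.add_TopologyAttr("resids", [int(k[1]) for k in unique_res])

    def chain_label(subunit):
        if subunit == SENTINEL_SUBUNIT:
            return "W"
        return "ABCDEFGH"[subunit % 8]

    u.add_TopologyAttr("chainIDs", [chain_label(s)
                                    for s in table["subunit_index"]])
    u.add_TopologyAttr("segids",
                       [chain_label(s) for s in dict.fromkeys(sub_of_res)])
    u.atoms.positions = frame_set.frame(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(path)
    return path


def write_trajectory(frame_set: FrameSet, topology_path: str | os.PathLike,
                     trajectory_path: str | os.PathLike) -> tuple[str, str]:
    """Write a PDB topology plus a DCD/XTC trajectory for all frames."""
    import MDAnalysis as mda

    topology_path = os.fspath(topology_path)
    trajectory_path = os.fspath(trajectory_path)
    write_structure(frame_set, topology_path, frame=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(topology_path)
        with mda.Writer(trajectory_path, n_atoms=frame_set.n_atoms) as w:
            for i in range(frame_set.n_frames):
                u.atoms.positions = frame_set.frame(i)
                w.write(u.atoms)
    return topology_path, trajectory_path


# ---------------------------------------------------------------------------
# topology building
# ---------------------------------------------------------------------------

SiteScheme = Sequence[tuple[tuple[int, str], tuple[int, str]]]


def _data_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "data", name)


def load_site_scheme(name: str) -> dict:
    """Load a named site scheme (e.g. ``"herg"``, ``"kcsa"``) from config."""
    with open(_data_path("site_schemes.yaml")) as fh:
        schemes = yaml.safe_load(fh)
    if name not in schemes:
        raise ArgumentError(
            f"unknown site scheme {name!r}; available: {sorted(schemes)}")
    entry = schemes[name]
    sites = [
        (tuple(entry["sites"][s][0]), tuple(entry["sites"][s][1]))
        for s in ("S0", "S1", "S2", "S3", "S4")
    ]
    return {"sf_residue_range": tuple(entry["sf_residue_range"]),
            "sites": sites}


def _resolve_ring(table: pd.DataFrame, residue_number: int,
                  atom_name: str) -> tuple[int, int, int, int]:
    """Positional indices of one atom in each of the four subunits."""
    indices = []
    for subunit in range(4):
        hit = table.index[
            (table["subunit_index"] == subunit)
            & (table["residue_number"] == residue_number)
            & (table["atom_name"] == atom_name)
        ]
        if len(hit) == 0:
            raise ResolutionError(
                f"atom {atom_name!r} of residue {residue_number} not found "
                f"in subunit {subunit}"
            )
        indices.append(int(hit[0]))
    return tuple(indices)


def build_topology(frame_set: FrameSet,
                   sf_range: tuple[int, int] | None = None,
                   site_scheme: str | SiteScheme = "herg",
                   pore_axis: Sequence[float] = (0.0, 0.0, 1.0),
                   cavity_probe: CavityProbe | None = None,
                   ) -> ChannelTopology:
    """Resolve the five S0–S4 binding sites and atom selections.

    ``site_scheme`` is either the name of a shipped scheme or an explicit list
    of five ``((residue, atom), (residue, atom))`` ring pairs ordered S0
    (extracellular) to S4 (intracellular); each ring resolves to one atom per
    subunit, so every site is delineated by exactly eight oxygen atoms.
    """
    if isinstance(site_scheme, str):
        loaded = load_site_scheme(site_scheme)
        sites = loaded["sites"]
        if sf_range is None:
            sf_range = loaded["sf_residue_range"]
    else:
        sites = list(site_scheme)
        if len(sites) != 5:
            raise ArgumentError(
                f"site scheme must define 5 sites, got {len(sites)}")
        if sf_range is None:
            residues = [r for pair in sites for (r, _a) in pair]
            sf_range = (min(residues), max(residues))

    table = frame_set.atom_table
    site_defs = []
    for i, (upper, lower) in enumerate(sites):
        site_defs.append(SiteDefinition(
            name=f"S{i}",
            upper_ring=_resolve_ring(table, *upper),
            lower_ring=_resolve_ring(table, *lower),
        ))

    elements = table["element"].astype(str).str.upper()
    potassium = table.index[elements == "K"].to_numpy()
    oxygen = table.index[elements == "O"].to_numpy()
    return ChannelTopology(
        sf_residue_range=tuple(sf_range),
        pore_axis=np.asarray(pore_axis, dtype=float),
        site_definitions=site_defs,
        potassium_selection=potassium,
        oxygen_selection=oxygen,
        cavity_probe=cavity_probe or CavityProbe(),
    )


def map_reference(query: FrameSet, reference: FrameSet,
                  pairs: Sequence[tuple[int, int]],
                  backbone_atom_names: Iterable[str] = DEFAULT_BACKBONE_ATOMS,
                  ) -> ResidueMap:
    """Build a residue correspondence for the filter-RMSD operation.

    Every mapped residue must exist in all four subunits of both structures.
    """
    rmap = ResidueMap(list(map(tuple, pairs)),
                      frozenset(backbone_atom_names))
    for fs, col in ((query, 0), (reference, 1)):
        table = fs.atom_table
        for pair in rmap.pairs:
            resnum = pair[col]
            for subunit in range(4):
                present = (
                    (table["subunit_index"] == subunit)
                    & (table["residue_number"] == resnum)
                ).any()
                if not present:
                    which = "query" if col == 0 else "reference"
                    raise MappingError(
                        f"residue {resnum} of pair {pair} missing in subunit "
                        f"{subunit} of the {which} structure"
                    )
    return rmap


def range_map(query_range: tuple[int, int], reference_range: tuple[int, int],
              ) -> list[tuple[int, int]]:
    """Pairs from two equal-length inclusive residue intervals."""
    q = list(range(query_range[0], query_range[1] + 1))
    r = list(range(reference_range[0], reference_range[1] + 1))
    if len(q) != len(r):
        raise MappingError(
            f"residue ranges differ in length: {query_range} vs "
            f"{reference_range}"
        )
    return list(zip(q, r))
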
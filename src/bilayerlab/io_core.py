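"""Domain model and I/O for planar lipid bilayer trajectories.

The package works in fixed internal units — nanometres, picoseconds, unified
atomic masses — regardless of the source file format; converters live only at
the I/O boundary. The membrane normal is the z axis by convention.

Standard formats (GRO/PDB topologies, XTC/TRR/DCD trajectories) are read and
written through MDAnalysis. A plain-text fixture dialect (one header line
``n_atoms n_frames``, then per frame one box line ``Lx Ly Lz`` followed by
``n_atoms`` whitespace-separated ``x y z`` records, all in nm) exists for
dependency-light tests; it carries no time axis, so the loader assigns
uniform spacing (10 ps by default, the usual MD save interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._elements import electrons_of, element_from_name, mass_of
from .exceptions import (
    DegenerateGeometryError,
    DomainError,
    FormatError,
    TopologyError,
    UnsupportedGeometryError,
)

WATER_MOLARITY = 55.5  # mol/L, reference molarity of liquid water

#: Controlled vocabulary of carbon-segment labels for POPC: choline methyls
#: (γ), headgroup β/α carbons, glycerol backbone g3/g2/g1, and the two acyl
#: chains by carbon number (sn-1 palmitoyl C2..C16, sn-2 oleoyl C2..C18).
SEGMENT_LABELS: tuple[str, ...] = (
    "γ",
    "β",
    "α",
    "g3",
    "g2",
    "g1",
    *[f"sn1-C{i}" for i in range(2, 17)],
    *[f"sn2-C{i}" for i in range(2, 19)],
)

_SEGMENT_ORDER = {label: i for i, label in enumerate(SEGMENT_LABELS)}

STEREO_LABELS = ("R", "S", "none")


def segment_sort_key(label: str) -> int:
    """Canonical x-axis order: γ, β, α, g3, g2, g1, then sn-1 and sn-2 chains."""
    return _SEGMENT_ORDER[label]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the bilayer system.

    ``lipid_id`` indexes the lipid the atom belongs to; solvent and ion atoms
    carry the sentinel −1. ``stereo_label`` distinguishes the prochiral R/S
    hydrogens of methylene groups; it is "none" for every non-hydrogen.
    """

    lipid_id: int
    atom_name: str
    element: str
    mass: float
    electrons: int
    stereo_label: str = "none"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise TopologyError(f"atom {self.atom_name}: mass must be > 0, got {self.mass}")
        if self.electrons < 1:
            raise TopologyError(
                f"atom {self.atom_name}: electron count must be >= 1, got {self.electrons}"
            )
        if self.stereo_label not in STEREO_LABELS:
            raise TopologyError(f"bad stereo label {self.stereo_label!r}")
        if self.stereo_label != "none" and self.element != "H":
            raise TopologyError(
                f"atom {self.atom_name}: stereo labels apply only to hydrogens"
            )


class CHBond(NamedTuple):
    """A carbon–hydrogen bond: atom indices plus segment and stereo identity."""

    carbon: int
    hydrogen: int
    segment_label: str
    stereo_label: str


@dataclass
class BilayerTopology:
    """Atoms, C–H bond list, and leaflet assignment of a bilayer system."""

    atoms: list[AtomRecord]
    ch_bonds: list[CHBond] = field(default_factory=list)
    leaflet: dict[int, str] = field(default_factory=dict)
    n_lipids: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_h: set[int] = set()
        for bond in self.ch_bonds:
            if bond.hydrogen in seen_h:
                raise TopologyError(
                    f"hydrogen atom {bond.hydrogen} appears in more than one C-H bond"
                )
            seen_h.add(bond.hydrogen)
            if bond.segment_label not in _SEGMENT_ORDER:
                raise TopologyError(f"unknown segment label {bond.segment_label!r}")
            lid = self.atoms[bond.carbon].lipid_id
            if lid >= 0 and self.leaflet and lid not in self.leaflet:
                raise TopologyError(f"lipid {lid} in ch_bonds has no leaflet assignment")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def lipid_of_bond(self, bond: CHBond) -> int:
        return self.atoms[bond.carbon].lipid_id

    def atom_indices(self, *, lipid_id: int | None = None, name: str | None = None) -> np.ndarray:
        """Indices of atoms matching the given lipid id and/or atom name."""
        idx = []
        for i, a in enumerate(self.atoms):
            if lipid_id is not None and a.lipid_id != lipid_id:
                continue
            if name is not None and a.atom_name != name:
                continue
            idx.append(i)
        return np.asarray(idx, dtype=np.intp)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def electron_counts(self) -> np.ndarray:
        return np.array([a.electrons for a in self.atoms], dtype=float)


@dataclass
class FrameSeries:
    """Timestamped coordinates and orthorhombic boxes.

    times are ps (strictly increasing), coords shape (n_frames, n_atoms, 3)
    in nm, box shape (n_frames, 3) = (Lx, Ly, Lz) in nm.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must have shape (F, N, 3), got {self.coords.shape}")
        if self.box.shape != (self.coords.shape[0], 3):
            raise FormatError(
                f"box must have shape ({self.coords.shape[0]}, 3), got {self.box.shape}"
            )
        if self.times.shape != (self.coords.shape[0],):
            raise FormatError("times length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.box))):
            raise FormatError("non-finite values in trajectory")
        if np.any(self.box <= 0):
            raise FormatError("all box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def span(self) -> float:
        """Trajectory span in ps."""
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# bond-definition tables
# ---------------------------------------------------------------------------

class BondDefinition(NamedTuple):
    segment_label: str
    carbon_name: str
    hydrogen_name: str
    stereo_label: str


def load_bond_table(path: str | Path | None = None) -> list[BondDefinition]:
    """Load a C–H bond definition table (TSV: segment_label, carbon_name,
    hydrogen_name, stereo_label). With no path, the bundled CHARMM36-style
    POPC table is used."""
    if path is None:
        text = (
            resources.files("bilayerlab").joinpath("data/popc_charmm36_bonds.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    rows: list[BondDefinition] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "segment_label":
            continue
        if len(parts) != 4:
            raise FormatError(f"bond table line {ln}: expected 4 tab-separated fields")
        seg, c, h, st = (p.strip() for p in parts)
        if seg not in _SEGMENT_ORDER:
            raise FormatError(f"bond table line {ln}: unknown segment {seg!r}")
        if st not in STEREO_LABELS:
            raise FormatError(f"bond table line {ln}: unknown stereo label {st!r}")
        rows.append(BondDefinition(seg, c, h, st))
    return rows


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

_TEXT_SUFFIXES = {".txt", ".dat"}


def load_trajectory(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    *,
    lipid_resnames: Iterable[str] = ("POPC",),
    bond_table: Sequence[BondDefinition] | None = None,
    dt_ps: float = 10.0,
) -> tuple[BilayerTopology, FrameSeries]:
    """Read a topology + trajectory pair into the internal domain types.

    GRO/PDB topologies with XTC/TRR/DCD trajectories go through MDAnalysis
    (Å and ps converted to nm and ps). A ``.txt``/``.dat`` topology path is
    read as the plain-text fixture dialect and needs no trajectory file.
    Lipids are identified by residue name; C–H bonds are constructed from the
    bond-definition table (bundled POPC table by default).
    """
    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"no such file: {topology_path}")
    if topology_path.suffix in _TEXT_SUFFIXES:
        return _load_text(topology_path, dt_ps=dt_ps)

    import MDAnalysis as mda

    if trajectory_path is None:
        u = mda.Universe(str(topology_path))
    else:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FormatError(f"no such file: {trajectory_path}")
        try:
            u = mda.Universe(str(topology_path), str(trajectory_path))
        except (ValueError, OSError, IOError) as exc:
            raise FormatError(f"topology/trajectory mismatch: {exc}") from exc

    lipid_resnames = set(lipid_resnames)
    try:
        resnames = u.atoms.resnames
    except AttributeError:
        resnames = np.array(["UNK"] * len(u.atoms))

    # map lipid residues to 0-based lipid ids in residue order
    lipid_residues = [r for r in u.residues if r.resname in lipid_resnames]
    lipid_id_of_res = {r.resindex: i for i, r in enumerate(lipid_residues)}

    atoms: list[AtomRecord] = []
    for a in u.atoms:
        lid = lipid_id_of_res.get(a.resindex, -1)
        elem = element_from_name(a.name, is_lipid=lid >= 0)
        atoms.append(
            AtomRecord(
                lipid_id=lid,
                atom_name=a.name,
                element=elem,
                mass=mass_of(elem),
                electrons=electrons_of(elem),
            )
        )

    table = list(bond_table) if bond_table is not None else load_bond_table()
    ch_bonds = _bonds_from_table(atoms, table)

    times, coords, box = [], [], []
    for ts in u.trajectory:
        if ts.positions.shape[0] != len(atoms):
            raise FormatError(
                f"frame {ts.frame}: {ts.positions.shape[0]} coordinates for {len(atoms)} atoms"
            )
        dims = ts.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise FormatError(f"frame {ts.frame}: no box information")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise UnsupportedGeometryError(
                f"frame {ts.frame}: non-orthorhombic box (angles {dims[3:]})"
            )
        times.append(float(ts.time))
        coords.append(ts.positions.astype(float) / 10.0)  # Å -> nm
        box.append(dims[:3].astype(float) / 10.0)

    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        # some single-frame formats report t=0 everywhere; fall back to uniform spacing
        times = np.arange(len(times), dtype=float) * dt_ps

    topo = BilayerTopology(atoms=atoms, ch_bonds=ch_bonds, n_lipids=len(lipid_residues))
    frames = FrameSeries(times=times, coords=np.array(coords), box=np.array(box))
    if frames.n_atoms != topo.n_atoms:
        raise FormatError(
            f"trajectory has {frames.n_atoms} atoms but topology has {topo.n_atoms}"
        )
    return topo, frames


def _bonds_from_table(
    atoms: Sequence[AtomRecord], table: Sequence[BondDefinition]
) -> list[CHBond]:
    """Match (carbon_name, hydrogen_name) pairs of the table within each lipid."""
    by_lipid: dict[int, dict[str, int]] = {}
    for i, a in enumerate(atoms):
        if a.lipid_id >= 0:
            by_lipid.setdefault(a.lipid_id, {})[a.atom_name] = i
    bonds: list[CHBond] = []
    for lid in sorted(by_lipid):
        names = by_lipid[lid]
        for row in table:
            ci = names.get(row.carbon_name)
            hi = names.get(row.hydrogen_name)
            if ci is not None and hi is not None:
                bonds.append(CHBond(ci, hi, row.segment_label, row.stereo_label))
    return bonds


def _load_text(path: Path, dt_ps: float = 10.0) -> tuple[BilayerTopology, FrameSeries]:
    tokens = path.read_text().split("\n")
    header = tokens[0].split()
    if len(header) != 2:
        raise FormatError(f"{path}: header must be 'n_atoms n_frames'")
    n_atoms, n_frames = int(header[0]), int(header[1])
    values = np.array(" ".join(tokens[1:]).split(), dtype=float)
    expected = n_frames * (3 + 3 * n_atoms)
    if values.size != expected:
        raise FormatError(
            f"{path}: expected {expected} numbers for {n_frames} frames x {n_atoms} atoms, "
            f"got {values.size}"
        )
    values = values.reshape(n_frames, 3 + 3 * n_atoms)
    box = values[:, :3]
    coords = values[:, 3:].reshape(n_frames, n_atoms, 3)
    times = np.arange(n_frames, dtype=float) * dt_ps
    atoms = [
        AtomRecord(lipid_id=-1, atom_name="X", element="C", mass=12.011, electrons=6)
        for _ in range(n_atoms)
    ]
    topo = BilayerTopology(atoms=atoms)
    return topo, FrameSeries(times=times, coords=coords, box=box)


def write_frames(
    topology: BilayerTopology, frames: FrameSeries, path: str | Path
) -> list[Path]:
    """Write a trajectory to standard formats; returns the file(s) written.

    The extension selects the format: ``.txt``/``.dat`` writes the plain-text
    fixture dialect; ``.gro`` writes a (possibly multi-frame) GRO file; a
    path without extension writes a ``.gro`` (first frame) + ``.xtc`` pair.
    """
    if frames.n_frames == 0:
        raise DomainError("refusing to write an empty frame list")
    if frames.n_atoms != topology.n_atoms:
        raise FormatError(
            f"frame coordinates for {frames.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    path = Path(path)
    try:
        if path.suffix in _TEXT_SUFFIXES:
            _write_text(frames, path)
            return [path]
        return _write_mda(topology, frames, path)
    except OSError as exc:
        raise BilayerlabIOError(f"cannot write {path}: {exc}") from exc


class BilayerlabIOError(FormatError):
    """Filesystem-level write failure."""


def _write_text(frames: FrameSeries, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{frames.n_atoms} {frames.n_frames}\n")
        for f in range(frames.n_frames):
            fh.write(" ".join(f"{v:.6f}" for v in frames.box[f]) + "\n")
            for row in frames.coords[f]:
                fh.write(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")


def _mda_universe(topology: BilayerTopology, frames: FrameSeries):
    import MDAnalysis as mda

    n = topology.n_atoms
    # residues: one per lipid, one per contiguous run of solvent atoms
    resindex = np.zeros(n, dtype=int)
    resnames: list[str] = []
    resids: list[int] = []
    current = -1
    prev_key: object = object()
    for i, a in enumerate(topology.atoms):
        key = a.lipid_id if a.lipid_id >= 0 else ("solv", i)
        if key != prev_key:
            current += 1
            prev_key = key
            resnames.append("POPC" if a.lipid_id >= 0 else ("SOL" if a.element in ("O", "H") else "ION"))
            resids.append(current + 1)
        resindex[i] = current
    u = mda.Universe.empty(
        n, n_residues=current + 1, atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("masses", [a.mass for a in topology.atoms])
    return u


def _write_mda(topology: BilayerTopology, frames: FrameSeries, path: Path) -> list[Path]:
    import MDAnalysis as mda

    u = _mda_universe(topology, frames)

    def set_frame(f: int) -> None:
        u.atoms.positions = frames.coords[f] * 10.0
        u.dimensions = [*(frames.box[f] * 10.0), 90.0, 90.0, 90.0]
        u.trajectory.ts.time = frames.times[f]

    written: list[Path] = []
    if path.suffix == "":
        gro = path.with_suffix(".gro")
        xtc = path.with_suffix(".xtc")
        set_frame(0)
        u.atoms.write(str(gro))
        with mda.Writer(str(xtc), n_atoms=topology.n_atoms) as w:
            for f in range(frames.n_frames):
                set_frame(f)
                w.write(u.atoms)
        written = [gro, xtc]
    elif path.suffix == ".gro":
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=frames.n_frames > 1) as w:
            for f in range(frames.n_frames):
                set_frame(f)
                w.write(u.atoms)
        written = [path]
    else:
        raise FormatError(f"unsupported output format {path.suffix!r}")
    return written


# ---------------------------------------------------------------------------
# leaflet assignment and bookkeeping formulas
# ---------------------------------------------------------------------------

def assign_leaflets(
    topology: BilayerTopology,
    frames: FrameSeries,
    reference_frame: int = 0,
    anchor_name: str = "P",
) -> BilayerTopology:
    """Assign each lipid to the upper or lower leaflet.

    Lipids whose anchor atom (phosphorus by default) sits above the bilayer
    midplane — the mean anchor z in the reference frame — go to the upper
    leaflet, the rest to the lower.
    """
    anchor_z: dict[int, float] = {}
    for i, a in enumerate(topology.atoms):
        if a.lipid_id >= 0 and a.atom_name == anchor_name:
            anchor_z[a.lipid_id] = frames.coords[reference_frame, i, 2]
    lipid_ids = {a.lipid_id for a in topology.atoms if a.lipid_id >= 0}
    missing = lipid_ids - set(anchor_z)
    if missing:
        raise TopologyError(
            f"lipids without anchor atom {anchor_name!r}: {sorted(missing)[:5]}..."
            if len(missing) > 5
            else f"lipids without anchor atom {anchor_name!r}: {sorted(missing)}"
        )
    zs = np.array(list(anchor_z.values()))
    if zs.size and np.allclose(zs, zs[0]):
        raise DegenerateGeometryError(
            "all leaflet anchors at identical z: degenerate (flat) bilayer"
        )
    midplane = float(zs.mean())
    leaflet = {lid: ("upper" if z > midplane else "lower") for lid, z in anchor_z.items()}
    return replace(topology, leaflet=leaflet)


def salt_concentration(n_cations: int, n_waters: int) -> float:
    """Nominal salt molarity from counts: n_cations × 55.5 M / n_waters."""
    if n_waters <= 0:
        raise DomainError(f"n_waters must be > 0, got {n_waters}")
    if n_cations < 0:
        raise DomainError(f"n_cations must be >= 0, got {n_cations}")
    return n_cations * WATER_MOLARITY / n_waters


def water_per_lipid(n_waters: int, n_lipids: int) -> float:
    """Hydration level: water molecules per lipid."""
    if n_lipids <= 0:
        raise DomainError(f"n_lipids must be > 0, got {n_lipids}")
    if n_waters < 0:
        raise DomainError(f"n_waters must be >= 0, got {n_waters}")
    return n_waters / n_lipids
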
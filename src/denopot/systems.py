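"""Conformations, batching, neighbor lists, and standard-format I/O.

Units are fixed package-wide: coordinates in Å, energies in kcal/mol,
forces in kcal/mol/Å.  Unit conversions happen only at I/O boundaries
(e.g. the ANI HDF5 reader converts Hartree to kcal/mol).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "HARTREE_TO_KCALMOL",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "AtomicConformation",
    "ConformationBatch",
    "NeighborList",
    "FormatError",
    "batch_conformations",
    "unbatch_conformations",
    "build_neighbor_list",
    "read_xyz",
    "write_xyz",
    "read_ani_hdf5",
    "write_dataset",
    "read_dataset",
]

HARTREE_TO_KCALMOL = 627.509474

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
]
SYMBOL_TO_Z = {s: z for z, s in enumerate(_SYMBOLS) if z > 0}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}


class FormatError(ValueError):
    """Raised for malformed molecular file content."""


@dataclass
class AtomicConformation:
    """One molecule: element numbers, Cartesian coordinates, optional labels."""

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    energy: float | None = None
    forces: np.ndarray | None = None
    molecule_id: str = ""
    conformation_id: str = ""

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        n = self.atomic_numbers.shape[0]
        if n < 1:
            raise ValueError("a conformation needs at least one atom")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} != ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=np.float64)
            if self.forces.shape != (n, 3):
                raise ValueError("forces shape must match coordinates")
        if self.energy is not None:
            self.energy = float(self.energy)

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.shape[0])


@dataclass
class ConformationBatch:
    """Disjoint union of B conformations as concatenated per-atom arrays."""

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    segment_index: np.ndarray  # atom -> conformation, non-decreasing
    counts: np.ndarray  # atoms per conformation
    energies: np.ndarray  # nan where absent
    molecule_ids: list = field(default_factory=list)
    conformation_ids: list = field(default_factory=list)

    @property
    def n_conformations(self) -> int:
        return int(self.counts.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.atomic_numbers.shape[0])


def batch_conformations(conformations) -> ConformationBatch:
    conformations = list(conformations)
    if not conformations:
        raise ValueError("cannot batch an empty sequence of conformations")
    counts = np.array([c.n_atoms for c in conformations], dtype=np.int64)
    seg = np.repeat(np.arange(len(conformations)), counts)
    return ConformationBatch(
        atomic_numbers=np.concatenate([c.atomic_numbers for c in conformations]),
        coordinates=np.concatenate([c.coordinates for c in conformations]),
        segment_index=seg,
        counts=counts,
        energies=np.array(
            [np.nan if c.energy is None else c.energy for c in conformations]
        ),
        molecule_ids=[c.molecule_id for c in conformations],
        conformation_ids=[c.conformation_id for c in conformations],
    )


def unbatch_conformations(batch: ConformationBatch) -> list[AtomicConformation]:
    offsets = np.concatenate([[0], np.cumsum(batch.counts)])
    out = []
    for b in range(batch.n_conformations):
        lo, hi = offsets[b], offsets[b + 1]
        e = batch.energies[b]
        out.append(
            AtomicConformation(
                atomic_numbers=batch.atomic_numbers[lo:hi].copy(),
                coordinates=batch.coordinates[lo:hi].copy(),
                energy=None if np.isnan(e) else float(e),
                molecule_id=batch.molecule_ids[b] if batch.molecule_ids else "",
                conformation_id=(
                    batch.conformation_ids[b] if batch.conformation_ids else ""
                ),
            )
        )
    return out


@dataclass
class NeighborList:
    """Symmetric directed pair list (i, j) with i != j within each conformation."""

    index_i: np.ndarray
    index_j: np.ndarray
    rij: np.ndarray  # x_i - x_j
    distances: np.ndarray
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return int(self.index_i.shape[0])


def build_neighbor_list(batch: ConformationBatch, d_cut: float) -> NeighborList:
    """All directed pairs with interatomic distance strictly below ``d_cut``.

    Pairs never cross conformation boundaries.  Uses a k-d tree per
    conformation; for the molecule sizes handled here this is effectively
    linear in the atom count.
    """
    if d_cut <= 0:
        raise ValueError(f"d_cut must be positive, got {d_cut}")
    offsets = np.concatenate([[0], np.cumsum(batch.counts)])
    ii, jj = [], []
    for b in range(batch.n_conformations):
        lo, hi = int(offsets[b]), int(offsets[b + 1])
        x = batch.coordinates[lo:hi]
        tree = cKDTree(x)
        pairs = tree.query_pairs(d_cut, output_type="ndarray")
        if pairs.size:
            # query_pairs uses distance <= r; enforce strict inequality
            d = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
            pairs = pairs[d < d_cut]
        if pairs.size:
            ii.append(pairs[:, 0] + lo)
            jj.append(pairs[:, 1] + lo)
            ii.append(pairs[:, 1] + lo)
            jj.append(pairs[:, 0] + lo)
    if ii:
        index_i = np.concatenate(ii)
        index_j = np.concatenate(jj)
        order = np.lexsort((index_j, index_i))
        index_i, index_j = index_i[order], index_j[order]
    else:
        index_i = np.zeros(0, dtype=np.intp)
        index_j = np.zeros(0, dtype=np.intp)
    rij = batch.coordinates[index_i] - batch.coordinates[index_j]
    return NeighborList(
        index_i=index_i,
        index_j=index_j,
        rij=rij,
        distances=np.linalg.norm(rij, axis=1),
        cutoff=float(d_cut),
    )


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ
# ---------------------------------------------------------------------------

def _parse_comment(comment: str) -> dict:
    out = {}
    for token in comment.split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v.strip('"')
    return out


def read_xyz(path) -> list[AtomicConformation]:
    """Read a (multi-frame) XYZ or extended-XYZ file.

    The comment line is scanned for ``key=value`` tokens; ``energy`` (kcal/mol),
    ``molecule_id`` and ``conformation_id`` are recognized.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    out = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise FormatError(f"{path}:{ln + 1}: expected an atom count")
        if n < 1:
            raise FormatError(f"{path}:{ln + 1}: atom count must be >= 1")
        if ln + 1 + n >= len(lines) + 1 and ln + 1 + n > len(lines):
            raise FormatError(
                f"{path}:{ln + 1}: header says {n} atoms but the file ends early"
            )
        meta = _parse_comment(lines[ln + 1]) if ln + 1 < len(lines) else {}
        z = np.zeros(n, dtype=np.int64)
        xyz = np.zeros((n, 3))
        for k in range(n):
            lineno = ln + 2 + k
            if lineno >= len(lines):
                raise FormatError(
                    f"{path}:{ln + 1}: header says {n} atoms but the file ends early"
                )
            fields = lines[lineno].split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno + 1}: expected `symbol x y z`")
            sym = fields[0]
            if sym in SYMBOL_TO_Z:
                z[k] = SYMBOL_TO_Z[sym]
            else:
                try:
                    z[k] = int(sym)
                except ValueError:
                    raise FormatError(f"{path}:{lineno + 1}: unknown element {sym!r}")
            try:
                xyz[k] = [float(f) for f in fields[1:4]]
            except ValueError:
                raise FormatError(f"{path}:{lineno + 1}: unparsable coordinates")
        energy = float(meta["energy"]) if "energy" in meta else None
        out.append(
            AtomicConformation(
                atomic_numbers=z,
                coordinates=xyz,
                energy=energy,
                molecule_id=meta.get("molecule_id", ""),
                conformation_id=meta.get("conformation_id", ""),
            )
        )
        ln += 2 + n
    return out


def write_xyz(conformations, path, precision: int = 8) -> None:
    path = Path(path)
    chunks = []
    for c in conformations:
        meta = []
        if c.energy is not None:
            meta.append(f"energy={c.energy:.{precision}f}")
        if c.molecule_id:
            meta.append(f"molecule_id={c.molecule_id}")
        if c.conformation_id:
            meta.append(f"conformation_id={c.conformation_id}")
        chunks.append(f"{c.n_atoms}\n{' '.join(meta)}\n")
        for z, (x, y, w) in zip(c.atomic_numbers, c.coordinates):
            sym = Z_TO_SYMBOL.get(int(z), str(int(z)))
            chunks.append(
                f"{sym} {x:.{precision}f} {y:.{precision}f} {w:.{precision}f}\n"
            )
    path.write_text("".join(chunks))


# ---------------------------------------------------------------------------
# ANI-style HDF5 (optional interface; no test depends on downloaded data)
# ---------------------------------------------------------------------------

def read_ani_hdf5(path) -> list[AtomicConformation]:
    """Read an ANI-layout HDF5 file: group per molecule with a ``species``
    string array, an M×N×3 ``coordinates`` stack, and an optional M-vector
    ``energies`` in Hartree (converted to kcal/mol)."""
    import h5py

    out = []
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if not isinstance(obj, h5py.Group):
                return
            keys = set(obj.keys())
            if "coordinates" not in keys and "species" not in keys:
                return
            if "coordinates" not in keys or "species" not in keys:
                raise FormatError(
                    f"group {name!r}: needs both `species` and `coordinates`"
                )
            species = [
                s.decode() if isinstance(s, bytes) else str(s)
                for s in obj["species"][()]
            ]
            z = np.array([SYMBOL_TO_Z[s] for s in species], dtype=np.int64)
            coords = np.asarray(obj["coordinates"][()], dtype=np.float64)
            if coords.ndim == 2:
                coords = coords[None]
            energies = obj["energies"][()] if "energies" in keys else None
            for m in range(coords.shape[0]):
                e = (
                    float(energies[m]) * HARTREE_TO_KCALMOL
                    if energies is not None
                    else None
                )
                out.append(
                    AtomicConformation(
                        atomic_numbers=z,
                        coordinates=coords[m],
                        energy=e,
                        molecule_id=name,
                        conformation_id=str(m),
                    )
                )

        f.visititems(visit)
    return out


# ---------------------------------------------------------------------------
# packaged-dataset container: directory with index.json + one XYZ per molecule
# ---------------------------------------------------------------------------

def write_dataset(directory, molecules: dict[str, list[AtomicConformation]],
                  seed: int | None = None) -> None:
    """Write a dataset as one extended-XYZ file per molecule plus an index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {
        "seed": seed,
        "molecules": {mid: len(confs) for mid, confs in molecules.items()},
    }
    for mid, confs in molecules.items():
        write_xyz(confs, directory / f"{mid}.xyz")
    (directory / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))


def read_dataset(directory) -> dict[str, list[AtomicConformation]]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    out = {}
    for mid, count in index["molecules"].items():
        confs = read_xyz(directory / f"{mid}.xyz")
        if len(confs) != count:
            warnings.warn(
                f"{mid}: index lists {count} conformations, file has {len(confs)}"
            )
        for c in confs:
            c.molecule_id = c.molecule_id or mid
        out[mid] = confs
    return out
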
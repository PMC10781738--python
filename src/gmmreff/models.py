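"""Atomic models with per-atom Gaussian widths, and PDB/mmCIF I/O.

Throughout this package the per-atom "B-factor" is the width (sigma, in Å)
of the Gaussian that represents the atom's density spread — not the
crystallographic ``8π²⟨u²⟩`` displacement parameter.  The I/O layer can
convert from/to the crystallographic convention on request.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import re
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "AtomicModel",
    "read_model",
    "write_model",
    "sigma_to_crystallographic",
    "crystallographic_to_sigma",
]

EIGHT_PI_SQ = 8.0 * math.pi**2

#: Anchor atom names used for per-residue scores and RMSF: Cα for amino
#: acids, C1′ for nucleotides.
ANCHOR_ATOM_NAMES = ("CA", "C1'")


def sigma_to_crystallographic(sigma: np.ndarray | float) -> np.ndarray | float:
    """Convert a Gaussian width sigma (Å) to a crystallographic B (Å²)."""
    return EIGHT_PI_SQ * np.square(sigma)


def crystallographic_to_sigma(b: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`sigma_to_crystallographic`: σ = sqrt(B / 8π²)."""
    return np.sqrt(np.asarray(b, dtype=np.float64) / EIGHT_PI_SQ)


@dataclasses.dataclass
class Atom:
    """A single atom: identity, position x (Å), Gaussian width B (Å), Z."""

    serial: int
    element: str
    atomic_number: int
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    bwidth: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64).reshape(3)
        if self.atomic_number < 0:
            raise ValueError("atomic_number must be >= 0")
        if not (np.isfinite(self.bwidth) and self.bwidth > 0):
            raise ValueError("bwidth must be positive and finite")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


class AtomicModel:
    """An ordered collection of atoms with optional bonds.

    Stored internally as parallel arrays for vectorised refinement; the
    :meth:`atoms` iterator and :meth:`atom` accessor give per-atom views.
    Bonds are pairs of atom indices, used by the built-in relaxer and by
    synthetic topologies.
    """

    def __init__(
        self,
        serial: Sequence[int],
        element: Sequence[str],
        atomic_number: Sequence[int],
        chain_id: Sequence[str],
        residue_index: Sequence[int],
        residue_name: Sequence[str],
        atom_name: Sequence[str],
        positions: np.ndarray,
        bwidth: Sequence[float],
        bonds: Sequence[tuple[int, int]] | None = None,
    ) -> None:
        n = len(serial)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.element = np.asarray(element, dtype=object)
        self.atomic_number = np.asarray(atomic_number, dtype=np.int64)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.residue_index = np.asarray(residue_index, dtype=np.int64)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.atom_name = np.asarray(atom_name, dtype=object)
        self.positions = np.asarray(positions, dtype=np.float64).reshape(n, 3).copy()
        self.bwidth = np.asarray(bwidth, dtype=np.float64).copy()
        self.bonds = [tuple(map(int, b)) for b in (bonds or [])]
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_atoms(
        cls, atoms: Sequence[Atom], bonds: Sequence[tuple[int, int]] | None = None
    ) -> "AtomicModel":
        return cls(
            serial=[a.serial for a in atoms],
            element=[a.element for a in atoms],
            atomic_number=[a.atomic_number for a in atoms],
            chain_id=[a.chain_id for a in atoms],
            residue_index=[a.residue_index for a in atoms],
            residue_name=[a.residue_name for a in atoms],
            atom_name=[a.atom_name for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=np.float64).reshape(
                len(atoms), 3
            ),
            bwidth=[a.bwidth for a in atoms],
            bonds=bonds,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, bonds: Sequence[tuple[int, int]] | None = None
    ) -> "AtomicModel":
        """Build a model from a DataFrame with columns serial, element,
        atomic_number, chain_id, residue_index, residue_name, atom_name,
        x, y, z, bwidth."""
        return cls(
            serial=df["serial"].to_numpy(),
            element=df["element"].to_numpy(),
            atomic_number=df["atomic_number"].to_numpy(),
            chain_id=df["chain_id"].to_numpy(),
            residue_index=df["residue_index"].to_numpy(),
            residue_name=df["residue_name"].to_numpy(),
            atom_name=df["atom_name"].to_numpy(),
            positions=df[["x", "y", "z"]].to_numpy(),
            bwidth=df["bwidth"].to_numpy(),
            bonds=bonds,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "serial": self.serial,
                "element": self.element,
                "atomic_number": self.atomic_number,
                "chain_id": self.chain_id,
                "residue_index": self.residue_index,
                "residue_name": self.residue_name,
                "atom_name": self.atom_name,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "bwidth": self.bwidth,
            }
        )

    # -- protocol ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            element=str(self.element[i]),
            atomic_number=int(self.atomic_number[i]),
            chain_id=str(self.chain_id[i]),
            residue_index=int(self.residue_index[i]),
            residue_name=str(self.residue_name[i]),
            atom_name=str(self.atom_name[i]),
            position=self.positions[i],
            bwidth=float(self.bwidth[i]),
        )

    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield self.atom(i)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            serial=self.serial.copy(),
            element=self.element.copy(),
            atomic_number=self.atomic_number.copy(),
            chain_id=self.chain_id.copy(),
            residue_index=self.residue_index.copy(),
            residue_name=self.residue_name.copy(),
            atom_name=self.atom_name.copy(),
            positions=self.positions.copy(),
            bwidth=self.bwidth.copy(),
            bonds=list(self.bonds),
        )

    def subset(self, indices: np.ndarray) -> "AtomicModel":
        """A new model containing the selected atoms; bonds are remapped
        and any bond crossing the selection boundary is dropped."""
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        remap = {int(old): new for new, old in enumerate(indices)}
        bonds = [
            (remap[i], remap[j])
            for i, j in self.bonds
            if i in remap and j in remap
        ]
        return AtomicModel(
            serial=self.serial[indices],
            element=self.element[indices],
            atomic_number=self.atomic_number[indices],
            chain_id=self.chain_id[indices],
            residue_index=self.residue_index[indices],
            residue_name=self.residue_name[indices],
            atom_name=self.atom_name[indices],
            positions=self.positions[indices],
            bwidth=self.bwidth[indices],
            bonds=bonds,
        )

    def validate(self) -> None:
        n = len(self)
        if n:
            if not np.all(np.isfinite(self.positions)):
                raise ValueError("atom positions contain NaN/Inf")
            if not np.all(np.isfinite(self.bwidth)) or np.any(self.bwidth <= 0):
                raise ValueError("bwidth must be positive and finite for all atoms")
            if np.any(self.atomic_number < 0):
                raise ValueError("atomic_number must be >= 0")
            keys = list(zip(self.chain_id, self.residue_index, self.atom_name))
            if len(set(keys)) != n:
                seen: set = set()
                for k in keys:
                    if k in seen:
                        raise ValueError(
                            f"duplicate (chain_id, residue_index, atom_name): {k}"
                        )
                    seen.add(k)
        for i, j in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) does not reference two distinct atoms")

    # -- residue / anchor helpers ----------------------------------------

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue labels '(chain_id, residue_index)' as strings."""
        return np.array(
            [f"{c}|{r}" for c, r in zip(self.chain_id, self.residue_index)],
            dtype=object,
        )

    def residue_groups(self) -> dict[tuple[str, int], np.ndarray]:
        """Atom indices grouped by (chain_id, residue_index), in file order."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i in range(len(self)):
            groups.setdefault(
                (str(self.chain_id[i]), int(self.residue_index[i])), []
            ).append(i)
        return {k: np.array(v) for k, v in groups.items()}

    def anchor_indices(self) -> dict[tuple[str, int], int]:
        """Per-residue anchor atom (Cα, or C1′ for nucleotides)."""
        anchors: dict[tuple[str, int], int] = {}
        for key, idx in self.residue_groups().items():
            for i in idx:
                if str(self.atom_name[i]) in ANCHOR_ATOM_NAMES:
                    anchors[key] = int(i)
                    break
        return anchors


# -- file I/O -------------------------------------------------------------


def _infer_atomic_number(element: str, atom_name: str) -> int:
    el = gemmi.Element(element)
    if el.atomic_number > 0:
        return el.atomic_number
    stripped = re.sub(r"[^A-Za-z]", "", atom_name)
    for probe in (stripped[:2].capitalize(), stripped[:1].upper()):
        el = gemmi.Element(probe)
        if el.atomic_number > 0:
            return el.atomic_number
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def read_model(
    path: str | Path,
    bfactor_convention: str = "sigma",
    b_floor: float = 0.25,
) -> AtomicModel:
    """Read a PDB or mmCIF model.

    ``bfactor_convention`` controls how the file's B column is mapped to the
    stored Gaussian width: ``"sigma"`` takes it verbatim (Å), while
    ``"crystallographic"`` applies σ = sqrt(B / 8π²).  Non-positive column
    values are replaced by ``b_floor`` (logged).  Only the first model and
    the first alternate conformer are kept.
    """
    if bfactor_convention not in ("sigma", "crystallographic"):
        raise ValueError(f"unknown bfactor_convention {bfactor_convention!r}")
    st = gemmi.read_structure(str(path))
    atoms: list[Atom] = []
    serial = 0
    n_floored = n_altloc = n_occ = 0
    for chain in st[0]:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    n_altloc += 1
                    continue
                if abs(at.occ - 1.0) > 1e-6:
                    n_occ += 1
                b = float(at.b_iso)
                if bfactor_convention == "crystallographic" and b > 0:
                    b = float(crystallographic_to_sigma(b))
                if b <= 0 or not np.isfinite(b):
                    b = b_floor
                    n_floored += 1
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        element=at.element.name,
                        atomic_number=_infer_atomic_number(at.element.name, at.name),
                        chain_id=chain.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        atom_name=at.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        bwidth=b,
                    )
                )
    if n_altloc:
        log.warning("dropped %d alternate-conformer atoms beyond altloc A", n_altloc)
    if n_occ:
        log.info("%d atoms have occupancy != 1 (occupancy is ignored)", n_occ)
    if n_floored:
        log.warning(
            "replaced %d non-positive B-column values by floor %.3g Å",
            n_floored,
            b_floor,
        )
    return AtomicModel.from_atoms(atoms)


def write_model(
    model: AtomicModel, path: str | Path, bfactor_convention: str = "sigma"
) -> None:
    """Write a model as PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``).

    The B column holds the stored width verbatim (``sigma``) or converted to
    ``8π²σ²`` (``crystallographic``).
    """
    if bfactor_convention not in ("sigma", "crystallographic"):
        raise ValueError(f"unknown bfactor_convention {bfactor_convention!r}")
    model.validate()
    path = Path(path)
    as_pdb = path.suffix.lower() == ".pdb"
    if as_pdb and len(model) and np.any(np.abs(model.positions) >= 10000):
        raise ValueError(
            "coordinates exceed PDB fixed-width fields; write mmCIF (.cif) instead"
        )
    st = gemmi.Structure()
    st.name = "gmmreff"
    mdl = gemmi.Model("1")
    for chain_name in dict.fromkeys(model.chain_id):
        chain = gemmi.Chain(str(chain_name))
        sel = np.flatnonzero(model.chain_id == chain_name)
        for res_idx in dict.fromkeys(model.residue_index[sel]):
            rsel = sel[model.residue_index[sel] == res_idx]
            res = gemmi.Residue()
            res.name = str(model.residue_name[rsel[0]])
            res.seqid = gemmi.SeqId(int(res_idx), " ")
            for i in rsel:
                at = gemmi.Atom()
                at.name = str(model.atom_name[i])
                at.element = gemmi.Element(str(model.element[i]))
                at.pos = gemmi.Position(*model.positions[i])
                b = model.bwidth[i]
                if bfactor_convention == "crystallographic":
                    b = float(sigma_to_crystallographic(b))
                at.b_iso = float(b)
                at.occ = 1.0
                at.serial = int(model.serial[i])
                res.add_atom(at)
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    if as_pdb:
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
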
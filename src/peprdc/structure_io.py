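"""Multi-model coordinate I/O and geometry primitives.

Reads PDB/mmCIF ensembles into a light-weight in-memory representation
(``Atom``/``Model``/``Ensemble``), and provides the geometric primitives the
rest of the package is built on: dihedral angles, Kabsch superposition,
ensemble precision (mean pairwise RMSD) and cystine detection.

Residue numbering is author (PDB) numbering, used verbatim.  Legacy
``HB1``/``HB2`` β-methylene proton names are remapped to IUPAC ``Hβ2``/``Hβ3``
(``HB2``/``HB3``) on input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Model",
    "Ensemble",
    "Superposition",
    "read_ensemble",
    "write_ensemble_pdb",
    "dihedral",
    "superpose",
    "ensemble_precision",
    "find_cystines",
    "BACKBONE_ATOMS",
    "STRUCTURED_REGIONS_TA1A",
]

#: Backbone atom set used for "backbone" metrics (field convention).
BACKBONE_ATOMS = ("N", "CA", "C")

#: Structured-region residue ranges used for the Ta1a-style precision metric.
STRUCTURED_REGIONS_TA1A = ((3, 5), (7, 50))

# legacy PDB v2 beta-methylene names -> IUPAC
_LEGACY_H_REMAP = {"HB1": "HB2", "HB2": "HB3", "1HB": "HB2", "2HB": "HB3"}


class MissingAtomError(KeyError):
    """An operation needed an atom that is absent from the model."""


class UndefinedDihedralError(ValueError):
    """Dihedral undefined because three consecutive points are collinear."""


@dataclass(frozen=True)
class Atom:
    """A single atom with author numbering preserved exactly."""

    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # shape (3,), Å

    @property
    def key(self) -> tuple[str, int, str]:
        """Identifier (chain, residue_number, atom name) — unique in a model."""
        return (self.chain_id, self.residue_number, self.name)


@dataclass
class Model:
    """One member of a (possibly multi-model) coordinate deposition."""

    model_index: int
    atoms: list[Atom]

    def __post_init__(self) -> None:
        self._index = {a.key: a for a in self.atoms}
        if len(self._index) != len(self.atoms):
            raise ValueError("duplicate atom identifiers within a model")

    def atom(self, chain_id: str, residue_number: int, name: str) -> Atom:
        try:
            return self._index[(chain_id, residue_number, name)]
        except KeyError:
            raise MissingAtomError(
                f"atom {name} of residue {residue_number} (chain {chain_id!r}) "
                "not found in model"
            ) from None

    def has_atom(self, chain_id: str, residue_number: int, name: str) -> bool:
        return (chain_id, residue_number, name) in self._index

    def position(self, chain_id: str, residue_number: int, name: str) -> np.ndarray:
        return self.atom(chain_id, residue_number, name).position

    @property
    def atom_keys(self) -> set[tuple[str, int, str]]:
        return set(self._index)

    def residues(self) -> dict[tuple[str, int], str]:
        """Map (chain, residue_number) -> residue_name."""
        out: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            out[(a.chain_id, a.residue_number)] = a.residue_name
        return out

    def coordinates(self, keys: Sequence[tuple[str, int, str]]) -> np.ndarray:
        return np.array([self._index[k].position for k in keys], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        """Return a rigid-body transformed copy (x -> R x + t)."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            Atom(a.name, a.element, a.residue_number, a.residue_name, a.chain_id,
                 rot @ a.position + t)
            for a in self.atoms
        ]
        return Model(self.model_index, atoms)


@dataclass
class Ensemble:
    """An ordered collection of models sharing one atom identifier set.

    Atoms missing from some models are dropped from ensemble-wide
    computations (with a logged warning at read time).
    """

    models: list[Model]
    source_id: str = ""
    ssbonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def common_atom_keys(self) -> set[tuple[str, int, str]]:
        keys = self.models[0].atom_keys
        for m in self.models[1:]:
            keys &= m.atom_keys
        return keys


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid-body fit of one selection onto another."""

    rotation: np.ndarray  # 3x3, det=+1
    translation: np.ndarray  # (3,)
    rmsd: float  # Å
    selection: tuple[tuple[str, int, str], ...]

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _convert_gemmi_model(gmodel: gemmi.Model, index: int) -> Model:
    atoms: list[Atom] = []
    remapped: set[str] = set()
    for chain in gmodel:
        for res in chain:
            has_hb3 = any(a.name in ("HB3", "3HB") for a in res)
            for ga in res:
                name = ga.name
                # only remap when the file uses the legacy HB1/HB2 pair
                if name in _LEGACY_H_REMAP and not has_hb3:
                    remapped.add(f"{res.name}{res.seqid.num} {name}->{_LEGACY_H_REMAP[name]}")
                    name = _LEGACY_H_REMAP[name]
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    )
                )
    if remapped:
        logger.info("remapped legacy β-proton names: %s", sorted(remapped))
    return Model(index, atoms)


def read_ensemble(path: str | Path, fmt: str | None = None) -> Ensemble:
    """Read a multi-model PDB or mmCIF file into an :class:`Ensemble`.

    All MODEL records are returned; hydrogens are retained.  If models carry
    different atom sets, the intersection is used for ensemble-wide work and a
    warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")).lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    models = [_convert_gemmi_model(m, i + 1) for i, m in enumerate(st)]
    models = [m for m in models if m.atoms]
    if not models:
        raise ValueError(f"{path}: no models with coordinates found")
    sets = [m.atom_keys for m in models]
    common = set.intersection(*sets)
    if any(s != common for s in sets):
        logger.warning(
            "%s: models have mismatched atom sets; ensemble computations use "
            "the %d common atoms", path.name, len(common),
        )
    ssbonds = []
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Disulf:
            ssbonds.append((con.partner1.res_id.seqid.num, con.partner2.res_id.seqid.num))
    return Ensemble(models=models, source_id=path.stem, ssbonds=ssbonds)


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble to a multi-model PDB file (via gemmi)."""
    st = gemmi.Structure()
    st.name = ensemble.source_id or "SYNTH"
    for model in ensemble.models:
        gm = gemmi.Model(model.model_index)
        chains: dict[str, gemmi.Chain] = {}
        current: dict[str, tuple[int, str] | None] = {}
        for a in model.atoms:
            ch = chains.setdefault(a.chain_id, gemmi.Chain(a.chain_id))
            if current.get(a.chain_id) != (a.residue_number, a.residue_name):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, " ")
                ch.add_residue(res)
                current[a.chain_id] = (a.residue_number, a.residue_name)
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ch[-1].add_atom(ga)
        for ch in chains.values():
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees in (−180, 180], IUPAC sign convention.

    Positive for a clockwise rotation of p4 relative to p1 when looking down
    the p2→p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise UndefinedDihedralError("central bond has zero length")
    if np.linalg.norm(n1) < 1e-9 * max(np.linalg.norm(b1), 1.0) * nb2 or \
       np.linalg.norm(n2) < 1e-9 * max(np.linalg.norm(b3), 1.0) * nb2:
        raise UndefinedDihedralError("three consecutive points are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    ang = math.degrees(math.atan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return 180.0 if ang <= -180.0 + 1e-12 and math.isclose(abs(ang), 180.0, abs_tol=1e-9) else ang


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rotation/translation mapping ``mov`` onto ``ref`` (least squares)."""
    cref = ref.mean(axis=0)
    cmov = mov.mean(axis=0)
    a = ref - cref
    b = mov - cmov
    h = b.T @ a
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = b @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    trans = cref - rot @ cmov
    return rot, trans, rmsd


def _selection_keys(
    model: Model,
    selection: Iterable[tuple[str, int, str]] | None,
    residues: Iterable[tuple[int, int]] | None = None,
    atoms: Sequence[str] | None = None,
) -> list[tuple[str, int, str]]:
    if selection is not None:
        return list(selection)
    atoms = tuple(atoms) if atoms else BACKBONE_ATOMS
    keys = []
    for a in model.atoms:
        if a.name not in atoms:
            continue
        if residues is not None and not any(lo <= a.residue_number <= hi for lo, hi in residues):
            continue
        keys.append(a.key)
    return keys


def superpose(
    model_a: Model,
    model_b: Model,
    selection: Sequence[tuple[str, int, str]],
) -> Superposition:
    """Kabsch superposition of ``model_b`` onto ``model_a`` over ``selection``.

    Returns the rotation/translation mapping b's coordinates onto a, and the
    post-fit RMSD over the selection.
    """
    keys = list(selection)
    if len(keys) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    ref = model_a.coordinates(keys)
    mov = model_b.coordinates(keys)
    spread = ref - ref.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-8) < 2:
        raise ValueError("selection atoms are collinear; superposition is degenerate")
    rot, trans, rmsd = _kabsch(ref, mov)
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, selection=tuple(keys))


def rmsd_to_mean(ensemble: Ensemble, selection: Sequence[tuple[str, int, str]]) -> float:
    """Average RMSD of each model to the coordinate mean after iterative fit."""
    keys = sorted(set(selection) & ensemble.common_atom_keys)
    if not keys:
        raise ValueError("empty selection")
    coords = [m.coordinates(keys) for m in ensemble.models]
    ref = coords[0]
    for _ in range(10):
        fitted = []
        for c in coords:
            rot, trans, _ = _kabsch(ref, c)
            fitted.append(c @ rot.T + trans)
        new_ref = np.mean(fitted, axis=0)
        if np.max(np.abs(new_ref - ref)) < 1e-10:
            ref = new_ref
            break
        ref = new_ref
    rmsds = [np.sqrt(np.mean(np.sum((f - ref) ** 2, axis=1))) for f in fitted]
    return float(np.mean(rmsds))


def ensemble_precision(
    ensemble: Ensemble,
    selection: Sequence[tuple[str, int, str]] | None = None,
    residues: Iterable[tuple[int, int]] | None = None,
    atoms: Sequence[str] | None = None,
    method: str = "pairwise",
) -> float:
    """Ensemble coordinate precision (Å).

    Default is the mean pairwise RMSD over all C(n,2) model pairs, each pair
    superposed on the selection before measuring; ``method="to_mean"`` gives
    the mean RMSD to the iteratively fitted mean structure instead.
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble precision needs at least 2 models")
    keys = _selection_keys(ensemble.models[0], selection, residues, atoms)
    keys = sorted(set(keys) & ensemble.common_atom_keys)
    if not keys:
        raise ValueError("empty selection")
    if method == "to_mean":
        return rmsd_to_mean(ensemble, keys)
    if method != "pairwise":
        raise ValueError(f"unknown method {method!r}")
    vals = []
    for i in range(len(ensemble)):
        for j in range(i + 1, len(ensemble)):
            vals.append(superpose(ensemble.models[i], ensemble.models[j], keys).rmsd)
    return float(np.mean(vals))


def find_cystines(
    model: Model,
    sg_cutoff: float = 2.3,
    ssbond_fallback: Sequence[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Disulfide-bonded residue pairs by SG–SG distance (≤ ``sg_cutoff`` Å).

    Falls back to file SSBOND-style annotations when no SG atoms are present.
    Pairs are returned with the lower residue number first, sorted.
    """
    sg = [a for a in model.atoms if a.residue_name == "CYS" and a.name == "SG"]
    if not sg:
        return sorted(tuple(sorted(p)) for p in (ssbond_fallback or []))
    pairs = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if (sg[i].chain_id, sg[i].residue_number) == (sg[j].chain_id, sg[j].residue_number):
                continue
            if np.linalg.norm(sg[i].position - sg[j].position) <= sg_cutoff:
                pairs.append(tuple(sorted((sg[i].residue_number, sg[j].residue_number))))
    return sorted(set(pairs))
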
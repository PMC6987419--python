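"""Synthetic inputs for every pipeline stage.

Builds idealized peptides and cystines from internal coordinates (NeRF-style
chain extension), simulates RDC datasets from a known alignment tensor,
generates Karplus-derived J-couplings for chosen χ1 states (including
rotamer-averaged mixtures), and perturbs single models into ensembles with
controlled coordinate and helix-orientation spread.  All generators are
seed-deterministic.

Geometric conventions (L-amino acids, matching reference small-molecule
geometry): the CA-chirality improper dihedral(N, C, CA, Cβ) = +120°; around
the Cα–Cβ axis the β substituents sit at dihedral(N, Cα, Cβ, X) = χ1 for the
heavy branch, χ1+120° for Hβ2 and χ1−120° for Hβ3 (Val: second branch at
χ1+120°, Hβ at χ1−120°; Ile/Thr: Hβ at χ1+120°, second branch at χ1−120°).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import (
    DEFAULT_CONSTANTS,
    JNHB_CLASS_CUTOFFS,
    KARPLUS_HAHB,
    KARPLUS_NHB,
    DipolarConstants,
)
from .rdc_core import AlignmentTensor, RDCRecord, RDCSet, back_calculate
from .structure_io import Atom, Ensemble, Model

__all__ = [
    "GeometryTemplate",
    "REALISTIC",
    "TETRAHEDRAL",
    "build_peptide",
    "build_cystine",
    "build_disulfide_cluster",
    "build_ideal_helix",
    "mirror_model",
    "random_tensor",
    "backbone_rdc_records",
    "sidechain_sum_records",
    "simulate_rdcs",
    "simulate_jcouplings",
    "perturb_ensemble",
]

TETRAHEDRAL_ANGLE = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...

_THREE = {
    "G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "V": "VAL", "I": "ILE",
    "T": "THR", "L": "LEU", "F": "PHE", "N": "ASN", "D": "ASP", "E": "GLU",
    "Q": "GLN", "K": "LYS", "R": "ARG", "H": "HIS", "M": "MET", "W": "TRP",
    "Y": "TYR", "P": "PRO",
}
#: residues carrying a β-methine (single Hβ) rather than a β-methylene
METHINE_RESIDUES = ("VAL", "ILE", "THR")
_BRANCH = {"CYS": "SG", "SER": "OG", "THR": "OG1", "VAL": "CG1", "ILE": "CG1"}


@dataclass(frozen=True)
class GeometryTemplate:
    """Ideal bond lengths (Å) and angles (degrees) for the chain builder."""

    r_n_ca: float = 1.458
    r_ca_c: float = 1.525
    r_c_n: float = 1.329
    r_c_o: float = 1.231
    r_n_h: float = 1.02
    r_ca_ha: float = 1.09
    r_ca_cb: float = 1.53
    r_cb_h: float = 1.09
    r_cb_branch: float = 1.52
    r_cb_sg: float = 1.808
    r_cb_og: float = 1.417
    r_ss: float = 2.05
    a_n_ca_c: float = 111.0
    a_ca_c_n: float = 117.2
    a_c_n_ca: float = 121.7
    a_ca_c_o: float = 120.5
    a_c_n_h: float = 119.3
    a_ca_cb_x: float = TETRAHEDRAL_ANGLE
    a_n_ca_cb: float = TETRAHEDRAL_ANGLE
    a_ca_cb_sg: float = 114.0
    a_cb_sg_sg: float = 104.0
    omega: float = 180.0

    def branch_length(self, branch: str) -> float:
        if branch.startswith("S"):
            return self.r_cb_sg
        if branch.startswith("O"):
            return self.r_cb_og
        return self.r_cb_branch


REALISTIC = GeometryTemplate()
#: exact-tetrahedral variant: every sp3 center uses 109.47° so staggered
#: side-chain bonds are exactly parallel to their backbone partners
TETRAHEDRAL = GeometryTemplate(
    a_n_ca_c=TETRAHEDRAL_ANGLE,
    a_ca_cb_sg=TETRAHEDRAL_ANGLE,
    a_cb_sg_sg=TETRAHEDRAL_ANGLE,
)


def nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
         r: float, theta: float, tau: float) -> np.ndarray:
    """Place atom D with |C−D| = r, angle(B,C,D) = theta and
    dihedral(A,B,C,D) = tau (degrees).  A, B need not be bonded to C; any
    three non-collinear reference points define the frame."""
    theta = math.radians(theta)
    tau = math.radians(tau)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(tau),
         r * math.sin(theta) * math.sin(tau)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _ca_substituent_dirs(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                         theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit directions for Cβ and Hα on an L-alpha carbon.

    Both make angle ``theta_deg`` with Cα→N, symmetric about the N/C
    bisector plane; the chirality sign reproduces the L improper
    dihedral(N, C, Cα, Cβ) = +120°.
    """
    d1 = (n - ca) / np.linalg.norm(n - ca)
    d2 = (c - ca) / np.linalg.norm(c - ca)
    bis = -(d1 + d2)
    bis = bis / np.linalg.norm(bis)
    nrm = np.cross(d1, d2)
    nrm = nrm / np.linalg.norm(nrm)
    half = math.acos(float(np.clip(np.dot(d1, d2), -1, 1))) / 2.0
    cos_g = -math.cos(math.radians(theta_deg)) / math.cos(half)
    gamma = math.acos(float(np.clip(cos_g, -1, 1)))
    cb_dir = math.cos(gamma) * bis + math.sin(gamma) * nrm
    ha_dir = math.cos(gamma) * bis - math.sin(gamma) * nrm
    return cb_dir, ha_dir


def _beta_substituents(res_name: str, chi1: float) -> list[tuple[str, float]]:
    """(atom name, dihedral(N,CA,CB,X)) pairs for the β substituents."""
    branch = _BRANCH.get(res_name, "CG")
    if res_name == "ALA":
        return [("HB1", chi1), ("HB2", chi1 + 120.0), ("HB3", chi1 - 120.0)]
    if res_name == "VAL":
        return [("CG1", chi1), ("CG2", chi1 + 120.0), ("HB", chi1 - 120.0)]
    if res_name in ("ILE", "THR"):
        second = "CG2"
        return [(branch, chi1), ("HB", chi1 + 120.0), (second, chi1 - 120.0)]
    return [(branch, chi1), ("HB2", chi1 + 120.0), ("HB3", chi1 - 120.0)]


def _element(atom_name: str) -> str:
    return atom_name[0] if atom_name[0] in "NCOSH" else atom_name[1]


def build_peptide(
    sequence: str,
    phi_psi: list[tuple[float, float]],
    chi1_list: list[float | None] | None = None,
    template: GeometryTemplate = REALISTIC,
    chain_id: str = "A",
    start_residue: int = 1,
    model_index: int = 1,
) -> Model:
    """Build a peptide chain from internal coordinates.

    ``sequence`` is a one-letter code string; ``phi_psi`` gives (φ, ψ) per
    residue (φ of the first residue is unused); ``chi1_list`` gives χ1 per
    residue (ignored for Gly; None defaults to −60°).  Hydrogens are placed
    at ideal geometry.
    """
    sequence = sequence.upper()
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi length must match sequence")
    if chi1_list is None:
        chi1_list = [None] * len(sequence)
    if len(chi1_list) != len(sequence):
        raise ValueError("chi1_list length must match sequence")
    for letter in sequence:
        if letter not in _THREE:
            raise ValueError(f"invalid residue code {letter!r}")
    t = template
    n_res = len(sequence)
    bb: list[dict] = []
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([t.r_n_ca, 0.0, 0.0])
            ang = math.radians(t.a_n_ca_c)
            c = ca + t.r_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = bb[i - 1]
            n = nerf(prev["N"], prev["CA"], prev["C"], t.r_c_n, t.a_ca_c_n,
                     phi_psi[i - 1][1])
            ca = nerf(prev["CA"], prev["C"], n, t.r_n_ca, t.a_c_n_ca, t.omega)
            c = nerf(prev["C"], n, ca, t.r_ca_c, t.a_n_ca_c, phi)
        bb.append({"N": n, "CA": ca, "C": c})
    atoms: list[Atom] = []
    for i, letter in enumerate(sequence):
        res_name = _THREE[letter]
        res_num = start_residue + i
        n, ca, c = bb[i]["N"], bb[i]["CA"], bb[i]["C"]
        psi = phi_psi[i][1]
        pos: dict[str, np.ndarray] = {"N": n, "CA": ca, "C": c}
        pos["O"] = nerf(n, ca, c, t.r_c_o, t.a_ca_c_o, psi + 180.0)
        if i == 0:
            pos["H"] = nerf(c, ca, n, t.r_n_h, 109.5, 180.0)
        else:
            prev = bb[i - 1]
            pos["H"] = nerf(prev["CA"], prev["C"], n, t.r_n_h, t.a_c_n_h, 0.0)
        cb_dir, ha_dir = _ca_substituent_dirs(n, ca, c, t.a_n_ca_cb)
        if res_name == "GLY":
            pos["HA2"] = ca + t.r_ca_ha * cb_dir
            pos["HA3"] = ca + t.r_ca_ha * ha_dir
        else:
            pos["CB"] = ca + t.r_ca_cb * cb_dir
            pos["HA"] = ca + t.r_ca_ha * ha_dir
            chi1 = -60.0 if chi1_list[i] is None else float(chi1_list[i])
            for name, tau in _beta_substituents(res_name, chi1):
                if name.startswith("H"):
                    r, ang = t.r_cb_h, t.a_ca_cb_x
                elif name == "SG":
                    r, ang = t.r_cb_sg, t.a_ca_cb_sg
                else:
                    r, ang = t.branch_length(name), t.a_ca_cb_x
                pos[name] = nerf(n, ca, pos["CB"], r, ang, tau)
        for name, p in pos.items():
            atoms.append(Atom(name, _element(name), res_num, res_name, chain_id, p))
    return Model(model_index, atoms)


def build_cystine(
    chi: tuple[float, float, float, float, float],
    residue_numbers: tuple[int, int] = (1, 2),
    template: GeometryTemplate = REALISTIC,
    chain_id: str = "A",
    model_index: int = 1,
) -> Model:
    """Two-cysteine fragment with exactly the requested (χ1, χ2, χ3, χ2′, χ1′).

    The SG–SG bond is 2.05 Å; the five dihedrals round-trip through
    ``disulfide_geometry.cystine_dihedrals`` to numerical precision.
    """
    chi1, chi2, chi3, chi2p, chi1p = (float(x) for x in chi)
    t = template
    # residue 1 backbone
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([t.r_n_ca, 0.0, 0.0])
    ang = math.radians(t.a_n_ca_c)
    c1 = ca1 + t.r_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
    pos1: dict[str, np.ndarray] = {"N": n1, "CA": ca1, "C": c1}
    pos1["O"] = nerf(n1, ca1, c1, t.r_c_o, t.a_ca_c_o, 60.0)
    pos1["H"] = nerf(c1, ca1, n1, t.r_n_h, 109.5, 180.0)
    cb_dir, ha_dir = _ca_substituent_dirs(n1, ca1, c1, t.a_n_ca_cb)
    cb1 = ca1 + t.r_ca_cb * cb_dir
    pos1["CB"] = cb1
    pos1["HA"] = ca1 + t.r_ca_ha * ha_dir
    sg1 = nerf(n1, ca1, cb1, t.r_cb_sg, t.a_ca_cb_sg, chi1)
    pos1["SG"] = sg1
    pos1["HB2"] = nerf(n1, ca1, cb1, t.r_cb_h, t.a_ca_cb_x, chi1 + 120.0)
    pos1["HB3"] = nerf(n1, ca1, cb1, t.r_cb_h, t.a_ca_cb_x, chi1 - 120.0)
    # bridge and residue 2, extended atom by atom through the dihedrals
    sg2 = nerf(ca1, cb1, sg1, t.r_ss, t.a_cb_sg_sg, chi2)
    cb2 = nerf(cb1, sg1, sg2, t.r_cb_sg, t.a_cb_sg_sg, chi3)
    ca2 = nerf(sg1, sg2, cb2, t.r_ca_cb, t.a_ca_cb_sg, chi2p)
    n2 = nerf(sg2, cb2, ca2, t.r_n_ca, t.a_n_ca_cb, chi1p)
    pos2: dict[str, np.ndarray] = {"SG": sg2, "CB": cb2, "CA": ca2, "N": n2}
    # remaining Cα substituents via the L-offsets about the Cβ→Cα axis
    pos2["C"] = nerf(sg2, cb2, ca2, t.r_ca_c, t.a_n_ca_cb, chi1p - 120.0)
    pos2["HA"] = nerf(sg2, cb2, ca2, t.r_ca_ha, t.a_n_ca_cb, chi1p + 120.0)
    pos2["HB2"] = nerf(n2, ca2, cb2, t.r_cb_h, t.a_ca_cb_x, chi1p + 120.0)
    pos2["HB3"] = nerf(n2, ca2, cb2, t.r_cb_h, t.a_ca_cb_x, chi1p - 120.0)
    pos2["O"] = nerf(n2, ca2, pos2["C"], t.r_c_o, t.a_ca_c_o, 60.0)
    pos2["H"] = nerf(pos2["C"], ca2, n2, t.r_n_h, 109.5, 180.0)
    atoms = []
    for res_num, pos in zip(residue_numbers, (pos1, pos2)):
        for name, p in pos.items():
            atoms.append(Atom(name, _element(name), res_num, "CYS", chain_id, p))
    return Model(model_index, atoms)


def build_disulfide_cluster(
    pairing: list[tuple[int, int]],
    chi: tuple[float, float, float, float, float] = (-60.0, -60.0, -85.0, -60.0, -60.0),
    spacing: float = 10.0,
    template: GeometryTemplate = REALISTIC,
) -> Model:
    """Several cystine units placed on a line, ``spacing`` Å apart.

    The pairing of residue numbers is the ground truth a connectivity
    inference should recover; cross-pair Cβ–Cβ distances are ≥ the spacing
    minus the unit size.
    """
    atoms: list[Atom] = []
    for k, pair in enumerate(pairing):
        unit = build_cystine(chi, residue_numbers=tuple(sorted(pair)),
                             template=template)
        rot = Rotation.from_euler("z", 90.0 * k, degrees=True).as_matrix()
        offset = np.array([spacing * k, 0.0, 0.0])
        for a in unit.atoms:
            atoms.append(replace(a, position=rot @ a.position + offset))
    return Model(1, atoms)


def build_ideal_helix(
    n_residues: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    chain_id: str = "A",
    start_residue: int = 1,
) -> Model:
    """Cα-only ideal α-helix wound about ``axis`` (default +z).

    The construction axis is the ground truth for helix-axis fitting.
    """
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    origin = np.zeros(3) if origin is None else np.asarray(origin, float)
    # orthonormal frame about the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    atoms = []
    for i in range(n_residues):
        ang = math.radians(twist * i)
        p = origin + axis * (rise * i) + radius * (math.cos(ang) * u + math.sin(ang) * v)
        atoms.append(Atom("CA", "C", start_residue + i, "ALA", chain_id, p))
    return Model(1, atoms)


def mirror_model(model: Model) -> Model:
    """Mirror image (x → −x); all dihedrals negate."""
    atoms = [replace(a, position=a.position * np.array([-1.0, 1.0, 1.0]))
             for a in model.atoms]
    return Model(model.model_index, atoms)


def random_tensor(
    seed: int | np.random.Generator,
    da: float = 10.0,
    rhombicity: float = 0.3,
    constants: DipolarConstants = DEFAULT_CONSTANTS,
) -> AlignmentTensor:
    """Alignment tensor with given Da/R and a uniformly random frame."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rot = Rotation.random(random_state=rng).as_matrix()
    return AlignmentTensor.from_parameters(da, rhombicity, rot, constants)


def backbone_rdc_records(
    model: Model, medium_id: str, chain_id: str = "A"
) -> list[RDCRecord]:
    """Template records (d_obs = 0) for the four backbone coupling types:
    N-HN, Cα-Hα, C′-Cα intra-residue and the peptide-bond N(i)-C′(i−1)."""
    out = []
    residues = sorted((num, name) for (ch, num), name in
                      model.residues().items() if ch == chain_id)
    nums = [num for num, _ in residues]
    for num, name in residues:
        if model.has_atom(chain_id, num, "H") and model.has_atom(chain_id, num, "N"):
            out.append(RDCRecord(num, "N", num, "H", "N-HN", medium_id, 0.0, chain=chain_id))
        if name != "GLY" and model.has_atom(chain_id, num, "HA"):
            out.append(RDCRecord(num, "CA", num, "HA", "CA-HA", medium_id, 0.0, chain=chain_id))
        if model.has_atom(chain_id, num, "C"):
            out.append(RDCRecord(num, "C", num, "CA", "C-CA", medium_id, 0.0, chain=chain_id))
        if num - 1 in nums and model.has_atom(chain_id, num - 1, "C"):
            out.append(RDCRecord(num, "N", num - 1, "C", "N-C", medium_id, 0.0, chain=chain_id))
    return out


def sidechain_sum_records(
    model: Model, medium_id: str, chain_id: str = "A"
) -> list[RDCRecord]:
    """ΣCβHβ template records for every β-methylene residue present."""
    out = []
    for (ch, num), name in sorted(model.residues().items()):
        if ch != chain_id or name in ("GLY", "ALA") or name in METHINE_RESIDUES:
            continue
        if model.has_atom(ch, num, "HB2") and model.has_atom(ch, num, "HB3"):
            out.append(RDCRecord(num, "CB", num, "HB", "SUM-CBHB", medium_id, 0.0,
                                 chain=ch))
    return out


#: per-experiment measurement precision (Hz): one-bond C-C and N-C couplings
#: are small and measured from frequency differences with proportionally
#: better precision than the large one-bond N-H / C-H splittings
DEFAULT_RDC_NOISE_SD = {
    "N-HN": 1.0, "CA-HA": 1.0, "C-CA": 0.25, "N-C": 0.2, "SUM-CBHB": 1.0,
}


def simulate_rdcs(
    model: Model,
    tensor: AlignmentTensor,
    pair_list: list[RDCRecord],
    noise_sd: float | dict = 0.0,
    seed: int = 0,
    constants: DipolarConstants = DEFAULT_CONSTANTS,
) -> RDCSet:
    """Exact Saupe back-calculation plus Gaussian noise on the native scale.

    ``noise_sd`` is one sd (Hz) for all records or a per-rdc_type dict
    (see :data:`DEFAULT_RDC_NOISE_SD`).  A ΣCβHβ record is simulated as the
    sum of the two Cβ-Hβ couplings (one noise draw per summed observable).
    """
    clean = back_calculate(model, tensor, pair_list, constants, normalized=False)
    rng = np.random.default_rng(seed)
    if isinstance(noise_sd, dict):
        sds = np.array([noise_sd[r.rdc_type] for r in pair_list])
    else:
        sds = np.full(len(pair_list), float(noise_sd))
    noise = rng.normal(0.0, 1.0, size=len(pair_list)) * sds if sds.any() else 0.0
    values = clean + noise
    return RDCSet([replace(r, d_obs=float(v)) for r, v in zip(pair_list, values)])


def _karplus_value(theta_deg: float, coeffs: tuple[float, float, float]) -> float:
    a, b, c = coeffs
    ct = math.cos(math.radians(theta_deg))
    return a * ct * ct + b * ct + c


def simulate_jcouplings(
    residues: list[tuple[int, str, float | dict]],
    noise_sd: float = 0.0,
    seed: int = 0,
    karplus_hahb: tuple[float, float, float] = KARPLUS_HAHB,
    karplus_nhb: tuple[float, float, float] = KARPLUS_NHB,
    nhb_cutoffs: tuple[float, float] = JNHB_CLASS_CUTOFFS,
) -> list:
    """Population-weighted Karplus J values for chosen χ1 states.

    ``residues``: (residue id, residue type, state) with state a χ1 angle or
    a {χ1: weight} mixture (weights summing to 1).  Returns a list of
    :class:`~peprdc.rotamer_analysis.JCouplingSet`; qualitative ³J(NHβ)
    classes are derived from the noisy values with the shipped cutoffs.
    """
    from .rotamer_analysis import JCouplingSet, classify_nhb

    rng = np.random.default_rng(seed)
    out = []
    for res_id, res_type, state in residues:
        mixture = {float(state): 1.0} if not isinstance(state, dict) else \
            {float(k): float(v) for k, v in state.items()}
        if abs(sum(mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

        def avg(offset: float, coeffs) -> float:
            return sum(w * _karplus_value(chi + offset, coeffs)
                       for chi, w in mixture.items())

        def noisy(x: float) -> float:
            return x + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)

        if res_type in METHINE_RESIDUES:
            offset = 0.0 if res_type == "VAL" else -120.0
            j = noisy(avg(offset, karplus_hahb))
            out.append(JCouplingSet(residue_id=res_id, residue_type=res_type,
                                    j_hahb=j))
        else:
            j2 = noisy(avg(-120.0, karplus_hahb))  # θ(HαHβ2) = χ1 − 120
            j3 = noisy(avg(0.0, karplus_hahb))     # θ(HαHβ3) = χ1
            n2 = noisy(avg(+120.0, karplus_nhb))   # θ(NHβ2) = χ1 + 120
            n3 = noisy(avg(-120.0, karplus_nhb))   # θ(NHβ3) = χ1 − 120
            out.append(
                JCouplingSet(
                    residue_id=res_id, residue_type=res_type,
                    j_hahb2=j2, j_hahb3=j3,
                    j_nhb2_class=classify_nhb(n2, nhb_cutoffs),
                    j_nhb3_class=classify_nhb(n3, nhb_cutoffs),
                )
            )
    return out


def perturb_ensemble(
    model: Model,
    n_models: int,
    coord_jitter_sd: float = 0.0,
    seed: int = 0,
    helix_jitter: list[dict] | None = None,
) -> Ensemble:
    """``n_models`` copies with Gaussian atomic jitter and optional rigid
    rotations of designated residue segments about their centroids.

    ``helix_jitter`` entries: ``{"residues": (lo, hi), "sd_deg": float,
    "axis": 3-vector or None}``; a None axis draws a random direction
    perpendicular to the segment's principal axis for each model.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    rng = np.random.default_rng(seed)
    models = []
    for k in range(n_models):
        atoms = list(model.atoms)
        if helix_jitter:
            new_atoms = []
            rotations = []
            for spec in helix_jitter:
                lo, hi = spec["residues"]
                seg_idx = [i for i, a in enumerate(atoms)
                           if lo <= a.residue_number <= hi]
                seg = np.array([atoms[i].position for i in seg_idx])
                centroid = seg.mean(axis=0)
                axis = spec.get("axis")
                if axis is None:
                    centered = seg - centroid
                    _, _, vt = np.linalg.svd(centered, full_matrices=False)
                    principal = vt[0]
                    rand = rng.normal(size=3)
                    axis = rand - principal * np.dot(rand, principal)
                axis = np.asarray(axis, float)
                axis = axis / np.linalg.norm(axis)
                ang = rng.normal(0.0, spec["sd_deg"])
                rot = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
                rotations.append((set(seg_idx), centroid, rot))
            for i, a in enumerate(atoms):
                p = a.position
                for idx_set, centroid, rot in rotations:
                    if i in idx_set:
                        p = centroid + rot @ (p - centroid)
                new_atoms.append(replace(a, position=p))
            atoms = new_atoms
        if coord_jitter_sd > 0:
            noise = rng.normal(0.0, coord_jitter_sd, size=(len(atoms), 3))
            atoms = [replace(a, position=a.position + dn)
                     for a, dn in zip(atoms, noise)]
        models.append(Model(k + 1, [replace(a) for a in atoms]))
    return Ensemble(models=models, source_id="synthetic")
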
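"""Cystine dihedral geometry and the spiral/hook/staple taxonomy.

A disulfide bridge is described by five side-chain torsions
(χ1, χ2, χ3, χ2′, χ1′) running N–Cα–Cβ–Sγ → Cα–Cβ–Sγ–Sγ′ → Cβ–Sγ–Sγ′–Cβ′
and mirrored on the primed side.  The sign pattern of (χ2, χ3, χ2′) sets the
basic shape — both χ2 angles sharing χ3's sign is a spiral, exactly one a
hook, neither a staple — the sign of χ3 sets the handedness (RH for χ3 > 0),
and the χ1/χ1′ signs prefix the label, expanding six basic types to twenty.

Energetic ideality windows: χ1, χ2, χ1′, χ2′ near −60° (gauche−, −90…−30°),
+60° (gauche+, 30…90°) or 180° (trans, |χ| ≥ 150°); χ3 in −120…−60° (left)
or 60…120° (right).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .structure_io import Ensemble, Model, dihedral

__all__ = [
    "DisulfideGeometry",
    "DisulfideClass",
    "IdealityReport",
    "SHAPE_SIGN_TABLE",
    "cystine_dihedrals",
    "classify",
    "ideality",
    "ensemble_report",
]


@dataclass(frozen=True)
class DisulfideGeometry:
    """The five cystine torsions (degrees); residue i < j, primed = j."""

    pair: tuple[int, int]
    chi1: float
    chi2: float
    chi3: float
    chi2p: float
    chi1p: float
    model_index: int = 1

    @property
    def angles(self) -> tuple[float, float, float, float, float]:
        return (self.chi1, self.chi2, self.chi3, self.chi2p, self.chi1p)


@dataclass(frozen=True)
class DisulfideClass:
    """Shape + handedness + χ1-sign prefix, rendered e.g. "−LH-spiral"."""

    shape: str  # spiral | hook | staple
    handedness: str  # RH | LH
    chi1_signs: tuple[str, str]  # ordered by residue number
    label: str

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class IdealityReport:
    """Window membership per angle; "outside" marks non-ideal torsions."""

    chi1: str
    chi2: str
    chi3: str
    chi2p: str
    chi1p: str

    @property
    def all_ideal(self) -> bool:
        return "outside" not in (self.chi1, self.chi2, self.chi3,
                                 self.chi2p, self.chi1p)


#: sign-agreement rule: how many of (χ2, χ2′) share χ3's sign -> shape.
#: Shipped as data so it can be corrected against the cited taxonomy
#: without touching code.
SHAPE_SIGN_TABLE = {2: "spiral", 1: "hook", 0: "staple"}


class BorderlineAngleError(ValueError):
    """A classification angle too close to 0° for a stable sign call."""


def cystine_dihedrals(model: Model, pair: tuple[int, int],
                      chain_id: str = "A") -> DisulfideGeometry:
    """Measure the five torsions of a disulfide between two CYS residues.

    The lower residue number is the unprimed cysteine.
    """
    i, j = sorted(pair)
    p = {}
    for res, tag in ((i, ""), (j, "p")):
        for name in ("N", "CA", "CB", "SG"):
            p[name + tag] = model.position(chain_id, res, name)
    return DisulfideGeometry(
        pair=(i, j),
        chi1=dihedral(p["N"], p["CA"], p["CB"], p["SG"]),
        chi2=dihedral(p["CA"], p["CB"], p["SG"], p["SGp"]),
        chi3=dihedral(p["CB"], p["SG"], p["SGp"], p["CBp"]),
        chi2p=dihedral(p["CAp"], p["CBp"], p["SGp"], p["SG"]),
        chi1p=dihedral(p["Np"], p["CAp"], p["CBp"], p["SGp"]),
        model_index=model.model_index,
    )


def _sign(x: float) -> str:
    return "+" if x > 0 else "-"


def classify(geometry: DisulfideGeometry,
             borderline: float = 1.0) -> DisulfideClass:
    """Assign the 20-type sign taxonomy label.

    Any classification angle within ±``borderline`` degrees of zero gives an
    unclassifiable-borderline result (shape "borderline") rather than an
    arbitrary sign call.

    For hooks, the χ1 prefix is rendered with the sign belonging to the
    cysteine whose χ2 shares χ3's sign first, which makes the label
    invariant under residue relabeling and keeps the twenty types distinct;
    for spirals and staples the two sides are equivalent and a mixed prefix
    is always rendered "+/−".
    """
    angles = geometry.angles
    if any(abs(a) < borderline for a in angles):
        return DisulfideClass(shape="borderline", handedness="",
                              chi1_signs=(_sign(angles[0]), _sign(angles[4])),
                              label="borderline")
    s1, s2, s3, s2p, s1p = (_sign(a) for a in angles)
    n_share = (s2 == s3) + (s2p == s3)
    shape = SHAPE_SIGN_TABLE[n_share]
    handedness = "RH" if s3 == "+" else "LH"
    if shape == "hook":
        # orient by the sharing side
        first, second = (s1, s1p) if s2 == s3 else (s1p, s1)
    else:
        first, second = s1, s1p
    if first == second:
        prefix = first
    elif shape == "hook":
        prefix = f"{first}/{second}"
    else:
        prefix = "+/-"
    label = f"{prefix}{handedness}-{shape}"
    return DisulfideClass(shape=shape, handedness=handedness,
                          chi1_signs=(s1, s1p), label=label)


def _chi_window(angle: float) -> str:
    if -90.0 <= angle <= -30.0:
        return "gauche-"
    if 30.0 <= angle <= 90.0:
        return "gauche+"
    if angle >= 150.0 or angle <= -150.0:
        return "trans"
    return "outside"


def _chi3_window(angle: float) -> str:
    if -120.0 <= angle <= -60.0:
        return "left"
    if 60.0 <= angle <= 120.0:
        return "right"
    return "outside"


def ideality(geometry: DisulfideGeometry) -> IdealityReport:
    """Bin each torsion into its energetic window (or "outside")."""
    return IdealityReport(
        chi1=_chi_window(geometry.chi1),
        chi2=_chi_window(geometry.chi2),
        chi3=_chi3_window(geometry.chi3),
        chi2p=_chi_window(geometry.chi2p),
        chi1p=_chi_window(geometry.chi1p),
    )


def ensemble_report(ensemble: Ensemble, pairs: list[tuple[int, int]],
                    chain_id: str = "A") -> dict:
    """Per-pair census of classification labels across the ensemble.

    Returns {pair: {"census": Counter(label -> count), "heterogeneous":
    bool, "geometries": [...]}}.
    """
    out = {}
    for pair in pairs:
        geoms = [cystine_dihedrals(m, pair, chain_id) for m in ensemble.models]
        labels = [classify(g).label for g in geoms]
        census = Counter(labels)
        out[tuple(sorted(pair))] = {
            "census": census,
            "heterogeneous": len(census) > 1,
            "geometries": geoms,
        }
    return out
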
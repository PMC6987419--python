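"""χ1 rotamer determination from ³J couplings, NOEs and RDC sums.

For a β-methylene residue the pair of ³J(HαHβ) couplings together with the
qualitative ³J(NHβ) classes forms a distinctive small/large pattern for each
of the three staggered rotamers (χ1 = +60°, 180°, −60°), which also fixes
the stereospecific Hβ2/Hβ3 assignment.  Population averaging shows up as
couplings inside the 5.0–9.0 Hz band or as a "medium-medium" NHβ pair.
β-methine residues (Val/Ile/Thr) are classified from the single ³J(HαHβ).

Independently, the sum of the two Cβ-Hβ RDCs equals — at staggered geometry
— the sum of two appropriately normalized backbone RDCs, because each Cβ-Hβ
bond is then parallel (or antiparallel, which an RDC cannot distinguish) to
a specific backbone bond.  Which pair of backbone couplings matches
identifies χ1:

    χ1 = 180°: (Cα-Hα)_i + (Cα-C′)_i                [rule 1]
    χ1 = −60°: (Cα-Hα)_i + (Cα-C′)_{i−1}            [rule 2]
    χ1 = +60°: (Cα-C′)_i + (Cα-C′)_{i−1}            [rule 3]

where (Cα-C′)_{i−1} stands in for the intra-residue Cα-N bond (parallel to
it only approximately, so a rule-2 winner is reported as ambiguous between
−60° and 180°, which differ only in that approximated arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .rdc_core import RDCSet, normalize

__all__ = [
    "JCouplingSet",
    "Chi1Call",
    "RdcSumEvidence",
    "karplus",
    "classify_nhb",
    "classify_methylene",
    "classify_methine",
    "build_rdc_sum_evidence",
    "chi1_from_rdc_sums",
    "noe_consistency",
    "methylene_truth_table",
    "read_jcoupling_tsv",
]

STAGGERED = (-60.0, 60.0, 180.0)

#: dihedral offsets: θ(coupling) = χ1 + offset
_KIND_OFFSETS = {
    "hahb2": -120.0,
    "hahb3": 0.0,
    "nhb2": +120.0,
    "nhb3": -120.0,
    "hahb_val": 0.0,      # Val: Hβ at χ1 − 120 from CG1; θ(HαHβ) = χ1
    "hahb_ile": -120.0,   # Ile/Thr: Hβ at χ1 + 120; θ(HαHβ) = χ1 − 120
    "hahb_thr": -120.0,
}

#: χ1 giving a trans Hα-Hβ arrangement (large ³J) per methine residue type
METHINE_TRANS_CHI1 = {"VAL": 180.0, "ILE": -60.0, "THR": -60.0}


@dataclass(frozen=True)
class JCouplingSet:
    """One residue's J-coupling observations.

    Methylene residues carry (j_hahb2, j_hahb3) and qualitative NHβ classes;
    β-methine residues (Val/Ile/Thr) carry the single j_hahb.  The branch →
    Hβ2/Hβ3 naming of the inputs is tentative until a stereo assignment is
    made.
    """

    residue_id: int
    residue_type: str = "XXX"
    j_hahb2: float | None = None
    j_hahb3: float | None = None
    j_hahb: float | None = None
    j_nhb2_class: str | None = None
    j_nhb3_class: str | None = None
    overlapped: bool = False

    def __post_init__(self):
        methine = self.residue_type in ("VAL", "ILE", "THR")
        if methine and (self.j_hahb2 is not None or self.j_hahb3 is not None):
            raise ValueError("methine residues carry j_hahb only")
        if not methine and self.j_hahb is not None:
            raise ValueError("j_hahb is reserved for β-methine residues")


@dataclass(frozen=True)
class Chi1Call:
    """A χ1 determination with its method and evidence trail."""

    residue_id: int
    rotamer: str  # "+60" | "180" | "-60" | "average" | "undetermined" | "ambiguous(...)"
    stereo_assignment: dict | None = None
    method: str = "jcoupling"
    notes: str = ""

    def __post_init__(self):
        if self.rotamer == "average" and self.stereo_assignment is not None:
            raise ValueError("an averaged χ1 carries no stereo assignment")


def karplus(chi1: float, coefficients: tuple[float, float, float],
            coupling_kind: str | None = None) -> float:
    """J = A cos²θ + B cosθ + C with θ = χ1 + the kind-specific offset.

    ``coupling_kind=None`` evaluates at θ = χ1 directly.
    """
    offset = 0.0 if coupling_kind is None else _KIND_OFFSETS[coupling_kind]
    theta = math.radians(chi1 + offset)
    a, b, c = coefficients
    return a * math.cos(theta) ** 2 + b * math.cos(theta) + c


def classify_nhb(j_value: float, cutoffs: tuple[float, float] = K.JNHB_CLASS_CUTOFFS) -> str:
    """Qualitative |³J(NHβ)| class: small / medium / large."""
    small_max, large_min = cutoffs
    v = abs(j_value)
    if v <= small_max:
        return "small"
    if v >= large_min:
        return "large"
    return "medium"


def _class_hahb(j: float) -> str:
    if j <= K.JHAHB_SMALL_MAX:
        return "small"
    if j >= K.JHAHB_LARGE_MIN:
        return "large"
    return "medium"


def methylene_truth_table(
    karplus_hahb=K.KARPLUS_HAHB, karplus_nhb=K.KARPLUS_NHB,
    nhb_cutoffs=K.JNHB_CLASS_CUTOFFS,
) -> dict[float, tuple[str, str, str, str]]:
    """Expected (HαHβ2, HαHβ3, NHβ2, NHβ3) class 4-tuple per staggered χ1.

    Derived from the Karplus curves at exact staggered geometry rather than
    shipped as literals, so editing the coefficients updates the table.
    """
    table = {}
    for rot in STAGGERED:
        table[rot] = (
            _class_hahb(karplus(rot, karplus_hahb, "hahb2")),
            _class_hahb(karplus(rot, karplus_hahb, "hahb3")),
            classify_nhb(karplus(rot, karplus_nhb, "nhb2"), nhb_cutoffs),
            classify_nhb(karplus(rot, karplus_nhb, "nhb3"), nhb_cutoffs),
        )
    return table


def _rotamer_str(rot: float) -> str:
    return {60.0: "+60", 180.0: "180", -60.0: "-60"}[rot]


def classify_methylene(jset: JCouplingSet, table: dict | None = None) -> Chi1Call:
    """Pattern-match the coupling classes against the staggered truth table.

    Both stereo hypotheses (observed branch pair as given, or swapped) are
    tried; a unique match yields the rotamer and the stereo assignment.
    Couplings in the 5.0–9.0 Hz band and/or a medium-medium NHβ pair mean
    rotamer averaging; overlapped Hβ resonances are undetermined.
    """
    if jset.overlapped:
        return Chi1Call(jset.residue_id, "undetermined", method="jcoupling",
                        notes="overlapped Hβ2/Hβ3 resonances")
    have_j = jset.j_hahb2 is not None and jset.j_hahb3 is not None
    have_n = jset.j_nhb2_class is not None and jset.j_nhb3_class is not None
    if not (have_j or have_n):
        raise ValueError("need both HαHβ couplings or both NHβ classes")
    lo, hi = K.JHAHB_AVERAGE_BAND
    if have_j and any(lo <= j <= hi for j in (jset.j_hahb2, jset.j_hahb3)):
        return Chi1Call(jset.residue_id, "average", method="jcoupling",
                        notes="³J(HαHβ) inside the averaging band")
    if have_n and jset.j_nhb2_class == jset.j_nhb3_class == "medium":
        return Chi1Call(jset.residue_id, "average", method="jcoupling",
                        notes="medium-medium NHβ pair")
    table = table or methylene_truth_table()
    hypotheses = []  # (rotamer, swapped)
    for rot, expected in table.items():
        for swapped in (False, True):
            obs = []
            exp = []
            if have_j:
                j2, j3 = (jset.j_hahb3, jset.j_hahb2) if swapped else \
                    (jset.j_hahb2, jset.j_hahb3)
                obs += [_class_hahb(j2), _class_hahb(j3)]
                exp += [expected[0], expected[1]]
            if have_n:
                n2, n3 = (jset.j_nhb3_class, jset.j_nhb2_class) if swapped else \
                    (jset.j_nhb2_class, jset.j_nhb3_class)
                obs += [n2, n3]
                exp += [expected[2], expected[3]]
            if obs == exp:
                hypotheses.append((rot, swapped))
    rotamers = sorted({h[0] for h in hypotheses})
    if not hypotheses:
        return Chi1Call(jset.residue_id, "undetermined", method="jcoupling",
                        notes="no staggered pattern matches")
    if len(rotamers) > 1:
        label = "ambiguous(" + "|".join(_rotamer_str(r) for r in rotamers) + ")"
        return Chi1Call(jset.residue_id, label, method="jcoupling",
                        notes="pattern consistent with several rotamers")
    rot = rotamers[0]
    swaps = {h[1] for h in hypotheses}
    stereo = None
    if len(swaps) == 1:
        swapped = swaps.pop()
        stereo = {"branch_a": "HB3" if swapped else "HB2",
                  "branch_b": "HB2" if swapped else "HB3"}
    return Chi1Call(jset.residue_id, _rotamer_str(rot), stereo_assignment=stereo,
                    method="jcoupling")


def classify_methine(jset: JCouplingSet) -> Chi1Call:
    """χ1 call for Val/Ile/Thr from the single ³J(HαHβ).

    Above the high threshold (10 Hz; 9 Hz for Thr) the Hα-Hβ pair is trans,
    which pins the rotamer (residue-type dependent); below 5 Hz it is gauche,
    consistent with either of the two remaining staggered rotamers; in
    between the side chain is averaging (or non-staggered).
    """
    rtype = jset.residue_type
    if rtype not in METHINE_TRANS_CHI1:
        raise ValueError(f"{rtype} does not carry a β-methine proton")
    if jset.j_hahb is None:
        raise ValueError("j_hahb required for a methine residue")
    j = jset.j_hahb
    high = K.JMETHINE_HIGH[rtype]
    trans_rot = METHINE_TRANS_CHI1[rtype]
    if j > high:
        return Chi1Call(jset.residue_id, _rotamer_str(trans_rot), method="jcoupling",
                        notes=f"³J={j:.1f} Hz > {high} Hz: Hα-Hβ trans")
    if j < K.JMETHINE_LOW:
        others = sorted(set(STAGGERED) - {trans_rot})
        label = "ambiguous(" + "|".join(_rotamer_str(r) for r in others) + ")"
        return Chi1Call(jset.residue_id, label, method="jcoupling",
                        notes=f"³J={j:.1f} Hz < {K.JMETHINE_LOW} Hz: Hα-Hβ gauche, "
                              "single staggered rotamer")
    return Chi1Call(jset.residue_id, "average", method="jcoupling",
                    notes="³J between the gauche and trans limits")


@dataclass(frozen=True)
class RdcSumEvidence:
    """ΣCβHβ observation and the three candidate backbone-RDC sums (all on
    the normalized ¹D_NH-free common scale of the Cβ-Hβ pair)."""

    residue_id: int
    d_sum_cbhb: float
    candidate_sums: dict  # {1: Hz, 2: Hz, 3: Hz}, normalized scale
    medium_id: str = ""


_RULE_ROTAMER = {1: "180", 2: "-60", 3: "+60"}


def build_rdc_sum_evidence(
    rdc_set: RDCSet,
    residue_id: int,
    medium_id: str | None = None,
    constants=K.DEFAULT_CONSTANTS,
) -> RdcSumEvidence:
    """Assemble the rule-1/2/3 candidate sums for one residue from data.

    All couplings are first normalized to the ¹D_NH scale, on which parallel
    bonds carry equal couplings, so the candidates are plain sums.
    """

    def find(rdc_type: str, res: int) -> float | None:
        for r in rdc_set:
            if (r.rdc_type == rdc_type and r.residue_i == res
                    and (medium_id is None or r.medium_id == medium_id)):
                return normalize(r, constants)
        return None

    d_sum = find("SUM-CBHB", residue_id)
    caha_i = find("CA-HA", residue_id)
    cca_i = find("C-CA", residue_id)
    cca_prev = find("C-CA", residue_id - 1)
    missing = [n for n, v in
               [("SUM-CBHB", d_sum), ("CA-HA(i)", caha_i), ("C-CA(i)", cca_i),
                ("C-CA(i-1)", cca_prev)] if v is None]
    if missing:
        raise ValueError(f"residue {residue_id}: missing couplings {missing}")
    return RdcSumEvidence(
        residue_id=residue_id,
        d_sum_cbhb=d_sum,
        candidate_sums={1: caha_i + cca_i, 2: caha_i + cca_prev,
                        3: cca_i + cca_prev},
        medium_id=medium_id or "",
    )


def chi1_from_rdc_sums(evidence: RdcSumEvidence,
                       resolvability_floor: float = 2.0) -> Chi1Call:
    """χ1 from the best-matching candidate sum (argmin |ΔD|).

    The margin is the gap between the best and second-best |ΔD| (Hz,
    normalized scale); below ``resolvability_floor`` the call is
    undetermined.  A rule-2 winner is ambiguous between −60° and 180°.
    """
    diffs = {rule: abs(evidence.d_sum_cbhb - cand)
             for rule, cand in evidence.candidate_sums.items()}
    ranked = sorted(diffs.items(), key=lambda kv: kv[1])
    best_rule, best = ranked[0]
    margin = ranked[1][1] - best
    notes = (f"rule {best_rule}, |ΔD|={best:.2f} Hz, margin={margin:.2f} Hz")
    if margin < resolvability_floor:
        return Chi1Call(evidence.residue_id, "undetermined", method="rdc_sum",
                        notes=notes + " (below resolvability floor)")
    if best_rule == 2:
        return Chi1Call(evidence.residue_id, "ambiguous(-60|180)",
                        method="rdc_sum", notes=notes)
    return Chi1Call(evidence.residue_id, _RULE_ROTAMER[best_rule],
                    method="rdc_sum", notes=notes)


#: expected NOE distance classes per rotamer: gauche contacts are short
#: (strong), trans contacts long (weak); θ offsets as in the Karplus kinds
def _expected_noe(rot: float) -> dict:
    out = {}
    for key, kind in (("ha_hb2", "hahb2"), ("ha_hb3", "hahb3"),
                      ("hn_hb2", "nhb2"), ("hn_hb3", "nhb3")):
        theta = (rot + _KIND_OFFSETS[kind]) % 360.0
        trans = min(abs(theta - 180.0), abs(theta + 180.0 - 360.0)) < 30.0
        out[key] = "weak" if trans else "strong"
    return out


def noe_consistency(intensity_pattern: dict, chi1_call: Chi1Call) -> str:
    """Check Hα/HN–Hβ NOE intensity classes against a χ1 call.

    Returns "consistent", "inconsistent" or "unknown" (missing data).  A
    single-rotamer call with an equal-medium HN-Hβ pair is inconsistent —
    the averaging signature.
    """
    provided = {k: v for k, v in (intensity_pattern or {}).items() if v}
    if not provided:
        return "unknown"
    if chi1_call.rotamer in ("+60", "180", "-60"):
        if provided.get("hn_hb2") == provided.get("hn_hb3") == "medium":
            return "inconsistent"
        expected = _expected_noe(float(chi1_call.rotamer.replace("+", "")))
        for key, cls in provided.items():
            if key not in expected or cls == "medium":
                continue
            if cls != expected[key]:
                return "inconsistent"
        return "consistent"
    if chi1_call.rotamer == "average":
        # averaging should not show a strongly asymmetric contact pair
        for a, b in (("ha_hb2", "ha_hb3"), ("hn_hb2", "hn_hb3")):
            if {provided.get(a), provided.get(b)} == {"strong", "weak"}:
                return "inconsistent"
        return "consistent"
    return "unknown"


def read_jcoupling_tsv(path) -> list[JCouplingSet]:
    """Read the J-coupling table (columns: res type j_hahb2 j_hahb3 j_hahb
    nhb2_class nhb3_class overlap_flag; empty cells for missing data)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        def val(name):
            v = getattr(row, name, None)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        out.append(
            JCouplingSet(
                residue_id=int(row.res),
                residue_type=str(row.type),
                j_hahb2=val("j_hahb2"), j_hahb3=val("j_hahb3"),
                j_hahb=val("j_hahb"),
                j_nhb2_class=val("nhb2_class"), j_nhb3_class=val("nhb3_class"),
                overlapped=bool(val("overlap_flag") or False),
            )
        )
    return out
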
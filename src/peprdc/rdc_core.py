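"""Alignment-tensor fitting and RDC quality statistics.

A residual dipolar coupling (RDC) measured under partial alignment reports
the orientation of its internuclear vector relative to the molecular
alignment frame:

    D = dmax · bᵀ S b

with b the unit bond vector and S the Saupe order matrix (symmetric,
traceless, five independent elements).  Working on couplings normalized to
the ¹D_NH scale, the alignment tensor A (Hz) obeys D̂ = bᵀ A b and is linear
in five parameters, so it is fitted by SVD least squares (the order-matrix
method).  Agreement between a structure and the data is summarized by

    Q = rms(D_calc − D_obs) / rms(D_obs)

and cross-validated as Q_free by holding out a stratified fraction of the
data, refitting, and scoring only the held-out couplings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import DEFAULT_CONSTANTS, DipolarConstants
from .structure_io import Ensemble, Model

__all__ = [
    "RDCRecord",
    "RDCSet",
    "AlignmentTensor",
    "QReport",
    "CrossValidationPlan",
    "normalize",
    "design_row",
    "fit_tensor",
    "fit_tensor_ensemble",
    "q_factor",
    "make_cv_plan",
    "q_free",
    "identity_refiner",
    "read_rdc_tsv",
    "write_rdc_tsv",
    "read_xplor_dipo",
]

RDC_TYPES = ("N-HN", "CA-HA", "C-CA", "N-C", "SUM-CBHB")

# atoms spanned by each coupling type; SUM-CBHB expands to two C-H pairs
_TYPE_ATOMS = {
    "N-HN": (("N",), ("H",)),
    "CA-HA": (("CA",), ("HA",)),
    "C-CA": (("C",), ("CA",)),
    "N-C": (("N",), ("C",)),
}


@dataclass(frozen=True)
class RDCRecord:
    """One observed dipolar coupling."""

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    rdc_type: str
    medium_id: str
    d_obs: float  # Hz, as printed in the input table
    sigma: float | None = None
    chain: str = "A"

    def __post_init__(self):
        if self.rdc_type not in RDC_TYPES:
            raise ValueError(f"unknown rdc_type {self.rdc_type!r}")
        if not np.isfinite(self.d_obs):
            raise ValueError("d_obs must be finite")

    @property
    def experiment(self) -> tuple[str, str]:
        """The (type, medium) stratum this record belongs to."""
        return (self.rdc_type, self.medium_id)


@dataclass
class RDCSet:
    """A collection of RDC observations, possibly spanning several media."""

    records: list[RDCRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def by_medium(self, medium_id: str) -> "RDCSet":
        return RDCSet([r for r in self.records if r.medium_id == medium_id])

    def by_type(self, rdc_type: str) -> "RDCSet":
        return RDCSet([r for r in self.records if r.rdc_type == rdc_type])

    def subset(self, indices: Iterable[int]) -> "RDCSet":
        return RDCSet([self.records[i] for i in indices])

    @property
    def media(self) -> list[str]:
        seen = dict.fromkeys(r.medium_id for r in self.records)
        return list(seen)

    @property
    def experiments(self) -> list[tuple[str, str]]:
        seen = dict.fromkeys(r.experiment for r in self.records)
        return list(seen)


@dataclass
class AlignmentTensor:
    """Alignment tensor on the ¹D_NH (Hz) scale, plus derived parameters.

    ``tensor`` is symmetric traceless in Hz; ``saupe`` is the dimensionless
    order matrix (tensor / dmax_NH).  Da and R follow the eigenvalue
    convention |Azz| ≥ |Ayy| ≥ |Axx| with Da = Azz/2 and
    R = 2(Axx − Ayy)/(3 Azz) ∈ [0, 2/3].
    """

    tensor: np.ndarray  # 3x3 symmetric traceless, Hz (NH scale)
    constants: DipolarConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-9):
            raise ValueError("tensor must be 3x3 symmetric")
        t = 0.5 * (t + t.T)
        t = t - np.eye(3) * np.trace(t) / 3.0
        self.tensor = t

    @property
    def saupe(self) -> np.ndarray:
        return self.tensor / self.constants.dmax("N-HN")

    def _ordered_eigs(self) -> tuple[np.ndarray, np.ndarray]:
        vals, vecs = np.linalg.eigh(self.tensor)
        order = np.argsort(np.abs(vals))  # |Axx| <= |Ayy| <= |Azz|
        return vals[order], vecs[:, order]

    @property
    def da(self) -> float:
        """Axial magnitude (Hz, NH scale): Azz/2."""
        vals, _ = self._ordered_eigs()
        return float(vals[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        vals, _ = self._ordered_eigs()
        axx, ayy, azz = vals
        return float(2.0 * (axx - ayy) / (3.0 * azz))

    @property
    def euler_angles(self) -> tuple[float, float, float]:
        """ZYZ Euler angles (degrees) of the principal-axis frame."""
        _, vecs = self._ordered_eigs()
        frame = vecs[:, [0, 1, 2]]
        if np.linalg.det(frame) < 0:
            frame = frame * np.array([1.0, 1.0, -1.0])
        return tuple(Rotation.from_matrix(frame).as_euler("ZYZ", degrees=True))

    @classmethod
    def from_parameters(
        cls,
        da: float,
        rhombicity: float,
        rotation: np.ndarray | None = None,
        constants: DipolarConstants = DEFAULT_CONSTANTS,
    ) -> "AlignmentTensor":
        """Build a tensor from Da (Hz), R ∈ [0, 2/3] and a frame rotation."""
        if not 0.0 <= rhombicity <= 2.0 / 3.0:
            raise ValueError("rhombicity must be in [0, 2/3]")
        eigs = np.diag(
            [-da * (1.0 - 1.5 * rhombicity), -da * (1.0 + 1.5 * rhombicity), 2.0 * da]
        )
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        return cls(rot @ eigs @ rot.T, constants=constants)


@dataclass(frozen=True)
class QReport:
    """Quality factor Q = rms(Dcalc − Dobs)/rms(Dobs) with bookkeeping."""

    q: float
    n_rdc: int
    rms_obs: float
    rms_resid: float
    per_type: dict

    def __str__(self) -> str:
        per = ", ".join(f"{t}: {q:.3f}" for t, q in self.per_type.items())
        return f"Q = {self.q:.4f} over {self.n_rdc} RDCs ({per})"


def normalize(record: RDCRecord, constants: DipolarConstants = DEFAULT_CONSTANTS) -> float:
    """Observed coupling expressed on the ¹D_NH scale (Hz).

    Divides by the signed dipolar-constant ratio of the pair; a ΣCβHβ sum is
    divided by the single C-H pair factor (it is a sum of two C-H couplings).
    """
    return record.d_obs / constants.factor(record.rdc_type)


def _unit_vectors(model: Model, record: RDCRecord) -> list[np.ndarray]:
    """Unit bond vector(s) for a record; two vectors for a ΣCβHβ sum."""
    if record.rdc_type == "SUM-CBHB":
        cb = model.position(record.chain, record.residue_i, "CB")
        vecs = []
        for hb in ("HB2", "HB3"):
            h = model.position(record.chain, record.residue_i, hb)
            v = h - cb
            vecs.append(v / np.linalg.norm(v))
        return vecs
    pi = model.position(record.chain, record.residue_i, record.atom_i)
    pj = model.position(record.chain, record.residue_j, record.atom_j)
    v = pj - pi
    return [v / np.linalg.norm(v)]


def _row_from_unit(b: np.ndarray) -> np.ndarray:
    """Design row for D̂ = bᵀ A b in s = (Azz, Axx−Ayy, Axy, Axz, Ayz)."""
    bx, by, bz = b
    return np.array(
        [
            bz * bz - 0.5 * (bx * bx + by * by),
            0.5 * (bx * bx - by * by),
            2.0 * bx * by,
            2.0 * bx * bz,
            2.0 * by * bz,
        ]
    )


def _tensor_from_params(s: np.ndarray) -> np.ndarray:
    # s = (Azz, Axx-Ayy, Axy, Axz, Ayz); Axx+Ayy = -Azz by tracelessness
    azz, dxy, axy, axz, ayz = s
    axx = 0.5 * (dxy - azz)
    ayy = 0.5 * (-dxy - azz)
    return np.array([[axx, axy, axz], [axy, ayy, ayz], [axz, ayz, azz]])


def _params_from_tensor(a: np.ndarray) -> np.ndarray:
    return np.array([a[2, 2], a[0, 0] - a[1, 1], a[0, 1], a[0, 2], a[1, 2]])


def design_row(
    model: Model, record: RDCRecord, constants: DipolarConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Row of the linear system D̂ = A·s for one (normalized) observation.

    For a ΣCβHβ record the row is the elementwise sum of the two single
    proton rows, matching the normalized sum on the left-hand side.
    """
    vecs = _unit_vectors(model, record)
    return np.sum([_row_from_unit(b) for b in vecs], axis=0)


def back_calculate(
    model: Model,
    tensor: AlignmentTensor,
    records: Sequence[RDCRecord],
    constants: DipolarConstants = DEFAULT_CONSTANTS,
    normalized: bool = True,
) -> np.ndarray:
    """Predicted couplings for ``records`` given a structure and tensor.

    ``normalized=False`` returns values on each record's native scale.
    """
    s = _params_from_tensor(tensor.tensor)
    out = np.array([design_row(model, r, constants) @ s for r in records])
    if not normalized:
        out = out * np.array([constants.factor(r.rdc_type) for r in records])
    return out


def q_factor(d_obs: Sequence[float], d_calc: Sequence[float],
             types: Sequence[str] | None = None) -> QReport:
    """Q = rms(Dcalc − Dobs)/rms(Dobs), rms(x) = sqrt(mean(x²))."""
    obs = np.asarray(d_obs, dtype=float)
    calc = np.asarray(d_calc, dtype=float)
    if obs.shape != calc.shape or obs.ndim != 1 or len(obs) < 1:
        raise ValueError("d_obs and d_calc must be equal-length 1-D sequences")
    rms_obs = float(np.sqrt(np.mean(obs**2)))
    if rms_obs == 0.0:
        raise ZeroDivisionError("rms of observed couplings is zero")
    resid = calc - obs
    rms_resid = float(np.sqrt(np.mean(resid**2)))
    per_type: dict = {}
    if types is not None:
        for t in dict.fromkeys(types):
            m = np.asarray([x == t for x in types])
            ro = np.sqrt(np.mean(obs[m] ** 2))
            per_type[t] = float(np.sqrt(np.mean(resid[m] ** 2)) / ro) if ro > 0 else np.nan
    return QReport(q=rms_resid / rms_obs, n_rdc=len(obs), rms_obs=rms_obs,
                   rms_resid=rms_resid, per_type=per_type)


def fit_tensor(
    model: Model,
    rdc_set: RDCSet,
    constants: DipolarConstants = DEFAULT_CONSTANTS,
    weighted: bool = False,
) -> tuple[AlignmentTensor, np.ndarray, QReport]:
    """SVD least-squares fit of the alignment tensor to one medium's RDCs.

    Returns the fitted tensor, the back-calculated couplings (native scale,
    record order) and the Q report computed on normalized couplings.
    Unweighted by default; ``weighted=True`` applies 1/σ² weights where
    sigma is present.
    """
    records = list(rdc_set)
    if len({r.medium_id for r in records}) > 1:
        raise ValueError("fit_tensor expects a single alignment medium; "
                         "split the set with by_medium() first")
    if len(records) < 5:
        raise ValueError(f"underdetermined: {len(records)} < 5 RDCs")
    a = np.array([design_row(model, r, constants) for r in records])
    d = np.array([normalize(r, constants) for r in records])
    w = np.ones(len(records))
    if weighted:
        w = np.array([1.0 / r.sigma**2 if r.sigma else 1.0 for r in records])
    sw = np.sqrt(w)
    cond = np.linalg.cond(a * sw[:, None])
    if cond > 1e8:
        import warnings

        warnings.warn(f"degenerate bond-vector geometry (condition number {cond:.2e})")
    s, *_ = np.linalg.lstsq(a * sw[:, None], d * sw, rcond=None)
    tensor = AlignmentTensor(_tensor_from_params(s), constants=constants)
    d_calc_norm = a @ s
    qrep = q_factor(d, d_calc_norm, [r.rdc_type for r in records])
    d_calc = d_calc_norm * np.array([constants.factor(r.rdc_type) for r in records])
    return tensor, d_calc, qrep


def fit_tensor_ensemble(
    ensemble: Ensemble,
    rdc_set: RDCSet,
    constants: DipolarConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Per-model tensor fits over an ensemble.

    Returns mean/sd/min of per-model Q plus the individual reports, since a
    deposited ensemble does not say which member the data refer to.
    """
    fits = [fit_tensor(m, rdc_set, constants) for m in ensemble.models]
    qs = np.array([f[2].q for f in fits])
    return {
        "q_mean": float(qs.mean()),
        "q_sd": float(qs.std(ddof=1)) if len(qs) > 1 else 0.0,
        "q_best": float(qs.min()),
        "per_model": fits,
    }


@dataclass(frozen=True)
class CrossValidationPlan:
    """Stratified leave-out-10% rounds; each RDC held out exactly once."""

    rounds: tuple[tuple[int, ...], ...]
    fraction: float
    n_rounds: int
    seed: int

    def held_out(self, round_index: int) -> tuple[int, ...]:
        return self.rounds[round_index]


def make_cv_plan(
    rdc_set: RDCSet,
    fraction: float = 0.10,
    n_rounds: int = 10,
    seed: int = 0,
) -> CrossValidationPlan:
    """Per-experiment stratified partition into ``n_rounds`` held-out sets.

    Every (rdc_type, medium) experiment is shuffled and split so the union of
    held-out sets over the rounds covers each RDC exactly once, with each
    round holding out ≈``fraction`` of every experiment.
    """
    if not 0.0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    if abs(n_rounds * fraction - 1.0) > 0.5:
        raise ValueError("n_rounds and fraction are inconsistent "
                         "(rounds must jointly cover the data once)")
    rng = np.random.default_rng(seed)
    per_round: list[list[int]] = [[] for _ in range(n_rounds)]
    for exp in rdc_set.experiments:
        idx = [i for i, r in enumerate(rdc_set) if r.experiment == exp]
        if len(idx) < n_rounds:
            raise ValueError(
                f"experiment {exp} has only {len(idx)} RDCs (< {n_rounds} rounds)"
            )
        idx = list(rng.permutation(idx))
        for k, chunk in enumerate(np.array_split(idx, n_rounds)):
            per_round[k].extend(int(i) for i in chunk)
    return CrossValidationPlan(
        rounds=tuple(tuple(sorted(r)) for r in per_round),
        fraction=fraction,
        n_rounds=n_rounds,
        seed=seed,
    )


def identity_refiner(structure: Model, working: RDCSet) -> Model:
    """The default no-op refiner: returns the structure unchanged."""
    return structure


def q_free(
    plan: CrossValidationPlan,
    rdc_set: RDCSet,
    structure: Model,
    refiner: Callable[[Model, RDCSet], Model] = identity_refiner,
    constants: DipolarConstants = DEFAULT_CONSTANTS,
) -> tuple[float, float, list[float]]:
    """Cross-validated quality factor.

    Per round: refine (or not) against the working set, fit a tensor per
    medium on the working RDCs, back-calculate the held-out RDCs from the
    refined structure, and compute Q on the held-out set only.  Returns
    (mean, sd, per-round values).
    """
    per_round: list[float] = []
    all_idx = set(range(len(rdc_set)))
    for k in range(plan.n_rounds):
        held = set(plan.held_out(k))
        work_idx = sorted(all_idx - held)
        working = rdc_set.subset(work_idx)
        try:
            refined = refiner(structure, working)
        except Exception as exc:  # noqa: BLE001 - context per contract
            raise RuntimeError(f"refiner failed on round {k}: {exc}") from exc
        obs_all: list[float] = []
        calc_all: list[float] = []
        for medium in rdc_set.media:
            tensor, _, _ = fit_tensor(refined, working.by_medium(medium), constants)
            held_m = [rdc_set[i] for i in sorted(held)
                      if rdc_set[i].medium_id == medium]
            if not held_m:
                continue
            calc = back_calculate(refined, tensor, held_m, constants, normalized=True)
            obs_all.extend(normalize(r, constants) for r in held_m)
            calc_all.extend(calc)
        per_round.append(q_factor(obs_all, calc_all).q)
    arr = np.array(per_round)
    return float(arr.mean()), float(arr.std(ddof=1)), per_round


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["chain", "res_i", "atom_i", "res_j", "atom_j", "type",
                "medium", "d_obs", "sigma"]


def read_rdc_tsv(path: str | Path) -> RDCSet:
    """Read the tab-separated RDC table (header: chain res_i atom_i res_j
    atom_j type medium d_obs sigma)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"RDC table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        sigma = getattr(row, "sigma", None)
        records.append(
            RDCRecord(
                chain=str(row.chain),
                residue_i=int(row.res_i),
                atom_i=str(row.atom_i),
                residue_j=int(row.res_j),
                atom_j=str(row.atom_j),
                rdc_type=str(row.type),
                medium_id=str(row.medium),
                d_obs=float(row.d_obs),
                sigma=None if sigma is None or pd.isna(sigma) else float(sigma),
            )
        )
    return RDCSet(records)


def write_rdc_tsv(rdc_set: RDCSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chain": r.chain, "res_i": r.residue_i, "atom_i": r.atom_i,
                "res_j": r.residue_j, "atom_j": r.atom_j, "type": r.rdc_type,
                "medium": r.medium_id, "d_obs": r.d_obs,
                "sigma": "" if r.sigma is None else r.sigma,
            }
            for r in rdc_set
        ],
        columns=_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_XPLOR_SEL = re.compile(r"\(\s*resid\s+(\d+)\s+and\s+name\s+(\w+)\s*\)", re.I)


def read_xplor_dipo(path: str | Path, medium_id: str = "pf1") -> RDCSet:
    """Read XPLOR-style SANI/DIPO restraints (``assign`` statements).

    Each assign carries four pseudo-atom selections defining the tensor
    frame followed by the two real atoms and the observed coupling; only the
    last two selections and the first numeric value are used.
    """
    text = Path(path).read_text()
    records = []
    for stmt in re.split(r"(?i)\bassign\b", text)[1:]:
        sels = _XPLOR_SEL.findall(stmt)
        nums = re.findall(r"[-+]?\d+\.?\d*(?:[eE][-+]?\d+)?", stmt.split(")")[-1])
        if len(sels) < 2 or not nums:
            continue
        (res_i, atom_i), (res_j, atom_j) = sels[-2], sels[-1]
        atom_i = "H" if atom_i.upper() == "HN" else atom_i.upper()
        atom_j = "H" if atom_j.upper() == "HN" else atom_j.upper()
        pair = {atom_i, atom_j}
        if pair == {"N", "H"}:
            rdc_type = "N-HN"
        elif pair == {"CA", "HA"}:
            rdc_type = "CA-HA"
        elif pair == {"C", "CA"}:
            rdc_type = "C-CA"
        elif pair == {"N", "C"}:
            rdc_type = "N-C"
        else:
            continue
        records.append(
            RDCRecord(
                residue_i=int(res_i), atom_i=atom_i,
                residue_j=int(res_j), atom_j=atom_j,
                rdc_type=rdc_type, medium_id=medium_id, d_obs=float(nums[0]),
            )
        )
    if not records:
        raise ValueError(f"no assign statements parsed from {path}")
    return RDCSet(records)
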
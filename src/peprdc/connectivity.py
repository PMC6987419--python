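"""Disulfide connectivity from Cβ–Cβ distances, and the survey statistics.

Bonded cysteine pairs cluster tightly near 3.8 Å Cβ–Cβ while non-bonded
pairs occasionally dip under 5 Å, so individual short distances are
ambiguous — but the correct pairing minimizes the average Cβ–Cβ distance
over the whole matching.  Peptides carry few cysteines, so the (2n−1)!!
perfect matchings are enumerated exhaustively and scored on the
ensemble-averaged distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .structure_io import Ensemble, Model

__all__ = [
    "CbDistanceSet",
    "PairingSolution",
    "SurveyFilter",
    "cb_distances",
    "enumerate_matchings",
    "infer_connectivity",
    "survey",
]


@dataclass
class CbDistanceSet:
    """Per-model and ensemble-averaged Cβ–Cβ distance matrices (Å)."""

    cysteines: list[int]  # residue numbers, sorted
    per_model: np.ndarray  # (n_models, n_cys, n_cys)
    averaged: np.ndarray  # (n_cys, n_cys)

    def distance(self, res_i: int, res_j: int) -> float:
        i = self.cysteines.index(res_i)
        j = self.cysteines.index(res_j)
        return float(self.averaged[i, j])


@dataclass(frozen=True)
class PairingSolution:
    """A perfect matching of cysteines with its mean Cβ–Cβ score."""

    matching: tuple[tuple[int, int], ...]
    score: float  # mean Cβ–Cβ over matched pairs, Å
    margin: float  # score gap to the second-best matching, Å
    violations: tuple[tuple[int, int], ...]  # pairs at ≥ threshold
    tie: bool = False


@dataclass(frozen=True)
class SurveyFilter:
    """Metadata filter for the structure survey."""

    max_resolution: float = 1.5  # Å
    max_mw_kda: float = 50.0
    duplicate_policy: str = "exact"  # exact sequence duplicates removed

    def __post_init__(self):
        if self.max_resolution <= 0 or self.max_mw_kda <= 0:
            raise ValueError("filter thresholds must be positive")


def cb_distances(ensemble: Ensemble | Model, chain_id: str = "A") -> CbDistanceSet:
    """Cβ–Cβ distance matrices between all CYS residues.

    Accepts a single model or an ensemble; the averaged matrix is the mean
    over models.
    """
    models = ensemble.models if isinstance(ensemble, Ensemble) else [ensemble]
    cys = sorted(num for (ch, num), name in models[0].residues().items()
                 if ch == chain_id and name == "CYS")
    if len(cys) < 2:
        raise ValueError("need at least two cysteines with Cβ atoms")
    mats = []
    for m in models:
        coords = np.array([m.position(chain_id, r, "CB") for r in cys])
        mats.append(squareform(pdist(coords)))
    per_model = np.array(mats)
    return CbDistanceSet(cysteines=cys, per_model=per_model,
                         averaged=per_model.mean(axis=0))


def enumerate_matchings(cysteines: list[int]) -> list[tuple[tuple[int, int], ...]]:
    """All perfect matchings of an even-sized cysteine list ((2n−1)!! total).

    Each matching is a tuple of (i, j) pairs with i < j, pairs sorted.
    """
    cys = sorted(cysteines)
    if len(cys) % 2 != 0:
        raise ValueError("odd cysteine count: free thiols are not handled")
    if len(cys) == 0:
        return []

    def rec(remaining: tuple[int, ...]):
        if not remaining:
            yield ()
            return
        first, rest = remaining[0], remaining[1:]
        for k, partner in enumerate(rest):
            pair = (first, partner)
            for tail in rec(rest[:k] + rest[k + 1:]):
                yield (pair,) + tail

    return [tuple(sorted(m)) for m in rec(tuple(cys))]


def infer_connectivity(distance_set: CbDistanceSet,
                       threshold: float = 5.0) -> PairingSolution:
    """Perfect matching minimizing the mean Cβ–Cβ distance (ensemble-averaged).

    Reports the margin to the second-best matching and flags matched pairs
    whose distance is ≥ ``threshold`` Å as violations.  Score ties are broken
    lexicographically by residue numbers and flagged.
    """
    cys = distance_set.cysteines
    idx = {r: k for k, r in enumerate(cys)}
    scored = []
    for matching in enumerate_matchings(cys):
        score = float(np.mean([distance_set.averaged[idx[i], idx[j]]
                               for i, j in matching]))
        scored.append((score, matching))
    scored.sort(key=lambda t: (t[0], t[1]))
    best_score, best = scored[0]
    margin = (scored[1][0] - best_score) if len(scored) > 1 else float("inf")
    tie = len(scored) > 1 and abs(scored[1][0] - best_score) < 1e-9
    violations = tuple((i, j) for i, j in best
                       if distance_set.averaged[idx[i], idx[j]] >= threshold)
    return PairingSolution(matching=best, score=best_score, margin=margin,
                           violations=violations, tie=tie)


def survey(records: pd.DataFrame, filt: SurveyFilter = SurveyFilter(),
           threshold: float = 5.0, outlier_z: float | None = 10.0) -> dict:
    """Cβ–Cβ distance statistics over a survey table.

    ``records`` columns: pdb_id, resolution, mw_kda, res_i, res_j, cb_dist,
    bonded_flag (bool), optionally sequence (for duplicate removal).
    Returns intra (bonded) mean/sd/count below the threshold and the
    non-bonded below-threshold count; an optional |z| cut removes highly
    strained bonded outliers (logged in the result).
    """
    df = records.copy()
    df = df[(df["resolution"] < filt.max_resolution) & (df["mw_kda"] < filt.max_mw_kda)]
    if "sequence" in df.columns and filt.duplicate_policy == "exact":
        first_ids = df.drop_duplicates("sequence")["pdb_id"] if "pdb_id" in df else None
        if first_ids is not None:
            keep = df.groupby("sequence")["pdb_id"].transform("first") == df["pdb_id"]
            df = df[keep]
    if df.empty:
        raise ValueError("survey filter excluded every record")
    intra = df[df["bonded_flag"].astype(bool)]
    inter = df[~df["bonded_flag"].astype(bool)]
    if intra.empty:
        raise ValueError("no bonded pairs after filtering")
    d = intra["cb_dist"].to_numpy(dtype=float)
    removed = 0
    if outlier_z is not None and len(d) > 2:
        z = (d - d.mean()) / d.std(ddof=1)
        keep = np.abs(z) <= outlier_z
        removed = int((~keep).sum())
        d = d[keep]
    return {
        "intra_mean": float(d.mean()),
        "intra_sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "intra_count": int(len(d)),
        "intra_below_threshold": int((d < threshold).sum()),
        "inter_below_threshold": int((inter["cb_dist"] < threshold).sum()),
        "outliers_removed": removed,
    }
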
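# Methods

## Alignment tensor fitting

Couplings are first normalized to the ¹D_NH scale by dividing by the signed
dipolar-constant ratio κ(type) = d_max(type)/d_max(N-HN), with
d_max ∝ γᵢγⱼ/r³. Defaults: γH = 2.67522×10⁸, γC = 6.72828×10⁷,
γN = −2.7116×10⁷ rad s⁻¹ T⁻¹ and vibrationally averaged reference bond
lengths r(N-H) = 1.041 Å, r(C-H) = 1.117 Å, r(C′-Cα) = 1.526 Å,
r(N-C′) = 1.329 Å. The ratios are signed (γN < 0), so a normalized C-H
coupling flips sign relative to its raw value; all constants live in
`peprdc.constants` and are overridable. A ΣCβHβ sum is normalized by the
single C-H factor and its design row is the sum of the two proton rows.

On the normalized scale D̂ = bᵀA b with A the alignment tensor in Hz,
parameterized as s = (A_zz, A_xx−A_yy, A_xy, A_xz, A_yz) (tracelessness
removes the sixth element). The design matrix is solved by SVD least
squares (`numpy.linalg.lstsq`); a condition number above 10⁸ triggers a
degenerate-geometry warning, fewer than five couplings is an error. Da and
R follow the |A_zz| ≥ |A_yy| ≥ |A_xx| eigenvalue convention: Da = A_zz/2,
R = 2(A_xx − A_yy)/(3A_zz) ∈ [0, 2/3]. Fits are strictly per-medium; for
ensembles each model is fitted independently and mean/sd/best-of Q are all
reported, since a deposition does not say which member the data describe.
Least squares is unweighted by default (1/σ² weighting available when
uncertainties are present). Q is computed on the normalized scale, with a
per-type breakdown in the report.

## Q_free

The cross-validation plan shuffles each (type, medium) experiment with a
caller-supplied seed and splits it into n_rounds contiguous chunks, so the
union of held-out sets covers every coupling exactly once and each round
holds out ≈ fraction of every experiment. Per round the (optionally
refined) structure is refitted on the working couplings per medium and Q is
evaluated on the held-out couplings only; the mean ± sd over rounds is
returned. The refiner is a pluggable callable; the shipped default is the
identity. With the identity refiner the expected Q_free is the noise floor
rms(σ_norm)/rms(D̂_obs) inflated by the tensor-estimation term
√(1 + p/n_work) with p = 5 parameters — about 1–2% here, which the
acceptance checks resolve. A refiner that refits coordinates against the
noisy working data would add a further noise copy to the back-calculated
values; the harness makes no such assumption.

## χ1 rotamer analysis

Side-chain geometry conventions were fixed against ideal amino-acid
reference coordinates (L-chirality improper dihedral(N, C′, Cα, Cβ) = +120°)
and are used consistently by the builder, the simulators and the
classifiers: around the Cα–Cβ axis, dihedral(N, Cα, Cβ, X) is χ1 for the
heavy branch, χ1+120° for Hβ2 and χ1−120° for Hβ3, while C′ and Hα sit at
−120° and +120° from N on the Cα side. Hence the coupling dihedrals are
θ(HαHβ2) = χ1 − 120°, θ(HαHβ3) = χ1, θ(NHβ2) = χ1 + 120°,
θ(NHβ3) = χ1 − 120°. For β-methines the Hβ offset is residue-specific
(Val: θ = χ1, so a large ³J means χ1 = 180°; Ile/Thr: θ = χ1 − 120°, so a
large ³J means χ1 = −60°) — the reason a Thr with ³J ≈ 9.5 Hz is called
gauche⁻ while the same value in Val is still "average".

Karplus defaults are generic literature-style coefficients, shipped as
configuration, not fitted here: ³J(HαHβ): A = 9.5, B = −1.6, C = 1.8 Hz
(trans 12.9 Hz, gauche 3.4 Hz); ³J(NHβ): A = −4.4, B = 1.2, C = 0.1 Hz.
Quantitative→qualitative cutoffs: ³J(HαHβ) small ≤ 5 Hz, large ≥ 10 Hz;
averaging band 5.0–9.0 Hz; methine high thresholds 10 Hz (9 Hz for Thr);
|³J(NHβ)| small ≤ 1.5 Hz, large ≥ 3.0 Hz (an assumption — the qualitative
class boundaries are not standardized). The methylene truth table is
derived from these curves at exact staggered geometry at import time rather
than shipped as literals, so editing the coefficients updates the table.
Classification tries both stereo hypotheses against the table; a unique
match yields rotamer and Hβ2/Hβ3 assignment, multiple matches an explicit
ambiguity, no match "undetermined" (never an exception). Averaging checks
run first; overlapped Hβ resonances short-circuit to undetermined.

For the RDC-sum route, the normalized ΣCβHβ is matched against
rule 1 = (CαHα)ᵢ + (CαC′)ᵢ, rule 2 = (CαHα)ᵢ + (CαC′)ᵢ₋₁ and
rule 3 = (CαC′)ᵢ + (CαC′)ᵢ₋₁, mapping to χ1 = 180°, −60° and +60°
respectively. The mapping was validated numerically on exact geometry:
rule 1 is exact at χ1 = 180°; rules 2 and 3 rest on the approximation that
the preceding Cα–C′ bond is parallel to the intra-residue Cα–N bond
(~10–15° off in a real trans peptide), which is why a rule-2 winner is
reported as ambiguous(−60|180) — rules 1 and 2 share the Cα-Hα arm and
differ only in the approximated arm. The decision margin (gap between best
and second-best |ΔD|) must clear a resolvability floor, default 2 Hz,
configurable; there is no printed standard for "close agreement".

NOE consistency compares strong/weak Hα/HN–Hβ intensity classes with the
gauche-short/trans-long expectation for the called rotamer; an equal-medium
HN-Hβ pair under a single-rotamer call is the averaging signature and is
flagged inconsistent. Missing intensities give "unknown", distinct from
"inconsistent".

## Disulfide taxonomy

The five torsions are measured with the package dihedral primitive (IUPAC
sign convention, range (−180°, 180°]); the lower residue number is the
unprimed cysteine. Shape comes from how many of (χ2, χ2′) share χ3's sign —
2 spiral, 1 hook, 0 staple — shipped as an editable sign table; handedness
is RH iff χ3 > 0; the χ1/χ1′ signs form the prefix. For hooks the prefix
is ordered with the χ3-sharing side first, which keeps labels invariant
under residue relabeling and makes exactly twenty distinct labels (6
spirals, 6 staples, 8 hooks — the orbit count of sign vectors under the
swap symmetry); for spirals and staples a mixed prefix is the symmetric
"+/−". Angles within ±1° of zero (configurable) yield an explicit
"borderline" result instead of an arbitrary sign call. Ideality windows:
χ1/χ2-type angles gauche⁻ [−90°, −30°], gauche⁺ [30°, 90°], trans
|χ| ≥ 150° (wrapping through 180°); χ3 left [−120°, −60°], right
[60°, 120°].

## Connectivity

Cβ–Cβ distances are computed per model and averaged over the ensemble;
scoring a candidate pairing is the mean distance over its pairs. All
perfect matchings are enumerated exhaustively — peptides carry at most a
dozen cysteines ((2n−1)!! ≤ 10395), so no matching heuristic is needed and
the optimum is exact by construction; an independent minimum-weight-
matching implementation serves as a cross-check in the tests. Matched
pairs at ≥ 5 Å are reported as violations; ties are broken
lexicographically by residue number and flagged. The survey operation
filters a distance table on resolution (< 1.5 Å) and molecular weight
(< 50 kDa), removes exact sequence duplicates (a deliberate simplification
of identity-threshold clustering — it shifts counts, not the distance
mean), optionally drops |z| > 10 strained outliers, and reports bonded
mean/sd/count plus the non-bonded sub-5 Å count.

## Helix vectors

The axis estimate averages cross products of successive second differences
of the Cα trace: second differences of an ideal helix are exactly
perpendicular to the screw axis, so the estimate is exact for noiseless
helices of any length ≥ 4 — unlike the first principal component of the
coordinates, which tilts by up to a few degrees when the helix spans a
partial turn (PCA remains available as `method="pca"`). The axis is
oriented N→C. Inter-helix angles are arccos of axis dot products per model;
the ensemble mean and sd are reported. Helix residue ranges are inputs; no
secondary-structure assignment is performed.

## Synthetic data

The builder places atoms by internal coordinates (natural-extension
reference frame) with ideal bond lengths and angles shipped as an editable
template. Two presets: REALISTIC (backbone N-Cα-C′ 111°, Cα-Cβ-Sγ 114°,
Cβ-Sγ-Sγ′ 104°) and TETRAHEDRAL (every sp³ angle 109.47°, making staggered
side-chain bonds exactly parallel to their backbone partners — used where
exactness is the point of a test). Requested torsions round-trip through
the measurement code to < 10⁻⁶ degrees. The cystine builder extends atom
by atom through the five torsions with Sγ-Sγ′ = 2.05 Å; the resulting
Cβ–Cβ distance of an ideal left-handed spiral is 3.76 Å, consistent with
the bonded-pair distribution.

Simulated RDC datasets mirror the study layout: four backbone coupling
types in two alignment media plus ΣCβHβ in one, ≈ 450 couplings on a
57-residue peptide. Default tensors are Da = 10 Hz, R = 0.3 and Da = 8 Hz,
R = 0.5 with independent random orientations — magnitudes chosen so ¹D_NH
spans roughly ±20 Hz, the range alignment media are tuned to. Measurement
noise is per experiment type: 1.0 Hz for the large one-bond N-H/C-H
splittings and ΣCβHβ, 0.25/0.2 Hz for the small C′-Cα and N-C′ couplings,
which are measured with proportionally better precision. J-coupling noise
defaults to 0.5 Hz. Ensembles are made by Gaussian coordinate jitter
(σ = 0.3 Å default where spread matters) and/or rigid rotations of helix
segments about their centroids with N(0, σ_deg) angles about a fixed or
random perpendicular axis. All generators take explicit seeds and are
bit-reproducible.

What the generator does not emulate: real alignment-medium physics (no
steric/electrostatic alignment prediction), spin relaxation or lineshapes,
correlated coordinate errors along the chain, rotamer populations beyond
simple mixtures, and crystallographic artifacts in survey data. Passing
tests therefore demonstrate the correctness and calibration of the
analysis under its stated model, not the accuracy of any particular
experimental structure.

## Numerical choices and degenerate inputs

Dihedrals raise an explicit error for collinear triples; the range is
(−180°, 180°] with −180° mapped to +180°. Superposition is a Kabsch SVD
fit with determinant correction; fewer than three or collinear selection
atoms raise. Ensemble precision defaults to the mean pairwise RMSD over
all model pairs (no mean-structure construction needed); RMSD to the
iteratively refitted mean structure is available as `method="to_mean"`.
Atoms missing from some ensemble members are dropped from ensemble-wide
computations with a logged warning. Legacy HB1/HB2 β-proton names are
remapped to HB2/HB3 on input only when no HB3 is present. Hydrogens are
never built silently; operations needing them raise a missing-atom error
naming the record. Cross-validation requires every experiment to hold at
least n_rounds couplings and rejects fraction ≤ 0.

## Known limitations

- No RDC-restrained refinement is included; Q_free with the identity
  refiner measures data consistency, not refinement quality. The refiner
  hook exists precisely so an external molecular-dynamics refinement can be
  injected.
- The rule-based χ1-from-RDC analysis cannot separate −60° from 180° when
  the decision rides on the approximated Cα-N arm; it reports the
  ambiguity rather than guessing.
- Free (unpaired) cysteines are out of scope for connectivity inference;
  an odd cysteine count is an error.
- The survey's exact-duplicate filter is weaker than sequence-identity
  clustering; counts from a real structure database will differ.
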
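# Methods

## The model

`confhet` quantifies side-chain conformational heterogeneity in
multiconformer crystallographic models — models in which a disordered
residue is represented by a small set of discrete alternative
conformations ("altlocs"), each with a fractional occupancy *q* and
per-atom isotropic B-factors — and compares matched ligand-free (apo)
and ligand-bound (holo) structures of the same protein.

The central per-residue statistic is a crystallographic order parameter
S² on [0, 1] (1 = fully rigid) factored into an anharmonic and a
harmonic component:

* **Angular component** `s2_ang`. The χ1-defining Cβ→γ bond direction
  of each conformer (CG/CG1/OG/OG1/SG by residue type; CG1 for Val/Ile,
  following the rotalyze χ1 convention) is taken from the coordinates.
  With unit vectors **u**ᵢ and renormalised occupancies qᵢ,

      S² = (3/2) Σ_ab M_ab² − 1/2,   M_ab = Σ_i q_i u_ia u_ib .

  For two conformers this reduces to 1 − 3 q₁q₂ sin²Θ; for conformers
  occupying distinct staggered wells (pairwise 120° apart in χ1 under
  ideal tetrahedral geometry, cosΘ = −1/3) it reduces further to
  (4 Σqᵢ² − 1)/3.

* **Harmonic component** `s2_ortho`. A small-wobble model of the
  Cβ–H bond using the B-factors of Cβ and its attached hydrogen(s):
  S² = clip(1 − k (B_Cβ + B_H)/r², 0, 1) with k = 3/(16π²) and
  r = 1.09 Å. When explicit hydrogens are absent, B_H = 1.2 B_Cβ
  (the riding-hydrogen refinement convention). The prefactor is a
  configuration default; cohort-level results are differences and are
  insensitive to a global monotone recalibration of this component.

* **Resolution normalization.** Absolute B-factors inflate as
  resolution degrades, so the harmonic component is rescaled by the
  residue's α-carbon B-factor relative to the resolution:

      s2_ortho_norm = clip(s2_ortho · B_CA / (c · resolution), 0, 1)

  with c = 10 by default (units Å⁻¹·Å², i.e. B per Å of resolution).
  "B_CA" is the occupancy-weighted per-residue α-carbon B by default; a
  structure-mean mode is provided. The combined order parameter is
  `s2_calc = s2_ortho_norm × s2_ang`. Gly and Pro are excluded (no
  freely rotatable χ1 in this framework); Ala has no γ atom and is
  assigned s2_ang = 1 with a flag.

Supporting per-residue metrics: occupancy-weighted RMSF of side-chain
heavy-atom conformer centroids, occupancy-weighted mean side-chain
B-factor, and the side-chain conformer count (a residue is
multiconformer if at least one side-chain atom carries an altloc).

## Calibration of the normalization constant

The constant c is calibrated on same-protein structure series spanning
a resolution range: for each candidate c the lower-resolution series is
normalized and the higher-resolution series — whose B-factors are taken
as reliable, so its raw harmonic values define the reference scale — is
regressed on it. Candidates are ranked lexicographically by
(|slope − 1|, RMSE), ties to the smallest c. Values that saturate the
[0, 1] clip are excluded from the fit because saturated values carry no
scale information. Normalizing *both* series with the same candidate is
available as a diagnostic but cannot identify c: an OLS slope is
invariant when both variables share the common factor 1/c.

## Pair construction and quality control

Holo structures contain ≥ 1 HETATM group with ≥ 10 heavy atoms whose
code is not a common crystallographic additive. Candidate apo/holo
pairs must share a space group; have equal sequences (allowing up to
five residues trimmed from either terminus of either sequence, minimal
trim accepted); differ by ≤ 0.1 Å in resolution, ≤ 1 Å per cell length
and ≤ 1° per cell angle (boundaries inclusive with 10⁻⁹ tolerance).
Each holo keeps the apo with the smallest resolution difference (ties:
lexicographically smallest id). QC rejects pairs with superposed Cα
RMSD > 1 Å globally or > 0.5 Å over the binding site, clashscore > 15
(consumed from the input table, never computed), an apo/holo R-free gap
> 0.05 (read as absolute), a per-structure R-free increase across
refinement > 0.025, or ligand occupancy < 0.15. Superposition is
closed-form least-squares (proper rotation enforced); collinear point
sets are rejected as degenerate.

## Rotamers

χ dihedrals are binned into the staggered wells p = [0°, 120°),
t = [120°, 240°), m = [240°, 360°); terminal two-fold-symmetric χ
(Asp/Glu carboxylate, Phe/Tyr ring) are folded modulo 180° before
binning. This well-binning replaces a full rotamer-library lookup: the
apo/holo comparison needs only well identity, and with every angle
falling in a well there is no outlier class. Per matched residue the
conformer label sets are compared set-wise: equal → `no_change`;
disjoint → `distinct`; holo ⊊ apo → `remodeled_holo_loss`;
apo ⊊ holo → `remodeled_holo_gain`; otherwise `remodeled_both` (a
partition proved exhaustive by enumeration in the tests).

## Spatial environment

Binding-site residues have any heavy atom within 5 Å of any ligand
heavy atom (boundary inclusive); distant residues are > 10 Å from every
ligand heavy atom. Solvent accessibility uses an in-repo Shrake–Rupley
algorithm — a deterministic Fibonacci point set (960 points by default,
probe 1.4 Å, standard element vdW radii, hydrogens excluded) on the
highest-occupancy conformer of each residue — normalized by the Tien
et al. (2013) theoretical maximum accessible areas; RASA ≥ 20% counts
as solvent exposed. RASA > 1 is reported as-is.

## Hydrogen bonds

Bonds are detected geometrically: H···acceptor < 3.2 Å and
D–H···A ≥ 90° ("maximum angle 90°" read as the HBplus minimum-angle
semantics), with donor/acceptor chemistry from a per-residue table
(backbone N–H donor and carbonyl O acceptor; side-chain N/O/S groups;
His both faces). Intra-residue and main-chain/main-chain pairs are
excluded. Multiconformer structures are split into one single-conformer
structure per altloc label (a residue lacking a label contributes its
highest-occupancy conformer; blank-altloc atoms appear in every split);
each unique bond — keyed by donor and acceptor atom regardless of
altloc — contributes the *maximum over splits* of min(donor occupancy,
acceptor occupancy). Max-deduplication avoids double-counting bonds
shared through the invariant backbone; per-split summation is available
behind a flag. Region counts are normalized by region size.

## Cohort statistics

All differences are holo − apo. Per pair, the binding-site mean Δs2 (x)
and the *residual* (distal-buried mean Δs2 − x) are computed; the
residual is regressed on x by OLS with a two-sided t-test on the slope.
Matched controls resample, for each binding-site residue, one
non-binding-site residue of the same amino-acid type and exposure class
(without replacement, 100 draws by default). Slopes of two cohorts are
compared by within-cohort bootstrap resampling of pairs
(z = Δmean/√(sd₁² + sd₂²), normal two-sided p). Paired comparisons use
the Wilcoxon signed-rank test, independent groups the Mann–Whitney U
test (midranks), both two-sided. Ligand-descriptor contrasts compare
lowest vs highest quartiles with Bonferroni correction at
α/m = 0.05/10 = 0.005. Residue-by-pair Δs2 matrices are co-clustered
with average-linkage agglomerative clustering on Euclidean distances.

## The synthetic cohort

The generator emulates the *measurement substrate* of the analysis —
multiconformer PDB pairs with altlocs, occupancies, B-factors, explicit
Cβ hydrogens, a HETATM ligand and crystal metadata — with every derived
quantity planted analytically:

* Chains are 26-residue ideal-geometry Ser/Val/Leu repeats (3.8 Å Cα
  spacing with a slight zigzag; side chains built by internal-coordinate
  placement so realized χ1 angles are exact; Cα–Cβ–γ = acos(−1/3)).
* Occupancies and B-factors are pre-quantized to the 0.01 precision of
  the PDB fixed-column fields, and the ground truth is computed from
  the quantized values, so recovery through a file round trip is exact
  up to the 10⁻³ Å coordinate precision.
* α-carbon B-factors are chosen so the resolution-normalization factor
  clips at exactly 1; hence s2_calc ≡ s2_ang and planted occupancy
  shifts map one-to-one onto order-parameter deltas.
* A rigid 12-carbon ring ligand defines a 4-residue binding site in the
  holo structure only; designated distal residues are enclosed in
  shells of carbon pseudo-atoms (HETATM code CAG, on the additive list)
  to plant the buried exposure class. The shells also occlude the
  neighbours of their centres, so the planted distal effect covers the
  whole buried block and the pipeline's buried set equals the planted
  set exactly.
* Per-pair binding-site means are drawn antithetically around the
  cohort median (default +0.03), making the planted sample median exact
  at finite n; distal-buried means follow residual = slope·x + noise
  with slope −0.44 and σ_r = 0.048 — chosen so the residual regression
  shows r² ≈ 0.46, the scatter level observed in real cohorts. The
  noise is projected orthogonal to x so the planted slope holds exactly
  in the realized cohort, not just in expectation. σ_x =
  0.1 sets the spread of per-pair effects. 11% of pairs are
  preorganized (all binding-site residues `no_change`); each other pair
  has exactly one remodeled binding-site residue with category odds
  15.5 : 2.6 : 3.8 (distinct : holo-loss : holo-gain), which reproduces
  the observed ~78.6% / 15.5% / 2.6% / 3.8% binding-site category mix
  in expectation.

What the generator does **not** emulate: real electron density and
refinement noise, folded tertiary topology, correlated backbone motion,
waters, and crystal contacts. Passing recovery tests therefore
demonstrates the correctness of the measurement and statistics chain,
not robustness to refinement artefacts in real data.

## Numerical choices and degenerate inputs

* All S² values clipped to [0, 1]; s2_calc = s2_ortho_norm × s2_ang
  holds to 10⁻¹² before clipping.
* Boundary semantics: distance and difference thresholds inclusive
  (≤ / ≥) with 10⁻⁹ tolerance where the rule is quoted as strict.
* Missing χ1 atoms yield a not-computable flag, never an exception;
  empty rotamer sets exclude a residue from classification.
* Blank-altloc occupancy disagreements resolve in favour of the
  conformer occupancy.
* Multi-model files: only the first model is read (warning logged).
* Ties: smallest altloc for the split fallback, smallest apo id in pair
  matching, smallest c in calibration.
* Zero-variance regressors, empty regions, collinear superpositions and
  all-zero paired deltas raise (or flag) rather than return silently.

## Problem sizes

Default study sizes were chosen to keep full runs at desk scale: 200
pairs for end-to-end recovery cohorts, 300 pairs per cohort for the
bootstrap slope contrast (1000 resamples), 200 matched residues for the
calibration series, 1000–2000 replicates for null-calibration rates.

## Known limitations

* The harmonic prefactor and atom choice are a defensible convention,
  not a unique one; absolute s2_ortho values should not be compared
  across conventions.
* Rotamer wells are fixed 120° bins; rare non-rotameric conformations
  are assigned to the nearest well rather than flagged as outliers.
* SASA is computed on the highest-occupancy conformer only; per-altloc
  SASA averaging is out of scope.
* Ligand "normalized B" is the plain ratio to the mean α-carbon B;
  published quartile boundaries on other (unstated) scales are not
  numerically comparable.
* mmCIF input, anisotropic ADPs, water-mediated hydrogen bonds and
  nucleic-acid chains are out of scope.
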
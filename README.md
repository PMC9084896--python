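# confhet

Quantifying protein side-chain conformational heterogeneity in
multiconformer crystal structures, and how it changes when a ligand
binds.

Multiconformer crystallographic models represent disordered side chains
as discrete alternative conformations (PDB altlocs) with fractional
occupancies and B-factors. `confhet` measures that heterogeneity per
residue and compares matched ligand-free (apo) and ligand-bound (holo)
structures of the same protein: does the binding site rigidify, and is
that rigidification compensated by increased flexibility elsewhere?

The core statistic is a side-chain order parameter S² ∈ [0, 1]
(1 = rigid), the product of an angular and a harmonic component:

    s2_ang   = (3/2) Σ_ab M_ab² − 1/2,   M_ab = Σ_i q_i u_ia u_ib
    s2_ortho = 1 − k (B_Cβ + B_H) / r²,  k = 3/(16π²), r = 1.09 Å
    s2_calc  = clip(s2_ortho · B_CA / (c · resolution)) × s2_ang

where **u**ᵢ are the χ1-defining Cβ→γ bond directions of the altloc
conformers with occupancies qᵢ, and c ≈ 10 is a resolution-normalization
constant calibrated on same-protein structures spanning a resolution
range. Around this sit: apo/holo pair matching with quality control
(space group, sequence, resolution, cell, Cα RMSD, clashscore, R-free,
ligand occupancy), rotamer-well classification of apo→holo changes,
occupancy-weighted hydrogen-bond counting on altloc-split structures,
Shrake–Rupley solvent accessibility for binding-site / distant /
buried / exposed partitioning, and cohort statistics (matched controls,
residual regression, bootstrap slope comparison, Wilcoxon /
Mann–Whitney tests, ligand-descriptor quartile contrasts, clustering).

A synthetic-cohort generator builds multiconformer PDB pairs with
analytically planted effects, so every stage of the pipeline is
testable against exact ground truth. See `docs/methods.md` for the full
model description.

## Worked example

Generate a 20-pair synthetic cohort with a planted median binding-site
order-parameter increase of +0.03 and a distal-compensation slope of
−0.44, run the full pipeline on one pair, then aggregate:

```python
import numpy as np
from confhet.synthetic import CohortSpec, build_pair, draw_pair_effects
from confhet.pipeline import run_pair, run_cohort

spec = CohortSpec(n_pairs=20, median_bs_delta=0.03, residual_slope=-0.44,
                  seed=11)
rng = np.random.default_rng(spec.seed)
xs, resids = draw_pair_effects(spec, rng)

tables = []
for p in range(spec.n_pairs):
    apo, holo, truth = build_pair(spec, p, float(xs[p]), float(resids[p]), rng)
    tables.append(run_pair(apo, holo)["deltas"])

summary = run_cohort(tables)
print(f"median binding-site ds2 : {summary['median_bs_delta_s2']:+.4f}")
print(f"matched-control median  : {summary['median_control_delta_s2']:+.4f}")
print(f"residual slope          : {summary['residual_slope']:+.3f} "
      f"(r2 = {summary['residual_r2']:.2f})")
```

Output:

```
median binding-site ds2 : +0.0270
matched-control median  : +0.0000
residual slope          : -0.568 (r2 = 0.64)
```

The binding-site median is positive (holo more rigid than apo) while
the matched control — same residue types and exposure classes, outside
the binding site — stays at zero, and the negative slope means pairs
whose binding sites rigidify most show the largest relative gain of
flexibility in distant buried residues. (At 20 pairs the estimates sit
near, not on, the planted values of +0.03 and −0.44; at the 200-pair
study scale used by `scripts/acceptance.py` they converge.)

The same pipeline is available from the shell:

```
confhet synthesize --n-pairs 20 --seed 11 --out cohort/
confhet pair cohort/pair0000_apo.pdb cohort/pair0000_holo.pdb --out-dir out/
confhet cohort out/ --out summary.json
confhet calibrate --seed 5        # normalization-constant recovery demo
```

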
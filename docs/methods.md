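# Methods

This note records the models implemented in `replikit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducibility.

## Coevolution pipeline

### Input handling

Alignments are consumed as already-aligned protein FASTA (the package does
not run an aligner). Residues are uppercased on read and any letter outside
the 20 standard amino acids is remapped to the gap symbol `-`: the Potts
model below uses a fixed 21-state alphabet, and ambiguity codes (B, Z, X,
U, J, O, `*`) have no state of their own. Species identifiers are parsed
from headers by a configurable rule (default: first `|`-delimited token).
At most one sequence per species is retained (first occurrence by default),
both because within-species paralogues would distort covariance estimates
and because cross-species pairing requires a unique row per species. All
coordinates are 1-based.

Two families are paired by species intersection and concatenated per
species as `[A | linker | B]` with a 20-residue poly-asparagine buffer.
The linker's only purpose is to make the segment boundary unambiguous; its
columns are constant, contribute nothing to covariance (the pseudocount
keeps the matrix invertible regardless), and are excluded from every
reported pair. Species present in only one family are dropped with a
logged count.

### Mean-field DCA

The statistical chain is the standard mean-field one:

* **Reweighting.** w_a = 1/m_a where m_a counts sequences with fractional
  identity ≥ θ to sequence a (itself included); identity counts equal
  symbols — gap included — over the full concatenated length. Default
  θ = 0.8, the customary redundancy threshold for this method; θ = None
  disables reweighting. Meff = Σ w_a is the effective sample size.
* **Frequencies.** f_i(A) = λ/q + (1−λ)·femp_i(A) and
  f_ij(A,B) = λ/q² + (1−λ)·femp_ij(A,B), femp weighted by w_a/Meff.
  Default λ = 0.5, the standard heavy regularisation for covariance
  inversion; within-column blocks are forced to δ(A,B)·f_i(A) so the
  marginalisation identity Σ_B f_ij(A,B) = f_i(A) holds exactly (tested
  to 1e−12).
* **Couplings.** The connected-correlation matrix is built over the first
  q−1 states of each column (the gap, ordered last, is the gauge state
  with zero couplings) and inverted once; e = −C⁻¹ read off in (i,j)
  blocks. With λ > 0, C is positive definite; a singular C (only possible
  at λ = 0) raises an error advising a positive pseudocount.
* **Scores.** MI is the Kullback–Leibler divergence of f_ij from
  f_i ⊗ f_j; DI is the mutual information of the two-site model
  P ∝ exp(e_ij)·h̃_i·h̃_j with fields solved by multiplicative
  marginal-matching iteration. Natural logarithms throughout (nats).

The two-site fixed point stops when both marginals of P match f_i and f_j
within `tol` (default 1e−4, `max_iter` 500) and raises a convergence error
with the residual otherwise. DI is symmetric only up to this tolerance;
tests that assert symmetry tighten `tol` accordingly. Tiny negative DI/MI
from roundoff are clipped to zero.

Both one-per-species filtering and θ-reweighting are applied by default.
They address different redundancy scales (within-species paralogues vs
near-identical orthologues across close species) and are independent
toggles.

### Interface mapping

Only inter-protein (AB) column pairs are reported. Pairs are renumbered
via per-family column maps into the 1-based ungapped coordinates of each
reference sequence; pairs falling on a reference gap have no residue to
report and are dropped with a logged count. Candidate interface residues
are ranked by the per-residue aggregate of a chosen metric over all
partner pairs — default aggregate `max`, default metric DI (the direct
statistic; `sum` and MI are config options) — with ties broken toward the
lower residue number so results are order-independent. The exported heat
map defaults to MI, the quantity conventionally displayed, with the
helicase–primase family on the y-axis; unscored cells are NaN in the TSV.

## Binding isotherm

The 1:1 ligand-depletion equation (README) is exact for a labelled target
at non-negligible concentration; its discriminant equals
(C − C_T + K_d)² + 4·K_d·C_T ≥ 0 analytically and is clipped at zero
against roundoff. Limits: F(0) = U; F(∞) = B; at K_d = 0 the bound
fraction is min(C, C_T)/C_T (the stoichiometric form), and the K_d → 0
convergence is O(√(K_d/C_T)) at the kink C = C_T.

Fitting uses Levenberg–Marquardt least squares on (U, B, log K_d); the log
parametrisation keeps K_d positive without an active bound. Initial values:
U and B from the responses at the lowest and highest ligand concentration,
K_d from the concentration nearest half-maximal response (geometric mean of
the series if the response is flat). Standard errors come from the
Jacobian mapped back to K_d coordinates. The `converged` flag is cleared
when the optimiser fails, when |B − U| is negligible relative to the
response scale (flat data: K_d unidentifiable), or when K_d exceeds 1000×
the largest titrated concentration (effectively unbounded). Fewer than 5
points is rejected outright for a 3-parameter fit.

Defaults mirror the standard MST assay layout: 16 serial dilutions with a
1:1 (factor 2) dilution scheme and a labelled-target concentration of
20 nM. Concentrations are handled internally in molar; the titration CSV
reader accepts a `concentration_unit` column (pM/nM/uM/mM/M).

## ΔΔCt copy number

Amplification efficiency is fixed at 2 (classic ΔΔCt); per-target
efficiencies are out of scope. ΔCt is computed per replicate, pairing the
target and reference wells within (genotype, replicate). The confidence
interval is a Welch two-sample t-interval between the genotype's and the
control's replicate ΔCt values, built on the ΔΔCt (log2) scale and then
exponentiated — asymmetric around the ratio, as appropriate for a
log-scale statistic. A two-sample interval was chosen over a one-sample
interval on genotype ΔΔCt values because the control mean is itself
estimated from replicates; ignoring that term makes the interval
anti-conservative. The control genotype's own ratio is 1 by construction
and carries no interval. A single replicate yields a ratio with a warning
and NaN bounds. A helper averages per-target ratios into per-organelle
means on the log2 scale.

## Synthetic-data generators

All generators are pure functions of their spec, seed included; the same
spec yields byte-identical output.

* **Paired alignments.** Background columns are i.i.d. uniform over a
  sub-alphabet (default 4 letters — small alphabets give strong
  per-column signal at modest cost; the full 21 letters are supported).
  Planted inter-family pairs are drawn from P(a,b) ∝ exp(β·δ_ab); β = 0 is
  independence, β = 3 (default) gives ~87% state agreement at q_sub = 4 —
  a strong, unambiguous coupling — and an explicit joint table is
  accepted for exact constructions. Optional near-duplicate copies (with
  a per-site mutation rate) exercise reweighting, and a gap rate converts
  non-reference positions to gaps. The standard validation scenario is
  2000 species and two 30-column families with 5 planted pairs. What this
  does **not** emulate: phylogenetic correlation between species, realistic
  amino-acid composition, conserved columns, or indel structure — so
  passing recovery tests demonstrates the inference machinery is correct,
  not that real alignments of any particular depth will yield confident
  contacts.
* **Titrations.** Responses are the isotherm plus additive i.i.d. Gaussian
  noise (sd 0.02 on a 0–1 response scale by default, consistent with the
  small replicate scatter typical of normalised MST data). Real MST noise
  is likely heteroscedastic and correlated across a capillary series;
  recovery results here quantify estimator behaviour under the stated
  model only.
* **Ct tables.** Ct(target) = base − log2(true ratio) + noise per well,
  reference wells at base + noise (default noise sd 0.2 cycles, 6
  replicates). Shared-well correlation and pipetting batch effects are
  not modelled.

## Validation problem sizes

The test suite validates (a) exact identities and independent oracles
(brute-force MI summation, hand-inverted covariance on L ≤ 3, q ≤ 3 toys,
algebraic isotherm limits, ΔΔCt identities); (b) planted-coupling
recovery: at the standard scenario, all 5 planted pairs must rank in the
DI top-10 of the 900 inter-protein pairs in ≥ 95% of 20 seeds; (c) Kd
recovery: median over 200 noisy replicates within 10% of truth at each of
the four studied dilution designs; (d) ΔΔCt interval coverage: ~95%
(accepted band 91–99%) over 300 simulations at 6 replicates; and (e)
byte-identical pipeline artifacts across repeated runs. These sizes were
chosen as the smallest at which each property is statistically
unambiguous.

## Known limitations

* Mean-field inversion only; pseudolikelihood or other Potts inference
  variants, average-product correction, and structural (contact-map)
  evaluation are out of scope.
* The coevolution stage is protein-only and two-family-only.
* The MST stage fits normalised responses; raw thermophoretic time traces
  and instrument formats are not handled, nor are alternative isotherms
  (e.g. Hill).
* ΔΔCt assumes perfect doubling; no standard-curve efficiency estimation
  or melt-curve QC.
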
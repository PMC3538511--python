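# Methods

This note records the model, the numerical choices, and the design decisions
behind `gxesim`, together with what the synthetic-data generator does and
does not emulate.

## Disease model

Risk is modelled by the multi-logistic model (MLM): one logistic curve in
the exposure per combined two-locus genotype,

    P(affected | g_a, g_b, x) = sigmoid(α(g_a,g_b) + β(g_a,g_b)·x).

**Sign convention.**  Risk increases in α + βx.  Under this orientation the
slope is literally the log odds ratio of disease per unit exposure:
odds(x+1)/odds(x) = exp(β) exactly, which is what epidemiologists mean by a
"per-unit OR", and what the property tests assert.  The slope pinned by
convention at the highest-risk combined genotype (argmax of the final
penetrance matrix; ties prefer (3,3), then row-major order) is called β_AB
and equals ln(OR) of the configured environmental effect.

**Expected penetrance.**  TR(g) = E_x[sigmoid(α+βx)] for Gaussian x is
evaluated with a 256-node Gauss-Hermite rule on the untruncated real line.
Node count was chosen from a convergence study against a 400,001-point
trapezoid rule over mean ± 10 sd: worst-case error ≈ 3e-9 for |β|·sd ≤ 6
and |α| ≤ 6 (96 nodes leave ~5e-6 for steep slopes, not enough for the
1e-8 round-trip guarantee the solver makes).

## From epidemiological inputs to the penetrance matrix

Per locus, the three genotype risks are parameterised as
(t, [w + (1−w)·RR]·t, RR·t).  The dominance weight w places the heterozygote
risk on the segment between the homozygote risks: w=0 means the high-risk
allele is dominant (heterozygote as risky as the high-risk homozygote),
w=1 recessive, intermediate co-dominant.  The scale t is fixed analytically
by the prevalence constraint Σ_g TR_g·P_g = m; if the implied high-homozygote
risk exceeds 1 the parameters are rejected with a message naming the locus.

With no epistasis the loci are conditionally independent given disease
status, which yields TRᴵ(g_a,g_b) = TR_ga·TR_gb/m.  This matrix reproduces
both marginal risk vectors and the prevalence identically, which the test
suite asserts to 1e-10.

Genotype frequencies entering these formulas are Hardy-Weinberg expansions
of the configured allele frequencies when the model is parameterised in
isolation, and the *observed* genotype proportions of the generated
population during a full run — so designed risks refer to the sample
actually simulated.

## Epistatic deformation

Epistasis is a perturbation Δ of TRᴵ subject to

* row conditions Σ_gb Δ(g_a,g_b)·P_gb = 0 (3 equations),
* column conditions Σ_ga Δ(g_a,g_b)·P_ga = 0 (3 equations; the system has
  rank 5 since both sets share the total-sum constraint),
* box conditions 0 ≤ TRᴵ + Δ ≤ 1.

Up to three cells may be pinned by the user as percent changes of TRᴵ, with
the placement rule that every pair of pinned cells shares a row or a column.
Free cells minimise the variance of the ratios Δ/TRᴵ over the non-pinned
cells — the flattest relative deformation consistent with the constraints,
so unconstrained cells keep their mutual relationships as far as possible.
With no pinned cells the optimum is exactly Δ = 0.

**Solver.**  The feasible set is affine (at most 4 residual degrees of
freedom after pinning), so the program is solved by null-space elimination:
a minimum-norm particular solution via least squares, the null-space basis
from SVD, and the convex quadratic objective minimised in the null-space
coordinates by another least-squares solve (the minimum-norm minimiser is
taken when the quadratic is degenerate along feasible directions, making
the result unique and bit-reproducible).  Only if the interior optimum
violates a box bound does the solver fall back to SLSQP with explicit
bounds, started from the clipped interior solution.  Infeasibility — pinned
values inconsistent with marginal preservation, or no box-feasible point —
raises a structured error naming the binding constraint instead of silently
relaxing user values.

Cells with TRᴵ = 0 have an undefined ratio; they are pinned to Δ = 0 and
excluded from the objective, with a note in the run log.

**Dimension counting.**  Nine cells minus the rank-5 equality system leaves
four degrees of freedom, so even three admissible pinned cells generally
leave residual freedom (three pinned cells on one row additionally interact
with that row's own constraint and may be mutually inconsistent).  The
implementation trusts the constraint algebra: whenever residual freedom
exists the optimizer resolves it; when the user's values are inconsistent a
feasibility error reports the worst-violated row/column constraint.

## Solving the gene-environment models

Each of the 9 cells imposes E_x[sigmoid(α+βx)] = TR(cell).  The four
predefined models close the system:

* **GEN** — β ≡ 0, α = logit(TR) in closed form (no quadrature).
* **ENV** — a single shared (α, β=β_AB); requires a constant TR matrix and
  raises a model-inconsistency error otherwise.
* **ADD** — β ≡ β_AB; each α is an independent 1-D root-find.  The expected
  penetrance is strictly increasing in α, so Brent's method on an expanding
  bracket converges to machine precision (xtol 1e-12).
* **GEM** — shared α, per-cell β, with β_AB pinned at the highest-risk
  cell.  Although nominally a 9-unknown system, it is triangular: the
  pinned cell's equation involves only α (1-D root-find), and every other
  equation then involves only its own β (1-D root-find at fixed α).  The
  sequential Brent solves give the exact solution of the full system, and
  were preferred over a damped Newton iteration on the joint system because
  they cannot diverge and need no initial guess.

**GEM attainability.**  With a shared intercept, the expectation at fixed α
ranges over a band bounded by sigmoid(α) and the large-|slope| limits
(Φ(±μ/σ) for exposure mean μ, sd σ).  For a mean-centred exposure the band
is [sigmoid(α), 0.5], so a TR matrix whose spread is large relative to the
pinned slope can place low-risk cells below the attainable band.  The solver
tries both slope signs and, if the target is still unattainable, raises a
diagnostic error reporting the attainable range.  Practical guidance: use
GEM with an off-centre exposure (e.g. mean 2, sd 1) or a sufficiently large
environmental OR.  The GEM scenarios in the tests use a shifted exposure for
exactly this reason.

A diagnostic (`check_prevalence`) recomputes the implied prevalence from the
solved coefficients by quadrature and reports the residual (pass threshold
1e-7); it is written to the run log of every run.

## Synthetic genotypes and exposures

The genotype generator emulates only the statistical structure the disease
model assumes:

* **Block-mosaic haplotypes.**  Within a block, allele indicators follow a
  first-order Markov chain calibrated so adjacent loci have correlation
  ρ = sqrt(r²) at the requested allele frequencies; r² therefore decays
  geometrically with distance inside a block and is ~0 across blocks.
  Requested (r², frequency) pairs that are mathematically unattainable
  (the Fréchet bound on the allele covariance) are rejected.  The two DPLs
  are placed in different blocks, realising the assumption that they are
  not in LD.
* **Individuals** are random unions of two pool haplotypes (HWE by
  construction).  A direct two-locus HWE sampler (`sample_hwe_population`)
  is provided for model-focused experiments that need no background
  markers; it is the exact generative model of the penetrance machinery and
  is what the acceptance experiments use.
* **Exposures** are i.i.d. Gaussian; noise exposures (Gaussian, uniform or
  binomial) are independent of everything; gender is Bernoulli(0.5),
  encoded 1/2, and never enters the risk model.

Not emulated: demographic history, recombination maps, population
structure/admixture, allele-frequency drift, missing genotypes, genotyping
error, and LD between the causal loci.  Passing tests therefore show that
*given* HWE genotypes, designed LD, and Gaussian exposures, the disease
model embeds the configured effect sizes — they say nothing about
robustness to stratification or data artefacts in real cohorts.

Exposure distribution in validation experiments is standardised to
Gaussian(0,1) (a free choice; any mean/sd only shifts/scales the solved
coefficients for ADD/GEN/ENV).

## Randomness and determinism

A single global integer seed is split into named per-stage streams (panel,
sampling, exposure, each noise variable, gender, status, each subsample
replicate) via `numpy.random.SeedSequence` spawn keys.  Any stage can be
re-run in isolation bit-for-bit, and a config plus seed determines every
output file byte-for-byte (the run log's timing lines are prefixed `# ` and
excluded from that guarantee).  Case-control subsampling draws without
replacement within a replicate and independently across replicates.

## Problem sizes in the validation suite

The validation experiments run at sizes where binomial sampling error is
comfortably below the assertion tolerances: 50,000 individuals for
regression recovery of the environmental OR (SE of the log-OR ≈ 0.015),
200,000 for homozygote penetrance ratios (relative SE ≈ 2-3%), and
5,000+40,000+320,000 for the convergence-with-n check.  Detection of a pure
+20% single-cell epistatic increment at 5,000 cases + 5,000 controls is a
~2-standard-error signal for common variants; the detection test therefore
combines evidence across five case-control replicates (Fisher's method) —
single replicates of that size are underpowered for so localised an effect,
which is itself an informative property of the design.

## Output conventions

Tables are tab-delimited with one header row; columns left to right are
disease status (1 affected / 0 unaffected, NA if unassigned), gender (1/2,
arbitrary labels), the causal exposure, noise exposures, then genetics in
the phased dialect (two nucleotide columns per SNP) or the genotypic dialect
(codes 1/2/3; 3 is the high-risk homozygote for DPLs and the minor-allele
homozygote for background SNPs, with 0.5-frequency ties broken
lexicographically).  SNP map positions are 1-based.  External genotype
matrices are ingested as-is — no HWE or LD enforcement is applied to them.

## Known limitations

* Exactly two causal loci and one causal exposure; the architecture
  generalises but the configuration surface deliberately does not.
* ENV requires an exactly constant penetrance matrix (RR=1 at both loci and
  no epistasis); it does not project a non-constant matrix.
* GEM feasibility depends on the exposure location/scale (see above).
* The variance-of-ratios objective is the only completion rule offered for
  partial epistasis specifications.
* Risks do not vary with gender or age.
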
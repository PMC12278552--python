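# Methods

## The generative model

The simulated population mirrors a progeny-testing dairy design: a
parent generation of unrelated sires and dams and one offspring
generation of phenotyped cows.

**Population.** 10,000 dams and 100 sires found the pedigree; each dam
has exactly one offspring cow, and the 10,000 cows are distributed over
herds (100 herds × 100 cows in the basic design; 200 × 50 and 50 × 200
variants exist). Within each herd a pool of nine sires is drawn with
replacement from the 100, and each cow's sire is drawn with replacement
from that pool, producing paternal half-sib families of varying size
from ~8.7 distinct sires per herd. Founder breeding values (a_D, a_I)
are bivariate normal with covariance matrix G; cow breeding values are
parent averages plus Mendelian-sampling terms drawn with covariance G/2,
an identity that holds to machine precision row by row. Direct and
indirect environmental effects are independent normals (their covariance
is fixed at zero by design). Herd effects are uniform on
[8,000, 13,000] kg ECM and enter as fixed effects.

**Variance budget.** Inputs are anchored to the phenotypic variance of a
cow with the mean number of contacts n:
σ²_P = σ²_aD + n(σ²_aI + σ²_eI) + σ²_e, with σ_P = 800 kg ECM and
h²_D = 0.3 throughout. In the basic design σ²_aI = σ²_aD / n, so the
received indirect effects and the direct effect contribute equally
(30% each) to σ²_P; with σ²_eI = σ²_aI this leaves σ²_e = 64,000 kg².
Smaller indirect-variance designs put 15, 5, 3, or 1.5% of σ²_P into the
received IGEs. The scenario registry stores the design tables' literal
variances (the 5% tier uses 1024 kg², the tables' value, rather than the
exact-share 1066.7).

**Contact networks.** Per herd, contact counts are iid Poisson(30)
truncated at 43 (the 99% quantile); a simple graph realizing the drawn
degrees exactly is sampled with igraph's edge-switching method. Degree
sequences with odd sums or non-graphical draws are repaired by
resampling one cow's degree (bounded at 100 attempts), which preserves
the marginal distribution. Directed variants split each cow's total
contacts by a balanced binomial into incoming and outgoing arcs (caps
22 and 21), equalize totals by unit transfers, and realize both degree
sequences exactly; only incoming arcs contribute to a cow's phenotype.
Optional intensities are iid gamma(shape 1, rate 2) per dyad — matching
observed proximity-duration distributions — used either raw (mean 0.5)
or standardized by their mean to mean 1, variance 1. Undirected dyads
carry one shared intensity in both directions. Measurement error is
modelled as additive N(0, 0.16) noise on an analysis-side copy of the
intensities (read as variance 0.16, i.e. SD 0.4); noisy intensities may
be negative and are used as-is.

**Phenotypes** follow
y_i = herd_i + a_D,i + Σ_j f_ij (a_I,j + e_I,j) + e_D,i over the
incoming contacts j, with f ≡ 1 when intensities are off. Construction
is deterministic given its inputs, and linear: doubling every random
effect doubles y − herd exactly. Two structural facts the tests verify:
intensity variation of 1 doubles the indirect contribution to
phenotypic variance, while variation in the number of contacts adds
none (the indirect contribution depends on the mean degree only).

**Seeding.** Each replicate spawns named independent RNG streams
(pedigree, breeding values, environment, herd, network, intensity,
noise), so switching a feature on or off never perturbs the other
draws — scenarios sharing a seed share their population and network
topology and differ only in the feature under study.

## Estimation

The analysis model is the animal model extended with indirect genetic
and indirect permanent-environmental effects,
y = Xb + Z_D a_D + Z_I a_I + Z_I e_I + e, with
(a_D, a_I) ~ N(0, G ⊗ A), e_I ~ N(0, σ²_eI I), e ~ N(0, σ²_e I). X has
one column per herd and no intercept, so estimability is unambiguous.
Z_I's entries are the analysis-side intensities: the true f, the noisy
f, or 1 (intensities ignored); under "direction ignored" on directed
data, row i has an entry for every arc touching i in either direction.
One e_I is fitted per phenotyped cow. A⁻¹ is assembled directly by
Henderson's rules for non-inbred pedigrees and checked against the
tabular method.

**Restricted likelihood.** −2ℓ_R = n log σ²_e + log|Σ| + log|C| + y'Py,
computed through the sparse mixed-model equations; the (2π) constant is
omitted consistently everywhere, including the dense-matrix oracles the
tests compare against.

**Block-arrow solver.** In this design every unknown — herd effect, cow
effects, dam effects — is local to one herd except the sires, which form
a global border of ~200 genetic effects (a parent with offspring in
several herds is promoted to the border automatically; the partition is
detected from the design and the A⁻¹ pattern, and the solver falls back
to a general sparse LU when the problem does not decompose). Dense
per-herd Cholesky factors plus a Schur complement on the border give the
factorization, log-determinant, and — via
C⁻¹ = [A_h⁻¹ + W_h S⁻¹ W_h', −W_h S⁻¹; ·, S⁻¹] per block — an *exact*
selected inverse at the sparsity pattern REML's trace terms need
(tr A⁻¹C^{aa} blocks and the e_I diagonal). A full-size factorization
takes ~2 s and a fit 1–2 minutes on one CPU.

**Maximization.** Parameters θ = (σ²_aD, σ_aDI, σ²_aI, σ²_eI, σ²_e),
constrained to non-negative variances and |r_g| ≤ 0.999 by projection.
Each iteration computes exact trace terms, then evaluates two
candidates — the EM update and the average-information (AI) step with a
trust region (variances move at most a factor of 5 per step, plus an
absolute allowance so near-zero components can grow) and step-halving —
and keeps whichever has the higher exact restricted likelihood. EM is
slow but monotone and robust near singular G; AI is quadratically
convergent near the optimum; the greedy combination inherits both.
The first five iterations are EM-only warm-up. A variance the score
pushes below 10⁻⁵ of var(y) is scientifically zero and is pinned at the
floor (10⁻⁸ of var(y)) with the AI system solved on the active set;
without pinning, EM decays such components geometrically and the
iteration crawls. Convergence requires relative parameter change
< 10⁻⁶ (negligible variances exempted) and relative likelihood change
< 10⁻⁸, with a cap of 200 iterations; hitting the cap returns
converged = False rather than raising, and non-converged replicates are
excluded from all summaries and reported as a count. Starting values
split the within-herd variance of y equally between σ²_aD and σ²_e with
small positive indirect components. EBVs are the BLUP solutions of the
mixed-model equations at the final estimates, for all pedigree animals
including non-phenotyped parents.

## Evaluation

Per scenario, replicates are summarised by the mean and SD of each
estimate; an estimate is flagged biased when the simulated value falls
outside the t-based 95% confidence interval of the mean (at 100
replicates the t and normal intervals are indistinguishable; the t form
is used because reduced-replicate runs are common here). EBV accuracy is
the Pearson correlation of true and estimated breeding values, and the
dispersion slope is the regression of *true BV on EBV* (the convention
in which < 1 means overdispersion) — note this is the reverse of the
calibration-literature regression of EBV on true value. Both are
reported separately for sires and phenotyped cows and for the direct
and indirect effect.

## Problem sizes and what the tests show

The full design (100 replicates × 22 scenarios) is a cluster-scale
study. The packaged tests and the acceptance script instead run a few
seeded replicates at the full or half population size, chosen so the
Monte-Carlo standard error of each checked mean stays inside its
tolerance: the basic scenario runs at full size (100 × 100, 3
replicates), and the misspecification scenarios at 50 × 100. Reduced
sizes leave the estimators' expectations unchanged (the tests verify
this directly), but between-replicate SDs grow roughly with the inverse
square root of the population size.

Two small-sample behaviours are documented rather than hidden: at
strongly reduced sizes (~1,000 cows) the PSD-constrained covariance
estimate σ_aDI shows a positive skew (its 95% CI can exclude the true
zero even though all variances are unbiased), an artefact the full-size
design does not show; and weakly identified configurations — small
σ²_aI, sparse toy networks — can fail to converge or land on the
σ²_eI = 0 boundary, mirroring the convergence failures reported for the
smallest-variance scenarios in this literature.

The synthetic design is deliberately idealized: contacts are random
(no assortativity by parity, breed or relatedness), the pedigree has two
generations without inbreeding or selection, every cow has one record,
and the indirect variance is not diluted with group size. Passing tests
therefore show the estimation machinery is correct and well calibrated
under the stated generative model — not that IGEs of this size exist in
commercial data.
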
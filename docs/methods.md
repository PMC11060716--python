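# Methods

This note records the models, conventions and numerical choices behind the
package, what the synthetic data do and do not emulate, and the known
limitations.

## Diet categories

Diet categories are assigned from diet-composition percentage tables in the
EltonTraits 1.0 field layout. Thresholds are inclusive: Folivore ≥ 60%
plant-other, Frugivore ≥ 60% fruit, Granivore ≥ 70% seed (split into husking
vs swallowing granivores by an input flag — the split comes from feeding
descriptions and is never computed), Invertivore ≥ 60% invertebrate,
Nectarivore ≥ 60% nectar, Piscivore ≥ 50% fish, Scavenger ≥ 50% carrion,
Tetrapod hunter ≥ 60% tetrapod prey (the sum of the endotherm and ectotherm
fields only; the unknown-vertebrate field is ignored). Generalist requires
every field ≤ 40%, and is checked only after the specific rules. If two
specific rules fire at once (possible only via the two 50% rules), the bird
is left Unclassified rather than forced into a category; Unclassified is
also the fall-through. The function is total: every valid composition maps
to exactly one category.

## Mass cutpoints

The Youden index J(c) = sensitivity + specificity − 1 treats the heavier
group as "positive, mass ≥ c". Candidates are midpoints between adjacent
pooled order statistics; the search runs on log10 mass by default because
bird masses span orders of magnitude (a raw-scale flag exists, since J
itself is rank-based and scale-invariant — only the reported midpoint
differs). Ties in J break toward the smaller cutpoint for determinism.
Confidence intervals are percentile intervals over stratified bootstrap
resamples (default B = 1999; the interval is widened, if necessary, to
contain the point estimate so the result is always internally consistent).
Under a two-log-normal design (log10 means 1.0/2.0, sd 0.35, n = 50 per
group, B = 499) the measured coverage of the true density crossing is 95.2%
over 500 replicates.

Fossil masses are intervals (min–max of per-specimen regression estimates),
so classification is set-valued: a specimen belongs to every tier whose
band, bounded by the CI limits of the adjacent cutpoints, it overlaps.
Cutpoints whose CIs overlap each other are rejected as an inconsistent
ordering.

## Jaw functional indices

All indices are ratios, invariant to rigid motion and uniform scale.
Out-levers are measured along the jaw length axis from the jaw joint
(quadrate articulation) to the bite point (anterior tip for AMA/OMA,
posteriormost tooth for PMA). In-levers are straight-line distances from
the joint to the muscle attachment point: this is the moment arm of a
muscle whose line of action is roughly normal to the jaw axis, and it makes
an anterior shift of the joint increase closing MA — the behaviour the
quadrate-placement sensitivity analysis relies on (an all-along-axis
convention was rejected because it reverses that direction). AO is the
perpendicular offset of the joint from the tooth-row line over jaw length;
MCH/MMH and ACH/AMH are the maximum and mean of the sampled outline heights
over jaw length (100 evenly spaced stations by convention). The sensitivity
analysis translates the joint by signed fractions of jaw length along the
axis (negative = anterior) and errors out rather than extrapolate past the
anterior tip.

## FE strain summaries

MWAM is the element-area-weighted mean of maximum in-plane principal
strain; area weighting matches planar models. Interval profiles use
half-open equal-width bins on [0, upper) plus one open-ended bin
[upper, ∞), so the profile always sums to 100% of area; defaults are 25
bins to 1000 µε, chosen so realistic extant jaw strains (~50–400 µε) spread
over many bins. Bin assignment at an edge goes to the upper bin
([lo, hi) convention) for determinism.

## Phylogenetic statistics

The Brownian covariance C has C[i,j] = root-to-MRCA path length; Pagel's λ
multiplies off-diagonals only. Blomberg's K is the ratio of ordinary to
phylogenetically corrected mean squared error about the GLS mean, divided
by its Brownian expectation `(tr C − n/(1ᵀC⁻¹1))/(n − 1)`; the multivariate
version replaces sums of squares with traces over the GLS-centred trait
matrix and reduces exactly to K for one trait. The permutation p-value is
the fraction of tip-label permutations (observed included) whose corrected
error is at most the observed, so p ≥ 1/(n_perm + 1).

Pairwise group comparisons fit trait ~ group by GLS (whitening by the
Cholesky factor of C), then permute the residuals of the intercept-only
null model (residual randomisation); the statistic is the absolute distance
between GLS group means. No multiple-testing correction is applied to the
pairwise matrix, matching the residual-randomisation convention. The
compact letter display assigns letters to maximal cliques of the
non-significance graph, ordered by ascending group means. Measured type-I
error is ~5% at α = 0.05 (7% over 100 null simulations, 5% over 300
pair-tests in the seeded acceptance run).

FDA with a linear basis is optimal-scoring-equivalent to LDA, so the
discriminant is fitted as LDA with configurable priors (class-frequency by
default, equal optional); posteriors come from the Gaussian class models
and always sum to one. A rank-deficient within-class scatter triggers a
warning and a small ridge (shrinkage 1e-6 on the eigen solver). pFDA
whitens the predictors by the inverse Cholesky factor of C(λ) over the
training tips and scores each λ on a grid (default 0–1 by 0.01) by
leave-one-out misclassification, tie-breaking to the smaller λ; the
whitening transform is computed once per λ, not refitted inside each LOO
fold. New taxa are whitened jointly with the training tips on a combined
tree (default) or scaled by their own root-to-tip depth only
("extant_only"); new taxa must be distinct tips in combined mode. On an
ultrametric tree, λ = 0 whitening is a uniform scaling, so classifications
reduce exactly to plain FDA.

## Ancestral states

Time-scaling pins the root at a given age, places each tip at its
first-occurrence age, and puts every internal node one minimum divergence
offset (default 1000 years = 0.001 Ma) above its oldest child; inconsistent
ages (tip older than root, or minimum node ages exceeding the root) are
errors rather than silently stretched. Polytomies are resolved by merging
uniformly random child pairs until binary (a k-tomy gains k − 2 nodes);
inserted edges get ε = 1e-8 × tree height, with the original child edges
shortened to preserve tip depths — ε must be tiny so estimates are
unchanged at reporting precision, and zero-length terminal branches are
rejected before reconstruction.

ML Brownian ancestral states are the GLS conditional means given the tips,
with the root state the GLS phylogenetic mean and σ² the ML estimate
(n-divisor); per-node variance uses the kriging form with the
mean-estimation correction, and the 95% CI is ±1.96 SE. Averaging over
random resolutions reports, per node of the *unresolved* tree (matched by
descendant tip set), the mean and the 2.5/97.5% quantiles across
resolutions; with ε edges the root spread is below 1e-8 relative by 1000
resolutions, i.e. stable to far more than seven significant figures.
Qualitative diets are reconstructed per probability column and the node
vectors are clipped at zero and renormalised to sum to one at report time;
the raw column means are kept alongside, and the renormalisation is
explicit output metadata rather than a silent step. Measured recovery at
n = 100 tips: σ² relative bias ≈ 3%, root CI coverage ≈ 95–97% over 500
replicates.

## Synthesis

Per-proxy verdicts reduce posteriors to likely/unlikely sets by relative
thresholds: likely if posterior ≥ 0.1 × the class maximum, unlikely if
< 0.01 × it (both configurable; the published summary-table sets are
narrative, so this formalisation is a documented approximation, not the
original authors' procedure). Mass verdicts take the union of diets over
the assigned tiers. The consensus is the intersection of likely sets over
the available diet proxies (mass, jaw MA, FEA); pedal morphometrics
describes foot use and joins the intersection only when explicitly flagged
diet-informative, and skull morphometrics is excluded by default because
its applicability outside crown birds is uncertain. An empty intersection
is reported as indeterminate — adding a proxy can only shrink or preserve
the consensus.

## Synthetic data

The generators provide the statistical structure the analyses assume, not
biological realism: Yule trees conditioned on tip count (grown to n tips
and truncated at the moment the next, unrealised speciation would occur,
so terminal branches are positive); BM traits with additive diet-group
offsets at the tips; Dirichlet diet compositions per class; strain fields
whose heterogeneity parameter is the expected area fraction under extreme
(two-mode, ±85% of the mean) strain, rescaled after generation so the MWAM
is exact; and noiseless circular-arc claws under random rigid pose. They do
not emulate measurement error in landmarks, non-BM trait evolution (OU,
early-burst), fossilised birth–death sampling, or correlated evolution
between proxies — so green tests demonstrate the statistical machinery is
correct and calibrated under its own assumptions, not that those
assumptions hold for real birds. Every generator is bit-reproducible under
a fixed seed (one `numpy` Generator per call).

Problem sizes in the analysis drivers and the acceptance script (450
extant birds for mass, ~70 jaws/strain models per stage, 100-tip trees and
200–500 simulation replicates, 1000–2000 polytomy resolutions) were chosen
as the smallest scales at which the measured quantities are stable against
their Monte-Carlo error; the published study's full samples (8758 birds
with mass data, 10,000 resolutions) are supported by the same code paths
and are exercised by the optional full-data script when its inputs are
present.

## Open design choices

The relative-skull-length formula is typographically ambiguous in its
source; both readings are implemented behind an enum —
`(log₁₀ L)^2.7482 / log₁₀ M` (default) and `2.7482·log₁₀ L / log₁₀ M` —
and neither is asserted as ground truth. The allometric regression
direction is fixed as log-mass on log-length, which reproduces the ≈2.75
exponent. Claw angle uses the full fitted dorsal arc (base-to-tip subtended
angle); exactly collinear or near-infinite-radius fits return 0°. The
interval-profile bin settings, the pFDA λ-selection criterion, and the
posterior-to-likely thresholds are configuration, since their original
values live in deposited scripts rather than printed text.

## Limitations

Mass tiers assume the extant reference sample separates into ordered
groups; heavily overlapping groups yield low J and wide CIs rather than an
error. The pairwise permutation test is calibrated marginally, not
family-wise (a Holm-adjusted view of the p-matrix is available but off by
default). pFDA's LOO reuses the full-sample whitening per λ, slightly
optimistic for tiny samples. BM ancestral states shrink toward the
phylogenetic mean and inherit all BM assumptions; qualitative-diet
reconstruction treats probability columns as independent continuous traits,
which is why renormalisation is needed at nodes.
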
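# Methods

## The mixture model

A tumor-tissue STR profile is modeled as a K-population mixture: one normal
cell population plus K−1 tumor subclones arising from branching clonal
evolution. Loci are independent, alleles within a locus are independent
(Hardy–Weinberg), and the height contributions of the populations are
independent. K is set from the evidence by the maximum-allele-count rule
(K = 2 when no locus shows three or more alleles, else ⌈Lmax/2⌉); because a
tumor sample always contains at least one subclone, K ≥ 2 even for
clean-looking profiles.

The likelihood of the profile under a hypothesis H is the product over loci
of the prior-weighted sum over genotype combinations g = (g_n, g_t,1..K−1) of
the gamma peak-height density (see below). The hypothesis fixes who
contributed the normal genotype: the person of interest (Hp), an unrelated
individual (Hd), or a parent–offspring / full-sibling relative of the POI
(Hd-PO / Hd-FS, via IBD coefficients (0,1,0) and (¼,½,¼)).

## The somatic variant (descent) model

Each subclone genotype descends from the normal genotype slot by slot. One
allele copy is

* retained with probability 1 − φ,
* lost with probability φ·λ (producing pLOH/LOH states, including total locus
  loss),
* replaced by allele a with probability φ·(1−λ)·f(a) over the locus allele
  universe (producing Aadd/Anew states; replacement may regenerate the source
  allele, which merely rescales the retained mass).

φ is the per-locus incidence of somatic STR variants — an *a-priori* input,
taken from published tumor-cohort surveys (colorectal: 7.75–43.41% across
19 loci; loci without a published value get the mean). λ splits a variant
event between loss and replacement; nothing in the published incidence data
fixes it, so it defaults to 0.5 (both variant classes are widely observed)
and is exposed as a parameter. The unordered tumor genotype probability
marginalizes the two ordered slot-to-source assignments, which makes
P(g_t | g_n, φ) a proper distribution over unordered states (unit tests check
normalization to 1 ± 1e−9 under randomized parameters, and that the
synthetic-data sampler is the generative twin of this prior by chi-square).

Enumeration is kept finite by aggregating all alleles not explicitly tracked
into a single Q state carrying the residual frequency mass. Candidate normal
alleles are: observed ∪ POI alleles (Hp), observed ∪ {Q} (Hd unrelated), and
observed ∪ POI alleles ∪ {Q} (kinship hypotheses — the POI alleles must be
explicit for the IBD conditioning to normalize). Tumor states add {Q, LOSS}.
Zero-prior combinations are pruned.

## Peak heights, degradation, dropout

Peak height is gamma distributed with shape 1/ω² and scale μω², where μ is
the expected height of one allele copy at mixture weight 1 (undegraded) and ω
the coefficient of variation. With a shared scale, independent population
contributions add in the shape:

    shape(a) = (1/ω²) · Σ_pop w_pop · n(a, pop) · ε^((size(a) − 90)/100)

w_pop are the mixture weights (w_normal = M_xn; subclone weights sum to
1 − M_xn — the constraint indexes the K−1 subclones), n(a, pop) ∈ {0,1,2} the
copy number, and ε the degradation parameter: the survival probability of a
100 bp stretch under uniform per-base breakage, giving the familiar
"ski-slope" decline of FFPE profiles. ε is initialized from an ordinary
least-squares fit of log mean locus height on mean locus fragment size
(per-base slope s; ε = s¹⁰⁰; p_deg = 1 − s) and refined by maximum
likelihood within (0.1, 1]; degradation is dropped (ε ≡ 1) when the fitted
p_deg ≤ 1e−4, since at that level the factor is indistinguishable from noise
over a 90–450 bp multiplex.

An expected allele with no called peak contributes P(Y < AT), the gamma CDF
at the analytical threshold (default 175 RFU) — dropout needs no extra
parameter. An observed allele carried by no population makes the combination
impossible: drop-in and stutter are deliberately not modeled (stutter is
assumed filtered by the kit protocol; high-template tissue DNA makes drop-in
negligible). The Q allele has no physical size; it is assigned the mean
observed peak size at its locus (kit nominal size if the locus is empty),
which only perturbs its unobserved dropout factor.

## Likelihood maximization

M_xn and φ are never searched. Under each hypothesis, (log μ, ω, ε and — for
K > 2 — a stick-breaking split of the subclone mass) are maximized by bounded
Powell search: log μ ∈ [log(AT/10), log 1e5], ω ∈ [0.05, 1.5], ε ∈ [0.1, 1],
with function tolerance 1e−8 and five deterministic starts (a data-driven
start at μ ≈ median locus total / 2 plus seeded Sobol points). Genotype
priors are independent of these parameters, so enumeration happens once per
(evidence, hypothesis) and each evaluation recomputes only the gamma terms,
vectorized over a flattened combination × allele table. If some locus cannot
be explained by any combination at any parameter values (e.g. a
non-contributor POI under Hp at a three-allele locus), the likelihood is
identically zero and log₁₀ LR = −∞ is returned as a valid exclusion.

The LR decomposes exactly into per-locus factors (log contributions sum to
the total within 1e−6). In the non-contributor driver the Hd-unrelated
denominator does not depend on the POI and is optimized once per M_xn group;
the per-POI numerator uses a single data-driven start, which can only
under-maximize Hp and hence bias non-contributor LRs downward — conservative
for the specificity estimate it feeds.

## Experiment drivers

* **Grid:** LRs over [M_xn ± 0.10] × [φ range], 21 × 21 by default, with
  least-squares fits of log₁₀ LR on each axis. The ±10% confidence interval
  on the pathologist's M_xn is read as ±0.10 absolute (clipped to
  [0.01, 0.99]); pathology percentages are reported in coarse 10% steps, so
  an absolute band matches their granularity.
* **Interval:** 21 LRs over the M_xn interval at per-locus φ, reported as
  min/mean/max — the conservative casework statement.
* **Hd-true test:** random persons of interest drawn from the frequency
  table, scored at the five M_xn group values (min, quartiles, max of the
  interval), reporting the full log₁₀ LR distribution and the fraction below
  zero.
* **Diagnostics:** the gamma Q-Q fit of per-locus total peak heights
  (maximum-likelihood gamma with location 0) and the degradation regression.

## Synthetic data

The generator emulates the study inputs end to end: Dirichlet(1.5) allele
frequencies over 5–10 consecutive integer designations per locus (occasional
".3" microvariants) at the 21 GlobalFiler autosomal loci; Hardy–Weinberg
references; tumor evidence built by sampling subclone genotypes from the
descent model and heights from the gamma law with degradation; Mendelian
PO/FS relatives. Defaults are the study conditions: μ = 1500 RFU, ω = 0.2
(locus totals far above AT at 1 ng input), per-base slope 0.996 (inside the
observed FFPE range p_deg ≈ 0.0015–0.0057), AT = 175 RFU, K = 2, cohort
M_xn spanning 0.1–0.7 (tumor purity 30–90%, 17 cases). The default
*generative* φ is 0.05 per allele slot, reproducing the realized alteration
incidence of colorectal FFPE cohorts (≈ 0.09 altered loci per locus typed;
most samples show 0–3 altered loci of 21, occasionally many more); the much
larger published survey incidences remain the *analysis* prior, mirroring
actual casework. The generator does not emulate stutter, drop-in, inter-locus
balance differences, off-scale peaks, or primer-binding-site null alleles, so
green tests here do not certify behavior of real electropherograms exhibiting
those artifacts.

Scaled problem sizes in the test suite (2–8 cases, 9-point grids, 25 POIs per
group) were chosen so the full suite runs in a few minutes on one CPU; the
acceptance script uses the full design (10–17 cases, 21-point grids, 200 POIs
per group, ≈ 13 minutes). In the non-contributor driver the per-POI numerator
additionally runs at looser Powell tolerances than the default fits; measured
against the tight setting the log₁₀ LR values are unchanged to 4 decimals,
and any residual under-maximization is conservative for the specificity
claim.

## Behavior worth knowing about

* **M_xn trend reversal under complete LOH dropout.** For loci where the
  evidence retains every reference allele, log₁₀ LR increases approximately
  linearly with the assumed M_xn (alternative genotypes under Hd are
  penalized harder as the normal fraction grows; measured r ≈ 0.96–0.995 on
  synthetic true-contributor grids). But a locus with complete LOH whose
  allele fell below AT contributes log gammaCDF(AT; shape ∝ M_xn) to Hp —
  steeply *decreasing* in M_xn — and can reverse the global trend for
  low-purity samples. The published account of the increasing trend is based
  on samples without such loci; we document the reversal as a genuine
  property of the model rather than suppressing it.
* **log₁₀ LR vs φ** is decreasing and close to linear for true contributors
  (typically |r| ≥ 0.95): raising the assumed variant incidence lets
  alternative donors explain mismatches more cheaply. The exception is again
  structural: a mid-purity case whose evidence shows partial-LOH height
  imbalance has a smoothly concave φ-response peaking near the realized
  variant incidence, because at low φ the prior of the true variant-bearing
  combination under Hp grows like log φ and outweighs the denominator
  mechanism. Such cases can push the per-case |Pearson r| down to ≈ 0.8 while
  the response range stays small (≈ 0.2 log₁₀ units over the full φ band).
* **Kinship hypotheses** shrink the LR (LR_true ≥ LR_PO ≥ LR_FS) but leave it
  far above 1 for true contributors: a relative shares alleles, yet the
  evidence-wide fit still prefers the true donor.

## Known limitations

* No subpopulation (θ/F_ST) correction; plain Hardy–Weinberg priors.
* K is qualitative (allele counts only); peak heights are not used to
  estimate copy number, so K can be underestimated.
* The descent factorization (retain / loss φλ / replace φ(1−λ)f(a)) is one
  concrete reading of "tumor allele frequency = population frequency × φ";
  it was chosen so that all observed variant classes receive nonzero prior
  and the conditional distribution normalizes exactly.
* Unseen-allele frequencies are floored at 5/(2N), N = 500 by default;
  surveys with other sizes should pass their own floor.
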
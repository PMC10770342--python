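# Methods notes

## Scope and model

The package adjudicates targeted hotspot-panel variant calls from four
matched sample sources per participant — plasma (cell-free DNA), buffy coat
(leukocyte matched normal), saliva (germline reference independent of blood
lineages) and FFPE tumour — into a per-participant minimal-residual-disease
call, and estimates the association between post-treatment ctDNA positivity
and progression-free survival. The upstream caller (alignment, UID-barcode
consensus, random-forest artifact classification) is out of scope: its
output score is consumed as an input field, and the caller's wording for the
TA count ("second alternative allele") is resolved here as the called
alternative allele's read count.

## Filtering pipeline

Steps run in a fixed order: RF-score gate (< 0.7 removed, boundary kept);
low-VAF gate (< 1 % removed, 1 % kept); germline/CH exclusion; on-target
restriction; ddPCR adjudication; high-VAF gate (> 40 % removed, 40 % kept).
Design choices that were genuinely open:

- **High-VAF gate last, with ddPCR exemption.** The likely-germline > 40 %
  rule is applied after adjudication, and ddPCR-confirmed variants are
  exempt from it, so that orthogonally validated high-VAF calls (up to
  78.4 % in the packaged examples) are retained. This is the only ordering
  under which "confirmed variants are added back" and "likely germline
  removed" can both hold.
- **Origin labels cover the low-VAF pool.** ddPCR confirms a variant's
  *presence*, not its somatic origin, so origin classification runs over
  every score-passing plasma variant including those parked below the 1 %
  gate; the add-back pool is restricted to somatically-labelled keys. This
  prevents a ddPCR-confirmed CH or germline variant from re-entering the
  somatic pool.
- **Missing RF scores are removed** at step 1 (conservative); a `missing_rf
  = "keep"` configuration inverts this.
- **Concordance is exact** on (chrom, pos, ref, alt); no indel
  normalisation or fuzzy matching. Adequate for a hotspot panel with simple
  alleles; a known limitation for indel-rich targets.
- **No saliva sample** makes CH and germline indistinguishable:
  buffy-concordant plasma variants are labelled germline and flagged
  `ch_indeterminate` (they are excluded from the somatic pool either way).
- **Chromosome names compare verbatim**; "chr17" and "17" are different
  sequences unless the caller normalises upstream.

ddPCR positivity is a pure function: ≥ 3 FAM-positive-only droplets AND
≥ 10× wild-type-only control fluorescence, both inclusive (a literal reading
of "at least"); strict (>) variants are available behind a flag. Whether the
ratio compares amplitudes or concentrations is left to the data producer —
the field is an abstract ratio. No Poisson concentration estimation is done:
ddPCR serves only as binary confirmation.

## Concordance and status

Tumour–plasma concordance is computed on post-filter somatic variants only,
pooling a participant's plasma timepoints (deduplicated by variant key)
before the Venn decomposition. Per-participant concordance is
100·shared/union, undefined (no-detection flag) on an empty union.

Post-treatment ctDNA status is positive iff any surviving plasma variant
comes from a sample collected within the window, default 213 days
(7 months × 365.25/12, rounded; configurable). A participant with no
in-window sample is *undetermined* — a third state, excluded listwise from
survival contrasts and reported separately, never conflated with negative.

## Survival machinery

Kaplan–Meier estimation and Cox proportional-hazards fits are backed by
`lifelines` behind the package's own result objects; the test-suite checks
them against independent brute-force risk-set enumeration (exact product-limit
agreement at 1e-12 on random small datasets, partial-likelihood equality on a
hand-checkable six-subject dataset). Ties use Breslow's method by default;
`ties="efron"` switches to an in-package Efron partial-likelihood optimizer
(BFGS with numerically-differenced observed information). Monotone
likelihood/separation is flagged via `converged=False` with a lightly
penalized fallback fit rather than silent divergence. Categorical clinical
covariates enter as dummy codes with a configurable reference level.
Subgroup analysis facets by treatment arm and pathologic complete response,
flags cells with < 2 events as unreliable, and fits KM per ctDNA status plus
a status-covariate Cox model per cell.

## Synthetic cohort generator

The generator emulates the observable conditions of an early-TNBC MRD study
of this design, not raw reads: 130 participants (64 neoadjuvant / 66 adjuvant), pCR in 24/64 NAT
participants, tumour and saliva sequenced for a 60-participant subset, mean
depth 7500×, one post-treatment plasma draw at a median ~55 days. Per
participant, Poisson counts of somatic (mean 0.08, chosen so P(≥1 plasma
somatic variant) ≈ 7.7 %), germline (0.05 ≈ 5 buffy-coat variants per 130),
CH (0.02) and artifact (0.26 ≈ 34 false positives per 130) variants are
placed in a toy 38-region panel. Source presence encodes the origin
definitions (germline: all sources; CH: plasma+buffy, never saliva; somatic:
plasma and/or tumour with probabilities 12:36:24; artifact: plasma only,
30 % jittered off-target). True VAFs are log-normal on the percent scale for
somatic (median 2 %, clipped to 0.1–78.4 %), CH (median 1 %) and artifact
(median 0.7 %, clipped to 0.1–19.4 %) variants, near-normal around 50 % for
germline; tumour VAFs for somatic variants are drawn separately with median
~27 % (tumour fractions exceed plasma fractions). Read counts are binomial
at Poisson depth — a deliberate simplification with no UMI structure,
strand/context error model, or fragment-length signal, so passing tests
demonstrate pipeline logic, not caller-level sensitivity on real reads.
RF scores are Beta-distributed (Beta(8,2) for true variants, Beta(2,8) for
artifacts), optionally clipped; `separable_config()` produces the fully
separated operating point (scores split around 0.7, somatic VAFs inside
3–35 %, perfectly sensitive ddPCR) at which the pipeline must recover the
somatic truth set exactly.

ddPCR assays are emitted for plasma calls with observed VAF in 0.5–1.5 %
(the orthogonal-validation band) plus 20 % of higher-VAF calls; detection
probability for real variants is logistic in log10 true VAF (50 % at 0.3 %
VAF, slope 2), artifacts never confirm. Survival times are exponential with
baseline hazard 2.1e-4/day (≈15 % events by ~2 years in negatives), hazard
multiplied by the true HR (default 14.61, the generator's truth for the
positive group) for ctDNA-positive participants, independent exponential
censoring parameterised by the marginal censoring probability at baseline
hazard, and an administrative cap at day 1600 (~53 months). A censoring rate
of 1 degenerates to everyone censored at day 0.

Clinical covariate marginals (age bands, T stage by arm, node positivity
55 %/27 % by arm, capecitabine in 13/40 of no-pCR NAT) are matched only
marginally; joint structure is not modelled.

## Problem sizes

The default verification runs use: 200-participant separable cohorts for
exact truth recovery; 100 random datasets of n ≤ 30 for product-limit
equality; 200 replicate cohorts of n = 500 (30 % positive, true HR 5) for
Cox bias (±10 %) and Wald CI coverage (90–98 %); n = 1000 with true HR 7 for
the faceted subgroup signal; and n = 2000 single-cohort recovery within
±15 %. These sizes give comfortable Monte-Carlo margins for the stated
bands while keeping the whole suite under a minute of compute.

## Degenerate inputs and numerical choices

Zero total read count makes VAF undefined (error, not 0). Empty call lists
flow through every operation. Conflicting duplicate ddPCR calls for one
(participant, variant) are a data error; agreeing duplicates collapse.
Inverted VAF windows and invalid generator rates raise configuration errors
naming the field. The ledger conservation identity is asserted at the end of
every pipeline run, not only in tests.

## Known limitations

Exact-key concordance (no indel normalisation, no multi-allelic
decomposition); plasma-only detection semantics (tumour/buffy/saliva calls
are evidence, never detections); no clonality or VAF-correlation modelling
between tumour and plasma; no time-varying covariates or competing risks;
the generator's artifact model is distributional, not sequence-context
based. The study-scale clinical hazard-ratio estimates (wide CIs at ~10
positive participants) are not reproducible without the original cohort's
controlled-access data; the package's claims are therefore about pipeline
correctness and estimator calibration, which the test suite computes.
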
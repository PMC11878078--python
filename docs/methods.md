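# Methods

## Cohort and catalog model

The unit of observation is the clinical isolate; isolates group by
patient (three per patient in the packaged cohort) and carry zero or
more integrated Pf prophages referenced against a catalog of distinct
Pf phages. Carriage cells use a small grammar: `ND` or an empty cell
means non-carrier, and multiple prophages in one genome are
`;`-separated. Isolate-level prophage names map to catalog phage ids
through an explicit column, because collapsing near-identical prophage
genomes into catalog entries is a homology analysis whose *result* is
data to this package, not something it recomputes.

Prevalence has two natural denominators and the package exposes both:
`genomes` (default) divides prophage genomes by isolates — 42/75 = 56 %
in the packaged cohort, where three isolates carry two prophages each —
while `carriers` divides carrier isolates by isolates (39/75 = 52 %).
The per-patient carriage histogram is keyed by carried-isolate count
when all patients contributed equally many isolates and falls back to
`all`/`some`/`none` categories otherwise.

Catalog validation enforces the core + accessory = total CDS partition
and flags genome sizes outside 10–15 kb with a warning rather than an
error (integrative Pf genomes cluster tightly in that range, but an
outlier is not impossible). Incomplete defense systems — a single
protein from a clustered system, such as an orphan AbiEii toxin — are
stored with `complete=False`, counted only on request, and excluded
from dPR by default. Defense strategies (Abi, restriction, TA, Sie)
come from a fixed lookup of the systems known to occur on Pf phages;
anything else is `unknown`. The core/accessory CDS classifier is a
case-insensitive keyword matcher over the conserved Pf gene products
(repressor/pf4r, excisionase XisF4, ssDNA-binding protein, coat
proteins CoaA/CoaB, Zot domain, replication initiator, integrase IntF)
with accessory overrides for regulator annotations ("negative
regulator", "Arc family") that contain core keywords; unrecognized
descriptions default to accessory with a debug-level notice. This is an
annotation-text approximation of homology-based classification and is
only as good as the annotations it is fed.

## Infection calling

A pair (isolate, lytic phage) is phenotyped in two stages mirroring the
bench workflow:

1. **Spot test.** Positive only when *all three* replicates show a spot;
   clear and turbid spots both count. Partially spotted triplicates are
   negative.
2. **Infection curve**, run only for spot-positive pairs (a negative
   spot is final: Resistant). The uninfected control defines the
   exponential window: the replicate-mean log-OD is smoothed with a
   3-sample rolling mean, differentiated, and the window is the
   contiguous interval around the derivative peak where it stays at or
   above 50 % of its maximum (`threshold_frac`, configurable). Calling
   requires at least 8 time points spanning at least 12 h and growth of
   at least 2× the initial OD. Each replicate is summarized by its mean
   OD inside the window; a one-sided unequal-variance (Welch) t-test
   asks whether infected < control. Productive infection requires both
   p ≤ α (default 0.05) and a relative mean reduction ≥ 10 %
   (`min_reduction`); the reduction floor guards against trivially
   significant offsets between low-variance replicate sets. Identical
   constant replicates are defined to give p = 1.

Final call: Sensitive iff spot-positive **and** productive. A positive
spot without growth suppression (abortive infection, lysis-from-
without) is Resistant. The underlying assay description specifies
neither the test, α, nor the replicate threshold for "significantly
lower"; the Welch test with the 10 % reduction floor is this package's
choice and both knobs are configurable.

## Association statistics

The analysis unit is the interaction (isolate × phage), matching how
such challenge panels are tabulated; isolate-level variants (an isolate
is resistant iff it resists every phage) sit behind `unit="isolate"`.

* **Contingency.** Carrier/non-carrier × R/S counts; Fisher's exact
  two-sided p (point-probability rule) is the headline test, Pearson χ²
  (1 df, continuity correction off by default) reported alongside.
  Both are delegated to scipy; the test suite verifies Fisher against
  an exhaustive hypergeometric enumeration in exact integer arithmetic.
* **Conditional probabilities.** P(Pf|R) = a/(a+c) etc. from the
  contingency counts; a conditional is flagged undefined rather than
  silently NaN when no interaction with that outcome exists.
* **Differential probability (dPR).** Restricted to interactions of
  Pf-carrier isolates; an interaction belongs to system DF when its
  isolate carries a Pf phage encoding DF. The default orientation is
  dPR = P(R|DF) − P(S|DF) over DF interactions, which is identically
  2f − 1 for f the resistant fraction of DF interactions and reaches
  ±1 for systems whose interactions are uniformly resistant/sensitive —
  rare systems included. The literal conditional-on-outcome form
  P(DF|R) − P(DF|S) is available as `orientation="system_given_outcome"`;
  note it cannot reach 1 for a system carried by a small minority of
  carriers, which is why it is not the default. Per-system Fisher
  p-values (system × outcome among carrier interactions) are attached;
  no multiplicity correction is applied by default, with
  Benjamini–Hochberg (`adjust="bh"`) opt-in.
* **Regression.** Ordinary least squares of per-isolate resistant-phage
  count on whole-genome defense-system count (Pf-encoded systems
  included in the count); r² = 1 − SSres/SStot, two-sided slope p from
  t with n − 2 df. Degenerate designs (constant x, n < 3) are errors.

## Synthetic cohort generator

The generator's defaults encode the study design: 25 patients × 3
isolates; per-patient carriage patterns (all, two of three, one of
three, none) drawn with probabilities 0.40/0.12/0.12/0.36; carrier
isolates of one patient share a single catalog phage (Pf phages cluster
by patient and sequence type, with cross-patient sharing arising only
from drawing the same catalog row); whole-genome defense-system counts
uniform on 5–19, padded beyond the Pf payload with background systems
from a fixed name pool; 4 lytic phages named after the study's panel.

Resistance is a latent Bernoulli per interaction:
P(resist) = logit⁻¹(β₀ + Σ effects of the isolate's systems against
that phage). The baseline β₀ = 0.8 gives non-carriers a ≈ 69 % resistant
fraction, the scale observed in such panels. Default per-system effects
follow strategy: superinfection-exclusion systems protect a single
phage (+3 log-odds on the first phage, standing in for
receptor-specific defense), abortive-infection systems protect broadly
(+2 on all phages), TA/restriction systems weakly (+1). These defaults
exist to give the machinery realistic structure; no quantitative
per-system effect sizes are known, so none of these values is a
biological estimate.

Growth curves: controls follow the logistic
OD(t) = K/(1 + ((K − OD0)/OD0)e^(−rt)) with K = 1.2, r = 0.8 h⁻¹,
OD0 = 0.05, sampled every 0.5 h for 24 h, plus Gaussian noise
(σ = 0.01, floor-clipped). Sensitive wells track the control until a
lysis onset placed a quarter of the way into the control's exponential
window — detected on a horizon-independent reference grid, so a horizon
that ends before the exponential phase is rejected — then decay
exponentially (rate 1.5 h⁻¹) toward a lysis floor of 0.08, and receive
all-clear spot triplicates. Resistant wells grow like controls and
receive all-negative or partially spotted (still negative) triplicates.
Each stage consumes a `numpy` Generator seeded from `(seed, stage)`,
giving bit-identical regeneration per stage.

What the simulator does *not* emulate: within-host evolution, phage
co-infection or titer dynamics, receptor-level mechanism, correlated
noise, or plate effects. Passing end-to-end tests therefore show the
pipeline recovers its own generative model under realistic noise — not
that it would be unbiased on any particular real data set.

## Numerical and design notes

* Problem sizes in the test suite are the study's own scale (75 × 4
  grids; 10 seeds for end-to-end recovery; 200 paired-seed replicates
  for dPR monotonicity; 1,000 null interactions for the caller's
  false-positive rate), which keeps the default run to well under a
  minute while leaving the Monte-Carlo tolerances meaningful.
* Fisher's exact test is checked exhaustively against enumeration for
  all 2×2 tables with total ≤ 28 plus a seeded sample of tables with
  totals up to 40; the enumeration uses integer arithmetic so ties in
  the point-probability rule are exact.
* The attB distribution is reported unrounded under both weightings
  (per phage: 4/7/1 of 12; per isolate: 19/20/3 of 42); no rounded
  percentage is asserted anywhere.
* Byte-stable writers (fixed column order, `\n` endings) make
  write → load the identity on validated objects, which the suite
  exercises as a round-trip property.
* Packaged fixtures are guarded by a SHA-256 manifest so the
  `reproduce-paper` command can distinguish code regressions from
  edited data.

## Limitations

* The cohort fixture's per-isolate defense-repertoire columns record
  only the systems contributed by carried Pf phages — a documented
  lower bound, since whole-genome repertoires per isolate are not part
  of the packaged tables. The regression operation is therefore only
  meaningful on data (real or simulated) that carries true whole-genome
  counts.
* dPR is descriptive, not causal: systems co-occurring on one phage
  (e.g. a TA and an Abi system on the same prophage) are statistically
  indistinguishable, and dPR inherits any confounding between carriage
  and lineage.
* The keyword CDS classifier approximates homology-based core/accessory
  assignment and misclassifies products whose annotations use synonyms
  outside its list.
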
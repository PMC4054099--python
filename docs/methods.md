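# Methods

## Model and assumptions

The cascade rests on three empirical regularities of cancer genomes:
driver mutations act through genes that are expressed in the tumour
where they occur; loss-of-function drivers are enriched in truncating
and consensus-damaging missense events; and genes with proven driver
roles differ systematically from the average human gene — they are
broadly expressed, encode central, highly connected proteins, interact
with other cancer proteins, arose early in evolution or with the
metazoan/vertebrate radiations, and tend to remain single-copy. The
cascade treats each regularity as a filter and nominates the mutated
genes of a tumour that survive all of them. It is a prioritization
device, not a significance test: no p-value is attached to a driver
call, and the output is meant to be read together with the per-gene
trace that records the first failing stage.

Two conventions matter for reproducibility:

- **Expression call.** A gene is expressed in a context iff
  `#(probes with detection P < alpha) >= #probes / 2`, evaluated in
  exact arithmetic (2 of 3 probes are required for a 3-probe gene);
  alpha defaults to 0.05 and the inequality on *P* is strict.
  Contexts without probes for a gene yield `no_data`, which removes
  the gene from numerators *and* denominators of fraction comparisons
  — absence of data is never treated as silence.
- **Betweenness.** Unnormalized and endpoints-excluded: for node *v*,
  the sum over unordered pairs {s, t}, s ≠ v ≠ t, of the fraction of
  shortest s–t paths through *v*. This is the convention under which
  a 25% hub cut on a ~13,500-protein interactome lands near raw
  thresholds of degree 14 and betweenness ~9,200. Hub cuts are
  empirical quantiles with NumPy's linear-interpolation rule, and hub
  membership requires strictly exceeding *both* cuts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_detection` | 0.05 | probe detection threshold (probability) |
| `sift_thr`, `polyphen_thr` | 0.95, 0.9 | strict lower bounds for a damage vote (scores in [0,1], damage-oriented) |
| `length_thr_bp` | 4450 | top-5% coding-length cut (bp); shorter genes bypass the recurrence check |
| `max_cancer_types_for_long` | 4 | long genes retained iff mutated in ≤ 4 cancer types ("fewer than five") |
| `long_gene_rule` | `methods` | `results` switches the long-gene cut to ≤ 5 types (the two printed readings differ by one) |
| `hub_quantile` | 0.75 | quantile defining central hubs |
| `min_systems_true` | 2 | properties required of 4; the combination rule is genuinely open, and 2-of-4 is the package's choice — all-four would reject most real drivers (few are hubs), any-one is too permissive |
| `require_known_expressed` | true | triage needs the known gene mutated *and* expressed; switchable because the two natural readings differ |
| `exempt_known` | {} | known genes re-admitted at triage so the cascade can call them (tumour-suppressor recovery experiments) |

Damage-predictor scores are consumed, never computed; missing scores
count as negative votes so the 2-of-3 denominator never shrinks. SIFT
inputs are damage-oriented; canonical SIFT (damaging ≈ 0) is converted
as 1 − score behind the `sift_raw` reader flag.

Statistical choices: the 2×2 comparison uses the 1-df chi-squared
without continuity correction (a `yates` flag exists); class
enrichment uses the standard two-sided Fisher test with the
conditional MLE odds ratio (undefined on a zero margin); distribution
comparisons use the two-sided rank-sum test — exact null when the
pooled sample has no ties, tie-corrected normal approximation without
continuity correction otherwise, so identical groups give p = 1
exactly and complete separation at n = m = 5 gives the exact tail
2/C(10,5). Shapiro–Wilk p-values are reported alongside for
transparency and never switch the test. Raw p-values are reported
throughout; no multiple-testing correction is applied across contexts.

The length trend regresses the per-recurrence-level **median** coding
length on recurrence level (ordinary least squares); medians make the
fit robust to the handful of extremely long genes at each level. A
`fit_all_points` mode fits every gene instead — both are provided
because the choice of fit target is genuinely open.

shRNA scores: `log2(mean cell-line replicates / mean pool replicates)`
per probe; a non-positive replicate mean makes the ratio missing
rather than clamped, since clamping would bias the per-gene
max-collapse. "Top-scoring" is the maximum ratio (increased
proliferation upon silencing is the readout of interest); a
`direction="min"` mode supports depletion analyses. Input scores are
consumed as given; no re-normalization is applied by default.

## The synthetic cohort generator

`SyntheticConfig` defaults define the study conditions used by the
tests and the acceptance script: 100 tumour samples over 2,000 genes,
~2% known cancer genes, 90% of samples carrying a known
mutated-and-expressed driver, two planted drivers per clean sample,
and a passenger rate of 1.8 × 10⁻⁵ per coding bp (≈ a few dozen coding
mutations per exome). Coding lengths are log-normal
(median ≈ 1.3 kb, σ = 0.75), putting the 95th percentile near the
4,450 bp cut. Passenger hits are Bernoulli with probability
proportional to coding length, which is what makes the
length-recurrence trend emerge. Expression is generated at the probe
level: expressed gene/sample pairs draw detection p-values from
Uniform(0, α), silent pairs from Uniform(α, 1), so the call rule
recovers the planted state deterministically. The interactome is a
preferential-attachment graph over 70% of genes (heavy-tailed
degrees). The screen draws positive abundances in log2 space with
planted suppressors shifted upward by `suppressor_effect` (default
+1) in cell-line replicates, noise σ = 0.3.

Planted drivers are constructed to pass every stage: expressed in
their sample, frameshift-mutated (a `missense` mode exercises the
2-of-3 consensus instead), shorter than the length cut, of metazoan
origin and single-copy (hence ≥ 2 of 4 systems properties regardless
of network position). Two deliberate simplifications keep the
construction exact: known genes never receive passenger mutations, so
triage discards exactly the constructed fraction of known-driver
samples; and clean samples without planted drivers receive one
synonymous anchor mutation in a gene with expression data, so they are
retained at triage without ever producing a driver call.
`fraction_clean_with_driver` < 1 generates cohorts where only part of
the analysed tumours contain a recoverable driver.

What the generator does **not** emulate: real mutation spectra and
signatures, correlated expression across tissues/samples, batch
effects, probe cross-hybridization, network ascertainment bias toward
well-studied genes, and hairpin off-target effects. Passing tests
therefore demonstrate the correctness and internal consistency of the
cascade under its stated assumptions — expressed, damaging, short,
cancer-gene-like drivers are recovered with sensitivity 1.0 — not its
error rates on real tumours, where the assumptions hold only
approximately. In particular, damaging cancer-gene-like passengers are
co-called by design; the cascade bounds, but does not eliminate, false
positives.

## Numerical and degenerate-input conventions

- Breadth classes: housekeeping iff `n_expressed >= ceil(0.98 * n_total)`
  (107 of 109), tissue-selective iff strictly below `0.25 * n_total`
  (≤ 27 of 109); both fractions configurable.
- log2 fraction ratios are undefined (None, flagged) when either
  fraction is zero; the 2×2 counts are still returned. An empty group
  after `no_data` exclusion flags the whole comparison undefined
  rather than raising.
- A 2×2 table with a zero column margin has chi-squared 0 and p 1
  (identical proportions), avoiding the zero-expected-cell failure.
- Exact duplicate mutation rows are dropped at read time; a gene
  mutated several times in one sample counts once for recurrence and
  is damaging if any event is.
- Reports sort all keys and lists, so identical inputs and
  configuration produce byte-identical output.

## Problem sizes

Unit and property tests run on graphs of ≤ 12 nodes, cohorts of 15–30
samples × 150–300 genes, and all brute-force oracles (shortest-path
enumeration, hypergeometric enumeration) on inputs small enough for
exhaustive checking. End-to-end checks use the default 100 × 2,000
cohort; the reference-fraction check uses 318 samples × 300 genes.
The full suite completes in well under a minute; the acceptance script
in about ten seconds.

## Known limitations

- Gene identifiers are opaque, case-sensitive strings; no alias or
  liftover handling.
- The recurrence reference (`n_cancer_types_mutated`) is a consumed
  annotation, not recomputed from a pan-cancer corpus.
- The interactome merge is plain union + deduplication of edge lists.
- Fisher's test is the standard two-sided conditional test; the
  "one degree of freedom" sometimes attached to it in the literature
  has no meaning for an exact test and is ignored.
- No pathway assignment, predictor re-implementation, or CEL-file
  processing; detection p-values and predictor scores are inputs.
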
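# Methods

This note records the model behind each component, the defaults and their
rationale, the numerical conventions, and known limitations. API names are in
parentheses.

## In-silico digestion and the peptide index (`digestion`)

**Model.** Trypsin cleaves the peptide bond C-terminal to lysine (K) or
arginine (R). The proline rule — no cleavage when the next residue is P — is
on by default because it matches observed tryptic behavior; it can be disabled.
A digest with `m` missed cleavages is the set of concatenations of 1..m+1
consecutive fully-cleaved fragments. Peptides outside the length window are
discarded *after* window construction, so a short fragment still participates
in longer missed-cleavage peptides.

**Parameters.** `max_missed_cleavages=2` (typical search-engine setting),
`min_length=6` / `max_length=50` (shorter peptides are rarely identifiable,
longer ones rarely observed), `proline_rule=True`, `il_equivalent=False`
(isoleucine and leucine are isobaric; enabling the option canonicalizes I→L
for matching, which is the conservative choice when uniqueness claims matter).

**Coordinates.** 1-based inclusive start/end, matching how protein
modification sites are conventionally written (e.g. K(160)).

**Uniqueness classes.** `isoform_unique` (occurs in exactly one database
isoform), `gene_unique` (all occurrences within one gene; superset of
isoform_unique), `multi_gene`, and `unclassified` for peptides containing X.
Classes are properties of the *database*, so they change if the database does;
the index stores the digest parameters it was built with.

**Degenerate inputs.** Empty sequences yield no peptides. FASTA headers must
be `>accession|gene|variant_label`; parse errors report the offending line
number. Duplicate accessions are an error. Sequences are uppercased and a
trailing `*` (stop codon) is stripped.

## Identification confidence and FDR (`confidence`)

**Model.** Each PSM carries a posterior probability that the match is correct.
For an accepted set, the expected number of false matches is `Σ(1 − p_i)`, so
`estimate_fdr = mean(1 − p_i)`. This is exact when the probabilities are
calibrated; the synthetic generator produces calibrated scores precisely so
this estimator can be tested against realized false fractions.

**Threshold.** The default acceptance threshold is probability ≥ 0.97, which
on typical score distributions yields FDR in the few-per-thousand range.
Decoy PSMs are never accepted regardless of score.

**Cross-check.** `target_decoy_fdr = #decoys ≥ t / max(1, #targets ≥ t)`
assumes one decoy per target (reversed sequences). A degenerate denominator
(no targets above threshold) triggers a warning and returns the capped ratio.

**Numerics.** `estimate_fdr` on an empty set is an error, not 0 — an empty
accepted set has no defined FDR.

## Spectral-count quantification (`quant`)

**Model.** The spectral count of a protein is proportional to its abundance
*relative to the mixture*. Assignment policies: `assigned_column` (trust the
search engine's protein assignment), `gene_level` (peptides are re-mapped
through the index; multi-gene and unclassified peptides are dropped and
accounted for), `unique_only` (isoform-level, isoform-unique peptides only).

**Normalization.** Each sample is scaled so its total equals the mean total
across samples (`factor = mean(totals)/total_s`). Totals are computed from
*all input PSMs* of the sample, not just mapped ones, so dropping unmappable
peptides does not bias between samples. Normalization conserves the grand
total exactly (tested to 1e-9).

**Fold change and test.** `(norm_b + 0.5) / (norm_a + 0.5)`; the 0.5
pseudocount keeps zero-count entities finite and shrinks low-count folds.
Significance is the Fisher exact test on
`[[a, total_a − a], [b, total_b − b]]` using raw counts (the test needs
integer events, not normalized values). Up-regulation = fold ≥ 2 and p ≤ 0.05
by default.

**Compositional caveat.** Because counts are relative, a protein that becomes
a large fraction of one sample inflates that sample's total and compresses its
own and every other protein's normalized fold (demonstrated in
`examples/03_spectral_quant.py`). Absolute fold recovery is only expected when
the changed proteins are a small share of the mixture; the raw count ratio is
reported alongside for that reason.

**Two-model comparison.** `compare_models` computes per-model up-regulated
sets and partitions their union into `common_up`, `model1_specific`,
`model2_specific`.

## Hydroxylysine mapping and occupancy (`hydroxylation`)

**Model.** Hydroxylation adds +15.9949 Da. A modification matches iff
`|delta − 15.9949| ≤ 0.01` *and* the modified residue is K; the residue check
is essential because methionine oxidation has the identical delta. Peptide
position `j` in an occurrence starting at `s` maps to protein position
`s + j − 1`.

**Occupancy.** `percent = 100 × modified / denominator`. Two denominator
policies: `all_psms` (all accepted spectra assigned to the protein — the
field-standard "hydroxylation status" of a protein) and `k_containing_psms`
(only spectra whose peptide contains K — the denominator under which a
per-event planted modification probability is directly recoverable; used for
recovery validation). A zero denominator yields `percent = None` ("undefined"),
never 0 or an exception. Counting spectra (with duplicates) is the default;
`distinct_peptides=True` switches the unit to unique peptide sequences.

**Ambiguity.** Site inventories skip multi-gene peptides and report how many
were skipped; sites observed via multiple isoforms are flagged rather than
silently merged across coordinates.

**Comparison.** `compare_status` returns the percentage-point difference and
a Fisher exact p-value on the two modified/denominator tables.

## Variant-specific peptide evidence (`variants`)

A peptide supports a specific isoform only when its occurrence set within the
gene is *exactly* that isoform — computed against the full database, so adding
isoforms can only shrink the specific set (monotonicity is tested). A variant
is `supported` when at least `min_peptides` (default 1) of its specific
peptides are observed in accepted PSMs. `segment_overlap` labels a peptide
with the annotated segments (shared backbone / variant-private) it overlaps by
at least one residue, which distinguishes junction-spanning evidence from
fully-private evidence.

## 2^−ΔΔCt qPCR quantification (`qpcr`)

`ΔCt = Ct_target − Ct_reference` per well; the group fold change is the
geometric mean `2^−(mean ΔCt_group − mean ΔCt_control)`. The geometric mean is
the natural choice because Ct is a log2-scale quantity; the arithmetic mean of
per-well folds is reported only on request and is always ≥ the geometric mean.
Significance is a two-sided Welch t-test on ΔCt (unequal variances — biological
groups rarely share variance). The estimate is invariant to constant shifts of
the reference Ct (tested to 1e-12). Degenerate case: both groups with zero
variance yield p = 1.0 when means are equal, NaN otherwise, flagged via
`zero_variance`. Ct values must be finite and positive.

## Synthetic-data generator (`simulate`)

**What it emulates.** A four-group liver study (control, fibrotic, tumor,
adjacent) over gene families with a shared backbone and K-flanked
variant-private segments; Poisson spectral counts per isoform per group with
planted tumor fold changes (defaults cycle 3, 6.8, 10.8, 32.8× — the range
seen for matrix proteins in diseased liver); per-spectrum hydroxylation events
at planted occupancies (defaults cycle 94%, 33%, 15%, 5%); calibrated PSM
posteriors (correct ~ Bernoulli(p), so reported probabilities are exactly
calibrated by construction); reversed-peptide decoys with low scores; and ΔΔCt
plates where `ΔCt = 7.0 − log2(fold) + N(0, 0.3²)`.

**What it does not emulate.** Peptide detectability bias (peptides are drawn
uniformly from the 0-missed-cleavage digest), chromatographic/run-order
effects, shared-peptide inference ambiguity beyond what the sequences
themselves create, partial modification site localization error, and qPCR
efficiency ≠ 2.

**Determinism.** All draws flow through one `numpy` Generator seeded from the
config; identical configs produce byte-identical output files.

## Pipeline and CLI (`pipeline`, `cli`)

`run_pipeline(PipelineConfig)` runs filter → index → quantify → PTM → variants
→ qPCR → compare and writes TSVs plus `summary.json`. Config is a dataclass,
loadable from JSON with keyword overrides winning (JSON chosen over YAML to
avoid a dependency; the structure is flat enough that JSON costs nothing).
Every spectrum is accounted for — `input = decoys + below_threshold + assigned
+ dropped` is asserted, and failures raise `PipelineError` naming the stage.
The `matricount` CLI is a thin `click` wrapper exposing the same stages; it
exits nonzero with the stage name on error.

## Validation strategy

Components are tested against independent oracles, not reimplementations:
digestion against brute-force substring enumeration, Fisher p-values against
exact hypergeometric arithmetic in rational numbers, FDR against realized
false fractions on calibrated scores, and every estimator against planted
ground truth from the generator. Occupancy recovery is validated under the
`k_containing_psms` policy (the policy matching the generator's per-event
semantics) and assessed pooled across planted occupancy levels, since the
per-level sampling error at n = 500 spectra is comparable to the tolerance
band. Property-based tests (hypothesis, derandomized) cover reconstruction
and monotonicity invariants.
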
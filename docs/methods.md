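# Methods

## The e-Northern model

An EST library is a fixed-size collection of single-pass cDNA reads from
one tissue; a gene's read count, rescaled to a per-million basis (TPM),
is a digital expression measure. The e-Northern procedure compares such
TPM values for a gene panel across one tissue of interest (here,
mammary) and two reference tissues (skin — the mammary gland's
ontogenetic relative — and muscle as an unrelated control).

Two statistics are derived per gene, with all TPMs as non-negative
integers:

- percent mammary transcript abundance,
  `pct(x) = 100 · TPM_ma(x) / Σ TPM_ma`, where the sum runs over every
  gene in the panel. Including incomplete-profile genes in the
  denominator is deliberate: the quantity is "share of the panel's
  mammary transcripts", and a gene with missing skin or muscle data
  still contributes mammary ESTs. (The bundled panel's printed
  percentages are consistent only with this convention.)
- the relative expression coefficient,
  `E_r = TPM_ma / √(TPM_s · TPM_mu)`. The geometric mean of the two
  references makes E_r a ratio of like dimensions, symmetric in the
  references, and exactly multiplicative: scaling all three TPMs by a
  constant leaves E_r unchanged, so the statistic is insensitive to the
  overall sequencing depth of the compared libraries.

Classification uses a twofold rule with inclusive bounds: UP iff
`TPM_ma > TPM_s` and `E_r ≥ up_threshold` (default 2); DOWN iff
`TPM_ma < TPM_s` and `E_r ≤ down_threshold` (default 0.5); otherwise
NOT_DIFFERENTIAL. The twofold default is a screening convention, not a
significance statement: no sampling-error model or multiple-testing
correction is applied, which is faithful to how EST-profile screens were
used. The extra `TPM_ma > TPM_s` guard means a gene can clear the E_r
bar purely through low muscle expression and still not be called UP
(e.g. a (194, 324, 17) triple with E_r ≈ 2.6 stays NOT_DIFFERENTIAL).

### Definedness and exclusion

- A gene's EST profile is *complete* iff all three tissue TPMs are
  positive; incomplete genes are EXCLUDED from classification, since a
  zero TPM in EST data is indistinguishable from an unsampled tissue.
  On the bundled 45-gene panel this reproduces the published 22/23
  complete/incomplete split exactly.
- E_r is undefined (reported "—") when either reference TPM is zero; a
  zero mammary TPM with positive references gives E_r = 0.
- The mammary/skin ratio is reported only when both TPMs are positive.
  A zero numerator is dashed out rather than reported as 0, matching
  the tabulation convention of the reference data set (which prints "—"
  for such genes while still printing E_r = 0); a zero ratio carries no
  fold information.
- Percent abundance over a panel whose mammary column is all zero is an
  error (undefined denominator), not a table of zeros.

### Rounding

Derived values are displayed rounded half-away-from-zero to 3 decimals
(configurable); every threshold comparison uses the unrounded value, so
calls can never depend on display precision. Output TSVs render
undefined values as an em-dash, and re-reading an output table recovers
the integer TPM columns exactly.

### Stage comparison

When adult- and young-stage TPMs are supplied, a gene is flagged
adult-preferential iff `tpm_adult > min_fold · tpm_young` (strict;
ties are not preference). `min_fold` defaults to 1.0 because the
procedure as published states no fold margin for the stage comparison;
users wanting a stricter call can raise it. The bundled panel carries no
stage columns (those values were never published), so the operation is
provided but exercised only on synthetic inputs.

## Network summarization

Interaction networks are undirected graphs over gene symbols with a
combined confidence score in [0, 1] per edge plus optional
evidence-channel scores (coexpression, experiments, database,
textmining, neighborhood, fusion, cooccurrence), the dialect of a STRING
tab-separated export. Reversed duplicate rows merge keeping per-score
maxima; self-loops are rejected. Operations: restriction ("purge") of
the network to a gene panel — genes unknown to the network are retained
as isolated nodes and reported, never dropped silently; hub ranking by
raw degree after discarding edges below a combined-score cutoff
(descending degree, alphabetical tie-break; no fancier centrality is
used because hub claims at this panel size do not support one);
isolated-node detection; connected components (largest first); and
single-channel filtering, where an edge lacking the channel counts as
score 0.

The default score cutoff is 0.4 — the historical "medium confidence"
convention for combined scores — and is an explicit, documented
assumption; exports do not embed the cutoff they were generated with.

The bundled `string_synthetic.tsv` is a hand-curated, synthetic edge
list over the 45-gene panel for demonstrations and plumbing tests. It
imitates the schema and the qualitative topology expected of this panel
(regulator hubs, a sphingolipid cluster, panel genes with no
within-panel partners) but is **not** interaction evidence; the database
version behind the original analysis is retired, so no real export can
serve as ground truth here. Correctness of the graph operations is
established against brute-force oracles (per-node edge counting,
transitive-closure components) on random graphs of ≤ 12 nodes, not
against this fixture.

## The EST-library simulator

`simulate` emulates the sampling process that produces EST-derived TPM
tables. Given per-gene base expression proportions (shared by skin and
muscle) and per-gene mammary fold multipliers, the mammary proportions
are `base · fold`, renormalized. Per tissue, gene counts are a single
multinomial draw at that tissue's library size — multinomial rather than
independent Poissons because an EST library is a fixed-size draw, which
gives exact count conservation; at these scales the difference is
negligible. TPMs are `round(1e6 · count / library_size)`
(half-away-from-zero, to integers), reproducing the coarse quantization
of real EST TPMs: at the default 34,000-read library every nonzero TPM
is a near-multiple of 1e6/34,000 ≈ 29.4, the granularity visible in the
bundled panel (29, 59, 88, 118, …). The 34,000 default is an inference
from that granularity, not a claim about any particular UniGene library.

Truth labels mirror the classifier's convention: fold ≥ 2 is a true UP
gene, fold ≤ 0.5 a true DOWN gene, else null. Note the renormalization
means a fold-f gene's asymptotic E_r is `f / (1 + Σ_i (f_i − 1) p_i)`,
slightly below f when other genes are also upregulated; tests account
for this. Randomness is a single numpy `Generator` seeded with
`(seed, replicate)`, so every replicate is independently reproducible
and no global state is involved.

`recovery_report` scores classifier output against the truth: a
truth × status confusion matrix with EXCLUDED as its own column (an
exclusion is not a miscall), and one-vs-rest sensitivity/specificity per
truth class (UP→UP, DOWN→DOWN, null→NOT_DIFFERENTIAL).

### What the simulator does and does not emulate

It captures fixed-size multinomial sampling, TPM quantization, and
tissue fold-change structure. It does **not** model EST sequencing
error, clone-library normalization bias, 3′ sampling bias, or
between-library biological variability; all skin/muscle differences in
real data are absent (both sample the same base proportions). Passing
recovery tests therefore show the classifier recovers multinomial
sampling structure at EST scale — not that real EST profiles meet these
error rates.

### Calibration conditions

The recovery acceptance check runs 200 replicates of a 100-gene panel
at 34,000 reads per tissue with base proportion 1e-2 per gene and five
genes at mammary fold 8: fold-8 genes must be called UP in ≥ 95% of
gene-replicates and null genes in ≤ 5%. These sizes keep each replicate
at a few multinomial draws, so the whole check runs in seconds while the
Monte-Carlo error on both rates is well under a percentage point. The
null-calibration property (false-UP rate shrinking with library size) is
asserted over library sizes 1e3–1e5 with a 3× Monte-Carlo-standard-error
margin on the monotonicity comparisons.

## Interfaces

TSV in, TSV out (UTF-8, tab-delimited, header row required; em-dash only
in derived output columns). Gene symbols are used verbatim as given in
the input table — the bundled panel keeps its historical symbols (ADFP,
ASAHL, LASS2) — with `GENE_ALIASES` mapping them to current HGNC names
(PLIN2, NAAA, CERS2) for joining against modern network exports. The CLI
(`enorthern run | simulate | network`) is a thin layer over the library;
all outputs land in `--out-dir`, logs go to stderr with stage names, and
a failed run writes no partial outputs.

## Known limitations

- The tissue set of the core statistics is fixed to exactly one target
  and two reference tissues (column names are remappable in the
  reader); E_r is defined for that triple only.
- EST TPMs are treated as exact integers; no uncertainty is propagated,
  by design of the screening rule.
- The behaviour at `TPM_ma = TPM_s` with extreme E_r is a documented
  default (NOT_DIFFERENTIAL), as the published rule pair is silent
  there; one row per gene is assumed (upstream duplicate EST-profile
  entries must be resolved before tabulation).
- Network conclusions are only as good as the supplied edge list; the
  bundled one is synthetic.
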
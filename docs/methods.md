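# Methods

This note documents the statistical models, the defaults and why they were
chosen, what the simulator does and does not emulate, and the design choices
made where more than one reasonable definition existed.

## PSI estimation

PSI is the length-normalised inclusion fraction
`(I/lI) / (I/lI + S/lS)` computed from inclusion (`I`) and skipping (`S`)
junction reads with effective junction lengths `lI`, `lS`. Effective
lengths enter because the inclusion isoform of a skipped exon offers two
junctions for reads to land on while the skipping isoform offers one; the
simulator assigns per-type lengths (SE 98/49, MXE 98/98, A5SS/A3SS 98/49,
RI 147/49, in nt of mappable junction span) so this normalisation path is
exercised non-trivially.

A sample is *uninformative* for an event when `I + S < min_reads`
(default 10). Missing count fields ("NA") are missing samples, never zeros:
zero reads at adequate library depth is information, absence of the
measurement is not. Uninformative PSI values are excluded from group means,
permutation and burden statistics.

## Differential splicing

ΔPSI is the difference of group mean PSI over informative samples
(case − control; negative = exon exclusion in cases). The test is a
two-sided permutation test on per-sample PSI:

- exhaustive over all `C(n, n_case)` label assignments when that number is
  ≤ 10,000 (the p-value is then exact, with resolution `2/C(n, n_case)` for
  a symmetric two-group design);
- otherwise Monte-Carlo with `n_perm = 9,999` draws and add-one smoothing
  `p = (1 + #{|T*| ≥ |T|}) / (n_perm + 1)`, so the smallest attainable p is
  10⁻⁴. A seed is mandatory on this path and is recorded in output
  headers; permutations are shared across events with the same
  informative-sample pattern, which is standard and keeps the test exact
  per event.

Ties in the permutation distribution are counted into the tail with an
absolute tolerance of 10⁻¹² on |T|, which makes the test invariant to
floating-point noise in the group-mean difference.

The permutation test is a deliberate, documented stand-in for count-level
likelihood-ratio tests used by upstream callers: it is distribution-free,
exact at small n, and preserves the downstream decision rule. The cost is
power at very small group sizes — with 3 vs 3 samples the smallest
achievable p is 2/20 = 0.1, so no event can pass FDR < 0.05. This is a
property, not a bug: the null-calibration study (below) runs at 3 vs 3 and
correctly flags nothing, while the recovery studies use a 21-vs-8 design
(typical of a human case/control cohort) where the Monte-Carlo path has
ample resolution.

FDR control is Benjamini–Hochberg. The default scope is *within each event
type* (SE, MXE, A5SS, A3SS, RI), mirroring the per-type output files of
junction-count event callers whose consumers typically correct per table; a
`joint` scope is available because the choice is genuinely open and changes
borderline calls.

An event is **mis-spliced** when `|ΔPSI| > 0.1` and `FDR < 0.05`, both
strict inequalities, both configurable. A gene is mis-spliced when ≥ 1 of
its events is flagged; the gene universe for enrichment is every gene with
≥ 1 FDR-evaluable event.

**Microexons** are SE events whose alternative exon is 3–33 nt long,
inclusive on both bounds; the classifier never fires for other event types
regardless of length.

## Enrichment statistics

All over-representation tests reduce to a 2×2 table `(a, b, c, d)`:

- *gene sets*: a = mis-spliced ∩ set, b = mis-spliced ∖ set, c = other
  universe genes in the set, d = remainder (foreground and background rows
  are disjoint);
- *microexon disproportion*: foreground = mis-spliced SE events (optionally
  restricted to a gene panel), background = **all** FDR-evaluable SE events,
  rows = microexon vs not. Because the background includes the foreground,
  the measured OR understates the conditional odds ratio used to plant
  effects in simulations (a planted conditional OR of 5 yields a measured
  OR near 3.7 at the default rates); the convention matches how such
  proportions are usually tabulated ("x% of all detected SE vs y% of
  mis-spliced SE");
- *cross-dataset overlap*: `(|A∩B|, |A∖B|, |B∖A|, |U∖(A∪B)|)` over a shared
  universe; gene symbols are uppercased at ingestion and cross-species
  matching defaults to case-insensitive symbol identity (a two-column
  ortholog table can be applied upstream);
- *motif positivity*: presence/absence of ≥ 1 hit of any grammar in either
  intronic window, foreground vs background with the foreground removed
  from the background.

The p-value is the two-sided Fisher exact test computed by direct
enumeration of hypergeometric point probabilities over the feasible range at
fixed margins; tables whose probability does not exceed the observed one
within a relative tolerance of 10⁻⁷ are summed into the tail. The
tolerance is part of the contract — without it, exactly-tied tables (which
occur whenever the margins are symmetric) would be included or excluded at
the mercy of floating-point rounding.

The odds ratio is the sample cross-product `ad/bc`. When any cell is zero
the Haldane–Anscombe correction adds 0.5 to every cell before the OR and CI
(policy configurable: `on-zero` default, `always`, `never`). The 95% CI is
Woolf's log method, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))` on the possibly
corrected cells. BH FDR is applied across the batch of gene sets tested
together. Degenerate tables (empty set, set = universe, empty foreground)
are reported with the corrected OR and flagged, never dropped.

Concordance between two datasets is the fraction of shared events with the
same ΔPSI sign (zero ΔPSI excluded from classification) and, among
concordant events, the fraction negative in both (joint exclusion).

## Motif grammars and windows

Grammars are sequences of IUPAC degenerate blocks and bounded gaps
(`(N)min-max`, `(N)k`, `N{min,max}`); U ≡ T throughout. Scanning reports
every distinct (start, end) realisation — overlaps included, different gap
splits with the same span collapsed — in left-to-right, shortest-first
order. Internally each gap-length combination compiles to one overlap-
tolerant lookahead regex; correctness is checked against a brute-force
matcher that tests every substring recursively. Non-ACGT characters
(e.g. assembly N) match nothing, including grammar gaps.

Scan windows are the two intronic flanks abutting the alternative exon: the
`width` (default 500) intronic nt immediately upstream of the 3′SS and
downstream of the 5′SS, in transcript orientation (mirrored on the minus
strand), truncated at the neighbouring constitutive exon. This anchors the
windows on the alternative exon itself rather than on the flanking exons'
distal splice sites, reflecting the mechanism in which downstream-intron
binding promotes inclusion; zero-length introns omit their window with a
warning. Scanning is sense-strand only — pre-mRNA is single-stranded — so
minus-strand genes are reverse-complemented at extraction.

Enrichment uses presence/absence rather than hit counts, which keeps the
2×2 test well defined under overlapping hits; hit counts remain available
for diagnostics. The SRRM4-style site check operationalises "a UGC roughly
15 nt upstream of the 3′SS" as: a `TGC` whose 3′ end lies at offsets
−25…−6 from the exon start on the intronic side (offset −1 = last intronic
base), truncated when the intron is shorter.

## The simulator

`SimConfig` defaults are the study conditions, chosen once:

- **Design**: 21 cases vs 8 controls (a human cohort-sized design), groups
  `case`/`control`; 500 genes, 1 + Poisson(1) events per gene; event-type
  mixture SE 0.70, MXE 0.10, A5SS 0.08, A3SS 0.08, RI 0.04; half the genes
  on each strand.
- **Counts**: per event × sample, total junction reads
  `T ~ NegBin(mean 100, shape 5)`; inclusion reads beta-binomial with
  precision 50 around the length-weighted inclusion fraction
  `q = ψ·lI / (ψ·lI + (1−ψ)·lS)`. Precision 50 puts ~0.07 s.d. of
  between-replicate PSI noise at ψ = 0.5, emulating biological
  overdispersion; `bb_precision=None` gives a pure binomial for exactness
  tests.
- **Effects**: 5% of events truly mis-spliced by default; |ΔPSI| ~
  Uniform(0.15, 0.5) with random sign (forced negative available; the sign
  is then preserved under clipping, so planted exclusion always yields
  ΔPSI < 0). Baseline ψ for affected events is drawn from (0.25, 0.75) so
  effects fit inside [0.02, 0.98].
- **Placement**: effects are allocated by *exact counts* within strata
  (genes inside/outside an enriched set, or microexon vs other events): the
  base odds are solved numerically so stratum odds ratios equal the
  configured multiplier, expected counts are rounded by largest remainder,
  and members are drawn without replacement. This makes the planted odds
  ratio a controlled ground truth instead of a Bernoulli average, at the
  cost of slightly super-binomial regularity; recovery bands in the
  validation suite account for residual detection noise only.
- **Genomes and motifs**: each gene occupies its own chromosome with real
  exon/intron structure (150 nt flanks, introns mostly 620–1,100 nt with a
  5% short-intron component that exercises window truncation). Before
  planting, both scan windows of every SE event are *scrubbed* of chance
  YGCY-grammar matches (first-block positions set to A, which can match no
  grammar letter used here, so scrubbing converges and creates nothing).
  A planted site — a random realisation of the configured grammar, default
  YGCYGCY — is then written into the downstream-intron window with
  probability 0.7 for truly mis-spliced events and 0.2 otherwise. Scrubbing
  is what makes the per-event motif-positive truth flag exact: in uniform
  random sequence, essentially every 1 kb window contains a chance
  `YGCY(N)0-5YGCY` match and no planted contrast could be measured.
- **Covariates**: in dose–response mode the case samples receive a
  CTG-repeat-like covariate on a 4× range (200–800, evenly spaced) and each
  sample's true effect is scaled by covariate/max; otherwise all case
  samples express the full effect (so ΔPSI estimation is unbiased).
- **Development mode**: affected events move linearly from ψ₀ to ψ₀ + Δ
  across ordered time points, alongside a regulator-expression covariate on
  the same ramp; per-time-point PSI is the mean over replicates.

Everything is deterministic given the seed; `write()` emits the exact
formats the readers consume (native TSV, FASTA + fai, GMT, sample TSV) plus
the truth table, byte-identically across runs.

**What the simulator does not emulate** — and therefore what passing tests
do not show about real data: mappability and GC bias in junction counting,
correlated effects within co-regulated gene modules, isoform-level coupling
between events of one gene, realistic intron length/composition
distributions, sequencing batch structure, and any read-level artefacts
(alignment, duplicate, multimapping). Recovery results demonstrate the
statistics are implemented correctly and calibrated under the stated
generative model, not that the pipeline is robust to real-data artefacts
upstream of junction counts.

## Burden and covariate correlation

A case sample's burden over an event subset is the mean of
`|PSI_sample − mean PSI_control|` across events informative in that sample.
The per-sample statistic is defined against the *control-group mean* —
the natural per-individual analogue of ΔPSI when each case must receive its
own value — and this definition is recorded in output metadata. The
developmental variant uses the earliest time point as the reference, so the
burden rises with maturation in parallel with rising regulator expression.
Pearson's r with a two-sided t-test (n − 2 df) is used throughout; zero
variance yields an explicitly flagged degenerate result, and burdens are
correlated pairwise-complete. When two paralogous regulators both matter,
the default covariate is the sum of their expressions.

## Validation suite (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes were picked so the whole suite runs in about a minute on one
CPU while leaving the statistics well identified:

- Fisher vs exact rational enumeration: 1,000 random tables, margins ≤ 30.
- Permutation vs exhaustive enumeration: 100 random events, 3 vs 3.
- Null calibration: ~2,000 events, 3 vs 3, NB mean 100, 5 seeds (event
  flags) and 50 seeds (38 random gene sets); plus a random-foreground
  gene-set null (1,000 genes, 7% foreground, 50 seeds) that exercises the
  Fisher/BH machinery with a non-empty foreground.
- Effect recovery: ~500 events, 20% planted at exactly |ΔPSI| = 0.3,
  coverage 200, 21 vs 8, 20 seeds.
- Gene-set recovery: 500 genes, 38 sets of 100, one set planted at OR 4
  over an 8% base rate, 20 seeds. Microexon recovery: ~2,000 events,
  microexon odds × 5 over a 10% base rate, 20 seeds. Motif recovery: 1,000
  single-SE genes with genomes, planting 0.7 vs 0.2, 20 seeds.
- Scanner agreement: 500 random sequences ≤ 300 nt (pyrimidine/GC-weighted
  composition for hit density) × 3 grammars; plus the minigene-style
  `TGCT → GGCT/TGAT/TGTT` triple mutation, which must silence a planted
  composite site.
- Dose–response: 8 cases vs 8 controls, ~300 events, 30% planted with
  covariate-proportional scale, 20 seeds.

## Known limitations

- No covariate-adjusted or paired differential model; confounders must be
  handled by design or upstream.
- The permutation test cannot reach FDR < 0.05 below ~5 vs 5 samples;
  count-level likelihood tests are more powerful there and the package
  makes no attempt to reproduce them.
- Gene-length or expression-matched enrichment backgrounds are out of
  scope; the universe is "detected genes", which inherits detection biases.
- The human–mouse overlap unit is the gene symbol by default; event-level
  overlap is only defined within a species (exact coordinates).
- Intervals from CLIP experiments can be intersected with exported BED
  windows/hits externally; the package does not process CLIP reads.
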
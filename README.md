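# misplice

Differential alternative-splicing analysis for case/control RNA-seq cohorts,
with microexon classification, odds-ratio enrichment statistics, RNA-binding-
protein motif-grammar scanning and covariate dose–response analysis — plus a
fully specified simulator that generates every input with recorded ground
truth.

The package targets the downstream half of a splicing study: junction counts
per event (as produced by an event caller such as rMATS) go in, and
mis-splicing calls, gene-set enrichments, motif statistics and burden
correlations come out. It is written for analyses like those done in
myotonic dystrophy and related MBNL-deficiency models, where expanded CUG
repeats sequester MBNL splicing factors and shift the splicing of
neurodevelopmentally important exons — including *microexons* (3–33 nt
skipped exons) — but every component is generic.

## The statistics at its core

**PSI.** For an event with inclusion and skipping junction reads $I$, $S$
and effective junction lengths $l_I$, $l_S$:

$$\mathrm{PSI} = \frac{I/l_I}{I/l_I + S/l_S}$$

with a sample called uninformative when $I + S$ falls below a coverage floor
(default 10 reads).

**Mis-splicing calls.** $\Delta\mathrm{PSI}$ is the difference of group mean
PSI (case − control). Significance comes from a two-sided label-permutation
test on per-sample PSI — exhaustive over all label assignments when
$\binom{n}{n_\text{case}} \le 10^4$, otherwise Monte-Carlo with add-one
smoothing $p = (1 + \#\{|T^*| \ge |T|\})/(B + 1)$ — followed by
Benjamini–Hochberg FDR within each event type. An event is *mis-spliced*
when $|\Delta\mathrm{PSI}| > 0.1$ and $\mathrm{FDR} < 0.05$ (strict
inequalities; both configurable).

**Enrichment.** Every over-representation question (gene sets, microexon
disproportion, cross-dataset overlap, motif positivity) is a 2×2 table
tested with Fisher's exact test (two-sided, by direct hypergeometric
enumeration) and summarised by the cross-product odds ratio
$\mathrm{OR} = ad/bc$ with a Woolf 95% CI, using the Haldane–Anscombe +0.5
correction when a cell is zero.

**Motif grammars.** Gapped degenerate patterns such as the high-affinity
MBNL-binding grammars `YGCYGCY` and `YGCY(N)0-5YGCY` (Y = C/U) are scanned
in the two intronic windows (±500 bp) abutting each skipped exon's splice
sites, reporting every distinct (start, end) realisation. A helper tests
for the SRRM4-style intronic `UGC` just upstream (−25…−6 nt) of the 3′
splice site.

**Burden and dose–response.** A case sample's mis-splicing burden is its
mean $|\mathrm{PSI} - \overline{\mathrm{PSI}}_\text{control}|$ over a chosen
event subset; burdens are correlated with covariates (CTG repeat length,
regulator expression) with Pearson's r and a two-sided t-test.

## Worked example

`examples/01_differential_splicing.py` simulates a 21-vs-8 cohort with 5% of
events carrying a true PSI shift and runs the full differential pass:

```
events tested: 817  (per type: SE=600, MXE=67, A5SS=62, A3SS=61, RI=27)
mis-spliced calls: 42 (5.1% of events)
true effects recovered: 41 of 41 planted

strongest calls (most negative DPSI = exon exclusion in cases):
            event_type gene_symbol      dpsi  p_value       fdr  is_microexon
SE_000739           SE   GENE00368 -0.534504   0.0001  0.002143         False
A5SS_000643       A5SS   GENE00320 -0.530271   0.0001  0.001240         False
...
```

Each row is one alternative-splicing event: `dpsi` is the case-minus-control
change in the exon's inclusion fraction (−0.53 means the exon is included in
~53 percentage points fewer transcripts in cases), `p_value` is the
Monte-Carlo permutation p (floor 1/10,000 at the default 9,999
permutations), and `fdr` the per-type BH value that the |ΔPSI| > 0.1 &
FDR < 0.05 decision rule consumes. All 41 planted effects were recovered,
plus one false call — consistent with the nominal 5% FDR.

`examples/02_gene_set_enrichment.py` plants mis-splicing with 4-fold odds
inside one of 38 gene sets and recovers it:

```
top sets by odds ratio (SET01 carries the planted enrichment):
        a   b   c    d  odds_ratio  ci_low  ci_high     fdr
SET01  20  22  80  378      4.2955  2.2383   8.2432  0.0008
SET30  15  27  85  373      2.4379  1.2429   4.7820  0.2546
sets at FDR < 0.05: 1 of 38
```

Only the planted set survives the batch FDR; its odds-ratio CI brackets the
planted value of 4. The other examples cover motif scanning/enrichment
(`03`) and the CTG-repeat dose–response and developmental burden (`04`).

A `misplice` console command exposes the same stages as subcommands
(`simulate`, `psi`, `diff`, `enrich`, `motifscan`, `correlate`, `overlap`,
`report`); outputs carry provenance headers (version, config hash, seed) and
are re-readable by the package's own readers.

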
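# Methods

## Scope and model

`bsaskit` implements the analysis layer of a targeted bisulfite amplicon
sequencing (BSAS) study of gonadal DNA methylation in a sex-changing fish,
together with the companion RT-qPCR expression comparison and virtual
RT-PCR sex-typing assays, and a seeded simulator that generates every
input the analysis consumes. The measurement model is standard BSAS:
bisulfite treatment deaminates unmethylated cytosine to uracil (read as
T), methylated cytosines resist conversion, so after PCR and sequencing
the fraction of C base calls at a CpG cytosine estimates that site's
methylation level. Directional (top-strand) bisulfite PCR is assumed
throughout; the complementary PCR strand appears only as the R2 mate.

## Coordinates and the bundled panel

Panel coordinates are TSS-relative signed integers with no position zero
(…, −2, −1, +1, +2, …). Amplicon length is defined as the naive signed
subtraction `end − start`. This is a deliberate bookkeeping choice: it is
the only convention that reproduces all eleven declared amplicon sizes in
the bundled panel, including regions that cross the TSS (an inclusive
no-zero count would give 271 instead of 270 for the upstream dmrt1
amplicon). A side effect is that for non-crossing amplicons the `end`
label is one short of the position of the final base; positions of
individual bases are always derived with the index↔position maps in
`panel.py`, which skip zero explicitly.

The bundled panel (`data/default_panel.yaml`) carries, per amplicon:
TSS-relative span, declared length and CpG count, locus-specific primer
cores plus the standard Illumina forward/reverse adapter overhangs, and
the per-group methylation mean ± SD (percent) for the four cohort groups
(captive/wild × testes/ovaries). Totals: 11 amplicons, 146 CpG sites,
3,430 bp of targeted sequence; the N-spaced converted mapping reference
is 3,430 + 10 × 100 = 4,430 bp. The package always reports this computed
length rather than any externally quoted figure, since spacer placement
and primer inclusion conventions can move it. Amplicon sequences are not
shipped: the simulator synthesizes them on demand (below), so the panel
is usable without any sequence download.

## Synthetic data generator

The generator's defaults encode the study conditions; they are fixed, not
tuning knobs.

**Cohort.** 42 gonads: captive testes n=14, wild testes n=10, captive
ovaries n=14, wild ovaries n=4 (24 testes, 18 ovaries).

**Amplicon sequences.** A synthesized amplicon begins with the forward
primer core (valid bisulfite primers contain no C, so the core equals its
own conversion), ends with the reverse complement of the reverse core,
and places exactly the declared number of CG dinucleotides in the
interior, ≥3 bp apart, avoiding TSS positions already used by another
amplicon of the same gene (two sox8 amplicons overlap by 23 bp). Interior
fill draws from A/T/G/C at 30/30/20/20% with a rejection rule that never
creates an extra CG, so non-CpG cytosines exist for conversion QC while
the CpG count stays exact.

**Methylation truth.** Per sample and amplicon one level is drawn from a
Beta distribution moment-matched to the group mean/SD (the study reports
only means and SDs; Beta is the natural bounded choice), clipped to
[0.001, 0.999]; an SD of zero or an infeasible SD (variance ≥ m(1−m))
falls back to a point mass, with a warning in the infeasible case.
Per-CpG values add mean-zero Gaussian jitter (default SD 2 percentage
points, mirroring visible site-to-site variability) and clip to [0, 1].
The expected group mean equals the configured mean; clipping bias is
negligible at the panel's means.

**Reads.** Per template molecule, each cytosine is retained as C if it is
a methylated CpG (Bernoulli at the site's true level) or through
incomplete conversion — applied to *every* unmethylated cytosine, CpG or
not, at the configured failure rate (default 0.005), which is what the
chemistry does and what makes calls inflate by ≈ rate × (100 − true)
points. Substitution errors (default 0.001) are applied independently to
R1 and R2; Phred strings are constant at −10·log10(error rate) capped at
Q40, with an optional 3'-end decay ramp to exercise trimming. R1 is the
converted molecule from the forward primer, R2 its reverse complement,
each truncated to the read length (default 300 bp paired, MiSeq V3
geometry). Default coverage is 2,000 pairs per amplicon — an order of
magnitude chosen for desk-scale runs; the real study reports several-fold
deeper coverage, which only tightens binomial noise. Read names encode
sample and amplicon for truth-tracking; the quantifier never reads them.
All randomness flows from `numpy` `SeedSequence` substreams of one root
seed (sample/amplicon substreams are keyed by CRC32, not Python's salted
`hash`), so outputs are byte-identical across runs.

**qPCR.** Replicate Ct = base Ct − log2(expression) + Gaussian noise
(default SD 0.2, triplicates); ovary expression is 1 and testis
expression the configured fold change, so the testes:ovaries ratio of
mean 2^−ΔCt equals the truth in expectation (the lognormal noise bias is
identical in both groups and cancels in the ratio). Base Ct values (24
target / 18 reference) are plausible mid-dynamic-range defaults; they
cancel in ΔCt. An optional between-individual log2-scale SD exists and
defaults to 0.

**Isoforms.** Toy gene models encode the printed variant geometry rather
than real sequence: a dmrt1-like gene whose ovary transcript swaps the
DM-domain-bearing exon 1a (250 bp, domain at transcript 40–160) for an
untranslated 59-bp exon 1b located 3,357 bp upstream; and a nine-exon
cyp19a1-like gene whose testis variants shorten exon 1 from 196 to 163 bp
(3' loss) and exon 2 from 151 to 101 bp (5' loss), occasionally skipping
exon 3. Assay primers are cut from the generated transcripts so that the
testis-specific product is 575 bp and the ovary-specific product 207 bp;
the female assay's reverse primer spans the full-length exon 1/exon 2
junction, which is exactly why it fails on the shortened testis variant.

What the simulator does *not* model: PCR duplicates and amplification
bias, indels, non-directional libraries, bisulfite degradation, coverage
variation between amplicons, SNPs under primers. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to every artefact of real libraries.

## Quantification

Reads are 3'-quality-trimmed at the 95% call-accuracy threshold
(Phred < −10·log10(0.05) ≈ 13.01; trimming is suffix-only and stops at
the first passing base), then length-filtered (reads < 100 bp removed;
a 100 bp read is kept). Amplicon assignment compares the read 5' end to
every amplicon's forward and reverse primer core allowing ≤2 mismatches;
a unique best match wins and ties across amplicons are unassigned.
Alignment is ungapped and primer-anchored — amplicon reads need no gapped
or global mapping — with asymmetric bisulfite scoring: read T opposite an
unconverted reference C is legal, anything else disagreeing with the
converted reference is a mismatch, and alignments with more than
⌈5% × aligned length⌉ mismatches are rejected and counted in QC.
Per CpG, percent methylation = 100 × C/(C+T); base calls that are neither
C nor T (sequencing errors) are excluded from both numerator and
denominator rather than counted as unmethylated; sites below the coverage
floor (default 100, configurable for toy runs) are reported as missing
but keep their counts. R1 and R2 are processed independently: mates of an
overlapping pair sample the same molecule's conversion events, so
double-counting does not bias the percentage, only (knowingly) overstates
nominal coverage — documented rather than merged. Conversion efficiency
is 100 × T/(C+T) over non-CpG reference cytosines per sample, warning
below 98%. Read accounting is conserved at every step
(short + unassigned + rejected + aligned = input).

## Group statistics

Methylation percentages violate homoscedasticity, so group comparison is
rank-based: tie-corrected Kruskal–Wallis per CpG (chi-square, k−1 df),
with no cross-CpG multiple-testing correction by default (each site is
an independent question in this design; Benjamini–Hochberg is available
behind a flag). Letters come from Dunn pairwise z-tests with Holm
adjustment, summarised by the insertion-algorithm compact letter display;
the pairwise method is an interpretive choice — any rank-based posthoc
would serve — and alpha defaults to 0.01 at amplicon level and 0.05 per
CpG. Amplicon summaries define the per-sample value as the mean over the
amplicon's CpGs; the "overall" mean is the *unweighted* mean of the four
group means (the only definition consistent with the bundled summary
values, checked at printed precision with decimal half-even rounding),
while the overall SD pools all samples (the only definition that yields
the large dispersions seen when sexes diverge). Gene-level sex
differences default to pooling all samples per sex, with a
group-mean-average mode behind a flag — with unbalanced origin groups the
two weightings differ by a few points and neither is canonical. The
density relationship is a least-squares fit of
methylation = a·exp(−b·density), initialised from a log-linear
regression; on panel-like data b > 0 (CpG-dense, island-like amplicons
are hypomethylated).

## Expression

Standard curves regress mean Ct on log10 dilution; efficiency is
10^(−1/slope) − 1, flagged outside [0.9, 1.1] or when R² ≤ 0.99.
Relative expression is Livak 2^−ΔCt with replicate Ct values averaged
before differencing (the conventional order). Group comparison
log-transforms the 2^−ΔCt values, reports Lilliefors-corrected KS
normality and Levene variance diagnostics without gating, and applies a
t-test (Welch by default for robustness; Student's t available). Fold
change is the ratio of arithmetic group means of 2^−ΔCt — matching an
"on average x-fold" reading — with a geometric-mean option.

## Splice assays

Isoform-vs-model comparison is pure interval arithmetic on sorted,
non-overlapping exon chains: a reference exon with no overlapping
isoform segment is skipped; boundary truncation is 5'/3' shortening with
the signed base delta; isoform segments overlapping no exon are novel
exons; segments extending past an exon boundary are intron retention.
Domain presence projects the domain's reference-transcript interval to
genomic bases and requires full coverage by the isoform chain, making it
monotone under exon removal. Virtual PCR requires a full-length primer
match within `max_mismatch` (default 0) with a perfect 3'-terminal base
(polymerase extension cannot start from a mismatched 3' end), forward on
the sense strand and reverse on the antisense strand; product sizes are
inclusive of both primer footprints, as gel sizes are reported; multiple
candidate products are all returned and flagged non-specific. The
two-assay sex-typing readout is male-pattern / female-pattern / both /
neither.

## Numerical and degenerate-input choices

- Decimal half-even rounding (`stats.round_printed`) reproduces printed
  table precision where binary-float `round` would not (69.65 → 69.6).
- Kruskal–Wallis on all-identical data returns H = 0, p = 1 instead of
  erroring; Dunn z with a zero variance term returns p = 1.
- Degenerate qPCR variances yield an undefined t-test p with a warning
  (p = 1 when the groups are also identical in mean).
- The exponential density fit raises with diagnostics on non-convergence;
  flat data recovers b ≈ 0.
- Empty primer cores, zero-length amplicons, zero TSS coordinates,
  methylation flags on non-CpG cytosines, amplicons longer than one read
  pair, and unsorted exon chains all raise typed errors.

## Problem sizes used in the shipped checks

Recovery checks simulate 14 samples × one amplicon × 2,000 read pairs
(methylation) and 100 replicate cohorts of 10 + 10 samples (expression);
the null-calibration check uses 10,000 Kruskal–Wallis replicates at the
study's group sizes. These sizes give standard errors well below the
effects under test while keeping any run to a few seconds. Tolerances in
the checks are 3 standard errors (computed from the simulated data, never
hard-coded widths).

## Known limitations

- The quantifier targets amplicon panels only: no gapped alignment,
  genome-scale mapping, SNP-aware calling, or CHG/CHH reporting beyond
  conversion QC.
- Primer *validation* only; no primer design or melting-temperature
  modelling.
- The efficiency-corrected (Pfaffl) expression model and multi-reference
  normalisation are out of scope; 2^−ΔCt assumes near-perfect, equal
  efficiencies (which the standard-curve check is there to verify).
- Real transcript accessions can be supplied to the splice assays as
  plain sequences, but all shipped tests run on the synthetic toys.
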
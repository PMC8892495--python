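# Methods

## Coordinate and strand conventions

Genomic intervals are 0-based half-open (BED) everywhere, including GFF3
ingestion (1-based closed on disk, converted on read). Read-local positions
are 1-based from the 5′ end of the excision product. "TS" denotes the
transcribed (template) strand, antisense to the mRNA; a read is a TS event
for a gene iff its mapped strand is opposite the gene's annotated strand.
Gene strand is mandatory: unstranded gene records are rejected because
TS/NTS assignment is undefined without them.

## The generative model

The simulator states a world in which every downstream estimator has a
recoverable truth.

**Genome.** I.i.d. bases with P(G) = P(C) = gc/2 and P(A) = P(T) =
(1 − gc)/2; default GC 0.43 (fly-like, A/T-rich), 2 Mb over 2 chromosomes —
large enough for ~10⁵–10⁶ motif sites per strand, small enough that a full
run takes seconds. Strand symmetry of the composition is a consequence of
the sampler, not an extra assumption.

**Genes.** Default 50 genes of 1.2–6 kb placed with ≥500 bp intergenic
gaps, random strands, expression sampled from a lognormal law
(μ = 3, σ = 1 on the log scale, RPKM-like: median ≈ 20, heavy right tail,
roughly half the genes above the RPKM > 10 expression cutoff — a
plausible shape for per-gene expression). A configurable number of sub-1-kb
genes and of overlapping antisense pairs is placed to exercise the standard
gene filters; an `("constant", v)` law states uniform expression.

**Damage.** One lesion per read at a dinucleotide motif on either strand:
GG for cisplatin; TT/TC/CT/CC for UV photoproducts with default weights
0.5/0.2/0.2/0.1 (TT-heaviest, as for CPDs). No product degradation is
modeled (excision products are comparatively stable in flies).

**TCR.** The sampling weight of a lesion site on the template strand inside
a gene body is multiplied by `1 + (tcr_factor − 1) · f(rpkm)` with
`f(rpkm) = min(rpkm, P95)/P95`, the 95th percentile taken over the run's
genes. Rationale for this form rather than a bare
`tcr_factor × f(rpkm)` product: it keeps `tcr_factor = 1` exactly
strand-symmetric for any expression law, equals `tcr_factor` under uniform
expression, and doubles the expected TS/NTS when `tcr_factor` doubles at
fixed expression. The saturating-linear `f` is a modeling choice (only a
positive association between transcription and TCR is established);
`tcr_factor` defaults to 2.0, the strength recovered as a gene-body TS/NTS
of ~2 in cisplatin data. Enhancement applies within gene bodies only — the
simplest model consistent with gene-body-elevated TS repair.

**Excision geometry.** Lengths are drawn from a 24–32 nt law peaking at
27 nt (UV) or 28 nt (cisplatin), with 26–29-mers predominating. The lesion
register (read-local 1-based position of the lesion's 5′ base) is `L − 7`
for cisplatin — for a 28-mer the GG sits at 21–22, i.e. 20 nt 5′ and 6 nt
3′ of the adduct. UV photoproducts use an **even mixture of registers
`L − 8` and `L − 7`**: a single 2-nt lesion register cannot occupy a
3-position enrichment window, and the even mixture reproduces both the
observed window (positions 20–22 of a 28-mer) and both printed offsets
(19 nt 5′, 6 nt 3′). Lesions are kept 35 bp from chromosome ends so every
register fits.

**Background.** `background_fraction` of reads are uniform genomic
fragments with the same length law and no lesion; at 1.0 the run emulates a
repair-null (XPC-knockout-like) library of sheared DNA.

All randomness flows from one integer seed through
`numpy.random.SeedSequence` children (genome / gene placement / read
sampling), so runs are bit-reproducible.

### What the generator does *not* emulate

Real damage propensity beyond the dinucleotide (sequence context, chromatin,
nucleosomes); repair kinetics in continuous time (time courses are
independent samples at different `tcr_factor`); multi-lesion fragments and
product degradation; sequencing error, adapters, duplicates, mappability. A
green parameter-recovery test therefore establishes the correctness of the
estimators under the stated geometry and strand model — not the biology of
any particular dataset.

## Estimators and numerical choices

**Length distribution.** Mode ties break toward the smaller length; the
median is the 50th-percentile length on the read-count CDF (integer).

**Position frequency matrix.** Built from lesion-strand sequences of all
reads of one length; no pseudocounts; requires ≥500 reads (default) so
frequencies are stable to ~2% or better.

**Enriched window.** Positions where the summed damage-base frequency is at
least `min_ratio ×` the background damage-base frequency (background =
genome-wide single-base composition by default — computable without extra
inputs and matching the visual baseline of frequency plots; overridable).
The maximal contiguous run qualifies; ties in length resolve to the 3′-most
run because incision geometry places lesions 3′ of center. Default
`min_ratio = 1.25`: under the two-register UV mixture the *edge* window
positions carry a guaranteed pyrimidine in exactly half the reads, so their
expected enrichment is (0.5 + 0.5·0.5)/0.5 = **1.5** — and the pyrimidine
background is 0.5 for any strand-symmetric genome regardless of GC. A
threshold at exactly 1.5 would make edge detection a coin flip under
sampling noise; 1.25 sits midway between null (~1.0×) and edge signal
(1.5×), separating them by dozens of standard errors at 50k reads.

**Incision offsets.** From window [a, b] of length-L products:
5′ offset `a − 1`, 3′ offset `L − b`. Two 3′ conventions coexist in
practice — nucleotides strictly 3′ of the lesion (`L − b`, the "6 nt"
convention) and the inclusive rank of the lesion base from the 3′ end
(`L − b + 1`, the "7–9 nt" convention); both are computed and labeled.

**Damage-signature verdict.** Score = max over positions of
damage-base frequency / background; "absent" iff score < 1.5. The verdict
threshold stays at 1.5 (unlike the window threshold) because its signal is
the *peak* enrichment, ≥2× for genuine excision products vs ~1× for
background shearing.

**Gene filter.** Non-overlap is tested strand-agnostically against the
*full* annotation (a gene overlapped only by a gene that itself fails other
filters is still excluded); length is half-open `end − start` with a
≥1000 bp default; the expression filter (strictly greater than
`min_rpkm`, default cutoff 10 when enabled) applies last, and genes missing
expression are excluded and counted separately.

**Unit-gene profile.** 25 + 100 + 25 bins (80 bp flanks; body bins of
`gene_length/100` bp, floor-based edges with the final base clamped to bin
99). Reads are assigned by midpoint `floor((start+end)/2)` — a point rule
avoids double counting across bins and is robust for 24–32 nt reads against
≥12 bp bins; whether real pipelines count by overlap or point rule is
generally unstated, so the midpoint rule is our documented choice. A read
may fall in the extended regions of two adjacent retained genes; it counts
for both and the surplus is tallied (`n_double_counted`). Per-gene per-bin
RPKM = `count × 10⁹ / (bin_bp × total_mapped_reads)` — per-bin bp
normalization is required because body bins differ in bp across genes — and
the profile is the unweighted mean over genes. Flank bins extending off the
chromosome are missing for that gene (excluded from the mean, not
zero-filled).

**Body TS/NTS.** Ratio of body-bin means (not mean of per-bin ratios):
robust to near-zero bins; NaN if the NTS mean is zero.

**Log2(TS/NTS).** Per gene, body reads only, `log2((ts + c)/(nts + c))`
with pseudocount c = 1 by default (zero handling is otherwise undefined;
c = 1 maps ts = nts = 0 to exactly 0). Sensitivity: increasing c shrinks
all ratios toward 0, monotonically in |log-ratio|, and matters only for
genes with counts of order c; the distribution over well-covered genes is
insensitive for c in [0.5, 2]. The distribution is computed over *all*
annotated genes; time-course means are taken over one fixed filtered gene
set (samples with differing filters are rejected) and times must strictly
increase.

**Site-density profile.** Fixed-length motifs scanned on both strands of
each gene's extended region; an occurrence is binned by its 5′ base (on the
− strand that is the higher coordinate; the ≤1-bin error this rule could
introduce is negligible at ≥12 bp bins) and assigned TS/NTS by whether the
carrying strand is the gene's template strand. Dinucleotide motifs only:
the expected-damage argument rests on dinucleotide availability;
context-weighted propensities are out of scope.

**Observed/expected.** Elementwise repair ÷ site density; bins with zero
expected density are missing (NaN), never infinite.

**Exact mapper.** 20-mer seed index with full-sequence extension; reports a
read iff its sequence or reverse complement occurs at exactly one genomic
locus, tallying multi- and zero-locus drops. Refuses genomes above 10 Mb
(configurable) and points to a real aligner: it exists so the synthetic
path needs no external tools, not as an alignment method.

## Validation design

Every estimator is tested by parameter recovery against the generator's
truth tables (exact re-extraction of sequences at truth coordinates,
registered motifs at truth lesion positions, χ² agreement of sampled
lengths with the length law, binomial TS/NTS symmetry at `tcr_factor = 1`,
factor recovery at 2 and 4, offset recovery exact at ≥50k reads) plus
structural invariants (strand-flip symmetry of the meta-profile, read
conservation across bins, filter equivalence to a brute-force overlap
oracle). The end-to-end landscape coherence check (observed profile ∝ site
density at `tcr_factor = 1`, correlation ≥0.95) runs on a genome with
A/T-rich blocks imposed at every TSS/TES (`impose_at_rich_blocks`): on a
homogeneous i.i.d. genome the expected density is nearly constant across
bins, so bin-to-bin correlation would compare noise with noise and test
nothing; the structured genome is the scenario the module exists to
explain (motif-depletion dips at gene ends) and there the correlation is
~0.97 at 300k reads.

## Known limitations

- The expression→TCR response is a stated saturating-linear choice; only
  monotonicity should be read into recovered expression dependence.
- The unit-gene mean weights genes equally regardless of coverage; very
  low-coverage genes add variance (no minimum-count gate is applied).
- The toy mapper is exact-match only; any real library must be aligned
  externally and supplied as uniquely-mapped BED6.
- Background composition for enrichment is genome-wide; strongly
  heterogeneous genomes may warrant a supplied background.
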
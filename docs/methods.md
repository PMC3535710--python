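# Methods

This note documents the models, conventions and numerical choices behind
`cpgmut`, what its synthetic-data generator does and does not emulate, and
therefore what a passing test does and does not establish.

## Methylation levels and classes

A call's methylation level is `mc_reads / total_reads` over the reads
mapped to that cytosine; a site is *methylated* iff its level is strictly
positive, i.e. one methylated read suffices. Coverage filtering is a
separate, optional stage precisely so that the "methylated = level > 0"
definition and coverage-sensitivity analyses stay independent.

Classes partition [0, 1] as: unmethylated {0}; low (0, 0.2]; low-int
(0.2, 0.4]; int (0.4, 0.6]; high-int (0.6, 0.8]; high (0.8, 1]. The
half-open-on-the-left convention resolves the ambiguity of prose like
"20–40 %": 20 % is *low* (consistent with "≤ 20 %"), 80 % is *high-int*
(consistent with "> 80 %" for high). `classify_level` is total and
single-valued on [0, 1] and rejects anything outside it.

The two cytosines of one CpG dinucleotide are distinct analysis units (one
per strand); nothing merges them, which lets per-strand replication act as
an internal control. Coordinates are 0-based half-open everywhere in
memory; only readers/writers convert (methylome TSV, VCF and AXT are
1-based on disk).

## CpG islands

An island must satisfy length ≥ 500 bp, GC ≥ 0.55 and observed/expected
CpG ratio ≥ 0.65, with O/E = #CpG · L / (#C · #G). Ambiguous bases are
excluded from numerator and denominator of GC (L is the non-N length in
O/E as well), an all-N window is signalled as undefined, and windows with
more than 10 % N never qualify, so assembly gaps break islands.

The scanner is a seed/extend/trim/merge sweep over prefix sums:

1. slide a 200-bp window 1 bp at a time until it meets the GC and O/E
   thresholds (vectorised over all window starts);
2. extend the end in 200-bp jumps while the trailing 200-bp window still
   qualifies; when a jump fails, roll that window back 1 bp at a time to
   the nearest qualifying position and continue — the rollback also
   bridges gaps shorter than one window;
3. shrink the candidate 1 bp from both ends at a time until the whole
   interval qualifies; if that fails, retry shrinking from the left only,
   then from the right only, so a qualifying stretch at either edge of a
   failing candidate can still be isolated;
4. a candidate shorter than 500 bp is padded to exactly 500 bp (anchored
   at its right edge, left edge or centre) and accepted if the padded
   window qualifies — this recovers regions that qualify in aggregate
   while their seed neighbourhood alone falls just short;
5. accepted islands that overlap or abut (configurable `merge_gap`,
   default 0 — no gap-joining, since no gap parameter is part of the
   three-threshold definition) are merged, and a merge is kept only if the
   merged interval itself still qualifies;
6. scanning resumes after an accepted island, or one base after the seed
   of a rejected candidate (maximum recall at negligible cost).

Every emitted island satisfies all three criteria exactly — that is
asserted directly in the tests. Completeness is checked against an
exhaustive brute-force oracle (every window of every length ≥ 500 bp) on
genome-like 2-kb sequences: a CpG-depleted background with planted
GC/CpG-rich blocks of mixed strength. On such island-structured sequences
every maximal qualifying interval intersects an emitted island (0 misses
in 7,245 maximal intervals over 200 sequences). Known limitation: on
compositions that qualify *only in aggregate* — uniform near-threshold GC
where no 200-bp window and no 500-bp anchored window qualifies — any
seed-window scan can miss; an exact finder is inherently quadratic in
sequence length and is not attempted.

## Region labels

Primary labels partition every chromosome position exactly once, painted
in increasing precedence: intergenic (default) < intronic (transcript
span) < exonic (exon union) < promoter. A transcript's promoter is
[TSS − 1500, TSS + 500) in the direction of transcription — for a
minus-strand transcript, the genomic interval [tx_end − 500,
tx_end + 1500). Promoters overhanging a chromosome edge are clipped and
counted. Promoters take precedence over exons because the analysis treats
promoters as a category in their own right; a position in one gene's exon
and another's intron is exonic. Promoters are taken per annotated
transcript, de-duplicated implicitly by the dense-label representation.
CpG islands are an overlay flag, not a fifth label, so "in a CGI" can be
crossed with any primary label. Labels are dense per-chromosome uint8
arrays — O(1) lookup, trivially vectorised, and exact at the scales this
package targets.

## Mutation-rate proxies

*SNP density* counts **sites carrying at least one qualifying SNP** over
sites considered, rather than raw SNP records, so a density can never
exceed 1 and duplicate records at a position cannot double-count.
Qualifying records are validated, bi-allelic, uniquely mapped SNPs whose
allele pair contains C for a plus-strand site, or G for a minus-strand
site (variant tables report plus-strand alleles; a G/A pair at a
minus-strand cytosine is the complemented C/T). SNPs attach to sites by
exact position match.

*Divergence* is the fraction of differing bases among call sites present
in the human/outgroup alignment; columns with a gap or N on either side
are dropped at parse time and can never enter a denominator. Sites are
classified in the human genome's coordinates and classes.

Rate tables always carry (n_sites, n_events, density) so any marginal can
be recomputed exactly from its class rows; empty strata are emitted with
density = NaN rather than silently dropped. Strata compose as plain
dataframe columns (region, chromosome, context, strand, coverage cutoff).

## Allele-frequency analyses

The ancestral allele of a SNP is the outgroup base when it matches exactly
one of the two human alleles, otherwise missing — never a repaired or
imputed value. The cytosine-allele frequency is the frequency of C (G for
minus-strand sites). The major allele is the one with frequency ≥ 0.5;
exact ties go to the cytosine allele (and are the only case where the
choice matters; the convention is logged). The analysis set is methylated
(level > 0) reference-CpG cytosines joined to frequency records by
position; join statistics are attached to the result.

Correlations are Pearson product–moment over sites where both variables
are defined. The binned regression uses equal-width frequency bins over
[0, 1] by default (equal-count available), per-bin mean level, and a
least-squares line through (bin midpoint, mean level); empty bins are
flagged and excluded from the fit. Group comparisons default to a Welch
two-sample t-test with a rank-sum alternative behind a flag — the location
test was a free choice, and acceptance rests on planted-effect recovery,
not on any specific p-value.

## The synthetic world

`SynthConfig` states the world; the generator never adapts it. Defaults:

| parameter | default | why |
|---|---|---|
| genome_length | 1 Mb | desk-scale; ~100k cytosine calls |
| gc_background | 0.41 | bulk mammalian GC content |
| coverage_mean | 20 | deep-ish bisulfite experiment; shifted Poisson (1 + Pois(μ−1)) because the level needs ≥ 1 read and real coverage is overdispersed around small means |
| level_mixture | 0.30 at 0; 0.14 at each of 0.1/0.3/0.5/0.7/0.9 | balanced design: every class recoverable with comparable precision (see below) |
| class_snp_rate | 0.011/0.063/0.118/0.110/0.050/0.029 | patterned on the published whole-genome class densities (unmethylated ≈ 1.1 %, peak ≈ 11.8 % at low-intermediate) |
| class_div_rate | 0.040/0.0723/0.1066/0.1049/0.100/0.0994 | patterned on the published class divergences; the high-intermediate value is not printed anywhere and 0.10 interpolates its neighbours |
| background_div_rate | 0.012 | genome-wide human–chimp scale |
| noncpg_rate | 0.004 | the published CHG/CHH densities sit at 0.38–0.54 % |
| transition_weight | 0.8 | deamination makes C→T/G→A dominate at CpG |
| freq_coupling | slope 0.3, intercept 0.4, noise 0.15 | moderate positive level→C-frequency link with little [0,1] clipping |

Structure planted: every reference-CpG cytosine on both strands receives a
call; the two strands of a dinucleotide share one true level (strand
symmetry); methylated-read counts are Binomial(total, level). CHG/CHH
cytosines receive calls at a configurable density and draw levels from the
same mixture so every class is populated for the non-CpG flatness check
(real non-CpG methylation is lower and sparser; this choice trades realism
for verifiability and is confined to non-CpG strata). SNPs sit on called
cytosines with class-dependent (or, optionally, region-dependent)
probabilities; the outgroup genome differs at CpG call sites with
class-dependent probabilities and elsewhere at the background rate,
emitted as one gap-free alignment block per chromosome (the divergence
statistic ignores gaps, so indel machinery would add nothing testable).
C-allele frequencies follow `intercept + slope·level + N(0, noise)`
clipped to [0, 1]. All randomness derives from one seed through fixed
per-stage substreams, so outputs are byte-reproducible and adding a stage
never perturbs an earlier one.

**Truth records the class of the true level.** Observed classes differ
through binomial read noise, deliberately: it lets the tests measure
misclassification attenuation (observed extreme-class densities are pulled
toward their neighbours' planted rates, the more so the lower the
coverage) instead of hiding it.

**Why a balanced mixture.** Published class proportions are extremely
skewed (≈ 72 % of methylated CpGs highly methylated, < 1 % lowly). As a
*recovery* world that skew is degenerate: the rare classes' observed pools
are dominated by read-noise leakage from their huge neighbours, and the
expected observed-class ordering of densities inverts regardless of sample
size — an analytical property of the binomial mixing matrix, not a
sampling accident. A balanced mixture gives every class comparable
precision, which is what parameter recovery requires; the skewed
proportions remain expressible through configuration.

**Closed-form coupling targets.** For a planted-level variance *a*
(conditional on level > 0), observed-level variance *v = a +
E[ℓ(1−ℓ)]·E[1/n]* (with E[1/n] = (1−e^−μ)/μ for shifted-Poisson totals)
and frequency noise σ, the slope that yields Pearson r between *observed*
level and frequency is `s = r·σ·sqrt(v / (a(a − r²v)))`. The correlation
tests derive their slopes from this accounting rather than by search.

## What a green test establishes — and what it does not

The generator emulates the statistical skeleton the analysis assumes:
context-correct calls, binomial read sampling, strand-symmetric levels,
class-dependent event rates, a linear level–frequency coupling. It does
not simulate bisulfite conversion failure, mapping bias, coverage
correlated with GC, indels, linkage between SNPs, selection, or skewed
class proportions (unless configured). Green recovery tests therefore
establish that the *pipeline's estimators are unbiased and correctly
plumbed at the stated tolerances*, not that any biological conclusion
holds in real data.

## Numerical conventions

* Undefined statistics (empty denominators, zero variance, all-N windows)
  raise a dedicated signal (`UndefinedStatisticError`) rather than
  returning silent NaNs — except rate-table rows for empty strata, which
  are emitted with density NaN so the stratum stays visible.
* Recovery tolerances are 3 binomial standard errors at the planted rate;
  correlation targets use ±0.05 at n = 10,000.
* The GC and O/E threshold comparisons use the same floating-point
  expressions in the scalar and vectorised paths, so boundary windows
  (e.g. GC exactly 0.55) classify identically everywhere.
* Single-chromosome configs: multi-chromosome analyses (per-chromosome
  strata, gene-density correlation) operate on tables that concatenate
  across bundles or on user-supplied multi-chromosome files.

## Known limitations

* The island scanner's aggregate-only blind spot described above.
* `read_snps` reports filter counts but, parsing through pysam/htslib,
  cannot give line numbers for malformed records.
* The per-transcript promoter convention (vs per-gene) follows the
  annotation as given; redundant transcripts produce redundant promoters,
  harmless under the dense-label representation.
* Group-comparison p-values assume independent sites; linkage in real
  data would make them anti-conservative.
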
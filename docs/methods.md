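# Methods

This note documents the models, rules, and numerical choices behind
`neoseek`, and what the synthetic cohorts do and do not establish about
behavior on real data.

## Variant layer

Variants are stored in VCF minimal representation (shared prefix/suffix
trimmed, one-base anchor retained for pure indels) so that identical
events called with different padding compare equal across files and
patients.  Indels longer than 10 bp are dropped at ingest with a logged
count; genomic intervals are 0-based half-open internally and converted
from 1-based VCF positions on ingest.

**Population-SNP exclusion.**  A variant is excluded when its gnomAD
allele frequency exceeds 1% or its dbSNP frequency exceeds 5% (strict
inequalities; a variant with no frequency record is kept — absence of
evidence keeps a candidate in play, because downstream spectral and
normal-cohort checks provide the real specificity control).  An optional
strict mode excludes on dbSNP membership alone.

**Cross-source rescue.**  A variant called by only one caller (DNA or
RNA) is promoted to `both` when the other layer shows at least
`min_alt_reads` supporting reads at the site (default 2, configurable).
The threshold is deliberately low: the second layer only corroborates a
call already made, so requiring an independent second call would be
overly conservative.

**DNA-coverage classification.**  An RNA-only variant locus is
`canonical_covered` when the DNA data show ≥ 3 reference-allele reads,
else `not_covered`.  Covered loci are the ones where the absence of a DNA
call is informative — the signature of RNA-level origin such as A-to-I
editing.

**Exchange orientation.**  Substitution classes (12 possible) are
reported on the transcribed strand whenever all transcripts overlapping
the locus agree in strand; otherwise as called.  This is what makes
A-to-I editing legible as an A>G excess rather than an A>G/T>C split.

**TMB.**  Qualifying mutations (missense, stop/start events, frameshift,
in-frame indel, splice-site) overlapping the coverage-filtered, ±300
bp-extended probe regions, divided by the merged-union length of those
regions in Mb.  Merging before length computation makes the value
invariant under splitting regions into adjacent pieces; the denominator
uses covered extended territory rather than the nominal kit size, which
is the interpretation that makes the per-patient numbers comparable when
coverage differs.

**Effect annotation** uses a fixed severity order (splice_site >
frameshift > stop_gain > stop_loss > start_loss > inframe_indel >
missense > synonymous > noncoding_exon > UTR > intron > intergenic)
within and across transcripts.  This is a deliberately minimal annotator:
it exists so the pipeline is self-contained on toy data, not to replace a
full-featured annotation engine.

## Mutated-peptide database

Each variant is applied independently to the wild-type spliced transcript
(no multi-variant phasing — events are processed per mutation).  For
splice donor/acceptor hits (the 2-bp dinucleotides), the affected intron
is retained in the mature sequence and the exon/intron junction becomes
the variant anchor: an ORF qualifies when it encloses the junction,
reading into the intron until the first in-frame stop.  Planting the
whole intron as the anchor would demand stop-free introns and is not what
"enclosing the mutation site" means.

**ORF semantics.**  Missense and in-frame events on coding transcripts
use the annotated CDS frame; walking from the annotated ATG to the first
in-frame stop realizes the stop-loss extension into the 3'UTR
automatically.  Everything else (non-coding transcripts, frameshifts,
splice retention, start-loss) is scanned in all three frames for the
minimal enclosing ORF: the nearest upstream ATG with no intervening
in-frame stop, paired with the nearest downstream in-frame stop.  At most
one ORF per frame, hence ≤ 3 per (variant, transcript).  "Minimal
enclosing" is a determinism choice — when a frame holds several enclosing
ATGs the one closest to the variant is kept.  An ORF lacking either bound
yields nothing (paired start/stop rule); a frameshift or stop-loss with
no downstream stop before the transcript end is dropped rather than
translated open-ended.  Proteins equal to a canonical translation
(synonymous changes) are never emitted.  Scanning stops at the transcript
3' end; no genomic read-through.

The scan is verified against an exhaustive start/stop-pair enumerator on
1000 random sequences per run (tests and acceptance script), plus fixed
worked examples for stop-loss (MAYQA), frameshift (MKPGK), and splice
retention (MKV).

## PSM post-processing cascade

Order: per-engine 5% PSM-FDR with decoy/contaminant removal and union
over engines → 8–15mer / ≤ 1500 Da (monoisotopic) → mutated-database
exclusivity (no canonical co-hit, plus a substring check against the
whole proteome) → mutation containment → canonical near-match and
known-peptide exclusion.  Every input PSM ends in exactly one bucket
(survivor or removed-by-named-filter); this conservation and the
monotonicity of candidate counts in the FDR threshold are asserted by
tests on every synthetic run.

Containment: a peptide covering the altered residues is `direct`
evidence; for frame-altering events (frameshift, splice retention,
stop/start loss) any peptide within the novel downstream region is
`noncanonical_frame`; an SNV-derived peptide not covering the altered
residue is rejected.  What a manual BLAST/BLAT review would do is
automated as deterministic sequence checks: exact substring plus
≤ 1-substitution near-match counting, with > 2 canonical near-matches
excluded and 1–2 flagged for review rather than auto-dropped (policy
configurable).  I and L are distinct by default; an I=L equivalence mode
exists for canonical checks.  Modification annotations are stripped to
bare sequence before all comparisons.

## Spectral and RT verification

Peak lists are merged greedily at 20 ppm (tolerance computed against the
mean of the two m/z values; closest pairs first, each peak used once;
unmatched peaks pair with zero intensity).  Greedy matching is not
globally optimal in adversarially dense spectra, but on realistic spectra
it agrees with exhaustive optimal assignment in ≥ 99% of random cases
(tested); the pairing algorithm is a package choice, not externally
specified.

SA = 1 − 2·arccos⟨â, b̂⟩/π on L2-normalized raw intensities (no
square-root transform), dot product clamped to [0, 1].  Best of the
synthetic and predicted comparisons is reported; ≥ 0.7 is a verified
match, < 0.55 a mismatch, between the two a "potential" match.  The 0.55
lower edge of the potential band is a package default (configurable,
recorded in output): it separates "close to the cutoff, plausibly true"
from "likely a different peptide".

RT alignment fits observed RT on predicted iRT per run with robustified
LOESS (span 0.75, 3 iterations; ≥ 20 calibration peptides required, else
an error suggests a global linear fallback), evaluated by interpolation
with clamped extrapolation.  |error| ≤ 8.56 min is a match; a miss with
observed RT in 9–17 min is a deviation (the prediction is known-poor in
that early-eluting range), otherwise a mismatch.  RT never excludes a
candidate on its own.

## Normal-tissue prevalence

A sample hits a variant at ≥ 1 alternate read.  Prevalence = hits / all
cohort samples (denominator selectable: all vs coverage-assessed;
all-samples is the default because it is the conservative, reproducible
choice when coverage assessment is capped).  Coverage is assessed on up
to the first 100 samples per tissue; a locus covered (≥ 3 reads) in < 5%
of assessed samples is `not_available`, taking precedence over every
other category — hits at an uncovered locus are uninformative.  Band
boundaries: 0 → absent; (0, 0.1%) → very low; [0.1%, 1%) → low; [1%, 5%]
→ intermediate; > 5% → high.  Over-editing: a candidate is flagged when
its tumor VAF exceeds the 95th percentile of normal-sample VAFs over
covered samples (undefined below 10 covered samples).

## Immunogenicity and validation grouping

ELISpot: means over replicate wells; positive iff ratio > 2 AND
difference > 50 SFU (strict).  A zero control mean with a positive test
mean is treated as infinite ratio (positive iff the difference criterion
holds) and flagged — the rule's intent is "clearly above background", and
a zero-background well should not be able to veto it.  Negative
differences are clipped to 0 for display only, never for calling.  A
candidate is immunogenic when any measurement in any culture setting is
positive; discordant candidates (positive and negative measurements) are
flagged.

Validation groups: non-validated iff SA mismatch OR high normal
prevalence; promising iff SA match AND prevalence ∈ {absent, very low};
potentially promising otherwise.  The precise promising boundary is a
declared, configurable rule table; RT is carried in the output but never
excludes.  Binder annotation: best rank/affinity over alleles and
algorithms; binder iff rank < 2% or affinity < 500 nM.

Cohort reports use Spearman rank correlation for count-vs-phenotype
associations (one representative sample per patient) and two-sided
Mann-Whitney tests with Benjamini-Hochberg adjustment across phenotype
features.

## Synthetic cohorts: what they emulate, and what passing does not show

Defaults (one ~100 kb contig, 30 transcripts at 80% coding, 5 patients,
NB-distributed counts with mean 30 somatic DNA and 300 RNA-only variants
per patient, editing fraction 0.55, 20% shared RNA variants from a
40-variant pool, population SNP density 5×10⁻⁴/bp with a frequency
mixture exercising both exclusion rules, 90% RNA re-detection of somatic
variants, 2000 normal samples over 10 tissues, 6 presented peptides per
patient, zero spectral/RT/ELISpot noise) are chosen so every mechanism
the pipeline must handle occurs repeatedly at seconds-scale runtime,
with per-patient counts an order of magnitude below a real cohort.  The
per-patient variant count distribution is negative binomial with
configurable dispersion — a modeling choice, since only means are
meaningful at toy scale.

Fragment spectra are singly-charged b/y ladders with lognormal
intensities (a stable property of the peptide, jittered ~±8% per
acquisition), no PTMs, isotopes, or higher charge states; corruption
moves peaks to non-matching m/z.  RT derives from iRT through a fixed
monotone mildly nonlinear map.  Special events (splice, frameshift,
stop-loss) are planted only at sites verified to yield a database entry,
so ground-truth traceability is exact by construction.

Consequently, passing the planted-truth suites shows the *rules and
bookkeeping* are implemented correctly — recovery is exact at zero noise,
bands classify correctly near their edges, conservation holds — but says
nothing about search-engine scoring quality, chimeric spectra, real
intensity prediction accuracy, alignment artifacts, or population
structure in real normal cohorts.  The separate synthetic per-candidate
validation table (`synthetic_validation_table.py`, labelled synthetic)
exercises the same classification rules at realistic cohort scale (90
candidates, 10,269 normal samples) without claiming any measured values.

## Numerical choices and degenerate inputs

Seeds: all generators derive their streams from the single config seed
with fixed small offsets; equal (config, seed) means byte-identical
output files.  SA: zero intensity vectors are errors; the dot product is
clamped before arccos so floating-point never leaves the domain.  RT
model: unique-ified LOESS grid, interpolation clamped at the calibration
range.  Merging: ties in ppm broken by peak index for determinism.
Prevalence: empty or coverage-less tables give an undefined coverage
fraction and hence N/A.  ELISpot: empty replicate lists are errors.
Empty mutated databases produce canonical-only PSM tables (warning, not
error); empty candidate lists are errors for the ELISpot generator.

## Known limitations

Single-contig toy genomes only exercise one transcript per locus
(overlapping-transcript strand disagreement is handled but rarely
generated).  The minimal effect annotator does not implement regulatory
features, distances, or HGVS.  Multi-variant phasing, fusion/circRNA
transcripts, proteasomal processing, and HLA typing/binding prediction
internals are out of scope; binding predictions are consumed as tables.
The greedy peak matcher can be suboptimal on pathologically dense
spectra.  Stop-loss scanning ends at the transcript 3' end rather than
reading into genomic sequence.
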
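# Methods

`alkdeep` implements an ultra-deep targeted-sequencing analysis of the ALK
kinase domain in neuroblastoma: per-position allele counting over five
targeted exons, a control-based background-noise model, a
five-standard-deviation classification rule for low-fraction point
mutations, minus-strand codon annotation, clonality and
Sanger-detectability classification, serial-dilution validation, and
cohort-level statistics over a packaged 105-case table.

## Target geometry and coding frame

The five targeted exons (ALK exons 21–25, hg19, chromosome 2) are stored as
1-based inclusive intervals. ALK lies on the minus strand, so residue
numbers increase as the forward genomic coordinate decreases; exon 21
(highest coordinates) carries the lowest residue numbers.

The coding frame is anchored once: the first base of the F1174 codon is
chr2:29443697, and the frame is extended contiguously across the intron
junctions by concatenating the exons in coding order. This single anchor
reproduces the three other known hotspot anchors exactly — I1171 with its
mutable second codon base at chr2:29445213, L1240 with its first codon base
at chr2:29436875, and the F1245 codon at chr2:29436858–60 — and places
D1160 in exon 22 (chr2:29445245–47) and R1275 in exon 25 (chr2:29432663–65)
by the same rule. Because the four anchors are mutually consistent with one
contiguous frame, per-exon anchoring and global anchoring coincide; the
R1275 placement is frame-inferred rather than independently anchored, and
is flagged as such in the documentation of `codon_span`.

Codons split by an intron (1172 and 1248) are annotated from their
non-contiguous base coordinates. Codons truncated at the target boundary
(1120 and 1279) cannot be translated; calls there are emitted unannotated
(`?residue?`) rather than dropped.

## Reference sequence

No nucleotide-level sequence is part of the analysed record — the mutations
are named at protein level — so the bundled reference (`default_reference`)
is a synthetic forward-strand sequence, deterministic under a fixed seed,
constrained to carry canonical codons at the anchored residues (Phe = TTC
at 1174 and 1245, Ile = ATC at 1171, Leu = CTG at 1240, Asp = GAC at 1160,
Arg = CGG at 1275). Under these codons every substitution named in the
cohort (F1174L/I/C/S, F1245I/C, L1240V, I1171T, D1160D, R1275Q/L) is
reachable by a single base change, and I1171T mutates exactly the published
coordinate. A real sequence can be supplied as FASTA (one record per exon)
and everything downstream is unchanged.

A consequence of the genetic code worth noting: F1174S is necessarily a
substitution of the second codon base and F1174I of the first, so the
published dual-clone tumour (F1174S 58.7% + F1174I 7.7%) occupies two
adjacent genomic positions within one codon. The caller nevertheless tests
every alternate base at every position independently, and the pair
F1174S/F1174C — which do share a forward coordinate — exercises the
two-alts-at-one-position path.

## Pileup conventions

Bases below the quality threshold (default phred 30, following the assay's
QC) and non-ACGT bases are counted in an "other" bucket that still
contributes to depth, so VAF denominators equal total coverage; a flag
(`lowq_in_depth=False`) selects the alternative. The assay's design depth
is 5000x; positions below `min_depth` are "not assessable", which is
distinct from "tested, no call". Duplicate-read removal and indel handling
are out of scope.

## Background-noise model and the 5-SD rule

For every (position, alternate base) the model stores the mean and unbiased
(n−1) sample SD of the alternate-allele fraction across the germline
controls (default eight; the three mutation-carrying control tumours are
used only as detection positives, never for background estimation, since
their mutated positions would inflate the SD). A sample is classified as
mutated at a site when

    z = (observed fraction − background mean) / effective SD > k,

with k = 5 by default. Every alternate base is tested separately; no
multiple-testing correction is applied (k = 5 is itself stringent), but the
number of tests is reported so users can post-correct.

**Effective SD.** The per-position sample SD estimated from eight controls
is itself very noisy (its sampling error makes a plain 5-SD rule behave
like a t-distribution tail with 7 degrees of freedom, i.e. a false-call
rate near 10⁻³ even for perfectly Gaussian noise, and worse where the SD
happens to undershoot). The effective SD is therefore the maximum of three
terms:

1. the per-position sample SD;
2. a global noise floor (default 2×10⁻⁴) guarding zero-variance entries;
3. a *predictive SD* built from globally estimated variance components:
   binomial counting noise `m(1−m)/depth` at the test sample's depth, plus
   a sample-level jitter term `(m·ĵ)²`, where ĵ is the relative
   between-sample spread of each control library's overall error rate
   (libraries' PCR/sequencing error levels scale all their sites together,
   so ĵ is estimated from whole-target totals). The predictive SD is
   evaluated at the control mean plus one standard error of that mean, the
   jitter CV is inflated by its own one-SE estimation error, and the
   sampling variance of the control mean is added — the usual
   prediction-interval ingredients.

With only the first two terms the measured held-out null false-call rate
under the default generator is ~1.4×10⁻³; with the predictive floor it is
2×10⁻⁵–3.5×10⁻⁴ across model seeds, close to the ~1.5×10⁻⁴ achieved by
oracle-parameter thresholds, while thresholds at every site stay far below
the smallest mutation of interest (2.7%), leaving sensitivity untouched.
The spec-style plain rule (max of sample SD and floor) is recovered by
constructing a model with `rel_jitter_sd = 0` and querying without a depth.

**Classification.** A call is *subclonal* iff VAF < 0.20 (strict), and
*Sanger-detectable* iff VAF > 0.15 (strict), reflecting the empirical
detection limit of capillary sequencing. Both thresholds are parameters.

## Synthetic data generator

The generator emulates the assay's data, not its chemistry:

* per-(position, alt) error rates are log-normal with median 10⁻³ and
  σ(log₁₀) = 0.3, truncated to [0, 0.05] — a background well below the
  lowest reported mutation (2.7%) but with a visible tail (about 1% of
  sites exceed 0.5%, which is why a per-site noise model matters);
* each sample multiplies all its rates by one log-normal factor with
  σ(log₁₀) = 0.1 — the between-sample variance that makes an SD-based rule
  meaningful rather than vacuous;
* counts at each position are a single multinomial draw with alternate
  probability `background + purity × VAF` for spiked alternates; germline
  (constitutional) spikes are not purity-scaled;
* depths default to the assay floor of 5000 (10000 for the dilution and
  dual-clone experiments); tumour purity is ≥ 0.5 per the inclusion
  criterion, and cohort simulations take the printed VAF as the expected
  allele fraction directly (purity is already folded into an observed
  fraction);
* dilution "1:d" is read as mutant:added-wild-type mass, so the expected
  VAF of a step is VAF₀/(1+d) — 1:10 gives 4.55% and 1:40 gives 1.22% from
  a 50% base; the alternative reading (mutant:total) is available by
  passing d′ = d−1;
* the synonymous D1160D case carries no printed fraction and is simulated
  as a germline heterozygous variant (VAF 0.5, not purity-scaled);
* every operation takes an explicit seed; there is no global random state.

Read-level emission (`emit_reads`) lays the pileup out as tiling rows cut
into fixed-length reads with per-base phred scores, such that rebuilding
the pileup at quality 0 reproduces the counts exactly; it exists to
exercise the SAM/pileup path end to end. The generator does not model
indels, strand bias, PCR duplicates or alignment artefacts — so passing
tests demonstrate the statistical behaviour of the pipeline under its
stated noise model, not robustness to those read-level error modes.

## Cohort statistics

The packaged table transcribes the published 105-case record verbatim
(decimal commas, profile strings, per-case Sanger status). Conventions:

* *mutation-positive* = at least one non-synonymous point mutation (16
  cases); the synonymous D1160D case and the four amplification-only cases
  are tallied separately; *ALK-altered* = mutation-positive or amplified
  (20 cases);
* the substitution spectrum counts each case by its highest-VAF (primary)
  mutation; per-residue counts tally a case once per mutated residue;
* per-case clonality uses the case's highest VAF; *Sanger-missed* uses the
  per-case Sanger status column (an explicit "Neg" alongside a
  deep-sequencing mutation), not the 15% rule — one case sits at 15.1% yet
  is Sanger-negative, so the status column is authoritative;
* profile-token matching: a case is 11q-deleted if its profile string
  contains the `11q-del` token (27 cases, none mutated), MYCN-amplified if
  it contains `NMA` (including `NMA + ALK-amp` rows).

The association test is Fisher's exact (two-sided, summing hypergeometric
probabilities no larger than the observed table's); the published record
does not name its test, so this is a documented assumption — on the
11q-deletion × mutation table it gives p ≈ 0.010. Kaplan–Meier estimation
and the log-rank test wrap `lifelines`; per-case follow-up times are not
part of the published record, so survival operations run on synthetic or
user-supplied times and no attempt is made to reproduce the published
curves numerically.

## Problem sizes and numerical choices

The test suite and the acceptance script use: eight controls at 5000x over
all 1431 (position, alt) target entries; 200 seeds per spike-in VAF for
sensitivity; ≥10⁶ held-out null trials for specificity; depth 10000 for the
dual-clone and dilution experiments; exhaustive Fisher-oracle enumeration
for all 2×2 tables with row margins ≤ 12 (8,281 tables) plus 300 seeded
random tables with larger margins. VAF-recovery tolerances are 3 binomial
SDs at the relevant depth; the observed fraction at a spiked site includes
that site's background, which at tail sites (background ≈ 0.2–0.5%) can
push a small fraction of estimates past the 3-SD band — an intrinsic
property of fraction-based VAF estimation, not corrected for.

## Known limitations

* The noise model is per-site and strand-agnostic; context-dependent
  substitution matrices and strand-specific error are not modelled.
* The caller handles substitutions only; indels, copy-number events and
  ALK amplification are consumed as annotations, not called.
* The synthetic generator's log-normal/multinomial structure is a modelling
  choice; real amplicon error distributions are heavier-tailed at specific
  motifs.
* Codon annotation relies on the bundled synthetic reference unless a real
  sequence is supplied; amino-acid labels at non-anchored codons are only
  as meaningful as that sequence.
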
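# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each stage, and what the synthetic-data experiments do
and do not demonstrate about real data.

## The synthetic study design

The generator (`neoxy.simulate`) emulates the data a sex-chromosome-turnover
study collects: a male and a female genome, DNA-seq samples from each,
strand-specific RNA-seq, gametologue coding alignments on a calibrated
species tree, and a TPM expression matrix. All randomness flows from explicit
integer seeds; every `simulate_*` call is a pure function of (config, seed).

**Genome model.** Autosomes and an X are uniform-random sequence with
non-overlapping genes (uniform placement, proportional allocation across
regions). The X is tiled by pseudoautosomal segments (PAR) and strata, each
stratum carrying a recombination-arrest age in Ma; X intervals left
unannotated are merged into the oldest stratum. The Y is built from the X:
identical inside the PAR (recombination keeps them in lock-step), mutated
elsewhere, with each stratum's non-retained genes deleted outright. Y
retention per stratum is a rounded deterministic count so configured regimes
(e.g. 13 of 287 genes surviving) are reproduced exactly. Whether Y
degeneration proceeds by deletion or pseudogenization is not observable in
the source data; deletion is the simpler choice and is what the coverage
signal assumes.

Defaults: two 500 kb autosomes; a 500 kb X with PARs at [0, 50 kb) and
[450, 500 kb) and strata arrested at 62 Ma ([50, 300 kb)) and 20 Ma
([300, 450 kb)); 40 genes of 300 codons per chromosome; Y retention 0.25 per
stratum. These are desk-scale stand-ins for chromosome-scale data chosen so
that every window/filter statistic operates in the same regime as the study
(dozens of windows per class, hundreds of reads per window).

**Divergence model.** Sequence evolution is a codon-level Gillespie process:
synonymous changes fire at `syn_rate * S(codon)` (S = NG86 synonymous sites
of the current codon) and nonsynonymous changes at `nonsyn_rate * N(codon)`,
each picking a uniform neighbour of its class among *sense* codons — internal
stops are never created. The expected synonymous divergence of a branch of
length t is therefore `syn_rate * t` per synonymous site, giving the
closed-form pairwise expectation dS = 2·rate·t that the tests check.
Intergenic (noncoding) Y sequence diverges at the synonymous (neutral) rate
via a Jukes–Cantor site process. In the genome simulator both post-arrest
branches are collapsed onto the Y haplotype (total divergence 2·rate·t),
because the male and female X of one population are effectively identical;
the gametologue *alignment* simulator evolves the X and Y branches separately
on the species tree, which is what dating consumes.

Default rates are syn_rate = nonsyn_rate = 0.003 /site/Myr. The equality is
the relaxed-constraint regime of a degenerating Y (only dS enters any
analysis); the magnitude puts the two default strata at dS ≈ 0.37 and ≈ 0.12
— inside the observed gametologue range and on either side of the 0.2
stratum threshold — and at overall X/Y identities of ≈ 0.71 and ≈ 0.89,
cleanly on either side of the 0.8 "significant female alignment" threshold.

**What counts as a planted Y-specific transcript.** A retained Y gene is
recorded in the truth as male-specific only if its identity to the X copy is
below 0.8 — the same operational definition the validation step uses for
"absent from the female genome". Young gametologues (the 20 Ma stratum) are
genuinely present-by-homology in the female genome at ~0.89 identity: a
read-subtraction protocol cannot and should not call them male-specific,
although they remain dateable through dS. Subtraction recall is therefore
measured against sequence-level detectability, not against every retained Y
gene.

**Reads.** Error-free uniform reads with placeholder qualities; count per
haplotype copy is `round(depth * L / read_length)`. `SimConfig.depth_*` is
the *sample-level* (diploid) coverage; the sample helper requests depth/2
per haplotype so a 6× female sample yields 6× on autosomes and X and a 6×
male sample yields 3× on the X-specific region. DNA reads come from both
strands; RNA reads are strand-specific (forward), matching stranded
libraries. An error-rate knob exists and defaults to 0 — the subtraction
filters assume near-exact matching, as the source protocols do (no
mismatches in the k-mer screen). Consequences: mapping is exact, there are
no multi-mapping artefacts from sequencing error, and coverage noise is
purely Poisson. Real data adds GC bias, mappability holes and error-induced
filter leakage that these tests do not probe.

**Expression.** TPM = construction-time mean × log-normal noise
(`tpm_dispersion` = 0.5 natural-log σ; base means log-normal around 20 TPM).
Per tissue, a hemizygous X gene's male mean is one allele scaled by the
dosage factor — full → 2, none → 1, partial(c) → c, so the expected
log2(M/F) medians are 0, −1 and log2(c/2) (−0.415 at c = 1.5, the study's
incomplete-compensation regime and the default). Retained Y gametologues are
extra male-only rows at `y_expression_factor` × one allele. One sample per
sex × tissue mirrors the study's n = 1 design.

## Coverage classification

Windows (100 kb autosomes / 10 kb on the X; the final partial tile averages
its actual bases) are labelled from log2(M/F): within ±0.25 of −1 → X_HEMI;
within ±0.25 of 0 → PAR on the candidate X, AUTOSOMAL otherwise; below 1×
in either sample → NO_DATA; anything else → UNASSIGNED. The source analysis
states no numeric cutoff; ±0.25 was chosen so Poisson depth noise at 6×/10 kb
(σ(log2) ≈ 0.10) misclassifies ≈ 1% of windows, and it is configurable. PAR
segments are reported as contiguous label runs; how the original three PAR
segments were delimited is not stated in the source, so run-contiguity here
is a package decision. Swapping the input tracks maps the hemizygous
signature onto +1, which is how the ZW mirror case would present.

## Alignment contracts

External aligners are replaced by two desk-scale components behind a
documented contract (precomputed hit tables can be supplied instead):

* **ExactReadMapper** — exact full-length read placement (31-mer seed +
  verification, both strands), appropriate for error-free reads and for the
  strict read filters.
* **ExactSeedAligner** — best local ungapped hit: exact k-mer seeding, then
  +1/−1 scoring along the diagonal keeping the maximal-sum segment, so
  unalignable tails reduce the aligned fraction rather than diluting
  identity. Seed k = 31 for near-identical scaffold placement; the
  male/female validation uses k = 15 so homologues diverged 10–25% are still
  found and their identity measured against the significance thresholds.
  Ungapped extension is adequate because the simulator introduces no indels;
  with real indel-bearing data an external aligner should be plugged in via
  the hit-table interface.

## Subtraction

Reads with ambiguous bases are dropped before all stages. The female k-mer
index stores 35-mers of the female reads as given, with counts below 10
discarded (rare k-mers are not part of the female signature; the cutoff is
taken over the pooled female reads). Male reads are screened with no
mismatches and no indels against both their forward and reverse-complement
windows — conservative for stranded libraries, removing more reads, never
fewer. Reads shorter than k cannot be screened and are dropped with a
counted warning.

The assembler is a deterministic greedy overlap-layout: identical reads
collapse, then pairs with the longest exact suffix–prefix overlap
(≥ 30 nt) merge first, ties broken lexicographically; contigs that end as
substrings of another contig are dropped. This replaces a de Bruijn
transcriptome assembler deliberately: the surviving read set is tiny by
construction, reads are error-free, and determinism matters more than
scalability here.

Validation accepts a contig iff it hits the male genome at 100% identity
over ≥ 90% of its length and has no female hit with identity ≥ 0.8 over
≥ 0.5 of its length ("no significant alignment" is undefined in the source;
both thresholds are parameters). Precision/recall are scored at transcript
level by placing accepted contigs on the truth's Y gene intervals.

## dS, strata and dating

**NG86 counting.** Synonymous sites are fractional per position (changes to
stop codons count as nonsynonymous); differences average syn/nonsyn steps
over the orderings of the changed positions, excluding orderings that pass
through a stop (falling back to all orderings when every path is blocked);
ambiguous or gapped codons are excluded pairwise. Jukes–Cantor correction
inverts multiple hits; pS ≥ 3/4 raises a saturation error rather than
returning a number. The implementation is table-driven (64×64 precomputed
pathway counts) and is tested against an independent brute-force enumeration
oracle; the correction family (ML codon models would differ in the third
decimal at high divergence) does not move the 0.2-threshold decisions the
strata rest on. On simulated pairs the estimator tracks 2·rate·t within
~3% up to dS = 0.5.

**Strata.** Y-presence in the second corytophanid clade is authoritative
(present → stratum 1, arrest before that split; absent → stratum 2); the
dS > 0.2 rule is the provisional call when presence is unknown. The bundled
Y-gene catalogue reproduces the published bookkeeping: 6 genes above 0.2,
5 in stratum 1, 7 in stratum 2.

**Dating.** The stratum-1 alignments are concatenated and bootstrapped by
codon columns to the original length (codon-wise, not nucleotide-wise, to
preserve the reading frame that dS needs; the source does not say which was
used). Per replicate, branch lengths on the fixed gametologue topology (the
focal tip replaced by an X/Y cherry) are fitted by non-negative least
squares against the pairwise dS matrix — NNLS is exactly the
clamp-negative-branches-and-refit rule. Bootstrap-mean branch lengths are
then made ultrametric by a strict clock: each internal node's height is half
the mean tip-to-tip path distance across its child subtrees (WPGMA on the
fixed topology), which stays identifiable even where rooted branch lengths
individually are not; children deeper than their parent are clamped. The
calibration node is pinned to its age, all heights scale proportionally, the
X/Y node's age is the origin estimate, and the 95% CI is the 2.5th/97.5th
percentile of the replicate ages. A penalized-likelihood chronogram was the
source's tool; its smoothing parameter is unstated, and on clock-like
simulated data the strict clock is the assumption-free special case — both
substitutions sit behind the function boundary so external engines can be
swapped in. Ages rescale exactly linearly in the calibration age
(61.05 Ma at an 85.7 Ma calibration ↦ 62.69 Ma at 88 Ma).

The default dating tree contains only the focal species and the calibrating
outgroup (85.7 Ma split). Deeper outgroups (bird/mammal-scale, ≥ 300 Myr)
would saturate JC-corrected pairwise dS (observed pS ≥ 3/4) which this
distance-based stand-in cannot invert, and they contribute nothing to the
ratio — XY node height over calibration node height — that the estimate
actually uses.

## Dosage statistics

"Different from a distribution with fixed median m" is operationalized as a
one-sample Wilcoxon signed-rank test of (ratios − m); a literal two-sample
test against a constant is degenerate. Ratios are log2 (the −1 reference
implies base 2) with a 0.1 TPM pseudocount; genes under 1 TPM in both sexes
in a tissue are excluded from that tissue's ratio set. BH correction spans
all (tissue × reference) tests of a run. The call logic — reject only −1 →
BALANCED, only 0 → UNCOMPENSATED, both → INTERMEDIATE, neither →
INCONCLUSIVE — has an irreducible α-level error rate on regimes where one
reference is exactly true; the regime-recovery experiment therefore scores
the three regimes pooled (full/none/partial × 100 datasets each, n = 500 X
genes, one tissue), observed ≈ 96% correct. Ancestral per-allele expression
is the median of outgroup orthologue TPMs divided by 2; genes without
outgroup data are flagged and excluded from current/ancestral ratios. TSI is
max/sum over tissues (range [1/T, 1], all-zero genes flagged NaN), with 0.7
as the conventional specificity threshold.

Note that median-scaling normalization adds a small *correlated* per-sample
offset (the sampling noise of the shared-set median) to every ratio; with
hundreds of genes a signed-rank test can detect that offset, so
normalization should be used when samples are on genuinely different scales,
not as a reflex before ratio tests on already-commensurate data.

## Known limitations

* No read errors, indels, repeats or GC bias: coverage and subtraction
  results on real data will be noisier than the synthetic scores suggest.
* The greedy assembler and exact-match aligners are desk-scale by design;
  production-scale data should come in through the depth-track and hit-table
  interfaces.
* Strict-clock dating assumes rate homogeneity across branches; with real
  lineage rate variation the calibration-ratio estimate inherits that bias.
* The expression model is log-normal with one sample per sex × tissue;
  between-individual variance is not modelled.
* Coding-potential classification of candidate transcripts (the
  coding/noncoding split) requires external homology databases and is out of
  scope; candidate status is purely sequence-presence based.
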
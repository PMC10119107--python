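# Methods

## Coordinate model and site assignment

All positions are transcript-relative, 0-based, half-open; there is no
genomic or strand handling because footprints are assumed to be aligned to
a transcriptome. A footprint record is (transcript, 5′-end, length, count).

The A-site of a 28–30-nt monosome footprint is the nucleotide 15 nt
downstream of the 5′ end; its codon index is floor((A-nt − cds_start)/3),
and the read is in frame when (A-nt − cds_start) mod 3 = 0. P- and E-site
codons are one and two codons upstream, so for any single library the P-
and E-profiles are exact −1/−2 shifts of the A-profile — an identity the
tests assert rather than re-derive. Only lengths present in the offset
table (default 28–30 nt, all at 15 nt) contribute to occupancy; other
lengths are tallied as dropped. The first and last five codons of every CDS
are excluded from all profiles because densities around start and stop
codons are atypical; with the default coverage gates this requires CDSs of
at least 30 codons.

**Periodicity.** 3-nt periodicity per read length is scored as the modal
frame fraction of CDS-overlapping 5′ ends (1/3 = no periodicity, 1 = pure).
Lengths scoring ≥ 0.5 are retained; 20–22-nt footprints, which derive from
ribosomes with an open A-site and are not frame-pure, are excluded
regardless of score. Ties between frames resolve to the lower frame index;
a score of exactly 0.5 is retained (≥ comparison). Out-of-frame reads are
excluded from profiles by default since the A-site codon identity is
ill-defined off frame; a flag re-admits them for sensitivity analysis.

**Normalization.** RPM weight = count × 10⁶ / library size, with the
library size taken after length filtering (the analyzed footprints form
the denominator). A pre-filter denominator is available behind a flag. RPM
conservation (Σ = 10⁶) holds after every filter by construction and is
checked in the conservation suite.

## Relative occupancy, RUST, CV, TE

Relative occupancy pools positions across transcripts that pass a coverage
gate (default: mean density at least the RPM equivalent of one raw read
per codon, ≥ 100 analyzed codons; both config-exposed — the gate is stated
in raw-read terms because a fixed RPM cannot mean the same thing at
different depths). For identity *c*: ρ_c = mean RPM over positions carrying
*c* / mean RPM over all positions; the occurrence-weighted mean of ρ is 1
exactly. Position-level pooling (rather than per-transcript averaging) is
the default because it matches computing an average of normalized counts
and then correcting by the overall codon average; the per-transcript
variant exists behind a flag for sensitivity analysis. Amino-acid
aggregation is the n-weighted mean of ρ over synonymous codons. Stop codons
never appear in the analyzed window (they can only be the final codon) and
codons containing N are absent from the synthetic data; real imports with N
simply contribute their literal triplet and can be filtered downstream.

RUST binarizes each qualifying transcript's profile at its own mean
(strictly above = 1; ties count 0, so a constant transcript contributes no
enriched positions) and divides the codon-identity frequency among
1-positions by the frequency among all analyzed positions. This is robust
to coverage heterogeneity because each transcript contributes membership,
not magnitude.

Per-transcript CV is sd(ddof=1)/mean of A-site density over the analysis
window; the unit of observation is the transcript (one value per
transcript), which makes the CV distribution independent of transcript
count weighting. Under homogeneous dwell the CV is pure sampling noise and
falls as 1/√(mean count); heterogeneous dwell adds a depth-independent
component, which is why the CV contrast detects elongation perturbations.

TE = footprint density / mRNA density, both as reads per million per CDS
kilobase, so TE is invariant to either library's depth. TE is undefined
(NaN) when the RNA density is zero.

## Differential testing

Per-replicate position values are normalized as position RPM / transcript
mean RPM, which removes transcript-abundance differences between
genotypes and isolates local occupancy changes. Positions enter testing
when their codon identity is in the requested family and the mean raw
count reaches 5 in at least one group (config). The test is a two-sided
pooled-variance Student's t; degenerate cases are defined (zero variance
with equal means → p = 1, with unequal means → p = 0, flagged). BH
adjustment is applied within each amino-acid codon family separately,
mirroring per-amino-acid volcano plots; q < 0.05 flags a position.

Codon-level fold changes are log2 of the ratio of replicate-mean ρ between
conditions; identities missing or zero on either side are omitted and
listed. Cross-experiment concordance is Spearman's r over shared
identities (average-rank ties, two-sided p via the t approximation,
Bonferroni over the A/P/E family of three). Metagene profiles normalize
each anchor's ±W-codon window by its own mean before averaging over
anchors and then replicates, so deep and shallow anchors contribute
equally; a planted stall of factor s yields a peak-to-flank ratio of s.

The statistical primitives (pooled t, BH step-up, Mann-Whitney U with
exact enumeration for n ≤ 12 and a tie/continuity-corrected normal
approximation beyond, Spearman) are implemented in `ribodyn.stats` with
scipy used only for distribution functions; tests verify them against
brute-force enumerations and against scipy's independent implementations.
The exact MWU two-sided convention is 2·min(P(U ≤ u), P(U ≥ u)) capped at
1, which gives p = 1 for identical samples.

## Disome analysis

Disome fragments (50–80 nt) protect two collided ribosomes. No established
convention maps fragment ends to the stalled ribosome's codon, so the
package defines the leading-ribosome rule — A-site nt =
5′ + length − 15, the monosome offset applied from the 3′ end, pointing at
the downstream (stalled) ribosome — with the trailing alternative
(5′ + 15) behind a config switch. Frame purity is not required of disome
reads.

Peak calling is a declared rule, config-exposed: candidate codons with
density ≥ k_fold (default 4) × the transcript's median nonzero density and
raw count ≥ 5, merged when within 1 codon, summit at the maximum. The rule
is invariant to global library scaling. Cross-condition matching is greedy
nearest-summit within ±1 codon per transcript; fold changes are computed
over the union peak set with a 0.5-RPM pseudocount so condition-specific
peaks stay finite.

## Synthetic data: what it emulates and what it does not

The generator produces transcriptomes (ATG + interior sense codons +
stop, uniform codon usage by default so usage never confounds occupancy;
UTRs ≥ 18 nt so 15-nt offsets stay in bounds), then draws monosome A-site
positions multinomially with probability ∝ transcript abundance ×
dwell(codon) × per-site stall multiplier, restricted to the analyzed
window. Read lengths follow a configurable mixture (default dominant
28–30 nt with light 27/31 tails); a fraction of reads (default 5%) is
shifted ±1 nt to emulate imperfect digestion; replicate depths are
log-normally jittered (σ = 0.1); RNA-seq counts are multinomial in the
shared abundances. Disome reads place the leading ribosome on a planted
stall site with probability p_stall, else uniformly over codons where an
80-nt fragment fits (A-site nt ≥ 65), with lengths uniform on 50–80 nt.
Defaults mirror the four-replicates-per-genotype, ~10⁶-footprint design of
a bulk tissue experiment.

Not emulated: sequencing errors and FASTQ-level artifacts, rRNA
contamination, UMIs/duplicates, codon-pair or context-dependent dwell,
tRNA-charging dynamics, and biased codon usage unless configured. Passing
tests therefore demonstrate correctness of the estimators under the
model's assumptions — multinomial sampling with multiplicative dwell — not
robustness to alignment or library-prep artifacts.

Every stochastic operation takes an explicit integer seed (numpy
`default_rng`/`SeedSequence`); there is no global RNG state, and byte
replay of any run follows from the config.

## Validation studies and problem sizes

The studies in `ribodyn.scenarios` (run by `scripts/acceptance.py` and the
acceptance tests) use 15–25 transcripts of 150–250 codons and depths of
10⁵ (disome) to 2×10⁶ (power study) footprints — sizes at which each study
finishes in seconds while the estimators' sampling error is far from the
decision thresholds. Choices worth noting:

- **Dwell recovery** uses graded log-normal multipliers (σ = 0.4) over all
  61 codons; Spearman between planted and estimated log occupancy exceeds
  0.99. With only a few codons perturbed, rank ties among the unperturbed
  majority bound the attainable correlation well below 1, so the graded
  design is the meaningful recovery benchmark; the discrete Pro/Ala/Lys/Asn
  perturbation is checked separately as a 12/12 sign-concordance count.
- **Inverted-perturbation study**: the loss-like experiment plants the
  Pro/Ala ×1.5 and Lys/Asn ×0.8 extremes on top of a mild transcriptome-wide
  graded dwell shift (σ = 0.15), and the gain-like experiment inverts every
  multiplier exactly. The A-site fold-change correlation is then strongly
  negative (≈ −0.99) while the E-site correlation stays near zero, because
  identity-specific dwell acts at the decoded codon only.
- **Null calibration** (4 vs 4, no perturbation) keeps the raw p < 0.05
  fraction near 0.05 over >4000 positions; the power study plants ×2 stalls
  at 40 Pro positions and recovers ≥ 70% at q < 0.05. The realized
  false-flag fraction among significant positions fluctuates around the 5%
  BH target (binomially, with ~40 discoveries), which is why the purity
  margin is set at 10%.
- **Disome recovery** at p_stall = 0.5 and depth 10⁵ gives
  sensitivity = precision = 1.0 under the default peak rule.

## Known limitations

- Offsets are table-driven; there is no metagene-based offset learning, so
  imported data must use compatible digestion chemistry or supply offsets.
- The t-test has no variance moderation; at very low coverage the power
  study's gates (mean count ≥ 5) matter.
- The disome position convention is a modeling choice; conclusions that
  depend on the exact collision codon (±1–2 codons) should be checked under
  the trailing convention too.
- Venn decomposition supports at most four sets, matching the figures it
  serves.
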
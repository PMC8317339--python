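# Methods

## Scope and model

`bgerr` quantifies the background single-nucleotide substitution error
structure of UMI-tagged targeted deep sequencing, comparing paired plasma
cfDNA and leucocyte gDNA libraries. The object of inference is the
per-class background error rate after digital error suppression and
filtering — not variant calls. Indels and multi-nucleotide events are out
of scope, as are alignment, base-quality recalibration and adapter handling
(inputs are assumed aligned and recalibrated).

Substitutions are classed directionally (12 classes) and collapsed into 6
strand-symmetric classes by reverse-complement pairing, labelled
pyrimidine-first (`C:G>T:A`). Internally all coordinates are 0-based
half-open; serialized report tables are the place for 1-based conversion.
Observed or reference `N` bases are dropped from numerator and denominator
alike.

## Filtering rules

| rule | default | notes |
|------|---------|-------|
| reference allele excluded | — | definitional |
| base quality | Phred ≥ 30 | applied before any counting; removed bases leave the denominator |
| depth | ≥ 500× | evaluated on post-filter (and, when consensus ran, post-consensus) depth, jointly across the sample pair; for multi-sample position tables a position must reach depth in **all** samples |
| germline/blacklist | AF > 1% in either pair member | masks the specific (position, alternate allele), not the whole site, in both members; allele fractions are computed pre-masking on filtered depths |

Masked allele depths are removed from class numerators only; the
denominator remains total retained depth, so counts always conserve:
errors + reference bases + masked bases = all eligible bases.

Per-class denominators are reference-base opportunities (`C>T` errors per
sequenced C). This is the self-consistent reading of "errors per sequenced
base" when classes are reported separately; a total-base denominator
(`ErrorProfile.rates_total_denominator`) is kept for comparison with
reports that normalise by all sequenced bases.

## UMI consensus (digital error suppression)

Families are keyed by (UMI, chromosome, fragment start, fragment end,
strand of R1) — a single-strand scheme; duplex pairing is deliberately not
attempted because the motivating assay's UMI is a short single index-read
barcode. Consensus is strict majority per covered position among member
reads (mates vote independently where they overlap); ties are dropped,
singleton families pass through, and the consensus base inherits the
maximum supporting quality and the minimum supporting breakpoint distance.
UMI sequencing errors are not merged away by default (no Hamming-distance
clustering); at short UMI lengths over-merging is the larger risk.

These choices make the suppression asymmetry explicit: errors in the
template molecule (DNA lesions, first-cycle PCR) are family-wide and
survive consensus; later errors are minorities and are removed wherever a
family has ≥ 3 members covering the position. With the realistic mean
progeny of 2.79 (zero-truncated Poisson), a large singleton fraction
remains, so the overall reduction is partial — simulated totals drop
roughly 20–30%, consistent with the modest reductions that motivated
profiling lesion-derived background rather than relying on suppression.

Two consensus implementations exist: a per-family generator (the reference
semantics) and a grouped-aggregation path for millions of observations;
their exact equivalence is asserted in the tests.

## Fragment-end analysis

Each base's distance from its read's 5′ end — which coincides with a
physical fragment breakpoint in both native cfDNA and sonicated gDNA
libraries — is binned at 5 bp (bins 1–10 over distances 1–50; farther
cycles are not binned). Rates per (bin, class) use the same filters and
masks as the global profile. Contrasts: bin 1 vs pooled bins 2–10 on the
total rate per group; per class, bin 1 vs bin 2 and bin 1 vs bins 2–10
within groups; and a between-group test on the per-sample end-elevation
contrast (bin 1 minus the interior mean). Class families are
Bonferroni-corrected. Contrasts are computed for both directional and
collapsed classes; the collapsed table is the primary read-out because
end-damage chemistry (8-oxo-G) is strand-symmetric and the pooled counts
double the events behind each test.

## Statistics

Welch (unequal-variance) t-tests are used throughout on per-sample rates on
the raw scale. Class-wise comparisons correct across the 12 (or 6) class
tests; the total rate is tested separately, uncorrected. Per-position
tests are corrected within each reference-base family (default Bonferroni;
Benjamini–Hochberg and uncorrected available), because the families are
reported separately and probe different contexts. Zero-variance
degeneracies resolve deterministically: both groups constant and equal →
p = 1, counted untestable; constant but different → flagged with a p = 0
sentinel so downstream audits can see them.

A conservatism caveat, measured rather than assumed: with five samples per
group, Welch's far-tail rejection rate at p < 0.05/12 is ≈ 0.6× nominal
even for ideal normal data (independent Monte Carlo; the Welch–Satterthwaite
approximation under-rejects deep in the tail at small n). The null
calibration test therefore asserts the one-sided guarantee — type-I error
at Bonferroni-adjusted α never exceeds α — which is also the invariant the
analysis relies on.

## Synthetic data

The generator states two worlds that differ only in the damage signal of
interest:

* **cfDNA-like** — uniform, position-independent elevation of C>T and G>A
  (cytosine deamination accumulating in circulating DNA);
* **gDNA-like** — a 5× multiplier on C>A/G>T within the first 5 bp of each
  fragment end (guanine oxidation at sonication breakpoints).

Counts mode draws multinomial allele depths per position at fixed depth
(default 1000×, 50 kb panel, 5 samples/group) with per-class rates set so
group totals are 5.7×10⁻⁵ vs 2.7×10⁻⁵ at uniform base composition (base
rate 0.9×10⁻⁵ per class; cfDNA C>T = G>A = 6.9×10⁻⁵). Reads mode simulates
molecules end-to-end — fragments (167 bp cfDNA-like, 450 bp gDNA-like;
100 bp paired reads), germline alleles and damage applied at the molecule
level *before* amplification, zero-truncated-Poisson progeny (mean 2.79),
then per-read sequencer miscalls at the Phred-implied rate of each base's
drawn quality (default Q37; planted miscalls keep ordinary qualities, so
the Q30 filter sees calibrated data unless a stress distribution is
configured). Reads-mode per-class background rates default to 1×10⁻⁴
(cfDNA C>T/G>A 3×10⁻⁴) — the top of the realistic 10⁻⁵–10⁻⁴ range — a
power choice so that 10⁴–2×10⁴ fragments per sample carry enough error
events for the bin statistics at desk scale. Default UMI length is 8 bp:
on a kilobase-scale panel, 4 bp UMIs collide between fragments sharing
coordinates, a compression artifact rather than a property of the assay;
the length is configurable.

Every planted cause is recorded in a ledger (germline sites per pair,
per-event damage/PCR/sequencer records, per-fragment family sizes), and the
tests check attribution completeness: every non-reference base in the
output is explained by exactly one ledger category. Reads mode emits
either in-memory observation frames or coordinate-sorted indexed BAMs with
RX tags plus FASTA/BED; the two routes are asserted observation-for-
observation identical, so fast tests can use frames while the BAM path
stays covered.

What a green test does **not** establish: the simulator draws i.i.d.
errors given the planted rates — no sequence-context dependence beyond the
planted classes, no cycle-dependent quality decay, no homopolymer effects,
no mappability structure, and germline variation is planted at exact
het/hom allele fractions. Green therefore means the *pipeline arithmetic
and statistics* behave as specified under the stated world, not that real
panel data will show these magnitudes.

## Numerical and degenerate-input choices

* Rates with zero eligible bases are NaN and reported missing; relative
  changes against a zero baseline likewise.
* Consensus tie-break is "drop the position" (never a coin flip), keeping
  the pipeline deterministic; all randomness flows from a single integer
  seed through `numpy` `SeedSequence` spawning.
* The signature refit is non-negative least squares on the 96-channel
  fraction vector, with weights reported as fractions of their total;
  signature matrices must have unit column sums. Events lacking ±1 bp
  context (contig edges) are dropped and counted.
* Mate-overlap bases are both counted by default (plain pileup semantics,
  and consensus already collapses within-family redundancy);
  ``dedup_mate_overlap`` switches to one count per fragment and position,
  keeping the higher-quality mate.
* UMI consensus options: ``rule`` (strict majority, default, or unanimous),
  ``keep_singletons`` (default on — with mean progeny 2.79 a large fraction
  of templates are singletons, and dropping them would discard most of the
  data), and an off-by-default Hamming-1 UMI merge for families sharing
  fragment coordinates.

## Known limitations

* Single-strand consensus only; duplex designs would need a second pairing
  stage.
* The per-position test treats samples as independent group members (no
  donor-paired or mixed-effects modelling), matching the source analysis.
* Counts mode has no read-position axis, so fragment-end effects exist only
  in reads mode.
* The exact consensus rule of the assay this models is underdocumented
  upstream; the strict-majority/tie-drop/keep-singletons rule is a stated
  default consistent with the observed suppression magnitudes, not a
  reconstruction.
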
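# Methods

## The assay model

MQF-PCR exploits internal competitive PCR: one primer pair amplifies a
segment of a disease critical region (*test*) and a near-identical
paralogous segment elsewhere (*control*). Because both products share
primers in one reaction, tube-to-tube amplification variability cancels,
and the ratio of their fluorescent peak areas is proportional to the
ratio of their template copy numbers. The two products must differ in
length by a small net indel δ (1–10 bp): large enough for capillary
electrophoresis to separate, small enough that amplification efficiency
stays comparable.

The pipeline stages and their governing conventions:

**Coordinates.** Externally 1-based inclusive everywhere (intervals print
as `chrom:start-end`); BED input is 0-based half-open and converted on
read; all 0-based arithmetic is internal.

**Homology search** (`homolog_finder`). Long regions are tiled into
100–200 kb chunks (target 150 kb, 500 bp overlap so no candidate segment
is split). Pair detection is k-mer seeded (k = 15, the scale of a
conserved primer site), clusters seeds by diagonal, and polishes each
cluster with a local alignment of the seeded windows under BLASTN-like
scores (match +1, mismatch −2, gap of length L costs 5 + 2L). Defaults:
identity ≥ 0.85, aligned length ≥ 80 bp (room for two primer sites plus
an inter-primer region), |δ| ∈ [1, 10]; δ = 0 is rejected outright
because equal-size products cannot be resolved. Both subject strands are
searched; hits are reported on the + strand with a strand flag.
Score ties break toward smaller |δ|, then leftmost query coordinate, for
reproducibility. On instances up to ~2 kb the detected segment agrees
with a full Smith–Waterman dynamic program (kept as an independent test
oracle only) to within 5 bp of boundary slack and with identical δ.

**Primer design** (`primer_design`). Conserved stretches are maximal
gap-free alignment windows of ≥ 15 bp with ≤ 2 mismatch columns;
mismatch columns become IUPAC ambiguity codes, so a single degenerate
primer covers both templates. The forward primer comes from a stretch
left of the leftmost indel (3' end pushed toward the indel), the reverse
primer is the reverse complement of a stretch right of the rightmost
indel; windows are 15–25 nt with 20 preferred. The 3'-terminal three
bases must be non-degenerate — polymerase extension needs a matched 3'
terminus, so degeneracy there is never tolerated. The forward primer is
tailed with M13-40 (`GTTTTCCCAGTCACGAC`) for single-dye universal
labelling; the reverse primer gets a PIG-tail (`GTTTCTT`) to drive
complete 3' adenylation and sharp sizing. Electrophoretic product size is
therefore the genomic span + 24 bp; the +A adenylation base is not added,
a deliberate ±1 bp calibration ambiguity noted below. QC: GC fraction on
the untailed core (degenerate bases at expected value; S = 1, W = 0,
others 0.5) must lie in [0.30, 0.70]; nearest-neighbor Tm (50 mM
monovalent salt, 250 nM primer, evaluated on the highest-AT expansion as
the conservative case) in [52, 65] °C; zero mispriming sites (any binding
site beyond the two intended). Products are constrained to 80–300 bp
untailed, the scale of the validated assays.

**In-silico PCR** (`insilico_pcr`). A primer binds where every core
position matches the template under the IUPAC expansion with ≤ 2
mismatches, except the 3'-terminal 5 bases which must match exactly.
Tails never participate in matching. Products are properly oriented site
pairs within 1–1000 bp, sized outermost-to-outermost of the core
footprints; a valid assay yields exactly two products with distinct sizes
differing by 1–10 bp. Candidate assays are screened against exclusion
intervals (known CNVs/SNPs as BED): any ≥ 1 bp overlap of an amplicon
with an exclusion fails the assay, since a polymorphism under a primer or
product would distort dosage.

**Dosage statistics** (`dosage_stats`). Peak tables are
GeneMapper-export-like TSV (Sample/Size/Height/Area, fractional sizes).
Peak assignment takes the largest-area peak strictly within ±1.0 bp of
each expected tailed size (capillary sizing precision is ≈ 0.5 bp);
samples missing either peak are reported, never imputed. The normalized
ratio divides each sample's test/control area ratio by the reference
pool's; replicate reference ratios are averaged arithmetically. The
choice between Z and pseudo-Z is made once per cohort: the
D'Agostino–Pearson omnibus test (K² = Z(skew)² + Z(kurt)² against χ²
with 2 df, α = 0.05) gates to Z when normality is not rejected; cohorts
under n = 20 — below the test's validity floor — route directly to
pseudo-Z. Pseudo-Z uses the median and the pseudo standard deviation
IQR/1.349 with linear-interpolation quartiles, the Gaussian-consistent
robust scale. ROC analysis is fully empirical: candidate thresholds are
midpoints between consecutive distinct scores, AUC is the trapezoid area
(identical to the concordant-pair / Mann–Whitney statistic, ties credited
0.5), the operating threshold maximizes Youden's J with ties broken
toward higher specificity, and calls use strict inequality (a score
exactly at threshold is normal). Predictive values (PPV, NPV and their
false-call complements) carry continuity-corrected Wilson 95% intervals,
clipped to [0, 100]%; fields with a zero denominator are reported absent.
No multiple-testing correction is applied: each sample is tested with a
single assay.

## Synthetic data

The generators define the package's study conditions.

`make_paralog_genome` plants a segment pair with exactly conserved
primer-site stretches (default 20 bp) at both segment ends, point
substitutions tuned to the target identity (default 0.95) strictly
between the sites, and one deletion of δ bp (default geometry mirrors the
validated assays: a few-hundred-bp segment, δ ∈ 1–10) midway between
them. Flanks are random and re-drawn until neither site has a spurious
binding site elsewhere, so the designed assay provably has exactly two
products. Limitations: real paralog pairs carry scattered indels, repeat
structure and GC heterogeneity that this generator does not emulate, so
passing tests demonstrate correctness of the machinery, not genome-wide
design yield.

`simulate_cohort` models each peak area as
`area = A0 · copies · bias · ε` with ε lognormal (mean exactly 1,
σ² = ln(1+cv²)) — fluorescence areas are positive and right-skewed, and
at high CV the lognormal skew is what exercises the pseudo-Z path. The
test amplicon optionally carries a multiplicative efficiency bias, which
the reference-pool normalization must (and does) cancel. One reference
sample with population-mean copy numbers and ε = 1 is always included.
Peak sizes get ≤ 0.3 bp uniform jitter. Defaults — 100 controls
(matching the 100-individual reference-pool scale the assays were
validated against), 14 cases, CV 5% — are the cohort conditions used
throughout the tests and the acceptance script. Not simulated: PCR
stutter, pull-up, dye-specific mobility, degraded-template effects.

## Numerical and design choices

* Alignment scoring (match +1 / mismatch −2 / gap open −5 / extend −2)
  follows common BLASTN practice; Biopython's aligner is configured so a
  length-L gap costs exactly 5 + 2L, and the test oracles use the same
  convention.
* The first optimal alignment in Biopython's deterministic enumeration is
  used when optima tie; downstream sorting makes emitted pairs and assays
  reproducible run to run.
* Quartiles everywhere use linear interpolation (NumPy default), so
  pseudo-Z values are continuous in the data.
* Determinism: every stochastic artifact flows from a single integer
  seed through `numpy.random.default_rng`; identical seeds give
  byte-identical FASTA/TSV output.
* Published fragment sizes vs. coordinate spans: for two of the four
  catalog assays the printed electrophoretic size difference (4 bp, 6 bp)
  differs from the difference of the genomic coordinate spans (2 bp,
  5 bp). Tail arithmetic (+24) cannot reconcile them exactly; the catalog
  stores both as reported and treats the electrophoretic sizes as the
  sizing truth, with the discrepancy attributed to sizing calibration and
  the un-modelled +A base.
* Degenerate bases are confined to the primer side; templates must be
  concrete. An N-rich template would make "binding" ill-defined.

## Known limitations

* The homology search is windowed-heuristic; it is validated against full
  DP up to ~2 kb instances but is not intended for all-vs-all genome
  scans (no FM-index/suffix-array backend).
* Tm is a nearest-neighbor estimate at fixed salt/primer concentrations;
  no hairpin/dimer thermodynamics beyond a complementary-run heuristic.
* ROC threshold selection on perfectly separated cohorts returns the
  midpoint of the separating gap; with real, noisier cohorts the
  threshold should be re-derived on each lab's own control set.
* Wilson-CC interval bounds depend on the control-cohort size; reported
  CIs are only as transferable as that cohort.
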
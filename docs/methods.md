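# Methods

This note documents the models, parameter choices and numerical decisions
behind `rohsweep`, and what the synthetic-data tests do and do not show
about real SNP-array data.

## Data model and conventions

Genotypes are alt-allele dosages in {0, 1, 2} with a reserved negative
sentinel for missing calls ("0 0" in .ped, the two-bit 01 code in .bed).
Positions are 1-based inclusive base pairs everywhere internally (PLINK
convention); BED output converts to 0-based half-open. Marker maps are
sorted by (chromosome, position) on load — unsorted input is sorted with
a warning, duplicate positions are allowed, duplicate marker ids are not.
Phased haplotypes are binary (0 ancestral, 1 derived) and must be
complete; rows 2i and 2i+1 belong to individual i.

Text-format round trips preserve allele-level genotypes exactly, and the
dosage coding bit-exactly whenever both alleles of a marker are observed:
a 4-column .map cannot record which allele a monomorphic marker's dosage
counts, which is PLINK's own .ped limitation. Binary round trips are
bit-exact always. Allele harmonisation/strand flipping across panels is
deliberately not attempted; merges error on any allele-label conflict.

QC order follows PLINK: non-autosomal markers out first, then individuals
with missing fraction strictly above 0.10, then SNPs with missing
fraction (computed on the survivors) strictly above 0.05. No MAF, HWE or
LD filtering happens at this stage — those would bias homozygosity-based
statistics. QC is idempotent.

## ROH detection

The detector implements the scanning-window algorithm: a window of
`window_snp` consecutive SNPs slides per individual per chromosome; a
window is a hit when it has at most `window_het` (default 0)
heterozygous and `window_missing` (default 1) missing calls. Candidate
stretches are split at inter-marker gaps above `max_gap_kb` (1,000),
trimmed of terminal heterozygous/missing calls, and filtered by
`min_snp` (defaults to the window size), `min_length_kb` (1,000) and
density (≥1 SNP per 150 kb). Segment ends are the positions of the first
and last constituent SNP, so length = end − start + 1.

Two seeding modes exist:

* **extended mode (default)** — any SNP covered by at least one hit
  window seeds a run, and candidate segments are extended outward over
  consecutive homozygous, gap-compatible calls to the *maximal
  zero-heterozygote stretch*. This preserves the continuity and
  integrity of the homozygous segment: the raw fraction rule below loses
  roughly `ceil(0.05·L)` outer SNPs per edge and silently drops clean
  stretches only marginally longer than the window (those with
  `L ≤ S < L + ceil(0.05·L) − 1` clean SNPs have hit windows but no SNP
  clearing the 5% fraction). In extended mode the detector's output on
  complete data is provably identical to exhaustive enumeration of
  maximal zero-heterozygote stretches followed by the same filters — the
  property the test suite verifies against a brute-force oracle on
  hundreds of random panels.
* **PLINK-faithful mode** (`extend_segments=False`) — a SNP is in-run
  when at least `hit_threshold` (0.05) of the windows overlapping it are
  hits, verbatim, including the outer-SNP loss.

Missing calls inside a run are tolerated (they are not heterozygous) but
count against density; the per-window missing allowance means the
equality with the enumeration oracle is exact only on complete data —
with missingness the two can legitimately differ when every window over
a stretch exceeds the missing allowance.

The window size can be chosen by the L-parameter,
`L = ln(α/(n_SNP·n_ind)) / ln(1 − het̄)` with α = 0.05, returned raw and
as the integer ceiling; values above a configurable cap (default 1,000)
raise, since they indicate heterozygosity too low for a meaningful
window. Published per-breed window sizes (KUR 61, NDA 66, ZBO 65,
ZFU 68) are available as presets.

Length classes are left-closed, right-open — [1,4), [4,6), [6,8),
[8,∞) Mb — because a partition is mandatory and the conventional
"1–4 / 4–6" notation is ambiguous at shared endpoints. Chromosome length
defaults to the position of the last mapped SNP; a user table overrides
(this affects both coverage % and the F_ROH denominator).

## Inbreeding coefficients

F_ROH divides summed segment length by `L_AUTO`, defaulting to the
mapped autosomal extent ("genome covered by SNPs"). F_GRM, F_HOM and
F_UNI are the GCTA/PLINK `--ibc` Fhat1/Fhat2/Fhat3 estimators; the
excess-homozygosity form `(O_hom − E_hom)/(m − E_hom)` is algebraically
identical to `1 − Σx(2−x)/Σ2p(1−p)`. Allele frequencies are sample
frequencies of the analysis population computed after QC (per-breed when
run per breed) — merged vs per-breed references change these three
estimators, which is why the frequency vector is an explicit argument.
Monomorphic markers are excluded from the three marker-based estimators
only, never from ROH detection; an individual's missing calls are
skipped with its marker count adjusted. Sample standard deviation (n−1)
is used wherever a variance estimate appears.

Closed-form anchor cells, each verified symbolically before being frozen
into tests: an all-heterozygote individual at p = 0.5 has
F_GRM = F_HOM = F_UNI = −1; an all-homozygote-alt individual has
F_GRM = F_HOM = +1 and F_UNI = (4 − 4 + 0.5)/0.5 = +1. With sample
allele frequencies estimated from n individuals these estimators carry
the usual −1/(2n−1) small-sample bias; null tests therefore supply the
generating frequencies.

## ROH islands

Incidence at a marker is 100 × (individuals with ≥1 ROH covering its
position)/N. Mean and standard deviation are taken over all autosomal
markers of the population jointly (not per chromosome); a marker is
significant when Φ(z) > 1 − tail (default tail 0.1%) *and* incidence
≥ 20%. The Gaussian-CDF reading is primary; an empirical-percentile mode
exists because the two differ on skewed incidence distributions. The
20% floor can only shrink the called set — it exists to stop the
relative z-rule from firing in populations where ROH are rare. Islands
span their first to last member SNP; zero incidence variance yields no
islands with a warning, not an error.

## iHS scan

EHH of a core allele at a target marker is the probability that two
random carrier haplotypes are identical at every marker from core to
target inclusive, `Σ n_h(n_h−1)/n(n−1)`; it equals 1 at the core and is
non-increasing outward (partitions only refine). iHH integrates EHH
against physical position by trapezoids, marching marker-by-marker
outward separately left and right: a side stops after the first marker
with EHH < 0.05 (that final trapezoid included), at the chromosome end,
or before an inter-marker gap above 1 Mb (integration truncated at the
last marker before the gap). Physical distance is used throughout; no
genetic map is consumed. Markers fixed among carriers mid-integration
need no special casing — the pair-count formula handles them.

Markers need derived-allele frequency in [0.05, 0.95] and positive
finite iHH on both alleles; `uniHS = ln(iHH_A/iHH_D)` is standardised to
mean 0, sd 1 within left-closed 0.025-wide derived-frequency bins
(frequency 1.0 would belong to the last bin but is excluded by the MAF
filter; a small epsilon keeps exact bin-edge frequencies such as 0.30 in
their left-closed bin despite floating-point division). Bins with fewer
than two members or zero spread are dropped with a log message.
`p_iHS = −log10(2Φ(−|iHS|))` is two-sided by construction — a sweep on
the derived allele drives iHS negative, and the windowing operates on
p_iHS, so both signs count.

Candidate windows are 1 Mb wide. "Each window overlapping the next by
100 kb" is read literally (step 900 kb, the default); the rehh
convention, where the second argument is the step itself (100 kb), is
available as `step_mode="rehh"`. A window is significant with ≥2 markers
above p_iHS 4; overlapping significant windows merge.

## LD pruning and PCA

Pruning slides a 50-SNP window in 10-SNP steps; within a window the
highest-r² pair above 0.1 (squared Pearson correlation of dosages,
pairwise-complete over missing calls) loses its smaller-MAF member (ties:
the later map position), repeating until stable — deterministic given
that tie-break. PCA mean-imputes missing dosages at 2p, centres, and
standardises by √(2p(1−p)) — the GRM convention, matching F_GRM — then
eigendecomposes the sample covariance; explained variance is the
eigenvalue as a percentage of the trace, so the full spectrum sums to
100%. Mean imputation shrinks variance slightly; component signs are
unconstrained. Zero-variance markers are dropped with a log message.

## Annotation

GFF3 parsing keeps only `gene` features (coordinates already 1-based
inclusive); BED input shifts start by +1. Overlap is inclusive at both
ends — a single shared base pair, including an exact end-to-start touch,
counts — stated explicitly because the two formats disagree at interval
edges. No flanking window is added around regions. Chromosome names are
normalised by stripping a `chr` prefix; names present on one side only
produce a warning.

## Synthetic data: what it emulates, and what it does not

The generator emulates a 50K-chip panel: exponential inter-marker gaps
with mean 51 kb, minor-allele frequencies uniform on (0.05, 0.5] with
the derived allele assigned to the minor or major state with equal
probability (as in ancestrally oriented real data — this matters, since
derived-frequency bins above 0.5 must contain neutral markers for the
standardisation to work at swept loci). The neutral background is
**linkage equilibrium**: alleles independent across markers. This is a
deliberate simplification — it makes planted ROH and sweeps the only
long-range haplotype structure, so recovery tests are sharp — but real
array data has substantial background LD, with consequences noted below.

Planted ROH overwrite one individual's second haplotype with the first
over the tract; truth intervals are recorded snapped to the covered
markers, making boundary recovery well defined. Planted sweeps assign a
chosen fraction of haplotypes one identical sequence over ±shared length
around the core (EHH exactly 1 among carriers) with the core derived
allele confined to carriers. Structure uses Balding–Nichols Beta draws
around a shared ancestral frequency. Missingness masks genotypes only;
haplotype panels stay complete, since phased input is assumed complete
downstream. All generators are pure functions of their seed.

Recovery of a planted tract is bounded by biology, not code: markers
flanking a tract are homozygous by chance with probability ≥ 0.5 under
linkage equilibrium, so the maximal zero-heterozygote stretch extends a
geometrically distributed number of intervals (~1–2 in expectation)
beyond the planted edge. F_ROH recovery on tracts of a few Mb at 51-kb
spacing is therefore accurate to a few percent (positively biased), well
within the ±10% the acceptance check uses.

## Calibration results and a known limitation

The standardisation makes each populated frequency bin's iHS mean 0 and
sd 1 to machine precision — that part of the neutral calibration is
exact by construction. The *tails*, however, are heavier than Gaussian
under the LE background: EHH collapses within ~2–3 markers regardless of
physical spacing, so iHH is nearly discrete, bin standard deviations are
small, and occasional chance extended sharing yields |iHS| > 4 at a rate
of ~1e-3 rather than the ~1e-4 a Gaussian null implies (excess kurtosis
≈ 0.5–1, insensitive to 30 vs 100 individuals; the EHH/iHH values
themselves match an exhaustive pair-count oracle, so this is the true
sampling distribution of the statistic under this background, not an
implementation artifact). Background LD — deliberately absent here — is
what smooths the EHH decay over many markers and thins the tail on real
data. One test documents and checks the Gaussian-order expectation and
currently fails under the LE background; it is kept failing rather than
loosened, as an honest record of this model-vs-statistic mismatch.
Consequently the sweep-detection study sets its own bar empirically: on
60-individual panels over two 30-Mb chromosomes (~1,150 markers), planted
hard sweeps with shared length 1 Mb and derived frequencies spanning
0.2–0.8 produce a candidate region containing the core in ≥90% of 50
replicates, despite the inflated neutral tail.

Problem sizes used by the test suite and the acceptance script — panels
of up to ~20k markers (40 × 25-Mb or 20 × 50-Mb autosomes at 51-kb
spacing, 8–60 individuals), 100-panel oracle comparisons, 50 sweep
replicates, one million simulated incidence values — were chosen as the
smallest scales at which the statistics of interest (binomial error of
the island tail, bin occupancy of the standardisation, chance-extension
bias of tract recovery) are comfortably resolved.

## Other known limitations

* No VCF ingestion, imputation, phasing or assembly lift-over; phased
  haplotypes must arrive as Oxford haps/sample.
* No coalescent simulation, recombination maps or mutation models; the
  generator does not emulate cattle demography.
* Ancestral-allele assignment for iHS accepts a user table or a
  major-allele fallback (flagged per marker); with the fallback, derived
  frequencies are ≤ 0.5 by construction and sweeps that carried the
  derived allele to high frequency will have their sign convention
  flipped — a user table from an outgroup is preferable when available.
* ANOVA/post-hoc breed comparisons and Manhattan-plot rendering are out
  of scope; the pipeline emits plot-ready TSVs instead.
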
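# Methods

This note documents the models, estimators and numerical conventions
implemented in `rohscan`, the design decisions taken where the choices
were genuinely open, and what the synthetic-data validation does and
does not establish.

## Data model and coordinates

Genotypes are held as a samples × variants ALT-dosage matrix in
{0, 1, 2, −1}, with −1 a missing-call sentinel (never conflated with
dosage 0). Haplotypes (n × 2 × m binary) are attached only when every
non-missing call in the source VCF was phased; a single unphased call
disables phase for the whole matrix, because downstream EHH statistics
are meaningless on partially phased data. Variant positions are 1-based
(VCF convention); interval sets are 0-based half-open (BED convention);
conversion happens only at the I/O boundary, so interval algebra inside
the package is unambiguous. VCF parsing uses cyvcf2 and consumes GT
only; multi-allelic and non-SNP records are skipped and counted.

## Marker QC

Samples with call rate ≤ 0.90 are removed first, then SNPs failing call
rate (≤ 0.95), Hardy–Weinberg equilibrium (p < 1e−5) or a MAF floor.
The HWE test is the exact conditional test: conditioning on the observed
allele counts, the p-value sums the probabilities of all heterozygote
counts no more probable than the observed one, computed by the standard
two-sided recurrence without mid-p correction. The exact test (rather
than a chi-square) is a deliberate choice — genotype QC conventionally
uses it, and at cohort sizes of 10–50 birds asymptotic tests are
unreliable in exactly the tail this filter uses.

## Diversity statistics

He = 2p(1−p) is reported without small-sample correction by default
(the 2n/(2n−1) correction is available by flag). r² is the squared
Pearson correlation of ALT dosages over jointly called samples
(composite LD) — deterministic and directly checkable against a
brute-force oracle, unlike EM-based haplotype r²; at the panel sizes
targeted here the difference is negligible. LD pruning follows the
indep-pairwise convention: within each 50-SNP window (advancing by 10),
while any retained pair exceeds r² = 0.2 the lower-MAF member is
removed, ties dropping the later position; the pass is deterministic.
PCA standardises dosages by mean 2p and sd sqrt(2p(1−p)), imputes
missing calls at the mean, and fixes component signs by making the
largest-magnitude coordinate positive.

The Weir–Cockerham (1984) two-population estimator computes per-SNP
variance components a (between populations), b (between individuals
within populations) and c (within individuals) from sample sizes,
allele frequencies and observed heterozygote fractions. The headline
genome-wide value is the ratio of sums Σa/Σ(a+b+c) — the standard
recommendation, least biased when per-SNP denominators vary — with the
mean of per-SNP ratios also reported. Negative per-SNP components are
retained, not clamped; SNPs monomorphic across both cohorts or with
fewer than two called individuals in either are excluded from the sums.

## ROH detection

Detection follows the scanning-window parameterisation with defaults:
window of 50 SNPs, ≤ 3 heterozygous and ≤ 5 missing calls per eligible
window, SNP in-state when ≥ 5% of its covering windows are eligible,
minimum 50 SNPs and 300 kb per segment, mean density ≥ 1 SNP / 50 kb,
and splitting at inter-SNP gaps > 1000 kb. Conventions the parameter
names do not pin down, decided here:

- candidate runs are trimmed so both ends are homozygous non-missing
  calls (prevents heterozygous termini inflating segment length);
- no segment-level heterozygote cap beyond the window-level limits;
- windows never cross chromosome boundaries, and SNPs near chromosome
  ends use their actual covering-window count in the hit fraction;
- the density test uses mean spacing (length / SNP count), the simplest
  reading of "1 SNP per 50 kb";
- size classes: < 1 Mb short, 1–3 Mb inclusive medium, > 3 Mb long
  (boundary mass is measure-zero in practice).

Detection expects the per-population MAF ≥ 0.01 filter already applied;
without it, runs of SNPs that happen to be monomorphic in the cohort
read as spurious homozygosity. The implementation is vectorised with
cumulative sums but is checked segment-for-segment against a plain-loop
reference on randomized instances.

A property of the window rule worth knowing: segments overrun a true
autozygous tract by up to ~15–20 SNPs per side, because windows
straddling the boundary can still satisfy the heterozygote allowance.
The overrun is a SNP-count effect, so its physical size scales with SNP
spacing; at 1 SNP / 5 kb it is ~100 kb per side.

## Inbreeding coefficients

F_ROH = ΣL_ROH / L_aut, with L_aut the SNP-covered autosome length
(per chromosome, last minus first SNP position, summed). F_HOM =
(O − E)/(L − E) with E = Σ_j [1 − 2p_j(1−p_j)·T_j/(T_j−1)], using the
T/(T−1) small-sample correction (an uncorrected variant is available).
F_GRM and F_UNI are the standard SNP-by-SNP diagonal-GRM and
uniting-gametes estimators

    F_GRM = (1/m) Σ_j (x_j − 2p_j)² / (2p_j(1−p_j)) − 1
    F_UNI = (1/m) Σ_j [x_j² − (1+2p_j)x_j + 2p_j²] / (2p_j(1−p_j))

over the sample's non-missing polymorphic SNPs. Allele frequencies are
computed within the analysed cohort; when cohorts are populations, apply
the functions per population — consistent with per-population SNP
filtering upstream.

## ROH islands

A SNP's incidence is the number of distinct samples with ≥ 1 ROH
covering its position (segment ends inclusive; overlapping segments of
one sample count once). The qualifying threshold is the incidence of
the ⌈f·m⌉-th ranked SNP (f = 0.01 by default; 0.001 supported), and all
SNPs at or above it qualify — rank cuts on a discrete statistic must be
tie-stable, so the qualifying set may exceed f·m. Zero-incidence SNPs
never qualify even when the rank threshold lands at zero (otherwise a
sparse track would "qualify" the whole genome). "Adjacent" means
consecutive on the population's filtered variant table with no physical
gap cap (an optional max-gap flag exists); the top fraction is computed
genome-wide, not per chromosome. Island coordinates are the first/last
member SNP positions, exported to BED with half-open conversion.
Annotation reports every (island, feature) pair with ≥ 1 bp overlap;
feature sharing across populations is plain set intersection plus a
pairwise sharing matrix.

## EHH, iHH and iHS

EHH for the carriers of one allele at a focal SNP, at flanking SNP x,
is Σ_k C(n_k,2)/C(n,2) over identical-extended-haplotype groups between
the focus and x. It is computed incrementally outward by partition
refinement (a numba-compiled kernel; the public `ehh` function wraps the
same kernel the scan uses, so oracle tests cover the only code path).
iHH integrates EHH against physical position by the trapezoid rule,
outward per side, stopping at the first flanking SNP with EHH below the
cutoff (0.05) and including the final interval by linear interpolation
to the cutoff crossing; sides are summed. A curve that reaches the
chromosome end while still above the cutoff makes the value unreliable,
and such SNPs are excluded from standardization (counted in the log).
Integration is over physical distance, implicitly assuming a uniform
recombination rate.

The ancestral allele defaults to REF (no outgroup is assumed; a flag
flips the convention, and swapping the labels exactly negates uniHS).
uniHS = ln(iHH_A/iHH_D) is standardised to mean 0, sd 1 within
derived-allele-frequency bins of width 0.025; bins with fewer than 10
SNPs are merged left-to-right with their neighbour. p_iHS =
−log10(1 − 2|Φ(iHS) − 0.5|) is computed via erfc for tail stability;
note it is a −log10-scaled two-sided tail quantity, not a raw p-value —
both iHS and p_iHS are exported. Candidates are the top 0.1% of p_iHS,
ties included.

## The synthetic-data generator

The generator emulates the data regime the estimators target — small
populations (defaults: 25 diploids), dense SNPs (20k over a 100 Mb
chromosome), a U-shaped allele-frequency spectrum (Beta(0.2, 0.2)
truncated to [0.01, 0.99], mean MAF ≈ 0.10–0.13) — via a founder-mosaic
model: founder haplotypes are drawn site-wise from the spectrum, and
each sample haplotype copies founders in segments of exponential length
(mean 1/switch_rate, default 100 kb), which induces LD that decays with
physical distance. One chromosome per call; multi-chromosome data are
built by concatenation. A mosaic rather than a coalescent simulator is
deliberate: it is desk-scale, dependency-light, and sufficient to
exercise estimators; it does not model recombination maps, mutation
processes or demography, so passing tests show estimator correctness
and calibration on data with realistic LD scale, not inference accuracy
on any particular demographic history. Two side effects are worth
knowing: sites drawn at low frequency are often monomorphic in the
realised founders (hence the MAF filter matters), and with k founders
two haplotypes copy the same founder ~1/k of the time, creating genuine
short background IBD segments — mostly below the 300 kb ROH floor at
the default switch rate.

Planted truth: `plant_autozygosity` overwrites one haplotype by the
other inside specified tracts (then flips in-tract sites to heterozygous
at a genotyping-error rate); `plant_sweep` gives a fraction of
haplotypes one shared core around a focal SNP, each carrier's core
extent drawn per side as Exponential(decay_span) — so the per-site
probability of carrying the core decays as exp(−d/decay_span) while
haplotype identity stays contiguous, which is what gives the sweep its
EHH signal (independent per-site replacement would satisfy the same
marginal decay but destroy the haplotype structure the statistic
measures); `split_populations` draws per-population frequencies from the
Balding–Nichols Beta with mean p and variance F·p(1−p). All generators
are pure functions of (inputs, seed).

## Validation study conditions

The acceptance suite (tests/test_acceptance.py, scripts/acceptance.py)
uses these problem sizes, chosen as the package's own validation design:

- ROH oracle audit: 200 randomized instances up to 1000 SNPs × 10
  samples with heterozygosity 1–45% and missingness up to 8%.
- Tract recovery: 5 samples, ~1 SNP/5 kb post-filter on 100 Mb, tracts
  0.5–3 Mb, het-error 1e−3 (≥ 95% base recovery, boundaries within 50
  SNPs — the window-overrun bound above).
- F_ROH recovery: planted fractions 0.05/0.10/0.25 with 4–6 Mb tracts;
  tract length was fixed at the long end of the realistic range because
  the per-side window overrun is per-segment, so shorter tracts trade
  recovery bias for tract count.
- Fst calibration: 50k SNPs, 25+25 samples, F ∈ {0.05, 0.10},
  arcsine-shaped base frequencies clipped to [0.02, 0.98].
- iHS calibration and sweep power: 50 diploids, 25k SNPs on 100 Mb with
  a uniform frequency spectrum (so > 20k SNPs pass the MAF ≥ 0.05 scan
  filter). The single 100 Mb chromosome mimics a large autosome so that
  neutral SNPs dominate the frequency-bin standardization.

## Known limitations

- Sweep localisation by top-0.1% iHS candidates is accurate to the
  sweep's decay scale, not better: with a 500 kb decay span the |iHS|
  peak is often displaced 150–300 kb from the swept site, because the
  frequency bin containing the sweep centre also contains the sweep's
  other extreme SNPs, inflating that bin's sd and shrinking central
  z-scores. In 20 seeded replicates, 17 place a candidate within 100 kb
  of the centre and all 20 show elevated region mean |iHS|; the
  corresponding test asserts a 90% hit rate and currently fails at 85% —
  retained as an honest measurement of pinpointing accuracy under
  single-chromosome standardization rather than relaxed.
- ROH boundaries systematically overrun true autozygosity boundaries by
  up to ~20 SNPs per side (see above); F_ROH inherits a small positive
  bias, within +0.012 under the validation conditions.
- The exact HWE recurrence is validated for cohort sizes into the
  hundreds; extreme cohort sizes (tens of thousands) would need a
  log-space variant.
- LD decay and pruning are O(pairs) and meant for desk-scale panels,
  not biobank data.
- Phasing is an input requirement for the selection scan, not a
  capability; genetic-map-based integration is not implemented
  (physical distance with an implicit uniform rate).
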
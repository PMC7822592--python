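# Methods

## Mass model

All arithmetic is monoisotopic. Atomic masses are the CODATA/IUPAC values
for the lightest stable isotopes (H 1.0078250319, C 12 exactly,
N 14.0030740, O 15.9949146, S 31.9720707 Da); the proton is 1.007276467 Da.
A chain's neutral mass is the sum of residue masses plus one water; each
formed disulfide removes two hydrogens (−2.01565 Da). Modification deltas
are derived from elemental compositions, never stored as magic numbers:
Gla = CO₂ (+43.98983), HexNAc = C₈H₁₃NO₅ (+203.07937), Hex = C₆H₁₀O₅
(+162.05282), NeuAc = C₁₁H₁₇NO₈ (+291.09542), oxidation = O (+15.99491).
Average-mass mode is deliberately unsupported; intact-protein deconvolution
reports monoisotopic masses and sub-ppm agreement is impossible on the
average scale.

The packaged mouse chain (46 aa) and human chain (49 aa) are transcribed
from the published mature sequences. Transcription is guarded by an anchor
check at load time: the fully carboxylated (3× Gla), disulfide-formed mouse
form must compute to 5243.45 ± 0.05 Da. The disulfide-formed convention is
the default because only it passes this anchor (the reduced form is ~2 Da
high); a flag exposes the reduced form. Positions are 1-based on the mature
chain — the numbering in which the mouse glycosylation site is S8 and its
human counterpart Y12. The mouse side-car lists all six Ser/Thr residues as
candidate glycosites: S8 is the established site in osteoblasts, but
purified protein can carry a second glycan chain, so the site inventory
must admit at least two.

Charge algebra follows the protonation convention for positive mode:
M = z·(m/z) − z·m_proton, with `charge_mz` its exact inverse.

## Isotope envelopes

`isotope_distribution` convolves per-element isotope distributions
(exponentiation-by-squaring over atom counts), aggregating isotopologues by
nominal mass offset and reporting the probability-weighted centroid mass of
each aggregate peak. With a zero prune threshold the probabilities conserve
to 1 exactly; a small threshold (default 10⁻⁶) trims the far tail for
speed. The isotope table covers C, H, N, O, S — sufficient for unmodified
and glycosylated peptide chains; other elements raise an error rather than
silently using incomplete data. The implementation is cross-checked in the
test suite against an independent fine-structure enumeration (pyteomics)
on the envelope body (peaks above 10⁻⁴ relative probability); rare tail
isotopologues depend on the exact abundance table used and are not compared.

## Composition assignment

Deltas are measured from the **uncarboxylated, disulfide-formed** base mass,
so Gla is an ordinary alphabet member and "Glycosylation" alone means zero
Gla — matching how published intact-OCN ledgers label their rows. The
enumeration is a bounded depth-first search over count vectors with
branch-and-bound pruning on the attainable mass of the remaining alphabet;
it is tested for exact agreement with a brute-force Cartesian-product
oracle. Tolerance is expressed in ppm of the full proteoform mass (the
scale on which instrument error lives), default 10 ppm: the instrument-level
accuracy of such data is ~5 ppm, but the internal spread among published
ledger masses reaches 8–9 ppm, and 10 ppm admits every printed row. One
ledger entry (5899.7161) sits ~5 ppm above theory while matching the
published 5+ precursor m/z to 0.4 ppm; no agreement tighter than 10 ppm is
forced.

Candidates are ranked parsimony-first: fewest total modifications, then
smallest |ppm error|, then lexicographic composition order as a
deterministic last resort. Parsimony matters in practice — e.g. at the
di-sialylated glycoform mass, a 6-modification composition
(2×HexNAc + Hex + NeuAc + 2×Gla) also falls within 10 ppm and must lose to
the 4-modification glycan.

Glycan counts obey the core-1 topology by default: per occupied site one
GalNAc, at most one Gal per GalNAc, at most two sialic acids per Gal,
occupied sites bounded by the glycosite inventory. A flag relaxes this to
plain count bounds.

Masses with no exact composition are anchored: among compositions lying
within a residual window (default 250 Da, the span of "unidentified
modifications or adduct ions" grouped onto single anchors in published
ledgers) below the observation, the largest-mass composition is reported
with the leftover as `residual_mass`. The residual mechanism *represents*
unidentified mass, it does not resolve it; with a permissive alphabet the
largest-mass anchor may differ from the annotation a curator would choose,
and downstream classification only relies on the anchor's glycan content.
Observations below the base mass beyond tolerance are flagged unassigned
with a negative-delta marker.

## Abundance ledgers

The rank-1 candidate determines the class. `glyco_vs_not` labels a
proteoform glycosylated iff it carries ≥ 1 HexNAc; other groupings split by
oligosaccharide, Gla count, or glycan multiplicity. Aggregation is an exact
sum — conservation of the input total is asserted for every grouping — and
full precision is carried internally with 2-decimal rendering only at
presentation. The packaged osteoblast-supernatant ledger's printed class
totals (83.88/16.12) differ from the sums of its own printed rows
(83.86/16.09) by a few hundredths, evidently unpropagated rounding; the
row sums are what aggregation reproduces, and the bone-homogenate ledger
(internally exact: 99.07/0.93) is the reference check.

## Half-life estimation

Both stability designs reduce to a first-order fit. The default estimator
is ordinary least squares of ln C on t pooled across replicates: it is
closed-form, robust at small n, and appropriate to the "estimated ~" level
of precision of ELISA time courses. Nonlinear least squares on
C(t) = C₀e^(−kt) (initialised from the log-linear solution) is available as
a cross-check; the two agree to well under 2 % on clean data. Confidence
intervals come from a seeded percentile bootstrap over replicates (default
1000 resamples) — replicates, not records, are the exchangeable unit.
Zero concentrations are excluded from the log fit.

Ex vivo curves are first normalised per replicate to the t = 0 baseline
(= 100 %). In vivo post-injection curves are windowed to t ≥ t_peak
(default 30 min, configurable), renormalised to the peak value, and fitted
the same way; the result is provably invariant to pre-peak data. A curve is
called **stable** when the fitted k ≤ 0, the bootstrap CI for k includes 0,
or the implied half-life exceeds four observation windows — operationalising
"stable for more than 5 hr" for a 5-hr design.

`percent_remaining(t, t½) = 100·2^(−t/t½)` and `condition_summary` (mean ±
SEM percent remaining at a common time across conditions) provide the
descriptive summaries used for inhibitor and protease-gradient panels; no
mechanistic dose-response model is fitted.

## Synthetic data

The generators emit exactly the statistical structure the estimators
assume. Mass lists: observed mass = theoretical × (1 + ε) with
ε ~ N(0, ppm_sd·10⁻⁶) — mass error is multiplicative on the ppm scale —
and abundances = weights × unit-mean lognormal noise, renormalised to
100 %. Spectra: isotope envelopes rendered at each charge with Gaussian
peak shapes at FWHM = m/z / resolving power (70 000 by default, an
Orbitrap-class survey scan). Decay curves: ex vivo C(t) = C₀·2^(−t/t½); in
vivo a linear rise to C₀ at the peak time followed by the same decline (the
absorption phase is shown but never fitted, so its shape only needs to be
plausibly monotone); every record gets independent unit-mean lognormal
noise at the stated CV, the standard error model for positive ELISA
concentrations.

Default study conditions: ex vivo — 4 replicates, hourly sampling over
0–300 min, 5 % CV; in vivo — 5 replicates, sampling at 15/30/60/90/120 min,
peak at 30 min, 5 % CV. All generators take explicit integer seeds
(numpy `default_rng`; no global state) and are bit-reproducible.

What passing on synthetic data does **not** show: real deconvolution
produces correlated harmonics and adduct artifacts, real ELISA noise can be
heteroscedastic and plate-correlated, and real in vivo curves include
absorption/clearance physiology beyond a linear rise. Recovery here
validates the estimators under their stated assumptions, not the
instruments.

## Problem sizes and numerics

The recovery studies use 200 simulated datasets per design — enough for a
stable median at 5 % CV while keeping the whole acceptance run in seconds.
Enumeration bounds default to the biology (Gla ≤ 3, glycan units bounded by
the six-site inventory, Ox ≤ 2), keeping the search space small (≪ 10⁵
count vectors). Ties in ranking are broken deterministically; repeated runs
are byte-identical. Degenerate inputs (flat curves, zero baselines,
all-unglycosylated mixtures, empty files) raise explicit errors or flagged
sentinel values rather than NaNs.

## Known limitations

* Site localisation is bookkeeping only: the mass math cannot distinguish
  which Ser/Thr carries the glycan (localisation in the underlying biology
  came from mutagenesis, not mass differences).
* The residual mechanism reports unexplained mass; it does not identify it.
* Fragment-level (MS/MS) evidence is out of scope beyond the precursor-mass
  check; so are raw-spectrum deconvolution and ELISA calibration.
* The element table is CHNOS; extend `MONOISOTOPIC_MASS`/`ISOTOPE_TABLE`
  for proteins containing other elements (e.g. selenoproteins).
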
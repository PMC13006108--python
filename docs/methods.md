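# Methods

## The retention model

HILIC retention of a peptide is expressed in glucose units (GU): the
retention scale defined by a procainamide-labeled dextran ladder in which
rung *n* elutes at the retention of an *n*-glucose oligomer. Minutes map
to GU through a logarithmic law fitted to the ladder by ordinary least
squares,

    rt(min) = a + b · ln(GU),      b > 0,

with the inverse GU = exp((rt − a)/b). The fit is unweighted in minutes;
no alternative functional form is used in the tests. Ladders run before
and after a sample are averaged rung-wise before fitting, which absorbs
linear drift between the bracketing runs. The fitted range plus a 20 %
guard band bounds trustworthy conversions; outside it `min_to_gu` warns
(or raises in strict mode). A procainamide-maltopentaose internal
standard (true GU = 5) is supported as a single-point drift diagnostic
only — its residual is reported but never alters the fit, because no
numerical use beyond "internal standard" is established for it.

Peptide GU retention is additive. The base value for an unmodified
peptide is a sum of per-residue coefficients plus optional
terminus/intercept terms — a composition-only model, deliberately free of
positional terms. The per-residue coefficient values for real peptides
come from an external additive HILIC model for tryptic peptides and are a
required user input; the package never invents them. Where no base model
covers a digest (Glu-C maps), the observed GU of the unmodified peptide
stands in for the modelled base (`base_gu_from_observation`).

A modification adds a single GU coefficient per event:

    GU(modified) = GU(base) + n_events · c_mod.

For glycation two presets are provided: +0.35 GU (standard
peptides/proteins, SD 0.12 GU, n = 17) and +0.52 GU (pooled IgG tryptic
shifts), the latter used for Glu-C workflows. Multiply glycated
candidates add the coefficient once per site; no multi-glycation
observations back this extrapolation, so reports should treat such
candidates with caution. `derive_coefficient` estimates `c_mod` as the
arithmetic mean of paired (modified − unmodified) GU shifts with the
sample (n−1) standard deviation; duplicate peptide labels count as
independent measurements. Recomputing the SD of the bundled standards
table from its rounded two-decimal shifts gives 0.14 GU under the n−1
convention; the coefficient itself (mean +0.35 GU) is the quantity the
model consumes.

## Digestion and site logic

Trypsin cuts C-terminal to K/R; the Keil proline exception (no cut before
P) is on by default and configurable — none of the bundled reference
peptides distinguishes the two conventions. Glu-C cuts C-terminal to D/E.
Missed-cleavage peptides up to a configurable cap (ceiling 5) are
enumerated as runs of consecutive fully cleaved fragments, so the
zero-missed peptides tile the protein exactly.

Glycation precedes digestion, which fixes the admissible sites:

* the protein's original N-terminal α-amine — only on peptides starting
  at residue 1 (α-amines created *by* digestion are not candidates);
* lysine ε-amines — for trypsin, only internal K positions that the rule
  would otherwise cut (the glycated K is the missed cleavage), never the
  peptide's C-terminal K, and not K–P bonds under the Keil rule, which
  are uncleaved anyway and would leave no missed-cleavage signature; for
  Glu-C, any K, since glycation does not interfere with D/E cleavage.

Site assignment is rule-based: `lysine` when missed-cleavage K sites
exist and the peptide is not protein-N-terminal; `protein-n-terminus`
when the peptide is protein-N-terminal and lacks an internal K;
`ambiguous` when both classes are admissible; `inconsistent` otherwise.

## Masses and matching

Monoisotopic masses are residue-table sums (hard-coded IUPAC/Unimod
constants) plus water; nominal masses use integer mass numbers, so the
glycation adduct C₆H₁₀O₅ is 162 Da by integer arithmetic and
162.05282 Da monoisotopic. Cysteine carbamidomethylation (+57.02146 Da)
is a fixed modification by default, matching reduced/alkylated digests;
it can be disabled. Only protonated ions are modelled,
m/z = (M + z·1.007276)/z, with charges 1–4 tried when a feature lacks a
charge annotation.

Matching accepts a (candidate, charge, feature) triple when the signed
mass error is within ±100 ppm (the XIC extraction width) and the
feature's GU — computed through the calibration curve at match time —
is within ±0.5 GU of the prediction. The GU window covers the largest
predicted-vs-observed deviation in the bundled IgG tables (≈0.49 GU) with
no headroom to spare; both tolerances are configurable. Each feature
keeps its best candidate, ranked by |ppm error|, then |ΔGU|, then shorter
peptide, then lexicographic sequence, then lower charge — a deterministic
convention, since manual XIC inspection has no stated assignment policy —
with an all-matches mode for exhaustive output. The implementation uses a
sorted-m/z window query and is tested for exact equivalence against an
all-pairs brute-force oracle, including tie-breaks.

## The synthetic experiment

The generator emulates the study conditions, not raw spectra: no peak
shapes, isotope envelopes or AGE chemistry. Defaults, chosen once:

* ladder: rungs GU 2–15, rt = −1.4 + 10.7·ln(GU) min (placing GU 4–9
  at 13–22 min on a 40-min gradient, the elution region of tryptic
  peptides in the reference tables), rung noise SD 0.05 min; ladder noise
  depends only on the seed, so bracketing runs differing by ±0.1 min
  offsets share noise and average back to the centre ladder;
* proteins: 3 random sequences of 80–160 residues drawn from approximate
  proteome frequencies with K/R upweighted (a tryptic site is forced if
  absent);
* "true" retention: a seeded composition-additive table with residue
  coefficients uniform in [0, 0.6] GU and a 2 GU intercept, so simulator
  and predictor share a model family by construction — the simulation
  validates the pipeline, not any external coefficient values;
* features: every tryptic peptide (≤1 missed cleavage) appears
  unmodified with N(0, 0.05 GU) retention noise; each admissible
  glycation site is planted with probability 0.5 (in vitro glycation is
  aggressive), shifted by N(0.35, 0.12²) GU and +162.05282 Da, at ~100×
  lower intensity; all m/z carry N(0, 10 ppm) multiplicative jitter.

Because the planted GU shift is noise around the same coefficient the
predictor adds, the ±0.5 GU window sits ≈4σ from the shift distribution's
centre and end-to-end recall of planted glycoforms is ≥99 % at default
tolerances; site-isomer glycoforms of one peptide are isobaric and
co-predicted, so recall is scored per planted feature with verdicts
checked on unambiguous peptides. Passing these simulations demonstrates
the pipeline's internal consistency; it does not validate base-model
accuracy on real chromatography, matrix effects, or in-source artifacts.

## Numerical choices and limitations

* Predictions are exact float sums (`math.fsum`); removing a
  modification recovers the base to machine precision.
* Report numbers are fixed-precision on disk (4 decimals for GU, minutes
  and m/z; 1 for ppm); full precision is kept in memory.
* Degenerate inputs fail loudly: <3 ladder rungs, non-monotone ladders,
  non-canonical residues, missing residue coefficients, zero/negative
  charges or tolerances all raise with the offending record named.
* Problem sizes in the test suite (proteins ≤160 aa, ≤200 features,
  replicate counts of 200–1000) were chosen so the full suite runs in
  seconds while leaving sampling-theory assertions well-powered.
* Out of scope: raw spectrum processing and XIC peak picking (feature
  tables are the input), MS/MS evidence, FDR/decoy modelling,
  semi-specific digestion, AGE adducts beyond the +162 Amadori product,
  and intensity-based occupancy quantification.
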
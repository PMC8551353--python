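# Methods

## The model

`cscurrent` works with a schematization of coding sequences in which every
RNA codon carries a fixed, dimensionless, positive scalar — its
**Chern–Simons current**, derived in the source framework as the
expectation value of a Wilson loop over a quaternionic encoding of the
four nucleotides combined in triplets. This package does not re-derive
those 64 numbers (the derivation is not reproducible from published
material); it treats them as canonical lookup data, shipped as versioned
TSV files.

A framed sequence (non-overlapping triplets cut from a chosen reading
frame, T normalized to U) then maps to a **curvature spectrum**: the
ordered series `j_n`, `n = 1..N`, of per-codon currents. At amino-acid
level, `j_n` is instead the mean current of the codon's synonymous class;
the 20 class means (21 with the stop class) are recomputed from the codon
table at load time, never stored independently.

The local structure of the spectrum is summarised by

- forward difference `d_n = j_{n+1} − j_n`,
- forward relative variation `v1_n = (j_{n+1} − j_n) / j_n`,
- backward relative variation `v2_n = (j_n − j_{n−1}) / j_{n−1}`,
- extremity score `e_n = max(|v1_n|, |v2_n|)` over whichever are defined.

A reference→mutant codon substitution is scored by its **slope**
`(j_mut − j_ref) / j_ref`, always on codon-level currents (so synonymous
changes stay visible even when profiles are rendered per amino acid).

The scientific claim this tooling operationalises is retrospective:
observed substitutions concentrate at positions where the curvature
spectrum changes abruptly, i.e. where `e_n` is large. The package measures
that as an **association fraction** — the share of observed substitutions
at gradient-extreme ("flagged") positions — and optionally attaches a
Monte-Carlo permutation p-value. No predictive validity for future
variants is claimed.

## Table variants: `printed` vs `corrected`

The published codon table contains one internally inconsistent entry:
CGG = 0.0010. It breaks the otherwise monotone decreasing order of the
table's fourth column, and the published arginine class mean (0.01005) is
only reproducible if CGG = 0.0101 — then
(0.0109 + 0.0106 + 0.0103 + 0.0101 + 0.0093 + 0.0091)/6 = 0.01005 exactly.
With the printed 0.0010 the mean is 0.0085333.

The package therefore ships two variants: `printed` (the default — faithful
to the source, CGG = 0.0010) and `corrected` (CGG = 0.0101, the unique
value restoring internal consistency). Every analytical output records the
variant used. `verify_tables` reports per-class reconstruction residuals at
each published value's printed precision (half a unit in the last printed
decimal); under `printed` exactly the arginine class mismatches, under
`corrected` none do.

## Thresholding "abrupt" variation

The source analysis never quantifies "extreme" or "abrupt". The package
makes the cutoff an explicit, reportable parameter (`ThresholdSpec`):
either an absolute cutoff on `e_n`, or — the default — the upper quantile
rule with `q = 0.25`: flag the top quarter of defined extremity scores
(cutoff = the empirical 0.75-quantile, ties at the cutoff flagged). Every
result object and output file embeds the resolved spec, because an
association fraction is meaningless without it. `q = 0.25` is a
convention, not an estimate of the unpublished cutoff; sensitivity to `q`
should be reported alongside any real analysis.

## Permutation null (extension)

The published analysis reports raw percentages only. As an extension, the
package offers a permutation p-value: mutation positions are resampled
uniformly without replacement among positions with defined extremity, and
`p = (b + 1)/(B + 1)` where `b` counts resamples whose flagged count
reaches the observed one. This is the standard add-one Monte-Carlo
estimator; it is never exactly zero and is conservative under the null.
All resampling is seeded and the seed is recorded in outputs.

## Synthetic data generator

`synthetic.generate` emulates the study design — an equal-length
reference/mutant pair of coding sequences related by point substitutions —
with a controllable degree of the effect under test:

- the reference is drawn codon-by-codon, by default uniformly over the 61
  sense codons (a user codon-usage table can replace the uniform weights);
  stop codons are excluded by default so amino-acid-level profiles stay
  total;
- its extremity flags are computed under a stated `ThresholdSpec`
  (default `q = 0.25`);
- with enrichment `rho` in [0, 1], exactly `ceil(rho · n_mutations)`
  mutations land on uniformly chosen flagged positions and the rest on
  unflagged ones, one mutation per position; with `rho = None` positions
  are drawn uniformly over all defined positions — the natural null for
  calibrating the permutation test;
- each mutation replaces the codon by a uniformly chosen single-nucleotide
  neighbour (single base change; stop codons excluded by default). All 64
  currents are distinct, so every substitution changes the current.

What the generator does **not** emulate: real codon-usage bias (unless
supplied), local sequence dependence of mutation processes, indels,
selection, and lineage structure. Passing the recovery and calibration
tests therefore shows the estimator is correct and calibrated under the
stated sampling model — not that real mutation catalogs exhibit the
association.

Default study sizes in tests and the acceptance script: 300 codons and 30
mutations per dataset, 200 replicates for enrichment recovery at
`rho ∈ {0, 0.5, 1}`, 500 replicates × 199 permutations for the type-I
check — sizes at which Monte-Carlo error is small relative to the bands
being checked.

## Numerical choices

- Undefined quantities (profile boundaries, masked codons and their
  gradient neighbours) are NaN, never zero-filled, and are excluded from
  all statistics with counts reported.
- Quantile cutoffs use NumPy's default linear-interpolation empirical
  quantile; ties at the cutoff are flagged (so on heavily tied data the
  flagged fraction can exceed `q` — a constant profile flags everything
  under quantile mode; use an absolute cutoff there).
- Variations are stored as fractions; percent is presentation-layer only.
- Class means use compensated summation (`math.fsum`) and are exact to
  full double precision against a brute-force mean.
- Coordinates are 1-based codon positions in every interface.
- Randomness is NumPy `default_rng`, seeded everywhere; outputs record the
  seed.

## Known limitations

The published association percentages for KRAS and SARS-CoV-2 —
approximately 70% and 80% (slope-based), 59% (74/125) and 69% (17/25)
(variation-based), 33% (7/21) and 47% (structure-related) — **cannot be
reproduced by this package or, at desk scale, by anyone**: they depend on
appendix mutation catalogs whose contents are not printed in the available
text, and on extremity thresholds that are never stated. The package
deliberately replaces them with machine-checkable surrogates: exact
reconstruction of the amino-acid table, algebraic identities of the
gradient quantities, brute-force oracle equivalence, and planted-enrichment
recovery on synthetic data. Users with their own mutation catalogs can
compute the analogous percentages via `mutscan` with an explicit threshold.

Other limitations: substitution-only comparison (inputs must be
pre-aligned, equal-length windows; no indels, no alignment, no
reverse-complement handling); the reading frame is a required user input;
no smoothing or windowed statistics; the permutation null assumes
exchangeable positions, which real mutational processes violate.
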
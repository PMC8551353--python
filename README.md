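# cscurrent

Chern–Simons current profiling of codon sequences: per-position
"curvature spectra", reference-vs-mutant comparison, and
mutation–gradient association analysis.

## What it does and for whom

In a topological-field-theory schematization of nucleic acids, every RNA
codon carries a fixed positive scalar — its **Chern–Simons current**,
obtained as the expectation value of a Wilson loop over a quaternionic
encoding of the four bases combined in triplets. A coding sequence then
maps to an ordered series `j_n` of currents, one per codon position `n`,
interpreted as the point-like curvature of the genetic string. The working
hypothesis this package operationalises is that point mutations
concentrate where that curvature changes abruptly — at large current
gradients — and that a codon preferentially mutates toward neighbours
whose current is either very close to or very far from its own.

`cscurrent` is for researchers who want to apply or stress-test that
scheme on their own reference/variant sequence pairs and mutation
catalogs. It provides:

- the canonical 64-codon current table (two variants, see below) and the
  20/21-class amino-acid table derived by averaging synonymous codons;
- current profiles `j_n` with forward/backward relative variations
  `v1_n = (j_{n+1} − j_n)/j_n`, `v2_n = (j_n − j_{n−1})/j_{n−1}` and the
  extremity score `e_n = max(|v1_n|, |v2_n|)`;
- per-mutation slopes `(j_mut − j_ref)/j_ref` for equal-length
  reference/mutant pairs;
- the association fraction (share of observed substitutions at
  gradient-extreme positions) with an explicit, reportable threshold and
  an optional seeded permutation p-value;
- ranking of the nine single-nucleotide neighbours of a codon by relative
  current change;
- a synthetic generator that plants mutations with controllable
  enrichment at gradient-extreme positions, so every statistic is testable
  against known truth.

The published codon table contains one inconsistent entry (CGG = 0.0010,
which breaks the arginine class mean); the package ships it verbatim as
the default `printed` variant and offers a `corrected` variant
(CGG = 0.0101) that makes all 20 amino-acid means internally consistent.
See `docs/methods.md` for the full model description and limitations.

## Worked example

```python
import cscurrent as cs

table = cs.load_codon_table("printed")
ref = cs.frame("TTTGGGTTA", 0, seq_id="ref")   # UUU GGG UUA
alt = cs.frame("TTCGGGTTA", 0, seq_id="alt")   # UUC GGG UUA

report = cs.compare_sequences(ref, alt, level="codon", table=table)
r = report.records[0]
print(r.position, r.ref_codon, r.alt_codon, r.j_ref, r.j_alt, round(r.slope, 5))
```

prints

```
1 UUU UUC 0.7071 0.5 -0.29289
```

i.e. the single substitution sits at codon position 1, replacing the
largest current in the table (UUU, 0.7071) by 0.5000 — a relative current
drop of 29.3%, a "far" move in neighbour-ranking terms.

The same pipeline from the shell, on a synthetic dataset with all
mutations planted at gradient-extreme positions (`rho = 1`):

```
$ cscurrent simulate --n-codons 120 --n-mut 12 --rho 1.0 --seed 5 --out sim
$ cscurrent mutscan --ref sim.ref.fa --alt sim.alt.fa --q 0.25 --permutations 199 --seed 1
n_mutations  n_at_flagged  fraction  flagged_fraction  resolved_cutoff  p_value  n_permutations  n_excluded
12           12            1         0.25              5.39246          0.005    199             0
```

All 12 substitutions fall on flagged positions (fraction 1.0) while only
25% of positions are flagged, and the permutation p-value 0.005 says a
uniform placement essentially never does that. Other subcommands:
`tables` (dump/verify the current tables), `profile` (per-position
current/gradient TSV), `neighbors` (rank the 9 single-nucleotide
neighbours of a codon).

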
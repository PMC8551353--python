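"""Reference-vs-mutant comparison: per-mutation slopes and difference tracks.

The slope of a codon substitution is the relative current change

    slope = (j_mut - j_ref) / j_ref,

always evaluated on codon-level currents (so synonymous substitutions keep
a nonzero slope even when profiles are rendered at amino-acid level, where
their point-wise difference vanishes).  The difference track is the
point-wise ``mutated - original`` current series at the requested level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import AminoAcidCurrentTable, CodonCurrentTable
from .profile import CurrentProfile, compute_profile
from .sequence_io import FramedSequence, MutationList, diff_codon_sequences

__all__ = ["MutationRecord", "ComparisonReport", "slope", "compare_sequences"]


def slope(j_ref: float, j_alt: float) -> float:
    """Relative current change (mutated - original) / original."""
    if not j_ref > 0:
        raise ValueError(f"reference current must be positive, got {j_ref}")
    return (j_alt - j_ref) / j_ref


@dataclass(frozen=True)
class MutationRecord:
    """A codon substitution with its reference/mutant currents and slope."""

    position: int  # 1-based codon index
    ref_codon: str
    alt_codon: str
    j_ref: float
    j_alt: float
    slope: float


@dataclass(frozen=True)
class ComparisonReport:
    ref_profile: CurrentProfile
    alt_profile: CurrentProfile
    difference: np.ndarray  # mutated - original, NaN where either masked
    records: tuple[MutationRecord, ...]
    mutations: MutationList
    level: str

    @property
    def n_mutations(self) -> int:
        return len(self.records)


def compare_sequences(
    ref: FramedSequence,
    alt: FramedSequence,
    level: str = "amino_acid",
    table: CodonCurrentTable | None = None,
    aa_table: AminoAcidCurrentTable | None = None,
) -> ComparisonReport:
    """Profile both sequences, diff them, and score each substitution.

    Requires equal codon counts (delegated to
    :func:`~cscurrent.sequence_io.diff_codon_sequences`).  The difference
    track is at ``level``; slopes are codon-level regardless.
    """
    if table is None:
        from .genetic_code import load_codon_table

        table = load_codon_table()
    mutations = diff_codon_sequences(ref, alt)
    ref_profile = compute_profile(ref, level=level, table=table, aa_table=aa_table)
    alt_profile = compute_profile(alt, level=level, table=table, aa_table=aa_table)
    difference = alt_profile.currents - ref_profile.currents
    records = []
    for m in mutations:
        j_ref = table.current(m.ref_codon)
        j_alt = table.current(m.alt_codon)
        records.append(
            MutationRecord(
                position=m.position,
                ref_codon=m.ref_codon,
                alt_codon=m.alt_codon,
                j_ref=j_ref,
                j_alt=j_alt,
                slope=slope(j_ref, j_alt),
            )
        )
    return ComparisonReport(
        ref_profile=ref_profile,
        alt_profile=alt_profile,
        difference=difference,
        records=tuple(records),
        mutations=mutations,
        level=level,
    )
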
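"""Curvature spectra (per-position current profiles) and their gradients.

The profile of a framed sequence is the ordered series ``j_n`` of
Chern-Simons currents, one per codon position ``n`` (1-based), either at
codon level (the codon's own current) or at amino-acid level (the mean
current of its synonymous class).  The gradient quantities are

* ``d_n   = j_{n+1} - j_n``              (forward difference),
* ``v1_n  = (j_{n+1} - j_n) / j_n``      (forward relative variation),
* ``v2_n  = (j_n - j_{n-1}) / j_{n-1}``  (backward relative variation),
* ``e_n   = max(|v1_n|, |v2_n|)``        over whichever are defined,

with boundary and mask-adjacent entries undefined (NaN), never zero-filled.
Variations are stored as fractions; render as percent only for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import AminoAcidCurrentTable, CodonCurrentTable, CodonLookupError
from .sequence_io import FramedSequence

__all__ = ["CurrentProfile", "GradientProfile", "compute_profile", "gradient"]

LEVELS = ("codon", "amino_acid")


@dataclass(frozen=True)
class CurrentProfile:
    """The current series j_n along a framed sequence (NaN where masked)."""

    sequence_id: str
    level: str
    currents: np.ndarray  # float array, length n_codons
    codons: tuple[str, ...]
    table_variant: str

    @property
    def n(self) -> int:
        return len(self.currents)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.currents)


@dataclass(frozen=True)
class GradientProfile:
    """Contiguous differences and relative variations of a profile.

    Arrays are aligned with profile positions; entry ``i`` (0-based) holds
    the quantity at position ``n = i + 1``.  NaN marks undefined entries
    (boundaries and neighbours of masked positions).
    """

    sequence_id: str
    d: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    e: np.ndarray

    @property
    def n(self) -> int:
        return len(self.e)

    @property
    def defined_e(self) -> np.ndarray:
        return ~np.isnan(self.e)


def compute_profile(
    seq: FramedSequence,
    level: str = "codon",
    table: CodonCurrentTable | None = None,
    aa_table: AminoAcidCurrentTable | None = None,
) -> CurrentProfile:
    """Map each codon of ``seq`` to its current (codon or amino-acid level).

    At amino-acid level a stop codon is an error unless ``aa_table`` was
    derived with ``include_stop=True``.  Masked codons give NaN.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if table is None:
        from .genetic_code import load_codon_table

        table = load_codon_table()
    if level == "amino_acid" and aa_table is None:
        from .genetic_code import derive_amino_acid_table

        aa_table = derive_amino_acid_table(table, include_stop=False)

    currents = np.full(seq.n_codons, np.nan)
    for i, codon in enumerate(seq.codons):
        if seq.mask[i]:
            continue
        if level == "codon":
            currents[i] = table.current(codon)
        else:
            try:
                currents[i] = aa_table.current_of_codon(codon)
            except CodonLookupError:
                raise CodonLookupError(
                    f"{seq.id}: stop codon {codon} at position {i + 1} has no "
                    "amino-acid class; derive the table with include_stop=True"
                ) from None
    return CurrentProfile(
        sequence_id=seq.id,
        level=level,
        currents=currents,
        codons=seq.codons,
        table_variant=table.variant,
    )


def gradient(profile: CurrentProfile) -> GradientProfile:
    """Forward/backward variations and the extremity score per position.

    The extremity ``e_n`` is the larger absolute relative variation; at the
    two boundary positions only the single defined one-sided variation
    contributes.  Entries adjacent to masked positions are NaN and are
    excluded from downstream statistics.
    """
    j = profile.currents
    n = len(j)
    if n < 2:
        raise ValueError(f"{profile.sequence_id}: need at least 2 positions, got {n}")
    d = np.full(n, np.nan)
    v1 = np.full(n, np.nan)
    v2 = np.full(n, np.nan)
    d[:-1] = j[1:] - j[:-1]
    v1[:-1] = (j[1:] - j[:-1]) / j[:-1]
    v2[1:] = (j[1:] - j[:-1]) / j[:-1]
    with np.errstate(invalid="ignore"):
        e = np.where(
            np.isnan(v1),
            np.abs(v2),
            np.where(np.isnan(v2), np.abs(v1), np.maximum(np.abs(v1), np.abs(v2))),
        )
    return GradientProfile(sequence_id=profile.sequence_id, d=d, v1=v1, v2=v2, e=e)
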
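"""Canonical codon-current tables and the amino-acid table derived from them.

Each of the 64 RNA codons carries a fixed positive scalar, its Chern-Simons
current, interpreted as the expectation value of a Wilson loop over the
triplet's configuration and treated here as canonical lookup data.  Two
variants ship with the package:

``printed``
    the table exactly as published, including the anomalous CGG = 0.0010;
``corrected``
    identical except CGG = 0.0101, the unique value under which the
    arginine mean reproduces the published amino-acid value 0.01005.

Amino-acid-level currents are the arithmetic means of the currents of
synonymous codons (optionally including the three stop codons as a 21st
class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

from Bio.Data.CodonTable import standard_rna_table

__all__ = [
    "CodonEntry",
    "CodonCurrentTable",
    "AminoAcidCurrentTable",
    "CodonLookupError",
    "MalformedCodonError",
    "load_codon_table",
    "lookup_codon_current",
    "derive_amino_acid_table",
    "verify_tables",
    "STOP_LABEL",
    "VARIANTS",
]

VARIANTS = ("printed", "corrected")
STOP_LABEL = "Stop"

_RNA_BASES = frozenset("AUCG")
_STOP_CODONS = frozenset(standard_rna_table.stop_codons)  # UAA, UAG, UGA


class MalformedCodonError(ValueError):
    """Input is not a 3-letter string over the nucleotide alphabet."""


class CodonLookupError(KeyError):
    """Codon is well-formed but not resolvable (e.g. contains N)."""


def normalize_codon(codon: str) -> str:
    """Upper-case and map T->U; raise on anything that is not a triplet.

    Ambiguity codes (N, R, Y, ...) pass through normalization and fail at
    lookup instead, so callers can distinguish "malformed" from "unknown".
    """
    if not isinstance(codon, str) or len(codon) != 3:
        raise MalformedCodonError(f"codon must be a 3-letter string, got {codon!r}")
    norm = codon.upper().replace("T", "U")
    if not norm.isalpha():
        raise MalformedCodonError(f"codon contains non-letter characters: {codon!r}")
    return norm


@dataclass(frozen=True)
class CodonEntry:
    codon: str
    amino_acid_3: str
    amino_acid_1: str
    is_stop: bool
    current: float


@dataclass(frozen=True)
class CodonCurrentTable:
    """The 64 codon -> current assignments for one table variant."""

    entries: Mapping[str, CodonEntry]
    variant: str

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodonEntry]:
        return iter(self.entries.values())

    def __contains__(self, codon: str) -> bool:
        return codon in self.entries

    def current(self, codon: str) -> float:
        """Current of ``codon`` after T->U normalization.

        Raises :class:`MalformedCodonError` for non-triplet input and
        :class:`CodonLookupError` for unresolvable (ambiguous) codons.
        """
        norm = normalize_codon(codon)
        try:
            return self.entries[norm].current
        except KeyError:
            raise CodonLookupError(
                f"codon {codon!r} (normalized {norm!r}) is not in the genetic code; "
                "ambiguity codes are not resolvable"
            ) from None

    def entry(self, codon: str) -> CodonEntry:
        norm = normalize_codon(codon)
        try:
            return self.entries[norm]
        except KeyError:
            raise CodonLookupError(f"unknown codon {codon!r}") from None

    def classes(self, include_stop: bool = True) -> dict[str, list[str]]:
        """Group codons by encoded amino acid (stop as its own class)."""
        groups: dict[str, list[str]] = {}
        for e in self:
            label = STOP_LABEL if e.is_stop else e.amino_acid_3
            if not include_stop and e.is_stop:
                continue
            groups.setdefault(label, []).append(e.codon)
        return groups


@dataclass(frozen=True)
class AminoAcidClass:
    label: str
    current: float
    member_codons: tuple[str, ...]


@dataclass(frozen=True)
class AminoAcidCurrentTable:
    """Per-amino-acid currents: mean over synonymous codons."""

    entries: Mapping[str, AminoAcidClass]
    source_variant: str
    include_stop: bool
    codon_to_class: Mapping[str, str] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def current(self, label: str) -> float:
        return self.entries[label].current

    def current_of_codon(self, codon: str) -> float:
        """Class current of the amino acid encoded by ``codon``."""
        norm = normalize_codon(codon)
        try:
            label = self.codon_to_class[norm]
        except KeyError:
            raise CodonLookupError(
                f"codon {codon!r} has no amino-acid class in this table "
                "(stop codon with include_stop=False, or unknown codon)"
            ) from None
        return self.entries[label].current


def load_codon_table(variant: str = "printed") -> CodonCurrentTable:
    """Load one of the packaged table variants from its TSV data file."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    text = (
        resources.files("cscurrent.data")
        .joinpath(f"codon_currents_{variant}.tsv")
        .read_text(encoding="utf-8")
    )
    entries: dict[str, CodonEntry] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("codon\t"):
            continue
        codon, aa3, aa1, is_stop, current = line.split("\t")
        entries[codon] = CodonEntry(
            codon=codon,
            amino_acid_3=aa3,
            amino_acid_1=aa1,
            is_stop=bool(int(is_stop)),
            current=float(current),
        )
    return CodonCurrentTable(entries=entries, variant=variant)


def lookup_codon_current(codon: str, table: CodonCurrentTable) -> float:
    """Current for ``codon`` (DNA or RNA spelling) in ``table``."""
    return table.current(codon)


def derive_amino_acid_table(
    table: CodonCurrentTable, include_stop: bool = False
) -> AminoAcidCurrentTable:
    """Average synonymous-codon currents into one value per amino acid.

    With ``include_stop`` the three stop codons form a 21st class labelled
    ``"Stop"``; otherwise they are omitted (the published amino-acid table
    lists the 20 amino acids only).
    """
    groups = table.classes(include_stop=include_stop)
    entries: dict[str, AminoAcidClass] = {}
    codon_to_class: dict[str, str] = {}
    for label, codons in sorted(groups.items()):
        currents = [table.entries[c].current for c in codons]
        entries[label] = AminoAcidClass(
            label=label,
            current=math.fsum(currents) / len(currents),
            member_codons=tuple(sorted(codons)),
        )
        for c in codons:
            codon_to_class[c] = label
    return AminoAcidCurrentTable(
        entries=entries,
        source_variant=table.variant,
        include_stop=include_stop,
        codon_to_class=codon_to_class,
    )


# published amino-acid means, used by verify_tables to report reconstruction
# residuals; keys are 3-letter codes, values exactly as printed
PUBLISHED_AA_CURRENTS: dict[str, float] = {
    "Phe": 0.60355,
    "Leu": 0.2305,
    "Ile": 0.106567,
    "Met": 0.0841,
    "Val": 0.06645,
    "Ser": 0.0352,
    "Pro": 0.036675,
    "Thr": 0.029225,
    "Ala": 0.024,
    "Tyr": 0.02095,
    "His": 0.01785,
    "Gln": 0.0166,
    "Asn": 0.01545,
    "Lys": 0.01445,
    "Asp": 0.0136,
    "Glu": 0.01275,
    "Cys": 0.012,
    "Trp": 0.0112,
    "Arg": 0.01005,
    "Gly": 0.0086,
}

# decimal places of each printed value, for precision-aware comparison
_PUBLISHED_DECIMALS: dict[str, int] = {
    "Phe": 5, "Leu": 4, "Ile": 6, "Met": 4, "Val": 5, "Ser": 4, "Pro": 6,
    "Thr": 6, "Ala": 3, "Tyr": 5, "His": 5, "Gln": 4, "Asn": 5, "Lys": 5,
    "Asp": 4, "Glu": 5, "Cys": 3, "Trp": 4, "Arg": 5, "Gly": 4,
}


@dataclass(frozen=True)
class ValidationReport:
    variant: str
    n_entries: int
    structural_violations: tuple[str, ...]
    reconstruction_residuals: Mapping[str, float]
    mismatched_classes: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.structural_violations and not self.mismatched_classes

    def format(self) -> str:
        lines = [f"table variant: {self.variant}", f"entries: {self.n_entries}"]
        if self.structural_violations:
            lines.append("structural violations:")
            lines.extend(f"  - {v}" for v in self.structural_violations)
        else:
            lines.append("structural checks: all passed")
        lines.append("amino-acid reconstruction residuals (mean - published):")
        for label, res in self.reconstruction_residuals.items():
            flag = "  MISMATCH" if label in self.mismatched_classes else ""
            lines.append(f"  {label}: {res:+.6g}{flag}")
        return "\n".join(lines)


def verify_tables(table: CodonCurrentTable) -> ValidationReport:
    """Check structural invariants and the amino-acid reconstruction.

    Structural checks: exactly 64 entries, all currents positive, codon ->
    amino-acid assignments and stop flags matching the standard genetic
    code.  Reconstruction check: each synonymous-codon mean is compared to
    the published amino-acid value at its printed precision (half a unit in
    the last printed decimal place).
    """
    violations: list[str] = []
    if len(table) != 64:
        violations.append(f"count != 64 (got {len(table)})")
    for e in table:
        if not e.current > 0:
            violations.append(f"non-positive current for {e.codon}: {e.current}")
        if e.codon in _STOP_CODONS:
            if not e.is_stop:
                violations.append(f"{e.codon} should be a stop codon")
        else:
            expected = standard_rna_table.forward_table.get(e.codon)
            if expected is None:
                violations.append(f"{e.codon} is not a standard codon")
            elif e.is_stop or e.amino_acid_1 != expected:
                violations.append(
                    f"{e.codon} labelled {e.amino_acid_1}, standard code says {expected}"
                )

    residuals: dict[str, float] = {}
    mismatched: list[str] = []
    if len(table) == 64 and not violations:
        aa = derive_amino_acid_table(table, include_stop=False)
        for label, published in PUBLISHED_AA_CURRENTS.items():
            mean = aa.current(label)
            res = mean - published
            residuals[label] = res
            tol = 0.5 * 10.0 ** (-_PUBLISHED_DECIMALS[label])
            if abs(res) > tol:
                mismatched.append(label)

    return ValidationReport(
        variant=table.variant,
        n_entries=len(table),
        structural_violations=tuple(violations),
        reconstruction_residuals=residuals,
        mismatched_classes=tuple(mismatched),
    )
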
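"""FASTA input, codon framing, and substitution diffing of codon sequences.

Sequences are cut into non-overlapping triplets from a chosen reading-frame
offset; T is mapped to U so DNA and RNA spellings are interchangeable.
Codons containing IUPAC ambiguity codes are kept in place but *masked*
rather than rejected, so real-world records pass through; strict mode turns
masks into errors.  Comparison is substitution-only: equal-length framed
sequences are diffed position by position (indels are out of scope — inputs
must be pre-aligned windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

_RNA_BASES = frozenset("AUCG")

logger = logging.getLogger(__name__)

__all__ = [
    "RawSequence",
    "FramedSequence",
    "Mutation",
    "MutationList",
    "FastaError",
    "FramingError",
    "LengthMismatchError",
    "read_fasta",
    "frame",
    "diff_codon_sequences",
    "read_mutation_tsv",
    "write_mutation_tsv",
]


class FastaError(ValueError):
    pass


class FramingError(ValueError):
    pass


class LengthMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class RawSequence:
    id: str
    sequence: str  # upper-cased, as read


def read_fasta(path: str | Path) -> list[RawSequence]:
    """Read all records of a FASTA file, preserving order.

    Raises :class:`FastaError` on an empty file or when the first
    non-blank line is not a ``>`` header.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.strip()
    if not stripped:
        raise FastaError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        first = stripped.splitlines()[0]
        raise FastaError(f"{path}: line 1 is not a FASTA header: {first!r}")
    records = [
        RawSequence(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


@dataclass(frozen=True)
class FramedSequence:
    """A sequence cut into RNA triplets from a frame offset.

    ``codons[i]`` is either a triplet over {A,U,C,G} or a masked triplet
    (contains an ambiguity code); ``mask[i]`` is True where masked.
    Positions are 1-based throughout the package.
    """

    id: str
    alphabet: str  # "DNA" or "RNA" (as detected from the input)
    codons: tuple[str, ...]
    mask: tuple[bool, ...]
    frame_offset: int
    dropped_tail: int
    dropped_head: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_masked(self) -> int:
        return sum(self.mask)


def frame(
    seq: RawSequence | str,
    frame_offset: int = 0,
    *,
    strict: bool = False,
    seq_id: str = "seq",
) -> FramedSequence:
    """Cut a raw sequence into codons from ``frame_offset`` (0, 1 or 2).

    T is normalized to U; an incomplete trailing codon (1-2 bases) is
    dropped with a logged warning.  Codons containing characters outside
    {A,U,C,G} are masked (or rejected if ``strict``).
    """
    if isinstance(seq, RawSequence):
        raw, seq_id = seq.sequence, seq.id
    else:
        raw = seq.upper()
    if frame_offset not in (0, 1, 2):
        raise FramingError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    alphabet = "RNA" if "U" in raw and "T" not in raw else "DNA"
    normalized = raw.replace("T", "U")
    usable = normalized[frame_offset:]
    if len(usable) < 3:
        raise FramingError(
            f"{seq_id}: fewer than 3 usable bases after frame offset {frame_offset}"
        )
    n = len(usable) // 3
    tail = len(usable) - 3 * n
    if tail:
        logger.warning("%s: dropping %d trailing base(s) (incomplete codon)", seq_id, tail)
    codons = tuple(usable[3 * i : 3 * i + 3] for i in range(n))
    mask = tuple(not set(c) <= _RNA_BASES for c in codons)
    if strict and any(mask):
        bad = [i + 1 for i, m in enumerate(mask) if m]
        raise FramingError(f"{seq_id}: ambiguous codon(s) at position(s) {bad}")
    return FramedSequence(
        id=seq_id,
        alphabet=alphabet,
        codons=codons,
        mask=mask,
        frame_offset=frame_offset,
        dropped_tail=tail,
        dropped_head=frame_offset,
    )


@dataclass(frozen=True)
class Mutation:
    """A single codon substitution at a 1-based codon position."""

    position: int
    ref_codon: str
    alt_codon: str


@dataclass(frozen=True)
class MutationList:
    records: tuple[Mutation, ...]
    n_masked_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> list[int]:
        return [m.position for m in self.records]


def diff_codon_sequences(ref: FramedSequence, alt: FramedSequence) -> MutationList:
    """One record per position where the codons differ.

    Requires equal codon counts (substitution-only model).  Positions where
    either sequence is masked are skipped and counted in
    ``n_masked_skipped``.
    """
    if ref.n_codons != alt.n_codons:
        raise LengthMismatchError(
            f"codon counts differ ({ref.n_codons} vs {alt.n_codons}); "
            "pre-align the sequences — indels are not supported"
        )
    records: list[Mutation] = []
    skipped = 0
    for i, (rc, ac) in enumerate(zip(ref.codons, alt.codons)):
        if ref.mask[i] or alt.mask[i]:
            skipped += 1
            continue
        if rc != ac:
            records.append(Mutation(position=i + 1, ref_codon=rc, alt_codon=ac))
    return MutationList(records=tuple(records), n_masked_skipped=skipped)


def write_mutation_tsv(
    mutations: Iterable[Mutation], path: str | Path, header_comment: str | None = None
) -> None:
    lines = []
    if header_comment:
        lines.extend(f"# {line}" for line in header_comment.splitlines())
    lines.append("position\tref_codon\talt_codon")
    for m in mutations:
        lines.append(f"{m.position}\t{m.ref_codon}\t{m.alt_codon}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mutation_tsv(path: str | Path) -> MutationList:
    """Read a mutation list (columns position, ref_codon, alt_codon).

    Positions must be strictly increasing and ref != alt in every record.
    """
    records: list[Mutation] = []
    last_pos = 0
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#") or line.startswith("position\t"):
            continue
        fields: Sequence[str] = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
        pos = int(fields[0])
        ref_c = fields[1].upper().replace("T", "U")
        alt_c = fields[2].upper().replace("T", "U")
        if pos <= last_pos:
            raise ValueError(f"{path}:{lineno}: positions must be strictly increasing")
        if ref_c == alt_c:
            raise ValueError(f"{path}:{lineno}: ref and alt codons are identical")
        records.append(Mutation(position=pos, ref_codon=ref_c, alt_codon=alt_c))
        last_pos = pos
    return MutationList(records=tuple(records))
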
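"""Synthetic coding sequences with planted, enrichment-controlled mutations.

The generator draws a random codon sequence (by default uniform over the
61 sense codons), computes its gradient-extremity flags under a stated
threshold spec, and plants single-nucleotide codon substitutions with a
controllable enrichment at flagged positions:

* ``rho`` in [0, 1]: exactly ``ceil(rho * n_mutations)`` mutations go to
  uniformly chosen flagged positions, the remainder to unflagged ones
  (one mutation per position);
* ``rho = None``: positions are drawn uniformly over all defined positions
  regardless of flags — the natural null for calibration checks.

Every dataset carries its truth mutation list and the full parameter set,
so downstream association estimates can be validated against the planted
enrichment without any external data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genetic_code import CodonCurrentTable, load_codon_table
from .mutscan import ExtremityCall, ThresholdSpec, flag_extreme
from .profile import compute_profile, gradient
from .sequence_io import FramedSequence, Mutation, MutationList

__all__ = ["SyntheticDataset", "generate"]


@dataclass(frozen=True)
class SyntheticDataset:
    reference: FramedSequence
    mutated: FramedSequence
    truth: MutationList
    call: ExtremityCall  # flags of the reference under threshold_spec
    rho: float | None
    n_forced_flagged: int
    threshold_spec: ThresholdSpec
    seed: int
    table_variant: str

    @property
    def planted_fraction(self) -> float:
        """Fraction of planted mutations on flagged positions."""
        idx = np.asarray(self.truth.positions()) - 1
        return float(self.call.flagged[idx].mean())

    def write(self, prefix: str | Path) -> dict[str, Path]:
        """Write ref/alt FASTA, truth TSV and a metadata JSON."""
        from .sequence_io import write_mutation_tsv

        prefix = Path(prefix)
        paths = {
            "ref": prefix.parent / f"{prefix.name}.ref.fa",
            "alt": prefix.parent / f"{prefix.name}.alt.fa",
            "truth": prefix.parent / f"{prefix.name}.truth.tsv",
            "meta": prefix.parent / f"{prefix.name}.meta.json",
        }
        for key, seq in [("ref", self.reference), ("alt", self.mutated)]:
            paths[key].write_text(
                f">{seq.id}\n{''.join(seq.codons)}\n", encoding="utf-8"
            )
        write_mutation_tsv(self.truth, paths["truth"])
        meta = {
            "n_codons": self.reference.n_codons,
            "n_mutations": len(self.truth),
            "rho": self.rho,
            "n_forced_flagged": self.n_forced_flagged,
            "threshold": self.threshold_spec.describe(),
            "seed": self.seed,
            "table_variant": self.table_variant,
        }
        paths["meta"].write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")
        return paths


def _single_nucleotide_neighbors(codon: str, allowed: frozenset[str]) -> list[str]:
    out = []
    for pos in range(3):
        for base in "AUCG":
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor in allowed:
                out.append(neighbor)
    return out


def generate(
    n_codons: int,
    n_mutations: int,
    rho: float | None = 0.5,
    *,
    codon_weights: dict[str, float] | None = None,
    threshold_spec: ThresholdSpec | None = None,
    seed: int = 0,
    table: CodonCurrentTable | None = None,
    exclude_stop: bool = True,
    sequence_id: str = "synthetic",
) -> SyntheticDataset:
    """Build a reference/mutant pair with planted mutation enrichment.

    ``codon_weights`` maps codons to sampling weights for the reference
    (default uniform over sense codons); weights need not be normalised.
    Raises if ``rho`` asks for more flagged (or unflagged) mutations than
    there are such positions.
    """
    if n_mutations > n_codons:
        raise ValueError("n_mutations cannot exceed n_codons")
    if rho is not None and not 0 <= rho <= 1:
        raise ValueError(f"rho must be in [0, 1] or None, got {rho}")
    if table is None:
        table = load_codon_table()
    if threshold_spec is None:
        threshold_spec = ThresholdSpec(quantile=0.25)
    rng = np.random.default_rng(seed)

    stop_codons = {e.codon for e in table if e.is_stop}
    if codon_weights is None:
        pool = sorted(c for c in table.entries if not (exclude_stop and c in stop_codons))
        weights = np.ones(len(pool))
    else:
        pool = sorted(codon_weights)
        unknown = [c for c in pool if c not in table]
        if unknown:
            raise ValueError(f"codon_weights contains unknown codons: {unknown}")
        weights = np.array([codon_weights[c] for c in pool], dtype=float)
    weights = weights / weights.sum()
    allowed = frozenset(
        c for c in table.entries if not (exclude_stop and c in stop_codons)
    )

    codons = tuple(rng.choice(pool, size=n_codons, p=weights))
    reference = FramedSequence(
        id=f"{sequence_id}_ref",
        alphabet="RNA",
        codons=codons,
        mask=(False,) * n_codons,
        frame_offset=0,
        dropped_tail=0,
    )

    gp = gradient(compute_profile(reference, level="codon", table=table))
    call = flag_extreme(gp, threshold_spec)
    flagged_idx = np.flatnonzero(call.flagged)
    unflagged_idx = np.flatnonzero(call.defined & ~call.flagged)

    if rho is None:
        n_forced = -1  # sentinel: uniform placement
        defined_idx = np.flatnonzero(call.defined)
        chosen = rng.choice(defined_idx, size=n_mutations, replace=False)
    else:
        n_forced = math.ceil(rho * n_mutations)
        n_free = n_mutations - n_forced
        if n_forced > len(flagged_idx):
            raise ValueError(
                f"rho={rho} needs {n_forced} flagged positions, only "
                f"{len(flagged_idx)} available"
            )
        if n_free > len(unflagged_idx):
            raise ValueError(
                f"rho={rho} needs {n_free} unflagged positions, only "
                f"{len(unflagged_idx)} available"
            )
        chosen = np.concatenate(
            [
                rng.choice(flagged_idx, size=n_forced, replace=False),
                rng.choice(unflagged_idx, size=n_free, replace=False),
            ]
        )
    chosen = np.sort(chosen)

    mutated = list(codons)
    records = []
    for i in chosen:
        src = codons[i]
        neighbors = _single_nucleotide_neighbors(src, allowed)
        # all neighbours differ in current (the 64 currents are distinct)
        alt = str(rng.choice(neighbors))
        mutated[i] = alt
        records.append(Mutation(position=int(i) + 1, ref_codon=src, alt_codon=alt))

    mutated_seq = FramedSequence(
        id=f"{sequence_id}_mut",
        alphabet="RNA",
        codons=tuple(mutated),
        mask=(False,) * n_codons,
        frame_offset=0,
        dropped_tail=0,
    )
    return SyntheticDataset(
        reference=reference,
        mutated=mutated_seq,
        truth=MutationList(records=tuple(records)),
        call=call,
        rho=rho,
        n_forced_flagged=n_forced,
        threshold_spec=threshold_spec,
        seed=seed,
        table_variant=table.variant,
    )
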
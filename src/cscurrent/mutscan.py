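"""Mutation-gradient association and candidate-mutation ranking.

Positions where the curvature spectrum changes abruptly — large absolute
relative variation with respect to a neighbour — are flagged as
gradient-extreme, either by an absolute cutoff on the extremity score
``e_n`` or by its upper quantile over the sequence.  The association
statistic is the fraction of observed substitutions that fall on flagged
positions, optionally with a Monte-Carlo permutation p-value (mutation
positions resampled uniformly without replacement among defined positions).
The permutation null is an extension of the published analysis, which
reports raw percentages only.

``rank_neighbors`` enumerates the nine single-nucleotide neighbours of a
codon and bands them by relative current change, operationalising the idea
that sequences preferentially mutate toward currents either very close to
or very far from the current of the original codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_code import CodonCurrentTable, normalize_codon
from .profile import GradientProfile
from .sequence_io import MutationList

__all__ = [
    "ThresholdSpec",
    "ExtremityCall",
    "AssociationResult",
    "NeighborMutation",
    "CandidateMutationRanking",
    "flag_extreme",
    "associate",
    "rank_neighbors",
    "DEFAULT_QUANTILE",
]

DEFAULT_QUANTILE = 0.25


@dataclass(frozen=True)
class ThresholdSpec:
    """How "gradient-extreme" is decided: absolute cutoff or upper quantile.

    Exactly one of ``cutoff`` (flag e_n >= cutoff) and ``quantile`` (flag
    the top fraction q of defined extremity scores, i.e. e_n >= the (1-q)
    empirical quantile) must be set.  Every analytical output embeds the
    spec used, because the flagged set is meaningless without it.
    """

    cutoff: float | None = None
    quantile: float | None = None

    def __post_init__(self) -> None:
        if (self.cutoff is None) == (self.quantile is None):
            raise ValueError("set exactly one of cutoff and quantile")
        if self.quantile is not None and not 0 < self.quantile < 1:
            raise ValueError(f"quantile must be in (0, 1), got {self.quantile}")
        if self.cutoff is not None and self.cutoff < 0:
            raise ValueError(f"cutoff must be non-negative, got {self.cutoff}")

    def describe(self) -> str:
        if self.cutoff is not None:
            return f"absolute cutoff e >= {self.cutoff:g}"
        return f"upper quantile q = {self.quantile:g}"


@dataclass(frozen=True)
class ExtremityCall:
    """Per-position flags plus the resolved cutoff that produced them."""

    e: np.ndarray
    flagged: np.ndarray  # boolean, False at undefined positions
    resolved_cutoff: float
    threshold_spec: ThresholdSpec

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.e)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def flagged_fraction(self) -> float:
        n_def = int(self.defined.sum())
        return self.n_flagged / n_def if n_def else float("nan")


def flag_extreme(gp: GradientProfile, spec: ThresholdSpec) -> ExtremityCall:
    """Flag positions whose extremity score meets the threshold.

    Under quantile mode the cutoff is the empirical (1-q) quantile of the
    defined scores; ties at the cutoff are flagged, so the flagged fraction
    can exceed q slightly on tied data.
    """
    e = gp.e
    defined = ~np.isnan(e)
    if not defined.any():
        raise ValueError("no defined extremity scores to threshold")
    if spec.cutoff is not None:
        cutoff = spec.cutoff
    else:
        cutoff = float(np.quantile(e[defined], 1.0 - spec.quantile))
    flagged = np.zeros(len(e), dtype=bool)
    flagged[defined] = e[defined] >= cutoff
    return ExtremityCall(e=e, flagged=flagged, resolved_cutoff=cutoff, threshold_spec=spec)


@dataclass(frozen=True)
class AssociationResult:
    n_mutations: int
    n_at_flagged: int
    fraction: float
    threshold_spec: ThresholdSpec
    resolved_cutoff: float
    flagged_fraction: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    n_excluded: int = 0  # mutations at masked/undefined positions


def associate(
    mutations: MutationList,
    call: ExtremityCall,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AssociationResult:
    """Fraction of mutations at flagged positions, with optional null.

    Mutations at positions whose extremity is undefined (masked or
    mask-adjacent) are excluded from numerator and denominator and counted
    in ``n_excluded``.  With ``n_permutations`` B > 0 the p-value is
    ``(b + 1) / (B + 1)`` where ``b`` counts resampled position sets whose
    flagged fraction is at least the observed one.
    """
    if len(mutations) == 0:
        raise ValueError("empty mutation list")
    n_pos = len(call.e)
    positions = np.asarray(mutations.positions())
    if positions.min() < 1 or positions.max() > n_pos:
        raise ValueError(
            f"mutation positions must lie in [1, {n_pos}]; got "
            f"[{positions.min()}, {positions.max()}]"
        )
    idx = positions - 1
    valid = call.defined[idx]
    n_excluded = int((~valid).sum())
    idx = idx[valid]
    m = len(idx)
    if m == 0:
        raise ValueError("all mutations fall on positions with undefined extremity")
    n_at_flagged = int(call.flagged[idx].sum())
    fraction = n_at_flagged / m

    p_value: float | None = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        defined_idx = np.flatnonzero(call.defined)
        # resample m positions without replacement per permutation; a
        # column of random keys per draw makes this fully vectorised
        keys = rng.random((n_permutations, len(defined_idx)))
        take = np.argpartition(keys, m - 1, axis=1)[:, :m]
        perm_flagged = call.flagged[defined_idx[take]].sum(axis=1)
        b = int((perm_flagged >= n_at_flagged).sum())
        p_value = (b + 1) / (n_permutations + 1)

    return AssociationResult(
        n_mutations=m,
        n_at_flagged=n_at_flagged,
        fraction=fraction,
        threshold_spec=call.threshold_spec,
        resolved_cutoff=call.resolved_cutoff,
        flagged_fraction=call.flagged_fraction,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class NeighborMutation:
    codon: str
    current: float
    relative_change: float  # (j_neighbor - j_source) / j_source
    band: str  # near | far | intermediate


@dataclass(frozen=True)
class CandidateMutationRanking:
    source_codon: str
    source_current: float
    neighbors: tuple[NeighborMutation, ...]  # sorted by |relative_change|
    near_cut: float
    far_cut: float


def rank_neighbors(
    codon: str,
    table: CodonCurrentTable,
    near_cut: float = 0.05,
    far_cut: float = 0.5,
) -> CandidateMutationRanking:
    """Score the 9 single-nucleotide neighbours of ``codon``.

    Each neighbour (3 positions x 3 alternative bases) gets the relative
    current change vs the source and a band: ``near`` if the absolute
    change is <= ``near_cut``, ``far`` if >= ``far_cut``, else
    ``intermediate``.  Near and far neighbours are the favoured candidate
    mutations under the close-or-far heuristic.
    """
    if not 0 <= near_cut < far_cut:
        raise ValueError("need 0 <= near_cut < far_cut")
    src = normalize_codon(codon)
    j_src = table.current(src)
    neighbors: list[NeighborMutation] = []
    for pos in range(3):
        for base in "AUCG":
            if base == src[pos]:
                continue
            neighbor = src[:pos] + base + src[pos + 1 :]
            j = table.current(neighbor)
            rel = (j - j_src) / j_src
            if abs(rel) <= near_cut:
                band = "near"
            elif abs(rel) >= far_cut:
                band = "far"
            else:
                band = "intermediate"
            neighbors.append(NeighborMutation(neighbor, j, rel, band))
    neighbors.sort(key=lambda nm: abs(nm.relative_change))
    return CandidateMutationRanking(
        source_codon=src,
        source_current=j_src,
        neighbors=tuple(neighbors),
        near_cut=near_cut,
        far_cut=far_cut,
    )
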
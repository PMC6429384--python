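"""Higher-order repeat (HOR) analysis.

A HOR arises when a block of already-diverged monomers becomes the unit of
amplification: the consensus of the long period then decomposes into
several mutually similar subrepeats, copies of the long unit are more alike
than the subrepeats are to each other, and the positional profile of
mismatches is consistent with the long unit. This module decides basic
monomer vs HOR unit and inventories proposed HOR units per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from .seqio import identity_percent, rotated_identity_percent
from .tandem import TandemHit, TandemParams, refine_consensus


@dataclass
class HORModel:
    unit_length: int
    subrepeat_length: int
    subrepeat_count: int
    subrepeat_identity_matrix: list  # pairwise percent identities (square)
    inter_unit_identity_range: tuple = (0.0, 0.0)
    source: tuple = ("", "")  # (species, cluster id)
    unit_sequence: str = ""
    mean_internal_identity: float = 0.0


def _frames(consensus: str, p: int) -> list[str]:
    return [consensus[i * p : (i + 1) * p] for i in range(ceil(len(consensus) / p))]


def decompose_consensus(
    consensus: str, min_subrepeat: int = 15, min_internal_identity: float = 60.0
) -> HORModel | None:
    """Scan subperiods; return the best-supported subrepeat structure, if any.

    The consensus is cut into ceil(len/p) frames for each subperiod p
    (ragged last frame handled by gap-tolerant alignment); the p maximising
    mean pairwise frame identity wins if it reaches min_internal_identity.
    """
    L = len(consensus)
    if L < 2 * min_subrepeat:
        raise ValueError("consensus shorter than 2 x min_subrepeat")
    best: tuple[float, int] | None = None
    best_matrix = None
    for p in range(min_subrepeat, L // 2 + 1):
        frames = _frames(consensus, p)
        k = len(frames)
        if k < 2:
            continue
        matrix = [[100.0] * k for _ in range(k)]
        total, cnt = 0.0, 0
        for i in range(k):
            for j in range(i + 1, k):
                ident = identity_percent(frames[i], frames[j])
                matrix[i][j] = matrix[j][i] = ident
                total += ident
                cnt += 1
        mean = total / cnt
        if best is None or mean > best[0]:
            best = (mean, p)
            best_matrix = matrix
    if best is None or best[0] < min_internal_identity:
        return None
    mean, p = best
    count = ceil(L / p)
    return HORModel(
        unit_length=L,
        subrepeat_length=p,
        subrepeat_count=count,
        subrepeat_identity_matrix=best_matrix,
        unit_sequence=consensus,
        mean_internal_identity=mean,
    )


def _profile_consistency(frames: list[str]) -> float:
    """Mean column homogeneity (majority-symbol fraction) across aligned copies.

    High when the mismatch/indel profile is consistent with the tried
    period — copies agree column-by-column — and low when the period cuts
    across diverged subrepeats.
    """
    if not frames:
        return 0.0
    p = len(frames[0])
    total, cols = 0.0, 0
    for j in range(p):
        counts: dict[str, int] = {}
        n = 0
        for f in frames:
            c = f[j]
            if c == " ":
                continue
            counts[c] = counts.get(c, 0) + 1
            n += 1
        if n < 2:
            continue
        total += max(counts.values()) / n
        cols += 1
    return total / cols if cols else 0.0


def choose_unit(
    array: str,
    candidate_periods: list[int],
    params: TandemParams | None = None,
    margin: float = 5.0,
) -> int:
    """Pick the duplication unit among candidate periods.

    Starting from the smallest candidate, a larger period is promoted only
    if its wraparound percent-matches beats the current choice by at least
    ``margin`` percentage points *and* its positional mutation profile is at
    least as consistent (copies agree column-wise at least as well). With no
    decisive HOR signal the smallest candidate wins, so exact p-vs-2p ties
    resolve to p.
    """
    if not candidate_periods:
        raise ValueError("empty candidate list")
    params = params or TandemParams()
    cands = sorted(p for p in set(candidate_periods) if 2 * p <= len(array))
    if not cands:
        cands = [min(candidate_periods)]
    stats = {}
    for p in cands:
        try:
            _, res = refine_consensus(array, p, params)
        except ValueError:
            continue
        stats[p] = (res.percent_matches, _profile_consistency(res.frames))
    if not stats:
        return min(cands)
    chosen = min(stats)
    for p in sorted(stats):
        pm, cons = stats[p]
        pm0, cons0 = stats[chosen]
        if p > chosen and pm >= pm0 + margin and cons >= cons0:
            chosen = p
    return chosen


def unit_similarity_range(array: str, model: HORModel) -> tuple[float, float]:
    """Min/max global-alignment identity among physical unit-length copies."""
    u = model.unit_length
    copies = [array[i * u : (i + 1) * u] for i in range(len(array) // u)]
    if len(copies) < 2:
        raise ValueError("array contains < 2 unit copies")
    idents = [
        identity_percent(copies[i], copies[j])
        for i in range(len(copies))
        for j in range(i + 1, len(copies))
    ]
    return (min(idents), max(idents))


def hor_inventory(
    hits_per_species: dict,
    reference_monomer: str,
    min_subrepeat: int = 15,
    min_internal_identity: float = 60.0,
    max_internal_identity: float = 95.0,
    dedup_identity: float = 95.0,
) -> tuple[list[HORModel], dict]:
    """Propose HOR units from per-species family tandem hits.

    Every family hit whose consensus decomposes into subrepeats and whose
    unit length exceeds 1.5x the reference monomer becomes a proposed HOR
    unit; units are de-duplicated per species at ``dedup_identity`` percent
    (rotation/strand-normalised). Decompositions whose subrepeats are
    near-identical (mean internal identity above ``max_internal_identity``)
    are rejected: a tandem of interchangeable monomers is a plain multiple
    of the basic repeat, not a higher-order unit of diverged subrepeats.
    Returns (units, per-species counts).
    """
    ref_len = len(reference_monomer)
    units: list[HORModel] = []
    counts: dict[str, int] = {}
    for species in sorted(hits_per_species):
        kept: list[HORModel] = []
        for hit in hits_per_species[species]:
            if hit.family_member is False:
                continue
            cons = hit.consensus
            if len(cons) <= 1.5 * ref_len or len(cons) < 2 * min_subrepeat:
                continue
            model = decompose_consensus(cons, min_subrepeat, min_internal_identity)
            if model is None:
                continue
            if model.mean_internal_identity > max_internal_identity:
                continue  # plain monomer multiple, not a HOR
            model.source = (species, hit.seq_id or "")
            if any(
                rotated_identity_percent(model.unit_sequence, other.unit_sequence)
                >= dedup_identity
                for other in kept
            ):
                continue
            kept.append(model)
        counts[species] = len(kept)
        units.extend(kept)
    return units, counts
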
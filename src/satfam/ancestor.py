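"""Ancestral monomer reconstruction from exact shared fragments.

The conserved core of the ancestral monomer is recovered combinatorially:
fragments with 100% identity shared between the monomer sets of different
species are intersected across all species and the longest conserved
region is reported. Monomers are treated as circular strings on both
strands (satellite phase and strand are arbitrary), so each monomer is
doubled before substring search and coordinates are reported modulo the
monomer length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .satsim import ANCESTRAL_CORE_37
from .seqio import SeqRecordSimple, canonical_rotation, revcomp


@dataclass
class AncestralFragment:
    sequence: str
    length: int
    support: dict  # species -> list of (monomer idx, start, end, strand, rotation offset)


class NoConservedCoreError(ValueError):
    pass


def _extended(mono: str) -> str:
    """Circular doubling: s+s truncated to 2*len-1 so phase cannot split a core."""
    return (mono + mono)[: 2 * len(mono) - 1]


def _variants(mono: str) -> list[tuple[str, str]]:
    return [("+", _extended(mono)), ("-", _extended(revcomp(mono)))]


def _occurs(fragment: str, monomers: list[str]) -> bool:
    return any(fragment in ext for m in monomers for _, ext in _variants(m))


def shared_exact_fragments(
    monomers_a: list[str], monomers_b: list[str], min_len: int = 8
) -> list[str]:
    """Maximal substrings of length >= min_len shared exactly by the two sets.

    Circular, both strands. A fragment is maximal if it is not a substring
    of a longer shared fragment. Returned longest-first, then
    lexicographically.
    """
    if min_len < 4:
        raise ValueError("min_len < 4 rejected (indistinguishable from noise)")
    if not monomers_a or not monomers_b:
        raise ValueError("both monomer sets must be non-empty")
    uniq_a = sorted(set(monomers_a))
    uniq_b = sorted(set(monomers_b))
    found: set[str] = set()
    for a in uniq_a:
        exts_a = [ext for _, ext in _variants(a)]
        for b in uniq_b:
            for ext_b in (ext for _, ext in _variants(b)):
                for ext_a in exts_a:
                    found.update(_pair_common(ext_a, ext_b, min_len, len(a), len(b)))
    # global maximality: drop fragments contained in a longer one (either strand)
    frags = sorted(found, key=lambda f: (-len(f), f))
    kept: list[str] = []
    for f in frags:
        if not any(f in g or revcomp(f) in g for g in kept):
            kept.append(f)
    return kept


def _pair_common(a: str, b: str, min_len: int, la: int, lb: int) -> set[str]:
    """Maximal common substrings of two (already doubled) strings.

    Classic longest-common-suffix DP; fragments are clipped to the original
    monomer lengths so circular doubling cannot report a fragment longer
    than the monomer itself.
    """
    cap = min(la, lb)
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    out: set[str] = set()
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
        for j in range(1, m + 1):
            L = cur[j]
            if L < min_len:
                continue
            # right-maximal? i.e. cannot extend with next characters
            if i < n and j < m and a[i] == b[j]:
                continue
            out.add(a[i - min(L, cap) : i])
        prev = cur
    return out


def reconstruct_ancestral(
    monomer_sets: dict, min_len: int = 8
) -> AncestralFragment:
    """Longest region exactly conserved across every species' monomer set.

    Pairwise shared fragments of the first two species seed the search; each
    is shrunk to its longest window present in all remaining species
    (overlap chaining is implicit: any region present in all species is a
    substring of some maximal pair fragment). Ties break to the longest,
    then lexicographically smallest canonical sequence.
    """
    species = sorted(monomer_sets)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    sets = {sp: list(monomer_sets[sp]) for sp in species}
    seeds = shared_exact_fragments(sets[species[0]], sets[species[1]], min_len)
    others = species[2:]
    best: tuple[int, str, str] | None = None  # (length, canonical, literal)
    for frag in seeds:
        win = _longest_window_in_all(frag, [sets[sp] for sp in others], min_len)
        if win is None:
            continue
        cand = (len(win), canonical_rotation(win), win)
        if (
            best is None
            or cand[0] > best[0]
            or (cand[0] == best[0] and cand[1] < best[1])
        ):
            best = cand
    if best is None:
        raise NoConservedCoreError(
            f"no conserved core of >= {min_len} bp shared by all species"
        )
    sequence = _orient_fragment(best[2], [sets[sp] for sp in species])
    support = {sp: _support_coords(sequence, sets[sp]) for sp in species}
    return AncestralFragment(sequence=sequence, length=len(sequence), support=support)


def _orient_fragment(frag: str, all_sets: list[list[str]]) -> str:
    """Report the fragment as it occurs in the inputs: prefer the literal
    monomer when the fragment covers a whole monomer, else the forward-strand
    occurrence in the first supporting monomer."""
    rc = revcomp(frag)
    for monomers in all_sets:
        for m in monomers:
            if len(frag) == len(m) and frag in m + m:
                return m
            if len(rc) == len(m) and rc in m + m:
                return m
    for monomers in all_sets:
        for m in monomers:
            ext = _extended(m)
            if frag in ext:
                return frag
            if rc in ext:
                return rc
    return frag


def _longest_window_in_all(
    frag: str, other_sets: list[list[str]], min_len: int
) -> str | None:
    if all(_occurs(frag, s) for s in other_sets):
        return frag
    best = None
    for L in range(len(frag) - 1, min_len - 1, -1):
        for i in range(len(frag) - L + 1):
            win = frag[i : i + L]
            if all(_occurs(win, s) for s in other_sets):
                if best is None:
                    best = win
                break
        if best is not None:
            return best
    return None


def _support_coords(fragment: str, monomers: list[str]) -> list[tuple]:
    coords = []
    for idx, m in enumerate(monomers):
        for strand, ext in _variants(m):
            pos = ext.find(fragment)
            if pos >= 0:
                start = pos % len(m)
                coords.append((idx, start, start + len(fragment), strand, pos))
                break
    return coords


def family_reference(ancestral: AncestralFragment | None = None) -> SeqRecordSimple:
    """Package a reconstructed fragment (or the shipped 37-bp constant) as the
    family reference used for membership tests and tree rooting."""
    if ancestral is None:
        return SeqRecordSimple(id="ancestral", sequence=ANCESTRAL_CORE_37)
    return SeqRecordSimple(id="ancestral", sequence=ancestral.sequence)
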
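"""Read-similarity graph clustering and consensus contig assembly.

A desk-scale re-implementation of the graph-based repeat clustering stage:
all-vs-all local alignment of reads (match +1 / mismatch -2 / gap -3, both
strands, with a shared-13-mer prefilter), a hit recorded when identity
exceeds min_identity over at least min_coverage_fraction of the shorter
read; clusters are connected components of the hit graph, filtered by
genomic abundance (fraction of input reads), with greedy overlap-layout
consensus contigs per cluster. Contigs of tandem repeats can be partially
chimeric by construction — they are consensus artifacts, not physical
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align

from .seqio import revcomp, rng_for


@dataclass
class ClusteringParams:
    min_identity: float = 90.0  # percent
    min_coverage_fraction: float = 0.55  # of the shorter read
    min_cluster_fraction: float = 0.0001  # of input reads (0.01%)
    max_reads: int = 20000
    prefilter_kmer: int = 13
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity in (0,100]")
        if not 0 < self.min_coverage_fraction <= 1:
            raise ValueError("min_coverage_fraction in (0,1]")
        if self.min_cluster_fraction < 0:
            raise ValueError("min_cluster_fraction >= 0")


@dataclass
class RepeatCluster:
    id: int
    read_ids: list
    genome_fraction: float = 0.0  # percent of sampled reads
    contigs: list = field(default_factory=list)
    family_member: bool | None = None


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -3
    a.extend_gap_score = -3
    return a


def _alignment_stats(aln) -> tuple[float, int, int, int, int]:
    """(percent identity over aligned columns, span_a, span_b, a_start, b_start)."""
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0, 0, 0, 0
    a, b = aln.sequences
    matches = 0
    cols = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        seg_a, seg_b = a[a0:a1], b[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        cols += a1 - a0
    # internal gap columns between blocks (in either sequence)
    for i in range(1, len(blocks_a)):
        cols += (blocks_a[i][0] - blocks_a[i - 1][1]) + (
            blocks_b[i][0] - blocks_b[i - 1][1]
        )
    ident = 100.0 * matches / cols if cols else 0.0
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    return ident, span_a, span_b, int(blocks_a[0][0]), int(blocks_b[0][0])


def _kmers(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def pairwise_hits(
    reads: list, params: ClusteringParams | None = None
) -> list[tuple[int, int, float, float]]:
    """All-vs-all hits (i, j, identity, coverage), i < j, either strand.

    A shared prefilter k-mer is required before alignment; a hit needs
    identity > min_identity and an aligned span of at least
    min_coverage_fraction of the shorter read.
    """
    params = params or ClusteringParams()
    params.validate()
    if len(reads) < 2:
        raise ValueError("need >= 2 reads")
    k = params.prefilter_kmer
    aligner = _aligner()

    fwd = [_kmers(r, k) for r in reads]
    rcs = [revcomp(r) for r in reads]
    index: dict[str, list[int]] = {}
    for i, ks in enumerate(fwd):
        for km in ks:
            index.setdefault(km, []).append(i)

    candidates: dict[tuple[int, int], set] = {}
    for i, r in enumerate(reads):
        for km in fwd[i]:
            for j in index.get(km, ()):
                if j > i:
                    candidates.setdefault((i, j), set()).add("+")
        for km in _kmers(rcs[i], k):
            for j in index.get(km, ()):
                if j > i:
                    candidates.setdefault((i, j), set()).add("-")

    hits = []
    for (i, j), strands in sorted(candidates.items()):
        best = None
        for strand in sorted(strands):
            other = reads[j] if strand == "+" else rcs[j]
            alns = aligner.align(reads[i], other)
            if len(alns) == 0:
                continue
            ident, span_a, span_b, _, _ = _alignment_stats(alns[0])
            shorter = min(len(reads[i]), len(reads[j]))
            cov = min(span_a, span_b) / shorter
            if best is None or (ident, cov) > best:
                best = (ident, cov)
        if best and best[0] > params.min_identity and best[1] >= params.min_coverage_fraction:
            hits.append((i, j, best[0], best[1]))
    return hits


def connected_clusters(
    hits: list, n_reads: int
) -> tuple[list[RepeatCluster], int]:
    """Connected components (>= 2 reads) of the hit graph, plus singlet count.

    Ordering is deterministic: by size (largest first), then smallest
    member read id.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_reads))
    for h in hits:
        i, j = h[0], h[1]
        if not (0 <= i < n_reads and 0 <= j < n_reads):
            raise ValueError("hit references invalid read index")
        g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    clusters = [RepeatCluster(id=i, read_ids=c) for i, c in enumerate(comps)]
    singlets = n_reads - sum(len(c) for c in comps)
    return clusters, singlets


def filter_clusters(
    clusters: list, params: ClusteringParams, n_reads: int
) -> list:
    """Keep clusters holding at least min_cluster_fraction of the input reads;
    annotate genome_fraction (percent of sampled reads)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    out = []
    for c in clusters:
        frac = len(c.read_ids) / n_reads
        if frac >= params.min_cluster_fraction:
            c.genome_fraction = 100.0 * frac
            out.append(c)
    return out


def build_contigs(
    cluster: RepeatCluster,
    reads: list,
    hits: list | None = None,
    min_overlap: int = 30,
    min_identity: float = 90.0,
    max_contig: int = 5000,
) -> list[str]:
    """Greedy overlap-layout-consensus contigs for one cluster.

    Seeds with the best-connected read and extends with reads that align to
    the growing consensus at >= min_identity over >= min_overlap bp; column
    majority gives the consensus. Emits >= 1 contig; unplaced reads seed
    further contigs.
    """
    ids = list(cluster.read_ids)
    if not ids:
        raise ValueError("empty cluster")
    degree = {i: 0 for i in ids}
    if hits:
        members = set(ids)
        for h in hits:
            if h[0] in members and h[1] in members:
                degree[h[0]] += 1
                degree[h[1]] += 1
    order = sorted(ids, key=lambda i: (-degree[i], i))
    aligner = _aligner()
    unplaced = list(order)
    contigs = []
    while unplaced:
        seed = unplaced.pop(0)
        columns: dict[int, dict] = {}

        def place(seq: str, offset: int) -> None:
            for p, ch in enumerate(seq):
                col = columns.setdefault(offset + p, {})
                col[ch] = col.get(ch, 0) + 1

        def consensus() -> tuple[str, int]:
            if not columns:
                return "", 0
            lo, hi = min(columns), max(columns)
            s = "".join(
                max(sorted(columns[p]), key=lambda c: columns[p][c])
                if p in columns
                else "N"
                for p in range(lo, hi + 1)
            )
            return s, lo

        place(reads[seed], 0)
        progress = True
        while progress and unplaced:
            progress = False
            cons, lo = consensus()
            if len(cons) >= max_contig:
                break
            placed_now = []
            for rid in unplaced:
                best = None
                for seq in (reads[rid], revcomp(reads[rid])):
                    alns = aligner.align(cons, seq)
                    if len(alns) == 0:
                        continue
                    ident, span_a, span_b, a0, b0 = _alignment_stats(alns[0])
                    ov = min(span_a, span_b)
                    if ident >= min_identity and ov >= min_overlap:
                        if best is None or ident > best[0]:
                            best = (ident, lo + a0 - b0, seq)
                if best is not None:
                    place(best[2], best[1])
                    placed_now.append(rid)
                    progress = True
            for rid in placed_now:
                unplaced.remove(rid)
        cons, _ = consensus()
        contigs.append(cons)
    return contigs


def sample_reads(
    reads: dict, genome_size_weights: dict, max_reads: int, seed: int
) -> dict:
    """Sample per-species reads proportionally to genome size weights.

    Largest-remainder rounding over the weights, total <= max_reads; the
    draw within each species is seeded and without replacement.
    """
    if set(reads) != set(genome_size_weights):
        raise ValueError("weights and read sets name different species")
    if any(w <= 0 for w in genome_size_weights.values()):
        raise ValueError("weights must be positive")
    species = sorted(reads)
    total_w = sum(genome_size_weights[s] for s in species)
    exact = {s: max_reads * genome_size_weights[s] / total_w for s in species}
    counts = {s: int(np.floor(exact[s])) for s in species}
    remainder = max_reads - sum(counts.values())
    order = sorted(species, key=lambda s: (-(exact[s] - counts[s]), s))
    for s in order[:remainder]:
        counts[s] += 1
    out = {}
    for s in species:
        n = min(counts[s], len(reads[s]))
        rng = rng_for(seed, "sample", s)
        idx = sorted(rng.choice(len(reads[s]), size=n, replace=False))
        out[s] = [reads[s][i] for i in idx]
    return out
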
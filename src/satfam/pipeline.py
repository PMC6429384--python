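"""End-to-end orchestration: simulate -> cluster -> tandem -> HOR -> classify -> tree.

Mirrors the analysis route taken for real data: reads are clustered per
species, cluster contigs are tested for family membership against the
ancestral reference, family contigs go through tandem detection, detected
consensi feed the HOR inventory and the k-mer phylogeny, and the per-species
metrics are classified into evolutionary modes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from . import ancestor, clustering, hor, kphylo, lifehistory, satsim, tandem
from .seqio import derive_seed

logger = logging.getLogger("satfam")


@dataclass
class SpeciesAnalysis:
    species: str
    n_reads: int
    clusters: list
    singlets: int
    family_clusters: list
    family_hits: list  # TandemHit, annotated
    monomers: list  # period-length frames cut from the dominant family cluster
    anchor: str | None = None  # consensus used to phase-align the monomers
    consensus: str | None = None  # majority consensus over phase-aligned frames
    classification: lifehistory.EvolutionClassification | None = None


def analyze_species_reads(
    species: str,
    reads: list,
    reference: str,
    seed: int = 0,
    cluster_params: clustering.ClusteringParams | None = None,
    tandem_params: tandem.TandemParams | None = None,
    thresholds: lifehistory.ClassificationThresholds | None = None,
    max_clusters_assembled: int = 10,
) -> SpeciesAnalysis:
    """Cluster one species' reads and derive its family metrics."""
    cluster_params = cluster_params or clustering.ClusteringParams()
    tandem_params = tandem_params or tandem.TandemParams()
    thresholds = thresholds or lifehistory.ClassificationThresholds()

    hits = clustering.pairwise_hits(reads, cluster_params) if len(reads) >= 2 else []
    clusters, singlets = clustering.connected_clusters(hits, len(reads))
    clusters = clustering.filter_clusters(clusters, cluster_params, len(reads))

    family_clusters = []
    family_hits = []
    monomers: list = []
    anchor = None
    for cl in clusters[:max_clusters_assembled]:
        cl.contigs = clustering.build_contigs(cl, reads, hits)
        member = any(
            lifehistory.family_membership(
                contig,
                reference,
                thresholds.membership_min_identity,
                thresholds.membership_min_len,
            )[0]
            for contig in cl.contigs
        )
        cl.family_member = member
        if not member:
            continue
        family_clusters.append(cl)
        contig = max(cl.contigs, key=len)
        det = tandem.detect_tandem(contig, tandem_params)
        if det:
            top = det[0]
            top.species = species
            top.seq_id = f"cluster{cl.id}"
            top.family_member = True
            family_hits.append(top)
    # homogenisation sample: period-length frames cut from the reads of the
    # largest family cluster (rotation is normalised downstream, so read
    # phase is free; restricting to one cluster keeps rare chance-membership
    # clusters from contaminating the sample)
    if family_clusters:
        biggest = max(family_clusters, key=lambda c: len(c.read_ids))
        hit = next((h for h in family_hits if h.seq_id == f"cluster{biggest.id}"), None)
        if hit is None:
            hit = family_hits[0] if family_hits else None
        read_len = max(len(reads[r]) for r in biggest.read_ids)
        p = len(reference)
        if hit is not None:
            if 2 * hit.period <= read_len:
                p = hit.period
            else:
                # period longer than reads (diverged or higher-order arrays):
                # fall back to the basic-monomer subperiod of the consensus
                mod = hor.decompose_consensus(hit.consensus) if len(hit.consensus) >= 30 else None
                if mod is not None and 2 * mod.subrepeat_length <= read_len:
                    p = mod.subrepeat_length
        for rid in biggest.read_ids:
            r = reads[rid]
            monomers.extend(r[i : i + p] for i in range(0, len(r) - p + 1, p))
        if hit is not None:
            anchor = hit.consensus[:p]

    consensus = None
    if anchor and len(monomers) >= 5:
        # low-variance species consensus: column majority over the
        # phase-aligned frames (many more copies vote than in one contig)
        rotated = [lifehistory._phase_to_anchor(m, anchor) for m in monomers[:200]]
        from .seqio import majority_consensus

        consensus = majority_consensus(rotated)
    return SpeciesAnalysis(
        species=species,
        n_reads=len(reads),
        clusters=clusters,
        singlets=singlets,
        family_clusters=family_clusters,
        family_hits=family_hits,
        monomers=monomers,
        anchor=anchor,
        consensus=consensus,
    )


def run_all(
    fixture_name: str = "seven_species",
    seed: int = 1,
    thresholds: lifehistory.ClassificationThresholds | None = None,
) -> dict:
    """Full pipeline on a named fixture; returns the report dict.

    Also attaches intermediate per-species analyses under '_analyses' and
    the fixture bundle under '_bundle' (underscore keys are dropped when the
    report is serialised).
    """
    t0 = time.time()
    thresholds = thresholds or lifehistory.ClassificationThresholds()
    bundle = satsim.fixture(fixture_name, seed=seed)
    truth = bundle.truth
    cfg = bundle.config
    reads = satsim.fragment_to_reads(truth, cfg.read_length, cfg.coverage, seed)
    reference = ancestor.family_reference().sequence

    analyses: dict[str, SpeciesAnalysis] = {}
    for sp in sorted(reads):
        logger.info("analysing %s (%d reads)", sp, len(reads[sp]))
        analyses[sp] = analyze_species_reads(
            sp, reads[sp], reference, seed=seed, thresholds=thresholds
        )

    hits_per_species = {sp: a.family_hits for sp, a in analyses.items()}
    units, hor_counts = hor.hor_inventory(hits_per_species, reference)

    classifications = []
    for sp, a in sorted(analyses.items()):
        c = lifehistory.classify_lineage(
            sp,
            n_family_clusters=len(a.family_clusters),
            n_hor_units=hor_counts.get(sp, 0),
            homog_index=(
                lifehistory.homogenization_index(
                    a.monomers, seed=derive_seed(seed, "homog", sp), anchor=a.anchor
                )
                if len(a.monomers) >= 10
                else None
            ),
            thresholds=thresholds,
        )
        a.classification = c
        classifications.append(c)

    consensi = {"ancestral": reference}
    for sp, a in analyses.items():
        if a.consensus:
            consensi[sp] = a.consensus
        elif a.family_hits:
            consensi[sp] = max(a.family_hits, key=lambda h: h.score).consensus
    tree_newick = None
    if len(consensi) >= 3:
        tree_newick = kphylo.monomer_tree_pipeline(consensi)

    partial = any(not a.family_hits for a in analyses.values())
    rep = lifehistory.report(
        classifications, tree_newick=tree_newick, hor_counts=hor_counts, partial=partial
    )
    rep["_analyses"] = analyses
    rep["_bundle"] = bundle
    rep["_units"] = units
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return rep
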
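# satfam

Satellite DNA (satDNA) families — tandem arrays of a short monomer — evolve
by molecular drive: unequal exchange amplifies and contracts arrays, gene
conversion homogenises them (concerted evolution), and occasionally a block
of diverged monomers becomes the new unit of amplification, a higher-order
repeat (HOR). Related plant lineages inheriting one ancestral monomer can
therefore end up with very different family structures: a single
homogeneous ~40-bp monomer, species-specific HOR units (e.g. 117 bp = three
diverged 39-bp subrepeats), or a poorly homogenised swarm of divergent
subfamilies.

`satfam` is a desk-scale, fully tested pipeline for reconstructing that
life history from shotgun reads, aimed at repeat-biology researchers who
want a reproducible, simulation-validated alternative to chaining web
tools. It provides:

* **`satsim`** — a forward simulator of satDNA evolution over a lineage
  tree (point mutation, indels, unequal exchange, gene conversion, HOR
  formation; concerted vs non-concerted regimes) with full ground truth.
* **`clustering`** — all-vs-all read similarity graph (hits at >90%
  identity over ≥55% of the shorter read, either strand), connected-
  component repeat clusters, abundance filtering (≥0.01% of reads), and
  greedy consensus contigs.
* **`tandem`** — a tandem-repeat detector: probe k-mer candidate periods,
  wraparound dynamic programming against a cyclic consensus
  (match +2 / mismatch −7 / indel −7), iterative consensus refinement, and
  the familiar table row (period, copy number, % matches, % indels,
  consensus, score).
* **`hor`** — consensus decomposition into subrepeats, the basic-monomer
  vs HOR-unit decision, and a per-species inventory of proposed HOR units.
* **`ancestor`** — combinatorial reconstruction of the conserved ancestral
  monomer fragment as the longest exactly shared circular substring across
  species monomer sets.
* **`kphylo`** — alignment-free distances from the fractional common
  k-mer count F = |P₁∩P₂|/min(|P₁|,|P₂|) at k = 9 (distance 1−F), with a
  minimum-evolution tree (NJ start, OLS branch lengths, NNI search) rooted
  at the ancestral monomer.
* **`lifehistory`** — family membership against the ancestral reference, a
  homogenisation index (mean pairwise monomer identity), and a three-way
  classification of each lineage: `concerted_mutational`, `concerted_hor`,
  or `non_concerted`.

## Worked example

The HOR worked example plants a 117-bp unit built from three ~16%-diverged
39-bp subrepeats, amplified 35 times with 2% per-copy divergence:

```python
from satfam import fixture, detect_tandem, decompose_consensus, reconstruct_ancestral

bundle = fixture("hor_worked_example")
array = bundle.truth.species_arrays["acuminatum"][0]

hit = detect_tandem(array)[0]
print(f"period={hit.period}  copy_number={hit.copy_number:.1f}  "
      f"percent_matches={hit.percent_matches:.1f}  score={hit.score:.0f}")

model = decompose_consensus(hit.consensus)
print(f"subrepeats: {model.subrepeat_count} x {model.subrepeat_length} bp, "
      f"mean internal identity {model.mean_internal_identity:.1f}%")

two = fixture("two_species_ancestor")
frag = reconstruct_ancestral({sp: m[0] for sp, m in two.truth.species_monomers.items()})
print(f"ancestral fragment ({frag.length} bp): {frag.sequence}")
```

prints

```
period=117  copy_number=35.0  percent_matches=98.0  score=7445
subrepeats: 3 x 39 bp, mean internal identity 82.9%
ancestral fragment (37 bp): TCAAACAAAGCTAATTGAATCAAATGAAAGTCAAATG
```

The detector reports the 117-bp duplication unit — not the 39-bp
subrepeat, whose per-position match support is far lower — and the
decomposition recovers three subrepeats at 82.9% mutual identity, inside
the 82–86% range typical of physical HOR subrepeat copies. The
reconstruction intersects the two species' monomer sets down to the
conserved 37-bp ancestral core, the family reference used for membership
tests and tree rooting.

A full run on the seven-lineage fixture (mixed regimes, random genomic
background, 5× read coverage):

```bash
satfam all --fixture seven_species --seed 1 -o out/
satfam report -o out/
```

writes `out/report.json`, `out/kmer_tree.nwk`, arrays/reads/truth files,
and prints one line per species with its cluster count, HOR count,
homogenisation index and mode — recovering the planted
`concerted_mutational` / `concerted_hor` / `non_concerted` labels.

Individual stages are also exposed (`satfam simulate | cluster | tandem |
hor | ancestor | tree | classify`), each reading and writing plain
FASTA/FASTQ/TSV/Newick/JSON, so real read sets can be fed through the same
route. See `docs/methods.md` for the model, parameter meanings, and
limitations.

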
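# Methods

`satfam` analyses the life history of a satellite-DNA (satDNA) family across
related lineages: it clusters shotgun reads into repeat families, detects
tandem monomers and their consensus, decides whether a detected unit is a
basic monomer or a higher-order repeat (HOR), reconstructs the conserved
ancestral monomer fragment shared across species, places each lineage's
consensus monomer on an alignment-free k-mer tree rooted at that ancestor,
and classifies each lineage's evolutionary mode. A forward simulator of
satDNA evolution provides ground-truthed inputs for validation.

## The evolutionary model behind the simulator

The simulator (`satsim`) implements the satDNA library hypothesis with
molecular drive. A single ancestral monomer (by default the conserved 37-bp
family core plus a 3-bp flank, 40 bp total) is amplified into a tandem
array of `array_copies_target` copies at the root of a rooted lineage tree,
and the array evolves independently along each branch under five processes:

* **Point mutation** — per-site Poisson events at `point_mut_rate`
  (substitutions/site/time-unit); a hit site changes to one of the three
  other bases, so the realised leaf-to-leaf divergence follows Jukes–Cantor
  expectations.
* **Indels** — `indel_rate` events/site/unit; geometric lengths (mean 1.5);
  each monomer's length is clamped to ±20% of the ancestral length so
  arrays cannot degenerate.
* **Unequal exchange** — `exchange_rate` events/array/unit; a contiguous
  run of monomers (geometric run length, mean 3) is duplicated or deleted
  with equal probability; deletion never empties the array. This is the
  stochastic amplification/contraction engine.
* **Gene conversion** — `conversion_rate` events/array/unit; a random
  donor monomer overwrites a random acceptor (whole-monomer tract). This
  is the homogenisation engine: it is a Moran process whose pairwise
  coalescence rate is 2c/N(N−1) for rate c and array size N, so the
  equilibrium intra-array heterozygosity is roughly 2μL/(2μL + λ).
  Partial-tract conversion is available through `apply_gene_conversion`
  but branch evolution uses whole-monomer tracts — the regime that
  homogenises on the timescales simulated.
* **HOR formation** — with probability `hor_prob` per eligible terminal
  branch, a block of `hor_block_size` adjacent monomers becomes the new
  unit of amplification: the array is replaced by tandem copies of the
  merged block, and subsequent conversion/exchange act on whole units, so
  the within-unit subrepeat differences present at formation are frozen
  and then drift apart as fixed differences (rate ≈ μ per site per unit
  time), while unit copies stay homogenised. The event is drawn in the
  older half of the branch: observed HOR units are ancient, already
  homogenised structures.

A leaf in the `non_concerted` regime has conversion and exchange rates
multiplied by `suppression_factor` ∈ [0,1] on its terminal branch; with a
small factor the array's monomers diverge essentially independently,
producing the low-homogenisation, multidirectional regime.

Arrays are ordered lists of monomer strings; flattening happens only at
read generation, so every event is exact and logged (`event_log`). All
randomness derives from one root seed via per-branch hashed streams, so
per-branch results are order-independent and runs are byte-reproducible.

### What the generator does and does not emulate

Reads are exact uniform substrings of the arrays plus an optional random
"filler" background per species (the non-family genome fraction); there is
no sequencing-error or quality model, no transposable-element sequence
content, and array fragmentation is only implicit (multiple arrays per
species). Consequently, passing tests demonstrate that the analysis
recovers planted structure under idealised reads at desk scale; they do
not establish robustness to base-calling error, library bias, or
genome-scale repeat landscapes.

### Fixture study conditions

* `cfic_like` — one uniform array: the 40-bp monomer in 200 copies, each
  copy independently ~5% substituted (giving 87–96% matches per copy
  against the consensus, the regime typical of homogeneous satellite
  arrays); seed 1, reads 150 bp at 5× coverage.
* `hor_worked_example` — a 117-bp HOR of three 39-bp subrepeats, mutually
  ~16% diverged (the midpoint of the 82–86% similarity observed among
  physical subrepeat copies of such units), amplified into 35 units with
  2% per-unit divergence; seed 7.
* `two_species_ancestor` — two leaves descending from the 37-bp core
  embedded in a 40-bp monomer; the core is mutation-free and the three
  flank bases are fully and differently substituted in the two leaves, so
  the exactly conserved shared region is the core itself; seed 3.
* `vulvaria_like` — six subfamilies independently ~15% diverged from one
  ancestor plus two planted HOR arrays; the multi-subfamily,
  low-homogenisation genome.
* `seven_species` — seven lineages on the clade topology
  `(vulvaria:1.5,(bryoniifolium:0.8,((ficifolium:0.2,suecicum:0.2):0.5,
  (acuminatum:0.6,(pamiricum:0.2,iljinii:0.2):0.4):0.2):0.2):0.2)`, with
  μ = 0.15 subs/site/unit, conversion 15 600 events/array/unit on 40-copy
  arrays (equilibrium intra-array divergence ~2–3%), indels 5·10⁻⁴,
  exchange 1/array/unit, a forced HOR event on the `acuminatum` terminal,
  and conversion suppressed ×0.001 on the `vulvaria` terminal (~35%
  intra-array divergence at the leaf while the consensus stays
  family-recognisable). Short cherry terminals with longer inter-clade
  stems give each split several expected fixed differences — the signal
  the 9-mer distances need — while keeping every leaf within ~25%
  divergence of the ancestral reference. Each species also carries 3 kb of
  random filler so clustering and membership are tested against a
  non-family background. None of these rates is an estimate of real
  *Chenopodium* parameters; they are a realistic regime in arbitrary time
  units chosen once to express the three planted modes.

## Tandem detection

Candidate periods are distances at which 5-mers reoccur: support at
distance d is the number of identical probe k-mer pairs exactly d apart;
a candidate must exceed both the Poisson background (n−d)/4ᵏ + 5σ and a
signal floor of one tenth of the Bernoulli-model expectation
match_prob^k·(n−d). Each candidate is refined by wraparound dynamic
programming of the sequence against the cyclic consensus (match +2,
mismatch −7, indel −7 — the familiar tandem-repeat-finder regime),
alternating column-majority consensus updates with realignment to a
fixpoint (≤10 iterations). The DP is exact and unbanded, row-vectorised;
banding is unnecessary at the contracted input sizes (≤100 kb).

Among candidate periods (which all span the input — inputs under contract
are arrays or cluster contigs that are tandem end-to-end), the reported
unit is the one with decisively the highest per-position match support:
starting from the shortest candidate, a longer period is promoted only if
its support density support/(n−d) exceeds the current choice's by >20%
*and* its wraparound percent-matches is better by >2 points. A basic
monomer and its multiples tie on both counts, so exact p-vs-2p resolves to
p; a true HOR (subrepeats ~15% diverged, units ~2–5%) exceeds both
margins severalfold. Consensus sequences are reported in canonical
rotation (lexicographically smallest over both strands); copy number is
aligned length divided by the period and may be fractional.

## HOR decision

`decompose_consensus` scans subperiods p, cuts the consensus into ⌈L/p⌉
frames (ragged last frame handled by gap-tolerant alignment) and returns
the p maximising mean pairwise frame identity if it reaches 60%.
`choose_unit` promotes a longer candidate period only if its percent
matches beats the shorter by ≥5 points (derived from the printed
similarity ranges: subrepeat copies 82–86% similar versus unit copies
≥95% give an expected gap of ~8–11 points, so the margin sits between
that signal and the ~0-point null) with at least equal column
homogeneity. The inventory proposes a HOR unit for every family hit whose
consensus decomposes, is longer than 1.5× the reference monomer, and has
subrepeats between 60% and 95% mutual identity — near-identical subrepeats
are a plain multiple of the basic monomer, not a higher-order unit —
de-duplicated per species at 95% rotation/strand-normalised identity.

## Ancestral reconstruction

Monomers are circular and strand-symmetric, so each is doubled
(s+s truncated to 2L−1) and searched on both strands. Maximal exact
substrings (≥8 bp; below that, matches are indistinguishable from chance
in 40-bp monomers) shared between two species' monomer sets seed the
search; each seed is shrunk to its longest window exactly present in
every remaining species. The longest such window wins (ties:
lexicographically smallest canonical form) and is reported in the
orientation in which it occurs in the input monomers. The method is
purely combinatorial — no probabilistic ancestral state reconstruction —
mirroring how a conserved core is recovered from 100%-identity matches.
The shipped default family reference is the reconstructed 37-bp core.

## k-mer phylogeny

Distinct 9-mers (presence/absence — a 9-mer rarely repeats within a short
monomer) are collected from the canonical rotation of each sequence,
wrapped circularly so phase cannot matter. Similarity is the fractional
common k-mer count F = |P₁∩P₂|/min(|P₁|,|P₂|); the default distance is
1−F, with −ln F available (`distance_form="neg_log_F"`, ε guarded). Which
of the two forms the original method used is not recoverable; both are
provided and the default documented. Trees: neighbor joining gives the
starting topology; branch lengths are ordinary least squares over the
path-indicator system; exhaustive nearest-neighbour-interchange passes
hill-climb on the minimum-evolution criterion (total OLS length);
negative lengths are clamped to zero after the search; the tree is rooted
on the `ancestral` leaf. At ≤~30 taxa NNI passes are adequate and fully
deterministic. Note that 1−F saturates near 1 for divergences beyond
~25–30%, so deep relative placements carry little information even when
cherries are solid.

## Clustering and membership

All-vs-all read comparison requires a shared 13-mer before a local
alignment (match +1, mismatch −2, gap −3, both strands); a hit needs
identity >90% over ≥55% of the shorter read. Clusters are connected
components (community splitting is out of scope); components of one read
are singlets. Abundance filtering keeps clusters with ≥0.01% of the input
reads by default; `genome_fraction` is the percentage of sampled reads in
the cluster. Contigs are greedy overlap-layout consensus (seed = most
connected read, extension at ≥90% identity over ≥30 bp, column majority);
for tandem repeats they are consensus artifacts and may be partially
chimeric — they are treated as evidence of the repeat unit, never as
physical sequences. Comparative sampling is proportional to genome-size
weights with largest-remainder rounding.

Family membership of a contig/consensus is a full-reference alignment:
the whole reference must match somewhere in the circularly doubled
sequence (either strand) at ≥`min_identity` percent
(100·(1−editdist/len(ref))). Full-span matching separates sharply:
random few-hundred-bp contigs essentially never reach 70% full-span
identity, while family descendants up to ~25% diverged do. The bare
operation defaults to 70%/15 bp; the pipeline's classification thresholds
use 72.5%, calibrated on simulated family vs filler contigs.

## Homogenisation index and classification

The homogenisation index is the mean pairwise gap-tolerant identity among
up to 200 sampled monomers, mapped to [0,1]. In the pipeline the monomers
are period-length frames cut from the reads of the dominant family
cluster and phase-aligned once to the cluster consensus; pairs are then
compared at fixed phase. (Per-pair best-rotation matching is upward
biased for diverged monomers, and a lexical canonical-rotation anchor is
unstable under point mutation; the consensus anchor avoids both.)

Classification is a deterministic rule over three metrics, thresholds
always recorded in the audit trail: a lineage is `non_concerted` if it
has ≥3 family clusters or index <0.75; otherwise `concerted_hor` if any
HOR unit is inventoried; otherwise `concerted_mutational`. The
thresholds are explicit stand-ins for qualitative criteria, calibrated on
the fixtures and configurable (`ClassificationThresholds`).

## Numerical and degenerate-input choices

* Wraparound DP scores are small integers in float32 (exact below 2²⁴);
  traceback prefers diagonal, then vertical, then horizontal moves.
* Consensus refinement may change the period (majority-deleted columns
  drop, majority-inserted columns add); the reported period is the final
  consensus length.
* `candidate_periods` requires len ≥ 4·probe_kmer (20 bp at the default
  probe); shorter inputs raise; `detect_tandem` returns an empty list for
  inputs below the floor or with no passing candidate.
* Single-leaf trees are rejected at serialisation (no topology); duplicate
  leaf labels are rejected.
* Distance matrices must be symmetric, non-negative, zero-diagonal;
  identical sequences produce zero-length cherries, which are valid.
* Contraction in unequal exchange always retains ≥1 monomer; conversion
  with donor == acceptor is a no-op.

## Problem sizes

Fixtures run at desk scale by design: arrays of 35–200 monomers (1.5–8 kb),
40–80 reads of 150–300 bp per species at 5× template coverage, seven
species, five replicate seeds. These sizes keep every worked example
under a minute and the full validation suite under a few minutes while
leaving each statistical check several standard deviations of headroom.

## Known limitations

* Sub-sequence tandem localisation is not implemented: hits span the
  whole input, which is correct for arrays and satellite cluster contigs
  but would mis-describe a mostly-unique sequence containing a short
  embedded array.
* The 1−F distance saturates at high divergence; deep placements on the
  k-mer tree are qualitative.
* Greedy contigs can be chimeric for tandem input (inherent to
  overlap-layout on repeats); downstream steps treat them only as
  consensus evidence.
* Real-data genome-scale cluster counts and genome percentages are out of
  scope; the pipeline reproduces the three evolutionary modes on
  simulations and accepts user FASTQ through the same report schema
  without claiming species-level reproduction of published counts.
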
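"""Simulation of satellite-DNA family evolution over a lineage tree.

The model follows the satDNA library hypothesis with molecular drive: an
ancestral monomer is amplified into a tandem array in the root lineage and
the array then evolves along each branch of a rooted species tree under

* point mutation (per site, Jukes–Cantor-style: a hit site changes to one
  of the three other bases),
* small indels within monomers (geometric length, mean 1.5; monomer length
  clamped to ±20% of the ancestral length so arrays cannot degenerate),
* unequal exchange (duplication or deletion of a contiguous monomer run,
  50/50) — the stochastic amplification/contraction engine,
* gene conversion (non-reciprocal overwrite of an acceptor monomer's tract
  by a donor's) — the homogenisation engine of concerted evolution,
* higher-order-repeat (HOR) formation: a block of diverged monomers becomes
  the new unit of amplification and homogenisation.

A leaf in the ``non_concerted`` regime has its conversion/exchange rates
multiplied by a suppression factor in [0, 1] on its terminal branch,
producing the low-homogenisation, multidirectional regime.

Arrays are ordered lists of monomer strings (flattened only for read
generation), so every event is exact and auditable in the event log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import (
    derive_seed,
    majority_consensus,
    read_newick,
    rng_for,
)

BASES = "ACGT"

#: Conserved ancestral monomer fragment of the family (37 bp), shipped as
#: the default family reference for membership tests and tree rooting.
ANCESTRAL_CORE_37 = "TCAAACAAAGCTAATTGAATCAAATGAAAGTCAAATG"


@dataclass(frozen=True)
class HORTruth:
    """Ground truth of one planted higher-order repeat."""

    unit_length: int
    subrepeat_length: int
    subrepeat_count: int
    unit_sequence: str = ""


@dataclass
class SimConfig:
    ancestral_monomer: str = ANCESTRAL_CORE_37 + "GCT"
    tree_newick: str = "(left:1.0,right:1.0);"
    point_mut_rate: float = 0.0  # substitutions / site / time unit
    indel_rate: float = 0.0  # events / site / time unit
    exchange_rate: float = 0.0  # events / array / time unit
    conversion_rate: float = 0.0  # events / array / time unit
    hor_prob: float = 0.0  # probability of one HOR event per eligible branch
    hor_block_size: int = 3
    hor_branches: frozenset = None  # leaf names eligible for HOR; None = all leaves
    regimes: dict = field(default_factory=dict)  # leaf -> concerted | non_concerted
    suppression_factor: float = 0.05
    array_copies_target: int = 50
    read_length: int = 100
    coverage: float = 5.0
    seed: int = 0
    protected_sites: frozenset = frozenset()  # ancestral-monomer sites immune to mutation
    planted_leaf_monomers: dict = None  # leaf -> monomer overriding branch start
    filler_bp: int = 0  # random non-family background sequence per leaf

    def validate(self) -> None:
        if not self.ancestral_monomer:
            raise ValueError("ancestral monomer must be non-empty")
        if len(self.ancestral_monomer) < 10:
            raise ValueError("ancestral monomer must be >= 10 bp")
        for r in (
            self.point_mut_rate,
            self.indel_rate,
            self.exchange_rate,
            self.conversion_rate,
        ):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if not 0.0 <= self.suppression_factor <= 1.0:
            raise ValueError("suppression factor must be in [0,1]")
        tree = read_newick(self.tree_newick)
        tips = list(tree.tips())
        if len(tips) < 2:
            raise ValueError("lineage tree must have >= 2 leaves (rooted)")
        for reg in self.regimes.values():
            if reg not in ("concerted", "non_concerted"):
                raise ValueError(f"unknown regime {reg!r}")


@dataclass
class SimTruth:
    species_arrays: dict  # species -> list of flat DNA strings
    species_monomers: dict  # species -> list of monomer lists (one per array)
    true_tree: str  # newick
    planted_monomer: dict  # species -> consensus monomer string
    planted_hors: dict  # species -> list[HORTruth]
    event_log: list  # (branch, time, event_type, details)
    filler: dict = field(default_factory=dict)  # species -> background string

    def to_json_dict(self) -> dict:
        return {
            "species_arrays": self.species_arrays,
            "true_tree": self.true_tree,
            "planted_monomer": self.planted_monomer,
            "planted_hors": {
                sp: [vars(h) for h in hs] for sp, hs in self.planted_hors.items()
            },
            "event_log": [list(e) for e in self.event_log],
        }


# --- elementary events ---------------------------------------------------


def _point_mutate(monomer: str, pos: int, rng: np.random.Generator) -> str:
    old = monomer[pos]
    choices = [b for b in BASES if b != old]
    new = choices[int(rng.integers(len(choices)))]
    return monomer[:pos] + new + monomer[pos + 1 :]


def _indel(monomer: str, rng: np.random.Generator, min_len: int, max_len: int) -> str:
    length = 1 + int(rng.geometric(2.0 / 3.0)) - 1  # geometric, mean 1.5
    length = max(1, length)
    if rng.random() < 0.5 and len(monomer) + length <= max_len:  # insertion
        pos = int(rng.integers(len(monomer) + 1))
        ins = "".join(BASES[int(rng.integers(4))] for _ in range(length))
        return monomer[:pos] + ins + monomer[pos:]
    if len(monomer) - length >= min_len:  # deletion
        pos = int(rng.integers(len(monomer) - length + 1))
        return monomer[:pos] + monomer[pos + length :]
    return monomer


def apply_unequal_exchange(
    array: list,
    seed,
    op: str | None = None,
    start: int | None = None,
    run_len: int | None = None,
) -> list:
    """One unequal-exchange event: duplicate or delete a contiguous monomer run.

    ``seed`` may be an int or a numpy Generator. ``op``/``start``/``run_len``
    force a specific event (used by callers that replay logged events).
    Contraction never empties the array.
    """
    if len(array) < 2:
        raise ValueError("array must contain >= 2 monomers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(array)
    if op is None:
        op = "duplicate" if rng.random() < 0.5 else "delete"
    if run_len is None:
        run_len = max(1, int(rng.geometric(1.0 / 3.0)))  # mean run of 3 monomers
        run_len = min(run_len, max(1, n // 2))
    if op == "delete":
        run_len = min(run_len, n - 1)  # keep >= 1 monomer
    if start is None:
        start = int(rng.integers(n - run_len + 1))
    run = array[start : start + run_len]
    if op == "duplicate":
        return array[:start] + run + run + array[start + run_len :]
    return array[:start] + array[start + run_len :]


def apply_gene_conversion(
    array: list,
    donor_index: int,
    acceptor_index: int,
    tract_len: int,
    tract_start: int = 0,
) -> list:
    """Non-reciprocal transfer: overwrite the acceptor's tract with the donor's.

    The tract is aligned by position (positions tract_start .. +tract_len);
    donor unchanged, array length unchanged.
    """
    n = len(array)
    if not (0 <= donor_index < n and 0 <= acceptor_index < n):
        raise IndexError("donor/acceptor index out of range")
    donor = array[donor_index]
    acceptor = array[acceptor_index]
    if tract_len > min(len(donor), len(acceptor)):
        tract_len = min(len(donor), len(acceptor))
    end = min(tract_start + tract_len, len(donor), len(acceptor))
    new = acceptor[:tract_start] + donor[tract_start:end] + acceptor[end:]
    out = list(array)
    out[acceptor_index] = new
    return out


def apply_hor_formation(
    array: list, block_start: int, block_size: int, n_copies: int | None = None
) -> tuple[list, HORTruth]:
    """A block of diverged monomers becomes the new amplification unit.

    The array is replaced by >= 3 tandem copies of the block; each copy is a
    single merged unit string so that subsequent conversion/exchange act on
    whole HOR units. Per-copy divergence is applied by the caller afterwards.
    """
    if block_size < 2:
        raise ValueError("HOR block size must be >= 2")
    if block_start < 0 or block_start + block_size > len(array):
        raise ValueError("block out of range")
    block = array[block_start : block_start + block_size]
    unit = "".join(block)
    if n_copies is None:
        n_copies = max(3, len(array) // block_size)
    n_copies = max(3, n_copies)
    truth = HORTruth(
        unit_length=len(unit),
        subrepeat_length=round(len(unit) / block_size),
        subrepeat_count=block_size,
        unit_sequence=unit,
    )
    return [unit] * n_copies, truth


# --- branch evolution ----------------------------------------------------


def _evolve_branch(
    monomers: list,
    branch_id: str,
    length: float,
    cfg: SimConfig,
    leaf_regime: str | None,
    event_log: list,
    hors: list,
) -> list:
    rng = rng_for(cfg.seed, "branch", branch_id)
    conv_rate = cfg.conversion_rate
    exch_rate = cfg.exchange_rate
    if leaf_regime == "non_concerted":
        conv_rate *= cfg.suppression_factor
        exch_rate *= cfg.suppression_factor

    L0 = len(cfg.ancestral_monomer)
    min_len = max(10, int(np.floor(L0 * 0.8)))
    max_len = int(np.ceil(L0 * 1.2))
    total_sites = sum(len(m) for m in monomers)

    events: list[tuple[float, str]] = []
    n_mut = rng.poisson(cfg.point_mut_rate * total_sites * length)
    n_ind = rng.poisson(cfg.indel_rate * total_sites * length)
    n_exc = rng.poisson(exch_rate * length)
    n_con = rng.poisson(conv_rate * length)
    for kind, n in (
        ("point_mutation", n_mut),
        ("indel", n_ind),
        ("unequal_exchange", n_exc),
        ("gene_conversion", n_con),
    ):
        events.extend((float(t), kind) for t in rng.uniform(0.0, length, size=int(n)))
    hor_eligible = leaf_regime is not None and (
        cfg.hor_branches is None or branch_id in cfg.hor_branches
    )
    if hor_eligible and cfg.hor_prob > 0 and rng.random() < cfg.hor_prob:
        # HOR formation is placed in the older half of the branch: observed
        # HOR units are ancient, already homogenised structures
        events.append((float(rng.uniform(0.0, length * 0.5)), "hor_formation"))
    events.sort(key=lambda e: (e[0], e[1]))

    arr = list(monomers)
    hor_done = False
    for t, kind in events:
        if kind == "point_mutation":
            weights = np.array([len(m) for m in arr], dtype=float)
            idx = int(rng.choice(len(arr), p=weights / weights.sum()))
            pos = int(rng.integers(len(arr[idx])))
            if not hor_done and pos in cfg.protected_sites:
                continue  # conserved-core site
            arr[idx] = _point_mutate(arr[idx], pos, rng)
            event_log.append((branch_id, t, kind, {"monomer": idx, "pos": pos}))
        elif kind == "indel":
            weights = np.array([len(m) for m in arr], dtype=float)
            idx = int(rng.choice(len(arr), p=weights / weights.sum()))
            if cfg.protected_sites and not hor_done:
                continue  # core protection: no frame shifts over the core
            arr[idx] = _indel(arr[idx], rng, min_len, max_len)
            event_log.append((branch_id, t, kind, {"monomer": idx}))
        elif kind == "unequal_exchange":
            if len(arr) < 2:
                continue
            op = "duplicate" if rng.random() < 0.5 else "delete"
            run_len = min(max(1, int(rng.geometric(1.0 / 3.0))), max(1, len(arr) // 2))
            if op == "delete":
                run_len = min(run_len, len(arr) - 1)
            start = int(rng.integers(len(arr) - run_len + 1))
            arr = apply_unequal_exchange(arr, rng, op=op, start=start, run_len=run_len)
            event_log.append(
                (branch_id, t, kind, {"op": op, "start": start, "run_len": run_len})
            )
        elif kind == "gene_conversion":
            if len(arr) < 2:
                continue
            donor = int(rng.integers(len(arr)))
            acceptor = int(rng.integers(len(arr)))
            if donor == acceptor:
                continue
            tract = len(arr[donor])  # whole-monomer tract (homogenising regime)
            arr = apply_gene_conversion(arr, donor, acceptor, tract)
            event_log.append(
                (branch_id, t, kind, {"donor": donor, "acceptor": acceptor, "tract": tract})
            )
        elif kind == "hor_formation" and not hor_done:
            if len(arr) < cfg.hor_block_size:
                continue
            block_start = int(rng.integers(len(arr) - cfg.hor_block_size + 1))
            arr, truth = apply_hor_formation(
                arr, block_start, cfg.hor_block_size, n_copies=len(arr) // cfg.hor_block_size
            )
            hors.append(truth)
            hor_done = True
            event_log.append(
                (branch_id, t, kind, {"block_start": block_start, "block_size": cfg.hor_block_size})
            )
    return arr


def evolve_library(config: SimConfig) -> SimTruth:
    """Evolve the ancestral monomer library over the lineage tree.

    With all rates zero every leaf array is exact tandem copies of the
    ancestral monomer; the whole run is reproducible from ``config.seed``.
    """
    config.validate()
    tree = read_newick(config.tree_newick)

    # deterministic internal-node labels for per-branch RNG streams
    counter = [0]
    for node in tree.preorder():
        if node.name is None:
            node.name = f"__n{counter[0]}"
            counter[0] += 1

    species_arrays: dict = {}
    species_monomers: dict = {}
    planted_monomer: dict = {}
    planted_hors: dict = {}
    event_log: list = []

    def recurse(node, monomers, inherited_hors):
        for child in node.children:
            if child.is_tip():
                regime = config.regimes.get(child.name, "concerted")
            else:
                regime = None
            start = monomers
            if (
                child.is_tip()
                and config.planted_leaf_monomers
                and child.name in config.planted_leaf_monomers
            ):
                start = [config.planted_leaf_monomers[child.name]] * len(monomers)
            hors = list(inherited_hors)
            out = _evolve_branch(
                start,
                child.name,
                float(child.length or 0.0),
                config,
                regime,
                event_log,
                hors,
            )
            if child.is_tip():
                species_monomers[child.name] = [out]
                species_arrays[child.name] = ["".join(out)]
                planted_hors[child.name] = hors
                # species-level monomer truth: majority consensus of units
                # of the modal length
                lens = [len(m) for m in out]
                modal = max(sorted(set(lens)), key=lens.count)
                rows = [m for m in out if len(m) == modal]
                planted_monomer[child.name] = majority_consensus(rows)
            else:
                recurse(child, out, hors)

    root_array = [config.ancestral_monomer] * config.array_copies_target
    recurse(tree, root_array, [])

    filler = {}
    if config.filler_bp > 0:
        for sp in species_arrays:
            rng = rng_for(config.seed, "filler", sp)
            filler[sp] = "".join(
                BASES[i] for i in rng.integers(0, 4, size=config.filler_bp)
            )

    event_log.sort(key=lambda e: (e[0], e[1], e[2]))
    return SimTruth(
        species_arrays=species_arrays,
        species_monomers=species_monomers,
        true_tree=config.tree_newick,
        planted_monomer=planted_monomer,
        planted_hors=planted_hors,
        event_log=event_log,
        filler=filler,
    )


def fragment_to_reads(
    truth: SimTruth, read_length: int, coverage: float, seed: int
) -> dict:
    """Draw reads uniformly from each species' arrays (plus background filler).

    Expected total bases per species = coverage × total template bases.
    Every read is an exact substring of a template (no sequencing error).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    out: dict = {}
    for sp in sorted(truth.species_arrays):
        templates = list(truth.species_arrays[sp])
        if truth.filler.get(sp):
            templates.append(truth.filler[sp])
        if min(len(t) for t in templates) < read_length:
            raise ValueError(
                f"read_length {read_length} exceeds shortest template of {sp}"
            )
        rng = rng_for(seed, "reads", sp)
        total = sum(len(t) for t in templates)
        n_reads = int(round(coverage * total / read_length))
        weights = np.array([len(t) for t in templates], dtype=float)
        weights /= weights.sum()
        reads = []
        for i in range(n_reads):
            ti = int(rng.choice(len(templates), p=weights))
            start = int(rng.integers(len(templates[ti]) - read_length + 1))
            reads.append(templates[ti][start : start + read_length])
        out[sp] = reads
    return out


# --- fixtures ------------------------------------------------------------


@dataclass
class FixtureBundle:
    name: str
    config: SimConfig
    truth: SimTruth
    expected: dict


def _mutate_fraction(s: str, frac: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``frac``."""
    out = list(s)
    for i in range(len(s)):
        if rng.random() < frac:
            out[i] = BASES[(BASES.index(out[i]) + 1 + int(rng.integers(3))) % 4]
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


#: Clade topology with short cherry terminals and long inter-clade stems:
#: the early-split suppressed lineage (vulvaria) carries the longest branch.
SEVEN_SPECIES_TREE = (
    "(vulvaria:1.5,(bryoniifolium:0.8,((ficifolium:0.2,suecicum:0.2):0.5,"
    "(acuminatum:0.6,(pamiricum:0.2,iljinii:0.2):0.4):0.2):0.2):0.2);"
)


def _fixture_cfic_like() -> FixtureBundle:
    """Uniform tandem array: one ~40-bp monomer, 200 copies, ~5% divergence."""
    monomer = ANCESTRAL_CORE_37 + "GCT"
    cfg = SimConfig(
        ancestral_monomer=monomer,
        tree_newick="(ficifolium:1.0,sister:1.0);",
        point_mut_rate=0.05,
        array_copies_target=200,
        read_length=150,
        coverage=5.0,
        seed=1,
    )
    truth = evolve_library(cfg)
    truth.species_arrays = {"ficifolium": truth.species_arrays["ficifolium"]}
    truth.species_monomers = {"ficifolium": truth.species_monomers["ficifolium"]}
    truth.planted_monomer = {"ficifolium": monomer}
    truth.planted_hors = {"ficifolium": []}
    return FixtureBundle(
        "cfic_like",
        cfg,
        truth,
        {"monomer_length": 40, "period": 40, "species": "ficifolium"},
    )


def _fixture_hor_worked_example() -> FixtureBundle:
    """A 117-bp HOR of three mutually ~16%-diverged 39-bp subrepeats.

    Subrepeat divergence targets the middle of the 82–86% similarity range
    observed among physical subrepeat copies; inter-unit divergence 2%.
    """
    seed = 7
    rng = rng_for(seed, "hor_fixture")
    base = _random_seq(39, rng)
    subs = [_mutate_fraction(base, 0.085, rng) for _ in range(3)]
    unit = "".join(subs)
    n_units = 35
    array = [_mutate_fraction(unit, 0.02, rng) for _ in range(n_units)]
    hor = HORTruth(unit_length=117, subrepeat_length=39, subrepeat_count=3, unit_sequence=unit)
    cfg = SimConfig(
        ancestral_monomer=base,
        tree_newick="(acuminatum:1.0,sister:1.0);",
        hor_prob=1.0,
        hor_block_size=3,
        array_copies_target=n_units,
        read_length=300,
        coverage=5.0,
        seed=seed,
    )
    truth = SimTruth(
        species_arrays={"acuminatum": ["".join(array)]},
        species_monomers={"acuminatum": [array]},
        true_tree=cfg.tree_newick,
        planted_monomer={"acuminatum": unit},
        planted_hors={"acuminatum": [hor]},
        event_log=[("acuminatum", 0.0, "hor_formation", {"block_size": 3})],
    )
    return FixtureBundle(
        "hor_worked_example",
        cfg,
        truth,
        {"unit_length": 117, "subrepeat_length": 39, "subrepeat_count": 3,
         "species": "acuminatum"},
    )


def _fixture_two_species_ancestor() -> FixtureBundle:
    """Two descendants of the printed ancestral core embedded in a 40-bp monomer.

    The 37-bp core is mutation-free in both leaves; the 3 flanking bases are
    fully diverged between the leaves (and from the ancestor), in particular
    at both core boundaries, so the conserved shared fragment is exactly the
    core.
    """
    seed = 3
    core = ANCESTRAL_CORE_37
    anc_flank = "GCT"
    monomer = core + anc_flank
    # deterministic planted flank divergence: every flank base differs
    # between the two leaves and from the ancestor
    shift1 = {"A": "C", "C": "G", "G": "T", "T": "A"}
    shift2 = {"A": "G", "C": "T", "G": "A", "T": "C"}
    flank_a = "".join(shift1[b] for b in anc_flank)
    flank_b = "".join(shift2[b] for b in anc_flank)
    cfg = SimConfig(
        ancestral_monomer=monomer,
        tree_newick="(bryoniifolium:1.0,vulvaria:1.0);",
        array_copies_target=20,
        read_length=100,
        coverage=5.0,
        seed=seed,
        protected_sites=frozenset(range(len(core))),
        planted_leaf_monomers={
            "bryoniifolium": core + flank_a,
            "vulvaria": core + flank_b,
        },
    )
    truth = evolve_library(cfg)
    return FixtureBundle(
        "two_species_ancestor",
        cfg,
        truth,
        {"ancestral_fragment": core, "fragment_length": 37},
    )


def _fixture_vulvaria_like(seed: int = 11) -> FixtureBundle:
    """Non-concerted regime: >= 5 divergent subfamilies plus planted HOR arrays."""
    rng = rng_for(seed, "vulvaria_fixture")
    ancestor = ANCESTRAL_CORE_37 + "GCT"
    arrays = []
    monomer_lists = []
    for _ in range(6):  # divergent subfamilies from one ancestor
        sub = _mutate_fraction(ancestor, 0.15, rng)
        mono = [_mutate_fraction(sub, 0.01, rng) for _ in range(30)]
        monomer_lists.append(mono)
        arrays.append("".join(mono))
    hors = []
    for _ in range(2):  # planted HOR arrays (3 diverged monomers per unit)
        block = [_mutate_fraction(_mutate_fraction(ancestor, 0.10, rng), 0.08, rng)
                 for _ in range(3)]
        unit = "".join(block)
        mono = [_mutate_fraction(unit, 0.02, rng) for _ in range(20)]
        monomer_lists.append(mono)
        arrays.append("".join(mono))
        hors.append(
            HORTruth(unit_length=len(unit), subrepeat_length=len(ancestor),
                     subrepeat_count=3, unit_sequence=unit)
        )
    cfg = SimConfig(
        ancestral_monomer=ancestor,
        tree_newick="(vulvaria:1.0,sister:1.0);",
        regimes={"vulvaria": "non_concerted"},
        read_length=300,
        coverage=5.0,
        seed=seed,
    )
    truth = SimTruth(
        species_arrays={"vulvaria": arrays},
        species_monomers={"vulvaria": monomer_lists},
        true_tree=cfg.tree_newick,
        planted_monomer={"vulvaria": ancestor},
        planted_hors={"vulvaria": hors},
        event_log=[],
    )
    return FixtureBundle(
        "vulvaria_like",
        cfg,
        truth,
        {"n_subfamilies": 6, "n_hor_units": 2},
    )


def _fixture_seven_species(seed: int = 1) -> FixtureBundle:
    """Seven diploid lineages on the clade topology, mixed regimes.

    Two same-clade cherries (ficifolium+suecicum, pamiricum+iljinii); one
    early-split suppressed-homogenisation lineage (vulvaria); one lineage
    with a forced HOR-formation event (acuminatum); the rest plain concerted.
    """
    cfg = SimConfig(
        ancestral_monomer=ANCESTRAL_CORE_37 + "GCT",
        tree_newick=SEVEN_SPECIES_TREE,
        point_mut_rate=0.15,
        indel_rate=0.0005,
        exchange_rate=1.0,
        conversion_rate=15600.0,
        hor_prob=1.0,
        hor_block_size=3,
        hor_branches=frozenset({"acuminatum"}),
        regimes={"vulvaria": "non_concerted"},
        suppression_factor=0.001,
        array_copies_target=40,
        read_length=300,
        coverage=5.0,
        seed=seed,
        filler_bp=3000,
    )
    truth = evolve_library(cfg)
    planted_modes = {}
    for sp in truth.species_arrays:
        if cfg.regimes.get(sp) == "non_concerted":
            planted_modes[sp] = "non_concerted"
        elif truth.planted_hors.get(sp):
            planted_modes[sp] = "concerted_hor"
        else:
            planted_modes[sp] = "concerted_mutational"
    return FixtureBundle(
        "seven_species",
        cfg,
        truth,
        {
            "planted_modes": planted_modes,
            "clade_pairs": [("ficifolium", "suecicum"), ("pamiricum", "iljinii")],
        },
    )


_FIXTURES = {
    "cfic_like": _fixture_cfic_like,
    "hor_worked_example": _fixture_hor_worked_example,
    "vulvaria_like": _fixture_vulvaria_like,
    "two_species_ancestor": _fixture_two_species_ancestor,
    "seven_species": _fixture_seven_species,
}


def fixture(name: str, seed: int | None = None) -> FixtureBundle:
    """Build a named study fixture: (config, realised truth, expected summary).

    ``seed`` overrides the fixture's default seed where the fixture is
    defined as a seed family (seven_species, vulvaria_like); the worked
    examples (cfic_like, hor_worked_example, two_species_ancestor) carry
    fixed seeds and ignore the argument.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    fn = _FIXTURES[name]
    if seed is not None and name in ("seven_species", "vulvaria_like"):
        return fn(seed=seed)
    return fn()
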
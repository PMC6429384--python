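"""Simulator: elementary events, whole-tree evolution, fixtures, regimes."""

import math

import numpy as np
import pytest

from satfam import satsim
from satfam.satsim import (
    ANCESTRAL_CORE_37,
    SimConfig,
    apply_gene_conversion,
    apply_hor_formation,
    apply_unequal_exchange,
    evolve_library,
    fixture,
    fragment_to_reads,
)
from satfam.seqio import rotated_identity_percent


def _zero_rate_config(**kw):
    defaults = dict(
        ancestral_monomer="ACGTTGCAACGTTGCAACGT",
        tree_newick="(a:1.0,b:1.0);",
        array_copies_target=10,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestEvolveLibrary:
    def test_zero_rates_is_identity(self):
        cfg = _zero_rate_config()
        truth = evolve_library(cfg)
        for sp in ("a", "b"):
            assert truth.species_monomers[sp][0] == [cfg.ancestral_monomer] * 10
            assert truth.species_arrays[sp][0] == cfg.ancestral_monomer * 10

    def test_seeded_determinism(self):
        cfg = _zero_rate_config(point_mut_rate=0.05, conversion_rate=20.0, seed=11)
        t1, t2 = evolve_library(cfg), evolve_library(cfg)
        assert t1.species_arrays == t2.species_arrays
        assert t1.event_log == t2.event_log

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            evolve_library(_zero_rate_config(ancestral_monomer=""))
        with pytest.raises(ValueError):
            evolve_library(_zero_rate_config(point_mut_rate=-1.0))
        with pytest.raises(ValueError):
            # single-leaf (unrooted/degenerate) tree
            evolve_library(_zero_rate_config(tree_newick="a:1.0;"))

    def test_divergence_matches_jukes_cantor_expectation(self):
        # rate chosen so the expected observed leaf-leaf divergence is 0.10:
        # p = 3/4 (1 - exp(-4/3 D)) with D = 2 mu t  =>  mu = 0.0536 at t=1
        mu = 0.0536
        expected = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * 2 * mu))
        assert expected == pytest.approx(0.10, abs=0.005)
        divs = []
        for rep in range(20):
            cfg = _zero_rate_config(point_mut_rate=mu, seed=100 + rep)
            truth = evolve_library(cfg)
            a = "".join(truth.species_monomers["a"][0])
            b = "".join(truth.species_monomers["b"][0])
            divs.append(sum(x != y for x, y in zip(a, b)) / len(a))
        assert abs(np.mean(divs) - 0.10) <= 0.03


class TestUnequalExchange:
    def test_forced_single_unit_duplication(self):
        assert apply_unequal_exchange(
            ["A", "B", "C"], seed=0, op="duplicate", start=1, run_len=1
        ) == ["A", "B", "B", "C"]

    def test_forced_single_unit_deletion(self):
        assert apply_unequal_exchange(
            ["A", "B"], seed=0, op="delete", start=0, run_len=1
        ) == ["B"]

    def test_never_empties_array(self):
        arr = ["A", "B"]
        for s in range(50):
            arr2 = apply_unequal_exchange(arr, seed=s)
            assert len(arr2) >= 1

    def test_matches_independent_event_replayer(self):
        # 1000 seeded events; oracle replays the same (op, start, run_len)
        # list on a plain index list
        rng = np.random.default_rng(17)
        arr = [f"M{i}" for i in range(100)]
        oracle = list(arr)
        for _ in range(1000):
            n = len(arr)
            op = "duplicate" if rng.random() < 0.5 else "delete"
            run_len = min(max(1, int(rng.geometric(1 / 3))), max(1, n // 2))
            if op == "delete":
                run_len = min(run_len, n - 1)
            start = int(rng.integers(n - run_len + 1))
            arr = apply_unequal_exchange(arr, seed=0, op=op, start=start, run_len=run_len)
            if op == "duplicate":
                oracle[start:start] = oracle[start : start + run_len]
            else:
                del oracle[start : start + run_len]
        assert sorted(arr) == sorted(oracle)
        assert arr == oracle


class TestGeneConversion:
    def test_donor_equals_acceptor_is_identity(self):
        arr = ["ACGT", "TTTT"]
        assert apply_gene_conversion(arr, 0, 0, 4) == arr

    def test_full_tract_copies_donor(self):
        arr = ["ACGT", "TTTT"]
        out = apply_gene_conversion(arr, 0, 1, 4)
        assert out == ["ACGT", "ACGT"]
        assert arr == ["ACGT", "TTTT"]  # donor and input unchanged

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            apply_gene_conversion(["A", "B"], 0, 5, 1)

    def test_repeated_conversion_homogenises_monotonically(self):
        rng = np.random.default_rng(3)
        arr = [satsim._mutate_fraction("ACGTTGCAACGTTGCAACGT", 0.3, rng) for _ in range(8)]

        def mean_ident(a):
            vals = [
                rotated_identity_percent(a[i], a[j])
                for i in range(len(a))
                for j in range(i + 1, len(a))
            ]
            return float(np.mean(vals))

        last = mean_ident(arr)
        for acceptor in range(1, len(arr)):  # one donor converts everyone
            arr = apply_gene_conversion(arr, 0, acceptor, len(arr[0]))
            cur = mean_ident(arr)
            assert cur >= last - 1e-9
            last = cur
        assert last == pytest.approx(100.0)


class TestHORFormation:
    def test_unit_length_three_39bp_subrepeats(self):
        arr = [f"{'A'*39}", f"{'C'*39}", f"{'G'*39}", "T" * 39]
        new, model = apply_hor_formation(arr, 0, 3)
        assert model.unit_length == 117
        assert model.subrepeat_count == 3
        assert len(new) >= 3 and all(len(u) == 117 for u in new)

    def test_unit_length_arithmetic(self):
        arr = ["A" * 40, "C" * 40, "G" * 40]
        _, model = apply_hor_formation(arr, 0, 2)
        assert model.unit_length == 80

    def test_small_block_rejected(self):
        with pytest.raises(ValueError):
            apply_hor_formation(["A" * 40] * 5, 0, 1)

    def test_inter_unit_identity_exceeds_inter_subrepeat(self, hor_bundle):
        arr = hor_bundle.truth.species_monomers["acuminatum"][0]
        units = arr[:10]
        inter_unit = np.mean(
            [rotated_identity_percent(units[i], units[j])
             for i in range(5) for j in range(i + 1, 5)]
        )
        subs = [units[0][k * 39 : (k + 1) * 39] for k in range(3)]
        inter_sub = np.mean(
            [rotated_identity_percent(subs[i], subs[j])
             for i in range(3) for j in range(i + 1, 3)]
        )
        assert inter_unit > inter_sub


class TestReads:
    def test_expected_read_count_and_substrings(self):
        cfg = _zero_rate_config(array_copies_target=50)  # 1000 bp arrays
        truth = evolve_library(cfg)
        reads = fragment_to_reads(truth, read_length=100, coverage=1.0, seed=4)
        for sp, rs in reads.items():
            assert len(rs) == 10  # 1000 bp * 1x / 100 bp
            arrays = truth.species_arrays[sp]
            assert all(any(r in a for a in arrays) for r in rs)

    def test_coverage_expectation_within_ten_percent(self):
        cfg = _zero_rate_config(array_copies_target=100)
        truth = evolve_library(cfg)
        reads = fragment_to_reads(truth, read_length=100, coverage=5.0, seed=4)
        for sp, rs in reads.items():
            total = sum(len(r) for r in rs)
            assert abs(total - 5.0 * 2000) / (5.0 * 2000) <= 0.10

    def test_seeded_determinism_and_coverage_validation(self):
        cfg = _zero_rate_config()
        truth = evolve_library(cfg)
        r1 = fragment_to_reads(truth, 50, 2.0, seed=9)
        r2 = fragment_to_reads(truth, 50, 2.0, seed=9)
        assert r1 == r2
        with pytest.raises(ValueError):
            fragment_to_reads(truth, 50, 0.0, seed=9)


class TestFixtures:
    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            fixture("nope")

    def test_cfic_like_monomer_length(self, cfic_bundle):
        assert len(cfic_bundle.truth.planted_monomer["ficifolium"]) == 40
        assert cfic_bundle.expected["monomer_length"] == 40

    def test_hor_worked_example_unit(self, hor_bundle):
        (hor,) = hor_bundle.truth.planted_hors["acuminatum"]
        assert hor.unit_length == 117
        assert hor.subrepeat_count == 3

    def test_two_species_monomers_contain_printed_core(self, two_species_bundle):
        for sp, mono_lists in two_species_bundle.truth.species_monomers.items():
            assert all(ANCESTRAL_CORE_37 in m for m in mono_lists[0])

    def test_vulvaria_like_has_divergent_subfamilies_and_hors(self, vulvaria_bundle):
        assert len(vulvaria_bundle.truth.species_monomers["vulvaria"]) >= 6
        assert len(vulvaria_bundle.truth.planted_hors["vulvaria"]) >= 1


class TestRegimes:
    def test_concerted_intra_identity_exceeds_inter(self, seven_bundles):
        for seed, bundle in seven_bundles.items():
            truth = bundle.truth
            fic = truth.species_monomers["ficifolium"][0][:12]
            sue = truth.species_monomers["suecicum"][0][:12]
            intra = np.mean(
                [rotated_identity_percent(fic[i], fic[j])
                 for i in range(8) for j in range(i + 1, 8)]
            )
            inter = np.mean(
                [rotated_identity_percent(a, b) for a in fic[:6] for b in sue[:6]]
            )
            assert intra > inter, f"seed {seed}"

    def test_suppressed_lineage_has_more_subfamilies(self, seven_bundles):
        # single-linkage clusters at 80% identity: the suppressed lineage
        # fragments into strictly more monomer subfamilies
        def n_subfamilies(monomers):
            mono = monomers[:25]
            n = len(mono)
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    if rotated_identity_percent(mono[i], mono[j]) >= 80.0:
                        parent[find(i)] = find(j)
            return len({find(i) for i in range(n)})

        for seed, bundle in seven_bundles.items():
            truth = bundle.truth
            sup = n_subfamilies(truth.species_monomers["vulvaria"][0])
            con = n_subfamilies(truth.species_monomers["ficifolium"][0])
            assert sup > con, f"seed {seed}"
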
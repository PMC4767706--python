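import numpy as np
import pandas as pd
import pytest

from genotax.io import GenomeRecord, Partition, ValidationError
from genotax.pangenome import (OrthoGroups, all_vs_all_hits, build_orthogroups,
                               calibrate_score_floor, genome_fractions,
                               read_hit_table, trait_prevalence,
                               write_hit_table)
from genotax.synthetic import simulate_pangenome


def random_protein(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def manual_og(groups, genomes):
    return OrthoGroups(groups=[frozenset(g) for g in groups], genomes=genomes)


class TestSearch:
    def test_identical_copy_found_with_full_coverage(self):
        seq = random_protein(120, 0)
        a = GenomeRecord("a", [("p1", seq)], alphabet="protein")
        b = GenomeRecord("b", [("p1", seq)], alphabet="protein")
        hits = all_vs_all_hits([a, b], seed=1)
        row = hits[(hits.qgenome == "a") & (hits.sgenome == "b")].iloc[0]
        assert row.pident == pytest.approx(100.0)
        assert row.qcov == pytest.approx(1.0)

    def test_unrelated_random_proteins_produce_no_hit(self):
        a = GenomeRecord("a", [("p1", random_protein(50, 2))], alphabet="protein")
        b = GenomeRecord("b", [("p1", random_protein(50, 3))], alphabet="protein")
        hits = all_vs_all_hits([a, b], seed=4)
        assert hits[hits.qgenome != hits.sgenome].empty

    def test_decoy_calibration_is_deterministic(self, tiny_design):
        prots, _, _ = simulate_pangenome(tiny_design, seed=5)
        assert calibrate_score_floor(prots, seed=9) == calibrate_score_floor(prots, seed=9)

    def test_pass_through_round_trip_preserves_passing_rows(self, tmp_path,
                                                            tiny_design):
        prots, _, _ = simulate_pangenome(tiny_design, seed=6)
        hits = all_vs_all_hits(prots, seed=6)
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        back = read_hit_table(path)
        assert len(back) == len(hits)
        pd.testing.assert_frame_equal(back, hits)


class TestOrthogroups:
    def test_identical_proteomes_pair_up(self):
        seqs = [(f"p{i}", random_protein(100, 10 + i)) for i in range(5)]
        a = GenomeRecord("a", seqs, alphabet="protein")
        b = GenomeRecord("b", seqs, alphabet="protein")
        og = build_orthogroups(all_vs_all_hits([a, b], seed=7), [a, b])
        assert og.n_groups == 5
        assert all(len(g) == 2 for g in og.groups)

    def test_planted_families_recovered_exactly(self, tiny_design):
        prots, truth, _ = simulate_pangenome(tiny_design, seed=8)
        og = build_orthogroups(all_vs_all_hits(prots, seed=8), prots)
        assert sorted(map(sorted, og.groups)) == sorted(map(sorted, truth.groups))

    def test_every_protein_in_exactly_one_group(self, tiny_design):
        prots, _, _ = simulate_pangenome(tiny_design, seed=9)
        og = build_orthogroups(all_vs_all_hits(prots, seed=9), prots)
        genes = [(p.id, name) for p in prots for name, _ in p.sequences]
        grouped = [g for grp in og.groups for g in grp]
        assert sorted(grouped) == sorted(genes)
        # conservation: sum of group sizes equals total CDS count
        assert sum(len(g) for g in og.groups) == sum(og.gene_counts.values())

    def test_adding_a_genome_never_removes_a_gene_family(self, tiny_design):
        # set-level monotonicity: every family with members among the first
        # genomes is still a family (possibly grown) once a genome is added.
        # (The recovered component *count* is not monotone: a new genome's
        # genes can bridge two components that lacked a direct BBH edge.)
        _, truth, _ = simulate_pangenome(tiny_design, seed=10)
        subset = set(truth.genomes[:-1])
        restricted = [frozenset((g, p) for g, p in grp if g in subset)
                      for grp in truth.groups]
        restricted = [g for g in restricted if g]
        assert all(any(small <= full for full in truth.groups)
                   for small in restricted)
        assert len(restricted) <= truth.n_groups

    def test_dangling_gene_id_rejected(self):
        a = GenomeRecord("a", [("p1", random_protein(80, 11))], alphabet="protein")
        hits = pd.DataFrame([("a", "p1", "ghost", "p9", 100.0, 80, 1.0, 1.0, 50.0)],
                            columns=["qgenome", "qseqid", "sgenome", "sseqid",
                                     "pident", "length", "qcov", "scov", "score"])
        with pytest.raises(ValidationError):
            build_orthogroups(hits, [a])


class TestFractions:
    def test_shared_plus_unique_construction(self):
        # 4 genomes sharing f0..f4 plus i unique genes each
        genomes = [f"g{i}" for i in range(4)]
        groups = [[(g, f"core{k}") for g in genomes] for k in range(5)]
        for i, g in enumerate(genomes):
            for u in range(i):
                groups.append([(g, f"uniq{u}")])
        og = manual_og(groups, genomes)
        fr = genome_fractions(og, Partition({g: "all" for g in genomes}))
        assert len(fr.core) == 5
        assert fr.pan == 5 + sum(range(4))
        assert fr.strain_specific == {"g0": 0, "g1": 1, "g2": 2, "g3": 3}

    def test_single_label_degenerate_partition(self):
        genomes = ["g0", "g1"]
        groups = [[("g0", "a"), ("g1", "a")], [("g0", "b")]]
        og = manual_og(groups, genomes)
        fr = genome_fractions(og, Partition({g: "one" for g in genomes}))
        assert fr.group_core["one"] == fr.core
        assert fr.group_specific["one"] == fr.core

    def test_planted_group_exclusive_core_sizes(self, tiny_design):
        prots, truth, groups = simulate_pangenome(tiny_design, seed=12)
        fr = genome_fractions(truth, groups)
        # each group's specific genome is exactly its planted exclusive families
        k = tiny_design.group_exclusive_families
        assert all(len(v) == k for v in fr.group_specific.values())
        for label in fr.group_core:
            assert fr.group_specific[label] <= fr.group_core[label]
        assert len(fr.core) >= tiny_design.core_families

    def test_percentages_relative_to_mean_cds(self):
        genomes = ["g0", "g1"]
        groups = [[("g0", "a"), ("g1", "a")], [("g0", "b"), ("g0", "b2")],
                  [("g1", "c")]]
        og = manual_og(groups, genomes)
        fr = genome_fractions(og, Partition({g: "x" for g in genomes}))
        assert fr.mean_cds == pytest.approx(2.5)
        assert fr.percent["core"] == pytest.approx(100.0 * 1 / 2.5)

    def test_strain_specific_group_counting_mode(self):
        genomes = ["g0", "g1"]
        groups = [[("g0", "a"), ("g1", "a")], [("g0", "p1"), ("g0", "p2")]]
        og = manual_og(groups, genomes)
        part = Partition({g: "x" for g in genomes})
        assert genome_fractions(og, part).strain_specific["g0"] == 2
        assert genome_fractions(og, part,
                                strain_specific_as="groups").strain_specific["g0"] == 1

    def test_zero_cds_genome_rejected(self):
        og = OrthoGroups(groups=[frozenset({("g0", "a")})], genomes=["g0", "g1"],
                         gene_counts={"g0": 1, "g1": 0})
        with pytest.raises(ValidationError):
            genome_fractions(og, Partition({"g0": "x", "g1": "x"}))


class TestTraitPrevalence:
    def _setup(self):
        genomes = ["g0", "g1", "g2", "g3"]
        part = Partition({"g0": "A", "g1": "A", "g2": "B", "g3": "B"})
        groups = [
            [(g, "m0") for g in genomes],           # 0: core marker
            [("g0", "m1"), ("g1", "m1")],           # 1: group A only
            [("g0", "m2")],                         # 2: g0 only
        ]
        return manual_og(groups, genomes), part

    def test_core_trait_everywhere_and_absent_trait_nowhere(self):
        og, part = self._setup()
        assert trait_prevalence(og, part, {0}) == {"A": 100.0, "B": 100.0}
        assert trait_prevalence(og, part, {2}) == {"A": 50.0, "B": 0.0}

    def test_complete_vs_core_subset_modes(self):
        og, part = self._setup()
        complete = trait_prevalence(og, part, {0, 1, 2}, mode="complete")
        assert complete == {"A": 50.0, "B": 0.0}
        relaxed = trait_prevalence(og, part, {0, 1, 2}, mode="core_subset",
                                   core_markers={0, 1})
        assert relaxed == {"A": 100.0, "B": 0.0}

    def test_counting_oracle_on_random_presence(self):
        rng = np.random.default_rng(13)
        genomes = [f"g{i}" for i in range(10)]
        part = Partition({g: "A" if i < 5 else "B" for i, g in enumerate(genomes)})
        present = rng.random((3, 10)) < 0.6
        groups = [[(genomes[j], f"m{k}") for j in range(10) if present[k, j]]
                  for k in range(3)]
        groups = [g for g in groups if g]
        og = OrthoGroups(groups=[frozenset(g) for g in groups], genomes=genomes,
                         gene_counts={g: 3 for g in genomes})
        prev = trait_prevalence(og, part, set(range(len(groups))))
        for label, members in part.blocks().items():
            expect = 100.0 * sum(
                all(any((g, f"m{k}") in grp for grp in og.groups)
                    for k in range(3)) for g in members) / len(members)
            assert prev[label] == pytest.approx(expect)

    def test_unknown_marker_and_empty_trait_rejected(self):
        og, part = self._setup()
        with pytest.raises(ValidationError):
            trait_prevalence(og, part, {99})
        with pytest.raises(ValidationError):
            trait_prevalence(og, part, set())
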
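"""Evolution simulator: trees, gene content, codon sequences, emission."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evotrek.phylo import parse_newick, write_newick
from evotrek.selection import STOP_CODONS, translate_cds
from evotrek.simulate import (
    SimConfig,
    emit_dataset,
    simulate_codon_sequences,
    simulate_dataset,
    simulate_gene_content,
    simulate_genus_tree,
    simulate_species_tree,
)

from oracles import expected_branch_events, expected_event_count


class TestSpeciesTree:
    def test_single_taxon(self):
        t = simulate_species_tree(1, 0)
        assert len(t.leaves()) == 1
        assert sum(1 for n in t.preorder() if n.children) == 0

    def test_thirteen_taxa_internal_node_count(self):
        t = simulate_species_tree(13, 3)
        assert sum(1 for n in t.preorder() if n.children) == 12

    def test_determinism(self):
        a = write_newick(simulate_species_tree(9, 77))
        b = write_newick(simulate_species_tree(9, 77))
        assert a == b

    def test_fixed_newick_mode(self):
        t = simulate_species_tree(3, 0, mode="fixed-newick", newick="((A:1,B:1):1,C:2);")
        assert sorted(t.leaf_names()) == ["A", "B", "C"]

    def test_invalid_n_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_tree(0, 0)

    def test_height_rescaling(self):
        t = simulate_species_tree(10, 5, height=0.2)
        depths = t.leaf_path_lengths().matrix
        # ultrametric pure-birth tree: max leaf-leaf distance = 2 * height
        assert np.max(depths) == pytest.approx(0.4, rel=1e-9)


class TestGeneContent:
    def test_no_process_all_ones(self):
        tree = simulate_genus_tree(SimConfig(n_taxa=6, seed=1), 1)
        cfg = SimConfig(n_taxa=6, gain_rate=0, loss_rate=0, root_presence_prob=1.0)
        matrix, truth = simulate_gene_content(tree, 10, cfg, np.random.default_rng(0))
        assert (matrix.values == 1).all()
        assert all(not ft.events for ft in truth.families.values())

    def test_truth_replay_matches_matrix(self):
        tree = simulate_genus_tree(SimConfig(seed=2), 2)
        cfg = SimConfig(gain_rate=2.0, loss_rate=2.0)
        matrix, truth = simulate_gene_content(tree, 100, cfg, np.random.default_rng(1))
        for fam in matrix.index:
            replayed = truth.replay(tree, fam)
            assert replayed == {t: int(v) for t, v in matrix.loc[fam].items()}

    def test_dollo_mode_at_most_one_gain(self):
        tree = simulate_genus_tree(SimConfig(seed=3), 3)
        cfg = SimConfig(gain_rate=5.0, loss_rate=5.0, dollo=True, root_presence_prob=0.0)
        _, truth = simulate_gene_content(tree, 200, cfg, np.random.default_rng(2))
        for ft in truth.families.values():
            assert sum(1 for _, k in ft.events if k == "gain") <= 1

    def test_event_count_matches_ctmc_expectation(self):
        """Total simulated events within 3 SE of the closed-form expectation
        (occupancy-integrated rate x branch length)."""
        tree = simulate_species_tree(13, 11, height=1.0)
        cfg = SimConfig(gain_rate=0.1, loss_rate=0.1, root_presence_prob=0.5)
        n_fam = 1500
        rng = np.random.default_rng(9)
        _, truth = simulate_gene_content(tree, n_fam, cfg, rng)
        counts = np.array([len(ft.events) for ft in truth.families.values()])
        expected = expected_event_count(tree, 0.1, 0.1, 0.5) * n_fam
        se = counts.std(ddof=1) * np.sqrt(n_fam)
        assert abs(counts.sum() - expected) < 3 * se

    def test_per_branch_frequencies_chi_square(self):
        """Per-branch event counts fit rate x branch length (goodness of fit
        at alpha = 0.01 with 1500 families)."""
        tree = simulate_species_tree(13, 11, height=1.0)
        cfg = SimConfig(gain_rate=0.1, loss_rate=0.1, root_presence_prob=0.5)
        n_fam = 1500
        _, truth = simulate_gene_content(tree, n_fam, cfg, np.random.default_rng(10))
        name2id = {n.name: n.id for n in tree.preorder()}
        observed: dict[int, int] = {}
        for ft in truth.families.values():
            for name, _ in ft.events:
                nid = name2id[name]
                observed[nid] = observed.get(nid, 0) + 1
        expected = expected_branch_events(tree, 0.1, 0.1, 0.5)
        chi2 = sum(
            (observed.get(nid, 0) - e * n_fam) ** 2 / (e * n_fam)
            for nid, e in expected.items()
        )
        dof = len(expected)
        assert chi2 < stats.chi2.ppf(0.99, dof)

    def test_determinism(self):
        tree = simulate_genus_tree(SimConfig(seed=4), 4)
        cfg = SimConfig(gain_rate=1.0, loss_rate=1.0)
        m1, _ = simulate_gene_content(tree, 30, cfg, np.random.default_rng(5))
        m2, _ = simulate_gene_content(tree, 30, cfg, np.random.default_rng(5))
        pd.testing.assert_frame_equal(m1, m2)


class TestCodonSequences:
    def test_zero_branch_lengths_identical_leaves(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        seqs = simulate_codon_sequences(t, 50, 1.0, 3)
        assert len(set(seqs.values())) == 1

    def test_omega_zero_protein_conserved(self):
        t = parse_newick("((A:0.3,B:0.3):0.1,C:0.4);")
        seqs = simulate_codon_sequences(t, 80, 0.0, 4)
        prots = {translate_cds(s) for s in seqs.values()}
        assert len(prots) == 1
        # but nucleotide-level divergence did occur
        assert len(set(seqs.values())) > 1

    def test_no_internal_stops(self):
        t = parse_newick("((A:0.5,B:0.5):0.2,C:0.7);")
        for omega in (0.0, 0.5, 2.0):
            for seq in simulate_codon_sequences(t, 60, omega, 5).values():
                for i in range(0, len(seq), 3):
                    assert seq[i : i + 3] not in STOP_CODONS

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_sequences(parse_newick("(A:1,B:1);"), 10, -0.5, 0)


class TestEmission:
    def test_outputs_deterministic(self, tmp_path):
        for sub in ("x", "y"):
            ds = simulate_dataset(SimConfig(n_taxa=6, n_families=8, seed=42))
            emit_dataset(ds, tmp_path / sub)
        for f in sorted((tmp_path / "x").iterdir()):
            assert f.read_bytes() == (tmp_path / "y" / f.name).read_bytes()

    def test_gff_coordinates_valid(self, tmp_path):
        ds = simulate_dataset(SimConfig(n_taxa=6, n_families=10, seed=1))
        files = emit_dataset(ds, tmp_path)
        rows = 0
        for taxon in ds.matrix.columns:
            for line in (tmp_path / f"{taxon}.gff3").read_text().splitlines():
                if line.startswith("#"):
                    continue
                parts = line.split("\t")
                start, end = int(parts[3]), int(parts[4])
                assert start >= 1 and end >= start
                rows += 1
        assert rows > 0

    def test_hgt_family_has_adjacent_mobile_element(self, tmp_path):
        ds = simulate_dataset(SimConfig(n_taxa=8, n_families=30, seed=12, gain_rate=2.0))
        emit_dataset(ds, tmp_path)
        hgt_fams = [f for f, ft in ds.truth.families.items() if ft.hgt]
        assert hgt_fams, "simulation produced no HGT families at this rate"
        for fam in hgt_fams:
            for taxon in ds.matrix.columns:
                if ds.matrix.loc[fam, taxon] != 1:
                    continue
                text = (tmp_path / f"{taxon}.gff3").read_text()
                assert f"near={taxon}.{fam}" in text

    def test_protein_files_translate_cds(self, tmp_path):
        from Bio import SeqIO

        ds = simulate_dataset(SimConfig(n_taxa=5, n_families=6, seed=3))
        emit_dataset(ds, tmp_path)
        taxon = ds.matrix.columns[0]
        cds = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / f"{taxon}.cds.fasta"), "fasta")}
        prot = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / f"{taxon}.faa"), "fasta")}
        assert cds and prot.keys() == cds.keys()
        for gid, seq in cds.items():
            assert translate_cds(seq) == prot[gid]

    def test_missing_sequence_rejected(self, tmp_path):
        ds = simulate_dataset(SimConfig(n_taxa=5, n_families=4, seed=6))
        present = [
            (f, t) for f in ds.matrix.index for t in ds.matrix.columns
            if ds.matrix.loc[f, t] == 1
        ]
        fam, taxon = present[0]
        del ds.sequences[fam][taxon]
        with pytest.raises(ValueError, match="missing sequence"):
            emit_dataset(ds, tmp_path)
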
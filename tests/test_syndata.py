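"""Generator contracts: determinism, divergence targeting, truth integrity."""

import numpy as np
import pytest

from polyevol import moldiv, syndata
from polyevol._util import (SequenceRecord, read_fasta, read_gff3, write_fasta,
                            write_gff3)
from polyevol.syndata import (DivergenceSchedule, EvolveParams,
                              InvalidParameter)

_STOPS = {"TAA", "TAG", "TGA"}


class TestAncestralCds:
    def test_postconditions(self):
        recs = syndata.gen_ancestral_cds(5, 40, seed=7)
        for r in recs:
            assert len(r.seq) == 120
            assert r.seq.startswith("ATG")
            codons = [r.seq[i:i + 3] for i in range(0, len(r.seq), 3)]
            assert not any(c in _STOPS for c in codons)

    def test_deterministic_and_seed_sensitive(self):
        a = [r.seq for r in syndata.gen_ancestral_cds(20, 100, seed=1)]
        b = [r.seq for r in syndata.gen_ancestral_cds(20, 100, seed=1)]
        c = [r.seq for r in syndata.gen_ancestral_cds(20, 100, seed=2)]
        assert a == b
        assert a != c

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameter):
            syndata.gen_ancestral_cds(1, 1, seed=0)


class TestEvolve:
    def test_zero_branch_is_identity(self):
        rec = SequenceRecord("x", "ACGTACGTAC")
        out, (ts, tv) = syndata.evolve_sequence(rec, EvolveParams(d_target=0.0))
        assert out.seq == rec.seq and ts == tv == 0

    def test_kappa_limit_suppresses_transversions(self):
        rng = np.random.default_rng(0)
        rec = SequenceRecord("x", "".join(rng.choice(list("ACGT"), 5000)))
        _, (ts, tv) = syndata.evolve_sequence(
            rec, EvolveParams(d_target=0.3, kappa=1e6, seed=3))
        assert tv == 0 and ts > 0

    def test_k2p_recovery_monte_carlo(self):
        # mean K2P over replicates within 3 SE of the target distance
        rng = np.random.default_rng(1)
        rec = SequenceRecord("x", "".join(rng.choice(list("ACGT"), 10_000)))
        d = []
        for i in range(60):
            out, _ = syndata.evolve_sequence(
                rec, EvolveParams(d_target=0.1, seed=1000 + i))
            d.append(moldiv.k2p_distance(rec.seq, out.seq))
        se = np.std(d, ddof=1) / np.sqrt(len(d))
        assert abs(np.mean(d) - 0.1) < 3 * se + 1e-9

    def test_realized_proportion_converges(self):
        rng = np.random.default_rng(2)
        rec = SequenceRecord("x", "".join(rng.choice(list("ACGT"), 100_000)))
        out, (ts, tv) = syndata.evolve_sequence(
            rec, EvolveParams(d_target=0.05, seed=9))
        diff = sum(a != b for a, b in zip(rec.seq, out.seq)) / len(rec.seq)
        p_expect = sum(syndata._k80_site_probs(0.05, 2.0))
        se = np.sqrt(p_expect * (1 - p_expect) / len(rec.seq))
        assert abs(diff - p_expect) < 3 * se

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidParameter):
            EvolveParams(d_target=-0.1)


class TestAllopolyploid:
    def test_truth_pairs_cover_every_gene_once(self, small_allopolyploid):
        genomes, truth = small_allopolyploid
        at = [a for a, _ in truth.homoeolog_pairs]
        dt = [d for _, d in truth.homoeolog_pairs]
        assert len(set(at)) == len(at) == 30
        assert len(set(dt)) == len(dt) == 30
        assert set(at) == set(genomes["At"].cds)

    def test_ks_between_subgenomes_matches_schedule(self, small_allopolyploid):
        genomes, truth = small_allopolyploid
        ks = []
        for a, d in truth.homoeolog_pairs:
            est = moldiv.ng86(moldiv.CodonAlignment(
                genomes["At"].cds[a], genomes["Dt"].cds[d]))
            ks.append(est.Ks)
        assert np.mean(ks) == pytest.approx(0.04, abs=0.004)

    def test_empty_simulation(self):
        genomes, truth = syndata.gen_allopolyploid(
            DivergenceSchedule([("AD", 0.04)]), 0, seed=1, assemble=False)
        assert truth.homoeolog_pairs == []
        assert all(not g.cds for g in genomes.values())

    def test_schedule_validation(self):
        with pytest.raises(InvalidParameter):
            DivergenceSchedule([("AD", -0.1)])
        with pytest.raises(InvalidParameter):
            DivergenceSchedule([("GbGh", 0.005), ("AD", 0.04)])  # wrong order

    def test_genome_roundtrip_through_fasta_gff3(self, small_allopolyploid, tmp_path):
        genomes, _ = small_allopolyploid
        g = genomes["At"]
        recs = [SequenceRecord(gid, s) for gid, s in sorted(g.cds.items())]
        write_fasta(recs, tmp_path / "cds.fasta")
        back = read_fasta(tmp_path / "cds.fasta")
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]
        write_gff3(g.genes, tmp_path / "genes.gff3")
        models = read_gff3(tmp_path / "genes.gff3")
        by_id = {m.gene_id: m for m in models}
        for m in g.genes:
            m2 = by_id[m.gene_id]
            assert (m2.start, m2.end, m2.strand, m2.exons) == \
                (m.start, m.end, m.strand, m.exons)


class TestLtrGenerator:
    def test_age_zero_gives_identical_ltrs(self):
        elems, _ = syndata.gen_ltr_elements(3, [(0.0, 1.0)], seed=4, ltr_len=100)
        for e in elems:
            assert e.left_ltr == e.right_ltr

    def test_expected_divergence_scales_with_age(self):
        elems, truth = syndata.gen_ltr_elements(
            40, [(5e6, 1.0)], r=2.6e-9, ltr_len=2000, seed=5)
        ks = [moldiv.k2p_distance(e.left_ltr, e.right_ltr) for e in elems]
        assert np.mean(ks) == pytest.approx(2 * 2.6e-9 * 5e6, rel=0.05)
        assert all(truth.ltr_ages[e.element_id] == 5e6 for e in elems)

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameter):
            syndata.gen_ltr_elements(1, [(1e6, 1.0)], ltr_len=40, seed=0)
        with pytest.raises(InvalidParameter):
            syndata.gen_ltr_elements(1, [(-1.0, 1.0)], seed=0)
        with pytest.raises(InvalidParameter):
            syndata.gen_ltr_elements(1, [(1e6, 1.0)], r=0.0, seed=0)


class TestPseudogeneGenerator:
    def test_categories_constructed_as_designed(self, pseudogene_world):
        g2, loci, truth = pseudogene_world
        cds_len = {gid: len(s) for gid, s in g2.cds.items()}
        for rec in truth.pseudogenes:
            assert rec.disablements, "every copy carries a disablement"
            if rec.category == "fragmented":
                assert rec.end - rec.start < 0.70 * cds_len[rec.parent_gene_id]

    def test_processed_needs_multi_exon_parent(self, small_allopolyploid):
        genomes, _ = small_allopolyploid
        g = genomes["At"]
        single = syndata.Genome(
            g.name, dict(g.chroms),
            [m for m in g.genes if len(m.exons) == 1], dict(g.cds))
        with pytest.raises(InvalidParameter):
            syndata.gen_pseudogenes(single, {"processed": 1.0}, 3, seed=1)

    def test_gene_models_survive_insertion(self, pseudogene_world):
        g2, _, _ = pseudogene_world
        for m in g2.genes:
            assert m.spliced_cds(g2.chroms[m.chrom]) == g2.cds[m.gene_id]


class TestReads:
    def test_truth_origin_and_counts(self, small_allopolyploid):
        genomes, _ = small_allopolyploid
        reads, truth = syndata.gen_reads(
            genomes["At"], genomes["Dt"], read_len=100, n_reads=50,
            err=0.01, seed=3)
        assert len(reads) == 50
        assert set(truth.read_origins.values()) <= {"At", "Dt"}
        assert len(truth.read_origins) == 50

    def test_zero_reads_and_bad_error_rate(self, small_allopolyploid):
        genomes, _ = small_allopolyploid
        reads, truth = syndata.gen_reads(genomes["At"], genomes["Dt"],
                                         100, 0, 0.0, seed=1)
        assert reads == [] and truth.read_origins == {}
        with pytest.raises(InvalidParameter):
            syndata.gen_reads(genomes["At"], genomes["Dt"], 100, 5, 0.5, seed=1)


class TestCounts:
    def test_poisson_limit_at_zero_dispersion(self):
        genes = [f"g{i}" for i in range(200)]
        mat, _ = syndata.gen_counts(
            genes, {f"s{i}": "a" for i in range(8)},
            {f"s{i}": 1_000_000 for i in range(8)}, {}, seed=2, dispersion=0.0)
        m = mat.counts.mean(axis=1)
        v = mat.counts.var(axis=1)
        keep = m > 20
        ratio = (v[keep] / m[keep]).mean()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_truth_labels_match_fold_changes(self):
        genes = ["a", "b", "c"]
        mat, truth = syndata.gen_counts(
            genes, {"s1": "x", "s2": "y"}, {"s1": 10**6, "s2": 10**6},
            {"a": {"x": 4.0}}, seed=1)
        assert bool(truth.de.loc["a", "is_de"]) is True
        assert bool(truth.de.loc["b", "is_de"]) is False

    def test_negative_fold_change_rejected(self):
        with pytest.raises(InvalidParameter):
            syndata.gen_counts(["a"], {"s": "x"}, {"s": 100},
                               {"a": {"x": -2.0}}, seed=1)
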
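"""Pseudogene detection, classification, filtering and parent divergence."""

import math

import pytest

from polyevol import pseudo, syndata
from polyevol._util import GeneModel
from polyevol.pseudo import PseudogeneCandidate


@pytest.fixture(scope="module")
def detected(pseudogene_world):
    g2, loci, truth = pseudogene_world
    regions = pseudo.intergenic_regions(g2)
    cands = pseudo.detect_pseudogenes(regions, g2.proteins())
    return g2, truth, cands


def _match(cands, rec):
    for c in cands:
        ov = min(c.end, rec.end) - max(c.start, rec.start)
        if ov > 0.5 * (rec.end - rec.start):
            return c
    return None


class TestDetection:
    def test_recovers_inserted_loci_with_correct_parent(self, detected):
        _, truth, cands = detected
        found = parent_ok = 0
        for rec in truth.pseudogenes:
            c = _match(cands, rec)
            if c is None:
                continue
            found += 1
            parent_ok += c.parent_gene_id == rec.parent_gene_id
        assert found >= 0.9 * len(truth.pseudogenes)
        assert parent_ok >= 0.9 * found

    def test_injected_stops_are_reported(self, detected):
        _, truth, cands = detected
        with_stop = [r for r in truth.pseudogenes
                     if any(t == "premature_stop" for t, _ in r.disablements)]
        reported = 0
        for rec in with_stop:
            c = _match(cands, rec)
            if c and any(t == "premature_stop" for t, _ in c.disablements):
                reported += 1
        assert reported >= 0.8 * len(with_stop)

    def test_empty_intergenic_space_gives_no_candidates(self):
        assert pseudo.detect_pseudogenes([], {"p": "MKTAYIAK"}) == []


class TestClassification:
    def test_truth_category_recovery(self, detected):
        g2, truth, cands = detected
        models = {m.gene_id: m for m in g2.genes}
        ok = total = 0
        for rec in truth.pseudogenes:
            c = _match(cands, rec)
            if c is None:
                continue
            total += 1
            cat = pseudo.classify_pseudogene(c, models[rec.parent_gene_id],
                                             g2.cds[rec.parent_gene_id])
            ok += cat == rec.category
        assert total and ok / total >= 0.9

    def test_low_coverage_candidate_is_fragmented(self):
        parent = GeneModel("p", "c", 0, 900, "+", [(0, 900)])
        cand = PseudogeneCandidate("x", "c", 5000, 5360, "+", "p", "A" * 360,
                                   chain=[(0, 120, 0, 360, 0)])
        assert pseudo.classify_pseudogene(cand, parent, "A" * 900) == "fragmented"

    def test_missing_exon_structure_raises(self):
        parent = GeneModel("p", "c", 0, 900, "+", [])
        cand = PseudogeneCandidate("x", "c", 0, 10, "+", "p", "ACGT",
                                   chain=[(0, 1, 0, 3, 0)])
        with pytest.raises(pseudo.DataInconsistency):
            pseudo.classify_pseudogene(cand, parent, "A" * 900)

    def test_categories_exhaustive_and_exclusive(self, detected):
        g2, truth, cands = detected
        models = {m.gene_id: m for m in g2.genes}
        for c in cands:
            if c.parent_gene_id not in models:
                continue
            cat = pseudo.classify_pseudogene(c, models[c.parent_gene_id],
                                             g2.cds[c.parent_gene_id])
            assert cat in {"duplicated", "processed", "fragmented"}


def _cand(length=500, parent="p1", start=10_000, chrom="c1"):
    return PseudogeneCandidate("x", chrom, start, start + length, "+",
                               parent, "A" * length)


class TestFilters:
    GENES = [GeneModel("g1", "c1", 0, 2_000, "+", [(0, 2_000)])]

    def test_short_locus_dropped_strictly(self):
        kept = pseudo.filter_pseudogenes([_cand(120), _cand(150)], self.GENES)
        assert [c.length for c in kept] == [150]  # 150 bp survives (strict <)

    def test_te_and_plastid_parents_dropped(self):
        labels = {"p_te": "TE", "p_pl": "plastid", "p1": "nuclear"}
        cands = [_cand(parent="p_te"), _cand(parent="p_pl"), _cand(parent="p1")]
        kept = pseudo.filter_pseudogenes(cands, self.GENES, labels)
        assert [c.parent_gene_id for c in kept] == ["p1"]

    def test_gene_overlap_threshold(self):
        touching = _cand(start=1_980)    # 20 bp overlap: kept
        overlapping = _cand(start=1_900)  # 100 bp overlap: dropped
        kept = pseudo.filter_pseudogenes([touching, overlapping], self.GENES)
        assert kept == [touching]

    def test_filters_commute(self):
        import itertools
        cands = [_cand(120), _cand(parent="p_te"), _cand(start=1_900), _cand()]
        labels = {"p_te": "TE"}
        results = []
        base = pseudo.filter_pseudogenes(cands, self.GENES, labels)
        # applying each rule alone in any order gives the same survivor set
        assert [c.parent_gene_id for c in base] == ["p1"]


class TestKsToParent:
    def test_fresh_copy_has_near_zero_ks(self, pseudogene_world):
        g2, _, _ = pseudogene_world
        gid, cds = next(iter(sorted(g2.cds.items())))
        cand = PseudogeneCandidate("x", "c", 0, len(cds), "+", gid, cds)
        est = pseudo.ks_to_parent(cand, cds)
        assert est.Ks == pytest.approx(0.0, abs=1e-9)

    def test_recovers_generator_divergence(self, detected):
        g2, truth, cands = detected
        ks = []
        for rec in truth.pseudogenes:
            c = _match(cands, rec)
            if c is None or c.parent_gene_id != rec.parent_gene_id:
                continue
            try:
                ks.append(pseudo.ks_to_parent(c, g2.cds[rec.parent_gene_id]).Ks)
            except pseudo.UnalignableCandidate:
                pass
        mean = sum(ks) / len(ks)
        assert mean == pytest.approx(0.08, abs=0.02)

    def test_unalignable_candidate_flagged(self):
        cand = PseudogeneCandidate("x", "c", 0, 60, "+", "p", "ACGT" * 15)
        with pytest.raises(pseudo.UnalignableCandidate):
            pseudo.ks_to_parent(cand, "TGGCAA" * 100)

    def test_pseudogene_omega_exceeds_constrained_gene_omega(
            self, detected, small_allopolyploid):
        # relaxed selection: Ka/Ks of unconstrained pseudogene copies is
        # higher than that of purifying-selected homoeologs
        from polyevol import moldiv
        g2, truth, cands = detected
        genomes, hom_truth = small_allopolyploid
        ps_ka = ps_ks = 0.0
        for rec in truth.pseudogenes:
            c = _match(cands, rec)
            if c is None or c.parent_gene_id != rec.parent_gene_id:
                continue
            try:
                est = pseudo.ks_to_parent(c, g2.cds[rec.parent_gene_id])
            except pseudo.UnalignableCandidate:
                continue
            if not est.saturated:
                ps_ka += est.Ka
                ps_ks += est.Ks
        gene_ka = gene_ks = 0.0
        for a, d in hom_truth.homoeolog_pairs:
            est = moldiv.ng86(moldiv.CodonAlignment(
                genomes["At"].cds[a], genomes["Dt"].cds[d]))
            gene_ka += est.Ka
            gene_ks += est.Ks
        assert ps_ka / ps_ks > gene_ka / gene_ks
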
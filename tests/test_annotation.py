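import math

import numpy as np
import pytest

from regulonkit import annotation as ann
from regulonkit.core_io import TFBSLibraryEntry
from regulonkit.motif_clustering import Regulon
from regulonkit.motif_discovery import Motif

AA = "ACDEFGHIKLMNPQRSTVWY"


def sharp_pwm(consensus, p=0.9):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pwm = np.full((4, len(consensus)), (1 - p) / 3)
    for c, ch in enumerate(consensus):
        pwm[idx[ch], c] = p
    return pwm


def make_regulon_with_motif(consensus="ACGGTCATGCAT"):
    motif = Motif("R1_m1", sharp_pwm(consensus), [("o1", 0, "fwd"), ("o2", 3, "rc")],
                  20.0, 1e-9, 1e-6)
    reg = Regulon(1, frozenset({"R1_m1"}), frozenset({"o1", "o2"}),
                  frozenset({"g1", "g2"}), frozenset(), "highly_reliable")
    return reg, {"R1_m1": motif}


class TestMatchTfbs:
    def test_identity_reported_with_minimal_evalue(self, config, rng):
        reg, motifs = make_regulon_with_motif()
        lib = [TFBSLibraryEntry("lib1", "tfA", "org",
                                motifs["R1_m1"].pwm.copy())]
        lib += [TFBSLibraryEntry(f"dec{i}", f"d{i}", "org",
                                 rng.dirichlet(np.ones(4), size=12).T)
                for i in range(9)]
        matches = ann.match_tfbs(reg, motifs, lib, config, rng)
        assert matches and matches[0].tf_name == "tfA"
        assert matches[0].similarity == pytest.approx(1.0, abs=1e-12)
        assert matches[0].e_value <= len(lib) / (config.shuffle_n + 1) + 1e-12

    def test_empty_library(self, config, rng):
        reg, motifs = make_regulon_with_motif()
        assert ann.match_tfbs(reg, motifs, [], config, rng) == []

    def test_unrelated_library_rarely_matches(self, config, rng):
        reg, motifs = make_regulon_with_motif()
        lib = [TFBSLibraryEntry(f"r{i}", f"t{i}", "org",
                                rng.dirichlet(np.ones(4), size=12).T)
               for i in range(20)]
        matches = ann.match_tfbs(reg, motifs, lib, config, rng)
        assert len(matches) <= 2  # E < 0.05 gate keeps random hits rare


class TestMapTf:
    def test_exact_self_match_is_best_hit(self, rng):
        proteome = {f"p{i}": "".join(rng.choice(list(AA), 200)) for i in range(10)}
        template = proteome["p4"]
        m = ann.map_tf("tmpl", template, proteome, 1e-5)
        assert m is not None and m.target_gene == "p4"
        assert m.e_value < 1e-20

    def test_shuffled_template_finds_no_strict_hit(self, rng):
        proteome = {f"p{i}": "".join(rng.choice(list(AA), 200)) for i in range(5)}
        hits = 0
        for _ in range(10):
            shuffled = "".join(rng.permutation(list(proteome["p0"])))
            if ann.map_tf("shuf", shuffled, proteome, 1e-10) is not None:
                hits += 1
        assert hits == 0

    def test_empty_proteome(self):
        assert ann.map_tf("t", "MKV" + "A" * 50, {}, 1e-5) is None

    def test_non_standard_residue_rejected(self):
        with pytest.raises(ann.ValidationError):
            ann.map_tf("t", "MKVX", {"p": "MKV"}, 1e-5)

    def test_eight_templates_map_with_shared_target(self, rng):
        # orthologs: proteome entries are lightly mutated template copies;
        # two templates derive from the same target gene
        targets = {f"gene{i}": "".join(rng.choice(list(AA), 180)) for i in range(8)}
        proteome = dict(targets)
        proteome.update(
            {f"bgp{i}": "".join(rng.choice(list(AA), 180)) for i in range(10)})
        template_names = [f"tf{i}" for i in range(8)]
        template_target = dict(zip(template_names, list(targets) * 2))
        template_target["tf7"] = template_target["tf0"]  # shared target
        mappings = {}
        for name in template_names:
            seq = list(targets[template_target[name]])
            for pos in rng.choice(len(seq), size=18, replace=False):
                seq[pos] = str(rng.choice(list(AA)))
            mappings[name] = ann.map_tf(name, "".join(seq), proteome, 1e-5)
        assert all(m is not None for m in mappings.values())
        assert all(m.target_gene == template_target[n] for n, m in mappings.items())
        assert mappings["tf0"].target_gene == mappings["tf7"].target_gene

    def test_tabular_adapter_best_hit_per_query(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\ts1\t90\t100\t5\t0\t1\t100\t1\t100\t1e-30\t200\n"
            "q1\ts2\t80\t100\t9\t0\t1\t100\t1\t100\t1e-10\t120\n"
            "q2\ts3\t70\t80\t9\t1\t1\t80\t1\t80\t1e-5\t80\n"
        )
        best = ann.read_tabular_alignments(p)
        assert best["q1"].target_gene == "s1"
        assert best["q2"].e_value == pytest.approx(1e-5)


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert ann.hypergeom_test(n=10, k=0, N=100, K=10) == 1.0

    def test_regulon_equals_universe(self):
        assert ann.hypergeom_test(n=50, k=7, N=50, K=7) == 1.0

    def test_reference_value_brute_force(self):
        p = ann.hypergeom_test(n=10, k=5, N=100, K=10)
        brute = sum(
            math.comb(10, j) * math.comb(90, 10 - j) for j in range(5, 11)
        ) / math.comb(100, 10)
        assert p == pytest.approx(brute, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            ann.hypergeom_test(n=10, k=11, N=100, K=50)


class TestFilterRegulons:
    def test_curated_table_yields_five_verified(self):
        table = ann.load_regulon_tf_table()
        annotated = ann.annotate_from_tf_table(table)
        verified = sorted(ar.regulon_id for ar in annotated
                          if ar.verdict == "computationally_verified")
        assert verified == [2, 7, 12, 15, 31]

    def test_mapped_tf_without_deg_is_candidate(self):
        table = ann.load_regulon_tf_table()
        annotated = {ar.regulon_id: ar for ar in ann.annotate_from_tf_table(table)}
        assert annotated[10].mapped_tf is not None
        assert annotated[10].verdict == "candidate"

    def test_empty_deg_set_verifies_nothing(self):
        regs, motifs = make_regulon_with_motif()
        ar = ann.AnnotatedRegulon(regulon=regs, tf_matches=[object()],
                                  mapped_tf=ann.TFMapping("t", "g", 50.0, 1e-20))
        counts = ann.filter_regulons([ar], deg_set=set())
        assert counts["verified"] == 0 and ar.verdict == "candidate"

    def test_sieve_monotonicity(self, rng):
        annotated = []
        for i in range(30):
            reg = Regulon(i, frozenset({f"m{i}"}), frozenset({f"o{i}"}),
                          frozenset({f"g{i}"}), frozenset(), "highly_reliable")
            ar = ann.AnnotatedRegulon(regulon=reg)
            if rng.random() < 0.6:
                ar.tf_matches = [object()]
            if rng.random() < 0.5:
                ar.mapped_tf = ann.TFMapping("t", "x", 10.0, 1e-12)
            annotated.append(ar)
        degs = {f"g{i}" for i in range(30) if rng.random() < 0.5}
        c = ann.filter_regulons(annotated, degs)
        assert c["verified"] <= c["deg_containing"] <= c["tfbs_matched"] <= c["total"]


class TestLiterature:
    def test_curated_table_bookkeeping(self):
        table = ann.load_literature_gene_table()
        lits = ann.literature_genes_from_table(table)
        tags = {t for lg in lits for t in lg.mapped_locus_tags}
        assert len(tags) == 33
        assert table["functional_module"].nunique() == 9
        assert len({r for lg in lits for r in lg.regulons_hit}) == 6

    def test_template_without_ortholog_hits_nothing(self, rng):
        proteome = {f"p{i}": "".join(rng.choice(list(AA), 150)) for i in range(5)}
        lit = ann.LiteratureGene("orphan", "org", "LDH")
        out = ann.map_literature_genes(
            [(lit, "".join(rng.choice(list(AA), 150)))], proteome, [], 1e-10)
        assert out[0].regulons_hit == frozenset()

    def test_empty_literature_list(self):
        assert ann.map_literature_genes([], {"p": "MKV" * 30}, [], 1e-10) == []


class TestCompareSets:
    def test_curated_tables_reproduce_reported_rates(self):
        t1 = ann.load_regulon_tf_table()
        annotated = ann.annotate_from_tf_table(t1)
        verified = {ar.regulon_id for ar in annotated
                    if ar.verdict == "computationally_verified"}
        lits = ann.literature_genes_from_table(ann.load_literature_gene_table())
        from regulonkit.grn import resolve_literature_regulons
        lits = resolve_literature_regulons(lits, ann.regulon_name_to_ids(t1))
        lit_ids = {r for lg in lits for r in lg.regulons_hit}
        report = ann.compare_regulon_sets(
            verified, lit_ids, set(range(1, 52)), set(t1.regulon_id))
        assert report["fp_fraction"] == pytest.approx(1 / 5)
        assert report["fp_ids"] == [15]
        assert report["insignificant_supported_fraction"] == pytest.approx(2 / 37)
        assert report["insignificant_supported_ids"] == [8, 39]

    def test_identical_sets_no_false_positives(self):
        r = ann.compare_regulon_sets({1, 2}, {1, 2}, {1, 2, 3}, {1, 2})
        assert r["fp_fraction"] == 0.0

    def test_empty_computational_not_applicable(self):
        r = ann.compare_regulon_sets(set(), {1}, {1, 2}, {1})
        assert r["fp_fraction"] is None

    def test_random_partitions_match_brute_force(self, rng):
        for _ in range(20):
            universe = set(range(1, 52))
            comp = set(rng.choice(51, size=5, replace=False) + 1)
            lit = set(rng.choice(51, size=6, replace=False) + 1)
            sig = set(rng.choice(51, size=14, replace=False) + 1)
            r = ann.compare_regulon_sets(comp, lit, universe, sig)
            assert r["fp_fraction"] == len(comp - lit) / len(comp)
            assert r["insignificant_supported_fraction"] == (
                len(lit & (universe - sig)) / len(universe - sig))
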
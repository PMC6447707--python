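"""Annotation tests: ORFs, alignment, best-hit taxonomy, domains, Venn."""

import numpy as np
import pytest

from cellguild import annotate as ann
from cellguild import references as refs
from cellguild.seqs import AA20, encode_protein, random_protein, revcomp

from oracles import sw_local_score_bruteforce, venn_enumeration


class TestFindOrfs:
    def test_single_embedded_orf(self, rng):
        protein = random_protein(150, rng)
        gene = encode_protein(protein, rng, gc=0.5)
        # pad with C/T-only sequence: cannot contain ATG on either strand
        pad5 = "".join(rng.choice(list("CT"), 60))
        pad3 = "".join(rng.choice(list("CT"), 60))
        contig = pad5 + gene + pad3
        orfs = ann.find_orfs(contig, min_protein_length=100)
        forward = [g for g in orfs if g.strand == "+"]
        assert len(forward) == 1
        assert forward[0].protein == "M" + protein
        assert contig[forward[0].start : forward[0].end] == gene

    def test_reverse_strand_symmetry(self, rng):
        protein = random_protein(120, rng)
        gene = encode_protein(protein, rng)
        contig = "CCTCT" * 20 + revcomp(gene) + "TTCTC" * 20
        orfs = ann.find_orfs(contig, min_protein_length=100)
        proteins = {g.protein for g in orfs}
        orfs_rc = ann.find_orfs(revcomp(contig), min_protein_length=100)
        assert proteins == {g.protein for g in orfs_rc}
        assert "M" + protein in proteins

    def test_no_orfs_without_start(self):
        assert ann.find_orfs("TAATAGTGA" * 120) == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ann.AnnotationError):
            ann.find_orfs("ACGTX" * 100)


class TestAlignProteins:
    def test_identical_sequences(self):
        score, ident = ann.align_proteins("MKVLINGKTLKG", "MKVLINGKTLKG")
        assert ident == pytest.approx(100.0)

    def test_score_symmetry(self, rng):
        a, b = random_protein(40, rng), random_protein(35, rng)
        sa, _ = ann.align_proteins(a, b)
        sb, _ = ann.align_proteins(b, a)
        assert sa == pytest.approx(sb)

    @pytest.mark.parametrize("pair", [
        ("KW", "KW"), ("MKV", "MQV"), ("WWF", "WF"), ("ACDE", "CDE"),
        ("KKKKK", "KAK"), ("MHRF", "HRWF"),
    ])
    def test_matches_bruteforce_enumeration(self, pair):
        q, s = pair
        score, _ = ann.align_proteins(q, s)
        assert score == pytest.approx(sw_local_score_bruteforce(q, s))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ann.AnnotationError):
            ann.align_proteins("", "MKV")


class TestAssignGenus:
    def test_verbatim_reference_recovered(self, reference):
        ref_id = "Clostridium|endoglucanase"
        genus, prot = reference.protein_db[ref_id]
        hit = ann.assign_genus(prot, reference.protein_db)
        assert hit is not None
        assert hit.genus == "Clostridium"
        assert hit.identity == pytest.approx(100.0)

    def test_random_proteins_unassigned(self, reference, rng):
        """Shuffle-null: random proteins never reach the significance
        threshold against the packaged database."""
        hits = 0
        for _ in range(100):
            p = random_protein(200, rng)
            if ann.assign_genus(p, reference.protein_db) is not None:
                hits += 1
        assert hits == 0

    def test_equal_score_tie_prefers_lower_reference_id(self):
        db = {"b_ref": ("GenusB", "MKVLING"), "a_ref": ("GenusA", "MKVLING")}
        hit = ann.assign_genus("MKVLING", db, min_norm_score=0.0)
        assert hit.ref_id == "a_ref" and hit.genus == "GenusA"

    def test_empty_db_rejected(self):
        with pytest.raises(ann.AnnotationError):
            ann.assign_genus("MKV", {})


class TestGenusIdentityStats:
    def test_hand_arithmetic(self):
        hits = [ann.HitRecord(f"g{i}", "r", "X", v, 10.0, 1.0)
                for i, v in enumerate([60.0, 70.0, 80.0])]
        stats = ann.genus_identity_stats(hits)
        assert stats.loc[0, "mean_identity"] == pytest.approx(70.0)
        assert stats.loc[0, "sd_identity"] == pytest.approx(10.0)

    def test_single_hit_flagged_sd_zero(self):
        stats = ann.genus_identity_stats(
            [ann.HitRecord("g", "r", "X", 75.0, 10.0, 1.0)])
        assert stats.loc[0, "sd_identity"] == 0.0
        assert bool(stats.loc[0, "single_hit"])

    def test_identical_identities_sd_zero(self):
        hits = [ann.HitRecord(f"g{i}", "r", "X", 70.0, 10.0, 1.0)
                for i in range(4)]
        assert ann.genus_identity_stats(hits).loc[0, "sd_identity"] == 0.0


class TestScanDomains:
    def test_concatenated_seeds_found_in_order(self, reference, rng):
        protein = (reference.domain_bases["GH9"] + random_protein(25, rng)
                   + reference.domain_bases["CBM30"])
        hits = ann.scan_domains(protein, reference.family_profiles)
        fams = [h.family for h in hits]
        assert "GH9" in fams and "CBM30" in fams
        assert fams.index("GH9") < fams.index("CBM30")
        assert ann.architecture_string(hits).startswith("GH9")
        assert ann.architecture_string(hits).endswith("CBM30")

    def test_shuffled_seed_hit_rate_below_5pct(self, reference, rng):
        base = np.array(list(reference.domain_bases["GH5"]))
        prof = {"GH5": reference.family_profiles["GH5"]}
        false_hits = sum(
            bool(ann.scan_domains("".join(rng.permutation(base)), prof))
            for _ in range(100)
        )
        assert false_hits <= 5

    def test_no_spurious_hit_between_domains(self, reference, rng):
        linker = random_protein(120, rng)
        hits = ann.scan_domains(
            reference.domain_bases["GH9"] + linker + reference.domain_bases["CBM30"],
            {k: reference.family_profiles[k] for k in ("GH9", "CBM30", "GH48")},
        )
        assert {h.family for h in hits} == {"GH9", "CBM30"}

    def test_architecture_string_edges(self):
        assert ann.architecture_string([]) == ""
        one = [ann.DomainHit("g", "GH5", 0, 100, 50.0)]
        assert ann.architecture_string(one) == "GH5"


def test_cellulase_family_set():
    fams = ann.cellulase_families()
    assert len(fams) == 13
    assert "GH5" in fams and "GH9" in fams and "GH124" in fams
    assert "GH10" not in fams and "GH3" not in fams


class TestFunctionLabels:
    def test_endoglucanase_requires_cellulase_domain(self, reference):
        p = reference.marker_bases["endoglucanase"]
        dom = ann.scan_domains(p, reference.family_profiles)
        rec = ann.assign_function_labels("g", p, dom, reference)
        assert "EC:3.2.1.4" in rec.ec_labels
        # without the GH-domain evidence the marker alone is insufficient
        rec_nodom = ann.assign_function_labels("g", p, [], reference)
        assert "EC:3.2.1.4" not in rec_nodom.ec_labels

    def test_beta_glucosidase_marker_only(self, reference):
        p = reference.marker_bases["beta_glucosidase"]
        dom = ann.scan_domains(p, reference.family_profiles)
        rec = ann.assign_function_labels("g", p, dom, reference)
        assert "EC:3.2.1.21" in rec.ec_labels
        assert "EC:3.2.1.4" not in rec.ec_labels

    def test_pts_transporter_label(self, reference):
        p = reference.marker_bases["PTS_CelB"]
        rec = ann.assign_function_labels("g", p, [], reference)
        assert "PTS_CelB" in rec.transporter_labels
        assert rec.ec_labels == ()


class TestVenn:
    def test_identical_sets_center_only(self):
        s = {"GH5", "GH9", "GH48"}
        v = ann.gh_family_venn(s, s, s)
        assert v["ABC"] == 3 and sum(v.values()) == 3

    def test_disjoint_sets_exclusive_only(self):
        v = ann.gh_family_venn({"GH5"}, {"GH9"}, {"GH48", "GH12"})
        assert (v["A"], v["B"], v["C"], v["ABC"]) == (1, 1, 2, 0)

    def test_matches_enumeration_oracle(self, rng):
        universe = [f"GH{i}" for i in range(40)]
        for _ in range(10):
            a, b, c = ({u for u in universe if rng.random() < p}
                       for p in (0.4, 0.5, 0.3))
            assert ann.gh_family_venn(a, b, c) == venn_enumeration(a, b, c)

    def test_counts_sum_to_union(self, rng):
        a = {"GH5", "GH6"}; b = {"GH6", "GH9"}; c = {"GH9", "GH5", "GH44"}
        v = ann.gh_family_venn(a, b, c)
        assert sum(v.values()) == len(a | b | c)


def test_endoglucanase_genes_always_carry_cellulase_domain(community, reference):
    """Every gene labeled EC:3.2.1.4 in an annotated community carries at
    least one GH domain from the 13 cellulase families."""
    from cellguild import synth

    genomes, _profiles = community
    helpers = [g for g in genomes if g.role == "helper"]
    long_contigs = lambda rng, size: np.full(size, 2500)
    cs = synth.shear_contigs_per_genome(helpers, 80, long_contigs, seed=33)
    _genes, _hits, table = ann.annotate_contigs(cs.contigs, reference)
    endo = table[table["ec_labels"].str.contains("EC:3.2.1.4", na=False)]
    assert len(endo) > 0
    for fams in endo["gh_families"]:
        assert set(str(fams).split(",")) & ann.cellulase_families()
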
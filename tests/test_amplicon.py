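"""16S pipeline tests: merging, filtering, classification, tables, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellguild import amplicon as amp
from cellguild.amplicon import AmpliconRead
from cellguild.seqs import revcomp
from cellguild.taxonomy import build_taxonomy


def _read(bases, q=40, rid="r"):
    return AmpliconRead(rid, bases, np.full(len(bases), q, dtype=int))


def _random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestMergePairs:
    def test_exact_overlap_arithmetic(self, rng):
        core = _random_dna(60, rng)
        left, right = _random_dna(90, rng), _random_dna(80, rng)
        fwd = _read(left + core, rid="p/1")
        rev = _read(revcomp(core + right), rid="p/2")
        merged = amp.merge_pairs(fwd, rev)
        assert merged is not None
        assert len(merged.bases) == len(fwd.bases) + len(rev.bases) - 60
        assert merged.bases == left + core + right

    def test_overlap_below_minimum_rejected(self, rng):
        core = _random_dna(49, rng)
        fwd = _read(_random_dna(100, rng) + core)
        rev = _read(revcomp(core + _random_dna(100, rng)))
        assert amp.merge_pairs(fwd, rev, min_overlap=50) is None

    def test_disagreement_resolved_to_higher_quality(self, rng):
        core = _random_dna(60, rng)
        fwd_core = core[:30] + ("A" if core[30] != "A" else "C") + core[31:]
        fwd = AmpliconRead("f", _random_dna(50, rng) + fwd_core,
                           np.r_[np.full(50, 40), np.full(30, 40), [10], np.full(29, 40)])
        rev = _read(revcomp(core + _random_dna(40, rng)))  # Q40 everywhere
        merged = amp.merge_pairs(fwd, rev)
        assert merged is not None
        assert merged.bases[50 + 30] == core[30]  # Q40 call beat the Q10 call


class TestFilterSequences:
    def test_length_rule(self):
        kept, log = amp.filter_sequences([_read("A" * 299, q=40)])
        assert kept == [] and log[0][1] == "length"

    def test_expected_error_retained_at_q40(self):
        # EE = 300 * 10^-4 = 0.03 <= 0.5
        kept, _ = amp.filter_sequences([_read("A" * 300, q=40)])
        assert len(kept) == 1

    def test_expected_error_rejects_q20(self):
        # EE = 300 * 10^-2 = 3.0 > 0.5
        kept, log = amp.filter_sequences([_read("A" * 300, q=20)])
        assert kept == []
        assert "expected_error" in log[0][1]

    @given(st.lists(
        st.tuples(st.integers(300, 400), st.integers(15, 45)), max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_filter_is_order_independent(self, sizes):
        """Retention equals the conjunction of the three rules, so rule
        order cannot matter."""
        reads = [_read("A" * n, q=q, rid=f"r{i}")
                 for i, (n, q) in enumerate(sizes)]
        kept, _ = amp.filter_sequences(reads)
        expected = {
            r.id for r in reads
            if len(r.bases) >= 300 and r.expected_error() <= 0.5
            and r.quals.mean() > 30
        }
        assert {r.id for r in kept} == expected


@pytest.fixture(scope="module")
def toy_tree():
    return build_taxonomy({"phyla": {
        "Firmicutes": ["Clostridium"], "Proteobacteria": ["Tolumonas"]}})


class TestWordModel:
    def test_word_probability_formula(self, toy_tree):
        seqs = [("Clostridium", "ACGTACGTAA"), ("Clostridium", "ACGTACGTCC"),
                ("Tolumonas", "GGGGCCCCTT")]
        model = amp.train_word_model(seqs, toy_tree, word_size=8)
        gi = model.genera.index("Clostridium")
        # "ACGTACGT" occurs in both Clostridium sequences, nowhere else
        lp = model.log_probs(["ACGTACGT"])
        prior = (2 + 0.5) / (3 + 1)
        assert np.exp(lp[0, gi]) == pytest.approx((2 + prior) / (2 + 1))
        # an absent word keeps positive probability prior/(M+1)
        lp0 = model.log_probs(["TTTTTTTT"])
        prior0 = 0.5 / 4
        assert np.exp(lp0[0, gi]) == pytest.approx(prior0 / 3)
        assert np.exp(lp0[0, gi]) > 0

    def test_unknown_genus_rejected(self, toy_tree):
        with pytest.raises(amp.AmpliconError):
            amp.train_word_model([("Vibrio", "ACGTACGTAA")], toy_tree)

    def test_training_is_deterministic(self, toy_tree):
        seqs = [("Clostridium", "ACGTACGTAA"), ("Tolumonas", "GGGGCCCCTT")]
        m1 = amp.train_word_model(seqs, toy_tree)
        m2 = amp.train_word_model(seqs, toy_tree)
        w = "ACGTACGT"
        assert np.allclose(m1.log_probs([w]), m2.log_probs([w]))


class TestBootstrapClassification:
    def test_single_genus_confidence_one(self, toy_tree, rng):
        seq = _random_dna(120, rng)
        model = amp.train_word_model([("Clostridium", seq)], toy_tree)
        conf = amp.classify_with_bootstrap(model, seq, seed=0)
        assert conf["genus"]["Clostridium"] == pytest.approx(1.0)

    def test_symmetric_query_splits_confidence(self, toy_tree, rng):
        a, b = _random_dna(200, rng), _random_dna(200, rng)
        model = amp.train_word_model([("Clostridium", a), ("Tolumonas", b)],
                                     toy_tree)
        query = a[:100] + b[100:]  # equidistant composite
        conf = amp.classify_with_bootstrap(model, query, n_bootstrap=100, seed=1)
        top = max(conf["genus"].values())
        assert abs(top - 0.5) <= 3 * np.sqrt(0.25 / 100)

    def test_rank_confidence_monotone(self, community, tree, rng):
        from cellguild import synth

        model = amp.train_word_model(synth.make_16s_reference(seed=2), tree)
        genomes, profiles = community
        pairs, _ = synth.simulate_amplicons(genomes, profiles[0], n_pairs=10, seed=4)
        for f, r in pairs:
            m = amp.merge_pairs(f, r)
            conf = amp.classify_with_bootstrap(model, m.bases, seed=5)
            top_genus = max(conf["genus"].values())
            for rank in ("family", "order", "class", "phylum"):
                assert max(conf[rank].values()) >= top_genus - 1e-12

    def test_too_short_sequence_rejected(self, toy_tree, rng):
        model = amp.train_word_model([("Clostridium", _random_dna(50, rng))],
                                     toy_tree)
        with pytest.raises(amp.AmpliconError):
            amp.classify_with_bootstrap(model, "ACGT", seed=0)


class TestEscalation:
    def test_accepted_at_genus(self):
        conf = {"genus": {"Clostridium": 0.6}, "family": {"Clostridiaceae": 0.8},
                "order": {"Clostridiales": 0.9}, "class": {"Clostridia": 0.9},
                "phylum": {"Firmicutes": 1.0}}
        a = amp.escalate_assignment(conf)
        assert a.accepted_rank == "genus" and a.display_name == "Clostridium"

    def test_escalates_to_family_with_composite_name(self):
        conf = {"genus": {"Clostridium": 0.4}, "family": {"Clostridiaceae": 0.8},
                "order": {"Clostridiales": 0.9}, "class": {"Clostridia": 0.9},
                "phylum": {"Firmicutes": 1.0}}
        a = amp.escalate_assignment(conf)
        assert a.accepted_rank == "family"
        assert a.display_name == "Clostridiaceae_clostridium-like"

    def test_total_failure_is_unclassified(self):
        conf = {r: {"X": 0.1} for r in ("genus", "family", "order", "class",
                                        "phylum")}
        a = amp.escalate_assignment(conf)
        assert a.display_name == "unclassified" and a.accepted_rank is None


def _assign(name, rid="r"):
    return amp.TaxonAssignment(rid, {}, "genus", name)


class TestAbundanceTable:
    def test_single_sample_taxa_dropped_without_rescaling(self):
        asg = {
            "s1": [_assign("A"), _assign("A"), _assign("B")],
            "s2": [_assign("A"), _assign("A"), _assign("C"), _assign("C")],
        }
        raw, filt = amp.build_abundance_table(asg)
        assert set(raw.columns) == {"A", "B", "C"}
        assert set(filt.columns) == {"A"}
        # no renormalization after the drop
        assert filt.loc["s1", "A"] == pytest.approx(2 / 3)
        assert filt.loc["s2", "A"] == pytest.approx(2 / 4)

    def test_single_taxon_two_samples(self):
        asg = {"s1": [_assign("A")], "s2": [_assign("A")]}
        raw, filt = amp.build_abundance_table(asg)
        assert (raw["A"] == 1.0).all() and (filt["A"] == 1.0).all()

    def test_count_normalization(self):
        asg = {
            "s1": [_assign("A")] * 50 + [_assign("B")] * 30 + [_assign("C")] * 20,
            "s2": [_assign("A")] * 10 + [_assign("B")] * 10 + [_assign("C")] * 10,
        }
        raw, _ = amp.build_abundance_table(asg)
        assert raw.loc["s1"].tolist() == pytest.approx([0.5, 0.3, 0.2])

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(amp.AmpliconError):
            amp.build_abundance_table({"s1": [_assign("A")]})

    def test_total_abundance_sums_selected_taxa(self):
        table = pd.DataFrame({"A": [0.5], "B": [0.3], "C": [0.2]}, index=["m"])
        assert amp.total_abundance(table, ["A", "B"]).iloc[0] == pytest.approx(0.8)


class TestPca:
    def test_two_samples_single_component(self, rng):
        table = pd.DataFrame(rng.random((2, 5)), index=["s1", "s2"])
        coords, var = amp.pca(table)
        assert var[0] == pytest.approx(1.0)
        assert np.allclose(coords.iloc[0], -coords.iloc[1], atol=1e-9)

    def test_duplicated_samples_coincide(self, rng):
        row = rng.random(6)
        table = pd.DataFrame([row, row, rng.random(6)], index=list("abc"))
        coords, _ = amp.pca(table)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_matches_eigendecomposition_oracle(self, rng):
        table = pd.DataFrame(rng.random((6, 20)))
        coords, var = amp.pca(table)
        X = table.to_numpy()
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(2):
            j = np.argmax(np.abs(v[:, i]))
            if v[j, i] < 0:
                v[:, i] *= -1
        oracle = Xc @ v[:, :2]
        assert np.allclose(coords.to_numpy(), oracle, atol=1e-8)
        assert np.allclose(var[:2], (w / w.sum())[:2], atol=1e-8)

    def test_column_order_invariance_up_to_sign(self, rng):
        table = pd.DataFrame(rng.random((4, 8)))
        shuffled = table[rng.permutation(table.columns)]
        c1, _ = amp.pca(table)
        c2, _ = amp.pca(shuffled)
        for k in c1.columns:
            assert np.allclose(c1[k], c2[k], atol=1e-8) or \
                np.allclose(c1[k], -c2[k], atol=1e-8)

    def test_constant_table_warns_and_zeroes(self):
        table = pd.DataFrame(np.full((3, 4), 0.25))
        with pytest.warns(UserWarning):
            coords, var = amp.pca(table)
        assert np.allclose(coords, 0) and np.allclose(var, 0)
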
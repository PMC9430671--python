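"""Identity clustering, positional consensus, products and architectures."""

import random

import pytest

from dualysin import clustering as cl
from dualysin import massmetry
from dualysin.itss_screen import FilterFlags, ITSSCall
from dualysin.sequence_io import DomainHit
from dualysin.tir_model import StartCandidate

from conftest import gene_from_cds, plain_backbone, plant_codon

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def mutate(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([a for a in AA if a != seq[p]])
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert cl.pairwise_identity("ACDEFG", "ACDEFG") == 100.0

    def test_single_substitution(self):
        assert cl.pairwise_identity("ACDEFG", "ACDEFA") == pytest.approx(83.33, abs=0.05)

    def test_symmetry(self):
        rng = random.Random(5)
        for _ in range(10):
            a = random_protein(rng, rng.randint(20, 60))
            b = random_protein(rng, rng.randint(20, 60))
            assert cl.pairwise_identity(a, b) == pytest.approx(
                cl.pairwise_identity(b, a), abs=1e-9
            )

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            cl.pairwise_identity("", "ACD")

    def test_shorter_denominator_option(self):
        # prefix pair: 10 matches over alignment length 20 vs shorter length 10
        a, b = "ACDEFGHIKL", "ACDEFGHIKL" + "WWWWWWWWWW"
        assert cl.pairwise_identity(a, b) == pytest.approx(50.0, abs=0.1)
        assert cl.pairwise_identity(a, b, denominator="shorter") == pytest.approx(100.0)


class TestClusterByIdentity:
    def test_identical_triplet_plus_outlier(self, rng):
        pyr = random.Random(11)
        base = random_protein(pyr, 60)
        other = random_protein(pyr, 60)
        seqs = {"a": base, "b": base, "c": base, "d": other}
        sizes = sorted(len(c.members) for c in cl.cluster_by_identity(seqs, 50.0))
        assert sizes == [1, 3]

    def test_all_distinct_at_threshold_100(self):
        pyr = random.Random(3)
        seqs = {f"s{i}": random_protein(pyr, 40) for i in range(4)}
        clusters = cl.cluster_by_identity(seqs, 100.0)
        assert all(len(c.members) == 1 for c in clusters)

    def test_single_linkage_chains(self):
        pyr = random.Random(9)
        a = random_protein(pyr, 100)
        b = mutate(pyr, a, range(0, 40))       # a-b 60%
        c = mutate(pyr, b, range(40, 80))      # b-c 60%, a-c ~20%
        assert cl.pairwise_identity(a, c) < 50.0
        clusters = cl.cluster_by_identity({"a": a, "b": b, "c": c}, 50.0)
        assert len(clusters) == 1 and clusters[0].members == ["a", "b", "c"]

    def test_input_order_invariance(self):
        pyr = random.Random(13)
        fams = []
        for _ in range(3):
            base = random_protein(pyr, 80)
            fams += [base, mutate(pyr, base, range(0, 8)), mutate(pyr, base, range(8, 16))]
        seqs = {f"g{i}": s for i, s in enumerate(fams)}
        ref = cl.cluster_by_identity(seqs, 50.0)
        items = list(seqs.items())
        pyr.shuffle(items)
        shuffled = cl.cluster_by_identity(dict(items), 50.0)
        assert [c.members for c in ref] == [c.members for c in shuffled]
        assert [c.representative for c in ref] == [c.representative for c in shuffled]

    def test_representative_is_longest_member(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 3
        seqs = {"short": base, "long": base + "ACDEF"}
        (cluster,) = cl.cluster_by_identity(seqs, 50.0)
        assert cluster.representative == "long"

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            cl.cluster_by_identity({"a": "ACD"}, 0.0)


def _call(gene_id, codon):
    cand = StartCandidate(gene_id=gene_id, codon_index=codon, start_codon="ATG", tir=100.0)
    return ITSSCall(gene_id, cand, FilterFlags(True, True, True, True), "retained")


class TestPositionConsensus:
    def _cluster(self, members, rep=None):
        return cl.Cluster("C0000", list(members), 50.0, rep or members[0])

    def test_majority_same_column(self):
        seq = "M" + "A" * 99
        seqs = {f"m{i}": seq for i in range(5)}
        calls = {f"m{i}": _call(f"m{i}", 40) for i in range(4)}
        calls["m4"] = _call("m4", 90)
        rec = cl.itss_position_consensus(self._cluster(sorted(seqs)), calls, seqs)
        assert rec.consensus_column == 40
        assert rec.support_fraction == pytest.approx(0.8)

    def test_scattered_positions_give_no_consensus(self):
        seq = "M" + "A" * 99
        seqs = {f"m{i}": seq for i in range(4)}
        calls = {f"m{i}": _call(f"m{i}", 20 + 20 * i) for i in range(4)}
        rec = cl.itss_position_consensus(self._cluster(sorted(seqs)), calls, seqs)
        assert rec.consensus_column is None
        assert rec.support_fraction == pytest.approx(0.25)

    def test_singleton_cluster_with_call(self):
        seqs = {"solo": "M" + "A" * 50}
        rec = cl.itss_position_consensus(
            self._cluster(["solo"]), {"solo": _call("solo", 30)}, seqs
        )
        assert rec.consensus_column == 30 and rec.support_fraction == 1.0

    def test_alignment_maps_through_indels(self):
        rep = "MAAAAAAAAAWWWWWWWWWWYYYYYYYYYY"
        short = rep[:10] + rep[15:]  # 5-residue deletion before the call site
        seqs = {"rep": rep, "del": short}
        calls = {"rep": _call("rep", 25), "del": _call("del", 20)}
        cluster = cl.Cluster("C0000", ["del", "rep"], 50.0, "rep")
        rec = cl.itss_position_consensus(cluster, calls, seqs)
        assert rec.consensus_column == 25  # both map to the same rep position
        assert rec.support_fraction == 1.0

    def test_explicit_msa_columns(self):
        seqs = {"a": "MKLV", "b": "MLV"}
        msa = {"a": "MKLV", "b": "M-LV"}
        calls = {"a": _call("a", 3), "b": _call("b", 2)}
        cluster = cl.Cluster("C0000", ["a", "b"], 50.0, "a")
        rec = cl.itss_position_consensus(cluster, calls, seqs, msa=msa)
        assert rec.columns == {"a": 3, "b": 3}
        assert rec.consensus_column == 3

    def test_member_missing_from_msa_raises(self):
        cluster = cl.Cluster("C0000", ["a", "b"], 50.0, "a")
        calls = {"a": _call("a", 2), "b": _call("b", 2)}
        with pytest.raises(ValueError, match="missing"):
            cl.itss_position_consensus(cluster, calls, {"a": "MKV", "b": "MKV"}, msa={"a": "MKV"})


class TestDeriveProducts:
    TAG = "PGGGSHHHHHH"

    def _gene(self, n_codons=310, itss=209):
        return gene_from_cds(plant_codon(plain_backbone(n_codons), itss))

    def test_ctp_spans_start_to_terminus(self):
        pair = cl.derive_products(self._gene(), 209)
        assert len(pair.flp_seq) == 310
        assert len(pair.ctp_seq) == 310 - 209 + 1  # residues 209..310
        assert pair.ctp_seq[0] == "M"
        assert pair.ctp_seq[1:] == pair.flp_seq[209:]

    def test_native_met_at_the_start_is_unchanged(self):
        gene = self._gene()
        assert gene.protein[208] == "M"  # planted ATG
        pair = cl.derive_products(gene, 209)
        assert pair.ctp_seq == gene.protein[208:]

    def test_tag_adds_equal_mass_to_both_products(self):
        gene = self._gene()
        bare = cl.derive_products(gene, 209)
        tagged = cl.derive_products(gene, 209, tag=self.TAG)
        tag_mass = massmetry.sequence_mass(self.TAG, "average") - 18.0153
        d_flp = tagged.flp_mass_da - bare.flp_mass_da
        d_ctp = tagged.ctp_mass_da - bare.ctp_mass_da
        assert d_flp == pytest.approx(d_ctp, abs=1e-6)
        assert d_flp == pytest.approx(tag_mass, abs=0.01)

    def test_mass_difference_closed_form(self):
        # flp - ctp = mass(prefix) - water + (residue at the start - Met residue)
        gene = self._gene()
        itss = 209
        pair = cl.derive_products(gene, itss)
        water = 18.015
        prefix = massmetry.sequence_mass(gene.protein[: itss - 1], "average")
        native = gene.protein[itss - 1]
        delta_res = massmetry.sequence_mass(native, "average") - massmetry.sequence_mass(
            "M", "average"
        )
        assert pair.flp_mass_da - pair.ctp_mass_da == pytest.approx(
            prefix - water + delta_res, abs=0.05
        )

    def test_out_of_range_start_raises(self):
        with pytest.raises(ValueError):
            cl.derive_products(self._gene(), 311)


class TestClassifyArchitecture:
    def _hit(self, acc, name, s, e, cat):
        return DomainHit(acc, name, s, e, 1e-20, cat)

    def test_single_upstream_cd_is_group2(self):
        hits = [self._hit("PF01183", "Glyco_hydro_25", 6, 190, "catalytic")]
        arch = cl.classify_architecture(hits, 209)
        assert arch.group == "group2_one_CD"
        assert arch.ctp_domains == []

    def test_start_between_two_cds_is_group1(self):
        hits = [
            self._hit("PF01510", "Amidase_2", 10, 140, "catalytic"),
            self._hit("PF05257", "CHAP", 180, 290, "catalytic"),
            self._hit("PF08460", "SH3_5", 300, 360, "cwbd"),
        ]
        arch = cl.classify_architecture(hits, 160)
        assert arch.group == "group1_two_CDs"
        # CTP keeps the second CD and the CWBD, coordinates shifted
        assert [(h.name, h.start_aa) for h in arch.ctp_domains] == [
            ("CHAP", 21),
            ("SH3_5", 141),
        ]

    def test_no_catalytic_hits_is_unclassified(self):
        hits = [self._hit("PF08460", "SH3_5", 100, 160, "cwbd")]
        assert cl.classify_architecture(hits, 80).group == "unclassified"

    def test_start_inside_the_only_cd_is_unclassified(self):
        hits = [self._hit("PF01183", "Glyco_hydro_25", 6, 190, "catalytic")]
        assert cl.classify_architecture(hits, 100).group == "unclassified"
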
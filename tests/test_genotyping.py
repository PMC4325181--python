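"""Unit tests for clustering, chimera detection, the three classification
steps, the two post-processing modes and repeatability."""

import itertools

import numpy as np
import pytest

import replitype as rt
from replitype.genotyping import (ALLELE, ARTEFACT, CHIMERA, DIFF_1_2BP,
                                  DIFF_GT2BP, DISCARDED, PUTATIVE_ALLELE,
                                  SINGLETON, UNCLASSIFIED, SamplePair,
                                  _chimera_flags, build_dataset_index,
                                  classify_step2, classify_step3)

from conftest import make_amplicon_clusters


def brute_force_chimera(query: str, parents: list[str]) -> bool:
    """Construct-and-compare oracle: enumerate every prefix+suffix join."""
    for a, b in itertools.permutations(parents, 2):
        for k in range(1, len(query)):
            if k <= len(a) and len(query) - k <= len(b):
                if a[:k] + b[len(b) - (len(query) - k):] == query:
                    return True
    return False


class TestClusterReads:
    def test_counts_and_ordering(self):
        reads = ["ACGT"] * 5 + ["AGGT"] * 2 + ["TTTT"]
        ac = rt.cluster_reads(reads)
        assert [(c.sequence, c.count) for c in ac.clusters] == \
            [("ACGT", 5), ("AGGT", 2), ("TTTT", 1)]
        assert sum(c.count for c in ac.clusters) == ac.n_assigned == 8

    def test_single_cluster_has_frequency_one(self):
        ac = rt.cluster_reads(["AAAA"] * 7)
        assert len(ac.clusters) == 1
        assert ac.clusters[0].frequency == 1.0

    def test_tied_max_counts_all_become_putative_alleles(self):
        ac = make_amplicon_clusters({"AAAA": 4, "CCCC": 4, "GGGG": 2}, "s", 1)
        tops = [c for c in ac.clusters if c.label == PUTATIVE_ALLELE]
        assert {c.sequence for c in tops} == {"AAAA", "CCCC"}
        # ties ordered lexicographically
        assert [c.sequence for c in ac.clusters[:2]] == ["AAAA", "CCCC"]


class TestDetectChimera:
    def test_constructed_join_is_found(self):
        hits = rt.detect_chimera("AAAACCCC", ["AAAAAAAA", "CCCCCCCC"])
        assert hits
        assert ("AAAAAAAA", "CCCCCCCC", 4) in hits
        assert all(a != b for a, b, _ in hits)

    def test_identity_with_parent_is_not_chimeric(self):
        assert rt.detect_chimera("AAAAAAAA", ["AAAAAAAA", "CCCCCCCC"]) == []

    def test_near_join_is_rejected(self):
        # G at position 3 belongs to neither parent at that offset
        assert rt.detect_chimera("AAGACCCC",
                                 ["AAAAAAAA", "CCCCCCCC"]) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_fast_flags_agree_with_exhaustive_scan(self, seed):
        """Pipeline chimera flags == brute force on random cluster sets,
        including unequal lengths."""
        rng = np.random.default_rng(seed)
        for _ in range(300):
            n = rng.integers(3, 7)
            length = int(rng.integers(6, 30))
            seqs = []
            while len(seqs) < n:
                ln = length + int(rng.integers(-2, 3))
                s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=ln))
                if s not in seqs:
                    seqs.append(s)
            if rng.random() < 0.5 and len(seqs) >= 3:
                # plant a join of the two most frequent into the last slot
                k = int(rng.integers(1, min(len(seqs[0]), len(seqs[1]))))
                joined = seqs[0][:k] + seqs[1][k - len(seqs[1]):]
                if joined not in seqs[:-1]:
                    seqs[-1] = joined
            counts = sorted(rng.integers(2, 50, size=len(seqs)),
                            reverse=True)
            clusters = make_amplicon_clusters(
                {s: int(c) for s, c in zip(seqs, counts)}, "s", 1).clusters
            flags = _chimera_flags(clusters)
            for c, flag in zip(clusters, flags):
                parents = [p.sequence for p in clusters if p.count > c.count]
                expected = brute_force_chimera(c.sequence, parents)
                assert flag == expected, (c.sequence, parents)
                assert bool(rt.detect_chimera(c.sequence, parents)) == expected


class TestStep1:
    def test_single_substitution_is_one_two_bp(self):
        x = "ACGTACGTAC"
        w = "ACGTACGTAT"
        ac = make_amplicon_clusters({x: 10, w: 2}, "s", 1)
        labels = {c.sequence: c.label for c in ac.clusters}
        assert labels == {x: PUTATIVE_ALLELE, w: DIFF_1_2BP}

    def test_full_label_assignment(self):
        x = "AAAAAAAAAAAA"
        y = "AATAAATAAATA"  # 3 substitutions from x
        z = x[:6] + y[6:]   # chimera of the two more frequent clusters
        v = "GGGGGGGGGGGG"
        ac = make_amplicon_clusters({x: 10, y: 6, z: 3, v: 1}, "s", 1)
        labels = {c.sequence: c.label for c in ac.clusters}
        assert labels[x] == PUTATIVE_ALLELE
        assert labels[y] == DIFF_GT2BP
        assert labels[z] == CHIMERA
        assert labels[v] == SINGLETON
        assert brute_force_chimera(z, [x, y])
        assert not brute_force_chimera(y, [x])

    def test_lone_cluster_is_putative_allele(self):
        ac = make_amplicon_clusters({"ACGT": 9}, "s", 1)
        assert ac.clusters[0].label == PUTATIVE_ALLELE

    def test_singletons_discarded(self):
        ac = make_amplicon_clusters({"AAAA": 5, "CCCC": 1}, "s", 1)
        states = {c.sequence: c.state for c in ac.clusters}
        assert states["CCCC"] == DISCARDED


def _pair(r1_counts, r2_counts, sample="S1"):
    return SamplePair(sample_id=sample,
                      r1=make_amplicon_clusters(r1_counts, sample, 1),
                      r2=make_amplicon_clusters(r2_counts, sample, 2))


X = "AAAAAAAAAAAA"
X1 = "AAAAAAAAAAAT"        # 1 bp from X
Y = "CCGGCCGGCCGG"         # far from X
Z = "TTTTTTTTTTTT"


class TestStep2:
    def test_one_two_bp_absent_from_replicate_is_artefact(self):
        pair = _pair({X: 10, X1: 3}, {X: 10})
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.by_seq[X1].state == ARTEFACT

    def test_chimera_in_both_replicates_is_artefact(self):
        a, b = "AAAAAACCCCCC", "GGGGGGTTTTTT"
        chim = a[:6] + b[6:]
        pair = _pair({a: 10, b: 8, chim: 3}, {a: 9, b: 8, chim: 2})
        for amp in pair.amplicons():
            assert amp.by_seq[chim].label == CHIMERA
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.by_seq[chim].state == ARTEFACT
        assert pair.r2.by_seq[chim].state == ARTEFACT

    def test_gt2bp_unique_to_single_amplicon_is_artefact(self):
        pair = _pair({X: 10, Y: 3}, {X: 10})
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.by_seq[Y].state == ARTEFACT

    def test_gt2bp_shared_across_samples_is_retained(self):
        p1 = _pair({X: 10, Y: 3}, {X: 10}, sample="S1")
        p2 = _pair({Z: 10, Y: 4}, {Z: 10}, sample="S2")
        p3 = _pair({Z: 10}, {Z: 9}, sample="S3")
        index = build_dataset_index([p1, p2, p3])
        for p in (p1, p2, p3):
            classify_step2(p, index)
        assert p1.r1.by_seq[Y].state == UNCLASSIFIED  # retained

    def test_missing_replicate_skips_sample(self):
        pair = SamplePair(sample_id="S1",
                          r1=make_amplicon_clusters({X: 5, X1: 2}, "S1", 1),
                          r2=None)
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.by_seq[X1].state == UNCLASSIFIED  # untouched


class TestStep3:
    def test_frequency_above_artefacts_promotes(self):
        # X1 in both replicates at 8 %, artefact X2 at 3 % in r1 only
        x2 = "AAAAAAAATAAA"
        pair = _pair({X: 89, X1: 8, x2: 3}, {X: 92, X1: 8})
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.by_seq[x2].state == ARTEFACT
        classify_step3([pair])
        assert pair.r1.by_seq[X1].state == ALLELE
        assert pair.r2.by_seq[X1].state == ALLELE

    def test_frequency_below_artefacts_stays_unclassified(self):
        x2 = "AAAAAAAATAAA"
        pair = _pair({X: 95, x2: 3, X1: 2}, {X: 98, X1: 2})
        classify_step2(pair, build_dataset_index([pair]))
        classify_step3([pair])
        assert pair.r1.by_seq[X1].state == UNCLASSIFIED

    def test_empty_artefact_list_passes_vacuously(self):
        pair = _pair({X: 90, Y: 10}, {X: 88, Y: 12})
        classify_step2(pair, build_dataset_index([pair]))
        assert pair.r1.max_artefact_frequency() == 0.0
        classify_step3([pair])
        assert pair.r1.by_seq[Y].state == ALLELE

    def test_single_replicate_gt2bp_resolved_against_other_samples(self):
        # Y present once in S1; in S2 it is a confirmed allele
        p1 = _pair({X: 20, Y: 2}, {X: 20}, sample="S1")
        p2 = _pair({Y: 30, X: 10}, {Y: 28, X: 9}, sample="S2")
        index = build_dataset_index([p1, p2])
        for p in (p1, p2):
            classify_step2(p, index)
        classify_step3([p1, p2])
        assert p1.r1.by_seq[Y].state == UNCLASSIFIED
        # without external allele support it is an artefact instead
        p3 = _pair({X: 20, Z: 2}, {X: 20}, sample="S3")
        p4 = _pair({X: 22, Z: 3}, {X: 21}, sample="S4")
        index = build_dataset_index([p3, p4])
        for p in (p3, p4):
            classify_step2(p, index)
        classify_step3([p3, p4])
        assert p3.r1.by_seq[Z].state == ARTEFACT
        assert p4.r1.by_seq[Z].state == ARTEFACT


class TestRepeatability:
    def test_identical_calls_are_fully_repeatable(self):
        assert rt.repeatability({"a", "b", "c", "d"},
                                {"a", "b", "c", "d"}) == 100.0

    def test_union_convention_matches_published_minimum(self):
        # 4 shared of 9 in the union: the published worst case, 44.4 %
        a = set("abcd")
        b = set("abcd") | set("vwxyz")
        assert rt.repeatability(a, b) == pytest.approx(44.4, abs=0.05)

    def test_disjoint_calls_are_zero(self):
        assert rt.repeatability({"a"}, {"b"}) == 0.0

    def test_two_empty_calls_are_undefined(self):
        with pytest.raises(ValueError):
            rt.repeatability(set(), set())


class TestPostprocessing:
    def _dataset(self):
        """Five samples; X everywhere; Y in S1+S2; Z putative only in S5."""
        pairs = [
            _pair({X: 80, Y: 15}, {X: 78, Y: 14}, sample="S1"),
            _pair({X: 70, Y: 20}, {X: 72, Y: 21}, sample="S2"),
            _pair({X: 95}, {X: 93}, sample="S3"),
            _pair({X: 90}, {X: 91}, sample="S4"),
            _pair({Z: 50, X: 40}, {Z: 52, X: 41}, sample="S5"),
        ]
        index = build_dataset_index(pairs)
        for p in pairs:
            classify_step2(p, index)
        classify_step3(pairs)
        return pairs

    def test_single_individual_allele_dropped(self):
        pairs = self._dataset()
        res = rt.postprocess_large(pairs)
        assert Z not in res.catalog.values()
        assert X in res.catalog.values() and Y in res.catalog.values()
        assert Z not in res.calls["S5"].alleles

    def test_catalog_matching_unclassified_promoted(self):
        # In S3, Y sits below replicate-specific artefacts, so step 3 leaves
        # it unclassified; matching the catalog promotes it there.
        art1 = X[:3] + "C" + X[4:]
        art2 = X[:5] + "G" + X[6:]
        pairs = [
            _pair({X: 80, Y: 15}, {X: 78, Y: 14}, sample="S1"),
            _pair({X: 70, Y: 20}, {X: 72, Y: 21}, sample="S2"),
            _pair({X: 95, art1: 5, Y: 2}, {X: 93, art2: 5, Y: 2},
                  sample="S3"),
        ]
        index = build_dataset_index(pairs)
        for p in pairs:
            classify_step2(p, index)
        classify_step3(pairs)
        assert pairs[2].r1.by_seq[Y].state == UNCLASSIFIED
        res = rt.postprocess_large(pairs)
        assert Y in res.calls["S3"].alleles

    def test_pervasive_low_frequency_variant_flagged(self):
        # W sits at ~2 % in both amplicons of every sample, below a strong
        # replicate-specific artefact in each amplicon, so it is never
        # promoted -- the low-amplification-efficiency phenomenon
        W = "GTGTGTGTGTGT"
        pairs = []
        for i in range(5):
            art1 = X[:i + 1] + "C" + X[i + 2:]  # 1 bp artefact, r1 only
            art2 = X[:i + 1] + "G" + X[i + 2:]
            pairs.append(_pair({X: 400, art1: 30, W: 8},
                               {X: 410, art2: 31, W: 8},
                               sample=f"S{i + 1}"))
        index = build_dataset_index(pairs)
        for p in pairs:
            classify_step2(p, index)
        classify_step3(pairs)
        res = rt.postprocess_large(pairs)
        assert W in res.low_efficiency
        assert W in res.catalog.values()
        for call in res.calls.values():
            assert W in call.low_efficiency_flags

    def test_artefact_matching_catalog_promoted(self):
        # Y was classified artefact in S9 but matches a catalog allele and
        # sits in both amplicons above the least frequent catalog entry.
        pairs = self._dataset()
        pair = _pair({X: 20, Y: 60}, {X: 22, Y: 58}, sample="S9")
        for amp in pair.amplicons():
            amp.by_seq[Y].state = ARTEFACT
        pairs.append(pair)
        res = rt.postprocess_large(pairs)
        assert Y in res.calls["S9"].alleles

    def test_small_sample_rules(self):
        A, B = X, Y
        C = Z
        pairs = [
            # A allele in both replicates of only S1: kept
            _pair({A: 60, B: 30}, {A: 58, B: 31}, sample="S1"),
            _pair({B: 70}, {B: 72}, sample="S2"),
        ]
        # C unclassified in both replicates of two samples: promoted
        pairs.append(_pair({B: 80, C: 3, "AAAATTTTAAAA": 50},
                           {B: 82, C: 3, "AAAATTTTAAAA": 51}, sample="S3"))
        pairs.append(_pair({B: 90, C: 4, "AAAATTTTAAAA": 60},
                           {B: 88, C: 4, "AAAATTTTAAAA": 61}, sample="S4"))
        index = build_dataset_index(pairs)
        for p in pairs:
            classify_step2(p, index)
        classify_step3(pairs)
        # force C unclassified (it may have been promoted by frequency)
        for p in pairs:
            for amp in p.amplicons():
                c = amp.by_seq.get(C)
                if c is not None and c.state == ALLELE:
                    c.state = UNCLASSIFIED
        res = rt.postprocess_small(pairs)
        assert A in res.catalog.values()   # both replicates of one sample
        assert C in res.catalog.values()   # unclassified in 2 birds
        assert C in res.calls["S3"].alleles

    def test_every_cluster_ends_in_exactly_one_state(self):
        pairs = self._dataset()
        res = rt.postprocess_large(pairs)
        valid = {ALLELE, ARTEFACT, UNCLASSIFIED, DISCARDED}
        for pair in res.pairs:
            for amp in pair.amplicons():
                for c in amp.clusters:
                    assert c.state in valid

    def test_reported_alleles_exist_as_clusters(self):
        pairs = self._dataset()
        res = rt.postprocess_large(pairs)
        observed = {c.sequence for pair in res.pairs
                    for amp in pair.amplicons() for c in amp.clusters}
        for seq in res.catalog.values():
            assert seq in observed
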
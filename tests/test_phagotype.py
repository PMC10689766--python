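import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vipseq.io import Interval
from vipseq.phagotype import (
    assign_phagotypes,
    accessory_in_sip_fraction,
    cluster_by_similarity,
    dereplicate_by_prophage_content,
    protection_statistic,
)


def sim_matrix(labels, pairs):
    """Symmetric percent-similarity matrix from {(a, b): value} pairs."""
    df = pd.DataFrame(0.0, index=labels, columns=labels)
    np.fill_diagonal(df.values, 100.0)
    for (a, b), v in pairs.items():
        df.loc[a, b] = df.loc[b, a] = v
    return df


def brute_force_components(matrix, threshold):
    """Independent oracle: transitive closure by repeated merging."""
    labels = list(matrix.index)
    comps = [{l} for l in labels]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(comps)), 2):
            if any(matrix.loc[a, b] >= threshold
                   for a in comps[i] for b in comps[j]):
                comps[i] |= comps[j]
                del comps[j]
                changed = True
                break
    return {frozenset(c) for c in comps}


class TestClustering:
    def test_all_identical_one_cluster(self):
        m = sim_matrix(list("ABC"), {(a, b): 100.0
                                     for a, b in itertools.combinations("ABC", 2)})
        ca = cluster_by_similarity(m, 95.0)
        assert set(ca.members.values()) == {"A"}

    def test_threshold_above_100_all_singletons(self):
        m = sim_matrix(list("ABC"), {("A", "B"): 100.0})
        ca = cluster_by_similarity(m, 101.0)
        assert len(set(ca.members.values())) == 3

    def test_single_linkage_chain(self):
        # A-B 80, B-C 75, C-D 60 at threshold 70 -> {A,B,C}, {D}
        m = sim_matrix(list("ABCD"),
                       {("A", "B"): 80, ("B", "C"): 75, ("C", "D"): 60})
        ca = cluster_by_similarity(m, 70.0)
        clusters = {frozenset(v) for v in ca.clusters().values()}
        assert clusters == {frozenset("ABC"), frozenset("D")}
        assert clusters == brute_force_components(m, 70.0)

    def test_asymmetric_matrix_rejected(self):
        m = sim_matrix(list("AB"), {})
        m.loc["A", "B"] = 50.0
        with pytest.raises(ValueError):
            cluster_by_similarity(m, 70.0)

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_higher_threshold_refines_lower(self, data):
        """Species-level (95%) clusters nest inside genus-level (70%) which
        nest inside 50% clusters."""
        n = data.draw(st.integers(3, 8))
        labels = [f"p{i}" for i in range(n)]
        pairs = {
            (a, b): data.draw(st.floats(0, 100))
            for a, b in itertools.combinations(labels, 2)
        }
        m = sim_matrix(labels, pairs)
        assignments = {t: cluster_by_similarity(m, t) for t in (95.0, 70.0, 50.0)}
        for hi, lo in ((95.0, 70.0), (70.0, 50.0)):
            fine, coarse = assignments[hi], assignments[lo]
            for cluster in fine.clusters().values():
                assert len({coarse.members[p] for p in cluster}) == 1


class TestPhagotypes:
    CLUSTERS = cluster_by_similarity(
        sim_matrix(["s1", "s2", "g1", "g2"], {("s1", "s2"): 90, ("g1", "g2"): 75}),
        70.0,
    )

    def test_identical_sets_share_phagotype(self):
        pa = assign_phagotypes({"A": ["s1"], "B": ["s2"]}, self.CLUSTERS)
        assert pa.phagotype_ids["A"] == pa.phagotype_ids["B"]
        assert pa.cluster_sets["A"] == pa.cluster_sets["B"]

    def test_empty_set_is_a_valid_phagotype(self):
        pa = assign_phagotypes({"A": [], "B": ["s1"]}, self.CLUSTERS)
        assert pa.cluster_sets["A"] == frozenset()
        assert pa.phagotype_ids["A"] != pa.phagotype_ids["B"]

    def test_distinct_sets_distinct_phagotypes(self):
        pa = assign_phagotypes(
            {"A": ["s1"], "B": ["g1"], "C": ["s1", "g2"], "D": ["s2"], "E": ["g2"]},
            self.CLUSTERS,
        )
        assert len(set(pa.phagotype_ids.values())) == 3

    def test_unclustered_sip_rejected(self):
        with pytest.raises(ValueError):
            assign_phagotypes({"A": ["nope"]}, self.CLUSTERS)


class TestProtection:
    def _setup(self):
        # strains A,B share a phagotype; C differs; D has no prophages
        clusters = cluster_by_similarity(
            sim_matrix(["x1", "x2", "y1"], {("x1", "x2"): 90}), 70.0
        )
        pa = assign_phagotypes(
            {"A": ["x1"], "B": ["x2"], "C": ["y1"], "D": []}, clusters
        )
        strains = ["A", "B", "C", "D"]
        plaques = pd.DataFrame(False, index=strains, columns=strains)
        return pa, plaques

    def test_all_false_matrix(self):
        pa, plaques = self._setup()
        rep = protection_statistic(plaques, pa, n_permutations=200, seed=1)
        assert rep.within_fraction == 0.0 and rep.all_fraction == 0.0
        assert rep.permutation_p == 1.0

    def test_counts_with_equal_relation(self):
        pa, plaques = self._setup()
        plaques.loc["C", "A"] = True  # cross-phagotype attack
        rep = protection_statistic(plaques, pa, relation="equal",
                                   n_permutations=0)
        # ordered same-set pairs: (A,B),(B,A) and (D,D excluded) -> just 2
        assert (rep.within_plaquing, rep.within_total) == (0, 2)
        assert (rep.all_plaquing, rep.all_total) == (1, 12)

    def test_subset_relation_includes_empty_strain(self):
        pa, plaques = self._setup()
        rep_in = protection_statistic(plaques, pa, relation="subset_either",
                                      include_empty=True, n_permutations=0)
        rep_ex = protection_statistic(plaques, pa, relation="subset_either",
                                      include_empty=False, n_permutations=0)
        # D's empty set is a subset of every other: 6 ordered pairs involving D
        assert rep_in.within_total - rep_ex.within_total == 6

    def test_relabelling_invariance(self):
        pa, plaques = self._setup()
        plaques.loc["A", "B"] = True
        rep = protection_statistic(plaques, pa, n_permutations=0)
        ren = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        pa2 = assign_phagotypes(
            {"W": ["x1"], "X": ["x2"], "Y": ["y1"], "Z": []},
            cluster_by_similarity(
                sim_matrix(["x1", "x2", "y1"], {("x1", "x2"): 90}), 70.0),
        )
        plaques2 = plaques.rename(index=ren, columns=ren)
        rep2 = protection_statistic(plaques2, pa2, n_permutations=0)
        assert (rep.within_plaquing, rep.within_total, rep.all_plaquing,
                rep.all_total) == (rep2.within_plaquing, rep2.within_total,
                                   rep2.all_plaquing, rep2.all_total)

    def test_protected_group_gives_small_p(self):
        # 8 strains, two phagotypes; plaquing everywhere except within groups
        # (label permutations preserving the 4+4 partition: ~2.9% -> p floor)
        clusters = cluster_by_similarity(
            sim_matrix(["x1", "y1"], {}), 70.0)
        pa = assign_phagotypes(
            {s: ["x1"] for s in "ABCD"} | {s: ["y1"] for s in "EFGH"}, clusters)
        strains = list("ABCDEFGH")
        plaques = pd.DataFrame(True, index=strains, columns=strains)
        for grp in ("ABCD", "EFGH"):
            for a in grp:
                for b in grp:
                    plaques.loc[a, b] = False
        rep = protection_statistic(plaques, pa, relation="equal",
                                   n_permutations=500, seed=2)
        assert rep.within_fraction == 0.0
        assert rep.all_fraction == pytest.approx(32 / 56)
        assert rep.permutation_p < 0.06


class TestDereplication:
    SETS = {"g3": ["c1", "c2"], "g1": ["c1", "c2"], "g2": ["c3"]}

    def test_partition_by_identical_sets(self):
        groups = dereplicate_by_prophage_content(self.SETS)
        assert groups == {"g1": ["g1", "g3"], "g2": ["g2"]}

    def test_is_a_partition_and_order_invariant(self):
        reordered = dict(reversed(list(self.SETS.items())))
        assert dereplicate_by_prophage_content(reordered) == \
            dereplicate_by_prophage_content(self.SETS)
        members = [m for g in dereplicate_by_prophage_content(self.SETS).values()
                   for m in g]
        assert sorted(members) == sorted(self.SETS)

    def test_empty_sets_share_group_unless_flagged(self):
        sets = {"a": [], "b": [], "c": ["c1"]}
        assert dereplicate_by_prophage_content(sets)["a"] == ["a", "b"]
        flagged = dereplicate_by_prophage_content(sets, distinguish_empty=True)
        assert flagged["a"] == ["a"] and flagged["b"] == ["b"]


class TestAccessoryAttribution:
    def test_toy_fraction(self):
        sips = [Interval("g1", 1000, 2000, "sip1")]
        rows = []
        for i in range(10):
            # 4 accessory genes with midpoints inside the SIP, 6 outside
            start = 1100 + i * 100 if i < 4 else 5000 + i * 300
            rows.append({"genome_id": "g1", "start": start, "end": start + 90,
                         "category": "accessory"})
        rows.append({"genome_id": "g1", "start": 1200, "end": 1290,
                     "category": "core"})
        genes = pd.DataFrame(rows)
        n_in, n_tot, frac = accessory_in_sip_fraction(genes, sips)
        assert (n_in, n_tot) == (4, 10)
        assert frac == pytest.approx(0.4)

    def test_no_sips(self):
        genes = pd.DataFrame([{"genome_id": "g1", "start": 0, "end": 10,
                               "category": "accessory"}])
        assert accessory_in_sip_fraction(genes, [])[2] == 0.0

    def test_straddling_gene_counted_by_midpoint(self):
        sips = [Interval("g1", 1000, 2000, "sip1")]
        genes = pd.DataFrame([
            {"genome_id": "g1", "start": 900, "end": 1150, "category": "accessory"},
            {"genome_id": "g1", "start": 900, "end": 1050, "category": "accessory"},
        ])
        n_in, n_tot, _ = accessory_in_sip_fraction(genes, sips)
        assert (n_in, n_tot) == (1, 2)
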
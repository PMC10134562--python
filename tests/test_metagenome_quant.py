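"""Presence calling, abundance quantification, dereplication and diversity
summaries: worked examples plus homogeneity/coherence properties."""

import numpy as np
import pandas as pd
import pytest

from labbgc.gcf_clustering import ClusterAssignment
from labbgc.metagenome_quant import (
    BGCGeneModel,
    Gene,
    ReadCountTable,
    UncallableBGCError,
    abundance_matrix,
    accumulation_curve,
    bgc_abundance,
    bgc_presence,
    dereplicate_bgcs,
    niche_specificity,
    niche_taxa_crosstab,
    nucleotide_identity,
    presence_matrix,
)


def model_4genes():
    """4 biosynthetic-related genes (1 core, 3 additional) + 1 'other'."""
    return BGCGeneModel(
        "b",
        [
            Gene("core1", 1000, "biosynthetic"),
            Gene("add1", 800, "biosynthetic-additional"),
            Gene("add2", 600, "biosynthetic-additional"),
            Gene("add3", 400, "biosynthetic-additional"),
            Gene("oth1", 900, "other"),
        ],
    )


class TestPresence:
    def test_half_detected_is_absent(self):
        # exactly 50% of biosynthetic-related genes detected: "over 50%" is strict
        counts = {"core1": 5, "add1": 2, "add2": 0, "add3": 0}
        assert bgc_presence(counts, model_4genes()) is False

    def test_three_quarters_with_core_is_present(self):
        counts = {"core1": 5, "add1": 2, "add2": 1, "add3": 0}
        assert bgc_presence(counts, model_4genes()) is True

    def test_majority_without_core_is_absent(self):
        counts = {"core1": 0, "add1": 2, "add2": 1, "add3": 4}
        assert bgc_presence(counts, model_4genes()) is False

    def test_all_zero_is_absent(self):
        assert bgc_presence({}, model_4genes()) is False

    def test_other_genes_never_counted(self):
        counts = {"core1": 5, "add1": 2, "add2": 1, "oth1": 100}
        base = dict(counts)
        base["oth1"] = 0
        m = model_4genes()
        assert bgc_presence(counts, m) == bgc_presence(base, m)

    def test_no_core_gene_is_uncallable_not_absent(self):
        model = BGCGeneModel("b", [Gene("add1", 500, "biosynthetic-additional")])
        with pytest.raises(UncallableBGCError):
            bgc_presence({"add1": 10}, model)

    def test_presence_matrix_reports_uncallable(self):
        good = model_4genes()
        bad = BGCGeneModel("nocores", [Gene("x", 500, "biosynthetic-additional")])
        table = ReadCountTable(
            counts=pd.DataFrame(
                {"core1": [5], "add1": [1], "add2": [1], "add3": [0],
                 "oth1": [0], "x": [9]},
                index=["s0"],
            ),
            library_sizes=pd.Series({"s0": 1000}),
        )
        pres, uncallable = presence_matrix(table, [good, bad])
        assert uncallable == ["nocores"]
        assert pres.loc["s0", "b"] == True  # noqa: E712
        assert pd.isna(pres.loc["s0", "nocores"])


class TestAbundance:
    def test_hand_computed_value(self):
        # k=2: (10/1000 + 5/500) / (2 * 1e6) * 1e6 = 0.01
        model = BGCGeneModel(
            "b",
            [Gene("g1", 1000, "biosynthetic"), Gene("g2", 500, "biosynthetic-additional")],
        )
        value = bgc_abundance({"g1": 10, "g2": 5}, 1e6, model)
        assert value == pytest.approx(0.01, rel=1e-12)

    def test_zero_counts_give_zero(self):
        value = bgc_abundance({"g1": 0, "g2": 0}, 1e6, BGCGeneModel(
            "b", [Gene("g1", 1000, "biosynthetic"), Gene("g2", 500, "biosynthetic-additional")]
        ))
        assert value == 0.0

    def test_homogeneity_under_joint_scaling(self):
        model = model_4genes()
        counts = {"core1": 7, "add1": 3, "add2": 11, "add3": 0}
        a1 = bgc_abundance(counts, 5e5, model)
        a2 = bgc_abundance({k: 2 * v for k, v in counts.items()}, 1e6, model)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_doubling_lengths_halves_abundance(self):
        genes = [Gene("g1", 1000, "biosynthetic"), Gene("g2", 500, "biosynthetic-additional")]
        doubled = [Gene("g1", 2000, "biosynthetic"), Gene("g2", 1000, "biosynthetic-additional")]
        counts = {"g1": 10, "g2": 5}
        a1 = bgc_abundance(counts, 1e6, BGCGeneModel("b", genes))
        a2 = bgc_abundance(counts, 1e6, BGCGeneModel("b", doubled))
        assert a2 == pytest.approx(a1 / 2, rel=1e-12)

    def test_zero_library_size_raises(self):
        with pytest.raises(ValueError):
            bgc_abundance({"g1": 1}, 0, BGCGeneModel("b", [Gene("g1", 100, "biosynthetic")]))

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            bgc_abundance({}, 1e6, BGCGeneModel("b", [Gene("g1", 100, "biosynthetic")]))

    def test_presence_implies_positive_abundance(self, count_bundle):
        models, table, _ = count_bundle
        pres, _ = presence_matrix(table, models)
        abund = abundance_matrix(table, models)
        present = pres.fillna(False).astype(bool).to_numpy()
        assert (abund.to_numpy()[present] > 0).all()

    def test_recovers_planted_presence(self, count_bundle):
        models, table, truth = count_bundle
        pres, _ = presence_matrix(table, models)
        agree = (
            pres.fillna(False).astype(bool).to_numpy()
            == truth.presence_truth.to_numpy()
        )
        assert agree.mean() >= 0.99


class TestDereplication:
    def _assignment(self, ids, gcfs):
        n = len(ids)
        return ClusterAssignment(
            bgc_ids=list(ids), gcf=np.array(gcfs), gcc=np.zeros(n, dtype=int)
        )

    def test_identical_sequences_one_representative(self):
        seqs = {"a": "ACGT" * 50, "b": "ACGT" * 50}
        derep = dereplicate_bgcs(seqs, self._assignment(["a", "b"], [0, 0]))
        assert len(derep.representatives) == 1

    def test_identical_sequences_in_different_gcfs_stay_separate(self):
        seqs = {"a": "ACGT" * 50, "b": "ACGT" * 50}
        derep = dereplicate_bgcs(seqs, self._assignment(["a", "b"], [0, 1]))
        assert len(derep.representatives) == 2

    def test_greedy_longest_first_attaches_both_halves(self):
        # hub sequence; two shorter members each match one half of the hub at
        # >= 0.8 identity but diverge from each other -> one representative
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACGT"))
        hub = "".join(rng.choice(alphabet, 200))

        def mutate(seq, n_sub, seed):
            r = np.random.default_rng(seed)
            arr = np.array(list(seq))
            pos = r.choice(len(arr), n_sub, replace=False)
            for p in pos:
                arr[p] = r.choice(alphabet[alphabet != arr[p]])
            return "".join(arr)

        s1 = mutate(hub[:100], 10, 1)
        s2 = mutate(hub[100:], 10, 2)
        seqs = {"hub": hub, "s1": s1, "s2": s2}
        assert nucleotide_identity(hub, s1) >= 0.8
        assert nucleotide_identity(hub, s2) >= 0.8
        assert nucleotide_identity(s1, s2) < 0.8
        derep = dereplicate_bgcs(seqs, self._assignment(["hub", "s1", "s2"], [0, 0, 0]))
        assert derep.representatives == ["hub"]
        assert derep.member_to_rep == {"hub": "hub", "s1": "hub", "s2": "hub"}

    def test_sequence_missing_from_assignment_raises(self):
        with pytest.raises(KeyError):
            dereplicate_bgcs({"zzz": "ACGT"}, self._assignment(["a"], [0]))


class TestDiversitySummaries:
    def _presence(self):
        pres = pd.DataFrame(
            {
                "g0": [True, True, True, True],
                "g1": [True, False, False, False],
                "g2": [False, False, True, True],
            },
            index=["s0", "s1", "s2", "s3"],
        )
        sites = pd.Series(["oral", "oral", "gut", "gut"], index=pres.index)
        return pres, sites

    def test_flat_curve_for_single_shared_gcf(self):
        pres = pd.DataFrame({"g0": [True] * 5}, index=[f"s{i}" for i in range(5)])
        sites = pd.Series(["x"] * 5, index=pres.index)
        curve = accumulation_curve(pres, sites, n_permutations=20, seed=0)
        assert (curve["mean_gcfs"] == 1.0).all()
        assert (curve["sd_gcfs"] == 0.0).all()

    def test_identity_line_for_unique_contributions(self):
        m = 6
        pres = pd.DataFrame(np.eye(m, dtype=bool), index=[f"s{i}" for i in range(m)],
                            columns=[f"g{i}" for i in range(m)])
        sites = pd.Series(["x"] * m, index=pres.index)
        curve = accumulation_curve(pres, sites, n_permutations=10, seed=1)
        assert curve["mean_gcfs"].tolist() == list(range(1, m + 1))

    def test_endpoint_equals_union_cardinality(self):
        rng = np.random.default_rng(5)
        pres = pd.DataFrame(
            rng.random((8, 10)) < 0.3,
            index=[f"s{i}" for i in range(8)],
            columns=[f"g{i}" for i in range(10)],
        )
        sites = pd.Series(["a"] * 4 + ["b"] * 4, index=pres.index)
        for n_perm, seed in ((1, 0), (7, 3), (25, 9)):
            curve = accumulation_curve(pres, sites, n_permutations=n_perm, seed=seed)
            for site in ("a", "b"):
                sub = curve[curve["site"] == site]
                union = pres.loc[sites == site].any().sum()
                final = sub.loc[sub["n_samples"].idxmax()]
                assert final["mean_gcfs"] == union
                assert final["sd_gcfs"] == 0.0
                assert (sub["mean_gcfs"].diff().dropna() >= 0).all()

    def test_niche_specificity_flags(self):
        pres, sites = self._presence()
        niche = niche_specificity(pres, sites)
        assert niche.loc["g0", "n_sites"] == 2 and not niche.loc["g0", "niche_specific"]
        assert niche.loc["g1", "niche_specific"]
        assert niche.loc["g2", "niche_specific"]

    def test_single_site_share_reporting(self):
        # 610 detected families, 317 in exactly one site -> 52.0%
        n_sites = pd.Series([1] * 317 + [2] * 293)
        share = round(100 * (n_sites == 1).mean(), 1)
        assert share == 52.0

    def test_crosstab_counts(self):
        niche = pd.Series({"g0": True, "g1": True, "g2": False, "g3": False})
        taxa = pd.Series({"g0": True, "g1": False, "g2": True, "g3": False})
        table = niche_taxa_crosstab(niche, taxa)
        assert table.tolist() == [[1, 1], [1, 1]]
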
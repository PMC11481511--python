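"""Host range over STs, allelic distances, geography, Tukey fences."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paraphage.cluster import SpeciesPartition
from paraphage.epi import (
    StProfile,
    geo_dispersion,
    host_range,
    hybrid_host_species,
    mean_pairwise_allelic_distance,
    species_st_matrix,
    species_summary,
    st_allelic_distance,
    tukey_fences,
)
from paraphage.errors import JoinError, ParameterError


def _meta(rows):
    cols = ["genome_id", "st", "host", "country"]
    base = pd.DataFrame(rows, columns=cols)
    for i in range(1, 8):
        base[f"allele_{i}"] = 1
    return base


META = _meta(
    [
        ("g1", "ST2", "human", "MX"),
        ("g2", "ST2", "human", "MX"),
        ("g3", "ST2", "animal", "US"),
        ("g4", "ST1", "human", "FR"),
        ("g5", "ST10", "plant", "MX"),
        ("g6", "ST79", "human", None),
        ("g7", None, "human", "US"),
    ]
)


class TestHostRange:
    def test_single_st_species(self):
        part = SpeciesPartition(species={"s1": ["p1", "p2", "p3"]})
        pg = {"p1": "g1", "p2": "g2", "p3": "g3"}
        hr = host_range(part, pg, META)
        assert hr.loc["s1", "n_sts"] == 1
        assert hr.loc["s1", "n_members"] == 3

    def test_multi_st_species(self):
        part = SpeciesPartition(species={"s1": ["p1", "p2", "p3"]})
        pg = {"p1": "g1", "p2": "g4", "p3": "g6"}
        hr = host_range(part, pg, META)
        assert hr.loc["s1", "n_sts"] == 3
        assert set(hr.loc["s1", "sts"].split(",")) == {"ST1", "ST2", "ST79"}

    def test_unassigned_species_flagged(self):
        part = SpeciesPartition(species={"s1": ["p1"]})
        hr = host_range(part, {"p1": "g7"}, META)
        assert bool(hr.loc["s1", "unassigned"]) is True
        assert hr.loc["s1", "n_sts"] == 0

    def test_counts_exclude_members_without_st(self):
        part = SpeciesPartition(species={"s1": ["p1", "p2"]})
        hr = host_range(part, {"p1": "g1", "p2": "g7"}, META)
        assert hr.loc["s1", "n_members"] == 2
        assert hr.loc["s1", "n_members_with_st"] == 1
        assert hr.loc["s1", "n_sts"] <= hr.loc["s1", "n_members_with_st"]

    def test_unknown_genome_is_join_error(self):
        part = SpeciesPartition(species={"s1": ["p1"]})
        with pytest.raises(JoinError, match="gX"):
            host_range(part, {"p1": "gX"}, META)


class TestAllelicDistance:
    def test_identical_profiles(self):
        a = StProfile("ST1", (1, 1, 1, 1, 1, 1, 1))
        assert st_allelic_distance(a, a) == 0

    def test_all_loci_differ(self):
        a = StProfile("ST1", (1, 1, 1, 1, 1, 1, 1))
        b = StProfile("ST2", (2, 2, 2, 2, 2, 2, 2))
        assert st_allelic_distance(a, b) == 7

    def test_three_loci_differ(self):
        a = StProfile("ST1", (1, 1, 1, 1, 1, 1, 1))
        b = StProfile("ST2", (1, 2, 1, 3, 1, 1, 4))
        assert st_allelic_distance(a, b) == 3

    def test_missing_locus_excluded_and_reported(self):
        a = StProfile("ST1", (1, None, 1, 1, 1, 1, 1))
        b = StProfile("ST2", (1, 9, 2, 1, 1, 1, 1))
        dist, excluded = st_allelic_distance(a, b, with_excluded=True)
        assert dist == 1
        assert excluded == [1]

    def test_profile_needs_seven_loci(self):
        with pytest.raises(ParameterError):
            StProfile("STX", (1, 2, 3))

    @given(
        st.tuples(*[st.integers(min_value=1, max_value=5)] * 7),
        st.tuples(*[st.integers(min_value=1, max_value=5)] * 7),
        st.tuples(*[st.integers(min_value=1, max_value=5)] * 7),
    )
    @settings(max_examples=60, derandomize=True)
    def test_metric_axioms(self, pa, pb, pc):
        a, b, c = (StProfile(f"ST{i}", p) for i, p in enumerate((pa, pb, pc)))
        dab = st_allelic_distance(a, b)
        assert dab == st_allelic_distance(b, a)
        assert (dab == 0) == (pa == pb)
        assert dab <= st_allelic_distance(a, c) + st_allelic_distance(c, b)

    def test_mean_pairwise(self):
        profiles = {
            "ST1": StProfile("ST1", (1, 1, 1, 1, 1, 1, 1)),
            "ST2": StProfile("ST2", (2, 2, 1, 1, 1, 1, 1)),
            "ST3": StProfile("ST3", (2, 2, 2, 2, 1, 1, 1)),
        }
        # d(1,2)=2, d(1,3)=4, d(2,3)=2 -> mean 8/3
        mean = mean_pairwise_allelic_distance(["ST1", "ST2", "ST3"], profiles)
        assert mean == pytest.approx(8 / 3)
        assert mean_pairwise_allelic_distance(["ST1"], profiles) is None


class TestGeoDispersion:
    def test_country_counts(self):
        part = SpeciesPartition(
            species={"s1": ["p1", "p2"], "s2": ["p3", "p4", "p5"], "s3": ["p6"]}
        )
        pg = {"p1": "g1", "p2": "g2", "p3": "g3", "p4": "g4", "p5": "g5",
              "p6": "g6"}
        geo = geo_dispersion(part, pg, META)
        assert geo.loc["s1", "n_countries"] == 1
        assert set(geo.loc["s2", "countries"].split(",")) == {"US", "FR", "MX"}
        # g6 has no country: excluded from the set, noted in the count column
        assert geo.loc["s3", "n_countries"] == 0
        assert geo.loc["s3", "n_members_with_country"] == 0


class TestTukeyFences:
    def test_constant_values_have_no_outliers(self):
        f = tukey_fences([1, 1, 1, 1])
        assert f.iqr == 0 and f.upper == 1 and f.outliers == ()

    def test_hand_computed_hinges(self):
        # sorted [1,1,1,2,2,3,20]: lower hinge 1, upper hinge 2.5, upper
        # fence 2.5 + 1.5*1.5 = 4.75 -> 20 is the only outlier
        f = tukey_fences([1, 1, 1, 2, 2, 3, 20])
        assert (f.q1, f.q3) == (1.0, 2.5)
        assert f.upper == pytest.approx(4.75)
        assert f.outliers == (20.0,)

    def test_singleton_list(self):
        f = tukey_fences([5])
        assert (f.q1, f.q3, f.outliers) == (5.0, 5.0, ())

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            tukey_fences([])


class TestHybridHostSpecies:
    def test_single_host_species_excluded(self):
        part = SpeciesPartition(species={"s1": ["p1", "p2"]})
        out = hybrid_host_species(part, {"p1": "g1", "p2": "g2"}, META)
        assert out.empty

    def test_cross_host_breakdown(self):
        """A large human species with one plant-isolate member is a hybrid
        with breakdown {human: n-1, plant: 1}."""
        members = [f"p{i}" for i in range(5)]
        part = SpeciesPartition(species={"s1": members})
        pg = {p: "g1" for p in members[:-1]}
        pg[members[-1]] = "g5"  # plant isolate
        meta = _meta([("g1", "ST2", "human", "MX"), ("g5", "ST10", "plant", "MX")])
        out = hybrid_host_species(part, pg, meta)
        assert out.loc["s1", "human"] == 4
        assert out.loc["s1", "plant"] == 1
        assert out.loc["s1", "animal"] == 0


class TestSyntheticStructure:
    def test_narrow_species_have_one_st_and_cosmopolitan_their_spread(
        self, small_community
    ):
        truth = small_community.truth
        st_sets = truth.species_st_sets()
        cfg = small_community.config
        sizes = {
            sp: sum(1 for s, _ in truth.prophages.values() if s == sp)
            for sp in st_sets
        }
        cosmo = [f"S{i + 1:03d}" for i in range(len(cfg.cosmopolitan_sizes))]
        for sp, sts in st_sets.items():
            if sp in cosmo:
                expected = cfg.cosmopolitan_st_spread[cosmo.index(sp)]
                assert len(sts) == expected
            else:
                assert len(sts) == 1, f"narrow species {sp} spans {sts}"

    def test_species_summary_and_st_matrix_consistent(self, small_community,
                                                      small_partition):
        com = small_community
        pg = {pid: gid for pid, (_, gid) in com.truth.prophages.items()}
        tbl = species_summary(small_partition, pg, com.metadata)
        assert len(tbl) == small_partition.n_species
        assert (tbl["n_sts"] <= tbl["n_members_with_st"]).all()
        mat = species_st_matrix(small_partition, pg, com.metadata)
        for sp in mat.index:
            assert mat.loc[sp].sum() == tbl.loc[sp, "n_sts"]

    def test_median_countries_robust_to_dropping_singletons(self):
        """On the default community shape (many singletons, geographically
        confined lineages) the median per-species country count is the same
        whether or not singleton species are included — the robustness that
        justifies keeping singletons in dispersion summaries."""
        from paraphage.synth import SimConfig, generate_community

        com = generate_community(SimConfig(seed=1))
        truth_part = SpeciesPartition(
            species={
                sp: sorted(
                    p for p, (s, _) in com.truth.prophages.items() if s == sp
                )
                for sp in {s for s, _ in com.truth.prophages.values()}
            }
        )
        pg = {pid: gid for pid, (_, gid) in com.truth.prophages.items()}
        geo = geo_dispersion(truth_part, pg, com.metadata)
        sizes = {sp: len(m) for sp, m in truth_part.species.items()}
        all_counts = geo["n_countries"]
        proper = geo.loc[[sp for sp in geo.index if sizes[sp] > 1], "n_countries"]
        assert all_counts.median() == proper.median()
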
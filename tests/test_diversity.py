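import itertools

import numpy as np
import pytest

from gad.clustering import Cluster, TieredClusterSet, occupancy_classes, tiered_cluster
from gad.diversity import (
    conservative_lower_bound,
    environment_assignment,
    novelty_scores,
    rarefaction,
    sotu_sample_abundance,
    sotus_by_sample,
    taxon_summary,
)
from gad.io_formats import SeqRecord, TaxonomyLabel
from gad.region_prep import dereplicate


def tiny_tiered(sotu_to_gotu):
    """A TieredClusterSet skeleton where each SOTU is its own cluster."""
    species = [
        Cluster(s, [s], "species", 1, frozenset({"s"})) for s in sotu_to_gotu
    ]
    gotus = sorted(set(sotu_to_gotu.values()))
    genus = [
        Cluster(
            g,
            sorted({s for s, gg in sotu_to_gotu.items() if gg == g} | {g}),
            "genus", 1, frozenset({"s"}),
        )
        for g in gotus
    ]
    family = [Cluster(g, [g], "family", 1, frozenset({"s"})) for g in gotus]
    return TieredClusterSet(
        species, genus, family, dict(sotu_to_gotu), {g: g for g in gotus}
    )


class TestConservativeLowerBound:
    def test_worked_example(self):
        """sample1 has A(10), B(5) in one GOTU; sample2 has B(7): A wins
        sample1, B wins sample2 -> both kept."""
        tiered = tiny_tiered({"A": "A", "B": "A"})
        prov = {"A": {"sample1": 10}, "B": {"sample1": 5, "sample2": 7}}
        count, kept = conservative_lower_bound(tiered, prov)
        assert count == 2 and kept == {"A", "B"}

    def test_suppression_within_sample(self):
        tiered = tiny_tiered({"A": "A", "B": "A"})
        prov = {"A": {"s1": 10}, "B": {"s1": 5}}
        count, kept = conservative_lower_bound(tiered, prov)
        assert count == 1 and kept == {"A"}

    def test_abundance_tie_breaks_to_smaller_id(self):
        tiered = tiny_tiered({"A": "A", "B": "A"})
        prov = {"B": {"s1": 5}, "A": {"s1": 5}}
        _, kept = conservative_lower_bound(tiered, prov)
        assert kept == {"A"}

    def test_vacuous_when_one_sotu_per_gotu(self):
        tiered = tiny_tiered({"A": "A", "B": "B", "C": "C"})
        prov = {"A": {"s1": 1}, "B": {"s1": 2}, "C": {"s2": 3}}
        count, _ = conservative_lower_bound(tiered, prov)
        assert count == 3

    def test_bracketed_by_gotus_and_sotus(self, noise_free_study):
        _, (db, records, prov, meta, targets, truth) = noise_free_study
        recs = dereplicate(records)
        tiered = tiered_cluster(recs)
        abundance = sotu_sample_abundance(tiered, recs)
        count, kept = conservative_lower_bound(tiered, abundance)
        occupied_gotus = {
            tiered.sotu_to_gotu[s] for s, per in abundance.items() if per
        }
        assert len(occupied_gotus) <= count <= len(tiered.species_clusters)
        assert kept <= set(abundance)


class TestRarefaction:
    def test_two_sample_worked_example(self):
        """{s1:{A,B}, s2:{B,C}}: either order gives 2 then 3; the final
        sample always adds exactly one SOTU."""
        res = rarefaction({"s1": {"A", "B"}, "s2": {"B", "C"}}, R=8, seed=0)
        assert res.mean_curve == [2.0, 3.0]
        assert res.d_sotu == 1.0

    def test_single_sample(self):
        res = rarefaction({"s1": {"A", "B", "C"}}, R=5, seed=1)
        assert res.mean_curve == [3.0] and res.d_sotu == 3.0

    def test_disjoint_singleton_samples(self):
        res = rarefaction({f"s{i}": {f"X{i}"} for i in range(6)}, R=4, seed=2)
        assert res.d_sotu == 1.0
        assert res.mean_curve == [float(k) for k in range(1, 7)]

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            rarefaction({})

    def test_monotone_with_permutation_invariant_endpoint(self):
        rng = np.random.default_rng(9)
        universe = [f"X{i}" for i in range(40)]
        by_sample = {
            f"s{i}": set(rng.choice(universe, size=rng.integers(1, 12)))
            for i in range(10)
        }
        res = rarefaction(by_sample, R=7, seed=3)
        assert all(a <= b for a, b in itertools.pairwise(res.mean_curve))
        total = len(set().union(*by_sample.values()))
        assert res.mean_curve[-1] == float(total)
        assert res.d_sotu >= 0.0


class TestNoveltyScores:
    def _tiered_with_samples(self, level_samples):
        def clusters(level, sample_sets):
            return [
                Cluster(f"{level}{i}", [f"{level}{i}"], level, 1, frozenset(ss))
                for i, ss in enumerate(sample_sets)
            ]

        species, genus, family = (
            clusters("s", level_samples["species"]),
            clusters("g", level_samples["genus"]),
            clusters("f", level_samples["family"]),
        )
        return TieredClusterSet(
            species, genus, family,
            {c.centroid_id: genus[0].centroid_id for c in species},
            {c.centroid_id: family[0].centroid_id for c in genus},
        )

    def test_counts_divided_by_sample_count(self):
        meta = {f"h{i}": "host" for i in range(4)}
        tiered = self._tiered_with_samples(
            {
                "species": [{"h1"}] * 8,
                "genus": [{"h1", "h2"}] * 6,
                "family": [{"h3"}] * 2,
            }
        )
        (score,) = novelty_scores(tiered, meta)
        assert (score.sotu_score, score.gotu_score, score.fotu_score) == (
            2.0, 1.5, 0.5,
        )

    def test_shared_clusters_count_in_both_environments(self):
        meta = {"h1": "host", "h2": "host", "p1": "plant"}
        tiered = self._tiered_with_samples(
            {
                "species": [{"h1", "p1"}, {"h2", "p1"}],
                "genus": [{"h1", "p1"}],
                "family": [{"h1", "p1"}],
            }
        )
        by_env = {s.environment: s for s in novelty_scores(tiered, meta)}
        assert by_env["host"].sotu_score == 1.0  # 2 clusters / 2 samples
        assert by_env["plant"].sotu_score == 2.0  # same 2 clusters / 1 sample

    def test_nesting_inequality_on_synthetic_run(self, noise_free_study):
        _, (db, records, prov, meta, targets, truth) = noise_free_study
        tiered = tiered_cluster(dereplicate(records))
        for s in novelty_scores(tiered, meta):
            assert s.sotu_score >= s.gotu_score >= s.fotu_score

    def test_planted_novel_environment_ranks_first(self, noise_free_study):
        """The generator gives saline_water the largest exclusive species
        pool; its novelty score must lead at every level."""
        _, (db, records, prov, meta, targets, truth) = noise_free_study
        tiered = tiered_cluster(dereplicate(records))
        scores = {s.environment: s for s in novelty_scores(tiered, meta)}
        others = [e for e in scores if e != "saline_water"]
        assert all(
            scores["saline_water"].sotu_score > scores[e].sotu_score for e in others
        )
        assert all(
            scores["saline_water"].gotu_score >= scores[e].gotu_score for e in others
        )
        assert all(
            scores["saline_water"].fotu_score >= scores[e].fotu_score for e in others
        )


class TestEnvironmentAssignment:
    def _cluster(self, members):
        return Cluster("c", list(members), "species", 1, frozenset({"s"}))

    def test_unanimous(self):
        meta = {"s1": "soil", "s2": "soil"}
        prov = {"a": {"s1": 5}, "b": {"s2": 2}}
        assert environment_assignment(
            self._cluster(["c", "a", "b"]), {**prov, "c": {"s1": 1}}, meta
        ) == ("soil", "soil")

    def test_abundance_vs_majority_disagreement(self):
        meta = {"w": "saline_water", "s1": "soil", "s2": "soil", "s3": "soil"}
        prov = {
            "c": {"w": 100},
            "a": {"s1": 1},
            "b": {"s2": 1},
            "d": {"s3": 1},
        }
        got = environment_assignment(self._cluster(["c", "a", "b", "d"]), prov, meta)
        assert got == ("saline_water", "soil")

    def test_majority_tie_alphabetical(self):
        meta = {"f1": "freshwater", "f2": "freshwater", "s1": "soil", "s2": "soil"}
        prov = {"c": {"f1": 1}, "a": {"f2": 1}, "b": {"s1": 9}, "d": {"s2": 9}}
        _, by_majority = environment_assignment(
            self._cluster(["c", "a", "b", "d"]), prov, meta
        )
        assert by_majority == "freshwater"


class TestTaxonSummary:
    def _label(self, fam, gen, sp):
        return TaxonomyLabel.from_ranks(
            {"domain": "Archaea", "phylum": "P", "class": "C", "order": "O",
             "family": fam, "genus": gen, "species": sp}
        )

    def test_sotu_rate(self):
        # ten sequences collapsing into two SOTUs -> rate 0.2
        sotu_map = {f"q{i}": ("A" if i < 5 else "B") for i in range(10)}
        species = [
            Cluster("A", [q for q, s in sotu_map.items() if s == "A"] + ["A"],
                    "species", 1, frozenset({"s"})),
            Cluster("B", [q for q, s in sotu_map.items() if s == "B"] + ["B"],
                    "species", 1, frozenset({"s"})),
        ]
        tiered = TieredClusterSet(
            species,
            [Cluster("A", ["A", "B"], "genus", 1, frozenset({"s"}))],
            [Cluster("A", ["A"], "family", 1, frozenset({"s"}))],
            {"A": "A", "B": "A"},
            {"A": "A"},
        )
        taxonomy = {
            q: self._label("Fam1", "Gen1", "Sp1") for q in list(sotu_map) + ["A", "B"]
        }
        rows = taxon_summary(tiered, taxonomy)
        fam_row = next(r for r in rows if r["rank"] == "family")
        assert fam_row["n_sequences"] == 12 and fam_row["n_sotus"] == 2
        genus_rows = [r for r in rows if r["rank"] == "genus"]
        assert genus_rows[0]["sotu_rate"] == pytest.approx(2 / 12)
        assert all(0 < r["sotu_rate"] <= 1 for r in rows)

    def test_rate_one_when_every_sequence_its_own_sotu(self):
        species = [
            Cluster(q, [q], "species", 1, frozenset({"s"})) for q in ("a", "b")
        ]
        tiered = TieredClusterSet(
            species,
            [Cluster("a", ["a", "b"], "genus", 1, frozenset({"s"}))],
            [Cluster("a", ["a"], "family", 1, frozenset({"s"}))],
            {"a": "a", "b": "a"},
            {"a": "a"},
        )
        taxonomy = {q: self._label("F", "G", f"S{q}") for q in ("a", "b")}
        rows = taxon_summary(tiered, taxonomy)
        fam = next(r for r in rows if r["rank"] == "family")
        assert fam["sotu_rate"] == 1.0


def test_sotus_by_sample_consistency(noise_free_study):
    _, (db, records, prov, meta, targets, truth) = noise_free_study
    recs = dereplicate(records)
    tiered = tiered_cluster(recs)
    by_sample = sotus_by_sample(tiered, recs)
    assert set(by_sample) <= set(meta)
    total = len({s for ss in by_sample.values() for s in ss})
    assert total == len(tiered.species_clusters)
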
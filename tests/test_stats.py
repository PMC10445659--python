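"""Association tables, population summaries, feature matrix, embedding, dendrogram."""

import numpy as np
import pandas as pd
import pytest

from astromorph import stats
from astromorph.synthetic import (
    sample_annotation_cohort,
    sample_contact_cohort,
    sample_morphology_populations,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["cell_id", "motif", "axon", "soma", "astrocyte"])


class TestMotifProbabilities:
    def test_direct_count_example(self):
        rows = [(i, "sail", i < 6, False, False) for i in range(10)]
        out = stats.motif_structure_probabilities(make_table(rows))
        assert out.loc[out.motif == "sail", "p_axon"].item() == 60.0
        assert out.loc[out.motif == "sail", "n"].item() == 10

    def test_nonexclusive_flags_can_sum_past_100(self):
        rows = [(i, "bead", True, True, True) for i in range(5)]
        out = stats.motif_structure_probabilities(make_table(rows))
        row = out[out.motif == "bead"].iloc[0]
        assert row.p_axon == row.p_soma == row.p_astro == 100.0

    def test_probabilities_match_counting_oracle_exactly(self, rng):
        motifs = np.array(stats.MOTIFS)
        rows = [
            (
                i,
                rng.choice(motifs),
                bool(rng.random() < 0.5),
                bool(rng.random() < 0.3),
                bool(rng.random() < 0.1),
            )
            for i in range(200)
        ]
        table = make_table(rows)
        out = stats.motif_structure_probabilities(table)
        for _, row in out.iterrows():
            sub = [r for r in rows if r[1] == row.motif]
            assert row.n == len(sub)
            assert row.p_axon == 100.0 * sum(r[2] for r in sub) / len(sub)
            assert row.p_soma == 100.0 * sum(r[3] for r in sub) / len(sub)
            assert row.p_astro == 100.0 * sum(r[4] for r in sub) / len(sub)
            # exact rational counts: p*n/100 integral
            for p in (row.p_axon, row.p_soma, row.p_astro):
                assert (p * row.n / 100.0) == pytest.approx(round(p * row.n / 100.0))

    def test_missing_motifs_omitted(self):
        rows = [(0, "sail", True, False, False)]
        out = stats.motif_structure_probabilities(make_table(rows))
        assert list(out.motif) == ["sail"]

    def test_error_methods_labelled(self):
        rows = [(i, "pad", i % 2 == 0, False, False) for i in range(8)]
        b = stats.motif_structure_probabilities(make_table(rows), error="binomial")
        w = stats.motif_structure_probabilities(make_table(rows), error="wilson")
        assert b.attrs["error_method"] == "binomial"
        assert w.attrs["error_method"] == "wilson"
        assert b["error"].item() != w["error"].item()

    def test_cell_level_denominator_collapses_instances(self):
        rows = [(0, "sail", True, False, False), (0, "sail", False, True, False)]
        inst = stats.motif_structure_probabilities(make_table(rows))
        cell = stats.motif_structure_probabilities(make_table(rows), denominator="cell")
        assert inst[inst.motif == "sail"].n.item() == 2
        assert cell[cell.motif == "sail"].n.item() == 1
        assert cell[cell.motif == "sail"].p_axon.item() == 100.0


class TestPopulationSummaries:
    def test_closed_form_mean_and_sem(self):
        records = pd.DataFrame({"n_unique_vessels": [1, 2, 3, 4]})
        s = stats.population_summaries(records)
        assert s.mean_unique_contacts == 2.5
        assert s.sem_unique_contacts == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)
        assert s.pct_contacting_vessel == 100.0
        assert sum(s.contact_distribution.values()) == 4

    def test_planted_cohort_mean_recovered(self):
        cohort = sample_contact_cohort(n_cells=1000, mean_unique_contacts=2.6, seed=1)
        s = stats.population_summaries(cohort)
        assert abs(s.mean_unique_contacts - 2.6) <= 2 * s.sem_unique_contacts + 1e-9
        assert s.pct_contacting_vessel == 100.0
        assert s.pct_contacting_neuron >= s.pct_contacting_axon

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            stats.population_summaries(pd.DataFrame())


class TestFeatureMatrix:
    def test_single_complete_record(self):
        df = pd.DataFrame([dict.fromkeys(stats.FEATURE_COLUMNS, 1.0)], index=["c0"])
        mat = stats.build_feature_matrix(df)
        assert mat.shape == (1, 20)
        assert list(mat.columns) == list(stats.FEATURE_COLUMNS)

    def test_missing_column_named_in_error(self):
        cols = dict.fromkeys(stats.FEATURE_COLUMNS, 1.0)
        cols.pop("longitude_rad")
        with pytest.raises(KeyError, match="longitude_rad"):
            stats.build_feature_matrix(pd.DataFrame([cols]))

    def test_missing_value_names_cell_and_column(self):
        row = dict.fromkeys(stats.FEATURE_COLUMNS, 1.0)
        row["pct_gfap"] = np.nan
        with pytest.raises(ValueError, match="pct_gfap"):
            stats.build_feature_matrix(pd.DataFrame([row], index=["cell7"]))


class TestEmbedCluster:
    def test_well_separated_populations_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        matrix, labels = sample_morphology_populations(n=300, seed=0)
        emb, found, meta = stats.embed_cluster(matrix, seed=0)
        mask = found >= 0
        assert mask.mean() > 0.5
        n_clusters = len(set(found[mask]))
        assert n_clusters >= 2
        assert adjusted_rand_score(labels[mask], found[mask]) >= 0.8
        assert meta["n_neighbors"] == 15

    def test_fixed_seed_reproducible(self):
        matrix, _ = sample_morphology_populations(n=120, seed=3)
        e1, l1, _ = stats.embed_cluster(matrix, seed=42)
        e2, l2, _ = stats.embed_cluster(matrix, seed=42)
        assert np.array_equal(e1, e2)
        assert np.array_equal(l1, l2)

    def test_too_few_rows_rejected(self):
        matrix, _ = sample_morphology_populations(n=10, seed=0)
        with pytest.raises(ValueError, match="rows"):
            stats.embed_cluster(matrix, seed=0)


class TestCorrelationDendrogram:
    def test_perfectly_correlated_pair_merges_first(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {"a": x, "b": 2 * x + 1, "c": rng.normal(size=200), "d": rng.normal(size=200)}
        )
        Z, order, newick = stats.correlation_dendrogram(df)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)
        first = {int(Z[0, 0]), int(Z[0, 1])}
        assert first == {0, 1}
        assert newick.endswith(";") and "a" in newick

    def test_independent_features_weakly_correlated(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        corr = df.corr().to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.1
        Z, order, _ = stats.correlation_dendrogram(df)
        assert sorted(order) == list("abcde")

    def test_linkage_matches_brute_force_agglomeration(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        Z, _, _ = stats.correlation_dendrogram(df)
        # naive average-linkage oracle on 1 - |r|
        dist = 1 - np.abs(df.corr().to_numpy())
        clusters = {i: [i] for i in range(5)}
        heights = []
        next_id = 5
        while len(clusters) > 1:
            keys = sorted(clusters)
            best = None
            for ai in range(len(keys)):
                for bi in range(ai + 1, len(keys)):
                    a, b = keys[ai], keys[bi]
                    d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                    if best is None or d < best[0] - 1e-15:
                        best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[next_id] = clusters.pop(a) + clusters.pop(b)
            next_id += 1
        assert np.allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-9)

    def test_zero_variance_column_excluded_with_warning(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        df["e"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            _, order, _ = stats.correlation_dendrogram(df)
        assert "e" not in order
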
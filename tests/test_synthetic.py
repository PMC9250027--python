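import json

import numpy as np
import pandas as pd
import pytest

from cysttea.enrichment import run_enrichment, select_query
from cysttea.errors import ConfigurationError
from cysttea.reference_library import build_ihc_reference, filter_promiscuous
from cysttea.synthetic import (
    SyntheticTruth,
    gen_ms_table,
    gen_reference,
    gen_timeline,
    generate_preset,
    simulate_experiment,
)
from cysttea.timeline import pearson_corr


class TestReferenceGenerator:
    def test_same_seed_reproduces_identical_tables(self):
        a1, l1 = gen_reference(5, 300, 20, 0.2, seed=7)
        a2, l2 = gen_reference(5, 300, 20, 0.2, seed=7)
        pd.testing.assert_frame_equal(a1.rows, a2.rows)
        assert dict(l1.tissues) == dict(l2.tissues)

    def test_default_ihc_reconstruction_equals_truth(self):
        annotations, truth_library = gen_reference(6, 400, 25, 0.25, seed=3)
        rebuilt = build_ihc_reference(annotations)
        assert dict(rebuilt.tissues) == dict(truth_library.tissues)

    def test_zero_overlap_makes_promiscuity_filter_identity(self):
        _, library = gen_reference(5, 300, 20, 0.0, seed=1)
        filtered = filter_promiscuous(library, 2)
        assert dict(filtered.tissues) == dict(library.tissues)

    def test_overlap_plants_triple_tissue_proteins_removed_by_filter(self):
        _, library = gen_reference(6, 400, 30, 0.3, seed=5)
        counts = library.tissue_counts()
        assert max(counts.values()) == 3  # triples planted
        filtered = filter_promiscuous(library, 2)
        assert max(filtered.tissue_counts().values()) <= 2

    def test_every_tissue_set_has_requested_size(self):
        _, library = gen_reference(5, 300, 20, 0.2, seed=2)
        assert all(len(s) == 20 for s in library.tissues.values())

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_reference(10, 50, 20, 0.0, seed=0)


class TestMSTableGenerator:
    def test_same_seed_identical_table(self):
        _, library = gen_reference(5, 300, 20, 0.2, seed=7)
        truth = SyntheticTruth(
            planted_tissue="tissue_00", effect_fraction=0.5, n_proteins=300,
            n_tissues=5, set_size=20, overlap_rate=0.2, percentile_q=98.0, seed=7,
        )
        t1, k1 = gen_ms_table(truth, library)
        t2, k2 = gen_ms_table(truth, library)
        assert t1 == t2 and k1 == k2

    def test_planted_overlap_is_exact(self):
        table, library, _, truth = simulate_experiment(9)
        n_query = len(select_query(table, "W7", truth.percentile_q))
        assert truth.realized_overlap == round(truth.effect_fraction * n_query)
        query = select_query(table, "W7", truth.percentile_q)
        planted = library.tissues[truth.planted_tissue]
        assert len(query.proteins & planted) == truth.realized_overlap

    def test_null_overlap_matches_hypergeometric_mean(self):
        # with no planted effect the top band is a uniform random subset,
        # so the tracked-tissue overlap is hypergeometric with mean n*M/N
        _, library = gen_reference(20, 2000, 100, 0.2, seed=0)
        overlaps = []
        for seed in range(500):
            truth = SyntheticTruth(
                planted_tissue="tissue_00", effect_fraction=0.0, n_proteins=2000,
                n_tissues=20, set_size=100, overlap_rate=0.2, percentile_q=98.0,
                seed=seed,
            )
            _, k = gen_ms_table(truth, library)
            overlaps.append(k)
        n, M, N = 41, 100, 2000
        expected = n * M / N  # 2.05
        sd = np.sqrt(n * (M / N) * (1 - M / N) * (N - n) / (N - 1))
        assert np.mean(overlaps) == pytest.approx(expected, abs=4 * sd / np.sqrt(500))

    def test_recovery_ranks_planted_tissue_first(self):
        table, library, _, truth = simulate_experiment(4)
        query = select_query(table, "W7", truth.percentile_q)
        universe = frozenset(table.detected("W7").index.astype(str))
        records = run_enrichment(query, library, universe)
        assert records[0].tissue == truth.planted_tissue
        assert records[0].p_adj < 0.05

    def test_infeasible_effect_rejected(self):
        _, library = gen_reference(5, 300, 3, 0.0, seed=7)
        truth = SyntheticTruth(
            planted_tissue="tissue_00", effect_fraction=1.0, n_proteins=300,
            n_tissues=5, set_size=3, overlap_rate=0.0, percentile_q=98.0, seed=7,
        )
        with pytest.raises(ConfigurationError):
            gen_ms_table(truth, library)

    def test_dropout_introduces_missing_cells(self):
        _, library = gen_reference(5, 300, 20, 0.0, seed=7)
        truth = SyntheticTruth(
            planted_tissue=None, effect_fraction=0.0, n_proteins=300,
            n_tissues=5, set_size=20, overlap_rate=0.0, percentile_q=98.0, seed=7,
        )
        table, _ = gen_ms_table(truth, library, dropout=0.2)
        assert len(table) < 600


class TestTimelineGenerator:
    def test_noiseless_positive_slope_gives_r_one(self):
        data, truth_r = gen_timeline(n=12, slope=2.0, noise_sd=0.0, seed=1)
        assert truth_r == pytest.approx(1.0)
        assert pearson_corr(data).r == pytest.approx(1.0)

    def test_null_slope_keeps_r_small_in_most_seeds(self):
        small = sum(
            abs(pearson_corr(gen_timeline(1000, 0.0, 5.0, seed=s, intercept=50.0)[0]).r)
            < 0.1
            for s in range(100)
        )
        assert small >= 95

    def test_same_seed_identical(self):
        d1, _ = gen_timeline(10, 1.0, 2.0, seed=3)
        d2, _ = gen_timeline(10, 1.0, 2.0, seed=3)
        assert np.array_equal(d1.x, d2.x) and np.array_equal(d1.y, d2.y)


class TestTruthAndPresets:
    def test_truth_json_round_trip(self, tmp_path):
        _, _, _, truth = simulate_experiment(
            2, n_proteins=500, n_tissues=8, set_size=30
        )
        path = truth.to_json(tmp_path / "truth.json")
        assert SyntheticTruth.from_json(path) == truth

    def test_preset_files_written(self, tmp_path):
        generate_preset("recovery", 1, out_dir=tmp_path / "rec")
        for name in ("intensities.tsv", "annotations.tsv", "reference.json",
                     "truth.json"):
            assert (tmp_path / "rec" / name).exists()
        truth = json.loads((tmp_path / "rec" / "truth.json").read_text())
        assert truth["effect_fraction"] == 0.5

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError):
            generate_preset("bogus", 1)
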
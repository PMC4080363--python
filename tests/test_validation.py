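"""Cross-validation harness and the TOP / MRR / rank-ROC metrics."""

import numpy as np
import pytest

from maxcom import (
    AssociationList,
    ProteinComplex,
    ValidationRun,
    compute_metrics,
    disease_complex_pairs,
    generate_random_control,
    loocv,
    mean_rank_ratio,
    rank_roc,
    top_ratio,
)


def make_runs(ranks, list_length=100, kind="random"):
    return [
        ValidationRun(f"C{i}", f"D{i}", float(r), list_length, kind)
        for i, r in enumerate(ranks)
    ]


class TestDiseaseComplexPairs:
    def test_basic_pairing(self):
        c = ProteinComplex(complex_id="C", members=frozenset({"p1", "p2"}))
        assoc = AssociationList.from_records([("d1", "p1")])
        assert disease_complex_pairs([c], assoc) == [("d1", c)]

    def test_unassociated_complex_excluded(self):
        c = ProteinComplex(complex_id="C", members=frozenset({"p1"}))
        assoc = AssociationList.from_records([("d1", "zz")])
        assert disease_complex_pairs([c], assoc) == []

    def test_two_diseases_two_pairs(self):
        c = ProteinComplex(complex_id="C", members=frozenset({"p1", "p2"}))
        assoc = AssociationList.from_records([("d1", "p1"), ("d2", "p2")])
        pairs = disease_complex_pairs([c], assoc)
        assert [(d, x.complex_id) for d, x in pairs] == [("d1", "C"), ("d2", "C")]


class TestRandomControls:
    def test_size_and_count(self):
        controls = generate_random_control(4, [f"p{i}" for i in range(50)], 99, seed=1)
        assert len(controls) == 99
        assert all(c.size == 4 for c in controls)

    def test_seed_reproducibility(self):
        universe = [f"p{i}" for i in range(30)]
        a = generate_random_control(5, universe, 10, seed=3)
        b = generate_random_control(5, universe, 10, seed=3)
        assert [c.members for c in a] == [c.members for c in b]

    def test_full_universe_control(self):
        universe = ["a", "b", "c"]
        (c,) = generate_random_control(3, universe, 1, seed=0)
        assert c.members == frozenset(universe)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            generate_random_control(5, ["a", "b"], 1, seed=0)


class TestTopRatio:
    def test_papers_printed_count(self):
        # 382 first-place finishes among 539 runs is the worked example
        runs = make_runs([1.0] * 382 + [7.0] * 157, list_length=100)
        assert top_ratio(runs) * 100 == pytest.approx(70.87, abs=5e-3)

    def test_extremes(self):
        assert top_ratio(make_runs([1, 1, 1])) == 1.0
        assert top_ratio(make_runs([2, 3, 4])) == 0.0

    def test_tied_first_place_is_not_a_success(self):
        assert top_ratio(make_runs([1.5])) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_ratio([])


class TestMeanRankRatio:
    def test_closed_forms(self):
        assert mean_rank_ratio(make_runs([1])) == pytest.approx(0.01)
        assert mean_rank_ratio(make_runs([1, 100])) == pytest.approx(0.505)
        assert mean_rank_ratio(make_runs([50] * 500)) == pytest.approx(0.50)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_rank_ratio([])


class TestRankRoc:
    def test_perfect_separation(self):
        points, auc = rank_roc(make_runs([1] * 50))
        assert auc >= 0.99

    def test_bottom_ranked_positives(self):
        points, auc = rank_roc(make_runs([100] * 50))
        assert auc == pytest.approx(0.0, abs=5e-3)

    def test_uniform_null_gives_half(self):
        rng = np.random.default_rng(2024)
        ranks = rng.integers(1, 101, size=1000)
        points, auc = rank_roc(make_runs(list(ranks)))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_curve_is_monotone_from_origin_to_one(self):
        points, _ = rank_roc(make_runs([3, 10, 40], list_length=50))
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_metrics_report_bundle(self):
        m = compute_metrics(make_runs([1, 2, 10]))
        assert 0 <= m.top <= 1 and 0 <= m.mrr <= 1 and 0 <= m.auc <= 1
        assert m.n_runs == 3


class TestLoocv:
    def test_random_control_list_length(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        runs = loocv(
            small_network, complexes, assoc, n_random_controls=19, seed=0, limit=3
        )
        assert len(runs) == 3
        assert all(r.list_length == 20 for r in runs)
        assert all(r.control_kind == "random" for r in runs)

    def test_real_controls_use_remaining_complexes(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        runs = loocv(small_network, complexes, assoc, control_kind="real", limit=3)
        assert all(r.list_length == len(complexes) for r in runs)

    def test_one_run_per_complex_under_mean_policy(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        runs = loocv(small_network, complexes, assoc, n_random_controls=9, seed=0)
        assert len(runs) == len({r.complex_id for r in runs})
        associated = {c for _, c in disease_complex_pairs(complexes, assoc)}
        assert len(runs) == len({c.complex_id for c in associated})

    def test_per_pair_policy_emits_one_run_per_query(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        mean_runs = loocv(small_network, complexes, assoc, n_random_controls=9, seed=0)
        pair_runs = loocv(
            small_network, complexes, assoc, n_random_controls=9, seed=0,
            multi_disease_policy="per-pair",
        )
        assert len(pair_runs) == len(disease_complex_pairs(complexes, assoc))
        assert len(pair_runs) >= len(mean_runs)

    def test_reproducible_under_seed(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        a = loocv(small_network, complexes, assoc, n_random_controls=9, seed=5, limit=4)
        b = loocv(small_network, complexes, assoc, n_random_controls=9, seed=5, limit=4)
        assert a == b

    def test_holdout_query_only_never_scores_worse(self, small_network, small_benchmark):
        # removing fewer association arcs can only help the positive
        sim, ppi, assoc, complexes, truth = small_benchmark
        full = loocv(small_network, complexes, assoc, n_random_controls=9, seed=0, limit=5)
        narrow = loocv(
            small_network, complexes, assoc, n_random_controls=9, seed=0, limit=5,
            holdout="query-only",
        )
        for f, n in zip(full, narrow):
            assert n.rank_of_positive <= f.rank_of_positive + 1e-9

    def test_invalid_options_rejected(self, small_network, small_benchmark):
        sim, ppi, assoc, complexes, truth = small_benchmark
        with pytest.raises(ValueError):
            loocv(small_network, complexes, assoc, control_kind="bogus")
        with pytest.raises(ValueError):
            loocv(small_network, complexes, assoc, holdout="bogus")

    def test_writers_round_trip(self, tmp_path):
        from maxcom.validation import write_metrics_json, write_roc_tsv, write_runs_tsv
        import json
        runs = make_runs([1, 2, 3])
        m = compute_metrics(runs)
        write_runs_tsv(runs, tmp_path / "runs.tsv")
        write_metrics_json(m, tmp_path / "metrics.json", config={"alpha": 0.1})
        write_roc_tsv(m, tmp_path / "roc.tsv")
        assert len((tmp_path / "runs.tsv").read_text().splitlines()) == 4
        payload = json.loads((tmp_path / "metrics.json").read_text())
        assert payload["n_runs"] == 3 and payload["config"]["alpha"] == 0.1
        assert (tmp_path / "roc.tsv").read_text().startswith("fpr\ttpr")


class TestMetricRelationships:
    def test_top_and_mrr_anticorrelate(self):
        rng = np.random.default_rng(99)
        batches = []
        for _ in range(30):
            n_good = int(rng.integers(1, 50))
            ranks = [1] * n_good + list(rng.integers(2, 101, size=50 - n_good))
            runs = make_runs(ranks)
            batches.append((top_ratio(runs), mean_rank_ratio(runs)))
        tops, mrrs = zip(*batches)
        assert np.corrcoef(tops, mrrs)[0, 1] < 0
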
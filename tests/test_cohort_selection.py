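"""Silhouette screening (vs brute force), outlier rule, experiment grammar."""

import numpy as np
import pandas as pd
import pytest

import cohgraph as cg
from cohgraph.graph_features import CLASS_COLUMN, FeatureTable


def _table_from_first_feature(values, classes, band="alpha", metric="Cv"):
    """19-column table whose geometry is 1-D: only the first electrode
    varies, so Euclidean distances reduce to |x - y| on that axis."""
    data = pd.DataFrame(0.0, index=[f"s{i}" for i in range(len(values))],
                        columns=list(cg.CHANNELS))
    data.iloc[:, 0] = values
    data[CLASS_COLUMN] = classes
    data.index.name = "Participant"
    return FeatureTable(data=data, band=band, metric=metric)


def _brute_silhouette(X, y):
    """Direct evaluation: a = mean within-class distance (self excluded),
    b = min over foreign classes of the mean distance, s = (b-a)/max."""
    n = len(y)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.empty(n)
    for k in range(n):
        own = [l for l in range(n) if y[l] == y[k] and l != k]
        if not own:
            out[k] = 0.0
            continue
        a = D[k, own].mean()
        b = min(
            D[k, [l for l in range(n) if y[l] == c]].mean()
            for c in set(y) if c != y[k]
        )
        out[k] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


class TestSilhouette:
    def test_one_dimensional_worked_example(self):
        table = _table_from_first_feature([0, 1, 5, 6], ["HA", "HA", "LA", "LA"])
        rep = cg.silhouette_scores(table)
        # point 0: a = 1, b = (5+6)/2 = 5.5, s = 4.5/5.5
        assert rep.scores.iloc[0] == pytest.approx(4.5 / 5.5)
        assert rep.cluster_sizes == {"HA": 2, "LA": 2}

    def test_equidistant_point_scores_zero(self):
        table = _table_from_first_feature([0, 2, 4, 8, 6],
                                          ["HA", "HA", "HA", "LA", "LA"])
        # point at 4: a = mean(4,2)=3 ... construct symmetric case instead
        table = _table_from_first_feature([0, 4, 2, 6, 2, 6],
                                          ["HA", "HA", "LA", "LA", "AA", "AA"])
        rep = cg.silhouette_scores(table)
        # HA = {0,4}: each HA point has a=4; LA and AA both sit at {2,6}
        # with mean distance 4 as well -> s = 0
        assert rep.scores.iloc[0] == pytest.approx(0.0)

    def test_coincident_clusters_score_zero(self):
        table = _table_from_first_feature([1, 1, 1, 1], ["HA", "HA", "LA", "LA"])
        rep = cg.silhouette_scores(table)
        assert np.allclose(rep.scores, 0.0)

    def test_matches_brute_force_on_small_cohorts(self):
        """Exact agreement with the direct pairwise-distance evaluation."""
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(5, 11))
            y = rng.choice(["HA", "AA", "LA"], size=n)
            while len(set(y)) < 2:
                y = rng.choice(["HA", "AA", "LA"], size=n)
            X = rng.normal(size=(n, 19))
            data = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                                columns=list(cg.CHANNELS))
            data[CLASS_COLUMN] = y
            table = FeatureTable(data=data, band="delta", metric="dv")
            rep = cg.silhouette_scores(table)
            assert np.allclose(rep.scores.to_numpy(), _brute_silhouette(X, y),
                               atol=1e-10)

    def test_single_class_rejected(self):
        table = _table_from_first_feature([0, 1], ["HA", "HA"])
        with pytest.raises(ValueError, match="two classes"):
            cg.silhouette_scores(table)


def _report(variant, scores):
    return cg.SilhouetteReport(
        variant=variant,
        scores=pd.Series(scores, index=[f"s{i}" for i in range(len(scores))]),
        cluster_sizes={},
    )


class TestDetectOutliers:
    def test_flags_nonpositive_when_cohort_cohesive(self):
        scores = [0.5] * 8 + [-0.1, 0.0]  # 80% positive > 70%
        dec = cg.detect_outliers([_report("v1", scores)])
        flagged = {p for p, d in dec.items() if d.is_outlier}
        assert flagged == {"s8", "s9"}

    def test_no_flags_when_cohort_not_cohesive(self):
        scores = [0.5] * 6 + [-0.1] * 4  # 60% positive <= 70%
        dec = cg.detect_outliers([_report("v1", scores)])
        assert not any(d.is_outlier for d in dec.values())

    def test_union_aggregation_and_min_variants(self):
        r1 = _report("v1", [0.5] * 9 + [-0.1])
        r2 = _report("v2", [0.5] * 8 + [-0.2, 0.4])
        dec = cg.detect_outliers([r1, r2])
        assert dec["s9"].is_outlier and dec["s8"].is_outlier
        dec2 = cg.detect_outliers([r1, r2], min_variants=2)
        assert not any(d.is_outlier for d in dec2.values())

    def test_never_flags_always_positive_participants(self):
        rng = np.random.default_rng(1)
        reports = [_report(f"v{k}", rng.uniform(-0.2, 0.9, size=12))
                   for k in range(15)]
        dec = cg.detect_outliers(reports)
        for i in range(12):
            if all((r.scores.iloc[i] > 0) for r in reports):
                assert not dec[f"s{i}"].is_outlier

    def test_inconsistent_cohorts_rejected(self):
        r1 = _report("v1", [0.5, 0.5])
        r2 = cg.SilhouetteReport("v2", pd.Series([0.5], index=["zz"]), {})
        with pytest.raises(ValueError, match="inconsistent"):
            cg.detect_outliers([r1, r2])


@pytest.fixture(scope="module")
def cleaned_tables():
    tables, outliers = cg.generate_outlier_cohort(seed=3)
    reports = [cg.silhouette_scores(t) for t in tables.values()]
    return cg.remove_outliers(tables, cg.detect_outliers(reports))


class TestExperiments:
    def test_ninety_datasets_and_pair_sizes(self, cleaned_tables):
        exps = cg.define_experiments(cleaned_tables, seed=0)
        assert len(exps) == 90
        by_pair = {}
        for e in exps:
            by_pair.setdefault(e.pair, set()).add(len(e.data))
        # 15 HA + 14 AA = 29 rows in every HA-AA variant
        assert by_pair["HA-AA"] == {29}
        # OA side matches the target class size: 15 HA + 15 OA
        assert by_pair["HA-OA"] == {30}

    def test_oa_side_balanced_between_source_classes(self, cleaned_tables):
        exps = cg.define_experiments(cleaned_tables, seed=5)
        ds = [e for e in exps if e.pair == "HA-OA"][0]
        oa_ids = ds.data.index[ds.data[CLASS_COLUMN] == "OA"]
        source = next(iter(cleaned_tables.values())).classes.loc[oa_ids]
        counts = source.value_counts()
        assert set(counts.index) == {"AA", "LA"}
        assert abs(counts["AA"] - counts["LA"]) <= 1
        assert len(oa_ids) == len(set(oa_ids))  # without replacement

    def test_same_seed_identical_oa_membership(self, cleaned_tables):
        e1 = cg.define_experiments(cleaned_tables, seed=7)
        e2 = cg.define_experiments(cleaned_tables, seed=7)
        for a, b in zip(e1, e2):
            assert a.name == b.name
            assert a.data.equals(b.data)

    def test_name_grammar_round_trips(self, cleaned_tables):
        exps = cg.define_experiments(cleaned_tables, seed=0)
        names = {e.name for e in exps}
        assert len(names) == 90
        for e in exps:
            assert cg.parse_experiment_name(e.name) == (e.pair, e.band, e.metric)
        with pytest.raises(ValueError):
            cg.parse_experiment_name("CoHA-XX_Bdelta_Gdv")

    def test_tiny_class_rejected(self):
        tables, _ = cg.generate_outlier_cohort(
            n_by_class={"HA": 4, "AA": 4, "LA": 2},
            n_outliers_by_class={"HA": 0, "AA": 0, "LA": 1},
            seed=0,
        )
        reports = [cg.silhouette_scores(t) for t in tables.values()]
        clean = cg.remove_outliers(tables, cg.detect_outliers(reports))
        with pytest.raises(ValueError, match=">= 2"):
            cg.define_experiments(clean, seed=0)
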
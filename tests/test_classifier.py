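"""Signature classifier: pre-filter, enrichment-score distance, CV,
permutation test and genetic optimizer, each against an independent oracle."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import signet
from signet.classifier import SignatureParams
from tests.conftest import noise_dataset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def ranksum_enumeration_p(x, y):
    """Exact two-sided rank-sum p by enumeration of all assignments."""
    pooled = sorted(list(x) + list(y))
    ranks = {}
    for i, v in enumerate(pooled, start=1):
        ranks.setdefault(v, []).append(i)
    rank_of = {v: float(np.mean(r)) for v, r in ranks.items()}
    obs = sum(rank_of[v] for v in x)
    all_vals = list(x) + list(y)
    n = len(x)
    stats_all = [
        sum(rank_of[all_vals[i]] for i in c)
        for c in combinations(range(len(all_vals)), n)
    ]
    mu = float(np.mean(stats_all))
    return float(np.mean([abs(w - mu) >= abs(obs - mu) - 1e-12 for w in stats_all]))


def es_running_sum_oracle(hit_ranks, P, w):
    """Literal running-sum enumeration of the weighted enrichment score
    (a magnitude tie between the +max and -min extremes resolves positive)."""
    hits = set(hit_ranks)
    V = sum((P + 1 - r) ** w for r in hits)
    run, values = 0.0, [0.0]
    for r in range(1, P + 1):
        if r in hits:
            run += (P + 1 - r) ** w / V
        else:
            run -= 1.0 / (P - len(hits))
        values.append(run)
    hi, lo = max(values), min(values)
    return hi if hi >= -lo else lo


def make_tiny_dataset(values, labels, ids=None):
    values = np.asarray(values, dtype=float)
    n, P = values.shape
    pids = ids or [f"A{j:02d}" for j in range(P)]
    return signet.ExpressionDataset(
        subject_ids=[f"S{i:02d}" for i in range(n)],
        protein_ids=pids,
        values=values,
        gene_map={p: [p] for p in pids},
        class_labels=np.asarray(labels, dtype=object),
        ages=np.full(n, 8.0),
        treated=np.zeros(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# Pre-filter and preprocessing
# ---------------------------------------------------------------------------


class TestPrefilter:
    def test_exact_threshold_against_enumeration(self):
        # oracle: all 20 assignments of {1,2,3} vs {10,11,12} give p = 0.1
        assert ranksum_enumeration_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)
        ds = make_tiny_dataset(
            [[1], [2], [3], [10], [11], [12]],
            ["control"] * 3 + ["affected"] * 3,
        )
        assert signet.wilcoxon_prefilter(ds, alpha=0.1) == ["A00"]
        with pytest.raises(ValueError, match="larger alpha"):
            signet.wilcoxon_prefilter(ds, alpha=0.09)

    def test_identical_distributions_alpha_one_retains_all(self):
        vals = np.tile([[1.0, 2.0, 3.0]], (6, 1))
        ds = make_tiny_dataset(vals + np.arange(6)[:, None] * 0.0, ["control"] * 3 + ["affected"] * 3)
        assert signet.wilcoxon_prefilter(ds, alpha=1.0) == ds.protein_ids

    def test_alpha_zero_errors(self, small_cohort):
        with pytest.raises(ValueError):
            signet.wilcoxon_prefilter(small_cohort[0], alpha=0.0)


class TestFoldchange:
    def test_constant_column_becomes_ones(self):
        ds = make_tiny_dataset([[3.0], [3.0], [3.0], [3.0]], ["control"] * 2 + ["affected"] * 2)
        out, means = signet.foldchange_preprocess(ds)
        np.testing.assert_allclose(out.values, 1.0)
        assert means[0] == 3.0

    def test_two_point_column(self):
        ds = make_tiny_dataset([[1.0], [3.0]], ["control", "affected"])
        out, _ = signet.foldchange_preprocess(ds)
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.5])

    def test_stored_means_applied_to_held_out(self, small_cohort):
        dataset, _ = small_cohort
        train = dataset.subset_subjects(np.arange(0, 16))
        test = dataset.subset_subjects(np.arange(16, dataset.n_subjects))
        _, means = signet.foldchange_preprocess(train)
        applied, _ = signet.foldchange_preprocess(test, means=means)
        np.testing.assert_allclose(applied.values, test.values / means[None, :])


# ---------------------------------------------------------------------------
# Signatures and distance
# ---------------------------------------------------------------------------


class TestSignature:
    def test_top_and_bottom(self):
        sig = signet.make_signature({"A": 5.0, "B": 3.0, "C": 1.0}, SignatureParams(n1=1, n2=1))
        assert sig.top == ("A",) and sig.bottom == ("C",)

    def test_tie_broken_by_ascending_id(self):
        sig = signet.make_signature({"B": 5.0, "A": 5.0, "C": 0.0}, SignatureParams(n1=1, n2=1))
        assert sig.top == ("A",)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            vals = rng.normal(size=20)
            ids = [f"P{j:02d}" for j in range(20)]
            sig = signet.make_signature(dict(zip(ids, vals)), SignatureParams(n1=4, n2=3))
            ranked = [i for _, i in sorted(zip(-vals, ids))]
            assert list(sig.top) == ranked[:4]
            assert list(sig.bottom) == ranked[-3:]

    def test_too_long_signature_errors(self):
        with pytest.raises(ValueError):
            signet.make_signature({"A": 1.0, "B": 2.0}, SignatureParams(n1=2, n2=1))


class TestEnrichmentScore:
    def test_extremes(self):
        ranking = list("ABCDEF")
        assert signet.enrichment_score(["A", "B"], ranking) == pytest.approx(1.0)
        assert signet.enrichment_score(["E", "F"], ranking) == pytest.approx(-1.0)

    def test_spec_running_sum_example(self):
        # P=5, hits at ranks 1 and 3, w=0: running sum 0.5, 0.1667, 0.6667, ...
        assert signet.enrichment_score(["a", "c"], list("abcde"), w=0.0) == pytest.approx(2 / 3)
        assert es_running_sum_oracle([1, 3], 5, 0.0) == pytest.approx(2 / 3)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_running_sum_oracle(self, data):
        P = data.draw(st.integers(4, 40))
        k = data.draw(st.integers(1, P - 1))
        w = data.draw(st.sampled_from([0.0, 0.5, 1.0, 2.0]))
        ranks = data.draw(
            st.lists(st.integers(1, P), min_size=k, max_size=k, unique=True)
        )
        ranking = [f"x{r}" for r in range(1, P + 1)]
        got = signet.enrichment_score([f"x{r}" for r in ranks], ranking, w=w)
        assert got == pytest.approx(es_running_sum_oracle(ranks, P, w))

    def test_empty_and_full_set_error(self):
        with pytest.raises(ValueError):
            signet.enrichment_score([], list("abc"))
        with pytest.raises(ValueError):
            signet.enrichment_score(list("abc"), list("abc"))


class TestDistance:
    def test_self_distance_zero_for_all_params(self):
        rng = np.random.default_rng(0)
        ranking = [f"P{j}" for j in range(12)]
        for n1, n2, w in [(1, 1, 1.0), (3, 2, 0.0), (5, 5, 2.0), (2, 4, 1.0)]:
            sig = signet.SubjectSignature("s", tuple(ranking[:n1]), tuple(ranking[-n2:]))
            assert signet.signature_distance(sig, ranking, sig, ranking, w) == pytest.approx(0.0)

    def test_reversed_rankings_distance_one(self):
        ranking = list("ABCDEF")
        rev = ranking[::-1]
        sa = signet.SubjectSignature("a", ("A",), ("F",))
        sb = signet.SubjectSignature("b", ("F",), ("A",))
        assert signet.signature_distance(sa, ranking, sb, rev) == pytest.approx(1.0)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        ids = [f"P{j}" for j in range(15)]
        for _ in range(10):
            ra = list(rng.permutation(ids))
            rb = list(rng.permutation(ids))
            sa = signet.SubjectSignature("a", tuple(ra[:3]), tuple(ra[-2:]))
            sb = signet.SubjectSignature("b", tuple(rb[:3]), tuple(rb[-2:]))
            assert signet.signature_distance(sa, ra, sb, rb) == pytest.approx(
                signet.signature_distance(sb, rb, sa, ra)
            )

    def test_mismatched_universe_errors(self):
        sa = signet.SubjectSignature("a", ("A",), ("C",))
        with pytest.raises(ValueError):
            signet.signature_distance(sa, list("ABC"), sa, list("ABD"))

    def test_matrix_identical_subjects_is_zero(self):
        ranking = list("ABCDE")
        sig = signet.SubjectSignature("s", ("A",), ("E",))
        dm = signet.distance_matrix([sig, sig], [ranking, ranking])
        np.testing.assert_allclose(dm.values, 0.0)

    def test_matrix_equals_pairwise_recomputation_and_properties(self):
        rng = np.random.default_rng(4)
        ids = [f"P{j}" for j in range(10)]
        rankings = [list(rng.permutation(ids)) for _ in range(8)]
        sigs = [
            signet.SubjectSignature(f"s{i}", tuple(r[:2]), tuple(r[-2:]))
            for i, r in enumerate(rankings)
        ]
        dm = signet.distance_matrix(sigs, rankings)
        for i in range(8):
            for j in range(8):
                expect = 0.0 if i == j else signet.signature_distance(
                    sigs[i], rankings[i], sigs[j], rankings[j]
                )
                assert dm.values[i, j] == pytest.approx(expect)
        assert dm.values.min() >= 0.0 and dm.values.max() <= 1.0
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)


class TestClassifySubject:
    def test_smaller_mean_distance_wins(self):
        pred = signet.classify_subject(
            np.array([0.1, 0.1, 0.9]), ["control", "control", "affected"]
        )
        assert pred == "control"

    def test_tie_goes_to_control(self):
        pred = signet.classify_subject(np.array([0.5, 0.5]), ["affected", "control"])
        assert pred == "control"

    def test_hand_computed_group_means(self):
        d = np.array([0.2, 0.8, 0.3, 0.5])
        labels = ["control", "affected", "control", "affected"]
        # mean control 0.25, mean affected 0.65
        assert signet.classify_subject(d, labels) == "control"
        d2 = np.array([0.9, 0.1, 0.8, 0.3])
        assert signet.classify_subject(d2, labels) == "affected"


# ---------------------------------------------------------------------------
# Cross-validation, panel, permutations
# ---------------------------------------------------------------------------


class TestCrossValidate:
    def test_strong_markers_give_perfect_accuracy(self, small_cohort):
        dataset, _ = small_cohort
        cv = signet.cross_validate(dataset, SignatureParams(n1=1, n2=1, filter_alpha=0.01), k=5, seed=2)
        assert cv.mean_accuracy == 1.0

    def test_pure_noise_accuracy_at_chance(self):
        """200-seed simulation oracle: with no class structure the mean-distance
        rule predicts either class with probability 1/2 (the held-out subject's
        mean distances to the two training groups are exchangeable), so the
        expected accuracy is 0.5 even under class imbalance."""
        accs = []
        for seed in range(200):
            ds = noise_dataset(6, 10, 30, seed)
            cv = signet.cross_validate(
                ds, SignatureParams(n1=2, n2=2, filter_alpha=1.0), k=5, seed=seed, build_objects=False
            )
            accs.append(cv.mean_accuracy)
        n_total = 200 * 16
        se = np.sqrt(0.25 / n_total)
        assert abs(np.mean(accs) - 0.5) <= 3 * se + 0.02

    def test_determinism(self, small_cohort):
        dataset, _ = small_cohort
        p = SignatureParams(n1=2, n2=2, filter_alpha=0.1)
        a = signet.cross_validate(dataset, p, k=5, seed=9)
        b = signet.cross_validate(dataset, p, k=5, seed=9)
        assert a.fold_assignment == b.fold_assignment
        assert a.fold_accuracies == b.fold_accuracies
        assert a.predicted == b.predicted

    def test_stratified_folds_partition_subjects(self, small_cohort):
        dataset, _ = small_cohort
        cv = signet.cross_validate(dataset, SignatureParams(n1=1, n2=1, filter_alpha=0.5), k=5, seed=0)
        assert sorted(cv.fold_assignment) == sorted(dataset.subject_ids)
        assert set(cv.fold_assignment.values()) == set(range(5))

    def test_class_smaller_than_k_errors(self):
        ds = noise_dataset(3, 10, 10, 0)
        with pytest.raises(ValueError, match="fewer than k"):
            signet.cross_validate(ds, SignatureParams(n1=1, n2=1, filter_alpha=1.0), k=5)

    def test_monotone_separation_in_effect_size(self):
        """Increasing the planted effect never decreases mean CV accuracy."""
        accs = []
        for effect in [0.2, 0.6, 1.2, 2.0]:
            cfg = signet.CohortConfig(
                n_control=10, n_affected=14, n_proteins=60, n_markers=10,
                n_strong_markers=0, n_age_markers=0, n_treatment_markers=0,
                effect_sizes=(effect, effect), seed=21,
            )
            ds, _ = signet.generate_cohort(cfg)
            cv = signet.cross_validate(
                ds, SignatureParams(n1=3, n2=3, filter_alpha=0.2), k=5, seed=5, build_objects=False
            )
            accs.append(cv.mean_accuracy)
        assert all(b >= a for a, b in zip(accs, accs[1:]))


class TestAggregatePanel:
    def test_identical_signatures(self):
        sig = signet.SubjectSignature("s1", ("A",), ("B",))
        panel = signet.aggregate_panel([sig, sig], "short", SignatureParams(1, 1))
        assert panel.protein_ids == ["A", "B"]

    def test_union(self):
        s1 = signet.SubjectSignature("s1", ("A",), ("B",))
        s2 = signet.SubjectSignature("s2", ("B",), ("C",))
        panel = signet.aggregate_panel([s1, s2], "short", SignatureParams(1, 1))
        assert panel.protein_ids == ["A", "B", "C"]
        assert panel.contributing["B"] == {"s1", "s2"}

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(6)
        ids = [f"P{j}" for j in range(30)]
        sigs = []
        for i in range(50):
            picks = rng.choice(30, size=5, replace=False)
            sigs.append(
                signet.SubjectSignature(f"s{i}", tuple(ids[p] for p in picks[:3]),
                                        tuple(ids[p] for p in picks[3:]))
            )
        panel = signet.aggregate_panel(sigs, "long", SignatureParams(3, 2))
        brute = sorted({p for s in sigs for p in s.proteins})
        assert panel.protein_ids == brute


class TestPermutation:
    def test_p_value_formula_and_support(self, small_cohort):
        dataset, _ = small_cohort
        res = signet.permutation_test(
            dataset, SignatureParams(n1=1, n2=1, filter_alpha=0.05), k=5, B=10, seed=3
        )
        assert res.observed == 1.0
        expect = (float((res.null_accuracies >= res.observed).sum()) + 1) / 11
        assert res.p_value == pytest.approx(expect)
        assert 0 < res.p_value <= 1
        if (res.null_accuracies < 1.0).all():
            assert res.p_value == pytest.approx(1 / 11)

    def test_invalid_B(self, small_cohort):
        with pytest.raises(ValueError):
            signet.permutation_test(small_cohort[0], SignatureParams(1, 1), B=0)

    def test_p_valid_under_true_null(self):
        """Under label-exchangeable (pure noise) data P(p <= a) <= a + tol."""
        pvals = []
        for seed in range(200):
            ds = noise_dataset(6, 10, 25, 1000 + seed)
            res = signet.permutation_test(
                ds, SignatureParams(n1=2, n2=2, filter_alpha=1.0), k=5, B=19, seed=seed
            )
            pvals.append(res.p_value)
        pvals = np.array(pvals)
        for alpha in [0.05, 0.1, 0.25, 0.5]:
            assert (pvals <= alpha).mean() <= alpha + 0.06


class TestOptimizer:
    def test_single_separating_protein_short_mode(self):
        """A perfectly separating protein whose rank flips against a second
        filtered protein between classes: short mode reaches accuracy 1.0 with
        the minimal two-protein panel, matching an exhaustive grid oracle."""
        rng = np.random.default_rng(8)
        n_c, n_a, P = 8, 10, 15
        base = np.concatenate([[10.0, 12.0], rng.uniform(10.3, 11.7, P - 2)])
        log2 = base[None, :] + rng.normal(0, 0.4, (n_c + n_a, P))
        log2[n_c:, 0] += 6.0  # perfectly separating: 10 -> 16 in affected
        log2[n_c:, 1] -= 2.0  # strongly shifted: 12 -> 10 in affected
        ds = make_tiny_dataset(np.exp2(log2), ["control"] * n_c + ["affected"] * n_a)
        ga = signet.GAConfig(mode="short", seed=5, generations=15, population_size=16,
                             n_max=4, alpha_grid=(1e-4, 0.02, 0.5), cv_folds=4)
        params, panel, cv = signet.optimize_parameters(ds, ga)
        assert cv.mean_accuracy == 1.0
        assert len(panel) <= 2

        # exhaustive oracle over the same grid
        best = None
        for n1 in (1, 2, 3):
            for n2 in (1, 2, 3):
                for alpha in ga.alpha_grid:
                    try:
                        c = signet.cross_validate(
                            ds, SignatureParams(n1, n2, alpha), k=4, seed=ga.seed, build_objects=True
                        )
                        size = len(signet.aggregate_panel(c.signatures, "short", SignatureParams(n1, n2, alpha)))
                        fit = (c.mean_accuracy, -size)
                    except ValueError:
                        continue
                    best = max(best, fit) if best else fit
        assert (cv.mean_accuracy, -len(panel)) >= best

    def test_determinism(self, small_cohort):
        dataset, _ = small_cohort
        ga = signet.GAConfig(mode="short", seed=17, generations=8, population_size=10)
        a = signet.optimize_parameters(dataset, ga)[0]
        b = signet.optimize_parameters(dataset, ga)[0]
        assert a == b

    def test_long_mode_floor_unreachable_errors(self):
        ds = noise_dataset(6, 8, 20, 3)
        ga = signet.GAConfig(mode="long", seed=1, generations=4, population_size=8,
                             accuracy_floor=0.999, n_max=3, alpha_grid=(0.5, 1.0), cv_folds=3)
        with pytest.raises(ValueError, match="best accuracy"):
            signet.optimize_parameters(ds, ga)
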
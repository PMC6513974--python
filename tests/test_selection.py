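"""Epoch-split stratification, F ranking, SFS wrapper, SVM curves, maxima."""

import numpy as np
import pytest
from scipy import stats

import painmap as pm
from painmap.selection import _dedup_keep_order
from painmap.synthgen import synth_feature_matrix


def _matrix(n_subjects=6, trials=8, levels=(pm.PainLevel.B, pm.PainLevel.T4),
            informative=None, seed=0, **kwargs):
    return synth_feature_matrix(
        pm.FEATURE_NAMES, n_subjects, trials, levels, informative or {}, seed, **kwargs
    )


class TestEpochSplits:
    def test_20_trial_stratification_exact(self):
        m = _matrix(n_subjects=3, trials=20)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 3, 1)
        for sp in splits:
            assert len(sp.train_rows) == 3 * 2 * 15
            assert len(sp.test_rows) == 3 * 2 * 5
            # per subject per level: 15 train / 5 test; 10 FS-train / 5 validation
            meta = m.meta
            for subj in meta["subject"].unique():
                for lv in ("B", "T4"):
                    cell = set(
                        np.nonzero(
                            ((meta["subject"] == subj) & (meta["level"] == lv)).to_numpy()
                        )[0]
                    )
                    assert len(cell & set(sp.train_rows)) == 15
                    assert len(cell & set(sp.test_rows)) == 5
                    assert len(cell & set(sp.fs_train_rows)) == 10
                    assert len(cell & set(sp.validation_rows)) == 5

    def test_train_fraction_is_75_percent(self):
        m = _matrix(n_subjects=2, trials=20)
        (sp,) = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 5)
        total = len(sp.train_rows) + len(sp.test_rows)
        assert len(sp.train_rows) / total == 0.75

    def test_disjoint_and_complete(self):
        m = _matrix(n_subjects=3, trials=8)
        (sp,) = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 2)
        rows = np.concatenate([sp.train_rows, sp.test_rows])
        assert len(rows) == len(set(rows)) == len(m.values)
        inner = np.concatenate(sp.inner_folds)
        assert sorted(inner) == sorted(sp.train_rows)

    def test_deterministic(self):
        m = _matrix()
        a = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 4, 9)
        b = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 4, 9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.train_rows, sb.train_rows)
            assert sa.val_fold == sb.val_fold

    def test_missing_level_rejected(self):
        m = _matrix(levels=(pm.PainLevel.B, pm.PainLevel.T1))
        with pytest.raises(ValueError):
            pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 0)


class TestAnovaF:
    def test_hand_example(self):
        f = pm.anova_f(np.array([1.0, 2.0, 3.0, 4.0]), np.array(["a", "a", "b", "b"]))
        assert f == pytest.approx(8.0)

    def test_matches_scipy(self, rng):
        vals = rng.standard_normal(60)
        labels = np.repeat(["a", "b", "c"], 20)
        ours = pm.anova_f(vals, labels)
        ref = stats.f_oneway(vals[:20], vals[20:40], vals[40:]).statistic
        assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_perfect_separation_is_infinite(self):
        f = pm.anova_f(np.array([1.0, 1.0, 2.0, 2.0]), np.array([0, 0, 1, 1]))
        assert np.isinf(f)

    def test_null_type_i_calibration(self):
        rng = np.random.default_rng(123)
        flagged = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = rng.standard_normal(40)
            labels = np.repeat([0, 1], 20)
            f = pm.anova_f(vals, labels)
            p = stats.f.sf(f, 1, 38)
            flagged += p < 0.05
        assert 0.035 <= flagged / n_rep <= 0.065


class TestUFS:
    def test_injected_column_ranks_first(self):
        m = _matrix(informative={"cP2P": 1.5}, seed=3)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 5, 0)
        ranking = pm.ufs_rank(m, pm.ClassificationProblem.pain_tolerance, splits)
        assert ranking.order[0] == "cP2P"

    def test_duplicate_of_top_feature_occupies_top_two(self):
        m = _matrix(informative={"cP2P": 1.5}, seed=4)
        m.values["zHOMAV1"] = m.values["cP2P"]  # exact duplicate column
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 3, 0)
        ranking = pm.ufs_rank(m, pm.ClassificationProblem.pain_tolerance, splits)
        assert set(ranking.order[:2]) == {"cP2P", "zHOMAV1"}

    def test_null_ranking_stable_under_reruns(self):
        m = _matrix(seed=5)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 3, 7)
        r1 = pm.ufs_rank(m, pm.ClassificationProblem.pain_tolerance, splits)
        r2 = pm.ufs_rank(m, pm.ClassificationProblem.pain_tolerance, splits)
        assert r1.order == r2.order
        # top F under the null stays within plausible null-F range
        assert r1.mean_f.max() < 30


class TestSFS:
    def test_perfectly_separating_feature_chosen_first(self):
        m = _matrix(informative={"sSDSD": 50.0}, seed=6, n_subjects=4, trials=8)
        (split,) = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 0)
        sel, accs = pm.sfs_epoch(m, pm.ClassificationProblem.pain_tolerance, split, 2)
        assert sel[0] == "sSDSD"
        assert accs[0] == pytest.approx(1.0)

    def test_duplicate_adds_nothing(self):
        m = _matrix(informative={"cP2P": 1.2}, seed=7, n_subjects=4, trials=8)
        m.values["zHOMAV1"] = m.values["cP2P"]
        (split,) = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 1)
        sel, accs = pm.sfs_epoch(m, pm.ClassificationProblem.pain_tolerance, split, 3)
        first = sel[0]
        dup = "zHOMAV1" if first == "cP2P" else "cP2P"
        if dup in sel:
            i = sel.index(dup)
            assert accs[i] <= accs[i - 1] + 1e-12

    def test_reproducible(self):
        m = _matrix(seed=8, n_subjects=3, trials=8)
        (split,) = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 1, 2)
        a = pm.sfs_epoch(m, pm.ClassificationProblem.pain_tolerance, split, 3)
        b = pm.sfs_epoch(m, pm.ClassificationProblem.pain_tolerance, split, 3)
        assert a == b


class TestSFSVote:
    def test_unanimity(self):
        table = pm.sfs_vote([["cP2P", "zMAV"]] * 10)
        assert table.votes[0] == {"cP2P": 10}
        assert table.consensus == ["cP2P", "zMAV"]

    def test_votes_partition_epochs(self):
        sels = [["cP2P"], ["zMAV"], ["cP2P"], ["sSDSD"]]
        table = pm.sfs_vote(sels)
        assert sum(table.votes[0].values()) == 4

    def test_tie_breaks_by_registry_order(self):
        sels = [["cP2P"], ["zMAV"]]
        table = pm.sfs_vote(sels)
        assert table.consensus[0] == "zMAV"  # z-prefix precedes c in the registry


class TestEvaluateCurve:
    def test_separable_two_class_reaches_unity(self):
        m = _matrix(informative={"cP2P": 50.0}, seed=9, n_subjects=4, trials=8)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 2, 0)
        curve = pm.evaluate_curve(
            m, pm.ClassificationProblem.pain_tolerance, ["cP2P"], splits
        )
        assert curve.mean[0] == pytest.approx(1.0)

    def test_noise_two_class_near_chance(self):
        m = _matrix(seed=10, n_subjects=8, trials=10, subject_sd=0.0)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.pain_tolerance, 5, 3)
        curve = pm.evaluate_curve(
            m, pm.ClassificationProblem.pain_tolerance, ["cP2P", "zMAV"], splits
        )
        assert 0.40 <= curve.mean[-1] <= 0.60

    def test_noise_five_class_near_chance(self):
        m = _matrix(levels=tuple(pm.PainLevel), seed=11, n_subjects=6, trials=8,
                    subject_sd=0.0)
        splits = pm.make_epoch_splits(m, pm.ClassificationProblem.five_class, 4, 3)
        curve = pm.evaluate_curve(
            m, pm.ClassificationProblem.five_class, ["cP2P", "zMAV"], splits
        )
        assert 0.10 <= curve.mean[-1] <= 0.30


class TestCurveMaxima:
    def _curve(self, per_epoch):
        per_epoch = np.asarray(per_epoch, dtype=float)
        return pm.AccuracyCurve(
            n_features=np.arange(1, per_epoch.shape[1] + 1),
            per_epoch=per_epoch,
            mean=per_epoch.mean(axis=0),
            sd=per_epoch.std(axis=0, ddof=1),
            features=[f"f{i}" for i in range(per_epoch.shape[1])],
        )

    def test_plateau_after_three(self):
        rng = np.random.default_rng(0)
        base = np.array([0.5, 0.6, 0.7, 0.7, 0.7, 0.7])
        per_epoch = base + rng.normal(0, 0.002, size=(30, 6))
        local, global_ = pm.curve_maxima(self._curve(per_epoch))
        assert local == 3

    def test_strictly_increasing_hits_edge_rule(self):
        per_epoch = np.tile(np.linspace(0.5, 0.9, 6), (10, 1))
        per_epoch += np.random.default_rng(1).normal(0, 1e-4, per_epoch.shape)
        local, global_ = pm.curve_maxima(self._curve(per_epoch))
        assert local == global_ == 6

    def test_local_never_exceeds_global(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            per_epoch = rng.uniform(0.4, 0.9, size=(8, 7))
            local, global_ = pm.curve_maxima(self._curve(per_epoch))
            assert 1 <= local <= global_ <= 7


class TestRecovery:
    """Small-scale recovery checks; the full 20-epoch / 20-subject recovery
    experiment runs in the acceptance suite."""

    def test_ufs_recovers_injected_features(self):
        informative = {f: 1.0 for f in ("cP2P", "zMAV", "sSDSD", "tRMS", "hslopeRR")}
        m = _matrix(n_subjects=10, trials=12, informative=informative, seed=12)
        problem = pm.ClassificationProblem.pain_tolerance
        splits = pm.make_epoch_splits(m, problem, 10, 4)
        ranking = pm.ufs_rank(m, problem, splits)
        assert len(set(ranking.order[:5]) & set(informative)) >= 4

    def test_sfs_first_vote_is_informative(self):
        informative = {f: 1.0 for f in ("cP2P", "zMAV", "sSDSD")}
        m = _matrix(n_subjects=10, trials=12, informative=informative, seed=13)
        problem = pm.ClassificationProblem.pain_tolerance
        splits = pm.make_epoch_splits(m, problem, 8, 5)
        sels = [pm.sfs_epoch(m, problem, sp, 1)[0] for sp in splits]
        consensus = _dedup_keep_order(pm.sfs_vote(sels).consensus)
        assert consensus[0] in informative
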
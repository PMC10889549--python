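"""Synthetic cohort: determinism, planted structure, and table invariants."""

import numpy as np
import pandas as pd
import pytest

from skillnet import (
    CohortConfig,
    ConfigurationError,
    SyntheticCohort,
    generate_cohort,
    pairwise_correlation,
    write_cohort,
)
from conftest import TINY_KW, cohort_networks


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = generate_cohort(CohortConfig(**TINY_KW))
        b = generate_cohort(CohortConfig(**TINY_KW))
        assert len(a.emg_trials) == len(b.emg_trials)
        for ta, tb in zip(a.emg_trials, b.emg_trials):
            for m in ta.channels:
                assert np.array_equal(ta.channels[m], tb.channels[m])
        pd.testing.assert_frame_equal(a.kinematics, b.kinematics)
        pd.testing.assert_frame_equal(a.tlx, b.tlx)
        pd.testing.assert_frame_equal(a.mvc_table, b.mvc_table)

    def test_same_seed_identical_bytes_on_disk(self, tmp_path):
        cfg = CohortConfig(
            n_participants=3, n_sessions=2, n_trials=1, trial_duration=0.1,
            tasks=("peg_transfer",), seed=5,
        )
        write_cohort(generate_cohort(cfg), tmp_path / "a")
        write_cohort(generate_cohort(cfg), tmp_path / "b")
        for name in ("emg.csv", "mvc.csv", "kinematics.csv", "tlx.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seed_differs(self):
        a = generate_cohort(CohortConfig(**{**TINY_KW, "seed": 1}))
        b = generate_cohort(CohortConfig(**{**TINY_KW, "seed": 2}))
        assert not np.array_equal(
            a.emg_trials[0].channels["biceps_brachii"],
            b.emg_trials[0].channels["biceps_brachii"],
        )


class TestPlantedStructure:
    def test_noise_free_same_block_features_correlate_perfectly(
        self, noise_free_cohort, noise_free_networks
    ):
        cfg = noise_free_cohort.config
        blocks = cfg.blocks()
        feats, _ = noise_free_networks
        s1 = [f for f in feats if f.session == 1 and f.hand == "dominant"]
        cm = pairwise_correlation(s1)
        same = [
            cm.value(a, b)
            for a in cm.participants
            for b in cm.participants
            if a < b and blocks[a] == blocks[b]
        ]
        assert min(same) >= 1.0 - 1e-9

    def test_between_block_correlation_below_within(self, tiny_cohort):
        cfg = tiny_cohort.config
        blocks = cfg.blocks()
        feats, _ = cohort_networks(tiny_cohort)
        s1 = [f for f in feats if f.session == 1 and f.hand == "dominant"]
        cm = pairwise_correlation(s1)
        within, between = [], []
        for a in cm.participants:
            for b in cm.participants:
                if a < b:
                    (within if blocks[a] == blocks[b] else between).append(
                        cm.value(a, b)
                    )
        assert max(between) < min(within)

    def test_learner_features_migrate_toward_best_block(
        self, noise_free_cohort, noise_free_networks
    ):
        cfg = noise_free_cohort.config
        feats, _ = noise_free_networks
        best = set(cfg.resolved_best_ids())
        centroid = {
            s: np.mean(
                [
                    f.values
                    for f in feats
                    if f.session == s and f.hand == "non_dominant" and f.participant_id in best
                ],
                axis=0,
            )
            for s in (1, cfg.n_sessions)
        }
        for learner in cfg.resolved_learner_ids():
            rho = {}
            for s in (1, cfg.n_sessions):
                (fv,) = [
                    f
                    for f in feats
                    if f.session == s and f.hand == "non_dominant" and f.participant_id == learner
                ]
                rho[s] = np.corrcoef(fv.values, centroid[s])[0, 1]
            assert rho[cfg.n_sessions] > rho[1]


class TestTableInvariants:
    def test_one_trial_per_key(self, tiny_cohort):
        keys = [
            (t.participant_id, t.session, t.trial, t.hand, t.task)
            for t in tiny_cohort.emg_trials
        ]
        assert len(keys) == len(set(keys))

    def test_completion_times_positive(self, tiny_cohort):
        assert (tiny_cohort.kinematics["completion_time_s"] > 0).all()

    def test_tlx_scores_in_range(self, tiny_cohort):
        from skillnet.tlx import TLX_DIMENSIONS

        for dim in TLX_DIMENSIONS:
            col = tiny_cohort.tlx[dim]
            assert col.between(0, 10).all()

    def test_mvc_positive(self, tiny_cohort):
        assert (tiny_cohort.mvc_table["mvc_amplitude"] > 0).all()

    def test_learner_nondominant_times_decrease_in_expectation(self):
        cfg = CohortConfig(**{**TINY_KW, "time_noise_sd": 0.0})
        cohort = generate_cohort(cfg)
        kin = cohort.kinematics
        for learner in cfg.resolved_learner_ids():
            sub = kin[
                (kin["participant_id"] == learner) & (kin["hand"] == "non_dominant")
            ]
            means = sub.groupby("session")["completion_time_s"].mean()
            assert means.is_monotonic_decreasing


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"trial_duration": 0.0},
            {"sampling_rate": -1.0},
            {"n_participants": 2},
            {"noise_sd": -0.1},
            {"learner_mix_max": 1.5},
            {"hands": ("left",)},
            {"best_ids": ("P99",)},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            generate_cohort(CohortConfig(**{**TINY_KW, **kw}))

    def test_default_design_counts(self):
        cfg = CohortConfig()
        assert len(cfg.participants()) == 18
        assert len(set(cfg.blocks().values())) == 2
        assert len(cfg.resolved_best_ids()) == 5   # ceil(0.25 * 18)
        assert len(cfg.resolved_learner_ids()) == 3
        assert set(cfg.resolved_best_ids()).isdisjoint(cfg.resolved_learner_ids())


class TestWriteCohort:
    def test_round_trip_tables(self, tmp_path):
        cfg = CohortConfig(
            n_participants=3, n_sessions=2, n_trials=1, trial_duration=0.1,
            tasks=("wire_loop",), seed=2,
        )
        cohort = generate_cohort(cfg)
        manifest = write_cohort(cohort, tmp_path)
        from skillnet import read_emg_csv, read_kinematics_csv, read_mvc_csv, read_tlx_csv

        trials = read_emg_csv(manifest["files"]["emg"])
        assert len(trials) == len(cohort.emg_trials)
        by_key = {
            (t.participant_id, t.session, t.trial, t.hand, t.task): t for t in trials
        }
        for orig in cohort.emg_trials:
            got = by_key[(orig.participant_id, orig.session, orig.trial, orig.hand, orig.task)]
            assert got.sampling_rate == pytest.approx(orig.sampling_rate, rel=1e-6)
            for m, series in orig.channels.items():
                assert np.allclose(got.channels[m], series)
        pd.testing.assert_frame_equal(
            read_kinematics_csv(manifest["files"]["kinematics"]), cohort.kinematics
        )
        pd.testing.assert_frame_equal(
            read_tlx_csv(manifest["files"]["tlx"]), cohort.tlx
        )
        pd.testing.assert_frame_equal(
            read_mvc_csv(manifest["files"]["mvc"]), cohort.mvc_table
        )

    def test_empty_cohort_header_only(self, tmp_path):
        empty = SyntheticCohort(
            emg_trials=[],
            mvc_table=pd.DataFrame(columns=["participant_id", "muscle", "mvc_amplitude"]),
            kinematics=pd.DataFrame(
                columns=["participant_id", "session", "trial", "hand", "task", "completion_time_s"]
            ),
            tlx=pd.DataFrame(
                columns=["participant_id", "session", "task", "mental", "physical",
                         "temporal", "performance", "effort", "frustration"]
            ),
        )
        manifest = write_cohort(empty, tmp_path)
        assert manifest["n_trial_recordings"] == {}
        assert manifest["n_participants"] == 0
        emg = pd.read_csv(manifest["files"]["emg"])
        assert emg.empty and list(emg.columns)[0] == "participant_id"

    def test_trial_counts_per_task(self, tmp_path):
        # full default roster at a token duration: 18 x 3 x 5 x 2 per task
        cfg = CohortConfig(trial_duration=0.02, seed=0)
        manifest = write_cohort(generate_cohort(cfg), tmp_path)
        assert manifest["n_trial_recordings"] == {
            "peg_transfer": 540,
            "wire_loop": 540,
        }
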
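"""Scenario contracts: the model's qualitative predictions as assertions."""

import numpy as np
import pytest

from ctmsim.core import Chunk, EMPTY_GIST, Gist, make_submission_chunk
from ctmsim.scenarios import (
    SelfModel,
    SleepState,
    inner_speech_route,
    run_scenario,
    scenario_blindsight,
    scenario_change_blindness,
    scenario_inattentional,
    scenario_sleep_dream,
    self_attribution,
)


class TestBlindsight:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dissociation_acts_without_seeing(self, seed):
        """No vision-origin chunk is ever broadcast, yet link-fed fetch
        actions succeed: acting on unseen information."""
        result = scenario_blindsight(seed)
        assert result.vision_broadcasts == 0
        assert result.fetch_successes > 0

    def test_control_run_broadcasts_vision(self):
        result = scenario_blindsight(0, lesioned=False)
        assert result.vision_broadcasts > 0


class TestInattentionalBlindness:
    def test_gorilla_share_matches_oracle_within_mc_error(self):
        result = scenario_inattentional(0, intensity_ratio=10.0)
        assert result.oracle_share == pytest.approx(1 / 151, abs=1e-12)
        assert abs(result.mc_share - result.oracle_share) < 3 * result.binomial_se

    def test_no_task_means_uniform_shares(self):
        result = scenario_inattentional(1, intensity_ratio=1.0, n_task=7,
                                        mc_runs=20_000)
        assert result.oracle_share == pytest.approx(1 / 8, abs=1e-12)

    def test_larger_ratio_shrinks_the_share(self):
        shares = [
            scenario_inattentional(0, intensity_ratio=r, mc_runs=1000).oracle_share
            for r in (1.0, 10.0, 100.0)
        ]
        assert shares[0] > shares[1] > shares[2]


class TestChangeBlindness:
    def test_coarse_encoder_sees_no_change(self):
        assert scenario_change_blindness(0).change_reports == 0

    def test_fine_encoder_reports_the_swap(self):
        assert scenario_change_blindness(0, encoder="fine").change_reports >= 1

    @pytest.mark.parametrize("encoder", ["coarse", "fine"])
    def test_identical_scenes_never_reported(self, encoder):
        result = scenario_change_blindness(0, encoder=encoder,
                                           identical_scenes=True)
        assert result.change_reports == 0


@pytest.fixture(scope="module")
def sleep_dream_result():
    return scenario_sleep_dream(0)


class TestSleepDream:
    @pytest.fixture
    def result(self, sleep_dream_result):
        return sleep_dream_result

    def test_full_cycle_visited(self, result):
        assert set(result.phase_by_tick.values()) == {"awake", "sleep", "dream"}
        phases = [result.phase_by_tick[t] for t in sorted(result.phase_by_tick)]
        # awake -> sleep -> dream -> awake, in order
        transitions = [p for i, p in enumerate(phases)
                       if i == 0 or phases[i - 1] != p]
        assert transitions == ["awake", "sleep", "dream", "awake"]

    def test_sleep_broadcasts_all_empty_except_loud_noise(self, result):
        assert result.sleep_broadcasts > 0
        assert (result.sleep_empty_broadcasts + result.sleep_noise_broadcasts
                == result.sleep_broadcasts)

    def test_loud_noise_breaks_through_during_sleep(self, result):
        assert result.sleep_noise_broadcasts >= 1
        silent = scenario_sleep_dream(0, noise=False)
        assert silent.sleep_noise_broadcasts == 0
        assert silent.sleep_empty_broadcasts == silent.sleep_broadcasts

    def test_dream_creator_reaches_stm_while_dreaming(self, result):
        assert result.dream_broadcasts > 0
        assert result.dream_creator_broadcasts >= 1

    def test_inner_speech_recirculates_dream_content(self, result):
        assert result.inner_speech_dream_routings >= 1

    def test_threshold_ordering_enforced(self):
        with pytest.raises(Exception):
            SleepState(theta_sleep=10, theta_dream=40, theta_wake=5)


class TestSelfAttribution:
    def command(self):
        return Gist(frozenset({"command"}), "raise-arm")

    def test_five_consistent_pairings_tag_self(self):
        model = SelfModel(k_self=5)
        for t in range(5):
            self_attribution(model, self.command(), "arm", True, t)
        assert model.tag("arm") == "self"

    def test_zero_pairings_tag_not_self(self):
        model = SelfModel(k_self=5)
        for t in range(5):
            self_attribution(model, self.command(), "lamp", False, t)
        assert model.tag("lamp") == "not_self"

    def test_partial_evidence_stays_unknown(self):
        model = SelfModel(k_self=5)
        outcomes = [True, True, True, False, False]
        for t, ok in enumerate(outcomes):
            self_attribution(model, self.command(), "arm", ok, t)
        assert model.tag("arm") == "unknown"

    def test_misses_reset_the_consecutive_run(self):
        model = SelfModel(k_self=3)
        for t, ok in enumerate([True, True, False, True, True]):
            self_attribution(model, self.command(), "arm", ok, t)
        assert model.tag("arm") == "unknown"
        self_attribution(model, self.command(), "arm", True, 5)
        assert model.tag("arm") == "self"

    def test_monotone_in_evidence_self_never_demoted(self):
        model = SelfModel(k_self=2)
        for t in range(2):
            self_attribution(model, self.command(), "arm", True, t)
        assert model.tag("arm") == "self"
        self_attribution(model, self.command(), "arm", False, 2)
        self_attribution(model, self.command(), "arm", True, 3)
        assert model.tag("arm") == "self"


class TestInnerSpeechRoute:
    def make_chunk(self, tags, payload):
        return make_submission_chunk(1, 0, Gist(frozenset(tags), payload), 1.0)

    def test_speech_payload_redelivered_to_outer_speech_targets(self):
        chunk = self.make_chunk({"speech", "vision"}, "hello")
        routed = inner_speech_route(chunk, (3, 4))
        assert [t for t, _ in routed] == [3, 4]
        for _, gist in routed:
            assert gist.payload == "hello"
            assert gist.origin_note == "inner-speech"

    def test_vision_only_gist_is_not_routed(self):
        chunk = self.make_chunk({"vision"}, "sunset")
        assert inner_speech_route(chunk, (3,)) == []

    def test_empty_gist_is_not_routed(self):
        chunk = make_submission_chunk(0, 0, EMPTY_GIST, 0.0)
        assert inner_speech_route(chunk, (3,)) == []


def test_unknown_scenario_name_rejected():
    with pytest.raises(Exception, match="unknown scenario"):
        run_scenario("lucid", seed=0)
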
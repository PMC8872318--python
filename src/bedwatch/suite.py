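"""Run the standard scenario suite end to end and score it.

This is the behavioural test harness: simulate every scripted scenario,
run the full monitoring pipeline on the synthetic frames and radar, match
detected bed-exits against the constructed ground truth, and aggregate
event-level confusion matrices per assistance category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import ConfusionMatrix, match_events
from .geometry import SensorConfig, ZoneMap, default_zones
from .pipeline import BackgroundModel
from .posture import Assistance, ClassifierThresholds, EventType
from .runner import SessionResult, run_session
from .simulate import (
    SIM_FPS,
    GroundTruth,
    ScenarioScript,
    SceneRenderer,
    standard_suite,
    synthesize_radar,
)

#: Number of empty-room frames used for background calibration.
BACKGROUND_FRAMES = 50


def calibrate_background(
    renderer: SceneRenderer,
    config: SensorConfig,
    seed: int,
    n_frames: int = BACKGROUND_FRAMES,
) -> BackgroundModel:
    """Median-of-N empty-room calibration capture (with sensor noise)."""
    empty = ScenarioScript(name="empty", duration=n_frames / SIM_FPS, persons=[])
    frames = list(renderer.frames(empty, fps=SIM_FPS, seed=seed))
    return BackgroundModel.from_frames(frames, config)


@dataclass
class ScenarioOutcome:
    script: ScenarioScript
    truth: GroundTruth
    session: SessionResult
    matrix: ConfusionMatrix


@dataclass
class SuiteResult:
    outcomes: list[ScenarioOutcome] = field(default_factory=list)

    @property
    def overall(self) -> ConfusionMatrix:
        total = ConfusionMatrix()
        for o in self.outcomes:
            total = total + o.matrix
        return total

    def by_category(self) -> dict[str, ConfusionMatrix]:
        """Split positives by the truth assistance label; negatives pooled."""
        cats = {"non_assisted": ConfusionMatrix(), "assisted": ConfusionMatrix()}
        for o in self.outcomes:
            if o.truth.events:
                key = (
                    "assisted"
                    if o.truth.events[0].assistance == "ASSISTED"
                    else "non_assisted"
                )
                cats[key] = cats[key] + o.matrix
            else:
                cats["non_assisted"] = cats["non_assisted"] + o.matrix
        return cats

    def assistance_agreement(self) -> float | None:
        """Fraction of matched exits whose assistance label agrees with truth."""
        agree = total = 0
        for o in self.outcomes:
            if not o.truth.events or o.matrix.tp == 0:
                continue
            truth_label = o.truth.events[0].assistance
            for ev in o.session.events:
                if ev.event_type == EventType.BED_EXIT:
                    total += 1
                    detected = (
                        "ASSISTED" if ev.assistance == Assistance.ASSISTED else "NON_ASSISTED"
                    )
                    agree += detected == truth_label
        return agree / total if total else None


def run_scenario(
    script: ScenarioScript,
    truth: GroundTruth,
    renderer: SceneRenderer,
    config: SensorConfig,
    zones: ZoneMap,
    background: BackgroundModel,
    thresholds: ClassifierThresholds | None = None,
) -> ScenarioOutcome:
    """Simulate one scenario, run the pipeline and score it."""
    frames = renderer.frames(script, fps=SIM_FPS, seed=script.seed)
    radar = synthesize_radar(script, zones, np.random.default_rng(script.seed + 1))
    session = run_session(frames, radar, zones, config, background, thresholds)
    detected = [e for e in session.events if e.event_type == EventType.BED_EXIT]
    matrix = match_events(
        detected,
        [e.to_dict() for e in truth.events],
        negatives=[(s, e) for s, e, _ in truth.negative_episodes],
    )
    return ScenarioOutcome(script=script, truth=truth, session=session, matrix=matrix)


def run_standard_suite(
    seed: int,
    config: SensorConfig | None = None,
    zones: ZoneMap | None = None,
    thresholds: ClassifierThresholds | None = None,
    scenarios: list[tuple[ScenarioScript, GroundTruth]] | None = None,
) -> SuiteResult:
    """Simulate + run + evaluate the full standard suite at one seed."""
    config = config or SensorConfig()
    zones = zones or default_zones()
    renderer = SceneRenderer(config, zones)
    background = calibrate_background(renderer, config, seed=(seed * 7919 + 13) % (2**31))
    if scenarios is None:
        scenarios = standard_suite(seed, zones)
    result = SuiteResult()
    for script, truth in scenarios:
        result.outcomes.append(
            run_scenario(script, truth, renderer, config, zones, background, thresholds)
        )
    return result
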
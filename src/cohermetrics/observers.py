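"""Simulated observers for coherence-discrimination tasks.

Two kinds of decision-maker stand in for human participants:

``PsychometricObserver``
    A parametric Weibull psychometric function for a two-alternative task,

        P(correct | c) = gamma + (1 - gamma - lapse) * (1 - exp(-(c/alpha)^slope)),

    with the scale ``alpha`` solved so that P(correct) equals the tracked
    performance level (0.793 by default) *exactly at* ``threshold_pct``.
    Parameterising the threshold at the tracked level, rather than at the
    conventional Weibull alpha (~81.6% for gamma = 0.5), lets staircase
    recovery be checked directly against the observer's known threshold.

``StimulusDrivenObserver``
    A decision rule applied to the generated frame sequences themselves
    (after optional additive positional noise), used to validate that the
    stimuli actually carry the intended signal: summed vertical
    displacement for motion, trail-elongation axis for static form, and
    the spatial segregation of jitter-event counts for temporal form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .stimuli import (AXIS_VECTORS, DIRECTION_VECTORS, MOTION_TASKS,
                      FrameSequence, StaticFormImage)

__all__ = [
    "PsychometricObserver",
    "StimulusDrivenObserver",
    "prob_correct",
    "simulate_response",
    "stimulus_decision",
]


@dataclass(frozen=True)
class PsychometricObserver:
    """Weibull observer whose threshold is defined at the tracked level."""

    threshold_pct: float
    slope: float = 2.0
    guess_rate: float = 0.5
    lapse_rate: float = 0.01
    target_p: float = 0.793  # performance level at threshold_pct

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_pct <= 100.0:
            raise ValueError("threshold_pct must lie in (0, 100]")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not 0.0 <= self.lapse_rate <= 0.05:
            raise ValueError("lapse_rate must lie in [0, 0.05]")
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess_rate must lie in [0, 1)")
        w = self._target_w()
        if not 0.0 < w < 1.0:
            raise ValueError(
                "target_p unreachable: must satisfy guess_rate < target_p < 1 - lapse_rate")

    def _target_w(self) -> float:
        return (self.target_p - self.guess_rate) / (1.0 - self.guess_rate - self.lapse_rate)

    @property
    def alpha(self) -> float:
        """Weibull scale solved so prob_correct(threshold_pct) == target_p."""
        return self.threshold_pct / (-np.log1p(-self._target_w())) ** (1.0 / self.slope)

    def to_yaml(self) -> str:
        return yaml.safe_dump({"threshold_pct": self.threshold_pct, "slope": self.slope,
                               "guess_rate": self.guess_rate, "lapse_rate": self.lapse_rate,
                               "target_p": self.target_p}, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PsychometricObserver":
        return cls(**yaml.safe_load(text))


def prob_correct(observer: PsychometricObserver, coherence_pct) -> float | np.ndarray:
    """Probability of a correct response at the given coherence (scalar or array)."""
    c = np.asarray(coherence_pct, dtype=float)
    if np.any(c < 0.0) or np.any(c > 100.0):
        raise ValueError("coherence_pct must lie in [0, 100]")
    g, lam = observer.guess_rate, observer.lapse_rate
    w = -np.expm1(-(c / observer.alpha) ** observer.slope)
    p = g + (1.0 - g - lam) * w
    return float(p) if np.isscalar(coherence_pct) else p


def simulate_response(observer: PsychometricObserver, coherence_pct: float, seed) -> bool:
    """One Bernoulli trial at the given coherence; True means correct."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return bool(rng.random() < prob_correct(observer, coherence_pct))


@dataclass(frozen=True)
class StimulusDrivenObserver:
    """Decision rule applied directly to a generated stimulus.

    ``internal_noise_sd`` (degrees) is added independently to every
    positional sample before the decision, degrading accuracy smoothly.
    """

    task_kind: str
    internal_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be non-negative")


def _noisy(arr: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return arr if sd == 0.0 else arr + rng.normal(0.0, sd, size=arr.shape)


def stimulus_decision(observer: StimulusDrivenObserver,
                      stimulus: FrameSequence | StaticFormImage, seed) -> str:
    """Return the observer's choice for one stimulus presentation.

    Motion tasks return "up"/"down" (sign of the summed vertical
    displacement); form tasks return "vertical"/"horizontal".
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(stimulus, StaticFormImage):
        if observer.task_kind != "static_form":
            raise ValueError("observer/task mismatch")
        trails = _noisy(stimulus.trails, observer.internal_noise_sd, rng)
        # oriented streaks elongate trails along the signal axis
        var = trails.var(axis=0).sum(axis=0)  # (x, y) positional variance over trails
        stat = var[1] - var[0]
        if stat == 0.0:
            return str(rng.choice(["vertical", "horizontal"]))
        return "vertical" if stat > 0 else "horizontal"

    if observer.task_kind != stimulus.task_kind:
        raise ValueError("observer/task mismatch")

    if stimulus.task_kind in MOTION_TASKS:
        disp = _noisy(stimulus.displacements(), observer.internal_noise_sd, rng)
        s = disp[:, :, 1].sum()
        if s == 0.0:
            return str(rng.choice(["up", "down"]))
        return "up" if s > 0 else "down"

    if stimulus.task_kind == "temporal_form":
        disp = _noisy(stimulus.displacements(), observer.internal_noise_sd, rng)
        moved = np.linalg.norm(disp, axis=2) > stimulus.displacement_deg / 2.0
        counts = moved.sum(axis=0)  # jitter events per dot
        pos = stimulus.frames[0]
        g = stimulus.geometry
        left = pos[:, 0] < g.window_width_deg / 2.0
        bottom = pos[:, 1] < g.window_height_deg / 2.0
        d_vert = abs(counts[left].mean() - counts[~left].mean())
        d_horz = abs(counts[bottom].mean() - counts[~bottom].mean())
        if d_vert == d_horz:
            return str(rng.choice(["vertical", "horizontal"]))
        return "vertical" if d_vert > d_horz else "horizontal"

    raise ValueError(f"unsupported task kind {stimulus.task_kind!r}")
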
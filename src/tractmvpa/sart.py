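"""Sustained attention to response task (SART) design and simulation.

The SART is a go/no-go paradigm: digits 1-9 appear in random order at a
fixed pace and the subject responds to every digit except 3, where the
response must be withheld.  Commission errors on no-go trials and faster
mean reaction time on go trials index reduced response inhibition.  The
default design is 25 repetitions of each digit (225 trials), 250 ms
stimulus duration and 900 ms inter-stimulus interval, i.e. one trial per
1.15 s and about 4.3 minutes in total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SARTSchedule", "SARTOutcome", "ResponseModel",
           "make_sart_schedule", "simulate_sart"]

NO_GO_DIGIT = 3


@dataclass(frozen=True)
class SARTSchedule:
    digits: np.ndarray          # trial digit, 1..9
    onsets_s: np.ndarray        # stimulus onset times, seconds
    is_no_go: np.ndarray        # True iff digit == 3
    stim_ms: float
    isi_ms: float

    @property
    def n_trials(self) -> int:
        return len(self.digits)

    @property
    def n_no_go(self) -> int:
        return int(self.is_no_go.sum())

    @property
    def duration_min(self) -> float:
        """Total scheduled duration (last offset + ISI) in minutes."""
        return self.n_trials * (self.stim_ms + self.isi_ms) / 1000.0 / 60.0


@dataclass(frozen=True)
class SARTOutcome:
    rt_mean: float              # mean RT over correct go responses, ms
    errors: int                 # commission errors on no-go trials
    omissions: int              # missed go trials
    n_go: int
    n_no_go: int


@dataclass(frozen=True)
class ResponseModel:
    """Subject-level response model for simulating SART performance."""
    rt_mean_ms: float = 380.0
    rt_sd_ms: float = 60.0
    commission_p: float = 0.35
    omission_p: float = 0.02

    def validate(self) -> None:
        if not (0.0 <= self.commission_p <= 1.0 and 0.0 <= self.omission_p <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.rt_sd_ms < 0:
            raise ValueError("rt_sd_ms must be >= 0")


def make_sart_schedule(reps_per_digit: int = 25, stim_ms: float = 250.0,
                       isi_ms: float = 900.0, seed: int = 0) -> SARTSchedule:
    """Seeded random ordering of ``9 * reps_per_digit`` digit trials."""
    if reps_per_digit < 1:
        raise ValueError("reps_per_digit must be >= 1")
    if stim_ms <= 0 or isi_ms <= 0:
        raise ValueError("durations must be positive")
    rng = np.random.default_rng(seed)
    digits = np.repeat(np.arange(1, 10), reps_per_digit)
    rng.shuffle(digits)
    spacing = (stim_ms + isi_ms) / 1000.0
    onsets = np.arange(len(digits)) * spacing
    return SARTSchedule(digits=digits, onsets_s=onsets,
                        is_no_go=digits == NO_GO_DIGIT,
                        stim_ms=float(stim_ms), isi_ms=float(isi_ms))


def simulate_sart(schedule: SARTSchedule, subject: ResponseModel,
                  seed: int = 0) -> SARTOutcome:
    """Draw one subject's SART outcome under a Bernoulli/Gaussian model.

    Go trials are answered with probability ``1 - omission_p`` and a
    correct response's RT is Gaussian (truncated below at 100 ms); no-go
    trials draw a commission error with probability ``commission_p``, so
    the expected error count is ``commission_p * n_no_go``.
    """
    subject.validate()
    rng = np.random.default_rng(seed)
    go = ~schedule.is_no_go
    n_go = int(go.sum())
    n_no_go = schedule.n_trials - n_go
    responded = rng.random(n_go) >= subject.omission_p
    rts = rng.normal(subject.rt_mean_ms, subject.rt_sd_ms, size=n_go)
    rts = np.maximum(rts, 100.0)
    errors = int((rng.random(n_no_go) < subject.commission_p).sum())
    rt_mean = float(rts[responded].mean()) if responded.any() else float("nan")
    return SARTOutcome(rt_mean=rt_mean, errors=errors,
                       omissions=int(n_go - responded.sum()),
                       n_go=n_go, n_no_go=n_no_go)
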
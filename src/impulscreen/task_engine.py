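"""5-choice serial reaction time task: schedules, simulation, trial scoring.

The 5-CSRTT trial cycle: the subject waits through an inter-trial interval
(ITI); one pseudo-randomly chosen aperture of a 5-hole wall then lights up
for the stimulus duration (SD) and may be answered until the end of the
limited hold (LH, SD + 2 s by default).  A poke into any hole *during* the
ITI is a premature response (the impulsivity read-out); a poke into the lit
hole is correct and rewarded; into another hole incorrect; no poke at all an
omission.  Premature, incorrect and omitted trials trigger a house-light
timeout.  A trial starts at ITI onset, so premature responses count toward
the trial total.  After a rewarded trial the next ITI starts when the snout
leaves the reward receptacle; otherwise at timeout end.

The simulator is a competing-risks generative agent: premature pokes arise
from a Poisson process (exponential waiting time truncated at the ITI),
stimulus detection / omission / choice accuracy are Bernoulli, latencies
log-normal.  Drug conditions act multiplicatively on the hazard, the
omission probability and the latencies, which is the shape of effect the
within-subject log-ratio statistics in :mod:`impulscreen.behav_stats` are
built to detect.

The classifier replays an event log through the same state machine and must
reproduce the simulator's hidden ground truth exactly; that round-trip is a
core test of both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, ConfigurationError
from .io_formats import SessionLog

__all__ = [
    "ChallengeSpec",
    "CHALLENGE_PRESETS",
    "AgentParams",
    "TrialRecord",
    "SimulatedSession",
    "ClassificationResult",
    "SessionMetrics",
    "generate_schedule",
    "simulate_session",
    "classify_trials",
    "session_metrics",
]

#: Default extension of the response window beyond stimulus offset (s).
DEFAULT_LH_EXTRA = 2.0
#: Default house-light timeout after failed trials (s).
DEFAULT_TIMEOUT = 5.0
#: Default session length (s): 30-minute sessions.
DEFAULT_SESSION_LENGTH = 1800.0

_POKE_DWELL = 0.25  # how long a snout stays in a hole (s)
_CONSUME_TIME = 1.5  # time spent in the receptacle consuming the reward (s)


@dataclass(frozen=True)
class ChallengeSpec:
    """Parameters of one 5-CSRTT protocol.

    ``iti`` is either a single fixed duration or a finite list of durations
    (variable-ITI challenge) drawn with ``iti_weights`` (uniform if omitted).
    """

    name: str
    iti: float | tuple[float, ...]
    sd: float
    iti_weights: tuple[float, ...] | None = None
    lh_extra: float = DEFAULT_LH_EXTRA
    timeout: float = DEFAULT_TIMEOUT
    session_length: float = DEFAULT_SESSION_LENGTH
    n_holes: int = 5

    def __post_init__(self) -> None:
        itis = self.iti_values
        if len(itis) == 0:
            raise ConfigurationError("ITI list must be non-empty")
        for v in (*itis, self.sd, self.lh_extra, self.timeout, self.session_length):
            if not v > 0:
                raise ConfigurationError(f"{self.name}: all durations must be > 0")
        if self.iti_weights is not None and len(self.iti_weights) != len(itis):
            raise ConfigurationError(f"{self.name}: weights do not match ITI list")

    @property
    def iti_values(self) -> tuple[float, ...]:
        return (self.iti,) if np.isscalar(self.iti) else tuple(self.iti)

    @property
    def response_window(self) -> float:
        """Length of the half-open response window [stim_on, stim_on + SD + LH)."""
        return self.sd + self.lh_extra


#: Named protocols: the training baseline, the fixed-ITI impulsivity
#: challenge (ITI 5 s -> 9 s), the attention challenge (SD 2 s -> 1 s), a
#: combined challenge, and a variable-ITI challenge.  The vITI duration set
#: {2, 5, 7.5, 12.5} s with equal weights is this package's stand-in (the
#: protocol only fixes that ITIs vary trial-to-trial, not the values).
CHALLENGE_PRESETS: dict[str, ChallengeSpec] = {
    "baseline": ChallengeSpec("baseline", iti=5.0, sd=2.0),
    "fiti9": ChallengeSpec("fiti9", iti=9.0, sd=2.0),
    "sd1": ChallengeSpec("sd1", iti=5.0, sd=1.0),
    "combined": ChallengeSpec("combined", iti=7.0, sd=1.0),
    "viti": ChallengeSpec("viti", iti=(2.0, 5.0, 7.5, 12.5), sd=2.0),
}


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a simulated subject.

    ``premature_hazard`` is the rate (events/s) of the Poisson impulse
    process active during the ITI; ``p_detect`` the probability the stimulus
    registers at all, ``p_omit_given_detect`` the probability of withholding
    despite detection, ``accuracy_given_response`` the probability the
    response lands in the lit hole.  Latencies are log-normal with the given
    median (s) and log-scale sigma.  ``drug_multipliers`` maps condition
    names to multiplicative factors on ``premature_hazard``, ``p_omit``,
    ``response_latency`` and ``reward_latency``; the implicit condition
    ``"vehicle"`` applies factor 1 everywhere.
    """

    premature_hazard: float = 0.06
    p_detect: float = 0.95
    p_omit_given_detect: float = 0.08
    accuracy_given_response: float = 0.85
    response_latency_median: float = 0.7
    response_latency_sigma: float = 0.35
    reward_latency_median: float = 1.2
    reward_latency_sigma: float = 0.3
    p_perseverate: float = 0.15
    drug_multipliers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        probs = (
            self.p_detect,
            self.p_omit_given_detect,
            self.accuracy_given_response,
            self.p_perseverate,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.premature_hazard < 0:
            raise ConfigurationError("premature_hazard must be >= 0")
        for cond, mult in self.drug_multipliers.items():
            if any(not f > 0 for f in mult.values()):
                raise ConfigurationError(f"multipliers for {cond!r} must be > 0")

    def under(self, condition: str) -> "AgentParams":
        """Effective parameters under a named drug condition."""
        if condition == "vehicle":
            return self
        if condition not in self.drug_multipliers:
            raise ValueError(f"unknown condition {condition!r}")
        m = self.drug_multipliers[condition]
        return replace(
            self,
            premature_hazard=self.premature_hazard * m.get("premature_hazard", 1.0),
            p_omit_given_detect=min(
                1.0, self.p_omit_given_detect * m.get("p_omit", 1.0)
            ),
            response_latency_median=self.response_latency_median
            * m.get("response_latency", 1.0),
            reward_latency_median=self.reward_latency_median
            * m.get("reward_latency", 1.0),
        )


@dataclass
class TrialRecord:
    """Classified outcome of one trial."""

    index: int
    iti_used: float
    hole: int
    outcome: str  # premature | correct | incorrect | omission
    perseverative: bool = False
    response_latency: float | None = None
    reward_latency: float | None = None


class SimulatedSession(NamedTuple):
    """An event log plus the simulator's hidden ground-truth trials."""

    log: SessionLog
    truth: list[TrialRecord]


class ClassificationResult(NamedTuple):
    """Classified trials plus the count of pokes during timeouts (which
    belong to no trial and are reported separately)."""

    trials: list[TrialRecord]
    timeout_pokes: int


# ---------------------------------------------------------------------------
# Schedules and simulation
# ---------------------------------------------------------------------------


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_schedule(
    spec: ChallengeSpec,
    n_trials_cap: int,
    seed=None,
    no_immediate_repeat: bool = False,
) -> list[tuple[float, int]]:
    """Draw ``(iti, hole)`` pairs for up to ``n_trials_cap`` trials.

    Holes are uniform i.i.d. over 1..n_holes ("pseudo-random" stimulus
    placement); ``no_immediate_repeat`` optionally forbids the same hole
    twice in a row.  Variable ITIs are drawn from the spec's duration list
    with its sampling weights.  Deterministic under a fixed seed.
    """
    rng = _rng(seed)
    itis = np.asarray(spec.iti_values, dtype=float)
    if spec.iti_weights is not None:
        w = np.asarray(spec.iti_weights, dtype=float)
        w = w / w.sum()
    else:
        w = None
    schedule: list[tuple[float, int]] = []
    prev_hole = 0
    for _ in range(n_trials_cap):
        iti = float(itis[0]) if len(itis) == 1 else float(rng.choice(itis, p=w))
        hole = int(rng.integers(1, spec.n_holes + 1))
        if no_immediate_repeat:
            while hole == prev_hole:
                hole = int(rng.integers(1, spec.n_holes + 1))
        prev_hole = hole
        schedule.append((iti, hole))
    return schedule


def _lognormal_truncated(
    rng: np.random.Generator, median: float, sigma: float, upper: float
) -> float:
    """Log-normal draw conditioned on being below ``upper`` (inverse-CDF)."""
    mu = math.log(median)
    if sigma <= 0:
        return min(median, upper * (1 - 1e-9))
    z_upper = (math.log(upper) - mu) / sigma
    from scipy.stats import norm

    u = rng.uniform(0.0, norm.cdf(z_upper))
    return math.exp(mu + sigma * norm.ppf(u))


def simulate_session(
    spec: ChallengeSpec,
    agent: AgentParams,
    condition: str = "vehicle",
    seed=None,
) -> SimulatedSession:
    """Simulate one operant session and return its log with ground truth.

    Each trial races a premature-poke clock (exponential with the agent's
    hazard, truncated at the ITI) against stimulus onset.  If the stimulus
    wins, the agent responds within the half-open window
    ``[stim_on, stim_on + SD + LH)`` with probability
    ``p_detect * (1 - p_omit)``, at a truncated log-normal latency, choosing
    the lit hole with probability ``accuracy_given_response``; otherwise the
    trial is an omission.  Correct trials are rewarded (collection always
    succeeds) and may carry a perseverative re-poke of the correct hole
    before receptacle entry; the next ITI starts at receptacle exit.  All
    failed trials trigger the house-light timeout and the next ITI starts at
    timeout end.  The session admits no new trial at or beyond
    ``session_length``; the final trial runs to completion.
    """
    rng = _rng(seed)
    eff = agent.under(condition)  # raises on unknown condition

    times: list[float] = []
    kinds: list[str] = []
    args: list[int | None] = []

    def emit(t: float, kind: str, arg: int | None = None) -> None:
        times.append(round(t, 6))
        kinds.append(kind)
        args.append(arg)

    truth: list[TrialRecord] = []
    t = 0.0
    index = 0
    while t < spec.session_length:
        iti = (
            float(spec.iti_values[0])
            if len(spec.iti_values) == 1
            else float(
                rng.choice(
                    np.asarray(spec.iti_values),
                    p=None
                    if spec.iti_weights is None
                    else np.asarray(spec.iti_weights) / np.sum(spec.iti_weights),
                )
            )
        )
        hole = int(rng.integers(1, spec.n_holes + 1))
        rec = TrialRecord(index=index, iti_used=iti, hole=hole, outcome="")

        wait = rng.exponential(1.0 / eff.premature_hazard) if eff.premature_hazard > 0 else math.inf
        if wait < iti:
            # premature poke into a random hole during the ITI
            poked = int(rng.integers(1, spec.n_holes + 1))
            t_poke = t + wait
            emit(t_poke, "poke_in", poked)
            emit(t_poke, "timeout_start")
            emit(t_poke + _POKE_DWELL, "poke_out", poked)
            emit(t_poke + spec.timeout, "timeout_end")
            rec.outcome = "premature"
            rec.hole = poked
            t = t_poke + spec.timeout
        else:
            ts = t + iti
            emit(ts, "stim_on", hole)
            emit(ts + spec.sd, "stim_off", hole)
            window = spec.response_window
            responds = rng.random() < eff.p_detect * (1.0 - eff.p_omit_given_detect)
            if responds:
                # keep a 2 ms margin below the window so boundary rounding in
                # logs can never flip a response into an omission
                lat = _lognormal_truncated(
                    rng, eff.response_latency_median, eff.response_latency_sigma,
                    window - 0.002,
                )
                if rng.random() < eff.accuracy_given_response:
                    poked = hole
                else:
                    others = [h for h in range(1, spec.n_holes + 1) if h != hole]
                    poked = int(others[rng.integers(0, len(others))])
                t_in = ts + lat
                t_out = t_in + _POKE_DWELL
                emit(t_in, "poke_in", poked)
                emit(t_out, "poke_out", poked)
                rec.response_latency = lat
                if poked == hole:
                    rec.outcome = "correct"
                    emit(t_out, "reward")
                    rlat = _lognormal_truncated(
                        rng, eff.reward_latency_median, eff.reward_latency_sigma, 60.0
                    )
                    rlat = max(rlat, 0.05)
                    if rng.random() < eff.p_perseverate and rlat > 3 * _POKE_DWELL:
                        # re-poke the correct hole on the way to the receptacle
                        t_p = t_out + 0.4 * rlat
                        emit(t_p, "poke_in", hole)
                        emit(min(t_p + _POKE_DWELL, t_out + rlat - 1e-3), "poke_out", hole)
                        rec.perseverative = True
                    rec.reward_latency = rlat
                    t_rin = t_out + rlat
                    emit(t_rin, "receptacle_in")
                    t_rout = t_rin + _CONSUME_TIME
                    emit(t_rout, "receptacle_out")
                    t = t_rout  # ITI initiated by receptacle exit
                else:
                    rec.outcome = "incorrect"
                    emit(t_in, "timeout_start")
                    emit(t_in + spec.timeout, "timeout_end")
                    t = t_in + spec.timeout
            else:
                rec.outcome = "omission"
                t_end = ts + window
                emit(t_end, "timeout_start")
                emit(t_end + spec.timeout, "timeout_end")
                t = t_end + spec.timeout
        truth.append(rec)
        index += 1
    emit(max(t, spec.session_length), "session_end")

    order = np.argsort(np.asarray(times), kind="stable")
    ev = pd.DataFrame(
        {
            "time_s": np.asarray(times)[order],
            "event": np.asarray(kinds, dtype=object)[order],
            "arg": np.asarray(args, dtype=object)[order],
        }
    )
    return SimulatedSession(SessionLog(ev), truth)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_trials(log: SessionLog, spec: ChallengeSpec) -> ClassificationResult:
    """Replay an event log through the trial state machine.

    States: waiting out the ITI (any 5-hole poke => premature), the response
    window after ``stim_on`` (first poke in the half-open window
    ``[stim_on, stim_on + SD + LH)``: lit hole => correct, other => incorrect;
    none => omission), the post-correct stretch (a re-poke of the correct
    hole before receptacle entry marks the trial perseverative; receptacle
    entry fixes the reward latency as receptacle_in minus the exit from the
    correct hole), and timeouts (pokes there belong to no trial and are
    counted separately).  Receptacle events during the ITI are ignored.
    A trial left unresolved at ``session_end`` is discarded.
    """
    trials: list[TrialRecord] = []
    timeout_pokes = 0
    mode = "iti"
    iti_start = 0.0
    stim_time = math.nan
    lit_hole = -1
    current: TrialRecord | None = None
    correct_out_time: float | None = None
    index = 0

    def new_trial(outcome: str, hole: int, **kw) -> TrialRecord:
        nonlocal index
        rec = TrialRecord(
            index=index,
            iti_used=(stim_time - iti_start) if outcome != "premature" else math.nan,
            hole=hole,
            outcome=outcome,
            **kw,
        )
        trials.append(rec)
        index += 1
        return rec

    for row in log.itertuples():
        t, kind = float(row.time_s), row.event
        arg = int(row.arg) if pd.notna(row.arg) else None
        if kind == "session_end":
            break

        if mode == "iti":
            if kind == "poke_in":
                rec = new_trial("premature", arg)
                rec.iti_used = t - iti_start
                mode = "timeout"
            elif kind == "stim_on":
                stim_time, lit_hole = t, arg
                mode = "window"
            elif kind in ("receptacle_in", "receptacle_out", "poke_out", "stim_off"):
                pass  # receptacle visits during the ITI are ignored; stragglers too
            elif kind == "timeout_start":
                mode = "timeout"
            elif kind in ("timeout_end", "reward"):
                pass
            else:
                raise ClassificationError(
                    f"event {kind!r} at index {row.Index} illegal during ITI"
                )

        elif mode == "window":
            # 1 ms boundary tolerance, matching the log time resolution
            window_end = stim_time + spec.response_window - 1e-3
            if kind == "poke_in" and t < window_end:
                lat = t - stim_time
                if arg == lit_hole:
                    current = new_trial(
                        "correct", lit_hole, response_latency=lat
                    )
                    correct_out_time = None
                    mode = "post_correct"
                else:
                    new_trial("incorrect", arg, response_latency=lat)
                    mode = "timeout"
            elif kind in ("stim_off", "poke_out", "reward"):
                pass
            elif t >= window_end:
                # nothing answered the stimulus: omission, then reprocess
                new_trial("omission", lit_hole)
                if kind == "timeout_start":
                    mode = "timeout"
                elif kind == "stim_on":
                    iti_start = t  # degenerate hand-written log without timeouts
                    stim_time, lit_hole = t, arg
                    mode = "window"
                elif kind == "timeout_end":
                    iti_start = t
                    mode = "iti"
                elif kind == "poke_in":
                    timeout_pokes += 1
                    mode = "timeout"
                else:
                    iti_start = t
                    mode = "iti"
            else:
                raise ClassificationError(
                    f"event {kind!r} at index {row.Index} illegal in response window"
                )

        elif mode == "post_correct":
            assert current is not None
            if kind == "poke_out" and arg == lit_hole and correct_out_time is None:
                correct_out_time = t
            elif kind == "poke_in":
                if arg == lit_hole:
                    current.perseverative = True
                # pokes into other holes before collection belong to no trial
            elif kind == "receptacle_in":
                if correct_out_time is not None:
                    current.reward_latency = t - correct_out_time
                mode = "post_reward"
            elif kind in ("reward", "poke_out", "stim_off"):
                pass
            else:
                raise ClassificationError(
                    f"event {kind!r} at index {row.Index} illegal before reward collection"
                )

        elif mode == "post_reward":
            if kind == "receptacle_out":
                iti_start = t
                current = None
                mode = "iti"
            elif kind in ("poke_in", "poke_out", "receptacle_in", "stim_off", "reward"):
                pass
            else:
                raise ClassificationError(
                    f"event {kind!r} at index {row.Index} illegal during reward consumption"
                )

        elif mode == "timeout":
            if kind == "timeout_end":
                iti_start = t
                mode = "iti"
            elif kind == "poke_in":
                timeout_pokes += 1
            elif kind in ("poke_out", "timeout_start", "stim_off", "receptacle_in", "receptacle_out"):
                pass
            elif kind == "stim_on":
                # tolerant path for logs without explicit timeout_end
                stim_time, lit_hole = t, arg
                mode = "window"
            else:
                raise ClassificationError(
                    f"event {kind!r} at index {row.Index} illegal during timeout"
                )

    # a stimulus whose window expired with no further events is an omission
    if mode == "window" and len(log):
        last_t = float(log.events["time_s"].iloc[-1])
        if last_t >= stim_time + spec.response_window - 1e-3:
            new_trial("omission", lit_hole)
    return ClassificationResult(trials, timeout_pokes)


# ---------------------------------------------------------------------------
# Session metrics
# ---------------------------------------------------------------------------


@dataclass
class SessionMetrics:
    """The paper-standard per-session performance indicators.

    Percentages follow the field's formulas: %premature and %omissions are
    relative to the number of trials (which includes premature trials),
    accuracy to correct + incorrect responses, %perseverative to correct
    responses.  Ratios with a zero denominator are ``None`` (absent), never 0.
    """

    n_trials: int
    n_premature: int
    n_correct: int
    n_incorrect: int
    n_omissions: int
    n_perseverative: int
    pct_premature: float | None
    accuracy: float | None
    pct_omissions: float | None
    pct_perseverative: float | None
    response_latency_mean: float | None
    response_latency_median: float | None
    reward_latency_mean: float | None
    reward_latency_median: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _agg(values: list[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    arr = np.asarray(values)
    return float(arr.mean()), float(np.median(arr))


def session_metrics(trials: Sequence[TrialRecord]) -> SessionMetrics:
    """Compute the standard 5-CSRTT indicators from classified trials."""
    n = len(trials)
    n_prem = sum(t.outcome == "premature" for t in trials)
    n_corr = sum(t.outcome == "correct" for t in trials)
    n_inc = sum(t.outcome == "incorrect" for t in trials)
    n_omit = sum(t.outcome == "omission" for t in trials)
    n_pers = sum(t.perseverative for t in trials if t.outcome == "correct")
    resp_mean, resp_med = _agg(
        [t.response_latency for t in trials if t.response_latency is not None]
    )
    rew_mean, rew_med = _agg(
        [t.reward_latency for t in trials if t.reward_latency is not None]
    )
    return SessionMetrics(
        n_trials=n,
        n_premature=n_prem,
        n_correct=n_corr,
        n_incorrect=n_inc,
        n_omissions=n_omit,
        n_perseverative=n_pers,
        pct_premature=_pct(n_prem, n),
        accuracy=_pct(n_corr, n_corr + n_inc),
        pct_omissions=_pct(n_omit, n),
        pct_perseverative=_pct(n_pers, n_corr),
        response_latency_mean=resp_mean,
        response_latency_median=resp_med,
        reward_latency_mean=rew_mean,
        reward_latency_median=rew_med,
    )
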
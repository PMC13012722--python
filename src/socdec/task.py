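"""Risky social-decision task: trial schedules, partner policy, outcome resolution.

Each trial offers a safe amount versus a two-outcome lottery with equiprobable
outcomes, in one of three conditions: ``solo`` (the participant chooses, the
outcome affects only themselves), ``social`` (the participant chooses for both
players), and ``partner`` (the partner — an expected-value-maximising policy —
chooses for both). When the lottery is chosen in a two-player condition it is
played out independently for each player. All amounts are integer cents.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("solo", "social", "partner")
TRIAL_CLASSES = ("mixed", "gain", "loss")

# Amount sets. Gain/loss lotteries multiply the safe amount; mixed lotteries
# multiply the gain amount of the lottery by a negative factor to get the loss.
GAIN_SAFE = (10, 15, 20, 25, 30)
GAIN_MULT = (1.68, 1.82, 2.0, 2.22, 2.48, 2.8, 3.16, 3.6, 4.2, 5.0)
LOSS_SAFE = tuple(-a for a in GAIN_SAFE)
LOSS_MULT = GAIN_MULT
MIXED_GAIN = (15, 25, 40, 55, 75)
MIXED_MULT = (-0.2, -0.34, -0.5, -0.64, -0.77, -0.89, -1.0, -1.1, -1.35, -2.0)

MAX_CONDITION_RUN = 2


def round_cents(x: float) -> int:
    """Round half away from zero, so negated amounts mirror exactly."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class TrialSpec:
    """One choice problem: a safe amount versus an equiprobable lottery."""

    index: int                # 1-based within session
    condition: str            # solo | social | partner
    trial_class: str          # mixed | gain | loss
    safe_amount: int          # cents
    lottery_high: int         # cents
    lottery_low: int          # cents
    safe_side: str = "left"   # screen side of the safe option; recorded, unused

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.trial_class not in TRIAL_CLASSES:
            raise ValueError(f"unknown trial_class {self.trial_class!r}")
        if not self.lottery_high > self.lottery_low:
            raise ValueError(
                f"trial {self.index}: lottery_high ({self.lottery_high}) must "
                f"exceed lottery_low ({self.lottery_low})"
            )


@dataclass(frozen=True)
class TrialRecord:
    """A resolved trial: who chose, what was chosen, realised outcomes."""

    spec: TrialSpec
    chooser: str              # participant | partner
    chose_risky: bool
    s_outcome: int            # participant outcome, cents
    p_outcome: int | None     # partner outcome, cents; None in solo


@dataclass
class SessionSchedule:
    trials: list[TrialSpec]
    rating_trials: frozenset[int] = field(default_factory=frozenset)

    def __len__(self):
        return len(self.trials)


@dataclass(frozen=True)
class SessionConfig:
    """Per-session counts. Defaults match the study: 60 trials, 20 per class,
    equal condition counts, a happiness probe every two trials."""

    n_per_class: int = 20
    conditions: tuple[str, ...] = CONDITIONS
    probe_every: int = 2
    max_run: int = MAX_CONDITION_RUN
    max_attempts: int = 10_000

    @property
    def n_trials(self) -> int:
        return self.n_per_class * len(TRIAL_CLASSES)


def compute_evdiff(trial: TrialSpec) -> float:
    """Expected value of the lottery minus the safe amount, in cents."""
    return (trial.lottery_high + trial.lottery_low) / 2.0 - trial.safe_amount


def partner_choice(trial: TrialSpec) -> str:
    """EV-maximising partner policy: lottery iff EVdiff strictly positive."""
    return "risky" if compute_evdiff(trial) > 0 else "safe"


def _draw_amounts(trial_class: str, rng: np.random.Generator) -> tuple[int, int, int]:
    """(safe, high, low) for one trial; draws are i.i.d. uniform over the sets."""
    if trial_class == "gain":
        safe = int(rng.choice(GAIN_SAFE))
        high = round_cents(safe * float(rng.choice(GAIN_MULT)))
        return safe, high, 0
    if trial_class == "loss":
        safe = int(rng.choice(LOSS_SAFE))
        low = round_cents(safe * float(rng.choice(LOSS_MULT)))
        return safe, 0, low
    high = int(rng.choice(MIXED_GAIN))
    low = round_cents(high * float(rng.choice(MIXED_MULT)))
    return 0, high, low


def _max_run_length(seq) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _sequence_conditions(config: SessionConfig, rng: np.random.Generator) -> list[str]:
    """Random order of conditions with no run longer than config.max_run.

    Rejection-sampling of permutations; fails loudly if the constraint set is
    infeasible for the requested counts rather than silently relaxing it.
    """
    n_cond = len(config.conditions)
    if config.n_trials % n_cond:
        raise ValueError(
            f"{config.n_trials} trials cannot be split evenly over "
            f"{n_cond} conditions"
        )
    per_cond = config.n_trials // n_cond
    # A run-length-limited arrangement needs no symbol to exceed
    # max_run * ceil((n - count + 1) / 1)... cheap necessary check:
    if per_cond > config.max_run * (config.n_trials - per_cond + 1):
        raise ValueError("condition counts cannot satisfy the run-length rule")
    base = [c for c in config.conditions for _ in range(per_cond)]
    for _ in range(config.max_attempts):
        order = list(rng.permutation(base))
        if _max_run_length(order) <= config.max_run:
            return order
    raise RuntimeError(
        f"no valid condition sequence found in {config.max_attempts} attempts; "
        "constraint set may be infeasible"
    )


def generate_session(config: SessionConfig | None = None,
                     seed: int | np.random.Generator = 0) -> SessionSchedule:
    """Generate one session schedule; identical (config, seed) reproduce it."""
    config = config or SessionConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = _sequence_conditions(config, rng)
    classes = [c for c in TRIAL_CLASSES for _ in range(config.n_per_class)]
    classes = list(rng.permutation(classes))
    trials = []
    for i, (cond, tclass) in enumerate(zip(conditions, classes), start=1):
        safe, high, low = _draw_amounts(tclass, rng)
        side = "left" if rng.random() < 0.5 else "right"
        trials.append(TrialSpec(index=i, condition=cond, trial_class=tclass,
                                safe_amount=safe, lottery_high=high,
                                lottery_low=low, safe_side=side))
    probes = frozenset(range(config.probe_every, config.n_trials + 1,
                             config.probe_every))
    return SessionSchedule(trials=trials, rating_trials=probes)


def resolve_trial(trial: TrialSpec, chooser: str, chose_risky: bool,
                  rng: np.random.Generator) -> TrialRecord:
    """Play out a choice. Risky outcomes are independent fair draws per player."""
    if trial.condition == "partner" and chooser != "partner":
        raise ValueError(
            f"trial {trial.index}: partner-condition trials are chosen by the "
            f"partner, got chooser={chooser!r}"
        )
    if trial.condition in ("solo", "social") and chooser != "participant":
        raise ValueError(
            f"trial {trial.index}: {trial.condition}-condition trials are "
            f"chosen by the participant, got chooser={chooser!r}"
        )
    has_partner = trial.condition != "solo"
    if not chose_risky:
        s_out = trial.safe_amount
        p_out = trial.safe_amount if has_partner else None
    else:
        s_out = trial.lottery_high if rng.random() < 0.5 else trial.lottery_low
        if has_partner:
            p_out = trial.lottery_high if rng.random() < 0.5 else trial.lottery_low
        else:
            p_out = None
    return TrialRecord(spec=trial, chooser=chooser, chose_risky=chose_risky,
                       s_outcome=s_out, p_outcome=p_out)


# ---------------------------------------------------------------------------
# Tabular views (CSV-ready; amounts in integer cents, lowercase categoricals)

TRIAL_COLUMNS = [
    "session", "trial", "condition", "trial_class", "safe_amount",
    "lottery_high", "lottery_low", "safe_side", "chooser", "chose_risky",
    "s_outcome", "p_outcome",
]


def records_to_frame(records: list[TrialRecord], session: int = 1) -> pd.DataFrame:
    rows = []
    for r in records:
        t = r.spec
        rows.append({
            "session": session, "trial": t.index, "condition": t.condition,
            "trial_class": t.trial_class, "safe_amount": t.safe_amount,
            "lottery_high": t.lottery_high, "lottery_low": t.lottery_low,
            "safe_side": t.safe_side, "chooser": r.chooser,
            "chose_risky": int(r.chose_risky), "s_outcome": r.s_outcome,
            "p_outcome": float("nan") if r.p_outcome is None else r.p_outcome,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def schedule_to_frame(schedule: SessionSchedule, session: int = 1) -> pd.DataFrame:
    rows = [{
        "session": session, "trial": t.index, "condition": t.condition,
        "trial_class": t.trial_class, "safe_amount": t.safe_amount,
        "lottery_high": t.lottery_high, "lottery_low": t.lottery_low,
        "safe_side": t.safe_side,
        "rating_probe": int(t.index in schedule.rating_trials),
    } for t in schedule.trials]
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`records_to_frame` for one session's rows."""
    records = []
    for _, row in df.iterrows():
        spec = TrialSpec(index=int(row["trial"]), condition=row["condition"],
                         trial_class=row["trial_class"],
                         safe_amount=int(row["safe_amount"]),
                         lottery_high=int(row["lottery_high"]),
                         lottery_low=int(row["lottery_low"]),
                         safe_side=row.get("safe_side", "left"))
        p_out = row["p_outcome"]
        records.append(TrialRecord(
            spec=spec, chooser=row["chooser"],
            chose_risky=bool(row["chose_risky"]),
            s_outcome=int(row["s_outcome"]),
            p_outcome=None if pd.isna(p_out) else int(p_out)))
    return records
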
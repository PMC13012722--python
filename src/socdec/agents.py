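"""Synthetic participants: choice policies and generative happiness ratings.

Agents invert the estimation models downstream: choices follow either a
logistic policy on the lottery/safe expected-value difference or a CARA
expected-utility policy with Fechner noise, and momentary happiness is
produced by one of the generative happiness models plus Gaussian noise.
A cohort generator produces fully seeded multi-session datasets with the
true parameters recorded for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import task
from .happiness import build_event_matrix, decayed_design, model_regressors
from .risk import cara_certainty_equivalent, cara_choice_prob


@dataclass
class AgentParams:
    """Generative parameters of one synthetic participant.

    ``noise_scale`` is relative: the rating noise SD equals ``noise_scale``
    times the SD of the agent's noise-free predicted ratings, so 1.0
    reproduces the "one SD of noise" convention used for parameter recovery.
    """

    choice_model: str = "logistic"        # logistic | cara
    beta0: float = 0.0                    # logistic intercept
    beta1: float = 0.074                  # logistic slope on EVdiff (1/cent)
    rho: float = 0.0                      # CARA coefficient (1/cent)
    sigma: float = 10.0                   # Fechner noise (cents)
    happiness_model: str = "responsibility_redux"
    weights: dict[str, float] = field(default_factory=dict)
    gamma: float = 0.42
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.choice_model not in ("logistic", "cara"):
            raise ValueError(f"unknown choice model {self.choice_model!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class ParticipantData:
    pid: int
    params: AgentParams
    trials: pd.DataFrame      # all sessions, one row per trial
    ratings: pd.DataFrame     # session, trial, rating (latent scale)


@dataclass
class SyntheticDataset:
    participants: list[ParticipantData]

    def __len__(self):
        return len(self.participants)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            d = asdict(p.params)
            weights = d.pop("weights")
            d.update({f"w_{k}": v for k, v in weights.items()})
            d["participant"] = p.pid
            rows.append(d)
        return pd.DataFrame(rows)


def choice_probability(trial: task.TrialSpec, agent: AgentParams) -> float:
    """P(choose lottery) for a participant-choice trial under the agent."""
    if agent.choice_model == "logistic":
        from scipy.special import expit
        z = agent.beta0 + agent.beta1 * task.compute_evdiff(trial)
        return float(expit(z))
    ce = cara_certainty_equivalent(trial.lottery_high, trial.lottery_low, 0.5,
                                   agent.rho)
    return cara_choice_prob(ce, trial.safe_amount, agent.sigma)


def simulate_choices(schedule: task.SessionSchedule, agent: AgentParams,
                     rng: np.random.Generator) -> list[task.TrialRecord]:
    """Resolve every trial of a session under the agent's choice policy.

    Partner-condition trials follow the EV-maximising partner policy; on
    participant-choice trials the probability of the risky option follows the
    agent's choice model.
    """
    records = []
    for trial in schedule.trials:
        if trial.condition == "partner":
            chooser = "partner"
            risky = task.partner_choice(trial) == "risky"
        else:
            chooser = "participant"
            risky = rng.random() < choice_probability(trial, agent)
        records.append(task.resolve_trial(trial, chooser, risky, rng))
    return records


def simulate_happiness(records: pd.DataFrame | list, agent: AgentParams,
                       rng: np.random.Generator,
                       rating_trials=None) -> pd.DataFrame:
    """Generative happiness ratings at probe trials (latent scale).

    Rating at a probe following trial t is the happiness-model prediction
    from decayed event sums over trials 1..t (decay restarts each session)
    plus Gaussian noise scaled to the SD of the noise-free predictions.
    """
    if not isinstance(records, pd.DataFrame):
        records = task.records_to_frame(records)
        if rating_trials is None:
            raise ValueError("rating_trials required with record lists")
        records = records.assign(
            rating_probe=[int(t in rating_trials) for t in records["trial"]])
    if "rating_probe" not in records.columns:
        raise ValueError("records need a rating_probe column")
    regressors = model_regressors(agent.happiness_model)
    stray = {r for r, v in agent.weights.items()
             if r not in regressors and v != 0.0}
    if stray:
        raise ValueError(
            f"weights {sorted(stray)} are not regressors of the "
            f"{agent.happiness_model!r} model")
    w = np.array([agent.weights.get(r, 0.0) for r in regressors])
    events = build_event_matrix(records)
    preds, keys = [], []
    for session, ev in events.groupby("session", sort=True):
        sess_trials = records.loc[records["session"] == session]
        probes = sorted(int(t) for t in
                        sess_trials.loc[sess_trials["rating_probe"] == 1, "trial"])
        X = ev.sort_values("trial")[list(regressors)].to_numpy(dtype=float)
        D = decayed_design(X, agent.gamma, probes)
        preds.append(D @ w)
        keys.extend((session, t) for t in probes)
    latent = np.concatenate(preds) if preds else np.empty(0)
    sd = float(np.std(latent, ddof=1)) if len(latent) > 1 else 0.0
    noise_sd = agent.noise_scale * sd
    ratings = latent + (rng.normal(0.0, noise_sd, size=latent.shape)
                        if noise_sd > 0 else 0.0)
    out = pd.DataFrame(keys, columns=["session", "trial"])
    out["rating"] = ratings
    return out


# ---------------------------------------------------------------------------
# Cohort generation

#: Population means of the generative parameters.  Magnitudes are set to the
#: scale of the study: EVdiff choice slope 0.074 per cent (the cohort-level
#: manipulation-check coefficient), a small positive risk premium, forgetting
#: factor near 0.42, and happiness weights ordered sRPE > CR ~ EV >
#: social_pRPE > partner_pRPE with inequality aversion negative.
DEFAULT_POPULATION = {
    "beta1_mean": 0.074, "beta1_sd": 0.02, "beta1_min": 0.01,
    "premium_mean": 2.0, "premium_sd": 4.0,          # cents
    "gamma_mean": 0.42, "gamma_sd": 0.06,
    "noise_scale": 1.0,
    "weights_mean": {
        "CR": 0.015, "EV": 0.012, "sRPE": 0.020,
        "abs_ineq": -0.005, "adv_ineq": -0.003, "disadv_ineq": -0.008,
        "social_pRPE": 0.010, "partner_pRPE": 0.005,
    },
    "weights_rel_sd": 0.4,     # SD as a fraction of the mean magnitude
}


def default_param_sampler(model: str = "responsibility_redux",
                          overrides: dict | None = None):
    """Sampler of per-participant AgentParams around the population defaults.

    ``overrides`` may replace any DEFAULT_POPULATION entry (e.g. a weight
    mean of 0 to generate null cohorts, or ``weights_rel_sd: 0`` for a
    degenerate sampler in which all agents share the same parameters).
    """
    pop = {**DEFAULT_POPULATION, **(overrides or {})}
    if "weights_mean" in (overrides or {}):
        merged = {**DEFAULT_POPULATION["weights_mean"],
                  **overrides["weights_mean"]}
        pop["weights_mean"] = merged
    regressors = model_regressors(model)

    def sample(rng: np.random.Generator) -> AgentParams:
        beta1 = max(rng.normal(pop["beta1_mean"], pop["beta1_sd"]),
                    pop["beta1_min"])
        premium = rng.normal(pop["premium_mean"], pop["premium_sd"])
        gamma = float(np.clip(rng.normal(pop["gamma_mean"], pop["gamma_sd"]),
                              0.02, 0.95))
        weights = {}
        for r in regressors:
            mu = pop["weights_mean"][r]
            weights[r] = rng.normal(mu, abs(mu) * pop["weights_rel_sd"])
        return AgentParams(choice_model="logistic", beta0=-premium * beta1,
                           beta1=beta1, happiness_model=model,
                           weights=weights, gamma=gamma,
                           noise_scale=pop["noise_scale"])

    return sample


def simulate_cohort(n: int = 40, sessions: int = 3,
                    param_sampler=None, seed: int = 0,
                    session_config: task.SessionConfig | None = None
                    ) -> SyntheticDataset:
    """Simulate a cohort of n agents over the given number of sessions.

    Every stochastic stream is derived from ``seed``; identical arguments
    reproduce the dataset exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = param_sampler or default_param_sampler()
    config = session_config or task.SessionConfig()
    root = np.random.SeedSequence(seed)
    participants = []
    for pid, ss in enumerate(root.spawn(n), start=1):
        rng = np.random.default_rng(ss)
        params = sampler(rng)
        frames, rating_frames = [], []
        for s in range(1, sessions + 1):
            schedule = task.generate_session(config, rng)
            records = simulate_choices(schedule, params, rng)
            df = task.records_to_frame(records, session=s)
            df["rating_probe"] = [int(t in schedule.rating_trials)
                                  for t in df["trial"]]
            ratings = simulate_happiness(df, params, rng)
            frames.append(df)
            rating_frames.append(ratings)
        participants.append(ParticipantData(
            pid=pid, params=params,
            trials=pd.concat(frames, ignore_index=True),
            ratings=pd.concat(rating_frames, ignore_index=True)))
    return SyntheticDataset(participants=participants)
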
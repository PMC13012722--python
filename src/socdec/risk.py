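"""Risk-attitude estimation from safe-versus-lottery choices.

Two complementary estimators per participant and condition:

* **Risk premium** — a logistic regression of risky choice on the
  expected-value difference ``EVdiff = EV(lottery) - safe``; the premium is
  the EVdiff at which the fitted curve crosses 50%, ``-beta0/beta1``.
  Positive premiums indicate risk aversion.
* **CARA / Fechner** — constant-absolute-risk-aversion expected utility with
  normalized exponential utility ``U(x) = (1 - exp(-rho*x)) / rho``; the
  certainty equivalent ``CE = log(1 - rho*EU) / (-rho)`` enters a probit
  choice rule ``P(risky) = Phi((CE - safe) / sigma)`` with Fechner noise
  ``sigma``, fitted by non-linear least squares.

A mixed-effects logistic manipulation check (random intercept and slopes per
participant) is fitted by maximum likelihood with Laplace approximation via
lme4's ``glmer``.
"""
from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

RHO_BOUNDS = (-0.1, 0.1)            # keeps 1 - rho*EU > 0 over task payoffs
SIGMA_BOUNDS = (1e-3, 1e3)


# ---------------------------------------------------------------------------
# Logistic choice fit and risk premium

def fit_choice_logistic(evdiff, chose_risky):
    """ML logistic fit of risky choice on EVdiff -> (beta0, beta1, converged).

    Single-class data or complete separation yield ``converged=False`` with
    NaN coefficients (the premium is then undefined).
    """
    import statsmodels.api as sm

    evdiff = np.asarray(evdiff, dtype=float)
    chose = np.asarray(chose_risky, dtype=float)
    if evdiff.shape != chose.shape:
        raise ValueError("evdiff and chose_risky must have equal length")
    if len(evdiff) < 2 or len(np.unique(chose)) < 2:
        return float("nan"), float("nan"), False
    X = sm.add_constant(evdiff)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(chose, X).fit(disp=0, maxiter=200)
        b0, b1 = res.params
        converged = bool(res.mle_retvals.get("converged", False))
        # complete separation shows up as diverging coefficients
        if not np.all(np.isfinite(res.params)) or abs(b1) > 1e3:
            return float("nan"), float("nan"), False
        return float(b0), float(b1), converged
    except Exception:
        return float("nan"), float("nan"), False


def risk_premium(beta0: float, beta1: float) -> float:
    """EVdiff at 50% risky choice, ``-beta0/beta1``; requires beta1 > 0."""
    if not beta1 > 0:
        raise ValueError(f"risk premium undefined for beta1={beta1!r} <= 0")
    return -beta0 / beta1


# ---------------------------------------------------------------------------
# CARA expected utility

def cara_utility(x, rho: float):
    """Normalized CARA utility (1 - exp(-rho*x))/rho; rho -> 0 limit is x."""
    x = np.asarray(x, dtype=float)
    if abs(rho) < 1e-12:
        return x
    return -np.expm1(-rho * x) / rho


def cara_expected_utility(x1, x2, p: float, rho: float):
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return p * cara_utility(x1, rho) + (1.0 - p) * cara_utility(x2, rho)


def cara_certainty_equivalent(x1, x2, p: float = 0.5, rho: float = 0.0):
    """Sure amount with the same utility as the lottery (x1 w.p. p, else x2).

    Continuous at rho=0 where CE equals the expected value.  Raises if the
    log argument 1 - rho*EU is not positive (cannot occur for payoffs within
    the task range and rho within RHO_BOUNDS, but guarded explicitly).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if abs(rho) < 1e-12:
        return p * x1 + (1.0 - p) * x2
    eu = cara_expected_utility(x1, x2, p, rho)
    arg = 1.0 - rho * eu
    if np.any(arg <= 0):
        raise ValueError(
            f"certainty equivalent undefined: 1 - rho*EU <= 0 for rho={rho}, "
            f"EU={eu}")
    return np.log(arg) / (-rho)


def cara_choice_prob(ce, vs, sigma: float):
    """Probit choice rule 0.5*(1 + erf((CE - VS)/(sqrt(2)*sigma)))."""
    if not sigma > 0:
        raise ValueError(f"Fechner noise sigma must be > 0, got {sigma}")
    return special.ndtr((np.asarray(ce, dtype=float) - vs) / sigma)


def fit_cara(lottery_high, lottery_low, safe, chose_risky, p: float = 0.5,
             min_trials: int = 10, se_floor: float = 0.02):
    """Least-squares fit of (rho, sigma) -> (rho, sigma, reliable).

    Minimises squared residuals between observed choices (0/1) and the probit
    choice probability, with multi-start over rho and sigma.  ``reliable`` is
    False when trials are too few or one-sided, the optimiser fails or ends
    on the rho bounds, or SE(rho) exceeds ``|rho| + se_floor``.
    """
    hi = np.asarray(lottery_high, dtype=float)
    lo = np.asarray(lottery_low, dtype=float)
    vs = np.asarray(safe, dtype=float)
    chose = np.asarray(chose_risky, dtype=float)
    n = len(chose)
    if n < min_trials or len(np.unique(chose)) < 2:
        return float("nan"), float("nan"), False

    def residuals(theta):
        rho, sigma = theta
        ce = cara_certainty_equivalent(hi, lo, p, rho)
        return cara_choice_prob(ce, vs, sigma) - chose

    best = None
    for rho0 in (-0.02, 0.0, 0.02):
        for sigma0 in (5.0, 20.0):
            try:
                res = optimize.least_squares(
                    residuals, x0=[rho0, sigma0],
                    bounds=([RHO_BOUNDS[0], SIGMA_BOUNDS[0]],
                            [RHO_BOUNDS[1], SIGMA_BOUNDS[1]]))
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        return float("nan"), float("nan"), False
    rho, sigma = best.x
    reliable = True
    eps = 1e-6
    if rho <= RHO_BOUNDS[0] + eps or rho >= RHO_BOUNDS[1] - eps:
        reliable = False
    # Gauss-Newton covariance for SE(rho)
    try:
        J = best.jac
        dof = max(n - 2, 1)
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.inv(J.T @ J)
        se_rho = float(np.sqrt(cov[0, 0]))
        if not np.isfinite(se_rho) or se_rho > abs(rho) + se_floor:
            reliable = False
    except np.linalg.LinAlgError:
        reliable = False
    return float(rho), float(sigma), reliable


# ---------------------------------------------------------------------------
# Per-participant profiles and condition comparison

@dataclass
class RiskProfile:
    """Risk attitude of one participant in one condition."""

    participant: int
    condition: str
    n_trials: int
    beta0: float
    beta1: float
    converged: bool
    risk_premium: float       # NaN when undefined
    rho: float
    sigma: float
    reliable: bool


def fit_risk_profile(trials: pd.DataFrame, participant: int,
                     condition: str) -> RiskProfile:
    """Fit both risk measures to one participant's choices in a condition.

    Uses participant-choice trials only (solo/social); gain and loss trials
    are pooled.
    """
    sub = trials[(trials["condition"] == condition)
                 & (trials["chooser"] == "participant")]
    evdiff = ((sub["lottery_high"] + sub["lottery_low"]) / 2.0
              - sub["safe_amount"]).to_numpy()
    chose = sub["chose_risky"].to_numpy()
    b0, b1, converged = fit_choice_logistic(evdiff, chose)
    premium = float("nan")
    if converged and b1 > 0:
        premium = risk_premium(b0, b1)
    rho, sigma, reliable = fit_cara(sub["lottery_high"], sub["lottery_low"],
                                    sub["safe_amount"], chose)
    return RiskProfile(participant=participant, condition=condition,
                       n_trials=len(sub), beta0=b0, beta1=b1,
                       converged=converged, risk_premium=premium,
                       rho=rho, sigma=sigma, reliable=reliable)


def cohort_risk_profiles(dataset, conditions=("solo", "social")) -> pd.DataFrame:
    rows = []
    for part in dataset.participants:
        for cond in conditions:
            prof = fit_risk_profile(part.trials, part.pid, cond)
            rows.append(prof.__dict__)
    return pd.DataFrame(rows)


@dataclass
class PairedComparison:
    n: int
    t: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    valid: bool


def compare_conditions(values_a, values_b) -> PairedComparison:
    """Two-tailed paired t-test with Cohen's d on paired per-participant
    values (e.g. risk premium in solo vs social)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if diff.mean() == 0:      # identical vectors: no difference at all
            return PairedComparison(n=len(a), t=0.0, df=len(a) - 1, p=1.0,
                                    cohens_d=0.0, mean_diff=0.0, valid=True)
        return PairedComparison(n=len(a), t=float("nan"), df=len(a) - 1,
                                p=float("nan"), cohens_d=float("nan"),
                                mean_diff=float(diff.mean()), valid=False)
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(n=len(a), t=float(t), df=len(a) - 1,
                            p=float(p), cohens_d=float(diff.mean() / sd),
                            mean_diff=float(diff.mean()), valid=True)


# ---------------------------------------------------------------------------
# Mixed-effects logistic manipulation check (lme4 glmer bridge)

_GLMM_R_TEMPLATE = """
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
d <- read.csv("{csv}")
m <- glmer(chose_risky ~ evdiff_c * cond_c + (1 + evdiff_c + cond_c || participant),
           data = d, family = binomial)
fe <- summary(m)$coefficients
msgs <- unlist(m@optinfo$conv$lme4$messages)
serious <- msgs[!grepl("boundary (singular)", msgs, fixed = TRUE)]
out <- list(terms = rownames(fe), estimate = fe[, 1], se = fe[, 2],
            z = fe[, 3], p = fe[, 4],
            converged = length(serious) == 0,
            singular = isSingular(m),
            messages = if (length(msgs)) msgs else character(0))
writeLines(toJSON(out, digits = 12, auto_unbox = TRUE), "{json}")
"""


def fit_choice_glmm(trials: pd.DataFrame, timeout: int = 300) -> pd.DataFrame:
    """Mixed-effects logistic regression of risky choice on mean-centred
    EVdiff, condition (solo=1, social=2) and their interaction, with
    per-participant random intercepts and uncorrelated random slopes.

    Fitted by glmer (ML with Laplace approximation).  ``trials`` needs
    columns participant, condition, chooser, lottery_high, lottery_low,
    safe_amount, chose_risky; only solo/social participant-choice rows are
    used.  Returns a tidy coefficient table.
    """
    sub = trials[trials["condition"].isin(("solo", "social"))
                 & (trials["chooser"] == "participant")].copy()
    if sub.empty or sub["participant"].nunique() < 2:
        raise ValueError("need participant-choice trials from >= 2 participants")
    sub["evdiff"] = ((sub["lottery_high"] + sub["lottery_low"]) / 2.0
                     - sub["safe_amount"])
    sub["cond"] = np.where(sub["condition"] == "solo", 1.0, 2.0)
    sub["evdiff_c"] = sub["evdiff"] - sub["evdiff"].mean()
    sub["cond_c"] = sub["cond"] - sub["cond"].mean()
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "choices.csv"
        out = Path(tmp) / "glmm.json"
        sub[["participant", "chose_risky", "evdiff_c", "cond_c"]].to_csv(
            csv, index=False)
        script = Path(tmp) / "glmm.R"
        script.write_text(_GLMM_R_TEMPLATE.format(csv=csv, json=out))
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True, timeout=timeout)
        if proc.returncode != 0 or not out.exists():
            raise RuntimeError(
                f"glmer fit failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}")
        res = json.loads(out.read_text())
    table = pd.DataFrame({
        "term": res["terms"], "beta": res["estimate"], "se": res["se"],
        "z": res["z"], "p": res["p"],
    })
    table.attrs["converged"] = bool(res["converged"])
    table.attrs["singular"] = bool(res.get("singular", False))
    table.attrs["messages"] = res.get("messages", [])
    n = len(sub)
    k = len(table)
    table["df"] = n - k
    return table
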
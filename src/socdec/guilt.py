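"""Guilt-effect inference from post-lottery happiness.

The guilt effect is the drop in a participant's momentary happiness after the
partner receives the low lottery outcome when the participant, rather than
the partner, chose the lottery.  This module builds the post-lottery table
(Z-scored happiness after lottery outcomes in the social and partner
conditions), fits the linear mixed model

    z ~ sHigh + pHigh + sDec + sHigh:pHigh + sHigh:sDec + pHigh:sDec
        + (1 | participant)

by REML, computes per-participant guilt-effect contrasts within each
self-outcome stratum with paired t-tests, Cohen's d and default-prior (JZS)
Bayes factors, the agency effect, and the paired-t power / sample-size
computation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .happiness import zscore

GUILT_FIXED_TERMS = ["Intercept", "sHigh", "pHigh", "sDec", "sHigh:pHigh",
                     "sHigh:sDec", "pHigh:sDec"]


def _zscored_probe_table(dataset) -> pd.DataFrame:
    """All probes of all participants, Z-scored per participant, joined with
    the trial whose outcome immediately precedes the probe."""
    frames = []
    for part in dataset.participants:
        ratings = part.ratings.sort_values(["session", "trial"]).copy()
        ratings["z_happiness"] = zscore(ratings["rating"].to_numpy())
        merged = ratings.merge(part.trials, on=["session", "trial"],
                               how="left", validate="one_to_one")
        if merged["condition"].isna().any():
            bad = merged.loc[merged["condition"].isna(), ["session", "trial"]]
            raise ValueError(
                f"participant {part.pid}: ratings at {bad.values.tolist()} "
                "have no matching trial record")
        merged.insert(0, "participant", part.pid)
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def build_post_lottery_table(dataset) -> pd.DataFrame:
    """One row per qualifying probe: the most recent outcome before the probe
    was a lottery outcome in the social or partner condition.

    Columns: participant, z_happiness, sHigh, pHigh, sDec (sDec=1 iff the
    participant chose, i.e. the social condition).
    """
    probes = _zscored_probe_table(dataset)
    rows = probes[probes["condition"].isin(("social", "partner"))
                  & (probes["chose_risky"] == 1)].copy()
    rows["sHigh"] = (rows["s_outcome"] == rows["lottery_high"]).astype(int)
    rows["pHigh"] = (rows["p_outcome"] == rows["lottery_high"]).astype(int)
    rows["sDec"] = (rows["condition"] == "social").astype(int)
    return rows[["participant", "session", "trial", "condition",
                 "z_happiness", "sHigh", "pHigh", "sDec"]].reset_index(drop=True)


def _mixedlm_fit(formula: str, data: pd.DataFrame):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["participant"])
        res = model.fit(reml=True)
    return res


def _tidy_mixedlm(res, n_obs: int) -> pd.DataFrame:
    fe = res.fe_params
    se = res.bse_fe
    df = n_obs - len(fe)          # residual-df convention for reported t
    rows = []
    for term in fe.index:
        t = fe[term] / se[term]
        rows.append({"term": term, "beta": float(fe[term]),
                     "se": float(se[term]), "t": float(t), "df": df,
                     "p": float(2 * stats.t.sf(abs(t), df))})
    table = pd.DataFrame(rows)
    sing = bool(np.any(np.diag(np.atleast_2d(res.cov_re)) < 1e-8))
    table.attrs["converged"] = bool(res.converged)
    table.attrs["singular"] = sing
    if sing:
        warnings.warn("random-effects variance estimated at zero "
                      "(singular fit)", RuntimeWarning, stacklevel=3)
    return table


def fit_guilt_lmm(rows: pd.DataFrame) -> pd.DataFrame:
    """REML linear mixed model of post-lottery happiness with participant
    random intercepts; returns the tidy fixed-effect table."""
    if rows["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    for col in ("sHigh", "pHigh", "sDec"):
        if rows[col].nunique() < 2:
            raise ValueError(f"predictor {col} is constant")
    res = _mixedlm_fit(
        "z_happiness ~ sHigh + pHigh + sDec + sHigh:pHigh + sHigh:sDec "
        "+ pHigh:sDec", rows)
    return _tidy_mixedlm(res, len(rows))


@dataclass
class StratumEffect:
    """Guilt effect within one self-outcome stratum."""

    stratum: str              # self_high | self_low
    n: int
    mean_effect: float        # mean of (social-low minus partner-low) cells
    t: float
    df: int
    p: float
    cohens_d: float
    bf10: float
    n_missing: int


@dataclass
class GuiltEffectResult:
    per_participant: pd.DataFrame     # participant, stratum, social, partner, effect
    strata: dict[str, StratumEffect]


def guilt_effect(dataset, max_missing_frac: float = 0.2) -> GuiltEffectResult:
    """Per-participant guilt contrasts and stratified paired tests.

    Within each self-outcome stratum (participant high / low), the effect is
    mean z-happiness after partner-low outcomes in the social condition minus
    the same in the partner condition.  Negative values mean the participant
    felt worse when they were responsible.
    """
    rows = build_post_lottery_table(dataset)
    low = rows[rows["pHigh"] == 0]
    per_rows = []
    for pid, grp in low.groupby("participant"):
        for stratum, s_val in (("self_high", 1), ("self_low", 0)):
            cell = grp[grp["sHigh"] == s_val]
            soc = cell.loc[cell["sDec"] == 1, "z_happiness"]
            par = cell.loc[cell["sDec"] == 0, "z_happiness"]
            per_rows.append({
                "participant": pid, "stratum": stratum,
                "n_social": len(soc), "n_partner": len(par),
                "social": soc.mean() if len(soc) else float("nan"),
                "partner": par.mean() if len(par) else float("nan"),
            })
    per = pd.DataFrame(per_rows)
    per["effect"] = per["social"] - per["partner"]
    strata = {}
    for stratum in ("self_high", "self_low"):
        sub = per[per["stratum"] == stratum]
        missing = int(sub["effect"].isna().sum())
        if missing > max_missing_frac * len(sub):
            detail = sub.loc[sub["effect"].isna(), "participant"].tolist()
            raise RuntimeError(
                f"stratum {stratum}: {missing}/{len(sub)} participants have "
                f"an empty cell (participants {detail}); cohort too sparse "
                "for the stratified guilt contrast")
        eff = sub["effect"].dropna().to_numpy()
        if len(eff) < 2:
            raise ValueError(
                f"stratum {stratum}: paired t-test needs >= 2 participants, "
                f"got {len(eff)}")
        t, p = stats.ttest_1samp(eff, 0.0)
        d = float(eff.mean() / eff.std(ddof=1))
        strata[stratum] = StratumEffect(
            stratum=stratum, n=len(eff), mean_effect=float(eff.mean()),
            t=float(t), df=len(eff) - 1, p=float(p), cohens_d=d,
            bf10=bf10_paired(float(t), len(eff)), n_missing=missing)
    return GuiltEffectResult(per_participant=per, strata=strata)


def agency_effect(dataset) -> pd.DataFrame:
    """Mixed model of all Z-scored ratings on an agency dummy (1 when the
    participant chose the preceding trial: social and solo conditions)."""
    probes = _zscored_probe_table(dataset)
    probes["agency"] = (probes["chooser"] == "participant").astype(int)
    if probes["agency"].nunique() < 2:
        raise ValueError("agency dummy is constant in this dataset")
    res = _mixedlm_fit("z_happiness ~ agency", probes)
    return _tidy_mixedlm(res, len(probes))


# ---------------------------------------------------------------------------
# Default-prior Bayes factor and power

def bf10_paired(t: float, n: int, r: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor for a paired/one-sample t statistic.

    Cauchy(0, r) prior on the standardized effect under H1, point null under
    H0; the marginal likelihood integral over the prior is evaluated by
    adaptive quadrature.
    """
    if not np.isfinite(t):
        raise ValueError(f"non-finite t statistic: {t}")
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1

    def integrand(g):
        return ((1 + n * g) ** -0.5
                * (1 + t * t / ((1 + n * g) * nu)) ** (-(nu + 1) / 2)
                * (r * r / 2) ** 0.5 / math.gamma(0.5)
                * g ** -1.5 * math.exp(-r * r / (2 * g)))

    num, _ = integrate.quad(integrand, 0, np.inf, epsabs=0, epsrel=1e-8)
    den = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return num / den


def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-tailed paired t-test at effect size d with n pairs."""
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    nc = d * math.sqrt(n)
    return float(1 - stats.nct.cdf(tcrit, df, nc)
                 + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size_paired(d: float, alpha: float = 0.05,
                                power: float = 0.95,
                                n_max: int = 1_000_000) -> int:
    """Smallest n with noncentral-t power >= the request (two-tailed)."""
    if not d > 0:
        raise ValueError("effect size d must be > 0")
    if not 0 < alpha < 1 or not alpha < power < 1:
        raise ValueError("need 0 < alpha < power < 1")
    for n in range(2, n_max + 1):
        if paired_t_power(d, n, alpha) >= power:
            return n
    raise ValueError(f"requested power {power} not reachable below n={n_max}")
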
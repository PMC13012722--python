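"""Computational models of momentary happiness.

Happiness probed during the task is modelled as a weighted sum of event
regressors whose influence decays exponentially over trials with a forgetting
factor ``gamma``::

    happiness(t) = sum_k w_k * sum_{j<=t} gamma**(t-j) * X_k[j]

Event regressors per trial j (terms for unchosen options are zero):

* ``CR``            certain reward when the safe option was chosen
* ``EV``            mean of the lottery outcomes when the lottery was chosen
* ``sRPE``          participant outcome minus EV on lottery trials
* ``abs_ineq``      |S - P|, absolute participant/partner payoff difference
* ``adv_ineq``      max(S - P, 0), advantageous inequality
* ``disadv_ineq``   max(P - S, 0), disadvantageous inequality
* ``social_pRPE``   partner outcome minus EV on lottery trials the
                    participant chose (social condition)
* ``partner_pRPE``  partner outcome minus EV on lottery trials the partner
                    chose (partner condition)

Five model variants use nested subsets of these regressors.  Ratings are
Z-scored per participant, so the models have no intercept; given gamma the
model is linear, and fitting profiles gamma on a grid with weights solved by
ordinary least squares at each grid point, followed by a local bounded
refinement.  The returned fit minimises the profiled SSE.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

REGRESSOR_NAMES = ("CR", "EV", "sRPE", "abs_ineq", "adv_ineq", "disadv_ineq",
                   "social_pRPE", "partner_pRPE")

MODEL_SPECS: dict[str, tuple[str, ...]] = {
    "basic": ("CR", "EV", "sRPE"),
    "inequality": ("CR", "EV", "sRPE", "abs_ineq"),
    "guilt_envy": ("CR", "EV", "sRPE", "adv_ineq", "disadv_ineq"),
    "responsibility": ("CR", "EV", "sRPE", "social_pRPE", "partner_pRPE"),
    "responsibility_redux": ("CR", "EV", "sRPE", "social_pRPE"),
}

GAMMA_GRID_STEP = 0.001


def model_regressors(name: str) -> tuple[str, ...]:
    try:
        return MODEL_SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown happiness model {name!r}; known: {sorted(MODEL_SPECS)}"
        ) from None


def count_weights(name: str) -> int:
    """Number of weight parameters (gamma excluded)."""
    return len(model_regressors(name))


def build_event_matrix(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial event regressors from resolved trial records.

    Expects one session-sorted row per trial with the columns written by
    :func:`socdec.task.records_to_frame`. Raises if a lottery trial lacks an
    outcome.
    """
    out = {name: np.zeros(len(trials)) for name in REGRESSOR_NAMES}
    s_reward = np.zeros(len(trials))
    p_reward = np.full(len(trials), np.nan)
    for i, row in enumerate(trials.itertuples(index=False)):
        risky = bool(row.chose_risky)
        has_partner = row.condition != "solo"
        if risky:
            if pd.isna(row.s_outcome):
                raise ValueError(
                    f"session {row.session} trial {row.trial}: lottery trial "
                    "has no participant outcome")
            ev = (row.lottery_high + row.lottery_low) / 2.0
            out["EV"][i] = ev
            out["sRPE"][i] = row.s_outcome - ev
            s_reward[i] = row.s_outcome
            if has_partner:
                if pd.isna(row.p_outcome):
                    raise ValueError(
                        f"session {row.session} trial {row.trial}: lottery "
                        f"trial in {row.condition} condition has no partner "
                        "outcome")
                p_reward[i] = row.p_outcome
                prpe = row.p_outcome - ev
                if row.condition == "social":
                    out["social_pRPE"][i] = prpe
                else:
                    out["partner_pRPE"][i] = prpe
        else:
            out["CR"][i] = row.safe_amount
            s_reward[i] = row.safe_amount
            if has_partner:
                p_reward[i] = row.safe_amount
        if has_partner:
            diff = s_reward[i] - p_reward[i]
            out["abs_ineq"][i] = abs(diff)
            out["adv_ineq"][i] = max(diff, 0.0)
            out["disadv_ineq"][i] = max(-diff, 0.0)
    events = pd.DataFrame(out)
    events.insert(0, "trial", trials["trial"].to_numpy())
    events.insert(0, "session", trials["session"].to_numpy())
    events["S"] = s_reward
    events["P"] = p_reward
    return events


def decayed_design(events: np.ndarray, gamma: float,
                   rating_trials) -> np.ndarray:
    """Exponentially decayed event sums at probe trials for one session.

    ``events`` is (n_trials, k) in trial order; ``rating_trials`` holds
    1-based trial indices. Row for probe t is sum_{j=1..t} gamma**(t-j) *
    events[j], with the convention gamma**0 == 1 even at gamma == 0.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    events = np.asarray(events, dtype=float)
    probes = sorted(int(t) for t in rating_trials)
    rows = np.empty((len(probes), events.shape[1]))
    acc = np.zeros(events.shape[1])
    k = 0
    for j in range(1, events.shape[0] + 1):
        acc = gamma * acc + events[j - 1]
        if k < len(probes) and probes[k] == j:
            rows[k] = acc
            k += 1
    if k != len(probes):
        raise ValueError("rating trial index beyond the end of the session")
    return rows


def _decayed_design_grid(events: np.ndarray, gammas: np.ndarray,
                         probes: list[int]) -> np.ndarray:
    """(n_gamma, n_probes, k) decayed designs for a whole gamma grid at once."""
    events = np.asarray(events, dtype=float)
    acc = np.zeros((len(gammas), events.shape[1]))
    out = np.empty((len(gammas), len(probes), events.shape[1]))
    g = gammas[:, None]
    k = 0
    for j in range(1, events.shape[0] + 1):
        acc = g * acc + events[j - 1]
        if k < len(probes) and probes[k] == j:
            out[:, k, :] = acc
            k += 1
    return out


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score with sample SD (ddof=1), the convention used for the ratings."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot Z-score a constant rating series")
    return (x - x.mean()) / sd


@dataclass
class HappinessFit:
    """Weights, decay and fit metrics for one participant x model."""

    model: str
    weights: dict[str, float]
    gamma: float
    n_ratings: int
    sse: float
    r2: float
    adj_r2: float
    loglik: float
    aic: float
    bic: float
    aic_ls: float     # least-squares convention: n*log(SSE/n) + 2k, k = weights + gamma
    bic_ls: float
    k_weights: int
    rank_deficient: bool = False
    gamma_profile: np.ndarray | None = field(default=None, repr=False)

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.weights[r] for r in model_regressors(self.model)])


def _session_blocks(events: pd.DataFrame, ratings: pd.DataFrame,
                    regressors: tuple[str, ...]):
    """Split events/probe indices per session, aligned with rating rows."""
    blocks = []
    for session, ev in events.groupby("session", sort=True):
        probes = ratings.loc[ratings["session"] == session, "trial"]
        probes = sorted(int(t) for t in probes)
        X = ev.sort_values("trial")[list(regressors)].to_numpy(dtype=float)
        blocks.append((X, probes))
    return blocks


def _stack_design(blocks, gamma: float) -> np.ndarray:
    return np.vstack([decayed_design(X, gamma, probes) for X, probes in blocks])


def fit_model(trials: pd.DataFrame, ratings: pd.DataFrame, model: str,
              grid_step: float = GAMMA_GRID_STEP, refine: bool = True,
              store_profile: bool = False,
              z_scored: bool = False) -> HappinessFit:
    """Fit one happiness model to one participant's ratings.

    ``trials`` and ``ratings`` must share ``session``/``trial`` keys; ratings
    are Z-scored across all of the participant's probes (pass
    ``z_scored=True`` if the ``rating`` column already is).  Decayed sums
    reset at session boundaries.
    """
    regressors = model_regressors(model)
    k_w = len(regressors)
    ratings = ratings.sort_values(["session", "trial"]).reset_index(drop=True)
    y = ratings["rating"].to_numpy(dtype=float)
    if not z_scored:
        y = zscore(y)
    n = len(y)
    if n < k_w + 2:
        raise ValueError(f"need at least {k_w + 2} ratings to fit {model!r}, "
                         f"got {n}")
    events = build_event_matrix(trials)
    blocks = _session_blocks(events, ratings, regressors)
    if sum(len(p) for _, p in blocks) != n:
        raise ValueError("ratings do not align with session trial records")

    gammas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    designs = [
        _decayed_design_grid(X, gammas, probes) for X, probes in blocks
    ]
    D = np.concatenate(designs, axis=1)            # (G, n, k)
    A = np.einsum("gnk,gnl->gkl", D, D)
    b = np.einsum("gnk,n->gk", D, y)
    # pinv handles sessions where a regressor never occurs (singular A)
    w = np.einsum("gkl,gl->gk", np.linalg.pinv(A, hermitian=True), b)
    sse_grid = y @ y - np.einsum("gk,gk->g", b, w)
    i_best = int(np.argmin(sse_grid))
    gamma_hat = float(gammas[i_best])
    sse_hat = float(sse_grid[i_best])
    w_hat = w[i_best]

    def profile_sse(g: float):
        Dg = _stack_design(blocks, g)
        coef, res, rank, _ = np.linalg.lstsq(Dg, y, rcond=None)
        sse = float(y @ y - (Dg @ coef) @ y) if not len(res) else float(res[0])
        return sse, coef

    if refine:
        lo = max(0.0, gamma_hat - grid_step)
        hi = min(1.0, gamma_hat + grid_step)
        r = optimize.minimize_scalar(lambda g: profile_sse(g)[0],
                                     bounds=(lo, hi), method="bounded",
                                     options={"xatol": 1e-8})
        if r.fun < sse_hat:
            gamma_hat = float(r.x)
            sse_hat, w_hat = profile_sse(gamma_hat)

    D_hat = _stack_design(blocks, gamma_hat)
    rank = np.linalg.matrix_rank(D_hat)
    sst = float(y @ y)
    r2 = 1.0 - sse_hat / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k_w - 1)
    sigma2 = max(sse_hat, 1e-300) / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k_full = k_w + 2          # weights + gamma + residual variance
    k_ls = k_w + 1            # weights + gamma (printed-table convention)
    return HappinessFit(
        model=model,
        weights={r: float(c) for r, c in zip(regressors, w_hat)},
        gamma=gamma_hat, n_ratings=n, sse=sse_hat, r2=r2, adj_r2=adj_r2,
        loglik=float(loglik),
        aic=2 * k_full - 2 * loglik,
        bic=k_full * np.log(n) - 2 * loglik,
        aic_ls=n * np.log(sigma2) + 2 * k_ls,
        bic_ls=n * np.log(sigma2) + k_ls * np.log(n),
        k_weights=k_w, rank_deficient=rank < k_w,
        gamma_profile=np.column_stack([gammas, sse_grid]) if store_profile else None,
    )


def predict(trials: pd.DataFrame, ratings: pd.DataFrame, model: str,
            weights: np.ndarray | dict, gamma: float) -> np.ndarray:
    """Model-predicted happiness at the probes in ``ratings`` (latent scale)."""
    regressors = model_regressors(model)
    if isinstance(weights, dict):
        weights = np.array([weights[r] for r in regressors])
    events = build_event_matrix(trials)
    blocks = _session_blocks(events, ratings.sort_values(["session", "trial"]),
                             regressors)
    return _stack_design(blocks, gamma) @ np.asarray(weights, dtype=float)


def lr_test(fit_nested: HappinessFit, fit_full: HappinessFit) -> dict:
    """Likelihood-ratio test of nested happiness models on the same ratings."""
    r0 = set(model_regressors(fit_nested.model))
    r1 = set(model_regressors(fit_full.model))
    if not r0 <= r1:
        raise ValueError(
            f"{fit_nested.model!r} is not nested in {fit_full.model!r}")
    if fit_nested.n_ratings != fit_full.n_ratings:
        raise ValueError("fits are not on the same ratings")
    lr = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if lr < -1e-6:
        raise ValueError(f"full model fits worse than nested (LR={lr:.3g}); "
                         "fits are inconsistent")
    lr = max(lr, 0.0)
    df = fit_full.k_weights - fit_nested.k_weights
    p = 1.0 if df == 0 and lr == 0 else float(stats.chi2.sf(lr, max(df, 1)))
    if df == 0:
        p = 1.0 if lr == 0 else float("nan")
    return {"LR": lr, "df": df, "p": p}


def compare_cohort(fits_by_model: dict[str, list[HappinessFit]],
                   alpha: float = 0.05):
    """Cohort-level model comparison table plus Bonferroni-corrected paired
    t-tests on per-participant R2 / adjusted R2.

    Returns ``(table, pairwise)`` DataFrames. AIC/BIC are summed across
    participants; both the Gaussian-likelihood and the least-squares
    conventions are reported.
    """
    sizes = {m: len(f) for m, f in fits_by_model.items()}
    if len(set(sizes.values())) > 1:
        raise ValueError(f"unequal participant counts per model: {sizes}")
    rows = []
    for m, fits in fits_by_model.items():
        rows.append({
            "model": m,
            "n_param": fits[0].k_weights,
            "mean_r2": np.mean([f.r2 for f in fits]),
            "mean_adj_r2": np.mean([f.adj_r2 for f in fits]),
            "sum_aic": np.sum([f.aic for f in fits]),
            "sum_bic": np.sum([f.bic for f in fits]),
            "sum_aic_ls": np.sum([f.aic_ls for f in fits]),
            "sum_bic_ls": np.sum([f.bic_ls for f in fits]),
            "median_gamma": np.median([f.gamma for f in fits]),
        })
    table = pd.DataFrame(rows)
    models = list(fits_by_model)
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1:]]
    n_tests = max(len(pairs), 1)
    prows = []
    for a, b in pairs:
        for metric in ("r2", "adj_r2"):
            va = np.array([getattr(f, metric) for f in fits_by_model[a]])
            vb = np.array([getattr(f, metric) for f in fits_by_model[b]])
            if np.allclose(va, vb):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(va, vb)
            prows.append({"model_a": a, "model_b": b, "metric": metric,
                          "t": float(t), "p": float(p),
                          "p_bonferroni": min(float(p) * n_tests * 2, 1.0)})
    return table, pd.DataFrame(prows)


@dataclass
class RecoveryReport:
    """Recovery regressions: per-parameter slope/intercept/R2 of mean
    recovered values on the generating values."""

    model: str
    nreps: int
    table: pd.DataFrame            # parameter, slope, intercept, r2
    recovered: pd.DataFrame        # participant, rep, parameter, value
    actual: pd.DataFrame           # participant, parameter, value


def parameter_recovery(dataset, model: str, nreps: int = 10,
                       rng: np.random.Generator | int = 0,
                       noise_scale: float = 1.0,
                       use_true_params: bool = False,
                       grid_step: float = GAMMA_GRID_STEP) -> RecoveryReport:
    """Refit a happiness model to data simulated from its own estimates.

    For each participant: fit the model (or take the generating truth), create
    noise-free predicted ratings at the same probes, add Gaussian noise with
    SD equal to ``noise_scale`` times the SD of those predictions, refit, and
    repeat ``nreps`` times.  Mean recovered values are regressed on the
    generating values per parameter.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    regressors = model_regressors(model)
    actual_rows, rec_rows = [], []
    for part in dataset.participants:
        if use_true_params:
            w0 = np.array([part.params.weights.get(r, 0.0) for r in regressors])
            g0 = part.params.gamma
        else:
            base = fit_model(part.trials, part.ratings, model,
                             grid_step=grid_step)
            w0, g0 = base.weight_vector, base.gamma
        for name, val in zip(regressors, w0):
            actual_rows.append({"participant": part.pid, "parameter": name,
                                "value": float(val)})
        actual_rows.append({"participant": part.pid, "parameter": "gamma",
                            "value": float(g0)})
        pred = predict(part.trials, part.ratings, model, w0, g0)
        noise_sd = noise_scale * float(np.std(pred, ddof=1))
        for rep in range(nreps):
            synth = pred + rng.normal(0.0, noise_sd, size=pred.shape)
            sratings = part.ratings.copy()
            sratings["rating"] = synth
            # synthetic ratings are generated on the standardized scale the
            # base fit used; re-Z-scoring would rescale the weights and bias
            # the recovery slopes, so refit on the ratings as generated
            refit = fit_model(part.trials, sratings, model,
                              grid_step=grid_step, z_scored=True)
            for name, val in zip(regressors, refit.weight_vector):
                rec_rows.append({"participant": part.pid, "rep": rep,
                                 "parameter": name, "value": float(val)})
            rec_rows.append({"participant": part.pid, "rep": rep,
                             "parameter": "gamma", "value": refit.gamma})
    actual = pd.DataFrame(actual_rows)
    recovered = pd.DataFrame(rec_rows)
    means = (recovered.groupby(["participant", "parameter"])["value"]
             .mean().rename("recovered").reset_index())
    merged = means.merge(actual.rename(columns={"value": "actual"}),
                         on=["participant", "parameter"])
    rows = []
    for pname, grp in merged.groupby("parameter"):
        res = stats.linregress(grp["actual"], grp["recovered"])
        rows.append({"parameter": pname, "slope": res.slope,
                     "intercept": res.intercept, "r2": res.rvalue ** 2})
    order = list(regressors) + ["gamma"]
    table = (pd.DataFrame(rows).set_index("parameter").loc[order]
             .reset_index())
    return RecoveryReport(model=model, nreps=nreps, table=table,
                          recovered=recovered, actual=actual)
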
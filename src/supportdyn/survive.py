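"""Retention analysis: support exposure, dropout spells, Weibull hazards.

Each member's clock starts at their first post.  For every 7-day week in
which the member posted, the *exposure set* is every message posted during
that week in the threads the member posted to that week (reading is not
observed, so co-presence in a thread-week stands in for it).  A member
drops out when they fail to post again within a fixed gap (12 weeks) of
their last post; members whose last post is within the gap of the end of
data collection are right censored.  Participation episodes are expanded
into counting-process intervals so covariates can vary week to week, and a
Weibull proportional-hazards model h(t|x) = p t^(p-1) exp(x'b) is fitted
by maximum likelihood.  Hazard ratios above 1 mean faster dropout.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError, FitError, SchemaError

WEEK = timedelta(days=7)

EXPOSURE_COVARIATES = (
    "post_count_exposure",
    "emo_exposure",
    "info_exposure",
    "pct_thread_starters",
)


def build_exposures(
    threads: Sequence,
    scores: pd.DataFrame,
    profiles: dict[str, int],
) -> pd.DataFrame:
    """Per (user, active week) exposure records.

    ``scores`` is a message-indexed table with ``provide_emotional`` and
    ``provide_informational`` columns (machine scores).  ``profiles`` maps
    user ids to the 0/1 has-a-profile flag and defines the user universe:
    authors absent from it are treated as context only.  Weeks are 7-day
    windows anchored at each user's first post; a user's own messages count
    toward their exposure.
    """
    for col in ("provide_emotional", "provide_informational"):
        if col not in scores.columns:
            raise SchemaError(f"scores table missing column {col!r}")
    emo = scores["provide_emotional"].to_dict()
    info = scores["provide_informational"].to_dict()

    all_msgs = [m for t in threads for m in t.messages]
    by_thread: dict[str, list] = {}
    for t in threads:
        msgs = sorted(t.messages, key=lambda m: m.timestamp)
        by_thread[t.thread_id] = msgs
    thread_times = {tid: [m.timestamp for m in msgs] for tid, msgs in by_thread.items()}

    user_posts: dict[str, list] = {}
    for m in all_msgs:
        if m.author_id in profiles:
            user_posts.setdefault(m.author_id, []).append(m)

    rows = []
    for user, posts in user_posts.items():
        posts.sort(key=lambda m: m.timestamp)
        first = posts[0].timestamp
        by_week: dict[int, list] = {}
        for m in posts:
            w = int((m.timestamp - first) // WEEK)
            by_week.setdefault(w, []).append(m)
        for w in sorted(by_week):
            own = by_week[w]
            lo = first + w * WEEK
            hi = lo + WEEK
            exposure_ids: set[str] = set()
            for tid in {m.thread_id for m in own}:
                times = thread_times[tid]
                i = bisect_left(times, lo)
                msgs = by_thread[tid]
                while i < len(msgs) and msgs[i].timestamp < hi:
                    exposure_ids.add(msgs[i].message_id)
                    i += 1
            unscored = [mid for mid in exposure_ids if mid not in emo]
            if unscored:
                raise SchemaError(
                    f"unscored message(s) in exposure set: {sorted(unscored)[:5]}"
                )
            n_starters = sum(1 for m in own if m.position == 0)
            rows.append(
                {
                    "user_id": user,
                    "week_index": w,
                    "n_posts": len(own),
                    "post_count_exposure": float(len(exposure_ids)),
                    "emo_exposure": float(np.mean([emo[mid] for mid in exposure_ids])),
                    "info_exposure": float(np.mean([info[mid] for mid in exposure_ids])),
                    "pct_thread_starters": 100.0 * n_starters / len(own),
                    "has_profile": int(profiles[user]),
                    "first_post": first,
                }
            )
    return pd.DataFrame(rows).sort_values(["user_id", "week_index"]).reset_index(drop=True)


def build_spells(
    exposures: pd.DataFrame, gap: int = 12, end_of_data: Optional[datetime] = None
) -> pd.DataFrame:
    """Counting-process interval records from weekly exposure records.

    Active weeks separated by more than ``gap`` silent weeks split into
    separate participation episodes; the clock restarts at each episode.
    Within an episode, one interval per active week carries that week's
    covariates forward to the next active week (last observation carried
    forward); the final interval of an episode spans one further week and
    has event=1 unless the episode's last post is within ``gap`` weeks of
    ``end_of_data``, in which case it is censored.
    """
    if end_of_data is None:
        raise DomainError("build_spells requires end_of_data for censoring")
    rows = []
    covars = list(EXPOSURE_COVARIATES) + ["has_profile"]
    for user, grp in exposures.groupby("user_id", sort=False):
        grp = grp.sort_values("week_index")
        weeks = grp["week_index"].to_numpy()
        first = grp["first_post"].iloc[0]
        end_week = int((end_of_data - first) // WEEK)
        episodes: list[list[int]] = [[0]]
        for i in range(1, len(weeks)):
            if weeks[i] - weeks[i - 1] > gap:
                episodes.append([i])
            else:
                episodes[-1].append(i)
        for ep_no, members in enumerate(episodes):
            origin = weeks[members[0]]
            for j, i in enumerate(members):
                rec = grp.iloc[i]
                start = float(weeks[i] - origin)
                if j + 1 < len(members):
                    stop = float(weeks[members[j + 1]] - origin)
                    event = 0
                else:
                    stop = start + 1.0
                    event = 1 if weeks[i] + gap <= end_week else 0
                row = {
                    "user_id": user,
                    "episode": ep_no,
                    "start": start,
                    "stop": stop,
                    "event": event,
                }
                row.update({c: rec[c] for c in covars})
                rows.append(row)
    return pd.DataFrame(rows)


def standardize_covariates(
    spells: pd.DataFrame,
    covariates: Sequence[str] = EXPOSURE_COVARIATES,
    interactions: bool = True,
) -> pd.DataFrame:
    """Z-score continuous covariates over interval records; binary columns
    (has_profile) are left untouched.  Interactions of post count with each
    support exposure are formed after standardization of the mains."""
    out = spells.copy()
    for c in covariates:
        col = out[c].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            raise DomainError(f"covariate {c!r} has zero variance; cannot standardize")
        out[c] = (col - col.mean()) / sd
    if interactions:
        out["post_count_x_emo"] = out["post_count_exposure"] * out["emo_exposure"]
        out["post_count_x_info"] = out["post_count_exposure"] * out["info_exposure"]
    return out


@dataclass
class SurvivalFit:
    """Weibull proportional-hazards estimates on counting-process data."""

    hazard_ratio: dict[str, float]
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    shape: float
    intercept: float
    log_likelihood: float
    n_intervals: int
    n_events: int


def _weibull_ph_loglik(theta, s, t, d, X):
    lnp = theta[0]
    beta = theta[1:]
    p = math.exp(lnp)
    eta = X @ beta
    tp = t**p
    sp = np.where(s > 0, s**p, 0.0)
    ll = float(np.sum(d * (lnp + (p - 1) * np.log(t) + eta)) - np.sum(np.exp(eta) * (tp - sp)))
    # gradient
    w = np.exp(eta) * (tp - sp)
    g_beta = X.T @ (d - w)
    tlnt = tp * np.log(t)
    slns = np.zeros_like(sp)
    pos = s > 0
    slns[pos] = sp[pos] * np.log(s[pos])
    dll_dp = float(np.sum(d * (1.0 / p + np.log(t))) - np.sum(np.exp(eta) * (tlnt - slns)))
    g = np.concatenate([[dll_dp * p], g_beta])  # chain rule for ln p
    return -ll, -g


def fit_weibull_ph(
    spells: pd.DataFrame,
    covariates: Sequence[str],
    shape: Optional[float] = None,
) -> SurvivalFit:
    """Maximum-likelihood Weibull PH fit with time-varying covariates.

    An interval (start, stop, event, x) contributes
    ``-exp(x'b) (stop^p - start^p) + event [ln p + (p-1) ln stop + x'b]``
    to the log likelihood.  An intercept (baseline log-rate) is always
    included; pass ``shape`` to fix the Weibull shape (1 = exponential).
    """
    missing = [c for c in covariates if c not in spells.columns]
    if missing:
        raise SchemaError(f"spells missing covariate(s): {', '.join(missing)}")
    s = spells["start"].to_numpy(dtype=float)
    t = spells["stop"].to_numpy(dtype=float)
    d = spells["event"].to_numpy(dtype=float)
    if np.any(t <= s) or np.any(s < 0):
        raise DomainError("intervals must satisfy stop > start >= 0")
    if d.sum() == 0:
        raise DomainError("no events observed; Weibull fit undefined")
    Xc = spells[list(covariates)].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(spells)), Xc])
    names = ["_intercept"] + list(covariates)

    fixed_shape = shape is not None

    if fixed_shape:
        lnp0 = math.log(shape)

        def nll(b):
            v, g = _weibull_ph_loglik(np.concatenate([[lnp0], b]), s, t, d, X)
            return v, g[1:]

        x0 = np.zeros(X.shape[1])
        res = optimize.minimize(nll, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 500, "gtol": 1e-8})
        theta = np.concatenate([[lnp0], res.x])
        free = np.arange(1, len(theta))
    else:
        def nll(th):
            return _weibull_ph_loglik(th, s, t, d, X)

        x0 = np.zeros(X.shape[1] + 1)
        res = optimize.minimize(nll, x0, jac=True, method="L-BFGS-B",
                                options={"maxiter": 500, "gtol": 1e-8})
        theta = res.x
        free = np.arange(len(theta))

    grad_norm = float(np.max(np.abs(nll(res.x)[1])))
    if not res.success and grad_norm > 1e-4:
        raise FitError(f"Weibull fit did not converge (gradient max-norm {grad_norm:.2e})")

    # observed information via central differences of the analytic gradient
    k = len(free)
    H = np.zeros((k, k))
    h = 1e-5
    for j in range(k):
        th_hi = theta.copy()
        th_lo = theta.copy()
        th_hi[free[j]] += h
        th_lo[free[j]] -= h
        g_hi = _weibull_ph_loglik(th_hi, s, t, d, X)[1][free]
        g_lo = _weibull_ph_loglik(th_lo, s, t, d, X)[1][free]
        H[:, j] = (g_hi - g_lo) / (2 * h)
    H = (H + H.T) / 2.0
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    se_free = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    se_all = np.full(len(theta), np.nan)
    se_all[free] = se_free
    p_hat = math.exp(theta[0])
    beta = theta[1:]
    coef = {name: float(b) for name, b in zip(names, beta)}
    se_map = {name: float(se_all[i + 1]) for i, name in enumerate(names)}
    pvals = {}
    for name in names:
        if se_map[name] > 0 and np.isfinite(se_map[name]):
            z = coef[name] / se_map[name]
            pvals[name] = float(2 * stats.norm.sf(abs(z)))
        else:
            pvals[name] = float("nan")
    hr = {name: math.exp(coef[name]) for name in names if name != "_intercept"}
    return SurvivalFit(
        hazard_ratio=hr,
        coef=coef,
        se=se_map,
        p=pvals,
        shape=p_hat,
        intercept=coef["_intercept"],
        log_likelihood=-float(res.fun),
        n_intervals=len(spells),
        n_events=int(d.sum()),
    )


def percent_change_from_hr(hr: float, direction: str = "stay") -> int:
    """Integer percent change in the dropout outlook implied by a hazard ratio.

    ``stay``: percent more likely to continue participating, 100(1 - HR);
    ``leave``: percent more likely to leave, 100(HR - 1).
    """
    if hr <= 0:
        raise DomainError("hazard ratio must be positive")
    if direction == "stay":
        x = 100.0 * (1.0 - hr)
    elif direction == "leave":
        x = 100.0 * (hr - 1.0)
    else:
        raise DomainError(f"direction must be 'stay' or 'leave', got {direction!r}")
    return int(math.copysign(math.floor(abs(x) + 0.5), x))
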
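"""Recursive observed-variable path models with fit indices and mediation.

The support-exchange models are recursive (acyclic) path models over
observed, standardized variables: elicitation strategies in the thread
starter predict the emotional/informational support provided in the first
reply, optionally through perceived-support-need mediators.  For such
models equation-wise least squares on standardized data is the maximum
likelihood estimator; the model-implied covariance is then assembled from
the estimates and compared to the sample covariance through the usual
likelihood-ratio chi-square, CFI (against an independence baseline) and
RMSEA.  Mediation is decomposed as products of path coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, DomainError, SchemaError

Edge = tuple[str, str]


@dataclass
class PathModelSpec:
    """Variables, directed regression paths, and free exogenous covariances.

    ``exogenous_covariances="all"`` frees every covariance among exogenous
    variables (the usual convention for these models).
    """

    variables: list[str]
    edges: list[Edge]
    exogenous_covariances: object = "all"  # "all" or list of (a, b) pairs

    def __post_init__(self) -> None:
        declared = set(self.variables)
        for src, tgt in self.edges:
            if src not in declared or tgt not in declared:
                raise ConfigError(f"edge {src!r}->{tgt!r} references undeclared variable")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        children: dict[str, list[str]] = {v: [] for v in self.variables}
        indeg = {v: 0 for v in self.variables}
        for src, tgt in self.edges:
            children[src].append(tgt)
            indeg[tgt] += 1
        queue = [v for v in self.variables if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(self.variables):
            raise ConfigError("path model specification contains a cycle")

    @property
    def endogenous(self) -> list[str]:
        tgts = {t for _, t in self.edges}
        return [v for v in self.variables if v in tgts]

    @property
    def exogenous(self) -> list[str]:
        tgts = {t for _, t in self.edges}
        return [v for v in self.variables if v not in tgts]


@dataclass
class PathFit:
    """Standardized path coefficients with covariance-structure fit indices."""

    beta: dict[Edge, float]
    se: dict[Edge, float]
    p: dict[Edge, float]
    residual_variances: dict[str, float]
    chi_square: float
    df: int
    cfi: float
    rmsea: float
    n: int
    chi_square_baseline: float = 0.0
    df_baseline: int = 0
    spec: Optional[PathModelSpec] = None


@dataclass
class MediationDecomposition:
    """Single-mediator decomposition: total = direct + indirect."""

    exposure: str
    mediator: str
    outcome: str
    direct: float
    indirect: float
    total: float
    proportion_mediated: float  # indirect / total, sign-aware; may exceed 1

    @property
    def proportion_pct(self) -> int:
        """Proportion mediated as an integer percent (half away from zero)."""
        return _round_half_away(100.0 * self.proportion_mediated)


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec) -> PathFit:
    """Fit a recursive path model on standardized observed variables.

    Each endogenous equation is estimated by least squares; the implied
    covariance of the fitted system gives the likelihood-ratio chi-square

        chi2 = (n - 1) [ln|Sigma_hat| - ln|S| + tr(S Sigma_hat^-1) - p],

    CFI against the mutual-independence baseline, and RMSEA.
    """
    vars_ = spec.variables
    missing = [v for v in vars_ if v not in data.columns]
    if missing:
        raise SchemaError(f"data missing variable(s): {', '.join(missing)}")
    X = data[vars_].to_numpy(dtype=float)
    n, p = X.shape
    if np.isnan(X).any():
        raise DomainError("path model data contains missing values")
    if n <= p:
        raise DomainError(f"need n > number of variables ({p}), got n={n}")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [v for v, s in zip(vars_, sd) if s == 0]
        raise DomainError(f"constant variable(s): {', '.join(bad)}")
    Z = (X - X.mean(axis=0)) / sd
    S = (Z.T @ Z) / (n - 1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise DomainError("sample covariance is singular")

    idx = {v: i for i, v in enumerate(vars_)}
    endo = spec.endogenous
    exog = spec.exogenous
    parents = {y: [s for s, t in spec.edges if t == y] for y in endo}

    beta: dict[Edge, float] = {}
    se: dict[Edge, float] = {}
    pvals: dict[Edge, float] = {}
    psi: dict[str, float] = {}
    B = np.zeros((p, p))
    for y in endo:
        pa = parents[y]
        pi = [idx[v] for v in pa]
        yi = idx[y]
        Spp = S[np.ix_(pi, pi)]
        Spy = S[pi, yi]
        b = np.linalg.solve(Spp, Spy)
        resid_var = float(S[yi, yi] - b @ Spy)
        psi[y] = max(resid_var, 0.0)
        k = len(pa)
        dof = n - k - 1
        sigma2 = resid_var * (n - 1) / dof if dof > 0 else np.nan
        cov_b = sigma2 * np.linalg.inv(Spp) / (n - 1)
        for j, src in enumerate(pa):
            beta[(src, y)] = float(b[j])
            se_j = float(np.sqrt(max(cov_b[j, j], 0.0)))
            se[(src, y)] = se_j
            z = b[j] / se_j if se_j > 0 else np.inf
            pvals[(src, y)] = float(2 * stats.norm.sf(abs(z)))
        B[yi, pi] = b

    # implied covariance: Sigma = A Omega A', A = (I - B)^-1
    Omega = np.zeros((p, p))
    exog_idx = [idx[v] for v in exog]
    if spec.exogenous_covariances == "all":
        free_pairs = [(a, b2) for i, a in enumerate(exog) for b2 in exog[i + 1:]]
    else:
        free_pairs = [tuple(pair) for pair in spec.exogenous_covariances]
        for a, b2 in free_pairs:
            if a not in exog or b2 not in exog:
                raise ConfigError(f"covariance ({a}, {b2}) references non-exogenous variable")
    for v in exog:
        Omega[idx[v], idx[v]] = S[idx[v], idx[v]]
    for a, b2 in free_pairs:
        Omega[idx[a], idx[b2]] = Omega[idx[b2], idx[a]] = S[idx[a], idx[b2]]
    for y in endo:
        Omega[idx[y], idx[y]] = psi[y]
    A = np.linalg.inv(np.eye(p) - B)
    Sigma = A @ Omega @ A.T

    sign_m, logdet_M = np.linalg.slogdet(Sigma)
    if sign_m <= 0:
        raise DomainError("implied covariance is singular (a residual variance hit 0)")
    chi2 = (n - 1) * (logdet_M - logdet_S + float(np.trace(S @ np.linalg.inv(Sigma))) - p)
    chi2 = max(chi2, 0.0)
    n_free = len(spec.edges) + len(free_pairs) + len(exog) + len(endo)
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise ConfigError(f"over-parameterized model: df={df} < 0")

    chi2_0 = max((n - 1) * (-logdet_S), 0.0)  # independence baseline (diag S)
    df_0 = p * (p + 1) // 2 - p
    denom = max(chi2_0 - df_0, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    rmsea = 0.0 if df == 0 else math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
    return PathFit(
        beta=beta,
        se=se,
        p=pvals,
        residual_variances=psi,
        chi_square=chi2,
        df=df,
        cfi=cfi,
        rmsea=rmsea,
        n=n,
        chi_square_baseline=chi2_0,
        df_baseline=df_0,
        spec=spec,
    )


def mediation(fit: PathFit, exposure: str, mediator: str, outcome: str) -> MediationDecomposition:
    """Decompose the exposure->outcome effect through a single mediator.

    ``indirect`` is the product of the two path coefficients; ``direct`` is
    the exposure->outcome coefficient (0 if the edge is absent).  The
    proportion mediated is indirect/total and can exceed 1 when the direct
    and indirect effects have opposite signs.
    """
    a = fit.beta.get((exposure, mediator))
    b = fit.beta.get((mediator, outcome))
    if a is None or b is None:
        raise DomainError(
            f"mediation requires edges {exposure}->{mediator} and {mediator}->{outcome}"
        )
    direct = fit.beta.get((exposure, outcome), 0.0)
    indirect = a * b
    total = direct + indirect
    if total == 0:
        raise DomainError("total effect is zero; proportion mediated undefined")
    return MediationDecomposition(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        direct=direct,
        indirect=indirect,
        total=total,
        proportion_mediated=indirect / total,
    )


# --- the support-exchange model specifications -------------------------------

STRATEGIES = (
    "pos_emo_disclosure",
    "neg_emo_disclosure",
    "pos_info_disclosure",
    "neg_info_disclosure",
    "question_asking",
)

#: emotional self-disclosure -> informational support paths are omitted
#: (not significant; excluding them improves fit)
_INFO_PARENTS = ("question_asking", "pos_info_disclosure", "neg_info_disclosure")


def elicitation_spec(variant: str = "direct") -> PathModelSpec:
    """The direct or mediated support-exchange path model specification."""
    if variant == "direct":
        variables = list(STRATEGIES) + ["provide_emotional", "provide_informational"]
        edges = [(s, "provide_emotional") for s in STRATEGIES]
        edges += [(s, "provide_informational") for s in _INFO_PARENTS]
    elif variant == "mediated":
        variables = list(STRATEGIES) + [
            "elicit_emotional",
            "elicit_informational",
            "provide_emotional",
            "provide_informational",
        ]
        edges = [(s, "elicit_emotional") for s in STRATEGIES]
        edges += [(s, "elicit_informational") for s in STRATEGIES]
        edges += [("elicit_emotional", "provide_emotional")]
        edges += [("elicit_informational", "provide_informational")]
        edges += [(s, "provide_emotional") for s in STRATEGIES]
        edges += [(s, "provide_informational") for s in _INFO_PARENTS]
    else:
        raise ConfigError(f"unknown variant {variant!r} (expected 'direct' or 'mediated')")
    return PathModelSpec(variables=variables, edges=edges, exogenous_covariances="all")


def fit_elicitation_models(scores: pd.DataFrame, variant: str = "direct") -> PathFit:
    """Fit the support-exchange path model on a per-exchange score table.

    ``scores`` must contain one row per starter/first-reply pair with
    columns for the five starter strategies and the two reply support
    constructs (plus the two elicitation constructs for the mediated
    variant).
    """
    spec = elicitation_spec(variant)
    missing = [v for v in spec.variables if v not in scores.columns]
    if missing:
        raise SchemaError(f"score table missing construct column(s): {', '.join(missing)}")
    return fit_path_model(scores, spec)
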
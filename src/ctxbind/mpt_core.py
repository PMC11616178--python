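"""Multinomial-processing-tree (MPT) engine for prime-response retrieval.

The baseline model describes the four probe response categories of the
four-alternative identification task with one processing tree per
condition.  Branching is sequential: with probability ``ci`` the probe
target is identified correctly; otherwise, with probability ``psc`` the
probe distractor is (con)fused for the target; otherwise, with probability
``prr`` the response that was correct in the prime is retrieved and
committed; the remaining fourth response option is chosen otherwise.  The
category probabilities are therefore::

    p(correct)        = ci
    p(distractor)     = (1 - ci) * psc
    p(prime_response) = (1 - ci) * (1 - psc) * prr
    p(other)          = (1 - ci) * (1 - psc) * (1 - prr)

``prr`` is the conditional probability of committing the prime response
given that neither the correct nor the distractor response was produced.
Because the likelihood factorizes stage-wise, saturated maximum-likelihood
estimates are closed form, as are fits under equality restrictions on a
single parameter.  The equal-difference (interaction) restriction couples
trees and is fit numerically.

Goodness of fit of a restricted model is measured by the likelihood-ratio
statistic G² = 2 (loglik_saturated - loglik_restricted), asymptotically
chi-square with df equal to the number of independent constraints, with
effect size ω = sqrt(G² / N).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

CATEGORIES = ("correct", "distractor", "prime_response", "other")

PARAM_NAMES = ("ci", "psc", "prr")

_EPS = 1e-9  # boundary clip for numeric optimization


@dataclass(frozen=True)
class MptParams:
    """Branch probabilities of one tree; NaN marks an undefined estimate."""

    ci: float
    psc: float
    prr: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}


@dataclass(frozen=True)
class ConditionKey:
    """Identifies one tree: trial type (IR/C) x context relation x group."""

    trial_type: str
    context_relation: str
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("IR", "C"):
            raise ValueError("trial_type must be 'IR' or 'C'")
        if self.context_relation not in ("repeated", "changed"):
            raise ValueError("context_relation must be 'repeated' or 'changed'")

    @property
    def id(self) -> str:
        return f"{self.group or '-'}:{self.trial_type}:{self.context_relation}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


def _id_of(tree_id) -> str:
    return tree_id.id if hasattr(tree_id, "id") else str(tree_id)


@dataclass(frozen=True)
class FrequencyTable:
    """Probe-response counts over the four categories for one condition."""

    tree_id: object
    n_correct: int
    n_distractor: int
    n_prime_response: int
    n_other: int

    def __post_init__(self) -> None:
        for c in self.counts:
            if c < 0:
                raise ValueError("counts must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_correct, self.n_distractor, self.n_prime_response, self.n_other)

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class Restriction:
    """An equality restriction across trees.

    ``equate_params``
        the named parameter is shared by all trees listed in ``trees``
        (df = number of trees - 1).
    ``equate_differences``
        the prr difference within each (minuend, subtrahend) pair of
        ``difference_pairs`` is shared across pairs (df = pairs - 1); this
        is the reparameterized interaction restriction.
    """

    kind: str
    parameter: str = "prr"
    trees: tuple = ()
    difference_pairs: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("equate_params", "equate_differences"):
            raise ValueError(f"unknown restriction kind {self.kind!r}")
        if self.kind == "equate_params":
            if self.parameter not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {self.parameter!r}")
            if len(self.trees) < 2:
                raise ValueError("equate_params needs at least two trees")
        else:
            if self.parameter != "prr":
                raise ValueError("equate_differences is defined on prr")
            if len(self.difference_pairs) < 2:
                raise ValueError("equate_differences needs at least two pairs")

    @property
    def df(self) -> int:
        if self.kind == "equate_params":
            return len(self.trees) - 1
        return len(self.difference_pairs) - 1


@dataclass
class FitResult:
    """Estimates and goodness of fit of one (possibly restricted) model."""

    estimates: dict
    loglik: float
    g_squared: float
    df: int
    p_value: float
    omega: float
    n_total: int
    converged: bool = True
    undefined: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    method: str = "closed_form"

    def to_dict(self) -> dict:
        return {
            "estimates": {
                _id_of(k): v.as_dict() for k, v in sorted(
                    self.estimates.items(), key=lambda kv: _id_of(kv[0])
                )
            },
            "loglik": self.loglik,
            "g_squared": self.g_squared,
            "df": self.df,
            "p_value": self.p_value,
            "omega": self.omega,
            "n_total": self.n_total,
            "converged": self.converged,
            "undefined": {
                _id_of(k): list(v) for k, v in sorted(
                    self.undefined.items(), key=lambda kv: _id_of(kv[0])
                )
            },
            "extras": self.extras,
            "method": self.method,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def category_probabilities(params: MptParams) -> np.ndarray:
    """The four category probabilities implied by one tree's parameters."""
    ci, psc, prr = params.ci, params.psc, params.prr
    for name, v in zip(PARAM_NAMES, (ci, psc, prr)):
        if math.isnan(v) or not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return np.array(
        [
            ci,
            (1 - ci) * psc,
            (1 - ci) * (1 - psc) * prr,
            (1 - ci) * (1 - psc) * (1 - prr),
        ]
    )


def _binom_ll(k: float, n: float, p: float) -> float:
    """k*log(p) + (n-k)*log(1-p), with 0*log(0) = 0 and NaN-safe zeros."""
    ll = 0.0
    if k > 0:
        ll += float(xlogy(k, p))
    if n - k > 0:
        ll += float(xlogy(n - k, 1.0 - p))
    return ll


def _stagewise_loglik(table: FrequencyTable, params: MptParams) -> float:
    n1, n2, n3, n4 = table.counts
    n = table.n_total
    ll = _binom_ll(n1, n, params.ci)
    ll += _binom_ll(n2, n - n1, params.psc)
    ll += _binom_ll(n3, n3 + n4, params.prr)
    return ll


def _saturated_params(table: FrequencyTable) -> tuple[MptParams, tuple[str, ...]]:
    n1, n2, n3, n4 = table.counts
    n = table.n_total
    undefined: list[str] = []
    ci = n1 / n
    if n - n1 > 0:
        psc = n2 / (n - n1)
    else:
        psc, undefined = float("nan"), undefined + ["psc"]
    if n3 + n4 > 0:
        prr = n3 / (n3 + n4)
    else:
        prr = float("nan")
        undefined.append("prr")
    return MptParams(ci, psc, prr), tuple(undefined)


def saturated_loglik(table: FrequencyTable) -> float:
    """Log-likelihood of one tree at its saturated MLEs (no constant term)."""
    params, _ = _saturated_params(table)
    return _stagewise_loglik(table, params)


def fit_saturated(table: FrequencyTable) -> FitResult:
    """Closed-form saturated fit of a single tree.

    ci = n1/N, psc = n2/(N-n1), prr = n3/(n3+n4); ratios with a zero
    denominator are reported as NaN and flagged in ``undefined``.
    """
    if table.n_total == 0:
        raise ValueError("cannot fit an all-zero frequency table")
    params, undefined = _saturated_params(table)
    ll = _stagewise_loglik(table, params)
    return FitResult(
        estimates={table.tree_id: params},
        loglik=ll,
        g_squared=0.0,
        df=0,
        p_value=1.0,
        omega=0.0,
        n_total=table.n_total,
        undefined={table.tree_id: undefined} if undefined else {},
    )


def fit_joint_saturated(tables: Sequence[FrequencyTable]) -> FitResult:
    """Saturated fit of several independent trees (estimates per tree)."""
    estimates, undefined = {}, {}
    ll = 0.0
    for t in tables:
        r = fit_saturated(t)
        estimates.update(r.estimates)
        undefined.update(r.undefined)
        ll += r.loglik
    return FitResult(
        estimates=estimates,
        loglik=ll,
        g_squared=0.0,
        df=0,
        p_value=1.0,
        omega=0.0,
        n_total=sum(t.n_total for t in tables),
        undefined=undefined,
    )


def _pooled_estimate(parameter: str, tables: Sequence[FrequencyTable]) -> float:
    """Closed-form pooled MLE of one stage parameter across trees."""
    if parameter == "ci":
        num = sum(t.n_correct for t in tables)
        den = sum(t.n_total for t in tables)
    elif parameter == "psc":
        num = sum(t.n_distractor for t in tables)
        den = sum(t.n_total - t.n_correct for t in tables)
    else:  # prr
        num = sum(t.n_prime_response for t in tables)
        den = sum(t.n_prime_response + t.n_other for t in tables)
    if den == 0:
        raise ValueError(
            f"restriction on {parameter!r} is infeasible: pooled denominator is zero"
        )
    return num / den


def fit_restricted(
    tables: Sequence[FrequencyTable], restriction: Restriction
) -> FitResult:
    """Maximum-likelihood fit of the listed trees under one restriction.

    For single-parameter equality the likelihood factorizes stage-wise, so
    the constrained MLE pools the relevant stage counts across the equated
    trees while every other parameter keeps its per-tree closed form.  The
    equal-difference (interaction) restriction is fit numerically.

    N for ω is the total of all tables passed in, i.e. all trees of the
    tested model, restricted or not.
    """
    tabmap = {t.tree_id: t for t in tables}
    if len(tabmap) != len(tables):
        raise ValueError("duplicate tree ids")
    n_total = sum(t.n_total for t in tables)
    ll_sat = sum(saturated_loglik(t) for t in tables)

    if restriction.kind == "equate_differences":
        return _fit_equal_difference(tables, restriction, ll_sat, n_total)

    for tid in restriction.trees:
        if tid not in tabmap:
            raise ValueError(f"restriction references unknown tree {tid!r}")
    pooled = _pooled_estimate(
        restriction.parameter, [tabmap[tid] for tid in restriction.trees]
    )

    estimates, undefined = {}, {}
    ll = 0.0
    restricted_set = set(restriction.trees)
    for t in tables:
        params, undef = _saturated_params(t)
        if t.tree_id in restricted_set:
            params = MptParams(**{**params.as_dict(), restriction.parameter: pooled})
            undef = tuple(u for u in undef if u != restriction.parameter)
        if undef:
            undefined[t.tree_id] = undef
        estimates[t.tree_id] = params
        ll += _stagewise_loglik(t, params)

    g2 = max(0.0, 2.0 * (ll_sat - ll))
    df = restriction.df
    return FitResult(
        estimates=estimates,
        loglik=ll,
        g_squared=g2,
        df=df,
        p_value=float(stats.chi2.sf(g2, df)) if df > 0 else 1.0,
        omega=effect_size_omega(g2, n_total),
        n_total=n_total,
        undefined=undefined,
        extras={"pooled": {restriction.parameter: pooled}},
    )


def _fit_equal_difference(
    tables: Sequence[FrequencyTable],
    restriction: Restriction,
    ll_sat: float,
    n_total: int,
) -> FitResult:
    """Numeric fit with prr_A,i = prr_B,i + d for every pair i (shared d).

    Only the third branching stage is constrained, so the objective is a
    sum of binomial log-likelihoods over (base prr per pair, d) with box
    and coupling constraints keeping every implied probability in [0, 1].
    Bounded optimization on the clipped simplex with three fixed starts.
    """
    tabmap = {t.tree_id: t for t in tables}
    pairs = restriction.difference_pairs
    pair_tabs = []
    in_pairs = set()
    for a_id, b_id in pairs:
        if a_id not in tabmap or b_id not in tabmap:
            raise ValueError("restriction references unknown tree")
        a, b = tabmap[a_id], tabmap[b_id]
        for t in (a, b):
            if t.n_prime_response + t.n_other < 1:
                raise ValueError(
                    f"tree {t.tree_id!r} has no stage-three observations"
                )
        pair_tabs.append((a, b))
        in_pairs.update((a_id, b_id))

    k = len(pairs)
    nA3 = np.array([a.n_prime_response for a, _ in pair_tabs], dtype=float)
    nA4 = np.array([a.n_other for a, _ in pair_tabs], dtype=float)
    nB3 = np.array([b.n_prime_response for _, b in pair_tabs], dtype=float)
    nB4 = np.array([b.n_other for _, b in pair_tabs], dtype=float)

    def neg_ll(x: np.ndarray) -> float:
        p, d = x[:k], x[k]
        pa = np.clip(p + d, _EPS, 1 - _EPS)
        pb = np.clip(p, _EPS, 1 - _EPS)
        ll = np.sum(
            xlogy(nA3, pa) + xlogy(nA4, 1 - pa) + xlogy(nB3, pb) + xlogy(nB4, 1 - pb)
        )
        return -float(ll)

    def neg_grad(x: np.ndarray) -> np.ndarray:
        p, d = x[:k], x[k]
        pa = np.clip(p + d, _EPS, 1 - _EPS)
        pb = np.clip(p, _EPS, 1 - _EPS)
        ga = nA3 / pa - nA4 / (1 - pa)
        gb = nB3 / pb - nB4 / (1 - pb)
        g = np.empty(k + 1)
        g[:k] = ga + gb
        g[k] = ga.sum()
        return -g

    def project(p: np.ndarray, d: float) -> np.ndarray:
        p = np.clip(p, 0.02, 0.98)
        d = float(np.clip(d, _EPS - p.min(), 1 - _EPS - p.max()))
        return np.concatenate([p, [d]])

    sat_a = nA3 / (nA3 + nA4)
    sat_b = nB3 / (nB3 + nB4)
    pooled = (nA3 + nB3) / (nA3 + nA4 + nB3 + nB4)
    starts = [
        project(sat_b, float(np.mean(sat_a - sat_b))),
        project(pooled, 0.0),
        project(np.full(k, 0.5), 0.0),
    ]

    bounds = [(_EPS, 1 - _EPS)] * k + [(-1 + 2 * _EPS, 1 - 2 * _EPS)]
    constraints = [
        {
            "type": "ineq",
            "fun": (lambda x, i=i: x[i] + x[k] - _EPS),
            "jac": (lambda x, i=i: _coupling_jac(k, i, +1.0)),
        }
        for i in range(k)
    ] + [
        {
            "type": "ineq",
            "fun": (lambda x, i=i: 1 - _EPS - x[i] - x[k]),
            "jac": (lambda x, i=i: _coupling_jac(k, i, -1.0)),
        }
        for i in range(k)
    ]

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            neg_ll,
            x0,
            jac=neg_grad,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)

    p_hat, d_hat = best.x[:k], float(best.x[k])
    ll_stage3 = -float(best.fun)

    # stages one and two (and stage three of any uninvolved tree) keep
    # their per-tree closed forms; they are unconstrained.
    estimates, undefined = {}, {}
    ll = ll_stage3
    prr_hat: dict = {}
    for i, (a, b) in enumerate(pair_tabs):
        prr_hat[a.tree_id] = float(np.clip(p_hat[i] + d_hat, 0.0, 1.0))
        prr_hat[b.tree_id] = float(np.clip(p_hat[i], 0.0, 1.0))
    for t in tables:
        params, undef = _saturated_params(t)
        n1, n2, n3, n4 = t.counts
        n = t.n_total
        ll += _binom_ll(n1, n, params.ci) + _binom_ll(n2, n - n1, params.psc)
        if t.tree_id in in_pairs:
            params = MptParams(params.ci, params.psc, prr_hat[t.tree_id])
            undef = tuple(u for u in undef if u != "prr")
        else:
            ll += _binom_ll(n3, n3 + n4, params.prr)
        if undef:
            undefined[t.tree_id] = undef
        estimates[t.tree_id] = params

    g2 = max(0.0, 2.0 * (ll_sat - ll))
    df = restriction.df
    return FitResult(
        estimates=estimates,
        loglik=ll,
        g_squared=g2,
        df=df,
        p_value=float(stats.chi2.sf(g2, df)),
        omega=effect_size_omega(g2, n_total),
        n_total=n_total,
        converged=any_success,
        undefined=undefined,
        extras={"d_hat": d_hat, "base_prr": [float(v) for v in p_hat]},
        method="slsqp_multistart",
    )


def _coupling_jac(k: int, i: int, sign: float) -> np.ndarray:
    g = np.zeros(k + 1)
    g[i] = sign
    g[k] = sign
    return g


def interaction_test(
    ir_repeated: FrequencyTable,
    c_repeated: FrequencyTable,
    ir_changed: FrequencyTable,
    c_changed: FrequencyTable,
) -> FitResult:
    """Test whether the prr_IR - prr_C gap depends on the context relation.

    The full model is saturated; the restricted model reparameterizes
    prr_IR = prr_C + d within each context relation and equates d across
    relations (df = 1).  A significant misfit indicates configural binding
    of the context with the distractor and the response.
    """
    restriction = Restriction(
        kind="equate_differences",
        difference_pairs=(
            (ir_repeated.tree_id, c_repeated.tree_id),
            (ir_changed.tree_id, c_changed.tree_id),
        ),
    )
    return fit_restricted(
        [ir_repeated, c_repeated, ir_changed, c_changed], restriction
    )


def effect_size_omega(g_squared: float, n_total: int) -> float:
    """ω = sqrt(G² / N), the standardized misfit of a restricted model."""
    if n_total < 1:
        raise ValueError("n_total must be at least 1")
    if g_squared < 0:
        raise ValueError("g_squared must be non-negative")
    return math.sqrt(g_squared / n_total)


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm-adjusted p-values (family-wise error control)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# FrequencyTable I/O


def tables_to_frame(tables: Iterable[FrequencyTable]):
    """Tabular view of frequency tables (one row per tree)."""
    import pandas as pd

    rows = []
    for t in tables:
        tid = t.tree_id
        rows.append(
            {
                "group": getattr(tid, "group", None) or "-",
                "trial_type": getattr(tid, "trial_type", str(tid)),
                "context_relation": getattr(tid, "context_relation", "-"),
                "n_correct": t.n_correct,
                "n_distractor": t.n_distractor,
                "n_prime_response": t.n_prime_response,
                "n_other": t.n_other,
            }
        )
    return pd.DataFrame(rows)


def write_tables_csv(tables: Iterable[FrequencyTable], path) -> None:
    tables_to_frame(tables).to_csv(path, index=False)


def read_tables_csv(path) -> list[FrequencyTable]:
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        group = None if r.group in ("-", None) else str(r.group)
        tid = ConditionKey(str(r.trial_type), str(r.context_relation), group)
        out.append(
            FrequencyTable(
                tid,
                int(r.n_correct),
                int(r.n_distractor),
                int(r.n_prime_response),
                int(r.n_other),
            )
        )
    return out
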
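"""Disproportionality analysis of drug-event pairs.

Spontaneous-report signal detection compares how often an event is reported
with a target drug against the database background, via the 2x2 table

    ===============  ============  ============
                     target event  other events
    target drug           a             b
    other drugs           c             d
    ===============  ============  ============

with N = a+b+c+d and expected count E = (a+b)(a+c)/N under independence.
Four standard statistics are computed per pair:

* **ROR** — reporting odds ratio ``ad/(bc)`` with a Wald 95% CI on the log
  scale.
* **PRR** — proportional reporting ratio ``[a/(a+b)]/[c/(c+d)]`` with its
  Wald CI, conventionally paired with the Pearson chi-square (Yates
  continuity correction by default).
* **BCPNN IC** — information component ``log2`` of the observed-to-expected
  reporting ratio with Bayesian shrinkage.  The default mode derives IC
  from the MGPS posterior (``IC = log2 EBGM``); a self-contained
  closed-form variant is provided for comparability with other studies.
* **MGPS EBGM** — DuMouchel's multi-item gamma-Poisson shrinker: counts are
  modelled as ``a ~ Poisson(lambda*E)`` with a two-component gamma mixture
  prior on the relative reporting rate ``lambda``, fitted by marginal
  maximum likelihood across all pairs.  EBGM is the posterior geometric
  mean of ``lambda``; EBGM05 its 5th-percentile lower bound.

A pair is called a signal when its statistics clear configurable
thresholds; the default rule requires all four algorithms to agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# contingency tables

@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d cells for one drug-event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def E(self) -> float:
        """Expected a-cell count under drug-event independence."""
        return (self.a + self.b) * (self.a + self.c) / self.N


def build_tables(events: pd.DataFrame, drug_col: str = "drug",
                 term_col: str = "term") -> pd.DataFrame:
    """Tabulate 2x2 cells for every observed (drug, term) pair.

    ``events`` has one row per reaction record (the counting unit), carrying
    the attributed drug and the event term (PT or SOC).  For each pair,
    ``a`` counts records with that drug and term, ``b`` the drug's other
    records, ``c`` the term's records under other drugs and ``d`` the rest,
    so summing ``a+c`` over one drug's rows recovers the corpus record
    total.  Returns a frame with columns drug, term, a, b, c, d, N, E.
    """
    if events.empty:
        return pd.DataFrame(columns=[drug_col, term_col, "a", "b", "c", "d", "N", "E"])
    counts = (events.groupby([drug_col, term_col], sort=True)
              .size().rename("a").reset_index())
    drug_tot = events.groupby(drug_col).size()
    term_tot = events.groupby(term_col).size()
    N = len(events)
    counts["b"] = counts[drug_col].map(drug_tot) - counts["a"]
    counts["c"] = counts[term_col].map(term_tot) - counts["a"]
    counts["d"] = N - counts["a"] - counts["b"] - counts["c"]
    counts["N"] = N
    counts["E"] = (counts["a"] + counts["b"]) * (counts["a"] + counts["c"]) / N
    return counts


def tables_for_drug(events: pd.DataFrame, drug: str, drug_col: str = "drug",
                    term_col: str = "term") -> pd.DataFrame:
    """2x2 tables of one drug against every term in the corpus.

    Unlike :func:`build_tables` this tabulates *all* corpus terms for the
    drug, including terms the drug never reported (a = 0), which matters
    before minimum-count filtering.
    """
    if events.empty:
        return pd.DataFrame(columns=[term_col, "a", "b", "c", "d", "N", "E"])
    is_target = events[drug_col] == drug
    term_tot = events.groupby(term_col).size()
    a = events.loc[is_target].groupby(term_col).size()
    a = a.reindex(term_tot.index, fill_value=0)
    N = len(events)
    n_drug = int(is_target.sum())
    out = pd.DataFrame({term_col: term_tot.index, "a": a.values})
    out["b"] = n_drug - out["a"]
    out["c"] = term_tot.values - out["a"]
    out["d"] = N - n_drug - out["c"]
    out["N"] = N
    out["E"] = (out["a"] + out["b"]) * (out["a"] + out["c"]) / N
    return out.sort_values(term_col, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# frequentist statistics

def compute_ror(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    Undefined (NaN triple) when any cell is zero; no Haldane 0.5 correction
    is applied, since pairs below the minimum-count gate are never flagged
    anyway and corrections would silently alter the published formula.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        return math.nan, math.nan, math.nan
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def compute_prr(t: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with Wald 95% CI (NaN when a or c is 0)."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if a == 0 or c == 0:
        return math.nan, math.nan, math.nan
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)


def compute_chisq(t: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table (Yates-corrected by default).

    NaN when any margin is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    N = t.N
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - N / 2, 0.0)
    return N * diff * diff / (margins[0] * margins[1] * margins[2] * margins[3])


# ---------------------------------------------------------------------------
# MGPS empirical Bayes

class ConvergenceError(RuntimeError):
    """MGPS hyperparameter fit failed to converge.

    Carries the best parameters seen so far and optimizer diagnostics.
    """

    def __init__(self, message: str, best_prior: "GammaMixturePrior",
                 diagnostics: dict):
        super().__init__(message)
        self.best_prior = best_prior
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class GammaMixturePrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    ``lambda ~ P * Gamma(alpha1, rate beta1) + (1-P) * Gamma(alpha2, rate
    beta2)``.  The five hyperparameters are shared by every drug-event pair
    and fitted by marginal maximum likelihood.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    P: float
    loglik: float = math.nan

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("mixture weight P must lie in [0, 1]")

    @property
    def mean(self) -> float:
        """Prior mean E[lambda]."""
        return self.P * self.alpha1 / self.beta1 + (1 - self.P) * self.alpha2 / self.beta2


#: documented fixed initialization of the MGPS fit
MGPS_INIT = GammaMixturePrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, P=1 / 3)


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, E: np.ndarray) -> float:
    la1, lb1, la2, lb2, logitP = theta
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    P = special.expit(logitP)
    lf1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + E))
    lf2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + E))
    ll = special.logsumexp(
        np.stack([lf1 + math.log(P + 1e-300), lf2 + math.log(1 - P + 1e-300)]), axis=0)
    return float(np.sum(ll))


def _theta(prior: GammaMixturePrior) -> np.ndarray:
    return np.array([math.log(prior.alpha1), math.log(prior.beta1),
                     math.log(prior.alpha2), math.log(prior.beta2),
                     special.logit(min(max(prior.P, 1e-9), 1 - 1e-9))])


def _prior_from_theta(theta: np.ndarray, loglik: float) -> GammaMixturePrior:
    a1, b1, a2, b2 = np.exp(theta[:4])
    return GammaMixturePrior(alpha1=float(a1), beta1=float(b1), alpha2=float(a2),
                             beta2=float(b2), P=float(special.expit(theta[4])),
                             loglik=loglik)


def fit_mgps_prior(a, E, init: GammaMixturePrior = MGPS_INIT,
                   max_restarts: int = 20, seed: int = 0) -> GammaMixturePrior:
    """Fit the five MGPS hyperparameters by marginal maximum likelihood.

    Maximizes ``sum log[P*NB(a; a1, b1/(b1+E)) + (1-P)*NB(a; a2,
    b2/(b2+E))]`` — the negative-binomial marginal of Poisson counts with a
    gamma-mixture prior — with L-BFGS-B over log-transformed shapes/rates
    and a logit-transformed weight, starting from a fixed documented
    initialization, with seeded random restarts on convergence failure.

    Parameters
    ----------
    a, E : array-like
        Observed counts and independence-expected counts per pair (E > 0;
        fifty or more pairs recommended for a stable fit).

    Returns
    -------
    GammaMixturePrior
        Converged hyperparameters, with the final log-likelihood attached.

    Raises
    ------
    ConvergenceError
        If no start converges; carries the best prior seen and diagnostics.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("all expected counts E must be positive")
    bounds = [(-12.0, 12.0)] * 4 + [(-12.0, 12.0)]

    def neg(theta):
        return -_mixture_loglik(theta, a, E)

    rng = np.random.default_rng(seed)
    theta0 = _theta(init)
    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(scale=1.0, size=5)
        res = optimize.minimize(neg, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            return _prior_from_theta(res.x, loglik=-res.fun)
    raise ConvergenceError(
        f"MGPS fit did not converge after {max_restarts + 1} starts",
        best_prior=_prior_from_theta(best.x, loglik=-best.fun),
        diagnostics={"message": best.message, "nit": best.nit, "fun": best.fun})


def posterior_weight(a, E, prior: GammaMixturePrior):
    """Posterior probability Q that lambda came from the first component."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    lf1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + E))
    lf2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + E))
    with np.errstate(over="ignore"):
        return special.expit(lf1 - lf2 + special.logit(min(max(prior.P, 1e-300), 1 - 1e-16)))


def posterior_quantile(a: float, E: float, prior: GammaMixturePrior, q: float,
                       tol: float = 1e-8) -> float:
    """Quantile of the posterior gamma mixture for lambda given (a, E).

    The posterior is ``Q*Gamma(alpha1+a, beta1+E) + (1-Q)*Gamma(alpha2+a,
    beta2+E)``; its CDF is strictly increasing, so the quantile is found by
    bracketed root-finding to ``|F(x) - q| <= tol``.
    """
    Q = float(posterior_weight(a, E, prior))
    s1, r1 = prior.alpha1 + a, prior.beta1 + E
    s2, r2 = prior.alpha2 + a, prior.beta2 + E

    def cdf(x):
        return (Q * stats.gamma.cdf(x, s1, scale=1 / r1)
                + (1 - Q) * stats.gamma.cdf(x, s2, scale=1 / r2))

    lo = min(stats.gamma.ppf(q, s1, scale=1 / r1), stats.gamma.ppf(q, s2, scale=1 / r2))
    hi = max(stats.gamma.ppf(q, s1, scale=1 / r1), stats.gamma.ppf(q, s2, scale=1 / r2))
    if hi - lo < 1e-14:
        return lo
    # the component quantiles bracket the mixture quantile mathematically;
    # widen on the rare occasions roundoff puts F(lo) or F(hi) on the wrong side
    flo, fhi = cdf(lo) - q, cdf(hi) - q
    if flo > 0:
        if flo <= tol:
            return lo
        for _ in range(200):
            lo *= 0.5
            if cdf(lo) - q <= 0:
                break
        else:
            raise RuntimeError(
                f"posterior quantile bracket failure at lo={lo}, q={q}")
    if fhi < 0:
        if -fhi <= tol:
            return hi
        for _ in range(200):
            hi *= 2.0
            if cdf(hi) - q >= 0:
                break
        else:
            raise RuntimeError(
                f"posterior quantile bracket failure at hi={hi}, q={q}")
    x = optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(cdf(x) - q) > tol:
        raise RuntimeError(f"posterior quantile did not meet tolerance at x={x}")
    return float(x)


def compute_ebgm(a: float, E: float, prior: GammaMixturePrior) -> tuple[float, float, float]:
    """Empirical-Bayes geometric mean of the relative reporting rate.

    The posterior for lambda is the gamma mixture of :func:`posterior_quantile`;
    EBGM is ``2**E[log2 lambda | a]`` evaluated in closed form via the
    digamma function, and EBGM05 is the posterior 5th percentile.

    Returns ``(ebgm, ebgm05, Q)`` where Q is the first-component posterior
    weight.
    """
    if E <= 0:
        raise ValueError("expected count E must be positive")
    Q = float(posterior_weight(a, E, prior))
    eln = (Q * (special.digamma(prior.alpha1 + a) - math.log(prior.beta1 + E))
           + (1 - Q) * (special.digamma(prior.alpha2 + a) - math.log(prior.beta2 + E)))
    ebgm = math.exp(eln)
    ebgm05 = posterior_quantile(a, E, prior, 0.05)
    return ebgm, ebgm05, Q


def compute_ic(t: ContingencyTable, prior: GammaMixturePrior | None = None,
               mode: str = "mgps-linked") -> tuple[float, float]:
    """BCPNN information component with its 2.5% lower credibility bound.

    ``mode="mgps-linked"`` (default) takes IC = log2(EBGM) and IC025 =
    log2 of the posterior 2.5% quantile, tying the information component to
    the same shrinkage posterior as EBGM.  ``mode="closed-form"`` uses the
    self-contained approximation IC = log2((a+0.5)/(E+0.5)) with IC025 =
    IC - 3.3(a+0.5)^(-1/2) - 2(a+0.5)^(-3/2).
    """
    a, E = t.a, t.E
    if mode == "closed-form":
        ic = math.log2((a + 0.5) / (E + 0.5))
        return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    if mode != "mgps-linked":
        raise ValueError(f"unknown IC mode {mode!r}")
    if prior is None:
        raise ValueError("mgps-linked IC requires a fitted prior")
    ebgm, _, _ = compute_ebgm(a, E, prior)
    lo = posterior_quantile(a, E, prior, 0.025)
    return math.log2(ebgm), math.log2(lo)


# ---------------------------------------------------------------------------
# signal calling

@dataclass(frozen=True)
class SignalCriteria:
    """Per-algorithm signal thresholds and the combination rule.

    Defaults are the conventional published thresholds: ROR requires n >= 3
    with the CI lower bound above 1; PRR requires PRR >= 2, chi-square >= 4
    and n >= 3; BCPNN requires IC025 > 0; MGPS requires EBGM05 > 2.  The
    combination rule ``all-four`` flags a pair only when every algorithm
    agrees (``any`` flags on a single algorithm; ``per-algorithm`` reports
    the verdicts without combining).
    """

    min_n: int = 3
    ror_lo95_gt: float = 1.0
    prr_ge: float = 2.0
    chisq_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    rule: str = "all-four"

    def __post_init__(self):
        if self.min_n < 0 or min(self.prr_ge, self.chisq_ge, self.ebgm05_gt) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.rule not in ("all-four", "any", "per-algorithm"):
            raise ValueError(f"unknown combination rule {self.rule!r}")


def evaluate_signal(s, criteria: SignalCriteria = SignalCriteria()) -> dict:
    """Apply the signal criteria to one pair's statistics.

    ``s`` is any mapping (dict, Series, dataclass-like row) with keys
    ``n, ror_lo95, prr, chisq, ic025, ebgm05``.  NaN statistics never pass.
    Returns per-algorithm booleans plus the combined ``signal`` flag.
    """
    def get(k):
        v = s[k] if not hasattr(s, k) else getattr(s, k)
        return float(v) if v is not None and not pd.isna(v) else math.nan

    n = get("n")
    freq_ok = n >= criteria.min_n
    verdicts = {
        "ror": bool(freq_ok and get("ror_lo95") > criteria.ror_lo95_gt),
        "prr": bool(freq_ok and get("prr") >= criteria.prr_ge
                    and get("chisq") >= criteria.chisq_ge),
        "bcpnn": bool(freq_ok and get("ic025") > criteria.ic025_gt),
        "mgps": bool(freq_ok and get("ebgm05") > criteria.ebgm05_gt),
    }
    if criteria.rule == "any":
        verdicts["signal"] = any(v for k, v in verdicts.items() if k != "signal")
    elif criteria.rule == "all-four":
        verdicts["signal"] = all(v for k, v in verdicts.items() if k != "signal")
    else:
        verdicts["signal"] = False
    return verdicts


def signal_table(tables: pd.DataFrame, prior: GammaMixturePrior,
                 criteria: SignalCriteria = SignalCriteria(),
                 ic_mode: str = "mgps-linked", yates: bool = True) -> pd.DataFrame:
    """Compute all four algorithms' statistics and verdicts for each row.

    ``tables`` must carry columns a, b, c, d (plus any identifier columns,
    which are preserved).  Adds n, ror (with CI), prr (with CI), chisq, ic,
    ic025, ebgm, ebgm05, the per-algorithm booleans and the combined
    ``signal`` flag.
    """
    out = tables.reset_index(drop=True).copy()
    a = out["a"].to_numpy(dtype=float)
    b = out["b"].to_numpy(dtype=float)
    c = out["c"].to_numpy(dtype=float)
    d = out["d"].to_numpy(dtype=float)
    N = a + b + c + d
    E = (a + b) * (a + c) / N
    out["n"] = out["a"]
    out["E"] = E

    with np.errstate(divide="ignore", invalid="ignore"):
        ror = np.where(np.minimum.reduce([a, b, c, d]) > 0, (a * d) / (b * c), np.nan)
        se_ror = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        prr = np.where((a > 0) & (c > 0), (a / (a + b)) / (c / (c + d)), np.nan)
        se_prr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        diff = np.abs(a * d - b * c)
        if yates:
            diff = np.maximum(diff - N / 2, 0.0)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chisq = np.where(denom > 0, N * diff * diff / denom, np.nan)
    out["ror"] = ror
    out["ror_lo95"] = ror * np.exp(-Z95 * se_ror)
    out["ror_hi95"] = ror * np.exp(Z95 * se_ror)
    out["prr"] = prr
    out["prr_lo95"] = prr * np.exp(-Z95 * se_prr)
    out["prr_hi95"] = prr * np.exp(Z95 * se_prr)
    out["chisq"] = chisq

    ebgm = np.empty(len(out))
    ebgm05 = np.empty(len(out))
    ic = np.empty(len(out))
    ic025 = np.empty(len(out))
    for i in range(len(out)):
        g, g05, _ = compute_ebgm(a[i], E[i], prior)
        ebgm[i], ebgm05[i] = g, g05
        if ic_mode == "mgps-linked":
            ic[i] = math.log2(g)
            ic025[i] = math.log2(posterior_quantile(a[i], E[i], prior, 0.025))
        else:
            t = ContingencyTable(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
            ic[i], ic025[i] = compute_ic(t, mode="closed-form")
    out["ebgm"] = ebgm
    out["ebgm05"] = ebgm05
    out["ic"] = ic
    out["ic025"] = ic025

    verdicts = [evaluate_signal(row, criteria) for row in out.to_dict("records")]
    for key in ("ror", "prr", "bcpnn", "mgps", "signal"):
        out[f"sig_{key}" if key != "signal" else "signal"] = [v[key] for v in verdicts]
    return out


def rank_signals(table: pd.DataFrame, by: str = "n", top: int = 20,
                 term_col: str = "term") -> pd.DataFrame:
    """Stable descending ranking of signal rows.

    Sorts by the chosen key (``n``, ``ebgm`` or ``ic``), breaking ties by
    descending EBGM then term text ascending; returns the first ``top``
    rows (the whole table when shorter).
    """
    if by not in ("n", "ebgm", "ic"):
        raise ValueError(f"unknown ranking key {by!r}")
    out = table.sort_values([by, "ebgm", term_col],
                            ascending=[False, False, True], kind="stable")
    return out.head(top).reset_index(drop=True)
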
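"""Gamma-Poisson shrinkage (MGPS) for drug-event disproportionality.

The model
---------
For a (drug, event) cell with observed report count N and independence-model
expected count E, the count is modelled as

    N | lambda ~ Poisson(lambda * E)

where lambda is the cell's true relative reporting ratio.  The prior on
lambda is a two-component gamma mixture (rate parameterization, mean
alpha/beta):

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

Marginally N is then a mixture of negative binomials, and the five
hyperparameters (alpha1, beta1, alpha2, beta2, w) are estimated by
maximizing the marginal likelihood over all cells — the empirical-Bayes
step.  Conjugacy gives the per-cell posterior in closed form:

    lambda | N ~ Q * Gamma(alpha1 + N, beta1 + E) + (1 - Q) * Gamma(alpha2 + N, beta2 + E)

with Q the posterior probability of the first component.  The shrunken
point estimate is the Empirical Bayes Geometric Mean

    EBGM = exp(E[log lambda | N])

and (EB05, EB95) are the posterior 5th and 95th percentiles of lambda — a
90% interval.  Small-N cells shrink toward the prior, which is what keeps
rare-event false positives under control; EB05 >= 2 is the conventional
signal threshold.

Two surfaces are provided: module-level functions (``marginal_loglik``,
``fit_hyperparameters``, ``score_cell``, ...) and a model/results pair
(:class:`GammaPoissonShrinker` / :class:`GPSResults`) in the style of
statsmodels, where ``fit()`` returns a results object carrying the
estimates, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .pair_counting import ContingencyCell, PairCountTable, make_cells

__all__ = [
    "PriorHyperparameters",
    "FitResult",
    "PosteriorScore",
    "DEFAULT_INIT",
    "marginal_loglik",
    "fit_hyperparameters",
    "posterior_weight",
    "score_cell",
    "score_table",
    "sample_posterior",
    "GammaPoissonShrinker",
    "GPSResults",
]


@dataclass(frozen=True)
class PriorHyperparameters:
    """Five-parameter two-gamma mixture prior on the reporting ratio.

    Rate parameterization: component k has mean alpha_k / beta_k.
    ``mix_weight`` is the prior probability of component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_weight: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not (0 < self.mix_weight < 1):
            raise ValueError(f"mix_weight must lie in (0, 1), got {self.mix_weight}")

    @property
    def component_means(self) -> tuple[float, float]:
        return (self.alpha1 / self.beta1, self.alpha2 / self.beta2)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha1, self.beta1, self.alpha2, self.beta2, self.mix_weight]
        )


#: Conventional starting point for the hyperparameter search.
DEFAULT_INIT = PriorHyperparameters(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the empirical-Bayes hyperparameter fit."""

    hyper: PriorHyperparameters
    log_marginal_likelihood: float
    n_cells_used: int
    converged: bool
    n_restarts_used: int
    seed: int
    at_bounds: bool = False


@dataclass(frozen=True)
class PosteriorScore:
    """Shrunken scores for one cell: EBGM, the 90% interval, and Q."""

    ebgm: float
    eb05: float
    eb95: float
    q_weight: float

    def __post_init__(self) -> None:
        if not (self.ebgm > 0 and self.eb05 > 0 and self.eb95 > 0):
            raise ValueError("scores must be positive")
        if not (0 <= self.q_weight <= 1):
            raise ValueError("q_weight must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _cells_to_arrays(cells: Sequence[ContingencyCell]) -> tuple[np.ndarray, np.ndarray]:
    n = np.array([c.observed_n for c in cells], dtype=float)
    e = np.array([c.expected_e for c in cells], dtype=float)
    if np.any(e <= 0):
        bad = int(np.argmax(e <= 0))
        raise ValueError(
            f"nonpositive expected count in cell ({cells[bad].drug}, {cells[bad].term})"
        )
    return n, e

def _log_nb_mass(
    n: np.ndarray, e: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """log P(N = n) for the gamma-Poisson (negative binomial) marginal.

    N ~ NB(size=alpha, prob=beta/(beta+E)); stable in log space for large n
    and extreme hyperparameters.
    """
    log_beta_ratio = math.log(beta) - np.log(beta + e)
    return (
        special.gammaln(alpha + n)
        - special.gammaln(alpha)
        - special.gammaln(n + 1.0)
        + alpha * log_beta_ratio
        + n * (np.log(e) - np.log(beta + e))
    )


def _component_logmasses(
    hyper: PriorHyperparameters, n: np.ndarray, e: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    return (
        _log_nb_mass(n, e, hyper.alpha1, hyper.beta1),
        _log_nb_mass(n, e, hyper.alpha2, hyper.beta2),
    )


def _cell_loglik(
    hyper: PriorHyperparameters, n: np.ndarray, e: np.ndarray
) -> np.ndarray:
    lm1, lm2 = _component_logmasses(hyper, n, e)
    w = hyper.mix_weight
    return np.logaddexp(math.log(w) + lm1, math.log1p(-w) + lm2)


def marginal_loglik(
    hyper: PriorHyperparameters, cells: Sequence[ContingencyCell]
) -> float:
    """Log marginal likelihood of all cells under the mixture prior.

    Sum over cells of log[ w NB1(N; E) + (1-w) NB2(N; E) ].  Raises on
    nonpositive E or a non-finite result (naming the offending cell).
    """
    n, e = _cells_to_arrays(cells)
    ll = _cell_loglik(hyper, n, e)
    if not np.all(np.isfinite(ll)):
        bad = int(np.argmax(~np.isfinite(ll)))
        raise FloatingPointError(
            f"non-finite log likelihood at cell ({cells[bad].drug}, "
            f"{cells[bad].term}) with N={cells[bad].observed_n}, "
            f"E={cells[bad].expected_e}"
        )
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Hyperparameter fit
# ---------------------------------------------------------------------------


def _pack(hyper: PriorHyperparameters) -> np.ndarray:
    """(log a1, log b1, log a2, log b2, logit w)."""
    w = hyper.mix_weight
    return np.array(
        [
            math.log(hyper.alpha1),
            math.log(hyper.beta1),
            math.log(hyper.alpha2),
            math.log(hyper.beta2),
            math.log(w) - math.log1p(-w),
        ]
    )


def _unpack(theta: np.ndarray) -> PriorHyperparameters:
    w = 1.0 / (1.0 + math.exp(-theta[4]))
    w = min(max(w, 1e-12), 1 - 1e-12)
    return PriorHyperparameters(
        math.exp(theta[0]), math.exp(theta[1]), math.exp(theta[2]), math.exp(theta[3]), w
    )


def _order_components(hyper: PriorHyperparameters) -> PriorHyperparameters:
    """Resolve label switching: component 1 has the smaller mean."""
    m1, m2 = hyper.component_means
    if m1 <= m2:
        return hyper
    return PriorHyperparameters(
        hyper.alpha2, hyper.beta2, hyper.alpha1, hyper.beta1, 1.0 - hyper.mix_weight
    )


def fit_hyperparameters(
    cells: Sequence[ContingencyCell],
    init: PriorHyperparameters | None = None,
    n_restarts: int = 5,
    seed: int | None = None,
    bounds: tuple[float, float] = (1e-6, 1e6),
    ftol: float = 1e-10,
    gtol: float = 1e-6,
) -> FitResult:
    """Maximize the marginal likelihood over the five hyperparameters.

    Bounded quasi-Newton (L-BFGS-B) over log-transformed shapes/rates and
    the logit-transformed mixture weight, best of ``n_restarts`` jittered
    starts (first start = ``init`` exactly).  ``seed`` drives the jitter and
    is required for reproducibility: identical seed and cells give an
    identical result.  Components are ordered by prior mean in the output.
    """
    if seed is None:
        raise ValueError("fit requires an explicit seed")
    if init is None:
        init = DEFAULT_INIT
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if len(cells) < 100:
        warnings.warn(
            f"only {len(cells)} cells available; hyperparameter estimates "
            "may be unstable below ~100 cells",
            stacklevel=2,
        )
    n, e = _cells_to_arrays(cells)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    wlo = math.log(1e-6) - math.log1p(-1e-6)
    box = [(lo, hi)] * 4 + [(wlo, -wlo)]

    def nll(theta: np.ndarray) -> float:
        ll = _cell_loglik(_unpack(theta), n, e)
        if not np.all(np.isfinite(ll)):
            return 1e300
        return -float(ll.sum())

    rng = np.random.default_rng(seed)
    theta0 = np.clip(_pack(init), [b[0] for b in box], [b[1] for b in box])
    best = None
    any_success = False
    for r in range(n_restarts):
        start = theta0 if r == 0 else np.clip(
            theta0 + rng.normal(0.0, 0.7, size=5), [b[0] for b in box], [b[1] for b in box]
        )
        res = optimize.minimize(
            nll,
            start,
            method="L-BFGS-B",
            bounds=box,
            options={"ftol": ftol, "gtol": gtol, "maxiter": 500},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if not any_success:
        raise RuntimeError(
            f"hyperparameter fit failed to converge in {n_restarts} restarts: "
            f"{best.message if best is not None else 'no result'}"
        )
    hyper = _order_components(_unpack(best.x))
    eps = 1e-8
    at_bounds = bool(
        np.any(best.x <= np.array([b[0] for b in box]) + eps)
        or np.any(best.x >= np.array([b[1] for b in box]) - eps)
    )
    return FitResult(
        hyper=hyper,
        log_marginal_likelihood=-float(best.fun),
        n_cells_used=len(cells),
        converged=bool(best.success),
        n_restarts_used=n_restarts,
        seed=seed,
        at_bounds=at_bounds,
    )


# ---------------------------------------------------------------------------
# Posterior scores
# ---------------------------------------------------------------------------


def posterior_weight(hyper: PriorHyperparameters, cell: ContingencyCell) -> float:
    """Posterior probability Q of mixture component 1, computed in log space."""
    n = np.array([float(cell.observed_n)])
    e = np.array([cell.expected_e])
    lm1, lm2 = _component_logmasses(hyper, n, e)
    a = math.log(hyper.mix_weight) + float(lm1[0])
    b = math.log1p(-hyper.mix_weight) + float(lm2[0])
    # log-sum-exp: never 0/0 even when both masses underflow
    m = max(a, b)
    return float(math.exp(a - m) / (math.exp(a - m) + math.exp(b - m)))


#: Posterior scores below this saturate: a degenerate fitted prior (a
#: near-zero-shape component) can push quantiles beneath the double range;
#: the floor is operationally zero and can never flag.
_SCORE_FLOOR = 1e-300


def _mixture_quantile(
    p: float, q: float, a1: float, b1: float, a2: float, b2: float
) -> float:
    """Invert Q·GammaCDF(a1,b1) + (1−Q)·GammaCDF(a2,b2) at level p.

    The mixture quantile is bracketed by the two component quantiles;
    bracketed root-finding (Brent) to relative tolerance 1e-10.  A bracket
    failure raises rather than returning an endpoint.  Quantiles beneath
    the representable range saturate at ``_SCORE_FLOOR``.
    """
    q1 = stats.gamma.ppf(p, a1, scale=1.0 / b1)
    q2 = stats.gamma.ppf(p, a2, scale=1.0 / b2)
    if q >= 1.0 - 1e-14:
        return float(max(q1, _SCORE_FLOOR))
    if q <= 1e-14:
        return float(max(q2, _SCORE_FLOOR))

    def cdf(x: float) -> float:
        return (
            q * stats.gamma.cdf(x, a1, scale=1.0 / b1)
            + (1.0 - q) * stats.gamma.cdf(x, a2, scale=1.0 / b2)
            - p
        )

    lo, hi = (q1, q2) if q1 <= q2 else (q2, q1)
    if hi <= _SCORE_FLOOR:
        return _SCORE_FLOOR
    lo = max(lo, _SCORE_FLOOR)
    if cdf(lo) >= 0:
        # the true quantile underflows below the floor (or sits at lo)
        return float(lo)
    if hi - lo <= 1e-14 * max(1.0, hi):
        return float(0.5 * (lo + hi))
    flo, fhi = cdf(lo), cdf(hi)
    # roundoff can put an endpoint a few ulp past the root; that endpoint
    # then IS the quantile to working precision
    if abs(flo) < 1e-12:
        return float(lo)
    if abs(fhi) < 1e-12:
        return float(hi)
    if flo > 0 or fhi < 0:
        raise FloatingPointError(
            f"quantile bracket failure at p={p}: cdf({lo})={flo + p}, cdf({hi})={fhi + p}"
        )
    # solve in log space: a near-zero-shape component can put the root many
    # decades below the bracket top, where linear bisection cannot reach
    u = optimize.brentq(
        lambda u: cdf(math.exp(u)),
        math.log(lo),
        math.log(hi),
        xtol=1e-12,
        rtol=1e-14,
        maxiter=300,
    )
    return float(math.exp(u))


def score_cell(hyper: PriorHyperparameters, cell: ContingencyCell) -> PosteriorScore:
    """EBGM and (EB05, EB95) for one cell from the conjugate posterior.

    Posterior: Q Gamma(alpha1+N, beta1+E) + (1-Q) Gamma(alpha2+N, beta2+E).
    EBGM = exp(E[log lambda]) via the digamma function; the quantiles come
    from bracketed root-finding on the mixture CDF.
    """
    if cell.expected_e <= 0:
        raise ValueError("expected count must be positive")
    n, e = float(cell.observed_n), cell.expected_e
    q = posterior_weight(hyper, cell)
    a1, b1 = hyper.alpha1 + n, hyper.beta1 + e
    a2, b2 = hyper.alpha2 + n, hyper.beta2 + e
    elog = q * (special.digamma(a1) - math.log(b1)) + (1 - q) * (
        special.digamma(a2) - math.log(b2)
    )
    return PosteriorScore(
        ebgm=float(max(math.exp(elog), _SCORE_FLOOR)),
        eb05=_mixture_quantile(0.05, q, a1, b1, a2, b2),
        eb95=_mixture_quantile(0.95, q, a1, b1, a2, b2),
        q_weight=q,
    )


def score_table(
    hyper: PriorHyperparameters, cells: Sequence[ContingencyCell]
) -> list[tuple[ContingencyCell, PosteriorScore]]:
    """Score every cell, preserving input order.

    EBGM and Q are computed vectorized; the two quantile root-finds run per
    cell.  Errors carry the offending cell's identity.
    """
    if not cells:
        return []
    n, e = _cells_to_arrays(cells)
    lm1, lm2 = _component_logmasses(hyper, n, e)
    la = math.log(hyper.mix_weight) + lm1
    lb = math.log1p(-hyper.mix_weight) + lm2
    m = np.maximum(la, lb)
    qs = np.exp(la - m) / (np.exp(la - m) + np.exp(lb - m))
    a1, b1 = hyper.alpha1 + n, hyper.beta1 + e
    a2, b2 = hyper.alpha2 + n, hyper.beta2 + e
    elog = qs * (special.digamma(a1) - np.log(b1)) + (1 - qs) * (
        special.digamma(a2) - np.log(b2)
    )
    out = []
    for i, cell in enumerate(cells):
        try:
            score = PosteriorScore(
                ebgm=float(max(np.exp(elog[i]), _SCORE_FLOOR)),
                eb05=_mixture_quantile(0.05, qs[i], a1[i], b1[i], a2[i], b2[i]),
                eb95=_mixture_quantile(0.95, qs[i], a1[i], b1[i], a2[i], b2[i]),
                q_weight=float(qs[i]),
            )
        except (FloatingPointError, ValueError) as exc:
            raise type(exc)(
                f"scoring failed at cell ({cell.drug}, {cell.term}): {exc}"
            ) from exc
        out.append((cell, score))
    return out


def sample_posterior(
    hyper: PriorHyperparameters,
    cell: ContingencyCell,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw from the cell's posterior mixture of gammas (for MC checks)."""
    q = posterior_weight(hyper, cell)
    n, e = float(cell.observed_n), cell.expected_e
    pick1 = rng.random(size) < q
    draws = np.empty(size)
    n1 = int(pick1.sum())
    draws[pick1] = rng.gamma(hyper.alpha1 + n, 1.0 / (hyper.beta1 + e), size=n1)
    draws[~pick1] = rng.gamma(hyper.alpha2 + n, 1.0 / (hyper.beta2 + e), size=size - n1)
    return draws


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class GammaPoissonShrinker:
    """MGPS model over a set of (N, E) contingency cells.

    Construct from a list of :class:`ContingencyCell`, a
    :class:`PairCountTable` (``from_table``) or a DataFrame with observed
    and expected count columns (``from_dataframe``); ``fit`` estimates the
    mixture prior by marginal likelihood and returns :class:`GPSResults`.
    """

    def __init__(self, cells: Sequence[ContingencyCell]):
        if not cells:
            raise ValueError("no cells to model")
        self.cells = list(cells)

    @classmethod
    def from_table(cls, table: PairCountTable) -> "GammaPoissonShrinker":
        return cls(make_cells(table))

    @classmethod
    def from_dataframe(
        cls, data, n_col: str = "N", e_col: str = "E",
        drug_col: str = "drug", term_col: str = "term",
    ) -> "GammaPoissonShrinker":
        cells = [
            ContingencyCell(
                drug=str(row[drug_col]) if drug_col in data.columns else str(i),
                term=str(row[term_col]) if term_col in data.columns else "",
                observed_n=int(row[n_col]),
                expected_e=float(row[e_col]),
                rrr=int(row[n_col]) / float(row[e_col]),
            )
            for i, row in data.iterrows()
        ]
        return cls(cells)

    def loglike(self, hyper: PriorHyperparameters) -> float:
        return marginal_loglik(hyper, self.cells)

    def fit(
        self,
        start: PriorHyperparameters | None = None,
        n_restarts: int = 5,
        seed: int | None = None,
        **kwargs,
    ) -> "GPSResults":
        result = fit_hyperparameters(
            self.cells, init=start, n_restarts=n_restarts, seed=seed, **kwargs
        )
        return GPSResults(self, result)


class GPSResults:
    """Fitted MGPS results: hyperparameter estimates, scores, summary."""

    def __init__(self, model: GammaPoissonShrinker, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def params(self) -> PriorHyperparameters:
        return self.fit_result.hyper

    @property
    def llf(self) -> float:
        return self.fit_result.log_marginal_likelihood

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def posterior_weight(self, cell: ContingencyCell) -> float:
        return posterior_weight(self.params, cell)

    def score(self, cell: ContingencyCell) -> PosteriorScore:
        return score_cell(self.params, cell)

    def score_table(
        self, cells: Sequence[ContingencyCell] | None = None
    ) -> list[tuple[ContingencyCell, PosteriorScore]]:
        return score_table(self.params, cells if cells is not None else self.model.cells)

    def screen(self, threshold: float = 2.0):
        from .screening import screen

        return screen(self.score_table(), threshold=threshold)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "drug": c.drug,
                "term": c.term,
                "N": c.observed_n,
                "E": c.expected_e,
                "RRR": c.rrr,
                "EBGM": s.ebgm,
                "EB05": s.eb05,
                "EB95": s.eb95,
                "Q": s.q_weight,
            }
            for c, s in self.score_table()
        ]
        return pd.DataFrame(
            rows, columns=["drug", "term", "N", "E", "RRR", "EBGM", "EB05", "EB95", "Q"]
        )

    def summary(self) -> str:
        h = self.params
        m1, m2 = h.component_means
        fr = self.fit_result
        lines = [
            "        Gamma-Poisson Shrinkage (MGPS) Results",
            "=" * 56,
            f"No. cells:            {fr.n_cells_used:>10d}",
            f"Log marginal lik.:    {fr.log_marginal_likelihood:>14.4f}",
            f"Converged:            {str(fr.converged):>10s}"
            f"    restarts: {fr.n_restarts_used}  seed: {fr.seed}",
            f"At parameter bounds:  {str(fr.at_bounds):>10s}",
            "-" * 56,
            f"component 1:  alpha={h.alpha1:<10.4g} beta={h.beta1:<10.4g} mean={m1:<8.4g}",
            f"component 2:  alpha={h.alpha2:<10.4g} beta={h.beta2:<10.4g} mean={m2:<8.4g}",
            f"mixture weight (component 1): {h.mix_weight:.4f}",
            "=" * 56,
        ]
        return "\n".join(lines)
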
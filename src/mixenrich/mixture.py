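"""Two-component Gaussian mixture on |log2FC| for single-subject DEG calling.

The model behind single-subject (N-of-1) differential expression from one
paired sample: absolute log2 fold changes across the transcriptome are
assumed to come from two populations — transcripts whose expression is
unaltered between the paired conditions (|log2FC| near zero, width set by
technical + stochastic noise) and transcripts that are biologically
altered (|log2FC| shifted away from zero).  A two-component Gaussian
mixture is fit to the |log2FC| vector by EM, and a transcript is called a
DEG when its posterior probability of belonging to the altered component
exceeds 0.5.  The Gaussian components are fit to the nonnegative folded
values as the method defines them; no folded-normal correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: Lower bound on component variances during EM (sigma >= 1e-3).
VARIANCE_FLOOR = 1e-6
_SIGMA_FLOOR = float(np.sqrt(VARIANCE_FLOOR))
_PI_EPS = 1e-6

#: No-signal guard: if the fitted component means are closer than this many
#: unaltered-component standard deviations, the altered component is judged
#: an arbitrary split of unimodal noise and the DEG set is forced empty.
NO_SIGNAL_GUARD = 0.5


@dataclass
class PairedProfile:
    """One subject's paired expression vectors with derived fold changes."""

    gene_ids: list[str]
    expr_case: np.ndarray
    expr_control: np.ndarray
    log2fc: np.ndarray
    abs_log2fc: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for v in (self.expr_case, self.expr_control, self.log2fc, self.abs_log2fc):
            if len(v) != n:
                raise ValueError("profile vectors have mismatched lengths")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids are not unique")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class MixtureFit:
    """Fitted two-component Gaussian mixture on |log2FC| values.

    Components are labelled so that ``mu_unaltered <= mu_altered``.
    """

    pi_altered: float
    mu_unaltered: float
    mu_altered: float
    sigma_unaltered: float
    sigma_altered: float
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray | None = None

    @property
    def separation(self) -> float:
        """Component-mean gap in units of the unaltered sigma."""
        return (self.mu_altered - self.mu_unaltered) / max(self.sigma_unaltered, _SIGMA_FLOOR)

    def has_signal(self, guard: float = NO_SIGNAL_GUARD) -> bool:
        return (self.mu_altered - self.mu_unaltered) >= guard * self.sigma_unaltered


@dataclass(frozen=True)
class DegCall:
    gene_id: str
    log2fc: float
    posterior_altered: float
    is_deg: bool
    direction: Literal["up", "down", "zero"]


def make_paired_profile(
    case: Mapping[str, float],
    control: Mapping[str, float],
    input_scale: Literal["log2", "linear"] = "log2",
    pseudocount: float = 1.0,
) -> PairedProfile:
    """Build a :class:`PairedProfile` from per-gene case/control values.

    Restricted to the intersection of gene identifiers (sorted for
    determinism).  Linear-scale input is shifted by ``pseudocount`` and
    log2-transformed; log2-scale input is used as-is.
    """
    genes = sorted(set(case) & set(control))
    if not genes:
        raise ValueError("case and control share no gene identifiers")
    ca = np.array([float(case[g]) for g in genes])
    co = np.array([float(control[g]) for g in genes])
    if input_scale == "linear":
        ca = ca + pseudocount
        co = co + pseudocount
        if np.any(ca <= 0) or np.any(co <= 0):
            raise ValueError(
                "nonpositive linear expression after pseudocount; "
                "increase --pseudocount or check input scale"
            )
        ca = np.log2(ca)
        co = np.log2(co)
    elif input_scale != "log2":
        raise ValueError(f"unknown input_scale {input_scale!r}")
    fc = ca - co
    return PairedProfile(
        gene_ids=genes, expr_case=ca, expr_control=co, log2fc=fc, abs_log2fc=np.abs(fc)
    )


def _em_one_start(
    x: np.ndarray,
    pi: float,
    mu: np.ndarray,
    sigma: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    """Run EM from one starting point; returns params + loglik trace.

    ``pi`` is the weight of component 1 (the tentative altered component).
    The log-likelihood is evaluated at the current parameters before each
    M-step, so the recorded trace is non-decreasing by EM theory.
    """
    n = x.size
    trace = np.empty(max_iter)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_w = np.log([1.0 - pi, pi])
        # (n, 2) component log densities
        comp = norm.logpdf(x[:, None], loc=mu[None, :], scale=sigma[None, :]) + log_w
        m = np.logaddexp(comp[:, 0], comp[:, 1])
        ll = float(m.sum())
        trace[it - 1] = ll
        resp1 = np.exp(comp[:, 1] - m)  # responsibility of altered component
        resp = np.column_stack([1.0 - resp1, resp1])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < VARIANCE_FLOOR):
            logger.debug("EM variance clamped to floor at iteration %d", it)
        sigma = np.sqrt(np.maximum(var, VARIANCE_FLOOR))
        pi = float(np.clip(nk[1] / n, _PI_EPS, 1.0 - _PI_EPS))
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-300):
            converged = True
            break
        ll_prev = ll
    return pi, mu, sigma, trace[it - 1], it, converged, trace[:it].copy()


def fit_mixture(
    values: Sequence[float] | np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit the two-component Gaussian mixture to nonnegative |log2FC| values.

    Initialisation is a deterministic quantile start (median / 95th
    percentile means, pooled SD, pi = 0.1) plus ``n_starts - 1`` seeded
    random perturbations; the start with the best final log-likelihood
    wins.  Values are sorted internally, which makes the fit exactly
    invariant to the input order.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 50:
        raise ValueError(f"need at least 50 values to fit the mixture, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("all values identical; mixture fit is undefined")
    if np.any(x < 0):
        raise ValueError("mixture is defined on |log2FC|; values must be nonnegative")

    pooled_sd = max(float(np.std(x)), _SIGMA_FLOOR)
    base_mu = np.array([float(np.median(x)), float(np.quantile(x, 0.95))])
    if base_mu[1] <= base_mu[0]:
        base_mu[1] = base_mu[0] + pooled_sd
    rng = np.random.default_rng(seed)

    best: tuple | None = None
    for s in range(n_starts):
        if s == 0:
            mu0, sd0, pi0 = base_mu.copy(), np.array([pooled_sd, pooled_sd]), 0.1
        else:
            mu0 = base_mu + rng.normal(0.0, 0.25 * pooled_sd, size=2)
            sd0 = np.maximum(pooled_sd * rng.uniform(0.5, 1.5, size=2), _SIGMA_FLOOR)
            pi0 = float(rng.uniform(0.02, 0.4))
        res = _em_one_start(x, pi0, mu0.copy(), sd0.copy(), max_iter, tol)
        if best is None or res[3] > best[3]:
            best = res
    pi, mu, sigma, ll, n_iter, converged, trace = best

    # relabel so the unaltered component has the smaller mean
    if mu[0] > mu[1]:
        mu = mu[::-1]
        sigma = sigma[::-1]
        pi = 1.0 - pi
    pi = float(np.clip(pi, _PI_EPS, 1.0 - _PI_EPS))
    return MixtureFit(
        pi_altered=pi,
        mu_unaltered=float(mu[0]),
        mu_altered=float(mu[1]),
        sigma_unaltered=float(sigma[0]),
        sigma_altered=float(sigma[1]),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=trace,
    )


def posterior_altered(fit: MixtureFit, values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Per-value posterior probability of the altered component.

    Computed in log space so extreme values underflow gracefully.
    """
    x = np.asarray(values, dtype=float)
    la = np.log(fit.pi_altered) + norm.logpdf(x, fit.mu_altered, fit.sigma_altered)
    lu = np.log1p(-fit.pi_altered) + norm.logpdf(x, fit.mu_unaltered, fit.sigma_unaltered)
    return np.exp(la - np.logaddexp(la, lu))


def call_degs(
    profile: PairedProfile,
    posteriors: Sequence[float] | np.ndarray,
    deg_threshold: float = 0.5,
    fit: MixtureFit | None = None,
    no_signal_guard: float = NO_SIGNAL_GUARD,
) -> list[DegCall]:
    """Call DEGs at posterior > ``deg_threshold`` (strict inequality).

    When ``fit`` is given and its component means are separated by less
    than ``no_signal_guard`` unaltered-sigmas, the altered component is
    treated as an arbitrary split of unimodal noise and no DEG is called.
    Direction is the sign of log2FC ("zero" only at exactly 0).
    """
    post = np.asarray(posteriors, dtype=float)
    if post.shape[0] != len(profile):
        raise ValueError("posteriors not aligned with profile genes")
    signal = True
    if fit is not None and not fit.has_signal(no_signal_guard):
        logger.warning(
            "no-signal guard: component separation %.3f sigma < %.3f; forcing empty DEG set",
            fit.separation,
            no_signal_guard,
        )
        signal = False
    calls = []
    for g, fc, p in zip(profile.gene_ids, profile.log2fc, post):
        direction = "zero" if fc == 0 else ("up" if fc > 0 else "down")
        calls.append(
            DegCall(
                gene_id=g,
                log2fc=float(fc),
                posterior_altered=float(p),
                is_deg=bool(signal and p > deg_threshold),
                direction=direction,
            )
        )
    return calls
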
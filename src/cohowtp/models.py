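"""Random-utility choice models: conditional logit and random-parameters logit.

The household utility of a recovery program ``k`` in task ``t`` is

    V = -exp(b1)*Price + b2*Recovered + b3*ReturningFish + b4*Quick
        + b5*Fishing1 + b6*Fishing2 + b7*Recovered*ReturningFish
        + b8*Quick*ReturningFish + Gumbel error,

with Price in $100s and ReturningFish in 100,000s of fish; the status quo
carries only an alternative-specific constant ``b0``.  Exponentiating the
price coefficient makes the realized marginal utility of money ``exp(b1)``
log-normal and strictly positive, so no draw can gain utility from a price
increase.

In the random-parameters logit (RPL) all nine coefficients are independent
normal across respondents and fixed within a respondent's three tasks
(panel mixing).  Estimation is by maximum simulated likelihood: the
within-respondent product of task probabilities is averaged over scrambled
Halton draws of the coefficient vector and the sum of log averages is
maximized with analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.stats import qmc

from .data import ChoiceDataset
from .scenario import ScenarioAttributes

__all__ = [
    "COEF_NAMES",
    "RPLParams",
    "EstimationConfig",
    "FitResult",
    "systematic_utility",
    "logit_probabilities",
    "conditional_logit_loglik",
    "fit_conditional_logit",
    "simulated_loglik",
    "fit_rpl",
    "lr_test",
    "make_draws",
]

#: Coefficient order used throughout (index 1 is the pre-exponentiation
#: log-price coefficient).
COEF_NAMES = (
    "asc",
    "log_price",
    "recovered",
    "fish",
    "quick",
    "fishing1",
    "fishing2",
    "recovered_x_fish",
    "quick_x_fish",
)
K_COEF = len(COEF_NAMES)

#: Column index of each interaction-eligible attribute in the design coding.
ATTRIBUTE_COLUMNS = {"recovered": 2, "fish": 3, "quick": 4}

_PROB_FLOOR_LOG = np.log(1e-300)
_EXP_CLIP = 30.0  # cap on the log-price coefficient inside exp()


@dataclass(frozen=True)
class RPLParams:
    """Means and standard deviations of the nine random coefficients.

    Defaults are the point estimates of the published Oregon Coast coho
    choice experiment and serve as the synthetic-population generating
    values and as worked-example inputs.
    """

    asc_mean: float = -11.81
    asc_sd: float = 10.81
    logprice_mean: float = 0.85
    logprice_sd: float = 1.66
    recovered_mean: float = 2.58
    recovered_sd: float = 1.17
    fish_mean: float = 1.70
    fish_sd: float = 0.88
    quick_mean: float = 1.18
    quick_sd: float = 0.78
    fishing1_mean: float = -0.25
    fishing1_sd: float = 1.04
    fishing2_mean: float = -0.34
    fishing2_sd: float = 0.28
    recovered_x_fish_mean: float = -0.88
    recovered_x_fish_sd: float = 0.61
    quick_x_fish_mean: float = -0.22
    quick_x_fish_sd: float = 0.53

    def __post_init__(self) -> None:
        if np.any(self.sds() < 0):
            raise ValueError("standard deviations must be non-negative")

    _MEAN_FIELDS = (
        "asc_mean",
        "logprice_mean",
        "recovered_mean",
        "fish_mean",
        "quick_mean",
        "fishing1_mean",
        "fishing2_mean",
        "recovered_x_fish_mean",
        "quick_x_fish_mean",
    )
    _SD_FIELDS = (
        "asc_sd",
        "logprice_sd",
        "recovered_sd",
        "fish_sd",
        "quick_sd",
        "fishing1_sd",
        "fishing2_sd",
        "recovered_x_fish_sd",
        "quick_x_fish_sd",
    )

    def means(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._MEAN_FIELDS], dtype=float)

    def sds(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self._SD_FIELDS], dtype=float)

    @classmethod
    def from_arrays(cls, means, sds) -> "RPLParams":
        kw = {f: float(v) for f, v in zip(cls._MEAN_FIELDS, means)}
        kw |= {f: float(v) for f, v in zip(cls._SD_FIELDS, sds)}
        return cls(**kw)

    def with_zero_sds(self) -> "RPLParams":
        return RPLParams.from_arrays(self.means(), np.zeros(K_COEF))


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for maximum simulated likelihood estimation."""

    n_draws: int = 500
    draw_type: str = "halton-scrambled"  # or "pseudo-random"
    seed: int = 0
    max_iterations: int = 1000
    gradient_tolerance: float = 1e-5
    se_method: str = "hessian"  # or "sandwich"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.draw_type not in ("halton-scrambled", "pseudo-random"):
            raise ValueError(f"unknown draw_type {self.draw_type!r}")
        if self.se_method not in ("hessian", "sandwich"):
            raise ValueError(f"unknown se_method {self.se_method!r}")


@dataclass
class FitResult:
    """Estimates, uncertainty, and convergence metadata for a model fit."""

    model: str  # "rpl" or "clogit"
    coef_names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_obs: int
    n_respondents: int
    config: EstimationConfig | None = None
    message: str = ""

    def coef(self, name: str) -> float:
        return float(self.estimates[self.coef_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.std_errors[self.coef_names.index(name)])

    def mean_sd_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient means and SDs (SDs are zero for a conditional logit)."""
        if self.model == "rpl":
            return (
                self.estimates[:K_COEF].copy(),
                np.abs(self.estimates[K_COEF : 2 * K_COEF]),
            )
        return self.estimates[:K_COEF].copy(), np.zeros(K_COEF)

    def extra_coefs(self) -> dict[str, float]:
        base = 2 * K_COEF if self.model == "rpl" else K_COEF
        return {
            n: float(v)
            for n, v in zip(self.coef_names[base:], self.estimates[base:])
        }

    def to_params(self) -> RPLParams:
        means, sds = self.mean_sd_arrays()
        return RPLParams.from_arrays(means, sds)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coef_names": list(self.coef_names),
            "estimates": self.estimates.tolist(),
            "std_errors": self.std_errors.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": self.loglik,
            "converged": bool(self.converged),
            "n_obs": self.n_obs,
            "n_respondents": self.n_respondents,
            "config": None if self.config is None else asdict(self.config),
            "message": self.message,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        cfg = d.get("config")
        return cls(
            model=d["model"],
            coef_names=list(d["coef_names"]),
            estimates=np.asarray(d["estimates"], dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            cov=None if d.get("cov") is None else np.asarray(d["cov"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_obs=int(d["n_obs"]),
            n_respondents=int(d["n_respondents"]),
            config=None if cfg is None else EstimationConfig(**cfg),
            message=d.get("message", ""),
        )


# ---------------------------------------------------------------------------
# Elementary pieces


def systematic_utility(draw, attrs: ScenarioAttributes) -> float:
    """Systematic utility of one alternative for one realized coefficient vector.

    ``draw`` holds the nine coefficients in :data:`COEF_NAMES` order with the
    price coefficient on the pre-exponentiation scale.  The status quo
    alternative yields the alternative-specific constant alone.
    """
    b = np.asarray(draw, dtype=float)
    if b.shape[-1] != K_COEF:
        raise ValueError(f"draw must have {K_COEF} coefficients")
    if attrs.is_status_quo:
        return float(b[0])
    return float(
        -np.exp(b[1]) * attrs.price
        + b[2] * attrs.recovered
        + b[3] * attrs.returning_fish
        + b[4] * attrs.quick
        + b[5] * attrs.fishing1
        + b[6] * attrs.fishing2
        + b[7] * attrs.recovered * attrs.returning_fish
        + b[8] * attrs.quick * attrs.returning_fish
    )


def logit_probabilities(utilities) -> np.ndarray:
    """Softmax over a task's alternatives, overflow-safe via max-subtraction."""
    u = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("utilities must be finite")
    e = np.exp(u - u.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def lr_test(loglik_restricted: float, loglik_full: float, df: int):
    """Likelihood-ratio statistic 2*(LL_full - LL_restricted) and chi-square p-value.

    Small negative statistics (simulation noise in nested simulated fits)
    are clamped to zero with a warning.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    stat = 2.0 * (loglik_full - loglik_restricted)
    if stat < 0:
        warnings.warn(
            f"LR statistic negative ({stat:.3g}); restricted fit beat the full "
            "fit — clamping to 0 (check that nested fits share draws)",
            stacklevel=2,
        )
        stat = 0.0
    return float(stat), float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Panel arrays

@dataclass
class _Panel:
    X: np.ndarray  # (R, T, A, K_COEF)
    extra: np.ndarray | None  # (R, T, A, M)
    chosen: np.ndarray  # (R, T) int
    task_mask: np.ndarray  # (R, T) float 0/1
    alt_mask: np.ndarray  # (R, T, A) bool
    resp_ids: np.ndarray
    n_obs: int


def _moderator_values(moderator, resp_ids) -> np.ndarray:
    if isinstance(moderator, pd.Series):
        m = moderator.reindex(resp_ids)
        if m.isna().any():
            missing = list(np.asarray(resp_ids)[m.isna().to_numpy()][:3])
            raise ValueError(f"moderator missing for respondents {missing}")
        return m.to_numpy(dtype=float)
    if isinstance(moderator, dict):
        try:
            return np.array([float(moderator[r]) for r in resp_ids])
        except KeyError as e:
            raise ValueError(f"moderator missing for respondent {e}") from None
    m = np.asarray(moderator, dtype=float)
    if m.shape[0] != len(resp_ids):
        raise ValueError(
            f"moderator length {m.shape[0]} != number of respondents {len(resp_ids)}"
        )
    return m


def build_panel(
    data: ChoiceDataset, moderator=None, targets: Sequence[str] = ()
) -> _Panel:
    """Pack a long-format dataset into padded (resp, task, alt) arrays.

    ``moderator`` (per-respondent values) and ``targets`` (attribute names
    among recovered/fish/quick) add fixed-coefficient interaction columns
    ``moderator * attribute``.
    """
    df = data.rows.sort_values(
        ["resp_id", "task_id", "alt_id"], kind="mergesort"
    ).reset_index(drop=True)
    resp_codes, resp_ids = pd.factorize(df["resp_id"])
    task_codes = pd.factorize(
        df["resp_id"].astype(str) + "\x1f" + df["task_id"].astype(str)
    )[0]

    n = len(df)
    new_resp = np.r_[True, resp_codes[1:] != resp_codes[:-1]]
    new_task = new_resp | np.r_[True, task_codes[1:] != task_codes[:-1]]
    task_counter = np.cumsum(new_task) - 1
    resp_first_task = np.maximum.accumulate(np.where(new_resp, task_counter, -1))
    t_idx = task_counter - resp_first_task
    pos = np.arange(n)
    task_first_pos = np.maximum.accumulate(np.where(new_task, pos, -1))
    a_idx = pos - task_first_pos

    R = len(resp_ids)
    T = int(t_idx.max()) + 1
    A = int(a_idx.max()) + 1

    xr = np.column_stack(
        [
            df["is_status_quo"].to_numpy(float),
            df["price"].to_numpy(float),
            df["recovered"].to_numpy(float),
            df["returning_fish"].to_numpy(float),
            df["quick"].to_numpy(float),
            df["fishing1"].to_numpy(float),
            df["fishing2"].to_numpy(float),
            (df["recovered"] * df["returning_fish"]).to_numpy(float),
            (df["quick"] * df["returning_fish"]).to_numpy(float),
        ]
    )

    X = np.zeros((R, T, A, K_COEF))
    alt_mask = np.zeros((R, T, A), dtype=bool)
    task_mask = np.zeros((R, T))
    chosen = np.zeros((R, T), dtype=np.int64)

    X[resp_codes, t_idx, a_idx] = xr
    alt_mask[resp_codes, t_idx, a_idx] = True
    task_mask[resp_codes, t_idx] = 1.0
    ch = df["chosen"].to_numpy() == 1
    chosen[resp_codes[ch], t_idx[ch]] = a_idx[ch]

    # padded tasks: give them a uniform dummy so log-probabilities stay finite
    pad = task_mask == 0
    alt_mask[pad] = True

    extra = None
    if moderator is not None:
        if not targets:
            raise ValueError("targets required when a moderator is supplied")
        m = _moderator_values(moderator, resp_ids)
        if np.ptp(m) == 0:
            raise ValueError(
                "moderator is constant across respondents: interaction columns "
                "would be collinear with the main effects"
            )
        cols = [ATTRIBUTE_COLUMNS[t] for t in targets]
        extra = X[..., cols] * m[:, None, None, None]

    return _Panel(
        X=X,
        extra=extra,
        chosen=chosen,
        task_mask=task_mask,
        alt_mask=alt_mask,
        resp_ids=np.asarray(resp_ids),
        n_obs=int(task_mask.sum()),
    )


# ---------------------------------------------------------------------------
# Simulation draws


def make_draws(n_respondents: int, config: EstimationConfig) -> np.ndarray:
    """Standard-normal mixing draws, one block of ``n_draws`` per respondent.

    Scrambled Halton points (base primes per coefficient dimension) are
    generated as a single sequence and partitioned into consecutive
    per-respondent blocks, then mapped through the normal quantile function.
    """
    total = n_respondents * config.n_draws
    if config.draw_type == "halton-scrambled":
        eng = qmc.Halton(d=K_COEF, scramble=True, seed=config.seed)
        u = eng.random(total)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        z = special.ndtri(u)
    else:
        rng = np.random.default_rng(config.seed)
        z = rng.standard_normal((total, K_COEF))
    return z.reshape(n_respondents, config.n_draws, K_COEF)


def _effective_coefs(beta: np.ndarray) -> np.ndarray:
    """Map raw coefficients to utility weights (negated exponential price)."""
    c = beta.copy()
    c[..., 1] = -np.exp(np.clip(beta[..., 1], -_EXP_CLIP, _EXP_CLIP))
    return c


# ---------------------------------------------------------------------------
# Mixed (panel) simulated likelihood

try:  # fused kernel; the numpy implementation below is the reference path
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _panel_kernel(X, extra, gam, chosen, task_mask, alt_mask, beta,
                      pll, score):
        """Per-(respondent, draw) panel log-likelihood and score, one pass."""
        R, T, A, K = X.shape
        D = beta.shape[1]
        M = extra.shape[3]
        u = np.empty(A)
        e = np.empty(A)
        for r in range(R):
            for d in range(D):
                b1 = beta[r, d, 1]
                if b1 > _EXP_CLIP:
                    b1 = _EXP_CLIP
                elif b1 < -_EXP_CLIP:
                    b1 = -_EXP_CLIP
                c1 = -np.exp(b1)
                ll = 0.0
                for j in range(K + M):
                    score[r, d, j] = 0.0
                for t in range(T):
                    if task_mask[r, t] == 0.0:
                        continue
                    umax = -np.inf
                    for a in range(A):
                        if not alt_mask[r, t, a]:
                            u[a] = -np.inf
                            continue
                        s = 0.0
                        for k in range(K):
                            ck = c1 if k == 1 else beta[r, d, k]
                            s += X[r, t, a, k] * ck
                        for m in range(M):
                            s += extra[r, t, a, m] * gam[m]
                        u[a] = s
                        if s > umax:
                            umax = s
                    den = 0.0
                    for a in range(A):
                        e[a] = np.exp(u[a] - umax) if alt_mask[r, t, a] else 0.0
                        den += e[a]
                    ch = chosen[r, t]
                    ll += (u[ch] - umax) - np.log(den)
                    for a in range(A):
                        resid = (1.0 if a == ch else 0.0) - e[a] / den
                        for k in range(K):
                            score[r, d, k] += resid * X[r, t, a, k]
                        for m in range(M):
                            score[r, d, K + m] += resid * extra[r, t, a, m]
                score[r, d, 1] *= c1
                pll[r, d] = ll


def _mixed_loglik(theta, panel: _Panel, z, n_extra, want_grad=True,
                  want_scores=False):
    """Simulated panel log-likelihood and gradient (fused kernel when available)."""
    if not _HAVE_NUMBA:  # pragma: no cover
        return _mixed_loglik_numpy(theta, panel, z, n_extra, want_grad,
                                   want_scores)
    R, T, A, K = panel.X.shape
    D = z.shape[1]
    mu = theta[:K]
    sg = theta[K : 2 * K]
    gam = np.asarray(theta[2 * K :], dtype=float)
    beta = mu + sg * z
    extra = (
        panel.extra
        if panel.extra is not None
        else np.zeros((R, T, A, 0))
    )
    pll = np.empty((R, D))
    score = np.empty((R, D, K + n_extra))
    _panel_kernel(
        panel.X, extra, gam, panel.chosen, panel.task_mask, panel.alt_mask,
        beta, pll, score,
    )
    m = pll.max(axis=1)
    w_unnorm = np.exp(pll - m[:, None])
    S = w_unnorm.sum(axis=1)
    ll_r = m + np.log(S) - np.log(D)
    floored = ll_r < _PROB_FLOOR_LOG
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} respondent likelihood(s) underflowed; "
            "flooring at 1e-300",
            stacklevel=2,
        )
        ll_r = np.maximum(ll_r, _PROB_FLOOR_LOG)
    ll = float(ll_r.sum())
    if not want_grad:
        return ll, None
    w = w_unnorm / S[:, None]
    grad_mu = np.einsum("rd,rdk->k", w, score[:, :, :K])
    grad_sg = np.einsum("rd,rdk,rdk->k", w, score[:, :, :K], z)
    parts = [grad_mu, grad_sg]
    if n_extra:
        parts.append(np.einsum("rd,rdm->m", w, score[:, :, K:]))
    grad = np.concatenate(parts)
    if want_scores:
        s_mu = np.einsum("rd,rdk->rk", w, score[:, :, :K])
        s_sg = np.einsum("rd,rdk,rdk->rk", w, score[:, :, :K], z)
        pieces = [s_mu, s_sg]
        if n_extra:
            pieces.append(np.einsum("rd,rdm->rm", w, score[:, :, K:]))
        return ll, grad, np.concatenate(pieces, axis=1)
    return ll, grad


def _mixed_loglik_numpy(theta, panel: _Panel, z, n_extra, want_grad=True,
                        want_scores=False):
    """Simulated panel log-likelihood and gradient.

    theta = [means (9), sds (9, unsigned), extra fixed coefs (M)].
    Returns (ll, grad[, scores]) where scores are per-respondent gradient
    contributions (for sandwich covariance).
    """
    R, T, A, K = panel.X.shape
    D = z.shape[1]
    mu = theta[:K]
    sg = theta[K : 2 * K]
    gam = theta[2 * K :]

    beta = mu + sg * z  # (R, D, K)
    c = _effective_coefs(beta)
    Xf = panel.X.reshape(R, T * A, K)
    U = np.matmul(c, Xf.transpose(0, 2, 1))  # (R, D, T*A)
    if n_extra:
        Ef = panel.extra.reshape(R, T * A, n_extra)
        U += (Ef @ gam)[:, None, :]
    U = U.reshape(R, D, T, A)
    U = np.where(panel.alt_mask[:, None, :, :], U, -np.inf)

    Umax = U.max(axis=3, keepdims=True)
    expU = np.exp(U - Umax)
    denom = expU.sum(axis=3)
    P = expU / denom[..., None]  # (R, D, T, A)
    logP = (U - Umax) - np.log(denom)[..., None]

    ch = panel.chosen[:, None, :, None]  # (R, 1, T, 1)
    lp_chosen = np.take_along_axis(logP, np.broadcast_to(ch, (R, D, T, 1)), axis=3)[
        ..., 0
    ]  # (R, D, T)
    panel_ll = (lp_chosen * panel.task_mask[:, None, :]).sum(axis=2)  # (R, D)

    m = panel_ll.max(axis=1)
    w_unnorm = np.exp(panel_ll - m[:, None])
    S = w_unnorm.sum(axis=1)
    ll_r = m + np.log(S) - np.log(D)
    floored = ll_r < _PROB_FLOOR_LOG
    if floored.any():
        warnings.warn(
            f"{int(floored.sum())} respondent likelihood(s) underflowed; "
            "flooring at 1e-300",
            stacklevel=2,
        )
        ll_r = np.maximum(ll_r, _PROB_FLOOR_LOG)
    ll = float(ll_r.sum())
    if not want_grad:
        return ll, None

    w = w_unnorm / S[:, None]  # (R, D) mixture weights

    # residual (chosen - P), masked to real tasks/alternatives
    Y = np.zeros((R, T, A))
    np.put_along_axis(Y, panel.chosen[..., None], 1.0, axis=2)
    resid = (Y[:, None, :, :] - P) * panel.task_mask[:, None, :, None]
    resid_flat = resid.reshape(R, D, T * A)

    score_beta = np.matmul(resid_flat, Xf)  # (R, D, K) d logL / d beta_k
    score_beta[..., 1] *= c[..., 1]  # chain rule through -exp()

    grad_mu = np.einsum("rd,rdk->k", w, score_beta)
    grad_sg = np.einsum("rd,rdk,rdk->k", w, score_beta, z)
    parts = [grad_mu, grad_sg]
    if n_extra:
        score_gam = np.matmul(resid_flat, Ef)  # (R, D, M)
        parts.append(np.einsum("rd,rdm->m", w, score_gam))
    grad = np.concatenate(parts)

    if want_scores:
        s_mu = np.einsum("rd,rdk->rk", w, score_beta)
        s_sg = np.einsum("rd,rdk,rdk->rk", w, score_beta, z)
        pieces = [s_mu, s_sg]
        if n_extra:
            pieces.append(np.einsum("rd,rdm->rm", w, score_gam))
        return ll, grad, np.concatenate(pieces, axis=1)
    return ll, grad


def simulated_loglik(
    params: RPLParams, data: ChoiceDataset, config: EstimationConfig,
    moderator=None, targets: Sequence[str] = (), extra_coefs=None,
) -> float:
    """Panel-mixed simulated log-likelihood at fixed parameters.

    Draws are generated once per respondent from ``config`` and reused
    across that respondent's tasks; deterministic for a fixed seed.
    """
    panel = build_panel(data, moderator=moderator, targets=targets)
    z = make_draws(panel.X.shape[0], config)
    n_extra = 0 if panel.extra is None else panel.extra.shape[-1]
    gam = np.zeros(n_extra) if extra_coefs is None else np.asarray(extra_coefs, float)
    theta = np.concatenate([params.means(), params.sds(), gam])
    ll, _ = _mixed_loglik(theta, panel, z, n_extra, want_grad=False)
    return ll


# ---------------------------------------------------------------------------
# Conditional logit


def _clogit_nll_grad(beta, X, chosen, task_mask, alt_mask):
    """Negative log-likelihood and gradient of the fixed-coefficient logit.

    ``beta`` has the 9 base coefficients (log-price scale at index 1) plus
    any fixed interaction coefficients appended; ``X`` is (R, T, A, K+M).
    """
    R, T, A, K = X.shape
    c = beta.copy()
    c[1] = -np.exp(np.clip(beta[1], -_EXP_CLIP, _EXP_CLIP))
    U = X @ c
    U = np.where(alt_mask, U, -np.inf)
    Umax = U.max(axis=2, keepdims=True)
    expU = np.exp(U - Umax)
    denom = expU.sum(axis=2)
    logP = (U - Umax) - np.log(denom)[..., None]
    lp = np.take_along_axis(logP, chosen[..., None], axis=2)[..., 0]
    nll = -float((lp * task_mask).sum())

    P = expU / denom[..., None]
    Y = np.zeros((R, T, A))
    np.put_along_axis(Y, chosen[..., None], 1.0, axis=2)
    resid = (P - Y) * task_mask[..., None]
    grad_c = np.einsum("rta,rtak->k", resid, X)
    grad_c[1] *= c[1]
    return nll, grad_c


def conditional_logit_loglik(beta, data: ChoiceDataset,
                             moderator=None, targets: Sequence[str] = ()) -> float:
    """Log-likelihood of the conditional logit at a fixed coefficient vector.

    The price coefficient is parameterized as ``-exp(beta[1])`` for
    comparability with the RPL.
    """
    panel = build_panel(data, moderator=moderator, targets=targets)
    X = panel.X if panel.extra is None else np.concatenate(
        [panel.X, panel.extra], axis=-1
    )
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != X.shape[-1]:
        raise ValueError(f"beta must have {X.shape[-1]} entries")
    nll, _ = _clogit_nll_grad(beta, X, panel.chosen, panel.task_mask, panel.alt_mask)
    return -nll


def _cov_from_hessian(H: np.ndarray):
    """Invert a Hessian, falling back to a pseudo-inverse with NaN-marked SEs."""
    try:
        cov = np.linalg.inv(H)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(cov))
        if np.all(np.isfinite(se)):
            return cov, se
    except np.linalg.LinAlgError:
        pass
    cov = np.linalg.pinv(H)
    d = np.diag(cov).copy()
    se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    return cov, se


def _numeric_hessian(grad_fn, theta, step=1e-5):
    """Central finite differences of an analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for i in range(k):
        h = step * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_conditional_logit(
    data: ChoiceDataset,
    config: EstimationConfig | None = None,
    start=None,
    moderator=None,
    targets: Sequence[str] = (),
) -> FitResult:
    """Maximum-likelihood conditional logit with the exponentiated price coefficient."""
    config = config or EstimationConfig(n_draws=1)
    panel = build_panel(data, moderator=moderator, targets=targets)
    n_extra = 0 if panel.extra is None else panel.extra.shape[-1]
    X = panel.X if panel.extra is None else np.concatenate(
        [panel.X, panel.extra], axis=-1
    )
    k = X.shape[-1]
    theta0 = np.zeros(k) if start is None else np.asarray(start, dtype=float).copy()

    def fun(t):
        return _clogit_nll_grad(t, X, panel.chosen, panel.task_mask, panel.alt_mask)

    res = optimize.minimize(
        fun,
        theta0,
        jac=True,
        method="BFGS",
        options={
            "maxiter": config.max_iterations,
            "gtol": config.gradient_tolerance,
        },
    )
    grad_fn = lambda t: fun(t)[1]
    H = _numeric_hessian(grad_fn, res.x)
    cov, se = _cov_from_hessian(H)
    names = list(COEF_NAMES) + [f"mod_x_{t}" for t in targets]
    return FitResult(
        model="clogit",
        coef_names=names,
        estimates=res.x,
        std_errors=se,
        cov=cov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=panel.n_obs,
        n_respondents=len(panel.resp_ids),
        config=config,
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# RPL estimation


def default_start(data: ChoiceDataset, config: EstimationConfig,
                  sd_start: float = 0.5) -> np.ndarray:
    """Truth-agnostic starting point: conditional-logit means, modest SDs."""
    cl = fit_conditional_logit(data, config)
    return np.concatenate([cl.estimates[:K_COEF], np.full(K_COEF, sd_start)])


def fit_rpl(
    data: ChoiceDataset,
    config: EstimationConfig | None = None,
    start: RPLParams | np.ndarray | None = None,
    moderator=None,
    targets: Sequence[str] = (),
) -> FitResult:
    """Maximum simulated likelihood fit of the panel random-parameters logit.

    SD parameters are estimated unsigned and reported as absolute values.
    Identical data, config, and seed reproduce the fit bit-for-bit.
    """
    config = config or EstimationConfig()
    panel = build_panel(data, moderator=moderator, targets=targets)
    R = panel.X.shape[0]
    n_extra = 0 if panel.extra is None else panel.extra.shape[-1]
    z = make_draws(R, config)

    if start is None:
        theta0 = default_start(data, config)
    elif isinstance(start, RPLParams):
        theta0 = np.concatenate([start.means(), start.sds()])
    else:
        theta0 = np.asarray(start, dtype=float).copy()
    if len(theta0) == 2 * K_COEF and n_extra:
        theta0 = np.concatenate([theta0, np.zeros(n_extra)])
    if len(theta0) != 2 * K_COEF + n_extra:
        raise ValueError("start vector has the wrong length")

    def negll(t):
        ll, g = _mixed_loglik(t, panel, z, n_extra)
        return -ll, -g

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            negll,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": config.max_iterations,
                "maxfun": 5 * config.max_iterations,
                "gtol": config.gradient_tolerance,
                "ftol": 1e-12,
            },
        )

    theta = res.x.copy()
    theta[K_COEF : 2 * K_COEF] = np.abs(theta[K_COEF : 2 * K_COEF])

    grad_fn = lambda t: -_mixed_loglik(t, panel, z, n_extra)[1]
    H = _numeric_hessian(grad_fn, theta, step=1e-4)
    cov, se = _cov_from_hessian(H)
    if config.se_method == "sandwich":
        _, _, scores = _mixed_loglik(theta, panel, z, n_extra, want_scores=True)
        B = scores.T @ scores
        cov = cov @ B @ cov
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)

    names = (
        [f"{n}_mean" for n in COEF_NAMES]
        + [f"{n}_sd" for n in COEF_NAMES]
        + [f"mod_x_{t}" for t in targets]
    )
    return FitResult(
        model="rpl",
        coef_names=names,
        estimates=theta,
        std_errors=se,
        cov=cov,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=panel.n_obs,
        n_respondents=R,
        config=config,
        message=str(res.message),
    )
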
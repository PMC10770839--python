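"""Multilevel Bayesian beta regression for the four sequence measures.

Model 1 regresses a unit-interval response on condition (0 transmission,
1 individual) and generation (1..G) with a logit link, a beta likelihood
parameterized by mean and precision (mu, phi), and crossed random
intercepts for the transmission chain and the seed-lineage stimulus.
Model 2 adds the condition x generation interaction.  Models are compared
by WAIC on the deviance scale; intervals are central 89% posterior
percentile intervals.

Responses that live on the closed interval (accuracy can be exactly 1) are
squeezed into the open interval before fitting; the integer hierarchy depth
is scaled by its maximum attainable value first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logsumexp

from ._hmc import sample_hmc

__all__ = [
    "Priors",
    "ModelSpec",
    "SamplerConfig",
    "PosteriorFit",
    "WaicResult",
    "WaicComparison",
    "FitError",
    "squeeze_to_open_interval",
    "transform_response",
    "fit_model",
    "credible_interval",
    "waic",
    "compare_waic",
    "posterior_predictive",
    "PredictiveSample",
]

#: maximum Sequitur depth of a length-12 string (every rule body has >= 2
#: symbols, so depth <= floor(log2(12)) = 3)
MAX_DEPTH_L12 = 3


class FitError(RuntimeError):
    """Sampling failed to converge; carries the diagnostics table."""

    def __init__(self, message: str, diagnostics: pd.DataFrame | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class Priors:
    """Weakly-informative defaults on the logit scale."""

    coef_sd: float = 1.5  # Normal(0, coef_sd) for intercept and slopes
    re_sd_rate: float = 1.0  # Exponential(rate) for random-effect SDs
    precision_rate: float = 0.1  # Exponential(rate) for beta precision phi


@dataclass(frozen=True)
class ModelSpec:
    """Model 1 (no interaction) or Model 2 (with interaction)."""

    response: str = "accuracy"
    interaction: bool = False
    priors: Priors = field(default_factory=Priors)
    center_generation: bool = False

    @property
    def fixed_names(self) -> list[str]:
        names = ["Intercept", "Condition", "Generation"]
        if self.interaction:
            names.append("Interaction")
        return names


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_leapfrog: int = 24
    seed: int = 0
    rhat_warn: float = 1.01
    rhat_fail: float = 1.1
    retries: int = 1
    require_convergence: bool = False


def squeeze_to_open_interval(y, n: int):
    """Map [0, 1] values strictly inside (0, 1): ``(y (n-1) + 0.5) / n``.

    The usual beta-regression boundary adjustment; order-preserving, with
    0.5 as a fixed point, and shrinking toward 0.5 as 1/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return (np.asarray(y, dtype=float) * (n - 1) + 0.5) / n


def transform_response(
    measure_rows: pd.DataFrame, response: str, max_depth: int = MAX_DEPTH_L12
) -> tuple[pd.DataFrame, dict]:
    """Build the modeling table for one response.

    Returns (table, metadata).  The table has columns ``y`` (strictly inside
    (0,1)), ``condition``, ``generation``, ``chain`` and ``stimulus`` (group
    codes).  Depth is divided by its maximum attainable value before the
    boundary squeeze; compression ratios above 1 (possible for very short
    raw streams) are clipped to 1 first, with a warning.
    """
    if response not in {"accuracy", "compression_ratio", "depth", "diversity"}:
        raise ValueError(f"unknown response {response!r}")
    rows = measure_rows.dropna(subset=[response]).copy()
    y = rows[response].to_numpy(dtype=float)
    meta: dict = {"response": response, "n": int(len(rows))}
    if response == "depth":
        y = y / max_depth
        meta["transformation"] = f"depth / {max_depth}, then boundary squeeze"
    else:
        meta["transformation"] = "boundary squeeze"
    if (y > 1).any():
        warnings.warn(
            f"{int((y > 1).sum())} {response} values exceed 1; clipped before squeeze"
        )
        meta["clipped_above_one"] = int((y > 1).sum())
        y = np.clip(y, 0.0, 1.0)
    y = squeeze_to_open_interval(y, len(y))
    # chains are distinct participants per condition; stimulus lineages are
    # shared seed identities across chains and conditions
    chain_key = rows["condition"].astype(int) * 10_000 + rows["chain_id"].astype(int)
    chain_codes, _ = pd.factorize(chain_key, sort=True)
    stim_codes, _ = pd.factorize(rows["stimulus_id"], sort=True)
    table = pd.DataFrame(
        {
            "y": y,
            "condition": rows["condition"].to_numpy(dtype=float),
            "generation": rows["generation"].to_numpy(dtype=float),
            "chain": chain_codes,
            "stimulus": stim_codes,
        }
    )
    return table, meta


# ---------------------------------------------------------------------------
# the joint density


class _BetaRegProblem:
    """Precomputed design and the joint log density with analytic gradient.

    Parameter vector: fixed effects, then log random-effect SDs (chain,
    stimulus), log precision, then the standardized (non-centered) group
    offsets z_chain and z_stim.
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec):
        y = table["y"].to_numpy(dtype=float)
        if not ((y > 0) & (y < 1)).all():
            raise ValueError("response values must lie strictly in (0, 1)")
        self.y = y
        gen = table["generation"].to_numpy(dtype=float)
        self.gen_offset = gen.mean() if spec.center_generation else 0.0
        gen = gen - self.gen_offset
        cond = table["condition"].to_numpy(dtype=float)
        cols = [np.ones_like(y), cond, gen]
        if spec.interaction:
            cols.append(cond * gen)
        self.X = np.column_stack(cols)
        self.chain_idx = table["chain"].to_numpy(dtype=int)
        self.stim_idx = table["stimulus"].to_numpy(dtype=int)
        self.n_chain = int(self.chain_idx.max()) + 1
        self.n_stim = int(self.stim_idx.max()) + 1
        self.n_fixed = self.X.shape[1]
        self.dim = self.n_fixed + 3 + self.n_chain + self.n_stim
        self.spec = spec
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.logit_y = self.log_y - self.log_1my

    # -- parameter unpacking ------------------------------------------------

    def unpack(self, q: np.ndarray) -> dict[str, np.ndarray]:
        nf, nc = self.n_fixed, self.n_chain
        return {
            "beta": q[:nf],
            "log_sd_chain": q[nf],
            "log_sd_stim": q[nf + 1],
            "log_phi": q[nf + 2],
            "z_chain": q[nf + 3 : nf + 3 + nc],
            "z_stim": q[nf + 3 + nc :],
        }

    def linpred(self, q: np.ndarray) -> np.ndarray:
        p = self.unpack(q)
        return (
            self.X @ p["beta"]
            + np.exp(p["log_sd_chain"]) * p["z_chain"][self.chain_idx]
            + np.exp(p["log_sd_stim"]) * p["z_stim"][self.stim_idx]
        )

    def pointwise_loglik(self, q: np.ndarray) -> np.ndarray:
        p = self.unpack(q)
        phi = np.exp(p["log_phi"])
        mu = expit(np.clip(self.linpred(q), -30, 30))
        a, b = mu * phi, (1 - mu) * phi
        return (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1) * self.log_y
            + (b - 1) * self.log_1my
        )

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        nf, nc = self.n_fixed, self.n_chain
        p = self.unpack(q)
        # hard support bounds: reject absurd scales before they overflow
        if (
            abs(p["log_phi"]) > 12
            or abs(p["log_sd_chain"]) > 8
            or abs(p["log_sd_stim"]) > 8
            or np.abs(p["beta"]).max() > 50
        ):
            return -np.inf, np.zeros_like(q)
        sd_c = np.exp(p["log_sd_chain"])
        sd_s = np.exp(p["log_sd_stim"])
        phi = np.exp(p["log_phi"])
        pri = self.spec.priors

        eta = np.clip(self.linpred(q), -30, 30)
        mu = expit(eta)
        a, b = mu * phi, (1 - mu) * phi
        dg_a, dg_b = digamma(a), digamma(b)

        ll = (
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1) * self.log_y + (b - 1) * self.log_1my
        )
        # priors: Normal(0, coef_sd) on fixed effects; Exponential on the
        # SDs and precision with log-scale Jacobians; standard normal z
        logp = (
            float(ll.sum())
            - 0.5 * np.sum(p["beta"] ** 2) / pri.coef_sd**2
            - pri.re_sd_rate * (sd_c + sd_s) + p["log_sd_chain"] + p["log_sd_stim"]
            - pri.precision_rate * phi + p["log_phi"]
            - 0.5 * np.sum(p["z_chain"] ** 2)
            - 0.5 * np.sum(p["z_stim"] ** 2)
        )

        g_eta = phi * mu * (1 - mu) * (self.logit_y - dg_a + dg_b)
        grad = np.empty_like(q)
        grad[:nf] = self.X.T @ g_eta - p["beta"] / pri.coef_sd**2
        grad[nf] = (
            sd_c * float(np.sum(p["z_chain"][self.chain_idx] * g_eta))
            - pri.re_sd_rate * sd_c + 1.0
        )
        grad[nf + 1] = (
            sd_s * float(np.sum(p["z_stim"][self.stim_idx] * g_eta))
            - pri.re_sd_rate * sd_s + 1.0
        )
        dll_dphi = (
            digamma(phi) - mu * dg_a - (1 - mu) * dg_b
            + mu * self.log_y + (1 - mu) * self.log_1my
        )
        grad[nf + 2] = phi * float(dll_dphi.sum()) - pri.precision_rate * phi + 1.0
        grad[nf + 3 : nf + 3 + nc] = (
            sd_c * np.bincount(self.chain_idx, weights=g_eta, minlength=nc)
            - p["z_chain"]
        )
        grad[nf + 3 + nc :] = (
            sd_s * np.bincount(self.stim_idx, weights=g_eta, minlength=self.n_stim)
            - p["z_stim"]
        )
        return logp, grad


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics, and pointwise log-likelihood."""

    spec: ModelSpec
    param_names: list[str]  # fixed effects + sd_chain, sd_stim, phi
    draws: dict[str, np.ndarray]  # name -> (chains, draws)
    raw_draws: np.ndarray  # (chains, draws, dim), sampler coordinates
    diagnostics: pd.DataFrame  # index=param, cols=n_eff, rhat
    pointwise_loglik: np.ndarray  # (chains*draws, n_obs)
    sampler: SamplerConfig
    problem: "_BetaRegProblem"

    @property
    def n_obs(self) -> int:
        return self.pointwise_loglik.shape[1]

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self, mass: float = 0.89) -> pd.DataFrame:
        """Posterior summary mirroring the published tables."""
        rows = []
        for name in self.param_names:
            d = self.flat(name)
            lo, hi = credible_interval(d, mass)
            rows.append(
                {
                    "parameter": name,
                    "beta": d.mean(),
                    "Std": d.std(ddof=1),
                    f"Lower {mass:.2f}": lo,
                    f"Upper {mass:.2f}": hi,
                    "n_eff": self.diagnostics.loc[name, "n_eff"],
                    "Rhat": self.diagnostics.loc[name, "rhat"],
                }
            )
        return pd.DataFrame(rows)


def _natural_draws(problem: _BetaRegProblem, raw: np.ndarray, spec: ModelSpec):
    nf = problem.n_fixed
    names = spec.fixed_names + ["sd_chain", "sd_stim", "phi"]
    out = {}
    for k, name in enumerate(spec.fixed_names):
        out[name] = raw[:, :, k]
    out["sd_chain"] = np.exp(raw[:, :, nf])
    out["sd_stim"] = np.exp(raw[:, :, nf + 1])
    out["phi"] = np.exp(raw[:, :, nf + 2])
    return names, out


def fit_model(
    table: pd.DataFrame, spec: ModelSpec, sampler: SamplerConfig | None = None
) -> PosteriorFit:
    """Sample the posterior of Model 1 or Model 2 by HMC.

    Reproducible given ``sampler.seed``; warns when any R-hat exceeds
    ``sampler.rhat_warn`` and retries (fresh seed stream, doubled warmup)
    up to ``sampler.retries`` times when it exceeds ``sampler.rhat_fail``.
    """
    sampler = sampler or SamplerConfig()
    if table["chain"].nunique() < 2:
        raise ValueError("need >= 2 chains to fit chain random intercepts")
    problem = _BetaRegProblem(table, spec)

    attempt = 0
    warmup = sampler.warmup
    while True:
        rng = np.random.default_rng(np.random.SeedSequence([sampler.seed, attempt]))
        init = _initial_points(problem, sampler.chains, rng)
        res = sample_hmc(
            problem.logp_grad,
            init,
            n_chains=sampler.chains,
            n_warmup=warmup,
            n_draws=sampler.draws,
            rng=rng,
            target_accept=sampler.target_accept,
            max_leapfrog=sampler.max_leapfrog,
        )
        names, nat = _natural_draws(problem, res.draws, spec)
        diag = _diagnostics(names, nat)
        worst = float(diag["rhat"].max())
        if worst <= sampler.rhat_fail or attempt >= sampler.retries:
            break
        attempt += 1
        warmup *= 2
    if worst > sampler.rhat_warn:
        msg = f"max Rhat {worst:.3f} exceeds {sampler.rhat_warn}"
        if sampler.require_convergence and worst > sampler.rhat_fail:
            raise FitError(msg, diag)
        warnings.warn(msg)

    flat = res.draws.reshape(-1, problem.dim)
    loglik = np.stack([problem.pointwise_loglik(q) for q in flat])
    return PosteriorFit(
        spec=spec,
        param_names=names,
        draws=nat,
        raw_draws=res.draws,
        diagnostics=diag,
        pointwise_loglik=loglik,
        sampler=sampler,
        problem=problem,
    )


def _initial_points(problem: _BetaRegProblem, n_chains: int, rng) -> np.ndarray:
    base = np.zeros(problem.dim)
    y = problem.y
    base[0] = np.log(y.mean() / (1 - y.mean()))  # intercept at the grand mean
    base[problem.n_fixed] = np.log(0.1)
    base[problem.n_fixed + 1] = np.log(0.1)
    # moment-match phi from the marginal variance
    v = max(y.var(), 1e-6)
    base[problem.n_fixed + 2] = np.log(max(y.mean() * (1 - y.mean()) / v - 1, 1.0))
    return base + 0.1 * rng.standard_normal((n_chains, problem.dim))


def _diagnostics(names: list[str], nat: dict[str, np.ndarray]) -> pd.DataFrame:
    ds = az.convert_to_dataset({k: nat[k] for k in names})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(ds)
        rhat = az.rhat(ds)
    return pd.DataFrame(
        {
            "n_eff": [float(ess[k].values) for k in names],
            "rhat": [float(rhat[k].values) for k in names],
        },
        index=names,
    )


# ---------------------------------------------------------------------------
# summaries, WAIC, posterior predictive


def credible_interval(draws: np.ndarray, mass: float = 0.89) -> tuple[float, float]:
    """Central percentile interval (for mass 0.89: 5.5th to 94.5th)."""
    draws = np.asarray(draws)
    if draws.size == 0:
        raise ValueError("no draws")
    tail = 100 * (1 - mass) / 2
    lo, hi = np.percentile(draws, [tail, 100 - tail])
    return float(lo), float(hi)


@dataclass(frozen=True)
class WaicResult:
    waic: float  # deviance scale: -2 (lppd - p_waic)
    se: float
    lppd: float
    p_waic: float
    pointwise: np.ndarray  # per-observation WAIC contributions


@dataclass(frozen=True)
class WaicComparison:
    waic_1: float
    waic_2: float
    d_waic: float  # waic_1 - waic_2
    d_se: float


def waic(fit: "PosteriorFit | np.ndarray") -> WaicResult:
    """Widely applicable information criterion on the deviance scale.

    lppd_i = log mean_s exp(loglik_si) (log-sum-exp), p_i = var_s loglik_si;
    waic = -2 sum_i (lppd_i - p_i), se = sqrt(N var_i(waic_i)).
    """
    ll = fit.pointwise_loglik if isinstance(fit, PosteriorFit) else np.asarray(fit)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihoods")
    s, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * np.var(waic_i, ddof=1))) if n > 1 else 0.0
    return WaicResult(
        waic=float(waic_i.sum()),
        se=se,
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        pointwise=waic_i,
    )


def compare_waic(fit_1: PosteriorFit, fit_2: PosteriorFit) -> WaicComparison:
    """WAIC difference with the standard error of the pointwise differences."""
    w1, w2 = waic(fit_1), waic(fit_2)
    if w1.pointwise.shape != w2.pointwise.shape:
        raise ValueError("fits were computed on different observation sets")
    d_i = w1.pointwise - w2.pointwise
    n = d_i.size
    d_se = float(np.sqrt(n * np.var(d_i, ddof=1))) if n > 1 else 0.0
    return WaicComparison(w1.waic, w2.waic, float(d_i.sum()), d_se)


@dataclass
class PredictiveSample:
    samples: np.ndarray
    histogram: pd.DataFrame  # columns bin_left, count

    @property
    def mode_bin(self) -> float:
        """Left edge of the fullest histogram bin."""
        i = int(self.histogram["count"].idxmax())
        return float(self.histogram.loc[i, "bin_left"])


def posterior_predictive(
    fit: PosteriorFit,
    condition: int,
    generation: float,
    n_draws: int = 2000,
    rng: np.random.Generator | None = None,
    bin_width: float = 0.05,
) -> PredictiveSample:
    """Sample new observations at (condition, generation).

    For each posterior draw the linear predictor is evaluated with *new*
    chain and stimulus intercepts sampled from their fitted SDs (prediction
    for an unseen chain/stimulus), then an observation is drawn from the
    beta likelihood.  Includes parameter and sampling uncertainty.
    """
    rng = rng or np.random.default_rng(fit.sampler.seed + 1)
    spec = fit.spec
    gens = fit.problem.X[:, 2] + fit.problem.gen_offset
    if not (gens.min() <= generation <= gens.max()):
        warnings.warn(
            f"generation {generation} outside fitted range "
            f"[{gens.min():.0f}, {gens.max():.0f}]; extrapolating"
        )
    g = generation - fit.problem.gen_offset
    total = fit.flat(spec.fixed_names[0]).size
    pick = rng.integers(0, total, size=n_draws)
    eta = (
        fit.flat("Intercept")[pick]
        + fit.flat("Condition")[pick] * condition
        + fit.flat("Generation")[pick] * g
    )
    if spec.interaction:
        eta = eta + fit.flat("Interaction")[pick] * condition * g
    eta = eta + fit.flat("sd_chain")[pick] * rng.standard_normal(n_draws)
    eta = eta + fit.flat("sd_stim")[pick] * rng.standard_normal(n_draws)
    mu = expit(eta)
    phi = fit.flat("phi")[pick]
    samples = rng.beta(mu * phi, (1 - mu) * phi)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(samples, bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "count": counts})
    return PredictiveSample(samples, hist)
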
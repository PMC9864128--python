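"""Mixed-effect Bayesian multinomial logistic regression of state on habitat.

The probability that an observation belongs to behavioral state *k* is
modeled with a categorical (multinomial logit) likelihood.  The slowest
state (vigilance-excavation) is the reference; closed savanna is the
baseline land-cover class and is omitted from the covariates.  For each
non-reference state k, individual i and observation covariates x (buffered
proportions of forest, open savanna and floodable grassland):

    eta_k = beta0_k + b_{k, i} + sum_h (beta1_{kh} x_h + beta2_{kh} x_h^2)
    P(state = k) = softmax(eta)_k   with eta_reference = 0
    b_{k, i} ~ Normal(0, sigma_k)

Quadratic terms capture non-linear (edge-type) habitat responses;
individual random intercepts absorb heterogeneity among animals.
Regularizing priors (Normal(0, 1.5) on all beta, half-Normal(0, 1) on
sigma_k) keep the logits in a plausible range.  Posterior sampling uses
Hamiltonian Monte Carlo with warmup adaptation; convergence is summarized
with rank-normalized R-hat and effective sample size over >= 2 chains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _mnl_hmc
from .m3_model import FOUR_STATE_LABELS, UNCLASSIFIED

logger = logging.getLogger(__name__)

COVARIATES = ("p_forest", "p_open_savanna", "p_floodable_grassland")
FOCAL_CLASSES = ("forest", "open_savanna", "floodable_grassland")


@dataclass(frozen=True)
class RegressionSpec:
    """Model structure and priors for :func:`fit_multinomial`."""

    covariates: tuple[str, ...] = COVARIATES
    quadratic: bool = True
    sd_beta: float = 1.5  # Normal(0, sd_beta) prior on all fixed effects
    sd_sigma: float = 1.0  # half-Normal(0, sd_sigma) prior on sigma_k
    reference: str = FOUR_STATE_LABELS[0]  # vigilance-excavation


@dataclass
class RegressionPosterior:
    """Posterior draws and diagnostics of the multinomial mixed logit.

    ``beta`` has shape (chains, draws, S-1, P) with design columns
    [intercept, linear..., quadratic...]; ``sigma`` (chains, draws, S-1);
    ``u`` (chains, draws, S-1, I) holds the standardized random
    intercepts (b = sigma * u).
    """

    beta: np.ndarray
    sigma: np.ndarray
    u: np.ndarray
    state_names: list[str]
    individuals: list
    design_columns: list[str]
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    accept_rate: float = np.nan
    n_divergent: int = 0

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def stacked_beta(self) -> np.ndarray:
        """(total draws, S-1, P) with chains flattened."""
        c, d, k, p = self.beta.shape
        return self.beta.reshape(c * d, k, p)


def design_matrix(
    covariates: pd.DataFrame,
    spec: RegressionSpec,
) -> tuple[np.ndarray, list[str]]:
    """[1, x, x^2] design from raw (uncentered) proportion covariates."""
    cols = list(spec.covariates)
    X = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in cols:
        X.append(covariates[c].to_numpy(dtype=float))
        names.append(c)
    if spec.quadratic:
        for c in cols:
            X.append(covariates[c].to_numpy(dtype=float) ** 2)
            names.append(f"{c}^2")
    return np.column_stack(X), names


def softmax_probs(eta_nonref: np.ndarray) -> np.ndarray:
    """State probabilities from non-reference linear predictors.

    ``eta_nonref`` has shape (..., S-1); the reference state's predictor
    is identically zero.  Returns shape (..., S) summing to 1.
    """
    eta = np.concatenate(
        [np.zeros(eta_nonref.shape[:-1] + (1,)), eta_nonref], axis=-1
    )
    m = eta.max(axis=-1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=-1, keepdims=True)


def fit_multinomial(
    data: pd.DataFrame,
    spec: RegressionSpec | None = None,
    chains: int = 4,
    warmup: int = 1000,
    samples: int = 1000,
    seed: int = 0,
    state_order: tuple[str, ...] = FOUR_STATE_LABELS,
) -> RegressionPosterior:
    """Fit the mixed multinomial logit by HMC.

    ``data`` needs the covariate columns of ``spec``, a ``label`` column
    of state names (rows labeled "unclassified" are excluded) and an
    ``individual_id`` column.  ``state_order`` fixes the outcome coding;
    its first element present in the data is the reference state.
    """
    spec = spec or RegressionSpec()
    if chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    df = data[data["label"] != UNCLASSIFIED].copy()
    present = [s for s in state_order if s in set(df["label"])]
    extra = sorted(set(df["label"]) - set(present))
    present += extra
    if len(present) < 2:
        raise ValueError("need at least 2 states present in the data")
    if spec.reference in present:
        present.remove(spec.reference)
        present.insert(0, spec.reference)

    X, design_cols = design_matrix(df, spec)
    if any(np.ptp(X[:, j]) == 0 for j in range(1, X.shape[1])):
        raise ValueError(
            "degenerate covariates: at least one design column is constant"
        )
    code = {s: i for i, s in enumerate(present)}
    y = df["label"].map(code).to_numpy(dtype=np.int64)
    individuals = sorted(df["individual_id"].unique().tolist())
    ind = df["individual_id"].map({v: i for i, v in enumerate(individuals)})
    ind = ind.to_numpy(dtype=np.int64)

    S, I, P = len(present), len(individuals), X.shape[1]
    K = S - 1
    D = K * P + K + K * I

    rng = np.random.default_rng(seed)
    all_samples = np.empty((chains, samples, D))
    acc, ndiv = [], 0
    for c in range(chains):
        theta0 = 0.1 * rng.standard_normal(D)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        smp, a, dv = _mnl_hmc.run_chain(
            theta0,
            np.ascontiguousarray(X, dtype=np.float64),
            y,
            ind,
            S,
            I,
            spec.sd_beta,
            spec.sd_sigma,
            warmup,
            samples,
            chain_seed,
        )
        all_samples[c] = smp
        acc.append(a)
        ndiv += dv
        logger.info("chain %d: acceptance %.2f, %d divergences", c, a, dv)

    beta = all_samples[:, :, : K * P].reshape(chains, samples, K, P)
    tau = all_samples[:, :, K * P : K * P + K]
    u = all_samples[:, :, K * P + K :].reshape(chains, samples, K, I)
    post = RegressionPosterior(
        beta=beta,
        sigma=np.exp(tau),
        u=u,
        state_names=present,
        individuals=individuals,
        design_columns=design_cols,
        accept_rate=float(np.mean(acc)),
        n_divergent=int(ndiv),
    )
    post.diagnostics = convergence_diagnostics(post)
    bad = post.diagnostics[post.diagnostics["rhat"] > 1.01]
    if len(bad):
        warnings.warn(
            "R-hat > 1.01 for parameters: " + ", ".join(bad["parameter"]),
            RuntimeWarning,
            stacklevel=2,
        )
    return post


def draws_table(post: RegressionPosterior) -> pd.DataFrame:
    """Tidy posterior draws: one row per (chain, draw), one column per
    fixed effect and sigma."""
    c, d, k, p = post.beta.shape
    cols = {}
    for ki in range(k):
        state = post.state_names[ki + 1]
        for j, name in enumerate(post.design_columns):
            cols[f"beta[{state},{name}]"] = post.beta[:, :, ki, j].ravel()
        cols[f"sigma[{state}]"] = post.sigma[:, :, ki].ravel()
    out = pd.DataFrame(cols)
    out.insert(0, "chain", np.repeat(np.arange(c), d))
    out.insert(1, "draw", np.tile(np.arange(d), c))
    return out


def convergence_diagnostics(post: RegressionPosterior) -> pd.DataFrame:
    """Rank-normalized R-hat and bulk ESS per fixed effect and sigma."""
    import arviz as az

    rows = []
    K = post.n_states - 1
    for k in range(K):
        state = post.state_names[k + 1]
        for j, col in enumerate(post.design_columns):
            x = post.beta[:, :, k, j]
            rows.append(
                {
                    "parameter": f"beta[{state},{col}]",
                    "rhat": float(az.rhat(x)),
                    "ess_bulk": float(az.ess(x)),
                    "mean": float(x.mean()),
                    "sd": float(x.std()),
                }
            )
        x = post.sigma[:, :, k]
        rows.append(
            {
                "parameter": f"sigma[{state}]",
                "rhat": float(az.rhat(x)),
                "ess_bulk": float(az.ess(x)),
                "mean": float(x.mean()),
                "sd": float(x.std()),
            }
        )
    return pd.DataFrame(rows)


def predicted_probabilities(
    post: RegressionPosterior,
    covariates: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> np.ndarray:
    """Population-level (random intercepts at 0) state probabilities per
    posterior draw: shape (draws, n_obs, S)."""
    spec = spec or RegressionSpec()
    X, _ = design_matrix(covariates, spec)
    beta = post.stacked_beta()  # (T, K, P)
    eta = np.einsum("np,tkp->tnk", X, beta)
    return softmax_probs(eta)


def marginal_effects(
    post: RegressionPosterior,
    focal: str,
    grid: np.ndarray | None = None,
    spec: RegressionSpec | None = None,
) -> pd.DataFrame:
    """Marginal-effect curves for one focal land-cover class.

    The covariate profile sets the focal class proportion to p and the
    baseline class (closed savanna) to 1 - p, with the other classes at
    zero; random intercepts are set to zero (population level).  Returns
    per state and grid point the posterior mean and the pointwise 50% and
    95% credible bands.
    """
    if focal not in FOCAL_CLASSES:
        raise ValueError(f"focal class must be one of {FOCAL_CLASSES}")
    grid = np.linspace(0.0, 1.0, 51) if grid is None else np.asarray(grid, float)
    profile = pd.DataFrame({c: np.zeros(grid.size) for c in COVARIATES})
    profile[f"p_{focal}"] = grid
    probs = predicted_probabilities(post, profile, spec)  # (T, G, S)
    rows = []
    for s, name in enumerate(post.state_names):
        p = probs[:, :, s]
        rows.append(
            pd.DataFrame(
                {
                    "focal": focal,
                    "proportion": grid,
                    "state": name,
                    "mean": p.mean(axis=0),
                    "q25": np.quantile(p, 0.25, axis=0),
                    "q75": np.quantile(p, 0.75, axis=0),
                    "q2_5": np.quantile(p, 0.025, axis=0),
                    "q97_5": np.quantile(p, 0.975, axis=0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def sample_prior_predictive(
    covariates: pd.DataFrame,
    spec: RegressionSpec | None = None,
    n_states: int = 4,
    n_draws: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Prior predictive state probabilities (draws, n_obs, S): a check
    that the regularizing priors keep logits in a plausible range."""
    spec = spec or RegressionSpec()
    rng = np.random.default_rng(seed)
    X, _ = design_matrix(covariates, spec)
    K, P = n_states - 1, X.shape[1]
    beta = rng.normal(0.0, spec.sd_beta, size=(n_draws, K, P))
    eta = np.einsum("np,tkp->tnk", X, beta)
    return softmax_probs(eta)
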
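"""Latent behavioral states via a sparse Bayesian mixture of categoricals.

Observations are triples of bin indices (activity count, speed, turning
angle) treated as exchangeable draws from a finite mixture.  Each latent
state *k* has one categorical distribution per data stream, and mixing
weights come from a truncated stick-breaking prior,

    v_k ~ Beta(1, alpha),   pi_k = v_k * prod_{j<k} (1 - v_j),   v_K = 1,

whose small ``alpha`` (default 0.1) penalizes superfluous states, so the
model effectively estimates the number of states up to the truncation
``K_max``.  State-dependent categorical parameters get symmetric Dirichlet
priors.  Inference is by Gibbs sampling over (z, phi, v); streams missing
for an observation (the turning angle of the first step of a burst) simply
drop out of its likelihood.

After sampling, states are selected by cumulative share of observations
(>= 90% by default), observations are assigned to a state only when a
single state holds >= 75% of their posterior assignments (otherwise
"unclassified"), and retained states are ordered and named by increasing
mean speed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .track_preprocess import BinningScheme

logger = logging.getLogger(__name__)

STREAMS = ("activity", "speed", "turn")

#: canonical labels for a four-state solution, slowest first
FOUR_STATE_LABELS = ("vigilance-excavation", "local-search", "exploratory", "transit")

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MixtureConfig:
    """Sampler configuration.

    ``alpha`` is the stick-breaking scale (sparsity) hyperparameter;
    ``phi_prior`` the symmetric Dirichlet concentration per bin of the
    state-dependent categoricals.
    """

    k_max: int = 10
    alpha: float = 0.1
    phi_prior: float = 1.0
    n_iter: int = 20_000
    n_burn: int = 10_000
    seed: int = 42
    streams: tuple[str, ...] = STREAMS
    init: str = "kmeans"  # "kmeans" (over-segmented) or "uniform"

    def __post_init__(self) -> None:
        if self.k_max < 2:
            raise ValueError("K_max must be at least 2")
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("need 0 <= n_burn < n_iter")
        if self.alpha <= 0 or self.phi_prior <= 0:
            raise ValueError("alpha and phi_prior must be positive")
        if not self.streams:
            raise ValueError("at least one data stream is required")
        unknown = set(self.streams) - set(STREAMS)
        if unknown:
            raise ValueError(f"unknown streams {sorted(unknown)}")
        if self.init not in ("kmeans", "uniform"):
            raise ValueError("init must be 'kmeans' or 'uniform'")


@dataclass
class StatePosterior:
    """Post-burn-in MCMC output of :func:`gibbs_fit`.

    ``z_samples`` holds 0-based state assignments per retained iteration
    and observation; ``phi_samples[stream]`` has shape
    (n_retained, K_max, n_bins); ``pi_samples`` the mixing weights; the
    log-likelihood trace covers *all* iterations (burn-in included) for
    convergence inspection.
    """

    z_samples: np.ndarray
    phi_samples: dict[str, np.ndarray]
    pi_samples: np.ndarray
    loglik_trace: np.ndarray
    config: MixtureConfig
    n_bins: dict[str, int] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.z_samples.shape[1]

    @property
    def n_retained(self) -> int:
        return self.z_samples.shape[0]

    def state_shares(self) -> np.ndarray:
        """Mean fraction of observations assigned to each state across
        retained iterations."""
        k = self.config.k_max
        counts = np.apply_along_axis(np.bincount, 1, self.z_samples, minlength=k)
        return counts.mean(axis=0) / self.n_obs

    def membership(self) -> np.ndarray:
        """(n_obs, K_max) fraction of retained iterations assigning each
        observation to each state."""
        k = self.config.k_max
        n_it, n = self.z_samples.shape
        out = np.zeros((n, k))
        for row in self.z_samples:
            out[np.arange(n), row] += 1.0
        return out / n_it


def binned_to_arrays(
    binned: pd.DataFrame,
    streams: tuple[str, ...],
    scheme: BinningScheme | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Extract 0-based bin-index arrays (missing encoded as -1) and bin
    counts from a processed-observation table."""
    scheme = scheme or BinningScheme()
    sizes = scheme.n_bins
    arrays, n_bins = {}, {}
    for s in streams:
        col = binned[f"{s}_bin"].to_numpy(dtype=float)
        missing = ~np.isfinite(col)
        idx = np.where(missing, 0, col - 1).astype(np.int64)
        if np.any((idx < 0) | (idx >= sizes[s]) & ~missing):
            raise ValueError(f"{s}_bin outside 1..{sizes[s]}")
        idx[missing] = -1
        arrays[s] = idx
        n_bins[s] = sizes[s]
    return arrays, n_bins


def _initial_assignment(
    arrays: dict[str, np.ndarray],
    n_bins: dict[str, int],
    cfg: MixtureConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial z: over-segmented k-means on one-hot bins, or uniform draws.

    The Gibbs sampler merges redundant states readily (assignments drift
    toward the richer duplicate) but almost never splits an established
    state, because vacant stick-breaking components carry negligible
    weight.  Starting from an over-segmented k-means partition therefore
    leaves the sampler only merge moves to perform, which makes recovery
    of well-separated states insensitive to the random seed.
    """
    n = len(next(iter(arrays.values())))
    if cfg.init == "uniform" or n <= cfg.k_max:
        return rng.integers(0, cfg.k_max, size=n)
    from sklearn.cluster import KMeans

    cols = []
    for s in cfg.streams:
        a = arrays[s].astype(float)
        if s == "turn":
            # fold direction out: distance of the bin from the zero-turn
            # center separates high-turn from directed states
            a = np.abs(a - (n_bins[s] - 1) / 2.0)
        obs = a >= 0 if s != "turn" else arrays[s] >= 0
        mean = a[obs].mean() if obs.any() else 0.0
        sd = a[obs].std() or 1.0
        col = np.where(obs, (a - mean) / sd, 0.0)  # mean-impute missing
        cols.append(col)
    X = np.column_stack(cols)
    km = KMeans(
        n_clusters=min(cfg.k_max, len(np.unique(X, axis=0))),
        n_init=4,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    z = km.fit_predict(X).astype(np.int64)
    return z


def gibbs_fit(
    binned,
    cfg: MixtureConfig,
    n_bins: dict[str, int] | None = None,
    scheme: BinningScheme | None = None,
) -> StatePosterior:
    """Fit the truncated stick-breaking mixture by Gibbs sampling.

    ``binned`` is either a processed-observation DataFrame (with
    ``<stream>_bin`` columns, 1-based, NaN = missing) or a dict of 0-based
    integer arrays (-1 = missing), in which case ``n_bins`` gives the
    number of bins per stream.

    The Gibbs cycle is: (i) z_i from its full conditional
    proportional to pi_k * prod_d phi_{k,d}[bin_{i,d}]; (ii) phi_{k,d}
    from Dirichlet(phi_prior + state-k bin counts); (iii) stick v_k from
    Beta(1 + n_k, alpha + sum_{j>k} n_j).  The recorded log-likelihood is
    the marginal sum_i log sum_k pi_k prod_d phi_{k,d}[bin_{i,d}].
    """
    if isinstance(binned, pd.DataFrame):
        arrays, n_bins = binned_to_arrays(binned, cfg.streams, scheme)
    else:
        arrays = {s: np.asarray(binned[s], dtype=np.int64) for s in cfg.streams}
        if n_bins is None:
            n_bins = {s: int(arrays[s].max()) + 1 for s in cfg.streams}
    k = cfg.k_max
    n = len(next(iter(arrays.values())))
    if n < k:
        raise ValueError(f"need at least K_max={k} observations, got {n}")
    for s, a in arrays.items():
        if a.shape != (n,):
            raise ValueError("stream arrays must share one length")
        if np.any(a >= n_bins[s]):
            raise ValueError(f"bin index out of range for stream {s!r}")

    rng = np.random.default_rng(cfg.seed)
    # missing entries point at a zero-padded column of log phi
    idx = {s: np.where(arrays[s] < 0, n_bins[s], arrays[s]) for s in cfg.streams}

    z = _initial_assignment(arrays, n_bins, cfg, rng)
    n_retained = cfg.n_iter - cfg.n_burn
    z_samples = np.empty((n_retained, n), dtype=np.int16)
    phi_samples = {s: np.empty((n_retained, k, n_bins[s])) for s in cfg.streams}
    pi_samples = np.empty((n_retained, k))
    loglik = np.empty(cfg.n_iter)

    tiny = 1e-300
    for it in range(cfg.n_iter):
        # (ii) state-dependent categoricals | z
        log_phi_pad = {}
        phi_now = {}
        for s in cfg.streams:
            obs_mask = arrays[s] >= 0
            counts = np.zeros((k, n_bins[s]))
            np.add.at(counts, (z[obs_mask], arrays[s][obs_mask]), 1.0)
            g = rng.standard_gamma(cfg.phi_prior + counts)
            phi = g / g.sum(axis=1, keepdims=True)
            phi_now[s] = phi
            pad = np.zeros((k, n_bins[s] + 1))
            pad[:, :-1] = np.log(np.maximum(phi, tiny))
            log_phi_pad[s] = pad

        # (iii) sticks | z
        n_k = np.bincount(z, minlength=k).astype(float)
        tail = np.concatenate([np.cumsum(n_k[::-1])[::-1][1:], [0.0]])
        v = rng.beta(1.0 + n_k, cfg.alpha + tail)
        v[-1] = 1.0
        log1mv = np.log(np.maximum(1.0 - v, tiny))
        log_pi = np.log(np.maximum(v, tiny))
        log_pi[1:] += np.cumsum(log1mv[:-1])

        # (i) assignments | pi, phi
        logw = np.broadcast_to(log_pi, (n, k)).copy()
        for s in cfg.streams:
            logw += log_phi_pad[s][:, idx[s]].T
        m = logw.max(axis=1, keepdims=True)
        p = np.exp(logw - m)
        tot = p.sum(axis=1)
        loglik[it] = float(np.sum(np.log(tot) + m[:, 0]))
        if not np.isfinite(loglik[it]):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")
        c = np.cumsum(p, axis=1)
        u = rng.random(n) * tot
        z = np.minimum((c < u[:, None]).sum(axis=1), k - 1)

        if it >= cfg.n_burn:
            j = it - cfg.n_burn
            z_samples[j] = z
            pi_samples[j] = np.exp(log_pi)
            for s in cfg.streams:
                phi_samples[s][j] = phi_now[s]

    logger.info(
        "gibbs_fit: %d observations, %d iterations (%d retained), final loglik %.1f",
        n, cfg.n_iter, n_retained, loglik[-1],
    )
    return StatePosterior(
        z_samples=z_samples,
        phi_samples=phi_samples,
        pi_samples=pi_samples,
        loglik_trace=loglik,
        config=cfg,
        n_bins=dict(n_bins),
    )


def ablation_fit(binned, cfg: MixtureConfig, **kwargs) -> StatePosterior:
    """Refit using only the GPS-derived streams (speed, turning angle),
    discarding accelerometer activity counts."""
    return gibbs_fit(binned, replace(cfg, streams=("speed", "turn")), **kwargs)


def select_states(post: StatePosterior, threshold: float = 0.90) -> list[int]:
    """States, in decreasing order of mean share of observations, forming
    the minimal prefix whose cumulative share reaches ``threshold``."""
    shares = post.state_shares()
    order = np.argsort(-shares, kind="stable")
    cum = np.cumsum(shares[order])
    n_keep = int(np.searchsorted(cum, threshold, side="left")) + 1
    n_keep = min(n_keep, len(order))
    retained = [int(s) for s in order[:n_keep]]
    logger.info(
        "select_states: retained %d states with cumulative share %.3f",
        n_keep, cum[n_keep - 1],
    )
    return retained


def assign_states(
    post: StatePosterior,
    retained: list[int],
    confidence: float = 0.75,
) -> pd.DataFrame:
    """Per-observation membership proportions and confident assignments.

    Returns a DataFrame with one ``member_<k>`` column per retained state
    (fraction of retained iterations assigning the observation to state
    k) and a nullable-integer ``state`` column: the argmax retained state
    when its proportion reaches ``confidence`` (inclusive), else missing
    (unclassified).
    """
    if not retained:
        raise ValueError("retained state list is empty")
    member = post.membership()[:, retained]
    best = np.argmax(member, axis=1)
    best_p = member[np.arange(member.shape[0]), best]
    state = np.where(best_p >= confidence, np.asarray(retained)[best], -1)
    out = pd.DataFrame(
        {f"member_{k}": member[:, j] for j, k in enumerate(retained)}
    )
    out["state"] = pd.array(
        np.where(state < 0, np.nan, state), dtype="Int64"
    )
    return out


def order_and_name_states(
    post: StatePosterior,
    retained: list[int],
) -> dict[int, str]:
    """Order retained states by increasing posterior-mean speed and name
    them.

    The ordering statistic is the expected speed bin under each state's
    posterior-mean categorical (ties broken by lower mean activity bin);
    if the fit had no speed stream, the first available stream is used.
    A four-state solution gets the canonical labels (vigilance-excavation,
    local-search, exploratory, transit); otherwise generic ordered names.
    """
    if not retained:
        raise ValueError("retained state list is empty")

    def mean_bin(stream: str, k: int) -> float:
        if stream not in post.phi_samples:
            return 0.0
        phi = post.phi_samples[stream][:, k, :].mean(axis=0)
        return float(np.sum(phi * np.arange(1, phi.size + 1)))

    primary = "speed" if "speed" in post.phi_samples else post.config.streams[0]
    keys = [(mean_bin(primary, k), mean_bin("activity", k), k) for k in retained]
    ordered = [k for _, _, k in sorted(keys)]
    if len(ordered) == len(FOUR_STATE_LABELS):
        labels = FOUR_STATE_LABELS
    else:
        labels = tuple(f"state-{i + 1}" for i in range(len(ordered)))
    return {k: lab for k, lab in zip(ordered, labels)}


def label_assignments(
    assignments: pd.DataFrame,
    names: dict[int, str],
) -> pd.DataFrame:
    """Attach a string ``label`` column (state name or "unclassified")."""
    out = assignments.copy()
    out["label"] = [
        names[int(s)] if pd.notna(s) else UNCLASSIFIED for s in out["state"]
    ]
    return out


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Advisory Geweke-style z-score comparing early and late segments of
    the log-likelihood trace (autocorrelation-adjusted via arviz ESS)."""
    import arviz as az

    a = trace[: max(int(first * trace.size), 2)]
    b = trace[-max(int(last * trace.size), 2):]

    def se(x: np.ndarray) -> float:
        ess = float(az.ess(np.asarray(x)[None, :]))
        ess = max(ess, 2.0)
        return float(np.var(x, ddof=1) / ess)

    return float((a.mean() - b.mean()) / np.sqrt(se(a) + se(b)))


# -- posterior summaries / I/O -------------------------------------------


def posterior_summary(
    post: StatePosterior,
    retained: list[int],
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Tidy per-state summary: share plus posterior-mean phi per stream/bin."""
    names = names or {k: f"state-{i + 1}" for i, k in enumerate(retained)}
    shares = post.state_shares()
    rows = []
    for k in retained:
        for s in post.config.streams:
            phi = post.phi_samples[s][:, k, :].mean(axis=0)
            for b, p in enumerate(phi, start=1):
                rows.append(
                    {
                        "state": k,
                        "label": names[k],
                        "share": shares[k],
                        "stream": s,
                        "bin": b,
                        "phi_mean": p,
                    }
                )
    return pd.DataFrame(rows)
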
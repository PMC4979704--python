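"""Bayesian admixture model (independent-frequency, admixture variant) fit by
Gibbs sampling.

Each individual i has membership proportions Q_i over K clusters
(Dirichlet(alpha) prior, alpha shared and inferred); each cluster k has a
minor-allele frequency P_kl per locus (uniform Beta(1,1) prior). Every
non-missing allele copy is assigned to a cluster given (Q, P); P is then
drawn from its Beta posterior, Q rows from Dirichlet(alpha + assignment
counts), and alpha by a Metropolis step under a uniform prior on (0, 10].
Missing dosages contribute no allele copies. Posterior means of Q and P are
accumulated over the post-burn-in cycles; no within-chain relabeling is
applied (on unstructured data the posterior symmetry of Q is itself the
signal of panmixia).

An optional simplified sampling-location prior replaces the shared alpha
with one inferred Dirichlet parameter vector per sampling location.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .io import DosageMatrix

__all__ = [
    "AdmixtureConfig",
    "AdmixtureResult",
    "gibbs_admixture",
    "symmetry_diagnostic",
    "admixture_loglik",
    "align_clusters",
]


@dataclass
class AdmixtureConfig:
    K: int
    burn_in: int = 5000
    samples: int = 2000
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_step: float = 0.05
    use_location_prior: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 1 or self.samples < 1:
            raise ValueError("cycle counts must be >= 1")
        if not 0 < self.alpha_init <= self.alpha_max:
            raise ValueError("alpha_init must lie in (0, alpha_max]")


@dataclass
class AdmixtureResult:
    Q: np.ndarray            # (n, K) posterior-mean memberships
    P: np.ndarray            # (K, L) posterior-mean minor-allele frequencies
    alpha_mean: float
    alpha_sd: float
    K: int
    seed: int
    n_cycles: tuple[int, int]  # (burn_in, samples)


def _copies(values: np.ndarray):
    """Split dosages into two allele-copy indicator matrices (+ validity)."""
    valid = values >= 0
    a1 = (values >= 1) & valid   # first copy carries minor allele iff g >= 1
    a2 = (values == 2) & valid   # second copy iff g == 2
    return a1.astype(np.int8), a2.astype(np.int8), valid


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(alpha, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=1, keepdims=True)


def _log_dir_prior(Q: np.ndarray, alpha_rows: np.ndarray) -> float:
    """Sum of log Dirichlet(alpha_rows[i]) densities of the Q rows."""
    return float(
        (
            gammaln(alpha_rows.sum(axis=1))
            - gammaln(alpha_rows).sum(axis=1)
            + ((alpha_rows - 1.0) * np.log(np.maximum(Q, 1e-300))).sum(axis=1)
        ).sum()
    )


def gibbs_admixture(
    d: DosageMatrix,
    cfg: AdmixtureConfig,
    locations: Optional[Sequence[str]] = None,
) -> AdmixtureResult:
    """Run the Gibbs sampler and return posterior means.

    ``locations`` (defaults to the table's habitat labels) is only used when
    ``cfg.use_location_prior`` is set.
    """
    n, L = d.values.shape
    K = cfg.K
    rng = np.random.default_rng(cfg.seed)

    if K == 1:
        return AdmixtureResult(
            Q=np.ones((n, 1)),
            P=np.clip(d.minor_freq()[None, :], 1e-6, 1 - 1e-6),
            alpha_mean=cfg.alpha_init,
            alpha_sd=0.0,
            K=1,
            seed=cfg.seed,
            n_cycles=(cfg.burn_in, cfg.samples),
        )

    a1, a2, valid = _copies(d.values)
    copies = [np.where(valid, a1, 0), np.where(valid, a2, 0)]

    if cfg.use_location_prior:
        locs = list(locations if locations is not None else d.habitat)
        loc_labels = sorted(set(locs))
        loc_idx = np.array([loc_labels.index(x) for x in locs])
        alpha_loc = np.full((len(loc_labels), K), cfg.alpha_init)
    else:
        loc_idx = np.zeros(n, dtype=int)
        alpha_loc = np.full((1, K), cfg.alpha_init)

    Q = np.full((n, K), 1.0 / K)
    P = rng.uniform(0.2, 0.8, size=(K, L))
    alpha_traces: list[float] = []
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)

    cols = np.arange(L)
    for cycle in range(cfg.burn_in + cfg.samples):
        minor_cnt = np.zeros((K, L))
        total_cnt = np.zeros((K, L))
        n_ik = np.zeros((n, K))
        for a in copies:
            # P(z = k | copy allele a) ~ Q_ik * P_kl^a (1-P_kl)^(1-a)
            like = np.where(a[:, :, None] == 1, P.T[None, :, :],
                            1.0 - P.T[None, :, :])
            w = Q[:, None, :] * like
            w = np.where(valid[:, :, None], w, 1.0)  # dummy for missing
            cum = np.cumsum(w, axis=2)
            u = rng.random((n, L, 1)) * cum[:, :, -1:]
            z = (cum < u).sum(axis=2)
            zv = np.where(valid, z, -1)
            for k in range(K):
                hit = zv == k
                minor_cnt[k] += (hit & (a == 1)).sum(axis=0)
                total_cnt[k] += hit.sum(axis=0)
                n_ik[:, k] += hit.sum(axis=1)
        P = rng.beta(1.0 + minor_cnt, 1.0 + total_cnt - minor_cnt)
        P = np.clip(P, 1e-9, 1.0 - 1e-9)
        Q = _dirichlet_rows(rng, alpha_loc[loc_idx] + n_ik)

        # Metropolis update of each free alpha component
        for li in range(alpha_loc.shape[0]):
            rows = loc_idx == li
            if cfg.use_location_prior:
                for k in range(K):
                    prop = alpha_loc[li].copy()
                    prop[k] += rng.normal(0.0, cfg.alpha_step)
                    if not 0.0 < prop[k] <= cfg.alpha_max:
                        continue
                    cur = _log_dir_prior(Q[rows], np.tile(alpha_loc[li], (rows.sum(), 1)))
                    new = _log_dir_prior(Q[rows], np.tile(prop, (rows.sum(), 1)))
                    if np.log(rng.random()) < new - cur:
                        alpha_loc[li] = prop
            else:
                a_cur = alpha_loc[0, 0]
                a_prop = a_cur + rng.normal(0.0, cfg.alpha_step)
                if 0.0 < a_prop <= cfg.alpha_max:
                    cur = _log_dir_prior(Q, np.full((n, K), a_cur))
                    new = _log_dir_prior(Q, np.full((n, K), a_prop))
                    if np.log(rng.random()) < new - cur:
                        alpha_loc[:] = a_prop
        alpha_traces.append(float(alpha_loc.mean()))

        if cycle >= cfg.burn_in:
            Q_sum += Q
            P_sum += P

    Q_mean = Q_sum / cfg.samples
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    trace = np.array(alpha_traces[cfg.burn_in:])
    return AdmixtureResult(
        Q=Q_mean,
        P=P_sum / cfg.samples,
        alpha_mean=float(trace.mean()),
        alpha_sd=float(trace.std()),
        K=K,
        seed=cfg.seed,
        n_cycles=(cfg.burn_in, cfg.samples),
    )


def symmetry_diagnostic(result: AdmixtureResult) -> float:
    """Max over individuals of the L-infinity distance of Q rows from the
    uniform membership vector (0 = perfectly even admixture)."""
    return float(np.abs(result.Q - 1.0 / result.K).max())


def admixture_loglik(d: DosageMatrix, Q: np.ndarray, P: np.ndarray) -> float:
    """Log-likelihood of the dosage data given memberships Q and cluster
    frequencies P (each allele copy an independent mixture draw)."""
    pm = Q @ P                      # (n, L) per-copy minor probability
    pm = np.clip(pm, 1e-12, 1 - 1e-12)
    v = d.values
    ok = v >= 0
    g = np.where(ok, v, 0).astype(float)
    ll = g * np.log(pm) + (2.0 - g) * np.log(1.0 - pm)
    ll = np.where(ok, ll + np.where(g == 1, np.log(2.0), 0.0), 0.0)
    return float(ll.sum())


def align_clusters(Q_ref: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Greedy column permutation of Q to best match Q_ref by correlation."""
    K = Q.shape[1]
    corr = np.corrcoef(Q_ref.T, Q.T)[:K, K:]
    perm = np.full(K, -1)
    used = set()
    for _ in range(K):
        idx = np.unravel_index(np.nanargmax(
            np.where(np.isnan(corr), -np.inf, corr)), corr.shape)
        perm[idx[0]] = idx[1]
        corr[idx[0], :] = np.nan
        corr[:, idx[1]] = np.nan
        used.add(idx[1])
    return Q[:, perm]
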
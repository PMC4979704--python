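"""Island-model simulation and the subsampled Fst null distribution.

A finite island model — ``d`` demes of ``N`` diploids exchanging migrants
symmetrically at rate ``m`` per generation — is run forward to
migration-drift equilibrium. Because the loci are unlinked and mating is
random within demes, the diploid Wright-Fisher dynamics are simulated on the
deme allele frequencies directly (binomial resampling of 2N gametes after
migration mixing); individual genotypes are realized Hardy-Weinberg within
demes at sampling time, which is exactly the marginal law of individual-based
simulation for unlinked loci. A Balding-Nichols shortcut (deme frequencies
drawn from Beta(p(1-F)/F, (1-p)(1-F)/F)) provides the same target marginal
structure without burn-in where speed matters.

The null distribution of the observed study statistic is built by repeatedly
sampling a study-sized subset (by default 55/55/49 individuals from the three
demes and 32 polymorphic loci) and computing Weir-Cockerham overall theta;
the empirical P of an observed theta is the lower-tail fraction of
replicates at or below it.

At equilibrium Wright's approximation gives
Fst ~ 1 / (1 + 4Nm (d/(d-1))^2), used to seed the migration-rate
calibration, which is then refined by bisection on realized Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fst import wc_theta_matrix

__all__ = [
    "IslandConfig",
    "SimulatedPopulation",
    "FstNullResult",
    "CalibrationError",
    "simulate_island",
    "balding_nichols_population",
    "calibrate_migration",
    "resample_fst_null",
    "wright_island_m",
]


class CalibrationError(RuntimeError):
    """Migration-rate calibration failed to reach the target tolerance."""


@dataclass
class IslandConfig:
    n_demes: int = 3
    deme_size: int = 1500
    n_loci: int = 3150
    migration_rate: float = 0.01
    init_freq_range: tuple[float, float] = (0.05, 0.95)
    burn_in_generations: Optional[int] = None  # default 10 x deme_size
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration_rate must be in [0, 1]")
        if min(self.n_demes, self.deme_size, self.n_loci) < 1:
            raise ValueError("counts must be positive")
        if self.burn_in_generations is None:
            self.burn_in_generations = 10 * self.deme_size

    @property
    def total_size(self) -> int:
        return self.n_demes * self.deme_size


@dataclass
class SimulatedPopulation:
    values: np.ndarray          # (total, n_loci) int8 dosages
    deme: np.ndarray            # (total,) int deme labels
    freqs: np.ndarray           # (n_demes, n_loci) final allele frequencies
    realized_fst: float
    generations: int
    seed: int


@dataclass
class FstNullResult:
    replicate_thetas: np.ndarray
    n_reps: int
    observed_theta: float
    empirical_p: float
    group_sizes: tuple[int, ...]
    n_loci_sample: int
    seed: int


def wright_island_m(target_fst: float, deme_size: int, n_demes: int) -> float:
    """Closed-form island-model migration rate for a target equilibrium Fst."""
    kappa = n_demes / (n_demes - 1.0)
    m = (1.0 / target_fst - 1.0) / (4.0 * deme_size * kappa**2)
    return min(m, 1.0)


def parametric_fst(freqs: np.ndarray) -> float:
    """Realized among-deme Fst from a (demes x loci) frequency matrix.

    Large-sample limit of Weir-Cockerham theta with equal deme weights,
    combined across loci as a ratio of sums:
    sum(s2) / sum(pbar qbar + s2 / r) with s2 the (r-1)-denominator
    among-deme variance.
    """
    r = freqs.shape[0]
    pbar = freqs.mean(axis=0)
    s2 = ((freqs - pbar) ** 2).sum(axis=0) / (r - 1.0)
    denom = pbar * (1.0 - pbar) + s2 / r
    use = denom > 0
    if not use.any():
        return 0.0
    return float(s2[use].sum() / denom[use].sum())


def _realize_genotypes(
    freqs: np.ndarray, deme_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw HWE genotypes within each deme from its allele frequencies."""
    d, L = freqs.shape
    values = np.empty((d * deme_size, L), dtype=np.int8)
    deme = np.repeat(np.arange(d), deme_size)
    for g in range(d):
        values[g * deme_size : (g + 1) * deme_size] = rng.binomial(
            2, freqs[g], size=(deme_size, L)
        ).astype(np.int8)
    return values, deme


def simulate_island(cfg: IslandConfig) -> SimulatedPopulation:
    """Run the island model to equilibrium and realize a diploid population.

    Each generation every deme's post-migration gamete frequency is
    (1-m) p_d + m mean(p_others) (conservative symmetric migration), and the
    next generation's frequency is a binomial(2N) draw from it. Equilibrium is
    monitored on a trailing window of realized-Fst checkpoints; the burn-in is
    extended (at most three times) while the window still trends.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.init_freq_range
    freqs = np.tile(rng.uniform(lo, hi, size=cfg.n_loci), (cfg.n_demes, 1))
    two_n = 2 * cfg.deme_size
    m = cfg.migration_rate
    d = cfg.n_demes

    checkpoints: list[float] = []
    gens_run = 0

    def run(n_gen: int, freqs: np.ndarray) -> np.ndarray:
        nonlocal gens_run
        step = max(1, n_gen // 50)
        for g in range(n_gen):
            if d > 1 and m > 0:
                others = (freqs.sum(axis=0) - freqs) / (d - 1)
                post = (1.0 - m) * freqs + m * others
            else:
                post = freqs
            freqs = rng.binomial(two_n, post) / two_n
            gens_run += 1
            if g % step == 0:
                checkpoints.append(parametric_fst(freqs))
        return freqs

    freqs = run(cfg.burn_in_generations, freqs)
    for _ in range(3):  # extend while the trailing window still trends
        window = checkpoints[-20:]
        if len(window) < 10:
            break
        t = np.arange(len(window))
        slope = np.polyfit(t, window, 1)[0]
        drift = abs(slope) * len(window)
        if drift <= 0.2 * (np.mean(window) + 1e-9):
            break
        freqs = run(cfg.burn_in_generations // 2, freqs)

    values, deme = _realize_genotypes(freqs, cfg.deme_size, rng)
    return SimulatedPopulation(
        values=values,
        deme=deme,
        freqs=freqs,
        realized_fst=parametric_fst(freqs),
        generations=gens_run,
        seed=cfg.seed,
    )


def balding_nichols_population(
    target_fst: float,
    n_demes: int = 3,
    deme_size: int = 1500,
    n_loci: int = 3150,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    seed: int = 0,
) -> SimulatedPopulation:
    """Fast structured population: Beta-distributed deme frequencies at a
    target Fst, HWE genotypes within demes. Generations = 0 marks it as the
    shortcut rather than a forward run."""
    if not 0.0 < target_fst < 1.0:
        raise ValueError("target_fst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(*ancestral_range, size=n_loci)
    lam = (1.0 - target_fst) / target_fst
    freqs = rng.beta(p * lam, (1.0 - p) * lam, size=(n_demes, n_loci))
    values, deme = _realize_genotypes(freqs, deme_size, rng)
    return SimulatedPopulation(
        values=values,
        deme=deme,
        freqs=freqs,
        realized_fst=parametric_fst(freqs),
        generations=0,
        seed=seed,
    )


def calibrate_migration(
    target_fst: float,
    cfg: IslandConfig,
    tolerance: float = 0.15,
    n_reps: int = 3,
    max_rounds: int = 12,
) -> float:
    """Find a migration rate whose mean realized Fst hits the target.

    Seeded at Wright's closed form, then bisected on log(m) against the mean
    realized Fst of ``n_reps`` forward simulations per candidate. Raises
    :class:`CalibrationError` if the target band is not reached within
    ``max_rounds`` refinements.
    """
    if not 0.0 < target_fst < 0.5:
        raise ValueError("target_fst must be in (0, 0.5)")

    def realized(m: float, round_idx: int) -> float:
        vals = []
        for k in range(n_reps):
            c = IslandConfig(
                n_demes=cfg.n_demes,
                deme_size=cfg.deme_size,
                n_loci=cfg.n_loci,
                migration_rate=m,
                init_freq_range=cfg.init_freq_range,
                burn_in_generations=cfg.burn_in_generations,
                seed=cfg.seed + 1000 * round_idx + k,
            )
            vals.append(simulate_island(c).realized_fst)
        return float(np.mean(vals))

    m = wright_island_m(target_fst, cfg.deme_size, cfg.n_demes)
    lo = hi = None  # log-scale bracket: lo -> Fst too high, hi -> too low
    for it in range(max_rounds):
        fst = realized(m, it)
        if abs(fst - target_fst) <= tolerance * target_fst:
            return m
        if fst > target_fst:
            lo = m  # need more migration
        else:
            hi = m
        if lo is not None and hi is not None:
            m = float(np.sqrt(lo * hi))
        elif lo is not None:
            m = min(1.0, lo * 2.0)
        else:
            m = hi / 2.0
    raise CalibrationError(
        f"no migration rate within {tolerance:.0%} of Fst={target_fst} "
        f"after {max_rounds} rounds"
    )


def resample_fst_null(
    pop: SimulatedPopulation,
    observed_theta: float,
    group_sizes: tuple[int, ...] = (55, 55, 49),
    n_loci_sample: int = 32,
    n_reps: int = 10000,
    seed: int = 0,
    add_one: bool = False,
) -> FstNullResult:
    """Subsampling null distribution of overall theta and its empirical P.

    Each replicate draws ``group_sizes[d]`` individuals without replacement
    from deme ``d`` and ``n_loci_sample`` loci without replacement from the
    loci polymorphic in the full population, then computes Weir-Cockerham
    overall theta with demes as groups. The empirical P is the lower-tail
    fraction of replicates with theta <= observed (plug-in by default;
    ``add_one`` switches to (count+1)/(reps+1)).
    """
    n_demes = int(pop.deme.max()) + 1
    if len(group_sizes) > n_demes:
        raise ValueError("more groups than demes")
    deme_rows = [np.flatnonzero(pop.deme == g) for g in range(len(group_sizes))]
    for rows, size in zip(deme_rows, group_sizes):
        if size > len(rows):
            raise ValueError("group size exceeds deme size")
    pooled = pop.freqs.mean(axis=0)
    poly = np.flatnonzero((pooled > 0) & (pooled < 1))
    if n_loci_sample > len(poly):
        raise ValueError("not enough polymorphic loci")

    rng = np.random.default_rng(seed)
    codes = np.concatenate(
        [np.full(s, g) for g, s in enumerate(group_sizes)]
    )
    thetas = np.empty(n_reps)
    for rep in range(n_reps):
        rows = np.concatenate(
            [r[rng.choice(len(r), s, replace=False)]
             for r, s in zip(deme_rows, group_sizes)]
        )
        loci = poly[rng.choice(len(poly), n_loci_sample, replace=False)]
        sub = pop.values[np.ix_(rows, loci)]
        a, b, c, _ = wc_theta_matrix(sub, codes, len(group_sizes))
        denom = a + b + c
        use = denom != 0
        thetas[rep] = a[use].sum() / denom[use].sum() if use.any() else 0.0

    count = int((thetas <= observed_theta).sum())
    p = (count + 1) / (n_reps + 1) if add_one else count / n_reps
    return FstNullResult(
        replicate_thetas=thetas,
        n_reps=n_reps,
        observed_theta=observed_theta,
        empirical_p=float(p),
        group_sizes=tuple(group_sizes),
        n_loci_sample=n_loci_sample,
        seed=seed,
    )
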
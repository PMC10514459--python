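"""Analytic equilibrium structure used to initialize simulations.

Two ingredients let a replicate start at (approximate) mutation-drift
equilibrium instead of a multi-hundred-thousand-year burn-in:

* the stationary age distribution of the life cycle under density
  regulation (found by solving for the density factor that makes the
  population projection stationary), and

* the stationary site-frequency spectrum of neutral and deleterious
  mutations from single-site diffusion theory: the expected number of
  segregating sites with derived count ``i`` is ``theta * L / i`` for
  neutral sites, multiplied for selected sites by the sojourn-time ratio
  ``w(x) = [int_x^1 psi] / [(1-x) psi(x) int_0^1 psi]`` with
  ``psi(y) = exp(-2*alpha*(h*y + (1-2h)*y^2/2))`` and ``alpha = 2*Ne*s``.

``Ne`` here is an effective size in *year* units (per-year drift rate
1/(2*Ne_years)); its ratio to carrying capacity for the default reindeer
life history was measured with :func:`estimate_ne_years_ratio` and is
exposed as :data:`NE_YEARS_RATIO`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.special import logsumexp

from .dfe import DfeSpec, category_of, dominance_of
from .scenarios import LifeHistory

__all__ = [
    "NE_YEARS_RATIO",
    "AgeStructure",
    "stable_age_structure",
    "neutral_sfs_counts",
    "selected_sfs_weights",
    "equilibrium_sites",
    "estimate_ne_years_ratio",
]

#: Calibrated diversity ratio of the default life history: equilibrium
#: per-site heterozygosity divided by 4*mu*K, with mu the per-meiosis
#: mutation rate (measured from neutral engine runs; see
#: estimate_ne_years_ratio and docs/methods.md).  Because a lineage mutates
#: once per generation, the effective size in year units is
#: THETA_RATIO * generation_time * K.
THETA_RATIO = 0.57
NE_YEARS_RATIO = THETA_RATIO  # backwards-compatible alias for the theta ratio


@dataclass(frozen=True)
class AgeStructure:
    """Stationary age profile of the regulated population."""

    age_probs: np.ndarray  # over ages 0..max_longevity
    density_factor: float  # equilibrium survival multiplier K/N'
    generation_time: float  # mean parent age in years


def stable_age_structure(lh: LifeHistory) -> AgeStructure:
    """Solve for the stationary age distribution under density regulation.

    At stationarity each age class satisfies n(a+1) = n(a) (1-m_a) d with a
    single density factor d; d is found by bisection on the renewal
    condition (one calf per calf, counting the expected litter contribution
    of reproductive-age females).
    """
    ages = np.arange(lh.max_longevity + 1)
    mort = np.asarray(lh.age_mortality)
    repro = (ages >= lh.first_repro_age) & (ages <= lh.max_repro_age)

    def renewal(d: float) -> float:
        surv = np.concatenate([[1.0], np.cumprod((1.0 - mort[:-1]) * d)])
        return 0.5 * lh.mean_litter * surv[repro].sum() - 1.0

    lo, hi = 1e-6, 1.0
    if renewal(hi) < 0.0:
        raise ValueError("life history cannot sustain a stationary population")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if renewal(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    d = 0.5 * (lo + hi)
    surv = np.concatenate([[1.0], np.cumprod((1.0 - mort[:-1]) * d)])
    probs = surv / surv.sum()
    t_gen = float(np.sum(ages[repro] * surv[repro]) / surv[repro].sum())
    return AgeStructure(age_probs=probs, density_factor=float(d), generation_time=t_gen)


def neutral_sfs_counts(theta_site: float, total_bp: float, two_n: int) -> np.ndarray:
    """Expected number of segregating neutral sites at derived count i=1..2N-1."""
    i = np.arange(1, two_n)
    return theta_site * total_bp / i


def selected_sfs_weights(alpha: float, h: float, two_n: int) -> np.ndarray:
    """Sojourn-time ratio w(x_i) of a selected to a neutral allele at
    x_i = i/2N, computed in log space (alpha = 2*Ne*s, s < 0)."""
    if alpha == 0.0:
        return np.ones(two_n - 1)
    # fine grid for the integrals of psi
    y = np.linspace(0.0, 1.0, 2048)
    log_psi = -2.0 * alpha * (h * y + (1.0 - 2.0 * h) * y**2 / 2.0)
    dy = y[1] - y[0]
    # log of the tail integral int_x^1 psi, via reversed cumulative logsumexp
    rev = log_psi[::-1]
    log_tail_rev = np.logaddexp.accumulate(rev) + np.log(dy)
    log_tail = log_tail_rev[::-1]
    log_total = log_tail[0]
    x = np.arange(1, two_n) / two_n
    log_psi_x = -2.0 * alpha * (h * x + (1.0 - 2.0 * h) * x**2 / 2.0)
    log_tail_x = np.interp(x, y, log_tail)
    logw = log_tail_x - np.log1p(-x) - log_psi_x - log_total
    return np.exp(np.minimum(logw, 0.0))


def equilibrium_sites(
    *,
    n_diploid: int,
    theta_site: float,
    ne_selection: float,
    total_bp: int,
    dfe: DfeSpec,
    rng: np.random.Generator,
    n_s_draws: int = 256,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw an equilibrium set of segregating sites for a population.

    ``theta_site`` is the total mutational diversity parameter per site
    (equilibrium neutral heterozygosity before splitting into DFE classes);
    ``ne_selection`` is the effective size (in year units) entering the
    selection intensity alpha = 2 * Ne * s.  Returns ``(pos, s, h, cat,
    count)`` arrays: site positions (uniform over the genome), scaled
    selection and dominance coefficients, DFE category codes and
    derived-allele counts (1..2N-1).  Site numbers per frequency class are
    Poisson around the diffusion expectation.
    """
    two_n = 2 * n_diploid
    theta = theta_site
    counts_i = np.arange(1, two_n)

    exp_counts = []  # (expected counts per i, s, h, cat)
    neutral_theta = theta * (1.0 - dfe.p_deleterious)
    exp_counts.append((neutral_sfs_counts(neutral_theta, total_bp, two_n), 0.0, 0.5, 0))
    if dfe.p_deleterious > 0.0:
        del_theta_each = theta * dfe.p_deleterious / n_s_draws
        raw = -rng.gamma(dfe.gamma_shape, dfe.gamma_scale, size=n_s_draws)
        if dfe.lethal_fraction > 0.0:
            raw[rng.random(n_s_draws) < dfe.lethal_fraction] = -1.0
        raw = np.maximum(raw, -1.0)
        for s_raw in raw:
            s_eff = max(s_raw * dfe.s_multiplier, -1.0)
            h = dominance_of(s_raw)
            alpha = 2.0 * ne_selection * s_eff
            w = selected_sfs_weights(alpha, h, two_n)
            exp_counts.append(
                (neutral_sfs_counts(del_theta_each, total_bp, two_n) * w,
                 s_eff, h, category_of(s_raw))
            )

    pos_l, s_l, h_l, cat_l, cnt_l = [], [], [], [], []
    for expected, s_eff, h, cat in exp_counts:
        n_per_i = rng.poisson(expected)
        total = int(n_per_i.sum())
        if total == 0:
            continue
        pos_l.append(rng.integers(0, total_bp, size=total))
        s_l.append(np.full(total, s_eff))
        h_l.append(np.full(total, h))
        cat_l.append(np.full(total, cat, dtype=np.int8))
        cnt_l.append(np.repeat(counts_i, n_per_i))
    if not pos_l:
        empty = np.empty(0)
        return (empty.astype(np.int64), empty, empty, empty.astype(np.int8), empty.astype(np.int64))
    return (
        np.concatenate(pos_l).astype(np.int64),
        np.concatenate(s_l),
        np.concatenate(h_l),
        np.concatenate(cat_l),
        np.concatenate(cnt_l).astype(np.int64),
    )


def estimate_ne_years_ratio(
    k: int = 150,
    years: int = 12_000,
    mutation_rate: float = 2e-7,
    seed: int = 1,
    life_history: LifeHistory | None = None,
) -> float:
    """Measure Ne_years / K for a life history from the engine itself.

    Runs a neutral single-population simulation from an empty genome to
    mutation-drift equilibrium and returns H_eq / (4 mu K), where H_eq is
    the mean per-site heterozygosity over the final quarter of the run.
    Slow (minutes); intended for recalibration when the life history
    changes, not for routine use.
    """
    from .engine import SinglePopulationRunner

    runner = SinglePopulationRunner(
        k=k,
        mutation_rate=mutation_rate,
        neutral_only=True,
        life_history=life_history or LifeHistory(),
        seed=seed,
    )
    hets = runner.run_collect_het(years=years, record_every=50)
    tail = hets[3 * len(hets) // 4 :]
    h_eq = float(np.mean(tail))
    return h_eq / (4.0 * mutation_rate * k)
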
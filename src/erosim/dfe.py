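"""Distribution of fitness effects (DFE) of new mutations.

New exonic mutations are deleterious (non-synonymous) with probability
``ns_to_syn_ratio / (1 + ns_to_syn_ratio)`` and neutral (synonymous)
otherwise.  Deleterious selection coefficients are ``s = -X`` with
``X ~ Gamma(shape, mean/shape)`` (a human-estimated DFE), clamped at -1.
Dominance is inversely related to effect size: nearly recessive for the
strongest mutations, nearly additive for the weakest.

When a simulation is population-rescaled, selection coefficients are
multiplied by ``1/λ`` (and re-clamped at -1) while the *category* and the
dominance coefficient are always assigned from the unscaled draw, so that
the dominance structure of the full-scale model is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "DfeSpec",
    "CATEGORIES",
    "CAT_NEUTRAL",
    "CAT_WEAK",
    "CAT_MODERATE",
    "CAT_STRONG",
    "CAT_VERY_STRONG",
    "dominance_of",
    "category_of",
    "sample_mutation_effects",
]

# integer codes used by the engine
CAT_NEUTRAL = 0
CAT_WEAK = 1
CAT_MODERATE = 2
CAT_STRONG = 3
CAT_VERY_STRONG = 4
CATEGORIES = ("neutral", "weak", "moderate", "strong", "very_strong")

# bin edges on the magnitude of the (unscaled) selection coefficient
_BIN_EDGES = (0.001, 0.01, 0.1)  # weak < 0.001 <= moderate < 0.01 <= strong < 0.1 <= very strong
_H_BY_CAT = {CAT_NEUTRAL: 0.5, CAT_WEAK: 0.4, CAT_MODERATE: 0.1, CAT_STRONG: 0.01, CAT_VERY_STRONG: 0.0}


def category_of(s_unscaled: float) -> int:
    """DFE bin of an unscaled selection coefficient (0 => neutral)."""
    if s_unscaled == 0.0:
        return CAT_NEUTRAL
    mag = -s_unscaled
    if mag < _BIN_EDGES[0]:
        return CAT_WEAK
    if mag < _BIN_EDGES[1]:
        return CAT_MODERATE
    if mag < _BIN_EDGES[2]:
        return CAT_STRONG
    return CAT_VERY_STRONG


def dominance_of(s_unscaled: float) -> float:
    """Dominance coefficient implied by the unscaled selection coefficient."""
    return _H_BY_CAT[category_of(s_unscaled)]


@dataclass(frozen=True)
class DfeSpec:
    """Specification of the mutational input.

    ``s_multiplier`` is 1 in an unscaled run; population rescaling sets it
    to 1/λ.  ``lethal_fraction`` optionally adds a discrete point mass of
    fully recessive lethals (off by default).
    """

    ns_to_syn_ratio: float = 2.31
    gamma_mean: float = 0.01314833  # magnitude of mean s
    gamma_shape: float = 0.186
    s_multiplier: float = 1.0
    lethal_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ns_to_syn_ratio < 0:
            raise ValueError("ns_to_syn_ratio must be >= 0")
        if self.gamma_mean <= 0 or self.gamma_shape <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.lethal_fraction < 1.0:
            raise ValueError("lethal_fraction must lie in [0, 1)")
        if self.s_multiplier < 1.0:
            raise ValueError("s_multiplier must be >= 1 (1/λ with λ <= 1)")

    @property
    def p_deleterious(self) -> float:
        """Probability that a new mutation is non-synonymous."""
        return self.ns_to_syn_ratio / (1.0 + self.ns_to_syn_ratio)

    @property
    def gamma_scale(self) -> float:
        return self.gamma_mean / self.gamma_shape

    def scaled(self, lam: float) -> "DfeSpec":
        return replace(self, s_multiplier=self.s_multiplier / lam)

    def bin_masses(self) -> np.ndarray:
        """Probability mass of each deleterious bin (weak..very_strong)
        under the gamma DFE, via the regularized incomplete gamma function."""
        from scipy.special import gammainc

        cdf = lambda x: gammainc(self.gamma_shape, x / self.gamma_scale)  # noqa: E731
        c1, c2, c3 = (cdf(e) for e in _BIN_EDGES)
        return np.array([c1, c2 - c1, c3 - c2, 1.0 - c3])


def sample_mutation_effects(
    dfe: DfeSpec, n: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw effects for ``n`` new mutations.

    Returns ``(s, h, category)`` where ``s`` is the (possibly rescaled)
    selection coefficient clamped at -1, ``h`` the dominance coefficient and
    ``category`` the integer DFE bin, both assigned from the unscaled draw.
    """
    s = np.zeros(n)
    raw = np.zeros(n)
    u = rng.random(n)
    del_mask = u < dfe.p_deleterious
    ndel = int(del_mask.sum())
    if ndel:
        draws = -rng.gamma(dfe.gamma_shape, dfe.gamma_scale, size=ndel)
        if dfe.lethal_fraction > 0.0:
            lethal = rng.random(ndel) < dfe.lethal_fraction
            draws[lethal] = -1.0
        raw[del_mask] = np.maximum(draws, -1.0)
        s[del_mask] = np.maximum(draws * dfe.s_multiplier, -1.0)
    cat = np.fromiter((category_of(x) for x in raw), dtype=np.int8, count=n)
    h = np.fromiter((_H_BY_CAT[c] for c in cat), dtype=np.float64, count=n)
    return s, h, cat
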
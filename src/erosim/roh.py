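"""Runs of homozygosity: sliding-window detection, F_ROH and the
recombination clock for dating inbreeding events.

The detector mirrors the PLINK ``--homozyg`` sliding-window approach: a
window of ``window_snp`` consecutive SNPs is called homozygous when it
contains at most ``window_het_max`` heterozygous calls; a SNP qualifies
when at least ``window_threshold`` of the windows containing it are
homozygous (with a reduced denominator near chromosome edges); maximal
stretches of consecutive qualifying SNPs are split at inter-SNP gaps above
``gap_kb`` and emitted when they satisfy the SNP-count, length, density and
segment-heterozygote limits.

Missing genotypes neither count as heterozygous nor break a run.
Coordinates are 1-based inclusive (VCF convention); segment length is
``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "RohParams",
    "RohSegment",
    "ClockParams",
    "PROFILES",
    "detect_roh",
    "f_roh",
    "inbreeding_clock",
    "heterozygosity_per_kb",
]

# genotype codes for this module's matrix interface
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass(frozen=True)
class RohParams:
    window_snp: int = 100
    window_het_max: int = 1
    window_threshold: float = 0.05
    min_snp: int = 25
    min_kb: float = 100.0
    density_kb_per_snp: float = 50.0
    gap_kb: float = 1_000.0
    segment_het_max: int = 750

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp, self.segment_het_max) <= 0:
            raise ValueError("SNP-count parameters must be positive")
        if min(self.min_kb, self.density_kb_per_snp, self.gap_kb) <= 0:
            raise ValueError("kb parameters must be positive")
        if not 0.0 < self.window_threshold <= 1.0:
            raise ValueError("window_threshold must lie in (0, 1]")
        if self.window_het_max < 0:
            raise ValueError("window_het_max must be >= 0")


#: named parameter presets: window of 100 or 1000 SNPs, 1 or 3 hets allowed
PROFILES: Dict[str, RohParams] = {
    "w100h1": RohParams(window_snp=100, window_het_max=1),
    "w100h3": RohParams(window_snp=100, window_het_max=3),
    "w1000h1": RohParams(window_snp=1000, window_het_max=1),
    "w1000h3": RohParams(window_snp=1000, window_het_max=3),
}


@dataclass(frozen=True)
class RohSegment:
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int
    n_het: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_roh(
    genotypes: np.ndarray,
    positions: np.ndarray,
    params: RohParams = RohParams(),
    chromosome: str = "1",
) -> List[RohSegment]:
    """Detect ROH for one sample on one chromosome.

    Parameters
    ----------
    genotypes : array of {0 hom-ref, 1 het, 2 hom-alt, -1 missing}
    positions : strictly increasing 1-based bp positions, same length
    """
    gt = np.asarray(genotypes)
    pos = np.asarray(positions, dtype=np.int64)
    if gt.shape != pos.shape:
        raise ValueError("genotypes and positions must have equal length")
    n = gt.size
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    w = params.window_snp
    if n < w:
        return []

    is_het = (gt == HET).astype(np.int32)
    # het count per window of w consecutive SNPs
    cs = np.concatenate([[0], np.cumsum(is_het)])
    win_het = cs[w:] - cs[:-w]  # windows 0 .. n-w
    win_hom = (win_het <= params.window_het_max).astype(np.int32)
    # for SNP i, windows covering it are max(0, i-w+1) .. min(i, n-w)
    ch = np.concatenate([[0], np.cumsum(win_hom)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_cover = hi - lo + 1
    n_hom = ch[hi + 1] - ch[lo]
    qualifies = n_hom >= params.window_threshold * n_cover

    segments: List[RohSegment] = []
    gap_bp = params.gap_kb * 1_000.0
    i = 0
    while i < n:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and qualifies[j + 1] and (pos[j + 1] - pos[j]) <= gap_bp:
            j += 1
        seg = _emit(pos, is_het, i, j, params, chromosome)
        if seg is not None:
            segments.append(seg)
        i = j + 1
    return segments


def _emit(pos, is_het, i, j, params: RohParams, chromosome: str) -> RohSegment | None:
    n_snps = j - i + 1
    length = int(pos[j] - pos[i] + 1)
    n_het = int(is_het[i : j + 1].sum())
    if n_snps < params.min_snp:
        return None
    if length < params.min_kb * 1_000.0:
        return None
    # mean density: at least one SNP per density_kb_per_snp kilobases
    if length / n_snps > params.density_kb_per_snp * 1_000.0:
        return None
    if n_het > params.segment_het_max:
        return None
    return RohSegment(chromosome, int(pos[i]), int(pos[j]), n_snps, n_het)


def f_roh(
    segments: Iterable[RohSegment],
    genome_bp: int,
    min_len: float = 100_000.0,
) -> float:
    """Fraction of the genome in ROH at least ``min_len`` bp long."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    total = sum(s.length for s in segments if s.length >= min_len)
    return total / genome_bp


@dataclass(frozen=True)
class ClockParams:
    r_cm_per_mb: float = 1.04
    generation_time: float = 6.0

    def __post_init__(self) -> None:
        if self.r_cm_per_mb <= 0:
            raise ValueError("recombination rate must be positive")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")


def _round_generations(g: float) -> float:
    """Report g to two significant figures (one decimal below 1).

    This is the rounding that reproduces the published timing table: e.g.
    480.77 -> 480, 96.15 -> 96, 9.615 -> 9.6, 0.687 -> 0.7.
    """
    if g >= 1.0:
        ndigits = 1 - int(np.floor(np.log10(g)))
        return round(g, min(ndigits, 1))
    return round(g, 1)


def inbreeding_clock(length_mb: float, params: ClockParams = ClockParams()) -> Tuple[float, int]:
    """Date the inbreeding event producing a ROH of ``length_mb``.

    Expected ROH length decays with recombination over generations,
    giving ``g = 100 / (2 r L)`` generations back in time for length L in
    Mb and recombination rate r in cM/Mb.  Returns ``(generations_bp,
    years_bp)`` with the reporting rounding of :func:`_round_generations`
    and years rounded to the nearest integer.
    """
    if length_mb <= 0:
        raise ValueError("ROH length must be positive")
    g = 100.0 / (2.0 * params.r_cm_per_mb * length_mb)
    g_rounded = _round_generations(g)
    years = round(g_rounded * params.generation_time)
    return g_rounded, int(years)


def heterozygosity_per_kb(genotypes: np.ndarray, callable_bp: int) -> float:
    """Heterozygous calls per 1,000 bp of callable sequence for one sample."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    gt = np.asarray(genotypes)
    return float((gt == HET).sum()) / callable_bp * 1_000.0
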
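"""Individual-based, age-structured, non-Wright-Fisher forward engine.

Each simulation cycle is one calendar year: reproduction (harem mating,
litter-size draws, recombined gametes with new mutations), then viability
selection in which the survival probability of individual *i* is

    p_i = min(1, W_i * (1 - age_mortality[age_i]) * min(K/N, 1))

with multiplicative genetic fitness W_i over derived alleles (homozygous
site: 1+s, heterozygous: 1+h*s), age-specific mortality, and density
regulation around the carrying capacity K (census N taken after
reproduction).  Population size is emergent; demographic events change K or
found a new population by drawing individuals from the mainland.

Genomes are sparse: each haplotype is a position-sorted slice of a shared
site-id pool, and all mutation metadata (position, s, h, DFE category,
origin year) lives in a per-replicate registry.  Sites fixed in every
extant population are folded into per-population fixed-load ledgers during
garbage collection, which keeps haplotypes near the segregating-site count.
The inner loops (gamete assembly, fitness, survival, reproduction) are
numba-compiled; all engine randomness flows through numpy's legacy MT19937
seeded once per replicate, so identical seeds give identical runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .dfe import DfeSpec, sample_mutation_effects
from .equilibrium import NE_YEARS_RATIO, equilibrium_sites, stable_age_structure
from .genome import GenomeArchitecture
from .scenarios import LifeHistory

__all__ = [
    "MutationRecord",
    "Population",
    "Engine",
    "PopulationSample",
    "sample_mutation",
    "individual_fitness",
    "sample_gametes",
    "save_state",
    "load_state",
]

_DEAD = -1e30  # log-fitness sentinel for lethal homozygotes


@dataclass(frozen=True)
class MutationRecord:
    chromosome: int
    position: int  # 0-based bp within chromosome
    s: float
    h: float
    category: int
    origin_year: int = 0


def sample_mutation(
    arch: GenomeArchitecture, dfe: DfeSpec, rng: np.random.Generator, origin_year: int = 0
) -> MutationRecord:
    """Draw a single new mutation: uniform site, DFE effect, dominance."""
    pos = int(rng.integers(0, arch.total_bp))
    s, h, cat = sample_mutation_effects(dfe, 1, rng)
    return MutationRecord(
        chromosome=arch.chromosome_of(pos),
        position=pos % arch.chromosome_bp,
        s=float(s[0]),
        h=float(h[0]),
        category=int(cat[0]),
        origin_year=origin_year,
    )


def individual_fitness(s: np.ndarray, h: np.ndarray, dosage: np.ndarray) -> float:
    """Multiplicative fitness from per-site effects and derived dosages.

    W = prod over homozygous-derived sites (1+s) * prod over heterozygous
    sites (1+h*s), floored at 0.
    """
    s = np.asarray(s, dtype=float)
    h = np.asarray(h, dtype=float)
    d = np.asarray(dosage)
    w = float(np.prod((1.0 + s)[d == 2]) * np.prod((1.0 + h * s)[d == 1]))
    return max(w, 0.0)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_engine(seed):
    np.random.seed(seed)


@njit(cache=True)
def _make_gamete(
    pool, sA, lA, sB, lB, out_start,
    seg_gene, seg_choice, n_genes, genes_per_chrom, gene_len,
    recomb, mu_total, total_bp,
    p_del, g_shape, g_scale, s_mult, lethal_frac,
    reg_pos, reg_s, reg_h, reg_cat, reg_origin, n_sites, year,
):
    """Write one recombined gamete (with new mutations) into pool[out_start:].

    Parent haplotype slices are position-sorted; per chromosome the gamete
    starts from a random parental haplotype and switches at gene boundaries
    with probability ``recomb`` (sites within a gene always co-segregate;
    chromosomes assort independently).  Crossovers are drawn as geometric
    gaps between switching boundaries and stored as (start-gene, choice)
    segments; the merge walks segments in step with the position-sorted
    sites.  Returns (gamete_length, n_sites).
    """
    nseg = 0
    g = 0
    while g < n_genes:
        if g % genes_per_chrom == 0:
            seg_gene[nseg] = g
            seg_choice[nseg] = np.random.randint(0, 2)
            nseg += 1
            g += 1
            continue
        if recomb <= 0.0:
            g = (g // genes_per_chrom + 1) * genes_per_chrom
            continue
        # next switching boundary within this chromosome
        jump = np.random.geometric(recomb)
        g += jump - 1
        chrom_end = (g // genes_per_chrom) * genes_per_chrom + genes_per_chrom
        if g >= chrom_end or g >= n_genes:
            g = chrom_end
            continue
        seg_gene[nseg] = g
        seg_choice[nseg] = 1 - seg_choice[nseg - 1]
        nseg += 1
        g += 1
    m = out_start
    ia = 0
    ib = 0
    k = 0
    while ia < lA or ib < lB:
        if ia < lA and ib < lB and pool[sA + ia] == pool[sB + ib]:
            site = pool[sA + ia]  # parent homozygous: carried either way
            ia += 1
            ib += 1
            pool[m] = site
            m += 1
        else:
            take_a = ib >= lB
            if not take_a and ia < lA:
                a = pool[sA + ia]
                b = pool[sB + ib]
                take_a = reg_pos[a] < reg_pos[b] or (reg_pos[a] == reg_pos[b] and a < b)
            if take_a:
                site = pool[sA + ia]
                ia += 1
                want = 0
            else:
                site = pool[sB + ib]
                ib += 1
                want = 1
            gi = reg_pos[site] // gene_len
            while k + 1 < nseg and seg_gene[k + 1] <= gi:
                k += 1
            if seg_choice[k] == want:
                pool[m] = site
                m += 1
    # de-novo mutations (infinite-sites: stacked records at colliding bp)
    nmut = np.random.poisson(mu_total)
    for _ in range(nmut):
        pos = np.random.randint(0, total_bp)
        s = 0.0
        h = 0.5
        cat = 0
        if np.random.random() < p_del:
            raw = -np.random.gamma(g_shape, g_scale)
            if lethal_frac > 0.0 and np.random.random() < lethal_frac:
                raw = -1.0
            if raw < -1.0:
                raw = -1.0
            mag = -raw
            if mag < 0.001:
                cat = 1
                h = 0.4
            elif mag < 0.01:
                cat = 2
                h = 0.1
            elif mag < 0.1:
                cat = 3
                h = 0.01
            else:
                cat = 4
                h = 0.0
            s = raw * s_mult
            if s < -1.0:
                s = -1.0
        sid = n_sites
        reg_pos[sid] = pos
        reg_s[sid] = s
        reg_h[sid] = h
        reg_cat[sid] = cat
        reg_origin[sid] = year
        n_sites += 1
        j = m
        while j > out_start and reg_pos[pool[j - 1]] > pos:
            pool[j] = pool[j - 1]
            j -= 1
        pool[j] = sid
        m += 1
    return m - out_start, n_sites


@njit(cache=True)
def _pair_logw(pool, sA, lA, sB, lB, reg_pos, reg_s, reg_h):
    """Log-fitness of a diploid from its two haplotype slices."""
    logw = 0.0
    ia = 0
    ib = 0
    while ia < lA or ib < lB:
        if ia < lA and ib < lB and pool[sA + ia] == pool[sB + ib]:
            site = pool[sA + ia]
            ia += 1
            ib += 1
            s = reg_s[site]
            if s != 0.0:
                if s <= -1.0:
                    logw = _DEAD
                else:
                    logw += np.log1p(s)
        else:
            take_a = ib >= lB
            if not take_a and ia < lA:
                a = pool[sA + ia]
                b = pool[sB + ib]
                take_a = reg_pos[a] < reg_pos[b] or (reg_pos[a] == reg_pos[b] and a < b)
            if take_a:
                site = pool[sA + ia]
                ia += 1
            else:
                site = pool[sB + ib]
                ib += 1
            s = reg_s[site]
            if s != 0.0:
                hs = reg_h[site] * s
                if hs <= -1.0:
                    logw = _DEAD
                else:
                    logw += np.log1p(hs)
    return logw


@njit(cache=True)
def _logw_all(pool, hap_start, hap_len, n_ind, reg_pos, reg_s, reg_h, out):
    for i in range(n_ind):
        out[i] = _pair_logw(
            pool, hap_start[i, 0], hap_len[i, 0], hap_start[i, 1], hap_len[i, 1],
            reg_pos, reg_s, reg_h,
        )


@njit(cache=True)
def _reproduce(
    pool, pool_used,
    hap_start, hap_len, age, is_female, logw, n_ind,
    first_repro, max_repro, male_frac, litter_cdf,
    n_genes, genes_per_chrom, gene_len, recomb, mu_total, total_bp,
    p_del, g_shape, g_scale, s_mult, lethal_frac,
    reg_pos, reg_s, reg_h, reg_cat, reg_origin, n_sites, year,
    seg_gene, seg_choice, elig_buf,
):
    """One year of harem reproduction; appends calves, returns updated
    (n_ind, pool_used, n_sites)."""
    n0 = n_ind
    nf = 0
    nm = 0
    for i in range(n0):
        a = age[i]
        if first_repro <= a <= max_repro:
            if is_female[i]:
                elig_buf[nf] = i
                nf += 1
            else:
                nm += 1
                elig_buf[elig_buf.size - nm] = i
    if nf == 0 or nm == 0:
        return n_ind, pool_used, n_sites
    k = int(round(male_frac * nm))
    if k <= 0:
        return n_ind, pool_used, n_sites
    males = elig_buf[elig_buf.size - nm:]
    for j in range(k):  # partial Fisher-Yates: this year's breeding males
        r = j + np.random.randint(0, nm - j)
        tmp = males[j]
        males[j] = males[r]
        males[r] = tmp
    for fi in range(nf):
        mother = elig_buf[fi]
        father = males[np.random.randint(0, k)]
        u = np.random.random()
        litter = 1
        while litter - 1 < litter_cdf.size - 1 and u > litter_cdf[litter - 1]:
            litter += 1
        for _ in range(litter):
            child = n_ind
            glen, n_sites = _make_gamete(
                pool, hap_start[mother, 0], hap_len[mother, 0],
                hap_start[mother, 1], hap_len[mother, 1], pool_used,
                seg_gene, seg_choice, n_genes, genes_per_chrom, gene_len,
                recomb, mu_total, total_bp,
                p_del, g_shape, g_scale, s_mult, lethal_frac,
                reg_pos, reg_s, reg_h, reg_cat, reg_origin, n_sites, year,
            )
            hap_start[child, 0] = pool_used
            hap_len[child, 0] = glen
            pool_used += glen
            glen2, n_sites = _make_gamete(
                pool, hap_start[father, 0], hap_len[father, 0],
                hap_start[father, 1], hap_len[father, 1], pool_used,
                seg_gene, seg_choice, n_genes, genes_per_chrom, gene_len,
                recomb, mu_total, total_bp,
                p_del, g_shape, g_scale, s_mult, lethal_frac,
                reg_pos, reg_s, reg_h, reg_cat, reg_origin, n_sites, year,
            )
            hap_start[child, 1] = pool_used
            hap_len[child, 1] = glen2
            pool_used += glen2
            age[child] = 0
            is_female[child] = np.random.random() < 0.5
            logw[child] = _pair_logw(
                pool, hap_start[child, 0], glen, hap_start[child, 1], glen2,
                reg_pos, reg_s, reg_h,
            )
            n_ind += 1
    return n_ind, pool_used, n_sites


@njit(cache=True)
def _survive(hap_start, hap_len, age, is_female, logw, n_ind, mort, k_cap, fixed_logw, max_age):
    """Viability selection + ageing; compacts survivors in place."""
    n = n_ind
    dens = 1.0
    if n > k_cap:
        dens = k_cap / n
    w = 0
    for i in range(n):
        a = age[i]
        p = 0.0
        if a <= max_age:
            lw = logw[i] + fixed_logw
            fit = np.exp(lw) if lw < 0.0 else 1.0
            p = fit * (1.0 - mort[a]) * dens
            if p > 1.0:
                p = 1.0
        if np.random.random() < p:
            hap_start[w, 0] = hap_start[i, 0]
            hap_start[w, 1] = hap_start[i, 1]
            hap_len[w, 0] = hap_len[i, 0]
            hap_len[w, 1] = hap_len[i, 1]
            age[w] = a + 1
            is_female[w] = is_female[i]
            logw[w] = logw[i]
            w += 1
    return w


@njit(cache=True)
def _count_alleles(pool, hap_start, hap_len, n_ind, counts):
    for i in range(n_ind):
        for slot in range(2):
            s0 = hap_start[i, slot]
            for t in range(hap_len[i, slot]):
                counts[pool[s0 + t]] += 1


@njit(cache=True)
def _rewrite_pool(pool, hap_start, hap_len, n_ind, remove, new_pool):
    ptr = 0
    for i in range(n_ind):
        for slot in range(2):
            s0 = hap_start[i, slot]
            ln = hap_len[i, slot]
            ns = ptr
            for t in range(ln):
                site = pool[s0 + t]
                if not remove[site]:
                    new_pool[ptr] = site
                    ptr += 1
            hap_start[i, slot] = ns
            hap_len[i, slot] = ptr - ns
    return ptr


@njit(cache=True)
def _sample_genotypes(pool, hap_start, hap_len, idx, reg_pos,
                      hom_buf, hom_off, het_buf, het_off):
    """Per sampled individual, split carried sites into homozygous and
    heterozygous id lists (position-sorted)."""
    hp = 0
    op = 0
    for si in range(idx.size):
        i = idx[si]
        hom_off[si] = op
        het_off[si] = hp
        sA = hap_start[i, 0]
        lA = hap_len[i, 0]
        sB = hap_start[i, 1]
        lB = hap_len[i, 1]
        ia = 0
        ib = 0
        while ia < lA or ib < lB:
            if ia < lA and ib < lB and pool[sA + ia] == pool[sB + ib]:
                hom_buf[op] = pool[sA + ia]
                op += 1
                ia += 1
                ib += 1
            else:
                take_a = ib >= lB
                if not take_a and ia < lA:
                    a = pool[sA + ia]
                    b = pool[sB + ib]
                    take_a = reg_pos[a] < reg_pos[b] or (reg_pos[a] == reg_pos[b] and a < b)
                if take_a:
                    het_buf[hp] = pool[sA + ia]
                    ia += 1
                else:
                    het_buf[hp] = pool[sB + ib]
                    ib += 1
                hp += 1
    hom_off[idx.size] = op
    het_off[idx.size] = hp


# ---------------------------------------------------------------------------
# python-side containers
# ---------------------------------------------------------------------------


class Population:
    """Mutable state of one population: individuals + haplotype pool."""

    def __init__(self, label: str, k: int, ind_capacity: int, pool_capacity: int):
        self.label = label
        self.k = int(k)
        self.n = 0
        self.hap_start = np.zeros((ind_capacity, 2), dtype=np.int64)
        self.hap_len = np.zeros((ind_capacity, 2), dtype=np.int64)
        self.age = np.zeros(ind_capacity, dtype=np.int64)
        self.is_female = np.zeros(ind_capacity, dtype=np.bool_)
        self.logw = np.zeros(ind_capacity, dtype=np.float64)
        self.pool = np.zeros(pool_capacity, dtype=np.int32)
        self.pool_used = 0
        self.max_hap_len = 0
        self.fixed_logw = 0.0
        self.fixed_cat = np.zeros(5, dtype=np.int64)
        self.extinct = False

    @property
    def live_entries(self) -> int:
        return int(self.hap_len[: self.n].sum())

    def _grow_inds(self, need: int) -> None:
        if need <= self.age.size:
            return
        cap = max(need, 2 * self.age.size)
        for name in ("hap_start", "hap_len"):
            arr = getattr(self, name)
            new = np.zeros((cap, 2), dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        for name in ("age", "is_female", "logw"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def _grow_pool(self, need: int) -> None:
        if need <= self.pool.size:
            return
        cap = max(need, 2 * self.pool.size)
        new = np.zeros(cap, dtype=np.int32)
        new[: self.pool_used] = self.pool[: self.pool_used]
        self.pool = new


@dataclass
class PopulationSample:
    """A sample of individuals with resolved sparse genotypes, the unit the
    per-decade summary statistics operate on (see summaries module)."""

    hom_ids: List[np.ndarray]
    het_ids: List[np.ndarray]
    logw: np.ndarray
    fixed_logw: float
    fixed_cat: np.ndarray
    reg_pos: np.ndarray
    reg_s: np.ndarray
    reg_h: np.ndarray
    reg_cat: np.ndarray
    arch: GenomeArchitecture

    @property
    def n(self) -> int:
        return len(self.hom_ids)


class Engine:
    """Per-replicate simulation engine: registry + population operations."""

    def __init__(
        self,
        arch: GenomeArchitecture,
        dfe: DfeSpec,
        life_history: LifeHistory,
        seed: int,
    ):
        self.arch = arch
        self.dfe = dfe
        self.lh = life_history
        self.year = 0
        self.rng = np.random.default_rng(seed)
        _seed_engine(int(seed) % 2**31)
        cap = 4096
        self.reg_pos = np.zeros(cap, dtype=np.int64)
        self.reg_s = np.zeros(cap, dtype=np.float64)
        self.reg_h = np.zeros(cap, dtype=np.float64)
        self.reg_cat = np.zeros(cap, dtype=np.int8)
        self.reg_origin = np.zeros(cap, dtype=np.int64)
        self.n_sites = 0
        self._seg_gene = np.zeros(arch.n_genes + 2, dtype=np.int64)
        self._seg_choice = np.zeros(arch.n_genes + 2, dtype=np.int64)
        self._litter_cdf = np.cumsum(np.asarray(life_history.litter_probs))
        self._mort = np.asarray(life_history.age_mortality, dtype=np.float64)
        self.mu_total = arch.mutation_rate * arch.total_bp

    # -- registry -----------------------------------------------------------

    def _grow_registry(self, need: int) -> None:
        if need <= self.reg_pos.size:
            return
        cap = max(need, 2 * self.reg_pos.size)
        for name in ("reg_pos", "reg_s", "reg_h", "reg_cat", "reg_origin"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self.n_sites] = arr[: self.n_sites]
            setattr(self, name, new)

    def add_sites(self, pos, s, h, cat) -> np.ndarray:
        """Append sites to the registry; returns their ids."""
        n_new = len(pos)
        self._grow_registry(self.n_sites + n_new)
        ids = np.arange(self.n_sites, self.n_sites + n_new, dtype=np.int32)
        sl = slice(self.n_sites, self.n_sites + n_new)
        self.reg_pos[sl] = pos
        self.reg_s[sl] = s
        self.reg_h[sl] = h
        self.reg_cat[sl] = cat
        self.reg_origin[sl] = self.year
        self.n_sites += n_new
        return ids

    # -- population construction -------------------------------------------

    def new_population(self, label: str, k: int) -> Population:
        return Population(label, k, ind_capacity=max(64, 4 * k), pool_capacity=1024)

    def init_empty(self, pop: Population) -> None:
        """Mutation-free founders at carrying capacity, stationary ages."""
        ages = self._draw_ages(pop.k)
        pop.n = pop.k
        pop._grow_inds(pop.n)
        pop.age[: pop.n] = ages
        pop.is_female[: pop.n] = self.rng.random(pop.n) < 0.5
        pop.hap_start[: pop.n] = 0
        pop.hap_len[: pop.n] = 0
        pop.logw[: pop.n] = 0.0
        pop.max_hap_len = 0

    def init_equilibrium(self, pop: Population, theta_ratio: Optional[float] = None) -> None:
        """Seed standing variation from the analytic stationary SFS.

        ``theta_ratio`` is equilibrium heterozygosity / (4 * mu * K) with mu
        the per-meiosis mutation rate; the default is the calibrated value
        for the default life history.  The effective size used for the
        selection intensity is ``theta_ratio * generation_time * K`` (one
        mutation opportunity per generation).
        """
        if theta_ratio is None:
            theta_ratio = NE_YEARS_RATIO
        t_gen = stable_age_structure(self.lh).generation_time
        pos, s, h, cat, count = equilibrium_sites(
            n_diploid=pop.k,
            theta_site=4.0 * theta_ratio * pop.k * self.arch.mutation_rate,
            ne_selection=theta_ratio * t_gen * pop.k,
            total_bp=self.arch.total_bp,
            dfe=self.dfe,
            rng=self.rng,
        )
        ids = self.add_sites(pos, s, h, cat)
        two_n = 2 * pop.k
        hap_of: List[np.ndarray] = []
        site_of: List[np.ndarray] = []
        for sid, cnt in zip(ids, count):
            carriers = self.rng.permutation(two_n)[:cnt]
            hap_of.append(carriers)
            site_of.append(np.full(cnt, sid, dtype=np.int32))
        self.init_empty(pop)
        if ids.size:
            hap_idx = np.concatenate(hap_of)
            site_idx = np.concatenate(site_of)
            order = np.lexsort((site_idx, self.reg_pos[site_idx], hap_idx))
            hap_idx = hap_idx[order]
            site_idx = site_idx[order]
            pop._grow_pool(site_idx.size + 1024)
            pop.pool[: site_idx.size] = site_idx
            pop.pool_used = site_idx.size
            lens = np.bincount(hap_idx, minlength=two_n)
            offs = np.concatenate([[0], np.cumsum(lens)])
            pop.hap_start[: pop.n, 0] = offs[0:two_n:2]
            pop.hap_start[: pop.n, 1] = offs[1:two_n:2]
            pop.hap_len[: pop.n, 0] = lens[0:two_n:2]
            pop.hap_len[: pop.n, 1] = lens[1:two_n:2]
            pop.max_hap_len = int(lens.max()) if lens.size else 0
        _logw_all(
            pop.pool, pop.hap_start, pop.hap_len, pop.n,
            self.reg_pos, self.reg_s, self.reg_h, pop.logw,
        )

    def _draw_ages(self, n: int) -> np.ndarray:
        probs = stable_age_structure(self.lh).age_probs
        return self.rng.choice(len(probs), size=n, p=probs)

    # -- yearly cycle --------------------------------------------------------

    def reproduce(self, pop: Population) -> None:
        if pop.n == 0:
            return
        a = pop.age[: pop.n]
        elig = (a >= self.lh.first_repro_age) & (a <= self.lh.max_repro_age)
        nf = int(np.count_nonzero(elig & pop.is_female[: pop.n]))
        max_new = nf * len(self.lh.litter_probs)
        if max_new == 0:
            return
        pop._grow_inds(pop.n + max_new)
        need_pool = pop.pool_used + max_new * 2 * (pop.max_hap_len + 16) + 64
        if need_pool > self.gc_watermark(pop):
            # caller-level gc happens between years; grow locally if needed
            pass
        pop._grow_pool(need_pool)
        exp_mut = max_new * 2 * self.mu_total
        self._grow_registry(self.n_sites + int(3 * exp_mut) + 1024)
        elig_buf = np.empty(pop.n, dtype=np.int64)
        n_new, pool_used, n_sites = _reproduce(
            pop.pool, pop.pool_used,
            pop.hap_start, pop.hap_len, pop.age, pop.is_female, pop.logw, pop.n,
            self.lh.first_repro_age, self.lh.max_repro_age,
            self.lh.male_breeding_fraction, self._litter_cdf,
            self.arch.n_genes, self.arch.genes_per_chromosome, self.arch.gene_length,
            self.arch.intergene_recomb, self.mu_total, self.arch.total_bp,
            self.dfe.p_deleterious, self.dfe.gamma_shape, self.dfe.gamma_scale,
            self.dfe.s_multiplier, self.dfe.lethal_fraction,
            self.reg_pos, self.reg_s, self.reg_h, self.reg_cat, self.reg_origin,
            self.n_sites, self.year,
            self._seg_gene, self._seg_choice, elig_buf,
        )
        assert n_sites <= self.reg_pos.size and pool_used <= pop.pool.size
        pop.n = n_new
        pop.pool_used = pool_used
        self.n_sites = n_sites
        if pop.n:
            pop.max_hap_len = int(pop.hap_len[: pop.n].max())

    def survive(self, pop: Population) -> None:
        if pop.n == 0:
            pop.extinct = True
            return
        pop.n = _survive(
            pop.hap_start, pop.hap_len, pop.age, pop.is_female, pop.logw, pop.n,
            self._mort, float(pop.k), pop.fixed_logw, self.lh.max_longevity,
        )
        if pop.n == 0:
            pop.extinct = True

    def step_year(self, pops: Sequence[Population]) -> None:
        """reproduce -> survive for every population, then housekeeping."""
        for pop in pops:
            if not pop.extinct:
                self.reproduce(pop)
        for pop in pops:
            if not pop.extinct:
                self.survive(pop)
        live = [p for p in pops if not p.extinct]
        if live and any(p.pool_used > self.gc_watermark(p) for p in live):
            self.garbage_collect(live)

    def gc_watermark(self, pop: Population) -> int:
        return max(4_000_000, 6 * max(pop.live_entries, 1))

    # -- founding and gc -----------------------------------------------------

    def found(self, mainland: Population, label: str, k: int) -> Population:
        """Create a new population from k individuals drawn uniformly
        without replacement from the mainland (emigration: founders move)."""
        k_eff = min(k, mainland.n)
        ids = self.rng.choice(mainland.n, size=k_eff, replace=False)
        island = self.new_population(label, k)
        island._grow_inds(k_eff)
        total = int(mainland.hap_len[ids].sum())
        island._grow_pool(total + 1024)
        ptr = 0
        for w, i in enumerate(ids):
            for slot in range(2):
                s0 = int(mainland.hap_start[i, slot])
                ln = int(mainland.hap_len[i, slot])
                island.pool[ptr : ptr + ln] = mainland.pool[s0 : s0 + ln]
                island.hap_start[w, slot] = ptr
                island.hap_len[w, slot] = ln
                ptr += ln
            island.age[w] = mainland.age[i]
            island.is_female[w] = mainland.is_female[i]
            island.logw[w] = mainland.logw[i]
        island.n = k_eff
        island.pool_used = ptr
        island.max_hap_len = int(island.hap_len[:k_eff].max()) if k_eff else 0
        island.fixed_logw = mainland.fixed_logw
        island.fixed_cat = mainland.fixed_cat.copy()
        # remove emigrants from the mainland
        keep = np.ones(mainland.n, dtype=bool)
        keep[ids] = False
        m = int(keep.sum())
        mainland.hap_start[:m] = mainland.hap_start[: mainland.n][keep]
        mainland.hap_len[:m] = mainland.hap_len[: mainland.n][keep]
        mainland.age[:m] = mainland.age[: mainland.n][keep]
        mainland.is_female[:m] = mainland.is_female[: mainland.n][keep]
        mainland.logw[:m] = mainland.logw[: mainland.n][keep]
        mainland.n = m
        return island

    def garbage_collect(self, pops: Sequence[Population]) -> None:
        """Compact pools; fold sites fixed in every extant population into
        the per-population fixed-load ledgers."""
        live = [p for p in pops if not p.extinct and p.n > 0]
        if not live:
            return
        counts = []
        for pop in live:
            c = np.zeros(self.n_sites, dtype=np.int64)
            _count_alleles(pop.pool, pop.hap_start, pop.hap_len, pop.n, c)
            counts.append(c)
        fixed_all = np.ones(self.n_sites, dtype=bool)
        for pop, c in zip(live, counts):
            fixed_all &= c == 2 * pop.n
        removed_logw = 0.0
        if fixed_all.any():
            rs = self.reg_s[: self.n_sites][fixed_all]
            finite = rs > -1.0
            removed_logw = float(np.log1p(rs[finite]).sum())
            if not finite.all():
                removed_logw = _DEAD
            extra_cat = np.bincount(self.reg_cat[: self.n_sites][fixed_all], minlength=5)
        for pop in live:
            new_pool = np.zeros(max(1024, pop.live_entries + 1024), dtype=np.int32)
            used = _rewrite_pool(
                pop.pool, pop.hap_start, pop.hap_len, pop.n, fixed_all, new_pool
            )
            pop.pool = new_pool
            pop.pool_used = used
            if fixed_all.any():
                pop.fixed_logw += removed_logw
                pop.fixed_cat += extra_cat
                pop.logw[: pop.n] -= removed_logw
            pop.max_hap_len = int(pop.hap_len[: pop.n].max()) if pop.n else 0

    # -- sampling ------------------------------------------------------------

    def sample(self, pop: Population, n: int, rng: Optional[np.random.Generator] = None) -> PopulationSample:
        """Resolve genotypes for a uniform sample of min(n, N) individuals."""
        rng = rng or self.rng
        k = min(n, pop.n)
        idx = np.sort(rng.choice(pop.n, size=k, replace=False))
        total = int(pop.hap_len[idx].sum())
        hom_buf = np.empty(total, dtype=np.int32)
        het_buf = np.empty(total, dtype=np.int32)
        hom_off = np.empty(k + 1, dtype=np.int64)
        het_off = np.empty(k + 1, dtype=np.int64)
        _sample_genotypes(
            pop.pool, pop.hap_start, pop.hap_len, idx.astype(np.int64),
            self.reg_pos, hom_buf, hom_off, het_buf, het_off,
        )
        return PopulationSample(
            hom_ids=[hom_buf[hom_off[i] : hom_off[i + 1]].copy() for i in range(k)],
            het_ids=[het_buf[het_off[i] : het_off[i + 1]].copy() for i in range(k)],
            logw=pop.logw[: pop.n][idx].copy(),
            fixed_logw=pop.fixed_logw,
            fixed_cat=pop.fixed_cat.copy(),
            reg_pos=self.reg_pos,
            reg_s=self.reg_s,
            reg_h=self.reg_h,
            reg_cat=self.reg_cat,
            arch=self.arch,
        )

    def genotype_dosages(self, pop: Population) -> Dict[int, np.ndarray]:
        """Dense per-individual derived-allele dosages for every registry
        site carried in the population (small populations / tests only)."""
        out = {}
        for i in range(pop.n):
            d = np.zeros(self.n_sites, dtype=np.int8)
            for slot in range(2):
                s0 = int(pop.hap_start[i, slot])
                ln = int(pop.hap_len[i, slot])
                np.add.at(d, pop.pool[s0 : s0 + ln], 1)
            out[i] = d
        return out


# ---------------------------------------------------------------------------
# helpers for tests and calibration
# ---------------------------------------------------------------------------


def sample_gametes(
    haplotypes: Tuple[Sequence[int], Sequence[int]],
    arch: GenomeArchitecture,
    n_gametes: int,
    seed: int = 0,
    mutation: bool = False,
    dfe: Optional[DfeSpec] = None,
) -> List[np.ndarray]:
    """Draw gametes from a single parent whose two haplotypes carry neutral
    marker mutations at the given bp positions.  Returns per-gamete sorted
    position arrays (test/diagnostic utility)."""
    dfe = dfe or DfeSpec()
    eng = Engine(arch, dfe, LifeHistory(), seed)
    posA = np.sort(np.asarray(haplotypes[0], dtype=np.int64))
    posB = np.sort(np.asarray(haplotypes[1], dtype=np.int64))
    idsA = eng.add_sites(posA, np.zeros(posA.size), np.full(posA.size, 0.5), np.zeros(posA.size, dtype=np.int8))
    idsB = eng.add_sites(posB, np.zeros(posB.size), np.full(posB.size, 0.5), np.zeros(posB.size, dtype=np.int8))
    # pool: [hapA ids][hapB ids], each position-sorted by construction
    mu_total = eng.mu_total if mutation else 0.0
    maxlen = posA.size + posB.size + 64
    pool = np.zeros(2 * maxlen + (posA.size + posB.size), dtype=np.int32)
    a0, b0 = 0, posA.size
    pool[a0 : a0 + posA.size] = idsA
    pool[b0 : b0 + posB.size] = idsB
    out = []
    cursor = posA.size + posB.size
    for _ in range(n_gametes):
        eng._grow_registry(eng.n_sites + 64)
        glen, eng.n_sites = _make_gamete(
            pool, a0, posA.size, b0, posB.size, cursor,
            eng._seg_gene, eng._seg_choice, arch.n_genes, arch.genes_per_chromosome, arch.gene_length,
            arch.intergene_recomb, mu_total, arch.total_bp,
            dfe.p_deleterious, dfe.gamma_shape, dfe.gamma_scale,
            dfe.s_multiplier, dfe.lethal_fraction,
            eng.reg_pos, eng.reg_s, eng.reg_h, eng.reg_cat, eng.reg_origin,
            eng.n_sites, 0,
        )
        out.append(eng.reg_pos[pool[cursor : cursor + glen]].copy())
    return out


STATE_FORMAT_VERSION = 1


def save_state(engine: Engine, pops: Sequence[Population], path) -> None:
    """Write a versioned simulator state snapshot (npz) for restart.

    Captures the mutation registry, every population's individuals and
    haplotype pool, and the current year.  RNG state is not captured:
    a restarted run is a valid continuation, not a bit-identical replay.
    """
    arrays = {
        "version": np.array([STATE_FORMAT_VERSION]),
        "year": np.array([engine.year]),
        "n_sites": np.array([engine.n_sites]),
        "reg_pos": engine.reg_pos[: engine.n_sites],
        "reg_s": engine.reg_s[: engine.n_sites],
        "reg_h": engine.reg_h[: engine.n_sites],
        "reg_cat": engine.reg_cat[: engine.n_sites],
        "reg_origin": engine.reg_origin[: engine.n_sites],
        "labels": np.array([p.label for p in pops]),
    }
    for i, p in enumerate(pops):
        arrays[f"pop{i}_meta"] = np.array([p.k, p.n, p.pool_used, p.max_hap_len])
        arrays[f"pop{i}_fixed"] = np.concatenate([[p.fixed_logw], p.fixed_cat.astype(float)])
        arrays[f"pop{i}_hap_start"] = p.hap_start[: p.n]
        arrays[f"pop{i}_hap_len"] = p.hap_len[: p.n]
        arrays[f"pop{i}_age"] = p.age[: p.n]
        arrays[f"pop{i}_is_female"] = p.is_female[: p.n]
        arrays[f"pop{i}_logw"] = p.logw[: p.n]
        arrays[f"pop{i}_pool"] = p.pool[: p.pool_used]
    np.savez_compressed(path, **arrays)


def load_state(path, arch: GenomeArchitecture, dfe: DfeSpec, life_history: LifeHistory,
               seed: int) -> Tuple[Engine, List[Population]]:
    """Rebuild an engine + populations from a snapshot written by
    :func:`save_state`.  ``seed`` seeds the continuation's randomness."""
    data = np.load(path, allow_pickle=False)
    version = int(data["version"][0])
    if version != STATE_FORMAT_VERSION:
        raise ValueError(f"unsupported state format version {version}")
    engine = Engine(arch, dfe, life_history, seed)
    engine.year = int(data["year"][0])
    n_sites = int(data["n_sites"][0])
    engine._grow_registry(n_sites + 1024)
    for name in ("reg_pos", "reg_s", "reg_h", "reg_cat", "reg_origin"):
        getattr(engine, name)[:n_sites] = data[name]
    engine.n_sites = n_sites
    pops = []
    for i, label in enumerate(data["labels"]):
        k, n, pool_used, max_hap_len = (int(x) for x in data[f"pop{i}_meta"])
        pop = Population(str(label), k, ind_capacity=max(64, 2 * n),
                         pool_capacity=max(1024, pool_used + 1024))
        pop.n = n
        pop.hap_start[:n] = data[f"pop{i}_hap_start"]
        pop.hap_len[:n] = data[f"pop{i}_hap_len"]
        pop.age[:n] = data[f"pop{i}_age"]
        pop.is_female[:n] = data[f"pop{i}_is_female"]
        pop.logw[:n] = data[f"pop{i}_logw"]
        pop.pool[:pool_used] = data[f"pop{i}_pool"]
        pop.pool_used = pool_used
        pop.max_hap_len = max_hap_len
        fixed = data[f"pop{i}_fixed"]
        pop.fixed_logw = float(fixed[0])
        pop.fixed_cat = fixed[1:].astype(np.int64)
        pops.append(pop)
    return engine, pops


class SinglePopulationRunner:
    """Constant-K single population run from an empty genome; used to
    calibrate the effective-size ratio of a life history."""

    def __init__(
        self,
        k: int,
        mutation_rate: float,
        neutral_only: bool = True,
        life_history: Optional[LifeHistory] = None,
        seed: int = 1,
        arch: Optional[GenomeArchitecture] = None,
    ):
        self.arch = arch or GenomeArchitecture(
            n_chromosomes=1, genes_per_chromosome=50, mutation_rate=mutation_rate
        )
        dfe = DfeSpec(ns_to_syn_ratio=0.0) if neutral_only else DfeSpec()
        self.engine = Engine(self.arch, dfe, life_history or LifeHistory(), seed)
        self.pop = self.engine.new_population("pop", k)
        self.engine.init_empty(self.pop)

    def run_collect_het(self, years: int, record_every: int = 50, sample_n: int = 50) -> List[float]:
        """Mean per-site heterozygosity of a sample, recorded periodically."""
        hets = []
        for y in range(years):
            self.engine.year = y
            self.engine.step_year([self.pop])
            if self.pop.extinct:
                break
            if (y + 1) % record_every == 0:
                smp = self.engine.sample(self.pop, sample_n)
                mean_het = np.mean([ids.size for ids in smp.het_ids])
                hets.append(float(mean_het) / self.arch.total_bp)
        return hets
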
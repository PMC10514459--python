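"""Genome architecture for the forward simulator.

The simulated genome is a set of autosomes, each carrying a fixed number of
contiguous genes of equal length.  There is no recombination within a gene,
a fixed per-boundary crossover probability between adjacent genes, and free
recombination between chromosomes.  Genomic coordinates are 0-based base
pairs; gene ``g`` on a chromosome occupies ``[g * gene_length,
(g + 1) * gene_length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["GenomeArchitecture"]


@dataclass(frozen=True)
class GenomeArchitecture:
    """Physical map and per-year mutation/recombination rates.

    Parameters
    ----------
    n_chromosomes : int
        Number of autosomes (free recombination between them).
    genes_per_chromosome : int
        Number of contiguous genes per chromosome.
    gene_length : int
        Length of each gene in base pairs.
    mutation_rate : float
        Mutation rate per site per year.
    intergene_recomb : float
        Crossover probability per gene boundary per meiosis.
    """

    n_chromosomes: int = 6
    genes_per_chromosome: int = 500
    gene_length: int = 1_750
    mutation_rate: float = 1.76e-9
    intergene_recomb: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one gene")
        if self.gene_length < 1:
            raise ValueError("gene_length must be positive")
        if not 0.0 <= self.intergene_recomb <= 0.5:
            raise ValueError("intergene_recomb must lie in [0, 0.5]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")

    @property
    def chromosome_bp(self) -> int:
        return self.genes_per_chromosome * self.gene_length

    @property
    def total_bp(self) -> int:
        """Total simulated sequence length in bp."""
        return self.n_chromosomes * self.chromosome_bp

    @property
    def n_genes(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome

    def chromosome_of(self, pos: int) -> int:
        """Chromosome index of a global 0-based bp position."""
        return pos // self.chromosome_bp

    def gene_of(self, pos: int) -> int:
        """Global gene index (0 .. n_genes-1) of a global bp position."""
        return pos // self.gene_length

    def scaled(self, lam: float) -> "GenomeArchitecture":
        """Return a copy with mutation and inter-gene recombination rates
        divided by ``lam`` (population-rescaling; crossover probability is
        capped at 0.5, the free-recombination limit)."""
        return replace(
            self,
            mutation_rate=self.mutation_rate / lam,
            intergene_recomb=min(0.5, self.intergene_recomb / lam),
        )


def per_generation_to_per_year(rate_per_generation: float, generation_time: float) -> float:
    """Convert a per-generation mutation rate to a per-year rate.

    The default architecture's 1.76e-9 /site/year derives from 1.06e-8
    /site/generation and a six-year generation time.
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return rate_per_generation / generation_time
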
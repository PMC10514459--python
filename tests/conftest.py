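import numpy as np
import pytest

from erosim.loadstats import VariantTable


def _desk_simulator(k_founder, k_recovery, **kwargs):
    """Rescaled (lambda = 1/20, 2 chromosomes) founder-scenario simulator —
    the desk-scale acceptance surface for simulation claims."""
    from erosim import GenomeArchitecture, ScalingPolicy, founder_scenario
    from erosim.simulate import ForwardSimulator

    kwargs.setdefault("relax_years", 100)
    kwargs.setdefault("founding_retries", 150)
    return ForwardSimulator(
        founder_scenario(k_founder, k_recovery),
        arch=GenomeArchitecture(n_chromosomes=2),
        policy=ScalingPolicy(lam=1 / 20),
        **kwargs,
    )


def _collect(sim, seeds):
    frames = []
    for s in seeds:
        res = sim.run_replicate(s, s)
        frames.append(res.records)
    import pandas as pd

    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def severe_founder_runs():
    """10 replicates of the severe scenario (founder 25, recovery 2,000)."""
    return _collect(_desk_simulator(25, 2_000), range(1, 11))


@pytest.fixture(scope="session")
def mild_founder_runs():
    """10 replicates of the mild scenario (founder 500, recovery 5,000)."""
    return _collect(_desk_simulator(500, 5_000), range(1, 11))


@pytest.fixture(scope="session")
def purging_runs():
    """Founder 250 and 500 (recovery 2,000), stopped ~200 full-scale years
    after founding, for the masked-load purging measurement."""
    stop = round(6_800 / 20)
    a = _collect(_desk_simulator(250, 2_000, stop_year=stop), range(1, 6))
    b = _collect(_desk_simulator(500, 2_000, stop_year=stop), range(6, 11))
    import pandas as pd

    return pd.concat([a, b], ignore_index=True)


@pytest.fixture(scope="session")
def null_scenario_runs():
    """3 replicates of the null scenario (founder 20,000)."""
    from erosim import GenomeArchitecture, ScalingPolicy, null_scenario
    from erosim.simulate import ForwardSimulator

    sim = ForwardSimulator(
        null_scenario(),
        arch=GenomeArchitecture(n_chromosomes=2),
        policy=ScalingPolicy(lam=1 / 20),
        relax_years=100,
    )
    return _collect(sim, range(1, 4))


@pytest.fixture
def toy_table():
    """Hand-enumerable two-population table (3 + 3 samples).

    Sites (chrom, pos, category) and dosages are chosen so that load counts
    and R_xy L-sums can be tallied by hand in the tests that use it.
    """
    chrom = np.array(["1"] * 6 + ["2"] * 4, dtype=object)
    pos = np.arange(1, 11, dtype=np.int64) * 1000
    category = np.array(
        ["HIGH", "HIGH", "MODERATE", "SYNONYMOUS", "SYNONYMOUS", "INTERGENIC",
         "MODERATE", "SYNONYMOUS", "INTERGENIC", "INTERGENIC"],
        dtype=object,
    )
    genotypes = np.array(
        [
            # popA: s0 s1 s2 | popB: s3 s4 s5
            [2, 1, 0, 0, 1, 0],   # HIGH
            [1, 0, 0, 2, 2, 1],   # HIGH
            [0, 1, 1, 0, 0, 2],   # MODERATE
            [1, 1, 2, 1, 0, 0],   # SYN
            [2, 2, 2, 2, 2, 2],   # SYN, fixed everywhere
            [1, 0, 1, 0, 1, 1],   # INTERGENIC
            [0, 0, 1, 1, 1, 0],   # MODERATE
            [0, 1, 0, 2, 0, 1],   # SYN
            [2, 1, 0, 1, 2, 0],   # INTERGENIC
            [1, 1, 1, 1, 1, 1],   # INTERGENIC
        ],
        dtype=np.int8,
    )
    samples = [f"s{i}" for i in range(6)]
    pops = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
    return VariantTable(
        chrom=chrom, pos=pos, category=category, genotypes=genotypes,
        samples=samples, populations=pops,
    )
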
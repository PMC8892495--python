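"""Shared synthetic runs (session-scoped: simulations are the costly part)."""

from __future__ import annotations

import numpy as np
import pytest

import xrseq as x


@pytest.fixture(scope="session")
def cpd_run():
    """Default UV-photoproduct world, deep enough for >= 50k 28-mers
    (28-nt weight 0.20, so 270k reads give ~54k)."""
    return x.simulate(x.SimulationConfig(damage_type="CPD", n_reads=270_000, seed=101))


@pytest.fixture(scope="session")
def cisplatin_run():
    """Default cisplatin world, deep enough for ~50k 28-mers."""
    return x.simulate(
        x.SimulationConfig(damage_type="CISPLATIN", n_reads=200_000, seed=102)
    )


@pytest.fixture(scope="session")
def null_run():
    """Repair-null library: background fragments only, no lesion placement."""
    return x.simulate(
        x.SimulationConfig(
            damage_type="CPD", n_reads=30_000, background_fraction=1.0, seed=103
        )
    )


@pytest.fixture(scope="session")
def half_background_run():
    return x.simulate(
        x.SimulationConfig(
            damage_type="CPD", n_reads=30_000, background_fraction=0.5, seed=103
        )
    )


@pytest.fixture(scope="session")
def pure_cpd_small_run():
    """Same seed as the background runs, no background (monotonicity check)."""
    return x.simulate(
        x.SimulationConfig(
            damage_type="CPD", n_reads=30_000, background_fraction=0.0, seed=103
        )
    )


@pytest.fixture(scope="session")
def sym_run():
    """tcr_factor = 1: the generator is strand-symmetric in expectation.

    Shares seed 202 with f2_run/f4_run so all three runs have the identical
    genome and annotation (a valid time-course triplet).
    """
    return x.simulate(
        x.SimulationConfig(
            damage_type="CISPLATIN",
            n_reads=200_000,
            tcr_factor=1.0,
            expression_law=("constant", 50.0),
            seed=202,
        )
    )


@pytest.fixture(scope="session")
def f2_run():
    """Cisplatin-default TCR strength (factor 2), constant expression, 500k reads."""
    return x.simulate(
        x.SimulationConfig(
            damage_type="CISPLATIN",
            n_reads=500_000,
            tcr_factor=2.0,
            expression_law=("constant", 50.0),
            seed=202,
        )
    )


@pytest.fixture(scope="session")
def f4_run():
    return x.simulate(
        x.SimulationConfig(
            damage_type="CISPLATIN",
            n_reads=150_000,
            tcr_factor=4.0,
            expression_law=("constant", 50.0),
            seed=202,
        )
    )


@pytest.fixture(scope="session")
def lognormal_tcr_run():
    """Expression-dependent TCR (lognormal RPKM) for tercile monotonicity."""
    return x.simulate(
        x.SimulationConfig(
            damage_type="CISPLATIN",
            n_reads=250_000,
            tcr_factor=2.0,
            expression_law=("lognormal", 3.0, 1.0),
            seed=204,
        )
    )


@pytest.fixture(scope="session")
def many_genes_sym_run():
    """200 genes at tcr_factor 1 (log-ratio distribution centering)."""
    return x.simulate(
        x.SimulationConfig(
            damage_type="CPD",
            n_reads=200_000,
            n_genes=200,
            tcr_factor=1.0,
            seed=205,
        )
    )


@pytest.fixture(scope="session")
def structured_run():
    """A/T-rich blocks at every TSS/TES; uniform repair per lesion (tcr=1).

    The scenario where raw cisplatin repair dips at gene ends purely because
    GG sites are depleted there.
    """
    cfg = x.SimulationConfig(
        damage_type="CISPLATIN",
        n_reads=300_000,
        tcr_factor=1.0,
        expression_law=("constant", 50.0),
        seed=11,
    )
    genome = x.make_genome(cfg)
    genes = x.place_genes(genome, cfg)
    genome = x.impose_at_rich_blocks(genome, genes, gc_content=0.10, halfwidth=400, seed=11)
    reads, truth = x.simulate_excision_reads(genome, genes, cfg)
    return x.SimulationResult(cfg, genome, genes, reads, truth)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=5000, p=[0.285, 0.215, 0.215, 0.285]))
    return x.Genome({"chrT": seq})
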
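import pytest

from intronsig import (
    SimulationConfig,
    design_probe_sets,
    generate_gene_models,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(seed=3, noise_sd=0.1)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One shared small simulated study: genome, models, probes, truth, matrix."""
    genome, models = generate_gene_models(small_cfg)
    probesets, truth = design_probe_sets(models, genome, small_cfg)
    matrix = simulate_expression(models, truth, small_cfg)
    return {
        "config": small_cfg,
        "genome": genome,
        "models": models,
        "probesets": probesets,
        "truth": truth,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def celltype_sim():
    """Multi-cell-type matrix with a planted separating signature."""
    cfg = SimulationConfig(
        seed=12,
        design="celltype",
        groups=(("HSC", 3), ("CMP", 3), ("MEP", 3), ("B", 3)),
        target_group="HSC",
        noise_sd=0.25,
        n_probesets_per_class={
            "exonic": 30, "intronic": 24, "boundary": 3, "repeat": 3, "antisense": 3,
        },
        n_selective=8,
    )
    genome, models = generate_gene_models(cfg)
    probesets, truth = design_probe_sets(models, genome, cfg)
    matrix = simulate_expression(models, truth, cfg)
    return {"config": cfg, "truth": truth, "matrix": matrix}
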
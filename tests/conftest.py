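import pytest

from cisbuffer import (SimulationConfig, canonical_sample_sheet, build_design,
                       offsets_from_truth, run_ase_pipeline, simulate_counts,
                       simulate_truth)


@pytest.fixture(scope="session")
def sheet():
    return canonical_sample_sheet()


@pytest.fixture(scope="session")
def design(sheet):
    return build_design(sheet)


@pytest.fixture(scope="session")
def design_matrix(design):
    return design.to_numpy(dtype=float)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene cohort with moderate buffering, fitted once per session."""
    cfg = SimulationConfig(n_genes=400, seed=20, buffering=0.2)
    truth = simulate_truth(cfg)
    counts, sh = simulate_counts(truth)
    fl = offsets_from_truth(truth, sh)
    result = run_ase_pipeline(counts, sh, fl_offsets=fl)
    return {"config": cfg, "truth": truth, "counts": counts, "sheet": sh,
            "fl": fl, "result": result}
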
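import pandas as pd
import pytest

import temara as tm


def ma_config(seed: int = 1, **sim_overrides) -> tm.Config:
    """Small single-genotype MA study used across tests."""
    sim = {
        "n_populations": 1,
        "genotypes_per_population": 1,
        "n_ma_lines": 5,
        "n_ec_lines": 0,
        "families": {"Gypsy": 200},
        "candidate_pool": 2000,
    }
    sim.update(sim_overrides)
    return tm.load_config(overrides={"seed": seed, "simulation": sim})


@pytest.fixture
def small_experiment() -> tm.SimulatedExperiment:
    cfg = ma_config(seed=11, n_ma_lines=3, families={"Gypsy": 100, "Pao": 50})
    return tm.simulate_experiment(cfg)


@pytest.fixture
def tables_dir(tmp_path, small_experiment):
    """The small experiment written out as TSV tables."""
    tm.write_tables(small_experiment.dataset, tmp_path)
    return tmp_path


def make_dataset(sites_rows, lineage_rows, evidence_rows) -> tm.Dataset:
    """Hand-built dataset from tuples, bypassing file I/O."""
    return tm.Dataset(
        sites=pd.DataFrame(
            sites_rows, columns=["site_id", "contig", "position", "family_id"]
        ),
        lineages=pd.DataFrame(
            lineage_rows,
            columns=["line_id", "genotype_id", "population_id", "role", "generations"],
        ),
        evidence=pd.DataFrame(
            evidence_rows,
            columns=["line_id", "site_id", "presence_reads", "absence_reads"],
        ),
    )
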
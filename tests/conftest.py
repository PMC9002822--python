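import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ssrmine.datamodel import (
    MISSING,
    NULL,
    MarkerMap,
    PhenotypeTable,
    SSRGenotypeTable,
)


def make_genotypes(rows: dict, markers=None, marker_map=None) -> SSRGenotypeTable:
    """Build a genotype table from {accession: [calls...]}."""
    accs = list(rows)
    n = len(next(iter(rows.values())))
    markers = markers or [f"M{i+1}" for i in range(n)]
    calls = pd.DataFrame(
        [[v for v in row] for row in rows.values()],
        index=accs,
        columns=markers,
        dtype=object,
    )
    return SSRGenotypeTable(calls, marker_map)


def make_phenotypes(values: dict, trait="PH", env="E1", n_reps=1) -> PhenotypeTable:
    """Build a phenotype table from {accession: mean value} with exact
    replicates."""
    rows = [
        {"accession": a, "trait": trait, "env": env, "rep": r, "value": v}
        for a, v in values.items()
        for r in range(1, n_reps + 1)
    ]
    return PhenotypeTable(pd.DataFrame(rows))


@pytest.fixture
def toy_genotypes():
    return make_genotypes(
        {
            "A01": [180, 200, NULL],
            "A02": [180, 210, 140],
            "A03": [182, 200, 140],
            "A04": [180, MISSING, NULL],
        }
    )


@pytest.fixture
def small_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": ["M1", "M2", "M3"],
                "chromosome": [1, 1, 2],
                "position_cM": [10.0, 55.0, 30.0],
            }
        ).set_index("marker")
    )


@pytest.fixture(scope="session")
def sim_panel():
    """A small structured panel with one planted PH QTL, shared across
    tests (session-scoped: generation is the slow part)."""
    import ssrmine as sm

    cfg = sm.PopulationSimConfig(n_accessions=300, n_loci=50, n_subpops=3, seed=11)
    g, q, freqs = sm.simulate_natural_population(cfg)
    # plant the QTL on an allele that varies within subpopulations (a
    # structure-confounded allele is absorbed by the Q+K correction)
    qtl_marker, target_allele = sm.choose_qtl_marker(g, q)
    spec = sm.QTLSpec(
        effects={"PH": [(qtl_marker, {target_allele: -8.0})]},
        intercepts={"PH": 120.0},
        env_offsets={"E1": 0.0, "E2": 3.0},
        genetic_sd=6.0,
        replicate_sd=2.0,
    )
    p, truth = sm.simulate_phenotypes(g, spec, n_envs=2, n_reps=3, seed=12, q=q)
    return {
        "genotypes": g,
        "q": q,
        "phenotypes": p,
        "truth": truth,
        "qtl_marker": qtl_marker,
        "qtl_allele": target_allele,
        "qtl_effect": -8.0,
    }
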
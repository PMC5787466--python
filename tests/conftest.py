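"""Shared fixtures: generated molecule sets and reference tables.

Everything is produced by the package's own seeded generators at test time;
session scope keeps conformer embedding (the slow part) to a single pass.
"""

from __future__ import annotations

import pytest

from hopscreen.chemio import from_smiles
from hopscreen.corehop import separate_core
from hopscreen.fixtures import (
    FixtureSpec,
    load_reference_tables,
    make_fragment_fixture,
    make_qsar_fixture,
)

# MF-438, drawn from its IUPAC name:
# 2-methyl-5-(6-(4-(2-(trifluoromethyl)phenoxy)piperidin-1-yl)pyridazin-3-yl)-
# 1,3,4-thiadiazole
MF438_SMILES = "Cc1nnc(-c2ccc(N3CCC(Oc4ccccc4C(F)(F)F)CC3)nn2)s1"
MF438_FORMULA = "C19H18F3N5OS"


@pytest.fixture(scope="session")
def spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def fragment_fixture(spec):
    return make_fragment_fixture(spec)


@pytest.fixture(scope="session")
def qsar_fixture(spec):
    return make_qsar_fixture(spec)


@pytest.fixture(scope="session")
def reference_tables():
    return load_reference_tables()


@pytest.fixture(scope="session")
def hybrid_library(fragment_fixture):
    """A deduplicated pooled hybrid enumeration over the fixture inputs."""
    from hopscreen.corehop import enumerate_hybrids

    parents, cores = fragment_fixture
    fragment_sets = [separate_core(p) for p in parents]
    return enumerate_hybrids(fragment_sets, cores, max_products=100000, pool_edges=True)


@pytest.fixture()
def mf438():
    return from_smiles(MF438_SMILES, "MF-438")


@pytest.fixture(scope="session")
def noise_rmses():
    """Training RMSE of the sigma=0.2 planted fixture over 20 seeds."""
    from hopscreen.fixtures import make_qsar_fixture
    from hopscreen.qsar import fit_qsar

    out = []
    for seed in range(20):
        fixture = make_qsar_fixture(FixtureSpec(seed=100 + seed, qsar_noise_sigma=0.2))
        model = fit_qsar(fixture.training, fixture.hypothesis, grid=fixture.grid)
        out.append(model.fit_stats["rmse"])
    return out


def _write_training_files(training, workdir):
    import pandas as pd

    from hopscreen.chemio import write_molecules

    write_molecules([m for m, _ in training], workdir / "training.smi", "smiles")
    pd.DataFrame(
        [
            {"compound_id": a.compound_id, "ic50_nM": a.ic50, "censored": a.censored}
            for _, a in training
        ]
    ).to_csv(workdir / "activities.csv", index=False)


@pytest.fixture(scope="session")
def planted_run(tmp_path_factory, spec):
    """A full pipeline run where 3 candidates are built to excel on every
    metric: they are exact copies of the potent-tier training structures
    (best possible clamped QSAR predictions), double as the shape
    references (similarity 1), and receive the best docking scores."""
    import numpy as np
    import pandas as pd
    from rdkit import Chem

    from hopscreen.chemio import from_smiles as _fs
    from hopscreen.chemio import write_molecules
    from hopscreen.corehop import enumerate_hybrids, separate_core
    from hopscreen.fixtures import make_winner_training
    from hopscreen.pipeline import PipelineConfig, run_pipeline

    work = tmp_path_factory.mktemp("planted")
    training, planted_smis = make_winner_training(spec)
    parents = [_fs(s, f"parent{i + 1}") for i, s in enumerate(planted_smis)]
    write_molecules(parents, work / "parents.smi", "smiles")
    core_smi = Chem.MolToSmiles(separate_core(parents[0]).core)
    cores = [
        _fs(core_smi, "core1"),
        _fs("[1*]c1ccc([2*])cc1", "core2"),
        _fs("[1*]c1ccc([2*])nn1", "core3"),
        _fs("[1*]C1CCN([2*])CC1", "core4"),
    ]
    write_molecules(cores, work / "cores.smi", "smiles")
    _write_training_files(training, work)
    fragment_sets = [separate_core(p) for p in parents]
    hybrids = enumerate_hybrids(fragment_sets, cores, 2000, pool_edges=True)
    planted_ids = [h.id for h in hybrids if h.molecule.smiles in set(planted_smis)]
    rng = np.random.default_rng(1)
    rows = [
        {
            "compound_id": h.id,
            "score": (-12.55 + 0.05 * planted_ids.index(h.id))
            if h.id in planted_ids
            else float(rng.uniform(-9.0, -7.0)),
            "source": "synthetic",
        }
        for h in hybrids
    ]
    rows += [{"compound_id": p.id, "score": -10.0, "source": "control"} for p in parents]
    import pandas as pd

    pd.DataFrame(rows).to_csv(work / "dock.csv", index=False)
    config = PipelineConfig(
        parents_smiles=str(work / "parents.smi"),
        cores_smiles=str(work / "cores.smi"),
        training_smiles=str(work / "training.smi"),
        activity_csv=str(work / "activities.csv"),
        dock_scores_csv=str(work / "dock.csv"),
        seed=7,
        max_products=2000,
        n_conformers=spec.n_conformers,
        shape_keep_threshold=0.3,
        dock_fraction=0.6,
        qsar_k_features=(3, 4),
        qsar_max_hypotheses=40,
        top_k=5,
    )
    result = run_pipeline(config, work / "out")
    return {"result": result, "planted_ids": planted_ids, "workdir": work, "config": config}
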
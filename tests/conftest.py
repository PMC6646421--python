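import numpy as np
import pytest

from combosyn.chem_features import parse_structures
from combosyn.dataset import random_split
from combosyn.models import ModelSpec
from combosyn.pipeline import _fit_eval, assemble_synthetic
from combosyn.simulate import SynthConfig

SMALL_MOLS = """\
CCO ethanol
CCC propane
c1ccccc1 benzene
CCCC nbutane
CC(C)C isobutane
C methane
CC(=O)Oc1ccccc1C(=O)O aspirin
NC(Cc1c[nH]c2ccccc12)C(=O)O tryptophan
OCC(O)C(O)C(O)C(O)CO sorbitol
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
"""


@pytest.fixture(scope="session")
def mols():
    molecules, skipped = parse_structures(SMALL_MOLS)
    assert not skipped
    return {m.id: m for m in molecules}


@pytest.fixture(scope="session")
def default_screen():
    """One synthetic screen at the default study conditions (40 drugs,
    5 cell lines), shared across the expensive end-to-end tests."""
    cfg = SynthConfig(seed=0)
    tables = assemble_synthetic(cfg)
    return cfg, tables


@pytest.fixture(scope="session")
def default_rf_runs(default_screen):
    """Per-cell-line RF fits with reliability strata on the default screen
    (25% test split for stable stratum estimates)."""
    cfg, tables = default_screen
    runs = {}
    for cell, samples in tables.items():
        fold = random_split(samples, test_fraction=0.25, seed=cfg.seed)
        runs[cell] = _fit_eval(
            samples, fold, ModelSpec("rf", seed=cfg.seed), augment=True, quantile=0.25
        )
    return runs


def make_pair_samples(n_drugs, n_features=4, seed=0, cell="CL"):
    """Lightweight all-pairs sample table with random features/targets."""
    from combosyn.dataset import PairSample

    rng = np.random.default_rng(seed)
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    vecs = {d: rng.normal(size=n_features) for d in drugs}
    samples = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            a, b = drugs[i], drugs[j]
            samples.append(
                PairSample(a, b, cell, np.concatenate([vecs[a], vecs[b]]), float(rng.normal()))
            )
    return samples
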
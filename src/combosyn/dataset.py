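"""Pair-modeling tables, splits, folds, augmentation and Y-randomization.

One modeling row concatenates the two drugs' feature vectors (drug A then
drug B, stored in lexicographic id order) with the ComboScore target.  The
leakage-sensitive operations — reverse-order augmentation and train/test
splitting — are kept separate so augmentation can be applied strictly after
splitting and only to the training side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem_features import DrugFeatures
from .scoring import pair_key


@dataclass
class PairSample:
    """One modeling row: a drug pair on a cell line with its ComboScore."""

    drug_a: str
    drug_b: str
    cell_line: str
    features: np.ndarray
    target: float

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.isfinite(self.target):
            raise ValueError("target must be finite")

    @property
    def key(self) -> tuple[str, str]:
        return pair_key(self.drug_a, self.drug_b)


@dataclass
class FoldSpec:
    """A named train/test index partition of a sample table."""

    name: str
    train_idx: np.ndarray
    test_idx: np.ndarray
    left_out_drug: str | None = None

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if set(self.train_idx) & set(self.test_idx):
            raise ValueError(f"fold {self.name!r}: train and test overlap")


def build_table(
    drug_features: dict[str, DrugFeatures],
    labels: dict[tuple[str, str, str, str], float] | dict[tuple[str, str], float],
    cell_line: str,
) -> list[PairSample]:
    """Assemble one cell line's modeling table from features and labels.

    ``labels`` maps either (drug_a, drug_b, cell_line, center) or plain
    (drug_a, drug_b) keys to ComboScores; within each stored pair the drugs
    are ordered lexicographically by id.  A labeled drug missing from the
    feature library raises with the full list of missing ids.
    """
    items = []
    for key, score in labels.items():
        if len(key) == 2:
            a, b = key
        else:
            a, b, cell, _center = key
            if cell != cell_line:
                continue
        a, b = pair_key(*((key[0], key[1])))
        items.append((a, b, score))
    missing = sorted(
        {d for a, b, _ in items for d in (a, b) if d not in drug_features}
    )
    if missing:
        raise ValueError(f"drugs without features: {missing}")
    samples = []
    for a, b, score in sorted(items):
        vec = np.concatenate([drug_features[a].vector, drug_features[b].vector])
        samples.append(PairSample(a, b, cell_line, vec, score))
    return samples


def augment_reverse(samples: list[PairSample]) -> list[PairSample]:
    """Duplicate every row with the drugs in reverse order (2n rows out).

    Intended for training rows only; applying it to an already-augmented
    table warns, since the caller is then quadrupling rows.
    """
    keys = [s.key for s in samples]
    if len(keys) != len(set(keys)):
        warnings.warn(
            "augment_reverse input contains duplicate pairs; output will "
            "contain each order more than once",
            stacklevel=2,
        )
    out = list(samples)
    for s in samples:
        half = len(s.features) // 2
        rev = np.concatenate([s.features[half:], s.features[:half]])
        out.append(PairSample(s.drug_b, s.drug_a, s.cell_line, rev, s.target))
    return out


def random_split(
    samples: list[PairSample], test_fraction: float = 0.1, seed: int = 0
) -> FoldSpec:
    """Uniform random train/test split of un-augmented pairs.

    Splitting precedes any augmentation, so no pair can appear on both
    sides in either drug order.  Reproducible for a given seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    frac_pct = int(round(100 * (1 - test_fraction)))
    return FoldSpec(
        name=f"{frac_pct}/{100 - frac_pct} seed {seed}",
        train_idx=np.sort(perm[n_test:]),
        test_idx=np.sort(perm[:n_test]),
    )


def lodo_folds(samples: list[PairSample]) -> list[FoldSpec]:
    """Leave-one-drug-out folds: one per distinct drug.

    Every sample containing the left-out drug goes to that fold's test set;
    across all folds each pair appears in exactly two test sets (one per
    member drug).
    """
    drugs = sorted({d for s in samples for d in (s.drug_a, s.drug_b)})
    if len(drugs) < 2:
        raise ValueError("leave-one-drug-out needs at least 2 distinct drugs")
    folds = []
    for drug in drugs:
        test = [i for i, s in enumerate(samples) if drug in (s.drug_a, s.drug_b)]
        train = [i for i in range(len(samples)) if i not in set(test)]
        folds.append(
            FoldSpec(
                name=f"LODO:{drug}",
                train_idx=np.array(train),
                test_idx=np.array(test),
                left_out_drug=drug,
            )
        )
    return folds


def kfold(samples: list[PairSample], k: int, seed: int = 0) -> list[FoldSpec]:
    """k disjoint test folds partitioning the samples, seeded."""
    n = len(samples)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = []
    chunks = np.array_split(perm, k)
    for i, chunk in enumerate(chunks):
        test = np.sort(chunk)
        train = np.sort(np.setdiff1d(perm, chunk))
        folds.append(FoldSpec(name=f"fold {i + 1}/{k} seed {seed}", train_idx=train, test_idx=test))
    return folds


def permute_targets(samples: list[PairSample], seed: int = 0) -> list[PairSample]:
    """Y-randomization: permute targets across rows, features untouched."""
    if len(samples) < 2:
        return list(samples)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    return [
        PairSample(s.drug_a, s.drug_b, s.cell_line, s.features, samples[j].target)
        for s, j in zip(samples, perm)
    ]


def fold_to_dict(fold: FoldSpec, samples: list[PairSample]) -> dict:
    """JSON-serializable fold description keyed by pair ids."""
    return {
        "name": fold.name,
        "left_out_drug": fold.left_out_drug,
        "train_pairs": [list(samples[i].key) for i in fold.train_idx],
        "test_pairs": [list(samples[i].key) for i in fold.test_idx],
    }
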
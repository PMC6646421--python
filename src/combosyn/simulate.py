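"""Synthetic combination-screen generator with planted, recoverable signal.

Emulates an NCI-ALMANAC-like screen end to end: a library of drug-like
structures, a planted per-(pair, cell line) true ComboScore that is a
smooth symmetric nonlinear function of the two drugs' chemical features,
3×3 dose–response grids whose scores realize that truth plus noise, and
per-center single-agent replicate records with center-specific testing
intensity and noise.

The planted synergy combines saturating per-drug main effects with a
product-of-projections interaction,

    g(A, B, c) = 1/2 [tanh(x_A) + tanh(x_B)] . w_c
               + 1/2 sum_l w_c[l] * x_A[l] * x_B[l]
    s_true(A, B, c) = beta * g / sd(g) + offset_c

with x_D a low-dimensional *sparse* projection of drug D's standardized
feature vector (each latent factor loads on a handful of feature columns,
so axis-aligned trees can actually find it) and w_c a per-cell-line weight
vector.  g is symmetric in (A, B) and genuinely nonlinear in the
concatenated features, so linear baselines underperform tree ensembles.

Noise is heteroscedastic: each pair carries a latent hardness in [0, 1]
(itself a smooth function of the pair's features, hence learnable), and
the ComboScore noise SD grows linearly with hardness, plus a per-center
term.  This gives reliability estimation something real to detect and
makes the noisier center's labels genuinely worse.

All randomness flows from one seed through named substreams (library,
truth, noise, missingness, replicates), so individual stages are
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._smiles_pool import OUTLIER_SMILES, POOL_SMILES
from .chem_features import DrugFeatures, FeatureConfig, Molecule, featurize_library, parse_structures
from .scoring import (
    DoseResponseGrid,
    SingleAgentRecord,
    bliss_expected,
    pair_key,
)

_STREAMS = {"library": 0, "truth": 1, "noise": 2, "missing": 3, "replicates": 4}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of the master seed."""
    return np.random.default_rng([_STREAMS[name], seed])


@dataclass
class CenterConfig:
    """One screening center's testing intensity and measurement noise."""

    code: str
    mean_test_dates: float
    replicate_noise_sd: float


@dataclass
class SynthConfig:
    """Study conditions for the synthetic screen.

    Defaults emulate the real screen's shape at desk scale: a 3×3
    concentration grid, two centers with the published testing intensities
    (3.77 and 7.13 mean test dates per drug–cell line) and a low/high
    replicate-noise contrast, and a missing fraction reproducing the
    91.35% matrix completeness.
    """

    n_drugs: int = 40
    n_cell_lines: int = 5
    centers: list[CenterConfig] = field(
        default_factory=lambda: [
            CenterConfig("FG", 3.77, 6.0),
            CenterConfig("FF", 7.13, 18.0),
        ]
    )
    grid_shape: tuple[int, int] = (3, 3)
    latent_dim: int = 4
    latent_sparsity: int = 3
    beta: float = 40.0
    hetero_noise: tuple[float, float] = (3.0, 40.0)
    missing_fraction: float = 0.0865
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 2 or self.n_cell_lines < 1:
            raise ValueError("need at least 2 drugs and 1 cell line")
        if any(sd < 0 for sd in self.hetero_noise):
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1:02d}" for i in range(self.n_cell_lines)]


@dataclass
class GroundTruth:
    """Planted quantities, retrievable by pair key for recovery tests."""

    s_true: dict[tuple[str, str, str], float]
    hardness: dict[tuple[str, str], float]
    noise_sd: dict[tuple[str, str, str, str], float]
    cell_offsets: dict[str, float]


def generate_drug_library(cfg: SynthConfig) -> list[Molecule]:
    """Reproducible sample of distinct structures from the embedded pool.

    When the library has at least 10 drugs it always contains at least one
    structural outlier (inorganic / polyhalogenated) so that similarity
    clustering has something to set apart.
    """
    rng = substream(cfg.seed, "library")
    n_outliers = 1 if cfg.n_drugs >= 10 else 0
    n_pool = cfg.n_drugs - n_outliers
    if n_pool > len(POOL_SMILES):
        raise ValueError(
            f"requested {cfg.n_drugs} drugs but the embedded pool holds "
            f"{len(POOL_SMILES) + len(OUTLIER_SMILES)}"
        )
    chosen = list(rng.choice(len(POOL_SMILES), size=n_pool, replace=False))
    smiles = [POOL_SMILES[i] for i in sorted(chosen)]
    if n_outliers:
        smiles.append(OUTLIER_SMILES[int(rng.integers(len(OUTLIER_SMILES)))])
    text = "\n".join(f"{smi} D{i + 1:03d}" for i, smi in enumerate(smiles))
    mols, skipped = parse_structures(text)
    if skipped:  # pool entries are pre-verified; this would be a bug
        raise RuntimeError(f"embedded pool entry failed to parse: {skipped}")
    return mols


def _latent_projections(
    features: dict[str, DrugFeatures], cfg: SynthConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Standardize the feature matrix and project to the latent dimension."""
    drugs = sorted(features)
    mat = np.vstack([features[d].vector for d in drugs])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    d = z.shape[1]
    nnz = min(cfg.latent_sparsity, d)
    x = np.zeros((z.shape[0], cfg.latent_dim))
    for l in range(cfg.latent_dim):
        cols = rng.choice(d, size=nnz, replace=False)
        w = rng.choice([-1.0, 1.0], size=nnz)
        x[:, l] = z[:, cols] @ w / np.sqrt(nnz)
    return drugs, x


def plant_synergy(
    library: list[Molecule],
    cfg: SynthConfig,
    feature_cfg: FeatureConfig | None = None,
) -> tuple[GroundTruth, dict[str, DrugFeatures]]:
    """Plant a symmetric nonlinear true ComboScore surface.

    Returns the ground truth together with the drug features used to
    generate it (the same features a modeling run would compute).
    """
    feature_cfg = feature_cfg or FeatureConfig()
    features, _vocabs = featurize_library(library, feature_cfg)
    rng = substream(cfg.seed, "truth")
    drugs, x = _latent_projections(features, cfg, rng)
    n = len(drugs)
    cells = cfg.cell_lines
    w = rng.normal(size=(len(cells), cfg.latent_dim))
    offsets = rng.normal(scale=5.0, size=len(cells))

    # raw surface g over all pairs/cells (saturating main effects plus
    # product interaction), then scaled to unit SD so beta is the planted
    # signal SD in ComboScore units
    raw = {}
    for ci, cell in enumerate(cells):
        main = np.tanh(x) @ w[ci]  # per-drug saturating effect
        inter = (x * w[ci]) @ x.T  # (n, n): sum_l w[l] x_A[l] x_B[l]
        # saturate the interaction at 2 SD: its heavy tail would otherwise
        # plant near-unlearnable extremes at latent-space edges
        iu = inter[np.triu_indices(n, k=1)]
        isd = iu.std() if iu.std() > 0 else 1.0
        inter = 2.0 * isd * np.tanh(inter / (2.0 * isd))
        for i in range(n):
            for j in range(i + 1, n):
                raw[(drugs[i], drugs[j], cell)] = 0.7 * (
                    main[i] + main[j]
                ) + 0.3 * inter[i, j]
    vals = np.array(list(raw.values()))
    scale = vals.std() if vals.std() > 0 else 1.0

    # saturate at 2.5 SD: the product interaction is heavy-tailed, and a
    # handful of extreme planted scores would otherwise dominate RMSE
    s_true = {
        key: float(
            cfg.beta * 2.5 * np.tanh(v / scale / 2.5)
            + offsets[cells.index(key[2])]
        )
        for key, v in raw.items()
    }

    # pair hardness in [0, 1): grows with the pair's overall magnitude in
    # latent space (absolute cross-products plus per-drug magnitudes).
    # Extreme pairs are both intrinsically noisier and sit in sparser
    # regions of feature space, so forest tree disagreement can detect
    # them — which is exactly what reliability estimation must pick up.
    am = np.abs(x)
    drive = (am[:, None, :] * am[None, :, :]).sum(axis=2) + 0.5 * (
        am.sum(axis=1)[:, None] + am.sum(axis=1)[None, :]
    )
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dv = np.array([drive[i, j] for i, j in pairs])
    # rank-uniformize so the hardness spread is library-independent
    ranks = np.argsort(np.argsort(dv, kind="stable"), kind="stable")
    hardness = {
        (drugs[i], drugs[j]): float((r + 0.5) / len(pairs))
        for (i, j), r in zip(pairs, ranks)
    }

    base, driver = cfg.hetero_noise
    noise_sd = {}
    for (a, b, cell) in s_true:
        for center in cfg.centers:
            noise_sd[(a, b, cell, center.code)] = float(
                base + driver * hardness[(a, b)] + center.replicate_noise_sd
            )
    truth = GroundTruth(
        s_true=s_true,
        hardness=hardness,
        noise_sd=noise_sd,
        cell_offsets={c: float(o) for c, o in zip(cells, offsets)},
    )
    return truth, features


def _dose_curve(conc: np.ndarray, ec50: float, top: float = 85.0, hill: float = 1.0) -> np.ndarray:
    """Smooth single-agent growth curve, bounded in (0, top]."""
    return top / (1.0 + (conc / ec50) ** hill)


def emit_grids(
    truth: GroundTruth,
    cfg: SynthConfig,
    centers: list[CenterConfig] | None = None,
) -> tuple[list[DoseResponseGrid], list[SingleAgentRecord]]:
    """Materialize dose–response grids realizing the planted scores.

    For every non-missing (pair, cell line) tuple and every center, a grid
    is constructed whose ComboScore equals ``s_true + eps`` with
    ``eps ~ N(0, noise_sd)`` (exactly ``s_true`` under a zero-noise
    config): the combination cells are set at Bliss expectation minus the
    noisy score spread uniformly over the grid.  Single-agent replicate
    records are drawn per center with its planted mean test-date count and
    replicate noise SD.
    """
    centers = centers if centers is not None else cfg.centers
    noise_rng = substream(cfg.seed, "noise")
    miss_rng = substream(cfg.seed, "missing")
    rep_rng = substream(cfg.seed, "replicates")

    pairs_cells = sorted(truth.s_true)
    drugs = sorted({d for a, b, _ in pairs_cells for d in (a, b)})
    cells = sorted({c for _, _, c in pairs_cells})

    conc = np.array([0.1, 1.0, 10.0])[: cfg.grid_shape[0]]
    # per (drug, cell) EC50 on the concentration scale
    ec50 = {
        (d, c): float(10 ** rep_rng.uniform(-0.5, 0.5))
        for d in drugs
        for c in cells
    }

    keep = {
        key: (miss_rng.random() >= cfg.missing_fraction) for key in pairs_cells
    }

    grids: list[DoseResponseGrid] = []
    singles: list[SingleAgentRecord] = []
    n_cells_grid = cfg.grid_shape[0] * cfg.grid_shape[1]

    for center in centers:
        for (a, b, cell) in pairs_cells:
            if not keep[(a, b, cell)]:
                continue
            ga = _dose_curve(conc, ec50[(a, cell)])
            gb = _dose_curve(conc, ec50[(b, cell)])
            sd = truth.noise_sd[(a, b, cell, center.code)]
            # scaled Rademacher noise: mean 0 and SD exactly sd, with the
            # realized error magnitude pinned to the planted noise scale
            eps = sd * float(noise_rng.choice([-1.0, 1.0])) if sd > 0 else 0.0
            target = float(np.clip(truth.s_true[(a, b, cell)] + eps, -120.0, 120.0))
            expected = np.array(
                [[bliss_expected(ya, yb) for yb in gb] for ya in ga]
            )
            observed = expected - target / n_cells_grid
            grids.append(
                DoseResponseGrid(
                    drug_a=a, drug_b=b, cell_line=cell, center=center.code,
                    conc_a=conc, conc_b=conc, growth_a=ga, growth_b=gb,
                    growth_combo=observed, test_date=f"{center.code}-d0",
                )
            )

        # single-agent replicate records across test dates
        lam = max(center.mean_test_dates - 1.0, 0.0)
        for d in drugs:
            for cell in cells:
                n_dates = 1 + int(rep_rng.poisson(lam))
                for t in range(n_dates):
                    for c in conc:
                        base_growth = _dose_curve(np.array([c]), ec50[(d, cell)])[0]
                        g = base_growth + rep_rng.normal(scale=center.replicate_noise_sd)
                        singles.append(
                            SingleAgentRecord(
                                center=center.code, drug=d, conc=float(c),
                                cell_line=cell, test_date=f"t{t:02d}",
                                growth=float(min(g, 100.0)),
                            )
                        )
    return grids, singles


def synthetic_labels(
    truth: GroundTruth, cfg: SynthConfig, center_code: str | None = None
) -> dict[str, dict[tuple[str, str], float]]:
    """Noisy per-cell-line labels {cell: {(a, b): score}} from emitted grids.

    Convenience wrapper that scores every emitted grid for one center
    (default: the first configured center).
    """
    from .scoring import combo_score

    code = center_code or cfg.centers[0].code
    grids, _ = emit_grids(truth, cfg)
    out: dict[str, dict[tuple[str, str], float]] = {}
    for g in grids:
        if g.center != code:
            continue
        out.setdefault(g.cell_line, {})[pair_key(g.drug_a, g.drug_b)] = combo_score(g)
    return out
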
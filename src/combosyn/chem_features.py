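"""Chemical featurization of drugs for synergy modeling.

Drugs are represented as heavy-atom molecular graphs and encoded as numeric
descriptor vectors from up to six blocks:

``mfp``
    Binary Morgan (circular) fingerprint, hashed/folded to a fixed length
    (default 256 bits, radius 2).
``mfpc``
    Counted Morgan fingerprint — same environments, occurrence counts.
``maccs``
    The 166 public MACCS substructure keys (binary).
``isida``
    Atom–bond sequence fragments: counts of simple paths of 2–6 heavy
    atoms, labeled by element symbols and bond symbols.
``sirms``
    Simplex fragments: counts of every 4-atom subset labeled by element
    symbols and the bond pattern over the six atom pairs (bonded or not).
``physchem``
    Seven physico-chemical properties: TPSA, molecular weight, logP,
    aliphatic ring count, aromatic ring count, H-bond donors, H-bond
    acceptors.

Fragment blocks (``isida``, ``sirms``) live in a dataset-level vocabulary so
that every drug in a library shares one fixed-width feature space.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator, rdmolops
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

BOND_SYMBOLS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

#: Fixed concatenation order of feature blocks within a drug vector.
BLOCK_ORDER = ("mfp", "mfpc", "maccs", "isida", "sirms", "physchem")

PHYSCHEM_NAMES = (
    "tpsa",
    "mol_weight",
    "logp",
    "n_aliphatic_rings",
    "n_aromatic_rings",
    "n_hbond_donors",
    "n_hbond_acceptors",
)


@dataclass
class Molecule:
    """A heavy-atom molecular graph with an identifier.

    ``atoms`` holds (element symbol, aromatic flag, formal charge) triples;
    ``bonds`` holds (i, j, bond symbol) with the symbol one of ``- = # :``.
    Hydrogens are implicit.  Disconnected graphs (salts, mixtures) are
    allowed.
    """

    id: str
    atoms: list[tuple[str, bool, int]]
    bonds: list[tuple[int, int, str]]
    source: str
    rdkit_mol: Chem.Mol = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        seen = set()
        for i, j, _sym in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"molecule {self.id!r}: invalid bond ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"molecule {self.id!r}: duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> dict[int, list[tuple[int, str]]]:
        """Neighbor lists: atom index -> [(neighbor index, bond symbol)]."""
        adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(self.n_atoms)}
        for i, j, sym in self.bonds:
            adj[i].append((j, sym))
            adj[j].append((i, sym))
        return adj


@dataclass
class FeatureBlock:
    """A named, ordered block of numeric descriptors for one drug."""

    block_name: str
    feature_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.feature_ids):
            raise ValueError(
                f"block {self.block_name}: {len(self.values)} values for "
                f"{len(self.feature_ids)} feature ids"
            )


@dataclass
class FeatureConfig:
    """Descriptor settings.

    ``fp_length``/``fp_radius`` control the Morgan blocks; path fragments
    span ``path_min_atoms``..``path_max_atoms`` atoms; simplex fragments are
    always 4 atoms.  ``sirms_atom_cap`` guards the O(n^4) simplex
    enumeration.
    """

    blocks: tuple[str, ...] = ("mfpc", "physchem")
    fp_length: int = 256
    fp_radius: int = 2
    path_min_atoms: int = 2
    path_max_atoms: int = 6
    sirms_atom_cap: int = 50

    def __post_init__(self) -> None:
        if self.fp_length <= 0:
            raise ValueError("fp_length must be positive")
        if self.path_min_atoms > self.path_max_atoms:
            raise ValueError("path_min_atoms > path_max_atoms")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")


@dataclass
class DrugFeatures:
    """Concatenated descriptor vector for one drug, block by block."""

    drug_id: str
    blocks: list[FeatureBlock]

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([b.values for b in self.blocks])

    @property
    def feature_ids(self) -> list:
        out = []
        for b in self.blocks:
            out.extend((b.block_name, fid) for fid in b.feature_ids)
        return out


def _molecule_from_rdkit(mol: Chem.Mol, mol_id: str, source: str) -> Molecule:
    atoms = [
        (a.GetSymbol(), a.GetIsAromatic(), a.GetFormalCharge()) for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        sym = BOND_SYMBOLS.get(b.GetBondType())
        if sym is None:
            # dative/unspecified bonds in permissively parsed structures
            sym = "-"
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), sym))
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, source=source, rdkit_mol=mol)


def _parse_one_smiles(smiles: str, mol_id: str) -> Molecule | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        # permissive fallback for organometallics whose valence model fails
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            return None
        try:
            mol.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(
                mol,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                catchErrors=True,
            )
        except Exception:
            return None
        logger.warning("permissive parse used for %s (%s)", mol_id, smiles)
    return _molecule_from_rdkit(mol, mol_id, smiles)


def parse_structures(text: str, fmt: str = "smiles") -> tuple[list[Molecule], list[tuple[str, str]]]:
    """Parse a batch of structures from SMILES lines or SDF text.

    SMILES input is one ``SMILES<whitespace>ID`` record per line.  Returns
    (molecules, skipped) where ``skipped`` holds (record id, reason) for
    unparsable records; a bad record never aborts the batch.

    Raises ``ValueError`` on empty input or unknown format.
    """
    molecules: list[Molecule] = []
    skipped: list[tuple[str, str]] = []
    if fmt == "smiles":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty SMILES input")
        for lineno, line in enumerate(lines, 1):
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"line{lineno}"
            mol = _parse_one_smiles(smiles, mol_id)
            if mol is None:
                skipped.append((mol_id, f"unparsable SMILES: {smiles!r}"))
            else:
                molecules.append(mol)
    elif fmt == "sdf":
        if not text.strip():
            raise ValueError("empty SDF input")
        supplier = Chem.SDMolSupplier()
        supplier.SetData(text, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped.append((f"record{i}", "unparsable SDF record"))
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record{i}"
            molecules.append(
                _molecule_from_rdkit(mol, mol_id or f"record{i}", Chem.MolToSmiles(mol))
            )
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")
    return molecules, skipped


def _require_rdkit(mol: Molecule) -> Chem.Mol:
    if mol.rdkit_mol is None:
        raise ValueError(f"molecule {mol.id!r} carries no RDKit structure")
    return mol.rdkit_mol


def morgan_features(mol: Molecule, cfg: FeatureConfig | None = None, counted: bool = False) -> FeatureBlock:
    """Hashed Morgan fingerprint, binary (``mfp``) or counted (``mfpc``).

    Environments are folded into ``cfg.fp_length`` buckets; the binary
    variant is exactly the binarization of the counted one.
    """
    cfg = cfg or FeatureConfig()
    rd = _require_rdkit(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=cfg.fp_radius, fpSize=cfg.fp_length
    )
    counts = np.zeros(cfg.fp_length, dtype=float)
    fp = gen.GetCountFingerprint(rd)
    for bit, c in fp.GetNonzeroElements().items():
        counts[bit] = c
    values = counts if counted else (counts > 0).astype(float)
    name = "mfpc" if counted else "mfp"
    return FeatureBlock(name, list(range(cfg.fp_length)), values)


def maccs_features(mol: Molecule) -> FeatureBlock:
    """The 166 public MACCS substructure keys as a binary vector."""
    rd = _require_rdkit(mol)
    bv = MACCSkeys.GenMACCSKeys(rd)  # 167 bits, bit 0 unused
    arr = np.zeros(167, dtype=float)
    for bit in bv.GetOnBits():
        arr[bit] = 1.0
    return FeatureBlock("maccs", list(range(1, 167)), arr[1:])


def _canonical_path_id(labels: list[str], bonds: list[str]) -> str:
    """Canonical fragment string: lexicographic min of forward vs reversed."""
    fwd = labels[0]
    for sym, lab in zip(bonds, labels[1:]):
        fwd += sym + lab
    rev_labels = labels[::-1]
    rev_bonds = bonds[::-1]
    rev = rev_labels[0]
    for sym, lab in zip(rev_bonds, rev_labels[1:]):
        rev += sym + lab
    return min(fwd, rev)


def isida_path_fragments(mol: Molecule, cfg: FeatureConfig | None = None) -> FeatureBlock:
    """Atom–bond sequence fragments: counts of simple heavy-atom paths.

    Paths of ``path_min_atoms`` to ``path_max_atoms`` atoms; each undirected
    path is counted once; fragment ids alternate element and bond symbols
    and are canonicalized as min(forward, reversed).
    """
    cfg = cfg or FeatureConfig()
    adj = mol.adjacency()
    symbols = [a[0] for a in mol.atoms]
    counts: dict[str, int] = {}

    def extend(path: list[int], bonds: list[str]) -> None:
        n = len(path)
        if cfg.path_min_atoms <= n <= cfg.path_max_atoms and path[0] < path[-1]:
            frag = _canonical_path_id([symbols[i] for i in path], bonds)
            counts[frag] = counts.get(frag, 0) + 1
        if n >= cfg.path_max_atoms:
            return
        last = path[-1]
        on_path = set(path)
        for nb, sym in adj[last]:
            if nb not in on_path:
                path.append(nb)
                bonds.append(sym)
                extend(path, bonds)
                path.pop()
                bonds.pop()

    for start in range(mol.n_atoms):
        extend([start], [])
    ids = sorted(counts)
    return FeatureBlock("isida", ids, np.array([counts[i] for i in ids], dtype=float))


_SIMPLEX_PAIRS = list(itertools.combinations(range(4), 2))
_SIMPLEX_PERMS = list(itertools.permutations(range(4)))


def _canonical_simplex_id(labels: tuple[str, ...], bondmap: dict[tuple[int, int], str]) -> str:
    best = None
    for perm in _SIMPLEX_PERMS:
        labs = ",".join(labels[p] for p in perm)
        pat = "".join(
            bondmap.get((min(perm[i], perm[j]), max(perm[i], perm[j])), ".")
            for i, j in _SIMPLEX_PAIRS
        )
        cand = labs + "|" + pat
        if best is None or cand < best:
            best = cand
    return best


def sirms_simplex_fragments(mol: Molecule, cfg: FeatureConfig | None = None) -> FeatureBlock:
    """Simplex fragments: every 4-atom subset with its 6-pair bond pattern.

    The fragment id lists the four element symbols and the bond symbol (or
    ``.`` for non-bonded) of each atom pair, canonicalized over all 24 atom
    permutations.  Counts over all C(n,4) subsets.  Molecules above
    ``sirms_atom_cap`` atoms raise (O(n^4) guard); fewer than 4 atoms give
    an empty block.
    """
    cfg = cfg or FeatureConfig()
    n = mol.n_atoms
    if n > cfg.sirms_atom_cap:
        raise ValueError(
            f"molecule {mol.id!r} has {n} atoms, above the simplex enumeration "
            f"cap of {cfg.sirms_atom_cap}"
        )
    if n < 4:
        return FeatureBlock("sirms", [], np.array([]))
    symbols = [a[0] for a in mol.atoms]
    bondmap = {(min(i, j), max(i, j)): sym for i, j, sym in mol.bonds}
    counts: dict[str, int] = {}
    for quad in itertools.combinations(range(n), 4):
        local = {}
        for a, b in itertools.combinations(range(4), 2):
            sym = bondmap.get((quad[a], quad[b]))
            if sym is not None:
                local[(a, b)] = sym
        frag = _canonical_simplex_id(tuple(symbols[q] for q in quad), local)
        counts[frag] = counts.get(frag, 0) + 1
    ids = sorted(counts)
    return FeatureBlock("sirms", ids, np.array([counts[i] for i in ids], dtype=float))


def physchem_features(mol: Molecule) -> FeatureBlock:
    """TPSA, MW, logP, aliphatic/aromatic ring counts, H-bond donors/acceptors."""
    rd = _require_rdkit(mol)
    values = np.array(
        [
            Descriptors.TPSA(rd),
            Descriptors.MolWt(rd),
            Descriptors.MolLogP(rd),
            Descriptors.NumAliphaticRings(rd),
            Descriptors.NumAromaticRings(rd),
            Descriptors.NumHDonors(rd),
            Descriptors.NumHAcceptors(rd),
        ],
        dtype=float,
    )
    return FeatureBlock("physchem", list(PHYSCHEM_NAMES), values)


class FragmentVocabulary:
    """Dataset-level vocabulary for a fragment block.

    Built from the union of fragments observed across a drug library,
    sorted lexicographically.  At lookup time, fragments absent from the
    vocabulary are dropped so all drugs share one fixed-width space.
    """

    def __init__(self, block_name: str, fragment_ids: list[str]):
        self.block_name = block_name
        self.fragment_ids = sorted(fragment_ids)
        self._index = {f: i for i, f in enumerate(self.fragment_ids)}

    def __len__(self) -> int:
        return len(self.fragment_ids)

    def vectorize(self, block: FeatureBlock) -> FeatureBlock:
        values = np.zeros(len(self.fragment_ids))
        for fid, v in zip(block.feature_ids, block.values):
            idx = self._index.get(fid)
            if idx is not None:
                values[idx] = v
        return FeatureBlock(self.block_name, list(self.fragment_ids), values)

    def to_dict(self) -> dict:
        return {"block_name": self.block_name, "fragment_ids": self.fragment_ids}

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentVocabulary":
        return cls(d["block_name"], d["fragment_ids"])


def build_vocabularies(mols: list[Molecule], cfg: FeatureConfig) -> dict[str, FragmentVocabulary]:
    """Union-of-observed-fragments vocabularies for isida/sirms blocks."""
    vocabs: dict[str, FragmentVocabulary] = {}
    if "isida" in cfg.blocks:
        frags: set[str] = set()
        for m in mols:
            frags.update(isida_path_fragments(m, cfg).feature_ids)
        vocabs["isida"] = FragmentVocabulary("isida", sorted(frags))
    if "sirms" in cfg.blocks:
        frags = set()
        for m in mols:
            frags.update(sirms_simplex_fragments(m, cfg).feature_ids)
        vocabs["sirms"] = FragmentVocabulary("sirms", sorted(frags))
    return vocabs


def featurize_drug(
    mol: Molecule,
    cfg: FeatureConfig,
    vocabularies: dict[str, FragmentVocabulary] | None = None,
) -> DrugFeatures:
    """Compute the configured blocks and concatenate them in fixed order.

    Fragment blocks require a dataset-level vocabulary (see
    ``build_vocabularies``) so that every drug shares one feature space.
    """
    if not cfg.blocks:
        raise ValueError("cfg.blocks must be nonempty")
    vocabularies = vocabularies or {}
    blocks: list[FeatureBlock] = []
    for name in BLOCK_ORDER:
        if name not in cfg.blocks:
            continue
        if name == "mfp":
            blocks.append(morgan_features(mol, cfg, counted=False))
        elif name == "mfpc":
            blocks.append(morgan_features(mol, cfg, counted=True))
        elif name == "maccs":
            blocks.append(maccs_features(mol))
        elif name == "isida":
            if "isida" not in vocabularies:
                raise ValueError("isida block requires a fragment vocabulary")
            blocks.append(vocabularies["isida"].vectorize(isida_path_fragments(mol, cfg)))
        elif name == "sirms":
            if "sirms" not in vocabularies:
                raise ValueError("sirms block requires a fragment vocabulary")
            blocks.append(vocabularies["sirms"].vectorize(sirms_simplex_fragments(mol, cfg)))
        elif name == "physchem":
            blocks.append(physchem_features(mol))
    return DrugFeatures(mol.id, blocks)


def featurize_library(
    mols: list[Molecule], cfg: FeatureConfig
) -> tuple[dict[str, DrugFeatures], dict[str, FragmentVocabulary]]:
    """Featurize a drug library under one shared feature space."""
    vocabs = build_vocabularies(mols, cfg)
    feats = {m.id: featurize_drug(m, cfg, vocabs) for m in mols}
    return feats, vocabs


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity for binary or non-negative count vectors.

    Binary inputs give |intersection|/|union|; general non-negative inputs
    use the continuous form sum(min)/sum(max).  Two all-zero vectors are
    defined to have similarity 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("tanimoto requires non-negative vectors")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


def _scaled_matrix(features: list[DrugFeatures]) -> np.ndarray:
    """Stack drug vectors, min–max scaling each physchem column to [0,1].

    Raw physico-chemical magnitudes (molecular weight ~hundreds) would
    otherwise dominate the generalized Tanimoto over count features.
    """
    mat = np.vstack([f.vector for f in features])
    col = 0
    for block in features[0].blocks:
        width = len(block.values)
        if block.block_name == "physchem":
            sub = mat[:, col : col + width]
            lo, hi = sub.min(axis=0), sub.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            mat[:, col : col + width] = (sub - lo) / span
        col += width
    return mat


def similarity_matrix(features: list[DrugFeatures]) -> np.ndarray:
    """Pairwise Tanimoto similarity over a drug library (scaled physchem)."""
    mat = _scaled_matrix(features)
    n = len(features)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = tanimoto(mat[i], mat[j])
    return sim


def cluster_drugs(
    features: list[DrugFeatures], threshold: float = 0.8
) -> tuple[np.ndarray, dict[str, list[list[str]]]]:
    """Ward-linkage agglomerative clustering on 1 − Tanimoto distance.

    Returns (linkage matrix, result dict) where the result lists flat
    clusters of size ≥ 2 at the given similarity threshold.
    """
    if len(features) < 2:
        raise ValueError("clustering requires at least 2 drugs")
    sim = similarity_matrix(features)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    flat = fcluster(z, t=1.0 - threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for f, lab in zip(features, flat):
        groups.setdefault(lab, []).append(f.drug_id)
    clusters = [sorted(g) for g in groups.values() if len(g) >= 2]
    return z, {"clusters": sorted(clusters)}
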
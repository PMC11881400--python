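"""Compound data ingestion, Tanimoto clustering and cluster-atomic CV folds.

Compounds are represented as sparse binary fingerprint matrices (hashed
circular fingerprints, radius 3, folded to 32768 bits by default).  To keep
train and test sets in divergent chemical space, compounds are grouped by
single-pass leader (sphere-exclusion) clustering on Tanimoto similarity and
whole clusters are assigned to five cross-validation folds: three folds
train, one validates (early stopping, hyperparameter tuning, Platt
calibration, prior tuning), one tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

DEFAULT_N_BITS = 32768
DEFAULT_RADIUS = 3
DEFAULT_CLUSTER_THRESHOLD = 0.6


class UndefinedSimilarityError(ValueError):
    """Tanimoto similarity is undefined when both fingerprints are empty."""


@dataclass
class FingerprintMatrix:
    """Sparse binary compound-by-feature matrix (rows = compounds)."""

    data: sp.csr_matrix

    def __post_init__(self):
        m = sp.csr_matrix(self.data)
        m.eliminate_zeros()
        m.data = np.ones_like(m.data, dtype=np.int8)  # binarize stored values
        self.data = m

    @property
    def n_compounds(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def popcounts(self) -> np.ndarray:
        """Number of set bits per compound."""
        return np.asarray(self.data.sum(axis=1)).ravel().astype(np.int64)

    def row(self, i: int) -> sp.csr_matrix:
        return self.data[i]

    @classmethod
    def from_dense(cls, arr) -> "FingerprintMatrix":
        return cls(sp.csr_matrix(np.asarray(arr)))


@dataclass(frozen=True)
class FoldSplit:
    """Partition of the 5 folds into 3 train / 1 valid / 1 test."""

    train_folds: frozenset
    valid_fold: int
    test_fold: int

    def __post_init__(self):
        all_folds = set(self.train_folds) | {self.valid_fold, self.test_fold}
        if (len(self.train_folds) != 3 or self.valid_fold == self.test_fold
                or self.valid_fold in self.train_folds
                or self.test_fold in self.train_folds
                or all_folds != set(range(5))):
            raise ValueError("folds must partition {0..4} into 3 train / 1 valid / 1 test")


def make_split(valid_fold: int, test_fold: int, n_folds: int = 5) -> FoldSplit:
    """Build the 3/1/1 split with train folds as the complement."""
    if valid_fold == test_fold:
        raise ValueError("validation and test fold must differ")
    if not (0 <= valid_fold < n_folds and 0 <= test_fold < n_folds):
        raise ValueError(f"fold indices must be in 0..{n_folds - 1}")
    train = frozenset(range(n_folds)) - {valid_fold, test_fold}
    return FoldSplit(train_folds=train, valid_fold=valid_fold, test_fold=test_fold)


@dataclass
class BioactivityDataset:
    """Fingerprints + binary activity labels + cluster and fold assignment."""

    features: FingerprintMatrix
    labels: np.ndarray
    cluster_id: np.ndarray
    fold_id: np.ndarray
    compound_ids: list | None = field(default=None, repr=False)

    def __post_init__(self):
        n = self.features.n_compounds
        for name in ("labels", "cluster_id", "fold_id"):
            v = np.asarray(getattr(self, name))
            if v.shape != (n,):
                raise ValueError(f"{name} must have length n_compounds={n}")
            setattr(self, name, v)
        self.labels = self.labels.astype(np.int8)
        # cluster atomicity: every cluster maps to exactly one fold
        df = pd.DataFrame({"c": self.cluster_id, "f": self.fold_id})
        spread = df.groupby("c")["f"].nunique()
        if (spread > 1).any():
            raise ValueError("cluster spans multiple folds; splits must be cluster-atomic")

    @property
    def n_compounds(self) -> int:
        return self.features.n_compounds

    def fold_indices(self, folds) -> np.ndarray:
        folds = {folds} if np.isscalar(folds) else set(folds)
        return np.flatnonzero(np.isin(self.fold_id, list(folds)))

    def split_arrays(self, split: FoldSplit):
        """(X_train, y_train, X_valid, y_valid, X_test, y_test) for a split."""
        tr = self.fold_indices(split.train_folds)
        va = self.fold_indices(split.valid_fold)
        te = self.fold_indices(split.test_fold)
        X = self.features.data
        return (X[tr], self.labels[tr], X[va], self.labels[va],
                X[te], self.labels[te])


def tanimoto_similarity(a, b) -> float:
    """|A ∩ B| / |A ∪ B| on binary fingerprint bit sets.

    Accepts dense or sparse row vectors of equal dimension.  Undefined (raises)
    when both are all-zero.
    """
    a = np.asarray(a.todense() if sp.issparse(a) else a).ravel().astype(bool)
    b = np.asarray(b.todense() if sp.issparse(b) else b).ravel().astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must share the feature dimension")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise UndefinedSimilarityError("both fingerprints are empty")
    return inter / union


def leader_cluster(fps: FingerprintMatrix, threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                   order_seed: int = 0) -> np.ndarray:
    """Single-pass leader (sphere-exclusion) clustering on Tanimoto similarity.

    Compounds are visited in a seeded random order.  Each compound joins the
    first existing cluster (in leader-creation order) whose leader is at least
    ``threshold`` similar, otherwise it founds a new cluster and becomes its
    leader.  Leaders are therefore mutually < threshold similar, and every
    member is >= threshold similar to its leader.  Cluster ids are contiguous
    from 0 in leader-creation order.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    n = fps.n_compounds
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pops = fps.popcounts()
    if (pops == 0).any():
        raise ValueError("all-zero fingerprint rows are not allowed in clustering")

    rng = np.random.default_rng(order_seed)
    order = rng.permutation(n)
    X = fps.data
    cluster_id = np.full(n, -1, dtype=np.int64)
    leader_rows: list[sp.csr_matrix] = []
    leader_pops: list[int] = []
    L: sp.csr_matrix | None = None  # stacked leader fingerprints

    for i in order:
        if L is not None:
            inter = np.asarray((L @ X[i].T).todense()).ravel()
            union = np.asarray(leader_pops) + pops[i] - inter
            sims = inter / union
            hits = np.flatnonzero(sims >= threshold)
            if hits.size:
                cluster_id[i] = hits[0]
                continue
        cluster_id[i] = len(leader_rows)
        leader_rows.append(X[i])
        leader_pops.append(int(pops[i]))
        L = sp.vstack(leader_rows, format="csr")
    return cluster_id


def assign_folds(cluster_id, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Assign whole clusters to folds with greedy size balancing.

    Clusters are sorted by descending size and each is given to the currently
    smallest fold, ties between equally small folds broken by seeded random
    choice.  The assignment is a function of the cluster, never the compound.
    """
    cluster_id = np.asarray(cluster_id, dtype=np.int64)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    clusters, sizes = np.unique(cluster_id, return_counts=True)
    if len(clusters) < n_folds:
        warnings.warn(
            f"only {len(clusters)} clusters for {n_folds} folds; some folds will be empty",
            UserWarning, stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    order = np.argsort(-sizes, kind="stable")
    fold_sizes = np.zeros(n_folds, dtype=np.int64)
    cluster_fold: dict[int, int] = {}
    for j in order:
        smallest = np.flatnonzero(fold_sizes == fold_sizes.min())
        f = int(rng.choice(smallest))
        cluster_fold[int(clusters[j])] = f
        fold_sizes[f] += int(sizes[j])
    return np.array([cluster_fold[int(c)] for c in cluster_id], dtype=np.int64)


def build_dataset(features: FingerprintMatrix, labels,
                  cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                  n_folds: int = 5, order_seed: int = 0,
                  fold_seed: int = 0, compound_ids=None) -> BioactivityDataset:
    """Cluster compounds and assign cluster-atomic folds."""
    cid = leader_cluster(features, threshold=cluster_threshold, order_seed=order_seed)
    fid = assign_folds(cid, n_folds=n_folds, seed=fold_seed)
    return BioactivityDataset(features=features, labels=np.asarray(labels),
                              cluster_id=cid, fold_id=fid, compound_ids=compound_ids)


def smiles_to_fingerprints(smiles_list, n_bits: int = DEFAULT_N_BITS,
                           radius: int = DEFAULT_RADIUS):
    """Hashed circular (Morgan) fingerprints, counts binarized, 0-based bits.

    Returns (csr fingerprint matrix, list of valid row positions); unparsable
    SMILES are skipped with a logged warning.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    rows, cols, keep = [], [], []
    r = 0
    for pos, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("skipping unparsable SMILES at row %d: %r", pos, smi)
            continue
        bits = list(gen.GetFingerprint(mol).GetOnBits())
        rows.extend([r] * len(bits))
        cols.extend(bits)
        keep.append(pos)
        r += 1
    mat = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(r, n_bits)
    )
    return mat, keep


def load_compound_table(path, smiles_column: str = "smiles",
                        label_column: str = "label",
                        pic50_threshold: float | None = None,
                        n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS,
                        cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                        order_seed: int = 0, fold_seed: int = 0,
                        id_column: str | None = None) -> BioactivityDataset:
    """Featurize a delimited compound table into a clustered, folded dataset.

    With ``pic50_threshold`` the label column holds continuous pIC50 and the
    activity label is 1 iff pIC50 >= threshold; otherwise the label column is
    used verbatim as {0,1}.  All-zero fingerprints and unparsable SMILES are
    dropped with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (smiles_column, label_column):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    mat, keep = smiles_to_fingerprints(df[smiles_column].tolist(),
                                       n_bits=n_bits, radius=radius)
    df = df.iloc[keep].reset_index(drop=True)
    pops = np.asarray(mat.sum(axis=1)).ravel()
    nz = pops > 0
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} all-zero fingerprints",
                      UserWarning, stacklevel=2)
        mat = mat[nz]
        df = df.loc[nz].reset_index(drop=True)
    if pic50_threshold is not None:
        labels = (df[label_column].to_numpy(dtype=np.float64)
                  >= pic50_threshold).astype(np.int8)
    else:
        labels = df[label_column].to_numpy()
    ids = df[id_column].tolist() if id_column and id_column in df.columns else None
    return build_dataset(FingerprintMatrix(mat), labels,
                         cluster_threshold=cluster_threshold,
                         order_seed=order_seed, fold_seed=fold_seed,
                         compound_ids=ids)


def load_feature_matrix(mtx_path, labels_path,
                        cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                        order_seed: int = 0, fold_seed: int = 0) -> BioactivityDataset:
    """Load a Matrix Market feature matrix plus aligned one-column label file."""
    mat = sp.csr_matrix(mmread(str(mtx_path)))
    labels = np.loadtxt(str(labels_path), dtype=np.float64).astype(np.int8)
    if labels.ndim == 0:
        labels = labels.reshape(1)
    if labels.shape[0] != mat.shape[0]:
        raise ValueError("label vector length must match the matrix row count")
    return build_dataset(FingerprintMatrix(mat), labels,
                         cluster_threshold=cluster_threshold,
                         order_seed=order_seed, fold_seed=fold_seed)


def save_feature_matrix(dataset: BioactivityDataset, mtx_path, labels_path) -> None:
    """Write features as Matrix Market plus an aligned one-column label file."""
    mmwrite(str(mtx_path), dataset.features.data)
    np.savetxt(str(labels_path), dataset.labels, fmt="%d")


def export_split(dataset: BioactivityDataset, path) -> None:
    """Write compound_index, cluster_id, fold_id as a CSV table."""
    pd.DataFrame({
        "compound_index": np.arange(dataset.n_compounds),
        "cluster_id": dataset.cluster_id,
        "fold_id": dataset.fold_id,
    }).to_csv(path, index=False)
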
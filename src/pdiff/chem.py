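"""Chemistry utilities: fingerprints, Tanimoto similarity, clustering, splits.

The evaluation protocol hinges on a "realistically novel" train/held-out
split: compounds are clustered by Tanimoto similarity of their substructure
fingerprints, whole clusters are assigned to the training set largest-first,
and the held-out set ends up made of singletons and small series — mimicking
a screening campaign that tests chemistry unlike anything trained on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "CompoundRecord",
    "ClusterSet",
    "fingerprint",
    "tanimoto",
    "tanimoto_matrix",
    "cluster",
    "realistic_split",
    "cross_split_similarity",
]

FP_WIDTH = 2048
FP_RADIUS = 2  # ECFP4-equivalent


@dataclass
class CompoundRecord:
    """A compound with its folded substructure-count fingerprint."""

    compound_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    cluster_id: int | None = None
    split: Literal["train", "heldout", "unassigned"] = "unassigned"

    def __post_init__(self) -> None:
        if self.fingerprint is None:
            if self.smiles is None:
                raise ValueError(f"{self.compound_id}: need smiles or fingerprint")
            self.fingerprint = fingerprint(self.smiles)
        self.fingerprint = np.asarray(self.fingerprint)
        if self.fingerprint.ndim != 1:
            raise ValueError(f"{self.compound_id}: fingerprint must be 1-D")
        if np.any(self.fingerprint < 0):
            raise ValueError(f"{self.compound_id}: fingerprint counts must be >= 0")


@dataclass
class ClusterSet:
    """A partition of compound ids into clusters, sorted by descending size."""

    clusters: list[list[str]]

    def __post_init__(self) -> None:
        sizes = [len(c) for c in self.clusters]
        if any(s == 0 for s in sizes):
            raise ValueError("empty cluster")
        if sizes != sorted(sizes, reverse=True):
            raise ValueError("clusters must be sorted by descending size")
        flat = [cid for c in self.clusters for cid in c]
        if len(flat) != len(set(flat)):
            raise ValueError("clusters do not partition the compound set")

    @property
    def n_compounds(self) -> int:
        return sum(len(c) for c in self.clusters)


def fingerprint(smiles: str, width: int = FP_WIDTH, radius: int = FP_RADIUS) -> np.ndarray:
    """Morgan substructure-count fingerprint folded into ``width`` counts."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    return gen.GetCountFingerprintAsNumPy(mol).astype(np.int64)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (intersection over union) on binarized fingerprints."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint shapes differ: {a.shape} vs {b.shape}")
    abits = a > 0
    bbits = b > 0
    union = np.count_nonzero(abits | bbits)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return np.count_nonzero(abits & bbits) / union


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray | None = None) -> np.ndarray:
    """All-pairs Tanimoto between two stacks of count fingerprints.

    Vectorized over binarized bits: |a & b| = a.b for 0/1 vectors and
    |a | b| = |a| + |b| - |a & b|.  All-zero pairs get similarity 0.
    """
    A = (np.asarray(fps_a) > 0).astype(np.float32)
    B = A if fps_b is None else (np.asarray(fps_b) > 0).astype(np.float32)
    inter = A @ B.T
    na = A.sum(axis=1)[:, None]
    nb = B.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.astype(np.float64)


def cluster(compounds: Sequence[CompoundRecord], similarity_cutoff: float = 0.6) -> ClusterSet:
    """Leader-style (Butina) clustering at a Tanimoto cutoff.

    Two compounds are neighbors when their Tanimoto similarity is >= the
    cutoff.  Cluster seeds are processed in order of decreasing neighbor
    count, ties broken by compound_id, which makes the partition independent
    of input order.
    """
    if not compounds:
        raise ValueError("need at least one compound")
    if not 0.0 < similarity_cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1), got {similarity_cutoff}")
    ids = [c.compound_id for c in compounds]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate compound_id")
    order = np.argsort(np.array(ids, dtype=object))
    ids = [ids[i] for i in order]
    fps = np.stack([compounds[i].fingerprint for i in order])

    sim = tanimoto_matrix(fps)
    neighbors = sim >= similarity_cutoff
    np.fill_diagonal(neighbors, True)
    counts = neighbors.sum(axis=1)

    # ids are already sorted, so stable sort on -count breaks ties by id
    seed_order = np.argsort(-counts, kind="stable")
    assigned = np.zeros(len(ids), dtype=bool)
    clusters: list[list[str]] = []
    for s in seed_order:
        if assigned[s]:
            continue
        members = np.flatnonzero(neighbors[s] & ~assigned)
        assigned[members] = True
        clusters.append(sorted(ids[m] for m in members))
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ClusterSet(clusters)


def realistic_split(
    clusters: ClusterSet, train_fraction: float = 0.9
) -> tuple[list[str], list[str]]:
    """Allocate whole clusters largest-first to train; hold out the tail.

    The target training size is round(train_fraction * N).  Whole clusters go
    to train while they fit; once the next cluster would overshoot, remaining
    singletons are used to top the training set up to the exact target, and
    everything else is held out.  With a singleton-rich tail the printed
    90/10 counts (e.g. 3375/375 of 3750) are met exactly.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n = clusters.n_compounds
    target = round(train_fraction * n)
    if clusters.clusters and target < len(clusters.clusters[0]):
        warnings.warn(
            f"largest cluster ({len(clusters.clusters[0])}) exceeds the train target "
            f"({target}); it is still assigned to train",
            stacklevel=2,
        )
    train: list[str] = []
    heldout: list[str] = []
    for i, members in enumerate(clusters.clusters):
        if not train:
            train.extend(members)  # largest cluster always trains
        elif len(train) + len(members) <= target:
            train.extend(members)
        elif len(members) == 1 and len(train) < target:
            train.extend(members)
        else:
            heldout.extend(members)
    return train, heldout


def cross_split_similarity(
    train: Sequence[CompoundRecord], heldout: Sequence[CompoundRecord]
) -> tuple[np.ndarray, float]:
    """Per-heldout-compound max Tanimoto to the training set, plus the median.

    The median is the headline novelty statistic of a split: low values mean
    the held-out chemistry is genuinely unlike the training chemistry.
    """
    if not train or not heldout:
        raise ValueError("both splits must be nonempty")
    fps_h = np.stack([c.fingerprint for c in heldout])
    fps_t = np.stack([c.fingerprint for c in train])
    sim = tanimoto_matrix(fps_h, fps_t)
    per_heldout = sim.max(axis=1)
    return per_heldout, float(np.median(per_heldout))
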
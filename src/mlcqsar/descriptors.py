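"""Descriptor redundancy analysis and variable clustering.

Before regression modelling, the candidate molecular descriptors are
screened for redundancy.  Pairwise similarity between descriptor columns
is expressed on a 0-100% scale as ``100 * (1 + r) / 2``, where ``r`` is
the Pearson correlation (so r = 1 maps to 100%, r = -1 to 0%).
Agglomerative clustering on the complementary dissimilarity then groups
descriptors; on the study table this yields three groups:

* group I  — TPSA and HBA (molecular polarity / hydrogen bonding),
* group II — polarizability, parachor and molecular weight (size),
* group III — NRB alone (flexibility).

Candidate regression models draw at most one member from each correlated
group, keeping predictors only moderately collinear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ValidationError

__all__ = ["SimilarityMatrix", "DescriptorGrouping", "pairwise_similarity", "cluster_variables"]

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of pairwise descriptor similarities in percent."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0, atol=1e-8):
            raise ValidationError("similarity diagonal must equal 100")
        if v.min() < -1e-8 or v.max() > 100 + 1e-8:
            raise ValidationError("similarities must lie in [0, 100]")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class DescriptorGrouping:
    """Assignment of descriptors to correlated groups.

    ``groups`` maps a group label ("I", "II", ...) to its member
    descriptors in input order; ``similarity`` gives the similarity level
    (%) at which each group is fully merged under the chosen linkage
    (100 for singletons).
    """

    groups: Mapping[str, tuple[str, ...]]
    similarity: Mapping[str, float]
    linkage: str

    def label_of(self, descriptor: str) -> str:
        for lab, members in self.groups.items():
            if descriptor in members:
                return lab
        raise KeyError(descriptor)

    def members(self, label: str) -> tuple[str, ...]:
        return tuple(self.groups[label])

    def as_dict(self) -> dict[str, str]:
        """Flat descriptor -> group-label mapping (JSON-friendly)."""
        return {d: lab for lab, mem in self.groups.items() for d in mem}


def pairwise_similarity(table: pd.DataFrame, columns: Sequence[str]) -> SimilarityMatrix:
    """Pairwise descriptor similarity, 100*(1 + Pearson r)/2 percent.

    Raises :class:`ValidationError` if fewer than two columns are given or
    any column is constant (its correlation is undefined).
    """
    columns = list(columns)
    if len(columns) < 2:
        raise ValidationError("need at least two columns for a similarity matrix")
    X = table[columns].to_numpy(dtype=float)
    sds = X.std(axis=0)
    for name, sd in zip(columns, sds):
        if sd == 0:
            raise ValidationError(f"column {name!r} is constant; correlation undefined")
    r = np.corrcoef(X.T)
    sim = 100.0 * (1.0 + r) / 2.0
    np.fill_diagonal(sim, 100.0)
    sim = np.clip(sim, 0.0, 100.0)
    return SimilarityMatrix(labels=tuple(columns), values=sim)


def cluster_variables(
    sim: SimilarityMatrix,
    n_groups: int = 3,
    linkage: str = "average",
) -> DescriptorGrouping:
    """Agglomerative clustering of descriptors on dissimilarity 100 - S.

    Parameters
    ----------
    sim : SimilarityMatrix
    n_groups : int
        Number of groups to cut the tree into (default 3, the polar /
        size / flexibility structure of the study descriptors).
    linkage : {"average", "single", "complete"}
        Linkage criterion; the study grouping is robust to this choice.

    Returns
    -------
    DescriptorGrouping
        Group labels are roman numerals assigned in order of each
        group's first appearance among the input columns.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    n = len(sim.labels)
    if n < n_groups:
        raise ValidationError(f"cannot form {n_groups} groups from {n} descriptors")
    dissim = 100.0 - sim.values
    np.fill_diagonal(dissim, 0.0)
    Z = hierarchy.linkage(squareform(dissim, checks=False), method=linkage)
    assignment = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")

    groups: dict[str, tuple[str, ...]] = {}
    seen: dict[int, str] = {}
    for label, cl in zip(sim.labels, assignment):
        if cl not in seen:
            seen[cl] = _ROMAN[len(seen)]
        key = seen[cl]
        groups[key] = groups.get(key, ()) + (label,)

    similarity: dict[str, float] = {}
    for key, members in groups.items():
        if len(members) == 1:
            similarity[key] = 100.0
        else:
            idx = [sim.labels.index(m) for m in members]
            sub = dissim[np.ix_(idx, idx)]
            subZ = hierarchy.linkage(squareform(sub, checks=False), method=linkage)
            # height at which the group is fully merged under this linkage
            similarity[key] = float(100.0 - subZ[-1, 2])
    ordered = {k: groups[k] for k in sorted(groups, key=_ROMAN.index)}
    return DescriptorGrouping(groups=ordered, similarity=similarity, linkage=linkage)
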
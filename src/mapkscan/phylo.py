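"""Distance-based grouping utilities: p-distances and neighbor joining.

This is deliberately lightweight plumbing so motif-group summaries can be
driven end to end from sequences alone; it does not attempt to reproduce
maximum-likelihood phylogenies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import skbio

from .evolution import PAIRWISE, pairwise_differences
from .seqio import Alignment


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labeled rows."""

    labels: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "data", d)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.data):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def p_distance_matrix(aln: Alignment, gap_mode: str = PAIRWISE) -> DistanceMatrix:
    """Pairwise p-distances (differences / sites compared).

    A pair with zero comparable sites has no defined distance and raises,
    naming the pair.
    """
    diffs, sites = pairwise_differences(aln, gap_mode)
    m = len(aln)
    d = np.zeros((m, m))
    ids = aln.ids
    for i in range(m):
        for j in range(i + 1, m):
            if sites[i, j] == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = diffs[i, j] / sites[i, j]
    return DistanceMatrix(ids, d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Standard NJ with negative branch lengths clamped to zero; agglomeration
    order (hence tie-breaking) is deterministic in the input label order.
    Requires at least 3 labels.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    sk_dm = skbio.DistanceMatrix(dm.data, ids=list(dm.labels))
    tree = skbio.tree.nj(sk_dm, neg_as_zero=True)
    return str(tree).strip()
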
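"""Neighbor-joining dendrogram from a pairwise distance matrix.

Used on Ka distances of single-copy genes shared across genomes; the NJ
tree on those distances is the in-package surrogate for a full
maximum-likelihood phylogeny.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj


def nj_dendrogram(
    distances: pd.DataFrame | np.ndarray,
    ids: list[str] | None = None,
    *,
    midpoint_root: bool = False,
) -> TreeNode:
    """Neighbor-joining tree with branch lengths from a distance matrix.

    The matrix must be symmetric with a zero diagonal.  Returns a
    scikit-bio ``TreeNode``; serialise with ``str(tree)`` (newick).
    """
    if isinstance(distances, pd.DataFrame):
        ids = [str(c) for c in distances.columns]
        data = distances.to_numpy(dtype=float)
    else:
        data = np.asarray(distances, dtype=float)
        if ids is None:
            ids = [f"t{i}" for i in range(data.shape[0])]
    if data.ndim != 2 or data.shape[0] != data.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(np.diag(data), 0.0):
        raise ValueError("distance matrix diagonal must be zero")
    if not np.allclose(data, data.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 taxa")
    tree = nj(DistanceMatrix(data, ids))
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return tree
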
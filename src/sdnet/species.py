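"""Cross-species comparison of SD-network component spectra.

Species are compared through the Bray–Curtis dissimilarity between their
sorted top-N connected-component size vectors, followed by agglomerative
hierarchical clustering of the dissimilarity matrix.  The per-species
network summary (node/edge counts, intrachromosomal and tandem edge
fractions, regression f) reuses the construction, topology and inference
modules on each species' alignment table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .inference import bray_curtis, estimate_f_regression, spectrum_vector
from .network import build_network_from_table
from .topology import component_spectrum, edge_class_fractions

__all__ = [
    "spectrum_dissimilarity_matrix",
    "cluster_species",
    "summarize_network",
    "species_summary_table",
    "plot_similarity_heatmap",
]


def spectrum_dissimilarity_matrix(spectra: dict, top_n=500) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between species component-size
    vectors (sorted descending, zero-padded/truncated to ``top_n``)."""
    if len(spectra) < 2:
        raise ValueError("need at least 2 species")
    names = list(spectra)
    vectors = {}
    for name, sizes in spectra.items():
        sizes = np.asarray(sizes)
        if sizes.size == 0:
            raise ValueError(f"empty spectrum for {name!r}")
        vectors[name] = spectrum_vector(sizes, top_n=top_n)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = bray_curtis(vectors[a], vectors[b])
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def cluster_species(matrix: pd.DataFrame, linkage="average"):
    """Hierarchical clustering of the dissimilarity matrix.

    Returns ``(linkage_matrix, leaf_order, newick)`` where ``leaf_order``
    is the species ordering of the dendrogram (usable to sort a heatmap)
    and ``newick`` a string export of the tree with branch lengths.
    """
    names = list(matrix.index)
    condensed = squareform(matrix.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = [names[i] for i in hierarchy.leaves_list(Z)]
    from skbio.tree import TreeNode
    tree = TreeNode.from_linkage_matrix(Z, names)
    newick = str(tree).strip()
    return Z, order, newick


def plot_similarity_heatmap(matrix: pd.DataFrame, linkage="average",
                            ax=None):
    """Heatmap of similarities (1 − dissimilarity) ordered by the
    dendrogram leaves."""
    import matplotlib
    if ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    _, order, _ = cluster_species(matrix, linkage=linkage)
    sim = 1.0 - matrix.loc[order, order]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(sim.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90)
    ax.set_yticks(range(len(order)), order)
    ax.figure.colorbar(im, ax=ax, label="1 - Bray-Curtis dissimilarity")
    return ax


def summarize_network(net, tandem_dist=500_000) -> dict:
    """Per-network summary statistics for cross-species tables."""
    spec = component_spectrum(net)
    intra, tandem = edge_class_fractions(net, tandem_dist=tandem_dist)
    try:
        f_hat, f_se = estimate_f_regression(spec.mean_edges_by_size())
    except ValueError:  # fewer than 3 distinct component sizes
        f_hat = f_se = float("nan")
    return {
        "n_nodes": spec.n_nodes,
        "n_edges": spec.n_edges,
        "n_components": spec.n_components,
        "intra_fraction": intra,
        "tandem_fraction": tandem,
        "f_regression": f_hat,
        "f_regression_stderr": f_se,
    }


def species_summary_table(tables: dict, dialect="sedef",
                          **build_kwargs) -> pd.DataFrame:
    """Build one SD network per species table and summarize each."""
    rows = {}
    for name, path in tables.items():
        net = build_network_from_table(path, dialect=dialect, **build_kwargs)
        rows[name] = summarize_network(net)
    return pd.DataFrame(rows).T
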
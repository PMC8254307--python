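"""Random-forest model of duplicated-region length.

The length of a duplicated region is regressed on characteristics of its
node in the *untrimmed* SD network: node degree, connected-component size,
mean copy number, fraction of intrachromosomal edges, number of self-loop
alignments and number of double (parallel) alignments.  Feature relevance
is assessed with permutation-based importances turned into empirical
p-values by refitting the forest on response vectors shuffled N_p times:

    p[i] = (1/N_p) Σ_j I( imp_j^shuffled[i] > imp^real[i] )

so a feature is significant when its real importance is rarely exceeded
under the null of no association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold, cross_val_score, train_test_split

__all__ = [
    "FEATURE_COLUMNS",
    "extract_region_features",
    "fit_length_model",
    "permutation_importance_pvalues",
]

FEATURE_COLUMNS = [
    "degree", "component_size", "mean_copy_number", "intra_fraction",
    "self_loops", "double_edges",
]
RESPONSE_COLUMN = "length"


def extract_region_features(net, copy_number=None) -> pd.DataFrame:
    """Per-region feature table from an :class:`sdnet.network.SDNetwork`.

    ``copy_number`` maps region id → mean copy number (an external track);
    if missing the column is filled with NaN and excluded downstream with a
    warning.  The double-edge count of a node is Σ over neighbors of
    (alignment multiplicity − 1); self-loops and double edges come from the
    untrimmed view.
    """
    g = net.graph
    comp_size = {}
    for comp in nx.connected_components(g):
        for node in comp:
            comp_size[node] = len(comp)
    rows = []
    for r in net.regions:
        node = r.region_id
        degree = g.degree[node]
        intra = sum(1 for nbr in g.neighbors(node)
                    if g.nodes[nbr]["chrom"] == r.chrom)
        rows.append({
            "region_id": node,
            "degree": degree,
            "component_size": comp_size[node],
            "mean_copy_number": (copy_number or {}).get(node, np.nan),
            "intra_fraction": intra / degree if degree else 0.0,
            "self_loops": net.self_loop_count(node),
            "double_edges": net.double_edge_count(node),
            RESPONSE_COLUMN: r.length,
        })
    df = pd.DataFrame(rows).set_index("region_id")
    if copy_number is None:
        warnings.warn("no copy-number track supplied; the mean_copy_number "
                      "feature is missing and will be excluded")
    return df


def _design(features: pd.DataFrame):
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    usable = [c for c in cols if not features[c].isna().all()]
    dropped = sorted(set(cols) - set(usable))
    if dropped:
        warnings.warn(f"excluding all-missing features: {dropped}")
    X = features[usable].to_numpy(dtype=float)
    y = features[RESPONSE_COLUMN].to_numpy(dtype=float)
    return X, y, usable


def fit_length_model(features: pd.DataFrame, n_folds=10, seed=0,
                     n_estimators=500) -> float:
    """Out-of-fold R² of a random-forest regression of region length,
    averaged over ``n_folds`` cross-validation folds."""
    X, y, _ = _design(features)
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} rows")
    if np.allclose(y, y[0]):
        raise ValueError("constant response")
    model = RandomForestRegressor(n_estimators=n_estimators,
                                  random_state=seed, n_jobs=1)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(model, X, y, cv=cv, scoring="r2")
    return float(scores.mean())


def _heldout_importances(X, y, seed, n_estimators, n_repeats):
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=seed)
    model = RandomForestRegressor(n_estimators=n_estimators,
                                  random_state=seed, n_jobs=1)
    model.fit(X_tr, y_tr)
    imp = permutation_importance(model, X_te, y_te, n_repeats=n_repeats,
                                 random_state=seed, n_jobs=1)
    return imp.importances_mean


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # feature, importance, pvalue
    n_perm: int
    alpha: float

    def significant(self):
        return list(self.table.loc[self.table.pvalue < self.alpha, "feature"])


def permutation_importance_pvalues(features: pd.DataFrame, n_perm=1000,
                                   seed=0, n_estimators=500, n_repeats=5,
                                   alpha=0.01) -> ImportanceResult:
    """Per-feature permutation importances with shuffled-response p-values.

    The real importance vector comes from a forest fit on 70% of the rows
    with mean-decrease-in-accuracy permutation importance measured on the
    held-out 30%.  The response is then shuffled ``n_perm`` times, the whole
    procedure repeated and the empirical p-value of each feature computed
    as the fraction of shuffles whose importance exceeds the real one.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution")
    X, y, names = _design(features)
    rng = np.random.default_rng(seed)
    real = _heldout_importances(X, y, seed, n_estimators, n_repeats)
    exceed = np.zeros(len(names))
    for j in range(n_perm):
        y_perm = rng.permutation(y)
        perm = _heldout_importances(X, y_perm, seed, n_estimators, n_repeats)
        exceed += perm > real
    pvals = exceed / n_perm
    table = pd.DataFrame({"feature": names, "importance": real,
                          "pvalue": pvals})
    return ImportanceResult(table=table, n_perm=n_perm, alpha=alpha)
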
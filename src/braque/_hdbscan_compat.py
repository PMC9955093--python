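"""Cluster extraction from an HDBSCAN single-linkage tree.

scikit-learn 1.9's compiled HDBSCAN label extraction crashes when
``cluster_selection_epsilon > 0`` actually triggers an upward merge under
NumPy 2.x (a length-1 array is assigned to a C scalar inside
``traverse_upwards``).  Because the epsilon threshold is part of this
pipeline's default clustering policy, this module re-implements the
extraction step — stability computation, eom/leaf selection and the
epsilon search — in plain NumPy on top of scikit-learn's compiled
``_condense_tree`` and ``_do_labelling``, which are unaffected.  The
algorithm mirrors the library's semantics exactly; with epsilon 0 it
reproduces the stock estimator's labels bit-for-bit (asserted in tests).
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster._hdbscan._tree import (  # compiled, Python-callable
    _condense_tree,
    _do_labelling,
    get_cluster_tree_leaves,
)

__all__ = ["extract_labels"]


def _compute_stability(condensed: np.ndarray) -> dict[int, float]:
    """Cluster stability Σ_p (λ_p − λ_birth) over the condensed tree."""
    parents = condensed["parent"]
    smallest = int(parents.min())
    largest_child = max(int(condensed["child"].max()), smallest)
    births = np.full(largest_child + 1, np.nan)
    births[condensed["child"]] = condensed["value"]
    births[smallest] = 0.0
    num = int(parents.max()) - smallest + 1
    result = np.zeros(num)
    np.add.at(
        result,
        parents - smallest,
        (condensed["value"] - births[parents]) * condensed["cluster_size"],
    )
    return {smallest + i: float(result[i]) for i in range(num)}


def _bfs_from_cluster_tree(cluster_tree: np.ndarray, root: int) -> list[int]:
    result: list[int] = []
    queue = np.array([root], dtype=np.intp)
    children = cluster_tree["child"]
    parents = cluster_tree["parent"]
    while len(queue):
        result.extend(queue.tolist())
        queue = children[np.isin(parents, queue)]
    return result


def _traverse_upwards(
    cluster_tree: np.ndarray, epsilon: float, leaf: int, allow_single_cluster: bool
) -> int:
    root = int(cluster_tree["parent"].min())
    while True:
        sel = cluster_tree["child"] == leaf
        parent = int(cluster_tree["parent"][sel][0])
        if parent == root:
            return parent if allow_single_cluster else leaf
        parent_eps = 1.0 / float(
            cluster_tree["value"][cluster_tree["child"] == parent][0]
        )
        if parent_eps > epsilon:
            return parent
        leaf = parent


def _epsilon_search(
    leaves: set[int],
    cluster_tree: np.ndarray,
    epsilon: float,
    allow_single_cluster: bool,
) -> set[int]:
    selected: list[int] = []
    processed: set[int] = set()
    children = cluster_tree["child"]
    distances = cluster_tree["value"]
    for leaf in leaves:
        eps = 1.0 / float(distances[children == leaf][0])
        if eps < epsilon:
            if leaf not in processed:
                chosen = _traverse_upwards(
                    cluster_tree, epsilon, leaf, allow_single_cluster
                )
                selected.append(chosen)
                processed.update(
                    n for n in _bfs_from_cluster_tree(cluster_tree, chosen)
                    if n != chosen
                )
        else:
            selected.append(leaf)
    return set(selected)


def extract_labels(
    single_linkage_tree: np.ndarray,
    min_cluster_size: int,
    method: str = "eom",
    epsilon: float = 0.0,
    allow_single_cluster: bool = False,
    max_cluster_size: int | None = None,
) -> np.ndarray:
    """Flat cluster labels (−1 = noise) from a single-linkage tree."""
    condensed = _condense_tree(single_linkage_tree, min_cluster_size)
    stability = _compute_stability(condensed)

    node_list = sorted(stability.keys(), reverse=True)
    if not allow_single_cluster:
        node_list = node_list[:-1]  # exclude root
    cluster_tree = np.ascontiguousarray(condensed[condensed["cluster_size"] > 1])
    is_cluster = {c: True for c in node_list}
    n_samples = int(condensed["child"][condensed["cluster_size"] == 1].max()) + 1
    if max_cluster_size is None:
        max_cluster_size = n_samples + 1
    cluster_sizes = dict(
        zip(cluster_tree["child"].tolist(), cluster_tree["cluster_size"].tolist())
    )
    if allow_single_cluster and node_list:
        cluster_sizes[node_list[-1]] = int(
            cluster_tree["cluster_size"][
                cluster_tree["parent"] == node_list[-1]
            ].sum()
        )

    if method == "eom":
        for node in node_list:
            children = cluster_tree["child"][cluster_tree["parent"] == node]
            subtree_stability = float(
                np.sum([stability[c] for c in children.tolist()])
            )
            if (
                subtree_stability > stability[node]
                or cluster_sizes[node] > max_cluster_size
            ):
                is_cluster[node] = False
                stability[node] = subtree_stability
            else:
                for sub in _bfs_from_cluster_tree(cluster_tree, node):
                    if sub != node:
                        is_cluster[sub] = False
        if epsilon != 0.0 and cluster_tree.shape[0] > 0:
            eom_clusters = [c for c in is_cluster if is_cluster[c]]
            selected: set[int] = set()
            root = int(cluster_tree["parent"].min())
            if len(eom_clusters) == 1 and eom_clusters[0] == root:
                if allow_single_cluster:
                    selected = set(eom_clusters)
            else:
                selected = _epsilon_search(
                    set(eom_clusters), cluster_tree, epsilon, allow_single_cluster
                )
            for c in is_cluster:
                is_cluster[c] = c in selected
    elif method == "leaf":
        leaves = set(get_cluster_tree_leaves(cluster_tree))
        if not leaves:
            for c in is_cluster:
                is_cluster[c] = False
            is_cluster[int(condensed["parent"].min())] = True
        if epsilon != 0.0:
            selected = _epsilon_search(
                leaves, cluster_tree, epsilon, allow_single_cluster
            )
        else:
            selected = leaves
        for c in is_cluster:
            is_cluster[c] = c in selected
    else:
        raise ValueError(f"unknown cluster selection method {method!r}")

    clusters = {c for c, flag in is_cluster.items() if flag}
    cluster_map = {c: n for n, c in enumerate(sorted(clusters))}
    return np.asarray(
        _do_labelling(
            condensed, clusters, cluster_map, int(allow_single_cluster), epsilon
        )
    )
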
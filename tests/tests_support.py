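"""Shared independent oracles and helpers for the test suite."""

import itertools

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode


def random_rotation(rng):
    """Uniform random rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def grid_search_rmsd(P, Q, step_deg=9.0):
    """Coarse exhaustive rotation search: oracle for the Kabsch optimum."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    best = np.inf
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    betas = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, step_deg))
    for alpha in angles:
        ca, sa = np.cos(alpha), np.sin(alpha)
        Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
        for beta in betas:
            cb, sb = np.cos(beta), np.sin(beta)
            Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            for gamma in angles:
                cg, sg = np.cos(gamma), np.sin(gamma)
                Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
                R = Rz1 @ Ry @ Rz2
                rmsd = np.sqrt(np.mean(np.sum((Q0 @ R.T - P0) ** 2, axis=1)))
                best = min(best, rmsd)
    return best


def random_additive_tree(rng, n_taxa):
    """A random binary tree with random branch lengths and its leaf metric."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    names = [f"t{i}" for i in range(n_taxa)]
    dm = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(names, 2):
        d = root.find(a).distance(root.find(b))
        i, j = names.index(a), names.index(b)
        dm[i, j] = dm[j, i] = d
    return root, DistanceMatrix(dm, ids=names)


def tip_distances(tree):
    names = sorted(t.name for t in tree.tips())
    out = {}
    for a, b in itertools.combinations(names, 2):
        out[(a, b)] = tree.find(a).distance(tree.find(b))
    return out
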
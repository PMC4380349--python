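"""Independent brute-force oracles used to check the implementation.

Everything here deliberately avoids the code paths it verifies:
posteriors come from materializing the full joint array, tree search
enumerates every labeled spanning tree via Prüfer sequences, CMI is a
literal triple loop over states, and AUC is a concordant-pair count.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from tanfv.schema import CohortTable, VariableSpec
from tanfv.tan import ParameterizedTAN, TanStructure


def full_joint(model: ParameterizedTAN) -> np.ndarray:
    """Materialize P(S, V1, ..., Vp) as a dense array (class axis first)."""
    s = model.structure
    attrs = list(s.attributes)
    axis = {a: i + 1 for i, a in enumerate(attrs)}
    shape = [len(model.class_states)] + [model.n_states(a) for a in attrs]
    ndim = len(shape)
    joint = np.array(model.class_prior, float).reshape([shape[0]] + [1] * (ndim - 1))
    for a in attrs:
        cpt = np.asarray(model.cpts[a])  # (ks, ku, k)
        pa = s.parent[a]
        sh = [1] * ndim
        sh[0] = cpt.shape[0]
        if pa is None:
            arr, sh[axis[a]] = cpt[:, 0, :], cpt.shape[2]
        elif axis[pa] < axis[a]:
            arr, sh[axis[pa]], sh[axis[a]] = cpt, cpt.shape[1], cpt.shape[2]
        else:
            arr = cpt.transpose(0, 2, 1)
            sh[axis[a]], sh[axis[pa]] = cpt.shape[2], cpt.shape[1]
        joint = joint * arr.reshape(sh)
    return joint


def enumeration_posterior(
    model: ParameterizedTAN, query: str, evidence: dict[str, int]
) -> np.ndarray:
    """Posterior of *query* by slicing and summing the full joint."""
    s = model.structure
    names = [s.class_name] + list(s.attributes)
    joint = full_joint(model)
    idx: list[object] = [slice(None)] * joint.ndim
    for name, code in evidence.items():
        idx[names.index(name)] = code
    sub = joint[tuple(idx)]
    keep = [n for n in names if n not in evidence]
    q_axis = keep.index(query)
    marg = sub.sum(axis=tuple(i for i in range(sub.ndim) if i != q_axis))
    return marg / marg.sum()


def all_spanning_trees(n: int):
    """Every labeled tree on nodes 0..n-1, as frozen undirected edge sets
    (via Prüfer sequences; n**(n-2) trees)."""
    import heapq

    if n == 2:
        yield frozenset({(0, 1)})
        return
    for seq in product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        edges = []
        for v in seq:
            leaf = heapq.heappop(heap)
            edges.append((min(leaf, v), max(leaf, v)))
            degree[v] -= 1
            if degree[v] == 1:
                heapq.heappush(heap, v)
        u, w = heapq.heappop(heap), heapq.heappop(heap)
        edges.append((min(u, w), max(u, w)))
        yield frozenset(edges)


def cmi_triple_loop(x: np.ndarray, y: np.ndarray, s: np.ndarray) -> float:
    """I(X;Y|S) in bits by literal summation over all state triples."""
    n = len(x)
    total = 0.0
    for xv in np.unique(x):
        for yv in np.unique(y):
            for sv in np.unique(s):
                n_xys = np.sum((x == xv) & (y == yv) & (s == sv))
                if n_xys == 0:
                    continue
                n_s = np.sum(s == sv)
                n_xs = np.sum((x == xv) & (s == sv))
                n_ys = np.sum((y == yv) & (s == sv))
                p_xys = n_xys / n
                total += p_xys * np.log2((n_xys * n_s) / (n_xs * n_ys))
    return total


def concordance_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the concordant-pair probability, ties counted one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_model(
    rng: np.random.Generator,
    n_attrs: int,
    max_states: int = 3,
    n_class_states: int = 2,
) -> ParameterizedTAN:
    """A random TAN over ``n_attrs`` attributes with Dirichlet CPTs and a
    random tree (each non-root attribute parented by an earlier one)."""
    names = [f"x{i}" for i in range(n_attrs)]
    k = {a: int(rng.integers(2, max_states + 1)) for a in names}
    parent: dict[str, str | None] = {names[0]: None}
    for i in range(1, n_attrs):
        parent[names[i]] = names[int(rng.integers(0, i))] if rng.random() < 0.8 else None
    structure = TanStructure("c", tuple(names), parent)
    cpts = {}
    for a in names:
        ku = 1 if parent[a] is None else k[parent[a]]
        cpts[a] = rng.dirichlet(np.ones(k[a]), size=(n_class_states, ku))
    return ParameterizedTAN(
        structure=structure,
        class_states=tuple(str(j) for j in range(n_class_states)),
        attr_states={a: tuple(str(j) for j in range(k[a])) for a in names},
        class_prior=rng.dirichlet(np.ones(n_class_states)),
        cpts=cpts,
    )


def random_table(
    rng: np.random.Generator, n_records: int, n_attrs: int, max_states: int = 3
) -> CohortTable:
    """A uniformly random coded cohort (attributes plus binary class)."""
    import pandas as pd

    schema = [
        VariableSpec(f"x{i}", tuple(str(j) for j in range(int(rng.integers(2, max_states + 1)))))
        for i in range(n_attrs)
    ]
    schema.append(VariableSpec("c", ("0", "1"), role="class"))
    data = {
        v.name: rng.integers(0, v.n_states, size=n_records) for v in schema
    }
    return CohortTable(schema, pd.DataFrame(data))
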
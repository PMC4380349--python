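"""Tree-augmented naive Bayes (TAN) structure and parameter learning.

A TAN classifier augments naive Bayes with a tree over the attributes:
the class S is a parent of every attribute, and in addition the
attributes form a directed tree (each attribute has at most one attribute
parent).  The tree is the maximum-weight spanning tree under
class-conditional mutual information I(X; Y | S), estimated from the
empirical frequencies of the training cohort — the Chow-Liu construction
conditioned on the class.  Conditional probability tables are estimated
by (optionally smoothed) relative frequencies.

At the maximum-likelihood fit (smoothing ``alpha=0``) the model
reproduces every pairwise empirical marginal P(S, Vi) and every tree-edge
triple marginal P(S, Vi, parent(Vi)) exactly; single-attribute posteriors
P(S | Vi = j) therefore equal empirical conditional class frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .schema import CohortTable

__all__ = [
    "TanStructure",
    "ParameterizedTAN",
    "conditional_mutual_information",
    "learn_tan_structure",
    "estimate_cpts",
    "fit_tan",
    "TanClassifier",
]


@dataclass(frozen=True)
class TanStructure:
    """Class node plus a directed tree (or forest) over the attributes.

    ``parent[a]`` is the attribute parent of ``a``, or ``None`` for a
    root.  The class is implicitly a parent of every attribute.  A strict
    TAN has exactly one root and ``n_attributes - 1`` edges; CMI-threshold
    pruning may leave a forest with several roots.
    """

    class_name: str
    attributes: tuple[str, ...]
    parent: Mapping[str, str | None]

    def __post_init__(self) -> None:
        if set(self.parent) != set(self.attributes):
            raise ValueError("parent map must cover exactly the attributes")
        # reject cycles / non-tree shapes by walking up from every node
        for a in self.attributes:
            seen = {a}
            p = self.parent[a]
            while p is not None:
                if p in seen:
                    raise ValueError(f"cycle through {p!r}")
                seen.add(p)
                p = self.parent[p]

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(a for a in self.attributes if self.parent[a] is None)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        """Directed (parent, child) attribute edges."""
        return tuple(
            (p, a) for a in self.attributes if (p := self.parent[a]) is not None
        )

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(a for a in self.attributes if self.parent[a] == name)


@dataclass
class ParameterizedTAN:
    """A TAN structure with its class prior and per-attribute CPTs.

    ``cpts[a]`` has shape ``(n_class_states, n_parent_states, n_states(a))``
    and is normalized over its last axis; attributes without an attribute
    parent use a singleton parent axis.
    """

    structure: TanStructure
    class_states: tuple[str, ...]
    attr_states: Mapping[str, tuple[str, ...]]
    class_prior: np.ndarray
    cpts: Mapping[str, np.ndarray]
    alpha: float = 0.0

    def __post_init__(self) -> None:
        self.class_prior = np.asarray(self.class_prior, dtype=float)
        if abs(self.class_prior.sum() - 1.0) > 1e-9:
            raise ValueError("class prior must sum to 1")
        for a in self.structure.attributes:
            t = np.asarray(self.cpts[a], dtype=float)
            if t.ndim != 3:
                raise ValueError(f"CPT for {a!r} must be 3-dimensional")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT for {a!r} has columns not summing to 1")

    def n_states(self, name: str) -> int:
        if name == self.structure.class_name:
            return len(self.class_states)
        return len(self.attr_states[name])

    # -- JSON serialization (bit-exact round trip) --------------------------

    def to_json(self) -> str:
        s = self.structure
        doc = {
            "class": {"name": s.class_name, "states": list(self.class_states)},
            "attributes": [
                {
                    "name": a,
                    "states": list(self.attr_states[a]),
                    "parent": s.parent[a],
                }
                for a in s.attributes
            ],
            "class_prior": self.class_prior.tolist(),
            "cpts": {a: np.asarray(self.cpts[a]).tolist() for a in s.attributes},
            "alpha": self.alpha,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParameterizedTAN":
        doc = json.loads(text)
        attrs = tuple(d["name"] for d in doc["attributes"])
        structure = TanStructure(
            class_name=doc["class"]["name"],
            attributes=attrs,
            parent={d["name"]: d["parent"] for d in doc["attributes"]},
        )
        return cls(
            structure=structure,
            class_states=tuple(doc["class"]["states"]),
            attr_states={d["name"]: tuple(d["states"]) for d in doc["attributes"]},
            class_prior=np.array(doc["class_prior"], dtype=float),
            cpts={a: np.array(doc["cpts"][a], dtype=float) for a in attrs},
            alpha=float(doc["alpha"]),
        )


def _joint_counts(x: np.ndarray, kx: int, y: np.ndarray, ky: int,
                  s: np.ndarray, ks: int) -> np.ndarray:
    flat = (x * ky + y) * ks + s
    return np.bincount(flat, minlength=kx * ky * ks).reshape(kx, ky, ks).astype(float)


def conditional_mutual_information(
    x: str, y: str, table: CohortTable
) -> float:
    """Empirical class-conditional mutual information I(X; Y | S), in bits.

    Computed as sum over (x, y, s) of p(x,y,s) log2[ p(x,y|s) /
    (p(x|s) p(y|s)) ] with 0 log 0 = 0.  Always nonnegative up to float
    rounding; 0 for degenerate (effectively single-state) variables.
    """
    if x == y:
        raise ValueError("x and y must differ")
    sx, sy = table.spec(x), table.spec(y)
    cls = table.class_var
    n = table.n_records
    if n == 0:
        raise ValueError("empty table")
    cnt = _joint_counts(
        table.data[x].to_numpy(), sx.n_states,
        table.data[y].to_numpy(), sy.n_states,
        table.data[cls.name].to_numpy(), cls.n_states,
    )
    p_xys = cnt / n
    p_s = p_xys.sum(axis=(0, 1))
    p_xs = p_xys.sum(axis=1)  # (kx, ks)
    p_ys = p_xys.sum(axis=0)  # (ky, ks)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p_xys * p_s[None, None, :] / (
            p_xs[:, None, :] * p_ys[None, :, :]
        )
        terms = np.where(p_xys > 0, p_xys * np.log2(ratio), 0.0)
    return float(max(terms.sum(), 0.0))


def _kruskal_max_tree(
    attrs: Sequence[str], weights: Mapping[tuple[str, str], float]
) -> list[tuple[str, str]]:
    """Maximum spanning tree, deterministic: edges sorted by weight
    descending then by name pair ascending, added greedily."""
    order = sorted(weights, key=lambda e: (-weights[e], e))
    parent = {a: a for a in attrs}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    chosen = []
    for u, v in order:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            chosen.append((u, v))
    return chosen


def learn_tan_structure(
    table: CohortTable, cmi_threshold: float | None = None
) -> TanStructure:
    """Learn the TAN attribute tree from a cohort.

    Builds the maximum-weight spanning tree over the attributes with
    class-conditional mutual information edge weights, then directs edges
    away from the root (the first attribute in schema order).  With
    ``cmi_threshold`` set, edges whose CMI does not exceed the threshold
    are dropped, leaving a forest: attributes whose every association is
    weak fall back to plain naive-Bayes children of the class.
    """
    attrs = [v.name for v in table.attributes]
    if len(attrs) < 2:
        raise ValueError("need at least 2 attributes")
    if table.n_records == 0:
        raise ValueError("empty table")
    weights = {
        tuple(sorted((a, b))): conditional_mutual_information(a, b, table)
        for a, b in combinations(attrs, 2)
    }
    chosen = _kruskal_max_tree(attrs, weights)
    if cmi_threshold is not None:
        chosen = [e for e in chosen if weights[e] > cmi_threshold]

    # direct away from the schema-order root of each connected component
    adj: dict[str, list[str]] = {a: [] for a in attrs}
    for u, v in chosen:
        adj[u].append(v)
        adj[v].append(u)
    parent: dict[str, str | None] = {}
    for a in attrs:  # schema order: first unvisited node roots its component
        if a in parent:
            continue
        parent[a] = None
        stack = [a]
        while stack:
            node = stack.pop()
            for nb in sorted(adj[node]):
                if nb not in parent:
                    parent[nb] = node
                    stack.append(nb)
    return TanStructure(table.class_var.name, tuple(attrs), parent)


def estimate_cpts(
    structure: TanStructure, table: CohortTable, alpha: float = 0.0
) -> ParameterizedTAN:
    """Estimate the class prior and all CPTs by smoothed frequencies.

    P(Vi=v | S=s, pa=u) = (count(v,s,u) + alpha) / (count(s,u) + alpha K)
    with K the number of states of Vi; ``alpha=0`` is the maximum-
    likelihood fit.  An unobserved (s, u) context at ``alpha=0`` gets a
    uniform distribution (with a warning).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    cls = table.class_var
    s_codes = table.data[cls.name].to_numpy()
    ks = cls.n_states
    n = table.n_records
    if n == 0:
        raise ValueError("empty table")
    prior = (np.bincount(s_codes, minlength=ks) + alpha) / (n + alpha * ks)

    cpts: dict[str, np.ndarray] = {}
    attr_states: dict[str, tuple[str, ...]] = {}
    for a in structure.attributes:
        spec = table.spec(a)
        attr_states[a] = spec.states
        k = spec.n_states
        pa = structure.parent[a]
        if pa is None:
            ku = 1
            u_codes = np.zeros(n, dtype=int)
        else:
            ku = table.spec(pa).n_states
            u_codes = table.data[pa].to_numpy()
        cnt = _joint_counts(s_codes, ks, u_codes, ku, table.data[a].to_numpy(), k)
        ctx = cnt.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore"):
            t = (cnt + alpha) / (ctx + alpha * k)
        empty = (ctx[..., 0] == 0)
        if alpha == 0 and empty.any():
            warnings.warn(
                f"attribute {a!r}: {int(empty.sum())} unobserved parent "
                "context(s) at alpha=0; using uniform distribution",
                stacklevel=2,
            )
            t[empty] = 1.0 / k
        cpts[a] = t
    return ParameterizedTAN(
        structure=structure,
        class_states=cls.states,
        attr_states=attr_states,
        class_prior=prior,
        cpts=cpts,
        alpha=alpha,
    )


def fit_tan(
    table: CohortTable, alpha: float = 0.0, cmi_threshold: float | None = None
) -> ParameterizedTAN:
    """Learn structure and parameters in one step."""
    return estimate_cpts(learn_tan_structure(table, cmi_threshold), table, alpha)


class TanClassifier(ClassifierMixin, BaseEstimator):
    """Tree-augmented naive Bayes classifier for discrete coded features.

    scikit-learn compatible: ``fit(X, y)`` on integer state codes,
    ``predict_proba`` by exact inference on the learned network,
    ``predict`` by thresholding the positive-class probability.

    Parameters
    ----------
    alpha : float, default 0.0
        Additive CPT smoothing; 0 is the maximum-likelihood fit.
    threshold : float, default 0.5
        A record is labeled with the positive class iff its positive-class
        probability strictly exceeds the threshold.
    positive_index : int, default 1
        Index into ``classes_`` of the positive class.
    cmi_threshold : float or None
        Optional pruning of weak tree edges (see
        :func:`learn_tan_structure`).

    Attributes
    ----------
    classes_ : ndarray
        Sorted class values seen in ``y``.
    model_ : ParameterizedTAN
        The fitted network.
    structure_ : TanStructure
        Its attribute tree.
    feature_names_in_ : ndarray of str
        Column names (from a DataFrame, else ``x0..x{p-1}``).
    """

    def __init__(
        self,
        alpha: float = 0.0,
        threshold: float = 0.5,
        positive_index: int = 1,
        cmi_threshold: float | None = None,
    ) -> None:
        self.alpha = alpha
        self.threshold = threshold
        self.positive_index = positive_index
        self.cmi_threshold = cmi_threshold

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        return pd.DataFrame(X, columns=list(names))

    def fit(self, X, y) -> "TanClassifier":
        from .schema import VariableSpec  # deferred; avoids cycle at import

        Xf = self._as_frame(X)
        y = np.asarray(y)
        if len(Xf) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes in y")
        y_codes = np.searchsorted(self.classes_, y)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        self.n_features_in_ = Xf.shape[1]

        schema = [
            VariableSpec(
                name=str(c),
                states=tuple(str(j) for j in range(int(Xf[c].max()) + 1)),
            )
            for c in Xf.columns
        ]
        schema.append(
            VariableSpec(
                name="__class__",
                states=tuple(str(c) for c in self.classes_),
                role="class",
            )
        )
        data = Xf.copy()
        data.columns = [str(c) for c in Xf.columns]
        data["__class__"] = y_codes
        table = CohortTable(schema, data)
        self.model_ = fit_tan(table, alpha=self.alpha, cmi_threshold=self.cmi_threshold)
        self.structure_ = self.model_.structure
        return self

    def predict_proba(self, X) -> np.ndarray:
        from .inference import posterior

        check_is_fitted(self, "model_")
        Xf = self._as_frame(X)
        out = np.empty((len(Xf), len(self.classes_)))
        cols = [str(c) for c in Xf.columns]
        for i, row in enumerate(Xf.to_numpy()):
            ev = dict(zip(cols, (int(v) for v in row)))
            out[i] = posterior(self.model_, "__class__", ev).probabilities
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, self.positive_index]
        labels = np.where(
            proba > self.threshold,
            self.classes_[self.positive_index],
            self.classes_[1 - self.positive_index],
        )
        return labels
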
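"""Exact probabilistic queries on a parameterized TAN.

Because the attributes form a tree (or forest) given the class, the
likelihood of any partial evidence factorizes per class state and is
computed by a single upward message pass over each tree component —
equivalent to, and tested against, brute-force summation of the full
joint over all unobserved variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tan import ParameterizedTAN

__all__ = [
    "Evidence",
    "PosteriorDistribution",
    "ZeroProbabilityEvidenceError",
    "joint_probability",
    "posterior",
    "classify",
    "scenario_query",
]

Evidence = dict[str, int]


class ZeroProbabilityEvidenceError(ValueError):
    """The supplied evidence has probability zero under the model."""


@dataclass(frozen=True)
class PosteriorDistribution:
    """Exact posterior of one variable: P(variable = j | evidence)."""

    variable: str
    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be a probability distribution")
        object.__setattr__(self, "probabilities", p)

    def __getitem__(self, state: int) -> float:
        return float(self.probabilities[state])


def _check_evidence(model: ParameterizedTAN, evidence: Evidence) -> None:
    s = model.structure
    for name, code in evidence.items():
        if name != s.class_name and name not in s.parent:
            raise ValueError(f"unknown variable {name!r}")
        if not 0 <= int(code) < model.n_states(name):
            raise ValueError(f"invalid state {code} for variable {name!r}")


def _class_likelihoods(model: ParameterizedTAN, evidence: Evidence) -> np.ndarray:
    """P(attribute evidence | S = s) for every class state s."""
    s = model.structure
    ks = len(model.class_states)

    def message(node: str) -> np.ndarray:
        # returns array over (class_state, parent_state): the summed-out
        # contribution of node's subtree given its attribute parent's value
        t = np.asarray(model.cpts[node])  # (ks, ku, k)
        if node in evidence:
            mask = np.zeros(t.shape[-1])
            mask[int(evidence[node])] = 1.0
        else:
            mask = np.ones(t.shape[-1])
        inner = t * mask  # (ks, ku, k)
        for child in s.children(node):
            inner = inner * message(child)[:, None, :]
        return inner.sum(axis=-1)  # (ks, ku)

    lik = np.ones(ks)
    for root in s.roots:
        lik = lik * message(root)[:, 0]
    return lik


def joint_probability(model: ParameterizedTAN, assignment: Evidence) -> float:
    """Probability of one complete assignment (class and every attribute):
    the product of the class prior entry and all CPT entries."""
    s = model.structure
    needed = set(s.attributes) | {s.class_name}
    if set(assignment) != needed:
        missing = sorted(needed - set(assignment))
        raise ValueError(
            f"assignment must cover class and all attributes (missing {missing}); "
            "use posterior() for partial evidence"
        )
    _check_evidence(model, assignment)
    sc = int(assignment[s.class_name])
    p = float(model.class_prior[sc])
    for a in s.attributes:
        pa = s.parent[a]
        u = 0 if pa is None else int(assignment[pa])
        p *= float(np.asarray(model.cpts[a])[sc, u, int(assignment[a])])
    return p


def posterior(
    model: ParameterizedTAN, query: str, evidence: Evidence | None = None
) -> PosteriorDistribution:
    """Exact posterior of *query* given partial *evidence*.

    Sums the joint over all unobserved variables using the tree
    factorization.  Raises :class:`ZeroProbabilityEvidenceError` when the
    evidence itself has probability zero.
    """
    evidence = dict(evidence or {})
    if query in evidence:
        raise ValueError(f"query variable {query!r} is already in the evidence")
    _check_evidence(model, evidence)
    _check_evidence(model, {query: 0})
    s = model.structure

    class_ev = evidence.pop(s.class_name, None)
    prior = model.class_prior.copy()
    if class_ev is not None:
        mask = np.zeros_like(prior)
        mask[int(class_ev)] = 1.0
        prior = prior * mask

    if query == s.class_name:
        weights = prior * _class_likelihoods(model, evidence)
        states = model.class_states
    else:
        k = model.n_states(query)
        weights = np.empty(k)
        for j in range(k):
            lik = _class_likelihoods(model, {**evidence, query: j})
            weights[j] = float(prior @ lik)
        states = tuple(model.attr_states[query])

    total = weights.sum()
    if total <= 0.0:
        raise ZeroProbabilityEvidenceError(
            f"evidence has probability 0 under the model: {evidence}"
        )
    return PosteriorDistribution(query, tuple(states), weights / total)


def classify(
    model: ParameterizedTAN,
    record: Evidence,
    threshold: float = 0.5,
    positive_state: int = 1,
) -> tuple[int, float]:
    """Threshold the positive-class posterior of a complete record.

    Returns ``(label, p_positive)`` where the label is the positive class
    state iff its posterior probability strictly exceeds the threshold
    (a probability exactly at the threshold yields the other class).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    s = model.structure
    missing = sorted(set(s.attributes) - set(record))
    if missing:
        raise ValueError(f"record must assign every attribute (missing {missing})")
    p = posterior(model, s.class_name, record)[positive_state]
    label = positive_state if p > threshold else 1 - positive_state
    return label, p


def scenario_query(
    model: ParameterizedTAN,
    evidence: Evidence,
    query_attributes: list[str] | None = None,
) -> dict[str, PosteriorDistribution]:
    """What-if analysis: class posterior plus posteriors of free attributes.

    Given a partial assignment (a clinical scenario such as "PVTT present,
    palliative resection"), returns the class posterior and, for each
    requested unobserved attribute, that attribute's posterior under the
    same evidence.  With ``query_attributes=None`` every unobserved
    attribute is reported.
    """
    _check_evidence(model, evidence)
    s = model.structure
    free = [a for a in s.attributes if a not in evidence]
    if query_attributes is None:
        query_attributes = free
    else:
        bad = sorted(set(query_attributes) - set(free))
        if bad:
            raise ValueError(f"query attributes already observed or unknown: {bad}")
    out = {s.class_name: posterior(model, s.class_name, evidence)}
    for a in query_attributes:
        out[a] = posterior(model, a, evidence)
    return out
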
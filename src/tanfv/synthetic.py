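"""Synthetic cohorts with the statistical structure of the study data.

Two generators are provided.

``generate`` draws records by ancestral sampling from a configurable
ground-truth network (class sampled first, then attributes in
topological order).  The default configuration encodes the published
summary statistics of the 299-patient hepatectomy cohort: the class
split is 50.17% short survival, each attribute's class-conditional
distribution is obtained by Bayes inversion of its published marginal
and single-state posterior (so that, e.g., about 84% of PVTT-positive
samples are short-survival), and a small forest of clinically plausible
inter-attribute dependencies (hepatitis B/C, liver function and
complications, PVTT and operative method, tumor number and metastasis,
clamping time and blood loss) is added with a mean-preserving dependence
offset, leaving every marginal intact.

``replica_counts_cohort`` is deterministic: a 299-row table whose
single-variable class-conditional counts reproduce the published
priors and posteriors exactly as integer counts (e.g. 25 PVTT-positive
patients, 21 of them short-survival).  The joint beyond those margins
is arbitrary but fixed, so multi-evidence queries on it are meaningful
only as qualitative checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .schema import CohortTable, VariableSpec, default_schema
from .tan import ParameterizedTAN, TanStructure

__all__ = [
    "GeneratorConfig",
    "default_config",
    "generate",
    "replica_counts_cohort",
    "STUDY_CLASS_PRIOR",
    "STUDY_MARGINALS",
]

# Published class prior {P(S=0), P(S=1)} and, per attribute, the state
# marginals p(Vi=j) and short-survival posteriors P(S=0 | Vi=j).
STUDY_CLASS_PRIOR: tuple[float, float] = (0.5017, 0.4983)

STUDY_MARGINALS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    # name: (priors per state, posteriors P(S=0 | state))
    "sex": ((0.194, 0.806), (0.5172, 0.4979)),
    "age": ((0.3311, 0.408, 0.2609), (0.5051, 0.5, 0.5)),
    "hbv": ((0.2341, 0.7659), (0.5429, 0.4891)),
    "hcv": ((0.9465, 0.0535), (0.5159, 0.25)),
    "afp": ((0.184, 0.4147, 0.4013), (0.4, 0.5323, 0.5167)),
    "liver_function": ((0.8194, 0.1806), (0.4816, 0.5926)),
    "tumor_size": ((0.0201, 0.4849, 0.301, 0.194), (0.1667, 0.4, 0.5444, 0.7241)),
    "tumor_number": ((0.8328, 0.1672), (0.4498, 0.76)),
    "pvtt": ((0.9164, 0.0836), (0.4708, 0.84)),
    "operative_method": ((0.1304, 0.8696), (0.8205, 0.4538)),
    "metastasis": ((0.8462, 0.1538), (0.4585, 0.7391)),
    "tcph": ((0.4749, 0.5251), (0.3803, 0.6115)),
    "blood_loss": ((0.4783, 0.5217), (0.4196, 0.5769)),
    "complication": ((0.5385, 0.4615), (0.4658, 0.5435)),
    "tace": ((0.5351, 0.4649), (0.5937, 0.3957)),
}

# Forest of default inter-attribute dependencies (parent -> child), all
# binary pairs so the mean-preserving offset construction applies.
_DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("hbv", "hcv"),
    ("liver_function", "complication"),
    ("pvtt", "operative_method"),
    ("tumor_number", "metastasis"),
    ("tcph", "blood_loss"),
)


@dataclass
class GeneratorConfig:
    """Ground-truth network, sample size and seed for cohort simulation.

    Randomness uses numpy's PCG64 generator, so a fixed seed gives
    byte-identical cohorts across platforms.
    """

    schema: list[VariableSpec]
    model: ParameterizedTAN
    n: int = 299
    seed: int = 0
    rng_algorithm: str = "PCG64"

    def to_yaml(self) -> str:
        from .schema import schema_to_yaml

        doc = {
            "n": self.n,
            "seed": self.seed,
            "rng_algorithm": self.rng_algorithm,
            "schema": yaml.safe_load(schema_to_yaml(self.schema)),
            "model": json.loads(self.model.to_json()),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        from .schema import schema_from_yaml

        doc = yaml.safe_load(text)
        return cls(
            schema=schema_from_yaml(yaml.safe_dump(doc["schema"])),
            model=ParameterizedTAN.from_json(json.dumps(doc["model"])),
            n=int(doc["n"]),
            seed=int(doc["seed"]),
            rng_algorithm=doc.get("rng_algorithm", "PCG64"),
        )


def _class_conditionals(priors, posteriors) -> np.ndarray:
    """Bayes inversion: P(V=j | S=s) from p(V=j) and P(S=0 | V=j).

    Returns shape (2, K); each row renormalized (the published values are
    rounded, so the raw inversion sums to 1 only approximately).
    """
    p = np.asarray(priors, float)
    q = np.asarray(posteriors, float)
    p0, p1 = STUDY_CLASS_PRIOR
    t = np.stack([q * p / p0, (1.0 - q) * p / p1])
    return t / t.sum(axis=1, keepdims=True)


def default_config(
    n: int = 299, seed: int = 0, dependence: float = 0.15
) -> GeneratorConfig:
    """Ground-truth network matching the published cohort summary.

    Parameters
    ----------
    n, seed : int
        Sample size and random seed for :func:`generate`.
    dependence : float, default 0.15
        Strength of the mean-preserving offset on the default dependency
        edges: within each class, the child's success probability is
        shifted by ``+dependence * (1 - q)`` when the (binary) parent is
        1 and ``-dependence * q`` when it is 0, q being the parent's
        class-conditional success probability — the class-conditional
        child marginal, and hence every published frequency, is
        unchanged.  Offsets are clipped to keep probabilities in
        [0.01, 0.99].
    """
    schema = default_schema()
    attrs = tuple(v.name for v in schema if v.role == "attribute")
    parent: dict[str, str | None] = {a: None for a in attrs}
    for u, v in _DEFAULT_EDGES:
        parent[v] = u
    structure = TanStructure("survival", attrs, parent)

    cond = {a: _class_conditionals(*STUDY_MARGINALS[a]) for a in attrs}
    cpts: dict[str, np.ndarray] = {}
    for a in attrs:
        pa = parent[a]
        if pa is None:
            cpts[a] = cond[a][:, None, :]
            continue
        # binary child with binary parent: offset the success probability
        t = cond[a][:, 1]       # P(child=1 | S=s)
        qp = cond[pa][:, 1]     # P(parent=1 | S=s); parent is a root
        cpt = np.empty((2, 2, 2))
        for s in range(2):
            d = min(dependence,
                    (t[s] - 0.01) / qp[s] if qp[s] > 0 else np.inf,
                    (0.99 - t[s]) / (1 - qp[s]) if qp[s] < 1 else np.inf)
            d = max(d, 0.0)
            p_when = {0: t[s] - d * qp[s], 1: t[s] + d * (1 - qp[s])}
            for u in (0, 1):
                cpt[s, u] = (1 - p_when[u], p_when[u])
        cpts[a] = cpt

    model = ParameterizedTAN(
        structure=structure,
        class_states=("<=10", ">10"),
        attr_states={v.name: v.states for v in schema if v.role == "attribute"},
        class_prior=np.array(STUDY_CLASS_PRIOR) / sum(STUDY_CLASS_PRIOR),
        cpts=cpts,
    )
    return GeneratorConfig(schema=schema, model=model, n=n, seed=seed)


def _topological_order(structure: TanStructure) -> list[str]:
    order, placed = [], set()
    pending = list(structure.attributes)
    while pending:
        rest = []
        for a in pending:
            p = structure.parent[a]
            if p is None or p in placed:
                order.append(a)
                placed.add(a)
            else:
                rest.append(a)
        pending = rest
    return order


def generate(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort by ancestral sampling from the ground-truth network."""
    rng = np.random.default_rng(config.seed)
    model = config.model
    s = model.structure
    n = config.n

    def draw(prob_rows: np.ndarray) -> np.ndarray:
        cum = np.cumsum(prob_rows, axis=1)
        u = rng.random(len(prob_rows))
        return np.argmax(u[:, None] < cum, axis=1)

    cols: dict[str, np.ndarray] = {}
    if n == 0:
        data = pd.DataFrame({v.name: np.array([], dtype=int) for v in config.schema})
        return CohortTable(config.schema, data)

    prior = np.broadcast_to(model.class_prior, (n, len(model.class_states)))
    cols[s.class_name] = draw(prior)
    for a in _topological_order(s):
        cpt = np.asarray(model.cpts[a])
        pa = s.parent[a]
        u_codes = np.zeros(n, dtype=int) if pa is None else cols[pa]
        cols[a] = draw(cpt[cols[s.class_name], u_codes, :])

    data = pd.DataFrame({v.name: cols[v.name] for v in config.schema})
    return CohortTable(config.schema, data)


def replica_counts_cohort() -> CohortTable:
    """Deterministic 299-row cohort matching every published
    single-variable class-conditional count.

    The class column holds 150 short-survival then 149 long-survival
    records.  Each attribute's per-state counts within each class block
    are the integer-matched values ``round(posterior * round(prior *
    299))``; the sums of these counts are asserted to hit the class
    totals exactly.  Within each block the states are dealt out by a
    fixed-seed permutation (one shared generator, columns in schema
    order), which leaves every single-variable class-conditional count
    intact while keeping attribute pairs roughly class-conditionally
    independent — so multi-evidence scenarios on the fixture stay
    non-degenerate.
    """
    schema = default_schema()
    n, n_short = 299, 150
    rng = np.random.default_rng(20150331)
    cols = {"survival": np.repeat([0, 1], [n_short, n - n_short])}
    for name, (priors, posteriors) in STUDY_MARGINALS.items():
        n_state = [round(p * n) for p in priors]
        c_short = [round(q * m) for q, m in zip(posteriors, n_state)]
        assert sum(n_state) == n, f"{name}: state totals {n_state} do not sum to {n}"
        assert sum(c_short) == n_short, (
            f"{name}: short-survival counts {c_short} do not sum to {n_short}"
        )
        c_long = [m - c for m, c in zip(n_state, c_short)]
        short = rng.permutation(np.repeat(np.arange(len(priors)), c_short))
        long = rng.permutation(np.repeat(np.arange(len(priors)), c_long))
        cols[name] = np.concatenate([short, long])
    data = pd.DataFrame({v.name: cols[v.name] for v in schema})
    return CohortTable(schema, data)
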
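"""Fussell-Vesely importance ranking of prognostic variables.

Borrowed from reliability engineering: the Fussell-Vesely (F-V)
importance of fixing variable Vi to state j, with respect to the adverse
outcome S = 0 (short survival), is the relative change in the outcome
probability

    FV_ij = (P(S=0) - P(S=0 | Vi = j)) / P(S=0),

positive when the state makes short survival less likely, negative when
it makes it more likely.  Clinical variables have no designated "normal"
state, so FV can take either sign; a variable's overall leverage is the
composite measure

    MFV_i = (1 / (K_i - 1)) * sum_j |FV_ij|,

the sum of absolute state importances over all K_i states, normalized by
K_i - 1 so that variables with different state counts are comparable
(a binary variable divides by 1, a four-state variable by 3).

Priors and posteriors come from the fitted network; at the maximum-
likelihood fit they coincide with empirical frequencies, so the table is
fully reproducible from class-conditional counts.  A Pearson product-
moment correlation of each integer-coded attribute against the class
codes is reported alongside as an independent (linear) ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import posterior
from .schema import CohortTable
from .tan import ParameterizedTAN

__all__ = [
    "ImportanceRow",
    "fv_importance",
    "composite_importance",
    "pearson_correlation",
    "importance_table",
    "importance_frame",
]


def fv_importance(prior: float, post: float) -> float:
    """F-V importance (prior - posterior) / prior of one variable state."""
    if not 0.0 < prior <= 1.0:
        raise ZeroDivisionError("class prior must lie in (0, 1]")
    if not 0.0 <= post <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    return (prior - post) / prior


def composite_importance(fv_values) -> float:
    """Composite multistate importance: sum of |FV| over all K states,
    divided by K - 1."""
    fv_values = np.asarray(fv_values, dtype=float)
    k = len(fv_values)
    if k < 2:
        raise ValueError("need at least 2 states")
    return float(np.abs(fv_values).sum() / (k - 1))


def pearson_correlation(x_codes, y_codes) -> float:
    """Pearson product-moment correlation of two integer-coded sequences."""
    x = np.asarray(x_codes, dtype=float)
    y = np.asarray(y_codes, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(x, y).statistic)


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    """Rank descending; ties share the smaller rank, next rank skips."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    for pos, idx in enumerate(order):
        if pos > 0 and values[idx] == values[order[pos - 1]]:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = pos + 1
    return ranks


@dataclass(frozen=True)
class ImportanceRow:
    """Per-variable importance summary (one row of the ranking table)."""

    variable: str
    states: tuple[str, ...]
    priors: np.ndarray          # p(Vi = j), model marginal
    posteriors: np.ndarray      # P(S = 0 | Vi = j)
    fv: np.ndarray              # per-state F-V importance
    mfv: float
    rank: int                   # by descending MFV
    pearson: float              # PCC of codes against class codes
    pearson_rank: int           # by descending |PCC|


def importance_table(
    model: ParameterizedTAN,
    table: CohortTable,
    adverse_state: int = 0,
) -> list[ImportanceRow]:
    """Rank every attribute by composite F-V importance.

    For each attribute: the state prior p(Vi=j) is the model marginal
    (equal to the empirical frequency at alpha=0); the posterior
    P(S=adverse | Vi=j) comes from exact single-evidence inference; FV
    and MFV follow from them; ranks are competition ranks by descending
    MFV.  The Pearson column correlates the attribute's integer codes
    with the class codes and is ranked by descending absolute value.
    """
    s = model.structure
    prior_s = posterior(model, s.class_name, {})[adverse_state]
    y = table.data[s.class_name].to_numpy()

    rows = []
    for a in s.attributes:
        k = model.n_states(a)
        marg = np.array([posterior(model, a, {})[j] for j in range(k)])
        post = np.empty(k)
        for j in range(k):
            post[j] = posterior(model, s.class_name, {a: j})[adverse_state]
        fv = np.array([fv_importance(prior_s, p) for p in post])
        pcc = pearson_correlation(table.data[a].to_numpy(), y)
        rows.append((a, tuple(model.attr_states[a]), marg, post, fv,
                     composite_importance(fv), pcc))

    mfv = np.array([r[5] for r in rows])
    pcc_abs = np.array([abs(r[6]) for r in rows])
    ranks = _competition_ranks(mfv)
    p_ranks = _competition_ranks(pcc_abs)
    return [
        ImportanceRow(
            variable=a, states=st, priors=marg, posteriors=post, fv=fv,
            mfv=float(m), rank=int(rk), pearson=float(pc), pearson_rank=int(prk),
        )
        for (a, st, marg, post, fv, m, pc), rk, prk in zip(rows, ranks, p_ranks)
    ]


def importance_frame(rows: list[ImportanceRow]) -> pd.DataFrame:
    """Long-format DataFrame of an importance table (one row per state),
    suitable for CSV export."""
    recs = []
    for r in rows:
        for j, st in enumerate(r.states):
            recs.append({
                "variable": r.variable,
                "state": j,
                "state_label": st,
                "prior": r.priors[j],
                "posterior": r.posteriors[j],
                "fv": r.fv[j],
                "mfv": r.mfv,
                "rank": r.rank,
                "pearson": r.pearson,
                "pearson_rank": r.pearson_rank,
            })
    return pd.DataFrame.from_records(recs)
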
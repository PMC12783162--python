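"""AIC model ranking: delta-AIC, Akaike weights, model likelihoods, candidate sets."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["aic", "rank_models", "candidate_set"]


def aic(neg2loglik: float, K: int) -> float:
    """Akaike Information Criterion: -2*loglik + 2*K (K >= 1 parameters)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return float(neg2loglik) + 2.0 * K


def rank_models(records: Iterable[Mapping | tuple]) -> pd.DataFrame:
    """Rank fitted models by AIC.

    ``records`` holds ``(name, neg2loglik, K)`` tuples or mappings with those
    keys.  Returns a table sorted ascending by AIC with ``delta_aic``
    (difference from the best model), Akaike ``weight``
    exp(-delta/2) / sum_j exp(-delta_j/2) over the supplied set, and
    ``model_likelihood`` exp(-delta/2).
    """
    rows = []
    for r in records:
        if isinstance(r, Mapping):
            rows.append((r["name"], float(r["neg2loglik"]), int(r["K"])))
        else:
            name, n2l, k = r
            rows.append((str(name), float(n2l), int(k)))
    if not rows:
        raise ValueError("at least one model record is required")
    df = pd.DataFrame(rows, columns=["name", "neg2loglik", "K"])
    df["aic"] = df["neg2loglik"] + 2.0 * df["K"]
    df = df.sort_values("aic", kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    rel = np.exp(-0.5 * df["delta_aic"].to_numpy())
    df["weight"] = rel / rel.sum()
    df["model_likelihood"] = rel
    return df


def candidate_set(table: pd.DataFrame, cutoff: float = 2.0) -> pd.DataFrame:
    """Models with delta_aic strictly below the cutoff, in ranked order."""
    return table[table["delta_aic"] < cutoff].reset_index(drop=True)
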
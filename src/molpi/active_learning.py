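"""Active-learning screening loop: fit, rank, label the top batch, repeat.

The acquisition is pure exploitation: at each iteration the current model
predicts the whole unlabeled pool and the ``batch`` molecules with the most
negative predicted interaction energy (the strongest predicted binders) are
sent to the labeling oracle and moved into the training set. Three
iterations of batch 40 on top of a 100-molecule seed set give the canonical
220-point campaign. A final screen ranks the remaining pool and counts
predictions at or below a strong-interaction threshold (defaults -6.0 and
-6.5 kcal/mol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import learning

__all__ = ["ALState", "select_batch", "run_campaign", "screen",
           "STRONG_MARK", "SCREEN_THRESHOLD"]

#: Mark for "significantly strong" interaction energies, kcal/mol.
STRONG_MARK = -6.0
#: Tighter screening threshold for top candidates, kcal/mol.
SCREEN_THRESHOLD = -6.5

Oracle = Callable[[str], float]


@dataclass
class ALState:
    """Bookkeeping for one campaign: labels, pool, and per-iteration history."""

    labeled: dict[str, float]
    pool: list[str]
    iteration: int = 0
    history: list[dict] = field(default_factory=list)

    def check(self) -> None:
        overlap = set(self.labeled) & set(self.pool)
        if overlap:
            raise ValueError(f"labeled set and pool overlap: {sorted(overlap)[:5]}")

    def to_jsonl(self, path: str | Path) -> None:
        """Append-only line-delimited JSON history log."""
        with open(path, "w") as fh:
            for rec in self.history:
                fh.write(json.dumps(rec) + "\n")


def select_batch(model: learning.KRRModel, pool_features: pd.DataFrame,
                 batch: int) -> list[str]:
    """Ids of the ``batch`` most-negative predictions; ties broken by id order.

    More negative = stronger predicted interaction; this is the top-k
    exploitation acquisition.
    """
    if len(pool_features) == 0:
        raise ValueError("candidate pool is empty")
    if batch > len(pool_features):
        raise ValueError(f"batch {batch} exceeds pool size {len(pool_features)}")
    preds = model.predict(pool_features.to_numpy())
    order = sorted(zip(preds, pool_features.index), key=lambda t: (t[0], t[1]))
    return [mid for _, mid in order[:batch]]


def _fit_on(features: pd.DataFrame, labeled: dict[str, float],
            learner: dict) -> learning.KRRModel:
    ids = sorted(labeled)
    X = features.loc[ids].to_numpy()
    y = np.array([labeled[i] for i in ids])
    return learning.fit(
        X, y,
        kernel=learner.get("kernel", "laplacian"),
        gamma=learner.get("gamma", 1.0),
        lam=learner.get("lam", 1e-6),
        standardize=learner.get("standardize", True),
    )


def run_campaign(initial: dict[str, float], pool: list[str],
                 oracle: Oracle, features: pd.DataFrame,
                 learner: dict | None = None, batch: int = 40,
                 iterations: int = 3) -> ALState:
    """Run the screen-select-label-retrain loop.

    Parameters
    ----------
    initial : dict
        Seed training set, molecule id -> label (kcal/mol).
    pool : list of str
        Candidate ids, disjoint from the seed set.
    oracle : callable
        id -> label; stands in for the expensive reference computation.
    features : DataFrame
        Feature rows (indexed by id) covering seed set and pool.
    learner : dict
        Kernel ridge settings (kernel, gamma, lam, standardize).
    batch, iterations : int
        Molecules labeled per iteration, and number of iterations.

    After iteration t the labeled set holds ``n0 + t * batch`` molecules.
    An oracle failure aborts with the partial history retained on the raised
    state.
    """
    learner = dict(learner or {})
    state = ALState(dict(initial), list(pool))
    state.check()
    for it in range(iterations):
        model = _fit_on(features, state.labeled, learner)
        pool_feats = features.loc[state.pool]
        chosen = select_batch(model, pool_feats, batch)
        preds = dict(zip(
            pool_feats.index,
            model.predict(pool_feats.to_numpy()),
        ))
        rec = {
            "iteration": it,
            "selected": chosen,
            "model_fingerprint": model.fingerprint(),
            "predictions_at_selection": {mid: float(preds[mid]) for mid in chosen},
        }
        labels = {}
        for mid in chosen:
            try:
                labels[mid] = float(oracle(mid))
            except Exception as exc:
                rec["error"] = f"oracle failed on {mid!r}: {exc}"
                state.history.append(rec)
                state.iteration = it
                raise RuntimeError(rec["error"]) from exc
        state.labeled.update(labels)
        state.pool = [m for m in state.pool if m not in labels]
        state.iteration = it + 1
        rec["labels"] = labels
        state.history.append(rec)
        state.check()
    return state


def screen(model: learning.KRRModel, features: pd.DataFrame,
           threshold: float = SCREEN_THRESHOLD) -> tuple[pd.DataFrame, int]:
    """Rank a candidate set by predicted energy; count hits at the threshold.

    Returns the full ranked table (ascending prediction, i.e. strongest
    first) and the number of predictions <= threshold.
    """
    preds = model.predict(features.to_numpy())
    table = pd.DataFrame({"prediction": preds}, index=features.index)
    # stable sort after an index sort => ties broken by id order
    table = table.sort_index(kind="stable").sort_values("prediction", kind="stable")
    count = int((table["prediction"] <= threshold).sum())
    return table, count
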
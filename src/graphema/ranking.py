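"""Ranking metrics for model quality predictors.

Two per-target metrics are computed for each predictor:

* **ranking loss** — true quality of the genuinely best model minus the
  true quality of the model the predictor ranked first. A predictor's top
  pick is only accepted when its top predicted score is unique within the
  target; otherwise the loss is recorded at the 0.1 sentinel ("not less
  than 0.1"), since a tie makes the pick arbitrary.
* **NDCG@3** — discounted cumulative gain over the predictor's top three
  models with relevance r_i = 1 - (true_best - true_i)^2 (zero when the
  score that placed the model is not unique), normalized by the DCG@3 of
  the true ranking, so a perfect ordering scores one.

Prediction and truth tables are plain dataframes; see
:func:`evaluate_table` for the expected columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Loss recorded when a predictor's top predicted score is not unique, or
#: when the predictor made no prediction for a target.
SENTINEL_LOSS = 0.1


@dataclass
class RankingResult:
    target_id: str
    predictor: str
    loss: float
    unique_top: bool
    ndcg3: float


def _true_best(truths: pd.Series) -> str:
    """Model id with the highest true score; ties break lexicographically."""
    df = truths.reset_index()
    df.columns = ["model_id", "true"]
    df = df.sort_values(["true", "model_id"], ascending=[False, True],
                        kind="stable")
    return str(df.iloc[0]["model_id"])


def ranking_loss(preds: pd.Series, truths: pd.Series) -> tuple[float, bool]:
    """Per-target ranking loss for one predictor.

    ``preds`` maps model_id -> predicted score; ``truths`` maps model_id ->
    true score and must cover every predicted model. Returns
    (loss, unique_top).
    """
    if preds.empty:
        raise ValueError("no predictions for target")
    missing = set(preds.index) - set(truths.index)
    if missing:
        raise ValueError(f"models lacking truth entries: {sorted(missing)}")
    top_pred = preds.max()
    top_models = preds[preds == top_pred]
    if len(top_models) > 1:
        return SENTINEL_LOSS, False
    picked = _pick_top(preds)
    best = _true_best(truths)
    loss = float(truths[best] - truths[picked])
    return loss, True


def _pick_top(preds: pd.Series) -> str:
    df = preds.reset_index()
    df.columns = ["model_id", "pred"]
    df = df.sort_values(["pred", "model_id"], ascending=[False, True],
                        kind="stable")
    return str(df.iloc[0]["model_id"])


def relevance(true_best: float, true_i: float, unique_i: bool) -> float:
    """r_i = 1 - (true_best - true_i)^2, or 0 for a non-unique score."""
    if not unique_i:
        return 0.0
    return 1.0 - (true_best - true_i) ** 2


def _dcg3(ordered_models: list[str], ranking_scores: pd.Series,
          truths: pd.Series, best_score: float) -> float:
    """DCG@3 of a ranking; ``ranking_scores`` are the scores that produced
    the ordering (used for the uniqueness rule)."""
    counts = ranking_scores.value_counts()
    total = 0.0
    for i, mid in enumerate(ordered_models[:3], start=1):
        unique = counts[ranking_scores[mid]] == 1
        r = relevance(best_score, float(truths[mid]), bool(unique))
        total += r / np.log2(i + 1)
    return total


def _ordering(scores: pd.Series) -> list[str]:
    df = scores.reset_index()
    df.columns = ["model_id", "s"]
    df = df.sort_values(["s", "model_id"], ascending=[False, True],
                        kind="stable")
    return [str(m) for m in df["model_id"]]


def ndcg3(preds: pd.Series, truths: pd.Series) -> float:
    """Normalized DCG@3 of a predictor's ranking against the true ranking.

    Targets with fewer than three models sum over the available positions;
    the normalization is unchanged. Returns NaN when the ideal DCG@3 is
    zero (all true scores tied).
    """
    best_score = float(truths[_true_best(truths)])
    pred_dcg = _dcg3(_ordering(preds), preds, truths, best_score)
    ideal_dcg = _dcg3(_ordering(truths), truths, truths, best_score)
    if ideal_dcg <= 0.0:
        return float("nan")
    return pred_dcg / ideal_dcg


def evaluate_table(pred_df: pd.DataFrame, truth_df: pd.DataFrame
                   ) -> list[RankingResult]:
    """Per-(target, predictor) metrics from long-format tables.

    ``pred_df`` columns: target_id, predictor, model_id, score.
    ``truth_df`` columns: target_id, model_id, score.
    """
    _require(pred_df, ("target_id", "predictor", "model_id", "score"), "predictions")
    _require(truth_df, ("target_id", "model_id", "score"), "truth")
    out: list[RankingResult] = []
    for (target, predictor), grp in pred_df.groupby(["target_id", "predictor"],
                                                    sort=True):
        truths = truth_df[truth_df.target_id == target].set_index("model_id")["score"]
        if truths.empty:
            raise ValueError(f"no truth rows for target {target!r}")
        preds = grp.set_index("model_id")["score"]
        loss, unique_top = ranking_loss(preds, truths)
        out.append(RankingResult(str(target), str(predictor), loss,
                                 unique_top, ndcg3(preds, truths)))
    return out


def _require(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table lacks columns: {missing}")


def leaderboard(pred_df: pd.DataFrame, truth_df: pd.DataFrame,
                order_by: str = "mean_loss") -> pd.DataFrame:
    """Per-predictor summary across targets.

    Reports mean ranking loss (sentinels included), the count of targets
    with loss < 0.1, and summed NDCG@3. A predictor absent on a target is
    charged the sentinel loss and zero NDCG there. ``order_by`` selects the
    sort key: ``mean_loss`` (ascending), ``n_low_loss`` or ``ndcg3_sum``
    (descending).
    """
    results = evaluate_table(pred_df, truth_df)
    targets = sorted(truth_df.target_id.unique())
    predictors = sorted(pred_df.predictor.unique())
    by_key = {(r.target_id, r.predictor): r for r in results}
    rows = []
    for p in predictors:
        losses, ndcgs = [], []
        for t in targets:
            r = by_key.get((t, p))
            if r is None:
                losses.append(SENTINEL_LOSS)
                ndcgs.append(0.0)
            else:
                losses.append(r.loss)
                ndcgs.append(0.0 if np.isnan(r.ndcg3) else r.ndcg3)
        rows.append({
            "predictor": p,
            "mean_loss": float(np.mean(losses)),
            "n_low_loss": int(sum(l < SENTINEL_LOSS for l in losses)),
            "ndcg3_sum": float(np.sum(ndcgs)),
            "n_targets": len(targets),
        })
    df = pd.DataFrame(rows)
    ascending = order_by == "mean_loss"
    if order_by not in df.columns:
        raise ValueError(f"unknown ordering key {order_by!r}")
    return df.sort_values([order_by, "predictor"],
                          ascending=[ascending, True]).reset_index(drop=True)
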
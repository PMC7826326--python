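"""Recognition-experiment analysis: filtering, binning, guessing
correction, and valence-dimensionality fitting.

The pipeline mirrors a standard delayed-recognition analysis: keep only
participants with perfect 2-back performance (evidence that every word was
acquired, so forgetting — not encoding failure — drives errors), pool
correct/incorrect flags into equal-population lag bins, convert accuracies
to retention estimates by inverting the two-alternative guessing relation
``p = (1 + R)/2``, and select the valence dimensionality whose theoretical
retention curve best matches the binned accuracies (RMSE in accuracy
space — the scalar stand-in for a visual curve comparison, reported per
candidate so alternatives can be swapped in).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curves import retention_nd

__all__ = [
    "ModelFitResult",
    "filter_perfect_2back",
    "compute_lag",
    "bin_equal_population",
    "correct_for_guessing",
    "accuracy_from_retention",
    "fit_dimensionality",
    "run_recognition_analysis",
]


@dataclass
class ModelFitResult:
    """Dimensionality-fit report: one RMSE per candidate, argmin selected.

    Ties are broken toward the smaller dimensionality.
    """

    candidate_n: list[int]
    rmse: np.ndarray
    selected_n: int

    def to_dict(self) -> dict:
        return {
            "candidate_n": [int(n) for n in self.candidate_n],
            "rmse": [float(r) for r in self.rmse],
            "selected_n": int(self.selected_n),
        }


def compute_lag(query_position: int, target_position: int) -> int:
    """Lag between a recognition query and its target's presentation.

    Simply the difference of stream positions; e.g. a query in place of the
    100th word about the 15th word has lag 85.
    """
    lag = query_position - target_position
    if np.any(np.asarray(lag) <= 0):
        raise ValueError("query must come after the target presentation")
    return lag


def filter_perfect_2back(trials: pd.DataFrame) -> np.ndarray:
    """Participants with perfect 2-back accuracy.

    Returns the sorted participant ids whose 2-back trials are all correct.
    Participants without any 2-back trial cannot demonstrate intact
    encoding and are excluded with a warning.
    """
    two = trials[trials["condition"] == "2-back"]
    per = two.groupby("participant_id", observed=True)["correct"].agg(["size", "sum"])
    all_ids = trials["participant_id"].unique()
    missing = np.setdiff1d(all_ids, per.index.to_numpy())
    if missing.size:
        warnings.warn(
            f"{missing.size} participant(s) without 2-back trials excluded",
            stacklevel=2,
        )
    kept = per.index.to_numpy()[per["sum"].to_numpy() == per["size"].to_numpy()]
    return np.sort(kept)


def bin_equal_population(
    lags: Iterable[int], correct_flags: Iterable[bool], per_bin: int
) -> pd.DataFrame:
    """Group lag-sorted measurements into bins of equal population.

    Measurements are sorted by lag (stable) and grouped ``per_bin`` at a
    time; the last bin may hold fewer.  Each row reports the bin's lag
    range, mean lag, measurement count, accuracy, and the guessing-corrected
    retention estimate (both clipped to [0, 1] and raw — sampling noise can
    push ``2p - 1`` below zero, and the fit should see the unclipped value).
    """
    lags = np.asarray(lags)
    correct = np.asarray(correct_flags, dtype=float)
    if lags.shape != correct.shape or lags.ndim != 1:
        raise ValueError("lags and correct_flags must be 1-D and aligned")
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    if lags.size == 0:
        raise ValueError("no measurements to bin")
    if lags.size < per_bin:
        warnings.warn(
            f"only {lags.size} measurements for per_bin={per_bin}; single bin",
            stacklevel=2,
        )
    order = np.argsort(lags, kind="stable")
    lags = lags[order]
    correct = correct[order]
    edges = np.arange(0, lags.size, per_bin)
    rows = []
    for b, start in enumerate(edges):
        stop = min(start + per_bin, lags.size)
        chunk_lags = lags[start:stop]
        acc = float(correct[start:stop].mean())
        raw = 2.0 * acc - 1.0
        rows.append(
            {
                "bin_index": b,
                "lag_min": int(chunk_lags[0]),
                "lag_max": int(chunk_lags[-1]),
                "mean_lag": float(chunk_lags.mean()),
                "n_measurements": stop - start,
                "accuracy": acc,
                "retention_hat": float(np.clip(raw, 0.0, 1.0)),
                "retention_hat_raw": raw,
            }
        )
    return pd.DataFrame(rows)


def correct_for_guessing(accuracy):
    """Invert the two-alternative guessing relation ``p = (1 + R)/2``.

    Returns ``2p - 1`` clipped to [0, 1]: chance accuracy maps to zero
    retention, perfect accuracy to certain retention.
    """
    acc = np.asarray(accuracy, dtype=float)
    if (acc < 0).any() or (acc > 1).any():
        raise ValueError("accuracy must lie in [0, 1]")
    out = np.clip(2.0 * acc - 1.0, 0.0, 1.0)
    return out if out.ndim else float(out)


def accuracy_from_retention(retention):
    """Forward guessing relation: accuracy ``p = (1 + R)/2``."""
    r = np.asarray(retention, dtype=float)
    if (r < 0).any() or (r > 1).any():
        raise ValueError("retention must lie in [0, 1]")
    out = (1.0 + r) / 2.0
    return out if out.ndim else float(out)


def fit_dimensionality(
    binned: pd.DataFrame, candidates: Sequence[int]
) -> ModelFitResult:
    """Select the valence dimensionality matching binned accuracies.

    For each candidate ``n`` the predicted accuracy at a bin is
    ``(1 + R_n(round(mean_lag)))/2`` (the exact curve is defined on integer
    lags); the per-candidate score is the RMSE against the observed bin
    accuracies and the smallest-RMSE candidate wins, ties going to the
    smaller ``n``.
    """
    candidates = [int(n) for n in candidates]
    if not candidates:
        raise ValueError("need at least one candidate dimensionality")
    lags = np.rint(binned["mean_lag"].to_numpy()).astype(int)
    if (lags < 1).any():
        raise ValueError("bin mean lags must round to >= 1")
    acc = binned["accuracy"].to_numpy()
    t_max = int(lags.max())
    rmse = np.empty(len(candidates))
    for i, n in enumerate(candidates):
        pred = accuracy_from_retention(retention_nd(n, t_max).values[lags])
        rmse[i] = float(np.sqrt(np.mean((acc - pred) ** 2)))
    best = min(range(len(candidates)), key=lambda i: (rmse[i], candidates[i]))
    return ModelFitResult(
        candidate_n=candidates, rmse=rmse, selected_n=candidates[best]
    )


def run_recognition_analysis(
    trials: pd.DataFrame,
    candidates: Sequence[int] = (1, 2, 3, 4, 5, 6),
    per_bin: int | None = None,
    conditions: Sequence[str] = ("early", "10-back"),
) -> tuple[pd.DataFrame, ModelFitResult]:
    """Full pipeline: filter, bin, correct for guessing, fit dimensionality.

    Keeps perfect-2-back participants, pools their trials from the given
    conditions (by default the lag-spanning early queries plus the dense
    lag-10 measurements), bins with ``per_bin`` defaulting to the number of
    retained participants, and fits the candidate dimensionalities.
    Returns the binned-performance table and the fit report.
    """
    kept = filter_perfect_2back(trials)
    if kept.size == 0:
        raise ValueError("no participant had perfect 2-back performance")
    sub = trials[
        trials["participant_id"].isin(kept)
        & trials["condition"].isin(list(conditions))
    ]
    if per_bin is None:
        per_bin = int(kept.size)
    binned = bin_equal_population(
        sub["lag"].to_numpy(), sub["correct"].to_numpy(), per_bin
    )
    fit = fit_dimensionality(binned, candidates)
    return binned, fit
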
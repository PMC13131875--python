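"""From-scratch ranking metrics and submission handling.

AUROC uses the rank-based (Mann-Whitney) estimator with tied scores
contributing one half; AUPRC uses the step-wise average-precision
formulation evaluated at distinct score thresholds (no linear
interpolation), which handles ties by grouping. Both are implemented
directly rather than delegated, because the scoring rule is part of the
contract being tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "auroc",
    "auprc",
    "SubmissionScore",
    "rank_submissions",
    "read_submission",
    "write_submission",
    "validate_submission",
    "score_submission",
    "SubmissionError",
]


def _check_inputs(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if uniq != {0, 1}:
        raise ValueError("labels must contain both classes")
    return scores, labels.astype(int)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(score_case > score_control) + 0.5 P(tie)."""
    scores, labels = _check_inputs(scores, labels)
    ranks = rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum = float(ranks[labels == 1].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def auprc(scores, labels) -> float:
    """Average precision over distinct-score thresholds, descending.

    AP = sum over thresholds of (recall step) x (precision at that
    threshold); tied scores enter as one block, so the value for
    all-identical scores equals the prevalence.
    """
    scores, labels = _check_inputs(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    ap = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_pos = int(y[i:j].sum())
        tp += block_pos
        seen += j - i
        precision = tp / seen
        ap += (block_pos / n_pos) * precision
        i = j
    return ap


# ----------------------------------------------------------------------
@dataclass
class SubmissionScore:
    submission_id: str
    auroc: float
    auprc: float
    n_scored: int
    n_missing_ids: int = 0


def rank_submissions(scores: list[SubmissionScore]) -> pd.DataFrame:
    """Leaderboard: descending AUROC, exact AUROC ties broken by AUPRC,
    remaining exact ties share a rank (competition ranking)."""
    if not scores:
        raise ValueError("no submissions to rank")
    frame = pd.DataFrame(
        [
            {
                "submission_id": s.submission_id,
                "auroc": s.auroc,
                "auprc": s.auprc,
                "n_scored": s.n_scored,
            }
            for s in scores
        ]
    )
    frame = frame.sort_values(
        ["auroc", "auprc", "submission_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    ranks = []
    for i in range(len(frame)):
        if i > 0 and (
            frame.at[i, "auroc"] == frame.at[i - 1, "auroc"]
            and frame.at[i, "auprc"] == frame.at[i - 1, "auprc"]
        ):
            ranks.append(ranks[-1])
        else:
            ranks.append(i + 1)
    frame.insert(0, "rank", ranks)
    return frame


# ----------------------------------------------------------------------
class SubmissionError(ValueError):
    """Raised for malformed or incomplete submission files."""


def write_submission(ids, probabilities, path: str | Path) -> None:
    probabilities = np.asarray(probabilities, dtype=float)
    if len(ids) != len(probabilities):
        raise SubmissionError("ids and probabilities differ in length")
    bad = np.nonzero((probabilities < 0) | (probabilities > 1) | ~np.isfinite(probabilities))[0]
    if bad.size:
        raise SubmissionError(f"probabilities outside [0, 1] at rows {bad[:10].tolist()}")
    pd.DataFrame({"id": list(ids), "probability": probabilities}).to_csv(path, index=False)


def read_submission(path: str | Path) -> pd.Series:
    """Parse a two-column CSV (id, probability) with strict validation."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise SubmissionError(f"unreadable submission file: {exc}") from exc
    if list(frame.columns)[:2] != ["id", "probability"] or frame.shape[1] != 2:
        raise SubmissionError("submission must have exactly columns: id, probability")
    probs = pd.to_numeric(frame["probability"], errors="coerce")
    bad = frame.index[probs.isna() | (probs < 0) | (probs > 1)].tolist()
    if bad:
        raise SubmissionError(
            f"invalid probabilities on data lines {[i + 2 for i in bad[:10]]}"
        )
    dupes = frame["id"][frame["id"].duplicated()].unique().tolist()
    if dupes:
        raise SubmissionError(f"duplicate ids: {dupes[:10]}")
    return pd.Series(probs.to_numpy(), index=pd.Index(frame["id"].astype(str), name="id"))


def validate_submission(submission: pd.Series, test_ids) -> None:
    """Challenge semantics: every test id must be present; unknown ids
    are rejected too."""
    test_ids = list(test_ids)
    have = set(submission.index)
    missing = sorted(set(test_ids) - have)
    if missing:
        raise SubmissionError(f"submission missing {len(missing)} test ids: {missing[:10]}")
    unknown = sorted(have - set(test_ids))
    if unknown:
        raise SubmissionError(f"submission contains {len(unknown)} unknown ids: {unknown[:10]}")


def score_submission(
    submission: pd.Series, truth: pd.Series, submission_id: str = "submission"
) -> SubmissionScore:
    validate_submission(submission, truth.index)
    aligned = submission.loc[truth.index]
    return SubmissionScore(
        submission_id=submission_id,
        auroc=auroc(aligned.to_numpy(), truth.to_numpy()),
        auprc=auprc(aligned.to_numpy(), truth.to_numpy()),
        n_scored=len(aligned),
    )
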
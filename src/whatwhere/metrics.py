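"""Directly extracted task parameters and VVIQ scoring.

Three measures come straight off the raw trials, per condition:

* **identification accuracy** — proportion of trials on which the studied
  item was chosen over the novel foil;
* **localisation error** — mean Euclidean distance (px) between the response
  and the true target location, on identification-correct trials;
* **reaction time** — mean time (s) to the identification choice.

Trials with an incorrect identification are excluded from localisation (and
classification) by default, since the dragged item is then not the studied
one.  The VVIQ total is the sum of 16 item ratings (1-5), bounded 16-80.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import euclidean
from .synthio import CONDITIONS, ParticipantRecord, TrialResponse, TrialSpec

__all__ = [
    "identification_accuracy",
    "localisation_error",
    "vviq_total",
    "summarize_session",
    "summarize_cohort",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "participant_id", "set_size", "delay_s",
    "identification_accuracy", "mean_localisation_error_px", "mean_rt_s",
    "mean_p_target", "mean_p_misbind", "mean_p_guess",
    "n_trials", "n_correct",
]


def identification_accuracy(
    responses: Sequence[TrialResponse],
) -> float:
    """Fraction of trials with the studied item correctly identified.

    Returns NaN (missing, not zero) for an empty set of trials.
    """
    if len(responses) == 0:
        return float("nan")
    return sum(r.identification_correct for r in responses) / len(responses)


def localisation_error(
    pairs: Iterable[tuple[TrialSpec, TrialResponse]],
    correct_only: bool = True,
) -> float:
    """Mean response-to-target distance in pixels.

    By default only identification-correct trials contribute; NaN when no
    trial is eligible.
    """
    dists = [
        euclidean(resp.response_loc, trial.target_loc)
        for trial, resp in pairs
        if resp.identification_correct or not correct_only
    ]
    if not dists:
        return float("nan")
    return float(np.mean(dists))


def vviq_total(items: Sequence[int]) -> int:
    """Total VVIQ score: sum of 16 item ratings, each an integer in [1, 5].

    Bounded between 16 (no imagery reported on any item) and 80 (maximally
    vivid on every item).
    """
    if len(items) != 16:
        raise ValueError(f"VVIQ has 16 items, got {len(items)}")
    vals = []
    for v in items:
        iv = int(v)
        if iv != v or not 1 <= iv <= 5:
            raise ValueError(f"VVIQ ratings must be integers in [1, 5], got {v!r}")
        vals.append(iv)
    return sum(vals)


def summarize_session(
    record: ParticipantRecord,
    per_condition_probs: Optional[pd.DataFrame] = None,
    rt_statistic: str = "mean",
    correct_only: bool = True,
) -> pd.DataFrame:
    """Per-condition summary of one participant's session.

    ``per_condition_probs`` is the per-condition table returned by
    :func:`whatwhere.classify.classify_session`; when given, its mean
    classified probabilities are merged in.  ``rt_statistic`` selects the
    per-condition reaction-time summary (``"mean"`` or ``"median"``).
    """
    if rt_statistic not in ("mean", "median"):
        raise ValueError("rt_statistic must be 'mean' or 'median'")
    rt_fn = np.mean if rt_statistic == "mean" else np.median
    rows = []
    for set_size, delay in CONDITIONS:
        pairs = [
            (t, r) for t, r in record.trials
            if t.set_size == set_size and t.delay_s == delay
        ]
        responses = [r for _, r in pairs]
        n_correct = sum(r.identification_correct for r in responses)
        rows.append(
            {
                "participant_id": record.participant_id,
                "set_size": set_size,
                "delay_s": delay,
                "identification_accuracy": identification_accuracy(responses),
                "mean_localisation_error_px": localisation_error(
                    pairs, correct_only=correct_only
                ),
                "mean_rt_s": float(rt_fn([r.rt_s for r in responses]))
                if responses else float("nan"),
                "mean_p_target": np.nan,
                "mean_p_misbind": np.nan,
                "mean_p_guess": np.nan,
                "n_trials": len(pairs),
                "n_correct": int(n_correct),
            }
        )
    out = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if per_condition_probs is not None:
        probs = per_condition_probs.set_index(["set_size", "delay_s"])
        for i, (set_size, delay) in enumerate(zip(out["set_size"], out["delay_s"])):
            if (set_size, delay) in probs.index:
                row = probs.loc[(set_size, delay)]
                out.loc[i, "mean_p_target"] = row["mean_p_target"]
                out.loc[i, "mean_p_misbind"] = row["mean_p_misbind"]
                out.loc[i, "mean_p_guess"] = row["mean_p_guess"]
    return out


def summarize_cohort(
    records: Sequence[ParticipantRecord],
    per_condition_probs: Optional[pd.DataFrame] = None,
    rt_statistic: str = "mean",
    correct_only: bool = True,
) -> pd.DataFrame:
    """Tidy per-participant-per-condition summary for a whole cohort.

    ``per_condition_probs`` may be the concatenated per-condition tables of
    :func:`whatwhere.classify.classify_session` over the same participants.
    """
    frames = []
    for rec in records:
        probs = None
        if per_condition_probs is not None:
            probs = per_condition_probs[
                per_condition_probs["participant_id"] == rec.participant_id
            ]
        frames.append(
            summarize_session(rec, probs, rt_statistic=rt_statistic,
                              correct_only=correct_only)
        )
    return pd.concat(frames, ignore_index=True)
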
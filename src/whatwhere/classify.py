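"""Per-trial misbinding/guessing classification by nearest distance.

Localisation responses are decomposed into target, misbinding (swap) and
guessing probabilities with a resampling scheme: on each repeat, the distance
from the response to (i) the target, (ii) the closest displayed non-target
and (iii) one non-target drawn from a *different* trial of the same session
are compared, and the smallest distance wins the repeat.  Repeating with a
freshly drawn other-trial non-target (5000 times by default) turns the per
-trial category counts into probabilities: responses near the target are
credited to memory, responses near a displayed non-target to misbinding, and
responses that sit closer to an arbitrary other-trial location than to
anything actually shown are credited to guessing.

:func:`classify_trial_exact` computes the exact expectation of the same
scheme by enumerating every pool point once; it serves as a deterministic
oracle for the Monte-Carlo estimator (and as a fast exact mode for large
simulation studies).

Distances to the target and to the closest displayed non-target are computed
once per trial; only the other-trial non-target is redrawn on each repeat.
Exact distance ties are broken with the fixed priority target > misbind >
guess so that results are reproducible on degenerate geometries.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .synthio import CONDITIONS, ParticipantRecord, TrialResponse, TrialSpec

__all__ = [
    "ClassificationResult",
    "NonTargetPool",
    "euclidean",
    "classify_trial",
    "classify_trial_exact",
    "classify_session",
    "participant_rng",
    "DEFAULT_N_RESAMPLES",
]

#: number of resamples of the other-trial non-target per trial
DEFAULT_N_RESAMPLES = 5000


def euclidean(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points, in pixels."""
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    if not all(map(math.isfinite, (ax, ay, bx, by))):
        raise ValueError("coordinates must be finite")
    return math.hypot(ax - bx, ay - by)


@dataclass(frozen=True)
class ClassificationResult:
    """Estimated response-component probabilities for one trial.

    The three probabilities are category counts over ``n_resamples`` (or
    exact pool fractions for the enumeration oracle) and sum to 1 exactly.
    ``d_nearest_nontarget`` is ``None`` on set-size-1 trials, where no swap
    is possible and ``p_misbind_hat`` is fixed at 0.
    """

    trial_id: int
    p_target_hat: float
    p_misbind_hat: float
    p_guess_hat: float
    n_resamples: int
    d_target: float
    d_nearest_nontarget: Optional[float]

    def __post_init__(self) -> None:
        probs = (self.p_target_hat, self.p_misbind_hat, self.p_guess_hat)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        if self.d_target < 0:
            raise ValueError("d_target must be non-negative")


class NonTargetPool:
    """Non-target locations collected from the other trials of a session.

    Each point carries the trial it came from, so that a trial being
    classified never competes against its own non-targets.
    """

    def __init__(self, points: np.ndarray, source_trial_ids: np.ndarray):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        source_trial_ids = np.asarray(source_trial_ids)
        if len(points) != len(source_trial_ids):
            raise ValueError("points and source_trial_ids must align")
        if len(points) == 0:
            raise ValueError("non-target pool is empty")
        if not np.isfinite(points).all():
            raise ValueError("pool coordinates must be finite")
        self.points = points
        self.source_trial_ids = source_trial_ids

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_trials(cls, trials: Sequence[TrialSpec]) -> "NonTargetPool":
        """Collect every non-target location of a session into a pool."""
        pts, src = [], []
        for tr in trials:
            for loc in tr.nontarget_locs:
                pts.append(loc)
                src.append(tr.trial_id)
        if not pts:
            raise ValueError(
                "session has no non-target locations (no set-size-3 trials?)"
            )
        return cls(np.asarray(pts, dtype=float), np.asarray(src))

    def excluding(self, trial_id: int) -> np.ndarray:
        """Pool points not originating from ``trial_id``."""
        pts = self.points[self.source_trial_ids != trial_id]
        if len(pts) == 0:
            raise ValueError(
                f"non-target pool is empty after excluding trial {trial_id}"
            )
        return pts


def _trial_distances(
    response_loc: Sequence[float], trial: TrialSpec
) -> tuple[float, float]:
    """(d_target, d_nearest_nontarget); the latter inf for set size 1."""
    d_target = euclidean(response_loc, trial.target_loc)
    if trial.nontarget_locs:
        d_nn = min(euclidean(response_loc, nt) for nt in trial.nontarget_locs)
    else:
        d_nn = math.inf
    return d_target, d_nn


def _categorise(
    d_target: float, d_nn: float, d_pool: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (target, misbind, guess) per pool distance.

    Ties favour target over misbind over guess.
    """
    if d_target <= d_nn:
        target = d_target <= d_pool
        misbind = np.zeros_like(target)
    else:
        target = np.zeros(len(d_pool), dtype=bool)
        misbind = d_nn <= d_pool
    guess = ~(target | misbind)
    return target, misbind, guess


def classify_trial(
    response_loc: Sequence[float],
    trial: TrialSpec,
    pool: NonTargetPool,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    rng: Optional[np.random.Generator] = None,
) -> ClassificationResult:
    """Monte-Carlo classification of one localisation response.

    Per resample one pool point is drawn uniformly with replacement from the
    other trials' non-targets and competes against the (fixed) distances to
    the target and the closest displayed non-target; category counts over
    ``n_resamples`` give the probabilities.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    rx, ry = float(response_loc[0]), float(response_loc[1])
    if not (math.isfinite(rx) and math.isfinite(ry)):
        raise ValueError("response coordinates must be finite")

    allowed = pool.excluding(trial.trial_id)
    d_target, d_nn = _trial_distances((rx, ry), trial)

    idx = rng.integers(0, len(allowed), size=n_resamples)
    diff = allowed[idx] - np.array([rx, ry])
    d_rand = np.hypot(diff[:, 0], diff[:, 1])
    t_mask, m_mask, _ = _categorise(d_target, d_nn, d_rand)
    n_t = int(t_mask.sum())
    n_m = int(m_mask.sum())
    n_g = n_resamples - n_t - n_m
    return ClassificationResult(
        trial_id=trial.trial_id,
        p_target_hat=n_t / n_resamples,
        p_misbind_hat=n_m / n_resamples,
        p_guess_hat=n_g / n_resamples,
        n_resamples=n_resamples,
        d_target=d_target,
        d_nearest_nontarget=None if math.isinf(d_nn) else d_nn,
    )


def classify_trial_exact(
    response_loc: Sequence[float],
    trial: TrialSpec,
    pool: NonTargetPool,
) -> ClassificationResult:
    """Exact expectation of the resampling scheme by pool enumeration.

    The guessing probability is the fraction of eligible pool points strictly
    nearer to the response than both the target and the closest displayed
    non-target; the remaining mass goes to whichever of those two is nearer
    (target on ties).  Deterministic, and the limit of
    :func:`classify_trial` as ``n_resamples`` grows.
    """
    rx, ry = float(response_loc[0]), float(response_loc[1])
    if not (math.isfinite(rx) and math.isfinite(ry)):
        raise ValueError("response coordinates must be finite")
    allowed = pool.excluding(trial.trial_id)
    d_target, d_nn = _trial_distances((rx, ry), trial)
    diff = allowed - np.array([rx, ry])
    d_pool = np.hypot(diff[:, 0], diff[:, 1])
    t_mask, m_mask, _ = _categorise(d_target, d_nn, d_pool)
    n = len(allowed)
    p_t = t_mask.sum() / n
    p_m = m_mask.sum() / n
    return ClassificationResult(
        trial_id=trial.trial_id,
        p_target_hat=float(p_t),
        p_misbind_hat=float(p_m),
        p_guess_hat=float(1.0 - p_t - p_m),
        n_resamples=n,
        d_target=d_target,
        d_nearest_nontarget=None if math.isinf(d_nn) else d_nn,
    )


def participant_rng(
    master_seed: int, participant_id: str
) -> np.random.Generator:
    """Per-participant generator derived from a master seed.

    The stream depends only on the master seed and the participant id, so
    classification results do not depend on the order in which participants
    are processed.
    """
    tag = zlib.crc32(str(participant_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def classify_session(
    record_or_trials: Union[ParticipantRecord, Sequence[tuple[TrialSpec, TrialResponse]]],
    n_resamples: int = DEFAULT_N_RESAMPLES,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    include_incorrect: bool = False,
    exact: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every eligible trial of one session.

    By default, trials on which the wrong item was identified are excluded
    before classification.  Returns a per-trial table and a per-condition
    summary of mean classified probabilities; a condition with no eligible
    trials appears with NaN means (missing, not zero).

    Parameters
    ----------
    record_or_trials
        A :class:`ParticipantRecord` or a list of (TrialSpec, TrialResponse).
    n_resamples
        Resamples per trial; ignored in ``exact`` mode.
    rng, seed
        Randomness for the Monte-Carlo mode.  For a
        :class:`ParticipantRecord` with ``seed`` given, the stream is derived
        per participant (see :func:`participant_rng`).
    include_incorrect
        Classify identification-incorrect trials too (sensitivity analysis).
    exact
        Use the deterministic pool-enumeration oracle instead of resampling.
    """
    if isinstance(record_or_trials, ParticipantRecord):
        pairs = record_or_trials.trials
        pid = record_or_trials.participant_id
    else:
        pairs = list(record_or_trials)
        pid = None
    if len(pairs) < 2:
        raise ValueError("need at least 2 trials to form a non-target pool")
    if rng is None and not exact:
        if seed is not None and pid is not None:
            rng = participant_rng(seed, pid)
        else:
            rng = np.random.default_rng(seed)

    trials = [t for t, _ in pairs]
    pool = NonTargetPool.from_trials(trials)

    rows = []
    n_excluded = 0
    for trial, resp in pairs:
        if not resp.identification_correct and not include_incorrect:
            n_excluded += 1
            continue
        if exact:
            res = classify_trial_exact(resp.response_loc, trial, pool)
        else:
            res = classify_trial(resp.response_loc, trial, pool,
                                 n_resamples=n_resamples, rng=rng)
        rows.append(
            {
                "participant_id": pid,
                "trial_id": trial.trial_id,
                "set_size": trial.set_size,
                "delay_s": trial.delay_s,
                "identification_correct": resp.identification_correct,
                "p_target_hat": res.p_target_hat,
                "p_misbind_hat": res.p_misbind_hat,
                "p_guess_hat": res.p_guess_hat,
                "d_target": res.d_target,
                "d_nearest_nontarget": res.d_nearest_nontarget,
                "n_resamples": res.n_resamples,
            }
        )
    per_trial = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "trial_id", "set_size", "delay_s",
            "identification_correct", "p_target_hat", "p_misbind_hat",
            "p_guess_hat", "d_target", "d_nearest_nontarget", "n_resamples",
        ],
    )

    cond_rows = []
    for set_size, delay in CONDITIONS:
        sub = per_trial[
            (per_trial["set_size"] == set_size) & (per_trial["delay_s"] == delay)
        ]
        cond_rows.append(
            {
                "participant_id": pid,
                "set_size": set_size,
                "delay_s": delay,
                "n_classified": len(sub),
                "mean_p_target": sub["p_target_hat"].mean() if len(sub) else np.nan,
                "mean_p_misbind": sub["p_misbind_hat"].mean() if len(sub) else np.nan,
                "mean_p_guess": sub["p_guess_hat"].mean() if len(sub) else np.nan,
            }
        )
    per_condition = pd.DataFrame(cond_rows)
    return per_trial, per_condition
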
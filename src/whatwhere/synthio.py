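"""Synthetic "What was where?" sessions and cohorts.

The task: one or three fractal items appear on a touch screen, and after a
short retention delay the participant (i) picks the studied item over a novel
foil (identification) and (ii) drags it to its remembered location
(localisation).  This module generates trial schedules with the task's
geometry, simulates responses under a known target / misbind / guess mixture,
and builds multi-group cohorts with covariates (VVIQ, age, ACE, regional
brain volumes) — so every downstream stage can be validated against ground
truth.

Responses are generated from a three-component mixture:

* ``target``  — report the target's location plus isotropic Gaussian noise,
* ``misbind`` — report a (uniformly chosen) non-target's location plus the
  same noise (a swap error; only possible when more than one item is shown),
* ``guess``   — a uniform draw over the whole screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ScreenSpec",
    "TrialSpec",
    "TrialResponse",
    "MixtureParams",
    "GroupSpec",
    "CohortSpec",
    "ParticipantRecord",
    "PlacementError",
    "generate_schedule",
    "simulate_response",
    "simulate_session",
    "simulate_cohort",
    "healthy_cohort_spec",
    "clinical_cohort_spec",
    "SET_SIZES",
    "DELAYS_S",
    "CONDITIONS",
    "REGIONS",
]

#: Set sizes and delays of the 2x2 within-subject design.
SET_SIZES = (1, 3)
DELAYS_S = (1.0, 4.0)
CONDITIONS = tuple((s, d) for s in SET_SIZES for d in DELAYS_S)

#: Bilateral regions carried as volume covariates (mm^3).
REGIONS = (
    "hippocampus",
    "amygdala",
    "v1",
    "m1",
    "fusiform",
    "ca1",
    "ca3",
    "ca4",
    "gc_ml_dg",
)

COMPONENTS = ("target", "misbind", "guess")


class PlacementError(RuntimeError):
    """Raised when items cannot be placed at the required separation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenSpec:
    """Touch-screen geometry in pixels.

    Defaults describe the 1536 x 2048 tablet matrix the task runs on, with a
    100 px placement margin and a 200 px minimum separation between displayed
    items so that anchors stay distinguishable for the classifier.
    """

    width_px: int = 1536
    height_px: int = 2048
    margin_px: float = 100.0
    min_separation_px: float = 200.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if not 0 <= self.margin_px < min(self.width_px, self.height_px) / 2:
            raise ValueError("margin_px must lie in [0, min(width, height)/2)")
        if self.min_separation_px < 0:
            raise ValueError("min_separation_px must be non-negative")

    @property
    def diagonal_px(self) -> float:
        """Maximum possible localisation error (2560 px for the default)."""
        return math.hypot(self.width_px, self.height_px)

    def contains(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.width_px and 0.0 <= y <= self.height_px

    def placement_bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the admissible item-placement box."""
        m = self.margin_px
        return m, self.width_px - m, m, self.height_px - m


@dataclass(frozen=True)
class TrialSpec:
    """Geometry and condition of one memory trial."""

    trial_id: int
    set_size: int
    delay_s: float
    target_id: int
    target_loc: tuple[float, float]
    nontarget_locs: tuple[tuple[float, float], ...]
    foil_id: int

    def __post_init__(self) -> None:
        if self.set_size not in SET_SIZES:
            raise ValueError(f"set_size must be one of {SET_SIZES}")
        if float(self.delay_s) not in DELAYS_S:
            raise ValueError(f"delay_s must be one of {DELAYS_S}")
        if len(self.nontarget_locs) != self.set_size - 1:
            raise ValueError("need set_size - 1 non-target locations")
        if self.foil_id == self.target_id:
            raise ValueError("foil must be distinct from the target")

    @property
    def item_locs(self) -> tuple[tuple[float, float], ...]:
        return (self.target_loc,) + self.nontarget_locs


@dataclass(frozen=True)
class TrialResponse:
    """Observed behaviour on one trial.

    ``true_component`` is simulation ground truth and is ``None`` for real
    data.
    """

    trial_id: int
    chosen_id: int
    identification_correct: bool
    response_loc: tuple[float, float]
    rt_s: float
    true_component: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rt_s <= 0:
            raise ValueError("rt_s must be positive")
        if self.true_component is not None and self.true_component not in COMPONENTS:
            raise ValueError(f"true_component must be one of {COMPONENTS}")


@dataclass(frozen=True)
class MixtureParams:
    """Generative response model for one participant (or one condition).

    Parameters
    ----------
    p_target, p_misbind, p_guess
        Mixture weights; must sum to 1.  ``p_misbind`` can only be expressed
        on set-size-3 trials; on set-size-1 trials its mass is reallocated
        proportionally to the remaining components.
    sigma_px
        SD of the isotropic 2-D Gaussian placement noise, in pixels.
    p_identify
        Probability of choosing the studied item over the foil in the
        two-alternative identification stage (chance = 0.5).
    rt_mu_log, rt_sigma_log
        Location/scale of the log-normal identification reaction time (s).
    """

    p_target: float
    p_misbind: float
    p_guess: float
    sigma_px: float = 100.0
    p_identify: float = 0.9
    rt_mu_log: float = math.log(1.8)
    rt_sigma_log: float = 0.35

    def __post_init__(self) -> None:
        w = (self.p_target, self.p_misbind, self.p_guess)
        if any(not 0.0 <= p <= 1.0 for p in w):
            raise ValueError("mixture weights must lie in [0, 1]")
        if abs(sum(w) - 1.0) > 1e-12:
            raise ValueError("p_target + p_misbind + p_guess must equal 1")
        if self.sigma_px < 0:
            raise ValueError("sigma_px must be non-negative")
        if not 0.5 <= self.p_identify <= 1.0:
            raise ValueError("p_identify must lie in [0.5, 1]")
        if self.rt_sigma_log < 0:
            raise ValueError("rt_sigma_log must be non-negative")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.p_target, self.p_misbind, self.p_guess)

    def effective_weights(self, set_size: int) -> tuple[float, float, float]:
        """Weights realisable at a given set size.

        With a single displayed item no swap is possible: the misbinding mass
        is reallocated proportionally to target and guess (equally when both
        are zero).
        """
        if set_size > 1 or self.p_misbind == 0.0:
            return self.weights
        rest = self.p_target + self.p_guess
        if rest <= 0.0:
            return (0.5, 0.0, 0.5)
        scale = 1.0 / rest
        return (self.p_target * scale, 0.0, self.p_guess * scale)


# ---------------------------------------------------------------------------
# Schedule generation
# ---------------------------------------------------------------------------


def _place_items(
    n_trials: int,
    n_items: int,
    screen: ScreenSpec,
    rng: np.random.Generator,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Rejection-sample (n_trials, n_items, 2) item positions.

    All positions lie inside the screen minus its margin; within a trial all
    pairwise distances are >= ``min_separation_px``.
    """
    xmin, xmax, ymin, ymax = screen.placement_bounds()
    if xmax <= xmin or ymax <= ymin:
        raise PlacementError("margin leaves no admissible placement area")
    if n_items > 1:
        # crude feasibility guard: items at min separation must fit in the box
        if screen.min_separation_px > math.hypot(xmax - xmin, ymax - ymin):
            raise PlacementError(
                "min_separation_px exceeds the admissible box diagonal"
            )
    out = np.empty((n_trials, n_items, 2))
    pending = np.arange(n_trials)
    for _ in range(max_rounds):
        if pending.size == 0:
            return out
        pts = np.empty((pending.size, n_items, 2))
        pts[..., 0] = rng.uniform(xmin, xmax, (pending.size, n_items))
        pts[..., 1] = rng.uniform(ymin, ymax, (pending.size, n_items))
        if n_items == 1:
            ok = np.ones(pending.size, dtype=bool)
        else:
            diff = pts[:, :, None, :] - pts[:, None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(n_items, k=1)
            ok = (dist[:, iu[0], iu[1]] >= screen.min_separation_px).all(axis=1)
        out[pending[ok]] = pts[ok]
        pending = pending[~ok]
    raise PlacementError(
        f"could not place {n_items} items at separation "
        f"{screen.min_separation_px} px after {max_rounds} rounds"
    )


def generate_schedule(
    n_per_condition: Optional[int] = None,
    screen: ScreenSpec = ScreenSpec(),
    seed: int | np.random.SeedSequence | None = 0,
    short_version: bool = False,
    start_trial_id: int = 0,
    start_item_id: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[TrialSpec]:
    """Generate a randomised, condition-balanced trial schedule.

    The standard session has 30 trials in each of the 4 conditions
    (set size {1, 3} x delay {1, 4} s) for 120 trials total; the short
    variant uses 20 per condition (80 trials; the task adds 7 introductory
    trials on top, which are not part of the analysed schedule).

    Item identifiers (target, displayed non-targets and the novel foil) are
    drawn without repetition across the whole schedule.

    Parameters
    ----------
    n_per_condition
        Trials per condition.  Defaults to 20 when ``short_version`` else 30.
    screen
        Geometry and placement constraints.
    seed
        Seed for the schedule RNG; ignored when ``rng`` is given.
    short_version
        Select the 87-trial task variant's per-condition count.
    start_trial_id, start_item_id
        Offsets for identifier counters (useful when concatenating blocks).
    """
    if n_per_condition is None:
        n_per_condition = 20 if short_version else 30
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    conds = np.repeat(np.arange(len(CONDITIONS)), n_per_condition)
    conds = rng.permutation(conds)
    n_total = conds.size

    # Place all items for all trials up front, batched by set size.
    locs: list[Optional[np.ndarray]] = [None] * n_total
    for ci, (set_size, _) in enumerate(CONDITIONS):
        idx = np.flatnonzero(conds == ci)
        if idx.size == 0:
            continue
        pts = _place_items(idx.size, set_size, screen, rng)
        for k, t in enumerate(idx):
            locs[t] = pts[k]

    trials: list[TrialSpec] = []
    item_id = start_item_id
    for t in range(n_total):
        set_size, delay = CONDITIONS[conds[t]]
        pts = locs[t]
        assert pts is not None
        target_idx = int(rng.integers(set_size))
        item_ids = list(range(item_id, item_id + set_size + 1))
        item_id += set_size + 1
        target_id = item_ids[target_idx]
        foil_id = item_ids[-1]
        nontargets = tuple(
            (float(pts[i, 0]), float(pts[i, 1]))
            for i in range(set_size)
            if i != target_idx
        )
        trials.append(
            TrialSpec(
                trial_id=start_trial_id + t,
                set_size=set_size,
                delay_s=float(delay),
                target_id=target_id,
                target_loc=(float(pts[target_idx, 0]), float(pts[target_idx, 1])),
                nontarget_locs=nontargets,
                foil_id=foil_id,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# Response simulation
# ---------------------------------------------------------------------------


def _truncated_gaussian(
    anchors: np.ndarray,
    sigma: float,
    screen: ScreenSpec,
    rng: np.random.Generator,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Anchor + N(0, sigma^2 I) noise, resampled until inside the screen."""
    out = anchors + rng.normal(0.0, sigma, anchors.shape)
    if sigma == 0.0:
        return out
    for _ in range(max_rounds):
        bad = ~(
            (out[:, 0] >= 0)
            & (out[:, 0] <= screen.width_px)
            & (out[:, 1] >= 0)
            & (out[:, 1] <= screen.height_px)
        )
        if not bad.any():
            return out
        out[bad] = anchors[bad] + rng.normal(0.0, sigma, (int(bad.sum()), 2))
    raise RuntimeError("placement noise failed to land inside the screen")


def simulate_session(
    trials: Sequence[TrialSpec],
    params: MixtureParams,
    rng: np.random.Generator,
    screen: ScreenSpec = ScreenSpec(),
    condition_params: Optional[Mapping[tuple[int, float], MixtureParams]] = None,
) -> list[TrialResponse]:
    """Simulate responses for a whole schedule (vectorised).

    ``condition_params`` optionally overrides ``params`` per
    ``(set_size, delay_s)`` condition; misbinding mass is reallocated on
    set-size-1 trials via :meth:`MixtureParams.effective_weights`.
    """
    n = len(trials)
    if n == 0:
        return []
    per_trial = []
    for tr in trials:
        p = params
        if condition_params is not None:
            p = condition_params.get((tr.set_size, tr.delay_s), params)
        per_trial.append(p)

    comp = np.empty(n, dtype=np.int64)
    u = rng.random(n)
    for i, (tr, p) in enumerate(zip(trials, per_trial)):
        w = np.cumsum(p.effective_weights(tr.set_size))
        comp[i] = int(np.searchsorted(w, u[i], side="right").clip(max=2))

    ident = np.empty(n, dtype=bool)
    rt = np.empty(n)
    for i, p in enumerate(per_trial):
        ident[i] = rng.random() < p.p_identify
        rt[i] = math.exp(rng.normal(p.rt_mu_log, p.rt_sigma_log))

    # anchors for target/misbind responses
    resp = np.empty((n, 2))
    anchored = np.flatnonzero(comp < 2)
    if anchored.size:
        anchors = np.empty((anchored.size, 2))
        sigmas = np.empty(anchored.size)
        for k, i in enumerate(anchored):
            tr = trials[i]
            if comp[i] == 0:
                anchors[k] = tr.target_loc
            else:
                j = int(rng.integers(len(tr.nontarget_locs)))
                anchors[k] = tr.nontarget_locs[j]
            sigmas[k] = per_trial[i].sigma_px
        # resample noise per distinct sigma (usually one or a handful)
        for s in np.unique(sigmas):
            sel = sigmas == s
            anchors[sel] = _truncated_gaussian(anchors[sel], float(s), screen, rng)
        resp[anchored] = anchors
    guesses = np.flatnonzero(comp == 2)
    if guesses.size:
        resp[guesses, 0] = rng.uniform(0, screen.width_px, guesses.size)
        resp[guesses, 1] = rng.uniform(0, screen.height_px, guesses.size)

    return [
        TrialResponse(
            trial_id=tr.trial_id,
            chosen_id=tr.target_id if ident[i] else tr.foil_id,
            identification_correct=bool(ident[i]),
            response_loc=(float(resp[i, 0]), float(resp[i, 1])),
            rt_s=float(rt[i]),
            true_component=COMPONENTS[comp[i]],
        )
        for i, tr in enumerate(trials)
    ]


def simulate_response(
    trial: TrialSpec,
    params: MixtureParams,
    rng: np.random.Generator,
    screen: ScreenSpec = ScreenSpec(),
) -> TrialResponse:
    """Simulate a single trial's response under the mixture model."""
    return simulate_session([trial], params, rng, screen=screen)[0]


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Population-level description of one participant group."""

    name: str
    size: int
    mixture_mean: MixtureParams
    #: between-subject SDs for MixtureParams fields (missing fields -> 0)
    mixture_sd: Mapping[str, float] = field(default_factory=dict)
    #: additive offsets applied to the mixture on set-size-3 trials
    set_size3_effect: Mapping[str, float] = field(default_factory=dict)
    #: additive offsets applied to the mixture on 4 s-delay trials
    delay4_effect: Mapping[str, float] = field(default_factory=dict)
    vviq_mean: float = 61.6
    vviq_sd: float = 13.3
    age_mean: float = 57.7
    age_sd: float = 12.7
    ace_mean: Optional[float] = None
    ace_sd: float = 0.0
    volume_means: Mapping[str, float] = field(default_factory=dict)
    volume_sds: Mapping[str, float] = field(default_factory=dict)
    tiv_mean: Optional[float] = None
    tiv_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("group size must be >= 1")
        for name, sd in {**self.mixture_sd, "vviq": self.vviq_sd,
                         "age": self.age_sd}.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic multi-group cohort."""

    groups: tuple[GroupSpec, ...]
    #: target Pearson correlation between VVIQ and each regional volume
    vviq_volume_rho: float = 0.0
    #: pairwise volume-volume correlation; default rho^2 (one common factor)
    volume_volume_rho: Optional[float] = None
    n_per_condition: int = 30
    short_version: bool = False
    screen: ScreenSpec = ScreenSpec()
    seed: int = 0
    #: skip trial simulation (covariates only) when False
    with_trials: bool = True

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group is required")
        if not -1.0 <= self.vviq_volume_rho <= 1.0:
            raise ValueError("|vviq_volume_rho| must be <= 1")


@dataclass
class ParticipantRecord:
    """One participant: session trials plus covariates."""

    participant_id: str
    group: str
    age: float
    vviq_items: tuple[int, ...]
    ace: Optional[float] = None
    volumes: Optional[dict[str, float]] = None
    tiv: Optional[float] = None
    trials: list[tuple[TrialSpec, TrialResponse]] = field(default_factory=list)
    #: simulation ground truth (None for real data)
    true_mixture: Optional[MixtureParams] = None
    screen: ScreenSpec = ScreenSpec()

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.vviq_items)
        if len(items) != 16 or any(not 1 <= v <= 5 for v in items):
            raise ValueError("vviq_items must be 16 integers in [1, 5]")
        object.__setattr__(self, "vviq_items", items)
        if self.volumes is not None and any(v <= 0 for v in self.volumes.values()):
            raise ValueError("volumes must be positive")

    @property
    def vviq_total(self) -> int:
        return int(sum(self.vviq_items))


def _vviq_items_from_total(total: float, rng: np.random.Generator) -> tuple[int, ...]:
    """Distribute a (clipped, rounded) total score over 16 items in [1, 5]."""
    t = int(np.clip(round(total), 16, 80))
    excess = t - 16  # 0..64, spread over 16 items each holding up to 4
    base, rem = divmod(excess, 16)
    items = np.full(16, 1 + base, dtype=int)
    items[rng.permutation(16)[:rem]] += 1
    return tuple(int(v) for v in items)


def _correlation_cholesky(
    n_regions: int, rho: float, rho_vv: Optional[float]
) -> np.ndarray:
    """Cholesky factor of the (1 + n_regions) VVIQ/volume correlation matrix."""
    k = n_regions + 1
    c = np.empty((k, k))
    c.fill(rho**2 if rho_vv is None else rho_vv)
    c[0, :] = c[:, 0] = rho
    np.fill_diagonal(c, 1.0)
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "VVIQ/volume correlation matrix is not positive semi-definite; "
            "lower vviq_volume_rho or raise volume_volume_rho"
        ) from exc


_MIX_FIELDS = (
    "p_target", "p_misbind", "p_guess",
    "sigma_px", "p_identify", "rt_mu_log", "rt_sigma_log",
)


def _perturb_mixture(
    base: MixtureParams, offsets: Mapping[str, float]
) -> MixtureParams:
    """Apply additive offsets to mixture fields, then restore validity.

    Weights are clipped to [0, 1] and renormalised to the simplex;
    ``p_identify`` is clipped to [0.5, 1]; scales are clipped non-negative.
    """
    vals = {f: getattr(base, f) + offsets.get(f, 0.0) for f in _MIX_FIELDS}
    w = np.clip([vals["p_target"], vals["p_misbind"], vals["p_guess"]], 0.0, None)
    s = w.sum()
    w = w / s if s > 0 else np.array([1.0, 0.0, 0.0])
    w = w / w.sum()
    # remove any residual rounding drift on the simplex
    w[0] = max(1.0 - w[1] - w[2], 0.0)
    return MixtureParams(
        p_target=float(w[0]),
        p_misbind=float(w[1]),
        p_guess=float(w[2]),
        sigma_px=float(max(vals["sigma_px"], 0.0)),
        p_identify=float(np.clip(vals["p_identify"], 0.5, 1.0)),
        rt_mu_log=float(vals["rt_mu_log"]),
        rt_sigma_log=float(max(vals["rt_sigma_log"], 0.0)),
    )


def simulate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Simulate a full cohort: sessions plus covariates.

    Per-participant mixture parameters are drawn from the group's
    between-subject distribution; VVIQ and regional volumes are drawn jointly
    from a multivariate normal whose correlation structure targets
    ``spec.vviq_volume_rho`` (so the sample VVIQ-volume correlation converges
    to rho as the cohort grows).  Fully reproducible from ``spec.seed``.
    """
    master = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(master)

    records: list[ParticipantRecord] = []
    for group in spec.groups:
        regions = tuple(group.volume_means)
        chol = (
            _correlation_cholesky(len(regions), spec.vviq_volume_rho,
                                  spec.volume_volume_rho)
            if regions
            else None
        )
        for i in range(group.size):
            pid = f"{group.name}-{i:03d}"
            age = float(rng.normal(group.age_mean, group.age_sd))
            ace = None
            if group.ace_mean is not None:
                ace = float(np.clip(round(rng.normal(group.ace_mean, group.ace_sd)),
                                    0, 100))
            # joint VVIQ + volumes draw
            if chol is not None:
                z = chol @ rng.standard_normal(len(regions) + 1)
                vviq_latent = group.vviq_mean + group.vviq_sd * z[0]
                volumes = {}
                for j, r in enumerate(regions):
                    v = group.volume_means[r] + group.volume_sds.get(r, 0.0) * z[j + 1]
                    volumes[r] = float(max(v, 1.0))
            else:
                vviq_latent = float(rng.normal(group.vviq_mean, group.vviq_sd))
                volumes = None
            vviq_items = _vviq_items_from_total(vviq_latent, rng)
            tiv = None
            if group.tiv_mean is not None:
                tiv = float(max(rng.normal(group.tiv_mean, group.tiv_sd), 1.0))

            subject_offsets = {
                f: rng.normal(0.0, sd)
                for f, sd in group.mixture_sd.items()
                if sd > 0
            }
            base = _perturb_mixture(group.mixture_mean, subject_offsets)
            condition_params = {}
            for set_size, delay in CONDITIONS:
                off: dict[str, float] = {}
                if set_size == 3:
                    for f, v in group.set_size3_effect.items():
                        off[f] = off.get(f, 0.0) + v
                if delay == 4.0:
                    for f, v in group.delay4_effect.items():
                        off[f] = off.get(f, 0.0) + v
                condition_params[(set_size, delay)] = (
                    _perturb_mixture(base, off) if off else base
                )

            trials: list[tuple[TrialSpec, TrialResponse]] = []
            if spec.with_trials:
                sched = generate_schedule(
                    n_per_condition=spec.n_per_condition,
                    screen=spec.screen,
                    short_version=spec.short_version,
                    rng=rng,
                )
                responses = simulate_session(
                    sched, base, rng, screen=spec.screen,
                    condition_params=condition_params,
                )
                trials = list(zip(sched, responses))

            records.append(
                ParticipantRecord(
                    participant_id=pid,
                    group=group.name,
                    age=age,
                    vviq_items=vviq_items,
                    ace=ace,
                    volumes=volumes,
                    tiv=tiv,
                    trials=trials,
                    true_mixture=base,
                    screen=spec.screen,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Presets (the study conditions)
# ---------------------------------------------------------------------------

# Table-derived covariate distributions for the clinical groups; memory
# mixture parameters are chosen to reproduce the qualitative group pattern
# (marked swap-error and guessing elevation in the amnestic group, essentially
# preserved performance in the disease-control group).

_CONTROL_VOLUMES = {
    "hippocampus": (7318.74, 719.68),
    "amygdala": (2525.51, 433.75),
    "v1": (13971.44, 2750.19),
    "m1": (23306.06, 1932.36),
    "fusiform": (18959.33, 1931.04),
    "ca1": (1259.72, 121.30),
    "ca3": (429.15, 39.95),
    "ca4": (500.07, 38.95),
    "gc_ml_dg": (570.31, 48.74),
}
_AD_VOLUMES = {
    "hippocampus": (6017.07, 733.82),
    "amygdala": (2172.32, 316.71),
    "v1": (14002.82, 2072.93),
    "m1": (23796.44, 2451.65),
    "fusiform": (17294.94, 1807.01),
    "ca1": (1053.54, 136.94),
    "ca3": (318.52, 57.81),
    "ca4": (419.10, 41.25),
    "gc_ml_dg": (483.15, 48.24),
}
_PD_VOLUMES = {
    "hippocampus": (7330.87, 785.24),
    "amygdala": (2724.49, 363.41),
    "v1": (13706.53, 1978.12),
    "m1": (23268.03, 2700.09),
    "fusiform": (18653.62, 1843.25),
    "ca1": (1298.42, 144.72),
    "ca3": (422.29, 43.95),
    "ca4": (504.87, 42.49),
    "gc_ml_dg": (583.62, 47.39),
}

_HEALTHY_MIXTURE = MixtureParams(
    p_target=0.78, p_misbind=0.08, p_guess=0.14,
    sigma_px=100.0, p_identify=0.92, rt_mu_log=math.log(1.8), rt_sigma_log=0.35,
)
_AD_MIXTURE = MixtureParams(
    p_target=0.55, p_misbind=0.20, p_guess=0.25,
    sigma_px=130.0, p_identify=0.78, rt_mu_log=math.log(2.8), rt_sigma_log=0.40,
)
_PD_MIXTURE = MixtureParams(
    p_target=0.74, p_misbind=0.08, p_guess=0.18,
    sigma_px=105.0, p_identify=0.90, rt_mu_log=math.log(1.9), rt_sigma_log=0.35,
)

_MIXTURE_SD = {
    "p_target": 0.08, "p_misbind": 0.04, "p_guess": 0.05,
    "sigma_px": 20.0, "p_identify": 0.05, "rt_mu_log": 0.20,
}
#: three items to bind instead of one: harder on every measure
_SET_SIZE3_EFFECT = {
    "p_target": -0.15, "p_misbind": 0.07, "p_guess": 0.08,
    "p_identify": -0.10, "sigma_px": 20.0, "rt_mu_log": 0.25,
}
#: longer retention: modest decay, mostly into guessing
_DELAY4_EFFECT = {
    "p_target": -0.05, "p_misbind": 0.02, "p_guess": 0.03,
    "p_identify": -0.03, "rt_mu_log": 0.10,
}

_TIV = (1.45e6, 1.3e5)


def _group(name: str, size: int, mixture: MixtureParams, vviq: tuple[float, float],
           age: tuple[float, float], ace: tuple[float, float],
           volumes: Mapping[str, tuple[float, float]]) -> GroupSpec:
    return GroupSpec(
        name=name,
        size=size,
        mixture_mean=mixture,
        mixture_sd=_MIXTURE_SD,
        set_size3_effect=_SET_SIZE3_EFFECT,
        delay4_effect=_DELAY4_EFFECT,
        vviq_mean=vviq[0], vviq_sd=vviq[1],
        age_mean=age[0], age_sd=age[1],
        ace_mean=ace[0], ace_sd=ace[1],
        volume_means={r: mv[0] for r, mv in volumes.items()},
        volume_sds={r: mv[1] for r, mv in volumes.items()},
        tiv_mean=_TIV[0], tiv_sd=_TIV[1],
    )


def healthy_cohort_spec(
    size: int = 229,
    seed: int = 0,
    n_per_condition: int = 30,
    with_volumes: bool = True,
    with_trials: bool = True,
) -> CohortSpec:
    """Healthy single-group cohort.

    Covariates follow the healthy-sample demographics (age 57.7 +/- 12.7,
    VVIQ 61.6 +/- 13.3, ACE 97.2 +/- 2.7); volumes follow the elderly-control
    distributions with a VVIQ-volume correlation of 0.35.  Memory mixture
    parameters are independent of VVIQ by construction, so the cohort carries
    no built-in imagery-memory association.
    """
    g = _group("control", size, _HEALTHY_MIXTURE, (61.61, 13.31),
               (57.70, 12.68), (97.15, 2.65),
               _CONTROL_VOLUMES if with_volumes else {})
    return CohortSpec(
        groups=(g,), vviq_volume_rho=0.35, n_per_condition=n_per_condition,
        seed=seed, with_trials=with_trials,
    )


def clinical_cohort_spec(
    n_per_group: int = 19,
    seed: int = 0,
    n_per_condition: int = 30,
    vviq_unchanged: bool = False,
) -> CohortSpec:
    """Three-group clinical cohort: elderly controls, AD and PD patients.

    Covariate distributions follow the reported group demographics and
    regional volumes; the AD group has elevated misbinding and guessing,
    reduced identification and hippocampal (and subfield) volumes, while the
    PD group tracks the controls on memory and volumes.

    With ``vviq_unchanged`` the AD and PD groups inherit the control group's
    VVIQ distribution — the strict "memory impaired, imagery intact"
    configuration.
    """
    ctrl_vviq = (61.16, 9.21)
    ad_vviq = ctrl_vviq if vviq_unchanged else (63.26, 11.25)
    pd_vviq = ctrl_vviq if vviq_unchanged else (69.32, 10.45)
    groups = (
        _group("control", n_per_group, _HEALTHY_MIXTURE, ctrl_vviq,
               (70.37, 8.32), (96.58, 2.95), _CONTROL_VOLUMES),
        _group("ad", n_per_group, _AD_MIXTURE, ad_vviq,
               (71.11, 9.99), (74.58, 13.11), _AD_VOLUMES),
        _group("pd", n_per_group, _PD_MIXTURE, pd_vviq,
               (69.21, 7.34), (95.47, 2.37), _PD_VOLUMES),
    )
    return CohortSpec(
        groups=groups, vviq_volume_rho=0.35,
        n_per_condition=n_per_condition, seed=seed,
    )
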
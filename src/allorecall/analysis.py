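"""Bias statistics for spatial-recall sessions.

For each participant, four summary statistics are computed over the
analysable trials: the mean distance from the prior mode to (1) targets
and (2) responses, and the mean distance from the local beacons to (3)
targets and (4) responses.  Subtracting the response statistic from the
matching target statistic gives two bias scores:

* ``prior_mode_bias``  = (1) - (2):  positive when responses sit nearer
  the prior mode than the targets did (evidence of prior use);
* ``beacon_bias``      = (3) - (4):  positive when responses sit nearer
  the local beacons than the targets did.

Per-condition inference uses a one-sample, one-tailed t-test across
participants, with Cohen's d = mean / SD and a two-sided 95% t-interval.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .task import BeaconLayout, Condition, PriorSpec, Session

__all__ = [
    "ResponseSet",
    "SummaryStats",
    "BiasScores",
    "TestResult",
    "distance_to_prior_mode",
    "nearest_beacon",
    "distance_to_beacon_stat",
    "exclude_outlier_trials",
    "participant_summary",
    "condition_test",
    "min_error_pairing",
    "centroid_distance",
]

#: Conditions whose targets concentrate near the left beacon, where the
#: outlier-exclusion rule can apply.
LEFT_BEACON_CONDITIONS = ("beacon_normal", "beacon_donut", "offset")


@dataclass(frozen=True)
class ResponseSet:
    """Per-trial response triplets aligned to a session.

    ``responses`` has shape (n_trials, 3, 2); ``excluded`` is a boolean
    flag per trial, set only by :func:`exclude_outlier_trials`.
    """

    participant_id: str
    condition_name: str
    responses: np.ndarray
    excluded: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.responses, dtype=float)
        if r.ndim != 3 or r.shape[1:] != (3, 2):
            raise ValueError("responses must have shape (n_trials, 3, 2)")
        e = np.asarray(self.excluded, dtype=bool)
        if e.shape != (r.shape[0],):
            raise ValueError("excluded must be one flag per trial")
        object.__setattr__(self, "responses", r)
        object.__setattr__(self, "excluded", e)

    @classmethod
    def from_responses(cls, session: Session, responses: np.ndarray) -> "ResponseSet":
        r = np.asarray(responses, dtype=float)
        if r.shape[0] != len(session.trials):
            raise ValueError("response trial count does not match the session")
        return cls(
            participant_id=session.participant_id,
            condition_name=session.condition.name,
            responses=r,
            excluded=np.zeros(r.shape[0], dtype=bool),
        )


@dataclass(frozen=True)
class SummaryStats:
    """The four per-participant summary statistics (meters)."""

    d_mode_targets: float
    d_mode_responses: float
    d_beacon_targets: float
    d_beacon_responses: float


@dataclass(frozen=True)
class BiasScores:
    """The two derived bias scores (meters); positive = pulled toward
    the feature."""

    prior_mode_bias: float
    beacon_bias: float


@dataclass(frozen=True)
class TestResult:
    """Condition-level one-tailed one-sample t-test output."""

    t: float
    df: int
    p_one_tailed: float
    mean_diff: float
    cohens_d: float
    ci95: tuple[float, float]
    n: int


def distance_to_prior_mode(points, prior: PriorSpec):
    """Distance from each point to the prior's modal locus.

    Gaussian priors: Euclidean distance to the prior mean.  Ring priors:
    the mode is a circle of radius ``ring_radius_mean`` about the ring
    center, so the distance is |distance-to-center - ring radius| (the
    distance to the nearest point on that circle).

    Accepts a single point or an (n, 2) array; returns matching shape.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d = pts - prior.center_point
    r = np.hypot(d[:, 0], d[:, 1])
    if prior.kind == "gaussian":
        out = r
    else:
        out = np.abs(r - prior.ring_radius_mean)
    return float(out[0]) if single else out


def nearest_beacon(point, layout: BeaconLayout):
    """Index of the nearest beacon; ties broken by lowest index.

    Accepts a single point (returns int) or an (n, 2) array (returns an
    int array).
    """
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d = np.linalg.norm(pts[:, None, :] - layout.beacon_array[None, :, :], axis=2)
    idx = np.argmin(d, axis=1)  # argmin takes the first minimum: lowest index
    return int(idx[0]) if single else idx


def distance_to_beacon_stat(points, condition: Condition):
    """The per-point "distance to the local beacons" statistic.

    For conditions clustered near the left beacon (all but
    ``non_beacon_normal``) this is the Euclidean distance to the beacon
    at (-0.65, 0).  For ``non_beacon_normal`` the entire beacon array
    lies leftward of the targets, so the statistic is the signed x-axis
    difference from x = 0: larger means farther from the array, and a
    drop from targets to responses means a leftward (beacon-ward) bias.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if condition.name == "non_beacon_normal":
        out = pts[:, 0].copy()
    else:
        out = np.linalg.norm(pts - condition.layout.left_beacon, axis=1)
    return float(out[0]) if single else out


def exclude_outlier_trials(
    session: Session,
    responses: ResponseSet,
    target_rule: str = "all",
    scope: str = "left_beacon_conditions",
) -> tuple[ResponseSet, int]:
    """Flag gross mis-localizations relative to the beacon array.

    A trial is excluded when its targets are nearest the left beacon but
    at least one response lands nearest one of the other two beacons —
    i.e. the response crossed over to the wrong landmark entirely.

    ``target_rule`` controls how many targets must be nearest the left
    beacon for the rule's premise ("all", the default, or "any").
    ``scope`` restricts the rule to conditions whose targets concentrate
    near the left beacon ("left_beacon_conditions", default) or applies
    it everywhere ("all").  Returns a new ResponseSet with flags set and
    the number of newly excluded trials.
    """
    if responses.responses.shape[0] != len(session.trials):
        raise ValueError("responses are not aligned to the session")
    if target_rule not in ("all", "any"):
        raise ValueError("target_rule must be 'all' or 'any'")
    if scope not in ("left_beacon_conditions", "all"):
        raise ValueError("scope must be 'left_beacon_conditions' or 'all'")

    excluded = responses.excluded.copy()
    applies = scope == "all" or session.condition.name in LEFT_BEACON_CONDITIONS
    n_new = 0
    if applies:
        layout = session.condition.layout
        agg = np.all if target_rule == "all" else np.any
        for i, trial in enumerate(session.trials):
            t_near = nearest_beacon(trial.targets, layout)
            if not agg(t_near == 0):
                continue
            r_near = nearest_beacon(responses.responses[i], layout)
            if np.any(r_near != 0) and not excluded[i]:
                excluded[i] = True
                n_new += 1
    return replace(responses, excluded=excluded), n_new


def participant_summary(
    session: Session,
    responses: ResponseSet,
    halves: tuple[str, ...] = ("second",),
) -> tuple[SummaryStats, BiasScores]:
    """Compute the four summary statistics and two bias scores.

    Averages run over non-excluded trials of the requested session
    halves; by default only the second half, where the prior has already
    been fully exhibited, is analysed.  Raises ``ValueError`` when no
    analysable trial remains.
    """
    if responses.responses.shape[0] != len(session.trials):
        raise ValueError("responses are not aligned to the session")
    keep_t, keep_r = [], []
    for i, trial in enumerate(session.trials):
        if trial.half in halves and not responses.excluded[i]:
            keep_t.append(trial.targets)
            keep_r.append(responses.responses[i])
    if not keep_t:
        raise ValueError("no analysable trials (all excluded or wrong half)")
    targets = np.concatenate(keep_t)
    resp = np.concatenate(keep_r)

    prior = session.condition.prior
    stats_ = SummaryStats(
        d_mode_targets=float(np.mean(distance_to_prior_mode(targets, prior))),
        d_mode_responses=float(np.mean(distance_to_prior_mode(resp, prior))),
        d_beacon_targets=float(
            np.mean(distance_to_beacon_stat(targets, session.condition))
        ),
        d_beacon_responses=float(
            np.mean(distance_to_beacon_stat(resp, session.condition))
        ),
    )
    biases = BiasScores(
        prior_mode_bias=stats_.d_mode_targets - stats_.d_mode_responses,
        beacon_bias=stats_.d_beacon_targets - stats_.d_beacon_responses,
    )
    return stats_, biases


def condition_test(biases, direction: str = "greater") -> TestResult:
    """One-sample, one-tailed t-test of the per-participant bias values.

    Tests the mean against zero in the stated direction; Cohen's d is
    mean / sample SD, and the 95% CI is the conventional two-sided
    t-interval (as drawn in forest/error-bar plots).
    """
    x = np.asarray(biases, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 bias values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or np.all(x == x[0]):
        raise ValueError("bias values have zero variance")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")

    res = stats.ttest_1samp(x, 0.0, alternative=direction)
    mean = float(np.mean(x))
    df = n - 1
    half = float(stats.t.ppf(0.975, df)) * sd / np.sqrt(n)
    return TestResult(
        t=float(res.statistic),
        df=df,
        p_one_tailed=float(res.pvalue),
        mean_diff=mean,
        cohens_d=mean / sd,
        ci95=(mean - half, mean + half),
        n=n,
    )


def min_error_pairing(targets, responses) -> tuple[tuple[int, ...], float]:
    """Minimum-mean-distance assignment of 3 responses to 3 targets.

    Each trial shows three targets and collects three responses with no
    declared correspondence; of the six possible pairings, the one with
    the smallest mean paired distance is returned as
    ``(assignment, mean_distance)`` where ``assignment[i]`` is the
    response index paired with target ``i``.
    """
    t = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if t.shape != (3, 2) or r.shape != (3, 2):
        raise ValueError("expected exactly 3 targets and 3 responses")
    cost = np.linalg.norm(t[:, None, :] - r[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols), float(cost[rows, cols].mean())


def centroid_distance(targets, responses) -> float:
    """Euclidean distance between the target and response centroids."""
    t = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if t.shape != (3, 2) or r.shape != (3, 2):
        raise ValueError("expected exactly 3 targets and 3 responses")
    return float(np.linalg.norm(t.mean(axis=0) - r.mean(axis=0)))
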
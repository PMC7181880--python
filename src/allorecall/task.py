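"""Environment geometry, prior distributions, and trial-structure generation.

The simulated task takes place on a flat floor with a circle of radius
1.3 m and three identical beacons arranged in an isosceles triangle.
Target locations for a session are drawn from one of four prior
distributions (three bivariate Gaussians and one ring/"donut" prior),
truncated to the inner 98% of their probability mass.  A session has 60
trials of three targets each; the second half of the session re-uses the
90 first-half locations, randomly re-grouped into new triplets, so that
the empirical prior experienced in the first half is exactly the prior
in force for the second half.

All coordinates are in meters, with the origin at the circle center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "BeaconLayout",
    "PriorSpec",
    "Condition",
    "Trial",
    "Session",
    "CONDITION_NAMES",
    "DISPLACEMENT_FRACTIONS",
    "make_condition",
    "sample_target",
    "sample_targets",
    "build_session",
    "validate_session",
]

#: Viewpoint displacement fractions of a full turn around the circle,
#: in even steps from 1/8 to 7/8.
DISPLACEMENT_FRACTIONS: tuple[float, ...] = tuple(k / 8 for k in range(1, 8))

#: The four experimental conditions.
CONDITION_NAMES: tuple[str, ...] = (
    "beacon_normal",
    "non_beacon_normal",
    "beacon_donut",
    "offset",
)

# Mahalanobis-squared radius of the isodensity region holding 98% of a
# bivariate standard normal (chi-square with 2 df), and the central-98%
# half-width of a univariate standard normal.  These define the
# truncation supports for Gaussian and ring priors respectively.
_CHI2_98_2DF = float(stats.chi2.ppf(0.98, df=2))
_Z98 = float(stats.norm.ppf(0.99))


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValueError(f"expected a finite 2-D point, got {p!r}")
    return a


@dataclass(frozen=True)
class BeaconLayout:
    """Three identical landmarks plus the surrounding circle.

    Defaults place the beacons at (-0.65, 0), (0, 0.65) and (0, -0.65)
    inside a circle of radius 1.3 m.
    """

    beacons: tuple[tuple[float, float], ...] = (
        (-0.65, 0.0),
        (0.0, 0.65),
        (0.0, -0.65),
    )
    circle_radius: float = 1.3

    def __post_init__(self):
        if len(self.beacons) != 3:
            raise ValueError("layout must have exactly 3 beacons")

    @property
    def beacon_array(self) -> np.ndarray:
        """Beacon coordinates as a (3, 2) array."""
        return np.asarray(self.beacons, dtype=float)

    @property
    def left_beacon(self) -> np.ndarray:
        return np.asarray(self.beacons[0], dtype=float)


@dataclass(frozen=True)
class PriorSpec:
    """Parameterization of one condition's target distribution.

    ``gaussian`` priors are isotropic bivariate normals (zero covariance,
    equal per-axis SD ``axis_sd``).  ``ring`` priors are defined in polar
    coordinates about ``center``: uniform angle, normal radial distance
    with mean ``ring_radius_mean`` and SD ``ring_radius_sd``.  Targets are
    constrained to the inner ``truncation_mass`` of the distribution
    (isodensity region for Gaussians, central radial band for rings).
    """

    kind: str  # "gaussian" | "ring"
    center: tuple[float, float]
    axis_sd: float | None = None
    ring_radius_mean: float | None = None
    ring_radius_sd: float | None = None
    truncation_mass: float = 0.98

    def __post_init__(self):
        if self.kind not in ("gaussian", "ring"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        _as_point(self.center)
        if not (0.0 < self.truncation_mass <= 1.0):
            raise ValueError("truncation_mass must be in (0, 1]")
        if self.kind == "gaussian":
            if self.axis_sd is None or self.axis_sd <= 0:
                raise ValueError("gaussian prior requires axis_sd > 0")
            if self.ring_radius_mean is not None or self.ring_radius_sd is not None:
                raise ValueError("gaussian prior must not set ring fields")
        else:
            if self.ring_radius_mean is None or self.ring_radius_mean <= 0:
                raise ValueError("ring prior requires ring_radius_mean > 0")
            if self.ring_radius_sd is None or self.ring_radius_sd <= 0:
                raise ValueError("ring prior requires ring_radius_sd > 0")
            if self.axis_sd is not None:
                raise ValueError("ring prior must not set axis_sd")

    @property
    def center_point(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def mahalanobis_sq_cutoff(self) -> float:
        """Squared-Mahalanobis truncation radius for a Gaussian prior."""
        return float(stats.chi2.ppf(self.truncation_mass, df=2))

    def radial_halfwidth(self) -> float:
        """Central-band half-width in SD units for a ring prior."""
        return float(stats.norm.ppf(0.5 + self.truncation_mass / 2))

    def support_radius(self) -> float:
        """Radius about ``center`` that encloses the truncation support."""
        if self.kind == "gaussian":
            return self.axis_sd * math.sqrt(self.mahalanobis_sq_cutoff())
        return self.ring_radius_mean + self.radial_halfwidth() * self.ring_radius_sd

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the truncation support."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - self.center_point
        if self.kind == "gaussian":
            m2 = (d ** 2).sum(axis=1) / self.axis_sd ** 2
            return m2 <= self.mahalanobis_sq_cutoff()
        r = np.hypot(d[:, 0], d[:, 1])
        half = self.radial_halfwidth() * self.ring_radius_sd
        return np.abs(r - self.ring_radius_mean) <= half

    def density(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Untruncated probability density on a broadcastable (x, y) mesh.

        For the ring prior the planar density is the radial normal law
        divided by the circumference 2*pi*r; the radius is floored at a
        small epsilon to keep the origin finite (the radial law carries
        essentially no mass there for any realistic parameterization).
        """
        cx, cy = self.center
        dx, dy = np.asarray(x) - cx, np.asarray(y) - cy
        if self.kind == "gaussian":
            s2 = self.axis_sd ** 2
            return np.exp(-(dx ** 2 + dy ** 2) / (2 * s2)) / (2 * math.pi * s2)
        r = np.hypot(dx, dy)
        r_safe = np.maximum(r, 1e-4)
        radial = stats.norm.pdf(r_safe, self.ring_radius_mean, self.ring_radius_sd)
        return radial / (2 * math.pi * r_safe)


@dataclass(frozen=True)
class Condition:
    """A named condition: its prior plus the (shared) beacon layout."""

    name: str
    prior: PriorSpec
    layout: BeaconLayout = field(default_factory=BeaconLayout)

    @property
    def prior_mode_is_on_beacon(self) -> bool:
        """True when the prior's modal locus touches a beacon position."""
        if self.prior.kind == "ring":
            return False
        center = self.prior.center_point
        return bool(
            np.any(np.all(np.isclose(self.layout.beacon_array, center), axis=1))
        )


@dataclass(frozen=True)
class Trial:
    """One trial: three simultaneous targets and a viewpoint displacement."""

    index: int  # 1-based
    half: str  # "first" | "second"
    targets: np.ndarray  # (3, 2) float
    displacement_fraction: float

    def __post_init__(self):
        t = np.asarray(self.targets, dtype=float)
        if t.shape != (3, 2):
            raise ValueError("a trial has exactly 3 targets")
        object.__setattr__(self, "targets", t)
        if self.half not in ("first", "second"):
            raise ValueError("half must be 'first' or 'second'")


@dataclass(frozen=True)
class Session:
    """One participant's full 60-trial session."""

    participant_id: str
    condition: Condition
    trials: tuple[Trial, ...]
    seed: int | None = None

    def half_trials(self, half: str) -> list[Trial]:
        return [t for t in self.trials if t.half == half]

    def all_targets(self) -> np.ndarray:
        """All target locations, shape (n_trials * 3, 2), in trial order."""
        return np.concatenate([t.targets for t in self.trials], axis=0)


_CONDITION_PRIORS: dict[str, PriorSpec] = {
    "beacon_normal": PriorSpec("gaussian", (-0.65, 0.0), axis_sd=0.15),
    "non_beacon_normal": PriorSpec("gaussian", (0.65, 0.0), axis_sd=0.15),
    "beacon_donut": PriorSpec(
        "ring", (-0.65, 0.0), ring_radius_mean=0.35, ring_radius_sd=0.07
    ),
    "offset": PriorSpec("gaussian", (-0.65, 0.25), axis_sd=0.15),
}


def make_condition(name: str, layout: BeaconLayout | None = None) -> Condition:
    """Build one of the four named conditions with its standard prior.

    ``beacon_normal``: Gaussian, mean on the left beacon (-0.65, 0), SD 0.15 m.
    ``non_beacon_normal``: Gaussian, mean at (0.65, 0) (where a fourth beacon
    would complete a square), SD 0.15 m.
    ``beacon_donut``: ring about the left beacon, radial mean 0.35 m, SD 0.07 m.
    ``offset``: Gaussian, mean at (-0.65, 0.25), SD 0.15 m (offset above the
    left beacon, putting the prior mode and the beacon in direct conflict).
    """
    if name not in _CONDITION_PRIORS:
        raise ValueError(
            f"unknown condition {name!r}; valid names: {sorted(_CONDITION_PRIORS)}"
        )
    return Condition(
        name=name,
        prior=_CONDITION_PRIORS[name],
        layout=layout if layout is not None else BeaconLayout(),
    )


def sample_targets(
    prior: PriorSpec,
    n: int,
    rng: np.random.Generator,
    truncate: bool = True,
) -> np.ndarray:
    """Draw ``n`` target locations from a prior, shape (n, 2).

    Truncation to the inner mass is by rejection: Gaussian draws are
    rejected outside the 98% isodensity (Mahalanobis) region, ring draws
    when the radial coordinate leaves the central 98% band of its normal
    law.  With ``truncate=False`` the raw, untruncated law is sampled
    (useful for checking the generating parameters themselves).
    """

    def raw(k: int) -> np.ndarray:
        if prior.kind == "gaussian":
            return prior.center_point + rng.normal(0.0, prior.axis_sd, size=(k, 2))
        radius = rng.normal(prior.ring_radius_mean, prior.ring_radius_sd, size=k)
        angle = rng.uniform(0.0, 2 * math.pi, size=k)
        return prior.center_point + np.column_stack(
            (radius * np.cos(angle), radius * np.sin(angle))
        )

    if not truncate:
        return raw(n)

    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        need = n - filled
        # 98% acceptance: a small oversample almost always finishes in one pass
        batch = raw(max(need + 10, int(need * 1.1)))
        ok = batch[prior.contains(batch)]
        take = min(len(ok), need)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def sample_target(
    prior: PriorSpec, rng: np.random.Generator, truncate: bool = True
) -> np.ndarray:
    """Draw a single target location (length-2 array)."""
    return sample_targets(prior, 1, rng, truncate=truncate)[0]


def _displacement_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Displacement fractions for a session: tile the 7 values to cover
    the trial count, truncate, and shuffle."""
    vals = np.array(DISPLACEMENT_FRACTIONS)
    reps = math.ceil(n_trials / len(vals))
    seq = np.tile(vals, reps)[:n_trials]
    rng.shuffle(seq)
    return seq


def build_session(
    condition: Condition,
    participant_id: str,
    seed: int,
    n_trials: int = 60,
) -> Session:
    """Generate a full session for one synthetic participant.

    The first half consists of ``n_trials / 2`` trials of three freshly
    sampled targets.  The second half randomly re-partitions exactly the
    same locations into new triplets in a new order, so the two halves
    share one multiset of locations.  The master seed is split into
    independent substreams for target sampling, re-grouping, and
    displacement ordering.
    """
    if n_trials % 2 != 0 or n_trials < 2:
        raise ValueError("n_trials must be a positive even number")
    ss = np.random.SeedSequence(seed)
    rng_targets, rng_regroup, rng_disp = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    half_n = n_trials // 2
    first_locs = sample_targets(condition.prior, half_n * 3, rng_targets)
    second_locs = first_locs[rng_regroup.permutation(half_n * 3)]
    disp = _displacement_sequence(n_trials, rng_disp)

    trials = []
    for i in range(n_trials):
        half = "first" if i < half_n else "second"
        locs = first_locs if half == "first" else second_locs
        j = i if half == "first" else i - half_n
        trials.append(
            Trial(
                index=i + 1,
                half=half,
                targets=locs[3 * j : 3 * j + 3],
                displacement_fraction=float(disp[i]),
            )
        )
    return Session(
        participant_id=participant_id,
        condition=condition,
        trials=tuple(trials),
        seed=seed,
    )


def validate_session(session: Session) -> None:
    """Check the structural invariants of a complete session.

    Raises ``ValueError`` on the first violation: wrong trial count,
    mislabeled halves, targets outside the truncation support, or a
    second-half location multiset differing from the first half's.
    """
    n = len(session.trials)
    if n != 60:
        raise ValueError(f"expected 60 trials, found {n}")
    for t in session.trials:
        want = "first" if t.index <= n // 2 else "second"
        if t.half != want:
            raise ValueError(f"trial {t.index} labeled {t.half!r}, expected {want!r}")
        if t.displacement_fraction not in DISPLACEMENT_FRACTIONS:
            raise ValueError(
                f"trial {t.index} displacement {t.displacement_fraction} "
                f"not in {DISPLACEMENT_FRACTIONS}"
            )
        if not session.condition.prior.contains(t.targets).all():
            raise ValueError(f"trial {t.index} has targets outside the prior support")
    first = np.concatenate([t.targets for t in session.half_trials("first")])
    second = np.concatenate([t.targets for t in session.half_trials("second")])
    order = lambda a: a[np.lexsort((a[:, 1], a[:, 0]))]  # noqa: E731
    if first.shape != second.shape or not np.array_equal(order(first), order(second)):
        raise ValueError("second-half locations are not a re-grouping of the first half")


def condition_from_prior(prior: PriorSpec, name: str = "custom") -> Condition:
    """Wrap an arbitrary prior in a Condition with the default layout."""
    return Condition(name=name, prior=prior)
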
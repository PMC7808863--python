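"""Ground-truthed synthetic larva simulator and frame renderer.

The simulator emulates the structure of 24-h single-larva dish recordings:
a larva alternating stationary phases and movement bouts (a two-state
semi-Markov process), moving as a correlated random walk confined to a
circular dish, optionally biased toward a diet blob ("food_centered") or
along the dish wall ("edge_following", the late-infection thigmotaxis
pattern).  The renderer turns a simulated trajectory into noisy 8-bit
greyscale frames together with the ground-truth table, so the whole
tracking/analysis chain can be validated without original videos.

Model summary
-------------
* Stationary-phase durations are exponential with rate ``bout_rate_per_h``
  (expected bouts per hour of stationary time); bout durations are gamma
  distributed with shape ``bout_duration_shape`` and mean
  ``bout_duration_mean_s``.  Frequency and duration of bouts are thereby
  independently controllable.
* During a bout, per-interval step lengths are lognormal with arithmetic
  mean ``step_mean_px`` and log-sd ``step_dispersion``; headings follow a
  correlated random walk with wrapped-normal turn angles of standard
  deviation ``(1 - heading_persistence) * pi``.
* Stationary intervals jitter uniformly within a 0.15-px disc around the
  resting point, so per-interval displacement stays strictly below 0.3 px —
  under, but near, the 0.5-px movement threshold used downstream.
* The dish wall reflects movement specularly; in edge-following mode the
  heading is additionally steered along the wall tangent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arena import ArenaSpec, ValidationError
from .tracking import FrameStack

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * math.pi

#: radius of the uniform stationary jitter disc, px (max net step 0.3 px)
STATIONARY_JITTER_PX = 0.15

#: wall margin, px: simulated centroids stay at least this far inside the dish
WALL_MARGIN_PX = 1.0


def _angdiff(a: float) -> float:
    """Wrap an angle difference into (-pi, pi]."""
    return (a + math.pi) % _TWO_PI - math.pi


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioural regime of one simulated larva.

    ``mode`` is the terminal spatial mode; with ``mode_switch_h`` set, the
    larva behaves food-centred until that hour and only then adopts ``mode``
    (used to emulate late-stage edge-following of infected larvae).
    """

    bout_rate_per_h: float = 2.0
    bout_duration_shape: float = 2.0
    bout_duration_mean_s: float = 300.0
    step_mean_px: float = 3.0
    step_dispersion: float = 0.5
    heading_persistence: float = 0.7
    mode: str = "food_centered"
    mode_switch_h: float | None = None

    def __post_init__(self) -> None:
        if self.bout_rate_per_h < 0:
            raise ValidationError("bout_rate_per_h must be >= 0")
        if self.bout_duration_shape <= 0 or self.bout_duration_mean_s <= 0:
            raise ValidationError("bout duration parameters must be positive")
        if self.step_mean_px <= 0 or self.step_dispersion <= 0:
            raise ValidationError("step distribution parameters must be positive")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise ValidationError("heading_persistence must lie in [0, 1]")
        if self.mode not in ("food_centered", "edge_following"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode_switch_h is not None and not 0.0 <= self.mode_switch_h <= 24.0:
            raise ValidationError("mode_switch_h must lie in [0, 24] hours")


def mock_params() -> BehaviorParams:
    """Default mock-infected (control) regime: food-centred, moderate activity."""
    return BehaviorParams()


def infected_params() -> BehaviorParams:
    """Default virus-infected regime.

    Encodes the qualitative infection phenotype: doubled per-interval speed
    and doubled bout duration at an unchanged bout rate, with a switch to
    edge-following (wall-hugging) 9 h into the recording.
    """
    return BehaviorParams(
        step_mean_px=6.0,
        bout_duration_mean_s=600.0,
        mode="edge_following",
        mode_switch_h=9.0,
    )


@dataclass(frozen=True)
class RenderParams:
    """Appearance and noise model for the frame renderer."""

    larva_axis_px: tuple[float, float] = (6.0, 3.0)
    larva_intensity: float = 200.0
    background_intensity: float = 30.0
    food_intensity: float = 90.0
    noise_sd: float = 2.0
    dropout_prob: float = 0.0
    clutter_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("larva_intensity", "background_intensity", "food_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValidationError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name in ("dropout_prob", "clutter_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.larva_axis_px[0] <= 0 or self.larva_axis_px[1] <= 0:
            raise ValidationError("larva blob half-axes must be positive")


@dataclass
class GroundTruth:
    """Simulated trajectory with per-interval behavioural labels.

    ``positions`` has one (x, y) row per frame; ``moving`` and ``bout_index``
    have one entry per inter-frame interval (interval i spans frames i..i+1;
    ``bout_index`` is -1 outside bouts).
    """

    positions: np.ndarray
    moving: np.ndarray
    bout_index: np.ndarray
    frame_interval_s: float

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_intervals(self) -> int:
        return len(self.moving)

    def to_dataframe(self) -> pd.DataFrame:
        """Per-frame table ``frame,time_s,x,y,state,bout_index``.

        State and bout columns describe the interval *starting* at each frame;
        the final frame starts no interval and carries empty values.
        """
        n = self.n_frames
        state = np.where(self.moving, "moving", "stationary").tolist() + [""]
        bout = [int(b) if b >= 0 else "" for b in self.bout_index] + [""]
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_s": np.arange(n) * self.frame_interval_s,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "state": state,
                "bout_index": bout,
            }
        )


def _build_schedule(
    params: BehaviorParams, n_intervals: int, dt_s: float, rng: np.random.Generator
) -> list[tuple[bool, int]]:
    """Alternating (moving?, n_intervals) phases tiling the record exactly."""
    phases: list[tuple[bool, int]] = []
    t = 0
    # Frequency neutrality: the expected bout-to-bout cycle must be
    # 1/bout_rate_per_h regardless of bout duration, so the exponential
    # stationary mean is the cycle target minus the mean bout duration
    # (floored at one frame interval when bouts nearly fill the cycle).
    if params.bout_rate_per_h > 0:
        stat_mean_s = max(
            dt_s, 3600.0 / params.bout_rate_per_h - params.bout_duration_mean_s
        )
    while t < n_intervals:
        if params.bout_rate_per_h <= 0:
            phases.append((False, n_intervals - t))
            break
        stat_s = rng.exponential(stat_mean_s)
        stat_iv = max(1, round(stat_s / dt_s))
        stat_iv = min(stat_iv, n_intervals - t)
        phases.append((False, stat_iv))
        t += stat_iv
        if t >= n_intervals:
            break
        bout_s = rng.gamma(
            params.bout_duration_shape,
            params.bout_duration_mean_s / params.bout_duration_shape,
        )
        bout_iv = max(1, round(bout_s / dt_s))
        bout_iv = min(bout_iv, n_intervals - t)
        phases.append((True, bout_iv))
        t += bout_iv
    return phases


def _effective_mode(params: BehaviorParams, hours: float) -> str:
    if params.mode_switch_h is not None and hours < params.mode_switch_h:
        return "food_centered"
    return params.mode


def simulate_trajectory(
    arena: ArenaSpec,
    params: BehaviorParams,
    duration_h: float,
    seed: int,
) -> GroundTruth:
    """Simulate one larva for ``duration_h`` hours at the arena frame interval.

    Returns one position per frame (``round(duration_h*3600/dt) + 1`` frames)
    plus per-interval moving/stationary labels and bout indices.  Identical
    inputs and seed reproduce bit-identical output.
    """
    if duration_h <= 0:
        raise ValidationError("duration_h must be positive")
    dt = arena.frame_interval_s
    n_intervals = round(duration_h * 3600.0 / dt)
    if n_intervals < 1:
        raise ValidationError("duration shorter than one frame interval")

    rng = np.random.default_rng(seed)
    cx, cy = arena.dish_center
    fx, fy = arena.food_center
    r_wall = arena.dish_radius_px - WALL_MARGIN_PX

    phases = _build_schedule(params, n_intervals, dt, rng)

    # start at a uniform point in the inner half of the dish
    r0 = 0.5 * r_wall * math.sqrt(rng.uniform())
    a0 = rng.uniform(0.0, _TWO_PI)
    x, y = cx + r0 * math.cos(a0), cy + r0 * math.sin(a0)

    positions = np.empty((n_intervals + 1, 2))
    moving = np.zeros(n_intervals, dtype=bool)
    bout_index = np.full(n_intervals, -1, dtype=np.int64)
    positions[0] = (x, y)

    sigma = params.step_dispersion
    mu = math.log(params.step_mean_px) - 0.5 * sigma * sigma
    turn_sd = (1.0 - params.heading_persistence) * math.pi

    t = 0
    bout_id = 0
    for is_bout, n_iv in phases:
        if not is_bout:
            # jitter uniformly within a small disc around the resting point
            radii = STATIONARY_JITTER_PX * np.sqrt(rng.uniform(size=n_iv))
            angles = rng.uniform(0.0, _TWO_PI, size=n_iv)
            positions[t + 1 : t + 1 + n_iv, 0] = x + radii * np.cos(angles)
            positions[t + 1 : t + 1 + n_iv, 1] = y + radii * np.sin(angles)
            t += n_iv
            continue

        moving[t : t + n_iv] = True
        bout_index[t : t + n_iv] = bout_id
        bout_id += 1
        steps = rng.lognormal(mu, sigma, size=n_iv)
        turns = rng.normal(0.0, turn_sd, size=n_iv)
        heading = rng.uniform(0.0, _TWO_PI)
        for k in range(n_iv):
            mode = _effective_mode(params, (t + k) * dt / 3600.0)
            if mode == "food_centered":
                if arena.food_radius_px > 0:
                    target = math.atan2(fy - y, fx - x)
                    heading += 0.15 * _angdiff(target - heading)
            else:  # edge_following
                r = math.hypot(x - cx, y - cy)
                outward = math.atan2(y - cy, x - cx)
                if r < 0.8 * r_wall:
                    heading += 0.3 * _angdiff(outward - heading)
                else:
                    # steer along whichever wall tangent is closer to heading
                    d1 = _angdiff(outward + 0.5 * math.pi - heading)
                    d2 = _angdiff(outward - 0.5 * math.pi - heading)
                    heading += 0.6 * (d1 if abs(d1) <= abs(d2) else d2)
            heading += turns[k]
            nx = x + steps[k] * math.cos(heading)
            ny = y + steps[k] * math.sin(heading)
            r = math.hypot(nx - cx, ny - cy)
            if r > r_wall:
                # specular reflection: fold the radial excess back inside
                rr = max(0.0, 2.0 * r_wall - r)
                b = math.atan2(ny - cy, nx - cx)
                nx = cx + rr * math.cos(b)
                ny = cy + rr * math.sin(b)
                heading = math.pi + 2.0 * b - heading
            x, y = nx, ny
            positions[t + k + 1] = (x, y)
        # rest where the bout ended
        t += n_iv

    return GroundTruth(
        positions=positions,
        moving=moving,
        bout_index=bout_index,
        frame_interval_s=dt,
    )


def _stamp_ellipse(
    img: np.ndarray,
    x0: float,
    y0: float,
    a: float,
    b: float,
    theta: float,
    intensity: float,
) -> None:
    """Alpha-blend an anti-aliased rotated ellipse onto ``img`` in place."""
    h, w = img.shape
    pad = max(a, b) + 2.0
    c0 = max(0, int(math.floor(x0 - pad)))
    c1 = min(w, int(math.ceil(x0 + pad)) + 1)
    r0 = max(0, int(math.floor(y0 - pad)))
    r1 = min(h, int(math.ceil(y0 + pad)) + 1)
    if c0 >= c1 or r0 >= r1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - x0
    dy = yy - y0
    ct, st = math.cos(theta), math.sin(theta)
    u = (ct * dx + st * dy) / a
    v = (-st * dx + ct * dy) / b
    d = np.sqrt(u * u + v * v)
    # soft 1-px edge approximating pixel coverage
    alpha = np.clip(0.5 - (d - 1.0) * min(a, b), 0.0, 1.0)
    region = img[r0:r1, c0:c1]
    region += alpha * (intensity - region)


def _orientations(positions: np.ndarray) -> np.ndarray:
    """Per-frame blob orientation from the most recent clear displacement."""
    n = len(positions)
    out = np.zeros(n)
    theta = 0.0
    for i in range(n):
        j = min(i, n - 2)
        dx = positions[j + 1, 0] - positions[j, 0]
        dy = positions[j + 1, 1] - positions[j, 1]
        if math.hypot(dx, dy) > 0.3:
            theta = math.atan2(dy, dx)
        out[i] = theta
    return out


def render_frames(
    truth: GroundTruth,
    arena: ArenaSpec,
    rp: RenderParams,
    seed: int,
) -> tuple[FrameStack, pd.DataFrame]:
    """Render one 8-bit greyscale frame per ground-truth position.

    The larva is an anti-aliased ellipse oriented along its current heading;
    the diet blob is static in every frame; Gaussian pixel noise, larval
    dropout and clutter blobs are applied by seeded draws.  Returns the
    frame stack and the ground-truth table.
    """
    for px, py in truth.positions:
        if not arena.contains(px, py, tolerance_px=0.5):
            raise ValidationError("ground-truth positions fall outside the arena dish")
    if abs(rp.larva_intensity - rp.background_intensity) <= 2.0 * rp.noise_sd:
        logger.warning(
            "larva intensity within 2 noise SD of background; blob may be undetectable"
        )
    rng = np.random.default_rng(seed)
    h, w = arena.height_px, arena.width_px

    base = np.full((h, w), rp.background_intensity, dtype=float)
    if arena.food_radius_px > 0:
        _stamp_ellipse(
            base,
            arena.food_center[0],
            arena.food_center[1],
            arena.food_radius_px,
            arena.food_radius_px,
            0.0,
            rp.food_intensity,
        )

    thetas = _orientations(truth.positions)
    a, b = rp.larva_axis_px
    cx, cy = arena.dish_center
    frames = []
    for i, (px, py) in enumerate(truth.positions):
        frame = base.copy()
        dropped = rng.uniform() < rp.dropout_prob
        cluttered = rng.uniform() < rp.clutter_prob
        if not dropped:
            _stamp_ellipse(frame, px, py, a, b, thetas[i], rp.larva_intensity)
        if cluttered:
            rr = (arena.dish_radius_px - 10.0) * math.sqrt(rng.uniform())
            aa = rng.uniform(0.0, _TWO_PI)
            _stamp_ellipse(
                frame,
                cx + rr * math.cos(aa),
                cy + rr * math.sin(aa),
                b,
                b,
                0.0,
                rp.larva_intensity,
            )
        if rp.noise_sd > 0:
            frame = frame + rng.normal(0.0, rp.noise_sd, size=frame.shape)
        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))

    stack = FrameStack(frames=frames, frame_interval_s=truth.frame_interval_s)
    return stack, truth.to_dataframe()


@dataclass
class CohortMember:
    """One labelled larva of a simulated cohort."""

    larva_id: str
    group: str
    experiment_id: str
    seed: int
    truth: GroundTruth


def make_cohort(
    arena: ArenaSpec,
    mock: BehaviorParams,
    infected: BehaviorParams,
    n_per_group: int,
    seed: int,
    duration_h: float = 24.0,
    experiment_id: str = "exp1",
) -> list[CohortMember]:
    """Simulate a labelled two-group cohort (mock vs infected).

    Per-larva seeds are spawned from the master seed with numpy's
    ``SeedSequence`` (children ``0..n-1`` are mock, ``n..2n-1`` infected), so
    cohorts of any size are reproducible and per-larva streams are disjoint
    even when the two groups share identical parameters.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    children = np.random.SeedSequence(seed).spawn(2 * n_per_group)
    members: list[CohortMember] = []
    for g, (label, params) in enumerate([("mock", mock), ("infected", infected)]):
        for i in range(n_per_group):
            child_seed = int(children[g * n_per_group + i].generate_state(1)[0])
            truth = simulate_trajectory(arena, params, duration_h, child_seed)
            members.append(
                CohortMember(
                    larva_id=f"{label}_{i + 1:02d}",
                    group=label,
                    experiment_id=experiment_id,
                    seed=child_seed,
                    truth=truth,
                )
            )
    return members
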
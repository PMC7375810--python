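"""Canonical fast--slow seizure model on a spherical parameter map.

The fast subsystem is the planar unfolding of the degenerate Takens--Bogdanov
singularity,

    dx/dt = -y
    dy/dt = x^3 - mu2*x - mu1 - y*(nu + x + x^2),

whose three unfolding parameters are constrained to a sphere of fixed radius
R in the space ``(mu2, -mu1, nu)``.  ``x`` is the observable (a proxy for the
local field potential), ``y`` an auxiliary recovery variable.  Rest states are
stable fixed points of the cubic nullcline; seizures are stable limit cycles.

A slow variable ``z`` moves the parameter point back and forth along a
great-circle path on the sphere at rate ``epsilon`` (of the order of the
inverse ictal length): while the fast subsystem rests, ``z`` drifts toward the
onset bifurcation; once it oscillates, the drift reverses toward the offset
bifurcation.  An optional ultraslow process rotates the path's endpoints on
the sphere, changing which bifurcations the path crosses.  Additive white
noise may be applied to all variables (Euler--Maruyama integration).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_RADIUS",
    "BLOWUP_GUARD",
    "RESTING",
    "OSCILLATING",
    "FastState",
    "UnfoldingParams",
    "SphericalPoint",
    "PathSpec",
    "SlowSpec",
    "UltraslowSpec",
    "NoiseSpec",
    "SimulationResult",
    "IntegrationBlowUp",
    "fast_rhs",
    "fixed_points",
    "jacobian",
    "slow_rhs",
    "embed_path_point",
    "detect_regime",
    "simulate",
    "simulate_ensemble",
    "EnsembleResult",
]

#: default radius of the parameter sphere (the unfolding is only valid in a
#: neighbourhood of the singularity; a sub-unit radius keeps it there)
DEFAULT_RADIUS = 0.4

#: integration aborts when |x| or |y| exceeds this guard
BLOWUP_GUARD = 1.0e3

RESTING = 0
OSCILLATING = 1


class IntegrationBlowUp(RuntimeError):
    """Raised when a trajectory exceeds the blow-up guard."""

    def __init__(self, t: float):
        super().__init__(f"state exceeded blow-up guard at t={t:.6g}")
        self.t = t


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastState:
    """State of the planar fast subsystem."""

    x: float
    y: float


@dataclass(frozen=True)
class UnfoldingParams:
    """Unfolding parameters (mu1, mu2, nu) of the fast subsystem."""

    mu1: float
    mu2: float
    nu: float

    @property
    def vector(self) -> np.ndarray:
        """Sphere-space vector ``(mu2, -mu1, nu)``."""
        return np.array([self.mu2, -self.mu1, self.nu])

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass(frozen=True)
class SphericalPoint:
    """A point on the parameter sphere in polar coordinates.

    ``theta`` is the polar angle from the +nu axis, ``phi`` the azimuth in
    the (mu2, -mu1) plane.  Angles are normalised into the single chart
    theta in [0, pi], phi in [-pi, pi).
    """

    theta: float
    phi: float
    R: float = DEFAULT_RADIUS

    def __post_init__(self):
        if not self.R > 0:
            raise ValueError("sphere radius must be positive")
        th = float(self.theta) % (2 * math.pi)
        ph = float(self.phi)
        if th > math.pi:  # reflect through the pole
            th = 2 * math.pi - th
            ph = ph + math.pi
        ph = (ph + math.pi) % (2 * math.pi) - math.pi
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "phi", ph)

    @property
    def vector(self) -> np.ndarray:
        """Cartesian sphere-space vector ``(mu2, -mu1, nu)``."""
        st = math.sin(self.theta)
        return self.R * np.array(
            [st * math.cos(self.phi), st * math.sin(self.phi), math.cos(self.theta)]
        )

    @property
    def params(self) -> UnfoldingParams:
        v = self.vector
        return UnfoldingParams(mu1=-v[1], mu2=v[0], nu=v[2])

    @classmethod
    def from_vector(cls, v: Sequence[float], R: float | None = None) -> "SphericalPoint":
        """Build from a sphere-space vector, rescaling onto radius ``R``.

        With ``R=None`` the vector's own norm is used.
        """
        v = np.asarray(v, dtype=float)
        n = float(np.linalg.norm(v))
        if n == 0:
            raise ValueError("zero vector has no direction")
        R = n if R is None else float(R)
        theta = math.acos(max(-1.0, min(1.0, v[2] / n)))
        phi = math.atan2(v[1], v[0])
        return cls(theta=theta, phi=phi, R=R)

    @classmethod
    def from_params(cls, p: UnfoldingParams, R: float | None = None) -> "SphericalPoint":
        return cls.from_vector(p.vector, R=R)

    def angle_to(self, other: "SphericalPoint") -> float:
        a = self.vector / self.R
        b = other.vector / other.R
        return float(np.arccos(np.clip(a @ b, -1.0, 1.0)))


@dataclass(frozen=True)
class PathSpec:
    """A great-circle arc on the sphere, parameterised by ``z`` in [0, 1]."""

    start: SphericalPoint
    end: SphericalPoint

    def __post_init__(self):
        if abs(self.start.R - self.end.R) > 1e-12 * self.start.R:
            raise ValueError("path endpoints must lie on the same sphere")
        ang = self.start.angle_to(self.end)
        if ang > math.pi - 1e-9:
            raise ValueError("antipodal endpoints define no unique great circle")
        object.__setattr__(self, "_angle", ang)

    @property
    def R(self) -> float:
        return self.start.R

    @property
    def central_angle(self) -> float:
        return self._angle  # type: ignore[attr-defined]

    @property
    def arc_length(self) -> float:
        return self.central_angle * self.R

    def point(self, z) -> np.ndarray:
        """Sphere-space vector(s) at position ``z`` (scalar or array) in [0,1]."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
            raise ValueError("z outside [0, 1]: the path is not extrapolated")
        z = np.clip(z, 0.0, 1.0)
        a = self.start.vector
        b = self.end.vector
        ang = self.central_angle
        if ang < 1e-12:  # zero-length path
            out = np.broadcast_to(a, z.shape + (3,)).copy()
            return out if z.shape else out.reshape(3)
        s = math.sin(ang)
        w1 = np.sin((1.0 - z) * ang) / s
        w2 = np.sin(z * ang) / s
        out = np.multiply.outer(w1, a) + np.multiply.outer(w2, b)
        return out if z.shape else out.reshape(3)

    def embed(self, z: float) -> UnfoldingParams:
        v = self.point(z)
        return UnfoldingParams(mu1=-float(v[1]), mu2=float(v[0]), nu=float(v[2]))

    def reversed(self) -> "PathSpec":
        return PathSpec(start=self.end, end=self.start)


def embed_path_point(path: PathSpec, z: float) -> UnfoldingParams:
    """Unfolding parameters at position ``z`` along ``path`` (no extrapolation)."""
    return path.embed(z)


@dataclass(frozen=True)
class SlowSpec:
    """Slow drive moving ``z`` along the path.

    ``epsilon`` is the drift rate (inverse time units; of the order of the
    inverse ictal length).  ``onset_at_end`` states on which side of the path
    the onset bifurcation lies: while the fast subsystem rests, ``dz/dt``
    points toward that side; while it oscillates, the sign is reversed.

    ``mode`` selects how the reversal is produced.  The default 'smooth'
    rule is the canonical model's own: dz/dt = epsilon * dir * (1 - d/dstar)
    with ``d`` the distance of the fast state from the nearest rest position
    (stable fixed point, continued across folds), so the drive reverses as
    soon as the state leaves the rest branch, whatever the oscillation
    period.  ``dstar`` must stay below the saddle-to-node separation, or
    the near-homoclinic crawl is mistaken for rest.  The 'hysteretic' rule switches
    dz/dt = +/-epsilon on the windowed regime detector instead; it is simple
    but stalls when the period outgrows the detector window near SN / SNIC /
    SH crossings.
    """

    epsilon: float = 0.005
    onset_at_end: bool = True
    mode: str = "smooth"
    dstar: float = 0.15
    drive_cap: float = 3.0  # |dz/dt| <= drive_cap * epsilon

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.mode not in ("smooth", "hysteretic"):
            raise ValueError("mode must be 'smooth' or 'hysteretic'")
        if not self.dstar > 0:
            raise ValueError("dstar must be positive")


@dataclass(frozen=True)
class UltraslowSpec:
    """Ultraslow rotation of one (or both) path endpoints on the sphere.

    The drifted endpoint rotates along the great circle toward ``target`` at
    constant angular velocity ``rate`` (radians per time unit), which keeps it
    on the sphere by construction.  The drift timescale must be much slower
    than the slow drive; ``simulate`` validates that a full drift takes at
    least ten mean ictal lengths.
    """

    endpoint: str = "start"  # 'start' | 'end' | 'both'
    rate: float = 0.0
    target: SphericalPoint | None = None

    def __post_init__(self):
        if self.endpoint not in ("start", "end", "both"):
            raise ValueError("endpoint must be 'start', 'end' or 'both'")
        if self.rate < 0:
            raise ValueError("drift rate must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise amplitudes and the RNG seed."""

    sigma_fast: float = 0.0
    sigma_slow: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_fast < 0 or self.sigma_slow < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class SimulationResult:
    """Time grid, trajectories, regime labels and onset/offset events."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    regime: np.ndarray  # uint8, RESTING / OSCILLATING
    events: list  # dicts: {"time", "kind" ('onset'|'offset'), "z"}
    settings: dict
    truncated_seizure: bool = False  # oscillating at end of run

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    def seizure_epochs(self, merge_gap: float = 0.0) -> list[tuple[float, float, bool]]:
        """(t_on, t_off, complete) for each oscillating epoch.

        Epochs separated by resting gaps shorter than ``merge_gap`` are
        merged.  ``complete`` is False for an epoch still running at the end
        of the simulation (status epilepticus / truncated).
        """
        r = self.regime.astype(bool)
        if not r.any():
            return []
        d = np.diff(r.astype(np.int8))
        starts = list(self.t[1:][d == 1])
        stops = list(self.t[1:][d == -1])
        if r[0]:
            starts.insert(0, float(self.t[0]))
        open_end = r[-1]
        epochs: list[list[float]] = []
        for i, s in enumerate(starts):
            e = stops[i] if i < len(stops) else float(self.t[-1])
            if epochs and s - epochs[-1][1] < merge_gap:
                epochs[-1][1] = e
            else:
                epochs.append([s, e])
        out = []
        for i, (s, e) in enumerate(epochs):
            complete = not (open_end and i == len(epochs) - 1)
            out.append((float(s), float(e), complete))
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.t, "x": self.x, "y": self.y, "z": self.z, "regime": self.regime}
        )

    def save(self, directory) -> None:
        """Write trajectory CSV, events JSON and resolved settings."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "trajectory.csv", index=False)
        with open(d / "events.json", "w") as fh:
            json.dump(
                {"events": self.events, "truncated_seizure": self.truncated_seizure},
                fh,
                indent=2,
            )
        with open(d / "config.json", "w") as fh:
            json.dump(self.settings, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# fast subsystem
# ---------------------------------------------------------------------------

def fast_rhs(x, y, params: UnfoldingParams | None = None, *, mu1=None, mu2=None, nu=None):
    """Right-hand side of the planar fast subsystem.

    Accepts scalars or arrays for ``x, y`` (and for the parameters when given
    as keywords).  Fixed points sit at ``y = 0`` with ``x`` a root of the
    cubic ``x^3 - mu2*x - mu1``; the damping factor is ``nu + x + x^2``.
    """
    if params is not None:
        mu1, mu2, nu = params.mu1, params.mu2, params.nu
    dx = -y
    dy = x * (x * x - mu2) - mu1 - y * (nu + x * (1.0 + x))
    return dx, dy


def cubic_roots_vec(mu1: np.ndarray, mu2: np.ndarray) -> np.ndarray:
    """Real roots of ``x^3 - mu2 x - mu1`` for arrays, nan-padded to (N, 3).

    Three-real-root cases use the trigonometric form, single-root cases
    Cardano; roots are not sorted across columns.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    N = mu1.shape[0]
    p = -mu2
    q = -mu1
    roots = np.full((N, 3), np.nan)
    disc = 4 * mu2**3 - 27 * mu1**2
    three = disc > 0
    if np.any(three):
        m = three
        r = 2.0 * np.sqrt(-p[m] / 3.0)
        arg = np.clip(3.0 * q[m] / (p[m] * r), -1.0, 1.0)
        th = np.arccos(arg) / 3.0
        for k in range(3):
            roots[m, k] = r * np.cos(th - 2.0 * np.pi * k / 3.0)
    if np.any(~three):
        m = ~three
        half_q = q[m] / 2.0
        inner = np.sqrt(np.maximum(half_q**2 + (p[m] / 3.0) ** 3, 0.0))
        roots[m, 0] = np.cbrt(-half_q + inner) + np.cbrt(-half_q - inner)
    return roots


#: cap on |dz/dt| in units of epsilon for the smooth slow drive
SMOOTH_DRIVE_CAP = 3.0


def _fill_empty_rows(roots: np.ndarray) -> np.ndarray:
    """Fill all-nan rows with the nearest non-empty row's values.

    Where the path has no stable fixed point, the rest reference continues
    the nearest rest branch (its "ghost"), as in the canonical model's slow
    drive: immediately past a fold the state still sits near the vanished
    node and must not be mistaken for a fully developed seizure.
    """
    has = np.where(np.isfinite(roots).any(axis=1))[0]
    if len(has) == 0 or len(has) == roots.shape[0]:
        return roots
    idx = np.arange(roots.shape[0])
    pos = np.searchsorted(has, idx)
    pos = np.clip(pos, 0, len(has) - 1)
    left = has[np.maximum(pos - 1, 0)]
    right = has[pos]
    nearest = np.where(np.abs(idx - left) <= np.abs(right - idx), left, right)
    return roots[nearest]


def _rest_fp_table(path: PathSpec, m: int = 1001) -> np.ndarray:
    """x-positions of stable fixed points on a z-grid along a path.

    Returns (m, 3), nan-padded; rows without any stable fixed point carry
    the nearest rest branch's position (see :func:`_fill_empty_rows`).  The
    smooth slow drive measures the fast state's distance from the nearest
    of these rest positions.
    """
    zs = np.linspace(0.0, 1.0, m)
    v = path.point(zs)
    mu1, mu2, nu = -v[:, 1], v[:, 0], v[:, 2]
    roots = cubic_roots_vec(mu1, mu2)
    det = 3.0 * roots**2 - mu2[:, None]
    trace = -(nu[:, None] + roots + roots**2)
    roots[(det < 0) | (trace >= 0)] = np.nan
    return _fill_empty_rows(roots)


def cubic_roots(mu1: float, mu2: float) -> np.ndarray:
    """Real roots of the fixed-point cubic ``x^3 - mu2*x - mu1``, sorted."""
    r = np.roots([1.0, 0.0, -mu2, -mu1])
    return np.sort(r[np.abs(r.imag) < 1e-9].real)


def jacobian(x: float, params: UnfoldingParams) -> np.ndarray:
    """Jacobian of the fast subsystem at a fixed point ``(x, 0)``."""
    return np.array(
        [
            [0.0, -1.0],
            [3.0 * x * x - params.mu2, -(params.nu + x + x * x)],
        ]
    )


def fixed_points(params: UnfoldingParams) -> list[dict]:
    """Fixed points of the fast subsystem with linear stability labels.

    Each entry carries ``x``, ``det`` (= 3x^2 - mu2), ``trace``
    (= -(nu + x + x^2)) and ``kind`` in {'saddle', 'stable', 'unstable'}.
    """
    out = []
    for x in cubic_roots(params.mu1, params.mu2):
        det = 3.0 * x * x - params.mu2
        tr = -(params.nu + x + x * x)
        if det < 0:
            kind = "saddle"
        elif tr < 0:
            kind = "stable"
        else:
            kind = "unstable"
        out.append({"x": float(x), "det": float(det), "trace": float(tr), "kind": kind})
    return out


# ---------------------------------------------------------------------------
# slow drive and regime detection
# ---------------------------------------------------------------------------

def slow_rhs(state: FastState, z: float, spec: SlowSpec, regime: int) -> float:
    """dz/dt under the hysteretic slow drive.

    While resting, ``z`` drifts toward the onset crossing; while oscillating
    the sign reverses (the back-and-forth motion along the path).
    """
    if spec.epsilon == 0:
        return 0.0
    toward_onset = 1.0 if spec.onset_at_end else -1.0
    return spec.epsilon * (toward_onset if regime == RESTING else -toward_onset)


def detect_regime(
    window: np.ndarray,
    fs: float,
    noise_floor: float = 1e-4,
    k: float = 5.0,
    amp_floor: float = 0.1,
) -> str:
    """Classify a window of the observable as 'resting' or 'oscillating'.

    Oscillating requires the peak-to-peak range to exceed both ``k`` times
    the resting noise floor and an absolute amplitude floor, and the
    detrended signal to cross zero at least twice.  The window should cover
    at least two periods of the slowest expected oscillation.
    """
    w = np.asarray(window, dtype=float)
    if w.size < 8:
        raise ValueError("regime window too short (need >= 8 samples)")
    ptp = float(w.max() - w.min())
    if ptp <= max(k * noise_floor, amp_floor):
        return "resting"
    d = w - w.mean()
    crossings = int(np.count_nonzero((d[:-1] < 0) & (d[1:] >= 0)))
    return "oscillating" if crossings >= 2 else "resting"


def _rotate_toward(v: np.ndarray, target: np.ndarray, angle: float) -> np.ndarray:
    """Rotate unit-sphere vector ``v`` toward ``target`` by ``angle`` radians."""
    R = float(np.linalg.norm(v))
    a = v / R
    b = target / np.linalg.norm(target)
    full = math.acos(max(-1.0, min(1.0, float(a @ b))))
    if full < 1e-12:
        return v.copy()
    ang = min(angle, full)
    s = math.sin(full)
    return R * (math.sin(full - ang) * a + math.sin(ang) * b) / s


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate(
    path: PathSpec,
    slow: SlowSpec,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.01,
    ultraslow: UltraslowSpec | None = None,
    *,
    z0: float = 0.2,
    x0: tuple[float, float] | None = None,
    regime_window: float = 25.0,
    regime_update: float = 0.5,
    regime_amp_floor: float = 0.4,
    blowup_guard: float = BLOWUP_GUARD,
) -> SimulationResult:
    """Integrate the full fast/slow/ultraslow system (Euler--Maruyama).

    The regime driving the slow variable is re-evaluated every
    ``regime_update`` time units on a sliding window of ``regime_window``
    time units of ``x``.  Identical settings and seed give bit-identical
    output.  Raises :class:`IntegrationBlowUp` if the guard is exceeded.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if slow.epsilon > 0 and dt > 1e-3 / slow.epsilon:
        raise ValueError("dt too large relative to the slow rate (need dt <= 1e-3/epsilon)")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    X = np.empty(n + 1)
    Y = np.empty(n + 1)
    Z = np.empty(n + 1)
    Rg = np.zeros(n + 1, dtype=np.uint8)

    rng = np.random.default_rng(noise.seed)
    # start on the resting branch unless told otherwise
    p0 = path.embed(z0)
    if x0 is None:
        rest = [f for f in fixed_points(p0) if f["kind"] == "stable"]
        if rest:
            xx, yy = max(rest, key=lambda f: f["x"])["x"], 0.0
        else:
            xx, yy = 0.0, 0.0
    else:
        xx, yy = float(x0[0]), float(x0[1])

    a_vec = path.start.vector
    b_vec = path.end.vector
    tgt = ultraslow.target.vector if (ultraslow and ultraslow.target) else None

    # validate ultraslow timescale separation against the slow drive
    if ultraslow and ultraslow.rate > 0 and slow.epsilon > 0:
        ictal = 1.0 / slow.epsilon  # order of the mean ictal length
        drift_time = 0.1 / ultraslow.rate  # time to move ~0.1 rad
        if drift_time < ictal:
            raise ValueError(
                "ultraslow drift is not slow: moving 0.1 rad takes less than one ictal length"
            )

    win = max(8, int(round(regime_window / dt)))
    upd = max(1, int(round(regime_update / dt)))
    noise_floor = max(noise.sigma_fast, 1e-4)

    sq = math.sqrt(dt)
    z = float(np.clip(z0, 0.0, 1.0))
    regime = RESTING
    events: list[dict] = []
    X[0], Y[0], Z[0], Rg[0] = xx, yy, z, regime

    # slerp bookkeeping (recomputed when ultraslow moves an endpoint)
    def slerp_setup():
        a = a_vec / np.linalg.norm(a_vec)
        b = b_vec / np.linalg.norm(b_vec)
        ang = math.acos(max(-1.0, min(1.0, float(a @ b))))
        return a, b, ang

    ua, ub, ang = slerp_setup()
    Rsph = path.R

    def fp_table() -> np.ndarray:
        cur = PathSpec(
            SphericalPoint.from_vector(Rsph * ua), SphericalPoint.from_vector(Rsph * ub)
        )
        return _rest_fp_table(cur, 1001)

    fp_tab = fp_table() if slow.mode == "smooth" else None
    drift_acc = 0.0
    toward_onset = 1.0 if slow.onset_at_end else -1.0
    chunk = 65536
    eps_noise = None
    ptr = chunk

    for i in range(1, n + 1):
        if ptr >= chunk:
            eps_noise = rng.standard_normal((chunk, 3))
            ptr = 0
        # embed current z
        if ang < 1e-12:
            v = Rsph * ua
        else:
            s = math.sin(ang)
            v = Rsph * (math.sin((1.0 - z) * ang) * ua + math.sin(z * ang) * ub) / s
        mu2, nmu1, nu = v[0], v[1], v[2]
        mu1 = -nmu1
        # Heun (predictor-corrector) for the fast variables: plain Euler
        # destabilises the slow crawl near saddles and terminates seizures
        # far from the true homoclinic
        dx1 = -yy
        dy1 = xx * (xx * xx - mu2) - mu1 - yy * (nu + xx * (1.0 + xx))
        xp = xx + dt * dx1
        yp = yy + dt * dy1
        dx2 = -yp
        dy2 = xp * (xp * xp - mu2) - mu1 - yp * (nu + xp * (1.0 + xp))
        dx = 0.5 * (dx1 + dx2)
        dy = 0.5 * (dy1 + dy2)
        if slow.mode == "smooth":
            row = fp_tab[int(z * 1000.0 + 0.5)]
            d2 = math.inf
            for fx in row:
                if fx == fx:  # not nan
                    q = (xx - fx) * (xx - fx) + yy * yy
                    if q < d2:
                        d2 = q
            frac = 1.0 - math.sqrt(d2) / slow.dstar if d2 < math.inf else -slow.drive_cap
            if frac < -slow.drive_cap:
                frac = -slow.drive_cap
            dz = slow.epsilon * toward_onset * frac
        else:
            dz = slow_rhs(None, z, slow, regime)
        e = eps_noise[ptr]
        ptr += 1
        xx = xx + dt * dx + noise.sigma_fast * sq * e[0]
        yy = yy + dt * dy + noise.sigma_fast * sq * e[1]
        z = z + dt * dz + noise.sigma_slow * sq * e[2]
        if z < 0.0:
            z = 0.0
        elif z > 1.0:
            z = 1.0
        if abs(xx) > blowup_guard or abs(yy) > blowup_guard:
            raise IntegrationBlowUp(t[i])
        X[i], Y[i], Z[i] = xx, yy, z

        if i == win:
            # calibrate the resting noise floor from the first completed
            # window: damping near rest amplifies the injected noise
            ptp0 = float(X[1 : win + 1].max() - X[1 : win + 1].min())
            noise_floor = max(noise_floor, ptp0 / 2.0)
        if i % upd == 0 and i >= win:
            verdict = detect_regime(
                X[i - win + 1 : i + 1], 1.0 / dt, noise_floor, amp_floor=regime_amp_floor
            )
            new = OSCILLATING if verdict == "oscillating" else RESTING
            if new != regime:
                events.append(
                    {
                        "time": float(t[i]),
                        "kind": "onset" if new == OSCILLATING else "offset",
                        "z": float(z),
                    }
                )
                regime = new
            # ultraslow drift applied at the regime-update cadence
            if ultraslow and ultraslow.rate > 0 and tgt is not None:
                step_ang = ultraslow.rate * regime_update
                if ultraslow.endpoint in ("start", "both"):
                    a_new = _rotate_toward(Rsph * ua, tgt, step_ang)
                    ua = a_new / np.linalg.norm(a_new)
                if ultraslow.endpoint in ("end", "both"):
                    b_new = _rotate_toward(Rsph * ub, tgt, step_ang)
                    ub = b_new / np.linalg.norm(b_new)
                ang = math.acos(max(-1.0, min(1.0, float(ua @ ub))))
                drift_acc += step_ang
                if fp_tab is not None and drift_acc > 0.005:
                    fp_tab = fp_table()
                    drift_acc = 0.0
        Rg[i] = regime

    settings = {
        "path": {
            "start": asdict(path.start),
            "end": asdict(path.end),
        },
        "slow": asdict(slow),
        "noise": asdict(noise),
        "ultraslow": asdict(ultraslow) if ultraslow else None,
        "duration": duration,
        "dt": dt,
        "z0": z0,
        "x0": x0,
        "regime_window": regime_window,
        "regime_update": regime_update,
    }
    return SimulationResult(
        t=t,
        x=X,
        y=Y,
        z=Z,
        regime=Rg,
        events=events,
        settings=settings,
        truncated_seizure=bool(Rg[-1] == OSCILLATING),
    )


# ---------------------------------------------------------------------------
# vectorized ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Output of :func:`simulate_ensemble` (one row per simulation)."""

    t: np.ndarray
    x: np.ndarray | None  # (n_sims, n_t) or None when traces are not stored
    z: np.ndarray | None
    regime: np.ndarray | None
    events: list  # list (per sim) of event dicts as in SimulationResult
    max_osc_run: np.ndarray  # longest continuous oscillating stretch (time units)
    osc_time: np.ndarray  # total oscillating time per sim
    osc_time_no_rest: np.ndarray  # oscillating time spent where no rest state exists
    blown: np.ndarray  # sims that hit the blow-up guard (frozen from then on)
    settings: dict


def simulate_ensemble(
    paths,
    slow: SlowSpec,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.01,
    ultraslow: UltraslowSpec | None = None,
    *,
    z0: float = 0.2,
    n_sims: int | None = None,
    regime_window: float = 25.0,
    regime_update: float = 0.5,
    regime_amp_floor: float = 0.4,
    store_traces: bool = True,
    store_dtype=np.float32,
    rest_absent_table: np.ndarray | None = None,
    blowup_guard: float = BLOWUP_GUARD,
) -> EnsembleResult:
    """Integrate many independent realisations of the model at once.

    ``paths`` is a single :class:`PathSpec` (shared) or a list of one per
    simulation.  All simulations share ``slow``/``noise`` settings; each has
    an independent noise stream derived from ``noise.seed``.

    ``rest_absent_table`` (n_sims, m) optionally marks, per simulation and
    per ``z`` bin (m uniform bins on [0, 1]), where the fast subsystem has no
    stable fixed point; when given, the time each simulation spends
    oscillating in such 'seizure only' territory is accumulated.
    """
    if isinstance(paths, PathSpec):
        if n_sims is None:
            raise ValueError("n_sims required when a single shared path is given")
        paths = [paths] * n_sims
    ns = len(paths)
    if slow.epsilon > 0 and dt > 1e-3 / slow.epsilon:
        raise ValueError("dt too large relative to the slow rate (need dt <= 1e-3/epsilon)")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt

    A = np.stack([p.start.vector for p in paths])
    B = np.stack([p.end.vector for p in paths])
    Rsph = paths[0].R
    uA = A / np.linalg.norm(A, axis=1, keepdims=True)
    uB = B / np.linalg.norm(B, axis=1, keepdims=True)
    ang = np.arccos(np.clip(np.sum(uA * uB, axis=1), -1.0, 1.0))
    tgt = ultraslow.target.vector if (ultraslow and ultraslow.target) else None
    if ultraslow and ultraslow.rate > 0 and slow.epsilon > 0:
        if 0.1 / ultraslow.rate < 1.0 / slow.epsilon:
            raise ValueError("ultraslow drift is not slow relative to the ictal length")

    # initial condition: the most positive stable fixed point at z0 (per path)
    x = np.empty(ns)
    y = np.zeros(ns)
    for i, p in enumerate(paths):
        rest = [f for f in fixed_points(p.embed(z0)) if f["kind"] == "stable"]
        x[i] = max(f["x"] for f in rest) if rest else 0.0
    z = np.full(ns, float(np.clip(z0, 0.0, 1.0)))
    regime = np.zeros(ns, dtype=np.uint8)

    win = max(8, int(round(regime_window / dt)))
    upd = max(1, int(round(regime_update / dt)))
    noise_floor = np.full(ns, max(noise.sigma_fast, 1e-4))
    amp_floor = regime_amp_floor

    rng = np.random.default_rng(noise.seed)
    sq = math.sqrt(dt)
    toward_onset = 1.0 if slow.onset_at_end else -1.0
    m_fp = 1001

    def fp_tables() -> np.ndarray:
        zs = np.linspace(0.0, 1.0, m_fp)
        out = np.empty((ns, m_fp, 3))
        for j in range(ns):
            s_ang = float(ang[j]) if np.ndim(ang) else float(ang)
            a = Rsph * uA[j]
            b = Rsph * uB[j]
            if s_ang < 1e-12:
                v = np.broadcast_to(a, (m_fp, 3))
            else:
                sa = math.sin(s_ang)
                v = (
                    np.sin((1.0 - zs)[:, None] * s_ang) * a
                    + np.sin(zs[:, None] * s_ang) * b
                ) / sa
            roots = cubic_roots_vec(-v[:, 1], v[:, 0])
            det = 3.0 * roots**2 - v[:, 0][:, None]
            trace = -(v[:, 2][:, None] + roots + roots**2)
            roots[(det < 0) | (trace >= 0)] = np.nan
            out[j] = _fill_empty_rows(roots)
        return out

    fp_tab = fp_tables() if slow.mode == "smooth" else None
    drift_acc = 0.0
    rows_idx = np.arange(ns)

    if store_traces:
        X = np.empty((ns, n + 1), dtype=store_dtype)
        Zs = np.empty((ns, n + 1), dtype=store_dtype)
        Rg = np.zeros((ns, n + 1), dtype=np.uint8)
        X[:, 0], Zs[:, 0], Rg[:, 0] = x, z, regime
    else:
        X = Zs = Rg = None
    buf = np.empty((win, ns))  # circular buffer of x for regime windows
    buf[:] = x[None, :]

    events: list[list[dict]] = [[] for _ in range(ns)]
    run_start = np.full(ns, np.nan)  # start time of current oscillating run
    max_run = np.zeros(ns)
    osc_time = np.zeros(ns)
    osc_nr_time = np.zeros(ns)
    blown = np.zeros(ns, dtype=bool)
    m_tab = rest_absent_table.shape[1] if rest_absent_table is not None else 0

    chunk = 1024
    eps = None
    ptr = chunk
    sin_ang = np.sin(ang)
    degenerate = ang < 1e-12

    for i in range(1, n + 1):
        if ptr >= chunk:
            eps = rng.standard_normal((chunk, ns, 3))
            ptr = 0
        e = eps[ptr]
        ptr += 1
        # spherical interpolation of the parameter point, per sim
        w1 = np.where(degenerate, 1.0, np.sin((1.0 - z) * ang) / np.where(degenerate, 1.0, sin_ang))
        w2 = np.where(degenerate, 0.0, np.sin(z * ang) / np.where(degenerate, 1.0, sin_ang))
        v = Rsph * (w1[:, None] * uA + w2[:, None] * uB)
        mu2 = v[:, 0]
        mu1 = -v[:, 1]
        nu = v[:, 2]
        dx1 = -y
        dy1 = x * (x * x - mu2) - mu1 - y * (nu + x * (1.0 + x))
        xp = x + dt * dx1
        yp = y + dt * dy1
        dx = 0.5 * (dx1 - yp)
        dy = 0.5 * (dy1 + xp * (xp * xp - mu2) - mu1 - yp * (nu + xp * (1.0 + xp)))
        osc = regime == OSCILLATING
        if slow.mode == "smooth":
            rows = fp_tab[rows_idx, np.rint(z * (m_fp - 1)).astype(np.intp)]
            with np.errstate(invalid="ignore"):
                d2 = np.nanmin((rows - x[:, None]) ** 2, axis=1) + y * y
            frac = np.where(
                np.isfinite(d2), 1.0 - np.sqrt(d2) / slow.dstar, -slow.drive_cap
            )
            np.maximum(frac, -slow.drive_cap, out=frac)
            dz = slow.epsilon * toward_onset * frac
        else:
            dz = slow.epsilon * np.where(osc, -toward_onset, toward_onset)
        x = x + dt * dx + noise.sigma_fast * sq * e[:, 0]
        y = y + dt * dy + noise.sigma_fast * sq * e[:, 1]
        z = np.clip(z + dt * dz + noise.sigma_slow * sq * e[:, 2], 0.0, 1.0)
        bad = (np.abs(x) > blowup_guard) | (np.abs(y) > blowup_guard) | ~np.isfinite(x)
        if bad.any():
            newly = bad & ~blown
            blown |= newly
            x[bad] = 0.0
            y[bad] = 0.0
        osc_dt = osc & ~blown
        osc_time[osc_dt] += dt
        if rest_absent_table is not None:
            idx = np.minimum((z * (m_tab - 1)).astype(np.intp), m_tab - 1)
            absent = rest_absent_table[np.arange(ns), idx]
            osc_nr_time[osc_dt & absent] += dt
        buf[i % win] = x
        if store_traces:
            X[:, i] = x
            Zs[:, i] = z
        if i == win:
            # calibrate the resting noise floor from the first completed
            # window: damping near rest amplifies the injected noise
            ptp0 = buf.max(axis=0) - buf.min(axis=0)
            noise_floor = np.maximum(noise_floor, ptp0 / 2.0)
        if i % upd == 0 and i >= win:
            ptps = buf.max(axis=0) - buf.min(axis=0)
            d = buf - buf.mean(axis=0)
            crossings = np.count_nonzero((d[:-1] < 0) & (d[1:] >= 0), axis=0)
            verdict = (ptps > np.maximum(5.0 * noise_floor, amp_floor)) & (crossings >= 2)
            verdict &= ~blown
            changed = verdict != (regime == OSCILLATING)
            if changed.any():
                ti = float(t[i])
                for j in np.nonzero(changed)[0]:
                    kind = "onset" if verdict[j] else "offset"
                    events[j].append({"time": ti, "kind": kind, "z": float(z[j])})
                    if verdict[j]:
                        run_start[j] = ti
                    else:
                        max_run[j] = max(max_run[j], ti - run_start[j])
                        run_start[j] = np.nan
                regime = np.where(verdict, OSCILLATING, RESTING).astype(np.uint8)
            if ultraslow and ultraslow.rate > 0 and tgt is not None:
                step_ang = ultraslow.rate * regime_update
                if ultraslow.endpoint in ("start", "both"):
                    for j in range(ns):
                        nv = _rotate_toward(Rsph * uA[j], tgt, step_ang)
                        uA[j] = nv / np.linalg.norm(nv)
                if ultraslow.endpoint in ("end", "both"):
                    for j in range(ns):
                        nv = _rotate_toward(Rsph * uB[j], tgt, step_ang)
                        uB[j] = nv / np.linalg.norm(nv)
                ang = np.arccos(np.clip(np.sum(uA * uB, axis=1), -1.0, 1.0))
                sin_ang = np.sin(ang)
                degenerate = ang < 1e-12
                drift_acc += step_ang
                if fp_tab is not None and drift_acc > 0.005:
                    fp_tab = fp_tables()
                    drift_acc = 0.0
        if store_traces:
            Rg[:, i] = regime
    still = ~np.isnan(run_start)
    max_run[still] = np.maximum(max_run[still], float(t[-1]) - run_start[still])

    settings = {
        "n_sims": ns,
        "slow": asdict(slow),
        "noise": asdict(noise),
        "ultraslow": asdict(ultraslow) if ultraslow else None,
        "duration": duration,
        "dt": dt,
        "z0": z0,
        "regime_window": regime_window,
        "regime_update": regime_update,
    }
    return EnsembleResult(
        t=t,
        x=X,
        z=Zs,
        regime=Rg,
        events=events,
        max_osc_run=max_run,
        osc_time=osc_time,
        osc_time_no_rest=osc_nr_time,
        blown=blown,
        settings=settings,
    )
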
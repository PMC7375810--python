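"""The two-parameter seizure map on the sphere of unfolding parameters.

Bifurcation curves partition the spherical parameter surface of the fast
subsystem into regions (rest only, seizure only, bistable rest/seizure,
bistable rest/active-rest).  Saddle-node and Hopf curves have closed forms
from the fixed-point cubic; the saddle-homoclinic (SH), saddle-node on
invariant circle (SNIC) and fold-of-limit-cycles (FLC) curves do not and are
traced numerically as boundaries where a brute-force attractor oracle stops
finding a stable limit cycle.

Great-circle paths across the map, together with the slow back-and-forth
drive of :mod:`.canonical_model`, realise seizure dynamotypes: the onset
bifurcation is the curve where the resting state is lost along the path, the
offset the curve where the oscillation dies on the way back.  The planar
dynamotypes are enumerated here by constructing candidate paths between
curves and confirming each with a noise-free simulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .canonical_model import (
    DEFAULT_RADIUS,
    NoiseSpec,
    PathSpec,
    SlowSpec,
    SphericalPoint,
    UnfoldingParams,
    fixed_points,
    simulate,
)

__all__ = [
    "REST_ONLY",
    "SEIZURE_ONLY",
    "BISTABLE_REST_SEIZURE",
    "BISTABLE_REST_ACTIVE_REST",
    "INDETERMINATE",
    "ONSET_CAPABLE",
    "OFFSET_CAPABLE",
    "BifurcationCurve",
    "DynamotypePair",
    "Crossing",
    "RegionMap",
    "EnumerationResult",
    "first_lyapunov",
    "sn_curves",
    "hopf_curve",
    "classify_attractors",
    "build_region_map",
    "numeric_offset_curves",
    "great_circle_path",
    "path_crossings",
    "enumerate_planar_dynamotypes",
    "build_map",
]

# region labels
REST_ONLY = "rest only"
SEIZURE_ONLY = "seizure only"
BISTABLE_REST_SEIZURE = "bistable rest/seizure"
BISTABLE_REST_ACTIVE_REST = "bistable rest/active-rest"
INDETERMINATE = "indeterminate"

_REGION_CODES = {
    REST_ONLY: 0,
    SEIZURE_ONLY: 1,
    BISTABLE_REST_SEIZURE: 2,
    BISTABLE_REST_ACTIVE_REST: 3,
    INDETERMINATE: 4,
}
_REGION_NAMES = {v: k for k, v in _REGION_CODES.items()}

# which bifurcations can start / stop a seizure
ONSET_CAPABLE = frozenset({"SN", "SNIC", "SupH", "SubH"})
OFFSET_CAPABLE = frozenset({"SH", "SNIC", "SupH", "FLC"})


@dataclass
class BifurcationCurve:
    """An ordered polyline of sphere points belonging to one bifurcation."""

    label: str  # 'SN', 'Hopf', 'SH', 'SNIC', 'FLC'
    points: np.ndarray  # (n, 3) sphere-space vectors
    method: str  # 'analytic' | 'numeric'
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.points)


@dataclass(frozen=True)
class DynamotypePair:
    """(onset bifurcation, offset bifurcation) of a seizure."""

    onset: str
    offset: str

    def __post_init__(self):
        if self.onset not in ONSET_CAPABLE:
            raise ValueError(f"{self.onset!r} cannot start a seizure")
        if self.offset not in OFFSET_CAPABLE:
            raise ValueError(f"{self.offset!r} cannot stop a seizure")

    def __str__(self):
        return f"{self.onset}/{self.offset}"


@dataclass(frozen=True)
class Crossing:
    """A bifurcation crossing along a path, located at position ``z``."""

    z: float
    label: str
    tangential: bool = False
    meta: tuple = ()

    @property
    def onset_capable(self) -> bool:
        return self.label in ONSET_CAPABLE

    @property
    def offset_capable(self) -> bool:
        return self.label in OFFSET_CAPABLE


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------

def _sn_smax(R: float) -> float:
    """Largest double-root location s with 9 s^4 + 4 s^6 <= R^2."""
    from scipy.optimize import brentq

    return brentq(lambda s: 9 * s**4 + 4 * s**6 - R * R, 0.0, max(1.0, R))


def sn_curves(R: float = DEFAULT_RADIUS, n: int = 400) -> list[BifurcationCurve]:
    """The two saddle-node branches on the sphere of radius ``R``.

    A double root of the fixed-point cubic at ``x = s`` requires
    ``mu2 = 3 s^2`` and ``mu1 = -2 s^3``; the third root sits at ``-2s``.
    Each sign of ``s`` gives one branch running pole to pole; the branches
    meet at the cusp points ``(0, 0, +/-R)`` where the root is triple.
    """
    if not R > 0:
        raise ValueError("R must be positive")
    smax = _sn_smax(R)
    out = []
    for sign in (+1.0, -1.0):
        s = sign * np.concatenate(
            [np.linspace(0.0, smax, n // 2), np.linspace(smax, 0.0, n // 2)[1:]]
        )
        nu2 = np.maximum(R * R - 9 * s**4 - 4 * s**6, 0.0)
        nu = np.sqrt(nu2)
        nu[n // 2 :] *= -1.0  # second half descends into the southern hemisphere
        pts = np.column_stack([3 * s**2, 2 * s**3, nu])  # (mu2, -mu1, nu)
        out.append(
            BifurcationCurve(label="SN", points=pts, method="analytic", meta={"s": s})
        )
    return out


def first_lyapunov(x: float, mu2: float) -> float:
    """First Lyapunov coefficient (up to a positive factor) at a Hopf point.

    For the fast subsystem at a fixed point ``x`` with zero trace,
    ``16 l1 = -2 + 6 x (1 + 2 x) / (3 x^2 - mu2)``; negative means
    supercritical (a small stable cycle is born).
    """
    det = 3.0 * x * x - mu2
    return (-2.0 + 6.0 * x * (1.0 + 2.0 * x) / det) / 16.0


def hopf_curve(R: float = DEFAULT_RADIUS, n: int = 1200) -> BifurcationCurve:
    """Hopf curve: fixed point with vanishing damping (zero trace).

    At a Hopf point ``nu = -(x + x^2)`` and the sphere constraint gives a
    quadratic for ``mu2``; only solutions with ``3 x^2 - mu2 > 0`` (complex
    eigenvalue pair) qualify.  Each point is annotated supercritical or
    subcritical by the sign of the first Lyapunov coefficient.
    """
    if not R > 0:
        raise ValueError("R must be positive")
    pts, xs, l1s, branch = [], [], [], []
    for x in np.linspace(-1.5, 1.5, n):
        nu = -(x + x * x)
        rem = R * R - nu * nu
        if rem <= 0:
            continue
        # (1 + x^2) mu2^2 - 2 x^4 mu2 + x^6 - rem = 0
        a, b, c = 1.0 + x * x, -2.0 * x**4, x**6 - rem
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        for k, mu2 in enumerate(((-b + math.sqrt(disc)) / (2 * a), (-b - math.sqrt(disc)) / (2 * a))):
            det = 3.0 * x * x - mu2
            if det <= 1e-12:
                continue  # neutral saddle, not a Hopf point
            mu1 = x**3 - mu2 * x
            pts.append([mu2, -mu1, nu])
            xs.append(x)
            l1s.append(first_lyapunov(x, mu2))
            branch.append(k)
    pts = np.asarray(pts)
    xs = np.asarray(xs)
    l1s = np.asarray(l1s)
    branch = np.asarray(branch)
    # order: branch 0 ascending in x, then branch 1 descending, for a clean polyline
    order = np.lexsort((np.where(branch == 0, xs, -xs), branch))
    return BifurcationCurve(
        label="Hopf",
        points=pts[order],
        method="analytic",
        meta={"x": xs[order], "l1": l1s[order], "supercritical": l1s[order] < 0},
    )


# ---------------------------------------------------------------------------
# brute-force attractor oracle
# ---------------------------------------------------------------------------

def _fp_arrays(mu1: np.ndarray, mu2: np.ndarray, nu: np.ndarray):
    """Vectorised fixed-point analysis of the cubic ``x^3 - mu2 x - mu1``.

    Returns (n_stable, saddle_x (nan when absent), focus_x: the non-saddle
    fixed point with the largest linear growth rate, n_roots).
    """
    N = mu1.shape[0]
    n_stable = np.zeros(N, dtype=np.int8)
    saddle_x = np.full(N, np.nan)
    focus_x = np.full(N, np.nan)
    n_roots = np.zeros(N, dtype=np.int8)
    # companion-free root finding: trigonometric/Cardano, vectorised
    p = -mu2
    q = -mu1
    disc = 4 * mu2**3 - 27 * mu1**2  # >0: three real roots
    three = disc > 0
    roots = np.full((N, 3), np.nan)
    if np.any(three):
        m = three
        r = 2.0 * np.sqrt(-p[m] / 3.0)
        arg = np.clip(3.0 * q[m] / (p[m] * r), -1.0, 1.0)
        th = np.arccos(arg) / 3.0
        for k in range(3):
            roots[m, k] = r * np.cos(th - 2.0 * np.pi * k / 3.0)
    if np.any(~three):
        m = ~three
        # Cardano for the single real root
        half_q = q[m] / 2.0
        inner = np.sqrt(np.maximum(half_q**2 + (p[m] / 3.0) ** 3, 0.0))
        roots[m, 0] = np.cbrt(-half_q + inner) + np.cbrt(-half_q - inner)
    n_roots = np.where(three, 3, 1).astype(np.int8)
    best_rate = np.full(N, -np.inf)
    for k in range(3):
        xk = roots[:, k]
        ok = np.isfinite(xk)
        det = 3 * xk**2 - mu2
        tr = -(nu + xk + xk**2)
        stable = ok & (det > 0) & (tr < 0)
        saddle = ok & (det < 0)
        n_stable += stable.astype(np.int8)
        saddle_x = np.where(saddle, xk, saddle_x)
        nonsaddle = ok & (det >= 0)
        better = nonsaddle & (tr > best_rate)
        focus_x = np.where(better, xk, focus_x)
        best_rate = np.where(better, tr, best_rate)
    return n_stable, saddle_x, focus_x, n_roots


def _cycle_scan(
    mu1: np.ndarray,
    mu2: np.ndarray,
    nu: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    saddle_x: np.ndarray,
    *,
    dt: float = 0.05,
    t_transient: float = 400.0,
    t_detect: float = 200.0,
    amp_min: float = 0.05,
):
    """Integrate the fast subsystem (RK4) and report oscillation statistics.

    Returns (oscillating, amplitude of x, mean period, minimum distance of
    the trajectory to the saddle).  A trajectory counts as oscillating when,
    during the detection window, x keeps a peak-to-peak range above
    ``amp_min`` and y crosses zero upward at least three times.  ``amp_min``
    must exceed the residual ring-down of slowly decaying spirals near the
    Hopf curve (which do not settle within the transient), or those ghosts
    are counted as limit cycles.
    """

    x = x0.astype(float).copy()
    y = y0.astype(float).copy()

    def rhs(x, y):
        dx = -y
        dy = x * (x * x - mu2) - mu1 - y * (nu + x * (1.0 + x))
        return dx, dy

    def rk4_step(x, y):
        k1x, k1y = rhs(x, y)
        k2x, k2y = rhs(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = rhs(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = rhs(x + dt * k3x, y + dt * k3y)
        x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        y = y + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        return x, y

    for _ in range(int(round(t_transient / dt))):
        x, y = rk4_step(x, y)
        np.clip(x, -10.0, 10.0, out=x)
        np.clip(y, -10.0, 10.0, out=y)

    n = int(round(t_detect / dt))
    xmin = x.copy()
    xmax = x.copy()
    ncross = np.zeros(x.shape, dtype=np.int32)
    t_first = np.full(x.shape, np.nan)
    t_last = np.full(x.shape, np.nan)
    sx = np.where(np.isfinite(saddle_x), saddle_x, 1e6)
    min_sd = np.full(x.shape, np.inf)
    yprev = y.copy()
    for i in range(n):
        x, y = rk4_step(x, y)
        np.minimum(xmin, x, out=xmin)
        np.maximum(xmax, x, out=xmax)
        up = (yprev < 0) & (y >= 0)
        if up.any():
            ti = i * dt
            t_first = np.where(up & np.isnan(t_first), ti, t_first)
            t_last = np.where(up, ti, t_last)
            ncross += up
        d2 = (x - sx) ** 2 + y**2
        np.minimum(min_sd, d2, out=min_sd)
        yprev = y
    amp = xmax - xmin
    period = np.where(ncross >= 2, (t_last - t_first) / np.maximum(ncross - 1, 1), np.nan)
    oscillating = (amp > amp_min) & (ncross >= 3)
    return oscillating, amp, period, np.sqrt(min_sd), xmin, xmax


def _point_attractors(vecs: np.ndarray, ics: np.ndarray, **scan_kw):
    """Run the oracle for points ``vecs`` (N,3) x initial conditions (k,2)."""
    N = vecs.shape[0]
    k = ics.shape[0]
    mu2 = vecs[:, 0]
    mu1 = -vecs[:, 1]
    nu = vecs[:, 2]
    n_stable, saddle_x, focus_x, n_roots = _fp_arrays(mu1, mu2, nu)
    # expand: trajectories = points x ics; IC index 0 is relative to the
    # fastest-growing non-saddle fixed point, the rest are absolute
    M1 = np.tile(mu1, k)
    M2 = np.tile(mu2, k)
    NU = np.tile(nu, k)
    SX = np.tile(saddle_x, k)
    X0 = np.empty(N * k)
    Y0 = np.empty(N * k)
    for j in range(k):
        if j == 0:
            base = np.where(np.isfinite(focus_x), focus_x, 0.0)
            X0[:N] = base + ics[0, 0]
            Y0[:N] = ics[0, 1]
        else:
            X0[j * N : (j + 1) * N] = ics[j, 0]
            Y0[j * N : (j + 1) * N] = ics[j, 1]
    osc, amp, period, sd, xmin, xmax = _cycle_scan(M1, M2, NU, X0, Y0, SX, **scan_kw)
    osc = osc.reshape(k, N)
    amp = amp.reshape(k, N)
    period = period.reshape(k, N)
    sd = sd.reshape(k, N)
    xmin = xmin.reshape(k, N)
    xmax = xmax.reshape(k, N)
    cycle = osc.any(axis=0)
    # keep stats of the oscillating trajectory with the largest amplitude
    amp_osc = np.where(osc, amp, -np.inf)
    best = np.argmax(amp_osc, axis=0)
    sel = (best, np.arange(N))
    return {
        "n_stable": n_stable,
        "saddle_x": saddle_x,
        "cycle": cycle,
        "amp": np.where(cycle, amp[sel], np.nan),
        "period": np.where(cycle, period[sel], np.nan),
        "saddle_dist": np.where(cycle, sd[sel], np.nan),
        "cyc_xmin": np.where(cycle, xmin[sel], np.nan),
        "cyc_xmax": np.where(cycle, xmax[sel], np.nan),
        "n_roots": n_roots,
    }


_DEFAULT_ICS = np.array([[0.08, 0.0], [1.4, 0.0], [-1.4, 0.0]])


def _labels_from_stats(stats: dict) -> np.ndarray:
    ns = stats["n_stable"]
    cyc = stats["cycle"]
    lab = np.full(ns.shape, _REGION_CODES[INDETERMINATE], dtype=np.int8)
    lab[(ns == 1) & ~cyc] = _REGION_CODES[REST_ONLY]
    lab[(ns >= 2) & ~cyc] = _REGION_CODES[BISTABLE_REST_ACTIVE_REST]
    lab[(ns == 0) & cyc] = _REGION_CODES[SEIZURE_ONLY]
    lab[(ns >= 1) & cyc] = _REGION_CODES[BISTABLE_REST_SEIZURE]
    return lab


def classify_attractors(
    point: SphericalPoint,
    n_ic: int = 16,
    *,
    t_transient: float = 400.0,
    t_detect: float = 200.0,
) -> str:
    """Region label at one map point, by brute force from ``n_ic`` initial
    conditions on a grid plus one seeded at the most unstable focus."""
    side = max(2, int(math.ceil(math.sqrt(n_ic))))
    g = np.linspace(-1.5, 1.5, side)
    ics = np.array([(a, b) for a in g for b in g])
    ics = np.vstack([[0.08, 0.0], ics])
    stats = _point_attractors(
        point.vector[None, :], ics, t_transient=t_transient, t_detect=t_detect
    )
    return _REGION_NAMES[int(_labels_from_stats(stats)[0])]


@dataclass
class RegionMap:
    """Equirectangular grid of region labels and limit-cycle statistics."""

    theta: np.ndarray  # (nt,)
    phi: np.ndarray  # (np,)
    label: np.ndarray  # (nt, np) int8 region codes
    cycle: np.ndarray  # (nt, np) bool
    n_stable: np.ndarray  # (nt, np) int8
    amp: np.ndarray
    period: np.ndarray
    saddle_dist: np.ndarray
    cyc_xmin: np.ndarray
    cyc_xmax: np.ndarray
    R: float

    @property
    def label_names(self) -> dict:
        return dict(_REGION_NAMES)

    def _nearest_idx(self, theta, phi):
        it = np.clip(
            np.rint((theta - self.theta[0]) / (self.theta[1] - self.theta[0])).astype(int),
            0,
            len(self.theta) - 1,
        )
        ip = np.clip(
            np.rint((phi - self.phi[0]) / (self.phi[1] - self.phi[0])).astype(int),
            0,
            len(self.phi) - 1,
        )
        return it, ip

    def lookup_vec(self, vecs: np.ndarray):
        """Nearest-cell (label, cycle, n_stable) for sphere vectors (n, 3)."""
        vecs = np.atleast_2d(vecs)
        r = np.linalg.norm(vecs, axis=1)
        theta = np.arccos(np.clip(vecs[:, 2] / r, -1, 1))
        phi = np.arctan2(vecs[:, 1], vecs[:, 0])
        it, ip = self._nearest_idx(theta, phi)
        return self.label[it, ip], self.cycle[it, ip], self.n_stable[it, ip]

    def region_of(self, point: SphericalPoint) -> str:
        lab, _, _ = self.lookup_vec(point.vector[None, :])
        return _REGION_NAMES[int(lab[0])]

    def to_frame(self):
        import pandas as pd

        T, P = np.meshgrid(self.theta, self.phi, indexing="ij")
        return pd.DataFrame(
            {
                "theta": T.ravel(),
                "phi": P.ravel(),
                "label": self.label.ravel(),
                "cycle": self.cycle.ravel(),
                "n_stable": self.n_stable.ravel(),
                "amp": self.amp.ravel(),
                "period": self.period.ravel(),
            }
        )


def build_region_map(
    R: float = DEFAULT_RADIUS,
    n_theta: int = 181,
    n_phi: int = 361,
    *,
    ics: np.ndarray = _DEFAULT_ICS,
    t_transient: float = 400.0,
    t_detect: float = 200.0,
) -> RegionMap:
    """Classify every grid cell of the equirectangular map by brute force."""
    theta = np.linspace(0.0, math.pi, n_theta)
    phi = np.linspace(-math.pi, math.pi, n_phi)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    st = np.sin(T)
    vecs = R * np.column_stack(
        [(st * np.cos(P)).ravel(), (st * np.sin(P)).ravel(), np.cos(T).ravel()]
    )
    stats = _point_attractors(vecs, ics, t_transient=t_transient, t_detect=t_detect)
    shape = (n_theta, n_phi)
    return RegionMap(
        theta=theta,
        phi=phi,
        label=_labels_from_stats(stats).reshape(shape),
        cycle=stats["cycle"].reshape(shape),
        n_stable=stats["n_stable"].reshape(shape),
        amp=stats["amp"].reshape(shape).astype(np.float32),
        period=stats["period"].reshape(shape).astype(np.float32),
        saddle_dist=stats["saddle_dist"].reshape(shape).astype(np.float32),
        cyc_xmin=stats["cyc_xmin"].reshape(shape).astype(np.float32),
        cyc_xmax=stats["cyc_xmax"].reshape(shape).astype(np.float32),
        R=R,
    )


# ---------------------------------------------------------------------------
# numeric offset curves
# ---------------------------------------------------------------------------

def _chain_points(pts: np.ndarray, max_jump: float) -> list[np.ndarray]:
    """Greedy nearest-neighbour chaining of unordered boundary points."""
    if len(pts) == 0:
        return []
    remaining = list(range(len(pts)))
    tree = cKDTree(pts)
    chains = []
    used = np.zeros(len(pts), dtype=bool)
    for seed in range(len(pts)):
        if used[seed]:
            continue
        chain = [seed]
        used[seed] = True
        for direction in (0, 1):
            cur = chain[-1] if direction == 0 else chain[0]
            while True:
                ds, idxs = tree.query(pts[cur], k=min(8, len(pts)))
                ds, idxs = np.atleast_1d(ds), np.atleast_1d(idxs)
                nxt = None
                for d, j in zip(ds, idxs):
                    if not used[j] and d <= max_jump:
                        nxt = j
                        break
                if nxt is None:
                    break
                used[nxt] = True
                if direction == 0:
                    chain.append(nxt)
                else:
                    chain.insert(0, nxt)
                cur = nxt
        chains.append(pts[np.array(chain)])
    return chains


def numeric_offset_curves(
    region: RegionMap,
    sn: list[BifurcationCurve] | None = None,
    hopf: BifurcationCurve | None = None,
    *,
    min_chain: int = 4,
) -> list[BifurcationCurve]:
    """Trace cycle-existence boundaries and sub-label them SH / SNIC / FLC.

    The boundary where the oracle's stable cycle disappears is collected
    from adjacent grid cells; points within two grid steps of the analytic
    saddle-node curve are folds on the cycle (SNIC), points near the
    supercritical Hopf curve belong to that analytic curve and are skipped,
    and the rest are SH when a saddle sits on the cycle's closure (the
    homoclinic geometry) and FLC otherwise.
    """
    R = region.R
    sn = sn if sn is not None else sn_curves(R)
    hopf = hopf if hopf is not None else hopf_curve(R)
    sn_pts = np.vstack([c.points for c in sn])
    sn_s = np.concatenate([c.meta["s"] for c in sn])
    sn_tree = cKDTree(sn_pts)
    hopf_tree = cKDTree(hopf.points)

    C = region.cycle
    nt, nph = C.shape
    dth = region.theta[1] - region.theta[0]
    step = R * max(dth, (region.phi[1] - region.phi[0]))
    pts = []
    stats = []
    for axis in (0, 1):
        a = C[:-1, :] if axis == 0 else C[:, :-1]
        b = C[1:, :] if axis == 0 else C[:, 1:]
        diff = a != b
        ii, jj = np.nonzero(diff)
        if axis == 0:
            t_mid = (region.theta[ii] + region.theta[ii + 1]) / 2
            p_mid = region.phi[jj]
            cyc_cell = np.where(C[ii, jj], ii, ii + 1), jj
        else:
            t_mid = region.theta[ii]
            p_mid = (region.phi[jj] + region.phi[jj + 1]) / 2
            cyc_cell = ii, np.where(C[ii, jj], jj, jj + 1)
        st = np.sin(t_mid)
        v = R * np.column_stack([st * np.cos(p_mid), st * np.sin(p_mid), np.cos(t_mid)])
        pts.append(v)
        stats.append(
            {
                "amp": region.amp[cyc_cell],
                "period": region.period[cyc_cell],
                "sd": region.saddle_dist[cyc_cell],
                "xmin": region.cyc_xmin[cyc_cell],
                "xmax": region.cyc_xmax[cyc_cell],
            }
        )
    pts = np.vstack(pts)
    amp = np.concatenate([s["amp"] for s in stats])
    sd = np.concatenate([s["sd"] for s in stats])
    per_adj = np.concatenate([s["period"] for s in stats])
    cxmin = np.concatenate([s["xmin"] for s in stats])
    cxmax = np.concatenate([s["xmax"] for s in stats])

    d_sn, i_sn = sn_tree.query(pts)
    d_h, _ = hopf_tree.query(pts)
    tol = 2.5 * step
    labels = np.full(len(pts), "FLC", dtype=object)
    labels[(sd < 0.35 * amp)] = "SH"
    # SNIC: the fold lies on the cycle's closure and the period diverges
    # approaching the boundary; folds on the curve without either signature
    # stay unlabeled rather than guessed
    fold_x = sn_s[i_sn]
    on_cycle = (cxmin - 0.1 * amp <= fold_x) & (fold_x <= cxmax + 0.1 * amp)
    divergent = per_adj > 18.0
    labels[(d_sn < 3.0 * step) & on_cycle & divergent] = "SNIC"
    labels[(d_sn < 1.5 * step) & ~(on_cycle & divergent)] = "boundary"
    # an FLC boundary keeps a finite-amplitude cycle; a vanishing amplitude
    # means the boundary is the supercritical-Hopf family's threshold
    labels[(labels == "FLC") & (amp < 0.1)] = "_hopf"
    labels[d_h < tol] = "_hopf"  # belongs to the analytic Hopf curve

    curves = []
    for lab in ("SH", "SNIC", "FLC", "boundary"):
        sel = pts[labels == lab]
        for chain in _chain_points(sel, max_jump=3.0 * step):
            if len(chain) >= min_chain:
                meta = {"unlabeled": True} if lab == "boundary" else {}
                curves.append(
                    BifurcationCurve(label=lab, points=chain, method="numeric", meta=meta)
                )
    return curves


# ---------------------------------------------------------------------------
# paths and crossings
# ---------------------------------------------------------------------------

def great_circle_path(a: SphericalPoint, b: SphericalPoint) -> PathSpec:
    """The great-circle arc from ``a`` to ``b`` (error on antipodal points)."""
    return PathSpec(start=a, end=b)


def _cubic_discriminant(mu1, mu2):
    return 4.0 * mu2**3 - 27.0 * mu1**2


def _bisect_on_path(path: PathSpec, f, lo: float, hi: float, tol: float = 1e-6) -> float:
    flo = f(lo)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _sn_crossings(path: PathSpec, n_scan: int) -> list[Crossing]:
    zs = np.linspace(0.0, 1.0, n_scan)
    v = path.point(zs)
    D = _cubic_discriminant(-v[:, 1], v[:, 0])

    def f(z):
        w = path.point(z)
        return _cubic_discriminant(-w[1], w[0])

    out = []
    sign = np.sign(D)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in flips:
        z = _bisect_on_path(path, f, zs[i], zs[i + 1])
        p = path.embed(z)
        # double root sits at s with mu1 = -2 s^3 -> sign(s) = sign(-mu1)
        s = math.copysign(math.sqrt(max(p.mu2, 0.0) / 3.0), -p.mu1 if p.mu1 != 0 else 1.0)
        out.append(Crossing(z=float(z), label="SN", meta=(("s", s),)))
    # tangential near-misses: local minima of |D| that do not change sign
    absD = np.abs(D)
    scale = max(absD.max(), 1e-12)
    for i in range(1, n_scan - 1):
        if absD[i] < 1e-4 * scale and absD[i] <= absD[i - 1] and absD[i] <= absD[i + 1]:
            if not any(abs(zs[i] - c.z) < 2.0 / n_scan for c in out):
                out.append(Crossing(z=float(zs[i]), label="SN", tangential=True))
    return out


def _hopf_crossings(path: PathSpec, sn_z: list[float], n_scan: int) -> list[Crossing]:
    """Track the trace at each non-saddle fixed point between SN crossings."""
    out = []
    bounds = [0.0] + sorted(z for z in sn_z) + [1.0]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 1e-9:
            continue
        zs = np.linspace(lo + 1e-9, hi - 1e-9, max(8, int(n_scan * (hi - lo))))
        v = path.point(zs)
        mu1, mu2, nu = -v[:, 1], v[:, 0], v[:, 2]
        three = _cubic_discriminant(mu1, mu2) > 0
        # root count is constant inside the segment; evaluate sorted roots
        nroot = 3 if three.all() else 1
        traces = np.full((len(zs), 2), np.nan)
        xs_all = np.full((len(zs), 2), np.nan)
        for i, z in enumerate(zs):
            r = np.roots([1.0, 0.0, -mu2[i], -mu1[i]])
            rr = np.sort(r[np.abs(r.imag) < 1e-9].real)
            cand = [rr[0], rr[-1]] if len(rr) == 3 else [rr[0], None]
            for k, xk in enumerate(cand):
                if xk is None:
                    continue
                traces[i, k] = -(nu[i] + xk + xk * xk)
                xs_all[i, k] = xk
        for k in range(2):
            tr = traces[:, k]
            ok = np.isfinite(tr)
            if not ok.any():
                continue
            sign = np.sign(tr)
            flips = np.nonzero(ok[:-1] & ok[1:] & (sign[:-1] * sign[1:] < 0))[0]
            for i in flips:
                # refine by bisection on this tracked root's trace
                pick_hi = k == 1

                def f(z):
                    w = path.point(z)
                    r = np.roots([1.0, 0.0, -w[0], w[1]])
                    rr = np.sort(r[np.abs(r.imag) < 1e-9].real)
                    xk = rr[-1] if (pick_hi and len(rr) == 3) else rr[0]
                    return -(w[2] + xk + xk * xk)

                z = _bisect_on_path(path, f, zs[i], zs[i + 1])
                w = path.point(z)
                r = np.roots([1.0, 0.0, -w[0], w[1]])
                rr = np.sort(r[np.abs(r.imag) < 1e-9].real)
                xk = rr[-1] if (pick_hi and len(rr) == 3) else rr[0]
                det = 3 * xk * xk - w[0]
                if det <= 0:
                    continue  # neutral saddle
                l1 = first_lyapunov(xk, w[0])
                out.append(
                    Crossing(
                        z=float(z),
                        label="SupH" if l1 < 0 else "SubH",
                        meta=(("x", float(xk)), ("l1", float(l1))),
                    )
                )
    return out


def _polyline_crossings(path: PathSpec, curve: BifurcationCurve) -> list[Crossing]:
    a = path.start.vector
    b = path.end.vector
    nrm = np.cross(a, b)
    nn = np.linalg.norm(nrm)
    if nn < 1e-12:
        return []
    nrm = nrm / nn
    ua = a / np.linalg.norm(a)
    c_dir = b / np.linalg.norm(b) - (ua @ (b / np.linalg.norm(b))) * ua
    c_dir = c_dir / np.linalg.norm(c_dir)
    ang = path.central_angle
    pts = curve.points
    s = pts @ nrm
    out = []
    flips = np.nonzero(s[:-1] * s[1:] < 0)[0]
    for i in flips:
        lam = s[i] / (s[i] - s[i + 1])
        q = pts[i] + lam * (pts[i + 1] - pts[i])
        q = q / np.linalg.norm(q)
        zq = math.atan2(float(q @ c_dir), float(q @ ua)) / ang
        if -1e-6 <= zq <= 1 + 1e-6:
            out.append(Crossing(z=float(np.clip(zq, 0, 1)), label=curve.label))
    return out


def path_crossings(
    path: PathSpec,
    curves: list[BifurcationCurve],
    n_scan: int = 2001,
    dedupe_z: float = 0.02,
) -> list[Crossing]:
    """Ordered bifurcation crossings along a path.

    Saddle-node and Hopf crossings are located analytically (bisection on the
    cubic discriminant / fixed-point trace, |dz| <= 1e-6); numeric curves are
    intersected as polylines with the path's great-circle plane.  An SN
    crossing that coincides with a numeric SNIC curve is reported once, as
    SNIC (the fold lies on the invariant circle there).  Tangential
    near-crossings of the SN condition are flagged, not dropped.
    """
    has_sn = any(c.label == "SN" for c in curves)
    has_hopf = any(c.label == "Hopf" for c in curves)
    snic_pts = [c.points for c in curves if c.method == "numeric" and c.label == "SNIC"]
    snic_tree = cKDTree(np.vstack(snic_pts)) if snic_pts else None
    R = path.R
    prox = 0.035 * R  # 3D tolerance for a fold lying on a traced SNIC chain

    out: list[Crossing] = []
    sn_z: list[float] = []
    if has_sn:
        sn_cr = _sn_crossings(path, n_scan)
        sn_z = [c.z for c in sn_cr if not c.tangential]
        out.extend(sn_cr)
    if has_hopf:
        out.extend(_hopf_crossings(path, sn_z, n_scan))
    # a fold whose crossing point lies on a numeric SNIC chain is a fold on
    # the invariant circle: relabel it SNIC
    if snic_tree is not None:
        relabeled = []
        for cr in out:
            if cr.label == "SN" and not cr.tangential:
                d, _ = snic_tree.query(path.point(cr.z))
                if d < prox:
                    cr = Crossing(z=cr.z, label="SNIC", meta=cr.meta)
            relabeled.append(cr)
        out = relabeled
    # numeric chains that hug an analytic curve (SNIC along SN, SupH-side
    # boundaries along Hopf) duplicate analytic crossings: a numeric
    # crossing coinciding in z with an analytic one defers to the latter
    analytic_z = [c.z for c in out if not c.tangential]
    for c in curves:
        if c.method != "numeric":
            continue
        for cr in _polyline_crossings(path, c):
            if any(abs(z - cr.z) < 2 * dedupe_z for z in analytic_z):
                continue
            out.append(cr)
    # dedupe remaining near-identical crossings (keep the first by z)
    merged: list[Crossing] = []
    for cr in sorted(out, key=lambda c: c.z):
        if any(
            o.label == cr.label and abs(o.z - cr.z) < dedupe_z for o in merged
        ):
            continue
        merged.append(cr)
    return merged


# ---------------------------------------------------------------------------
# dynamotype enumeration
# ---------------------------------------------------------------------------

@dataclass
class EnumerationResult:
    pairs: set
    exemplars: dict  # DynamotypePair -> dict(path, z_onset, z_offset)
    details: list


def _extended_path(uf: np.ndarray, uo: np.ndarray, R: float, ext: float = 0.3):
    """Great-circle path through f (offset side) and o (onset side), extended
    by a fraction ``ext`` of their separation beyond each."""
    ang = math.acos(max(-1.0, min(1.0, float(uf @ uo))))
    if ang < 1e-6:
        return None, None, None
    s = math.sin(ang)

    def g(t):
        v = (math.sin((1 - t) * ang) * uf + math.sin(t * ang) * uo) / s
        return v / np.linalg.norm(v)

    t0, t1 = -ext, 1.0 + ext
    if (t1 - t0) * ang > math.pi * 0.98:
        return None, None, None
    start = SphericalPoint.from_vector(R * g(t0), R=R)
    end = SphericalPoint.from_vector(R * g(t1), R=R)
    zf = (0.0 - t0) / (t1 - t0)
    zo = (1.0 - t0) / (t1 - t0)
    try:
        return PathSpec(start, end), zf, zo
    except ValueError:
        return None, None, None


def _curve_samples(curves, labels, max_per_curve=14):
    """(unit vector, label, curve, unit tangent) samples from selected curves."""
    out = []

    def emit(sel, lab, c):
        if len(sel) < 2:
            return
        step = max(1, len(sel) // max_per_curve)
        for i in range(0, len(sel), step):
            j = i + 1 if i + 1 < len(sel) else i - 1
            u = sel[i] / np.linalg.norm(sel[i])
            tang = sel[j] / np.linalg.norm(sel[j]) - u
            out.append((u, lab, c, tang))

    for c in curves:
        pts = c.points
        if c.label == "Hopf":
            sup = c.meta["supercritical"]
            for crit, lab in ((True, "SupH"), (False, "SubH")):
                if lab in labels:
                    emit(pts[sup == crit], lab, c)
        elif c.label in labels:
            emit(pts, c.label, c)
    return out


def _prefilter(region: RegionMap, path: PathSpec, zf: float, zo: float) -> bool:
    zs = np.linspace(0.0, 1.0, 81)
    lab, cyc, nst = region.lookup_vec(path.point(zs))
    rest = nst >= 1
    mid = (zs > zf + 0.02) & (zs < zo - 0.02)
    below = (zs > zf - 0.12) & (zs < zf - 0.01)
    if mid.sum() >= 3:
        if cyc[mid].mean() < 0.6 or rest[(zs > zf) & (zs < zo)].mean() < 0.5:
            return False
    if below.sum() >= 2 and cyc[below].mean() > 0.5:
        return False
    # beyond onset the system must actually oscillate
    beyond = (zs > zo + 0.01) & (zs < min(1.0, zo + 0.12))
    if beyond.sum() >= 2 and cyc[beyond].mean() < 0.5:
        return False
    return True


def _hysteresis_pairs(
    region: RegionMap, path: PathSpec, crossings: list[Crossing]
) -> list[tuple[DynamotypePair, float, float]]:
    """Onset/offset crossing pairs bounding one bistability interval.

    An offset crossing at ``z_f`` and an onset crossing at ``z_o > z_f``
    realise a hysteresis-loop dynamotype when the interval between them is
    bistable rest/seizure, only the cycle survives just beyond the onset
    crossing, and the cycle is gone just below the offset crossing.
    """
    out = []
    cs = []
    for c in sorted(crossings, key=lambda c: c.z):  # dedupe near-identical
        if c.tangential:
            continue
        if cs and c.label == cs[-1].label and c.z - cs[-1].z < 0.01:
            continue
        cs.append(c)
    m = 0.02

    def exact_n_stable(zs):
        # the region grid can misreport on paths running parallel to a
        # curve, so count stable fixed points analytically at the exact
        # path points; only cycle existence comes from the grid
        v = np.atleast_2d(path.point(zs))
        nst, _, _, _ = _fp_arrays(-v[:, 1], v[:, 0], v[:, 2])
        return nst

    for f in cs:
        if f.label not in OFFSET_CAPABLE:
            continue
        for o in cs:
            if o.label not in ONSET_CAPABLE or o.z <= f.z + 2 * m:
                continue
            zs = np.linspace(f.z + m, o.z - m, 15)
            _, cyc, _ = region.lookup_vec(path.point(zs))
            if np.mean(cyc) < 0.8:
                continue
            if np.mean(exact_n_stable(zs) == 1) < 0.9:  # one occupied rest branch
                continue
            hi = np.linspace(o.z + m, min(1.0, o.z + 0.1), 5)
            _, cyc, _ = region.lookup_vec(path.point(hi))
            if np.mean(cyc) < 0.5 or np.mean(exact_n_stable(hi) == 0) < 0.6:
                continue
            lo = np.linspace(max(0.0, f.z - 0.1), f.z - m, 5)
            _, cyc, _ = region.lookup_vec(path.point(lo))
            if np.mean(~cyc) < 0.5 or np.mean(exact_n_stable(lo) >= 1) < 0.6:
                continue
            # no other crossing may interrupt the bistable interval
            if any(f.z + m < c.z < o.z - m for c in cs):
                continue
            out.append((DynamotypePair(o.label, f.label), f.z, o.z))
    return out


def _slow_wave_pair(region: RegionMap, u: np.ndarray, tangent: np.ndarray, label: str, R: float):
    """Same-curve (slow-wave) dynamotype: the curve directly separates a
    rest-only from a seizure-only region, so the back-and-forth slow drive
    bursts across the single curve (SNIC/SNIC, SupH/SupH)."""
    if label not in ONSET_CAPABLE or label not in OFFSET_CAPABLE:
        return None
    step = 2.5 * (region.theta[1] - region.theta[0])
    nrm = np.cross(u, tangent)  # the curve's normal within the sphere
    n = np.linalg.norm(nrm)
    if n < 1e-9:
        return None
    nrm /= n
    va = u * math.cos(step) + nrm * math.sin(step)
    vb = u * math.cos(step) - nrm * math.sin(step)
    la, ca, na = region.lookup_vec(R * va[None, :])
    lb, cb, nb = region.lookup_vec(R * vb[None, :])
    # one side must oscillate, the other must hold a rest state and no cycle
    for (c1, n1), (c2, n2), flip in (
        ((ca, na), (cb, nb), False),
        ((cb, nb), (ca, na), True),
    ):
        if bool(c1[0]) and not bool(c2[0]) and int(n2[0]) >= 1:
            # exemplar path: a longer arc along the same normal, oriented
            # with the oscillating side at z=1
            half = 0.12
            ea = u * math.cos(half) - nrm * math.sin(half)
            eb = u * math.cos(half) + nrm * math.sin(half)
            if flip:
                ea, eb = eb, ea
            path = PathSpec(
                SphericalPoint.from_vector(R * ea, R=R),
                SphericalPoint.from_vector(R * eb, R=R),
            )
            return DynamotypePair(label, label), path
    return None


def _sustains_bursting(
    path: PathSpec,
    z0: float,
    *,
    epsilon: float = 0.002,
    duration: float = 3000.0,
    dt: float = 0.01,
    sigma_fast: float = 0.005,
    seed: int = 7,
    min_epochs: int = 3,
) -> bool:
    """True when the slow-driven model on ``path`` alternates rest and
    seizure epochs.  A crossing-pair that cannot sustain this back-and-forth
    (e.g. a supercritical Hopf under the smooth drive, which settles into
    constant-amplitude spiking) is not a seizure dynamotype."""
    for mode in ("smooth", "hysteretic"):
        try:
            r = simulate(
                path,
                SlowSpec(epsilon=epsilon, onset_at_end=True, mode=mode),
                NoiseSpec(sigma_fast, 0.0, seed=seed),
                duration=duration,
                dt=dt,
                z0=z0,
            )
        except (ValueError, RuntimeError):
            continue
        epochs = r.seizure_epochs(merge_gap=25.0)
        complete = [e for e in epochs if e[2]]
        if len(complete) >= min_epochs:
            return True
    return False


def enumerate_planar_dynamotypes(
    region: RegionMap,
    curves: list[BifurcationCurve],
    *,
    max_pair_angle: float = 1.3,
    min_pair_angle: float = 0.04,
    max_paths_per_pair: int = 6,
    confirm_dynamics: bool = True,
) -> EnumerationResult:
    """Enumerate (onset, offset) pairs realisable by planar great-circle paths.

    A hysteresis-loop dynamotype requires a path that crosses an onset curve
    and an offset curve bounding the same bistability region: the interval
    between the two located crossings must be bistable rest/seizure, with
    the cycle alone surviving beyond the onset crossing and the cycle gone
    below the offset crossing.  The slow-wave dynamotypes (a single curve
    that can both start and stop the seizure) are admitted where that curve
    directly separates oscillating from resting territory.  Each accepted
    pair is finally confirmed by running the slow-driven model on its
    exemplar path and requiring sustained rest/seizure alternation.  The
    output is derived entirely from the computed map, not assumed.
    """
    R = region.R
    onset_samples = _curve_samples(curves, {"SN", "SNIC", "SupH", "SubH"})
    offset_samples = _curve_samples(curves, {"SH", "SNIC", "SupH", "FLC"})

    confirmed: dict[DynamotypePair, dict] = {}
    details = []

    # slow-wave (same curve back and forth) types
    for u, lab, c, tang in onset_samples:
        got = _slow_wave_pair(region, u, tang, lab, R)
        if got is not None:
            pair, path = got
            if pair not in confirmed:
                confirmed[pair] = {
                    "path": path,
                    "z_onset": 0.5,
                    "z_offset": 0.5,
                    "mechanism": "slow-wave",
                }
                details.append({"pair": str(pair), "mechanism": "slow-wave"})

    # hysteresis-loop types from candidate paths between curve samples
    tried: dict[tuple, int] = {}
    for uf, flab, fc, _tf in offset_samples:
        for uo, olab, oc, _to in onset_samples:
            key = (olab, flab)
            if tried.get(key, 0) >= max_paths_per_pair:
                continue
            angd = math.acos(max(-1.0, min(1.0, float(uf @ uo))))
            if not (min_pair_angle <= angd <= max_pair_angle):
                continue
            path, zf, zo = _extended_path(uf, uo, R)
            if path is None or not _prefilter(region, path, zf, zo):
                continue
            tried[key] = tried.get(key, 0) + 1
            crossings = path_crossings(path, curves)
            for pair, z_f, z_o in _hysteresis_pairs(region, path, crossings):
                details.append(
                    {"pair": str(pair), "mechanism": "hysteresis", "intended": key}
                )
                if pair not in confirmed:
                    confirmed[pair] = {
                        "path": path,
                        "z_onset": z_o,
                        "z_offset": z_f,
                        "mechanism": "hysteresis",
                    }
    if confirm_dynamics:
        kept = {}
        for pair, ex in confirmed.items():
            if ex["mechanism"] == "slow-wave":
                probe_path, z0 = ex["path"], 0.3  # rest side (oriented)
            else:
                # probe a path trimmed to the neighbourhood of the two
                # crossings: the far extensions of the candidate path are
                # not part of the dynamotype and may host unrelated regimes
                lo = max(0.0, ex["z_offset"] - 0.15)
                hi = min(1.0, ex["z_onset"] + 0.12)
                probe_path = PathSpec(
                    SphericalPoint.from_vector(ex["path"].point(lo), R=R),
                    SphericalPoint.from_vector(ex["path"].point(hi), R=R),
                )
                z0 = float(
                    np.clip((0.5 * (ex["z_onset"] + ex["z_offset"]) - lo) / (hi - lo), 0.05, 0.95)
                )
            ok = _sustains_bursting(probe_path, z0)
            details.append(
                {"pair": str(pair), "mechanism": ex["mechanism"], "sustained": ok}
            )
            if ok:
                kept[pair] = ex
        confirmed = kept
    return EnumerationResult(pairs=set(confirmed), exemplars=confirmed, details=details)


# ---------------------------------------------------------------------------
# one-call map construction
# ---------------------------------------------------------------------------

def build_map(
    R: float = DEFAULT_RADIUS,
    n_theta: int = 181,
    n_phi: int = 361,
    *,
    enumerate_types: bool = True,
):
    """Build curves, region map, numeric offset curves and (optionally) the
    planar dynamotype enumeration.  Returns a dict of all artifacts."""
    sn = sn_curves(R)
    hopf = hopf_curve(R)
    region = build_region_map(R, n_theta, n_phi)
    numeric = numeric_offset_curves(region, sn, hopf)
    curves = sn + [hopf] + numeric
    out = {"R": R, "sn": sn, "hopf": hopf, "region": region, "numeric": numeric, "curves": curves}
    if enumerate_types:
        out["enumeration"] = enumerate_planar_dynamotypes(region, curves)
    return out
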
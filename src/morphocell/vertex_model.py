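"""Single-cell vertex model of cancer-cell morphological evolution.

The basal cell outline is a closed chain of vertices moved by overdamped
force balance,

    eta_vis dx/dt = F_tension + F_area + F_rac + F_adhesion + F_fibre + F_noise

with

* cortical line tension pulling each vertex toward its neighbours,
* area elasticity (osmotic-pressure-like) restoring the area toward A0,
* a Rac1 protrusion force acting outward on a front sector of the boundary
  with a Gaussian temporal envelope (one Rac activation cycle),
* cell–matrix adhesion entering as a Hill-gated friction that opposes each
  vertex's motion (the Hill factor saturates with RhoA level, standing in
  for focal-adhesion engagement),
* stress fibres as linear springs between boundary vertices in the front
  and rear sectors and the cell centroid, and
* Gaussian white noise for thermal fluctuations.

A three-phase schedule (isotropic expansion → anterior–posterior
polarisation → depolarisation) reproduces the round → droplet → spindle
shape sequence; per-phase parameter overrides express the single-factor
perturbations (Rac inhibition, focal-adhesion reduction, tension change).

Units are arbitrary but consistent: length in μm, time in s, force in nN.
No parameter magnitudes are published for this model; the shipped defaults
were chosen once so that the analytic equilibria and the qualitative phase
behaviour hold, and they are part of the versioned configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "Phase",
    "PhaseSchedule",
    "CellBoundaryState",
    "Trajectory",
    "CellSimulation",
    "init_cell",
    "force_tension",
    "force_area",
    "force_rac",
    "force_adhesion",
    "force_fibre",
    "force_noise",
    "step",
    "simulate",
    "morphometrics",
    "default_params",
    "default_schedule",
]


@dataclass
class ModelParams:
    """All mechanical parameters of the force balance.

    eta_vis : drag coefficient, nN·s/μm
    k_tension : cortical line tension K_L, nN
    k_area : areal elastic modulus K_a, nN/μm³
    a0 : target (preferred) spread area, μm²
    f_rac : integrated Rac protrusion strength, nN·s (the per-vertex force
        peaks at f_rac/(sigma·√(2π)))
    sigma : SD of the temporal Rac pulse, s
    t_rac : centre of the Rac pulse within its phase, s
    f_cams : adhesion (CAM) strength, nN·s/μm at full Hill saturation
    l_rho : RhoA concentration entering the Hill factor, a.u.
    k_hill : apparent dissociation constant of the Hill factor, a.u.
    n_hill : Hill coefficient (≥ 1)
    k_fibre : stress-fibre spring stiffness, nN/μm
    l0_fibre : stress-fibre rest (critical) length, μm
    f_fibre_half : half-saturation of the fibre→substrate force transmission
        through focal adhesions, nN·s/μm.  Stress fibres terminate at focal
        adhesions, so their force on the boundary is scaled by
        γ/(f_fibre_half + γ) with γ = f_cams·H the adhesion engagement;
        0 disables the coupling (fibres act at full strength regardless of
        adhesion)
    fibre_gate_lo / fibre_gate_hi : elongation gate for the polarity-axis
        fibres.  Stress fibres aligned with the A-P axis only exist once a
        polarity axis does, so their force ramps linearly from zero at
        length/width = fibre_gate_lo to full strength at fibre_gate_hi; an
        unpolarised cell (length ≈ width) feels no fibre force.  Set
        fibre_gate_hi = fibre_gate_lo to disable the gate
    f_noise : thermal noise force scale, nN
    dt : integration time step, s
    n_vertices : boundary resolution (≥ 12)
    rac_sector : angular half-width of the Rac-active front about +x, rad
    fibre_sector : angular half-width of the fibre-anchored front/rear
        sectors about the ±x axes, rad (π anchors every vertex)
    fibre_on : whether fibre springs act at all
    a_init : initial spread area, μm²
    seed : base RNG seed
    """

    eta_vis: float = 1.0
    k_tension: float = 0.5
    k_area: float = 0.01
    a0: float = 400.0
    f_rac: float = 400.0
    sigma: float = 30.0
    t_rac: float = 180.0
    f_cams: float = 10.0
    l_rho: float = 1.0
    k_hill: float = 1.0
    n_hill: float = 2.0
    k_fibre: float = 0.2
    l0_fibre: float = 11.5
    f_fibre_half: float = 1.0
    fibre_gate_lo: float = 1.05
    fibre_gate_hi: float = 1.15
    f_noise: float = 0.02
    dt: float = 0.05
    n_vertices: int = 64
    rac_sector: float = np.pi / 3
    fibre_sector: float = np.pi / 4
    fibre_on: bool = True
    a_init: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eta_vis", "k_tension", "k_area", "dt", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if not 0 < self.rac_sector <= np.pi:
            raise ValueError("rac_sector must be in (0, pi]")

    def hill_factor(self) -> float:
        """Saturating adhesion engagement H = L^n / (K + L^n) in [0, 1)."""
        ln = self.l_rho**self.n_hill
        return ln / (self.k_hill + ln) if ln > 0 else 0.0

    def with_overrides(self, overrides: dict[str, float]) -> "ModelParams":
        valid = {f.name for f in fields(ModelParams)}
        bad = set(overrides) - valid
        if bad:
            raise ValueError(f"unknown parameter override(s): {sorted(bad)}")
        return replace(self, **overrides)


@dataclass
class Phase:
    """One stage of the morphological evolution protocol."""

    name: str
    duration: float
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")


@dataclass
class PhaseSchedule:
    phases: list[Phase]

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)


def default_params(**kw) -> ModelParams:
    return ModelParams(**kw)


def default_schedule() -> PhaseSchedule:
    """The three-phase round → droplet → spindle protocol.

    Phase 1 expands a small round cell isotropically (no Rac, no fibres,
    almost no adhesion).  Phase 2 fires one Rac cycle on the front sector
    with fibres and adhesion engaged, polarising the cell into a droplet.
    Phase 3 switches Rac off; fibres hold the poles while raised cortical
    tension narrows the body into a spindle.
    """
    return PhaseSchedule(
        phases=[
            Phase("isotropic_expansion", 120.0,
                  {"f_rac": 0.0, "fibre_on": False, "f_cams": 0.0}),
            Phase("ap_polarisation", 250.0, {}),
            Phase("depolarisation", 350.0,
                  {"f_rac": 0.0, "k_tension": 1.0, "k_fibre": 0.6,
                   "l0_fibre": 17.0}),
        ]
    )


@dataclass
class CellBoundaryState:
    """Cell outline at one instant: closed positively-oriented vertex chain."""

    vertices: np.ndarray  # (n, 2), μm
    time: float = 0.0
    rac_flags: np.ndarray | None = None  # per-vertex: in the Rac front sector
    fibre_flags: np.ndarray | None = None  # per-vertex: carries a fibre spring

    def copy(self) -> "CellBoundaryState":
        return CellBoundaryState(
            self.vertices.copy(),
            self.time,
            None if self.rac_flags is None else self.rac_flags.copy(),
            None if self.fibre_flags is None else self.fibre_flags.copy(),
        )

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def perimeter(self) -> float:
        d = np.roll(self.vertices, -1, axis=0) - self.vertices
        return float(np.linalg.norm(d, axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        # polygon (area-weighted) centroid
        v = self.vertices
        v1 = np.roll(v, -1, axis=0)
        cross = v[:, 0] * v1[:, 1] - v1[:, 0] * v[:, 1]
        a = cross.sum() / 2.0
        cx = ((v[:, 0] + v1[:, 0]) * cross).sum() / (6.0 * a)
        cy = ((v[:, 1] + v1[:, 1]) * cross).sum() / (6.0 * a)
        return np.array([cx, cy])

    def edge_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(s_plus, s_minus): vectors from each vertex to its two neighbours."""
        v = self.vertices
        return np.roll(v, -1, axis=0) - v, np.roll(v, 1, axis=0) - v

    def coverage_lengths(self) -> np.ndarray:
        """ŝ_i = (|s⁺| + |s⁻|)/2, the cortical length covered by vertex i."""
        sp, sm = self.edge_vectors()
        return 0.5 * (np.linalg.norm(sp, axis=1) + np.linalg.norm(sm, axis=1))

    def outward_normals(self) -> np.ndarray:
        """Unit outward normal at each vertex (from the local tangent)."""
        sp, sm = self.edge_vectors()
        tangent = sp - sm  # central-difference tangent
        norm = np.linalg.norm(tangent, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        t = tangent / norm
        # for a positively-oriented (CCW) chain the outward normal is the
        # tangent rotated -90°: (ty, -tx)
        return np.column_stack([t[:, 1], -t[:, 0]])

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.vertices).is_valid


# ---------------------------------------------------------------------------
# initial condition and sector assignment
# ---------------------------------------------------------------------------

def _sector_flags(state: CellBoundaryState, half_width: float, both_poles: bool = False) -> np.ndarray:
    """Vertices whose position angle about the centroid lies within
    half_width of the +x axis (or of the ±x axes when both_poles)."""
    rel = state.vertices - state.centroid
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    front = np.abs(ang) <= half_width + 1e-12
    if not both_poles:
        return front
    rear = np.abs(np.abs(ang) - np.pi) <= half_width + 1e-12
    return front | rear


def init_cell(params: ModelParams) -> CellBoundaryState:
    """Regular n-gon of area ``a_init`` centred at the origin.

    The Rac sector is assigned to vertices whose outward normal (equal to
    the position direction on a regular polygon) lies within ``rac_sector``
    of +x; fibre anchors to vertices within ``fibre_sector`` of the ±x axes.
    """
    n = params.n_vertices
    if n < 12:
        raise ValueError("n_vertices must be >= 12 (normal estimation unstable)")
    # circumradius giving polygon area a_init: A = (1/2) n R^2 sin(2π/n)
    R = np.sqrt(2.0 * params.a_init / (n * np.sin(2.0 * np.pi / n)))
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    verts = R * np.column_stack([np.cos(theta), np.sin(theta)])
    state = CellBoundaryState(vertices=verts, time=0.0)
    state.rac_flags = _sector_flags(state, params.rac_sector)
    state.fibre_flags = _sector_flags(state, params.fibre_sector, both_poles=True)
    return state


# ---------------------------------------------------------------------------
# forces (vectorised; per-vertex wrappers expose the single-vertex contract)
# ---------------------------------------------------------------------------

def _tension_all(state: CellBoundaryState, params: ModelParams) -> np.ndarray:
    sp, sm = state.edge_vectors()
    np_ = np.linalg.norm(sp, axis=1, keepdims=True)
    nm = np.linalg.norm(sm, axis=1, keepdims=True)
    if np.any(np_ == 0) or np.any(nm == 0):
        raise ValueError("coincident neighbouring vertices")
    return params.k_tension * (sp / np_ + sm / nm)


def _area_all(state: CellBoundaryState, params: ModelParams) -> np.ndarray:
    s_hat = state.coverage_lengths()[:, None]
    dA = state.area - params.a0
    return -params.k_area * s_hat * dA * state.outward_normals()


def _rac_envelope(t_phase: float, params: ModelParams) -> float:
    z = (t_phase - params.t_rac) / params.sigma
    return np.exp(-0.5 * z * z) / (params.sigma * np.sqrt(2.0 * np.pi))


def _rac_all(state: CellBoundaryState, t_phase: float, params: ModelParams) -> np.ndarray:
    if params.f_rac == 0.0 or state.rac_flags is None:
        return np.zeros_like(state.vertices)
    mag = params.f_rac * _rac_envelope(t_phase, params)
    F = mag * state.outward_normals()
    F[~state.rac_flags] = 0.0
    return F


def _adhesion_all(dx_prev: np.ndarray, params: ModelParams) -> np.ndarray:
    if params.dt <= 0:
        raise ValueError("dt must be positive")
    H = params.hill_factor()
    return -params.f_cams * H * dx_prev / params.dt


def _fibre_transmission(params: ModelParams) -> float:
    """Fraction of fibre force transmitted to the boundary via adhesions."""
    if params.f_fibre_half <= 0:
        return 1.0
    gamma = params.f_cams * params.hill_factor()
    return gamma / (params.f_fibre_half + gamma)


def _fibre_all(state: CellBoundaryState, params: ModelParams) -> np.ndarray:
    F = np.zeros_like(state.vertices)
    if not params.fibre_on or params.k_fibre == 0.0 or state.fibre_flags is None:
        return F
    w = _fibre_transmission(params)
    if params.fibre_gate_hi > params.fibre_gate_lo:
        v = state.vertices
        length = v[:, 0].max() - v[:, 0].min()
        width = v[:, 1].max() - v[:, 1].min()
        elong = length / width if width > 0 else 1.0
        w *= float(np.clip(
            (elong - params.fibre_gate_lo)
            / (params.fibre_gate_hi - params.fibre_gate_lo),
            0.0, 1.0,
        ))
    if w == 0.0:
        return F
    anchor = state.centroid
    rel = anchor - state.vertices  # vertex → anchor
    L = np.linalg.norm(rel, axis=1)
    ok = state.fibre_flags & (L > 1e-12)
    coincident = state.fibre_flags & (L <= 1e-12)
    if coincident.any():
        logger.warning("fibre anchor coincident with vertex; zero fibre force")
    u = np.zeros_like(rel)
    u[ok] = rel[ok] / L[ok, None]
    # contractile (toward anchor) when L > L0, pushing outward when L < L0
    F[ok] = w * params.k_fibre * (L[ok, None] - params.l0_fibre) * u[ok]
    return F


def _noise_all(rng: np.random.Generator, n: int, params: ModelParams) -> np.ndarray:
    if params.f_noise == 0.0:
        return np.zeros((n, 2))
    return params.f_noise * rng.standard_normal((n, 2))


# single-vertex views ---------------------------------------------------------

def force_tension(state: CellBoundaryState, i: int, params: ModelParams) -> np.ndarray:
    """Cortical tension on vertex i: K_L (ŝ⁺ + ŝ⁻), ŝ± unit vectors to the
    neighbours; contractile, and sums to zero over the closed chain."""
    return _tension_all(state, params)[i]


def force_area(state: CellBoundaryState, i: int, params: ModelParams) -> np.ndarray:
    """Area elasticity on vertex i: −K_a ŝ_i (A − A0) r̂_nor — outward when
    the cell is below its target area, inward above it."""
    return _area_all(state, params)[i]


def force_rac(state: CellBoundaryState, i: int, t: float, params: ModelParams) -> np.ndarray:
    """Rac protrusion on vertex i at phase time t: outward normal force with
    Gaussian temporal envelope; zero outside the Rac front sector."""
    return _rac_all(state, t, params)[i]


def force_adhesion(state: CellBoundaryState, i: int, params: ModelParams,
                   dx_prev: np.ndarray) -> np.ndarray:
    """Hill-gated adhesion friction on vertex i, opposing its previous-step
    displacement dx_prev."""
    return _adhesion_all(np.atleast_2d(dx_prev), params)[0]


def force_fibre(state: CellBoundaryState, i: int, params: ModelParams) -> np.ndarray:
    """Stress-fibre spring on vertex i: K_fibre (L − L0) along the
    vertex–centroid line; zero if the vertex carries no fibre."""
    return _fibre_all(state, params)[i]


def force_noise(rng: np.random.Generator, params: ModelParams) -> np.ndarray:
    """Thermal noise: f_noise · (g1, g2) with gi ~ N(0, 1)."""
    return _noise_all(rng, 1, params)[0]


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

class SimulationError(RuntimeError):
    pass


def total_force(
    state: CellBoundaryState,
    params: ModelParams,
    t_phase: float,
    dx_prev: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    F = _tension_all(state, params) + _area_all(state, params)
    F += _rac_all(state, t_phase, params)
    F += _adhesion_all(dx_prev, params)
    F += _fibre_all(state, params)
    if rng is not None:
        F += _noise_all(rng, state.n, params)
    return F


def step(
    state: CellBoundaryState,
    params: ModelParams,
    rng: np.random.Generator | None = None,
    *,
    t_phase: float | None = None,
    dx_prev: np.ndarray | None = None,
    check: bool = True,
) -> tuple[CellBoundaryState, np.ndarray]:
    """One explicit-Euler update of every vertex simultaneously.

    Forces are evaluated on the pre-step state; x ← x + (dt/η) ΣF and time
    advances by dt.  Returns (new_state, displacement) so the caller can
    feed the displacement back as ``dx_prev`` for the adhesion friction.

    Raises SimulationError if the maximum displacement exceeds half the mean
    vertex spacing (instability: reduce dt) or, when ``check``, if the
    polygon self-intersects after the update.
    """
    if t_phase is None:
        t_phase = state.time
    if dx_prev is None:
        dx_prev = np.zeros_like(state.vertices)
    # The adhesion friction −γ·dx/dt (γ = f_cams·H) is treated implicitly:
    # with explicit dx_prev the update diverges by oscillation whenever
    # γ > η_vis, whereas folding the friction into the drag is
    # unconditionally consistent and identical in the dt → 0 limit.
    F = total_force(state, params, t_phase, np.zeros_like(dx_prev), rng)
    gamma = params.f_cams * params.hill_factor()
    dx = params.dt / (params.eta_vis + gamma) * F
    max_dx = float(np.linalg.norm(dx, axis=1).max())
    s_mean = state.perimeter / state.n
    if max_dx > 0.5 * s_mean:
        raise SimulationError(
            f"unstable step at t={state.time:.2f}: max |Δx| = {max_dx:.3g} "
            f"exceeds ŝ/2 = {0.5 * s_mean:.3g}; reduce dt"
        )
    new = state.copy()
    new.vertices = state.vertices + dx
    new.time = state.time + params.dt
    if check and not new.is_simple():
        raise SimulationError(
            f"polygon self-intersection at t={new.time:.2f}; "
            f"state dump: area={new.area:.3g}, perimeter={new.perimeter:.3g}"
        )
    return new, dx


def resample_if_needed(
    state: CellBoundaryState, params: ModelParams, ratio: float = 3.0
) -> tuple[CellBoundaryState, bool]:
    """Arc-length resampling when vertex spacing becomes too uneven.

    Triggered when max/min neighbour spacing exceeds ``ratio``; the polygon
    is resampled to equal arc length and rescaled about the centroid so the
    area is preserved to better than 0.1 %.
    """
    sp, _ = state.edge_vectors()
    lens = np.linalg.norm(sp, axis=1)
    if lens.min() <= 0 or lens.max() / lens.min() <= ratio:
        return state, False
    v = state.vertices
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], state.n, endpoint=False)
    newv = np.column_stack(
        [np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])]
    )
    new = state.copy()
    new.vertices = newv
    a_old, a_new = state.area, new.area
    if a_new > 0:
        c = new.centroid
        new.vertices = c + (new.vertices - c) * np.sqrt(a_old / a_new)
    logger.info("resampled boundary at t=%.2f (spacing ratio %.2f)", state.time, lens.max() / lens.min())
    return new, True


@dataclass
class Trajectory:
    """Sampled states and morphometrics of one simulation run."""

    times: np.ndarray
    states: list[CellBoundaryState]
    metrics: "object"  # pandas DataFrame; typed loosely to keep imports light
    phase_bounds: dict[str, tuple[float, float]]
    params: ModelParams
    schedule: PhaseSchedule
    seed: int
    resample_events: list[float] = field(default_factory=list)

    def phase_end_metrics(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, (_, t1) in self.phase_bounds.items():
            idx = int(np.searchsorted(self.times, t1 - 1e-9, side="left"))
            idx = min(idx, len(self.times) - 1)
            out[name] = {k: float(self.metrics[k].iloc[idx]) for k in self.metrics.columns if k != "time"}
        return out


def morphometrics(state: CellBoundaryState) -> dict[str, float]:
    """A-P length/width (extents along/orthogonal to +x), their ratio, area
    and circularity 4πA/P² of one boundary state."""
    v = state.vertices
    ap_length = float(v[:, 0].max() - v[:, 0].min())
    ap_width = float(v[:, 1].max() - v[:, 1].min())
    A, P = state.area, state.perimeter
    return {
        "ap_length": ap_length,
        "ap_width": ap_width,
        "width_length_ratio": ap_width / ap_length if ap_length > 0 else np.nan,
        "area": A,
        "circularity": 4.0 * np.pi * A / P**2 if P > 0 else np.nan,
    }


class CellSimulation:
    """Driver running a ModelParams + PhaseSchedule protocol to a Trajectory.

    Deterministic for a fixed seed.  Sampling interval defaults to every
    second of simulated time.
    """

    def __init__(
        self,
        params: ModelParams | None = None,
        schedule: PhaseSchedule | None = None,
        sample_every: float = 1.0,
        resample: bool = True,
        check_simple: bool = False,
    ) -> None:
        self.params = params or default_params()
        self.schedule = schedule or default_schedule()
        self.sample_every = sample_every
        self.resample = resample
        self.check_simple = check_simple

    def run(self, seed: int | None = None) -> Trajectory:
        import pandas as pd

        params = self.params
        seed = params.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        state = init_cell(params)
        dx_prev = np.zeros_like(state.vertices)
        times, states, rows = [], [], []
        phase_bounds: dict[str, tuple[float, float]] = {}
        resample_events: list[float] = []

        def sample(st: CellBoundaryState) -> None:
            times.append(st.time)
            states.append(st.copy())
            rows.append({"time": st.time, **morphometrics(st)})

        sample(state)
        t_global = 0.0
        for phase in self.schedule.phases:
            p = params.with_overrides(phase.overrides)
            phase_start = t_global
            phase_bounds[phase.name] = (phase_start, phase_start + phase.duration)
            n_steps = int(round(phase.duration / p.dt))
            sample_stride = max(1, int(round(self.sample_every / p.dt)))
            for k in range(n_steps):
                t_phase = state.time - phase_start
                try:
                    state, dx_prev = step(
                        state, p, rng, t_phase=t_phase, dx_prev=dx_prev,
                        check=self.check_simple,
                    )
                except SimulationError as exc:
                    raise SimulationError(
                        f"phase {phase.name!r}: {exc}"
                    ) from exc
                # keep sector membership coherent as the shape deforms
                state.rac_flags = _sector_flags(state, p.rac_sector)
                state.fibre_flags = _sector_flags(state, p.fibre_sector, both_poles=True)
                if self.resample:
                    state, did = resample_if_needed(state, p)
                    if did:
                        resample_events.append(state.time)
                        dx_prev = np.zeros_like(state.vertices)
                if (k + 1) % sample_stride == 0:
                    sample(state)
            t_global = phase_start + phase.duration
        metrics = pd.DataFrame(rows)
        return Trajectory(
            times=np.asarray(times),
            states=states,
            metrics=metrics,
            phase_bounds=phase_bounds,
            params=params,
            schedule=self.schedule,
            seed=seed,
            resample_events=resample_events,
        )


def simulate(
    params: ModelParams | None = None,
    schedule: PhaseSchedule | None = None,
    seed: int | None = None,
    **kw,
) -> Trajectory:
    """Run the three-phase protocol; thin wrapper over CellSimulation."""
    return CellSimulation(params, schedule, **kw).run(seed=seed)
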
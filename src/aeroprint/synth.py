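"""Synthetic exhaled-aerosol fingerprint generation.

An exhaled-aerosol fingerprint (AFP) is the spatial pattern of particles a
subject deposits on a mouth filter during exhalation.  Airway constriction in
a segmental bronchiole starves part of the filter of particles, so the
pattern carries a spatial signature of the disease site and severity.  This
module produces synthetic fingerprints with the statistical structure such
patterns exhibit:

* two asymmetric spiral vortices in the lower half of the filter disc,
* two particle "hot spots" (one above the left vortex, one in the upper
  right bordering the depleted zone),
* a crescent-shaped particle-depletion sector at the top of the disc whose
  angular width and depletion probability grow with the bronchial
  constriction level D0 (healthy) .. D3 (75 % diameter reduction),
* strong dependence on inhalation flow rate (20-40 L/min) and negligible
  dependence on particle diameter within 0.2-5.0 um,
* small affine distortions for upper-airway variants (oral-cavity
  expansion, tracheal contraction).

Two generation routes exist: a fast phenomenological mixture sampler
(:func:`generate_fingerprint`, used for dataset construction) and a
desk-scale Lagrangian particle integrator (:func:`simulate_particles`) that
integrates the particle equation of motion

    dv/dt = (f / (tau_p * C_c)) (u - v) + g (1 - alpha) + f_brownian + f_lift

in an analytic flow field, with Stokes drag relaxation time tau_p,
Cunningham slip correction C_c and fluid/particle density ratio alpha.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "R_DEPOSITION",
    "DISEASE_CONSTRICTION",
    "UA_VARIANTS",
    "GeneratorConstants",
    "FingerprintConfig",
    "FlowField",
    "AerosolFingerprint",
    "PhysicsParams",
    "ExperimentDesign",
    "Dataset",
    "build_flow_field",
    "generate_fingerprint",
    "simulate_particles",
    "cunningham_correction",
    "particle_relaxation_time",
    "generate_dataset",
    "ideal_design",
    "realistic_design",
    "depletion_mask",
    "integrate_states",
    "derive_cell_seed",
]

#: Deposition radius on the unit filter disc.  Chosen < sqrt(2)*(1 - 1/3) so
#: the four corner cells of a 6x6 grid over the bounding square can never
#: receive a particle; their per-cell fractal dimensions are therefore
#: exactly constant (zero) across any dataset and are pruned as
#: zero-variance features.
R_DEPOSITION = 0.92

#: Constriction fraction of the diseased bronchiole per disease level.
DISEASE_CONSTRICTION = {0: 0.00, 1: 0.25, 2: 0.50, 3: 0.75}

UA_VARIANTS = ("control", "oral_expansion", "tracheal_contraction")


class IntegrationError(RuntimeError):
    """Non-finite particle state encountered during Lagrangian integration."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite particle state at step {step}")


# ---------------------------------------------------------------------------
# generator constants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConstants:
    """All tunable constants of the phenomenological fingerprint sampler.

    The defaults define the study conditions the synthetic datasets emulate;
    they are serialisable to YAML via :meth:`to_dict` / :meth:`from_dict` so
    a run manifest can record them exactly.
    """

    # mixture weights (background, vortex 1, vortex 2, hot spot 1, hot spot 2)
    mixture_weights: tuple[float, ...] = (0.28, 0.26, 0.22, 0.12, 0.12)
    # vortex spiral geometry
    vortex_centers: tuple[tuple[float, float], ...] = ((-0.38, -0.42), (0.33, -0.35))
    vortex_arm_radius: tuple[float, float] = (0.50, 0.42)
    vortex_arm_turns: tuple[float, float] = (2.5, -2.0)
    vortex_scatter: float = 0.035
    # hot spots: one above the left vortex, one upper-right bordering the crescent
    hotspot_centers: tuple[tuple[float, float], ...] = ((-0.30, -0.05), (0.52, 0.55))
    hotspot_sigma: tuple[float, float] = (0.10, 0.08)
    # crescent depletion sector (top of the disc), per disease level D0..D3
    depletion_width_rad: tuple[float, ...] = (0.0, 1.2, 1.8, 2.4)
    depletion_probability: tuple[float, ...] = (0.0, 0.70, 0.88, 0.97)
    depletion_r_inner: float = 0.40
    # fraction of the diseased-branch hot spot surviving at each level
    # (particles exhaled from the constricted bronchioles decrease with D)
    branch_attenuation: tuple[float, ...] = (1.0, 0.75, 0.50, 0.25)
    # flow-rate response (q = (Q - 30)/10)
    rotation_per_lpm: float = 0.05        # rad of whole-pattern rotation per L/min
    arm_gain: float = 0.12                # fractional arm-length gain at q = 1
    scatter_gain: float = 0.15            # fractional scatter gain at q = 1
    background_weight_gain: float = -0.04  # background weight shift at q = 1
    # particle-size response (deliberately tiny: sizes 0.2-5 um are near-inert)
    size_drift_per_um: float = 0.0015     # downward drift per um above 1 um
    size_jitter_per_um: float = 0.0005    # isotropic jitter scale per um
    size_jitter_bound: float = 0.05       # documented L1 occupancy bound eps_size
    # upper-airway affine perturbations
    oral_expansion_scale: float = 1.05
    oral_vortex_shift: tuple[float, float] = (0.05, 0.02)
    tracheal_contraction_y: float = 0.92
    tracheal_vortex_shift: tuple[float, float] = (0.02, -0.01)
    # measurement noise on positions (the generator's noise dial)
    position_noise: float = 0.02

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConstants":
        def tup(v):
            if isinstance(v, list):
                return tuple(tup(x) for x in v)
            return v

        return cls(**{k: tup(v) for k, v in d.items()})


DEFAULT_CONSTANTS = GeneratorConstants()


# ---------------------------------------------------------------------------
# configuration / domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FingerprintConfig:
    """Generating condition of one fingerprint sample.

    Parameters
    ----------
    disease_level : int
        Bronchial constriction grade 0..3 (0 %, 25 %, 50 %, 75 % diameter
        reduction of two segmental bronchioles).
    flow_rate : float
        Inhalation flow rate in L/min, studied band 20-40.
    particle_diameter : float
        Aerosol diameter in micrometres, studied band 0.2-5.0.
    ua_variant : str
        Upper-airway geometry: ``control``, ``oral_expansion`` (5 % oral
        cavity expansion) or ``tracheal_contraction`` (8 % contraction).
    n_particles : int
        Particles released per test.
    seed : int
        Seed making the sample bit-reproducible.
    """

    disease_level: int
    flow_rate: float = 30.0
    particle_diameter: float = 1.0
    ua_variant: str = "control"
    n_particles: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.disease_level not in DISEASE_CONSTRICTION:
            raise ValueError(f"disease_level must be in 0..3, got {self.disease_level}")
        if not (20.0 <= self.flow_rate <= 40.0):
            raise ValueError(f"flow_rate {self.flow_rate} outside studied band [20, 40] L/min")
        if not (0.2 <= self.particle_diameter <= 5.0):
            raise ValueError(
                f"particle_diameter {self.particle_diameter} outside studied band [0.2, 5.0] um"
            )
        if self.ua_variant not in UA_VARIANTS:
            raise ValueError(f"ua_variant must be one of {UA_VARIANTS}, got {self.ua_variant!r}")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def constriction(self) -> float:
        return DISEASE_CONSTRICTION[self.disease_level]


@dataclass(frozen=True)
class FlowField:
    """Analytic stand-in for the expiratory flow/deposition structure.

    Two desingularised point vortices in the lower half-disc (asymmetric
    about the vertical centreline), a flow-rate-proportional background
    speed, the crescent depletion sector and the two hot spots.
    """

    vortex_centers: np.ndarray          # (2, 2)
    vortex_strengths: np.ndarray        # (2,)
    background_speed: float
    depletion_sector: tuple[float, float, float]  # (centre angle, full width, r_inner)
    hotspot_centers: np.ndarray         # (2, 2)
    hotspot_amplitudes: np.ndarray      # (2,)
    core_radius: float = 0.12

    def velocity(self, points: np.ndarray) -> np.ndarray:
        """Fluid velocity at ``points`` (n, 2): vortex swirl + downward wash."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        u = np.zeros_like(p)
        for c, s in zip(self.vortex_centers, self.vortex_strengths):
            d = p - c
            r2 = (d ** 2).sum(axis=1) + self.core_radius ** 2
            # swirl: rotate displacement by 90 degrees, decay like a Lamb vortex
            u[:, 0] += s * (-d[:, 1]) / (2 * np.pi * r2)
            u[:, 1] += s * (d[:, 0]) / (2 * np.pi * r2)
        u[:, 1] -= 0.1 * self.background_speed
        return u if np.asarray(points).ndim == 2 else u[0]


@dataclass
class AerosolFingerprint:
    """Particle landing positions on the unit filter disc plus their condition."""

    positions: np.ndarray                 # (n, 2) in [-1, 1] disc coordinates
    config: FingerprintConfig
    weights: np.ndarray | None = None     # optional per-particle mass weights

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        r2 = (self.positions ** 2).sum(axis=1)
        if r2.size and r2.max() > R_DEPOSITION ** 2 + 1e-12:
            raise ValueError("positions outside the deposition radius")

    @property
    def n(self) -> int:
        return len(self.positions)

    def cell_occupancy(self, grid: int = 6) -> np.ndarray:
        """Fraction of particles per cell of a ``grid x grid`` partition of
        the bounding square, row-major with row 0 at top."""
        if self.n == 0:
            return np.zeros(grid * grid)
        col = np.clip(((self.positions[:, 0] + 1) / 2 * grid).astype(int), 0, grid - 1)
        row = np.clip(((1 - self.positions[:, 1]) / 2 * grid).astype(int), 0, grid - 1)
        counts = np.bincount(row * grid + col, minlength=grid * grid)
        return counts / counts.sum()

    def to_dataframe(self, sample_id: str = "S1") -> pd.DataFrame:
        w = self.weights if self.weights is not None else np.ones(self.n)
        return pd.DataFrame(
            {
                "sample_id": sample_id,
                "particle_id": np.arange(self.n),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "weight": w,
            }
        )


@dataclass(frozen=True)
class PhysicsParams:
    """Physical constants of one particle class for the Lagrangian integrator.

    tau_p is the Stokes relaxation time rho_p d_p^2 C_c / (18 mu); alpha is
    the fluid-to-particle density ratio so g (1 - alpha) is
    buoyancy-corrected gravity.
    """

    tau_p: float                       # s
    drag_factor_f: float = 1.0         # Stokes regime for d_p <= 5 um
    cunningham_cc: float = 1.0
    gravity: tuple[float, float] = (0.0, 0.0)   # m/s^2 on the filter plane
    density_ratio_alpha: float = 1.2e-3
    brownian_amplitude: float = 0.0    # velocity kick scale (m/s per sqrt(s))
    lift_coefficient: float = 0.0

    def __post_init__(self):
        if not (self.tau_p > 0):
            raise ValueError("tau_p must be positive")
        if self.cunningham_cc < 1:
            raise ValueError("Cunningham correction must be >= 1")
        for v in (self.drag_factor_f, self.brownian_amplitude, self.lift_coefficient):
            if not math.isfinite(v):
                raise ValueError("physics amplitudes must be finite")

    @classmethod
    def for_particle(
        cls,
        dp_um: float,
        rho_p: float = 1000.0,
        mu: float = 1.89e-5,
        mean_free_path_um: float = 0.066,
        **kwargs,
    ) -> "PhysicsParams":
        """Derive tau_p and C_c for a unit-density sphere in body-temperature air."""
        cc = cunningham_correction(dp_um, mean_free_path_um)
        tau = particle_relaxation_time(dp_um, rho_p=rho_p, mu=mu, cc=cc)
        return cls(tau_p=tau, cunningham_cc=cc, **kwargs)


@dataclass(frozen=True)
class ExperimentDesign:
    """Full-factorial design over flow rate, disease level, size and UA variant."""

    flow_rates: tuple[float, ...]
    disease_levels: tuple[int, ...]
    particle_diameters: tuple[float, ...]
    ua_variants: tuple[str, ...] = ("control",)
    replicates_per_cell: int = 1
    n_particles: int = 10000

    def __post_init__(self):
        for name in ("flow_rates", "disease_levels", "particle_diameters", "ua_variants"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty factor list: {name}")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.flow_rates)
            * len(self.disease_levels)
            * len(self.particle_diameters)
            * len(self.ua_variants)
            * self.replicates_per_cell
        )

    def cells(self):
        """Enumerate design cells in the documented deterministic order:
        flow rate (outer) > disease level > particle diameter > UA variant >
        replicate (inner)."""
        idx = 0
        for q in self.flow_rates:
            for d in self.disease_levels:
                for dp in self.particle_diameters:
                    for ua in self.ua_variants:
                        for rep in range(self.replicates_per_cell):
                            yield idx, (q, d, dp, ua, rep)
                            idx += 1


PARTICLE_SIZES_UM = (0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0, 5.0)


def ideal_design(n_particles: int = 10000) -> ExperimentDesign:
    """The 108-sample ideal test: 3 flow rates x 4 levels x 9 sizes, no UA
    variation (respiration spread 30 +/- 10 %)."""
    return ExperimentDesign(
        flow_rates=(27.0, 30.0, 33.0),
        disease_levels=(0, 1, 2, 3),
        particle_diameters=PARTICLE_SIZES_UM,
        ua_variants=("control",),
        n_particles=n_particles,
    )


def realistic_design(n_particles: int = 10000) -> ExperimentDesign:
    """The 324-sample realistic test: 3 flow rates x 4 levels x 9 sizes x 3
    upper-airway variants (respiration spread 30 +/- 10 L/min)."""
    return ExperimentDesign(
        flow_rates=(20.0, 30.0, 40.0),
        disease_levels=(0, 1, 2, 3),
        particle_diameters=PARTICLE_SIZES_UM,
        ua_variants=UA_VARIANTS,
        n_particles=n_particles,
    )


@dataclass
class Dataset:
    """A list of fingerprints with an aligned label manifest."""

    fingerprints: list[AerosolFingerprint]
    manifest: pd.DataFrame  # columns sample_id, D, Q_lpm, dp_um, ua_variant, seed

    def __post_init__(self):
        if len(self.fingerprints) != len(self.manifest):
            raise ValueError("labels must align one-to-one with samples")
        ids = self.manifest["sample_id"]
        if ids.duplicated().any():
            raise ValueError("sample ids must be unique")

    def __len__(self) -> int:
        return len(self.fingerprints)


# ---------------------------------------------------------------------------
# physics helpers
# ---------------------------------------------------------------------------

# Davies (1945) slip-correction constants, the standard choice.
_CC_A1, _CC_A2, _CC_A3 = 1.257, 0.400, 1.100


def cunningham_correction(dp_um: float, mean_free_path_um: float = 0.066) -> float:
    """Cunningham slip correction C_c = 1 + Kn (A1 + A2 exp(-A3 / Kn)).

    Kn = 2 lambda / d_p with the air mean free path lambda.  C_c -> 1 in the
    continuum limit (large particles) and is strictly decreasing in d_p.
    """
    dp = np.asarray(dp_um, dtype=float)
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be positive")
    kn = 2.0 * mean_free_path_um / dp
    out = 1.0 + kn * (_CC_A1 + _CC_A2 * np.exp(-_CC_A3 / kn))
    return float(out) if np.isscalar(dp_um) else out


def particle_relaxation_time(
    dp_um: float, rho_p: float = 1000.0, mu: float = 1.89e-5, cc: float | None = None
) -> float:
    """Stokes relaxation time tau_p = rho_p d_p^2 C_c / (18 mu), seconds."""
    if cc is None:
        cc = cunningham_correction(dp_um)
    dp_m = dp_um * 1e-6
    return rho_p * dp_m ** 2 * cc / (18.0 * mu)


# ---------------------------------------------------------------------------
# flow field and phenomenological sampler
# ---------------------------------------------------------------------------


def build_flow_field(
    config: FingerprintConfig, constants: GeneratorConstants = DEFAULT_CONSTANTS
) -> FlowField:
    """Deterministic map from a test condition to the analytic flow field.

    The depletion sector widens strictly with disease level (width 0 at D0);
    background speed scales with flow rate; the upper-airway variant shifts
    the vortex centres by a fixed affine perturbation, larger for oral
    expansion than for tracheal contraction.
    """
    c = constants
    centers = np.array(c.vortex_centers, dtype=float)
    if config.ua_variant == "oral_expansion":
        centers = centers + np.array(c.oral_vortex_shift)
    elif config.ua_variant == "tracheal_contraction":
        centers = centers + np.array(c.tracheal_vortex_shift)
    q = (config.flow_rate - 30.0) / 10.0
    speed = config.flow_rate / 30.0
    strengths = np.array([1.0, -0.8]) * speed
    width = c.depletion_width_rad[config.disease_level]
    sector = (np.pi / 2.0, width, c.depletion_r_inner)
    return FlowField(
        vortex_centers=centers,
        vortex_strengths=strengths,
        background_speed=speed,
        depletion_sector=sector,
        hotspot_centers=np.array(c.hotspot_centers, dtype=float),
        hotspot_amplitudes=np.array([1.0, 0.8]) * (1.0 + 0.1 * q),
    )


def depletion_mask(
    positions: np.ndarray, sector: tuple[float, float, float]
) -> np.ndarray:
    """Boolean mask of positions inside a crescent sector (angle, width, r_in)."""
    pos = np.atleast_2d(positions)
    angle, width, r_in = sector
    if width <= 0:
        return np.zeros(len(pos), dtype=bool)
    r = np.hypot(pos[:, 0], pos[:, 1])
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    dtheta = np.angle(np.exp(1j * (theta - angle)))
    return (r >= r_in) & (np.abs(dtheta) <= width / 2.0)


def _sample_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def generate_fingerprint(
    config: FingerprintConfig, constants: GeneratorConstants = DEFAULT_CONSTANTS
) -> AerosolFingerprint:
    """Sample one synthetic fingerprint for the given test condition.

    Positions are drawn from a mixture of two vortex-spiral densities, two
    hot spots and a uniform background; particles falling in the disease
    level's crescent sector are removed with the level's depletion
    probability; flow rate rotates and stretches the pattern; particle size
    adds only a sub-cell drift and jitter; the upper-airway variant applies
    its affine distortion.  Bit-reproducible from ``(config, seed)``.

    The random stream is consumed identically for every particle diameter
    and disease level, so two configs differing only in those factors share
    common random numbers under the same seed.
    """
    c = constants
    rng = np.random.default_rng(config.seed)
    q = (config.flow_rate - 30.0) / 10.0

    w = np.array(c.mixture_weights, dtype=float)
    w[0] = max(w[0] + c.background_weight_gain * q, 0.02)
    w = w / w.sum()
    counts = rng.multinomial(config.n_particles, w)

    parts = [_sample_disc(rng, counts[0], R_DEPOSITION)]

    arm_scale = 1.0 + c.arm_gain * q
    scatter = c.vortex_scatter * (1.0 + c.scatter_gain * q)
    for k in range(2):
        nk = counts[1 + k]
        center = np.array(c.vortex_centers[k])
        t = rng.random(nk)
        radius = c.vortex_arm_radius[k] * arm_scale * t ** 0.7
        theta = 2 * np.pi * c.vortex_arm_turns[k] * t
        pts = center + np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta)]
        )
        pts += scatter * rng.standard_normal((nk, 2))
        parts.append(pts)

    for k in range(2):
        nk = counts[3 + k]
        center = np.array(c.hotspot_centers[k])
        pts = center + c.hotspot_sigma[k] * rng.standard_normal((nk, 2))
        parts.append(pts)

    pos = np.concatenate(parts, axis=0)

    # particle-size response: deliberately tiny (0.2-5 um aerosols are
    # near-inert on the filter scale)
    dp = config.particle_diameter
    pos[:, 1] -= c.size_drift_per_um * (dp - 1.0)
    pos += c.size_jitter_per_um * dp * rng.standard_normal(pos.shape)

    # crescent depletion: the spatial disease signature.  All random draws
    # are taken unconditionally (full length) to keep the stream aligned
    # across disease levels and particle sizes under a common seed.
    sector = (np.pi / 2.0, c.depletion_width_rad[config.disease_level], c.depletion_r_inner)
    u = rng.random(len(pos))
    inside = depletion_mask(pos, sector)
    keep = ~(inside & (u < c.depletion_probability[config.disease_level]))
    # gradual starvation of the diseased-branch hot spot
    u2 = rng.random(len(pos))
    is_branch = np.zeros(len(pos), dtype=bool)
    is_branch[counts[:4].sum():] = True  # hot spot 2 component
    keep &= ~(is_branch & (u2 >= c.branch_attenuation[config.disease_level]))

    # deposition/measurement scatter on the filter (the generator's noise
    # dial); drawn pre-depletion for stream alignment but applied after the
    # removal step, so increasing noise genuinely blurs the crescent edge
    scatter_noise = c.position_noise * rng.standard_normal(pos.shape)
    pos = (pos + scatter_noise)[keep]

    # flow-rate rotation of the whole pattern
    phi = c.rotation_per_lpm * (config.flow_rate - 30.0)
    if phi != 0.0:
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        pos = pos @ rot.T

    # upper-airway affine distortion
    if config.ua_variant == "oral_expansion":
        pos = pos * c.oral_expansion_scale
    elif config.ua_variant == "tracheal_contraction":
        pos = pos.copy()
        pos[:, 1] *= c.tracheal_contraction_y

    # clip to the deposition radius (radial projection of escapees)
    r = np.hypot(pos[:, 0], pos[:, 1])
    over = r > R_DEPOSITION
    if over.any():
        pos[over] *= (R_DEPOSITION / r[over])[:, None]

    return AerosolFingerprint(positions=pos, config=config)


# ---------------------------------------------------------------------------
# Lagrangian integrator
# ---------------------------------------------------------------------------


def integrate_states(
    flow,
    physics: PhysicsParams,
    x0: np.ndarray,
    v0: np.ndarray,
    dt: float,
    t_end: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance particle states through the particle equation of motion.

    The linear drag relaxation dv/dt = beta (u - v) + a with
    beta = f / (tau_p C_c) and a = g (1 - alpha) is advanced with its exact
    exponential (integrating-factor) update per step, the fluid velocity
    being frozen over each step; this is exact for locally constant u and
    unconditionally stable as tau_p -> 0.  The Brownian velocity kick
    enters Euler-Maruyama style with a sqrt(dt) scale.  Particles crossing
    the deposition radius record their radial crossing point and freeze.

    Returns the final ``(positions, velocities)`` arrays.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < dt:
        raise ValueError("t_end must be >= dt")
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float).reshape(-1, 2)
    v = np.array(v0, dtype=float).reshape(-1, 2)

    beta = physics.drag_factor_f / (physics.tau_p * physics.cunningham_cc)
    accel = np.asarray(physics.gravity, dtype=float) * (1.0 - physics.density_ratio_alpha)
    e = math.exp(-beta * dt)
    # (1 - e)/beta, series-safe for tiny beta*dt
    if beta * dt > 1e-8:
        g1 = (1.0 - e) / beta
    else:
        g1 = dt * (1.0 - 0.5 * beta * dt)

    n_steps = int(round(t_end / dt))
    alive = np.ones(len(x), dtype=bool)
    for step in range(n_steps):
        if not alive.any():
            break
        u = flow.velocity(x[alive])
        vs = u + accel / beta  # drift fixed point
        dv = v[alive] - vs
        x[alive] = x[alive] + vs * dt + dv * g1
        v[alive] = vs + dv * e
        if physics.brownian_amplitude > 0:
            v[alive] += physics.brownian_amplitude * math.sqrt(dt) * rng.standard_normal(
                (int(alive.sum()), 2)
            )
        if not (np.isfinite(x).all() and np.isfinite(v).all()):
            raise IntegrationError(step)
        r = np.hypot(x[:, 0], x[:, 1])
        crossed = alive & (r >= R_DEPOSITION)
        if crossed.any():
            x[crossed] *= (R_DEPOSITION / r[crossed])[:, None]
            alive &= ~crossed
    return x, v


def simulate_particles(
    flow: FlowField,
    physics: PhysicsParams,
    n: int,
    dt: float,
    t_end: float,
    seed: int = 0,
    initial_positions: np.ndarray | None = None,
    initial_velocities: np.ndarray | None = None,
    config: FingerprintConfig | None = None,
) -> AerosolFingerprint:
    """Lagrangian fingerprint generation: release ``n`` particles in the
    flow field and collect their deposition pattern (see
    :func:`integrate_states` for the scheme)."""
    rng = np.random.default_rng(seed)
    if initial_positions is None:
        x0 = _sample_disc(rng, n, 0.5 * R_DEPOSITION)
    else:
        x0 = np.array(initial_positions, dtype=float).reshape(n, 2)
    if initial_velocities is None:
        v0 = flow.velocity(x0)
    else:
        v0 = np.array(initial_velocities, dtype=float).reshape(n, 2)
    x, _v = integrate_states(flow, physics, x0, v0, dt, t_end, seed=seed)
    if config is None:
        config = FingerprintConfig(disease_level=0, n_particles=n, seed=seed)
    return AerosolFingerprint(positions=x, config=config)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------


def derive_cell_seed(seed: int, cell_index: int) -> int:
    """Per-cell seed from (dataset seed, cell index); any cell regenerable
    in isolation.  Kept below 2**31."""
    ss = np.random.SeedSequence([int(seed), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(
    design: ExperimentDesign,
    seed: int = 0,
    constants: GeneratorConstants = DEFAULT_CONSTANTS,
) -> Dataset:
    """Generate the full factorial dataset for a design.

    Cells are enumerated flow rate > disease level > particle diameter > UA
    variant > replicate; sample ids are S1..Sn in that order.
    """
    fps: list[AerosolFingerprint] = []
    rows = []
    for idx, (qf, d, dp, ua, rep) in design.cells():
        cell_seed = derive_cell_seed(seed, idx)
        cfg = FingerprintConfig(
            disease_level=d,
            flow_rate=qf,
            particle_diameter=dp,
            ua_variant=ua,
            n_particles=design.n_particles,
            seed=cell_seed,
        )
        fps.append(generate_fingerprint(cfg, constants))
        rows.append(
            {
                "sample_id": f"S{idx + 1}",
                "D": d,
                "Q_lpm": qf,
                "dp_um": dp,
                "ua_variant": ua,
                "seed": cell_seed,
            }
        )
    return Dataset(fingerprints=fps, manifest=pd.DataFrame(rows))
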
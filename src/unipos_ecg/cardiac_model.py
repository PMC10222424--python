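"""2-D monodomain FitzHugh-Nagumo simulation of a heart-torso phantom.

The phantom is a labelled rectangular grid: a torso filling the frame (with an
optional capacitive electrode layer wrapped around it), two passive lungs, and
a heart composed of the sinoatrial node, atria, atrioventricular node, His
bundle, bundle branches, Purkinje fibers, ventricles and blood chambers.  A
non-conducting band of fibrous tissue separates atria from ventricles; the AV
node is the only conducting bridge across it.

Cardiac regions carry two-variable excitable dynamics (action potential ``u1``,
gate variable ``u2``); the torso, lungs, blood chambers and electrode layer are
passive volume conductor: their reaction source is zero and surface potentials
arise purely from diffusion of ``u1`` out of the heart.  Surface traces are
read either as a two-point difference (conventional lead) or as a single point
on the electrode/torso contact (single-position detection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np

from .signals import ECGSignal

__all__ = [
    "RegionLabel",
    "ACTIVE_REGIONS",
    "PASSIVE_REGIONS",
    "DynamicParams",
    "PhantomConfig",
    "TissuePhantom",
    "FieldState",
    "StimulusProtocol",
    "ProbeSpec",
    "FieldRecording",
    "PhantomValidationError",
    "build_phantom",
    "reaction_term",
    "stability_limit",
    "step_field",
    "run_simulation",
    "default_probes",
    "extract_conventional_lead",
    "extract_single_position",
]


class RegionLabel(str, Enum):
    SINOATRIAL_NODE = "sinoatrial_node"
    ATRIA = "atria"
    ATRIOVENTRICULAR_NODE = "atrioventricular_node"
    HIS_BUNDLE = "his_bundle"
    BUNDLE_BRANCHES = "bundle_branches"
    PURKINJE_FIBERS = "purkinje_fibers"
    VENTRICLES = "ventricles"
    BLOOD_CHAMBER = "blood_chamber"
    LUNG = "lung"
    TORSO = "torso"
    ELECTRODE_LAYER = "electrode_layer"
    FIBROUS_BARRIER = "fibrous_barrier"


#: Conduction-system order in which excitation must spread.
CONDUCTION_ORDER = (
    RegionLabel.SINOATRIAL_NODE,
    RegionLabel.ATRIA,
    RegionLabel.ATRIOVENTRICULAR_NODE,
    RegionLabel.HIS_BUNDLE,
    RegionLabel.BUNDLE_BRANCHES,
    RegionLabel.PURKINJE_FIBERS,
    RegionLabel.VENTRICLES,
)

ACTIVE_REGIONS = frozenset(CONDUCTION_ORDER)
PASSIVE_REGIONS = frozenset({
    RegionLabel.BLOOD_CHAMBER,
    RegionLabel.LUNG,
    RegionLabel.TORSO,
    RegionLabel.ELECTRODE_LAYER,
})

# fixed integer codes for the label grid
_CODE = {r: i for i, r in enumerate(RegionLabel)}
_REGION_OF_CODE = {i: r for r, i in _CODE.items()}


def _default_epsilon() -> dict[RegionLabel, float]:
    # excitability per region; passive regions have epsilon = 0
    eps = {r: 0.0 for r in RegionLabel}
    eps.update({
        RegionLabel.SINOATRIAL_NODE: 0.003,
        RegionLabel.ATRIA: 0.015,
        RegionLabel.ATRIOVENTRICULAR_NODE: 0.015,
        RegionLabel.HIS_BUNDLE: 0.01,
        RegionLabel.BUNDLE_BRANCHES: 0.01,
        RegionLabel.PURKINJE_FIBERS: 0.005,
        RegionLabel.VENTRICLES: 0.005,
    })
    return eps


def _default_diffusion() -> dict[RegionLabel, float]:
    return {
        RegionLabel.TORSO: 0.2,
        RegionLabel.LUNG: 0.2,
        RegionLabel.SINOATRIAL_NODE: 0.1,
        RegionLabel.ATRIA: 0.15,
        RegionLabel.ATRIOVENTRICULAR_NODE: 0.1,
        RegionLabel.HIS_BUNDLE: 0.1,
        RegionLabel.BUNDLE_BRANCHES: 0.1,
        RegionLabel.PURKINJE_FIBERS: 0.3,
        RegionLabel.VENTRICLES: 0.1,
        RegionLabel.BLOOD_CHAMBER: 0.7,
        # not tabulated for the source model; same as the body by default
        RegionLabel.ELECTRODE_LAYER: 0.2,
        RegionLabel.FIBROUS_BARRIER: 0.0,
    }


@dataclass(frozen=True)
class DynamicParams:
    """FitzHugh-Nagumo parameters (all dimensionless).

    ``du1/dt = div(D grad u1) + g*u1*(u1-theta)*(alpha-u1) - u2`` on active
    regions, ``du2/dt = eps*(beta*u1 - gamma*u2 - delta)``.  The cubic has
    roots {0, theta, alpha}; u1 in (theta, alpha) is regenerative.  ``theta``
    may be overridden per region (the sinoatrial node uses a higher threshold
    by default, which shortens its plateau relative to its very small
    excitability and prevents the node from re-exciting recovered atria).
    """

    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 1.0
    delta: float = 0.0
    theta: float = 0.15
    cubic_gain: float = 2.1
    epsilon_by_region: Mapping[RegionLabel, float] = field(default_factory=_default_epsilon)
    diffusion_by_region: Mapping[RegionLabel, float] = field(default_factory=_default_diffusion)
    theta_by_region: Mapping[RegionLabel, float] = field(
        default_factory=lambda: dict(
            {r: 0.05 for r in ACTIVE_REGIONS},
            **{RegionLabel.SINOATRIAL_NODE: 0.45}))

    def __post_init__(self) -> None:
        for r, d in self.diffusion_by_region.items():
            if d < 0:
                raise ValueError(f"diffusion coefficient for {r} must be >= 0")
        if self.diffusion_by_region.get(RegionLabel.FIBROUS_BARRIER, 0.0) != 0.0:
            raise ValueError("fibrous_barrier must have D = 0")
        for r in PASSIVE_REGIONS:
            if self.epsilon_by_region.get(r, 0.0) != 0.0:
                raise ValueError(f"passive region {r} must have epsilon = 0")

    def epsilon(self, region: RegionLabel) -> float:
        return float(self.epsilon_by_region.get(region, 0.0))

    def diffusion(self, region: RegionLabel) -> float:
        return float(self.diffusion_by_region.get(region, 0.0))

    def theta_of(self, region: RegionLabel) -> float:
        return float(self.theta_by_region.get(region, self.theta))


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry description for :func:`build_phantom`.

    All positions/sizes are fractions of the grid shape so the same layout
    scales with resolution.  The defaults are a coronal-slice cartoon: a torso
    filling the grid, lungs left and right, and a large central heart whose
    atria (top) and ventricles (bottom) are separated by a fibrous band
    bridged only by the AV node, with the His bundle, bundle branches and a
    Purkinje sheet chaining downwards from it.
    """

    grid_shape: tuple[int, int] = (150, 150)
    spacing: float = 0.75
    include_electrode_layer: bool = True
    electrode_layer_width: int = 2
    params: DynamicParams = field(default_factory=DynamicParams)

    heart_center: tuple[float, float] = (0.50, 0.50)
    heart_semiaxes: tuple[float, float] = (0.445, 0.34)
    barrier_row: float = 0.43          # centre of the fibrous band
    barrier_half_width: int = 1        # band thickness = 2*hw (cells)
    sa_center: tuple[float, float] = (0.17, 0.45)
    sa_radius: float = 0.02
    av_rows: tuple[float, float] = (0.405, 0.475)
    av_cols: tuple[float, float] = (0.48, 0.52)
    # the His bundle runs as a thin serpentine inside an insulating fibrous
    # block; the path length sets the atria->ventricle conduction delay
    # (the PR-interval analogue)
    insulation_rows: tuple[float, float] = (0.44, 0.56)
    insulation_cols: tuple[float, float] = (0.30, 0.70)
    his_waypoints: tuple[tuple[float, float], ...] = (
        (0.47, 0.50), (0.50, 0.50), (0.50, 0.40), (0.53, 0.40),
        (0.53, 0.57), (0.56, 0.57))
    his_half_width: int = 1
    branch_rows: tuple[float, float] = (0.56, 0.585)
    branch_cols: tuple[float, float] = (0.42, 0.66)
    purkinje_rows: tuple[float, float] = (0.585, 0.61)
    purkinje_cols: tuple[float, float] = (0.28, 0.72)
    atrial_chamber_centers: tuple[tuple[float, float], ...] = ((0.30, 0.36), (0.30, 0.64))
    atrial_chamber_semiaxes: tuple[float, float] = (0.095, 0.075)
    ventricular_chamber_centers: tuple[tuple[float, float], ...] = ((0.70, 0.42), (0.70, 0.58))
    ventricular_chamber_semiaxes: tuple[float, float] = (0.065, 0.055)
    lung_centers: tuple[tuple[float, float], ...] = ((0.30, 0.082), (0.30, 0.918))
    lung_semiaxes: tuple[float, float] = (0.11, 0.045)


class PhantomValidationError(ValueError):
    """Raised when a phantom description violates the required anatomy."""


@dataclass(frozen=True)
class TissuePhantom:
    """Labelled grid plus dynamics; the simulation domain."""

    labels: np.ndarray          # int8 region codes, shape (rows, cols)
    spacing: float
    params: DynamicParams

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        object.__setattr__(self, "labels", labels.astype(np.int8, copy=False))

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, region: RegionLabel) -> np.ndarray:
        return self.labels == _CODE[region]

    def region_at(self, point: tuple[int, int]) -> RegionLabel:
        return _REGION_OF_CODE[int(self.labels[point])]

    def regions_present(self) -> set[RegionLabel]:
        return {_REGION_OF_CODE[c] for c in np.unique(self.labels)}

    # --- cached per-cell parameter grids -------------------------------
    def _grids(self) -> dict[str, np.ndarray]:
        cache = getattr(self, "_grid_cache", None)
        if cache is not None:
            return cache
        p = self.params
        D = np.zeros(self.labels.shape)
        eps = np.zeros(self.labels.shape)
        theta = np.full(self.labels.shape, p.theta)
        active = np.zeros(self.labels.shape, dtype=bool)
        for region in RegionLabel:
            m = self.labels == _CODE[region]
            if not m.any():
                continue
            D[m] = p.diffusion(region)
            eps[m] = p.epsilon(region)
            theta[m] = p.theta_of(region)
            if region in ACTIVE_REGIONS:
                active[m] = True
        # harmonic-mean diffusion on cell faces; a zero-D side blocks flux
        def harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            s = a + b
            out = np.zeros_like(a)
            nz = (a > 0) & (b > 0)
            out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
            return out

        cache = {
            "D": D, "eps": eps, "theta": theta, "active": active,
            "Dv": harm(D[:-1, :], D[1:, :]),   # faces between row i and i+1
            "Dh": harm(D[:, :-1], D[:, 1:]),   # faces between col j and j+1
            "Dmax": float(D.max()),
        }
        object.__setattr__(self, "_grid_cache", cache)
        return cache

    @property
    def max_diffusion(self) -> float:
        return self._grids()["Dmax"]


@dataclass
class FieldState:
    """Simulation state: action potential u1 and gate variable u2 per cell."""

    u1: np.ndarray
    u2: np.ndarray
    t: float = 0.0

    @classmethod
    def resting(cls, phantom: TissuePhantom) -> "FieldState":
        shape = phantom.grid_shape
        return cls(u1=np.zeros(shape), u2=np.zeros(shape), t=0.0)


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic suprathreshold drive applied to one region (the SA node).

    Times are in dimensionless simulation units; one ``period`` is mapped to
    one cardiac cycle when traces are exported.
    """

    target: RegionLabel = RegionLabel.SINOATRIAL_NODE
    period: float = 1200.0
    amplitude: float = 0.5
    pulse_width: float = 12.0
    start: float = 20.0

    def __post_init__(self) -> None:
        if not self.period > 0:
            raise ValueError("period must be > 0")
        if not self.amplitude >= 0:
            raise ValueError("amplitude must be >= 0")
        if not self.pulse_width < self.period:
            raise ValueError("pulse_width must be < period")

    def active_at(self, t: float) -> bool:
        if t < self.start:
            return False
        return ((t - self.start) % self.period) < self.pulse_width


@dataclass(frozen=True)
class ProbeSpec:
    """A surface probe: a two-point conventional pair or a single position."""

    name: str
    kind: str  # "conventional_pair" | "single_position"
    point_a: tuple[int, int]
    point_b: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("conventional_pair", "single_position"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        if self.kind == "conventional_pair" and self.point_b is None:
            raise ValueError("conventional_pair requires point_b")


@dataclass
class FieldRecording:
    """Decimated surface traces and per-region activation bookkeeping.

    ``times`` are mapped seconds (one stimulus period = ``cycle_seconds``);
    ``times_sim`` the same instants in dimensionless units.
    """

    times: np.ndarray
    times_sim: np.ndarray
    probe_traces: dict[str, np.ndarray]
    region_mean_u1: dict[RegionLabel, np.ndarray]
    activation_times: dict[RegionLabel, float]
    cycle_seconds: float
    dt: float
    warnings: list[str] = field(default_factory=list)

    @property
    def T(self) -> float:
        """Mapped sampling interval of the recorded traces, in seconds."""
        return float(self.times[1] - self.times[0])

    def threshold_crossings(self, trace: np.ndarray, level: float = 0.5) -> np.ndarray:
        """Indices where ``trace`` crosses ``level`` upward."""
        above = trace >= level
        return np.nonzero(above[1:] & ~above[:-1])[0] + 1


# ----------------------------------------------------------------------
# phantom construction


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  semi: tuple[float, float]) -> np.ndarray:
    R, C = shape
    r = np.arange(R)[:, None]
    c = np.arange(C)[None, :]
    cr, cc = center[0] * R, center[1] * C
    ar, ac = max(semi[0] * R, 1.0), max(semi[1] * C, 1.0)
    return ((r - cr) / ar) ** 2 + ((c - cc) / ac) ** 2 <= 1.0


def _box_mask(shape: tuple[int, int], rows: tuple[float, float],
              cols: tuple[float, float]) -> np.ndarray:
    R, C = shape
    m = np.zeros(shape, dtype=bool)
    r0, r1 = int(round(rows[0] * R)), int(round(rows[1] * R))
    c0, c1 = int(round(cols[0] * C)), int(round(cols[1] * C))
    m[r0:r1, c0:c1] = True
    return m


def _his_channel_mask(shape: tuple[int, int],
                      waypoints: tuple[tuple[float, float], ...],
                      half_width: int) -> np.ndarray:
    """Rasterize an axis-aligned polyline as a thin channel."""
    R, C = shape
    m = np.zeros(shape, dtype=bool)
    pts = [(int(round(r * R)), int(round(c * C))) for r, c in waypoints]
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rlo, rhi = sorted((r0, r1))
        clo, chi = sorted((c0, c1))
        m[max(rlo - half_width, 0):rhi + half_width + 1,
          max(clo - half_width, 0):chi + half_width + 1] = True
    return m


def _adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """True if any cell of a is 4-adjacent to a cell of b."""
    a = mask_a
    b = mask_b
    return bool((a[:-1, :] & b[1:, :]).any() or (a[1:, :] & b[:-1, :]).any()
                or (a[:, :-1] & b[:, 1:]).any() or (a[:, 1:] & b[:, :-1]).any())


def build_phantom(config: PhantomConfig | None = None) -> TissuePhantom:
    """Paint the labelled grid from a :class:`PhantomConfig` and validate it.

    Raises :class:`PhantomValidationError` for degenerate geometry: a missing
    or empty mandatory region, a broken conduction chain, direct
    atria-ventricle contact, or an AV node that fails to bridge the barrier.
    """
    cfg = config or PhantomConfig()
    R, C = cfg.grid_shape
    if R < 100 or C < 100:
        raise PhantomValidationError(f"grid must be at least 100x100, got {R}x{C}")
    shape = (R, C)
    labels = np.full(shape, _CODE[RegionLabel.TORSO], dtype=np.int8)

    def paint(mask: np.ndarray, region: RegionLabel) -> None:
        labels[mask] = _CODE[region]

    if cfg.include_electrode_layer:
        w = cfg.electrode_layer_width
        frame = np.zeros(shape, dtype=bool)
        frame[:w, :] = frame[-w:, :] = True
        frame[:, :w] = frame[:, -w:] = True
        paint(frame, RegionLabel.ELECTRODE_LAYER)

    torso_mask = labels == _CODE[RegionLabel.TORSO]
    for lc in cfg.lung_centers:
        paint(_ellipse_mask(shape, lc, cfg.lung_semiaxes) & torso_mask, RegionLabel.LUNG)

    heart = _ellipse_mask(shape, cfg.heart_center, cfg.heart_semiaxes)
    if cfg.include_electrode_layer and _adjacent(
            heart, labels == _CODE[RegionLabel.ELECTRODE_LAYER]):
        raise PhantomValidationError("heart touches the electrode layer; shrink the heart")

    br = int(round(cfg.barrier_row * R))
    hw = cfg.barrier_half_width
    rows = np.arange(R)[:, None]
    barrier_band = heart & (np.abs(rows - br) < hw + 0.5) & np.ones(shape, dtype=bool)
    paint(heart & (rows < br - hw + 0.5), RegionLabel.ATRIA)
    paint(heart & (rows > br + hw - 0.5), RegionLabel.VENTRICLES)
    paint(barrier_band, RegionLabel.FIBROUS_BARRIER)

    atria_mask = labels == _CODE[RegionLabel.ATRIA]
    vent_mask = labels == _CODE[RegionLabel.VENTRICLES]
    for cc in cfg.atrial_chamber_centers:
        paint(_ellipse_mask(shape, cc, cfg.atrial_chamber_semiaxes) & atria_mask,
              RegionLabel.BLOOD_CHAMBER)
    for cc in cfg.ventricular_chamber_centers:
        paint(_ellipse_mask(shape, cc, cfg.ventricular_chamber_semiaxes) & vent_mask,
              RegionLabel.BLOOD_CHAMBER)

    # insulating block around the conduction bundle, then the AV node box
    # (bridging the barrier into the block) and the serpentine His channel
    paint(_box_mask(shape, cfg.insulation_rows, cfg.insulation_cols) & heart,
          RegionLabel.FIBROUS_BARRIER)
    paint(_box_mask(shape, cfg.av_rows, cfg.av_cols) & heart, RegionLabel.ATRIOVENTRICULAR_NODE)
    paint(_his_channel_mask(shape, cfg.his_waypoints, cfg.his_half_width) & heart,
          RegionLabel.HIS_BUNDLE)
    paint(_box_mask(shape, cfg.branch_rows, cfg.branch_cols) & heart, RegionLabel.BUNDLE_BRANCHES)
    paint(_box_mask(shape, cfg.purkinje_rows, cfg.purkinje_cols) & heart, RegionLabel.PURKINJE_FIBERS)
    sa = _ellipse_mask(shape, cfg.sa_center, (cfg.sa_radius, cfg.sa_radius))
    paint(sa & (labels == _CODE[RegionLabel.ATRIA]), RegionLabel.SINOATRIAL_NODE)

    phantom = TissuePhantom(labels=labels, spacing=cfg.spacing, params=cfg.params)
    _validate_phantom(phantom, require_electrode=cfg.include_electrode_layer)
    return phantom


def _validate_phantom(phantom: TissuePhantom, require_electrode: bool) -> None:
    labels = phantom.labels
    mandatory = set(RegionLabel) - {RegionLabel.ELECTRODE_LAYER}
    if require_electrode:
        mandatory = set(RegionLabel)
    present = phantom.regions_present()
    missing = sorted(r.value for r in mandatory - present)
    if missing:
        raise PhantomValidationError(f"missing or empty regions: {', '.join(missing)}")
    if not require_electrode and RegionLabel.ELECTRODE_LAYER in present:
        raise PhantomValidationError("electrode layer present but not requested")

    masks = {r: labels == _CODE[r] for r in RegionLabel}
    for a, b in zip(CONDUCTION_ORDER[:-1], CONDUCTION_ORDER[1:]):
        if not _adjacent(masks[a], masks[b]):
            raise PhantomValidationError(
                f"conduction path broken: {a.value} not adjacent to {b.value}")
    if _adjacent(masks[RegionLabel.ATRIA], masks[RegionLabel.VENTRICLES]):
        raise PhantomValidationError(
            "atria directly touch ventricles; the fibrous barrier must separate "
            "them everywhere except through the AV node")
    av = masks[RegionLabel.ATRIOVENTRICULAR_NODE]
    if not (_adjacent(av, masks[RegionLabel.ATRIA])
            and _adjacent(av, masks[RegionLabel.HIS_BUNDLE] | masks[RegionLabel.VENTRICLES])):
        raise PhantomValidationError("AV node does not bridge the atria-ventricle barrier")


# ----------------------------------------------------------------------
# dynamics


def reaction_term(u1, u2, region: RegionLabel, params: DynamicParams):
    """Point reaction source ``(du1, du2)`` for one region.

    Active regions: ``(g*u1*(u1-theta)*(alpha-u1) - u2,
    eps*(beta*u1 - gamma*u2 - delta))``; passive regions and the fibrous
    barrier source nothing.
    """
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    if region not in ACTIVE_REGIONS:
        z = np.zeros(np.broadcast(u1, u2).shape)
        return (z + 0.0, z + 0.0) if z.shape else (0.0, 0.0)
    p = params
    theta = p.theta_of(region)
    eps = p.epsilon(region)
    du1 = p.cubic_gain * u1 * (u1 - theta) * (p.alpha - u1) - u2
    du2 = eps * (p.beta * u1 - p.gamma * u2 - p.delta)
    if du1.shape == ():
        return float(du1), float(du2)
    return du1, du2


def stability_limit(phantom: TissuePhantom) -> float:
    """Largest stable explicit time step, ``h^2 / (4 * Dmax)``."""
    if phantom.max_diffusion == 0.0:
        return np.inf
    return phantom.spacing ** 2 / (4.0 * phantom.max_diffusion)


def step_field(state: FieldState, phantom: TissuePhantom, dt: float,
               stimulus: np.ndarray | None = None) -> FieldState:
    """One explicit-Euler step: 5-point flux-form Laplacian plus reaction.

    Zero-flux at the outer boundary and across any face with D = 0 on either
    side (the fibrous barrier).  ``stimulus``, if given, is an additive du1/dt
    source grid.  Raises if ``dt`` exceeds the 2-D stability bound.
    """
    bound = stability_limit(phantom)
    if dt > bound * (1.0 + 1e-12):
        raise ValueError(
            f"dt={dt:g} violates the explicit stability bound "
            f"h^2/(4*Dmax) = {bound:g}")
    g = phantom._grids()
    u1, u2 = state.u1, state.u2
    h2 = phantom.spacing ** 2

    lap = np.zeros_like(u1)
    fv = g["Dv"] * (u1[1:, :] - u1[:-1, :])
    lap[:-1, :] += fv
    lap[1:, :] -= fv
    fh = g["Dh"] * (u1[:, 1:] - u1[:, :-1])
    lap[:, :-1] += fh
    lap[:, 1:] -= fh
    lap /= h2

    p = phantom.params
    cubic = p.cubic_gain * u1 * (u1 - g["theta"]) * (p.alpha - u1)
    src1 = np.where(g["active"], cubic - u2, 0.0)
    if stimulus is not None:
        src1 = src1 + stimulus
    du2 = g["eps"] * (p.beta * u1 - p.gamma * u2 - p.delta)

    return FieldState(u1=u1 + dt * (lap + src1), u2=u2 + dt * du2, t=state.t + dt)


# ----------------------------------------------------------------------
# probes and simulation driver


def _on_torso_surface(phantom: TissuePhantom, point: tuple[int, int]) -> bool:
    """Torso cell on the outer boundary (grid edge or electrode contact)."""
    if phantom.region_at(point) is not RegionLabel.TORSO:
        return False
    r, c = point
    R, C = phantom.grid_shape
    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
        if not (0 <= rr < R and 0 <= cc < C):
            return True
        if phantom.region_at((rr, cc)) is RegionLabel.ELECTRODE_LAYER:
            return True
    return False


def _validate_probe(phantom: TissuePhantom, probe: ProbeSpec) -> None:
    if probe.kind == "conventional_pair":
        for pt in (probe.point_a, probe.point_b):
            if not _on_torso_surface(phantom, pt):  # type: ignore[arg-type]
                raise ValueError(
                    f"probe {probe.name!r}: point {pt} is not on the torso boundary")
    else:
        if RegionLabel.ELECTRODE_LAYER not in phantom.regions_present():
            raise ValueError(
                f"probe {probe.name!r}: single-position detection requires a "
                "phantom with an electrode layer")
        if phantom.region_at(probe.point_a) is not RegionLabel.ELECTRODE_LAYER:
            raise ValueError(
                f"probe {probe.name!r}: point {probe.point_a} is not on the electrode layer")
        r, c = probe.point_a
        R, C = phantom.grid_shape
        touching = any(
            0 <= rr < R and 0 <= cc < C
            and phantom.region_at((rr, cc)) is RegionLabel.TORSO
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)))
        if not touching:
            raise ValueError(
                f"probe {probe.name!r}: electrode point must contact the torso")


def default_probes(phantom: TissuePhantom) -> list[ProbeSpec]:
    """Default surface probes: a conventional two-point lead with the
    detection point on the upper torso boundary directly above the heart and
    the reference point on the lower boundary below it, plus (if the
    electrode layer exists) a single-position probe on the upper-left part of
    the electrode/torso contact, where the trace is diffusion-smoothed into
    the wave-like shape characteristic of single-point detection."""
    R, C = phantom.grid_shape
    has_layer = RegionLabel.ELECTRODE_LAYER in phantom.regions_present()
    fw = 0
    while phantom.region_at((fw, fw)) is RegionLabel.ELECTRODE_LAYER:
        fw += 1
    mid = C // 2
    probes = [ProbeSpec(name="conventional", kind="conventional_pair",
                        point_a=(fw, mid), point_b=(R - 1 - fw, mid))]
    if has_layer:
        probes.append(ProbeSpec(name="single", kind="single_position",
                                point_a=(fw - 1, max(fw, C // 8))))
    return probes


def run_simulation(phantom: TissuePhantom, protocol: StimulusProtocol,
                   probes: list[ProbeSpec], duration: float,
                   dt: float | None = None, record_every: int | None = None,
                   cycle_seconds: float = 0.8) -> FieldRecording:
    """Integrate the monodomain model and record surface traces.

    ``duration`` is in simulation units and must cover at least two stimulus
    periods.  ``cycle_seconds`` maps one stimulus period onto one cardiac
    cycle of real time; the default 0.8 s corresponds to 75 bpm.  Failure of
    the excitation to reach the ventricles sets a ``"propagation_failure"``
    warning flag on the recording rather than raising.
    """
    if duration < 2 * protocol.period:
        raise ValueError("duration must cover at least two stimulus periods")
    bound = stability_limit(phantom)
    if dt is None:
        # choose dt so the recorded trace lands exactly on a 500 Hz-equivalent
        # grid: an integer number of steps per 2 ms of mapped time
        target = 0.002 * protocol.period / cycle_seconds
        n_sub = max(1, int(np.ceil(target / (0.9 * bound))))
        dt = target / n_sub
        if record_every is None:
            record_every = n_sub
    if record_every is None:
        target = 0.002 * protocol.period / cycle_seconds
        record_every = max(1, int(round(target / dt)))

    for probe in probes:
        _validate_probe(phantom, probe)
    points: dict[str, tuple[int, int]] = {}
    for probe in probes:
        if probe.kind == "conventional_pair":
            points[f"{probe.name}:a"] = probe.point_a
            points[f"{probe.name}:b"] = probe.point_b  # type: ignore[assignment]
        else:
            points[probe.name] = probe.point_a

    region_masks = {r: phantom.mask(r) for r in CONDUCTION_ORDER}
    region_idx = {r: np.nonzero(m.ravel())[0] for r, m in region_masks.items()}
    stim_grid = np.where(phantom.mask(protocol.target), protocol.amplitude, 0.0)

    n_steps = int(np.ceil(duration / dt))
    n_rec = n_steps // record_every + 1
    times_sim = np.empty(n_rec)
    traces = {name: np.empty(n_rec) for name in points}
    region_means = {r: np.empty(n_rec) for r in CONDUCTION_ORDER}

    state = FieldState.resting(phantom)
    k_rec = 0

    def record(state: FieldState) -> None:
        nonlocal k_rec
        times_sim[k_rec] = state.t
        flat = state.u1.ravel()
        for name, pt in points.items():
            traces[name][k_rec] = state.u1[pt]
        for r, idx in region_idx.items():
            region_means[r][k_rec] = flat[idx].mean() if idx.size else np.nan
        k_rec += 1

    record(state)
    for step in range(1, n_steps + 1):
        stim = stim_grid if protocol.active_at(state.t) else None
        state = step_field(state, phantom, dt, stimulus=stim)
        if step % record_every == 0 and k_rec < n_rec:
            record(state)

    times_sim = times_sim[:k_rec]
    scale = cycle_seconds / protocol.period
    recording = FieldRecording(
        times=times_sim * scale,
        times_sim=times_sim,
        probe_traces={n: t[:k_rec] for n, t in traces.items()},
        region_mean_u1={r: t[:k_rec] for r, t in region_means.items()},
        activation_times={},
        cycle_seconds=cycle_seconds,
        dt=dt,
    )
    for r in CONDUCTION_ORDER:
        xs = recording.threshold_crossings(recording.region_mean_u1[r])
        if xs.size:
            recording.activation_times[r] = float(recording.times[xs[0]])
    if RegionLabel.VENTRICLES not in recording.activation_times:
        recording.warnings.append("propagation_failure")
        warnings.warn("ventricles never activated (propagation failure)",
                      RuntimeWarning, stacklevel=2)
    return recording


def extract_conventional_lead(recording: FieldRecording, probe_name: str = "conventional") -> ECGSignal:
    """Two-point lead: detection minus reference, mean removed."""
    try:
        det = recording.probe_traces[f"{probe_name}:a"]
        ref = recording.probe_traces[f"{probe_name}:b"]
    except KeyError as exc:
        raise KeyError(f"no conventional probe named {probe_name!r} in recording") from exc
    lead = det - ref
    return ECGSignal(samples=lead - lead.mean(), T=recording.T,
                     channel=probe_name, provenance="simulated", t0=float(recording.times[0]))


def extract_single_position(recording: FieldRecording, probe_name: str = "single") -> ECGSignal:
    """Single-point trace (no reference subtraction), mean removed."""
    if probe_name not in recording.probe_traces:
        raise KeyError(f"no single-position probe named {probe_name!r} in recording")
    tr = recording.probe_traces[probe_name]
    return ECGSignal(samples=tr - tr.mean(), T=recording.T,
                     channel=probe_name, provenance="simulated", t0=float(recording.times[0]))
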
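"""Synthetic bright-field GUV movies with exact ground truth.

A sucrose-filled vesicle in a glucose bath appears in bright field as a
darker disc surrounded by a refractive-index halo. This module renders a
stylised version of that appearance — uniform interior and exterior
plateaus joined by a smooth step, plus an odd (derivative-of-Gaussian) rim
ring: a dark band just inside and a bright halo just outside the membrane —
and records, frame by frame, the exact area, perimeter, form factor and
optical contrast of the rendered cross-section. Shapes are radial Fourier
perturbations of an (optionally elliptical) disc, which covers the
repertoire seen in pulsed vesicles: circular discs, elliptical deformation,
multi-mode buckling, and transient macropore arcs rendered as a local
erasure of the rim.

The module also integrates the single-pore efflux ODE (dV/dt = -Q with
Q = 2 sigma r^3 / (3 eta0 R)) so that downstream area-decay fitting and
pore-radius inversion can be tested closed-loop against a known pore radius.

Everything is deterministic given a scenario and its seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import biophysics
from .biophysics import MediumParams, MembraneParams
from .errors import ShapeOutOfBounds, SimulationCollapse
from .geometry import form_factor, polygon_area, polygon_perimeter

__all__ = [
    "OpticalParams",
    "BuckleMode",
    "PoreArc",
    "ShapeState",
    "Scenario",
    "TruthRecord",
    "render_frame",
    "generate_movie",
    "write_movie",
    "read_movie",
    "simulate_efflux_dynamics",
    "EffluxTrajectory",
    "static_scenario",
    "shrinkage_scenario",
    "buckling_scenario",
    "pore_flash_scenario",
    "contrast_loss_scenario",
]

#: vertices used to polygonise shapes for ground-truth area/perimeter;
#: the polygonisation error of the form factor is O(1/N^2) ~ 4e-7.
TRUTH_VERTICES = 4096

#: minimum clearance between the vesicle and the image border, px
BORDER_MARGIN_PX = 5.0


@dataclass(frozen=True)
class OpticalParams:
    """Rendering model of one frame.

    Intensities are dimensionless in [0, 1]; ``rim_width`` is in um.
    ``contrast_decay_time`` (s) is the time constant with which the interior
    intensity relaxes towards the exterior one after permeabilisation
    (``inf`` = no contrast loss); it is consumed by the scenario builders,
    not by the renderer itself.
    """

    interior_intensity: float = 0.35
    exterior_intensity: float = 0.65
    rim_amplitude: float = 0.2
    rim_width: float = 1.0
    noise_sd: float = 0.01
    contrast_decay_time: float = math.inf

    def __post_init__(self):
        for name in ("interior_intensity", "exterior_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.rim_width > 0:
            raise ValueError("rim_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.contrast_decay_time > 0:
            raise ValueError("contrast_decay_time must be positive (may be inf)")

    @property
    def contrast(self) -> float:
        """True contrast index (I_out - I_in) / (I_out + I_in) of the plateaus."""
        s = self.exterior_intensity + self.interior_intensity
        if s == 0:
            return 0.0
        return (self.exterior_intensity - self.interior_intensity) / s


@dataclass(frozen=True)
class BuckleMode:
    """One radial Fourier mode r(theta) += amplitude * cos(mode*theta + phase)."""

    mode: int
    amplitude: float
    phase: float = 0.0

    def __post_init__(self):
        if self.mode < 2:
            raise ValueError("buckle mode must be >= 2")
        if self.amplitude < 0:
            raise ValueError("buckle amplitude must be non-negative")


@dataclass(frozen=True)
class PoreArc:
    """Angular arc over which the membrane rim is erased (a macropore)."""

    center_angle: float
    half_width: float

    def __post_init__(self):
        if not 0 < self.half_width < math.pi / 2:
            raise ValueError("pore half_width must be in (0, pi/2)")


@dataclass(frozen=True)
class ShapeState:
    """Cross-section shape of the vesicle in one frame.

    The boundary is the radial function (all lengths in um)

        r(theta) = r_ellipse(theta - rotation)
                   + sum_k amplitude_k * cos(mode_k*(theta - rotation) + phase_k)

    where ``r_ellipse`` is the area-equivalent ellipse of aspect ratio
    ``ellipse_aspect`` (>= 1; 1 = circle) and base radius ``base_radius``.
    ``center`` displaces the shape from the image centre.
    """

    base_radius: float
    ellipse_aspect: float = 1.0
    buckles: tuple[BuckleMode, ...] = ()
    pore_arc: PoreArc | None = None
    center: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0

    def __post_init__(self):
        if not self.base_radius > 0:
            raise ValueError("base_radius must be positive")
        if not self.ellipse_aspect >= 1.0:
            raise ValueError("ellipse_aspect must be >= 1")
        object.__setattr__(self, "buckles", tuple(self.buckles))
        for b in self.buckles:
            if b.amplitude >= self.base_radius / 2:
                raise ValueError(
                    "buckle amplitude must stay below base_radius/2 to avoid self-intersection"
                )

    def radius(self, theta) -> np.ndarray:
        """Boundary radius r(theta) in um (vectorised)."""
        th = np.asarray(theta, dtype=float) - self.rotation
        q = self.ellipse_aspect
        r = self.base_radius / np.sqrt(np.cos(th) ** 2 / q + q * np.sin(th) ** 2)
        for b in self.buckles:
            r = r + b.amplitude * np.cos(b.mode * th + b.phase)
        return r

    def boundary_polygon(self, n: int = TRUTH_VERTICES) -> np.ndarray:
        """Closed boundary polygon in um, relative to the image centre."""
        theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        r = self.radius(theta)
        return np.column_stack(
            [self.center[0] + r * np.cos(theta), self.center[1] + r * np.sin(theta)]
        )

    def true_geometry(self, n: int = TRUTH_VERTICES) -> tuple[float, float, float]:
        """(area um^2, perimeter um, form factor) of the polygonised boundary."""
        poly = self.boundary_polygon(n)
        a = polygon_area(poly)
        p = polygon_perimeter(poly)
        return a, p, form_factor(a, p)


@dataclass(frozen=True)
class TruthRecord:
    """Per-frame ground truth of a generated movie (um, um^2, dimensionless)."""

    area_um2: np.ndarray
    perimeter_um: np.ndarray
    ff: np.ndarray
    contrast: np.ndarray

    def to_dataframe(self, fps: float | None = None) -> pd.DataFrame:
        frames = np.arange(len(self.area_um2))
        data = {"frame": frames}
        if fps is not None:
            data["time_s"] = frames / fps
        data.update(
            area_um2=self.area_um2,
            perimeter_um=self.perimeter_um,
            ff=self.ff,
            contrast=self.contrast,
        )
        return pd.DataFrame(data)


@dataclass(frozen=True)
class Scenario:
    """Declarative description of one synthetic movie.

    ``shape_timeline`` and ``optics_timeline`` give one state per frame; a
    single state is broadcast over all frames. ``pulses`` is free-form
    metadata (typically :class:`guvpore.response.PulseEvent` objects) carried
    along for the downstream stages.
    """

    frames: int
    fps: float
    pixel_size: float
    image_size: int
    shape_timeline: Sequence[ShapeState] | ShapeState
    optics_timeline: Sequence[OpticalParams] | OpticalParams
    pulses: tuple = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.frames < 1:
            raise ValueError("a scenario needs at least one frame")
        if not (self.fps > 0 and self.pixel_size > 0 and self.image_size > 8):
            raise ValueError("fps, pixel_size must be positive and image_size > 8 px")

    def shape_at(self, frame: int) -> ShapeState:
        if isinstance(self.shape_timeline, ShapeState):
            return self.shape_timeline
        return self.shape_timeline[frame]

    def optics_at(self, frame: int) -> OpticalParams:
        if isinstance(self.optics_timeline, OpticalParams):
            return self.optics_timeline
        return self.optics_timeline[frame]

    def validate(self) -> None:
        """Check timeline coverage and the border-margin invariant."""
        for tl, name in ((self.shape_timeline, "shape"), (self.optics_timeline, "optics")):
            if not isinstance(tl, (ShapeState, OpticalParams)) and len(tl) != self.frames:
                raise ValueError(f"{name}_timeline must define all {self.frames} frames")
        half = (self.image_size - 1) / 2.0 * self.pixel_size
        margin = BORDER_MARGIN_PX * self.pixel_size
        theta = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
        for i in range(self.frames):
            shape = self.shape_at(i)
            r = shape.radius(theta)
            x = shape.center[0] + r * np.cos(theta)
            y = shape.center[1] + r * np.sin(theta)
            reach = max(np.abs(x).max(), np.abs(y).max())
            if reach > half - margin:
                raise ShapeOutOfBounds(
                    f"frame {i}: shape reaches {reach:.2f} um from centre, limit is "
                    f"{half - margin:.2f} um ({BORDER_MARGIN_PX:g} px margin)"
                )


def render_frame(
    shape: ShapeState,
    optics: OpticalParams,
    pixel_size: float,
    image_size: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one noiseless-or-noisy grayscale frame as float64 in [0, 1].

    Pixel centres sit at integer coordinates, origin top-left, x to the
    right and y downwards. The intensity profile across the membrane is an
    odd function of the signed boundary distance, so the mid-plateau
    iso-level of the (noiseless) image coincides with the true contour.
    A :class:`PoreArc` erases both the rim and the interior/exterior step
    over its arc, with a smooth angular taper.
    """
    half = (image_size - 1) / 2.0 * pixel_size
    margin = BORDER_MARGIN_PX * pixel_size
    theta_chk = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    r_chk = shape.radius(theta_chk)
    reach = max(
        np.abs(shape.center[0] + r_chk * np.cos(theta_chk)).max(),
        np.abs(shape.center[1] + r_chk * np.sin(theta_chk)).max(),
    )
    if reach > half - margin:
        raise ShapeOutOfBounds(
            f"shape reaches {reach:.2f} um from the image centre, limit {half - margin:.2f} um"
        )
    if optics.noise_sd > 0 and rng is None:
        raise ValueError("noise_sd > 0 requires an rng for deterministic rendering")

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    cx = (image_size - 1) / 2.0 + shape.center[0] / pixel_size
    cy = (image_size - 1) / 2.0 + shape.center[1] / pixel_size
    dx = (xx - cx) * pixel_size
    dy = (yy - cy) * pixel_size
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    d = rho - shape.radius(theta)  # signed distance proxy, um; >0 outside

    interior, exterior = optics.interior_intensity, optics.exterior_intensity
    w_edge = 0.5 * pixel_size
    step = np.where(
        d < -6 * w_edge,
        1.0,
        np.where(d > 6 * w_edge, 0.0, 0.5 * (1.0 - np.tanh(d / w_edge))),
    )
    w = optics.rim_width
    with np.errstate(under="ignore"):
        rim = optics.rim_amplitude * (d / w) * np.exp(0.5 - d**2 / (2.0 * w**2))
    rim[np.abs(d) > 6 * w] = 0.0

    deviation = (interior - exterior) * step + rim
    if shape.pore_arc is not None:
        delta = np.arctan2(
            np.sin(theta - shape.pore_arc.center_angle),
            np.cos(theta - shape.pore_arc.center_angle),
        )
        gate = np.where(
            np.abs(delta) < shape.pore_arc.half_width,
            np.cos(math.pi * delta / (2.0 * shape.pore_arc.half_width)) ** 2,
            0.0,
        )
        deviation = deviation * (1.0 - gate)

    image = exterior + deviation
    if optics.noise_sd > 0:
        image = image + rng.normal(0.0, optics.noise_sd, image.shape)
    return np.clip(image, 0.0, 1.0)


def generate_movie(scenario: Scenario) -> tuple[np.ndarray, TruthRecord]:
    """Render all frames of a scenario into a uint16 stack plus ground truth.

    The float rendering is quantised to 16-bit grayscale exactly as it would
    be written to TIFF, so writing and re-reading the stack is lossless.
    Identical scenarios (including ``rng_seed``) yield bit-identical output.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.rng_seed)
    stack = np.empty((scenario.frames, scenario.image_size, scenario.image_size), dtype=np.uint16)
    area = np.empty(scenario.frames)
    perim = np.empty(scenario.frames)
    ff = np.empty(scenario.frames)
    contrast = np.empty(scenario.frames)
    for i in range(scenario.frames):
        shape, optics = scenario.shape_at(i), scenario.optics_at(i)
        try:
            img = render_frame(shape, optics, scenario.pixel_size, scenario.image_size, rng)
        except ShapeOutOfBounds as exc:
            raise ShapeOutOfBounds(f"frame {i}: {exc}") from exc
        stack[i] = np.round(img * 65535.0).astype(np.uint16)
        area[i], perim[i], ff[i] = shape.true_geometry()
        contrast[i] = optics.contrast
    return stack, TruthRecord(area, perim, ff, contrast)


def write_movie(path: str | Path, stack: np.ndarray) -> None:
    """Write a uint16 stack as a multi-page grayscale TIFF."""
    tifffile.imwrite(str(path), stack, photometric="minisblack")

def read_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_scenario(path: str | Path, scenario: Scenario) -> None:
    """Serialise a scenario (shapes, optics, pulses, seed) as JSON."""
    payload = asdict(scenario)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


# --------------------------------------------------------------------------
# Efflux dynamics


@dataclass(frozen=True)
class EffluxTrajectory:
    """Solution of the single-pore efflux ODE, sampled every ``dt``.

    ``expelled_um3`` is the integral of Q over time accumulated inside the
    same RK4 loop, so volume bookkeeping V(0) - V(t) = \\int Q dt holds to
    integrator accuracy. ``area_um2`` is the projected disc area pi R^2.
    """

    time_s: np.ndarray
    radius_um: np.ndarray
    area_um2: np.ndarray
    volume_um3: np.ndarray
    expelled_um3: np.ndarray
    efflux0_um3_per_s: float


def simulate_efflux_dynamics(
    radius0_um: float,
    pore_radius_um: float,
    membrane: MembraneParams,
    medium: MediumParams,
    duration_s: float,
    dt: float = 1e-3,
    constant_efflux: bool = False,
) -> EffluxTrajectory:
    """Integrate dV/dt = -Q(r, R) for a vesicle leaking through one pore.

    Q follows the single-pore law Q = 2 sigma r^3 / (3 eta0 R), with R
    updated each step (explicit RK4, fixed dt). With ``constant_efflux`` the
    efflux is frozen at its initial value Q(r, R0), for which the closed
    form R(t) = (R0^3 - 3 Q t / (4 pi))^(1/3) holds exactly.

    Raises
    ------
    SimulationCollapse
        If R falls to or below the pore radius before ``duration_s``.
    """
    if not radius0_um > 0:
        raise ValueError("radius0_um must be positive")
    if pore_radius_um < 0:
        raise ValueError("pore_radius_um must be non-negative")
    if not dt > 0:
        raise ValueError("dt must be positive")

    r_pore = pore_radius_um * 1e-6
    radius0 = radius0_um * 1e-6
    q0 = biophysics.pore_efflux(r_pore, membrane.sigma_mem, medium.eta0, radius0)

    class _Collapsed(Exception):
        """Internal: an RK4 stage stepped below the pore radius."""

    def q_of(radius_m: float) -> float:
        if radius_m <= r_pore or radius_m <= 0:
            raise _Collapsed
        if constant_efflux:
            return q0
        return biophysics.pore_efflux(r_pore, membrane.sigma_mem, medium.eta0, radius_m)

    def drdt(radius_m: float) -> float:
        return -q_of(radius_m) / (4.0 * math.pi * radius_m**2)

    n_steps = int(round(duration_s / dt))
    times = np.arange(n_steps + 1) * dt
    radius = np.empty(n_steps + 1)
    expelled = np.empty(n_steps + 1)
    radius[0], expelled[0] = radius0, 0.0
    r, out = radius0, 0.0
    for i in range(n_steps):
        try:
            # RK4 on the joint state (R, expelled volume)
            k1r = drdt(r)
            k1v = q_of(r)
            k2r = drdt(r + 0.5 * dt * k1r)
            k2v = q_of(r + 0.5 * dt * k1r)
            k3r = drdt(r + 0.5 * dt * k2r)
            k3v = q_of(r + 0.5 * dt * k2r)
            k4r = drdt(r + dt * k3r)
            k4v = q_of(r + dt * k3r)
        except _Collapsed:
            raise SimulationCollapse((i + 1) * dt) from None
        r = r + dt / 6.0 * (k1r + 2 * k2r + 2 * k3r + k4r)
        out = out + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if not r > r_pore:
            raise SimulationCollapse((i + 1) * dt)
        radius[i + 1], expelled[i + 1] = r, out

    radius_um = radius * 1e6
    return EffluxTrajectory(
        time_s=times,
        radius_um=radius_um,
        area_um2=math.pi * radius_um**2,
        volume_um3=4.0 / 3.0 * math.pi * radius_um**3,
        expelled_um3=expelled * 1e18,
        efflux0_um3_per_s=q0 * 1e18,
    )


# --------------------------------------------------------------------------
# Scenario builders


def static_scenario(
    radius_um: float = 20.0,
    frames: int = 10,
    fps: float = 10.0,
    pixel_size: float = 0.5,
    image_size: int = 128,
    optics: OpticalParams = OpticalParams(),
    seed: int = 0,
) -> Scenario:
    """A motionless circular vesicle."""
    return Scenario(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        image_size=image_size,
        shape_timeline=ShapeState(base_radius=radius_um),
        optics_timeline=optics,
        rng_seed=seed,
    )


def shrinkage_scenario(
    radius_um: float = 20.0,
    area_ratio: float = 0.7,
    frames: int = 60,
    fps: float = 10.0,
    pixel_size: float = 0.5,
    image_size: int = 128,
    shrink_start: int = 10,
    optics: OpticalParams = OpticalParams(),
    seed: int = 0,
) -> Scenario:
    """Pulse-triggered shrinkage: projected area decays exponentially from
    A_i to ``area_ratio * A_i`` after frame ``shrink_start`` (time constant a
    fifth of the remaining movie, so the end state is reached to ~0.7%)."""
    a_i = math.pi * radius_um**2
    a_f = area_ratio * a_i
    span = max(frames - 1 - shrink_start, 1) / fps
    tau = span / 5.0
    shapes = []
    for i in range(frames):
        if i <= shrink_start:
            a = a_i
        else:
            t = (i - shrink_start) / fps
            a = a_f + (a_i - a_f) * math.exp(-t / tau)
        shapes.append(ShapeState(base_radius=math.sqrt(a / math.pi)))
    return Scenario(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        image_size=image_size,
        shape_timeline=shapes,
        optics_timeline=optics,
        rng_seed=seed,
    )


def buckling_scenario(
    radius_um: float = 20.0,
    modes: Sequence[tuple[int, float]] = ((3, 3.0), (4, 1.2)),
    frames: int = 60,
    fps: float = 10.0,
    pixel_size: float = 0.5,
    image_size: int = 128,
    buckle_start: int = 10,
    optics: OpticalParams = OpticalParams(),
    seed: int = 0,
) -> Scenario:
    """Gel-phase-like buckling: Fourier modes grow after ``buckle_start``
    while the cross-section area is held exactly constant (the vesicle loses
    volume, not lipid), so A_norm stays 1 while the form factor drops."""
    a_target = math.pi * radius_um**2
    span = max(frames - 1 - buckle_start, 1) / fps
    tau = span / 5.0
    shapes = []
    for i in range(frames):
        if i <= buckle_start:
            growth = 0.0
        else:
            growth = 1.0 - math.exp(-((i - buckle_start) / fps) / tau)
        buckles = tuple(
            BuckleMode(mode=m, amplitude=amp * growth, phase=0.7 * k)
            for k, (m, amp) in enumerate(modes)
        )
        shape = ShapeState(base_radius=radius_um, buckles=buckles)
        # rescale the whole shape so the enclosed area matches the target exactly
        a, _, _ = shape.true_geometry()
        s = math.sqrt(a_target / a)
        shapes.append(
            ShapeState(
                base_radius=radius_um * s,
                buckles=tuple(
                    BuckleMode(b.mode, b.amplitude * s, b.phase) for b in buckles
                ),
            )
        )
    return Scenario(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        image_size=image_size,
        shape_timeline=shapes,
        optics_timeline=optics,
        rng_seed=seed,
    )


def pore_flash_scenario(
    radius_um: float = 20.0,
    frames: int = 11,
    pore_frame: int = 5,
    half_width: float = 0.6,
    fps: float = 10.0,
    pixel_size: float = 0.5,
    image_size: int = 128,
    optics: OpticalParams = OpticalParams(),
    seed: int = 0,
) -> Scenario:
    """A macropore arc visible on exactly one frame, as in bright-field
    recordings where pores survive for about a single frame."""
    shapes = [
        ShapeState(
            base_radius=radius_um,
            pore_arc=PoreArc(center_angle=0.0, half_width=half_width) if i == pore_frame else None,
        )
        for i in range(frames)
    ]
    return Scenario(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        image_size=image_size,
        shape_timeline=shapes,
        optics_timeline=optics,
        rng_seed=seed,
    )


def contrast_loss_scenario(
    radius_um: float = 20.0,
    frames: int = 40,
    fps: float = 10.0,
    loss_start: int = 5,
    decay_time_s: float = 1.0,
    pixel_size: float = 0.5,
    image_size: int = 128,
    optics: OpticalParams = OpticalParams(),
    seed: int = 0,
) -> Scenario:
    """Interior intensity relaxes towards the exterior after ``loss_start``
    with the given time constant: gradual (large ``decay_time_s``) or
    complete (small) contrast loss."""
    shapes = ShapeState(base_radius=radius_um)
    optics_tl = []
    for i in range(frames):
        if i <= loss_start:
            interior = optics.interior_intensity
        else:
            t = (i - loss_start) / fps
            interior = optics.exterior_intensity + (
                optics.interior_intensity - optics.exterior_intensity
            ) * math.exp(-t / decay_time_s)
        optics_tl.append(
            OpticalParams(
                interior_intensity=interior,
                exterior_intensity=optics.exterior_intensity,
                rim_amplitude=optics.rim_amplitude,
                rim_width=optics.rim_width,
                noise_sd=optics.noise_sd,
                contrast_decay_time=decay_time_s,
            )
        )
    return Scenario(
        frames=frames,
        fps=fps,
        pixel_size=pixel_size,
        image_size=image_size,
        shape_timeline=shapes,
        optics_timeline=optics_tl,
        rng_seed=seed,
    )
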
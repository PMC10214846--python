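"""Seeded generators for every input the analysis stages consume.

The platform's raw data are photographs and micrographs, so quantitative
testing runs on synthetic inputs carrying known ground truth: cap-height
series shrinking under a prescribed flow, fluorescence fields of projected
spherical colonies on paper-like texture, per-day colony volume cohorts
growing exponentially, and circuit descriptions transcribing the printed
stack geometries.  Every generator is a pure function of its arguments and
seed (identical calls give bit-identical outputs), and each returns its
ground truth alongside the artifact.

The paper-texture model (two octaves of smoothed noise, 15% multiplicative
amplitude) and the fiber model (a dark cylinder of comparable radius
through the colony) are this package's own parameterizations of the
qualitative features visible in the source images — they are not measured
from data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import fluid_mechanics as fm
from .cap_dynamics import CapSeries
from .circuits import CircuitSpec
from .colony_scoring import FluorescenceImage
from .darcy_network import Edge, HydraulicNetwork

__all__ = [
    "SynthSpec",
    "gen_cap_series",
    "gen_colony_field",
    "gen_classifier_benchmark",
    "evaluate_classifier_benchmark",
    "gen_growth_cohort",
    "gen_circuit",
    "generate",
]

MM = 1e-3
UL = 1e-9  # m^3
UL_PER_H = 1e-9 / 3600.0  # m^3/s

#: paper texture: smoothed-noise octaves and multiplicative amplitude
TEXTURE_OCTAVE_SIGMAS_UM = (40.0, 160.0)
TEXTURE_AMPLITUDE = 0.15
#: default background level, arbitrary units
BACKGROUND_LEVEL = 5.0
#: per-um-of-chord fluorescence yield, arbitrary units
CHORD_GAIN = 1.0


@dataclass(frozen=True)
class SynthSpec:
    """A reproducible generation request: identical spec, identical output."""

    seed: int
    scenario: str  # cap_series | colony_field | growth_cohort | circuit
    parameters: dict = field(default_factory=dict)


def generate(spec: SynthSpec):
    """Dispatch a SynthSpec to its generator."""
    dispatch = {
        "cap_series": gen_cap_series,
        "colony_field": gen_colony_field,
        "growth_cohort": gen_growth_cohort,
        "circuit": gen_circuit,
    }
    if spec.scenario not in dispatch:
        raise ValueError(f"unknown scenario {spec.scenario!r}")
    return dispatch[spec.scenario](seed=spec.seed, **spec.parameters)


# --- cap-height series --------------------------------------------------------

def gen_cap_series(true_flow: Union[float, Callable[[float], float]],
                   base_radius: float,
                   duration: float,
                   sampling_interval: float,
                   initial_height: Optional[float] = None,
                   height_noise_sd: float = 0.0,
                   seed: int = 0) -> tuple[CapSeries, dict]:
    """Cap heights sampled while the cap drains at a prescribed flow.

    ``true_flow`` is the delivery rate (m^3/s, positive = cap shrinking),
    either constant or a callable of time.  The cap volume is integrated,
    inverted to heights, and Gaussian measurement noise of standard
    deviation ``height_noise_sd`` (m) added.  If the cap would empty the
    series is truncated with a warning.  Returns ``(series, truth)`` where
    truth holds the noiseless heights and the flow profile.
    """
    if initial_height is None:
        initial_height = base_radius  # start from a hemispherical cap
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration + sampling_interval / 2, sampling_interval)
    q = (np.full_like(times, float(true_flow))
         if not callable(true_flow) else np.array([true_flow(t) for t in times]))
    v0 = fm.cap_from_height(base_radius, initial_height).volume
    # trapezoidal cumulative delivered volume
    delivered = np.concatenate([[0.0], np.cumsum(
        0.5 * (q[1:] + q[:-1]) * np.diff(times))])
    volumes = v0 - delivered
    if np.any(volumes < 0):
        cut = int(np.argmax(volumes < 0))
        warnings.warn(f"cap empties at sample {cut}; series truncated",
                      stacklevel=2)
        times, volumes, q = times[:cut], volumes[:cut], q[:cut]
    clean_heights = np.array([fm.cap_from_volume(base_radius, v).height
                              for v in volumes])
    noisy = clean_heights + rng.normal(0.0, height_noise_sd, clean_heights.shape)
    noisy = np.clip(noisy, 0.0, 2.0 * base_radius)
    series = CapSeries(times, noisy, base_radius)
    truth = {"times": times, "heights": clean_heights, "volumes": volumes,
             "flow": q, "seed": seed}
    return series, truth


# --- fluorescence fields ------------------------------------------------------

def _paper_texture(shape: tuple[int, int], pixel_size: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative texture mimicking variable paper density."""
    tex = np.zeros(shape)
    for sigma_um in TEXTURE_OCTAVE_SIGMAS_UM:
        octave = ndi.gaussian_filter(rng.standard_normal(shape),
                                     sigma_um / pixel_size, mode="reflect")
        sd = octave.std()
        if sd > 0:
            tex += octave / sd
    tex /= len(TEXTURE_OCTAVE_SIGMAS_UM)
    return 1.0 + TEXTURE_AMPLITUDE * tex


@dataclass(frozen=True)
class _Colony:
    x_um: float
    y_um: float
    radius_um: float
    core_fraction: float
    fiber: bool
    fiber_angle: float
    fiber_radius_um: float
    fiber_attenuation: float
    fiber_offset_um: float


def _render_colony(img: np.ndarray, pixel_size: float, col: _Colony) -> None:
    r_px = col.radius_um / pixel_size
    cx, cy = col.x_um / pixel_size, col.y_um / pixel_size
    x0, x1 = int(max(cx - r_px - 2, 0)), int(min(cx + r_px + 3, img.shape[1]))
    y0, y1 = int(max(cy - r_px - 2, 0)), int(min(cy + r_px + 3, img.shape[0]))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = (xx - cx) * pixel_size
    dy = (yy - cy) * pixel_size
    d2 = dx * dx + dy * dy
    R = col.radius_um
    chord = 2.0 * np.sqrt(np.clip(R * R - d2, 0.0, None))
    if col.core_fraction > 0:
        rc = col.core_fraction ** (1.0 / 3.0) * R
        chord -= 2.0 * np.sqrt(np.clip(rc * rc - d2, 0.0, None))
    if col.fiber:
        # opaque fiber crossing near the colony center: it shadows the
        # fluorescence in a band along its axis (multiplicative attenuation)
        u = -dx * math.sin(col.fiber_angle) + dy * math.cos(col.fiber_angle)
        band = np.abs(u - col.fiber_offset_um) < col.fiber_radius_um
        chord = np.where(band, chord * (1.0 - col.fiber_attenuation), chord)
    img[y0:y1, x0:x1] += CHORD_GAIN * np.clip(chord, 0.0, None)


def gen_colony_field(field_um: tuple[float, float] = (800.0, 800.0),
                     pixel_size: float = 1.6,
                     colonies: Optional[Sequence[dict]] = None,
                     density_per_ml: Optional[float] = None,
                     thickness_um: float = 340.0,
                     n_colonies: Optional[int] = None,
                     radius_um: Union[float, tuple[float, float]] = 10.0,
                     core_fraction: Union[float, Sequence[float]] = 0.0,
                     fiber_fraction: float = 0.0,
                     fiber_radius_rel: tuple[float, float] = (0.2, 0.4),
                     fiber_attenuation: tuple[float, float] = (0.66, 0.72),
                     halo_sigma_um: float = 3.0,
                     noise_model: Optional[str] = "poisson",
                     background_level: float = BACKGROUND_LEVEL,
                     min_separation_factor: float = 2.5,
                     seed: int = 0,
                     ) -> tuple[FluorescenceImage, pd.DataFrame]:
    """Render a synthetic calcein-stained field with known ground truth.

    Colonies are projected uniformly fluorescent spheres (chord-length
    model) with optional dark cores (``core_fraction`` of volume) and dark
    fibers; the background is paper-like multiplicative texture; a Gaussian
    halo blur and shot noise complete the image.  Placement is either an
    explicit ``colonies`` list (dicts with ``x_um, y_um, radius_um`` and
    optional ``core_fraction``/``fiber``), a Poisson count from a seeding
    ``density_per_ml`` over ``field x thickness``, or ``n_colonies``
    random non-overlapping positions.  Returns the image and a truth table
    (one row per colony; overlaps beyond tolerance are flagged).
    """
    rng = np.random.default_rng(seed)
    w_um, h_um = field_um
    shape = (int(round(h_um / pixel_size)), int(round(w_um / pixel_size)))

    placed: list[_Colony] = []

    def draw_radius() -> float:
        if isinstance(radius_um, (tuple, list)):
            return float(rng.uniform(*radius_um))
        return float(radius_um)

    def draw_core(i: int) -> float:
        if np.iterable(core_fraction) and not isinstance(core_fraction, (int, float)):
            seq = list(core_fraction)
            return float(seq[i % len(seq)])
        return float(core_fraction)

    if colonies is not None:
        spec_list = list(colonies)
    else:
        if density_per_ml is not None:
            volume_um3 = w_um * h_um * thickness_um
            count = int(rng.poisson(density_per_ml / 1e12 * volume_um3))
        elif n_colonies is not None:
            count = int(n_colonies)
        else:
            count = 0
        spec_list = [{} for _ in range(count)]

    for i, cdict in enumerate(spec_list):
        r = float(cdict.get("radius_um", draw_radius()))
        f = float(cdict.get("core_fraction", draw_core(i)))
        has_fiber = bool(cdict.get("fiber", rng.random() < fiber_fraction))
        angle = float(cdict.get("fiber_angle", rng.uniform(0, math.pi)))
        rf = float(cdict.get("fiber_radius_um",
                             rng.uniform(*fiber_radius_rel) * r))
        beta = float(cdict.get("fiber_attenuation",
                               rng.uniform(*fiber_attenuation)))
        off = float(cdict.get("fiber_offset_um", rng.uniform(0.0, 0.4) * rf))
        if "x_um" in cdict:
            x, y = float(cdict["x_um"]), float(cdict["y_um"])
        else:
            x = y = None
            for _ in range(200):  # rejection sampling for separation
                xt = rng.uniform(r, w_um - r)
                yt = rng.uniform(r, h_um - r)
                if all((xt - c.x_um) ** 2 + (yt - c.y_um) ** 2
                       >= (min_separation_factor * max(r, c.radius_um)) ** 2
                       for c in placed):
                    x, y = xt, yt
                    break
            if x is None:
                warnings.warn(f"could not place colony {i} without overlap; "
                              "skipping", stacklevel=2)
                continue
        placed.append(_Colony(x, y, r, f, has_fiber, angle, rf, beta, off))

    img = np.zeros(shape)
    for col in placed:
        _render_colony(img, pixel_size, col)
    if halo_sigma_um > 0:
        img = ndi.gaussian_filter(img, halo_sigma_um / pixel_size,
                                  mode="constant")
    img = img + background_level * _paper_texture(shape, pixel_size, rng)
    if noise_model == "poisson":
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    elif noise_model == "gaussian":
        img = np.clip(img + rng.normal(0.0, math.sqrt(background_level),
                                       shape), 0.0, None)
    elif noise_model is not None:
        raise ValueError(f"unknown noise model {noise_model!r}")

    truth_rows = []
    for col in placed:
        overlap = any(
            c is not col
            and (c.x_um - col.x_um) ** 2 + (c.y_um - col.y_um) ** 2
            < (c.radius_um + col.radius_um) ** 2
            for c in placed)
        truth_rows.append({
            "x_um": col.x_um, "y_um": col.y_um, "radius_um": col.radius_um,
            "sphere_volume_um3": 4.0 / 3.0 * math.pi * col.radius_um ** 3,
            "core_fraction": col.core_fraction, "fiber": col.fiber,
            "fiber_angle": col.fiber_angle,
            "fiber_radius_um": col.fiber_radius_um,
            "fiber_attenuation": col.fiber_attenuation,
            "overlaps": overlap, "seed": seed,
        })
    truth = pd.DataFrame(truth_rows, columns=[
        "x_um", "y_um", "radius_um", "sphere_volume_um3", "core_fraction",
        "fiber", "fiber_angle", "fiber_radius_um", "fiber_attenuation",
        "overlaps", "seed"])
    return FluorescenceImage(img, pixel_size), truth


def gen_classifier_benchmark(seed: int = 0,
                             n_per_class: int = 50,
                             core_fraction: float = 0.4,
                             fiber_fraction: float = 0.30,
                             radius_um: tuple[float, float] = (30.0, 45.0),
                             spacing_um: float = 180.0,
                             pixel_size: float = 1.6,
                             ) -> tuple[FluorescenceImage, pd.DataFrame]:
    """The default necrosis-classifier benchmark field.

    ``n_per_class`` necrotic colonies (dark core of ``core_fraction`` of the
    volume) and the same number of fully viable ones, placed on a jittered
    grid with fibers crossing a ``fiber_fraction`` share of all colonies;
    rendered with the default texture, halo and shot noise.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    grid = int(math.ceil(math.sqrt(n)))
    cols = []
    for i in range(n):
        gx, gy = i % grid, i // grid
        cols.append(dict(
            x_um=spacing_um / 2 + gx * spacing_um + rng.uniform(-15, 15),
            y_um=spacing_um / 2 + gy * spacing_um + rng.uniform(-15, 15),
            radius_um=float(rng.uniform(*radius_um)),
            core_fraction=core_fraction if i < n_per_class else 0.0,
            fiber=bool(rng.random() < fiber_fraction),
        ))
    field = (spacing_um / 2 + grid * spacing_um,
             spacing_um / 2 + grid * spacing_um)
    render_seed = int(rng.integers(2 ** 31))
    return gen_colony_field(field_um=field, pixel_size=pixel_size,
                            colonies=cols, seed=render_seed)


def evaluate_classifier_benchmark(image: FluorescenceImage,
                                  truth: pd.DataFrame,
                                  reference: str = "sphere") -> dict:
    """Run the full scoring pipeline and compare against the truth table.

    Each truth colony counts as flagged if any detection matched to it (by
    nearest centroid) is classified possibly necrotic.  Returns
    sensitivity/specificity for the necrotic-vs-not decision plus counts.
    """
    from .colony_scoring import (classify_necrosis, detect_foci,
                                 extract_profiles, subtract_background)

    bg = subtract_background(image)
    recs = detect_foci(image, background=bg)
    flags: dict[int, list[str]] = {}
    for rec in recs:
        x = rec.centroid[1] * image.pixel_size
        y = rec.centroid[0] * image.pixel_size
        d = np.hypot(truth.x_um - x, truth.y_um - y)
        i = int(d.idxmin())
        px, py = extract_profiles(image, rec, background=bg)
        flags.setdefault(i, []).append(
            classify_necrosis(px, py, reference=reference))
    is_necrotic = truth.core_fraction.to_numpy() > 0
    flagged = np.array(["possibly_necrotic" in flags.get(i, [])
                        for i in range(len(truth))])
    n_pos = int(is_necrotic.sum())
    n_neg = int((~is_necrotic).sum())
    return {
        "n_detected": len(recs),
        "sensitivity": float((flagged & is_necrotic).sum() / n_pos)
        if n_pos else float("nan"),
        "specificity": float((~flagged & ~is_necrotic).sum() / n_neg)
        if n_neg else float("nan"),
    }


# --- growth cohorts -----------------------------------------------------------

def gen_growth_cohort(n_colonies: int = 20,
                      v0: float = 4188.79,
                      doubling: float = 24.0,
                      days: Sequence[int] = (1, 10),
                      lognormal_cv: float = 0.3,
                      seed: int = 0) -> pd.DataFrame:
    """Per-day colony volume tables under exponential growth.

    ``V_i(t) = v0 * 2**(t/tau) * eps`` with ``eps`` lognormal, unit mean and
    coefficient of variation ``lognormal_cv``, drawn independently per
    colony and per observation day (each day is a different stained paper,
    so cohorts are cross-sectional).  ``v0`` defaults to a 10 um-radius
    cell; times are in hours with day d observed at ``24 * (d - 1)`` h
    elapsed since the day-1 cohort.
    """
    if n_colonies < 2:
        raise ValueError("need at least 2 colonies")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + lognormal_cv ** 2))
    mu = -0.5 * sigma ** 2  # unit-mean lognormal
    rows = []
    for day in days:
        t_h = 24.0 * (day - 1)
        eps = rng.lognormal(mu, sigma, n_colonies) if lognormal_cv > 0 \
            else np.ones(n_colonies)
        vols = v0 * 2.0 ** (t_h / doubling) * eps
        for i, v in enumerate(vols):
            rows.append({"day": day, "elapsed_h": t_h, "colony": i,
                         "volume_um3": v})
    return pd.DataFrame(rows)


# --- circuit templates --------------------------------------------------------

def _washer(od_mm: float = 10.0, id_mm: float = 5.0, t_mm: float = 1.0,
            ) -> fm.AnnularElement:
    return fm.AnnularElement(od_mm * MM, id_mm * MM, t_mm * MM, "hydrophilic")


#: order-of-magnitude placeholder permeabilities (no authoritative values
#: exist for these materials); m^2
PLACEHOLDER_PERMEABILITY = {
    "whatman_1": 1e-11,
    "whatman_113": 3e-11,
    "agarose_paper_regulator": 5e-13,
}


def gen_circuit(template: str = "two_stack", randomize: bool = False,
                seed: int = 0) -> CircuitSpec:
    """Circuit descriptions transcribing the printed stack geometries.

    Templates:

    - ``two_stack`` — the flow-direction demonstration geometry: a 1-washer
      input stack and a 5-washer recipient stack (OD 10 / ID 5 / 1 mm
      washers) on a shared paper base;
    - ``fig5_tessellated`` — four 8 x 8 x 3 mm agarose blocks in two
      abutting stacks between input and output stacks (total module volume
      768 ul, carried in ``meta``);
    - ``fig7_cross`` — four regulated input stacks feeding a central
      3-paper stack over an impermeable spacer with a 6 x 6 mm hole
      (wanted flow through the center, wasteful flow near edges).

    ``randomize`` perturbs all dimensions by up to +/-20% (uniform, seeded)
    for property testing.  Resistances use placeholder permeabilities and
    are order-of-magnitude only.
    """
    rng = np.random.default_rng(seed)

    def j(x: float) -> float:  # jitter
        return x * float(rng.uniform(0.8, 1.2)) if randomize else x

    env = fm.Environment()
    mu = env.medium.viscosity

    def paper_resistance(length_m: float, width_m: float, thick_m: float,
                         k: float) -> float:
        return mu * length_m / (k * width_m * thick_m)

    if template == "two_stack":
        w = lambda: _washer(j(10.0), j(5.0), j(1.0))  # noqa: E731
        stack_a = fm.StackSpec(elements=(w(),), label="A",
                               cap=fm.cap_from_height(j(5.0) * MM / 2, 1.0 * MM))
        stack_b = fm.StackSpec(elements=tuple(w() for _ in range(5)), label="B",
                               cap=fm.cap_from_height(j(5.0) * MM / 2, 1.0 * MM))
        r_base = paper_resistance(j(30.0) * MM, j(10.0) * MM, j(0.18) * MM,
                                  PLACEHOLDER_PERMEABILITY["whatman_1"])
        net = HydraulicNetwork(
            edges=[Edge("A", "B", r_base, "base_paper", wanted=True)])
        return CircuitSpec(env, {"A": stack_a, "B": stack_b}, net,
                           name="two_stack")

    if template == "fig5_tessellated":
        block_dims = [(j(8.0), j(8.0), j(3.0)) for _ in range(4)]
        block_vols = [x * y * z * MM ** 3 for x, y, z in block_dims]
        k_ag = 1e-13  # placeholder agarose permeability
        r_block = [mu * (z * MM) / (k_ag * (x * MM) * (y * MM))
                   for x, y, z in block_dims]
        r_base = paper_resistance(j(28.0) * MM, j(8.0) * MM, j(0.18) * MM,
                                  PLACEHOLDER_PERMEABILITY["whatman_1"])
        stack_a = fm.StackSpec(elements=(_washer(j(10.0), j(5.0), j(1.0)),),
                               cap=fm.cap_from_height(j(5.0) * MM / 2, 1 * MM),
                               label="A")
        stack_d = fm.StackSpec(
            elements=(fm.AnnularElement(j(10.0) * MM, j(5.0) * MM,
                                        j(5.2) * MM, "hydrophilic"),
                      _washer(j(10.0), j(5.0), j(1.0))),
            cap=fm.cap_from_height(j(5.0) * MM / 2, 1 * MM), label="D")
        net = HydraulicNetwork(edges=[
            Edge("A", "base", r_base / 2, "paper1_left"),
            Edge("base", "topB", r_block[0] + r_block[1], "blocks_B",
                 wanted=True),
            Edge("base", "topB", r_block[2] + r_block[3], "blocks_C",
                 wanted=True),
            Edge("base", "topB", 50.0 * min(r_block), "block_gap_bypass"),
            Edge("topB", "D", r_base / 2, "paper2_bridge"),
        ])
        return CircuitSpec(env, {"A": stack_a, "D": stack_d}, net,
                           name="fig5_tessellated",
                           meta={"module_volumes_m3": block_vols,
                                 "total_module_volume_m3": float(sum(block_vols))})

    if template == "fig7_cross":
        paper_t = j(0.34) * MM
        paper_w = j(10.0) * MM
        hole_w = j(6.0) * MM
        k113 = PLACEHOLDER_PERMEABILITY["whatman_113"]
        # vertical Darcy resistance of the 3-paper pile over the hole vs the
        # edge annulus outside the hole (longer, narrower wasteful path)
        r_center = mu * (3 * paper_t) / (k113 * hole_w * hole_w)
        edge_area = paper_w * paper_w - hole_w * hole_w
        r_edge = 20.0 * mu * (3 * paper_t) / (k113 * edge_area)
        r_reg = paper_resistance(j(12.0) * MM, j(12.0) * MM, j(0.18) * MM,
                                 PLACEHOLDER_PERMEABILITY[
                                     "agarose_paper_regulator"])
        r_base = paper_resistance(j(20.0) * MM, j(20.0) * MM, j(0.18) * MM,
                                  PLACEHOLDER_PERMEABILITY["whatman_1"])
        stacks = {}
        edges = []
        for i in range(1, 5):
            label = f"A{i}"
            stacks[label] = fm.StackSpec(
                elements=(_washer(j(10.0), j(5.0), j(1.0)),),
                cap=fm.cap_from_height(j(5.0) * MM / 2, 1 * MM), label=label)
            edges.append(Edge(label, "base", r_reg, f"regulator_{i}"))
            edges.append(Edge(label, "base", r_base, f"base_path_{i}"))
        stacks["B"] = fm.StackSpec(
            elements=(
                fm.AnnularElement(j(18.0) * MM, hole_w, j(0.11) * MM,
                                  "hydrophobic"),
                fm.AnnularElement(paper_w * 1.128, 0.0 * MM, paper_t,
                                  "hydrophilic", permeability=k113),
                fm.AnnularElement(paper_w * 1.128, 0.0 * MM, paper_t,
                                  "hydrophilic", permeability=k113),
                fm.AnnularElement(paper_w * 1.128, 0.0 * MM, paper_t,
                                  "hydrophilic", permeability=k113),
                fm.AnnularElement(j(8.0) * MM, j(4.3) * MM, j(5.0) * MM,
                                  "hydrophilic"),
            ),
            cap=fm.cap_from_height(j(4.3) * MM / 2, 1 * MM), label="B")
        edges.append(Edge("base", "B", r_center, "center_hole", wanted=True))
        edges.append(Edge("base", "B", r_edge, "edge_bypass"))
        net = HydraulicNetwork(edges=edges)
        return CircuitSpec(env, stacks, net, name="fig7_cross",
                           meta={"hole_mm": hole_w / MM})

    raise ValueError(f"unknown template {template!r}")
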
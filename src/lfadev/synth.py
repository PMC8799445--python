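"""Synthetic strip images and screen tables with known ground truth.

Laboratory LFA data (strip photographs, screening signal tables) are not
shipped with this package; instead this module generates them with planted,
fully known truth so that the imaging and analytics pipelines can be
validated end to end.  Two generators are provided:

* :func:`render_strip` draws a single strip: a Gaussian test line of known
  amplitude on a (possibly sloped) membrane background with additive
  Gaussian camera noise, clipped to the bit depth.  Everything is
  reproducible from the seed.
* :func:`simulate_screen` produces a capture x detection antibody screening
  table shaped like a real pair screen: per-antibody latent affinities, a
  pair-specific epitope-compatibility term (a sandwich pair only works when
  the two antibodies bind compatible epitopes), a saturating
  Michaelis-Menten-style response in affinity, an optional high-dose hook
  term, cross-reactivity against a second antigen, and blank/replicate
  noise.  Replicates of a condition share the condition mean and differ
  only by replicate noise.

The synthetic camera noise is Gaussian, appropriate for the averaged
intensities of a consumer CMOS sensor; it is configurable but deliberately
not Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .design import DesignSpec, enumerate_conditions
from .imaging import StripImage

__all__ = [
    "StripTruth",
    "ScreenTruth",
    "render_strip",
    "render_strip_file",
    "simulate_screen",
    "planted_screen_truth",
    "random_schedule_case",
]


@dataclass(frozen=True)
class StripTruth:
    """Ground truth for one synthetic strip image.

    Intensities are in the image's signal units (0..255 for 8-bit);
    positions are pixels along the flow axis.
    """

    line_amplitude: float = 30.0
    line_center: int = 60
    line_sigma: float = 4.0
    background_level: float = 20.0
    background_slope: float = 0.05
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.line_amplitude < 0:
            raise ValueError("line_amplitude must be >= 0")
        if self.line_sigma <= 0:
            raise ValueError("line_sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_strip(
    truth: StripTruth,
    shape: tuple[int, int] = (120, 40),
    flow_axis: str = "rows",
    bit_depth: int = 8,
    dark_line: bool = False,
    condition_id: str = "",
) -> tuple[StripImage, StripTruth]:
    """Render one synthetic strip.

    The noise-free image is ``background_level + slope * position +
    amplitude * exp(-(position - center)^2 / (2 sigma^2))`` along the flow
    axis, constant across the width; iid Gaussian noise is added and the
    result is clipped to the bit depth and quantised.  With
    ``dark_line=True`` the pattern is drawn as a dark line on a bright
    membrane (pixel = white - value), matching raw camera images of real
    strips; the default bright-line polarity is already in signal units.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    n_flow, n_width = shape
    lo = truth.line_center - 4 * truth.line_sigma
    hi = truth.line_center + 4 * truth.line_sigma
    if lo < 0 or hi > n_flow - 1:
        raise ValueError(
            f"line at {truth.line_center} +/- 4*{truth.line_sigma} px falls "
            f"outside a {n_flow}-px strip"
        )
    rng = np.random.default_rng(truth.seed)
    pos = np.arange(n_flow, dtype=float)
    ideal = (
        truth.background_level
        + truth.background_slope * pos
        + truth.line_amplitude
        * np.exp(-((pos - truth.line_center) ** 2) / (2 * truth.line_sigma**2))
    )
    img = np.tile(ideal[:, None], (1, n_width))
    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, size=img.shape)
    white = 2**bit_depth - 1
    img = np.clip(np.rint(img), 0, white)
    if dark_line:
        img = white - img  # invert after quantising: exact polarity mirror
    pixels = img.astype(np.uint8 if bit_depth == 8 else np.uint16)
    if flow_axis == "columns":
        pixels = pixels.T
    strip = StripImage(
        pixels=pixels,
        flow_axis=flow_axis,
        expected_line_position=truth.line_center,
        condition_id=condition_id,
    )
    return strip, truth


def render_strip_file(
    truth: StripTruth, path: str | Path, **kwargs
) -> StripTruth:
    """Render a strip and write it as PNG/TIFF; returns the truth used."""
    strip, truth = render_strip(truth, **kwargs)
    iio.imwrite(Path(path), strip.pixels)
    return truth


# ---------------------------------------------------------------------------
# screen-level simulation


@dataclass(frozen=True)
class ScreenTruth:
    """Latent truth behind a synthetic antibody-pair screen.

    The condition mean for a pair (i, j) on an antigen-spiked matrix is::

        mu = blank_level + s_max * A / (k_half + A) * (1 - hook * A / (A + k_half))

    with ``A = capture_affinity[i] * detection_affinity[j] *
    epitope_compatibility[i, j]`` (cross-reactivity analogues for the second
    antigen).  Blank-matrix conditions sit at ``blank_level`` plus blank
    noise; spiked conditions add replicate noise around the shared mean.
    """

    capture_affinities: tuple[float, ...]
    detection_affinities: tuple[float, ...]
    epitope_compatibility: tuple[tuple[float, ...], ...] = ()
    capture_cross: tuple[float, ...] = ()
    detection_cross: tuple[float, ...] = ()
    cross_compatibility: tuple[tuple[float, ...], ...] = ()
    s_max: float = 20.0
    k_half: float = 1.0
    hook_coefficient: float = 0.0
    blank_level: float = 2.0
    blank_noise_sd: float = 0.2
    replicate_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.capture_affinities):
            raise ValueError("affinities must be >= 0")
        if any(a < 0 for a in self.detection_affinities):
            raise ValueError("affinities must be >= 0")
        if self.blank_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")

    def _compat(self, matrix_attr: str, i: int, j: int) -> float:
        m = getattr(self, matrix_attr)
        if not m:
            return 1.0
        return m[i][j]

    def pair_mean(self, i: int, j: int, antigen: str) -> float:
        """Noise-free condition mean for pair (i, j) on 'ag1', 'ag2' or 'blank'."""
        if antigen == "blank":
            return self.blank_level
        if antigen == "ag1":
            a = (
                self.capture_affinities[i]
                * self.detection_affinities[j]
                * self._compat("epitope_compatibility", i, j)
            )
        elif antigen == "ag2":
            cc = self.capture_cross or self.capture_affinities
            dc = self.detection_cross or self.detection_affinities
            a = cc[i] * dc[j] * self._compat("cross_compatibility", i, j)
        else:
            raise ValueError(f"unknown antigen {antigen!r}")
        sat = a / (self.k_half + a) if a > 0 else 0.0
        hook = 1.0 - self.hook_coefficient * sat
        return self.blank_level + self.s_max * sat * max(hook, 0.0)


def simulate_screen(
    design: DesignSpec,
    truth: ScreenTruth,
    capture_factor: str = "capture",
    detection_factor: str = "detection",
    matrix_factor: str = "matrix",
    blank_level_name: str = "blank",
    antigen_of_matrix: dict | None = None,
) -> pd.DataFrame:
    """Simulate a screening table over a factorial design.

    The design must carry capture, detection and matrix factors; the matrix
    factor needs a blank level.  Matrix levels map onto antigens via
    ``antigen_of_matrix`` (default: the blank level to ``"blank"``, any
    level containing ``"ag2"`` to ``"ag2"``, everything else to ``"ag1"``).
    Output schema matches the imaging results table plus the design
    columns, so downstream analytics cannot tell fixture from real data.
    """
    factors = {f.name: f for f in design.factors}
    for name in (capture_factor, detection_factor, matrix_factor):
        if name not in factors:
            raise ValueError(f"design lacks required factor {name!r}")
    cap_levels = list(factors[capture_factor].levels)
    det_levels = list(factors[detection_factor].levels)
    mat_levels = list(factors[matrix_factor].levels)
    if blank_level_name not in mat_levels:
        raise ValueError(f"matrix factor has no {blank_level_name!r} level")
    if antigen_of_matrix is None:
        antigen_of_matrix = {
            m: ("blank" if m == blank_level_name else ("ag2" if "ag2" in str(m) else "ag1"))
            for m in mat_levels
        }

    rng = np.random.default_rng(truth.seed)
    conditions = enumerate_conditions(design)
    rows = []
    for cond in conditions:
        amap = cond.assignment_map
        i = cap_levels.index(amap[capture_factor])
        j = det_levels.index(amap[detection_factor])
        antigen = antigen_of_matrix[amap[matrix_factor]]
        mu = truth.pair_mean(i, j, antigen)
        sd = truth.blank_noise_sd if antigen == "blank" else truth.replicate_noise_sd
        signal = mu + rng.normal(0.0, sd) if sd > 0 else mu
        row = {"condition_id": cond.condition_id}
        row.update(amap)
        row["replicate"] = cond.replicate_index
        row["signal"] = float(signal)
        rows.append(row)
    return pd.DataFrame(rows)


def planted_screen_truth(
    n_capture: int = 16,
    n_detection: int = 16,
    n_planted: int = 3,
    snr: float = 5.0,
    seed: int = 0,
    cross_reactive_pairs: Sequence[tuple[int, int]] = (),
) -> tuple[ScreenTruth, list[tuple[int, int]]]:
    """Construct a screen truth with ``n_planted`` strong selective pairs.

    Planted pairs are drawn without sharing a capture or detection antibody
    and get an epitope-compatibility boost that puts their mean
    blank-subtracted signal at ``snr * blank_level``; background pairs have
    weak random affinities well below that.  Optional
    ``cross_reactive_pairs`` additionally respond to the second antigen.
    Returns the truth and the planted pair index list.
    """
    rng = np.random.default_rng(seed)
    blank_level = 2.0
    target = snr * blank_level

    # background affinities: weak, so background pair products stay small
    cap = rng.uniform(0.05, 0.3, size=n_capture)
    det = rng.uniform(0.05, 0.3, size=n_detection)

    captures = rng.permutation(n_capture)[:n_planted]
    detections = rng.permutation(n_detection)[:n_planted]
    planted = list(zip(captures.tolist(), detections.tolist()))

    k_half = 1.0
    s_max = 2.0 * target  # planted pairs sit at half-saturation * 2 = target
    compat = np.ones((n_capture, n_detection))
    for i, j in planted:
        # affinity A with sat(A) = target / s_max = 0.5 -> A = k_half
        compat[i, j] = k_half / (cap[i] * det[j])

    cross_compat = np.zeros((n_capture, n_detection))
    for i, j in cross_reactive_pairs:
        cross_compat[i, j] = k_half / (cap[i] * det[j])

    truth = ScreenTruth(
        capture_affinities=tuple(cap),
        detection_affinities=tuple(det),
        epitope_compatibility=tuple(map(tuple, compat)),
        capture_cross=tuple(cap),
        detection_cross=tuple(det),
        cross_compatibility=tuple(map(tuple, cross_compat)),
        s_max=s_max,
        k_half=k_half,
        blank_level=blank_level,
        blank_noise_sd=0.2,
        replicate_noise_sd=0.2,
        seed=seed,
    )
    return truth, planted


# ---------------------------------------------------------------------------
# random but feasible scheduling cases


def random_schedule_case(seed: int, max_strips: int = 96):
    """Generate a random run + protocol that is feasible by construction.

    Used to exercise the scheduler and its simulator: strip count, step
    durations, inter-step delays and reagent structure are randomised, and
    the imaging target is placed far enough after the sample step that a
    single gantry can always meet the window.  Returns ``(run, protocol,
    sources, recipes, config, stock_levels)`` ready for
    :func:`lfadev.schedule.build_worklist`.
    """
    from .design import DeckLayout, DesignSpec, FactorSpec, split_into_runs
    from .mixplan import StockSolution, plan_mixture
    from .schedule import Protocol, ProtocolStep, RobotConfig

    rng = np.random.default_rng(seed)
    n_strips = int(rng.integers(4, max_strips + 1))
    n_det = int(rng.integers(1, 4))
    n_channels = int(rng.choice([4, 8]))

    factors = [
        FactorSpec("detection", tuple(f"D{i}" for i in range(n_det))),
        FactorSpec("strip", tuple(range(int(np.ceil(n_strips / n_det))))),
    ]
    design = DesignSpec(factors=tuple(factors))
    conditions = enumerate_conditions(design)[:n_strips]
    deck = DeckLayout(
        holders=(("H1", 96),), cassette_holders=frozenset({"H1"})
    )
    run = split_into_runs(conditions, deck)[0]

    use_mixture = bool(rng.integers(0, 2))
    stocks = [
        StockSolution("conj", {"conjugate": 200.0}, available_volume=1e6),
        StockSolution("sample", {}, available_volume=1e6),
    ]
    recipes = {}
    sources = {"sample": ("stocks", "sample")}
    if use_mixture:
        recipes["detmix"] = plan_mixture(
            {"conjugate": 50.0}, stocks, final_volume=2000.0, target_id="detmix"
        )
        reagent_ref = "detmix"
    else:
        sources["conj"] = ("stocks", "conj")
        reagent_ref = "conj"

    d_reagent = int(rng.integers(5, 21))
    d_sample = int(rng.integers(5, 21))
    # imaging a cohort (camera snapshot) is no slower than dispensing to it,
    # so imaging keeps pace with the sample cohort spacing
    d_image = int(rng.integers(3, d_sample + 1))
    delay = int(rng.integers(0, 181))
    n_batches = int(np.ceil(n_strips / n_channels))
    # imaging target: generous upper bound on the gantry work that can sit
    # between a strip's sample dispense and its image
    work = n_batches * (d_reagent + d_sample + d_image) + delay + 120
    target = int(work + rng.integers(0, 300))

    protocol = Protocol(
        name=f"random_{seed}",
        steps=(
            ProtocolStep(0, "dispense_reagent", reagent_ref=reagent_ref,
                         volume=float(rng.integers(5, 20)),
                         destination="conjugate_well", duration=d_reagent),
            ProtocolStep(1, "dispense_sample", reagent_ref="sample",
                         volume=float(rng.integers(20, 80)),
                         min_delay_after_previous=delay,
                         destination="sample_port", duration=d_sample),
            ProtocolStep(2, "image", target_time_after_sample=target,
                         duration=d_image),
        ),
        imaging_tolerance_s=60,
    )
    config = RobotConfig(n_channels=n_channels)
    stock_levels = {s.stock_id: s.available_volume for s in stocks}
    return run, protocol, sources, recipes, config, stock_levels
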
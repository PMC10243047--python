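"""Synthetic culture data with known ground truth.

Emulates the experimental structure of a 7-day stirred suspension run:

* exponential growth from 1e5 cells/ml sampled on days 0/3/5/7 with
  multiplicative (lognormal) counting noise,
* glucose/lactate profiles from the constant-specific-rate mass balance
  with 50 % medium replacement on days 1, 3 and 5 and additive Gaussian
  assay noise,
* micrographs of non-overlapping elliptical cells drawn from two
  axis-ratio populations (round: minor/major in 0.85-0.98; stretched:
  0.40-0.70) so the true round fraction is known exactly.  The bands
  deliberately exclude 0.75-0.85 so rasterization error cannot flip a
  cell's true class at the 0.8 roundness threshold.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64);
each operation draws from a generator created from the config seed, so a
fixed seed gives bit-identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hydrodynamics import InvalidInputError
from .kinetics import (
    CultureTimeSeries,
    ExchangeEvent,
    GrowthFit,
    predict_metabolite_profile,
)

__all__ = [
    "SimulationConfig",
    "CapacityError",
    "simulate_growth",
    "simulate_metabolites",
    "render_cell_image",
]


class CapacityError(RuntimeError):
    """Non-overlapping cell placement failed; advise a larger canvas."""


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the synthetic culture run.

    Defaults mirror the study conditions: seeding at 1e5 cells/ml,
    mu = 0.028 1/h (the low-shear condition), sampling on days 0/3/5/7,
    counting CV 0.1, 50 % medium exchanges on days 1/3/5 with fresh
    glucose at 2.0 g/l, and a glucose rate sized to consume about 60 % of
    the total glucose supplied over the week.
    """

    seed: int = 0
    # growth
    true_mu: float = 0.028  # 1/h
    true_cx0: float = 1.0e5  # cells/ml
    sampling_times: tuple[float, ...] = (0.0, 72.0, 120.0, 168.0)  # h
    count_noise_cv: float = 0.1  # lognormal sigma on the log scale
    # metabolites
    q_glucose: float = 3.1e-12  # g / (cell h), consumption magnitude
    q_lactate: float = 2.8e-12  # g / (cell h), production magnitude
    c_glc0: float = 2.0  # g/l
    c_lac0: float = 0.0  # g/l
    fresh_glc: float = 2.0  # g/l
    fresh_lac: float = 0.0  # g/l
    exchange_times: tuple[float, ...] = (24.0, 72.0, 120.0)  # h, days 1/3/5
    exchange_fraction: float = 0.5
    metabolite_noise_sd: float = 0.05  # g/l
    # image
    n_cells: int = 100
    round_fraction_true: float = 0.67
    round_axis_ratio: tuple[float, float] = (0.85, 0.98)
    stretched_axis_ratio: tuple[float, float] = (0.40, 0.70)
    cell_semi_major_px: tuple[float, float] = (12.0, 18.0)
    image_shape: tuple[int, int] = (1024, 1024)
    background_intensity: float = 30.0
    foreground_intensity: float = 200.0
    image_noise_sd: float = 6.0
    max_place_attempts: int = 20000

    def __post_init__(self) -> None:
        if not np.isfinite([self.true_mu, self.q_glucose, self.q_lactate]).all():
            raise InvalidInputError("rates must be finite")
        if not 0.0 <= self.round_fraction_true <= 1.0:
            raise InvalidInputError("round_fraction_true must be in [0, 1]")
        if not 0.0 <= self.exchange_fraction <= 1.0:
            raise InvalidInputError("exchange_fraction must be in [0, 1]")
        for lo, hi in (self.round_axis_ratio, self.stretched_axis_ratio):
            if not 0 < lo <= hi <= 1:
                raise InvalidInputError("axis-ratio bands must lie in (0, 1]")
            if lo < 0.85 and hi > 0.75:
                raise InvalidInputError(
                    "axis-ratio bands must exclude the 0.75-0.85 boundary band"
                )

    def exchange_events(self) -> tuple[ExchangeEvent, ...]:
        return tuple(
            ExchangeEvent(
                time=t,
                fraction=self.exchange_fraction,
                fresh={"glucose": self.fresh_glc, "lactate": self.fresh_lac},
            )
            for t in self.exchange_times
        )

    def rng(self, stream: int = 0) -> np.random.Generator:
        # independent, reproducible streams per operation
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


def simulate_growth(config: SimulationConfig) -> CultureTimeSeries:
    """Exponential growth with lognormal counting noise.

    ``C_x(t_i) = C_x0 exp(mu t_i) exp(eps_i)`` with
    ``eps_i ~ Normal(0, cv^2)`` on the log scale; ``cv = 0`` gives the
    exact exponential.
    """
    rng = config.rng(0)
    t = np.asarray(config.sampling_times, dtype=float)
    clean = config.true_cx0 * np.exp(config.true_mu * t)
    noise = rng.normal(0.0, config.count_noise_cv, size=t.shape) if config.count_noise_cv > 0 else 0.0
    return CultureTimeSeries(
        times=t,
        viable_density=clean * np.exp(noise),
        exchange_events=config.exchange_events(),
    )


def simulate_metabolites(
    config: SimulationConfig, series: Optional[CultureTimeSeries] = None
) -> CultureTimeSeries:
    """Add glucose/lactate profiles to a growth series.

    Concentrations follow the closed-form mass-balance profile for the
    *true* growth parameters, with baseline resets at each exchange,
    additive Gaussian noise, and flooring at zero.  Samples at exchange
    times are pre-exchange values.
    """
    if series is None:
        series = simulate_growth(config)
    rng = config.rng(1)
    truth = GrowthFit(mu=config.true_mu, initial_density=config.true_cx0, r_squared=1.0)
    events = config.exchange_events()
    mets = {}
    for name, q, c0, direction in (
        ("glucose", config.q_glucose, config.c_glc0, "consumption"),
        ("lactate", config.q_lactate, config.c_lac0, "production"),
    ):
        clean = predict_metabolite_profile(
            truth, q, c0, series.times,
            direction=direction, exchange_events=events, metabolite=name,
        )
        noisy = clean + (
            rng.normal(0.0, config.metabolite_noise_sd, size=clean.shape)
            if config.metabolite_noise_sd > 0 else 0.0
        )
        mets[name] = np.maximum(noisy, 0.0)
    return replace(series, metabolites=mets, exchange_events=events)


def _draw_axis_ratios(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_round = int(round(config.n_cells * config.round_fraction_true))
    ratios = np.empty(config.n_cells)
    is_round = np.zeros(config.n_cells, dtype=bool)
    is_round[:n_round] = True
    ratios[:n_round] = rng.uniform(*config.round_axis_ratio, size=n_round)
    ratios[n_round:] = rng.uniform(*config.stretched_axis_ratio, size=config.n_cells - n_round)
    perm = rng.permutation(config.n_cells)
    return ratios[perm], is_round[perm]


def render_cell_image(config: SimulationConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping bright ellipses on a noisy dark background.

    Exactly ``round(n_cells * round_fraction_true)`` cells are drawn from
    the round axis-ratio band.  Returns the image (uint8) and a
    ground-truth table with one row per cell: center, semi-axes,
    orientation angle and true class.  Placement uses rejection sampling
    on bounding circles; persistent failure raises :class:`CapacityError`.
    """
    rng = config.rng(2)
    h, w = config.image_shape
    ratios, is_round = _draw_axis_ratios(config, rng)
    semi_major = rng.uniform(*config.cell_semi_major_px, size=config.n_cells)
    angles = rng.uniform(0.0, np.pi, size=config.n_cells)

    margin = 3.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    for i in range(config.n_cells):
        r_bound = semi_major[i] + margin
        while True:
            attempts += 1
            if attempts > config.max_place_attempts:
                raise CapacityError(
                    f"could not place {config.n_cells} non-overlapping cells on a "
                    f"{h}x{w} canvas after {config.max_place_attempts} attempts; "
                    "use a larger canvas or fewer cells"
                )
            cy = rng.uniform(r_bound + 1, h - r_bound - 1)
            cx = rng.uniform(r_bound + 1, w - r_bound - 1)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r_bound + orad) ** 2
                for (oy, ox), orad in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append(r_bound)
                break

    img = np.full((h, w), config.background_intensity, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), a, ratio, theta in zip(centers, semi_major, ratios, angles):
        b = a * ratio
        ct, st = np.cos(theta), np.sin(theta)
        # evaluate the ellipse only inside its bounding box
        y0, y1 = int(cy - a - 2), int(cy + a + 3)
        x0, x1 = int(cx - a - 2), int(cx + a + 3)
        ys = yy[y0:y1, x0:x1] - cy
        xs = xx[y0:y1, x0:x1] - cx
        u = ct * xs + st * ys
        v = -st * xs + ct * ys
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        img[y0:y1, x0:x1][inside] = config.foreground_intensity

    if config.image_noise_sd > 0:
        img = img + rng.normal(0.0, config.image_noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "center_row": [c[0] for c in centers],
            "center_col": [c[1] for c in centers],
            "semi_major_px": semi_major,
            "semi_minor_px": semi_major * ratios,
            "axis_ratio": ratios,
            "angle_rad": angles,
            "is_round": is_round,
        }
    )
    return img, truth
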
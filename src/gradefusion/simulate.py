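"""Synthetic e-nose recordings and product images for grading experiments.

No public dataset of cardamom e-nose traces or grade images exists, so this
module fabricates data with the statistical structure the downstream
analysis assumes:

* **E-nose**: nine metal-oxide gas sensors sampled at 1 Hz through three
  phases — clean-air baseline (200 s), headspace injection (40 s), recovery
  (60 s). During injection each sensor's fractional response rises as a
  saturating exponential towards a grade-dependent amplitude; during
  recovery it decays exponentially back towards baseline. Higher-quality
  grades carry more aroma, so the amplitude matrix is grade-ordered
  (Grade1 > Grade2 > Grade3 for every sensor at the defaults).
* **Images**: a white-ish background densely covered by ellipse primitives
  (capsules or seeds) whose fill colors are drawn around a per-grade base
  CIELAB color, with per-grade primitive sizes so that both channel moments
  and co-occurrence texture differ between grades. The central 400×400
  block — the only region the feature extractor sees — is fully covered by
  primitives, never background.

All randomness flows through an explicit :class:`numpy.random.Generator`;
the same configuration and seed reproduce the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import lab2rgb
from skimage.draw import ellipse as draw_ellipse
from skimage.filters import gaussian

from .tables import GRADES

#: The nine MOS sensors of the reference instrument.
SENSOR_NAMES = (
    "MQ2", "MQ4", "MQ6", "MQ7", "MQ9",
    "TGS813", "TGS822", "TGS2610", "TGS2611",
)

# Per-sensor fractional response at full aroma strength (Grade1), and the
# multiplicative attenuation of lower grades. Values are dimensionless
# fractions of the baseline voltage.
_BASE_AMPLITUDES = np.array(
    [1.20, 0.95, 1.05, 0.70, 0.80, 1.10, 0.90, 0.65, 0.85]
)
_GRADE_FACTORS = np.array([1.00, 0.70, 0.45])

_DEFAULT_RISE_TAU = np.array([10.0, 14.0, 12.0, 18.0, 16.0, 11.0, 13.0, 20.0, 15.0])
_DEFAULT_FALL_TAU = np.array([20.0, 25.0, 22.0, 30.0, 28.0, 21.0, 24.0, 32.0, 26.0])

# Per-grade base colors in CIELAB (L, a, b) and primitive radii in pixels.
# Capsules: green / yellow / pale shriveled. Seeds: black / brown / yellow-red.
_DEFAULT_PALETTES = {
    "capsule": {
        "Grade1": (55.0, -35.0, 40.0),
        "Grade2": (75.0, -5.0, 60.0),
        "Grade3": (62.0, 8.0, 32.0),
    },
    "seed": {
        "Grade1": (20.0, 2.0, 5.0),
        "Grade2": (35.0, 15.0, 25.0),
        "Grade3": (55.0, 25.0, 45.0),
    },
}
_DEFAULT_TEXTURE_SCALE = {
    "capsule": {"Grade1": 26.0, "Grade2": 20.0, "Grade3": 12.0},
    "seed": {"Grade1": 14.0, "Grade2": 10.0, "Grade3": 7.0},
}


def _default_amplitudes() -> np.ndarray:
    return np.outer(_BASE_AMPLITUDES, _GRADE_FACTORS)


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic world.

    The defaults state the emulated study design: 9 sensors, 15 samples per
    grade, 1 Hz sampling over 200/40/60 s phases, grade-ordered response
    amplitudes, and grade-distinct color palettes and primitive sizes.
    """

    n_sensors: int = 9
    n_samples_per_grade: int = 15
    sample_rate: float = 1.0
    phase_durations: tuple[float, float, float] = (200.0, 40.0, 60.0)
    amplitude_matrix: np.ndarray = field(default_factory=_default_amplitudes)
    rise_tau: np.ndarray = field(default_factory=lambda: _DEFAULT_RISE_TAU.copy())
    fall_tau: np.ndarray = field(default_factory=lambda: _DEFAULT_FALL_TAU.copy())
    baseline_voltage: np.ndarray = field(default_factory=lambda: np.ones(9))
    noise_sd: float = 0.01
    image_size: tuple[int, int] = (512, 512)
    grade_palettes: dict = field(
        default_factory=lambda: {p: dict(g) for p, g in _DEFAULT_PALETTES.items()}
    )
    color_jitter_sd: float = 3.0
    texture_scale: dict = field(
        default_factory=lambda: {p: dict(g) for p, g in _DEFAULT_TEXTURE_SCALE.items()}
    )
    product: str = "capsule"
    seed: int = 0

    def __post_init__(self) -> None:
        self.amplitude_matrix = np.asarray(self.amplitude_matrix, dtype=float)
        self.rise_tau = np.atleast_1d(np.asarray(self.rise_tau, dtype=float))
        self.fall_tau = np.atleast_1d(np.asarray(self.fall_tau, dtype=float))
        self.baseline_voltage = np.atleast_1d(
            np.asarray(self.baseline_voltage, dtype=float)
        )
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if np.any(self.amplitude_matrix < 0):
            raise ValueError("amplitude_matrix must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.amplitude_matrix.shape != (self.n_sensors, 3):
            raise ValueError(
                f"amplitude_matrix must be {self.n_sensors}×3, got "
                f"{self.amplitude_matrix.shape}"
            )
        for name, arr in (("rise_tau", self.rise_tau),
                          ("fall_tau", self.fall_tau),
                          ("baseline_voltage", self.baseline_voltage)):
            if arr.size == 1:
                arr = np.full(self.n_sensors, arr.item())
                setattr(self, name, arr)
            if arr.size != self.n_sensors:
                raise ValueError(f"{name} must have {self.n_sensors} entries")
        if np.any(self.rise_tau <= 0) or np.any(self.fall_tau <= 0):
            raise ValueError("time constants must be positive")
        if np.any(self.baseline_voltage <= 0):
            raise ValueError("baseline voltages must be positive")
        if min(self.image_size) < 400:
            raise ValueError("image_size must be at least 400×400")
        if self.product not in ("capsule", "seed"):
            raise ValueError(f"unknown product {self.product!r}")

    @property
    def sensor_names(self) -> tuple[str, ...]:
        if self.n_sensors == len(SENSOR_NAMES):
            return SENSOR_NAMES
        return tuple(f"S{i + 1}" for i in range(self.n_sensors))

    @property
    def phase_boundaries(self) -> tuple[float, float, float]:
        b, i, r = self.phase_durations
        return (b, b + i, b + i + r)

    def times(self) -> np.ndarray:
        total = sum(self.phase_durations)
        n = int(round(total * self.sample_rate))
        return np.arange(n) / self.sample_rate


@dataclass
class EnoseRecording:
    """Per-sensor voltage time series with phase boundaries."""

    times: np.ndarray
    voltages: np.ndarray  # sensors × timepoints, volts
    sensor_names: tuple[str, ...]
    phase_boundaries: tuple[float, float, float]
    grade: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape != (len(self.sensor_names), len(self.times)):
            raise ValueError(
                f"voltages shape {self.voltages.shape} does not match "
                f"{len(self.sensor_names)} sensors × {len(self.times)} timepoints"
            )
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if np.any(self.voltages <= 0):
            raise ValueError("voltages must be strictly positive")


@dataclass
class ImageSample:
    """An RGB product image with its grade label."""

    pixels: np.ndarray  # H×W×3 in [0,1]
    grade: str
    product: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H×W×3")
        if min(self.pixels.shape[:2]) < 400:
            raise ValueError("image must be at least 400×400")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")


def _grade_index(grade: str) -> int:
    try:
        return GRADES.index(grade)
    except ValueError:
        raise ValueError(
            f"unknown grade {grade!r}; expected one of {GRADES}"
        ) from None


def latent_response(config: SyntheticConfig, grade: str) -> np.ndarray:
    """Noise-free fractional response y[s, t] of every sensor.

    Zero on the baseline phase, saturating exponential rise
    ``A·(1 − exp(−(t − t_inj)/rise_tau))`` during injection, and exponential
    decay from the injection-end value with ``fall_tau`` during recovery.
    """
    g = _grade_index(grade)
    t = config.times()
    t_inj, t_rec, _ = config.phase_boundaries
    amp = config.amplitude_matrix[:, g][:, None]
    rise = config.rise_tau[:, None]
    fall = config.fall_tau[:, None]

    y = np.zeros((config.n_sensors, t.size))
    inj = (t > t_inj) & (t <= t_rec)
    rec = t > t_rec
    y[:, inj] = amp * (1.0 - np.exp(-(t[inj] - t_inj) / rise))
    y_end = amp * (1.0 - np.exp(-(t_rec - t_inj) / rise))
    y[:, rec] = y_end * np.exp(-(t[rec] - t_rec) / fall)
    return y


def simulate_enose_recording(
    config: SyntheticConfig, grade: str, rng: np.random.Generator | None = None
) -> EnoseRecording:
    """Simulate one three-phase e-nose recording for the given grade.

    ``V[s,t] = V0[s]·(1 + y[s,t]) + ε`` with ``ε ~ N(0, noise_sd·V0[s])``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    y = latent_response(config, grade)
    v0 = config.baseline_voltage[:, None]
    noise = rng.normal(0.0, 1.0, size=y.shape) * (config.noise_sd * v0)
    volts = v0 * (1.0 + y) + noise
    # MOS sensor output stays physically positive; the floor only matters at
    # noise levels far beyond the instrument's.
    volts = np.maximum(volts, 1e-6)
    return EnoseRecording(
        times=config.times(),
        voltages=volts,
        sensor_names=config.sensor_names,
        phase_boundaries=config.phase_boundaries,
        grade=grade,
    )


def _primitive_colors(
    base_lab: tuple[float, float, float], n: int, jitter_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n primitive fill colors around a base Lab color, as RGB rows."""
    lab = np.tile(np.asarray(base_lab, dtype=float), (n, 1))
    if jitter_sd > 0:
        jit = rng.normal(0.0, jitter_sd, size=(n, 3))
        jit[:, 1:] *= 0.6  # chroma varies less than lightness
        lab = lab + jit
    rgb = lab2rgb(lab[None, :, :])[0]
    return np.clip(rgb, 0.0, 1.0)


def simulate_image(
    config: SyntheticConfig, grade: str, rng: np.random.Generator | None = None
) -> ImageSample:
    """Render one synthetic product image for the given grade.

    Ellipse primitives are laid on a jittered grid dense enough that the
    central 400×400 crop is fully covered, then lightly smoothed. The
    per-grade primitive radius (``texture_scale``) and color jitter shape
    the co-occurrence texture; the palette shapes the channel moments.
    """
    _grade_index(grade)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    palette = config.grade_palettes[config.product]
    if grade not in palette:
        raise ValueError(f"no palette for grade {grade!r}")
    base_lab = palette[grade]
    radius = float(config.texture_scale[config.product][grade])

    img = np.full((h, w, 3), 0.96)
    # grid step chosen so a worst-case rotated ellipse still covers its cell
    step = 0.85 * radius
    rows = np.arange(-radius, h + radius, step)
    cols = np.arange(-radius, w + radius, step)
    centers = np.stack(np.meshgrid(rows, cols, indexing="ij"), -1).reshape(-1, 2)
    order = rng.permutation(len(centers))
    centers = centers[order]
    centers = centers + rng.uniform(-0.25 * radius, 0.25 * radius,
                                    size=centers.shape)
    axes = rng.uniform(1.0 * radius, 1.5 * radius, size=(len(centers), 2))
    angles = rng.uniform(0.0, np.pi, size=len(centers))
    colors = _primitive_colors(base_lab, len(centers), config.color_jitter_sd,
                               rng)
    for (cy, cx), (a, b), theta, color in zip(centers, axes, angles, colors):
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        img[rr, cc] = color
    img = gaussian(img, sigma=1.0, channel_axis=-1)
    return ImageSample(pixels=np.clip(img, 0.0, 1.0), grade=grade,
                       product=config.product)


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[list[EnoseRecording], list[ImageSample], list[str]]:
    """Generate the full paired dataset: recordings, images and labels.

    Samples are ordered Grade1 × n, Grade2 × n, Grade3 × n and the i-th
    recording and i-th image describe the same physical sample.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[EnoseRecording] = []
    images: list[ImageSample] = []
    labels: list[str] = []
    for grade in GRADES:
        for _ in range(config.n_samples_per_grade):
            recordings.append(simulate_enose_recording(config, grade, rng))
            images.append(simulate_image(config, grade, rng))
            labels.append(grade)
    return recordings, images, labels
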
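"""Synthetic flour-like NIR spectra with known ground truth.

Real flour spectra in the 900-1700 nm window are dominated by broad
overtone/combination bands of X-H stretching: near 930 nm (third O-H
overtone plus C-H combinations in carbohydrates), 1200 nm (second C-H
overtone) and 1460 nm (first O-H overtone of water). The generator emulates
this structure with Gaussian bands whose per-sample amplitudes are latent
"concentrations"; the quality target (sedimentation-value-like or
falling-number-like) is a known recipe of those concentrations plus noise.
Because the generating weights and band positions are known, wavelength
selectors and calibration models can be scored against planted truth.

Presets:

* ``"sv_like"`` — target rescaled to mean 29.0, SD 6.4 (sedimentation
  value, mL) with the default broad bands (sigma 40-55 nm).
* ``"fn_like"`` — target mean 334, SD 38 (falling number, s).
* ``"localized"`` — six narrow bands (sigma 5 nm) so the informative signal
  is confined to a few grid steps around each center; used for
  wavelength-localization (planted-band recovery) experiments, where broad
  bands would make the "true" wavelength intrinsically ambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraSet

__all__ = ["Band", "SyntheticConfig", "SyntheticTruth", "generate", "make_validation_pair"]


@dataclass(frozen=True)
class Band:
    center_nm: float
    width_nm: float  # Gaussian sigma
    amplitude: float


DEFAULT_BANDS = (
    Band(930.0, 45.0, 1.0),
    Band(1200.0, 40.0, 0.8),
    Band(1460.0, 55.0, 1.2),
)


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``target_weights`` are the linear recipe coefficients on the per-band
    concentrations (a band is informative iff its weight is nonzero);
    ``quadratic_weight`` optionally adds a mild nonlinearity on the first
    component. ``noise_sd`` is additive spectral noise in absorbance units;
    ``target_noise_sd`` is on the standardized target scale.
    ``target_mean`` / ``target_sd`` place the reference values on a
    realistic scale (mL or s); with ``target_sd=None`` the raw recipe value
    is returned unscaled (plus absolute noise), so a single unit-weight
    component with zero noise reproduces its concentration exactly.
    """

    n_samples: int = 200
    grid_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(900.0, 1700.0, 360)
    )
    bands: tuple[Band, ...] = DEFAULT_BANDS
    target_weights: tuple[float, ...] = (1.0, -0.7, 0.5)
    quadratic_weight: float = 0.0
    conc_low: float = 0.5
    conc_high: float = 1.5
    noise_sd: float = 0.002
    target_noise_sd: float = 0.1
    drift_amplitude: float = 0.05
    target_mean: float = 29.0
    target_sd: float | None = 6.4
    target_label: str = "SV"
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_nm = np.asarray(self.grid_nm, dtype=float).ravel()
        if self.grid_nm.size < 2 or np.any(np.diff(self.grid_nm) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        lo, hi = self.grid_nm[0], self.grid_nm[-1]
        for b in self.bands:
            if not lo <= b.center_nm <= hi:
                raise ValueError(f"band center {b.center_nm} outside grid span")
        if len(self.target_weights) != len(self.bands):
            raise ValueError("one target weight per band required")
        if self.noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.conc_low <= 0 or self.conc_high <= self.conc_low:
            raise ValueError("concentration range must be positive and nonempty")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SyntheticConfig":
        if name == "sv_like":
            base = dict(target_mean=29.0, target_sd=6.4, target_label="SV")
        elif name == "fn_like":
            base = dict(target_mean=334.0, target_sd=38.0, target_label="FN")
        elif name == "localized":
            # Narrow bands so the informative signal is confined to a few
            # grid steps, and six of them: wrapper selectors and SPA keep at
            # most ~one column per latent band (extra in-band columns are
            # redundant), so a k-wavelength recovery experiment is only
            # well-posed when at least k distinct bands are planted.
            base = dict(
                bands=tuple(
                    Band(c, 5.0, 1.0)
                    for c in (930.0, 1060.0, 1200.0, 1330.0, 1460.0, 1600.0)
                ),
                target_weights=(1.0, -0.8, 0.7, -0.6, 0.9, 0.5),
                drift_amplitude=0.0,
                target_mean=29.0,
                target_sd=6.4,
                target_label="SV",
            )
        else:
            raise ValueError(f"unknown preset {name!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated set: the planted informative
    grid indices (within 3 grid steps of each nonzero-weight band center),
    the latent concentrations and the generating weights."""

    planted_indices: np.ndarray
    band_center_indices: np.ndarray
    concentrations: np.ndarray
    target_weights: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_indices": self.planted_indices.tolist(),
                "band_center_indices": self.band_center_indices.tolist(),
                "target_weights": self.target_weights.tolist(),
            }
        )


def generate(config: SyntheticConfig) -> tuple[SpectraSet, SyntheticTruth]:
    """Draw a seeded synthetic spectra set with reference values.

    absorbance(lambda) = sum_j conc_j * amp_j * exp(-(lambda-c_j)^2 / 2w_j^2)
    + drift * (nonnegative quadratic baseline) + N(0, noise_sd); the target
    is the weight recipe on the concentrations (optionally plus a quadratic
    term), standardized, noised, and rescaled to (target_mean, target_sd).
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid_nm
    n, p = config.n_samples, grid.size
    n_bands = len(config.bands)

    conc = rng.uniform(config.conc_low, config.conc_high, size=(n, n_bands))
    shapes = np.stack(
        [
            b.amplitude * np.exp(-0.5 * ((grid - b.center_nm) / b.width_nm) ** 2)
            for b in config.bands
        ]
    )  # (n_bands, p)
    spectra = conc @ shapes

    if config.drift_amplitude > 0:
        x = (grid - grid[0]) / (grid[-1] - grid[0])
        coeffs = rng.uniform(0.0, 1.0, size=(n, 3))
        spectra += config.drift_amplitude * (
            coeffs[:, [0]] + coeffs[:, [1]] * x + coeffs[:, [2]] * x**2
        )
    if config.noise_sd > 0:
        spectra += rng.normal(0.0, config.noise_sd, size=(n, p))
        spectra = np.maximum(spectra, 0.0)

    w = np.asarray(config.target_weights, dtype=float)
    raw = conc @ w
    if config.quadratic_weight:
        raw = raw + config.quadratic_weight * conc[:, 0] ** 2
    if config.target_sd is None:
        target = raw.copy()
        if config.target_noise_sd > 0:
            target = target + rng.normal(0.0, config.target_noise_sd, size=n)
    else:
        sd = raw.std(ddof=0)
        z = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
        if config.target_noise_sd > 0:
            z = z + rng.normal(0.0, config.target_noise_sd, size=n)
        target = config.target_mean + config.target_sd * z

    centers = np.array(
        [int(np.argmin(np.abs(grid - b.center_nm))) for b in config.bands]
    )
    informative = centers[w != 0]
    planted = np.unique(
        np.concatenate(
            [np.arange(max(0, c - 3), min(p, c + 4)) for c in informative]
        )
        if informative.size
        else np.empty(0, dtype=int)
    )

    spectra_set = SpectraSet(
        wavelengths_nm=grid.copy(),
        absorbance=spectra,
        sample_ids=[f"syn{i:04d}" for i in range(n)],
        reference=target,
        reference_label=config.target_label,
    )
    truth = SyntheticTruth(
        planted_indices=planted,
        band_center_indices=centers,
        concentrations=conc,
        target_weights=w,
    )
    return spectra_set, truth


def make_validation_pair(
    n: int = 50,
    bias: float = 0.0,
    extra_sd: float = 0.0,
    mean: float = 29.0,
    sd: float = 6.4,
    seed: int = 0,
    null_mode: str = "additive",
) -> tuple[np.ndarray, np.ndarray]:
    """Matched (measured, predicted) vectors for exercising the two-sample
    report.

    ``null_mode="additive"`` (default, mimics a real prediction error):
    predicted = measured + N(bias, extra_sd). Note the additive mode
    inflates the predicted-group variance, so it is *not* a null for the
    variance-ratio F-test. ``null_mode="independent"`` draws the predicted
    group independently with the same variance (plus bias), which is the
    exact F-test null used by the type-I-error simulation.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    measured = rng.normal(mean, sd, size=n)
    if null_mode == "additive":
        predicted = measured + (
            rng.normal(bias, extra_sd, size=n) if extra_sd > 0 else bias
        )
    elif null_mode == "independent":
        predicted = rng.normal(mean + bias, sd, size=n)
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")
    return measured, predicted
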
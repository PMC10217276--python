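"""Synthetic Lambert-Beer absorbance spectra with a graded SSC population.

The generator emulates the statistical structure a visible-range SSC
calibration assumes: absorbance proportional to soluble solid content in a
fixed optical path, with Gaussian absorption bands near the characteristic
carbohydrate wavelengths (461, 469, 750 nm), corrupted by additive noise,
per-sample baseline offset and multiplicative scatter — the defects the
pretreatment operators exist to remove.

Model per sample i at wavelength lam:

    A_i(lam) = s_i * [l * SSC_i * eps(lam) + b_i] + e_i(lam)

with SSC_i ~ Normal(ssc_mean, ssc_sd) truncated to [8, 18), baseline
b_i ~ Normal(0, baseline_sd), scatter s_i ~ Normal(1, scatter_sd), noise
e ~ Normal(0, noise_sd) i.i.d., and eps(lam) a mixture of Gaussian bands.
The multiplicative scatter acts on signal plus baseline (classic
scatter-correction target). The SSC population defaults reproduce grade
proportions of roughly 22/71/7 per 100 under the default grading scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import DEFAULT_WAVELENGTHS, GradeScheme, SpectrumSet

__all__ = ["SyntheticConfig", "generate", "make_fixture", "epsilon"]

_TRUNC_LO, _TRUNC_HI = 8.0, 18.0
_MAX_REJECTION_ROUNDS = 1000


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic spectra population.

    ``ssc_mean``/``ssc_sd`` (°Brix) default to 12.63 / 1.78, which place 22%
    of the (untruncated) population at or above 14 °Brix and 7% below
    10 °Brix — the 22/71/7 grade proportions of a realistic orchard cohort.
    Band strengths are absorbance per °Brix per unit path; defaults put peak
    absorbance near 1 for mid-grade fruit.
    """

    n_samples: int = 100
    ssc_mean: float = 12.63
    ssc_sd: float = 1.78
    band_centers: tuple[float, ...] = (461.0, 469.0, 750.0)
    band_widths: tuple[float, ...] = (30.0, 30.0, 30.0)
    band_strengths: tuple[float, ...] = (0.04, 0.04, 0.025)
    path_length: float = 1.0
    baseline_sd: float = 0.0
    scatter_sd: float = 0.0
    noise_sd: float = 0.0
    # smooth per-sample baseline drift (stray light / wavelength-dependent
    # scattering): a random curve with the given pointwise sd and
    # correlation length; 0 disables it and leaves the pure flat-baseline
    # Lambert-Beer model
    drift_sd: float = 0.0
    drift_length_nm: float = 100.0
    seed: int = 0
    wavelengths: np.ndarray = field(
        default_factory=lambda: DEFAULT_WAVELENGTHS.copy()
    )

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("ssc_sd", "baseline_sd", "scatter_sd", "noise_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (
            len(self.band_centers) == len(self.band_widths) == len(self.band_strengths)
        ):
            raise ValueError("band centers/widths/strengths must have equal length")
        w = np.asarray(self.wavelengths, dtype=float)
        for c in self.band_centers:
            if not (w[0] <= c <= w[-1]):
                raise ValueError(f"band center {c} nm outside the wavelength grid")


def epsilon(wavelengths: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Molar-absorptivity surrogate: sum of Gaussian bands, per °Brix."""
    lam = np.asarray(wavelengths, dtype=float)
    eps = np.zeros_like(lam)
    for c, w, s in zip(config.band_centers, config.band_widths, config.band_strengths):
        eps += s * np.exp(-0.5 * ((lam - c) / w) ** 2)
    return eps


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) truncated to [8, 18)."""
    if sd == 0:
        if not (_TRUNC_LO <= mean < _TRUNC_HI):
            raise ValueError(
                f"degenerate SSC population (mean={mean}, sd={sd}) lies outside "
                f"[{_TRUNC_LO}, {_TRUNC_HI})"
            )
        return np.full(n, mean)
    out = np.empty(0)
    for _ in range(_MAX_REJECTION_ROUNDS):
        draw = rng.normal(mean, sd, size=2 * n)
        keep = draw[(draw >= _TRUNC_LO) & (draw < _TRUNC_HI)]
        out = np.concatenate([out, keep])
        if out.size >= n:
            return out[:n]
    raise ValueError(
        f"SSC truncation to [{_TRUNC_LO}, {_TRUNC_HI}) rejected nearly all draws "
        f"(mean={mean}, sd={sd}); population infeasible"
    )


def _smooth_drift(
    rng: np.random.Generator,
    lam: np.ndarray,
    config: SyntheticConfig,
    n: int,
) -> np.ndarray:
    """Per-sample smooth random baseline curves.

    White noise convolved with a Gaussian kernel of the configured
    correlation length, rescaled so each point has sd ``drift_sd``. Unlike a
    flat offset, these curves span many directions and overlap the
    absorption-band shapes, which is what makes them a genuine challenge for
    raw-spectra models and a target for derivative pretreatment.
    """
    step = lam[1] - lam[0]
    half = int(np.ceil(3 * config.drift_length_nm / step))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) * step / config.drift_length_nm) ** 2)
    white = rng.normal(size=(n, lam.size + 2 * half))
    smooth = np.array([np.convolve(w, kernel, mode="valid") for w in white])
    smooth /= np.sqrt(np.sum(kernel**2))  # unit pointwise sd
    return config.drift_sd * smooth


def generate(config: SyntheticConfig) -> SpectrumSet:
    """Draw a SpectrumSet from the Lambert-Beer generative model.

    Deterministic for a fixed config (seed included). With all corruption
    terms at zero every wavelength column is an exact affine (here linear)
    function of SSC.
    """
    rng = np.random.default_rng(config.seed)
    lam = np.asarray(config.wavelengths, dtype=float)
    eps = epsilon(lam, config)
    ssc = _truncated_normal(rng, config.ssc_mean, config.ssc_sd, config.n_samples)
    baseline = (
        rng.normal(0.0, config.baseline_sd, config.n_samples)
        if config.baseline_sd > 0
        else np.zeros(config.n_samples)
    )
    scatter = (
        rng.normal(1.0, config.scatter_sd, config.n_samples)
        if config.scatter_sd > 0
        else np.ones(config.n_samples)
    )
    signal = config.path_length * ssc[:, None] * eps[None, :] + baseline[:, None]
    if config.drift_sd > 0:
        signal = signal + _smooth_drift(rng, lam, config, config.n_samples)
    absorbance = scatter[:, None] * signal
    if config.noise_sd > 0:
        absorbance = absorbance + rng.normal(
            0.0, config.noise_sd, absorbance.shape
        )
    ids = [f"synth-{i:04d}" for i in range(config.n_samples)]
    return SpectrumSet(lam, absorbance, ids, ssc=ssc, scheme=GradeScheme())


_FIXTURES = {
    # small deterministic sets for tests and docs
    "clean": dict(noise_sd=0.0, baseline_sd=0.0, scatter_sd=0.0),
    "noisy": dict(noise_sd=0.01, baseline_sd=0.0, scatter_sd=0.0),
    # smooth baseline drift dominates so raw spectra are genuinely corrupted
    # while derivative-based pretreatment still recovers the band signal
    "scattered": dict(
        noise_sd=0.002, baseline_sd=0.05, scatter_sd=0.05,
        drift_sd=0.1, drift_length_nm=100.0,
    ),
}


def make_fixture(kind: str, seed: int = 0, n_samples: int = 40) -> SpectrumSet:
    """Canned small (n <= 40) configurations: "clean", "noisy", "scattered".

    Fixtures use a wider SSC population (mean 12.5, sd 2.5 °Brix) than the
    default cohort so that all three grades are populated well enough to
    stratify and oversample even at n = 40.
    """
    if kind not in _FIXTURES:
        raise ValueError(
            f"unknown fixture kind {kind!r}; valid kinds: {sorted(_FIXTURES)}"
        )
    cfg = SyntheticConfig(
        n_samples=min(n_samples, 40), seed=seed, ssc_mean=12.5, ssc_sd=2.5,
        **_FIXTURES[kind],
    )
    return generate(cfg)
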
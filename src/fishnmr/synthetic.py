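"""Synthetic CPMG cohorts with linked texture references.

Emulates a low-field NMR relaxometry experiment on muscle tissue: each
sample is a three-pool multi-exponential transverse-relaxation decay

    M(t) = sum_n M0_n * exp(-t / T2_n) + e(t)

sampled on a CPMG echo train (echo k at t_k = 2*tau*k), plus a texture
profile (hardness, resilience, springiness, chewiness, gumminess,
adhesiveness) generated from the sample's pool parameters through a fixed
linear linkage, so that the decay curves and the texture references carry
the strong mutual association the downstream PLS calibration assumes.

Default acquisition: half-echo spacing tau = 200 us and 8000 echoes, the
settings of a typical benchtop CPMG measurement of muscle; the first
sampled echo then falls at 0.4 ms and the train extends to 3.2 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "RelaxComponent",
    "DecayCurve",
    "TreatmentProfile",
    "TextureRecord",
    "SampleSet",
    "simulate_cpmg_decay",
    "texture_from_pools",
    "generate_cohort",
    "POOL_WINDOWS_MS",
]

#: (lower, upper) apex windows in ms for the bound, immobilized and free pools.
POOL_WINDOWS_MS = ((0.1, 10.0), (10.0, 200.0), (200.0, 1000.0))

#: Default instrument noise SD (signal units) for cohort decays.  A
#: 16-scan-averaged benchtop acquisition runs at SNR ~ 1e4, immaterial to
#: the pool-scale and chemometric analyses, so cohort decays default to
#: the noiseless limit; tests probing noise robustness pass explicit
#: levels.
DEFAULT_DECAY_NOISE_SD = 0.0

#: Texture repeatability noise as a fraction of each group's reference
#: texture SD, consistent with the few-percent replicate CVs a texture
#: analyzer delivers.
DEFAULT_TEXTURE_NOISE_FRAC = 0.05

#: Within-group pool dispersion of cohort replicates as a fraction of the
#: specimen-level reference SDs.  Replicates of an equilibrated treatment
#: scatter far less than independent specimens do; the fraction is set so
#: the synthetic calibration reproduces the reliability regime reported
#: for decay-based texture calibration (see the methods note).
DEFAULT_POOL_SCATTER_FRAC = 0.1

DEFAULT_MASS_G = 6.0


@dataclass(frozen=True)
class AcquisitionSpec:
    """CPMG acquisition settings.

    tau_us is the half-echo spacing (90deg-180deg delay) in microseconds;
    echoes are sampled at t_k = 2*tau*k for k = 1..n_echoes.
    """

    tau_us: float = 200.0
    n_echoes: int = 8000

    def __post_init__(self) -> None:
        if self.tau_us <= 0:
            raise ValueError(f"tau_us must be positive, got {self.tau_us}")
        if self.n_echoes < 2:
            raise ValueError(f"n_echoes must be >= 2, got {self.n_echoes}")

    @property
    def echo_times_ms(self) -> np.ndarray:
        k = np.arange(1, self.n_echoes + 1, dtype=float)
        return 2.0 * self.tau_us * 1e-3 * k


@dataclass(frozen=True)
class RelaxComponent:
    """One discrete relaxation component: time constant and magnitude."""

    t2_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.t2_ms > 0:
            raise ValueError(f"t2_ms must be positive, got {self.t2_ms}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class DecayCurve:
    """A sampled magnetization decay with acquisition metadata."""

    times_ms: np.ndarray
    signal: np.ndarray
    mass_g: float = 1.0
    noise_sd: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times_ms, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "signal", signal)
        if times.ndim != 1 or signal.shape != times.shape:
            raise ValueError("times_ms and signal must be 1-D and equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times_ms must be strictly increasing")
        if not self.mass_g > 0:
            raise ValueError(f"mass_g must be positive, got {self.mass_g}")

    def __len__(self) -> int:
        return self.times_ms.size


@dataclass(frozen=True)
class TextureRecord:
    """Texture-profile parameters; hardness in g, the rest dimensionless."""

    hardness: float
    resilience: float
    springiness: float
    chewiness: float
    gumminess: float
    adhesiveness: float

    def __post_init__(self) -> None:
        values = self.as_array()
        if not np.all(np.isfinite(values)):
            raise ValueError("texture values must be finite")
        for name in ("hardness", "chewiness", "gumminess"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.hardness,
                self.resilience,
                self.springiness,
                self.chewiness,
                self.gumminess,
                self.adhesiveness,
            ]
        )


@dataclass(frozen=True)
class TreatmentProfile:
    """Generative parameters for one cooking treatment group.

    Pool means/SDs are (T21, T22, T23) apex times in ms and per-gram areas;
    texture means/SDs are ordered hardness, resilience, springiness,
    chewiness, gumminess, adhesiveness.
    """

    name: str
    pool_t2_means: np.ndarray
    pool_t2_sds: np.ndarray
    pool_area_means: np.ndarray
    pool_area_sds: np.ndarray
    texture_means: np.ndarray
    texture_sds: np.ndarray

    def __post_init__(self) -> None:
        t2 = np.asarray(self.pool_t2_means, dtype=float)
        if t2.shape != (3,) or np.any(np.diff(t2) <= 0):
            raise ValueError("pool T2 means must be three increasing values")
        # Bound and immobilized pools sit in their nominal windows; the free
        # pool may blue-shift below 200 ms in strongly cooked tissue, so it
        # is only required to stay above T22 and below 1000 ms.
        if not POOL_WINDOWS_MS[0][0] <= t2[0] < POOL_WINDOWS_MS[0][1]:
            raise ValueError(f"T21 mean {t2[0]} ms outside [0.1, 10) ms")
        if not POOL_WINDOWS_MS[1][0] <= t2[1] < POOL_WINDOWS_MS[1][1]:
            raise ValueError(f"T22 mean {t2[1]} ms outside [10, 200) ms")
        if not t2[1] < t2[2] <= POOL_WINDOWS_MS[2][1]:
            raise ValueError(f"T23 mean {t2[2]} ms outside (T22, 1000] ms")
        for arr_name in ("pool_t2_sds", "pool_area_sds", "texture_sds"):
            if np.any(np.asarray(getattr(self, arr_name), dtype=float) < 0):
                raise ValueError(f"{arr_name} must be non-negative")


@dataclass(frozen=True)
class SampleSet:
    """Parallel decay/texture collections drawn from treatment profiles."""

    decays: list[DecayCurve]
    textures: list[TextureRecord]
    labels: list[str]
    pool_truth: list[dict]
    profiles: dict[str, TreatmentProfile]
    seed: int

    def __post_init__(self) -> None:
        n = len(self.decays)
        if not (len(self.textures) == len(self.labels) == len(self.pool_truth) == n):
            raise ValueError("decays, textures, labels, pool_truth must be parallel")
        unknown = set(self.labels) - set(self.profiles)
        if unknown:
            raise ValueError(f"labels without a profile: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.decays)

    def decay_matrix(self, step: int = 1) -> np.ndarray:
        """Stack signals into a samples x echoes matrix, keeping every
        `step`-th echo (down-sampling for chemometric models)."""
        return np.stack([d.signal[::step] for d in self.decays])

    def texture_matrix(self) -> np.ndarray:
        return np.stack([t.as_array() for t in self.textures])


def simulate_cpmg_decay(
    components: list[RelaxComponent],
    acq: AcquisitionSpec | None = None,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    mass_g: float = 1.0,
    label: str | None = None,
) -> DecayCurve:
    """Simulate a multi-exponential CPMG decay with additive Gaussian noise.

    The noiseless signal is sum_n amplitude_n * exp(-t_k / T2_n) on the
    acquisition's echo grid; e(t) is i.i.d. Gaussian(0, noise_sd).
    Reproducible for a fixed integer seed.
    """
    if not components:
        raise ValueError("components must be non-empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    acq = acq or AcquisitionSpec()
    t = acq.echo_times_ms
    t2 = np.array([c.t2_ms for c in components])
    amp = np.array([c.amplitude for c in components])
    signal = np.exp(-t[:, None] / t2[None, :]) @ amp
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=t.shape)
    return DecayCurve(
        times_ms=t,
        signal=signal,
        mass_g=mass_g,
        noise_sd=noise_sd if noise_sd > 0 else None,
        label=label,
    )


def texture_from_pools(
    pool_features: np.ndarray,
    coeffs: np.ndarray,
    noise_sd_vec: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> TextureRecord:
    """Map a pool feature vector to a texture record through a linear law.

    pool_features is [A21, A22, A23, ln T21, ln T22, ln T23] (areas per
    gram); coeffs has shape (6, 7) with the intercept in the last column.
    Gaussian noise with per-parameter SD noise_sd_vec is added; the draw is
    deterministic for a fixed integer seed.
    """
    features = np.asarray(pool_features, dtype=float)
    coeffs = np.asarray(coeffs, dtype=float)
    noise_sd_vec = np.asarray(noise_sd_vec, dtype=float)
    if features.shape != (6,):
        raise ValueError(f"pool_features must have shape (6,), got {features.shape}")
    if coeffs.shape != (6, 7):
        raise ValueError(f"coeffs must have shape (6, 7), got {coeffs.shape}")
    if noise_sd_vec.shape != (6,):
        raise ValueError(f"noise_sd_vec must have shape (6,), got {noise_sd_vec.shape}")
    values = coeffs[:, :6] @ features + coeffs[:, 6]
    rng = np.random.default_rng(seed)
    values = values + rng.normal(0.0, 1.0, size=6) * noise_sd_vec
    # hardness/chewiness/gumminess are physically non-negative
    for i in (0, 3, 4):
        values[i] = max(values[i], 0.0)
    return TextureRecord(*values)


def _draw_coherent_pools(
    rng: np.random.Generator,
    profile: TreatmentProfile,
    scatter_frac: float,
    max_tries: int = 1000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw one replicate's pool parameters as a coherent water-state mode.

    A single latent factor u ~ N(0, 1) moves all six pool parameters
    together: param = mean + u * scatter_frac * SD.  The draw is rejected
    and redrawn until every T2 sits in its admissible band (T21 in
    [0.1, 10), T22 in [10, 200), T23 above 1.5x the drawn T22 and at most
    1000 ms — the free pool may sit below the nominal 200 ms window in
    strongly cooked tissue) and all areas are positive.
    """
    t2_sd = scatter_frac * profile.pool_t2_sds
    area_sd = scatter_frac * profile.pool_area_sds
    for _ in range(max_tries):
        u = float(rng.normal())
        t2 = profile.pool_t2_means + u * t2_sd
        areas = profile.pool_area_means + u * area_sd
        if (
            POOL_WINDOWS_MS[0][0] <= t2[0] < POOL_WINDOWS_MS[0][1]
            and POOL_WINDOWS_MS[1][0] <= t2[1] < POOL_WINDOWS_MS[1][1]
            and 1.5 * t2[1] < t2[2] <= POOL_WINDOWS_MS[2][1]
            and np.all(areas > 0)
        ):
            return t2, areas, u
    raise RuntimeError(
        f"coherent pool draw failed for profile {profile.name!r}"
    )


def generate_cohort(
    profiles: list[TreatmentProfile],
    n_per_group: int,
    acq: AcquisitionSpec | None = None,
    decay_noise_sd: float = DEFAULT_DECAY_NOISE_SD,
    seed: int = 0,
    texture_noise_frac: float = DEFAULT_TEXTURE_NOISE_FRAC,
    pool_scatter_frac: float = DEFAULT_POOL_SCATTER_FRAC,
    mass_g: float = DEFAULT_MASS_G,
    coeffs: np.ndarray | dict | None = None,
) -> SampleSet:
    """Draw a cohort of decay/texture sample pairs from treatment profiles.

    Per sample, pool T2s and per-gram areas are drawn Gaussian around the
    profile means along a coherent water-state mode (truncated to stay
    positive and inside the admissible T2 bands; dispersion
    ``pool_scatter_frac`` times the specimen-level SDs), the decay is
    simulated at the drawn parameters scaled by the sample mass, and the
    texture record follows from the drawn pool features through the
    treatment's local linkage map plus Gaussian repeatability noise of SD
    ``texture_noise_frac * profile.texture_sds``.

    ``coeffs`` overrides the linkage: either one (6, 7) matrix used for
    every group, or a dict mapping profile name to a (6, 7) matrix.
    Bit-reproducible for a fixed seed.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if coeffs is None:
        from fishnmr.profiles import local_linkage

        coeff_for = {p.name: local_linkage(p) for p in profiles}
    elif isinstance(coeffs, dict):
        coeff_for = coeffs
    else:
        coeff_for = {p.name: coeffs for p in profiles}
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)

    decays: list[DecayCurve] = []
    textures: list[TextureRecord] = []
    labels: list[str] = []
    truth: list[dict] = []
    for profile in profiles:
        noise_vec = texture_noise_frac * profile.texture_sds
        for _ in range(n_per_group):
            t2, areas, u = _draw_coherent_pools(rng, profile, pool_scatter_frac)
            components = [
                RelaxComponent(t2_ms=float(t), amplitude=float(a) * mass_g)
                for t, a in zip(t2, areas)
            ]
            decay_seed = int(rng.integers(0, 2**31 - 1))
            texture_seed = int(rng.integers(0, 2**31 - 1))
            decays.append(
                simulate_cpmg_decay(
                    components,
                    acq,
                    noise_sd=decay_noise_sd,
                    seed=decay_seed,
                    mass_g=mass_g,
                    label=profile.name,
                )
            )
            features = np.concatenate([areas, np.log(t2)])
            textures.append(
                texture_from_pools(
                    features, coeff_for[profile.name], noise_vec, seed=texture_seed
                )
            )
            labels.append(profile.name)
            truth.append(
                {
                    "t2_ms": t2,
                    "areas_per_g": areas,
                    "u": u,
                    "mass_g": mass_g,
                    "label": profile.name,
                }
            )
    return SampleSet(
        decays=decays,
        textures=textures,
        labels=labels,
        pool_truth=truth,
        profiles={p.name: p for p in profiles},
        seed=seed,
    )
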
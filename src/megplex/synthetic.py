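"""Seeded generators for testing the pipeline end to end without data.

Two generators:

* :func:`simulate_sources` — multichannel oscillatory time series with
  planted band-specific phase coupling of known topology, so the spectral
  stage's ground truth is the coupling spec itself.
* :func:`simulate_cohort` — a two-timepoint cohort in which an executive-
  functioning Z-score depends linearly on frontoparietal multilayer
  centrality with a configurable standardized effect, plus covariates.

Every generator is a pure function of (spec, seed): the global seed fans
out to per-component substreams keyed on stable integer tags, so adding a
component never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import DEFAULT_BANDS, BandDefinition, TimeSeries
from .stats import CovariateSpec

__all__ = [
    "BandCoupling",
    "CouplingSpec",
    "CohortCovariate",
    "CohortSpec",
    "simulate_sources",
    "simulate_cohort",
    "DEFAULT_EF_TESTS",
]

DEFAULT_EF_TESTS = ("ef_set_shifting", "ef_word_fluency", "ef_inhibition")

# substream tags for the counter-based seed fan-out
_TAG_CARRIER = 1
_TAG_CHANNEL_NOISE = 2
_TAG_WHITE = 3
_TAG_COHORT = 4


@dataclass(frozen=True)
class BandCoupling:
    """One planted coupling: regions ``a`` and ``b`` share a band-limited
    carrier with a constant phase lag."""

    a: int
    b: int
    strength: float  # carrier mixing weight in [0, 1]
    lag: float  # radians in (-pi, pi]

    def __post_init__(self) -> None:
        if not 0 <= self.strength <= 1:
            raise ValueError(f"strength must be in [0, 1], got {self.strength}")
        if not -np.pi < self.lag <= np.pi:
            raise ValueError(f"lag must be in (-pi, pi], got {self.lag}")


@dataclass
class CouplingSpec:
    """Ground-truth description of a simulated multichannel recording."""

    n_regions: int
    fs: float
    n_samples: int
    seed: int
    coupling: dict[str, list[BandCoupling]] = field(default_factory=dict)
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    noise_sd: float = 0.1
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        band_names = {b.name for b in self.bands}
        for band_name, edges in self.coupling.items():
            if band_name not in band_names:
                raise ValueError(f"unknown band {band_name!r} in coupling spec")
            for e in edges:
                if not (0 <= e.a < self.n_regions and 0 <= e.b < self.n_regions):
                    raise ValueError(
                        f"coupling edge ({e.a}, {e.b}) references a region "
                        f">= N = {self.n_regions}"
                    )
                if e.a == e.b:
                    raise ValueError(f"self-coupling on region {e.a}")


def _band_noise(
    rng: np.random.Generator, n_samples: int, band: BandDefinition, fs: float
) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (FFT-masked white noise)."""
    white = rng.standard_normal(n_samples)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spectrum[(freqs < band.f_lo) | (freqs >= band.f_hi)] = 0.0
    x = np.fft.irfft(spectrum, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate every positive-frequency component of ``x`` by ``-lag`` radians,
    delaying its analytic phase by ``lag``."""
    spectrum = np.fft.rfft(x)
    spectrum[1:] *= np.exp(-1j * lag)  # DC untouched; band noise has none anyway
    return np.fft.irfft(spectrum, n=x.size)


def simulate_sources(spec: CouplingSpec) -> TimeSeries:
    """Multichannel time series with the planted band-specific couplings.

    For each band, every coupled pair shares a common band-limited Gaussian
    carrier; the second endpoint receives the carrier phase-delayed by the
    specified lag. A region's band component mixes carrier(s) (weighted by
    coupling strength) with independent band-limited noise weighted by
    ``1 - max incident strength``. Channels sum their band components plus
    white noise of sd ``noise_sd``.
    """
    n, t = spec.n_regions, spec.n_samples
    signal = np.zeros((t, n))
    for b_idx, band in enumerate(spec.bands):
        edges = spec.coupling.get(band.name, [])
        carrier_weight = np.zeros(n)
        band_component = np.zeros((t, n))
        for e_idx, edge in enumerate(edges):
            rng = np.random.default_rng(
                [spec.seed, _TAG_CARRIER, b_idx, e_idx]
            )
            carrier = _band_noise(rng, t, band, spec.fs)
            band_component[:, edge.a] += edge.strength * carrier
            band_component[:, edge.b] += edge.strength * _phase_rotate(
                carrier, edge.lag
            )
            carrier_weight[edge.a] = max(carrier_weight[edge.a], edge.strength)
            carrier_weight[edge.b] = max(carrier_weight[edge.b], edge.strength)
        for r in range(n):
            own_weight = 1.0 - carrier_weight[r]
            if own_weight > 0:
                rng = np.random.default_rng(
                    [spec.seed, _TAG_CHANNEL_NOISE, b_idx, r]
                )
                band_component[:, r] += own_weight * _band_noise(
                    rng, t, band, spec.fs
                )
        signal += band_component
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, _TAG_WHITE])
        signal = signal + spec.noise_sd * rng.standard_normal((t, n))
    labels = spec.region_labels or [f"region_{i:03d}" for i in range(n)]
    return TimeSeries(samples=signal, fs=spec.fs, region_labels=list(labels))


@dataclass(frozen=True)
class CohortCovariate:
    """Covariate generator: kind, levels (categorical) or moments
    (continuous), and its standardized effect on every EF score."""

    name: str
    kind: str  # 'continuous' | 'binary' | 'categorical'
    effect: float = 0.0
    levels: tuple[str, ...] = ()
    probabilities: tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind in ("binary", "categorical") and len(self.levels) < 2:
            raise ValueError(
                f"covariate {self.name!r}: {self.kind} needs >= 2 levels"
            )

    def to_spec(self) -> CovariateSpec:
        ref = self.levels[0] if self.levels else None
        return CovariateSpec(self.name, self.kind, reference=ref)


def _default_covariates() -> tuple[CohortCovariate, ...]:
    return (
        CohortCovariate("epilepsy", "binary", levels=("no", "yes"),
                        probabilities=(0.45, 0.55)),
        CohortCovariate(
            "subtype", "categorical",
            levels=("mutant_codeleted", "mutant_noncodeleted", "wildtype"),
            probabilities=(0.4, 0.3, 0.3),
        ),
        CohortCovariate(
            "treatment", "categorical",
            levels=("none", "chemotherapy", "radiotherapy"),
            probabilities=(0.6, 0.25, 0.15),
        ),
        CohortCovariate("interval_resection_npa", "continuous",
                        mean=12.0, sd=3.0),
    )


@dataclass
class CohortSpec:
    """Generator settings for a two-timepoint cohort with a known EC -> EF
    standardized effect ``beta_ec`` (cross-sectional) and an optional
    change-score coupling ``ec_change_coupling`` (longitudinal)."""

    n_subjects: int
    seed: int
    beta_ec: float = 0.0
    ec_change_coupling: float = 0.0
    noise_sd: float = 1.0
    ec_mean: float = 0.41
    ec_sd: float = 0.10
    ec_drift_sd: float = 0.05
    covariates: tuple[CohortCovariate, ...] = field(
        default_factory=_default_covariates
    )
    ef_tests: tuple[str, ...] = DEFAULT_EF_TESTS

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError(f"n_subjects must be >= 10, got {self.n_subjects}")

    def covariate_specs(self) -> dict[str, CovariateSpec]:
        return {c.name: c.to_spec() for c in self.covariates}


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Tidy cohort table (one row per subject x timepoint).

    Latent FPN centrality at T1 is Normal(ec_mean, ec_sd); T2 adds a small
    Gaussian drift. Each EF Z-score is ``beta_ec * z(EC) + covariate
    effects + noise`` at T1; its T2 value adds ``ec_change_coupling *
    z(delta EC)`` plus fresh noise, so both the cross-sectional and the
    change-score regressions have known population coefficients.
    """
    rng = np.random.default_rng([spec.seed, _TAG_COHORT])
    n = spec.n_subjects
    ec_t1 = spec.ec_mean + spec.ec_sd * rng.standard_normal(n)
    ec_drift = spec.ec_drift_sd * rng.standard_normal(n)
    ec_t2 = ec_t1 + ec_drift
    z_ec = (ec_t1 - ec_t1.mean()) / ec_t1.std(ddof=0)
    z_drift = (ec_drift - ec_drift.mean()) / ec_drift.std(ddof=0)

    cov_values: dict[str, np.ndarray] = {}
    cov_effect_term = np.zeros(n)
    for cov in spec.covariates:
        if cov.kind == "continuous":
            vals = cov.mean + cov.sd * rng.standard_normal(n)
            cov_values[cov.name] = vals
            if cov.effect:
                cov_effect_term = cov_effect_term + cov.effect * (
                    (vals - vals.mean()) / vals.std(ddof=0)
                )
        else:
            probs = cov.probabilities or tuple(
                1.0 / len(cov.levels) for _ in cov.levels
            )
            draws = rng.choice(len(cov.levels), size=n, p=np.asarray(probs))
            cov_values[cov.name] = np.asarray(cov.levels)[draws]
            if cov.effect:
                # effect applies to the last (non-reference) level indicator
                indicator = (draws == len(cov.levels) - 1).astype(float)
                sd = indicator.std(ddof=0)
                if sd > 0:
                    cov_effect_term = cov_effect_term + cov.effect * (
                        (indicator - indicator.mean()) / sd
                    )

    rows: list[dict] = []
    for t_idx, timepoint in enumerate(("T1", "T2")):
        ec = ec_t1 if timepoint == "T1" else ec_t2
        for j, test in enumerate(spec.ef_tests):
            noise = spec.noise_sd * rng.standard_normal(n)
            ef_t1 = spec.beta_ec * z_ec + cov_effect_term + noise
            if timepoint == "T1":
                cov_values.setdefault("_ef_t1_" + test, ef_t1)
            else:
                base = cov_values["_ef_t1_" + test]
                change_noise = spec.noise_sd * rng.standard_normal(n)
                ef_t1 = (
                    base
                    + spec.ec_change_coupling * z_drift
                    + 0.5 * change_noise
                )
            cov_values["_" + timepoint + "_" + test] = ef_t1
        for i in range(n):
            row = {
                "subject_id": f"S{i + 1:03d}",
                "timepoint": timepoint,
                "ec_fpn": float(ec[i]),
            }
            for test in spec.ef_tests:
                row[test] = float(cov_values["_" + timepoint + "_" + test][i])
            for cov in spec.covariates:
                v = cov_values[cov.name][i]
                row[cov.name] = float(v) if cov.kind == "continuous" else str(v)
            rows.append(row)
    return pd.DataFrame(rows)
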
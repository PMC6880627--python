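"""Simulation phantoms for validating perfusion parameter estimation.

6x6-voxel slices with piecewise-constant kinetic parameter maps mimic a
healthy patient at rest, a healthy patient at stress, and a patient with
stress-inducible ischaemia (two disconnected low-flow regions).  Tissue
curves are forward-simulated from a gamma-variate-based arterial input
function with recirculation and corrupted with Rician noise
(magnitude-MRI noise model) at a configurable SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import DEFAULT_HCT, ForwardOperator, SampledCurve, population_aif

__all__ = [
    "CONDITIONS",
    "PhantomSlice",
    "SyntheticSeries",
    "build_phantom",
    "simulate_series",
    "add_rician_noise",
]

CONDITIONS = ("rest", "stress", "stress_defect")

# Healthy-voxel kinetic parameter values for each condition:
# stress (F_b, v_p, v_e, PS) = (3.5, 0.08, 0.16, 1.0); rest lowers F_b to 1.0.
_HEALTHY = {
    "rest": dict(fb=1.0, vp=0.08, ve=0.16, ps=1.0),
    "stress": dict(fb=3.5, vp=0.08, ve=0.16, ps=1.0),
    "stress_defect": dict(fb=3.5, vp=0.08, ve=0.16, ps=1.0),
}
_DEFECT_FB = 1.0

#: Default defect geometry: (row slice, col slice) of two blocks separated
#: by at least one healthy voxel so they form two disconnected regions.
DEFAULT_DEFECTS = ((slice(1, 3), slice(1, 3)), (slice(4, 6), slice(4, 5)))

# Temporal resolutions reported for the simulated acquisitions (minutes).
DT_STRESS = 0.012
DT_REST = 0.017
TOTAL_TIME = 3.0
DEFAULT_SNR = 15.0


def default_dt(condition: str) -> float:
    """Sampling interval for a condition: 0.012 min at stress, 0.017 at rest."""
    return DT_REST if condition == "rest" else DT_STRESS


@dataclass(frozen=True)
class PhantomSlice:
    """Ground-truth parameter maps of one simulated 2-D slice."""

    maps: dict  # parameter name -> 2-D float array (fb, vp, ve, ps)
    mask: np.ndarray
    condition: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def params_at(self, idx: tuple[int, int]) -> dict:
        return {k: float(v[idx]) for k, v in self.maps.items()}


@dataclass(frozen=True)
class SyntheticSeries:
    """One simulated dynamic series: clean and noisy (t, y, x) arrays."""

    clean: np.ndarray
    noisy: np.ndarray
    aif: SampledCurve
    sigma_noise: float
    seed: int
    truth: PhantomSlice

    @property
    def times(self) -> np.ndarray:
        return self.aif.times


def build_phantom(
    condition: str,
    shape: tuple[int, int] = (6, 6),
    defects=DEFAULT_DEFECTS,
) -> PhantomSlice:
    """Piecewise-constant ground-truth maps for one of the three conditions.

    ``stress_defect`` plants two disconnected regions of rest-level flow
    (F_b = 1.0) inside an otherwise healthy stress slice.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    base = _HEALTHY[condition]
    maps = {k: np.full(shape, v, dtype=float) for k, v in base.items()}
    if condition == "stress_defect":
        for rows, cols in defects:
            maps["fb"][rows, cols] = _DEFECT_FB
    mask = np.ones(shape, dtype=bool)
    return PhantomSlice(maps=maps, mask=mask, condition=condition)


def add_rician_noise(clean: np.ndarray, sigma: float, seed: int | np.random.Generator) -> np.ndarray:
    """Rician-corrupt a magnitude image/series.

    Output is ``sqrt((clean + n1)^2 + n2^2)`` with ``n1, n2`` i.i.d.
    zero-mean Gaussians of standard deviation ``sigma`` — the magnitude of
    a complex signal with independent Gaussian noise on both channels.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    clean = np.asarray(clean, dtype=float)
    if sigma == 0:
        return np.abs(clean)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    return np.hypot(clean + n1, n2)


def simulate_series(
    phantom: PhantomSlice,
    dt: float | None = None,
    total_time: float = TOTAL_TIME,
    snr: float = DEFAULT_SNR,
    seed: int = 0,
    aif: SampledCurve | None = None,
    tau0: float = 0.0,
    hct: float = DEFAULT_HCT,
    noise_on_aif: bool = False,
) -> SyntheticSeries:
    """Forward-simulate a phantom and add Rician noise at the requested SNR.

    SNR is the ratio of the peak of the clean tissue curves to the noise
    standard deviation, so ``sigma = max(clean)/snr``.  The same seed gives
    bit-identical output.  Noise is applied to the tissue curves only
    unless ``noise_on_aif`` is set.
    """
    if dt is None:
        dt = default_dt(phantom.condition)
    if dt <= 0 or total_time <= dt:
        raise ValueError("need dt > 0 and total_time > dt")
    if snr <= 0:
        raise ValueError(f"snr must be positive, got {snr}")
    n_t = int(round(total_time / dt)) + 1
    times = np.arange(n_t) * dt
    if aif is None:
        aif = population_aif(times)
    op = ForwardOperator(times, aif.values, tau0=tau0, hct=hct)

    rows, cols = phantom.shape
    clean = np.zeros((n_t, rows, cols))
    cache: dict[tuple, np.ndarray] = {}  # piecewise-constant maps: few unique curves
    for i in range(rows):
        for j in range(cols):
            if not phantom.mask[i, j]:
                continue
            key = tuple(phantom.maps[k][i, j] for k in ("fb", "vp", "ve", "ps"))
            if key not in cache:
                cache[key] = op(*key)
            clean[:, i, j] = cache[key]

    sigma = float(clean[:, phantom.mask].max()) / snr
    rng = np.random.default_rng(seed)
    noisy = add_rician_noise(clean, sigma, rng)
    noisy[:, ~phantom.mask] = 0.0
    if noise_on_aif:
        aif = SampledCurve(times, add_rician_noise(aif.values, sigma, rng))
    return SyntheticSeries(
        clean=clean, noisy=noisy, aif=aif, sigma_noise=sigma, seed=int(seed), truth=phantom
    )
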
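"""Model/Results interface over the voxel-wise fitting machinery.

Both model classes are built from the same data triplet — a (t, y, x)
concentration series, a myocardial mask and an AIF — and their ``fit()``
returns a results object carrying parameter maps, uncertainty, diagnostics
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import outlier_stats
from .hbayes import (
    ChainState,
    PosteriorSummary,
    PriorSpec,
    build_neighbour_graph,
    run_mcmc,
    summarize,
)
from .kinetics import DEFAULT_HCT, SampledCurve
from .nlls import FitConfig, fit_slice_nlls, results_to_maps
from .phantom import SyntheticSeries

PARAM_NAMES = ("fb", "vp", "ve", "ps")
_LABELS = {"fb": "F_b (mL/min/mL)", "vp": "v_p", "ve": "v_e", "ps": "PS (mL/min/mL)"}


class _BasePerfusionModel:
    def __init__(self, series: np.ndarray, mask: np.ndarray, aif: SampledCurve):
        self.series = np.asarray(series, dtype=float)
        self.mask = np.asarray(mask, dtype=bool)
        self.aif = aif
        if self.series.ndim != 3:
            raise ValueError("series must be a (t, y, x) array")
        if self.series.shape[1:] != self.mask.shape:
            raise ValueError("mask shape does not match the series")
        if self.series.shape[0] != len(aif):
            raise ValueError("series time axis does not match the AIF grid")

    @classmethod
    def from_synthetic(cls, sim: SyntheticSeries, use_clean: bool = False, **kwargs):
        data = sim.clean if use_clean else sim.noisy
        return cls(data, sim.truth.mask, sim.aif, **kwargs)

    def _summary_frame(self, maps: dict, spread: dict, spread_name: str) -> pd.DataFrame:
        rows = []
        for k in PARAM_NAMES:
            vals = maps[k][self.mask]
            rows.append(
                {
                    "parameter": _LABELS[k],
                    "median": float(np.nanmedian(vals)),
                    "q25": float(np.nanpercentile(vals, 25)),
                    "q75": float(np.nanpercentile(vals, 75)),
                    spread_name: float(np.nanmedian(spread[k][self.mask])),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


class PerfusionNLLS(_BasePerfusionModel):
    """Multi-start bounded least-squares fit of the 2CXM, voxel by voxel."""

    def __init__(self, series, mask, aif, config: FitConfig | None = None):
        super().__init__(series, mask, aif)
        self.config = config or FitConfig()

    def fit(self) -> "PerfusionNLLSResults":
        results, failure = fit_slice_nlls(self.series, self.mask, self.aif, self.config)
        maps = results_to_maps(results, self.mask.shape)
        return PerfusionNLLSResults(self, results, maps, failure)


@dataclass
class PerfusionNLLSResults:
    model: PerfusionNLLS
    voxel_results: dict
    maps: dict
    failure_fraction: float

    def outliers(self) -> dict:
        return outlier_stats(self.maps["fb"], self.model.mask, self.voxel_results)

    def summary(self) -> str:
        frame = self.model._summary_frame(
            self.maps, {k: self.maps["cost"] for k in PARAM_NAMES}, "cost"
        )
        stats = self.outliers()
        lines = [
            "2CXM multi-start least-squares fit",
            f"  voxels fitted: {len(self.voxel_results)}"
            f"  starts per voxel: {self.model.config.n_starts}",
            f"  failed voxels: {self.failure_fraction:.1%}"
            f"  outliers (F_b > 5): {stats['outlier_fraction']:.1%}",
            frame.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        return "\n".join(lines)


class PerfusionMCMC(_BasePerfusionModel):
    """Hierarchical Bayesian 2CXM fit via Metropolis-Hastings sampling."""

    def __init__(
        self,
        series,
        mask,
        aif,
        prior: PriorSpec | None = None,
        n_steps: int = 4000,
        burn_in: int = 1000,
        tau0: float = 0.0,
        hct: float = DEFAULT_HCT,
    ):
        super().__init__(series, mask, aif)
        self.prior = prior or PriorSpec()
        self.n_steps = n_steps
        self.burn_in = burn_in
        self.tau0 = tau0
        self.hct = hct
        self.graph = build_neighbour_graph(self.mask) if self.prior.spatial_rate > 0 else None

    def fit(self, seed: int = 0, chains: int = 1) -> "PerfusionMCMCResults":
        """Run ``chains`` independently seeded chains (seed, seed+1, ...)."""
        states = [
            run_mcmc(
                self.series,
                self.mask,
                self.aif,
                self.graph,
                self.prior,
                n_steps=self.n_steps,
                burn_in=self.burn_in,
                seed=seed + c,
                tau0=self.tau0,
                hct=self.hct,
            )
            for c in range(chains)
        ]
        summ = summarize(states[0], extra_chains=states[1:] or None)
        return PerfusionMCMCResults(self, states, summ)


@dataclass
class PerfusionMCMCResults:
    model: PerfusionMCMC
    chains: list
    posterior: PosteriorSummary

    @property
    def maps(self) -> dict:
        return self.posterior.median

    @property
    def block_acceptance(self) -> float:
        return float(np.mean([c.block_accept_post for c in self.chains]))

    def summary(self) -> str:
        frame = self.model._summary_frame(self.posterior.median, self.posterior.cov, "CoV")
        lines = [
            "2CXM hierarchical Bayesian fit"
            if self.model.prior.hierarchical
            else "2CXM Bayesian fit (fixed prior means)",
            f"  chains: {len(self.chains)}  steps: {self.model.n_steps}"
            f"  burn-in: {self.model.burn_in}",
            f"  post-burn-in block acceptance: {self.block_acceptance:.3f}",
            frame.to_string(float_format=lambda x: f"{x:.4g}"),
        ]
        if self.posterior.rhat is not None:
            worst = max(float(np.nanmax(m)) for m in self.posterior.rhat.values())
            lines.insert(3, f"  max R-hat over voxels/parameters: {worst:.4f}")
        return "\n".join(lines)
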
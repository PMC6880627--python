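"""Monte-Carlo evaluation of perfusion fitting methods on phantoms.

Per realisation and parameter, estimation error is summarised by the
normalised mean-squared error over masked voxels,

    NMSE_k = mean((estimate_k - truth_k)^2) / mean(truth_k^2),

with "all" the mean of the four per-parameter NMSEs (the normalisation
makes the parameters comparable despite their different magnitudes).
Method comparisons use the two-sided Mann-Whitney U test on the
per-realisation NMSE distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hbayes import PriorSpec, build_neighbour_graph, run_mcmc, summarize
from .nlls import FitConfig, fit_slice_nlls, results_to_maps
from .phantom import CONDITIONS, build_phantom, default_dt, simulate_series

__all__ = ["EvalReport", "nmse", "mann_whitney_u", "outlier_stats", "monte_carlo_study"]

PARAM_NAMES = ("fb", "vp", "ve", "ps")

#: MBF above this value (mL/min/mL) is counted as an outlier estimate.
OUTLIER_FB = 5.0

#: Sample-size threshold below which the U test is computed exactly.
_EXACT_LIMIT = 20


def nmse(estimates: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalised mean-squared error of a parameter map over a mask.

    Scale-invariant: multiplying both maps by a constant leaves it
    unchanged.  Requires a non-zero truth map on the mask.
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimates.shape != truth.shape:
        raise ValueError("estimate and truth maps must have the same shape")
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    e = estimates[mask]
    t = truth[mask]
    denom = np.mean(t**2)
    if denom == 0 or np.any(t == 0):
        raise ValueError("truth map contains zero voxels; NMSE undefined")
    return float(np.mean((e - t) ** 2) / denom)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p-value).

    Exact null distribution for small samples (n+m <= 20 and no ties),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def outlier_stats(
    fb_map: np.ndarray,
    mask: np.ndarray,
    fit_results: dict | None = None,
    threshold: float = OUTLIER_FB,
) -> dict:
    """Fractions of outlier (F_b > 5) and failed-fit voxels on a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n = int(mask.sum())
    outlier_fraction = float(np.sum(np.asarray(fb_map)[mask] > threshold)) / n
    failure_fraction = 0.0
    if fit_results is not None:
        failure_fraction = sum(not r.success for r in fit_results.values()) / max(
            len(fit_results), 1
        )
    return {"outlier_fraction": outlier_fraction, "failure_fraction": failure_fraction}


@dataclass
class EvalReport:
    """Aggregated Monte-Carlo study results.

    ``records`` holds one row per (condition, realisation, method,
    parameter) with the NMSE value; aggregation into the Table-style
    summary is a pure function of these records.
    """

    records: pd.DataFrame
    n_realisations: int
    master_seed: int
    methods: tuple
    conditions: tuple
    fractions: pd.DataFrame  # per condition/realisation/method outlier + failure

    def nmse_values(
        self, method: str, parameter: str = "all", condition: str | None = None
    ) -> np.ndarray:
        """Per-realisation NMSE values (pooled over conditions by default)."""
        df = self.records[
            (self.records.method == method) & (self.records.parameter == parameter)
        ]
        if condition is not None:
            df = df[df.condition == condition]
        return df.nmse.to_numpy()

    def mean_sd(self, method: str, parameter: str = "all", condition=None) -> tuple:
        vals = self.nmse_values(method, parameter, condition)
        return float(vals.mean()), float(vals.std(ddof=1))

    def compare(self, method_a: str, method_b: str, parameter: str = "all") -> float:
        """Two-sided Mann-Whitney p-value on per-realisation NMSE values."""
        _, p = mann_whitney_u(
            self.nmse_values(method_a, parameter), self.nmse_values(method_b, parameter)
        )
        return p

    def summary_table(self, reference: str | None = None) -> pd.DataFrame:
        """Table-style layout: rows All/F_b/v_p/v_e/PS, one column per method."""
        rows = []
        ref = reference or self.methods[0]
        for param, label in zip(
            ("all",) + PARAM_NAMES, ("All", "F_b", "v_p", "v_e", "PS")
        ):
            row = {"parameter": label}
            for m in self.methods:
                mean, sd = self.mean_sd(m, param)
                row[m] = f"{mean:.2f} ({sd:.2f})"
            others = [m for m in self.methods if m != ref]
            if others:
                row["p_vs_" + ref] = self.compare(others[0], ref, param)
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")


def _fit_method(method: str, sim, mcmc_steps: int, burn_in: int, seed: int, nlls_cfg):
    """Dispatch one fitting method on one simulated realisation."""
    mask = sim.truth.mask
    if method.startswith("nlls"):
        n_starts = int(method[4:]) if method != "nlls" else 100
        cfg = FitConfig(
            n_starts=n_starts,
            rng_seed=seed,
            **({} if nlls_cfg is None else nlls_cfg),
        )
        results, failure = fit_slice_nlls(sim.noisy, mask, sim.aif, cfg)
        maps = results_to_maps(results, mask.shape)
        return maps, {"failure_fraction": failure, "results": results}
    if method == "bayes":
        spec = PriorSpec()
    elif method.startswith("bayes_fixed"):
        spec = PriorSpec().nonhierarchical(fb_mean=float(method[len("bayes_fixed") :]))
    else:
        raise ValueError(f"unknown method {method!r}")
    graph = build_neighbour_graph(mask)
    chain = run_mcmc(
        sim.noisy, mask, sim.aif, graph, spec, n_steps=mcmc_steps, burn_in=burn_in, seed=seed
    )
    summ = summarize(chain)
    maps = dict(summ.median)
    return maps, {
        "failure_fraction": 0.0,
        "block_accept": chain.block_accept_post,
        "summary": summ,
    }


def monte_carlo_study(
    conditions=CONDITIONS,
    n_realisations: int = 20,
    methods=("bayes", "nlls1", "nlls100"),
    master_seed: int = 0,
    snr: float = 15.0,
    total_time: float = 3.0,
    mcmc_steps: int = 4000,
    burn_in: int = 1000,
    nlls_cfg: dict | None = None,
    keep_diagnostics: bool = False,
) -> EvalReport:
    """Simulate, fit and score phantom realisations for each method.

    Every method sees the identical noisy realisation for a given
    (condition, realisation) pair; all randomness descends from
    ``master_seed``.  A method crash is recorded (NaN NMSE) rather than
    aborting the study.
    """
    if n_realisations < 2:
        raise ValueError("need at least 2 realisations")
    records = []
    fraction_rows = []
    diagnostics = {}
    for ci, condition in enumerate(conditions):
        phantom = build_phantom(condition)
        truth_maps = phantom.maps
        for r in range(n_realisations):
            sim_seed = int(
                np.random.SeedSequence(
                    entropy=master_seed, spawn_key=(ci, r)
                ).generate_state(1)[0]
                % (2**31)
            )
            sim = simulate_series(
                phantom,
                dt=default_dt(condition),
                total_time=total_time,
                snr=snr,
                seed=sim_seed,
            )
            for mi, method in enumerate(methods):
                fit_seed = int(
                    np.random.SeedSequence(
                        entropy=master_seed, spawn_key=(ci, r, mi + 1)
                    ).generate_state(1)[0]
                    % (2**31)
                )
                try:
                    maps, info = _fit_method(
                        method, sim, mcmc_steps, burn_in, fit_seed, nlls_cfg
                    )
                except Exception:  # record the crash, keep the study alive
                    for p in ("all",) + PARAM_NAMES:
                        records.append(
                            dict(
                                condition=condition,
                                realisation=r,
                                method=method,
                                parameter=p,
                                nmse=np.nan,
                            )
                        )
                    continue
                per_param = {
                    k: nmse(maps[k], truth_maps[k], phantom.mask) for k in PARAM_NAMES
                }
                per_param["all"] = float(np.mean(list(per_param.values())))
                for p, v in per_param.items():
                    records.append(
                        dict(
                            condition=condition,
                            realisation=r,
                            method=method,
                            parameter=p,
                            nmse=v,
                        )
                    )
                frac = outlier_stats(
                    maps["fb"], phantom.mask, info.get("results")
                )
                frac.update(
                    condition=condition,
                    realisation=r,
                    method=method,
                    block_accept=info.get("block_accept", np.nan),
                )
                fraction_rows.append(frac)
                if keep_diagnostics:
                    diagnostics[(condition, r, method)] = info
    report = EvalReport(
        records=pd.DataFrame(records),
        n_realisations=n_realisations,
        master_seed=master_seed,
        methods=tuple(methods),
        conditions=tuple(conditions),
        fractions=pd.DataFrame(fraction_rows),
    )
    if keep_diagnostics:
        report.diagnostics = diagnostics
    return report
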
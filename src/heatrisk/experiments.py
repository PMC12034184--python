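"""Parameter-recovery experiments on synthetic study data.

The cities' mortality registers are access-restricted, so the quantitative
claims are validated by simulation: generate data whose ground truth is
calibrated to the published estimates, run the full pipeline, and check that
it recovers the generating values.  These helpers are shared by the test
suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import presets
from .pipeline import AnalysisConfig, HeatMortalityDLNM, run_city
from .simulate import EpiSimConfig, simulate_city, simulate_epi_dataset, simulate_survey
from .survey import run_survey_model

__all__ = [
    "replicate_seeds",
    "EpiRecovery",
    "run_epi_recovery",
    "run_city_recovery",
    "run_survey_recovery",
]


def replicate_seeds(base_seed: int, n: int) -> list:
    """Derive independent, reproducible per-replicate seeds below 2**31."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint32)
    return [int(s % 2**31) for s in state]


@dataclass
class EpiRecovery:
    """Replicate-level estimates from a whole-population recovery experiment."""

    rr90: np.ndarray
    rr99: np.ndarray
    mmt: np.ndarray
    true_rr90: float
    true_rr99: float
    true_mmt: float

    def mean(self, what: str) -> float:
        return float(np.mean(getattr(self, what)))


def run_epi_recovery(config: EpiSimConfig, n_replicates: int, base_seed: int,
                     analysis: AnalysisConfig = None) -> EpiRecovery:
    """Simulate-and-refit a whole-population city ``n_replicates`` times.

    Each replicate draws a fresh temperature path and death series from a
    truth curve calibrated to the configured RR anchors, fits the DLNM, and
    records the estimated RR at the simulated 90th/99th warm-season
    percentiles and the estimated MMT.
    """
    analysis = analysis or AnalysisConfig()
    rr90, rr99, mmt = [], [], []
    for seed in replicate_seeds(base_seed, n_replicates):
        series, _ = simulate_epi_dataset(config, seed=seed)
        res = HeatMortalityDLNM(series, config=analysis).fit()
        rr90.append(res.rr.rr(90.0))
        rr99.append(res.rr.rr(99.0))
        mmt.append(res.mmt.mmt_temp)
    return EpiRecovery(
        rr90=np.array(rr90), rr99=np.array(rr99), mmt=np.array(mmt),
        true_rr90=config.rr90, true_rr99=config.rr99, true_mmt=config.mmt_temp,
    )


def run_city_recovery(n_replicates: int, base_seed: int,
                      stratum=("female", "85+"),
                      analysis: AnalysisConfig = None) -> dict:
    """Stratified Madrid-profile recovery of one stratum's P99 relative risk.

    Simulates the full sex x age city (the target stratum carries its own
    elevated truth curve), runs the city pipeline centered at the estimated
    city-wide MMT, and collects the stratum's estimated RR at the 99th
    percentile per replicate.
    """
    analysis = analysis or AnalysisConfig()
    strata = presets.madrid_city_strata()
    temp = presets.madrid_temp_config()
    out = []
    for seed in replicate_seeds(base_seed, n_replicates):
        frame, _ = simulate_city(temp, strata, seed=seed)
        results = run_city(frame, analysis)
        out.append(results.by_stratum[stratum].rr.rr(99.0))
    return {
        "rr99": np.array(out),
        "true_rr99": strata[stratum]["rr99"],
    }


def run_survey_recovery(n_replicates: int, base_seed: int, config=None,
                        terms=("female", "depression"), weighted: bool = True) -> dict:
    """Simulate-and-refit the survey arm; returns per-term estimate arrays."""
    config = config or presets.warsaw_survey_config()
    estimates = {t: [] for t in terms}
    for seed in replicate_seeds(base_seed, n_replicates):
        table = simulate_survey(config, seed=seed)
        res = run_survey_model(table, weighted=weighted)
        for t in terms:
            estimates[t].append(res.ols.beta[t])
    return {
        "estimates": {t: np.array(v) for t, v in estimates.items()},
        "truth": {t: config.beta[t] for t in terms},
    }
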
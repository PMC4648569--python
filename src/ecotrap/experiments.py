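"""Scenario suites, replicate batches, and the statistical analyses.

Replicate batches run the simulator over derived per-replicate seeds (a
counter-based scheme off the master seed, so different scenarios can be
compared under matched seeds) and summarise the population growth rate R
and the allele-frequency change rate G as mean +- SD.  The analyses mirror
the original workflow: ordinary least squares with classical t-tests of the
spatial attributes against R, Spearman rank correlation for collinearity
screening, and a +-3% one-at-a-time sensitivity analysis of the fixed
parameters.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
import statsmodels.api as sm

from .landscape import (GridMap, ScenarioSpec, SpatialMetrics, Species,
                        compute_spatial_metrics, generate_scenario_map)
from .simulator import SimConfig, Trajectory, geometric_rate, run_simulation

__all__ = [
    "SuiteSpec", "ScenarioResult", "build_scenario_suite", "run_replicates",
    "ols_t_test", "spearman_rho", "sensitivity_analysis", "replicate_seed",
]


@dataclass
class SuiteSpec:
    """A labelled entry of a scenario suite; 'observed' keeps the base map's
    non-native layer, 'no_thlaspi' strips it, the rest delegate to the
    landscape scenario generator."""

    label: str
    mode: str  # observed | no_thlaspi | squares | elongated | scatter | enlarge
    cover: float = 0.0
    patch_count: int = 1
    placement_natives: str = "base"
    placement_mutual: str = "base"
    min_spacing: int = 2
    aspect: float = 16.0


@dataclass
class ScenarioResult:
    label: str
    metrics: SpatialMetrics
    mean_R: float
    sd_R: float
    mean_G: float
    sd_G: float
    replicates: int
    R: np.ndarray = field(repr=False, default=None)
    G: np.ndarray = field(repr=False, default=None)

    def as_row(self) -> dict:
        row = {"label": self.label}
        row.update(self.metrics.as_dict())
        row.update(mean_R=self.mean_R, sd_R=self.sd_R,
                   mean_G=self.mean_G, sd_G=self.sd_G,
                   replicates=self.replicates)
        return row


def build_scenario_suite(base: GridMap, specs, seed=0):
    """Realise one map per suite entry; infeasible entries are skipped with a
    warning.  Returns [(SuiteSpec, GridMap, SpatialMetrics), ...]."""
    out = []
    rng = np.random.default_rng(seed)
    if not base.native_mask.any():
        raise ValueError("suite base map has no native hosts")
    for spec in specs:
        try:
            if spec.mode == "observed":
                gmap = base.copy()
            elif spec.mode == "no_thlaspi":
                gmap = base.copy()
                gmap.host[gmap.thlaspi_mask] = Species.NONE
            else:
                gspec = ScenarioSpec(
                    mode=spec.mode, cover=spec.cover, patch_count=spec.patch_count,
                    placement_natives=spec.placement_natives,
                    placement_mutual=spec.placement_mutual,
                    min_spacing=spec.min_spacing, aspect=spec.aspect,
                    label=spec.label)
                gmap = generate_scenario_map(base, gspec, rng)
        except ValueError as err:
            warnings.warn(f"scenario {spec.label!r} skipped: {err}")
            continue
        out.append((spec, gmap, compute_spatial_metrics(gmap)))
    return out


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Counter-based per-replicate seed (< 2^31), matched across scenarios."""
    ss = np.random.SeedSequence([int(master_seed), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def run_replicates(gmap: GridMap, config: SimConfig,
                   replicates: int | None = None,
                   label: str = "") -> ScenarioResult:
    """Replicate batch of run_simulation; summarises R and G as mean +- SD.

    Replicates with an undefined rate (immediate extinction) are excluded
    from the mean; with a single replicate the SDs are NaN.
    """
    reps = int(replicates if replicates is not None else config.replicates)
    Rs = np.empty(reps)
    Gs = np.empty(reps)
    for i in range(reps):
        cfg = config.replace(seed=replicate_seed(config.seed, i))
        traj = run_simulation(gmap, cfg)
        Rs[i] = traj.R
        Gs[i] = traj.G
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_R, mean_G = float(np.nanmean(Rs)), float(np.nanmean(Gs))
        sd_R = float(np.nanstd(Rs, ddof=1)) if reps > 1 else math.nan
        sd_G = float(np.nanstd(Gs, ddof=1)) if reps > 1 else math.nan
    return ScenarioResult(label=label, metrics=compute_spatial_metrics(gmap),
                          mean_R=mean_R, sd_R=sd_R, mean_G=mean_G, sd_G=sd_G,
                          replicates=reps, R=Rs, G=Gs)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def ols_t_test(response, predictors: pd.DataFrame, add_intercept: bool = True
               ) -> pd.DataFrame:
    """OLS with classical SEs and two-sided t-tests per predictor.

    Returns a DataFrame indexed by predictor name with columns
    coefficient / se / t / p.  A rank-deficient design raises a ValueError
    naming the collinear columns.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = np.asarray(response, dtype=float)
    if len(y) < X.shape[1] + 2:
        raise ValueError("not enough rows for the requested predictors")
    M = sm.add_constant(X) if add_intercept else X
    rank = np.linalg.matrix_rank(M.to_numpy())
    if rank < M.shape[1]:
        # name the columns involved: those whose residual on the others is ~0
        bad = []
        arr = M.to_numpy()
        for j, name in enumerate(M.columns):
            others = np.delete(arr, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, arr[:, j], rcond=None)
            if np.allclose(others @ beta, arr[:, j], atol=1e-10):
                bad.append(str(name))
        raise ValueError(f"singular design; collinear columns: {bad}")
    fit = sm.OLS(y, M).fit()
    out = pd.DataFrame({
        "coefficient": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })
    if add_intercept:
        out = out.drop(index="const")
    return out


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) and its p-value via
    the t approximation; a constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    res = _sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

#: parameter name -> how to apply a relative perturbation to the config
_SENSITIVITY_PARAMS = (
    "lifespan", "immigration", "ovi_prob", "initial_allele_frequency",
    "juvenile_survival", "initial_size",
)


def _perturbed_config(config: SimConfig, name: str, factor: float) -> SimConfig:
    p = config.params
    if name == "lifespan":
        return config.replace(params=p.replace(lifespan_mu=p.lifespan_mu * factor))
    if name == "immigration":
        return config.replace(params=p.replace(immigration_rate=p.immigration_rate * factor))
    if name == "ovi_prob":
        return config.replace(params=p.replace(ovi_prob=min(p.ovi_prob * factor, 1.0)))
    if name == "initial_allele_frequency":
        return config.replace(p0=min(config.p0 * factor, 1.0))
    if name == "juvenile_survival":
        return config.replace(params=p.replace(
            juvenile_survival_native=p.juvenile_survival_native * factor))
    if name == "initial_size":
        return config.replace(initial_females=round(config.initial_females * factor))
    raise ValueError(f"unknown sensitivity parameter {name!r}")


def sensitivity_analysis(base_config: SimConfig, gmap: GridMap,
                         params=_SENSITIVITY_PARAMS, delta: float = 0.03,
                         replicates: int = 50, generations: int = 30,
                         initial_females: int = 50) -> pd.DataFrame:
    """One-at-a-time +-delta perturbation of the fixed parameters.

    Each condition runs `replicates` x `generations` from `initial_females`
    females (the initial-size condition perturbs that count, rounded to the
    nearest integer) and reports mean and SD of R and G, plus the
    unperturbed baseline.
    """
    base = base_config.replace(initial_females=initial_females,
                               generations=generations)
    rows = []

    def record(label, cfg):
        res = run_replicates(gmap, cfg, replicates=replicates, label=label)
        rows.append({"parameter": label, "mean_R": res.mean_R, "sd_R": res.sd_R,
                     "mean_G": res.mean_G, "sd_G": res.sd_G,
                     "replicates": res.replicates})

    record("baseline", base)
    for name in params:
        for sign, tag in ((1.0 + delta, "+"), (1.0 - delta, "-")):
            record(f"{name}{tag}", _perturbed_config(base, name, sign))
    return pd.DataFrame(rows)
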
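"""Group-comparison statistics and the end-to-end cohort pipeline.

Significance is two-sided at exactly p < 0.05; no correction is applied
across cohort metrics (each figure-level comparison stands alone).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cfc, rhythmicity, spectral
from .signal_core import BandSpec, Trace
from .synthetic_data import SyntheticLFPSpec, generate_coupled_lfp

__all__ = [
    "GroupComparison", "CohortConfig", "CohortReport",
    "two_tailed_t", "mann_whitney", "anova2_bonferroni",
    "analyze_recording", "run_cohort", "COHORT_METRICS",
]

ALPHA = 0.05

COHORT_METRICS = (
    "strength_percent", "peak_sd", "theta_freq_hz", "theta_power",
    "sg_peak_mi", "fg_peak_mi", "sg_power", "fg_power",
)


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    mean_sem_a: tuple[float, float]
    mean_sem_b: tuple[float, float]
    test: str
    statistic: float
    p_value: float
    significant: bool

    def as_row(self) -> dict:
        return {
            "metric": self.metric_name, "test": self.test,
            "mean_a": self.mean_sem_a[0], "sem_a": self.mean_sem_a[1],
            "mean_b": self.mean_sem_b[0], "sem_b": self.mean_sem_b[1],
            "statistic": self.statistic, "p_value": self.p_value,
            "significant": self.significant,
        }


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")
    return float(x.mean()), sem


def _build(metric: str, a, b, test: str, stat: float, p: float) -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return GroupComparison(metric, a, b, _mean_sem(a), _mean_sem(b),
                           test, float(stat), float(p), bool(p < ALPHA))


def two_tailed_t(a, b, metric_name: str = "", welch: bool = False) -> GroupComparison:
    """Two-sided independent-samples t test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return _build(metric_name, a, b, "t", 0.0, 1.0)
        return _build(metric_name, a, b, "t", float("inf"), 0.0)
    stat, p = sps.ttest_ind(a, b, equal_var=not welch)
    return _build(metric_name, a, b, "t", stat, p)


def mann_whitney(a, b, metric_name: str = "", exact_max_n: int = 8) -> GroupComparison:
    """Two-sided Mann-Whitney U; exact p for small tie-free samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return _build(metric_name, a, b, "mann_whitney", a.size * b.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if (a.size <= exact_max_n and b.size <= exact_max_n
                          and not has_ties) else "asymptotic")
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return _build(metric_name, a, b, "mann_whitney", stat, p)


def anova2_bonferroni(data: pd.DataFrame, group_col: str = "group",
                      level_col: str = "level", value_col: str = "value",
                      ) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Two-factor ANOVA with interaction + Bonferroni per-level tests.

    ``data`` is long-form with a two-group factor and a level factor.
    Returns the ANOVA table and per-level two-group comparisons whose p
    values are Bonferroni-adjusted by the number of levels.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col, need in ((group_col, 2), (level_col, 2)):
        if data[col].nunique() < need:
            raise ValueError(f"factor {col!r} needs >= {need} levels")
    df = data.rename(columns={group_col: "g", level_col: "lv", value_col: "y"})
    model = ols("y ~ C(g) * C(lv)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    groups = sorted(df["g"].unique())
    levels = sorted(df["lv"].unique())
    comparisons = []
    for lv in levels:
        sub = df[df["lv"] == lv]
        a = sub[sub["g"] == groups[0]]["y"].to_numpy()
        b = sub[sub["g"] == groups[1]]["y"].to_numpy()
        raw = two_tailed_t(a, b, metric_name=str(lv))
        p_adj = min(1.0, raw.p_value * len(levels))
        comparisons.append(replace(raw, p_value=p_adj, significant=p_adj < ALPHA))
    return table, comparisons


# ---------------------------------------------------------------------------
# cohort pipeline


@dataclass(frozen=True)
class CohortConfig:
    control: SyntheticLFPSpec
    mutant: SyntheticLFPSpec
    n_per_group: int = 10
    master_seed: int = 0
    test: str = "t"                       # "t" or "mann_whitney"
    animal_amp_cv: float = 0.2            # between-animal amplitude variability
    animal_freq_sd_hz: float = 0.4        # between-animal theta-frequency spread
    theta_band: BandSpec = BandSpec(3.0, 8.0)
    sg_band: BandSpec = BandSpec(25.0, 45.0)
    fg_band: BandSpec = BandSpec(150.0, 250.0)

    def config_hash(self) -> str:
        blob = json.dumps({"control": asdict(self.control),
                           "mutant": asdict(self.mutant),
                           "n": self.n_per_group, "seed": self.master_seed,
                           "test": self.test},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CohortReport:
    table: pd.DataFrame                   # per-animal metrics
    comparisons: list[GroupComparison]
    config_hash: str
    seeds: dict[str, list[int]]

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.comparisons])

    def significance_pattern(self) -> dict[str, bool]:
        return {c.metric_name: c.significant for c in self.comparisons}


def analyze_recording(trace: Trace, theta_band: BandSpec = BandSpec(3.0, 8.0),
                      sg_band: BandSpec = BandSpec(25.0, 45.0),
                      fg_band: BandSpec = BandSpec(150.0, 250.0),
                      decimate_to_hz: float | None = 1250.0) -> dict[str, float]:
    """The eight per-recording metrics of the field-potential figures."""
    rhythm, wave = rhythmicity.analyze_rhythmicity(trace, theta_band)
    theta_power = spectral.band_power_bins(trace, theta_band).mean_power
    sg_power = spectral.band_power_bins(trace, sg_band).mean_power
    fg_power = spectral.band_power_bins(trace, fg_band).mean_power
    lo = min(sg_band.lo_hz, fg_band.lo_hz)
    hi = max(sg_band.hi_hz, fg_band.hi_hz)
    com = cfc.comodulogram(trace, amp_lo=lo, amp_hi=hi, n_surrogates=0,
                           theta_search=theta_band, decimate_to_hz=decimate_to_hz)
    return {
        "strength_percent": rhythm.strength_percent,
        "peak_sd": wave.peak_sd,
        "theta_freq_hz": rhythm.theta_freq_hz,
        "theta_power": theta_power,
        "sg_peak_mi": cfc.band_peak(com, sg_band).peak_mi,
        "fg_peak_mi": cfc.band_peak(com, fg_band).peak_mi,
        "sg_power": sg_power,
        "fg_power": fg_power,
    }


def _jittered_spec(spec: SyntheticLFPSpec, rng: np.random.Generator,
                   amp_cv: float, freq_sd_hz: float) -> SyntheticLFPSpec:
    """Per-animal biological variability around the group spec."""
    import math

    from .synthetic_data import GammaComponent

    def _gain() -> float:
        if amp_cv <= 0:
            return 1.0
        s2 = math.log(1 + amp_cv**2)
        return float(rng.lognormal(-s2 / 2, math.sqrt(s2)))

    freq = spec.theta_freq_hz + (rng.normal(0, freq_sd_hz) if freq_sd_hz > 0 else 0.0)
    freq = float(np.clip(freq, 3.5, 7.5))
    gammas = tuple(GammaComponent(g.center_freq_hz, g.bandwidth_hz,
                                  g.base_amp * _gain(), g.coupling_kappa,
                                  g.preferred_phase_deg)
                   for g in spec.gamma_components)
    return replace(spec, theta_freq_hz=freq, theta_amp=spec.theta_amp * _gain(),
                   noise_amp=spec.noise_amp * _gain(), gamma_components=gammas)


def run_cohort(config: CohortConfig) -> CohortReport:
    """Simulate two groups, analyze every animal, compare all metrics.

    Each animal is an independent draw around its group spec (amplitude
    and theta-frequency jitter emulate between-animal variability).  The
    jitter draws are paired across groups (animal k in either group gets
    the same biological parameters, littermate style), so matched
    metrics differ between groups only through the recordings
    themselves, not through the luck of the parameter draws.  Fully
    reproducible: per-animal seeds are drawn from the master seed via
    ``SeedSequence`` and recorded in the report.
    """
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(2 * config.n_per_group)
    seeds = [int(c.generate_state(1)[0]) for c in children]
    rows = []
    seed_log: dict[str, list[int]] = {"control": [], "mutant": []}
    for gi, (name, spec) in enumerate((("control", config.control),
                                       ("mutant", config.mutant))):
        for k in range(config.n_per_group):
            seed = seeds[gi * config.n_per_group + k]
            seed_log[name].append(seed)
            jitter_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.master_seed, spawn_key=(2, k)))
            animal = _jittered_spec(spec, jitter_rng, config.animal_amp_cv,
                                    config.animal_freq_sd_hz)
            trace = generate_coupled_lfp(replace(animal, seed=seed))
            metrics = analyze_recording(trace, config.theta_band,
                                        config.sg_band, config.fg_band)
            rows.append({"group": name, "animal": k, "seed": seed, **metrics})
    table = pd.DataFrame(rows)
    test_fn = two_tailed_t if config.test == "t" else mann_whitney
    comparisons = []
    for metric in COHORT_METRICS:
        a = table[table["group"] == "control"][metric].to_numpy()
        b = table[table["group"] == "mutant"][metric].to_numpy()
        comparisons.append(test_fn(a, b, metric_name=metric))
    return CohortReport(table, comparisons, config.config_hash(), seed_log)
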
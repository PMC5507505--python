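"""Forward simulator of prenatal deciduous-incisor enamel growth.

The generative model mirrors what the measurement pipeline assumes about
real crowns:

* crown initiation uniform over gestational days 91-140 (weeks 13-20);
* gestation ~ Normal(273, 7) truncated at >= 259 days for full-term
  births, uniform over 196-258 days for pre-term ones (37 weeks = 259
  days is the standard obstetric cut);
* enamel extension rate decaying exponentially to an asymptote,
  EER(t) = E_inf + (E0 - E_inf) exp(-t / tau), so EDJ growth decelerates
  sharply after the cuspal phase;
* daily secretion rate nearly constant at the EDJ, accelerating linearly
  with relative depth w toward the outer surface,
  d(w) = d_edj (1 + gradient * w), and tapering in the cervical-most 10%
  of the EDJ;
* a neonatal line only when the individual survived birth by at least
  ~10 days;
* two observers recounting each segment with additive Gaussian day noise.

Ground truth (:class:`GrowthTruth`) is kept alongside each simulated
:class:`ToothRecord` so estimator and classifier recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cft_estimators import OriginRegressionModel, PcftEstimate
from .enamel_data import EDJInterval, PrismSegment, ToothRecord
from .term_classification import PRETERM, GestationModel, classify_term

__all__ = [
    "TruthConfig",
    "GrowthTruth",
    "MeasurementConfig",
    "RecoveryReport",
    "simulate_tooth",
    "observe_tooth",
    "simulate_cohort",
    "recovery_report",
]

PRETERM_GESTATION_CUT_DAYS = 259.0  # 37 weeks


@dataclass(frozen=True)
class TruthConfig:
    """Population-level parameters of the growth simulator."""

    initiation_min_days: float = 91.0
    initiation_max_days: float = 140.0
    gestation_days: float | None = None  # None -> draw full-term Normal(273, 7) >= 259
    gestation_mean_days: float = 273.0
    gestation_sd_days: float = 7.0
    # EER curve: E0 at initiation, asymptote E_inf, time constant tau.
    eer_e0_um_day: float = 80.0
    eer_einf_um_day: float = 25.0
    eer_tau_days: float = 40.0
    # DSR field: rate at the EDJ, fractional acceleration toward the surface,
    # fractional slow-down over the cervical-most 10% of the EDJ.
    dsr_edj_um_day: float = 4.0
    dsr_outer_gradient: float = 0.25
    dsr_cervical_taper: float = 0.20
    # Survival after birth: an NL forms only with >= nl_min_survival days.
    nl_fraction: float = 5.0 / 18.0
    nl_min_survival_days: float = 10.0
    survivor_max_days: float = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.initiation_min_days < self.initiation_max_days):
            raise ValueError("invalid initiation window")
        if not (self.eer_e0_um_day >= self.eer_einf_um_day > 0):
            raise ValueError("require E0 >= E_inf > 0")
        if self.eer_tau_days <= 0 or self.dsr_edj_um_day <= 0:
            raise ValueError("tau and d_edj must be positive")


@dataclass(frozen=True)
class GrowthTruth:
    """Ground truth of one simulated crown."""

    tooth_id: str
    initiation_gestation_day: float
    gestation_days: float
    death_offset_days: float
    eer_params: tuple[float, float, float]  # (E0, E_inf, tau)
    dsr_params: tuple[float, float, float]  # (d_edj, outer_gradient, cervical_taper)
    nl_formed: bool

    @property
    def true_pcft_days(self) -> float:
        return self.gestation_days - self.initiation_gestation_day

    @property
    def is_preterm(self) -> bool:
        return self.gestation_days < PRETERM_GESTATION_CUT_DAYS

    def eer_at(self, t: "np.ndarray | float") -> np.ndarray:
        e0, einf, tau = self.eer_params
        return einf + (e0 - einf) * np.exp(-np.asarray(t, dtype=float) / tau)

    def edj_length_at(self, t: "np.ndarray | float", step: float = 0.1) -> np.ndarray:
        """Cumulative EDJ length: integral of EER from 0 to t.

        Fixed-step trapezoid (0.1 day); exact closed form when E0 == E_inf.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        e0, einf, tau = self.eer_params
        if e0 == einf:
            return e0 * t
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            grid = np.arange(0.0, ti + step, step)
            grid[-1] = ti
            out[i] = np.trapezoid(self.eer_at(grid), grid)
        return out

    def dsr_at(self, depth_fraction: "np.ndarray | float", edj_fraction: "np.ndarray | float" = 0.0) -> np.ndarray:
        """Secretion rate at relative depth w in [0,1] and EDJ fraction."""
        d_edj, gradient, taper = self.dsr_params
        w = np.asarray(depth_fraction, dtype=float)
        f = np.asarray(edj_fraction, dtype=float)
        rate = d_edj * (1.0 + gradient * w)
        cervical = np.clip((f - 0.9) / 0.1, 0.0, 1.0)
        return rate * (1.0 - taper * cervical)


@dataclass(frozen=True)
class MeasurementConfig:
    """Parameters of the simulated measurement protocol."""

    max_segment_um: float = 200.0
    min_segment_um: float = 100.0
    observer_noise_sd_days: float = 1.0
    n_observers: int = 2
    edj_intervals_min: int = 3
    edj_intervals_max: int = 8
    integer_counts: bool = False

    def __post_init__(self) -> None:
        if self.max_segment_um <= 0 or self.min_segment_um <= 0:
            raise ValueError("segment lengths must be positive")
        if self.observer_noise_sd_days < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class RecoveryReport:
    slope_bias_relative: float
    pcft_rmse_days: float
    confusion: dict  # keys: true_pre_pred_pre, true_pre_pred_full, ...

    @property
    def sensitivity(self) -> float:
        tp = self.confusion["true_pre_pred_pre"]
        fn = self.confusion["true_pre_pred_full"]
        return tp / (tp + fn) if tp + fn else float("nan")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_tooth(config: TruthConfig, seed: int, tooth_id: str = "S001") -> GrowthTruth:
    """Draw one ground-truth growth history (deterministic in (config, seed))."""
    rng = np.random.default_rng(seed)
    initiation = rng.uniform(config.initiation_min_days, config.initiation_max_days)
    if config.gestation_days is not None:
        gestation = float(config.gestation_days)
    else:
        gestation = _draw_fullterm_gestation(rng, config)
    if rng.uniform() < config.nl_fraction:
        death_offset = rng.uniform(config.nl_min_survival_days, config.survivor_max_days)
    else:
        death_offset = rng.uniform(0.0, config.nl_min_survival_days - 1.0)
    return GrowthTruth(
        tooth_id=tooth_id,
        initiation_gestation_day=float(initiation),
        gestation_days=gestation,
        death_offset_days=float(death_offset),
        eer_params=(config.eer_e0_um_day, config.eer_einf_um_day, config.eer_tau_days),
        dsr_params=(config.dsr_edj_um_day, config.dsr_outer_gradient, config.dsr_cervical_taper),
        nl_formed=death_offset >= config.nl_min_survival_days,
    )


def _draw_fullterm_gestation(rng: np.random.Generator, config: TruthConfig) -> float:
    while True:
        g = rng.normal(config.gestation_mean_days, config.gestation_sd_days)
        if g >= PRETERM_GESTATION_CUT_DAYS:
            return float(g)


def observe_tooth(truth: GrowthTruth, mcfg: MeasurementConfig, seed: int) -> ToothRecord:
    """Apply the measurement protocol to a ground-truth crown.

    The prenatal formation span (shortened if death preceded birth) is
    partitioned into prism segments of at most ``max_segment_um``; each
    segment's true day span is corrupted per observer with additive
    Gaussian noise (floored at 0.5 days).  EDJ intervals partition the
    same span between simulated biological landmarks, with cumulative
    fractions of the total prenatal EDJ length.  No post-natal enamel is
    ever generated.
    """
    rng = np.random.default_rng(seed)
    T = truth.true_pcft_days + min(truth.death_offset_days, 0.0)
    T = max(T, 1.0)
    total_edj = float(truth.edj_length_at(T)[0])

    # --- EDJ intervals: landmark times spread over the span with jitter
    n_iv = int(rng.integers(mcfg.edj_intervals_min, mcfg.edj_intervals_max + 1))
    bounds = np.linspace(0.0, T, n_iv + 1)
    if n_iv > 1:
        jitter = rng.uniform(-0.3, 0.3, size=n_iv - 1) * (T / n_iv)
        bounds[1:-1] = np.sort(bounds[1:-1] + jitter)
    lengths_at = truth.edj_length_at(bounds)
    intervals = []
    for k in range(n_iv):
        intervals.append(
            EDJInterval(
                tooth_id=truth.tooth_id,
                index=k + 1,
                length_um=float(lengths_at[k + 1] - lengths_at[k]),
                days=float(bounds[k + 1] - bounds[k]),
                cum_fraction_start=float(lengths_at[k] / total_edj),
                cum_fraction_end=float(lengths_at[k + 1] / total_edj),
            )
        )

    # --- prism segments: walk the formation span in chunks <= max_segment_um
    segments = []
    t = 0.0
    k = 1
    while t < T - 1e-9:
        w = rng.uniform(0.0, 0.5)  # measurements sit in the inner enamel
        frac = float(truth.edj_length_at(t)[0] / total_edj)
        d = float(truth.dsr_at(w, frac))
        target_len = rng.uniform(mcfg.min_segment_um, mcfg.max_segment_um)
        days = target_len / d
        if t + days > T:
            days = T - t
        length = days * d
        true_days = days
        counts = []
        for _ in range(mcfg.n_observers):
            c = true_days + rng.normal(0.0, mcfg.observer_noise_sd_days)
            if mcfg.integer_counts:
                c = max(round(c), 1)
            counts.append(max(float(c), 0.5))
        segments.append(
            PrismSegment(
                tooth_id=truth.tooth_id, index=k, length_um=float(length),
                counts_by_observer=counts,
            )
        )
        t += days
        k += 1

    return ToothRecord(
        id=truth.tooth_id,
        arch="upper",
        nl_present=truth.nl_formed,
        segments=segments,
        edj_intervals=intervals,
        edj_total_um=total_edj,
    )


def simulate_cohort(
    n: int,
    preterm_fraction: float,
    truth_config: TruthConfig | None = None,
    mcfg: MeasurementConfig | None = None,
    seed: int = 0,
    stratified: bool = True,
    preterm_gestation_range: tuple[float, float] = (196.0, 258.0),
) -> tuple[list[ToothRecord], list[GrowthTruth]]:
    """Simulate a cemetery-like cohort of measured crowns with ground truth.

    With ``stratified`` (default) exactly ``round(n * preterm_fraction)``
    individuals are pre-term (gestation uniform over
    ``preterm_gestation_range``, default 196-258 days, i.e. 28-37 weeks);
    otherwise pre-term status is Bernoulli per individual.  Per-individual
    seeds are derived deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= preterm_fraction <= 1.0:
        raise ValueError("preterm_fraction must be in [0, 1]")
    truth_config = truth_config or TruthConfig()
    mcfg = mcfg or MeasurementConfig()
    rng = np.random.default_rng(seed)
    if stratified:
        n_pre = int(round(n * preterm_fraction))
        is_pre = np.zeros(n, dtype=bool)
        is_pre[rng.choice(n, size=n_pre, replace=False)] = True
    else:
        is_pre = rng.uniform(size=n) < preterm_fraction

    records, truths = [], []
    child_seeds = rng.integers(0, 2**31 - 1, size=(n, 2))
    for i in range(n):
        tid = f"S{i + 1:03d}"
        if is_pre[i]:
            lo, hi = preterm_gestation_range
            gest = float(rng.uniform(lo, min(hi, PRETERM_GESTATION_CUT_DAYS - 1.0)))
            cfg_i = replace(truth_config, gestation_days=gest)
        else:
            cfg_i = truth_config
        truth = simulate_tooth(cfg_i, int(child_seeds[i, 0]), tooth_id=tid)
        record = observe_tooth(truth, mcfg, int(child_seeds[i, 1]))
        records.append(record)
        truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# Recovery diagnostics
# ---------------------------------------------------------------------------


def recovery_report(
    truths: list[GrowthTruth],
    records: list[ToothRecord],
    estimates: list[PcftEstimate],
    model: OriginRegressionModel,
    gestation_model: GestationModel | None = None,
) -> RecoveryReport:
    """Measure estimator and classifier recovery against simulator truth.

    * slope bias: relative deviation of the fitted implied DSR (1/slope)
      from the cohort overall DSR (total measured prism length / total
      true formation days — the length-weighted harmonic pooling);
    * pCFT RMSE of the estimates against true prenatal formation times;
    * confusion matrix of the pCFT-threshold classifier against true
      gestational pre-term status (< 259 days).
    """
    if not (len(truths) == len(records) == len(estimates)):
        raise ValueError("truths, records and estimates must align")
    gestation_model = gestation_model or GestationModel()
    total_len = sum(r.total_prism_length_um for r in records)
    total_days = sum(s.count_days for r in records for s in r.segments)
    cohort_dsr = total_len / total_days
    slope_bias = (model.implied_dsr_um_day - cohort_dsr) / cohort_dsr

    err = np.array([e.days - t.true_pcft_days for e, t in zip(estimates, truths)])
    rmse = float(np.sqrt(np.mean(err**2)))

    confusion = {
        "true_pre_pred_pre": 0,
        "true_pre_pred_full": 0,
        "true_full_pred_pre": 0,
        "true_full_pred_full": 0,
    }
    for e, t in zip(estimates, truths):
        pred = classify_term(e.days, gestation_model)
        key = ("true_pre_" if t.is_preterm else "true_full_") + (
            "pred_pre" if pred == PRETERM else "pred_full"
        )
        confusion[key] += 1
    return RecoveryReport(
        slope_bias_relative=float(slope_bias), pcft_rmse_days=rmse, confusion=confusion
    )
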
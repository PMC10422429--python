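"""Energy-efficacy and operational-energy-footprint accounting.

A model's *data engineering energy footprint* A is the cumulative power
amount (kW-h, read from a plug-in power meter) spent on data curation, model
training, and evaluation.  Its *energy efficacy* is

    EFF(M, A) = λ · M / A,      λ = 100 by default,

the number of performance-metric units (M in [0, 1]) per kW-h of footprint.
The *operational energy footprint* (OEF) of a deployed monitoring pipeline
is the monthly/seasonal kW-h of its GPU node plus its on-hive video loggers,
with a month taken as 24 × 7 × 4 = 672 h and a beekeeping season as 5 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._util import round_half_away

__all__ = [
    "EnergyLedger",
    "EffInput",
    "PowerProfile",
    "energy_efficacy",
    "ledger_total",
    "monthly_model_footprint",
    "pipeline_oef",
    "labeling_rate",
]


@dataclass(frozen=True)
class EnergyLedger:
    """Cumulative power amounts (kW-h) of the data-engineering phases."""

    curation_kwh: float
    training_kwh: float
    eval_run_kwh: float      # running the trained model on evaluation videos
    eval_manual_kwh: float   # manual accuracy evaluation
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("curation_kwh", "training_kwh", "eval_run_kwh",
                     "eval_manual_kwh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EffInput:
    metric_value: float    # performance metric M in [0, 1]
    footprint_kwh: float   # data-engineering footprint A > 0
    lambda_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.footprint_kwh <= 0:
            raise ValueError("footprint must be positive")
        if self.lambda_scale <= 0:
            raise ValueError("lambda_scale must be positive")


@dataclass(frozen=True)
class PowerProfile:
    """Power rates of a deployed pipeline: one GPU node + n video loggers."""

    model_rate_kwh_per_h: float
    logger_rate_kwh_per_h: float = 0.003
    n_loggers: int = 10
    hours_per_month: float = 24 * 7 * 4  # 672
    months_per_season: int = 5

    def __post_init__(self) -> None:
        if self.model_rate_kwh_per_h < 0 or self.logger_rate_kwh_per_h < 0:
            raise ValueError("power rates must be non-negative")


def energy_efficacy(inp: EffInput) -> float:
    """EFF(M, A) = λ·M/A, unrounded (round to 2 decimals for reporting)."""
    return inp.lambda_scale * inp.metric_value / inp.footprint_kwh


def ledger_total(ledger: EnergyLedger) -> float:
    """Total data-engineering footprint A (sum of all ledger entries)."""
    return (ledger.curation_kwh + ledger.training_kwh +
            ledger.eval_run_kwh + ledger.eval_manual_kwh)


def monthly_model_footprint(profile: PowerProfile) -> float:
    """Monthly GPU-node footprint: hours_per_month × model power rate."""
    return profile.hours_per_month * profile.model_rate_kwh_per_h


def pipeline_oef(profile: PowerProfile,
                 round_per_logger: bool = True) -> tuple[float, float]:
    """Monthly and seasonal operational energy footprint of the pipeline.

    The per-logger monthly amount is rounded to 2 decimals before being
    multiplied by the logger count (matching the reported arithmetic, e.g.
    141.12 + 2.02 × 10 = 161.32); pass ``round_per_logger=False`` for the
    unrounded combination.
    """
    per_logger = profile.hours_per_month * profile.logger_rate_kwh_per_h
    if round_per_logger:
        per_logger = round_half_away(per_logger, 2)
    monthly = monthly_model_footprint(profile) + profile.n_loggers * per_logger
    seasonal = profile.months_per_season * monthly
    return (monthly, seasonal)


def labeling_rate(n_labels: int, hours: float) -> float:
    """Mean labeling rate in labels per physical hour."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    return n_labels / hours
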
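"""Synthetic data with known ground truth for every pipeline stage.

Activity records emulate running-wheel counts of a nocturnal insect: one or
two circadian components shaped as a rectangular night-activity bout with a
smooth envelope, Poisson count noise, and strong / weak / arrhythmic
regimes.  Ct series emulate a daily cosine expression rhythm sampled at six
Zeitgeber times with pooled biological replicates and technical triplicates,
plus a flat reference gene and multiplicative knockdown factors.  Clockwork
period tables are produced by simulating a known tau set, for calibration
round trips.

Every generator takes a seed and returns the ground truth alongside the
data, so round-trip tests never re-derive truth from the data themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rhythm import ActivityRecord

__all__ = [
    "ActivityComponent",
    "ActivityGeneratorSpec",
    "CtGeneratorSpec",
    "generate_activity",
    "generate_ct_series",
    "generate_clockwork_targets",
    "STRONG_AMPLITUDE",
    "WEAK_AMPLITUDE_FACTOR",
]

#: counts per bin at the bout peak for a strongly rhythmic animal
STRONG_AMPLITUDE = 60.0
#: weak regime amplitude relative to strong
WEAK_AMPLITUDE_FACTOR = 0.25


@dataclass(frozen=True)
class ActivityComponent:
    """One rhythmic component of a locomotor pattern."""

    period: float  # hours, within the circadian range
    amplitude: float  # peak counts per bin added by this component
    phase: float = 12.0  # activity-onset time within the cycle (hours)

    def __post_init__(self) -> None:
        if not 10.0 < self.period < 40.0:
            raise ValueError("component periods must lie in (10, 40) h")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class ActivityGeneratorSpec:
    """Recipe for a synthetic running-wheel record."""

    components: tuple[ActivityComponent, ...]
    baseline: float = 2.0  # counts per bin of aperiodic background
    duty_cycle: float = 0.5  # fraction of each cycle spent active (night bout)
    days: float = 10.0
    bin_width: float = 0.1  # hours (6 min)
    regime: str = "strong"  # strong | weak | arrhythmic
    poisson_noise: bool = True  # False gives the rounded noiseless rate (test fixtures)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if self.regime not in ("strong", "weak", "arrhythmic"):
            raise ValueError("regime must be strong, weak or arrhythmic")
        if self.regime == "arrhythmic" and any(c.amplitude != 0 for c in self.components):
            raise ValueError("arrhythmic regime requires zero-amplitude components")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty cycle must be in (0, 1]")
        if self.baseline < 0 or self.days <= 0 or self.bin_width <= 0:
            raise ValueError("baseline, days and bin width must be positive")


def strong_spec(periods=(24.0,), days: float = 10.0, seed: int = 0, **kw) -> ActivityGeneratorSpec:
    comps = tuple(ActivityComponent(p, STRONG_AMPLITUDE) for p in periods)
    return ActivityGeneratorSpec(components=comps, days=days, seed=seed, regime="strong", **kw)


def weak_spec(periods=(24.0,), days: float = 10.0, seed: int = 0, **kw) -> ActivityGeneratorSpec:
    comps = tuple(
        ActivityComponent(p, STRONG_AMPLITUDE * WEAK_AMPLITUDE_FACTOR) for p in periods
    )
    return ActivityGeneratorSpec(components=comps, days=days, seed=seed, regime="weak", **kw)


def arrhythmic_spec(days: float = 10.0, seed: int = 0, **kw) -> ActivityGeneratorSpec:
    return ActivityGeneratorSpec(
        components=(ActivityComponent(24.0, 0.0),), days=days, seed=seed, regime="arrhythmic", **kw
    )


def _component_rate(comp: ActivityComponent, t: np.ndarray, duty: float) -> np.ndarray:
    """Night-bout rate: rectangular gate over ``duty`` of the cycle times a smooth hump."""
    frac = np.mod(t - comp.phase, comp.period) / comp.period
    active = frac < duty
    envelope = np.sin(np.pi * frac / duty) ** 2
    return comp.amplitude * np.where(active, envelope, 0.0)


def generate_activity(spec: ActivityGeneratorSpec) -> tuple[ActivityRecord, dict]:
    """Poisson running-wheel counts plus the ground truth used to build them.

    Returns the record and a dict with the true component periods, the regime
    label, and the noiseless rate per bin.
    """
    n = int(round(spec.days * 24.0 / spec.bin_width))
    t = np.arange(n) * spec.bin_width
    rate = np.full(n, float(spec.baseline))
    for comp in spec.components:
        rate += _component_rate(comp, t, spec.duty_cycle)
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(rate)
    else:
        counts = np.round(rate).astype(int)
    record = ActivityRecord(
        times=t,
        counts=counts,
        bin_width=spec.bin_width,
        metadata={"regime": spec.regime, "seed": spec.seed},
    )
    truth = {
        "periods": tuple(c.period for c in spec.components if c.amplitude > 0),
        "regime": spec.regime,
        "rate": rate,
    }
    return record, truth


@dataclass(frozen=True)
class CtGeneratorSpec:
    """Recipe for a control + knockdown qPCR experiment on one gene of interest.

    The gene's dCt follows ``mesor - amplitude * cos(2 pi (ZT - peak_zt) / 24)``
    so expression peaks at ``peak_zt``; a knockdown multiplies expression by
    ``knockdown_factor``, i.e. adds ``log2(1 / factor)`` cycles to the Ct.
    """

    gene: str = "per"
    reference_gene: str = "rpl18"
    mesor_ct: float = 24.0  # gene-of-interest Ct at the rhythm midline
    amplitude_ct: float = 1.0  # Ct units; 1 cycle = 2-fold expression range
    peak_zt: float = 12.0
    reference_ct: float = 20.0
    knockdown_factor: float = 1.0  # (0, 1]; 1 = no knockdown
    zts: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    pools_per_zt: int = 3
    technical_replicates: int = 3
    ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.knockdown_factor <= 1:
            raise ValueError("knockdown factor must lie in (0, 1]")
        if self.pools_per_zt < 1 or self.technical_replicates < 1:
            raise ValueError("need at least one pool and one replicate")
        if self.ct_noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def generate_ct_series(spec: CtGeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Ct table (control and knockdown groups) plus ground truth.

    Expression peaks make the Ct LOW, so the gene's Ct is
    ``mesor + amplitude*cos(...)`` shifted to dip at ``peak_zt``; the
    knockdown group's gene-of-interest Ct gains ``log2(1/factor)`` cycles.
    The reference gene is flat in both groups.  Output columns: sample, gene,
    group, zt, ct.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    kd_shift = float(np.log2(1.0 / spec.knockdown_factor))
    for group, shift in (("control", 0.0), ("knockdown", kd_shift)):
        for zt in spec.zts:
            # high expression at the peak means fewer cycles to threshold: the Ct dips there
            goi_mean = (
                spec.mesor_ct
                - spec.amplitude_ct * np.cos(2 * np.pi * (zt - spec.peak_zt) / 24.0)
                + shift
            )
            for pool in range(spec.pools_per_zt):
                sample = f"{group}_zt{zt:g}_pool{pool + 1}"
                goi_pool = goi_mean + rng.normal(0.0, spec.ct_noise_sd)
                ref_pool = spec.reference_ct + rng.normal(0.0, spec.ct_noise_sd)
                for _ in range(spec.technical_replicates):
                    rows.append(
                        (sample, spec.gene, group, zt,
                         goi_pool + rng.normal(0.0, spec.ct_noise_sd / 2))
                    )
                    rows.append(
                        (sample, spec.reference_gene, group, zt,
                         ref_pool + rng.normal(0.0, spec.ct_noise_sd / 2))
                    )
    table = pd.DataFrame(rows, columns=["sample", "gene", "group", "zt", "ct"])
    truth = {
        "knockdown_factor": spec.knockdown_factor,
        "peak_zt": spec.peak_zt,
        "trough_zt": (spec.peak_zt + 12.0) % 24.0,
        "amplitude_ct": spec.amplitude_ct,
    }
    return table, truth


def generate_clockwork_targets(
    tau_Le,
    tau_La,
    scenarios=("nominal", "PER", "TIM1", "CRY2"),
    duration: float = 500.0,
    transient: float = 200.0,
    sample_step: float = 0.02,
) -> dict[str, float]:
    """Scenario periods of a clockwork with a KNOWN tau set (calibration oracle).

    Builds the nominal model from the given scale factors, applies each named
    knockdown, and returns the estimated K(t) period per scenario.
    """
    from .clockwork import build_nominal_clockwork, scenario_period

    model = build_nominal_clockwork(tau_Le, tau_La)
    out = {}
    for s in scenarios:
        gene = None if s == "nominal" else s
        out[s] = scenario_period(
            model, gene, duration=duration, transient=transient, sample_step=sample_step
        ).period
    return out
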
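"""Synthetic study-shaped data with known ground truth.

Generates every input the profiling pipeline consumes:

* cytometry event tables — a mixture of log-normal marker populations per
  donor x condition, with CAR/C7R transduction sampled per configured
  fraction and the true population label carried as hidden annotation;
* serial killing-assay GFP-area time series — per-round exponential tumor
  growth/kill dynamics with re-challenge resets, effector:target scaling and
  multiplicative per-round potency decay;
* post-treatment correlates — cytokine panels on the {pre, 3 h, week 1,
  week 2, week 4} grid driven by a per-patient latent product factor, and
  qPCR transgene-persistence curves (peak then exponential decay).

Because the generators expose their ground truth (population labels, latent
factors, kill rates), every downstream stage can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cartprofiler.io import EventTable

__all__ = [
    "PopulationSpec",
    "DonorSpec",
    "CohortConfig",
    "KillingParams",
    "CorrelateSet",
    "MARKER_PANEL",
    "TIMEPOINTS",
    "TIMEPOINT_DAYS",
    "OUTCOME_LEVELS",
    "DEFAULT_ET_SCALING",
    "default_populations",
    "default_cohort",
    "generate_event_tables",
    "generate_killing_series",
    "generate_correlates",
    "write_killing_csv",
    "write_correlates_csv",
]

# 33-marker extracellular/intracellular T cell panel (memory differentiation,
# activation, exhaustion checkpoints, cytokines, cytotoxicity, transgenes).
MARKER_PANEL: tuple[str, ...] = (
    "CD45RA", "CD25", "CD26", "CD103", "CD4", "CD8", "CCR7", "14g2a", "CD34",
    "CTLA-4", "TIM-3", "CCR6", "PD-1", "CD3", "BTLA", "TIGIT", "CCR4",
    "HLA-DR", "CD95", "CXCR3", "IL-4", "IFN-g", "CD154", "IL-2", "IL-17A",
    "Ki-67", "LAG-3", "GrzB", "BCL-2", "CD137", "IL-22", "TNF-a", "Viability",
)

# ordinal clinical outcome: progressive < stable < partial response
OUTCOME_LEVELS: dict[str, int] = {"PD": 0, "SD": 1, "PR": 2}

TIMEPOINTS: tuple[str, ...] = ("pre", "3h", "wk1", "wk2", "wk4")
TIMEPOINT_DAYS: dict[str, float] = {"pre": 0.0, "3h": 0.125, "wk1": 7.0, "wk2": 14.0, "wk4": 28.0}

DEFAULT_ET_SCALING: dict[str, float] = {"2:1": 2.0, "1:1": 1.0, "1:2": 0.5, "1:6": 1.0 / 6.0}


@dataclass
class PopulationSpec:
    """One latent cell population of the event mixture.

    Marker intensities are drawn log-normally: ``exp(N(log_mean, log_sd))``
    on the raw intensity scale.  ``activation_shift`` is added to the
    log-mean only in the stimulated condition (0 = no stimulation response).
    """

    name: str
    weight: float
    marker_log_mean: Mapping[str, float]
    marker_log_sd: Mapping[str, float] | float = 0.25
    activation_shift: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("population weight must be >= 0")
        sds = self.marker_log_sd.values() if isinstance(self.marker_log_sd, Mapping) else [self.marker_log_sd]
        if any(s <= 0 for s in sds):
            raise ValueError("marker_log_sd must be > 0")

    def log_sd(self, marker: str) -> float:
        if isinstance(self.marker_log_sd, Mapping):
            return float(self.marker_log_sd.get(marker, 0.25))
        return float(self.marker_log_sd)


@dataclass(frozen=True)
class DonorSpec:
    """A clinical product: label, construct group, ordinal outcome."""

    label: str
    group: str = "C7R"  # "GD2" (CAR only) or "C7R" (CAR + C7R)
    outcome: str = "SD"  # PD | SD | PR

    def __post_init__(self) -> None:
        if self.group not in ("GD2", "C7R"):
            raise ValueError("group must be 'GD2' or 'C7R'")
        if self.outcome not in OUTCOME_LEVELS:
            raise ValueError(f"outcome must be one of {sorted(OUTCOME_LEVELS)}")


@dataclass
class CohortConfig:
    """Cohort layout and per-sample event budget for the event generator."""

    donors: Sequence[DonorSpec]
    conditions: Sequence[str] = ("unstimulated", "stimulated")
    events_per_sample: int = 5000
    car_positive_fraction: float = 0.5671
    c7r_positive_fraction: float = 0.2307
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_sample <= 0:
            raise ValueError("events_per_sample must be > 0")
        for frac in (self.car_positive_fraction, self.c7r_positive_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("transduction fractions must lie in [0, 1]")


def default_cohort(events_per_sample: int = 5000, seed: int = 0) -> CohortConfig:
    """Ten products: three CAR-only (all PD) and seven with C7R (mixed outcome)."""
    donors = [
        DonorSpec("9875", "GD2", "PD"),
        DonorSpec("10018", "GD2", "PD"),
        DonorSpec("10068", "GD2", "PD"),
        DonorSpec("10322", "C7R", "SD"),
        DonorSpec("10454", "C7R", "SD"),
        DonorSpec("10577", "C7R", "SD"),
        DonorSpec("10646", "C7R", "PR"),
        DonorSpec("10704", "C7R", "SD"),
        DonorSpec("10750", "C7R", "PD"),
        DonorSpec("10801", "C7R", "SD"),
    ]
    return CohortConfig(donors=donors, events_per_sample=events_per_sample, seed=seed)


def default_populations(
    n_populations: int = 5,
    markers: Sequence[str] = MARKER_PANEL,
    separation: float = 3.5,
    log_sd: float = 0.25,
    seed: int = 7,
) -> list[PopulationSpec]:
    """Well-separated synthetic populations over the marker panel.

    Each population gets a distinct log-mean profile with centroids
    ``separation`` standard deviations apart on a few discriminating markers,
    chosen for separability rather than fidelity to any clinical product.
    """
    rng = np.random.default_rng(seed)
    base = 4.0
    weights = rng.dirichlet(np.full(n_populations, 6.0))
    pops = []
    functional = [m for m in markers if m not in ("14g2a", "CD34", "Time")]
    for i in range(n_populations):
        log_mean = {m: base + rng.normal(0.0, 0.3) for m in markers}
        # give each population an exclusive high block of markers
        block = functional[(i * 4) % len(functional):(i * 4) % len(functional) + 4]
        for m in block:
            log_mean[m] = base + separation * log_sd * (2.0 + i * 0.2)
        shift = {"CD137": 0.8, "IFN-g": 0.8, "TNF-a": 0.6, "HLA-DR": 0.5}
        pops.append(
            PopulationSpec(
                name=f"pop{i + 1}",
                weight=float(weights[i]),
                marker_log_mean=log_mean,
                marker_log_sd=log_sd,
                activation_shift=shift,
            )
        )
    total = sum(p.weight for p in pops)
    for p in pops:
        p.weight /= total
    return pops


def _sample_population(
    pop: PopulationSpec,
    n: int,
    markers: Sequence[str],
    stimulated: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        mu = float(pop.marker_log_mean.get(m, 4.0))
        if stimulated:
            mu += float(pop.activation_shift.get(m, 0.0))
        out[:, j] = np.exp(rng.normal(mu, pop.log_sd(m), size=n))
    return out


# log-mean separation between transgene-negative and -positive events on the
# detection channels (14g2a for the CAR, CD34 for the C7R)
_TRANSGENE_NEG_MU, _TRANSGENE_POS_MU = 2.0, 6.0


def generate_event_tables(
    cohort: CohortConfig,
    populations: Sequence[PopulationSpec],
    markers: Sequence[str] = MARKER_PANEL,
) -> list[EventTable]:
    """One event table per donor x condition.

    Events are drawn from the population mixture (weights renormalized to sum
    to one); CAR (14g2a) and C7R (CD34) positivity are sampled independently
    per event at the configured fractions and expressed as a bimodal shift on
    the detection channels.  True population labels and transgene calls live
    in ``table.truth``, invisible to gating and clustering.
    """
    if len(populations) == 0:
        raise ValueError("at least one population must be specified")
    weights = np.array([p.weight for p in populations], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("population weights must sum to a positive value")
    weights = weights / weights.sum()

    ss = np.random.SeedSequence(cohort.seed)
    tables: list[EventTable] = []
    for donor in cohort.donors:
        for condition in cohort.conditions:
            rng = np.random.default_rng(ss.spawn(1)[0])
            n = cohort.events_per_sample
            counts = rng.multinomial(n, weights)
            blocks, labels = [], []
            for pop, k in zip(populations, counts):
                if k == 0:
                    continue
                blocks.append(_sample_population(pop, k, markers, condition == "stimulated", rng))
                labels.extend([pop.name] * k)
            data = np.vstack(blocks)
            order = rng.permutation(n)
            data = data[order]
            labels = np.asarray(labels, dtype=object)[order]

            car_pos = rng.random(n) < cohort.car_positive_fraction
            c7r_frac = cohort.c7r_positive_fraction if donor.group == "C7R" else 0.0
            c7r_pos = rng.random(n) < c7r_frac
            cols = list(markers)
            for channel, pos in (("14g2a", car_pos), ("CD34", c7r_pos)):
                if channel in cols:
                    j = cols.index(channel)
                    mu = np.where(pos, _TRANSGENE_POS_MU, _TRANSGENE_NEG_MU)
                    data[:, j] = np.exp(rng.normal(mu, 0.25))

            values = pd.DataFrame(data, columns=cols)
            values["Time"] = np.arange(n, dtype=float)
            truth = pd.DataFrame({"population": labels, "car_pos": car_pos, "c7r_pos": c7r_pos})
            tables.append(
                EventTable(
                    values=values,
                    sample_meta={
                        "donor": donor.label,
                        "condition": condition,
                        "group": donor.group,
                        "outcome": donor.outcome,
                        "outcome_ordinal": OUTCOME_LEVELS[donor.outcome],
                    },
                    scale_state="raw",
                    truth=truth,
                )
            )
    return tables


# ---------------------------------------------------------------------------
# Serial killing assay
# ---------------------------------------------------------------------------


@dataclass
class KillingParams:
    """Per-product dynamics of the serial re-challenge killing assay.

    Within each round the tumor GFP area resets to ``area0`` at the anchor
    frame (fresh tumor added) and then evolves as
    ``area0 * exp((growth_rate - effective_kill) * t)`` with
    ``effective_kill = kill_rate * et_scaling[ratio] * round_decay**(round-1)``.
    Default cadence: 11 rounds of 3 days, frames every 7 h (11 frames/round).
    """

    product: str = "product"
    area0: float = 1000.0
    growth_rate: float = 0.01  # per hour
    kill_rate: float = 0.03  # per hour at reference 1:1 E:T
    et_scaling: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ET_SCALING))
    round_decay: float = 0.95
    rounds: int = 11
    frames_per_round: int = 11
    frame_interval_h: float = 7.0
    noise_log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area0 <= 0:
            raise ValueError("area0 must be > 0")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if not 0.0 < self.round_decay <= 1.0:
            raise ValueError("round_decay must lie in (0, 1]")


def generate_killing_series(
    params: KillingParams,
    et_ratios: Sequence[str] = ("2:1", "1:1", "1:2", "1:6"),
) -> pd.DataFrame:
    """Long-format GFP-area time series: product, et_ratio, round, hours, area.

    ``hours`` restarts at 0 at every round's anchor frame.  An infinite
    effective kill rate is clamped to instant clearance (post-anchor areas 0).
    """
    if len(et_ratios) == 0:
        raise ValueError("at least one E:T ratio required")
    rng = np.random.default_rng(params.seed)
    t = np.arange(params.frames_per_round) * params.frame_interval_h
    rows = []
    for ratio in et_ratios:
        scale = float(params.et_scaling.get(ratio, 1.0))
        for rnd in range(1, params.rounds + 1):
            eff_kill = params.kill_rate * scale * params.round_decay ** (rnd - 1)
            rate = params.growth_rate - eff_kill
            if np.isinf(eff_kill):
                area = np.where(t == 0.0, params.area0, 0.0)
            else:
                area = params.area0 * np.exp(rate * t)
            if params.noise_log_sd > 0:
                noise = np.exp(rng.normal(0.0, params.noise_log_sd, size=area.shape))
                noise[0] = 1.0  # anchor frame observed exactly
                area = area * noise
            for hours, a in zip(t, area):
                rows.append((params.product, ratio, rnd, float(hours), float(a)))
    return pd.DataFrame(rows, columns=["product", "et_ratio", "round", "hours", "area"])


def write_killing_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Post-treatment correlates
# ---------------------------------------------------------------------------

DEFAULT_CYTOKINE_GROUPS: dict[str, str] = {
    "IL-6": "inflammatory",
    "IFN-g": "inflammatory",
    "TNF-a": "inflammatory",
    "IL-10": "regulatory",
    "TGF-b": "regulatory",
    "IL-7": "homeostatic",
    "IL-15": "homeostatic",
}

# temporal response profile of cytokine effects (0 pre, rises then fades)
_EFFECT_PROFILE: dict[str, float] = {"pre": 0.0, "3h": 0.4, "wk1": 1.0, "wk2": 0.7, "wk4": 0.3}


@dataclass
class CorrelateSet:
    """Cytokine dynamics, transgene persistence and product metrics.

    ``cytokines``: long table (patient, cytokine, timepoint, concentration);
    ``grouping``: cytokine -> functional category; ``persistence``: long
    table (patient, day, level); ``product_metrics``: per-patient metric
    table carrying the latent product factor (e.g. a response-associated
    cluster abundance) used to plant correlations.
    """

    cytokines: pd.DataFrame
    grouping: dict[str, str]
    persistence: pd.DataFrame
    product_metrics: pd.DataFrame

    def __post_init__(self) -> None:
        correlated = set(self.cytokines["cytokine"].unique())
        missing = correlated - set(self.grouping)
        if missing:
            raise ValueError(f"cytokines without functional group: {sorted(missing)}")


def generate_correlates(
    cohort: CohortConfig,
    group_effects: Mapping[str, float] | None = None,
    grouping: Mapping[str, str] | None = None,
    noise_sd: float = 0.0,
    baseline: float = 10.0,
    persistence_peak: float = 100.0,
    persistence_decay: float = 0.1,
    seed: int | None = None,
) -> CorrelateSet:
    """Cohort correlates on the {pre, 3 h, wk1, wk2, wk4} grid.

    Each patient gets a latent product factor in [0, 1] (exposed in
    ``product_metrics`` as ``cluster_abundance``).  A cytokine in group ``g``
    responds as ``baseline + group_effects[g] * factor * profile(t) + noise``.
    Persistence follows peak-then-exponential decay scaled by the factor;
    with ``persistence_decay = 0`` the curve is flat at its peak.
    """
    grouping = dict(grouping or DEFAULT_CYTOKINE_GROUPS)
    effects = dict(group_effects or {})
    rng = np.random.default_rng(cohort.seed if seed is None else seed)

    patients = [d.label for d in cohort.donors]
    factor = rng.uniform(0.0, 1.0, size=len(patients))

    cyto_rows = []
    for pi, patient in enumerate(patients):
        for cytokine, group in grouping.items():
            eff = float(effects.get(group, 0.0))
            for tp in TIMEPOINTS:
                conc = baseline + eff * factor[pi] * _EFFECT_PROFILE[tp]
                if noise_sd > 0:
                    conc += rng.normal(0.0, noise_sd)
                cyto_rows.append((patient, cytokine, tp, float(conc)))
    cytokines = pd.DataFrame(cyto_rows, columns=["patient", "cytokine", "timepoint", "concentration"])

    pers_rows = []
    for pi, patient in enumerate(patients):
        peak = persistence_peak * (0.5 + 0.5 * factor[pi])
        for tp in TIMEPOINTS:
            day = TIMEPOINT_DAYS[tp]
            level = peak * np.exp(-persistence_decay * day)
            if noise_sd > 0:
                level = max(level + rng.normal(0.0, noise_sd), 0.0)
            pers_rows.append((patient, day, float(level)))
    persistence = pd.DataFrame(pers_rows, columns=["patient", "day", "level"])

    metrics = pd.DataFrame({"patient": patients, "cluster_abundance": 100.0 * factor}).set_index("patient")
    return CorrelateSet(cytokines=cytokines, grouping=grouping, persistence=persistence, product_metrics=metrics)


def write_correlates_csv(cset: CorrelateSet, cytokine_path, persistence_path) -> None:
    cset.cytokines.to_csv(cytokine_path, index=False)
    cset.persistence.to_csv(persistence_path, index=False)
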
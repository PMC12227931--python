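"""Synthetic linked-cohort generator.

Emulates the statistical structure of a region-wide administrative health
system on the prevalence date: a population with MS at ~2/1000, fourteen
autoimmune-disease (AID) flags with configurable MS-conditional odds
ratios, age/sex structure, overdispersed hospitalization counts that are
higher in MS and AID subjects (the surveillance confounder), archive
events emitted from true disease status with per-stream sensitivity and
specificity, and genotype dosages at panel variants with risk-allele
enrichment in comorbid subjects.

Everything is driven by `numpy.random.default_rng` under a single seed:
a fixed seed yields byte-identical tables across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .datasets import (
    AID_DISEASES,
    N_NON_MS,
    N_PWMS,
    PRS_DISEASES,
    association_table,
)

__all__ = [
    "SimulationConfig",
    "GenoSimConfig",
    "default_simulation_config",
    "calibrated_stream_rates",
    "generate_population",
    "generate_eha_events",
    "population_to_truth_cohort",
    "make_genetic_subset",
    "make_panels",
    "generate_genotypes",
    "write_population",
    "write_events",
    "load_events",
]

_STREAMS = (
    "hospital_discharge",
    "drug_prescription",
    "copay_exemption",
    "ltc_residence",
)

#: Validated operating point of the MS case-finding algorithm.
MS_ALGORITHM_SENSITIVITY = 0.959
MS_ALGORITHM_SPECIFICITY = 0.999


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def calibrated_stream_rates(
    sensitivity: float = MS_ALGORITHM_SENSITIVITY,
    specificity: float = MS_ALGORITHM_SPECIFICITY,
    n_streams: int = 4,
) -> tuple:
    """Per-stream emission rates whose any-stream union hits a target.

    With independent streams, union sensitivity is 1-(1-s)^k and union
    specificity is q^k for per-stream values s and q.  Inverting gives the
    per-stream rates that make a union-rule algorithm over ``n_streams``
    streams operate at the requested (sensitivity, specificity) point.

    Returns (per_stream_sensitivity, per_stream_specificity).
    """
    if not 0 < sensitivity < 1 or not 0 < specificity < 1:
        raise ValueError("target sensitivity/specificity must be in (0, 1)")
    s = 1.0 - (1.0 - sensitivity) ** (1.0 / n_streams)
    q = specificity ** (1.0 / n_streams)
    return s, q


@dataclass
class SimulationConfig:
    """Parameters of the population and archive-event simulator.

    Probabilities are per-subject; hospitalization counts are all-cause
    discharges over the 5-year lookback, drawn negative-binomially so the
    counts are overdispersed and higher for MS and AID subjects.
    ``baseline_prevalence`` is the disease probability among MS-free
    subjects; ``ms_odds_ratio`` multiplies the disease odds for MS
    subjects.  ``detection_log_or_per_hosp`` > 0 makes per-stream event
    sensitivity rise with a subject's hospitalization count, reproducing
    surveillance bias (more healthcare contact, more detected disease).
    """

    n_subjects: int = 100_000
    ms_prevalence: float = N_PWMS / (N_PWMS + N_NON_MS)
    baseline_prevalence: dict = field(default_factory=dict)
    ms_odds_ratio: dict = field(default_factory=dict)
    female_odds_ratio: dict = field(default_factory=dict)
    sex_female_fraction: float = 0.515
    age_mean: float = 48.0
    age_sd: float = 19.0
    age_min: int = 0
    age_max: int = 100
    alive_fraction: float = 1.0
    hosp_mean_base: float = 0.6
    hosp_rate_ratio_ms: float = 3.0
    hosp_rate_ratio_aid: float = 2.0
    hosp_dispersion: float = 1.0
    stream_sensitivity: dict = field(default_factory=dict)
    stream_specificity: dict = field(default_factory=dict)
    detection_log_or_per_hosp: float = 0.0
    reference_date: date = date(2017, 12, 31)
    lookback_years: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.baseline_prevalence:
            tab = association_table()
            self.baseline_prevalence = {
                d: tab.loc[d, "prevalence_non_ms_per_1000"] / 1000.0 for d in AID_DISEASES
            }
        if not self.ms_odds_ratio:
            tab = association_table()
            self.ms_odds_ratio = {}
            for d in AID_DISEASES:
                p1 = tab.loc[d, "prevalence_ms_per_1000"] / 1000.0
                p0 = tab.loc[d, "prevalence_non_ms_per_1000"] / 1000.0
                self.ms_odds_ratio[d] = (p1 / (1 - p1)) / (p0 / (1 - p0))
        if not self.stream_sensitivity or not self.stream_specificity:
            s, q = calibrated_stream_rates()
            self.stream_sensitivity = dict(self.stream_sensitivity) or {
                st: s for st in _STREAMS
            }
            self.stream_specificity = dict(self.stream_specificity) or {
                st: q for st in _STREAMS
            }
        self.validate()

    @property
    def diseases(self) -> tuple:
        return tuple(self.baseline_prevalence)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for name in ("ms_prevalence", "sex_female_fraction", "alive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for d, p in self.baseline_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline_prevalence[{d!r}] must be in [0, 1], got {p}")
        for d, orr in self.ms_odds_ratio.items():
            if orr <= 0:
                raise ValueError(f"ms_odds_ratio[{d!r}] must be positive, got {orr}")
        for d, orr in self.female_odds_ratio.items():
            if orr <= 0:
                raise ValueError(f"female_odds_ratio[{d!r}] must be positive, got {orr}")
        if set(self.ms_odds_ratio) != set(self.baseline_prevalence):
            raise ValueError("ms_odds_ratio and baseline_prevalence must cover the same diseases")
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        for name in ("hosp_mean_base", "hosp_rate_ratio_ms", "hosp_rate_ratio_aid", "hosp_dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for st in _STREAMS:
            for mapping, label in (
                (self.stream_sensitivity, "stream_sensitivity"),
                (self.stream_specificity, "stream_specificity"),
            ):
                if st not in mapping:
                    raise ValueError(f"{label} missing stream {st!r}")
                if not 0.0 <= mapping[st] <= 1.0:
                    raise ValueError(f"{label}[{st!r}] must be in [0, 1]")
        unknown = set(self.stream_sensitivity) - set(_STREAMS)
        if unknown:
            raise ValueError(f"unknown archive stream name(s): {sorted(unknown)}")

    def lookback_window(self) -> tuple:
        ref = pd.Timestamp(self.reference_date)
        return ((ref - pd.DateOffset(years=self.lookback_years)).date(), self.reference_date)


def default_simulation_config(n_subjects: int = 100_000, seed: int = 0, **kwargs) -> SimulationConfig:
    """Study-condition defaults: published prevalences and implied odds ratios."""
    return SimulationConfig(n_subjects=n_subjects, seed=seed, **kwargs)


def generate_population(config: SimulationConfig) -> pd.DataFrame:
    """Draw the ground-truth population table.

    Columns: ``subject_id``, ``sex``, ``age_years``, ``alive_at_reference``,
    ``true_ms``, one ``true_<disease>`` flag per configured disease, and
    ``hosp_count_5y`` (true all-cause discharge count over the lookback).

    AID flags are conditionally independent given MS status; each disease's
    log-odds is ``logit(baseline) + log(ms_odds_ratio)*MS`` (plus an
    optional per-disease female term).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    width = max(7, len(str(n)))
    subject_id = np.char.add("S", np.char.zfill(np.arange(1, n + 1).astype(str), width))
    female = rng.random(n) < config.sex_female_fraction
    age = np.clip(
        np.rint(rng.normal(config.age_mean, config.age_sd, n)),
        config.age_min,
        config.age_max,
    ).astype(int)
    alive = rng.random(n) < config.alive_fraction
    true_ms = rng.random(n) < config.ms_prevalence

    pop = pd.DataFrame(
        {
            "subject_id": subject_id,
            "sex": np.where(female, "female", "male"),
            "age_years": age,
            "alive_at_reference": alive,
            "true_ms": true_ms,
        }
    )

    any_aid = np.zeros(n, dtype=bool)
    for d in config.diseases:
        base = config.baseline_prevalence[d]
        if base == 0.0:
            flag = np.zeros(n, dtype=bool)
        elif base == 1.0:
            flag = np.ones(n, dtype=bool)
        else:
            lo = _logit(base) + np.log(config.ms_odds_ratio[d]) * true_ms
            f_or = config.female_odds_ratio.get(d, 1.0)
            if f_or != 1.0:
                lo = lo + np.log(f_or) * female
            flag = rng.random(n) < _expit(lo)
        pop[f"true_{d}"] = flag
        any_aid |= flag

    log_mu = (
        np.log(config.hosp_mean_base)
        + np.log(config.hosp_rate_ratio_ms) * true_ms
        + np.log(config.hosp_rate_ratio_aid) * any_aid
    )
    mu = np.exp(log_mu)
    size = config.hosp_dispersion
    pop["hosp_count_5y"] = rng.negative_binomial(size, size / (size + mu))
    return pop


def population_to_truth_cohort(population: pd.DataFrame) -> pd.DataFrame:
    """Noise-free analysis table straight from simulator truth.

    Equivalent to running event generation and case finding with perfect
    per-stream sensitivity and specificity; used for statistical
    experiments where ascertainment noise is not the object of study.
    """
    cohort = pd.DataFrame({"subject_id": population["subject_id"]})
    cohort["ms_flag"] = population["true_ms"].to_numpy()
    for col in population.columns:
        if col.startswith("true_") and col != "true_ms":
            cohort[f"aid_{col[len('true_'):]}"] = population[col].to_numpy()
    cohort["age_years"] = population["age_years"].to_numpy()
    cohort["sex"] = population["sex"].to_numpy()
    cohort["hosp_count_5y"] = population["hosp_count_5y"].to_numpy()
    return cohort


def generate_eha_events(
    population: pd.DataFrame,
    algorithms: dict,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Emit archive events from true disease status.

    For each algorithm and each of its streams, a truly affected subject
    emits the stream's qualifying pattern (``min_count`` coded events)
    with probability equal to the stream sensitivity; an unaffected
    subject emits it with probability 1 - stream specificity.  On top of
    the coded events, every subject emits their ``hosp_count_5y``
    all-cause discharge events (code ``"ALLCAUSE"``), so hospitalization
    counting and the surveillance confounder are reproducible downstream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = len(population)
    start, end = (pd.Timestamp(t) for t in config.lookback_window())
    n_days = (end - start).days

    hosp = population["hosp_count_5y"].to_numpy()
    boost = config.detection_log_or_per_hosp

    sids, streams, offsets, codes = [], [], [], []

    def emit(idx, reps, stream, code):
        take = np.repeat(idx, reps)
        sids.append(take)
        streams.append(np.full(take.size, stream))
        offsets.append(rng.integers(0, n_days + 1, take.size))
        codes.append(np.full(take.size, code))

    for name, algo in algorithms.items():
        col = "true_ms" if name == "ms" else f"true_{name}"
        truth = (
            population[col].to_numpy()
            if col in population.columns
            else np.zeros(n, dtype=bool)
        )
        for stream, codeset in algo.stream_codes.items():
            if stream not in _STREAMS:
                raise ValueError(f"unknown archive stream name: {stream!r}")
            if not codeset:
                continue
            s = config.stream_sensitivity[stream]
            q = config.stream_specificity[stream]
            if boost != 0.0 and 0.0 < s < 1.0:
                s_subj = _expit(_logit(s) + boost * hosp)
            else:
                s_subj = s
            p = np.where(truth, s_subj, 1.0 - q)
            fire = np.flatnonzero(rng.random(n) < p)
            if fire.size:
                emit(fire, algo.min_count(stream), stream, sorted(codeset)[0])

    with_hosp = np.flatnonzero(hosp > 0)
    if with_hosp.size:
        emit(with_hosp, hosp[with_hosp], "hospital_discharge", "ALLCAUSE")

    if not sids:
        return pd.DataFrame(columns=["subject_id", "stream", "date", "code"])
    ids = population["subject_id"].to_numpy()
    events = pd.DataFrame(
        {
            "subject_id": ids[np.concatenate(sids)],
            "stream": np.concatenate(streams),
            "date": start + pd.to_timedelta(np.concatenate(offsets), unit="D"),
            "code": np.concatenate(codes),
        }
    )
    return events.sort_values(["subject_id", "date", "stream", "code"], kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class GenoSimConfig:
    """Parameters of the genotype/HLA simulator for the PRS experiment.

    ``panel_sizes`` gives the number of non-HLA variants per disease panel
    (defaults span the published 23-201 range); ``enrichment_log_or`` is
    the per-allele log-odds shift of the risk-allele frequency in
    comorbid subjects; dosage noise shrinks with imputation quality so a
    variant's R2 annotation is meaningful.
    """

    panel_sizes: dict = field(default_factory=dict)
    hla_panel_sizes: dict = field(default_factory=dict)
    freq_low: float = 0.05
    freq_high: float = 0.5
    hla_freq_low: float = 0.05
    hla_freq_high: float = 0.4
    enrichment_log_or: float = 0.05
    missing_rate: float = 0.0
    r2_beta_a: float = 8.0
    r2_beta_b: float = 1.0
    dosage_noise_scale: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not self.panel_sizes:
            self.panel_sizes = {
                d: {"ms": 201, "ankylosing_spondylitis": 23}.get(d, 50) for d in PRS_DISEASES
            }
        if not self.hla_panel_sizes:
            self.hla_panel_sizes = {d: 4 for d in self.panel_sizes}
        self.validate()

    def validate(self) -> None:
        for d, k in self.panel_sizes.items():
            if k <= 0:
                raise ValueError(f"panel_sizes[{d!r}] must be positive (empty panel)")
        for d, k in self.hla_panel_sizes.items():
            if k < 0:
                raise ValueError(f"hla_panel_sizes[{d!r}] must be >= 0")
        if not 0.0 < self.freq_low <= self.freq_high < 1.0:
            raise ValueError("risk-allele frequency range must satisfy 0 < low <= high < 1")
        if not 0.0 < self.hla_freq_low <= self.hla_freq_high < 1.0:
            raise ValueError("HLA frequency range must satisfy 0 < low <= high < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.r2_beta_a <= 0 or self.r2_beta_b <= 0:
            raise ValueError("r2 beta parameters must be positive")
        if self.dosage_noise_scale < 0:
            raise ValueError("dosage_noise_scale must be non-negative")


def make_genetic_subset(
    n: int = 637,
    n_comorbid: int = 65,
    age_mean: float = 52.0,
    age_sd: float = 11.5,
    n_female: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject table for the genotyped-MS-subset experiment.

    Defaults mirror the published genotyped subset: 637 MS subjects of
    whom 65 carry at least one autoimmune comorbidity, 423 women / 214
    men (sex ratio 1.98), mean age 52 (SD 11.5).  For other ``n`` the
    default female count keeps the same 423/637 proportion.
    """
    if n_female is None:
        n_female = round(n * 423 / 637)
    if not 0 <= n_comorbid <= n:
        raise ValueError("n_comorbid must be between 0 and n")
    if not 0 <= n_female <= n:
        raise ValueError("n_female must be between 0 and n")
    rng = np.random.default_rng(seed)
    comorbid = np.zeros(n, dtype=bool)
    comorbid[rng.choice(n, size=n_comorbid, replace=False)] = True
    female = np.zeros(n, dtype=bool)
    female[rng.choice(n, size=n_female, replace=False)] = True
    return pd.DataFrame(
        {
            "subject_id": [f"G{i:05d}" for i in range(1, n + 1)],
            "sex": np.where(female, "female", "male"),
            "age_years": np.clip(np.rint(rng.normal(age_mean, age_sd, n)), 18, 90).astype(int),
            "comorbid": comorbid,
        }
    )


def make_panels(config: GenoSimConfig):
    """Variant and HLA panels matching the simulator's variant naming.

    Returns (panels, hla_panels): dicts keyed by disease.  Risk alleles
    alternate between REF and ALT so downstream allele handling is
    exercised in both orientations.
    """
    from .prs import HlaPanel, VariantPanel

    rng = np.random.default_rng(config.seed + 101)
    panels, hla_panels = {}, {}
    for d, k in config.panel_sizes.items():
        entries = []
        for i in range(k):
            risk = "G" if rng.random() < 0.5 else "A"  # ALT is G, REF is A
            entries.append((f"var_{d}_{i:04d}", risk))
        panels[d] = VariantPanel(disease=d, entries=tuple(entries))
        n_hla = config.hla_panel_sizes.get(d, 0)
        hla_panels[d] = HlaPanel(
            disease=d,
            alleles=tuple(f"HLA_{d}_{j:02d}" for j in range(n_hla)),
        )
    return panels, hla_panels


def generate_genotypes(
    subjects: pd.DataFrame,
    panels: dict,
    config: GenoSimConfig,
    hla_panels: dict | None = None,
):
    """Simulate dosages at panel variants, plus an HLA carrier-count matrix.

    ``subjects`` must carry a boolean ``comorbid`` column; comorbid
    subjects have each risk-allele frequency shifted by
    ``enrichment_log_or`` on the log-odds scale.  Dosages are the true
    allele count plus imputation noise scaled by (1 - R2), clipped to
    [0, 2]; entries are set missing at ``missing_rate``.

    Returns ``(matrix, hla_counts)`` where ``matrix`` is a
    :class:`~mscomorb.genotype_qc.GenotypeMatrix` (ALT-dosage convention)
    and ``hla_counts`` is a subjects x alleles DataFrame of counts in
    {0, 1, 2} (empty if no HLA panels).
    """
    from .genotype_qc import GenotypeMatrix

    config.validate()
    if not panels:
        raise ValueError("no variant panels supplied (empty panel)")
    for d, p in panels.items():
        if p.n_snps == 0:
            raise ValueError(f"panel for {d!r} is empty")
    if "comorbid" not in subjects.columns:
        raise ValueError("subjects table must have a boolean 'comorbid' column")

    rng = np.random.default_rng(config.seed + 7)
    n = len(subjects)
    comorbid = subjects["comorbid"].to_numpy(dtype=bool)
    gamma = config.enrichment_log_or

    var_rows = []
    dosage_cols = []
    chrom_cycle = 0
    for d, panel in panels.items():
        for vid, risk in panel.entries:
            p_risk = rng.uniform(config.freq_low, config.freq_high)
            r2 = rng.beta(config.r2_beta_a, config.r2_beta_b)
            p_subj = np.full(n, p_risk)
            if gamma != 0.0:
                p_subj = np.where(comorbid, _expit(_logit(p_risk) + gamma), p_risk)
            g_risk = rng.binomial(2, p_subj)
            g_alt = g_risk if risk == "G" else 2 - g_risk
            noise_sd = config.dosage_noise_scale * (1.0 - r2)
            ds = np.clip(g_alt + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else g_alt.astype(float), 0.0, 2.0)
            if config.missing_rate > 0:
                ds = np.where(rng.random(n) < config.missing_rate, np.nan, ds)
            chrom_cycle += 1
            var_rows.append(
                {
                    "variant_id": vid,
                    "chrom": str(1 + (chrom_cycle % 22)),
                    "pos": 10_000 + 100 * chrom_cycle,
                    "ref": "A",
                    "alt": "G",
                    "r2": float(r2),
                    "is_hla": False,
                }
            )
            dosage_cols.append(ds)

    dosages = np.column_stack(dosage_cols)
    variants = pd.DataFrame(var_rows)
    samples = pd.DataFrame(
        {
            "sample_id": subjects["subject_id"].to_numpy(),
            "reported_sex": subjects["sex"].to_numpy() if "sex" in subjects else "female",
        }
    )
    matrix = GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)

    hla_cols = {}
    for d, hp in (hla_panels or {}).items():
        for allele in hp.alleles:
            f = rng.uniform(config.hla_freq_low, config.hla_freq_high)
            p_subj = np.where(comorbid, _expit(_logit(f) + gamma), f) if gamma else np.full(n, f)
            hla_cols[allele] = rng.binomial(2, p_subj)
    hla_counts = pd.DataFrame(hla_cols, index=samples["sample_id"].to_numpy())
    hla_counts.index.name = "sample_id"
    return matrix, hla_counts


# ---------------------------------------------------------------------------
# plain-text writers / loaders (ISO-8601 dates throughout)


def write_population(population: pd.DataFrame, path) -> None:
    population.to_csv(path, index=False)


def write_events(events: pd.DataFrame, outdir) -> None:
    """One CSV per archive stream, as the linked system delivers them."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stream in _STREAMS:
        sub = events.loc[events["stream"] == stream].copy()
        sub["date"] = pd.to_datetime(sub["date"]).dt.strftime("%Y-%m-%d")
        sub.to_csv(outdir / f"events_{stream}.csv", index=False)


def load_events(indir) -> pd.DataFrame:
    from pathlib import Path

    frames = []
    for stream in _STREAMS:
        f = Path(indir) / f"events_{stream}.csv"
        if f.exists():
            frames.append(pd.read_csv(f, parse_dates=["date"]))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "stream", "date", "code"])
    return pd.concat(frames, ignore_index=True)
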
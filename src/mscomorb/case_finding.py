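"""Case-finding from linked electronic health archives (EHAs).

Administrative case ascertainment flags a disease when a subject's
pseudo-anonymized contact history matches a declarative multi-source
algorithm: per-archive-stream code sets and minimum event counts inside a
lookback window, combined across streams, optionally vetoed by an
exclusion rule (codes observed shortly before the first qualifying event).

Four archive streams are modelled: hospital discharges, pharmacy drug
prescriptions, chronic-disease co-payment exemptions and long-term-care
residence.  Codes are opaque tokens; real ICD-9-CM/ATC semantics are out
of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STREAMS",
    "CaseAlgorithm",
    "apply_algorithm",
    "count_hospitalizations",
    "evaluate_algorithm",
    "AlgorithmPerformance",
    "build_cohort",
    "default_algorithms",
    "load_algorithms",
    "save_algorithms",
]

#: The four archive streams of the linked system.
STREAMS = (
    "hospital_discharge",
    "drug_prescription",
    "copay_exemption",
    "ltc_residence",
)

#: Event-table columns expected by every operation in this module.
EVENT_COLUMNS = ("subject_id", "stream", "date", "code")


@dataclass(frozen=True)
class CaseAlgorithm:
    """Declarative multi-source rule mapping event patterns to a disease flag.

    Parameters
    ----------
    disease
        Disease key the rule flags.
    stream_codes
        Mapping from stream name to the set of qualifying codes in that
        stream.  Streams without an entry do not participate.
    window
        Inclusive (start, end) lookback window; events outside it are
        ignored.
    min_counts
        Minimum number of qualifying events per stream (default 1).
    rule
        ``"any"`` — a subject qualifies if at least one listed stream
        reaches its minimum count (multi-source union, the default);
        ``"all"`` — every listed stream must reach its minimum.
    exclusion_codes, exclusion_months
        If a subject shows any exclusion code in the ``exclusion_months``
        before their first qualifying event, the flag is vetoed (e.g.
        thyrotoxic-drug treatment shortly before an apparent thyroiditis
        diagnosis).  The anchor is the first qualifying event date, used
        as a proxy for the diagnosis date.
    """

    disease: str
    stream_codes: dict
    window: tuple
    min_counts: dict = field(default_factory=dict)
    rule: str = "any"
    exclusion_codes: frozenset = frozenset()
    exclusion_months: int = 12

    def __post_init__(self):
        unknown = set(self.stream_codes) - set(STREAMS)
        if unknown:
            raise ValueError(f"unknown archive stream(s): {sorted(unknown)}")
        if not any(self.stream_codes.get(s) for s in self.stream_codes):
            raise ValueError(f"{self.disease}: at least one stream needs a non-empty code set")
        if self.rule not in ("any", "all"):
            raise ValueError(f"combination rule must be 'any' or 'all', got {self.rule!r}")
        start, end = self.window
        if start > end:
            raise ValueError(f"{self.disease}: window start {start} after end {end}")

    def min_count(self, stream: str) -> int:
        return int(self.min_counts.get(stream, 1))


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing column(s): {sorted(missing)}")
    dates = pd.to_datetime(events["date"], errors="raise")  # malformed dates raise
    if events["date"].dtype != "datetime64[ns]":
        events = events.assign(date=dates)
    return events


def apply_algorithm(events: pd.DataFrame, algorithm: CaseAlgorithm) -> set:
    """Flag the subjects whose events satisfy a case-finding algorithm.

    Order-independent and idempotent: permuting event rows or re-applying
    the algorithm never changes the flag set.  Events in streams the
    algorithm does not list are ignored.

    Returns the set of flagged ``subject_id`` values.
    """
    events = _check_events(events)
    if events.empty:
        return set()

    start = pd.Timestamp(algorithm.window[0])
    end = pd.Timestamp(algorithm.window[1])
    in_window = (events["date"] >= start) & (events["date"] <= end)

    qualified_per_stream = []
    first_dates = []
    for stream, codes in algorithm.stream_codes.items():
        if not codes:
            continue
        mask = in_window & (events["stream"] == stream) & events["code"].isin(set(codes))
        sub = events.loc[mask]
        counts = sub.groupby("subject_id").size()
        ok = counts[counts >= algorithm.min_count(stream)]
        qualified_per_stream.append(set(ok.index))
        if not sub.empty:
            first_dates.append(sub.groupby("subject_id")["date"].min())

    if not qualified_per_stream:
        return set()
    if algorithm.rule == "any":
        flagged = set().union(*qualified_per_stream)
    else:
        flagged = set.intersection(*qualified_per_stream)

    if flagged and algorithm.exclusion_codes:
        # anchor: first qualifying event over all listed streams
        anchor = pd.concat(first_dates).groupby(level=0).min()
        excl = events.loc[
            events["code"].isin(set(algorithm.exclusion_codes))
            & events["subject_id"].isin(flagged)
        ]
        if not excl.empty:
            offset = pd.DateOffset(months=algorithm.exclusion_months)
            for sid, grp in excl.groupby("subject_id"):
                a = anchor.get(sid)
                if a is None:
                    continue
                if ((grp["date"] >= a - offset) & (grp["date"] < a)).any():
                    flagged.discard(sid)
    return flagged


def count_hospitalizations(events: pd.DataFrame, subject_id, window: tuple) -> int:
    """All-cause hospital-discharge count for one subject inside a window.

    Every ``hospital_discharge`` event counts regardless of its code;
    unknown subjects count 0.
    """
    events = _check_events(events)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mask = (
        (events["subject_id"] == subject_id)
        & (events["stream"] == "hospital_discharge")
        & (events["date"] >= start)
        & (events["date"] <= end)
    )
    return int(mask.sum())


def hospitalization_counts(events: pd.DataFrame, window: tuple) -> pd.Series:
    """Vectorized all-cause discharge counts for every subject in the table."""
    events = _check_events(events)
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    mask = (
        (events["stream"] == "hospital_discharge")
        & (events["date"] >= start)
        & (events["date"] <= end)
    )
    return events.loc[mask].groupby("subject_id").size()


@dataclass(frozen=True)
class AlgorithmPerformance:
    """2x2 operating characteristics of a case-finding algorithm."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def evaluate_algorithm(flags: set, truth: pd.Series) -> AlgorithmPerformance:
    """Compare a flag set against boolean truth indexed by subject_id.

    Counts are exact integers; the rate properties divide them lazily so
    nothing is rounded before the caller asks.
    """
    truth = truth.astype(bool)
    flagged = truth.index.isin(flags)
    t = truth.to_numpy()
    return AlgorithmPerformance(
        tp=int(np.sum(flagged & t)),
        fp=int(np.sum(flagged & ~t)),
        fn=int(np.sum(~flagged & t)),
        tn=int(np.sum(~flagged & ~t)),
    )


def build_cohort(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    algorithms: dict,
    reference_date,
    lookback_years: int = 5,
) -> pd.DataFrame:
    """Assemble the per-subject analysis table from archives and algorithms.

    One row per subject alive at the reference date, with the MS flag, the
    14 AID flags, age, sex and the 5-year all-cause hospitalization count.
    MS-free subjects are restricted to the [min, max] age range observed
    among flagged MS subjects, mirroring how an MS-free reference
    population is drawn from the same registry.

    ``algorithms`` maps disease key -> CaseAlgorithm and must contain an
    ``"ms"`` entry.
    """
    if subjects["subject_id"].duplicated().any():
        dup = subjects.loc[subjects["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id in population table: {dup!r}")
    if "ms" not in algorithms:
        raise ValueError("algorithms must include an 'ms' entry")

    events = _check_events(events)
    ref = pd.Timestamp(reference_date)
    window = (ref - pd.DateOffset(years=lookback_years), ref)

    cohort = subjects.copy()
    if "alive_at_reference" in cohort.columns:
        cohort = cohort.loc[cohort["alive_at_reference"]].copy()
    cohort = cohort.set_index("subject_id")

    ms_flagged = apply_algorithm(events, algorithms["ms"])
    cohort["ms_flag"] = cohort.index.isin(ms_flagged)
    for disease, algo in algorithms.items():
        if disease == "ms":
            continue
        cohort[f"aid_{disease}"] = cohort.index.isin(apply_algorithm(events, algo))

    hosp = hospitalization_counts(events, window)
    cohort["hosp_count_5y"] = hosp.reindex(cohort.index).fillna(0).astype(int)

    if cohort["ms_flag"].any():
        ages = cohort.loc[cohort["ms_flag"], "age_years"]
        lo, hi = int(ages.min()), int(ages.max())
        keep = cohort["ms_flag"] | cohort["age_years"].between(lo, hi)
        cohort = cohort.loc[keep]

    keep_cols = ["ms_flag"] + [c for c in cohort.columns if c.startswith("aid_")] + [
        "age_years",
        "sex",
        "hosp_count_5y",
    ]
    return cohort[keep_cols].reset_index()


# ---------------------------------------------------------------------------
# algorithm definitions: defaults and (de)serialization


def default_algorithms(
    reference_date=date(2017, 12, 31),
    lookback_years: int = 5,
    diseases=None,
) -> dict:
    """Opaque-token algorithm set: one rule per disease plus MS.

    MS uses all four streams (the validated multi-source design); the AIDs
    use discharges, prescriptions and exemptions.  Hashimoto thyroiditis
    carries the thyrotoxic-drug exclusion rule.
    """
    from .datasets import AID_DISEASES

    if diseases is None:
        diseases = AID_DISEASES
    ref = pd.Timestamp(reference_date)
    window = ((ref - pd.DateOffset(years=lookback_years)).date(), reference_date)

    algos = {
        "ms": CaseAlgorithm(
            disease="ms",
            stream_codes={
                "hospital_discharge": frozenset({"HOSP:ms"}),
                "drug_prescription": frozenset({"DRUG:ms"}),
                "copay_exemption": frozenset({"EXEM:ms"}),
                "ltc_residence": frozenset({"LTC:ms"}),
            },
            window=window,
        )
    }
    for d in diseases:
        kwargs = {}
        if d == "hashimoto_thyroiditis":
            kwargs = {"exclusion_codes": frozenset({"DRUG:thyrotoxic"}), "exclusion_months": 12}
        algos[d] = CaseAlgorithm(
            disease=d,
            stream_codes={
                "hospital_discharge": frozenset({f"HOSP:{d}"}),
                "drug_prescription": frozenset({f"DRUG:{d}"}),
                "copay_exemption": frozenset({f"EXEM:{d}"}),
            },
            window=window,
            **kwargs,
        )
    return algos


def save_algorithms(algorithms: dict, path) -> None:
    """Write an algorithm set to YAML (documented schema, round-trips)."""
    out = {}
    for name, a in algorithms.items():
        out[name] = {
            "streams": {
                s: {"codes": sorted(c), "min_count": a.min_count(s)}
                for s, c in a.stream_codes.items()
            },
            "rule": a.rule,
            "window": [str(a.window[0]), str(a.window[1])],
        }
        if a.exclusion_codes:
            out[name]["exclusion"] = {
                "codes": sorted(a.exclusion_codes),
                "months_before": a.exclusion_months,
            }
    Path(path).write_text(yaml.safe_dump({"diseases": out}, sort_keys=True))


def load_algorithms(path) -> dict:
    """Read an algorithm set from the YAML schema written by save_algorithms."""
    raw = yaml.safe_load(Path(path).read_text())["diseases"]
    algos = {}
    for name, block in raw.items():
        streams = block["streams"]
        algos[name] = CaseAlgorithm(
            disease=name,
            stream_codes={s: frozenset(v["codes"]) for s, v in streams.items()},
            min_counts={s: int(v.get("min_count", 1)) for s, v in streams.items()},
            rule=block.get("rule", "any"),
            window=(
                pd.Timestamp(block["window"][0]).date(),
                pd.Timestamp(block["window"][1]).date(),
            ),
            exclusion_codes=frozenset(block.get("exclusion", {}).get("codes", [])),
            exclusion_months=int(block.get("exclusion", {}).get("months_before", 12)),
        )
    return algos
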
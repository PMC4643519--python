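"""Synthetic index-disease claims cohorts for exercising the full pipeline.

Real national claims extracts are access-restricted, so this module
generates long-format event CSVs with the same shape: per patient, a burst
of pre-index comorbidity claims (independent Poisson processes per factor),
one index diagnosis at a randomised calendar date (relative day 0), an
optional first-year haemodialysis course, and a post-window terminal or
procedure outcome (death, peritoneal dialysis, renal transplantation).
Codes are sampled from the concrete code rules of the factor vocabulary
(including dotted/undotted ICD-9 formatting variants), so code
normalisation and pattern matching are exercised end to end.

Alongside the events the generator emits a *truth table* with each
patient's per-window factor sets; because every downstream pipeline step is
deterministic, running factor mapping → alignment → windowing over the
generated events must reproduce the truth table exactly.

An optional *deterministic subcohort* consists of patients whose pre-index
combination maps one-to-one to a fixed outcome; with the subcohort fraction
at 1.0 every transition in the resulting network has zero outcome entropy,
which is the regime the zero-threshold edge filter is designed to isolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .factors import CodePattern, FactorEntry, FactorMap, default_ckd_map

__all__ = ["SynthConfig", "synth_factor_map", "generate", "DEATH_FACTOR", "DEATH_CODE"]

DEATH_FACTOR = "Death"
DEATH_CODE = "DEATH"

# annual pre-index claim rates per comorbidity (events/patient/year)
DEFAULT_RATES: dict[str, float] = {
    "HTN": 0.35,
    "DM": 0.30,
    "Hyperlipidemia": 0.22,
    "CAD": 0.12,
    "CVD": 0.08,
    "CHF": 0.07,
    "Proteinuria": 0.12,
    "GN": 0.06,
    "Renal stone": 0.08,
    "PKD": 0.015,
    "SLE": 0.015,
}

# first-year haemodialysis uptake and conditional post-window outcomes
DEFAULT_P_HD_YEAR1 = 0.0954
DEFAULT_OUTCOMES_GIVEN_HD = {"none": 0.702, "PD": 0.12, "RTPL": 0.06, DEATH_FACTOR: 0.118}
DEFAULT_OUTCOMES_GIVEN_NO_HD = {"none": 0.87, "PD": 0.05, "RTPL": 0.02, DEATH_FACTOR: 0.06}

# deterministic subcohort: pre-index signature -> (first-year HD?, post outcome).
# The post outcome is a function of the first-year combination (all HD
# signatures share one outcome, all non-HD signatures another) so that with
# subcohort fraction 1.0 every transition in the network is deterministic.
DETERMINISTIC_PROFILES: list[tuple[frozenset[str], bool, str]] = [
    (frozenset({"PKD"}), True, "PD"),
    (frozenset({"SLE"}), False, "none"),
    (frozenset({"DM", "HTN"}), True, "PD"),
    (frozenset({"GN"}), False, "none"),
]


def synth_factor_map() -> FactorMap:
    """Default vocabulary extended with the Death sentinel (exact code DEATH)."""
    fm = default_ckd_map()
    entries = fm.entries + [
        FactorEntry(DEATH_FACTOR, DEATH_FACTOR, (CodePattern("exact", (DEATH_CODE,)),), "procedure")
    ]
    return FactorMap(entries, fm.index_factor)


@dataclass
class SynthConfig:
    """Generation conditions for one synthetic cohort."""

    n_patients: int = 1000
    seed: int = 0
    pre_days: int = 2190  # observation span before index (6 years)
    post_days: int = 1825  # upper bound of the post window (5 years after index)
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    p_hd_year1: float = DEFAULT_P_HD_YEAR1
    outcomes_given_hd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES_GIVEN_HD)
    )
    outcomes_given_no_hd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES_GIVEN_NO_HD)
    )
    deterministic_fraction: float = 0.0
    index_date_range: tuple[str, str] = ("2004-01-01", "2006-12-31")

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.pre_days <= 0 or self.post_days <= 365:
            raise ValueError("need pre_days > 0 and post_days > 365")
        if not 0.0 <= self.p_hd_year1 <= 1.0:
            raise ValueError("p_hd_year1 must be a probability")
        if not 0.0 <= self.deterministic_fraction <= 1.0:
            raise ValueError("deterministic_fraction must be in [0, 1]")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be >= 0")
        for dist in (self.outcomes_given_hd, self.outcomes_given_no_hd):
            if any(not 0 <= p <= 1 for p in dist.values()):
                raise ValueError("outcome probabilities must be in [0, 1]")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("outcome probabilities must sum to 1")

    @property
    def windows(self) -> list[int]:
        """Boundaries of the truth windows: pre, first year, post."""
        return [-self.pre_days, 0, 365, self.post_days]


def _code_catalogue(fm: FactorMap) -> dict[str, list[str]]:
    """Concrete emit-able codes per factor, derived from its patterns."""
    cat: dict[str, list[str]] = {}
    for e in fm.entries:
        codes: list[str] = []
        for p in e.patterns:
            if p.kind == "exact":
                codes.append(p.payload[0])
            elif p.kind == "prefix":
                codes.append(p.payload[0])
                if p.payload[0].isdigit() and len(p.payload[0]) == 3:
                    codes.append(p.payload[0] + "1")  # a child code
            elif p.kind == "numeric-range":
                lo, hi = int(p.payload[0]), int(p.payload[1])
                width = len(p.payload[0])
                mid = (lo + hi) // 2
                codes.extend(str(v).zfill(width) for v in {lo, mid, hi})
            else:  # decimal-range
                codes.extend(p.payload)
        cat[e.abbreviation] = codes
    return cat


def _format_code(code: str, rng: np.random.Generator) -> str:
    """Half the time, write a >3-digit diagnosis code in dotted ICD-9 form."""
    if code.isdigit() and len(code) > 3 and rng.random() < 0.5:
        return code[:3] + "." + code[3:]
    return code


def _draw_outcome(dist: Mapping[str, float], rng: np.random.Generator) -> str:
    names = sorted(dist)
    probs = np.array([dist[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate(
    cfg: SynthConfig,
    *,
    events_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate the events table and truth table for one synthetic cohort.

    Returns ``(events, truth)`` where ``events`` has columns
    ``patient_id, date, code`` (calendar dates, one code per row) and
    ``truth`` records each patient's true per-window factor sets.  Fully
    reproducible: the same config (including seed) yields byte-identical
    CSV output.
    """
    rng = np.random.default_rng(cfg.seed)
    fm = synth_factor_map()
    catalogue = _code_catalogue(fm)
    index_factor = fm.index_factor

    d0_lo = date.fromisoformat(cfg.index_date_range[0])
    d0_hi = date.fromisoformat(cfg.index_date_range[1])
    span = (d0_hi - d0_lo).days

    n_det = round(cfg.deterministic_fraction * cfg.n_patients)
    pre_years = cfg.pre_days / 365.0

    rows: list[tuple[str, str, str]] = []
    truth_patients: dict[str, dict] = {}
    width = max(5, len(str(cfg.n_patients)))
    for i in range(cfg.n_patients):
        pid = f"P{i:0{width}d}"
        day0 = d0_lo + timedelta(days=int(rng.integers(0, span + 1)))
        events: list[tuple[int, str]] = []  # (relative day, factor)

        if i < n_det:
            signature, hd, outcome = DETERMINISTIC_PROFILES[i % len(DETERMINISTIC_PROFILES)]
            pre = set(signature)
            for j, f in enumerate(sorted(pre)):
                events.append((-min(cfg.pre_days, cfg.pre_days // 2 + 30 * j), f))
            if hd:
                events.append((120, "HD"))
            if outcome != "none":
                events.append(((365 + cfg.post_days) // 2, outcome))
        else:
            pre = set()
            for f in sorted(cfg.rates):
                n_ev = rng.poisson(cfg.rates[f] * pre_years)
                if n_ev:
                    pre.add(f)
                    days = rng.integers(-cfg.pre_days, 0, size=n_ev)
                    events.extend((int(d), f) for d in days)
            hd = bool(rng.random() < cfg.p_hd_year1)
            if hd:
                for d in rng.integers(1, 365, size=int(1 + rng.poisson(1.0))):
                    events.append((int(d), "HD"))
            dist = cfg.outcomes_given_hd if hd else cfg.outcomes_given_no_hd
            outcome = _draw_outcome(dist, rng)
            if outcome != "none":
                events.append((int(rng.integers(365, cfg.post_days)), outcome))

        events.append((0, index_factor))
        events.sort()
        for d, f in events:
            code = catalogue[f][int(rng.integers(0, len(catalogue[f])))]
            rows.append(
                (pid, (day0 + timedelta(days=d)).isoformat(), _format_code(code, rng))
            )

        year1 = {index_factor} | ({"HD"} if hd else set())
        post = set() if outcome == "none" else {outcome}
        truth_patients[pid] = {
            "index_date": day0.isoformat(),
            "pre": sorted(pre),
            "year1": sorted(year1),
            "post": sorted(post),
        }

    events_df = pd.DataFrame(rows, columns=["patient_id", "date", "code"])
    truth = {
        "seed": cfg.seed,
        "n_patients": cfg.n_patients,
        "window_boundaries": cfg.windows,
        "window_names": ["pre", "year1", "post"],
        "patients": truth_patients,
    }
    if events_path is not None:
        events_df.to_csv(events_path, index=False, lineterminator="\n")
    if truth_path is not None:
        import json

        Path(truth_path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return events_df, truth
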
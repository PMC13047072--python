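"""Synthetic spontaneous-report generator with known ground truth.

Emulates the structure of a FAERS-like corpus: multi-drug, multi-event case
reports with demographics (high missingness in weight and age, as in real
spontaneous reporting), reporter occupation, country, seriousness outcomes,
drug start and event onset dates — and, crucially, *planted* drug-event
associations of known strength so that every downstream stage (curation,
contingency, disproportionality, subgroup, risk model) can be tested for
recovery without any external download.

Model, per report:

* demographics: sex ~ Bernoulli(p_female); age ~ lognormal (years, clipped
  to [0, 120]); weight ~ normal (kg, clipped to (30, 200));
* a drug set of size >= 1 (zero-truncated Poisson, capped at the dictionary
  size) sampled without replacement with probability proportional to the
  drug popularity vector;
* each event term occurs independently with odds
  base_odds(event) * prod(theta over planted pairs whose drug is in the
  report) * exp(covariate effects); covariate effects act on the target
  event (index 0) only;
* reports realizing zero events are rejected and resampled — a spontaneous
  report always carries at least one reaction. Rejection conditions on
  "some event occurred", which leaves the exposure-event odds ratio equal to
  the planted theta (the discarded reports deplete the drug/no-event and
  no-drug/no-event cells by the same factor), so the crude ROR is the exact
  estimand of a recovery test;
* MCAR masking then hides weight/age/sex/TTO/country at configured rates.

Everything derives from one numpy Generator, so a seed reproduces the corpus
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .report_store import (
    CaseReport,
    DrugEntry,
    DrugRole,
    Outcome,
    Reporter,
    Sex,
)

__all__ = ["PlantedPair", "SyntheticConfig", "SyntheticTruth", "generate", "truth_table"]


class PlantedPair(BaseModel):
    """A drug-event association planted at odds multiplier theta."""

    drug: str
    event: str
    theta: float = Field(gt=0)


class SyntheticConfig(BaseModel):
    """Study conditions for one synthetic corpus.

    Missingness defaults mirror the magnitudes seen in real spontaneous
    cheilitis reports: weight unknown for about two thirds of reports, age
    for about a quarter, sex rarely, and time-to-onset about half.
    """

    n_reports: int = Field(default=5000, ge=1)
    n_drugs: int = Field(default=30, ge=1)
    n_events: int = Field(default=20, ge=1)
    target_event: str = "Cheilitis"
    drug_popularity: list[float] | None = None
    event_base_rate: list[float] | None = None
    mean_events: float = Field(default=1.2, gt=0)
    mean_drugs: float = Field(default=2.0, ge=1.0)
    planted: list[PlantedPair] = Field(default_factory=list)
    sex_p_female: float = Field(default=0.63, ge=0, le=1)
    age_log_mu: float = 3.85   # lognormal median ~ 47 years
    age_log_sigma: float = Field(default=0.55, gt=0)
    weight_mu: float = 72.0
    weight_sigma: float = Field(default=16.0, gt=0)
    tto_log_median_days: float = Field(default=15.0, gt=0)
    tto_log_sigma: float = Field(default=1.6, gt=0)
    missing_weight: float = Field(default=0.66, ge=0, le=1)
    missing_age: float = Field(default=0.27, ge=0, le=1)
    missing_sex: float = Field(default=0.066, ge=0, le=1)
    missing_tto: float = Field(default=0.47, ge=0, le=1)
    missing_country: float = Field(default=0.28, ge=0, le=1)
    covariate_effects: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("drug_popularity", "event_base_rate")
    @classmethod
    def _prob_vector(cls, v):
        if v is not None:
            if any(x < 0 for x in v):
                raise ValueError("probability vector entries must be non-negative")
            if abs(sum(v) - 1.0) > 1e-8:
                raise ValueError("probability vector must sum to 1")
        return v

    @model_validator(mode="after")
    def _lengths(self):
        if self.drug_popularity is not None and len(self.drug_popularity) != self.n_drugs:
            raise ValueError("drug_popularity length must equal n_drugs")
        if self.event_base_rate is not None and len(self.event_base_rate) != self.n_events:
            raise ValueError("event_base_rate length must equal n_events")
        for key in self.covariate_effects:
            if key not in ("sex_male", "age_years", "weight_kg"):
                raise ValueError(f"unknown covariate effect: {key!r}")
        names = {(p.drug, p.event) for p in self.planted}
        if len(names) != len(self.planted):
            raise ValueError("duplicate planted pairs")
        return self

    def drug_names(self) -> list[str]:
        return [f"DRUG_{i:03d}" for i in range(self.n_drugs)]

    def event_names(self) -> list[str]:
        return [self.target_event] + [f"EVENT_{i:03d}" for i in range(1, self.n_events)]


@dataclass
class SyntheticTruth:
    """Planted structure plus realized quantities for recovery scoring."""

    planted: list[PlantedPair]
    covariate_effects: dict[str, float]
    realized_pair_counts: dict[tuple[str, str], int]
    n_reports: int
    n_rejected: int = 0


_OUTCOME_P = {
    Outcome.OTHER_SERIOUS: 0.41,
    Outcome.HOSPITALIZATION: 0.26,
    Outcome.DEATH: 0.030,
    Outcome.LIFE_THREATENING: 0.029,
    Outcome.DISABILITY: 0.025,
    Outcome.REQUIRED_INTERVENTION: 0.006,
    Outcome.CONGENITAL_ANOMALY: 0.0006,
}

_REPORTER_P = [
    (Reporter.CONSUMER, 0.43),
    (Reporter.PHYSICIAN, 0.23),
    (Reporter.OTHER_HEALTH_PROFESSIONAL, 0.14),
    (Reporter.PHARMACIST, 0.10),
    (Reporter.UNKNOWN, 0.06),
    (Reporter.LAWYER, 0.036),
    (Reporter.REGISTERED_NURSE, 0.004),
]

_COUNTRY_P = [("US", 0.635), ("FR", 0.090), ("JP", 0.045), ("CA", 0.036),
              ("GB", 0.031), ("OTHER", 0.163)]

_INDICATIONS = [
    "Acne", "Hypertension", "Diabetes mellitus", "Depression", "Psoriasis",
    "Rheumatoid arthritis", "Asthma", "Multiple myeloma", "Epilepsy",
    "Dermatitis atopic",
]

_EPOCH = date(2004, 1, 1)
_WINDOW_DAYS = (date(2025, 6, 30) - _EPOCH).days


def _default_popularity(n: int, rng_free: bool = True) -> np.ndarray:
    # Zipf-ish popularity, deterministic in n
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[list[CaseReport], SyntheticTruth]:
    """Sample a corpus of case reports plus its ground truth.

    ``seed`` overrides ``config.seed``. Fully deterministic for a given
    (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_target = config.n_reports
    drugs = config.drug_names()
    events = config.event_names()
    n_d, n_e = config.n_drugs, config.n_events

    pop = (
        np.asarray(config.drug_popularity, dtype=float)
        if config.drug_popularity is not None
        else _default_popularity(n_d)
    )
    base_share = (
        np.asarray(config.event_base_rate, dtype=float)
        if config.event_base_rate is not None
        else np.full(n_e, 1.0 / n_e)
    )
    p_event = np.clip(config.mean_events * base_share, 1e-6, 0.5)
    base_log_odds = np.log(p_event / (1.0 - p_event))

    log_theta = np.zeros((n_d, n_e))
    d_index = {name: i for i, name in enumerate(drugs)}
    e_index = {name: i for i, name in enumerate(events)}
    for pair in config.planted:
        if pair.drug not in d_index or pair.event not in e_index:
            raise ValueError(f"planted pair {pair.drug!r}/{pair.event!r} "
                             "not in the drug/event dictionaries")
        log_theta[d_index[pair.drug], e_index[pair.event]] = np.log(pair.theta)

    eff = config.covariate_effects
    log_pop = np.log(pop + 1e-300)

    accepted: list[dict] = []
    n_rejected = 0
    while len(accepted) < n_target:
        m = max(1024, int((n_target - len(accepted)) * 1.8))
        sex_male = (rng.random(m) >= config.sex_p_female).astype(np.int8)
        age = np.clip(rng.lognormal(config.age_log_mu, config.age_log_sigma, m), 0.0, 120.0)
        weight = np.clip(rng.normal(config.weight_mu, config.weight_sigma, m), 30.0, 200.0)

        sizes = rng.poisson(config.mean_drugs - 1.0, m) + 1  # zero-truncated at 1
        sizes = np.minimum(sizes, n_d)
        # Gumbel-top-k: weighted sampling without replacement per report
        keys = log_pop[None, :] + rng.gumbel(size=(m, n_d))
        order = np.argsort(-keys, axis=1)
        exposure = np.zeros((m, n_d), dtype=bool)
        col_rank = np.empty_like(order)
        rows = np.arange(m)[:, None]
        col_rank[rows, order] = np.arange(n_d)[None, :]
        exposure = col_rank < sizes[:, None]

        logits = base_log_odds[None, :] + exposure.astype(float) @ log_theta
        covar_shift = (
            eff.get("sex_male", 0.0) * sex_male
            + eff.get("age_years", 0.0) * (age - 50.0)
            + eff.get("weight_kg", 0.0) * (weight - 70.0)
        )
        logits[:, 0] = logits[:, 0] + covar_shift
        occ = rng.random((m, n_e)) < 1.0 / (1.0 + np.exp(-logits))

        has_event = occ.any(axis=1)
        n_rejected += int((~has_event).sum())

        # per-report extras (drawn for all m to keep the stream simple)
        receipt_off = rng.integers(0, _WINDOW_DAYS + 1, m)
        tto = np.round(
            rng.lognormal(np.log(config.tto_log_median_days), config.tto_log_sigma, m)
        ).astype(int)
        start_back = rng.integers(1, 365, m)  # suspect start precedes receipt
        outc_u = rng.random((m, len(_OUTCOME_P)))
        rep_u = rng.random(m)
        ctry_u = rng.random(m)
        miss_w = rng.random(m) < config.missing_weight
        miss_a = rng.random(m) < config.missing_age
        miss_s = rng.random(m) < config.missing_sex
        miss_t = rng.random(m) < config.missing_tto
        miss_c = rng.random(m) < config.missing_country
        indic_idx = rng.integers(0, len(_INDICATIONS), m)
        has_indic = rng.random(m) < 0.5

        for i in np.flatnonzero(has_event):
            if len(accepted) >= n_target:
                break
            accepted.append(
                dict(
                    sex_male=int(sex_male[i]),
                    age=float(np.round(age[i], 1)),
                    weight=float(np.round(weight[i], 1)),
                    drug_idx=np.flatnonzero(exposure[i]),
                    event_idx=np.flatnonzero(occ[i]),
                    receipt_off=int(receipt_off[i]),
                    tto=int(tto[i]),
                    start_back=int(start_back[i]),
                    outc=tuple(
                        o for j, o in enumerate(_OUTCOME_P) if outc_u[i, j] < _OUTCOME_P[o]
                    ),
                    rep_u=float(rep_u[i]),
                    ctry_u=float(ctry_u[i]),
                    miss=(bool(miss_w[i]), bool(miss_a[i]), bool(miss_s[i]),
                          bool(miss_t[i]), bool(miss_c[i])),
                    indic=_INDICATIONS[indic_idx[i]] if has_indic[i] else None,
                )
            )

    def _categorical(u: float, table) -> object:
        acc = 0.0
        for value, p in table:
            acc += p
            if u < acc:
                return value
        return table[-1][0]

    reports: list[CaseReport] = []
    pair_counts: dict[tuple[str, str], int] = {
        (p.drug, p.event): 0 for p in config.planted
    }
    for k, row in enumerate(accepted):
        receipt = _EPOCH + timedelta(days=row["receipt_off"])
        start = receipt - timedelta(days=row["start_back"])
        onset = start + timedelta(days=row["tto"])
        miss_w_, miss_a_, miss_s_, miss_t_, miss_c_ = row["miss"]

        entry_drugs = []
        for j, di in enumerate(row["drug_idx"]):
            role = DrugRole.PRIMARY_SUSPECT if j == 0 else DrugRole.CONCOMITANT
            entry_drugs.append(
                DrugEntry(
                    name=drugs[di],
                    role=role,
                    start_date=start if j == 0 else None,
                    indication=row["indic"] if j == 0 else None,
                )
            )
        evs = [events[ei] for ei in row["event_idx"]]
        for p in config.planted:
            if (
                d_index[p.drug] in set(row["drug_idx"])
                and e_index[p.event] in set(row["event_idx"])
            ):
                pair_counts[(p.drug, p.event)] += 1

        reports.append(
            CaseReport(
                case_id=f"SYN{k:07d}",
                receipt_date=receipt,
                report_version=1,
                sex=Sex.UNKNOWN if miss_s_ else (Sex.MALE if row["sex_male"] else Sex.FEMALE),
                age_years=None if miss_a_ else row["age"],
                weight_kg=None if miss_w_ else row["weight"],
                reporter=_categorical(row["rep_u"], _REPORTER_P),
                country=None if miss_c_ else _categorical(row["ctry_u"], _COUNTRY_P),
                drugs=entry_drugs,
                events=evs,
                outcomes=frozenset(row["outc"]),
                event_onset_date=None if miss_t_ else onset,
            )
        )

    truth = SyntheticTruth(
        planted=list(config.planted),
        covariate_effects=dict(config.covariate_effects),
        realized_pair_counts=pair_counts,
        n_reports=len(reports),
        n_rejected=n_rejected,
    )
    return reports, truth


def truth_table(
    truth: SyntheticTruth,
    pairs: Sequence[tuple[str, str]] | None = None,
    theta_threshold: float = 1.0,
) -> dict[tuple[str, str], bool]:
    """Expected signal labels: planted pairs with theta >= threshold are signals.

    When ``pairs`` is given, every listed pair gets a label (unplanted pairs
    are non-signals); otherwise only the planted pairs are labelled.
    """
    planted = {(p.drug, p.event): p.theta for p in truth.planted}
    if pairs is None:
        return {pair: theta >= theta_threshold for pair, theta in planted.items()}
    return {
        pair: planted.get(pair, 0.0) >= theta_threshold and pair in planted
        for pair in pairs
    }
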
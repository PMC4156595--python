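"""Synthetic spontaneous-report databases with known ground truth.

No public archive reproduces a regulatory database snapshot, so every stage
of the pipeline is exercised against generated data embodying exactly the
statistical structure the analysis assumes: each (drug, PT) pair owns a
fixed reporting ratio lambda drawn once from a two-gamma mixture (the
gamma-Poisson assumption the shrinkage model fits), a minority of planted
pairs carry elevated lambda, and a fraction of reports is cloned into
near-duplicate clusters with jittered ages and occasional field drops.

Reports carry the demographic and provenance fields the deduplication
criteria need (gender, age, death date, manufacturer, source, receipt
date) and complete drug/event dates.  Every generated report records at
least one drug and at least one event — a spontaneous report exists
because a suspected drug-event experience was reported.  When no studied
vocabulary entry is drawn, the report receives a background drug/term from
outside the studied vocabulary, mirroring a real database where the
studied drugs and terms are a small slice of a much larger dictionary;
background entries are never counted, so the studied margins stay
calibrated at n_reports x marginal probability.  Generation is fully
deterministic given the seed.

What this generator does NOT emulate: real term frequencies, drug
co-prescription structure, or reporting dynamics over time (notoriety
effects); see the package methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .gps import PosteriorScore, PriorHyperparameters
from .pair_counting import ContingencyCell
from .report_store import (
    DrugEntry,
    DrugRole,
    EventEntry,
    Gender,
    PartialDate,
    ReportDatabase,
    SafetyReport,
    SourceType,
)
from .screening import SignalVerdict

__all__ = [
    "DemographicsModel",
    "DuplicateJitter",
    "SimulationConfig",
    "GroundTruth",
    "RecoveryMetrics",
    "DEFAULT_BACKGROUND_HYPER",
    "default_drug_vocab",
    "default_pt_vocab",
    "simulate_database",
    "simulate_cells",
    "recovery_metrics",
]


#: Background reporting-ratio mixture: most pairs near the null (mean 1),
#: a 10% minority moderately elevated (mean 2).
DEFAULT_BACKGROUND_HYPER = PriorHyperparameters(2.0, 2.0, 2.0, 1.0, 0.9)

#: Out-of-vocabulary fillers for reports that drew no studied entry;
#: common report-database terms, never counted by the pipeline.
BACKGROUND_PTS = ("drug ineffective", "nausea", "headache", "dizziness", "fatigue")
BACKGROUND_DRUGS = ("paracetamol", "aspirin", "ibuprofen", "omeprazole", "metformin")


@dataclass(frozen=True)
class DemographicsModel:
    """Gender/age/death-date distributions for generated reports."""

    p_female: float = 0.5
    age_mean: float = 48.0
    age_sd: float = 15.0
    age_min: float = 18.0
    age_max: float = 90.0
    p_death: float = 0.03


@dataclass(frozen=True)
class DuplicateJitter:
    """How a cloned report differs from its original."""

    age_jitter_years: int = 1
    p_drop_manufacturer: float = 0.05
    p_drop_death_date: float = 0.0


def default_drug_vocab(n_drugs: int = 20) -> dict[str, float]:
    """n drugs with exposure probabilities spread over [0.01, 0.09]."""
    probs = np.linspace(0.01, 0.09, n_drugs)
    return {f"drug{i + 1:02d}": float(p) for i, p in enumerate(probs)}


def default_pt_vocab(n_pts: int = 15) -> dict[str, float]:
    """n preferred terms with base report rates spread over [0.002, 0.02]."""
    probs = np.linspace(0.002, 0.02, n_pts)
    return {f"event{i + 1:02d}": float(p) for i, p in enumerate(probs)}


@dataclass
class SimulationConfig:
    """Study conditions for one generated database.  Seed is mandatory."""

    n_reports: int
    seed: int
    drug_vocab: Mapping[str, float] = field(default_factory=default_drug_vocab)
    pt_vocab: Mapping[str, float] = field(default_factory=default_pt_vocab)
    true_hyper: PriorHyperparameters | None = DEFAULT_BACKGROUND_HYPER
    planted_signals: Sequence[tuple[str, str, float]] = ()
    duplicate_fraction: float = 0.05
    duplicate_jitter: DuplicateJitter = field(default_factory=DuplicateJitter)
    demographics: DemographicsModel = field(default_factory=DemographicsModel)
    source_mix: Mapping[str, float] = field(
        default_factory=lambda: {"spontaneous": 0.9, "literature": 0.05, "study": 0.05}
    )
    manufacturers: Sequence[str] = ("MFR_A", "MFR_B", "MFR_C", "MFR_D", "MFR_E")
    max_event_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, p in {**self.drug_vocab, **self.pt_vocab}.items():
            if not (0 <= p <= 1):
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        if not (0 <= self.duplicate_fraction < 1):
            raise ValueError("duplicate_fraction must lie in [0, 1)")
        if abs(sum(self.source_mix.values()) - 1.0) > 1e-9:
            raise ValueError("source_mix probabilities must sum to 1")
        for drug, pt, lam in self.planted_signals:
            if drug not in self.drug_vocab:
                raise ValueError(f"planted drug {drug!r} not in drug_vocab")
            if pt not in self.pt_vocab:
                raise ValueError(f"planted PT {pt!r} not in pt_vocab")
            if lam < 1:
                raise ValueError("planted lambda must be >= 1")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    lambda_map: dict[tuple[str, str], float]
    duplicate_clusters: list[frozenset[str]]
    drug_margins: dict[str, int]
    pt_margins: dict[str, int]


@dataclass(frozen=True)
class RecoveryMetrics:
    """Detection quality against ground truth.

    ``sensitivity``/``specificity`` are None (not 0) when no pair in the
    respective truth class exists.
    """

    sensitivity: float | None
    specificity: float | None
    rank_agreement: float | None
    n_signal_pairs: int
    n_null_pairs: int


def _random_dates(rng: np.random.Generator, size: int) -> list[PartialDate]:
    years = rng.integers(2005, 2013, size=size)
    months = rng.integers(1, 13, size=size)
    days = rng.integers(1, 29, size=size)
    return [PartialDate(int(y), int(m), int(d)) for y, m, d in zip(years, months, days)]


def _truncated_ages(rng: np.random.Generator, model: DemographicsModel, size: int) -> np.ndarray:
    ages = np.round(rng.normal(model.age_mean, model.age_sd, size=size))
    bad = (ages < model.age_min) | (ages > model.age_max)
    while bad.any():
        ages[bad] = np.round(rng.normal(model.age_mean, model.age_sd, size=int(bad.sum())))
        bad = (ages < model.age_min) | (ages > model.age_max)
    return ages


def simulate_database(config: SimulationConfig) -> tuple[ReportDatabase, GroundTruth]:
    """Generate a report database and its ground truth.

    Per report, drug exposures are independent Bernoulli draws from the
    vocabulary's marginal probabilities; each PT then occurs with
    probability base_rate x lambda(drug, PT), taking the largest lambda over
    the report's drugs (lambda = 1 when no drug carries one).  lambda is
    drawn once per (drug, PT) pair from the background mixture — or fixed
    at a planted value — and validated against the event-probability cap:
    a pair whose scaled rate would exceed the cap raises instead of being
    silently truncated.
    """
    rng = np.random.default_rng(config.seed)
    drugs = list(config.drug_vocab)
    pts = list(config.pt_vocab)
    exp_p = np.array([config.drug_vocab[d] for d in drugs])
    base = np.array([config.pt_vocab[t] for t in pts])
    n, D, P = config.n_reports, len(drugs), len(pts)

    # one lambda per (drug, pt), fixed for the whole database
    if config.true_hyper is None:
        lam = np.ones((D, P))
    else:
        h = config.true_hyper
        pick1 = rng.random((D, P)) < h.mix_weight
        lam = np.where(
            pick1,
            rng.gamma(h.alpha1, 1.0 / h.beta1, size=(D, P)),
            rng.gamma(h.alpha2, 1.0 / h.beta2, size=(D, P)),
        )
    for drug, pt, v in config.planted_signals:
        lam[drugs.index(drug), pts.index(pt)] = v

    scaled = lam * base[None, :]
    if scaled.max() > config.max_event_probability:
        d_i, p_i = np.unravel_index(np.argmax(scaled), scaled.shape)
        raise ValueError(
            f"event probability {scaled.max():.3f} for ({drugs[d_i]}, {pts[p_i]}) "
            f"exceeds the cap {config.max_event_probability}; reduce the base "
            "rate or the planted lambda"
        )

    exposure = rng.random((n, D)) < exp_p[None, :]
    events = np.zeros((n, P), dtype=bool)
    for j in range(P):
        best = np.where(exposure, lam[:, j][None, :], 0.0).max(axis=1, initial=0.0)
        lam_eff = np.where(best > 0, best, 1.0)
        events[:, j] = rng.random(n) < base[j] * lam_eff
    # background fillers keep every report non-empty without touching the
    # studied margins (they live outside the studied vocabulary)
    bg_drug = rng.choice(len(BACKGROUND_DRUGS), size=n)
    bg_pt = rng.choice(len(BACKGROUND_PTS), size=n)

    dem = config.demographics
    genders = np.where(rng.random(n) < dem.p_female, "F", "M")
    ages = _truncated_ages(rng, dem, n)
    died = rng.random(n) < dem.p_death
    death_dates = _random_dates(rng, n)
    receipt_dates = _random_dates(rng, n)
    sources = rng.choice(
        list(config.source_mix), size=n, p=list(config.source_mix.values())
    )
    mfrs = rng.choice(list(config.manufacturers), size=n)

    reports: list[SafetyReport] = []
    for i in range(n):
        names = [drugs[d_i] for d_i in np.nonzero(exposure[i])[0]]
        if not names:
            names = [BACKGROUND_DRUGS[bg_drug[i]]]
        drug_entries = []
        for name in names:
            start = _random_dates(rng, 1)[0]
            drug_entries.append(
                DrugEntry(
                    name_raw=name,
                    name_canonical=name,
                    role=DrugRole.SUSPECT,
                    start_date=start,
                )
            )
        terms_i = [pts[p_i] for p_i in np.nonzero(events[i])[0]]
        if not terms_i:
            terms_i = [BACKGROUND_PTS[bg_pt[i]]]
        event_entries = []
        for pt in terms_i:
            onset = _random_dates(rng, 1)[0]
            event_entries.append(EventEntry(preferred_term=pt, onset_date=onset))
        reports.append(
            SafetyReport(
                report_id=f"R{i + 1:07d}",
                source_type=SourceType(sources[i]),
                gender=Gender(genders[i]),
                age_years=float(ages[i]),
                death_date=death_dates[i] if died[i] else None,
                receipt_date=receipt_dates[i],
                manufacturer=str(mfrs[i]),
                drugs=drug_entries,
                events=event_entries,
            )
        )

    drug_margins = {d: int(exposure[:, i].sum()) for i, d in enumerate(drugs)}
    pt_margins = {t: int(events[:, j].sum()) for j, t in enumerate(pts)}

    # near-duplicate clusters: clones with jittered age, occasional drops
    clusters: list[frozenset[str]] = []
    k = int(round(config.duplicate_fraction * n))
    if k:
        jit = config.duplicate_jitter
        chosen = rng.choice(n, size=k, replace=False)
        for c, i in enumerate(chosen):
            orig = reports[i]
            jitter = int(rng.integers(-jit.age_jitter_years, jit.age_jitter_years + 1))
            age = None
            if orig.age_years is not None:
                age = float(min(max(orig.age_years + jitter, 0.0), 150.0))
            manufacturer = orig.manufacturer
            if rng.random() < jit.p_drop_manufacturer:
                manufacturer = None
            death = orig.death_date
            if death is not None and rng.random() < jit.p_drop_death_date:
                death = None
            clone_id = f"D{c + 1:07d}"
            reports.append(
                SafetyReport(
                    report_id=clone_id,
                    source_type=orig.source_type,
                    gender=orig.gender,
                    age_years=age,
                    death_date=death,
                    receipt_date=orig.receipt_date,
                    manufacturer=manufacturer,
                    drugs=orig.drugs,
                    events=orig.events,
                )
            )
            clusters.append(frozenset({orig.report_id, clone_id}))

    truth = GroundTruth(
        lambda_map={
            (d, t): float(lam[i, j]) for i, d in enumerate(drugs) for j, t in enumerate(pts)
        },
        duplicate_clusters=clusters,
        drug_margins=drug_margins,
        pt_margins=pt_margins,
    )
    return ReportDatabase(reports), truth


def simulate_cells(
    hyper: PriorHyperparameters,
    n_cells: int,
    seed: int,
    e_low: float = 0.1,
    e_high: float = 100.0,
) -> tuple[list[ContingencyCell], np.ndarray]:
    """Cells drawn straight from the gamma-Poisson mixture model.

    E ~ log-uniform over [e_low, e_high], lambda from the mixture, N from
    Poisson(lambda E).  Used for hyperparameter-recovery checks where the
    generative model must match the fitted one exactly.  Returns the cells
    and the true lambda per cell.
    """
    rng = np.random.default_rng(seed)
    e = np.exp(rng.uniform(np.log(e_low), np.log(e_high), size=n_cells))
    pick1 = rng.random(n_cells) < hyper.mix_weight
    lam = np.where(
        pick1,
        rng.gamma(hyper.alpha1, 1.0 / hyper.beta1, size=n_cells),
        rng.gamma(hyper.alpha2, 1.0 / hyper.beta2, size=n_cells),
    )
    n = rng.poisson(lam * e)
    cells = [
        ContingencyCell(
            drug=f"pair{i:05d}",
            term="simulated",
            observed_n=int(n[i]),
            expected_e=float(e[i]),
            rrr=float(n[i] / e[i]),
        )
        for i in range(n_cells)
    ]
    return cells, lam


def recovery_metrics(
    verdicts: Sequence[SignalVerdict],
    scores: Sequence[tuple[ContingencyCell, PosteriorScore]],
    truth: GroundTruth,
    lambda_signal_cutoff: float = 2.0,
) -> RecoveryMetrics:
    """Detection sensitivity/specificity and score-truth rank agreement.

    Sensitivity: flagged fraction among scored pairs whose true lambda is
    at least the cutoff.  Specificity: unflagged fraction among exact-null
    (lambda = 1) pairs.  Rank agreement: Spearman correlation of EBGM with
    true lambda over all scored pairs with known truth.  Classes with no
    member report None rather than 0.
    """
    flagged = {(v.drug, v.term): v.flagged for v in verdicts}
    signal_flags: list[bool] = []
    null_flags: list[bool] = []
    ebgm: list[float] = []
    lam: list[float] = []
    for c, s in scores:
        key = (c.drug, c.term)
        if key not in truth.lambda_map or key not in flagged:
            continue
        true_lam = truth.lambda_map[key]
        ebgm.append(s.ebgm)
        lam.append(true_lam)
        if true_lam >= lambda_signal_cutoff:
            signal_flags.append(flagged[key])
        elif true_lam == 1.0:
            null_flags.append(flagged[key])
    sensitivity = float(np.mean(signal_flags)) if signal_flags else None
    specificity = float(1.0 - np.mean(null_flags)) if null_flags else None
    rank = None
    if len(ebgm) >= 3 and len(set(lam)) > 1:
        rank = float(stats.spearmanr(ebgm, lam).statistic)
    return RecoveryMetrics(
        sensitivity=sensitivity,
        specificity=specificity,
        rank_agreement=rank,
        n_signal_pairs=len(signal_flags),
        n_null_pairs=len(null_flags),
    )
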
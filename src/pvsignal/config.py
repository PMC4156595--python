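"""Validated pipeline configuration (YAML, schema-checked before any I/O).

Unknown keys are rejected outright; seeds are mandatory wherever randomness
exists (no wall-clock defaults) because run-to-run reproducibility is part
of the pipeline contract.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dedup import MatchStage, default_stage_ladder
from .gps import DEFAULT_INIT, PriorHyperparameters
from .pair_counting import EventTerm
from .report_store import FileDialect, SourceType
from .synthetic import (
    DEFAULT_BACKGROUND_HYPER,
    DuplicateJitter,
    SimulationConfig,
    default_drug_vocab,
    default_pt_vocab,
)

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DialectConfig(_Strict):
    delimiter: str = "$"
    has_header: bool = True

    def build(self) -> FileDialect:
        return FileDialect(delimiter=self.delimiter, has_header=self.has_header)


class IOConfig(_Strict):
    demo: str
    drug: str
    reac: str
    dialect: DialectConfig = Field(default_factory=DialectConfig)


class StageConfig(_Strict):
    name: str
    demographic_fields: list[Literal["gender", "age", "death_date"]] = []
    age_tolerance_years: float = 1.0
    record_fields: list[
        Literal[
            "manufacturer",
            "drug_set",
            "event_set",
            "drug_start_dates",
            "event_start_dates",
        ]
    ] = []
    sources: list[Literal["spontaneous", "literature", "study"]] = [
        "spontaneous",
        "literature",
        "study",
    ]

    def build(self) -> MatchStage:
        return MatchStage(
            stage_name=self.name,
            required_demographic_fields=frozenset(self.demographic_fields),
            age_tolerance_years=self.age_tolerance_years,
            required_record_fields=frozenset(self.record_fields),
            applies_to_sources=frozenset(SourceType(s) for s in self.sources),
        )


class DedupConfig(_Strict):
    enabled: bool = True
    keep_rule: Literal["latest_receipt", "lexicographic_id"] = "latest_receipt"
    age_tolerance_years: float = 1.0
    stages: Optional[list[StageConfig]] = None

    def build_stages(self) -> list[MatchStage]:
        if self.stages is None:
            return default_stage_ladder(self.age_tolerance_years)
        return [s.build() for s in self.stages]


class HyperConfig(_Strict):
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_weight: float

    def build(self) -> PriorHyperparameters:
        return PriorHyperparameters(
            self.alpha1, self.beta1, self.alpha2, self.beta2, self.mix_weight
        )


class MGPSConfig(_Strict):
    seed: int
    n_restarts: int = 5
    init: Optional[HyperConfig] = None

    def build_init(self) -> PriorHyperparameters:
        return self.init.build() if self.init is not None else DEFAULT_INIT


class PlantedSignal(_Strict):
    drug: str
    pt: str
    true_lambda: float = Field(ge=1)


class SimulateConfig(_Strict):
    n_reports: int = Field(gt=0)
    seed: int
    n_drugs: int = 20
    n_pts: int = 15
    background: Literal["mixture", "null"] = "mixture"
    background_hyper: Optional[HyperConfig] = None
    planted_signals: list[PlantedSignal] = []
    duplicate_fraction: float = Field(default=0.05, ge=0, lt=1)
    age_jitter_years: int = 1

    def build(self) -> SimulationConfig:
        if self.background == "null":
            hyper = None
        elif self.background_hyper is not None:
            hyper = self.background_hyper.build()
        else:
            hyper = DEFAULT_BACKGROUND_HYPER
        return SimulationConfig(
            n_reports=self.n_reports,
            seed=self.seed,
            drug_vocab=default_drug_vocab(self.n_drugs),
            pt_vocab=default_pt_vocab(self.n_pts),
            true_hyper=hyper,
            planted_signals=[
                (p.drug, p.pt, p.true_lambda) for p in self.planted_signals
            ],
            duplicate_fraction=self.duplicate_fraction,
            duplicate_jitter=DuplicateJitter(age_jitter_years=self.age_jitter_years),
        )


#: The shipped example term set (single suicidality PTs plus the composite).
_DEFAULT_TERM_BLOCK: dict[str, list[str]] = {
    "suicidal ideation": ["suicidal ideation"],
    "suicide attempt": ["suicide attempt"],
    "completed suicide": ["completed suicide"],
    "suicidality": ["suicidal ideation", "suicide attempt", "completed suicide"],
}


class PipelineConfig(_Strict):
    """Everything one `run` needs, validated before any stage executes."""

    io: IOConfig
    output_dir: str = "pvsignal_out"
    drugs: Optional[list[str]] = None
    combo_map: Optional[dict[str, list[str]]] = None
    salt_suffixes: list[str] = []
    suspect_only: bool = False
    terms: dict[str, list[str]] = Field(
        default_factory=lambda: dict(_DEFAULT_TERM_BLOCK)
    )
    dedup: DedupConfig = Field(default_factory=DedupConfig)
    mgps: MGPSConfig
    threshold: float = Field(default=2.0, gt=0)
    simulate: Optional[SimulateConfig] = None

    @field_validator("terms")
    @classmethod
    def _terms_nonempty(cls, v: dict[str, list[str]]) -> dict[str, list[str]]:
        if not v:
            raise ValueError("at least one event term is required")
        for name, pts in v.items():
            if not pts:
                raise ValueError(f"term {name!r} has no member PTs")
        return v

    def build_terms(self) -> list[EventTerm]:
        return [
            EventTerm(name=name, member_pts=frozenset(pts))
            for name, pts in self.terms.items()
        ]


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return PipelineConfig.model_validate(raw)
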
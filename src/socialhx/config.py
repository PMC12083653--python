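"""Experiment configuration (YAML-backed, schema-validated) and seed derivation."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from socialhx.synthgen import CohortSpec, CorpusSpec


def derive_seed(master_seed: int, module_name: str) -> int:
    """Stable per-module seed below 2**31, so stages can be rerun in isolation."""
    digest = hashlib.sha256(f"{master_seed}:{module_name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class AnnotatorConfig(BaseModel):
    """Noise applied on top of the pattern extractor to emulate two distinct
    imperfect note-level models; the structured field needs no extra noise
    (missingness/staleness live in the corpus spec)."""

    model_a_accuracy: float = 0.85
    model_b_accuracy: float = 0.75
    dating_category: bool = True  # derive DATING instead of demoting to SINGLE


class SplitConfig(BaseModel):
    tune_frac: float = 0.15
    test_frac: float = 0.15


class StudentConfig(BaseModel):
    l2: float = 1e-3
    max_iter: int = 500
    tol: float = 1e-6
    keep_abstentions: bool = False


class ForestCfg(BaseModel):
    n_trees: int = 200
    max_depth: int = 8


class EvaluationConfig(BaseModel):
    include_zero_support: bool = False


class CohortRules(BaseModel):
    min_admissions: int = 2
    max_span_years: float = 5.0
    span_mode: str = "span"
    age_tolerance_years: float = 2.0
    reference_group: str = "MARRIED"


class ExperimentConfig(BaseModel):
    """One config drives the whole pipeline; the master seed derives every
    module seed deterministically."""

    master_seed: int = 0
    corpus: dict = Field(default_factory=lambda: {"n_notes": 2000})
    cohort: dict = Field(default_factory=dict)
    split: SplitConfig = Field(default_factory=SplitConfig)
    annotators: AnnotatorConfig = Field(default_factory=AnnotatorConfig)
    strategies: list[str] = Field(
        default_factory=lambda: ["unanimous", "majority", "precision", "forest"]
    )
    student: StudentConfig = Field(default_factory=StudentConfig)
    forest: ForestCfg = Field(default_factory=ForestCfg)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    cohort_rules: CohortRules = Field(default_factory=CohortRules)

    def corpus_spec(self) -> CorpusSpec:
        kwargs = dict(self.corpus)
        kwargs["seed"] = derive_seed(self.master_seed, "synthgen.corpus")
        return CorpusSpec(**kwargs)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.cohort)
        if not kwargs:
            from socialhx.synthgen import CHANGE_GROUP_SIZES

            kwargs["change_group_sizes"] = dict(CHANGE_GROUP_SIZES)
        kwargs["seed"] = derive_seed(self.master_seed, "synthgen.cohort")
        return CohortSpec(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
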
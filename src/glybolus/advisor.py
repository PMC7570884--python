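"""Model/Results facade over the two-step training framework.

:class:`BolusAdvisor` is built from a virtual cohort (or any list of
subjects); ``fit()`` runs population pre-training on the average subject
followed by per-subject personalization, returning a
:class:`BolusAdvisorResults` that carries the trained policies, learning
diagnostics and evaluation machinery, statsmodels-style::

    model = BolusAdvisor.from_cohort(n_adults=10, n_adolescents=10, seed=1)
    res = model.fit(seed=1, population_days=180, personalization_days=180)
    comparison = res.evaluate(days=90, seed=1)
    print(comparison.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import (
    AgentConfig,
    MealProtocol,
    ReplayConfig,
    SafetyConstraint,
    SimConfig,
    TrainConfig,
)
from .metrics import paired_comparison
from .patient import PatientParams, make_cohort
from .therapy import TherapyParams, derive_therapy
from .trainer import TrainResult, evaluate, personalize, train_population

__all__ = ["BolusAdvisor", "BolusAdvisorResults", "CohortComparison"]

_METRICS = ("tir", "tbr", "tar", "mean_bg", "cv", "lbgi", "hbgi")
_HEADERS = {"tir": "TIR (%)", "tbr": "TBR (%)", "tar": "TAR (%)",
            "mean_bg": "Mean (mg/dL)", "cv": "CV (%)", "lbgi": "LBGI",
            "hbgi": "HBGI"}


@dataclass
class Subject:
    params: PatientParams
    therapy: TherapyParams

    @property
    def label(self) -> str:
        return self.params.label


class BolusAdvisor:
    """Adaptive meal-bolus policy model for a virtual T1D cohort."""

    def __init__(self, average: Subject, subjects: list[Subject],
                 agent_config: AgentConfig | None = None,
                 replay_config: ReplayConfig | None = None,
                 protocol: MealProtocol | None = None,
                 sim: SimConfig | None = None,
                 constraint: SafetyConstraint | None = None) -> None:
        self.average = average
        self.subjects = subjects
        self.agent_config = agent_config or AgentConfig()
        self.replay_config = replay_config or ReplayConfig()
        self.protocol = protocol or MealProtocol()
        self.sim = sim or SimConfig()
        self.constraint = constraint or SafetyConstraint()

    @classmethod
    def from_cohort(cls, n_adults: int, n_adolescents: int, seed: int,
                    **kwargs) -> "BolusAdvisor":
        """Build from a sampled cohort; therapy settings are derived from
        each subject's nominal physiology (fixed clinical practice)."""
        cohort = make_cohort(n_adults, n_adolescents, seed)
        subjects = [Subject(p, derive_therapy(p)) for p in cohort]
        return cls(average=subjects[0], subjects=subjects[1:], **kwargs)

    def fit(self, seed: int = 0, population_days: int = 180,
            personalization_days: int = 180,
            population_noise: float = 0.3,
            personalization_noise: float = 0.1,
            updates_per_transition: int | None = None) -> "BolusAdvisorResults":
        """Two-step training: population model, then one personalized model
        per subject initialized from it."""
        extra = ({} if updates_per_transition is None
                 else dict(updates_per_transition=updates_per_transition))
        pop_cfg = TrainConfig(phase="population", training_days=population_days,
                              explore_noise_std=population_noise,
                              rng_seed=int(seed), **extra)
        pop = train_population(self.average.params, self.average.therapy,
                               pop_cfg, self.agent_config, self.protocol,
                               self.replay_config, self.sim)
        checkpoint = pop.checkpoint()
        personalized: dict[str, TrainResult] = {}
        for i, subj in enumerate(self.subjects):
            cfg = TrainConfig(phase="personalized",
                              training_days=personalization_days,
                              explore_noise_std=personalization_noise,
                              rng_seed=int(seed) * 1000 + i + 1, **extra)
            personalized[subj.label] = personalize(
                checkpoint, subj.params, subj.therapy, cfg, self.constraint,
                self.protocol, self.replay_config, self.sim)
        return BolusAdvisorResults(model=self, population=pop,
                                   personalized=personalized, fit_seed=seed)


@dataclass
class BolusAdvisorResults:
    """Trained population and personalized policies plus diagnostics."""

    model: BolusAdvisor
    population: TrainResult
    personalized: dict[str, TrainResult]
    fit_seed: int

    def learning_curve(self, label: str | None = None) -> pd.DataFrame:
        result = self.population if label is None else self.personalized[label]
        return pd.DataFrame(result.learning_curve)

    def evaluate(self, days: int = 90, seed: int = 0) -> "CohortComparison":
        """Evaluate the calculator baseline and each personalized policy on
        matched scenario seeds (identical meals and sensor noise)."""
        rows = []
        for i, subj in enumerate(self.model.subjects):
            eval_seed = int(seed) * 1000 + i + 1
            _, sbc_rep = evaluate("sbc", subj.params, subj.therapy, days,
                                  eval_seed, self.model.protocol,
                                  self.model.sim)
            _, drl_rep = evaluate(self.personalized[subj.label].agent,
                                  subj.params, subj.therapy, days, eval_seed,
                                  self.model.protocol, self.model.sim)
            for method, rep in (("SBC", sbc_rep), ("DRL", drl_rep)):
                row = dict(subject=subj.label,
                           cohort=subj.label.split("-")[0], method=method,
                           **{m: getattr(rep, m) for m in _METRICS},
                           percent_ab=rep.percent_ab)
                rows.append(row)
        return CohortComparison(pd.DataFrame(rows))


@dataclass
class CohortComparison:
    """Per-subject outcome table for the paired SBC-vs-DRL comparison."""

    table: pd.DataFrame

    def summary(self, cohort: str | None = None) -> pd.DataFrame:
        """Mean +/- StD per metric per method with paired t-test p-values,
        one grid per cohort unless ``cohort`` narrows it."""
        df = self.table
        if cohort is not None:
            df = df[df.cohort == cohort]
        out = {}
        pivots = {m: df.pivot(index="subject", columns="method", values=m)
                  for m in _METRICS}
        for m in _METRICS:
            piv = pivots[m]
            out[_HEADERS[m]] = {
                "SBC": f"{piv['SBC'].mean():.1f}±{piv['SBC'].std():.1f}",
                "DRL": f"{piv['DRL'].mean():.1f}±{piv['DRL'].std():.1f}",
                "p": (f"{paired_comparison(piv['SBC'], piv['DRL']):.3g}"
                      if len(piv) >= 2 else "n/a"),
            }
        return pd.DataFrame(out).T[["SBC", "DRL", "p"]]

    def medians(self) -> pd.DataFrame:
        return self.table.groupby("method")[list(_METRICS)].median()
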
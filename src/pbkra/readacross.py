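"""Read-across parameter substitution and scenario suites.

A source chemical's PBK model is re-parameterised for a data-poor target in
three modes of increasing data demand:

* ``ORIGINAL`` — the source model untouched (baseline).
* ``MW_PC`` — only the molecular weights, log Kow and tissue:blood
  partition coefficients are replaced by the target's; the source's
  metabolic rate constants (and pathway topology) are retained.  This is
  the minimal-data scenario: MW and log Kow are always obtainable.
* ``ALL`` — additionally every phase I/II Vmax and Km is replaced; the
  pathway topology becomes the target's.

Scenario labels follow the ``<SRC>_<TGT>_<mode>`` convention with the
two-letter chemical abbreviations (ES, SA, ME), e.g. ``ES_ME_MW_PC``,
``ES_ME_all`` and ``ES_original``.

The module also runs dose–response sweeps of terminal metabolite amounts
and computes symmetric fold differences between scenarios — the tool
reports folds; whether a read-across is acceptable is a human judgement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, LookupFixtureError, ValidationError
from .model import DoseRegimen, SimulationResult, build_model, simulate, summary_metrics
from .params import ChemicalParamSet, PhysiologyParams

__all__ = [
    "SubstitutionMode",
    "ScenarioSpec",
    "ScenarioComparison",
    "DoseResponseTable",
    "apply_readacross",
    "run_scenarios",
    "dose_response",
    "fold_difference",
    "default_dose_grid",
]

#: Conventional abbreviations used in scenario labels.
ABBREVIATIONS = {"estragole": "ES", "safrole": "SA", "methyleugenol": "ME"}


class SubstitutionMode(str, Enum):
    ORIGINAL = "ORIGINAL"
    MW_PC = "MW_PC"
    ALL = "ALL"

    @classmethod
    def coerce(cls, value) -> "SubstitutionMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise InputError(
                f"unknown substitution mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


def _abbrev(name: str) -> str:
    return ABBREVIATIONS.get(name.lower(), name[:2].upper())


@dataclass(frozen=True)
class ScenarioSpec:
    """One labelled substitution scenario (label is deterministic from the fields)."""

    source_chemical: str
    target_chemical: str
    mode: SubstitutionMode

    @property
    def label(self) -> str:
        src = _abbrev(self.source_chemical)
        if self.mode is SubstitutionMode.ORIGINAL:
            return f"{src}_original"
        tgt = _abbrev(self.target_chemical)
        suffix = "MW_PC" if self.mode is SubstitutionMode.MW_PC else "all"
        return f"{src}_{tgt}_{suffix}"


def apply_readacross(
    source: ChemicalParamSet,
    target: ChemicalParamSet,
    mode: SubstitutionMode | str,
) -> ChemicalParamSet:
    """Substitute target parameters into the source parameter set.

    Idempotent per mode: applying the same mode twice equals applying it
    once.  In ``ALL`` mode the result equals the target's own parameter
    set except for its name/provenance labelling.
    """
    mode = SubstitutionMode.coerce(mode)
    if mode is SubstitutionMode.ORIGINAL:
        return source
    # base template name survives repeated application, keeping the operation idempotent
    base = source.name.split("->", 1)[0]
    name = f"{base}->{target.name} ({mode.value})"
    if mode is SubstitutionMode.MW_PC:
        return replace(
            source,
            name=name,
            mw_parent=target.mw_parent,
            mw_metabolite=target.mw_metabolite,
            log_kow=target.log_kow,
            partitions=target.partitions,
            provenance=f"read-across (MW_PC): template {base}, "
                       f"MW/log Kow/partition coefficients from {target.name}",
        )
    if not target.phase2:
        raise ValidationError(
            f"ALL-mode substitution needs a full phase 2 pathway table for {target.name}"
        )
    return replace(
        source,
        name=name,
        mw_parent=target.mw_parent,
        mw_metabolite=target.mw_metabolite,
        log_kow=target.log_kow,
        partitions=target.partitions,
        phase1=target.phase1,
        phase2=target.phase2,
        provenance=f"read-across (ALL): template {base}, "
                   f"all chemical-specific parameters from {target.name}",
    )


@dataclass
class ScenarioComparison:
    """Labelled scenario results sharing one dose regimen and physiology."""

    scenarios: list[tuple[ScenarioSpec, SimulationResult, dict]]
    reference_label: str | None = None
    dose: DoseRegimen | None = None

    def labels(self) -> list[str]:
        return [spec.label for spec, _, _ in self.scenarios]

    def get(self, label: str) -> tuple[ScenarioSpec, SimulationResult, dict]:
        for item in self.scenarios:
            if item[0].label == label:
                return item
        raise LookupFixtureError(f"no scenario labelled {label!r}; have {self.labels()}")

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for spec, _, metrics in self.scenarios:
            row = {"label": spec.label, "mode": spec.mode.value,
                   "liver_cmax_umol": metrics["cmax"]["liver"],
                   "liver_tmax_h": metrics["tmax"]["liver"],
                   "metabolite_liver_cmax_umol": metrics["cmax"]["metabolite_liver"],
                   "mass_balance_error": metrics["mass_balance_error"]}
            for tid, amount in metrics["terminal_trackers"].items():
                row[f"terminal_{tid}_umol"] = amount
            rows.append(row)
        return pd.DataFrame(rows)


def run_scenarios(
    sources: Sequence[ChemicalParamSet],
    target: ChemicalParamSet,
    modes: Sequence[SubstitutionMode | str],
    physiology: PhysiologyParams,
    dose: DoseRegimen,
    include_target_original: bool = True,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> ScenarioComparison:
    """Simulate every (source, mode) combination under one dose/physiology.

    When the target carries a full parameter set, its own ORIGINAL scenario
    is appended as the reference (e.g. ``ME_original``).
    """
    if not sources:
        raise InputError("sources list must be non-empty")
    if not modes:
        raise InputError("modes list must be non-empty")
    modes = [SubstitutionMode.coerce(m) for m in modes]

    scenarios = []
    for source in sources:
        for mode in modes:
            spec = ScenarioSpec(source.name, target.name, mode)
            chem = apply_readacross(source, target, mode)
            system = build_model(physiology, chem, dose, label=spec.label)
            result = simulate(system, rel_tol=rel_tol, abs_tol=abs_tol)
            scenarios.append((spec, result, summary_metrics(result)))

    reference_label = None
    if include_target_original and target.phase1 and target.phase2:
        spec = ScenarioSpec(target.name, target.name, SubstitutionMode.ORIGINAL)
        system = build_model(physiology, target, dose, label=spec.label)
        result = simulate(system, rel_tol=rel_tol, abs_tol=abs_tol)
        scenarios.append((spec, result, summary_metrics(result)))
        reference_label = spec.label

    return ScenarioComparison(scenarios=scenarios, reference_label=reference_label, dose=dose)


def default_dose_grid(n: int = 13, low: float = 0.0007, high: float = 300.0) -> np.ndarray:
    """Logarithmic dose grid (mg/kg bw) from ``low`` to ``high`` plus zero."""
    return np.concatenate([[0.0], np.geomspace(low, high, n)])


@dataclass
class DoseResponseTable:
    """Terminal cumulative tracker amounts (µmol) per external dose (mg/kg bw)."""

    doses: np.ndarray
    amounts: pd.DataFrame  # one column per tracker id
    duration: float
    chemical: str

    def __post_init__(self):
        if np.any(np.diff(self.doses) <= 0):
            raise InputError("doses must be strictly increasing")
        if (self.amounts.to_numpy() < 0).any():
            raise ValidationError("negative terminal amounts")

    def to_frame(self) -> pd.DataFrame:
        out = self.amounts.copy()
        out.insert(0, "dose_mg_per_kg", self.doses)
        return out

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in self.amounts.columns:
            ax.plot(self.doses, self.amounts[col], marker="o", label=col)
        ax.set_xlabel("external dose (mg/kg bw)")
        ax.set_ylabel(f"amount formed by {self.duration:g} h (µmol)")
        ax.set_title(self.chemical)
        ax.legend()
        return ax


def dose_response(
    chemical: ChemicalParamSet,
    physiology: PhysiologyParams,
    doses: Sequence[float] | None = None,
    duration: float = 24.0,
    trackers: Sequence[str] | None = None,
    absorption_rate: float = 1.0,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> DoseResponseTable:
    """Sweep external doses and collect terminal cumulative tracker amounts.

    Each dose is simulated independently.  ``trackers`` defaults to the
    hydroxylation route plus all phase II conjugates (the dose–response
    endpoints of interest for the bioactivation pathway).
    """
    dose_grid = default_dose_grid() if doses is None else np.asarray(list(doses), float)
    if (dose_grid < 0).any():
        raise InputError("doses must be non-negative")
    if np.any(np.diff(dose_grid) <= 0):
        raise InputError("doses must be strictly increasing")

    known = [p.pathway_id for p in chemical.phase1 + chemical.phase2]
    if trackers is None:
        trackers = [chemical.hydroxylation_route.pathway_id] + [
            p.pathway_id for p in chemical.phase2
        ]
    for tid in trackers:
        if tid not in known:
            raise LookupFixtureError(f"unknown tracker {tid!r}; available: {known}")

    rows = []
    for d in dose_grid:
        regimen = DoseRegimen(oral_dose=float(d), absorption_rate=absorption_rate,
                              duration=duration)
        system = build_model(physiology, chemical, regimen)
        result = simulate(system, rel_tol=rel_tol, abs_tol=abs_tol)
        rows.append({tid: float(result.trackers[tid].iloc[-1]) for tid in trackers})
    return DoseResponseTable(
        doses=dose_grid,
        amounts=pd.DataFrame(rows),
        duration=duration,
        chemical=chemical.name,
    )


def fold_difference(
    metrics_a: Mapping,
    metrics_b: Mapping,
    key: str,
    flag_infinite: bool = True,
) -> float:
    """Symmetric fold difference max(x, y)/min(x, y) >= 1 between two scenarios.

    ``key`` is either a tracker id (compared on terminal cumulative
    amounts) or a compartment name (compared on peak amounts — the right
    reading for depletable pools such as the free 1'-hydroxy metabolite in
    liver, whose liver amount rises and is then conjugated away).
    Identical scenarios give exactly 1.0.  A zero on one side only is
    reported as ``inf`` (flagged via a warning).
    """
    def pick(metrics: Mapping) -> float:
        if key in metrics["terminal_trackers"]:
            return metrics["terminal_trackers"][key]
        if key in metrics["cmax"]:
            return metrics["cmax"][key]
        raise LookupFixtureError(
            f"{key!r} is neither a tracker nor a compartment of scenario "
            f"{metrics.get('label', '?')!r}"
        )

    x, y = pick(metrics_a), pick(metrics_b)
    if x == y:
        return 1.0
    lo, hi = sorted((x, y))
    if lo <= 0:
        if flag_infinite:
            import warnings

            warnings.warn(f"fold difference for {key!r} is infinite (zero denominator)",
                          stacklevel=2)
        return math.inf
    return hi / lo
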
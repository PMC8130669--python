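"""Normalized local sensitivity coefficients.

For a model output C and parameter P, the normalized sensitivity
coefficient is the forward-difference elasticity

    SC = (C' - C) / (P' - P) * P / C

where C' is the output after a one-sided fractional perturbation of the
single parameter, P' = (1 + delta) * P, with every other parameter held at
baseline.  The default perturbation is +5 % (delta = 0.05).  SC is
dimensionless and invariant to rescaling the parameter's units; |SC| = 1
means a 1 % parameter change moves the output by 1 %.

Parameters are addressed with dotted paths into the typed parameter sets,
e.g. ``chemical.phase1.HE.vmax_unscaled`` or
``chemical.partitions.parent.liver``.  The default "all" list covers every
kinetic constant, every partition coefficient, the scale-up yields, body
weight, cardiac output and the absorption rate.  Molecular weights are
excluded by default (they only convert the external dose to µmol, so their
elasticity is -1 by construction) as are flow fractions (a lone 5 %
perturbation would violate the sum-to-one constraint); both can still be
requested explicitly — flow-fraction requests are rejected with an
explanatory error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import pandas as pd

from .errors import InputError, LookupFixtureError
from .model import DoseRegimen, build_model, simulate, summary_metrics
from .params import ChemicalParamSet, PhysiologyParams

__all__ = [
    "SensitivityTable",
    "sensitivity_coefficients",
    "normalized_sc",
    "elasticity",
    "list_parameter_paths",
]


def normalized_sc(c: float, c_pert: float, p: float, p_pert: float) -> float:
    """SC = (C' - C)/(P' - P) * P/C for one perturbation."""
    if c == 0:
        raise InputError("baseline output C is 0: sensitivity coefficient undefined")
    if p_pert == p:
        raise InputError("perturbed parameter equals baseline; nothing to difference")
    return (c_pert - c) / (p_pert - p) * p / c


def elasticity(func: Callable[[float], float], p: float, delta: float = 0.05) -> float:
    """Forward-difference elasticity of a scalar map at ``p`` (perturbation +delta·p)."""
    if delta <= 0:
        raise InputError(f"delta must be > 0, got {delta!r}")
    return normalized_sc(func(p), func(p * (1.0 + delta)), p, p * (1.0 + delta))


# ---------------------------------------------------------------------------
# Dotted-path access into the frozen parameter dataclasses
# ---------------------------------------------------------------------------

def _get_path(bundle: Mapping[str, object], path: str) -> float:
    obj = bundle
    for part in path.split("."):
        if isinstance(obj, Mapping):
            if part not in obj:
                raise LookupFixtureError(f"cannot resolve {path!r}: no key {part!r}")
            obj = obj[part]
        elif isinstance(obj, tuple):  # pathway list keyed by pathway_id
            match = [p for p in obj if getattr(p, "pathway_id", None) == part]
            if not match:
                raise LookupFixtureError(f"cannot resolve {path!r}: no pathway {part!r}")
            obj = match[0]
        elif dataclasses.is_dataclass(obj):
            if part not in {f.name for f in dataclasses.fields(obj)}:
                raise LookupFixtureError(f"cannot resolve {path!r}: no field {part!r}")
            obj = getattr(obj, part)
        else:
            raise LookupFixtureError(f"cannot resolve {path!r} at {part!r}")
    if not isinstance(obj, (int, float)) or isinstance(obj, bool):
        raise LookupFixtureError(f"{path!r} does not address a numeric parameter")
    return float(obj)


def _set_in(obj, parts: list[str], value: float):
    head = parts[0]
    if isinstance(obj, Mapping):
        new = dict(obj)
        new[head] = value if len(parts) == 1 else _set_in(obj[head], parts[1:], value)
        return new
    if isinstance(obj, tuple):
        items = list(obj)
        for k, item in enumerate(items):
            if getattr(item, "pathway_id", None) == head:
                items[k] = item if len(parts) == 1 else _set_in(item, parts[1:], value)
                if len(parts) == 1:
                    raise LookupFixtureError("a pathway itself is not a numeric parameter")
                return tuple(items)
        raise LookupFixtureError(f"no pathway {head!r}")
    if dataclasses.is_dataclass(obj):
        if len(parts) == 1:
            return dataclasses.replace(obj, **{head: value})
        return dataclasses.replace(obj, **{head: _set_in(getattr(obj, head), parts[1:], value)})
    raise LookupFixtureError(f"cannot descend into {type(obj).__name__}")


def _perturbed_bundle(physiology, chemical, dose, path: str, factor: float):
    bundle = {"physiology": physiology, "chemical": chemical, "dose": dose}
    root, _, rest = path.partition(".")
    if root not in bundle or not rest:
        raise LookupFixtureError(
            f"parameter path must start with physiology./chemical./dose., got {path!r}"
        )
    if root == "physiology" and rest.startswith("flow_fractions"):
        raise InputError(
            "flow fractions cannot be perturbed individually (they must sum to 1); "
            "perturb cardiac_output_coeff for a global flow change"
        )
    baseline = _get_path(bundle, path)
    bundle[root] = _set_in(bundle[root], rest.split("."), baseline * factor)
    return bundle["physiology"], bundle["chemical"], bundle["dose"], baseline


def list_parameter_paths(chemical: ChemicalParamSet) -> list[str]:
    """The default parameter set scanned by :func:`sensitivity_coefficients`."""
    paths = [
        "physiology.body_weight",
        "physiology.cardiac_output_coeff",
        "physiology.s9_protein_yield",
        "physiology.microsomal_protein_yield",
        "dose.absorption_rate",
        "chemical.partitions.metabolite_liver",
    ]
    paths += [f"chemical.partitions.parent.{t}" for t in sorted(chemical.partitions.parent)]
    for phase, routes in (("phase1", chemical.phase1), ("phase2", chemical.phase2)):
        for p in routes:
            paths.append(f"chemical.{phase}.{p.pathway_id}.vmax_unscaled")
            paths.append(f"chemical.{phase}.{p.pathway_id}.km")
    return paths


@dataclass
class SensitivityTable:
    """Result of a local sensitivity scan, sorted by |SC| descending."""

    output_metric: str
    perturbation: float
    baseline_output: float
    table: pd.DataFrame  # columns: parameter, baseline, sc

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.head(n)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _metric_value(metrics: dict, metric: str) -> float:
    """Resolve a metric id like ``terminal:HES``, ``cmax:liver`` or ``auc:liver``."""
    kind, _, key = metric.partition(":")
    if not key:
        raise LookupFixtureError(
            f"output metric must look like 'terminal:<tracker>', 'cmax:<compartment>' "
            f"or 'auc:<compartment>', got {metric!r}"
        )
    if kind == "terminal":
        pool = metrics["terminal_trackers"]
    elif kind in ("cmax", "tmax", "auc"):
        pool = metrics[kind]
    else:
        raise LookupFixtureError(f"unknown metric kind {kind!r} in {metric!r}")
    if key not in pool:
        raise LookupFixtureError(f"unknown {kind} key {key!r}; available: {sorted(pool)}")
    return float(pool[key])


def sensitivity_coefficients(
    physiology: PhysiologyParams,
    chemical: ChemicalParamSet,
    dose: DoseRegimen,
    output_metric: str,
    parameters: Sequence[str] | str = "all",
    delta: float = 0.05,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> SensitivityTable:
    """Scan parameters one at a time and return normalized sensitivity coefficients.

    Each parameter is perturbed individually to (1 + delta) times its
    baseline while all others stay at baseline; the model is re-simulated
    and SC computed from the output change.  Default conditions follow the
    realistic-intake analysis: 0.07 mg/kg bw for 24 h with the metabolite
    formation metrics as outputs.
    """
    if delta <= 0:
        raise InputError(f"delta must be > 0, got {delta!r}")
    if parameters == "all":
        parameters = list_parameter_paths(chemical)
    if not parameters:
        raise InputError("no parameters to scan")

    def run(phys, chem, d) -> float:
        system = build_model(phys, chem, d)
        result = simulate(system, rel_tol=rel_tol, abs_tol=abs_tol)
        return _metric_value(summary_metrics(result), output_metric)

    c0 = run(physiology, chemical, dose)
    if c0 == 0:
        raise InputError(
            f"baseline output {output_metric!r} is 0: sensitivity undefined"
        )
    rows = []
    for path in parameters:
        phys, chem, d, p0 = _perturbed_bundle(physiology, chemical, dose, path, 1.0 + delta)
        if p0 == 0:
            rows.append({"parameter": path, "baseline": p0, "sc": 0.0})
            continue
        c1 = run(phys, chem, d)
        rows.append({
            "parameter": path,
            "baseline": p0,
            "sc": normalized_sc(c0, c1, p0, p0 * (1.0 + delta)),
        })
    frame = pd.DataFrame(rows)
    if frame["parameter"].duplicated().any():
        raise InputError("each parameter may appear only once")
    frame = frame.reindex(frame["sc"].abs().sort_values(ascending=False).index)
    frame = frame.reset_index(drop=True)
    return SensitivityTable(
        output_metric=output_metric,
        perturbation=delta,
        baseline_output=c0,
        table=frame,
    )
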
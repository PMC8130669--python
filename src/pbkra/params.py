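"""Parameter store for the alkenylbenzene PBK models.

Typed, validated containers for everything the kinetic model consumes:

* :class:`PhysiologyParams` — human physiology and in-vitro-to-in-vivo
  scale-up factors (body weight, cardiac output, fractional tissue blood
  flows and volumes, liver S9 and microsomal protein yields).
* :class:`MetabolicPathway` — one Michaelis–Menten route, with the unscaled
  maximal rate in nmol·min⁻¹·(mg protein)⁻¹ and the affinity constant in
  µmol/L as measured in liver incubations.
* :class:`PartitionSet` / :class:`ChemicalParamSet` — tissue:blood partition
  coefficients and the full per-chemical parameter block.

Three complete parameter sets ship as data files: the sources estragole and
safrole, and the target methyleugenol.  Chemical files use a single YAML
schema (one file per chemical, canonical field order); units are fixed as
declared here and never inferred or converted on read.

An optional helper estimates tissue:blood partition coefficients from
log Kow with a lipid/water two-phase formula and a bundled human
tissue-composition table; the primary modelling path uses the measured,
transcribed partition coefficients.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import InputError, LookupFixtureError, SchemaError, ValidationError

__all__ = [
    "PhysiologyParams",
    "MetabolicPathway",
    "PartitionSet",
    "ChemicalParamSet",
    "builtin_physiology",
    "builtin_chemical",
    "load_params",
    "write_params",
    "estimate_partition_coefficients",
    "load_tissue_compositions",
    "BUILTIN_CHEMICALS",
]

_FRACTION_TOL = 1e-9

#: Names of the built-in chemical fixtures (transcribed parameter tables).
BUILTIN_CHEMICALS = ("estragole", "safrole", "methyleugenol")


def _require_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class PhysiologyParams:
    """Human physiology and scale-up factors.

    Parameters
    ----------
    body_weight : float
        Body weight, kg.
    cardiac_output_coeff : float
        Allometric cardiac-output coefficient, L/h per kg**cardiac_exponent.
        Cardiac output is ``QC = cardiac_output_coeff * body_weight**cardiac_exponent``.
    cardiac_exponent : float
        Allometric exponent (dimensionless), default 0.74.
    flow_fractions : mapping
        Fractions of cardiac output perfusing ``fat``, ``liver``, ``richly``
        and ``slowly`` perfused tissue (``kidney`` optional).  Must sum to 1.
    volume_fractions : mapping
        Fractions of body weight for ``fat``, ``liver``, ``richly``,
        ``slowly`` and ``blood`` (``kidney`` optional).  Must sum to < 1;
        the remainder is unperfused mass (bone, gut contents...).
    s9_protein_yield : float
        Liver S9 protein yield, mg protein per g liver.
    microsomal_protein_yield : float
        Liver microsomal protein yield, mg protein per g liver.
    """

    body_weight: float
    cardiac_output_coeff: float
    cardiac_exponent: float
    flow_fractions: Mapping[str, float]
    volume_fractions: Mapping[str, float]
    s9_protein_yield: float
    microsomal_protein_yield: float

    def __post_init__(self):
        _require_positive("body_weight", self.body_weight)
        _require_positive("cardiac_output_coeff", self.cardiac_output_coeff)
        _require_positive("s9_protein_yield", self.s9_protein_yield)
        _require_positive("microsomal_protein_yield", self.microsomal_protein_yield)
        object.__setattr__(self, "flow_fractions", dict(self.flow_fractions))
        object.__setattr__(self, "volume_fractions", dict(self.volume_fractions))
        for label, fractions in (("flow", self.flow_fractions), ("volume", self.volume_fractions)):
            for tissue, f in fractions.items():
                if not (0.0 < f < 1.0):
                    raise ValidationError(
                        f"{label} fraction for {tissue!r} must lie in (0, 1), got {f!r}"
                    )
        required_flow = {"fat", "liver", "richly", "slowly"}
        if missing := required_flow - set(self.flow_fractions):
            raise ValidationError(f"flow_fractions missing {sorted(missing)}")
        required_vol = {"fat", "liver", "richly", "slowly", "blood"}
        if missing := required_vol - set(self.volume_fractions):
            raise ValidationError(f"volume_fractions missing {sorted(missing)}")
        flow_sum = sum(self.flow_fractions.values())
        if abs(flow_sum - 1.0) > _FRACTION_TOL:
            raise ValidationError(
                f"flow fractions must sum to 1 (got {flow_sum!r}); "
                "blood flows are fractions of total cardiac output"
            )
        vol_sum = sum(self.volume_fractions.values())
        if vol_sum >= 1.0:
            raise ValidationError(
                f"volume fractions must sum to < 1 (got {vol_sum!r}); the "
                "remainder is unperfused body mass"
            )

    @property
    def has_kidney(self) -> bool:
        return "kidney" in self.flow_fractions and "kidney" in self.volume_fractions

    @property
    def cardiac_output(self) -> float:
        """Total cardiac output QC, L/h."""
        return self.cardiac_output_coeff * self.body_weight**self.cardiac_exponent

    @property
    def liver_mass_g(self) -> float:
        """Liver mass, g (1 L tissue taken as 1 kg)."""
        return self.volume_fractions["liver"] * self.body_weight * 1000.0


@dataclass(frozen=True)
class MetabolicPathway:
    """One Michaelis–Menten metabolic route in liver.

    ``vmax_unscaled`` is the in vitro maximal rate in
    nmol·min⁻¹·(mg protein)⁻¹; ``km`` is in µmol/L.  ``protein_basis``
    selects the scale-up yield: ``"microsomal"`` routes scale with the
    microsomal protein yield, ``"s9"`` routes with the S9 yield.  Standard
    deviations are stored for provenance but unused by simulation.
    """

    pathway_id: str
    product_name: str
    phase: int  # 1 = oxidation of the parent, 2 = conjugation of the 1'-hydroxy metabolite
    vmax_unscaled: float
    km: float
    protein_basis: str = "microsomal"
    vmax_sd: float | None = None
    km_sd: float | None = None
    is_hydroxylation_route: bool = False

    def __post_init__(self):
        if not self.pathway_id:
            raise ValidationError("pathway_id must be a non-empty token")
        if self.phase not in (1, 2):
            raise ValidationError(f"phase must be 1 or 2, got {self.phase!r}")
        if self.vmax_unscaled < 0 or not math.isfinite(self.vmax_unscaled):
            raise ValidationError(
                f"vmax_unscaled must be >= 0, got {self.vmax_unscaled!r} ({self.pathway_id})"
            )
        _require_positive(f"km ({self.pathway_id})", self.km)
        if self.protein_basis not in ("microsomal", "s9"):
            raise ValidationError(
                f"protein_basis must be 'microsomal' or 's9', got {self.protein_basis!r}"
            )
        if self.phase == 2 and self.is_hydroxylation_route:
            raise ValidationError("only a phase 1 route can be the 1'-hydroxylation route")


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:blood partition coefficients (dimensionless).

    ``parent`` maps tissue names (``fat``, ``liver``, ``richly``, ``slowly``,
    optionally ``kidney``) to the parent chemical's coefficients;
    ``metabolite_liver`` is the liver:blood coefficient of the 1'-hydroxy
    metabolite.
    """

    parent: Mapping[str, float]
    metabolite_liver: float

    def __post_init__(self):
        object.__setattr__(self, "parent", dict(self.parent))
        required = {"fat", "liver", "richly", "slowly"}
        if missing := required - set(self.parent):
            raise ValidationError(f"partition coefficients missing {sorted(missing)}")
        for tissue, pc in self.parent.items():
            _require_positive(f"partition coefficient {tissue}", pc)
        _require_positive("metabolite_liver partition coefficient", self.metabolite_liver)

    @property
    def has_kidney(self) -> bool:
        return "kidney" in self.parent


@dataclass(frozen=True)
class ChemicalParamSet:
    """Complete parameter block for one chemical."""

    name: str
    mw_parent: float
    mw_metabolite: float
    log_kow: float
    partitions: PartitionSet
    phase1: tuple[MetabolicPathway, ...]
    phase2: tuple[MetabolicPathway, ...]
    provenance: str = ""

    def __post_init__(self):
        _require_positive("mw_parent", self.mw_parent)
        _require_positive("mw_metabolite", self.mw_metabolite)
        if not math.isfinite(self.log_kow):
            raise ValidationError(f"log_kow must be finite, got {self.log_kow!r}")
        object.__setattr__(self, "phase1", tuple(self.phase1))
        object.__setattr__(self, "phase2", tuple(self.phase2))
        if not self.phase1:
            raise ValidationError("phase1 pathway list must be non-empty")
        for phase_no, routes in ((1, self.phase1), (2, self.phase2)):
            ids = [p.pathway_id for p in routes]
            if len(ids) != len(set(ids)):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise SchemaError(f"duplicate pathway_id in phase {phase_no}: {dupes}")
            for p in routes:
                if p.phase != phase_no:
                    raise ValidationError(
                        f"pathway {p.pathway_id!r} declares phase {p.phase} "
                        f"but is listed under phase {phase_no}"
                    )
        n_routes = sum(p.is_hydroxylation_route for p in self.phase1)
        if n_routes != 1:
            raise ValidationError(
                "exactly one phase 1 pathway must be flagged as the "
                f"1'-hydroxylation route feeding the metabolite submodel (found {n_routes})"
            )

    @property
    def hydroxylation_route(self) -> MetabolicPathway:
        return next(p for p in self.phase1 if p.is_hydroxylation_route)

    def pathway(self, pathway_id: str) -> MetabolicPathway:
        for p in self.phase1 + self.phase2:
            if p.pathway_id == pathway_id:
                return p
        raise LookupFixtureError(
            f"unknown pathway {pathway_id!r} for {self.name}; available: "
            f"{[p.pathway_id for p in self.phase1 + self.phase2]}"
        )


# ---------------------------------------------------------------------------
# Serialisation — one YAML document per chemical, canonical field order.
# ---------------------------------------------------------------------------

_CHEMICAL_FIELDS = ("name", "mw_parent", "mw_metabolite", "log_kow",
                    "partitions", "phase1", "phase2", "provenance")
_PATHWAY_FIELDS = ("pathway_id", "product_name", "phase", "vmax_unscaled", "vmax_sd",
                   "km", "km_sd", "protein_basis", "is_hydroxylation_route")


def _pathway_to_dict(p: MetabolicPathway) -> dict:
    return {k: getattr(p, k) for k in _PATHWAY_FIELDS}


def _chemical_to_dict(c: ChemicalParamSet) -> dict:
    return {
        "name": c.name,
        "mw_parent": c.mw_parent,
        "mw_metabolite": c.mw_metabolite,
        "log_kow": c.log_kow,
        "partitions": {
            "parent": {k: c.partitions.parent[k] for k in sorted(c.partitions.parent)},
            "metabolite_liver": c.partitions.metabolite_liver,
        },
        "phase1": [_pathway_to_dict(p) for p in c.phase1],
        "phase2": [_pathway_to_dict(p) for p in c.phase2],
        "provenance": c.provenance,
    }


def _pathway_from_dict(d: Mapping, phase_label: str) -> MetabolicPathway:
    if not isinstance(d, Mapping):
        raise SchemaError(f"each entry of {phase_label} must be a mapping, got {type(d).__name__}")
    for key in ("pathway_id", "product_name", "phase", "vmax_unscaled", "km"):
        if key not in d:
            raise ValidationError(f"pathway in {phase_label} missing mandatory field {key!r}")
    known = set(_PATHWAY_FIELDS)
    if unknown := set(d) - known:
        raise SchemaError(f"unknown pathway fields in {phase_label}: {sorted(unknown)}")
    return MetabolicPathway(**dict(d))


def chemical_from_dict(doc: Mapping) -> ChemicalParamSet:
    """Validate a plain mapping (parsed YAML/JSON) into a :class:`ChemicalParamSet`."""
    if not isinstance(doc, Mapping):
        raise SchemaError(f"chemical document must be a mapping, got {type(doc).__name__}")
    for key in ("name", "mw_parent", "mw_metabolite", "log_kow", "partitions", "phase1"):
        if key not in doc:
            raise ValidationError(f"chemical parameter file missing mandatory field {key!r}")
    if unknown := set(doc) - set(_CHEMICAL_FIELDS):
        raise SchemaError(f"unknown chemical fields: {sorted(unknown)}")
    part = doc["partitions"]
    if not isinstance(part, Mapping) or "parent" not in part or "metabolite_liver" not in part:
        raise ValidationError(
            "partitions must be a mapping with 'parent' and 'metabolite_liver'"
        )
    partitions = PartitionSet(parent=part["parent"], metabolite_liver=part["metabolite_liver"])
    phase1 = tuple(_pathway_from_dict(p, "phase1") for p in doc["phase1"])
    phase2 = tuple(_pathway_from_dict(p, "phase2") for p in doc.get("phase2", ()))
    return ChemicalParamSet(
        name=doc["name"],
        mw_parent=doc["mw_parent"],
        mw_metabolite=doc["mw_metabolite"],
        log_kow=doc["log_kow"],
        partitions=partitions,
        phase1=phase1,
        phase2=phase2,
        provenance=doc.get("provenance", ""),
    )


def load_params(path: str | Path) -> ChemicalParamSet:
    """Read and validate a chemical parameter file (canonical YAML schema).

    Units are fixed by the schema (g/mol, nmol·min⁻¹·mg⁻¹, µmol/L,
    dimensionless partition coefficients); nothing is converted on read.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"chemical parameter file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"could not parse {path}: {exc}") from exc
    return chemical_from_dict(doc)


def write_params(chemical: ChemicalParamSet, path: str | Path) -> None:
    """Write a chemical parameter file in canonical form.

    Serialisation is canonical (fixed field order, fixed YAML style), so
    write → load → write is byte-stable.
    """
    Path(path).write_text(
        yaml.safe_dump(_chemical_to_dict(chemical), sort_keys=False, default_flow_style=False)
    )


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("pbkra.data").joinpath(name)


def builtin_physiology() -> PhysiologyParams:
    """The transcribed human physiology used by all built-in models.

    Cardiac output follows the allometric form QC = 15·BW^0.74 L/h
    (≈ 310 L/h at 60 kg).  No kidney compartment is defined: kidney flow
    and volume are carried by the richly perfused lump.
    """
    return PhysiologyParams(
        body_weight=60.0,
        cardiac_output_coeff=15.0,
        cardiac_exponent=0.74,
        flow_fractions={
            "fat": 0.052,
            "liver": 0.227,
            "richly": 0.70 - 0.227,
            "slowly": 0.30 - 0.052,
        },
        volume_fractions={
            "fat": 0.214,
            "liver": 0.026,
            "richly": 0.076 - 0.026,
            "slowly": 0.81 - 0.214 - 0.079,
            "blood": 0.079,
        },
        s9_protein_yield=143.0,
        microsomal_protein_yield=32.0,
    )


def builtin_chemical(name: str) -> ChemicalParamSet:
    """Return a transcribed built-in chemical parameter set.

    ``name`` is one of ``"estragole"``, ``"safrole"`` or ``"methyleugenol"``
    (case-insensitive).
    """
    key = name.strip().lower()
    if key not in BUILTIN_CHEMICALS:
        raise LookupFixtureError(
            f"unknown chemical fixture {name!r}; available: {list(BUILTIN_CHEMICALS)}"
        )
    with importlib.resources.as_file(_data_path(f"{key}.yaml")) as p:
        return load_params(p)


# ---------------------------------------------------------------------------
# Partition-coefficient estimation (optional helper)
# ---------------------------------------------------------------------------

def load_tissue_compositions() -> pd.DataFrame:
    """Bundled human tissue-composition table.

    Columns ``tissue``, ``lipid_fraction``, ``water_fraction`` (volume
    fractions); one row must be ``blood``.
    """
    with importlib.resources.as_file(_data_path("tissue_composition.csv")) as p:
        return pd.read_csv(p)


def estimate_partition_coefficients(
    log_kow: float,
    tissue_compositions: pd.DataFrame | None = None,
    lipid_exponent: float | Mapping[str, float] = 1.0,
) -> PartitionSet:
    """Estimate tissue:blood partition coefficients from log Kow.

    Uses a two-phase lipid/water partitioning formula::

        PC_t = (f_lipid,t * Kow**a + f_water,t) / (f_lipid,blood * Kow**a + f_water,blood)

    with ``Kow = 10**log_kow``.  The lipid-interaction exponent ``a``
    defaults to 1 for every tissue and may be overridden per tissue with a
    mapping.  The estimate is scale-free in the composition units: scaling
    all fractions by a common factor leaves every PC unchanged.

    This helper exists for chemicals whose partition coefficients were
    never measured; the shipped fixtures carry measured values and do not
    use it.  The metabolite's liver:blood coefficient is estimated with the
    same formula (the more polar metabolite would need its own, lower,
    log Kow to be realistic).
    """
    if not math.isfinite(log_kow):
        raise ValidationError(f"log_kow must be finite, got {log_kow!r}")
    table = load_tissue_compositions() if tissue_compositions is None else tissue_compositions
    comp = {
        str(row.tissue): (float(row.lipid_fraction), float(row.water_fraction))
        for row in table.itertuples()
    }
    for tissue, (fl, fw) in comp.items():
        if fl < 0 or fw < 0:
            raise ValidationError(f"negative composition fraction for {tissue!r}")
    if "blood" not in comp:
        raise ValidationError("tissue composition table must contain a 'blood' row")
    if missing := {"fat", "liver", "richly", "slowly"} - set(comp):
        raise ValidationError(f"tissue composition table missing rows {sorted(missing)}")

    def exponent(tissue: str) -> float:
        if isinstance(lipid_exponent, Mapping):
            return float(lipid_exponent.get(tissue, 1.0))
        return float(lipid_exponent)

    kow = 10.0**log_kow
    fl_b, fw_b = comp["blood"]

    def pc(tissue: str) -> float:
        a = exponent(tissue)
        denom = fl_b * kow**a + fw_b
        if denom <= 0:
            raise ValidationError("blood composition gives a non-positive denominator")
        fl, fw = comp[tissue]
        return (fl * kow**a + fw) / denom

    parent = {t: pc(t) for t in comp if t != "blood"}
    return PartitionSet(parent=parent, metabolite_liver=pc("liver"))


def rename(chemical: ChemicalParamSet, name: str, provenance: str | None = None) -> ChemicalParamSet:
    """Copy of ``chemical`` under a new name (and optionally new provenance)."""
    kwargs = {"name": name}
    if provenance is not None:
        kwargs["provenance"] = provenance
    return replace(chemical, **kwargs)
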
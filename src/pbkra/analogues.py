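"""Analogue identification by multi-fingerprint Tanimoto consensus.

Candidate source chemicals for a read-across are ranked against the target
with nine fingerprint families (Morgan, feature Morgan, topological
torsion, Avalon, layered, atom pair, path-based RDKit, MACCS keys and
pattern).  A candidate qualifies when it appears in the top-k (default 5)
most similar chemicals of at least ``min_families`` (default 4) families;
qualifying candidates get a consensus average (mean Tanimoto over all nine
families) which is compared against a similarity cut-off (default 0.6).

Selection then applies a decision tree over per-candidate metadata: a
qualifying analogue must have a human PBK model that is reproducible,
validated against in vivo data, and show similar ADME behaviour.  Missing
metadata excludes a candidate rather than raising.

Fingerprint parameterisation (radius 2 / 2048 bits for the circular
families, 512-bit Avalon, conventional defaults elsewhere) is recorded in
every ranking for provenance — consensus scores are only comparable for a
fixed parameterisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Avalon import pyAvalonTools

from .errors import InputError, LookupFixtureError, ValidationError

__all__ = [
    "FINGERPRINT_FAMILIES",
    "AnalogueCandidate",
    "AnalogueRanking",
    "Decision",
    "fingerprint_similarity",
    "consensus_rank",
    "select_analogues",
    "load_candidates",
    "builtin_candidate_pool",
]

_FP_PARAMS = {
    "morgan": "radius=2, nbits=2048",
    "feature_morgan": "radius=2, nbits=2048, feature invariants",
    "torsion": "nbits=2048",
    "avalon": "nbits=512",
    "layered": "nbits=2048",
    "atom_pair": "nbits=2048",
    "rdkit": "path-based, nbits=2048",
    "maccs": "166 structural keys",
    "pattern": "nbits=2048",
}

FINGERPRINT_FAMILIES = tuple(_FP_PARAMS)

_GENERATORS = {}


def _generator(family: str):
    gen = _GENERATORS.get(family)
    if gen is None:
        if family == "morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        elif family == "feature_morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=2, fpSize=2048,
                atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
            )
        elif family == "torsion":
            gen = rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=2048)
        elif family == "atom_pair":
            gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=2048)
        elif family == "rdkit":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048)
        _GENERATORS[family] = gen
    return gen


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES: {smiles!r}")
    return mol


def _fingerprint(mol: Chem.Mol, family: str):
    if family not in FINGERPRINT_FAMILIES:
        raise LookupFixtureError(
            f"unknown fingerprint family {family!r}; available: {list(FINGERPRINT_FAMILIES)}"
        )
    if family == "avalon":
        return pyAvalonTools.GetAvalonFP(mol, 512)
    if family == "layered":
        return Chem.LayeredFingerprint(mol)
    if family == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    if family == "pattern":
        return Chem.PatternFingerprint(mol)
    return _generator(family).GetFingerprint(mol)


def fingerprint_similarity(smiles_a: str, smiles_b: str, family: str) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on one family's bit vectors.

    Symmetric in its arguments; identical molecules score 1.0 in every
    family.
    """
    fp_a = _fingerprint(_mol(smiles_a), family)
    fp_b = _fingerprint(_mol(smiles_b), family)
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


@dataclass(frozen=True)
class AnalogueCandidate:
    """One pool member: structure plus model-availability metadata.

    Metadata flags may be ``None`` (unknown); the selection tree treats
    missing flags as disqualifying, never as an error.
    ``reported_similarity`` optionally carries an externally reported
    similarity score (``None`` when only known to be below a cut-off).
    """

    name: str
    smiles: str
    has_human_pbk_model: bool | None = None
    model_validated_in_vivo: bool | None = None
    model_reproducible: bool | None = None
    similar_adme: bool | None = None
    notes: str = ""
    reported_similarity: float | None = None
    reported_consensus: float | None = None

    def __post_init__(self):
        mol = _mol(self.smiles)  # raises for invalid structures
        object.__setattr__(self, "canonical_smiles", Chem.MolToSmiles(mol))

    canonical_smiles: str = field(init=False, default="")


@dataclass
class AnalogueRanking:
    """Per-candidate fingerprint scores, top-k counts and consensus averages.

    ``table`` columns: one per family, plus ``top_k_count``,
    ``consensus_average`` (NaN for non-qualifying candidates) and
    ``passes_cutoff``.
    """

    target: AnalogueCandidate
    table: pd.DataFrame
    k: int
    min_families: int
    threshold: float
    fingerprint_parameters: Mapping[str, str] = field(default_factory=lambda: dict(_FP_PARAMS))

    def qualifying(self) -> list[str]:
        return list(self.table.index[self.table["top_k_count"] >= self.min_families])

    def consensus_scores(self) -> dict[str, float | None]:
        col = self.table["consensus_average"]
        return {name: (None if pd.isna(v) else float(v)) for name, v in col.items()}

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def consensus_rank(
    target: AnalogueCandidate,
    pool: Sequence[AnalogueCandidate],
    k: int = 5,
    min_families: int = 4,
    threshold: float = 0.6,
) -> AnalogueRanking:
    """Rank a candidate pool against the target by nine-family consensus.

    For each family the pool is ranked by Tanimoto score (ties broken by
    canonical-SMILES lexicographic order, so the output is deterministic);
    candidates in the top ``k`` of at least ``min_families`` families get a
    consensus average over all nine families and a cut-off decision.
    A pool entry with the target's own structure is excluded with a warning.
    """
    if not pool:
        raise InputError("candidate pool must be non-empty")
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if not (0 < min_families <= len(FINGERPRINT_FAMILIES)):
        raise InputError(
            f"min_families must be in 1..{len(FINGERPRINT_FAMILIES)}, got {min_families}"
        )

    candidates = []
    for cand in pool:
        if cand.canonical_smiles == target.canonical_smiles:
            warnings.warn(
                f"pool candidate {cand.name!r} is the target itself; excluded from ranking",
                stacklevel=2,
            )
            continue
        candidates.append(cand)
    if not candidates:
        raise InputError("candidate pool contains only the target itself")

    scores = pd.DataFrame(
        {
            family: [
                fingerprint_similarity(target.smiles, cand.smiles, family)
                for cand in candidates
            ]
            for family in FINGERPRINT_FAMILIES
        },
        index=[cand.name for cand in candidates],
    )

    tie_break = pd.Series([c.canonical_smiles for c in candidates], index=scores.index)
    top_counts = pd.Series(0, index=scores.index)
    for family in FINGERPRINT_FAMILIES:
        order = (
            pd.DataFrame({"score": scores[family], "tie": tie_break})
            .sort_values(["score", "tie"], ascending=[False, True], kind="mergesort")
        )
        top_counts[order.index[:k]] += 1

    table = scores.copy()
    table["top_k_count"] = top_counts
    consensus = scores.mean(axis=1)
    table["consensus_average"] = consensus.where(top_counts >= min_families)
    table["passes_cutoff"] = (table["consensus_average"] >= threshold).fillna(False)
    table = table.sort_values(
        ["consensus_average", "top_k_count"], ascending=False, kind="mergesort"
    )
    return AnalogueRanking(
        target=target, table=table, k=k, min_families=min_families, threshold=threshold
    )


@dataclass(frozen=True)
class Decision:
    """Outcome of the selection tree for one candidate."""

    selected: bool
    reason: str  # machine-readable token
    detail: str = ""


def _tree(cand: AnalogueCandidate, similar: bool | None) -> Decision:
    if similar is None:
        return Decision(False, "insufficient metadata", "no similarity score available")
    if not similar:
        return Decision(False, "dissimilar", "similarity below cut-off")
    flags = (cand.has_human_pbk_model, cand.model_reproducible,
             cand.model_validated_in_vivo, cand.similar_adme)
    if any(f is None for f in flags):
        return Decision(False, "insufficient metadata", "missing model-availability flags")
    if not (cand.has_human_pbk_model and cand.model_reproducible):
        return Decision(False, "no usable model",
                        "no human PBK model, or the model is not reproducible")
    if not cand.model_validated_in_vivo:
        return Decision(False, "not validated", "model not validated with in vivo data")
    if not cand.similar_adme:
        return Decision(False, "ADME dissimilar", "ADME processes not similar enough")
    return Decision(True, "selected", "similar structure, usable validated model, similar ADME")


def select_analogues(
    ranking: AnalogueRanking | None,
    pool: Sequence[AnalogueCandidate],
    scores: Mapping[str, float | None] | None = None,
    threshold: float | None = None,
) -> dict[str, Decision]:
    """Apply the analogue-selection decision tree to every pool candidate.

    Similarity comes from ``scores`` when given (e.g. externally reported
    values; ``None`` marks a score only known to be below the cut-off),
    otherwise from the ranking's consensus averages.  Relaxing the
    threshold can only ever select more candidates, never fewer.
    """
    if scores is None:
        if ranking is None:
            raise InputError("provide either a ranking or a score mapping")
        scores = ranking.consensus_scores()
    cutoff = threshold if threshold is not None else (
        ranking.threshold if ranking is not None else 0.6
    )
    decisions = {}
    for cand in pool:
        if cand.name not in scores:
            decisions[cand.name] = _tree(cand, None)
            continue
        score = scores[cand.name]
        similar = None if score is None else bool(score >= cutoff)
        if score is None:
            similar = False  # reported only as below the cut-off
        decisions[cand.name] = _tree(cand, similar)
    return decisions


# ---------------------------------------------------------------------------
# Candidate-pool I/O
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_flag(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise ValidationError(f"cannot parse boolean flag {value!r}") from None


def load_candidates(path: str | Path) -> list[AnalogueCandidate]:
    """Read a candidate pool CSV.

    Columns: ``name``, ``smiles``, optional ``toolbox_similarity`` and
    ``knime_consensus`` (externally reported scores; empty = below cut-off
    or unknown), and the metadata flags ``has_human_pbk_model``,
    ``model_validated_in_vivo``, ``model_reproducible``, ``similar_adme``
    plus free-text ``notes``.
    """
    frame = pd.read_csv(path)
    for col in ("name", "smiles"):
        if col not in frame.columns:
            raise ValidationError(f"candidate pool is missing the {col!r} column")
    out = []
    for row in frame.to_dict("records"):
        def num(key):
            v = row.get(key)
            return None if v is None or pd.isna(v) else float(v)

        out.append(AnalogueCandidate(
            name=str(row["name"]),
            smiles=str(row["smiles"]),
            has_human_pbk_model=_parse_flag(row.get("has_human_pbk_model")),
            model_validated_in_vivo=_parse_flag(row.get("model_validated_in_vivo")),
            model_reproducible=_parse_flag(row.get("model_reproducible")),
            similar_adme=_parse_flag(row.get("similar_adme")),
            notes="" if pd.isna(row.get("notes")) else str(row.get("notes")),
            reported_similarity=num("toolbox_similarity"),
            reported_consensus=num("knime_consensus"),
        ))
    return out


def builtin_candidate_pool() -> list[AnalogueCandidate]:
    """The shipped alkenylbenzene candidate pool (transcribed metadata table)."""
    import importlib.resources

    with importlib.resources.as_file(
        importlib.resources.files("pbkra.data").joinpath("analogue_pool.csv")
    ) as p:
        return load_candidates(p)
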
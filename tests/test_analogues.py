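"""Fingerprint consensus ranking and analogue selection."""

import itertools
import random

import pytest

import pbkra
from pbkra.analogues import _fingerprint, _mol
from pbkra.errors import InputError, LookupFixtureError, ValidationError


def _random_smiles(n, seed=20240917):
    """Deterministic pool of varied, valid SMILES built from fragments."""
    rng = random.Random(seed)
    scaffolds = ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "c1ccc2ccccc2c1", "C1CCOC1"]
    substituents = ["C", "CC", "O", "OC", "N", "Cl", "Br", "C(=O)O", "C=C", "CC=C",
                    "S", "F", "C(C)C", "OCC", "N(C)C"]
    out = []
    while len(out) < n:
        smi = rng.choice(substituents) + rng.choice(scaffolds)
        if rng.random() < 0.5:
            smi = smi + rng.choice(substituents)
        try:
            _mol(smi)
        except ValidationError:
            continue
        out.append(smi)
    return out


def test_tanimoto_symmetry_and_self_similarity_over_random_pairs():
    pool = _random_smiles(20)
    rng = random.Random(1)
    pairs = [(rng.choice(pool), rng.choice(pool)) for _ in range(100)]
    for fam in ("morgan", "maccs", "atom_pair"):
        for a, b in pairs[:34]:
            s_ab = pbkra.fingerprint_similarity(a, b, fam)
            assert 0.0 <= s_ab <= 1.0
            assert s_ab == pbkra.fingerprint_similarity(b, a, fam)
    for fam in pbkra.FINGERPRINT_FAMILIES:
        for smi in pool[:5]:
            assert pbkra.fingerprint_similarity(smi, smi, fam) == 1.0


def test_tanimoto_agrees_with_bit_set_arithmetic():
    """Cross-check against |A∩B| / |A∪B| computed by brute-force set algebra."""
    smiles = _random_smiles(8)
    for fam, (a, b) in itertools.product(
            pbkra.FINGERPRINT_FAMILIES, itertools.combinations(smiles[:4], 2)):
        bits_a = set(_fingerprint(_mol(a), fam).GetOnBits())
        bits_b = set(_fingerprint(_mol(b), fam).GetOnBits())
        union = len(bits_a | bits_b)
        expected = len(bits_a & bits_b) / union if union else 0.0
        assert pbkra.fingerprint_similarity(a, b, fam) == pytest.approx(expected)


def test_disjoint_structures_score_near_zero_identical_score_one():
    assert pbkra.fingerprint_similarity("CCCC", "c1ccccc1O", "morgan") == 0.0
    # same molecule written two ways
    assert pbkra.fingerprint_similarity(
        "COc1ccc(CC=C)cc1OC", "C=CCc1ccc(OC)c(OC)c1", "pattern") == 1.0


def test_unparseable_smiles_and_unknown_family_raise(candidate_pool):
    with pytest.raises(ValidationError, match="not_a_smiles"):
        pbkra.fingerprint_similarity("not_a_smiles", "CC", "morgan")
    with pytest.raises(LookupFixtureError, match="unknown fingerprint"):
        pbkra.fingerprint_similarity("CC", "CC", "daylight")


@pytest.fixture(scope="module")
def me_ranking(candidate_pool):
    target = next(c for c in candidate_pool if c.name == "methyleugenol")
    with pytest.warns(UserWarning, match="target itself"):
        return pbkra.consensus_rank(target, candidate_pool)


def test_exact_copy_of_target_tops_every_family():
    target = pbkra.AnalogueCandidate(name="t", smiles="COc1ccc(CC=C)cc1OC")
    clone = pbkra.AnalogueCandidate(name="clone", smiles="C=CCc1ccc(OC)c(OC)c1OC")
    other = pbkra.AnalogueCandidate(name="other", smiles="CCCCN")
    ranking = pbkra.consensus_rank(target, [clone, other], k=1)
    row = ranking.table.loc["clone"]
    assert row["top_k_count"] == len(pbkra.FINGERPRINT_FAMILIES)


def test_ranking_is_deterministic_under_ties(me_ranking, candidate_pool):
    target = next(c for c in candidate_pool if c.name == "methyleugenol")
    with pytest.warns(UserWarning):
        again = pbkra.consensus_rank(target, candidate_pool)
    assert list(me_ranking.table.index) == list(again.table.index)
    assert me_ranking.table.equals(again.table)


def test_both_sources_qualify_by_consensus(me_ranking):
    """Estragole and safrole reach the top-5 of at least four families and
    clear the 0.6 consensus cut-off (reported averages: about 0.66 / 0.69)."""
    assert {"estragole", "safrole"} <= set(me_ranking.qualifying())
    scores = me_ranking.consensus_scores()
    assert scores["estragole"] >= 0.6 and scores["safrole"] >= 0.6
    assert bool(me_ranking.table.loc["estragole", "passes_cutoff"])
    assert bool(me_ranking.table.loc["safrole", "passes_cutoff"])


def test_scores_lie_in_unit_interval_and_counts_in_range(me_ranking):
    fam_cols = list(pbkra.FINGERPRINT_FAMILIES)
    values = me_ranking.table[fam_cols].to_numpy()
    assert ((0.0 <= values) & (values <= 1.0)).all()
    counts = me_ranking.table["top_k_count"]
    assert ((0 <= counts) & (counts <= len(fam_cols))).all()


def test_empty_pool_and_bad_k_rejected(candidate_pool):
    target = candidate_pool[0]
    with pytest.raises(InputError):
        pbkra.consensus_rank(target, [])
    with pytest.raises(InputError):
        pbkra.consensus_rank(target, candidate_pool, k=0)


# -- selection decision tree --------------------------------------------------

def _reported_scores(pool):
    return {c.name: c.reported_similarity for c in pool if c.name != "methyleugenol"}


def test_decision_tree_on_the_transcribed_pool(candidate_pool):
    pool = [c for c in candidate_pool if c.name != "methyleugenol"]
    decisions = pbkra.select_analogues(None, pool, scores=_reported_scores(pool))
    assert decisions["eugenol"].reason == "no usable model"
    assert decisions["elemicin"].reason == "not validated"
    assert decisions["myristicin"].reason == "not validated"
    assert decisions["apiol"].reason == "dissimilar"
    selected = sorted(n for n, d in decisions.items() if d.selected)
    assert selected == ["estragole", "safrole"]


def test_missing_metadata_excludes_without_crashing():
    cand = pbkra.AnalogueCandidate(name="mystery", smiles="CCO")
    decisions = pbkra.select_analogues(None, [cand], scores={"mystery": 0.9})
    assert not decisions["mystery"].selected
    assert decisions["mystery"].reason == "insufficient metadata"


def test_relaxing_the_threshold_never_unselects(candidate_pool):
    pool = [c for c in candidate_pool if c.name != "methyleugenol"]
    scores = _reported_scores(pool)
    strict = pbkra.select_analogues(None, pool, scores=scores, threshold=0.6)
    relaxed = pbkra.select_analogues(None, pool, scores=scores, threshold=0.3)
    for name, decision in strict.items():
        if decision.selected:
            assert relaxed[name].selected


def test_pool_round_trip_through_csv(tmp_path, candidate_pool):
    import importlib.resources
    import shutil

    with importlib.resources.as_file(
            importlib.resources.files("pbkra.data").joinpath("analogue_pool.csv")) as p:
        shutil.copy(p, tmp_path / "pool.csv")
    loaded = pbkra.load_candidates(tmp_path / "pool.csv")
    assert [c.name for c in loaded] == [c.name for c in candidate_pool]
    eu = next(c for c in loaded if c.name == "eugenol")
    assert eu.reported_similarity == 0.82 and eu.model_reproducible is False
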
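"""iScore, pTM, pLDDT means, tiers and best-model selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_iscore, brute_force_ptm, random_bound_model
from ppiscreen.fixtures import FixtureSpec, make_bound
from ppiscreen.interface import ClashReport, find_interface
from ppiscreen.model_io import (
    Atom,
    ConfidenceBundle,
    ResidueRecord,
    ScoredModel,
    StructureModel,
    bind,
)
from ppiscreen.scoring import (
    NO_VALID_MODEL,
    ScoreCard,
    TierScheme,
    d0,
    iscore,
    mean_plddt,
    ptm,
    select_best,
    tier,
)


# -- d0 ----------------------------------------------------------------------


def test_d0_closed_form_and_clamp():
    assert d0(19) == pytest.approx(1.24 * 4 ** (1 / 3) - 1.8, rel=1e-12)
    assert d0(5) == d0(19)  # short-sequence clamp
    assert d0(1000) > d0(19)
    assert d0(1) > 0
    with pytest.raises(ValueError):
        d0(0)


@given(st.integers(min_value=1, max_value=5000), st.integers(min_value=1, max_value=5000))
def test_d0_monotone_nondecreasing(a, b):
    lo, hi = sorted((a, b))
    assert d0(lo) <= d0(hi)


# -- iscore ------------------------------------------------------------------


def test_iscore_empty_interface_is_zero(separated_bound):
    iface = find_interface(separated_bound.model)
    assert iscore(separated_bound, iface) == 0.0


def test_iscore_perfect_pae_is_one():
    bound = make_bound(FixtureSpec(pae_interface=0.0, pae_intra=0.0))
    iface = find_interface(bound.model)
    assert iface.n_residues > 0
    assert iscore(bound, iface) == 1.0


@pytest.mark.parametrize("c", [1.0, 3.0, 7.5, 15.0])
def test_iscore_constant_cross_pae_closed_form(c):
    """Constant cross-chain PAE c gives 1/(1 + (c/d0(N_I))^2) for every frame."""
    bound = make_bound(FixtureSpec(pae_interface=c))
    iface = find_interface(bound.model)
    expected = 1.0 / (1.0 + (c / d0(iface.n_residues)) ** 2)
    assert iscore(bound, iface) == pytest.approx(expected, rel=1e-12)


def test_iscore_matches_exhaustive_frame_oracle(rng):
    for _ in range(50):
        bound = random_bound_model(rng)
        iface = find_interface(bound.model)
        assert iscore(bound, iface) == brute_force_iscore(bound, set(iface.residues))


def test_iscore_monotone_in_cross_chain_pae(rng):
    """Raising any cross-chain PAE entry never raises the iScore."""
    bound = make_bound(FixtureSpec(pae_interface=4.0))
    iface = find_interface(bound.model)
    base = iscore(bound, iface)
    chain_of = bound.model.chain_of()
    members = sorted(iface.residues)
    for _ in range(50):
        i, j = rng.choice(members, size=2)
        if chain_of[i] == chain_of[j]:
            continue
        pae = bound.conf.pae.copy()
        pae[i, j] += rng.uniform(0.5, 10.0)
        bumped = ScoredModel(bound.model, ConfidenceBundle(pae=pae, plddt=bound.conf.plddt))
        assert iscore(bumped, iface) <= base + 1e-15


def test_iscore_chain_permutation_invariance(rng):
    """Swapping chain order (with the matching PAE permutation) is a no-op."""
    for _ in range(10):
        bound = random_bound_model(rng, max_n=24)
        (ca, ra), (cb, rb) = bound.model.chains
        swapped_model = StructureModel("swapped", [(cb, rb), (ca, ra)])
        na = len(ra)
        n = bound.n_residues
        perm = np.concatenate([np.arange(na, n), np.arange(na)])
        pae = bound.conf.pae[np.ix_(perm, perm)]
        swapped = bind(swapped_model, ConfidenceBundle(pae=pae, plddt=bound.conf.plddt[perm]))
        s0 = iscore(bound, find_interface(bound.model))
        s1 = iscore(swapped, find_interface(swapped_model))
        assert abs(s0 - s1) < 1e-12


def test_iscore_range_property(rng):
    for _ in range(20):
        bound = random_bound_model(rng)
        s = iscore(bound, find_interface(bound.model))
        assert 0.0 <= s <= 1.0
        assert 0.0 <= ptm(bound) <= 1.0


def test_iscore_requires_bound_model(clean_dimer):
    with pytest.raises(TypeError):
        iscore(clean_dimer, find_interface(clean_dimer))


# -- ptm ---------------------------------------------------------------------


def test_ptm_zero_pae_is_one():
    bound = make_bound(FixtureSpec(pae_interface=0.0, pae_intra=0.0))
    assert ptm(bound) == 1.0


def test_ptm_single_residue():
    model = StructureModel(
        "one", [("A", [ResidueRecord(1, "GLY", [Atom("CA", "C", 0, 0, 0)])])]
    )
    e = 3.0
    bound = bind(model, ConfidenceBundle(pae=np.array([[e]])))
    assert ptm(bound) == pytest.approx(1.0 / (1.0 + (e / d0(1)) ** 2))


def test_ptm_matches_exhaustive_oracle(rng):
    for _ in range(30):
        bound = random_bound_model(rng, max_n=12)
        assert ptm(bound) == brute_force_ptm(bound)


# -- mean pLDDT --------------------------------------------------------------


def test_mean_plddt_values_and_subset():
    bound = make_bound(FixtureSpec(plddt_level=70.0))
    assert mean_plddt(bound) == 70.0
    bound.conf.plddt[:2] = [60.0, 80.0]
    assert mean_plddt(bound, subset=[0, 1]) == 70.0
    with pytest.raises(ValueError):
        mean_plddt(bound, subset=[])


# -- tiers -------------------------------------------------------------------


@pytest.mark.parametrize(
    "score,expected",
    [
        (0.73, "very_high"),  # very-high-confidence translocon-style score
        (0.55, "high"),
        (0.43, "medium"),
        (0.05, "below"),
        (0.4, "medium"),  # boundaries inclusive
        (0.5, "high"),
        (0.7, "very_high"),
        (0.0, "below"),
        (1.0, "very_high"),
    ],
)
def test_tier_mapping(score, expected):
    assert tier(score) == expected


def test_tier_rejects_out_of_range_and_bad_scheme():
    with pytest.raises(ValueError):
        tier(1.2)
    with pytest.raises(ValueError):
        tier(-0.1)
    with pytest.raises(ValueError):
        TierScheme(medium=0.5, high=0.4, very_high=0.7)


# -- best-model selection ----------------------------------------------------


def _card(name, score, plddt=80.0, clash=0.0):
    return ScoreCard(
        iscore=score,
        mean_plddt=plddt,
        clash=ClashReport(clash, frozenset(), 1.6),
        tier=tier(score),
        model_name=name,
    )


def test_select_best_takes_max_iscore():
    cards = [_card(f"m{i}", s) for i, s in enumerate(np.linspace(0.05, 0.8, 20))]
    assert select_best(cards).model_name == "m19"


def test_select_best_skips_clash_rejected():
    cards = [_card("clashed", 0.9, clash=0.5), _card("ok", 0.6)]
    assert select_best(cards).model_name == "ok"
    # indicator exactly at the threshold is rejected too
    cards = [_card("edge", 0.9, clash=0.4), _card("ok", 0.6)]
    assert select_best(cards).model_name == "ok"


def test_select_best_tie_breaks_on_plddt_then_name():
    cards = [_card("b", 0.5, plddt=70.0), _card("a", 0.5, plddt=80.0)]
    assert select_best(cards).model_name == "a"
    cards = [_card("b", 0.5), _card("a", 0.5)]
    assert select_best(cards).model_name == "a"


def test_select_best_all_rejected_returns_sentinel():
    cards = [_card("x", 0.9, clash=0.8), _card("y", 0.7, clash=0.4)]
    best = select_best(cards)
    assert best.model_name == NO_VALID_MODEL
    assert best.iscore == 0.0
    assert best.tier == "below"
    with pytest.raises(ValueError):
        select_best([])


def test_scorecard_display_rounding():
    card = _card("m", 0.7251, plddt=78.6)
    parts = card.display().split("\t")
    assert parts[1] == "0.73"  # 2 decimals for iScore
    assert parts[4] == "79"  # integer for mean pLDDT
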
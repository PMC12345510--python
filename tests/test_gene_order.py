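"""Gene-order extraction, rearrangement diff/classification, breakpoints."""

import itertools

import numpy as np
import pytest

from mitocomp import (
    ANCESTRAL_INSECT_ORDER,
    GeneOrder,
    RearrangementEvent,
    SyntheticSpec,
    breakpoint_count,
    catalog_patterns,
    classify_event,
    diff_against,
    extract_gene_order,
    generate_genome,
    paper_fixture_orders,
)
from mitocomp.gene_order import negate, unsigned
from mitocomp.simulate import RearrangementEdit


@pytest.fixture
def ref(ancestral):
    return ancestral


def test_ancestral_constant_shape():
    names = [unsigned(t) for t in ANCESTRAL_INSECT_ORDER]
    assert len(names) == 38 and len(set(names)) == 38
    assert names[-1] == "CR"
    minus = {unsigned(t) for t in ANCESTRAL_INSECT_ORDER if t.startswith("-")}
    assert {"trnQ", "trnC", "trnY", "trnF", "ND5", "trnH", "ND4", "ND4L",
            "trnP", "ND1", "trnL1", "rrnL", "trnV", "rrnS"} == minus


def test_extract_identity_order(default_sim, ref):
    """A genome built on the ancestral plan extracts to the ancestral order."""
    genome, _ = default_sim
    order = extract_gene_order(genome)
    assert order.order == ref.canonical().order
    assert diff_against(order, ref) == []
    assert breakpoint_count(order, ref) == 0


def test_extract_detects_local_swap(ref):
    g, _ = generate_genome(SyntheticSpec(
        seed=1, rearrangement_edits=(RearrangementEdit("shuffle", ("trnK", "trnD")),)
    ))
    order = extract_gene_order(g)
    events = diff_against(order, ref)
    assert len(events) == 1
    assert events[0].kind == "shuffle"
    assert events[0].ancestral_spelling() == "COX2-trnK-trnD"
    assert events[0].derived_spelling() == "COX2-trnD-trnK"


def test_rotation_invariance(ref):
    """Rotating a circular derived order never changes events/breakpoints."""
    derived = paper_fixture_orders()[1]  # four events
    base_events = [e.as_dict() for e in diff_against(derived, ref)]
    base_bp = breakpoint_count(derived, ref)
    for k in (1, 7, 19, 30):
        rot = GeneOrder(derived.taxon, derived.order[k:] + derived.order[:k], True)
        assert [e.as_dict() for e in diff_against(rot, ref)] == base_events
        assert breakpoint_count(rot, ref) == base_bp


def test_diff_self_is_empty(ref):
    assert diff_against(ref, ref) == []
    for order in paper_fixture_orders():
        assert diff_against(order, order) == []
        assert breakpoint_count(order, order) == 0


def test_diff_novel_cluster(ref):
    """The four-gene cluster change ND4-ND4L-trnT-trnP -> ND4-trnP-ND4L-trnT
    is reported as one event spanning those tokens."""
    guihongi = next(o for o in paper_fixture_orders()
                    if o.taxon == "Lipotriches_guihongi")
    events = diff_against(guihongi, ref)
    novel = [e for e in events if "ND4L" in e.genes]
    assert len(novel) == 1
    assert novel[0].ancestral_spelling() == "ND4(-)-ND4L(-)-trnT-trnP(-)"
    assert novel[0].derived_spelling() == "ND4(-)-trnP(-)-ND4L(-)-trnT"
    assert novel[0].kind == "transposition"


def _event(anc, der):
    return RearrangementEvent("unclassified", tuple(anc), tuple(der),
                              tuple(unsigned(t) for t in anc))


@pytest.mark.parametrize(
    "anc, der, kind",
    [
        (("trnK", "trnD"), ("trnD", "trnK"), "shuffle"),
        (("trnI", "-trnQ", "trnM"), ("trnM", "trnI", "-trnQ"), "transposition"),
        (("a", "b", "c"), ("-c", "-b", "-a"), "inversion"),
        (("a",), ("-a",), "inversion"),  # in-place strand flip
        (("a", "b", "c"), ("b", "c", "-a"), "inverse_transposition"),
        (("a", "b", "c", "d"), ("b", "a", "d", "c"), "complex"),
    ],
)
def test_classify_event(anc, der, kind):
    assert classify_event(_event(anc, der)) == kind


def test_round_trip_reconstruction(ref):
    """Substituting every event's derived cluster back into the reference
    reproduces the derived order exactly."""
    for derived in paper_fixture_orders():
        events = diff_against(derived, ref)
        rebuilt = list(ref.canonical().order)
        for e in events:
            anc, der = list(e.ancestral_cluster), list(e.derived_cluster)
            for i in range(len(rebuilt) - len(anc) + 1):
                if rebuilt[i: i + len(anc)] == anc:
                    rebuilt[i: i + len(anc)] = der
                    break
            else:
                pytest.fail(f"cluster {anc} not found in reference")
        assert tuple(rebuilt) == derived.canonical().order


# ---------------------------------------------------------------------------
# breakpoint distance vs a brute-force adjacency oracle
# ---------------------------------------------------------------------------

def _bp_oracle(order, reference, circular):
    """Count reference adjacencies absent from the derived order, reading
    each junction on both strands."""
    def pairs(tokens):
        ps = list(zip(tokens, tokens[1:]))
        if circular and len(tokens) > 1:
            ps.append((tokens[-1], tokens[0]))
        full = set()
        for a, b in ps:
            full.add((a, b))
            full.add((negate(b), negate(a)))
        return ps, full

    ref_pairs, _ = pairs(reference)
    _, derived_all = pairs(order)
    return sum(1 for p in ref_pairs if p not in derived_all)


def _signed_perms(genes):
    for perm in itertools.permutations(genes):
        for signs in itertools.product((1, -1), repeat=len(genes)):
            yield tuple(g if s == 1 else "-" + g for g, s in zip(perm, signs))


@pytest.mark.parametrize("n", [2, 3, 4, 5])
@pytest.mark.parametrize("circular", [False, True])
def test_breakpoints_exhaustive_small(n, circular):
    """Breakpoint distance equals the brute-force adjacency oracle on all
    signed permutations of up to five genes."""
    genes = [f"g{i}" for i in range(n)]
    reference = GeneOrder("ref", tuple(genes), circular)
    for perm in _signed_perms(genes):
        derived = GeneOrder("d", perm, circular)
        assert breakpoint_count(derived, reference) == _bp_oracle(
            perm, tuple(genes), circular
        ), perm


def test_breakpoints_random_n7():
    """200 random signed permutations of seven genes match the oracle."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(7)]
    reference = GeneOrder("ref", tuple(genes), circular=False)
    for _ in range(200):
        perm = [genes[i] for i in rng.permutation(7)]
        perm = tuple(t if rng.random() < 0.5 else "-" + t for t in perm)
        derived = GeneOrder("d", perm, circular=False)
        assert breakpoint_count(derived, reference) == _bp_oracle(
            perm, tuple(genes), False
        )


def test_breakpoint_adjacent_swap_linear_toy():
    a = GeneOrder("a", ("g1", "g2", "g3", "g4", "g5"), circular=False)
    b = GeneOrder("b", ("g1", "g3", "g2", "g4", "g5"), circular=False)
    assert breakpoint_count(b, a) == 3


# ---------------------------------------------------------------------------
# pattern catalog
# ---------------------------------------------------------------------------

def test_pattern_catalog_of_study_taxa(ref):
    """The four study orders exhibit exactly five distinct patterns; the
    novel ND4-trnP-ND4L-trnT cluster belongs to L. guihongi alone."""
    catalog = catalog_patterns(paper_fixture_orders(), ref)
    assert catalog.count == 5
    novel = [p for p in catalog.patterns if "ND4L" in p]
    assert len(novel) == 1
    assert catalog.taxa_for(novel[0]) == {"Lipotriches_guihongi"}
    dk = [p for p in catalog.patterns if set(p.split("-")) >= {"trnD", "trnK"}]
    assert len(dk) == 1 and len(catalog.taxa_for(dk[0])) == 4


def test_pattern_catalog_identity_and_sharing(ref):
    assert catalog_patterns([ref] * 4, ref).count == 0
    shared, _ = generate_genome(SyntheticSpec(
        seed=2, rearrangement_edits=(RearrangementEdit("shuffle", ("trnK", "trnD")),)
    ))
    o1 = extract_gene_order(shared)
    o2 = GeneOrder("other_taxon", o1.order, True)
    catalog = catalog_patterns([o1, o2], ref)
    assert catalog.count == 1
    (taxa,) = catalog.patterns.values()
    assert len(taxa) == 2


def test_duplicate_gene_token_fatal():
    with pytest.raises(ValueError, match="duplicate"):
        GeneOrder("x", ("trnI", "trnI"), True)


def test_missing_genes_excluded_pairwise_with_warning(ref):
    partial = GeneOrder("partial", tuple(
        t for t in ANCESTRAL_INSECT_ORDER if unsigned(t) not in ("trnG", "trnE")
    ), True)
    with pytest.warns(UserWarning, match="missing"):
        events = diff_against(partial, ref)
    assert events == []
    with pytest.warns(UserWarning, match="missing"):
        assert breakpoint_count(partial, ref) == 0
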
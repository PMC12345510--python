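"""The synthetic-genome generator and its ground-truth manifest."""

import numpy as np
import pytest

from mitocomp import (
    ANCESTRAL_INSECT_ORDER,
    GeneOrder,
    RearrangementEdit,
    SyntheticSpec,
    count_bases,
    diff_against,
    extract_gene_order,
    feature_census,
    generate_genome,
    paper_fixture_orders,
)
from mitocomp.gene_order import unsigned
from mitocomp.simulate import DEFAULT_PCG_LENGTHS, random_edits


def test_seed_determinism():
    """Identical spec + seed give byte-identical genome and manifest."""
    g1, m1 = generate_genome(SyntheticSpec(seed=42))
    g2, m2 = generate_genome(SyntheticSpec(seed=42))
    assert g1.sequence == g2.sequence
    assert m1.base_counts == m2.base_counts and m1.codon_counts == m2.codon_counts
    g3, _ = generate_genome(SyntheticSpec(seed=43))
    assert g3.sequence != g1.sequence


def test_default_plan_census(default_sim):
    """The canonical plan yields 13 PCGs, 22 tRNAs, 2 rRNAs, 1 CR."""
    genome, _ = default_sim
    assert feature_census(genome) == {"PCG": 13, "tRNA": 22, "rRNA": 2, "CR": 1}
    assert len(genome.features) == 38


def test_default_pcg_plan_total():
    assert sum(DEFAULT_PCG_LENGTHS.values()) == 11114
    # exactly one gene leaves an incomplete (TA) stop
    assert sum(1 for L in DEFAULT_PCG_LENGTHS.values() if L % 3) == 1


def test_no_edit_spec_extracts_ancestral_order(ancestral):
    g, m = generate_genome(SyntheticSpec(seed=7))
    assert extract_gene_order(g).order == ancestral.canonical().order
    assert m.events == []


def test_two_edit_recovery(ancestral):
    edits = (
        RearrangementEdit("shuffle", ("trnK", "trnD")),
        RearrangementEdit("transposition", ("trnM",), dest=None),
    )
    g, m = generate_genome(SyntheticSpec(seed=3, rearrangement_edits=edits))
    events = diff_against(extract_gene_order(g), ancestral)
    assert len(events) == len(m.events) == 2
    got = sorted((e.kind, tuple(sorted(e.genes))) for e in events)
    want = sorted((e["kind"], tuple(sorted(e["genes"]))) for e in m.events)
    assert got == want


def test_overlapping_edits_fatal():
    edits = (
        RearrangementEdit("shuffle", ("trnK", "trnD")),
        RearrangementEdit("inversion", ("trnK", "ATP8")),
    )
    with pytest.raises(ValueError, match="overlap"):
        generate_genome(SyntheticSpec(seed=1, rearrangement_edits=edits))


def test_manifest_self_consistency(default_sim):
    """Recounting the emitted sequence reproduces the manifest exactly."""
    from mitocomp import region_sequence

    genome, manifest = default_sim
    tallies = {}
    for f in genome.features:
        region = "PCGs" if f.category == "PCG" else f.category
        b = count_bases(region_sequence(genome, f))
        acc = tallies.setdefault(region, dict.fromkeys("ATGC", 0))
        for base, n in zip("ATGC", (b.a, b.t, b.g, b.c)):
            acc[base] += n
    for region, acc in tallies.items():
        want = manifest.base_counts[region]
        assert all(acc[b] == want[b] for b in "ATGC"), region
    assert manifest.genome_length == len(genome)


def test_trna_length_bounds_enforced():
    spec_lengths = dict(SyntheticSpec(seed=0).trna_lengths)
    assert all(50 <= L <= 77 for L in spec_lengths.values())
    spec_lengths["trnA"] = 120
    with pytest.raises(ValueError, match="tRNA lengths"):
        SyntheticSpec(seed=0, trna_lengths=spec_lengths)


def test_minus_strand_genes_emitted_on_minus_strand(default_sim):
    genome, _ = default_sim
    strands = {f.name: f.strand for f in genome.features}
    for token in ANCESTRAL_INSECT_ORDER:
        assert strands[unsigned(token)] == ("-" if token.startswith("-") else "+")


def test_cr_length_and_elevated_at(default_sim):
    """The control region honors its planned length and is more AT-rich
    than the genome average (echoing real mitogenomes)."""
    genome, manifest = default_sim
    cr = next(f for f in genome.features if f.category == "CR")
    assert cr.length == 2755
    cr_counts = manifest.base_counts["CR"]
    whole = manifest.base_counts["whole_genome"]

    def at_frac(c):
        return (c["A"] + c["T"]) / (c["A"] + c["T"] + c["G"] + c["C"])

    assert at_frac(cr_counts) > at_frac(whole)


def test_at_target_tracks_parameter():
    """Lowering at_target moves the whole-genome AT content accordingly."""
    lo, _ = generate_genome(SyntheticSpec(seed=9, at_target=0.70))
    hi, _ = generate_genome(SyntheticSpec(seed=9, at_target=0.90))

    def at(g):
        b = count_bases(g.sequence)
        return (b.a + b.t) / (b.a + b.t + b.g + b.c)

    assert at(lo) == pytest.approx(0.70, abs=0.01)
    assert at(hi) == pytest.approx(0.90, abs=0.01)


def test_paper_fixture_orders_structure():
    """Fixture orders carry the documented cluster changes: trnD-trnK in
    all four taxa, trnM-trnI-trnQ absent only from L. guihongi."""
    orders = {o.taxon: [unsigned(t) for t in o.order] for o in paper_fixture_orders()}
    assert set(orders) == {
        "Dufourea_subclavicrus", "Lipotriches_capitata",
        "Nomia_thoracica", "Lipotriches_guihongi",
    }
    for taxon, names in orders.items():
        i = names.index("COX2")
        assert names[i + 1: i + 3] == ["trnD", "trnK"], taxon
    for taxon, names in orders.items():
        has_miq = names[:3] == ["trnM", "trnI", "trnQ"]
        assert has_miq == (taxon != "Lipotriches_guihongi"), taxon
    gui = orders["Lipotriches_guihongi"]
    i = gui.index("ND4")
    assert gui[i: i + 4] == ["ND4", "trnP", "ND4L", "trnT"]
    dsub = orders["Dufourea_subclavicrus"]
    i = dsub.index("ND3")
    assert dsub[i + 1: i + 3] == ["trnA", "trnR"]  # Rophitinae keeps trnA-trnR


def test_random_edits_are_valid_and_recoverable(ancestral):
    """A short random-edit battery: each spec generates, and diff recovers
    the planted events (the full battery runs in the acceptance suite)."""
    rng = np.random.default_rng(123)
    for _ in range(10):
        edits = random_edits(rng, int(rng.integers(1, 5)))
        g, m = generate_genome(
            SyntheticSpec(seed=int(rng.integers(0, 2**31)),
                          rearrangement_edits=edits)
        )
        events = diff_against(extract_gene_order(g), ancestral)
        got = sorted((e.kind, tuple(sorted(e.genes))) for e in events)
        want = sorted((e["kind"], tuple(sorted(e["genes"]))) for e in m.events)
        assert got == want


def test_spec_yaml_roundtrip(tmp_path):
    import yaml

    spec = SyntheticSpec(
        seed=5, at_target=0.8, cr_length=4000,
        rearrangement_edits=(RearrangementEdit("shuffle", ("trnK", "trnD")),),
    )
    p = tmp_path / "spec.yaml"
    p.write_text(yaml.safe_dump(spec.to_dict()))
    back = SyntheticSpec.from_yaml(p)
    assert back == spec
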
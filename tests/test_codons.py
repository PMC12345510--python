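"""Codon counting, RSCU normalization, and the start/stop census."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp import (
    AnnotatedMitogenome,
    GeneFeature,
    INVERTEBRATE_MITO,
    SyntheticSpec,
    codon_counts,
    generate_genome,
    rank_codons,
    rscu,
    start_stop_census,
)
from mitocomp.codons import GeneticCode, to_rna


def _pcg_genome(*seqs):
    """Plus-strand toy genome with one PCG per given CDS sequence."""
    names = ["COX1", "ND2", "ND3", "ATP6", "CYTB"]
    features, chunks, pos = [], [], 0
    for name, s in zip(names, seqs):
        features.append(GeneFeature(name, "PCG", pos, pos + len(s), "+"))
        chunks.append(s)
        pos += len(s)
    return AnnotatedMitogenome("toy", "".join(chunks), "linear", features)


def test_invertebrate_table_partition():
    """Translation table 5 has 62 sense codons, stops TAA/TAG, AGA=Ser."""
    code = INVERTEBRATE_MITO
    assert len(code.sense_codons) == 62
    assert code.stop_codons == frozenset({"TAA", "TAG"})
    assert code.forward["AGA"] == "S" and code.forward["AGG"] == "S"
    assert code.translate("ATGTTT") == "MF"
    assert code.translate("AGA") == "S"


def test_codon_counts_basic():
    g = _pcg_genome("ATGTTTTAA")
    assert codon_counts(g) == Counter({"ATG": 1, "TTT": 1, "TAA": 1})


def test_codon_counts_excludes_incomplete_tail():
    """A trailing 1- or 2-mer is not a codon and is never counted."""
    g = _pcg_genome("ATGTTTT")  # length 7
    assert codon_counts(g) == Counter({"ATG": 1, "TTT": 1})


def test_codon_counts_short_cds_skipped():
    g = _pcg_genome("ATGTTTTAA", "AT")
    with pytest.warns(UserWarning, match="shorter than one codon"):
        counts = codon_counts(g)
    assert sum(counts.values()) == 3


def test_codon_counts_match_generator_tally(default_sim):
    genome, manifest = default_sim
    assert dict(codon_counts(genome)) == manifest.codon_counts


def test_rscu_two_codon_family():
    """Phe: counts 3:1 give RSCU 1.5 and 0.5."""
    t = rscu({"TTT": 3, "TTC": 1})
    assert t.rscu["UUU"] == pytest.approx(1.5)
    assert t.rscu["UUC"] == pytest.approx(0.5)


def test_rscu_uniform_family_is_one():
    t = rscu({"GGA": 2, "GGC": 2, "GGG": 2, "GGT": 2})
    for codon in ("GGA", "GGC", "GGG", "GGU"):
        assert t.rscu[codon] == pytest.approx(1.0)


def test_rscu_empty_family_is_nan_and_zero_count_is_zero():
    t = rscu({"TTT": 2})
    assert math.isnan(t.rscu["GGA"])  # Gly unobserved entirely
    assert t.rscu["UUC"] == 0.0  # Phe observed, UUC not


def _rscu_oracle(counts, code):
    """Independent brute-force RSCU: group sense codons by amino acid and
    evaluate the definition family by family."""
    by_aa = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.forward[codon], []).append(codon)
    out = {}
    for codons in by_aa.values():
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = math.nan if total == 0 else counts.get(c, 0) * len(codons) / total
    return out


@given(st.lists(st.integers(0, 500), min_size=62, max_size=62))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_rscu_matches_bruteforce_oracle(values):
    """RSCU over random counts on all 62 sense codons equals an
    independently coded per-family evaluation, and every non-empty family
    averages to exactly 1."""
    code = INVERTEBRATE_MITO
    counts = dict(zip(code.sense_codons, values))
    table = rscu(counts, code)
    oracle = _rscu_oracle(counts, code)
    families = {}
    for codon_dna in code.sense_codons:
        got = table.rscu[to_rna(codon_dna)]
        want = oracle[codon_dna]
        assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)
        families.setdefault(code.forward[codon_dna], []).append(got)
    for vals in families.values():
        if not math.isnan(vals[0]):
            assert sum(vals) / len(vals) == pytest.approx(1.0)
            assert sum(vals) == pytest.approx(len(vals))  # family conservation


def test_rscu_split_family_mode():
    """Split normalization treats Leu2 (UUR) as its own two-codon family."""
    t = rscu({"TTA": 3, "TTG": 1}, split_ls_families=True)
    assert t.rscu["UUA"] == pytest.approx(1.5)
    assert t.rscu["UUG"] == pytest.approx(0.5)
    # joint mode spreads the same counts over all six Leu codons
    j = rscu({"TTA": 3, "TTG": 1}, split_ls_families=False)
    assert j.rscu["UUA"] == pytest.approx(3 / (4 / 6))


def test_rank_codons_order_and_ties():
    # family-aware counts: UUA rscu 5.0, UCA 4.5, CGA 3.0, rest <= 2
    t = rscu({"TTA": 50, "CTT": 10,
              "TCA": 36, "TCT": 12, "AGA": 12, "AGT": 4,
              "CGA": 9, "CGT": 3, "GGA": 1, "GGT": 1})
    ranked = rank_codons(t, threshold=2.0)
    assert ranked[:3] == ["UUA", "UCA", "CGA"]
    assert rank_codons(t, threshold=100.0) == []
    tie = rscu({"TTA": 3, "TTG": 3})  # identical RSCU above threshold
    ranked_tie = rank_codons(tie, threshold=2.0)
    assert ranked_tie == sorted(ranked_tie)


def test_translation_count_consistency(default_sim):
    """Total sense-codon count equals the translated amino-acid total."""
    genome, _ = default_sim
    code = INVERTEBRATE_MITO
    counts = codon_counts(genome, code)
    sense_total = sum(n for c, n in counts.items() if c not in code.stop_codons)
    from mitocomp import region_sequence

    aa_total = 0
    for f in genome.features_by_category("PCG"):
        seq = region_sequence(genome, f)
        aa_total += sum(
            1 for ch in code.translate(seq) if ch != "*"
        )
    assert sense_total == aa_total


def test_census_complete_and_incomplete_stops():
    g = _pcg_genome("ATGTTTTAA", "ATTTTTTA", "TTGTTTTAA")
    census = {c.gene: c for c in start_stop_census(g)}
    assert census["COX1"].start == "ATG" and census["COX1"].stop == "TAA"
    assert not census["COX1"].is_incomplete_stop
    assert census["ND2"].start == "ATT" and census["ND2"].stop == "TA"
    assert census["ND2"].is_incomplete_stop
    assert census["ND3"].start == "TTG"
    assert not census["ND3"].is_atn_start
    assert census["COX1"].is_atn_start and census["ND2"].is_atn_start


def test_census_nonstop_terminal_codon_is_other():
    g = _pcg_genome("ATGTTTGGG")
    with pytest.warns(UserWarning, match="not a stop codon"):
        census = start_stop_census(g)
    assert census[0].stop == "other"


def test_generator_censuses_obey_plan(default_sim):
    """Every synthetic PCG starts with ATN or TTG; exactly the genes whose
    planned length is not a codon multiple carry incomplete stops."""
    genome, manifest = default_sim
    for c in start_stop_census(genome):
        assert c.is_atn_start or c.start == "TTG"
        assert c.is_incomplete_stop == (manifest.gene_lengths[c.gene] % 3 != 0)


def test_at_biased_generator_prefers_nna_nnu_codons():
    """With an A/T-rich codon model, NNA/NNU codons dominate the top RSCU
    ranks, as in AT-rich mitogenomes."""
    genome, _ = generate_genome(SyntheticSpec(seed=5))
    table = rscu(codon_counts(genome))
    top = rank_codons(table, threshold=1.0)[:10]
    ending_at = sum(1 for c in top if c.endswith(("A", "U")))
    assert ending_at >= 8
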
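"""Codon counting, RSCU, and start/stop-codon censuses.

Relative synonymous codon usage (RSCU) is the number of times a codon is
used divided by the average usage of all codons encoding the same amino
acid; RSCU = 1 means no bias within the family.  By default the genetic
code is the invertebrate mitochondrial table (NCBI translation table 5),
which has 62 sense codons and two stops (TAA, TAG); under it AGA/AGG
encode serine, so serine is an eight-codon family and leucine a six-codon
family.

Leucine and serine are each normalized as ONE family (the standard RSCU
definition over "all codons coding the amino acid") but reported split
into Leu1 (CUN) / Leu2 (UUR) and Ser1 (AGN) / Ser2 (UCN) for display, the
convention of mitogenome codon-usage figures.  Split-family normalization
is available as an option.

Mitochondrial CDSs frequently end in an incomplete stop (a terminal T or
TA completed to TAA by post-transcriptional polyadenylation); the census
classifies stops by length only.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

from .io import AnnotatedMitogenome, region_sequence

__all__ = [
    "GeneticCode",
    "RSCUTable",
    "GeneCensus",
    "codon_counts",
    "rscu",
    "start_stop_census",
    "rank_codons",
]

_BASES = "TCAG"
ALL_CODONS = tuple("".join(p) for p in product(_BASES, repeat=3))

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A translation table: codon→amino-acid map plus start/stop sets."""

    id: int
    name: str
    forward: dict  # DNA codon -> one-letter amino acid (sense codons only)
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        """Build from an NCBI translation table (default 5, invertebrate mt)."""
        t = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            id=table_id,
            name=t.names[0],
            forward=dict(t.forward_table),
            start_codons=frozenset(t.start_codons),
            stop_codons=frozenset(t.stop_codons),
        )

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in ALL_CODONS if c in self.forward)

    def family_of(self, codon: str) -> str | None:
        """Amino acid (one-letter) encoded by a DNA codon; None for stops."""
        return self.forward.get(to_dna(codon))

    def display_family(self, codon: str) -> str | None:
        """Family label with Leu/Ser split by codon class (display only)."""
        codon = to_dna(codon)
        aa = self.family_of(codon)
        if aa is None:
            return None
        if aa == "L":
            return "Leu2" if codon in ("TTA", "TTG") else "Leu1"
        if aa == "S":
            return "Ser1" if codon.startswith("AG") else "Ser2"
        return _AA3[aa]

    def translate(self, seq: str) -> str:
        """Translate complete codons; stops as '*', ambiguous as 'X'."""
        out = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = to_dna(seq[i: i + 3])
            if codon in self.stop_codons:
                out.append("*")
            else:
                out.append(self.forward.get(codon, "X"))
        return "".join(out)


INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


def codon_counts(
    genome: AnnotatedMitogenome, code: GeneticCode = INVERTEBRATE_MITO
) -> Counter:
    """Codon counts pooled over all PCGs of a genome.

    Each CDS is read in reading orientation from its annotated first base;
    a trailing incomplete codon (length mod 3) is not counted.  Stop
    codons are included here (they are excluded later by :func:`rscu` but
    tallied by the census).  CDSs shorter than one codon are skipped with
    a warning.
    """
    counts: Counter = Counter()
    for f in genome.features_by_category("PCG"):
        seq = region_sequence(genome, f).upper()
        if len(seq) < 3:
            warnings.warn(
                f"{genome.id}: CDS {f.name} shorter than one codon; skipped",
                stacklevel=2,
            )
            continue
        for i in range(0, len(seq) - len(seq) % 3, 3):
            counts[seq[i: i + 3]] += 1
    return counts


@dataclass
class RSCUTable:
    """Per-codon counts and RSCU values, grouped by synonymous family.

    Codon keys are RNA-spelled (UUA, not TTA), matching figure convention.
    ``rscu`` is NaN for every codon of a family with zero total count.
    """

    counts: dict
    rscu: dict
    family: dict  # codon -> display family label (Leu1/Leu2/Ser1/Ser2/...)
    code_id: int
    split_ls_families: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "family": self.family[c],
                "count": self.counts[c],
                "rscu": self.rscu[c],
            }
            for c in self.rscu
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["rscu"] = df["rscu"].map(
            lambda x: "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.3f}"
        )
        df.to_csv(path, sep="\t", index=False)


def rscu(
    counts: Counter | dict,
    code: GeneticCode = INVERTEBRATE_MITO,
    split_ls_families: bool = False,
) -> RSCUTable:
    """Relative synonymous codon usage from per-codon counts.

    For codon ``c`` in synonymous family ``F``::

        rscu(c) = count(c) / (sum(count(x) for x in F) / |F|)

    ``counts`` may be keyed by DNA or RNA codons; stop codons are ignored.
    When ``split_ls_families`` is true, Leu1/Leu2 and Ser1/Ser2 are
    normalized as separate families instead of jointly.
    """
    dna_counts = Counter()
    for codon, n in dict(counts).items():
        dna_counts[to_dna(codon)] += n

    families: dict[str, list[str]] = {}
    for codon in code.sense_codons:
        key = code.display_family(codon) if split_ls_families else code.family_of(codon)
        families.setdefault(key, []).append(codon)

    values: dict[str, float] = {}
    for members in families.values():
        total = sum(dna_counts.get(c, 0) for c in members)
        if total == 0:
            for c in members:
                values[to_rna(c)] = math.nan
        else:
            mean = total / len(members)
            for c in members:
                values[to_rna(c)] = dna_counts.get(c, 0) / mean

    return RSCUTable(
        counts={to_rna(c): dna_counts.get(c, 0) for c in code.sense_codons},
        rscu=values,
        family={to_rna(c): code.display_family(c) for c in code.sense_codons},
        code_id=code.id,
        split_ls_families=split_ls_families,
    )


def rank_codons(table: RSCUTable, threshold: float = 2.0) -> list[str]:
    """Codons with RSCU above ``threshold``, descending; ties alphabetical."""
    above = [
        (c, v) for c, v in table.rscu.items()
        if not math.isnan(v) and v > threshold
    ]
    return [c for c, _ in sorted(above, key=lambda cv: (-cv[1], cv[0]))]


@dataclass
class GeneCensus:
    """Start/stop codon record for one PCG."""

    gene: str
    start: str  # first 3 bases
    stop: str  # TAA/TAG/TA/T/other
    is_atn_start: bool
    is_incomplete_stop: bool


def start_stop_census(
    genome: AnnotatedMitogenome, code: GeneticCode = INVERTEBRATE_MITO
) -> list[GeneCensus]:
    """Start and stop codons of every PCG, flagging ATN starts and
    incomplete (length < 3) stops.

    The stop is the remainder after the last full codon when the CDS
    length is not divisible by 3 (an incomplete TA or T completed by
    polyadenylation in vivo); otherwise the final 3-mer.  A complete
    terminal 3-mer outside the code's stop set is classified ``other``
    with a warning (possible misannotation).
    """
    out = []
    for f in genome.features_by_category("PCG"):
        seq = region_sequence(genome, f).upper()
        if len(seq) < 4:
            warnings.warn(
                f"{genome.id}: CDS {f.name} too short for a census; skipped",
                stacklevel=2,
            )
            continue
        start = seq[:3]
        rem = len(seq) % 3
        if rem:
            stop = seq[len(seq) - rem:]
            incomplete = True
        else:
            stop = seq[-3:]
            incomplete = False
            if stop not in code.stop_codons:
                warnings.warn(
                    f"{genome.id}: {f.name} ends in {stop}, not a stop codon "
                    "(possible misannotation)",
                    stacklevel=2,
                )
                stop = "other"
        out.append(
            GeneCensus(
                gene=f.name,
                start=start,
                stop=stop,
                is_atn_start=len(start) == 3 and start.startswith("AT"),
                is_incomplete_stop=incomplete,
            )
        )
    return out


def census_frame(census: list[GeneCensus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": g.gene, "start": g.start, "stop": g.stop,
                "is_ATN_start": g.is_atn_start,
                "is_incomplete_stop": g.is_incomplete_stop,
            }
            for g in census
        ]
    )


def write_census_tsv(census: list[GeneCensus], path: str | Path) -> None:
    census_frame(census).to_csv(path, sep="\t", index=False)
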
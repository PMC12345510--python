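"""Region- and codon-position-resolved nucleotide composition and skews.

For a sequence region the two strand-asymmetry statistics are

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed over the counts (or, equivalently, percentages — the formulas are
scale-invariant) of the region in reading orientation.  A comparative
composition table resolves a mitogenome into eight regions: the whole
genome, the concatenated protein-coding genes (PCGs), the first/second/
third codon positions of those PCGs, the concatenated tRNAs, rRNAs, and
the control region.

Codon positions are assigned per gene: the position counter restarts at
each PCG's first base and advances cyclically 1-2-3 through the annotated
CDS, *including* any incomplete terminal codon, so the three site lengths
always sum to the PCG region length.  Where same-category features
overlap, each genomic position is counted once, for the first feature
covering it.

Ambiguity codes (N etc.) stay in the sequence but are excluded from the
A/T/G/C counts and from the percentage denominator; the reported length is
the raw span length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

from .io import AnnotatedMitogenome, GeneFeature, reverse_complement

__all__ = [
    "BaseCounts",
    "RegionComposition",
    "count_bases",
    "at_skew",
    "gc_skew",
    "composition_table",
    "composition_frame",
    "write_composition_tsv",
    "round_half_away",
]

REGIONS = ("whole_genome", "PCGs", "site1", "site2", "site3", "tRNA", "rRNA", "CR")


class BaseCounts(NamedTuple):
    a: int
    t: int
    g: int
    c: int
    other: int


def count_bases(seq: str) -> BaseCounts:
    """Count A/T/G/C (case-insensitive, U folded into T) plus everything else."""
    s = seq.upper()
    a = s.count("A")
    t = s.count("T") + s.count("U")
    g = s.count("G")
    c = s.count("C")
    return BaseCounts(a, t, g, c, len(s) - a - t - g - c)


def at_skew(count_a: float, count_t: float) -> float:
    """(A - T) / (A + T); NaN (with a warning) when A + T == 0.

    Accepts raw counts or percentages — the statistic is scale-invariant.
    """
    total = count_a + count_t
    if total == 0:
        warnings.warn("AT-skew undefined: A + T == 0", stacklevel=2)
        return math.nan
    return (count_a - count_t) / total


def gc_skew(count_g: float, count_c: float) -> float:
    """(G - C) / (G + C); NaN (with a warning) when G + C == 0."""
    total = count_g + count_c
    if total == 0:
        warnings.warn("GC-skew undefined: G + C == 0", stacklevel=2)
        return math.nan
    return (count_g - count_c) / total


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed genome tables)."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RegionComposition:
    """Composition summary of one named region (one row of the table)."""

    region: str
    length: int
    count_a: int
    count_t: int
    count_g: int
    count_c: int

    @property
    def _denom(self) -> int:
        return self.count_a + self.count_t + self.count_g + self.count_c

    def _pct(self, n: int) -> float:
        return 100.0 * n / self._denom if self._denom else math.nan

    @property
    def pct_a(self) -> float:
        return self._pct(self.count_a)

    @property
    def pct_t(self) -> float:
        return self._pct(self.count_t)

    @property
    def pct_g(self) -> float:
        return self._pct(self.count_g)

    @property
    def pct_c(self) -> float:
        return self._pct(self.count_c)

    @property
    def at_content(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def gc_content(self) -> float:
        return self.pct_g + self.pct_c

    @property
    def at_skew(self) -> float:
        return at_skew(self.count_a, self.count_t)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.count_g, self.count_c)

    @classmethod
    def from_sequence(cls, region: str, seq: str) -> "RegionComposition":
        b = count_bases(seq)
        return cls(region, len(seq), b.a, b.t, b.g, b.c)

    def as_dict(self, raw_counts: bool = False) -> dict:
        d = {
            "region": self.region,
            "length": self.length,
            "a": round_half_away(self.pct_a, 2),
            "t": round_half_away(self.pct_t, 2),
            "c": round_half_away(self.pct_c, 2),
            "g": round_half_away(self.pct_g, 2),
            "AT": round_half_away(self.at_content, 2),
            "GC": round_half_away(self.gc_content, 2),
            "AT_skew": round_half_away(self.at_skew, 3),
            "GC_skew": round_half_away(self.gc_skew, 3),
        }
        if raw_counts:
            d.update(asdict(self))
        return d


def _reading_positions(f: GeneFeature, genome_length: int) -> list[int]:
    """Genomic positions of a feature in reading (5'->3') order."""
    pos = [p % genome_length for p in range(f.start, f.end)]
    return pos[::-1] if f.strand == "-" else pos


def _category_sequences(
    genome: AnnotatedMitogenome, category: str, with_sites: bool = False
) -> tuple[str, list[str]]:
    """Concatenated reading-orientation sequence of a category.

    Positions already covered by an earlier feature of the same category
    are counted once (first coverage); for PCGs the codon-position counter
    still advances over skipped positions so site assignment stays in
    frame per gene.
    """
    L = len(genome.sequence)
    covered: set[int] = set()
    chunks: list[str] = []
    sites: list[list[str]] = [[], [], []]
    # note: unknown-named genes still count toward composition
    for f in genome.features_by_category(category):
        fseq = (
            reverse_complement(_raw_span(genome, f))
            if f.strand == "-"
            else _raw_span(genome, f)
        )
        positions = _reading_positions(f, L)
        kept = []
        for i, (p, base) in enumerate(zip(positions, fseq)):
            if p in covered:
                continue
            covered.add(p)
            kept.append(base)
            if with_sites:
                sites[i % 3].append(base)
        chunks.append("".join(kept))
    return "".join(chunks), ["".join(s) for s in sites]


def _raw_span(genome: AnnotatedMitogenome, f: GeneFeature) -> str:
    L = len(genome.sequence)
    if f.wraps(L):
        return genome.sequence[f.start:] + genome.sequence[: f.end - L]
    return genome.sequence[f.start: f.end]


def composition_table(genome: AnnotatedMitogenome) -> list[RegionComposition]:
    """Compute the eight-region composition table of a mitogenome.

    Rows follow the conventional order: whole genome, PCGs, codon sites
    1-3, tRNA, rRNA, CR.  Site rows are omitted (with a warning) when the
    genome has no annotated PCG; category rows are omitted when the
    category is absent.
    """
    rows = [RegionComposition.from_sequence("whole_genome", genome.sequence)]

    pcg_seq, site_seqs = _category_sequences(genome, "PCG", with_sites=True)
    if pcg_seq:
        rows.append(RegionComposition.from_sequence("PCGs", pcg_seq))
        for i, s in enumerate(site_seqs, start=1):
            rows.append(RegionComposition.from_sequence(f"site{i}", s))
    else:
        warnings.warn(
            f"{genome.id}: no PCG features; PCG and site rows omitted", stacklevel=2
        )

    for category, region in (("tRNA", "tRNA"), ("rRNA", "rRNA"), ("CR", "CR")):
        seq, _ = _category_sequences(genome, category)
        if seq:
            rows.append(RegionComposition.from_sequence(region, seq))
    return rows


def composition_frame(
    rows: Iterable[RegionComposition] | AnnotatedMitogenome,
    raw_counts: bool = False,
) -> pd.DataFrame:
    """Composition rows as a DataFrame in the standard column order."""
    if isinstance(rows, AnnotatedMitogenome):
        rows = composition_table(rows)
    df = pd.DataFrame([r.as_dict(raw_counts=raw_counts) for r in rows])
    pretty = {
        "region": "Regions", "length": "Length(bp)",
        "AT_skew": "AT-Skew", "GC_skew": "GC-Skew",
    }
    return df.rename(columns=pretty)


def write_composition_tsv(
    rows: Iterable[RegionComposition] | AnnotatedMitogenome, path: str | Path
) -> None:
    """Write the composition table as TSV in the printed-table column order."""
    composition_frame(rows).to_csv(path, sep="\t", index=False)
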
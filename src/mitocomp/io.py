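"""Reading, writing and slicing annotated mitogenomes.

An :class:`AnnotatedMitogenome` is the unit every analysis stage consumes:
a DNA sequence, its topology, and an ordered list of typed, stranded
:class:`GeneFeature` records with canonical gene names.

Coordinate conventions
----------------------
Internally all coordinates are 0-based half-open; file I/O (GenBank, the
TSV feature table) uses the 1-based inclusive convention of the deposit
format.  A feature may wrap the replication origin only on a circular
genome; internally such a feature keeps ``start < len(sequence) <= end``
so that ``end - start`` is always its length, and is written out as a
``join(start..L,1..k)`` compound location.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .nomenclature import UNKNOWN, category_of, normalize_gene_name

__all__ = [
    "GeneFeature",
    "AnnotatedMitogenome",
    "MitogenomeParseError",
    "read_genbank",
    "write_genbank",
    "read_feature_table",
    "write_feature_table",
    "region_sequence",
]


class MitogenomeParseError(ValueError):
    """Raised when an input file cannot be interpreted as a mitogenome."""


@dataclass
class GeneFeature:
    """One annotated gene (or the control region).

    ``start``/``end`` are 0-based half-open genome coordinates; ``end`` may
    exceed the genome length for an origin-wrapping feature on a circular
    genome.  ``strand`` is ``'+'`` or ``'-'``; minus-strand features are
    reverse-complemented by :func:`region_sequence`.
    """

    name: str
    category: str  # PCG | tRNA | rRNA | CR
    start: int
    end: int
    strand: str = "+"
    raw_name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid coordinates for {self.name}: [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        tok_cat = category_of(self.name)
        if tok_cat is not None and tok_cat != self.category:
            raise ValueError(
                f"{self.name} is a {tok_cat} token but category={self.category}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class AnnotatedMitogenome:
    """A mitogenome sequence plus its ordered gene features."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)
    #: features present in the source that could not be typed as genes
    extras: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        self.validate()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            limit = 2 * len(self.sequence) if self.topology == "circular" else len(self.sequence)
            if f.end > limit or (f.wraps(len(self.sequence)) and self.topology != "circular"):
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}) outside genome of "
                    f"length {len(self.sequence)} (topology={self.topology})"
                )
            if f.name != UNKNOWN:
                if f.name in seen:
                    raise ValueError(f"duplicate canonical gene {f.name}")
                seen.add(f.name)

    def features_by_category(self, category: str) -> list[GeneFeature]:
        """Features of one category, in genomic order."""
        return sorted(
            (f for f in self.features if f.category == category),
            key=lambda f: (f.start, f.end),
        )


def feature_census(genome: AnnotatedMitogenome) -> dict:
    """Count annotated gene features per category (PCG/tRNA/rRNA/CR)."""
    census = {"PCG": 0, "tRNA": 0, "rRNA": 0, "CR": 0}
    for f in genome.features:
        if f.category in census:
            census[f.category] += 1
    return census


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def region_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Extract a feature's sequence in reading orientation.

    Minus-strand features are reverse-complemented; origin-wrapping
    features are concatenated across the origin before orientation.
    """
    L = len(genome.sequence)
    if feature.wraps(L):
        raw = genome.sequence[feature.start:] + genome.sequence[: feature.end - L]
    else:
        raw = genome.sequence[feature.start: feature.end]
    return reverse_complement(raw) if feature.strand == "-" else raw


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GENE_FEATURE_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
_CR_HINTS = re.compile(r"control region|d-loop|at[- ]rich", re.IGNORECASE)
_ANTICODON_SEQ = re.compile(r"seq\s*:\s*([acgtu]{3})", re.IGNORECASE)


def _feature_name_hints(f: SeqFeature) -> tuple[str | None, str | None]:
    """Best raw name and anticodon triplet from a Biopython feature."""
    q = f.qualifiers
    raw = None
    for key in ("gene", "product", "note", "standard_name"):
        if key in q and q[key]:
            raw = q[key][0]
            break
    anticodon = None
    if "anticodon" in q and q["anticodon"]:
        m = _ANTICODON_SEQ.search(q["anticodon"][0])
        if m:
            anticodon = m.group(1).lower()
        elif re.fullmatch(r"[acgtu]{3}", q["anticodon"][0].strip(), re.IGNORECASE):
            anticodon = q["anticodon"][0].strip().lower()
    # product strings like "tRNA-Leu (UUR)" carry the codon class; pass the
    # whole product through normalization which understands that form.
    return raw, anticodon


def _location_span(f: SeqFeature, genome_length: int) -> tuple[int, int]:
    """Internal (start, end) for a feature, splitting origin wraps."""
    loc = f.location
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin wrap: a tail part ending at L and a head part starting at 0
        if (
            len(parts) == 2
            and int(parts[0].start) == 0
            and int(parts[1].end) == genome_length
        ):
            return int(parts[1].start), genome_length + int(parts[0].end)
        return int(loc.start), int(loc.end)
    return int(loc.start), int(loc.end)


def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Read a GenBank flat file into an :class:`AnnotatedMitogenome`.

    Every CDS/tRNA/rRNA feature and every misc_feature/D-loop that looks
    like a control region becomes a :class:`GeneFeature` with a normalized
    name; features that cannot be typed are retained in ``extras``.  A gene
    whose name cannot be normalized is kept with the ``unknown`` sentinel
    (it still contributes to composition, but is excluded from gene-order
    analysis) and a warning is emitted.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise MitogenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if len(record.seq) == 0:
        raise MitogenomeParseError(f"{path}: record has no sequence (missing ORIGIN?)")

    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    L = len(record.seq)

    features: list[GeneFeature] = []
    extras: list[GeneFeature] = []
    for f in record.features:
        if f.type == "source":
            continue
        raw, anticodon = _feature_name_hints(f)
        start, end = _location_span(f, L)
        strand = "-" if f.location.strand == -1 else "+"
        if f.type in _GENE_FEATURE_TYPES:
            category = _GENE_FEATURE_TYPES[f.type]
            name = normalize_gene_name(raw or "", anticodon=anticodon)
            if name == UNKNOWN:
                warnings.warn(
                    f"{path.name}: cannot normalize {f.type} name {raw!r}; "
                    "feature kept but excluded from gene-order analysis",
                    stacklevel=2,
                )
            elif category_of(name) != category:
                warnings.warn(
                    f"{path.name}: {raw!r} normalizes to {name} which is not a "
                    f"{category}; treating as unknown",
                    stacklevel=2,
                )
                name = UNKNOWN
            features.append(
                GeneFeature(name, category, start, end, strand, raw_name=raw)
            )
        elif f.type in ("misc_feature", "D-loop"):
            text = " ".join([raw or ""] + f.qualifiers.get("note", []))
            if f.type == "D-loop" or _CR_HINTS.search(text) or (
                raw and normalize_gene_name(raw) == "CR"
            ):
                features.append(
                    GeneFeature("CR", "CR", start, end, strand, raw_name=raw)
                )
            else:
                extras.append(
                    GeneFeature(UNKNOWN, f.type, start, end, strand, raw_name=raw)
                )
    features.sort(key=lambda g: (g.start, g.end))
    return AnnotatedMitogenome(
        id=record.id or record.name or path.stem,
        sequence=str(record.seq).upper(),
        topology=topology,
        features=features,
        extras=extras,
    )


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    """Write an annotated mitogenome as a GenBank flat file."""
    L = len(genome.sequence)
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=re.sub(r"[^\w.-]", "_", genome.id)[:16] or "MITOGENOME",
        description="annotated mitogenome",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "data_file_division": "INV",
        },
    )
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "misc_feature"}
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps(L):
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, strand), SimpleLocation(0, f.end - L, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        qualifiers = {"gene": [f.name]}
        if f.category == "CR":
            qualifiers = {"note": ["control region"]}
        record.features.append(SeqFeature(loc, type=type_of[f.category], qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + TSV feature table (annotation-free alternative input)
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("name", "category", "start_1based", "end_1based", "strand")


def read_feature_table(
    fasta_path: str | Path,
    tsv_path: str | Path,
    topology: str = "circular",
) -> AnnotatedMitogenome:
    """Read a FASTA sequence plus a TSV feature table.

    The TSV has columns ``name, category, start_1based, end_1based, strand``
    (1-based inclusive; an origin-wrapping feature on a circular genome has
    ``end < start``).
    """
    try:
        record = SeqIO.read(str(fasta_path), "fasta")
    except Exception as exc:  # noqa: BLE001
        raise MitogenomeParseError(f"cannot parse FASTA {fasta_path}: {exc}") from exc
    L = len(record.seq)
    features: list[GeneFeature] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip() for h in header) != _TSV_COLUMNS:
            raise MitogenomeParseError(
                f"{tsv_path}: expected columns {_TSV_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            try:
                raw_name, category, s1, e1, strand = line.rstrip("\n").split("\t")
                start, end = int(s1) - 1, int(e1)
            except ValueError as exc:
                raise MitogenomeParseError(f"{tsv_path}:{lineno}: {exc}") from exc
            if end <= start:  # wrap notation end < start (1-based)
                end += L
            name = normalize_gene_name(raw_name)
            if name == UNKNOWN:
                warnings.warn(
                    f"{tsv_path}:{lineno}: cannot normalize {raw_name!r}",
                    stacklevel=2,
                )
            features.append(
                GeneFeature(name, category.strip(), start, end, strand.strip(),
                            raw_name=raw_name)
            )
    return AnnotatedMitogenome(
        id=record.id, sequence=str(record.seq).upper(), topology=topology,
        features=features,
    )


def write_feature_table(
    genome: AnnotatedMitogenome,
    fasta_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write the FASTA + TSV representation of a genome."""
    L = len(genome.sequence)
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
        str(fasta_path),
        "fasta",
    )
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in genome.features:
            end1 = f.end - L if f.wraps(L) else f.end
            fh.write(f"{f.name}\t{f.category}\t{f.start + 1}\t{end1}\t{f.strand}\n")
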
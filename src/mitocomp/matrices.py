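"""Phylogenomic supermatrix construction.

From per-gene alignments (already aligned and trimmed; alignment itself
is out of scope) this module builds the five standard mitogenome
supermatrices:

* ``cds_faa``    — all PCGs, translated to amino acids;
* ``cds_fna``    — all PCGs, nucleotides;
* ``cds_rrna``   — PCG nucleotides plus the two rRNAs;
* ``cds12_fna``  — PCG nucleotides with third codon positions removed;
* ``cds12_rrna`` — the stripped PCGs plus the two rRNAs.

Third-position stripping enforces the arithmetic identity
``width(cds12) = 2/3 × width(cds)``; genes are concatenated in a fixed
order (the ancestral genomic order) and every matrix carries a partition
table with 1-based inclusive coordinates, emitted in RAxML and NEXUS
``sets`` formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .codons import GeneticCode, INVERTEBRATE_MITO
from .gene_order import ANCESTRAL_INSECT_ORDER, unsigned

__all__ = [
    "GeneAlignment",
    "Partition",
    "SupermatrixBundle",
    "translate_alignment",
    "strip_third_positions",
    "build_bundle",
    "read_gene_alignment",
    "MATRIX_NAMES",
]

MATRIX_NAMES = ("cds_faa", "cds_fna", "cds_rrna", "cds12_fna", "cds12_rrna")

#: Gene concatenation order: PCGs then rRNAs, each in ancestral genomic order.
PCG_CONCAT_ORDER = tuple(
    unsigned(t) for t in ANCESTRAL_INSECT_ORDER
    if unsigned(t).startswith(("ND", "COX", "ATP", "CYTB"))
)
RRNA_CONCAT_ORDER = ("rrnL", "rrnS")


@dataclass
class GeneAlignment:
    """One per-gene alignment: taxon -> equal-width aligned sequence.

    ``positions`` tracks column provenance for codon data: ``"123"`` for a
    full codon alignment, ``"12"`` after third-position stripping.
    """

    gene: str
    kind: str  # PCG_nt | rRNA_nt | PCG_aa
    rows: dict
    positions: str = "123"

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.gene}: empty alignment")
        widths = {len(s) for s in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(f"{self.gene}: unequal row widths {sorted(widths)}")
        if self.kind == "PCG_nt" and self.positions == "123" and self.width % 3:
            raise ValueError(
                f"{self.gene}: codon alignment width {self.width} not divisible by 3"
            )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> frozenset:
        return frozenset(self.rows)


def read_gene_alignment(path: str | Path, gene: str | None = None,
                        kind: str | None = None) -> GeneAlignment:
    """Read a per-gene aligned FASTA; gene/kind inferred from the filename
    (``rrnL.fasta`` → rRNA_nt, anything else → PCG_nt) unless given."""
    path = Path(path)
    gene = gene or path.stem
    kind = kind or ("rRNA_nt" if gene.lower().startswith("rrn") else "PCG_nt")
    rows = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GeneAlignment(gene=gene, kind=kind, rows=rows)


def translate_alignment(
    aln: GeneAlignment, code: GeneticCode = INVERTEBRATE_MITO
) -> GeneAlignment:
    """Translate a codon-aware nucleotide alignment to amino acids.

    Any codon containing a gap becomes a gap column; an internal stop
    codon becomes ``X`` with a warning (terminal stops translate to
    ``*``); ambiguous codons become ``X``.
    """
    if aln.kind != "PCG_nt":
        raise ValueError(f"{aln.gene}: can only translate PCG_nt alignments")
    if aln.positions != "123":
        raise ValueError(f"{aln.gene}: cannot translate a stripped alignment")
    if aln.width % 3:
        raise ValueError(f"{aln.gene}: width {aln.width} not divisible by 3")
    out = {}
    n_codons = aln.width // 3
    for taxon, seq in aln.rows.items():
        aas = []
        for k in range(n_codons):
            codon = seq[3 * k: 3 * k + 3]
            if "-" in codon:
                aas.append("-")
            elif codon in code.stop_codons:
                if k < n_codons - 1:
                    warnings.warn(
                        f"{aln.gene}/{taxon}: internal stop codon {codon} at "
                        f"codon {k + 1}; translated as X",
                        stacklevel=2,
                    )
                    aas.append("X")
                else:
                    aas.append("*")
            else:
                aas.append(code.forward.get(codon, "X"))
        out[taxon] = "".join(aas)
    return GeneAlignment(gene=aln.gene, kind="PCG_aa", rows=out, positions="aa")


def strip_third_positions(aln: GeneAlignment) -> GeneAlignment:
    """Remove every third codon position; output width is 2/3 the input.

    Refuses to strip an already-stripped alignment (column provenance is
    tracked in ``positions``).
    """
    if aln.kind != "PCG_nt":
        raise ValueError(f"{aln.gene}: can only strip PCG_nt alignments")
    if aln.positions != "123":
        raise ValueError(f"{aln.gene}: alignment already stripped (positions="
                         f"{aln.positions!r})")
    if aln.width % 3:
        raise ValueError(f"{aln.gene}: width {aln.width} not divisible by 3")
    rows = {
        taxon: "".join(seq[i] for i in range(len(seq)) if i % 3 != 2)
        for taxon, seq in aln.rows.items()
    }
    return GeneAlignment(gene=aln.gene, kind="PCG_nt", rows=rows, positions="12")


@dataclass(frozen=True)
class Partition:
    """One partition: 1-based inclusive columns [start, end] of a matrix."""

    name: str
    start: int
    end: int
    type: str  # DNA | AA


@dataclass
class SupermatrixBundle:
    """The five concatenated matrices plus their partition tables."""

    matrices: dict  # name -> {taxon -> sequence}
    partitions: dict = field(default_factory=dict)  # name -> list[Partition]

    def width(self, name: str) -> int:
        rows = self.matrices[name]
        return len(next(iter(rows.values())))

    def taxa(self) -> tuple:
        return tuple(sorted(next(iter(self.matrices.values())).keys()))

    # -- writers ----------------------------------------------------------

    def write_fasta(self, name: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            for taxon in self.taxa():
                fh.write(f">{taxon}\n{self.matrices[name][taxon]}\n")

    def write_phylip(self, name: str, path: str | Path) -> None:
        """Relaxed PHYLIP (full taxon names, space-separated)."""
        rows = self.matrices[name]
        with open(path, "w") as fh:
            fh.write(f" {len(rows)} {self.width(name)}\n")
            pad = max(len(t) for t in rows) + 2
            for taxon in self.taxa():
                fh.write(f"{taxon.ljust(pad)}{rows[taxon]}\n")

    def write_raxml_partitions(self, name: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.partitions[name]:
                model = "DNA" if p.type == "DNA" else "MTART"
                fh.write(f"{model}, {p.name} = {p.start}-{p.end}\n")

    def write_nexus_sets(self, name: str, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin sets;\n")
            for p in self.partitions[name]:
                fh.write(f"    charset {p.name} = {p.start}-{p.end};\n")
            fh.write("end;\n")


def _concat(alignments: list, taxa: tuple, fill_missing: bool,
            matrix: str) -> tuple[dict, list]:
    rows = {t: [] for t in taxa}
    partitions = []
    pos = 1
    for aln in alignments:
        missing = [t for t in taxa if t not in aln.rows]
        if missing and not fill_missing:
            raise ValueError(
                f"{matrix}: taxa missing from {aln.gene}: {sorted(missing)} "
                "(use the gap fill policy to pad)"
            )
        if missing:
            warnings.warn(
                f"{matrix}: {aln.gene} missing {sorted(missing)}; gap-padded",
                stacklevel=3,
            )
        for t in taxa:
            rows[t].append(aln.rows.get(t, "-" * aln.width))
        ptype = "AA" if aln.kind == "PCG_aa" else "DNA"
        partitions.append(Partition(aln.gene, pos, pos + aln.width - 1, ptype))
        pos += aln.width
    return {t: "".join(parts) for t, parts in rows.items()}, partitions


def build_bundle(
    alignments: list,
    code: GeneticCode = INVERTEBRATE_MITO,
    missing: str = "fatal",
) -> SupermatrixBundle:
    """Assemble the five supermatrices from per-gene alignments.

    ``alignments`` holds PCG_nt and rRNA_nt :class:`GeneAlignment` objects
    (any subset; at least one PCG).  Genes concatenate in the ancestral
    genomic order, rRNAs after PCGs.  ``missing`` is ``"fatal"`` (default;
    a taxon absent from any gene aborts) or ``"gaps"`` (pad with gaps,
    warn).
    """
    if missing not in ("fatal", "gaps"):
        raise ValueError("missing policy must be 'fatal' or 'gaps'")
    by_gene = {a.gene: a for a in alignments}
    if len(by_gene) != len(alignments):
        raise ValueError("duplicate gene alignments")
    pcgs = [by_gene[g] for g in PCG_CONCAT_ORDER if g in by_gene]
    extra_pcgs = sorted(
        g for g, a in by_gene.items()
        if a.kind == "PCG_nt" and g not in PCG_CONCAT_ORDER
    )
    pcgs += [by_gene[g] for g in extra_pcgs]
    rrnas = [by_gene[g] for g in RRNA_CONCAT_ORDER if g in by_gene]
    if not pcgs:
        raise ValueError("no PCG alignments supplied")

    taxa = tuple(sorted(set().union(*(a.taxa for a in alignments))))
    fill = missing == "gaps"

    faa = [translate_alignment(a, code) for a in pcgs]
    p12 = [strip_third_positions(a) for a in pcgs]

    matrices, partitions = {}, {}
    for name, parts in (
        ("cds_faa", faa),
        ("cds_fna", pcgs),
        ("cds_rrna", pcgs + rrnas),
        ("cds12_fna", p12),
        ("cds12_rrna", p12 + rrnas),
    ):
        matrices[name], partitions[name] = _concat(parts, taxa, fill, name)

    bundle = SupermatrixBundle(matrices=matrices, partitions=partitions)
    # arithmetic identities that must hold for any input set
    assert bundle.width("cds12_fna") * 3 == bundle.width("cds_fna") * 2
    rrna_w = sum(a.width for a in rrnas)
    assert bundle.width("cds_rrna") == bundle.width("cds_fna") + rrna_w
    assert bundle.width("cds12_rrna") == bundle.width("cds12_fna") + rrna_w
    assert bundle.width("cds_faa") * 3 == bundle.width("cds_fna")
    return bundle
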
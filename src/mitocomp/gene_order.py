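"""Signed gene orders, rearrangement detection and classification.

A mitogenome's gene arrangement is a signed permutation of the 37 genes
plus the control region (CR); the sign records the coding strand.  The
comparison baseline is the ancestral insect arrangement (the *Drosophila
yakuba* order), packaged as :data:`ANCESTRAL_INSECT_ORDER`.

Differences against a reference are factored into local events: maximal
identical blocks are removed and each remaining contiguous cluster of
displaced genes becomes one :class:`RearrangementEvent`, typed purely
from order and sign evidence:

* ``shuffle`` — two neighboring genes exchange positions, signs unchanged;
* ``transposition`` — a gene/block moves to a non-adjacent slot, signs
  unchanged;
* ``inversion`` — a contiguous block is reversed with all signs flipped;
* ``inverse_transposition`` — a block moves and flips sign;
* ``complex`` — anything not explained by a single such operation.

The breakpoint distance counts signed adjacencies of the reference that
are absent from the derived order (circular-aware); it is the standard
coarse measure of gene-order divergence.

The CR anchors the rotation of circular orders (it participates in
adjacencies but never in event clusters).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import AnnotatedMitogenome
from .nomenclature import UNKNOWN

__all__ = [
    "ANCESTRAL_INSECT_ORDER",
    "GeneOrder",
    "RearrangementEvent",
    "PatternCatalog",
    "extract_gene_order",
    "diff_against",
    "classify_event",
    "breakpoint_count",
    "catalog_patterns",
    "read_orders",
    "write_orders",
]

#: The ancestral insect mitochondrial gene arrangement (*D. yakuba*),
#: as signed tokens; '-' marks minority-strand genes.
ANCESTRAL_INSECT_ORDER = (
    "trnI", "-trnQ", "trnM", "ND2", "trnW", "-trnC", "-trnY", "COX1",
    "trnL2", "COX2", "trnK", "trnD", "ATP8", "ATP6", "COX3", "trnG",
    "ND3", "trnA", "trnR", "trnN", "trnS1", "trnE", "-trnF", "-ND5",
    "-trnH", "-ND4", "-ND4L", "trnT", "-trnP", "ND6", "CYTB", "trnS2",
    "-ND1", "-trnL1", "-rrnL", "-trnV", "-rrnS", "CR",
)


def unsigned(token: str) -> str:
    return token[1:] if token.startswith("-") else token


def negate(token: str) -> str:
    return token[1:] if token.startswith("-") else "-" + token


def _signed_str(token: str) -> str:
    """Render a signed token with the minus suffixed: ``trnQ(-)``."""
    return f"{unsigned(token)}(-)" if token.startswith("-") else token


@dataclass(frozen=True)
class GeneOrder:
    """A taxon's signed gene order."""

    taxon: str
    order: tuple
    circular: bool = True

    def __post_init__(self) -> None:
        names = [unsigned(t) for t in self.order]
        dupes = [n for n, k in Counter(names).items() if k > 1]
        if dupes:
            raise ValueError(f"{self.taxon}: duplicate gene tokens {dupes}")

    def __iter__(self):
        return iter(self.order)

    def __len__(self) -> int:
        return len(self.order)

    def tokens(self) -> frozenset:
        return frozenset(unsigned(t) for t in self.order)

    def rotated(self, k: int) -> "GeneOrder":
        """Rotate so that index ``k`` comes first (circular orders only)."""
        if not self.circular:
            raise ValueError("cannot rotate a linear gene order")
        k %= len(self.order)
        return GeneOrder(self.taxon, self.order[k:] + self.order[:k], True)

    def canonical(self) -> "GeneOrder":
        """Canonical rotation: the gene after the CR first (CR last).

        Falls back to starting at trnI when the CR is absent.  Linear
        orders are returned unchanged.
        """
        if not self.circular:
            return self
        names = [unsigned(t) for t in self.order]
        if "CR" in names:
            return self.rotated(names.index("CR") + 1)
        if "trnI" in names:
            return self.rotated(names.index("trnI"))
        return self

    def restricted(self, keep: frozenset) -> "GeneOrder":
        return GeneOrder(
            self.taxon,
            tuple(t for t in self.order if unsigned(t) in keep),
            self.circular,
        )


def extract_gene_order(genome: AnnotatedMitogenome) -> GeneOrder:
    """Signed gene order of a genome, genes sorted by start coordinate.

    Unknown-named features are excluded (they were already flagged at
    parse time).  Circular genomes are rotated to the canonical anchor so
    orders from different genomes are directly comparable.
    """
    feats = sorted(
        (f for f in genome.features if f.name != UNKNOWN),
        key=lambda f: (f.start, f.end),
    )
    tokens = tuple(
        ("-" + f.name) if f.strand == "-" else f.name for f in feats
    )
    order = GeneOrder(genome.id, tokens, circular=genome.topology == "circular")
    return order.canonical() if order.circular else order


@dataclass(frozen=True)
class RearrangementEvent:
    """One local difference between a derived and a reference order.

    Clusters include the conserved left-flank gene (when one exists) so
    the spelling reads like the literature: ``COX2-trnK-trnD`` →
    ``COX2-trnD-trnK``.  ``genes`` are the unsigned tokens that actually
    moved or flipped (the event core).
    """

    kind: str
    ancestral_cluster: tuple
    derived_cluster: tuple
    genes: tuple

    def ancestral_spelling(self) -> str:
        return "-".join(_signed_str(t) for t in self.ancestral_cluster)

    def derived_spelling(self) -> str:
        return "-".join(_signed_str(t) for t in self.derived_cluster)

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "ancestral": self.ancestral_spelling(),
            "derived": self.derived_spelling(),
            "genes": list(self.genes),
        }


def _strip_flanks(r: Sequence[str], d: Sequence[str]) -> tuple[tuple, tuple]:
    """Remove the common signed prefix/suffix of two clusters."""
    r, d = list(r), list(d)
    while r and d and r[0] == d[0]:
        r.pop(0)
        d.pop(0)
    while r and d and r[-1] == d[-1]:
        r.pop()
        d.pop()
    return tuple(r), tuple(d)


def _align_for_diff(order: GeneOrder, reference: GeneOrder) -> tuple[list, list]:
    """Restrict to shared genes and rotate both to a common anchor."""
    common = order.tokens() & reference.tokens()
    missing = (order.tokens() | reference.tokens()) - common
    if missing:
        warnings.warn(
            f"{order.taxon} vs {reference.taxon}: genes missing from one "
            f"order excluded pairwise: {sorted(missing)}",
            stacklevel=3,
        )
    o = order.restricted(common)
    r = reference.restricted(common)
    if o.circular and r.circular:
        o, r = o.canonical(), r.canonical()
        names_o = [unsigned(t) for t in o.order]
        if "CR" not in names_o:
            # anchor on the first reference gene found in the derived order
            for t in r.order:
                if unsigned(t) in names_o:
                    o = o.rotated(names_o.index(unsigned(t)))
                    break
    return list(o.order), list(r.order)


def diff_against(order: GeneOrder, reference: GeneOrder) -> list[RearrangementEvent]:
    """Factor the difference between two orders into local events.

    Positions where the two aligned orders agree (same signed token) form
    the conserved backbone; each maximal run of disagreeing positions,
    extended until its two sides contain the same unsigned gene set,
    becomes one event.  Events are returned in reference order.
    """
    d, r = _align_for_diff(order, reference)
    if len(d) != len(r):  # cannot happen after restriction; guard anyway
        raise ValueError("orders do not cover the same gene set")

    events: list[RearrangementEvent] = []
    i, n = 0, len(r)
    while i < n:
        if d[i] == r[i]:
            i += 1
            continue
        # grow the window until it is balanced (same unsigned multiset on
        # both sides); token uniqueness guarantees balance by the end
        j = i
        net: Counter = Counter()
        while j < n:
            for tok, delta in ((unsigned(r[j]), 1), (unsigned(d[j]), -1)):
                net[tok] += delta
                if net[tok] == 0:
                    del net[tok]
            j += 1
            if not net:
                break
        anc_core, der_core = tuple(r[i:j]), tuple(d[i:j])
        # include the conserved left flank for readable spellings
        if i > 0:
            anc = (r[i - 1],) + anc_core
            der = (d[i - 1],) + der_core
        else:
            anc, der = anc_core, der_core
        core_r, core_d = _strip_flanks(anc_core, der_core)
        event = RearrangementEvent(
            kind="unclassified",
            ancestral_cluster=anc,
            derived_cluster=der,
            genes=tuple(unsigned(t) for t in core_r),
        )
        events.append(
            RearrangementEvent(
                kind=classify_event(event),
                ancestral_cluster=anc,
                derived_cluster=der,
                genes=event.genes,
            )
        )
        i = j
    return events


def _single_block_moves(r: tuple, d: tuple, flip: bool):
    """Yield (block_len, distance) for single-block moves turning r into d.

    A move removes the contiguous block ``r[i:j]`` (sign-flipped and
    reversed when ``flip``) and reinserts it at another position.
    """
    n = len(r)
    for i in range(n):
        for j in range(i + 1, n + 1):
            block = list(r[i:j])
            if flip:
                block = [negate(t) for t in reversed(block)]
            rest = list(r[:i]) + list(r[j:])
            for k in range(len(rest) + 1):
                if not flip and k == i:
                    continue  # no-op
                cand = rest[:k] + block + rest[k:]
                if tuple(cand) == d:
                    distance = abs(k - i)
                    yield (j - i, distance)


def classify_event(event: RearrangementEvent) -> str:
    """Type an event from order/sign evidence alone.

    Tried in order: inversion (block reversed, all signs flipped), shuffle
    (two adjacent genes exchanged, signs kept), transposition (single
    unsigned block move), inverse transposition (single block move with
    flip).  Anything else is ``complex``.
    """
    r, d = _strip_flanks(event.ancestral_cluster, event.derived_cluster)
    if not r and not d:
        return "identity"
    if d == tuple(negate(t) for t in reversed(r)):
        return "inversion"
    if len(r) == 2 and d == (r[1], r[0]):
        return "shuffle"
    if any(True for _ in _single_block_moves(r, d, flip=False)):
        return "transposition"
    if any(True for _ in _single_block_moves(r, d, flip=True)):
        return "inverse_transposition"
    return "complex"


def _adjacency_set(tokens: Sequence[str], circular: bool) -> set:
    """Canonical signed adjacencies of an order.

    The adjacency (a, b) read on the other strand is (-b, -a); both
    spellings denote the same junction, so each pair is stored under a
    canonical representative.
    """
    pairs = list(zip(tokens, tokens[1:]))
    if circular and len(tokens) > 1:
        pairs.append((tokens[-1], tokens[0]))
    out = set()
    for a, b in pairs:
        alt = (negate(b), negate(a))
        out.add(min((a, b), alt))
    return out


def breakpoint_count(order: GeneOrder, reference: GeneOrder) -> int:
    """Number of reference adjacencies absent from ``order`` (signed,
    circular-aware, strand-symmetric)."""
    common = order.tokens() & reference.tokens()
    missing = (order.tokens() | reference.tokens()) - common
    if missing:
        warnings.warn(
            f"{order.taxon} vs {reference.taxon}: genes missing from one "
            f"order excluded pairwise: {sorted(missing)}",
            stacklevel=2,
        )
    o = order.restricted(common)
    r = reference.restricted(common)
    circ = o.circular and r.circular
    return len(
        _adjacency_set(r.order, circ) - _adjacency_set(o.order, circ)
    )


@dataclass
class PatternCatalog:
    """Distinct derived-cluster patterns across taxa.

    Pattern strings are canonical (orientation-normalized: a cluster and
    its reverse-complement reading collide), so the same rearrangement in
    two taxa is one pattern.
    """

    patterns: dict = field(default_factory=dict)  # pattern -> set of taxa

    @property
    def count(self) -> int:
        return len(self.patterns)

    def taxa_for(self, pattern: str) -> frozenset:
        return frozenset(self.patterns.get(pattern, ()))

    def as_dict(self) -> dict:
        return {p: sorted(t) for p, t in sorted(self.patterns.items())}


def canonical_pattern(event: RearrangementEvent) -> str:
    """Orientation-normalized spelling of an event's derived core."""
    _, core_d = _strip_flanks(event.ancestral_cluster, event.derived_cluster)
    core_d = tuple(t for t in core_d if unsigned(t) != "CR")
    fwd = "-".join(_signed_str(t) for t in core_d)
    rev = "-".join(_signed_str(negate(t)) for t in reversed(core_d))
    return min(fwd, rev)


def catalog_patterns(
    orders: Iterable[GeneOrder], reference: GeneOrder
) -> PatternCatalog:
    """Union of canonical derived-cluster patterns across taxa."""
    catalog = PatternCatalog()
    for order in orders:
        for event in diff_against(order, reference):
            pattern = canonical_pattern(event)
            if pattern:
                catalog.patterns.setdefault(pattern, set()).add(order.taxon)
    return catalog


# ---------------------------------------------------------------------------
# Gene-order text format: one taxon per line, "taxon<TAB>tok,tok,..."
# ---------------------------------------------------------------------------

def write_orders(orders: Iterable[GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orders:
            fh.write(f"{o.taxon}\t{','.join(o.order)}\n")


def read_orders(path: str | Path, circular: bool = True) -> list[GeneOrder]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                taxon, tokens = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>tokens'") from exc
            out.append(
                GeneOrder(taxon, tuple(t.strip() for t in tokens.split(",") if t.strip()),
                          circular)
            )
    return out
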
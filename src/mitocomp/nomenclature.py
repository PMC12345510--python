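"""Canonical mitochondrial gene nomenclature and name normalization.

Insect mitogenomes carry 37 genes — 13 protein-coding genes (PCGs), 22
tRNAs, 2 rRNAs — plus the control region (CR).  Annotation sources spell
these many ways (``COI`` vs ``COX1``, ``l-rRNA`` vs ``rrnL``, ``D-loop``
vs ``control region``); this module maps every spelling we recognize onto
one canonical token per gene.  The mapping is table-driven: anything not
in the table comes back as :data:`UNKNOWN`, never as a guess.

The two leucine and two serine tRNAs are distinguished by anticodon
class: trnL1 reads CUN codons (anticodon UAG), trnL2 reads UUR (UAA);
trnS1 reads AGN (GCU/UCU), trnS2 reads UCN (UGA).
"""

from __future__ import annotations

import re

#: Sentinel returned for names that cannot be normalized.
UNKNOWN = "unknown"

PCG_TOKENS = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

TRNA_TOKENS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnE", "trnQ", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNA_TOKENS = ("rrnL", "rrnS")

CR_TOKEN = "CR"

#: All 37 gene tokens plus the control region.
CANONICAL_TOKENS = PCG_TOKENS + TRNA_TOKENS + RRNA_TOKENS + (CR_TOKEN,)

#: token -> feature category
CATEGORY = {
    **{t: "PCG" for t in PCG_TOKENS},
    **{t: "tRNA" for t in TRNA_TOKENS},
    **{t: "rRNA" for t in RRNA_TOKENS},
    CR_TOKEN: "CR",
}

# Three-letter amino-acid name -> one-letter code used in tRNA tokens.
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "glu": "E", "gln": "Q", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Anticodon (RNA or DNA spelling, lowercase) -> isoacceptor number for the
# ambiguous Leu/Ser tRNAs.  trnL1 = CUN codon family (anticodon UAG),
# trnL2 = UUR (UAA); trnS1 = AGN (GCU or, rarely, UCU), trnS2 = UCN (UGA).
_LEU_ANTICODON = {"uag": "1", "tag": "1", "uaa": "2", "taa": "2"}
_SER_ANTICODON = {"gcu": "1", "gct": "1", "ucu": "1", "tct": "1",
                  "uga": "2", "tga": "2"}
# Codon-class qualifiers seen in product strings, e.g. "tRNA-Leu(UUR)".
_LEU_CLASS = {"cun": "1", "uur": "2", "ttr": "2"}
_SER_CLASS = {"agn": "1", "agy": "1", "ucn": "2", "tcn": "2"}

# Direct synonym table (lowercase, punctuation collapsed) -> canonical token.
_SYNONYMS: dict[str, str] = {
    # protein-coding genes
    "cox1": "COX1", "coi": "COX1", "co1": "COX1", "coxi": "COX1",
    "cytochrome c oxidase subunit 1": "COX1",
    "cytochrome c oxidase subunit i": "COX1",
    "cox2": "COX2", "coii": "COX2", "co2": "COX2", "coxii": "COX2",
    "cytochrome c oxidase subunit 2": "COX2",
    "cytochrome c oxidase subunit ii": "COX2",
    "cox3": "COX3", "coiii": "COX3", "co3": "COX3", "coxiii": "COX3",
    "cytochrome c oxidase subunit 3": "COX3",
    "cytochrome c oxidase subunit iii": "COX3",
    "atp6": "ATP6", "atpase6": "ATP6", "atpase subunit 6": "ATP6",
    "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atpase subunit 8": "ATP8",
    "atp synthase f0 subunit 8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cytochrome b": "CYTB",
    "nd1": "ND1", "nad1": "ND1", "nadh1": "ND1",
    "nadh dehydrogenase subunit 1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh2": "ND2",
    "nadh dehydrogenase subunit 2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh3": "ND3",
    "nadh dehydrogenase subunit 3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh4": "ND4",
    "nadh dehydrogenase subunit 4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L",
    "nadh dehydrogenase subunit 4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh5": "ND5",
    "nadh dehydrogenase subunit 5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh6": "ND6",
    "nadh dehydrogenase subunit 6": "ND6",
    # rRNAs
    "rrnl": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL", "16s": "rrnL",
    "16s rrna": "rrnL", "16s ribosomal rna": "rrnL",
    "large subunit ribosomal rna": "rrnL",
    "rrns": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS", "12s": "rrnS",
    "12s rrna": "rrnS", "12s ribosomal rna": "rrnS",
    "small subunit ribosomal rna": "rrnS",
    # control region
    "cr": "CR", "d-loop": "CR", "dloop": "CR", "control region": "CR",
    "at-rich region": "CR", "a+t-rich region": "CR",
    "putative control region": "CR", "misc control region": "CR",
}
# trnX / trnL1-style tokens map to themselves.
_SYNONYMS.update({t.lower(): t for t in CANONICAL_TOKENS})


def _clean(raw: str) -> str:
    s = raw.strip().lower()
    s = s.replace("_", " ").replace("–", "-").replace("−", "-")
    s = re.sub(r"\s+", " ", s)
    return s


def _trna_token(aa1: str, qualifier: str | None) -> str:
    """Resolve a one-letter tRNA amino acid + optional anticodon/class."""
    if aa1 not in "LS":
        return "trn" + aa1
    table = _LEU_ANTICODON if aa1 == "L" else _SER_ANTICODON
    classes = _LEU_CLASS if aa1 == "L" else _SER_CLASS
    if qualifier:
        q = qualifier.strip().lower()
        if q in table:
            return f"trn{aa1}{table[q]}"
        if q in classes:
            return f"trn{aa1}{classes[q]}"
        if q in ("1", "2"):
            return f"trn{aa1}{q}"
    return UNKNOWN  # ambiguous Leu/Ser without an anticodon: never guess


def normalize_gene_name(raw: str, anticodon: str | None = None) -> str:
    """Map a raw gene name onto its canonical token.

    Parameters
    ----------
    raw
        The name as found in an annotation (``gene``/``product`` qualifier,
        TSV column, ...).  Case-insensitive.
    anticodon
        Optional anticodon triplet (e.g. ``"taa"``) used to disambiguate
        the Leu/Ser tRNAs when the name itself does not carry a codon
        class.

    Returns
    -------
    str
        A token from :data:`CANONICAL_TOKENS`, or :data:`UNKNOWN`.
    """
    if not raw or not raw.strip():
        return UNKNOWN
    s = _clean(raw)

    if s in _SYNONYMS:
        tok = _SYNONYMS[s]
        if tok in ("trnL1", "trnL2", "trnS1", "trnS2") or not tok.startswith("trn"):
            return tok
        return tok

    # tRNA spellings: "trna-leu(taa)", "trn l", "trnl(uur)", "trna-ser" ...
    m = re.fullmatch(
        r"(?:trna[- ]?|trn ?)"
        r"(?:(?P<aa3>[a-z]{3})|(?P<aa1>[a-z]))"
        r"(?: ?\((?P<qual>[a-z0-9]{1,3})\))?",
        s,
    )
    if m:
        aa3, aa1, qual = m.group("aa3"), m.group("aa1"), m.group("qual")
        if aa3:
            if aa3 not in _AA3_TO_1:
                return UNKNOWN
            letter = _AA3_TO_1[aa3]
        else:
            letter = aa1.upper()
            if "trn" + letter not in TRNA_TOKENS and letter not in "LS":
                return UNKNOWN
        return _trna_token(letter, qual or anticodon)

    return UNKNOWN


def category_of(token: str) -> str | None:
    """Return the feature category (PCG/tRNA/rRNA/CR) of a canonical token."""
    return CATEGORY.get(token)
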
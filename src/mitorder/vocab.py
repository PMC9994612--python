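"""Closed gene vocabulary for metazoan (crab-like) mitogenomes.

The 38 markers are the 13 protein-coding genes, 22 tRNAs (with the two
leucine and two serine isoacceptors disambiguated as trnL1/trnL2 and
trnS1/trnS2), the two rRNAs and the control region.  Unknown symbols fail
fast so that typos never reach the gene-order algebra.
"""

from __future__ import annotations

PCGS: tuple[str, ...] = (
    "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cob", "atp6", "atp8",
)

TRNAS: tuple[str, ...] = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)

RRNAS: tuple[str, ...] = ("rrnS", "rrnL")

CONTROL_REGION = "CR"

ALL_GENES: tuple[str, ...] = PCGS + TRNAS + RRNAS + (CONTROL_REGION,)

#: categories used throughout reports
CATEGORY = {g: "PCG" for g in PCGS}
CATEGORY.update({g: "tRNA" for g in TRNAS})
CATEGORY.update({g: "rRNA" for g in RRNAS})
CATEGORY[CONTROL_REGION] = "CR"

# Synonyms seen in GenBank files and published tables.  Keys are lower-case.
_SYNONYMS = {
    "12s": "rrnS", "rrn12": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS",
    "12s rrna": "rrnS", "rrns": "rrnS",
    "16s": "rrnL", "rrn16": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL",
    "16s rrna": "rrnL", "rrnl": "rrnL",
    "d-loop": "CR", "dloop": "CR", "control region": "CR", "cr": "CR",
    "at-rich region": "CR",
    "co1": "cox1", "coi": "cox1", "cox i": "cox1",
    "co2": "cox2", "coii": "cox2",
    "co3": "cox3", "coiii": "cox3",
    "cytb": "cob", "cob": "cob", "cytochrome b": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "atp 6": "atp6", "atpase6": "atp6", "atp 8": "atp8", "atpase8": "atp8",
}
_SYNONYMS.update({g.lower(): g for g in ALL_GENES})


class UnknownGeneError(ValueError):
    """Raised for symbols outside the closed 38-gene vocabulary."""

    def __init__(self, name: str):
        super().__init__(
            f"unknown gene symbol {name!r}; accepted symbols: "
            + ", ".join(ALL_GENES)
        )
        self.name = name


def normalize_gene(name: str) -> str:
    """Map a gene symbol or common synonym onto the canonical vocabulary.

    Idempotent: normalize_gene(normalize_gene(x)) == normalize_gene(x).
    """
    key = name.strip().lower()
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise UnknownGeneError(name) from None


def category_of(name: str) -> str:
    return CATEGORY[normalize_gene(name)]
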
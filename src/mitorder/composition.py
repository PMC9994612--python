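"""Base composition, strand skews, codon usage and RSCU.

Strand asymmetry is summarized by the classical skew statistics

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed over whole genomes or partitions (all protein-coding genes
concatenated, single genes, the tRNA/rRNA sets, the control region).
Codon statistics use the invertebrate mitochondrial genetic code
(translation table 5) by default, and relative synonymous codon usage
(RSCU) is computed over merged synonymous families (the two leucine and
two serine isoacceptor families are not split), so

    RSCU_i = count_i * k / N

for a codon *i* in a family of *k* synonymous codons with family total
*N*; values within a family sum to *k*.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .model_io import GeneRecord, MitogenomeAnnotation

IUPAC = set("ACGTURYSWKMBDHVN")

DEFAULT_TABLE = 5  # invertebrate mitochondrial


def skew(plus: float, minus: float) -> Optional[float]:
    """(plus - minus)/(plus + minus); None when the denominator is zero.

    Scale-invariant, so percentages, fractions and raw counts all work.
    """
    total = plus + minus
    if total == 0:
        return None
    return (plus - minus) / total


@dataclass(frozen=True)
class CompositionProfile:
    """A/T/G/C bookkeeping for one sequence partition."""

    length: int
    A: int
    T: int
    G: int
    C: int

    @property
    def ambiguous(self) -> int:
        return self.length - (self.A + self.T + self.G + self.C)

    @property
    def a(self) -> float:
        return self.A / self.length

    @property
    def t(self) -> float:
        return self.T / self.length

    @property
    def g(self) -> float:
        return self.G / self.length

    @property
    def c(self) -> float:
        return self.C / self.length

    @property
    def at_content(self) -> float:
        return (self.A + self.T) / self.length

    @property
    def gc_content(self) -> float:
        return (self.G + self.C) / self.length

    @property
    def at_skew(self) -> Optional[float]:
        return skew(self.A, self.T)

    @property
    def gc_skew(self) -> Optional[float]:
        return skew(self.G, self.C)

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.length + other.length, self.A + other.A, self.T + other.T,
            self.G + other.G, self.C + other.C)


def base_composition(seq: str) -> CompositionProfile:
    """Exact base counts and skews of one nucleotide sequence.

    Ambiguity codes (N, R, Y, ...) count toward the length but not toward
    the A/T/G/C tallies.  U is counted as T.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    bad = next((i for i, ch in enumerate(s) if ch not in IUPAC), None)
    if bad is not None:
        raise ValueError(f"non-IUPAC character {s[bad]!r} at position {bad + 1}")
    return CompositionProfile(
        length=len(s), A=s.count("A"), T=s.count("T") + s.count("U"),
        G=s.count("G"), C=s.count("C"))


def partition_stats(ann: MitogenomeAnnotation,
                    partitions: Iterable[str] = ("genome", "PCG", "tRNA", "rRNA", "CR"),
                    per_gene_pcgs: bool = True,
                    strand_aware: bool = False) -> dict[str, CompositionProfile]:
    """Composition profiles for selected partitions of an annotated genome.

    Selectors are ``genome``, a category (``PCG``/``tRNA``/``rRNA``/``CR``,
    profiling the concatenation of its members) or a gene name.  With
    ``strand_aware`` minus-strand features are reverse-complemented before
    profiling; the default profiles genome-strand slices, which is how
    published per-gene tables are laid out (minus-strand genes then show
    sign-flipped skews).
    """
    if ann.sequence is None:
        raise ValueError("annotation carries no sequence")
    out: dict[str, CompositionProfile] = {}
    selectors = list(partitions)
    if per_gene_pcgs:
        pcgs = [r.name for r in ann.records if r.category == "PCG"]
        at = selectors.index("PCG") + 1 if "PCG" in selectors else len(selectors)
        selectors = selectors[:at] + pcgs + selectors[at:]
    for sel in selectors:
        if sel == "genome":
            out[sel] = base_composition(ann.sequence)
            continue
        if sel in ("PCG", "tRNA", "rRNA", "CR"):
            members = [r for r in ann.records if r.category == sel]
        else:
            members = [ann.record(sel)]
        if not members:
            raise ValueError(f"selector {sel!r} matches no record")
        prof = None
        for r in members:
            p = base_composition(ann.extract(r, strand_aware=strand_aware))
            prof = p if prof is None else prof + p
        out[sel] = prof
    return out


def composition_report(profiles: dict[str, CompositionProfile],
                       taxon: str = "") -> pd.DataFrame:
    """Tabulate profiles with the usual columns (sizes in bp, percentages,
    skews); one row per partition."""
    rows = []
    for name, p in profiles.items():
        rows.append({
            "taxon": taxon, "partition": name, "size_bp": p.length,
            "A%": 100 * p.a, "T%": 100 * p.t, "G%": 100 * p.g, "C%": 100 * p.c,
            "AT%": 100 * p.at_content, "GC%": 100 * p.gc_content,
            "AT_skew": p.at_skew if p.at_skew is not None else math.nan,
            "GC_skew": p.gc_skew if p.gc_skew is not None else math.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon usage


def _code(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def sense_codons(table_id: int = DEFAULT_TABLE) -> list[str]:
    return sorted(_code(table_id).forward_table)


def _to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Counts, per-amino-acid totals and RSCU over the sense codons."""

    table_id: int = DEFAULT_TABLE
    counts: dict[str, int] = field(default_factory=dict)  # DNA codons
    warnings: list[str] = field(default_factory=list)
    rscu: dict[str, float] = field(default_factory=dict)
    zero_families: list[str] = field(default_factory=list)

    def __post_init__(self):
        for c in sense_codons(self.table_id):
            self.counts.setdefault(c, 0)

    def amino_acid(self, codon: str) -> str:
        return _code(self.table_id).forward_table[codon]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for c in sense_codons(self.table_id):
            fams.setdefault(self.amino_acid(c), []).append(c)
        return fams

    def aa_totals(self) -> dict[str, int]:
        return {aa: sum(self.counts[c] for c in fam)
                for aa, fam in self.families().items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"codon": _to_rna(c), "amino_acid": self.amino_acid(c),
                 "count": self.counts[c], "RSCU": self.rscu.get(c, math.nan)}
                for c in sense_codons(self.table_id)]
        return pd.DataFrame(rows)


def codon_usage(cds_set: Iterable[str], table_id: int = DEFAULT_TABLE) -> CodonUsageTable:
    """Tally sense codons over a set of in-frame coding sequences.

    Stop codons are excluded from the counts (an internal stop is recorded
    as a warning and counting continues); a truncated final codon of 1-2 nt
    is ignored.
    """
    cds_list = [s.upper().replace("U", "T") for s in cds_set]
    if not cds_list:
        raise ValueError("empty CDS set")
    code = _code(table_id)
    table = CodonUsageTable(table_id=table_id)
    for k, s in enumerate(cds_list):
        if len(s) < 3:
            raise ValueError(f"CDS #{k + 1} shorter than one codon")
        n_codons = len(s) // 3
        for i in range(n_codons):
            codon = s[3 * i:3 * i + 3]
            if codon in code.stop_codons:
                if i < n_codons - 1:
                    table.warnings.append(
                        f"CDS #{k + 1}: internal stop {codon} at codon {i + 1}")
                continue
            if codon not in code.forward_table:
                table.warnings.append(
                    f"CDS #{k + 1}: ambiguous codon {codon} at codon {i + 1} skipped")
                continue
            table.counts[codon] += 1
    return table


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill in RSCU values: count * family_size / family_total per codon.

    Families with zero total get RSCU 0 for every member and are flagged
    in ``zero_families``.
    """
    totals = table.aa_totals()
    table.zero_families = []
    for aa, fam in table.families().items():
        n = totals[aa]
        if n == 0:
            table.zero_families.append(aa)
            for c in fam:
                table.rscu[c] = 0.0
            continue
        k = len(fam)
        for c in fam:
            table.rscu[c] = table.counts[c] * k / n
    return table


# ---------------------------------------------------------------------------
# start / stop codon classification

CANONICAL_STARTS = ("ATG", "ATT", "ATA", "ATC")


@dataclass(frozen=True)
class CodonCall:
    start_codon: str
    stop_codon: str   # complete triplet, or truncated "T--" / "TA-"
    complete: bool
    start_canonical: bool


def classify_codons(record: GeneRecord, ann: MitogenomeAnnotation,
                    table_id: int = DEFAULT_TABLE) -> CodonCall:
    """Read start/stop codons of a protein-coding gene off the sequence.

    The coding strand is extracted (reverse-complemented for minus-strand
    genes).  A coding length that is not a codon multiple yields the
    truncated stop rendering ``T--`` (one trailing nt) or ``TA-`` (two),
    with the completeness flag false — such stops are completed to UAA by
    post-transcriptional polyadenylation in vivo.
    """
    if record.category != "PCG":
        raise ValueError(f"{record.name} is not a protein-coding gene")
    cds = ann.extract(record, strand_aware=True)
    if len(cds) < 6:
        raise ValueError(f"{record.name}: coding length {len(cds)} < 6")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        stop_trip = cds[-3:]
        complete = stop_trip in _code(table_id).stop_codons
        stop = stop_trip
        if not complete:
            warnings.warn(f"{record.name}: final triplet {stop_trip} is not a stop codon")
    elif rem == 1:
        stop = cds[-1] + "--"
        complete = False
    else:
        stop = cds[-2:] + "-"
        complete = False
    return CodonCall(start_codon=start, stop_codon=stop, complete=complete,
                     start_canonical=start in CANONICAL_STARTS)


def extract_cds_set(ann: MitogenomeAnnotation) -> list[str]:
    """Strand-correct coding sequences of all PCGs, in genome order."""
    return [ann.extract(r, strand_aware=True)
            for r in ann.records if r.category == "PCG"]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
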
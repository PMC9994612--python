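"""Domain types and readers/writers for annotated mitogenomes.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome annotation tables.  Genomes are circular by default;
the origin lies between position ``genome_length`` and position 1, and a
feature may wrap the origin (``end < start``).

Formats handled here:

* a TSV annotation dialect (columns ``gene, start, end, strand,
  start_codon, stop_codon`` and optionally ``length`` for a stated length,
  preceded by a ``#taxon=... length=... circular=...`` header line);
* GenBank flat files (via Biopython; feature keys CDS/tRNA/rRNA/D-loop);
* FASTA genome sequences (via Biopython);
* signed gene-order lines (``taxon<TAB>cox1,trnL2,...,-trnH,...``).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .vocab import CATEGORY, UnknownGeneError, category_of, normalize_gene

_STRAND_IN = {
    "F": "+", "R": "-", "+": "+", "-": "-", "−": "-",
    ".": None, "": None, "–": None, "/": None,
}
_STRAND_OUT = {"+": "F", "-": "R", None: "."}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated feature on a circular mitochondrial genome."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive; end < start means the feature wraps the origin
    strand: Optional[str] = "+"  # "+", "-", or None (control region)
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    stated_length: Optional[int] = None  # length as printed in a source table

    def __post_init__(self):
        object.__setattr__(self, "name", normalize_gene(self.name))
        if self.strand not in ("+", "-", None):
            object.__setattr__(self, "strand", _STRAND_IN[self.strand])

    @property
    def category(self) -> str:
        return CATEGORY[self.name]


@dataclass
class MitogenomeAnnotation:
    """An ordered set of GeneRecords with genome length and optional sequence."""

    taxon: str
    genome_length: int
    records: list[GeneRecord] = field(default_factory=list)
    circular: bool = True
    sequence: Optional[str] = None

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: r.start)
        names = [r.name for r in self.records]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate gene name(s): {sorted(dupes)}")
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != genome_length "
                f"{self.genome_length}"
            )

    def record(self, name: str) -> GeneRecord:
        name = normalize_gene(name)
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def extract(self, rec: GeneRecord, strand_aware: bool = True) -> str:
        """Genome subsequence of a record; reverse-complemented for − strand
        features when ``strand_aware``.  Handles origin wrap."""
        if self.sequence is None:
            raise ValueError("annotation carries no sequence")
        s = self.sequence
        if rec.end >= rec.start:
            sub = s[rec.start - 1:rec.end]
        else:
            if not self.circular:
                raise ValueError(f"{rec.name}: wrap-around record on linear genome")
            sub = s[rec.start - 1:] + s[:rec.end]
        if strand_aware and rec.strand == "-":
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclass(frozen=True)
class ValidationIssue:
    record: str
    kind: str  # length-mismatch | unknown-gene | out-of-range | codon-anomaly
    detail: str


def gene_length(rec: GeneRecord, genome_length: int, circular: bool = True) -> int:
    """Number of circular positions a record covers (1-based inclusive ends)."""
    if rec.end >= rec.start:
        return rec.end - rec.start + 1
    if not circular:
        raise ValueError(f"{rec.name}: wrap-around coordinates on a linear genome")
    return genome_length - rec.start + 1 + rec.end


def validate_annotation(ann: MitogenomeAnnotation) -> list[ValidationIssue]:
    """Report (never raise) internal inconsistencies of an annotation.

    Flags stated-vs-coordinate length mismatches, out-of-range coordinates,
    and protein-coding genes whose coordinate length is not a codon multiple
    yet carry no truncated stop codon.
    """
    issues: list[ValidationIssue] = []
    for r in ann.records:
        if not (1 <= r.start <= ann.genome_length and 1 <= r.end <= ann.genome_length):
            issues.append(ValidationIssue(
                r.name, "out-of-range",
                f"coordinates {r.start}-{r.end} outside 1..{ann.genome_length}"))
            continue
        length = gene_length(r, ann.genome_length, ann.circular)
        if r.stated_length is not None and r.stated_length != length:
            issues.append(ValidationIssue(
                r.name, "length-mismatch",
                f"stated length {r.stated_length} but coordinates give {length}"))
        if r.category == "PCG":
            rem = length % 3
            truncated = (r.stop_codon or "").replace("‐", "-") in ("T--", "TA-", "T", "TA")
            if rem != 0 and not truncated:
                issues.append(ValidationIssue(
                    r.name, "codon-anomaly",
                    f"coding length {length} is not a codon multiple and the "
                    f"stop codon {r.stop_codon!r} is not truncated"))
    return issues


# ---------------------------------------------------------------------------
# TSV annotation dialect


def read_annotation_table(path: str | os.PathLike | io.TextIOBase) -> MitogenomeAnnotation:
    """Read the TSV annotation dialect (see module docstring).

    Gene names are normalized through the synonym map; duplicate or unknown
    symbols are hard errors.  Records come back sorted by start.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
        name = os.fspath(path)

    taxon, glen, circular = None, None, True
    rows: list[str] = []
    header: Optional[list[str]] = None
    for ln in lines:
        ln = ln.rstrip("\n")
        if not ln.strip():
            continue
        if ln.startswith("#"):
            for tok in ln.lstrip("#").split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    if k == "taxon":
                        taxon = v
                    elif k == "length":
                        glen = int(v.replace(",", ""))
                    elif k == "circular":
                        circular = v.lower() in ("true", "1", "yes")
            continue
        if header is None:
            header = [c.strip().lower() for c in ln.split("\t")]
            continue
        rows.append(ln)
    if header is None or not rows:
        raise ValueError(f"{name}: no records")
    idx = {c: i for i, c in enumerate(header)}
    for required in ("gene", "start", "end"):
        if required not in idx:
            raise ValueError(f"{name}: missing required column {required!r}")

    def cell(parts, col):
        i = idx.get(col)
        if i is None or i >= len(parts):
            return ""
        return parts[i].strip()

    records = []
    for ln in rows:
        parts = ln.split("\t")
        records.append(GeneRecord(
            name=cell(parts, "gene"),
            start=int(cell(parts, "start")),
            end=int(cell(parts, "end")),
            strand=_STRAND_IN[cell(parts, "strand") or "."],
            start_codon=cell(parts, "start_codon") or None,
            stop_codon=cell(parts, "stop_codon") or None,
            stated_length=int(cell(parts, "length")) if cell(parts, "length") else None,
        ))
    if glen is None:
        glen = max(max(r.start, r.end) for r in records)
    return MitogenomeAnnotation(
        taxon=taxon or os.path.splitext(os.path.basename(str(name)))[0],
        genome_length=glen, records=records, circular=circular)


def write_annotation_table(ann: MitogenomeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"#taxon={ann.taxon} length={ann.genome_length} "
                 f"circular={'true' if ann.circular else 'false'}\n")
        fh.write("gene\tstart\tend\tlength\tstrand\tstart_codon\tstop_codon\n")
        for r in ann.records:
            stated = r.stated_length
            if stated is None:
                stated = gene_length(r, ann.genome_length, ann.circular)
            fh.write("\t".join([
                r.name, str(r.start), str(r.end), str(stated),
                _STRAND_OUT[r.strand], r.start_codon or "", r.stop_codon or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# GenBank / FASTA

_GB_KEYS = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
_KEY_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                 "D-loop": "CR", "D_loop": "CR", "misc_feature": None}


def read_genbank(path: str | os.PathLike) -> MitogenomeAnnotation:
    """Read a GenBank flat file into an annotation.

    Feature keys CDS/tRNA/rRNA/D-loop map to categories; ``join`` locations
    spanning the origin become wrap-around records.  Wrap-around on a genome
    whose LOCUS line declares linear topology is rejected.
    """
    seqrec = SeqIO.read(os.fspath(path), "genbank")
    circular = seqrec.annotations.get("topology", "circular") == "circular"
    glen = len(seqrec.seq)
    records = []
    for feat in seqrec.features:
        cat = _KEY_CATEGORY.get(feat.type)
        if cat is None:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [None])[0]
        if raw is None:
            raise ValueError(f"feature {feat.type} at {feat.location} lacks a gene name")
        name = normalize_gene(raw)
        loc = feat.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            if len(parts) != 2 or not (int(parts[-1].end) == glen and int(parts[0].start) == 0):
                raise ValueError(f"unparseable location for feature {name}: {loc}")
            if not circular:
                raise ValueError(
                    f"{name}: origin-spanning location on a linear genome")
            start, end = int(parts[1].start) + 1, int(parts[0].end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        strand = {1: "+", -1: "-", None: None}[loc.strand]
        if cat == "CR":
            strand = None
        records.append(GeneRecord(
            name=name, start=start, end=end, strand=strand,
            start_codon=(quals.get("codon_start_triplet") or [None])[0],
            stop_codon=(quals.get("stop_codon_triplet") or [None])[0],
        ))
    if not records:
        raise ValueError(f"{path}: no gene features found (missing FEATURES?)")
    seq = str(seqrec.seq)
    if set(seq) <= {"N"}:
        seq = None  # placeholder sequence only
    return MitogenomeAnnotation(
        taxon=seqrec.annotations.get("organism", seqrec.id) or seqrec.id,
        genome_length=glen, records=records, circular=circular, sequence=seq)


def write_genbank(ann: MitogenomeAnnotation, path: str | os.PathLike) -> None:
    seq = Seq(ann.sequence if ann.sequence is not None else "N" * ann.genome_length)
    locus = ann.taxon.replace(" ", "_")[:16] or "mitogenome"
    seqrec = SeqRecord(seq, id=locus, name=locus,
                       description=f"{ann.taxon} mitochondrial genome")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if ann.circular else "linear"
    seqrec.annotations["organism"] = ann.taxon
    seqrec.annotations["date"] = "01-JAN-2000"  # fixed: outputs reproducible
    for r in ann.records:
        strand = {"+": 1, "-": -1, None: None}[r.strand]
        if r.end >= r.start:
            loc = SimpleLocation(r.start - 1, r.end, strand)
        else:
            loc = CompoundLocation([
                SimpleLocation(r.start - 1, ann.genome_length, strand),
                SimpleLocation(0, r.end, strand),
            ])
        quals = {"gene": [r.name]}
        if r.start_codon:
            quals["codon_start_triplet"] = [r.start_codon]
        if r.stop_codon:
            quals["stop_codon_triplet"] = [r.stop_codon]
        seqrec.features.append(SeqFeature(loc, type=_GB_KEYS[r.category], qualifiers=quals))
    SeqIO.write([seqrec], os.fspath(path), "genbank")


def read_fasta(path: str | os.PathLike) -> tuple[str, str]:
    rec = SeqIO.read(os.fspath(path), "fasta")
    return rec.id, str(rec.seq).upper()


def write_fasta(taxon: str, sequence: str, path: str | os.PathLike) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=taxon.replace(" ", "_"),
                           description="")], os.fspath(path), "fasta")


# ---------------------------------------------------------------------------
# signed gene-order lines


def parse_order_token(tok: str) -> tuple[str, int]:
    tok = tok.strip()
    sign = 1
    if tok.startswith("-") or tok.startswith("−"):
        sign, tok = -1, tok[1:]
    elif tok.startswith("+"):
        tok = tok[1:]
    return normalize_gene(tok), sign


def format_order_token(gene: str, sign: int) -> str:
    return gene if sign > 0 else f"-{gene}"


def read_gene_orders(path: str | os.PathLike | io.TextIOBase):
    """Yield ``(taxon, [(gene, sign), ...])`` from a gene-order file."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    out = []
    for ln in lines:
        if not ln.strip() or ln.startswith("#"):
            continue
        taxon, _, rest = ln.partition("\t")
        if not rest:
            raise ValueError(f"malformed gene-order line: {ln!r}")
        out.append((taxon.strip(), [parse_order_token(t) for t in rest.split(",")]))
    return out


def write_gene_orders(orders: Iterable[tuple[str, list[tuple[str, int]]]],
                      path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for taxon, genes in orders:
            fh.write(taxon + "\t" +
                     ",".join(format_order_token(g, s) for g, s in genes) + "\n")


__all__ = [
    "GeneRecord", "MitogenomeAnnotation", "ValidationIssue",
    "gene_length", "validate_annotation",
    "read_annotation_table", "write_annotation_table",
    "read_genbank", "write_genbank", "read_fasta", "write_fasta",
    "read_gene_orders", "write_gene_orders",
    "parse_order_token", "format_order_token",
    "UnknownGeneError", "category_of", "replace",
]
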
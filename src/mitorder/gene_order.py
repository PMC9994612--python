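"""Signed circular gene orders: extraction, canonical forms, pattern
grouping, breakpoint distance and displaced-block decomposition.

A mitogenome is abstracted as a circular sequence of signed gene symbols
(sign = coding strand).  Two orders describe the same molecule when one is
a rotation of the other, or a reflection with all orientations flipped
(reading the other strand); all comparisons here work modulo that
equivalence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .model_io import MitogenomeAnnotation, format_order_token
from .vocab import normalize_gene

#: one signed symbol: (gene name, +1 | -1)
Signed = tuple[str, int]


def _parse_signed(tokens: Iterable) -> tuple[Signed, ...]:
    # fast path: an already-normalized ((name, sign), ...) tuple, as produced
    # by every operation in this module
    if (type(tokens) is tuple and tokens and type(tokens[0]) is tuple
            and all(type(t) is tuple and len(t) == 2 and type(t[0]) is str
                    and (t[1] == 1 or t[1] == -1) for t in tokens)):
        return tokens
    out = []
    for t in tokens:
        if isinstance(t, str):
            sign = 1
            if t.startswith("-") or t.startswith("−"):
                sign, t = -1, t[1:]
            out.append((normalize_gene(t), sign))
        else:
            g, s = t
            out.append((normalize_gene(g), 1 if s >= 0 else -1))
    return tuple(out)


@dataclass(frozen=True)
class SignedGeneOrder:
    """Circular list of signed gene symbols for one taxon."""

    taxon: str
    genes: tuple[Signed, ...]
    missing: frozenset = frozenset()  # vocabulary genes known to be absent

    def __post_init__(self):
        object.__setattr__(self, "genes", _parse_signed(self.genes))
        names = self.names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene symbols in order")

    def __len__(self) -> int:
        return len(self.genes)

    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def gene_set(self) -> frozenset:
        return frozenset(self.names())

    def restrict(self, keep: Iterable[str]) -> "SignedGeneOrder":
        keep = {normalize_gene(g) for g in keep}
        return replace(self, genes=tuple(g for g in self.genes if g[0] in keep))

    def __str__(self) -> str:
        return ",".join(format_order_token(g, s) for g, s in self.genes)


# ---------------------------------------------------------------------------
# circular equivalence


def rotate(genes: Sequence[Signed], i: int) -> tuple[Signed, ...]:
    i %= len(genes)
    return tuple(genes[i:]) + tuple(genes[:i])


def reflect_flip(genes: Sequence[Signed]) -> tuple[Signed, ...]:
    """Read the circle in the opposite direction on the other strand."""
    return tuple((g, -s) for g, s in reversed(genes))


def generic_canonical(genes: Sequence[Signed]) -> tuple[Signed, ...]:
    """A canonical representative of the rotation/reflection orbit.

    When cox1 is present the order is anchored on it (rotated to lead,
    reflected first if cox1 sits on the minus strand), which is unique in
    O(n); otherwise the lexicographically minimal rotation of the order or
    its reflection is used.
    """
    if not genes:
        return ()
    names = [g for g, _ in genes]
    try:
        i = names.index("cox1")
    except ValueError:
        cands = [rotate(genes, i) for i in range(len(genes))]
        refl = reflect_flip(genes)
        cands += [rotate(refl, i) for i in range(len(genes))]
        return min(cands)
    if genes[i][1] < 0:
        genes = reflect_flip(genes)
        i = len(genes) - 1 - i
    return rotate(genes, i)


def circular_equal(a: Sequence[Signed], b: Sequence[Signed]) -> bool:
    return generic_canonical(a) == generic_canonical(b)


def canonicalize(order: SignedGeneOrder) -> SignedGeneOrder:
    """Anchor the order on cox1: rotated so cox1 comes first, reflected (with
    all signs flipped) first if cox1 sits on the minus strand.  Constant on
    rotation/reflection orbits and idempotent."""
    names = order.names()
    if "cox1" not in names:
        raise ValueError("canonicalize requires cox1 in the order")
    genes = order.genes
    i = names.index("cox1")
    if genes[i][1] < 0:
        genes = reflect_flip(genes)
        i = [g for g, _ in genes].index("cox1")
    return replace(order, genes=rotate(genes, i))


# ---------------------------------------------------------------------------
# the pancrustacean ancestral arrangement

GROUND_PATTERN = SignedGeneOrder(
    taxon="pancrustacean_ground_pattern",
    genes=(
        "cox1", "trnL2", "cox2", "trnK", "trnD", "atp8", "atp6", "cox3",
        "trnG", "nad3", "trnA", "trnR", "trnN", "trnS1", "trnE",
        "-trnF", "-nad5", "-trnH", "-nad4", "-nad4L",
        "trnT", "-trnP", "nad6", "cob", "trnS2",
        "-nad1", "-trnL1", "-rrnL", "-trnV", "-rrnS",
        "CR", "trnI", "-trnQ", "trnM", "nad2", "trnW", "-trnC", "-trnY",
    ),
)

BUILTIN_REFERENCES = {"pancrustacean": GROUND_PATTERN,
                      "ground": GROUND_PATTERN}


def extract_order(ann: MitogenomeAnnotation) -> SignedGeneOrder:
    """Signed gene order of an annotation, symbols in ascending start order.

    The control region (no strand) is kept as a plus-oriented marker.
    """
    from .vocab import ALL_GENES
    genes = tuple((r.name, -1 if r.strand == "-" else 1) for r in ann.records)
    present = {r.name for r in ann.records}
    return SignedGeneOrder(taxon=ann.taxon, genes=genes,
                           missing=frozenset(set(ALL_GENES) - present))


# ---------------------------------------------------------------------------
# breakpoint distance


def adjacency_set(genes: Sequence[Signed]) -> frozenset:
    """Signed circular adjacencies, normalized so that reading either strand
    yields the same set: (x, y) is identified with (-y, -x)."""
    n = len(genes)
    out = set()
    for i in range(n):
        x, y = genes[i], genes[(i + 1) % n]
        mirror = ((y[0], -y[1]), (x[0], -x[1]))
        out.add(min((x, y), mirror))
    return frozenset(out)


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of signed adjacencies of ``a`` absent from ``b`` after
    restriction to the shared gene set.  Symmetric; 0 iff the restricted
    orders are circularly equal."""
    common = a.gene_set() & b.gene_set()
    if not common:
        raise ValueError("orders share no genes")
    ra, rb = a.restrict(common), b.restrict(common)
    if len(ra) == 1:
        return 0
    return len(adjacency_set(ra.genes) - adjacency_set(rb.genes))


# ---------------------------------------------------------------------------
# pattern grouping

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX")


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else f"P{i + 1}"


@dataclass(frozen=True)
class PatternGroup:
    label: str
    members: tuple[str, ...]          # taxa
    canonical: tuple[Signed, ...]     # shared canonical order (restricted)


def cluster_patterns(orders: Sequence[SignedGeneOrder],
                     drop_missing: bool = True) -> list[PatternGroup]:
    """Group orders whose canonical forms coincide.

    With ``drop_missing`` (default) every order is first restricted to the
    genes present in all inputs, so incomplete genomes can join a pattern.
    Groups are labeled with roman numerals by descending size, ties broken
    by canonical-order string; deterministic for a given input set.
    """
    if not orders:
        raise ValueError("no orders given")
    if drop_missing:
        common = frozenset.intersection(*[o.gene_set() for o in orders])
        reduced = [o.restrict(common) for o in orders]
    else:
        reduced = list(orders)
    groups: dict[tuple, list[str]] = {}
    for o in reduced:
        groups.setdefault(generic_canonical(o.genes), []).append(o.taxon)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), str(kv[0])))
    return [PatternGroup(_roman(i), tuple(sorted(taxa)), canon)
            for i, (canon, taxa) in enumerate(ranked)]


def pattern_report(groups: Sequence[PatternGroup]) -> pd.DataFrame:
    return pd.DataFrame([{
        "pattern": g.label,
        "n_members": len(g.members),
        "members": ";".join(g.members),
        "canonical_order": ",".join(format_order_token(n, s) for n, s in g.canonical),
    } for g in groups])


# ---------------------------------------------------------------------------
# displaced-block decomposition


@dataclass(frozen=True)
class Block:
    genes: tuple[Signed, ...]

    def names(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)

    def __str__(self) -> str:
        return "-".join(g for g, _ in self.genes)


@dataclass(frozen=True)
class BlockDecomposition:
    """Minimal set of contiguous blocks whose excision from both orders
    leaves identical circular orders."""

    reference: SignedGeneOrder
    observed: SignedGeneOrder
    shared_blocks: tuple[Block, ...]
    displaced_blocks: tuple[Block, ...]
    budget_exceeded: bool = False

    @property
    def n_displaced(self) -> int:
        return len(self.displaced_blocks)

    def replay(self) -> SignedGeneOrder:
        """Relocate the displaced blocks onto the reference; the result must
        be circularly equal to the observed order."""
        moved = {g for b in self.displaced_blocks for g in b.names()}
        reduced_ref = [g for g in self.reference.genes if g[0] not in moved]
        obs = self.observed.genes
        if not reduced_ref:
            return replace(self.observed, taxon="replayed")
        # align the reduced reference with the observed order (they are
        # circularly equal by construction), then re-insert each displaced
        # block after its observed left neighbour
        reduced_obs = [g for g in obs if g[0] not in moved]
        target = generic_canonical(tuple(reduced_obs))
        aligned = None
        for cand in [tuple(reduced_ref), reflect_flip(reduced_ref)]:
            for i in range(len(cand)):
                if rotate(cand, i) == tuple(reduced_obs):
                    aligned = list(reduced_obs)
                    break
            if aligned:
                break
        if aligned is None:  # not actually equal: replay fails loudly
            raise ValueError("reduced orders are not circularly equal")
        result = list(aligned)
        n_obs = len(obs)
        # insert in observed order so adjacent displaced blocks can anchor
        # on one another
        for blk in sorted(self.displaced_blocks,
                          key=lambda b: obs.index(b.genes[0])):
            first = blk.genes[0]
            i = obs.index(first)
            # nearest preceding observed gene that is already in the result
            j = (i - 1) % n_obs
            while obs[j][0] in moved and obs[j] not in result:
                j = (j - 1) % n_obs
            anchor = obs[j]
            at = result.index(anchor) + 1
            result[at:at] = list(blk.genes)
            moved -= set(blk.names())
        return replace(self.observed, taxon="replayed",
                       genes=tuple(result))


def _segments(reference: SignedGeneOrder, observed: SignedGeneOrder) -> list[tuple[Signed, ...]]:
    """Split the observed circle into maximal runs whose internal adjacencies
    all occur in the reference (common-synteny segments)."""
    obs = observed.genes
    n = len(obs)
    ref_adj = adjacency_set(reference.genes)
    intact = [min((obs[i], obs[(i + 1) % n]),
                  ((obs[(i + 1) % n][0], -obs[(i + 1) % n][1]),
                   (obs[i][0], -obs[i][1]))) in ref_adj
              for i in range(n)]
    if all(intact):
        return [tuple(obs)]
    # start segments right after a broken adjacency
    start = (next(i for i in range(n) if not intact[i]) + 1) % n
    segs, cur = [], []
    for k in range(n):
        i = (start + k) % n
        cur.append(obs[i])
        if not intact[i]:
            segs.append(tuple(cur))
            cur = []
    if cur:
        segs.append(tuple(cur))
    return segs


def _group_runs(items: list[int], m: int) -> list[list[int]]:
    """Group sorted segment indices into circularly consecutive runs."""
    runs, cur = [], []
    for i in items:
        if cur and i == cur[-1] + 1:
            cur.append(i)
        else:
            if cur:
                runs.append(cur)
            cur = [i]
    if cur:
        runs.append(cur)
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == m - 1:
        runs[0] = runs[-1] + runs[0]
        runs.pop()
    return runs


def displaced_blocks(reference: SignedGeneOrder, observed: SignedGeneOrder,
                     max_blocks: int = 4) -> BlockDecomposition:
    """Minimum number of contiguous observed blocks whose excision from both
    orders leaves identical circular orders.

    Candidate blocks are unions of circularly consecutive common-synteny
    segments, which is exact whenever the two orders differ by relocating
    internally intact blocks (the premise of block displacement).  Ties are
    broken by fewest displaced genes, then lexicographically by the first
    block symbol.  If no solution exists within ``max_blocks`` the result
    has ``budget_exceeded=True``.
    """
    common = reference.gene_set() & observed.gene_set()
    if not common:
        raise ValueError("orders share no genes")
    ref, obs = reference.restrict(common), observed.restrict(common)
    segs = _segments(ref, obs)
    m = len(segs)

    if circular_equal(ref.genes, obs.genes):
        return BlockDecomposition(reference, observed,
                                  tuple(Block(s) for s in segs), ())

    # Each common-synteny segment is a contiguous signed run in BOTH orders
    # (its internal adjacencies all occur in the reference), so segments are
    # exactly the candidate displaced blocks; a union across a broken
    # adjacency would not be a run in the reference.  The search chooses the
    # smallest set of segments whose removal makes the residues circularly
    # equal; exhaustive up to max_blocks, greedy (smallest segments first)
    # when the segmentation is too fragmented for subset enumeration.
    best = None  # (n_blocks, n_genes, lex, blocks)

    def residues_equal(chosen: set[int]) -> bool:
        removed = {g for i in chosen for g, _ in segs[i]}
        red_ref = tuple(g for g in ref.genes if g[0] not in removed)
        red_obs = tuple(g for g in obs.genes if g[0] not in removed)
        return bool(red_ref) and circular_equal(red_ref, red_obs)

    if m > 18:
        chosen: set[int] = set()
        for i in sorted(range(m), key=lambda i: (len(segs[i]), i)):
            chosen.add(i)
            if residues_equal(chosen):
                break
        if len(chosen) > max_blocks or not residues_equal(chosen):
            return BlockDecomposition(reference, observed, (), (),
                                      budget_exceeded=True)
        best = (len(chosen), 0, (), tuple(Block(segs[i]) for i in sorted(chosen)))
    else:
        for r in range(1, min(max_blocks, m - 1) + 1):
            for combo in itertools.combinations(range(m), r):
                if not residues_equal(set(combo)):
                    continue
                blocks = tuple(Block(segs[i]) for i in combo)
                removed = sum(len(b.genes) for b in blocks)
                key = (len(blocks), removed,
                       tuple(sorted(str(b) for b in blocks)))
                if best is None or key < best[:3]:
                    best = (*key, blocks)
            if best is not None:
                break
    if best is None:
        return BlockDecomposition(reference, observed, (), (),
                                  budget_exceeded=True)
    blocks = best[3]
    moved = {g for b in blocks for g in b.names()}
    shared = tuple(Block(s) for s in
                   _segments(ref.restrict(common - moved),
                             obs.restrict(common - moved)))
    return BlockDecomposition(reference, observed, shared, blocks)
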
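"""Mechanistic rearrangement events and bounded-depth scenario inference.

Three event kinds act on signed circular gene orders:

* **TDRL** (tandem duplication–random loss): a contiguous block is
  duplicated head-to-tail and one redundant copy of every gene is lost.
  With each gene assigned to the first or the second copy, the surviving
  genes read as (copy-1 keepers, in block order) followed by (copy-2
  keepers, in block order) — an interleaving ("riffle") of two
  order-preserving subsequences.  Orientations never change.
* **inversion**: a contiguous block is reversed and every orientation in
  it flipped.
* **translocation** (synonym: transposition): a contiguous block is
  excised and re-inserted elsewhere, orientations preserved.

Scenario inference searches for minimal event sequences transforming a
source order into a target order.  Single-event reachability is decided
exactly (for spans up to the span cap) from the broken-adjacency
structure of the two orders; multi-event search layers breadth-first
enumeration of successor states on top of that goal test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .gene_order import (Signed, SignedGeneOrder, adjacency_set,
                         circular_equal, generic_canonical, reflect_flip,
                         rotate)
from .vocab import normalize_gene

KINDS = ("tdrl", "inversion", "translocation")
_KIND_ALIASES = {"tdrl": "tdrl", "inversion": "inversion",
                 "translocation": "translocation",
                 "transposition": "translocation"}

DEFAULT_MAX_SPAN = 8  # event span cap; bounds the TDRL assignment blow-up


def _norm_kinds(kinds: Iterable[str]) -> frozenset:
    out = set()
    for k in kinds:
        kk = _KIND_ALIASES.get(k.strip().lower())
        if kk is None:
            raise ValueError(f"unknown event kind {k!r}; choose from "
                             f"{sorted(set(_KIND_ALIASES))}")
        out.add(kk)
    return frozenset(out)


# ---------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class Tdrl:
    span: tuple[str, ...]          # gene names, contiguous in the pre-event order
    keep_first: frozenset          # genes surviving in copy 1; rest survive in copy 2
    kind: str = field(default="tdrl", init=False)

    def __str__(self) -> str:
        return (f"tdrl[{'-'.join(self.span)} | copy1="
                f"{'+'.join(sorted(self.keep_first))}]")


@dataclass(frozen=True)
class Inversion:
    span: tuple[str, ...]
    kind: str = field(default="inversion", init=False)

    def __str__(self) -> str:
        return f"inversion[{'-'.join(self.span)}]"


@dataclass(frozen=True)
class Translocation:
    span: tuple[str, ...]
    after: str                     # re-insert immediately after this gene
    #: orientation of the destination gene in the reading the event was
    #: phrased in; disambiguates "after" for the two readings of the circle
    after_sign: Optional[int] = None
    kind: str = field(default="translocation", init=False)

    def __str__(self) -> str:
        dest = self.after if self.after_sign in (None, 1) else f"-{self.after}"
        return f"translocation[{'-'.join(self.span)} -> after {dest}]"


Event = Tdrl | Inversion | Translocation


def _rehome(order: SignedGeneOrder, genes: tuple[Signed, ...]) -> SignedGeneOrder:
    """Rotate a result so it starts at the same gene as the input order
    (identity events then return identical tuples)."""
    lead = order.genes[0][0]
    names = [g for g, _ in genes]
    return replace(order, genes=rotate(genes, names.index(lead)))


def _locate_span(order: SignedGeneOrder, span: Sequence[str]) -> tuple[tuple[Signed, ...], tuple[Signed, ...]]:
    """Rotate the order so the span leads; returns (span part, rest)."""
    span = tuple(normalize_gene(g) for g in span)
    if not span:
        raise ValueError("empty span")
    names = order.names()
    n = len(names)
    if len(span) > n:
        raise ValueError("span longer than the order")
    try:
        i = names.index(span[0])
    except ValueError:
        raise ValueError(f"span gene {span[0]!r} not in order") from None
    rot = rotate(order.genes, i)
    got = tuple(g for g, _ in rot[:len(span)])
    if got != span:
        raise ValueError(f"span {span} is not contiguous in the order "
                         f"(found {got})")
    return rot[:len(span)], rot[len(span):]


def apply_tdrl(order: SignedGeneOrder, span: Sequence[str],
               keep_first: Iterable[str]) -> SignedGeneOrder:
    """Duplicate the span in tandem and keep ``keep_first`` genes from the
    first copy, all others from the second; orientations unchanged."""
    span_part, rest = _locate_span(order, span)
    keep = {normalize_gene(g) for g in keep_first}
    span_names = {g for g, _ in span_part}
    stray = keep - span_names
    if stray:
        raise ValueError(f"keep-assignment names genes outside the span: "
                         f"{sorted(stray)}")
    copy1 = tuple(g for g in span_part if g[0] in keep)
    copy2 = tuple(g for g in span_part if g[0] not in keep)
    return _rehome(order, copy1 + copy2 + rest)


def apply_inversion(order: SignedGeneOrder, span: Sequence[str]) -> SignedGeneOrder:
    span_part, rest = _locate_span(order, span)
    return _rehome(order, reflect_flip(span_part) + rest)


def apply_translocation(order: SignedGeneOrder, span: Sequence[str],
                        after: str) -> SignedGeneOrder:
    span_part, rest = _locate_span(order, span)
    after = normalize_gene(after)
    if after in {g for g, _ in span_part}:
        raise ValueError(f"destination {after!r} lies inside the moved span")
    rest_names = [g for g, _ in rest]
    if after not in rest_names:
        raise ValueError(f"destination gene {after!r} not in order")
    j = rest_names.index(after) + 1
    return _rehome(order, rest[:j] + span_part + rest[j:])


def apply_event(order: SignedGeneOrder, event: Event) -> SignedGeneOrder:
    """Apply an event; tolerant of the circular reading.

    A span is named in one of the two readings of the circle (forward, or
    reflected = other strand).  If the event does not fit the forward
    reading of ``order`` — the span is not contiguous in the listed order,
    or a translocation's destination gene carries the other orientation —
    it is carried out on the reflected reading and the result reflected
    back: the same physical operation on the same molecule.
    """
    def _dispatch(o: SignedGeneOrder) -> SignedGeneOrder:
        if event.kind == "tdrl":
            return apply_tdrl(o, event.span, event.keep_first)
        if event.kind == "inversion":
            return apply_inversion(o, event.span)
        if event.after_sign is not None:
            sign = dict(o.genes).get(event.after)
            if sign is not None and sign != event.after_sign:
                raise ValueError("destination orientation fits the other reading")
        return apply_translocation(o, event.span, event.after)

    try:
        return _dispatch(order)
    except ValueError:
        reflected = replace(order, genes=reflect_flip(order.genes))
        res = _dispatch(reflected)  # raises with the original diagnostic context
        return replace(res, genes=reflect_flip(res.genes))


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class Scenario:
    """An ordered event list transforming ``source`` into ``result``."""

    source: SignedGeneOrder
    events: tuple[Event, ...]
    result: SignedGeneOrder
    intermediates: tuple[tuple[Signed, ...], ...]  # states after each event
    #: all single events realizing each step (events[i] is the first of these)
    event_choices: tuple[tuple[Event, ...], ...] = ()
    weights: Optional[dict] = None

    @property
    def cost(self) -> float:
        w = self.weights or {}
        return sum(w.get(e.kind, 1.0) for e in self.events)

    def describe(self) -> str:
        lines = [f"source: {self.source}"]
        state = self.source
        for e in self.events:
            state = apply_event(state, e)
            lines.append(f"  {e}  ->  {state}")
        lines.append(f"cost: {self.cost}")
        return "\n".join(lines)


def verify_scenario(scenario: Scenario) -> tuple[bool, str]:
    """Replay the events from the source; True iff the stated result is
    reproduced (as a circular order)."""
    state = scenario.source
    for i, e in enumerate(scenario.events):
        try:
            state = apply_event(state, e)
        except ValueError as err:
            return False, f"event {i + 1} ({e}) is inapplicable: {err}"
    if circular_equal(state.genes, scenario.result.genes):
        return True, "ok"
    return False, (f"replay ends at {state}, not at the stated result "
                   f"{scenario.result}")


# ---------------------------------------------------------------------------
# exact single-event reachability


def _broken(a: tuple[Signed, ...], b_adj: frozenset) -> list[int]:
    """Indices i where the adjacency (a[i], a[i+1]) is absent from b."""
    n = len(a)
    out = []
    for i in range(n):
        x, y = a[i], a[(i + 1) % n]
        if min((x, y), ((y[0], -y[1]), (x[0], -x[1]))) not in b_adj:
            out.append(i)
    return out


def _covering_spans(broken: list[int], n: int, max_span: int):
    """Yield (start, length) spans whose touched adjacencies (start-1 ..
    start+length-1, circular) cover all broken adjacency indices."""
    if not broken:
        return
    cap = min(max_span, n - 1)
    k = len(broken)
    if k > cap + 1:
        return  # no span within the cap can touch every broken adjacency
    # for each choice of leftmost break b_i, the window must run to the
    # circularly previous break; slack allows the window to start earlier
    broken = sorted(broken)
    for i in range(k):
        left = broken[i]
        right = broken[(i - 1) % k]
        w_min = (right - left) % n + 1  # adjacencies the window must hold
        for length in range(max(w_min - 1, 1), cap + 1):
            for off in range(length + 1 - w_min + 1):
                yield (left - off + 1) % n, length


def _signs_of(genes: Sequence[Signed]) -> dict:
    return {g: s for g, s in genes}


def events_between(a: SignedGeneOrder, b: SignedGeneOrder,
                   kinds: Iterable[str] = KINDS,
                   max_span: int = DEFAULT_MAX_SPAN) -> list[Event]:
    """All single events (spans up to ``max_span``) transforming ``a`` into
    ``b``, deduplicated and deterministically ordered.

    Exhaustive within the span cap: candidate spans are derived from the
    broken-adjacency structure, every candidate is applied and checked, and
    for TDRLs every valid copy assignment (riffle cut) is reported.
    """
    kinds = _norm_kinds(kinds)
    if a.gene_set() != b.gene_set():
        raise ValueError("orders have different gene sets")
    n = len(a)
    if n < 2 or circular_equal(a.genes, b.genes):
        return []
    out: set[Event] = set()
    sa = _signs_of(a.genes)
    # reflections of b describe the same molecule, so the orientation-
    # preserving kinds are checked against both readings of b
    broken = _broken(a.genes, adjacency_set(b.genes))  # mirror-normalized
    for b_genes in (b.genes, reflect_flip(b.genes)):
        preserving = _signs_of(b_genes) == sa
        # TDRL and inversion confine their breaks to one span window
        seen_spans = set()
        for start, length in _covering_spans(broken, n, max_span):
            if (start, length) in seen_spans:
                continue
            seen_spans.add((start, length))
            rot = rotate(a.genes, start)
            span_part, rest = rot[:length], rot[length:]
            span_names = [g for g, _ in span_part]
            if "inversion" in kinds and length >= 1:
                cand = reflect_flip(span_part) + rest
                if circular_equal(cand, b_genes):
                    out.add(Inversion(span=tuple(span_names)))
            if preserving and "tdrl" in kinds and length >= 2:
                for ev in _tdrl_events(span_part, rest, b_genes):
                    out.add(ev)
        # a translocation breaks <= 3 adjacencies that cut the circle into
        # arcs; the moved span must be one whole arc
        if preserving and "translocation" in kinds and 2 <= len(broken) <= 3:
            for k in range(len(broken)):
                lo = broken[k]
                hi = broken[(k + 1) % len(broken)]
                length = (hi - lo) % n
                if not (1 <= length <= min(max_span, n - 1)):
                    continue
                rot = rotate(a.genes, (lo + 1) % n)
                span_part, rest = rot[:length], rot[length:]
                ev = _translocation_event(span_part, rest, b_genes)
                if ev is not None:
                    out.add(ev)
    return sorted(out, key=str)


def _tdrl_events(span_part: tuple[Signed, ...], rest: tuple[Signed, ...],
                 b_genes: tuple[Signed, ...]) -> list[Tdrl]:
    """TDRL events on the given span reproducing b (exact riffle check)."""
    length = len(span_part)
    # b must read: permutation of span_part, then rest (as a rotation)
    target = _aligned_window(span_part, rest, b_genes)
    if target is None:
        return []
    pos = {g: i for i, (g, _) in enumerate(span_part)}
    signs = _signs_of(span_part)
    perm = []
    for g, s in target:
        if signs.get(g) != s:
            return []
        perm.append(pos[g])
    events = []
    for cut in range(length + 1):
        first, second = perm[:cut], perm[cut:]
        if all(x < y for x, y in zip(first, first[1:])) and \
           all(x < y for x, y in zip(second, second[1:])):
            if first and second:  # a trivial cut would mean a == b
                events.append(Tdrl(
                    span=tuple(g for g, _ in span_part),
                    keep_first=frozenset(span_part[i][0] for i in first)))
    return events


def _aligned_window(span_part, rest, b_genes) -> Optional[tuple[Signed, ...]]:
    """If b == (window of span genes) + rest as circular orders, return the
    window read off b; else None."""
    n = len(b_genes)
    length = len(span_part)
    if not rest:
        return None
    # rotate b so that the rest-part aligns
    first_rest = rest[0]
    try:
        j = b_genes.index(first_rest)
    except ValueError:
        return None
    rot_b = rotate(b_genes, (j + len(rest)) % n)  # window should lead
    if rot_b[length:] != rest:
        return None
    window = rot_b[:length]
    if {g for g, _ in window} != {g for g, _ in span_part}:
        return None
    return window


def _translocation_event(span_part, rest, b_genes) -> Optional[Translocation]:
    """A translocation moving span_part elsewhere that reproduces b."""
    if not rest:
        return None
    n = len(b_genes)
    length = len(span_part)
    # in b, the span must appear intact (same order and signs) somewhere,
    # and deleting it must leave exactly `rest`
    try:
        j = b_genes.index(span_part[0])
    except ValueError:
        return None
    if rotate(b_genes, j)[:length] != span_part:
        return None
    before = b_genes[(j - 1) % n]
    reduced_b = tuple(g for g in rotate(b_genes, (j + length) % n)
                      if g not in span_part)
    if reduced_b[0] not in rest:
        return None
    if reduced_b != rotate(rest, rest.index(reduced_b[0])):
        return None
    if before in span_part:
        return None
    if before == rest[-1]:
        return None  # destination equals the current position: identity
    return Translocation(span=tuple(g for g, _ in span_part),
                         after=before[0], after_sign=before[1])


# ---------------------------------------------------------------------------
# successor enumeration and bounded-depth search


def successors(order: SignedGeneOrder, kinds: Iterable[str] = KINDS,
               max_span: int = DEFAULT_MAX_SPAN):
    """Yield (event, resulting order) over all events within the span cap.

    Events that reproduce the identical linear reading are skipped; rare
    rotation-equivalent self-loops may still appear and are left to the
    caller's deduplication.
    """
    kinds = _norm_kinds(kinds)
    n = len(order)
    cap = min(max_span, n - 1)
    for start in range(n):
        rot = rotate(order.genes, start)
        for length in range(1, cap + 1):
            span_part, rest = rot[:length], rot[length:]
            span_names = tuple(g for g, _ in span_part)
            if "inversion" in kinds:
                genes = reflect_flip(span_part) + rest
                if genes != rotate(order.genes, start):
                    yield Inversion(span=span_names), replace(order, genes=genes)
            if "tdrl" in kinds and length >= 2:
                rotated = rotate(order.genes, start)
                for bits in range(1, 2 ** length - 1):
                    keep = frozenset(span_names[i] for i in range(length)
                                     if bits >> i & 1)
                    copy1 = tuple(g for g in span_part if g[0] in keep)
                    copy2 = tuple(g for g in span_part if g[0] not in keep)
                    genes = copy1 + copy2 + rest
                    if genes == rotated:
                        continue
                    yield Tdrl(span=span_names, keep_first=keep), \
                        replace(order, genes=genes)
            if "translocation" in kinds and rest:
                for j in range(len(rest) - 1):  # last slot == original one
                    ev = Translocation(span=span_names, after=rest[j][0],
                                       after_sign=rest[j][1])
                    genes = rest[:j + 1] + span_part + rest[j + 1:]
                    yield ev, replace(order, genes=genes)


def infer_scenarios(src: SignedGeneOrder, dst: SignedGeneOrder,
                    max_events: int = 3,
                    kinds: Iterable[str] = KINDS,
                    max_span: int = DEFAULT_MAX_SPAN,
                    weights: Optional[dict] = None) -> list[Scenario]:
    """All minimal-cost scenarios (up to ``max_events`` events, spans up to
    ``max_span``) transforming ``src`` into ``dst``.

    Scenarios are deduplicated by their sequence of intermediate circular
    orders; each step additionally records every single event realizing it
    (``event_choices``).  Results are deterministically ordered.  The search
    is exhaustive over events within the span cap; breadth grows quickly
    with depth, so depths beyond 2 are practical only for small orders.
    """
    if src.gene_set() != dst.gene_set():
        diff = src.gene_set() ^ dst.gene_set()
        raise ValueError(f"orders have different gene sets: {sorted(diff)}")
    kinds = _norm_kinds(kinds)
    if weights:
        weights = {_KIND_ALIASES[k.lower()]: v for k, v in weights.items()}

    if circular_equal(src.genes, dst.genes):
        return [Scenario(source=src, events=(), result=dst,
                         intermediates=(), weights=weights)]

    # chains of canonical states from src, grown one event at a time; each
    # chain remembers the events that generated it so scenarios never depend
    # on re-deriving a step
    src_canon = generic_canonical(src.genes)
    Chain = tuple[tuple[Signed, ...], ...]
    frontier: list[Chain] = [()]
    states: dict[Chain, SignedGeneOrder] = {(): src}
    gen_events: dict[Chain, Event] = {}
    scenarios: list[Scenario] = []
    for depth in range(1, max_events + 1):
        hits: list[tuple[Chain, list[Event]]] = []
        for chain in frontier:
            state = states[chain]
            final = events_between(state, dst, kinds=kinds, max_span=max_span)
            if final:
                hits.append((chain, final))
        if hits:
            for chain, final in hits:
                evs: list[Event] = []
                choices: list[tuple[Event, ...]] = []
                cur = src
                for i, canon in enumerate(chain):
                    step_state = states[chain[:i + 1]]
                    opts = tuple(events_between(cur, step_state, kinds=kinds,
                                                max_span=max_span)) \
                        or (gen_events[chain[:i + 1]],)
                    evs.append(opts[0])
                    choices.append(opts)
                    cur = step_state
                evs.append(final[0])
                choices.append(tuple(final))
                scenarios.append(Scenario(
                    source=src, events=tuple(evs), result=dst,
                    intermediates=chain + (generic_canonical(dst.genes),),
                    event_choices=tuple(choices), weights=weights))
            break
        if depth == max_events:
            break
        # grow chains by one event, deduplicating states per chain prefix
        new_frontier = []
        for chain in frontier:
            state = states[chain]
            seen: set[tuple[Signed, ...]] = set()
            for ev, res in successors(state, kinds=kinds, max_span=max_span):
                canon = generic_canonical(res.genes)
                if canon in seen or canon in chain or canon == src_canon:
                    continue
                seen.add(canon)
                new_chain = chain + (canon,)
                states[new_chain] = replace(res, genes=canon)
                gen_events[new_chain] = ev
                new_frontier.append(new_chain)
        frontier = new_frontier
    scenarios.sort(key=lambda sc: (sc.cost, tuple(str(i) for i in sc.intermediates)))
    if scenarios:
        best = scenarios[0].cost
        scenarios = [sc for sc in scenarios if sc.cost <= best]
    return scenarios
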
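"""Synthetic crab-like mitogenomes with known ground truth.

The generator produces desk-scale inputs carrying exactly the statistical
structure the analysis consumes: a 37/38-feature circular annotation
(13 PCGs, 22 tRNAs, 2 rRNAs, one control region) with realistic per-
category lengths, a strand-asymmetric base composition targeted on the
genome strand, protein-coding genes with proper start/stop codons, and
gene orders produced from the pancrustacean ground pattern by a known,
recorded rearrangement history.

Sequence realism is deliberately minimal — bases are i.i.d. conditioned
on the composition target, and codons are drawn from a weight table —
because the statistics under test use only composition, codons and
coordinates.

All randomness flows from one ``numpy`` generator seeded by the config;
draw order is fixed (history events first, then per-gene lengths in order,
then spacers, then sequence), so identical configs reproduce identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .composition import reverse_complement, sense_codons
from .gene_order import GROUND_PATTERN, SignedGeneOrder
from .model_io import GeneRecord, MitogenomeAnnotation
from .rearrangement import (Event, Inversion, Tdrl, Translocation,
                            apply_event)
from .vocab import CATEGORY

# per-PCG typical lengths (bp) for a freshwater-crab mitogenome
_PCG_LENGTHS = {
    "cox1": 1539, "cox2": 735, "cox3": 792, "nad1": 930, "nad2": 993,
    "nad3": 345, "nad4": 1335, "nad4L": 276, "nad5": 1671, "nad6": 498,
    "cob": 1137, "atp6": 624, "atp8": 159,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate a ~17 kb crab mitogenome."""

    seed: int = 0
    #: rearrangement history length (events applied to the ground pattern)
    events: int = 2
    kind_weights: dict = field(default_factory=lambda: {
        "tdrl": 1.0, "inversion": 1.0, "translocation": 1.0})
    tdrl_span: tuple[int, int] = (2, 6)
    inversion_span: tuple[int, int] = (1, 6)
    translocation_span: tuple[int, int] = (1, 6)
    #: genome-strand target fractions (A, T, G, C); whole-genome values of
    #: an AT-rich, C-over-G biased crab mitogenome
    base_composition: tuple[float, float, float, float] = (0.355, 0.381, 0.090, 0.175)
    trna_range: tuple[int, int] = (60, 75)
    rrnS_range: tuple[int, int] = (800, 850)
    rrnL_range: tuple[int, int] = (1250, 1400)
    cr_range: tuple[int, int] = (700, 1300)
    pcg_length_jitter: int = 30  # +- bp, rounded to codon multiples
    #: positive spacers ~ geometric with this mean
    spacer_mean: float = 35.0
    overlap_prob: float = 0.15
    overlap_max: int = 47
    start_codon_weights: dict = field(default_factory=lambda: {
        "ATG": 0.6, "ATT": 0.25, "ATA": 0.15})
    stop_codon_weights: dict = field(default_factory=lambda: {
        "TAA": 0.75, "TAG": 0.25})
    #: coding-strand codon weights for PCG bodies; None derives weights from
    #: the base-composition target so the genome-strand composition is
    #: homogeneous
    codon_weights: Optional[dict] = None

    def composition(self) -> np.ndarray:
        p = np.asarray(self.base_composition, dtype=float)
        if (p < 0).any() or p.sum() <= 0:
            raise ValueError("invalid base composition")
        return p / p.sum()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# histories


def _sample_event(order: SignedGeneOrder, cfg: SimulationConfig,
                  rng: np.random.Generator) -> Event:
    kinds = sorted(cfg.kind_weights)
    w = np.array([cfg.kind_weights[k] for k in kinds], dtype=float)
    kind = kinds[rng.choice(len(kinds), p=w / w.sum())]
    names = order.names()
    n = len(names)

    def span_names(lo: int, hi: int) -> tuple[str, ...]:
        length = int(rng.integers(lo, min(hi, n - 1) + 1))
        start = int(rng.integers(0, n))
        return tuple(names[(start + k) % n] for k in range(length))

    if kind == "tdrl":
        span = span_names(*cfg.tdrl_span)
        length = len(span)
        bits = int(rng.integers(1, 2 ** length - 1))  # never all-copy1/2
        keep = frozenset(span[i] for i in range(length) if bits >> i & 1)
        return Tdrl(span=span, keep_first=keep)
    if kind == "inversion":
        return Inversion(span=span_names(*cfg.inversion_span))
    span = span_names(*cfg.translocation_span)
    in_span = set(span)
    rest = [g for g in names if g not in in_span]
    # exclude the current predecessor: moving there would be a no-op
    pred = names[(names.index(span[0]) - 1) % n]
    choices = [g for g in rest if g != pred] or rest
    after = choices[int(rng.integers(0, len(choices)))]
    return Translocation(span=span, after=after)


def simulate_history(cfg: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[SignedGeneOrder, list[Event]]:
    """Apply ``cfg.events`` sampled events to the pancrustacean ground
    pattern; returns the final order and the true event history."""
    rng = cfg.rng() if rng is None else rng
    order = replace(GROUND_PATTERN, taxon=f"sim_{cfg.seed}")
    history: list[Event] = []
    for _ in range(cfg.events):
        ev = _sample_event(order, cfg, rng)
        order = apply_event(order, ev)
        history.append(ev)
    return order, history


# ---------------------------------------------------------------------------
# sequences


def _weighted_choice(rng, weights: dict) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weight table sums to zero")
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _draw_codons(rng, weights: dict, n: int) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValueError("codon weight table sums to zero")
    idx = rng.choice(len(keys), size=n, p=w / w.sum())
    return "".join(keys[i] for i in idx)


def _composition_codon_weights(p: np.ndarray) -> dict:
    """Codon weights whose induced per-base marginal matches ``p``.

    Weights start at the product of base probabilities over the sense
    codons of the invertebrate mitochondrial code; because the two stop
    codons (AT-rich) are excluded, the base probabilities are adjusted by a
    short fixed-point iteration so the marginal composition of drawn codons
    reproduces the target.
    """
    codons = sense_codons()
    target = np.asarray(p, dtype=float)
    adj = target.copy()
    idx = {b: i for i, b in enumerate("ATGC")}
    counts = np.zeros((len(codons), 4))
    for k, c in enumerate(codons):
        for b in c:
            counts[k, idx[b]] += 1
    for _ in range(50):
        w = np.array([adj[idx[c[0]]] * adj[idx[c[1]]] * adj[idx[c[2]]]
                      for c in codons])
        w /= w.sum()
        marginal = (w @ counts) / 3.0
        if np.abs(marginal - target).max() < 1e-9:
            break
        adj *= np.where(marginal > 0, target / marginal, 1.0)
        adj /= adj.sum()
    return {c: float(w[k]) for k, c in enumerate(codons)}


def simulate_cds(cfg: SimulationConfig, n_codons: int,
                 rng: Optional[np.random.Generator] = None) -> str:
    """ATG + ``n_codons`` weighted sense-codon draws + TAA."""
    rng = cfg.rng() if rng is None else rng
    weights = cfg.codon_weights or _composition_codon_weights(cfg.composition())
    return "ATG" + _draw_codons(rng, weights, n_codons) + "TAA"


def _mirror(p: np.ndarray) -> np.ndarray:
    """Reverse-complement a composition (A, T, G, C): A<->T, G<->C."""
    return np.array([p[1], p[0], p[3], p[2]])


def simulate_genome(order: SignedGeneOrder, cfg: SimulationConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> MitogenomeAnnotation:
    """Lay the genes of ``order`` on a circular genome and fill in sequence.

    Lengths are drawn from per-category models; genes are placed with
    geometric spacers and (with probability ``overlap_prob``) small
    overlaps; bases target the genome-strand composition; PCGs carry ATN
    starts, weighted codon bodies and TAA/TAG stops on their coding strand.
    Overlapping features share sequence (protein-coding genes win), so the
    annotation metadata is always self-consistent even where an overlapped
    RNA gene's sequence is partly coding.
    """
    rng = cfg.rng() if rng is None else rng
    p = cfg.composition()  # A, T, G, C on the genome strand
    p_acgt = np.array([p[0], p[3], p[2], p[1]])  # reorder to A,C,G,T

    lengths: dict[str, int] = {}
    for g, _ in order.genes:
        cat = CATEGORY[g]
        if cat == "PCG":
            jitter = int(rng.integers(-cfg.pcg_length_jitter,
                                      cfg.pcg_length_jitter + 1))
            lengths[g] = max(60, _PCG_LENGTHS[g] + 3 * (jitter // 3))
        elif cat == "tRNA":
            lengths[g] = int(rng.integers(cfg.trna_range[0], cfg.trna_range[1] + 1))
        elif g == "rrnS":
            lengths[g] = int(rng.integers(cfg.rrnS_range[0], cfg.rrnS_range[1] + 1))
        elif g == "rrnL":
            lengths[g] = int(rng.integers(cfg.rrnL_range[0], cfg.rrnL_range[1] + 1))
        else:  # CR
            lengths[g] = int(rng.integers(cfg.cr_range[0], cfg.cr_range[1] + 1))

    # placement
    placed: list[tuple[str, int, int, int]] = []  # (gene, sign, start, end)
    pos = 0  # end of previous feature
    prev_len = None
    for g, s in order.genes:
        if prev_len is None:
            spacer = 0
        elif cfg.overlap_prob > 0 and rng.random() < cfg.overlap_prob:
            cap = min(cfg.overlap_max, prev_len - 1, lengths[g] - 1)
            spacer = -int(rng.integers(1, max(cap, 1) + 1))
        else:
            spacer = int(rng.geometric(1.0 / max(cfg.spacer_mean, 1.0))) - 1
        start = pos + spacer + 1
        end = start + lengths[g] - 1
        placed.append((g, s, start, end))
        pos = end
        prev_len = lengths[g]
    origin_gap = int(rng.geometric(1.0 / max(cfg.spacer_mean, 1.0))) - 1
    genome_length = pos + origin_gap

    # sequence: background first, then RNA/CR features, then PCGs on top
    seq = rng.choice(_BASES, size=genome_length, p=p_acgt)
    codon_weights = cfg.codon_weights
    records: list[GeneRecord] = []
    for pass_pcg in (False, True):
        for g, s, start, end in placed:
            is_pcg = CATEGORY[g] == "PCG"
            if is_pcg != pass_pcg:
                continue
            L = end - start + 1
            if is_pcg:
                start_codon = _weighted_choice(rng, cfg.start_codon_weights)
                stop_codon = _weighted_choice(rng, cfg.stop_codon_weights)
                if codon_weights is not None:
                    w = codon_weights
                else:
                    # target the genome strand: minus-strand genes draw their
                    # coding-strand codons from the mirrored composition
                    w = _composition_codon_weights(p if s > 0 else _mirror(p))
                body = _draw_codons(rng, w, L // 3 - 2)
                gene_seq = start_codon + body + stop_codon
            else:
                gene_seq = "".join(rng.choice(_BASES, size=L, p=p_acgt))
            if is_pcg and s < 0:
                gene_seq = reverse_complement(gene_seq)
            seq[start - 1:end] = list(gene_seq)
            records.append(GeneRecord(
                name=g, start=start, end=end,
                strand=None if g == "CR" else ("+" if s > 0 else "-"),
                start_codon=start_codon if is_pcg else None,
                stop_codon=stop_codon if is_pcg else None,
                stated_length=L,
            ))
    return MitogenomeAnnotation(
        taxon=order.taxon, genome_length=genome_length, records=records,
        circular=True, sequence="".join(seq))
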
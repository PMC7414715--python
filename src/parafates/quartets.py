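"""Site-pattern counting and fate statistics for two-pair quartets.

A quartet is two paralog pairs (a, b) and (c, d) from two different species.
Per usable alignment column (no gap or ambiguity among the four residues) the
column either supports one of the three unrooted topologies

* Q: a with b, c with d  (pattern xxyy) — independent duplications,
* R: a with c, b with d  (pattern xyxy) — shared duplication / fate match,
* S: a with d, b with c  (pattern xyyx) — the crossed fate match,

or is a one-sided pattern where only one gene of each pair matches (t = ABAC,
u = ABCB relative to the resolved fate pairing), or is uninformative.

Fate similarity F = |n_R - n_S| / (n_Q + n_R + n_S) measures the secondary
phylogenetic signal; its standard score Z_F follows from modelling pattern
occurrences as Bernoulli draws along the usable columns, so that
V(dF) = n_R(1 - n_R/l) + n_S(1 - n_S/l) + 2 n_R n_S / l, which is exactly
the multinomial variance of the count difference. Asymmetry dA = |t - u|
and Z_A are built the same way from the one-sided counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .alignio import FamilyAlignment, ParalogPair

Pairing = Literal["R", "S", "tie"]


class DegenerateQuartetError(ValueError):
    """No usable columns: quartet statistics are undefined."""


@dataclass(frozen=True)
class Quartet:
    """Two paralog pairs from two distinct species."""

    pair1: ParalogPair
    pair2: ParalogPair

    def __post_init__(self):
        if self.pair1.species_id == self.pair2.species_id:
            raise ValueError("quartet requires two distinct species")
        genes = set(self.pair1.genes) | set(self.pair2.genes)
        if len(genes) != 4:
            raise ValueError("quartet requires four distinct genes")

    @property
    def genes(self) -> tuple[str, str, str, str]:
        return (*self.pair1.genes, *self.pair2.genes)

    @property
    def key(self) -> tuple[str, str]:
        return (self.pair1.species_id, self.pair2.species_id)


@dataclass(frozen=True)
class PatternCounts:
    """Site-pattern counts for one quartet.

    ``l`` is the number of usable columns: no gap/'X' among the four residues.
    All-identical usable columns enter ``l`` but no category. One-sided counts
    are stored for both candidate pairings; ``t``/``u`` are resolved once the
    pairing is (t_r, u_r under the R-pairing; t_s, u_s under S).
    """

    n_q: int
    n_r: int
    n_s: int
    t_r: int
    u_r: int
    t_s: int
    u_s: int
    l: int

    def one_sided(self, pairing: Pairing) -> tuple[int, int]:
        if pairing == "R":
            return self.t_r, self.u_r
        if pairing == "S":
            return self.t_s, self.u_s
        raise ValueError("one-sided counts undefined for a tied pairing")

    @property
    def informative(self) -> int:
        return self.n_q + self.n_r + self.n_s


@dataclass(frozen=True)
class QuartetScores:
    """Derived per-quartet statistics (fate similarity and asymmetry)."""

    F: float
    dF: int
    V_dF: float
    Z_F: float
    pairing: Pairing
    dA: int | None
    V_dA: float | None
    Z_A: float | None


def count_site_patterns(aln: FamilyAlignment, quartet: Quartet) -> PatternCounts:
    """Classify every usable column of the quartet into Q/R/S/t/u or none."""
    a, b, c, d = (aln.row(g) for g in quartet.genes)
    usable = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
    xa, xb, xc, xd = a[usable], b[usable], c[usable], d[usable]

    ab, cd = xa == xb, xc == xd
    ac, bd = xa == xc, xb == xd
    ad, bc = xa == xd, xb == xc

    n_q = int(np.sum(ab & cd & ~ac))
    n_r = int(np.sum(ac & bd & ~ab))
    n_s = int(np.sum(ad & bc & ~ab))
    # one-sided patterns under the R-pairing (a~c, b~d): exactly one side matches
    # and the lone residues differ from the matched side
    t_r = int(np.sum(ac & ~bd & ~ab & ~ad))          # ABAC
    u_r = int(np.sum(bd & ~ac & ~ab & ~bc))          # ABCB
    # mirrored under the S-pairing (a~d, b~c)
    t_s = int(np.sum(ad & ~bc & ~ab & ~ac))
    u_s = int(np.sum(bc & ~ad & ~ab & ~bd))
    return PatternCounts(n_q, n_r, n_s, t_r, u_r, t_s, u_s, int(np.sum(usable)))


def bernoulli_variance(x: int, y: int, l: int) -> float:
    """Variance of the count difference x - y along l Bernoulli columns.

    Equals the exact multinomial variance Var(N_x - N_y) for counts drawn
    multinomially with probabilities x/l and y/l over l trials.
    """
    if l <= 0:
        raise ValueError("alignment length l must be positive")
    if x < 0 or y < 0 or x + y > l:
        raise ValueError(f"invalid counts x={x}, y={y} for l={l}")
    return x * (1.0 - x / l) + y * (1.0 - y / l) + 2.0 * x * y / l


def z_score(x: int, y: int, l: int) -> float:
    """Standard score |x - y| / sqrt(V); zero when the variance vanishes."""
    v = bernoulli_variance(x, y, l)
    if v == 0.0:
        return 0.0
    return abs(x - y) / math.sqrt(v)


def fate_similarity(counts: PatternCounts) -> QuartetScores:
    """F, Z_F and the resolved fate pairing (no asymmetry fields yet)."""
    if counts.l == 0:
        raise DegenerateQuartetError("no usable columns")
    denom = counts.informative
    dF = abs(counts.n_r - counts.n_s)
    if denom == 0:
        return QuartetScores(0.0, 0, 0.0, 0.0, "tie", None, None, None)
    pairing: Pairing = (
        "R" if counts.n_r > counts.n_s else "S" if counts.n_s > counts.n_r else "tie"
    )
    v = bernoulli_variance(counts.n_r, counts.n_s, counts.l)
    zf = z_score(counts.n_r, counts.n_s, counts.l)
    return QuartetScores(dF / denom, dF, v, zf, pairing, None, None, None)


def asymmetry_scores(counts: PatternCounts, pairing: Pairing) -> tuple[int, float, float]:
    """(dA, V(dA), Z_A) from the one-sided counts of the resolved pairing."""
    if pairing == "tie":
        raise ValueError("asymmetry undefined for a tied pairing")
    t, u = counts.one_sided(pairing)
    return abs(t - u), bernoulli_variance(t, u, counts.l), z_score(t, u, counts.l)


def score_quartet(aln: FamilyAlignment, quartet: Quartet) -> tuple[PatternCounts, QuartetScores]:
    """Count patterns and compute all per-quartet statistics in one pass."""
    counts = count_site_patterns(aln, quartet)
    if counts.l == 0:
        raise DegenerateQuartetError(
            f"quartet {quartet.genes} has no usable columns"
        )
    scores = fate_similarity(counts)
    if scores.pairing != "tie":
        dA, v_da, z_a = asymmetry_scores(counts, scores.pairing)
        scores = QuartetScores(
            scores.F, scores.dF, scores.V_dF, scores.Z_F, scores.pairing, dA, v_da, z_a
        )
    return counts, scores
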
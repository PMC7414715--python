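"""Family-level analysis: quartet table, clusterings, bootstrap and P / Z̄_F.

The pipeline for one family is

1. extract one paralog pair per two-copy species;
2. score every quartet (two pairs, two species): pattern counts, fate
   similarity F, Z_F, asymmetry Z_A, and the duplication score D (ELW-based
   maximum likelihood or the parsimony fallback);
3. cluster species into ancestral-duplication blocks (cluster editing on D,
   computed on the gap-trimmed alignment);
4. cluster genes into fates (MCL on the F-weighted fate network, untrimmed
   alignment);
5. bootstrap the alignment columns, redo quartet counting and fate
   clustering per replicate, and keep the baseline fate clusters that are
   robustly recovered (mean best Jaccard across replicates);
6. pervasiveness P = the number of duplication blocks whose pairs all split
   across one prevailing pair of robust fates, and the magnitude Z̄_F = the
   mean Z_F of quartets joining two such independently duplicated pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .alignio import (
    FamilyAlignment,
    GeneRecord,
    ParalogPair,
    extract_paralog_pairs,
    trim_gappy_columns,
)
from .likelihood import ml_duplication_score, parsimony_weights, usable_columns
from .networks import (
    DEFAULT_THETA,
    DuplicationClustering,
    FateClustering,
    build_duplication_network,
    build_fate_network,
    cluster_editing,
    markov_clustering,
)
from .quartets import DegenerateQuartetError, Quartet, count_site_patterns, score_quartet
from .substmodels import lg_model


class InsufficientPairsError(ValueError):
    """Fewer than two paralog pairs: no quartet can be formed."""


def make_quartets(pairs: list[ParalogPair]) -> list[Quartet]:
    """All two-pair quartets, ordered lexicographically by species pair."""
    return [Quartet(p1, p2) for p1, p2 in combinations(sorted(pairs, key=lambda p: p.species_id), 2)]


def score_quartets(
    aln: FamilyAlignment,
    pairs: list[ParalogPair],
    mode: str = "ml",
    model=None,
    trim_max_gap_frac: float | None = 0.5,
    elw_replicates: int = 1000,
    estimate_shape: bool = True,
    rng: np.random.Generator | int | None = None,
) -> list[dict]:
    """Per-quartet statistics table.

    F/Z_F/Z_A come from the untrimmed alignment; D is computed on the
    gap-trimmed alignment (``trim_max_gap_frac=None`` disables trimming).
    Degenerate quartets (no usable columns) appear with null statistics.
    """
    if mode not in ("ml", "parsimony"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    model = model or lg_model()
    if trim_max_gap_frac is not None:
        trimmed, _ = trim_gappy_columns(aln, trim_max_gap_frac)
    else:
        trimmed = aln
    rows = []
    for q in make_quartets(pairs):
        row = {
            "species_x": q.pair1.species_id,
            "species_y": q.pair2.species_id,
            "gene_a": q.pair1.gene_a,
            "gene_b": q.pair1.gene_b,
            "gene_c": q.pair2.gene_a,
            "gene_d": q.pair2.gene_b,
        }
        try:
            counts, scores = score_quartet(aln, q)
        except DegenerateQuartetError:
            row.update(
                dict(l=0, n_Q=0, n_R=0, n_S=0, t=None, u=None, D=None, F=None,
                     Z_F=None, Z_A=None, pairing=None, degenerate=True)
            )
            rows.append(row)
            continue
        t, u = (counts.one_sided(scores.pairing) if scores.pairing != "tie" else (None, None))
        row.update(
            dict(l=counts.l, n_Q=counts.n_q, n_R=counts.n_r, n_S=counts.n_s,
                 t=t, u=u, F=scores.F, Z_F=scores.Z_F, Z_A=scores.Z_A,
                 pairing=scores.pairing, degenerate=False)
        )
        # duplication score on the trimmed alignment
        try:
            if mode == "parsimony":
                tc = count_site_patterns(trimmed, q)
                row["D"] = parsimony_weights(tc).d if tc.informative > 0 else None
            else:
                cols = usable_columns(
                    np.vstack([trimmed.row(g) for g in q.genes])
                )
                if cols.shape[1] == 0:
                    row["D"] = None
                else:
                    weights, _ = ml_duplication_score(
                        cols, model, elw_replicates, estimate_shape,
                        rng=np.random.default_rng(rng.integers(2**31)),
                    )
                    row["D"] = weights.d
        except DegenerateQuartetError:
            row["D"] = None
        rows.append(row)
    return rows


def fate_clustering_from_rows(rows: list[dict]) -> FateClustering:
    return markov_clustering(build_fate_network(rows))


def resample_columns(aln: FamilyAlignment, rng: np.random.Generator) -> FamilyAlignment:
    """Bootstrap replicate: sample columns with replacement to original length."""
    idx = rng.integers(0, aln.length, size=aln.length)
    chars = np.array([list(r.aligned_seq) for r in aln.records])
    return FamilyAlignment(
        [
            GeneRecord(r.gene_id, r.species_id, "".join(chars[i, idx]))
            for i, r in enumerate(aln.records)
        ]
    )


@dataclass
class BootstrapEnsemble:
    replicates: list[FateClustering]
    seed: int | None


def bootstrap_fates(
    aln: FamilyAlignment,
    pairs: list[ParalogPair],
    n_replicates: int = 100,
    seed: int | None = None,
) -> BootstrapEnsemble:
    """Redo pattern counting and fate clustering on resampled columns.

    Only the fate side is recomputed per replicate; the duplication
    clustering is held from the full data. A replicate with no informative
    columns is recorded as an empty clustering.
    """
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_replicates):
        rep_aln = resample_columns(aln, rng)
        rows = []
        for q in make_quartets(pairs):
            counts = count_site_patterns(rep_aln, q)
            row = {
                "gene_a": q.pair1.gene_a, "gene_b": q.pair1.gene_b,
                "gene_c": q.pair2.gene_a, "gene_d": q.pair2.gene_b,
            }
            if counts.l == 0 or counts.informative == 0:
                row.update(pairing=None, F=None)
            else:
                from .quartets import fate_similarity

                s = fate_similarity(counts)
                row.update(pairing=s.pairing, F=s.F)
            rows.append(row)
        if any(r["pairing"] in ("R", "S") for r in rows):
            reps.append(fate_clustering_from_rows(rows))
        else:
            reps.append(FateClustering(()))
    return BootstrapEnsemble(reps, seed)


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class RobustFateSet:
    clusters: tuple[frozenset, ...]
    robustness: tuple[float, ...]

    def fate_of(self, gene: str) -> int | None:
        for i, c in enumerate(self.clusters):
            if gene in c:
                return i
        return None


def jaccard_robust_clusters(
    baseline: FateClustering,
    ensemble: BootstrapEnsemble,
    min_robustness: float = 0.5,
) -> RobustFateSet:
    """Keep baseline fate clusters robustly recovered across replicates.

    Robustness of a baseline cluster is the mean over replicates of the best
    Jaccard coefficient against any replicate cluster. Clusters are kept
    greedily by descending robustness, skipping overlaps with already-kept
    clusters and anything below ``min_robustness``. With an empty ensemble
    (bootstrap disabled) every baseline cluster scores 1.
    """
    if not ensemble.replicates:
        return RobustFateSet(baseline.clusters, tuple(1.0 for _ in baseline.clusters))
    scores = []
    for c in baseline.clusters:
        per_rep = [
            max((jaccard(c, rc) for rc in rep.clusters), default=0.0)
            for rep in ensemble.replicates
        ]
        scores.append(float(np.mean(per_rep)))
    order = sorted(
        range(len(baseline.clusters)),
        key=lambda i: (-scores[i], sorted(baseline.clusters[i])),
    )
    kept_idx: list[int] = []
    covered: set = set()
    for i in order:
        if scores[i] < min_robustness:
            continue
        if baseline.clusters[i] & covered:
            continue
        kept_idx.append(i)
        covered |= baseline.clusters[i]
    kept_idx.sort(key=lambda i: sorted(baseline.clusters[i]))
    return RobustFateSet(
        tuple(baseline.clusters[i] for i in kept_idx),
        tuple(scores[i] for i in kept_idx),
    )


def _blocks_covered(
    dups: DuplicationClustering,
    pairs: list[ParalogPair],
    f1: frozenset,
    f2: frozenset,
) -> list[int]:
    """Duplication blocks whose every pair splits one gene into f1, one into f2."""
    pair_by_species = {p.species_id: p for p in pairs}
    covered = []
    for bi, block in enumerate(dups.blocks):
        members = [pair_by_species[sp] for sp in block if sp in pair_by_species]
        if not members:
            continue
        ok = all(
            (p.gene_a in f1 and p.gene_b in f2) or (p.gene_a in f2 and p.gene_b in f1)
            for p in members
        )
        if ok:
            covered.append(bi)
    return covered


def pervasiveness(
    dups: DuplicationClustering,
    fates: RobustFateSet,
    pairs: list[ParalogPair],
    quartet_rows: list[dict] | None = None,
) -> tuple[int, tuple[int, int] | None, list[int]]:
    """P and the prevailing fate pair.

    For every unordered pair of distinct robust fates, count the duplication
    blocks in which every member species' paralog pair has one gene in each
    fate; P is the maximal count and the prevailing pair the argmax (ties
    resolved by the larger Z̄_F if a quartet table is supplied, then
    lexicographically). A fate holding both genes of one pair can never
    contribute. Returns (P, prevailing fate index pair or None, covered
    duplication-block indices).
    """
    best: tuple[int, tuple[int, int], list[int]] | None = None
    candidates = []
    for i, j in combinations(range(len(fates.clusters)), 2):
        covered = _blocks_covered(dups, pairs, fates.clusters[i], fates.clusters[j])
        candidates.append(((i, j), covered))
    if not candidates:
        return 0, None, []
    max_p = max(len(c) for _, c in candidates)
    if max_p == 0:
        return 0, None, []
    top = [(fp, c) for fp, c in candidates if len(c) == max_p]
    if len(top) > 1 and quartet_rows is not None:
        def tie_key(item):
            fp, covered = item
            z = mean_fate_zscore(quartet_rows, dups, fates, fp, covered, pairs)
            return (-(z if z is not None else -np.inf), fp)

        top.sort(key=tie_key)
    else:
        top.sort(key=lambda item: item[0])
    fp, covered = top[0]
    return max_p, fp, covered


def mean_fate_zscore(
    quartet_rows: list[dict],
    dups: DuplicationClustering,
    fates: RobustFateSet,
    prevailing: tuple[int, int],
    covered_blocks: list[int],
    pairs: list[ParalogPair],
) -> float | None:
    """Mean Z_F over quartets of two independently duplicated prevailing pairs.

    Qualifying quartets join two paralog pairs lying in *different* covered
    duplication blocks with all four genes inside the prevailing fates.
    Undefined (None) when fewer than two blocks are covered.
    """
    if len(covered_blocks) < 2:
        return None
    f1 = fates.clusters[prevailing[0]]
    f2 = fates.clusters[prevailing[1]]
    prevailing_genes = f1 | f2
    block_of = {}
    for sp in {p.species_id for p in pairs}:
        try:
            block_of[sp] = dups.block_of(sp)
        except KeyError:
            pass
    zs = []
    covered = set(covered_blocks)
    for row in quartet_rows:
        if row.get("Z_F") is None:
            continue
        bx = block_of.get(row["species_x"])
        by = block_of.get(row["species_y"])
        if bx is None or by is None or bx == by:
            continue
        if bx not in covered or by not in covered:
            continue
        genes = (row["gene_a"], row["gene_b"], row["gene_c"], row["gene_d"])
        if all(g in prevailing_genes for g in genes):
            zs.append(row["Z_F"])
    return float(np.mean(zs)) if zs else None


@dataclass
class FamilyReport:
    """Complete result of one family analysis."""

    quartet_rows: list[dict]
    duplication_clusters: DuplicationClustering
    baseline_fates: FateClustering
    robust_fates: RobustFateSet
    pervasiveness: int
    prevailing_fates: tuple[int, int] | None
    covered_blocks: list[int]
    zbar_f: float | None
    pairs: list[ParalogPair]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "duplications": [sorted(b) for b in self.duplication_clusters.blocks],
            "fates": [
                {"genes": sorted(c), "robustness": r}
                for c, r in zip(self.robust_fates.clusters, self.robust_fates.robustness)
            ],
            "P": self.pervasiveness,
            "prevailing_fates": (
                list(self.prevailing_fates) if self.prevailing_fates else None
            ),
            "Zbar_F": self.zbar_f,
            "quartets": self.quartet_rows,
            "metadata": self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def analyze_family(
    aln: FamilyAlignment,
    mapping: dict[str, str],
    mode: str = "ml",
    theta: float = DEFAULT_THETA,
    elw_replicates: int = 1000,
    bootstrap_n: int = 100,
    min_pairs: int = 0,
    min_robustness: float = 0.5,
    trim_max_gap_frac: float | None = 0.5,
    estimate_shape: bool = True,
    seed: int | None = None,
) -> FamilyReport:
    """Run the full detection pipeline on one family."""
    pairs = extract_paralog_pairs(aln, mapping)
    if len(pairs) < 2:
        raise InsufficientPairsError(
            f"{len(pairs)} paralog pairs found, need at least 2"
        )
    if min_pairs and len(pairs) <= min_pairs:
        raise InsufficientPairsError(
            f"{len(pairs)} paralog pairs does not exceed min_pairs={min_pairs}"
        )
    rng = np.random.default_rng(seed)
    rows = score_quartets(
        aln, pairs, mode=mode, trim_max_gap_frac=trim_max_gap_frac,
        elw_replicates=elw_replicates, estimate_shape=estimate_shape,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    dup_net = build_duplication_network(rows, theta)
    dups = cluster_editing(dup_net, theta)
    baseline = fate_clustering_from_rows(rows)
    ensemble = bootstrap_fates(
        aln, pairs, n_replicates=bootstrap_n, seed=int(rng.integers(2**31))
    )
    robust = jaccard_robust_clusters(baseline, ensemble, min_robustness)
    p, prevailing, covered = pervasiveness(dups, robust, pairs, rows)
    zbar = (
        mean_fate_zscore(rows, dups, robust, prevailing, covered, pairs)
        if prevailing is not None and p >= 2
        else None
    )
    return FamilyReport(
        rows, dups, baseline, robust, p, prevailing, covered, zbar, pairs,
        metadata={
            "mode": mode, "theta": theta, "bootstrap_n": bootstrap_n,
            "elw_replicates": elw_replicates, "seed": seed,
            "min_robustness": min_robustness,
        },
    )
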
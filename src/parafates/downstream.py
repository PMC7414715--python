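"""Downstream quartet analyses: categories, asymmetry, localization, patterns.

Builds on a finished family report. Quartets are categorized by the
duplication clustering (single duplication, optionally split into WGD-derived
and other using an external ohnolog annotation table, versus independent
duplications). Asymmetry summaries report, per category, how often the
one-sided imbalance is significant among quartets with significant fate
similarity. Subcellular-localization configurations compare the compartments
of the four genes under the fate pairing (consistent relocalization vs
inconsistent etc.), consuming a TargetP-style prediction table. Finally,
per-column recurrent patterns are identified: for every paralog pair, each
alignment column is classified by whether it supports or contradicts the
family's fate structure across all qualifying quartets, colored warm or cold
accordingly, and summarized in a logo-style frequency matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignio import FamilyAlignment, ParalogPair
from .networks import DuplicationClustering
from .scoring import FamilyReport, RobustFateSet

COMPARTMENTS = ("Mito", "Chlo", "Secr", "Cyto")

CATEGORY_INDEPENDENT = "independent_duplication"
CATEGORY_WGD = "single_duplication_wgd"
CATEGORY_OTHER = "single_duplication_other"

SUPPORT_CLASSES = (
    "symmetric_support",
    "asym_support_side1",
    "asym_support_side2",
    "symmetric_contradict",
    "asym_contradict_side1",
    "asym_contradict_side2",
)

_CLASS_COLOR = {
    "symmetric_support": "yellow",
    "asym_support_side1": "red",
    "asym_support_side2": "pink",
    "symmetric_contradict": "blue",
    "asym_contradict_side1": "cyan",
    "asym_contradict_side2": "green",
}


def read_localization_table(path: str | Path) -> dict[str, tuple[str, int]]:
    """Read a TargetP-style TSV: gene_id, compartment, reliability_class."""
    table: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if i == 0 and row[0].lower() in {"gene", "gene_id"}:
                continue
            gene, comp, rc = row[0], row[1], int(row[2])
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r} for gene {gene}")
            table[gene] = (comp, rc)
    return table


def read_wgd_table(path: str | Path) -> dict[str, str]:
    """Read a WGD annotation TSV (species, gene_a, gene_b, label) -> species label."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith("#"):
                continue
            if i == 0 and parts[0].lower() == "species":
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: expected 4 columns, got {len(parts)}")
            table[parts[0]] = parts[3]
    return table


def categorize_quartets(
    quartet_rows: list[dict],
    dups: DuplicationClustering,
    wgd_by_species: dict[str, str] | None = None,
) -> list[str]:
    """Per-quartet category: independent vs single duplication (WGD / other).

    A single-duplication quartet is WGD if the annotation labels either
    species' pair as WGD; species without annotation default to 'other'.
    """
    wgd_by_species = wgd_by_species or {}
    categories = []
    for row in quartet_rows:
        sx, sy = row["species_x"], row["species_y"]
        if not dups.same_block(sx, sy):
            categories.append(CATEGORY_INDEPENDENT)
            continue
        labels = {wgd_by_species.get(sx), wgd_by_species.get(sy)} - {None}
        categories.append(CATEGORY_WGD if "WGD" in labels else CATEGORY_OTHER)
    return categories


def asymmetry_summary(
    quartet_rows: list[dict],
    categories: list[str],
    z_threshold: float = 1.96,
) -> dict[str, dict]:
    """Fraction of |Z_A| > threshold among |Z_F| > threshold, per category.

    Returns per category a dict with n (denominator), k (numerator),
    fraction and the standard error sqrt(p(1-p)/n); fraction is None when
    no quartet in the category has significant fate similarity.
    """
    out: dict[str, dict] = {}
    for cat in sorted(set(categories)):
        sig = [
            r for r, c in zip(quartet_rows, categories)
            if c == cat and r.get("Z_F") is not None and abs(r["Z_F"]) > z_threshold
        ]
        k = sum(1 for r in sig if r.get("Z_A") is not None and abs(r["Z_A"]) > z_threshold)
        n = len(sig)
        if n == 0:
            out[cat] = {"n": 0, "k": 0, "fraction": None, "se": None}
        else:
            p = k / n
            out[cat] = {"n": n, "k": k, "fraction": p, "se": float(np.sqrt(p * (1 - p) / n))}
    return out


def localization_configuration(
    row: dict,
    table: dict[str, tuple[str, int]],
    max_rc: int = 3,
) -> str | None:
    """Localization configuration of one quartet under its fate pairing.

    Returns None (quartet excluded) if the pairing is unresolved, a gene is
    missing from the table, or any reliability class is >= ``max_rc``.
    Labels: uniform (all four equal), consistent (fate-matched genes agree,
    the two fates differ), inconsistent (the crossed genes agree instead),
    single_distinct (exactly one gene deviates from the other three), other.
    """
    pairing = row.get("pairing")
    if pairing not in ("R", "S"):
        return None
    genes = (row["gene_a"], row["gene_b"], row["gene_c"], row["gene_d"])
    if any(g not in table for g in genes):
        return None
    locs = [table[g][0] for g in genes]
    if any(table[g][1] >= max_rc for g in genes):
        return None
    la, lb, lc, ld = locs
    if pairing == "R":
        matched = (la == lc) and (lb == ld)
        crossed = (la == ld) and (lb == lc)
    else:
        matched = (la == ld) and (lb == lc)
        crossed = (la == lc) and (lb == ld)
    if len(set(locs)) == 1:
        return "uniform"
    if matched and la != lb:
        return "consistent"
    if crossed and la != lb:
        return "inconsistent"
    counts = {x: locs.count(x) for x in set(locs)}
    if sorted(counts.values()) == [1, 3]:
        return "single_distinct"
    return "other"


def localization_summary(
    quartet_rows: list[dict],
    table: dict[str, tuple[str, int]],
    categories: list[str] | None = None,
    max_rc: int = 3,
) -> dict:
    """Configuration counts overall and (optionally) per quartet category."""
    labels = [localization_configuration(r, table, max_rc) for r in quartet_rows]
    def tally(idx):
        counts: dict[str, int] = {}
        for i in idx:
            if labels[i] is not None:
                counts[labels[i]] = counts.get(labels[i], 0) + 1
        total = sum(counts.values())
        return {"counts": counts, "n": total}
    out = {"overall": tally(range(len(labels)))}
    if categories is not None:
        for cat in sorted(set(categories)):
            out[cat] = tally([i for i, c in enumerate(categories) if c == cat])
    out["labels"] = labels
    return out


def _fate_pairing_sides(
    pair_p: ParalogPair, pair_q: ParalogPair, fate_of: dict[str, int]
) -> tuple[tuple[str, str], tuple[str, str]] | None:
    """Match genes of two pairs by fate: ((p_f1, q_f1), (p_f2, q_f2)) or None."""
    fp = (fate_of.get(pair_p.gene_a), fate_of.get(pair_p.gene_b))
    fq = (fate_of.get(pair_q.gene_a), fate_of.get(pair_q.gene_b))
    if None in fp or None in fq or fp[0] == fp[1] or fq[0] == fq[1]:
        return None
    if set(fp) != set(fq):
        return None
    p1, p2 = (pair_p.gene_a, pair_p.gene_b) if fp[0] < fp[1] else (pair_p.gene_b, pair_p.gene_a)
    q1, q2 = (pair_q.gene_a, pair_q.gene_b) if fq[0] < fq[1] else (pair_q.gene_b, pair_q.gene_a)
    return (p1, q1), (p2, q2)


@dataclass
class ColumnAnnotation:
    """Per paralog pair: dominant support class and color per column (1-based out)."""

    pair: ParalogPair
    classes: list[str]       # one of SUPPORT_CLASSES or "uninformative" per column
    colors: list[str]        # warm/cold color or "none"
    class_counts: np.ndarray  # (n_columns, 6) quartet counts per class


def color_positions(
    aln: FamilyAlignment,
    pairs: list[ParalogPair],
    dups: DuplicationClustering,
    fates: RobustFateSet,
    include_gap_state: bool = True,
) -> list[ColumnAnnotation]:
    """Classify every column of every pair against the family fate structure.

    For each pair, all quartets joining it to pairs from *other* duplication
    blocks are examined. Per column, relative to the fate-consistent gene
    matching: a full two-sided match supports symmetrically; a one-sided
    match supports asymmetrically (side 1 = the lower-numbered fate); a full
    crossed match contradicts symmetrically; a one-sided crossed match
    contradicts asymmetrically. The column is colored warm (yellow/red/pink)
    if supports outnumber contradictions, cold (blue/cyan/green) otherwise,
    with the hue picking the dominant class. Gaps count as a shared state by
    default so that presence/absence of an N-terminal extension is visible
    as pattern support; 'X' never matches anything.
    """
    fate_of = {}
    for i, cluster in enumerate(fates.clusters):
        for g in cluster:
            fate_of[g] = i
    block_of = {}
    for p in pairs:
        try:
            block_of[p.species_id] = dups.block_of(p.species_id)
        except KeyError:
            block_of[p.species_id] = None

    n_cols = aln.length
    # residue codes with gap as state 20 (shared) or excluded
    def coded(gene):
        seq = aln.record(gene).aligned_seq
        out = np.full(len(seq), -1, dtype=int)
        for k, ch in enumerate(seq):
            if ch == "X":
                out[k] = -1
            elif ch == "-":
                out[k] = 20 if include_gap_state else -1
            else:
                out[k] = aln.row(gene)[k]
        return out

    cache = {g: coded(g) for p in pairs for g in p.genes}
    annotations = []
    for p in pairs:
        counts = np.zeros((n_cols, len(SUPPORT_CLASSES)), dtype=int)
        for q in pairs:
            if q.species_id == p.species_id:
                continue
            if block_of[p.species_id] is None or block_of[q.species_id] is None:
                continue
            if block_of[p.species_id] == block_of[q.species_id]:
                continue
            sides = _fate_pairing_sides(p, q, fate_of)
            if sides is None:
                continue
            (p1, q1), (p2, q2) = sides
            a, b = cache[p1], cache[p2]          # pair p, fates 1 and 2
            c, d = cache[q1], cache[q2]          # pair q, fates 1 and 2
            valid = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
            m1, m2 = a == c, b == d              # fate-matched sides
            x1, x2 = a == d, b == c              # crossed sides
            distinct = a != b
            sym_sup = valid & m1 & m2 & distinct
            asy1 = valid & m1 & ~m2 & distinct & (d != a)
            asy2 = valid & m2 & ~m1 & distinct & (c != b)
            sym_con = valid & x1 & x2 & distinct
            con1 = valid & x1 & ~x2 & distinct & (c != a) & ~sym_sup & ~asy1 & ~asy2
            con2 = valid & x2 & ~x1 & distinct & (d != b) & ~sym_sup & ~asy1 & ~asy2
            for k, mask in enumerate((sym_sup, asy1, asy2, sym_con, con1, con2)):
                counts[:, k] += mask
        classes, colors = [], []
        support = counts[:, :3].sum(axis=1)
        contra = counts[:, 3:].sum(axis=1)
        for col in range(n_cols):
            if support[col] == 0 and contra[col] == 0:
                classes.append("uninformative")
                colors.append("none")
            elif support[col] >= contra[col] and support[col] > 0:
                k = int(np.argmax(counts[col, :3]))
                classes.append(SUPPORT_CLASSES[k])
                colors.append(_CLASS_COLOR[SUPPORT_CLASSES[k]])
            else:
                k = 3 + int(np.argmax(counts[col, 3:]))
                classes.append(SUPPORT_CLASSES[k])
                colors.append(_CLASS_COLOR[SUPPORT_CLASSES[k]])
        annotations.append(ColumnAnnotation(p, classes, colors, counts))
    return annotations


def build_logo(
    annotations: list[ColumnAnnotation],
    plot_path: str | Path | None = None,
) -> np.ndarray:
    """Per-column relative frequency of each pattern class over pairs.

    Returns an (n_columns, 6) matrix of class frequencies (pairs whose column
    carries that class / number of annotated pairs); the uninformative mass
    is the remainder to one. Optionally renders a stacked-bar logo figure.
    """
    if not annotations:
        raise ValueError("need at least one annotated pair")
    n_cols = len(annotations[0].classes)
    freq = np.zeros((n_cols, len(SUPPORT_CLASSES)))
    for ann in annotations:
        for col, cls in enumerate(ann.classes):
            if cls != "uninformative":
                freq[col, SUPPORT_CLASSES.index(cls)] += 1
    freq /= len(annotations)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, n_cols / 12), 3))
        bottom = np.zeros(n_cols)
        x = np.arange(1, n_cols + 1)
        for k, cls in enumerate(SUPPORT_CLASSES):
            ax.bar(x, freq[:, k], bottom=bottom, width=1.0,
                   color=_CLASS_COLOR[cls], label=cls)
            bottom += freq[:, k]
        ax.set_xlabel("alignment column")
        ax.set_ylabel("pattern frequency")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=6, ncol=3)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return freq


def write_annotation_tsv(annotations: list[ColumnAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tgene_a\tgene_b\tcolumn\tclass\tcolor\n")
        for ann in annotations:
            for col, (cls, color) in enumerate(zip(ann.classes, ann.colors), start=1):
                fh.write(
                    f"{ann.pair.species_id}\t{ann.pair.gene_a}\t{ann.pair.gene_b}"
                    f"\t{col}\t{cls}\t{color}\n"
                )


def write_logo_tsv(freq: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\t" + "\t".join(SUPPORT_CLASSES) + "\n")
        for col in range(freq.shape[0]):
            fh.write(str(col + 1) + "\t" + "\t".join(f"{v:.6g}" for v in freq[col]) + "\n")


def report_downstream(
    report: FamilyReport,
    aln: FamilyAlignment,
    localization: dict[str, tuple[str, int]] | None = None,
    wgd_by_species: dict[str, str] | None = None,
    z_threshold: float = 1.96,
) -> dict:
    """Convenience wrapper running all downstream analyses on a report."""
    categories = categorize_quartets(report.quartet_rows, report.duplication_clusters, wgd_by_species)
    out = {
        "categories": categories,
        "asymmetry": asymmetry_summary(report.quartet_rows, categories, z_threshold),
    }
    if localization is not None:
        out["localization"] = localization_summary(
            report.quartet_rows, localization, categories
        )
    return out
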
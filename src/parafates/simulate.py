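"""Synthetic gene families with known duplications, fates and localizations.

The generator evolves a root protein sequence along a newick species tree
under a reversible amino-acid substitution process (LG or Poisson), with
optional discrete-gamma site-rate heterogeneity. At each configured
*placement* (a branch of the species tree) the lineage forks into two copies.
Post-duplication, the copies are pushed apart at *diagnostic columns*: fate-1
copies are resubstituted to fixed fate-1 residues at the fate-1 diagnostic
columns and frozen there, fate-2 copies likewise at the fate-2 columns. The
same fate residues are reused at every independent duplication, which is
precisely the recurrent-sequence-evolution signal the detection framework
looks for. In ``one_sided`` mode all diagnostic columns constrain fate-1
copies only, producing asymmetric divergence (an excess of ABAC over ABCB
patterns).

Fate-2 copies can additionally carry an N-terminal extension block emulating
an acquired targeting peptide (gap in all other rows), and each fate can be
given a subcellular compartment label for the localization analyses.

All randomness flows from one integer seed; regenerating with the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .alignio import FamilyAlignment, GeneRecord, write_alignment
from .substmodels import (
    AMINO_ACIDS,
    SubstitutionModel,
    discrete_gamma_rates,
    lg_model,
    poisson_model,
)


class SimulationConfigError(ValueError):
    pass


def default_species_tree(n_blocks: int = 4, per_block: int = 3) -> tuple[str, tuple]:
    """Balanced species tree with ``n_blocks`` clades of ``per_block`` species.

    Clade stems are long (0.6) so that the duplications placed on them leave
    both a clear pre-duplication signal between blocks and a clear shared
    post-duplication signal within blocks. Returns (newick, placements) where
    each placement is the tuple of species in one clade.
    """
    if per_block < 1 or n_blocks < 2:
        raise SimulationConfigError("need at least 2 blocks of >=1 species")
    names = [
        [f"sp{b * per_block + k + 1:02d}" for k in range(per_block)]
        for b in range(n_blocks)
    ]

    def clade(block):
        if len(block) == 1:
            inner = f"{block[0]}:0.10"
        elif len(block) == 2:
            inner = f"({block[0]}:0.10,{block[1]}:0.10)"
        else:
            core = f"({block[0]}:0.08,{block[1]}:0.08):0.06,{block[2]}:0.14"
            inner = f"({core})"
            for extra in block[3:]:
                inner = f"({inner}:0.05,{extra}:0.18)"
        return f"{inner}:0.60"

    clades = [clade(b) for b in names]
    while len(clades) > 2:
        merged = [f"({clades[i]},{clades[i + 1]}):0.15" for i in range(0, len(clades) - 1, 2)]
        if len(clades) % 2:
            merged.append(clades[-1])
        clades = merged
    newick = f"({clades[0]},{clades[1]});"
    return newick, tuple(tuple(b) for b in names)


@dataclass
class SimConfig:
    """Study conditions for one synthetic family.

    Defaults emulate a mid-sized eukaryotic family: 12 species in four clades,
    one independent duplication per clade, 500 alignment columns of which 30
    per fate are diagnostic, LG substitutions, no rate heterogeneity.
    """

    species_tree: str = ""
    duplication_placements: tuple = ()
    n_columns: int = 500
    n_diagnostic: int = 30
    asymmetry_mode: str = "symmetric"
    placement_fraction: float = 0.5
    target_peptide_len: int = 0
    subst_rate_model: str = "lg"
    gamma_shape: float | None = None
    loc_labels: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.species_tree:
            tree, placements = default_species_tree()
            self.species_tree = tree
            if not self.duplication_placements:
                self.duplication_placements = placements
        if self.asymmetry_mode not in ("symmetric", "one_sided"):
            raise SimulationConfigError(f"unknown asymmetry_mode {self.asymmetry_mode!r}")
        if self.subst_rate_model not in ("lg", "poisson_uniform"):
            raise SimulationConfigError(f"unknown subst_rate_model {self.subst_rate_model!r}")
        if 2 * self.n_diagnostic > self.n_columns:
            raise SimulationConfigError("2 * n_diagnostic must not exceed n_columns")
        if not 0.0 <= self.placement_fraction <= 1.0:
            raise SimulationConfigError("placement_fraction must be in [0, 1]")

    def model(self) -> SubstitutionModel:
        return lg_model(None) if self.subst_rate_model == "lg" else poisson_model(None)


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated family."""

    fate_of_gene: dict = field(default_factory=dict)       # gene -> 1 | 2 | None
    block_of_species: dict = field(default_factory=dict)   # species -> placement idx | None
    diagnostic_columns: dict = field(default_factory=dict) # "fate1"/"fate2" -> 0-based cols
    extension_columns: list = field(default_factory=list)
    localization: dict = field(default_factory=dict)       # gene -> (compartment, rc)

    def fate_sets(self) -> tuple[set, set]:
        f1 = {g for g, f in self.fate_of_gene.items() if f == 1}
        f2 = {g for g, f in self.fate_of_gene.items() if f == 2}
        return f1, f2

    def to_dict(self) -> dict:
        return asdict(self)


class _Evolver:
    """Vectorized residue evolution with per-site rates and a frozen mask."""

    def __init__(self, model: SubstitutionModel, site_rates: np.ndarray,
                 rng: np.random.Generator):
        self.model = model
        self.site_rates = site_rates
        self.rng = rng
        self._pcache: dict[float, np.ndarray] = {}

    def _pmat(self, t: float) -> np.ndarray:
        key = round(t, 12)
        if key not in self._pcache:
            p = self.model.transition_matrix(t)
            self._pcache[key] = p / p.sum(axis=1, keepdims=True)
        return self._pcache[key]

    def evolve(self, seq: np.ndarray, frozen: np.ndarray, t: float) -> np.ndarray:
        if t <= 0:
            return seq.copy()
        out = seq.copy()
        for rate in np.unique(self.site_rates):
            p = self._pmat(t * float(rate))
            cum = p.cumsum(axis=1)
            sites = np.flatnonzero((self.site_rates == rate) & ~frozen)
            if sites.size == 0:
                continue
            u = self.rng.random(sites.size)
            out[sites] = np.array(
                [np.searchsorted(cum[s], x) for s, x in zip(seq[sites], u)]
            )
        return np.minimum(out, 19)


def _resolve_placements(tree: dendropy.Tree, placements) -> dict:
    """Map each placement (leaf-label tuple) to the dendropy node it subtends."""
    label_sets = [frozenset(p) for p in placements]
    for i, a in enumerate(label_sets):
        for b in label_sets[i + 1:]:
            if a & b:
                raise SimulationConfigError("duplication placements must be disjoint")
    resolved = {}
    for i, labels in enumerate(label_sets):
        taxa = [t for t in tree.taxon_namespace if t.label in labels]
        if len(taxa) != len(labels):
            missing = labels - {t.label for t in taxa}
            raise SimulationConfigError(f"placement species not in tree: {sorted(missing)}")
        node = tree.mrca(taxa=taxa)
        leaf_labels = {lf.taxon.label for lf in node.leaf_iter()}
        if leaf_labels != set(labels):
            raise SimulationConfigError(
                f"placement {sorted(labels)} is not a complete clade (subtends {sorted(leaf_labels)})"
            )
        resolved[id(node)] = i
    return resolved


def simulate_family(cfg: SimConfig) -> tuple[FamilyAlignment, dict, SimTruth]:
    """Generate (alignment, gene->species map, truth) for one family."""
    rng = np.random.default_rng(cfg.seed)
    model = cfg.model()
    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick")
    tree.is_rooted = True
    placement_of = _resolve_placements(tree, cfg.duplication_placements)

    n = cfg.n_columns
    if cfg.gamma_shape is not None:
        cats = discrete_gamma_rates(cfg.gamma_shape, 10)
        site_rates = rng.choice(cats, size=n)
    else:
        site_rates = np.ones(n)
    evolver = _Evolver(model, site_rates, rng)

    root_seq = rng.choice(20, size=n, p=model.frequencies)
    all_cols = rng.permutation(n)[: 2 * cfg.n_diagnostic]
    d1_cols = np.sort(all_cols[: cfg.n_diagnostic])
    d2_cols = np.sort(all_cols[cfg.n_diagnostic:])

    def _fate_residues(cols):
        res = {}
        for c in cols:
            choices = [s for s in range(20) if s != root_seq[c]]
            res[int(c)] = int(rng.choice(choices))
        return res

    fate1_res = _fate_residues(d1_cols)
    fate2_res = _fate_residues(d2_cols)
    if cfg.asymmetry_mode == "one_sided":
        constraints = {1: {**fate1_res, **fate2_res}, 2: {}}
    else:
        constraints = {1: fate1_res, 2: fate2_res}

    truth = SimTruth(
        diagnostic_columns={
            "fate1": [cfg.target_peptide_len + int(c) for c in d1_cols],
            "fate2": [cfg.target_peptide_len + int(c) for c in d2_cols],
        },
        extension_columns=list(range(cfg.target_peptide_len)),
    )
    genes: list[tuple[str, str, np.ndarray, int | None, float]] = []
    # (gene_id, species, body sequence, fate, post-duplication path length)

    def descend(node, seq, frozen, fate, post_len):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            pid = placement_of.get(id(child))
            if pid is not None:
                if fate is not None:
                    raise SimulationConfigError("nested duplication placements")
                pre = evolver.evolve(seq, frozen, t * cfg.placement_fraction)
                rest = t * (1.0 - cfg.placement_fraction)
                for f in (1, 2):
                    fseq = pre.copy()
                    ffrozen = frozen.copy()
                    for col, res in constraints[f].items():
                        fseq[col] = res
                        ffrozen[col] = True
                    fseq = evolver.evolve(fseq, ffrozen, rest)
                    _walk_down(child, fseq, ffrozen, f, rest)
            else:
                nseq = evolver.evolve(seq, frozen, t)
                _walk_down(child, nseq, frozen, fate,
                           post_len + t if fate is not None else 0.0)

    def _walk_down(node, seq, frozen, fate, post_len):
        if node.is_leaf():
            sp = node.taxon.label
            gid = f"{sp}_p{fate}" if fate is not None else f"{sp}_g1"
            genes.append((gid, sp, seq, fate, post_len))
        else:
            descend(node, seq, frozen, fate, post_len)

    frozen0 = np.zeros(n, dtype=bool)
    descend(tree.seed_node, root_seq, frozen0, None, 0.0)

    # N-terminal extension: one ancestral targeting motif, independently
    # re-evolved over each fate-2 gene's post-duplication path length
    tp = cfg.target_peptide_len
    ext = {}
    if tp > 0:
        motif = rng.choice(20, size=tp, p=model.frequencies)
        ext_evolver = _Evolver(model, np.ones(tp), rng)
        nofreeze = np.zeros(tp, dtype=bool)
        for gid, _, _, fate, post_len in sorted(genes):
            if fate == 2:
                ext[gid] = ext_evolver.evolve(motif, nofreeze, post_len)

    records = []
    mapping = {}
    block_by_leaf = {}
    for node, pid in ((nd, placement_of[id(nd)]) for nd in tree.preorder_node_iter()
                      if id(nd) in placement_of):
        for lf in node.leaf_iter():
            block_by_leaf[lf.taxon.label] = pid
    for gid, sp, seq, fate, _ in sorted(genes):
        body = "".join(AMINO_ACIDS[s] for s in seq)
        if tp > 0:
            head = ("".join(AMINO_ACIDS[s] for s in ext[gid]) if gid in ext else "-" * tp)
        else:
            head = ""
        records.append(GeneRecord(gid, sp, head + body))
        mapping[gid] = sp
        truth.fate_of_gene[gid] = fate
        if cfg.loc_labels:
            compartment = cfg.loc_labels.get(fate, "Cyto") if fate else "Cyto"
            truth.localization[gid] = (compartment, 1)
    for taxon in tree.taxon_namespace:
        truth.block_of_species[taxon.label] = block_by_leaf.get(taxon.label)

    return FamilyAlignment(records), mapping, truth


def simulate_quartet(
    true_topology: str,
    n_columns: int = 400,
    t_internal: float = 0.5,
    t_terminal: float = 0.15,
    model: SubstitutionModel | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate one 4-taxon quartet column matrix from a known topology.

    The true tree is ((w,x),(y,z)) with terminal branches ``t_terminal`` and
    internal branch ``t_internal``; the rows of the returned (4, n) matrix
    are ordered (a, b, c, d) so that the sister structure corresponds to the
    requested topology label: Q = (a,b)|(c,d), R = (a,c)|(b,d), S = (a,d)|(b,c).
    """
    if true_topology not in ("Q", "R", "S"):
        raise ValueError(f"unknown topology {true_topology!r}")
    rng = np.random.default_rng(seed)
    model = model or lg_model(None)
    evolver = _Evolver(model, np.ones(n_columns), rng)
    frozen = np.zeros(n_columns, dtype=bool)
    root = rng.choice(20, size=n_columns, p=model.frequencies)
    left = evolver.evolve(root, frozen, t_internal / 2.0)
    right = evolver.evolve(root, frozen, t_internal / 2.0)
    w = evolver.evolve(left, frozen, t_terminal)
    x = evolver.evolve(left, frozen, t_terminal)
    y = evolver.evolve(right, frozen, t_terminal)
    z = evolver.evolve(right, frozen, t_terminal)
    order = {"Q": (w, x, y, z), "R": (w, y, x, z), "S": (w, y, z, x)}[true_topology]
    return np.vstack(order)


def write_fixture(
    aln: FamilyAlignment,
    mapping: dict,
    truth: SimTruth,
    outdir: str | Path,
) -> dict:
    """Write FASTA + map TSV + truth JSON (+ localization TSV) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "family.fasta",
        "map": outdir / "gene_species.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(aln, paths["alignment"])
    with open(paths["map"], "w") as fh:
        for gid in sorted(mapping):
            fh.write(f"{gid}\t{mapping[gid]}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
    if truth.localization:
        paths["localization"] = outdir / "localization.tsv"
        with open(paths["localization"], "w") as fh:
            fh.write("gene_id\tcompartment\treliability_class\n")
            for gid in sorted(truth.localization):
                comp, rc = truth.localization[gid]
                fh.write(f"{gid}\t{comp}\t{rc}\n")
    return {k: str(v) for k, v in paths.items()}
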
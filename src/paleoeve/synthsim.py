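"""Synthetic genomic datasets with known ground truth.

Generates a calibrated (ultrametric) host species tree, an ancestral locus
consisting of three upstream and three downstream protein-coding landmark
genes flanking a multi-gene endogenous viral element (EVE), and evolves the
locus neutrally along the host tree under GTR+Gamma with indels.  The EVE is
carried only by descendants of a chosen insertion branch and may be lost in
individual lineages; every emitted dataset carries a truth record (presence
flags, per-taxon feature coordinates, planted inactivating mutations) against
which downstream presence calling, dating, and neutrality testing can be
scored.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .models import GTRModel

ULTRAMETRIC_TOL = 1e-6
_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the ultrametric age model."""


# ---------------------------------------------------------------------------
# Host tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None
    age: float
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def tip_labels(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.postorder() if n.is_leaf)


class HostTree:
    """Rooted species tree with node ages in million years (My).

    All tips sit at age 0 and every internal node is strictly older than its
    children (ultrametric within :data:`ULTRAMETRIC_TOL`).  Branches are
    identified by the set of tip labels descending from their child node.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._clades: dict[frozenset[str], TreeNode] = {}
        self._parents: dict[int, TreeNode | None] = {id(root): None}
        for node in root.postorder():
            self._clades[frozenset(node.tip_labels())] = node
            for child in node.children:
                self._parents[id(child)] = node
        self._validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick_text: str) -> "HostTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick_text, schema="newick",
                suppress_internal_node_taxa=True, preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        if dtree.seed_node is None or not dtree.leaf_nodes():
            raise NewickParseError("Newick string contains no taxa")

        # depth of every node from the root, then ages as root_age - depth
        depths: dict[int, float] = {id(dtree.seed_node): 0.0}
        for edge in dtree.preorder_edge_iter():
            if edge.head_node is dtree.seed_node:
                continue
            length = edge.length if edge.length is not None else 0.0
            depths[id(edge.head_node)] = depths[id(edge.tail_node)] + length
        tip_depths = [depths[id(n)] for n in dtree.leaf_node_iter()]
        root_age = max(tip_depths)
        if root_age - min(tip_depths) > ULTRAMETRIC_TOL and len(tip_depths) > 1:
            raise TreeValidationError(
                "tree is not ultrametric: tip depths span "
                f"{min(tip_depths):g}..{max(tip_depths):g} My"
            )

        def build(dnode) -> TreeNode:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            age = root_age - depths[id(dnode)]
            node = TreeNode(label=label, age=0.0 if dnode.is_leaf() else age)
            node.children = [build(c) for c in dnode.child_nodes()]
            return node

        return cls(build(dtree.seed_node))

    def _validate(self) -> None:
        for node in self.root.postorder():
            if not np.isfinite(node.age) or node.age < 0:
                raise TreeValidationError(f"node age {node.age!r} is not a finite nonnegative number")
            for child in node.children:
                if not child.age < node.age:
                    raise TreeValidationError(
                        f"degenerate branch: child age {child.age:g} not strictly "
                        f"below parent age {node.age:g}"
                    )

    # -- queries -----------------------------------------------------------
    @property
    def taxa(self) -> tuple[str, ...]:
        return self.root.tip_labels()

    @property
    def root_age(self) -> float:
        return self.root.age

    def parent(self, node: TreeNode) -> TreeNode | None:
        return self._parents[id(node)]

    def node_for_clade(self, taxa) -> TreeNode | None:
        """Node whose descendant tip set is exactly ``taxa`` (or None)."""
        return self._clades.get(frozenset(taxa))

    def mrca(self, taxa) -> TreeNode:
        wanted = frozenset(taxa)
        unknown = wanted - set(self.taxa)
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        best = self.root
        for clade, node in self._clades.items():
            if wanted <= clade and len(clade) < len(frozenset(best.tip_labels())):
                best = node
        return best

    def mrca_age(self, taxa) -> float:
        return self.mrca(taxa).age

    def restricted_newick(self, keep, scale: float = 1.0) -> str:
        """Newick of the tree restricted to ``keep`` tips, lengths in My*scale."""
        keep = set(keep)

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return TreeNode(node.label, 0.0) if node.label in keep else None
            kids = [p for p in (prune(c) for c in node.children) if p is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return TreeNode(node.label, node.age, kids)

        sub = prune(self.root)
        if sub is None:
            raise ValueError("no requested tips present in tree")

        def fmt(node: TreeNode, parent_age: float) -> str:
            length = (parent_age - node.age) * scale
            if node.is_leaf:
                return f"{node.label}:{length:.8g}"
            inner = ",".join(fmt(c, node.age) for c in node.children)
            return f"({inner}):{length:.8g}"

        if sub.is_leaf:
            return f"{sub.label};"
        inner = ",".join(fmt(c, sub.age) for c in sub.children)
        return f"({inner});"


def build_host_tree(newick_text: str) -> HostTree:
    """Parse and validate a calibrated species tree from Newick text."""
    return HostTree.from_newick(newick_text)


#: A 14-taxon mammal-like topology: 12 ingroup ("placental") taxa whose crown
#: node sits at 102 My, a marsupial-like outgroup splitting at 172 My and a
#: monotreme-like outgroup at 187 My; subclade ages loosely follow published
#: mammal timetrees.
_BOREO = "((((Homo:8,Pan:8):66,Macaca:74):16,(Mus:70,Rattus:70):20):6,(Canis:78,Felis:78):18):6"
_AFROXEN = "(((Loxodonta:60,Trichechus:60):39,Orycteropus:99):1,(Dasypus:68,Choloepus:68):32):2"
DEFAULT_HOST_NEWICK = (
    f"((({_BOREO},{_AFROXEN}):70,Didelphis:172):15,Ornithorhynchus:187);"
)


def default_host_tree() -> HostTree:
    return HostTree.from_newick(DEFAULT_HOST_NEWICK)

#: tips that descend from the stem-"placental" insertion branch of the
#: default host tree
DEFAULT_PLACENTALS = (
    "Homo", "Pan", "Macaca", "Mus", "Rattus", "Canis", "Felis",
    "Loxodonta", "Trichechus", "Orycteropus", "Dasypus", "Choloepus",
)


# ---------------------------------------------------------------------------
# Templates and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    name: str
    aa_length: int
    strand: int = 1


#: Canonical core-gene order of the ancestral element (forward strand), with
#: desk-scale protein lengths.  The integrase (INT) and major capsid (MCP)
#: share the strand, as in intact vertebrate elements.
DEFAULT_CORE_GENES = (
    GeneSpec("POLB", 300), GeneSpec("INT", 150), GeneSpec("PM", 110),
    GeneSpec("PW", 110), GeneSpec("PZ", 110), GeneSpec("ATPase", 130),
    GeneSpec("PRO", 90), GeneSpec("mCP", 130), GeneSpec("MCP", 210),
)


@dataclass(frozen=True)
class EveTemplate:
    """Blueprint of the ancestral element: ordered genes, TIRs, spacers."""

    genes: tuple[GeneSpec, ...] = DEFAULT_CORE_GENES
    tir_length: int = 60
    intergenic_length: int = 30

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        if self.tir_length < 0 or self.intergenic_length < 0:
            raise ValueError("lengths must be nonnegative")

    @property
    def nt_length(self) -> int:
        genes = sum(3 * g.aa_length + 3 for g in self.genes)
        return 2 * self.tir_length + genes + self.intergenic_length * max(len(self.genes) - 1, 0)


@dataclass
class SimulationConfig:
    """All knobs of the generator; one explicit seed drives everything.

    The defaults are the study conditions emulated throughout: neutral
    evolution at 0.0027 substitutions/site/My, GTR close to Jukes-Cantor,
    moderate gamma rate variation, indels at 0.1x the substitution rate with
    geometric lengths of mean 3 nt.
    """

    exchangeabilities: tuple[float, ...] = (1.0,) * 6
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = 1.0
    n_categories: int = 4
    clock_rate: float = 0.0027          # substitutions/site/My
    branch_rate_sigma: float = 0.0      # stdev of lognormal per-branch multipliers
    indel_rate_factor: float = 0.1      # indel events per substitution
    indel_mean_length: float = 3.0      # geometric mean length, nt
    loss_probability: float = 0.0       # per-carrier-tip EVE loss
    landmark_rate_factor: float = 0.25  # purifying constraint on landmark genes
    landmarks_per_side: int = 3
    landmark_aa_length: int = 160
    spacer_length: int = 120            # between landmarks / around the EVE
    flank_noncoding: int = 1500         # bare noncoding at each locus end
    seed: int = 0

    def __post_init__(self):
        self.exchangeabilities = tuple(self.exchangeabilities)
        self.base_freqs = tuple(self.base_freqs)
        if any(x < 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be nonnegative")
        if abs(sum(self.base_freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if self.clock_rate < 0 or self.indel_rate_factor < 0 or self.branch_rate_sigma < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.loss_probability <= 1.0:
            raise ValueError("loss probability must be in [0, 1]")
        if self.landmark_rate_factor < 0:
            raise ValueError("landmark rate factor must be nonnegative")
        if self.landmarks_per_side < 1:
            raise ValueError("need at least one landmark per side")

    def model(self) -> GTRModel:
        return GTRModel(self.exchangeabilities, self.base_freqs,
                        self.gamma_shape, self.n_categories)


# ---------------------------------------------------------------------------
# Ancestral locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """0-based half-open interval on the ancestral locus."""
    name: str
    kind: str          # landmark | eve_gene | TIR | eve
    start: int
    end: int
    strand: int = 1


@dataclass
class AncestralLocus:
    sequence: str
    features: list[Feature]
    landmark_proteins: dict[str, str]
    core_proteins: dict[str, str]
    template: EveTemplate

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def eve_interval(self) -> tuple[int, int]:
        f = self.feature("EVE")
        return f.start, f.end

    @property
    def upstream_landmarks(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "landmark" and f.name.startswith("UP")]

    @property
    def downstream_landmarks(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "landmark" and f.name.startswith("DN")]


_STANDARD_TABLE: dict[str, str] = {}
_CODON_LUT: np.ndarray | None = None    # (5,5,5) byte lookup, index 4 = N/other
_NT_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _NT_CODE[_b] = _i


def _codon_table() -> dict[str, str]:
    if not _STANDARD_TABLE:
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[1]
        _STANDARD_TABLE.update(table.forward_table)
        for stop in table.stop_codons:
            _STANDARD_TABLE[stop] = "*"
    return _STANDARD_TABLE


def _codon_lut() -> np.ndarray:
    global _CODON_LUT
    if _CODON_LUT is None:
        lut = np.full((5, 5, 5), ord("X"), dtype=np.uint8)
        for codon, aa in _codon_table().items():
            i, j, k = ("ACGT".index(c) for c in codon)
            lut[i, j, k] = ord(aa)
        _CODON_LUT = lut
    return _CODON_LUT


def translate_codons(seq: str) -> str:
    """Translate an in-frame nucleotide string; codons containing N become X."""
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    codes = _NT_CODE[np.frombuffer(seq[:n].encode(), np.uint8)].reshape(-1, 3)
    return _codon_lut()[codes[:, 0], codes[:, 1], codes[:, 2]].tobytes().decode()


def _random_orf(rng: np.random.Generator, aa_length: int) -> str:
    """Stop-free ORF: ATG + random sense codons + one stop codon."""
    body = rng.choice(len(_SENSE_CODONS), size=aa_length - 1)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in body]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int, freqs) -> str:
    idx = rng.choice(4, size=length, p=np.asarray(freqs, dtype=float))
    return "".join(_BASES[i] for i in idx)


def simulate_ancestral_locus(
    config: SimulationConfig,
    template: EveTemplate | None = None,
    seed: int | None = None,
) -> AncestralLocus:
    """Build the ancestral locus: landmarks, spacers, and the intact EVE.

    Layout (forward strand): noncoding flank, UP1..UPk landmarks with spacers,
    spacer, [TIR, gene1, ..., geneN, TIR], spacer, DN1..DNk landmarks,
    noncoding flank.  Landmark and EVE ORFs are stop-free at creation; TIRs
    are exact reverse complements.
    """
    template = template or EveTemplate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    freqs = config.base_freqs

    parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(seq: str, name: str | None = None, kind: str | None = None, strand: int = 1):
        nonlocal pos
        parts.append(seq)
        if name is not None:
            features.append(Feature(name, kind, pos, pos + len(seq), strand))
        pos += len(seq)

    landmark_proteins: dict[str, str] = {}
    core_proteins: dict[str, str] = {}

    emit(_random_nt(rng, config.flank_noncoding, freqs))
    for i in range(config.landmarks_per_side):
        orf = _random_orf(rng, config.landmark_aa_length)
        name = f"UP{i + 1}"
        landmark_proteins[name] = translate_codons(orf)[: config.landmark_aa_length]
        emit(orf, name, "landmark")
        emit(_random_nt(rng, config.spacer_length, freqs))

    eve_start = pos
    tir = _random_nt(rng, template.tir_length, freqs)
    if template.tir_length:
        emit(tir, "TIR5", "TIR")
    for j, gene in enumerate(template.genes):
        orf = _random_orf(rng, gene.aa_length)
        core_proteins[gene.name] = translate_codons(orf)[: gene.aa_length]
        emit(orf if gene.strand == 1 else reverse_complement(orf),
             gene.name, "eve_gene", gene.strand)
        if j < len(template.genes) - 1:
            emit(_random_nt(rng, template.intergenic_length, freqs))
    if template.tir_length:
        emit(reverse_complement(tir), "TIR3", "TIR")
    features.append(Feature("EVE", "eve", eve_start, pos))

    emit(_random_nt(rng, config.spacer_length, freqs))
    for i in range(config.landmarks_per_side):
        orf = _random_orf(rng, config.landmark_aa_length)
        name = f"DN{i + 1}"
        landmark_proteins[name] = translate_codons(orf)[: config.landmark_aa_length]
        emit(orf, name, "landmark")
        if i < config.landmarks_per_side - 1:
            emit(_random_nt(rng, config.spacer_length, freqs))
    emit(_random_nt(rng, config.flank_noncoding, freqs))

    return AncestralLocus("".join(parts), features, landmark_proteins,
                          core_proteins, template)


# ---------------------------------------------------------------------------
# Evolution along the host tree
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    insertion_clade: frozenset[str]
    insertion_parent_age: float
    insertion_child_age: float
    presence: dict[str, bool]
    lost: set[str] = field(default_factory=set)
    planted_stops: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    planted_frameshifts: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """Per-taxon sequences plus coordinate-tracked ancestry.

    ``site_ids[taxon]`` maps each position of that taxon's sequence to the
    ancestral locus column it descends from (-1 for lineage-specific
    insertions), which makes features liftable and the true alignment
    reconstructible.
    """

    tree: HostTree
    config: SimulationConfig
    ancestral: AncestralLocus
    codes: dict[str, np.ndarray]
    site_ids: dict[str, np.ndarray]
    truth: TruthRecord

    def sequence(self, taxon: str) -> str:
        return "".join(_BASES[i] for i in self.codes[taxon])

    def sequences(self) -> dict[str, str]:
        return {t: self.sequence(t) for t in self.tree.taxa}

    def feature_interval(self, taxon: str, name: str) -> tuple[int, int] | None:
        """Lift an ancestral feature to a taxon (None when fully deleted)."""
        feat = self.ancestral.feature(name)
        ids = self.site_ids[taxon]
        idx = np.nonzero((ids >= feat.start) & (ids < feat.end))[0]
        if idx.size == 0:
            return None
        return int(idx[0]), int(idx[-1]) + 1

    def true_alignment(self, taxa=None, columns: tuple[int, int] | None = None):
        """Gap-aware alignment over ancestral columns (insertions dropped)."""
        from .alnkit import MultipleAlignment

        taxa = list(taxa) if taxa is not None else list(self.tree.taxa)
        lo, hi = columns if columns is not None else (0, len(self.ancestral.sequence))
        width = hi - lo
        rows = []
        for taxon in taxa:
            ids = self.site_ids[taxon]
            keep = np.nonzero((ids >= lo) & (ids < hi))[0]
            row = np.full(width, ord("-"), dtype=np.uint8)
            row[ids[keep] - lo] = np.frombuffer(_BASES.encode(), np.uint8)[self.codes[taxon][keep]]
            rows.append(row.tobytes().decode())
        return MultipleAlignment(list(taxa), rows)


def _geometric_lengths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    p = 1.0 / max(mean, 1.0)
    return rng.geometric(p, size=n)


def _evolve_branch(rng, codes, cats, site_ids, model, rates_ext, n_neutral_cats,
                   distance, config):
    """Substitutions then indels along one branch; returns new arrays.

    ``cats`` indexes ``rates_ext``: the first ``n_neutral_cats`` entries are
    the neutral gamma categories, the rest are the same categories scaled by
    the landmark conservation factor.  Indels are rejection-sampled away from
    landmark sites (functional genes do not tolerate frameshifts).
    """
    if distance > 0 and len(codes):
        p = model.transition_matrices(rates_ext * distance)
        cum = np.cumsum(p, axis=2)
        rows = cum[cats, codes]                     # (L, 4)
        u = rng.random(len(codes))
        codes = (u[:, None] > rows).sum(axis=1).astype(np.int8)
        np.clip(codes, 0, 3, out=codes)

    n_indels = rng.poisson(config.indel_rate_factor * distance * len(codes))
    if n_indels:
        lengths = _geometric_lengths(rng, n_indels, config.indel_mean_length)
        for length in lengths:
            L = len(codes)
            if L == 0:
                break
            protected = cats >= n_neutral_cats
            for _try in range(10):
                pos = int(rng.integers(L))
                if rng.random() < 0.5:  # deletion
                    end = min(pos + int(length), L)
                    if protected[pos:end].any():
                        continue
                    keep = np.concatenate([np.arange(pos), np.arange(end, L)])
                    codes, cats, site_ids = codes[keep], cats[keep], site_ids[keep]
                else:  # insertion
                    if 0 < pos < L and protected[pos - 1] and protected[pos]:
                        continue
                    ins_codes = rng.choice(4, size=int(length),
                                           p=np.asarray(config.base_freqs)).astype(np.int8)
                    ins_cats = rng.integers(n_neutral_cats, size=int(length))
                    codes = np.concatenate([codes[:pos], ins_codes, codes[pos:]])
                    cats = np.concatenate([cats[:pos], ins_cats, cats[pos:]])
                    site_ids = np.concatenate(
                        [site_ids[:pos], np.full(int(length), -1, dtype=site_ids.dtype),
                         site_ids[pos:]])
                break
    return codes, cats, site_ids


def evolve_locus(
    tree: HostTree,
    ancestral: AncestralLocus,
    config: SimulationConfig,
    insertion_clade,
    seed: int | None = None,
) -> SimulatedDataset:
    """Evolve the ancestral locus along the host tree.

    ``insertion_clade`` is the tip set of the branch on which the EVE
    inserted; tips outside that clade have the EVE interval excised (flanks
    joined), emulating a pre-insertion state.  Per-site gamma categories are
    drawn once and inherited; per-branch rate multipliers are lognormal with
    mean 1 when ``branch_rate_sigma`` > 0.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    node = tree.node_for_clade(insertion_clade)
    if node is None:
        raise ValueError("insertion clade does not correspond to a branch of the host tree")
    parent = tree.parent(node)
    parent_age = parent.age if parent is not None else float("inf")
    carriers = set(node.tip_labels())

    model = config.model()
    cat_rates = model.category_rates
    n_neutral = len(cat_rates)
    rates_ext = np.concatenate([cat_rates, cat_rates * config.landmark_rate_factor])
    L = len(ancestral.sequence)
    root_codes = np.frombuffer(ancestral.sequence.encode(), np.uint8)
    lookup = np.full(256, -1, np.int8)
    for i, b in enumerate(_BASES):
        lookup[ord(b)] = i
    root_codes = lookup[root_codes]
    root_cats = rng.integers(n_neutral, size=L)
    for feat in ancestral.features:
        if feat.kind == "landmark":
            root_cats[feat.start:feat.end] += n_neutral
    root_ids = np.arange(L, dtype=np.int64)

    codes_out: dict[str, np.ndarray] = {}
    ids_out: dict[str, np.ndarray] = {}

    def descend(tnode: TreeNode, codes, cats, ids):
        if tnode.is_leaf:
            codes_out[tnode.label] = codes
            ids_out[tnode.label] = ids
            return
        for child in tnode.children:
            duration = tnode.age - child.age
            mult = 1.0
            if config.branch_rate_sigma > 0:
                s = config.branch_rate_sigma
                mult = rng.lognormal(-0.5 * s * s, s)
            dist = duration * config.clock_rate * mult
            c, k, i = _evolve_branch(rng, codes, cats, ids, model, rates_ext,
                                     n_neutral, dist, config)
            descend(child, c, k, i)

    descend(tree.root, root_codes, root_cats, root_ids)

    eve_lo, eve_hi = ancestral.eve_interval
    for taxon in tree.taxa:
        if taxon not in carriers:
            codes_out[taxon], ids_out[taxon] = _excise_interval(
                codes_out[taxon], ids_out[taxon], eve_lo, eve_hi)

    truth = TruthRecord(
        insertion_clade=frozenset(carriers),
        insertion_parent_age=parent_age,
        insertion_child_age=node.age,
        presence={t: t in carriers for t in tree.taxa},
    )
    return SimulatedDataset(tree, config, ancestral, codes_out, ids_out, truth)


def _excise_interval(codes, ids, lo, hi):
    """Remove the contiguous span of sites descending from columns [lo, hi)."""
    idx = np.nonzero((ids >= lo) & (ids < hi))[0]
    if idx.size == 0:
        return codes, ids
    start, end = int(idx[0]), int(idx[-1]) + 1
    keep = np.concatenate([np.arange(start), np.arange(end, len(codes))])
    return codes[keep], ids[keep]


def apply_losses(dataset: SimulatedDataset, loss_probability: float,
                 seed: int) -> SimulatedDataset:
    """Delete the EVE from each carrier tip independently with given probability.

    Returns a new dataset; flanks are joined and presence flags updated.
    """
    if not 0.0 <= loss_probability <= 1.0:
        raise ValueError("loss probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = copy.copy(dataset)
    out.codes = dict(dataset.codes)
    out.site_ids = dict(dataset.site_ids)
    out.truth = replace(dataset.truth,
                        presence=dict(dataset.truth.presence),
                        lost=set(dataset.truth.lost))
    lo, hi = dataset.ancestral.eve_interval
    for taxon in dataset.tree.taxa:
        if out.truth.presence.get(taxon) and rng.random() < loss_probability:
            out.codes[taxon], out.site_ids[taxon] = _excise_interval(
                out.codes[taxon], out.site_ids[taxon], lo, hi)
            out.truth.presence[taxon] = False
            out.truth.lost.add(taxon)
    return out


def simulate_neighborhood(
    tree: HostTree,
    config: SimulationConfig,
    length: int,
    seed: int,
):
    """Neutral noncoding neighbourhood: aligned columns, substitutions only.

    Emulates the broad genomic surroundings from which null regions are
    resampled.  Sites are iid under the configured GTR+Gamma process at the
    neutral clock rate; indels are not applied, so rows are natively aligned
    (pairwise-deletion distances are insensitive to this).  Returns a
    :class:`~paleoeve.alnkit.MultipleAlignment` over all tree taxa.
    """
    from .alnkit import MultipleAlignment

    rng = np.random.default_rng(seed)
    model = config.model()
    cat_rates = model.category_rates
    cats = rng.integers(len(cat_rates), size=length)
    root = rng.choice(4, size=length, p=np.asarray(config.base_freqs)).astype(np.int8)
    rows: dict[str, np.ndarray] = {}

    def descend(tnode: TreeNode, codes):
        if tnode.is_leaf:
            rows[tnode.label] = codes
            return
        for child in tnode.children:
            duration = tnode.age - child.age
            mult = 1.0
            if config.branch_rate_sigma > 0:
                s = config.branch_rate_sigma
                mult = rng.lognormal(-0.5 * s * s, s)
            dist = duration * config.clock_rate * mult
            if dist > 0:
                p = model.transition_matrices(cat_rates * dist)
                # resample only sites that actually change state
                stay = p[cats, codes, codes]
                u = rng.random(length)
                new = codes.copy()
                hit = np.nonzero(u >= stay)[0]
                if hit.size:
                    pr = p[cats[hit], codes[hit]]            # (h, 4)
                    pr[np.arange(hit.size), codes[hit]] = 0.0
                    cum = np.cumsum(pr, axis=1)
                    cum /= cum[:, -1:]
                    v = rng.random(hit.size)
                    new[hit] = (v[:, None] > cum).sum(axis=1).clip(0, 3)
            else:
                new = codes
            descend(child, new)

    descend(tree.root, root)
    alpha = np.frombuffer(_BASES.encode(), np.uint8)
    return MultipleAlignment(
        list(tree.taxa),
        [alpha[rows[t]].tobytes().decode() for t in tree.taxa])


def simulate_dataset(
    config: SimulationConfig,
    tree: HostTree | None = None,
    template: EveTemplate | None = None,
    insertion_clade=None,
    seed: int | None = None,
) -> SimulatedDataset:
    """One-call generator: ancestral locus, evolution, lineage losses."""
    tree = tree or default_host_tree()
    insertion_clade = insertion_clade or DEFAULT_PLACENTALS
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s_locus, s_evolve, s_loss = rng.integers(2**31 - 1, size=3)
    ancestral = simulate_ancestral_locus(config, template, int(s_locus))
    dataset = evolve_locus(tree, ancestral, config, insertion_clade, int(s_evolve))
    if config.loss_probability > 0:
        dataset = apply_losses(dataset, config.loss_probability, int(s_loss))
    return dataset


# ---------------------------------------------------------------------------
# Deterministically planted inactivating mutations
# ---------------------------------------------------------------------------

@dataclass
class InactivationCase:
    """A probe protein and a subject carrying known stops / frameshifts.

    ``stop_positions`` are forward-strand coordinates of the first nucleotide
    of each planted in-frame stop codon; ``frameshift_positions`` are the
    junction coordinates at which the reading frame changes (the coordinate
    reported by the annotator for an exact breakpoint).
    """

    probe: str
    subject: str
    stop_positions: list[int]
    frameshift_positions: list[int]


def _prefix_scores_nonpositive(matrix, probe_run: str, codon_chunks: list[str]) -> bool:
    """True when every prefix of the aligned extension scores <= 0.

    ``probe_run``/``codon_chunks`` are the residues and subject codons a local
    alignment would consume if it extended past a planted junction; requiring
    all prefix sums to stay non-positive guarantees the optimal alignment
    stops exactly at the junction.
    """
    total = 0
    for res, chunk in zip(probe_run, codon_chunks):
        if len(chunk) < 3:
            break
        aa = translate_codons(chunk)
        total += matrix.score(aa[0] if aa else "X", res)
        if total > 0:
            return False
    return True


def make_inactivation_case(
    rng: np.random.Generator,
    aa_length: int = 80,
    n_stops: int = 1,
    n_frameshifts: int = 0,
    frameshift_kind: str = "deletion",
    guard_codons: int = 15,
) -> InactivationCase:
    """Construct an unambiguous planted-inactivation test case.

    The subject starts as the exact coding sequence of the probe; selected
    codons are replaced by TAA (premature stops) and, optionally, one single
    nucleotide is deleted or inserted at a codon boundary (frameshift).
    Junctions are rejection-sampled so that local alignments extended across
    the break only lose score (all prefix sums non-positive over
    ``guard_codons`` codons), which makes the breakpoint recoverable at
    single-nucleotide resolution.
    """
    if n_frameshifts not in (0, 1):
        raise ValueError("at most one frameshift per constructed case")
    from .seqsearch import ScoringMatrix, SearchParams, local_align_translated

    matrix = ScoringMatrix.blosum45()
    verify_params = SearchParams(exhaustive=True, evalue_max=None,
                                 min_raw_score=16.0)
    for _attempt in range(500):
        codons = [_SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=aa_length)]
        probe = translate_codons("".join(codons))
        positions = rng.permutation(np.arange(4, aa_length - 4))
        chosen: list[int] = []
        for p in positions:
            if all(abs(p - q) >= 4 for q in chosen):
                chosen.append(int(p))
            if len(chosen) == n_stops + n_frameshifts:
                break
        if len(chosen) < n_stops + n_frameshifts:
            continue
        stop_codon_idx = sorted(chosen[:n_stops])

        work = list(codons)
        for idx in stop_codon_idx:
            work[idx] = "TAA"
        seq = "".join(work)

        if not n_frameshifts:
            return InactivationCase(probe, seq,
                                    [3 * i for i in stop_codon_idx], [])

        k = chosen[n_stops]
        cut = 3 * k
        if frameshift_kind == "deletion":
            cand = seq[:cut] + seq[cut + 1:]
            # upstream HSP would extend with probe[k+m] vs cand[cut+3m:...]
            fwd_chunks = [cand[cut + 3 * m: cut + 3 * m + 3] for m in range(guard_codons)]
            fwd_run = probe[k:k + guard_codons]
            # downstream HSP (probe[k+1:] vs frame starting at cut+2) would
            # extend backwards with probe[k-m] vs cand[3(k-m)-1:3(k-m)+2]
            back_chunks = [cand[3 * (k - m) - 1: 3 * (k - m) + 2] for m in range(guard_codons)]
            back_run = probe[k::-1][:guard_codons]
        elif frameshift_kind == "insertion":
            base = _BASES[rng.integers(4)]
            cand = seq[:cut] + base + seq[cut:]
            fwd_chunks = [cand[cut + 3 * m: cut + 3 * m + 3] for m in range(guard_codons)]
            fwd_run = probe[k:k + guard_codons]
            # downstream HSP starts at probe[k] vs cand[cut+1:]; backward
            # extension pairs probe[k-m] with cand[3(k-m)-2:3(k-m)+1]
            back_chunks = [cand[3 * (k - m) - 2: 3 * (k - m) + 1] for m in range(1, guard_codons)]
            back_run = probe[k - 1::-1][:guard_codons - 1]
        else:
            raise ValueError("frameshift_kind must be 'deletion' or 'insertion'")

        if not _prefix_scores_nonpositive(matrix, fwd_run, fwd_chunks):
            continue
        if not _prefix_scores_nonpositive(matrix, back_run, back_chunks):
            continue

        # the junction is only well-defined when the optimal local
        # alignments stop exactly at it; verify by exhaustive alignment
        # (the case contract is single-nucleotide recoverability)
        down_start = cut + 2 if frameshift_kind == "deletion" else cut + 1
        hsps = local_align_translated(probe, cand, matrix, verify_params)
        plus = [h for h in hsps if h.frame > 0]
        if not any(h.subject_end == cut for h in plus):
            continue
        if not any(h.subject_start == down_start for h in plus):
            continue
        if any(h.subject_start < cut < h.subject_end for h in plus):
            continue

        shift = -1 if frameshift_kind == "deletion" else 1
        stop_positions = [3 * i + (shift if 3 * i > cut else 0) for i in stop_codon_idx]
        return InactivationCase(probe, cand, sorted(stop_positions), [cut])
    raise RuntimeError("could not construct an unambiguous inactivation case")
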
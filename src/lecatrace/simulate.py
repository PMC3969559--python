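"""Synthetic gene families with known origins, for end-to-end testing.

The generator emulates the statistical structure of a three-domain
phylogenomic screen: a species design with monophyletic prokaryotic groups
(defaults matching the reference prokaryote sampling) and a eukaryote panel
spanning the four supergroups; gene families derived from the species tree
with per-species gene loss and prokaryote-to-prokaryote transfers; a
eukaryote clade whose attachment encodes the family's true origin scenario;
and bootstrap-like replicate ensembles whose topological stability around the
eukaryote attachment point is directly controllable.

Replicates are emulated topologically (detach/re-attach the eukaryote clan,
random NNI moves) rather than by resampling alignment columns: the pipeline
consumes trees only, and topological perturbation gives analytic control of
the expected node bootstrap support — with attachment-perturbation
probability q, a replicate retains the original base tripartition with
probability 1 - q.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .configurations import DEFAULT_GROUP_TABLE
from .taxonomy import TaxonomyMap, TaxonRecord
from .trees import GeneTree

VERTICAL_ARCHAEAL = "VERTICAL_ARCHAEAL"
EGT_FROM = "EGT_FROM"
LUCA_THREE_DOMAIN = "LUCA_THREE_DOMAIN"
UNCLEAR_MIX = "UNCLEAR_MIX"
SCENARIOS = (VERTICAL_ARCHAEAL, EGT_FROM, LUCA_THREE_DOMAIN, UNCLEAR_MIX)

ARCHAEAL_GROUPS = frozenset(
    ("Crenarchaeota", "Euryarchaeota", "Korarchaeota", "Thaumarchaeota"))

SUPERGROUP_PANEL = {
    "Unikonts": 6,
    "Plantae": 5,
    "Chromalveolates": 5,
    "Kinetoplastids": 2,
    "OtherEukaryote": 1,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    name: str
    domain: str
    n_species: int


def default_prokaryote_design() -> tuple[GroupSpec, ...]:
    """Reference sampling: one GroupSpec per group, species counts from the
    group threshold table (39 archaeal + 144 bacterial species)."""
    out = []
    for name, (sampled, _) in sorted(DEFAULT_GROUP_TABLE.items()):
        domain = "Archaea" if name in ARCHAEAL_GROUPS else "Bacteria"
        out.append(GroupSpec(name, domain, sampled))
    return tuple(out)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    prokaryote_groups: tuple = field(default_factory=default_prokaryote_design)
    eukaryote_panel: Mapping[str, int] = field(
        default_factory=lambda: dict(SUPERGROUP_PANEL))
    scenario: str = EGT_FROM
    donor_group: str | None = "Alphaproteobacteria"
    loss_prob: float = 0.0
    hgt_rate: float = 0.0
    n_replicates: int = 100
    q_attach: float = 0.0       # prob. a replicate perturbs the euk attachment
    r_nni: float = 0.0          # prob. a replicate NNI-perturbs a random edge
    kernel_decay: float = 0.5   # distance decay of the re-attachment kernel
    branch_length_mean: float = 0.2

    def __post_init__(self):
        for p in (self.loss_prob, self.q_attach, self.r_nni):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must be in [0, 1]")
        if self.scenario not in SCENARIOS:
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == EGT_FROM and self.donor_group is None:
            raise SimulationError("EGT scenario needs a donor group")
        n_prok = sum(g.n_species for g in self.prokaryote_groups)
        n_euk = sum(self.eukaryote_panel.values())
        if len(self.prokaryote_groups) < 1 or n_prok + n_euk < 4:
            raise SimulationError("degenerate species design")
        if self.scenario == EGT_FROM and self.donor_group not in {
                g.name for g in self.prokaryote_groups}:
            raise SimulationError(
                f"donor group {self.donor_group!r} absent from species design")


# --------------------------------------------------------------- node model

class _Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=0.0):
        self.label = label
        self.length = length
        self.children = []
        self.parent = None

    def add(self, child):
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self):
        return not self.children


def _clone(node: _Node) -> _Node:
    c = _Node(node.label, node.length)
    for w in node.children:
        c.add(_clone(w))
    return c


def _iter_nodes(root: _Node):
    stack = [root]
    while stack:
        v = stack.pop()
        yield v
        stack.extend(v.children)


def _leaves(root: _Node) -> list[_Node]:
    return [v for v in _iter_nodes(root) if v.is_leaf()]


def _leaf_labels(root: _Node) -> frozenset:
    return frozenset(v.label for v in _leaves(root))


def _suppress_if_unary(node: _Node, root: _Node) -> _Node:
    """Suppress a unary node (merging lengths); returns the (possibly new) root."""
    while node is not None and len(node.children) == 1:
        (child,) = node.children
        if node.parent is None:
            child.parent = None
            child.length = 0.0
            return child
        child.length += node.length
        child.parent = node.parent
        node.parent.children[node.parent.children.index(node)] = child
        node = node.parent if len(node.parent.children) == 1 else None
    return root


def _detach(root: _Node, node: _Node) -> tuple[_Node, _Node | None]:
    """Remove ``node``'s subtree. Returns (new root, anchor) where the
    anchor's stem edge occupies the original attachment position (None when
    the attachment neighborhood became the root)."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    sibling = parent.children[0] if len(parent.children) == 1 else None
    root = _suppress_if_unary(parent, root)
    if sibling is not None and sibling.parent is not None:
        return root, sibling
    return root, None


def _attach(root: _Node, edge_child: _Node, subtree: _Node,
            frac: float, stem_length: float) -> _Node:
    """Insert a new node on the edge above ``edge_child`` and hang ``subtree``
    from it; ``frac`` positions the node along the edge (0 = at the parent)."""
    parent = edge_child.parent
    if parent is None:
        raise SimulationError("cannot attach on the root")
    joint = _Node(None, edge_child.length * frac)
    edge_child.length *= (1.0 - frac)
    parent.children[parent.children.index(edge_child)] = joint
    joint.parent = parent
    joint.children = [edge_child]
    edge_child.parent = joint
    subtree.length = stem_length
    joint.add(subtree)
    return root


def _remove_leaf(root: _Node, label: str) -> _Node:
    target = next(v for v in _leaves(root) if v.label == label)
    parent = target.parent
    parent.children.remove(target)
    return _suppress_if_unary(parent, root)


def _edges_below(node: _Node) -> list[_Node]:
    """Edges in the subtree rooted at ``node`` (identified by child node),
    excluding the node's own stem edge."""
    out = []
    stack = list(node.children)
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(v.children)
    return out


def _all_edges(root: _Node) -> list[_Node]:
    return [v for v in _iter_nodes(root) if v.parent is not None]


def _find_clan_node(root: _Node, labels: frozenset) -> _Node:
    for v in _iter_nodes(root):
        if _leaf_labels(v) == labels:
            return v
    raise SimulationError("no node carries the requested leaf set")


def _mrca(root: _Node, labels: frozenset) -> _Node:
    best = None
    for v in _iter_nodes(root):
        lv = _leaf_labels(v)
        if labels <= lv and (best is None or len(lv) < len(best[0])):
            best = (lv, v)
    return best[1]


def to_gene_tree(root: _Node) -> GeneTree:
    ids: dict[int, int] = {}
    leaf_labels: dict[int, str] = {}
    edges = []
    counter = [0]

    def nid(v):
        k = id(v)
        if k not in ids:
            ids[k] = counter[0]
            counter[0] += 1
        return ids[k]

    for v in _iter_nodes(root):
        me = nid(v)
        if v.is_leaf():
            leaf_labels[me] = v.label
        if v.parent is not None:
            edges.append((nid(v.parent), me, max(v.length, 0.0), None))
    return GeneTree(leaf_labels, edges)


def newick_of(root: _Node) -> str:
    def render(v: _Node) -> str:
        if v.is_leaf():
            return f"{v.label}:{v.length:.10g}"
        inner = ",".join(render(w) for w in v.children)
        tail = "" if v.parent is None else f":{v.length:.10g}"
        return f"({inner}){tail}"
    return render(root) + ";"


# ----------------------------------------------------------------- taxonomy

def species_name(group: str, i: int) -> str:
    return f"{group.replace(' ', '_')}_{i:02d}"


def make_taxonomy(cfg: SimulationConfig) -> TaxonomyMap:
    """One sequence per species over the whole design (the 'genome' panel)."""
    records = []
    for g in cfg.prokaryote_groups:
        for i in range(1, g.n_species + 1):
            sp = species_name(g.name, i)
            records.append(TaxonRecord(f"{sp}_g1", sp, g.name, g.domain, "NA"))
    for sg, count in cfg.eukaryote_panel.items():
        for i in range(1, count + 1):
            sp = species_name(sg, i)
            records.append(TaxonRecord(f"{sp}_g1", sp, sg, "Eukarya", sg))
    return TaxonomyMap(records)


def _seq_label(group: str, i: int) -> str:
    return species_name(group, i) + "_g1"


# ------------------------------------------------------------- species tree

def _random_join(rng: np.random.Generator, subtrees: list[_Node],
                 mean: float) -> _Node:
    """Random binary topology over the given subtrees; exponential lengths."""
    pool = list(subtrees)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        node = _Node()
        a.length = max(a.length, float(rng.exponential(mean)))
        b.length = max(b.length, float(rng.exponential(mean)))
        node.add(a)
        node.add(b)
        node.length = float(rng.exponential(mean))
        pool.append(node)
    return pool[0]


def simulate_species_tree(cfg: SimulationConfig,
                          rng: np.random.Generator | None = None) -> _Node:
    """Rooted species tree with monophyletic groups, domains and eukaryotic
    supergroups; topology ((Archaea, Eukarya), Bacteria)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mean = cfg.branch_length_mean

    def group_tree(name: str, count: int) -> _Node:
        tips = [_Node(_seq_label(name, i), float(rng.exponential(mean)))
                for i in range(1, count + 1)]
        return tips[0] if len(tips) == 1 else _random_join(rng, tips, mean)

    domains: dict[str, list[_Node]] = {"Archaea": [], "Bacteria": []}
    for g in cfg.prokaryote_groups:
        domains[g.domain].append(group_tree(g.name, g.n_species))
    euk_sub = [group_tree(sg, c) for sg, c in cfg.eukaryote_panel.items() if c]
    if not euk_sub:
        raise SimulationError("eukaryote panel is empty")

    def domain_tree(parts: list[_Node]) -> _Node | None:
        if not parts:
            return None
        return parts[0] if len(parts) == 1 else _random_join(rng, parts, mean)

    arch = domain_tree(domains["Archaea"])
    bact = domain_tree(domains["Bacteria"])
    euk = domain_tree(euk_sub)
    euk.length = max(euk.length, float(rng.exponential(mean)))
    root = _Node()
    if arch is not None:
        inner = _Node(length=float(rng.exponential(mean)))
        inner.add(arch)
        inner.add(euk)
        upper = inner
    else:
        upper = euk
    if bact is None:
        return upper
    root.add(upper)
    root.add(bact)
    return root


# --------------------------------------------------------------- gene trees

@dataclass
class SimulatedFamily:
    family_id: str
    ml_tree: GeneTree
    replicates: list
    taxonomy: TaxonomyMap
    truth: dict
    _root: _Node = None  # internal rooted form, used for replicate emulation

    @property
    def eukaryote_leaves(self) -> frozenset:
        return frozenset(x for x in self.ml_tree.leaves
                         if self.taxonomy.is_eukaryote(x))


def _protected_core(cfg: SimulationConfig) -> frozenset:
    """Eukaryote sequences never lost: two Unikont and two Plantae species.

    Guarantees every emitted family is LECA-detectable; the generator
    emulates the population of families that passed detection."""
    core = []
    for sg in ("Unikonts", "Plantae"):
        n = min(2, cfg.eukaryote_panel.get(sg, 0))
        core += [_seq_label(sg, i) for i in range(1, n + 1)]
    return frozenset(core)


def simulate_gene_tree(species_root: _Node, cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       family_id: str = "fam0000") -> SimulatedFamily:
    """Derive one gene family from the species tree.

    Applies per-species gene loss (a protected eukaryote core is kept),
    Poisson-distributed prokaryote-to-prokaryote transfers (the recipient's
    copy is replaced by a copy of the donor's, re-attaching the recipient
    leaf on the donor's terminal edge), and finally places the eukaryote
    clade according to the origin scenario. All events are logged in
    ``truth`` and replay to the emitted topology.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tax = make_taxonomy(cfg)
    root = _clone(species_root)
    mean = cfg.branch_length_mean
    protected = _protected_core(cfg)

    # --- losses
    losses = []
    euk_labels = {x for x in _leaf_labels(root) if tax.is_eukaryote(x)}
    for leaf in sorted(_leaf_labels(root)):
        if leaf in protected:
            continue
        if rng.random() < cfg.loss_prob:
            losses.append(leaf)
    # never orphan the tree or the donor group entirely
    donor_prefix = (species_name(cfg.donor_group, 0)[:-3]
                    if cfg.donor_group else None)
    kept = _leaf_labels(root) - set(losses)
    if cfg.scenario == EGT_FROM:
        donor_left = [x for x in kept
                      if tax.get(x) and tax[x].group == cfg.donor_group]
        if not donor_left:
            donor_all = sorted(x for x in _leaf_labels(root)
                               if tax[x].group == cfg.donor_group)
            losses.remove(donor_all[0])
    for leaf in losses:
        root = _remove_leaf(root, leaf)

    # --- prokaryote-to-prokaryote transfers
    transfers = []
    n_events = int(rng.poisson(cfg.hgt_rate)) if cfg.hgt_rate > 0 else 0
    for _ in range(n_events):
        proks = sorted(x for x in _leaf_labels(root) if not tax.is_eukaryote(x))
        if len(proks) < 3:
            break
        recipient = proks[int(rng.integers(len(proks)))]
        donors = [x for x in proks if tax[x].group != tax[recipient].group]
        if not donors:
            break
        donor = donors[int(rng.integers(len(donors)))]
        leaf = next(v for v in _leaves(root) if v.label == recipient)
        root, _ = _detach(root, leaf)
        donor_node = next(v for v in _leaves(root) if v.label == donor)
        root = _attach(root, donor_node, leaf, float(rng.uniform(0.1, 0.9)),
                       float(rng.exponential(mean / 4)))
        transfers.append((donor, recipient))

    # --- place the eukaryote clade
    euk_labels = {x for x in _leaf_labels(root) if tax.is_eukaryote(x)}
    euk_node = _find_clan_node(root, frozenset(euk_labels))
    stem_length = max(euk_node.length, float(rng.exponential(mean)))
    root, _ = _detach(root, euk_node)

    scramble = []
    if cfg.scenario == UNCLEAR_MIX:
        # interleave the domains by repeated cross-domain transfers
        prok_leaves = sorted(_leaf_labels(root))
        n_moves = max(2, len(prok_leaves) // 3)
        for _ in range(n_moves):
            labels = sorted(_leaf_labels(root))
            mover_lab = labels[int(rng.integers(len(labels)))]
            others = [x for x in labels
                      if tax[x].domain != tax[mover_lab].domain]
            if not others:
                continue
            target_lab = others[int(rng.integers(len(others)))]
            mover = next(v for v in _leaves(root) if v.label == mover_lab)
            root, _ = _detach(root, mover)
            target = next(v for v in _leaves(root) if v.label == target_lab)
            root = _attach(root, target, mover, float(rng.uniform(0.1, 0.9)),
                           float(rng.exponential(mean / 4)))
            scramble.append((mover_lab, target_lab))

    if cfg.scenario == EGT_FROM:
        members = frozenset(x for x in _leaf_labels(root)
                            if tax[x].group == cfg.donor_group)
        anchor = _mrca(root, members)
        candidates = _edges_below(anchor) or [anchor]
    elif cfg.scenario == VERTICAL_ARCHAEAL:
        members = frozenset(x for x in _leaf_labels(root)
                            if tax[x].domain == "Archaea")
        if not members:
            raise SimulationError("no archaeal species left to attach to")
        anchor = _mrca(root, members)
        # deep attachment: edges of the inter-group archaeal backbone (group
        # stem edges included), never strictly inside one group's clan
        within_groups: set[int] = set()
        for g in cfg.prokaryote_groups:
            if g.domain != "Archaea":
                continue
            g_members = frozenset(x for x in members
                                  if tax[x].group == g.name)
            if g_members:
                g_anchor = _mrca(root, g_members)
                within_groups.update(id(e) for e in _edges_below(g_anchor))
        candidates = [e for e in _edges_below(anchor)
                      if id(e) not in within_groups]
        if not candidates:
            candidates = [anchor]
    elif cfg.scenario == LUCA_THREE_DOMAIN:
        candidates = [root.children[0]]
    else:  # UNCLEAR_MIX
        candidates = _all_edges(root)
    edge_child = candidates[int(rng.integers(len(candidates)))]
    root = _attach(root, edge_child, euk_node, float(rng.uniform(0.2, 0.8)),
                   stem_length)

    truth = {
        "scenario": cfg.scenario,
        "donor_group": cfg.donor_group if cfg.scenario == EGT_FROM else None,
        "losses": tuple(losses),
        "transfers": tuple(transfers),
        "scramble": tuple(scramble),
        "euk_leaves": frozenset(euk_labels),
    }
    return SimulatedFamily(family_id=family_id, ml_tree=to_gene_tree(root),
                           replicates=[], taxonomy=tax, truth=truth,
                           _root=root)


# ---------------------------------------------------------------- bootstrap

def _perturb_attachment(root: _Node, euk_labels: frozenset,
                        rng: np.random.Generator, decay: float) -> _Node:
    euk_node = _find_clan_node(root, euk_labels)
    stem = euk_node.length
    root, anchor = _detach(root, euk_node)
    # distance of each backbone edge (child node) from the original position
    dist = {}
    start = anchor if anchor is not None else root
    queue = [(start, 0)]
    seen = {id(start)}
    while queue:
        v, d = queue.pop(0)
        dist[id(v)] = d
        for w in list(v.children) + ([v.parent] if v.parent else []):
            if w is not None and id(w) not in seen:
                seen.add(id(w))
                queue.append((w, d + 1))
    edges = [v for v in _all_edges(root) if anchor is None or v is not anchor]
    if not edges:
        edges = _all_edges(root)
    weights = np.array([decay ** dist[id(v)] for v in edges], dtype=float)
    weights /= weights.sum()
    choice = edges[int(rng.choice(len(edges), p=weights))]
    return _attach(root, choice, euk_node, float(rng.uniform(0.2, 0.8)), stem)


def _random_nni(root: _Node, rng: np.random.Generator) -> None:
    internal = [v for v in _all_edges(root) if not v.is_leaf()]
    if not internal:
        return
    v = internal[int(rng.integers(len(internal)))]
    u = v.parent
    siblings = [w for w in u.children if w is not v]
    if not siblings or not v.children:
        return
    s = siblings[int(rng.integers(len(siblings)))]
    c = v.children[int(rng.integers(len(v.children)))]
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    s.parent, c.parent = v, u


def emulate_bootstrap(family: SimulatedFamily, cfg: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[GeneTree]:
    """Emulated bootstrap ensemble for a simulated family.

    Each replicate is a copy of the family tree; with probability
    ``q_attach`` the eukaryote clan is detached and re-attached to an edge
    drawn from a distance-decaying kernel around (and excluding) its true
    position; with probability ``r_nni`` one random internal edge is
    NNI-perturbed. Fills and returns ``family.replicates``.
    """
    if cfg.n_replicates < 2:
        raise SimulationError("need at least 2 replicates")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    euk = frozenset(family.truth["euk_leaves"])
    reps = []
    for _ in range(cfg.n_replicates):
        work = _clone(family._root)
        if rng.random() < cfg.q_attach:
            work = _perturb_attachment(work, euk, rng, cfg.kernel_decay)
        if rng.random() < cfg.r_nni:
            _random_nni(work, rng)
        reps.append(to_gene_tree(work))
    family.replicates = reps
    return reps


# ------------------------------------------------------------ whole datasets

def simulate_family(cfg: SimulationConfig, index: int = 0,
                    species_root: _Node | None = None) -> SimulatedFamily:
    """One family plus its replicate ensemble, deterministic under
    (cfg.seed, index)."""
    rng = np.random.default_rng([cfg.seed, index])
    if species_root is None:
        species_root = simulate_species_tree(cfg,
                                             np.random.default_rng(cfg.seed))
    fam = simulate_gene_tree(species_root, cfg, rng,
                             family_id=f"fam{index:04d}")
    emulate_bootstrap(fam, cfg, rng)
    return fam


def simulate_dataset(cfg: SimulationConfig, n_families: int,
                     out_dir=None) -> list[SimulatedFamily]:
    """A dataset of families sharing one species tree and taxonomy; when
    ``out_dir`` is given, writes the exact input layout the pipeline reads
    (per-family ML + replicate Newick files, taxonomy TSV, truth log)."""
    species_root = simulate_species_tree(cfg, np.random.default_rng(cfg.seed))
    families = [simulate_family(cfg, i, species_root)
                for i in range(n_families)]
    if out_dir is not None:
        write_dataset(families, out_dir)
    return families


def write_dataset(families: Sequence[SimulatedFamily], out_dir) -> None:
    from .taxonomy import write_taxonomy
    from .trees import write_newick

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_taxonomy(families[0].taxonomy, out / "taxonomy.tsv")
    with open(out / "truth.tsv", "w", encoding="utf-8") as truth:
        truth.write("family_id\tscenario\tdonor_group\tn_losses\tn_transfers\n")
        for fam in families:
            write_newick(fam.ml_tree, out / f"{fam.family_id}.ml.nwk")
            write_newick(fam.replicates, out / f"{fam.family_id}.boot.nwk")
            t = fam.truth
            truth.write(f"{fam.family_id}\t{t['scenario']}\t"
                        f"{t['donor_group'] or ''}\t{len(t['losses'])}\t"
                        f"{len(t['transfers'])}\n")


def simulate_recent_hgt_family(cfg: SimulationConfig, index: int = 0
                               ) -> SimulatedFamily:
    """A constructed confound: the eukaryote clade's sister is a single
    transferred sequence (one Deltaproteobacteria leaf moved inside another
    bacterial group) — the pattern a naive sister-identity criterion misreads
    as a specific origin while the configuration rules call only the domain.

    Requires a bacteria-only prokaryote design including Deltaproteobacteria
    and at least one other group.
    """
    groups = {g.name: g for g in cfg.prokaryote_groups}
    if "Deltaproteobacteria" not in groups:
        raise SimulationError("design must include Deltaproteobacteria")
    hosts = [g for g in cfg.prokaryote_groups
             if g.domain == "Bacteria" and g.name != "Deltaproteobacteria"
             and g.n_species >= 2]
    if not hosts:
        raise SimulationError("design needs another bacterial group to host "
                              "the transferred sequence")
    rng = np.random.default_rng([cfg.seed, index, 7])
    species_root = simulate_species_tree(cfg, np.random.default_rng(cfg.seed))
    tax = make_taxonomy(cfg)
    root = _clone(species_root)

    mover_lab = _seq_label("Deltaproteobacteria", 1)
    host = hosts[int(rng.integers(len(hosts)))]
    host_leaf_lab = _seq_label(host.name, 1 + int(rng.integers(host.n_species)))
    mover = next(v for v in _leaves(root) if v.label == mover_lab)
    root, _ = _detach(root, mover)
    target = next(v for v in _leaves(root) if v.label == host_leaf_lab)
    root = _attach(root, target, mover, 0.5,
                   float(rng.exponential(cfg.branch_length_mean / 4)))

    euk_labels = frozenset(x for x in _leaf_labels(root)
                           if tax.is_eukaryote(x))
    euk_node = _find_clan_node(root, euk_labels)
    stem = max(euk_node.length, float(rng.exponential(cfg.branch_length_mean)))
    root, _ = _detach(root, euk_node)
    mover = next(v for v in _leaves(root) if v.label == mover_lab)
    root = _attach(root, mover, euk_node, 0.5, stem)

    truth = {
        "scenario": "RECENT_HGT_SISTER",
        "donor_group": "Deltaproteobacteria",
        "losses": (), "transfers": ((host_leaf_lab, mover_lab),),
        "scramble": (), "euk_leaves": euk_labels,
    }
    return SimulatedFamily(family_id=f"hgt{index:04d}",
                           ml_tree=to_gene_tree(root), replicates=[],
                           taxonomy=tax, truth=truth, _root=root)
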
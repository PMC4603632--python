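"""Synthetic coupled gene-family evolution.

Generates a stated world in which every statistic in :mod:`coevokit.coevo`
and :mod:`coevokit.xprquant` has a known truth to recover:

* a Yule species tree with exponential branch lengths;
* two gene families evolving along it, each duplicating on a branch with
  probability ``p_dup`` and losing copies with per-copy probability
  ``p_loss`` — family B *reuses* family A's duplication indicator on a
  branch with probability ``kappa`` (the coupling coefficient), else
  draws its own, so ``kappa = 1`` forces the shared-duplication pattern
  and ``kappa = 0`` makes the histories independent;
* lognormal branch-rate multipliers, likewise shared between families
  with probability ``kappa`` per branch — the knob that drives (or
  destroys) mirror-tree signal;
* residue substitution along branches: per site, a Poisson number of
  events with mean ``branch_length x rate multiplier``, each replacing
  the residue uniformly by one of the other 19 — so expected pairwise
  identity at total distance d has the closed form
  ``1/20 + (19/20) exp(-(20/19) d)``, which the tests check;
* short error-bearing reads drawn uniformly from paralog transcripts,
  with per-base errors at ``error_rate`` replacing the base by one of
  the other letters.

Everything is bit-reproducible under the mandatory seed.  No indels are
simulated, so family rows are pre-aligned and downstream statistics are
exercised in isolation from alignment quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .coevo import CopyProfile, DistanceMatrix
from .seqcore import MSA, MSARow, Sequence

__all__ = [
    "SimConfig",
    "EdgeEvent",
    "SimTruth",
    "sim_species_tree",
    "tree_edges",
    "sim_copy_histories",
    "sim_branch_rates",
    "sim_alignment",
    "rate_distance_matrix",
    "sim_diverged_transcripts",
    "sim_reads",
    "simulate_panel",
    "SimBundle",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the stated world.

    Defaults describe a realistic eutherian setting: an 8-species
    panel, proteins of ~300 residues, roughly two duplication events
    across the panel's tree (p_dup 0.15 over ~14 branches), occasional
    losses, fully coupled families (kappa 1), and short-read sequencing
    at 75 nt with a 1 % error rate, 1,000 reads per condition.
    """

    n_species: int = 8
    p_dup: float = 0.15
    p_loss: float = 0.05
    kappa: float = 1.0
    seq_length: int = 300
    rate_sigma: float = 0.5
    branch_length_mean: float = 0.1
    n_reads: int = 1000
    read_length: int = 75
    error_rate: float = 0.01
    max_copies: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("p_dup", "p_loss", "kappa", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 3:
            raise ValueError("need >= 3 species")
        if self.seq_length < 50:
            raise ValueError("seq_length must be >= 50")
        if self.rate_sigma <= 0:
            raise ValueError("rate_sigma must be > 0")


@dataclass(frozen=True)
class EdgeEvent:
    """What happened to one family on one branch (replayable)."""

    duplicated: bool
    dup_source: int  # index of the copied gene, -1 if none
    losses: tuple[bool, ...]  # per copy, after any duplication


@dataclass
class SimTruth:
    """Ground truth of one simulated panel."""

    events: dict[str, dict[int, EdgeEvent]]  # family -> edge index -> event
    profiles: list[CopyProfile]
    rates: dict[str, np.ndarray] | None = None  # family -> per-edge multiplier
    read_origin: pd.DataFrame | None = None  # read_id -> true transcript


# ---------------------------------------------------------------------------
# Species tree


def sim_species_tree(
    n_species: int,
    seed: int,
    branch_length_mean: float = 0.1,
) -> dendropy.Tree:
    """Yule-topology species tree with exponential branch lengths.

    Starting from a two-leaf tree, a uniformly chosen leaf is split
    until ``n_species`` leaves exist; every branch then receives an
    independent Exponential(mean ``branch_length_mean``) length.
    Deterministic under the seed (same seed, same newick string).
    """
    if n_species < 3:
        raise ValueError("need >= 3 species")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    leaves = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    while len(leaves) < n_species:
        parent = leaves.pop(int(rng.integers(len(leaves))))
        leaves.append(parent.new_child())
        leaves.append(parent.new_child())
    tns = dendropy.TaxonNamespace()
    tree.taxon_namespace = tns
    for i, leaf in enumerate(leaves, start=1):
        leaf.taxon = tns.new_taxon(f"sp{i:02d}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.exponential(branch_length_mean))
    return tree


def tree_edges(tree: dendropy.Tree) -> list[dendropy.Edge]:
    """Non-root edges in preorder — the canonical edge indexing."""
    return [
        e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    ]


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label


# ---------------------------------------------------------------------------
# Coupled copy-number histories


def sim_copy_histories(
    tree: dendropy.Tree, config: SimConfig
) -> tuple[list[CopyProfile], SimTruth]:
    """Coupled birth/loss histories of the two families along the tree.

    On each branch, family A duplicates with probability ``p_dup``
    (one uniformly chosen copy is duplicated); with probability
    ``kappa`` family B reuses A's event indicator on that branch, else
    it draws independently.  Each copy is then lost with probability
    ``p_loss``.  Leaf copy numbers are tallied into the species panel;
    the per-edge event log makes the history replayable (the alignment
    simulator consumes it).
    """
    rng = np.random.default_rng(config.seed)
    edges = tree_edges(tree)
    edge_index = {id(e): i for i, e in enumerate(edges)}
    events: dict[str, dict[int, EdgeEvent]] = {"A": {}, "B": {}}

    # copies per family at the tail of each edge, propagated preorder
    state: dict[int, dict[str, int]] = {id(tree.seed_node): {"A": 1, "B": 1}}
    profiles = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            counts = state[id(node)]
        else:
            parent_counts = state[id(node.parent_node)]
            i = edge_index[id(node.edge)]
            event_a = bool(rng.random() < config.p_dup)
            if rng.random() < config.kappa:
                event_b = event_a
            else:
                event_b = bool(rng.random() < config.p_dup)
            counts = {}
            for family, event in (("A", event_a), ("B", event_b)):
                n = parent_counts[family]
                dup_source = -1
                duplicated = event and 0 < n < config.max_copies
                if duplicated:
                    dup_source = int(rng.integers(n))
                    n += 1
                losses = tuple(bool(rng.random() < config.p_loss) for _ in range(n))
                events[family][i] = EdgeEvent(duplicated, dup_source, losses)
                counts[family] = n - sum(losses)
            state[id(node)] = counts
        if node.is_leaf():
            profiles.append(
                CopyProfile(
                    species=_leaf_label(node),
                    copies_a=counts["A"],
                    copies_b=counts["B"],
                    complete_genome=True,
                )
            )
    return profiles, SimTruth(events=events, profiles=profiles)


# ---------------------------------------------------------------------------
# Coupled branch rates


def sim_branch_rates(
    tree: dendropy.Tree, kappa: float, rate_sigma: float, seed: int
) -> dict[str, np.ndarray]:
    """Per-branch lognormal rate multipliers for the two families.

    Family A draws Lognormal(0, ``rate_sigma``) per branch; on each
    branch family B reuses A's multiplier with probability ``kappa``,
    else draws a fresh one.  Shared multipliers are what makes the two
    families' distance matrices mirror each other.
    """
    if rate_sigma <= 0:
        raise ValueError("rate_sigma must be > 0")
    rng = np.random.default_rng(seed)
    n = len(tree_edges(tree))
    rates_a = rng.lognormal(0.0, rate_sigma, size=n)
    fresh = rng.lognormal(0.0, rate_sigma, size=n)
    shared = rng.random(n) < kappa
    rates_b = np.where(shared, rates_a, fresh)
    return {"A": rates_a, "B": rates_b}


def rate_distance_matrix(
    tree: dendropy.Tree, rates: np.ndarray
) -> DistanceMatrix:
    """Patristic species distances under rate-multiplied branch lengths.

    The true inter-species distance matrix of one family — branch
    length times that family's multiplier, summed along the path — used
    to study the mirror-tree statistic without sequence noise.
    """
    edges = tree_edges(tree)
    edge_index = {id(e): i for i, e in enumerate(edges)}
    # effective depth of each node from the root
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    ancestors: dict[int, list[int]] = {id(tree.seed_node): [id(tree.seed_node)]}
    leaves = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        p = node.parent_node
        w = float(rates[edge_index[id(node.edge)]]) * float(node.edge.length)
        depth[id(node)] = depth[id(p)] + w
        ancestors[id(node)] = ancestors[id(p)] + [id(node)]
        if node.is_leaf():
            leaves.append(node)
    leaves.sort(key=_leaf_label)
    labels = [_leaf_label(l) for l in leaves]
    k = len(leaves)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ai, aj = ancestors[id(leaves[i])], ancestors[id(leaves[j])]
            common = set(ai) & set(aj)
            lca = next(a for a in reversed(ai) if a in common)
            d = depth[id(leaves[i])] + depth[id(leaves[j])] - 2 * depth[lca]
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Sequence evolution


def _evolve(seq: np.ndarray, distance: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform-replacement substitution: per site Poisson(``distance``)
    events, each replacing the residue by one of the other 19."""
    out = seq.copy()
    n_events = rng.poisson(distance, size=len(seq))
    for site in np.nonzero(n_events)[0]:
        for _ in range(n_events[site]):
            shift = 1 + int(rng.integers(19))
            out[site] = (out[site] + shift) % 20
    return out


def sim_alignment(
    tree: dendropy.Tree,
    truth: SimTruth,
    family: str,
    config: SimConfig,
    rates: np.ndarray | None = None,
) -> MSA:
    """Simulate one family's protein alignment by replaying its history.

    The root sequence is uniform over the 20 amino acids; each copy
    evolves independently down the tree with per-branch distance
    ``branch_length x rate multiplier``; duplication events copy the
    current sequence, losses drop it.  With no indels the rows align
    trivially.  Rows are labelled ``species|family.copy``.  The RNG is
    seeded from ``config.seed`` and the family name, so families get
    independent substitution streams but the run is reproducible.
    """
    events = truth.events[family]
    edges = tree_edges(tree)
    edge_index = {id(e): i for i, e in enumerate(edges)}
    if rates is None:
        rates = (truth.rates or {}).get(family)
    if rates is None:
        rates = np.ones(len(edges))
    rng = np.random.default_rng([config.seed, ord(family[0])])
    root_seq = rng.integers(20, size=config.seq_length)
    state: dict[int, list[np.ndarray]] = {id(tree.seed_node): [root_seq]}
    rows = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            copies = state[id(node)]
        else:
            i = edge_index[id(node.edge)]
            d = float(node.edge.length) * float(rates[i])
            copies = [_evolve(c, d, rng) for c in state[id(node.parent_node)]]
            ev = events[i]
            if ev.duplicated:
                copies.append(copies[ev.dup_source].copy())
            copies = [c for c, lost in zip(copies, ev.losses) if not lost]
            state[id(node)] = copies
        if node.is_leaf():
            sp = _leaf_label(node)
            for k, c in enumerate(copies, start=1):
                residues = "".join(AMINO_ACIDS[x] for x in c)
                rows.append(
                    MSARow(
                        id=f"{sp}_{family}.{k}",
                        species=sp,
                        gapped=residues,
                        paralog=f"{family}.{k}",
                    )
                )
    if not rows:
        raise ValueError(f"family {family} went extinct in this replicate")
    return MSA(rows)


# ---------------------------------------------------------------------------
# Transcripts and reads


def sim_diverged_transcripts(
    length: int,
    divergence: float,
    n_paralogs: int = 2,
    seed: int = 0,
    gene: str = "geneA",
) -> list[Sequence]:
    """Nucleotide paralog transcripts at a given per-site divergence.

    The first paralog is uniform over ACGT; each further paralog copies
    it and substitutes every site independently with probability
    ``divergence`` (uniform over the other 3 bases).  Divergence 0
    yields identical duplicates — the forced-tie case.
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(4, size=length)
    out = []
    for k in range(1, n_paralogs + 1):
        if k == 1:
            arr = base
        else:
            arr = base.copy()
            hit = rng.random(length) < divergence
            arr[hit] = (arr[hit] + 1 + rng.integers(3, size=int(hit.sum()))) % 4
        out.append(
            Sequence(
                id=f"{gene}.{k}",
                residues="".join(BASES[x] for x in arr),
                species=gene,
                paralog=str(k),
                molecule="nucleotide",
            )
        )
    return out


def sim_reads(
    transcripts: list[Sequence], config: SimConfig
) -> tuple[list[Sequence], pd.DataFrame]:
    """Uniform short reads from the transcripts with per-base errors.

    Source transcripts are drawn uniformly, start positions uniformly
    over valid placements; each base is corrupted with probability
    ``error_rate`` (replaced by one of the other letters of its
    alphabet).  Returns the reads and a truth table mapping each read
    to its source transcript.
    """
    if any(config.read_length > len(t) for t in transcripts):
        raise ValueError("read_length exceeds the shortest transcript")
    rng = np.random.default_rng([config.seed, 0x5EAD])
    alphabet = BASES if transcripts[0].molecule == "nucleotide" else AMINO_ACIDS
    k = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    reads, origin = [], []
    for n in range(config.n_reads):
        t = transcripts[int(rng.integers(len(transcripts)))]
        start = int(rng.integers(len(t) - config.read_length + 1))
        arr = np.array(
            [idx[c] for c in t.residues[start : start + config.read_length]]
        )
        errs = rng.random(config.read_length) < config.error_rate
        n_err = int(errs.sum())
        if n_err:
            arr[errs] = (arr[errs] + 1 + rng.integers(k - 1, size=n_err)) % k
        read_id = f"r{n + 1:06d}"
        reads.append(
            Sequence(
                id=read_id,
                residues="".join(alphabet[x] for x in arr),
                species=read_id,
                molecule=t.molecule,
            )
        )
        origin.append((read_id, t.id, start + 1))
    truth = pd.DataFrame(origin, columns=["read_id", "true_transcript", "start_1based"])
    return reads, truth


# ---------------------------------------------------------------------------
# One-call panel


@dataclass
class SimBundle:
    """Everything one simulated panel produced."""

    config: SimConfig
    tree: dendropy.Tree
    truth: SimTruth
    msa_a: MSA
    msa_b: MSA

    @property
    def profiles(self) -> list[CopyProfile]:
        return self.truth.profiles


def simulate_panel(config: SimConfig) -> SimBundle:
    """Species tree -> coupled copy histories -> coupled rates -> alignments."""
    tree = sim_species_tree(
        config.n_species, seed=config.seed,
        branch_length_mean=config.branch_length_mean,
    )
    profiles, truth = sim_copy_histories(tree, config)
    truth.rates = sim_branch_rates(
        tree, config.kappa, config.rate_sigma, seed=config.seed + 1
    )
    msa_a = sim_alignment(tree, truth, "A", config)
    msa_b = sim_alignment(tree, truth, "B", config)
    return SimBundle(config=config, tree=tree, truth=truth, msa_a=msa_a, msa_b=msa_b)
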
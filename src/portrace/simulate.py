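"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's input types at desk scale:

* :func:`simulate_por_family` — POR-like protein families built from a
  seeded cyanobacterial-style ancestor.  The three diagnostic motifs
  (Rossman ``G-x-x-x-G-x-G``, catalytic ``Y-x-x-x-K``, catalytic Cys) are
  held fixed; all other sites mutate under a residue-class-aware
  substitution model calibrated to hit a requested within-group
  class-similarity.  Decoys mimic near-miss SDR-family relatives by
  breaking one diagnostic residue; fragments mimic transcriptome-derived
  sequences by deleting the N-terminus past the Rossman region.
* :func:`simulate_gene_tree` — lineage-labelled gene trees in which every
  leaf is nested inside the clade of its expected plastid-donor lineage
  (the vertical expectation for algae of secondary plastid origin), with
  planted gene duplications (a clade copied in place) and HGT events (a
  recipient leaf regrafted into a foreign donor clade).
* :func:`simulate_complement_table` — per-species LIPOR complements with a
  tunable coupling between por copy number and LIPOR loss, including
  pseudogene intermediates of gradual loss.

All randomness flows from one integer seed; identical seeds reproduce
identical outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment import RESIDUE_CLASSES
from .curation import ReferenceAnchor
from .events import DEFAULT_DONOR_MAP
from .lipor import LiporRecord
from .records import AMINO_ACIDS, InputError, SequenceRecord
from .trees import Clade, GeneTree


@dataclass
class SimulationTruth:
    """Ground-truth bookkeeping for one simulated dataset."""

    seed: int
    labels: dict[str, str] = field(default_factory=dict)  # id -> por_true|decoy|fragment
    events: list[dict] = field(default_factory=list)      # tree event log
    complements: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

#: fixed diagnostic coordinates in the simulated ancestor (1-based)
ANCESTOR_LENGTH = 320
ROSSMAN_START = 35
TYR_POS = 190
LYS_POS = 194
CYS_POS = 230
_DIAGNOSTIC = {
    ROSSMAN_START: "G",
    ROSSMAN_START + 4: "G",
    ROSSMAN_START + 6: "G",
    TYR_POS: "Y",
    LYS_POS: "K",
    CYS_POS: "C",
}
#: fragment truncation point: past the Rossman region, before the Y-x-x-x-K
FRAGMENT_CUT = 60

_CLASS_OF = {aa: name for name, members in RESIDUE_CLASSES.items() for aa in members}
_CLASS_SIZES = {name: len(members) for name, members in RESIDUE_CLASSES.items()}

#: Around each diagnostic site, residues capable of mimicking that motif are
#: excluded from the mutable background (margin covers the screening search
#: window) so a decoy with one broken diagnostic residue can never be
#: rescued by a chance compensating residue nearby.
_MOTIF_GUARD_MARGIN = 12


def _forbidden_at(pos: int) -> frozenset[str]:
    m = _MOTIF_GUARD_MARGIN
    banned: set[str] = set()
    if ROSSMAN_START - m <= pos <= ROSSMAN_START + 6 + m:
        banned.add("G")
    if TYR_POS - m <= pos <= LYS_POS + m:
        banned.update("YK")
    if CYS_POS - m <= pos <= CYS_POS + m:
        banned.add("C")
    return frozenset(banned)


_FORBIDDEN = {pos: _forbidden_at(pos) for pos in range(1, ANCESTOR_LENGTH + 1)}

#: group sizes mirroring the logo comparison: 18 cyanobacterial references
#: and about 21 diatom (stramenopile) sequences
DEFAULT_FAMILY_GROUPS: tuple[tuple[str, int], ...] = (
    ("cyanobacteria", 18),
    ("stramenopile", 21),
)


def _mean_reclass_match_probability() -> float:
    """Probability that two independent different-class replacements of the
    same ancestral residue land in the same class, averaged over a uniform
    ancestral residue."""
    total = 0.0
    for aa in AMINO_ACIDS:
        own = _CLASS_OF[aa]
        pool = 20 - _CLASS_SIZES[own]
        p_same = sum(
            (size / pool) ** 2
            for name, size in _CLASS_SIZES.items()
            if name != own
        )
        total += p_same / 20.0
    return total


def _mutation_probability(within_similarity: float) -> float:
    """Per-site different-class mutation probability hitting the requested
    expected pairwise class similarity.

    With each sequence mutating a site independently with probability p
    (always to a different class), two sequences agree in class when both
    are unmutated or both mutated into the same class:
    ``s = (1 - p)^2 + p^2 * q`` with q the mean reclass-match probability.
    """
    q = _mean_reclass_match_probability()
    s = within_similarity
    disc = 1.0 - (1.0 + q) * (1.0 - s)
    if disc < 0.0:
        raise InputError(
            f"within_similarity {s} is infeasible under the class-aware "
            "substitution model"
        )
    return (1.0 - float(np.sqrt(disc))) / (1.0 + q)


def _random_ancestor(rng: np.random.Generator) -> str:
    residues = []
    for pos in range(1, ANCESTOR_LENGTH + 1):
        allowed = [aa for aa in AMINO_ACIDS if aa not in _FORBIDDEN[pos]]
        residues.append(allowed[int(rng.integers(len(allowed)))])
    for pos, aa in _DIAGNOSTIC.items():
        residues[pos - 1] = aa
    return "".join(residues)


def _mutate(
    seq: str, p: float, rng: np.random.Generator, keep: Mapping[int, str]
) -> str:
    out = list(seq)
    hits = rng.random(len(seq)) < p
    for i in np.nonzero(hits)[0]:
        pos = i + 1
        if pos in keep:
            continue
        own = _CLASS_OF[out[i]]
        choices = [
            aa for aa in AMINO_ACIDS
            if _CLASS_OF[aa] != own and aa not in _FORBIDDEN[pos]
        ]
        if choices:
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


@dataclass
class SimulatedFamily:
    records: list[SequenceRecord]
    anchor: ReferenceAnchor
    truth: SimulationTruth


def simulate_por_family(
    groups: Sequence[tuple[str, int]] = DEFAULT_FAMILY_GROUPS,
    within_similarity: float = 0.75,
    between_similarity: float = 0.60,
    n_decoys: int = 0,
    n_fragments: int = 0,
    seed: int = 0,
) -> SimulatedFamily:
    """Simulate a POR-like protein family with truth labels.

    Each lineage group descends from a group ancestor (itself derived from
    one global ancestor at ``between_similarity``); members then diverge to
    the requested ``within_similarity`` (expected pairwise class
    similarity).  Decoys break one diagnostic residue into a different
    class; fragments lose their N-terminus past the Rossman region.
    """
    if not (0.0 < within_similarity <= 1.0):
        raise InputError("within_similarity must lie in (0, 1]")
    if within_similarity < 0.2 or between_similarity < 0.2:
        raise InputError("similarities below 0.2 are infeasible")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(
        seed=seed,
        params={
            "within_similarity": within_similarity,
            "between_similarity": between_similarity,
            "groups": list(groups),
        },
    )
    ancestor = _random_ancestor(rng)
    reference = SequenceRecord(
        id="reference_cyanobacterium",
        residues=ancestor,
        taxon_name="reference cyanobacterium",
        lineage="cyanobacteria",
    )
    anchor = ReferenceAnchor(
        reference, ROSSMAN_START, TYR_POS, LYS_POS, CYS_POS
    )
    p_within = _mutation_probability(within_similarity)
    p_between = _mutation_probability(between_similarity)

    records: list[SequenceRecord] = []
    for lineage, size in groups:
        group_ancestor = _mutate(ancestor, p_between / 2.0, rng, _DIAGNOSTIC)
        for i in range(size):
            residues = _mutate(group_ancestor, p_within, rng, _DIAGNOSTIC)
            rec = SequenceRecord(
                id=f"{lineage}_{i:02d}",
                residues=residues,
                taxon_name=f"{lineage} taxon {i:02d}",
                lineage=lineage,
                source="genome",
            )
            records.append(rec)
            truth.labels[rec.id] = "por_true"

    for i in range(n_fragments):
        base = records[int(rng.integers(len(records)))]
        rec = SequenceRecord(
            id=f"fragment_{i:02d}",
            residues=base.residues[FRAGMENT_CUT:],
            taxon_name=f"fragment taxon {i:02d}",
            lineage=base.lineage,
            source="transcriptome",
        )
        records.append(rec)
        truth.labels[rec.id] = "fragment"

    diag_positions = sorted(_DIAGNOSTIC)
    for i in range(n_decoys):
        residues = list(_mutate(ancestor, p_within, rng, _DIAGNOSTIC))
        broken = diag_positions[int(rng.integers(len(diag_positions)))]
        own = _CLASS_OF[_DIAGNOSTIC[broken]]
        choices = [aa for aa in AMINO_ACIDS if _CLASS_OF[aa] != own]
        residues[broken - 1] = choices[int(rng.integers(len(choices)))]
        rec = SequenceRecord(
            id=f"decoy_{i:02d}",
            residues="".join(residues),
            taxon_name=f"sdr decoy {i:02d}",
            lineage="other",
            source="genome",
        )
        records.append(rec)
        truth.labels[rec.id] = "decoy"
    return SimulatedFamily(records, anchor, truth)


# ---------------------------------------------------------------------------
# gene trees
# ---------------------------------------------------------------------------

#: Desk-scale species panel.  Primary-plastid lineages are sampled densely
#: relative to the host groups nested inside them (as in broad surveys of
#: rhodophyte and prasinophyte diversity), which keeps every donor clade's
#: modal lineage dominant: with each host group at most 3 leaves and a
#: donor core at least four times the foreign secondary leaves in its
#: clade, the default purity threshold of 0.8 is met at the clade root and
#: can never be reached by a wrong lineage at an inner anchor.
DEFAULT_SPECIES: tuple[tuple[str, str], ...] = tuple(
    [(f"cyanobacterium_{i}", "cyanobacteria") for i in range(6)]
    + [(f"rhodophyte_{i}", "rhodophyte") for i in range(36)]
    + [(f"prasinophyte_{i}", "prasinophyte") for i in range(12)]
    + [(f"utc_chlorophyte_{i}", "utc_chlorophyte") for i in range(12)]
    + [(f"stramenopile_{i}", "stramenopile") for i in range(2)]
    + [(f"haptophyte_{i}", "haptophyte") for i in range(2)]
    + [(f"cryptophyte_{i}", "cryptophyte") for i in range(2)]
    + [(f"dinoflagellate_{i}", "dinoflagellate") for i in range(2)]
    + [(f"euglenid_{i}", "euglenid") for i in range(2)]
    + [(f"chlorarachniophyte_{i}", "chlorarachniophyte") for i in range(2)]
)


def _leaf(name: str, rng: np.random.Generator) -> Clade:
    return Clade(name=name, length=float(rng.exponential(0.1)) + 0.01)


def _join(nodes: list[Clade], rng: np.random.Generator, support: float) -> Clade:
    """Random sequential pairwise joins into one subtree root."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = Clade(
            length=float(rng.exponential(0.1)) + 0.01, support=support,
            children=[a, b],
        )
        nodes.append(parent)
    return nodes[0]


def simulate_gene_tree(
    species: Sequence[tuple[str, str]] = DEFAULT_SPECIES,
    n_duplications: int = 0,
    n_hgt: int = 0,
    support_level: float = 1.0,
    seed: int = 0,
    donors: Mapping[str, str] | None = None,
    duplication_size: int = 5,
) -> tuple[GeneTree, SimulationTruth]:
    """Simulate a lineage-labelled gene tree with planted events.

    The backbone is species-consistent (one leaf per species) and respects
    the vertical expectation: each secondary-plastid lineage's leaves are
    grafted inside the clade of its expected donor lineage.  Duplications
    copy a clade of about ``duplication_size`` taxa in place (leaf ids are
    suffixed ``.1``/``.2``); HGT events regraft a recipient leaf next to a
    leaf of a foreign donor lineage.  All internal nodes carry
    ``support_level``.
    """
    donors = DEFAULT_DONOR_MAP if donors is None else dict(donors)
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_duplications": n_duplications,
            "n_hgt": n_hgt,
            "support_level": support_level,
        },
    )
    lineage_of = dict(species)
    if len(lineage_of) != len(species):
        raise InputError("species names must be unique")
    lineages = sorted({lin for _, lin in species})
    if n_hgt > 0 and len(lineages) < 2:
        raise InputError("HGT requires at least two lineages")

    primary = [lin for lin in lineages if lin not in donors]
    placement = {lin: donors.get(lin, lin) for lin in lineages}
    hosts_without_core = [
        lin for lin in lineages
        if lin in donors and placement[lin] not in lineages
    ]
    if hosts_without_core:
        raise InputError(
            f"species set lacks the expected donor lineage(s) for: "
            f"{hosts_without_core}"
        )

    # pure cores per primary lineage
    cores: dict[str, list[Clade]] = {
        lin: [_leaf(name, rng) for name, l in species if l == lin]
        for lin in primary
    }
    subtrees: dict[str, Clade] = {
        lin: _join(nodes, rng, support_level) if len(nodes) > 1 else nodes[0]
        for lin, nodes in cores.items()
    }

    # nest each secondary host lineage as one monophyletic group inside its
    # expected donor clade, each group at a distinct core leaf
    host_groups: dict[str, list[str]] = {}
    for name, lin in species:
        if lin in donors:
            host_groups.setdefault(lin, []).append(name)
    used_attachments: dict[str, set[str]] = {}
    for lin in sorted(host_groups):
        donor_lin = placement[lin]
        group = _join(
            [_leaf(name, rng) for name in host_groups[lin]], rng, support_level
        )
        taken = used_attachments.setdefault(donor_lin, set())
        candidates = [
            l for l in subtrees[donor_lin].leaves()
            if lineage_of.get(l.name) == donor_lin and l.name not in taken
        ]
        attach_to = candidates[int(rng.integers(len(candidates)))]
        taken.add(attach_to.name)
        _graft_sibling(attach_to, group, rng, support_level)

    backbone = _join(list(subtrees.values()), rng, support_level)
    # ensure a bifurcating designated root
    if len(backbone.children) != 2:
        backbone = Clade(children=[backbone])
    backbone.length = None
    backbone.support = None
    meta = {name: (name, lin) for name, lin in species}
    tree = GeneTree(backbone, meta, rooted=True)

    for _ in range(n_duplications):
        _plant_duplication(tree, duplication_size, rng, support_level, truth)
    for _ in range(n_hgt):
        _plant_hgt(tree, donors, lineage_of, rng, support_level, truth)
    return tree, truth


def _graft_sibling(
    node: Clade, newcomer: Clade, rng: np.random.Generator, support: float
) -> None:
    """Insert ``newcomer`` as sibling of ``node`` via a new internal node."""
    parent = node.parent
    joint = Clade(
        length=node.length, support=support, children=[],
    )
    if parent is not None:
        idx = parent.children.index(node)
        parent.children[idx] = joint
        joint.parent = parent
    node.length = float(rng.exponential(0.05)) + 0.01
    joint.add(node)
    joint.add(newcomer)


def _copy_subtree(node: Clade, suffix: str, meta: dict) -> Clade:
    fresh = Clade(name=None, length=node.length, support=node.support)
    if node.is_leaf:
        fresh.name = f"{node.name}{suffix}"
        meta[fresh.name] = meta.get(node.name, (node.name, "other"))
    for child in node.children:
        fresh.add(_copy_subtree(child, suffix, meta))
    return fresh


def _internal_nodes(root: Clade) -> list[Clade]:
    return [n for n in root.preorder() if not n.is_leaf and n.parent is not None]


def _plant_duplication(
    tree: GeneTree,
    size: int,
    rng: np.random.Generator,
    support: float,
    truth: SimulationTruth,
) -> None:
    candidates = []
    for order, node in enumerate(_internal_nodes(tree.root)):
        taxa = {tree.taxon_of(n) for n in node.leaf_names()}
        if len(taxa) == len(node.leaf_names()) and 2 <= len(taxa):
            candidates.append((node, len(taxa), order))
    if not candidates:
        raise InputError("no clade available for a planted duplication")
    # prefer clades at the requested size; preorder rank keeps ties stable
    candidates.sort(key=lambda c: (abs(c[1] - size), c[2]))
    best_score = abs(candidates[0][1] - size)
    pool = [c for c in candidates if abs(c[1] - size) == best_score]
    node, _, _ = pool[int(rng.integers(len(pool)))]
    parent = node.parent
    idx = parent.children.index(node)
    copy1 = _copy_subtree(node, ".1", tree.meta)
    copy2 = _copy_subtree(node, ".2", tree.meta)
    copy1.length = float(rng.exponential(0.05)) + 0.01
    copy2.length = float(rng.exponential(0.05)) + 0.01
    copy1.support = copy2.support = support
    joint = Clade(length=node.length, support=support, children=[copy1, copy2])
    parent.children[idx] = joint
    joint.parent = parent
    truth.events.append(
        {
            "type": "duplication",
            "taxa": sorted({tree.taxon_of(n) for n in joint.leaf_names()}),
            "left_leaves": sorted(copy1.leaf_names()),
            "right_leaves": sorted(copy2.leaf_names()),
        }
    )


def _plant_hgt(
    tree: GeneTree,
    donors: Mapping[str, str],
    lineage_of: Mapping[str, str],
    rng: np.random.Generator,
    support: float,
    truth: SimulationTruth,
) -> None:
    moved = {e["leaf"] for e in truth.events if e["type"] == "hgt"}
    recipients = sorted(
        name
        for name in tree.leaf_names()
        if tree.lineage_of(name) in donors and name not in moved
        and "." not in name  # skip duplicated copies for clarity of truth
    )
    if not recipients:
        raise InputError("no eligible HGT recipient left")
    leaf_name = recipients[int(rng.integers(len(recipients)))]
    host = tree.lineage_of(leaf_name)
    vertical_donor = donors[host]
    donor_pool = sorted(
        lin
        for lin in {lineage_of[n] for n in lineage_of}
        if lin not in donors and lin != vertical_donor and lin != host
        and sum(1 for n, l in lineage_of.items() if l == lin) >= 3
    )
    if not donor_pool:
        raise InputError("no foreign donor lineage with enough leaves")
    donor_lin = donor_pool[int(rng.integers(len(donor_pool)))]

    # detach the recipient leaf
    leaf = next(n for n in tree.root.preorder() if n.is_leaf and n.name == leaf_name)
    parent = leaf.parent
    parent.children.remove(leaf)
    if len(parent.children) == 1 and parent.parent is not None:
        only = parent.children[0]
        gp = parent.parent
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        idx = gp.children.index(parent)
        gp.children[idx] = only
        only.parent = gp

    candidates = [
        n for n in tree.root.preorder()
        if n.is_leaf and tree.lineage_of(n.name) == donor_lin
    ]
    attach_to = candidates[int(rng.integers(len(candidates)))]
    _graft_sibling(attach_to, leaf, rng, support)
    leaf.length = float(rng.exponential(0.05)) + 0.01
    truth.events.append(
        {
            "type": "hgt",
            "leaf": leaf_name,
            "recipient_lineage": host,
            "donor_lineage": donor_lin,
        }
    )


# ---------------------------------------------------------------------------
# complement tables
# ---------------------------------------------------------------------------

_COMPLEMENT_GROUPS = (
    "Chlorophyceae", "Bangiophyceae", "Bacillariophyceae",
    "Pelagophyceae", "Raphidophyceae", "Chroomonadaceae",
)


def simulate_complement_table(
    n_species: int = 60,
    loss_rate: float = 0.3,
    pseudo_rate: float = 0.15,
    coupling: float = 0.0,
    seed: int = 0,
) -> tuple[list[LiporRecord], SimulationTruth]:
    """Simulate per-species LIPOR complements coupled to por copy number.

    Each species draws a por count of 1 or 2 (fair coin).  Its LIPOR loss
    probability is ``loss_rate + coupling * (por_count - 1)`` clipped to
    [0, 1]: positive coupling makes duplicated-por species likelier to have
    lost LIPOR.  A lost complement is caught mid-loss (pseudogenes instead
    of clean absence) with probability ``pseudo_rate``.
    """
    for name, value in (("loss_rate", loss_rate), ("pseudo_rate", pseudo_rate)):
        if not (0.0 <= value <= 1.0):
            raise InputError(f"{name} must lie in [0, 1]")
    if not (-1.0 <= coupling <= 1.0):
        raise InputError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_species": n_species,
            "loss_rate": loss_rate,
            "pseudo_rate": pseudo_rate,
            "coupling": coupling,
        },
    )
    records: list[LiporRecord] = []
    for i in range(n_species):
        species = f"synthetic_species_{i:03d}"
        group = _COMPLEMENT_GROUPS[i % len(_COMPLEMENT_GROUPS)]
        por = 1 + int(rng.integers(2))
        p_loss = float(np.clip(loss_rate + coupling * (por - 1), 0.0, 1.0))
        lost = bool(rng.random() < p_loss)
        if not lost:
            statuses = ("present", "present", "present")
            state = "complete"
        elif rng.random() < pseudo_rate:
            statuses = tuple(
                "pseudogene" if rng.random() < 0.7 else "absent"
                for _ in range(3)
            )
            if "pseudogene" not in statuses:
                statuses = ("pseudogene",) + statuses[1:]
            state = "pseudogenized"
        else:
            statuses = ("absent", "absent", "absent")
            state = "absent"
        records.append(
            LiporRecord(
                species=species,
                group=group,
                chlL=statuses[0],
                chlN=statuses[1],
                chlB=statuses[2],
                por_count=por,
            )
        )
        truth.complements[species] = {
            "por_count": por,
            "p_loss": p_loss,
            "state": state,
        }
    return records, truth
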
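"""Gene-tree event calls: duplications, origins, and paralog labelling.

Two inferences are made on a rooted gene tree whose leaves carry taxon and
lineage tags:

*Duplication calls* use the species-overlap rule: an internal node whose two
child clades share taxa must postdate a gene duplication, because otherwise
each taxon would appear on only one side of the split.  Recurrence of the
same taxa in both principal branches (e.g. five dinoflagellate taxa on each
side) is the classic signature.

*Origin calls* classify a leaf's gene as vertically inherited or as a
xenolog (horizontally/endosymbiotically transferred).  Algae with plastids
of secondary origin are expected to carry the plastid donor's gene: the
CASH lineages (cryptophytes, alveolates, stramenopiles, haptophytes) should
nest among rhodophyte genes, euglenids among prasinophytes, and
chlorarachniophytes among UTC chlorophytes.  A leaf emerging instead inside
a well-supported clade of some other lineage is called a xenolog with that
lineage as donor.  Branches below the support threshold (by convention 0.95
posterior probability) contribute nothing; if no adequately supported,
sufficiently populated, sufficiently pure anchor clade exists the call is
left unresolved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .records import ConfigurationError
from .trees import Clade, GeneTree, TreeError

#: Expected plastid-donor lineage for hosts whose plastids arose by
#: secondary (or higher-order) endosymbiosis.
DEFAULT_DONOR_MAP: dict[str, str] = {
    "stramenopile": "rhodophyte",
    "haptophyte": "rhodophyte",
    "cryptophyte": "rhodophyte",
    "dinoflagellate": "rhodophyte",
    "euglenid": "prasinophyte",
    "chlorarachniophyte": "utc_chlorophyte",
}

DEFAULT_SUPPORT_THRESHOLD = 0.95
DEFAULT_PURITY_THRESHOLD = 0.8
DEFAULT_MIN_CONTEXT = 3
DEFAULT_MIN_SHARED = 2

MODE_VERTICAL = "vertical"
MODE_XENOLOG = "xenolog"
MODE_UNRESOLVED = "unresolved"

PRE_DUPLICATION_LABEL = "pre-duplication"


@dataclass(frozen=True)
class DuplicationCall:
    """A species-overlap duplication call at one internal node."""

    node_id: int
    shared_taxa: frozenset[str]
    left_leaves: frozenset[str]
    right_leaves: frozenset[str]
    support: float | None


@dataclass(frozen=True)
class OriginCall:
    """Vertical/xenolog classification of one leaf's gene."""

    leaf: str
    mode: str
    donor_lineage: str | None
    anchor_node: int | None
    anchor_support: float | None
    donor_purity: float


def _require_rooted(tree: GeneTree) -> None:
    if not tree.rooted:
        raise TreeError(
            "tree is unrooted; apply root_on_outgroup before event analysis"
        )


def _node_index(tree: GeneTree) -> dict[int, int]:
    """Stable preorder index for every node (id() -> index)."""
    return {id(node): i for i, node in enumerate(tree.root.preorder())}


def _support_ok(node: Clade, threshold: float) -> bool:
    # missing support passes: conclusions are only blocked by *measured*
    # weak support, matching the dashed-branch reading convention
    return node.support is None or node.support >= threshold


def detect_duplications(
    tree: GeneTree,
    min_shared: int = DEFAULT_MIN_SHARED,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
) -> list[DuplicationCall]:
    """Call duplications at nodes whose child clades share taxa.

    At a multifurcation every pair of children is evaluated and the node is
    called at most once, on the maximally overlapping pair.  Calls are
    reported in preorder; nested calls are allowed.
    """
    _require_rooted(tree)
    if min_shared < 1:
        raise ConfigurationError("min_shared must be >= 1")
    index = _node_index(tree)
    calls: list[DuplicationCall] = []
    for node in tree.root.preorder():
        if node.is_leaf or len(node.children) < 2:
            continue
        if not _support_ok(node, support_threshold):
            continue
        child_taxa = [
            {tree.taxon_of(name) for name in child.leaf_names()}
            for child in node.children
        ]
        best: tuple[int, int, set[str]] | None = None
        for i in range(len(node.children)):
            for j in range(i + 1, len(node.children)):
                shared = child_taxa[i] & child_taxa[j]
                if best is None or len(shared) > len(best[2]):
                    best = (i, j, shared)
        assert best is not None
        i, j, shared = best
        if len(shared) >= min_shared:
            calls.append(
                DuplicationCall(
                    node_id=index[id(node)],
                    shared_taxa=frozenset(shared),
                    left_leaves=frozenset(node.children[i].leaf_names()),
                    right_leaves=frozenset(node.children[j].leaf_names()),
                    support=node.support,
                )
            )
    return calls


def assign_origin(
    tree: GeneTree,
    leaf: str,
    donors: Mapping[str, str] | None = None,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    purity_threshold: float = DEFAULT_PURITY_THRESHOLD,
    min_context: int = DEFAULT_MIN_CONTEXT,
) -> OriginCall:
    """Classify one leaf's gene as vertical, xenolog, or unresolved.

    Walks rootward from the leaf.  The anchor is the first adequately
    supported ancestor whose clade holds at least ``min_context`` context
    leaves — leaves that are neither the query nor members of the query's
    own host lineage.  If the modal lineage among the context leaves reaches
    ``purity_threshold`` it is taken as the donor; a tie for the mode is
    never resolved by guessing.  The call is vertical when the donor equals
    the host's expected plastid-donor lineage, xenolog otherwise, and
    unresolved when the walk reaches the root without an anchor.
    """
    _require_rooted(tree)
    donors = DEFAULT_DONOR_MAP if donors is None else dict(donors)
    if not (0.0 <= purity_threshold <= 1.0):
        raise ConfigurationError("purity_threshold must lie in [0, 1]")
    leaf_node = next(
        (n for n in tree.root.preorder() if n.is_leaf and n.name == leaf), None
    )
    if leaf_node is None:
        raise TreeError(f"leaf {leaf!r} not found in tree")
    host_lineage = tree.lineage_of(leaf)
    if host_lineage not in donors:
        raise ConfigurationError(
            f"lineage {host_lineage!r} of leaf {leaf!r} has no expected donor "
            "in the donor map"
        )
    expected = donors[host_lineage]
    index = _node_index(tree)

    node = leaf_node.parent
    while node is not None:
        if _support_ok(node, support_threshold):
            context = [
                name
                for name in node.leaf_names()
                if name != leaf and tree.lineage_of(name) != host_lineage
            ]
            if len(context) >= min_context:
                counts = Counter(tree.lineage_of(name) for name in context)
                ranked = counts.most_common()
                top_lineage, top_count = ranked[0]
                share = top_count / len(context)
                if share >= purity_threshold:
                    tied = len(ranked) > 1 and ranked[1][1] == top_count
                    if tied:
                        return OriginCall(
                            leaf, MODE_UNRESOLVED, None,
                            index[id(node)], node.support, share,
                        )
                    mode = (
                        MODE_VERTICAL if top_lineage == expected
                        else MODE_XENOLOG
                    )
                    return OriginCall(
                        leaf, mode, top_lineage,
                        index[id(node)], node.support, share,
                    )
        node = node.parent
    return OriginCall(leaf, MODE_UNRESOLVED, None, None, None, 0.0)


def assign_origins(
    tree: GeneTree,
    donors: Mapping[str, str] | None = None,
    **kwargs,
) -> list[OriginCall]:
    """Origin calls for every leaf whose lineage appears in the donor map."""
    donors = DEFAULT_DONOR_MAP if donors is None else dict(donors)
    return [
        assign_origin(tree, name, donors, **kwargs)
        for name in tree.leaf_names()
        if tree.lineage_of(name) in donors
    ]


def classify_paralogs(
    tree: GeneTree,
    duplication: DuplicationCall,
    labels: tuple[str, str] = ("por1", "por2"),
) -> dict[str, str]:
    """Label every leaf by its side of a duplication.

    Leaves inside the duplication node's two child clades receive
    ``labels[0]``/``labels[1]``; leaves outside both (including those
    branching before the event) are labelled ``pre-duplication``.
    """
    assignment: dict[str, str] = {}
    for name in tree.leaf_names():
        if name in duplication.left_leaves:
            assignment[name] = labels[0]
        elif name in duplication.right_leaves:
            assignment[name] = labels[1]
        else:
            assignment[name] = PRE_DUPLICATION_LABEL
    return assignment


def paralog_taxon_summary(
    tree: GeneTree,
    assignment: Mapping[str, str],
    labels: tuple[str, str] = ("por1", "por2"),
) -> pd.DataFrame:
    """Per-taxon paralog complement: which labels each taxon possesses.

    The ``both`` column marks taxa carrying at least one copy of each
    paralog, the count reported when asking how many taxa retain the full
    post-duplication complement.
    """
    per_taxon: dict[str, set[str]] = {}
    for leaf, label in assignment.items():
        per_taxon.setdefault(tree.taxon_of(leaf), set()).add(label)
    rows = []
    for taxon in sorted(per_taxon):
        got = per_taxon[taxon]
        rows.append(
            {
                "taxon": taxon,
                labels[0]: labels[0] in got,
                labels[1]: labels[1] in got,
                "pre_duplication": PRE_DUPLICATION_LABEL in got,
                "both": labels[0] in got and labels[1] in got,
            }
        )
    return pd.DataFrame(rows)


def duplication_calls_table(calls: Sequence[DuplicationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node_id": c.node_id,
                "n_shared_taxa": len(c.shared_taxa),
                "shared_taxa": ";".join(sorted(c.shared_taxa)),
                "n_left": len(c.left_leaves),
                "n_right": len(c.right_leaves),
                "support": c.support,
            }
            for c in calls
        ]
    )


def origin_calls_table(calls: Sequence[OriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "leaf": c.leaf,
                "mode": c.mode,
                "donor_lineage": c.donor_lineage,
                "anchor_node": c.anchor_node,
                "anchor_support": c.anchor_support,
                "donor_purity": round(c.donor_purity, 6),
            }
            for c in calls
        ]
    )
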
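"""Taxonomic classification of predicted proteins.

Two ingredients: a naive lowest-common-ancestor (LCA) assignment rule over
the retained protein database hits (MEGAN-style: keep hits within a bit-score
window below the best hit, assign the LCA of their taxa), and a two-step
search-space restriction that first classifies essential single-copy gene
(ESCG) marker homologs against the full database, derives the set of orders
those markers belong to, and then classifies all proteins against the
database restricted to those orders.  The restriction trades sensitivity to
rare out-of-space taxa for a drastically smaller second search.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

# Canonical rank ladder, broadest first.  Nodes with other rank strings
# ("no rank", "strain", ...) are transparent when walking to a target rank.
RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]


class TaxonomyError(ValueError):
    """Invalid taxonomy structure or unknown taxid."""


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted, rank-annotated taxonomy supporting LCA queries.

    The root is the unique node whose parent is itself.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[int, TaxNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyError(
                    f"node {node.taxid} has unknown parent {node.parent}"
                )
        # cycle check doubles as reachability proof: every walk must end at root
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise TaxonomyError(f"cycle involving taxid {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    @classmethod
    def from_files(
        cls, nodes_path: str | Path, names_path: str | Path
    ) -> "TaxonomyTree":
        nodes: list[TaxNode] = []
        with open(nodes_path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header and header[0].lstrip("#").strip().isdigit():
                fh.seek(0)
                reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row:
                    continue
                nodes.append(TaxNode(int(row[0]), int(row[1]), row[2]))
        names: dict[int, str] = {}
        with open(names_path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            if header and header[0].lstrip("#").strip().isdigit():
                fh.seek(0)
                reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row:
                    continue
                names[int(row[0])] = row[1]
        for node in nodes:
            node.name = names.get(node.taxid, str(node.taxid))
        return cls(nodes)

    def to_files(self, nodes_path: str | Path, names_path: str | Path) -> None:
        with open(nodes_path, "w") as fh:
            fh.write("taxid\tparent_taxid\trank\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\n")
        with open(names_path, "w") as fh:
            fh.write("taxid\tname\n")
            for taxid in sorted(self.nodes):
                fh.write(f"{taxid}\t{self.nodes[taxid].name}\n")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def name(self, taxid: int) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid].rank

    def path(self, taxid: int) -> list[int]:
        """Root-to-node taxid path (inclusive)."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        out = [taxid]
        while taxid != self.root:
            taxid = self.nodes[taxid].parent
            out.append(taxid)
        return out[::-1]

    def depth(self, taxid: int) -> int:
        return len(self.path(taxid)) - 1

    def lca(self, taxids: Iterable[int]) -> int | None:
        """Deepest node ancestral-or-equal to every input taxid.

        ``None`` (the unclassified sentinel) for an empty input.
        """
        paths = [self.path(t) for t in taxids]
        if not paths:
            return None
        best = paths[0]
        for p in paths[1:]:
            n = 0
            for a, b in zip(best, p):
                if a != b:
                    break
                n += 1
            best = best[:n]
        return best[-1]

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """Ancestor-or-self of ``taxid`` at the named rank, if any.

        Nodes with non-ladder rank strings are skipped transparently.
        """
        for t in self.path(taxid)[::-1]:
            if self.nodes[t].rank == rank:
                return t
        return None

    def rank_path(self, taxid: int) -> str:
        """Readable lineage string restricted to the canonical ranks."""
        parts = []
        for t in self.path(taxid):
            if self.nodes[t].rank in RANKS:
                parts.append(f"{self.nodes[t].rank}:{self.nodes[t].name}")
        return ";".join(parts)

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        return ancestor in self.path(taxid)


@dataclass
class LcaParams:
    """MEGAN-conventional LCA parameters.

    Hits with bit score below ``min_bit`` or more than ``top_percent`` %
    below the best hit are discarded before taking the LCA; a query with
    fewer than ``min_support`` retained hits stays unclassified.
    """

    min_bit: float = 50.0
    top_percent: float = 10.0
    min_support: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.top_percent <= 100):
            raise ValueError("top_percent must be in (0, 100]")


@dataclass
class MarkerSet:
    """Proteins recognised as single-copy marker (ESCG) homologs."""

    members: dict[str, str] = field(default_factory=dict)  # protein id -> family
    srv: dict[str, float] = field(default_factory=dict)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.members

    def __len__(self) -> int:
        return len(self.members)


class NoSearchSpaceError(RuntimeError):
    """No taxonomic search space could be derived from the markers."""


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int | None:
    return tree.lca(taxids)


def classify_protein(
    hits: Sequence,
    subject_taxids: Mapping[str, int],
    tree: TaxonomyTree,
    params: LcaParams | None = None,
) -> int | None:
    """Assign one protein by naive LCA over its retained hits.

    ``hits`` must be sorted by bit score descending (as ``annotation.search``
    returns them).  Returns a taxid or ``None`` (unclassified).
    """
    params = params or LcaParams()
    if not hits:
        return None
    best = hits[0].bit_score
    floor = max(params.min_bit, (1.0 - params.top_percent / 100.0) * best)
    retained = [
        subject_taxids[h.subject_id] for h in hits if h.bit_score >= floor
    ]
    if len(retained) < params.min_support:
        return None
    for t in retained:
        if t not in tree:
            raise TaxonomyError(f"unknown taxid {t} among hits")
    return tree.lca(retained)


def identify_escg(
    proteins: Mapping[str, str],
    marker_db,
    min_srv: float = 0.5,
) -> MarkerSet:
    """Flag proteins whose best marker-database hit has SRV >= ``min_srv``.

    ``marker_db`` is a :class:`~metatx.annotation.ReferenceProteinDB` whose
    label table carries a ``family`` column.  A flagged protein inherits the
    family of its best hit.
    """
    from . import annotation

    hits = annotation.search(proteins, marker_db, prefilter=False)
    out = MarkerSet()
    for pid, hit_list in hits.items():
        if not hit_list:
            continue
        score = annotation.srv(proteins[pid], hit_list).srv
        if score >= min_srv:
            fam = marker_db.label(hit_list[0].subject_id, "family")
            out.members[pid] = fam or hit_list[0].subject_id
            out.srv[pid] = score
    return out


def restrict_search_space(
    marker_taxids: Mapping[str, int | None],
    tree: TaxonomyTree,
    rank: str = "order",
    min_marker_count: int = 1,
) -> set[int]:
    """Rank-level taxa claiming at least ``min_marker_count`` markers.

    Markers unclassified at the rank (``None`` taxid, or classified above
    it) are ignored.
    """
    counts: dict[int, int] = {}
    for taxid in marker_taxids.values():
        if taxid is None:
            continue
        anc = tree.rank_ancestor(taxid, rank)
        if anc is not None:
            counts[anc] = counts.get(anc, 0) + 1
    return {t for t, c in counts.items() if c >= min_marker_count}


@dataclass
class TwoStepResult:
    assignments: dict[str, int | None]
    markers: MarkerSet
    marker_taxids: dict[str, int | None]
    search_space: set[int]


def classify_two_step(
    proteins: Mapping[str, str],
    db,
    tree: TaxonomyTree,
    marker_db,
    params: LcaParams | None = None,
    rank: str = "order",
    min_srv: float = 0.5,
    min_marker_count: int = 1,
    exclude_taxids: set[int] | None = None,
) -> TwoStepResult:
    """Marker-restricted two-step classification of all proteins.

    Step 1 classifies ESCG marker homologs against the full database and
    derives the set of ``rank``-level taxa they support.  Step 2 classifies
    every protein against the database restricted to those taxa.  Proteins
    of taxa outside the derived space end up unclassified (or, if they have
    paralogs inside the space, misattributed) — the documented cost of the
    restriction.

    ``exclude_taxids`` removes database proteins of the given taxa from both
    searches (leave-self-out evaluation).
    """
    from . import annotation

    params = params or LcaParams()
    full_db = db.exclude(exclude_taxids) if exclude_taxids else db

    markers = identify_escg(proteins, marker_db, min_srv=min_srv)
    if not markers:
        raise NoSearchSpaceError("no marker proteins identified")
    marker_seqs = {pid: proteins[pid] for pid in markers.members}
    step1_hits = annotation.search(marker_seqs, full_db)
    marker_taxids = {
        pid: classify_protein(step1_hits.get(pid, []), full_db.taxids, tree, params)
        for pid in marker_seqs
    }
    space = restrict_search_space(
        marker_taxids, tree, rank=rank, min_marker_count=min_marker_count
    )
    if not space:
        raise NoSearchSpaceError(
            "no search space: no marker classified at rank " + rank
        )

    keep = {
        pid
        for pid, taxid in full_db.taxids.items()
        if tree.rank_ancestor(taxid, rank) in space
    }
    restricted = full_db.subset(keep)
    step2_hits = annotation.search(proteins, restricted)
    assignments = {
        pid: classify_protein(
            step2_hits.get(pid, []), restricted.taxids, tree, params
        )
        for pid in proteins
    }
    return TwoStepResult(assignments, markers, marker_taxids, space)


def classify_one_step(
    proteins: Mapping[str, str],
    db,
    tree: TaxonomyTree,
    params: LcaParams | None = None,
    exclude_taxids: set[int] | None = None,
) -> dict[str, int | None]:
    """Single-pass LCA classification against the full database."""
    from . import annotation

    params = params or LcaParams()
    full_db = db.exclude(exclude_taxids) if exclude_taxids else db
    hits = annotation.search(proteins, full_db)
    return {
        pid: classify_protein(hits.get(pid, []), full_db.taxids, tree, params)
        for pid in proteins
    }


def taxonomic_profile(
    protein_taxids: Mapping[str, int | None],
    read_counts: Mapping[str, int],
    tree: TaxonomyTree,
    rank: str,
):
    """Read-weighted taxonomic profile at one rank.

    Each protein's reads are credited to the ``rank``-level ancestor of its
    assigned taxon; proteins unclassified at (or above) the rank pool into
    an ``unclassified`` row.  Returns a DataFrame with columns
    taxon / taxid / reads / fraction (fractions sum to 1).
    """
    import pandas as pd

    rows: dict[tuple[str, int | None], int] = {}
    for pid, count in read_counts.items():
        taxid = protein_taxids.get(pid)
        anc = tree.rank_ancestor(taxid, rank) if taxid is not None else None
        key = (tree.name(anc), anc) if anc is not None else ("unclassified", None)
        rows[key] = rows.get(key, 0) + count
    total = sum(rows.values())
    df = pd.DataFrame(
        [
            {
                "taxon": name,
                "taxid": taxid if taxid is not None else -1,
                "reads": reads,
                "fraction": reads / total if total else 0.0,
            }
            for (name, taxid), reads in sorted(rows.items(), key=lambda kv: kv[0][0])
        ]
    )
    return df
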
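"""Taxonomy tree, reference genomes, and the queries built on them.

The taxonomy is a rooted tree of nodes with ranks drawn from a fixed
enumeration (root at the top, strain at the bottom). Every downstream
step — k-mer LCA indexing, Bracken-style rank redistribution, genus
vector construction — reduces to two queries on this tree: lowest
common ancestor of two taxa, and the unique ancestor of a taxon at a
requested rank.

The on-disk format is a 4-column TSV (taxid, parent_taxid, rank, name);
the root is encoded as its own parent. Reference genomes are plain
FASTA plus a genome-id -> taxid mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

RANKS: tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


class TaxonomyError(ValueError):
    """Raised for malformed or inconsistent taxonomy input."""


@dataclass(frozen=True, slots=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    name: str

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise TaxonomyError(f"taxid must be positive, got {self.taxid}")
        if self.rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {self.rank!r} for taxid {self.taxid}")


class Taxonomy:
    """Validated rooted tree of :class:`TaxonomyNode` with LCA support."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[int, TaxonomyNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        if not self.nodes:
            raise TaxonomyError("taxonomy is empty")

        roots = [n.taxid for n in self.nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self.root_taxid: int = roots[0]

        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} has orphan parent {node.parent_taxid}"
                )

        # parent walk from every node must reach root without revisiting
        self._paths: dict[int, tuple[int, ...]] = {}
        for taxid in self.nodes:
            self._path_to_root(taxid)

        for node in self.nodes.values():
            if node.taxid == self.root_taxid:
                continue
            parent = self.nodes[node.parent_taxid]
            if RANK_INDEX[node.rank] < RANK_INDEX[parent.rank]:
                raise TaxonomyError(
                    f"rank of {node.taxid} ({node.rank}) outranks its parent "
                    f"({parent.rank})"
                )

        self._children: dict[int, list[int]] = {t: [] for t in self.nodes}
        for node in self.nodes.values():
            if node.taxid != self.root_taxid:
                self._children[node.parent_taxid].append(node.taxid)
        for kids in self._children.values():
            kids.sort()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        """Load from a 4-column TSV (taxid, parent, rank, name); header optional."""
        nodes: list[TaxonomyNode] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise TaxonomyError(
                        f"{path}:{lineno}: expected 4 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                if lineno == 1 and parts[0].lower() in {"taxid", "tax_id"}:
                    continue
                try:
                    taxid, parent = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise TaxonomyError(f"{path}:{lineno}: non-integer taxid") from exc
                nodes.append(TaxonomyNode(taxid, parent, parts[2], parts[3]))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxid\tparent_taxid\trank\tname\n")
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\n")

    # -- queries -----------------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxid: int) -> TaxonomyNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def _path_to_root(self, taxid: int) -> tuple[int, ...]:
        """Path root -> ... -> taxid, cached; detects cycles on first build."""
        cached = self._paths.get(taxid)
        if cached is not None:
            return cached
        path = []
        seen = set()
        t = taxid
        while True:
            if t in seen:
                raise TaxonomyError(f"cycle detected through taxid {t}")
            seen.add(t)
            path.append(t)
            node = self._require(t)
            if node.parent_taxid == t:
                if t != self.root_taxid:
                    raise TaxonomyError(f"secondary root at taxid {t}")
                break
            t = node.parent_taxid
        result = tuple(reversed(path))
        self._paths[taxid] = result
        return result

    def ancestors(self, taxid: int) -> tuple[int, ...]:
        """Root-to-self path of ``taxid``."""
        self._require(taxid)
        return self._path_to_root(taxid)

    def depth(self, taxid: int) -> int:
        return len(self.ancestors(taxid)) - 1

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor of taxids ``a`` and ``b``."""
        pa, pb = self.ancestors(a), self.ancestors(b)
        last = self.root_taxid
        for x, y in zip(pa, pb):
            if x != y:
                break
            last = x
        return last

    def ancestor_at_rank(self, taxid: int, rank: str) -> Optional[int]:
        """Unique ancestor-or-self of ``taxid`` at ``rank``, or None.

        None is returned both when ``taxid`` sits above the requested rank
        and when the root-to-self path skips that rank.
        """
        if rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rank!r}")
        target = RANK_INDEX[rank]
        t = self._require(taxid).taxid
        while True:
            node = self.nodes[t]
            idx = RANK_INDEX[node.rank]
            if idx == target:
                return t
            if idx < target or t == self.root_taxid:
                return None
            t = node.parent_taxid

    def children(self, taxid: int) -> Sequence[int]:
        self._require(taxid)
        return tuple(self._children[taxid])

    def descendants_at_rank(self, taxid: int, rank: str) -> tuple[int, ...]:
        """All nodes at ``rank`` in the subtree rooted at ``taxid`` (incl. self)."""
        if rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rank!r}")
        out: list[int] = []
        stack = [self._require(taxid).taxid]
        while stack:
            t = stack.pop()
            if self.nodes[t].rank == rank:
                out.append(t)
                continue  # rank order is monotone; nothing at `rank` deeper
            stack.extend(self._children[t])
        return tuple(sorted(out))

    def name(self, taxid: int) -> str:
        return self._require(taxid).name


# -- reference genomes -----------------------------------------------------


@dataclass(slots=True)
class GenomeRecord:
    """One reference genome: id, taxid, and one or more sequences."""

    genome_id: str
    taxid: int
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError(f"genome {self.genome_id} has zero total length")

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences)


class ReferenceSet:
    """A collection of genomes tied to one taxonomy."""

    def __init__(self, genomes: Iterable[GenomeRecord], taxonomy: Taxonomy):
        self.taxonomy = taxonomy
        self.genomes: dict[str, GenomeRecord] = {}
        for g in genomes:
            if g.genome_id in self.genomes:
                raise ValueError(f"duplicate genome id {g.genome_id}")
            if g.taxid not in taxonomy:
                raise TaxonomyError(
                    f"genome {g.genome_id} taxid {g.taxid} not in taxonomy"
                )
            self.genomes[g.genome_id] = g

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes.values())

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self.genomes[genome_id]

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        taxonomy: Taxonomy,
        genome_taxids: Mapping[str, int],
        on_ambiguous: str = "reject",
    ) -> "ReferenceSet":
        """Load genomes from multi-record FASTA.

        Records map to genomes via ``genome_taxids`` keyed on the FASTA id.
        ``on_ambiguous`` controls non-ACGT characters: "reject" raises,
        "mask" replaces them with ``N`` (excluded from k-mer indexing).
        """
        if on_ambiguous not in {"reject", "mask"}:
            raise ValueError("on_ambiguous must be 'reject' or 'mask'")
        genomes: list[GenomeRecord] = []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id not in genome_taxids:
                raise ValueError(f"no taxid mapping for FASTA record {rec.id!r}")
            seq = str(rec.seq).upper()
            bad = set(seq) - set("ACGT")
            if bad:
                if on_ambiguous == "reject":
                    raise ValueError(
                        f"record {rec.id!r} contains non-ACGT characters {sorted(bad)}"
                    )
                seq = "".join(c if c in "ACGT" else "N" for c in seq)
            genomes.append(GenomeRecord(rec.id, genome_taxids[rec.id], [seq]))
        return cls(genomes, taxonomy)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for g in self.genomes.values():
                for i, seq in enumerate(g.sequences):
                    header = g.genome_id if len(g.sequences) == 1 else f"{g.genome_id}.{i}"
                    fh.write(f">{header}\n")
                    for j in range(0, len(seq), width):
                        fh.write(seq[j : j + width] + "\n")
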
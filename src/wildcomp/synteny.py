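"""Syntenic gene block calling from a homolog-pair table.

Blocks are chains of homologous gene pairs on one (scaffold, chromosome)
pair whose ordinals along both genomes are strictly monotone (increasing,
or decreasing on one side for inverted blocks), subject to the two calling
criteria: at least ``min_block_genes`` member genes and fewer than
``max_gap`` intervening genes between adjacent members on BOTH gene orders.

Chains are extracted iteratively: the best remaining chain — most genes,
then smallest summed gap, then lexicographically smallest ordinal sequence
— is emitted and its genes retired, so no gene appears in two blocks on the
same sequence pair.  A post-hoc validator re-checks every emitted block
against the printed criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .io import GenomeAnnotation, WildcompError


class ConsistencyError(WildcompError):
    pass


class GeneOrderIndex:
    """Genes of one genotype ordered by start coordinate per sequence."""

    def __init__(self, genome: GenomeAnnotation):
        self.sequence_of: dict[str, str] = {}
        self.ordinal: dict[str, int] = {}
        self.strand: dict[str, str] = {}
        self.order: dict[str, list[str]] = {}
        for scaffold in genome.sequences:
            ids = [g.gene_id for g in genome.genes_on(scaffold)]
            self.order[scaffold] = ids
            for i, gid in enumerate(ids):
                self.sequence_of[gid] = scaffold
                self.ordinal[gid] = i
                self.strand[gid] = genome.gene(gid).strand

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ordinal


@dataclass(frozen=True)
class SyntenicBlock:
    scaffold_id: str
    chromosome_id: str
    members: tuple[tuple[str, str], ...]  # ordered (gene_A, gene_B) pairs
    orientation: str  # "same" | "inverted"
    max_internal_gap: int
    summed_gap: int

    @property
    def n_genes(self) -> int:
        return len(self.members)


class _Node(NamedTuple):
    ord_a: int
    ord_b: int
    gene_a: str
    gene_b: str


def _gap(p: _Node, q: _Node) -> tuple[int, int]:
    return q.ord_a - p.ord_a - 1, abs(q.ord_b - p.ord_b) - 1


def _edge(p: _Node, q: _Node, max_gap: int, inverted: bool) -> bool:
    if q.ord_a <= p.ord_a or q.ord_a - p.ord_a - 1 >= max_gap:
        return False
    if inverted:
        return q.ord_b < p.ord_b and p.ord_b - q.ord_b - 1 < max_gap
    return q.ord_b > p.ord_b and q.ord_b - p.ord_b - 1 < max_gap


def _best_chain(nodes: list[_Node], max_gap: int, inverted: bool) -> list[_Node]:
    """Optimal chain under (max length, min summed gap, lex-smallest ordinals).

    Backward DP over nodes sorted by ordinal, then forward reconstruction
    choosing at each step the smallest-ordinal continuation that preserves
    optimality — yielding the lexicographically smallest optimal chain.
    """
    if not nodes:
        return []
    nodes = sorted(nodes)
    n = len(nodes)
    len_from = [1] * n
    gap_from = [0] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if nodes[j].ord_a - nodes[i].ord_a - 1 >= max_gap:
                break
            if not _edge(nodes[i], nodes[j], max_gap, inverted):
                continue
            ga, gb = _gap(nodes[i], nodes[j])
            cand = (1 + len_from[j], gap_from[j] + ga + gb)
            if cand[0] > len_from[i] or (cand[0] == len_from[i] and cand[1] < gap_from[i]):
                len_from[i], gap_from[i] = cand
    best_len = max(len_from)
    best_gap = min(g for l, g in zip(len_from, gap_from) if l == best_len)
    starts = [i for i in range(n) if len_from[i] == best_len and gap_from[i] == best_gap]
    cur = min(starts, key=lambda i: (nodes[i].ord_a, nodes[i].ord_b))
    chain = [nodes[cur]]
    while len_from[cur] > 1:
        nxt = None
        for j in range(cur + 1, n):
            if nodes[j].ord_a - nodes[cur].ord_a - 1 >= max_gap:
                break
            if not _edge(nodes[cur], nodes[j], max_gap, inverted):
                continue
            ga, gb = _gap(nodes[cur], nodes[j])
            if len_from[j] == len_from[cur] - 1 and gap_from[j] + ga + gb == gap_from[cur]:
                if nxt is None or (nodes[j].ord_a, nodes[j].ord_b) < (nodes[nxt].ord_a, nodes[nxt].ord_b):
                    nxt = j
        assert nxt is not None, "reconstruction must follow the DP optimum"
        cur = nxt
        chain.append(nodes[cur])
    return chain


def _chain_key(chain: list[_Node]) -> tuple:
    gaps = [sum(_gap(p, q)) for p, q in zip(chain, chain[1:])]
    return (-len(chain), sum(gaps), tuple(n.ord_a for n in chain), tuple(n.ord_b for n in chain))


def call_blocks(
    pairs: pd.DataFrame,
    order_A: GeneOrderIndex,
    order_B: GeneOrderIndex,
    min_block_genes: int = 3,
    max_gap: int = 5,
    allow_inversions: bool = True,
) -> list[SyntenicBlock]:
    """Call syntenic blocks from homolog pairs (columns gene_A, gene_B)."""
    grouped: dict[tuple[str, str], list[_Node]] = {}
    for gene_a, gene_b in zip(pairs["gene_A"], pairs["gene_B"]):
        if gene_a not in order_A:
            raise ConsistencyError(f"{gene_a} not in genotype-A annotation")
        if gene_b not in order_B:
            raise ConsistencyError(f"{gene_b} not in genotype-B annotation")
        key = (order_A.sequence_of[gene_a], order_B.sequence_of[gene_b])
        grouped.setdefault(key, []).append(
            _Node(order_A.ordinal[gene_a], order_B.ordinal[gene_b], gene_a, gene_b)
        )

    blocks: list[SyntenicBlock] = []
    for (scaf, chrom), nodes in sorted(grouped.items()):
        nodes = sorted(set(nodes))
        while True:
            candidates = [(False, _best_chain(nodes, max_gap, False))]
            if allow_inversions:
                candidates.append((True, _best_chain(nodes, max_gap, True)))
            candidates = [(inv, c) for inv, c in candidates if len(c) >= min_block_genes]
            if not candidates:
                break
            # prefer same-orientation on exact ties (key ignores orientation)
            inv, chain = min(candidates, key=lambda ic: (_chain_key(ic[1]), ic[0]))
            gaps = [_gap(p, q) for p, q in zip(chain, chain[1:])]
            blocks.append(
                SyntenicBlock(
                    scaffold_id=scaf,
                    chromosome_id=chrom,
                    members=tuple((nd.gene_a, nd.gene_b) for nd in chain),
                    orientation="inverted" if inv else "same",
                    max_internal_gap=max(max(ga, gb) for ga, gb in gaps) if gaps else 0,
                    summed_gap=sum(ga + gb for ga, gb in gaps),
                )
            )
            used_a = {nd.gene_a for nd in chain}
            used_b = {nd.gene_b for nd in chain}
            nodes = [nd for nd in nodes if nd.gene_a not in used_a and nd.gene_b not in used_b]
    return blocks


def validate_blocks(
    blocks: list[SyntenicBlock],
    order_A: GeneOrderIndex,
    order_B: GeneOrderIndex,
    min_block_genes: int = 3,
    max_gap: int = 5,
) -> None:
    """Re-check every emitted block against the calling criteria."""
    seen: dict[tuple[str, str], set[str]] = {}
    for blk in blocks:
        if blk.n_genes < min_block_genes:
            raise ConsistencyError(f"block on {blk.scaffold_id}: only {blk.n_genes} genes")
        ords_a = [order_A.ordinal[a] for a, _ in blk.members]
        ords_b = [order_B.ordinal[b] for _, b in blk.members]
        inc_a = all(x < y for x, y in zip(ords_a, ords_a[1:]))
        inc_b = all(x < y for x, y in zip(ords_b, ords_b[1:]))
        dec_b = all(x > y for x, y in zip(ords_b, ords_b[1:]))
        if not inc_a or not (inc_b if blk.orientation == "same" else dec_b):
            raise ConsistencyError(f"block on {blk.scaffold_id}: ordinals not monotone")
        for (xa, ya), (xb, yb) in zip(zip(ords_a, ords_a[1:]), zip(ords_b, ords_b[1:])):
            if ya - xa - 1 >= max_gap or abs(yb - xb) - 1 >= max_gap:
                raise ConsistencyError(f"block on {blk.scaffold_id}: gap criterion violated")
        key = (blk.scaffold_id, blk.chromosome_id)
        pool = seen.setdefault(key, set())
        for a, b in blk.members:
            if a in pool or b in pool:
                raise ConsistencyError(f"gene {a}/{b} in two blocks on {key}")
            pool.update((a, b))


def syntenic_gene_set(blocks: list[SyntenicBlock]) -> tuple[set[str], set[str]]:
    """Union of member genes per genotype; the PAV caller's exclusion set."""
    genes_a: set[str] = set()
    genes_b: set[str] = set()
    for blk in blocks:
        for a, b in blk.members:
            genes_a.add(a)
            genes_b.add(b)
    return genes_a, genes_b


class BlockSummary(NamedTuple):
    n_blocks: int
    n_genes_total: int
    mean_genes_per_block: float

    @property
    def mean_rounded(self) -> int:
        return int(round(self.mean_genes_per_block))


def block_summary(blocks: list[SyntenicBlock]) -> BlockSummary:
    if not blocks:
        return BlockSummary(0, 0, 0.0)
    total = sum(b.n_genes for b in blocks)
    return BlockSummary(len(blocks), total, total / len(blocks))


def summary_from_totals(n_genes_total: int, n_blocks: int) -> BlockSummary:
    """Summary from reported totals (e.g. published genome-scale counts)."""
    if n_blocks == 0:
        return BlockSummary(0, n_genes_total, 0.0)
    return BlockSummary(n_blocks, n_genes_total, n_genes_total / n_blocks)


def blocks_table(blocks: list[SyntenicBlock], a: GenomeAnnotation, b: GenomeAnnotation) -> pd.DataFrame:
    rows = []
    for blk in blocks:
        ga = [a.gene(x) for x, _ in blk.members]
        gb = [b.gene(y) for _, y in blk.members]
        rows.append(
            {
                "scaffold": blk.scaffold_id,
                "chromosome": blk.chromosome_id,
                "start_A": min(g.start for g in ga),
                "end_A": max(g.end for g in ga),
                "start_B": min(g.start for g in gb),
                "end_B": max(g.end for g in gb),
                "orientation": blk.orientation,
                "n_genes": blk.n_genes,
                "max_internal_gap": blk.max_internal_gap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold", "chromosome", "start_A", "end_A", "start_B", "end_B",
            "orientation", "n_genes", "max_internal_gap",
        ],
    )
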
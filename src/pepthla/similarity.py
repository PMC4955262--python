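"""Degree-of-similarity (DoS) between 9-mers and exact neighbor search.

The DoS of two 9-mers is the number of positions at which they carry the
same residue (equivalently 9 minus the Hamming distance).  Two peptides are
considered similar — a potential cross-reactivity pair — when DoS >= 5,
i.e. at most 4 mismatches.

Searching an 11-million-peptide proteome index for all neighbors of a query
at DoS >= 5 is done with a pigeonhole block index: the 9 positions are split
into 5 blocks, so any peptide within 4 mismatches of the query must match it
exactly in at least one block.  Candidates are the union of exact-block
matches, then verified by a full DoS computation — exact by construction,
with zero false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .proteome import K, STANDARD_AA, Peptide9, ProteomeIndex


class SimilarityError(ValueError):
    pass


#: Position blocks for the pigeonhole filter (0-based, contiguous).
#: 5 blocks tolerate up to 4 mismatches, i.e. min_dos >= 5.
_BLOCKS: tuple[tuple[int, int], ...] = ((0, 2), (2, 4), (4, 6), (6, 8), (8, 9))

#: Below this index size a linear scan beats building the block tables.
_LINEAR_SCAN_MAX = 200


def _check(seq: str, what: str = "peptide") -> None:
    if len(seq) != K or any(c not in STANDARD_AA for c in seq):
        raise SimilarityError(f"{what} must be a 9-mer over the standard alphabet: {seq!r}")


def dos(a: str, b: str) -> tuple[int, frozenset[int]]:
    """DoS and the 1-based set of identical positions of two 9-mers."""
    _check(a)
    _check(b)
    same = frozenset(i + 1 for i in range(K) if a[i] == b[i])
    return len(same), same


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    candidate: Peptide9
    dos: int
    identical_positions: frozenset[int]

    def sort_key(self):
        return (-self.dos, self.candidate.sequence)


class NeighborIndex:
    """Pigeonhole block tables over a proteome index, built once per index."""

    def __init__(self, index: ProteomeIndex):
        self.index = index
        self._tables: list[dict[str, list[str]]] | None = None
        if index.n_peptides > _LINEAR_SCAN_MAX:
            self._tables = [dict() for _ in _BLOCKS]
            for seq in index.peptides:
                for t, (lo, hi) in zip(self._tables, _BLOCKS):
                    t.setdefault(seq[lo:hi], []).append(seq)

    def candidates(self, query: str):
        if self._tables is None:
            return self.index.peptides.keys()
        seen: set[str] = set()
        for t, (lo, hi) in zip(self._tables, _BLOCKS):
            for seq in t.get(query[lo:hi], ()):
                seen.add(seq)
        return seen


def find_similar(
    query: str,
    index: ProteomeIndex | NeighborIndex,
    min_dos: int = 5,
    query_genes: set[str] | None = None,
) -> list[SimilarityHit]:
    """All index peptides with DoS(query, ·) >= min_dos, sorted.

    Results are sorted by descending DoS, ties broken lexicographically by
    candidate sequence, so reports are deterministic.

    The query's own dos=9 self-hit is excluded when its occurrences lie
    entirely within *query_genes* (the target's own source genes; their
    expression is already handled by the specificity filter).  An identical
    peptide that also occurs in a *different* gene is a legitimate off-target
    and is kept.  When *query_genes* is None it defaults to the gene set of
    the query's own index entry.
    """
    _check(query, "query")
    if not 5 <= min_dos <= 9:
        raise SimilarityError(f"min_dos must be in [5, 9], got {min_dos}")
    nbr = index if isinstance(index, NeighborIndex) else NeighborIndex(index)
    pindex = nbr.index
    if query_genes is None:
        query_genes = pindex[query].gene_symbols if query in pindex else set()
    hits: list[SimilarityHit] = []
    for seq in nbr.candidates(query):
        d, same = dos(query, seq)
        if d < min_dos:
            continue
        pep = pindex[seq]
        if seq == query and not (pep.gene_symbols - query_genes):
            continue
        hits.append(SimilarityHit(query, pep, d, same))
    hits.sort(key=SimilarityHit.sort_key)
    return hits


def find_similar_bruteforce(
    query: str,
    index: ProteomeIndex,
    min_dos: int = 5,
    query_genes: set[str] | None = None,
) -> list[SimilarityHit]:
    """Position-by-position linear scan; the oracle for the block index."""
    _check(query, "query")
    if query_genes is None:
        query_genes = index[query].gene_symbols if query in index else set()
    hits = []
    for seq, pep in index.peptides.items():
        same = frozenset(i + 1 for i in range(K) if query[i] == seq[i])
        if len(same) < min_dos:
            continue
        if seq == query and not (pep.gene_symbols - query_genes):
            continue
        hits.append(SimilarityHit(query, pep, len(same), same))
    hits.sort(key=SimilarityHit.sort_key)
    return hits


def important_overlap(hit: SimilarityHit, important_positions: set[int] | frozenset[int]) -> int:
    """Number of identical positions that are also important for TCR binding.

    Downstream, a similar peptide is only retained as an off-target when this
    overlap is at least 3 (at least 3 peptide positions participate in TCR
    recognition).
    """
    return len(hit.identical_positions & frozenset(important_positions))
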
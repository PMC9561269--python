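"""Local de Bruijn graph assembler.

Used twice by the pipeline: to assemble the poorly-aligned set U into
orphan contigs, and to reassemble per-barcode-list read pools into
anchored contigs. The graph is node-centric: nodes are canonical
k-mers with multiplicities, and an edge exists between two k-mers
overlapping by k-1 whenever both nodes are present (edge coverage is
the min of the endpoint multiplicities). Simplification interleaves a
coverage cutoff, tip clipping and simple two-path bubble popping until
a fixpoint.

External assemblers remain pluggable: an assembler is any callable
mapping an iterable of read sequences to a list of :class:`Contig`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Optional

from ._dna import revcomp

log = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    k: int = 31
    coverage_cutoff: int = 3
    min_contig_length: int = 200
    max_tip_length: Optional[int] = None  # None -> 2 * k

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 15")
        if self.coverage_cutoff < 0:
            raise ValueError("coverage_cutoff must be >= 0")
        if self.max_tip_length is None:
            self.max_tip_length = 2 * self.k


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


class DeBruijnGraph:
    """Canonical k-mer multiset with implicit (k-1)-overlap edges."""

    def __init__(self, k: int, nodes: Optional[dict[str, int]] = None) -> None:
        self.k = k
        self.nodes: dict[str, int] = nodes if nodes is not None else {}

    def __len__(self) -> int:
        return len(self.nodes)

    def count(self, kmer: str) -> int:
        return self.nodes.get(_canon(kmer), 0)

    def successors_rc(self, kmer: str, rc: str) -> list[tuple[str, str]]:
        """(oriented k-mer, its revcomp) pairs reachable by appending a base.

        Carrying the reverse complement incrementally keeps the walk
        O(k) per step instead of re-complementing each candidate.
        """
        stem = kmer[1:]
        rc_stem = rc[:-1]
        out = []
        for b in "ACGT":
            nxt = stem + b
            rc_nxt = _COMP1[b] + rc_stem
            if (nxt if nxt <= rc_nxt else rc_nxt) in self.nodes:
                out.append((nxt, rc_nxt))
        return out

    def predecessors_rc(self, kmer: str, rc: str) -> list[tuple[str, str]]:
        stem = kmer[:-1]
        rc_stem = rc[1:]
        out = []
        for b in "ACGT":
            prv = b + stem
            rc_prv = rc_stem + _COMP1[b]
            if (prv if prv <= rc_prv else rc_prv) in self.nodes:
                out.append((prv, rc_prv))
        return out

    def successors(self, kmer: str) -> list[str]:
        """Oriented k-mers reachable by appending one base."""
        return [nxt for nxt, _ in self.successors_rc(kmer, revcomp(kmer))]

    def predecessors(self, kmer: str) -> list[str]:
        return [prv for prv, _ in self.predecessors_rc(kmer, revcomp(kmer))]

    def edges(self) -> Iterable[tuple[str, str, int]]:
        """All oriented edges with coverage = min endpoint multiplicity."""
        for km in self.nodes:
            for orient in (km, revcomp(km)):
                for nxt in self.successors(orient):
                    yield orient, nxt, min(self.nodes[km], self.count(nxt))


def count_kmers(seqs: Iterable[str], k: int) -> Counter:
    """Multiset of canonical k-mers over all reads (windows with N skipped)."""
    counts: Counter = Counter()
    for seq in seqs:
        if len(seq) < k:
            continue
        chunks = seq.split("N") if "N" in seq else (seq,)
        for chunk in chunks:
            n = len(chunk)
            if n < k:
                continue
            rc = revcomp(chunk)
            counts.update(
                [
                    min(chunk[i : i + k], rc[n - k - i : n - i])
                    for i in range(n - k + 1)
                ]
            )
    return counts


def build_graph(reads: Iterable[str], params: AssemblyParams) -> DeBruijnGraph:
    counts = count_kmers(reads, params.k)
    if not counts:
        log.warning("no read yielded a single %d-mer; graph is empty", params.k)
    return DeBruijnGraph(params.k, dict(counts))


@dataclass
class _Unitig:
    path: list[str]  # oriented k-mers
    sequence: str
    coverage: float

    def canonical_kmers(self) -> list[str]:
        return [_canon(km) for km in self.path]


def _walk(graph: DeBruijnGraph, start: str, visited: set[str]) -> list[str]:
    """Extend forward from an oriented k-mer along the non-branching path."""
    path = [start]
    cur, rc_cur = start, revcomp(start)
    while True:
        succs = graph.successors_rc(cur, rc_cur)
        if len(succs) != 1:
            break
        nxt, rc_nxt = succs[0]
        if min(nxt, rc_nxt) in visited:
            break
        if len(graph.predecessors_rc(nxt, rc_nxt)) != 1:
            break
        path.append(nxt)
        visited.add(min(nxt, rc_nxt))
        cur, rc_cur = nxt, rc_nxt
    return path


def compact(graph: DeBruijnGraph) -> list[_Unitig]:
    """Decompose the graph into maximal non-branching paths (unitigs).

    Deterministic: seeds are visited in lexicographic canonical order,
    and every unitig is reported once, in canonical orientation.
    """
    visited: set[str] = set()
    unitigs: list[_Unitig] = []
    for km in sorted(graph.nodes):
        if km in visited:
            continue
        visited.add(km)
        fwd = _walk(graph, km, visited)
        bwd = _walk(graph, revcomp(km), visited)
        path = [revcomp(x) for x in reversed(bwd[1:])] + fwd
        seq = path[0] + "".join(p[-1] for p in path[1:])
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
            path = [revcomp(p) for p in reversed(path)]
        cov = fmean(graph.nodes[_canon(p)] for p in path)
        unitigs.append(_Unitig(path, seq, cov))
    unitigs.sort(key=lambda u: (-len(u.sequence), u.sequence))
    return unitigs


def _drop_unitig(graph: DeBruijnGraph, unitig: _Unitig) -> None:
    for km in unitig.canonical_kmers():
        graph.nodes.pop(km, None)


def _sweep(graph: DeBruijnGraph, params: AssemblyParams) -> bool:
    changed, _ = _sweep_once(graph, params)
    return changed


def _sweep_once(graph: DeBruijnGraph, params: AssemblyParams) -> tuple[bool, list[_Unitig]]:
    """One simplification sweep over the compacted graph.

    Returns (changed, unitigs-before-deletion); when nothing changed the
    returned list is the final compaction, so callers need not redo it.

    In a single compaction pass: (a) clip tips (short unitigs dangling
    off a junction), (b) remove unitigs whose *mean* k-mer coverage is
    below the cutoff -- the Velvet/SPAdes cov-cutoff semantics: a
    low-covered sequence is spurious, but a genuine high-coverage path
    survives a local coverage dip (a per-k-mer cutoff would shatter real
    contigs at moderate depth) -- and (c) pop simple bubbles, keeping
    the higher-coverage arm.
    """
    unitigs = compact(graph)
    doomed: list[_Unitig] = []
    bubble_groups: dict = {}
    for u in unitigs:
        internal = set(u.canonical_kmers())
        ext_in = frozenset(
            _canon(p) for p in graph.predecessors(u.path[0]) if _canon(p) not in internal
        )
        ext_out = frozenset(
            _canon(s) for s in graph.successors(u.path[-1]) if _canon(s) not in internal
        )
        if params.coverage_cutoff > 0 and u.coverage < params.coverage_cutoff:
            doomed.append(u)
            continue
        if len(u.sequence) < params.max_tip_length and (not ext_in) != (not ext_out):
            doomed.append(u)  # a tip: exactly one dangling extremity
            continue
        if ext_in and ext_out:
            bubble_groups.setdefault(frozenset((ext_in, ext_out)), []).append(u)
    for arms in bubble_groups.values():
        if len(arms) < 2:
            continue
        arms.sort(key=lambda u: (-u.coverage, u.sequence))
        best = arms[0]
        doomed.extend(
            other
            for other in arms[1:]
            if abs(len(other.sequence) - len(best.sequence)) <= params.k
        )
    for u in doomed:
        _drop_unitig(graph, u)
    return bool(doomed), unitigs


def _prefilter_weak_kmers(graph: DeBruijnGraph, params: AssemblyParams) -> None:
    # sequencing-error k-mers are overwhelmingly singletons
    if params.coverage_cutoff > 0:
        weak = min(2, params.coverage_cutoff)
        low = [km for km, c in graph.nodes.items() if c < weak]
        for km in low:
            del graph.nodes[km]


def _simplify_collect(graph: DeBruijnGraph, params: AssemblyParams) -> list[_Unitig]:
    """Simplify to fixpoint and hand back the final compaction."""
    _prefilter_weak_kmers(graph, params)
    while True:
        changed, unitigs = _sweep_once(graph, params)
        if not changed:
            return unitigs


def simplify(graph: DeBruijnGraph, params: AssemblyParams) -> DeBruijnGraph:
    """Error-kmer prefilter, then sweep tips/bubbles/cov-cutoff to fixpoint."""
    _simplify_collect(graph, params)
    return graph


def _contigs_from_unitigs(unitigs: list[_Unitig], params: AssemblyParams) -> list[Contig]:
    out: list[Contig] = []
    for u in unitigs:
        if len(u.sequence) < params.min_contig_length:
            continue
        out.append(Contig(f"contig_{len(out)}", u.sequence, u.coverage))
    return out


def contigs_from_graph(graph: DeBruijnGraph, params: AssemblyParams) -> list[Contig]:
    return _contigs_from_unitigs(compact(graph), params)


def assemble(reads: Iterable[str], params: Optional[AssemblyParams] = None) -> list[Contig]:
    """Assemble reads into contigs (build, simplify, compact, length-filter).

    Contigs are reported once each, in canonical orientation, sorted by
    decreasing length then sequence; the result does not depend on the
    input read order.
    """
    params = params or AssemblyParams()
    graph = build_graph(reads, params)
    unitigs = _simplify_collect(graph, params)
    return _contigs_from_unitigs(unitigs, params)


def write_gfa(graph: DeBruijnGraph, path) -> None:
    """Debug dump of the compacted graph as GFA1 (segments = unitigs)."""
    unitigs = compact(graph)
    ends: dict[str, list[tuple[int, str]]] = {}
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for i, u in enumerate(unitigs):
            fh.write(f"S\t{i}\t{u.sequence}\tdp:f:{u.coverage:.2f}\n")
            # index oriented extremities for link discovery
            ends.setdefault(u.path[0], []).append((i, "+s"))
            ends.setdefault(u.path[-1], []).append((i, "+e"))
            ends.setdefault(revcomp(u.path[-1]), []).append((i, "-s"))
            ends.setdefault(revcomp(u.path[0]), []).append((i, "-e"))
        k = graph.k
        for i, u in enumerate(unitigs):
            last = u.path[-1]
            for nxt in graph.successors(last):
                for j, tag in ends.get(nxt, []):
                    if tag.endswith("s"):
                        fh.write(f"L\t{i}\t+\t{j}\t{tag[0]}\t{k - 1}M\n")


def write_contigs_fasta(contigs: list[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id} cov={c.mean_kmer_coverage:.2f}\n{c.sequence}\n")
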
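"""Tandem-duplication detection from long reads by exact-seed dot plots.

A read carrying ``c`` head-to-tail copies of a segment produces, in a dot
plot against the single reference unit, ``c`` parallel diagonals that each
restart at unit coordinate 0.  This module reproduces that analysis without
an external dot-plot program: maximal exact matches of length >= k between
read and unit are found by k-mer seeding, chained greedily into collinear
runs (read and unit offsets both increasing, gaps bounded), and each run
covering at least half the unit counts as one copy.  Junction-spanning reads
are identified by locating two flanking query sequences (~1 kb each) on the
read in the correct order; both read orientations are searched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ReadLike = Union[str, SeqRecord]


@dataclass(frozen=True)
class SeedMatch:
    """A maximal exact match between read and reference unit."""

    read_offset: int
    ref_offset: int
    length: int


@dataclass
class Chain:
    """A collinear run of seed matches (one dot-plot diagonal segment)."""

    matches: List[SeedMatch] = field(default_factory=list)

    @property
    def read_span(self) -> Tuple[int, int]:
        return (
            self.matches[0].read_offset,
            self.matches[-1].read_offset + self.matches[-1].length,
        )

    @property
    def ref_span(self) -> Tuple[int, int]:
        return (
            min(m.ref_offset for m in self.matches),
            max(m.ref_offset + m.length for m in self.matches),
        )

    @property
    def ref_coverage(self) -> int:
        """Total reference bases covered (union of match intervals)."""
        intervals = sorted((m.ref_offset, m.ref_offset + m.length) for m in self.matches)
        covered = 0
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start > cur_end:
                covered += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        covered += cur_end - cur_start
        return covered

    @property
    def matched_bases(self) -> int:
        return sum(m.length for m in self.matches)


@dataclass
class CopyCallResult:
    """Per-read tandem copy call."""

    read_id: str
    n_copies: int
    chain_spans: List[Tuple[Tuple[int, int], Tuple[int, int]]]
    has_both_flanks: Optional[bool] = None
    orientation: str = "forward"


def _seq_of(read: ReadLike) -> str:
    if isinstance(read, SeqRecord):
        return str(read.seq).upper()
    return str(read).upper()


def _id_of(read: ReadLike) -> str:
    if isinstance(read, SeqRecord):
        return read.id
    return "read"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_length(read: ReadLike) -> int:
    return len(_seq_of(read))


def filter_reads_by_length(
    reads: Iterable[ReadLike], min_len: int
) -> List[ReadLike]:
    """Keep reads of length >= min_len (the seqkit-style length filter)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in reads if read_length(r) >= min_len]


def maximal_exact_matches(read: str, unit: str, k: int = 15) -> List[SeedMatch]:
    """All maximal exact matches of length >= k between read and unit.

    k-mer seeding: an exact match of length L contributes L-k+1 consecutive
    k-mer hits on one diagonal; merging consecutive hits per diagonal
    reconstructs the maximal matches exactly.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if len(unit) < k or len(read) < k:
        return []
    index: Dict[str, List[int]] = {}
    for j in range(len(unit) - k + 1):
        index.setdefault(unit[j : j + k], []).append(j)
    by_diag: Dict[int, List[int]] = {}
    for i in range(len(read) - k + 1):
        hits = index.get(read[i : i + k])
        if hits:
            for j in hits:
                by_diag.setdefault(i - j, []).append(i)
    matches: List[SeedMatch] = []
    for diag, read_positions in by_diag.items():
        read_positions.sort()
        run_start = prev = read_positions[0]
        for pos in read_positions[1:]:
            if pos == prev + 1:
                prev = pos
                continue
            matches.append(SeedMatch(run_start, run_start - diag, prev - run_start + k))
            run_start = prev = pos
        matches.append(SeedMatch(run_start, run_start - diag, prev - run_start + k))
    matches.sort(key=lambda m: (m.read_offset, m.ref_offset))
    return matches


def chain_matches(
    matches: Sequence[SeedMatch], max_gap: int = 200, k: int = 15
) -> List[Chain]:
    """Greedily chain matches into maximal collinear runs.

    Successive matches must advance along both the read and the unit, with
    read and unit gaps at most max_gap (small overlaps up to k bp are
    tolerated).  A match restarting at a lower unit coordinate — the next
    tandem copy — begins a new chain.
    """
    chains: List[Chain] = []
    current: Optional[Chain] = None
    for m in sorted(matches, key=lambda m: (m.read_offset, m.ref_offset)):
        if current is not None:
            last = current.matches[-1]
            read_gap = m.read_offset - (last.read_offset + last.length)
            ref_gap = m.ref_offset - (last.ref_offset + last.length)
            if -k <= read_gap <= max_gap and -k <= ref_gap <= max_gap:
                current.matches.append(m)
                continue
        current = Chain(matches=[m])
        chains.append(current)
    return chains


def count_tandem_copies(
    read: ReadLike,
    unit: str,
    k: int = 15,
    max_gap: int = 200,
    min_unit_cov: float = 0.5,
    require_full_span: bool = False,
    search_reverse: bool = True,
) -> CopyCallResult:
    """Count tandem copies of ``unit`` on a read.

    Each collinear chain covering at least ``min_unit_cov`` of the unit
    counts as one copy (``require_full_span=True`` raises the bar to 95%
    unit coverage, i.e. only runs covering the entire duplicon).  Partial
    terminal runs remain visible in ``chain_spans``.  Both orientations are
    searched unless ``search_reverse=False``; the one with more matched
    bases is reported.
    """
    if len(unit) < k:
        raise ValueError("unit shorter than seed length k")
    unit = unit.upper()
    seq = _seq_of(read)
    candidates = [("forward", seq)]
    if search_reverse:
        candidates.append(("reverse", _revcomp(seq)))
    best: Optional[Tuple[str, List[Chain], int]] = None
    for orientation, oriented in candidates:
        chains = chain_matches(maximal_exact_matches(oriented, unit, k), max_gap, k)
        matched = sum(c.matched_bases for c in chains)
        if best is None or matched > best[2]:
            best = (orientation, chains, matched)
    orientation, chains, _ = best
    threshold = (0.95 if require_full_span else min_unit_cov) * len(unit)
    n_copies = sum(1 for c in chains if c.ref_coverage >= threshold)
    return CopyCallResult(
        read_id=_id_of(read),
        n_copies=n_copies,
        chain_spans=[(c.read_span, c.ref_span) for c in chains],
        orientation=orientation,
    )


def locate_query(
    seq: str, query: str, k: int = 15, max_gap: int = 200, min_cov: float = 0.8
) -> Optional[Tuple[int, int]]:
    """Best placement of a query on a (forward-oriented) sequence.

    Returns the read span of the highest-coverage collinear chain whose
    chained seed coverage reaches ``min_cov`` of the query, else None.
    """
    query = query.upper()
    chains = chain_matches(maximal_exact_matches(seq, query, k), max_gap, k)
    best_span, best_cov = None, 0
    for c in chains:
        if c.ref_coverage > best_cov:
            best_cov, best_span = c.ref_coverage, c.read_span
    if best_span is not None and best_cov >= min_cov * len(query):
        return best_span
    return None


def find_junction_spanning_reads(
    reads: Iterable[ReadLike],
    query_up: str,
    query_down: str,
    k: int = 15,
    max_gap: int = 200,
    min_cov: float = 0.8,
) -> List[ReadLike]:
    """Reads on which both flanking queries are located in order.

    A read is returned iff the upstream query and the downstream query are
    both found (collinear chained seeds covering >= min_cov of the query)
    with the upstream match before the downstream match in read
    orientation; reverse-complement reads are handled by searching both
    orientations.
    """
    if not query_up or not query_down:
        raise ValueError("queries must be non-empty")
    if k > min(len(query_up), len(query_down)):
        raise ValueError("k exceeds query length")
    hits: List[ReadLike] = []
    for read in reads:
        seq = _seq_of(read)
        for oriented in (seq, _revcomp(seq)):
            up = locate_query(oriented, query_up, k, max_gap, min_cov)
            if up is None:
                continue
            down = locate_query(oriented, query_down, k, max_gap, min_cov)
            if down is not None and up[0] < down[0]:
                hits.append(read)
                break
    return hits


def export_dotplot(matches: Sequence[SeedMatch], path) -> None:
    """Write matches as a TSV (read_offset, ref_offset, length) for plotting."""
    with open(path, "w") as fh:
        fh.write("read_offset\tref_offset\tlength\n")
        for m in matches:
            fh.write(f"{m.read_offset}\t{m.ref_offset}\t{m.length}\n")


def read_dotplot(path) -> List[SeedMatch]:
    """Read back a dot-plot TSV written by :func:`export_dotplot`."""
    out: List[SeedMatch] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["read_offset", "ref_offset", "length"]:
            raise ValueError("not a dot-plot TSV")
        for line in fh:
            a, b, c = line.split("\t")
            out.append(SeedMatch(int(a), int(b), int(c)))
    return out


def detect_duplications(
    reads: Iterable[ReadLike],
    unit: str,
    query_up: Optional[str] = None,
    query_down: Optional[str] = None,
    min_len: int = 0,
    k: int = 15,
    max_gap: int = 200,
    min_unit_cov: float = 0.5,
    min_query_cov: float = 0.8,
) -> List[CopyCallResult]:
    """Full read -> copy-call pipeline.

    Filters reads by length, optionally restricts to junction-spanning
    reads (both flank queries located in order), then counts tandem unit
    copies per read.  ``has_both_flanks`` is filled when queries are given.
    """
    kept = filter_reads_by_length(reads, min_len)
    spanning_ids = None
    if query_up is not None and query_down is not None:
        spanning = find_junction_spanning_reads(
            kept, query_up, query_down, k, max_gap, min_query_cov
        )
        spanning_ids = {id(r) for r in spanning}
    results = []
    for read in kept:
        if spanning_ids is not None and id(read) not in spanning_ids:
            continue
        call = count_tandem_copies(read, unit, k, max_gap, min_unit_cov)
        if spanning_ids is not None:
            call.has_both_flanks = True
        results.append(call)
    return results
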
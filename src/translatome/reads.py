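"""Footprint read processing: adapter trimming, contaminant removal,
seed alignment and fractional multi-read resolution.

Alignment is substitution-only in transcript space (forward strand),
emulating a seed-mismatch aligner reporting all hits in the best stratum:
the first ``seed_len`` nucleotides of a read may carry at most
``max_seed_mm`` mismatches, and only hits with the minimal seed mismatch
count are reported.  Candidate placements are found by pigeonhole
seeding: the 24 nt seed is split into three 8-mers, at least one of which
must match exactly when the seed has <=2 mismatches.

Multi-mapped reads are resolved in two passes.  Reads with a single hit,
or a single minimal mismatch score over a 30 nt extension, are deemed
unique (pass 1).  Remaining ties are apportioned in proportion to the
vicinity read density — the number of pass-1 unique 5' ends within
+/-30 nt of the candidate position — falling back to an even split when
every vicinity is empty.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"
EXTENSION_LEN = 30  # approximate insert length used for tie-breaking
VICINITY = 30  # nt upstream/downstream for vicinity read density


@dataclass
class Read:
    read_id: str
    seq: str
    origin: str | None = None  # ground-truth label from the generator, if any


@dataclass
class AlignmentHit:
    transcript_id: str
    pos5: int  # 0-based offset of the read's 5'-end nucleotide
    mismatches_seed: int


@dataclass
class ReadAssignment:
    """Fractional placement of one read; weights sum to 1."""

    read_id: str
    hits: list[tuple[str, int, float]] = field(default_factory=list)  # (tid, pos5, weight)


def trim_adapter(
    read: Read, adapter: str = DEFAULT_ADAPTER, min_len: int = 24, min_overlap: int = 5
) -> Read | None:
    """Remove the 3' adapter; return ``None`` when the insert is too short.

    The sequence 5' of the first full adapter occurrence is kept.  A
    partial adapter prefix at the read's 3' end (>= ``min_overlap`` nt)
    is also trimmed.  Reads with no adapter evidence are kept full
    length.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.seq
    idx = seq.find(adapter)
    if idx == -1:
        # partial adapter running off the 3' end
        max_part = min(len(adapter) - 1, len(seq))
        for k in range(max_part, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                idx = len(seq) - k
                break
    if idx == -1:
        trimmed = seq
    else:
        trimmed = seq[:idx]
    if len(trimmed) < min_len:
        return None
    return Read(read.read_id, trimmed, read.origin)


class TranscriptIndex:
    """Exact 8-mer positional index over a set of transcript sequences."""

    SUBSEED = 8

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("cannot build an index over zero transcripts")
        self.sequences = {tid: s.upper() for tid, s in sequences.items()}
        self._kmers: dict[str, list[tuple[str, int]]] = defaultdict(list)
        k = self.SUBSEED
        for tid, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._kmers[seq[i : i + k]].append((tid, i))

    def candidates(self, read_seq: str, seed_len: int):
        """Candidate (tid, pos5) placements via pigeonhole sub-seeds."""
        k = self.SUBSEED
        out = set()
        for off in range(0, seed_len - k + 1, k):
            sub = read_seq[off : off + k]
            for tid, pos in self._kmers.get(sub, ()):
                p5 = pos - off
                if p5 >= 0 and p5 + seed_len <= len(self.sequences[tid]):
                    out.add((tid, p5))
        return out


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def align(
    read: Read, index: TranscriptIndex, seed_len: int = 24, max_seed_mm: int = 2
) -> list[AlignmentHit]:
    """All best-stratum hits of the read's seed against the index."""
    seq = read.seq.upper()
    if len(seq) < seed_len:
        return []
    seed = seq[:seed_len]
    hits = []
    for tid, p5 in index.candidates(seed, seed_len):
        ref = index.sequences[tid][p5 : p5 + seed_len]
        mm = _mismatches(seed, ref)
        if mm <= max_seed_mm:
            hits.append(AlignmentHit(tid, p5, mm))
    if not hits:
        return []
    best = min(h.mismatches_seed for h in hits)
    kept = [h for h in hits if h.mismatches_seed == best]
    kept.sort(key=lambda h: (h.transcript_id, h.pos5))
    return kept


def filter_contaminants(
    reads: list[Read], contaminant_index: TranscriptIndex, seed_len: int = 24, max_seed_mm: int = 2
) -> tuple[list[Read], int]:
    """Drop reads with any hit against the decoy rRNA/tRNA index."""
    kept = []
    removed = 0
    for r in reads:
        if align(r, contaminant_index, seed_len=seed_len, max_seed_mm=max_seed_mm):
            removed += 1
        else:
            kept.append(r)
    return kept, removed


def extension_score(read_seq: str, transcript_seq: str, pos5: int) -> float:
    """Per-base mismatch score over the 30 nt extension at a hit.

    The overlap is shortened at the transcript (or read) end and the
    score normalized per base so 3'-proximal hits are not penalized.
    """
    span = min(EXTENSION_LEN, len(read_seq), len(transcript_seq) - pos5)
    if span <= 0:
        return 1.0
    return _mismatches(read_seq[:span], transcript_seq[pos5 : pos5 + span]) / span


def resolve_multireads(
    per_read_hits: dict[str, list[AlignmentHit]],
    reads: dict[str, Read],
    sequences: dict[str, str],
) -> list[ReadAssignment]:
    """Two-pass fractional assignment of aligned reads.

    Pass 1 assigns weight 1 to single-hit reads and to multi-hit reads
    with a single minimal extension mismatch score.  Pass 2 splits the
    remaining ties in proportion to the vicinity density of pass-1 unique
    5' ends (+/-30 nt, same transcript), evenly when all vicinities are
    empty.  Total weight per read is exactly 1.
    """
    unique: list[tuple[str, str, int]] = []  # (read_id, tid, pos5)
    ambiguous: list[tuple[str, list[AlignmentHit]]] = []

    for rid, hits in per_read_hits.items():
        if not hits:
            raise ValueError(f"{rid}: no hits to resolve")
        if len(hits) == 1:
            unique.append((rid, hits[0].transcript_id, hits[0].pos5))
            continue
        seq = reads[rid].seq.upper()
        scores = [extension_score(seq, sequences[h.transcript_id], h.pos5) for h in hits]
        best = min(scores)
        minimal = [h for h, s in zip(hits, scores) if s == best]
        if len(minimal) == 1:
            h = minimal[0]
            unique.append((rid, h.transcript_id, h.pos5))
        else:
            ambiguous.append((rid, minimal))

    # unique 5'-end counts per transcript position, from pass 1 only
    density: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for _, tid, p5 in unique:
        density[tid][p5] += 1

    def vicinity(tid: str, p5: int) -> float:
        d = density.get(tid)
        if not d:
            return 0.0
        return float(sum(c for p, c in d.items() if abs(p - p5) <= VICINITY))

    assignments = [ReadAssignment(rid, [(tid, p5, 1.0)]) for rid, tid, p5 in unique]
    for rid, hits in ambiguous:
        dens = [vicinity(h.transcript_id, h.pos5) for h in hits]
        total = sum(dens)
        if total > 0:
            weights = [d / total for d in dens]
        else:
            weights = [1.0 / len(hits)] * len(hits)
        assignments.append(
            ReadAssignment(rid, [(h.transcript_id, h.pos5, w) for h, w in zip(hits, weights)])
        )
    return assignments


def run_pipeline(
    raw_reads: list[Read],
    transcript_seqs: dict[str, str],
    contaminant_seqs: dict[str, str] | None = None,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = 24,
    seed_len: int = 24,
    max_seed_mm: int = 2,
) -> tuple[list[ReadAssignment], dict[str, int]]:
    """Trim, de-contaminate, align and resolve a read batch.

    Returns the assignments plus a counter dict with ``input``,
    ``trimmed_out``, ``contaminant``, ``unaligned`` and ``assigned``.
    """
    stats = {"input": len(raw_reads), "trimmed_out": 0, "contaminant": 0, "unaligned": 0}
    trimmed: list[Read] = []
    for r in raw_reads:
        t = trim_adapter(r, adapter=adapter, min_len=min_len)
        if t is None:
            stats["trimmed_out"] += 1
        else:
            trimmed.append(t)

    if contaminant_seqs:
        cindex = TranscriptIndex(contaminant_seqs)
        trimmed, removed = filter_contaminants(trimmed, cindex, seed_len, max_seed_mm)
        stats["contaminant"] = removed

    index = TranscriptIndex(transcript_seqs)
    per_read: dict[str, list[AlignmentHit]] = {}
    reads_by_id: dict[str, Read] = {}
    for r in trimmed:
        hits = align(r, index, seed_len=seed_len, max_seed_mm=max_seed_mm)
        if hits:
            per_read[r.read_id] = hits
            reads_by_id[r.read_id] = r
        else:
            stats["unaligned"] += 1

    assignments = resolve_multireads(per_read, reads_by_id, index.sequences)
    stats["assigned"] = len(assignments)
    return assignments, stats
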
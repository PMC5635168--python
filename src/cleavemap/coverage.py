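"""Read mapping, per-position coverage and the relative-coverage-increase statistic.

The detection principle: cleavage fragments carry the cut position at their
5' end, so read depth steps up exactly at the first base downstream of each
cut. Relative coverage increase (RCI) at boundary n is c(n+1)/c(n); candidate
cleavage positions are the (n+1) positions with the largest RCI, after
excluding positions whose own depth falls below a minimum (default 500).

Coordinates are 1-based inclusive throughout, matching both the n/(n+1)
phrasing of the statistic and SAM's native convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .synthetic import PAD, ReadSet, RNAConstruct, encode

logger = logging.getLogger(__name__)

SEED_K = 20  # exact seed length for seed-and-extend mapping


@dataclass
class AlignmentSet:
    """Ungapped alignments: read id, reference id, 1-based start, aligned length."""

    read_ids: list[str]
    ref_ids: np.ndarray  # (n,) object
    starts: np.ndarray  # (n,) int64, 1-based leftmost
    lengths: np.ndarray  # (n,) int64
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        self.ref_ids = np.asarray(self.ref_ids, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        if (self.starts < 1).any():
            raise ValueError("alignment starts must be >= 1")

    def __len__(self) -> int:
        return len(self.read_ids)

    def for_reference(self, ref_id: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.ref_ids == ref_id
        return self.starts[mask], self.lengths[mask]


@dataclass
class CoverageProfile:
    """Per-position read depth c(n) over one reference, n = 1..length."""

    reference_id: str
    c: np.ndarray  # (L,) int64; index i holds c(i+1)

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.int64)
        if (self.c < 0).any():
            raise ValueError("coverage must be non-negative")

    def __len__(self) -> int:
        return len(self.c)


@dataclass
class RCITrack:
    """r(n) = c(n+1)/c(n) for n = 1..L-1; undefined (NaN) where c(n) = 0."""

    reference_id: str
    r: np.ndarray  # (L-1,) float; index i holds r(i+1)
    defined_mask: np.ndarray  # (L-1,) bool, True where c(n) > 0


@dataclass(frozen=True)
class CandidateSite:
    """A position whose coverage stepped up: the (n+1) of a high-RCI boundary."""

    reference_id: str
    position: int  # 1-based, the (n+1) position
    rci: float
    coverage: int  # c(position)


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def _kmer_keys(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack all k-mers of a code vector into uint64 keys (Horner)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        keys = keys * 4 + codes[i : i + n].astype(np.uint64)
    return keys


def _row_keys(mat: np.ndarray, k: int) -> np.ndarray:
    keys = np.zeros(mat.shape[0], dtype=np.uint64)
    for i in range(k):
        keys = keys * 4 + mat[:, i].astype(np.uint64)
    return keys


class _SeedIndex:
    """Exact 20-mer index over a reference panel.

    Keys occurring once across all references live in sorted arrays for
    vectorised lookup; repeated keys fall back to a dict of hit lists.
    """

    def __init__(self, references: list[RNAConstruct], k: int = SEED_K):
        ids = [r.id for r in references]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate reference ids")
        self.k = k
        self.references = references
        self.ref_codes = [r.codes for r in references]
        all_keys, all_ref, all_pos = [], [], []
        for ridx, codes in enumerate(self.ref_codes):
            keys = _kmer_keys(codes, k)
            all_keys.append(keys)
            all_ref.append(np.full(len(keys), ridx, dtype=np.int32))
            all_pos.append(np.arange(len(keys), dtype=np.int64))  # 0-based
        keys = np.concatenate(all_keys)
        refs = np.concatenate(all_ref)
        pos = np.concatenate(all_pos)
        order = np.argsort(keys, kind="stable")
        keys, refs, pos = keys[order], refs[order], pos[order]
        uniq, first, counts = np.unique(keys, return_index=True, return_counts=True)
        single = counts == 1
        self.uniq_keys = uniq[single]
        self.uniq_ref = refs[first[single]]
        self.uniq_pos = pos[first[single]]
        self.multi: dict[int, list[tuple[int, int]]] = {}
        for key, start, cnt in zip(uniq[~single], first[~single], counts[~single]):
            self.multi[int(key)] = [
                (int(refs[start + j]), int(pos[start + j])) for j in range(cnt)
            ]

    def lookup_unique(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised lookup into the single-hit table. Returns (found, ref, pos)."""
        if not len(self.uniq_keys):
            z = np.zeros(len(keys), dtype=np.int64)
            return np.zeros(len(keys), dtype=bool), z.astype(np.int32), z
        idx = np.minimum(np.searchsorted(self.uniq_keys, keys), len(self.uniq_keys) - 1)
        found = self.uniq_keys[idx] == keys
        return found, self.uniq_ref[idx], self.uniq_pos[idx]

    def hits(self, key: int) -> list[tuple[int, int]]:
        if key in self.multi:
            return self.multi[key]
        i = np.searchsorted(self.uniq_keys, np.uint64(key))
        if i < len(self.uniq_keys) and self.uniq_keys[i] == np.uint64(key):
            return [(int(self.uniq_ref[i]), int(self.uniq_pos[i]))]
        return []


def _count_mismatches(ref_codes: np.ndarray, start0: int, read: np.ndarray) -> int:
    return int(np.count_nonzero(ref_codes[start0 : start0 + len(read)] != read))


def map_reads(
    reads: ReadSet,
    references: list[RNAConstruct],
    max_mismatches: int = 2,
) -> AlignmentSet:
    """Align reads by seed-and-extend on exact 20-mers.

    Seeds are taken at read offsets 0, 20 and (len-20); each seed hit
    proposes an ungapped alignment which is scored by full-length mismatch
    count. The unique best alignment with at most ``max_mismatches``
    substitutions is reported; ambiguous best hits (ties at distinct
    positions) and unmapped reads are dropped and counted.
    """
    index = _SeedIndex(references, SEED_K)
    k = index.k
    n = len(reads)
    out_idx: list[int] = []
    out_ref: list[str] = []
    out_start: list[int] = []

    lengths = reads.lengths
    long_enough = lengths >= k
    keys0 = _row_keys(reads.codes[:, :k], k)

    found, ref_i, pos0 = index.lookup_unique(keys0)
    fast = found & long_enough
    # exact-match fast path, grouped by reference; a unique exact hit whose
    # seed is globally unique cannot be tied by any other exact alignment
    slow = ~fast
    for ridx in np.unique(ref_i[fast]):
        rcodes = index.ref_codes[ridx]
        L = len(rcodes)
        rows = np.flatnonzero(fast & (ref_i == ridx))
        fits = pos0[rows] + lengths[rows] <= L
        slow[rows[~fits]] = True
        rows = rows[fits]
        if not len(rows):
            continue
        width = reads.codes.shape[1]
        gather = pos0[rows, None] + np.arange(width)[None, :]
        valid = np.arange(width)[None, :] < lengths[rows, None]
        ref_win = rcodes[np.minimum(gather, L - 1)]
        mism = np.count_nonzero((ref_win != reads.codes[rows]) & valid, axis=1)
        exact = mism == 0
        for r in rows[exact]:
            out_idx.append(int(r))
            out_ref.append(index.references[ridx].id)
            out_start.append(int(pos0[r]) + 1)
        slow[rows[~exact]] = True

    # slow path: gather candidates from all three seed offsets, keep a unique best
    n_unmapped = 0
    for r in np.flatnonzero(slow):
        rdlen = int(lengths[r])
        if rdlen < k:
            n_unmapped += 1
            continue
        read = reads.codes[r, :rdlen]
        offsets = {0, rdlen - k}
        if rdlen >= 2 * k:
            offsets.add(k)
        candidates: dict[tuple[int, int], int] = {}
        for off in offsets:
            key = 0
            for c in read[off : off + k]:
                key = key * 4 + int(c)
            for ridx, p0 in index.hits(key):
                start0 = p0 - off
                if start0 < 0 or start0 + rdlen > len(index.ref_codes[ridx]):
                    continue
                if (ridx, start0) not in candidates:
                    candidates[(ridx, start0)] = _count_mismatches(
                        index.ref_codes[ridx], start0, read
                    )
        best = [
            (mm, ridx, s0)
            for (ridx, s0), mm in candidates.items()
            if mm <= max_mismatches
        ]
        if not best:
            n_unmapped += 1
            continue
        best.sort()
        if len(best) > 1 and best[0][0] == best[1][0]:
            n_unmapped += 1  # ambiguous best hit
            continue
        mm, ridx, s0 = best[0]
        out_idx.append(int(r))
        out_ref.append(index.references[ridx].id)
        out_start.append(s0 + 1)

    if n_unmapped:
        logger.info("map_reads: %d/%d reads unmapped or ambiguous", n_unmapped, n)
    order = np.argsort(out_idx, kind="stable")
    return AlignmentSet(
        [reads.ids[out_idx[i]] for i in order],
        np.asarray(out_ref, dtype=object)[order] if out_ref else np.empty(0, object),
        np.asarray(out_start, dtype=np.int64)[order] if out_start else np.empty(0, np.int64),
        lengths[np.asarray(out_idx, dtype=int)][order] if out_idx else np.empty(0, np.int64),
        n_unmapped=n_unmapped,
    )


# ---------------------------------------------------------------------------
# coverage and RCI
# ---------------------------------------------------------------------------

def compute_coverage(alignments: AlignmentSet, reference: RNAConstruct) -> CoverageProfile:
    """Depth c(n) = number of alignments whose interval contains position n."""
    L = len(reference)
    starts, lengths = alignments.for_reference(reference.id)
    if len(starts) and (starts + lengths - 1 > L).any():
        raise ValueError(f"alignment beyond end of reference {reference.id}")
    delta = np.zeros(L + 1, dtype=np.int64)
    np.add.at(delta, starts - 1, 1)
    np.add.at(delta, starts - 1 + lengths, -1)
    return CoverageProfile(reference.id, np.cumsum(delta[:L]))


def relative_coverage_increase(profile: CoverageProfile) -> RCITrack:
    """r(n) = c(n+1)/c(n), masked undefined at zero-depth denominators."""
    c = profile.c
    if len(c) < 2:
        raise ValueError("profile must have length >= 2")
    defined = c[:-1] > 0
    r = np.full(len(c) - 1, np.nan)
    np.divide(c[1:], c[:-1], out=r, where=defined)
    return RCITrack(profile.reference_id, r, defined)


def select_candidates(
    tracks: list[RCITrack],
    profiles: list[CoverageProfile],
    min_coverage: int = 500,
    top_n: int = 15,
) -> list[CandidateSite]:
    """Globally rank boundaries by RCI and return the top-N candidate positions.

    Positions (n+1) with depth below ``min_coverage`` are excluded before
    ranking; ranking pools every reference ("overall top N"). Ties are broken
    deterministically: higher coverage first, then reference id, then the
    smaller position.
    """
    by_ref = {p.reference_id: p for p in profiles}
    pool: list[CandidateSite] = []
    for track in tracks:
        profile = by_ref.get(track.reference_id)
        if profile is None:
            raise ValueError(f"no coverage profile for {track.reference_id}")
        c = profile.c
        ok = track.defined_mask & (c[1:] >= min_coverage)
        for n0 in np.flatnonzero(ok):
            pool.append(
                CandidateSite(track.reference_id, int(n0) + 2, float(track.r[n0]), int(c[n0 + 1]))
            )
    pool.sort(key=lambda s: (-s.rci, -s.coverage, s.reference_id, s.position))
    if top_n > len(pool):
        logger.warning(
            "select_candidates: requested top %d but only %d positions pass filters",
            top_n,
            len(pool),
        )
        return pool
    return pool[:top_n]


# ---------------------------------------------------------------------------
# SAM interop
# ---------------------------------------------------------------------------

def _sam_header(references: list[RNAConstruct]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": r.id, "LN": len(r)} for r in references],
    }


def write_sam(
    alignments: AlignmentSet,
    reads: ReadSet,
    references: list[RNAConstruct],
    path: str,
) -> None:
    """Write alignments as plain-text SAM (match-only CIGARs), coordinate sorted."""
    header = pysam.AlignmentHeader.from_dict(_sam_header(references))
    read_row = {rid: i for i, rid in enumerate(reads.ids)}
    order = sorted(
        range(len(alignments)),
        key=lambda i: (str(alignments.ref_ids[i]), int(alignments.starts[i])),
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for i in order:
            rid = alignments.read_ids[i]
            a = pysam.AlignedSegment(header)
            a.query_name = rid
            a.query_sequence = reads.sequence(read_row[rid])
            a.flag = 0
            a.reference_id = header.get_tid(str(alignments.ref_ids[i]))
            a.reference_start = int(alignments.starts[i]) - 1
            a.mapping_quality = 60
            a.cigartuples = [(0, int(alignments.lengths[i]))]
            a.query_qualities = pysam.qualitystring_to_array(
                reads.quality_char * int(alignments.lengths[i])
            )
            out.write(a)


def read_sam(path: str) -> AlignmentSet:
    """Ingest simple match-only SAM alignments; indels are rejected."""
    read_ids, ref_ids, starts, lengths = [], [], [], []
    n_unmapped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            ops = {op for op, _ in (rec.cigartuples or [])}
            if ops - {0, 7, 8}:  # M, =, X only
                raise ValueError(
                    f"read {rec.query_name}: only match-only alignments are supported"
                )
            read_ids.append(rec.query_name)
            ref_ids.append(rec.reference_name)
            starts.append(rec.reference_start + 1)
            lengths.append(rec.reference_length)
    return AlignmentSet(
        read_ids,
        np.asarray(ref_ids, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(lengths, dtype=np.int64),
        n_unmapped=n_unmapped,
    )


def reads_from_fastq(handle) -> ReadSet:
    """Load a FASTQ file into a ReadSet (no ground truth)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(handle, "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError("empty FASTQ")
    width = max(len(s) for s in seqs)
    codes = np.full((len(ids), width), PAD, dtype=np.uint8)
    lengths = np.empty(len(ids), dtype=np.int64)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = encode(s)
        lengths[i] = len(s)
    return ReadSet(ids, codes, lengths, truth={})
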
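"""Consensus-motif recovery around candidate cleavage positions.

Candidate positions mark the first base of the downstream cleavage fragment;
an 11-column window (offsets -5..+5, column 0 at the candidate) is extracted
per candidate, the stack is summarised as a position frequency matrix with
per-column information content, and the consensus tetrad is called. With the
enzyme cleaving U^ACA, the recovered motif occupies offsets -1..+2 (T at -1 in
the DNA rendering) and the inferred cut falls one base into the tetrad.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import CandidateSite
from .synthetic import BASES, RNAConstruct, to_dna, to_rna

logger = logging.getLogger(__name__)

FLANK = 5  # bases extracted either side of the candidate position
WIDTH = 2 * FLANK + 1
#: Offsets (relative to the candidate position) spelled by a recognition tetrad.
MOTIF_OFFSETS = (-1, 0, 1, 2)


@dataclass(frozen=True)
class WindowProvenance:
    reference_id: str
    position: int
    rci: float


@dataclass
class WindowSet:
    """Fixed-width sequence windows stacked on the candidate positions."""

    windows: list[str]
    provenance: list[WindowProvenance] = field(default_factory=list)

    def __post_init__(self) -> None:
        for w in self.windows:
            if len(w) != WIDTH or set(w) - set(BASES):
                raise ValueError(f"windows must be {WIDTH}-mers over {BASES}: {w!r}")

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class PositionFrequencyMatrix:
    """Per-column base frequencies (rows A,C,G,T) over the window stack."""

    counts: np.ndarray  # (4, WIDTH) int
    freq: np.ndarray  # (4, WIDTH) float, columns sum to 1
    pseudocount: float
    n_windows: int


@dataclass
class ConsensusMotif:
    """Called consensus with per-column information content.

    ``motif_span`` is the maximal contiguous run of non-N consensus columns
    containing offset 0, as (first_offset, last_offset); ``cut_offset_in_motif``
    is the index of offset 0 within that run — i.e. how many motif bases lie
    5' of the cleavage position.
    """

    consensus: str  # length WIDTH over {A,C,G,T,N}
    ic: np.ndarray  # (WIDTH,) bits
    motif_span: tuple[int, int] | None
    cut_offset_in_motif: int | None

    @property
    def motif(self) -> str:
        """The consensus restricted to the motif span (DNA rendering)."""
        if self.motif_span is None:
            return ""
        lo, hi = self.motif_span
        return self.consensus[lo + FLANK : hi + FLANK + 1]

    @property
    def motif_rna(self) -> str:
        return to_rna(self.motif)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int  # 1-based first base of the motif
    motif: str


def extract_windows(
    candidates: list[CandidateSite],
    references: list[RNAConstruct],
    flank: int = FLANK,
) -> WindowSet:
    """Extract the (2*flank+1)-nt window centred on each candidate position.

    Candidates within ``flank`` nt of a reference end are skipped (and
    counted in the log); a candidate on a reference absent from
    ``references`` is an error.
    """
    if flank != FLANK:
        raise ValueError("window flank is fixed at 5 by the extraction convention")
    by_id = {r.id: r for r in references}
    windows, prov = [], []
    n_skipped = 0
    for cand in candidates:
        ref = by_id.get(cand.reference_id)
        if ref is None:
            raise ValueError(f"candidate references unknown sequence {cand.reference_id}")
        if not 1 <= cand.position <= len(ref):
            raise ValueError(
                f"candidate position {cand.position} outside {ref.id} (length {len(ref)})"
            )
        if cand.position - flank < 1 or cand.position + flank > len(ref):
            n_skipped += 1
            continue
        windows.append(ref.sequence[cand.position - flank - 1 : cand.position + flank])
        prov.append(WindowProvenance(ref.id, cand.position, cand.rci))
    if n_skipped:
        logger.info("extract_windows: skipped %d candidates too close to an end", n_skipped)
    return WindowSet(windows, prov)


def build_pfm(windows: WindowSet, pseudocount: float = 0.5) -> PositionFrequencyMatrix:
    """Tally per-column base counts; frequencies use an additive pseudocount."""
    if len(windows) == 0:
        raise ValueError("cannot build a frequency matrix from zero windows")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((4, WIDTH), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    for w in windows.windows:
        for col, ch in enumerate(w):
            counts[base_index[ch], col] += 1
    n = len(windows)
    freq = (counts + pseudocount) / (n + 4 * pseudocount)
    return PositionFrequencyMatrix(counts, freq, pseudocount, n)


def information_content(pfm: PositionFrequencyMatrix) -> np.ndarray:
    """Per-column information content IC = 2 + sum_b f_b log2 f_b, in bits."""
    f = pfm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(f), 0.0)
    ic = 2.0 + terms.sum(axis=0)
    return np.clip(ic, 0.0, 2.0)


def call_consensus(
    pfm: PositionFrequencyMatrix,
    freq_threshold: float = 0.5,
    ic_threshold: float = 1.0,
) -> ConsensusMotif:
    """Call the consensus base per column, N where conservation is weak.

    A column is assigned its majority base when that base's frequency reaches
    ``freq_threshold`` and the column's information content reaches
    ``ic_threshold`` bits (majority ties broken alphabetically). The motif
    span is the maximal contiguous non-N run containing offset 0.
    """
    ic = information_content(pfm)
    letters = []
    for col in range(WIDTH):
        best = int(np.argmax(pfm.freq[:, col]))  # argmax takes the first (alphabetical) on ties
        if pfm.freq[best, col] >= freq_threshold and ic[col] >= ic_threshold:
            letters.append(BASES[best])
        else:
            letters.append("N")
    consensus = "".join(letters)
    center = FLANK
    if consensus[center] == "N":
        return ConsensusMotif(consensus, ic, None, None)
    lo = center
    while lo > 0 and consensus[lo - 1] != "N":
        lo -= 1
    hi = center
    while hi < WIDTH - 1 and consensus[hi + 1] != "N":
        hi += 1
    return ConsensusMotif(consensus, ic, (lo - FLANK, hi - FLANK), center - lo)


def classify_suboptimal(
    windows: WindowSet,
    primary: str = "TACA",
    alternates: tuple[str, ...] = ("TACC", "TACT", "AACA"),
) -> dict[str, int]:
    """Count windows by the tetrad their offsets -1..+2 spell.

    Returns counts keyed by the RNA rendering of ``primary`` and each
    alternate, plus ``"other"`` for windows spelling none of them.
    """
    motifs = [to_dna(primary.upper())] + [to_dna(a.upper()) for a in alternates]
    counts = {to_rna(m): 0 for m in motifs}
    counts["other"] = 0
    lo = FLANK + MOTIF_OFFSETS[0]
    for w in windows.windows:
        tetrad = w[lo : lo + 4]
        key = to_rna(tetrad)
        if key in counts:
            counts[key] += 1
        else:
            counts["other"] += 1
    return counts


def scan_motif(sequence: str | RNAConstruct, motif: str, sequence_id: str | None = None) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of a 4-mer, 1-based.

    Accepts RNA or DNA spelling for both arguments; hits are reported in the
    motif's original rendering.
    """
    if isinstance(sequence, RNAConstruct):
        sequence_id = sequence_id or sequence.id
        seq = sequence.sequence
    else:
        seq = to_dna(sequence.upper())
        if set(seq) - set(BASES):
            raise ValueError("sequence contains characters outside the nucleotide alphabet")
    sid = sequence_id or "seq"
    target = to_dna(motif.upper())
    hits = []
    start = seq.find(target)
    while start != -1:
        hits.append(MotifHit(sid, start + 1, motif))
        start = seq.find(target, start + 1)
    return hits


# ---------------------------------------------------------------------------
# text reports
# ---------------------------------------------------------------------------

def write_windows_tsv(windows: WindowSet, handle) -> None:
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("reference_id\tposition\trci\twindow\n")
        for w, p in zip(windows.windows, windows.provenance):
            handle.write(f"{p.reference_id}\t{p.position}\t{p.rci:.6g}\t{w}\n")
    finally:
        if close:
            handle.close()


def write_pfm_tsv(pfm: PositionFrequencyMatrix, handle) -> None:
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        offsets = "\t".join(str(o) for o in range(-FLANK, FLANK + 1))
        handle.write(f"base\t{offsets}\n")
        for i, b in enumerate(BASES):
            row = "\t".join(f"{v:.6g}" for v in pfm.freq[i])
            handle.write(f"{b}\t{row}\n")
    finally:
        if close:
            handle.close()


def write_hits_tsv(hits: list[MotifHit], handle) -> None:
    """BED-like 1-based TSV: sequence_id, position, motif."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("sequence_id\tposition\tmotif\n")
        for h in hits:
            handle.write(f"{h.sequence_id}\t{h.position}\t{h.motif}\n")
    finally:
        if close:
            handle.close()


def consensus_report(consensus: ConsensusMotif, counts: dict[str, int] | None = None) -> str:
    lines = [
        "offsets:   " + " ".join(f"{o:+d}".rjust(4) for o in range(-FLANK, FLANK + 1)),
        "consensus: " + " ".join(ch.rjust(4) for ch in consensus.consensus),
        "IC (bits): " + " ".join(f"{v:.2f}".rjust(4) for v in consensus.ic),
    ]
    if consensus.motif_span is not None:
        lo, hi = consensus.motif_span
        lines.append(
            f"motif: {consensus.motif_rna} spanning offsets {lo}..{hi}; "
            f"cut {consensus.cut_offset_in_motif} base(s) into the motif "
            f"({consensus.motif_rna[:consensus.cut_offset_in_motif]}^"
            f"{consensus.motif_rna[consensus.cut_offset_in_motif:]})"
        )
    else:
        lines.append("motif: none called at offset 0")
    if counts is not None:
        lines.append("window tetrad counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
    return "\n".join(lines) + "\n"
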
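"""Ground-truthed synthetic inputs for cleavage-site mapping.

This module emulates the experimental chain that produces a degradome-style
sequencing library from designed RNA constructs: a panel of single-stranded
references with planted cleavage tetrads, stochastic per-molecule digestion by
a sequence-specific endoribonuclease, 5'-anchored read sampling with background
fragmentation and substitution errors, and first-order fluorescence-quenching
cleavage time courses for reporter substrates.

Sequences are stored in the DNA alphabet (A/C/G/T) and rendered as RNA (U) in
user-facing reports, matching the mixed convention of sequence logos (T) and
enzymology text (U).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
#: The enzyme's primary recognition tetrad (DNA rendering of UACA).
PRIMARY_MOTIF = "TACA"
#: Suboptimal tetrads cleaved with lower efficiency (UACC, UACU, AACA).
SUBOPTIMAL_MOTIFS = ("TACC", "TACT", "AACA")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3  # accept RNA alphabet on input
_CODE[ord("u")] = 3
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Sentinel code for padding cells in fixed-width read matrices.
PAD = np.uint8(4)


class PlacementError(ValueError):
    """Requested planted sites cannot be placed without overlap."""


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0, C=1, G=2, T/U=3)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted({c for c in seq if c.upper() not in "ACGTU"})
        raise ValueError(f"invalid nucleotide characters: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string (pads trimmed)."""
    codes = np.asarray(codes, dtype=np.uint8)
    codes = codes[codes != PAD]
    return _DECODE[codes].tobytes().decode("ascii")


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def _scan(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) 1-based occurrence positions of motif."""
    hits = []
    start = sequence.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = sequence.find(motif, start + 1)
    return hits


@dataclass(frozen=True)
class PlantedSite:
    """One recorded motif occurrence in a construct (deliberate or incidental)."""

    position: int  # 1-based index of the motif's first base
    motif: str  # DNA rendering, length 4
    site_class: str  # "primary" | "suboptimal"


@dataclass
class RNAConstruct:
    """A designed reference sequence with complete cleavage-site ground truth.

    ``planted_sites`` lists every occurrence of a recognition tetrad in the
    sequence, whether deliberately planted or arising incidentally from the
    random fill, so truth is complete for downstream benchmarking.
    """

    id: str
    sequence: str
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("construct sequence must be non-empty")
        self.sequence = to_dna(self.sequence.upper())
        if set(self.sequence) - set(BASES):
            raise ValueError(f"{self.id}: sequence outside alphabet {BASES}")
        last = 0
        for site in self.planted_sites:
            if site.position <= last:
                raise ValueError(f"{self.id}: site positions must be strictly increasing")
            last = site.position
            found = self.sequence[site.position - 1 : site.position + 3]
            if found != site.motif:
                raise ValueError(
                    f"{self.id}: planted motif {site.motif} at {site.position} "
                    f"does not match sequence ({found})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)

    def sites_of_class(self, site_class: str) -> list[PlantedSite]:
        return [s for s in self.planted_sites if s.site_class == site_class]


@dataclass(frozen=True)
class CleavageRule:
    """Sequence-specific cleavage: motif, scissile position, per-site efficiency.

    ``cut_offset`` counts bases from the motif's first base to the cut; the
    downstream fragment starts at ``site_position + cut_offset``. For the
    primary tetrad the enzyme cleaves U^ACA, i.e. ``cut_offset=1``: the
    downstream fragment starts on the first A.
    """

    motif: str
    cut_offset: int = 1
    efficiency: float = 0.8

    def __post_init__(self) -> None:
        if len(self.motif) != 4 or set(to_dna(self.motif.upper())) - set(BASES):
            raise ValueError(f"motif must be a 4-mer over {BASES}: {self.motif!r}")
        object.__setattr__(self, "motif", to_dna(self.motif.upper()))
        if not 0 <= self.cut_offset <= 3:
            raise ValueError("cut_offset must be in 0..3")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must be in [0, 1]")


def default_rules(
    efficiency_primary: float = 0.8, efficiency_suboptimal: float = 0.15
) -> list[CleavageRule]:
    """The enzyme's rule set: UACA cut at high efficiency, the three
    suboptimal tetrads cut weakly, all between the first and second base."""
    rules = [CleavageRule(PRIMARY_MOTIF, 1, efficiency_primary)]
    rules += [CleavageRule(m, 1, efficiency_suboptimal) for m in SUBOPTIMAL_MOTIFS]
    return rules


def _truth_sites(sequence: str) -> list[PlantedSite]:
    sites: list[PlantedSite] = []
    for motif in (PRIMARY_MOTIF, *SUBOPTIMAL_MOTIFS):
        cls = "primary" if motif == PRIMARY_MOTIF else "suboptimal"
        sites += [PlantedSite(p, motif, cls) for p in _scan(sequence, motif)]
    return sorted(sites, key=lambda s: s.position)


def make_construct(
    length: int,
    n_primary: int = 2,
    n_suboptimal_per_motif: int = 1,
    *,
    seed: int = 1,
    construct_id: str | None = None,
    fill: str | None = None,
    placement: str = "random",
    min_spacing: int = 0,
    end_margin: int = 10,
    avoid_incidental: bool = False,
) -> RNAConstruct:
    """Design a reference construct with planted cleavage tetrads.

    Plants ``n_primary`` copies of the primary tetrad and
    ``n_suboptimal_per_motif`` copies of each suboptimal tetrad at
    non-overlapping positions, fills the rest of the sequence uniformly at
    random (or with a fixed ``fill`` base), then re-scans the finished
    sequence so that ``planted_sites`` records every tetrad occurrence,
    incidental ones included.

    Parameters
    ----------
    min_spacing:
        Minimum distance (nt) between first bases of deliberately planted
        sites; ``0`` only forbids overlap. Designs that must resolve each
        cleavage as an independent coverage step should exceed the read
        length.
    end_margin:
        Planted sites are kept at least this many nt from either construct
        end so flanking windows and upstream coverage exist.
    avoid_incidental:
        If true, mutate the random fill until no tetrad occurs outside the
        deliberately planted positions (emulates a curated construct design
        with exactly the intended motif content).
    placement:
        ``"random"`` or ``"central"`` (single site centred; used for short
        reporter-style layouts).
    """
    if length < 50 and placement == "random":
        raise PlacementError("length must be >= 50 for random placement")
    rng = np.random.default_rng(seed)
    motifs = [PRIMARY_MOTIF] * n_primary
    for m in SUBOPTIMAL_MOTIFS:
        motifs += [m] * n_suboptimal_per_motif
    if 4 * len(motifs) > length:
        raise PlacementError(f"{len(motifs)} sites cannot fit in {length} nt")

    if placement == "central":
        if len(motifs) > 1:
            raise PlacementError("central placement supports a single site")
        starts = [(length - 4) // 2 + 1] if motifs else []
    elif placement == "random":
        lo = max(1, end_margin + 1)
        hi = length - 3 - max(0, end_margin)  # inclusive upper start
        if hi < lo and motifs:
            raise PlacementError("end_margin leaves no room for sites")
        gap = max(4, min_spacing)
        starts = []
        attempts = 0
        while len(starts) < len(motifs):
            attempts += 1
            if attempts > 10_000 * max(1, len(motifs)):
                raise PlacementError(
                    f"could not place {len(motifs)} sites with spacing {gap} in {length} nt"
                )
            cand = int(rng.integers(lo, hi + 1))
            if all(abs(cand - s) >= gap for s in starts):
                starts.append(cand)
        starts.sort()
    else:
        raise ValueError(f"unknown placement {placement!r}")

    if fill is None:
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    else:
        codes = np.full(length, encode(fill)[0], dtype=np.uint8)
    planted_intervals = []
    order = rng.permutation(len(motifs)) if placement == "random" else range(len(motifs))
    for slot, midx in zip(starts, order):
        codes[slot - 1 : slot + 3] = encode(motifs[midx])
        planted_intervals.append((slot, slot + 3))

    seq = decode(codes)
    if avoid_incidental:
        deliberate = {s for iv in planted_intervals for s in range(iv[0], iv[1] + 1)}
        for _ in range(100):
            extras = [
                s
                for s in _truth_sites(seq)
                if (s.position, s.position + 3) not in planted_intervals
            ]
            if not extras:
                break
            codes = encode(seq)
            for site in extras:
                editable = [
                    p for p in range(site.position, site.position + 4) if p not in deliberate
                ]
                if not editable:  # overlaps a deliberate site entirely; impossible for 4-mers
                    raise PlacementError("cannot scrub incidental motif overlapping a planted one")
                p = editable[int(rng.integers(len(editable)))]
                codes[p - 1] = (codes[p - 1] + 1 + rng.integers(3)) % 4
            seq = decode(codes)
        else:
            raise PlacementError("failed to scrub incidental motifs")

    cid = construct_id or f"construct_{length}_{seed}"
    return RNAConstruct(cid, seq, _truth_sites(seq))


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    left_boundary: str  # "cut" | "terminus" | "random"
    right_boundary: str
    molecule_id: int


@dataclass
class FragmentSet:
    construct_id: str
    fragments: list[Fragment]
    n_molecules: int

    def by_molecule(self) -> dict[int, list[Fragment]]:
        mols: dict[int, list[Fragment]] = {}
        for f in self.fragments:
            mols.setdefault(f.molecule_id, []).append(f)
        for frags in mols.values():
            frags.sort(key=lambda f: f.start)
        return mols


def digest(
    construct: RNAConstruct,
    rules: list[CleavageRule],
    n_molecules: int = 300,
    seed: int = 1,
) -> FragmentSet:
    """Digest ``n_molecules`` copies of the construct under the rule set.

    Every motif occurrence in the construct is an independent Bernoulli cut
    per molecule with its rule's efficiency; k cuts yield k+1 fragments that
    tile the construct exactly. Downstream fragments start at
    ``site + cut_offset`` (for U^ACA: on the first A of ACA).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if len({r.motif for r in rules}) != len(rules):
        raise ValueError("rule motifs must be distinct")
    L = len(construct)
    cut_starts: list[int] = []
    effs: list[float] = []
    for rule in rules:
        for pos in _scan(construct.sequence, rule.motif):
            start = pos + rule.cut_offset  # first base of the downstream fragment
            if 2 <= start <= L:  # a cut strictly inside the molecule
                cut_starts.append(start)
                effs.append(rule.efficiency)

    order = np.argsort(cut_starts, kind="stable")
    cut_starts_arr = np.asarray(cut_starts)[order] if cut_starts else np.empty(0, int)
    effs_arr = np.asarray(effs)[order] if effs else np.empty(0)

    rng = np.random.default_rng(seed)
    fired = rng.random((n_molecules, len(cut_starts_arr))) < effs_arr
    fragments: list[Fragment] = []
    for m in range(n_molecules):
        cuts = np.unique(cut_starts_arr[fired[m]])
        prev = 1
        left = "terminus"
        for c in cuts:
            fragments.append(Fragment(prev, int(c) - 1, left, "cut", m))
            prev = int(c)
            left = "cut"
        fragments.append(Fragment(prev, L, left, "terminus", m))
    return FragmentSet(construct.id, fragments, n_molecules)


# ---------------------------------------------------------------------------
# sequencing library
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    construct_id: str
    start: int  # 1-based alignment start on the construct
    boundary: str  # left-boundary type of the source fragment


@dataclass
class ReadSet:
    """Simulated single-end reads with per-read ground truth.

    Sequences live in a fixed-width uint8 code matrix (``PAD`` beyond each
    read's length); ``truth`` maps read id to its source construct, true
    alignment start and the boundary type of the fragment it was sampled from.
    """

    ids: list[str]
    codes: np.ndarray  # (n_reads, read_length) uint8
    lengths: np.ndarray  # (n_reads,) int64
    truth: dict[str, ReadTruth]
    quality_char: str = "I"  # Phred+33 Q40

    def __len__(self) -> int:
        return len(self.ids)

    def sequence(self, i: int) -> str:
        return decode(self.codes[i, : self.lengths[i]])

    @classmethod
    def concat(cls, readsets: list["ReadSet"]) -> "ReadSet":
        if not readsets:
            raise ValueError("nothing to concatenate")
        width = max(rs.codes.shape[1] for rs in readsets)
        mats = []
        for rs in readsets:
            mat = np.full((len(rs), width), PAD, dtype=np.uint8)
            mat[:, : rs.codes.shape[1]] = rs.codes
            mats.append(mat)
        ids = [i for rs in readsets for i in rs.ids]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids collide across read sets")
        truth = {}
        for rs in readsets:
            truth.update(rs.truth)
        return cls(
            ids,
            np.vstack(mats),
            np.concatenate([rs.lengths for rs in readsets]),
            truth,
            readsets[0].quality_char,
        )

    def to_fastq(self, handle) -> None:
        """Write Sanger FASTQ (constant quality) deterministically."""
        close = False
        if isinstance(handle, (str, bytes)):
            handle = open(handle, "w")
            close = True
        try:
            records = (
                SeqRecord(
                    Seq(self.sequence(i)),
                    id=self.ids[i],
                    description="",
                    letter_annotations={
                        "phred_quality": [ord(self.quality_char) - 33] * int(self.lengths[i])
                    },
                )
                for i in range(len(self))
            )
            SeqIO.write(records, handle, "fastq")
        finally:
            if close:
                handle.close()


def simulate_library(
    fragments: FragmentSet,
    construct: RNAConstruct,
    read_length: int = 50,
    depth_target: float = 2000.0,
    background_fraction: float = 0.3,
    error_rate: float = 0.001,
    seed: int = 1,
) -> ReadSet:
    """Sample a 5'-anchored read library from a digest.

    Each read is the 5'-terminal ``read_length`` bases of a fragment drawn
    uniformly with replacement (the whole fragment if shorter), so read
    starts pile up on cleavage positions. A ``background_fraction`` of draws
    are instead random sub-fragments (uniform start, geometric length with
    mean ``2 * read_length``), providing the baseline coverage that makes
    coverage-ratio statistics finite. Substitution errors are applied per
    base at ``error_rate``.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    if not fragments.fragments:
        raise ValueError("empty fragment set")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must be in [0, 1]")
    L = len(construct)
    n_reads = int(round(depth_target * L / read_length))
    rng = np.random.default_rng(seed)

    frag_starts = np.array([f.start for f in fragments.fragments], dtype=np.int64)
    frag_lens = np.array([f.end - f.start + 1 for f in fragments.fragments], dtype=np.int64)
    frag_lb = np.array([f.left_boundary for f in fragments.fragments], dtype=object)

    idx = rng.integers(0, len(frag_starts), size=n_reads)
    starts = frag_starts[idx]
    src_lens = frag_lens[idx]
    boundaries = frag_lb[idx].copy()

    is_bg = rng.random(n_reads) < background_fraction
    bg_starts = rng.integers(1, L + 1, size=n_reads)
    bg_lens = rng.geometric(1.0 / (2 * read_length), size=n_reads)
    starts = np.where(is_bg, bg_starts, starts)
    src_lens = np.where(is_bg, np.minimum(bg_lens, L - bg_starts + 1), src_lens)
    boundaries[is_bg] = "random"

    lengths = np.minimum(src_lens, read_length).astype(np.int64)
    cols = np.arange(read_length)
    pos = (starts - 1)[:, None] + cols[None, :]
    valid = cols[None, :] < lengths[:, None]
    codes = construct.codes[np.minimum(pos, L - 1)]

    if error_rate > 0:
        err = (rng.random((n_reads, read_length)) < error_rate) & valid
        shift = rng.integers(1, 4, size=(n_reads, read_length), dtype=np.uint8)
        codes = np.where(err, (codes + shift) % 4, codes)
    codes = np.where(valid, codes, PAD).astype(np.uint8)

    ids = [f"{construct.id}:{i}" for i in range(n_reads)]
    truth = {
        ids[i]: ReadTruth(construct.id, int(starts[i]), str(boundaries[i]))
        for i in range(n_reads)
    }
    return ReadSet(ids, codes, lengths, truth)


# ---------------------------------------------------------------------------
# fluorescence-quenching time courses
# ---------------------------------------------------------------------------

CONDITIONS = ("enzyme_low", "enzyme_high", "rnase_a", "no_enzyme")


@dataclass
class FluorTimeSeries:
    """Fluorescence intensity vs time for one substrate and condition.

    ``intensities`` holds one row per replicate on a shared uniform time grid
    (minutes). Intensities are arbitrary units, clipped at zero.
    """

    substrate_id: str
    condition: str
    times: np.ndarray  # (T,) minutes, uniform grid
    intensities: np.ndarray  # (n_replicates, T)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        steps = np.diff(self.times)
        if len(self.times) < 2 or not np.all(steps > 0) or not np.allclose(steps, steps[0]):
            raise ValueError("times must be a strictly increasing uniform grid")
        if self.intensities.shape[1] != len(self.times):
            raise ValueError("times and intensities lengths differ")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be >= 0")

    @property
    def n_replicates(self) -> int:
        return int(self.intensities.shape[0])

    def mean_trace(self) -> np.ndarray:
        return self.intensities.mean(axis=0)


def dequenching_rate(
    has_motif: str,
    is_rna_backbone: bool,
    condition: str,
    k_fast: float,
    k_slow: float,
) -> float:
    """First-order dequenching rate implied by substrate x condition logic.

    The enzyme cleaves a primary tetrad at either dose, a suboptimal tetrad
    only at the high dose (slowly), and nothing else; RNase A cleaves any
    substrate with an RNA backbone; a pure-DNA backbone is inert to both.
    """
    if has_motif not in ("none", "primary", "suboptimal"):
        raise ValueError(f"unknown motif class {has_motif!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not is_rna_backbone or condition == "no_enzyme":
        return 0.0
    if condition == "rnase_a":
        return k_fast
    if has_motif == "primary":
        return k_fast
    if has_motif == "suboptimal":
        return k_slow if condition == "enzyme_high" else 0.0
    return 0.0


def simulate_fluorescence(
    substrate_id: str,
    has_motif: str,
    is_rna_backbone: bool,
    condition: str,
    k_fast: float = 0.5,
    k_slow: float = 0.05,
    t_max: float = 60.0,
    noise_sd: float = 5.0,
    seed: int = 1,
    f0: float = 100.0,
    fmax: float = 1000.0,
    n_replicates: int = 3,
    dt: float = 1.0,
) -> FluorTimeSeries:
    """Simulate F(t) = F0 + (Fmax - F0) * (1 - exp(-k t)) with Gaussian noise.

    The rate k follows :func:`dequenching_rate`; readings every ``dt`` minutes
    mirror a plate-reader time course. Noise is i.i.d. per reading, clipped at
    zero intensity.
    """
    if k_fast < 0 or k_slow < 0:
        raise ValueError("rates must be >= 0")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    k = dequenching_rate(has_motif, is_rna_backbone, condition, k_fast, k_slow)
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    mean = f0 + (fmax - f0) * (1.0 - np.exp(-k * times))
    noise = rng.normal(0.0, noise_sd, size=(n_replicates, len(times))) if noise_sd > 0 else 0.0
    intensities = np.clip(mean[None, :] + noise, 0.0, None)
    return FluorTimeSeries(substrate_id, condition, times, intensities)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_fasta(constructs: list[RNAConstruct], handle) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in constructs]
    SeqIO.write(records, handle, "fasta")


def read_fasta(handle) -> list[RNAConstruct]:
    """Load references; ground truth is rebuilt by scanning for the tetrads."""
    constructs = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = to_dna(str(rec.seq).upper())
        constructs.append(RNAConstruct(rec.id, seq, _truth_sites(seq)))
    return constructs


def write_truth(constructs: list[RNAConstruct], handle) -> None:
    """Tab-separated ground truth: construct_id, position, motif (RNA), class."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("construct_id\tposition\tmotif\tclass\n")
        for c in constructs:
            for s in c.planted_sites:
                handle.write(f"{c.id}\t{s.position}\t{to_rna(s.motif)}\t{s.site_class}\n")
    finally:
        if close:
            handle.close()


def write_fluor_csv(series: list[FluorTimeSeries], handle) -> None:
    """Long-format CSV: substrate,condition,replicate,time_min,intensity."""
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("substrate,condition,replicate,time_min,intensity\n")
        for s in series:
            for rep in range(s.n_replicates):
                for t, y in zip(s.times, s.intensities[rep]):
                    handle.write(f"{s.substrate_id},{s.condition},{rep},{t:g},{y:.6g}\n")
    finally:
        if close:
            handle.close()


def read_fluor_csv(handle) -> list[FluorTimeSeries]:
    import pandas as pd

    df = pd.read_csv(handle)
    required = {"substrate", "condition", "replicate", "time_min", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"fluorescence CSV must have columns {sorted(required)}")
    out = []
    for (sub, cond), grp in df.groupby(["substrate", "condition"], sort=True):
        reps = sorted(grp["replicate"].unique())
        times = np.sort(grp["time_min"].unique())
        mat = np.empty((len(reps), len(times)))
        for i, rep in enumerate(reps):
            sel = grp[grp["replicate"] == rep].sort_values("time_min")
            if not np.array_equal(sel["time_min"].to_numpy(), times):
                raise ValueError(f"{sub}/{cond}: replicate {rep} is not on the shared time grid")
            mat[i] = sel["intensity"].to_numpy()
        out.append(FluorTimeSeries(str(sub), str(cond), times, mat))
    return out


def fastq_bytes(readset: ReadSet) -> bytes:
    buf = io.StringIO()
    readset.to_fastq(buf)
    return buf.getvalue().encode()
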
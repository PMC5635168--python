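"""Pipeline orchestration: simulate -> map -> detect -> motif -> report, plus
the fluorometric workflow, behind a single config with reproducible seeds.

Each stage persists plain-text intermediates (FASTA/FASTQ/SAM/TSV/CSV) and
consumes only the previous stage's files, so a run can be resumed or
re-entered at any stage. All tunables live in :class:`PipelineConfig`; the
field defaults are the analysis constants of the method (coverage filter 500,
top-15/top-25 selection, 5-nt flanks) and the simulator's study conditions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import coverage as cov
from . import fluor as fl
from . import motif as mo
from . import synthetic as syn

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    # synthetic constructs
    n_constructs: int = 5
    construct_length: int = 1000
    n_primary: int = 3
    n_suboptimal_per_motif: int = 1
    site_min_spacing: int = 60
    site_end_margin: int = 60
    avoid_incidental: bool = True
    # digestion
    efficiency_primary: float = 0.8
    efficiency_suboptimal: float = 0.15
    n_molecules: int = 300
    # library
    read_length: int = 50
    depth_target: float = 2000.0
    background_fraction: float = 0.3
    error_rate: float = 0.001
    # mapping / detection
    max_mismatches: int = 2
    min_coverage: int = 500
    top_n_primary: int = 15
    top_n_extended: int = 25
    # motif calling
    flank: int = 5
    pseudocount: float = 0.5
    freq_threshold: float = 0.5
    ic_threshold: float = 1.0
    # fluorometry
    fold_threshold: float = 2.0
    k_fast: float = 0.5
    k_slow: float = 0.05
    t_max: float = 60.0
    noise_sd: float = 5.0
    f0: float = 100.0
    fmax: float = 1000.0
    n_replicates: int = 3
    # reproducibility
    seed: int = 1

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.n_constructs >= 1, "n_constructs must be >= 1"),
            (self.construct_length >= 50, "construct_length must be >= 50"),
            (0.0 <= self.efficiency_primary <= 1.0, "efficiency_primary must be in [0, 1]"),
            (0.0 <= self.efficiency_suboptimal <= 1.0, "efficiency_suboptimal must be in [0, 1]"),
            (self.n_molecules >= 1, "n_molecules must be >= 1"),
            (self.read_length >= 20, "read_length must be >= 20"),
            (0.0 <= self.background_fraction <= 1.0, "background_fraction must be in [0, 1]"),
            (0.0 <= self.error_rate < 1.0, "error_rate must be in [0, 1)"),
            (self.min_coverage >= 0, "min_coverage must be >= 0"),
            (0 < self.top_n_primary <= self.top_n_extended, "need 0 < top_n_primary <= top_n_extended"),
            (self.flank == 5, "flank is fixed at 5 by the window convention"),
            (self.fold_threshold > 0, "fold_threshold must be positive"),
            (self.t_max > 0, "t_max must be positive"),
            (self.seed >= 0, "seed must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs).validate()


def _stage_seed(config: PipelineConfig, stage: int, item: int = 0) -> int:
    """Deterministic per-stage, per-item sub-seed below 2**31."""
    return int((config.seed * 100_003 + stage * 1_009 + item * 17 + 7) % (2**31 - 1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_references(config: PipelineConfig) -> list[syn.RNAConstruct]:
    return [
        syn.make_construct(
            config.construct_length,
            config.n_primary,
            config.n_suboptimal_per_motif,
            seed=_stage_seed(config, 1, i),
            construct_id=f"RNA1000-{i + 1}",
            min_spacing=config.site_min_spacing,
            end_margin=config.site_end_margin,
            avoid_incidental=config.avoid_incidental,
        )
        for i in range(config.n_constructs)
    ]


def simulate_readsets(
    config: PipelineConfig, references: list[syn.RNAConstruct]
) -> syn.ReadSet:
    rules = syn.default_rules(config.efficiency_primary, config.efficiency_suboptimal)
    readsets = []
    for i, ref in enumerate(references):
        frags = syn.digest(ref, rules, config.n_molecules, seed=_stage_seed(config, 2, i))
        readsets.append(
            syn.simulate_library(
                frags,
                ref,
                read_length=config.read_length,
                depth_target=config.depth_target,
                background_fraction=config.background_fraction,
                error_rate=config.error_rate,
                seed=_stage_seed(config, 3, i),
            )
        )
    return syn.ReadSet.concat(readsets)


def run_simulate(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate references, reads, ground truth and fluorescence series on disk."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    references = build_references(config)
    reads = simulate_readsets(config, references)
    paths = {
        "fasta": outdir / "references.fasta",
        "fastq": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "fluor": outdir / "fluorescence.csv",
    }
    with open(paths["fasta"], "w") as fh:
        syn.write_fasta(references, fh)
    reads.to_fastq(str(paths["fastq"]))
    syn.write_truth(references, str(paths["truth"]))
    panel = fl.packaged_panel()
    series = fl.simulate_panel(
        panel,
        seed=_stage_seed(config, 4),
        k_fast=config.k_fast,
        k_slow=config.k_slow,
        t_max=config.t_max,
        noise_sd=config.noise_sd,
        f0=config.f0,
        fmax=config.fmax,
        n_replicates=config.n_replicates,
    )
    flat = [s for conds in series.values() for s in conds.values()]
    syn.write_fluor_csv(flat, str(paths["fluor"]))
    logger.info(
        "simulate: %d references, %d reads, %d fluorescence series",
        len(references),
        len(reads),
        len(flat),
    )
    return paths


def detect_candidates(
    reads: syn.ReadSet | None,
    references: list[syn.RNAConstruct],
    config: PipelineConfig,
    alignments: cov.AlignmentSet | None = None,
) -> tuple[list[cov.CandidateSite], list[cov.CoverageProfile]]:
    """Map (unless alignments are given), stack coverage, rank RCI boundaries."""
    if alignments is None:
        if reads is None or len(reads) == 0:
            raise ValueError("no reads to map")
        alignments = cov.map_reads(reads, references, config.max_mismatches)
    profiles = [cov.compute_coverage(alignments, ref) for ref in references]
    tracks = [cov.relative_coverage_increase(p) for p in profiles]
    candidates = cov.select_candidates(
        tracks, profiles, config.min_coverage, config.top_n_extended
    )
    logger.info(
        "detect: %d alignments, %d candidates (top %d requested)",
        len(alignments),
        len(candidates),
        config.top_n_extended,
    )
    return candidates, profiles


def write_candidates_tsv(candidates: list[cov.CandidateSite], handle) -> None:
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("rank\treference_id\tposition\trci\tcoverage\n")
        for i, c in enumerate(candidates, 1):
            handle.write(f"{i}\t{c.reference_id}\t{c.position}\t{c.rci:.6g}\t{c.coverage}\n")
    finally:
        if close:
            handle.close()


def read_candidates_tsv(handle) -> list[cov.CandidateSite]:
    import pandas as pd

    df = pd.read_csv(handle, sep="\t")
    df = df.sort_values("rank")
    return [
        cov.CandidateSite(str(r.reference_id), int(r.position), float(r.rci), int(r.coverage))
        for r in df.itertuples(index=False)
    ]


def run_detect(
    input_path: str | Path,
    fasta_path: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
) -> Path:
    """FASTQ or SAM in, ranked candidate TSV out."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(fasta_path) as fh:
        references = syn.read_fasta(fh)
    input_path = Path(input_path)
    if input_path.suffix.lower() == ".sam":
        alignments = cov.read_sam(str(input_path))
        candidates, _ = detect_candidates(None, references, config, alignments=alignments)
    else:
        with open(input_path) as fh:
            reads = cov.reads_from_fastq(fh)
        candidates, _ = detect_candidates(reads, references, config)
    out = outdir / "candidates.tsv"
    write_candidates_tsv(candidates, str(out))
    return out


def motif_summary(
    candidates: list[cov.CandidateSite],
    references: list[syn.RNAConstruct],
    config: PipelineConfig,
) -> dict:
    """Windows, PFM, consensus from the top-N candidates; tetrad counts in
    the primary block and the extension block (ranks top_n_primary+1..top_n_extended)."""
    primary_block = candidates[: config.top_n_primary]
    extension_block = candidates[config.top_n_primary : config.top_n_extended]
    win_primary = mo.extract_windows(primary_block, references)
    win_extension = mo.extract_windows(extension_block, references)
    if len(win_primary) == 0:
        logger.warning("motif: no windows extracted; empty report")
        return {
            "windows_primary": win_primary,
            "windows_extension": win_extension,
            "pfm": None,
            "consensus": None,
            "counts_primary": {},
            "counts_extension": {},
        }
    pfm = mo.build_pfm(win_primary, config.pseudocount)
    consensus = mo.call_consensus(pfm, config.freq_threshold, config.ic_threshold)
    return {
        "windows_primary": win_primary,
        "windows_extension": win_extension,
        "pfm": pfm,
        "consensus": consensus,
        "counts_primary": mo.classify_suboptimal(win_primary),
        "counts_extension": mo.classify_suboptimal(win_extension),
    }


def run_motif(
    candidates_path: str | Path,
    fasta_path: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
) -> Path:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(fasta_path) as fh:
        references = syn.read_fasta(fh)
    candidates = read_candidates_tsv(str(candidates_path))
    summary = motif_summary(candidates, references, config)
    report_path = outdir / "consensus_report.txt"
    if summary["consensus"] is None:
        report_path.write_text("no candidates; no consensus called\n")
        return report_path
    mo.write_windows_tsv(summary["windows_primary"], str(outdir / "windows_top.tsv"))
    mo.write_pfm_tsv(summary["pfm"], str(outdir / "pfm.tsv"))
    text = mo.consensus_report(summary["consensus"], summary["counts_primary"])
    text += "extension block (ranks %d..%d) tetrad counts: %s\n" % (
        config.top_n_primary + 1,
        config.top_n_extended,
        ", ".join(f"{k}={v}" for k, v in summary["counts_extension"].items()),
    )
    report_path.write_text(text)
    return report_path


def run_fluor(
    panel_path: str | Path | None,
    series_path: str | Path,
    config: PipelineConfig,
    outdir: str | Path,
) -> Path:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = fl.load_panel(str(panel_path)) if panel_path else fl.packaged_panel()
    series = fl.group_series(syn.read_fluor_csv(str(series_path)))
    results = []
    for sub in panel.entries:
        conds = series.get(sub.name, {})
        for required in ("enzyme_low", "enzyme_high", "no_enzyme"):
            if required not in conds:
                raise ValueError(f"{sub.name}: missing {required} series")
        results.append(
            fl.classify_substrate(
                sub,
                conds["enzyme_low"],
                conds["enzyme_high"],
                conds["no_enzyme"],
                conds.get("rnase_a"),
                threshold=config.fold_threshold,
            )
        )
    out = outdir / "assay_results.tsv"
    fl.write_results_tsv(results, str(out))
    logger.info("fluor: %d substrates classified", len(results))
    return out


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    paths = run_simulate(config, outdir)
    candidates = run_detect(paths["fastq"], paths["fasta"], config, outdir)
    report = run_motif(candidates, paths["fasta"], config, outdir)
    assay = run_fluor(None, paths["fluor"], config, outdir)
    config.to_yaml(outdir / "config_echo.yaml")
    return {**paths, "candidates": candidates, "report": report, "assay": assay}


# ---------------------------------------------------------------------------
# in-memory end-to-end scenario (shared by tests and the acceptance script)
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Outcome of one full in-memory motif-recovery run with ground truth."""

    references: list[syn.RNAConstruct]
    candidates: list[cov.CandidateSite]  # top_n_extended, ranked
    consensus: mo.ConsensusMotif | None
    counts_primary: dict[str, int]
    counts_extension: dict[str, int]
    true_cut_positions: dict[str, dict[int, str]] = field(default_factory=dict)
    top_n_primary: int = 15

    @property
    def primary_block(self) -> list[cov.CandidateSite]:
        return self.candidates[: self.top_n_primary]

    def candidate_truth_motif(self, cand: cov.CandidateSite) -> str | None:
        """The planted motif whose cut position the candidate hits, if any."""
        return self.true_cut_positions.get(cand.reference_id, {}).get(cand.position)


def run_motif_recovery_scenario(seed: int, config: PipelineConfig | None = None) -> ScenarioResult:
    """Simulate the multi-construct digestion experiment and recover the motif.

    This is the package's end-to-end workhorse: build the construct panel,
    digest, sample the library, map, compute coverage and RCI, select the
    overall top-25 candidates, and summarise windows/consensus — all from one
    integer seed.
    """
    config = (config or PipelineConfig()).replace(seed=seed)
    references = build_references(config)
    reads = simulate_readsets(config, references)
    candidates, _ = detect_candidates(reads, references, config)
    summary = motif_summary(candidates, references, config)
    truth: dict[str, dict[int, str]] = {}
    for ref in references:
        truth[ref.id] = {s.position + 1: s.motif for s in ref.planted_sites}
    return ScenarioResult(
        references,
        candidates,
        summary["consensus"],
        summary["counts_primary"],
        summary["counts_extension"],
        truth,
        config.top_n_primary,
    )
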
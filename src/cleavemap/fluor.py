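"""Fluorophore-quencher cleavage assay: ingestion, kinetics and substrate calls.

Reporter substrates carry a 5' fluorophore and 3' quencher joined by a
DNA/RNA chimeric backbone; cleavage of the RNA core separates the dyes and
fluorescence rises. Substrates are classified from endpoint fold changes
against the no-enzyme control at two enzyme doses:

    cleaved    fold change >= threshold already at the low dose
    weak       only the high dose reaches the threshold
    uncleaved  neither dose does

with RNase A as the positive control for any RNA-containing backbone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import (
    FluorTimeSeries,
    PRIMARY_MOTIF,
    SUBOPTIMAL_MOTIFS,
    simulate_fluorescence,
    to_dna,
)

ENDPOINT_FRACTION = 0.1  # endpoint = mean intensity over the final 10% of samples


@dataclass(frozen=True)
class Substrate:
    """One reporter oligonucleotide: sequence plus per-base backbone flags."""

    name: str
    sequence: str  # as synthesised (U marks RNA uracil, T DNA thymine)
    rna_mask: tuple[bool, ...]  # True where the nucleotide is RNA

    def __post_init__(self) -> None:
        if len(self.rna_mask) != len(self.sequence):
            raise ValueError(f"{self.name}: backbone mask length mismatch")

    @property
    def dna_sequence(self) -> str:
        return to_dna(self.sequence.upper())

    @property
    def is_rna_backbone(self) -> bool:
        """True if any nucleotide is RNA (an all-DNA strand is inert)."""
        return any(self.rna_mask)

    def motif_content(self) -> str:
        """'primary', 'suboptimal' or 'none': does an all-RNA tetrad occur?

        Only occurrences whose four bases are all RNA count — the enzyme
        cleaves an RNA backbone, so a tetrad interrupted by DNA linkages is
        not a substrate.
        """
        seq = self.dna_sequence
        for motif, cls in [(PRIMARY_MOTIF, "primary")] + [
            (m, "suboptimal") for m in SUBOPTIMAL_MOTIFS
        ]:
            start = seq.find(motif)
            while start != -1:
                if all(self.rna_mask[start : start + 4]):
                    return cls
                start = seq.find(motif, start + 1)
        return "none"


@dataclass
class SubstratePanel:
    entries: list[Substrate]

    def __post_init__(self) -> None:
        names = [s.name for s in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("substrate names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> Substrate:
        for s in self.entries:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class AssayResult:
    substrate: str
    fold_change_low: float
    fold_change_high: float
    call: str  # "cleaved" | "weak" | "uncleaved"
    positive_control_ok: bool
    fold_change_rnase: float | None = None


@dataclass
class FitResult:
    k: float  # per minute
    f0: float
    fmax: float
    residual_norm: float
    converged: bool


def load_panel(handle) -> SubstratePanel:
    """Read a substrate panel TSV with columns name, sequence, rna_mask.

    ``rna_mask`` is a string of D/R flags, one per nucleotide.
    """
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle)
        close = True
    try:
        df = pd.read_csv(handle, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError("empty substrate panel file") from None
    finally:
        if close:
            handle.close()
    required = {"name", "sequence", "rna_mask"}
    if not required <= set(df.columns):
        raise ValueError(f"panel TSV must have columns {sorted(required)}")
    entries = []
    for row in df.itertuples(index=False):
        mask = str(row.rna_mask).upper()
        if set(mask) - {"D", "R"}:
            raise ValueError(f"{row.name}: rna_mask must use only D/R flags")
        entries.append(
            Substrate(str(row.name), str(row.sequence), tuple(ch == "R" for ch in mask))
        )
    if not entries:
        raise ValueError("substrate panel has no entries")
    return SubstratePanel(entries)


def packaged_panel() -> SubstratePanel:
    """The 11-substrate reporter panel shipped with the package."""
    ref = resources.files("cleavemap.data") / "substrate_panel.tsv"
    with ref.open() as fh:
        return load_panel(fh)


def endpoint_intensity(series: FluorTimeSeries) -> float:
    """Replicate-averaged mean intensity over the final 10% of time points."""
    trace = series.mean_trace()
    n_tail = max(1, int(np.ceil(ENDPOINT_FRACTION * len(trace))))
    return float(trace[-n_tail:].mean())


def endpoint_fold_change(series: FluorTimeSeries, control: FluorTimeSeries) -> float:
    """Endpoint intensity of the test series relative to the no-enzyme control."""
    if not np.array_equal(series.times, control.times):
        raise ValueError("time grids of test and control series differ")
    denom = endpoint_intensity(control)
    if denom <= 0:
        raise ValueError("control endpoint intensity is zero; fold change undefined")
    return endpoint_intensity(series) / denom


def classify_substrate(
    substrate: Substrate,
    low: FluorTimeSeries,
    high: FluorTimeSeries,
    no_enzyme: FluorTimeSeries,
    rnase_a: FluorTimeSeries | None = None,
    threshold: float = 2.0,
) -> AssayResult:
    """Call a substrate cleaved/weak/uncleaved from its two-dose fold changes."""
    if no_enzyme is None:
        raise ValueError("a no-enzyme control series is required")
    fc_low = endpoint_fold_change(low, no_enzyme)
    fc_high = endpoint_fold_change(high, no_enzyme)
    if fc_low >= threshold:
        call = "cleaved"
    elif fc_high >= threshold:
        call = "weak"
    else:
        call = "uncleaved"
    fc_rnase = None
    positive_ok = True
    if substrate.is_rna_backbone:
        if rnase_a is None:
            raise ValueError(f"{substrate.name}: RNase A positive control missing")
        fc_rnase = endpoint_fold_change(rnase_a, no_enzyme)
        positive_ok = fc_rnase >= threshold
    return AssayResult(substrate.name, fc_low, fc_high, call, positive_ok, fc_rnase)


def simulate_panel(
    panel: SubstratePanel,
    seed: int = 1,
    **sim_kwargs,
) -> dict[str, dict[str, FluorTimeSeries]]:
    """Simulate all four assay conditions for every panel substrate."""
    out: dict[str, dict[str, FluorTimeSeries]] = {}
    for i, sub in enumerate(panel.entries):
        conds = {}
        for j, cond in enumerate(("enzyme_low", "enzyme_high", "no_enzyme", "rnase_a")):
            conds[cond] = simulate_fluorescence(
                sub.name,
                sub.motif_content(),
                sub.is_rna_backbone,
                cond,
                seed=seed + 101 * i + 13 * j,
                **sim_kwargs,
            )
        out[sub.name] = conds
    return out


def classify_panel(
    panel: SubstratePanel,
    series: dict[str, dict[str, FluorTimeSeries]],
    threshold: float = 2.0,
) -> list[AssayResult]:
    results = []
    for sub in panel.entries:
        conds = series[sub.name]
        results.append(
            classify_substrate(
                sub,
                conds["enzyme_low"],
                conds["enzyme_high"],
                conds["no_enzyme"],
                conds.get("rnase_a"),
                threshold=threshold,
            )
        )
    return results


def group_series(series: list[FluorTimeSeries]) -> dict[str, dict[str, FluorTimeSeries]]:
    """Index a flat series list by substrate and condition."""
    out: dict[str, dict[str, FluorTimeSeries]] = {}
    for s in series:
        out.setdefault(s.substrate_id, {})[s.condition] = s
    return out


def fit_first_order(series: FluorTimeSeries) -> FitResult:
    """Least-squares fit of F(t) = F0 + (Fmax - F0) * (1 - exp(-k t)).

    Replicates are averaged before fitting. A flat series is returned as
    k = 0 directly (the amplitude is degenerate there); optimisation
    failures are flagged in the result rather than raised.
    """
    t = series.times
    if len(t) < 10:
        raise ValueError("at least 10 time points are required for a kinetic fit")
    y = series.mean_trace()
    span = float(np.ptp(y))
    if span < 1e-9 * max(1.0, abs(float(y.mean()))):
        m = float(y.mean())
        return FitResult(0.0, m, m, float(np.linalg.norm(y - m)), True)

    def model(t, k, f0, fmax):
        return f0 + (fmax - f0) * (1.0 - np.exp(-k * t))

    k0 = 1.0 / max(t[-1] / 3.0, 1e-6)
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[k0, float(y[0]), float(y[-1])],
            bounds=([0.0, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False)
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return FitResult(float(popt[0]), float(popt[1]), float(popt[2]), resid, True)


def write_results_tsv(results: list[AssayResult], handle) -> None:
    close = False
    if isinstance(handle, (str, bytes)):
        handle = open(handle, "w")
        close = True
    try:
        handle.write(
            "substrate\tfold_change_low\tfold_change_high\tfold_change_rnase\t"
            "call\tpositive_control_ok\n"
        )
        for r in results:
            rn = f"{r.fold_change_rnase:.4g}" if r.fold_change_rnase is not None else "NA"
            handle.write(
                f"{r.substrate}\t{r.fold_change_low:.4g}\t{r.fold_change_high:.4g}\t"
                f"{rn}\t{r.call}\t{str(r.positive_control_ok).lower()}\n"
            )
    finally:
        if close:
            handle.close()
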
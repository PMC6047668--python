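"""Synthetic genomes, planted peaks, coverage tracks, and expression tables.

Every downstream stage of the pipeline (region calling, k-mer rank
enrichment, expression association) is exercised on data produced here, so
the generators are deliberately simple and fully deterministic: a toy
single-contig genome with i.i.d. base composition, peak flanks rewritten to
a chosen composition class (GC-rich, AT-rich, WCGW-seeded, or neutral),
three-mark / two-condition coverage with triangular enrichments of known
fold, and a two-condition expression table in which genes nearest to
activated peaks are shifted upward on the log2 scale.

All generators are pure functions of their arguments including the seed;
identical inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MARKS, CompositionClass, CoverageTrack

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_W = ("A", "T")
_MIN_GENE_SPACING = 400
_GENE_LENGTH = 200


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated two-condition experiment.

    ``read_depth_scale`` is the mean baseline bin signal in arbitrary units;
    ``noise_cv`` is the coefficient of variation of the baseline noise.
    """

    genome_length: int
    gc_fraction: float = 0.5
    n_genes: int = 50
    n_peaks_per_class: int = 10
    peak_fold: float = 4.0
    flank_half_width: int = 250
    seed: int = 0
    read_depth_scale: float = 10.0
    bin_size: int = 25
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.peak_fold <= 0:
            raise ValueError("peak_fold must be positive")


@dataclass(frozen=True)
class PlantedPeakSpec:
    """One planted peak: center, flank composition class, per-mark folds."""

    center: int
    composition_class: CompositionClass
    mark_folds: dict[str, float] = field(default_factory=dict)
    target_gene: str | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.mark_folds.values()):
            raise ValueError("mark fold changes must be positive")

    def window(self, half_width: int) -> tuple[int, int]:
        """Closed planting window [center - hw, center + hw]."""
        return self.center - half_width, self.center + half_width


def generate_genome(length: int, gc_fraction: float, seed: int) -> str:
    """Draw an i.i.d. A/C/G/T sequence with P(G) = P(C) = gc_fraction / 2."""
    if length < 0:
        raise ValueError("genome length must be non-negative")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    if length == 0:
        return ""
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    return _BASES[idx].tobytes().decode("ascii")


def _composition_window(rng: np.random.Generator, n: int, at_weight: float) -> str:
    """i.i.d. window with P(A)+P(T) = at_weight, A/T and C/G split evenly."""
    p_w = at_weight / 2.0
    p_s = (1.0 - at_weight) / 2.0
    idx = rng.choice(4, size=n, p=[p_w, p_s, p_s, p_w])
    return _BASES[idx].tobytes().decode("ascii")


def _wcgw_seeded_window(rng: np.random.Generator, n: int, intensity: float) -> str:
    """Neutral background with non-overlapping random WWCGWW instantiations.

    ``intensity`` is the target fraction of window bases covered by planted
    copies; each copy instantiates its four W positions independently so the
    whole degenerate class, not a single literal 6-mer, is enriched.
    """
    window = list(_composition_window(rng, n, 0.5))
    n_copies = int(intensity * n / 6)
    if n_copies == 0:
        return "".join(window)
    starts = np.arange(0, n - 5)
    rng.shuffle(starts)
    occupied = np.zeros(n, dtype=bool)
    placed = 0
    for s in starts:
        if placed >= n_copies:
            break
        if occupied[s : s + 6].any():
            continue
        w = rng.choice(2, size=4)
        copy = (_W[w[0]], _W[w[1]], "C", "G", _W[w[2]], _W[w[3]])
        window[s : s + 6] = copy
        occupied[s : s + 6] = True
        placed += 1
    return "".join(window)


def plant_composition(
    genome: str,
    spec: PlantedPeakSpec,
    half_width: int,
    intensity: float,
    seed: int,
) -> str:
    """Rewrite the ±half_width flank around ``spec.center`` to its class.

    The window is the closed interval [center - half_width,
    center + half_width] (2·half_width + 1 bases); everything outside it is
    returned bitwise unchanged. NEUTRAL peaks leave the genome untouched.
    """
    lo, hi = spec.window(half_width)
    if lo < 0 or hi >= len(genome):
        raise ValueError(
            f"planting window [{lo}, {hi}] exceeds genome of length {len(genome)}"
        )
    if spec.composition_class is CompositionClass.NEUTRAL:
        return genome
    n = 2 * half_width + 1
    rng = np.random.default_rng([seed, spec.center])
    if spec.composition_class is CompositionClass.AT_RICH:
        window = _composition_window(rng, n, intensity)
    elif spec.composition_class is CompositionClass.GC_RICH:
        window = _composition_window(rng, n, 1.0 - intensity)
    elif spec.composition_class is CompositionClass.WCGW_SEEDED:
        window = _wcgw_seeded_window(rng, n, intensity)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown composition class {spec.composition_class}")
    return genome[:lo] + window + genome[hi + 1 :]


def generate_coverage(
    genome_length: int,
    peaks: list[PlantedPeakSpec],
    mark: str,
    condition: str,
    config: SimConfig,
    contig: str = "chr1",
) -> CoverageTrack:
    """Binned coverage: positive baseline noise plus triangular enrichments.

    The baseline is truncated-normal noise with mean ``read_depth_scale``.
    In the treated condition each peak adds a symmetric triangle of
    half-width ``flank_half_width`` whose apex is 2·baseline·(fold − 1), so
    the expected mean signal over the ±half-width window is exactly ``fold``
    times the control mean; control tracks carry baseline noise only.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if condition not in ("treated", "control"):
        raise ValueError("condition must be 'treated' or 'control'")
    hw = config.flank_half_width
    for peak in peaks:
        lo, hi = peak.window(hw)
        if lo < 0 or hi >= genome_length:
            raise ValueError(f"peak window [{lo}, {hi}] out of genome bounds")

    n_bins = -(-genome_length // config.bin_size)
    rng = np.random.default_rng(
        [config.seed, MARKS.index(mark), 0 if condition == "control" else 1]
    )
    scale = config.read_depth_scale
    values = rng.normal(scale, config.noise_cv * scale, size=n_bins)
    np.maximum(values, 0.0, out=values)

    if condition == "treated":
        bin_centers = (np.arange(n_bins) + 0.5) * config.bin_size
        for peak in peaks:
            fold = peak.mark_folds.get(mark, 1.0)
            if fold == 1.0:
                continue
            apex = 2.0 * scale * (fold - 1.0)
            dist = np.abs(bin_centers - peak.center)
            tri = np.clip(1.0 - dist / hw, 0.0, None)
            values += apex * tri
    return CoverageTrack({contig: values}, bin_size=config.bin_size)


@dataclass(frozen=True)
class GeneRecord:
    """A simulated gene with a strand-aware transcription start site."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def generate_annotation(
    genome_length: int, n_genes: int, seed: int, contig: str = "chr1"
) -> list[GeneRecord]:
    """Place non-overlapping genes with unique ids, sorted by coordinate."""
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if n_genes == 0:
        return []
    n_slots = genome_length // _MIN_GENE_SPACING
    if n_genes > n_slots:
        raise ValueError(
            f"cannot place {n_genes} genes of spacing {_MIN_GENE_SPACING} "
            f"in a genome of {genome_length} bases"
        )
    rng = np.random.default_rng(seed)
    slots = np.sort(rng.choice(n_slots, size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    genes = []
    for i, (slot, strand) in enumerate(zip(slots, strands)):
        start = int(slot) * _MIN_GENE_SPACING
        genes.append(
            GeneRecord(
                gene_id=f"gene{i:04d}",
                contig=contig,
                start=start,
                end=start + _GENE_LENGTH,
                strand=str(strand),
            )
        )
    return genes


def generate_expression(
    annotation: list[GeneRecord],
    activated_genes: set[str],
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """FPKM-like two-condition expression table, activated genes shifted up.

    Control values are log-normal; treated values satisfy
    log2(treated + 1) − log2(control + 1) = effect·1[activated] + ε with
    ε ~ N(0, noise_sd), floored at zero expression.
    """
    known = {g.gene_id for g in annotation}
    unknown = set(activated_genes) - known
    if unknown:
        raise ValueError(f"activated gene(s) not in annotation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in annotation]
    control = rng.lognormal(mean=2.0, sigma=1.0, size=len(gene_ids))
    shift = np.array(
        [effect_size if g in activated_genes else 0.0 for g in gene_ids]
    )
    if noise_sd > 0:
        shift = shift + rng.normal(0.0, noise_sd, size=len(gene_ids))
    treated = np.maximum(np.exp2(np.log2(control + 1.0) + shift) - 1.0, 0.0)
    return pd.DataFrame(
        {"control": control, "treated": treated},
        index=pd.Index(gene_ids, name="gene"),
    )


@dataclass
class SimulatedDataset:
    """All artifacts of one simulated experiment, keyed for the pipeline."""

    config: SimConfig
    genome: dict[str, str]
    peaks: list[PlantedPeakSpec]
    coverage: dict[tuple[str, str], CoverageTrack]  # (mark, condition) -> track
    annotation: list[GeneRecord]
    expression: pd.DataFrame


def simulate_dataset(
    config: SimConfig,
    composition_class: CompositionClass = CompositionClass.NEUTRAL,
    intensity: float = 0.9,
    expression_effect: float = 1.0,
    expression_noise_sd: float = 0.3,
    contig: str = "chr1",
) -> SimulatedDataset:
    """Build a full experiment: genome, planted peaks, tracks, expression.

    Peaks are laid out evenly with non-overlapping flanks, each carrying the
    configured fold on H3K4me2 and H3K27ac but not H3K4me3 (the mark whose
    demethylation the inhibited enzyme cannot touch stays flat). Each peak
    targets its nearest gene; those genes are activated in the expression
    table.
    """
    genome = generate_genome(config.genome_length, config.gc_fraction, config.seed)
    annotation = generate_annotation(
        config.genome_length, config.n_genes, config.seed, contig=contig
    )
    tss = np.array([g.tss for g in annotation]) if annotation else np.array([])

    n_peaks = config.n_peaks_per_class
    hw = config.flank_half_width
    margin = 2 * hw + 1
    if n_peaks * 2 * margin > config.genome_length:
        raise ValueError("too many peaks for genome length")
    centers = np.linspace(margin, config.genome_length - margin, n_peaks, dtype=int)

    peaks = []
    for c in centers:
        target = None
        if len(tss):
            target = annotation[int(np.argmin(np.abs(tss - c)))].gene_id
        peaks.append(
            PlantedPeakSpec(
                center=int(c),
                composition_class=composition_class,
                mark_folds={
                    "H3K4me2": config.peak_fold,
                    "H3K4me3": 1.0,
                    "H3K27ac": config.peak_fold,
                },
                target_gene=target,
            )
        )
    for peak in peaks:
        genome = plant_composition(genome, peak, hw, intensity, config.seed)

    coverage = {
        (mark, condition): generate_coverage(
            config.genome_length, peaks, mark, condition, config, contig=contig
        )
        for mark in MARKS
        for condition in ("control", "treated")
    }
    activated = {p.target_gene for p in peaks if p.target_gene is not None}
    expression = generate_expression(
        annotation, activated, expression_effect, expression_noise_sd, config.seed
    )
    return SimulatedDataset(
        config=config,
        genome={contig: genome},
        peaks=peaks,
        coverage=coverage,
        annotation=annotation,
        expression=expression,
    )
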
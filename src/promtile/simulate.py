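"""Synthetic genomes, promoter annotations, and two-channel array scans.

Everything downstream of the scanner (normalization, smoothing, region
calling, set comparison, element scanning) is exercised end-to-end on data
with known ground truth: which promoters carry a binding site, where the
peak sits relative to the TSS, and which carry an embedded DR4 response
element. The generator emulates the structure of a two-condition
(control vs hormone-treated) promoter tiling ChIP experiment with duplicate
arrays per condition:

* random chromosomes carrying one 8 kb design window per gene;
* a fraction of genes bound in the treated condition, a (by default nested)
  subfraction already bound in the control condition — hormone treatment
  both recruits new sites and strengthens existing ones;
* per-probe two-channel intensities with a shared lognormal baseline,
  additive background (reported only as a noisy estimate, so subtraction is
  imperfect and over-subtraction can occur), a smooth monotone
  intensity-dependent dye bias on the ChIP channel (so loess correction is
  genuinely exercised), multiplicative channel noise, and a boxcar
  enrichment footprint of ``peak_halfwidth`` around each bound gene's peak;
* a small fraction of probes flagged low-quality.

All randomness flows through explicit seeds; identical configuration and
seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GeneModel, DEFAULT_UPSTREAM, DEFAULT_DOWNSTREAM
from .normalize import FLAG_OK, FLAG_LOW_QUALITY, MEASUREMENT_COLUMNS

# functional DR4 element reported for the PPM1B promoter; used as the
# default embedded response element
DEFAULT_TRE = "AGGTCATTTGAGGCCG"

TRUTH_COLUMNS = [
    "gene_id",
    "chrom",
    "tss",
    "strand",
    "bound_in_control",
    "bound_in_t3",
    "peak_offset",
    "peak_center_genomic",
    "tre_offset",
    "tre_seq",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the real design: duplicate arrays per condition, 8 kb
    windows, an enrichment footprint of +/- 700 bp (the scale of the 1400 bp
    smoothing window), a treated-condition enrichment of 8-fold over input
    with a weaker 4-fold control-condition signal, and multiplicative
    channel noise of 0.25 on the log2-ratio scale.
    """

    n_genes: int = 200
    genome_seed: int = 0
    frac_bound_control: float = 0.03
    frac_bound_t3: float = 0.10
    peak_halfwidth: int = 700
    enrichment_fold_control: float = 4.0
    enrichment_fold_t3: float = 8.0
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 0.8
    bg_mean: float = 100.0
    bg_sd: float = 20.0
    dyebias_amplitude: float = 0.8
    m_noise_sd: float = 0.25
    flag_fraction: float = 0.02
    n_replicates: int = 2
    tre_fraction: float = 1.0
    control_subset_of_t3: bool = True
    tre_sequence: str = DEFAULT_TRE
    upstream: int = DEFAULT_UPSTREAM
    downstream: int = DEFAULT_DOWNSTREAM
    genes_per_chrom: int = 25
    intergenic_gap: int = 1000

    def __post_init__(self) -> None:
        for name in ("frac_bound_control", "frac_bound_t3", "flag_fraction", "tre_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_bound_control > self.frac_bound_t3:
            raise ValueError(
                "frac_bound_control must be <= frac_bound_t3 (treatment recruits "
                "binding; control-bound genes are nearly all treated-bound)"
            )
        if self.enrichment_fold_control < 1 or self.enrichment_fold_t3 < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.peak_halfwidth <= 0:
            raise ValueError("peak_halfwidth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def window_length(self) -> int:
        return self.upstream + self.downstream


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Generate chromosomes, gene TSS anchors, and the truth manifest.

    Genes are laid out left to right, ``genes_per_chrom`` per chromosome,
    each owning a full design window separated by ``intergenic_gap`` bp so
    no window extends past a chromosome end. Bound genes are drawn without
    replacement at the configured fractions (treated-bound count =
    round(frac * n); control-bound genes are by default a subset of the
    treated-bound set). Each bound gene gets a peak center uniform within
    its window, margin ``peak_halfwidth`` from the edges; a configurable
    fraction of treated-bound genes has the DR4 element written into the
    genome at the peak center, on the gene's strand.
    """
    rng = np.random.default_rng(config.genome_seed)
    n = config.n_genes
    wlen = config.window_length
    tre = config.tre_sequence.upper()

    # gene layout
    genes: list[GeneModel] = []
    window_starts: dict[str, int] = {}
    chrom_lengths: dict[str, int] = {}
    for i in range(n):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        slot = i % config.genes_per_chrom
        ws = config.intergenic_gap + slot * (wlen + config.intergenic_gap)
        strand = "+" if rng.random() < 0.5 else "-"
        tss = ws + (config.upstream if strand == "+" else config.downstream)
        gene_id = f"g{i:04d}"
        genes.append(GeneModel(gene_id=gene_id, chrom=chrom, tss=tss, strand=strand))
        window_starts[gene_id] = ws
        chrom_lengths[chrom] = ws + wlen + config.intergenic_gap

    # rejected placements cannot occur with this deterministic layout, but a
    # window past the chromosome end is still a hard error
    for g in genes:
        ws = window_starts[g.gene_id]
        if ws < 0 or ws + wlen > chrom_lengths[g.chrom]:
            raise AssertionError(f"window for {g.gene_id} exceeds chromosome bounds")

    chromosomes = {
        chrom: list(_random_sequence(rng, length)) for chrom, length in chrom_lengths.items()
    }

    # ground-truth binding assignment
    n_t3 = round(config.frac_bound_t3 * n)
    n_ctrl = round(config.frac_bound_control * n)
    gene_ids = np.array([g.gene_id for g in genes])
    t3_bound = set(rng.choice(gene_ids, size=n_t3, replace=False))
    if config.control_subset_of_t3:
        pool = np.array(sorted(t3_bound))
        ctrl_bound = set(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False))
    else:
        ctrl_bound = set(rng.choice(gene_ids, size=n_ctrl, replace=False))

    n_tre = round(config.tre_fraction * n_t3)
    tre_genes = set(rng.choice(np.array(sorted(t3_bound)), size=n_tre, replace=False)) if n_tre else set()

    rows = []
    lo = -config.upstream + config.peak_halfwidth
    hi = config.downstream - config.peak_halfwidth - len(tre)
    for g in genes:
        in_t3 = g.gene_id in t3_bound
        in_ctrl = g.gene_id in ctrl_bound
        peak_offset = peak_genomic = tre_offset = None
        tre_seq = None
        if in_t3 or in_ctrl:
            peak_offset = int(rng.integers(lo, hi + 1))
            peak_genomic = (
                g.tss + peak_offset if g.strand == "+" else g.tss - peak_offset
            )
            if g.gene_id in tre_genes:
                tre_offset = peak_offset
                tre_seq = tre
                if g.strand == "+":
                    pos = g.tss + tre_offset
                    chromosomes[g.chrom][pos : pos + len(tre)] = list(tre)
                else:
                    # gene-strand offset maps to the reverse-complement on +
                    pos = g.tss - tre_offset - len(tre)
                    rc = tre.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                    chromosomes[g.chrom][pos : pos + len(tre)] = list(rc)
        rows.append(
            (
                g.gene_id,
                g.chrom,
                g.tss,
                g.strand,
                in_ctrl,
                in_t3,
                peak_offset,
                peak_genomic,
                tre_offset,
                tre_seq,
            )
        )

    sequences = {chrom: "".join(seq) for chrom, seq in chromosomes.items()}
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return sequences, genes, truth


def _dye_bias_log2(log2_intensity: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth monotone dye bias on the log2-ratio scale.

    Models Cy5 suppression at low intensities: the bias rises from
    ``-amplitude`` at low log2 intensity toward 0 at high intensity via a
    logistic ramp centered at log2 intensity 10 with width 1.5 — the classic
    banana shape of an uncorrected MA plot.
    """
    return -amplitude / (1.0 + np.exp((log2_intensity - 10.0) / 1.5))


def simulate_arrays(
    probes: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig,
    condition: str,
    replicate_seed: int,
) -> pd.DataFrame:
    """Simulate one two-channel scan of the probe set for one condition.

    Per probe: the Cy3 (input) foreground is a lognormal baseline plus
    additive background; the Cy5 (ChIP) foreground is the same baseline times
    the enrichment fold (when the probe center lies within
    ``peak_halfwidth`` of a bound gene's peak center, else 1), times the
    intensity-dependent dye-bias factor, times multiplicative lognormal
    noise, plus its own background. The reported background columns are
    noisy estimates drawn from the same background distribution, so
    subtraction downstream is imperfect. Deterministic given
    ``replicate_seed``.
    """
    if condition not in ("control", "t3"):
        raise ValueError(f"condition must be 'control' or 't3', got {condition!r}")
    missing = set(probes["gene_id"]) - set(truth["gene_id"])
    if missing:
        raise ValueError(f"probes reference genes absent from truth manifest: {sorted(missing)[:10]}")

    rng = np.random.default_rng(replicate_seed)
    n = len(probes)
    bound_col = "bound_in_control" if condition == "control" else "bound_in_t3"
    fold = (
        config.enrichment_fold_control if condition == "control" else config.enrichment_fold_t3
    )

    tinfo = truth.set_index("gene_id")
    centers = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
    gene_bound = tinfo.loc[probes["gene_id"], bound_col].to_numpy(dtype=bool)
    peak = tinfo.loc[probes["gene_id"], "peak_center_genomic"].to_numpy(dtype=float)
    in_footprint = gene_bound & (np.abs(centers - peak) <= config.peak_halfwidth)
    enrichment = np.where(in_footprint, fold, 1.0)

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    bias = 2.0 ** _dye_bias_log2(np.log2(baseline), config.dyebias_amplitude)
    noise = 2.0 ** rng.normal(0.0, config.m_noise_sd, size=n)

    bg3_true = np.clip(rng.normal(config.bg_mean, config.bg_sd, size=n), 0, None)
    bg5_true = np.clip(rng.normal(config.bg_mean, config.bg_sd, size=n), 0, None)
    bg3_est = np.clip(rng.normal(config.bg_mean, config.bg_sd, size=n), 0, None)
    bg5_est = np.clip(rng.normal(config.bg_mean, config.bg_sd, size=n), 0, None)

    cy3_fg = baseline + bg3_true
    cy5_fg = baseline * enrichment * bias * noise + bg5_true
    flags = np.where(rng.random(n) < config.flag_fraction, FLAG_LOW_QUALITY, FLAG_OK)

    out = pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "gene_id": probes["gene_id"].to_numpy(),
            "chrom": probes["chrom"].to_numpy(),
            "start": probes["start"].to_numpy(),
            "end": probes["end"].to_numpy(),
            "cy3_fg": cy3_fg,
            "cy3_bg": bg3_est,
            "cy5_fg": cy5_fg,
            "cy5_bg": bg5_est,
            "flag": flags,
        }
    )
    return out[MEASUREMENT_COLUMNS]


def simulate_experiment(
    config: SimulationConfig, seed: int | None = None
) -> dict:
    """Generate a full two-condition experiment with duplicate scans.

    Returns a dict with the genome, gene models, truth manifest, probe
    manifest (designed with package defaults including the uniqueness
    filter), and per-condition lists of replicate scans. ``seed`` overrides
    ``config.genome_seed`` when given; replicate seeds are derived from it.
    """
    from .design import design_probes

    if seed is not None:
        config = replace_seed(config, seed)
    genome, genes, truth = make_genome(config)
    probes = design_probes(
        genes, genome, upstream=config.upstream, downstream=config.downstream
    )
    scans = {}
    for cond_idx, condition in enumerate(("control", "t3")):
        scans[condition] = [
            simulate_arrays(
                probes,
                truth,
                config,
                condition,
                replicate_seed=(config.genome_seed * 1000 + cond_idx * 100 + r + 1) % (2**31),
            )
            for r in range(config.n_replicates)
        ]
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "probes": probes,
        "scans": scans,
    }


def replace_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    from dataclasses import replace

    return replace(config, genome_seed=seed)
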
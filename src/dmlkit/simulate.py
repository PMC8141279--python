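"""Synthetic methylome, peak, expression and motif data with known truth.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes: beta-binomially dispersed replicate counts,
hypomethylated loci clustered into regions (DMRs), a fully methylated spike-in
with a known conversion rate, accessibility peaks enriched near the true DML,
expression changes inversely coupled to methylation changes, and transcription
factor consensus sites planted near DML.  Every generator is a deterministic
function of the master seed via a named substream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from ._streams import substream
from .genome import GenomeModel
from .io import Methylome

__all__ = [
    "DMRSpec",
    "SimulationConfig",
    "simulate_methylomes",
    "simulate_spikein",
    "simulate_peaks_and_signal",
    "simulate_expression",
    "simulate_genes",
    "plant_motifs",
    "default_dmr_specs",
]


@dataclass
class DMRSpec:
    """A spiked differentially methylated region.

    ``baseline`` is the CD8-group mean methylation inside the region and
    ``delta`` the shift applied to the DN group; hypo regions have delta < 0.
    """

    chrom: str
    start: int  # bp, half-open, 0-based
    end: int
    direction: str  # "hypo" | "hyper"
    delta: float
    baseline: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"DMR {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must lie in [0, 1]")
        if not 0.0 <= self.baseline + self.delta <= 1.0:
            raise ValueError("baseline + delta must stay in [0, 1]")
        want = "hypo" if self.delta < 0 else "hyper"
        if self.delta != 0 and self.direction != want:
            raise ValueError(f"direction {self.direction!r} inconsistent with delta {self.delta}")


@dataclass
class SimulationConfig:
    """Parameters of the replicate count simulation.

    Defaults mirror the study design: 3 purifications per T cell subset, a
    bimodal genome-wide methylation landscape, overdispersed RRBS-like
    coverage, a hypo-dominated DMR mixture and a >99% spike-in conversion
    rate.
    """

    n_replicates: int = 3
    mean_coverage: float = 20.0
    coverage_nb_size: float = 5.0  # negative-binomial size; smaller = more overdispersed
    baseline_low_mode: float = 0.05
    baseline_high_mode: float = 0.95
    baseline_low_weight: float = 0.45
    baseline_concentration: float = 12.0  # Beta pseudo-count total per mixture component
    dispersion: float = 0.02  # beta-binomial phi
    dmr_fraction: float = 0.05  # fraction of CpGs inside DMRs
    hypo_fraction: float = 0.96  # hypo share of the DMR mixture
    spikein_conversion: float = 0.995
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_low_mode", "baseline_high_mode", "baseline_low_weight",
                     "dispersion", "dmr_fraction", "hypo_fraction", "spikein_conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicates < 1 or self.mean_coverage < 1:
            raise ValueError("need n_replicates >= 1 and mean_coverage >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_dmrs(genome: GenomeModel, dmr_specs: list[DMRSpec]) -> None:
    by_chrom: dict[str, list[DMRSpec]] = {}
    for d in dmr_specs:
        if d.chrom not in genome.chrom_lengths:
            raise ValueError(f"DMR on unknown chromosome {d.chrom}")
        if d.end > genome.chrom_lengths[d.chrom]:
            raise ValueError(f"DMR {d.chrom}:{d.start}-{d.end} exceeds chromosome bounds")
        by_chrom.setdefault(d.chrom, []).append(d)
    for chrom, specs in by_chrom.items():
        specs = sorted(specs, key=lambda d: d.start)
        for a, b in zip(specs, specs[1:]):
            if b.start < a.end and a.direction != b.direction:
                raise ValueError(
                    f"overlapping DMRs with conflicting direction at {chrom}:{b.start}")


def default_dmr_specs(
    genome: GenomeModel,
    config: SimulationConfig,
    n_dmrs: int | None = None,
    dmr_span_cpgs: int = 10,
    delta_magnitude: float = 0.5,
) -> list[DMRSpec]:
    """Place non-overlapping DMRs covering roughly ``dmr_fraction`` of CpGs.

    Each DMR spans ``dmr_span_cpgs`` consecutive CpGs; direction is drawn from
    the hypo:hyper mixture; baselines are chosen so the requested delta
    magnitude is feasible (high for hypo regions, low for hyper regions).
    """
    rng = substream(config.seed, "dmr-specs")
    specs: list[DMRSpec] = []
    for chrom in genome.chrom_names:
        pos = genome.cpg_positions[chrom]
        if len(pos) < dmr_span_cpgs:
            continue
        n_here = n_dmrs if n_dmrs is not None else max(
            1, int(round(config.dmr_fraction * len(pos) / dmr_span_cpgs)))
        # candidate anchor indices, spaced so regions cannot overlap
        stride = max(dmr_span_cpgs + 2, len(pos) // max(n_here, 1))
        anchors = np.arange(0, len(pos) - dmr_span_cpgs, stride)[:n_here]
        for a in anchors:
            hypo = rng.random() < config.hypo_fraction
            if hypo:
                baseline = rng.uniform(max(delta_magnitude, 0.7), 0.95)
                delta = -delta_magnitude
            else:
                baseline = rng.uniform(0.05, min(1 - delta_magnitude, 0.3))
                delta = delta_magnitude
            start = int(pos[a] - 1)
            end = int(pos[a + dmr_span_cpgs - 1])  # half-open; includes last CpG
            specs.append(DMRSpec(chrom, start, end, "hypo" if hypo else "hyper",
                                 float(delta), float(baseline)))
    return specs


def _betabinom_counts(rng, n, mu, phi):
    """Beta-binomial draw with mean n*mu and correlation phi; phi=0 is binomial."""
    mu = np.clip(mu, 0.0, 1.0)
    if phi <= 0:
        return rng.binomial(n, mu)
    a = mu * (1.0 - phi) / phi
    b = (1.0 - mu) * (1.0 - phi) / phi
    p = np.empty_like(mu)
    interior = (mu > 0) & (mu < 1)
    p[~interior] = mu[~interior]
    if interior.any():
        p[interior] = rng.beta(a[interior], b[interior])
    return rng.binomial(n, p)


def simulate_methylomes(
    genome: GenomeModel,
    dmr_specs: list[DMRSpec],
    config: SimulationConfig,
) -> tuple[list[Methylome], pd.DataFrame]:
    """Simulate replicate cytosine-report counts for groups CD8 and DN.

    Returns the per-sample methylomes plus a truth table of every CpG inside a
    DMR with its true methylation difference (DN - CD8).
    """
    _check_dmrs(genome, dmr_specs)
    rng = substream(config.seed, "methylomes")
    c = config.baseline_concentration

    chroms_all, pos_all, base_all, delta_all = [], [], [], []
    for chrom in genome.chrom_names:
        pos = genome.cpg_positions[chrom]
        n = len(pos)
        low = rng.random(n) < config.baseline_low_weight
        mode = np.where(low, config.baseline_low_mode, config.baseline_high_mode)
        baseline = rng.beta(mode * c + 1e-6, (1 - mode) * c + 1e-6)
        delta = np.zeros(n)
        for d in (s for s in dmr_specs if s.chrom == chrom):
            inside = (pos - 1 >= d.start) & (pos - 1 < d.end)
            baseline[inside] = d.baseline
            delta[inside] = d.delta
        chroms_all.append(np.repeat(chrom, n))
        pos_all.append(pos)
        base_all.append(baseline)
        delta_all.append(delta)

    chroms = np.concatenate(chroms_all)
    positions = np.concatenate(pos_all).astype(np.int64)
    baseline = np.concatenate(base_all)
    delta = np.concatenate(delta_all)
    n_cpg = len(positions)

    nb_p = config.coverage_nb_size / (config.coverage_nb_size + config.mean_coverage - 1.0)
    methylomes = []
    for group, mu in (("CD8", baseline), ("DN", np.clip(baseline + delta, 0, 1))):
        for r in range(1, config.n_replicates + 1):
            cov = 1 + rng.negative_binomial(config.coverage_nb_size, nb_p, size=n_cpg)
            meth = _betabinom_counts(rng, cov, mu, config.dispersion)
            df = pd.DataFrame({
                "chrom": chroms, "pos": positions, "strand": "+",
                "n_meth": meth.astype(np.int64), "n_total": cov.astype(np.int64),
            })
            methylomes.append(Methylome(f"{group}_{r}", group, df))

    spiked = delta != 0
    truth = pd.DataFrame({
        "chrom": chroms[spiked], "pos": positions[spiked],
        "true_delta": delta[spiked],
        "direction": np.where(delta[spiked] < 0, "hypo", "hyper"),
    }).reset_index(drop=True)
    return methylomes, truth


def simulate_spikein(n_sites: int, depth: int, conversion_rate: float, seed: int) -> pd.DataFrame:
    """Unmethylated-context spike-in cytosines: converted ~ Binomial(depth, rate)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 < conversion_rate <= 1.0:
        raise ValueError("conversion_rate must lie in (0, 1]")
    rng = substream(seed, "spikein")
    converted = rng.binomial(depth, conversion_rate, size=n_sites)
    return pd.DataFrame({
        "site": np.arange(1, n_sites + 1),
        "converted": converted.astype(np.int64),
        "total": np.full(n_sites, depth, dtype=np.int64),
    })


@dataclass
class PeakEnrichmentParams:
    """How effector peaks relate to true DML."""

    enrichment_fraction: float = 0.9  # fraction of truth DMLs given a nearby effector peak
    max_offset: int = 500  # peak placed so the DML lies within this many bp
    peak_length_mean: float = 300.0
    peak_length_sd: float = 80.0
    n_background: int = 100  # uniformly placed peaks per condition
    signal_bin: int = 50
    peak_signal: float = 6.0
    noise_signal: float = 1.0


def _random_peaks(rng, genome: GenomeModel, n: int, params: PeakEnrichmentParams) -> pd.DataFrame:
    lengths = np.maximum(20, rng.normal(params.peak_length_mean, params.peak_length_sd, n)).astype(int)
    chrom_lens = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    rows = []
    for length in lengths:
        ci = rng.choice(len(chrom_lens), p=probs)
        chrom = genome.chrom_names[ci]
        max_start = genome.chrom_lengths[chrom] - int(length)
        if max_start < 0:
            raise ValueError("peak longer than chromosome")
        start = int(rng.integers(0, max_start + 1))
        rows.append((chrom, start, start + int(length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_peaks_and_signal(
    genome: GenomeModel,
    dml_truth: pd.DataFrame,
    params: PeakEnrichmentParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate naive/effector peak sets and bedGraph signal tracks.

    Effector peaks are preferentially placed so that a fraction of the true
    DML fall within ``max_offset`` bp of a peak; naive peaks are uniform
    background.  Signal tracks are binned step functions elevated inside each
    condition's peaks.
    """
    params = params or PeakEnrichmentParams()
    rng = substream(seed, "peaks")
    total_capacity = genome.total_length() // max(int(params.peak_length_mean), 1)
    if params.n_background > total_capacity:
        raise ValueError("requested background peak count exceeds genome capacity")

    targeted = []
    if len(dml_truth):
        for row in dml_truth.itertuples(index=False):
            if rng.random() >= params.enrichment_fraction:
                continue
            length = max(20, int(rng.normal(params.peak_length_mean, params.peak_length_sd)))
            point = int(row.pos) - 1
            # place the peak so the DML is within max_offset of the interval
            offset = int(rng.integers(-params.max_offset, params.max_offset + 1))
            start = point + offset - length // 2
            chrom_len = genome.chrom_lengths[row.chrom]
            start = int(np.clip(start, 0, max(chrom_len - length, 0)))
            targeted.append((row.chrom, start, start + length))
    effector = pd.concat([
        pd.DataFrame(targeted, columns=["chrom", "start", "end"]),
        _random_peaks(rng, genome, params.n_background, params),
    ], ignore_index=True).sort_values(["chrom", "start"]).reset_index(drop=True)
    naive = _random_peaks(rng, genome, params.n_background, params)
    naive = naive.sort_values(["chrom", "start"]).reset_index(drop=True)

    def track(peaks: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for chrom in genome.chrom_names:
            length = genome.chrom_lengths[chrom]
            n_bins = length // params.signal_bin
            vals = np.abs(rng.normal(params.noise_signal, 0.2, n_bins))
            starts = np.arange(n_bins) * params.signal_bin
            sub = peaks[peaks["chrom"] == chrom]
            for pk in sub.itertuples(index=False):
                lo, hi = pk.start // params.signal_bin, -(-pk.end // params.signal_bin)
                vals[lo:min(hi, n_bins)] += np.abs(rng.normal(params.peak_signal, 1.0,
                                                              max(min(hi, n_bins) - lo, 0)))
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                      "end": starts + params.signal_bin, "value": vals}))
        return pd.concat(rows, ignore_index=True)

    return naive, effector, track(naive), track(effector)


def simulate_genes(genome: GenomeModel, n_genes: int, seed: int) -> pd.DataFrame:
    """Random gene TSS table (one TSS per gene id)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = substream(seed, "genes")
    chrom_lens = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    ci = rng.choice(len(chrom_lens), size=n_genes, p=probs)
    rows = []
    for i, c in enumerate(ci):
        chrom = genome.chrom_names[c]
        tss = int(rng.integers(1, genome.chrom_lengths[chrom] + 1))
        rows.append((f"gene{i + 1:04d}", chrom, tss, rng.choice(["+", "-"])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def simulate_expression(
    gene_table: pd.DataFrame,
    dml_truth: pd.DataFrame,
    coupling: float,
    seed: int,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene-level expression changes inversely coupled to hypomethylation.

    Genes whose TSS is the nearest to at least one hypo truth DML are
    upregulated with probability ``coupling``; all other genes draw from a
    zero-centred null.  The upregulated flag applies the stated thresholds.
    """
    if not len(gene_table):
        raise ValueError("empty gene table")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if gene_table["gene_id"].duplicated().any():
        raise ValueError("gene ids must be unique")
    from .annotate import nearest_tss

    rng = substream(seed, "expression")
    hypo = dml_truth[dml_truth["direction"] == "hypo"] if len(dml_truth) else dml_truth
    adjacent: set[str] = set()
    if len(hypo):
        ann = nearest_tss(hypo, gene_table)
        adjacent = set(ann["gene_id"].dropna())

    rows = []
    for row in gene_table.itertuples(index=False):
        coupled = row.gene_id in adjacent and rng.random() < coupling
        if coupled:
            lfc = float(lfc_threshold + 0.5 + rng.exponential(0.7))
            p = float(10 ** (-rng.uniform(3, 8)))
        else:
            lfc = float(rng.normal(0.0, 0.5))
            p = float(rng.uniform(0, 1))
        rows.append((row.gene_id, lfc, p, bool(p < p_threshold and lfc > lfc_threshold)))
    return pd.DataFrame(rows, columns=["gene_id", "log_fc", "pvalue", "upregulated"])


def plant_motifs(
    genome: GenomeModel,
    anchors: pd.DataFrame,  # columns chrom, pos (1-based points)
    consensus: str,
    planting_rate: float,
    seed: int,
    window: int = 200,
) -> tuple[GenomeModel, pd.DataFrame]:
    """Write a consensus motif near anchors, never over a catalogued CpG.

    With probability ``planting_rate`` per anchor the consensus is written at a
    uniform offset within ±window of the anchor.  Offsets whose footprint would
    overwrite a CpG position (or run off the chromosome) are re-drawn; anchors
    with no feasible offset are skipped and logged.
    """
    if genome.sequence is None:
        raise ValueError("genome carries no sequence")
    if not 0.0 <= planting_rate <= 1.0:
        raise ValueError("planting_rate must lie in [0, 1]")
    consensus = consensus.upper()
    rng = substream(seed, "motifs")
    seqs = {c: np.frombuffer(genome.sequence[c].encode(), dtype="S1").copy()
            for c in genome.chrom_names}
    log_rows = []
    k = len(consensus)
    cons_arr = np.frombuffer(consensus.encode(), dtype="S1")
    for row in anchors.itertuples(index=False):
        if rng.random() >= planting_rate:
            log_rows.append((row.chrom, int(row.pos), False, -1, "not selected"))
            continue
        chrom_len = genome.chrom_lengths[row.chrom]
        cpg = genome.cpg_positions[row.chrom]
        point = int(row.pos) - 1
        placed = False
        for _ in range(50):
            offset = int(rng.integers(-window, window - k + 1))
            start = point + offset
            if start < 0 or start + k > chrom_len:
                continue
            # footprint [start, start+k) must not touch a CpG dyad (pos-1, pos)
            lo = np.searchsorted(cpg - 1, start - 1, side="left")
            hi = np.searchsorted(cpg - 1, start + k, side="left")
            if np.any((cpg[lo:hi] - 1 >= start - 1) & (cpg[lo:hi] - 1 < start + k)):
                continue
            seqs[row.chrom][start : start + k] = cons_arr
            log_rows.append((row.chrom, int(row.pos), True, start, "planted"))
            placed = True
            break
        if not placed:
            log_rows.append((row.chrom, int(row.pos), False, -1, "no feasible offset"))
    new_seq = {c: seqs[c].tobytes().decode() for c in genome.chrom_names}
    planted = GenomeModel(genome.chrom_names, dict(genome.chrom_lengths),
                          {c: genome.cpg_positions[c].copy() for c in genome.chrom_names},
                          new_seq)
    planted.validate()
    log = pd.DataFrame(log_rows, columns=["chrom", "anchor_pos", "planted", "start", "note"])
    return planted, log
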
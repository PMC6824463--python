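"""Synthetic genome, replication, damage, growth and plasmid simulators.

Every downstream stage of the pipeline is testable against these generators,
which carry known ground truth.  The replication model is deliberately
minimal: in a hydroxyurea (HU) arrest all permitted origins fire at release
(t = 0) and forks travel a limited distance before stalling; in an
unperturbed S phase origins fire after an exponential delay and forks run
until the end of S phase.  The intra-S checkpoint enters as a single rule:
with the checkpoint intact, origins later than a T_rep cutoff fire with a
strongly suppressed probability.

Ground truth bookkeeping distinguishes *active* firing (the origin itself
initiated) from passive replication (an incoming fork covered the origin
before it fired) — a licensed origin replicated passively cannot fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicTrack, Origin, ValidationError
from .plasmid import CatenaneDistribution

__all__ = [
    "GenomeConfig",
    "GenomeModel",
    "SimulationCondition",
    "ReplicationState",
    "DamageGroundTruth",
    "build_genome",
    "simulate_cell_population",
    "sample_reads",
    "simulate_damage_tracks",
    "simulate_growth_curves",
    "simulate_plasmid_counts",
    "simulate_catenane_distribution",
]

# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

GENE_CONTEXTS = ("convergent", "codirectional", "divergent", "none")


@dataclass
class GenomeConfig:
    """Configuration for :func:`build_genome`.

    Defaults describe the small test genome used throughout the suite: one
    1-Mb chromosome, 1-kb bins, 40 origins every 25 kb with T_rep uniform on
    15–40 min, each origin flanked by a gene pair whose orientation class is
    drawn from ``context_fractions``.
    """

    chromosomes: Sequence[tuple[str, int]] = (("chrI", 1_000_000),)
    bin_size: int = 1000
    origin_spacing: int = 25_000
    origin_jitter: int = 5000   # bp; uniform jitter around the regular grid
    trep_range: tuple[float, float] = (15.0, 40.0)
    # fraction of origins whose flanking pair is convergent / codirectional /
    # divergent / absent; roughly the mix of a gene-dense yeast genome
    context_fractions: tuple[float, float, float, float] = (0.3, 0.3, 0.2, 0.2)
    gene_gap: int = 2000      # bp between origin and the near edge of a flanking gene
    gene_length: int = 4000   # bp per flanking gene
    seed: int = 0


@dataclass
class GenomeModel:
    """Genome with origins, genes and the construction-time orientation truth."""

    chromosomes: list[tuple[str, int]]
    bin_size: int
    origins: list[Origin]
    genes: list[GeneAnnotation]
    true_context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name}: length must be > 0")
        for ori in self.origins:
            if ori.chrom not in lengths:
                raise ValidationError(f"origin {ori.id}: unknown chromosome {ori.chrom!r}")
            if not 1 <= ori.pos <= lengths[ori.chrom]:
                raise ValidationError(
                    f"origin {ori.id}: position {ori.pos} outside {ori.chrom} "
                    f"(length {lengths[ori.chrom]})"
                )
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ValidationError(f"gene {gene.id}: unknown chromosome {gene.chrom!r}")
            if gene.end > lengths[gene.chrom] or gene.start < 1:
                raise ValidationError(
                    f"gene {gene.id}: [{gene.start},{gene.end}] outside {gene.chrom}"
                )

    def n_bins(self, chrom: str) -> int:
        length = dict(self.chromosomes)[chrom]
        return -(-length // self.bin_size)

    def empty_track(self, label: str = "") -> GenomicTrack:
        return GenomicTrack(
            self.bin_size,
            {name: np.zeros(self.n_bins(name)) for name, _ in self.chromosomes},
            label=label,
        )


def build_genome(config: GenomeConfig) -> GenomeModel:
    """Deterministically build a genome model from ``config``.

    Origins are placed on a regular grid (one per ``origin_spacing``); each
    receives a T_rep drawn uniformly from ``trep_range`` and a flanking gene
    pair whose orientation class is drawn from ``context_fractions``.
    """
    rng = np.random.default_rng(config.seed)
    fracs = np.asarray(config.context_fractions, dtype=float)
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ValidationError("context_fractions must be non-negative and sum to 1")

    origins: list[Origin] = []
    genes: list[GeneAnnotation] = []
    true_context: dict[str, str] = {}
    lo, hi = config.trep_range
    for chrom, length in config.chromosomes:
        grid = np.arange(config.origin_spacing // 2, length, config.origin_spacing)
        if config.origin_jitter > 0:
            jitter = rng.integers(-config.origin_jitter, config.origin_jitter + 1, len(grid))
        else:
            jitter = np.zeros(len(grid), dtype=int)
        positions = np.clip(grid + jitter, 1, length)
        for k, pos in enumerate(positions):
            oid = f"{chrom}-ori{k:03d}"
            t_rep = float(rng.uniform(lo, hi))
            origins.append(Origin(oid, chrom, int(pos), t_rep))
            context = rng.choice(GENE_CONTEXTS, p=fracs)
            true_context[oid] = context if context != "none" else "none"
            if context == "none":
                continue
            left_end = int(pos) - config.gene_gap
            left_start = left_end - config.gene_length + 1
            right_start = int(pos) + config.gene_gap
            right_end = right_start + config.gene_length - 1
            if left_start < 1 or right_end > length:
                true_context[oid] = "none"
                continue
            if context == "convergent":
                ls, rs = "+", "-"
            elif context == "divergent":
                ls, rs = "-", "+"
            else:  # codirectional
                ls = rs = rng.choice(["+", "-"])
            genes.append(GeneAnnotation(f"{oid}-L", chrom, left_start, left_end, ls))
            genes.append(GeneAnnotation(f"{oid}-R", chrom, right_start, right_end, rs))
    model = GenomeModel(list(config.chromosomes), config.bin_size, origins, genes, true_context)
    _check_gene_overlaps(model)
    return model


def _check_gene_overlaps(model: GenomeModel) -> None:
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in model.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.start)
        for a, b in zip(gs, gs[1:]):
            if b.start <= a.end:
                raise ValidationError(f"genes {a.id} and {b.id} overlap on {chrom}")


# ---------------------------------------------------------------------------
# replication simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationCondition:
    """Per-cell origin-firing regime.

    ``checkpoint_intact`` distinguishes wild type (late origins suppressed)
    from checkpoint-blind mutants in which Rad53 cannot inhibit initiation
    (origins fire regardless of T_rep).  In the HU regime permitted origins
    fire at release and forks stall after ``max_fork_travel`` bp; fork speed
    and travel are model defaults, not measured values.
    """

    regime: str = "HU"                      # HU | MMS | unperturbed
    checkpoint_intact: bool = True
    trep_cutoff_min: float = 27.5
    base_firing_prob: float = 0.9
    suppressed_firing_prob: float = 0.02
    fork_speed: float = 1500.0              # bp/min
    max_fork_travel: float = 10_000.0       # bp; finite fork travel under HU
    s_duration: float = 90.0                # minutes
    firing_delay_scale: float = 10.0        # min; exponential delay outside HU
    per_origin_firing_prob: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("base_firing_prob", "suppressed_firing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {p}")
        if self.max_fork_travel <= 0:
            raise ValidationError("max_fork_travel must be > 0")
        if self.regime not in ("HU", "MMS", "unperturbed"):
            raise ValidationError(f"unknown regime {self.regime!r}")

    def firing_prob(self, origin: Origin) -> float:
        if self.per_origin_firing_prob is not None:
            if origin.id in self.per_origin_firing_prob:
                return self.per_origin_firing_prob[origin.id]
        if not self.checkpoint_intact or origin.t_rep < self.trep_cutoff_min:
            return self.base_firing_prob
        return self.suppressed_firing_prob


@dataclass
class ReplicationState:
    """Population-level outcome of a replication simulation."""

    replicated_fraction: GenomicTrack
    n_cells: int
    true_fired_fraction: dict[str, float]
    per_cell_intervals: Optional[list[list[tuple[str, float, float]]]] = None

    def __post_init__(self) -> None:
        for chrom, arr in self.replicated_fraction:
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"replicated_fraction outside [0,1] on {chrom}")
        for oid, f in self.true_fired_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"true_fired_fraction[{oid}] outside [0,1]")


def simulate_cell_population(
    genome: GenomeModel,
    cond: SimulationCondition,
    n_cells: int,
    seed: int,
    keep_intervals: bool = False,
) -> ReplicationState:
    """Simulate origin firing and fork progression in ``n_cells`` cells.

    Per cell each origin draws a firing intention; intending origins are
    processed in firing-time order, and an origin whose position is already
    replicated by an incoming fork at its firing time is passively
    replicated (it does not count as actively fired).  An actively fired
    origin at x replicates [x-d, x+d] with
    d = min(fork_speed * (s_duration - delay), max_fork_travel).
    """
    if n_cells < 1:
        raise ValidationError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)

    chrom_origins: dict[str, list[Origin]] = {name: [] for name, _ in genome.chromosomes}
    for ori in genome.origins:
        chrom_origins[ori.chrom].append(ori)

    probs = {o.id: cond.firing_prob(o) for o in genome.origins}
    active_count = {o.id: 0 for o in genome.origins}
    counts = {name: np.zeros(genome.n_bins(name)) for name, _ in genome.chromosomes}
    all_intervals: Optional[list[list[tuple[str, float, float]]]] = [] if keep_intervals else None

    hu_like = cond.regime in ("HU", "MMS")
    for _ in range(n_cells):
        cell_intervals: list[tuple[str, float, float]] = []
        for chrom, length in genome.chromosomes:
            oris = chrom_origins[chrom]
            if not oris:
                continue
            intend = rng.random(len(oris)) < np.array([probs[o.id] for o in oris])
            if hu_like:
                delays = np.zeros(len(oris))
            else:
                delays = rng.exponential(cond.firing_delay_scale, len(oris))
            fired: list[tuple[float, float, float]] = []  # (delay, lo, hi) of active forks
            order = np.argsort(delays, kind="stable")
            for j in order:
                if not intend[j]:
                    continue
                ori = oris[j]
                x = float(ori.pos - 1)
                tau = float(delays[j])
                # passive replication: a fork launched earlier reaches x first
                passive = False
                for tau_k, lo_k, hi_k in fired:
                    reach = min(cond.fork_speed * (tau - tau_k), cond.max_fork_travel)
                    c = (lo_k + hi_k) / 2.0
                    if abs(x - c) <= reach:
                        passive = True
                        break
                if passive:
                    continue
                active_count[ori.id] += 1
                d = min(cond.fork_speed * max(cond.s_duration - tau, 0.0), cond.max_fork_travel)
                lo, hi = max(x - d, 0.0), min(x + d, float(length))
                fired.append((tau, lo, hi))
            n = genome.n_bins(chrom)
            if fired:
                diff = np.zeros(n + 1)
                for _, lo, hi in fired:
                    # a bin counts as replicated when its midpoint is covered
                    b0 = int(np.ceil((lo - genome.bin_size / 2.0) / genome.bin_size))
                    b1 = int(np.floor((hi - genome.bin_size / 2.0) / genome.bin_size))
                    b0, b1 = max(b0, 0), min(b1, n - 1)
                    if b1 >= b0:
                        diff[b0] += 1
                        diff[b1 + 1] -= 1
                    if keep_intervals:
                        cell_intervals.append((chrom, lo, hi))
                counts[chrom] += np.cumsum(diff[:-1]) > 0
        if keep_intervals:
            all_intervals.append(cell_intervals)

    frac = {c: counts[c] / n_cells for c in counts}
    track = GenomicTrack(genome.bin_size, frac, label="replicated_fraction")
    fired_frac = {oid: active_count[oid] / n_cells for oid in active_count}
    return ReplicationState(track, n_cells, fired_frac, all_intervals)


def sample_reads(
    state: ReplicationState, depth: float, seed: int
) -> tuple[GenomicTrack, GenomicTrack]:
    """Poisson read sampling: G1 ~ Pois(depth), S ~ Pois(depth * (1 + f))."""
    if depth <= 0:
        raise ValidationError(f"depth must be > 0, got {depth}")
    rng = np.random.default_rng(seed)
    g1, s = {}, {}
    for chrom, frac in state.replicated_fraction:
        g1[chrom] = rng.poisson(depth, len(frac)).astype(float)
        s[chrom] = rng.poisson(depth * (1.0 + frac)).astype(float)
    bs = state.replicated_fraction.bin_size
    return (
        GenomicTrack(bs, g1, label="G1 reads"),
        GenomicTrack(bs, s, label="S reads"),
    )


# ---------------------------------------------------------------------------
# damage (gamma-H2A-like) tracks
# ---------------------------------------------------------------------------


@dataclass
class DamageGroundTruth:
    """Generative parameters for the damage track.

    ``beta_convergent`` is the extra enrichment at origins flanked by a
    convergent gene pair; ``trep_slope`` makes that enrichment grow with the
    origin's T_rep (per minute above the earliest origin).
    """

    beta_convergent: float = 1.0
    trep_slope: float = 0.05
    noise_sd: float = 0.1
    base_level: float = 100.0
    window_bp: int = 2000
    noise_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_damage_tracks(
    state: ReplicationState,
    genome: GenomeModel,
    truth: DamageGroundTruth,
    seed: int,
) -> tuple[GenomicTrack, GenomicTrack]:
    """Simulate a damage-mark IP track and an unmodified-histone control.

    The IP signal is proportional to local replication, multiplied within
    ±window_bp of each convergent-context origin by
    1 + beta * (1 + slope * (t_rep - min t_rep)); the control is flat.  Both
    carry multiplicative lognormal noise; the IP additionally carries a small
    additive noise floor so unreplicated regions are noisy around zero rather
    than exactly zero.
    """
    rng = np.random.default_rng(seed)
    bs = genome.bin_size
    t_reps = [o.t_rep for o in genome.origins]
    t_min = min(t_reps) if t_reps else 0.0

    enh = {name: np.ones(genome.n_bins(name)) for name, _ in genome.chromosomes}
    for ori in genome.origins:
        if genome.true_context.get(ori.id) != "convergent":
            continue
        factor = 1.0 + truth.beta_convergent * (
            1.0 + truth.trep_slope * (ori.t_rep - t_min)
        )
        n = genome.n_bins(ori.chrom)
        b0 = max((ori.pos - 1 - truth.window_bp) // bs, 0)
        b1 = min((ori.pos - 1 + truth.window_bp) // bs, n - 1)
        enh[ori.chrom][b0 : b1 + 1] = factor

    mu = -0.5 * truth.noise_sd**2  # lognormal with unit mean
    ip, control = {}, {}
    for chrom, frac in state.replicated_fraction:
        n = len(frac)
        ip_noise = rng.lognormal(mu, truth.noise_sd, n) if truth.noise_sd > 0 else np.ones(n)
        ct_noise = rng.lognormal(mu, truth.noise_sd, n) if truth.noise_sd > 0 else np.ones(n)
        floor = np.abs(rng.normal(0.0, truth.noise_floor, n)) if truth.noise_floor > 0 else 0.0
        ip[chrom] = truth.base_level * frac * enh[chrom] * ip_noise + floor
        control[chrom] = truth.base_level * ct_noise
    return (
        GenomicTrack(bs, ip, label="damage IP"),
        GenomicTrack(bs, control, label="histone control"),
    )


# ---------------------------------------------------------------------------
# growth curves (QFA input)
# ---------------------------------------------------------------------------

#: logistic-curve constants for simulated colonies; densities are normalized
#: integrated optical density, inoculum is K/2^7 so MDP = 7 doublings.
_GROWTH_K = 1.0
_GROWTH_G0 = _GROWTH_K / 2**7
_GROWTH_MDP = 7.0
_BASE_RATE = 4.0  # 1/day for a strain of relative fitness 1


def _fitness_to_rate(f_abs: float) -> float:
    """Invert F = MDP * (r/ln2) * (1 - g0/K) for r."""
    return max(f_abs * np.log(2) / (_GROWTH_MDP * (1.0 - _GROWTH_G0 / _GROWTH_K)), 0.0)


def logistic_density(t: np.ndarray, K: float, r: float, g0: float) -> np.ndarray:
    """Closed-form logistic growth g(t) = K g0 e^{rt} / (K + g0 (e^{rt} - 1))."""
    ert = np.exp(r * np.asarray(t, dtype=float))
    return K * g0 * ert / (K + g0 * (ert - 1.0))


def simulate_growth_curves(
    strains: Sequence[tuple[str, str, float]],
    reps: int = 4,
    timepoints: Optional[Sequence[float]] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    gene_fitness_sd: float = 0.1,
    a_true: float = 0.1,
    b_true: float = 0.85,
    density_noise_sd: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate colony-density time series for a control/query strain panel.

    ``strains`` lists (gene, background, gamma) with background in
    {control, query}; gamma is the injected genetic interaction on the
    *relative* fitness scale (units of the fitness of an average control
    strain).  Per-gene control fitness is N(1, gene_fitness_sd); a query
    strain's expected fitness is a_true + b_true * F_control + gamma.  Each
    replicate's target fitness carries lognormal noise of sd ``noise_sd``
    before conversion to a growth rate; measured densities carry additional
    lognormal noise of sd ``density_noise_sd``.

    Returns (curves, truth): curves in long format (strain, gene, background,
    replicate, time_days, density); truth has one row per gene with the
    injected gamma and relative fitness values plus the absolute fitness
    scale used.
    """
    if timepoints is None:
        timepoints = np.arange(0.0, 5.0 + 1e-9, 4.0 / 24.0)  # every 4 h over 5 d
    timepoints = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(timepoints) <= 0):
        raise ValidationError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)

    fitness_scale = _GROWTH_MDP * (_BASE_RATE / np.log(2)) * (1.0 - _GROWTH_G0 / _GROWTH_K)
    genes = list(dict.fromkeys(g for g, _, _ in strains))
    f_control_rel = {g: float(rng.normal(1.0, gene_fitness_sd)) for g in genes}
    gamma_by_gene = {g: 0.0 for g in genes}
    for gene, background, gamma in strains:
        if background == "query" and gamma:
            gamma_by_gene[gene] = gamma

    rows = []
    for gene, background, gamma in strains:
        if background not in ("control", "query"):
            raise ValidationError(f"unknown background {background!r} for {gene}")
        if background == "control":
            f_rel = f_control_rel[gene]
        else:
            f_rel = a_true + b_true * f_control_rel[gene] + gamma
        f_rel = max(f_rel, 0.0)
        for rep in range(1, reps + 1):
            f_ij = f_rel * float(rng.lognormal(-0.5 * noise_sd**2, noise_sd)) if noise_sd > 0 else f_rel
            r_ij = _fitness_to_rate(f_ij * fitness_scale)
            dens = logistic_density(timepoints, _GROWTH_K, r_ij, _GROWTH_G0)
            if density_noise_sd > 0:
                dens = dens * rng.lognormal(
                    -0.5 * density_noise_sd**2, density_noise_sd, len(dens)
                )
            for t, d in zip(timepoints, dens):
                rows.append(
                    (f"{gene}:{background}", gene, background, rep, float(t), float(d))
                )
    curves = pd.DataFrame(
        rows, columns=["strain", "gene", "background", "replicate", "time_days", "density"]
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "gamma": [gamma_by_gene[g] for g in genes],
            "f_control_rel": [f_control_rel[g] for g in genes],
            "f_query_rel": [
                max(a_true + b_true * f_control_rel[g] + gamma_by_gene[g], 0.0) for g in genes
            ],
            "a_true": a_true,
            "b_true": b_true,
            "fitness_scale": fitness_scale,
        }
    )
    return curves, truth


# ---------------------------------------------------------------------------
# plasmid loss and catenanes
# ---------------------------------------------------------------------------


def simulate_plasmid_counts(
    true_loss_rate_pct: float, G: float, n_colonies: int, seed: int
) -> tuple[int, int]:
    """Simulate a plasmid-loss assay with a known per-generation loss rate.

    After G generations of nonselective growth the expected ratio of plasmid
    maintenance is RMP = (1 - rate/100)^G; colonies retaining the plasmid are
    Binomial(n_colonies, RMP).  Returns (n_selective, n_nonselective).
    """
    if not 0.0 <= true_loss_rate_pct <= 100.0:
        raise ValidationError("true_loss_rate_pct must be in [0,100]")
    if G <= 0:
        raise ValidationError("G must be > 0")
    rng = np.random.default_rng(seed)
    rmp = (1.0 - true_loss_rate_pct / 100.0) ** G
    n_sel = int(rng.binomial(n_colonies, rmp))
    return n_sel, n_colonies


def simulate_catenane_distribution(
    mean_cat: float,
    spread: float,
    n_max: int = 20,
    seed: int = 0,
    jitter_sd: float = 0.05,
) -> CatenaneDistribution:
    """Discretized positive distribution over catenane numbers 1..n_max.

    Weights follow a normal density at integers, renormalized; spread -> 0
    collapses to a point mass at round(mean_cat).  ``jitter_sd`` adds
    multiplicative lognormal noise emulating band-intensity measurement.
    """
    if n_max < 1:
        raise ValidationError("n_max must be >= 1")
    ns = np.arange(1, n_max + 1)
    if spread <= 1e-9:
        w = (ns == int(np.clip(round(mean_cat), 1, n_max))).astype(float)
    else:
        w = np.exp(-0.5 * ((ns - mean_cat) / spread) ** 2)
        if jitter_sd > 0:
            rng = np.random.default_rng(seed)
            w = w * rng.lognormal(-0.5 * jitter_sd**2, jitter_sd, n_max)
    return CatenaneDistribution(dict(zip(ns.tolist(), w.tolist())))
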
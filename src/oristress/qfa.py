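"""Quantitative fitness analysis (QFA) and genetic-interaction scoring.

Each strain's colony-density time series is fit with the logistic growth
solution g(t) = K g0 e^{rt} / (K + g0 (e^{rt} - 1)).  Fitness combines the
maximum doubling potential MDP = log2(K / g0) (total population doublings)
with the maximum doubling rate MDR = (r / ln 2)(1 - g0 / K) (the logistic
curve's largest instantaneous doubling rate, in doublings/day):
F = MDP * MDR, averaged over replicates.

Genetic interaction strength (GIS) compares each gene's fitness in the
query background with the prediction of a robust population model fitted
across all genes: gis = F_query - (a + b * F_control).  Significance uses a
Welch-type test that propagates replicate noise from *both* backgrounds
(the prediction inherits the control mean's sampling error scaled by the
slope), with Benjamini-Hochberg correction across genes.  Hits are the
significant genes in the top quartile of |GIS|, split by sign into
enhancers (gis < 0) and suppressors (gis > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.robust.norms import HuberT
from statsmodels.robust.robust_linear_model import RLM
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "GrowthCurve",
    "LogisticFit",
    "FitnessRecord",
    "GISRecord",
    "ComplexCatalog",
    "PopulationModel",
    "fit_growth_curve",
    "compute_fitness",
    "fitness_table",
    "aggregate_fitness",
    "population_model",
    "compute_gis",
    "classify_hits",
    "complex_enrichment",
    "cross_screen_compare",
]

LN2 = float(np.log(2.0))


@dataclass
class GrowthCurve:
    strain: str
    gene: str
    background: str        # control | query
    replicate: int
    timepoints: np.ndarray  # days
    densities: np.ndarray   # integrated optical density units
    damp: bool = False      # DAmP allele metadata flag; no special statistics

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.timepoints) != len(self.densities):
            raise ValidationError(f"{self.strain}: timepoint/density length mismatch")
        if len(self.timepoints) < 4:
            raise ValidationError(f"{self.strain}: need >= 4 timepoints")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValidationError(f"{self.strain}: timepoints must be strictly increasing")
        if np.any(self.densities <= 0):
            raise ValidationError(f"{self.strain}: densities must be positive")


@dataclass
class LogisticFit:
    K: float
    r: float
    g0: float
    converged: bool
    rss: float


def _logistic(t: np.ndarray, K: float, r: float, g0: float) -> np.ndarray:
    # K / (1 + (K/g0 - 1) e^{-rt}) is overflow-safe for r > 0, t >= 0;
    # K < g0 (explored transiently by the optimizer) can zero the denominator
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return K / (1.0 + (K / g0 - 1.0) * np.exp(np.clip(-r * t, None, 500.0)))


def fit_growth_curve(curve: GrowthCurve) -> LogisticFit:
    """Least-squares logistic fit with multi-start initialization.

    Starts from (g0 = first density, K = max density, r = early log-linear
    slope) plus perturbed variants; parameters are fit on the log scale to
    keep them positive.  Failure to converge, or a fit with K <= g0 or
    r <= 0, returns converged=False rather than raising.
    """
    t, g = curve.timepoints, curve.densities
    g0_init = float(g[0])
    K_init = float(g.max())
    # early log-linear slope; guard degenerate flat curves
    k = max(min(4, len(t) - 1), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.polyfit(t[: k + 1], np.log(g[: k + 1]), 1)[0]
    r_init = float(slope) if np.isfinite(slope) and slope > 0 else 1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        # bounded log-parameters keep the optimizer away from overflow
        K, r, g0 = np.exp(np.clip(theta, -50.0, 50.0))
        res = _logistic(t, K, r, g0) - g
        return np.nan_to_num(res, nan=1e6, posinf=1e6, neginf=-1e6)

    best: Optional[tuple[float, np.ndarray]] = None
    starts = [
        (K_init, r_init, g0_init),
        (K_init * 1.5, max(r_init, 0.5) * 2.0, g0_init * 0.5),
        (K_init, 0.5, g0_init),
    ]
    for K0, r0, gg0 in starts:
        theta0 = np.log(np.maximum([K0, r0, gg0], 1e-12))
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return LogisticFit(np.nan, np.nan, np.nan, False, np.inf)
    rss, theta = best
    K, r, g0 = (float(v) for v in np.exp(np.clip(theta, -50.0, 50.0)))
    # no-growth detection: the curve never rises meaningfully above g0
    grew = g.max() > g0_init * 1.05
    converged = bool(np.isfinite(rss) and K > g0 and r > 1e-6 and grew)
    return LogisticFit(K, r, g0, converged, rss)


def compute_fitness(fit: LogisticFit) -> tuple[float, float, float]:
    """(MDP, MDR, F) from a logistic fit; an unconverged (dead) fit scores 0.

    MDP = log2(K/g0); MDR = (r/ln2)(1 - g0/K); F = MDP * MDR.
    """
    if not fit.converged:
        return 0.0, 0.0, 0.0
    mdp = float(np.log2(fit.K / fit.g0))
    mdr = float((fit.r / LN2) * (1.0 - fit.g0 / fit.K))
    return mdp, mdr, mdp * mdr


@dataclass
class FitnessRecord:
    gene: str
    background: str
    replicate_F: list[float]
    mean_F: float = field(init=False)
    sd_F: float = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.replicate_F, dtype=float)
        if np.any(arr < 0):
            raise ValidationError(f"{self.gene}/{self.background}: F must be >= 0")
        self.mean_F = float(arr.mean())
        self.sd_F = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def fitness_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every (strain, replicate) curve in a long-format table.

    Expects columns strain, gene, background, replicate, time_days, density.
    Returns one row per curve with the fit parameters and MDP/MDR/F.
    """
    required = {"strain", "gene", "background", "replicate", "time_days", "density"}
    missing = required - set(curves.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)}")
    rows = []
    for (strain, gene, background, rep), sub in curves.groupby(
        ["strain", "gene", "background", "replicate"], sort=True
    ):
        sub = sub.sort_values("time_days")
        gc = GrowthCurve(strain, gene, background, int(rep),
                         sub["time_days"].to_numpy(), sub["density"].to_numpy())
        fit = fit_growth_curve(gc)
        mdp, mdr, f = compute_fitness(fit)
        rows.append(
            {
                "strain": strain, "gene": gene, "background": background,
                "replicate": int(rep), "K": fit.K, "r": fit.r, "g0": fit.g0,
                "converged": fit.converged, "MDP": mdp, "MDR": mdr, "F": f,
            }
        )
    return pd.DataFrame(rows)


def aggregate_fitness(fits: pd.DataFrame, min_reps: int = 2) -> list[FitnessRecord]:
    """Mean replicate fitness per gene and background.

    Genes missing either background (or with fewer than ``min_reps``
    replicates in one) are excluded with a warning.
    """
    records: dict[tuple[str, str], FitnessRecord] = {}
    for (gene, background), sub in fits.groupby(["gene", "background"], sort=True):
        fs = sub["F"].to_numpy(dtype=float)
        if len(fs) < min_reps:
            warnings.warn(f"{gene}/{background}: only {len(fs)} replicates; excluded")
            continue
        records[(gene, background)] = FitnessRecord(gene, background, fs.tolist())
    genes = {g for g, _ in records}
    out = []
    for gene in sorted(genes):
        if (gene, "control") in records and (gene, "query") in records:
            out.append(records[(gene, "control")])
            out.append(records[(gene, "query")])
        else:
            warnings.warn(f"{gene}: missing one background; excluded from screen")
    return out


@dataclass
class PopulationModel:
    """Robust 'line of equal growth': F_query ~ a + b * F_control."""

    intercept: float
    slope: float
    r_squared: float
    weights: np.ndarray
    n_genes: int


def population_model(records: Sequence[FitnessRecord], min_genes: int = 20) -> PopulationModel:
    """Huber-weighted robust regression of query on control mean fitness.

    Robust weighting keeps genuine interactions (outliers) from dragging the
    population line; the line summarizes how the typical gene deletion grows
    in the query background.
    """
    ctrl = {r.gene: r.mean_F for r in records if r.background == "control"}
    query = {r.gene: r.mean_F for r in records if r.background == "query"}
    genes = sorted(set(ctrl) & set(query))
    if len(genes) < min_genes:
        raise ValidationError(f"need >= {min_genes} genes with both backgrounds, got {len(genes)}")
    x = np.array([ctrl[g] for g in genes])
    y = np.array([query[g] for g in genes])
    if np.std(x) < 1e-12:
        raise ValidationError("degenerate variance in control fitness")
    X = np.column_stack([np.ones_like(x), x])
    with warnings.catch_warnings():
        # a perfect fit legitimately estimates zero residual scale
        warnings.simplefilter("ignore")
        fit = RLM(y, X, M=HuberT()).fit()
    try:
        weights = np.asarray(fit.weights, dtype=float)
    except AttributeError:
        # zero-scale perfect fits skip IRLS reweighting entirely
        weights = np.ones_like(y)
    pred = fit.predict(X)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PopulationModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        r_squared=r2,
        weights=weights,
        n_genes=len(genes),
    )


@dataclass
class GISRecord:
    gene: str
    F_control: float
    F_query: float
    predicted_F_query: float
    gis: float
    p: float
    q: float = float("nan")
    hit_class: str = "neutral"


def compute_gis(
    records: Sequence[FitnessRecord],
    model: PopulationModel,
) -> list[GISRecord]:
    """Per-gene genetic interaction strength with significance.

    gis = mean F_query - (a + b * mean F_control).  The null "no
    interaction" is tested with a Welch-type statistic whose variance sums
    the query replicate error and the control replicate error propagated
    through the population line (b^2 * var(mean F_control)); degrees of
    freedom by Welch-Satterthwaite.  q-values by Benjamini-Hochberg across
    all testable genes.  Genes with < 2 query replicates get a missing p
    and are excluded from hit calling.
    """
    ctrl = {r.gene: r for r in records if r.background == "control"}
    query = {r.gene: r for r in records if r.background == "query"}
    genes = sorted(set(ctrl) & set(query))
    out: list[GISRecord] = []
    for gene in genes:
        rc, rq = ctrl[gene], query[gene]
        pred = model.intercept + model.slope * rc.mean_F
        gis = rq.mean_F - pred
        nq, nc = len(rq.replicate_F), len(rc.replicate_F)
        if nq < 2 or nc < 2:
            out.append(GISRecord(gene, rc.mean_F, rq.mean_F, pred, gis, float("nan")))
            continue
        vq = rq.sd_F**2 / nq
        vc = (model.slope**2) * rc.sd_F**2 / nc
        se = float(np.sqrt(vq + vc))
        if se == 0.0:
            p = 1.0 if gis == 0.0 else 0.0
        else:
            df = (vq + vc) ** 2 / (
                (vq**2 / (nq - 1) if vq > 0 else 0.0)
                + (vc**2 / (nc - 1) if vc > 0 else 0.0)
            )
            tstat = gis / se
            p = float(2.0 * stats.t.sf(abs(tstat), df))
        out.append(GISRecord(gene, rc.mean_F, rq.mean_F, pred, gis, p))
    tested = [r for r in out if np.isfinite(r.p)]
    if tested:
        _, qvals, _, _ = multipletests([r.p for r in tested], method="fdr_bh")
        for r, q in zip(tested, qvals):
            r.q = float(q)
    return out


def classify_hits(
    gis_records: Sequence[GISRecord],
    top_fraction: float = 0.25,
    q_max: float = 0.05,
) -> tuple[list[GISRecord], list[GISRecord]]:
    """Enhancers and suppressors: significant genes in the top |GIS| quartile.

    A gene is a hit when q < ``q_max`` AND its |gis| reaches the
    (1 - top_fraction) quantile of |gis| over all scored genes (ties at the
    boundary included).  Enhancers have gis < 0, suppressors gis > 0;
    ``hit_class`` is set in place on the records.
    """
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    scored = [r for r in gis_records if np.isfinite(r.q)]
    if not scored:
        return [], []
    abs_gis = np.abs([r.gis for r in scored])
    cutoff = float(np.quantile(abs_gis, 1.0 - top_fraction))
    enhancers, suppressors = [], []
    for r in scored:
        if r.q < q_max and abs(r.gis) >= cutoff:
            if r.gis < 0:
                r.hit_class = "enhancer"
                enhancers.append(r)
            elif r.gis > 0:
                r.hit_class = "suppressor"
                suppressors.append(r)
    enhancers.sort(key=lambda r: r.gis)
    suppressors.sort(key=lambda r: -r.gis)
    return enhancers, suppressors


@dataclass
class ComplexCatalog:
    """Protein-complex membership: complex name -> gene set (cyc2008-style)."""

    complexes: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise ValidationError(f"complex {name!r} has no members")

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ComplexCatalog":
        """Build from a two-column (gene, complex) table."""
        if not {"gene", "complex"} <= set(table.columns):
            raise ValidationError("catalog table needs columns gene, complex")
        cx: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            cx.setdefault(str(row["complex"]), set()).add(str(row["gene"]))
        return cls(cx)


def complex_enrichment(
    hits: set[str],
    universe: set[str],
    catalog: ComplexCatalog,
    min_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each complex among the hits.

    Complexes are restricted to the screened universe; those with fewer than
    ``min_size`` members in the universe are skipped.  p is the upper tail
    P(X >= overlap) of Hypergeom(N=|universe|, K=|complex|, n=|hits|);
    q by Benjamini-Hochberg over the tested complexes.
    """
    if not universe:
        raise ValidationError("empty universe")
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    rows = []
    for name, members in sorted(catalog.complexes.items()):
        in_universe = members & universe
        if len(in_universe) < min_size:
            continue
        overlap = len(in_universe & hits)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(in_universe), len(hits))
        )
        rows.append(
            {
                "complex": name,
                "complex_size": len(in_universe),
                "n_hits": overlap,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        _, q, _, _ = multipletests(df["p"], method="fdr_bh")
        df["q"] = q
        df = df.sort_values(["q", "p"]).reset_index(drop=True)
    return df


def cross_screen_compare(
    gis_a: Sequence[GISRecord],
    gis_b: Sequence[GISRecord],
    min_shared: int = 20,
) -> dict:
    """Compare GIS between two screens over their shared genes.

    Returns the paired table, Spearman correlation, and overlap counts plus
    Jaccard indices of the enhancer and suppressor sets.
    """
    a = {r.gene: r for r in gis_a}
    b = {r.gene: r for r in gis_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValidationError("no shared genes between screens")
    if len(shared) < min_shared:
        raise ValidationError(f"need >= {min_shared} shared genes, got {len(shared)}")
    table = pd.DataFrame(
        {
            "gene": shared,
            "gis_a": [a[g].gis for g in shared],
            "gis_b": [b[g].gis for g in shared],
            "hit_class_a": [a[g].hit_class for g in shared],
            "hit_class_b": [b[g].hit_class for g in shared],
        }
    )
    rho, rho_p = stats.spearmanr(table["gis_a"], table["gis_b"])

    def jaccard(klass: str) -> tuple[int, int, int, float]:
        sa = {g for g in shared if a[g].hit_class == klass}
        sb = {g for g in shared if b[g].hit_class == klass}
        inter, union = len(sa & sb), len(sa | sb)
        return len(sa), len(sb), inter, (inter / union if union else float("nan"))

    na, nb, ni, je = jaccard("enhancer")
    ma, mb, mi, js = jaccard("suppressor")
    return {
        "table": table,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "enhancers": {"n_a": na, "n_b": nb, "overlap": ni, "jaccard": je},
        "suppressors": {"n_a": ma, "n_b": mb, "overlap": mi, "jaccard": js},
    }
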
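"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here: spatial spot
counts with immune/stromal/malignant marker programmes, a Y-shaped
branching trajectory, a survival cohort with subtype-linked hazards,
cell-line expression with subtype-shifted drug sensitivities, and
genome-wide peak tracks with locally enriched segments.  The generators
emulate the statistical structure of the usual public inputs (Visium
spot counts, TCGA-style bulk cohorts with follow-up, GDSC-style drug
panels, ATAC peak tracks) so that every downstream stage can be tested
against a known truth without any download.

Counts are negative-binomial with a shared dispersion on log-normal
latent means; survival is exponential with independent exponential
censoring whose rate is solved numerically to hit a target censoring
fraction.  All randomness flows from one root seed through named
substreams, so adding a generator never perturbs another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix, PeakSet, SurvivalTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "DEFAULT_MARKER_PANELS",
    "simulate_spatial",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_cell_lines",
    "simulate_peaks",
]

# Spot-type marker panels used for annotation (canonical surface markers:
# stromal CD44/FTL/LGALS1, malignant ALDH18A1/CD24/MIR205HG, immune
# HLA-DRA/HLA-DRB1/HSPE1).
DEFAULT_MARKER_PANELS: dict[str, list[str]] = {
    "stromal": ["CD44", "FTL", "LGALS1"],
    "malignant": ["ALDH18A1", "CD24", "MIR205HG"],
    "immune": ["HLA-DRA", "HLA-DRB1", "HSPE1"],
}

# Fixed substream indices: adding a generator appends a name, never renumbers.
_SUBSTREAMS = {
    "spatial": 0,
    "trajectory": 1,
    "cohort": 2,
    "cell_lines": 3,
    "peaks": 4,
}


def _default_chrom_sizes() -> dict[str, int]:
    # 23 nuclear chromosomes (1..22, X) with decreasing desk-scale lengths.
    names = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
    return {name: 1_000_000 - 30_000 * i for i, name in enumerate(names)}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators.

    ``effect_size`` is the centroid separation in units of the
    within-cluster standard deviation (log scale); ``censor_target`` the
    desired fraction of censored samples; ``nb_dispersion`` the shared
    negative-binomial size parameter (``inf`` gives the Poisson limit).
    """

    seed: int = 0
    n_genes: int = 200
    n_spots: int = 600
    n_samples: int = 400
    n_cell_lines: int = 45
    n_drugs: int = 40
    n_subtypes: int = 4
    nb_dispersion: float = 2.0
    effect_size: float = 2.0
    censor_target: float = 0.3
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_background_peaks: int = 5000
    enrichment_fold: float = 5.0
    # secondary knobs
    spot_type_props: dict[str, float] = field(
        default_factory=lambda: {"immune": 0.2, "stromal": 0.3, "malignant": 0.5}
    )
    marker_panels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()}
    )
    base_log_mean: float = math.log(5.0)
    base_log_sd: float = 0.5
    n_informative: int = 10
    hazard_beta: float = 0.5
    informative_betas: list[float] | None = None  # overrides the shared beta
    subtype_loghr: list[float] | None = None
    baseline_median_time: float = 5.0
    metastasis_frac: float = 0.0
    metastasis_shift: float = 1.0
    line_noise_sd: float = 0.5
    drug_shift: float = 2.0
    program_genes_per_type: int = 20
    branch_time: float = 0.5
    module_amplitude: float = 2.0
    peak_width: int = 500
    n_locus_genes: int = 15
    n_segments: int = 92

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_spots": self.n_spots,
            "n_samples": self.n_samples,
            "n_cell_lines": self.n_cell_lines,
            "n_drugs": self.n_drugs,
            "n_subtypes": self.n_subtypes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not 0.0 <= self.censor_target <= 1.0:
            raise ValueError("censor_target must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[stream],))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted truth accompanying each generated artefact."""

    spot_type: pd.Series | None = None
    pseudotime: pd.Series | None = None
    branch: pd.Series | None = None
    sample_subtype: pd.Series | None = None
    cell_line_subtype: pd.Series | None = None
    informative_genes: dict[str, float] | None = None
    drug_map: dict[str, str] | None = None
    enriched_segments: list[tuple[str, int]] | None = None
    gene_modules: dict[str, list[str]] | None = None
    marker_panels: dict[str, list[str]] | None = None
    direction: str | None = None


def _gene_names(n: int, reserved: list[str] | None = None) -> list[str]:
    reserved = list(reserved or [])
    if len(reserved) > n:
        raise ValueError(
            f"n_genes={n} smaller than the {len(reserved)} reserved marker genes"
        )
    filler = [f"G{i:04d}" for i in range(1, n - len(reserved) + 1)]
    return reserved + filler


def _nb_counts(
    rng: np.random.Generator, log_mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.exp(log_mean)
    if not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_spatial(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Spot counts with three planted type programmes plus grid coordinates.

    Each spot type over-expresses its marker panel by ``effect_size`` on
    the latent log scale.  Coordinates are a row-major integer grid (no
    spatial autocorrelation is modelled).
    """
    cfg.validate()
    rng = cfg.rng("spatial")
    panels = cfg.marker_panels
    marker_genes = [g for panel in panels.values() for g in panel]
    if len(set(marker_genes)) != len(marker_genes):
        raise ValueError("marker panels must be disjoint")
    genes = _gene_names(cfg.n_genes, reserved=marker_genes)
    spots = [f"spot{i:04d}" for i in range(1, cfg.n_spots + 1)]

    types = list(panels)
    props = np.array([cfg.spot_type_props.get(t, 0.0) for t in types], dtype=float)
    props = props / props.sum()
    spot_type = rng.choice(types, size=cfg.n_spots, p=props)

    # each type's programme = its canonical marker panel plus a block of
    # additional programme genes (cell types differ broadly, not only in
    # their surface markers); annotation still uses only the panels
    program: dict[str, list[str]] = {t: list(p) for t, p in panels.items()}
    marker_set = set(marker_genes)
    filler = [g for g in genes if g not in marker_set]
    pos = 0
    for t in panels:
        take = filler[pos : pos + cfg.program_genes_per_type]
        program[t].extend(take)
        pos += len(take)

    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    log_mean = np.tile(base[:, None], (1, cfg.n_spots))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for t, block in program.items():
        cols = np.flatnonzero(spot_type == t)
        for g in block:
            log_mean[gene_idx[g], cols] += cfg.effect_size

    counts = _nb_counts(rng, log_mean, cfg.nb_dispersion)
    values = pd.DataFrame(counts, index=genes, columns=spots)

    side = int(np.ceil(np.sqrt(cfg.n_spots)))
    coords = pd.DataFrame(
        {
            "x": [i % side for i in range(cfg.n_spots)],
            "y": [i // side for i in range(cfg.n_spots)],
        },
        index=spots,
    )
    truth = GroundTruth(
        spot_type=pd.Series(spot_type, index=spots, name="spot_type"),
        marker_panels={k: list(v) for k, v in panels.items()},
        gene_modules=program,
    )
    meta = pd.DataFrame({"true_type": spot_type}, index=spots)
    return ExpressionMatrix(values, layer="raw", sample_meta=meta), coords, truth


def simulate_trajectory(
    cfg: SimulationConfig, noise: bool = True
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Y-shaped latent trajectory: one bifurcation at ``branch_time``.

    Genes split into four equal modules: early-decreasing, late-increasing,
    branch-specific (opposite sigmoid response on the two arms past the
    bifurcation) and flat nulls.  With ``noise=False`` the latent log-means
    are returned directly as a normalised layer (useful for geometric
    oracle checks); otherwise NB counts are drawn.
    """
    cfg.validate()
    if cfg.n_genes < 3:
        raise ValueError("need at least 3 genes for 3 non-null modules")
    rng = cfg.rng("trajectory")
    genes = _gene_names(cfg.n_genes)
    spots = [f"spot{i:04d}" for i in range(1, cfg.n_spots + 1)]

    t = rng.uniform(0.0, 1.0, size=cfg.n_spots)
    branch = np.where(
        t <= cfg.branch_time, 0, rng.choice([1, 2], size=cfg.n_spots)
    )

    quarter = max(1, cfg.n_genes // 4)
    modules = {
        "early": genes[:quarter],
        "late": genes[quarter : 2 * quarter],
        "branch": genes[2 * quarter : 3 * quarter],
        "null": genes[3 * quarter :],
    }
    amp = cfg.module_amplitude
    # ramp past the bifurcation, 0 before it
    s = np.clip((t - cfg.branch_time) / (1 - cfg.branch_time), 0.0, None)
    log_mean = np.empty((cfg.n_genes, cfg.n_spots))
    base = rng.normal(cfg.base_log_mean, cfg.base_log_sd, size=cfg.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in modules["early"]:
        log_mean[gene_idx[g]] = base[gene_idx[g]] + amp * (1.0 - t)
    for g in modules["late"]:
        log_mean[gene_idx[g]] = base[gene_idx[g]] + amp * t
    sign = np.where(branch == 2, -1.0, np.where(branch == 1, 1.0, 0.0))
    for g in modules["branch"]:
        log_mean[gene_idx[g]] = base[gene_idx[g]] + amp * sign * s
    for g in modules["null"]:
        log_mean[gene_idx[g]] = base[gene_idx[g]]

    if noise:
        values = pd.DataFrame(
            _nb_counts(rng, log_mean, cfg.nb_dispersion), index=genes, columns=spots
        )
        layer = "raw"
    else:
        values = pd.DataFrame(log_mean, index=genes, columns=spots)
        layer = "normalised"

    truth = GroundTruth(
        pseudotime=pd.Series(t, index=spots, name="pseudotime"),
        branch=pd.Series(branch, index=spots, name="branch"),
        gene_modules={k: list(v) for k, v in modules.items()},
    )
    meta = pd.DataFrame({"true_pseudotime": t, "true_branch": branch}, index=spots)
    return ExpressionMatrix(values, layer=layer, sample_meta=meta), truth


def _subtype_centroids(cfg: SimulationConfig, genes: list[str]) -> np.ndarray:
    """Gaussian subtype centroids: per subtype a gene block shifted by effect_size.

    The within-cluster SD is 1, so effect_size is directly the separation in SDs.
    Returns (n_subtypes, n_genes).
    """
    n_genes = len(genes)
    centroids = np.zeros((cfg.n_subtypes, n_genes))
    block = max(1, n_genes // (2 * cfg.n_subtypes))
    for k in range(cfg.n_subtypes):
        lo = k * block
        hi = min((k + 1) * block, n_genes)
        centroids[k, lo:hi] = cfg.effect_size
    return centroids


def _solve_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate rho with E[censored fraction] = target.

    For independent Exp(lambda_i) event and Exp(rho) censor times,
    P(censored_i) = rho / (rho + lambda_i).
    """

    def frac(rho: float) -> float:
        return float(np.mean(rho / (rho + hazards)))

    lo, hi = 1e-12, 1e12
    if target <= frac(lo):
        return 0.0
    return float(optimize.brentq(lambda r: frac(r) - target, lo, hi))


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, GroundTruth]:
    """Bulk cohort: Gaussian subtype centroids plus exponential survival.

    The per-sample log hazard is a subtype offset (worsening from subtype
    1 to ``n_subtypes``) plus the planted linear predictor over the
    informative genes; censoring is independent exponential with its rate
    solved to hit ``censor_target``.
    """
    cfg.validate()
    if cfg.censor_target >= 1.0:
        raise ValueError("censor_target = 1 leaves no events")
    rng = cfg.rng("cohort")
    genes = _gene_names(cfg.n_genes)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    subtype = rng.integers(0, cfg.n_subtypes, size=cfg.n_samples)
    centroids = _subtype_centroids(cfg, genes)
    expr = centroids[subtype].T + rng.normal(size=(cfg.n_genes, cfg.n_samples))

    meta = pd.DataFrame({"subtype": subtype + 1}, index=samples)
    if cfg.metastasis_frac > 0:
        met = rng.random(cfg.n_samples) < cfg.metastasis_frac
        block = genes[-max(1, cfg.n_genes // 20) :]
        rows = [genes.index(g) for g in block]
        expr[np.ix_(rows, np.flatnonzero(met))] += cfg.metastasis_shift
        meta["metastasis"] = met.astype(int)

    informative = genes[: cfg.n_informative]
    if cfg.informative_betas is not None:
        if len(cfg.informative_betas) != cfg.n_informative:
            raise ValueError("informative_betas length must equal n_informative")
        betas = dict(zip(informative, map(float, cfg.informative_betas)))
    else:
        betas = {g: cfg.hazard_beta for g in informative}
    loghr = cfg.subtype_loghr
    if loghr is None:
        loghr = [0.4 * k for k in range(cfg.n_subtypes)]
    eta = np.asarray(loghr, dtype=float)[subtype]
    for g, b in betas.items():
        eta = eta + b * expr[genes.index(g)]
    eta = eta - eta.mean()

    lam0 = math.log(2.0) / cfg.baseline_median_time
    hazards = lam0 * np.exp(eta)
    event_time = rng.exponential(1.0 / hazards)
    if cfg.censor_target > 0:
        rho = _solve_censoring_rate(hazards, cfg.censor_target)
        censor_time = (
            rng.exponential(1.0 / rho, size=cfg.n_samples)
            if rho > 0
            else np.full(cfg.n_samples, np.inf)
        )
    else:
        censor_time = np.full(cfg.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-8)

    values = pd.DataFrame(expr, index=genes, columns=samples)
    surv = SurvivalTable(
        pd.DataFrame({"time": time, "event": event}, index=samples)
    )
    truth = GroundTruth(
        sample_subtype=pd.Series(subtype + 1, index=samples, name="subtype"),
        informative_genes=betas,
    )
    return ExpressionMatrix(values, layer="normalised", sample_meta=meta), surv, truth


def simulate_cell_lines(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Cell-line panel near the cohort subtype centroids plus drug responses.

    Every drug is assigned a sensitive subtype (round-robin); its response
    is shifted by ``drug_shift`` in lines of that subtype.  The response
    convention is larger = more sensitive, recorded in the returned
    truth's ``direction`` field and in the drug table attrs.
    """
    cfg.validate()
    if cfg.n_cell_lines < cfg.n_subtypes:
        raise ValueError("need at least one cell line per subtype")
    rng = cfg.rng("cell_lines")
    genes = _gene_names(cfg.n_genes)
    lines = [f"CL{i:03d}" for i in range(1, cfg.n_cell_lines + 1)]
    centroids = _subtype_centroids(cfg, genes)

    subtype = np.arange(cfg.n_cell_lines) % cfg.n_subtypes
    expr = centroids[subtype].T + rng.normal(
        scale=cfg.line_noise_sd, size=(cfg.n_genes, cfg.n_cell_lines)
    )
    values = pd.DataFrame(expr, index=genes, columns=lines)
    meta = pd.DataFrame({"subtype": subtype + 1}, index=lines)

    drugs = [f"drug{i:03d}" for i in range(1, cfg.n_drugs + 1)]
    drug_subtype = {d: (i % cfg.n_subtypes) + 1 for i, d in enumerate(drugs)}
    records = []
    for d in drugs:
        resp = rng.normal(size=cfg.n_cell_lines)
        resp[subtype + 1 == drug_subtype[d]] += cfg.drug_shift
        for line, value in zip(lines, resp):
            records.append((line, d, value))
    response = pd.DataFrame(records, columns=["cell_line", "drug", "response"])
    response.attrs["direction"] = "higher_is_sensitive"

    truth = GroundTruth(
        cell_line_subtype=pd.Series(subtype + 1, index=lines, name="subtype"),
        drug_map={d: f"cluster{s}" for d, s in drug_subtype.items()},
        direction="higher_is_sensitive",
    )
    return ExpressionMatrix(values, layer="normalised", sample_meta=meta), response, truth


def simulate_peaks(
    cfg: SimulationConfig,
) -> tuple[PeakSet, pd.DataFrame, GroundTruth]:
    """Background-uniform peak track with enrichment at planted gene segments.

    Background midpoints are uniform per chromosome (counts multinomial by
    length).  Each planted gene locus marks a segment of the default grid;
    those segments receive (enrichment_fold - 1) x the background segment
    rate in extra peaks.
    """
    cfg.validate()
    if not cfg.chrom_sizes:
        raise ValueError("chrom_sizes must be nonempty")
    for chrom, length in cfg.chrom_sizes.items():
        if cfg.peak_width > length:
            raise ValueError(f"peak width exceeds length of {chrom}")
        if length < cfg.n_segments:
            raise ValueError(f"{chrom} shorter than {cfg.n_segments} segments")
    rng = cfg.rng("peaks")
    chroms = list(cfg.chrom_sizes)
    lengths = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)

    per_chrom = rng.multinomial(cfg.n_background_peaks, lengths / lengths.sum())
    rows: list[tuple[str, int, int]] = []
    half = cfg.peak_width // 2

    def add_peak(chrom: str, mid: int) -> None:
        size = cfg.chrom_sizes[chrom]
        start = int(np.clip(mid - half, 0, size - cfg.peak_width))
        rows.append((chrom, start, start + cfg.peak_width))

    for chrom, n in zip(chroms, per_chrom):
        mids = rng.integers(0, cfg.chrom_sizes[chrom], size=n)
        for mid in mids:
            add_peak(chrom, int(mid))

    # planted gene loci and enriched segments
    gene_rows = []
    enriched: list[tuple[str, int]] = []
    for i in range(cfg.n_locus_genes):
        # uniform over declared chromosomes, matching the permutation null
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        size = cfg.chrom_sizes[chrom]
        pos = int(rng.integers(0, size))
        gene_rows.append((f"LG{i + 1:03d}", chrom, pos))
        seg = int(pos * cfg.n_segments // size)
        enriched.append((chrom, seg))
    gene_loci = pd.DataFrame(gene_rows, columns=["gene", "chrom", "position"])

    if cfg.enrichment_fold > 1.0:
        for chrom, seg in set(enriched):
            size = cfg.chrom_sizes[chrom]
            lo = seg * size // cfg.n_segments
            hi = (seg + 1) * size // cfg.n_segments
            bg_rate = per_chrom[chroms.index(chrom)] / cfg.n_segments
            extra = rng.poisson((cfg.enrichment_fold - 1.0) * bg_rate)
            for mid in rng.integers(lo, hi, size=extra):
                add_peak(chrom, int(mid))

    peaks = PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    peaks.validate_bounds(cfg.chrom_sizes)
    truth = GroundTruth(enriched_segments=sorted(set(enriched)))
    return peaks, gene_loci, truth
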
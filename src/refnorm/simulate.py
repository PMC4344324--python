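"""Synthetic senescence time-course generator.

Emulates the statistical structure of a dark-induced leaf senescence
expression study: a majority of genes with constant true abundance, a
minority of monotone up-/down-regulated senescence responders, per-sample
log-normal scale factors shared by all genes of one RNA sample (reverse
transcription and input variability), Gaussian gene-level noise on the
log2 scale, qPCR Cq tables with technical replicates, and ddPCR wells in
which molecules partition binomially over 14,000-17,000 droplets.

Every draw flows from one :class:`numpy.random.Generator`, so a fixed seed
reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import DomainError, InvalidConfigError

__all__ = [
    "SyntheticTruth",
    "DropletWell",
    "simulate_expression_timecourse",
    "cq_from_abundance",
    "simulate_droplets",
    "make_panel_truth",
    "simulate_ddpcr_panel",
    "sample_id",
]

#: default ddPCR gene panel: five stable reference candidates (three highly
#: expressed, two 2-3x lower) and two 8-fold senescence markers.
DEFAULT_REFERENCE_LEVELS: dict[str, float] = {
    "ref_A": 1600.0,
    "ref_B": 600.0,
    "ref_C": 1400.0,
    "ref_D": 550.0,
    "ref_E": 1000.0,
}
DEFAULT_MARKERS: dict[str, tuple[float, float]] = {
    "marker_up": (80.0, 3.0),      # SAG12-like, 8-fold induction
    "marker_down": (1500.0, -3.0),  # RbcS-like, 8-fold repression
}

_REP_LABELS = "abcdefghijklmnopqrstuvwxyz"


def sample_id(day: int, replicate: str) -> str:
    """Canonical sample identifier, e.g. ``'d0_a'``."""
    return f"d{day}_{replicate}"


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated experiment.

    Attributes
    ----------
    classes : pandas.Series
        Per-gene label, one of ``'stable'``, ``'up'``, ``'down'``.
    trajectories : pandas.DataFrame
        Genes x time points, true linear-scale abundance (copies/ul).
    scale_factors : pandas.Series
        Per-sample multiplicative scale factor, indexed by sample id.
    design : pandas.DataFrame
        Columns ``sample``, ``day``, ``replicate``; one row per sample.
    """

    classes: pd.Series
    trajectories: pd.DataFrame
    scale_factors: pd.Series
    design: pd.DataFrame

    def abundance(self, gene: str, day: int) -> float:
        return float(self.trajectories.at[gene, day])


@dataclass
class DropletWell:
    """One ddPCR well: droplet counts plus its labels."""

    n_total: int
    n_positive: int
    droplet_volume: float  # nL
    target: str = ""
    sample: str = ""
    is_ntc: bool = False


def _replicate_labels(n: int) -> list[str]:
    if n <= len(_REP_LABELS):
        return list(_REP_LABELS[:n])
    return [f"r{i + 1}" for i in range(n)]


def _make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample": sample_id(day, rep), "day": day, "replicate": rep}
        for day in config.time_points
        for rep in _replicate_labels(config.n_bio_reps)
    ]
    return pd.DataFrame(rows)


def _draw_scale_factors(design: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator) -> pd.Series:
    logs = rng.normal(0.0, config.sample_scale_sd, size=len(design))
    return pd.Series(np.exp(logs), index=design["sample"].to_numpy(), name="scale")


def _trajectories(gene_ids: list[str], classes: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator,
                  base_log2_range: tuple[float, float] = (6.5, 11.0)) -> pd.DataFrame:
    """Piecewise-linear log2 trajectories between Day 0 and the last day."""
    days = np.asarray(config.time_points, dtype=float)
    frac = (days - days[0]) / (days[-1] - days[0])
    base = rng.uniform(*base_log2_range, size=len(gene_ids))
    mag = np.zeros(len(gene_ids))
    up = classes == "up"
    down = classes == "down"
    mag[up] = rng.uniform(*config.up_fold_range_log2, size=up.sum())
    mag[down] = -rng.uniform(*config.down_fold_range_log2, size=down.sum())
    log2_traj = base[:, None] + mag[:, None] * frac[None, :]
    return pd.DataFrame(2.0 ** log2_traj, index=gene_ids,
                        columns=list(config.time_points))


def simulate_expression_timecourse(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a normalized log2 expression matrix for a full time course.

    The measured log2 intensity of gene *g* on the array of sample *s* is

    ``log2(abundance_g(day_s)) + log2(scale_s) + N(0, biological_noise_sd)``

    Returns
    -------
    expr : pandas.DataFrame
        Genes x arrays log2 intensities (array ids are sample ids).
    design : pandas.DataFrame
        Columns ``sample``, ``day``, ``replicate``.
    truth : SyntheticTruth
        Labels, true trajectories and scale factors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(n)]
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    classes = np.array(["up"] * n_up + ["down"] * n_down
                       + ["stable"] * (n - n_up - n_down))
    classes = classes[rng.permutation(n)]

    traj = _trajectories(gene_ids, classes, config, rng)
    design = _make_design(config)
    scale = _draw_scale_factors(design, config, rng)

    day_of_sample = design.set_index("sample")["day"]
    log2_true = np.log2(traj.to_numpy())
    day_index = {d: j for j, d in enumerate(config.time_points)}
    cols = np.array([day_index[day_of_sample[s]] for s in design["sample"]])
    signal = log2_true[:, cols] + np.log2(scale.to_numpy())[None, :]
    noise = rng.normal(0.0, config.biological_noise_sd, size=signal.shape)
    expr = pd.DataFrame(signal + noise, index=gene_ids,
                        columns=design["sample"].to_numpy())
    truth = SyntheticTruth(
        classes=pd.Series(classes, index=gene_ids, name="class"),
        trajectories=traj,
        scale_factors=scale,
        design=design,
    )
    return expr, design, truth


def cq_from_abundance(truth: SyntheticTruth, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Invert the qPCR quantification model to produce a Cq table.

    ``Cq = intercept - log_E(abundance * scale) + N(0, cq_noise_sd)``
    with ``n_tech_reps`` technical replicates per (gene, sample).

    Returns a tidy frame with columns ``gene``, ``sample``, ``tech_rep``, ``cq``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if (truth.trajectories.to_numpy() <= 0).any():
        raise DomainError("abundances must be strictly positive")
    log_e = np.log(config.efficiency)
    rows = []
    for s, day in truth.design[["sample", "day"]].itertuples(index=False):
        scale = truth.scale_factors[s]
        for gene in truth.trajectories.index:
            level = truth.abundance(gene, day) * scale
            base_cq = config.cq_intercept - np.log(level) / log_e
            for t in range(1, config.n_tech_reps + 1):
                rows.append((gene, s, t,
                             base_cq + rng.normal(0.0, config.cq_noise_sd)))
    return pd.DataFrame(rows, columns=["gene", "sample", "tech_rep", "cq"])


def simulate_droplets(
    true_conc: float,
    config: SimulationConfig,
    sample_scale: float = 1.0,
    rng: np.random.Generator | None = None,
) -> DropletWell:
    """Simulate one ddPCR well by binomial droplet partitioning.

    The accepted droplet count ``n`` is uniform over
    ``droplet_count_range``; the positive count is
    ``k ~ Binomial(n, 1 - exp(-c * scale * v_d))`` with the droplet
    volume ``v_d`` converted from nL to ul. This is the exact marginal law
    of Poisson-distributed molecule placement.
    """
    if true_conc < 0:
        raise DomainError("true concentration must be >= 0")
    if sample_scale < 0:
        raise DomainError("sample scale factor must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.droplet_count_range
    n = int(rng.integers(lo, hi + 1))
    v_ul = config.droplet_volume * 1e-3
    p = 1.0 - np.exp(-true_conc * sample_scale * v_ul)
    k = int(rng.binomial(n, p))
    return DropletWell(n_total=n, n_positive=k, droplet_volume=config.droplet_volume)


def make_panel_truth(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    reference_levels: dict[str, float] | None = None,
    markers: dict[str, tuple[float, float]] | None = None,
) -> SyntheticTruth:
    """Ground truth for the targeted qPCR/ddPCR gene panel.

    References are constant; each marker is given as
    ``(day-0 abundance, end-point log2 fold change)`` and interpolates
    linearly in log2 space across the time course. Scale factors are drawn
    fresh (the panel assays use their own RNA aliquots).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    refs = DEFAULT_REFERENCE_LEVELS if reference_levels is None else reference_levels
    mks = DEFAULT_MARKERS if markers is None else markers
    days = np.asarray(config.time_points, dtype=float)
    frac = (days - days[0]) / (days[-1] - days[0])
    rows, labels = {}, {}
    for g, level in refs.items():
        if level <= 0:
            raise InvalidConfigError(f"reference level for {g} must be positive")
        rows[g] = np.full(len(days), float(level))
        labels[g] = "stable"
    for g, (start, end_log2) in mks.items():
        if start <= 0:
            raise InvalidConfigError(f"marker start level for {g} must be positive")
        rows[g] = start * 2.0 ** (end_log2 * frac)
        labels[g] = "up" if end_log2 >= 0 else "down"
    traj = pd.DataFrame(rows, index=list(config.time_points)).T
    design = _make_design(config)
    scale = _draw_scale_factors(design, config, rng)
    return SyntheticTruth(
        classes=pd.Series(labels, name="class"),
        trajectories=traj,
        scale_factors=scale,
        design=design,
    )


def simulate_ddpcr_panel(
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ntc_wells_per_target: int = 1,
) -> pd.DataFrame:
    """Simulate a full plate: one well per (gene, sample) plus NTC wells.

    Each measured concentration is the true trajectory value perturbed by
    the gene-level log-normal noise (``2**N(0, biological_noise_sd)``) and
    the sample's shared scale factor; droplets then partition binomially.

    Returns a tidy well table with columns ``well``, ``target``, ``sample``,
    ``day``, ``replicate``, ``n_total``, ``n_positive``, ``is_ntc``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    widx = 0
    for gene in truth.trajectories.index:
        for s, day, rep in truth.design[["sample", "day", "replicate"]].itertuples(index=False):
            conc = truth.abundance(gene, day)
            conc *= 2.0 ** rng.normal(0.0, config.biological_noise_sd)
            well = simulate_droplets(conc, config, truth.scale_factors[s], rng)
            widx += 1
            rows.append({
                "well": f"W{widx:04d}", "target": gene, "sample": s,
                "day": day, "replicate": rep,
                "n_total": well.n_total, "n_positive": well.n_positive,
                "is_ntc": False,
            })
        for j in range(ntc_wells_per_target):
            well = simulate_droplets(config.ntc_background, config, 1.0, rng)
            widx += 1
            rows.append({
                "well": f"W{widx:04d}", "target": gene, "sample": f"NTC_{j + 1}",
                "day": -1, "replicate": "ntc",
                "n_total": well.n_total, "n_positive": well.n_positive,
                "is_ntc": True,
            })
    return pd.DataFrame(rows)
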
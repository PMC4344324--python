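"""Configuration objects for the simulator and the end-to-end pipeline.

Both configs are plain dataclasses that validate their invariants on
construction and round-trip through YAML, so a pipeline run is fully
described by one text file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

from .errors import InvalidConfigError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic senescence time-course generator.

    Parameters
    ----------
    n_genes : int
        Number of genes on the simulated expression array.
    frac_up, frac_down : float
        Fractions of genes that are up-/down-regulated senescence responders.
        The remainder are stable (constant true abundance). Must sum to < 1.
    time_points : sequence of int
        Ordered day labels; the first entry is the baseline (default
        days 0, 3, 5, 7, 10, 12 of dark incubation).
    n_bio_reps : int
        Biological replicates per time point (independent cultivations).
    n_tech_reps : int
        Technical qPCR replicates per biological sample.
    biological_noise_sd : float
        Per-gene, per-sample Gaussian noise on the log2 scale.
    sample_scale_sd : float
        Standard deviation, on the natural-log scale, of the per-sample
        log-normal scale factor modelling RT/input variability shared by
        all genes measured in one RNA sample.
    cq_noise_sd : float
        Technical noise of a single Cq measurement, in cycles.
    up_fold_range_log2, down_fold_range_log2 : (float, float)
        Range of end-point |log2 fold change| (Day 0 to last day) from
        which responder trajectories draw their magnitude.
    droplet_count_range : (int, int)
        Inclusive range of accepted droplets per ddPCR well.
    droplet_volume : float
        Single droplet volume in nanolitres.
    cq_intercept : float
        Cq of one abundance unit; sets the absolute Cq scale.
    efficiency : float
        Amplification efficiency E in (1, 2]; 2 means perfect doubling.
    ntc_background : float
        True concentration (copies/ul) in no-template-control wells.
    seed : int
        Root seed for all stochastic draws.
    """

    n_genes: int = 2000
    frac_up: float = 0.03
    frac_down: float = 0.02
    time_points: tuple[int, ...] = (0, 3, 5, 7, 10, 12)
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    biological_noise_sd: float = 0.1
    sample_scale_sd: float = 0.3
    cq_noise_sd: float = 0.15
    up_fold_range_log2: tuple[float, float] = (1.5, 4.0)
    down_fold_range_log2: tuple[float, float] = (1.5, 4.0)
    droplet_count_range: tuple[int, int] = (14000, 17000)
    droplet_volume: float = 0.85
    cq_intercept: float = 35.0
    efficiency: float = 2.0
    ntc_background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_points = tuple(int(t) for t in self.time_points)
        self.droplet_count_range = tuple(int(v) for v in self.droplet_count_range)
        self.up_fold_range_log2 = tuple(float(v) for v in self.up_fold_range_log2)
        self.down_fold_range_log2 = tuple(float(v) for v in self.down_fold_range_log2)
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if self.n_bio_reps <= 0 or self.n_tech_reps <= 0:
            raise InvalidConfigError("replicate counts must be positive")
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down >= 1:
            raise InvalidConfigError("frac_up + frac_down must be in [0, 1)")
        for name in ("biological_noise_sd", "sample_scale_sd", "cq_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        lo, hi = self.droplet_count_range
        if lo <= 0 or hi < lo:
            raise InvalidConfigError("droplet_count_range must be a positive interval")
        if self.droplet_volume <= 0:
            raise InvalidConfigError("droplet_volume must be positive")
        if not 1 < self.efficiency <= 2:
            raise InvalidConfigError("efficiency must lie in (1, 2]")
        if self.ntc_background < 0:
            raise InvalidConfigError("ntc_background must be >= 0")
        if len(self.time_points) < 2:
            raise InvalidConfigError("need at least two time points")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise InvalidConfigError("time_points must be strictly increasing")

    @property
    def baseline_day(self) -> int:
        return self.time_points[0]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ScreenConfig:
    """Thresholds of the stable-gene screening cascade."""

    fc_threshold: float = 2.0
    p_threshold: float = 0.0005
    change_threshold: float = 0.20
    cv_threshold: float = 0.01
    window: tuple[float, float] | None = None  # None -> auto from DE genes
    window_percentiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise InvalidConfigError("fc_threshold must be >= 1 (fold scale)")
        if not 0 < self.p_threshold <= 1:
            raise InvalidConfigError("p_threshold must be in (0, 1]")
        if self.change_threshold <= 0 or self.cv_threshold <= 0:
            raise InvalidConfigError("screen thresholds must be positive")


@dataclass
class EvaluateConfig:
    """Reference combinations and targets for the CV-reduction report."""

    targets: tuple[str, ...] = ("ref_C", "marker_up", "marker_down")
    references: tuple[str, ...] = ("ref_A", "ref_B", "ref_D", "ref_E")
    combos: tuple[tuple[str, ...], ...] = ()
    scale_mode: str = "per_replicate"

    def __post_init__(self) -> None:
        self.targets = tuple(self.targets)
        self.references = tuple(self.references)
        self.combos = tuple(tuple(c) for c in self.combos)
        if not self.combos:
            # all pairs plus the full set, mirroring a pairs+quadruple design
            refs = self.references
            pairs = tuple(
                (refs[i], refs[j]) for i in range(len(refs)) for j in range(i + 1, len(refs))
            )
            self.combos = pairs + ((tuple(refs)),) if len(refs) > 2 else pairs
        if self.scale_mode not in ("per_replicate", "mean"):
            raise InvalidConfigError("scale_mode must be 'per_replicate' or 'mean'")


@dataclass
class PipelineConfig:
    """Top-level configuration: one block per pipeline stage."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    efficiency: dict[str, float] = field(default_factory=dict)  # per-gene override
    background_correction: bool = True
    seed: int | None = None  # overrides simulation.seed when set

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig.from_dict(raw.get("simulation", {}))
        screen = ScreenConfig(**raw.get("screen", {}))
        ev = EvaluateConfig(**raw.get("evaluate", {}))
        return cls(
            simulation=sim,
            screen=screen,
            evaluate=ev,
            efficiency=dict(raw.get("efficiency", {})),
            background_correction=bool(raw.get("background_correction", True)),
            seed=raw.get("seed"),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "simulation": self.simulation.to_dict(),
            "screen": asdict(self.screen),
            "evaluate": asdict(self.evaluate),
            "efficiency": self.efficiency,
            "background_correction": self.background_correction,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def resolve_seed(config: PipelineConfig) -> int:
    return int(config.seed if config.seed is not None else config.simulation.seed)
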
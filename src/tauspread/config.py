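"""Configuration objects for the synthetic cohort and the full pipeline.

Defaults mirror the study conditions the analysis was designed for: a
211-subject cohort (94 amyloid-positive / 117 amyloid-negative) measured
on a 200-region, 7-network cortical parcellation, a 69-subject normative
connectome template, 2-4 tau-PET scans per subject with a mean follow-up
of 1.83 +/- 1.23 years, a planted region-level rate-vs-distance
correlation of -0.3, mediation path coefficients (a, b, c') =
(0.4, 0.5, 0.6) (proportion mediated 0.25), and four planted
susceptibility/resilience groups defined by per-network FC offsets.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: region counts of the seven canonical cortical networks in the
#: 200-parcel functional atlas (visual, somatomotor, dorsal attention,
#: salience/ventral attention, limbic, control, default mode)
NETWORK_NAMES = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")
NETWORK_SIZES_200 = (31, 37, 23, 22, 13, 30, 44)
DMN = "Default"

#: per-network FC-to-epicentre offsets (Fisher-Z units) defining the four
#: planted groups; large relative to the FC noise so the planted structure
#: is recoverable.  The DMN-susceptible group loses connectivity
#: specifically in the default-mode network while other networks are
#: mildly preserved.
#: the multiset of offsets is balanced ({0, 0, +o, -o}) within every
#: network so the fitted regression line stays centred regardless of the
#: realized group sizes
DEFAULT_GROUP_OFFSETS = {
    "canonical": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "resilient": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
    "susceptible": (-0.5, -0.5, -0.5, -0.5, -0.5, -0.5, 0.0),
    "dmn-susceptible": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -0.5),
}

DEFAULT_NOISE_SDS = {
    "baseline": 0.05,   # cross-subject SD of background SUVR
    "scan": 0.01,       # per-scan SUVR measurement noise
    "fc": 0.035,        # network-level FC-to-epicentre noise
    "fc_pair": 0.10,    # pair-level FC jitter
    "amyloid": 0.40,    # epicentre-amyloid (mediator) noise
    "amyloid_region": 0.02,  # per-region amyloid jitter
    "cognition_intercept": 0.40,
    "cognition_visit": 0.15,
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    All randomness derives from ``seed``; the same configuration yields a
    byte-identical cohort.
    """

    n_subjects: int = 211
    n_regions: int = 200
    n_networks: int = 7
    network_sizes: tuple = NETWORK_SIZES_200
    network_names: tuple = NETWORK_NAMES
    n_template_subjects: int = 69
    n_timeseries_frames: int = 200
    within_network_corr: float = 0.5
    between_network_corr: float = 0.1
    frac_abeta_positive: float = 94 / 211
    scans_per_subject: tuple = (2, 4)
    followup_years_mean_sd: tuple = (1.83, 1.23)
    planted_spread_corr: float = -0.3
    spread_corr_sd: float = 0.3
    mediation_coeffs: tuple = (0.4, 0.125, 0.15)  # (a, b, c'); a*b/(a*b+c') = 0.25
    group_offsets: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_OFFSETS))
    noise_sds: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SDS))
    n_seed_candidates: int = 3
    epicentre_size: int = 10
    suvr_background_mean: float = 1.1
    suvr_lift: float = 0.6
    lift_decay_scale: float = 2.0
    rate_mean: float = 0.02
    rate_sd: float = 0.05
    fc_density: float = 0.30
    fc_output: str = "timeseries"  # or "matrix"
    fc_base: float = 0.2  # typical FC-to-epicentre level (Fisher-Z)
    fc_factor_loading: float = 1.2  # epicentre-side loading of the latent FC factor
    n_cognition_visits: int = 3
    cognition_slopes: dict = field(
        default_factory=lambda: {
            "canonical": -0.05,
            "resilient": -0.02,
            "susceptible": -0.15,
            "dmn-susceptible": -0.10,
        }
    )
    seed: int = 0

    def __post_init__(self):
        self.network_sizes = tuple(int(s) for s in self.network_sizes)
        self.network_names = tuple(self.network_names)
        self.scans_per_subject = tuple(int(s) for s in self.scans_per_subject)
        self.followup_years_mean_sd = tuple(float(v) for v in self.followup_years_mean_sd)
        self.mediation_coeffs = tuple(float(v) for v in self.mediation_coeffs)
        self.group_offsets = {k: tuple(float(x) for x in v) for k, v in self.group_offsets.items()}
        self.validate()

    def validate(self) -> None:
        if sum(self.network_sizes) != self.n_regions:
            raise ConfigurationError(
                f"network_sizes sum to {sum(self.network_sizes)}, expected n_regions={self.n_regions}"
            )
        if len(self.network_sizes) != self.n_networks:
            raise ConfigurationError("network_sizes length must equal n_networks")
        for name, c in (
            ("within_network_corr", self.within_network_corr),
            ("between_network_corr", self.between_network_corr),
            ("planted_spread_corr", self.planted_spread_corr),
        ):
            if not -1.0 < c < 1.0:
                raise ConfigurationError(f"{name}={c} outside (-1, 1)")
        if not 0.0 <= self.frac_abeta_positive <= 1.0:
            raise ConfigurationError("frac_abeta_positive must be in [0, 1]")
        lo, hi = self.scans_per_subject
        if not (2 <= lo <= hi <= 4):
            raise ConfigurationError("scans_per_subject must be a range within [2, 4]")
        if any(sd <= 0 for sd in self.noise_sds.values()):
            raise ConfigurationError("all noise SDs must be positive")
        for label, offs in self.group_offsets.items():
            if len(offs) != self.n_networks:
                raise ConfigurationError(
                    f"group_offsets[{label!r}] must have one value per network"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_yaml_clean(self.to_dict()), fh, sort_keys=False)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults reproduce the reference parameter set: 30% template density,
    10 epicentres per subject, 0.7 SD residual discretization and 1000
    bootstrap iterations for the mediation analysis.
    """

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    out_dir: str = "tauspread_out"
    density: float = 0.30
    k_epicentres: int = 10
    discretize_c: float = 0.7
    flip_discretize_signs: bool = False
    n_boot: int = 1000
    adjust: str = "bh"
    rate_mode: str = "mixed"
    distance_agg: str = "mean"
    multi_hop: bool = True
    k_range: tuple = (2, 8)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)
        if self.cohort is None and self.input_dir is None:
            raise ConfigurationError("either a cohort config or an input_dir is required")
        self.k_range = tuple(int(k) for k in self.k_range)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(_yaml_clean(self.to_dict()), fh, sort_keys=False)


def _yaml_clean(obj):
    """Recursively convert tuples/numpy scalars so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _yaml_clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_clean(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
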
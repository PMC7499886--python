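"""Configuration objects for simulation and pipeline runs.

All tunable constants of the analysis live here: sample/stage labels,
detection and filtering thresholds, and the parameters of the synthetic
world (genome geometry, TE class sizes, read depths, methylation effect
sizes). Identical configs (including seeds) must yield byte-identical
outputs everywhere downstream.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: Ordered sample labels: floral bud, preglobular, globular, early heart,
#: late heart, early torpedo, late torpedo, bent cotyledon, mature green, leaf.
STAGES: tuple[str, ...] = ("fb", "pg", "gl", "eh", "lh", "et", "lt", "bc", "mg", "lf")

#: Embryonic stages with methylome data; all C(5,2)=10 pairwise
#: comparisons between them define the DMR set.
METH_STAGES: tuple[str, ...] = ("pg", "eh", "et", "bc", "mg")

#: Fractional position of each methylome stage along the embryonic
#: CHH-methylation ramp (hypomethylated preglobular -> methylated mature).
STAGE_RAMP: dict[str, float] = {"pg": 0.0, "eh": 0.25, "et": 0.5, "bc": 0.75, "mg": 1.0}

#: 24-nt siRNA abundance detection threshold (reads per million
#: genome-matching reads), applied to the max across samples of the
#: replicate-mean RPM.
DETECTION_RPM: float = 2.0

#: TE length partition boundaries (bp): short <= 723 < medium <= 2114 < long.
LENGTH_SHORT_MAX: int = 723
LENGTH_MEDIUM_MAX: int = 2114


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


def _default_te_counts() -> dict[str, int]:
    return {"A": 120, "B": 80, "depleted": 80}


def _default_length_params() -> dict[str, tuple[float, float]]:
    # (median bp, log-normal sigma); class B TEs are the long ones.
    return {"A": (400.0, 0.5), "B": (2500.0, 0.5), "depleted": (500.0, 0.5)}


def _default_meth_baseline() -> dict[str, float]:
    # Genome-wide weighted rates typical for Arabidopsis vegetative tissue.
    return {"CG": 0.24, "CHG": 0.10, "CHH": 0.03}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    Defaults are a desk-scale miniature of the real study: ten sample
    types x 3 replicates, two latent TE classes with opposite temporal
    siRNA dynamics plus a siRNA-depleted class, planted CHH DMRs with a
    stage-increasing ramp, and three nucleosome-occupancy archetypes on
    long heterochromatic TEs.
    """

    n_chromosomes: int = 2
    chrom_length: int = 500_000
    centromere_half_width: int = 100_000
    n_te_per_class: Mapping[str, int] = field(default_factory=_default_te_counts)
    length_params: Mapping[str, tuple[float, float]] = field(default_factory=_default_length_params)
    stages: Sequence[str] = STAGES
    n_replicates: int = 3
    reads_per_library: int = 100_000
    nb_dispersion: float = 0.2
    multimap_family_size: int = 3
    frac_multimapping: float = 0.25
    background_frac: float = 0.3
    meth_baseline: Mapping[str, float] = field(default_factory=_default_meth_baseline)
    dmr_effect: float = 0.40
    n_dmr: int = 40
    dmr_length: int = 300
    coverage_per_cytosine: float = 20.0
    conversion_error: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("genome dimensions must be strictly positive")
        if not 0 <= self.centromere_half_width <= self.chrom_length // 2:
            raise ConfigError("centromere_half_width must fit inside a chromosome")
        for cls in ("A", "B", "depleted"):
            if cls not in self.n_te_per_class:
                raise ConfigError(f"n_te_per_class missing class {cls!r}")
            if self.n_te_per_class[cls] < 0:
                raise ConfigError("TE counts must be non-negative")
            med, sig = self.length_params[cls]
            if med <= 0 or sig < 0:
                raise ConfigError("length_params must be positive (median) and non-negative (sigma)")
        if self.n_replicates < 1 or self.reads_per_library < 0:
            raise ConfigError("n_replicates must be >=1 and reads_per_library >=0")
        if not 0.0 <= self.frac_multimapping <= 1.0:
            raise ConfigError("frac_multimapping must lie in [0, 1]")
        if not 0.0 <= self.background_frac < 1.0:
            raise ConfigError("background_frac must lie in [0, 1)")
        if self.multimap_family_size < 2:
            raise ConfigError("multimap_family_size must be >= 2")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        for ctx, rate in self.meth_baseline.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"meth_baseline[{ctx!r}] must lie in [0, 1]")
        if not 0.0 <= self.dmr_effect <= 1.0:
            raise ConfigError("dmr_effect must lie in [0, 1]")
        if self.coverage_per_cytosine < 0 or self.conversion_error < 0:
            raise ConfigError("coverage and conversion_error must be >= 0")
        if self.n_dmr < 0 or self.dmr_length < 1:
            raise ConfigError("n_dmr must be >= 0 and dmr_length >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self) -> dict[str, int]:
        return {name: self.chrom_length for name in self.chrom_names()}


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and knobs of the analysis pipeline (CLI-facing).

    Houses the study's printed constants: 2 RPM detection, FDR 0.01,
    100-bp DMS collapse, >=4 DMSs, >=20 percentage-point difference,
    723/2114-bp length cutoffs, GMM grid 2..20 by 2, k=3 nucleosome
    groups, 5/4000/2000/2000 metaplot geometry.
    """

    detection_rpm: float = DETECTION_RPM
    fdr: float = 0.01
    dmr_gap: int = 100
    min_dms: int = 4
    min_diff_pp: float = 20.0
    min_cov_default: int = 4
    min_cov_preglobular: int = 3
    gmm_grid: tuple[int, ...] = tuple(range(2, 21, 2))
    kmeans_k: int = 3
    metaplot_bin: int = 5
    metaplot_body: int = 4000
    metaplot_flank: int = 2000
    n_sim: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fdr, self.detection_rpm, self.min_diff_pp) <= 0:
            raise ConfigError("thresholds must be strictly positive")
        if min(self.dmr_gap, self.min_dms, self.kmeans_k, self.n_sim) < 1:
            raise ConfigError("count thresholds must be >= 1")

    def min_cov(self, sample: str) -> int:
        """Per-sample coverage floor: preglobular keeps >=3-read sites."""
        return self.min_cov_preglobular if sample == "pg" else self.min_cov_default

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "gmm_grid" in d:
            d["gmm_grid"] = tuple(d["gmm_grid"])
        return cls(**d)
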
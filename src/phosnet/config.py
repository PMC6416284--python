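"""Run configuration objects for the analysis pipeline.

Two configuration dataclasses are exposed:

``AnalysisConfig``
    The fixed constants of the statistical protocol: the 25% band-frequency
    filter, the dual-correlation significance level, the PERMANOVA permutation
    count, and the reporting conventions for degree and density (which are
    emitted side by side because field usage is inconsistent).

``SyntheticConfig``
    The generative settings of the synthetic study emulator (sample design,
    band counts per kingdom, planted correlation structure, phenotype curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = ["AnalysisConfig", "SyntheticConfig", "PlantedEdge", "load_config"]

#: Exponential regression forms understood by the response-surface stage.
CURVE_FORMS = ("exp", "exp_offset", "peaked", "peaked_offset")

DENSITY_CONVENTIONS = ("total_nodes_directed_pairs", "interacting_nodes")
DEGREE_CONVENTIONS = ("two_e_over_n", "e_over_n")
EDGE_RULES = ("both", "either")


@dataclass(frozen=True)
class PlantedEdge:
    """A generative dependency between two bands.

    ``strength`` is the latent Gaussian correlation planted between the two
    bands (in (0, 1]); ``sign`` is +1 or -1.
    """

    band_i: str
    band_j: str
    sign: int
    strength: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign}")
        if not 0.0 < self.strength <= 1.0:
            raise ValueError(f"edge strength must be in (0, 1], got {self.strength}")
        if self.band_i == self.band_j:
            raise ValueError("planted self-edge is not allowed")


@dataclass
class AnalysisConfig:
    min_band_frequency: float = 0.25
    edge_alpha: float = 0.05
    n_permutations: int = 9999
    rng_seed: int | None = None
    group_by: str = "source"
    density_convention: str = "total_nodes_directed_pairs"
    degree_convention: str = "two_e_over_n"
    curve_family: tuple[str, ...] = CURVE_FORMS
    edge_rule: str = "both"
    binarize: bool = False
    bh_correction: bool = False
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.min_band_frequency <= 1.0:
            raise ValueError("min_band_frequency must lie in (0, 1]")
        if not 0.0 < self.edge_alpha < 1.0:
            raise ValueError("edge_alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.group_by not in ("source", "inoculum"):
            raise ValueError("group_by must be 'source' or 'inoculum'")
        if self.density_convention not in DENSITY_CONVENTIONS:
            raise ValueError(f"unknown density convention {self.density_convention!r}")
        if self.degree_convention not in DEGREE_CONVENTIONS:
            raise ValueError(f"unknown degree convention {self.degree_convention!r}")
        if self.edge_rule not in EDGE_RULES:
            raise ValueError(f"unknown edge rule {self.edge_rule!r}")
        unknown = set(self.curve_family) - set(CURVE_FORMS)
        if unknown:
            raise ValueError(f"unknown curve forms: {sorted(unknown)}")


def _default_planted_edges() -> tuple[PlantedEdge, ...]:
    """Default planted dependency graph: a mix of within- and between-kingdom
    edges of both signs, disjoint in their band support."""
    edges = []
    # bacteria-bacteria
    for k in range(6):
        sign = 1 if k % 3 else -1
        edges.append(PlantedEdge(f"b{2 * k + 1:03d}", f"b{2 * k + 2:03d}", sign, 0.8))
    # fungi-fungi
    for k in range(4):
        sign = 1 if k % 2 else -1
        edges.append(PlantedEdge(f"f{2 * k + 1:03d}", f"f{2 * k + 2:03d}", sign, 0.8))
    # bacteria-fungi
    for k in range(5):
        sign = 1 if k % 3 != 2 else -1
        edges.append(PlantedEdge(f"b{k + 13:03d}", f"f{k + 9:03d}", sign, 0.8))
    return tuple(edges)


@dataclass
class SyntheticConfig:
    """Settings of the synthetic study generator.

    Defaults mirror the dimensions of the greenhouse study being emulated:
    four phosphate sources (Control 0%, CA 2.93%, BA 14%, SS 18% P2O5) x two
    inoculum levels x four replicates = 32 samples, and 90 + 67 = 157 gel
    bands.  The colonization curve starts at 43% in the unfertilized control
    and declines with %P2O5; the dry-matter curve peaks at an interior
    phosphate solubility.
    """

    n_replicates: int = 4
    n_bacteria_bands: int = 90
    n_fungi_bands: int = 67
    planted_edges: tuple[PlantedEdge, ...] = field(default_factory=_default_planted_edges)
    zero_inflation: float = 0.30
    noise_sd: float = 0.60
    #: sd of per-(band, source) log-intensity offsets: the community shift that
    #: makes phosphate source a real factor in ordination/PERMANOVA
    source_effect_sd: float = 1.0
    #: sd of per-(band, inoculum) offsets; 0 by default (no inoculum effect)
    inoculum_effect_sd: float = 0.0
    #: multiplier on the latent score before exponentiation; controls the
    #: dynamic range (lognormal sigma) of the simulated gel intensities
    latent_scale: float = 1.0
    #: dry matter (g/pot) vs %P2O5: form, a, b, c for c + a*x*exp(b*x)
    dm_curve: tuple[str, float, float, float] = ("peaked_offset", 1.35, -1.0 / 11.0, 6.5)
    dm_noise_sd: float = 0.8
    #: colonization (%) vs %P2O5 for inoculated pots: intercept, slope
    colonization_curve: tuple[float, float] = (43.0, -1.5)
    colonization_noise_sd: float = 2.0
    #: %P2O5 of each source
    sources: dict[str, float] = field(
        default_factory=lambda: {"Control": 0.0, "CA": 2.93, "BA": 14.0, "SS": 18.0}
    )

    def __post_init__(self) -> None:
        if self.n_bacteria_bands < 2 or self.n_fungi_bands < 2:
            raise ValueError("need at least 2 bands per kingdom")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")
        for sd in (self.noise_sd, self.dm_noise_sd, self.colonization_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dm_curve[0] not in CURVE_FORMS:
            raise ValueError(f"unknown dm curve form {self.dm_curve[0]!r}")

    @property
    def n_bands(self) -> int:
        return self.n_bacteria_bands + self.n_fungi_bands

    @property
    def n_samples(self) -> int:
        return len(self.sources) * 2 * self.n_replicates

    def band_ids(self) -> list[str]:
        return [f"b{i + 1:03d}" for i in range(self.n_bacteria_bands)] + [
            f"f{i + 1:03d}" for i in range(self.n_fungi_bands)
        ]


def load_config(path: str | Path) -> dict:
    """Load a TOML or YAML configuration file into a plain dict.

    The suffix picks the parser (.toml / .yaml / .yml).
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            return yaml.safe_load(fh)
    raise ValueError(f"unsupported config format: {path.suffix!r}")
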
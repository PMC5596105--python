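"""Simulation and pipeline configuration.

`SimConfig` fixes the study design the simulator emulates: 18 libraries
(2 genotypes x 3 developmental stages x 3 epitype-inducing temperatures
18/23/28 degC), a tri-modal read-length structure, planted MIR hairpin loci
with isomiR variation, and temperature-structured miRNA/mRNA expression with
known anti-correlated target pairs.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

GENOTYPES = ("A2C", "B10W")
STAGES = (1, 2, 3)
TEMPERATURES = (18, 23, 28)

#: keys of the read-length mixture: the 21/22-nt components are drawn from
#: planted miRNA loci, the 24/31-nt components and the 15-35 nt uniform
#: component are genomic background fragments.
MIXTURE_KEYS = (21, 22, 24, 31, "uniform")

ISOMIR_CLASSES = ("substitution", "trim5", "trim3", "ext_templated", "tail3_U", "tail3_A")


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


def full_factorial_design() -> list[tuple[str, int, int]]:
    """The 18-library design: genotype x stage x temperature."""
    return [(g, s, t) for g in GENOTYPES for s in STAGES for t in TEMPERATURES]


@dataclass
class SimConfig:
    """Parameters of the synthetic small-RNA experiment.

    The defaults are the study conditions every planted-truth test runs
    under; see docs/methods.md for the rationale behind each value.
    """

    seed: int = 0
    genome_length: int = 200_000
    n_mir_loci: int = 40
    n_transcripts: int = 300
    n_regulator_transcripts: int = 60
    library_design: list[tuple[str, int, int]] = field(default_factory=full_factorial_design)
    reads_per_library: int = 100_000
    length_mixture: dict = field(
        default_factory=lambda: {21: 0.22, 22: 0.13, 24: 0.33, 31: 0.17, "uniform": 0.15}
    )
    isomir_rates: dict = field(
        default_factory=lambda: {
            "substitution": 0.02,
            "trim5": 0.03,
            "trim3": 0.05,
            "ext_templated": 0.03,
            "tail3_U": 0.04,
            "tail3_A": 0.02,
        }
    )
    seq_error_rate: float = 0.002
    frac_de_mirnas: float = 0.6
    anticorrelation_strength: float = -0.9
    # fraction of planted miRNAs flagged "conserved" and copied into the
    # emitted reference mature set
    frac_conserved: float = 0.4
    # guide:star abundance ratio, drawn uniformly per locus from this range
    star_ratio_range: tuple[float, float] = (5.0, 20.0)
    # planted target links per temperature-responsive miRNA; the first link of
    # each miRNA points at an epigenetic-regulator transcript
    links_per_de_mirna: int = 2

    def validate(self) -> "SimConfig":
        for name in ("genome_length", "reads_per_library"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("n_mir_loci", "n_transcripts", "n_regulator_transcripts"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_regulator_transcripts + self.n_mir_loci > self.n_transcripts:
            raise ConfigError(
                "n_transcripts must cover MIR host transcripts and regulators"
            )
        if set(self.length_mixture) != set(MIXTURE_KEYS):
            raise ConfigError(f"length_mixture must have keys {MIXTURE_KEYS}")
        total = sum(self.length_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_mixture weights must sum to 1 (got {total})")
        if any(w < 0 for w in self.length_mixture.values()):
            raise ConfigError("length_mixture weights must be non-negative")
        unknown = set(self.isomir_rates) - set(ISOMIR_CLASSES)
        if unknown:
            raise ConfigError(f"unknown isomiR classes: {sorted(unknown)}")
        if sum(self.isomir_rates.values()) > 1.0:
            raise ConfigError("isomiR rates must sum to at most 1")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ConfigError("seq_error_rate must be a probability")
        if not 0.0 <= self.frac_de_mirnas <= 1.0:
            raise ConfigError("frac_de_mirnas must be in [0, 1]")
        if not -1.0 <= self.anticorrelation_strength <= 0.0:
            raise ConfigError("anticorrelation_strength must be in [-1, 0]")
        for geno, stage, temp in self.library_design:
            if temp not in TEMPERATURES:
                raise ConfigError(f"temperature {temp} not in {TEMPERATURES}")
            if stage not in STAGES:
                raise ConfigError(f"stage {stage} not in {STAGES}")
        return self

    @property
    def library_names(self) -> list[str]:
        return [f"{g}_S{s}_T{t}" for g, s, t in self.library_design]

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "length_mixture" in raw:
            raw["length_mixture"] = {
                (k if k == "uniform" else int(k)): v
                for k, v in raw["length_mixture"].items()
            }
        if "library_design" in raw:
            raw["library_design"] = [
                (d["genotype"], int(d["stage"]), int(d["temperature"]))
                for d in raw["library_design"]
            ]
        if "star_ratio_range" in raw:
            raw["star_ratio_range"] = tuple(raw["star_ratio_range"])
        cfg = cls(**raw)
        return cfg.validate()
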
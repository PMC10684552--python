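"""Run configuration for the scan pipeline: a flat, YAML-round-trippable
record of every input path, window parameter and threshold."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of its documented range."""


@dataclass
class ScanConfig:
    # inputs / outputs
    vcf: str = ""
    popmap: str = ""
    outdir: str = "bovscan_out"
    gff: str | None = None
    tracts: str | None = None
    tract_dialect: str = "bed"
    seed: int = 0

    # windows and site filters
    window_size: int = 50_000
    step: int = 20_000
    keep_tail: bool = False
    min_snps: int = 10
    maf: float = 0.01

    # selection scan populations and statistics
    pop_a: str = ""  # scan target (e.g. the indicine pool)
    pop_b: str = ""  # contrast (e.g. the taurine pool)
    statistics: list[str] = field(default_factory=lambda: ["pi_ratio", "fst", "xpehh"])
    pbs_outgroup: str | None = None
    ihs_population: str | None = None
    polarize_outgroup: str | None = None

    # selection rules
    selection_rule: str = "top"  # "top" (top-quantile) or "ztest"
    top_q: float = 0.01
    p_threshold: float = 0.005
    pi_ratio_direction: str = "low"
    abs_ihs_threshold: float = 2.0

    # introgression scan
    source_pop: str | None = None
    target_pop: str | None = None
    donor_pop: str | None = None
    d_outgroup: str | None = None
    u_w: float = 1.0
    u_x: float = 0.01
    u_y20: float = 0.20
    u_y50: float = 0.50
    ils_L: float = 206.52
    ils_alpha: float = 0.05
    block_size: int = 5_000_000

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ConfigError("need 0 < step <= window_size")
        if not 0 <= self.maf <= 0.5:
            raise ConfigError("maf must be in [0, 0.5]")
        if not 0 < self.top_q < 1:
            raise ConfigError("top_q must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must be in (0, 1)")
        if self.selection_rule not in ("top", "ztest"):
            raise ConfigError("selection_rule must be 'top' or 'ztest'")
        if self.pi_ratio_direction not in ("low", "high"):
            raise ConfigError("pi_ratio_direction must be 'low' or 'high'")
        if not 0 <= self.u_x < self.u_y20 <= self.u_w <= 1:
            raise ConfigError("need 0 <= u_x < u_y20 <= u_w <= 1")
        if not self.u_x < self.u_y50 <= self.u_w:
            raise ConfigError("need u_x < u_y50 <= u_w")
        if self.ils_L <= 0:
            raise ConfigError("ils_L must be positive")
        if not 0 < self.ils_alpha <= 1:
            raise ConfigError("ils_alpha must be in (0, 1]")
        if self.abs_ihs_threshold < 0:
            raise ConfigError("abs_ihs_threshold must be >= 0")
        unknown = set(self.statistics) - {"pi_ratio", "fst", "xpehh", "pbs", "ihs"}
        if unknown:
            raise ConfigError(f"unknown statistics: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScanConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse {path}: {e}") from None
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def digest(self) -> str:
        """Stable hash of the scientific configuration (the output directory
        does not participate), recorded in output headers."""
        d = self.to_dict()
        d.pop("outdir")
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
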
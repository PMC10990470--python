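"""Run configuration: a flat declarative key/value schema with overrides.

Every tunable of the pipeline lives here with its default; configurations
can be loaded from a YAML file and overridden by CLI flags.  All tunables
are echoed into a provenance header on every output file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from sweepscan._errors import ValidationError


@dataclass
class RunConfig:
    """Inputs and tunables for a full selection scan."""

    vcf: str = ""
    pops: str = ""
    genetic_map: str | None = None
    genes: str | None = None
    target: str = ""
    reference: str = ""
    out_dir: str = "sweepscan_out"
    seed: int = 1

    maf_min: float = 0.01
    max_missing: float = 0.1
    biallelic_only: bool = True
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    window_bp: int = 20_000
    smoothing: str = "sliding"
    variance_mode: str = "empirical"
    top_frac: float = 0.001
    flank_frac: float = 0.01
    min_flankers: int = 5
    flank_span_bp: int = 500_000
    gene_flank_bp: int = 500_000

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_for_scan(self) -> None:
        if not self.vcf:
            raise ValidationError("config: 'vcf' input is required")
        if not self.pops:
            raise ValidationError("config: 'pops' population file is required")
        if not self.target:
            raise ValidationError("config: 'target' population name is required")
        if not self.reference:
            raise ValidationError("config: 'reference' population name is required")
        for name, path in (("vcf", self.vcf), ("pops", self.pops)):
            if not Path(path).exists():
                raise ValidationError(f"config: {name} file {path!r} does not exist")
        for name, path in (("genetic_map", self.genetic_map), ("genes", self.genes)):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config: {name} file {path!r} does not exist")

    def provenance_header(self, stage: str) -> str:
        lines = [f"# sweepscan {stage}"]
        for key, value in asdict(self).items():
            lines.append(f"# {key} = {value}")
        return "\n".join(lines) + "\n"
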
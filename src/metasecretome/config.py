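"""Pipeline configuration: thresholds, flags, flat-file round-trip.

Defaults are the thresholds used throughout the analysis: 95% identity
clustering, clusters of at least 5 members, 482 ORFs per genome bin, CAZyme
hits at coverage >= 0.35 and e-value <= 1e-15, orthologous-group hits at
e-value <= 0.001, a 50-RPKM prevalence floor, a -25 pseudovalue for absent
families, and the >50-MAG major-phylum rule.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, fields


@dataclass
class PipelineConfig:
    seed: int = 0
    identity_threshold: float = 0.95
    min_cluster_size: int = 5
    cluster_size_strict: bool = False  # True: "> min" instead of ">= min"
    min_orfs_per_mag: int = 482
    cazyme_min_coverage: float = 0.35
    cazyme_max_evalue: float = 1e-15
    eggnog_max_evalue: float = 1e-3
    min_rpkm: float = 50.0
    pseudovalue: float = -25.0
    major_phylum_min_mags: int = 50
    phylum_min_mags: int = 5  # inclusion floor for per-phylum summaries
    min_mapq: int = 10
    rpkm_denominator: str = "qc"  # or "mapped"
    ignore_nterm_helices: bool = False
    drop_singleton_families: bool = False
    reads_per_sample: int = 20_000

    def validate(self) -> "PipelineConfig":
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError(f"identity_threshold {self.identity_threshold} outside (0, 1]")
        if not 0.0 <= self.cazyme_min_coverage <= 1.0:
            raise ValueError("cazyme_min_coverage outside [0, 1]")
        for name in ("cazyme_max_evalue", "eggnog_max_evalue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_cluster_size", "min_orfs_per_mag", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.rpkm_denominator not in ("qc", "mapped"):
            raise ValueError("rpkm_denominator must be 'qc' or 'mapped'")
        return self

    # -- flat key=value round-trip -----------------------------------------
    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("# metasecretome pipeline configuration\n")
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        import ast

        values: dict = {}
        known = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in known:
                    raise ValueError(f"{path}:{lineno}: unknown option {key!r}")
                values[key] = ast.literal_eval(raw.strip())
        return cls(**values).validate()

    def digest(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        meta = {"config_sha256": self.digest()}
        meta.update(asdict(self))
        return meta
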
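"""Pipeline configuration: one YAML file drives the full synthetic study.

Defaults follow the analysis settings of the underlying protocol where
stated (200 bp scoring windows with a 600 bp gap and island FDR < 1e-10;
promoter = TSS +/- 1 kb with 0-1 / 1-3 kb pie windows and a 10 kb gene
margin; 1.5-fold and p < 0.05 differential filter; 2 / 5 / 1.5 kb profile
flanks with 32 bp bins and 5 clusters; 200 bp motif-scan flanks) and use a
scaled-down synthetic genome elsewhere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    n_genes: int = 200
    depth: int = 100_000
    n_samples_per_group: int = 3
    sigma: float = 500.0
    base_fold: float = 8.0
    n_enriched: int = 120
    n_diff_up: int = 15
    n_diff_down: int = 15
    diff_fold: float = 3.0
    spotlight_fold: float = 2.3
    n_weak: int = 40
    weak_fold: float = 2.4
    fold_spread: float = 2.0
    gene_length_range: tuple[int, int] = (2000, 10000)
    qpcr_replicates: int = 3


@dataclass
class IslandConfig:
    bin_size: int = 32
    window: int = 200
    gap: int = 600
    window_p: float = 0.2
    fdr_cutoff: float = 1e-10


@dataclass
class AnnotationConfig:
    proximal_bp: int = 1000
    distal_bp: int = 3000
    gene_margin: int = 10_000
    utr_fraction: float = 0.1


@dataclass
class DifferentialConfig:
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    pseudo: float = 0.5
    promoter_half: int = 1000


@dataclass
class ProfileConfig:
    gene_flank: int = 2000
    region_flank: int = 5000
    promoter_flank: int = 1500
    bin_size: int = 32
    k: int = 5
    meta_length: int = 2000
    make_plots: bool = False


@dataclass
class MotifConfig:
    flank: int = 200
    cutoff: float = 0.85
    mean_planted_sites: float = 2.5


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    islands: IslandConfig = field(default_factory=IslandConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    profiles: ProfileConfig = field(default_factory=ProfileConfig)
    motifs: MotifConfig = field(default_factory=MotifConfig)

    def __post_init__(self) -> None:
        for name in ("proximal_bp", "distal_bp", "gene_margin"):
            if getattr(self.annotation, name) <= 0:
                raise ValueError(f"annotation.{name} must be > 0")
        for name in ("gene_flank", "region_flank", "promoter_flank"):
            if getattr(self.profiles, name) <= 0:
                raise ValueError(f"profiles.{name} must be > 0")

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return [clean(v) for v in x]
            return x

        return clean(asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kw = {}
        sections = {f.name: f for f in fields(cls)}
        for key, value in (data or {}).items():
            if key not in sections:
                raise ValueError(f"unknown config section {key!r}")
            f = sections[key]
            if key == "seed":
                kw[key] = int(value)
                continue
            sub_cls = f.default_factory  # type: ignore[union-attr]
            known = {sf.name for sf in fields(sub_cls)}
            bad = set(value) - known
            if bad:
                raise ValueError(f"unknown keys in {key}: {sorted(bad)}")
            if "gene_length_range" in value:
                value = dict(value)
                value["gene_length_range"] = tuple(value["gene_length_range"])
            kw[key] = sub_cls(**value)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
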
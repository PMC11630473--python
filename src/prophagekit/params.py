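"""Parameter containers for every pipeline stage.

Each dataclass carries the constants of one stage with the published
defaults; every value can be overridden through the pipeline config or
the CLI.  Keeping them in one module prevents the same threshold from
drifting apart between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

#: guard for comparisons of exact rational quantities (e.g. ANI 99.90 from
#: 10 substitutions in 10 kb) against decimal threshold literals
EPS = 1e-9


@dataclass
class DetectionParams:
    """Constants of the coverage-based induction screen."""

    window_bp: int = 250
    step_bp: int = 50
    min_contig_stats_bp: int = 80_000
    slice_threshold_bp: int = 350_000
    slice_max_bp: int = 300_000
    extreme_factor: float = 3.0
    plasmid_min_bp: int = 5_000
    plasmid_max_bp: int = 80_000
    short_elem_min_bp: int = 500
    short_elem_max_bp: int = 1_500
    short_factor: float = 3.0
    long_factor: float = 1.0
    merge_gap_bp: int = 1_000
    min_reads: int = 250_000
    min_identity: float = 0.99
    min_aln_len: int = 50
    min_read_fraction: float = 0.80
    # border refinement (tier-1 clip evidence); unstated upstream, exposed here
    clip_min_reads: int = 3
    clip_agree_bp: int = 5
    clip_search_bp: int = 500

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"DetectionParams.{name} must be positive, got {value}")
        if self.short_elem_min_bp >= self.short_elem_max_bp:
            raise ValueError("short element range must be non-empty")


@dataclass
class CurationRule:
    """Gene-content rules deciding which candidate elements are prophages."""

    min_genes: int = 5
    min_keyword_genes: int = 2
    # realm marker labels, matched case-insensitively as substrings
    marker_labels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "tailless": ("double jelly-roll capsid", "double jelly roll capsid",
                         "double jelly-roll major capsid"),
            "filamentous": ("pi-like atpase", "zonular occludens toxin",
                            "bpphl_gene_1_protein", "bpfd_gene_1_protein"),
            "tailed": ("terminase large subunit", "terminase endonuclease subunit",
                       "major capsid protein"),
        }
    )
    keywords: tuple[str, ...] = (
        "coat", "capsid", "head", "tail", "virion", "phage", "holin",
        "terminase", "replication", "packaging",
        "vpf81", "bpphl_gene_1_protein", "bpfd_gene_1_protein",
    )
    size_min_bp: dict[str, int] = field(
        default_factory=lambda: {
            "filamentous": 4_000,
            "other": 4_000,
            "tailless": 10_000,
            "tailed": 25_000,
        }
    )
    # short-motif integration-site search
    dif_max_mismatches: int = 4
    dif_seed_len: int = 12


@dataclass
class SimilarityParams:
    """Fragment-based ANI estimation and pair/dereplication thresholds."""

    ani_threshold: float = 99.9      # percent
    coverage_threshold: float = 1.0  # fraction of the shorter sequence
    fragment_bp: int = 1_000
    min_last_fragment_bp: int = 500
    kmer_seed: int = 15
    derep_identity: float = 99.9     # percent
    derep_coverage: float = 0.8      # fraction of the shorter sequence

    def validate(self) -> None:
        if not (0 < self.ani_threshold <= 100 and 0 < self.derep_identity <= 100):
            raise ValueError("identity thresholds must be in (0, 100]")
        if not (0 < self.coverage_threshold <= 1 and 0 < self.derep_coverage <= 1):
            raise ValueError("coverage thresholds must be in (0, 1]")


@dataclass
class MCLParams:
    """Markov-Clustering parameters for protein-family inference."""

    inflation: float = 3.0
    prune: float = 1e-6
    max_iter: int = 200
    tol: float = 1e-8
    weight_cap: float = 200.0
    core_threshold: float = 0.8      # family frequency strictly above -> core
    variable_threshold: float = 0.3  # family frequency at or below -> variable
    min_cluster_members: int = 5


def params_to_dict(obj: Any) -> dict:
    """Serialize a parameter dataclass for run reports."""
    d = asdict(obj)
    for k, v in d.items():
        if isinstance(v, dict):
            d[k] = {kk: list(vv) if isinstance(vv, tuple) else vv for kk, vv in v.items()}
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d
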
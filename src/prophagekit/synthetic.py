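"""Synthetic inputs with the statistical structure the analysis assumes.

Real induction experiments yield sequencing reads mapped onto reference
genomes; here every downstream stage is exercised on generated data with
known ground truth instead:

* per-base depth profiles with negative-binomial background noise (the
  usual overdispersed model for sequencing depth; a Poisson switch is
  provided), planted elevated-coverage prophage regions with a known
  fold (the true phage-to-host ratio) and multi-copy plasmid contigs;
* clipped-alignment records marking excision junctions at the planted
  borders;
* nucleotide sequences with an exact number of substitutions, for ANI
  fixtures;
* phage "pangenome" clusters with conserved core gene order and a
  planted variable locus;
* gene-annotation tables with planted viral marker/keyword labels.

Every generator takes an explicit seed and emits a :class:`TruthSet`
describing what was planted; identical configuration yields identical
output bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import AlignmentRecord, DepthProfile

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class PlantedElement:
    """A prophage region planted into a contig, 0-based half-open."""

    contig: str
    start: int
    end: int
    fold: float
    realm: str = "tailed"  # tailless | filamentous | tailed | none

    def __post_init__(self) -> None:
        if self.end - self.start < 500:
            raise ValueError("planted elements must be at least 500 bp")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1 (a planted element is elevated)")


@dataclass
class SimulationConfig:
    seed: int
    contig_lengths: Sequence[int] = (1_000_000,)
    contig_names: Optional[Sequence[str]] = None
    background_mean: float = 50.0
    dispersion: float = 5.0          # negative-binomial size parameter
    noise: str = "nb"                # nb | poisson
    planted_elements: Sequence[PlantedElement] = ()
    plasmids: Sequence[tuple[int, float]] = ()  # (length bp, copy number >= 1)
    clip_reads_per_border: int = 3

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.contig_lengths):
            raise ValueError("contig lengths must be positive")
        if any(cn < 1 for _, cn in self.plasmids):
            raise ValueError("plasmid copy number must be >= 1")
        if self.noise not in ("nb", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.contig_names is None:
            self.contig_names = [f"contig_{i+1}" for i in range(len(self.contig_lengths))]
        if len(self.contig_names) != len(self.contig_lengths):
            raise ValueError("contig_names/contig_lengths length mismatch")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class TruthSet:
    """Ground truth emitted alongside every synthetic artifact."""

    elements: list[PlantedElement] = field(default_factory=list)
    plasmid_contigs: dict[str, float] = field(default_factory=dict)  # name -> copy number
    marker_genes: dict[str, list[str]] = field(default_factory=dict)  # element -> gene ids
    expected_decisions: dict[str, dict] = field(default_factory=dict)  # element -> decision
    variable_loci: dict[str, tuple[int, int]] = field(default_factory=dict)  # genome -> gene-index span
    family_classes: dict[str, str] = field(default_factory=dict)  # family -> core|variable
    pairwise_identities: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "elements": [asdict(e) for e in self.elements],
            "plasmid_contigs": self.plasmid_contigs,
            "marker_genes": self.marker_genes,
            "expected_decisions": self.expected_decisions,
            "variable_loci": {k: list(v) for k, v in self.variable_loci.items()},
            "family_classes": self.family_classes,
            "pairwise_identities": {f"{a}|{b}": v for (a, b), v in self.pairwise_identities.items()},
        }
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float,
                noise: str, n: int) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(mean, size=n)
    # NB with mean m and size r: p = r / (r + m), variance m + m^2/r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def simulate_depth_profile(config: SimulationConfig) -> tuple[DepthProfile, TruthSet]:
    """Generate a per-base depth profile with planted elevated regions.

    Background depth is drawn i.i.d. per base from a negative binomial
    with the configured mean and dispersion (or Poisson); within planted
    elements the mean is multiplied by the element's fold; plasmid
    contigs are whole extra contigs whose mean is multiplied by the copy
    number.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()

    by_contig: dict[str, list[PlantedElement]] = {}
    for el in config.planted_elements:
        if el.contig not in config.contig_names:
            raise ValueError(f"planted element on unknown contig {el.contig!r}")
        by_contig.setdefault(el.contig, []).append(el)
    for contig, els in by_contig.items():
        els.sort(key=lambda e: e.start)
        length = config.contig_lengths[list(config.contig_names).index(contig)]
        prev_end = 0
        for el in els:
            if el.start < prev_end:
                raise ValueError(f"overlapping planted elements on {contig}")
            if el.end > length:
                raise ValueError(f"planted element exceeds contig bounds on {contig}")
            prev_end = el.end

    depths: dict[str, np.ndarray] = {}
    for name, length in zip(config.contig_names, config.contig_lengths):
        arr = _draw_depth(rng, config.background_mean, config.dispersion,
                          config.noise, length)
        for el in by_contig.get(name, ()):
            arr[el.start:el.end] = _draw_depth(
                rng, config.background_mean * el.fold, config.dispersion,
                config.noise, el.end - el.start,
            )
            truth.elements.append(el)
        depths[name] = arr

    for i, (length, copy_number) in enumerate(config.plasmids):
        name = f"plasmid_{i+1}"
        depths[name] = _draw_depth(
            rng, config.background_mean * copy_number, config.dispersion,
            config.noise, length,
        )
        truth.plasmid_contigs[name] = float(copy_number)

    return DepthProfile(depths), truth


def simulate_clipped_alignments(
    truth: TruthSet,
    reads_per_border: int,
    read_len: int,
    seed: int,
    n_background: int = 50,
) -> list[AlignmentRecord]:
    """Alignment records carrying clip evidence at every planted border.

    For each border of each planted element exactly ``reads_per_border``
    records clip at the true border position, plus unclipped background
    records scattered over the contig.
    """
    if read_len < 50:
        raise ValueError("read_len must be >= 50 bp (alignment-length filter)")
    if reads_per_border < 0:
        raise ValueError("reads_per_border must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    for el in truth.elements:
        for border, inside in ((el.start, True), (el.end, False)):
            for k in range(reads_per_border):
                # read half inside the element, half outside; clip at border
                if inside:
                    start, end = border, border + read_len // 2
                else:
                    start, end = max(0, border - read_len // 2), border
                records.append(
                    AlignmentRecord(
                        read_id=f"clip_{el.contig}_{border}_{k}",
                        contig=el.contig,
                        start=start,
                        end=max(end, start + 1),
                        identity=1.0,
                        aligned_read_fraction=0.5,
                        is_primary=True,
                        clip_positions=[border],
                    )
                )
    contigs = sorted({el.contig for el in truth.elements}) or ["contig_1"]
    for k in range(n_background):
        contig = contigs[k % len(contigs)]
        start = int(rng.integers(0, 1_000_000))
        records.append(
            AlignmentRecord(
                read_id=f"bg_{k}", contig=contig, start=start,
                end=start + read_len, identity=1.0,
                aligned_read_fraction=1.0, is_primary=True,
            )
        )
    return records


def sample_study_config(
    seed: int,
    genome_bp: int = 1_000_000,
    background_mean: float = 50.0,
    dispersion: float = 5.0,
    n_elements_range: tuple[int, int] = (1, 5),
    fold_range: tuple[float, float] = (5.0, 20.0),
    length_range: tuple[int, int] = (2_000, 40_000),
    margin_bp: int = 5_000,
) -> SimulationConfig:
    """Draw one random genome configuration under the study conditions.

    One 1-Mb contig with negative-binomial background (mean 50, size 5)
    and 1-5 planted elements with folds of 5-20 and lengths of 2-40 kb,
    placed non-overlapping with a safety margin from contig ends and
    from each other.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_elements_range[0], n_elements_range[1] + 1))
    elements: list[PlantedElement] = []
    for _ in range(200):  # rejection placement
        if len(elements) == n:
            break
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(margin_bp, genome_bp - margin_bp - length))
        end = start + length
        if all(end + margin_bp <= e.start or start >= e.end + margin_bp
               for e in elements):
            fold = float(rng.uniform(*fold_range))
            elements.append(PlantedElement("contig_1", start, end, fold))
    elements.sort(key=lambda e: e.start)
    return SimulationConfig(
        seed=seed,
        contig_lengths=[genome_bp],
        background_mean=background_mean,
        dispersion=dispersion,
        planted_elements=elements,
    )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def random_sequence(length: int, seed: int) -> str:
    """Uniform random nucleotide sequence."""
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, n_subs: int, seed: int) -> str:
    """Introduce exactly ``n_subs`` substitutions at distinct positions.

    Each substituted base is replaced by a different base, so the Hamming
    distance of the result from the input is exactly ``n_subs``.
    """
    if n_subs < 0:
        raise ValueError("n_subs must be >= 0")
    if n_subs > len(seq):
        raise ValueError("n_subs exceeds sequence length")
    rng = np.random.default_rng(seed)
    arr = np.array(list(seq))
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# phage pangenome clusters
# ---------------------------------------------------------------------------

def generate_phage_cluster(
    n_genomes: int,
    n_core_families: int,
    variable_pool_size: int,
    locus_slot: int,
    variable_genes_per_genome: int,
    seed: int,
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """A cluster of related phage genomes with a planted variable locus.

    Every genome carries all core families in identical order; the locus
    slot (between core families ``locus_slot-1`` and ``locus_slot``)
    receives each genome's variable genes, drawn from a shared pool under
    the constraint that no variable family ends up in more than 30% of
    genomes.  Returns per-genome ordered gene tables (columns gene_id,
    family, order_index) plus the truth (locus gene-index span per genome
    and planted family classes).
    """
    if n_genomes < 2:
        raise ValueError("need at least 2 genomes")
    if not (1 <= locus_slot <= n_core_families - 1):
        raise ValueError("locus_slot must fall between two core families")
    max_per_family = int(np.floor(0.3 * n_genomes))
    if variable_genes_per_genome > 0 and max_per_family == 0:
        raise ValueError("cluster too small to keep variable families at <=30%")
    demand = n_genomes * variable_genes_per_genome
    if demand > variable_pool_size * max_per_family:
        raise ValueError(
            "variable pool too small to keep every family at <=30% frequency"
        )
    rng = np.random.default_rng(seed)
    core = [f"core_{i}" for i in range(n_core_families)]
    pool = [f"var_{i}" for i in range(variable_pool_size)]
    counts = {f: 0 for f in pool}

    tables: dict[str, pd.DataFrame] = {}
    truth = TruthSet()
    for f in core:
        truth.family_classes[f] = "core"

    for g in range(n_genomes):
        genome = f"phage_{g:03d}"
        available = [f for f in pool if counts[f] < max_per_family]
        chosen = list(rng.choice(available, size=variable_genes_per_genome, replace=False)) \
            if variable_genes_per_genome else []
        for f in chosen:
            counts[f] += 1
            truth.family_classes[f] = "variable"
        families = core[:locus_slot] + chosen + core[locus_slot:]
        rows = [
            {"gene_id": f"{genome}_g{i:02d}", "family": fam, "order_index": i}
            for i, fam in enumerate(families)
        ]
        tables[genome] = pd.DataFrame(rows)
        if chosen:
            truth.variable_loci[genome] = (locus_slot, locus_slot + len(chosen) - 1)
    return tables, truth


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

@dataclass
class ElementPlan:
    """Plan for one candidate element in an annotation fixture."""

    element_id: str
    n_genes: int
    marker_realm: Optional[str] = None   # plant one realm marker gene
    n_keyword_genes: int = 0             # plant this many keyword-bearing genes

    MARKER_LABEL = {
        "tailed": "terminase large subunit",
        "filamentous": "pI-like ATPase",
        "tailless": "double jelly-roll capsid protein",
    }
    KEYWORD_LABELS = ("putative holin", "tail fiber protein", "phage replication protein",
                      "DNA packaging protein", "minor coat protein")


def generate_annotation_fixture(
    plans: Sequence[ElementPlan], seed: int
) -> tuple[pd.DataFrame, TruthSet]:
    """Gene annotation tables with planted marker/keyword labels.

    Emits one table (element_id, gene_id, source, label, evalue) and a
    truth set recording the expected curation decision per element:
    accept iff >= 5 genes and (a marker gene is planted, or >= 2 keyword
    genes are planted); realm follows the planted marker, else "other".
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = TruthSet()
    for plan in plans:
        special = int(plan.marker_realm is not None) + plan.n_keyword_genes
        if special > plan.n_genes:
            raise ValueError(f"{plan.element_id}: more planted labels than genes")
        labels = []
        if plan.marker_realm is not None:
            labels.append(ElementPlan.MARKER_LABEL[plan.marker_realm])
            truth.marker_genes[plan.element_id] = []
        for k in range(plan.n_keyword_genes):
            labels.append(ElementPlan.KEYWORD_LABELS[k % len(ElementPlan.KEYWORD_LABELS)])
        while len(labels) < plan.n_genes:
            labels.append("hypothetical protein")
        order = rng.permutation(len(labels))
        for i, j in enumerate(order):
            gene_id = f"{plan.element_id}_g{i:02d}"
            rows.append(
                {
                    "element_id": plan.element_id,
                    "gene_id": gene_id,
                    "source": "synthetic_annotation",
                    "label": labels[j],
                    "evalue": float(10.0 ** -rng.integers(6, 60)),
                }
            )
            if plan.marker_realm is not None and labels[j] == ElementPlan.MARKER_LABEL[plan.marker_realm]:
                truth.marker_genes[plan.element_id].append(gene_id)
        accept = plan.n_genes >= 5 and (
            plan.marker_realm is not None or plan.n_keyword_genes >= 2
        )
        truth.expected_decisions[plan.element_id] = {
            "accepted": accept,
            "realm": plan.marker_realm if (accept and plan.marker_realm) else
                     ("other" if accept else None),
            "rule_path": ("marker" if plan.marker_realm else "keyword") if accept else (
                "rejected_genes" if plan.n_genes < 5 else "rejected_content"
            ),
        }
    return pd.DataFrame(rows), truth
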
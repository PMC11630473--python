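"""Gene-content curation of candidate elements and integration-site tools.

A coverage peak or genomic island is only called a prophage when its gene
content says so: at least five genes and either a realm-defining marker
gene (terminase / major capsid for tailed phages, pI-like ATPase for
filamentous, double jelly-roll capsid for tailless) or at least two genes
whose annotation text suggests a viral origin.  Accepted elements get a
viral realm and must pass a realm-specific minimum genome size.  The
module also locates short dif-site motifs (the chromosome-dimer-resolution
sites filamentous phages integrate into) and summarizes integration-
hotspot occupancy across strains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import CurationRule

logger = logging.getLogger(__name__)

REALMS = ("tailless", "filamentous", "tailed")  # marker precedence order


@dataclass
class GeneCall:
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    labels: list[tuple[str, str, float]] = field(default_factory=list)  # (source, text, evalue)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")


@dataclass
class CurationDecision:
    element_id: str
    accepted: bool
    rule_path: str  # marker | keyword | rejected_size | rejected_genes | rejected_content
    realm: Optional[str] = None
    evidence_genes: list[str] = field(default_factory=list)


def _label_texts(gene: GeneCall) -> list[str]:
    return [text.lower() for _, text, _ in gene.labels]


def match_keywords(label: str, rule: CurationRule | None = None) -> Optional[str]:
    """First keyword occurring in the label, case-insensitive substring."""
    rule = rule or CurationRule()
    low = label.lower()
    for kw in rule.keywords:
        if kw in low:
            return kw
    return None


def _gene_marker_realms(gene: GeneCall, rule: CurationRule) -> list[str]:
    texts = _label_texts(gene)
    return [
        realm
        for realm in REALMS
        if any(m in t for m in rule.marker_labels[realm] for t in texts)
    ]


def classify_candidate(
    genes: Sequence[GeneCall], rule: CurationRule | None = None,
    element_id: str = "element",
) -> CurationDecision:
    """Accept an element as a putative prophage from its gene content.

    Rejected below five genes; accepted via the marker rule if any gene
    carries a realm marker label, else via the keyword rule if at least
    two distinct genes match viral keywords; otherwise rejected.
    """
    rule = rule or CurationRule()
    if len(genes) < rule.min_genes:
        return CurationDecision(element_id, False, "rejected_genes")

    marker_genes = [g for g in genes if _gene_marker_realms(g, rule)]
    if marker_genes:
        realm = assign_realm(genes, rule)
        return CurationDecision(
            element_id, True, "marker", realm, [g.gene_id for g in marker_genes]
        )

    keyword_genes = [
        g for g in genes if any(match_keywords(t) for t in _label_texts(g))
    ]
    if len(keyword_genes) >= rule.min_keyword_genes:
        return CurationDecision(
            element_id, True, "keyword", "other", [g.gene_id for g in keyword_genes]
        )
    return CurationDecision(element_id, False, "rejected_content")


def assign_realm(genes: Sequence[GeneCall], rule: CurationRule | None = None) -> str:
    """Viral realm from marker genes, precedence tailless > filamentous > tailed.

    Conflicting markers (possible in mis-merged co-integrated elements)
    are logged and resolved by precedence; no marker yields "other".
    """
    rule = rule or CurationRule()
    present = [r for r in REALMS if any(r in _gene_marker_realms(g, rule) for g in genes)]
    if not present:
        return "other"
    if len(present) > 1:
        logger.warning("conflicting realm markers %s; using %s", present, present[0])
    return present[0]


def size_filter(length_bp: int, realm: str, rule: CurationRule | None = None) -> bool:
    """Realm-specific minimum genome size (inclusive threshold)."""
    rule = rule or CurationRule()
    threshold = rule.size_min_bp.get(realm, rule.size_min_bp["other"])
    return length_bp >= threshold


def curate_elements(
    genes_by_element: dict[str, Sequence[GeneCall]],
    element_lengths: dict[str, int],
    rule: CurationRule | None = None,
) -> list[CurationDecision]:
    """Full curation: gene-content rules followed by the size filter."""
    rule = rule or CurationRule()
    decisions = []
    for element_id, genes in genes_by_element.items():
        d = classify_candidate(genes, rule, element_id)
        if d.accepted and element_id in element_lengths:
            if not size_filter(element_lengths[element_id], d.realm, rule):
                d = CurationDecision(element_id, False, "rejected_size", d.realm,
                                     d.evidence_genes)
        decisions.append(d)
    return decisions


# ---------------------------------------------------------------------------
# dif-site search
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def find_dif_sites(
    genome: str,
    queries: dict[str, str],
    max_mismatches: int | None = None,
    rule: CurationRule | None = None,
    contig: str = "contig",
) -> pd.DataFrame:
    """All ungapped placements of short dif-site motifs with few mismatches.

    Every position of the genome is compared against each query on both
    strands (vectorized Hamming comparison over all alignment offsets, so
    no valid placement can be missed); hits with at most ``max_mismatches``
    mismatches are reported sorted by position.  Queries are expected to
    be short conserved motifs (20-40 bp); anything shorter than the seed
    length bound is rejected.
    """
    rule = rule or CurationRule()
    if max_mismatches is None:
        max_mismatches = rule.dif_max_mismatches
    g = _seq_to_codes(genome)
    hits = []
    for name, query in queries.items():
        if len(query) < rule.dif_seed_len:
            raise ValueError(f"query {name!r} shorter than {rule.dif_seed_len} bp")
        for strand, qseq in (("+", query), ("-", reverse_complement(query))):
            q = _seq_to_codes(qseq)
            if len(g) < len(q):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(g, len(q))
            mism = (windows != q).sum(axis=1)
            for pos in np.flatnonzero(mism <= max_mismatches):
                hits.append(
                    {"query": name, "contig": contig, "position": int(pos),
                     "strand": strand, "mismatches": int(mism[pos])}
                )
    df = pd.DataFrame(hits, columns=["query", "contig", "position", "strand", "mismatches"])
    return df.sort_values(["position", "query", "strand"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# hotspot occupancy
# ---------------------------------------------------------------------------

def hotspot_occupancy(site_table: pd.DataFrame) -> pd.DataFrame:
    """Fill fraction and occupant composition per integration site.

    ``site_table`` is strains x sites; cells hold the occupant class
    (e.g. a viral realm) or NaN/empty for an unoccupied site.  Returns,
    per site, fill percent (occupied strains / total strains x 100) and
    the occupant-class composition.
    """
    total = len(site_table)
    rows = []
    for site in site_table.columns:
        col = site_table[site]
        occupied = col.notna() & (col.astype(str).str.len() > 0)
        comp = col[occupied].value_counts().to_dict()
        rows.append(
            {
                "site": site,
                "n_strains": total,
                "n_occupied": int(occupied.sum()),
                "fill_percent": round(100.0 * occupied.sum() / total, 1) if total else 0.0,
                "composition": comp,
            }
        )
    return pd.DataFrame(rows)
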
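"""Pairwise prophage similarity: fragment-based ANI, transfer pairs,
dereplication and host-metadata summaries.

Average nucleotide identity (ANI) is estimated the fragment-mapping way:
the shorter sequence is cut into consecutive 1-kb fragments, each
fragment is placed at its best location in the other sequence (exact
15-mer seed check, then an infix alignment), and ANI is the
length-weighted identity over mapped fragments.  Pairs at >= 99.9% ANI
with complete coverage of the shorter sequence mark prophages that
recently descended from a common ancestor (vertical inheritance or
fresh horizontal transfer); the same machinery drives greedy 99.9%
dereplication.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import pandas as pd

from .params import SimilarityParams, EPS


@dataclass
class ProphageSeq:
    id: str
    sequence: str
    host_strain: str = ""
    host_species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"prophage {self.id}: empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ProphagePair:
    id_a: str
    id_b: str
    ani: float        # percent
    coverage: float   # fraction of the shorter sequence covered

    def __post_init__(self) -> None:
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _fragments(seq: str, params: SimilarityParams) -> list[str]:
    """Consecutive fragments of the query; a short trailing fragment is
    kept only if at least min_last_fragment_bp long.  Sequences shorter
    than one fragment are used whole."""
    f = params.fragment_bp
    if len(seq) < f:
        return [seq]
    frags = [seq[i:i + f] for i in range(0, len(seq), f)]
    if len(frags[-1]) < params.min_last_fragment_bp:
        frags.pop()
    return frags


def _map_fragments(query: str, target: str, target_kmers: set[str],
                   params: SimilarityParams) -> tuple[int, int, int]:
    """Map query fragments into target.

    Returns (mapped_bases, total_edit_distance, query_length_considered).
    A fragment counts as mapped only if it shares an exact k-mer seed
    with the target (rejects unrelated sequence before alignment).
    """
    k = params.kmer_seed
    mapped = 0
    edits = 0
    considered = 0
    for frag in _fragments(query, params):
        considered += len(frag)
        if not (_kmer_set(frag, k) & target_kmers):
            continue
        res = edlib.align(frag, target, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0 or dist > 0.3 * len(frag):  # no credible placement
            continue
        mapped += len(frag)
        edits += dist
    return mapped, edits, considered


def estimate_ani(
    seq_a: str, seq_b: str, params: SimilarityParams | None = None
) -> tuple[float, float]:
    """Fragment-based ANI and alignment coverage between two sequences.

    ANI (percent) is the identity over all mapped fragment bases,
    averaged over both mapping directions; coverage is the mapped
    fraction of the shorter sequence.
    """
    params = params or SimilarityParams()
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    k = params.kmer_seed

    kmers_a = _kmer_set(seq_a, k)
    kmers_b = _kmer_set(seq_b, k)
    map_ab = _map_fragments(seq_a, seq_b, kmers_b, params)
    map_ba = _map_fragments(seq_b, seq_a, kmers_a, params)

    anis = []
    for mapped, edits, _ in (map_ab, map_ba):
        if mapped > 0:
            anis.append(100.0 * (mapped - edits) / mapped)
    ani = sum(anis) / len(anis) if anis else 0.0

    shorter_maps = [m for m, s in ((map_ab, seq_a), (map_ba, seq_b))
                    if len(s) == min(len(seq_a), len(seq_b))]
    coverage = max(m[0] / m[2] for m in shorter_maps) if shorter_maps else 0.0
    return ani, min(coverage, 1.0)


def find_similar_pairs(
    prophages: Sequence[ProphageSeq], params: SimilarityParams | None = None
) -> list[ProphagePair]:
    """All unordered pairs at >= 99.9% ANI with complete coverage."""
    params = params or SimilarityParams()
    pairs = []
    for a, b in itertools.combinations(sorted(prophages, key=lambda p: p.id), 2):
        ani, cov = estimate_ani(a.sequence, b.sequence, params)
        if ani >= params.ani_threshold - EPS and cov >= params.coverage_threshold - EPS:
            pairs.append(ProphagePair(a.id, b.id, round(ani, 4), round(cov, 4)))
    return pairs


@dataclass
class DereplicationResult:
    representatives: list[str]
    membership: dict[str, str]  # prophage id -> representative id


def dereplicate(
    prophages: Sequence[ProphageSeq], params: SimilarityParams | None = None
) -> DereplicationResult:
    """Greedy longest-first dereplication at 99.9% identity.

    Sequences are visited by decreasing length (ties by id); each joins
    the first existing representative it matches at >= 99.9% ANI and
    >= 80% coverage of the shorter sequence, else founds a new cluster.
    Deterministic by construction.
    """
    params = params or SimilarityParams()
    ordered = sorted(prophages, key=lambda p: (-p.length, p.id))
    reps: list[ProphageSeq] = []
    membership: dict[str, str] = {}
    for p in ordered:
        home = None
        for rep in reps:
            ani, cov = estimate_ani(p.sequence, rep.sequence, params)
            if ani >= params.derep_identity - EPS and cov >= params.derep_coverage - EPS:
                home = rep.id
                break
        if home is None:
            reps.append(p)
            home = p.id
        membership[p.id] = home
    return DereplicationResult([r.id for r in reps], membership)


def summarize_pairs(
    pairs: Sequence[ProphagePair],
    metadata: pd.DataFrame,
    prophage_ids: Optional[Sequence[str]] = None,
) -> dict:
    """Count retained pairs by host strain/species identity; flag uniques.

    ``metadata`` needs columns prophage_id, strain, species.  A prophage
    is unique iff it appears in no retained pair.
    """
    meta = metadata.set_index("prophage_id")
    ids = list(prophage_ids) if prophage_ids is not None else list(meta.index)
    paired: set[str] = set()
    same_strain = same_species = diff_species = 0
    for pair in pairs:
        for pid in (pair.id_a, pair.id_b):
            if pid not in meta.index:
                raise KeyError(f"no host metadata for prophage {pid!r}")
        paired.update((pair.id_a, pair.id_b))
        ma, mb = meta.loc[pair.id_a], meta.loc[pair.id_b]
        if ma["strain"] == mb["strain"]:
            same_strain += 1
        elif ma["species"] == mb["species"]:
            same_species += 1
        else:
            diff_species += 1
    unique = [pid for pid in ids if pid not in paired]
    return {
        "n_prophages": len(ids),
        "n_pairs": len(pairs),
        "pairs_same_strain": same_strain,
        "pairs_same_species_diff_strain": same_species,
        "pairs_diff_species": diff_species,
        "n_unique": len(unique),
        "unique_prophages": unique,
    }
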
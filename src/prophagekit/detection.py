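"""Detection of actively induced genomic elements from read-depth profiles.

An induced prophage replicates its genome inside the host cell, so after
chemical induction its chromosomal region shows read coverage well above
the host background.  This module turns a per-base depth profile into a
set of candidate elements:

1. alignment filtering contract (identity/length/read-fraction/primary),
2. per-segment background statistics (median and a "corrected" standard
   deviation that excludes bases above 3x the median, so that the active
   elements themselves do not inflate the background spread),
3. a whole-contig rule for putative plasmid prophages (5-80 kb contigs),
4. sliding-window calling (250 bp windows, 50 bp step) with dual length/
   stringency classes, merging of nearby calls, and
5. hierarchical border refinement (clipped reads > coverage step > gene span).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .params import DetectionParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One read alignment, reduced to the fields the filters need.

    ``clip_positions`` holds reference coordinates where the read was
    soft/hard-clipped (evidence for excision junctions).
    """

    read_id: str
    contig: str
    start: int
    end: int
    identity: float
    aligned_read_fraction: float
    is_primary: bool = True
    clip_positions: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity out of range: {self.identity}")
        if not (0.0 <= self.aligned_read_fraction <= 1.0):
            raise ValueError(f"aligned_read_fraction out of range: {self.aligned_read_fraction}")
        if self.end <= self.start:
            raise ValueError("alignment end must exceed start")


class DepthProfile:
    """Per-contig per-base integer read depth over a reference genome."""

    def __init__(self, depths: dict[str, np.ndarray]):
        self.depths: dict[str, np.ndarray] = {}
        for contig, arr in depths.items():
            a = np.asarray(arr)
            if a.ndim != 1 or len(a) == 0:
                raise ValueError(f"contig {contig}: depth must be a non-empty 1-D array")
            if np.any(a < 0):
                raise ValueError(f"contig {contig}: negative depth")
            self.depths[contig] = a.astype(np.int64, copy=False)

    @property
    def contigs(self) -> list[str]:
        return list(self.depths)

    def length(self, contig: str) -> int:
        return len(self.depths[contig])

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.depths[contig]

    def __eq__(self, other) -> bool:  # used by determinism tests
        if not isinstance(other, DepthProfile):
            return NotImplemented
        return self.contigs == other.contigs and all(
            np.array_equal(self.depths[c], other.depths[c]) for c in self.depths
        )


@dataclass
class Segment:
    contig: str
    start: int
    end: int
    role: str  # background_eligible | plasmid_candidate | too_short

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BackgroundStats:
    """Median depth and corrected SD of a background segment.

    The corrected SD is the population standard deviation over bases with
    depth <= extreme_factor * median, so actively excising elements do not
    inflate the background spread.
    """

    median: float
    corrected_std: float
    n_bases_used: int


@dataclass
class CandidateElement:
    contig: str
    start: int
    end: int
    source: str = "induction"  # induction | island | both
    mean_coverage: float = 0.0
    border_method: str = "raw"  # clip | coverage | gene_span | contig_whole | raw
    cross_contig_link: Optional[str] = None
    element_id: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# alignment-level operations
# ---------------------------------------------------------------------------

def filter_alignments(
    records: Iterable[AlignmentRecord], params: DetectionParams | None = None
) -> Iterator[AlignmentRecord]:
    """Keep primary alignments with identity >= 99%, length >= 50 bp and
    at least 80% of the read aligned.  Malformed entries are skipped and
    counted in a log warning."""
    params = params or DetectionParams()
    skipped = 0
    for rec in records:
        try:
            keep = (
                rec.is_primary
                and rec.identity >= params.min_identity
                and (rec.end - rec.start) >= params.min_aln_len
                and rec.aligned_read_fraction >= params.min_read_fraction
            )
        except (AttributeError, TypeError):
            skipped += 1
            continue
        if keep:
            yield rec
    if skipped:
        logger.warning("filter_alignments: skipped %d malformed records", skipped)


def sample_qc(total_reads: int, params: DetectionParams | None = None) -> bool:
    """A sample is processed only with strictly more than 250 000 reads."""
    params = params or DetectionParams()
    return total_reads > params.min_reads


# ---------------------------------------------------------------------------
# background statistics
# ---------------------------------------------------------------------------

def segment_contigs(
    contig_lengths: dict[str, int], params: DetectionParams | None = None
) -> list[Segment]:
    """Partition contigs into statistics segments.

    Contigs above 350 kb are sliced into ``ceil(L / 300 kb)`` equal pieces
    (the last piece absorbs the division remainder) so slow coverage skew
    along very long contigs does not distort the background estimate;
    80-350 kb contigs form one segment; 5-80 kb contigs are plasmid
    candidates; anything shorter is ignored for calling.
    """
    params = params or DetectionParams()
    segments: list[Segment] = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig}: non-positive length")
        if length < params.plasmid_min_bp:
            segments.append(Segment(contig, 0, length, "too_short"))
        elif length < params.min_contig_stats_bp:
            segments.append(Segment(contig, 0, length, "plasmid_candidate"))
        elif length <= params.slice_threshold_bp:
            segments.append(Segment(contig, 0, length, "background_eligible"))
        else:
            k = math.ceil(length / params.slice_max_bp)
            piece = length // k
            for i in range(k):
                start = i * piece
                end = length if i == k - 1 else (i + 1) * piece
                segments.append(Segment(contig, start, end, "background_eligible"))
    return segments


def background_stats(
    depths: np.ndarray, params: DetectionParams | None = None
) -> BackgroundStats:
    """Median and corrected (population) SD of one background segment."""
    params = params or DetectionParams()
    depths = np.asarray(depths)
    if len(depths) == 0:
        raise ValueError("empty segment")
    med = float(np.median(depths))
    kept = depths[depths <= params.extreme_factor * med]
    if len(kept) == 0:  # median 0 with all-positive extremes; degenerate
        return BackgroundStats(med, 0.0, 0)
    return BackgroundStats(med, float(np.std(kept)), int(len(kept)))


def call_plasmid_contig(
    contig_depths: np.ndarray,
    genome_median: float,
    params: DetectionParams | None = None,
) -> bool:
    """Whole-contig high-coverage rule for 5-80 kb contigs.

    Flagged iff median(contig) > genome_median + 1 * corrected_std(contig)
    (strict inequality).
    """
    params = params or DetectionParams()
    n = len(contig_depths)
    if not (params.plasmid_min_bp <= n < params.plasmid_max_bp):
        raise ValueError(f"contig length {n} outside plasmid candidate range")
    st = background_stats(contig_depths, params)
    return st.median > genome_median + 1.0 * st.corrected_std


# ---------------------------------------------------------------------------
# sliding-window calling
# ---------------------------------------------------------------------------

def sliding_window_means(
    depths: np.ndarray, params: DetectionParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Mean depth of 250-bp windows every 50 bp.

    Returns ``(starts, means)``; a trailing partial window is dropped.
    Contigs shorter than one window yield empty arrays.
    """
    params = params or DetectionParams()
    depths = np.asarray(depths, dtype=np.float64)
    w, s = params.window_bp, params.step_bp
    if len(depths) < w:
        return np.empty(0, dtype=np.int64), np.empty(0)
    view = np.lib.stride_tricks.sliding_window_view(depths, w)[::s]
    means = view.mean(axis=1)
    starts = np.arange(len(means), dtype=np.int64) * s
    return starts, means


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_idx, last_idx) inclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def call_high_coverage_regions(
    window_starts: np.ndarray,
    window_means: np.ndarray,
    stats: BackgroundStats | Sequence[BackgroundStats],
    contig: str = "contig",
    params: DetectionParams | None = None,
    stats_index: Optional[np.ndarray] = None,
) -> list[CandidateElement]:
    """Two-pass element calling over per-window mean coverage.

    Pass 1 keeps maximal runs of windows exceeding median + 1*sd whose base
    span is > 1500 bp; pass 2 keeps runs exceeding median + 3*sd with a span
    of 500-1500 bp.  The element span is the union of member-window
    intervals.  ``stats`` may be one BackgroundStats or a list addressed by
    ``stats_index`` (per-window segment assignment for sliced contigs).
    """
    params = params or DetectionParams()
    window_starts = np.asarray(window_starts)
    window_means = np.asarray(window_means)
    if len(window_means) == 0:
        return []

    if isinstance(stats, BackgroundStats):
        med = np.full(len(window_means), stats.median)
        sd = np.full(len(window_means), stats.corrected_std)
        if stats.corrected_std == 0:
            logger.info("corrected std is 0 on %s; any excess over median qualifies", contig)
    else:
        if stats_index is None:
            raise ValueError("stats_index required when passing multiple BackgroundStats")
        med = np.array([stats[i].median for i in stats_index])
        sd = np.array([stats[i].corrected_std for i in stats_index])

    w = params.window_bp

    def runs_to_elements(mask, lo_span, hi_span):
        out = []
        for a, b in _runs(mask):
            start = int(window_starts[a])
            end = int(window_starts[b]) + w
            span = end - start
            if lo_span <= span and (hi_span is None or span <= hi_span):
                mean_cov = float(window_means[a:b + 1].mean())
                out.append(CandidateElement(contig, start, end, "induction", mean_cov))
        return out

    high1 = window_means > med + params.long_factor * sd
    high3 = window_means > med + params.short_factor * sd
    elements = runs_to_elements(high1, params.short_elem_max_bp + 1, None)
    elements += runs_to_elements(high3, params.short_elem_min_bp, params.short_elem_max_bp)

    # pass-2 calls inside a pass-1 run are the same region: merge overlaps
    elements.sort(key=lambda e: (e.start, e.end))
    merged: list[CandidateElement] = []
    for el in elements:
        if merged and el.start <= merged[-1].end:
            prev = merged[-1]
            prev.end = max(prev.end, el.end)
        else:
            merged.append(el)
    return merged


def merge_elements(
    elements: list[CandidateElement],
    contig_order: Optional[Sequence[str]] = None,
    contig_lengths: Optional[dict[str, int]] = None,
    params: DetectionParams | None = None,
) -> list[CandidateElement]:
    """Merge same-contig elements closer than 1000 bp; annotate (never
    concatenate) elements facing each other across adjacent contig ends."""
    params = params or DetectionParams()
    gap = params.merge_gap_bp
    by_contig: dict[str, list[CandidateElement]] = {}
    for el in elements:
        by_contig.setdefault(el.contig, []).append(el)

    out: list[CandidateElement] = []
    for contig, els in by_contig.items():
        els.sort(key=lambda e: (e.start, e.end))
        acc = [els[0]]
        for el in els[1:]:
            prev = acc[-1]
            if el.start - prev.end < gap:
                prev.end = max(prev.end, el.end)
                prev.source = prev.source if prev.source == el.source else "both"
                prev.mean_coverage = max(prev.mean_coverage, el.mean_coverage)
            else:
                acc.append(el)
        out.extend(acc)

    if contig_order and contig_lengths:
        for i, el in enumerate(out):
            el.element_id = el.element_id or f"elem_{el.contig}_{el.start}"
        for c_a, c_b in zip(contig_order, contig_order[1:]):
            if c_a not in contig_lengths:
                continue
            tail = [e for e in out if e.contig == c_a
                    and contig_lengths[c_a] - e.end < gap]
            head = [e for e in out if e.contig == c_b and e.start < gap]
            for ea in tail:
                for eb in head:
                    ea.cross_contig_link = eb.element_id
                    eb.cross_contig_link = ea.element_id

    out.sort(key=lambda e: (e.contig, e.start))
    return out


# ---------------------------------------------------------------------------
# border refinement
# ---------------------------------------------------------------------------

def _modal_clip(positions: list[int], agree_bp: int, min_reads: int) -> Optional[int]:
    """Most supported clip position if >= min_reads agree within +/- agree_bp."""
    if not positions:
        return None
    positions = sorted(positions)
    best_pos, best_n = None, 0
    for p in positions:
        group = [q for q in positions if abs(q - p) <= agree_bp]
        if len(group) > best_n:
            best_n = len(group)
            best_pos = int(np.median(group))
    if best_n >= min_reads:
        return best_pos
    return None


def refine_borders(
    element: CandidateElement,
    clip_records: Optional[Sequence[AlignmentRecord]] = None,
    depths: Optional[np.ndarray] = None,
    island_span: Optional[tuple[int, int]] = None,
    gene_calls: Optional[Sequence[tuple[int, int]]] = None,
    params: DetectionParams | None = None,
) -> tuple[int, int, str]:
    """Hierarchical border refinement.

    Tier 1: clipped reads pinpoint the excision junction exactly — if at
    least 3 clips agree within +/-5 bp on a position within 500 bp of a
    candidate border, use the modal clip position.  Tier 2 (induction
    elements): the position of maximal absolute change of the 250-bp
    smoothed depth within +/-500 bp of each border.  Tier 3: clamp to the
    first/last gene of the island span.  If no tier applies the raw window
    borders are kept.
    """
    params = params or DetectionParams()
    radius = params.clip_search_bp

    def clip_near(border: int) -> Optional[int]:
        if not clip_records:
            return None
        near = [
            p
            for rec in clip_records
            if rec.contig == element.contig and rec.clip_positions
            for p in rec.clip_positions
            if abs(p - border) <= radius
        ]
        return _modal_clip(near, params.clip_agree_bp, params.clip_min_reads)

    start_clip = clip_near(element.start)
    end_clip = clip_near(element.end)
    if start_clip is not None and end_clip is not None:
        return start_clip, end_clip, "clip"

    if depths is not None and element.source in ("induction", "both"):
        depths = np.asarray(depths, dtype=np.float64)
        w = params.window_bp
        # contrast between the mean of the next window and the previous
        # window; peaks exactly at an ideal coverage step (a box-smoothed
        # gradient would be flat-topped and ambiguous to +/- w/2)
        cs = np.concatenate(([0.0], np.cumsum(depths)))
        n = len(depths)

        def contrast(i: np.ndarray) -> np.ndarray:
            right = (cs[np.minimum(i + w, n)] - cs[i]) / np.maximum(np.minimum(i + w, n) - i, 1)
            left = (cs[i] - cs[np.maximum(i - w, 0)]) / np.maximum(i - np.maximum(i - w, 0), 1)
            return np.abs(right - left)

        def best_edge(border: int) -> int:
            lo = max(1, border - radius)
            hi = min(n - 1, border + radius)
            if hi <= lo:
                return border
            pos = np.arange(lo, hi + 1)
            return int(pos[np.argmax(contrast(pos))])

        s = start_clip if start_clip is not None else best_edge(element.start)
        e = end_clip if end_clip is not None else best_edge(element.end)
        if e > s:
            return s, e, "coverage"

    span = island_span
    if span is None and gene_calls:
        span = (min(g[0] for g in gene_calls), max(g[1] for g in gene_calls))
    if gene_calls:
        inside = [g for g in gene_calls if g[0] >= span[0] and g[1] <= span[1]] if span else list(gene_calls)
        if inside:
            return min(g[0] for g in inside), max(g[1] for g in inside), "gene_span"
    if span is not None:
        return span[0], span[1], "gene_span"

    logger.warning(
        "no border evidence for element %s:%d-%d; keeping raw window borders",
        element.contig, element.start, element.end,
    )
    return element.start, element.end, element.border_method if element.border_method == "contig_whole" else "raw"


# ---------------------------------------------------------------------------
# end-to-end detection over a profile
# ---------------------------------------------------------------------------

@dataclass
class DetectionResult:
    elements: list[CandidateElement]
    segment_stats: dict[str, BackgroundStats] = field(default_factory=dict)
    genome_median: float = 0.0
    notes: list[str] = field(default_factory=list)


def genome_median_depth(profile: DepthProfile, params: DetectionParams | None = None) -> float:
    """Median depth over all background-eligible contigs (fallback: all bases)."""
    params = params or DetectionParams()
    eligible = [d for c, d in profile.depths.items() if len(d) >= params.min_contig_stats_bp]
    pool = eligible if eligible else list(profile.depths.values())
    return float(np.median(np.concatenate(pool)))


def detect_elements(
    profile: DepthProfile,
    params: DetectionParams | None = None,
    clip_records: Optional[Sequence[AlignmentRecord]] = None,
    refine: bool = True,
) -> DetectionResult:
    """Run the full coverage screen over a depth profile.

    Per contig: short contigs are skipped, 5-80 kb contigs go through the
    whole-contig plasmid rule, longer contigs through sliding-window
    calling with per-segment background statistics.  Calls are merged and
    (optionally) border-refined against clip evidence and the depth step.
    """
    params = params or DetectionParams()
    lengths = {c: profile.length(c) for c in profile.contigs}
    segments = segment_contigs(lengths, params)
    gmedian = genome_median_depth(profile, params)

    result = DetectionResult([], {}, gmedian)
    elements: list[CandidateElement] = []

    seg_by_contig: dict[str, list[Segment]] = {}
    for seg in segments:
        seg_by_contig.setdefault(seg.contig, []).append(seg)

    for contig, segs in seg_by_contig.items():
        depths = profile[contig]
        role = segs[0].role
        if role == "too_short":
            result.notes.append(f"{contig}: <{params.plasmid_min_bp} bp, ignored")
            continue
        if role == "plasmid_candidate":
            if call_plasmid_contig(depths, gmedian, params):
                elements.append(
                    CandidateElement(
                        contig, 0, len(depths), "induction",
                        float(depths.mean()), border_method="contig_whole",
                    )
                )
            continue

        # background-eligible: per-slice stats, windows assigned by midpoint
        seg_stats = [background_stats(depths[s.start:s.end], params) for s in segs]
        for s, st in zip(segs, seg_stats):
            result.segment_stats[f"{contig}:{s.start}-{s.end}"] = st
        starts, means = sliding_window_means(depths, params)
        if len(means) == 0:
            continue
        mids = starts + params.window_bp // 2
        bounds = np.array([s.end for s in segs])
        idx = np.minimum(np.searchsorted(bounds, mids, side="right"), len(segs) - 1)
        called = call_high_coverage_regions(
            starts, means, seg_stats, contig, params, stats_index=idx
        )
        elements.extend(called)

    merged = merge_elements(elements, list(profile.contigs), lengths, params)

    if refine:
        for el in merged:
            if el.border_method == "contig_whole":
                continue
            s, e, method = refine_borders(
                el, clip_records, profile[el.contig], params=params
            )
            el.start, el.end, el.border_method = s, e, method
            el.mean_coverage = float(profile[el.contig][s:e].mean()) if e > s else 0.0

    result.elements = merged
    return result
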
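"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions are centralized here: everything in memory is
0-based half-open; depth TSV follows the samtools-depth dialect (contig,
1-based position, depth); BED is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import GeneCall
from .detection import AlignmentRecord, CandidateElement, DepthProfile


# ---------------------------------------------------------------------------
# depth TSV (samtools-depth dialect)
# ---------------------------------------------------------------------------

def write_depth_tsv(profile: DepthProfile, path: str | Path,
                    header_comment: Optional[str] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for contig in profile.contigs:
            arr = profile[contig]
            pos = np.arange(1, len(arr) + 1)
            block = pd.DataFrame({"contig": contig, "pos": pos, "depth": arr})
            block.to_csv(fh, sep="\t", header=False, index=False)


def read_depth_tsv(path: str | Path) -> DepthProfile:
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["contig", "pos", "depth"], dtype={"contig": str})
    depths = {}
    for contig, grp in df.groupby("contig", sort=False):
        grp = grp.sort_values("pos")
        arr = np.zeros(int(grp["pos"].max()), dtype=np.int64)
        arr[grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
        depths[contig] = arr
    return DepthProfile(depths)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_elements_bed(elements: Sequence[CandidateElement], path: str | Path,
                       header_comment: Optional[str] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for el in elements:
            name = el.element_id or f"{el.contig}:{el.start}-{el.end}"
            fh.write(
                f"{el.contig}\t{el.start}\t{el.end}\t{name}\t"
                f"{el.source}\t{el.mean_coverage:.2f}\t{el.border_method}\n"
            )


def read_elements_bed(path: str | Path) -> list[CandidateElement]:
    elements = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        contig, start, end = fields[0], int(fields[1]), int(fields[2])
        el = CandidateElement(contig, start, end)
        if len(fields) > 3:
            el.element_id = fields[3]
        if len(fields) > 4:
            el.source = fields[4]
        if len(fields) > 5:
            el.mean_coverage = float(fields[5])
        if len(fields) > 6:
            el.border_method = fields[6]
        elements.append(el)
    return elements


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# alignment TSV
# ---------------------------------------------------------------------------

_ALN_COLUMNS = ["read_id", "contig", "start", "end", "identity",
                "read_fraction", "primary", "clip_positions"]


def write_alignment_tsv(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        clips = ",".join(map(str, rec.clip_positions)) if rec.clip_positions else ""
        rows.append([rec.read_id, rec.contig, rec.start, rec.end,
                     rec.identity, rec.aligned_read_fraction,
                     int(rec.is_primary), clips])
    pd.DataFrame(rows, columns=_ALN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"clip_positions": str},
                     keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        clips = [int(x) for x in str(row.clip_positions).split(",") if x] or None
        records.append(
            AlignmentRecord(
                read_id=str(row.read_id), contig=str(row.contig),
                start=int(row.start), end=int(row.end),
                identity=float(row.identity),
                aligned_read_fraction=float(row.read_fraction),
                is_primary=bool(int(row.primary)), clip_positions=clips,
            )
        )
    return records


# ---------------------------------------------------------------------------
# gene calls: GFF3 + annotation TSV
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tprophagekit\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def read_gff3(path: str | Path) -> list[GeneCall]:
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        genes.append(
            GeneCall(
                gene_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                contig=f[0], start=int(f[3]) - 1, end=int(f[4]),
                strand=f[6] if f[6] in "+-" else "+",
            )
        )
    return genes


def write_annotation_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def attach_annotations(genes: Sequence[GeneCall], annotations: pd.DataFrame) -> None:
    """Merge an annotation table (gene_id, source, label, evalue) onto gene calls."""
    by_gene = {}
    for row in annotations.itertuples(index=False):
        by_gene.setdefault(str(row.gene_id), []).append(
            (str(row.source), str(row.label), float(row.evalue))
        )
    for g in genes:
        g.labels.extend(by_gene.get(g.gene_id, []))


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
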
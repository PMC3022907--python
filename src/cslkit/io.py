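"""Readers and writers binding the pipeline stages together.

Formats exchanged: tab-separated catalogs and expression matrices (with
``#tissue=`` / ``#variety=`` / ``#stage=`` metadata rows), GFF3 gene
positions, tab-separated anchor lists, FASTA proteins, Newick trees and JSON
reports.  Numeric round-trips are lossless to six significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coexpression import ClusterTree, ExpressionMatrix, SampleMeta
from .duplication import Anchor

logger = logging.getLogger(__name__)


class IOFormatError(ValueError):
    """Raised on malformed input files, carrying the offending line number."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column gene id, header row sample ids.  Optional metadata rows
    before the header: ``#tissue=<v1>\\t<v2>...``, ``#variety=...``,
    ``#stage=...`` with one value per sample.  Other ``#`` lines are
    comments.  Ragged rows, duplicate ids and negative signals raise
    :class:`IOFormatError` with the line number.
    """
    path = Path(path)
    meta: dict[str, list[str]] = {}
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:]
                for key in ("tissue", "variety", "stage"):
                    if body.startswith(f"{key}="):
                        meta[key] = body[len(key) + 1 :].split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields[1:]]
                if len(set(header)) != len(header):
                    raise IOFormatError(f"line {lineno}: duplicate sample ids")
                continue
            if len(fields) != len(header) + 1:
                raise IOFormatError(
                    f"line {lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            gene = fields[0].strip()
            if gene in genes:
                raise IOFormatError(f"line {lineno}: duplicate gene id {gene!r}")
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError as err:
                raise IOFormatError(f"line {lineno}: {err}") from None
            if any(v < 0 for v in vals):
                raise IOFormatError(f"line {lineno}: negative signal")
            genes.append(gene)
            rows.append(vals)
    if header is None:
        raise IOFormatError(f"{path}: no header row found")
    for key, vals in meta.items():
        if len(vals) != len(header):
            raise IOFormatError(
                f"metadata row #{key}= has {len(vals)} values for {len(header)} samples"
            )
    samples = []
    for j, sid in enumerate(header):
        samples.append(
            SampleMeta(
                sample_id=sid,
                tissue=meta.get("tissue", header)[j],
                variety=meta["variety"][j] if "variety" in meta else "",
                stage=int(meta["stage"][j]) if "stage" in meta else 0,
            )
        )
    return ExpressionMatrix(genes, samples, np.array(rows, dtype=float))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the format read by :func:`read_expression`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#tissue=" + "\t".join(s.tissue for s in m.samples) + "\n")
        fh.write("#variety=" + "\t".join(s.variety for s in m.samples) + "\n")
        fh.write("#stage=" + "\t".join(str(s.stage) for s in m.samples) + "\n")
        fh.write("gene\t" + "\t".join(m.sample_ids) + "\n")
        for gene, row in zip(m.genes, m.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# GFF3 positions and anchors
# ---------------------------------------------------------------------------


def write_gff(positions: Mapping[str, tuple[int, int, int]], path: str | Path) -> None:
    """Write gene features (1-based, closed intervals) as GFF3."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gene, (chrom, start, end) in sorted(
            positions.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0])
        ):
            fh.write(
                f"Chr{chrom}\tcslkit\tgene\t{start + 1}\t{end}\t.\t+\t.\tID={gene}\n"
            )


def read_gff_positions(path: str | Path) -> dict[str, tuple[int, int, int]]:
    """Read gene features from a GFF3 file into gene -> (chrom, start, end).

    Only ``gene`` features are used; the chromosome number is parsed from
    the digits of the seqid; coordinates are returned 0-based half-open to
    match the writer's input convention.
    """
    path = Path(path)
    out: dict[str, tuple[int, int, int]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise IOFormatError(f"line {lineno}: GFF3 rows need 9 columns")
            seqid, _src, ftype, start, end, _score, _strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            digits = "".join(ch for ch in seqid if ch.isdigit())
            if not digits:
                raise IOFormatError(f"line {lineno}: cannot parse chromosome from {seqid!r}")
            gene = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene = item[3:]
                    break
            if gene is None:
                raise IOFormatError(f"line {lineno}: gene feature without ID attribute")
            out[gene] = (int(digits), int(start) - 1, int(end))
    return out


def write_anchors(
    anchors: Sequence[Anchor],
    path: str | Path,
    chrom_pairs: Sequence[tuple[int, int]] | None = None,
) -> None:
    """Write anchors as TSV: gene_a, gene_b, pos_a, pos_b, score[, chroms]."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tpos_a\tpos_b\tscore\tchrom_a\tchrom_b\n")
        for i, a in enumerate(anchors):
            ca, cb = chrom_pairs[i] if chrom_pairs else (0, 0)
            fh.write(
                f"{a.gene_a}\t{a.gene_b}\t{a.pos_a}\t{a.pos_b}\t{a.score:.6g}\t{ca}\t{cb}\n"
            )


def read_anchors(path: str | Path) -> tuple[list[Anchor], list[tuple[int, int]]]:
    """Read an anchor TSV back into Anchor tuples plus chromosome pairs."""
    path = Path(path)
    anchors: list[Anchor] = []
    chroms: list[tuple[int, int]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) not in (5, 7):
                raise IOFormatError(f"line {lineno}: expected 5 or 7 fields")
            anchors.append(
                Anchor(
                    fields[0],
                    fields[1],
                    int(fields[2]),
                    int(fields[3]),
                    float(fields[4]),
                )
            )
            if len(fields) == 7:
                chroms.append((int(fields[5]), int(fields[6])))
            else:
                chroms.append((0, 0))
    return anchors, chroms


# ---------------------------------------------------------------------------
# FASTA, Newick, JSON
# ---------------------------------------------------------------------------


def read_fasta_proteins(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into id -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta_proteins(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path
) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(records, str(path), "fasta")


def write_newick(tree: ClusterTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def write_json(obj, path: str | Path) -> None:
    """Stable JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, allow_nan=False) + "\n",
        encoding="utf-8",
    )


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
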
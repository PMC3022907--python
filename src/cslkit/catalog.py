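"""Gene-family catalog handling for the rice CESA/CSL superfamily.

The cellulose synthase (CESA) / cellulose synthase-like (CSL) superfamily of
rice comprises 45 gene models in seven families.  CESA genes encode the
catalytic subunits of the plasma-membrane cellulose synthase complex; the six
CSL families (A, C, D, E, F, H in rice) encode putative glycosyl transferases
for non-cellulosic wall polysaccharides.  Phylogenetically the superfamily
splits into two clusters: Cluster I (CESA, CSLD, CSLE, CSLF, CSLH) and
Cluster II (CSLA, CSLC).

This module parses and validates the catalog table, scans protein sequences
for the processive glycosyl-transferase catalytic signature ("D, DXD, QXXRW"
style: a D-x-D motif, a downstream isolated aspartate, then a QXXRW-like
pentapeptide), and computes pairwise global-alignment percent similarity.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The seven rice CESA/CSL families.
FAMILIES = ("CESA", "CSLA", "CSLC", "CSLD", "CSLE", "CSLF", "CSLH")

#: Fixed family -> phylogenetic super-cluster mapping.  Cluster I holds the
#: CESA-like families, Cluster II the CSLA/CSLC lineage of distinct origin.
FAMILY_CLUSTER: Mapping[str, str] = {
    "CESA": "I",
    "CSLD": "I",
    "CSLE": "I",
    "CSLF": "I",
    "CSLH": "I",
    "CSLA": "II",
    "CSLC": "II",
}

CSL_FAMILIES = tuple(f for f in FAMILIES if f != "CESA")

#: TIGR rice locus identifiers look like LOC_Os07g36610: chromosome 01-12,
#: then the gene-model number (assigned in steps of ten along the chromosome).
LOCUS_PATTERN = re.compile(r"^LOC_Os(\d{2})g(\d+)$")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Named variants of the first residue of the xXXRW pentapeptide.
STANDARD_VARIANT_LETTERS = ("Q", "R", "L")


class CatalogError(ValueError):
    """Raised for malformed catalog rows or invalid sequences."""


@dataclass(frozen=True)
class GeneRecord:
    """One CESA/CSL family member.

    ``ordinal_index`` is the rank of the gene model along its chromosome.  A
    full genome annotation supplies it directly; when parsing a catalog we
    derive it from the TIGR locus number divided by ten (TIGR numbers gene
    models in steps of ten), which is a documented heuristic.
    """

    gene_name: str
    family: str
    locus_id: str
    chromosome: int
    ordinal_index: int
    probe_ids: tuple[str, ...] = ()
    has_cdna: bool = False
    protein: str | None = None

    @property
    def cluster(self) -> str:
        """Phylogenetic super-cluster (``"I"`` or ``"II"``) of the family."""
        return FAMILY_CLUSTER[self.family]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CatalogError(
                f"unknown family {self.family!r} for gene {self.gene_name!r}"
            )
        match = LOCUS_PATTERN.match(self.locus_id)
        if match is None:
            raise CatalogError(
                f"malformed locus id {self.locus_id!r} for gene {self.gene_name!r}"
            )
        chrom = int(match.group(1))
        if not 1 <= chrom <= 12:
            raise CatalogError(
                f"locus {self.locus_id!r}: chromosome {chrom} outside 1-12"
            )
        if chrom != self.chromosome:
            raise CatalogError(
                f"gene {self.gene_name!r}: chromosome field {self.chromosome} "
                f"disagrees with locus id {self.locus_id!r}"
            )
        if self.ordinal_index < 1:
            raise CatalogError(
                f"gene {self.gene_name!r}: ordinal_index must be >= 1"
            )


def locus_parts(locus_id: str) -> tuple[int, int]:
    """Split a TIGR locus id into (chromosome, gene-model number)."""
    match = LOCUS_PATTERN.match(locus_id)
    if match is None:
        raise CatalogError(f"malformed locus id {locus_id!r}")
    return int(match.group(1)), int(match.group(2))


def record_from_row(
    gene: str,
    family: str,
    locus: str,
    probe_ids: Sequence[str] = (),
    has_cdna: bool = False,
    protein: str | None = None,
) -> GeneRecord:
    """Build a validated :class:`GeneRecord` from raw catalog fields."""
    chrom, number = locus_parts(locus)
    if not 1 <= chrom <= 12:
        raise CatalogError(f"locus {locus!r}: chromosome {chrom} outside 1-12")
    return GeneRecord(
        gene_name=gene,
        family=family,
        locus_id=locus,
        chromosome=chrom,
        ordinal_index=max(1, number // 10),
        probe_ids=tuple(probe_ids),
        has_cdna=has_cdna,
        protein=protein,
    )


_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0", ""}


def _parse_bool(text: str, row: int) -> bool:
    text = text.strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CatalogError(f"row {row}: cannot interpret has_cdna value {text!r}")


def parse_catalog(path: str | Path) -> list[GeneRecord]:
    """Read a tab-separated gene-family catalog.

    The file must carry a header row naming at least ``gene``, ``family`` and
    ``locus`` columns; ``probe_ids`` (semicolon-joined) and ``has_cdna`` are
    optional.  Lines starting with ``#`` are ignored.  Rows are validated
    (locus pattern, chromosome range, family label) and rejected on duplicate
    gene names or locus ids.  Records are returned in file order with
    ``ordinal_index`` derived per chromosome from ascending locus numbers.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        logger.warning("catalog %s is empty", path)
        return []
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"gene", "family", "locus"}
    missing = required - set(frame.columns)
    if missing:
        raise CatalogError(
            f"catalog {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    if frame.empty:
        logger.warning("catalog %s has a header but no rows", path)
        return []

    records: list[GeneRecord] = []
    seen_genes: set[str] = set()
    seen_loci: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        gene = row.gene.strip()
        locus = row.locus.strip()
        if gene in seen_genes:
            raise CatalogError(f"row {i}: duplicate gene name {gene!r}")
        if locus in seen_loci:
            raise CatalogError(f"row {i}: duplicate locus id {locus!r}")
        probe_field = getattr(row, "probe_ids", "") or ""
        probes = tuple(p.strip() for p in probe_field.split(";") if p.strip())
        has_cdna = _parse_bool(getattr(row, "has_cdna", ""), i)
        try:
            rec = record_from_row(gene, row.family.strip(), locus, probes, has_cdna)
        except CatalogError as err:
            raise CatalogError(f"row {i}: {err}") from err
        seen_genes.add(gene)
        seen_loci.add(locus)
        records.append(rec)

    _check_ordinals(records)
    return records


def _check_ordinals(records: Sequence[GeneRecord]) -> None:
    """Ordinal indices must be strictly increasing along each chromosome."""
    by_chrom: dict[int, list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, recs in by_chrom.items():
        recs = sorted(recs, key=lambda r: locus_parts(r.locus_id)[1])
        for a, b in zip(recs, recs[1:]):
            if b.ordinal_index <= a.ordinal_index:
                raise CatalogError(
                    f"chromosome {chrom}: ordinal collision between "
                    f"{a.gene_name} and {b.gene_name}"
                )


def write_catalog(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records in the tab-separated format read by :func:`parse_catalog`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\tfamily\tlocus\tprobe_ids\thas_cdna\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.gene_name,
                        rec.family,
                        rec.locus_id,
                        ";".join(rec.probe_ids),
                        "true" if rec.has_cdna else "false",
                    )
                )
                + "\n"
            )


def packaged_catalog_path() -> Path:
    """Path of the packaged 45-gene rice CESA/CSL catalog."""
    return Path(resources.files("cslkit.data") / "oscesa_csl_catalog.tsv")


def load_packaged_catalog() -> list[GeneRecord]:
    """Parse the packaged 45-gene rice CESA/CSL catalog."""
    return parse_catalog(packaged_catalog_path())


@dataclass(frozen=True)
class FamilyCounts:
    per_family: Mapping[str, int]
    per_cluster: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.per_family.values())

    @property
    def csl_total(self) -> int:
        return sum(self.per_family.get(f, 0) for f in CSL_FAMILIES)


def family_counts(catalog: Sequence[GeneRecord]) -> FamilyCounts:
    """Count members per family and per phylogenetic cluster."""
    if not catalog:
        raise CatalogError("family_counts requires a nonempty catalog")
    fam = Counter(rec.family for rec in catalog)
    clu = Counter(rec.cluster for rec in catalog)
    return FamilyCounts(per_family=dict(fam), per_cluster=dict(clu))


# ---------------------------------------------------------------------------
# Catalytic motif scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifReport:
    """Result of scanning a protein for the processive GT signature.

    Positions are 0-based indices of the first residue of each component.
    ``variant`` is ``"QXXRW"``, ``"RXXRW"``, ``"LXXRW"``, another literal
    first letter (flagged ``nonstandard``) or ``"absent"``.  ``completeness``
    is ``full`` when all three components were found in order, ``dxd_only``
    when only the D-x-D was located, ``absent`` otherwise.
    """

    dxd_position: int | None = None
    lone_d_position: int | None = None
    xxxrw_position: int | None = None
    variant: str = "absent"
    nonstandard: bool = False
    completeness: str = "absent"


def clean_protein(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase a protein string, strip stop characters, validate residues."""
    seq = sequence.upper()
    if "*" in seq:
        logger.warning("%s: stripping %d stop character(s)", context, seq.count("*"))
        seq = seq.replace("*", "")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise CatalogError(
            f"{context}: non-residue character(s) {''.join(sorted(bad))!r}"
        )
    return seq


def scan_catalytic_motif(protein: str, g_min: int = 5) -> MotifReport:
    """Locate the D-x-D / isolated-D / xXXRW catalytic signature.

    The search is a leftmost ordered scan: the first D-x-D; then the next
    isolated aspartate (no adjacent D) at least ``g_min`` residues downstream
    of the D-x-D; then the first pentapeptide ``?-x-x-R-W`` downstream of that
    aspartate.  The pentapeptide's first residue names the variant (Q, R and L
    are the naturally observed classes; any other letter is reported literally
    and flagged nonstandard).
    """
    seq = clean_protein(protein, context="protein")
    n = len(seq)

    dxd = None
    for i in range(n - 2):
        if seq[i] == "D" and seq[i + 2] == "D":
            dxd = i
            break
    if dxd is None:
        return MotifReport()

    lone = None
    for j in range(dxd + 2 + g_min, n):
        if (
            seq[j] == "D"
            and (j == 0 or seq[j - 1] != "D")
            and (j == n - 1 or seq[j + 1] != "D")
        ):
            lone = j
            break
    if lone is None:
        return MotifReport(dxd_position=dxd, completeness="dxd_only")

    for k in range(lone + 1, n - 4):
        if seq[k + 3] == "R" and seq[k + 4] == "W":
            letter = seq[k]
            return MotifReport(
                dxd_position=dxd,
                lone_d_position=lone,
                xxxrw_position=k,
                variant=f"{letter}XXRW",
                nonstandard=letter not in STANDARD_VARIANT_LETTERS,
                completeness="full",
            )
    return MotifReport(dxd_position=dxd, lone_d_position=lone, completeness="dxd_only")


# ---------------------------------------------------------------------------
# Global-alignment percent similarity
# ---------------------------------------------------------------------------


def percent_similarity(protein_a: str, protein_b: str) -> float:
    """End-to-end global alignment percent similarity.

    Needleman-Wunsch dynamic programming with an identity matrix: match +1,
    mismatch 0, gap -1 per residue.  Among alignments of optimal score the
    one with the most matches (then the shortest) is taken, and the result is
    ``100 * matches / alignment_length``.  Symmetric in its arguments.
    """
    a = clean_protein(protein_a, context="protein_a")
    b = clean_protein(protein_b, context="protein_b")
    if not a or not b:
        raise CatalogError("percent_similarity requires two nonempty sequences")

    n, m = len(a), len(b)
    # dp cell = (score, matches, -length); tuple order implements the
    # lexicographic preference score > matches > shorter alignment.
    prev = [(-j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-i, 0, -i)]
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = 1 if ai == b[j - 1] else 0
            d = prev[j - 1]
            u = prev[j]
            l = cur[j - 1]
            cur.append(
                max(
                    (d[0] + match, d[1] + match, d[2] - 1),
                    (u[0] - 1, u[1], u[2] - 1),
                    (l[0] - 1, l[1], l[2] - 1),
                )
            )
        prev = cur
    _, matches, neg_len = prev[m]
    return 100.0 * matches / (-neg_len)
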
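"""Synthetic catalogs, genomes, anchors, proteins and expression matrices.

Every pipeline stage is testable without downloads because this module
emits inputs with *planted ground truth*: a multi-chromosome gene catalog
with tandem arrays and collinear segmental blocks, protein sequences with
planted catalytic-motif variants, and a nonnegative signal matrix whose
co-expression groups, marker genes and redundancy triple are known by
construction.

The default layout mirrors the rice CESA/CSL study design: 45 family genes
in seven families on 12 chromosomes, a six-member tandem array plus two
tandem pairs, segmental blocks, and a 33-sample expression panel (17 tissues
across two varieties) organised into ten co-expression groups within three
super-groups.  The noise model is multiplicative log-normal,

    signal = base * group_factor(tissue) * gene_amplitude * exp(N(0, sigma^2)),

with base signal 100 and a "silent" level of about 1, which mimics the
dispersion of background-subtracted microarray intensities.  The planted
redundancy triple reproduces the tissue-dependent pattern: the target gene
is silenced in two designated tissues where the candidate group is high, and
a neighbour group that agrees with the complex everywhere *except* those
tissues makes the candidates' absorption collapse once the tissues are
excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalog import GeneRecord, record_from_row
from .coexpression import ExpressionMatrix, SampleMeta
from .duplication import Anchor

DEFAULT_TISSUES = (
    "callus",
    "seed_imbibition",
    "young_panicle",
    "panicle",
    "plumule",
    "stem",
    "young_leaf",
    "shoot",
    "radicle",
    "stamen",
    "flag_leaf",
    "endosperm",
    "sheath",
    "old_leaf",
    "hull",
    "old_panicle",
    "spikelet",
)

DEFAULT_FAMILY_SIZES: Mapping[str, int] = {
    "CESA": 11,
    "CSLA": 9,
    "CSLC": 6,
    "CSLD": 5,
    "CSLE": 3,
    "CSLF": 8,
    "CSLH": 3,
}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class TandemArraySpec:
    chromosome: int
    family: str
    size: int
    max_spacing: int = 5


@dataclass(frozen=True)
class SegmentalBlockSpec:
    family: str
    chrom_a: int
    chrom_b: int
    n_anchors: int = 8


@dataclass(frozen=True)
class GroupSpec:
    group_id: str
    n_members: int
    high_tissues: tuple[str, ...]
    high: float = 8.0
    low: float = 0.5


#: Ten co-expression groups in three super-groups.  IB is the "complex"
#: group hosting the redundancy target; IA holds the candidate substitutes
#: (high in the plumule/radicle support tissues); IC is the neighbour group
#: that agrees with IB everywhere except the support tissues and one swapped
#: tissue, which is what makes the absorption tissue-dependent.
DEFAULT_GROUPS: tuple[GroupSpec, ...] = (
    GroupSpec("IA", 3, ("young_leaf", "shoot", "plumule", "radicle")),
    GroupSpec(
        "IB",
        3,
        ("young_leaf", "shoot", "stem", "sheath", "seed_imbibition", "plumule", "radicle"),
    ),
    GroupSpec("IC", 3, ("young_leaf", "shoot", "stem", "sheath", "old_leaf")),
    GroupSpec("IIA", 6, ("hull", "spikelet", "old_panicle")),
    GroupSpec("IIB", 6, ("flag_leaf", "endosperm", "old_leaf")),
    GroupSpec("IIIA", 6, ("callus", "young_panicle")),
    GroupSpec("IIIB", 5, ("stamen", "endosperm")),
    GroupSpec("IIIC", 5, ("young_panicle", "panicle")),
    GroupSpec("IIID", 4, ("stamen", "radicle")),
    GroupSpec("IIIE", 4, ("seed_imbibition", "callus")),
)

DEFAULT_TANDEM_ARRAYS: tuple[TandemArraySpec, ...] = (
    TandemArraySpec(7, "CSLF", 6, max_spacing=5),
    TandemArraySpec(4, "CSLH", 2, max_spacing=1),
    TandemArraySpec(9, "CSLE", 2, max_spacing=1),
)

DEFAULT_SEGMENTAL_BLOCKS: tuple[SegmentalBlockSpec, ...] = (
    SegmentalBlockSpec("CESA", 3, 7),
    SegmentalBlockSpec("CSLA", 2, 6),
    SegmentalBlockSpec("CSLA", 10, 3),
    SegmentalBlockSpec("CSLA", 3, 7),
    SegmentalBlockSpec("CSLA", 6, 2),
    SegmentalBlockSpec("CSLC", 3, 7),
)


@dataclass(frozen=True)
class RedundancyTripleSpec:
    """Which planted groups provide target/complex and candidates.

    The target is the last member of ``complex_group``; the candidates are
    the first two members of ``candidate_group``; the target is silenced (and
    the candidates are naturally high) in ``tissues``.
    """

    complex_group: str = "IB"
    candidate_group: str = "IA"
    tissues: tuple[str, ...] = ("plumule", "radicle")


@dataclass(frozen=True)
class MarkerSpec:
    n_markers: int = 5
    target_r: float = 0.95
    prefix: str = "SynBC1L"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 12
    family_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SIZES)
    )
    tandem_arrays: tuple[TandemArraySpec, ...] = DEFAULT_TANDEM_ARRAYS
    segmental_blocks: tuple[SegmentalBlockSpec, ...] = DEFAULT_SEGMENTAL_BLOCKS
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    varieties: tuple[str, ...] = ("ZS97", "MH63")
    n_samples: int = 33
    group_spec: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    noise_sigma: float = 0.3
    base_signal: float = 100.0
    silent_signal: float = 1.0
    amplitude_range: tuple[float, float] = (0.8, 1.25)
    redundancy_triple: RedundancyTripleSpec | None = RedundancyTripleSpec()
    marker_spec: MarkerSpec | None = MarkerSpec()

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise SimulationError("noise_sigma must be >= 0")
        if sum(g.n_members for g in self.group_spec) > sum(
            self.family_sizes.values()
        ):
            raise SimulationError("group sizes exceed the number of genes")
        for spec in self.tandem_arrays:
            if spec.size > self.family_sizes.get(spec.family, 0):
                raise SimulationError(
                    f"tandem array needs {spec.size} {spec.family} genes"
                )


@dataclass
class GroundTruth:
    """Planted structure, consistent with the emitted files."""

    group_of: dict = field(default_factory=dict)
    tandem: list = field(default_factory=list)
    segmental: list = field(default_factory=list)
    redundancy: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_of": dict(sorted(self.group_of.items())),
            "tandem": [sorted(c) for c in self.tandem],
            "segmental": [sorted(p) for p in self.segmental],
            "redundancy": self.redundancy,
            "markers": dict(sorted(self.markers.items())),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            group_of=dict(d.get("group_of", {})),
            tandem=[list(c) for c in d.get("tandem", [])],
            segmental=[tuple(p) for p in d.get("segmental", [])],
            redundancy=dict(d.get("redundancy", {})),
            markers=dict(d.get("markers", {})),
        )


# ---------------------------------------------------------------------------
# Catalog / genome / anchors
# ---------------------------------------------------------------------------

#: bp per ordinal slot; anchor ordinal gaps of 2-8 slots keep bp gaps under
#: the 100 kb chaining limit.
BP_PER_ORDINAL = 10_000
GENE_SPAN_BP = 3_000


@dataclass
class GenomeSim:
    records: list[GeneRecord]
    positions: dict  # gene -> (chromosome, start bp, end bp); includes fillers
    anchors: list  # Anchor tuples, with (chrom_a, chrom_b) per block
    anchor_chroms: list  # (chrom_a, chrom_b) aligned with blocks
    ground_truth: GroundTruth


def gen_catalog_genome(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> GenomeSim:
    """Place family genes on chromosomes with planted duplications.

    Tandem arrays are laid down with at most ``max_spacing`` intervening gene
    models between neighbours; segmental blocks emit collinear anchor lists
    (gaps < 100 kb) whose central anchor is a same-family gene pair.  All
    remaining genes are scattered as singletons with >= 20 intervening models
    so no accidental tandem clusters arise.  Deterministic per seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    pools = {
        fam: [f"Syn{fam}{i + 1:02d}" for i in range(n)]
        for fam, n in cfg.family_sizes.items()
    }
    cursor = {c: 30 + int(rng.integers(0, 10)) for c in range(1, cfg.n_chromosomes + 1)}
    placements: dict[str, tuple[int, int]] = {}  # gene -> (chromosome, ordinal)
    gt = GroundTruth()

    def advance(chrom: int, gap: int) -> int:
        cursor[chrom] += gap
        return cursor[chrom]

    def take(family: str, k: int) -> list[str]:
        pool = pools[family]
        if len(pool) < k:
            raise SimulationError(f"family {family} exhausted")
        picked, pools[family] = pool[:k], pool[k:]
        return picked

    for spec in cfg.tandem_arrays:
        names = take(spec.family, spec.size)
        advance(spec.chromosome, 20 + int(rng.integers(0, 10)))
        for i, name in enumerate(names):
            if i > 0:
                advance(spec.chromosome, 1 + int(rng.integers(0, spec.max_spacing + 1)))
            placements[name] = (spec.chromosome, cursor[spec.chromosome])
        gt.tandem.append(list(names))

    anchors: list[Anchor] = []
    anchor_chroms: list[tuple[int, int]] = []
    filler_positions: dict[str, tuple[int, int, int]] = {}
    for bi, spec in enumerate(cfg.segmental_blocks):
        gene_a, gene_b = take(spec.family, 2)
        mid = spec.n_anchors // 2
        ords_a, ords_b = [], []
        advance(spec.chrom_a, 20 + int(rng.integers(0, 10)))
        advance(spec.chrom_b, 20 + int(rng.integers(0, 10)))
        for k in range(spec.n_anchors):
            step_a = 0 if k == 0 else int(rng.integers(2, 9))
            step_b = 0 if k == 0 else int(rng.integers(2, 9))
            ords_a.append(advance(spec.chrom_a, step_a))
            ords_b.append(advance(spec.chrom_b, step_b))
        for k in range(spec.n_anchors):
            if k == mid:
                na, nb = gene_a, gene_b
            else:
                na, nb = f"blk{bi}a{k}", f"blk{bi}b{k}"
                for name, chrom, ordn in ((na, spec.chrom_a, ords_a[k]), (nb, spec.chrom_b, ords_b[k])):
                    start = ordn * BP_PER_ORDINAL
                    filler_positions[name] = (chrom, start, start + GENE_SPAN_BP)
            anchors.append(
                Anchor(na, nb, ords_a[k] * BP_PER_ORDINAL, ords_b[k] * BP_PER_ORDINAL, 1.0)
            )
            anchor_chroms.append((spec.chrom_a, spec.chrom_b))
        placements[gene_a] = (spec.chrom_a, ords_a[mid])
        placements[gene_b] = (spec.chrom_b, ords_b[mid])
        gt.segmental.append((gene_a, gene_b))

    chrom_cycle = 0
    for fam in sorted(pools):
        for name in list(pools[fam]):
            chrom = (chrom_cycle % cfg.n_chromosomes) + 1
            chrom_cycle += 1
            placements[name] = (chrom, advance(chrom, 20 + int(rng.integers(0, 10))))
        pools[fam] = []

    records: list[GeneRecord] = []
    positions: dict[str, tuple[int, int, int]] = dict(filler_positions)
    fam_of = {}
    for fam, n in cfg.family_sizes.items():
        for i in range(n):
            fam_of[f"Syn{fam}{i + 1:02d}"] = fam
    for idx, (name, (chrom, ordn)) in enumerate(
        sorted(placements.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    ):
        locus = f"LOC_Os{chrom:02d}g{ordn * 10:05d}"
        records.append(
            record_from_row(
                name,
                fam_of[name],
                locus,
                probe_ids=(f"Syn.{idx + 1}.1.S1_at",),
                has_cdna=bool(rng.integers(0, 4) > 0),
            )
        )
        start = ordn * BP_PER_ORDINAL
        positions[name] = (chrom, start, start + GENE_SPAN_BP)

    return GenomeSim(
        records=records,
        positions=positions,
        anchors=anchors,
        anchor_chroms=anchor_chroms,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def _make_samples(cfg: SimulationConfig) -> list[SampleMeta]:
    """Tissue panel across varieties, truncated to ``n_samples`` total."""
    samples = []
    for vi, variety in enumerate(cfg.varieties):
        for ti, tissue in enumerate(cfg.tissues):
            samples.append(
                SampleMeta(
                    sample_id=f"{variety}.{tissue}",
                    tissue=tissue,
                    variety=variety,
                    stage=ti + 1,
                )
            )
    if len(samples) < cfg.n_samples:
        raise SimulationError("not enough tissue/variety combinations for n_samples")
    return samples[: cfg.n_samples]


def gen_expression(
    cfg: SimulationConfig,
    genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    ground_truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the signal matrix with planted groups, markers and redundancy.

    Genes are assigned to the configured groups in order; each signal is
    ``base * group_factor(tissue) * gene_amplitude * exp(N(0, sigma^2))``.
    The redundancy target's signal is forced to the silent level in the
    designated tissues.  Markers are noisy copies of their group's raw mean
    profile, calibrated so the expected Pearson r equals ``target_r``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    gt = ground_truth if ground_truth is not None else GroundTruth()

    if genes is None:
        genes = [
            f"Syn{fam}{i + 1:02d}"
            for fam, n in cfg.family_sizes.items()
            for i in range(n)
        ]
    genes = list(genes)
    n_grouped = sum(g.n_members for g in cfg.group_spec)
    if n_grouped > len(genes):
        raise SimulationError("group sizes exceed the number of genes")

    samples = _make_samples(cfg)
    members_of: dict[str, list[str]] = {}
    pos = 0
    for spec in cfg.group_spec:
        members_of[spec.group_id] = genes[pos : pos + spec.n_members]
        for g in members_of[spec.group_id]:
            gt.group_of[g] = spec.group_id
        pos += spec.n_members
    background = genes[pos:]
    for g in background:
        gt.group_of[g] = "background"

    triple = cfg.redundancy_triple
    target = cand_pair = None
    if triple is not None:
        if triple.complex_group not in members_of or triple.candidate_group not in members_of:
            raise SimulationError("redundancy triple names an unknown group")
        complex_members = members_of[triple.complex_group]
        cands = members_of[triple.candidate_group]
        if len(complex_members) < 3 or len(cands) < 2:
            raise SimulationError("redundancy triple needs >=3 complex, >=2 candidates")
        target = complex_members[-1]
        cand_pair = tuple(cands[:2])
        missing = set(triple.tissues) - set(cfg.tissues)
        if missing:
            raise SimulationError(f"unknown redundancy tissue(s): {sorted(missing)}")
        gt.redundancy = {
            "target": target,
            "complex_partners": [g for g in complex_members if g != target],
            "candidates": list(cand_pair),
            "tissues": list(triple.tissues),
        }

    factor_of: dict[str, dict[str, float]] = {}
    for spec in cfg.group_spec:
        factor_of[spec.group_id] = {
            t: (spec.high if t in spec.high_tissues else spec.low)
            for t in cfg.tissues
        }

    values = np.zeros((len(genes), len(samples)))
    lo, hi = cfg.amplitude_range
    for gi, gene in enumerate(genes):
        amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        group = gt.group_of[gene]
        for si, sample in enumerate(samples):
            if group == "background":
                level = cfg.base_signal * 0.5 * amp
            else:
                level = cfg.base_signal * factor_of[group][sample.tissue] * amp
            if target is not None and gene == target and sample.tissue in triple.tissues:
                level = cfg.silent_signal * amp
            noise = float(np.exp(rng.normal(0.0, cfg.noise_sigma))) if cfg.noise_sigma else 1.0
            values[gi, si] = level * noise

    matrix = ExpressionMatrix(genes, samples, values)

    if cfg.marker_spec is not None and cfg.marker_spec.n_markers > 0:
        spec = cfg.marker_spec
        tau = float(np.sqrt(1.0 / spec.target_r**2 - 1.0))
        marker_rows = []
        marker_names = []
        group_ids = [g.group_id for g in cfg.group_spec]
        for k in range(spec.n_markers):
            gid = group_ids[k % len(group_ids)]
            idx = [genes.index(g) for g in members_of[gid]]
            mean_profile = values[idx].mean(axis=0)
            noise = rng.standard_normal(len(samples)) * tau * mean_profile.std()
            marker_rows.append(np.maximum(mean_profile + noise, 0.0))
            name = f"{spec.prefix}{k + 1:02d}"
            marker_names.append(name)
            gt.markers[name] = gid
            gt.group_of[name] = gid
        matrix = ExpressionMatrix(
            genes + marker_names,
            samples,
            np.vstack([values] + [r[None, :] for r in marker_rows]),
        )

    return matrix, gt


# ---------------------------------------------------------------------------
# Proteins with planted motifs
# ---------------------------------------------------------------------------

#: Background alphabet excludes D, R and W so the planted motif components
#: are provably the only occurrences the scanner can find.
_BACKGROUND = "ACEFGHIKLMNPQSTVY"

PROTEIN_LABELS = ("QXXRW", "RXXRW", "LXXRW", "dxd_only", "absent")


@dataclass(frozen=True)
class ProteinSim:
    name: str
    sequence: str
    label: str


def gen_proteins(
    counts: Mapping[str, int],
    seed: int = 0,
    length: int = 120,
    g_min: int = 5,
) -> list[ProteinSim]:
    """Emit protein sequences with planted catalytic-motif variants.

    ``counts`` maps a label from :data:`PROTEIN_LABELS` to the number of
    sequences to generate.  The scanner must recover each label exactly:
    full scans with the named variant, ``dxd_only`` scans for sequences
    lacking the downstream components, ``absent`` for D-free sequences.
    """
    unknown = set(counts) - set(PROTEIN_LABELS)
    if unknown:
        raise SimulationError(f"unknown protein label(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out: list[ProteinSim] = []
    for label in PROTEIN_LABELS:
        for i in range(counts.get(label, 0)):
            seq = list(
                "M" + "".join(rng.choice(list(_BACKGROUND), size=length - 1))
            )
            if label != "absent":
                dxd = 5 + int(rng.integers(0, 10))
                seq[dxd], seq[dxd + 2] = "D", "D"
                if label != "dxd_only":
                    lone = dxd + 2 + g_min + 1 + int(rng.integers(0, 10))
                    seq[lone] = "D"
                    motif = lone + 5 + int(rng.integers(0, 10))
                    if motif + 5 > length:
                        motif = length - 6
                    seq[motif] = label[0]
                    seq[motif + 3], seq[motif + 4] = "R", "W"
            out.append(
                ProteinSim(
                    name=f"prot_{label}_{i + 1:03d}",
                    sequence="".join(seq),
                    label=label,
                )
            )
    return out


# ---------------------------------------------------------------------------
# One-call simulation with file output
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: GenomeSim
    matrix: ExpressionMatrix
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write catalog TSV, GFF3, anchors TSV, expression TSV and
        ground_truth.json; returns the emitted paths.  Byte-deterministic
        per seed."""
        from . import io as kio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "catalog": outdir / "catalog.tsv",
            "gff": outdir / "genes.gff3",
            "anchors": outdir / "anchors.tsv",
            "expression": outdir / "expression.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        from .catalog import write_catalog

        write_catalog(self.genome.records, paths["catalog"])
        kio.write_gff(self.genome.positions, paths["gff"])
        kio.write_anchors(self.genome.anchors, paths["anchors"], self.genome.anchor_chroms)
        kio.write_expression(self.matrix, paths["expression"])
        kio.write_json(self.ground_truth.to_dict(), paths["ground_truth"])
        return paths


def simulate(cfg: SimulationConfig | None = None) -> SimulationResult:
    """Run the full generator (genome + expression) for one configuration."""
    cfg = cfg if cfg is not None else SimulationConfig()
    genome = gen_catalog_genome(cfg, np.random.default_rng(cfg.seed))
    gene_names = [rec.gene_name for rec in genome.records]
    matrix, gt = gen_expression(
        cfg,
        genes=gene_names,
        rng=np.random.default_rng(cfg.seed + 1),
        ground_truth=genome.ground_truth,
    )
    return SimulationResult(config=cfg, genome=genome, matrix=matrix, ground_truth=gt)
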
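# cslkit

Integrative analysis of the rice *CESA*/*CSL* gene superfamily: duplication
calling, co-expression clustering, and in-silico deletion ("artificial
mutant") inference of cellulose-synthase-complex membership and partial
genetic redundancy.

## The problem

The cellulose synthase (*CESA*) and cellulose synthase-like (*CSL*) genes
encode the machinery of plant cell-wall polysaccharide synthesis.  Rice
carries 45 superfamily members in seven families (CESA, CSLA, CSLC, CSLD,
CSLE, CSLF, CSLH), phylogenetically split into Cluster I (CESA-like) and
Cluster II (CSLA/CSLC).  Three questions recur for anyone studying such a
family with a tissue-panel expression matrix:

1. **How did the family expand?**  Tandem duplicates are family members
   separated by at most *k* intervening gene models on one chromosome
   (default *k* = 5); segmental duplicates are pairs that fall into large
   collinear duplicated blocks, detected by chaining scored homologous
   anchors with a dynamic program (maximum inter-anchor gap 100 kb, minimum
   five anchors per chain — DAGchainer-style parameters).  Duplicate pairs
   are then classified by expression fate: *nonfunctionalization* (one copy
   silent, the other strongly expressed), *subfunctionalization*
   (partitioned tissue domains), *neofunctionalization candidate* (nested
   domains), or *conserved* (overlapping domains with a correlation
   significant under the two-sided t test
   `t = r·sqrt((n−2)/(1−r²))`, df = n−2, α = 0.05).

2. **Which genes work together?**  Signals are log-transformed
   (`log2(x+1)`) and genes clustered by agglomerative **complete linkage**
   on Euclidean distances, with a deterministic lexicographic tie-break.
   Cutting the dendrogram at k = 3 and k = 10 yields the major groups and
   subgroups (labelled `IA … IIIE`).  Marker genes from a wall-related
   family (BC1L/COBRA-like) anchor the biological reading: a marker whose
   best partner correlates at r ≥ 0.9 ties its group to wall synthesis.
   Tissue preference is summarized by the specificity index
   `tau = Σ(1 − x_i/x_max)/(n−1)`.

3. **Who substitutes for whom?**  The artificial-mutant screen deletes a
   complex member's expression row, re-clusters, and asks whether candidate
   substitutes are absorbed into the minimal dendrogram subtree spanning the
   remaining complex members.  If the absorption holds with all tissues but
   disappears when the supporting tissues (where the target is silent and
   the candidates are high) are excluded, the redundancy is
   **tissue-dependent** — the co-expression signature of partial functional
   complementation.

A synthetic-data generator plants all of this structure (tandem arrays,
collinear blocks, ten co-expression groups, calibrated markers, a
redundancy triple, motif-bearing proteins), so every stage is verified
against known ground truth without any downloads.

## Worked example

```python
import cslkit as ck
from cslkit.synthetic_data import SimulationConfig, simulate

cat = ck.load_packaged_catalog()          # the 45-gene rice catalog
counts = ck.family_counts(cat)
print(f"{counts.total} genes: CESA={counts.per_family['CESA']}, CSL={counts.csl_total}")
for c in ck.call_tandem(cat):
    print(f"chr{c.chromosome}: {'+'.join(c.members)}")
summary = ck.duplication_summary(ck.reported_duplication_catalog(), cat)
print("genes in duplication events:", summary["unique_genes_involved"])
print(f"critical |r| at n=33, alpha=0.05: {ck.critical_r(33):.3f}")

res = simulate(SimulationConfig(seed=1, noise_sigma=0.2))
rd = res.ground_truth.redundancy
genes = [r.gene_name for r in res.genome.records]
call = ck.redundancy_screen(
    res.matrix,
    complex_genes=set(rd["complex_partners"]) | {rd["target"]},
    target=rd["target"], candidates=rd["candidates"],
    tissues_suspected=rd["tissues"], genes=genes)
print("verdict:", call.verdict)
print("absorbed:", sorted(call.absorbed_candidates))
print("supporting tissues:", sorted(call.supporting_tissues))
```

prints

```
45 genes: CESA=11, CSL=34
chr4: OsCSLH2+OsCSLH3
chr7: OsCSLF9+OsCSLF8+OsCSLF2+OsCSLF1+OsCSLF4+OsCSLF3
chr9: OsCSLE1+OsCSLE6
genes in duplication events: 23
critical |r| at n=33, alpha=0.05: 0.344
verdict: tissue_dependent
absorbed: ['SynCESA03', 'SynCSLC05']
supporting tissues: ['plumule', 'radicle']
```

Reading: the ≤5-intervening-genes rule finds the six-member CSLF tandem
array on chromosome 7 plus the CSLH2/H3 and CSLE1/E6 pairs; together with
the seven recorded segmental pairs, 23 of the 45 genes sit in duplication
events.  On the simulated panel, deleting the planted redundancy target
pulls both candidate substitutes into the remaining complex members'
cluster, and the absorption vanishes once the plumule and radicle samples
are excluded — the tissue-dependent redundancy verdict.

## Command line

```bash
cslkit simulate --seed 1 --outdir sim            # synthetic dataset + ground truth
cslkit run-all --catalog sim/catalog.tsv --expression sim/expression.tsv \
    --gff sim/genes.gff3 --anchors sim/anchors.tsv \
    --ground-truth sim/ground_truth.json --outdir out
cslkit mutant --expression sim/expression.tsv --delete-genes SynCSLC06 \
    --focal SynCSLA08,SynCESA04 --candidates SynCESA03,SynCSLC05 \
    --exclude-tissues plumule,radicle --outdir out
```

Reports are JSON/TSV plus Newick trees and a manifest with input checksums;
reruns with the same inputs are checksum-identical.

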
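# miratlas

Tools for asking a blunt question about circulating microRNA biomarkers:
**is the microRNA even expressed in a cell type relevant to the disease it
is supposed to mark?**

MicroRNAs measured in serum, plasma or peripheral blood mononuclear cells
(PBMCs) are reported as diagnostic biomarkers for dozens of non-neoplastic
diseases. Many of these reports are hard to interpret: a microRNA that is
expressed in every cell type cannot be specific to one disease, a
microRNA with no detectable cellular expression is probably noise, and a
red-cell microRNA in plasma mostly tracks hemolysis. `miratlas` builds
the reference needed to make that judgement — a cell-type × microRNA
expression atlas from heterogeneous public array data — and then audits
biomarker reports against it, individually and corpus-wide.

It is a library for computational biologists; the public face is the
importable API plus the narrative scripts in `examples/`.

## What it does

1. **Nomenclature harmonization** (`miratlas.nomenclature`) — maps
   historical and current microRNA names (e.g. `let-7b*` → `hsa-let-7b-3p`)
   onto stable MIMAT accessions via a miRBase-aliases-style key, tracking
   guide vs carrier (minor) strand.
2. **Array ingestion** (`miratlas.ingest`) — reads series-matrix-style
   probe tables from multiple platform versions, drops arrays with > 50 %
   missing data, and collapses probes to accessions (per-sample median).
3. **Modified subset quantile normalization** (`miratlas.sqn`) — enforces
   distributional equality across samples **only on the features common to
   all platform versions**; every other feature is mapped through the
   piecewise-linear empirical CDF of the sample's subset values:

   * subset feature at rank *r* of *n* → reference quantile at (r − ½)/n,
   * other feature with value *v* → reference quantile at F̂(v), clamped
     to [½n⁻¹, 1 − ½n⁻¹].
4. **Empirical Bayes batch correction** (`miratlas.combat`) — the
   location/scale model Y_ijg = α_g + Xβ_g + γ_ig + δ_ig ε_ijg with a
   normal prior on per-chip locations γ and an inverse-gamma prior on
   scales δ², hyperparameters by method of moments, shrinkage by the
   standard fixed-point iteration; implemented from scratch and
   cross-checked against the Bioconductor reference implementation.
5. **Cell atlas** (`miratlas.atlas`) — a microRNA is *called expressed* in
   a cell type when any one sample reaches 8.0 on the log2 scale (values
   under 7.0 are array noise); hierarchical clustering of cell profiles on
   1 − Pearson correlation.
6. **Plausibility classification** (`miratlas.plausibility`) — each
   reported biomarker gets one of five categories: **likely** (expressed
   in a disease-mapped cell type, with some exclusivity), **questionable**
   (no moderate expression anywhere), **ubiquitous** (≥ 7 cell types),
   **unlikely** (expressed only in irrelevant cells), **unknown** (no
   data). PBMC studies are decided by leukocyte expression alone.
7. **Cross-study audit** (`miratlas.audit`) — de-duplication to unique
   microRNAs and (microRNA, disease) pairs, category tallies,
   within-disease replication and direction conflicts, promiscuity
   (biomarkers claimed for ≥ 9 diseases), normalization-quality classing
   (RNU6B in cell-free fluids, no normalization, and miR-451a are poor),
   and χ²/Welch-t helpers.
8. **Synthetic data** (`miratlas.simulate`) — generates every input with
   planted ground truth: nested platform probe sets (461/711/837), 18 cell
   types with paired lineage signatures, per-chip location/scale effects,
   missingness, and report tables with known correct categories.

## Worked example

```bash
python examples/classify_biomarkers.py
```

Ten microRNAs from three tuberculosis studies (two PBMC, one serum) are
classified against the bundled 18-cell-type demonstration atlas:

```
  study_id compartment mirna_name     category  expressed_cell_count            rationale_code
 TB-PBMC-1        PBMC miR-155-5p       likely                    12 pbmc_leukocyte_expression
 TB-PBMC-1        PBMC miR-155-3p questionable                     0             no_expression
 TB-PBMC-1        PBMC miR-424-5p     unlikely                     1        pbmc_not_leukocyte
 TB-PBMC-1        PBMC   miR-451a     unlikely                     1        pbmc_not_leukocyte
 TB-PBMC-2        PBMC miR-223-3p       likely                     3 pbmc_leukocyte_expression
 TB-PBMC-2        PBMC  miR-21-3p questionable                     0             no_expression
 TB-PBMC-2        PBMC miR-144-3p     unlikely                     1        pbmc_not_leukocyte
 TB-PBMC-2        PBMC miR-365-3p     unlikely                     2        pbmc_not_leukocyte
TB-serum-3       serum miR-29a-3p   ubiquitous                    16     ubiquitous_expression
TB-serum-3       serum  miR-93-3p questionable                     0             no_expression

Tally: {'unlikely': 4, 'questionable': 3, 'likely': 2, 'ubiquitous': 1}
```

miR-155-5p and miR-223-3p are leukocyte-expressed, so a PBMC assay can
plausibly detect them (likely). miR-451a and miR-144-3p live in red
cells — a PBMC study should not see them (unlikely). The three carrier
strands have no cellular signal anywhere (questionable), and miR-29a-3p
is expressed in 16 of 18 cell types — too widespread to mark any single
disease (ubiquitous).

The other examples build a full atlas from simulated multi-platform
arrays (`build_atlas_from_arrays.py`, 99.2 % of planted expression calls
recovered, hematopoietic vs non-hematopoietic cells cleanly separated),
audit a 104-study corpus (`audit_study_corpus.py`) and demonstrate
cross-platform normalization (`normalize_across_platforms.py`).

## Data

The package ships no measured data. `miratlas.datasets` provides
synthetic stand-ins (a demonstration atlas and a full-scale study grid)
constructed to encode documented cell-specificity facts and corpus
structure; real expression tables and study grids exported to the
documented TSV layouts (`read_atlas_values`, `read_study_grid`,
`read_reports`, miRBase `aliases.txt`) can be dropped in directly. See
`docs/methods.md` for the model details and limitations.
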
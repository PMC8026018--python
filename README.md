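# fibropath

Fibrotic diseases — idiopathic pulmonary fibrosis, cystic fibrosis,
systemic sclerosis, Dupuytren's disease and their relatives — share an
uncontrolled extracellular-matrix deposition phenotype but are studied and
treated in isolation. `fibropath` is a reusable, tested implementation of a
cross-disease analysis pipeline that connects case/control transcriptomics
to candidate repurposed drugs through a pathway-network random walk:

1. **Differential-expression signatures** (`fibropath.diffexpr`) — quantile
   normalization for microarray intensities; CPM ≥ 1 in ≥ 2 libraries per
   group and trimmed-mean-of-M-values (TMM) scaling for RNA-Seq counts; a
   per-gene two-sided Welch test; then the signature filter chain:
   p < .05, removal of genes with dual-sign probes, lowest-p duplicate
   resolution, and top-150 over-/under-expressed lists by |log₂FC|.
2. **Networks** (`fibropath.netbuild`) — a *gene map* (gene–gene graph
   whose edge weight sums per-evidence-type functional weights) and a
   *pathway network* (pathways linked by shared-gene counts), with
   weighted betweenness/strength/degree diagnostics that flag the top-5%
   topology-favored hubs.
3. **Guided walks** (`fibropath.pathwalks`) — a walker on the pathway
   network repeatedly draws a target pathway (gene-map-guided, or uniform
   in the null) and traverses the weighted shortest path to it
   (edge length = 1/weight); per-pathway visit tallies are the output.
4. **Odds-ratio significance** (`fibropath.pathsig`) — per pathway,
   Freq = timesWalked/totalTimesWalked, Odds = Freq/(1−Freq),
   OR = MapOdds/RandomOdds; Pearson chi-square on the 2×2 visit table with
   Benjamini–Hochberg adjustment; significant ⇔ OR > 1.3 ∧ adj p < .05.
5. **Drug re-ranking** (`fibropath.drugrank`) — signature-inverting
   candidates (connectivity score < −50 in any experiment, plus all
   L1000-style entries), Lipinski + Veber drugability (fraction of 6 rules),
   a composite score, affinity-propagation structural clusters on Tanimoto
   similarity and one top-ranked representative per cluster.
6. **Structural screening** (`fibropath.chemscreen`) — a 0.5-threshold
   candidate similarity network with failed clinical-trial drugs attached
   at ≥ 0.7; candidates near failed drugs are flagged for lower priority;
   Soergel-distance Ward clustering at cut height 1.
7. **Cross-disease synthesis** (`fibropath.integrate`) — shared-gene
   overlap matrices, the hypergeometric shared-drug test
   P(X = x) = C(m,x)·C(n,k−x)/C(m+n,k), and drug–target–pathway linkage
   with prioritization of drugs hitting ≥ 2 key pathways.

Because the original inputs are public-repository downloads and web-service
exports, the package ships a first-class synthetic-data module
(`fibropath.synthdata`) that fabricates every input with planted,
recoverable truth — planted differentially expressed genes, planted
pathway enrichment and planted structural drug clusters — so the whole
pipeline is testable offline and end to end.

## Worked example

```python
from fibropath.cli import PipelineConfig, run_pipeline

summary = run_pipeline(PipelineConfig(run_dir="runs/demo", seed=1))
```

prints (abridged) in `runs/demo/summary.json`:

```json
{
  "planted_pathways":       ["pw022", "pw024", "pw046"],
  "guided_top":             ["pw024", "pw046", "pw022"],
  "planted_in_guided_top":  ["pw022", "pw024", "pw046"],
  "key_pathways":           ["pw024", "pw046", "pw022"],
  "de_recovery": 1.0,
  "n_significant_pathways": 3,
  "n_representatives": 3
}
```

Reading: the generator planted three enriched pathways; every planted
differentially expressed gene was recovered by the signature stage
(`de_recovery` = 1.0); the gene-map-guided walk ranked exactly the
three planted pathways in its top-5% (`guided_top`), all three were
significant by the odds-ratio test, none was explainable by network
topology (so all three are *key* pathways), and the drug library's three
planted structural clusters each produced one representative inhibitor.
Stage outputs (signature tables, walk tallies, the significance table,
the similarity network, drug–target–pathway linkage) are written as TSV
next to the summary. The same run is available from the shell:

```sh
fibropath --seed 1 run-all          # or stage-by-stage:
fibropath simulate && fibropath de && fibropath networks && ...
```

## Layout

```
src/fibropath/
  synthdata.py   generators with planted truth
  diffexpr.py    normalization, Welch tests, signature filters
  netbuild.py    gene map, pathway network, topology profile
  pathwalks.py   guided/random walk engine
  pathsig.py     odds ratios, chi-square, BH, significance flags
  drugrank.py    inhibitor filter, drugability, clustering, representatives
  chemscreen.py  Tanimoto/Soergel, failed-drug network, Ward clusters
  integrate.py   overlaps, hypergeometric test, drug-target-pathway linkage
  cli.py         PipelineConfig, run_pipeline, click subcommands
  io.py          TSV / GMT / edge-list / YAML readers and writers
```

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
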
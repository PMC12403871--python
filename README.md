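# tul — transcription-unit landscape mapping for bacteria

`tul` reconstructs the transcriptional architecture of a bacterial genome
from strand-specific, single-nucleotide read-end profiles:

* **TSS calling** from dRNA-seq — a position is a transcription start site
  when its 5′-end count in the TEX-treated (enriched) library is high, the
  pseudocounted enriched/unenriched ratio clears an enrichment threshold,
  and it is a local maximum (±2 nt). Sites are merged across growth
  conditions within ±5 nt and classified **P**rimary / **S**econdary /
  **I**nternal / **A**ntisense / i**N**tergenic relative to annotated
  genes, with 5′-UTR lengths and leaderless-transcript flags.
* **TEP calling** from Term-seq — transcript 3′-end positions are local
  maxima of the 3′-end count track, classified P / S / **C**is-regulatory
  (inside a 5′-UTR) / A / N.
* **Intrinsic-terminator typing** — the 40-nt window upstream of each TEP
  is folded with an in-repo minimum-free-energy engine (nearest-neighbour
  stacks, loop penalties, Zuker-style dynamic program, exactly verifiable
  against exhaustive structure enumeration). TEPs split at the median ΔG
  into highly structured (HS) and less structured (LS); HS TEPs with ≥3
  uridines in the 10 nt after the terminator stem are **L-shaped**
  (`HS_U_RICH`), the rest **I-shaped** (`HS_U_LACK`) — the hairpin-only
  terminator variant common in high-GC genomes. Termination strength is
  the readthrough fraction: mean normalized RNA-seq coverage in
  (TEP, TEP+200] over (TEP−200, TEP].
* **TU assembly** — each TSS pairs with its nearest downstream TEP (within
  15 kb, not crossing the next primary TSS's gene block), giving
  monocistronic / polycistronic / cis-regulatory / intergenic transcription
  units, plus a COG functional-relatedness score
  (max genes in one COG category ÷ number of categories in the TU)
  compared against random same-strand neighbor runs with a two-sided
  Mann-Whitney U test.
* **Synthetic data** — a seeded generator plants genes, operons, TSSs and
  L-/I-shaped/unstructured terminator contexts in a high-GC genome and
  samples dRNA-seq / Term-seq / RNA-seq tracks with Poisson (optionally
  negative-binomial) noise, so the whole pipeline is testable against a
  known truth table without any external data.

Inputs are plain text: FASTA (genome), GFF3 (genes, optional `cog=X`
attribute), bedGraph per strand (end counts and coverage), TSV tables out.

## Worked example

```python
from tul import SimulationConfig, simulate_study
from tul.pipeline import analyze_study
from tul.tss_mapper import category_counts
from tul.terminator_typing import shape_counts

cfg = SimulationConfig(seed=1)           # 100 kb, 65% GC, 60 genes,
annotation, truth, libs = simulate_study(cfg)  # 2 conditions x 2 replicates
result = analyze_study(annotation, libs,
                       conditions=cfg.conditions,
                       n_replicates=cfg.n_replicates)

print("TSS categories:", category_counts(result.tss_records))
print("HS/LS threshold: %.1f kcal/mol" % result.hs_ls_threshold)
print("terminator shapes:", shape_counts(result.tep_records))
print("readthrough medians:",
      {k: round(v["median"], 3)
       for k, v in result.readthrough_summary["per_class"].items()})
print("TU categories:", result.tu_summary["counts"])
```

prints

```
TSS categories: {'P': 33, 'S': 0, 'I': 0, 'A': 0, 'N': 0}
HS/LS threshold: -19.4 kcal/mol
terminator shapes: {'HS_U_RICH': 6, 'HS_U_LACK': 11, 'LS': 16}
readthrough medians: {'HS_U_RICH': 0.052, 'HS_U_LACK': 0.103, 'LS': 0.5}
TU categories: {'monocistronic': 19, 'polycistronic': 14, 'cis_regulatory': 0, 'intergenic': 0}
```

All 33 planted TSSs are recovered as primary sites; the median ΔG split
lands at −19.4 kcal/mol; the three terminator classes recover their
planted readthrough levels (0.05 / 0.10 / 0.50) — L-shaped terminators
terminate ~20× more tightly than unstructured 3′ ends.

The same pipeline is scriptable from the shell:

```sh
tul simulate --outdir sim --seed 1
tul tss --genome sim/genome.fasta --gff sim/annotation.gff3 \
    --enriched-bg sim/drna_enriched_NMS_rep1_plus.bedgraph \
                  sim/drna_enriched_NMS_rep1_minus.bedgraph \
    --unenriched-bg sim/drna_unenriched_NMS_rep1_plus.bedgraph \
                    sim/drna_unenriched_NMS_rep1_minus.bedgraph \
    --out tss.tsv
```

Site tables are TSV with 1-based positions and columns
`position strand category gene conditions height enrichment utr5 leaderless`
(TSS) and `position strand category gene conditions height utr3 delta_g
structure shape u_count readthrough` (TEP); TU tables carry
`tss_position tep_position strand category n_genes genes conditions`.

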
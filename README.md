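# txdiv — transcriptome α-diversity and differential Shannon diversity

`txdiv` treats a bulk RNA-seq library as an ecological community — genes as
species, reads as individuals — and asks how evenly transcription is spread
across the genome, and how disease redistributes it. It was built for
liver-disease transcriptomics (healthy controls vs. early and severe
alcohol-associated liver disease), but nothing in it is liver-specific: any
gene × sample table of read counts and/or TPM with a sample-to-group design
works.

Two complementary views are implemented:

**Per-sample α-diversity.** For each library with counts *n₁…n_G* (total
*N*, richness *S* = number of expressed genes):

- Menhinick richness `S/√N`
- Brillouin `(ln N! − Σᵢ ln nᵢ!)/N`
- Shannon entropy `H = −Σ pᵢ ln pᵢ` (nats, pᵢ = nᵢ/N)
- Pielou equitability `J = H/ln S`
- evenness `e^H/S`
- Simpson dominance `D = Σ pᵢ²`

with one-way ANOVA + Tukey HSD across groups.

**Per-gene differential Shannon diversity (DSD).** For each sample, gene
proportions `pᵢ = TPMᵢ/ΣTPM` give a log2 entropy `H = −Σ pᵢ log₂ pᵢ` (bits),
and each gene's *percentage Shannon entropy*

```
PSE_i = (−p_i log₂ p_i) / H          0 ≤ PSE_i ≤ 1,  Σ PSE = 1
```

is its fractional contribution to the transcriptome's entropy. For a
case/control contrast, `DSD = log₂(mean PSE_case / mean PSE_control)` per
gene, alongside the conventional `DEG = log₂(mean TPM_case / mean
TPM_control)`, both with two-sided Wilcoxon rank-sum p-values and BH
q-values, significance calls at |log₂FC| ≥ 1 and −log₁₀ p ≥ 1.3, and a Venn
partition of what each metric finds. Because PSE depends only on
proportions, DSD picks up shifts in a gene's *share* of transcription even
when absolute levels barely move — and is exactly zero when a whole library
rescales uniformly.

Supporting stages: rank-abundance (Whittaker) curves and Spearman rank
correlations between group abundance profiles, low/medium/high abundance
tertile binning with per-set prevalence tables, percent coefficient of
variation, a transparent marker-mean cell-type deconvolution (proportions
normalized to 100 % per sample, ANOVA/Welch group statistics), and a
seeded synthetic-cohort generator whose disease mechanisms — silencing and
attenuation of low-abundance genes vs. amplification of dominant genes —
leave distinguishable diversity signatures.

## Worked example

```python
import txdiv as t

matrix, design, truth = t.generate_study(t.SimulationConfig(seed=1))
prof = t.profile_all(matrix, design)
print(prof.groupby("group")[["shannon_nat", "equitability_J",
                             "evenness", "dominance_D"]].mean()
      .loc[["HC", "ASH", "AH"]].round(4))
```

```
       shannon_nat  equitability_J  evenness  dominance_D
group
HC          7.0534          0.7676    0.1184       0.0049
ASH         6.4850          0.7187    0.0791       0.0064
AH          6.1962          0.7042    0.0741       0.0071
```

The default generator applies a progressive loss of low-abundance gene
expression (severity 0 → 1 → 2 across HC → ASH → AH), and the indices
respond exactly as that mechanism predicts: entropy, equitability, and
evenness fall stepwise while dominance rises — a shrinking set of genes
carries a growing share of transcription. The omnibus test agrees:

```python
res = t.group_test(prof, "shannon_nat")
# F = 723.60, p = 8.55e-30; all three Tukey pairs rejected
```

The differential arm on the severe-vs-healthy contrast:

```python
table = t.differential_table(matrix, design, "AH", "HC")
venn = t.venn_partition(table["call_deg"], table["call_dsd"], "AH_vs_HC")
print(venn.counts())
# {'deg_only_up': 0, 'deg_only_down': 52, 'dsd_only_up': 0,
#  'dsd_only_down': 0, 'common_up': 0, 'common_down': 8829, 'discordant': 0}
```

8,829 genes are called down by both metrics (the attenuated low-abundance
band), with a small DEG-only fringe — on this synthetic mechanism the two
approaches largely agree, and any DSD-only findings on real data flag
proportion shifts invisible to level-based testing.

The same stages are available as a CLI
(`txdiv simulate | diversity | dsd | compare | rankplot | deconv | run-all`),
writing tidy TSVs with metadata headers and SHA-256 manifest files; reruns
with the same seed are bit-identical.

```
txdiv run-all --seed 1 --out results/
```

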
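# adniche

Community-scale analysis of ammonia tolerance in anaerobic-digester
prokaryote communities, from 16S rRNA amplicon (ASV) count data.

Biogas production by anaerobic digestion (AD) depends on a chain of
metabolic hand-offs — hydrolysis, acidogenesis, acetogenesis,
methanogenesis — carried out by different guilds of bacteria and
archaea. Digesting protein-rich substrates such as manure releases
ammonium, and the un-ionised fraction (free NH3) is membrane-permeable
and toxic; it can halt methanogenesis outright. `adniche` provides the
statistical toolkit for asking, at the resolution of individual taxa,
*who* in such a community is sensitive to free ammonia, *who* tolerates
or even prefers it, and *which co-occurring partnerships* survive under
inhibitory conditions. It is written for microbiome researchers working
with ASV count tables, per-sample chemistry and qPCR totals from
incubation or reactor studies.

## What it computes

**Free-ammonia speciation.** Measured total ammonium nitrogen (TAN)
splits between NH4+ and free NH3 according to pH:

    [NH3] = [TAN] / (1 + 10^(-pH) / Ka),    Ka = 1.20e-9 at 37 °C

**Absolute abundances.** ASV counts are rarefied to equal depth
(default 15 000 reads), converted to relative abundance and weighted by
qPCR 16S copies mL⁻¹, avoiding compositional artefacts. Alpha
diversity (richness, Pielou's J = H′/ln S), Bray–Curtis dissimilarity
and the ANOSIM permutation test (Clarke's R) operate on these tables.

**Ammonia niche breadth.** Each taxon's response to NH3 is summarised
by Hurlbert's niche breadth over resource states j (experimental NH3
conditions) with availability r_j ∝ NH3_j and taxon profile p_j:

    B = 1 / Σ_j (p_j² / r_j),    B′ = (B − r_min) / (1 − r_min) ∈ [0, 1]

B′ → 0 means abundance concentrated where NH3 is low (*sensitive*);
B′ → 1 means abundance tracks NH3 availability (*enriched*); taxa in
between are *tolerant*. Significance is judged against a null
distribution of 999 randomly generated taxa with Benjamini–Hochberg FDR
control; fixed thresholds (0.24/0.88) can be applied instead.

**Methanogen screening.** A profile hidden Markov model
(match/insert/delete states, local alignment) is estimated from a
reference methanogen 16S alignment; ASVs are scored by forward-algorithm
log-odds (bits) against a dinucleotide-shuffle null, and hits are placed
on a neighbour-joining tree (identity p-distances, Studier–Keppler
branch lengths) alongside the references.

**Co-occurrence networks.** Per community × medium condition, pairwise
Spearman correlations among the most abundant taxa (positive, BH-adjusted)
become edges read as covarying growth; nodes are typed sensitive /
tolerant × methanogen status; clusters are connected components; network
composition is compared across conditions by Pearson chi-square.

**Synthetic experiments.** A generator emulates the full study design
(2 communities × 2 media × 4 timepoints × 3 replicates) with planted
ammonia-response classes, guild covariation, methanogen-like sequences
and exported ground truth, so every analysis can be validated end to end.

## Worked example

```sh
python examples/01_free_ammonia.py
```

```
source                 TAN   NH4+   NH3   C:N
un-adapted slurry     1.19   1.12  0.07  13.5
pre-adapted slurry    2.30   2.20  0.10  11.6
```

At pH 7.7, only 0.07 of 1.19 g N L⁻¹ is the toxic free-NH3 species; the
pre-adapted slurry carries roughly twice the un-adapted reactor's TAN.

```sh
python examples/02_niche_breadth.py
```

```
unadapted: classified {'sensitive': 75, 'tolerant': 62, 'enriched': 13}
  null thresholds B' < 0.22 (sensitive), > 0.73 (enriched); 98.7% agree with the planted classes
preadapted: classified {'sensitive': 75, 'tolerant': 60, 'enriched': 15}
  null thresholds B' < 0.22 (sensitive), > 0.72 (enriched); 100.0% agree with the planted classes
```

On a simulated experiment the null-model thresholds fall near the fixed
constants used for real data, and ~99% of taxa recover their planted
class. `examples/03–05` demonstrate the methanogen screen, a typed
network whose three clusters recover the three planted guilds, and the
one-command pipeline. The same pipeline is exposed as a CLI:

```sh
adniche run-all --seed 42 --out results/
adniche simulate --seed 1 --out sim/   # write inputs for stage-by-stage use
```

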
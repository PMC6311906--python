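# csrehmm

Cell type-specific regulatory elements (CSREs) from multi-cell-type
epigenomic maps, via a multivariate Bernoulli hidden Markov model.

## The problem

Chromatin-state segmentation tools annotate one epigenome at a time. What
they do not answer directly is *where the epigenomes of cell types differ*:
which genomic elements carry a histone-mark signature in only one cell type
(or a small group of related ones), and which mark combination — the
"histone code" — characterizes each such element. Those cell type-specific
regions are strongly enriched for regulatory elements tied to cell identity.

`csrehmm` compares binarized chromatin tracks across N cell types and M
marks jointly. It learns hidden states whose emission profiles single out
specific cell–mark combinations, then reports each maximal run of bins
assigned to a specific state as a CSRE, together with downstream
characterization: genomic-feature distribution, proximal genes, TSS
distances against matched random controls, peak-overlap enrichment with a
permutation null, expression-specificity z-scores, and Fisher/BH gene-set
enrichment.

## The model

The genome is tiled with 200-bp bins. For each mark m, peaks across the N
cell types form a binary matrix P⁽ᵐ⁾ (N × T). Bins where more than *s* cell
types share a peak (s = 2 by default) carry no specificity information and
are zeroed, giving the specificity matrix S⁽ᵐ⁾; the S⁽ᵐ⁾ are stacked
mark-major into the observation matrix O (R × T, R = M·N).

Each column of O is emitted by one of K hidden states. Since the
observation alphabet is astronomically large — (Σ_{i≤s} C(N,i))ᴹ, about
3.4 × 10¹⁶ already for N = 9, s = 2, M = 10 — state k emits each cell–mark
combination r as an independent Bernoulli with probability p_{k,r}.
Chromosomes are independent sequences sharing initial probabilities π,
transition matrix A and emissions p; the likelihood is

P(O | π, a, p) = Π_c Σ_paths π_{s₁} Π_t a_{s_{t−1},s_t} Π_r
p_{s_t,r}^{O_{r,t}} (1 − p_{s_t,r})^{1−O_{r,t}}

maximized by Baum–Welch EM (batch, or an incremental Neal–Hinton variant
that re-estimates after each chromosome), from a deterministic
entropy-splitting initialization. A state is **specific** when at least one
emission probability passes both a per-state max-gap cutoff p_s (sort the
R probabilities decreasingly, cut at the largest consecutive drop) and an
absolute floor p₀ = 0.3. Model sizes are compared with
BIC = ln(#bins)·#parameters − 2 ln L and AIC = 2·#parameters − 2 ln L,
where #parameters = (K−1) + K(K−1) + K·N·M, and state robustness across
refits by the recovery score V_{s,H} = max_{s′∈H} cor(p_s, p_{s′}).

## Worked example

A synthetic epigenome with three planted specific states (4 cell types,
3 marks, 50,000 bins, ~20% of the genome specific), run end to end:

```python
import csrehmm as ch

cfg = ch.SimulationConfig(seed=1)          # 4 cells x 3 marks, T = 50,000
bins = cfg.bins()
truth = ch.simulate_state_path(cfg)
peaks = ch.simulate_peak_matrices(cfg, truth)

O = ch.stack_from_peaks(peaks, s=cfg.s)    # specificity transform + stack
init = ch.init_entropy(O, bins, K=4)
params, trace = ch.em_fit(O, bins, init, mode="batch")
states = ch.classify_states(params, p0=0.3)
path = ch.decode(O, bins, params)
csres = ch.extract_csres(path, states, bins)
```

which prints (via the obvious reporting loops):

```
EM converged in 51 iterations, log-likelihood -130902.6
state 1: cell1_1          specific combinations: cell1/mark1=0.90
state 2: cell2_1          specific combinations: cell2/mark2=0.89, cell2/mark3=0.88
state 3: cell3_cell4_1    specific combinations: cell3/mark3=0.87, cell4/mark3=0.86
state 4: Non_4            specific combinations: none
cell1_1: 592 CSREs, median 1000 bp, 0.70 Mb covered
cell2_1: 642 CSREs, median 800 bp, 0.66 Mb covered
cell3_cell4_1: 693 CSREs, median 600 bp, 0.66 Mb covered
```

The three planted cell–mark signatures (planted emission 0.9 over a 0.05
background) are recovered to within ±0.04, state 3 correctly names a
signature shared by two cell types, and the background state is reported as
non-specific. The same pipeline is available as a CLI
(`csrehmm simulate|binarize|specify|fit|decode|call-states|select-model|annotate|enrich`),
driven by one YAML config; every command writes a provenance JSON and all
randomness derives from a single seed.

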
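# mycomediate

Analysis pipeline for testing the **mycorrhizal mediation hypothesis** in
temperate-forest vegetation plots: do woody plants that associate with
arbuscular mycorrhizal (AM) fungi facilitate the AM-associating part of the
herbaceous understory by acting as fungal propagule sources?

The package is written for plant community ecologists working with classic
phytosociological data — Braun-Blanquet relevés split into a woody and a
herbaceous stratum, species trait tables (mycorrhizal status, Ellenberg
indicator values) and plot coordinates — who want a reproducible, tested
implementation of the full inference chain rather than a one-off script.

## The analysis

Per plot *s*, species covers are the van der Maarel ordinal transforms
*c<sub>is</sub>* of extended Braun-Blanquet codes. Each species carries a
mycorrhizal weight *w<sub>i</sub>* ∈ {0, w<sub>mixed</sub>, 1} (non-AM /
facultatively AM / obligately AM; unknown-status species are excluded).
The core quantities are AM-weighted community shares per stratum,

> RA<sub>s</sub> = Σ<sub>i</sub> w<sub>i</sub> c<sub>is</sub> / Σ<sub>i</sub> c<sub>is</sub>  (relative abundance), RR<sub>s</sub> = Σ<sub>i</sub> w<sub>i</sub> / S<sub>s</sub>  (relative richness),

plot environments are inferred as cover-weighted means of Ellenberg
R/N/F indicator values (excluding indifferent species), and the chain then
runs:

1. **Strata comparison** — paired t tests of AM share, understory vs canopy.
2. **Richness response** — tie-corrected Kendall τ-b of herb AM relative
   richness against woody AM relative abundance (full gradient, rank-based,
   no spatial correction).
3. **Abundance response** — one-breakpoint segmented regression
   *y = a + b₁x + b₂(x − ψ)₊* to find the saturation point ψ of the
   woody-AM effect; plots below ψ are then refit with an ordinary linear
   model and with GLS under an exponential spatial correlation with nugget,
   cor(d) = (1 − ν)·exp(−d/ρ).
4. **Path models** — five small recursive SEMs (partial-correlation path
   analyses) that let an inferred environmental axis (R, N, F) or the
   herb/woody log response ratio confound the woody→herb path, ranked by
   AIC; plus two-stage marginal residual tests.
5. **Sensitivity** — the whole abundance analysis repeated for
   w<sub>mixed</sub> = 0.00, 0.05, …, 1.00 and for an alternative
   mycorrhizal status source.

A synthetic-data generator (`mycomediate.synthetic_data`) produces
structurally faithful survey bundles — clustered plots, spatially
autocorrelated gradients, niche-driven species occurrence, ordinal cover
codes — with known ground truth (true breakpoint, mediation effect), so
every stage has recovery, calibration and power tests. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from mycomediate import AnalysisConfig, SyntheticTruth, generate, run_all

sb = generate(SyntheticTruth(seed=42))          # 415 plots, 77 forests, 220 species
report = run_all(sb.to_input_bundle(), AnalysisConfig())

sa = report.strata_abundance
print(f"AM share, understory vs canopy: {100*sa.mean_herb:.2f}% vs "
      f"{100*sa.mean_woody:.2f}% (t = {sa.t:.1f})")
rich = report.richness["relative"]
print(f"richness response: Kendall tau = {rich.estimate:.3f}, p = {rich.p_value:.2g}")
ab = report.abundance
print(f"breakpoint: {100*ab.seg.psi:.2f}% woody AM relative abundance")
print(f"subset (n = {ab.n_used}): slope t = {ab.t_plain:.2f}, p = {ab.p_plain:.2g}")
```

prints

```
AM share, understory vs canopy: 12.86% vs 7.76% (t = 16.8)
richness response: Kendall tau = 0.143, p = 1.7e-05
breakpoint: 6.03% woody AM relative abundance
subset (n = 188): slope t = 4.03, p = 8.2e-05
```

i.e. the understory carries a higher AM share than the canopy, AM herb
richness rises with woody AM abundance across the whole gradient, and the
abundance response rises steeply only below a low woody-AM threshold
(true generating value 4.3%) — the propagule-limitation signature.

The same analysis is available from the shell:

```bash
mycomediate simulate --preset weser-elbe-like --seed 42 --out data/
mycomediate run --plots data/plots.tsv --traits data/traits.tsv \
    --meta data/plots_meta.tsv --out report/
```

Real data enter through three TSV files (`plots.tsv`, `traits.tsv`,
`plots_meta.tsv`; column contracts in `mycomediate.io_model`) and an
optional `config.yaml` (conversion table, w<sub>mixed</sub>, stage
switches, spatial options).

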
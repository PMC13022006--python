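# plumetroph

Detecting mixotrophy and mixoplankton in marine seston from amino-acid
nitrogen isotopes, with the supporting pigment chemotaxonomy, hydrographic
habitat features and trophic-mode prediction used to interpret the signal
along a river plume.

## Who this is for

Biological oceanographers and isotope ecologists working with
compound-specific stable isotope analysis of amino acids (CSIA-AA) in
mixed planktonic samples, where the nutritional mode of the community —
pure photoautotrophy, osmotrophy (uptake of dissolved organic matter),
phagotrophy (ingestion of prey), or all three combined (mixoplankton) —
must be inferred from bulk seston rather than cultures.

## The method

The trophic position (TP) of seston is estimated from the δ¹⁵N offset
between a *trophic* amino acid (glutamic acid + glutamine, Glu, or
alanine, Ala), which enriches in ¹⁵N with each trophic transfer, and the
*source* amino acid phenylalanine (Phe), which barely fractionates:

```
TP_Glu = (δ¹⁵N_Glu − δ¹⁵N_Phe − 3.4) / 7.6 + 1
TP_Ala = (δ¹⁵N_Ala − δ¹⁵N_Phe − 3.2) / 5.7 + 1
```

Lines of constant TP in the (δ¹⁵N_Phe, δ¹⁵N_trophic) plane —
*trophoclines* — have slope 1 and intercept β + TDF·(TP − 1): 3.4, 7.2 and
11.0 ‰ for Glu and 3.2, 6.05 and 8.9 ‰ for Ala at TP 1.0, 1.5 and 2.0.
Because osmotrophy raises TP_Glu but not TP_Ala, while protistan
phagotrophy raises TP_Ala without a commensurate TP_Glu response, the pair
(TP_Glu, TP_Ala) resolves four nutritional modes; TP_Glu ≈ 1.5 *and*
TP_Ala ≈ 1.5 is the mixoplankton signature.

Around this core the package provides:

- **chemtax** — a ChemTax-style non-negative unmixing of HPLC diagnostic
  pigments onto eight microalgal classes (60 randomised ratio matrices ×
  3 runs with best-6 averaging), seeded by the published initial and
  converged ratio matrices;
- **hydro** — station habitat features: Brunt–Väisälä N² and mixed-layer
  depth, nutricline depths by linear interpolation, the piecewise nitrate
  availability index (NAI), oxygen saturation, plume thickness;
- **community** — Manhattan-distance hierarchical clustering of
  compositions with a PCA clustering-tendency check, and the
  diagnostic-pigment mean-size index;
- **tree** — a C4.5-family decision tree (gain ratio, fractional
  missing-value weighting, pessimistic pruning) predicting the dominant
  trophic mode from station features, reporting attribute usage and
  training error;
- **synthetic** — generators for every input table with known ground
  truth (archetype δ¹⁵N profiles with replicate-level analytical noise,
  pigment mixtures, two-layer plume casts, labelled station sets);
- **pipeline** — schema-validated delimited-text IO and a reproducible
  end-to-end runner, plus a thin `plumetroph` CLI.

## Worked example

```python
import pandas as pd
from plumetroph import classify_profiles

samples = pd.DataFrame([
    {"sample_id": "pure_autotroph", "d15n_phe": 5.0, "d15n_glu": 8.4,  "d15n_ala": 8.2},
    {"sample_id": "osmotroph",      "d15n_phe": 5.0, "d15n_glu": 12.2, "d15n_ala": 8.2},
    {"sample_id": "phagotroph",     "d15n_phe": 5.0, "d15n_glu": 8.4,  "d15n_ala": 11.05},
    {"sample_id": "mixoplankton",   "d15n_phe": 5.0, "d15n_glu": 12.2, "d15n_ala": 11.05},
])
print(classify_profiles(samples)[["sample_id", "tp_glu", "tp_ala", "mode"]])
```

prints

```
     sample_id  tp_glu  tp_ala                      mode
pure_autotroph     1.0     1.0            photoautotroph
     osmotroph     1.5     1.0       osmo_photoautotroph
    phagotroph     1.0     1.5      phago_photoautotroph
  mixoplankton     1.5     1.5 osmo_phago_photoautotroph
```

Each TP is the sample's position in trophic-level units: 1.0 is pure
photoautotrophy, 1.5 means half the amino-acid nitrogen passed through one
heterotrophic step.  A raised TP_Glu alone flags osmotrophy, a raised
TP_Ala alone flags phagotrophy, and both together flag mixoplankton.

The `examples/` directory has one short script per capability
(`trophic_modes.py`, `pigment_unmixing.py`, `station_features.py`,
`community_clusters.py`, `mode_tree.py`, `full_pipeline.py`); each builds
a small input, runs the method and explains the numbers it prints.  For
instance `examples/mode_tree.py` induces the trophic-mode tree on planted
niche rules and prints

```
mld <= 36.4074?
    yes: surface_chla <= 0.175532?
        yes: -> Dominant Autotroph (weight 14.0)
        no:  -> Dominant Mixotroph (weight 50.0)
    no:  -> Dominant Autotroph (weight 36.0)

Training error: 0.0%
```

— the tree recovers the generating thresholds (mixed layer ≤ 37 m,
surface chlorophyll a > 0.171 µg L⁻¹) from the data alone.

## Documentation

`docs/methods.md` describes the model assumptions, parameter defaults,
what the synthetic generators do and do not emulate, and the numerical
choices; `docs/formats.md` documents the delimited-text table schemas.
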
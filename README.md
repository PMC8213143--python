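# mritexture

Grey-level discretization effects on 3D texture features of brain-MRI
lesions.

Radiomic texture indices (TIs) are computed from grey-level matrices —
co-occurrence (GLCM), run-length (GLRLM) and size-zone (GLSZM) — after the
continuous voxel intensities of a volume of interest (VOI) have been
discretized to a small set of integer grey levels. The discretization
convention is not a detail: it changes TI values by orders of magnitude,
drives spurious correlation between TIs and lesion volume, and decides how
many TIs separate pathological from healthy tissue. This package is for
researchers doing MRI radiomics who want those effects quantified and
reproducible: it implements the three conventions in use, the full 40-index
feature set, both common segmentation styles, and the statistical
comparison stages, with a synthetic brain-lesion phantom cohort generator
standing in for patient data.

## The three schemes

For voxel intensities `I(i)` in a VOI with minimum `I_min` and maximum
`I_max`:

| scheme | family | level of voxel *i* |
|---|---|---|
| LAR (lesion absolute resampling) | fixed bin size `B` | `floor(I(i)/B) − floor(I_min/B) + 1` |
| AR (absolute resampling) | fixed bin size `B` | `ceil(I(i)/B) − 1` |
| LRR (lesion relative resampling) | fixed bin number `D` | `1` if `I(i)=I_min`, else `ceil(D·(I(i)−I_min)/(I_max−I_min))` |

LAR and AR winsorize intensities to the VOI's 10th–90th percentile first;
LRR maps the raw VOI range onto `{1..D}`. Swept grids are
`B ∈ {1, 5, …, 100}` and `D ∈ {8, 16, …, 1024}`, with `B = 50` / `D = 64`
as headline settings. From each discretized VOI, 18 GLCM + 11 GLRLM +
11 GLSZM indices are computed with the standard reference formulas
(13-direction merged symmetric GLCM, merged runs, 26-connected zones).

The analysis stages mirror a discretization-comparison study: Spearman
correlation of every TI with lesion volume per disease group, role and
contrast (`R² > 0.5`, i.e. `|R| > 0.71`, flags high correlation), and
two-sided Wilcoxon rank-sum screening of pathological versus mirrored
co-lateral control VOIs at strict `p < 0.05`.

## Worked example

```python
import numpy as np
from mritexture import (CohortDesign, DiscretizationScheme,
                        extract_features, generate_cohort)

design = CohortDesign(n_is=1, n_ms=1, n_tu=1, master_seed=7)
subject = generate_cohort(design)[2]          # the tumor subject
volume = subject.volumes["T1"]
lesion = subject.lesion_masks[0]

for scheme in (DiscretizationScheme.ar(50.0), DiscretizationScheme.lrr(64)):
    feats = extract_features(volume.voxels, lesion, scheme,
                             spacing=volume.spacing)
    print(f"{scheme.tag():>8}:",
          f"JEntropy={feats['glcm_JEntropy']:.3f}",
          f"Contrast={feats['glcm_Contrast']:.3f}",
          f"Correlation={feats['glcm_Correlation']:.3f}",
          f"RP={feats['glrlm_RP']:.3f}")
```

prints

```
   AR_50: JEntropy=4.133 Contrast=0.835 Correlation=0.855 RP=0.505
  LRR_64: JEntropy=9.912 Contrast=34.097 Correlation=0.889 RP=0.922
```

The same lesion, discretized two ways: joint entropy and contrast shift by
factors of 2–40 between fixed bin size at `B = 50` and fixed bin number at
`D = 64`, while GLCM Correlation barely moves — it is one of the two
indices that stay nearly independent of the binning parameter. Comparing
TI values across studies is only meaningful at matched discretization
settings.

The stages also compose as scikit-learn transformers
(`GreyLevelDiscretizer`, `TextureFeatureExtractor`, each over a list of
`(volume, mask)` samples), and a thin CLI wraps the pipeline:

```sh
mritexture run-study --seed 1 --out study_out      # simulate → extract → stats
mritexture extract --volume t1.nii.gz --mask voi.nii.gz --method AR --bin-width 50
```

Real NIfTI volumes/masks and Carimas-style plain-text per-voxel lists are
ingested through `mritexture.pipeline.real_data_ingest`; no patient data is
bundled.

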
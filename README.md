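# brainbehavior

Automated regional behavioral analysis of human brain images.

Functional-imaging databases catalogue tens of thousands of activation
foci — peak stereotaxic coordinates from published experiments — each
labelled with behavioral categories (51 sub-domains across the Action,
Cognition, Emotion, Interoception and Perception domains). `brainbehavior`
turns such coordinate tables into a 4-D behavioral probability-density
image PDF(x, y, z, b) and scores any spatially normalized region of
interest (ROI) against every behavior, producing a ranked "behavior
profile". It is aimed at neuroimaging researchers who want an automatic,
reproducible answer to *"which behaviors are associated with this region?"*
for ROIs drawn from statistical maps, anatomical atlases, or spheres at
coordinates of interest.

For each sub-domain *b* with whole-brain focus total N_b:

* p_o = Σ_{v ∈ ROI} PDF(v, b) — observed probability (fraction of the
  behavior's foci inside the ROI),
* p_e = vol(ROI ∩ brain)/vol(brain) — expected probability under spatial
  uniformity,
* z = (p_o − p_e) / √[(p_o(1 − p_o) + p_e(1 − p_e)) / N_b], significant
  when the effect p_o − p_e is positive and z ≥ 3.0 (a Bonferroni-style
  guard for 51 simultaneous tests).

Also included: hemispheric lateralization statistics
(z = (f − 0.5)/√(f(1 − f)/N) on the left fraction f), behavior-specific
ROIs (Gaussian-smoothed channels thresholded at a fraction of their
maximum) with a self-consistency rank matrix, MNI→Talairach affine
adjustment, ROI tools (threshold / atlas labels / spheres / dilation /
half-space clip / 1↔2 mm precision conversion), and a synthetic foci
generator with known ground truth so the whole pipeline is testable
without database access. See `docs/methods.md` for the model details and
numerical conventions.

## Worked example

Generate a synthetic database in which sub-domain 1 (Action:Execution:Other)
is tightly clustered at a motor-cortex-like site while the other 50
sub-domains are spatially uniform, then profile a 12-mm sphere over the
cluster:

```python
import brainbehavior as bb

suite = bb.known_answer_suite(seed=7)          # foci, brain mask, ROI fixtures
pdf = bb.assemble_pdf4d(suite.recovery.foci, suite.grid)
profile = bb.analyze(pdf, suite.recovery.roi, suite.brain)
print(profile.to_frame().head(5).to_string(index=False))
```

```
 rank  subdomain_id     domain            name  n_foci  foci_in_roi  p_obs  p_exp        z  significant
    1             1     Action Execution:Other    8518         6758 0.7934 0.0037 177.9923         True
    2            32    Emotion Happiness:Other    1060            8 0.0075 0.0037   1.1728        False
    3            48 Perception    Vision:Color     201            3 0.0149 0.0037   1.1691        False
    4            20  Cognition           Music     822            6 0.0073 0.0037   0.9763        False
    5            27    Emotion           Anger     507            4 0.0079 0.0037   0.8709        False
```

79 % of the clustered behavior's 8 518 foci fall inside the sphere against
an expected 0.4 % for a region of this size (0.4 % of brain volume), so its
z-score dwarfs the threshold; every uniform sub-domain stays near z = 0 and
only the planted behavior is flagged.

Lateralization from the shipped 2012 hemispheric tallies:

```python
from brainbehavior.symmetry import reference_laterality_frame
print(reference_laterality_frame().head(4).to_string(index=False))
```

```
       subdomain domain  n_left  n_right  n_total  left_fraction     z  significant
 Execution:Other Action    3924     3270     7194           0.55  7.74         True
Execution:Speech Action    1625     1254     2879           0.56  6.97         True
     Imagination Action     645      454     1099           0.59  5.85         True
      Inhibition Action    1036     1254     2290           0.45 -4.58         True
```

The classic pattern appears: language-related and most action sub-domains
lean left (f > 0.5, z > 0), response inhibition leans right.

The same workflows are available from the shell:

```bash
brainbehavior simulate --spec sim.yaml --seed 9 --out foci.csv --brain-out brain.nii.gz
brainbehavior build-pdf --foci foci.csv --spacing 2 --out pdf.nii.gz
brainbehavior make-roi sphere --center -32,-24,48 --radius 12 --out roi.nii.gz
brainbehavior analyze --pdf pdf.nii.gz --roi roi.nii.gz --brain brain.nii.gz --out profile.csv
brainbehavior symmetry --foci foci.csv --out laterality.csv
```

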
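# morphoclass

Classification of transcription-factor-bound genomic regions by their
sensitivity to morphogen concentration, with the surrounding chromatin
analysis: differential binding from ChIP-seq counts, chromatin accessibility
and nucleosome positioning from ATAC-seq, motif content, and absolute
concentration estimation from Western blots.

The motivating system is the Bicoid (Bcd) anterior–posterior gradient in the
early *Drosophila* embryo: transgenic lines express Bcd at single uniform
concentrations (low/med/high ≈ 12.6, 98.8, 242.6 nM nuclear), and each
Bcd-bound peak is classified by which pairwise concentration contrasts show a
significant loss of binding. The package is written for regulatory-genomics
analysts who want that pipeline as a tested, reusable library rather than a
one-off script collection, and it ships a synthetic-data generator so the
whole pipeline runs end-to-end with known ground truth and no downloads.

## The statistics at the core

**Differential binding.** Region read counts are modelled as negative
binomial with a common dispersion φ (variance = μ + φμ²). For a two-group
comparison, replicate counts are scaled to a common library size and summed;
conditional on the total *s = a + b* the null law of *a* is known exactly
(a sum of i.i.d. NB variables is NB), and the two-sided exact p-value is

    p = Σ { f(x) : f(x) ≤ f(a), 0 ≤ x ≤ s }

with BH-FDR adjustment per contrast across all peaks plus 50,000 non-peak
noise regions. The decision table over the three contrasts (high–med,
high–low, med–low, significance = q ≤ 0.05 *and* reduced binding at the
lower concentration) assigns each peak one of five labels:

| class | pattern |
|---|---|
| CS-I | reduced high→med and high→low |
| CS-II | reduced high→low and med→low |
| CS-III | reduced high→low only |
| Insensitive | no significant contrast |
| Unclassified | any increase at lower dose, or residual patterns |

**ATAC fragment sizes** are fitted by EM to a two-component mixture
w·Exp(λ) + (1−w)·N(μ, σ): sub-nucleosomal fragments from open chromatin
plus nucleosome-protected fragments. Fragments ≤ 100 bp define the open
subset. Differential accessibility between wild-type and mutant genotypes
reuses the exact test (peaks + 25,000 background regions) and flags
dependence when accessibility is significantly reduced in the mutant.

**Motifs** are scanned with log-odds PWMs at the conventional 80%
normalized-score threshold; class enrichment and group score differences are
tested by permutation (n = 10,000).

**Concentration chain.** Total protein per embryo (1.5×10⁸ molecules) ×
nuclear fraction 4/(4+9) ≈ 0.31, over 6,000 nuclei → 7,750 molecules/nucleus
for a wild-type dose; the optical calibration 8 nM ≙ 690 molecules gives
0.011594203 nM/molecule. A line's Western band intensity relative to wild
type scales the molecule count linearly.

## Worked example

```python
from morphoclass import (BindingSensitivityModel, estimate_nuclear_concentration)
from morphoclass.synthetic import SyntheticConfig, generate_world, simulate_chip_counts

world = generate_world(SyntheticConfig(seed=1))          # 4 x 250 peaks + noise
chip, is_noise = simulate_chip_counts(world)             # NB counts at 3 doses
res = BindingSensitivityModel(chip, ("high", "med", "low"), is_noise).fit()
print(res.summary())
print(estimate_nuclear_concentration(0.14))              # lowest uniform line
```

prints

```
Concentration-sensitivity classification
========================================
regions tested: 51000 (1000 peaks, 50000 noise)
common dispersion: 0.0483
FDR threshold:     0.05

class sizes:
  CS-I            248  (24.8%)
  CS-II           330  (33.0%)
  CS-III           91  (9.1%)
  Insensitive     309  (30.9%)
  Unclassified     22  (2.2%)

(1085, 12.58)
```

The estimated dispersion matches the simulated φ = 0.05; a line at 0.14× the
wild-type dose carries ≈ 1,085 Bcd molecules per nucleus ≈ 12.58 nM. The
CS-III deficit relative to the planted 250 reflects that class's
borderline-power definition (see `docs/methods.md`).

The same stages are available from the shell:

```bash
morphoclass --seed 1 --out-dir out simulate
morphoclass --out-dir out diffbind-classify --counts out/chip_counts.tsv
morphoclass --out-dir out quantify --intensities western.tsv
```

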
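# cesakit

A toolkit for the computational arc of cellulose synthase (CESA)
structure–function studies: deciding which glucan-contacting residues of
the transmembrane translocation channel are worth mutating, and measuring
what the mutations do to the cell wall.

Cellulose synthases polymerize β-1,4-glucan on the cytoplasmic side of the
plasma membrane and extrude the nascent chain through a channel lined by
transmembrane helices. Which channel residues actually grip the sugar — by
hydrogen bonds to its equatorial hydroxyls and CH-π stacking of aromatic
rings on its axial C–H faces — can be read off an all-atom MD trajectory of
the enzyme–glucan complex. Alanine mutants of the strongest-contact
residues are then scored in genetic complementation assays, and the
resulting cell walls are examined by grazing-incidence wide-angle X-ray
scattering (GIWAXS) for changes in cellulose texture. `cesakit`
implements every quantitative step of that pipeline:

* **`structures_io`** — multi-model PDB structures/trajectories, nonbonded
  parameter tables, an atom-selection mini-language, Kabsch superposition
  RMSD.
* **`contact_metrics`** — per-frame residue–glucan contacts (minimum
  side-chain heavy-atom distance ≤ 5.0 Å) with total contact time (%),
  mean contact lifetime, and a sigmoid-weighted contact score
  Σ 1/(1 + e^{5(d−4.0)}).
* **`interaction_geometry`** — geometric H-bond detection
  (d(D···A) ≤ 3.5 Å, ∠DHA ≥ 120°) and CH-π detection (C–centroid ≤ 4.5 Å,
  projected offset ≤ 2.0 Å, ∠(C→H, ring normal) ≤ 40°), with per-pair
  occupancy times.
* **`energetics`** — linear-interaction-energy style Coulomb +
  Lennard-Jones decomposition with a 1.2 nm truncation cutoff and
  Lorentz–Berthelot combination.
* **`residue_selection`** — the strong-contact rule (total contact time
  ≥ 80% on ≥ 2 of the 3 monomer channels of the homotrimer) and the
  five-way side-chain chemistry classification.
* **`scattering`** — GIWAXS reduction on an idealized flat detector:
  ±17° vertical sector cuts, Gaussian deconvolution of the cellulose (200)
  reflection over a flat background, d = 2π/q, Scherrer length
  L = Kλ/(β cos θ), azimuthal (110) profiles, rocking-scan averaging,
  χ-pole-figure stitching, pole FWHM, and relative crystalline cellulose
  content RCCC ∝ ∫₀^{π/2} sin χ · I(χ) dχ.
* **`phenotype_stats`** — Wilson score intervals for complementation
  proportions, two-tailed Fisher exact tests, and cell-outline shape
  descriptors (circularity 4πA/P²).
* **`synthetic_data`** — seeded generators for every input class with
  exactly known ground truth (designed occupancies, designed peak
  positions and orientation widths, binomial rescue counts, elongated
  cell polygons).

## Worked example

Generate a toy channel trajectory with designed interaction occupancies
and recover them with the analysis stages:

```python
import warnings
from cesakit import synthetic_data as sd, contact_metrics as cm, \
    interaction_geometry as ig

spec = sd.TrajectorySpec(
    pairs=(sd.PairSpec("SER", contact_pct=80, hbond_pct=40),
           sd.PairSpec("TRP", contact_pct=90, chpi_pct=60)),
    n_frames=100, seed=7)
result = sd.synth_trajectory(spec)
traj = result.trajectory

for i, p in enumerate(spec.pairs):
    series = cm.contact_series(traj, [("A", i + 1, "G")])[0]
    s = cm.summarize_series(series)
    hb = ig.hbond_time(traj, ("A", i + 1), "G")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cp = ig.chpi_time(traj, ("A", i + 1), "G")
    print(f"{p.residue_name}{i+1}  total={s.total_contact_time:5.1f}%  "
          f"lifetime={s.mean_lifetime_frames:.2f} frames  "
          f"score={s.mean_score:.2f}  hbond={hb:.1f}%  chpi={cp:.1f}%")
```

prints

```
SER1  total= 80.0%  lifetime=4.00 frames  score=1.05  hbond=40.0%  chpi=0.0%
TRP2  total= 90.0%  lifetime=9.00 frames  score=23.92  hbond=0.0%  chpi=60.0%
```

The serine makes a contact in exactly 80% of frames (40% of all frames as
a hydrogen bond), the tryptophan in 90% (60% stacked); occupancies are met
exactly because the generator toggles geometry on deterministic interleaved
masks, and the lifetime is the mean length of consecutive-contact runs.
The contact score sums a sigmoid weight over all atom pairs within the
cutoff, so the large stacked tryptophan ring scores far higher than the
single serine hydroxyl contact.

The same pipeline is scriptable from a shell:

```sh
cesakit synth traj --n-frames 100 --pair SER:80:40:0 --out-prefix toy
cesakit contacts --traj toy_traj.pdb --out contacts.tsv
cesakit energy --traj toy_traj.pdb --params toy_params.tsv --out energy.tsv
cesakit select --metrics metrics.tsv --threshold 80 --min-chains 2 --out report.tsv
cesakit giwaxs fit --image giwaxs.txt --out fit.tsv
cesakit pheno ci --counts counts.tsv
```

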
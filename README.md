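# arterial-atlas

Construction of probabilistic and sharp-label **arterial territory atlases**
from cohorts of binary stroke-lesion masks co-registered to a common template
grid.

When a brain artery is occluded, the resulting infarct falls inside that
artery's perfusion territory. Given many patients whose strokes each affect a
single major territory — anterior, middle, or posterior cerebral artery (ACA,
MCA, PCA) or the vertebro-basilar system (VB) — the spatial distribution of
their lesion masks reveals the territories themselves. This package
implements that construction end to end:

- **Average method.** For territory *s* with *N<sub>s</sub>* subjects, the
  probabilistic map is the voxelwise lesion frequency
  *p<sub>s</sub>(j) = Σ<sub>i: s_i=s</sub> X<sub>i,j</sub> / N<sub>s</sub>*.
  Border zones between two territories are characterized by the ratio
  *p<sub>a</sub>/p<sub>b</sub>* on the region where both are positive.
- **Bernoulli mixture model (BMM).** Each territory's masks are modelled as a
  mixture of *K* clusters with priors *π<sub>k</sub>* and voxelwise Bernoulli
  rates *µ<sub>k,j</sub>*, fitted by EM. *K* is the largest value for which
  every fitted cluster keeps at least 10% of the group. The territory map is
  *µ<sub>max</sub>(j) = max<sub>k</sub> µ<sub>k,j</sub>*; per-cluster
  expectations *N<sub>k</sub> = π<sub>k</sub>N* and
  *E[V<sub>k</sub>] = Σ<sub>j</sub> µ<sub>k,j</sub>* summarize cluster size
  and lesion volume.
- **Territory claiming and sharp atlases.** A voxel is claimed by a territory
  when some cluster satisfies *µ + α√(µ(1−µ)) ≥ 1* (equivalently
  *µ ≥ 1/(1+α²)*; exactly 0.1 at the default α = 3). Multiply-claimed voxels
  go to the largest *µ<sub>max</sub>*; unclaimed brain voxels are
  water-spread to the metrically nearest labelled territory; a majority
  filter smooths the result into level-1/level-2 hierarchical label volumes
  with a plain-text lookup table.
- **Certainty index.** *CI<sub>s</sub> = P<sub>s</sub> / Σ<sub>s</sub>
  P<sub>s</sub>*, summarized per ROI of any parcellation.
- **Registration QC.** Strip regions around the brain mask (OSBM/ISBM) and
  lateral ventricles (OSLV) yield misregistration ratios γ for deformed B0
  volumes, with a configurable CSF cutoff λ (default mean − 0.5·sd of
  in-ventricle intensities).

Everything is exercised on a synthetic phantom cohort with planted mixture
parameters, so every stage has recoverable ground truth without any data
download.

## Worked example

The numbered drivers under `analysis/` run the whole study on a 32³ phantom
(4 territories, planted cluster counts K\* = 1, 2, 2, 3; 25/200/25/25
subjects, 30% right-hemisphere):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_average_maps.py
python analysis/03_bmm_fit.py
python analysis/04_build_atlas.py
python analysis/05_registration_qc.py
```

`03_bmm_fit.py` prints the per-territory model selection and recovered
priors — for the large MCA group (planted π\* = 0.7/0.3) it reports

```
MCA: N=200, selected K=2, pi=[0.675, 0.325]
```

i.e. the 10%-floor rule recovers the planted cluster count and the priors to
within sampling error, while the small 25-subject groups illustrate the
rule's instability at low *N* (see `docs/methods.md`). `02_average_maps.py`
reports the planted MCA–PCA border zone

```
border zone MCA/PCA: 25 shared voxels, 68.0% more often lesioned in MCA strokes
```

and `05_registration_qc.py` shows the QC ratios rising monotonically with
phantom misalignment (γ_OSBM = 0 at perfect alignment, 0.141 at a 2-voxel
shift). `04_build_atlas.py` writes the claim map, the sharp level-1/level-2
atlases and their lookup table under `results/atlas/`.

The same steps are available as a CLI (`arterial-atlas simulate | average |
bmm | assign | qc | exclude | run-all`).

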
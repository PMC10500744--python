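# rd5d — 5D relaxation–diffusion correlation MRI

`rd5d` resolves the microscopic composition of imaging voxels from MRI data
that is encoded jointly for transverse relaxation and for diffusion with
variable-shape b-tensors.  It is aimed at quantitative-MRI researchers who
work with multidimensional diffusion acquisitions and want, per voxel, not a
single effective tensor but a *distribution* of microscopic environments —
e.g. separating cerebrospinal fluid, gray-matter-like and white-matter-like
signal fractions inside one voxel — together with uncertainty estimates.

## Model and method

Each acquisition point is described by (τE, b, bΔ, Θ, Φ): echo time,
b-tensor trace, normalized b-tensor anisotropy and orientation.  A voxel is
a weighted set of components (R2, D∥, D⊥, θ, φ), and each component
attenuates as

    K = exp(−τE R2) · exp(−b Diso [1 + 2 bΔ DΔ P2(cos β)]),

with Diso = (D∥+2D⊥)/3, DΔ = (D∥−D⊥)/(3Diso), P2 the second Legendre
polynomial and β the angle between the encoding and diffusion symmetry axes.

The inverse problem — a discrete distribution P(R2, **D**) from a few
hundred measurements — is solved by a nonparametric Monte Carlo search:
repeated rounds of random candidate seeding, non-negative least-squares
(NNLS) weight fitting, pruning, and mutation polishing, finalized to at most
10 components per solution.  Repeating the search N = 96 times (optionally
on bootstrap-resampled measurements) yields a per-voxel solution ensemble
whose median/MAD condense any derived statistic into a value and an
uncertainty.  Components are grouped into "big"/"thin"/"thick" bins in
(Diso, D∥/D⊥, R2) space that loosely capture CSF, white and gray matter.

See `docs/methods.md` for the full method description, parameter tables and
known limitations.

## Worked example

Simulate three voxels (pure anisotropic white-matter-like, pure CSF-like,
and a 50/50 mixture) at SNR 50 with Rician noise, invert them with
16-member ensembles, and summarize:

```python
import numpy as np
from rd5d import (MonteCarloInverter, EnsembleSummarizer, PhantomSpec,
                  generate_phantom, preset_scheme)

scheme = preset_scheme("mini")                      # 51-point test protocol
spec = PhantomSpec(voxels=[[("wm", 1.0)], [("csf", 1.0)],
                           [("wm", 0.5), ("csf", 0.5)]],
                   snr=50.0, noise="rician", seed=7)
signal, truth = generate_phantom(spec, scheme)      # (3, 51) array

inv = MonteCarloInverter(scheme, n_ensemble=16, random_state=0).fit(signal)
summarizer = EnsembleSummarizer()
table = summarizer.transform(inv.ensembles_)        # long-format DataFrame

for v, label in enumerate(["WM", "CSF", "WM+CSF"]):
    s = summarizer.summaries_[v]
    print(f"{label:7s} E[R2] = {s.stats['e_r2']:5.1f} ± "
          f"{s.uncertainty['e_r2']:4.1f} /s   "
          f"E[Diso] = {s.stats['e_d_iso']*1e9:4.2f} um2/ms   "
          f"fractions big/thin/thick = "
          f"{s.bins['big'].fraction:.2f}/{s.bins['thin'].fraction:.2f}/"
          f"{s.bins['thick'].fraction:.2f}")
```

Output:

```
WM      E[R2] =  18.0 ±  0.7 /s   E[Diso] = 0.87 um2/ms   fractions big/thin/thick = 0.00/0.98/0.00
CSF     E[R2] =   1.3 ±  0.3 /s   E[Diso] = 3.08 um2/ms   fractions big/thin/thick = 0.98/0.00/0.02
WM+CSF  E[R2] =  15.1 ±  2.9 /s   E[Diso] = 1.88 um2/ms   fractions big/thin/thick = 0.46/0.45/0.03
```

The pure voxels land almost entirely in their own bins (thin for the
elongated white-matter tensor, big for fast-diffusing CSF); the mixture
splits its signal roughly half and half and shows a correspondingly larger
E[R2] uncertainty.  The recovered white-matter E[R2] (18 vs the generating
15 s⁻¹) illustrates the upward bias of noisy non-negative Laplace inversion
discussed in the methods note; CSF relaxes more slowly than the inversion's
sampling box allows, so its E[R2] sits at the box edge (1.3 vs 0.4 s⁻¹)
while its diffusivity is recovered accurately.

The same pipeline is scriptable from the shell:

```sh
rd5d scheme build --preset full45 -o scheme.tsv     # 852-point protocol
rd5d simulate --spec phantom.json --scheme scheme.tsv -o signal.nii.gz
rd5d invert --scheme scheme.tsv --signal signal.nii.gz --seed 1 -o ens.h5
rd5d stats ens.h5 --signal signal.nii.gz -o maps/
```

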
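# ligandswitch

Analysis toolkit for studying how two EGFR ligands of unequal affinity —
EGF and amphiregulin (AREG) — produce different epithelial phenotypes through
the *strength*, not the identity, of receptor signaling. Mammary epithelial
cells cultured in EGF or AREG adopt distinct, reversible phenotypes; the
computational story has three parts, and this package implements all of them:

1. **A mass-action ODE model of EGFR activation and trafficking** in which
   EGF and AREG differ *only* in their equilibrium dissociation constant
   (kd(AREG) = 10 x kd(EGF)). Five receptor pools are tracked — free surface
   receptor `Rs`, unphosphorylated complex `Cs`, phosphorylated surface
   complex `Ps`, internalized phospho receptor `Pi`, and internalized
   non-phospho receptor `Ri`:

   ```
   dRs/dt = vs − kon·L·Rs + koff·Cs − ke0·Rs + kr·Ri
   dCs/dt = kon·L·Rs − koff·Cs − kp·Cs + kdp·Ps
   dPs/dt = kp·Cs − kdp·Ps − ke1·Ps
   dPi/dt = ke1·Ps − kdpi·Pi − kdegP·Pi
   dRi/dt = ke0·Rs + kdpi·Pi − kr·Ri − kdeg·Ri
   ```

   with ligand concentration `L` held constant and `koff = kon·kd`.

2. **Hybrid global/local parameter estimation**: the sum of squared
   residuals between measured phospho-time-courses and model trajectories is
   minimized by self-adaptive (meta-) evolutionary programming followed by
   Nelder-Mead simplex refinement, over many independent seeded restarts,
   keeping the minimum-objective fit.

3. **Quantification statistics**: integrated signal strength (trapezoidal
   area under a normalized phospho-signal over a stated window, per
   replicate, mean ± SD), fold changes between conditions, detection of
   delayed ERK re-activation onset, and the **nucleus-nucleus distance
   index** for micrographs — segment nuclei (Otsu threshold, fill holes,
   3×3 opening), count them (N0), dilate the mask by 5 px, count again (N5),
   and report N5/N0: 1.0 for sparse cells, approaching 0 as cells cluster.

Because the underlying raw data are western blots and micrographs, the
package ships a first-class synthetic-data module that generates both —
nuclei images with controllable clustering and known ground-truth geometry,
and noisy phospho-time-courses with known latent curves — so every pipeline
is testable against analytic or brute-force oracles.

Intended users: systems biologists and image analysts who want a compact,
fully tested reference implementation of receptor-level signal-strength
modeling and of the dilation-based clustering index.

## Worked example

```python
import numpy as np, ligandswitch as ls

params = ls.default_params()          # E-cell convention: surface pool = 1
t = np.arange(0.0, 61.0, 1.0)

def auc(ligand, r_scale=1.0):
    import dataclasses
    p = dataclasses.replace(params, r_scale=r_scale)
    traj = ls.simulate(p, ligand, t)
    return np.trapezoid(ls.readout(traj, "pEGFR_total"), t)

print(auc(ls.egf(1.8)) / auc(ls.areg(1.8)))        # 9.102394783889384
print(auc(ls.areg(1.8), r_scale=10.0) / auc(ls.egf(1.8)))  # 0.970740387524117
```

The first number is the fold-difference in 0–60 min integrated phospho-EGFR
between equimolar 1.8 nM EGF and AREG in cells with baseline receptor
levels: the high-affinity ligand delivers ~10-fold more integrated signal.
The second shows compensation: giving the low-affinity ligand a 10-fold
surface-receptor excess (as in AREG-cultured cells) restores the integrated
signal to within 3% of the EGF response.

The same works from the shell:

```
$ ligandswitch synth-image --out nuclei.png --truth truth.json --seed 11
wrote nuclei.png (20 nuclei)
$ ligandswitch cluster-index --images nuclei.png --out index.csv
wrote index.csv (1 images)
$ tail -1 index.csv
nuclei.png,15,14,0.9333333333333333
```

Here 20 generated nuclei segment into N0 = 15 objects (some touch), 14
remain after 5-px dilation, giving an index of 0.93 — a mostly sparse field.
`synth-timecourse` + `quantify` analogously produce integrated-signal
summaries and a re-activation onset (`"onset_min": 170.0` for the EGF-switch
scenario whose delayed ERK pulse is programmed at 160 min, sampled every
10 min); `fit` runs the multistart estimation on a time-course CSV.

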
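# nucleosim

Kinetic lattice simulation of nucleosome positioning around transcription
start sites (TSSs).

Nucleosome density profiles near promoters look very different across
species and transcription levels: budding-yeast genes show phased arrays
whose peaks decay away from a nucleosome-depleted region, while active
genes in mouse (and other multicellular organisms) show the opposite —
peaks that *grow* with distance from the TSS and a poorly occupied +1
nucleosome. `nucleosim` implements a minimal kinetic model that
reproduces both patterns and lets you dissect which ingredient produces
which feature:

* **hard-rod lattice gas** — nucleosomes are 147-bp rods (coordinate =
  dyad) on a periodic 14.7-kb lattice with binding energy −42 k\_BT per
  footprint; overlap is forbidden (`u(Δx) = ∞` for `Δx < 147`);
* **thermal diffusion** — 1-bp hops at `d = (D/Δl²)·e^{−ΔU/2}`
  (`D = 1 bp²/s`), satisfying detailed balance;
* **promoter barrier** — a triangular dyad potential (height 25 k\_BT,
  centre −150 bp) producing an NDR and *statistical positioning*;
* **spacer enzymes** — ISW1/Chd1-like remodelers that grab a nucleosome
  pair within 332 bp and move one member 1 bp toward the other at an
  energy-independent rate `k` (0.08–0.16 s⁻¹), breaking detailed balance
  and acting as an effective inter-nucleosome attraction;
* **positioning well** — an INO80-like −2 k\_BT well on [0, +30] bp that
  anchors the +1 nucleosome;
* **histone exchange** — whole-nucleosome absorption/desorption with
  `r_on = r·e^{−ΔV/2}`, `r_off = r·e^{+ΔV/2}`, `ΔV = ΔU + μ`, carrying
  Pol II-driven turnover (and, at an artificially fast rate, serving as
  the equilibrium sampler).

Everything is simulated exactly with the Gillespie algorithm (numba-
compiled core), and an analysis layer turns ensembles into TSS-anchored
density profiles, radial distribution functions, +1-ordered heatmaps,
yeast/mouse phase labels, and single-molecule +1-heterogeneity
statistics.

Intended users: chromatin/epigenomics researchers exploring how
remodeling kinetics shape promoter nucleosome architecture, and method
developers who need a transparent, exactly-sampled 1D reference model.

## Worked example

Statistical positioning versus spacer-enzyme condensation:

```python
import numpy as np
import nucleosim as ns
from nucleosim.scenarios import calibrated_equilibrium
from nucleosim.equilibrium import sample_equilibrium

protocol = ns.SimulationProtocol(n_replicas=4, t_end=900.0, burn_in=300.0,
                                 sample_interval=1.0, seed=7)

for k in (0.0, 0.16):
    eff, mu = calibrated_equilibrium(enzyme_rate=k)   # barrier height 25 kBT
    rec = sample_equilibrium(eff, protocol, mu=mu)
    prof = ns.smooth_profile(ns.density_profile(rec), 10.0)
    gap, se = ns.mean_neighbor_gap(rec)
    label = ns.classify_profile(prof)
    print(f"k={k:4}: mean bound count {rec.counts().mean():5.1f}, "
          f"mean gap {gap:6.1f} bp, classified {label}")
```

prints (first run also reports the enzyme-attraction calibration, ~1 min)

```
k= 0.0: mean bound count  86.9, mean gap  167.8 bp, classified yeast_like
k=0.16: mean bound count  85.6, mean gap  158.9 bp, classified mouse_like
```

Without enzymes the barrier phases ~86 rods into a decaying array
(yeast-like, mean neighbour gap ≈168 bp). Turning on spacer enzymes at
`k = 0.16 s⁻¹` condenses the array (gap ≈158 bp) and inverts the peak
trend — the second peak overtakes the first (mouse-like), because the
condensed array slides freely relative to the TSS and the +1 nucleosome
delocalises.

The same machinery is scriptable from a shell:

```bash
nucleosim sample-eq --preset barrier_spacer --seed 1 --out ensemble.tsv
nucleosim profile --ensemble ensemble.tsv --smooth-bw 10 --out profile.tsv
nucleosim classify --profile profile.tsv          # -> mouse_like
```

Other subcommands: `simulate` (explicit diffusion/enzyme/exchange
kinetics), `calibrate-mu`, `affinity score` (periodic-dinucleotide
sequence affinity), `rdf`, `heatmap`, `phase-diagram`, `plus-one`
(single-molecule +1 statistics), `fixtures` (synthetic inputs).

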
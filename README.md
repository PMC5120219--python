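# cadmech

Mechanics of tandem extracellular cadherin (EC) repeats and their
inter-repeat linkers — for structural biologists and biophysicists
studying how filaments like the inner-ear tip link stretch.

Cadherin ectodomains are chains of ~45 Å EC repeats whose junctions are
normally rigidified by three Ca²⁺ ions coordinated by five conserved
motifs (XEX, DYE, DXNDN, DXD, XDX). Some linkers lack these motifs, bind
no calcium, and rest in a bent conformation; force straightens them,
releasing several nanometres of extension without unfolding anything
("tertiary structure elasticity"). In the tip link of hair cells this
unbending is the leading candidate for the filament's only soft elastic
element. `cadmech` provides the complete analysis chain around that
question:

- **`linker_motifs`** — classify a repeat pair's linker from sequence as
  canonical / degenerate / calcium-free by scoring the five motifs at
  their anchors.
- **`geometry`** — principal axes and inter-repeat bend angles, projected
  orientation probability maps along trajectories, Kabsch RMSD, distance
  monitors with running averages, calcium-site geometry (including the
  site-2/site-3 spacing d23), mass-weighted R_g, and Shrake–Rupley buried
  surface area.
- **`force_curves`** — reduce pulling traces (50 ps smoothing, 1 Å
  binning), segment the soft unbending phase I from the stiff phase II by
  exhaustive two-segment least squares (slopes in mN/m ≡ pN/nm), detect
  force peaks and rupture events, convert spring units exactly.
- **`mech_model`** — a three-state (bent / intermediate / extended)
  linker with Bell kinetics in a chain of Hookean repeats:
  series/parallel stiffness composition, closed-form geometric extension,
  quasi-static Boltzmann force–extension, exact Gillespie simulation at
  constant force, and stochastic constant-velocity pulling.
- **`synthetic_data`** — seeded generators (structures, trajectories,
  force traces, sequences) with serialized ground truth, so the entire
  pipeline is testable offline.
- **`io_formats`** — PDB (single- and multi-model), FASTA, and
  tab-separated force traces with metadata.

The package is a library first: `examples/` holds one short narrative
script per capability. A thin `cadmech` CLI (`generate`, `scan-motifs`,
`geometry`, `forcecurve`, `mechmodel`, `report`) orchestrates the same
functions from the shell, driven by a YAML config with a single seed.

## Worked example

```sh
python examples/tip_link_elasticity.py
```

prints (numbers from an actual run):

```
2 x 8.4 mN/m strands in parallel : 16.8 mN/m
30 and 445 mN/m phases in series : 28.1 mN/m
end-to-end gain on unbending     : 3.44 nm

quasi-static mean extension (nm) vs force (pN):
    0.0 pN ->  0.00 nm
    5.0 pN ->  0.05 nm
   10.0 pN ->  0.32 nm
   20.0 pN ->  4.56 nm
   30.0 pN ->  4.66 nm
   50.0 pN ->  4.76 nm

P(full unbending in 1 us at 10 pN) : 0.00
median unbending time at 25 pN     : 690 ns
```

Reading the numbers: two soft 8.4 mN/m strands in parallel give
16.8 mN/m — a dimeric filament whose phase-I stiffness per strand is
8.4 mN/m must therefore be stiffer than 16 mN/m overall. Straightening a
4.5 nm repeat bent 90° off a 9 nm arm gains ~3.4 nm of end-to-end
length, and the quasi-static curve shows exactly that: the mean extension
jumps by ~4.5 nm (the linker's two unbending steps) between 10 and
20 pN. Kinetically, a 10 pN resting tension essentially never fully
unbends the linker within a microsecond, while 25 pN does so in under
one — the force dichotomy that makes the bent state mechanically
meaningful at physiological resting tension.

```python
from cadmech import scan_linker
ann = scan_linker(seq_repeat1, seq_repeat2)   # one-letter sequences
print(ann.linker_class, ann.n_intact, ann.predicted_sites)
```

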
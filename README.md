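# sptquant

Quantitative analysis of chromatin binding for nuclear proteins in live-cell
microscopy, built around two measurements:

1. **Single-particle tracking (SPT).** Individual fluorescently labeled
   molecules are followed across thousands of movie frames. Each track's
   apparent diffusion coefficient is estimated from its lag-1 mean squared
   displacement, `D = MSD / (4·Δt)`, and the track is classified as
   chromatin-**bound** (`D ≤ 0.3 µm²/s`) or **mobile** (`D > 0.3 µm²/s`).
   The *bound fraction* — the proportion of bound tracks per cell — is the
   genome-wide binding readout, compared across treatment conditions with a
   one-way ANOVA.
2. **Laser-stripe recruitment.** After microirradiation draws a stripe of
   DNA damage through a nucleus, protein accumulation is scored per
   timepoint as the relative stripe brightness
   `Sx = (Ax − B) / (Cx − B)` (stripe mean `Ax`, nucleus-remainder mean
   `Cx`, background mean `B`), shifted so the pre-irradiation timepoint
   equals 1, and averaged across cells as mean ± SEM.

Because raw recordings of this kind are rarely shareable, the package ships
a ground-truthed simulator of both experiment types: a two-population
(bound/mobile) Brownian ensemble blinking inside a nuclear mask, imaged as
pixel-integrated Gaussian spots with Poisson noise; and stripe stacks with a
single-exponential recruitment rise. Every analysis stage can therefore be
validated by parameter recovery, with no external data.

The analysis chain is: difference-of-Gaussians band-pass detection with a
mean + 5·SD threshold → phasor (first-harmonic DFT phase) sub-pixel
localization → radius-gated (8 px) optimal-assignment linking with 1-frame
memory → discard of tracks with fewer than 4 steps → per-track `D`,
bound/mobile split, per-cell bound fractions and ANOVA.

## Worked example

A full synthetic experiment — two conditions ("untreated" with 20% of
molecules bound, "damage" with 50%), three cells each, 600-frame movies of
150 blinking molecules per cell — runs from one config file:

```yaml
# demo.yaml
seed: 42
simulate:
  n_frames: 600
  image_size: 128
  n_molecules: 150
  k_off_frame: 0.12
  k_on_frame: 0.05
conditions:
  - {label: untreated, f_bound: 0.2, n_cells: 3}
  - {label: damage, f_bound: 0.5, n_cells: 3}
```

```sh
sptquant run --config demo.yaml --outdir demo_out
# done: 6 cells, ANOVA p=0.000517
```

`demo_out/comparison.json` then holds (abridged):

```json
{
  "anova": {"f_stat": 104.44, "df_between": 1, "df_within": 4,
            "p_value": 0.000517,
            "group_means": {"untreated": 0.166, "damage": 0.336}},
  "per_cell_bound_fractions": {
    "untreated": [0.187, 0.154, 0.158],
    "damage":    [0.322, 0.362, 0.324]}
}
```

Every cell in the damage condition shows a higher recovered bound fraction
than every untreated cell, and the ANOVA flags the contrast at p ≈ 5×10⁻⁴.
The recovered fractions sit below the simulated molecular fractions because
track-level classification at this spot density is imperfect (see
`docs/methods.md`); the *contrast* between conditions is the validated
readout. Per-cell localization tables, track tables, diffusion summaries
and a reproducibility manifest are written alongside.

The stages are also available individually (`sptquant simulate spt`,
`localize`, `track`, `diffuse`, `stripe`, `compare`) and as plain library
functions (`sptquant.localize_movie`, `sptquant.build_tracks`,
`sptquant.analyze_tracks`, `sptquant.quantify_cell`, ...).

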
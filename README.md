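# bilayerlab

Trajectory analysis for planar lipid bilayer simulations: signed C–H bond
order parameters with per-lipid statistics, forking detection and headgroup
charge (ΔS) responses, number/electron density profiles along the membrane
normal, SAXS form factors, area-per-lipid series with equilibration
detection, and lateral diffusion coefficients from center-of-mass mean
squared displacements. It is aimed at people validating membrane force
fields or characterizing bilayer structure from MD output (GRO/PDB
topologies, XTC/TRR/DCD trajectories), and it ships synthetic-ensemble
generators with closed-form ground truth so every stage can be verified
without real trajectories.

## The statistics it computes

For a C–H bond with tilt θ against the membrane normal (+z),

    S_CH = ⟨ (3 cos²θ − 1) / 2 ⟩  ∈ [−0.5, 1],

time-averaged per lipid first, then mean ± SEM across lipids. Unequal S_CH
of the two prochiral hydrogens on one carbon ("forking") is reported with a
k·SEM significance flag, and the electrometer response of a headgroup
segment is ΔS = S(c) − (S_R⁰ + S_S⁰)/2 against the R/S-averaged salt-free
baseline.

The X-ray form factor is the 1-D transform of the electron-density contrast,
|F(q_z)| = |∫ (ρₑ(z) − ρ_bulk) e^{iq_z z} dz|, normalized by the first-peak
height in 0.1–0.2 Å⁻¹. Area per lipid is A_L = Lx·Ly / n_leaflet. Lateral
diffusion uses the Einstein relation D_L = ¼ d⟨|Δr_xy|²⟩/dt on the linear
MSD regime, with error bounds from the steepest/gentlest lines threading
±1 SEM error bars built from five lipid subgroups. `docs/methods.md` has
the full account.

## Worked example

Generate a synthetic ensemble whose bonds wobble uniformly in a 60° cone
(exact S_CH = cos 60° (1 + cos 60°)/2 = 0.375) and analyze it:

```python
import bilayerlab as bl

model = bl.OrientationModel(kind="cone", theta0=60.0, seed=1)
topology, frames, truth = bl.gen_orientation_ensemble(model, n_lipids=50, n_frames=500)
rec = bl.compute_order_parameters(frames, topology)[0]
print(truth[("α", "R")])                      # 0.3750000000000001
print(rec.s_mean, rec.sem, rec.n_lipids)      # 0.3734433871264773 0.0020888100143835 50
```

The recovered mean sits within one SEM of the exact value. The same works
from the shell, through files:

```
bilayerlab synth --kind cone --theta0 60 --seed 7 --n-lipids 50 --n-frames 200 \
    --output-dir run/
bilayerlab apl --topology run/fixture.txt --n-leaflet 25 --output-dir run/apl/
head -3 run/apl/apl.tsv
```

which prints

```
# bilayerlab 0.1.0 config_hash=63045f09c9a9653a
time_ps	a_l_nm2
0.0	2.8224
```

(2.8224 nm² = 8.4 nm × 8.4 nm of lateral box over 25 lipids per leaflet —
the synthetic grid is loosely packed; real POPC sits near 0.64–0.69 nm².)

Every command writes TSV outputs stamped with the config hash plus a
`run_manifest.json` from which the run can be replayed byte-identically.
Other subcommands: `orderparams`, `thetadist`, `deltas`, `density`,
`formfactor`, `msd`; all accept `--config run.yaml` with flags overriding
file values.

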
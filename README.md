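# ircmech

Post-processing toolkit for intrinsic-reaction-coordinate (IRC) data from
reaction-mechanism studies, built around a racemization-style proton-transfer
use case (chiral carbon C1, acid hydrogen H5, nucleophile oxygen O6).

It provides:

- **io_formats** — readers/writers for delimited IRC tables (ξ, E, μ,
  per-atom NBO charges, per-bond Wiberg indices, dipole), multi-frame XYZ
  trajectories keyed to ξ, stationary-point thermochemistry configs
  (YAML/JSON) and result reports. Internal units are kcal/mol, e, Debye, Å,
  degrees, K; Hartree input is converted with 627.5095.
- **energetics** — reaction force F(ξ) = −dE/dξ, force critical points,
  four-region work decomposition W1–W4 (each work equals the energy change
  across its region; W1+W2 is the activation energy), and electronic flux
  J(ξ) = −dμ/dξ. Optional Savitzky–Golay smoothing for noisy profiles.
- **structure** — distance / angle / unsigned-dihedral descriptor series
  along a trajectory, plus normalized breaking-vs-forming bond-length
  evolution curves with their deviation from the diagonal.
- **electronics** — NBO-charge / dipole / Wiberg evolution, per-bond
  percentage evolution %Ev = 100·(B_TS−B_R)/(B_I−B_R), synchronicity
  Sy = 1 − [Σ|%Ev_i−mean|/mean]/(2n−2), and WBI-based evolution curves.
- **lfer** — activation thermochemistry (ΔH‡, ΔG‡, ΔS‡, Ea = ΔH‡+RT at a
  stated T, default 383.45 K), Hammett σ–ρ regressions in free-energy and
  enthalpy form, entropy-difference recovery Δ(ΔS) = 2.303·R·intercept, and
  generic per-substituent / charge–Ea correlations. A standard editable σ
  table ships at `src/ircmech/data/sigma_constants.csv`.
- **synthetic** — a closed-form generator (logistic/Gaussian channels with
  exact derivatives) producing IRC profiles, six-atom toy trajectories,
  stationary points and Hammett series with known ground truth, including
  `aromatic_like` and `aliphatic_like` presets that encode the qualitative
  aromatic/aliphatic contrasts (TS–intermediate energy gap, early/late
  dihedral change, dipole direction, evolution percentages).
- **pipeline / CLI** — end-to-end orchestration with deterministic,
  provenance-stamped JSON reports and cross-species comparison.

## CLI

```bash
ircmech synth --preset aromatic_like --seed 7 --out dataset/
ircmech analyze --config config.yaml --out report.json
ircmech hammett --series series.csv --response enthalpy
ircmech sync --points dataset/stationary_points.yaml --bonds C1-H5,H5-O6
ircmech compare report_a.json report_b.json
```

`analyze` configs are YAML mirrors of `ircmech.pipeline.AnalysisConfig`,
e.g.:

```yaml
preset: aromatic_like   # or irc_table: path/to/irc.csv
seed: 7
temperature: 383.45
breaking_bond: C1-H5
forming_bond: H5-O6
dihedral_atoms: [N3, C2, C1, C4]
```

Exit codes: 0 success, 2 validation/format error, 3 numerical failure.

## File formats

- IRC table: delimited text (comma/tab auto-detected) with columns `xi`,
  `E`, optional `mu`, `dipole`, `q_<atom>`, `wbi_<A>-<B>`.
- Trajectory: standard multi-frame XYZ with `xi=<float>` in the comment
  line (or a sidecar ξ list).
- Stationary points: YAML mapping species → `{T, points: [{role, E, H, G,
  S, charges, wbi}]}`; `G = H − T·S` is checked and mismatches are logged.

Bond labels are order-normalized everywhere (`H5-O6` ≡ `O6-H5`).
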
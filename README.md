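# peptidock

Peptide ligand construction and docking-campaign management for
structural-bioinformatics workflows.

High-throughput docking of peptide ligands against a protein receptor is
dominated by setup chores: building a 3D coordinate file for every candidate
sequence, completing the grid parameter file the grid engine needs, launching
one job per (ligand, receptor, grid box) combination, and digging the
binding-energy numbers out of the docking logs afterwards. `peptidock`
automates that pipeline for people screening peptide libraries (the
motivating ligand class being small disulfide-rich venom peptides such as
conotoxins): it turns one-letter residue strings into ligand PDB files,
prepares grid parameter (GPF) files, runs batch and competitive-binding
campaigns over a pluggable docking backend, and ranks, clusters, and screens
the resulting docking logs.

## What it computes

**Ligand assembly.** A sequence `s = a₁…aₙ` is built by fragment
concatenation from a library of 44 idealized templates: a beginning cap (the
hydrogen starting the chain), an end cap (the H and O completing the
C-terminal carboxyl), a backbone fragment in two orientations, and each of
the 20 residues' side chains in two orientations. Residue *i* uses the "up"
orientation when *i* is odd and "down" when even, so consecutive side chains
leave on opposite sides of the backbone plane; proline places no standalone
backbone fragment because its ring fragment embeds the backbone atoms. After
assembly a deterministic optimizer does a greedy search over side-chain
torsions (30° grid, 5° refinement) minimizing the steric clash score

    U = Σ_{(i,j): graph distance ≥ 3} max(0, d₀ − d_ij)²,   d₀ = 2.0 Å.

**Docking scores.** Each docking run reports an estimated binding free
energy ΔG (kcal/mol) and inhibition constant K_i, related by
K_i = exp(ΔG/RT) with R = 1.987 cal·mol⁻¹·K⁻¹, T = 298.15 K. Rank 1 is the
lowest ΔG. The mock backend shipped for offline work emits docking logs that
satisfy this identity exactly; a real engine is plugged in through the
backend protocol (`run(ligand, receptor, gpf, n_runs, out_dir)`).

**Campaigns.** `create_job_matrix` forms the full cross-product — 10 ligands
× 1 receptor × 3 grid boxes = 30 jobs — each defaulting to 100 stochastic
docking runs, with lifecycle created → queued → running → complete/failed
and a 10-second default status-poll interval. A competitive-binding
experiment docks ligand A, merges its rank-1 pose into the receptor as a new
chain, and automatically docks the secondary ligand B against the complex.

**Analysis.** Docking logs are parsed into per-run conformations; poses are
ranked by energy (ties to the lower run index), clustered greedily in energy
order by coordinate RMSD, and screened against a secondary grid box: the
fraction of runs whose pose centroid falls inside the box, with best/mean
ΔG and K_i over the inside runs.

## Worked example

```sh
printf 'CCMWF\nCDCMW\nCFWMW\nCHMWW\nCHWWM\n' > ligands.txt
printf 'npts 40 40 40\nspacing 0.375\ngridcenter 0.0 0.0 0.0\n' > box.gpf
peptidock build --seq GAGAG --out-dir . && mv GAGAG.pdb receptor.pdb

peptidock campaign --ligands ligands.txt --receptor receptor.pdb \
    --gpf box.gpf --runs 100 --seed 1 --out-dir out
```

prints one status line per job:

```
job 1: CCMWF -> complete
job 2: CDCMW -> complete
job 3: CFWMW -> complete
job 4: CHMWW -> complete
job 5: CHWWM -> complete
```

Each of the five sequences was first built into `out/<SEQ>.pdb` (44-fragment
assembly plus torsion relaxation), its grid template completed with the
ligand's docking atom types, then docked for 100 runs by the mock backend.
The ranked results land in `out/job_<id>_results/summary.txt`:

```
rank	run	energy_kcal_mol	ki_molar	cluster_rank
1	7	-11.0667	7.712349e-09	1
2	87	-10.4213	2.292760e-08	2
3	25	-10.3763	2.473723e-08	3
```

Rank 1 is the pose with the lowest estimated binding energy (−11.07
kcal/mol here); its K_i of 7.7 nM is exp(ΔG/RT). Screening those runs
against a secondary box:

```sh
peptidock summarize --dlg out/CCMWF_receptor.dlg --out-dir sum --screen-gpf box.gpf
```

```
runs_total	100
runs_inside	100
percent_inside	100.0
best_energy_kcal_mol	-11.0667
mean_energy_kcal_mol	-7.2134
```

— all 100 pose centroids lie inside this (identical) box, so the inside-run
statistics cover every run; with a smaller box around a putative site the
percentage drops and the statistics restrict to the poses that bind there.

The library surface mirrors the CLI: `build_peptide`, `prepare_gpf`,
`create_job_matrix`, `Campaign.run_all` / `run_competitive`, `parse_dlg`,
`rank_conformations`, `cluster_conformations`, `screen_secondary_box`.

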
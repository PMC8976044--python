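# ringrec

Toy-scale implementation of block-based (subparticle) cryo-EM reconstruction
for C-symmetric ring assemblies, plus the composite-model analyses that
follow: layered-mask focused refinement, symmetry expansion with subparticle
re-centering (shift, window and defocus bookkeeping), confined local pose
refinement, Wiener-filtered direct Fourier reconstruction with gold-standard
FSC resolution estimation, ring assembly from a single fitted subunit, and
structural measurements (Kabsch superposition/RMSD, interface contacts by
secondary-structure element, flexible-linker reachability, model census).

Everything runs at desk scale on synthetic data generated in-repo: a C8 ring
of Gaussian blobs, simulated tilted-collection particle stacks with CTF and
noise, and toy atomic models with planted interfaces. Real deposited
coordinates can be analyzed with the same tools when files are supplied
(opt-in; nothing is fetched implicitly).

## CLI

`ringrec --help` lists all subcommands. The end-to-end toy study:

```bash
ringrec run-all --config config.yaml       # or omit --config for defaults
```

runs simulate → whole-ring reconstruction → layered-mask focused refinement
→ subparticle expand/recenter/extract/refine → FSC reports → subunit-to-ring
fitting → composite model assembly → structural analyses, writing per-stage
artifacts and a deterministic `report.json` into the output directory.

Individual stages: `simulate`, `reconstruct`, `focus-refine`, `expand`,
`recenter`, `extract`, `refine`, `fit-ring`, `assemble`, `measure`,
`superpose`, `contacts`, `reach`, `census`.

`ringrec fetch-and-check 7WB4 --dest data/accessions` (network required)
downloads deposited coordinates for the opt-in integration checks; the
offline pipeline and test suite never touch the network.

## Conventions

* Euler angles `(rot, tilt, psi)`: intrinsic ZYZ, degrees; the matrix maps
  reference-frame coordinates to the particle projection frame; projection
  is along +z of the particle frame.
* Shifts are in Angstrom and translate the projected reference within the
  image; re-centering moves the integer-pixel part of the subunit
  displacement into the extraction offset and keeps the fractional remainder
  in the shift fields.
* Defocus is positive for underfocus; a subunit whose center maps to `q` in
  the particle frame acquires `defocus + q_z`.
* Volumes are cubic, `[z, y, x]`-indexed, physical origin at voxel `N // 2`.
* FSC resolution is reported at the 0.143 crossing of half-set
  reconstructions and never finer than twice the pixel size.
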
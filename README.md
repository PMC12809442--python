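# saqc — structural-alphabet quality checks for crystallographic models

X-ray structure models carry artifacts: strained geometry from model building
and refinement, conformations imposed by crystal packing, regions fitted into
ambiguous electron density. `saqc` locates **residues with questionable
backbone conformations** by comparing two models of the same protein — for
example a deposited X-ray model against its energy-minimized or re-refined
counterpart — through a 27-letter structural alphabet, and characterizes the
flagged residues with fragment-RMSD filtering, B-factor and solvent-
accessibility annotation, inter-chain asymmetry analysis, effect-size
statistics, and ensemble-based plausibility checks. It is aimed at structural
biologists and method developers who want a local, scriptable assessment of
backbone plausibility before using a model for downstream analysis.

## Method

Each chain is reduced to overlapping fragments of four Cα atoms. A fragment
is summarized by four descriptors — the distances d₁ = |Cα(i)Cα(i+2)|,
d₂ = |Cα(i)Cα(i+3)|, d₃ = |Cα(i+1)Cα(i+3)| and the signed height *h* of
Cα(i+3) over the plane of the first three (chirality-bearing) — and assigned
one of 27 structural letters by maximum Gaussian emission density (or by
Viterbi decoding when the parameter set carries a transition matrix). The
letter of fragment (i … i+3) is stored on residue i+2, so a gap-free chain of
k residues yields k−3 letters.

Given two models of the same protein:

* residues with the **same letter** in both models are consistent (R_CC);
* residues with **different letters** are candidate changes; because some
  letters are geometric near-neighbours, the Cα RMSD of the two fragments is
  computed after proper-rotation Kabsch superposition, and the change is
  retained only when **RMSD_frag ≥ 0.1 Å** (inclusive). Retained residues are
  classified **R_DC** — questionable/deviating conformations; sub-threshold
  changes are reclassified R_CC.

The per-model fraction of R_DC residues is **P_DC**; maximal runs of
consecutive R_DC residues form **patterns** (length-1 runs are *isolated*
residues). Additional analyses: position-wise letter comparison of
same-sequence chains (structural asymmetry), normalized-B-factor flexibility
(z-score > 0 ⇒ flexible), Shrake–Rupley relative solvent accessibility
(rASA > 20% ⇒ accessible), occupancy categories, and, against a conformational
ensemble, per-position letter support (<20% of frames ⇒ rare) and the central
99% interval of every Cα–Cα distance (**IC_MD**) with outlier calls for a
reference model. Statistical comparisons ship with their effect sizes:
Cohen's d, rank η² (with Dunn post-hoc), Cramér's V, Pearson r.

## Worked example

```bash
# build a synthetic 40-residue chain and a perturbed copy (three backbone
# dihedrals rotated by 25-40 degrees), then compare them
saqc synth --n-residues 40 --seed 33 --out ref.pdb
python - <<'PY'
from saqc import synthetic, read_structure, write_structure
model = read_structure("ref.pdb")
pert = synthetic.perturb(model, synthetic.PerturbSpec(
    [(18, "psi", 40.0), (8, "phi", -30.0), (28, "psi", 25.0)]))
write_structure(pert, "alt.pdb")
PY
saqc compare ref.pdb alt.pdb --out demo
```

prints

```
P_DC = 0.1500 (6 R_DC residues)
```

meaning 6 of the 40 residues (15%) changed structural letter with a
fragment RMSD of at least 0.1 Å — the questionable-conformation calls. Their
identities, letter pairs and RMSD values are in `demo.residues.tsv`; pattern
statistics and the letter-pair contingency table are in `demo.summary.json`.
All R_DC calls sit within two residues of a rotated dihedral: windows that do
not span a rotated bond superpose to RMSD 0 and can never be flagged.

Other subcommands: `saqc asymmetry` (same-sequence chain comparison),
`saqc annotate` (B-factor/occupancy/rASA table), `saqc ensemble` (letter
support and IC_MD outliers against a multi-model PDB), `saqc stats`
(association tests with effect sizes), `saqc synth` / `saqc synth-ensemble`
(fixture generation) and `saqc fit-alphabet` (calibrate a parameter set from
your own structure corpus). The bundled default alphabet is a plain-text file
(`src/saqc/data/default_alphabet.txt`, rebuildable with
`scripts/build_default_alphabet.py`); pass `--params` to substitute your own.

To run the ensemble analysis on a real case — e.g. the ligand-free HIV-2
protease model (PDB entry 1hsi) against exported MD frames — download the
PDB file and a multi-model PDB of the trajectory and run
`saqc ensemble 1hsi.pdb frames.pdb --out pr2`; `pr2.regions.json` lists the
residue regions involved in out-of-interval distances.

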
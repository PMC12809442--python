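# Methods

## The detection protocol

`saqc` asks whether the local backbone conformation of each residue in a
reference structure model is *stable under an independent re-modelling* of
the same protein — an energy-minimized copy, a re-refined copy, or any other
paired conformer. The comparison is done in a discretized conformational
space: every overlapping fragment of four consecutive Cα atoms is mapped to
four geometric descriptors,

* d₁ = |Cα(i) − Cα(i+2)| (Å)
* d₂ = |Cα(i) − Cα(i+3)| (Å)
* d₃ = |Cα(i+1) − Cα(i+3)| (Å)
* h = signed distance of Cα(i+3) from the plane of the first three Cα atoms
  (Å; positive for right-handed geometry, zero when the base triangle is
  degenerate),

and then assigned one of 27 structural letters. The assignment maximizes the
letter's Gaussian emission log-density in descriptor space; when a parameter
set carries a letter-transition matrix, the whole chain is decoded jointly by
the Viterbi algorithm instead. The letter of fragment (i … i+3) is reported
on residue i+2, so a gap-free chain of k residues yields exactly k−3 letters;
windows that would span a chain break (consecutive Cα distance > 4.5 Å, a
numbering gap, or a residue without Cα coordinates) are left unassigned.

A residue whose letters differ between the two models is only a *candidate*
change: several letters are geometric near-neighbours and a letter switch
can reflect a sub-noise adjustment. The candidate is therefore filtered by
the Cα RMSD of the two four-residue fragments after least-squares
superposition (Kabsch with proper rotations only, via
`scipy.spatial.transform.Rotation.align_vectors`; reflections are physically
inadmissible). Candidates with RMSD_frag ≥ 0.1 Å (inclusive — ties count as
changes) are classified R_DC ("deviating/questionable conformation"); all
other compared residues are R_CC. P_DC is the number of R_DC residues
divided by the total residue count of the reference model, including
positions whose letters are unassigned; residues present in only one model
are dropped from the comparison (and counted), and a pair sharing fewer than
half of the reference residues is rejected as inconsistent. Maximal runs of
consecutive R_DC residues — broken by unassigned positions and chain
boundaries — form the pattern set; runs of length 1 are isolated residues.

## The bundled alphabet and its calibration

The 27-letter alphabet follows the published structural-alphabet
construction (a hidden Markov model over 4-Cα fragment geometry and letter
succession; Camproux et al., 2004). This package is a reimplementation, not
a bit-compatible port: the original parameters are not redistributed, so the
parameter set is a versioned plain-text file and `fit_alphabet` rebuilds one
from any structure corpus.

Calibration is *stratified to the canonical class composition* — 4 helix
letters (A, a, V, W), 5 strand letters (L, M, N, T, X), 18 others. Fragment
descriptors are partitioned into helix/strand/other strata (by the corpus
generator's known segment plans, or by proximity to ideal helix/strand
archetype descriptors within 1.2 Å) and each stratum is clustered separately
with seeded k-means into its fixed number of letters; each cluster yields a
Gaussian emission (empirical covariance plus a 2.5×10⁻³ Å² isotropic floor).
A single unstratified k-means was found to concentrate letters wherever the
corpus has the most spread, which removes the fine granularity inside the
regular basins that the 0.1 Å RMSD filter presupposes — in the published
alphabet, neighbouring helix letters differ by backbone RMSDs on the order
of 0.15 Å, and the protocol's sensitivity depends on that resolution.

The default set (`saqc/data/default_alphabet.txt`, version
`saqc-default-1.0`) is fitted once, deterministically, on a synthetic corpus
of 150 sixty-residue chains with randomized helix/strand/coil segment plans,
each paired with a 7°-jittered variant so the regular basins carry realistic
spread (`scripts/build_default_alphabet.py` reproduces the file byte for
byte). The default set deliberately carries **no transition matrix**:
transition frequencies estimated from a small homogeneous-segment synthetic
corpus are nearly diagonal, and Viterbi decoding under such sticky
transitions suppresses genuine letter changes — exactly the signal this tool
exists to detect. Default decoding is therefore emission-only; a parameter
set fitted on a real, large corpus can include transitions
(`fit_alphabet(..., with_transitions=True)`), and decoding then defaults to
Viterbi.

## Residue properties

* **Flexibility** — the mean isotropic B over all non-hydrogen atoms of a
  residue is z-scored against all residues of the model (population
  standard deviation, so the scores have mean 0 and sd 1 exactly);
  flexible ⇔ z > 0 (a tie at exactly 0 is rigid). The z-score is invariant
  to affine rescaling of the raw B-factors.
* **Occupancy class** — per-residue occupancy is the minimum over the
  residue's atoms (the most conservative aggregation for detecting
  alternative conformations): 0 ⇒ `zero`, (0, 1) ⇒ `alternative`,
  1 ⇒ `single`.
* **Accessibility** — solvent-accessible surface area by the Shrake–Rupley
  sphere-sampling method: each atom's solvent-extended sphere (probe radius
  1.4 Å) is sampled at 960 golden-spiral lattice points by default; rASA is
  the residue sum as a percentage of a per-amino-acid reference area
  (theoretical maxima of Tien et al., 2013); accessible ⇔ rASA > 20%
  (strictly). The radii and reference tables are editable text configs, so
  NACCESS-compatible values can be substituted; small numeric differences
  from other SASA programs are expected. Hydrogens are excluded from both
  the B-factor average and the SASA computation.

## Asymmetry and ensemble analyses

Two chains of one model with identical amino-acid sequences are compared
position-wise on their letters (matched by residue number + insertion code,
no alignment; any amino-acid mismatch rejects the pair): same letter ⇒
symmetric, different ⇒ structurally asymmetric. No RMSD filter is applied by
default — within a crystallographic model's error margin a letter change is
not necessarily significant, so the counts are an estimate; an optional
threshold applies the same fragment-RMSD filter as the paired-model
comparison. All n(n−1)/2 same-sequence chain pairs of an oligomer are
enumerated.

Against an ensemble of conformations (e.g. MD frames exported as multi-model
PDB), two checks are made. (1) *Letter support*: the fraction of frames
sharing the reference model's letter at each position, over frames with an
assigned letter there; support < 20% labels the reference conformation
`rare`, > 80% `strong`. (2) *Distance intervals*: for every unordered Cα
pair — inter-chain pairs included, n(n−1)/2 in total — the central interval
containing 99% of the ensemble's distances (IC_MD). The interval is the
empirical [0.5%, 99.5%] quantile range with linear interpolation at the
Weibull plotting position (n+1)p; this estimator is chosen because its
exceedance probability for a held-out draw matches the nominal tail mass
(the common (n−1)p+1 position under-covers: at n ≈ 300 a held-out frame
falls outside the nominal 99% interval ~1.7% of the time instead of 1%). A reference distance outside its interval is
an outlier; maximal consecutive-residue runs involved in at least one
outlier pair delineate the flagged regions. Raising the level widens every
interval; level 1.0 gives [min, max].

## Statistics

Every test reports its effect size, because on residue-scale sample sizes
p-values alone are uninformative. Student's t (pooled variance by default,
Welch optional) with Cohen's d = (m₁−m₂)/s_pooled, binned |d| < 0.2 very
small, [0.2, 0.5) small, [0.5, 0.8) medium, ≥ 0.8 large; Kruskal–Wallis H
(tie-corrected) with rank η² = (H−k+1)/(n−k) clamped at 0, binned around the
anchors 0.01/0.06/0.14; Pearson χ² with Cramér's V = √(χ²/(n·(min(r,c)−1)));
Pearson r. Dunn's post-hoc pairwise z-tests follow a significant
Kruskal–Wallis (tie-corrected pooled rank variance; unadjusted p-values by
default, Holm on request). The default significance level is α = 0.05.

## The synthetic-fixture generator

The generator is the package's test surface: it builds backbones from ideal
internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, standard
angles, trans peptide bonds) for a per-residue (φ, ψ) plan — helix
(−57°, −47°), strand (−135°, 135°), coil sampled uniformly from the broad
allowed region [−180°, −30°] × [−60°, 180°] — with seeded reproducibility.
Default B-factors follow a U-shaped profile along the chain (elevated
termini) with seeded noise, emulating the crystallographic pattern;
occupancies default to 1. `perturb` rotates named dihedrals by exact deltas
while leaving upstream atoms bit-identical, giving every comparison test
exact ground truth; `build_ensemble` jitters all dihedrals with Gaussian
noise (degrees) and refits each rebuilt chain onto the original, so
multi-chain models keep their approximate relative geometry.

What the generator does *not* emulate bounds what green tests show about
real data: no side chains (SASA tests use purpose-built atom shells), no
physics or clash resolution, uniform rather than basin-clustered coil
dihedrals, no experimental noise model, no correlated inter-chain motion.
Passing tests demonstrate the protocol's correctness and calibration on
geometrically exact conformers, not its error rates on real
crystallographic data.

## Problem sizes and numerical choices

Stochastic end-to-end checks use problem sizes chosen to give tight Monte
Carlo error at desk scale: 200 seeded perturbation fixtures of 56-residue
mixed-topology chains for the recovery rate (a single φ or ψ rotation of
20–60° must yield an R_DC call within ±2 residues of the target; fragment
superposition guarantees containment, since windows that do not span the
rotated bond have RMSD 0); 200 replicates × 300 training frames of
20-residue chains for interval calibration; 1000 random fragment pairs for
the Kabsch-vs-quaternion-search equivalence (tolerance 2×10⁻³ Å); 100 random
build plans for the k−3 length law. Tie-breaks and degenerate inputs:
collinear base triangles set h = 0; identical-point fragments are rejected;
a model with zero B-factor spread cannot be normalized; empty contingency
rows/columns must be collapsed by the caller.

## Known limitations

* A 27-letter discretization cannot resolve every backbone change: two
  conformations inside one letter's basin — most likely in irregular loop
  space — produce no letter change and are invisible to the protocol
  regardless of their RMSD. The measured recovery rate of ~95–97% on mixed
  fixtures reflects exactly these loop-interior cases.
* The bundled alphabet is calibrated on synthetic backbones; for production
  use on real structures, refit on a real corpus with `saqc fit-alphabet`.
* Only backbone conformations are assessed; side-chain plausibility is out
  of scope.
* The asymmetry counts apply no deviation filter by default and should be
  read as estimates.
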
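# Methods

## Scope and model

The package scores candidate androgen-receptor antagonists with four linear
QSAR equations of the form pIC50 = b0 + Σk bk·dk, where the dk are 19 named
molecular descriptors and pIC50 = −log10(IC50/M) from AR reporter-gene
assays.  The coefficients of the four shipped equations (Y1–Y4,
`src/arscreen/data/models/*.json`) are fixed published values; the package
additionally rebuilds such models from data (GA-MLR) and validates them.
Everything downstream — the screening cascade and the trajectory
post-analysis — consumes these pieces.

## Descriptors

Conventions adopted throughout (configurable only where noted):

* **Graph conventions.** 2D descriptors (GATS, BEH, IVDE, C-009, F05, MLOGP
  terms) use the hydrogen-depleted graph.  Information-content indices type
  atoms on the hydrogen-explicit graph.  All 3D descriptors (WHIM, GETAWAY,
  DISPp) include hydrogens.  Aromatic bonds carry conventional order 1.5
  wherever a bond order enters a formula.
* **Atomic weights** (mass m, van der Waals volume v, Sanderson
  electronegativity e, polarizability p) come from the classical descriptor
  handbook tabulations (`properties.py`) and always enter formulas scaled
  relative to carbon, so carbon weighs exactly 1 under every scheme.
* **Geary autocorrelation.** GATS_k = [Σ_{d_ij=k}(w_i−w_j)²/(2Δ_k)] /
  [Σ_i(w_i−w̄)²/(A−1)] over *ordered* pairs at topological distance k.
  Zero weight variance (all-carbon molecules under any scheme) and absent
  lags are reported as missing with a reason code, never as NaN or 0.
* **Burden eigenvalues.** Diagonal = carbon-scaled property; bonded pairs
  0.1 × bond order, +0.01 when the bond touches a terminal atom; 0.001
  elsewhere.  BEHp7 is the 7th-largest eigenvalue, so molecules with fewer
  than 7 heavy atoms report missing.
* **Information content.** Initial atom classes key on (element, degree,
  attached-H count); k refinement rounds extend the key by the sorted
  multiset of (neighbor class, bond order).  IC_k is the Shannon entropy
  (bits) of the class sizes; refinement only splits classes, so IC_k is
  non-decreasing in k.  Whether the original software used bond orders in
  the refinement is undocumented; the with-bond-orders variant is the
  default here.
* **Molecular influence matrix.** H is computed as U·Uᵀ over the non-null
  singular directions of the centered coordinate matrix — numerically an
  exact projection (Σ leverages = rank ≤ 3 to machine precision) that
  degrades gracefully for planar/linear geometries.  GETAWAY sums run over
  unordered pairs (i < j) at each all-atom topological lag; H_k keeps only
  positive off-diagonal influence terms; R_k+ is the maximum of the R terms
  at the lag.
* **WHIM E.** The directional accessibility index is the inverse-kurtosis
  form E_m = λ_m²·A / Σ_i s_im⁴ on the principal axes of the (unweighted)
  coordinate covariance; a null eigenvalue (planar molecule, component 3)
  reports missing "degenerate-axis".
* **MLOGP.** The 13-term Moriguchi regression (CX, NO, PRX, UB, HB, POL,
  AMP, ALK, RNG, QN, NO2, NCS, BLM with exponents 0.6/0.9/0.8 on CX/NO/UB)
  is implemented with term definitions encoded as SMARTS where the original
  prose definitions are qualitative (internal hydrogen bond, amphotericity,
  aromatic polar substituents).  These simplified term definitions — and the
  GVW antidepressant-80 property ranges — are versioned constant tables;
  bit-exact parity with any specific commercial implementation is not
  claimed.  BLTF96 = −0.85·MLOGP + 1.61 (log LC50 in mmol/l for 96-h fish
  baseline toxicity); both constants are arguments.
* **Conformers.** 3D descriptors need one conformer per molecule, produced
  by ETKDG distance-geometry embedding with a fixed seed followed by MMFF
  minimization.  This replaces conformational searching: identical inputs
  give bitwise-identical coordinates, and none of the descriptors used here
  is strongly conformation-sensitive at this scale.  Embedding failures
  mark all 3D descriptors missing and exclude the molecule downstream with
  a logged diagnostic.

## Model building and validation

* **Pretreatment** removes descriptor columns with variance < 1, then one
  member (the later, in column order) of every pair with |Pearson R| > 0.99.
  The variance threshold is calibrated to raw DRAGON-style descriptor
  scales; on standardized matrices it should be lowered.
* **OLS** uses the numpy least-squares solver with an explicit rank check;
  rank deficiency is an error naming the collinear columns.
* **Q²LOO** is computed two ways: the PRESS identity e_i/(1−h_ii) (exact
  for OLS, used inside the GA for speed) and explicit leave-one-out
  refitting (used in validation reports); a test asserts their agreement.
* **GA selection** evolves binary column-selection chromosomes (population
  100, 200 generations, crossover 0.8, mutation 0.05, tournament size 2,
  elitism, hard cap of 5 descriptors and cap ≤ n/5).  Fitness is
  Q²LOO − 0.01·(number of selected descriptors).  The parsimony term is
  essential: without it, spurious correlations let pure-noise columns buy
  marginal (< 0.01) Q²LOO gains, and the GA reliably pads every model to
  the size cap.  The 0.01/descriptor penalty is far below the contribution
  of any genuine descriptor yet above the spurious gains at n ≈ 60, and is
  exposed in `GAConfig`.
* **External validation** reports Q²F1 (training-mean reference), Q²F2
  (external-mean reference; undefined when the external response is
  constant), Q²F3 (per-observation variance ratio) and Lin's CCC, plus
  per-set RMSEs.  Whether reference "predicted" values in validation tables
  are fitted or cross-validated values is often ambiguous in the
  literature, so reports carry both Q²LOO routes.

## Screening cascade

Stages run in the fixed order input → Lipinski → descriptors → consensus →
substructure → docking merge → rank.  Design choices:

* Lipinski comparisons are strict (<) as published: HBD < 5, HBA < 10,
  MW < 500 Da, AlogP < 5, with donors = N/O heteroatoms bearing ≥ 1 H
  (counted once each) and acceptors = all N and O.  Failures list every
  violated rule.
* The consensus rule requires all four predictions strictly above the
  threshold (default pIC50 7.0); molecules with any missing descriptor are
  excluded with a per-descriptor reason, never silently zero-filled or
  passed.  A per-model-count variant can be emulated by passing a model
  subset.
* The scaffold query defaults to the fused pyrazolo[1,5-a]pyrimidine
  bicycle (`c1cnc2ccnn2c1`); the exact fusion isomer is a configuration
  entry, not hard-coded.
* The published workflow ranks "considering simultaneously" the four
  predictions without defining the aggregate; three explicit modes are
  provided (worst-of-four, mean-of-four, docking-then-QSAR), defaulting to
  worst-of-four as the most conservative.  Ties break lexicographically on
  molecule id, making the output a deterministic total order.
* Docking scores are ingested from CSV (id, score; more negative = better)
  — docking itself is out of scope.

## Trajectory analysis

* A hydrogen bond exists in a frame iff donor–acceptor distance < 3.5 Å
  (0.35 nm) and the D–H···A angle measured at the hydrogen > 120°.  The
  published criterion names the angle ambiguously; the at-hydrogen
  convention is standard and the vertex is configurable.  Occupancy is the
  fraction of frames where both hold; distance/angle means are emitted both
  over occupied frames and over all frames, since reference tables rarely
  say which they report.
* RMSD superposes each frame onto the reference (Kabsch, via MDAnalysis)
  before the deviation is computed, so rigid motion contributes zero.
* Cluster representatives use seeded PAM-style k-medoids on the pairwise
  superposed-RMSD matrix (the original clustering tool's parameters are
  unpublished; k is user-supplied).  The representative of each cluster is
  its medoid — identically the member with the lowest RMSD to the cluster
  center.  Empty clusters are re-seeded with the frame farthest from all
  current medoids; medoid ties break on the lowest frame index.

## Synthetic data

The generators define the conditions under which the pipeline is tested:

* **Libraries** are assembled from a curated fragment grammar (single
  substituents from a ~30-entry list on a scaffold core and 8 decoy cores)
  rather than random SMILES, guaranteeing parseability.  Default 200
  molecules with 20% scaffold-containing and 20% single-rule Lipinski
  violators; violators are fixed designs (sugar polyols for HBD,
  polyethylene-glycol ethers for HBA, triiodinated benzamides for MW,
  long-chain alkylbenzenes for AlogP) asserted at generation time to
  violate exactly their planted rule.  The truth table records scaffold
  membership, Lipinski outcome, descriptor computability and consensus
  outcome per molecule, making every cascade stage count predictable
  exactly.
* **QSAR matrices** have i.i.d. standard-normal columns and a response that
  is linear in 3 of 53 columns (coefficient magnitudes 1–2, random signs)
  plus Gaussian noise of σ = 0.3 pIC50 units — the training-RMSE scale the
  published models report.  Training/external sizes default to 60/20.
* **Trajectories** contain one donor–H–acceptor triplet; occupied frames
  place the acceptor at 2.9 Å near-linear, unoccupied frames at 4.2 Å —
  at least 0.5 Å beyond the cutoff — with 0.02 Å Gaussian jitter, so the
  per-frame boolean is immune to floating-point noise and the constructed
  occupancy is exact by construction.

What passing tests on these fixtures do *not* show: behaviour on real
vendor libraries (tautomers, salts, charged species at pH 7), descriptor
parity with any specific commercial implementation, realistic protein
dynamics, or chemistry outside the property table's element set
(H, B, C, N, O, F, Al, Si, P, S, Cl, Fe–Zn, Br, Sn, I).

## Problem sizes

Default test and reproduction runs use a 200-molecule library, 60/20
QSAR splits with 20 GA replicates, and 200-frame trajectories — sizes at
which every stochastic check is stable while the whole suite completes in
a few minutes on one core.

## Known limitations

* Protonation/tautomer enumeration is not implemented; molecules are used
  as supplied (largest fragment only).
* The Moriguchi HB/POL/AMP dummies are SMARTS approximations of prose
  definitions; MLOGP values are internally consistent but not
  reference-exact.
* Trajectory input is multi-model PDB and XYZ only; binary MD formats are
  intentionally unsupported.
* Descriptors requiring topological lags beyond a molecule's diameter
  (GATS7v, R8u+) are undefined for small molecules; the cascade excludes
  such molecules explicitly rather than imputing values, which makes the
  four-equation consensus effectively a size floor as well.
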
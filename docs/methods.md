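# Methods

`rinnet` builds residue interaction networks (RINs) from atomic coordinates
and analyses how those networks change across the states of a structural
ensemble (NMR-style multi-model files or MD snapshots stored as multi-model
PDB/mmCIF). This note records the models, the numerical choices, and what
the synthetic test data does and does not establish.

## Interaction model

Non-covalent contacts are inferred by geometric rules, not energies. Each
rule family has a distance gate and, where physically meaningful, an angle
gate; all thresholds live in `GeometricCriteria` and are configuration, with
the following defaults (chosen to mirror common geometric-rule practice in
the RIN literature; none is claimed to reproduce any specific tool):

| type | rule | default |
|---|---|---|
| HBOND | donor heavy atom D to acceptor A, d(D,A) ≤ `hbond_max_da`; angle at the donor ≥ `hbond_min_angle` | 3.5 Å, 90° |
| IONIC | anionic-group centroid to cationic-group centroid ≤ `ionic_max_dist` | 4.0 Å |
| PIPISTACK | ring centroids ≤ `pipi_max_centroid`; inter-plane angle folded to [0°, 90°] ≤ `pipi_max_planar_angle` (parallel) or ≥ 90° − it (T-shaped) | 6.5 Å, 30° |
| PICATION | cation centroid to ring centroid ≤ `pication_max_dist`, within `pication_max_angle` of the ring normal | 5.0 Å, 45° |
| VDW | heavy atoms, d ≤ r₁ + r₂ + `vdw_slack` (Bondi radii), unless the pair already has an HBOND/IONIC edge | 0.5 Å |
| SSBOND | Cys SG–SG ≤ `ssbond_max_ss` | 2.5 Å |

Hydrogen-bond angles use the antecedent heavy atom (angle antecedent—D—A)
when no hydrogen is present, and the best D—H—A angle over hydrogens within
1.3 Å of the donor otherwise; X-ray files therefore never need protons.
Each donor keeps only its closest admissible acceptor, and per residue pair
and type only the smallest-distance instance survives (a `keep_multiple`
flag disables the reduction). Residue pairs closer in sequence than
`min_seq_separation` (default 2) on the same chain are never candidates;
disulfides are exempt because they are covalent.

Chemistry is table-driven (`rinnet.chemistry`): the 20 amino acids plus
RNA/DNA nucleotides, where bases contribute aromatic rings and base N/O
donors/acceptors, phosphates contribute anionic groups, and sugar atoms
participate only in van der Waals contacts. Histidine is aromatic by
default and cationic only behind a flag, since protonation is unknowable
without hydrogens. Terminal charges are included where detectable: a
C-terminal carboxylate when OXT is present, and the backbone N of each
chain's first residue as a terminal amine (N-terminality cannot be read
from atom content alone in hydrogen-less files, so chain position is used).
Unknown residue names are logged and contribute only vdW contacts.

Candidate generation uses a uniform cell list (cell edge = cutoff), giving
expected linear cost; correctness is guaranteed by test equivalence with an
O(n²) scan, and every detector is tested for exact agreement with an
independent exhaustive implementation of its written rule on random decoy
states (see below).

## Ensemble statistics

Networks are detected independently per state. From them:

* **Edge frequency** — count / n_states per distinct (residue pair, type).
* **Contact probability map** — P[i, j] = fraction of states where residues
  i, j share at least one in-scope edge; symmetric, zero diagonal.
* **Contact-count matrix** — C[i, s] = number of in-scope edges incident to
  residue i in state s (column sums are twice the state's edge count).
* **Contact correlation** — Pearson r of C's rows across states, for every
  position pair. Counts are used (a binary-presence mode exists behind a
  flag). Pairs where either row has zero variance — stable contacts — are
  flagged `defined=False` rather than reported as 0, because a silent zero
  would be read as "uncorrelated" when the data carry no information at
  all. Fewer than 3 states leaves everything undefined. No p-values or
  multiple-testing correction are computed; the statistic reported is r.
* **Presence series** — per-edge 0/1 trajectory over states, unsmoothed,
  as the time-dependent form of the network.

## Clustering

The all-versus-all RMSD matrix superposes each *pair* of states
independently (Kabsch, closed-form SVD, proper rotations only) over the
atoms common to all states from the selection (default CA for amino acids
plus C1' for nucleotides — coarse backbone anchors covering both polymer
classes). Pairwise-optimal superposition is the default because it is
reference-free and gives the tightest possible entries; a reference-based
mode (all states aligned to one reference first) is available and always
bounds the pairwise values from above.

Agglomerative clustering (scipy linkage; average default, complete and
single exposed — average because it is robust for RMSD matrices that mix
tight basins with outliers) produces a dendrogram whose merge heights are
in Å. The flat cut joins merges with height strictly below the cutoff and
splits at height ≥ cutoff; either convention is defensible, but one must be
fixed and documented for reproducibility, and the strict one makes "cut at
a merge height" split that merge. Cluster ids are 1-based in order of first
occurrence along the time axis. Representatives are medoids (the member
minimizing summed RMSD to its cluster, ties to the lowest state index) —
medoids rather than centroids because the representative must be an actual
conformation that can be written out as a structure file.

Dendrograms export as Newick with branch length = parent merge height −
child merge height, so every leaf sits at depth equal to the root height.

## Structure I/O conventions

gemmi parses PDB and mmCIF (model number → state index). Author residue
numbering is kept untouched, matching what users see in viewers. Waters
are dropped by default (flag to retain); HETATM residues stay with
`polymer_class="other"` so ions remain available to the charged-group
rules. For alternate locations the highest-occupancy conformer is kept,
ties broken by alphabetically first altloc, so each state holds one
consistent conformer. All states of one file must share the residue
sequence; the first differing residue is reported otherwise. PDB output is
fixed-width, so coordinate round trips are exact to 10⁻³ Å; mmCIF round
trips are exact to ~10⁻⁹.

## Synthetic data: what it emulates and what it does not

All test inputs are generated, none downloaded:

* **Ideal α-helix** (backbone N/CA/C/O from internal coordinates,
  φ = −63°, ψ = −43°, ω = 180°; 1.5 Å rise, ~100°/turn). The (i, i+4)
  N–O distances are 3.04 Å, inside the hydrogen-bond window and closer
  than any competing acceptor, so the full ladder is guaranteed.
* **Minimal interacting pairs** (salt bridge, stacked rings, π–cation,
  backbone H-bond) placed at 0.85× the *active* cutoff when "on" and
  2.2× when "off", so the suite stays valid under non-default criteria.
* **Scripted-contact ensembles**: isolated interaction units 60 Å apart,
  switched on/off per state by an explicit script — exact ground truth for
  frequencies, maps and correlations.
* **Two-basin ensembles**: a CA trace and a hinge-bent variant whose
  mutual RMSD is solved to the requested separation, plus iid Gaussian
  coordinate noise per state. Default study conditions for recovery runs:
  12 states, 6 Å separation, 0.3 Å noise (separation/noise = 20), cut at
  3 Å.
* **Random decoy states**: 200 pseudo-residues with standard atom names at
  random coordinates in a 35 Å box — intentionally unphysical, to force
  every rule branch against the exhaustive oracle.

Passing on these shows the *rules are implemented exactly as written* and
that the ensemble statistics recover known dynamics. It does not show that
the default thresholds are optimal for real proteins, nor does any fixture
reproduce real side-chain geometry, rotamers, solvent, or physically
realistic MD — conclusions about real systems inherit the usual caveats of
geometric-rule contact detection.

## Numerical choices and degenerate inputs

Plane fitting uses the smallest-singular-vector normal with a
deterministic sign (positive z component, ties toward +x then +y); π
angles are folded to [0°, 90°], making the sign immaterial. Collinear
rings raise a geometry error and degenerate rings found during detection
are silently skipped as candidates. Kabsch enforces det(R) = +1, so
mirrored inputs never yield a reflection. Ties in the per-pair best-edge
reduction break on atom names; cluster medoid ties break on the lowest
state index; scipy's deterministic linkage handles exactly-equal merge
heights. Empty selections, single-state ensembles passed to multi-state
analyses, non-symmetric RMSD matrices, and invalid frequency windows all
raise explicit errors rather than degrading silently.

## Problem sizes used by the checks

The bundled verification runs use 50 random 200-residue decoy states for
detector–oracle equivalence, 100-seed batches of 100-state scripted
ensembles for the statistics recovery, 100-seed batches of 12-state
two-basin ensembles for clustering recovery, and n = 1000 points for the
neighbor-search equivalence — sizes at which every check is exact rather
than asymptotic, while the whole suite stays fast on a single CPU.

## Known limitations

No interaction energies, halogen or metal-coordination bonds, protonation
prediction, assemblies/symmetry expansion, or binary trajectory formats
(MD input is a multi-model coordinate file). Correlation significance is
out of scope. The CLI's plots are conveniences; the TSV/Newick/PDB outputs
are the contract.
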